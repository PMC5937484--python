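"""Configuration objects: marker definitions, simulation and pipeline settings.

Two markers are supported out of the box, matching the two universal
eukaryotic barcodes the pipeline targets:

* ``COI`` — the ~313-bp "Leray fragment" of mitochondrial cytochrome c
  oxidase I, amplified with the highly degenerate Leray-XT primer set
  (forward mlCOIintF-XT with extra degenerate bases and two inosines,
  reverse jgHCO2198).
* ``18S`` — the ~110-bp V7 region of the nuclear SSU rRNA, amplified with
  the 18S_allshorts primers.

Marker policies differ deliberately: singletons are removed before
clustering for 18S but kept for COI (where they are mostly one-off point
variants absorbed by their MOTU), low-abundance MOTUs (<5 reads) are pruned
after clustering for COI, and same-species MOTU merging is applied to COI
only (identical 18S sequences routinely collapse distinct species).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

from .taxonomy import DEFAULT_RANKS

# Leray-XT set for COI (forward mlCOIintF-XT, reverse jgHCO2198)
COI_FWD_PRIMER = "GGWACWRGWTGRACWITITAYCCYCC"
COI_REV_PRIMER = "TAIACYTCIGGRTGICCRAARAAYCA"
# original Leray forward (mlCOIintF); every position of the XT forward is a
# degeneracy superset of this one, so the XT set can only amplify more
COI_FWD_PRIMER_ORIGINAL = "GGWACWGGWTGAACWGTWTAYCCYCC"
# 18S_allshorts set for the V7 region of 18S
S18_FWD_PRIMER = "TTTGTCTGSTTAATTSCG"
S18_REV_PRIMER = "TCACAGACCTGTTATTGC"


@dataclass(frozen=True)
class Marker:
    """Per-marker amplicon geometry and curation policy."""

    name: str
    fwd_primer: str
    rev_primer: str
    length_range: tuple[int, int]       # closed interval for the insert
    cluster_identity: float             # greedy clustering threshold
    remove_singletons: bool             # drop total==1 uniques before clustering
    min_motu_reads: int                 # post-clustering MOTU prune (0 = off)
    merge_same_species: bool            # collapse MOTUs assigned to one species
    crop_l: float                       # CROP parameters recorded for provenance
    crop_u: float                       # (the Bayesian clusterer is not run here)
    read_len: int                       # simulated sequencing read length
    typical_insert_len: int


MARKERS: dict[str, Marker] = {
    "COI": Marker(
        name="COI",
        fwd_primer=COI_FWD_PRIMER,
        rev_primer=COI_REV_PRIMER,
        length_range=(300, 320),
        cluster_identity=0.97,
        remove_singletons=False,
        min_motu_reads=5,
        merge_same_species=True,
        crop_l=1.5,
        crop_u=2.5,
        read_len=300,
        typical_insert_len=313,
    ),
    "18S": Marker(
        name="18S",
        fwd_primer=S18_FWD_PRIMER,
        rev_primer=S18_REV_PRIMER,
        length_range=(75, 180),
        cluster_identity=0.99,
        remove_singletons=True,
        min_motu_reads=0,
        merge_same_species=False,
        crop_l=0.3,
        crop_u=0.5,
        read_len=150,
        typical_insert_len=110,
    ),
}


class ConfigError(ValueError):
    pass


def get_marker(name: str) -> Marker:
    try:
        return MARKERS[name]
    except KeyError:
        raise ConfigError(f"unknown marker {name!r}; known: {sorted(MARKERS)}") from None


@dataclass
class SimConfig:
    """Settings for the synthetic community / amplicon-read generator.

    Defaults emulate the study design the pipeline was built around: eight
    benthic communities split between two sites, each sieved into three size
    fractions (A: >10 mm, B: 1-10 mm, C: 63 um-1 mm) with three replicate
    samples, plus two control samples (PCR blanks) carrying only low-level
    contamination (~65 reads).
    """

    n_species: int = 100
    ranks: tuple[str, ...] = DEFAULT_RANKS
    marker: str = "COI"
    amplicon_len_range: tuple[int, int] = (308, 318)
    n_communities: int = 8
    fractions: tuple[str, ...] = ("A", "B", "C")
    n_replicates: int = 3
    n_blanks: int = 2
    n_technical_replicates: int = 0
    reads_per_sample: int = 20_000
    # between-species abundance scale within a community
    abundance_lognormal_mu: float = 0.0
    abundance_lognormal_sigma: float = 1.0
    # within-species structure: abundance variation between the communities a
    # species occupies, between replicate samples, and across size fractions
    community_sigma: float = 0.5
    replicate_sigma: float = 0.25
    fraction_dirichlet_alpha: float = 3.0
    community_share_prob: float = 0.25  # chance of occupying each extra community
    per_base_error_rate: float = 0.001
    chimera_rate: float = 0.01
    tag_switch_rate: float = 0.01
    blank_contam_reads: int = 65
    n_contaminant_species: int = 1      # species seen mainly in blanks/controls
    contaminant_rate_in_samples: float = 1e-4
    n_prokaryote_species: int = 0       # of n_species, placed under Bacteria
    branch_sub_rate: float = 0.05       # per-site substitution probability per tree edge
    intraspecific_variants: int = 2
    intraspecific_sub_rate: float = 0.002
    qual_profile: str = "constant"      # "constant" | "decay"
    base_quality: int = 37
    seed: int = 1

    @property
    def n_samples(self) -> int:
        return self.n_communities * len(self.fractions) * self.n_replicates

    def validate(self) -> None:
        if self.n_species < 2:
            raise ConfigError("n_species must be >= 2")
        if self.n_prokaryote_species >= self.n_species:
            raise ConfigError("n_prokaryote_species must be < n_species")
        for name in ("per_base_error_rate", "chimera_rate", "tag_switch_rate",
                     "community_share_prob", "branch_sub_rate",
                     "intraspecific_sub_rate", "contaminant_rate_in_samples"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.marker not in MARKERS:
            raise ConfigError(f"unknown marker {self.marker!r}")
        lo, hi = self.amplicon_len_range
        if not (0 < lo <= hi):
            raise ConfigError("invalid amplicon_len_range")
        if self.qual_profile not in ("constant", "decay"):
            raise ConfigError("qual_profile must be 'constant' or 'decay'")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data: dict[str, Any] = yaml.safe_load(fh) or {}
        for key in ("ranks", "fractions", "amplicon_len_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class PipelineConfig:
    """Thresholds for read preparation, clustering, and table curation."""

    # read preparation
    trim_quality: int = 30
    min_merge_score: float = 40.0
    min_overlap: int = 10
    max_overlap_mismatch_frac: float = 0.25
    max_primer_mismatch: int = 2
    # curation chain
    blank_fraction: float = 0.10
    renorm_cum_fraction: float = 0.03
    min_rel_abundance: float = 0.0001
    min_sample_reads: int = 10_000
    # diversity
    rarefaction_depth: int = 19_000
    # in-silico PCR
    max_pcr_mismatch: int = 2

    def validate(self) -> None:
        for name in ("blank_fraction", "renorm_cum_fraction", "min_rel_abundance",
                     "max_overlap_mismatch_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        for name in ("min_sample_reads", "rarefaction_depth"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
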