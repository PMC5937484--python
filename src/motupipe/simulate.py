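"""Synthetic communities, references, and tagged paired-end amplicon reads.

The generator emulates the study design the pipeline targets: several benthic
communities split between two sites, each sieved into three size fractions
(A coarse, B intermediate, C fine) with replicate samples, sequenced as one
tag-multiplexed library per marker, plus control samples (blanks) carrying
only trace contamination.

Every stochastic stage is driven by a single integer seed, so two runs with
equal configuration are byte-identical.  Every emitted read pair carries a
ground-truth record (true sample, observed sample, source species, chimera /
tag-switch / contamination flags), which is what makes each downstream
pipeline stage independently verifiable without any external dataset.

Model choices, deliberately minimal:

* sequence evolution is per-site independent substitution (Jukes-Cantor
  style uniform replacement) along the simulated taxonomy, which is enough
  to create the similarity gradient that clustering and LCA assignment need;
* chimeras are two-parent single-breakpoint crossovers between templates of
  the same sample, the signature de-novo chimera detection assumes;
* tag switching moves the full identical-tag pair to another sample of the
  same marker, the residual artefact left once mismatched tag pairs have
  been rejected;
* sequencing error is substitution-only, with constant high base quality or
  an optional decaying 3' tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, IUPAC_SETS, phred_to_ascii, revcomp
from .config import ConfigError, SimConfig, get_marker
from .refdb import RefRecord
from .samples import SampleSheet, SampleSheetEntry
from .taxonomy import TaxNode, TaxonomyTree

ECOLOGICAL_CATEGORIES = (
    "macroscopic seaweeds", "modular metazoa", "macrofaunal unitary metazoa",
    "meiofaunal metazoa", "microorganisms",
)


@dataclass
class SimTruth:
    """Ground truth for one simulated library.

    ``reads`` has one row per emitted read pair (read_id, true_sample_id,
    observed_sample_id, true_species_taxid, is_chimera, is_tag_switched,
    is_contamination); ``abundance`` holds the per-species per-sample
    template weights the reads were drawn from.
    """

    reads: pd.DataFrame
    abundance: pd.DataFrame  # columns: species_taxid, sample_id, weight

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
        self.abundance.to_csv(outdir / "truth_abundance.tsv", sep="\t", index=False)


@dataclass
class SimulationResult:
    cfg: SimConfig
    tree: TaxonomyTree
    refs: list[RefRecord]
    samplesheet: SampleSheet
    reads: list[tuple[str, str, str, str, str]]  # id, seq1, qual1, seq2, qual2
    truth: SimTruth
    species_taxids: list[int]
    phylum_categories: dict[int, str]  # phylum taxid -> ecological category


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per stage
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def simulate_taxonomy(cfg: SimConfig) -> TaxonomyTree:
    """Random rooted taxonomy with one node per rank on every root-leaf path.

    The root sits above the first configured rank; eukaryotic species hang
    under an "Eukaryota" superkingdom and, if requested, prokaryotic species
    under a parallel "Bacteria" superkingdom (so that non-target removal has
    something to remove).  Exactly ``cfg.n_species`` leaves carry the last
    rank.
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    ranks = list(cfg.ranks)
    nodes: list[TaxNode] = [TaxNode(1, 1, "root", "root")]
    next_id = 2

    def build_subtree(top_name: str, n_leaves: int, leaf_offset: int) -> None:
        nonlocal next_id
        depth = len(ranks)
        # geometric interpolation of level sizes from 1 down to n_leaves
        sizes = []
        for lev in range(depth):
            frac = lev / max(depth - 1, 1)
            sizes.append(max(1, min(n_leaves, round(n_leaves ** frac))))
        sizes[-1] = n_leaves
        prev_ids: list[int] = []
        for lev, rank in enumerate(ranks):
            n = sizes[lev]
            ids = list(range(next_id, next_id + n))
            next_id += n
            if lev == 0:
                parents = [1] * n
                names = [top_name] * n
            else:
                # every parent keeps at least one child; the rest attach randomly
                parents = list(prev_ids)[:n]
                extra = n - len(parents)
                if extra > 0:
                    parents += list(rng.choice(prev_ids, size=extra, replace=True))
                rng.shuffle(parents)
                if rank == "species":
                    names = [f"{top_name}_sp_{leaf_offset + i + 1}" for i in range(n)]
                else:
                    names = [f"{top_name}_{rank}_{i + 1}" for i in range(n)]
            for tid, par, name in zip(ids, parents, names):
                nodes.append(TaxNode(tid, par, rank, name))
            prev_ids = ids

    n_prok = cfg.n_prokaryote_species
    n_euk = cfg.n_species - n_prok
    if n_euk < 1:
        raise ConfigError("need at least one eukaryotic species")
    build_subtree("Eukaryota", n_euk, 0)
    if n_prok:
        build_subtree("Bacteria", n_prok, n_euk)
    return TaxonomyTree(nodes)


# ---------------------------------------------------------------------------
# reference sequences
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution with uniform replacement by one of the other bases."""
    if rate <= 0:
        return seq.copy()
    hit = rng.random(seq.size) < rate
    n = int(hit.sum())
    if n == 0:
        return seq.copy()
    out = seq.copy()
    # shift by 1..3 mod 4 guarantees a different base
    out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out


def _codes_to_str(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)


class _PrimerConcretizer:
    """Draws concrete primer molecules from a degenerate primer sequence."""

    def __init__(self, primer_seq: str):
        self.template = list(primer_seq.upper())
        self.var_pos: list[int] = []
        self.var_opts: list[str] = []
        for i, c in enumerate(self.template):
            allowed = sorted(IUPAC_SETS[c])
            if len(allowed) == 1:
                self.template[i] = allowed[0]
            else:
                self.var_pos.append(i)
                self.var_opts.append("".join(allowed))

    def draw(self, rng: np.random.Generator) -> str:
        out = self.template.copy()
        if self.var_pos:
            picks = rng.random(len(self.var_pos))
            for k, (i, opts) in enumerate(zip(self.var_pos, self.var_opts)):
                out[i] = opts[int(picks[k] * len(opts))]
        return "".join(out)


def concretize_primer(primer_seq: str, rng: np.random.Generator) -> str:
    """Replace each degenerate/inosine position by one base from its set."""
    return _PrimerConcretizer(primer_seq).draw(rng)


def simulate_references(tree: TaxonomyTree, cfg: SimConfig) -> list[RefRecord]:
    """Evolve a root sequence down the taxonomy; one or more records per species.

    Each record's sequence is primer-binding site + insert + reverse
    complement of the reverse binding site, so the references are directly
    usable for in-silico PCR.  Intraspecific variants add a thin cloud of
    near-identical sequences around each species, which gives the reference
    database realistic density for LCA assignment.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    marker = get_marker(cfg.marker)
    lo, hi = cfg.amplicon_len_range
    length = int(rng.integers(lo, hi + 1))
    root_seq = rng.integers(0, 4, size=length)

    # binding sites: one concretization shared by all references (conserved sites)
    fwd_site = concretize_primer(marker.fwd_primer, rng)
    rev_site_rc = revcomp(concretize_primer(marker.rev_primer, rng))

    seqs: dict[int, np.ndarray] = {tree.root: root_seq}
    # children listing for top-down traversal
    children: dict[int, list[int]] = {}
    for t, n in tree.nodes.items():
        if n.parent != t:
            children.setdefault(n.parent, []).append(t)
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for child in sorted(children.get(node, ())):
            seqs[child] = _mutate(seqs[node], cfg.branch_sub_rate, rng)
            stack.append(child)

    records: list[RefRecord] = []
    for leaf in tree.leaves(rank="species"):
        base = seqs[leaf]
        for v in range(max(1, cfg.intraspecific_variants)):
            var = base if v == 0 else _mutate(base, cfg.intraspecific_sub_rate, rng)
            insert = _codes_to_str(var)
            records.append(RefRecord(
                record_id=f"taxid{leaf}_v{v}",
                seq=fwd_site + insert + rev_site_rc,
                taxid=leaf,
                source="simulated",
            ))
    return records


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def make_samplesheet(cfg: SimConfig) -> SampleSheet:
    """Sample sheet mirroring the study design: site / community / fraction /
    replicate factors, unique random 8-nt tags, shared marker primers."""
    cfg.validate()
    rng = _rng(cfg, 2)
    marker = get_marker(cfg.marker)
    tags: set[str] = set()

    def new_tag() -> str:
        while True:
            t = _codes_to_str(rng.integers(0, 4, size=8))
            if t not in tags:
                tags.add(t)
                return t

    entries: list[SampleSheetEntry] = []
    half = math.ceil(cfg.n_communities / 2)
    for c in range(cfg.n_communities):
        site = "Atlantic" if c < half else "Mediterranean"
        for f in cfg.fractions:
            for r in range(1, cfg.n_replicates + 1):
                entries.append(SampleSheetEntry(
                    sample_id=f"c{c + 1:02d}_{f}_r{r}",
                    marker=cfg.marker, tag=new_tag(),
                    fwd_primer=marker.fwd_primer, rev_primer=marker.rev_primer,
                    site=site, community=f"community_{c + 1:02d}",
                    fraction=f, replicate=str(r), is_control=False,
                ))
    for t in range(1, cfg.n_technical_replicates + 1):
        entries.append(SampleSheetEntry(
            sample_id=f"tech_r{t}", marker=cfg.marker, tag=new_tag(),
            fwd_primer=marker.fwd_primer, rev_primer=marker.rev_primer,
            site="Atlantic", community="community_01",
            fraction=cfg.fractions[0], replicate=f"tech{t}", is_control=False,
        ))
    for b in range(1, cfg.n_blanks + 1):
        entries.append(SampleSheetEntry(
            sample_id=f"blank_{b}", marker=cfg.marker, tag=new_tag(),
            fwd_primer=marker.fwd_primer, rev_primer=marker.rev_primer,
            site="", community="", fraction="", replicate="",
            is_control=True,
        ))
    return SampleSheet(entries)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _quality_string(length: int, cfg: SimConfig) -> str:
    q = np.full(length, cfg.base_quality, dtype=np.int64)
    if cfg.qual_profile == "decay":
        tail = min(50, length)
        ramp = np.linspace(cfg.base_quality, 2, tail).round().astype(np.int64)
        q[length - tail:] = ramp
    return phred_to_ascii(q)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    pos = rng.choice(len(seq), size=n, replace=False)
    chars = list(seq)
    for p in pos:
        cur = chars[p]
        opts = [b for b in BASES if b != cur]
        chars[p] = opts[int(rng.integers(3))]
    return "".join(chars)


def _community_weights(cfg: SimConfig, species_taxids: Sequence[int],
                       contaminants: set[int], prokaryotes: set[int],
                       sheet: SampleSheet,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Per-species per-sample template weights.

    Each non-contaminant species occupies one home community plus each other
    community with probability ``community_share_prob``; within an occupied
    community its abundance is a between-species lognormal scale times a
    community-level factor, a Dirichlet fraction-affinity profile, and
    replicate-level jitter.  Contaminants get a uniform trace rate in every
    real sample (their main source is the blanks).
    """
    communities = sorted({e.community for e in sheet if not e.is_control and
                          not e.replicate.startswith("tech")})
    rows = []
    real = [e for e in sheet if not e.is_control]
    frac_index = {f: i for i, f in enumerate(cfg.fractions)}
    for sp in species_taxids:
        if sp in contaminants:
            for e in real:
                rows.append((sp, e.sample_id, cfg.contaminant_rate_in_samples))
            continue
        occupied = {communities[int(rng.integers(len(communities)))]}
        for c in communities:
            if c not in occupied and rng.random() < cfg.community_share_prob:
                occupied.add(c)
        scale = float(rng.lognormal(cfg.abundance_lognormal_mu,
                                    cfg.abundance_lognormal_sigma))
        comm_factor = {c: float(rng.lognormal(0.0, cfg.community_sigma))
                       for c in sorted(occupied)}
        alpha = [cfg.fraction_dirichlet_alpha] * len(cfg.fractions)
        frac_w = rng.dirichlet(alpha)
        for e in real:
            if e.community not in occupied:
                continue
            jitter = float(rng.lognormal(0.0, cfg.replicate_sigma))
            w = scale * comm_factor[e.community] * frac_w[frac_index[e.fraction]] * jitter
            rows.append((sp, e.sample_id, w))
    df = pd.DataFrame(rows, columns=["species_taxid", "sample_id", "weight"])
    # technical replicates share the template pool of the first real sample
    techs = [e.sample_id for e in sheet if e.replicate.startswith("tech")]
    if techs:
        first = real[0].sample_id
        base = df[df.sample_id == first]
        extra = [base.assign(sample_id=t) for t in techs
                 if t != first]
        df = pd.concat([df[~df.sample_id.isin(techs)]] + extra, ignore_index=True)
    return df


def simulate_reads(refs: Sequence[RefRecord], tree: TaxonomyTree,
                   cfg: SimConfig, sheet: SampleSheet
                   ) -> tuple[list[tuple[str, str, str, str, str]], SimTruth]:
    """Emit tagged paired-end reads plus a complete ground-truth table.

    Each read pair derives from one molecule
    ``spacer + tag + fwd-primer + insert + rc(rev-primer) + rc(tag) + rc(spacer)``
    with 2-4 random spacer bases and per-read concretization of degenerate
    primer positions; mate 1 is the molecule's 5' read, mate 2 the 3' read of
    its reverse complement, both with independent substitution errors.
    """
    cfg.validate()
    rng = _rng(cfg, 3)
    marker = get_marker(cfg.marker)
    read_len = marker.read_len

    species_taxids = tree.leaves(rank="species")
    prokaryotes = {t for t in species_taxids
                   if tree.name(t).startswith("Bacteria")}
    # last n_contaminant_species eukaryotic species act as lab contaminants
    euks = [t for t in species_taxids if t not in prokaryotes]
    contaminants = set(euks[len(euks) - cfg.n_contaminant_species:]
                       if cfg.n_contaminant_species else [])

    inserts_by_species: dict[int, list[str]] = {}
    flank_f = len(marker.fwd_primer)
    flank_r = len(marker.rev_primer)
    for rec in refs:
        inserts_by_species.setdefault(rec.taxid, []).append(
            rec.seq[flank_f:len(rec.seq) - flank_r])

    weights = _community_weights(cfg, species_taxids, contaminants,
                                 prokaryotes, sheet, rng)
    wmap: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sid, grp in weights.groupby("sample_id"):
        w = grp.weight.to_numpy(float)
        wmap[sid] = (grp.species_taxid.to_numpy(int), w / w.sum())

    marker_entries = sheet.for_marker(cfg.marker)
    all_sample_ids = [e.sample_id for e in marker_entries]
    tag_of = {e.sample_id: e.tag for e in marker_entries}
    real_ids = [e.sample_id for e in marker_entries if not e.is_control]
    blank_ids = [e.sample_id for e in marker_entries if e.is_control]

    # pooled template distribution feeding blank contamination
    pooled: dict[int, float] = {}
    for sid in real_ids:
        sp, p = wmap[sid]
        for s, q in zip(sp, p):
            pooled[s] = pooled.get(s, 0.0) + q
    pool_taxids = np.array(sorted(pooled), dtype=int)
    pool_p = np.array([pooled[t] for t in pool_taxids], dtype=float)
    # blanks: contaminant species dominate, the rest is pooled carry-over
    if contaminants:
        blank_p = np.where(np.isin(pool_taxids, sorted(contaminants)),
                           pool_p.sum(), pool_p)
    else:
        blank_p = pool_p
    blank_p = blank_p / blank_p.sum()

    reads: list[tuple[str, str, str, str, str]] = []
    truth_rows: list[tuple] = []
    qual_cache: dict[int, str] = {}
    fwd_conc = _PrimerConcretizer(marker.fwd_primer)
    rev_conc = _PrimerConcretizer(marker.rev_primer)
    read_no = 0

    def qual(length: int) -> str:
        if length not in qual_cache:
            qual_cache[length] = _quality_string(length, cfg)
        return qual_cache[length]

    for sid in all_sample_ids:
        is_blank = sid in blank_ids
        n_reads = cfg.blank_contam_reads if is_blank else cfg.reads_per_sample
        if is_blank:
            taxids, probs = pool_taxids, blank_p
        else:
            taxids, probs = wmap[sid]
        if n_reads == 0 or taxids.size == 0:
            continue
        draw = rng.choice(taxids.size, size=n_reads, p=probs)
        chim = rng.random(n_reads) < cfg.chimera_rate
        switch = (rng.random(n_reads) < cfg.tag_switch_rate) if len(all_sample_ids) > 1 \
            else np.zeros(n_reads, bool)
        sp_lens = rng.integers(2, 5, size=(n_reads, 2))
        for i in range(n_reads):
            sp1 = int(taxids[draw[i]])
            variants = inserts_by_species[sp1]
            insert = variants[int(rng.integers(len(variants)))]
            is_chimera = bool(chim[i]) and taxids.size > 1
            if is_chimera:
                j = int(rng.choice(taxids.size, p=probs))
                sp2 = int(taxids[j])
                other = inserts_by_species[sp2][0]
                b = int(rng.integers(1, min(len(insert), len(other))))
                insert = insert[:b] + other[b:]
            obs = sid
            is_switch = bool(switch[i])
            if is_switch:
                others = [s for s in all_sample_ids if s != sid]
                obs = others[int(rng.integers(len(others)))]
            tag = tag_of[obs]
            fwd_p = fwd_conc.draw(rng)
            rev_p = rev_conc.draw(rng)
            spacer5 = _codes_to_str(rng.integers(0, 4, size=int(sp_lens[i, 0])))
            spacer3 = _codes_to_str(rng.integers(0, 4, size=int(sp_lens[i, 1])))
            molecule = (spacer5 + tag + fwd_p + insert + revcomp(rev_p)
                        + revcomp(tag) + revcomp(spacer3))
            r1 = molecule[:read_len]
            r2 = revcomp(molecule)[:read_len]
            r1 = _apply_errors(r1, cfg.per_base_error_rate, rng)
            r2 = _apply_errors(r2, cfg.per_base_error_rate, rng)
            rid = f"read_{read_no:08d}"
            read_no += 1
            reads.append((rid, r1, qual(len(r1)), r2, qual(len(r2))))
            truth_rows.append((rid, sid, obs, sp1, is_chimera, is_switch, is_blank))

    truth = SimTruth(
        reads=pd.DataFrame(truth_rows, columns=[
            "read_id", "true_sample_id", "observed_sample_id",
            "true_species_taxid", "is_chimera", "is_tag_switched",
            "is_contamination"]),
        abundance=weights,
    )
    return reads, truth


def assign_categories(tree: TaxonomyTree, cfg: SimConfig) -> dict[int, str]:
    """Map each phylum node to one ecological size category (round-robin over
    a seeded shuffle), giving the simulator a ready-made category scheme."""
    rng = _rng(cfg, 4)
    phyla = sorted(t for t, n in tree.nodes.items() if n.rank == "phylum")
    cats = list(ECOLOGICAL_CATEGORIES)
    order = list(rng.permutation(len(phyla)))
    out: dict[int, str] = {}
    for k, idx in enumerate(order):
        out[phyla[idx]] = cats[k % len(cats)]
    return out


def simulate_all(cfg: SimConfig) -> SimulationResult:
    """Run taxonomy, references, sample sheet, and read generation in order."""
    tree = simulate_taxonomy(cfg)
    refs = simulate_references(tree, cfg)
    sheet = make_samplesheet(cfg)
    reads, truth = simulate_reads(refs, tree, cfg, sheet)
    return SimulationResult(
        cfg=cfg, tree=tree, refs=refs, samplesheet=sheet, reads=reads,
        truth=truth, species_taxids=tree.leaves(rank="species"),
        phylum_categories=assign_categories(tree, cfg),
    )


def write_fastq_pair(reads: Sequence[tuple[str, str, str, str, str]],
                     path1: str | Path, path2: str | Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rid, s1, q1, s2, q2 in reads:
            f1.write(f"@{rid}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{rid}/2\n{s2}\n+\n{q2}\n")


def write_simulation(result: SimulationResult, outdir: str | Path) -> None:
    """Write FASTQ pair, reference FASTA, taxonomy dump, sample sheet, truth."""
    from .refdb import write_refdb_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fastq_pair(result.reads, outdir / "reads_R1.fastq", outdir / "reads_R2.fastq")
    write_refdb_fasta(result.refs, outdir / "references.fasta")
    result.tree.write_dump(outdir / "taxonomy")
    result.samplesheet.write_tsv(outdir / "samplesheet.tsv")
    result.truth.write(outdir)
    cat = pd.DataFrame(
        [(t, result.tree.name(t), c) for t, c in sorted(result.phylum_categories.items())],
        columns=["phylum_taxid", "phylum", "category"])
    cat.to_csv(outdir / "categories.tsv", sep="\t", index=False)
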