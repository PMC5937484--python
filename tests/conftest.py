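"""Shared fixtures: small seeded simulations and toy taxonomies."""

import numpy as np
import pytest

from motupipe import SimConfig, simulate_all
from motupipe.readprep import ReadPair
from motupipe._seq import ascii_to_phred
from motupipe.taxonomy import TaxNode, TaxonomyTree


def reads_to_pairs(reads):
    return [ReadPair(rid, s1, ascii_to_phred(q1), s2, ascii_to_phred(q2))
            for rid, s1, q1, s2, q2 in reads]


@pytest.fixture(scope="session")
def small_sim():
    """Medium-small COI simulation with all artefact channels switched on."""
    cfg = SimConfig(n_species=25, n_communities=4, n_replicates=2,
                    reads_per_sample=600, n_blanks=2, blank_contam_reads=65,
                    per_base_error_rate=0.001, chimera_rate=0.01,
                    tag_switch_rate=0.01, n_contaminant_species=1, seed=101)
    return simulate_all(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free simulation: no errors, chimeras, switching, or blanks."""
    cfg = SimConfig(n_species=12, n_communities=2, n_replicates=1,
                    reads_per_sample=800, n_blanks=0, n_contaminant_species=0,
                    per_base_error_rate=0.0, chimera_rate=0.0,
                    tag_switch_rate=0.0, seed=77)
    return simulate_all(cfg)


@pytest.fixture()
def toy_tree():
    """Hand-built two-kingdom taxonomy: root -> (Euk, Bac); under Euk one
    phylum/class/... chain splitting into two genera with two species each."""
    nodes = [
        TaxNode(1, 1, "root", "root"),
        TaxNode(2, 1, "superkingdom", "Eukaryota"),
        TaxNode(3, 1, "superkingdom", "Bacteria"),
        TaxNode(4, 2, "kingdom", "Metazoa"),
        TaxNode(5, 4, "phylum", "Annelida"),
        TaxNode(6, 5, "class", "Polychaeta"),
        TaxNode(7, 6, "order", "Phyllodocida"),
        TaxNode(8, 7, "family", "Nereididae"),
        TaxNode(9, 8, "genus", "Nereis"),
        TaxNode(10, 8, "genus", "Platynereis"),
        TaxNode(11, 9, "species", "Nereis_a"),
        TaxNode(12, 9, "species", "Nereis_b"),
        TaxNode(13, 10, "species", "Platynereis_a"),
        TaxNode(14, 3, "kingdom", "Bacteria_k"),
        TaxNode(15, 14, "phylum", "Proteobacteria"),
        TaxNode(16, 15, "class", "Gamma"),
        TaxNode(17, 16, "order", "Vibrionales"),
        TaxNode(18, 17, "family", "Vibrionaceae"),
        TaxNode(19, 18, "genus", "Vibrio"),
        TaxNode(20, 19, "species", "Vibrio_a"),
    ]
    return TaxonomyTree(nodes)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)
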