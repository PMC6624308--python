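import numpy as np
import pytest

from minitax.index import IndexParams, build_index
from minitax.simulate import (
    SimConfig,
    draw_abundances,
    simulate_genomes,
    simulate_reads,
)
from minitax.taxonomy import Taxonomy, TaxonNode


def toy_tree() -> Taxonomy:
    """Hand-built tree: root > family > 2 genera > 3 species (+ a 'no rank')."""
    tax = Taxonomy(root_id=1)
    tax.add_node(TaxonNode(1, 1, "root", "root"))
    tax.add_node(TaxonNode(2, 1, "family", "Fam1"))
    tax.add_node(TaxonNode(3, 2, "genus", "GenA"))
    tax.add_node(TaxonNode(4, 2, "genus", "GenB"))
    tax.add_node(TaxonNode(5, 3, "species", "SpA1"))
    tax.add_node(TaxonNode(6, 3, "species", "SpA2"))
    tax.add_node(TaxonNode(7, 4, "species", "SpB1"))
    tax.add_node(TaxonNode(8, 5, "no rank", "SpA1 subgroup"))
    return tax


@pytest.fixture
def toy_taxonomy() -> Taxonomy:
    tax = toy_tree()
    # g1 -> species with an existing child (synthetic leaf); g2 -> childless
    # species (attached in place); g3/g4 -> shared species (two leaves)
    tax.attach_genomes({"g1": 5, "g2": 6, "g3": 7, "g4": 7})
    tax.validate()
    return tax


def random_tree(rng: np.random.Generator, n_nodes: int) -> Taxonomy:
    """Random rank-respecting tree for property tests."""
    ranks = ["species", "genus", "family", "order", "no rank"]
    tax = Taxonomy(root_id=1)
    tax.add_node(TaxonNode(1, 1, "root", "root"))
    ids = [1]
    for tid in range(2, n_nodes + 2):
        parent = int(rng.choice(ids))
        rank = str(rng.choice(ranks))
        tax.add_node(TaxonNode(tid, parent, rank, f"n{tid}"))
        ids.append(tid)
    return tax


@pytest.fixture(scope="session")
def sim_db():
    """Shared 5-genome synthetic database with reads at accuracy 0.88."""
    cfg = SimConfig(
        n_genomes=5,
        genome_length=50_000,
        divergence=0.10,
        total_bases=1_500_000,
        seed=11,
    )
    contigs, contig_map, genome_taxa, tax = simulate_genomes(cfg)
    abundances = dict(
        zip(sorted(genome_taxa), draw_abundances(cfg, np.random.default_rng(cfg.seed + 13)))
    )
    reads = simulate_reads(contigs, contig_map, abundances, cfg, tax)
    index = build_index(contigs, contig_map, IndexParams())
    return dict(
        config=cfg,
        contigs=contigs,
        contig_map=contig_map,
        genome_taxa=genome_taxa,
        taxonomy=tax,
        abundances=abundances,
        reads=reads,
        index=index,
    )


@pytest.fixture(scope="session")
def sim_mappings(sim_db):
    from minitax.mapping import map_reads

    return map_reads(
        [(r.read_id, r.sequence) for r in sim_db["reads"]], sim_db["index"]
    )
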