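"""Strain-extended NCBI-dialect taxonomy.

The classification database attaches every mappable genome to exactly one
node of the taxonomy. Genomes mapped to a taxon that already carries a
genome, or that has children, get a fresh synthetic *strain* leaf inserted
beneath that taxon; genomes mapped to a childless, genome-free node are
attached in place (for those, strain- and species-level resolution are
synonymous). Taxon ID 0 is a sentinel meaning "unassigned" and never
appears as a tree node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

#: Named ranks in increasing order of breadth. ``to_level`` only projects to
#: these; intermediate "no rank" nodes are walked through.
RANKS = (
    "strain",
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "superkingdom",
    "root",
)

#: First taxon ID handed out to synthetic strain leaves (reserved high range).
SYNTHETIC_ID_BASE = 1_000_000_000

UNASSIGNED = 0


class TaxonomyError(ValueError):
    pass


@dataclass
class TaxonNode:
    taxon_id: int
    parent_id: int
    rank: str
    name: str
    genome_id: Optional[str] = None


@dataclass
class Assignment:
    """Final taxonomic call for one read (taxon_id 0 = unassigned)."""

    read_id: str
    taxon_id: int
    genome_id: Optional[str] = None
    read_length: int = 0


@dataclass
class Taxonomy:
    nodes: dict[int, TaxonNode] = field(default_factory=dict)
    root_id: int = 1
    #: genome_id -> taxon_id of the node the genome is attached to
    genome_nodes: dict[str, int] = field(default_factory=dict)
    #: synthetic strain leaves inserted at load time: (taxon_id, parent_id, genome_id)
    synthetic_nodes: list[tuple[int, int, str]] = field(default_factory=list)

    # -- construction -----------------------------------------------------

    def add_node(self, node: TaxonNode) -> None:
        if node.taxon_id == UNASSIGNED:
            raise TaxonomyError("taxon_id 0 is reserved for 'unassigned'")
        if node.taxon_id in self.nodes:
            raise TaxonomyError(f"duplicate taxon_id {node.taxon_id}")
        self.nodes[node.taxon_id] = node

    def validate(self) -> None:
        for tid, node in self.nodes.items():
            if tid == self.root_id:
                continue
            if node.parent_id not in self.nodes:
                raise TaxonomyError(
                    f"node {tid} has missing parent {node.parent_id}"
                )
        # cycle check: every node must reach the root
        for tid in self.nodes:
            seen = set()
            cur = tid
            while cur != self.root_id:
                if cur in seen:
                    raise TaxonomyError(f"cycle involving taxon {tid}")
                seen.add(cur)
                cur = self.nodes[cur].parent_id
        children = self.children_map()
        for genome, tid in self.genome_nodes.items():
            if children.get(tid):
                raise TaxonomyError(
                    f"genome {genome} attached to internal node {tid}"
                )

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {tid: [] for tid in self.nodes}
        for tid, node in self.nodes.items():
            if tid != self.root_id:
                out[node.parent_id].append(tid)
        return out

    def attach_genomes(self, genome_map: dict[str, int]) -> None:
        """Attach genomes, inserting synthetic strain leaves where needed.

        A genome whose target taxon is childless and genome-free is attached
        in place; otherwise (the taxon has children, carries a genome, or
        several genomes map to it) each genome gets a fresh synthetic strain
        leaf, so genome-bearing nodes are always leaves.
        """
        children = self.children_map()
        next_id = SYNTHETIC_ID_BASE + len(self.synthetic_nodes)
        by_taxon: dict[int, list[str]] = {}
        for genome in sorted(genome_map):
            tid = genome_map[genome]
            if tid not in self.nodes:
                raise TaxonomyError(f"genome {genome} mapped to unknown taxon {tid}")
            by_taxon.setdefault(tid, []).append(genome)

        def insert_leaf(tid: int, genome: str) -> None:
            nonlocal next_id
            node = self.nodes[tid]
            leaf = TaxonNode(
                taxon_id=next_id,
                parent_id=tid,
                rank="strain",
                name=f"{node.name} strain {genome}",
                genome_id=genome,
            )
            self.add_node(leaf)
            children.setdefault(tid, []).append(next_id)
            children[next_id] = []
            self.synthetic_nodes.append((next_id, tid, genome))
            self.genome_nodes[genome] = next_id
            next_id += 1

        for tid in sorted(by_taxon):
            genomes = by_taxon[tid]
            node = self.nodes[tid]
            direct_ok = (
                not children.get(tid)
                and node.genome_id is None
                and len(genomes) == 1
            )
            if direct_ok:
                node.genome_id = genomes[0]
                self.genome_nodes[genomes[0]] = tid
                continue
            if node.genome_id is not None:
                # relocate a previously in-place genome to its own leaf
                prev = node.genome_id
                node.genome_id = None
                del self.genome_nodes[prev]
                insert_leaf(tid, prev)
            for genome in genomes:
                insert_leaf(tid, genome)

    # -- queries ----------------------------------------------------------

    def strain_node_of(self, genome_id: str) -> int:
        return self.genome_nodes[genome_id]

    def ancestors(self, taxon_id: int) -> list[int]:
        """Ancestor chain of ``taxon_id`` from itself up to the root."""
        if taxon_id not in self.nodes:
            raise TaxonomyError(f"unknown taxon {taxon_id}")
        chain = [taxon_id]
        cur = taxon_id
        while cur != self.root_id:
            cur = self.nodes[cur].parent_id
            chain.append(cur)
        return chain

    def to_level(self, taxon_id: int, level: str) -> int:
        """Project an assignment to a named rank; 0 when no such ancestor.

        ``to_level(a, l)`` is ``a`` itself when ``a`` already sits at rank
        ``l``, the ``l``-level ancestor when ``a`` is more specific, and 0
        when ``a`` is broader than ``l`` (or ``a`` is 0). At the special
        level ``'strain'`` the result is ``a`` iff a mappable genome is
        attached to ``a``, else 0.
        """
        if level not in RANKS:
            raise TaxonomyError(f"unknown rank {level!r}")
        if taxon_id == UNASSIGNED:
            return UNASSIGNED
        if taxon_id not in self.nodes:
            raise TaxonomyError(f"unknown taxon {taxon_id}")
        if level == "strain":
            node = self.nodes[taxon_id]
            return taxon_id if node.genome_id is not None else UNASSIGNED
        for tid in self.ancestors(taxon_id):
            if self.nodes[tid].rank == level:
                return tid
        return UNASSIGNED

    def lca(self, a: int, b: int) -> int:
        anc_a = self.ancestors(a)
        anc_b = set(self.ancestors(b))
        for tid in anc_a:
            if tid in anc_b:
                return tid
        return self.root_id

    # -- I/O ----------------------------------------------------------------

    def write_synthetic_sidecar(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#taxon_id\tparent_id\tgenome_id\n")
            for tid, parent, genome in self.synthetic_nodes:
                fh.write(f"{tid}\t{parent}\t{genome}\n")


def _parse_dmp_line(line: str) -> list[str]:
    return [f.strip() for f in line.rstrip("\n").rstrip("|").rstrip("\t").split("\t|\t")]


def read_genome_map(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genome, tid = line.split("\t")[:2]
            out[genome] = int(tid)
    return out


def load_taxonomy(
    nodes_table: str | Path,
    names_table: str | Path,
    genome_map: str | Path | dict[str, int] | None = None,
) -> Taxonomy:
    """Load NCBI nodes.dmp/names.dmp tables and attach genomes.

    ``genome_map`` is a 2-column TSV (genome_id <TAB> taxon_id) or an
    equivalent dict. Genomes whose target taxon has children or already
    carries a genome get a synthetic strain leaf inserted beneath it.
    """
    tax = Taxonomy()
    names: dict[int, str] = {}
    with open(names_table) as fh:
        for line in fh:
            fields = _parse_dmp_line(line)
            if len(fields) < 4:
                continue
            tid, name_txt, _unique, name_class = fields[:4]
            if name_class == "scientific name" or int(tid) not in names:
                names[int(tid)] = name_txt

    root_id = None
    with open(nodes_table) as fh:
        for line in fh:
            fields = _parse_dmp_line(line)
            if len(fields) < 3:
                continue
            tid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
            if tid == parent:
                root_id = tid
                rank = "root"
            tax.add_node(
                TaxonNode(tid, parent, rank, names.get(tid, str(tid)))
            )
    if root_id is None:
        raise TaxonomyError("no root node (taxon with parent == itself) found")
    tax.root_id = root_id

    if genome_map is not None:
        gmap = genome_map if isinstance(genome_map, dict) else read_genome_map(genome_map)
        tax.attach_genomes(gmap)
    tax.validate()
    return tax
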