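"""Synthetic reference databases, mixtures and error-bearing long reads.

The simulator emulates a pbsim-style long-read run: read lengths are
log-normal around a configurable mean (default 5000), per-base accuracy is
uniform (default 0.88) with a substitution-dominant error mix (90%
substitutions, 10% indels by default), and start positions are uniform over
length-weighted contigs. Genomes are generated by mutating a common ancestor
at a configurable divergence rate, grouped into species (and species into
genera) in an emitted toy taxonomy, so every truth label is known exactly.
All outputs are deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .taxonomy import Taxonomy, TaxonNode, UNASSIGNED

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    n_genomes: int = 10
    genome_length: int = 100_000
    divergence: float = 0.10  # per-base substitutions from the common ancestor
    strain_divergence: float = 0.02  # within-species divergence
    genomes_per_species: int = 1
    species_per_genus: int = 3
    abundance_model: str = "log-normal"  # or "uniform"
    lognormal_sigma: float = 1.0
    length_mean: int = 5000
    length_sigma: float = 0.45  # sigma of log read length
    min_read_length: int = 1000
    accuracy: float = 0.88
    indel_fraction: float = 0.10  # share of errors that are indels
    total_bases: int = 20_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.accuracy <= 1.0:
            raise ValueError("accuracy must be in (0.5, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _random_genome(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute a fraction ``rate`` of positions with a different base."""
    out = codes.copy()
    hit = rng.random(codes.size) < rate
    shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    out[hit] = (out[hit] + shift) % 4
    return out


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_genomes(
    config: SimConfig,
) -> tuple[dict[str, str], dict[str, str], dict[str, int], Taxonomy]:
    """Synthetic genome set with a matching toy taxonomy.

    Returns (contig sequences, contig->genome map, genome->taxon map,
    taxonomy). Each species' sequence is the common ancestor mutated at the
    divergence rate; strains within a species add strain-level divergence.
    """
    rng = np.random.default_rng(config.seed)
    ancestor = _random_genome(config.genome_length, rng)

    n_species = math.ceil(config.n_genomes / config.genomes_per_species)
    n_genera = math.ceil(n_species / config.species_per_genus)

    tax = Taxonomy(root_id=1)
    tax.add_node(TaxonNode(1, 1, "root", "root"))
    tax.add_node(TaxonNode(2, 1, "family", "Simulatae"))
    for gi in range(n_genera):
        tax.add_node(TaxonNode(100 + gi, 2, "genus", f"Genus{gi + 1}"))
    for si in range(n_species):
        genus = 100 + si // config.species_per_genus
        tax.add_node(TaxonNode(1000 + si, genus, "species", f"Species{si + 1}"))

    contigs: dict[str, str] = {}
    contig_map: dict[str, str] = {}
    genome_taxa: dict[str, int] = {}
    species_seqs = {
        si: _mutate(ancestor, config.divergence, rng) for si in range(n_species)
    }
    for g in range(config.n_genomes):
        si = g // config.genomes_per_species
        codes = species_seqs[si]
        if config.genomes_per_species > 1:
            codes = _mutate(codes, config.strain_divergence, rng)
        genome = f"G{g + 1:03d}"
        contig = f"{genome}_c1"
        contigs[contig] = _to_str(codes)
        contig_map[contig] = genome
        genome_taxa[genome] = 1000 + si
    tax.attach_genomes(genome_taxa)
    tax.validate()
    return contigs, contig_map, genome_taxa, tax


def draw_abundances(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.abundance_model == "uniform":
        return np.full(config.n_genomes, 1.0 / config.n_genomes)
    raw = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=config.n_genomes)
    return raw / raw.sum()


def _apply_errors(
    codes: np.ndarray, error_rate: float, indel_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitution-dominant error model; indels split evenly ins/del."""
    if error_rate <= 0.0:
        return codes
    u = rng.random(codes.size)
    sub_p = error_rate * (1.0 - indel_fraction)
    ins_p = del_p = error_rate * indel_fraction / 2.0
    sub = u < sub_p
    dele = (u >= sub_p) & (u < sub_p + del_p)
    ins = (u >= sub_p + del_p) & (u < sub_p + del_p + ins_p)
    out = codes.copy()
    shift = rng.integers(1, 4, size=int(sub.sum()), dtype=np.uint8)
    out[sub] = (out[sub] + shift) % 4
    counts = np.ones(codes.size, dtype=np.int64)
    counts[dele] = 0
    counts[ins] = 2
    idx = np.repeat(np.arange(codes.size), counts)
    out = out[idx]
    dup = np.flatnonzero(np.diff(idx) == 0) + 1  # second copy = inserted base
    out[dup] = rng.integers(0, 4, size=dup.size, dtype=np.uint8)
    return out


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: int
    taxon_id: int


def simulate_reads(
    contigs: dict[str, str],
    contig_map: dict[str, str],
    abundances: dict[str, float],
    config: SimConfig,
    taxonomy: Taxonomy | None = None,
    rng: np.random.Generator | None = None,
    read_prefix: str = "read",
) -> list[SimulatedRead]:
    """Error-bearing reads from a genome mixture, with exact truth labels.

    Lengths are log-normal with the configured mean, truncated below at half
    the minimum read length (so sub-length reads exist) and above at the
    source contig length; the read count is total_bases / mean length.
    """
    if abs(sum(abundances.values()) - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    genomes = sorted(abundances)
    probs = np.array([abundances[g] for g in genomes])
    by_genome: dict[str, list[str]] = {}
    for cid, g in contig_map.items():
        if cid in contigs:
            by_genome.setdefault(g, []).append(cid)
    codes_cache = {
        cid: np.frombuffer(contigs[cid].encode(), dtype=np.uint8) for cid in contigs
    }
    code_of = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code_of[b] = i
    comp = np.array([3, 2, 1, 0], dtype=np.uint8)

    n_reads = max(1, round(config.total_bases / config.length_mean))
    mu = math.log(config.length_mean) - config.length_sigma**2 / 2.0
    min_len = max(50, config.min_read_length // 2)
    error_rate = 1.0 - config.accuracy

    reads: list[SimulatedRead] = []
    g_choice = rng.choice(len(genomes), size=n_reads, p=probs)
    lengths = np.exp(rng.normal(mu, config.length_sigma, size=n_reads))
    lengths = np.maximum(lengths.astype(np.int64), min_len)
    strands = np.where(rng.random(n_reads) < 0.5, 1, -1)
    for i in range(n_reads):
        genome = genomes[g_choice[i]]
        cids = by_genome[genome]
        clens = np.array([len(contigs[c]) for c in cids], dtype=np.float64)
        cid = cids[int(rng.choice(len(cids), p=clens / clens.sum()))]
        raw = code_of[codes_cache[cid]]
        length = int(min(lengths[i], raw.size))
        start = int(rng.integers(0, raw.size - length + 1))
        frag = raw[start : start + length]
        if strands[i] < 0:
            frag = comp[frag][::-1]
        frag = _apply_errors(frag, error_rate, config.indel_fraction, rng)
        taxon = taxonomy.strain_node_of(genome) if taxonomy is not None else UNASSIGNED
        reads.append(
            SimulatedRead(
                read_id=f"{read_prefix}{i:06d}",
                sequence=_to_str(frag),
                genome_id=genome,
                contig_id=cid,
                start=start,
                end=start + length,
                strand=int(strands[i]),
                taxon_id=taxon,
            )
        )
    return reads


def simulate_contaminant(
    config: SimConfig,
    n_reads: int = 200,
    genome_length: int | None = None,
) -> list[SimulatedRead]:
    """Reads from an out-of-database genome; truth taxon 0 at all levels.

    The contaminant genome is drawn independently of the database ancestor
    (separate seed stream), emulating eukaryotic contamination of a sample.
    """
    rng = np.random.default_rng((config.seed + 97) * 31 + 7)
    length = genome_length or config.genome_length
    contigs = {"contam_c1": _to_str(_random_genome(length, rng))}
    contig_map = {"contam_c1": "CONTAM"}
    cfg = SimConfig(
        n_genomes=1,
        genome_length=length,
        length_mean=config.length_mean,
        length_sigma=config.length_sigma,
        min_read_length=config.min_read_length,
        accuracy=config.accuracy,
        indel_fraction=config.indel_fraction,
        total_bases=n_reads * config.length_mean,
        seed=config.seed,
    )
    reads = simulate_reads(
        contigs, contig_map, {"CONTAM": 1.0}, cfg, rng=rng, read_prefix="contam"
    )
    for r in reads:
        r.taxon_id = UNASSIGNED
    return reads


# -- writers ------------------------------------------------------------------


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for cid in contigs:
            fh.write(f">{cid}\n")
            seq = contigs[cid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: list[SimulatedRead], path: str | Path, accuracy: float) -> None:
    q = min(60, max(2, round(-10 * math.log10(max(1.0 - accuracy, 1e-6)))))
    qchar = chr(q + 33)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qchar * len(r.sequence)}\n")


def write_truth(reads: list[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\ttaxon_id\tlength\tgenome_id\tcontig\tstart\tend\tstrand\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.taxon_id}\t{len(r.sequence)}\t{r.genome_id}\t"
                f"{r.contig_id}\t{r.start}\t{r.end}\t{'+' if r.strand > 0 else '-'}\n"
            )


def write_contig_map(contig_map: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#contig_id\tgenome_id\n")
        for cid, g in contig_map.items():
            fh.write(f"{cid}\t{g}\n")


def write_taxonomy_tables(
    taxonomy: Taxonomy, genome_taxa: dict[str, int], outdir: str | Path
) -> tuple[Path, Path, Path]:
    """Emit nodes.dmp / names.dmp dialect tables plus the genome map TSV.

    Synthetic strain leaves inserted at attach time are *not* written: the
    tables describe the pre-attachment taxonomy, so reloading them with the
    genome map reproduces the same extended tree.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synthetic = {tid for tid, _, _ in taxonomy.synthetic_nodes}
    nodes_path = outdir / "nodes.dmp"
    names_path = outdir / "names.dmp"
    gmap_path = outdir / "genome_map.tsv"
    with open(nodes_path, "w") as fh:
        for tid, node in sorted(taxonomy.nodes.items()):
            if tid in synthetic:
                continue
            rank = "no rank" if node.rank == "root" else node.rank
            fh.write(f"{tid}\t|\t{node.parent_id}\t|\t{rank}\t|\n")
    with open(names_path, "w") as fh:
        for tid, node in sorted(taxonomy.nodes.items()):
            if tid in synthetic:
                continue
            fh.write(f"{tid}\t|\t{node.name}\t|\t\t|\tscientific name\t|\n")
    with open(gmap_path, "w") as fh:
        for genome, tid in sorted(genome_taxa.items()):
            fh.write(f"{genome}\t{tid}\n")
    return nodes_path, names_path, gmap_path
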