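"""End-to-end classification: map reads, fit the composition, write tables.

This is the glue the CLI and the test suite share; each stage is the
corresponding module's public API.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .composition import (
    CompositionModel,
    CompositionVector,
    filter_composition_by_identity,
    median_identities,
    project_composition,
)
from .index import IndexParams, MinimizerIndex, build_index, build_index_chunked
from .mapping import ReadMappingSet, map_reads
from .taxonomy import Assignment, Taxonomy, UNASSIGNED

DEFAULT_LEVELS = ("strain", "species", "genus", "family")


@dataclass
class ClassifyResult:
    mappings: list[ReadMappingSet]
    composition: CompositionVector
    assignments: list[Assignment]
    medians: dict[str, float]
    em_converged: bool
    em_iterations: int
    levels: dict[str, dict[int, float]] = field(default_factory=dict)


def build_indexes(
    genomes,
    contig_map=None,
    params: IndexParams | None = None,
    memory_target: int = 0,
    seed: int = 0,
) -> list[MinimizerIndex]:
    """One monolithic index, or several chunks when a memory target is set."""
    params = params or IndexParams()
    if memory_target:
        return list(
            build_index_chunked(genomes, contig_map, params, memory_target, seed)
        )
    return [build_index(genomes, contig_map, params)]


def classify(
    reads,
    indexes: Sequence[MinimizerIndex],
    taxonomy: Optional[Taxonomy] = None,
    levels: Sequence[str] = DEFAULT_LEVELS,
    identity_filter: Optional[float] = None,
    tol: float = 1e-5,
    max_iter: int = 500,
    denominator: str = "all-reads",
) -> ClassifyResult:
    """Map reads, run the composition EM and finalize assignments."""
    mappings = map_reads(reads, list(indexes))
    genome_contigs: dict[str, list[int]] = {}
    for idx in indexes:
        for g, lens in idx.genome_contig_lengths().items():
            genome_contigs.setdefault(g, []).extend(lens)
    if not any(m.mapped for m in mappings):
        comp = CompositionVector({g: 0.0 for g in genome_contigs}, 1.0)
        assignments = [
            Assignment(m.read_id, UNASSIGNED, None, m.read_length)
            for m in mappings
            if not (m.too_short and denominator == "long-reads")
        ]
        return ClassifyResult(mappings, comp, assignments, {}, True, 0)

    results = CompositionModel(mappings, genome_contigs).fit(tol=tol, max_iter=max_iter)
    comp, assignments = results.finalize(taxonomy=taxonomy, denominator=denominator)
    medians = median_identities(mappings, assignments)
    if identity_filter is not None:
        comp = filter_composition_by_identity(comp, medians, identity_filter)
    out = ClassifyResult(
        mappings,
        comp,
        assignments,
        medians,
        results.converged,
        results.n_iter,
    )
    if taxonomy is not None:
        for level in levels:
            out.levels[level] = project_composition(comp, taxonomy, level)
    return out


# -- tabular output -------------------------------------------------------------


def assignments_frame(result: ClassifyResult) -> pd.DataFrame:
    """Per-read assignment table including the chosen placement, if any."""
    by_read = {m.read_id: m for m in result.mappings}
    rows = []
    for a in result.assignments:
        rms = by_read[a.read_id]
        best = None
        if a.genome_id is not None:
            cands = [c for c in rms.candidates if c.genome_id == a.genome_id]
            best = max(cands, key=lambda c: (c.posterior, c.mapping_quality))
        rows.append(
            dict(
                read_id=a.read_id,
                taxon_id=a.taxon_id,
                genome_id=a.genome_id or "",
                contig=best.contig_id if best else "",
                start=best.start if best else -1,
                end=best.end if best else -1,
                strand=("+" if best.strand > 0 else "-") if best else "",
                identity_hat=round(best.identity_hat, 6) if best else float("nan"),
                mapping_quality=round(best.mapping_quality, 6) if best else float("nan"),
                posterior=round(best.posterior, 6) if best else float("nan"),
                read_length=a.read_length,
            )
        )
    return pd.DataFrame(rows)


def composition_frame(
    result: ClassifyResult, taxonomy: Optional[Taxonomy], level: str
) -> pd.DataFrame:
    comp = result.levels.get(level)
    if comp is None:
        comp = project_composition(result.composition, taxonomy, level)
    read_counts: dict[int, int] = {}
    for a in result.assignments:
        t = taxonomy.to_level(a.taxon_id, level) if taxonomy else UNASSIGNED
        read_counts[t] = read_counts.get(t, 0) + 1
    rows = []
    for tid in sorted(comp):
        name = "unassigned" if tid == UNASSIGNED else taxonomy.nodes[tid].name
        rows.append(
            dict(
                taxon_id=tid,
                name=name,
                level=level,
                fraction=comp[tid],
                read_count=read_counts.get(tid, 0),
            )
        )
    return pd.DataFrame(rows)


def _digest(params: dict) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True).encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    """TSV with a single '#'-prefixed header of column names and params digest."""
    params = params or {}
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(df.columns) + f"\t[params:{_digest(params)}]\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").split("\t")
        cols = [c for c in header if not c.startswith("[params:")]
        return pd.read_csv(fh, sep="\t", names=[c.strip() for c in cols])


def write_manifest(path: str | Path, stage: str, params: dict, inputs: Sequence[str | Path] = ()) -> None:
    """Run manifest: stage, parameters, seed, package version, input checksums."""
    checksums = {}
    for p in inputs:
        p = Path(p)
        if p.is_file():
            checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    manifest = {
        "stage": stage,
        "version": __version__,
        "python": platform.python_version(),
        "params": params,
        "input_sha256": checksums,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def write_outputs(
    result: ClassifyResult,
    taxonomy: Optional[Taxonomy],
    prefix: str | Path,
    levels: Sequence[str] = DEFAULT_LEVELS,
    params: dict | None = None,
) -> list[Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    p = Path(f"{prefix}.assignments.tsv")
    write_tsv(assignments_frame(result), p, params)
    written.append(p)
    if taxonomy is not None:
        for level in levels:
            p = Path(f"{prefix}.composition.{level}.tsv")
            write_tsv(composition_frame(result, taxonomy, level), p, params)
            written.append(p)
    med = pd.DataFrame(
        [
            dict(genome_id=g, median_identity=round(m, 6))
            for g, m in sorted(result.medians.items())
        ],
        columns=["genome_id", "median_identity"],
    )
    p = Path(f"{prefix}.genomes.tsv")
    write_tsv(med, p, params)
    written.append(p)
    return written
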