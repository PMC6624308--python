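"""Per-genome diagnostics and gene/functional-group overlap counting.

Diagnostics summarize, per genome, the distribution of estimated alignment
identities of its assigned reads (0.01-wide bins) and the spatial coverage
of its contigs (mean depth per fixed-size window) — uneven coverage together
with a shift of identities away from the expected sequencing accuracy flags
database-sample mismatches. Overlap counting aggregates, per functional
group (e.g. a COG category), how many final read placements overlap at least
one annotated feature carrying that group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


@dataclass
class GenomeDiagnostics:
    genome_id: str
    identity_histogram: np.ndarray  # 100 bins of width 0.01 over [0, 1]
    median_identity: float
    #: contig_id -> per-window mean depth (window = overlapping bases / size)
    window_depth: dict[str, np.ndarray] = field(default_factory=dict)
    n_reads: int = 0


#: columns a placement table must carry
_PLACEMENT_COLS = ("read_id", "genome_id", "contig", "start", "end", "identity_hat")


def genome_diagnostics(
    placements: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    genome_of_contig: Mapping[str, str],
    window: int = 1000,
) -> dict[str, GenomeDiagnostics]:
    """Identity histogram, median identity and windowed coverage per genome.

    ``placements`` needs columns read_id, genome_id, contig, start, end,
    identity_hat (half-open 0-based intervals). Genomes without assigned
    reads are simply absent from the result.
    """
    for col in _PLACEMENT_COLS:
        if col not in placements.columns:
            raise ValueError(f"placements table lacks column {col!r}")
    bins = np.linspace(0.0, 1.0, 101)
    out: dict[str, GenomeDiagnostics] = {}
    for genome, sub in placements.groupby("genome_id", sort=True):
        ident = np.clip(sub["identity_hat"].to_numpy(float), 0.0, 1.0)
        hist, _ = np.histogram(np.minimum(ident, 1.0 - 1e-12), bins=bins)
        diag = GenomeDiagnostics(
            genome_id=str(genome),
            identity_histogram=hist,
            median_identity=float(np.median(ident)),
            n_reads=len(sub),
        )
        for contig, csub in sub.groupby("contig"):
            clen = contig_lengths[contig]
            n_win = max(1, -(-clen // window))
            depth = np.zeros(n_win)
            starts = np.clip(csub["start"].to_numpy(np.int64), 0, clen)
            ends = np.clip(csub["end"].to_numpy(np.int64), 0, clen)
            for s, e in zip(starts, ends):
                w0, w1 = s // window, (max(e, s + 1) - 1) // window
                for wi in range(w0, w1 + 1):
                    lo = max(s, wi * window)
                    hi = min(e, (wi + 1) * window)
                    depth[wi] += max(hi - lo, 0)
            diag.window_depth[str(contig)] = depth / window
        out[str(genome)] = diag
    return out


def diagnostics_table(diags: Mapping[str, GenomeDiagnostics]) -> pd.DataFrame:
    rows = []
    for g, d in sorted(diags.items()):
        depths = np.concatenate(list(d.window_depth.values())) if d.window_depth else np.zeros(1)
        rows.append(
            dict(
                genome_id=g,
                n_reads=d.n_reads,
                median_identity=d.median_identity,
                mean_depth=float(depths.mean()),
                depth_cv=float(depths.std() / depths.mean()) if depths.mean() > 0 else np.nan,
            )
        )
    return pd.DataFrame(rows)


def read_gff3(path: str | Path, group_key: str = "cog_category") -> pd.DataFrame:
    """Minimal GFF3 feature table with a functional-group label column.

    Keeps features whose attribute list carries ``group_key``; the label may
    be comma-separated (one row per label). Coordinates are converted to
    0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            contig, _, ftype, start, end, _, strand, _, attrs = fields[:9]
            labels = []
            for kv in attrs.strip(";").split(";"):
                if "=" not in kv:
                    continue
                key, val = kv.split("=", 1)
                if key.strip() == group_key:
                    labels = [v for v in val.split(",") if v]
            for label in labels:
                rows.append(
                    dict(
                        contig=contig,
                        type=ftype,
                        start=int(start) - 1,
                        end=int(end),
                        strand=strand,
                        group=label,
                    )
                )
    return pd.DataFrame(rows, columns=["contig", "type", "start", "end", "strand", "group"])


def feature_overlap_counts(
    placements: pd.DataFrame,
    features: pd.DataFrame | str | Path,
    group_key: str = "cog_category",
    min_overlap: int = 1,
    known_contigs: Sequence[str] | None = None,
) -> pd.Series:
    """Reads overlapping >=1 feature per functional group.

    A placement increments every group attached to any overlapping feature
    (>= ``min_overlap`` bases, half-open intervals, strand ignored), at most
    once per group per read. Features on contigs absent from
    ``known_contigs`` (when given) are skipped with a warning.
    """
    if not isinstance(features, pd.DataFrame):
        features = read_gff3(features, group_key=group_key)
    trees: dict[str, IntervalTree] = {}
    for row in features.itertuples(index=False):
        if known_contigs is not None and row.contig not in known_contigs:
            import warnings

            warnings.warn(f"feature on unknown contig {row.contig}; skipped")
            continue
        if row.end > row.start:
            trees.setdefault(row.contig, IntervalTree()).addi(
                row.start, row.end, row.group
            )
    counts: dict[str, int] = {}
    for row in placements.itertuples(index=False):
        tree = trees.get(row.contig)
        if tree is None:
            continue
        groups = set()
        for iv in tree.overlap(row.start, row.end):
            if min(iv.end, row.end) - max(iv.begin, row.start) >= min_overlap:
                groups.add(iv.data)
        for g in groups:
            counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()
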