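"""Read-level, base-level and compositional evaluation metrics.

A read's call is correct at level l iff to_level(inference(r), l) equals
to_level(truth(r), l). Precision is computed over V' (reads that received an
assignment, including assignments projecting to 0), recall over the full
validation set V, and precision2 over V''(l), the assigned reads whose call
is non-0 at level l. Base-level variants weight each read by its length.
Compositional accuracy uses the L1 distance and Pearson's r^2 over columns
that are >0 in either vector, plus presence/absence ("binary") precision and
recall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import pearsonr

from .taxonomy import Assignment, Taxonomy, UNASSIGNED


@dataclass
class TruthRecord:
    taxon_id: int
    read_length: int


TruthSet = Mapping[str, TruthRecord]


def read_truth_tsv(path) -> dict[str, TruthRecord]:
    """Truth table: read_id <TAB> taxon_id <TAB> length."""
    out: dict[str, TruthRecord] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            out[fields[0]] = TruthRecord(int(fields[1]), int(fields[2]))
    return out


def _weighted_metrics(
    assignments: Sequence[Assignment],
    truth: TruthSet,
    taxonomy: Taxonomy,
    level: str,
    weights: Optional[Mapping[str, float]] = None,
) -> tuple[float, float, Optional[float]]:
    for a in assignments:
        if a.read_id not in truth:
            raise KeyError(f"assigned read {a.read_id} absent from truth set")
    w = weights or {r: 1.0 for r in truth}
    total_v = sum(w[r] for r in truth)
    correct_w = 0.0
    assigned_w = 0.0
    non0_w = 0.0
    correct_non0_w = 0.0
    for a in assignments:
        wt = w[a.read_id]
        assigned_w += wt
        inf_l = taxonomy.to_level(a.taxon_id, level)
        truth_l = taxonomy.to_level(truth[a.read_id].taxon_id, level)
        ok = inf_l == truth_l
        if ok:
            correct_w += wt
        if inf_l != UNASSIGNED:
            non0_w += wt
            if ok:
                correct_non0_w += wt
    precision = correct_w / assigned_w if assigned_w else float("nan")
    recall = correct_w / total_v if total_v else float("nan")
    precision2 = correct_non0_w / non0_w if non0_w else None
    return precision, recall, precision2


def read_metrics(
    assignments: Sequence[Assignment],
    truth: TruthSet,
    taxonomy: Taxonomy,
    level: str,
) -> tuple[float, float, Optional[float]]:
    """(precision, recall, precision2) at a level, one unit per read.

    Reads present in truth but absent from the assignments are unassigned
    without an assignment: they count in V but not in V'.
    """
    return _weighted_metrics(assignments, truth, taxonomy, level)


def base_metrics(
    assignments: Sequence[Assignment],
    truth: TruthSet,
    taxonomy: Taxonomy,
    level: str,
) -> tuple[float, float, Optional[float]]:
    """Read-length-reweighted precision, recall and precision2."""
    weights = {}
    for rid, rec in truth.items():
        if rec.read_length < 1:
            raise ValueError(f"read {rid} has non-positive length")
        weights[rid] = float(rec.read_length)
    return _weighted_metrics(assignments, truth, taxonomy, level, weights)


def _support_columns(
    estimate: Mapping[int, float], truth: Mapping[int, float]
) -> list[int]:
    keys = set(estimate) | set(truth)
    return sorted(
        k for k in keys if estimate.get(k, 0.0) > 0.0 or truth.get(k, 0.0) > 0.0
    )


def composition_metrics(
    estimate: Mapping[int, float], truth: Mapping[int, float]
) -> tuple[float, Optional[float]]:
    """(L1, r^2) between composition vectors at one level.

    Both computed over columns >0 in either vector; r^2 is None when fewer
    than two support columns exist (or either vector is constant).
    """
    cols = _support_columns(estimate, truth)
    est = np.array([estimate.get(c, 0.0) for c in cols])
    tru = np.array([truth.get(c, 0.0) for c in cols])
    l1 = float(np.abs(est - tru).sum())
    if len(cols) < 2 or np.all(est == est[0]) or np.all(tru == tru[0]):
        return l1, None
    r, _ = pearsonr(est, tru)
    return l1, float(r**2)


def binary_metrics(
    estimate: Mapping[int, float],
    truth: Mapping[int, float],
    min_abundance: float = 0.0,
) -> tuple[Optional[float], float]:
    """Presence/absence (binary_precision, binary_recall) at one level.

    Presence means abundance strictly greater than ``min_abundance``; the
    unassigned bin (taxon 0) is excluded. Precision is None when nothing is
    predicted present.
    """
    pred = {k for k, v in estimate.items() if v > min_abundance and k != UNASSIGNED}
    true = {k for k, v in truth.items() if v > min_abundance and k != UNASSIGNED}
    inter = pred & true
    precision = len(inter) / len(pred) if pred else None
    recall = len(inter) / len(true) if true else float("nan")
    return precision, recall


def evaluate_levels(
    assignments: Sequence[Assignment],
    truth: TruthSet,
    taxonomy: Taxonomy,
    levels: Sequence[str] = ("strain", "species", "genus", "family"),
) -> "pd.DataFrame":
    """Tidy per-level table of all read- and base-weighted metrics."""
    import pandas as pd

    rows = []
    for level in levels:
        p, r, p2 = read_metrics(assignments, truth, taxonomy, level)
        pb, rb, pb2 = base_metrics(assignments, truth, taxonomy, level)
        rows.append(
            dict(
                level=level,
                precision=p,
                recall=r,
                precision2=p2,
                precision_bases=pb,
                recall_bases=rb,
                precision2_bases=pb2,
            )
        )
    return pd.DataFrame(rows)
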