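"""Approximate long-read mapping with winnowed-minhash identity estimates.

Candidate mapping locations are reference windows of read-length extent that
share at least ``m_min`` minimizers with the read. For each surviving
candidate the Jaccard similarity between read and window k-mer sets is
estimated from the s smallest hashes of the sketch union,

    J_hat = |S_{r u i} & S_i & S_r| / |S_{r u i}|,

converted to an alignment identity estimate via (2*J/(1+J))^(1/k), and the
per-read mapping qualities P_r(i) are obtained by normalizing binomial
probabilities of the observed sketch-intersection counts with n = |S_{r u i}|
and k-mer survival rate p = (1-e)^k, where (1-e) is the estimated identity
of the read's highest-scoring candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from scipy.special import logsumexp
from scipy.stats import binom

from .index import IndexParams, MinimizerIndex, _winnow_arrays


def expected_kmer_matches(read_length: int, k: int, error_rate: float) -> float:
    """Expected exact k-mer matches between a read and its error-free source.

    Under a uniform per-base error model each of the read_length - k + 1
    k-mers survives with probability (1-e)^k.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if read_length < k:
        raise ValueError("read_length must be >= k")
    return (read_length - k + 1) * (1.0 - error_rate) ** k


def identity_from_jaccard(jaccard_hat: float, k: int) -> float:
    """Alignment-identity estimate (2*J/(1+J))^(1/k) from a Jaccard estimate."""
    if not 0.0 <= jaccard_hat <= 1.0:
        raise ValueError("jaccard_hat must be in [0, 1]")
    if jaccard_hat == 0.0:
        return 0.0
    return (2.0 * jaccard_hat / (1.0 + jaccard_hat)) ** (1.0 / k)


def jaccard_estimate(s_r, s_i, sketch_size: int) -> tuple[int, int, float]:
    """Winnowed-minhash Jaccard from two hash sets.

    The union sketch S_{r u i} holds the ``sketch_size`` smallest hashes of
    S_r | S_i; shared counts are members of the union sketch present in both
    input sets. Returns (n_union, n_shared, jaccard_hat).
    """
    s_r = np.asarray(sorted(s_r) if isinstance(s_r, set) else s_r, dtype=np.uint64)
    s_i = np.asarray(sorted(s_i) if isinstance(s_i, set) else s_i, dtype=np.uint64)
    if s_r.size == 0 or s_i.size == 0:
        raise ValueError("sketches must be nonempty")
    union = np.union1d(s_r, s_i)
    sketch = union[: min(sketch_size, union.size)]
    shared = np.intersect1d(sketch, np.intersect1d(s_r, s_i), assume_unique=True)
    n_union = int(sketch.size)
    n_shared = int(shared.size)
    return n_union, n_shared, n_shared / n_union


def min_shared_minimizers(params: IndexParams) -> int:
    """Stage-1 intersection cutoff m_min from the minimum identity.

    Inverts the identity estimator: J_min = id^k / (2 - id^k), scaled by the
    expected sketch size of a minimum-length read.
    """
    idk = params.min_identity**params.k
    j_min = idk / (2.0 - idk)
    s_exp = min(
        params.sketch_target,
        int(2 * params.min_read_length / (params.window_size + 1)),
    )
    return max(2, math.ceil(j_min * s_exp))


@dataclass
class CandidateMapping:
    read_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int  # half-open
    strand: int  # +1 / -1
    n_union: int = 0
    n_shared: int = 0
    jaccard_hat: float = 0.0
    identity_hat: float = 0.0
    mapping_quality: float = 0.0
    posterior: float = 0.0


@dataclass
class ReadMappingSet:
    read_id: str
    read_length: int
    candidates: list[CandidateMapping] = field(default_factory=list)
    error_estimate: float = 1.0
    too_short: bool = False

    @property
    def mapped(self) -> bool:
        return bool(self.candidates)


def candidate_locations(
    read_seq: str, index: MinimizerIndex, m_min: int | None = None
) -> list[CandidateMapping]:
    """Raw candidate intervals for one read (before identity estimation).

    Matches are grouped per (contig, relative strand) on the start diagonal;
    clusters with >= m_min matches become candidates of read-length extent.
    The candidate start is anchored on the match with the least accumulated
    indel drift for its orientation.
    """
    params = index.params
    if m_min is None:
        m_min = min_shared_minimizers(params)
    L = len(read_seq)
    r_hash, r_pos, r_strand = _winnow_arrays(read_seq, params)
    if r_hash.size == 0:
        return []
    qidx, c_contig, c_pos, c_strand = index.lookup(r_hash)
    if qidx.size == 0:
        return []
    rel = (r_strand[qidx] * c_strand).astype(np.int8)
    # diagonal: putative reference start of the read for each match
    read_off = r_pos[qidx]
    diag = np.where(rel > 0, c_pos - read_off, c_pos - (L - params.k - read_off))
    slack = max(2 * params.window_size, round(0.02 * L))

    out: list[CandidateMapping] = []
    key = c_contig.astype(np.int64) * 2 + (rel > 0)
    for k in np.unique(key):
        sel = key == k
        ci = int(c_contig[sel][0])
        strand = 1 if (k % 2) else -1
        d = diag[sel]
        ro = read_off[sel]
        order = np.argsort(d, kind="stable")
        d, ro = d[order], ro[order]
        clen = index.contig_lengths[index.contig_ids[ci]]
        # two-pointer clustering on the diagonal
        lo = 0
        clusters: list[tuple[int, int]] = []
        for hi in range(1, d.size + 1):
            if hi == d.size or d[hi] - d[lo] > slack:
                clusters.append((lo, hi))
                lo = hi
        for lo_, hi_ in clusters:
            count = hi_ - lo_
            if count < m_min:
                continue
            seg_ro = ro[lo_:hi_]
            anchor = np.argmin(seg_ro) if strand > 0 else np.argmax(seg_ro)
            start = int(np.clip(d[lo_:hi_][anchor], 0, max(clen - L, 0)))
            out.append(
                CandidateMapping(
                    read_id="",
                    genome_id=index.genome_of_contig[index.contig_ids[ci]],
                    contig_id=index.contig_ids[ci],
                    start=start,
                    end=min(start + L, clen),
                    strand=strand,
                    n_shared=count,
                )
            )
    # merge overlapping candidate windows on the same contig/strand,
    # keeping the maximal-count offset (ties: leftmost)
    merged: list[CandidateMapping] = []
    out.sort(key=lambda c: (c.contig_id, c.strand, c.start))
    for cand in out:
        prev = merged[-1] if merged else None
        if (
            prev
            and prev.contig_id == cand.contig_id
            and prev.strand == cand.strand
            and cand.start < prev.end
        ):
            if cand.n_shared > prev.n_shared:
                merged[-1] = cand
        else:
            merged.append(cand)
    return merged


def filter_low_identity(
    candidates: Sequence[CandidateMapping], min_identity: float
) -> list[CandidateMapping]:
    """Drop candidates with estimated identity below the threshold."""
    return [c for c in candidates if c.identity_hat >= min_identity]


def mapping_quality(
    candidates: Sequence[CandidateMapping], e: float, k: int
) -> list[CandidateMapping]:
    """Normalized binomial mapping qualities P_r(i) over one read's candidates.

    score_i = BinomialPMF(n_shared_i; n_union_i, (1-e)^k); normalization is
    done in log space so qualities are well-defined even when every PMF
    underflows.
    """
    if not candidates:
        return []
    if not 0.0 <= e < 1.0:
        raise ValueError("e must be in [0, 1)")
    p = (1.0 - e) ** k
    n = np.array([c.n_union for c in candidates], dtype=np.int64)
    m = np.array([c.n_shared for c in candidates], dtype=np.int64)
    with np.errstate(divide="ignore"):
        logscore = binom.logpmf(m, n, p)
    if np.all(np.isneginf(logscore)):
        quals = np.full(len(candidates), 1.0 / len(candidates))
    else:
        quals = np.exp(logscore - logsumexp(logscore))
        quals = quals / quals.sum()
    for c, q in zip(candidates, quals):
        c.mapping_quality = float(q)
    return list(candidates)


def map_read(
    read_id: str,
    read_seq: str,
    indexes: MinimizerIndex | Sequence[MinimizerIndex],
) -> ReadMappingSet:
    """Map one read against one index or a sequence of index chunks.

    Candidates from all chunks are pooled before identity filtering and
    mapping-quality computation, so chunked and monolithic runs agree.
    """
    if isinstance(indexes, MinimizerIndex):
        indexes = [indexes]
    params = indexes[0].params
    L = len(read_seq)
    rms = ReadMappingSet(read_id=read_id, read_length=L)
    if L < params.min_read_length:
        rms.too_short = True
        return rms

    r_hash, _, _ = _winnow_arrays(read_seq, params)
    s_r = np.unique(r_hash)
    if s_r.size == 0:
        return rms

    candidates: list[CandidateMapping] = []
    for index in indexes:
        for cand in candidate_locations(read_seq, index):
            cand.read_id = read_id
            ci = index.contig_ids.index(cand.contig_id)
            s_i = index.window_hashes(ci, cand.start, cand.end)
            if s_i.size == 0:
                continue
            s = min(s_r.size, s_i.size, params.sketch_target)
            cand.n_union, cand.n_shared, cand.jaccard_hat = jaccard_estimate(
                s_r, s_i, s
            )
            cand.identity_hat = identity_from_jaccard(cand.jaccard_hat, params.k)
            candidates.append(cand)

    candidates = filter_low_identity(candidates, params.min_identity)
    if not candidates:
        return rms
    candidates.sort(key=lambda c: (c.contig_id, c.start, c.strand))
    rms.error_estimate = 1.0 - max(c.identity_hat for c in candidates)
    rms.candidates = mapping_quality(candidates, rms.error_estimate, params.k)
    return rms


def _iter_reads(reads) -> Iterable[tuple[str, str]]:
    if isinstance(reads, (str, Path)):
        with pysam.FastxFile(str(reads)) as fh:
            for entry in fh:
                yield entry.name, entry.sequence
    else:
        yield from reads


def map_reads(
    reads,
    indexes: MinimizerIndex | Sequence[MinimizerIndex],
) -> list[ReadMappingSet]:
    """Map reads (FASTA/FASTQ path or iterable of (id, seq)) against the index."""
    return [map_read(rid, seq, indexes) for rid, seq in _iter_reads(reads)]
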