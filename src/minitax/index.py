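"""Winnowed-minimizer index over reference contigs.

Every contig is scanned for canonical k-mers (the lexicographically smaller
of a k-mer and its reverse complement, as 2-bit codes) which are hashed with
a fixed-seed 64-bit mix; winnowing keeps the minimum-hash k-mer of every
window of ``w`` consecutive k-mers. Window size is auto-tuned so a
minimum-length read is expected to retain at least ``sketch_target``
minimizers (winnowing density ~ 2/(w+1)). K-mers containing ambiguous bases
are skipped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pysam

#: fixed seed folded into every k-mer hash so runs are reproducible
HASH_SEED = np.uint64(0x9E3779B97F4A7C15 ^ 0x14D9)

_INVALID_HASH = np.uint64(0xFFFFFFFFFFFFFFFF)

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


class IndexParamError(ValueError):
    pass


class Minimizer(NamedTuple):
    hash: int
    position: int
    strand: int  # +1 / -1: orientation achieving the canonical form


def tune_density(min_read_length: int, min_identity: float, sketch_target: int = 200) -> int:
    """Window size w such that a min-length read keeps >= sketch_target minimizers.

    Expected winnowed-minimizer count of an L-base window is ~ 2L/(w+1), so
    w = floor(2L/target - 1), clamped to >= 1 (with a warning when even
    keeping every k-mer cannot reach the target).
    """
    if sketch_target < 10:
        raise IndexParamError("sketch_target must be >= 10")
    if not 0.0 < min_identity < 1.0:
        raise IndexParamError("min_identity must be in (0, 1)")
    w = int(2 * min_read_length / sketch_target - 1)
    if w < 1:
        warnings.warn(
            "sketch_target exceeds the k-mer count of a minimum-length read; "
            "keeping every k-mer (w=1)"
        )
        return 1
    return w


@dataclass
class IndexParams:
    k: int = 16
    min_read_length: int = 1000
    min_identity: float = 0.80
    sketch_target: int = 200
    window_size: int = 0  # derived when 0

    def __post_init__(self) -> None:
        if self.k < 4:
            raise IndexParamError("k must be >= 4")
        if self.window_size < 1:
            self.window_size = tune_density(
                self.min_read_length, self.min_identity, self.sketch_target
            )


def _encode(sequence: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _mix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer; deterministic, fixed seed."""
    with np.errstate(over="ignore"):
        x = (x ^ HASH_SEED) + np.uint64(0x9E3779B97F4A7C15)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return x ^ (x >> np.uint64(31))


def _kmer_hashes(sequence: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical hash, strand and validity for every k-mer start position.

    Invalid (ambiguous-base) k-mers get a sentinel max hash and valid=False.
    """
    codes = _encode(sequence)
    n = len(codes) - k + 1
    if n <= 0:
        e = np.empty(0)
        return e.astype(np.uint64), e.astype(np.int8), e.astype(bool)
    invalid = codes > 3
    codes = np.where(invalid, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        fwd = (fwd << two) | codes[j : j + n]
        rev = (rev << two) | (np.uint64(3) - codes[k - 1 - j : k - 1 - j + n])
    strand = np.where(fwd <= rev, 1, -1).astype(np.int8)
    canon = np.minimum(fwd, rev)
    hashes = _mix64(canon)
    # a k-mer is valid iff no position in [i, i+k) is ambiguous
    bad = np.convolve(invalid.astype(np.int32), np.ones(k, dtype=np.int32))[k - 1 : k - 1 + n]
    valid = bad == 0
    hashes[~valid] = _INVALID_HASH
    return hashes, strand, valid


def canonical_kmer_hash(seq: str) -> tuple[int, int]:
    """Hash and strand of a single k-length DNA string (k = len(seq))."""
    hashes, strand, valid = _kmer_hashes(seq, len(seq))
    if hashes.size != 1 or not valid[0]:
        raise ValueError("sequence must be a single unambiguous DNA k-mer")
    return int(hashes[0]), int(strand[0])


def _winnow_arrays(sequence: str, params: IndexParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Winnowed minimizers of a sequence as (hash, position, strand) arrays."""
    hashes, strand, valid = _kmer_hashes(sequence, params.k)
    n = hashes.size
    if n == 0:
        e = np.empty(0)
        return e.astype(np.uint64), e.astype(np.int64), e.astype(np.int8)
    w = min(params.window_size, n)
    windows = np.lib.stride_tricks.sliding_window_view(hashes, w)
    pos = windows.argmin(axis=1) + np.arange(n - w + 1)
    pos = np.unique(pos)
    pos = pos[valid[pos]]
    return hashes[pos], pos.astype(np.int64), strand[pos]


def winnow(sequence: str, params: IndexParams) -> list[Minimizer]:
    """Minimum-hash k-mer of every w-window, once each, sorted by position."""
    h, p, s = _winnow_arrays(sequence, params)
    return [Minimizer(int(a), int(b), int(c)) for a, b, c in zip(h, p, s)]


@dataclass
class MinimizerIndex:
    """Posting-list index: minimizer hash -> (genome, contig, position, strand).

    Postings are stored CSR-style (sorted unique hashes + offsets) together
    with per-contig position-sorted views used to extract the minimizer
    sketch of an arbitrary reference window.
    """

    params: IndexParams
    contig_ids: list[str]
    contig_lengths: dict[str, int]
    genome_of_contig: dict[str, str]
    uhash: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint64))
    offsets: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    post_contig: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    post_pos: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    post_strand: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    # per contig index: positions sorted, with parallel hashes
    _contig_pos: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _contig_hash: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def n_entries(self) -> int:
        return int(self.post_pos.size)

    def genome_contig_lengths(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for cid, length in self.contig_lengths.items():
            out.setdefault(self.genome_of_contig[cid], []).append(length)
        return out

    def lookup(self, hashes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Postings for an array of query hashes.

        Returns (query_index, contig_index, position, strand) flattened over
        all matching postings.
        """
        hashes = np.asarray(hashes, dtype=np.uint64)
        idx = np.searchsorted(self.uhash, hashes)
        idx = np.clip(idx, 0, self.uhash.size - 1) if self.uhash.size else idx
        found = self.uhash.size > 0
        hit = (self.uhash[idx] == hashes) if found else np.zeros(hashes.size, bool)
        qidx = np.flatnonzero(hit)
        if qidx.size == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e.astype(np.int32), e, e.astype(np.int8)
        starts = self.offsets[idx[qidx]]
        ends = self.offsets[idx[qidx] + 1]
        counts = ends - starts
        flat = np.concatenate([np.arange(s, e) for s, e in zip(starts, ends)])
        query_index = np.repeat(qidx, counts)
        return (
            query_index,
            self.post_contig[flat],
            self.post_pos[flat],
            self.post_strand[flat],
        )

    def window_hashes(self, contig_index: int, start: int, end: int) -> np.ndarray:
        """Minimizer hashes of the global winnowing restricted to [start, end)."""
        pos = self._contig_pos[contig_index]
        lo, hi = np.searchsorted(pos, [start, end])
        return np.unique(self._contig_hash[contig_index][lo:hi])

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {
            "params": asdict(self.params),
            "contig_ids": self.contig_ids,
            "contig_lengths": self.contig_lengths,
            "genome_of_contig": self.genome_of_contig,
        }
        np.savez_compressed(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            uhash=self.uhash,
            offsets=self.offsets,
            post_contig=self.post_contig,
            post_pos=self.post_pos,
            post_strand=self.post_strand,
        )

    @classmethod
    def load(cls, path: str | Path) -> "MinimizerIndex":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            idx = cls(
                params=IndexParams(**meta["params"]),
                contig_ids=list(meta["contig_ids"]),
                contig_lengths={k: int(v) for k, v in meta["contig_lengths"].items()},
                genome_of_contig=dict(meta["genome_of_contig"]),
                uhash=z["uhash"],
                offsets=z["offsets"],
                post_contig=z["post_contig"],
                post_pos=z["post_pos"],
                post_strand=z["post_strand"],
            )
        idx._build_contig_views()
        return idx

    def _build_contig_views(self) -> None:
        order = np.lexsort((self.post_pos, self.post_contig))
        contigs = self.post_contig[order]
        bounds = np.searchsorted(contigs, np.arange(len(self.contig_ids) + 1))
        hashes = np.repeat(self.uhash, np.diff(self.offsets))[order]
        for ci in range(len(self.contig_ids)):
            self._contig_pos[ci] = self.post_pos[order[bounds[ci] : bounds[ci + 1]]]
            self._contig_hash[ci] = hashes[bounds[ci] : bounds[ci + 1]]


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            if entry.name in out:
                raise ValueError(f"duplicate contig id {entry.name}")
            out[entry.name] = entry.sequence
    return out


def read_contig_map(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            contig, genome = line.split("\t")[:2]
            out[contig] = genome
    return out


def _as_contigs(genomes) -> dict[str, str]:
    if isinstance(genomes, (str, Path)):
        return read_fasta(genomes)
    return dict(genomes)


def _as_contig_map(genome_map, contigs: dict[str, str]) -> dict[str, str]:
    if genome_map is None:
        return {cid: cid for cid in contigs}
    if isinstance(genome_map, (str, Path)):
        return read_contig_map(genome_map)
    return dict(genome_map)


def _assemble(
    contig_minimizers: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]],
    lengths: dict[str, int],
    contig_map: dict[str, str],
    params: IndexParams,
) -> MinimizerIndex:
    contig_ids = [cid for cid, *_ in contig_minimizers]
    hash_parts, contig_parts, pos_parts, strand_parts = [], [], [], []
    for ci, (cid, h, p, s) in enumerate(contig_minimizers):
        hash_parts.append(h)
        contig_parts.append(np.full(h.size, ci, dtype=np.int32))
        pos_parts.append(p)
        strand_parts.append(s)
    all_hash = np.concatenate(hash_parts) if hash_parts else np.empty(0, np.uint64)
    all_contig = np.concatenate(contig_parts) if contig_parts else np.empty(0, np.int32)
    all_pos = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
    all_strand = np.concatenate(strand_parts) if strand_parts else np.empty(0, np.int8)
    order = np.lexsort((all_pos, all_contig, all_hash))
    all_hash, all_contig = all_hash[order], all_contig[order]
    all_pos, all_strand = all_pos[order], all_strand[order]
    uhash, counts = np.unique(all_hash, return_counts=True)
    offsets = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    idx = MinimizerIndex(
        params=params,
        contig_ids=contig_ids,
        contig_lengths={cid: lengths[cid] for cid in contig_ids},
        genome_of_contig={cid: contig_map[cid] for cid in contig_ids},
        uhash=uhash,
        offsets=offsets,
        post_contig=all_contig,
        post_pos=all_pos,
        post_strand=all_strand,
    )
    idx._build_contig_views()
    return idx


def build_index(genomes, genome_map=None, params: IndexParams | None = None) -> MinimizerIndex:
    """Monolithic minimizer index over all contigs.

    ``genomes`` is a FASTA path or dict contig_id -> sequence; ``genome_map``
    is a contig_id -> genome_id mapping (TSV path or dict; defaults to one
    genome per contig).
    """
    params = params or IndexParams()
    contigs = _as_contigs(genomes)
    if not contigs:
        raise ValueError("no input contigs")
    contig_map = _as_contig_map(genome_map, contigs)
    mins = []
    lengths = {}
    for cid, seq in contigs.items():
        if cid not in contig_map:
            raise ValueError(f"contig {cid} missing from genome map")
        h, p, s = _winnow_arrays(seq, params)
        mins.append((cid, h, p, s))
        lengths[cid] = len(seq)
    return _assemble(mins, lengths, contig_map, params)


def build_index_chunked(
    genomes,
    genome_map=None,
    params: IndexParams | None = None,
    memory_target: int = 0,
    seed: int = 0,
) -> Iterator[MinimizerIndex]:
    """Sequence of sub-indexes, each holding just below ``memory_target`` entries.

    Contig order is randomly permuted (seeded) before packing, so chunks are
    reproducible. The multiset union of chunk posting lists equals the
    monolithic index. A single contig whose minimizer count exceeds the
    budget gets its own chunk (with a warning).
    """
    params = params or IndexParams()
    contigs = _as_contigs(genomes)
    if not contigs:
        raise ValueError("no input contigs")
    contig_map = _as_contig_map(genome_map, contigs)
    rng = np.random.default_rng(seed)
    order = list(contigs)
    rng.shuffle(order)

    chunk: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
    lengths: dict[str, int] = {}
    entries = 0
    for cid in order:
        h, p, s = _winnow_arrays(contigs[cid], params)
        if memory_target and h.size > memory_target:
            warnings.warn(f"contig {cid} alone exceeds the memory target")
        if memory_target and chunk and entries + h.size > memory_target:
            yield _assemble(chunk, lengths, contig_map, params)
            chunk, lengths, entries = [], {}, 0
        chunk.append((cid, h, p, s))
        lengths[cid] = len(contigs[cid])
        entries += h.size
    if chunk:
        yield _assemble(chunk, lengths, contig_map, params)
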