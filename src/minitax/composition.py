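"""Sample-composition estimation by EM over probabilistic read mappings.

The composition vector F assigns each database genome g the probability that
a random sample read emanates from g. With composition-independent mapping
qualities P_r(i) and effective start counts E_{r;g} held fixed, the
likelihood of a mapped read is

    L_C(r; F) = sum_g sum_{i in map(r,g)} P_r(i) * (1/E_{r;g}) * F_g

and EM alternates the composition-dependent posterior

    P_r(i; F) = P_r(i) * (1/E_{r;g(i)}) * F_{g(i)} / L_C(r; F)

with the update F'_g = sum_r sum_{i in map(r,g)} P_r(i; F) / |R|. F is
initialized uniform at 1/|G| and iterated until the relative log-likelihood
improvement falls below a tolerance. Unmapped long reads and sub-length
reads are counted to the 'unassigned' bin (taxon ID 0) in a final
renormalization over the complete read set, and each mapped read is assigned
to its maximum-posterior location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mapping import ReadMappingSet
from .taxonomy import Assignment, Taxonomy, UNASSIGNED


def effective_start_positions(read_length: int, contig_lengths: Sequence[int]) -> int:
    """Count of effective start positions E_{r;g} of a read in a genome.

    Contig length minus read length, summed over contigs and clamped to >= 1
    per contig so the likelihood stays defined for reads longer than a
    contig. Contigs are treated as linear.
    """
    if not contig_lengths:
        raise ValueError("genome must have at least one contig")
    return int(sum(max(c - read_length, 1) for c in contig_lengths))


@dataclass
class CompositionVector:
    """Final composition: genome fractions plus the unassigned (taxon 0) bin."""

    fractions: dict[str, float]
    unassigned_fraction: float = 0.0

    def total(self) -> float:
        return sum(self.fractions.values()) + self.unassigned_fraction


class _EMData:
    """Flattened candidate table shared by all EM iterations."""

    def __init__(
        self,
        mappings: Sequence[ReadMappingSet],
        genome_contig_lengths: dict[str, Sequence[int]],
    ):
        self.genomes = sorted(genome_contig_lengths)
        g_index = {g: i for i, g in enumerate(self.genomes)}
        self.mapped = [m for m in mappings if m.mapped]
        read_idx, genome_idx, weight = [], [], []
        for ri, rms in enumerate(self.mapped):
            e_cache: dict[str, int] = {}
            for cand in rms.candidates:
                g = cand.genome_id
                if g not in e_cache:
                    e_cache[g] = effective_start_positions(
                        rms.read_length, genome_contig_lengths[g]
                    )
                read_idx.append(ri)
                genome_idx.append(g_index[g])
                weight.append(cand.mapping_quality / e_cache[g])
        self.read_idx = np.asarray(read_idx, dtype=np.int64)
        self.genome_idx = np.asarray(genome_idx, dtype=np.int64)
        self.weight = np.asarray(weight, dtype=np.float64)
        self.n_reads = len(self.mapped)
        self.n_genomes = len(self.genomes)

    def posteriors(self, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-candidate posteriors P_r(i;F) and per-read likelihoods."""
        num = self.weight * F[self.genome_idx]
        denom = np.bincount(self.read_idx, weights=num, minlength=self.n_reads)
        bad = denom <= 0.0
        if np.any(bad):
            warnings.warn(
                f"{int(bad.sum())} read(s) with zero-mass candidates; "
                "using uniform posteriors for them this iteration"
            )
            counts = np.bincount(self.read_idx, minlength=self.n_reads)
            num = np.where(bad[self.read_idx], 1.0 / counts[self.read_idx], num)
            denom = np.where(bad, 1.0, denom)
        return num / denom[self.read_idx], denom


def _as_F_array(F, genomes: list[str]) -> np.ndarray:
    if isinstance(F, dict):
        return np.array([F[g] for g in genomes], dtype=np.float64)
    return np.asarray(F, dtype=np.float64)


def read_likelihood(
    rms: ReadMappingSet,
    F: dict[str, float],
    genome_contig_lengths: dict[str, Sequence[int]],
) -> float:
    """Likelihood L_C(r;F) of a single mapped read."""
    if not rms.mapped:
        raise ValueError("read has no candidates")
    total = 0.0
    for cand in rms.candidates:
        e_rg = effective_start_positions(
            rms.read_length, genome_contig_lengths[cand.genome_id]
        )
        total += cand.mapping_quality * (1.0 / e_rg) * F[cand.genome_id]
    return total


def composition_posterior(
    rms: ReadMappingSet,
    F: dict[str, float],
    genome_contig_lengths: dict[str, Sequence[int]],
) -> list[float]:
    """Composition-dependent posterior P_r(i;F) for each candidate of a read."""
    terms = []
    for cand in rms.candidates:
        e_rg = effective_start_positions(
            rms.read_length, genome_contig_lengths[cand.genome_id]
        )
        terms.append(cand.mapping_quality * (1.0 / e_rg) * F[cand.genome_id])
    denom = sum(terms)
    if denom <= 0.0:
        warnings.warn("degenerate posterior denominator; using uniform posteriors")
        return [1.0 / len(terms)] * len(terms)
    return [t / denom for t in terms]


def em_update(
    mappings: Sequence[ReadMappingSet],
    F: dict[str, float],
    genome_contig_lengths: dict[str, Sequence[int]],
) -> dict[str, float]:
    """One EM step: F'_g = sum_r sum_{i in map(r,g)} P_r(i;F) / |R|."""
    data = _EMData(mappings, genome_contig_lengths)
    post, _ = data.posteriors(_as_F_array(F, data.genomes))
    newF = np.bincount(data.genome_idx, weights=post, minlength=data.n_genomes)
    newF /= data.n_reads
    return dict(zip(data.genomes, newF))


class CompositionModel:
    """EM model of sample composition over probabilistic read mappings.

    Parameters
    ----------
    mappings
        Per-read mapping sets (mapping qualities already computed). Reads
        without candidates are retained for the final unassigned bin.
    genome_contig_lengths
        Contig lengths per database genome (used for E_{r;g}); typically
        ``index.genome_contig_lengths()``.
    """

    def __init__(
        self,
        mappings: Sequence[ReadMappingSet],
        genome_contig_lengths: dict[str, Sequence[int]],
    ):
        self.mappings = list(mappings)
        self.genome_contig_lengths = {
            g: list(v) for g, v in genome_contig_lengths.items()
        }
        self.data = _EMData(self.mappings, self.genome_contig_lengths)

    @classmethod
    def from_index(cls, mappings, index) -> "CompositionModel":
        return cls(mappings, index.genome_contig_lengths())

    def loglike(self, F: np.ndarray) -> float:
        _, denom = self.data.posteriors(F)
        return float(np.sum(np.log(denom)))

    def fit(self, tol: float = 1e-5, max_iter: int = 500) -> "CompositionResults":
        """Run EM from the uniform start 1/|G| until likelihood convergence."""
        data = self.data
        if data.n_reads == 0:
            raise ValueError("no mapped reads to fit")
        F = np.full(data.n_genomes, 1.0 / data.n_genomes)
        trace = []
        converged = False
        post = None
        for it in range(1, max_iter + 1):
            post, denom = data.posteriors(F)
            ll = float(np.sum(np.log(denom)))
            trace.append(ll)
            newF = np.bincount(data.genome_idx, weights=post, minlength=data.n_genomes)
            newF /= data.n_reads
            F = newF
            if len(trace) > 1:
                prev = trace[-2]
                if abs(ll - prev) <= tol * max(abs(prev), 1.0):
                    converged = True
                    break
        if not converged:
            warnings.warn(f"EM did not converge in {max_iter} iterations")
        post, denom = data.posteriors(F)
        trace.append(float(np.sum(np.log(denom))))
        return CompositionResults(self, F, post, trace, converged)


class CompositionResults:
    """Fitted composition with per-candidate posteriors and diagnostics."""

    def __init__(self, model, F, posteriors, loglike_trace, converged):
        self.model = model
        self.genomes = model.data.genomes
        self.F = np.asarray(F)
        self.candidate_posteriors = np.asarray(posteriors)
        self.loglike_trace = list(loglike_trace)
        self.converged = bool(converged)
        self.n_iter = len(loglike_trace) - 1
        # write posteriors back onto the candidate objects
        flat = 0
        for rms in model.data.mapped:
            for cand in rms.candidates:
                cand.posterior = float(self.candidate_posteriors[flat])
                flat += 1

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.F, index=self.genomes, name="fraction")

    @property
    def llf(self) -> float:
        return self.loglike_trace[-1]

    def summary(self) -> str:
        lines = [
            "Sample composition (EM over mapped reads)",
            "=" * 45,
            f"mapped reads:   {self.model.data.n_reads}",
            f"genomes:        {len(self.genomes)}",
            f"iterations:     {self.n_iter} (converged: {self.converged})",
            f"log-likelihood: {self.llf:.4f}",
            "-" * 45,
        ]
        for g, f in self.params.sort_values(ascending=False).items():
            lines.append(f"{g:<24s} {f:10.6f}")
        return "\n".join(lines)

    def finalize(
        self,
        taxonomy: Optional[Taxonomy] = None,
        denominator: str = "all-reads",
    ) -> tuple[CompositionVector, list[Assignment]]:
        """Scale F to the complete read set and assign each read.

        Unmapped long reads and (under ``denominator='all-reads'``)
        sub-length reads join the unassigned bin (taxon 0). Each mapped read
        is assigned its maximum-posterior location, with ties broken by
        higher mapping quality, then lexicographic genome id, contig and
        start.
        """
        if denominator not in ("all-reads", "long-reads"):
            raise ValueError("denominator must be 'all-reads' or 'long-reads'")
        mapped = unmapped_long = sub_length = 0
        assignments: list[Assignment] = []
        for rms in self.model.mappings:
            if rms.too_short:
                sub_length += 1
                if denominator == "all-reads":
                    assignments.append(
                        Assignment(rms.read_id, UNASSIGNED, None, rms.read_length)
                    )
                continue
            if not rms.mapped:
                unmapped_long += 1
                assignments.append(
                    Assignment(rms.read_id, UNASSIGNED, None, rms.read_length)
                )
                continue
            mapped += 1
            best = min(
                rms.candidates,
                key=lambda c: (
                    -c.posterior,
                    -c.mapping_quality,
                    c.genome_id,
                    c.contig_id,
                    c.start,
                ),
            )
            taxon = (
                taxonomy.strain_node_of(best.genome_id)
                if taxonomy is not None
                else UNASSIGNED
            )
            assignments.append(
                Assignment(rms.read_id, taxon, best.genome_id, rms.read_length)
            )
        n_total = mapped + unmapped_long
        if denominator == "all-reads":
            n_total += sub_length
        if n_total == 0:
            return CompositionVector({g: 0.0 for g in self.genomes}, 1.0), assignments
        scale = mapped / n_total
        comp = CompositionVector(
            fractions={g: float(f) * scale for g, f in zip(self.genomes, self.F)},
            unassigned_fraction=(n_total - mapped) / n_total,
        )
        return comp, assignments


def run_em(
    mappings: Sequence[ReadMappingSet],
    genome_contig_lengths: dict[str, Sequence[int]],
    tol: float = 1e-5,
    max_iter: int = 500,
) -> CompositionResults:
    """Convenience wrapper: build the model and fit it."""
    return CompositionModel(mappings, genome_contig_lengths).fit(tol, max_iter)


def project_composition(
    comp: CompositionVector | dict[str, float],
    taxonomy: Taxonomy,
    level: str,
) -> dict[int, float]:
    """Sum genome masses into taxon buckets at a named level.

    Mass whose strain node projects to 0 at the level joins the unassigned
    bin (key 0). Output sums to the input total.
    """
    if isinstance(comp, CompositionVector):
        fractions, unassigned = comp.fractions, comp.unassigned_fraction
    else:
        fractions, unassigned = comp, 0.0
    out: dict[int, float] = {UNASSIGNED: unassigned}
    for genome, mass in fractions.items():
        node = taxonomy.strain_node_of(genome)
        bucket = taxonomy.to_level(node, level)
        out[bucket] = out.get(bucket, 0.0) + mass
    if out[UNASSIGNED] == 0.0:
        del out[UNASSIGNED]
    return out


def median_identities(mappings: Sequence[ReadMappingSet], assignments: Sequence[Assignment]) -> dict[str, float]:
    """Median estimated identity per genome over finally-assigned reads."""
    by_read = {m.read_id: m for m in mappings}
    pools: dict[str, list[float]] = {}
    for a in assignments:
        if a.genome_id is None:
            continue
        rms = by_read[a.read_id]
        ident = max(
            (c.identity_hat for c in rms.candidates if c.genome_id == a.genome_id),
            default=np.nan,
        )
        pools.setdefault(a.genome_id, []).append(ident)
    return {g: float(np.median(v)) for g, v in pools.items()}


def filter_composition_by_identity(
    comp: CompositionVector,
    medians: dict[str, float],
    threshold: float = 0.80,
) -> CompositionVector:
    """Remove strain entries whose median alignment identity is below a cutoff.

    Removed mass moves to the unassigned bin so the composition still sums to
    1; level projections of the filtered composition lose the removed
    strains' contributions at every level. Genomes without a median (no
    assigned reads) are kept.
    """
    kept: dict[str, float] = {}
    moved = 0.0
    for genome, mass in comp.fractions.items():
        med = medians.get(genome)
        if med is not None and med < threshold:
            moved += mass
        else:
            kept[genome] = mass
    return CompositionVector(kept, comp.unassigned_fraction + moved)
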