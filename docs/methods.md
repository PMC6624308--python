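# Methods

## Model overview

`minitax` treats metagenomic read classification as two coupled inference
problems: *where* each long read maps, and *what* the sample is made of.
The two are linked through a composition-dependent prior: the likelihood of
mapping location i for read r is P_r(i) · (1/E_{r;g}) · **F**_g, the product
of a composition-independent mapping quality, a genome-size regularizer, and
the (unknown) abundance of the genome the location belongs to. Reads from
genomes with close relatives in the database are ambiguous under a uniform
prior; estimating **F** by EM and re-weighting placements by it resolves
much of that ambiguity.

### Mapping qualities

For each read, candidate loci are scored by a binomial model of the
winnowed-minhash sketch intersection: conditional on a per-read error rate
e, each k-mer of the union sketch (size n = |S_{r∪i}|) survives sequencing
intact with probability p = (1 − e)^k, so the intersection count is
Binomial(n, p). The mapping quality P_r(i) is the candidate's PMF value
normalized over all of the read's candidates (computed in log space, so a
read whose every PMF underflows still gets well-defined qualities summing to
1). e is read-specific and unknown; it is set to 1 minus the estimated
identity of the read's best candidate. Model assumptions worth keeping in
mind: errors are uniform and independent across the read, and sketch
intersections are treated as n independent survival trials — both are
approximations (real platforms have context-dependent errors; minimizer
selections are weakly dependent).

### Identity estimation

Identity is estimated per candidate via the winnowed-minhash statistic: with
S_r and S_i the winnowed minimizer sets of read and reference window, and
S_{r∪i} the s smallest hashes of their union,
Ĵ = |S_{r∪i} ∩ S_i ∩ S_r|/|S_{r∪i}| estimates the k-mer Jaccard similarity
and (2Ĵ/(1+Ĵ))^(1/k) the per-base identity (the Poisson/Mash mapping
between k-mer survival and Jaccard). The sketch size is
s = min(|S_r|, |S_i|, sketch_target). A small negative bias (~0.0005 on
identity) arises because read-edge windows select minimizers the global
reference winnowing does not; it is far inside the ±0.02 calibration band
asserted by the tests.

### Candidate generation

Read minimizers are looked up in the index; each (read offset p, reference
position q, relative strand) match votes for a start diagonal (q − p
forward, q − (L − k − p) reverse). Matches per (contig, strand) are sorted
on the diagonal and clustered with a two-pointer pass using slack
max(2w, 0.02·L) to absorb indel drift; clusters with at least m_min matches
become candidates of read-length extent. The candidate start is taken from
the match closest to the drift-free end of the read for its orientation
(5′-most match on the forward strand, 3′-most on the reverse), which is
exact up to the first indel. m_min inverts the identity estimator at the
minimum identity: J_min = id_min^k/(2 − id_min^k) scaled by the expected
sketch size of a minimum-length read (m_min = 3 at the defaults). Candidates
below the minimum identity after estimation are dropped. The stage-2 filter
acts on the identity estimate itself (not on raw intersection counts); this
choice keeps the threshold semantics identical to the reported identity.

### EM composition estimation

E_{r;g} counts effective start positions of read r in genome g:
Σ_contigs max(contig_length − read_length, 1), contigs treated as linear.
The per-contig clamp to 1 keeps the likelihood defined when a read is longer
than a contig; it differs from the raw "length minus read length" only in
that degenerate case. P_r(i) and E_{r;g} are computed once and held fixed;
only **F** changes across iterations. **F** starts uniform at 1/|G| and EM
iterates until the relative change in total log-likelihood drops below 1e-5
(default; max 500 iterations, non-convergence returned flagged). Genomes may
reach F_g = 0 exactly; a read whose every candidate lies in zero-mass
genomes receives uniform posteriors for that iteration, with a warning,
rather than an invented prior floor.

Finalization scales **F** to the complete read set: unmapped long reads and
sub-length reads join the unassigned bin (taxon 0) and genome fractions are
multiplied by the mapped fraction, so all bins sum to 1. Sub-length reads
are included in the denominator by default; `denominator='long-reads'`
excludes them for comparisons against tools that never see those reads. Each
mapped read is assigned to its maximum-posterior location; exact ties break
by higher mapping quality, then lexicographic genome id, contig id, and
leftmost start, making outputs byte-identical across runs and read
orderings.

Identifiability: genomes with identical sequence in the database split a
read's posterior evenly, and EM preserves that split (a twin test asserts
this); strain-level estimates for indistinguishable strains are therefore
arbitrary within their species total, which is itself correct.

### Database-mismatch filtering

Per-genome median estimated identities over finally-assigned reads are a
mismatch diagnostic: strains whose median falls below a threshold (default
0.80) can be removed from the composition, their mass (and hence their
contribution at every higher level) moving to the unassigned bin. Genomes
with no assigned reads have no median and are kept.

## Taxonomy

Ranks are the named NCBI levels plus `strain` and `root`; `to_level` walks
the parent chain past unnamed ("no rank") nodes and returns 0 when the path
lacks the requested rank or the query is broader than it. At `strain`, a
node projects to itself iff a mappable genome is attached. Genomes mapped to
a childless, genome-free taxon attach in place (strain and species are then
synonymous for that genome); otherwise — the taxon has children, another
genome, or several genomes map to it — each genome gets a synthetic strain
leaf. Synthetic IDs are allocated sequentially from 1,000,000,000 in sorted
genome order and recorded in a sidecar table, so extension is reproducible.

## Index

Canonical k-mers (minimum of the 2-bit encodings of a k-mer and its reverse
complement; palindromes count as forward) are hashed with a splitmix64
finalizer under a fixed seed constant, so indexes are identical across
processes. Winnowing keeps the leftmost minimum-hash k-mer of every window
of w k-mers; k-mers containing ambiguous bases never become minimizers.
Expected winnowing density is 2/(w+1), so the auto-tuner sets
w = ⌊2·min_read_length/sketch_target − 1⌋ (w = 9 at the defaults
min_read_length 1000, sketch_target 200), clamped to ≥ 1 with a warning when
the target is infeasible. Coordinates are 0-based half-open everywhere.

Memory-limited builds randomly permute contig order (seeded) and pack
contigs sequentially into sub-indexes holding just under the entry budget; a
single contig exceeding the budget gets its own chunk with a warning. Reads
are mapped against every chunk and candidates pooled before identity
filtering and quality computation, so chunked and monolithic classification
produce identical outputs (asserted exactly in tests).

## Synthetic data

The simulator emulates a pbsim-style run at the defaults used throughout:
read lengths log-normal with mean 5000 (σ_log = 0.45), truncated below at
half the minimum read length so sub-length reads exist; per-base accuracy
0.88; errors 90% substitutions and 10% indels (split evenly
insertion/deletion) — the substitution-dominant CLR-like mix, configurable.
Genomes derive from a common random ancestor mutated per species at the
configured divergence (default 0.10) and per strain at strain_divergence
(default 0.02); species are grouped under genera in an emitted toy taxonomy.
Abundances are log-normal (σ = 1) or uniform. Everything is a deterministic
function of the seed, and FASTA/FASTQ/truth outputs are byte-identical
across runs.

What the simulator does *not* emulate: context-dependent and homopolymer
errors, chimeric reads, quality-score structure, real phylogenetic depth
(divergence tiers are uniform), GC/coverage biases, and plasmids or shared
mobile elements. Passing benchmarks on these mixtures therefore demonstrate
the correctness and calibration of the algorithms — identity estimates
tracking the simulated error rate, composition recovery (strain-level
r² ≥ 0.95, L1 ≤ 0.1 on a 10-genome log-normal mixture with 20 Mb of reads),
contaminant rejection — not performance on real communities, where database
incompleteness dominates.

## Problem sizes and numerical choices

Desk-scale study conditions used by the test suite and acceptance script:
identity calibration on a 1 Mb genome with 500 reads of mean length 5 kb;
composition recovery on 10 × 100 kb genomes with 20 Mb of reads (4000
reads); chunked-equivalence and contaminant runs on 5 × 50 kb genomes.
Tolerances: EM monotonicity slack 1e-9; posterior and composition sums
checked to 1e-9; identity calibration ±0.02. Degenerate inputs are defined
behaviors, not errors: sequences shorter than k winnow to nothing,
candidates with empty window sketches are dropped, empty candidate lists
mean "unmapped", and an all-unmapped read set yields a composition that is
pure unassigned mass.

## Known limitations

- No base-level alignment: intervals are read-length extents anchored on
  minimizer matches, accurate to a few bases but not CIGAR-exact.
- No split/chimeric or spliced mapping.
- The density auto-tuner uses the expected-count rule 2L/(w+1) ≥ target; it
  reproduces the intended behavior (density tied to minimum read length and
  identity) but is a stand-in for the tuning rule of the original
  approximate-mapping literature, which is not restated here.
- Streaming ("sequence until") updates and an explicit genomic-novelty term
  are out of scope.
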