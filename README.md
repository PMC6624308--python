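# minitax

Strain-level taxonomic classification of long metagenomic reads (PacBio /
Oxford Nanopore) against a reference genome database, with estimation of
overall sample composition.

Long reads are error-rich, but long enough that many short exact k-mer
matches survive between a read and its true source locus: a 1000 bp read at
a uniform 15% error rate still retains, in expectation,
(L − k + 1)·(1 − e)^k ≈ 73 exact 16-mers. `minitax` exploits this with an
approximate, alignment-free mapping pipeline:

1. **Minimizer index** — references are winnowed (minimum-hash k-mer per
   window of w consecutive k-mers, canonical over both strands); the window
   size is auto-tuned from the minimum read length and minimum identity so a
   minimum-length read keeps ≈ 200 minimizers.
2. **Identity estimation** — for each candidate locus, the Jaccard
   similarity of read and reference-window k-mer sets is estimated from the
   s smallest hashes of the sketch union,
   Ĵ = |S_{r∪i} ∩ S_i ∩ S_r| / |S_{r∪i}|, and converted to an alignment
   identity estimate (2Ĵ/(1+Ĵ))^(1/k).
3. **Mapping qualities** — per read, candidate scores are binomial
   probabilities of the observed sketch-intersection counts with
   n = |S_{r∪i}| and k-mer survival rate p = (1 − e)^k; normalizing them
   gives composition-independent posteriors P_r(i).
4. **EM composition** — the sample composition **F** (probability that a
   random read emanates from each database genome) maximizes
   L_C(R;**F**) = ∏_r Σ_g Σ_{i∈map(r,g)} P_r(i)·(1/E_{r;g})·**F**_g, where
   E_{r;g} is the count of effective read start positions in genome g. EM
   alternates composition-dependent posteriors P_r(i;**F**) with the update
   **F**′_g = Σ_r Σ_i P_r(i;**F**)/|R|. Reads are finally assigned to their
   maximum-posterior location; unmapped and sub-length reads enter an
   explicit "unassigned" bin (taxon ID 0) and the composition is
   renormalized over the complete read set.

The taxonomy is an NCBI-dialect tree extended with one strain-level leaf per
mappable genome, so "strain-level" accuracy means source-genome resolution.
The package also ships the full evaluation-metric suite (per-level
precision / recall / precision2, read- and base-weighted; compositional L1,
r², and presence/absence metrics), per-genome diagnostics (identity
histograms, windowed coverage, functional-group overlap counts from GFF3
annotations), and a pbsim-style read simulator so the entire pipeline is
testable at desk scale without downloads.

## Worked example

Simulate a 5-genome mock community (50 kb genomes, 10% divergence, 2 Mb of
reads at accuracy 0.88), classify it, and score the result:

```bash
cat > sim.yaml <<EOF
n_genomes: 5
genome_length: 50000
divergence: 0.1
total_bases: 2000000
seed: 11
EOF
minitax simulate --config sim.yaml --out data
minitax classify --db data/genomes.fasta --map data/contigs.tsv \
    --reads data/reads.fastq --taxonomy data --out run --seed 11
minitax evaluate --truth data/truth.tsv --calls run.assignments.tsv \
    --taxonomy data --out metrics.tsv
```

which prints

```
simulated 400 reads from 5 genomes
classified 400 reads (unassigned fraction 0.003, EM iterations 3)
  level  precision  recall  precision2  precision_bases  recall_bases  precision2_bases
 strain     0.9975  0.9975         1.0         0.996379      0.996379               1.0
species     0.9975  0.9975         1.0         0.996379      0.996379               1.0
```

399 of 400 reads are placed on their source genome; the one read left at
taxon 0 costs precision/recall 1/400 while precision2 (accuracy of non-0
calls) stays 1. The composition tables (`run.composition.<level>.tsv`) carry
per-taxon fractions that sum to 1 including the unassigned bin, and
`run.genomes.tsv` reports per-genome median identities (≈ 0.8806 here,
matching the simulated accuracy 0.88) used by `minitax filter` to drop
low-identity strains indicative of database–sample mismatches.

Library users can drive the same machinery through model objects:

```python
from minitax import CompositionModel, build_index, map_reads

index = build_index("data/genomes.fasta", "data/contigs.tsv")
mappings = map_reads("data/reads.fastq", index)
results = CompositionModel.from_index(mappings, index).fit()
print(results.summary())
composition, assignments = results.finalize(taxonomy)
```

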