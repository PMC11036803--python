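# Methods

This note documents the models and procedures implemented in `virome`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Synthetic study model

`virome.synthgen` generates a complete two-group cohort from one seed
(stage seeds are fanned out via `numpy.random.SeedSequence`, so the whole
study is byte-reproducible).

**Sequences.** Viral species are i.i.d.-uniform nucleotide ancestors
(default 200 species, lengths uniform on 5–20 kb, respecting the 5 kb
contig floor) plus `members_per_species` (default 3) full-length
substitution-only mutants at per-base rate `mutant_divergence`
(default 0.02). Substitution-only mutation keeps ANI analytically
predictable: ancestor–member ANI ≈ 1 − d, member–member ANI ≈ (1 − d)²,
both safely above the 95% clustering threshold for d ≤ 0.02, which is why
the config rejects d ≥ 0.05. Decoys (default 100) are independent random
sequences; two random 5–20 kb sequences share no 15-mer in practice, so
decoys never align to virals. No indels are simulated; the alignment layer
handles them, but the benchmark does not exercise indel-rich divergence.

**Hosts and links.** Bacterial genomes (default 20, 30–60 kb) are random
sequences, resampled if they collide with any viral 21-mer, so non-linked
hosts carry *no* viral homology by construction (asserted at generation
time). CRISPR links (default 30) copy an exact 25–40 bp viral substring
into a host's spacer table (and render a repeat–spacer array onto the
genome); prophage links (default 10) embed a 2 kb viral segment mutated at
3% (≈ 97% identity) at non-overlapping host positions — overlap avoidance
matters because a later insert overwriting an earlier one would silently
shorten the planted homology below the 1 kb link floor. Links are planted
only on species ancestors that survive decontamination, i.e. on the
sequences that become vOTU representatives, matching how host prediction
is applied to the catalog.

**Evidence.** True virals draw a random subset of the three triage
criteria to pass (at least one forced); decoys are constructed to fail all
three. A fraction (default 5%) of virals receive BUSCO counts strictly
above the 5% ratio cutoff (recorded as planted contaminants); the rest stay
at or below it. Completeness values are drawn from the five-tier mix
observed in real gut-virome catalogs (5.1 / 6.5 / 14.3 / 43.0 / 31.1% for
Complete / High / Medium / Low / Undetermined).

**Protein hits.** Each species is assigned a true family (70% of species)
or left unclassified. Family-bearing contigs get 30–60% of proteins
best-hitting the true family (floored above the quarter-vote); background
hits to other families are capped below the vote threshold so the truth
label is exact. Unclassified species never let any family exceed 25%.

**Abundances.** Per-feature location μᵢ ~ N(0, 1.5), per-sample
log-abundance μᵢ + ε with ε ~ N(0, 1) — log-normal abundances with σ = 1,
a standard compositional benchmark. The `n_diff` differential features
(default 40) have group means separated by `effect_log2fc`·ln 2 (default
2 log₂ units, i.e. ±0.69 nats per group). Planted virus–bacterium pairs
share a per-sample latent factor with loading λ = 2.5 on the log scale in
both groups, giving latent Pearson (hence approximately Spearman)
correlation λ²/(λ²+1) ≈ 0.86; the bacterium's loading sign sets the edge
sign. Viral counts are multinomial at `depth` per sample (default 200,000,
a scaled-down stand-in for rarefying to 4 million reads — chosen so the
benchmark runs on a laptop while keeping mean per-feature counts ≈ 1,000,
far from the sparse regime that destabilizes rank tests); bacterial
profiles are emitted directly as relative abundances (they stand in for an
externally provided bacteriome table, default 74 species).

**What the benchmark does not emulate:** sequencing error and read-level
artifacts, indel/rearrangement divergence, strain mixtures within a
species, compositional correlations induced by the closure itself, batch
effects, and covariate–group confounding. Passing tests therefore
demonstrate correctness of the statistical machinery and recoverability
under the declared generative model, not robustness to every property of
real metagenomes.

## Catalog

Triage combines the three criteria as a union (OR). The upstream pipelines
this emulates pool candidates from all three detectors and apply
stringency downstream (decontamination); an `intersection` mode is exposed
(`--triage-mode`). Strict inequalities throughout (score > 0.90,
p < 0.01, BUSCO ratio > 5% eliminates); contigs with zero annotated genes
have an undefined BUSCO ratio and are retained with a warning.

Pairwise similarity: candidate pairs are screened by strand-canonical
15-mer sketches (value-sampled at 1/16, so sampling is position- and
orientation-independent); pairs sharing anchors are aligned with edlib,
the shorter sequence as an infix of the longer (free end gaps on the
longer), orientation chosen by shared k-mer counts. ANI = matched columns /
alignment columns from the extended CIGAR; AF = aligned span / length,
tracked per sequence. This reproduces a full dynamic-programming alignment
to within 0.1 pp on substitution-divergent pairs (tested against a
Biopython oracle at ≤ 2 kb). Limitations: dovetail overlaps (neither
sequence containing the other) are penalized as end gaps, and pairs
sharing no exact 15-mer (≈ > 25% divergence) report "no alignment" — both
far outside the 95%-ANI regime the clustering rule cares about.

Clustering is greedy centroid assignment ordered by length descending
(ties lexicographic), aniclust-style, with the AF gate applied to **both**
sequences; this prevents short fragments from being absorbed into long
genomes and makes the result independent of input order. Quality tiers:
Complete is taken from the upstream completeness flag; the 50–90 band is
inclusive on both ends.

## Annotation

The quarter-vote denominator is *all* predicted proteins of the vOTU,
including proteins with no database hit; only best hits (highest bitscore,
ties by target id) vote. Ties between qualifying families yield
`unclassified`.

Spacer matching tolerates ≤ 1 mismatch over the spacer's full length on
either strand (standard spacer-matching practice balancing sensitivity
against a per-comparison false-positive probability < 10⁻⁸ for ≥ 25 bp
spacers), implemented by pigeonhole seeding (an ≤ 1-mismatch window
contains an exact half). Prophage thresholds are 1 kb at 90% identity —
the cutoffs are this package's defaults (exposed as parameters) in the
spirit of prophage-blast protocols; blocks are found by diagonal-clustered
21-mer anchors and realigned with edlib.

## Ecology

Shannon in natural log and Simpson as 1 − Σp² (the vegan defaults).
Accumulation curves subsample k samples without replacement (union
richness, mean ± sd over 30 replicates). PERMANOVA is run marginally, one
model per factor; the hat matrix comes from [1 | X] with dummy coding for
categorical factors, F = [tr(HGH)/m]/[tr((I−H)G(I−H))/(n−m−1)] on the
Gower-centered squared-distance matrix, verified to match both the classic
within/between decomposition and scikit-bio's implementation exactly.
Permutation p uses the +1/+1 convention; permutations that recompute F for
the observed grouping are counted as ties via a 10⁻¹⁰ relative tolerance
(pure float comparison would drop them at random). Adjusted R² =
1 − (1−R²)(n−1)/(n−m−1). PCoA drops negative eigenvalues (no Cailliez
correction); variance ratios are over the positive spectrum.

## Markers

Mann–Whitney U is exact for combined n ≤ 20 without ties, tie-corrected
normal approximation otherwise (scipy). BH adjustment runs across tested
features only; features constant across all samples are excluded first and
do not inflate the correction denominator. The fold change uses a
pseudocount of half the smallest nonzero abundance in the matrix
(scale-aware; keeps zero-mean features finite), and the marker gate is
q < 0.05 **and** fold change beyond 1.2× — the fold-change screen is on by
default with a `use_fc_gate=False` escape hatch, since a q-only rule is
the other defensible reading of the protocol.

## Networks

Spearman with average ranks; the 0.6 threshold is applied to |ρ| with the
sign retained as an edge attribute (the sign convention is ambiguous in
common usage; thresholding the absolute value is the inclusive choice and
a positive-only mode is a one-line filter). No p-value gate on edges.
Sharing is pair-identity only (sign-agreement left to the caller);
degrees and rankings break ties lexicographically.

## Classifier

Random forest with 500 trees and √p features per split (the R
randomForest defaults this analysis style relies on), evaluated by 5
repeats of stratified 5-fold CV. Out-of-fold probabilities are pooled
within each repeat into one ROC AUC; the reported AUC is the mean over
repeats. The 95% CI is Hanley–McNeil on the repeat-averaged out-of-fold
predictions — a rank-based SE that needs no refitting; a bootstrap would
also be defensible but is slower and noisier at n = 77. Importance is
permutation-based mean decrease in accuracy on each fold's held-out
samples (3 shuffles per feature, averaged over all folds). The panel sweep
retrains on top-k features (k ∈ {5, 10, …, 50} by default) with 10
independent CV repetitions per k, reporting mean ± sd AUC; best k is the
argmax of the mean with ties broken toward the smaller panel.

## Pipeline

`virome run` fans a single global seed out into per-stage seeds
(SeedSequence), executes catalog → annotate → profile → ecology → markers
→ netassoc → classify, writes each stage's outputs into its own directory,
and records a timestamp-free JSON manifest (package, config hash, stage
seeds, per-stage file lists) so identical (config, seed) runs are
file-identical. `<stage>.done` markers let interrupted runs resume.
Stage failures abort with the stage name and the offending input (the
evidence reader, for instance, reports the 1-based line number of the
first malformed row). The `--demo` profile shrinks the generator
(50 species, 15+15 samples, 200-tree forest) for a subminute smoke run;
analysis drivers and the acceptance script use the full design scale.

## Numerical notes

- Row-normalized abundances sum to 1 within 10⁻⁹; family rollup pools
  unclassified mass into its own column so totals are conserved exactly.
- Subsampling is multivariate hypergeometric (without replacement) rather
  than multinomial: rarefying draws from the realized read pool. Samples
  below the target depth raise an error naming the sample rather than
  being dropped silently.
- All orderings that could be tie-broken (cluster members, degree
  rankings, importance orderings, family votes) break ties
  lexicographically, making every output deterministic under a fixed seed.
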