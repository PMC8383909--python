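# Methods

This note documents the models, numerical choices and limitations behind
`mamut`. It covers, in order: the synthetic-data generator, the calling
filters, the rate and clustering statistics, the context features, the
spectrum statistics, and the mutability model.

## Synthetic MA experiments

The generator emulates the data structure of a mutation-accumulation
experiment in a GC-rich unicellular alga: a reference genome of ~66% GC,
26 clonal lines bottlenecked through single colonies for ~788
generations, roughly 2,600 accepted mutations genome-wide of which ~24%
are short INDELs, and per-site call-quality annotations from a
multi-sample haploid caller.

**Genome.** Bases are i.i.d. with P(G) = P(C) = gc/2. A configurable
fraction of each contig is overwritten with repeat blocks — tandem
repeats of a 1 bp (low-complexity) or 2–6 bp (microsatellite) unit, or
shuffled 500 bp templates (TE) — whose base composition preserves the
target GC in expectation. Gene models (UTR5–exons/introns–UTR3) are
tiled with intergenic gaps sized so genome-wide proportions land near
30% CDS, ~3.5% UTR and ~20% intron; everything else is intergenic.
Coordinates are 0-based half-open internally; VCF output is 1-based and
BED 0-based, per those standards.

**Mutations.** Per line the event count is Poisson(m·μ·L·t) where the
line multiplier m is lognormal with `sdlog = 1.15` (matching the
between-line heterogeneity of the emulated study) normalized to unit
mean, so μ stays the across-line mean rate. Folded SNM types are drawn
from a six-type spectrum (default C→T share 0.52, transitions above
transversions) and a site of the matching source-base class is then
sampled — this makes the realized folded spectrum converge to the
configured probabilities irrespective of genome GC. Site sampling is
weighted by canonical *upstream*-context multipliers (default CTC ×10,
CAC ×6, mirroring the hypermutable contexts reported for
*Chlamydomonas*); weighted sampling without replacement uses Gumbel
top-k. INDEL lengths are geometric with mean 3 bp (deletions) and 2 bp
(insertions), consistent with the reported medians of 2 and 1 bp; the
deletion:insertion split is 350:268. SNMs and INDELs share the line
multiplier, which reproduces the observed r > 0.97 correlation of their
per-line counts.

**Call records.** The noise model is parametric and per-site: low-MQ
regions, low-QUAL and low-GQ site fractions, Gaussian combined depth,
plus two record-level artifact classes — rejectable false-positive
singletons (low GQ or excess reference reads) and ≥14-line shared-alt
artifact sites that exercise the neighborhood filter. There is no
read-level simulation: the filters only consume summary fields
(MQ/QUAL/DP/GQ/AD), so a site-level model is sufficient and keeps the
default 2 Mb × 26-line experiment well under a minute. `NoiseModel()`
is noiseless (used for closure tests: precision = recall = 1 inside the
callable mask); `NoiseModel.realistic()` reproduces a ~72% callable
fraction like the study this emulates. Spike-in probes are planted at
the midpoint of every 27 kb interval and emitted round-robin across
lines so each is a single-line alternate allele, as in per-line spike-in
alignments; at the reduced genome scale the per-line probe counts are
small, so the per-line callability table is indicative while the overall
rate is well estimated.

**Scale.** The default pipeline genome is 2 Mb (spec'd down from
129 Mb); the default per-site rate is scaled up by the same factor so
the expected mutation yield (~100 events per line) matches the
experiment being emulated. Tests use 60–400 kb genomes. What passing
tests show is therefore fidelity of the *statistical structure* (rate
heterogeneity, spectrum, context effects, filter behavior), not of
genome-scale LD between features, long repeats, alignment artifacts or
read-level error processes, which the generator does not model.

## Calling filters

Thresholds follow the published cascade: MQ ≥ 50; QUAL ≥ 100 nuclear /
70 organelle; combined DP ≥ a per-class threshold, by default recomputed
as mean − 1 SD of the data (the rule the original value 167 was derived
with — fixed values are configurable); ≥ 3 haploid lines at the GQ
maximum of 99 (the focal line counts toward the three). Candidates must
be biallelic single-line alternates at GQ = 99 with ≥ 6 reads and a
reference-read *fraction* ≤ 1/6 (fraction, not "1 read of 6"), and no
site within ≤ 10 bp (inclusive, including distance 0) where ≥ 14 lines
carry > 1/6 alternate reads. All rules are conjunctive, so the accepted
set is order-independent and tightening any threshold is monotone.
Rejections are logged with the first failing rule; accepted INDEL/INV
calls are additionally placed on a review list, replacing the manual
IGV curation step of the original workflow without claiming to automate
it. The contamination screen flags line pairs whose alternate-allele
sharing exceeds mean + 5 SD of the off-diagonal entries; complete
sharing (share = 1) is always flagged since the SD rule is degenerate
when all entries are equal.

## Rates, overdispersion, clustering

`μ = Nμ/(Nc·Nlines·t)` is an exact quotient; stratified estimates
adjust numerator and denominator (per-line-and-generation rates use
Nc = 1). Generations come from colony counts, `t = log2(Nt/N0)`, summed
over transfers, with unmeasured lines imputed at the mean of measured
ones.

Distribution fits are maximum likelihood with AIC ranking; the
comparison applies discrete (Poisson) and continuous families to the
same numeric vector — a caveat inherited from the procedure this
mirrors, flagged here rather than hidden. Degenerate input fails the
scale families explicitly. The overdispersion test assumes equal
generations across lines; its KS p-value against Poisson(λ̂) is a
parametric bootstrap (default 2,000 replicates, λ re-estimated per
replicate) because the asymptotic KS distribution is invalid for
discrete data. The neutral null simulation draws `n_lines` Poisson
counts per replicate and summarizes the sample variances by median and
central 95% interval.

IMD and window-count clustering compare observed statistics with
equal-count uniform placements on callable positions. Significance is a
Monte-Carlo p-value: the two-sample KS statistic of the observed sample
against the pooled null is ranked among the same statistic computed for
each null replicate, `p = (1 + #{D_r ≥ D_obs})/(iters + 1)`. This keeps
the type-I error at nominal level for heavily tied discrete window
counts, where asymptotic two-sample KS p-values are badly conservative.
The short-range table reports <10 bp and adjacent-pair excess over the
null mean, with reference dinucleotides at adjacent pairs when the
genome is available.

## Context features

Windows are "site ± w, site included", i.e. length `2w+1` for
w ∈ {2, 10, 100, 1000} — which makes the Δ-statistic window lengths
{5, 21, 201, 2001} exactly consistent. E is base-composition entropy
normalized by 2 bits. L is the Trifonov-style distinct-substring ratio:
distinct substrings of length 1..K over `Σ_k min(4^k, n−k+1)`. The
scalar API uses the full range K = n; the windowed pipeline caps
K at 16 (configurable): at the 5 and 21 bp scales the cap is not
binding so the full-range definition is recovered exactly, and at
201/2001 bp the k ≤ 16 vocabulary already saturates the discriminative
signal while allowing an O(n) sliding computation (distinct k-mers per
window via previous-occurrence counting; window statistics and their
running SDs via cumulative sums, with values centred first and a 1e-6
floor snapping cancellation noise to zero — the smallest genuine
nonzero SD at these window sizes is ~1e-5).

ΔGC/ΔE/ΔL are the population SD (ddof = 0) across the W windows of
length W overlapping the focal site; the alternative reading of
"averaged" — averaging per-phase SDs — would be a different estimator
and is not implemented. Sites whose windows leave the contig or touch an
ambiguity code get missing values and are dropped from modelling rather
than imputed.

Trinucleotide contexts follow the worked convention: for AGATA with
focal middle A, (up, mid, down) = (AGA, GAT, ATA); focal G/T sites are
reverse complemented with up/down swapped, so the focal base is always
A or C. Each slot then has exactly 32 canonical triplets, with the
focal base at slot-specific position (3rd/2nd/1st) — the hypermutable
"CTC" is an upstream triplet: a C preceded by CT. Feature classes apply
CDS > UTR5/UTR3 > intron precedence; unannotated sites are intergenic.

Motif definitions (palindrome arm ≥ 5 = RC of opposite arm, loop 0–5;
mirror arm ≥ 5 = reverse of opposite arm; G4 = four runs of ≥ 3 G with
1–7 nt loops, either strand; triplex = homopurine/homopyrimidine mirror
repeat, arm ≥ 6, loop ≤ 8) are all configurable, since the external
scanners they mirror do not publish their thresholds; numeric identity
with those tools is not claimed. Enrichment compares the proportion of
site-centred windows containing ≥ 1 motif between mutated and random
sites with a Kruskal–Wallis rank test and 1,000-sample bootstrap CIs.

## Spectrum and Ka/Ks

Folding maps the 12 strand-specific SNM types onto 6 with the reference
base A or C; `fold(comp(ref), comp(alt)) = fold(ref, alt)`. Under equal
per-type rates the expected share of each C-source type is `gc/3` and of
each A-source type `(1−gc)/3`; the deviation is observed/expected share,
with a χ² goodness-of-fit against the expectation. This expected-share
form exactly reconciles a 52% C→T share at GC = 0.66 with a 2.36-fold
deviation. The correction uses whole-genome GC by default; conditioning
on callable-site composition instead is a caller-side choice
(`gc` is an explicit argument).

Ka/Ks uses equal-weight pathway counting: per-codon synonymous site
fractions (each position contributes the fraction of its three changes
that are synonymous), substitutions classified by codon effect (stop
gains/losses count as nonsynonymous), and
`ratio = (N_obs/N_sites)/(S_obs/S_sites)` with no multiple-hit
correction — appropriate for MA data where each codon carries at most a
few independent mutations. A Fisher exact test on the 2×2
observed-vs-sites table accompanies the ratio. No
transition/transversion weighting is applied.

## Mutability model

Predictors: the 24 windowed statistics, 3 × 32 context indicators,
feature-class and repeat-class indicators, and per-class feature
distances. Rows with any missing value are removed. Near-zero-variance
columns (<2 distinct values, or minority frequency < 1e-4) are dropped
and all remaining columns are centred and scaled to unit SD — using
training-row statistics only, so test rows never leak into the scaling.
The classifier is elastic-net-penalized logistic regression (mixing
parameter 0.5 by default; the original analysis does not print its
value) with the penalty strength chosen at minimum cross-validated
deviance over a log-spaced grid, folds stratified by label (fold
assignment was unspecified in the original; stratification is our
choice). The fit is repeated over replicates (default 10), each drawing
its own non-mutated training sample from callable sites (uniform,
without replacement, excluding mutated positions, seed recorded);
coefficient medians and percentile 95% CIs come from the replicate
ensemble. Class imbalance is left as-is in the mutability model (raw
imbalanced sets, as in the original); the binary C→T classifier
optionally balances by down-sampling, up-sampling or an internal
SMOTE-style nearest-neighbour interpolation. The C→T task drops
GC-derived predictors and reduces contexts to flanking dinucleotides so
the focal base cannot leak the label. A six-type multinomial classifier
is deliberately omitted: the analysis this package mirrors found it
never exceeded chance.

Calibration bins the ensemble-mean predicted mutability to one decimal
and regresses observed mutated fraction on the bin value, weighted by
bin occupancy (statsmodels WLS); with one occupied bin the fit is
reported missing. Cross-dataset prediction applies a trained model to
another dataset's encoded features; trained columns absent from the
target are reported and imputed at the training mean (standardized
zero).

The scikit-learn implementation was cross-checked against R glmnet at a
matched fixed penalty (λ = 1/(C·n)); coefficients agree to ~1e-3.

## Desk-scale choices

Defaults used by the test suite and the reduced pipeline configuration:
genomes of 60–400 kb, clustering nulls of 300–1,000 iterations, type-I
error checks over 100 null seeds, mutability training pools of ~3,000
non-mutated sites with 3–5 replicates. These sizes were chosen so the
statistical properties under test (recovery within stated standard
errors, nominal type-I error, CI behavior) are well powered; all are
configurable upward for production runs.

## Known limitations

- No read-level or alignment simulation; callability noise is
  summary-field-level by design.
- Linguistic complexity beyond k = 16 is not computed in windowed mode
  (exact at the two small scales; saturated at the large ones).
- Per-line spike-in callability is coarse at small genome scales.
- The Ka/Ks estimator is a counting method; it is not expected to match
  likelihood or weighted-pathway calculators numerically.
- The contamination screen is a screen, not a test: with near-zero
  background sharing its mean + 5 SD threshold can flag sporadic
  recurrent-site sharing between high-rate lines.
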