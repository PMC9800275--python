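# Methods

`icbtox` reimplements, as a reusable and tested pipeline, the repertoire,
expression and clinical-association computations used to characterise how a
germline risk allele at the *IL7* locus shapes immune-checkpoint-blockade
(ICB) toxicity in melanoma: depth-matched bootstrap clonality metrics on
T cell receptor (TCR) repertoires, B cell receptor (BCR) maturation
metrics, median-of-ratios normalization with geometric-mean signature
scoring, a lymphocyte-stability (LS) metric with fixed clinical time
windows, and genotype/expression–irAE association with mediation-style
covariate adjustment. Because the patient-level data such analyses run on
are access-controlled, the package ships a first-class synthetic cohort
generator that reproduces the statistical structure the analyses assume, so
every stage is testable offline.

## Clonality metrics

A *clone* is a set of receptor reads sharing an identity key — either the
CDR3 nucleotide sequence alone (`cdr3_only`) or CDR3 plus V and J gene
calls (`cdr3_vj`). Both keys are supported because both granularities are
in common use: CDR3-only for chain-level diversity summaries, CDR3+V+J for
clone-size occupancy. Neither is silently assumed; the key is explicit in
every aggregation call (pipeline default `cdr3_vj`).

The Gini index of clone read counts,

    G = sum_ij |x_i − x_j| / (2 n² x̄),

is computed via the equivalent sorted form (O(n log n)); a single-clone or
perfectly even repertoire scores 0. Occupancy bands partition clones by
repertoire frequency with *strict* inequalities at both edges: small
< 0.05%, large > 0.5%, boundary values mid. Fractions are read-weighted
and sum to 1.

All of these statistics are depth-biased, so cross-sample comparisons go
through bootstrap rarefaction: the rarefied depth is the minimum total read
count across samples, and each sample is resampled multinomially (with
replacement, from its empirical clone frequencies) to that depth, the
statistic recomputed per resample (clones drawn zero times are dropped),
over `n_iter` = 1,000 iterations by default. We resample **every** sample,
including the minimum-depth one, so all estimates carry comparable bootstrap
variance; resampling only the deeper samples would leave the reference
sample with zero resampling error, making its interval incomparable.
Percentile (2.5/97.5%) intervals are reported rather than normal
approximations because rarefied Gini distributions are skewed at low depth.
Each sample draws from a stream seeded by `(seed, crc32(sample_id))`, so
results are reproducible and independent of sample ordering.

One caveat worth stating: rarefaction makes samples *comparable*, it does
not remove the finite-depth bias of the statistic itself. Resampling a
perfectly even source to low depth produces a strictly positive Gini
(multinomial noise manufactures inequality), so rarefied values should only
ever be compared with other values rarefied to the same depth — which is
exactly how the pipeline reports them.

## BCR maturation metrics

Somatic hypermutation is proxied by germline-divergent events —
substitutions, insertions and deletions combined — counted once per unique
clone (not read-weighted). The per-chain mutation percentage is
100 × Σ(subs+ins+del) / Σ(aligned length), i.e. a per-base divergence rate
whose denominator is the summed per-clone aligned V(D)J lengths. An
alternative reading (a fixed receptor length per clone) is available via
`per_clone_length`; the summed-length default makes the statistic a genuine
rate per sequenced base. Isotype usage is the percentage of IGH clones (or
reads) carrying each constant-region gene segment (IGHM, IGHD, IGHG1–4,
IGHA1–2, IGHE), over the clones with an assigned constant region; clones
lacking one are excluded and counted. The IGHD clone percentage — the
standard readout of an unswitched, naive-like repertoire — is by
construction identical to the IGHD entry of clone-unit usage.

## Expression normalization and scoring

Raw count matrices are normalized by median-of-ratios size factors:
s_j = median over reference genes g of K_gj / (Π_j K_gj)^(1/m), where the
reference set is all genes with nonzero counts in every sample. Signature
scores (e.g. a mitotic/proliferation score over a 50-gene set) are
per-sample geometric means of the set on the normalized layer. Zero
handling for the log/geometric operations uses a pseudocount of 1 on the
normalized scale by default; it is configurable, and a pseudocount of 0 is
valid whenever all values are positive (homogeneity under global scaling
then holds exactly). The published 50-gene mitotic list comes from prior
single-cell work and is not redistributed here; the signature is a
pluggable gene set, and synthetic runs use generator-designated signature
genes loading on a latent per-sample mitotic factor.

Two-group expression effects are differences of group means of
log2(value + pseudocount), optionally with linear covariate adjustment,
with a Wald p-value from the corresponding linear model; the reference
level is explicit so carrier-vs-noncarrier effects carry the conventional
sign. Gene-set enrichment uses the one-tailed (upper) hypergeometric test
with fold change (overlap/|hits|)/(|annotation|/universe). Differential
expression scans are deliberately out of scope.

## Lymphocyte stability and association statistics

LS compares the pre-treatment blood lymphocyte count — the observation
closest to the first infusion, no more than 30 days before it, with day 0
counting as pre-treatment since bloods are drawn immediately before
infusion — with the first count at least 21 and at most 49 days after
treatment start. Stable means the count rose or fell by less than 20%; a
fall of exactly 20% is unstable (the stability definition is strict). The
boundary test uses a 1e-9 tolerance so that ratios like 1.6/2.0, which
round to −19.999999999999996%, classify as the exact 20% falls they are.
Patients missing either window are excluded with reason codes, never
errors. When several counts share the selected day, the last-entered row
wins (and this is deterministic in the row order of the input file).

2×2 odds ratios are ad/bc with Woolf (log-normal) 95% intervals, Haldane
+0.5 correction when any cell is zero (configurable), and a two-sided
Fisher exact p computed by enumerating the hypergeometric distribution over
tables with the observed margins. Adjusted odds ratios come from
maximum-likelihood logistic regression with Wald intervals; perfect
separation is detected and raised as an explicit diagnostic. Both routes
are always emitted side by side because cohort studies conventionally
report GLM-derived ORs with Fisher p-values. The random-effects structure
sometimes used for mediation-style analyses is deliberately replaced by
fixed-effect covariate adjustment: with one observation per patient the
random intercept is not identified, and the fixed-effect fit answers the
same question — whether the genotype coefficient survives conditioning on
B cell *IL7* expression.

## The synthetic cohort generator

The generator's defaults are the study conditions the analyses target:
214 patients (98 single-agent / 116 combination ICB), risk-allele minor
allele frequency 7.4% with genotypes under Hardy–Weinberg equilibrium, a
carrier odds ratio of 2.24 for severe irAEs on a base rate of 0.20
(non-carrier, single-agent), a five-fold combination-therapy odds offset
(single-agent recipients carry roughly 20% of the combination risk), and a
B cell *IL7* log2 shift of 0.57 between healthy donors (anchor 8.30) and
patients (8.87). Free parameters the source cohort does not print were
fixed once at design time:

- **IL7 residual sd = 0.8 log2 units**, back-derived from the reported
  significance of the healthy-vs-patient shift (p ≈ 5.9×10⁻⁶ at ~93 per
  group implies a per-group sd near 0.83).
- **Carrier IL7 shift = 0.6 log2 units** (carriers show increased
  induction; the magnitude is unprinted).
- **irAE base rate 0.20**, a plausible severe-irAE frequency yielding
  non-degenerate 2×2 tables at n = 214.
- **Clone sizes** follow a discrete bounded power law over ranks with
  exponent `powerlaw_alpha` (default 2.0, plus a per-call `skew`), reads
  multinomially sampled to the requested depth — reproducing the
  heavy-tailed occupancy structure of real repertoires.
- **BCR maturation**: per-clone mutation counts are Poisson with a
  per-base rate of 2.5% (×1.3 in carriers); IGHC segments are drawn from a
  fixed usage vector with the IGHD weight ×0.6 in carriers.
- **Lymphocyte series** are log-normal with median 1.82×10⁹ cells/L and
  IQR 1.26–2.33 at baseline; post-treatment counts are the baseline times
  a post/pre ratio centred at 0.85 for non-carriers and 1.0 for carriers.

Two outcome modes exist. In `direct` mode the carrier effect enters the
irAE logit directly. In `via_il7` mode it acts **only** through IL7
(genotype → IL7 → irAE), so genotype and outcome are conditionally
independent given IL7 — the generative analogue of the mediation
hypothesis. The IL7→outcome slope in this mode is solved by a fixed point
so that the *marginal* carrier OR still equals the configured 2.24: the
naive slope log(OR)/shift under-produces the marginal contrast because
averaging a logistic risk over the IL7 residual attenuates it (the
standard 1/sqrt(1 + 0.346 β²σ²) correction).

The mediation property is verified by fitting the carrier coefficient with
and without IL7 as a covariate and checking that conditioning shrinks it
toward zero. This check runs on cohorts of 1,000: at the study's n = 214
there are only ~30 carriers, the coefficient's sampling noise is of the
same order as the effect, and the per-cohort shrinkage comparison succeeds
in only ~87% of replicates even though the generating model is exactly
mediated; at n = 1,000 the structural property is resolved (~96%
shrinkage), which is what the test asserts.

Determinism: every generator derives an independent named stream
(`default_rng([seed, crc32(name), ...])`) from the single global seed, so a
given `SimConfig` yields byte-identical tables while sub-generators remain
statistically independent. What the generator does **not** emulate:
sequence-level VDJ recombination biology, hypermutation hotspots,
repertoire sharing between individuals, batch effects in expression, or
droplet single-cell data. Passing tests therefore certify the statistical
machinery and its oracles, not performance on any real cohort.

## Problem sizes in the test suite

The suite exercises Hardy–Weinberg and null-effect contracts at n = 10⁵
patients, odds-ratio recovery on 500 cohorts of 214, mediation shrinkage on
200 cohorts of 1,000, mutation-sign recovery on 100 repertoires of 400
clones, rarefaction on samples of 5,000/50,000 reads with 1,000 bootstrap
iterations, and end-to-end determinism on a 120-patient run with 8
repertoires at 400 iterations. These sizes give stable pass/fail behaviour
for each property while keeping the default `pytest` run around a minute.

## Known limitations

- The rarefied-metric point estimate carries the finite-depth bias of the
  statistic at the rarefied depth (see above); it is a comparator, not an
  estimate of the infinite-depth value.
- The Woolf interval and Haldane correction are first-order devices; for
  very sparse tables an exact conditional interval would differ.
- `group_effect` is a two-group linear contrast, not a general linear
  model scan; multi-level designs need the underlying statsmodels API.
- Clinical calendar parsing is confined to the I/O boundary; internally
  all times are integer day offsets from treatment start.
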