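# icbtox

Repertoire, expression and clinical-association analyses for
immune-checkpoint-blockade (ICB) toxicity cohorts — plus a synthetic
cohort generator so every stage runs and tests offline.

## What this is for

Severe immune-related adverse events (irAEs) in melanoma patients on ICB
are associated with a germline risk allele at the *IL7* locus, which acts
as a B cell *cis*-eQTL: carriers show higher B cell *IL7* expression, more
somatically hypermutated B cell receptors, fewer naive (IGHD-expressing)
B cell clones, more stable blood lymphocyte counts on treatment, and a
CD8⁺ T cell repertoire skewed toward large clones. Analysing a cohort like
this takes a specific toolbox of bespoke statistics, which this package
provides as tested, reusable components for anyone working with MiXCR- or
AIRR-style clonotype tables, bulk RNA-seq count matrices and routine
clinical bloods:

- **Clonality** — Gini index `G = Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄)` of clone sizes,
  clone-size occupancy bands (small < 0.05%, large > 0.5% of the
  repertoire, strict bounds), and large-clone counts, all under
  depth-matched bootstrap rarefaction: every sample is resampled
  multinomially to the minimum depth across samples, 1,000 times, and the
  bootstrap mean, sd and percentile interval are reported.
- **BCR maturation** — per-chain mutation percentage
  `100·Σ(subs+ins+del)/Σ(aligned length)` over clones, IGHC isotype usage
  per clones or reads, and the IGHD-expressing clone percentage.
- **Expression** — median-of-ratios size factors
  `sⱼ = medianᵍ K_gj/(Πⱼ K_gj)^{1/m}`, geometric-mean signature scores,
  two-group log2 effects with covariate adjustment, and one-tailed
  hypergeometric gene-set enrichment.
- **Clinical** — lymphocyte stability (LS: pre-treatment count within 30
  days before start vs the first count 21–49 days after; a fall ≥ 20% is
  unstable), 2×2 odds ratios with Woolf intervals and exact Fisher p by
  hypergeometric enumeration, and covariate-adjusted logistic odds ratios
  with separation diagnostics — the machinery behind "does the genotype
  effect survive conditioning on B cell *IL7*?".
- **Synthetic cohorts** — Hardy–Weinberg genotypes at 7.4% minor allele
  frequency, a logistic irAE outcome with carrier OR 2.24 (directly, or
  fully mediated through IL7), power-law repertoires, negative-binomial
  count matrices, and log-normal lymphocyte series calibrated to printed
  cohort summaries (see `docs/methods.md`).

## Worked example

```python
import numpy as np, pandas as pd
import icbtox as t

cfg = t.SimConfig(seed=1)                     # 214 patients, MAF 7.4%
cohort = t.gen_cohort(cfg)

carrier = cohort.carrier.to_numpy(); irae = cohort.irae.to_numpy()
table = np.array([[(carrier & irae).sum(), (carrier & ~irae).sum()],
                  [(~carrier & irae).sum(), (~carrier & ~irae).sum()]])
print(table.tolist())
print(t.odds_ratio_2x2(table))

rep = {s: t.aggregate_clones(t.gen_repertoire(cfg, sample_id=s), key="cdr3_only")
       for s in ("P0001", "P0002")}
for sid, r in t.rarefied_metric(rep, metric="gini", n_iter=1000, seed=1).items():
    print(sid, round(r.point, 4), "+/-", round(r.sd, 4), "at depth", r.rarefied_depth)

from icbtox.clinical import Observation
print(t.lymphocyte_stability(Observation(-2, 1.82), Observation(25, 1.52)))
```

prints

```
[[15, 15], [83, 101]]
AssociationResult(estimate=1.216867469879518, ci_lo=0.5621078237559834,
                  ci_hi=2.6343103167583646, p_value=0.6942114996376104,
                  method='fisher', n=214)
P0001 0.9596 +/- 0.0009 at depth 20000
P0002 0.9583 +/- 0.001 at depth 20000
LSResult(patient_id='', pre_count=1.82, post_count=1.52, pre_day=-2,
         post_day=25, delta=-0.30000000000000004,
         pct_change=-16.483516483516485, stable=True)
```

The 2×2 table is one seeded cohort draw: 15/30 carriers vs 83/184
non-carriers with severe irAEs gives a point OR of 1.22 with a wide CI —
a single 214-patient cohort is noisy, which is why recovery of the true
carrier OR is assessed over hundreds of simulated cohorts in the test
suite. The two repertoires, generated from the same clone-size law, have
indistinguishable rarefied Gini indices at the shared 20,000-read depth.
The LS example is a 16.5% fall, classed stable (falls of 20% or more are
unstable).

A command-line interface mirrors the library
(`icbtox simulate | metrics | bcr | scores | ls | associate | run-all |
validate`); `icbtox run-all --seed 7 --out-dir out/` writes every metric
table plus a manifest whose config hash makes the run reproducible
bit-for-bit.

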