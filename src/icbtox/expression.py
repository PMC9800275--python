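"""Count normalization, signature scoring and gene-set enrichment.

Normalization is the median-of-ratios scheme standard for bulk RNA-seq
count matrices: with m samples, each sample j gets the size factor

    s_j = median over genes g of  K_gj / (prod_j K_gj)^(1/m)

taken over the reference genes with nonzero counts in every sample, and
normalized values are K_gj / s_j.  Signature scores (e.g. the mitotic
proliferation score) are per-sample geometric means of a gene set on the
normalized layer.  Gene-set enrichment uses the one-tailed (upper)
hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PSEUDOCOUNT = 1.0


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class EffectEstimate:
    """Two-group expression difference on the log2 scale."""

    effect: float
    se: float
    statistic: float
    p_value: float
    n_per_group: tuple


@dataclass(frozen=True)
class EnrichmentResult:
    overlap: int
    p_value: float
    fold_change: float


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample (column).

    Genes with a zero count in any sample are excluded from the reference
    set; at least one all-nonzero gene is required.
    """
    mat = counts.to_numpy(dtype=float)
    ref = np.all(mat > 0, axis=1)
    if not ref.any():
        raise NormalizationError("no reference genes: every gene has a zero count somewhere")
    logs = np.log(mat[ref])
    log_geo = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    if factors is None:
        factors = size_factors(counts)
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise NormalizationError("size factors must be positive and cover every sample")
    return counts / factors


def signature_score(
    norm: pd.DataFrame,
    gene_set,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_present: float = 0.8,
) -> pd.Series:
    """Per-sample geometric mean of a gene set on normalized expression.

    score_j = exp( mean over present set genes of ln(value_gj + pseudocount) ).

    At least ``min_present`` of the set must be present in the matrix;
    otherwise an error lists the missing genes.  With ``pseudocount=0``
    every set gene must be positive everywhere.
    """
    members = list(dict.fromkeys(gene_set))
    if not members:
        raise ValueError("empty gene set")
    present = [g for g in members if g in norm.index]
    missing = sorted(set(members) - set(present))
    if len(present) < min_present * len(members):
        raise ValueError(f"gene set coverage below {min_present:.0%}; missing: {missing}")
    vals = norm.loc[present].to_numpy(dtype=float) + pseudocount
    if (vals <= 0).any():
        raise NormalizationError("non-positive value under pseudocount 0")
    return pd.Series(np.exp(np.log(vals).mean(axis=0)), index=norm.columns, name="score")


def group_effect(
    norm: pd.DataFrame,
    gene: str,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    reference: str | None = None,
) -> EffectEstimate:
    """Two-group difference in mean log2 expression of one gene.

    ``groups`` maps sample id to one of exactly two labels; the effect is
    the non-reference group's mean minus the reference group's, on
    log2(value + pseudocount), optionally with linear covariate
    adjustment (``reference`` defaults to the first label in sorted
    order).  The p-value is the two-sided Wald test of the group term in
    the corresponding linear model.
    """
    import statsmodels.api as sm

    if gene not in norm.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    groups = groups.dropna()
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    if reference is None:
        reference = labels[0]
    elif reference not in labels:
        raise ValueError(f"reference {reference!r} not among group labels {labels}")
    other = labels[0] if reference == labels[1] else labels[1]
    samples = [s for s in norm.columns if s in groups.index]
    y = np.log2(norm.loc[gene, samples].to_numpy(dtype=float) + pseudocount)
    g = (groups.loc[samples] == other).to_numpy(dtype=float)
    n0, n1 = int((g == 0).sum()), int((g == 1).sum())
    if min(n0, n1) < 2:
        raise ValueError(f"each group needs >= 2 samples, got {n0} and {n1}")

    X = pd.DataFrame({"group": g}, index=samples)
    if covariates is not None:
        X = X.join(covariates.loc[samples])
    X = sm.add_constant(X.astype(float))
    fit = sm.OLS(y, X).fit()
    return EffectEstimate(
        effect=float(fit.params["group"]),
        se=float(fit.bse["group"]),
        statistic=float(fit.tvalues["group"]),
        p_value=float(fit.pvalues["group"]),
        n_per_group=(n0, n1),
    )


def hypergeometric_enrichment(hits, annotation, background: int) -> EnrichmentResult:
    """One-tailed (upper) hypergeometric enrichment of ``hits`` in ``annotation``.

    p = P(X >= overlap) with X ~ Hypergeom(background, |annotation|, |hits|);
    fold change = (overlap / |hits|) / (|annotation| / background).
    """
    hits = set(hits)
    annotation = set(annotation)
    if not hits or not annotation:
        raise ValueError("hits and annotation must be non-empty")
    if len(hits) > background or len(annotation) > background:
        raise ValueError("set larger than background universe")
    overlap = len(hits & annotation)
    p = float(stats.hypergeom.sf(overlap - 1, background, len(annotation), len(hits)))
    fold = (overlap / len(hits)) / (len(annotation) / background)
    return EnrichmentResult(overlap=overlap, p_value=p, fold_change=float(fold))
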