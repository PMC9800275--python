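"""Synthetic cohort, repertoire, expression and lymphocyte-series generators.

Every generator derives an independent, named random stream from the single
integer seed in :class:`~icbtox.config.SimConfig`, so the same configuration
always produces byte-identical tables while the sub-generators remain
statistically independent of one another.

The statistical structure mirrors a melanoma immune-checkpoint-blockade
toxicity cohort: Hardy-Weinberg genotypes at a risk locus, a logistic severe
irAE outcome with a carrier odds ratio, a B cell IL7 expression shift that
can either accompany the genotype effect or fully mediate it, power-law
T cell receptor repertoires, B cell receptor repertoires whose mutation load
and IGHD usage depend on carriage, and log-normal blood lymphocyte series
calibrated to the printed pre-treatment median and inter-quartile range.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .config import ParameterError, SimConfig

IL7_LOG2_HEALTHY = 8.30
"""Mean log2 B cell IL7 expression in healthy donors (calibration anchor)."""

LYMPH_LOG_MEDIAN = float(np.log(1.82))
LYMPH_LOG_SIGMA = float((np.log(2.33) - np.log(1.26)) / 1.349)
"""Log-normal parameters matching a pre-treatment lymphocyte median of
1.82e9 cells/L with IQR 1.26-2.33 (1.349 = width of the standard-normal IQR)."""

NONCARRIER_POST_PRE_RATIO = 0.85
CARRIER_POST_PRE_RATIO = 1.0
RATIO_LOG_SIGMA = 0.25

TRBV_GENES = [f"TRBV{i}" for i in range(2, 31)]
TRBJ_GENES = [f"TRBJ{i}-{j}" for i in (1, 2) for j in range(1, 7)]
IGHV_GENES = [f"IGHV{i}-{j}" for i in range(1, 7) for j in (2, 18, 30, 34, 69)]
IGHJ_GENES = [f"IGHJ{i}" for i in range(1, 7)]
IGKV_GENES = [f"IGKV{i}-{j}" for i in range(1, 5) for j in (5, 12, 20, 33, 39)]
IGKJ_GENES = [f"IGKJ{i}" for i in range(1, 6)]
IGLV_GENES = [f"IGLV{i}-{j}" for i in range(1, 4) for j in (14, 40, 44, 47, 51)]
IGLJ_GENES = [f"IGLJ{i}" for i in (1, 2, 3, 7)]

IGHC_SEGMENTS = ["IGHM", "IGHD", "IGHG1", "IGHG2", "IGHG3", "IGHG4", "IGHA1", "IGHA2", "IGHE"]
IGHC_BASE_WEIGHTS = np.array([0.35, 0.15, 0.20, 0.08, 0.06, 0.02, 0.10, 0.03, 0.01])

CLONOTYPE_COLUMNS = [
    "sample_id", "chain", "cdr3_nt", "v_call", "j_call", "c_call",
    "read_count", "n_subs", "n_ins", "n_del", "aligned_length",
]


def _stream(seed: int, *names) -> np.random.Generator:
    """Named, reproducible child stream of a global integer seed."""
    keys = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng([int(seed)] + keys)


def _random_cdr3(rng: np.random.Generator, n: int, min_aa: int = 10, max_aa: int = 18) -> list[str]:
    """In-frame CDR3 nucleotide strings (conserved C...F motif not modelled)."""
    lengths = 3 * rng.integers(min_aa, max_aa + 1, size=n)
    bases = np.array(list("ACGT"))
    return ["".join(bases[rng.integers(0, 4, size=l)]) for l in lengths]


def _mediated_slope(log_or: float, shift: float, sd: float) -> float:
    """IL7 -> outcome slope giving the target *marginal* carrier log odds ratio.

    Averaging a logistic risk over the IL7 residual attenuates the marginal
    genotype contrast below beta * shift; the standard probit-style
    correction divides the slope by sqrt(1 + 0.346 * (beta * sd)^2).
    Solving the fixed point keeps the simulated marginal carrier OR at the
    configured value in via_il7 mode.
    """
    beta = log_or / shift
    for _ in range(50):
        new = (log_or / shift) * np.sqrt(1.0 + 0.346 * (beta * sd) ** 2)
        if abs(new - beta) < 1e-10:
            break
        beta = new
    return float(beta)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def gen_cohort(cfg: SimConfig) -> pd.DataFrame:
    """Simulate the clinical table: genotype, therapy, IL7 expression, irAE.

    Genotype doses follow Hardy-Weinberg equilibrium at ``cfg.maf``.  The
    severe-irAE outcome is logistic with ``cfg.base_irae_rate`` as the
    non-carrier single-agent reference, a combination-therapy offset of
    log(``cfg.cicb_irae_or``), and a carrier effect of
    log(``cfg.carrier_irae_or``) that acts directly (``direct`` mode) or
    entirely through the patient's log2 B cell IL7 expression
    (``via_il7`` mode, in which genotype and outcome are conditionally
    independent given IL7).
    """
    rng = _stream(cfg.seed, "cohort")
    n = cfg.n_patients

    dose = rng.binomial(2, cfg.maf, size=n)
    carrier = dose > 0
    sicb = rng.random(n) < cfg.sicb_fraction
    icb_type = np.where(sicb, "sICB", "cICB")

    patient_mean = IL7_LOG2_HEALTHY + cfg.eqtl_log2_shift
    il7 = patient_mean + cfg.carrier_log2_shift * carrier + rng.normal(0.0, cfg.il7_sd, size=n)

    base_logit = np.log(cfg.base_irae_rate / (1 - cfg.base_irae_rate))
    logit = base_logit + np.log(cfg.cicb_irae_or) * (~sicb)
    if cfg.mediation_mode == "direct":
        logit = logit + np.log(cfg.carrier_irae_or) * carrier
    else:  # via_il7: genotype acts only through IL7
        beta_il7 = _mediated_slope(
            np.log(cfg.carrier_irae_or), cfg.carrier_log2_shift, cfg.il7_sd
        )
        logit = logit + beta_il7 * (il7 - patient_mean)
    p = 1.0 / (1.0 + np.exp(-logit))
    irae = rng.random(n) < p

    start = pd.Timestamp("2016-01-04") + pd.to_timedelta(
        np.sort(rng.integers(0, 5 * 365, size=n)), unit="D"
    )

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(1, n + 1)],
            "genotype_dose": dose.astype(int),
            "carrier": carrier,
            "icb_type": icb_type,
            "irae": irae,
            "start_date": start.strftime("%Y-%m-%d"),
            "il7_expr": np.round(il7, 6),
        }
    )


# ---------------------------------------------------------------------------
# repertoires
# ---------------------------------------------------------------------------

def _powerlaw_freqs(n_clones: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n_clones + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


def gen_repertoire(cfg: SimConfig, skew: float = 0.0, sample_id: str = "S1") -> pd.DataFrame:
    """Simulate a TRB clonotype table with power-law clone sizes.

    Clone frequencies follow a discrete bounded power law with exponent
    ``cfg.powerlaw_alpha + skew`` over clone ranks; reads are multinomially
    sampled to exactly ``cfg.depth``.  Clones unobserved at that depth are
    dropped, so the table lists only clones with at least one read.
    """
    exponent = cfg.powerlaw_alpha + skew
    if exponent <= 0:
        raise ParameterError(f"power-law exponent must be positive, got {exponent}")
    rng = _stream(cfg.seed, "repertoire", sample_id, skew)

    freqs = _powerlaw_freqs(cfg.clone_count, exponent)
    reads = rng.multinomial(cfg.depth, freqs)
    keep = reads > 0

    n = int(keep.sum())
    cdr3 = _random_cdr3(rng, n)
    v = rng.choice(TRBV_GENES, size=n)
    j = rng.choice(TRBJ_GENES, size=n)

    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "chain": "TRB",
            "cdr3_nt": cdr3,
            "v_call": v,
            "j_call": j,
            "c_call": "",
            "read_count": reads[keep].astype(int),
            "n_subs": 0,
            "n_ins": 0,
            "n_del": 0,
            "aligned_length": [len(s) + 250 for s in cdr3],
        },
        columns=CLONOTYPE_COLUMNS,
    )


def gen_bcr_repertoire(cfg: SimConfig, carrier: bool, sample_id: str = "B1") -> pd.DataFrame:
    """Simulate a B cell receptor clonotype table across IGH/IGK/IGL.

    Per-clone germline-divergent mutation counts are Poisson with a
    per-nucleotide rate of ``cfg.bcr_mutation_rate``, multiplied by
    ``cfg.carrier_mutation_multiplier`` for risk-allele carriers.  IGH
    clones receive an isotype (IGHC segment) draw in which the IGHD
    probability is scaled by ``cfg.carrier_ighd_multiplier`` for carriers,
    encoding their reduced B cell naivety.
    """
    rng = _stream(cfg.seed, "bcr", sample_id, bool(carrier))

    n = cfg.clone_count
    chains = rng.choice(["IGH", "IGK", "IGL"], size=n, p=[0.5, 0.3, 0.2])
    freqs = _powerlaw_freqs(n, cfg.powerlaw_alpha)
    reads = rng.multinomial(cfg.depth, freqs)
    keep = reads > 0
    chains = chains[keep]
    reads = reads[keep]
    n = int(keep.sum())

    cdr3 = _random_cdr3(rng, n)
    lengths = np.array([len(s) + 300 for s in cdr3])

    rate = cfg.bcr_mutation_rate * (cfg.carrier_mutation_multiplier if carrier else 1.0)
    mutations = rng.poisson(rate * lengths)
    # split total mutations into substitutions / insertions / deletions
    subs = rng.binomial(mutations, 0.9)
    ins = rng.binomial(mutations - subs, 0.5)
    dels = mutations - subs - ins

    weights = IGHC_BASE_WEIGHTS.copy()
    if carrier:
        weights[IGHC_SEGMENTS.index("IGHD")] *= cfg.carrier_ighd_multiplier
    weights = weights / weights.sum()

    v = np.empty(n, dtype=object)
    jg = np.empty(n, dtype=object)
    c = np.empty(n, dtype=object)
    for chain, vpool, jpool in (
        ("IGH", IGHV_GENES, IGHJ_GENES),
        ("IGK", IGKV_GENES, IGKJ_GENES),
        ("IGL", IGLV_GENES, IGLJ_GENES),
    ):
        m = chains == chain
        v[m] = rng.choice(vpool, size=int(m.sum()))
        jg[m] = rng.choice(jpool, size=int(m.sum()))
        c[m] = rng.choice(IGHC_SEGMENTS, size=int(m.sum()), p=weights) if chain == "IGH" else ""

    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "chain": chains,
            "cdr3_nt": cdr3,
            "v_call": v,
            "j_call": jg,
            "c_call": c,
            "read_count": reads.astype(int),
            "n_subs": subs.astype(int),
            "n_ins": ins.astype(int),
            "n_del": dels.astype(int),
            "aligned_length": lengths.astype(int),
        },
        columns=CLONOTYPE_COLUMNS,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def gen_expression(
    cfg: SimConfig,
    cohort: pd.DataFrame,
    signature_genes: list[str] | None = None,
    n_genes: int = 500,
    status: str = "patient",
) -> pd.DataFrame:
    """Simulate a gene x sample raw count matrix (negative binomial).

    The designated ``IL7`` gene mean is multiplied by ``2**eqtl_log2_shift``
    in patients (relative to the healthy anchor) and further by
    ``2**carrier_log2_shift`` in risk-allele carriers; with
    ``status='healthy'`` neither shift is applied.  Signature genes load on
    a latent per-sample mitotic factor so that their geometric mean tracks
    a common proliferation axis.
    """
    if len(cohort) == 0:
        raise ParameterError("cohort must be nonempty")
    rng = _stream(cfg.seed, "expression", status)

    samples = cohort["patient_id"].tolist()
    carrier = cohort["carrier"].to_numpy(dtype=bool)
    signature_genes = list(signature_genes or [])

    genes = ["IL7"] + signature_genes
    genes += [f"G{i:04d}" for i in range(1, n_genes - len(genes) + 1)]
    if len(set(genes)) != len(genes):
        raise ParameterError("duplicate gene ids in signature set")

    base_means = np.exp(rng.normal(4.0, 1.5, size=len(genes)))
    base_means[0] = 2.0 ** IL7_LOG2_HEALTHY  # IL7 anchored to the healthy mean

    mu = np.tile(base_means[:, None], (1, len(samples)))
    if status == "patient":
        mu[0] *= 2.0 ** cfg.eqtl_log2_shift
        mu[0, carrier] *= 2.0 ** cfg.carrier_log2_shift

    mitotic = rng.normal(0.0, 1.0, size=len(samples))
    for gi in range(1, 1 + len(signature_genes)):
        mu[gi] *= 2.0 ** (0.5 * mitotic)

    disp = cfg.nb_dispersion
    shape = 1.0 / disp
    counts = rng.negative_binomial(shape, shape / (shape + mu))
    return pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)


# ---------------------------------------------------------------------------
# lymphocyte series
# ---------------------------------------------------------------------------

def gen_lymphocyte_series(
    cfg: SimConfig,
    cohort: pd.DataFrame,
    carrier_ratio: float = CARRIER_POST_PRE_RATIO,
    noncarrier_ratio: float = NONCARRIER_POST_PRE_RATIO,
) -> pd.DataFrame:
    """Simulate longitudinal blood lymphocyte counts (1e9 cells/L).

    Each patient's baseline is log-normal with median 1.82 and IQR
    1.26-2.33; counts after treatment start are multiplied by a post/pre
    ratio centred at ``carrier_ratio`` for carriers and
    ``noncarrier_ratio`` for non-carriers (log-normal noise around both).
    Day offsets are relative to treatment start and span [-60, 60]; a
    small fraction of patients miss the pre- or post-treatment window,
    as in routinely collected hospital counts.
    """
    if len(cohort) == 0:
        raise ParameterError("cohort must be nonempty")
    rng = _stream(cfg.seed, "lymphocytes")

    rows = []
    for pid, is_carrier in zip(cohort["patient_id"], cohort["carrier"].astype(bool)):
        baseline = float(np.exp(rng.normal(LYMPH_LOG_MEDIAN, LYMPH_LOG_SIGMA)))
        ratio = carrier_ratio if is_carrier else noncarrier_ratio

        pre_days = sorted(set(rng.integers(-60, 1, size=2).tolist()))
        post_days = sorted(set(rng.integers(10, 61, size=3).tolist()))
        if rng.random() < 0.05:  # missed pre-treatment bloods
            pre_days = []
        if rng.random() < 0.05:
            post_days = []
        for day in pre_days:
            count = baseline * float(np.exp(rng.normal(0.0, 0.05)))
            rows.append((pid, int(day), round(count, 3)))
        for day in post_days:
            count = baseline * ratio * float(np.exp(rng.normal(0.0, RATIO_LOG_SIGMA)))
            rows.append((pid, int(day), round(count, 3)))

    df = pd.DataFrame(rows, columns=["patient_id", "day_offset", "lymphocyte_count"])
    return df.sort_values(["patient_id", "day_offset"], kind="stable").reset_index(drop=True)
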