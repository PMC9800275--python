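"""Configuration objects shared across the toolkit.

Two dataclasses live here: :class:`SimConfig`, the full parameterisation of
the synthetic cohort generator, and :class:`BandThresholds`, the clone-size
band cut-offs used by the occupancy statistics.  Both validate eagerly on
construction so downstream code can assume well-formed parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


class ParameterError(ValueError):
    """Raised when a configuration value is outside its admissible range."""


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ParameterError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic melanoma checkpoint-blockade cohort.

    Defaults reproduce the study conditions the toolkit targets: 214
    genotyped patients (98 single-agent / 116 combination checkpoint
    blockade), a risk-allele minor allele frequency of 7.4%, a carrier
    odds ratio of 2.24 for severe immune-related adverse events (irAEs),
    and a B cell IL7 log2-expression shift of 0.57 between healthy donors
    and patients (8.30 -> 8.87).

    Parameters
    ----------
    n_patients : cohort size.
    maf : risk-allele minor allele frequency; genotype doses are drawn
        under Hardy-Weinberg equilibrium.
    carrier_irae_or : odds ratio for severe irAE conferred by carrying at
        least one risk allele.
    base_irae_rate : irAE probability for a non-carrier on single-agent
        therapy; the reference cell of the logistic outcome model.
    cicb_irae_or : odds-ratio offset for combination therapy relative to
        single-agent (combination recipients are roughly five-fold more
        likely to develop severe irAEs).
    sicb_fraction : fraction of the cohort on single-agent therapy.
    clone_count : clones per simulated receptor repertoire.
    depth : sequencing reads per repertoire.
    powerlaw_alpha : exponent of the discrete bounded power law used for
        clone sizes; larger values give flatter (more even) repertoires.
    eqtl_log2_shift : log2 IL7 shift of patients relative to healthy donors.
    carrier_log2_shift : additional log2 IL7 shift in risk-allele carriers.
    il7_sd : residual standard deviation of per-patient log2 IL7.
    nb_dispersion : negative-binomial dispersion of simulated counts
        (variance = mu + dispersion * mu**2).
    bcr_mutation_rate : per-nucleotide germline-divergence rate of B cell
        receptor clones in non-carriers.
    carrier_mutation_multiplier : fold increase of that rate in carriers.
    carrier_ighd_multiplier : fold change of the IGHD isotype probability
        in carriers (< 1 encodes the reduced naivety of carriers).
    mediation_mode : ``direct`` puts the carrier effect straight into the
        irAE model; ``via_il7`` routes it entirely through B cell IL7
        expression (genotype -> IL7 -> irAE), so that conditioning on IL7
        removes the genotype effect.
    seed : global integer seed; every generator derives an independent,
        reproducible stream from it.
    """

    n_patients: int = 214
    maf: float = 0.074
    carrier_irae_or: float = 2.24
    base_irae_rate: float = 0.20
    cicb_irae_or: float = 5.0
    sicb_fraction: float = 98 / 214
    clone_count: int = 2000
    depth: int = 20000
    powerlaw_alpha: float = 2.0
    eqtl_log2_shift: float = 0.57
    carrier_log2_shift: float = 0.6
    il7_sd: float = 0.8
    nb_dispersion: float = 0.1
    bcr_mutation_rate: float = 0.025
    carrier_mutation_multiplier: float = 1.3
    carrier_ighd_multiplier: float = 0.6
    mediation_mode: str = "direct"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        _check_fraction("maf", self.maf)
        _check_fraction("base_irae_rate", self.base_irae_rate)
        _check_fraction("sicb_fraction", self.sicb_fraction)
        _check_positive("carrier_irae_or", self.carrier_irae_or)
        _check_positive("cicb_irae_or", self.cicb_irae_or)
        if self.clone_count < 1:
            raise ParameterError("clone_count must be >= 1")
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        _check_positive("powerlaw_alpha", self.powerlaw_alpha)
        _check_positive("nb_dispersion", self.nb_dispersion)
        if self.bcr_mutation_rate < 0:
            raise ParameterError("bcr_mutation_rate must be >= 0")
        _check_positive("carrier_mutation_multiplier", self.carrier_mutation_multiplier)
        if self.carrier_ighd_multiplier < 0:
            raise ParameterError("carrier_ighd_multiplier must be >= 0")
        if self.mediation_mode not in ("direct", "via_il7"):
            raise ParameterError(
                f"mediation_mode must be 'direct' or 'via_il7', got {self.mediation_mode!r}"
            )

    def replace(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class BandThresholds:
    """Clone-size band cut-offs on repertoire frequency.

    ``small_lt`` and ``large_gt`` are strict bounds: a clone is *small* when
    its frequency is < ``small_lt`` (default 0.05% of the repertoire) and
    *large* when it is > ``large_gt`` (default 0.5%); boundary values fall
    in the middle band.
    """

    small_lt: float = 0.0005
    large_gt: float = 0.005

    def __post_init__(self) -> None:
        if not (0.0 < self.small_lt < self.large_gt < 1.0):
            raise ParameterError(
                f"require 0 < small_lt < large_gt < 1, got {self.small_lt}, {self.large_gt}"
            )
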