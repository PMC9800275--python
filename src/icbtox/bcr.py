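"""B cell receptor maturation metrics.

Somatic hypermutation is proxied by germline-divergent events (base
substitutions, insertions and deletions combined) carried per clone in the
clonotype table.  The per-chain mutation percentage is

    100 * sum over clones (subs + ins + del) / sum over clones (aligned length)

i.e. a per-base divergence rate whose denominator grows with the number of
clones.  Isotype usage is the percentage of IGH clones (or reads) assigned
each constant-region (IGHC) gene segment; the IGHD share of clones is the
standard readout of an unswitched, naive-like repertoire.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

BCR_CHAINS = ("IGH", "IGK", "IGL")


class BcrInputError(ValueError):
    pass


@dataclass(frozen=True)
class MutationSummary:
    chain: str
    total_mutations: int
    total_length: int
    mutation_pct: float


@dataclass(frozen=True)
class IsotypeUsage:
    """Percentage of IGH clones or reads per IGHC segment.

    ``excluded`` counts clones (or sums reads) lacking a constant-region
    call; they are left out of the denominator.
    """

    unit: str
    usage: dict
    excluded: int


def mutation_percentage(clones: pd.DataFrame, per_clone_length: int | None = None) -> dict:
    """Per-chain germline-divergent mutation percentage.

    Mutations are counted once per unique clone (not read-weighted).  By
    default the denominator is the summed per-clone aligned lengths; pass
    ``per_clone_length`` to use a fixed receptor length per clone instead.
    Chains absent from the table are omitted from the result.
    """
    out: dict[str, MutationSummary] = {}
    for chain in BCR_CHAINS:
        sub = clones[clones["chain"] == chain]
        if len(sub) == 0:
            continue
        if per_clone_length is None:
            lengths = sub["aligned_length"]
            if (lengths <= 0).any():
                bad = sub.loc[lengths <= 0].index[0]
                raise BcrInputError(f"clone at row {bad} has non-positive aligned_length")
            total_length = int(lengths.sum())
        else:
            if per_clone_length <= 0:
                raise BcrInputError("per_clone_length must be positive")
            total_length = int(per_clone_length) * len(sub)
        total_mut = int((sub["n_subs"] + sub["n_ins"] + sub["n_del"]).sum())
        out[chain] = MutationSummary(
            chain=chain,
            total_mutations=total_mut,
            total_length=total_length,
            mutation_pct=100.0 * total_mut / total_length,
        )
    return out


def ighc_usage(clones: pd.DataFrame, unit: str = "clones") -> IsotypeUsage:
    """IGHC gene-segment usage over IGH clones or reads.

    The denominator is the IGH clones (or their reads) carrying a
    constant-region call; clones without one are excluded and counted in
    ``excluded``.  Percentages over the assigned clones sum to 100.
    """
    if unit not in ("clones", "reads"):
        raise BcrInputError(f"unit must be 'clones' or 'reads', got {unit!r}")
    igh = clones[clones["chain"] == "IGH"]
    if len(igh) == 0:
        return IsotypeUsage(unit=unit, usage={}, excluded=0)
    has_c = igh["c_call"].fillna("") != ""
    kept = igh[has_c]
    if unit == "clones":
        excluded = int((~has_c).sum())
        if len(kept) == 0:
            return IsotypeUsage(unit=unit, usage={}, excluded=excluded)
        counts = kept.groupby("c_call").size()
    else:
        excluded = int(igh.loc[~has_c, "total_reads"].sum())
        if len(kept) == 0:
            return IsotypeUsage(unit=unit, usage={}, excluded=excluded)
        counts = kept.groupby("c_call")["total_reads"].sum()
    pct = 100.0 * counts / counts.sum()
    return IsotypeUsage(unit=unit, usage=pct.to_dict(), excluded=excluded)


def ighd_clone_percentage(clones: pd.DataFrame) -> float:
    """Percentage of constant-region-assigned IGH clones expressing IGHD."""
    usage = ighc_usage(clones, unit="clones")
    return float(usage.usage.get("IGHD", 0.0)) if usage.usage else 0.0
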