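"""Reading, writing and clone-aggregation of clonotype tables.

Two tab-separated dialects are supported:

* ``mixcr`` — an aligner-export-like layout (``cloneCount``, ``nSeqCDR3``,
  ``allVHitsWithScore`` ...) in which gene hits arrive as comma-separated,
  score-annotated allele lists such as ``TRBV12-3*00(1200),TRBV12-4*00(900)``;
  the top hit is taken and allele/score decorations are stripped.
* ``airr`` — the AIRR Rearrangement column names (``duplicate_count``,
  ``junction``, ``v_call``, ``j_call``, ``c_call``) plus the mutation-count
  extension columns this toolkit uses.

Records whose V and J calls imply different chains are quarantined to a
rejects table rather than silently kept or dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CLONOTYPE_COLUMNS

CHAINS = ("TRB", "IGH", "IGK", "IGL")

MIXCR_COLUMNS = {
    "sampleId": "sample_id",
    "cloneCount": "read_count",
    "nSeqCDR3": "cdr3_nt",
    "allVHitsWithScore": "v_call",
    "allJHitsWithScore": "j_call",
    "allCHitsWithScore": "c_call",
    "nSubstitutions": "n_subs",
    "nInsertions": "n_ins",
    "nDeletions": "n_del",
    "alignedLength": "aligned_length",
}
AIRR_COLUMNS = {
    "sample_id": "sample_id",
    "duplicate_count": "read_count",
    "junction": "cdr3_nt",
    "v_call": "v_call",
    "j_call": "j_call",
    "c_call": "c_call",
    "n_subs": "n_subs",
    "n_ins": "n_ins",
    "n_del": "n_del",
    "aligned_length": "aligned_length",
}
_MANDATORY = {"read_count", "cdr3_nt", "v_call", "j_call"}
_CDR3_RE = re.compile(r"^[ACGTN]+$")


class ParseError(ValueError):
    """Malformed clonotype file; message names the column and line."""


@dataclass
class ReadResult:
    """Validated records plus the quarantined rejects (with reasons)."""

    records: pd.DataFrame
    rejects: pd.DataFrame = field(default_factory=pd.DataFrame)


def normalize_gene_call(raw: str) -> str:
    """Top hit of a hit string, stripped of allele and score decorations.

    ``"TRBV12-3*00(1200),TRBV12-4*00(900)"`` -> ``"TRBV12-3"``.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ""
    first = str(raw).split(",")[0].strip()
    first = first.split("*")[0]
    first = re.sub(r"\(.*\)$", "", first)
    return first.strip()


def chain_of(gene_call: str) -> str:
    for chain in CHAINS:
        if gene_call.startswith(chain):
            return chain
    return "other"


def _dialect_map(dialect: str) -> dict:
    if dialect == "mixcr":
        return MIXCR_COLUMNS
    if dialect == "airr":
        return AIRR_COLUMNS
    raise ParseError(f"unknown dialect {dialect!r} (expected 'mixcr' or 'airr')")


def read_clonotypes(path, dialect: str, sample_id: str | None = None) -> ReadResult:
    """Read and validate a clonotype TSV in the given dialect.

    Gene calls are normalized to gene level (top hit, allele and score
    stripped); chain is inferred from the V call prefix.  Rows failing
    validation are returned in ``rejects`` with a ``reason`` naming the
    offending column and 1-based data line number.
    """
    colmap = _dialect_map(dialect)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    missing = [
        src for src, dst in colmap.items()
        if dst in _MANDATORY and src not in raw.columns
    ]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s) {missing} for dialect {dialect!r}")

    df = pd.DataFrame(index=raw.index)
    for src, dst in colmap.items():
        df[dst] = raw[src] if src in raw.columns else ""
    if sample_id is not None:
        df["sample_id"] = sample_id
    elif "sample_id" not in raw.columns and colmap is MIXCR_COLUMNS and "sampleId" not in raw.columns:
        df["sample_id"] = "S1"
    df.loc[df["sample_id"] == "", "sample_id"] = "S1"

    reasons = pd.Series("", index=df.index)

    for col in ("v_call", "j_call", "c_call"):
        df[col] = df[col].map(normalize_gene_call)

    for col in ("read_count", "n_subs", "n_ins", "n_del", "aligned_length"):
        vals = pd.to_numeric(df[col].replace("", "0"), errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ParseError(f"{path}: non-numeric value in column {col!r} at data line {line}")
        df[col] = vals.astype(int)

    bad_count = df["read_count"] < 1
    reasons[bad_count & (reasons == "")] = "read_count < 1"

    bad_cdr3 = ~df["cdr3_nt"].str.match(_CDR3_RE)
    reasons[bad_cdr3 & (reasons == "")] = "cdr3_nt not over {A,C,G,T,N}"

    v_chain = df["v_call"].map(chain_of)
    j_chain = df["j_call"].map(chain_of)
    conflict = (v_chain != j_chain) & (j_chain != "other") & (v_chain != "other")
    reasons[conflict & (reasons == "")] = "V/J chain conflict"
    df["chain"] = v_chain

    ok = reasons == ""
    rejects = df.loc[~ok].copy()
    if len(rejects):
        rejects["reason"] = reasons[~ok]
        rejects["line"] = rejects.index.to_numpy() + 1
    records = df.loc[ok, CLONOTYPE_COLUMNS].reset_index(drop=True)
    return ReadResult(records=records, rejects=rejects.reset_index(drop=True))


def write_clonotypes(table: pd.DataFrame, path, dialect: str) -> None:
    """Write a clonotype table as TSV in the given dialect (UTF-8, header)."""
    colmap = _dialect_map(dialect)
    out = pd.DataFrame()
    for src, dst in colmap.items():
        if dst in table.columns:
            out[src] = table[dst]
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")


def aggregate_clones(records: pd.DataFrame, key: str = "cdr3_vj") -> pd.DataFrame:
    """Aggregate reads into clones under the declared identity key.

    ``key='cdr3_only'`` groups by CDR3 nucleotide sequence alone;
    ``key='cdr3_vj'`` additionally requires identical V and J gene calls.
    Read counts, mutation counts and aligned lengths are summed within a
    clone; the constant-region call is a read-weighted majority vote.
    ``frequency`` is the clone's share of reads on its (sample, chain).
    """
    if key not in ("cdr3_only", "cdr3_vj"):
        raise ValueError(f"unknown clone key mode {key!r}")
    group_cols = ["sample_id", "chain", "cdr3_nt"]
    if key == "cdr3_vj":
        group_cols += ["v_call", "j_call"]

    if len(records) == 0:
        cols = group_cols + ["c_call", "total_reads", "n_subs", "n_ins", "n_del",
                             "aligned_length", "frequency"]
        return pd.DataFrame(columns=cols)

    def _majority_c(group: pd.DataFrame) -> str:
        with_c = group[group["c_call"] != ""]
        if len(with_c) == 0:
            return ""
        return with_c.groupby("c_call")["read_count"].sum().idxmax()

    agg = (
        records.groupby(group_cols, sort=True)
        .agg(
            total_reads=("read_count", "sum"),
            n_subs=("n_subs", "sum"),
            n_ins=("n_ins", "sum"),
            n_del=("n_del", "sum"),
            aligned_length=("aligned_length", "sum"),
        )
        .reset_index()
    )
    c_major = (
        records.groupby(group_cols, sort=True)[["c_call", "read_count"]]
        .apply(_majority_c)
        .rename("c_call")
        .reset_index()
    )
    agg = agg.merge(c_major, on=group_cols)

    chain_totals = agg.groupby(["sample_id", "chain"])["total_reads"].transform("sum")
    agg["frequency"] = agg["total_reads"] / chain_totals
    return agg


def reaggregate(clones: pd.DataFrame, key: str = "cdr3_vj") -> pd.DataFrame:
    """Aggregate an already-aggregated clone table (idempotence helper)."""
    renamed = clones.rename(columns={"total_reads": "read_count"})
    if "v_call" not in renamed.columns:
        renamed["v_call"] = ""
        renamed["j_call"] = ""
    return aggregate_clones(renamed, key=key)
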