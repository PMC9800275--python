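"""Config-driven orchestration of the full analysis.

A :class:`RunConfig` either points at input files (clonotype TSVs, a
clinical table, a lymphocyte table, a count matrix) or requests a synthetic
cohort via :class:`~icbtox.config.SimConfig`.  :func:`run_pipeline` then
runs every stage — repertoire metrics, BCR maturation metrics, signature
scores, lymphocyte stability, and the genotype/expression-irAE association
battery — and writes tidy TSV/JSON outputs plus a manifest (seed, config
hash, package version) sufficient to re-run identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bcr import ighc_usage, ighd_clone_percentage, mutation_percentage
from .clinical import SeparationError, logistic_association, ls_table, odds_ratio_2x2
from .clonality import rarefied_metric, results_to_frame
from .config import BandThresholds, SimConfig
from .expression import group_effect, normalize, signature_score, size_factors
from .repertoire_io import aggregate_clones, read_clonotypes
from .synthetic import (
    gen_bcr_repertoire,
    gen_cohort,
    gen_expression,
    gen_lymphocyte_series,
    gen_repertoire,
)


@dataclass
class RunConfig:
    """One document controlling a full pipeline run (no hidden defaults)."""

    mode: str = "synthetic"  # or "files"
    sim: SimConfig = field(default_factory=SimConfig)
    # files mode inputs
    clonotype_paths: dict = field(default_factory=dict)  # sample_id -> path
    clonotype_dialect: str = "airr"
    clinical_path: str | None = None
    lymphocyte_path: str | None = None
    counts_path: str | None = None
    signature_genes: list = field(default_factory=list)
    # analysis settings
    clone_key: str = "cdr3_vj"
    small_lt: float = 0.0005
    large_gt: float = 0.005
    n_iter: int = 1000
    n_repertoire_samples: int = 12
    seed: int = 0
    out_dir: str = "icbtox_run"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        return cls(sim=SimConfig(**sim) if isinstance(sim, dict) else sim, **d)

    def config_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        doc = self.to_dict()
        doc.pop("out_dir", None)
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def validate_inputs(cfg: RunConfig) -> dict:
    """Schema-check every referenced input file; report, never raise."""
    errors: list[str] = []
    warnings_: list[str] = []
    if cfg.mode == "synthetic":
        return {"errors": errors, "warnings": warnings_}

    for sid, path in cfg.clonotype_paths.items():
        if not Path(path).exists():
            errors.append(f"clonotypes[{sid}]: file not found: {path}")
            continue
        try:
            res = read_clonotypes(path, cfg.clonotype_dialect, sample_id=sid)
            if len(res.rejects):
                warnings_.append(f"clonotypes[{sid}]: {len(res.rejects)} rejected row(s)")
        except Exception as exc:  # report, don't raise
            errors.append(f"clonotypes[{sid}]: {exc}")

    if cfg.clinical_path:
        try:
            clin = pd.read_csv(cfg.clinical_path, sep="\t")
            for col in ("patient_id", "genotype_dose", "icb_type", "irae"):
                if col not in clin.columns:
                    errors.append(f"clinical table missing column {col!r}")
        except Exception as exc:
            errors.append(f"clinical table: {exc}")
    if cfg.lymphocyte_path:
        try:
            lym = pd.read_csv(cfg.lymphocyte_path, sep="\t")
            for col in ("patient_id", "day_offset", "lymphocyte_count"):
                if col not in lym.columns:
                    errors.append(f"lymphocyte table missing column {col!r}")
            if "day_offset" in lym.columns:
                bad = pd.to_numeric(lym["day_offset"], errors="coerce").isna()
                for i in lym.index[bad]:
                    errors.append(f"lymphocyte table: unparseable day_offset at row {int(i) + 1}")
        except Exception as exc:
            errors.append(f"lymphocyte table: {exc}")
    if cfg.counts_path and not Path(cfg.counts_path).exists():
        errors.append(f"counts matrix not found: {cfg.counts_path}")
    return {"errors": errors, "warnings": warnings_}


def _synthetic_bundle(cfg: RunConfig) -> dict:
    sim = cfg.sim.replace(seed=cfg.seed)
    cohort = gen_cohort(sim)
    n_rep = min(cfg.n_repertoire_samples, len(cohort))
    rep_patients = cohort.head(n_rep)
    tcr = {
        row.patient_id: aggregate_clones(
            gen_repertoire(sim, skew=0.0, sample_id=row.patient_id), key=cfg.clone_key
        )
        for row in rep_patients.itertuples()
    }
    bcr = {
        row.patient_id: aggregate_clones(
            gen_bcr_repertoire(sim, carrier=bool(row.carrier), sample_id=row.patient_id),
            key=cfg.clone_key,
        )
        for row in rep_patients.itertuples()
    }
    signature = cfg.signature_genes or [f"MITO{i:02d}" for i in range(1, 51)]
    counts = gen_expression(sim, cohort, signature_genes=signature)
    lymph = gen_lymphocyte_series(sim, cohort)
    return {
        "cohort": cohort,
        "tcr": tcr,
        "bcr": bcr,
        "counts": counts,
        "signature": signature,
        "lymphocytes": lymph,
    }


def _files_bundle(cfg: RunConfig) -> dict:
    tcr: dict = {}
    bcr: dict = {}
    for sid, path in cfg.clonotype_paths.items():
        res = read_clonotypes(path, cfg.clonotype_dialect, sample_id=sid)
        clones = aggregate_clones(res.records, key=cfg.clone_key)
        if (clones["chain"] == "TRB").any():
            tcr[sid] = clones[clones["chain"] == "TRB"].reset_index(drop=True)
        if clones["chain"].isin(["IGH", "IGK", "IGL"]).any():
            bcr[sid] = clones[clones["chain"].isin(["IGH", "IGK", "IGL"])].reset_index(drop=True)
    cohort = pd.read_csv(cfg.clinical_path, sep="\t") if cfg.clinical_path else None
    lymph = pd.read_csv(cfg.lymphocyte_path, sep="\t") if cfg.lymphocyte_path else None
    counts = (
        pd.read_csv(cfg.counts_path, sep="\t", index_col=0) if cfg.counts_path else None
    )
    return {
        "cohort": cohort,
        "tcr": tcr,
        "bcr": bcr,
        "counts": counts,
        "signature": cfg.signature_genes,
        "lymphocytes": lymph,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage end-to-end and write the report bundle to disk.

    Returns a dict of the in-memory outputs; on disk the run directory
    holds cohort.tsv, repertoire_metrics.tsv, bcr_metrics.tsv,
    isotype_usage.tsv, signature_scores.tsv, ls.tsv, associations.json and
    manifest.json.
    """
    report = validate_inputs(cfg)
    if report["errors"]:
        raise StageError("validate_inputs: " + "; ".join(report["errors"]))

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = BandThresholds(small_lt=cfg.small_lt, large_gt=cfg.large_gt)

    try:
        bundle = _synthetic_bundle(cfg) if cfg.mode == "synthetic" else _files_bundle(cfg)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"load_inputs: {exc}") from exc

    results: dict = {"validation": report}

    cohort = bundle["cohort"]
    if cohort is not None:
        cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)

    # --- repertoire clonality metrics -------------------------------------
    if bundle["tcr"]:
        try:
            frames = []
            for metric in ("gini", "large_clone_count", "occupancy_small",
                           "occupancy_mid", "occupancy_large"):
                res = rarefied_metric(
                    bundle["tcr"], metric=metric, n_iter=cfg.n_iter,
                    seed=cfg.seed, thresholds=thr,
                )
                frames.append(results_to_frame(res))
            rep = pd.concat(frames, ignore_index=True)
            rep.to_csv(out / "repertoire_metrics.tsv", sep="\t", index=False)
            results["repertoire_metrics"] = rep
        except Exception as exc:
            raise StageError(f"repertoire_metrics: {exc}") from exc

    # --- BCR maturation metrics -------------------------------------------
    if bundle["bcr"]:
        try:
            mut_rows, usage_rows = [], []
            for sid, clones in bundle["bcr"].items():
                for chain, summary in mutation_percentage(clones).items():
                    mut_rows.append(
                        {
                            "sample_id": sid,
                            "chain": chain,
                            "mutation_pct": summary.mutation_pct,
                            "total_mutations": summary.total_mutations,
                            "total_length": summary.total_length,
                        }
                    )
                for unit in ("clones", "reads"):
                    usage = ighc_usage(clones, unit=unit)
                    for seg, pct in sorted(usage.usage.items()):
                        usage_rows.append(
                            {"sample_id": sid, "unit": unit, "segment": seg, "pct": pct}
                        )
                usage_rows.append(
                    {"sample_id": sid, "unit": "clones", "segment": "IGHD_clone_pct",
                     "pct": ighd_clone_percentage(clones)}
                )
            pd.DataFrame(mut_rows).to_csv(out / "bcr_metrics.tsv", sep="\t", index=False)
            pd.DataFrame(usage_rows).to_csv(out / "isotype_usage.tsv", sep="\t", index=False)
            results["bcr_metrics"] = pd.DataFrame(mut_rows)
            results["isotype_usage"] = pd.DataFrame(usage_rows)
        except Exception as exc:
            raise StageError(f"bcr_metrics: {exc}") from exc

    # --- expression scores -------------------------------------------------
    if bundle["counts"] is not None:
        try:
            counts = bundle["counts"]
            norm = normalize(counts, size_factors(counts))
            scores = None
            if bundle["signature"]:
                scores = signature_score(norm, bundle["signature"])
                scores.rename("mitotic_score").to_frame().to_csv(
                    out / "signature_scores.tsv", sep="\t"
                )
                results["signature_scores"] = scores
            if cohort is not None and "IL7" in norm.index and "carrier" in cohort.columns:
                groups = pd.Series(
                    np.where(cohort["carrier"], "carrier", "noncarrier"),
                    index=cohort["patient_id"],
                )
                eff = group_effect(norm, "IL7", groups, reference="noncarrier")
                (out / "il7_effect.json").write_text(
                    json.dumps(dataclasses.asdict(eff), indent=2)
                )
                results["il7_effect"] = eff
        except Exception as exc:
            raise StageError(f"expression_scores: {exc}") from exc

    # --- lymphocyte stability ----------------------------------------------
    if bundle["lymphocytes"] is not None:
        try:
            ls = ls_table(bundle["lymphocytes"])
            ls.to_csv(out / "ls.tsv", sep="\t", index=False)
            results["ls"] = ls
        except Exception as exc:
            raise StageError(f"lymphocyte_stability: {exc}") from exc

    # --- association battery -----------------------------------------------
    assoc: dict = {}
    if cohort is not None and {"carrier", "irae", "icb_type"} <= set(cohort.columns):
        try:
            carrier = cohort["carrier"].astype(bool).to_numpy()
            irae = cohort["irae"].astype(bool).to_numpy()
            table = np.array(
                [
                    [int((carrier & irae).sum()), int((carrier & ~irae).sum())],
                    [int((~carrier & irae).sum()), int((~carrier & ~irae).sum())],
                ]
            )
            fisher = odds_ratio_2x2(table)
            assoc["carrier_irae_fisher"] = dataclasses.asdict(fisher)
            cicb = (cohort["icb_type"] == "cICB").astype(float)
            covs = {
                "carrier_irae_glm": pd.DataFrame({"cicb": cicb.to_numpy()}),
            }
            if "il7_expr" in cohort.columns:
                covs["carrier_irae_glm_il7_adjusted"] = pd.DataFrame(
                    {"cicb": cicb.to_numpy(),
                     "il7_expr": cohort["il7_expr"].to_numpy(dtype=float)}
                )
            for name, cov in covs.items():
                try:
                    glm = logistic_association(
                        irae.astype(float), carrier.astype(float), covariates=cov
                    )
                    assoc[name] = dataclasses.asdict(glm)
                except (SeparationError, ValueError) as exc:
                    # separation / degenerate design is a reported diagnostic
                    assoc[name] = {"error": str(exc)}
        except Exception as exc:
            raise StageError(f"associations: {exc}") from exc
    if assoc:
        (out / "associations.json").write_text(json.dumps(assoc, indent=2))
        results["associations"] = assoc

    manifest = {
        "package": "icbtox",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "stages": sorted(set(results) - {"validation"}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
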