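"""End-to-end orchestration: preprocess, split, screen, mediate, validate.

A run is described by a :class:`RunConfig` (loadable from YAML/JSON): input
paths, the outcome battery with model families, keyword profiles, the
exposure predictor list, thresholds, seeds, and the mode — ``mitm`` runs the
pathway-keyword preselection, ``ewas`` screens every CpG for every outcome
and is otherwise identical.  All report tables are TSV with fixed float
formatting so a repeated run with the same config is byte-identical, and the
structured log carries per-step counts and seeds (never wall-clock state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .mediate import MediationResult, bootstrap_mediation
from .pathways import (
    CpgUniverse,
    DEFAULT_KEYWORD_PROFILES,
    KeywordProfile,
    attach_metadata,
    read_gmt,
    read_manifest,
    read_pathway_metadata,
    select_universe,
)
from .preprocess import (
    beta_to_m,
    qc_filter,
    residualize_cells,
    split_cohort,
    trim_outliers,
)
from .screen import (
    CascadeResult,
    OutcomeSpec,
    Triple,
    fit_cpg_on_exposure,
    fit_outcome_on_cpg,
    run_sequential_screen,
)
from .synthetic import GroundTruth

__all__ = ["RunConfig", "RunResult", "run_pipeline", "validate_triples"]

_VERSION = "0.1.0"


@dataclass
class RunConfig:
    methylation_path: str
    cohort_path: str
    gene_sets_path: str
    pathway_metadata_path: str
    manifest_path: str
    outcomes: list[OutcomeSpec]
    exposures: list[str]
    out_dir: str
    keyword_profiles: dict[str, tuple[str, ...]] = field(default_factory=dict)
    transforms: list[dict] = field(default_factory=list)
    alpha: float = 0.05
    split_fraction: float = 0.70
    split_seed: int = 0
    n_boot: int = 500
    bootstrap_seed: int = 0
    ci_level: float = 0.95
    mode: str = "mitm"
    ground_truth_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("mitm", "ewas"):
            raise ValueError(f"mode must be 'mitm' or 'ewas', got {self.mode!r}")
        for spec in self.outcomes:
            if spec.name not in self.keyword_profiles:
                if spec.name in DEFAULT_KEYWORD_PROFILES:
                    self.keyword_profiles[spec.name] = DEFAULT_KEYWORD_PROFILES[spec.name]
                elif self.mode == "mitm":
                    raise ValueError(
                        f"no keyword profile for outcome {spec.name!r}"
                    )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        inputs = d["inputs"]
        outcomes = [
            OutcomeSpec(
                name=o["name"],
                family=o["family"],
                age_column=o.get("age_column"),
            )
            for o in d["outcomes"]
        ]
        split = d.get("split", {})
        boot = d.get("bootstrap", {})
        return cls(
            methylation_path=inputs["methylation"],
            cohort_path=inputs["cohort"],
            gene_sets_path=inputs["gene_sets"],
            pathway_metadata_path=inputs["pathway_metadata"],
            manifest_path=inputs["manifest"],
            ground_truth_path=inputs.get("ground_truth"),
            outcomes=outcomes,
            exposures=list(d["exposures"]),
            keyword_profiles={
                k: tuple(v) for k, v in d.get("keyword_profiles", {}).items()
            },
            transforms=list(d.get("transforms", [])),
            alpha=float(d.get("alpha", 0.05)),
            split_fraction=float(split.get("fraction", 0.70)),
            split_seed=int(split.get("seed", 0)),
            n_boot=int(boot.get("n_boot", 500)),
            bootstrap_seed=int(boot.get("seed", 0)),
            ci_level=float(boot.get("ci_level", 0.95)),
            mode=d.get("mode", "mitm"),
            out_dir=d["out_dir"],
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunResult:
    cascade: CascadeResult
    mediation: list[MediationResult]
    validation: pd.DataFrame
    discovery_ids: list[str]
    validation_ids: list[str]
    log: dict


def materialize_transforms(cohort: pd.DataFrame, transforms: list[dict]) -> pd.DataFrame:
    """Create declared exposure-transform columns (log, dichotomize-at-LOD).

    ``log`` adds ``<column>_log`` (non-positive values become missing);
    ``dichotomize`` adds ``<column>_gt_lod`` as a 0/1 indicator of exceeding
    the declared limit of detection.  Existing columns are left untouched.
    """
    cohort = cohort.copy()
    for t in transforms:
        col = t["column"]
        kind = t["transform"]
        if col not in cohort.columns:
            raise ValueError(f"transform references missing column {col!r}")
        vals = cohort[col].to_numpy(dtype=float)
        if kind == "log":
            name = f"{col}_log"
            if name not in cohort.columns:
                with np.errstate(divide="ignore", invalid="ignore"):
                    logged = np.where(vals > 0, np.log(vals), np.nan)
                cohort[name] = logged
        elif kind == "dichotomize":
            lod = float(t["lod"])
            cohort[f"{col}_gt_lod"] = (vals > lod).astype(float)
        else:
            raise ValueError(f"unknown transform {kind!r}")
    return cohort


def _check_schema(cohort: pd.DataFrame, config: RunConfig) -> None:
    required = ["sex", "ethnicity"]
    required += [s.name for s in config.outcomes]
    required += [s.age_column for s in config.outcomes]
    required += list(config.exposures)
    for col in required:
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")


def validate_triples(
    triples: list[Triple],
    cohort_val: pd.DataFrame,
    meth_val: pd.DataFrame,
    outcome_specs: list[OutcomeSpec],
    discovery: CascadeResult | None = None,
) -> pd.DataFrame:
    """Refit the CpG-outcome and exposure-CpG models on the validation set.

    Reports estimates and raw p-values plus sign-agreement flags against the
    discovery estimates; no selection decision is made here (replication is
    reported, not gated).  Triples whose validation data are missing or too
    small are flagged rather than fitted.
    """
    specs = {s.name: s for s in outcome_specs}
    rows = []
    for t in triples:
        spec = specs[t.outcome]
        for cpg in t.mediators:
            row: dict = {"outcome": t.outcome, "exposure": t.exposure, "cpg": cpg}
            missing = [
                c for c in (t.outcome, t.exposure, "sex", "ethnicity", spec.age_column)
                if c not in cohort_val.columns
            ]
            if missing or cpg not in meth_val.columns:
                row["flag"] = "missing_data"
                rows.append(row)
                continue
            r2 = fit_outcome_on_cpg(
                cohort_val[t.outcome],
                meth_val[cpg],
                cohort_val[["sex", "ethnicity", spec.age_column]],
                spec.family,
            )
            r3 = fit_cpg_on_exposure(
                meth_val[cpg],
                cohort_val[t.exposure],
                cohort_val[["sex", "ethnicity"]],
            )
            row.update(
                {
                    "cpg_outcome_estimate": r2.estimate,
                    "cpg_outcome_raw_p": r2.raw_p if r2.converged else np.nan,
                    "exposure_cpg_estimate": r3.estimate,
                    "exposure_cpg_raw_p": r3.raw_p if r3.converged else np.nan,
                    "flag": "" if (r2.converged and r3.converged) else ";".join(r2.flags + r3.flags),
                }
            )
            if discovery is not None:
                d2 = discovery.step2
                d2 = d2[(d2["outcome"] == t.outcome) & (d2["cpg"] == cpg)]
                d3 = discovery.step3
                d3 = d3[
                    (d3["outcome"] == t.outcome)
                    & (d3["cpg"] == cpg)
                    & (d3["exposure"] == t.exposure)
                ]
                if len(d2) == 1 and np.isfinite(r2.estimate):
                    row["cpg_outcome_sign_agrees"] = bool(
                        np.sign(r2.estimate) == np.sign(d2["estimate"].iloc[0])
                    )
                if len(d3) == 1 and np.isfinite(r3.estimate):
                    row["exposure_cpg_sign_agrees"] = bool(
                        np.sign(r3.estimate) == np.sign(d3["estimate"].iloc[0])
                    )
            rows.append(row)
    columns = [
        "outcome", "exposure", "cpg",
        "cpg_outcome_estimate", "cpg_outcome_raw_p", "cpg_outcome_sign_agrees",
        "exposure_cpg_estimate", "exposure_cpg_raw_p", "exposure_cpg_sign_agrees",
        "flag",
    ]
    return pd.DataFrame(rows, columns=columns)


def _mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        e = r.estimates
        rows.append(
            {
                "exposure": r.exposure,
                "cpgs": ";".join(r.mediators),
                "outcome": r.outcome,
                "total_effect": e.total,
                "direct_effect": e.direct,
                "indirect_effect": e.indirect,
                "mediation_pct": 100.0 * e.proportion,
                "direct_ci_lo": r.direct_ci[0],
                "direct_ci_hi": r.direct_ci[1],
                "indirect_ci_lo": r.indirect_ci[0],
                "indirect_ci_hi": r.indirect_ci[1],
                "mediation_pct_ci_lo": 100.0 * r.proportion_ci[0],
                "mediation_pct_ci_hi": 100.0 * r.proportion_ci[1],
                "n": e.n,
                "n_bootstrap": r.n_bootstrap,
                "unstable": r.unstable,
            }
        )
    columns = [
        "exposure", "cpgs", "outcome", "total_effect", "direct_effect",
        "indirect_effect", "mediation_pct", "direct_ci_lo", "direct_ci_hi",
        "indirect_ci_lo", "indirect_ci_hi", "mediation_pct_ci_lo",
        "mediation_pct_ci_hi", "n", "n_bootstrap", "unstable",
    ]
    return pd.DataFrame(rows, columns=columns)


def _overall_table(cascade: CascadeResult) -> pd.DataFrame:
    """Per-triple summary of the three screening coefficients."""
    rows = []
    for t in cascade.triples:
        for cpg in t.mediators:
            s2 = cascade.step2
            s2 = s2[(s2["outcome"] == t.outcome) & (s2["cpg"] == cpg)]
            s3 = cascade.step3
            s3 = s3[
                (s3["outcome"] == t.outcome)
                & (s3["cpg"] == cpg)
                & (s3["exposure"] == t.exposure)
            ]
            s4 = cascade.step4
            s4 = s4[(s4["outcome"] == t.outcome) & (s4["exposure"] == t.exposure)]
            for step, dep, ind, frame in (
                ("cpg_outcome", t.outcome, cpg, s2),
                ("exposure_cpg", cpg, t.exposure, s3),
                ("exposure_outcome", t.outcome, t.exposure, s4),
            ):
                if len(frame) == 1:
                    rows.append(
                        {
                            "step": step,
                            "dependent": dep,
                            "independent": ind,
                            "estimate": frame["estimate"].iloc[0],
                            "raw_p": frame["raw_p"].iloc[0],
                        }
                    )
    return pd.DataFrame(rows, columns=["step", "dependent", "independent", "estimate", "raw_p"])


def _truth_comparison(truth: GroundTruth, triples: list[Triple]) -> pd.DataFrame:
    selected = {
        (t.exposure, m, t.outcome) for t in triples for m in t.mediators
    }
    rows = []
    for p in truth.planted_paths:
        rows.append(
            {
                "exposure": p.exposure,
                "cpg": p.cpg,
                "outcome": p.outcome,
                "true_proportion": p.true_proportion,
                "recovered": (p.exposure, p.cpg, p.outcome) in selected,
            }
        )
    planted = {(p.exposure, p.cpg, p.outcome) for p in truth.planted_paths}
    for key in sorted(selected - planted):
        rows.append(
            {
                "exposure": key[0], "cpg": key[1], "outcome": key[2],
                "true_proportion": np.nan, "recovered": False,
            }
        )
    return pd.DataFrame(
        rows, columns=["exposure", "cpg", "outcome", "true_proportion", "recovered"]
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full cascade and write report tables under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = io.read_cohort_tsv(config.cohort_path)
    cohort = materialize_transforms(cohort, config.transforms)
    _check_schema(cohort, config)
    meth_beta = io.read_methylation_tsv(config.methylation_path, stage="beta")
    manifest = read_manifest(config.manifest_path)
    gene_sets = read_gmt(config.gene_sets_path)
    metadata = read_pathway_metadata(config.pathway_metadata_path)
    pathways = attach_metadata(gene_sets, metadata)
    truth = None
    if config.ground_truth_path:
        truth = GroundTruth.from_dict(io.read_json(config.ground_truth_path))

    cell_columns = [c for c in cohort.columns if c.startswith("cell_")]
    if not cell_columns:
        raise ValueError("cohort table lacks cell-proportion columns (cell_*)")

    # --- methylation preprocessing ----------------------------------------
    meth_qc, qc_report = qc_filter(meth_beta, manifest)
    meth_m = beta_to_m(meth_qc)
    shared = [s for s in meth_m.sample_ids if s in cohort.index]
    cohort = cohort.loc[shared].copy()
    meth_m.values = meth_m.values.loc[shared]
    meth_resid = residualize_cells(meth_m, cohort[cell_columns].rename(
        columns=lambda c: c.removeprefix("cell_")
    ))

    # --- outlier trimming on exposures and outcomes only -------------------
    trim_counts = {}
    for col in list(config.exposures) + [s.name for s in config.outcomes]:
        kept, removed = trim_outliers(cohort[col])
        trim_counts[col] = len(removed)
        if removed:
            cohort.loc[removed, col] = np.nan

    # --- discovery / validation split --------------------------------------
    discovery_ids, validation_ids = split_cohort(
        list(cohort.index), config.split_fraction, config.split_seed
    )
    cohort_disc = cohort.loc[discovery_ids]
    cohort_val = cohort.loc[validation_ids]
    meth_disc = meth_resid.values.loc[discovery_ids]
    meth_val = meth_resid.values.loc[validation_ids]

    # --- universe selection (skipped in EWAS mode) -------------------------
    universes: dict[str, CpgUniverse | frozenset] = {}
    all_cpgs = frozenset(meth_disc.columns)
    for spec in config.outcomes:
        if config.mode == "ewas":
            universes[spec.name] = all_cpgs
        else:
            profile = KeywordProfile(
                spec.name, tuple(config.keyword_profiles[spec.name])
            )
            uni = select_universe(pathways, profile, manifest)
            universes[spec.name] = CpgUniverse(
                outcome=uni.outcome,
                pathway_ids=uni.pathway_ids,
                genes=uni.genes,
                annotated_genes=uni.annotated_genes,
                cpg_ids=frozenset(uni.cpg_ids & all_cpgs),
            )

    # --- screening cascade on the discovery set ----------------------------
    cascade = run_sequential_screen(
        cohort_disc, meth_disc, universes, config.outcomes,
        list(config.exposures), alpha=config.alpha,
    )

    # --- mediation for surviving triples ------------------------------------
    specs = {s.name: s for s in config.outcomes}
    mediation_results: list[MediationResult] = []
    for t_idx, t in enumerate(cascade.triples):
        if not t.mediators:
            continue
        spec = specs[t.outcome]
        res = bootstrap_mediation(
            cohort_disc[t.outcome].to_numpy(dtype=float),
            cohort_disc[t.exposure].to_numpy(dtype=float),
            meth_disc[list(t.mediators)],
            cohort_disc[["sex", "ethnicity", spec.age_column]].to_numpy(dtype=float),
            cohort_disc[["sex", "ethnicity"]].to_numpy(dtype=float),
            spec.family,
            exposure=t.exposure,
            outcome=t.outcome,
            mediator_names=list(t.mediators),
            n_boot=config.n_boot,
            ci_level=config.ci_level,
            seed=config.bootstrap_seed + t_idx,
        )
        mediation_results.append(res)

    # --- validation refits ---------------------------------------------------
    validation = validate_triples(
        cascade.triples, cohort_val, meth_val, config.outcomes, discovery=cascade
    )

    # --- reports -------------------------------------------------------------
    io.write_table(qc_report.to_frame(), out / "qc_report.tsv")
    keywords_tbl = pd.DataFrame(
        {
            "outcome": [s.name for s in config.outcomes],
            "keywords": [
                ", ".join(config.keyword_profiles.get(s.name, ()))
                for s in config.outcomes
            ],
        }
    )
    io.write_table(keywords_tbl, out / "table1_keywords.tsv")
    io.write_table(cascade.counts, out / "table2_selection_counts.tsv")
    io.write_table(cascade.step2, out / "step2_full_results.tsv")
    io.write_table(cascade.step3, out / "table3_exposure_cpg.tsv")
    io.write_table(cascade.step4, out / "table4_exposure_outcome.tsv")
    med_tbl = _mediation_table(mediation_results)
    io.write_table(med_tbl, out / "table5_mediation.tsv")
    io.write_table(_overall_table(cascade), out / "table6_overall.tsv")
    io.write_table(validation, out / "validation.tsv")
    if truth is not None:
        io.write_table(_truth_comparison(truth, cascade.triples), out / "truth_comparison.tsv")

    log = {
        "version": _VERSION,
        "mode": config.mode,
        "alpha": config.alpha,
        "seeds": {"split": config.split_seed, "bootstrap": config.bootstrap_seed},
        "n_samples": int(len(cohort)),
        "n_discovery": len(discovery_ids),
        "n_validation": len(validation_ids),
        "n_cpgs_post_qc": int(meth_resid.shape[1]),
        "outlier_removals": trim_counts,
        "universe_sizes": {
            s.name: len(
                universes[s.name].cpg_ids
                if isinstance(universes[s.name], CpgUniverse)
                else universes[s.name]
            )
            for s in config.outcomes
        },
        "n_step2_selected": {
            s.name: int(
                (
                    (cascade.step2["outcome"] == s.name)
                    & (cascade.step2["adj_p"] < config.alpha)
                ).sum()
            )
            for s in config.outcomes
        },
        "n_triples": len(cascade.triples),
        "fit_failures": {
            "step2": int((~cascade.step2["converged"]).sum()) if len(cascade.step2) else 0,
            "step3": int((~cascade.step3["converged"]).sum()) if len(cascade.step3) else 0,
            "step4": int((~cascade.step4["converged"]).sum()) if len(cascade.step4) else 0,
        },
    }
    io.write_json(log, out / "log.json")

    return RunResult(
        cascade=cascade,
        mediation=mediation_results,
        validation=validation,
        discovery_ids=discovery_ids,
        validation_ids=validation_ids,
        log=log,
    )
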