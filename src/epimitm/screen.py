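"""Sequential association screens linking outcomes, CpGs, and exposures.

Three regression screens are run per outcome, each with its own
Benjamini-Hochberg multiple-testing family:

* outcome ~ CpG M-residual + sex + ethnicity + age-at-testing, Gaussian with
  identity link for continuous scores and NB2 with log link for count scores;
  family size = the outcome's preselected CpG universe;
* CpG M-residual ~ exposure + sex + ethnicity (no age — the mediator model
  deliberately carries a smaller covariate set), ordinary least squares;
  family size = exposures x CpGs surviving the first screen, per outcome;
* outcome ~ exposure + sex + ethnicity + age, same family as the first
  screen; family size = the exposure-outcome tests actually run at this step.

An (exposure, outcome) pair advances to mediation only if it is significant
at the final screen; its mediators are the CpGs significant in both of the
first two screens.  Failed fits (rank deficiency, non-convergence, too few
complete cases) are flagged, contribute p = 1 to their family, and never
abort the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import FitResult, nb2_fit, ols_fit
from .pathways import CpgUniverse

__all__ = [
    "OutcomeSpec",
    "ScreenResult",
    "Triple",
    "CascadeResult",
    "fit_outcome_on_cpg",
    "fit_cpg_on_exposure",
    "fit_outcome_on_exposure",
    "bh_adjust",
    "run_sequential_screen",
]

MIN_N = 20  # fewest complete cases a single fit will accept


@dataclass(frozen=True)
class OutcomeSpec:
    """How one outcome enters the models.

    ``family`` is ``continuous`` (Gaussian, identity link) or ``count`` (NB2,
    log link).  ``age_column`` names the cohort column holding the
    outcome-specific age at testing; it defaults to ``age_<name>`` because
    instruments administered at different ages are distinct outcomes.
    """

    name: str
    family: str
    age_column: str | None = None

    def __post_init__(self) -> None:
        if self.family not in ("continuous", "count"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.age_column is None:
            object.__setattr__(self, "age_column", f"age_{self.name}")


@dataclass
class ScreenResult:
    """One tested (predictor, response) pair."""

    response: str
    predictor: str
    estimate: float
    se: float
    raw_p: float
    n: int
    family_id: str
    converged: bool
    flags: tuple[str, ...] = ()
    adj_p: float | None = None


def _family_fit(X: np.ndarray, y: np.ndarray, family: str) -> FitResult:
    if family == "continuous":
        return ols_fit(X, y)
    return nb2_fit(X, y)


def _screen_fit(
    response: np.ndarray,
    predictor: np.ndarray,
    covs: np.ndarray,
    family: str,
    response_id: str,
    predictor_id: str,
    family_id: str,
) -> ScreenResult:
    """Complete-case fit of response ~ predictor + covs; predictor slope only."""
    cols = [response, predictor] + [covs[:, j] for j in range(covs.shape[1])]
    mask = np.ones(len(response), dtype=bool)
    for c in cols:
        mask &= np.isfinite(c)
    n = int(mask.sum())
    if n < MIN_N:
        return ScreenResult(
            response_id, predictor_id, np.nan, np.nan, 1.0, n, family_id,
            converged=False, flags=("insufficient_n",),
        )
    X = np.column_stack([np.ones(n), predictor[mask], covs[mask]])
    res = _family_fit(X, response[mask], family)
    if not res.converged:
        return ScreenResult(
            response_id, predictor_id, np.nan, np.nan, 1.0, n, family_id,
            converged=False, flags=res.flags,
        )
    return ScreenResult(
        response_id,
        predictor_id,
        float(res.params[1]),
        float(res.bse[1]),
        float(res.pvalues[1]),
        n,
        family_id,
        converged=True,
        flags=res.flags,
    )


def _covariate_block(cohort: pd.DataFrame, columns: list[str]) -> np.ndarray:
    missing = [c for c in columns if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table lacks covariate column(s) {missing}")
    return cohort[columns].to_numpy(dtype=float)


def fit_outcome_on_cpg(
    y: pd.Series,
    cpg: pd.Series,
    covs: pd.DataFrame,
    family: str,
    family_id: str = "step2",
) -> ScreenResult:
    """Outcome-on-CpG model: y ~ CpG + sex + ethnicity + age."""
    return _screen_fit(
        y.to_numpy(dtype=float),
        cpg.to_numpy(dtype=float),
        covs.to_numpy(dtype=float),
        family,
        str(y.name),
        str(cpg.name),
        family_id,
    )


def fit_cpg_on_exposure(
    cpg: pd.Series,
    x: pd.Series,
    covs: pd.DataFrame,
    family_id: str = "step3",
) -> ScreenResult:
    """Mediator model: CpG ~ exposure + sex + ethnicity (OLS, no age)."""
    return _screen_fit(
        cpg.to_numpy(dtype=float),
        x.to_numpy(dtype=float),
        covs.to_numpy(dtype=float),
        "continuous",
        str(cpg.name),
        str(x.name),
        family_id,
    )


def fit_outcome_on_exposure(
    y: pd.Series,
    x: pd.Series,
    covs: pd.DataFrame,
    family: str,
    family_id: str = "step4",
) -> ScreenResult:
    """Total-effect model: y ~ exposure + sex + ethnicity + age."""
    return _screen_fit(
        y.to_numpy(dtype=float),
        x.to_numpy(dtype=float),
        covs.to_numpy(dtype=float),
        family,
        str(y.name),
        str(x.name),
        family_id,
    )


def bh_adjust(raw_ps: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the family size; it may exceed the number of p-values supplied
    (tests that were planned but, e.g., failed to converge are then implicitly
    counted at p = 1).  ``adj_i = min_{j >= rank(i)} p_(j) * m / j``, capped
    at one.
    """
    ps = np.asarray(raw_ps, dtype=float)
    k = len(ps)
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"family size m={m} smaller than number of tests {k}")
    if k == 0:
        return np.empty(0)
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, k + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(k)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


@dataclass(frozen=True)
class Triple:
    """An exposure-outcome pair that survived all screens, with mediators."""

    exposure: str
    outcome: str
    mediators: tuple[str, ...]


@dataclass
class CascadeResult:
    step2: pd.DataFrame
    step3: pd.DataFrame
    step4: pd.DataFrame
    triples: list[Triple]
    counts: pd.DataFrame


def _results_frame(results: list[ScreenResult], extra: dict[str, list]) -> pd.DataFrame:
    base = {
        "estimate": [r.estimate for r in results],
        "se": [r.se for r in results],
        "raw_p": [r.raw_p for r in results],
        "adj_p": [r.adj_p for r in results],
        "n": [r.n for r in results],
        "converged": [r.converged for r in results],
        "flags": [";".join(r.flags) for r in results],
    }
    return pd.DataFrame({**extra, **base})


def run_sequential_screen(
    cohort: pd.DataFrame,
    meth: pd.DataFrame,
    universes: dict[str, CpgUniverse | frozenset[str]],
    outcome_specs: list[OutcomeSpec],
    exposures: list[str],
    alpha: float = 0.05,
) -> CascadeResult:
    """Run the outcome->CpG->exposure->outcome cascade on one cohort.

    ``meth`` is the samples x CpGs M-residual matrix aligned to ``cohort``'s
    index.  ``universes`` maps each outcome to its preselected CpG universe
    (a :class:`~epimitm.pathways.CpgUniverse` or a plain set of CpG ids, the
    latter used by the EWAS comparison mode).  Outcomes are processed
    independently, so their order never changes any result.
    """
    meth = meth.loc[cohort.index]
    meth_cols = {c: i for i, c in enumerate(meth.columns)}
    meth_vals = meth.to_numpy(dtype=float)

    step2_rows: list[ScreenResult] = []
    step2_meta: dict[str, list] = {"outcome": [], "cpg": []}
    selected_cpgs: dict[str, list[str]] = {}
    counts_rows = []

    specs = {s.name: s for s in outcome_specs}

    # --- screen outcomes against their CpG universes -----------------------
    for spec in outcome_specs:
        uni = universes.get(spec.name, frozenset())
        cpg_ids = sorted(uni.cpg_ids if isinstance(uni, CpgUniverse) else uni)
        cpg_ids = [c for c in cpg_ids if c in meth_cols]
        y = cohort[spec.name].to_numpy(dtype=float)
        covs = _covariate_block(cohort, ["sex", "ethnicity", spec.age_column])
        out_results = []
        for cpg in cpg_ids:
            r = _screen_fit(
                y, meth_vals[:, meth_cols[cpg]], covs, spec.family,
                spec.name, cpg, "step2",
            )
            out_results.append(r)
        if out_results:
            adj = bh_adjust([r.raw_p for r in out_results], m=len(out_results))
            for r, a in zip(out_results, adj):
                r.adj_p = float(a)
        sel = [r.predictor for r in out_results if r.adj_p is not None and r.adj_p < alpha]
        selected_cpgs[spec.name] = sel
        step2_rows.extend(out_results)
        step2_meta["outcome"].extend([spec.name] * len(out_results))
        step2_meta["cpg"].extend([r.predictor for r in out_results])

        row = {"outcome": spec.name}
        if isinstance(uni, CpgUniverse):
            row.update(uni.counts())
        else:
            row.update(
                {
                    "n_pathways": np.nan,
                    "n_genes": np.nan,
                    "n_annotated_genes": np.nan,
                    "n_cpgs": len(cpg_ids),
                }
            )
        row["n_significant_cpgs"] = len(sel)
        counts_rows.append(row)

    # --- exposures against the surviving CpGs, per outcome -----------------
    step3_rows: list[ScreenResult] = []
    step3_meta: dict[str, list] = {"outcome": [], "exposure": [], "cpg": []}
    step3_selected: dict[str, set[tuple[str, str]]] = {}
    for spec in outcome_specs:
        sel = selected_cpgs[spec.name]
        if not sel:
            continue
        y = cohort[spec.name].to_numpy(dtype=float)
        covs = _covariate_block(cohort, ["sex", "ethnicity"])
        y_present = np.isfinite(y)
        out_results = []
        for exposure in exposures:
            x = cohort[exposure].to_numpy(dtype=float)
            for cpg in sel:
                cvec = meth_vals[:, meth_cols[cpg]].copy()
                cvec[~y_present] = np.nan  # samples must carry the outcome too
                r = _screen_fit(
                    cvec, x, covs, "continuous", cpg, exposure, "step3",
                )
                out_results.append(r)
        adj = bh_adjust([r.raw_p for r in out_results], m=len(out_results))
        for r, a in zip(out_results, adj):
            r.adj_p = float(a)
        step3_selected[spec.name] = {
            (r.predictor, r.response)
            for r in out_results
            if r.adj_p is not None and r.adj_p < alpha
        }
        step3_rows.extend(out_results)
        step3_meta["outcome"].extend([spec.name] * len(out_results))
        step3_meta["exposure"].extend([r.predictor for r in out_results])
        step3_meta["cpg"].extend([r.response for r in out_results])

    # --- exposure-outcome tests for the surviving pairs --------------------
    step4_rows: list[ScreenResult] = []
    step4_meta: dict[str, list] = {"outcome": [], "exposure": []}
    pair_keys: list[tuple[str, str]] = []
    for spec in outcome_specs:
        pairs = step3_selected.get(spec.name, set())
        surviving_exposures = sorted({e for e, _ in pairs})
        y = cohort[spec.name].to_numpy(dtype=float)
        covs = _covariate_block(cohort, ["sex", "ethnicity", spec.age_column])
        for exposure in surviving_exposures:
            r = _screen_fit(
                y, cohort[exposure].to_numpy(dtype=float), covs, spec.family,
                spec.name, exposure, "step4",
            )
            step4_rows.append(r)
            step4_meta["outcome"].append(spec.name)
            step4_meta["exposure"].append(exposure)
            pair_keys.append((spec.name, exposure))
    if step4_rows:
        adj = bh_adjust([r.raw_p for r in step4_rows], m=len(step4_rows))
        for r, a in zip(step4_rows, adj):
            r.adj_p = float(a)

    # --- assemble surviving triples ----------------------------------------
    triples = []
    for (outcome, exposure), r in zip(pair_keys, step4_rows):
        if r.adj_p is not None and r.adj_p < alpha:
            mediators = tuple(
                sorted(c for e, c in step3_selected[outcome] if e == exposure)
            )
            triples.append(Triple(exposure=exposure, outcome=outcome, mediators=mediators))
    triples.sort(key=lambda t: (t.outcome, t.exposure))

    return CascadeResult(
        step2=_results_frame(step2_rows, step2_meta),
        step3=_results_frame(step3_rows, step3_meta),
        step4=_results_frame(step4_rows, step4_meta),
        triples=triples,
        counts=pd.DataFrame(counts_rows),
    )
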