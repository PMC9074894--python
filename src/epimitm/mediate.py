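"""Direct/indirect effect decomposition with bootstrap uncertainty.

For a surviving (exposure, outcome) pair with mediating CpGs, effects are
defined on the link scale by the difference-of-coefficients method:

* total effect  — exposure coefficient in ``outcome ~ exposure + covs``;
* direct effect — exposure coefficient in
  ``outcome ~ exposure + mediators + covs`` (same family and link);
* indirect effect = total - direct.

The difference method is used because it remains well defined under the
negative-binomial log link, where product- and difference-based definitions
no longer coincide.  In the linear-Gaussian case with identical covariate
sets in the mediator and outcome models, the difference equals the sum of
per-mediator products ``a_k * b_k`` exactly, which is the algebraic check the
tests rely on.  Per-mediator contributions are the products ``a_k * b_k``
(``a_k`` from ``mediator_k ~ exposure + sex + ethnicity``, ``b_k`` from the
full outcome model), rescaled to sum to the indirect effect.

The summary statistic is the mediated proportion
``p = |IE| / (|IE| + |DE|)``; it lies in [0, 1] by construction and is
undefined only when both effects are exactly zero.  Uncertainty comes from a
nonparametric bootstrap over individuals with percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import nb2_fit, ols_fit

__all__ = [
    "EffectEstimates",
    "MediationResult",
    "estimate_effects",
    "bootstrap_mediation",
    "mediation_proportion",
]


def mediation_proportion(indirect: float, direct: float) -> float:
    """``|IE| / (|IE| + |DE|)``; NaN (undefined) when both are zero."""
    denom = abs(indirect) + abs(direct)
    if denom == 0.0:
        return float("nan")
    return abs(indirect) / denom


@dataclass(frozen=True)
class EffectEstimates:
    total: float
    direct: float
    indirect: float
    per_mediator: dict[str, float]
    proportion: float
    n: int
    converged: bool
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class MediationResult:
    """Point estimates plus bootstrap percentile intervals for one triple."""

    exposure: str
    outcome: str
    mediators: tuple[str, ...]
    estimates: EffectEstimates
    ci_level: float
    direct_ci: tuple[float, float]
    indirect_ci: tuple[float, float]
    proportion_ci: tuple[float, float]
    n_bootstrap: int
    n_failed: int
    seed: int
    unstable: bool


def _fit(X: np.ndarray, y: np.ndarray, family: str):
    return ols_fit(X, y) if family == "continuous" else nb2_fit(X, y)


def estimate_effects(
    y: np.ndarray,
    x: np.ndarray,
    mediators: pd.DataFrame | np.ndarray,
    outcome_covs: np.ndarray,
    mediator_covs: np.ndarray,
    family: str,
    mediator_names: list[str] | None = None,
) -> EffectEstimates:
    """Difference-of-coefficients decomposition on one complete-case dataset.

    ``outcome_covs`` enter both outcome models (conventionally sex, ethnicity,
    age at testing); ``mediator_covs`` enter the mediator-on-exposure models
    (conventionally sex and ethnicity only).  Passing the same array for both
    recovers the setting in which difference and product methods coincide for
    the linear-Gaussian family.
    """
    med_names = mediator_names
    if isinstance(mediators, pd.DataFrame):
        med_names = med_names or [str(c) for c in mediators.columns]
        mediators = mediators.to_numpy(dtype=float)
    mediators = np.atleast_2d(np.asarray(mediators, dtype=float))
    if mediators.shape[0] != len(y):
        mediators = mediators.T
    n_med = mediators.shape[1]
    if med_names is None:
        med_names = [f"m{k}" for k in range(n_med)]

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    mask = np.isfinite(y) & np.isfinite(x)
    mask &= np.all(np.isfinite(mediators), axis=1)
    mask &= np.all(np.isfinite(outcome_covs), axis=1)
    mask &= np.all(np.isfinite(mediator_covs), axis=1)
    n = int(mask.sum())
    y, x = y[mask], x[mask]
    med = mediators[mask]
    oc = outcome_covs[mask]
    mc = mediator_covs[mask]

    ones = np.ones(n)
    total_fit = _fit(np.column_stack([ones, x, oc]), y, family)
    full_fit = _fit(np.column_stack([ones, x, med, oc]), y, family)
    if not (total_fit.converged and full_fit.converged):
        flags = tuple(set(total_fit.flags + full_fit.flags)) or ("nonconvergence",)
        return EffectEstimates(
            np.nan, np.nan, np.nan, {}, np.nan, n, converged=False, flags=flags
        )

    total = float(total_fit.params[1])
    direct = float(full_fit.params[1])
    indirect = total - direct

    # per-mediator products, rescaled so the contributions sum to IE
    contributions: dict[str, float] = {}
    products = np.empty(n_med)
    for k in range(n_med):
        a_fit = ols_fit(np.column_stack([ones, x, mc]), med[:, k])
        if not a_fit.converged:
            return EffectEstimates(
                total, direct, indirect, {}, mediation_proportion(indirect, direct),
                n, converged=False, flags=("mediator_model_failed",),
            )
        b_k = float(full_fit.params[2 + k])
        products[k] = float(a_fit.params[1]) * b_k
    prod_sum = float(products.sum())
    if prod_sum != 0.0:
        scaled = products * (indirect / prod_sum)
    else:
        scaled = products
    contributions = {name: float(v) for name, v in zip(med_names, scaled)}

    return EffectEstimates(
        total=total,
        direct=direct,
        indirect=indirect,
        per_mediator=contributions,
        proportion=mediation_proportion(indirect, direct),
        n=n,
        converged=True,
    )


def bootstrap_mediation(
    y: np.ndarray,
    x: np.ndarray,
    mediators: pd.DataFrame | np.ndarray,
    outcome_covs: np.ndarray,
    mediator_covs: np.ndarray,
    family: str,
    exposure: str = "exposure",
    outcome: str = "outcome",
    mediator_names: list[str] | None = None,
    n_boot: int = 500,
    ci_level: float = 0.95,
    seed: int = 0,
    max_fail_fraction: float = 0.20,
) -> MediationResult:
    """Nonparametric bootstrap of the effect decomposition.

    Individuals (rows) are resampled with replacement, preserving the joint
    exposure-mediator-outcome distribution; no stratification is applied.
    Point estimates come from the full sample, intervals are percentile
    intervals over the successful resamples.  If more than
    ``max_fail_fraction`` of resamples fail to converge the result is marked
    unstable.  Identical seeds give identical intervals.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if isinstance(mediators, pd.DataFrame):
        mediator_names = mediator_names or [str(c) for c in mediators.columns]
        mediators = mediators.to_numpy(dtype=float)
    mediators = np.atleast_2d(np.asarray(mediators, dtype=float))
    if mediators.shape[0] != len(y):
        mediators = mediators.T

    point = estimate_effects(
        y, x, mediators, outcome_covs, mediator_covs, family,
        mediator_names=mediator_names,
    )
    if not point.converged:
        raise RuntimeError(
            f"full-sample mediation fit failed for ({exposure}, {outcome}): "
            f"{point.flags}"
        )

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    des, ies, props = [], [], []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        est = estimate_effects(
            y[idx], x[idx], mediators[idx], outcome_covs[idx],
            mediator_covs[idx], family, mediator_names=mediator_names,
        )
        if not est.converged or not np.isfinite(est.indirect):
            n_failed += 1
            continue
        des.append(est.direct)
        ies.append(est.indirect)
        props.append(est.proportion)

    lo = 100 * (1 - ci_level) / 2
    hi = 100 - lo

    def _ci(vals: list[float]) -> tuple[float, float]:
        arr = np.asarray(vals)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            return (float("nan"), float("nan"))
        return (float(np.percentile(arr, lo)), float(np.percentile(arr, hi)))

    return MediationResult(
        exposure=exposure,
        outcome=outcome,
        mediators=tuple(mediator_names or [f"m{k}" for k in range(mediators.shape[1])]),
        estimates=point,
        ci_level=ci_level,
        direct_ci=_ci(des),
        indirect_ci=_ci(ies),
        proportion_ci=_ci(props),
        n_bootstrap=n_boot,
        n_failed=n_failed,
        seed=seed,
        unstable=n_failed > max_fail_fraction * n_boot,
    )
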