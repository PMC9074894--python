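"""Methylation preprocessing and cohort bookkeeping.

The modelling scale throughout the pipeline is the M-value residual: array
beta-values are logit2-transformed to M-values, and estimated cord-blood
cell-type proportions are regressed out per CpG so that downstream
associations are not driven by cell-composition differences between samples.
Cohort-level steps (4-SD outlier trimming of exposures and outcomes, the
70/30 discovery/validation split) also live here.

The fixed order is: coverage QC on beta-values, then the beta->M transform,
then cell residualization.  Outlier trimming applies only to exposure and
outcome columns, never to methylation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "QCReport",
    "qc_filter",
    "beta_to_m",
    "m_to_beta",
    "residualize_cells",
    "trim_outliers",
    "split_cohort",
]

#: chromosome labels treated as sex chromosomes by default
SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY", "23", "24"})

_STAGES = ("beta", "M", "M_residual")


@dataclass
class MethylationMatrix:
    """Samples x CpGs methylation grid tagged with its processing stage.

    ``values`` is indexed by sample id with CpG ids as columns.  ``stage`` is
    one of ``beta`` (fractions in [0, 1]), ``M`` (logit2 scale) or
    ``M_residual`` (M-values with cell composition regressed out).
    """

    values: pd.DataFrame
    stage: str = "beta"

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids in methylation matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate CpG ids in methylation matrix")
        vals = self.values.to_numpy(dtype=float, copy=False)
        finite = vals[np.isfinite(vals)]
        if self.stage == "beta" and finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta-stage values must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class QCReport:
    n_samples_in: int
    n_cpgs_in: int
    dropped_samples: tuple[str, ...]
    dropped_low_coverage_cpgs: tuple[str, ...]
    dropped_sex_cpgs: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "samples_in",
                    "cpgs_in",
                    "samples_dropped_low_coverage",
                    "cpgs_dropped_low_coverage",
                    "cpgs_dropped_sex_chromosome",
                    "samples_out",
                    "cpgs_out",
                ],
                "count": [
                    self.n_samples_in,
                    self.n_cpgs_in,
                    len(self.dropped_samples),
                    len(self.dropped_low_coverage_cpgs),
                    len(self.dropped_sex_cpgs),
                    self.n_samples_in - len(self.dropped_samples),
                    self.n_cpgs_in
                    - len(self.dropped_low_coverage_cpgs)
                    - len(self.dropped_sex_cpgs),
                ],
            }
        )


def qc_filter(
    m: MethylationMatrix,
    manifest: pd.DataFrame,
    sample_cpg_coverage_min: float = 0.95,
    cpg_sample_coverage_min: float = 0.70,
    sex_chromosomes: frozenset[str] = SEX_CHROMOSOMES,
) -> tuple[MethylationMatrix, QCReport]:
    """Coverage and sex-chromosome QC.

    Drops, in order: samples with fewer than ``sample_cpg_coverage_min``
    non-missing CpGs; CpGs with fewer than ``cpg_sample_coverage_min``
    non-missing samples; CpGs whose manifest chromosome is a sex chromosome.
    The defaults are 95% CpG coverage per sample and 70% sample coverage per
    CpG.  The manifest must carry a ``chr`` column indexed by CpG id.
    """
    vals = m.values
    n_samples, n_cpgs = vals.shape
    sample_cov = vals.notna().mean(axis=1)
    keep_samples = sample_cov >= sample_cpg_coverage_min
    if not keep_samples.any():
        raise ValueError(
            f"all {n_samples} samples fall below the "
            f"{sample_cpg_coverage_min:.0%} CpG-coverage threshold"
        )
    dropped_samples = tuple(vals.index[~keep_samples])
    vals = vals.loc[keep_samples]

    cpg_cov = vals.notna().mean(axis=0)
    keep_cpgs = cpg_cov >= cpg_sample_coverage_min
    dropped_cov_cpgs = tuple(vals.columns[~keep_cpgs])
    vals = vals.loc[:, keep_cpgs]

    chrom = manifest["chr"].astype(str).reindex(vals.columns)
    on_sex = chrom.isin(sex_chromosomes).to_numpy()
    dropped_sex = tuple(vals.columns[on_sex])
    vals = vals.loc[:, ~on_sex]

    report = QCReport(
        n_samples_in=n_samples,
        n_cpgs_in=n_cpgs,
        dropped_samples=dropped_samples,
        dropped_low_coverage_cpgs=dropped_cov_cpgs,
        dropped_sex_cpgs=dropped_sex,
    )
    return MethylationMatrix(values=vals.copy(), stage=m.stage), report


def beta_to_m(m: MethylationMatrix, eps: float = 1e-6) -> MethylationMatrix:
    """logit2 transform: ``M = log2(beta / (1 - beta))``.

    Betas at or beyond the [eps, 1-eps] boundary are clamped first; the number
    of clamped entries is reported via a warning so silent saturation cannot
    slip through.
    """
    if m.stage != "beta":
        raise ValueError(f"beta_to_m expects stage='beta', got {m.stage!r}")
    vals = m.values.to_numpy(dtype=float, copy=True)
    clamped = int(np.sum((vals < eps) | (vals > 1 - eps)))
    if clamped:
        warnings.warn(f"clamped {clamped} beta-values to [{eps}, {1 - eps}]")
        vals = np.clip(vals, eps, 1 - eps)
    mvals = np.log2(vals / (1.0 - vals))
    out = pd.DataFrame(mvals, index=m.values.index, columns=m.values.columns)
    return MethylationMatrix(values=out, stage="M")


def m_to_beta(m: MethylationMatrix) -> MethylationMatrix:
    """Inverse of :func:`beta_to_m` (for round-trip checks and simulation)."""
    if m.stage != "M":
        raise ValueError(f"m_to_beta expects stage='M', got {m.stage!r}")
    b = 1.0 / (1.0 + np.power(2.0, -m.values.to_numpy(dtype=float)))
    out = pd.DataFrame(b, index=m.values.index, columns=m.values.columns)
    return MethylationMatrix(values=out, stage="beta")


def residualize_cells(m: MethylationMatrix, cells: pd.DataFrame) -> MethylationMatrix:
    """Regress every CpG's M-values on cell proportions; keep the residuals.

    ``cells`` is samples x cell-types with rows summing to one; one cell-type
    column is dropped to remove the sum-to-one singularity and an intercept is
    added.  Any remaining rank deficiency is an error.  CpGs with missing
    entries are residualized on their complete cases.
    """
    if m.stage != "M":
        raise ValueError(f"residualize_cells expects stage='M', got {m.stage!r}")
    cells = cells.loc[m.values.index]
    sums = cells.to_numpy(dtype=float).sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("cell-proportion rows must sum to 1 (within 1e-6)")
    design = np.column_stack(
        [np.ones(len(cells)), cells.to_numpy(dtype=float)[:, :-1]]
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "cell-proportion design is rank deficient even after dropping "
            f"the {cells.columns[-1]!r} column"
        )
    Y = m.values.to_numpy(dtype=float, copy=True)
    missing = np.isnan(Y)
    if not missing.any():
        coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
        resid = Y - design @ coef
    else:
        resid = np.full_like(Y, np.nan)
        complete = ~missing
        for j in range(Y.shape[1]):
            mask = complete[:, j]
            coef, *_ = np.linalg.lstsq(design[mask], Y[mask, j], rcond=None)
            resid[mask, j] = Y[mask, j] - design[mask] @ coef
    out = pd.DataFrame(resid, index=m.values.index, columns=m.values.columns)
    return MethylationMatrix(values=out, stage="M_residual")


def trim_outliers(values: pd.Series, n_sd: float = 4.0) -> tuple[pd.Series, list]:
    """Single-pass trimming of values beyond ``n_sd`` SDs from the mean.

    Mean and SD are computed once from all non-missing values (the rule is not
    iterated).  A zero SD removes nothing.  Returns the kept series (missing
    entries preserved) and the ids of removed samples.
    """
    obs = values.dropna()
    if len(obs) < 3:
        return values, []
    mean = float(obs.mean())
    sd = float(obs.std(ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        return values, []
    out = np.abs(obs - mean) > n_sd * sd
    removed = list(obs.index[out])
    return values.drop(index=removed), removed


def split_cohort(
    sample_ids: list[str],
    fraction: float = 0.70,
    seed: int = 0,
    n_discovery: int | None = None,
) -> tuple[list[str], list[str]]:
    """Random discovery/validation split, reproducible by seed.

    Discovery size is ``floor(fraction * n + 0.5)`` (round-to-nearest, with
    the remainder going to validation).  Studies that fix the discovery
    count outright rather than deriving it from a fraction can pass
    ``n_discovery`` explicitly.  The two id lists are disjoint, exhaustive,
    and returned in the input order.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    ids = list(sample_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_disc = (
        int(n_discovery)
        if n_discovery is not None
        else int(np.floor(fraction * n + 0.5))
    )
    n_disc = min(max(n_disc, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    chosen = set(perm[:n_disc])
    discovery = [ids[i] for i in range(n) if i in chosen]
    validation = [ids[i] for i in range(n) if i not in chosen]
    return discovery, validation
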