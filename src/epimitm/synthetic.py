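"""Synthetic birth-cohort generator with planted mediation triangles.

The generator emulates the statistical structure the screening pipeline
assumes, with a ground-truth ledger so every downstream stage can be tested
for parameter recovery without any external data:

* exposures are log-normal analyte measurements; the cohort table carries
  both the raw column and its log transform, and planted effects act on the
  log scale (mirroring the convention of analysing log-transformed analytes
  as distinct predictors);
* methylation is generated on the M-value scale — per-CpG baseline plus an
  additive cell-composition shift proportional to (centred) cord-blood cell
  proportions plus the planted exposure effect plus Gaussian noise — and
  returned as beta-values through the inverse logit2 map, so that the
  preprocessing stack (logit2, cell residualization) recovers the generative
  scale exactly;
* one continuous outcome family (IQ-like: identity link, Gaussian noise) and
  one over-dispersed count family (CBCL-like: NB2 with log link) share the
  linear predictor  intercept + covariates + b * M-residual + c_direct *
  exposure, where the covariates are sex, ethnicity and an outcome-specific
  age at testing.

A planted path (a, b, c_direct) therefore has exposure->CpG slope ``a`` on
the M scale, CpG->outcome slope ``b`` on the link scale, and direct slope
``c_direct``; its closed-form mediated proportion is
``|a b| / (|a b| + |c_direct|)``.  Paths whose three effects are all zero are
not recorded — they leave every CpG in the null set.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .pathways import DEFAULT_KEYWORD_PROFILES, Pathway, PathwaySet
from .preprocess import MethylationMatrix

__all__ = [
    "OutcomeConfig",
    "PlantedPathConfig",
    "SimConfig",
    "PlantedPath",
    "GroundTruth",
    "generate_cohort",
    "generate_pathway_fixture",
]

#: keywords common to every outcome profile; not informative about any one
#: outcome, so theme pathways are built from the profile-specific remainder
SHARED_KEYWORDS = frozenset({"children", "brain", "neuron"})


@dataclass(frozen=True)
class OutcomeConfig:
    """Generative settings for one outcome score.

    ``intercept`` and the covariate effects live on the link scale (identity
    for ``continuous``, log for ``count``).  ``noise_sd`` applies to the
    continuous family only; ``dispersion`` is the NB2 size theta (variance
    ``mu + mu^2 / theta``) and must be positive for counts.
    """

    name: str
    family: str
    intercept: float
    noise_sd: float = 10.0
    dispersion: float = 5.0
    age_range: tuple[float, float] = (6.5, 7.5)
    sex_effect: float = 0.0
    ethnicity_effect: float = 0.0
    age_effect: float = 0.0
    keywords: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in ("continuous", "count"):
            raise ValueError(f"unknown outcome family {self.family!r}")
        if self.family == "count" and self.dispersion <= 0:
            raise ValueError("dispersion must be > 0 for count outcomes")
        if not self.keywords:
            object.__setattr__(
                self,
                "keywords",
                DEFAULT_KEYWORD_PROFILES.get(self.name, ("brain", "neuron")),
            )


@dataclass(frozen=True)
class PlantedPathConfig:
    """Requested effect sizes for one exposure -> CpG -> outcome triangle."""

    exposure: str
    outcome: str
    a: float
    b: float
    c_direct: float

    @property
    def is_null(self) -> bool:
        return self.a == 0.0 and self.b == 0.0 and self.c_direct == 0.0


def _default_outcomes() -> tuple[OutcomeConfig, ...]:
    return (
        OutcomeConfig(
            "iq_age7", "continuous", intercept=100.0, noise_sd=12.0,
            age_range=(6.5, 7.5), sex_effect=-2.0, ethnicity_effect=-3.0,
            age_effect=-0.5,
        ),
        OutcomeConfig(
            "cbcl_social_age7", "count", intercept=1.3, dispersion=5.0,
            age_range=(6.5, 7.5), sex_effect=0.2, ethnicity_effect=0.1,
            age_effect=0.05,
        ),
        OutcomeConfig(
            "cbcl_internal_age9", "count", intercept=1.5, dispersion=5.0,
            age_range=(8.5, 9.5), sex_effect=-0.1, ethnicity_effect=0.1,
            age_effect=0.05,
        ),
        OutcomeConfig(
            "dsm_adhd_age7", "count", intercept=1.2, dispersion=5.0,
            age_range=(6.5, 7.5), sex_effect=0.3, ethnicity_effect=0.0,
            age_effect=0.0,
        ),
    )


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level generative settings.

    The defaults reproduce the design of the motivating cohort where it is
    known — 341 samples split 70/30 downstream, ten exposure analytes, a
    mixed continuous/count outcome battery — and conventional values
    elsewhere (Bernoulli(0.5) sex and ethnicity, uniform ages within a year
    of the nominal testing age, Dirichlet cord-blood cell mixtures dominated
    by granulocytes).
    """

    n_samples: int = 341
    n_cpgs: int = 500
    exposure_names: tuple[str, ...] = (
        "pah", "bpa", "cpf", "dehp", "pbde",
        "pm25", "no2", "pah_adduct", "phthalate", "pcb",
    )
    exposure_log_mean: float = 0.0
    exposure_log_sd: float = 1.0
    outcomes: tuple[OutcomeConfig, ...] = field(default_factory=_default_outcomes)
    planted: tuple[PlantedPathConfig, ...] = ()
    cpg_noise_sd: float = 0.25
    cell_types: tuple[str, ...] = (
        "Bcell", "CD4T", "CD8T", "Gran", "Mono", "NK", "nRBC",
    )
    cell_alpha: tuple[float, ...] = (6.0, 12.0, 8.0, 45.0, 6.0, 3.0, 6.0)
    cell_effect_sd: float = 1.0
    cpgs_per_gene: int = 5
    genes_per_pathway: int = 6
    n_pathways: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_cpgs <= 0:
            raise ValueError("n_samples and n_cpgs must be positive")
        if len(self.cell_alpha) != len(self.cell_types):
            raise ValueError("cell_alpha must match cell_types")
        if self.n_pathways < 20:
            raise ValueError("pathway fixture requires at least 20 pathways")
        names = {o.name for o in self.outcomes}
        preds = set(self.predictors) | set(self.exposure_names)
        for p in self.planted:
            if p.outcome not in names:
                raise ValueError(f"planted outcome {p.outcome!r} not configured")
            if p.exposure not in preds:
                raise ValueError(f"planted exposure {p.exposure!r} not configured")
        if len(self.effective_paths) > self.n_cpgs:
            raise ValueError("more planted paths than CpGs")

    @property
    def predictors(self) -> list[str]:
        """The analysis-scale exposure columns (log transforms)."""
        return [f"{n}_log" for n in self.exposure_names]

    @property
    def effective_paths(self) -> tuple[PlantedPathConfig, ...]:
        return tuple(p for p in self.planted if not p.is_null)

    @property
    def cpg_ids(self) -> list[str]:
        return [f"cg{i:08d}" for i in range(self.n_cpgs)]

    def outcome(self, name: str) -> OutcomeConfig:
        for o in self.outcomes:
            if o.name == name:
                return o
        raise KeyError(name)


@dataclass(frozen=True)
class PlantedPath:
    """A realised planted triangle, with its closed-form truths."""

    exposure: str
    cpg: str
    outcome: str
    a: float
    b: float
    c_direct: float

    @property
    def true_proportion(self) -> float:
        denom = abs(self.a * self.b) + abs(self.c_direct)
        if denom == 0.0:
            return float("nan")
        return abs(self.a * self.b) / denom


@dataclass
class GroundTruth:
    """Ledger of planted effects plus the generative scale parameters needed
    for closed-form expectations of each screening coefficient."""

    planted_paths: list[PlantedPath]
    null_cpg_ids: list[str]
    exposure_log_sd: float
    cpg_noise_sd: float

    def path_for(self, cpg: str) -> PlantedPath:
        for p in self.planted_paths:
            if p.cpg == cpg:
                return p
        raise KeyError(cpg)

    def step2_slope(self, path: PlantedPath) -> float:
        """Expected outcome-on-CpG slope (link scale).

        The outcome model omits the exposure, so the slope is the projection
        coefficient ``b + c_direct * cov(X, M) / var(M)`` — exact here
        because exposure (log scale) and CpG noise are jointly Gaussian,
        which keeps the log link collapsible as well.
        """
        vx = self.exposure_log_sd**2
        vm = path.a**2 * vx + self.cpg_noise_sd**2
        return path.b + path.c_direct * path.a * vx / vm

    @staticmethod
    def step3_slope(path: PlantedPath) -> float:
        """Expected CpG-on-exposure slope (M scale): the planted ``a``."""
        return path.a

    @staticmethod
    def step4_slope(path: PlantedPath) -> float:
        """Expected total exposure-outcome slope: ``c_direct + a b``
        (Gaussian mediator noise keeps both links collapsible)."""
        return path.c_direct + path.a * path.b

    def standardized_indirect(self, path: PlantedPath) -> float:
        """|a b| scaled by the exposure SD on the analysis scale."""
        return abs(path.a * path.b) * self.exposure_log_sd

    def to_dict(self) -> dict:
        return {
            "planted_paths": [asdict(p) for p in self.planted_paths],
            "null_cpg_ids": self.null_cpg_ids,
            "exposure_log_sd": self.exposure_log_sd,
            "cpg_noise_sd": self.cpg_noise_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            planted_paths=[PlantedPath(**p) for p in d["planted_paths"]],
            null_cpg_ids=list(d["null_cpg_ids"]),
            exposure_log_sd=d["exposure_log_sd"],
            cpg_noise_sd=d["cpg_noise_sd"],
        )


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, MethylationMatrix, GroundTruth]:
    """Draw one cohort: covariates, exposures, methylation, outcomes.

    Returns the cohort table (covariates, cell proportions, exposures raw and
    log, outcomes, per-outcome ages), the beta-value methylation matrix, and
    the ground-truth ledger.  Identical ``config`` (including seed) gives
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n, n_cpgs = config.n_samples, config.n_cpgs
    sample_ids = [f"S{i:04d}" for i in range(n)]

    cohort = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    cohort["sex"] = rng.integers(0, 2, n)  # 1 = male
    cohort["ethnicity"] = rng.integers(0, 2, n)  # 1 = Dominican
    for oc in config.outcomes:
        cohort[f"age_{oc.name}"] = rng.uniform(*oc.age_range, n)

    z = rng.normal(size=(n, len(config.exposure_names)))
    x_log = config.exposure_log_mean + config.exposure_log_sd * z
    for j, name in enumerate(config.exposure_names):
        cohort[name] = np.exp(x_log[:, j])
        cohort[f"{name}_log"] = x_log[:, j]

    cells = rng.dirichlet(config.cell_alpha, n)
    for t, ct in enumerate(config.cell_types):
        cohort[f"cell_{ct}"] = cells[:, t]

    # methylation on the M scale: bimodal baselines (hypo/hyper-methylated
    # CpGs), additive cell shifts, planted exposure effects, Gaussian noise
    modes = rng.choice([-3.0, 3.0], size=n_cpgs)
    baseline = modes + rng.normal(0.0, 1.0, n_cpgs)
    gamma = rng.normal(0.0, config.cell_effect_sd, size=(len(config.cell_types), n_cpgs))
    eps = rng.normal(0.0, config.cpg_noise_sd, size=(n, n_cpgs))

    cell_mean = np.asarray(config.cell_alpha) / np.sum(config.cell_alpha)
    cell_shift = (cells - cell_mean) @ gamma

    paths: list[PlantedPath] = []
    planted_signal = np.zeros((n, n_cpgs))
    cpg_ids = config.cpg_ids
    for i, pc in enumerate(config.effective_paths):
        xvec = cohort[pc.exposure].to_numpy(dtype=float)
        planted_signal[:, i] = pc.a * xvec
        paths.append(
            PlantedPath(
                exposure=pc.exposure, cpg=cpg_ids[i], outcome=pc.outcome,
                a=pc.a, b=pc.b, c_direct=pc.c_direct,
            )
        )

    m_signal = planted_signal + eps  # what survives cell residualization
    m_values = baseline[None, :] + cell_shift + m_signal

    with np.errstate(over="ignore"):
        beta = 1.0 / (1.0 + np.power(2.0, -m_values))
    out_of_range = (beta <= 0.0) | (beta >= 1.0)
    if out_of_range.any():
        warnings.warn(
            f"clamped {int(out_of_range.sum())} generated beta-values to the "
            "machine-representable open interval"
        )
        beta = np.clip(beta, 1e-12, 1.0 - 1e-12)
    meth = MethylationMatrix(
        values=pd.DataFrame(beta, index=cohort.index, columns=cpg_ids),
        stage="beta",
    )

    for oc in config.outcomes:
        lin = (
            oc.intercept
            + oc.sex_effect * cohort["sex"].to_numpy(dtype=float)
            + oc.ethnicity_effect * cohort["ethnicity"].to_numpy(dtype=float)
            + oc.age_effect * cohort[f"age_{oc.name}"].to_numpy(dtype=float)
        )
        for i, p in enumerate(paths):
            if p.outcome == oc.name:
                lin = lin + p.b * m_signal[:, i] + p.c_direct * cohort[p.exposure].to_numpy(dtype=float)
        if oc.family == "continuous":
            cohort[oc.name] = lin + rng.normal(0.0, oc.noise_sd, n)
        else:
            mu = np.exp(np.clip(lin, -30.0, 30.0))
            theta = oc.dispersion
            cohort[oc.name] = rng.negative_binomial(theta, theta / (theta + mu), n)

    planted_ids = {p.cpg for p in paths}
    truth = GroundTruth(
        planted_paths=paths,
        null_cpg_ids=[c for c in cpg_ids if c not in planted_ids],
        exposure_log_sd=config.exposure_log_sd,
        cpg_noise_sd=config.cpg_noise_sd,
    )
    return cohort, meth, truth


# ---------------------------------------------------------------------------
# pathway / manifest fixture

_DECOY_TERMS = (
    "glycolysis", "fatty acid oxidation", "sterol biosynthesis",
    "tRNA charging", "DNA mismatch repair", "proteasome turnover",
    "oxidative phosphorylation", "pentose phosphate shunt",
    "sulfur metabolism", "starch catabolism", "heme salvage",
    "peroxisome assembly", "lysosomal transport", "purine salvage",
    "mannose trimming", "collagen crosslinking",
)


def _theme_keywords(oc: OutcomeConfig) -> tuple[str, ...]:
    specific = tuple(k for k in oc.keywords if k.lower() not in SHARED_KEYWORDS)
    return specific or tuple(oc.keywords)


def generate_pathway_fixture(
    config: SimConfig,
) -> tuple[PathwaySet, pd.DataFrame]:
    """Build the gene-set fixture and CpG manifest matching a cohort config.

    Every outcome theme gets two pathways whose metadata contains that
    outcome's specific keywords, two further pathways carry only the shared
    neuro keywords (so they match every profile), and the remainder are
    decoys whose text contains no profile keyword at all.  The gene of every
    planted CpG is forced into a pathway matching its target outcome, which
    guarantees planted mediators are inside the universe the cascade searches.
    The manifest maps CpGs to genes five-to-one, with every seventh CpG
    annotated to two genes (semicolon-joined), chromosomes cycling over the
    22 autosomes and 1-based positions.
    """
    n_genes = max(config.n_cpgs // config.cpgs_per_gene, config.genes_per_pathway)
    genes = [f"GENE{g:05d}" for g in range(n_genes)]

    cpg_rows = []
    for i, cpg in enumerate(config.cpg_ids):
        g = min(i // config.cpgs_per_gene, n_genes - 1)
        annot = genes[g]
        if i % 7 == 3 and g + 1 < n_genes:
            annot = f"{genes[g]};{genes[g + 1]}"
        cpg_rows.append(
            {
                "cpg_id": cpg,
                "chr": str((g % 22) + 1),
                "pos": 10_000 + 500 * i + 1,
                "gene": annot,
            }
        )
    manifest = pd.DataFrame(cpg_rows).set_index("cpg_id")

    rng = np.random.default_rng(config.seed + 1_000_003)
    all_keywords = {
        k.lower() for oc in config.outcomes for k in oc.keywords
    } | set(SHARED_KEYWORDS)

    themes: list[tuple[str, tuple[str, ...]]] = []
    seen = set()
    for oc in config.outcomes:
        kws = _theme_keywords(oc)
        if kws not in seen:
            seen.add(kws)
            themes.append((oc.name, kws))

    pathways: list[Pathway] = []

    def _sample_genes() -> list[str]:
        k = min(config.genes_per_pathway, n_genes)
        return [genes[i] for i in sorted(rng.choice(n_genes, size=k, replace=False))]

    for t_idx, (oname, kws) in enumerate(themes):
        for rep in range(2):
            pid = f"path{len(pathways):04d}"
            kw = kws[rep % len(kws)]
            pathways.append(
                Pathway(
                    id=pid,
                    genes=tuple(_sample_genes()),
                    name=f"Module {t_idx}{rep}: {kw} signalling",
                    description=(
                        f"Regulatory module implicated in {' and '.join(kws)}."
                    ),
                    disease=f"{kws[0]}-related disorder",
                    reference_titles=(
                        f"A cohort study of {kw} and early development",
                    ),
                )
            )
    for rep in range(2):
        pathways.append(
            Pathway(
                id=f"path{len(pathways):04d}",
                genes=tuple(_sample_genes()),
                name=f"Shared module {rep}: cortical development",
                description="Core programme of brain and neuron development.",
                disease="neurodevelopmental disorder",
                reference_titles=("Neuron migration in the developing brain",),
            )
        )
    d_idx = 0
    while len(pathways) < config.n_pathways:
        term = _DECOY_TERMS[d_idx % len(_DECOY_TERMS)]
        p = Pathway(
            id=f"path{len(pathways):04d}",
            genes=tuple(_sample_genes()),
            name=f"Decoy module {d_idx}: {term}",
            description=f"Housekeeping programme of {term}.",
            disease="metabolic syndrome",
            reference_titles=(f"Flux control of {term}",),
        )
        texts = (p.name, p.description, p.disease, *p.reference_titles)
        if any(kw in t.lower() for kw in all_keywords for t in texts):
            raise AssertionError(f"decoy pathway {p.id} leaks a keyword")
        pathways.append(p)
        d_idx += 1

    # force planted genes into a matching theme pathway
    theme_first = {
        kws: 2 * t_idx for t_idx, (_, kws) in enumerate(themes)
    }
    gene_map = {cpg: str(manifest.loc[cpg, "gene"]).split(";")[0] for cpg in manifest.index}
    for i, pc in enumerate(config.effective_paths):
        cpg = config.cpg_ids[i]
        gene = gene_map[cpg]
        kws = _theme_keywords(config.outcome(pc.outcome))
        idx = theme_first[kws]
        host = pathways[idx]
        if gene not in host.genes:
            pathways[idx] = Pathway(
                id=host.id,
                genes=host.genes + (gene,),
                name=host.name,
                description=host.description,
                disease=host.disease,
                reference_titles=host.reference_titles,
            )
    return PathwaySet(pathways), manifest
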