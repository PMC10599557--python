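"""Synthetic postmortem-cortex-style expression studies with planted co-expression modules.

The generator emulates the statistical design the downstream pipeline assumes: a few
dozen samples, a few thousand genes on an approximately Gaussian log scale, a covariate
table mixing covariates of interest (four genomic-score columns, two per trait) with
demographic, cell-composition, ancestry and RNA-quality nuisance covariates, and
block-correlated gene modules, a subset of which is partially driven by one of the
genomic scores.

Module structure
----------------
Each planted module ``m`` has a latent eigengene ``u_m ~ N(0, 1)`` per sample. A
score-coupled module's eigengene is tilted toward a designated score ``s``:
``u_m = g·s + sqrt(1 - g^2)·eta`` with ``g = gs_effect``, so ``cor(u_m, s) = g``.
Within a coupled module, a fraction ``frac_gs_driven_genes`` of genes loads instead on
a *score-mediated* shared factor ``z_m = a·s + sqrt(1 - a^2)·eps_m``: their pairwise
correlation travels mostly through the score, so residualizing the score out of the
expression dissolves their co-expression. This makes module fragmentation upon score
removal an analytic consequence of the construction rather than an accident.

Every gene is then
``x = mu + sum_c beta_c * cov_c + noise_sd * (rho * latent + sqrt(1 - rho^2) * e)``
with ``rho = latent_module_cor`` (gene-eigengene correlation given covariates) and
per-gene nuisance coefficients ``beta_c`` drawn from zero-mean normals with
covariate-specific scales. Genes not placed in any module carry covariate effects and
noise only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .screen import CovariateTable

SCORE_COLUMNS = ("GS3_SCZ", "GS5_SCZ", "GS3_HT", "GS5_HT")
#: Paper-style defaults: the two score sets of one trait are strongly correlated
#: (r = .72 for the SCZ pair, r = .94 for the height pair) while cross-trait
#: correlations are negligible.
DEFAULT_WITHIN_TRAIT_COR = (0.72, 0.94)


@dataclass
class NuisanceSpec:
    """Nuisance covariates and the scale of their per-gene effects.

    ``*_effect`` values are standard deviations of the per-gene regression
    coefficients on the standardized covariate (log-expression units per SD).
    """

    n_snp_pcs: int = 10
    n_qsvs: int = 5
    age_mean: float = 43.0
    age_sd: float = 15.8
    male_fraction: float = 64 / 78
    age_effect: float = 0.2
    sex_effect: float = 0.3
    neurons_effect: float = 0.5
    astrocytes_effect: float = 0.3
    endothelia_effect: float = 0.2
    rin_effect: float = 0.4
    total_assigned_effect: float = 0.3
    mito_rate_effect: float = 0.3
    snp_pc_effect: float = 0.15
    qsv_effect: float = 0.4

    def covariate_effects(self) -> dict[str, float]:
        eff = {
            "Age": self.age_effect,
            "Sex": self.sex_effect,
            "neurons": self.neurons_effect,
            "astrocytes": self.astrocytes_effect,
            "endothelia": self.endothelia_effect,
            "RIN": self.rin_effect,
            "totalAssignedGene": self.total_assigned_effect,
            "mitoRate": self.mito_rate_effect,
        }
        for i in range(1, self.n_snp_pcs + 1):
            eff[f"snpPC_{i}"] = self.snp_pc_effect
        for j in range(1, self.n_qsvs + 1):
            eff[f"qSV_{j}"] = self.qsv_effect
        return eff


def _default_module_sizes(n_modules: int) -> list[int]:
    # 150, 140, ..., down in steps of 10 (floor 30): 12 modules sum to 1140.
    return [max(150 - 10 * i, 30) for i in range(n_modules)]


@dataclass
class SimulationConfig:
    """Study-design knobs for one synthetic cohort."""

    n_samples: int = 80
    n_genes: int = 2000
    n_modules: int = 12
    module_sizes: list[int] | None = None
    latent_module_cor: float = 0.8
    gs_coupled_modules: tuple[int, ...] = (5, 7)
    gs_effect: float = 0.4
    frac_gs_driven_genes: float = 0.5
    #: correlation between the shared score-mediated latent factor and the score
    driven_latent_score_cor: float = 0.9
    #: which score column drives the coupled modules
    coupled_score: str = "GS3_SCZ"
    within_trait_score_cor: float | tuple[float, float] = DEFAULT_WITHIN_TRAIT_COR
    nuisance_spec: NuisanceSpec = field(default_factory=NuisanceSpec)
    noise_sd: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            self.module_sizes = _default_module_sizes(self.n_modules)
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_genes = {self.n_genes}"
            )
        if not 0.0 <= self.latent_module_cor <= 1.0:
            raise ValueError("latent_module_cor must be in [0, 1]")
        if not 0.0 <= self.frac_gs_driven_genes <= 1.0:
            raise ValueError("frac_gs_driven_genes must be in [0, 1]")
        if not -1.0 <= self.gs_effect <= 1.0:
            raise ValueError("gs_effect must be in [-1, 1]")
        for idx in self.gs_coupled_modules:
            if not 0 <= idx < self.n_modules:
                raise ValueError(f"coupled module index {idx} out of range")
        if self.coupled_score not in SCORE_COLUMNS:
            raise ValueError(f"coupled_score must be one of {SCORE_COLUMNS}")

    @property
    def within_trait_cor_pair(self) -> tuple[float, float]:
        w = self.within_trait_score_cor
        if np.isscalar(w):
            return (float(w), float(w))
        return (float(w[0]), float(w[1]))


@dataclass
class SyntheticStudy:
    """A generated study: expression (genes x samples), covariates, ground truth."""

    expression: pd.DataFrame
    covariates: CovariateTable
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.expression.to_csv(out / "expression.tsv", sep="\t", index_label="gene_id")
        self.covariates.data.to_csv(out / "covariates.tsv", sep="\t", index_label="sample_id")
        truth = dict(self.truth)
        truth["eigengenes"] = {
            k: list(map(float, v)) for k, v in self.truth["eigengenes"].items()
        }
        truth["coefficients"] = None  # large; kept in memory only
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=str)


def generate_scores(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the four genomic-score columns (two per trait).

    Each trait's two score sets come from a bivariate normal with the trait's
    within-trait target correlation; the two traits are drawn independently, so the
    cross-trait sample correlation is small at realistic n.
    """
    if config.n_samples < 4:
        raise ValueError("need at least 4 samples to simulate score correlations")
    r_scz, r_ht = config.within_trait_cor_pair
    for r in (r_scz, r_ht):
        if not -1.0 < r < 1.0:
            raise ValueError("within_trait_score_cor must be in (-1, 1)")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_samples
    out = {}
    for (c1, c2), r in zip((SCORE_COLUMNS[:2], SCORE_COLUMNS[2:]), (r_scz, r_ht)):
        cov = np.array([[1.0, r], [r, 1.0]])
        draws = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
        out[c1], out[c2] = draws[:, 0], draws[:, 1]
    return pd.DataFrame(out)


def _simulate_nuisance(
    spec: NuisanceSpec, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    cols["Age"] = rng.normal(spec.age_mean, spec.age_sd, n).clip(18, 95)
    cols["Sex"] = (rng.random(n) < spec.male_fraction).astype(float)
    # Three-part stick-breaking with a dominant neuronal component; the remainder
    # of each sample's simplex is left to unmodelled cell types, so the three
    # proportions are nonnegative and sum to < 1.
    neurons = rng.beta(8, 6, n)
    astro = (1 - neurons) * rng.beta(4, 4, n)
    endo = (1 - neurons - astro) * rng.beta(2, 6, n)
    cols["neurons"], cols["astrocytes"], cols["endothelia"] = neurons, astro, endo
    # Observed quality measures and qSVs share a latent degradation axis, giving
    # the realistic collinearity block the screening step must cope with.
    quality = rng.normal(size=n)
    cols["RIN"] = (7.5 + 0.9 * quality + 0.4 * rng.normal(size=n)).clip(4, 10)
    cols["totalAssignedGene"] = (
        0.5 + 0.04 * quality + 0.02 * rng.normal(size=n)
    ).clip(0.2, 0.9)
    cols["mitoRate"] = (0.03 - 0.008 * quality + 0.005 * rng.normal(size=n)).clip(
        1e-4, 0.2
    )
    for i in range(1, spec.n_snp_pcs + 1):
        cols[f"snpPC_{i}"] = rng.normal(size=n)
    for j in range(1, spec.n_qsvs + 1):
        w = 0.7 if j <= 2 else 0.3  # leading qSVs track the quality axis most
        cols[f"qSV_{j}"] = w * quality + np.sqrt(1 - w**2) * rng.normal(size=n)
    return pd.DataFrame(cols)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a full synthetic study, deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_genes
    scores = generate_scores(config, rng)
    nuis = _simulate_nuisance(config.nuisance_spec, n, rng)
    cov_df = pd.concat([scores, nuis], axis=1)
    cov_df.index = pd.Index([f"S{i+1:03d}" for i in range(n)], name="sample_id")

    s = _standardize(scores[config.coupled_score].to_numpy())
    g = config.gs_effect
    a = config.driven_latent_score_cor

    module_of = np.full(p, "none", dtype=object)
    latent_of = np.full(p, "none", dtype=object)
    eigengenes: dict[str, np.ndarray] = {}
    latents: dict[str, np.ndarray] = {}
    gene_latent = np.empty((p, n))
    gene_latent[:] = 0.0

    start = 0
    for m, size in enumerate(config.module_sizes):
        name = f"mod{m}"
        coupled = m in config.gs_coupled_modules
        eta = rng.normal(size=n)
        if coupled:
            u = g * s + np.sqrt(1 - g**2) * _standardize(eta)
        else:
            u = _standardize(eta)
        eigengenes[name] = u
        latents[name] = u
        idx = np.arange(start, start + size)
        module_of[idx] = name
        latent_of[idx] = name
        if coupled and config.frac_gs_driven_genes > 0 and config.gs_effect != 0:
            n_driven = int(round(config.frac_gs_driven_genes * size))
            driven_idx = idx[:n_driven]
            eps = _standardize(rng.normal(size=n))
            z = a * s + np.sqrt(1 - a**2) * eps
            latents[name + "_gs"] = z
            latent_of[driven_idx] = name + "_gs"
            gene_latent[driven_idx] = z
            gene_latent[idx[n_driven:]] = u
        else:
            gene_latent[idx] = u
        start += size

    effects = config.nuisance_spec.covariate_effects()
    cov_names = list(effects)
    X = np.column_stack([_standardize(cov_df[c].to_numpy()) for c in cov_names])
    beta = rng.normal(size=(p, len(cov_names))) * np.array(
        [effects[c] for c in cov_names]
    )

    rho = config.latent_module_cor
    noise = rng.normal(size=(p, n))
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=p)
    in_module = module_of != "none"
    structured = np.where(
        in_module[:, None],
        rho * gene_latent + np.sqrt(1 - rho**2) * noise,
        noise,
    )
    expr = mu[:, None] + beta @ X.T + config.noise_sd * structured

    genes = pd.Index([f"G{i+1:05d}" for i in range(p)], name="gene_id")
    expression = pd.DataFrame(expr, index=genes, columns=pd.Index(list(cov_df.index)))

    roles = {c: "interest" for c in SCORE_COLUMNS}
    roles.update({c: "non_interest" for c in nuis.columns})
    covariates = CovariateTable(cov_df, roles=roles)

    truth = {
        "module_of_gene": dict(zip(genes, module_of)),
        "latent_of_gene": dict(zip(genes, latent_of)),
        "eigengenes": {k: v for k, v in latents.items()},
        "coupled_modules": [f"mod{m}" for m in config.gs_coupled_modules],
        "coupled_score": config.coupled_score,
        "gs_effect": config.gs_effect,
        "coefficients": pd.DataFrame(beta, index=genes, columns=cov_names),
        "seed": config.seed,
    }
    if config.n_samples < 30:
        warnings.warn("fewer than 30 samples: correlation estimates will be unstable")
    return SyntheticStudy(expression=expression, covariates=covariates, truth=truth)


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A reduced study (300 genes, 8 modules) for fast calibration experiments."""
    defaults = dict(
        n_samples=80,
        n_genes=300,
        n_modules=8,
        module_sizes=[40, 36, 34, 32, 30, 28, 26, 24],
        gs_coupled_modules=(1, 3),
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "nuisance_spec" in d and isinstance(d["nuisance_spec"], dict):
        d["nuisance_spec"] = NuisanceSpec(**d["nuisance_spec"])
    for key in ("gs_coupled_modules",):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
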