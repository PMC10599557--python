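"""Covariate screening: variance partition and collinearity diagnostics.

Implements the two-step variance decomposition used to select covariates before
expression adjustment: gene expression is first residualized on technical covariates
(observed RNA-quality measures, quality surrogate variables) plus ancestry genomic
PCs; the residuals are then regressed on the biological covariates (age, sex, cell
proportions, genomic scores) and each covariate's marginal incremental R^2 is
reported. Collinearity is screened with pairwise correlations and variance inflation
factors so that near-duplicate regressors (e.g. two highly correlated cell-type
proportions) can be dropped before model fitting.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CovariateTable",
    "VarianceFractionTable",
    "CollinearityReport",
    "SelectionPolicy",
    "CovariateSelection",
    "partition_variance_two_step",
    "collinearity_diagnostics",
    "select_covariates",
]

#: column-name patterns treated as stage-1 (technical + ancestry) covariates
TECHNICAL_PATTERNS = (
    r"^RIN$",
    r"^totalAssignedGene$",
    r"^mitoRate$",
    r"^qSV_?\d+$",
    r"^snpPC_?\d+$",
)


@dataclass
class CovariateTable:
    """Per-sample covariates with interest / non-interest roles.

    ``data`` is samples x covariates; ``roles`` maps each column to ``"interest"``
    (genomic scores) or ``"non_interest"`` (everything regressed out during
    cleaning).
    """

    data: pd.DataFrame
    roles: dict[str, str]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("sample IDs must be unique")
        missing_roles = [c for c in self.data.columns if c not in self.roles]
        if missing_roles:
            raise ValueError(f"columns without a role: {missing_roles}")
        bad = {c: r for c, r in self.roles.items() if r not in ("interest", "non_interest")}
        if bad:
            raise ValueError(f"invalid roles: {bad}")
        if self.data.isna().any().any():
            cols = list(self.data.columns[self.data.isna().any()])
            raise ValueError(f"missing values in covariates: {cols}")
        non_numeric = [
            c for c in self.data.columns if not np.issubdtype(self.data[c].dtype, np.number)
        ]
        if non_numeric:
            raise ValueError(f"non-numeric covariate columns: {non_numeric}")

    @property
    def interest(self) -> list[str]:
        return [c for c in self.data.columns if self.roles[c] == "interest"]

    @property
    def non_interest(self) -> list[str]:
        return [c for c in self.data.columns if self.roles[c] == "non_interest"]

    @property
    def technical(self) -> list[str]:
        return [
            c
            for c in self.data.columns
            if any(re.match(p, c) for p in TECHNICAL_PATTERNS)
        ]

    @property
    def biological(self) -> list[str]:
        tech = set(self.technical)
        return [c for c in self.data.columns if c not in tech]

    def subset(self, columns: list[str]) -> "CovariateTable":
        return CovariateTable(
            self.data[columns].copy(), {c: self.roles[c] for c in columns}
        )

    def with_column(self, name: str, values: np.ndarray) -> "CovariateTable":
        data = self.data.copy()
        data[name] = values
        roles = dict(self.roles)
        roles.setdefault(name, "interest")
        return CovariateTable(data, roles)


@dataclass
class VarianceFractionTable:
    """Per-gene variance fractions from the two-step partition.

    ``technical`` is the stage-1 R^2 as a fraction of each gene's total variance.
    The remaining columns are stage-2 marginal incremental R^2 values (drop-one
    R^2 loss), expressed as fractions of the stage-1 *residual* variance;
    ``residual`` is 1 minus the full stage-2 R^2 on the same scale.
    """

    fractions: pd.DataFrame
    technical_covariates: list[str]
    biological_covariates: list[str]

    def mean_fraction(self, covariate: str) -> float:
        return float(self.fractions[covariate].mean())


@dataclass
class CollinearityReport:
    correlation: pd.DataFrame
    vif: pd.Series
    flagged: list[str]
    removable: list[str]
    vif_threshold: float


def _design(
    df: pd.DataFrame, columns: list[str], add_intercept: bool = True
) -> np.ndarray:
    X = df[columns].to_numpy(dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
    return X


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR on the standardized design
        from scipy.linalg import qr

        _, r, piv = qr(X, pivoting=True)
        tol = np.abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps
        dependent = sorted(piv[rank:])
        labels = ["(intercept)"] + names
        raise np.linalg.LinAlgError(
            "rank-deficient design; dependent columns: "
            + ", ".join(labels[i] for i in dependent)
        )


def _r2(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """R^2 of each column of Y (samples x genes) on design X with intercept inside X."""
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    yc = Y - Y.mean(axis=0)
    tss = (yc**2).sum(axis=0)
    rss = (resid**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - rss / tss
    return np.where(tss > 0, r2, 0.0)


def partition_variance_two_step(
    expr: pd.DataFrame,
    cov: CovariateTable,
    technical: list[str] | None = None,
    biological: list[str] | None = None,
) -> VarianceFractionTable:
    """Two-step per-gene variance partition.

    Stage 1 regresses each gene on the technical covariates (plus intercept) and
    records the explained fraction of total variance. Stage 2 fits the biological
    covariates on the stage-1 residuals; each covariate's fraction is its marginal
    incremental R^2 (full-model R^2 minus the R^2 of the model without it),
    relative to the stage-2 input variance.
    """
    technical = cov.technical if technical is None else technical
    biological = cov.biological if biological is None else biological
    n = expr.shape[1]
    max_p = max(len(technical), len(biological))
    if n <= max_p + 2:
        raise ValueError(
            f"need n_samples > covariates per stage + 2 (n={n}, p={max_p})"
        )
    df = cov.data.loc[expr.columns]
    Y = expr.to_numpy(dtype=float).T  # samples x genes

    X1 = _design(df, technical)
    _check_full_rank(X1, technical)
    tech_r2 = _r2(X1, Y)
    coef1, *_ = np.linalg.lstsq(X1, Y, rcond=None)
    resid = Y - X1 @ coef1

    X2 = _design(df, biological)
    _check_full_rank(X2, biological)
    full_r2 = _r2(X2, resid)
    out = {"technical": tech_r2}
    for j, c in enumerate(biological):
        keep = [0] + [1 + k for k in range(len(biological)) if k != j]
        out[c] = full_r2 - _r2(X2[:, keep], resid)
    out["residual"] = 1.0 - full_r2
    fractions = pd.DataFrame(out, index=expr.index).clip(lower=0.0, upper=1.0)
    return VarianceFractionTable(fractions, list(technical), list(biological))


def collinearity_diagnostics(
    cov: CovariateTable, vif_threshold: float = 10.0
) -> CollinearityReport:
    """Pairwise covariate correlations and variance inflation factors.

    Constant columns and perfectly collinear columns are flagged (VIF infinite)
    rather than raising; ``removable`` lists columns involved in exact
    collinearity.
    """
    df = cov.data
    if df.shape[1] < 2:
        raise ValueError("need at least 2 covariates for collinearity diagnostics")
    corr = df.corr()
    vifs = {}
    removable = []
    X = df.to_numpy(dtype=float)
    sds = X.std(axis=0)
    for j, c in enumerate(df.columns):
        if sds[j] == 0:
            vifs[c] = np.inf
            removable.append(c)
            continue
        others = np.delete(X, j, axis=1)
        others = others[:, np.delete(sds, j) > 0]
        design = np.column_stack([np.ones(len(X)), others])
        r2 = float(_r2(design, X[:, [j]])[0])
        if r2 >= 1.0 - 1e-12:
            vifs[c] = np.inf
            removable.append(c)
        else:
            vifs[c] = 1.0 / (1.0 - r2)
    vif = pd.Series(vifs, name="VIF")
    flagged = [c for c in df.columns if vif[c] > vif_threshold or not np.isfinite(vif[c])]
    return CollinearityReport(corr, vif, flagged, removable, vif_threshold)


@dataclass
class SelectionPolicy:
    """How to choose the covariates of interest.

    ``candidates`` groups candidate score columns by trait; the top
    ``n_per_trait`` by mean explained variance are selected per trait. Ties break
    by the order in which columns appear in the covariate table (stable sort).
    """

    candidates: dict[str, list[str]] = field(default_factory=dict)
    n_per_trait: int = 2


@dataclass
class CovariateSelection:
    interest: list[str]
    non_interest: list[str]
    dropped: list[str]
    table: pd.DataFrame


def select_covariates(
    vft: VarianceFractionTable,
    col: CollinearityReport,
    policy: SelectionPolicy,
) -> CovariateSelection:
    """Rank candidate score sets by mean explained variance; drop collinear nuisance."""
    if not policy.candidates or all(len(v) == 0 for v in policy.candidates.values()):
        raise ValueError("selection policy has no candidate score columns")
    rows = []
    interest: list[str] = []
    for trait, cands in policy.candidates.items():
        if not cands:
            raise ValueError(f"empty candidate list for trait {trait!r}")
        means = [vft.mean_fraction(c) for c in cands]
        order = sorted(range(len(cands)), key=lambda i: (-means[i], i))
        for rank, i in enumerate(order):
            selected = rank < policy.n_per_trait
            rows.append(
                {
                    "trait": trait,
                    "score": cands[i],
                    "mean_fraction": means[i],
                    "rank": rank + 1,
                    "selected": selected,
                }
            )
            if selected:
                interest.append(cands[i])
    all_candidates = {c for v in policy.candidates.values() for c in v}
    dropped = [c for c in col.flagged if c not in all_candidates]
    non_interest = [
        c
        for c in vft.biological_covariates + vft.technical_covariates
        if c not in all_candidates and c not in dropped
    ]
    if dropped:
        warnings.warn(f"dropping collinear nuisance covariates: {dropped}")
    return CovariateSelection(interest, non_interest, dropped, pd.DataFrame(rows))
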