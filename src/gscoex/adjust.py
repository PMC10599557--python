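"""Per-gene linear models and the preserve/remove cleaning transform.

Every gene is fit once with ordinary least squares on the full design

    expression ~ intercept + genomic score + nuisance covariates

and adjusted expression is formed by subtracting fitted nuisance terms:

* ``preserve`` keeps the intercept and the score term:
  ``y_clean = y - X_nuisance @ beta_nuisance``
* ``remove`` additionally subtracts the score term:
  ``y_clean = y - X_nuisance @ beta_nuisance - x_score * beta_score``

The coefficients come from the single joint fit, so refitting the full model on a
preserved matrix returns nuisance coefficients of exactly zero and an unchanged
score coefficient, and a removed matrix is numerically orthogonal to the score.
With two modes and four score columns this yields the eight adjusted expression
inputs that feed the network stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen import CovariateTable, _check_full_rank

MODES = ("preserve", "remove")


@dataclass
class GeneModelFits:
    """OLS fits of all genes on a shared design (intercept + score + nuisance)."""

    coefficients: pd.DataFrame  # genes x design columns
    residuals: pd.DataFrame  # genes x samples
    design: pd.DataFrame  # samples x design columns (incl. intercept)
    score_id: str
    nuisance: list[str]
    r_squared: pd.Series
    residual_sd: pd.Series

    @property
    def formula(self) -> str:
        return "expression ~ 1 + " + " + ".join([self.score_id] + self.nuisance)


@dataclass
class AdjustedExpression:
    """Cleaned expression with its provenance (mode and score column)."""

    data: pd.DataFrame  # genes x samples
    mode: str
    score_id: str
    formula: str

    @property
    def label(self) -> str:
        return f"{self.score_id}_{self.mode}"


def fit_gene_models(
    expr: pd.DataFrame,
    cov: CovariateTable,
    score_id: str,
    nuisance: list[str] | None = None,
) -> GeneModelFits:
    """One OLS fit per gene on intercept + score + all non-interest covariates."""
    if score_id not in cov.data.columns:
        raise KeyError(f"score column {score_id!r} not in covariate table")
    nuisance = cov.non_interest if nuisance is None else list(nuisance)
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = list(expr.index[~np.isfinite(values).all(axis=1)])
        raise ValueError(f"non-finite expression values in genes: {bad[:10]}")
    df = cov.data.loc[expr.columns]
    names = ["(intercept)", score_id] + nuisance
    X = np.column_stack(
        [np.ones(len(df)), df[score_id].to_numpy(dtype=float)]
        + [df[c].to_numpy(dtype=float) for c in nuisance]
    )
    n, p = X.shape
    if n <= p:
        raise ValueError(f"cannot fit: n_samples = {n} <= n_parameters = {p}")
    _check_full_rank(X, names[1:])
    Y = values.T  # samples x genes
    Q, R = np.linalg.qr(X)
    B = np.linalg.solve(R, Q.T @ Y)  # p x genes
    fitted = X @ B
    resid = Y - fitted
    yc = Y - Y.mean(axis=0)
    tss = (yc**2).sum(axis=0)
    rss = (resid**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
    return GeneModelFits(
        coefficients=pd.DataFrame(B.T, index=expr.index, columns=names),
        residuals=pd.DataFrame(resid.T, index=expr.index, columns=expr.columns),
        design=pd.DataFrame(X, index=expr.columns, columns=names),
        score_id=score_id,
        nuisance=nuisance,
        r_squared=pd.Series(r2, index=expr.index, name="r_squared"),
        residual_sd=pd.Series(
            resid.std(axis=0, ddof=p).T, index=expr.index, name="residual_sd"
        ),
    )


def clean_expression(
    expr: pd.DataFrame, fits: GeneModelFits, mode: str
) -> AdjustedExpression:
    """Subtract fitted nuisance (and, in remove mode, score) terms from expression."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    X = fits.design
    drop = list(fits.nuisance)
    if mode == "remove":
        drop = [fits.score_id] + drop
    contrib = fits.coefficients[drop].to_numpy() @ X[drop].to_numpy().T
    cleaned = expr.to_numpy(dtype=float) - contrib
    return AdjustedExpression(
        data=pd.DataFrame(cleaned, index=expr.index, columns=expr.columns),
        mode=mode,
        score_id=fits.score_id,
        formula=fits.formula,
    )


def make_eight_inputs(
    expr: pd.DataFrame,
    cov: CovariateTable,
    score_ids: list[str],
    nuisance: list[str] | None = None,
) -> dict[tuple[str, str], AdjustedExpression]:
    """The {preserve, remove} x {four score sets} adjusted expression matrices."""
    missing = [s for s in score_ids if s not in cov.data.columns]
    if missing:
        raise KeyError(f"score columns missing from covariate table: {missing}")
    out: dict[tuple[str, str], AdjustedExpression] = {}
    for score_id in score_ids:
        fits = fit_gene_models(expr, cov, score_id, nuisance=nuisance)
        for mode in MODES:
            out[(mode, score_id)] = clean_expression(expr, fits, mode)
    return out
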