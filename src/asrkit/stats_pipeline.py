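"""Annotation-bias statistics and the normalized splicing metric ASR*.

Three stages quantify and correct annotation-driven bias in
alternative-splicing estimates across species:

1. Pairwise Spearman correlation matrices between ASR and the
   annotation-report metrics (monotone association, average-rank ties,
   asymptotic P-values; significance starred at P < .05 and P < .001).

2. LASSO regression of ASR on a reduced predictor set, with a seeded
   80/20 train/test split and the penalty chosen by 10-fold
   cross-validated mean squared error. The coefficient path identifies
   the predictors that survive strong penalization.

3. A fourth-degree polynomial regression of ASR on x, the fraction of
   fully supported CDSs, yielding the expected value

       ASR_exp(x) = b0 + b1*x + b2*x^2 + b3*x^3 + b4*x^4,

   and the normalized metric

       ASR* = ASR_obs - ASR_exp + sigma_min,
       sigma_min = 1 - min_i (ASR_obs_i - ASR_exp_i),

   so that the smallest normalized value on the training species is
   exactly 1 (values below 1 are meaningless for a ratio-type splicing
   metric). The quartic is fitted on a scaled orthogonalized basis for
   numerical stability and reported on both bases; x is kept as a
   fraction in [0, 1] because a quartic in raw percentages (0-100) is
   severely ill-conditioned.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy import stats
from sklearn.linear_model import LassoCV, lasso_path
from sklearn.model_selection import KFold, train_test_split

from .metadata_report import SpeciesTable

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "LassoFit",
    "PolynomialFit",
    "NormalizationModel",
    "NormalizedASR",
    "spearman_matrix",
    "lasso_select",
    "fit_polynomial",
    "expected_asr",
    "build_normalization",
    "normalize_asr",
    "evaluate_normalization",
]

SUPPORT_FRACTION_COL = "cds_fully_supported_pct"  # stored as percent; x = pct/100


def _as_frame(table: SpeciesTable | pd.DataFrame) -> pd.DataFrame:
    if isinstance(table, SpeciesTable):
        return table.to_frame()
    return table


# ---------------------------------------------------------------------------
# Spearman correlation matrices


@dataclass(slots=True)
class CorrelationMatrix:
    """Pairwise Spearman correlations with significance stars.

    Stars follow the convention: "*" for P < .05, "**" for P < .001,
    "" otherwise. Undefined pairs (a constant variable) are NaN.
    """

    variables: list[str]
    rho: pd.DataFrame
    pvalues: pd.DataFrame
    stars: pd.DataFrame

    def write_tsv(self, prefix: str | Path) -> list[Path]:
        prefix = Path(prefix)
        paths = []
        for name, df in (("rho", self.rho), ("pvalues", self.pvalues)):
            p = prefix.with_name(prefix.name + f".spearman_{name}.tsv")
            df.to_csv(p, sep="\t", float_format="%.6g")
            paths.append(p)
        annotated = self.rho.round(3).astype(str) + self.stars
        p = prefix.with_name(prefix.name + ".spearman_starred.tsv")
        annotated.to_csv(p, sep="\t")
        paths.append(p)
        return paths


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def spearman_matrix(
    table: SpeciesTable | pd.DataFrame,
    variables: Sequence[str],
    bh_correct: bool = False,
) -> CorrelationMatrix:
    """Pairwise Spearman correlation matrix over complete records.

    Rows with a missing value in any of ``variables`` are dropped
    listwise. Ties receive average ranks; P-values use the asymptotic
    t approximation. With ``bh_correct`` the off-diagonal P-values are
    Benjamini-Hochberg adjusted (raw P by default).
    """
    df = _as_frame(table).dropna(subset=list(variables))
    if len(df) < 3:
        raise ValueError(f"need >= 3 complete records, got {len(df)}")
    k = len(variables)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi = df[variables[i]].to_numpy(float)
            xj = df[variables[j]].to_numpy(float)
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                warnings.warn(
                    f"constant variable in pair ({variables[i]}, {variables[j]}); "
                    "correlation undefined",
                    stacklevel=2,
                )
                rho[i, j] = rho[j, i] = np.nan
                pval[i, j] = pval[j, i] = np.nan
                continue
            r, p = stats.spearmanr(xi, xj)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    if bh_correct:
        iu = np.triu_indices(k, 1)
        flat = pval[iu]
        ok = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        adj[ok] = stats.false_discovery_control(flat[ok])
        pval[iu] = adj
        pval.T[iu] = adj

    vars_ = list(variables)
    rho_df = pd.DataFrame(rho, index=vars_, columns=vars_)
    p_df = pd.DataFrame(pval, index=vars_, columns=vars_)
    stars_df = p_df.map(_stars)
    np.fill_diagonal(stars_df.values, "")
    return CorrelationMatrix(variables=vars_, rho=rho_df, pvalues=p_df, stars=stars_df)


# ---------------------------------------------------------------------------
# LASSO variable selection


@dataclass(slots=True)
class LassoFit:
    """L1-penalized regression of ASR on annotation predictors.

    Predictors are standardized (zero mean, unit variance on the
    training split); coefficients are on the standardized scale.
    ``coefficient_path`` has one row per predictor, one column per
    penalty in ``lambda_grid`` (decreasing); at the largest penalty all
    slopes are exactly 0.
    """

    predictors: list[str]
    lambda_grid: np.ndarray
    coefficient_path: np.ndarray
    lambda_opt: float
    final_coefficients: pd.Series
    intercept: float
    test_r2: float
    split_seed: int
    cv_folds: int
    n_train: int
    n_test: int

    @property
    def selected(self) -> list[str]:
        return [p for p, c in self.final_coefficients.items() if c != 0.0]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "predictors": self.predictors,
            "lambda_grid": self.lambda_grid.tolist(),
            "coefficient_path": self.coefficient_path.tolist(),
            "lambda_opt": self.lambda_opt,
            "final_coefficients": self.final_coefficients.to_dict(),
            "intercept": self.intercept,
            "test_r2": self.test_r2,
            "split_seed": self.split_seed,
            "cv_folds": self.cv_folds,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "selected": self.selected,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


def lasso_select(
    table: SpeciesTable | pd.DataFrame,
    predictors: Sequence[str],
    response: str = "asr",
    split_fraction: float = 0.8,
    folds: int = 10,
    seed: int = 0,
) -> LassoFit:
    """LASSO regression with a seeded 80/20 split and 10-fold CV penalty choice.

    The penalty grid is the solver's default geometric grid from
    lambda_max (where every slope is zero) downward; lambda_opt
    minimizes cross-validated MSE on the training split. Held-out R^2
    is evaluated on the untouched test fraction.
    """
    df = _as_frame(table).dropna(subset=[response, *predictors])
    n = len(df)
    if n < folds:
        raise ValueError(f"fewer complete records ({n}) than CV folds ({folds})")
    if n < 30:
        raise ValueError(f"need >= 30 complete records for a stable fit, got {n}")
    X = df[list(predictors)].to_numpy(float)
    y = df[response].to_numpy(float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split_fraction, random_state=seed
    )
    mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
    if np.any(sd == 0):
        bad = [p for p, s in zip(predictors, sd) if s == 0]
        raise ValueError(f"constant predictors in training split: {bad}")
    Z_tr = (X_tr - mu) / sd
    Z_te = (X_te - mu) / sd

    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LassoCV(cv=cv, alphas=100, max_iter=50_000, random_state=seed)
    model.fit(Z_tr, y_tr)
    alphas, coef_path, _ = lasso_path(Z_tr, y_tr, alphas=model.alphas_)
    test_r2 = float(model.score(Z_te, y_te))

    fit = LassoFit(
        predictors=list(predictors),
        lambda_grid=alphas,
        coefficient_path=coef_path,
        lambda_opt=float(model.alpha_),
        final_coefficients=pd.Series(model.coef_, index=list(predictors)),
        intercept=float(model.intercept_),
        test_r2=test_r2,
        split_seed=seed,
        cv_folds=folds,
        n_train=len(y_tr),
        n_test=len(y_te),
    )
    logger.info(
        "lasso: lambda_opt=%.4g, selected=%s, test R2=%.3f",
        fit.lambda_opt,
        fit.selected,
        test_r2,
    )
    return fit


# ---------------------------------------------------------------------------
# quartic expectation and normalization


@dataclass(slots=True)
class PolynomialFit:
    """Degree-4 least-squares fit of ASR on the support fraction x in [0, 1].

    ``beta`` are the raw-basis coefficients (b0..b4) of ASR_exp(x);
    ``scaled_coef``/``domain`` describe the same fit on the shifted and
    scaled basis used internally for conditioning. ``r2`` is the
    coefficient of determination on the training data (defined as 0 for
    constant y).
    """

    beta: np.ndarray
    r2: float
    residuals: np.ndarray
    n: int
    x: np.ndarray
    scaled_coef: np.ndarray
    domain: tuple[float, float]
    degree: int = 4

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return expected_asr(self, x)

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "beta_raw_basis": self.beta.tolist(),
            "coef_scaled_basis": self.scaled_coef.tolist(),
            "domain": list(self.domain),
            "r2": self.r2,
            "n": self.n,
            "x_scale": "fraction of fully supported CDSs, in [0, 1]",
        }


def fit_polynomial(
    x: np.ndarray | Sequence[float],
    y: np.ndarray | Sequence[float],
    degree: int = 4,
) -> PolynomialFit:
    """Least-squares polynomial fit of ASR on the support fraction.

    Fitted on a shifted/scaled basis for numerical stability and
    reported as raw-basis coefficients b0..b4. Requires
    ``n >= degree + 2`` and non-degenerate x.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < degree + 2:
        raise ValueError(f"need n >= {degree + 2} points for degree {degree}, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; polynomial fit is degenerate")
    if np.any((x < 0) | (x > 1)):
        warnings.warn("x outside [0, 1]; expected a support fraction", stacklevel=2)

    poly = Polynomial.fit(x, y, degree)
    raw = poly.convert()
    beta = np.zeros(degree + 1)
    beta[: raw.coef.size] = raw.coef
    yhat = poly(x)
    resid = y - yhat
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return PolynomialFit(
        beta=beta,
        r2=r2,
        residuals=resid,
        n=n,
        x=x.copy(),
        scaled_coef=poly.coef.copy(),
        domain=(float(poly.domain[0]), float(poly.domain[1])),
        degree=degree,
    )


def expected_asr(fit: PolynomialFit, x: np.ndarray | float) -> np.ndarray | float:
    """Evaluate ASR_exp(x) = b0 + b1*x + ... + b4*x^4 on the raw basis."""
    arr = np.asarray(x, float)
    if np.any((arr < 0) | (arr > 1)):
        warnings.warn("x outside [0, 1]; extrapolating the quartic", stacklevel=2)
    val = np.polynomial.polynomial.polyval(arr, fit.beta)
    return float(val) if np.isscalar(x) or arr.ndim == 0 else val


@dataclass(slots=True)
class NormalizationModel:
    """Fitted quartic expectation plus the sigma_min shift.

    sigma_min = 1 - min_i (ASR_obs_i - ASR_exp_i) over the training
    species, so the training-set minimum of ASR* is exactly 1.
    """

    fit: PolynomialFit
    sigma_min: float
    training_species: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "polynomial": self.fit.to_dict(),
            "sigma_min": self.sigma_min,
            "n_training_species": len(self.training_species),
            "training_species": self.training_species,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


@dataclass(slots=True)
class NormalizedASR:
    """One species' observed, expected and normalized splicing values."""

    species: str
    asr_obs: float
    asr_exp: float
    asr_star: float
    below_training_min: bool = False


def build_normalization(
    fit: PolynomialFit,
    table: SpeciesTable | pd.DataFrame,
) -> NormalizationModel:
    """Compute sigma_min from the training species of ``table``.

    Residuals are recomputed with the raw-basis quartic so that
    :func:`normalize_asr` uses an identical code path and the
    training-set minimum of ASR* lands exactly on 1.
    """
    df = _as_frame(table).dropna(subset=["asr", SUPPORT_FRACTION_COL])
    if df.empty:
        raise ValueError("empty training set; cannot compute sigma_min")
    x = df[SUPPORT_FRACTION_COL].to_numpy(float) / 100.0
    resid = df["asr"].to_numpy(float) - expected_asr(fit, x)
    sigma_min = 1.0 - float(resid.min())
    return NormalizationModel(
        fit=fit,
        sigma_min=sigma_min,
        training_species=df["species_name"].astype(str).tolist(),
    )


def normalize_asr(model: NormalizationModel, species) -> NormalizedASR:
    """Normalize one species record: ASR* = ASR_obs - ASR_exp + sigma_min.

    For species outside the training set ASR* may fall below 1; such
    values are flagged (``below_training_min``), never clipped.
    """
    name = species.species_name
    asr_obs = species.asr
    pct = species.metadata.cds_fully_supported_pct
    if asr_obs is None:
        raise ValueError(f"{name}: ASR missing")
    if pct is None:
        raise ValueError(f"{name}: cds_fully_supported_pct missing")
    asr_exp = float(expected_asr(model.fit, pct / 100.0))
    asr_star = asr_obs - asr_exp + model.sigma_min
    return NormalizedASR(
        species=name,
        asr_obs=float(asr_obs),
        asr_exp=asr_exp,
        asr_star=float(asr_star),
        below_training_min=bool(asr_star < 1.0 and name not in model.training_species),
    )


def normalize_table(model: NormalizationModel, table: SpeciesTable) -> pd.DataFrame:
    """Vectorized normalization of a species table -> tidy DataFrame."""
    rows = []
    for rec in table.records:
        if rec.asr is None or rec.metadata.cds_fully_supported_pct is None:
            continue
        nz = normalize_asr(model, rec)
        rows.append(
            {
                "species_name": nz.species,
                "asr_obs": nz.asr_obs,
                "asr_exp": nz.asr_exp,
                "asr_star": nz.asr_star,
                "below_training_min": nz.below_training_min,
            }
        )
    return pd.DataFrame(rows)


def evaluate_normalization(
    model: NormalizationModel,
    table: SpeciesTable | pd.DataFrame,
) -> dict:
    """Decorrelation report: Spearman rho with x before and after normalization.

    Returns rho(ASR, x), rho(ASR*, x) (NaN when undefined, e.g. constant
    residuals on noiseless data) and the quartic's training r2.
    """
    df = _as_frame(table).dropna(subset=["asr", SUPPORT_FRACTION_COL])
    x = df[SUPPORT_FRACTION_COL].to_numpy(float) / 100.0
    asr = df["asr"].to_numpy(float)
    asr_star = asr - expected_asr(model.fit, x) + model.sigma_min

    def _safe_rho(a: np.ndarray, b: np.ndarray) -> float:
        # near-constant up to float rounding counts as constant: ranks of
        # pure rounding noise are meaningless
        tol = 1e-9 * max(1.0, float(np.max(np.abs(a))))
        if np.ptp(a) <= tol or np.ptp(b) == 0:
            return float("nan")
        return float(stats.spearmanr(a, b).statistic)

    return {
        "n": len(df),
        "rho_asr_x": _safe_rho(asr, x),
        "rho_asr_star_x": _safe_rho(asr_star, x),
        "fit_r2": model.fit.r2,
        "sigma_min": model.sigma_min,
        "min_asr_star": float(asr_star.min()) if len(df) else float("nan"),
    }
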