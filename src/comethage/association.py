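"""Group tests, robust correlation, PCs, and multivariate DNAm-age models.

Notes
-----
Multiple samples per individual are not modelled (no random effects); a
warning is logged on every model fit.  Categorical contrasts use fixed
reference levels (Male, NewZealand, frontal, control) so coefficient tables
are comparable row-for-row across runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from comethage.core_io import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "kruskal_wallis",
    "bicor",
    "cor_test",
    "principal_components",
    "ModelSpec",
    "FitResult",
    "fit_model",
    "coefficient_to_years",
]


def kruskal_wallis(values, groups):
    """Kruskal-Wallis rank test with tie correction.

    Returns ``(H, p)`` where p comes from the chi-square distribution with
    ``k - 1`` df.  With all values tied the statistic is 0 and p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("kruskal_wallis needs at least 2 groups")
    n = len(values)
    ranks = stats.rankdata(values)
    ssr = 0.0
    for g in labels:
        r = ranks[groups == g]
        if len(r) == 0:
            raise ValidationError(f"empty group {g!r}")
        ssr += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * ssr - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie == 0.0:
        return 0.0, 1.0  # all values identical
    h /= tie
    h = max(h, 0.0)
    p = float(stats.chi2.sf(h, len(labels) - 1))
    return float(h), min(max(p, np.nextafter(0, 1)), 1.0)


def _biweight_prep(x: np.ndarray, max_p_outliers: float) -> np.ndarray:
    """Median-centred, Tukey-biweight-weighted, unit-norm version of x.

    The weight scale is 9 * MAD; if more than ``max_p_outliers`` of either
    tail would receive zero weight, that side is rescaled so the tail
    quantile point sits exactly at the zero-weight boundary.
    """
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None  # caller falls back
    u = (x - med) / (9.0 * mad)
    if 0 < max_p_outliers < 0.5:
        lo = np.quantile(u, max_p_outliers)
        hi = np.quantile(u, 1.0 - max_p_outliers)
        if lo < -1:
            u = np.where(u < 0, u / abs(lo), u)
        if hi > 1:
            u = np.where(u > 0, u / hi, u)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    xt = (x - med) * w
    norm = np.sqrt(np.sum(xt**2))
    if norm == 0:
        return None
    return xt / norm


def bicor(x, y, max_p_outliers: float = 0.05) -> float:
    """Biweight midcorrelation of two vectors.

    Falls back to the Spearman rank correlation (with a warning) when a
    vector's median absolute deviation is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("length mismatch")
    if len(x) < 3:
        raise ValidationError("bicor needs length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero dispersion")
    xt = _biweight_prep(x, max_p_outliers)
    yt = _biweight_prep(y, max_p_outliers)
    if xt is None or yt is None:
        warnings.warn("zero MAD; falling back to Spearman rank correlation")
        return float(stats.spearmanr(x, y).statistic)
    return float(np.clip(xt @ yt, -1.0, 1.0))


def bicor_matrix(X: np.ndarray, max_p_outliers: float = 0.05) -> np.ndarray:
    """All pairwise biweight midcorrelations between rows of X.

    Rows with zero MAD fall back to rank-based (Spearman-equivalent)
    standardization so the matrix stays defined.
    """
    X = np.asarray(X, dtype=float)
    prepped = np.empty_like(X)
    fallback = 0
    for i in range(X.shape[0]):
        t = _biweight_prep(X[i], max_p_outliers)
        if t is None:
            fallback += 1
            r = stats.rankdata(X[i])
            r = r - r.mean()
            norm = np.sqrt(np.sum(r**2))
            t = r / norm if norm > 0 else np.zeros_like(r)
        prepped[i] = t
    if fallback:
        warnings.warn(f"{fallback} rows with zero MAD used rank fallback in bicor_matrix")
    C = prepped @ prepped.T
    return np.clip(C, -1.0, 1.0)


def cor_test(x, y, method: str = "bicor", max_p_outliers: float = 0.05):
    """Correlation with a Student-t p-value (n-2 df) applied to r.

    ``method`` is "bicor" or "pearson".  Returns ``(r, p)``; p is floored at
    the smallest positive float for perfectly correlated input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValidationError("cor_test needs n >= 4")
    if method == "bicor":
        r = bicor(x, y, max_p_outliers)
    elif method == "pearson":
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        raise ValueError(f"unknown method {method!r}")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return r, float(np.nextafter(0, 1))
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, max(min(p, 1.0), np.nextafter(0, 1))


def principal_components(values: np.ndarray, k: int) -> np.ndarray:
    """Top-k per-sample principal-component scores of a CpG x sample matrix.

    Rows (CpGs) are mean-centred; scores are the unit-norm right-singular
    vectors, ordered by decreasing singular value.  Returns an (n_samples, k)
    array.
    """
    X = np.asarray(values, dtype=float)
    if k <= 0:
        raise ValidationError("k must be positive")
    if k > min(X.shape):
        raise ValidationError(f"k={k} exceeds min matrix dimension {min(X.shape)}")
    Xc = X - X.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    return vt[:k].T


@dataclass
class ModelSpec:
    """Covariate list and reference levels for a DNAm-age linear model."""

    covariates: list[str]
    references: dict = field(
        default_factory=lambda: {
            "diagnosis": "control",
            "sex": "M",
            "bank": "NewZealand",
            "region": "frontal",
        }
    )

    def __post_init__(self):
        if "age" not in self.covariates:
            raise ValidationError("age must always be included")


@dataclass
class FitResult:
    table: pd.DataFrame  # term, coef, se, p
    n: int
    residual_sd: float

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").at[term, "coef"])


_CATEGORICAL = {"diagnosis", "sex", "bank", "region"}


def _design(data: pd.DataFrame, spec: ModelSpec):
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for cov in spec.covariates:
        if cov in _CATEGORICAL:
            ref = spec.references.get(cov)
            present = sorted(pd.unique(data[cov]))
            if ref not in present:
                ref = present[0]
                warnings.warn(f"reference level for {cov!r} not in data; using {ref!r}")
            levels = [l for l in present if l != ref]
            for lev in levels:
                cols.append((data[cov] == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev} vs {ref}]")
        else:
            cols.append(pd.to_numeric(data[cov]).to_numpy(dtype=float))
            names.append(cov)
    return np.column_stack(cols), names


def fit_model(data: pd.DataFrame, spec: ModelSpec, response: str = "dnam_age") -> FitResult:
    """Ordinary least squares with fixed contrasts; mirrors a printed
    coefficient table (one row per contrast, with SE and t-based p)."""
    log.warning(
        "fit_model treats samples as independent; repeated samples per "
        "individual are not adjusted for"
    )
    y = pd.to_numeric(data[response]).to_numpy(dtype=float)
    X, names = _design(data, spec)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name aliased columns via QR pivoting on the gram matrix
        _, R = np.linalg.qr(X)
        aliased = [names[j] for j in range(p) if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise ValidationError(f"rank-deficient design; aliased columns: {aliased}")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - p
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
    table = pd.DataFrame({"term": names, "coef": coef, "se": se, "p": pvals})
    return FitResult(table=table, n=n, residual_sd=float(np.sqrt(sigma2)))


def coefficient_to_years(hd_coef: float, age_coef: float) -> float:
    """Biological-age years implied by a disease coefficient: hd / age slope."""
    if not age_coef > 0:
        raise ValidationError("age coefficient must be positive")
    return hd_coef / age_coef
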