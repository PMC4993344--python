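"""Linear epigenetic clock: DNAm age, winsorization, and acceleration measures.

The clock is a weighted average of beta values passed through a monotone
age calibration that is logarithmic below ``adult_age`` and linear above it.
Acceleration is the residual of DNAm age from a 2-df spline trend fitted to
non-HD samples; the intrinsic variant additionally adjusts for the neuron
proportion.  Cerebellar samples are excluded from trend fitting and from
winsorization donor sets because the cerebellum ages more slowly than other
brain regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from comethage.core_io import BetaMatrix, FormatError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "ClockModel",
    "transform_age",
    "inverse_transform_age",
    "read_clock",
    "write_clock",
    "dnam_age",
    "winsorize_dnam_age",
    "NaturalSplineTrend",
    "fit_control_trend",
    "age_acceleration",
    "intrinsic_acceleration",
    "CEREBELLAR_REGIONS",
]

CEREBELLAR_REGIONS = {"cerebellum", "crbm"}


def transform_age(age, adult_age: float = 20.0):
    """Monotone age calibration F.

    ``F(a) = log(a+1) - log(adult_age+1)`` for ``a <= adult_age`` and
    ``F(a) = (a - adult_age) / (adult_age + 1)`` above, continuous with
    matching derivative at the knot.  Accepts scalars or arrays; requires
    ``age > -1``.
    """
    a = np.asarray(age, dtype=float)
    if np.any(a <= -1):
        raise ValidationError("age must be > -1")
    out = np.where(
        a <= adult_age,
        np.log(a + 1.0) - np.log(adult_age + 1.0),
        (a - adult_age) / (adult_age + 1.0),
    )
    return float(out) if out.ndim == 0 else out


def inverse_transform_age(y, adult_age: float = 20.0):
    """Inverse of :func:`transform_age`."""
    t = np.asarray(y, dtype=float)
    out = np.where(
        t <= 0,
        (adult_age + 1.0) * np.exp(t) - 1.0,
        adult_age + t * (adult_age + 1.0),
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class ClockModel:
    """Linear clock: DNAm age = F^-1(intercept + sum_j w_j * beta_j)."""

    cpg_ids: list[str]
    weights: np.ndarray
    intercept: float
    adult_age: float = 20.0

    def __post_init__(self):
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        self.weights = np.asarray(self.weights, dtype=float)
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise FormatError("duplicate clock CpG ids")
        if self.weights.shape != (len(self.cpg_ids),):
            raise ValidationError("weights length must match cpg_ids")

    def transform(self, age):
        return transform_age(age, self.adult_age)

    def inverse(self, y):
        return inverse_transform_age(y, self.adult_age)


def write_clock(model: ClockModel, path):
    """Clock file: '#key\tvalue' header block then (cpg_id, weight) TSV."""
    with open(path, "w") as fh:
        fh.write(f"#intercept\t{float(model.intercept)!r}\n")
        fh.write(f"#adult_age\t{float(model.adult_age)!r}\n")
        fh.write("cpg_id\tweight\n")
        for c, w in zip(model.cpg_ids, model.weights):
            fh.write(f"{c}\t{float(w)!r}\n")


def read_clock(path) -> ClockModel:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, val = line[1:].split("\t")
                meta[key] = float(val)
            elif line.startswith("cpg_id"):
                continue
            else:
                cpg, w = line.split("\t")
                rows.append((cpg, float(w)))
    if "intercept" not in meta:
        raise FormatError("clock file missing '#intercept' line")
    return ClockModel(
        cpg_ids=[r[0] for r in rows],
        weights=np.array([r[1] for r in rows]),
        intercept=meta["intercept"],
        adult_age=meta.get("adult_age", 20.0),
    )


def dnam_age(beta: BetaMatrix, model: ClockModel) -> pd.Series:
    """Per-sample DNAm age in years."""
    present = set(beta.cpg_ids)
    missing = [c for c in model.cpg_ids if c not in present]
    if missing:
        raise ValidationError(f"clock CpGs missing from beta matrix: {missing[:10]}")
    sub = beta.subset_cpgs(model.cpg_ids)
    lin = model.intercept + model.weights @ sub.values
    if not np.all(np.isfinite(lin)):
        raise ValidationError("non-finite linear predictor in DNAm age")
    ages = model.inverse(lin)
    return pd.Series(ages, index=beta.sample_ids, name="dnam_age")


class NaturalSplineTrend:
    """Least-squares natural cubic spline smoother with a fixed basis df.

    ``df=2`` uses boundary knots at the data range and one interior knot at
    the median, giving two basis columns beyond the intercept.  Queries
    outside the fitted range extrapolate linearly (natural-spline boundary
    behaviour) with a warning.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, df: int = 2):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if df < 1:
            raise ValueError("df must be >= 1")
        self.lo, self.hi = float(np.min(x)), float(np.max(x))
        interior = np.quantile(x, np.linspace(0, 1, df + 1)[1:-1]) if df > 1 else np.array([])
        self.knots = np.concatenate([[self.lo], interior, [self.hi]])
        B = self._basis(x)
        self.coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        self.residuals_ = y - B @ self.coef

    def _d(self, x, k):
        xi = self.knots
        last = xi[-1]
        return (np.clip(x - xi[k], 0, None) ** 3 - np.clip(x - last, 0, None) ** 3) / (last - xi[k])

    def _basis(self, x):
        x = np.asarray(x, dtype=float)
        cols = [np.ones_like(x), x]
        for k in range(len(self.knots) - 2):
            cols.append(self._d(x, k) - self._d(x, len(self.knots) - 2))
        return np.column_stack(cols)

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        outside = (x < self.lo) | (x > self.hi)
        if np.any(outside):
            warnings.warn(
                f"{int(np.sum(outside))} query ages outside fitted range "
                f"[{self.lo:.1f}, {self.hi:.1f}]; extrapolating linearly"
            )
        # the truncated-power natural basis is linear outside the boundary
        # knots, so evaluation doubles as linear extrapolation
        pred = self._basis(x) @ self.coef
        return float(pred) if pred.ndim == 0 else pred


def fit_control_trend(ages, dnam_ages, df: int = 2) -> NaturalSplineTrend:
    """Fit the non-HD spline trend of DNAm age on chronological age."""
    ages = np.asarray(ages, dtype=float)
    dnam_ages = np.asarray(dnam_ages, dtype=float)
    if len(ages) < 10:
        raise ValidationError(f"need >= 10 control samples, got {len(ages)}")
    if np.ptp(ages) < 20:
        raise ValidationError("control ages must span at least 20 years")
    return NaturalSplineTrend(ages, dnam_ages, df=df)


def age_acceleration(dnam_ages, ages, trend: NaturalSplineTrend) -> np.ndarray:
    """Vertical distance of each sample from the control trend (years)."""
    return np.asarray(dnam_ages, dtype=float) - trend(np.asarray(ages, dtype=float))


def winsorize_dnam_age(
    records: pd.DataFrame,
    trend: NaturalSplineTrend,
    threshold: float = 15.0,
) -> pd.DataFrame:
    """Replace grossly outlying DNAm age estimates using within-individual donors.

    ``records`` needs columns ``sample_id``, ``individual_id``, ``region``,
    ``age``, ``dnam_age``.  A sample is flagged when its absolute residual
    from the control trend exceeds ``threshold`` years.  Each flagged value
    is replaced by the same individual's second most extreme non-cerebellar
    DNAm age, where extremity is distance from the individual's non-cerebellar
    median.  Cerebellar samples are never donors.  Returns a copy with columns
    ``dnam_age`` (winsorized) and ``winsorized`` (bool); the original estimate
    is kept in ``dnam_age_raw``.
    """
    df = records.copy()
    required = {"sample_id", "individual_id", "region", "age", "dnam_age"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"winsorize records missing columns: {sorted(missing)}")
    df["dnam_age_raw"] = df["dnam_age"].astype(float)
    resid = df["dnam_age_raw"].to_numpy() - trend(df["age"].to_numpy(dtype=float))
    flagged = np.abs(resid) > threshold
    df["winsorized"] = False
    is_crbm = df["region"].str.lower().isin(CEREBELLAR_REGIONS).to_numpy()

    new_vals = df["dnam_age_raw"].to_numpy().copy()
    for i in np.where(flagged)[0]:
        ind = df["individual_id"].iloc[i]
        donors = df[(df["individual_id"] == ind) & ~is_crbm]
        if len(donors) < 2:
            log.warning(
                "cannot winsorize sample %s: individual %s has <2 non-cerebellar samples",
                df["sample_id"].iloc[i], ind,
            )
            continue
        vals = donors["dnam_age_raw"].to_numpy(dtype=float)
        med = np.median(vals)
        order = np.argsort(-np.abs(vals - med), kind="stable")
        new_vals[i] = vals[order[1]]  # second most extreme from the median
        df.iloc[i, df.columns.get_loc("winsorized")] = True
    df["dnam_age"] = new_vals
    return df


def intrinsic_acceleration(dnam_ages, ages, prop_neurons) -> np.ndarray:
    """Residual of DNAm age on chronological age and neuron proportion.

    Falls back to an age-only residual (with a warning) when the neuron
    proportion is constant across samples.
    """
    y = np.asarray(dnam_ages, dtype=float)
    a = np.asarray(ages, dtype=float)
    p = np.asarray(prop_neurons, dtype=float)
    if np.any(~np.isfinite(p)):
        raise ValidationError("prop_neurons must be present for all samples")
    if np.ptp(p) == 0:
        warnings.warn("constant prop_neurons; falling back to age-only residual")
        X = np.column_stack([np.ones_like(a), a])
    else:
        X = np.column_stack([np.ones_like(a), a, p])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef
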