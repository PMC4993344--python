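"""Consensus weighted co-methylation networks across brain lobes.

Stages: biweight midcorrelation -> signed-hybrid adjacency (negative
correlations zeroed, soft power 6) -> topological overlap (TOM) -> quantile
calibration of the per-lobe TOMs -> component-wise quantile consensus ->
average-linkage clustering with a static branch cut -> per-lobe module
eigenvectors, fuzzy module membership, and Stouffer meta-analysis of
module-trait correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from comethage.association import bicor_matrix, cor_test
from comethage.core_io import ValidationError
from comethage.ewas import p_to_signed_z, stouffer_meta

log = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "signed_hybrid_adjacency",
    "tom",
    "calibrate_toms",
    "quantile_normalize_columns",
    "consensus_dissimilarity",
    "cut_modules",
    "module_eigenvector",
    "module_membership",
    "consensus_hub_z",
    "module_trait_meta",
    "ModuleSet",
    "MODULE_COLORS",
]

MODULE_COLORS = [
    "grey", "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
]


def color_of(label: int) -> str:
    if label < len(MODULE_COLORS):
        return MODULE_COLORS[label]
    return f"module{label}"


@dataclass
class NetworkConfig:
    soft_power: float = 6.0
    max_p_outliers: float = 0.05
    consensus_quantile: float = 0.0
    min_module_size: int = 20
    cut_height: float | None = None  # None -> cut_height_fraction * max merge height
    cut_height_fraction: float = 0.98

    def __post_init__(self):
        if self.soft_power < 1:
            raise ValidationError("soft_power must be >= 1")
        if not 0.0 <= self.consensus_quantile <= 1.0:
            raise ValidationError("consensus quantile must lie in [0,1]")


def _check_square_symmetric(A: np.ndarray, name: str):
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError(f"{name} must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValidationError(f"{name} must be symmetric")
    return A


def signed_hybrid_adjacency(
    residuals: pd.DataFrame | np.ndarray, config: NetworkConfig | None = None
) -> np.ndarray:
    """A_ij = max(bicor_ij, 0) ** soft_power with a zero diagonal.

    Input rows are CpG profiles across the samples of one lobe.
    """
    config = config or NetworkConfig()
    X = residuals.to_numpy() if isinstance(residuals, pd.DataFrame) else np.asarray(residuals)
    if X.shape[1] < 3:
        raise ValidationError("need >= 3 samples per lobe")
    C = bicor_matrix(X, config.max_p_outliers)
    if not np.all(np.isfinite(C)):
        i, j = np.argwhere(~np.isfinite(C))[0]
        raise ValidationError(f"non-finite correlation for CpG pair ({i}, {j})")
    A = np.maximum(C, 0.0) ** config.soft_power
    np.fill_diagonal(A, 0.0)
    return A


def tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a non-negative symmetric adjacency.

    TOM_ij = (sum_u A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij) off the
    diagonal, TOM_ii = 1, where k is the row sum (zero-diagonal convention).
    """
    A = _check_square_symmetric(adjacency, "adjacency")
    if np.any(A < 0):
        raise ValidationError("adjacency entries must be non-negative")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (L + A) / (kmin + 1.0 - A)
    np.fill_diagonal(T, 1.0)
    T = np.clip(T, 0.0, 1.0)
    return T


def quantile_normalize_columns(M: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns to the mean of the per-rank sorted values.

    Ties within a column receive the mean of the reference values they span
    (the classic microarray normalization behaviour).
    """
    M = np.asarray(M, dtype=float)
    n, k = M.shape
    order = np.argsort(M, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(M, order, axis=0), axis=1)
    out = np.empty_like(M)
    for j in range(k):
        col = M[:, j]
        sort_idx = order[:, j]
        assigned = np.empty(n)
        assigned[sort_idx] = ref
        # average reference values over tie groups
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=assigned)
        counts = np.bincount(inv)
        out[:, j] = (sums / counts)[inv]
    return out


def calibrate_toms(toms: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Quantile-normalize the lower triangles of per-lobe TOMs to each other.

    After calibration the sorted off-diagonal values of every lobe equal the
    mean of the per-rank sorted values across lobes.  Symmetry is restored by
    mirroring; diagonals are untouched.
    """
    lobes = list(toms)
    n = toms[lobes[0]].shape[0]
    for lobe in lobes:
        T = _check_square_symmetric(toms[lobe], f"TOM[{lobe}]")
        if T.shape[0] != n:
            raise ValidationError("TOM dimension mismatch across lobes")
    tril = np.tril_indices(n, k=-1)
    stacked = np.column_stack([toms[l][tril] for l in lobes])
    normed = quantile_normalize_columns(stacked)
    out = {}
    for j, lobe in enumerate(lobes):
        C = toms[lobe].copy()
        C[tril] = normed[:, j]
        C.T[tril] = normed[:, j]
        out[lobe] = C
    return out


def consensus_dissimilarity(ctoms: dict[str, np.ndarray], q: float = 0.0) -> np.ndarray:
    """1 - element-wise q-quantile across calibrated TOMs (q=0 -> 1 - min)."""
    if not 0.0 <= q <= 1.0:
        raise ValidationError("quantile must lie in [0,1]")
    if len(ctoms) < 2:
        raise ValidationError("consensus needs >= 2 calibrated matrices")
    stack = np.stack(list(ctoms.values()))
    cons = np.quantile(stack, q, axis=0)
    return 1.0 - cons


@dataclass
class ModuleSet:
    """Module labels (0 = unassigned/grey) plus clustering metadata."""

    labels: np.ndarray
    cpg_ids: list[str]
    linkage: np.ndarray | None = None
    cut_height: float | None = None
    colors: list[str] = field(init=False)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.colors = [color_of(l) for l in self.labels]

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def members(self, label: int) -> list[str]:
        return [c for c, l in zip(self.cpg_ids, self.labels) if l == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cpg_id": self.cpg_ids, "module": self.labels, "color": self.colors}
        )


def cut_modules(
    cons_diss: np.ndarray, cpg_ids, config: NetworkConfig | None = None
) -> ModuleSet:
    """Average-linkage clustering of the consensus dissimilarity with a
    static branch cut.

    Branches below ``cut_height`` with at least ``min_module_size`` members
    become modules, labelled 1..m by decreasing size; everything else gets
    label 0 (grey).  Default cut height is ``cut_height_fraction`` of the
    dendrogram's maximum merge height.
    """
    config = config or NetworkConfig()
    D = _check_square_symmetric(cons_diss, "consensus dissimilarity")
    n = D.shape[0]
    if len(cpg_ids) != n:
        raise ValidationError("cpg_ids length mismatch")
    condensed = squareform(D, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    height = config.cut_height
    if height is None:
        height = config.cut_height_fraction * Z[:, 2].max()
    raw = hierarchy.fcluster(Z, t=height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(raw).value_counts()
    kept = sizes[sizes >= config.min_module_size]
    if kept.empty:
        warnings.warn("no branch reaches min_module_size; all CpGs left unassigned")
    for new_label, (old_label, _) in enumerate(kept.items(), start=1):
        labels[raw == old_label] = new_label
    return ModuleSet(labels=labels, cpg_ids=list(cpg_ids), linkage=Z, cut_height=float(height))


def module_eigenvector(residuals: pd.DataFrame, module_cpgs) -> tuple[pd.Series, float]:
    """Per-sample module eigenvector and variance explained for one lobe.

    CpG profiles are standardized (mean 0, sd 1); the eigenvector is the
    unit-norm top left-singular vector of the samples x CpGs matrix, with
    sign chosen so the average standardized profile correlates positively
    with it.  Constant CpGs are dropped with a warning.
    """
    module_cpgs = list(module_cpgs)
    if len(module_cpgs) < 2:
        raise ValidationError("module must contain >= 2 CpGs")
    X = residuals.loc[module_cpgs].to_numpy(dtype=float)
    sds = X.std(axis=1, ddof=1)
    const = sds == 0
    if np.any(const):
        warnings.warn(f"dropping {int(const.sum())} constant CpGs from module eigenvector")
        X = X[~const]
        if X.shape[0] < 2:
            raise ValidationError("fewer than 2 non-constant CpGs in module")
        sds = sds[~const]
    Z = (X - X.mean(axis=1, keepdims=True)) / sds[:, None]
    U, s, _ = np.linalg.svd(Z.T, full_matrices=False)  # samples x CpGs
    e = U[:, 0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    mean_profile = Z.mean(axis=0)
    if np.corrcoef(e, mean_profile)[0, 1] < 0:
        e = -e
    return pd.Series(e, index=residuals.columns, name="eigenvector"), var_explained


def module_membership(profile, eigenvector) -> float:
    """Fuzzy module membership: Pearson correlation of a CpG profile with a
    module eigenvector, in [-1, 1].  Constant profiles yield NaN with a
    warning."""
    x = np.asarray(profile, dtype=float)
    e = np.asarray(eigenvector, dtype=float)
    if len(x) != len(e):
        raise ValidationError("length mismatch")
    if np.ptp(x) == 0:
        warnings.warn("constant CpG profile; module membership undefined")
        return float("nan")
    return float(np.clip(np.corrcoef(x, e)[0, 1], -1.0, 1.0))


def membership_table(
    residuals_per_lobe: dict[str, pd.DataFrame],
    eigenvectors: dict[str, dict[int, pd.Series]],
) -> pd.DataFrame:
    """Per-CpG module membership in every lobe plus the consensus meta Z.

    Returns a long-format DataFrame with columns cpg_id, module,
    mm_<lobe>..., z_meta.
    """
    lobes = list(residuals_per_lobe)
    modules = sorted(eigenvectors[lobes[0]])
    cpgs = list(residuals_per_lobe[lobes[0]].index)
    # vectorized correlation per lobe: standardize rows, multiply by e
    rows = []
    mm = {}
    for lobe in lobes:
        R = residuals_per_lobe[lobe].to_numpy(dtype=float)
        Rc = R - R.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(Rc, axis=1)
        norm[norm == 0] = np.nan
        Rn = Rc / norm[:, None]
        mm[lobe] = {}
        for m in modules:
            e = eigenvectors[lobe][m].to_numpy()
            ec = e - e.mean()
            ec /= np.linalg.norm(ec)
            mm[lobe][m] = np.clip(Rn @ ec, -1.0, 1.0)
    n_per_lobe = {lobe: residuals_per_lobe[lobe].shape[1] for lobe in lobes}
    for m in modules:
        zmat = np.column_stack(
            [fisher_z_statistic(mm[lobe][m], n_per_lobe[lobe]) for lobe in lobes]
        )
        Z, _ = stouffer_meta(zmat)
        block = pd.DataFrame({"cpg_id": cpgs, "module": m})
        for lobe in lobes:
            block[f"mm_{lobe}"] = mm[lobe][m]
        block["z_meta"] = Z
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def fisher_z_statistic(r, n: int):
    """Correlation -> z-statistic via Fisher's transform times sqrt(n-3)."""
    r = np.clip(np.asarray(r, dtype=float), -1 + 1e-15, 1 - 1e-15)
    return np.arctanh(r) * np.sqrt(max(n - 3, 1))


def consensus_hub_z(mm_per_lobe: dict[str, float], n_per_lobe: dict[str, int]) -> float:
    """Meta-analysis Z summarizing one CpG's module membership across lobes."""
    lobes = [l for l, v in mm_per_lobe.items() if np.isfinite(v)]
    if not lobes:
        return float("nan")
    if len(lobes) < 2:
        raise ValidationError("consensus hub Z needs >= 2 lobes with defined MM")
    zs = [float(fisher_z_statistic(mm_per_lobe[l], n_per_lobe[l])) for l in lobes]
    Z, _ = stouffer_meta(zs)
    return Z


def module_trait_meta(
    eigenvectors: dict[str, dict[int, pd.Series]],
    traits: dict[str, np.ndarray],
    max_p_outliers: float = 0.05,
) -> pd.DataFrame:
    """Module-trait association per lobe plus Stouffer meta-analysis.

    ``eigenvectors[lobe][module]`` are per-sample eigenvectors; ``traits``
    maps lobe -> numeric trait aligned with those samples.  Lobes with a
    constant trait are skipped (reducing n_sets).  Returns one row per
    module with per-lobe r/p, z_meta and p_meta.
    """
    lobes = list(eigenvectors)
    modules = sorted(eigenvectors[lobes[0]])
    records = []
    for m in modules:
        row = {"module": m}
        zs = []
        for lobe in lobes:
            t = np.asarray(traits[lobe], dtype=float)
            if np.ptp(t) == 0:
                warnings.warn(f"constant trait in lobe {lobe}; skipping")
                row[f"r_{lobe}"] = np.nan
                row[f"p_{lobe}"] = np.nan
                continue
            e = eigenvectors[lobe][m].to_numpy()
            r, p = cor_test(e, t, method="bicor", max_p_outliers=max_p_outliers)
            row[f"r_{lobe}"] = r
            row[f"p_{lobe}"] = p
            zs.append(p_to_signed_z(p, 1 if r >= 0 else -1))
        if len(zs) >= 1:
            Z, p_meta = stouffer_meta(zs)
        else:
            Z, p_meta = np.nan, np.nan
        row["z_meta"] = Z
        row["p_meta"] = p_meta
        row["n_sets"] = len(zs)
        records.append(row)
    return pd.DataFrame(records)
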