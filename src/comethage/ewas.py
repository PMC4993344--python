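"""Per-lobe epigenome-wide association testing and signed Stouffer meta-analysis.

Per-lobe tests are Kruskal-Wallis on age/sex-residualized beta values; the
sign of each lobe's statistic comes from the HD-minus-control median
difference.  Meta p-values are descriptive rather than inferential: the
tests ignore repeated samples per individual, and inflation is reported via
a median-based genomic-control lambda.

Residualized methylation is carried as a pandas DataFrame (CpGs x samples);
residuals are not constrained to [0,1] so they cannot live in a BetaMatrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from comethage.association import kruskal_wallis
from comethage.core_io import BetaMatrix, CpGAnnotation, SampleSheet, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "EwasConfig",
    "variance_filter",
    "adjust_age_sex",
    "ewas_per_lobe",
    "p_to_signed_z",
    "stouffer_meta",
    "inflation_lambda",
    "bonferroni_threshold",
    "meta_analyse",
    "manhattan_export",
]

CHI2_1_MEDIAN = 0.454936423119572  # median of the 1-df chi-square


@dataclass
class EwasConfig:
    variance_threshold: float = 5e-4
    alpha: float = 0.05
    bonferroni_denominator: int = 500_000
    min_group_size: int = 3

    def __post_init__(self):
        if self.variance_threshold < 0:
            raise ValidationError("variance threshold must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0,1)")


def variance_filter(betas: dict[str, BetaMatrix], threshold: float = 5e-4):
    """CpGs whose sample variance reaches ``threshold`` in at least one lobe.

    Returns ``(kept_ids, report)`` where ``report`` has kept/dropped counts.
    All matrices must share the same CpG universe.
    """
    if not betas:
        raise ValidationError("no beta matrices supplied")
    lobes = list(betas)
    cpgs = betas[lobes[0]].cpg_ids
    for lobe in lobes[1:]:
        if betas[lobe].cpg_ids != cpgs:
            raise ValidationError(f"CpG ids differ between lobes {lobes[0]!r} and {lobe!r}")
    if any(b.n_samples == 0 for b in betas.values()):
        raise ValidationError("empty beta matrix")
    keep = np.zeros(len(cpgs), dtype=bool)
    for b in betas.values():
        keep |= b.values.var(axis=1, ddof=1) >= threshold
    kept = [c for c, k in zip(cpgs, keep) if k]
    report = {"kept": int(keep.sum()), "dropped": int((~keep).sum()), "threshold": threshold}
    log.info("variance filter kept %d / %d CpGs", report["kept"], len(cpgs))
    return kept, report


def adjust_age_sex(beta: BetaMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Residualize every CpG on age and a sex indicator by least squares.

    Returns a CpG x sample DataFrame of residuals (zero mean per CpG, zero
    sample covariance with age and the sex indicator).  In a single-sex
    stratum the sex term is dropped with a warning.
    """
    age = pd.to_numeric(sheet.table.loc[beta.sample_ids, "age"]).to_numpy(dtype=float)
    sex = sheet.table.loc[beta.sample_ids, "sex"].to_numpy()
    if np.any(pd.isna(age)):
        raise ValidationError("age missing for some samples")
    cols = [np.ones_like(age), age]
    if len(pd.unique(sex)) < 2:
        warnings.warn("single-sex stratum: dropping sex term from adjustment")
    else:
        cols.append((sex == "F").astype(float))
    X = np.column_stack(cols)
    # hat projection once, applied to all CpGs simultaneously
    coef, *_ = np.linalg.lstsq(X, beta.values.T, rcond=None)
    resid = beta.values - (X @ coef).T
    return pd.DataFrame(resid, index=beta.cpg_ids, columns=beta.sample_ids)


def ewas_per_lobe(
    residuals: pd.DataFrame,
    diagnosis: np.ndarray,
    case: str = "HD",
    control: str = "control",
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Kruskal-Wallis case/control test per CpG with a median-based direction.

    ``diagnosis`` is aligned with the residual columns; samples with other
    labels are ignored.  Returns a DataFrame indexed by CpG with columns
    ``statistic``, ``p``, ``direction`` (+1/-1).  CpGs cannot be skipped
    individually (completeness is enforced upstream), but the whole lobe is
    rejected when a group is smaller than ``min_group_size``.
    """
    diagnosis = np.asarray(diagnosis)
    case_mask = diagnosis == case
    ctrl_mask = diagnosis == control
    n_case, n_ctrl = int(case_mask.sum()), int(ctrl_mask.sum())
    if n_case < min_group_size or n_ctrl < min_group_size:
        raise ValidationError(
            f"need >= {min_group_size} samples per group, got {n_case} {case} / {n_ctrl} {control}"
        )
    keep = case_mask | ctrl_mask
    X = residuals.to_numpy()[:, keep]
    labels = diagnosis[keep]
    case_sub = labels == case
    stats_, ps, dirs = [], [], []
    for row in X:
        h, p = kruskal_wallis(row, labels)
        d = np.median(row[case_sub]) - np.median(row[~case_sub])
        stats_.append(h)
        ps.append(p)
        dirs.append(1 if d >= 0 else -1)  # exact ties resolve to +1
    return pd.DataFrame(
        {"statistic": stats_, "p": ps, "direction": dirs}, index=residuals.index
    )


def p_to_signed_z(p, direction):
    """Signed z from a two-sided p-value: z = direction * Phi^-1(1 - p/2).

    Underflow-safe for p down to ~1e-300.  Accepts scalars or arrays.
    """
    p = np.asarray(p, dtype=float)
    d = np.asarray(direction, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    z = -special.ndtri(p / 2.0) * np.sign(d)
    # direction 0 would zero the score; treat as +1 by convention
    z = np.where(d == 0, -special.ndtri(p / 2.0), z)
    return float(z) if z.ndim == 0 else z


def stouffer_meta(z_scores):
    """Stouffer combination: Z = sum(z)/sqrt(N); meta p = 2*Phi(-|Z|)."""
    z = np.asarray(z_scores, dtype=float)
    if z.ndim == 1:
        z = z[None, :]
    if z.shape[1] == 0:
        raise ValidationError("no z-scores to combine")
    if not np.all(np.isfinite(z)):
        raise ValidationError("non-finite z-score")
    Z = z.sum(axis=1) / np.sqrt(z.shape[1])
    p = 2.0 * special.ndtr(-np.abs(Z))
    p = np.maximum(p, np.nextafter(0, 1))
    if len(Z) == 1:
        return float(Z[0]), float(p[0])
    return Z, p


def inflation_lambda(p_values) -> float:
    """Genomic-control lambda: median(Phi^-1(p/2)^2) / median(chi^2_1)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    if len(p) < 100:
        warnings.warn(f"inflation_lambda on only {len(p)} p-values; estimate is unstable")
    chi2 = special.ndtri(p / 2.0) ** 2
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m."""
    if m < 1:
        raise ValidationError("test count must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0,1)")
    return alpha / m


def meta_analyse(per_lobe: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine per-lobe EWAS tables into a meta table.

    ``per_lobe`` maps lobe name -> DataFrame from :func:`ewas_per_lobe`; all
    tables must share an identical CpG index.  Output columns: per-lobe
    ``p_<lobe>`` and ``z_<lobe>``, plus ``z_meta``, ``p_meta``, ``n_sets``.
    The meta p-values are descriptive (see module docstring).
    """
    if len(per_lobe) < 2:
        raise ValidationError("meta-analysis needs >= 2 lobes")
    lobes = list(per_lobe)
    index = per_lobe[lobes[0]].index
    for lobe in lobes[1:]:
        if not per_lobe[lobe].index.equals(index):
            raise ValidationError("per-lobe tables must share the same CpG index")
    zmat = np.column_stack(
        [
            p_to_signed_z(per_lobe[l]["p"].to_numpy(), per_lobe[l]["direction"].to_numpy())
            for l in lobes
        ]
    )
    Z, p = stouffer_meta(zmat)
    out = pd.DataFrame(index=index)
    for j, lobe in enumerate(lobes):
        out[f"p_{lobe}"] = per_lobe[lobe]["p"].to_numpy()
        out[f"z_{lobe}"] = zmat[:, j]
    out["z_meta"] = Z
    out["p_meta"] = p
    out["n_sets"] = len(lobes)
    return out


def manhattan_export(
    meta: pd.DataFrame,
    annotation: CpGAnnotation,
    alpha: float = 0.05,
    bonferroni_denominator: int = 500_000,
    figure_path=None,
) -> pd.DataFrame:
    """Plot-ready table ordered by chromosome and position with -log10(p_meta).

    Unannotated CpGs land in an "unknown" chromosome bin with a warning.
    When ``figure_path`` is given a Manhattan figure is written there.
    """
    ann = annotation.table
    rows = []
    n_unknown = 0
    for cpg in meta.index:
        if cpg in ann.index:
            chrom = ann.at[cpg, "chromosome"]
            pos = int(ann.at[cpg, "position"])
            gene = ann.at[cpg, "gene_symbol"]
        else:
            chrom, pos, gene = "unknown", 0, ""
            n_unknown += 1
        rows.append((cpg, gene, chrom, pos))
    if n_unknown:
        warnings.warn(f"{n_unknown} CpGs without annotation placed in 'unknown' bin")
    table = pd.DataFrame(rows, columns=["cpg_id", "gene_symbol", "chromosome", "position"])
    table["z_meta"] = meta["z_meta"].to_numpy()
    table["p_meta"] = meta["p_meta"].to_numpy()
    table["neg_log10_p"] = -np.log10(table["p_meta"])
    threshold = bonferroni_threshold(alpha, bonferroni_denominator)
    table["threshold"] = threshold
    chrom_order = {c: i for i, c in enumerate(CpGAnnotation.CHROMOSOMES)}
    table["_c"] = table["chromosome"].map(lambda c: chrom_order.get(c, len(chrom_order)))
    table = table.sort_values(["_c", "position"]).drop(columns="_c").reset_index(drop=True)
    if figure_path is not None:
        _manhattan_figure(table, threshold, figure_path)
    return table


def _manhattan_figure(table: pd.DataFrame, threshold: float, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, sub) in enumerate(table.groupby("chromosome", sort=False)):
        x = offset + np.arange(len(sub))
        ax.scatter(x, sub["neg_log10_p"], s=6, color="C0" if i % 2 == 0 else "C1")
        ticks.append(offset + len(sub) / 2)
        labels.append(str(chrom))
        offset += len(sub)
    ax.axhline(-np.log10(threshold), color="red", lw=1, ls="--")
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(p_{meta})$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
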