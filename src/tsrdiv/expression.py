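"""Tissue-specificity scoring, expressed fractions, and splicing entropy.

Works on feature x tissue TPM matrices (pandas DataFrames, feature ids as
index).  Transcript-level matrices carry a transcript -> gene map for the
isoform-entropy computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, ValidationError


@dataclass
class TauResult:
    tau: pd.Series  # feature -> tau in [0, 1]
    xhat: pd.DataFrame  # max-normalized expression of retained features
    is_tra: pd.Series  # tau >= tau_min
    expressing_tissues: dict[str, list[str]]  # feature -> binarized tissue set


@dataclass
class EntropyResult:
    entropy: pd.DataFrame  # gene x column, bits; NaN where ineligible
    column_medians: pd.Series
    eligibility: str


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    residual_sd: float
    predictions: pd.Series  # at query x
    ci_half_widths: pd.Series  # 95% mean-response CI at query x


def aggregate_tissues(matrix: pd.DataFrame, tissue_of: dict[str, str]) -> pd.DataFrame:
    """Collapse replicate sample columns to one column per tissue (median TPM)."""
    groups: dict[str, list[str]] = {}
    for col in matrix.columns:
        if col not in tissue_of:
            raise ValidationError(f"column {col!r} has no tissue assignment")
        groups.setdefault(tissue_of[col], []).append(col)
    return pd.DataFrame(
        {tissue: matrix[cols].median(axis=1) for tissue, cols in sorted(groups.items())}
    )


def compute_tau(
    matrix: pd.DataFrame, tpm_min: float = 1.0, tau_min: float = 0.8
) -> TauResult:
    """Tissue-specificity index tau = sum(1 - x_i/max x) / (n - 1).

    Features whose maximum tissue TPM is below ``tpm_min`` are dropped before
    scoring.  tau is 0 for uniform expression and 1 for single-tissue
    expression; features with tau >= ``tau_min`` are flagged as
    tissue-restricted.  Expressing tissues come from :func:`binarize_tissues`.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("tau needs >= 2 tissue columns")
    if (matrix.to_numpy() < 0).any():
        raise ValidationError("expression matrix must be nonnegative")
    maxes = matrix.max(axis=1)
    retained = matrix.loc[maxes >= tpm_min]
    if retained.empty:
        return TauResult(
            tau=pd.Series(dtype=float),
            xhat=retained,
            is_tra=pd.Series(dtype=bool),
            expressing_tissues={},
        )
    xhat = retained.div(retained.max(axis=1), axis=0)
    n = matrix.shape[1]
    tau = (1.0 - xhat).sum(axis=1) / (n - 1)
    is_tra = tau >= tau_min
    expressing = {
        feat: binarize_tissues(retained.loc[feat]) for feat in retained.index
    }
    return TauResult(tau=tau, xhat=xhat, is_tra=is_tra, expressing_tissues=expressing)


def binarize_tissues(expression: pd.Series) -> list[str]:
    """Tissues above the largest gap in the sorted expression values.

    Values are sorted ascending and the largest difference between
    consecutive values located; tissues strictly above the lower edge of that
    gap are "expressing".  Gap ties resolve toward the gap at higher
    expression (the smaller expressing set); an all-equal vector returns all
    tissues.
    """
    if expression.empty:
        raise ValidationError("empty expression vector")
    vals = expression.to_numpy(dtype=float)
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    diffs = np.diff(sorted_vals)
    if diffs.size == 0 or diffs.max() == 0:
        return list(expression.index)
    # argmax of ties toward the end = gap at higher expression
    best = diffs.size - 1 - int(np.argmax(diffs[::-1]))
    threshold = sorted_vals[best]
    return [expression.index[i] for i in range(len(vals)) if vals[i] > threshold]


def expressed_fraction(
    matrix: pd.DataFrame,
    thresholds: Sequence[float],
    feature_set: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Fraction of features at or above each TPM threshold, per column.

    Returns a tidy table (column, threshold, fraction); fractions are
    non-increasing in the threshold.
    """
    for thr in thresholds:
        if thr <= 0:
            raise ValidationError(f"threshold {thr} must be positive")
    if feature_set is not None:
        keep = [f for f in matrix.index if f in set(feature_set)]
        if not keep:
            raise ValidationError("feature_set shares no ids with the matrix")
        matrix = matrix.loc[keep]
    rows = []
    for col in matrix.columns:
        vals = matrix[col].to_numpy(dtype=float)
        for thr in thresholds:
            rows.append(
                {
                    "column": col,
                    "threshold": float(thr),
                    "fraction": float(np.mean(vals >= thr)),
                    "n_expressed": int(np.sum(vals >= thr)),
                }
            )
    return pd.DataFrame(rows)


def splicing_entropy(
    matrix: pd.DataFrame,
    transcript_to_gene: dict[str, str],
    min_expressed_isoforms: int = 2,
) -> EntropyResult:
    """Shannon entropy (bits) of each gene's isoform usage, per column.

    For gene g and column s, P_i = TPM_i / sum over g's isoforms; the entropy
    is -sum P_i log2 P_i with 0 log 0 := 0.  Genes are eligible in a column
    when >= ``min_expressed_isoforms`` isoforms have TPM > 0; the column
    summary is the median entropy over eligible genes.
    """
    missing = [t for t in matrix.index if t not in transcript_to_gene]
    if missing:
        raise ValidationError(f"transcripts missing from the map: {missing[:5]}")
    gene_of = pd.Series({t: transcript_to_gene[t] for t in matrix.index})
    genes = sorted(set(gene_of))
    ent = pd.DataFrame(np.nan, index=genes, columns=matrix.columns)
    grouped = {g: matrix.loc[gene_of.index[gene_of == g]] for g in genes}
    for g, sub in grouped.items():
        arr = sub.to_numpy(dtype=float)
        for ci, col in enumerate(matrix.columns):
            v = arr[:, ci]
            pos = v[v > 0]
            if pos.size < min_expressed_isoforms:
                continue
            p = pos / pos.sum()
            ent.loc[g, col] = float(-(p * np.log2(p)).sum())
    medians = ent.median(axis=0, skipna=True)
    return EntropyResult(
        entropy=ent,
        column_medians=medians,
        eligibility=f">={min_expressed_isoforms} isoforms with TPM>0",
    )


def transcripts_vs_genes_fit(
    reference_points: Sequence[tuple[float, float]],
    query_points: Sequence[float],
    level: float = 0.95,
) -> RegressionFit:
    """OLS of expressed-transcript counts on expressed-gene counts.

    Returns the line, residual SD, and mean-response confidence half-widths
    at the query gene counts (t-based)."""
    pts = np.asarray(reference_points, dtype=float)
    if pts.shape[0] < 3:
        raise FitError("need >= 3 reference points")
    x, y = pts[:, 0], pts[:, 1]
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise FitError("zero variance in gene counts")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    dof = len(x) - 2
    s2 = float(np.sum(resid**2) / dof) if dof > 0 else 0.0
    s = math.sqrt(s2)
    tcrit = stats.t.ppf(0.5 + level / 2, dof) if dof > 0 else 0.0
    q = np.asarray(query_points, dtype=float)
    pred = intercept + slope * q
    hw = tcrit * s * np.sqrt(1.0 / len(x) + (q - x.mean()) ** 2 / sxx)
    return RegressionFit(
        slope=slope,
        intercept=intercept,
        residual_sd=s,
        predictions=pd.Series(pred, index=q),
        ci_half_widths=pd.Series(hw, index=q),
    )
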