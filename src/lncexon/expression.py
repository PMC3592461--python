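"""Normalization, summarization and exon-level differential statistics.

The pre-processing chain is a deterministic RMA-lite: quantile
normalization of linear probe intensities, log2 transform, then Tukey
median-polish summarization of each probe set and of each transcript
cluster (the cluster summary pools *all* retained probes of the
cluster, not the probe-set summaries).

Exon-level signal is expressed as the gene-level normalized intensity
(GNI): per sample, log2 probe-set expression minus log2 cluster
expression.  The Splice Index (SI) of a probe set is the difference of
mean GNI between the two sample groups — the log2 fold change of the
exon-specific signal — tested with Welch's t and Benjamini–Hochberg
FDR control across probe sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ValidationError
from .io import ExpressionMatrix


# ---------------------------------------------------------------------------
# Group design

@dataclass(frozen=True)
class GroupDesign:
    """A two-group sample design; group1 is the lexicographically smaller
    label, and every contrast is group1 - group2."""

    sample_to_group: Mapping[str, str]

    def __post_init__(self) -> None:
        labels = sorted(set(self.sample_to_group.values()))
        if len(labels) != 2:
            raise ValidationError(
                f"design must have exactly two group labels, got {labels}"
            )
        for label in labels:
            n = sum(1 for g in self.sample_to_group.values() if g == label)
            if n < 2:
                raise ValidationError(f"group {label!r} has {n} sample(s); >= 2 required")

    @property
    def groups(self) -> tuple[str, str]:
        labels = sorted(set(self.sample_to_group.values()))
        return labels[0], labels[1]

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.sample_to_group.items() if g == group]

    def check_samples(self, sample_ids: Sequence[str]) -> None:
        design_samples = set(self.sample_to_group)
        if design_samples != set(sample_ids):
            missing = sorted(design_samples ^ set(sample_ids))
            raise ValidationError(f"design/matrix sample mismatch: {missing[:5]}")


# ---------------------------------------------------------------------------
# Quantile normalization

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution of sorted means.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; tied values within a column receive the mean of their
    target quantiles.  Rank order within each column is preserved.
    """
    if matrix.scale != "linear":
        raise ValidationError("quantile normalization expects a linear matrix")
    X = matrix.values.astype(float)
    n, m = X.shape
    if m < 2:
        warnings.warn("single-sample matrix: quantile normalization is a no-op")
        return matrix
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        vals = np.empty(n)
        vals[order] = reference
        # ties share the mean of the reference values they span
        out[:, j] = pd.Series(vals).groupby(col, sort=False).transform("mean").values
    df = pd.DataFrame(out, index=matrix.row_ids, columns=matrix.sample_ids)
    return ExpressionMatrix(df, scale="linear")


# ---------------------------------------------------------------------------
# Median polish

def _lomedian(v: np.ndarray) -> float:
    """Lower median: for even-length vectors take the lower of the two
    middle order statistics."""
    s = np.sort(v)
    return float(s[(len(s) - 1) // 2])


def median_polish(
    X: np.ndarray, max_iter: int = 10, tol: float = 1e-6
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish: X ~= overall + row + col + residual.

    Alternates row- and column-median sweeps (lower-median convention)
    until the largest absolute change of the residual matrix drops below
    ``tol`` or ``max_iter`` iterations have run.
    """
    R = np.asarray(X, dtype=float).copy()
    nr, nc = R.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    for _ in range(max_iter):
        prev = R.copy()
        rdelta = np.apply_along_axis(_lomedian, 1, R)
        R -= rdelta[:, None]
        row += rdelta
        cadj = _lomedian(col)
        col -= cadj
        overall += cadj
        cdelta = np.apply_along_axis(_lomedian, 0, R)
        R -= cdelta[None, :]
        col += cdelta
        radj = _lomedian(row)
        row -= radj
        overall += radj
        if np.max(np.abs(R - prev)) < tol:
            break
    return overall, row, col, R


def summarize(
    matrix: ExpressionMatrix, feature_map: Mapping[str, Sequence[str]]
) -> ExpressionMatrix:
    """Median-polish summarization of probe groups into features.

    ``feature_map`` maps each target feature (probe set or cluster) to
    its probe ids; its order fixes the output row order.  The per-sample
    summary is overall effect + column (sample) effect on the log2 scale.
    """
    if matrix.scale != "linear":
        raise ValidationError("summarize expects a linear matrix")
    if (matrix.values <= 0).any():
        raise ValidationError("non-positive intensity in input matrix")
    log2 = np.log2(matrix.data)
    rows = []
    for feature, probe_ids in feature_map.items():
        if len(probe_ids) == 0:
            raise ValidationError(f"feature {feature!r} has zero probes")
        missing = [p for p in probe_ids if p not in log2.index]
        if missing:
            raise ValidationError(
                f"feature {feature!r}: probes missing from matrix: {missing[:5]}"
            )
        sub = log2.loc[list(probe_ids)].values
        overall, _row, col, _res = median_polish(sub)
        rows.append(overall + col)
    df = pd.DataFrame(
        np.asarray(rows, dtype=float) if rows else np.empty((0, len(matrix.sample_ids))),
        index=list(feature_map.keys()),
        columns=matrix.sample_ids,
    )
    return ExpressionMatrix(df, scale="log2")


# ---------------------------------------------------------------------------
# GNI / Splice Index

def compute_gni(
    probeset_expr: ExpressionMatrix,
    cluster_expr: ExpressionMatrix,
    probeset_to_cluster: Mapping[str, str],
) -> pd.DataFrame:
    """Per-sample gene-level normalized intensity:
    GNI[p, s] = log2 probe-set expression - log2 cluster expression."""
    if probeset_expr.scale != "log2" or cluster_expr.scale != "log2":
        raise ValidationError("GNI expects log2 matrices")
    if probeset_expr.sample_ids != cluster_expr.sample_ids:
        raise ValidationError("probe-set / cluster sample sets differ")
    rows = {}
    for ps in probeset_expr.row_ids:
        cl = probeset_to_cluster.get(ps)
        if cl is None or cl not in cluster_expr.data.index:
            raise ValidationError(f"probe set {ps!r} has no cluster summary")
        rows[ps] = probeset_expr.data.loc[ps] - cluster_expr.data.loc[cl]
    return pd.DataFrame(rows).T.reindex(probeset_expr.row_ids)


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sample t-test p-value; degenerate zero-variance inputs
    yield p = 1 for equal means and p = 0 otherwise."""
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


@dataclass(frozen=True)
class SpliceResult:
    probeset_id: str
    cluster_id: str
    si: float
    p_value: float
    fdr: float


def splice_index(
    gni: pd.DataFrame,
    design: GroupDesign,
    probeset_to_cluster: Mapping[str, str],
) -> list[SpliceResult]:
    """SI per probe set: mean GNI(group1) - mean GNI(group2), Welch t on
    the per-sample GNI values, BH-adjusted across all probe sets."""
    design.check_samples(list(gni.columns))
    g1, g2 = design.groups
    s1, s2 = design.samples(g1), design.samples(g2)
    sis, ps = [], []
    for probeset in gni.index:
        a = gni.loc[probeset, s1].to_numpy(dtype=float)
        b = gni.loc[probeset, s2].to_numpy(dtype=float)
        sis.append(float(np.mean(a) - np.mean(b)))
        ps.append(_welch(a, b))
    fdr = multipletests(ps, method="fdr_bh")[1] if ps else np.array([])
    return [
        SpliceResult(str(probeset), probeset_to_cluster[str(probeset)], si, p, q)
        for probeset, si, p, q in zip(gni.index, sis, ps, fdr)
    ]


@dataclass(frozen=True)
class DEResult:
    cluster_id: str
    log2_fold_change: float
    p_value: float
    fdr: float


def differential_expression(
    cluster_expr: ExpressionMatrix, design: GroupDesign
) -> list[DEResult]:
    """Cluster-level log2 fold change (group1 - group2), Welch t, BH FDR."""
    if cluster_expr.scale != "log2":
        raise ValidationError("differential expression expects a log2 matrix")
    design.check_samples(cluster_expr.sample_ids)
    g1, g2 = design.groups
    s1, s2 = design.samples(g1), design.samples(g2)
    fcs, ps = [], []
    for cl in cluster_expr.row_ids:
        a = cluster_expr.data.loc[cl, s1].to_numpy(dtype=float)
        b = cluster_expr.data.loc[cl, s2].to_numpy(dtype=float)
        fcs.append(float(np.mean(a) - np.mean(b)))
        ps.append(_welch(a, b))
    fdr = multipletests(ps, method="fdr_bh")[1] if ps else np.array([])
    return [
        DEResult(str(cl), fc, p, q)
        for cl, fc, p, q in zip(cluster_expr.row_ids, fcs, ps, fdr)
    ]


# ---------------------------------------------------------------------------
# Variance filter

def select_top_variance(matrix: ExpressionMatrix, n: int = 150) -> ExpressionMatrix:
    """Rows with the ``n`` largest sample variances (original order kept
    among the selected; ties resolved toward earlier rows)."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if n >= len(matrix.row_ids):
        return matrix
    var = matrix.data.var(axis=1, ddof=1).to_numpy()
    top = np.sort(np.argsort(-var, kind="stable")[:n])
    return ExpressionMatrix(matrix.data.iloc[top], scale=matrix.scale)
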