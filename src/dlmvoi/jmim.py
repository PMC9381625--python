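"""Feature selection by joint mutual information maximization (JMIM).

Features are discretized by equal-frequency binning and scored with the
plug-in (maximum-likelihood) mutual information estimator in bits.  The
greedy JMIM criterion picks first the feature with maximal I(f; Y) and then
repeatedly the candidate maximizing min over already-selected s of
I(f, s; Y) — the maximin over joint mutual informations, which penalizes
candidates that are redundant with any selected feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiscretizedFeature", "SelectionResult", "discretize_feature",
    "mutual_information", "joint_mi", "jmim_select",
]


@dataclass(frozen=True)
class DiscretizedFeature:
    """Per-sample integer bins 1..n_bins from equal-frequency binning."""

    bins: np.ndarray
    n_bins: int
    constant: bool = False  # flagged zero-information


@dataclass(frozen=True)
class SelectionResult:
    """Ordered selected feature names with the per-step criterion value."""

    selected: tuple[str, ...]
    criterion_values: tuple[float, ...]


def discretize_feature(x: np.ndarray, n_bins: int = 10) -> DiscretizedFeature:
    """Equal-frequency binning with stable tie handling.

    Bin edges are the interior quantiles; ties at an edge all land in the
    same bin (so bin counts can deviate by the number of tied boundary
    values).  A constant feature collapses to one bin and is flagged.
    """
    x = np.asarray(x, dtype=np.float64)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.unique(x).size == 1:
        return DiscretizedFeature(bins=np.ones(x.size, dtype=np.int64),
                                  n_bins=1, constant=True)
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    bins = np.searchsorted(edges, x, side="left") + 1
    return DiscretizedFeature(bins=bins.astype(np.int64),
                              n_bins=int(bins.max()), constant=False)


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _codes(v: np.ndarray) -> tuple[np.ndarray, int]:
    _, codes = np.unique(v, return_inverse=True)
    return codes, int(codes.max()) + 1


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information I(a; b) in bits."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.size != b.size:
        raise ValueError("length mismatch")
    ca, na = _codes(a)
    cb, nb = _codes(b)
    joint = np.bincount(ca * nb + cb, minlength=na * nb)
    return (_entropy_from_counts(np.bincount(ca))
            + _entropy_from_counts(np.bincount(cb))
            - _entropy_from_counts(joint))


def joint_mi(f: np.ndarray, s: np.ndarray, y: np.ndarray) -> float:
    """I((f, s); y) in bits — mutual information of the paired variable."""
    f = np.asarray(f).ravel()
    s = np.asarray(s).ravel()
    y = np.asarray(y).ravel()
    if not (f.size == s.size == y.size):
        raise ValueError("length mismatch")
    cf, nf = _codes(f)
    cs, ns = _codes(s)
    return mutual_information(cf * ns + cs, y)


def _joint_mi_all(X: np.ndarray, s: np.ndarray, y: np.ndarray) -> np.ndarray:
    """I((X[:, f], s); y) for every column f at once.

    X holds 0-based codes per column; a single flat bincount over the
    (column, f-bin, s-bin, y-bin) code keeps the greedy step O(n * F).
    """
    n, F = X.shape
    bx = int(X.max()) + 1
    cs, ns = _codes(s)
    cy, ny = _codes(y)
    nc = ns * ny
    code = cs * ny + cy  # composite (s, y) class per sample
    flat = (np.arange(F) * (bx * nc))[None, :] + X * nc + code[:, None]
    counts = np.bincount(flat.ravel(), minlength=F * bx * nc).astype(np.float64)
    c4 = counts.reshape(F, bx, ns, ny)

    def ent(c):
        p = c.reshape(F, -1) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(p > 0, p * np.log2(p), 0.0)
        return -t.sum(axis=1)

    h_fs = ent(c4.sum(axis=3))
    h_fsy = ent(c4)
    h_y = _entropy_from_counts(np.bincount(cy))
    return h_fs + h_y - h_fsy


def discretize_table(table: pd.DataFrame, n_bins: int = 10) -> np.ndarray:
    """0-based equal-frequency codes for every column of a feature table."""
    return np.column_stack([
        discretize_feature(table[c].to_numpy(), n_bins).bins
        for c in table.columns
    ]) - 1


def _jmim_core(X: np.ndarray, y: np.ndarray, k: int) -> tuple[list[int], list[float]]:
    """Greedy maximin selection on pre-discretized 0-based codes.

    Criterion values are snapped to 1e-10 bits before each argmax so that
    mathematically tied candidates break by column order rather than by
    floating-point summation order.
    """
    F = X.shape[1]
    relevance = np.round(_joint_mi_all(X, np.zeros(X.shape[0], dtype=np.int64), y), 10)
    first = int(np.argmax(relevance))
    selected = [first]
    crit = [float(relevance[first])]
    min_joint = np.full(F, np.inf)
    for _ in range(k - 1):
        new_s = X[:, selected[-1]]
        min_joint = np.minimum(min_joint, np.round(_joint_mi_all(X, new_s, y), 10))
        masked = min_joint.copy()
        masked[selected] = -np.inf
        best = int(np.argmax(masked))
        selected.append(best)
        crit.append(float(min_joint[best]))
    return selected, crit


def jmim_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    k: int,
    n_bins: int = 10,
) -> SelectionResult:
    """Greedy JMIM selection of ``k`` features from a feature table.

    The first pick maximizes I(f; Y); each later pick maximizes
    min over selected s of I(f, s; Y).  Ties break by column order
    (argmax returns the first maximizer).  Constant features carry zero
    information and are only picked when nothing informative remains.
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    if k > table.shape[1]:
        raise ValueError(f"k={k} exceeds {table.shape[1]} features")
    y = np.asarray(labels).ravel()
    if y.size != len(table):
        raise ValueError("labels length mismatch")
    X = discretize_table(table, n_bins)
    selected, crit = _jmim_core(X, y, k)
    cols = list(table.columns)
    return SelectionResult(
        selected=tuple(cols[i] for i in selected),
        criterion_values=tuple(crit),
    )
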