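"""Bray-Curtis dissimilarity, log transforms and ordination.

Two ordination pathways are offered and labelled distinctly: principal
component analysis of log-transformed counts (``pca_logcounts``) and
principal coordinates analysis — classical metric MDS — of the
Bray-Curtis dissimilarity matrix (``pcoa_braycurtis``). Both are
implemented directly on dense eigendecompositions with a fixed sign
convention (the largest-magnitude loading, or score for PCoA, on each
axis is made positive) so repeated runs are bit-identical.

Bray-Curtis is computed on per-sample proportions by default: on raw
counts the index changes under per-sample rescaling, on proportions it
does not. Both modes are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountTable, ValidationError

_EIG_TOL = 1e-10


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must share one taxa index")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValidationError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


@dataclass
class DistanceMatrix:
    """Symmetric sample x sample dissimilarities in [0, 1]."""

    ids: tuple[str, ...]
    matrix: np.ndarray
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(np.diag(m), 0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if (m < -1e-12).any() or (m > 1 + 1e-12).any():
            raise ValidationError("dissimilarities must lie in [0, 1]")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.ids), columns=list(self.ids))


def bray_curtis_matrix(table: CountTable, proportions: bool = True) -> DistanceMatrix:
    """All-pairs Bray-Curtis over a count table's samples.

    With ``proportions=True`` (default) each sample is first scaled to
    sum 1, making the result invariant to sequencing depth.
    """
    data = table.data.to_numpy(dtype=float)
    ids = tuple(table.samples)
    if proportions:
        totals = data.sum(axis=0)
        if (totals == 0).any():
            raise ValidationError("zero-total sample in Bray-Curtis input")
        data = data / totals
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(data[:, i], data[:, j])
    return DistanceMatrix(ids, out)


def log_counts(table: CountTable, pseudocount: float = 1.0) -> CountTable:
    """Element-wise natural log(count + pseudocount); zeros stay 0 when
    the pseudocount is 1."""
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    return CountTable(
        np.log(table.data + pseudocount), rank=table.rank, normalized=True
    )


@dataclass
class OrdinationResult:
    """Sample scores and percent variance explained per axis."""

    scores: pd.DataFrame          # samples x axes (PC1, PC2, ...)
    explained_pct: np.ndarray
    method: str

    def __post_init__(self) -> None:
        pct = np.asarray(self.explained_pct, dtype=float)
        if len(pct) > 1 and (np.diff(pct) > 1e-9).any():
            raise ValidationError("explained percentages must be non-increasing")
        if pct.sum() > 100 + 1e-6:
            raise ValidationError("explained percentages sum above 100")
        self.explained_pct = pct


def _fix_signs(scores: np.ndarray, loadings: np.ndarray | None = None) -> np.ndarray:
    """Make the largest-magnitude loading (or score) on each axis positive."""
    ref = loadings if loadings is not None else scores
    for k in range(scores.shape[1]):
        col = ref[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            scores[:, k] = -scores[:, k]
            if loadings is not None:
                loadings[:, k] = -loadings[:, k]
    return scores


def _pca_logcounts(table: CountTable) -> OrdinationResult:
    # samples are observations, taxa are features
    X = log_counts(table).data.to_numpy(dtype=float).T
    X = X - X.mean(axis=0)
    # SVD of the centered data == eigendecomposition of the covariance
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    keep = var > _EIG_TOL * max(var.sum(), 1.0)
    U, s, Vt, var = U[:, keep], s[keep], Vt[keep], var[keep]
    scores = U * s
    scores = _fix_signs(scores, Vt.T)
    explained = var / var.sum() * 100.0 if var.sum() > 0 else var
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return OrdinationResult(
        pd.DataFrame(scores, index=list(table.samples), columns=cols),
        explained, "pca_logcounts",
    )


def _pcoa(dm: DistanceMatrix) -> OrdinationResult:
    D2 = dm.matrix**2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > _EIG_TOL * max(abs(vals).max(), 1.0)
    vals, vecs = vals[keep], vecs[:, keep]
    scores = vecs * np.sqrt(vals)
    scores = _fix_signs(scores)
    explained = vals / vals.sum() * 100.0 if vals.sum() > 0 else vals
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return OrdinationResult(
        pd.DataFrame(scores, index=list(dm.ids), columns=cols),
        explained, "pcoa_braycurtis",
    )


def ordinate(
    data: CountTable | DistanceMatrix, method: str = "pcoa_braycurtis"
) -> OrdinationResult:
    """Ordinate samples by PCA of log counts or PCoA of Bray-Curtis.

    ``pca_logcounts`` needs a CountTable; ``pcoa_braycurtis`` accepts a
    CountTable (Bray-Curtis computed on proportions) or a ready
    DistanceMatrix. At least 3 samples are required. Axes with ~zero
    explained variance (and, for PCoA, negative eigenvalues) are dropped.
    """
    n = len(data.samples) if isinstance(data, CountTable) else len(data.ids)
    if n < 3:
        raise ValidationError("ordination needs at least 3 samples")
    if method == "pca_logcounts":
        if not isinstance(data, CountTable):
            raise ValidationError("pca_logcounts needs a CountTable")
        return _pca_logcounts(data)
    if method == "pcoa_braycurtis":
        dm = data if isinstance(data, DistanceMatrix) else bray_curtis_matrix(data)
        return _pcoa(dm)
    raise ValidationError(f"unknown ordination method {method!r}")


def compartment_dissimilarity_summary(
    profiles: dict, pair: tuple[str, str] = ("LAV", "throat"), proportions: bool = True
) -> tuple[float, float, pd.Series]:
    """Mean +/- sample sd of Bray-Curtis for a compartment pair across participants.

    Participants lacking either compartment are skipped. With a single
    participant the sd is undefined (NaN, flagged by a warning).
    """
    a, b = pair
    values = {}
    for pid, profile in profiles.items():
        if not profile.has(a, b):
            continue
        x = profile.counts[a].to_numpy(dtype=float)
        y = profile.counts[b].to_numpy(dtype=float)
        if proportions:
            if x.sum() == 0 or y.sum() == 0:
                continue
            x, y = x / x.sum(), y / y.sum()
        values[pid] = bray_curtis(x, y)
    if not values:
        raise ValidationError(f"no participant has both compartments {pair}")
    series = pd.Series(values, name=f"bc_{a}_{b}")
    mean = float(series.mean())
    sd = float(series.std(ddof=1)) if len(series) > 1 else float("nan")
    return mean, sd, series
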