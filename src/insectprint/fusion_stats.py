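"""Four-block data fusion, PLS-DA variable selection and cluster analysis.

Two fusion levels operate over the four Pareto-scaled block matrices
(meohpos, meohneg, etacpos, etacneg):

* low-level fusion concatenates every bin of every block (for PCA
  exploration);
* mid-level fusion first fits a 5-component PLS-DA per block on the
  training rows, ranks bins by their VIP (variable importance in
  projection) and concatenates only the selected informative ions —
  18 by default, at least two per block.

PLS-DA is fit against a column-centered one-hot class matrix, extracting
successive dominant cross-covariance directions with deflation after
each component; VIP aggregates the squared,
normalized component weights by the Y variance each component explains,
so the mean squared VIP over bins is exactly one.

The selected ions are summarized by hierarchical clustering with Pearson
distance (1 - r) and Ward linkage, together with a per-species mean
intensity matrix in heatmap orientation (rows = ions, columns = species).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .constants import BLOCK_ORDER
from .preprocessing import FeatureMatrix

__all__ = [
    "BlockSet",
    "PLSModel",
    "SelectedFeature",
    "FusedMatrix",
    "low_level_fuse",
    "pca_scores",
    "fit_plsda",
    "vip_scores",
    "select_informative",
    "mid_level_fuse",
    "cluster_heatmap",
]


def feature_label(mz: float, block: str) -> str:
    """Heatmap-style feature label, e.g. ``255.2325_etacneg``."""
    return f"{mz:.4f}_{block}"


class BlockSet(dict):
    """Mapping block id -> Pareto-scaled FeatureMatrix with aligned rows."""

    def __init__(self, blocks: dict[str, FeatureMatrix]):
        if set(blocks) != set(BLOCK_ORDER):
            raise ValueError(
                f"a BlockSet requires exactly the 4 blocks {list(BLOCK_ORDER)}, "
                f"got {sorted(blocks)}"
            )
        ref = blocks[BLOCK_ORDER[0]].values.index
        for b in BLOCK_ORDER:
            idx = blocks[b].values.index
            if not idx.equals(ref):
                offending = sorted(set(map(tuple, idx)) ^ set(map(tuple, ref)))
                raise ValueError(f"row keys of block {b} disagree: {offending[:5]}")
        super().__init__({b: blocks[b] for b in BLOCK_ORDER})

    @property
    def row_index(self) -> pd.MultiIndex:
        return self[BLOCK_ORDER[0]].values.index

    def rows_for(self, sample_ids) -> "BlockSet":
        return BlockSet({b: m.rows_for(sample_ids) for b, m in self.items()})


@dataclass
class FusedMatrix:
    """Concatenated per-replicate matrix; ``level`` is "low" or "mid"."""

    values: pd.DataFrame  # index (sample_id, replicate); columns = labels
    level: str

    @property
    def row_index(self) -> pd.MultiIndex:
        return self.values.index

    def rows_for(self, sample_ids) -> "FusedMatrix":
        keep = self.values.index.get_level_values("sample_id").isin(set(sample_ids))
        return FusedMatrix(values=self.values.loc[keep], level=self.level)


def low_level_fuse(blocks: BlockSet) -> FusedMatrix:
    """Column-wise concatenation of all bins of all blocks, in block order."""
    if not isinstance(blocks, BlockSet):
        blocks = BlockSet(blocks)
    parts = []
    for b in BLOCK_ORDER:
        part = blocks[b].values.copy()
        part.columns = [feature_label(mz, b) for mz in part.columns]
        parts.append(part)
    return FusedMatrix(values=pd.concat(parts, axis=1), level="low")


def pca_scores(fused: FusedMatrix, n_components: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean-centered PCA via SVD: scores plus explained-variance fractions.

    Component signs follow the convention that the largest-magnitude
    loading of each component is positive.
    """
    X = fused.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U[:, :n_components] * s[:n_components]
    ev = (s**2) / (s**2).sum()
    cols = [f"PC{i+1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=fused.values.index, columns=cols),
        ev[:n_components],
    )


@dataclass
class PLSModel:
    """NIPALS PLS-DA fit: weights, scores, loadings per component."""

    classes: list[str]
    x_mean: np.ndarray
    y_mean: np.ndarray
    W: np.ndarray  # p x a, X weights
    T: np.ndarray  # n x a, X scores
    P: np.ndarray  # p x a, X loadings
    Q: np.ndarray  # c x a, Y loadings
    bin_mz: np.ndarray

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def rotations(self) -> np.ndarray:
        """W* = W (P'W)^-1, mapping centered X directly to scores."""
        return self.W @ np.linalg.inv(self.P.T @ self.W)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) @ self.rotations()

    def predict_y(self, X: np.ndarray) -> np.ndarray:
        """Predicted (continuous) class-membership matrix."""
        return self.predict_scores(X) @ self.Q.T + self.y_mean

    def predict_labels(self, X: np.ndarray) -> list[str]:
        yhat = self.predict_y(X)
        return [self.classes[i] for i in np.argmax(yhat, axis=1)]


def _one_hot(labels, classes: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for r, lab in enumerate(labels):
        Y[r, index[lab]] = 1.0
    return Y


def fit_plsda(
    matrix: FeatureMatrix | pd.DataFrame,
    labels,
    n_components: int = 5,
) -> PLSModel:
    """Fit PLS-DA against a centered one-hot class matrix.

    X and Y are column-centered (Y is never variance-scaled); X is
    expected Pareto-scaled upstream, in which case X centering is a
    no-op on training rows. Each component's weight vector is the
    dominant left singular vector of the deflated cross-covariance
    X'Y — the exact fixed point the NIPALS iteration converges to —
    computed directly so degenerate late components (the one-hot Y of
    c classes has rank c-1 after centering) cannot stall a power
    iteration. X and Y are deflated by the X scores after every
    component. Components are sign-fixed so each weight vector's
    largest-magnitude element is positive.
    """
    if isinstance(matrix, FeatureMatrix):
        df = matrix.values
        bin_mz = matrix.bin_mz
    else:
        df = matrix
        bin_mz = np.asarray(df.columns, dtype=float)
    labels = list(labels)
    if len(labels) != df.shape[0]:
        raise ValueError("labels length must match the number of rows")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    n, p = df.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, bins)={min(n - 1, p)}"
        )

    X = df.to_numpy(dtype=float).copy()
    x_mean = X.mean(axis=0)
    X -= x_mean
    Y = _one_hot(labels, classes)
    y_mean = Y.mean(axis=0)
    Y = Y - y_mean

    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((len(classes), n_components))
    for a in range(n_components):
        M = X.T @ Y  # p x c cross-covariance of the deflated blocks
        if not np.any(np.abs(M) > 1e-14):
            raise RuntimeError(
                f"degenerate cross-covariance at component {a + 1}: "
                "no residual X-Y covariance to extract"
            )
        U_m, _, _ = np.linalg.svd(M, full_matrices=False)
        w = U_m[:, 0]
        t = X @ w
        tt = t @ t
        if tt == 0:
            raise RuntimeError(f"degenerate score vector at component {a + 1}")
        q = Y.T @ t / tt
        j = np.argmax(np.abs(w))
        if w[j] < 0:
            w, t, q = -w, -t, -q
        pload = X.T @ t / (t @ t)
        X = X - np.outer(t, pload)
        Y = Y - np.outer(t, q)
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, pload, q
    return PLSModel(
        classes=classes, x_mean=x_mean, y_mean=y_mean, W=W, T=T, P=P, Q=Q, bin_mz=bin_mz
    )


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable importance in projection over the fitted components.

    VIP_j = sqrt( p * sum_a[ SSY_a (w_ja/||w_a||)^2 ] / sum_a SSY_a ),
    where SSY_a = ||t_a||^2 ||q_a||^2 is the Y variance captured by
    component a. Mean squared VIP over the p bins equals 1 exactly.
    """
    p = model.W.shape[0]
    ssy = np.einsum("na,na->a", model.T, model.T) * np.einsum(
        "ca,ca->a", model.Q, model.Q
    )
    wnorm2 = (model.W**2).sum(axis=0)
    contrib = (model.W**2 / wnorm2) @ ssy
    return np.sqrt(p * contrib / ssy.sum())


@dataclass(frozen=True)
class SelectedFeature:
    """One informative ion chosen by per-block PLS-DA VIP ranking."""

    block: str
    bin_mz: float
    vip: float
    rank: int

    @property
    def label(self) -> str:
        return feature_label(self.bin_mz, self.block)


def select_informative(
    blocks: BlockSet,
    labels,
    total: int = 18,
    n_components: int = 5,
) -> list[SelectedFeature]:
    """Pick the ``total`` most informative ions across the four blocks.

    Per block, a 5-component PLS-DA is fit on the (training) rows and
    bins are ranked by VIP; the top ceil(total/4)+1 per block form the
    candidate pool, from which the global top ``total`` by VIP are kept
    under a floor of two features per block (the floor scales down to
    max(1, total//4) for small totals). Ties break deterministically by
    (higher VIP, lower m/z, block order).
    """
    if not isinstance(blocks, BlockSet):
        blocks = BlockSet(blocks)
    labels = list(labels)
    quota = math.ceil(total / len(BLOCK_ORDER)) + 1
    floor = max(1, min(2, total // len(BLOCK_ORDER)))

    candidates: list[tuple[float, float, int, str]] = []  # (vip, mz, block_rank, block)
    per_block: dict[str, list[tuple[float, float, int, str]]] = {}
    for bi, b in enumerate(BLOCK_ORDER):
        matrix = blocks[b]
        if matrix.n_bins < 2:
            raise ValueError(f"block {b} has fewer than 2 bins after filtering")
        k = min(n_components, matrix.values.shape[0] - 1, matrix.n_bins)
        model = fit_plsda(matrix, labels, n_components=k)
        vip = vip_scores(model)
        ranked = sorted(
            zip(vip, matrix.bin_mz), key=lambda t: (-t[0], t[1])
        )[:quota]
        entries = [(v, mz, bi, b) for v, mz in ranked]
        per_block[b] = entries
        candidates.extend(entries)

    def order_key(e):
        return (-e[0], e[1], e[2])

    chosen: list[tuple[float, float, int, str]] = []
    taken = set()
    for b in BLOCK_ORDER:  # per-block floor first
        for e in per_block[b][:floor]:
            chosen.append(e)
            taken.add((e[3], e[1]))
    for e in sorted(candidates, key=order_key):  # then global VIP order
        if len(chosen) >= total:
            break
        if (e[3], e[1]) not in taken:
            chosen.append(e)
            taken.add((e[3], e[1]))
    if len(chosen) != total:
        raise ValueError(
            f"could not select {total} features from the candidate pool "
            f"({len(chosen)} available)"
        )
    chosen.sort(key=order_key)
    return [
        SelectedFeature(block=b, bin_mz=float(mz), vip=float(v), rank=r + 1)
        for r, (v, mz, _, b) in enumerate(chosen)
    ]


def mid_level_fuse(blocks: BlockSet, selected: list[SelectedFeature]) -> FusedMatrix:
    """Concatenate only the selected ions, ordered by (block order, m/z)."""
    if not isinstance(blocks, BlockSet):
        blocks = BlockSet(blocks)
    cols = {}
    ordered = sorted(selected, key=lambda f: (BLOCK_ORDER.index(f.block), f.bin_mz))
    for feat in ordered:
        values = blocks[feat.block].values
        matches = [c for c in values.columns if np.isclose(c, feat.bin_mz, rtol=0, atol=5e-5)]
        if not matches:
            raise ValueError(
                f"selected feature {feat.label} is absent from block {feat.block}"
            )
        cols[feat.label] = values[matches[0]]
    return FusedMatrix(values=pd.DataFrame(cols), level="mid")


def _pearson_distance(data: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson(r) distance over rows; constant rows -> 1."""
    n = data.shape[0]
    sd = data.std(axis=1)
    centered = data - data.mean(axis=1, keepdims=True)
    dist = np.ones((n, n))
    ok = sd > 0
    if ok.any():
        sub = centered[ok]
        corr = (sub @ sub.T) / np.outer(np.linalg.norm(sub, axis=1), np.linalg.norm(sub, axis=1))
        idx = np.flatnonzero(ok)
        dist[np.ix_(idx, idx)] = 1.0 - np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


def cluster_heatmap(
    fused: FusedMatrix, labels
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Ward clustering on Pearson distance plus the species-mean matrix.

    Returns (row_linkage over ions, column_linkage over species,
    species_mean) where species_mean has ions as rows and species as
    columns — the heatmap orientation. A constant ion (undefined
    correlation) sits at the maximum distance 1 from every other.
    """
    if fused.values.shape[1] < 2:
        raise ValueError("clustering needs at least 2 features")
    labels = list(labels)
    df = fused.values
    species = sorted(set(labels))
    by_species = {
        sp: df.loc[[lab == sp for lab in labels]].mean(axis=0) for sp in species
    }
    species_mean = pd.DataFrame(by_species)  # rows = ion labels, cols = species

    ion_data = df.to_numpy(dtype=float).T  # ions x replicates
    row_linkage = linkage(_pearson_distance(ion_data), method="ward")
    col_linkage = linkage(_pearson_distance(species_mean.to_numpy().T), method="ward")
    return row_linkage, col_linkage, species_mean
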