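"""Emergent self-organizing map on a toroidal grid, with U/P/U* landscapes.

An emergent SOM uses far more neurons (default 50 x 80 = 4,000) than the
expected number of clusters, so that cluster structure can *emerge* on the
map instead of being imposed.  The grid is a torus (opposite edges joined),
which removes border effects.  After training, three height fields are
computed on the grid:

* **U-matrix** — per neuron, the mean weight-space distance to its 8
  toroidal Moore neighbors; high values mark cluster borders.
* **P-matrix** — per neuron, the number of data points within the Pareto
  radius of its weight vector (a density landscape).
* **U*-matrix** — the U-matrix rescaled by local density so that ridges
  inside dense regions are suppressed:
  ``U* = U * clamp((P - mean(P)) / (mean(P) - max(P)) + 1, 0, inf)``.

Training is online: samples are presented in a per-epoch shuffled order,
the best matching unit (BMU) is found by Euclidean distance, and all units
are pulled toward the sample with a neighborhood kernel whose radius and
learning rate decay linearly over the epochs.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted


def _toroidal_axis_dist(n: int) -> np.ndarray:
    """(n, n) matrix of minimum-image index distances on a ring of size n."""
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(d, n - d)


def bmu(weights: np.ndarray, x: np.ndarray) -> tuple[int, int]:
    """Best matching unit of ``x`` on a (rows, cols, D) weight grid.

    Returns the (row, col) of the unit with minimal Euclidean distance;
    ties are broken by the smallest row-major linear index (numpy argmin
    convention).
    """
    weights = np.asarray(weights, dtype=float)
    x = np.asarray(x, dtype=float)
    if weights.ndim != 3 or x.shape != (weights.shape[2],):
        raise ValueError(
            f"dimension mismatch: weights {weights.shape}, sample {x.shape}"
        )
    d2 = ((weights - x[None, None, :]) ** 2).sum(axis=2)
    flat = int(np.argmin(d2))
    return flat // weights.shape[1], flat % weights.shape[1]


def bmu_coords(weights: np.ndarray, X: np.ndarray) -> np.ndarray:
    """(n, 2) BMU coordinates for every row of ``X`` (vectorized)."""
    rows, cols, d = weights.shape
    W = weights.reshape(rows * cols, d)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != d:
        raise ValueError(f"dimension mismatch: weights D={d}, data D={X.shape[1]}")
    out = np.empty((len(X), 2), dtype=int)
    # explicit diff-square-sum: deterministic reduction order (no BLAS)
    step = max(1, 4_000_000 // max(rows * cols * d, 1))
    for start in range(0, len(X), step):
        chunk = X[start : start + step]
        d2 = ((chunk[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
        flat = np.argmin(d2, axis=1)
        out[start : start + step, 0] = flat // cols
        out[start : start + step, 1] = flat % cols
    return out


def umatrix(weights: np.ndarray, neighborhood: str = "moore") -> np.ndarray:
    """Mean weight-space distance of each unit to its toroidal neighbors.

    ``neighborhood`` is "moore" (8 neighbors, default) or "vonneumann"
    (4 neighbors).
    """
    weights = np.asarray(weights, dtype=float)
    if neighborhood == "moore":
        shifts = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    elif neighborhood == "vonneumann":
        shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        raise ValueError(f"unknown neighborhood {neighborhood!r}")
    total = np.zeros(weights.shape[:2])
    for dr, dc in shifts:
        shifted = np.roll(weights, shift=(dr, dc), axis=(0, 1))
        total += np.sqrt(((weights - shifted) ** 2).sum(axis=2))
    return total / len(shifts)


def pmatrix(weights: np.ndarray, X: np.ndarray, r: float) -> np.ndarray:
    """Per-unit count of data points within radius ``r`` of the unit weight."""
    weights = np.asarray(weights, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rows, cols, d = weights.shape
    W = weights.reshape(rows * cols, d)
    counts = np.empty(rows * cols, dtype=int)
    step = max(1, 4_000_000 // max(len(X) * d, 1))
    for start in range(0, len(W), step):
        chunk = W[start : start + step]
        d2 = ((chunk[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        counts[start : start + step] = (d2 <= r * r + 1e-12).sum(axis=1)
    return counts.reshape(rows, cols)


def ustar(U: np.ndarray, P: np.ndarray) -> np.ndarray:
    """U*-matrix: U-heights rescaled by local density.

    ``scale = (P - mean(P)) / (mean(P) - max(P)) + 1`` is 1 at mean density,
    0 at maximum density and > 1 in sparse regions; it is clamped below at
    0 so heights remain a landscape.  A constant P-matrix leaves U
    unchanged (degenerate but valid case).
    """
    U = np.asarray(U, dtype=float)
    P = np.asarray(P, dtype=float)
    if U.shape != P.shape:
        raise ValueError("U and P must have the same shape")
    mean_p, max_p = P.mean(), P.max()
    if max_p == mean_p:
        return U.copy()
    scale = (P - mean_p) / (mean_p - max_p) + 1.0
    return U * np.clip(scale, 0.0, None)


class Esom(BaseEstimator):
    """Toroidal emergent self-organizing map.

    Parameters
    ----------
    rows, cols : int
        Grid dimensions (default 50 x 80 = 4,000 units).
    epochs : int
        Number of sweeps through the data (default 30).
    lr0, lr1 : float
        Learning rate, decayed linearly from ``lr0`` to ``lr1`` over epochs.
    radius0, radius1 : float or None
        Neighborhood radius schedule, linear decay; ``radius0`` defaults to
        ``rows / 2``.
    kernel : {"gaussian", "cone"}
        Neighborhood kernel over toroidal grid distance d:
        ``exp(-d^2 / (2 radius^2))`` or ``max(0, 1 - d / radius)``.
    random_state : int or None
        Seed for weight initialization and per-epoch sample shuffling; a
        fixed seed makes training bit-reproducible.

    Attributes
    ----------
    weights_ : ndarray (rows, cols, D)
    umatrix_ : ndarray (rows, cols)
    quantization_errors_ : list of float, mean sample-to-BMU distance after
        each epoch.
    """

    def __init__(
        self,
        rows: int = 50,
        cols: int = 80,
        epochs: int = 30,
        lr0: float = 0.5,
        lr1: float = 0.05,
        radius0: float | None = None,
        radius1: float = 1.0,
        kernel: str = "gaussian",
        neighborhood: str = "moore",
        random_state: int | None = 0,
    ):
        self.rows = rows
        self.cols = cols
        self.epochs = epochs
        self.lr0 = lr0
        self.lr1 = lr1
        self.radius0 = radius0
        self.radius1 = radius1
        self.kernel = kernel
        self.neighborhood = neighborhood
        self.random_state = random_state

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y=None) -> "Esom":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values")
        if len(X) < 1:
            raise ValueError("need at least one sample")
        if self.kernel not in ("gaussian", "cone"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        n, d = X.shape
        rng = np.random.default_rng(self.random_state)

        lo, hi = X.min(axis=0), X.max(axis=0)
        W = rng.uniform(lo, hi, size=(self.rows, self.cols, d))
        Wf = W.reshape(-1, d)

        row_dist = _toroidal_axis_dist(self.rows)
        col_dist = _toroidal_axis_dist(self.cols)
        r0 = self.rows / 2 if self.radius0 is None else self.radius0

        self.quantization_errors_ = []
        for epoch in range(self.epochs):
            t = epoch / (self.epochs - 1) if self.epochs > 1 else 0.0
            lr = self.lr0 + t * (self.lr1 - self.lr0)
            radius = max(r0 + t * (self.radius1 - r0), 1e-9)
            order = rng.permutation(n)
            for i in order:
                x = X[i]
                d2 = ((Wf - x) ** 2).sum(axis=1)
                flat = int(np.argmin(d2))
                br, bc = flat // self.cols, flat % self.cols
                gd2 = (row_dist[br][:, None] ** 2 + col_dist[bc][None, :] ** 2).reshape(-1)
                if self.kernel == "gaussian":
                    h = np.exp(-gd2 / (2.0 * radius * radius))
                else:
                    h = np.clip(1.0 - np.sqrt(gd2) / radius, 0.0, None)
                active = h > 1e-4
                Wf[active] += lr * h[active, None] * (x - Wf[active])
            self.quantization_errors_.append(self._quantization_error(W, X))

        self.weights_ = W
        self.n_features_in_ = d
        self.umatrix_ = umatrix(W, neighborhood=self.neighborhood)
        return self

    @staticmethod
    def _quantization_error(W: np.ndarray, X: np.ndarray) -> float:
        coords = bmu_coords(W, X)
        w = W[coords[:, 0], coords[:, 1]]
        return float(np.sqrt(((X - w) ** 2).sum(axis=1)).mean())

    # -- inference ----------------------------------------------------------

    def bmus(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) best-matching-unit coordinates for the rows of ``X``."""
        check_is_fitted(self, "weights_")
        return bmu_coords(self.weights_, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Row-major linear BMU index per sample (sklearn-style labels)."""
        coords = self.bmus(X)
        return coords[:, 0] * self.cols + coords[:, 1]

    def landscape(
        self, X: np.ndarray, r: float | None = None, q: float = 0.18
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Compute and cache the (U, P, U*) height fields for data ``X``.

        ``r`` defaults to the Pareto radius of ``X`` at quantile ``q``.
        """
        check_is_fitted(self, "weights_")
        from olfcluster.mixture import pareto_radius

        if r is None:
            r = pareto_radius(X, q=q, random_state=self.random_state)
        self.pareto_radius_ = float(r)
        self.pmatrix_ = pmatrix(self.weights_, X, r)
        self.ustar_ = ustar(self.umatrix_, self.pmatrix_)
        return self.umatrix_, self.pmatrix_, self.ustar_


def export_heightmap(height: np.ndarray, path, cmap: str = "terrain") -> None:
    """Write a static heightmap PNG of a U/P/U* landscape."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(height, cmap=cmap, origin="upper")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
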