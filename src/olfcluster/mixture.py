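"""Pareto density estimation and Gaussian-mixture posterior features.

Each (age/sex-corrected) subtest score distribution is summarized in three
steps:

1. **Pareto density estimation (PDE)** — a sphere-count kernel density
   estimate.  The density at a point is the number of data points within
   the *Pareto radius* ``r`` of it; ``r`` is a quantile (default 18%) of
   the empirical pairwise-distance distribution, a choice that makes the
   estimate sensitive to group structure.
2. **Three-component Gaussian mixture** fitted in two phases: standard EM
   on the raw data (quantile-initialized), then a least-squares refinement
   that matches the mixture pdf to the PDE curve on a grid, mirroring the
   interactive density-matching fits used for score distributions.
3. **Bayesian posterior featurization** — every subject is mapped to the
   posterior probabilities of belonging to the low / mid / high component
   of each subtest's mixture, giving an n x 9 feature matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

DEFAULT_PARETO_QUANTILE = 0.18
PAIRWISE_SUBSAMPLE = 2000

FEATURE_COLUMNS = tuple(
    f"{subtest}_{level}" for subtest in ("thr", "disc", "ident") for level in ("low", "mid", "high")
)


# ---------------------------------------------------------------------------
# Pareto radius and Pareto density estimation
# ---------------------------------------------------------------------------

def pareto_radius(
    data: np.ndarray,
    q: float = DEFAULT_PARETO_QUANTILE,
    max_points: int = PAIRWISE_SUBSAMPLE,
    random_state: int | None = 0,
) -> float:
    """Pareto radius: the ``q``-quantile of pairwise Euclidean distances.

    ``data`` may be 1-D (n,) or 2-D (n, d).  For n > ``max_points`` the
    distance distribution is computed on a seeded subsample to keep the
    pair count manageable.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2 or len(x) < 2:
        raise ValueError("pareto_radius needs at least 2 points")
    if not 0 < q <= 1:
        raise ValueError("quantile q must be in (0, 1]")
    if len(x) > max_points:
        rng = np.random.default_rng(random_state)
        x = x[rng.choice(len(x), size=max_points, replace=False)]
    from scipy.spatial.distance import pdist

    d = pdist(x)
    r = float(np.quantile(d, q))
    if r <= 0:
        # quantile fell on duplicate points; use smallest positive distance
        positive = d[d > 0]
        if positive.size == 0:
            raise ValueError("zero spread: all points identical")
        r = float(positive.min())
    return r


@dataclass(frozen=True)
class PDEstimate:
    """Pareto density estimate on a grid: normalized to unit integral."""

    grid: np.ndarray
    density: np.ndarray
    r: float

    def raw_counts(self) -> np.ndarray:
        return self.density * self._norm

    _norm: float = 1.0


def sphere_counts(data: np.ndarray, centers: np.ndarray, r: float) -> np.ndarray:
    """Number of data points within distance ``r`` of each center (1-D)."""
    data = np.asarray(data, dtype=float).ravel()
    centers = np.asarray(centers, dtype=float).ravel()
    return (np.abs(data[None, :] - centers[:, None]) <= r).sum(axis=1)


def pde(
    data: np.ndarray,
    grid: np.ndarray | None = None,
    r: float | None = None,
    q: float = DEFAULT_PARETO_QUANTILE,
    n_grid: int = 200,
    random_state: int | None = 0,
) -> PDEstimate:
    """Pareto density estimate of a 1-D sample.

    The raw density at each grid point is the count of data points within
    the Pareto radius; the curve is then normalized so its trapezoidal
    integral over the grid equals 1.  The default grid spans the data range
    extended by one radius on each side (``n_grid`` equally spaced points).
    """
    data = np.asarray(data, dtype=float).ravel()
    if r is None:
        r = pareto_radius(data, q=q, random_state=random_state)
    if grid is None:
        grid = np.linspace(data.min() - r, data.max() + r, n_grid)
    else:
        grid = np.asarray(grid, dtype=float).ravel()
        if grid.size == 0:
            raise ValueError("pde: empty evaluation grid")
    counts = sphere_counts(data, grid, r).astype(float)
    area = np.trapezoid(counts, grid) if grid.size > 1 else counts.sum()
    if area <= 0:
        raise ValueError("pde: density integrates to zero on this grid")
    return PDEstimate(grid=grid, density=counts / area, r=float(r), _norm=float(area))


# ---------------------------------------------------------------------------
# Gaussian mixture model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianComponent:
    w: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0 < self.w <= 1:
            raise ValueError(f"component weight {self.w} outside (0, 1]")
        if self.sigma <= 0:
            raise ValueError(f"component sigma {self.sigma} must be > 0")


@dataclass(frozen=True)
class GMModel:
    """Univariate Gaussian mixture, components sorted by ascending mean."""

    subtest: str
    components: tuple[GaussianComponent, ...]

    def __post_init__(self) -> None:
        w = np.array([c.w for c in self.components])
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        mus = [c.mu for c in self.components]
        if any(b < a for a, b in zip(mus, mus[1:])):
            raise ValueError("components must be sorted by ascending mean")

    @property
    def m(self) -> int:
        return len(self.components)

    def params(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        w = np.array([c.w for c in self.components])
        mu = np.array([c.mu for c in self.components])
        sigma = np.array([c.sigma for c in self.components])
        return w, mu, sigma

    def pdf(self, x: np.ndarray) -> np.ndarray:
        w, mu, sigma = self.params()
        x = np.asarray(x, dtype=float)
        return (w[:, None] * norm.pdf(x[None, :], mu[:, None], sigma[:, None])).sum(axis=0)

    def to_dict(self) -> dict:
        return {
            "subtest": self.subtest,
            "components": [
                {"w": c.w, "mu": c.mu, "sigma": c.sigma} for c in self.components
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GMModel":
        comps = tuple(
            GaussianComponent(c["w"], c["mu"], c["sigma"]) for c in d["components"]
        )
        return cls(subtest=d["subtest"], components=comps)


def _sort_components(w: np.ndarray, mu: np.ndarray, sigma: np.ndarray):
    order = np.lexsort((sigma, mu))  # ascending mu, ties by sigma
    return w[order], mu[order], sigma[order]


def _log_likelihood(x, w, mu, sigma) -> float:
    log_pdf = norm.logpdf(x[None, :], mu[:, None], sigma[:, None]) + np.log(w)[:, None]
    return float(logsumexp(log_pdf, axis=0).sum())


def _em(x, m, rng, tol, max_iter, sigma_floor):
    n = len(x)
    # quantile-based initialization
    mu = np.quantile(x, (np.arange(m) + 0.5) / m)
    sigma = np.full(m, max(x.std(), sigma_floor))
    w = np.full(m, 1.0 / m)

    ll_old = -np.inf
    reseeded = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        log_comp = norm.logpdf(x[None, :], mu[:, None], sigma[:, None]) + np.log(w)[:, None]
        log_total = logsumexp(log_comp, axis=0)
        resp = np.exp(log_comp - log_total[None, :])  # (m, n)
        ll = float(log_total.sum())
        # EM guarantees monotone log-likelihood up to round-off
        assert ll >= ll_old - 1e-8 * max(1.0, abs(ll_old)), "EM log-likelihood decreased"
        nk = resp.sum(axis=1)
        w = nk / n
        # elementwise-and-reduce (not BLAS) keeps repeated fits bit-identical
        mu = (resp * x[None, :]).sum(axis=1) / nk
        var = (resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk
        sigma = np.sqrt(var)
        for k in range(m):
            if sigma[k] < sigma_floor or not np.isfinite(sigma[k]) or nk[k] < 1e-10:
                if reseeded[k]:
                    raise RuntimeError(
                        f"EM component {k} degenerated twice (sigma < floor); "
                        "data may be too discrete for this mixture order"
                    )
                logger.warning("re-seeding degenerate EM component %d", k)
                mu[k] = float(rng.choice(x))
                sigma[k] = max(x.std(), sigma_floor)
                w[k] = 1.0 / m
                w = w / w.sum()
                reseeded[k] = True
        if abs(ll - ll_old) < tol * max(1.0, abs(ll_old)):
            break
        ll_old = ll
    return w, mu, sigma


def _refine_on_pde(
    w, mu, sigma, estimate: PDEstimate, sigma_floor: float, max_iter: int = 200
):
    """Least-squares fit of the mixture pdf to the PDE curve.

    A small Levenberg-Marquardt loop with an analytic Jacobian, on the
    unconstrained parametrization (softmax weights, log sigmas).  Pure
    numpy so repeated fits are bit-reproducible.  Guaranteed not to
    increase the sum of squared pdf-vs-PDE residuals relative to the EM
    solution: the best iterate (or the EM fit itself) is returned.
    """
    grid, target = estimate.grid, estimate.density
    m = len(w)

    def unpack(theta):
        lw = theta[:m]
        wt = np.exp(lw - logsumexp(lw))
        mut = theta[m : 2 * m]
        st = np.maximum(np.exp(theta[2 * m :]), sigma_floor)
        return wt, mut, st

    def residuals_jac(theta):
        wt, mut, st = unpack(theta)
        phi = norm.pdf(grid[None, :], mut[:, None], st[:, None])  # (m, g)
        pdf = (wt[:, None] * phi).sum(axis=0)
        res = pdf - target
        z = (grid[None, :] - mut[:, None]) / st[:, None]
        J = np.empty((len(grid), 3 * m))
        J[:, :m] = (wt[:, None] * (phi - pdf[None, :])).T  # d/d logit-w
        J[:, m : 2 * m] = (wt[:, None] * phi * z / st[:, None]).T  # d/d mu
        J[:, 2 * m :] = (wt[:, None] * phi * (z**2 - 1.0)).T  # d/d log-sigma
        return res, J

    theta = np.concatenate([np.log(w), mu, np.log(sigma)])
    res, J = residuals_jac(theta)
    # einsum (not BLAS) keeps repeated fits bit-identical
    ssr = float(np.einsum("g,g->", res, res))
    best_theta, best_ssr = theta.copy(), ssr
    lam = 1e-3
    for _ in range(max_iter):
        A = np.einsum("gi,gj->ij", J, J)
        A_damped = A + lam * np.diag(np.diag(A)) + 1e-12 * np.eye(3 * m)
        try:
            step = np.linalg.solve(A_damped, -np.einsum("gi,g->i", J, res))
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        cand = theta + step
        cand_res, cand_J = residuals_jac(cand)
        cand_ssr = float(np.einsum("g,g->", cand_res, cand_res))
        if np.isfinite(cand_ssr) and cand_ssr < ssr:
            theta, res, J, ssr = cand, cand_res, cand_J, cand_ssr
            lam = max(lam / 3.0, 1e-12)
            if ssr < best_ssr:
                best_theta, best_ssr = theta.copy(), ssr
        else:
            lam *= 3.0
            if lam > 1e12:
                break
    return unpack(best_theta)


def fit_gmm(
    data: np.ndarray,
    m: int = 3,
    subtest: str = "score",
    random_state: int | None = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    refine: bool = True,
    pde_quantile: float = DEFAULT_PARETO_QUANTILE,
    n_grid: int = 200,
) -> GMModel:
    """Two-phase Gaussian-mixture fit of a 1-D score distribution.

    Phase 1 runs EM on the raw data with quantile-initialized means; phase 2
    refines the parameters by least squares against the Pareto density
    estimate on a grid (weights renormalized).  Components are returned
    sorted by ascending mean, labelled low / mid / high downstream.
    """
    x = np.asarray(data, dtype=float).ravel()
    if len(x) < 10 * m:
        raise ValueError(f"need at least {10 * m} points to fit m={m} components")
    if np.ptp(x) == 0:
        raise ValueError("zero spread: all points identical")
    rng = np.random.default_rng(random_state)
    sigma_floor = 1e-3 * x.std()

    w, mu, sigma = _em(x, m, rng, tol, max_iter, sigma_floor)
    if refine:
        estimate = pde(x, q=pde_quantile, n_grid=n_grid, random_state=random_state)
        w, mu, sigma = _refine_on_pde(w, mu, sigma, estimate, sigma_floor)
    # snap to a 1e-10 grid: absorbs run-to-run round-off so identical inputs
    # always serialize to identical models
    mu, sigma = np.round(mu, 10), np.round(sigma, 10)
    w = np.round(w, 10)
    w = w / w.sum()
    w, mu, sigma = _sort_components(w, mu, sigma)
    comps = tuple(GaussianComponent(float(a), float(b), float(c)) for a, b, c in zip(w, mu, sigma))
    return GMModel(subtest=subtest, components=comps)


def posterior(model: GMModel, x: np.ndarray) -> np.ndarray:
    """Bayesian posterior component memberships, shape (n, m).

    ``p_i(x) = w_i phi(x; mu_i, sigma_i) / sum_j w_j phi(x; mu_j, sigma_j)``,
    evaluated with log-sum-exp stabilization.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("posterior: input contains non-finite values")
    w, mu, sigma = model.params()
    log_num = norm.logpdf(x[:, None], mu[None, :], sigma[None, :]) + np.log(w)[None, :]
    return np.exp(log_num - logsumexp(log_num, axis=1, keepdims=True))


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

def build_feature_matrix(
    frame: pd.DataFrame,
    models: dict[str, GMModel],
    columns: dict[str, str] | None = None,
) -> pd.DataFrame:
    """n x 9 posterior feature matrix from three per-subtest mixtures.

    ``models`` maps subtest keys ("thr", "disc", "ident") to fitted 3-component
    mixtures; ``columns`` maps subtest keys to the score columns to read
    (default: the corrected columns ``thr_c``/``disc_c``/``ident_c``).
    Rows with a missing score are dropped with a logged subject id.
    """
    if columns is None:
        columns = {"thr": "thr_c", "disc": "disc_c", "ident": "ident_c"}
    for key in ("thr", "disc", "ident"):
        if key not in models:
            raise ValueError(f"missing mixture model for subtest {key!r}")
        if models[key].m != 3:
            raise ValueError(f"subtest {key!r}: expected 3 components, got {models[key].m}")

    score_cols = [columns[k] for k in ("thr", "disc", "ident")]
    valid = frame[score_cols].notna().all(axis=1)
    if not valid.all():
        dropped = frame.loc[~valid, "subject_id"] if "subject_id" in frame else frame.index[~valid]
        for sid in dropped:
            logger.warning("dropping subject %s: missing subtest score", sid)
    sub = frame.loc[valid]

    blocks = [posterior(models[k], sub[columns[k]].to_numpy(dtype=float)) for k in ("thr", "disc", "ident")]
    features = np.hstack(blocks)
    return pd.DataFrame(features, index=sub.index, columns=list(FEATURE_COLUMNS))


class MixtureFeaturizer(TransformerMixin, BaseEstimator):
    """Posterior-probability featurizer over the three olfactory subtests.

    Fits one ``m``-component Gaussian mixture per subtest column (two-phase
    fit, see :func:`fit_gmm`) and transforms score triplets into the
    concatenated posterior membership vector (n x 3m; 9 for the default
    m = 3).

    Parameters follow :func:`fit_gmm`; ``columns`` names the three score
    columns to model, in (threshold, discrimination, identification) order.
    """

    def __init__(
        self,
        m: int = 3,
        columns: tuple[str, str, str] = ("thr_c", "disc_c", "ident_c"),
        pde_quantile: float = DEFAULT_PARETO_QUANTILE,
        n_grid: int = 200,
        refine: bool = True,
        random_state: int | None = 0,
    ):
        self.m = m
        self.columns = columns
        self.pde_quantile = pde_quantile
        self.n_grid = n_grid
        self.refine = refine
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "MixtureFeaturizer":
        self.models_ = {}
        for key, col in zip(("thr", "disc", "ident"), self.columns):
            self.models_[key] = fit_gmm(
                X[col].to_numpy(dtype=float),
                m=self.m,
                subtest=key,
                random_state=self.random_state,
                refine=self.refine,
                pde_quantile=self.pde_quantile,
                n_grid=self.n_grid,
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "models_")
        mapping = dict(zip(("thr", "disc", "ident"), self.columns))
        return build_feature_matrix(X, self.models_, columns=mapping)

    def save_models(self, path) -> None:
        check_is_fitted(self, "models_")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({k: m.to_dict() for k, m in self.models_.items()}, fh, indent=2)

    @staticmethod
    def load_models(path) -> dict[str, GMModel]:
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return {k: GMModel.from_dict(v) for k, v in raw.items()}
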