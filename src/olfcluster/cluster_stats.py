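"""Cluster extraction from the U*-landscape and association statistics.

Clusters are read off the U*-matrix as low "valleys" separated by high
watershed ridges.  The extraction here is a reproducible surrogate for the
visual reading of the landscape: units at or below a configurable quantile
of the U*-heights are valley units, valleys are toroidally 8-connected
components, tiny basins are merged into their nearest large neighbor in
weight space, and subjects inherit the cluster of their best matching unit
(BMU); subjects whose BMU sits on a ridge are attached to the nearest
valley component by weight-space distance.

Association of clusters with etiology uses the chi-square test on the
etiology x cluster contingency table, the bounded relative difference

    relDiff = (n_expected - n_observed) / (0.5 * (n_expected + n_observed))

as an overrepresentation metric (range [-2, 2]), and Spearman rank
correlations between the subtest pairs, globally and per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RIDGE = 0  # unit label for non-valley units

SUBTEST_PAIRS = (
    ("disc", "ident"),
    ("disc", "thr"),
    ("thr", "ident"),
)


# ---------------------------------------------------------------------------
# Watershed-proxy cluster extraction
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Per-unit and per-subject cluster labels.

    ``unit_labels`` is (rows, cols) with 0 marking ridge units and 1..k the
    valley components, ids ordered by descending subject count.
    ``subject_labels`` holds each subject's inherited cluster id.
    """

    unit_labels: np.ndarray
    subject_labels: np.ndarray
    k: int
    threshold_quantile: float
    sizes: dict[int, int] = field(default_factory=dict)


def _toroidal_components(mask: np.ndarray) -> np.ndarray:
    """Label 8-connected components of ``mask`` on a torus (0 = background)."""
    rows, cols = mask.shape
    labels = np.zeros((rows, cols), dtype=int)
    current = 0
    shifts = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    for r0 in range(rows):
        for c0 in range(cols):
            if not mask[r0, c0] or labels[r0, c0]:
                continue
            current += 1
            stack = [(r0, c0)]
            labels[r0, c0] = current
            while stack:
                r, c = stack.pop()
                for dr, dc in shifts:
                    nr, nc = (r + dr) % rows, (c + dc) % cols
                    if mask[nr, nc] and not labels[nr, nc]:
                        labels[nr, nc] = current
                        stack.append((nr, nc))
    return labels


def cluster_landscape(
    ustar: np.ndarray,
    bmus: np.ndarray,
    weights: np.ndarray,
    threshold_quantile: float = 0.5,
    min_basin_units: int = 5,
) -> ClusterAssignment:
    """Extract clusters from a U*-landscape.

    Parameters
    ----------
    ustar : (rows, cols) height field.
    bmus : (n, 2) per-subject BMU coordinates.
    weights : (rows, cols, D) trained unit weights, used to merge small
        basins and to attach ridge-resident BMUs to the nearest valley.
    threshold_quantile : fraction of units classified as valley (heights at
        or below this quantile of the U*-values).
    min_basin_units : basins with fewer units are merged into the large
        component with the nearest mean weight.
    """
    ustar = np.asarray(ustar, dtype=float)
    weights = np.asarray(weights, dtype=float)
    bmus = np.asarray(bmus, dtype=int)
    if ustar.shape != weights.shape[:2]:
        raise ValueError("ustar and weights grids disagree in shape")

    threshold = np.quantile(ustar, threshold_quantile)
    valley = ustar <= threshold
    if valley.all():
        logger.warning("threshold quantile %.3g marks every unit as valley; single cluster", threshold_quantile)
    labels = _toroidal_components(valley)

    comp_ids = [cid for cid in np.unique(labels) if cid != 0]
    sizes = {cid: int((labels == cid).sum()) for cid in comp_ids}
    big = [cid for cid in comp_ids if sizes[cid] >= min_basin_units]
    if not big:  # nothing exceeds the floor: keep all basins
        big = comp_ids
    means = {cid: weights[labels == cid].mean(axis=0) for cid in comp_ids}
    remap = {}
    for cid in comp_ids:
        if cid in big:
            remap[cid] = cid
        else:
            target = min(big, key=lambda b: float(np.linalg.norm(means[cid] - means[b])))
            remap[cid] = target
    merged = np.zeros_like(labels)
    for cid in comp_ids:
        merged[labels == cid] = remap[cid]

    # subjects inherit their BMU's component; ridge BMUs attach to the
    # component of the nearest valley unit in weight space
    subj = np.empty(len(bmus), dtype=int)
    valley_idx = np.argwhere(merged > 0)
    valley_w = weights[valley_idx[:, 0], valley_idx[:, 1]]
    valley_lab = merged[valley_idx[:, 0], valley_idx[:, 1]]
    for i, (r, c) in enumerate(bmus):
        lab = merged[r, c]
        if lab == 0:
            w = weights[r, c]
            nearest = int(np.argmin(((valley_w - w) ** 2).sum(axis=1)))
            lab = int(valley_lab[nearest])
        subj[i] = lab

    # relabel 1..k by descending subject count (ties: unit count, then id)
    observed = np.unique(subj)
    counts = {cid: int((subj == cid).sum()) for cid in observed}
    order = sorted(observed, key=lambda cid: (-counts[cid], -int((merged == cid).sum()), cid))
    final_map = {cid: rank + 1 for rank, cid in enumerate(order)}

    unit_labels = np.zeros_like(merged)
    for cid in np.unique(merged):
        if cid == 0:
            continue
        unit_labels[merged == cid] = final_map.get(cid, 0)
    subject_labels = np.array([final_map[c] for c in subj], dtype=int)
    k = len(order)
    return ClusterAssignment(
        unit_labels=unit_labels,
        subject_labels=subject_labels,
        k=k,
        threshold_quantile=threshold_quantile,
        sizes={final_map[c]: counts[c] for c in observed},
    )


# ---------------------------------------------------------------------------
# Contingency table, chi-square, relDiff
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """Etiology x cluster cross-tabulation with margins and expected counts."""

    observed: pd.DataFrame  # rows: etiologies, cols: cluster ids

    @property
    def row_totals(self) -> pd.Series:
        return self.observed.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.observed.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.observed.to_numpy().sum())

    @property
    def expected(self) -> pd.DataFrame:
        r = self.row_totals.to_numpy(dtype=float)
        c = self.col_totals.to_numpy(dtype=float)
        exp = np.outer(r, c) / self.grand_total
        return pd.DataFrame(exp, index=self.observed.index, columns=self.observed.columns)


def contingency(
    frame: pd.DataFrame,
    clusters: np.ndarray | pd.Series,
    exclude: list[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate etiology against cluster id.

    ``exclude`` drops the named etiology rows (e.g. ``["Healthy"]``) before
    margins are computed.
    """
    etio = frame["etiology"].reset_index(drop=True)
    clus = pd.Series(np.asarray(clusters), name="cluster")
    if len(etio) != len(clus):
        raise ValueError("etiology and cluster vectors differ in length")
    table = pd.crosstab(etio, clus)
    if exclude:
        table = table.drop(index=[e for e in exclude if e in table.index])
    if table.empty or table.to_numpy().sum() == 0:
        raise ValueError("contingency table is empty after exclusion")
    return ContingencyTable(observed=table)


@dataclass
class AssociationResult:
    chi2: float
    df: int
    p: float
    reldiff: pd.DataFrame

    def p_text(self, floor: float = 2.2e-16) -> str:
        """R-style p-value string, floored near machine underflow."""
        return f"< {floor:g}" if self.p < floor else f"{self.p:.4g}"


def chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on the contingency table.

    Returns ``(chi2, df, p)`` with ``chi2 = sum (obs - exp)^2 / exp`` (no
    continuity correction) and ``df = (rows - 1)(cols - 1)``.
    """
    obs = table.observed.to_numpy(dtype=float)
    if np.any(table.expected.to_numpy() <= 0):
        raise ValueError(
            "zero expected cell count; merge sparse rows or columns before testing"
        )
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def rel_diff(table: ContingencyTable, sign_convention: str = "exp_minus_obs") -> pd.DataFrame:
    """Bounded overrepresentation metric per contingency cell.

    ``sign_convention="exp_minus_obs"`` (default) uses (expected - observed) in the numerator,
    so overrepresented cells are negative; ``"obs_minus_exp"`` flips the
    sign so overrepresented cells are positive.  Cells with
    expected + observed = 0 are set to 0 with a logged note.  Values always
    lie in [-2, 2].
    """
    if sign_convention not in ("exp_minus_obs", "obs_minus_exp"):
        raise ValueError(f"unknown sign_convention {sign_convention!r}")
    obs = table.observed.to_numpy(dtype=float)
    exp = table.expected.to_numpy(dtype=float)
    denom = 0.5 * (exp + obs)
    out = np.zeros_like(obs)
    ok = denom > 0
    if not ok.all():
        logger.warning("relDiff: %d empty cells set to 0", int((~ok).sum()))
    out[ok] = (exp[ok] - obs[ok]) / denom[ok]
    if sign_convention == "obs_minus_exp":
        out = -out
    return pd.DataFrame(out, index=table.observed.index, columns=table.observed.columns)


def associate(
    frame: pd.DataFrame,
    clusters: np.ndarray | pd.Series,
    exclude: list[str] | None = None,
    sign_convention: str = "exp_minus_obs",
) -> AssociationResult:
    """Contingency + chi-square + relDiff in one call."""
    table = contingency(frame, clusters, exclude=exclude)
    chi2, df, p = chi_square(table)
    return AssociationResult(chi2=chi2, df=df, p=p, reldiff=rel_diff(table, sign_convention))


# ---------------------------------------------------------------------------
# Spearman correlations per group
# ---------------------------------------------------------------------------

def spearman_by_group(
    frame: pd.DataFrame,
    grouping: str | None = None,
    columns: dict[str, str] | None = None,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Spearman rank correlations between subtest pairs.

    Computes rho (average ranks on ties) for discrimination/identification,
    discrimination/threshold and threshold/identification — globally and,
    if ``grouping`` names a column (e.g. "etiology" or "cluster"), per
    group.  Groups smaller than ``min_group_size`` are omitted with a
    logged warning.  Returns a tidy frame (group, pair, rho, p, n).
    """
    if columns is None:
        columns = {"thr": "thr", "disc": "disc", "ident": "ident"}
    rows = []

    def _add(group_name: str, sub: pd.DataFrame) -> None:
        for a, b in SUBTEST_PAIRS:
            xa = sub[columns[a]].to_numpy(dtype=float)
            xb = sub[columns[b]].to_numpy(dtype=float)
            rho, p = stats.spearmanr(xa, xb)
            rows.append(
                {"group": group_name, "pair": f"{a}/{b}", "rho": float(rho), "p": float(p), "n": len(sub)}
            )

    _add("all", frame)
    if grouping is not None:
        for name, sub in frame.groupby(grouping, sort=True):
            if len(sub) < min_group_size:
                logger.warning("group %r has %d subjects (< %d); omitted", name, len(sub), min_group_size)
                continue
            _add(str(name), sub)
    return pd.DataFrame(rows)
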