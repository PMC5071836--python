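"""Sex-specific linear age correction and TDI-based olfactory diagnosis.

Olfactory performance declines roughly linearly with age, and the decline
can differ between the sexes.  Before mixture modelling, the three subtest
scores are therefore corrected by regressing each score on age separately
within each sex and replacing the score by its residual plus the overall
(both-sex) subtest mean, which keeps corrected scores on the familiar
clinical scale.

The TDI score (threshold + discrimination + identification) classifies
subjects into anosmia / hyposmia / normosmia via two cutoffs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

SUBTESTS = ("thr", "disc", "ident")
SCORE_RANGES = {"thr": (1.0, 16.0), "disc": (0.0, 16.0), "ident": (0.0, 16.0)}

#: Established Sniffin'-Sticks TDI cutoffs: <= low -> anosmia, >= high -> normosmia.
DEFAULT_TDI_CUTOFFS = (16.5, 30.5)


class AgeSexCorrector(TransformerMixin, BaseEstimator):
    """Linear age correction of subtest scores, fitted per sex.

    For every sex stratum and subtest an ordinary least-squares line
    ``score ~ age`` is fitted; the corrected score is the residual plus the
    overall (both-sex) mean of that subtest.  A stratum with fewer than two
    subjects or a constant age degenerates to mean-centering (slope 0) with
    a logged warning.

    Parameters
    ----------
    columns : tuple of str
        Input score columns, in (threshold, discrimination, identification)
        order.
    suffix : str
        Suffix appended to each input column name for the corrected output.

    Attributes
    ----------
    slopes_, intercepts_ : dict
        ``(sex, column) -> float`` fit coefficients.
    grand_means_ : dict
        ``column -> float`` overall recentering constants.
    """

    def __init__(self, columns: tuple[str, ...] = SUBTESTS, suffix: str = "_c"):
        self.columns = columns
        self.suffix = suffix

    def fit(self, X: pd.DataFrame, y=None) -> "AgeSexCorrector":
        X = self._validate_frame(X)
        self.slopes_ = {}
        self.intercepts_ = {}
        self.grand_means_ = {col: float(X[col].mean()) for col in self.columns}
        for sex, sub in X.groupby("sex", sort=True):
            age = sub["age"].to_numpy(dtype=float)
            degenerate = len(sub) < 2 or np.ptp(age) == 0
            if degenerate:
                logger.warning(
                    "age correction for sex=%s degenerates to mean-centering "
                    "(%d subjects, age spread %.3g)",
                    sex,
                    len(sub),
                    np.ptp(age) if len(age) else 0.0,
                )
            for col in self.columns:
                score = sub[col].to_numpy(dtype=float)
                if degenerate:
                    slope, intercept = 0.0, float(score.mean())
                else:
                    # closed-form simple OLS: deterministic, no LAPACK
                    am, sm = age.mean(), score.mean()
                    slope = float(((age - am) * (score - sm)).sum() / ((age - am) ** 2).sum())
                    intercept = float(sm - slope * am)
                self.slopes_[(sex, col)] = float(slope)
                self.intercepts_[(sex, col)] = float(intercept)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "slopes_")
        X = self._validate_frame(X)
        out = X.copy()
        for col in self.columns:
            corrected = np.empty(len(X), dtype=float)
            for sex in X["sex"].unique():
                mask = (X["sex"] == sex).to_numpy()
                key = (sex, col)
                if key not in self.slopes_:
                    raise ValueError(f"sex stratum {sex!r} was not seen during fit")
                pred = self.intercepts_[key] + self.slopes_[key] * X.loc[mask, "age"].to_numpy(dtype=float)
                corrected[mask] = X.loc[mask, col].to_numpy(dtype=float) - pred + self.grand_means_[col]
            # 1e-10 snap absorbs round-off so reruns serialize identically
            out[col + self.suffix] = np.round(corrected, 10)
        return out

    def _validate_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("AgeSexCorrector expects a pandas DataFrame")
        missing = [c for c in ("sex", "age", *self.columns) if c not in X.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        return X


def age_sex_correct(frame: pd.DataFrame, columns: tuple[str, ...] = SUBTESTS, suffix: str = "_c") -> tuple[pd.DataFrame, AgeSexCorrector]:
    """Fit-and-apply convenience wrapper around :class:`AgeSexCorrector`."""
    corrector = AgeSexCorrector(columns=columns, suffix=suffix)
    return corrector.fit(frame).transform(frame), corrector


@dataclass(frozen=True)
class Diagnosis:
    """TDI sum and the categorical olfactory diagnosis derived from it."""

    tdi: float
    label: str  # anosmia | hyposmia | normosmia


def classify_tdi(
    thr: float,
    disc: float,
    ident: float,
    cutoffs: tuple[float, float] = DEFAULT_TDI_CUTOFFS,
) -> Diagnosis:
    """Classify a subject by the TDI sum of the three subtest scores.

    ``tdi <= cutoffs[0]`` -> anosmia, ``tdi >= cutoffs[1]`` -> normosmia,
    otherwise hyposmia.  Scores must lie in their legal raw ranges.
    """
    for name, val in (("thr", thr), ("disc", disc), ("ident", ident)):
        lo, hi = SCORE_RANGES[name]
        if not np.isfinite(val) or not (lo <= val <= hi):
            raise ValueError(f"{name}={val} outside legal range [{lo}, {hi}]")
    low, high = cutoffs
    if not low < high:
        raise ValueError("cutoffs must satisfy low < high")
    tdi = float(thr + disc + ident)
    if tdi <= low:
        label = "anosmia"
    elif tdi >= high:
        label = "normosmia"
    else:
        label = "hyposmia"
    return Diagnosis(tdi=tdi, label=label)


def diagnose_frame(frame: pd.DataFrame, cutoffs: tuple[float, float] = DEFAULT_TDI_CUTOFFS) -> pd.DataFrame:
    """Append ``tdi`` and ``diagnosis`` columns computed from raw scores."""
    out = frame.copy()
    tdi = frame["thr"].astype(float) + frame["disc"].astype(float) + frame["ident"].astype(float)
    out["tdi"] = tdi
    out["diagnosis"] = np.select(
        [tdi <= cutoffs[0], tdi >= cutoffs[1]], ["anosmia", "normosmia"], default="hyposmia"
    )
    return out
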