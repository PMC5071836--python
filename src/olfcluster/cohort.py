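"""Synthetic olfactory-test cohort generator.

Generates cohorts that mimic the demographic and etiologic structure of a
large clinical smell-and-taste database: nine etiology groups, a roughly
56:44 male:female ratio, ages 6-95 years, and three "Sniffin' Sticks"
subtest scores per subject (odor threshold on a 1-16 dilution-step scale at
quarter-step resolution, discrimination and identification as integer
0-16 counts).

Each subject is drawn from one of three latent olfactory profiles —
``good`` (low threshold, i.e. high dilution step, good discrimination and
identification), ``abolished`` (threshold at the first dilution step,
absent-to-poor discrimination/identification), and ``reduced`` (medium
threshold, reduced but preserved discrimination/identification).  The
profile is recorded per subject so downstream clustering can be scored
against the planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

ETIOLOGIES = (
    "Healthy",
    "Sinunasal disease",
    "Congenital",
    "Neurodegenerative",
    "Idiopathic",
    "Infectious",
    "Head trauma",
    "Toxic",
    "Tumor/apoplectic",
)

#: Demographic reference table: etiology -> (men, women) counts.
DEMOGRAPHICS_COUNTS = {
    "Healthy": (928, 1171),
    "Sinunasal disease": (852, 785),
    "Congenital": (79, 124),
    "Neurodegenerative": (91, 67),
    "Idiopathic": (928, 1021),
    "Infectious": (961, 2092),
    "Head trauma": (801, 690),
    "Toxic": (52, 38),
    "Tumor/apoplectic": (18, 16),
}

PROFILE_NAMES = ("good", "abolished", "reduced")

THR_RANGE = (1.0, 16.0)
DISC_RANGE = (0, 16)
IDENT_RANGE = (0, 16)
AGE_LIMITS = (6.0, 95.0)


@dataclass(frozen=True)
class LatentProfile:
    """One latent olfactory performance profile.

    Centers and spreads of the truncated-normal score model, in raw score
    units (threshold in dilution steps, discrimination/identification in
    points).
    """

    name: str
    thr_center: float
    thr_sd: float
    disc_center: float
    disc_sd: float
    ident_center: float
    ident_sd: float

    def __post_init__(self) -> None:
        if self.name not in PROFILE_NAMES:
            raise ValueError(f"unknown profile name {self.name!r}")
        if not (THR_RANGE[0] <= self.thr_center <= THR_RANGE[1]):
            raise ValueError(f"thr_center {self.thr_center} outside {THR_RANGE}")
        for val, rng, key in (
            (self.disc_center, DISC_RANGE, "disc_center"),
            (self.ident_center, IDENT_RANGE, "ident_center"),
        ):
            if not (rng[0] <= val <= rng[1]):
                raise ValueError(f"{key} {val} outside {rng}")
        for sd, key in (
            (self.thr_sd, "thr_sd"),
            (self.disc_sd, "disc_sd"),
            (self.ident_sd, "ident_sd"),
        ):
            if sd <= 0:
                raise ValueError(f"{key} must be > 0")


# Threshold centers follow the reported cluster medians (dilution steps
# 13.5 / 1 / 5); discrimination/identification centers are plausible for
# "good", "absent to poor" and "reduced but preserved" performance.
DEFAULT_PROFILES = {
    "good": LatentProfile("good", 13.5, 1.5, 14.0, 1.5, 14.0, 1.5),
    "abolished": LatentProfile("abolished", 1.0, 0.75, 3.0, 1.8, 3.0, 1.8),
    "reduced": LatentProfile("reduced", 5.0, 1.5, 9.0, 1.8, 9.0, 1.8),
}


def _default_profile_map() -> dict[str, dict[str, float]]:
    # Healthy subjects mostly smell well; congenital anosmics almost surely
    # lack olfaction; postinfectious dysfunction is typically partial.
    return {
        "Healthy": {"good": 0.90, "abolished": 0.02, "reduced": 0.08},
        "Sinunasal disease": {"good": 0.15, "abolished": 0.25, "reduced": 0.60},
        "Congenital": {"good": 0.01, "abolished": 0.95, "reduced": 0.04},
        "Neurodegenerative": {"good": 0.10, "abolished": 0.40, "reduced": 0.50},
        "Idiopathic": {"good": 0.10, "abolished": 0.40, "reduced": 0.50},
        "Infectious": {"good": 0.10, "abolished": 0.20, "reduced": 0.70},
        "Head trauma": {"good": 0.08, "abolished": 0.52, "reduced": 0.40},
        "Toxic": {"good": 0.10, "abolished": 0.40, "reduced": 0.50},
        "Tumor/apoplectic": {"good": 0.10, "abolished": 0.40, "reduced": 0.50},
    }


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort generator."""

    n_subjects: int
    etiology_weights: dict[str, float]
    profile_map: dict[str, dict[str, float]]
    age_range: tuple[float, float] = AGE_LIMITS
    sex_ratio: float = 6004 / 10714  # probability of male
    age_slope_per_subtest: float = -0.05  # score units per year
    age_mean: float = 52.2
    age_sd: float = 17.0
    profiles: dict[str, LatentProfile] = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be a positive count")
        w = np.array([self.etiology_weights.get(e, 0.0) for e in ETIOLOGIES])
        unknown = set(self.etiology_weights) - set(ETIOLOGIES)
        if unknown:
            raise ValueError(f"etiology_weights: unknown etiologies {sorted(unknown)}")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("etiology_weights: probabilities must be >= 0 and sum to 1")
        for etiology, row in self.profile_map.items():
            if etiology not in ETIOLOGIES:
                raise ValueError(f"profile_map: unknown etiology {etiology!r}")
            p = np.array([row.get(name, 0.0) for name in PROFILE_NAMES])
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"profile_map[{etiology!r}]: probabilities must be >= 0 and sum to 1"
                )
        for e in ETIOLOGIES:
            if self.etiology_weights.get(e, 0.0) > 0 and e not in self.profile_map:
                raise ValueError(f"profile_map: missing row for etiology {e!r}")
        lo, hi = self.age_range
        if not (AGE_LIMITS[0] <= lo < hi <= AGE_LIMITS[1]):
            raise ValueError(f"age_range must lie within {AGE_LIMITS} with min < max")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be a probability")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: demographics, etiology and the three raw subtest scores."""

    subject_id: str
    sex: str  # "M" or "F"
    age: float
    etiology: str
    thr: float  # dilution-step score in [1, 16], quarter-step grid
    disc: int  # 0..16
    ident: int  # 0..16
    latent_profile: str | None = None  # synthetic cohorts only


def default_config(n_subjects: int = 10_714, seed: int = 0) -> CohortConfig:
    """Default cohort configuration.

    Etiology weights are proportional to the demographic reference table
    (e.g. Healthy (928+1171)/10,714 ~ 0.196); latent-profile mixtures follow
    :func:`_default_profile_map`.
    """
    totals = {e: sum(DEMOGRAPHICS_COUNTS[e]) for e in ETIOLOGIES}
    grand = sum(totals.values())
    weights = {e: totals[e] / grand for e in ETIOLOGIES}
    cfg = CohortConfig(
        n_subjects=n_subjects,
        etiology_weights=weights,
        profile_map=_default_profile_map(),
        seed=seed,
    )
    cfg.validate()
    return cfg


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray, sd: float, low: float, high: float) -> np.ndarray:
    a = (low - mean) / sd
    b = (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw a synthetic cohort.

    Scores are drawn from the subject's latent profile as truncated normals,
    shifted by ``age_slope_per_subtest * (age - age-range midpoint)``, then
    clipped and rounded to the legal score grid (threshold: quarter steps in
    [1, 16]; discrimination/identification: integers in [0, 16]).  The same
    seed always yields an identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    weights = np.array([config.etiology_weights.get(e, 0.0) for e in ETIOLOGIES])
    weights = weights / weights.sum()
    etiology_idx = rng.choice(len(ETIOLOGIES), size=n, p=weights)
    sex = np.where(rng.random(n) < config.sex_ratio, "M", "F")

    lo, hi = config.age_range
    age = _truncated_normal(rng, np.full(n, config.age_mean), config.age_sd, lo, hi)
    age = np.round(age, 1)

    # profile per subject from the per-etiology mixture
    profile_probs = np.zeros((len(ETIOLOGIES), len(PROFILE_NAMES)))
    for i, e in enumerate(ETIOLOGIES):
        row = config.profile_map.get(e, {})
        profile_probs[i] = [row.get(name, 0.0) for name in PROFILE_NAMES]
        s = profile_probs[i].sum()
        if s > 0:
            profile_probs[i] /= s
        else:
            profile_probs[i] = 1.0 / len(PROFILE_NAMES)
    u = rng.random(n)
    cum = np.cumsum(profile_probs[etiology_idx], axis=1)
    profile_idx = (u[:, None] > cum).sum(axis=1)

    midpoint = 0.5 * (lo + hi)
    shift = config.age_slope_per_subtest * (age - midpoint)

    thr = np.empty(n)
    disc = np.empty(n)
    ident = np.empty(n)
    for j, name in enumerate(PROFILE_NAMES):
        mask = profile_idx == j
        if not np.any(mask):
            continue
        prof = config.profiles[name]
        thr[mask] = _truncated_normal(
            rng, prof.thr_center + shift[mask], prof.thr_sd, *THR_RANGE
        )
        disc[mask] = _truncated_normal(
            rng, prof.disc_center + shift[mask], prof.disc_sd, DISC_RANGE[0], DISC_RANGE[1]
        )
        ident[mask] = _truncated_normal(
            rng, prof.ident_center + shift[mask], prof.ident_sd, IDENT_RANGE[0], IDENT_RANGE[1]
        )

    thr = np.clip(np.round(thr * 4) / 4, *THR_RANGE)
    disc = np.clip(np.round(disc), *DISC_RANGE).astype(int)
    ident = np.clip(np.round(ident), *IDENT_RANGE).astype(int)

    width = max(5, len(str(n)))
    return [
        SubjectRecord(
            subject_id=f"S{i:0{width}d}",
            sex=str(sex[i]),
            age=float(age[i]),
            etiology=ETIOLOGIES[etiology_idx[i]],
            thr=float(thr[i]),
            disc=int(disc[i]),
            ident=int(ident[i]),
            latent_profile=PROFILE_NAMES[profile_idx[i]],
        )
        for i in range(n)
    ]


def scaled_config(n_subjects: int, seed: int = 0) -> CohortConfig:
    """Default configuration at a reduced cohort size (test profile)."""
    return replace(default_config(seed=seed), n_subjects=n_subjects)
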