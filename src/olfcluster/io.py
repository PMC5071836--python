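"""Cohort CSV reading/writing with validation.

Schema: ``subject_id,sex,age,etiology,thr,disc,ident`` with an optional
trailing ``latent_profile`` column (synthetic cohorts only).  Decimal
point, UTF-8; CRLF and LF files parse identically.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from olfcluster.cohort import ETIOLOGIES, PROFILE_NAMES, SubjectRecord

COHORT_COLUMNS = ("subject_id", "sex", "age", "etiology", "thr", "disc", "ident")


class CohortFormatError(ValueError):
    """Malformed cohort file; the message lists offending line numbers."""


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tabulate subject records; keeps latent_profile if any record has one."""
    frame = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "sex": [r.sex for r in records],
            "age": [r.age for r in records],
            "etiology": [r.etiology for r in records],
            "thr": [r.thr for r in records],
            "disc": [r.disc for r in records],
            "ident": [r.ident for r in records],
        }
    )
    if any(r.latent_profile is not None for r in records):
        frame["latent_profile"] = [r.latent_profile for r in records]
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[SubjectRecord]:
    has_profile = "latent_profile" in frame.columns
    return [
        SubjectRecord(
            subject_id=str(row.subject_id),
            sex=str(row.sex),
            age=float(row.age),
            etiology=str(row.etiology),
            thr=float(row.thr),
            disc=int(row.disc),
            ident=int(row.ident),
            latent_profile=str(row.latent_profile) if has_profile else None,
        )
        for row in frame.itertuples(index=False)
    ]


def _validate_row(parsed: dict, line_no: int, errors: list[str]) -> None:
    sex = parsed["sex"]
    if sex not in ("M", "F"):
        errors.append(f"line {line_no}: sex {sex!r} not in {{M, F}}")
    if parsed["etiology"] not in ETIOLOGIES:
        errors.append(f"line {line_no}: unknown etiology {parsed['etiology']!r}")
    try:
        thr = float(parsed["thr"])
        if not 1.0 <= thr <= 16.0:
            errors.append(f"line {line_no}: thr {thr} outside [1, 16]")
        elif round(thr * 4) != thr * 4:
            errors.append(f"line {line_no}: thr {thr} not on the 0.25 grid")
    except ValueError:
        errors.append(f"line {line_no}: thr {parsed['thr']!r} not numeric")
    for key in ("disc", "ident"):
        try:
            val = float(parsed[key])
            if val != int(val) or not 0 <= val <= 16:
                errors.append(f"line {line_no}: {key} {parsed[key]!r} not an integer in [0, 16]")
        except ValueError:
            errors.append(f"line {line_no}: {key} {parsed[key]!r} not numeric")
    try:
        float(parsed["age"])
    except ValueError:
        errors.append(f"line {line_no}: age {parsed['age']!r} not numeric")
    profile = parsed.get("latent_profile")
    if profile not in (None, "") and profile not in PROFILE_NAMES:
        errors.append(f"line {line_no}: unknown latent_profile {profile!r}")


def read_cohort(path) -> list[SubjectRecord]:
    """Read and validate a cohort CSV; raises listing every bad line."""
    path = Path(path)
    records: list[SubjectRecord] = []
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c for c in COHORT_COLUMNS if c not in reader.fieldnames]:
            raise CohortFormatError(
                f"{path}: header must contain columns {','.join(COHORT_COLUMNS)}"
            )
        for line_no, row in enumerate(reader, start=2):
            if any(row.get(c) in (None, "") for c in COHORT_COLUMNS):
                errors.append(f"line {line_no}: missing field(s)")
                continue
            _validate_row(row, line_no, errors)
            if errors and errors[-1].startswith(f"line {line_no}:"):
                continue
            records.append(
                SubjectRecord(
                    subject_id=row["subject_id"],
                    sex=row["sex"],
                    age=float(row["age"]),
                    etiology=row["etiology"],
                    thr=float(row["thr"]),
                    disc=int(float(row["disc"])),
                    ident=int(float(row["ident"])),
                    latent_profile=row.get("latent_profile") or None,
                )
            )
    if errors:
        raise CohortFormatError(f"{path}: " + "; ".join(errors))
    return records


def write_cohort(path, records: list[SubjectRecord]) -> None:
    """Write records as CSV (UTF-8, LF, decimal point)."""
    frame = records_to_frame(records)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, lineterminator="\n")


def read_cohort_frame(path) -> pd.DataFrame:
    """Validated cohort as a DataFrame (validation via :func:`read_cohort`)."""
    return records_to_frame(read_cohort(path))
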