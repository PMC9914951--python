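"""Cohort CSV reading/writing, survey-style recoding and the train/test split.

The cohort schema has one row per past-30-day drinker:

    age_band (or age_years), gender, usual_drinks, drinking_days,
    last_occasion_drinks [, days_5plus, days_4plus]

Reading applies the survey recodes: usual drinks above 24 are recoded down
to 24 and last-occasion counts above 20 down to 20 (such rows are flagged
censored), with per-column recode counts reported. Non-drinker rows
(drinking_days = 0 or last_occasion_drinks = 0) are excluded, and rows that
fail validation are rejected with their line numbers — never silently
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import floor
from typing import Sequence

import numpy as np
import pandas as pd

from .covariates import DrinkerProfile
from .estimation import ObservationRecord

__all__ = [
    "CohortReadResult",
    "read_cohort_csv",
    "write_cohort_csv",
    "records_to_frame",
    "frame_to_records",
    "split_train_test",
]

logger = logging.getLogger(__name__)

USUAL_DRINKS_BOUND = 24
LAST_OCCASION_BOUND = 20

REQUIRED_COLUMNS = ("gender", "usual_drinks", "drinking_days", "last_occasion_drinks")


@dataclass
class CohortReadResult:
    """Validated records plus an account of every recode and exclusion."""

    records: list[ObservationRecord]
    recode_counts: dict = field(default_factory=dict)
    n_excluded_nondrinkers: int = 0
    rejected_rows: list = field(default_factory=list)  # (line number, reason)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _opt_int(value):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return int(value)


def read_cohort_csv(path) -> CohortReadResult:
    """Read, validate and recode a cohort CSV.

    Returns the validated records together with recode counts, the number of
    excluded non-drinker rows and any rejected rows with line numbers.
    Raises a schema error if a required column is missing.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required column(s): {missing}")
    if "age_band" not in df.columns and "age_years" not in df.columns:
        raise ValueError("cohort CSV must contain an 'age_band' or 'age_years' column")

    result = CohortReadResult(records=[])
    n_recode_k = 0
    n_recode_y = 0
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        try:
            m = int(getattr(row, "drinking_days"))
            y = int(getattr(row, "last_occasion_drinks"))
            if m == 0 or y == 0:
                result.n_excluded_nondrinkers += 1
                continue
            k = int(getattr(row, "usual_drinks"))
            if k > USUAL_DRINKS_BOUND:
                k = USUAL_DRINKS_BOUND
                n_recode_k += 1
            if y > LAST_OCCASION_BOUND:
                y = LAST_OCCASION_BOUND
                n_recode_y += 1
            age = getattr(row, "age_band", None)
            if age is None or (isinstance(age, float) and np.isnan(age)):
                age = int(getattr(row, "age_years"))
            profile = DrinkerProfile(
                age_band=age,
                gender=getattr(row, "gender"),
                usual_drinks=k,
                drinking_days=m,
            )
            record = ObservationRecord(
                profile=profile,
                y_last=y,
                censored=(y == LAST_OCCASION_BOUND),
                days5=_opt_int(getattr(row, "days_5plus", None)),
                days4=_opt_int(getattr(row, "days_4plus", None)),
            )
        except (ValueError, TypeError) as err:
            result.rejected_rows.append((line, str(err)))
            continue
        result.records.append(record)

    result.recode_counts = {
        "usual_drinks_capped": n_recode_k,
        "last_occasion_capped": n_recode_y,
    }
    if n_recode_k or n_recode_y:
        logger.info(
            "recoded %d usual_drinks values down to %d and %d last_occasion values down to %d",
            n_recode_k, USUAL_DRINKS_BOUND, n_recode_y, LAST_OCCASION_BOUND,
        )
    if result.n_excluded_nondrinkers:
        logger.info("excluded %d non-drinker rows", result.n_excluded_nondrinkers)
    for line, reason in result.rejected_rows:
        logger.warning("rejected row at line %d: %s", line, reason)
    return result


def records_to_frame(records: Sequence[ObservationRecord]) -> pd.DataFrame:
    rows = [
        {
            "age_band": rec.profile.age_band,
            "gender": rec.profile.gender,
            "usual_drinks": rec.profile.usual_drinks,
            "drinking_days": rec.profile.drinking_days,
            "last_occasion_drinks": rec.y_last,
            "days_5plus": rec.days5,
            "days_4plus": rec.days4,
        }
        for rec in records
    ]
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[ObservationRecord]:
    records = []
    for row in df.itertuples(index=False):
        profile = DrinkerProfile(
            age_band=getattr(row, "age_band"),
            gender=getattr(row, "gender"),
            usual_drinks=int(getattr(row, "usual_drinks")),
            drinking_days=int(getattr(row, "drinking_days")),
        )
        records.append(
            ObservationRecord(
                profile=profile,
                y_last=int(getattr(row, "last_occasion_drinks")),
                censored=(int(getattr(row, "last_occasion_drinks")) == LAST_OCCASION_BOUND),
                days5=_opt_int(getattr(row, "days_5plus", None)),
                days4=_opt_int(getattr(row, "days_4plus", None)),
            )
        )
    return records


def write_cohort_csv(records: Sequence[ObservationRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def split_train_test(
    records: Sequence[ObservationRecord], fraction: float = 0.75, seed: int = 0
) -> tuple[list[ObservationRecord], list[ObservationRecord]]:
    """Seed-deterministic random partition into training and testing samples
    of sizes floor(n * fraction) and the remainder."""
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie strictly between 0 and 1, got {fraction!r}")
    records = list(records)
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = floor(n * fraction)
    perm = np.random.default_rng(seed).permutation(n)
    train = [records[i] for i in perm[:n_train]]
    test = [records[i] for i in perm[n_train:]]
    return train, test
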