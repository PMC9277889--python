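"""Sibling exposure variables derived from raw sibship records.

Every sibling-related covariate used downstream — status, number of older
siblings, age gap to the closest older sibling, categorical strata, sex of
the closest older sibling, and a scalar "sibling burden" — is derived here
from birth dates at an arbitrary reference date, so that exposure can be
evaluated longitudinally (a child can acquire younger siblings between
visits; the number of older siblings never changes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .io import years_between


class SiblingStatus(str, Enum):
    none = "none"
    older_only = "older_only"
    younger_only = "younger_only"
    both = "both"


@dataclass(frozen=True)
class Sibling:
    birth_date: date
    sex: str | None = None  # "male" / "female" / unknown


@dataclass(frozen=True)
class SibshipRecord:
    child_id: str
    child_birth_date: date
    siblings: tuple[Sibling, ...] = ()

    def __post_init__(self):
        for sib in self.siblings:
            if sib.birth_date == self.child_birth_date:
                raise ValueError(
                    f"{self.child_id}: sibling shares the child's birth date "
                    "(twins are excluded from sibship records)")


@dataclass(frozen=True)
class SiblingExposure:
    child_id: str
    status: SiblingStatus
    n_older: int
    n_younger: int
    gap_closest_older: float | None  # years; None when n_older == 0
    gap_category: str | None         # lt2 / from2to4 / gt4
    n_older_category: str | None     # one / two_plus
    sex_closest_older: str | None
    burden: float

    def as_dict(self) -> dict:
        return {
            "child_id": self.child_id,
            "status": self.status.value,
            "n_older": self.n_older,
            "n_younger": self.n_younger,
            "gap_closest_older": self.gap_closest_older,
            "gap_category": self.gap_category,
            "n_older_category": self.n_older_category,
            "sex_closest_older": self.sex_closest_older,
            "burden": self.burden,
        }


# Age-gap strata: lt2 = gap < 2.0; from2to4 = 2.0 <= gap <= 4.0; gt4 = gap > 4.0.
# The middle interval is closed on both ends, matching the label "2 to 4 years".
def gap_category(gap: float) -> str:
    if gap < 2.0:
        return "lt2"
    if gap <= 4.0:
        return "from2to4"
    return "gt4"


DEFAULT_BURDEN_TAU = 4.0


def sibling_burden(record: SibshipRecord, reference_date: date,
                   tau: float = DEFAULT_BURDEN_TAU) -> float:
    """Scalar burden from all older siblings: sum_i exp(-gap_i / tau).

    Increases with each additional older sibling and decreases with every
    age gap; ``tau`` (years) sets how quickly a distant sibling stops
    counting.  A single just-older sibling contributes ~1.
    """
    if tau <= 0:
        raise ValueError("kernel scale tau must be > 0")
    if reference_date < record.child_birth_date:
        raise ValueError("reference date before the child's birth")
    gaps = [years_between(s.birth_date, record.child_birth_date)
            for s in record.siblings if s.birth_date < record.child_birth_date]
    return float(sum(np.exp(-g / tau) for g in gaps))


def exposure_at(record: SibshipRecord, reference_date: date,
                tau: float = DEFAULT_BURDEN_TAU) -> SiblingExposure:
    """Evaluate every sibling exposure variable at ``reference_date``.

    Older = born before the index child (fixed over time); younger = born
    after the child and on/before the reference date (non-decreasing over
    time).  The closest older sibling is the latest-born older sibling;
    same-birth-date ties are broken by sex ordering then record order.
    """
    if reference_date < record.child_birth_date:
        raise ValueError(
            f"{record.child_id}: reference date {reference_date} before "
            f"birth {record.child_birth_date}")
    older = [s for s in record.siblings if s.birth_date < record.child_birth_date]
    younger = [s for s in record.siblings
               if record.child_birth_date < s.birth_date <= reference_date]

    if older and younger:
        status = SiblingStatus.both
    elif older:
        status = SiblingStatus.older_only
    elif younger:
        status = SiblingStatus.younger_only
    else:
        status = SiblingStatus.none

    gap = cat = ncat = sex = None
    burden = 0.0
    if older:
        latest = max(s.birth_date for s in older)
        closest = [s for s in older if s.birth_date == latest]
        if len(closest) > 1:
            warnings.warn(
                f"{record.child_id}: tie for closest older sibling; "
                "resolved by sex ordering then record order")
            closest = sorted(closest, key=lambda s: (s.sex or "zz",))
        gap = years_between(latest, record.child_birth_date)
        cat = gap_category(gap)
        ncat = "one" if len(older) == 1 else "two_plus"
        sex = closest[0].sex
        burden = sibling_burden(record, reference_date, tau=tau)

    return SiblingExposure(
        child_id=record.child_id, status=status,
        n_older=len(older), n_younger=len(younger),
        gap_closest_older=gap, gap_category=cat, n_older_category=ncat,
        sex_closest_older=sex, burden=burden)


def exposure_table(records, reference_dates) -> pd.DataFrame:
    """Exposures for every record at every reference date, long format."""
    rows = []
    for rec in records:
        for ref in reference_dates:
            d = exposure_at(rec, ref).as_dict()
            d["reference_date"] = ref
            rows.append(d)
    return pd.DataFrame(rows)


def records_from_table(df: pd.DataFrame) -> list[SibshipRecord]:
    """Build SibshipRecords from the long sibship TSV (one row per sibling)."""
    recs = []
    for child_id, grp in df.groupby("child_id", sort=True):
        birth = grp["child_birth_date"].iloc[0]
        sibs = tuple(
            Sibling(birth_date=r.sibling_birth_date, sex=r.sibling_sex)
            for r in grp.itertuples(index=False)
            if r.sibling_birth_date is not None)
        recs.append(SibshipRecord(str(child_id), birth, sibs))
    return recs


def gap_count_correlation(exposures) -> tuple[float, float]:
    """Spearman rank correlation of age gap vs number of older siblings.

    Restricted to children with at least one older sibling; ties handled by
    average ranks.  Returns ``(rho, p)``.
    """
    pairs = [(e.gap_closest_older, e.n_older) for e in exposures if e.n_older >= 1]
    if len(pairs) < 3:
        raise ValueError("need >= 3 children with older siblings")
    gaps, counts = map(np.asarray, zip(*pairs))
    if np.all(gaps == gaps[0]) or np.all(counts == counts[0]):
        raise ValueError("correlation undefined: an input is constant")
    res = stats.spearmanr(gaps, counts)
    return float(res.statistic), float(res.pvalue)
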