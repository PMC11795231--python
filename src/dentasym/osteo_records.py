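"""Skeletal observations: demography, periosteal new bone formation (PNBF),
periodontal disease (PD), and prevalence arithmetic.

Observability is explicit throughout: archaeological skeletons are rarely
complete, so every element or alveolar socket carries a "not observable"
state, and prevalence denominators count only units that could actually be
assessed.

Two prevalence notions are used:

* crude prevalence rate (CPR) — percentage of *individuals* affected among
  those for whom the condition could be assessed;
* true prevalence rate (TPR) — percentage of *elements* (long bones, or for
  PD the alveolar regions around molars) affected among observable elements.

PD follows a 0-3 alveolar-crest grading ('x' = unobservable): 0 none,
1 mild, 2 moderate, 3 severe. For modelling, grades collapse to a binary
severity class: moderate/severe (2-3) vs absent/mild (0-1).

PNBF is recorded per long bone (femur, tibia, fibula, humerus, radius, ulna;
left/right) as not_observable / absent / present_active / present_remodeled.
An individual with any active lesion is classed active (an unresolved
inflammatory process at death dominates mixed cases); laterality is bilateral
if any element type is affected on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError

LONG_BONES = ("femur", "tibia", "fibula", "humerus", "radius", "ulna")
PNBF_STATES = ("not_observable", "absent", "present_active", "present_remodeled")
PD_GRADES = ("x", 0, 1, 2, 3)
MATURITIES = ("immature", "mature")
SEXES = ("female", "male", "indeterminate", "not_assessed")


@dataclass
class SkeletalRecord:
    """One individual's demographic and lesion observations."""

    individual_id: str
    site: str
    maturity: str
    sex: str = "not_assessed"
    age_years: float | None = None
    # (element, side) -> status, e.g. ("femur", "L") -> "present_active"
    pnbf_elements: dict[tuple[str, str], str] = field(default_factory=dict)
    # socket label -> grade in {'x', 0, 1, 2, 3}
    pd_sockets: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.maturity not in MATURITIES:
            raise ValidationError(f"maturity must be one of {MATURITIES}")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}")
        if self.age_years is not None and not self.age_years > 0:
            raise ValidationError("age_years must be positive when present")
        for key, status in self.pnbf_elements.items():
            if status not in PNBF_STATES:
                raise ValidationError(f"bad PNBF status {status!r} for {key}")
        for key, grade in self.pd_sockets.items():
            if grade not in PD_GRADES:
                raise ValidationError(f"bad PD grade {grade!r} for socket {key}")


@dataclass
class PrevalenceResult:
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValidationError("need 0 <= numerator <= denominator")

    @property
    def rate_percent(self) -> float:
        return 100.0 * self.numerator / self.denominator

    @property
    def rate_rounded(self) -> float:
        """Rate rounded half-up to one decimal, matching report formatting."""
        import decimal

        d = decimal.Decimal(100 * self.numerator) / decimal.Decimal(self.denominator)
        return float(d.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))

    def __str__(self) -> str:
        return f"{self.rate_rounded}% ({self.numerator}/{self.denominator})"


# ---------------------------------------------------------------------------
# individual-level classifications
# ---------------------------------------------------------------------------


def classify_pnbf(record: SkeletalRecord) -> tuple[str, str | None, str | None]:
    """Individual-level PNBF summary: (presence, activity, laterality).

    presence is 'present'/'absent'/'not_assessable'. Activity: 'active' if
    any lesion is active, else 'remodeled'. Laterality: 'bilateral' if any
    element type carries lesions on both sides, 'unilateral' if all lesions
    are one-sided, 'unknown' when the contralateral sides were unobservable.
    """
    observable = {k: v for k, v in record.pnbf_elements.items() if v != "not_observable"}
    if not observable:
        return ("not_assessable", None, None)
    lesions = {k: v for k, v in observable.items() if v.startswith("present")}
    if not lesions:
        return ("absent", None, None)
    activity = (
        "active" if any(v == "present_active" for v in lesions.values()) else "remodeled"
    )
    affected_elements = {elem for (elem, _s) in lesions}
    bilateral = any(
        (elem, "L") in lesions and (elem, "R") in lesions for elem in affected_elements
    )
    if bilateral:
        laterality = "bilateral"
    else:
        # unilateral only if every affected element's other side was observable
        contralateral_known = all(
            (elem, "R" if s == "L" else "L") in observable for (elem, s) in lesions
        )
        laterality = "unilateral" if contralateral_known else "unknown"
    return ("present", activity, laterality)


def collapse_pd(grades: Iterable[object]) -> int | None:
    """Binary PD severity for an individual: 1 if any observable socket is
    moderate/severe (grade 2-3), 0 otherwise, None if nothing observable."""
    observable = [g for g in grades if g != "x"]
    if not observable:
        return None
    return 1 if max(int(g) for g in observable) >= 2 else 0


def pd_presence(grades: Iterable[object]) -> int | None:
    """1 if any observable socket shows PD (grade >= 1), else 0; None if
    no socket is observable."""
    observable = [g for g in grades if g != "x"]
    if not observable:
        return None
    return 1 if max(int(g) for g in observable) >= 1 else 0


# ---------------------------------------------------------------------------
# prevalence
# ---------------------------------------------------------------------------


def crude_prevalence(
    records: Iterable[SkeletalRecord],
    condition: Callable[[SkeletalRecord], bool | None],
) -> PrevalenceResult:
    """Individual-level prevalence over records where the condition was
    assessable (the predicate returns None when it could not be assessed)."""
    num = den = 0
    for rec in records:
        status = condition(rec)
        if status is None:
            continue
        den += 1
        num += bool(status)
    if den == 0:
        raise ValidationError("no record allowed the condition to be assessed")
    return PrevalenceResult(num, den)


def true_prevalence(
    records: Iterable[SkeletalRecord],
    element_condition: Callable[[SkeletalRecord], Iterable[bool | None]],
) -> PrevalenceResult:
    """Element-level prevalence: the callable yields, per record, one
    True/False/None entry per element or socket (None = unobservable)."""
    num = den = 0
    for rec in records:
        for status in element_condition(rec):
            if status is None:
                continue
            den += 1
            num += bool(status)
    if den == 0:
        raise ValidationError("no observable elements")
    return PrevalenceResult(num, den)


# convenience predicates ------------------------------------------------------


def pnbf_present(record: SkeletalRecord) -> bool | None:
    presence, _, _ = classify_pnbf(record)
    return None if presence == "not_assessable" else presence == "present"


def pnbf_elementwise(record: SkeletalRecord) -> list[bool | None]:
    return [
        None if v == "not_observable" else v.startswith("present")
        for v in record.pnbf_elements.values()
    ]


def pd_present_individual(record: SkeletalRecord) -> bool | None:
    res = pd_presence(record.pd_sockets.values())
    return None if res is None else bool(res)


def pd_socketwise(record: SkeletalRecord) -> list[bool | None]:
    return [
        None if g == "x" else int(g) >= 1 for g in record.pd_sockets.values()
    ]


def prevalence_by(
    records: list[SkeletalRecord],
    group_key: Callable[[SkeletalRecord], str],
    condition: Callable[[SkeletalRecord], bool | None],
    element_condition: Callable[[SkeletalRecord], Iterable[bool | None]] | None = None,
) -> pd.DataFrame:
    """CPR (and optionally TPR) per group; mirrors the site/maturity
    prevalence table layout."""
    groups: dict[str, list[SkeletalRecord]] = {}
    for rec in records:
        groups.setdefault(group_key(rec), []).append(rec)
    rows = []
    for name, recs in sorted(groups.items()):
        row: dict[str, object] = {"group": name}
        try:
            cpr = crude_prevalence(recs, condition)
            row.update(cpr=str(cpr), cpr_percent=cpr.rate_rounded)
        except ValidationError:
            row.update(cpr="-", cpr_percent=np.nan)
        if element_condition is not None:
            try:
                tpr = true_prevalence(recs, element_condition)
                row.update(tpr=str(tpr), tpr_percent=tpr.rate_rounded)
            except ValidationError:
                row.update(tpr="-", tpr_percent=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tabular I/O (wide, one row per individual)
# ---------------------------------------------------------------------------

N_SOCKET_COLUMNS = 6


def records_to_frame(records: list[SkeletalRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "individual": rec.individual_id,
            "site": rec.site,
            "maturity": rec.maturity,
            "sex": rec.sex,
            "age_years": np.nan if rec.age_years is None else rec.age_years,
        }
        for elem in LONG_BONES:
            for s in ("L", "R"):
                row[f"pnbf_{elem}_{s}"] = rec.pnbf_elements.get(
                    (elem, s), "not_observable"
                )
        for j in range(N_SOCKET_COLUMNS):
            row[f"pd_socket_{j + 1}"] = rec.pd_sockets.get(f"socket_{j + 1}", "x")
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[SkeletalRecord]:
    records = []
    for _, row in frame.iterrows():
        pnbf = {}
        for elem in LONG_BONES:
            for s in ("L", "R"):
                col = f"pnbf_{elem}_{s}"
                if col in row and isinstance(row[col], str):
                    pnbf[(elem, s)] = row[col]
        sockets = {}
        for j in range(N_SOCKET_COLUMNS):
            col = f"pd_socket_{j + 1}"
            if col in row and not pd.isna(row[col]):
                val = row[col]
                sockets[f"socket_{j + 1}"] = "x" if val == "x" else int(val)
        age = row.get("age_years")
        records.append(
            SkeletalRecord(
                individual_id=str(row["individual"]),
                site=str(row["site"]),
                maturity=str(row["maturity"]),
                sex=str(row["sex"]),
                age_years=None if pd.isna(age) else float(age),
                pnbf_elements=pnbf,
                pd_sockets=sockets,
            )
        )
    return records


def write_records(records: list[SkeletalRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_records(path) -> list[SkeletalRecord]:
    return frame_to_records(pd.read_csv(path, sep="\t"))
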