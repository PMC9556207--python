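"""Depression-scale scoring, group assignment, and the evaluation statistics.

Three self-report instruments grade depression severity: the Symptom
Checklist-90 depression sub-score (here an opaque 0-90 value), the Zung
Self-rating Depression Scale index (0-100), and the Patient Health
Questionnaire-9 (0-27). Study enrolment uses stricter criteria than the
severity bands: normal controls need SCL-90 < 8, SDS < 53 and PHQ-9 < 5,
while the mild-depression groups need SCL-90 > 26, SDS in [53, 62] and
PHQ-9 in [5, 9]. Group comparisons are independent two-sample t-tests
(pooled-variance by default, Welch available) computed from summary
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import GROUP_SIZES, N_TESTS, ScaleCohort

__all__ = [
    "SCALES",
    "SCALE_RANGES",
    "ScaleRecord",
    "TTestResult",
    "classify_severity",
    "assign_group",
    "summarize",
    "t_test_from_stats",
    "longitudinal_report",
]

SCALES = ("scl90", "sds", "phq9")
SCALE_RANGES = {"scl90": (0.0, 90.0), "sds": (0.0, 100.0), "phq9": (0.0, 27.0)}

# Severity bands: list of (upper-exclusive bound, band name); the final band
# is closed at the scale maximum. SCL-90 distinguishes only normal vs mild;
# PHQ-9 uses the standard five cuts.
_SEVERITY_BANDS = {
    "scl90": [(27.0, "normal"), (91.0, "mild")],
    "sds": [(53.0, "normal"), (63.0, "mild"), (73.0, "moderate"), (101.0, "moderately_severe")],
    "phq9": [(5.0, "normal"), (10.0, "mild"), (15.0, "moderate"), (20.0, "moderately_severe"), (28.0, "severe")],
}


@dataclass(frozen=True)
class ScaleRecord:
    """One subject's scores at one test occasion."""

    subject_id: str
    test_index: int
    scl90: float
    sds: float
    phq9: float

    def __post_init__(self) -> None:
        if not 1 <= self.test_index <= N_TESTS:
            raise ValueError(f"test_index must be 1..{N_TESTS}")
        for scale in SCALES:
            lo, hi = SCALE_RANGES[scale]
            v = getattr(self, scale)
            if not lo <= v <= hi:
                raise ValueError(f"{scale} score {v} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class TTestResult:
    """Independent two-sample t-test outcome."""

    t_stat: float
    df: float
    p_two_sided: float
    method: str  # pooled | welch

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")


def classify_severity(scale: str, score: float) -> str:
    """Severity band of a score.

    SCL-90: <=26 normal, >26 mild. SDS: <53 normal, 53-62 mild, 63-72
    moderate, >72 moderately severe. PHQ-9: 0-4 normal, 5-9 mild, 10-14
    moderate, 15-19 moderately severe, 20-27 severe. Non-integer scores fall
    in the band of the enclosing interval.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")
    lo, hi = SCALE_RANGES[scale]
    if not lo <= score <= hi:
        raise ValueError(f"{scale} score {score} outside admissible range [{lo}, {hi}]")
    for upper, band in _SEVERITY_BANDS[scale]:
        if score < upper:
            return band
    raise AssertionError("bands must cover the admissible range")  # pragma: no cover


def assign_group(scl90: float, sds: float, phq9: float, will_train: bool = False) -> str:
    """Study group for a baseline score triple.

    Mild-depression eligibility (SCL-90 > 26, 53 <= SDS <= 62, 5 <= PHQ-9
    <= 9) splits into ``feedback`` vs ``depression_control`` by the
    ``will_train`` flag; ``normal_control`` needs SCL-90 < 8, SDS < 53 and
    PHQ-9 < 5; anything else is ``ineligible``.
    """
    for scale, v in (("scl90", scl90), ("sds", sds), ("phq9", phq9)):
        lo, hi = SCALE_RANGES[scale]
        if not lo <= v <= hi:
            raise ValueError(f"{scale} score {v} outside admissible range")
    if scl90 < 8 and sds < 53 and phq9 < 5:
        return "normal_control"
    if scl90 > 26 and 53 <= sds <= 62 and 5 <= phq9 <= 9:
        return "feedback" if will_train else "depression_control"
    return "ineligible"


def summarize(cohort: ScaleCohort, scale: str, test_index: int) -> pd.DataFrame:
    """Per-group sample mean, SD (n-1 denominator) and n for one occasion."""
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    rows = []
    for group in cohort.groups:
        vals = cohort.group_scores(group, scale, test_index)
        if len(vals) == 0:
            raise ValueError(f"group {group!r} has no scores at test {test_index}")
        if len(vals) == 1:
            raise ValueError(f"group {group!r} has a single subject; SD undefined")
        rows.append(
            {
                "group": group,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)),
                "n": int(len(vals)),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def t_test_from_stats(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    method: str = "pooled",
) -> TTestResult:
    """Independent two-sample t-test from summary statistics.

    ``pooled`` uses the classic equal-variance statistic with
    ``df = n1 + n2 - 2``; ``welch`` uses the Welch-Satterthwaite
    approximation. Two identical degenerate groups (both SDs zero, equal
    means) return ``t = 0, p = 1`` by convention.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if method not in ("pooled", "welch"):
        raise ValueError(f"unknown method {method!r}")

    if method == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        denom = np.sqrt(v1 + v2)
        if v1 + v2 > 0:
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        else:
            df = n1 + n2 - 2

    if denom == 0.0:
        if mean1 == mean2:
            return TTestResult(0.0, float(df), 1.0, method)
        raise ValueError("zero variance with unequal means: t is unbounded")
    t = (mean1 - mean2) / denom
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), min(p, 1.0), method)


_PAIRS = (("feedback", "depression_control"), ("feedback", "normal_control"), ("depression_control", "normal_control"))


def longitudinal_report(cohort: ScaleCohort, method: str = "pooled") -> pd.DataFrame:
    """The per-scale, per-test group summary and pairwise t-test table.

    One row per (scale, test): the three group means/SDs, the three pairwise
    p-values (feedback vs depression control, feedback vs normal control,
    depression vs normal control). ``df.attrs['trends']`` holds the sign of
    the least-squares slope of each group's mean over the six tests.
    """
    groups = set(cohort.groups)
    missing_groups = set(GROUP_SIZES) - groups
    if missing_groups:
        raise ValueError(f"cohort is missing groups: {sorted(missing_groups)}")
    present = set(map(int, cohort.scores["test_index"].unique()))
    missing_tests = sorted(set(range(1, N_TESTS + 1)) - present)
    if missing_tests:
        raise ValueError(f"cohort is missing test occasions: {missing_tests}")

    rows = []
    trends: dict[tuple[str, str], int] = {}
    for scale in SCALES:
        means_by_group: dict[str, list[float]] = {g: [] for g in GROUP_SIZES}
        for test in range(1, N_TESTS + 1):
            summ = summarize(cohort, scale, test)
            row = {"scale": scale, "test_index": test}
            for g in GROUP_SIZES:
                row[f"{g}_mean"] = summ.loc[g, "mean"]
                row[f"{g}_sd"] = summ.loc[g, "sd"]
                means_by_group[g].append(summ.loc[g, "mean"])
            for ga, gb in _PAIRS:
                res = t_test_from_stats(
                    summ.loc[ga, "mean"], summ.loc[ga, "sd"], int(summ.loc[ga, "n"]),
                    summ.loc[gb, "mean"], summ.loc[gb, "sd"], int(summ.loc[gb, "n"]),
                    method=method,
                )
                row[f"p_{ga}_vs_{gb}"] = res.p_two_sided
            rows.append(row)
        x = np.arange(1, N_TESTS + 1, dtype=float)
        for g, means in means_by_group.items():
            slope = float(np.polyfit(x, np.asarray(means), 1)[0])
            trends[(scale, g)] = int(np.sign(slope))
    df = pd.DataFrame(rows).set_index(["scale", "test_index"])
    df.attrs["trends"] = trends
    df.attrs["slopes_method"] = "least-squares slope of group means over tests"
    return df
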