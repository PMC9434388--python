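"""Pilot-trial cohort metrics: feasibility rates, score summaries, paired
pre/post changes, youth HRQoL dichotomization/indexing, and 6-minute-walk-test
percentile conversion.

Feasibility rates follow the conventions of pediatric feasibility pilots:
opt-in is computed against reachable invitees, retention against baseline
completers, completion and module-completion against program commencers, and
tracker compliance against intervention completers.  Pre/post contrasts are
complete-case paired t statistics.  Normative tables (6MWT distance quantiles
by age and sex; EQ-5D-Y value sets) are consumed as user-supplied tables, not
bundled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ParticipantFlow",
    "Rate",
    "ScoreSet",
    "ScoreSummary",
    "PairedChange",
    "HRQoLRecord",
    "FitnessRecord",
    "feasibility_rates",
    "summarize_scores",
    "paired_change",
    "dichotomize_hrqol",
    "index_hrqol",
    "sixmwt_percentile",
]

HRQOL_DIMENSIONS = (
    "mobility",
    "looking_after_myself",
    "usual_activities",
    "pain_discomfort",
    "worried_sad_unhappy",
)


@dataclass(frozen=True)
class ParticipantFlow:
    """Recruitment/retention counts from which all feasibility rates derive."""

    screened: int
    ineligible: int
    invited: int
    unreachable: int
    refused: int
    opted_in: int
    baseline_complete: int
    commenced: int
    intervention_complete: int
    returned_accelerometer_post: int
    followup_complete: int
    tracker_compliant: int
    all_modules_complete: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{f.name} must be a non-negative integer, got {v!r}")
        checks = [
            ("ineligible", self.ineligible, self.screened),
            ("invited", self.invited, self.screened - self.ineligible),
            ("unreachable + refused", self.unreachable + self.refused, self.invited),
            ("opted_in", self.opted_in, self.invited - self.unreachable),
            ("baseline_complete", self.baseline_complete, self.opted_in),
            ("commenced", self.commenced, self.opted_in),
            ("intervention_complete", self.intervention_complete, self.commenced),
            ("returned_accelerometer_post", self.returned_accelerometer_post,
             self.intervention_complete),
            ("followup_complete", self.followup_complete, self.commenced),
            ("tracker_compliant", self.tracker_compliant, self.intervention_complete),
            ("all_modules_complete", self.all_modules_complete, self.commenced),
        ]
        for name, down, up in checks:
            if down > up:
                raise ValueError(f"{name} ({down}) exceeds its upstream denominator ({up})")


@dataclass(frozen=True)
class Rate:
    """A feasibility proportion: report-style integer percent plus exact value."""

    name: str
    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent_exact(self) -> float:
        return 100.0 * self.fraction

    @property
    def percent(self) -> int:
        """Percent rounded half-up, matching report conventions."""
        return int(math.floor(self.percent_exact + 0.5))


def feasibility_rates(flow: ParticipantFlow) -> dict[str, Rate]:
    """The named feasibility rates of a pilot recruitment flow.

    opt_in = opted_in / (invited − unreachable); retention =
    intervention_complete / baseline_complete; completion =
    intervention_complete / commenced; tracker_compliance =
    tracker_compliant / intervention_complete; module_completion =
    all_modules_complete / commenced.
    """
    defs = {
        "opt_in": (flow.opted_in, flow.invited - flow.unreachable),
        "retention": (flow.intervention_complete, flow.baseline_complete),
        "completion": (flow.intervention_complete, flow.commenced),
        "tracker_compliance": (flow.tracker_compliant, flow.intervention_complete),
        "module_completion": (flow.all_modules_complete, flow.commenced),
    }
    out = {}
    for name, (num, den) in defs.items():
        if den == 0:
            raise ZeroDivisionError(f"rate {name!r} has a zero denominator")
        out[name] = Rate(name, int(num), int(den))
    return out


@dataclass(frozen=True)
class ScoreSet:
    """Responses on a 0–100 acceptability item."""

    item: str
    responses: Sequence[float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.responses, dtype=float)
        if len(arr) and ((arr < 0) | (arr > 100)).any():
            raise ValueError("scores must lie in [0, 100]")


@dataclass(frozen=True)
class ScoreSummary:
    item: str
    n: int
    median: float
    q1: float
    q3: float


def summarize_scores(s: ScoreSet) -> ScoreSummary:
    """Median and IQR (25th–75th) by the linear-interpolation quantile rule."""
    arr = np.asarray(s.responses, dtype=float)
    if len(arr) == 0:
        raise ValueError(f"score set {s.item!r} is empty")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return ScoreSummary(s.item, len(arr), float(med), float(q1), float(q3))


@dataclass(frozen=True)
class PairedChange:
    """Complete-case paired contrast: mean change with t-based CI and p."""

    n: int
    n_excluded: int
    mean_change: float
    sd: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    level: float
    degenerate: bool  # zero-variance differences: CI collapses to a point


def paired_change(pre: Sequence[float], post: Sequence[float],
                  level: float = 0.95) -> PairedChange:
    """Mean within-participant change (post − pre) with t interval and p.

    Pairs are matched by position; a pair with either value missing (NaN) is
    excluded and counted in ``n_excluded``.  With zero-variance differences
    the interval degenerates to a point and is flagged; the null case
    (identical pre/post) reports p = 1.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have the same length")
    ok = ~(np.isnan(pre) | np.isnan(post))
    d = (post - pre)[ok]
    n = len(d)
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / math.sqrt(n)
    if sd == 0.0:
        return PairedChange(n, int((~ok).sum()), mean, 0.0, 0.0, mean, mean,
                            1.0 if mean == 0.0 else 0.0, level, True)
    tcrit = stats.t.ppf(0.5 + level / 2, df=n - 1)
    t = mean / se
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return PairedChange(n, int((~ok).sum()), mean, sd, se,
                        mean - tcrit * se, mean + tcrit * se, float(p), level, False)


@dataclass(frozen=True)
class HRQoLRecord:
    """A youth five-dimension, five-level HRQoL profile plus 0–100 VAS."""

    levels: tuple[int, int, int, int, int]
    vas: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.levels) != 5:
            raise ValueError("exactly five dimension levels are required")
        for lv in self.levels:
            if not isinstance(lv, (int, np.integer)) or not 1 <= lv <= 5:
                raise ValueError(f"levels must be integers in 1..5, got {lv!r}")
        if not np.isnan(self.vas) and not 0 <= self.vas <= 100:
            raise ValueError("VAS must lie in [0, 100]")


def dichotomize_hrqol(r: HRQoLRecord) -> dict[str, bool]:
    """Any-problem flag per dimension: level 1 = no problems, 2–5 = any problems."""
    return {dim: lv >= 2 for dim, lv in zip(HRQOL_DIMENSIONS, r.levels)}


def index_hrqol(r: HRQoLRecord, value_set: Mapping[tuple, float]) -> float:
    """Utility index in [0, 1] by value-set lookup of the 5-level profile.

    ``value_set`` maps level tuples to index values (user-supplied; any
    conformant set anchors the all-ones profile at 1.0).
    """
    key = tuple(int(v) for v in r.levels)
    try:
        return float(value_set[key])
    except KeyError:
        raise ValueError(f"profile {key} not present in the value set") from None


@dataclass(frozen=True)
class FitnessRecord:
    """A 6-minute-walk-test result with the age/sex stratum for norming."""

    distance_m: float
    age: int
    sex: str  # "F" or "M"

    def __post_init__(self) -> None:
        if self.distance_m <= 0:
            raise ValueError("distance must be positive")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")


def sixmwt_percentile(f: FitnessRecord, norms: pd.DataFrame) -> float:
    """Age- and sex-specific percentile of a 6MWT distance.

    ``norms`` has columns ``sex, age, quantile, distance_m`` giving reference
    distances at known percentiles per stratum.  The result interpolates
    linearly between the bracketing reference quantiles and clamps to 1
    (below the table) or 99 (above it).
    """
    required = {"sex", "age", "quantile", "distance_m"}
    if not required.issubset(norms.columns):
        raise ValueError(f"norms table must have columns {sorted(required)}")
    stratum = norms[(norms["sex"] == f.sex) & (norms["age"] == f.age)]
    if len(stratum) == 0:
        raise ValueError(f"no normative rows for sex={f.sex!r}, age={f.age}")
    stratum = stratum.sort_values("quantile")
    q = stratum["quantile"].to_numpy(dtype=float)
    d = stratum["distance_m"].to_numpy(dtype=float)
    if not np.all(np.diff(d) >= 0):
        raise ValueError("normative distances must be non-decreasing in quantile")
    if f.distance_m < d[0]:
        return 1.0
    if f.distance_m > d[-1]:
        return 99.0
    return float(np.clip(np.interp(f.distance_m, d, q), 1.0, 99.0))
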