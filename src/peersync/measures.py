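"""Questionnaire-derived individual and dyadic variables.

Affect-grid coherence and empathic accuracy, friendship status from mutual
nominations, closeness (IOS) and liking aggregates, dyadic affect sums,
gender/seating covariates, and Cronbach's alpha for scale consistency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DIST_MAX",
    "AffectGridValue",
    "affect_coherence",
    "empathic_accuracy",
    "friendship_status",
    "closeness_sum",
    "liking_sum",
    "cronbach_alpha",
    "dyadic_sums",
    "gender_combination",
    "seating_relation",
    "bmi",
    "LIKING_ITEMS",
    "REVERSE_ITEMS",
]

logger = logging.getLogger(__name__)

#: maximal Euclidean distance on the 3x3 affect grid: sqrt((3-1)^2 + (3-1)^2)
DIST_MAX = math.sqrt(8.0)

LIKING_ITEMS = ("nice", "fair", "interesting", "smart", "cool",
                "ready_to_help", "boring", "mean")
REVERSE_ITEMS = frozenset({"boring", "mean"})

GRID_LEVELS = (1, 2, 3)


@dataclass(frozen=True)
class AffectGridValue:
    """One 3x3 affect-grid response (self-report or estimate of a target)."""

    valence: int
    arousal: int
    timepoint: str = "T1"
    reporter_id: str = ""
    target_id: str = ""

    def __post_init__(self) -> None:
        if self.valence not in GRID_LEVELS or self.arousal not in GRID_LEVELS:
            raise ValueError(
                f"affect grid values must be in {GRID_LEVELS}; "
                f"got valence={self.valence}, arousal={self.arousal}"
            )

    @property
    def is_self_report(self) -> bool:
        return self.reporter_id == self.target_id or self.target_id == ""


def _grid_distance(v1: int, a1: int, v2: int, a2: int) -> float:
    return math.hypot(v1 - v2, a1 - a2)


def affect_coherence(a: AffectGridValue, b: AffectGridValue) -> float:
    """Recoded affective similarity of two simultaneous self-reports.

    ``DIST_MAX`` minus the Euclidean distance between the two grid
    coordinates; identical affect scores the maximum (~2.83), opposite
    corners score 0.
    """
    if a.timepoint != b.timepoint:
        raise ValueError("affect coherence requires reports at the same timepoint")
    return DIST_MAX - _grid_distance(a.valence, a.arousal, b.valence, b.arousal)


def empathic_accuracy(estimate: AffectGridValue, actual: AffectGridValue) -> float:
    """Recoded closeness of an estimated affect to the target's actual one."""
    if estimate.target_id and actual.reporter_id and \
            estimate.target_id != actual.reporter_id:
        raise ValueError("estimate target does not match the actual reporter")
    if estimate.timepoint != actual.timepoint:
        raise ValueError("empathic accuracy requires matching timepoints")
    return DIST_MAX - _grid_distance(
        estimate.valence, estimate.arousal, actual.valence, actual.arousal
    )


def friendship_status(
    nominations: dict[str, list[str]], dyad: tuple[str, str],
    roster: set[str] | None = None,
) -> str:
    """Classify a pair as ``mutual`` / ``one_sided`` / ``none``.

    ``nominations`` maps each subject to the classmates they named as
    friends. Self-nominations are ignored; ids outside ``roster`` (when
    given) are skipped with a warning.
    """
    a, b = dyad

    def _named(who: str, whom: str) -> bool:
        names = []
        for x in nominations.get(who, []):
            if x == who:
                continue
            if roster is not None and x not in roster:
                logger.warning("unknown id %r in nomination list of %r", x, who)
                continue
            names.append(x)
        return whom in names

    ab, ba = _named(a, b), _named(b, a)
    if ab and ba:
        return "mutual"
    if ab or ba:
        return "one_sided"
    return "none"


def closeness_sum(
    ios_a: dict[str, float], ios_b: dict[str, float],
    timepoints: tuple[str, str] = ("T0", "T1"),
) -> float:
    """Dyadic closeness: each rater's IOS (0-6) averaged over two
    timepoints, then summed over the two raters. Range 0-12.

    A rater missing one timepoint contributes the other alone; a rater
    missing both makes the dyad value missing (NaN).
    """
    def _rater_mean(ios: dict[str, float]) -> float:
        vals = [ios[t] for t in timepoints if t in ios and ios[t] is not None
                and np.isfinite(ios[t])]
        if not vals:
            return np.nan
        for v in vals:
            if not 0 <= v <= 6:
                raise ValueError(f"IOS rating {v} outside 0-6")
        return float(np.mean(vals))

    return _rater_mean(ios_a) + _rater_mean(ios_b)


def recode_reverse(value: float) -> float:
    """Reverse-code a 1-4 Likert item (involutive: 5 - x)."""
    return 5.0 - value


def _rater_liking(items_by_tp: dict[str, dict[str, float]],
                  max_missing: int = 2) -> float:
    tp_scores = []
    for tp, items in items_by_tp.items():
        vals = []
        n_missing = 0
        for name in LIKING_ITEMS:
            v = items.get(name)
            if v is None or not np.isfinite(v):
                n_missing += 1
                continue
            if not 1 <= v <= 4:
                raise ValueError(f"liking item {name}={v} outside 1-4")
            vals.append(recode_reverse(v) if name in REVERSE_ITEMS else v)
        if n_missing > max_missing:
            continue  # drop this timepoint for the rater
        tp_scores.append(float(np.mean(vals)))
    return float(np.mean(tp_scores)) if tp_scores else np.nan


def liking_sum(
    items_a: dict[str, dict[str, float]],
    items_b: dict[str, dict[str, float]],
) -> float:
    """Dyadic liking: per rater, the 8 items (negative ones reverse-coded)
    are averaged per timepoint and across T0/T4; the two rater values are
    summed. Range 2-8.
    """
    return _rater_liking(items_a) + _rater_liking(items_b)


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Internal consistency alpha = k/(k-1) * (1 - sum(item var)/var(total)).

    ``item_matrix`` is raters x items with no missing cells. Returns NaN
    when the total score has zero variance.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 raters and 2 items")
    if np.any(~np.isfinite(x)):
        raise ValueError("item matrix contains missing cells")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return np.nan
    return k / (k - 1) * (1.0 - item_vars.sum() / total_var)


def dyadic_sums(
    report_a: AffectGridValue, report_b: AffectGridValue
) -> tuple[float, float]:
    """(valence_sum, arousal_sum) of the two members' self-reports; 2-6."""
    if not (report_a.is_self_report and report_b.is_self_report):
        raise ValueError("dyadic sums use self-reports only")
    return (
        float(report_a.valence + report_b.valence),
        float(report_a.arousal + report_b.arousal),
    )


def gender_combination(gender_a: str, gender_b: str) -> str:
    g = {gender_a.lower()[0], gender_b.lower()[0]}
    if g == {"f"}:
        return "female_female"
    if g == {"m"}:
        return "male_male"
    return "mixed"


def seating_relation(seat_a: int, seat_b: int, group_size: int) -> str:
    """Relation of two circular seat indices: ``adjacent`` (distance 1),
    ``across`` (maximal circular distance), else ``non_adjacent``."""
    d = abs(seat_a - seat_b) % group_size
    d = min(d, group_size - d)
    if d == 1:
        return "adjacent"
    if d == group_size // 2 and group_size > 3:
        return "across"
    return "non_adjacent"


def bmi(weight_kg: float, height_m: float) -> float:
    return weight_kg / height_m**2


def dyad_table(
    roster: pd.DataFrame,
    nominations: dict[str, list[str]],
    ios: dict[str, dict[str, dict[str, float]]],
    liking: dict[str, dict[str, dict[str, dict[str, float]]]],
    self_affect: dict[str, AffectGridValue],
    estimates: dict[tuple[str, str], AffectGridValue],
) -> pd.DataFrame:
    """Assemble one row per within-group pair with every dyadic variable.

    ``ios[rater][target]`` maps timepoint -> rating; ``liking`` analogously
    with item dicts; ``estimates[(reporter, target)]`` holds affect-grid
    estimates at the affect timepoint.
    """
    rows = []
    roster_ids = set(roster["subject_id"])
    for group_id, grp in roster.groupby("group_id"):
        subs = grp.sort_values("seat_position")
        ids = list(subs["subject_id"])
        n = len(ids)
        info = subs.set_index("subject_id")
        for i in range(n):
            for j in range(i + 1, n):
                a, b = ids[i], ids[j]
                row: dict = {
                    "dyad_id": f"{a}__{b}",
                    "group_id": group_id,
                    "member_a": a,
                    "member_b": b,
                    "friendship_status": friendship_status(
                        nominations, (a, b), roster=roster_ids),
                    "gender_combo": gender_combination(
                        info.loc[a, "gender"], info.loc[b, "gender"]),
                    "seating": seating_relation(
                        int(info.loc[a, "seat_position"]),
                        int(info.loc[b, "seat_position"]), n),
                    "closeness_sum": closeness_sum(
                        ios.get(a, {}).get(b, {}), ios.get(b, {}).get(a, {})),
                    "liking_sum": liking_sum(
                        liking.get(a, {}).get(b, {}),
                        liking.get(b, {}).get(a, {})),
                }
                sa, sb = self_affect.get(a), self_affect.get(b)
                if sa is not None and sb is not None:
                    row["affect_coherence"] = affect_coherence(sa, sb)
                    row["valence_sum"], row["arousal_sum"] = dyadic_sums(sa, sb)
                else:
                    row["affect_coherence"] = np.nan
                    row["valence_sum"] = row["arousal_sum"] = np.nan
                ea = estimates.get((a, b))
                eb = estimates.get((b, a))
                acc = np.nan
                if ea is not None and sb is not None and eb is not None \
                        and sa is not None:
                    acc = empathic_accuracy(ea, sb) + empathic_accuracy(eb, sa)
                row["empathic_accuracy_sum"] = acc
                rows.append(row)
    return pd.DataFrame(rows)
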