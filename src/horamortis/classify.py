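"""Threshold-based time-of-death window prediction.

The 24-h clock read from the two ratios has only two usable hands: a high
N/B ratio points at a morning death (around 06:00) and a high B/N ratio at
an evening death (around 18:00).  The default decision rules map ratio
values through fixed, strictly-exceeded thresholds to closed clock-time
windows:

    N/B > 25  ->  death between 01:00 and 10:00   (low tier)
    N/B > 40  ->  death between 03:00 and 09:00   (high tier)
    B/N > 1.5 ->  death between 14:00 and 22:00   (low tier)
    B/N > 4   ->  death between 15:00 and 20:00   (high tier)

The highest applicable tier wins.  A case below every threshold receives
no statement at all: low ratios do NOT exclude a morning or evening death,
and nothing in the evaluation converts "no prediction" into an exclusion.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdRule",
    "Prediction",
    "DEFAULT_RULES",
    "predict_window",
    "predict_cohort",
    "evaluate_predictions",
    "tightest_window",
    "mutual_exclusivity_check",
    "validate_rules",
    "rules_from_json",
]


class RuleConfigurationError(ValueError):
    """Raised when a threshold-rule set is internally inconsistent."""


@dataclass(frozen=True)
class ThresholdRule:
    ratio_key: str          # "nb" or "bn"
    threshold: float        # strict ">" cut
    window: tuple[float, float]   # closed clock interval [start, end], hours
    tier: str               # "low" or "high"

    def __post_init__(self) -> None:
        if self.ratio_key not in ("nb", "bn"):
            raise RuleConfigurationError(f"ratio_key must be nb/bn, got {self.ratio_key!r}")
        if self.threshold <= 0:
            raise RuleConfigurationError("threshold must be positive")
        start, end = self.window
        if not (0 <= start < end <= 24):
            raise RuleConfigurationError(f"window must satisfy 0 <= start < end <= 24, got {self.window}")
        if self.tier not in ("low", "high"):
            raise RuleConfigurationError(f"tier must be low/high, got {self.tier!r}")

    @property
    def tier_name(self) -> str:
        side = "morning" if self.ratio_key == "nb" else "evening"
        return f"{self.tier}_{side}"


DEFAULT_RULES: tuple[ThresholdRule, ...] = (
    ThresholdRule("nb", 25.0, (1.0, 10.0), "low"),
    ThresholdRule("nb", 40.0, (3.0, 9.0), "high"),
    ThresholdRule("bn", 1.5, (14.0, 22.0), "low"),
    ThresholdRule("bn", 4.0, (15.0, 20.0), "high"),
)


@dataclass(frozen=True)
class Prediction:
    case_id: str
    tier: str                       # none / low_morning / high_morning / ...
    window: tuple[float, float] | None
    covered: bool | None = None     # window contains true time of death


def mutual_exclusivity_check(rules: tuple[ThresholdRule, ...] = DEFAULT_RULES) -> bool:
    """True iff no single case can trigger both a morning and an evening rule.

    Since bn = 1/nb, an nb rule at threshold a and a bn rule at threshold b
    can both fire only if nb > a and 1/nb > b, i.e. b < 1/nb < 1/a — possible
    exactly when a * b < 1.  The check uses the lowest threshold on each side.
    """
    nb_thr = [r.threshold for r in rules if r.ratio_key == "nb"]
    bn_thr = [r.threshold for r in rules if r.ratio_key == "bn"]
    if not nb_thr or not bn_thr:
        return True
    return min(nb_thr) * min(bn_thr) > 1.0


def validate_rules(rules: tuple[ThresholdRule, ...]) -> None:
    """Reject rule sets violating nesting or morning/evening exclusivity."""
    if not mutual_exclusivity_check(rules):
        raise RuleConfigurationError(
            "rule set not mutually exclusive: a single case could receive both "
            "a morning and an evening prediction"
        )
    for key in ("nb", "bn"):
        side = sorted(
            (r for r in rules if r.ratio_key == key), key=lambda r: r.threshold
        )
        for lo, hi in itertools.combinations(side, 2):
            if lo.tier == "high" and hi.tier == "low":
                raise RuleConfigurationError(
                    f"{key} rules: high tier at lower threshold than low tier"
                )
            if not (lo.window[0] <= hi.window[0] and hi.window[1] <= lo.window[1]):
                raise RuleConfigurationError(
                    f"{key} rules: window {hi.window} at threshold {hi.threshold} "
                    f"not nested inside {lo.window} at threshold {lo.threshold}"
                )


def rules_from_json(text: str) -> tuple[ThresholdRule, ...]:
    """Load and validate a rule set from JSON (list of rule objects)."""
    raw = json.loads(text)
    if not isinstance(raw, list):
        raise RuleConfigurationError("rules JSON must be a list")
    rules = tuple(
        ThresholdRule(
            ratio_key=r["ratio_key"],
            threshold=float(r["threshold"]),
            window=(float(r["window"][0]), float(r["window"][1])),
            tier=r["tier"],
        )
        for r in raw
    )
    validate_rules(rules)
    return rules


def predict_window(
    case_id: str,
    nb_ratio: float,
    bn_ratio: float,
    rules: tuple[ThresholdRule, ...] = DEFAULT_RULES,
    time_of_death: float | None = None,
) -> Prediction:
    """Apply the threshold rules to one case; highest applicable tier wins.

    Thresholds are strict (a ratio exactly at the cut does not trigger the
    rule); prediction windows are closed intervals.
    """
    value = {"nb": nb_ratio, "bn": bn_ratio}
    applicable = [r for r in rules if value[r.ratio_key] > r.threshold]
    if not applicable:
        return Prediction(case_id, "none", None)
    # highest tier = highest threshold among applicable rules on that side
    best = max(applicable, key=lambda r: (r.tier == "high", r.threshold))
    covered = None
    if time_of_death is not None:
        covered = bool(best.window[0] <= time_of_death <= best.window[1])
    return Prediction(case_id, best.tier_name, best.window, covered)


def predict_cohort(
    ratios: pd.DataFrame, rules: tuple[ThresholdRule, ...] = DEFAULT_RULES
) -> pd.DataFrame:
    """Predictions for every case in an annotated ratio table."""
    has_truth = "time_of_death" in ratios.columns
    rows = []
    for rec in ratios.itertuples(index=False):
        p = predict_window(
            rec.case_id,
            rec.nb_ratio,
            rec.bn_ratio,
            rules,
            time_of_death=rec.time_of_death if has_truth else None,
        )
        rows.append(
            {
                "case_id": p.case_id,
                "tier": p.tier,
                "window_start": p.window[0] if p.window else np.nan,
                "window_end": p.window[1] if p.window else np.nan,
                "covered": p.covered,
            }
        )
    return pd.DataFrame(rows)


def evaluate_predictions(
    ratios: pd.DataFrame, rules: tuple[ThresholdRule, ...] = DEFAULT_RULES
) -> dict:
    """Yield and coverage of the threshold rules on a cohort with known truth.

    Returns per-tier counts, the predicted fraction (cases receiving any
    window over all cases), and coverage (fraction of predicted cases whose
    true time of death lies inside the predicted closed window).  Coverage
    is None when no case is predicted.
    """
    if len(ratios) == 0:
        raise ValueError("empty cohort")
    if ratios["time_of_death"].isna().any():
        raise ValueError("evaluation requires a true time of death for every case")
    preds = predict_cohort(ratios, rules)
    total = len(preds)
    predicted = preds[preds["tier"] != "none"]
    tier_counts = preds["tier"].value_counts().to_dict()
    coverage = (
        float(predicted["covered"].mean()) if len(predicted) else None
    )
    tier_coverage = {
        t: float(g["covered"].mean())
        for t, g in predicted.groupby("tier")
    }
    return {
        "n_total": total,
        "n_predicted": int(len(predicted)),
        "predicted_fraction": len(predicted) / total,
        "coverage": coverage,
        "tier_counts": {t: int(c) for t, c in tier_counts.items()},
        "tier_coverage": tier_coverage,
    }


def tightest_window(
    ratios: pd.DataFrame, ratio_key: str, threshold: float
) -> tuple[float, float, float]:
    """Minimal circular clock arc covering all cases above a threshold.

    Reconstructs the empirical rule-derivation step: among cases whose
    ratio strictly exceeds ``threshold``, find the shortest arc of the
    24-h clock containing every true time of death.  The minimal covering
    arc is the complement of the largest gap between circularly sorted
    death times.  Returns (start, end, length_hours); start > end means the
    arc wraps midnight.  A single case gives a degenerate zero-length arc.
    """
    col = {"nb": "nb_ratio", "bn": "bn_ratio"}[ratio_key]
    times = np.sort(
        ratios.loc[ratios[col] > threshold, "time_of_death"].to_numpy(dtype=float)
    )
    if len(times) == 0:
        raise ValueError(f"no case exceeds {ratio_key} > {threshold}")
    if len(times) == 1:
        t = float(times[0])
        return t, t, 0.0
    gaps = np.diff(np.append(times, times[0] + 24.0))
    i = int(np.argmax(gaps))
    # arc starts just after the largest gap and ends at its left edge
    start = float(times[(i + 1) % len(times)])
    end = float(times[i])
    length = 24.0 - float(gaps[i])
    return start, end, length
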