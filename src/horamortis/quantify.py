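"""Clock-gene expression ratios and time-domain assignment.

The two statistics at the heart of the method are the NR1D1/BMAL1 (N/B)
and BMAL1/NR1D1 (B/N) ratios.  Because the two genes oscillate in
antiphase, the ratio oscillates with the sum of their log-amplitudes:
N/B peaks in the morning (~06:00) and B/N in the evening (~18:00).  The
ratio cancels any factor common to both transcripts (reference-gene
normalization, uniform postmortem RNA degradation), which is what makes it
usable on autopsy material.

Each case is binned into one of four 6-hour time domains of the 24-h
clock: morning [3, 9), noon [9, 15), evening [15, 21) and night
[21, 24) + [0, 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TIME_DOMAINS",
    "RatioResult",
    "QuantificationError",
    "compute_ratios",
    "ratios_from_ct",
    "assign_time_domain",
    "add_ratios",
]

#: domain label -> [start, end) in clock hours; night wraps midnight.
TIME_DOMAINS: dict[str, tuple[float, float]] = {
    "morning": (3.0, 9.0),
    "noon": (9.0, 15.0),
    "evening": (15.0, 21.0),
    "night": (21.0, 3.0),
}

DOMAIN_ORDER = ("morning", "noon", "evening", "night")


class QuantificationError(ValueError):
    """Raised for a case whose expression values cannot yield a ratio."""


@dataclass(frozen=True)
class RatioResult:
    case_id: str
    nb_ratio: float
    bn_ratio: float
    time_domain: str | None
    time_of_death: float | None = None


def compute_ratios(expr_bmal1: float, expr_nr1d1: float) -> tuple[float, float]:
    """N/B and B/N ratios from relative expression of the two genes.

    Both expressions must be strictly positive; the two returned ratios
    are exact reciprocals.
    """
    if not np.isfinite(expr_bmal1) or expr_bmal1 <= 0:
        raise QuantificationError(f"non-positive BMAL1 expression: {expr_bmal1}")
    if not np.isfinite(expr_nr1d1) or expr_nr1d1 <= 0:
        raise QuantificationError(f"non-positive NR1D1 expression: {expr_nr1d1}")
    nb = expr_nr1d1 / expr_bmal1
    return nb, 1.0 / nb


def ratios_from_ct(
    ct_bmal1: float,
    ct_nr1d1: float,
    efficiency: float = 1.0,
    ct_ceiling: float = 40.0,
) -> tuple[float, float]:
    """N/B and B/N ratios from raw Ct values of the two assays.

    Assumes a shared amplification efficiency for both genes, so
    ``nb = (1 + efficiency) ** (ct_bmal1 - ct_nr1d1)``.  A Ct above
    ``ct_ceiling`` is treated as a non-detect.
    """
    if not 0 < efficiency <= 1:
        raise ValueError(f"efficiency must lie in (0, 1], got {efficiency}")
    if not (np.isfinite(ct_bmal1) and np.isfinite(ct_nr1d1)):
        raise QuantificationError("missing Ct value")
    if ct_bmal1 > ct_ceiling or ct_nr1d1 > ct_ceiling:
        raise QuantificationError(
            f"non-detect Ct (> {ct_ceiling} cycles): "
            f"BMAL1={ct_bmal1}, NR1D1={ct_nr1d1}"
        )
    nb = (1.0 + efficiency) ** (ct_bmal1 - ct_nr1d1)
    return nb, 1.0 / nb


def assign_time_domain(t: float | np.ndarray) -> str | np.ndarray:
    """Map a clock time (hours in [0, 24)) to its time-domain label.

    The four 6-hour domains are half-open, so 9.0 is noon and 2.99 is
    night; night wraps across midnight.
    """
    arr = np.asarray(t, dtype=float)
    if np.any((arr < 0) | (arr >= 24.0)):
        raise ValueError("clock time must lie in [0, 24)")
    # shift by -3 h so the partition becomes contiguous 6-hour blocks
    idx = ((arr - 3.0) % 24.0 // 6.0).astype(int)
    labels = np.array(DOMAIN_ORDER, dtype=object)[idx]
    return labels if arr.ndim else str(labels)


def add_ratios(
    cohort: pd.DataFrame,
    source: str = "expression",
    efficiency: float = 1.0,
    ct_ceiling: float = 40.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate a case table with nb_ratio, bn_ratio and time_domain.

    Parameters
    ----------
    cohort:
        Case table with the documented schema.
    source:
        "expression" uses expr_bmal1/expr_nr1d1; "ct" uses the Ct columns
        through the shared-efficiency model.

    Returns
    -------
    (annotated, excluded):
        ``annotated`` holds the cases with valid ratios plus the three new
        columns; ``excluded`` holds the rejected rows with a ``reason``
        column.  ``len(annotated) + len(excluded) == len(cohort)`` always.
    """
    if source not in ("expression", "ct"):
        raise ValueError(f"source must be 'expression' or 'ct', got {source!r}")
    df = cohort.copy()
    if source == "expression":
        eb = df["expr_bmal1"].to_numpy(dtype=float)
        en = df["expr_nr1d1"].to_numpy(dtype=float)
        bad = ~np.isfinite(eb) | ~np.isfinite(en) | (eb <= 0) | (en <= 0)
        reason = "non-positive or missing expression"
        with np.errstate(divide="ignore", invalid="ignore"):
            nb = en / eb
    else:
        cb = df["ct_bmal1"].to_numpy(dtype=float)
        cn = df["ct_nr1d1"].to_numpy(dtype=float)
        bad = ~np.isfinite(cb) | ~np.isfinite(cn) | (cb > ct_ceiling) | (cn > ct_ceiling)
        reason = f"missing or non-detect Ct (> {ct_ceiling} cycles)"
        nb = (1.0 + efficiency) ** (cb - cn)

    excluded = df.loc[bad].copy()
    excluded["reason"] = reason
    annotated = df.loc[~bad].copy()
    annotated["nb_ratio"] = nb[~bad]
    annotated["bn_ratio"] = 1.0 / nb[~bad]
    if len(annotated):
        annotated["time_domain"] = assign_time_domain(
            annotated["time_of_death"].to_numpy(dtype=float)
        )
    else:
        annotated["time_domain"] = pd.Series(dtype=object)
    return annotated, excluded
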