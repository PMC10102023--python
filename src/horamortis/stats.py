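"""Group statistics: domain summaries, Scheffé post-hoc tests, t-tests.

Summaries are reported as mean ± SEM per time domain.  Differences across
the four domains are tested with Scheffé's post-hoc procedure after a
one-way ANOVA: for groups i, j among k groups with total size N,

    MSW  = sum of within-group squared deviations / (N - k)
    F_s  = (mean_i - mean_j)^2 / (MSW * (1/n_i + 1/n_j))
    p    = upper tail of F(k-1, N-k) at F_s / (k - 1)

which controls the familywise error over all contrasts.  Two-group
contrasts (acute vs chronic brain injury per domain) use the pooled-
variance two-sided Student t-test.  Significance is flagged at the
conventional 0.05 and 0.01 levels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import DOMAIN_ORDER

__all__ = [
    "DomainSummary",
    "ComparisonResult",
    "SUBGROUP_FACTORS",
    "domain_summary",
    "scheffe_pairwise",
    "t_test_unpaired",
    "subgroup_analysis",
    "significance_label",
]


@dataclass(frozen=True)
class DomainSummary:
    domain: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class ComparisonResult:
    pair: tuple[str, str]
    statistic: float
    p_value: float
    significance: str


def significance_label(p: float) -> str:
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def domain_summary(
    ratios: pd.DataFrame, which: str = "nb"
) -> list[DomainSummary]:
    """Per-time-domain mean ± SEM of the chosen ratio.

    Empty domains are reported with n = 0 and NaN mean/sem rather than
    raised; SEM uses the n-1 sample standard deviation and is NaN for
    n < 2.
    """
    col = {"nb": "nb_ratio", "bn": "bn_ratio"}[which]
    out = []
    for domain in DOMAIN_ORDER:
        vals = ratios.loc[ratios["time_domain"] == domain, col].to_numpy(dtype=float)
        n = len(vals)
        mean = float(np.mean(vals)) if n else float("nan")
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
        out.append(DomainSummary(domain, n, mean, sem))
    return out


def _check_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    for k, a in arrs.items():
        if len(a) < 2:
            raise ValueError(f"group {k!r} needs n >= 2, got {len(a)}")
    return arrs


def scheffe_pairwise(
    groups: Mapping[str, Sequence[float]],
) -> list[ComparisonResult]:
    """Scheffé's F test for every pair of groups.

    For k = 2 the p-value coincides with the one-way ANOVA omnibus test.
    A degenerate zero within-group variance yields p = 1 for equal means
    and p = 0 (with a warning) otherwise.
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    n_total = sum(len(a) for a in arrs.values())
    msw = sum(np.sum((a - a.mean()) ** 2) for a in arrs.values()) / (n_total - k)
    df1, df2 = k - 1, n_total - k

    results = []
    for gi, gj in itertools.combinations(arrs, 2):
        a, b = arrs[gi], arrs[gj]
        diff_sq = (a.mean() - b.mean()) ** 2
        if msw == 0:
            if diff_sq == 0:
                f_s, p = 0.0, 1.0
            else:
                warnings.warn(
                    "zero within-group variance with unequal means; p set to 0",
                    RuntimeWarning,
                    stacklevel=2,
                )
                f_s, p = float("inf"), 0.0
        else:
            f_s = diff_sq / (msw * (1 / len(a) + 1 / len(b)))
            p = float(sps.f.sf(f_s / df1, df1, df2))
        results.append(ComparisonResult((gi, gj), float(f_s), p, significance_label(p)))
    return results


def t_test_unpaired(
    a: Sequence[float], b: Sequence[float], labels: tuple[str, str] = ("a", "b")
) -> ComparisonResult:
    """Two-sided pooled-variance (Student) t-test for two groups."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if x.mean() == y.mean():
            return ComparisonResult(labels, 0.0, 1.0, "ns")
        warnings.warn(
            "zero pooled variance with unequal means; p set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return ComparisonResult(labels, float("inf"), 0.0, significance_label(0.0))
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return ComparisonResult(labels, float(t), float(p), significance_label(float(p)))


def _age_group(age: pd.Series) -> pd.Series:
    bins = pd.cut(
        age, [-np.inf, 19.0, 69.0, np.inf], labels=["<=19y", "20-69y", ">=70y"]
    )
    return bins.astype(object)


def _pmi_group(pmi: pd.Series) -> pd.Series:
    return pd.Series(
        np.where(pmi < 30.0, "<30h", ">30h"), index=pmi.index, dtype=object
    )


#: factor name -> function producing the level label per case.
SUBGROUP_FACTORS = {
    "sex": lambda df: df["sex"].astype(object),
    "age_group": lambda df: _age_group(df["age"]),
    "pmi_group": lambda df: _pmi_group(df["pmi"]),
    "cause_class": lambda df: df["cause_class"].astype(object),
    "brain_injury_course": lambda df: df["brain_injury"].astype(object),
}

_LEVEL_ORDER = {
    "sex": ["male", "female"],
    "age_group": ["<=19y", "20-69y", ">=70y"],
    "pmi_group": ["<30h", ">30h"],
    "cause_class": ["intrinsic", "extrinsic"],
    "brain_injury_course": ["acute", "chronic"],
}


def subgroup_analysis(
    ratios: pd.DataFrame, factor: str, min_per_domain: int = 2
) -> dict:
    """Per-level domain summaries and Scheffé comparisons for one factor.

    For ``brain_injury_course`` the analysis is restricted to head-injury
    deaths (acute vs chronic) and additionally reports per-domain
    acute-vs-chronic pooled t-tests.  Levels whose domains are too sparse
    for the Scheffé procedure are reported with a warning entry instead of
    raising.

    Returns a dict with keys ``factor``, ``levels`` (level -> dict with
    ``summaries`` {ratio: [DomainSummary]}, ``comparisons``
    {ratio: [ComparisonResult]}, ``n``), ``t_tests`` (brain-injury factor
    only) and ``warnings``.
    """
    if factor not in SUBGROUP_FACTORS:
        raise ValueError(f"unknown factor {factor!r}")
    df = ratios.copy()
    df["_level"] = SUBGROUP_FACTORS[factor](df)
    if factor == "brain_injury_course":
        df = df[df["_level"].isin(["acute", "chronic"])]

    result: dict = {"factor": factor, "levels": {}, "warnings": []}
    levels = [l for l in _LEVEL_ORDER[factor] if (df["_level"] == l).any()]
    for absent in set(_LEVEL_ORDER[factor]) - set(levels):
        result["warnings"].append(f"level {absent!r}: no cases, skipped")

    for level in levels:
        sub = df[df["_level"] == level]
        entry: dict = {"n": int(len(sub)), "summaries": {}, "comparisons": {}}
        for which, col in (("nb", "nb_ratio"), ("bn", "bn_ratio")):
            entry["summaries"][which] = domain_summary(sub, which)
            groups = {
                d: sub.loc[sub["time_domain"] == d, col].to_numpy(dtype=float)
                for d in DOMAIN_ORDER
            }
            usable = {d: v for d, v in groups.items() if len(v) >= min_per_domain}
            if len(usable) >= 2:
                entry["comparisons"][which] = scheffe_pairwise(usable)
            else:
                entry["comparisons"][which] = []
                result["warnings"].append(
                    f"level {level!r}: insufficient data for {which} comparisons"
                )
        result["levels"][level] = entry

    if factor == "brain_injury_course" and {"acute", "chronic"} <= set(levels):
        result["t_tests"] = {}
        for which, col in (("nb", "nb_ratio"), ("bn", "bn_ratio")):
            per_domain = []
            for d in DOMAIN_ORDER:
                a = df.loc[
                    (df["_level"] == "acute") & (df["time_domain"] == d), col
                ].to_numpy(dtype=float)
                c = df.loc[
                    (df["_level"] == "chronic") & (df["time_domain"] == d), col
                ].to_numpy(dtype=float)
                if len(a) >= 2 and len(c) >= 2:
                    res = t_test_unpaired(a, c, labels=("acute", "chronic"))
                    per_domain.append((d, res))
                else:
                    result["warnings"].append(
                        f"domain {d!r}: insufficient data for acute-vs-chronic t-test"
                    )
            result["t_tests"][which] = per_domain
    return result


def summaries_to_frame(analysis: dict) -> pd.DataFrame:
    """Flatten a subgroup_analysis result into a tidy table."""
    rows = []
    for level, entry in analysis["levels"].items():
        for which, summaries in entry["summaries"].items():
            for s in summaries:
                rows.append(
                    {
                        "factor": analysis["factor"],
                        "level": level,
                        "ratio": which,
                        "kind": "summary",
                        "domain_or_pair": s.domain,
                        "n": s.n,
                        "mean": s.mean,
                        "sem": s.sem,
                        "statistic": np.nan,
                        "p_value": np.nan,
                        "significance": "",
                    }
                )
        for which, comps in entry["comparisons"].items():
            for c in comps:
                rows.append(
                    {
                        "factor": analysis["factor"],
                        "level": level,
                        "ratio": which,
                        "kind": "scheffe",
                        "domain_or_pair": f"{c.pair[0]} vs {c.pair[1]}",
                        "n": entry["n"],
                        "mean": np.nan,
                        "sem": np.nan,
                        "statistic": c.statistic,
                        "p_value": c.p_value,
                        "significance": c.significance,
                    }
                )
    for which, tt in analysis.get("t_tests", {}).items():
        for domain, c in tt:
            rows.append(
                {
                    "factor": analysis["factor"],
                    "level": "acute vs chronic",
                    "ratio": which,
                    "kind": "t_test",
                    "domain_or_pair": domain,
                    "n": np.nan,
                    "mean": np.nan,
                    "sem": np.nan,
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                    "significance": c.significance,
                }
            )
    return pd.DataFrame(rows)
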