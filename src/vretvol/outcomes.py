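"""Cohort-level outcome statistics.

Paired pre/post comparisons use the standard paired t-test with the
paired-design effect size dz = t / sqrt(n) (equivalently
mean(diff) / sd(diff)); percent reduction is 100 * (pre - post) / pre.
FSQ severity strata follow the operational bands: high >= 80, moderate
50-79, low-moderate 40-49, excluded below 40.

PSQ scoring computes the five domain indices from the 15-item post-session
questionnaire: anxiety end/peak stay on their 0-100 scale and are never
pooled with the Likert items; avoidance, control and presence are plain
item means; tolerability reverse-codes T2 (8 - x on the 1-7 scale).
Step-up readiness requires R1 >= 5, tolerability >= 5, and no adverse
event.

Two-sided p-values throughout, with no multiplicity correction by
default; a Holm adjustment helper is provided but opt-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedResult",
    "PSQScores",
    "paired_t",
    "cohens_dz",
    "percent_reduction",
    "classify_fsq",
    "score_psq",
    "holm_adjust",
    "fsq_change_table",
    "paired_outcomes_table",
]


@dataclass
class PairedResult:
    t_stat: float
    df: int
    p_value: float
    cohens_dz: float
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    mean_diff: float
    pct_reduction: float

    def to_dict(self) -> dict:
        return asdict(self)


def cohens_dz(t_stat: float, n: int) -> float:
    """Paired-design effect size dz = t / sqrt(n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(t_stat) / math.sqrt(n)


def percent_reduction(pre_mean: float, post_mean: float) -> float:
    """Percent reduction from pre to post: 100 * (pre - post) / pre."""
    if pre_mean == 0:
        raise ValueError("pre_mean must be non-zero")
    return 100.0 * (pre_mean - post_mean) / pre_mean


def paired_t(pre, post) -> PairedResult:
    """Two-sided paired t-test with dz and percent reduction attached."""
    x = np.asarray(pre, dtype=float)
    y = np.asarray(post, dtype=float)
    if x.shape != y.shape:
        raise ValueError("pre and post must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    if np.std(diff, ddof=1) == 0.0:
        raise ValueError("zero-variance differences: t-test undefined")
    res = stats.ttest_rel(x, y)
    t = float(res.statistic)
    return PairedResult(
        t_stat=t,
        df=n - 1,
        p_value=float(res.pvalue),
        cohens_dz=cohens_dz(t, n),
        pre_mean=float(x.mean()),
        pre_sd=float(x.std(ddof=1)),
        post_mean=float(y.mean()),
        post_sd=float(y.std(ddof=1)),
        mean_diff=float(diff.mean()),
        pct_reduction=percent_reduction(float(x.mean()), float(y.mean())),
    )


def classify_fsq(score: float) -> str:
    """FSQ severity stratum: high / moderate / low_moderate / excluded."""
    if score < 0:
        raise ValueError("FSQ score must be non-negative")
    if score >= 80:
        return "high"
    if score >= 50:
        return "moderate"
    if score >= 40:
        return "low_moderate"
    return "excluded"


@dataclass
class PSQScores:
    anxiety_end: float
    anxiety_peak: float
    avoidance_index: float
    control_index: float
    presence_index: float
    tolerability_index: float
    readiness: float
    adverse_event: bool
    step_up_ready: bool

    def to_dict(self) -> dict:
        return asdict(self)


_PSQ_RANGES = {
    **{k: (0, 100) for k in ("A1", "A2")},
    **{k: (1, 7) for k in (
        "AV1", "AV2", "AV3", "C1", "C2", "C3",
        "P1", "P2", "P3", "T1", "T2", "T3", "R1",
    )},
    "AE": (0, 1),
}


def score_psq(item_responses) -> PSQScores:
    """Score one respondent's 15 PSQ items into domain indices."""
    r = dict(item_responses)
    for item, (lo, hi) in _PSQ_RANGES.items():
        if item not in r:
            raise ValueError(f"missing PSQ item {item!r}")
        if not lo <= float(r[item]) <= hi:
            raise ValueError(f"PSQ item {item!r} out of range [{lo}, {hi}]: {r[item]}")
    mean = lambda *items: float(np.mean([float(r[i]) for i in items]))
    tolerability = float(np.mean([float(r["T1"]), 8.0 - float(r["T2"]), float(r["T3"])]))
    readiness = float(r["R1"])
    ae = bool(int(r["AE"]))
    return PSQScores(
        anxiety_end=float(r["A1"]),
        anxiety_peak=float(r["A2"]),
        avoidance_index=mean("AV1", "AV2", "AV3"),
        control_index=mean("C1", "C2", "C3"),
        presence_index=mean("P1", "P2", "P3"),
        tolerability_index=tolerability,
        readiness=readiness,
        adverse_event=ae,
        step_up_ready=(readiness >= 5 and tolerability >= 5 and not ae),
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (opt-in; not applied by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def fsq_change_table(fsq: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum and total FSQ change summary (pre/post means, percent
    reduction, paired t) from a cohort FSQ table with columns
    ``stratum, fsq_pre, fsq_post``."""
    rows = []
    groups = [(label, sub) for label, sub in fsq.groupby("stratum", sort=False)]
    groups.append(("total", fsq))
    for label, sub in groups:
        res = paired_t(sub["fsq_pre"], sub["fsq_post"])
        rows.append(
            {
                "group": label,
                "n": len(sub),
                "pre_mean": res.pre_mean,
                "pre_sd": res.pre_sd,
                "post_mean": res.post_mean,
                "post_sd": res.post_sd,
                "mean_diff": -res.mean_diff,
                "pct_reduction": res.pct_reduction,
                "t": res.t_stat,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def paired_outcomes_table(pairs: dict) -> pd.DataFrame:
    """Paired t / dz summary for several measures.

    ``pairs`` maps measure name -> (pre, post) vectors.
    """
    rows = []
    for name, (pre, post) in pairs.items():
        res = paired_t(pre, post)
        rows.append({"measure": name, **res.to_dict()})
    return pd.DataFrame(rows)
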