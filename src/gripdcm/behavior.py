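"""Precision-grip performance scoring and group statistics.

Task performance is the root-mean-square error (RMSE) between the traced
force and the horizontal target line (10 % of maximal voluntary
contraction) over the full trial. Scores are the negative natural log of
the RMSE, so higher scores mean better precision. Group differences are
assessed with a classic one-way ANOVA followed by pairwise pooled-variance
t-tests with Holm step-down adjustment.

Pairwise tests use pooled variance of the two groups with df = n1+n2−2;
the convention is recorded in the output table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ForceTrace:
    """A pinch-force trace: ``samples`` in Newtons (or any force unit),
    ``target`` as a fraction of MVC, ``mvc`` in the sample unit."""

    samples: np.ndarray
    rate: float
    target: float = 0.10
    mvc: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size == 0:
            raise ValueError("empty force trace")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not 0.0 < self.target < 1.0:
            raise ValueError("target must be a fraction of MVC in (0, 1)")
        if self.mvc <= 0:
            raise ValueError("MVC must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def target_force(self) -> float:
        return self.target * self.mvc


@dataclass(frozen=True)
class PrecisionScore:
    """RMSE around the target line and its reverse-coded log transform."""

    rmse: float
    score: float


def compute_precision_score(trace: ForceTrace) -> PrecisionScore:
    """RMSE from the target line over the full trace; score = −ln(rmse)."""
    dev = trace.samples - trace.target_force
    rmse = float(np.sqrt(np.mean(dev**2)))
    if rmse == 0.0:
        raise ValueError("degenerate trace: zero RMSE, log score undefined")
    return PrecisionScore(rmse=rmse, score=float(-np.log(rmse)))


@dataclass
class GroupStats:
    F: float
    df: tuple[int, int]
    p: float
    pairwise: pd.DataFrame
    note: str = "pairwise: two-sided pooled-variance t-tests, df = n1+n2-2, Holm-adjusted"


def group_statistics(scores, groups) -> GroupStats:
    """One-way ANOVA over groups plus Holm-adjusted pairwise t-tests.

    ``scores`` may be floats or :class:`PrecisionScore`; ``groups`` are
    labels of equal length. Every group needs at least two members.
    """
    vals = np.array([s.score if isinstance(s, PrecisionScore) else float(s)
                     for s in scores])
    groups = np.asarray(groups)
    if vals.size != groups.size:
        raise ValueError("scores and groups must align")
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    by = {g: vals[groups == g] for g in labels}
    if any(v.size < 2 for v in by.values()):
        raise ValueError("every group needs at least two scores")

    F, p = stats.f_oneway(*[by[g] for g in labels])
    df = (len(labels) - 1, vals.size - len(labels))

    rows = []
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1:]:
            t, praw = stats.ttest_ind(by[g1], by[g2], equal_var=True)
            rows.append({"group1": g1, "group2": g2, "t": float(t),
                         "df": by[g1].size + by[g2].size - 2, "p_raw": float(praw)})
    table = pd.DataFrame(rows)
    table["p_holm"] = multipletests(table["p_raw"].to_numpy(), method="holm")[1]
    return GroupStats(F=float(F), df=df, p=float(p), pairwise=table)


def scores_table(subject_ids, groups, traces) -> pd.DataFrame:
    """Score a set of traces into the (subject_id, group, rmse, score) layout."""
    recs = []
    for sid, g, tr in zip(subject_ids, groups, traces):
        ps = compute_precision_score(tr)
        recs.append({"subject_id": sid, "group": g, "rmse": ps.rmse, "score": ps.score})
    return pd.DataFrame(recs)
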