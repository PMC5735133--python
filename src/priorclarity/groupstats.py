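"""Between-group and brain-behaviour statistics on model outputs.

Group comparisons of fitted parameters use the Wilcoxon rank-sum (Mann-
Whitney U) test with an exact null obtained by convolution over midranks
— appropriate for the small samples here (11 vs 11).  Associations
between behavioural parameters and neural measures are reported as both
Pearson and Spearman coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EXACT_N_LIMIT = 24


@dataclass(frozen=True)
class GroupComparison:
    statistic_name: str
    u_value: float
    u_complement: float
    p_two_sided: float
    n1: int
    n2: int
    mode: str


@dataclass(frozen=True)
class AssociationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int


def _exact_rank_sum_distribution(ranks: np.ndarray, n1: int):
    """Distribution of the first sample's rank sum under exchangeability.

    Convolution (shift-algorithm) over doubled midranks, which are always
    integers; returns (support_of_2*R1, counts).
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    # dp[j, s] = number of j-subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in r2:
        upper = min(n1, len(r2))
        for j in range(upper, 0, -1):
            dp[j, r:] += dp[j - 1, : total + 1 - r]
    counts = dp[n1]
    support = np.nonzero(counts)[0]
    return support, counts[support]


def rank_sum_test(x, y, mode: str = "exact") -> GroupComparison:
    """Wilcoxon rank-sum / Mann-Whitney U test with midranks for ties.

    ``u_value`` counts (x, y) pairs with x > y (ties count one half); the
    complement ``n1*n2 - U`` is also reported since conventions differ.
    Exact mode convolves the permutation null of the rank sum (feasible
    for n1 + n2 <= 24); ``normal`` uses the tie-corrected Gaussian
    approximation with continuity correction.  Two-sided p doubles the
    smaller tail, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0
    u_comp = n1 * n2 - u

    if mode == "exact":
        if n1 + n2 > EXACT_N_LIMIT:
            raise ValueError(
                f"exact null infeasible for n1+n2={n1 + n2} > {EXACT_N_LIMIT}; "
                "use mode='normal'"
            )
        support, counts = _exact_rank_sum_distribution(ranks, n1)
        total = counts.sum()
        obs = int(np.rint(2.0 * r1))
        p_low = counts[support <= obs].sum() / total
        p_high = counts[support >= obs].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
    elif mode == "normal":
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / np.sqrt(var)
            p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    else:
        raise ValueError("mode must be 'exact' or 'normal'")
    return GroupComparison("rank_sum_U", float(u), float(u_comp), float(p),
                           n1, n2, mode)


def association(x, y, kind: str = "pearson") -> AssociationResult:
    """Pearson and Spearman association with two-sided t-approximation p.

    Both coefficients are always computed; ``kind`` only validates the
    caller's primary choice.
    """
    if kind not in ("pearson", "spearman"):
        raise ValueError("kind must be 'pearson' or 'spearman'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return AssociationResult(
        float(pr.statistic), float(pr.pvalue),
        float(sr.statistic), float(sr.pvalue), int(x.size),
    )


def congruency_effect(exp1: pd.DataFrame) -> dict:
    """Match-minus-mismatch mean clarity difference, overall and per channel.

    Expects columns ``congruency``, ``channels``, ``rating``.
    """
    present = set(exp1["congruency"].unique())
    if not {"match", "mismatch"} <= present:
        raise ValueError("both match and mismatch trials are required")
    m = exp1[exp1["congruency"] == "match"]
    mm = exp1[exp1["congruency"] == "mismatch"]
    overall = float(m["rating"].mean() - mm["rating"].mean())
    per_channel = {}
    for ch in sorted(exp1["channels"].unique()):
        ms = m[m["channels"] == ch]
        mms = mm[mm["channels"] == ch]
        if ms.empty or mms.empty:
            raise ValueError(f"channel level {ch} missing one congruency cell")
        per_channel[int(ch)] = float(ms["rating"].mean() - mms["rating"].mean())
    return {"overall": overall, "per_channel": per_channel}
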