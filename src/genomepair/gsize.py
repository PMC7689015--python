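"""Flow-cytometry genome-size arithmetic and accession comparisons.

The 1C DNA content of a sample is the ratio of its G1 fluorescence peak to
the internal standard's G1 peak, scaled by the standard's known 1C value
(default *Pisum sativum*, 4.45 pg).  Picograms convert to megabases at
978 Mbp per pg.  Accession differences are tested with one-way ANOVA and a
Tukey-style post hoc implemented by seeded permutation of the studentized
range, summarised as a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: megabase pairs per picogram of DNA
MBP_PER_PG = 978.0

#: 1C DNA content of the Pisum sativum internal standard, in pg
DEFAULT_STANDARD_1C_PG = 4.45


@dataclass
class FlowSample:
    """One flow-cytometry measurement: accession, replicate and the G1 peak
    means of the sample and the internal standard (channel units)."""
    accession: str
    replicate: int
    sample_g1_mean: float
    standard_g1_mean: float


def estimate_1c(sample: FlowSample | float,
                standard_g1_mean: float | None = None,
                standard_1c_pg: float = DEFAULT_STANDARD_1C_PG) -> float:
    """1C DNA content in pg: (sample peak / standard peak) x standard 1C."""
    if isinstance(sample, FlowSample):
        s, r = sample.sample_g1_mean, sample.standard_g1_mean
    else:
        s, r = sample, standard_g1_mean
    if s is None or r is None or s <= 0 or r <= 0 or standard_1c_pg <= 0:
        raise ValueError("peak means and standard 1C must be positive")
    return (s / r) * standard_1c_pg


def pg_to_mbp(pg: float, rounded: bool = True) -> float:
    """Haploid genome size in Mbp (978 Mbp/pg); integer-rounded by default."""
    if pg < 0:
        raise ValueError("pg must be non-negative")
    mbp = pg * MBP_PER_PG
    return float(round(mbp)) if rounded else mbp


def percent_difference(a: float, b: float, headline: bool = False) -> float:
    """100 x (a - b) / b; integer-rounded when ``headline``, else 2 d.p."""
    if b <= 0:
        raise ValueError("reference value must be positive")
    pct = 100.0 * (a - b) / b
    return float(round(pct)) if headline else round(pct, 2)


class AnovaResult(NamedTuple):
    F: float
    df_between: int
    df_within: int
    p: float


def anova_oneway(groups: Mapping[str, Sequence[float]] |
                 Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA decomposition; the p-value is the F upper
    tail (regularized incomplete beta)."""
    values = list(groups.values()) if isinstance(groups, Mapping) \
        else list(groups)
    if len(values) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(v, dtype=float) for v in values]
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs at least two values")
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b = len(arrs) - 1
    df_w = all_vals.size - len(arrs)
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(0.0, df_b, df_w, 1.0)
        return AnovaResult(np.inf, df_b, df_w, 0.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p)


def tukey_groups(groups: Mapping[str, Sequence[float]],
                 alpha: float = 0.05,
                 n_perm: int = 10_000,
                 seed: int = 0) -> dict[str, str]:
    """Compact letter display from permutation Tukey-style comparisons.

    Pairwise studentized ranges q_ij = |mean_i - mean_j| / sqrt(MSE/2 *
    (1/n_i + 1/n_j)) are compared with the permutation distribution of the
    maximum studentized range over all pairs (pooled observations permuted,
    family-wise as in Tukey's HSD); letters are assigned greedily so that
    accessions sharing a letter are never significantly different.
    """
    names = list(groups)
    arrs = [np.asarray(groups[k], dtype=float) for k in names]
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs at least two values")
    sizes = [a.size for a in arrs]
    k = len(arrs)
    pooled = np.concatenate(arrs)
    df_w = pooled.size - k

    def max_q(values: np.ndarray) -> tuple[float, np.ndarray]:
        parts = np.split(values, np.cumsum(sizes)[:-1])
        means = np.array([p.mean() for p in parts])
        ssw = sum(((p - p.mean()) ** 2).sum() for p in parts)
        mse = ssw / df_w if df_w > 0 else 0.0
        qm = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(mse / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
                q = np.inf if se == 0 and means[i] != means[j] else (
                    0.0 if se == 0 else abs(means[i] - means[j]) / se)
                qm[i, j] = qm[j, i] = q
        return float(qm.max(initial=0.0)), qm

    _, q_obs = max_q(pooled)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    work = pooled.copy()
    for b in range(n_perm):
        rng.shuffle(work)
        null_max[b], _ = max_q(work)
    pvals = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            p = (1 + np.count_nonzero(null_max >= q_obs[i, j])) / (n_perm + 1)
            pvals[i, j] = pvals[j, i] = p

    # greedy compact letter display over groups sorted by mean
    order = sorted(range(k), key=lambda i: arrs[i].mean())
    letter_sets: list[list[int]] = []
    for gi in order:
        placed = False
        for members in letter_sets:
            if all(pvals[gi, m] >= alpha for m in members):
                members.append(gi)
                placed = True
        if not placed:
            letter_sets.append([gi])
    letters = {names[i]: "" for i in range(k)}
    for li, members in enumerate(letter_sets):
        ch = chr(ord("a") + li)
        for m in members:
            letters[names[m]] += ch
    return {n: "".join(sorted(l)) for n, l in letters.items()}


def shapiro_normality(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000; constant input is an
    error (zero variance)."""
    arr = np.asarray(values, dtype=float)
    if not (3 <= arr.size <= 5000):
        raise ValueError("Shapiro test requires 3 <= n <= 5000")
    if np.ptp(arr) == 0:
        raise ValueError("zero variance: Shapiro test undefined")
    w, p = stats.shapiro(arr)
    return float(w), float(p)


def size_report(samples: Sequence[FlowSample],
                standard_1c_pg: float = DEFAULT_STANDARD_1C_PG
                ) -> pd.DataFrame:
    """Per-replicate 1C (pg) and size (Mbp) with per-accession mean and
    median columns."""
    rows = []
    for s in samples:
        c1 = estimate_1c(s, standard_1c_pg=standard_1c_pg)
        rows.append((s.accession, s.replicate, c1, pg_to_mbp(c1)))
    df = pd.DataFrame(rows, columns=["accession", "replicate", "c1_pg",
                                     "size_mbp"])
    agg = df.groupby("accession")["c1_pg"].agg(["mean", "median"])
    df = df.merge(agg.rename(columns={"mean": "accession_mean_c1",
                                      "median": "accession_median_c1"}),
                  on="accession")
    return df
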