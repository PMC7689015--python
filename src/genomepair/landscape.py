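"""Repeat landscape summaries: windowed density tracks, TE-order
proportion tables, chi-square homogeneity tests and genome-fraction
arithmetic.

Overlapping annotations of the same class are merged before any bp is
counted, so per-class fractions stay in [0, 1]; features of different
classes may overlap and are counted in both classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaincc

from .formats import Annotation, classify_feature, TE_CLASSES
from .intervals import intersect_intervals, merge_intervals, total_length


def _class_intervals(annotations: Iterable[Annotation],
                     classes: Sequence[str]) -> dict[str, dict[str, list]]:
    """Per seqid, per class, merged 0-based half-open intervals."""
    raw: dict[str, dict[str, list]] = {}
    cset = set(classes)
    for a in annotations:
        cls = classify_feature(a.feature_type)
        if cls not in cset:
            continue
        raw.setdefault(a.seqid, {}).setdefault(cls, []).append(a.interval())
    return {
        seqid: {cls: merge_intervals(ivs) for cls, ivs in per.items()}
        for seqid, per in raw.items()
    }


def compute_density_tracks(annotations: Iterable[Annotation],
                           chrom_lengths: Mapping[str, int],
                           window: int = 100_000,
                           classes: Sequence[str] = TE_CLASSES
                           ) -> pd.DataFrame:
    """Fraction of each window covered per feature class.

    Returns a long-form frame with columns ``seqid``, ``window_start``,
    ``window_end``, ``feature_class``, ``fraction``; the last window of a
    chromosome may be short.
    """
    if window < 1_000:
        raise ValueError("window must be >= 1,000 bp")
    merged = _class_intervals(annotations, classes)
    for seqid in merged:
        if seqid not in chrom_lengths:
            raise ValueError(f"unknown sequence {seqid!r} in annotations")
    rows = []
    for seqid, L in chrom_lengths.items():
        per = merged.get(seqid, {})
        for ws in range(0, L, window):
            we = min(ws + window, L)
            for cls in classes:
                ivs = per.get(cls, [])
                cov = total_length(intersect_intervals(ivs, [(ws, we)]))
                rows.append((seqid, ws, we, cls, cov / (we - ws)))
    return pd.DataFrame(
        rows, columns=["seqid", "window_start", "window_end",
                       "feature_class", "fraction"])


def te_order_proportions(annotations: Iterable[Annotation],
                         chrom_lengths: Mapping[str, int],
                         orders: Sequence[str] = TE_CLASSES) -> pd.DataFrame:
    """Per chromosome and TE order: merged cumulative bp and percent of the
    chromosome length.  Rows are chromosomes; a two-level column index
    carries ``cum_bp`` and ``pct``."""
    merged = _class_intervals(annotations, orders)
    data = {}
    for seqid, L in chrom_lengths.items():
        per = merged.get(seqid, {})
        row = {}
        for cls in orders:
            bp = total_length(per.get(cls, []))
            row[("cum_bp", cls)] = bp
            row[("pct", cls)] = 100.0 * bp / L
        data[seqid] = row
    df = pd.DataFrame.from_dict(data, orient="index")
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return df.sort_index()


def chi_square_homogeneity(table: Sequence[Sequence[float]] | np.ndarray
                           ) -> tuple[float, int, float]:
    """Pearson chi-square test of homogeneity on a counts matrix.

    Expected counts come from the row/column margins; the p-value is the
    upper tail of the chi-square distribution with (r-1)(c-1) degrees of
    freedom, evaluated via the regularized incomplete gamma function.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows <= 0) or np.any(cols <= 0):
        raise ValueError("zero row or column margin")
    expected = np.outer(rows, cols) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(gammaincc(df / 2.0, stat / 2.0))
    return stat, df, p


def genome_te_fraction(cum_te_bp: float, genome_size_bp: float) -> float:
    """Percent of the genome occupied by TEs, rounded to 2 decimals."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    return round(100.0 * cum_te_bp / genome_size_bp, 2)


def rescale_fraction(pct_old: float, size_old: float, size_new: float) -> float:
    """Rescale a genome-fraction percentage from one genome-size estimate to
    another (exact inverse proportionality), rounded to 2 decimals."""
    if size_old <= 0 or size_new <= 0:
        raise ValueError("genome sizes must be positive")
    return round(pct_old * size_old / size_new, 2)
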