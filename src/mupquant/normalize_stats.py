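"""Normalization strategies, paired differential testing and frequency classes.

Three normalization strategies are compared throughout:

``none``
    raw areas, retaining total-concentration changes on the MS level;
``tas``
    total area sums — each sample is rescaled so its summed intensity
    equals the across-sample mean total;
``manual``
    division by an external per-sample scale factor, canonically the
    measured total protein concentration (ug/uL).

Differential expression between the paired time points uses two-sided
paired t-tests per proteoform, Bonferroni-Dunn control (alpha / number
of tests) and a two-fold change filter.  Detection frequencies over
individuals are binned into the ubiquitous / common / uncommon / rare
classes used for urinary proteoform surveys.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ProteoformIntensityTable

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationStrategy",
    "ProteoformResult",
    "FrequencyClass",
    "ConcordanceReport",
    "normalize",
    "paired_test",
    "bonferroni_dunn",
    "make_results",
    "significance_filter",
    "classify_frequency",
    "detection_frequency",
    "concordance",
]


@dataclass(frozen=True)
class NormalizationStrategy:
    """One of the three per-sample scaling rules.

    ``manual`` requires ``scale_factors`` (one positive factor per
    sample, e.g. protein concentrations); ``tas`` computes its factors
    from the data; ``none`` leaves the table unchanged.
    """

    kind: Literal["none", "tas", "manual"]
    scale_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind == "manual":
            if self.scale_factors is None:
                raise ValueError("manual normalization requires scale factors")
            if (self.scale_factors <= 0).any():
                bad = self.scale_factors[self.scale_factors <= 0]
                raise ValueError(f"non-positive scale factors for {list(bad.index)}")
        elif self.kind not in ("none", "tas"):
            raise ValueError(f"unknown normalization kind {self.kind!r}")


def normalize(
    table: ProteoformIntensityTable, strategy: NormalizationStrategy
) -> ProteoformIntensityTable:
    """Apply a normalization strategy, returning a new intensity table."""
    df = table.values
    if strategy.kind == "none":
        out = df.copy()
    elif strategy.kind == "tas":
        totals = df.sum(skipna=True)
        if (totals <= 0).any():
            bad = list(totals.index[totals <= 0])
            raise ValueError(f"samples with non-positive total area: {bad}")
        out = df * (totals.mean() / totals)
    else:  # manual
        factors = strategy.scale_factors
        missing = [s for s in df.columns if s not in factors.index]
        if missing:
            raise ValueError(f"missing scale factor for samples: {missing}")
        out = df / factors.reindex(df.columns)
    return ProteoformIntensityTable(
        values=out,
        level=table.level,
        rollup=table.rollup,
        library_context=table.library_context,
    )


# ---------------------------------------------------------------------------
# Paired testing


def paired_test(
    table: ProteoformIntensityTable | pd.DataFrame,
    metadata: pd.DataFrame,
    min_pairs: int = 3,
    log2: bool = False,
) -> pd.DataFrame:
    """Two-sided paired t-test per proteoform across the two time points.

    ``metadata`` must carry ``individual`` and ``time_point`` ('t1'/'t2')
    per sample.  Only individuals with the proteoform detected at both
    time points form pairs; proteoforms with fewer than ``min_pairs``
    pairs are excluded (logged).  Fold change is the ratio of group
    means mean(t2)/mean(t1) over the paired values; with ``log2`` the
    t-test runs on log2-transformed areas instead of the raw scale.

    Returns a DataFrame indexed by proteoform with columns
    ``fold_change``, ``p_raw``, ``n_pairs`` and ``note`` (empty, or
    ``zero_variance`` when the paired differences have no spread and the
    p-value is undefined).
    """
    df = table.values if isinstance(table, ProteoformIntensityTable) else table
    meta = metadata.loc[df.columns]
    t1 = meta.index[meta["time_point"] == "t1"]
    t2 = meta.index[meta["time_point"] == "t2"]
    ind1 = meta.loc[t1, "individual"]
    ind2 = meta.loc[t2, "individual"]
    both = sorted(set(ind1) & set(ind2))
    s1 = {i: s for s, i in ind1.items()}
    s2 = {i: s for s, i in ind2.items()}

    rows = {}
    for proteoform, values in df.iterrows():
        a = np.array([values[s1[i]] for i in both], dtype=float)
        b = np.array([values[s2[i]] for i in both], dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        n_pairs = int(ok.sum())
        if n_pairs < min_pairs:
            logger.info(
                "excluding %s: %d pairs < min_pairs=%d", proteoform, n_pairs, min_pairs
            )
            continue
        a, b = a[ok], b[ok]
        fold = float(b.mean() / a.mean()) if a.mean() != 0 else math.nan
        x1, x2 = (np.log2(a), np.log2(b)) if log2 else (a, b)
        diffs = x2 - x1
        if np.allclose(diffs, diffs[0]) and np.isclose(diffs.std(), 0):
            rows[proteoform] = (fold, math.nan, n_pairs, "zero_variance")
            continue
        t_res = stats.ttest_rel(x2, x1)
        rows[proteoform] = (fold, float(t_res.pvalue), n_pairs, "")
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["fold_change", "p_raw", "n_pairs", "note"]
    )
    out.index.name = "proteoform"
    return out


def bonferroni_dunn(
    p_raw: Sequence[float], alpha: float = 0.05
) -> tuple[float, list[bool]]:
    """Family-wise error control: alpha_adjusted = alpha / k.

    Returns the adjusted threshold and per-test significance calls
    (p < alpha_adjusted; undefined p-values are never significant).
    """
    k = len(p_raw)
    if k == 0:
        raise ValueError("no tests to correct")
    alpha_adjusted = alpha / k
    calls = [(not math.isnan(p)) and p < alpha_adjusted for p in p_raw]
    return alpha_adjusted, calls


@dataclass(frozen=True)
class ProteoformResult:
    """Differential-expression outcome for one proteoform.

    ``significant`` requires both the two-fold rule (fold > 2 up, or
    < 0.5 down) and p_raw below the Bonferroni-Dunn-adjusted threshold
    alpha / k_tests.
    """

    proteoform: str
    fold_change: float
    p_raw: float
    k_tests: int
    alpha_adjusted: float
    significant: bool
    direction: Literal["up", "down", "none"]


def make_results(
    test_table: pd.DataFrame,
    alpha: float = 0.05,
    fold_threshold: float = 2.0,
) -> list[ProteoformResult]:
    """Combine paired-test output with multiple-testing correction.

    k is the number of proteoforms actually tested (rows of
    ``test_table``), matching the convention that adjusted thresholds
    depend on the number of proteoforms quantified.
    """
    k = len(test_table)
    alpha_adjusted, _ = bonferroni_dunn(list(test_table["p_raw"]), alpha)
    results = []
    for proteoform, row in test_table.iterrows():
        fold = float(row["fold_change"])
        p = float(row["p_raw"])
        if fold > fold_threshold:
            direction = "up"
        elif fold < 1.0 / fold_threshold:
            direction = "down"
        else:
            direction = "none"
        significant = (
            direction != "none" and not math.isnan(p) and p < alpha_adjusted
        )
        results.append(
            ProteoformResult(
                proteoform=str(proteoform),
                fold_change=fold,
                p_raw=p,
                k_tests=k,
                alpha_adjusted=alpha_adjusted,
                significant=significant,
                direction=direction if significant else direction,
            )
        )
    return results


def significance_filter(
    results: Sequence[ProteoformResult],
) -> list[ProteoformResult]:
    """Retain proteoforms regulated more than two-fold (|log2 fold| > 1)
    with p below the adjusted threshold; direction is annotated."""
    kept = []
    for r in results:
        if math.isnan(r.fold_change) or r.fold_change <= 0:
            continue
        if abs(math.log2(r.fold_change)) > 1 and not math.isnan(r.p_raw) and (
            r.p_raw < r.alpha_adjusted
        ):
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# Detection frequency classes


@dataclass(frozen=True)
class FrequencyClass:
    proteoform: str
    frequency: int  # integer percent
    frequency_class: Literal["ubiquitous", "common", "uncommon", "rare", "unclassified"]


def classify_frequency(percent: float) -> str:
    """Bin an integer detection percentage.

    ubiquitous = 100; common = 50-70; uncommon = 30-49; rare < 10.
    Percentages in the gaps (10-29, 71-99) are reported as
    ``unclassified`` with a warning rather than silently re-binned.
    """
    p = int(round(percent))
    if p == 100:
        return "ubiquitous"
    if 50 <= p <= 70:
        return "common"
    if 30 <= p <= 49:
        return "uncommon"
    if p < 10:
        return "rare"
    warnings.warn(
        f"detection frequency {p}% falls outside the defined class bins",
        stacklevel=2,
    )
    return "unclassified"


def detection_frequency(
    detections: pd.DataFrame | Mapping[str, float],
    n_total: int | None = None,
    known_individuals: Sequence[str] | None = None,
) -> list[FrequencyClass]:
    """Frequency = individuals expressing a proteoform / total sample size.

    ``detections`` is a proteoform x individual boolean table (or a
    ready-made mapping of proteoform to detected count).  Frequencies
    are rounded to integer percent before binning.
    """
    if isinstance(detections, pd.DataFrame):
        if known_individuals is not None:
            unknown = set(detections.columns) - set(known_individuals)
            if unknown:
                raise ValueError(f"detections reference unknown individuals: {sorted(unknown)}")
        if n_total is None:
            n_total = detections.shape[1]
        counts = {acc: int(row.sum()) for acc, row in detections.iterrows()}
    else:
        counts = dict(detections)
        if n_total is None:
            raise ValueError("n_total is required with pre-counted detections")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    out = []
    for acc, detected in counts.items():
        pct = int(round(100.0 * detected / n_total))
        out.append(FrequencyClass(acc, pct, classify_frequency(pct)))
    return out


# ---------------------------------------------------------------------------
# MS1/MS2 concordance


@dataclass
class ConcordanceReport:
    """Agreement of fold changes between two quantification strategies."""

    pearson_r: float
    n_shared: int
    fold_ratios: dict[str, float]  # max(f1/f2, f2/f1) per proteoform
    discordant: list[str]
    ratio_threshold: float


def concordance(
    fold_a: Mapping[str, float],
    fold_b: Mapping[str, float],
    ratio_threshold: float = 2.0,
) -> ConcordanceReport:
    """Pearson correlation of log2 fold changes over shared proteoforms.

    Proteoforms whose fold changes disagree by more than
    ``ratio_threshold`` (in either direction) are listed as discordant.
    Requires at least three shared proteoforms.
    """
    shared = sorted(
        k
        for k in set(fold_a) & set(fold_b)
        if not (math.isnan(fold_a[k]) or math.isnan(fold_b[k]))
        and fold_a[k] > 0
        and fold_b[k] > 0
    )
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared proteoforms, got {len(shared)}")
    la = np.log2([fold_a[k] for k in shared])
    lb = np.log2([fold_b[k] for k in shared])
    if np.allclose(la, lb):
        r = 1.0  # identical profiles, including the zero-variance case
    else:
        r = float(stats.pearsonr(la, lb).statistic)
    ratios = {
        k: float(max(fold_a[k] / fold_b[k], fold_b[k] / fold_a[k])) for k in shared
    }
    discordant = sorted(k for k, v in ratios.items() if v > ratio_threshold)
    return ConcordanceReport(
        pearson_r=r,
        n_shared=len(shared),
        fold_ratios=ratios,
        discordant=discordant,
        ratio_threshold=ratio_threshold,
    )
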