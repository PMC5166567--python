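"""Relative proteoform composition and the family's share of total intensity.

Relative composition uses a 100% method on unique-peptide areas: each
proteoform's score is the sum of its proteotypic peptide areas divided
by its number of unique peptides (normalizing for unequal proteotypic
coverage), and scores are rescaled to sum to 100%.  Equal ionization
efficiency across the family's peptides is assumed — justified by the
high sequence homology, and a known bias source otherwise.  Proteoforms
below a share threshold are pooled into an "Others" bin.

The family fraction compares the summed areas of all family-derived
peptides (unique and shared) against the total intensity of everything
quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .quantify import IonLibrary

__all__ = ["CompositionReport", "relative_composition", "family_fraction"]

OTHERS_LABEL = "Others"


@dataclass
class CompositionReport:
    """Relative shares per proteoform with an aggregate "Others" bin.

    ``shares`` holds proteoforms at or above ``threshold`` percent;
    ``others_bin`` aggregates the rest.  Shares plus the bin sum to 100.
    """

    shares: dict[str, float]
    others_bin: float
    threshold: float
    raw_shares: dict[str, float] = field(default_factory=dict)
    family_fraction: float | None = None

    def as_json_records(self) -> list[dict[str, float | str]]:
        """Pie-chart-ready (label, percent) records, Others last."""
        records: list[dict[str, float | str]] = [
            {"label": k, "percent": v}
            for k, v in sorted(self.shares.items(), key=lambda kv: -kv[1])
        ]
        if self.others_bin > 0:
            records.append({"label": OTHERS_LABEL, "percent": self.others_bin})
        return records


def relative_composition(
    peptide_areas: pd.DataFrame,
    library: IonLibrary,
    unique_counts: Mapping[str, int] | None = None,
    threshold: float = 5.0,
    per_sample: bool = False,
) -> CompositionReport | pd.DataFrame:
    """Relative proteoform composition by the unique-peptide-normalized
    100% method.

    Per proteoform, score = (summed areas of its unique peptides across
    all samples) / number of unique peptides; scores are normalized to
    100%.  ``unique_counts`` defaults to the counts in the active ion
    library.  With ``per_sample`` a proteoform x sample percentage table
    is returned instead of the pooled report.
    """
    if unique_counts is None:
        unique_counts = library.unique_peptide_counts()
    bad = [p for p, c in unique_counts.items() if c <= 0]
    if bad:
        raise ValueError(f"non-positive unique-peptide counts for {bad}")
    pep_map = library.peptide_to_proteoform
    present = [p for p in peptide_areas.index if p in pep_map]
    groups = pd.Series({p: pep_map[p] for p in present})
    counts = pd.Series(unique_counts, dtype=float)

    if per_sample:
        per_prot = peptide_areas.loc[present].groupby(groups).sum(min_count=1)
        scores = per_prot.div(counts.reindex(per_prot.index), axis=0)
        totals = scores.sum(skipna=True)
        if (totals <= 0).any():
            raise ValueError("zero total score in at least one sample")
        return 100.0 * scores / totals

    summed = peptide_areas.loc[present].sum(axis=1, skipna=True)
    per_prot = summed.groupby(groups).sum()
    scores = per_prot / counts.reindex(per_prot.index)
    total = float(scores.sum())
    if not total > 0:
        raise ValueError("zero total score: nothing to normalize")
    raw = (100.0 * scores / total).to_dict()
    shares = {k: v for k, v in raw.items() if v >= threshold}
    others = float(sum(v for k, v in raw.items() if k not in shares))
    # re-express retained shares so shares + Others sum to exactly 100
    retained_total = sum(shares.values())
    if retained_total > 0:
        scale = (100.0 - others) / retained_total
        shares = {k: v * scale for k, v in shares.items()}
    return CompositionReport(
        shares=shares, others_bin=others, threshold=threshold, raw_shares=raw
    )


def family_fraction(
    all_peptide_areas: pd.DataFrame,
    family_peptides: Iterable[str],
) -> tuple[float, float, float]:
    """Family share of total MS intensity, in percent.

    ``family_peptides`` should include every family-derived peptide,
    unique and shared between proteoforms.  Returns
    ``(overall_percent, per_sample_mean, per_sample_sd)`` where the
    overall figure pools all samples and the mean/sd summarize the
    per-sample fractions.
    """
    fam = set(family_peptides)
    unknown = fam - set(all_peptide_areas.index)
    if unknown:
        raise ValueError(f"family peptides not in matrix: {sorted(unknown)[:5]} ...")
    total_by_sample = all_peptide_areas.sum(skipna=True)
    if not float(total_by_sample.sum()) > 0:
        raise ValueError("zero total intensity")
    if not fam:
        return 0.0, 0.0, 0.0
    fam_by_sample = all_peptide_areas.loc[sorted(fam)].sum(skipna=True)
    overall = 100.0 * float(fam_by_sample.sum()) / float(total_by_sample.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        per_sample = 100.0 * fam_by_sample / total_by_sample
    per_sample = per_sample.dropna()
    return overall, float(per_sample.mean()), float(per_sample.std(ddof=1))
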