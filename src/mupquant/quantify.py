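"""Ion-library construction and roll-up of peptide/fragment areas to proteoforms.

The ion library is the set of proteotypic peptides (each mapping to
exactly one proteoform in the active database context) whose signals are
extracted across all runs.  Proteoform intensity is the roll-up (sum by
default) of the proteoform's library peptides; at the MS2 level,
fragment rows are first summed to peptide areas.  Detections absent in a
sample are propagated as missing values, not zeros, unless zero
imputation is requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_db import DatabaseContext, PeptideRecord

logger = logging.getLogger(__name__)

__all__ = [
    "IonLibrary",
    "LibraryEntry",
    "ProteoformIntensityTable",
    "build_library",
    "quantify_ms1",
    "quantify_ms2",
    "split_fragment_index",
]

Rollup = Literal["sum", "mean"]


@dataclass(frozen=True)
class LibraryEntry:
    peptide: str
    proteoform: str
    charges: tuple[int, ...] = ()
    fragments: tuple[str, ...] = ()


@dataclass
class IonLibrary:
    """Proteotypic peptides of one database context, one proteoform each."""

    entries: list[LibraryEntry]
    context_name: str

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.peptide in seen:
                raise ValueError(f"duplicate library peptide {e.peptide!r}")
            seen.add(e.peptide)

    @property
    def peptide_to_proteoform(self) -> dict[str, str]:
        return {e.peptide: e.proteoform for e in self.entries}

    @property
    def proteoforms(self) -> list[str]:
        return sorted({e.proteoform for e in self.entries})

    def unique_peptide_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.proteoform] = counts.get(e.proteoform, 0) + 1
        return counts


@dataclass
class ProteoformIntensityTable:
    """Proteoform x sample intensities at one quantification level."""

    values: pd.DataFrame
    level: Literal["MS1", "MS2"]
    rollup: Rollup
    library_context: str


def build_library(
    peptides: Sequence[PeptideRecord],
    context: DatabaseContext,
    observed_in: Mapping[str, bool] | set[str] | None = None,
    n_fragments: int = 6,
) -> IonLibrary:
    """Assemble the ion library from proteotypic peptides observed in >= 1 run.

    ``observed_in`` restricts the library to peptides actually seen in at
    least one identification run (None = all proteotypic peptides are
    taken as observed).  Raises when no proteotypic peptide survives,
    listing the proteoforms that are unidentifiable in this context.
    """
    if observed_in is None:
        observed = None
    elif isinstance(observed_in, set):
        observed = observed_in
    else:
        observed = {p for p, seen in observed_in.items() if seen}
    entries = []
    for rec in peptides:
        if not rec.proteotypic_in.get(context.name, False):
            continue
        if observed is not None and rec.sequence not in observed:
            continue
        entries.append(
            LibraryEntry(
                peptide=rec.sequence,
                proteoform=rec.parent,
                charges=tuple(sorted(rec.admissible_charges)),
                fragments=tuple(f"f{k + 1}" for k in range(n_fragments)),
            )
        )
    if not entries:
        covered = {
            rec.parent
            for rec in peptides
            if rec.proteotypic_in.get(context.name, False)
        }
        missing = sorted(
            {e.accession for e in context.entries if e.is_family_member} - covered
        )
        raise ValueError(
            "empty ion library: no proteotypic peptide observed; "
            f"unidentifiable proteoforms: {missing}"
        )
    return IonLibrary(entries=entries, context_name=context.name)


def _rollup_peptides(
    matrix: pd.DataFrame,
    library: IonLibrary,
    rollup: Rollup,
    zero_impute: bool,
) -> pd.DataFrame:
    pep_map = library.peptide_to_proteoform
    present = [p for p in matrix.index if p in pep_map]
    sub = matrix.loc[present]
    if zero_impute:
        sub = sub.fillna(0.0)
    groups = pd.Series({p: pep_map[p] for p in present}, name="proteoform")
    if rollup == "sum":
        # min_count=1 keeps a sample NaN when every peptide is absent
        rolled = sub.groupby(groups).sum(min_count=1)
    elif rollup == "mean":
        rolled = sub.groupby(groups).mean()
    else:
        raise ValueError(f"unknown rollup {rollup!r}")
    return rolled.reindex(library.proteoforms)


def quantify_ms1(
    matrix: pd.DataFrame,
    library: IonLibrary,
    rollup: Rollup = "sum",
    zero_impute: bool = False,
) -> ProteoformIntensityTable:
    """Roll peptide-level MS1 peak areas up to proteoform intensities.

    ``matrix`` is peptide x sample; library peptides missing from the
    matrix are treated as absent in every sample.  Absent detections
    (NaN) propagate as absent and are excluded from downstream means.
    """
    if matrix.shape[1] == 0:
        raise ValueError("quantification matrix has no samples")
    values = _rollup_peptides(matrix, library, rollup, zero_impute)
    return ProteoformIntensityTable(
        values=values, level="MS1", rollup=rollup, library_context=library.context_name
    )


def split_fragment_index(index: Sequence[str]) -> pd.Series:
    """Map fragment row labels 'PEPTIDE.fN' to their peptide part."""
    peptides = {}
    for label in index:
        pep, sep, frag = label.rpartition(".")
        if not sep or not frag.startswith("f"):
            raise ValueError(f"fragment row {label!r} is not of the form PEPTIDE.fN")
        peptides[label] = pep
    return pd.Series(peptides)


def quantify_ms2(
    fragment_matrix: pd.DataFrame,
    library: IonLibrary,
    rollup: Rollup = "sum",
    zero_impute: bool = False,
) -> ProteoformIntensityTable:
    """Roll fragment-level areas up to proteoform intensities.

    Fragment rows labelled ``peptide.fN`` are summed to a peptide area;
    roll-up to proteoforms then matches :func:`quantify_ms1`.  Fragment
    rows whose peptide is not in the library are ignored (count logged).
    """
    if fragment_matrix.shape[0] == 0:
        empty = pd.DataFrame(
            np.nan, index=library.proteoforms, columns=fragment_matrix.columns
        )
        return ProteoformIntensityTable(
            values=empty, level="MS2", rollup=rollup,
            library_context=library.context_name,
        )
    pep_of_row = split_fragment_index(fragment_matrix.index)
    in_lib = pep_of_row.isin(set(library.peptide_to_proteoform))
    n_ignored = int((~in_lib).sum())
    if n_ignored:
        logger.info("ignoring %d fragment rows outside the ion library", n_ignored)
    sub = fragment_matrix.loc[in_lib[in_lib].index]
    peptide_areas = sub.groupby(pep_of_row[in_lib]).sum(min_count=1)
    values = _rollup_peptides(peptide_areas, library, rollup, zero_impute)
    return ProteoformIntensityTable(
        values=values, level="MS2", rollup=rollup, library_context=library.context_name
    )
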