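"""Proteoform sequence databases, in-silico tryptic digestion and proteotypic mapping.

Quantification of near-identical proteoforms (e.g. the major urinary
proteins, MUPs, of house mice) hinges on *proteotypic* peptides: tryptic
peptides whose sequence maps to exactly one proteoform within a given
database context.  This module provides the sequence-level machinery:

* reading and redundancy-clearing of FASTA proteoform databases,
* tryptic digestion with missed cleavages (cleave C-terminal to K/R,
  suppressed before P),
* monoisotopic peptide masses with fixed carbamidomethylation of Cys,
* m/z admissibility against the instrument acquisition window,
* proteotypic-status determination per database context, with optional
  treatment of isoleucine/leucine as indistinguishable,
* screening for putative long (C-terminally extended) proteoforms, and
* pairwise global-alignment sequence identity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from pyteomics import mass as _pmass

__all__ = [
    "STANDARD_RESIDUES",
    "WATER_MONO",
    "CARBAMIDOMETHYL_MONO",
    "PROTON_MASS",
    "ProteinEntry",
    "DatabaseContext",
    "PeptideRecord",
    "DigestionParams",
    "IdentitySummary",
    "ContextComparison",
    "LongFormReport",
    "read_fasta",
    "cleavage_sites",
    "tryptic_digest",
    "peptide_mass",
    "mz_admissible",
    "map_proteotypic",
    "compare_contexts",
    "screen_long_forms",
    "pairwise_identity",
    "identity_summary",
    "collapse_xle",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_RESIDUE_MONO = {aa: _pmass.std_aa_mass[aa] for aa in STANDARD_RESIDUES}

#: monoisotopic mass of water (Da), added once per peptide
WATER_MONO = 18.0105646863
#: fixed carbamidomethyl modification on cysteine (iodoacetamide alkylation)
CARBAMIDOMETHYL_MONO = 57.021464
#: proton mass used for m/z computation
PROTON_MASS = 1.00728


class FastaParseError(ValueError):
    """Raised when a FASTA file or record cannot be interpreted."""


def collapse_xle(sequence: str) -> str:
    """Replace isoleucine by leucine so that I/L-isobaric peptides compare equal."""
    return sequence.replace("I", "L")


@dataclass(frozen=True)
class ProteinEntry:
    """One proteoform sequence with its annotations.

    ``all_accessions`` collects accessions of redundant database records
    that were collapsed onto this entry during redundancy clearing; it
    always contains ``accession`` itself.
    """

    accession: str
    sequence: str
    gene_locus: str = ""
    is_family_member: bool = True
    reviewed: bool = False
    is_long_form: bool = False
    all_accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        for pos, aa in enumerate(self.sequence):
            if aa not in STANDARD_RESIDUES:
                raise ValueError(
                    f"{self.accession}: non-standard residue {aa!r} at position {pos}"
                )
        if not self.all_accessions:
            object.__setattr__(self, "all_accessions", (self.accession,))


@dataclass
class DatabaseContext:
    """A named set of proteoform/background entries used for uniqueness decisions.

    Typical contexts are a designated family-only database and a
    comprehensive database that adds a constant background proteome while
    containing the identical family sequences.
    """

    name: str
    entries: list[ProteinEntry]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.accession in seen:
                raise ValueError(f"duplicate accession {e.accession!r} in context {self.name!r}")
            seen.add(e.accession)

    @property
    def family(self) -> list[ProteinEntry]:
        return [e for e in self.entries if e.is_family_member]

    @property
    def background(self) -> list[ProteinEntry]:
        return [e for e in self.entries if not e.is_family_member]

    def get(self, accession: str) -> ProteinEntry:
        for e in self.entries:
            if e.accession == accession:
                return e
        raise KeyError(accession)


@dataclass
class PeptideRecord:
    """A digestion product with its parent set and proteotypic status.

    ``parents`` is the set of accessions whose digest produces this
    peptide sequence (under the active I/L-equivalence rule);
    ``proteotypic_in`` maps a context name to True iff the peptide has
    exactly one parent within that context.
    """

    sequence: str
    parents: frozenset[str]
    missed_cleavages: int
    mono_mass: float
    admissible_charges: frozenset[int] = frozenset()
    proteotypic_in: dict[str, bool] = field(default_factory=dict)

    @property
    def parent(self) -> str:
        """Sole parent accession; only meaningful for proteotypic peptides."""
        if len(self.parents) != 1:
            raise ValueError(f"peptide {self.sequence} has {len(self.parents)} parents")
        return next(iter(self.parents))


@dataclass(frozen=True)
class DigestionParams:
    """Settings controlling digestion and peptide admissibility.

    Peptides are retained when their length lies within
    ``[min_length, max_length]`` and at least one considered charge state
    puts them inside the acquisition m/z window.  Charge states 2-4 are
    considered throughout (typical for ESI tryptic peptides); singly
    charged ions are additionally considered for peptides of at most
    ``short_singly_charged_max`` residues, which would otherwise fall
    below the window at z >= 2.
    """

    max_missed: int = 2
    min_length: int = 6
    max_length: int = 30
    mz_window: tuple[float, float] = (250.0, 1500.0)
    charges: tuple[int, ...] = (2, 3, 4)
    short_singly_charged_max: int = 7
    il_equivalent: bool = True

    def charge_candidates(self, length: int) -> frozenset[int]:
        z = set(self.charges)
        if length <= self.short_singly_charged_max:
            z.add(1)
        return frozenset(z)


# ---------------------------------------------------------------------------
# FASTA input and redundancy clearing


def read_fasta(
    path: str | Path,
    annotations: Mapping[str, Mapping[str, object]] | None = None,
    signal_peptide_lengths: Mapping[str, int] | None = None,
) -> list[ProteinEntry]:
    """Read a FASTA database into :class:`ProteinEntry` records.

    Records with identical sequences are collapsed onto a single entry
    (redundancy clearing); all collapsed accessions are retained in
    ``all_accessions``.  When ``signal_peptide_lengths`` annotates a
    record, its signal peptide is trimmed before the equality comparison,
    so that precursor and mature forms of the same proteoform collapse.

    ``annotations`` maps accession to a dict with any of the keys
    ``gene_locus``, ``is_family_member``, ``reviewed``, ``is_long_form``.
    """
    path = Path(path)
    annotations = annotations or {}
    signal_peptide_lengths = signal_peptide_lengths or {}

    raw = path.read_text()
    if raw.strip() and not raw.lstrip().startswith(">"):
        raise FastaParseError(f"{path}: not FASTA-formatted (no '>' header)")

    entries: list[ProteinEntry] = []
    by_sequence: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        accession = record.id.split("|")[1] if "|" in record.id else record.id
        seq = str(record.seq).upper()
        if not seq:
            raise FastaParseError(f"{path}: record {record.id!r} has an empty sequence")
        trim = signal_peptide_lengths.get(accession, 0)
        if trim:
            if trim >= len(seq):
                raise FastaParseError(
                    f"{path}: record {record.id!r}: signal peptide length {trim} "
                    f">= sequence length {len(seq)}"
                )
            seq = seq[trim:]
        for pos, aa in enumerate(seq):
            if aa not in STANDARD_RESIDUES:
                raise FastaParseError(
                    f"{path}: record {record.id!r}: non-standard residue {aa!r} "
                    f"at position {pos}"
                )
        if seq in by_sequence:
            idx = by_sequence[seq]
            prev = entries[idx]
            entries[idx] = ProteinEntry(
                accession=prev.accession,
                sequence=prev.sequence,
                gene_locus=prev.gene_locus,
                is_family_member=prev.is_family_member,
                reviewed=prev.reviewed,
                is_long_form=prev.is_long_form,
                all_accessions=prev.all_accessions + (accession,),
            )
            continue
        ann = annotations.get(accession, {})
        entry = ProteinEntry(
            accession=accession,
            sequence=seq,
            gene_locus=str(ann.get("gene_locus", "")),
            is_family_member=bool(ann.get("is_family_member", True)),
            reviewed=bool(ann.get("reviewed", False)),
            is_long_form=bool(ann.get("is_long_form", False)),
        )
        by_sequence[seq] = len(entries)
        entries.append(entry)
    return entries


# ---------------------------------------------------------------------------
# Digestion and masses


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions after which trypsin cleaves (K/R not followed by P)."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(sequence: str, max_missed: int = 0) -> list[PeptideRecord]:
    """All tryptic peptides of ``sequence`` with 0..``max_missed`` missed cleavages.

    Cleavage occurs C-terminal to K or R except when the following residue
    is proline.  Records are returned in order of start position, then
    missed-cleavage count; parent sets are left empty (filled by
    :func:`map_proteotypic`).
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bounds = [0] + cleavage_sites(sequence) + [len(sequence)]
    records: list[PeptideRecord] = []
    for i in range(len(bounds) - 1):
        for m in range(max_missed + 1):
            j = i + 1 + m
            if j >= len(bounds):
                break
            pep = sequence[bounds[i] : bounds[j]]
            records.append(
                PeptideRecord(
                    sequence=pep,
                    parents=frozenset(),
                    missed_cleavages=m,
                    mono_mass=peptide_mass(pep),
                )
            )
    return records


def peptide_mass(sequence: str) -> float:
    """Monoisotopic peptide mass in Da with fixed carbamidomethyl-C.

    Sum of residue monoisotopic masses plus one water, plus 57.021464 Da
    per cysteine (iodoacetamide alkylation assumed complete).
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = WATER_MONO
    for pos, aa in enumerate(sequence):
        try:
            total += _RESIDUE_MONO[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {pos}") from None
        if aa == "C":
            total += CARBAMIDOMETHYL_MONO
    return total


def mz_admissible(
    mass: float,
    charges: Iterable[int],
    window: tuple[float, float] = (250.0, 1500.0),
) -> frozenset[int]:
    """Charge states z for which (mass + z*proton)/z lies within ``window``.

    The peptide is admissible for acquisition iff the returned set is
    non-empty.  Window bounds are inclusive.
    """
    if mass <= 0:
        raise ValueError(f"non-positive mass {mass}")
    low, high = window
    ok = frozenset(
        z for z in charges if low <= (mass + z * PROTON_MASS) / z <= high
    )
    return ok


# ---------------------------------------------------------------------------
# Proteotypic mapping


def map_proteotypic(
    db: DatabaseContext,
    params: DigestionParams = DigestionParams(),
) -> list[PeptideRecord]:
    """Digest every entry of ``db`` and mark proteotypic peptides.

    Identical peptide sequences from different entries are merged (with
    I treated as L when ``params.il_equivalent``); each merged record
    carries the full parent set and ``proteotypic_in[db.name]`` is True
    iff the parent set has exactly one member.  Peptides failing the
    length bounds or with no admissible charge state are dropped.
    """
    if not db.entries:
        raise ValueError("empty database context")
    merged: dict[str, PeptideRecord] = {}
    for entry in db.entries:
        for rec in tryptic_digest(entry.sequence, params.max_missed):
            n = len(rec.sequence)
            if n < params.min_length or n > params.max_length:
                continue
            charges = mz_admissible(
                rec.mono_mass, params.charge_candidates(n), params.mz_window
            )
            if not charges:
                continue
            key = collapse_xle(rec.sequence) if params.il_equivalent else rec.sequence
            if key in merged:
                prev = merged[key]
                merged[key] = PeptideRecord(
                    sequence=prev.sequence,
                    parents=prev.parents | {entry.accession},
                    missed_cleavages=min(prev.missed_cleavages, rec.missed_cleavages),
                    mono_mass=prev.mono_mass,
                    admissible_charges=prev.admissible_charges,
                    proteotypic_in=prev.proteotypic_in,
                )
            else:
                merged[key] = PeptideRecord(
                    sequence=rec.sequence,
                    parents=frozenset({entry.accession}),
                    missed_cleavages=rec.missed_cleavages,
                    mono_mass=rec.mono_mass,
                    admissible_charges=charges,
                )
    out = list(merged.values())
    for rec in out:
        rec.proteotypic_in[db.name] = len(rec.parents) == 1
    return out


@dataclass
class ContextComparison:
    """Per-proteoform proteotypic-peptide counts in two database contexts."""

    counts_a: dict[str, int]
    counts_b: dict[str, int]
    #: family proteoforms with proteotypic peptides in A but none in B
    unidentifiable_in_b: list[str]
    lost_peptides: dict[str, list[str]]


def compare_contexts(
    db_a: DatabaseContext,
    db_b: DatabaseContext,
    params: DigestionParams = DigestionParams(),
) -> ContextComparison:
    """Compare proteotypic coverage of the shared family across two contexts.

    Both contexts must contain identical family sequences (the typical
    comparison is family-only vs. family plus background).  Returns the
    per-proteoform proteotypic count in each context, the peptides each
    proteoform loses in B, and which proteoforms become unidentifiable.
    """
    fam_a = {e.accession: e.sequence for e in db_a.family}
    fam_b = {e.accession: e.sequence for e in db_b.family}
    if fam_a != fam_b:
        raise ValueError("family sequences differ between contexts")

    def _counts(db: DatabaseContext) -> tuple[dict[str, int], dict[str, set[str]]]:
        counts = {acc: 0 for acc in fam_a}
        peps: dict[str, set[str]] = {acc: set() for acc in fam_a}
        for rec in map_proteotypic(db, params):
            if rec.proteotypic_in[db.name]:
                acc = rec.parent
                if acc in counts:
                    counts[acc] += 1
                    peps[acc].add(rec.sequence)
        return counts, peps

    counts_a, peps_a = _counts(db_a)
    counts_b, peps_b = _counts(db_b)
    unident = sorted(acc for acc in fam_a if counts_a[acc] > 0 and counts_b[acc] == 0)
    lost = {
        acc: sorted(peps_a[acc] - peps_b[acc])
        for acc in fam_a
        if peps_a[acc] - peps_b[acc]
    }
    return ContextComparison(counts_a, counts_b, unident, lost)


@dataclass
class LongFormReport:
    """Protein-level evidence verdict for a putative long proteoform."""

    accession: str
    extension_peptides: list[str]
    observed_peptides: list[str]
    verdict: str  # "supported" | "not supported at protein level" | "undecidable"


def screen_long_forms(
    db: DatabaseContext,
    observed_peptides: set[str],
    params: DigestionParams = DigestionParams(),
) -> list[LongFormReport]:
    """Check whether putative long proteoforms are supported by observed peptides.

    For each ``is_long_form`` entry, the peptides unique to it within the
    context (absent from every non-long-form digest, I/L-aware) are
    collected subject to admissibility.  A long form is "supported" when
    at least one such peptide is in ``observed_peptides``, "not supported
    at protein level" when none is, and "undecidable" when its unique
    region yields no admissible tryptic peptide at all.
    """
    long_forms = [e for e in db.entries if e.is_long_form]
    if not long_forms:
        return []
    others = [e for e in db.entries if not e.is_long_form]
    other_peps: set[str] = set()
    for e in others:
        for rec in tryptic_digest(e.sequence, params.max_missed):
            other_peps.add(
                collapse_xle(rec.sequence) if params.il_equivalent else rec.sequence
            )
    observed_keys = {
        collapse_xle(p) if params.il_equivalent else p for p in observed_peptides
    }
    reports = []
    for lf in long_forms:
        unique: list[str] = []
        for rec in tryptic_digest(lf.sequence, params.max_missed):
            n = len(rec.sequence)
            key = collapse_xle(rec.sequence) if params.il_equivalent else rec.sequence
            if key in other_peps:
                continue
            if n < params.min_length or n > params.max_length:
                continue
            if not mz_admissible(
                rec.mono_mass, params.charge_candidates(n), params.mz_window
            ):
                continue
            unique.append(rec.sequence)
        hits = sorted(
            p
            for p in unique
            if (collapse_xle(p) if params.il_equivalent else p) in observed_keys
        )
        if not unique:
            verdict = "undecidable"
        elif hits:
            verdict = "supported"
        else:
            verdict = "not supported at protein level"
        reports.append(LongFormReport(lf.accession, sorted(set(unique)), hits, verdict))
    return reports


# ---------------------------------------------------------------------------
# Sequence identity


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: ProteinEntry | str, b: ProteinEntry | str) -> float:
    """Percent identity from global alignment (BLOSUM62, affine gaps 10/0.5).

    Identity = identical aligned columns / alignment length x 100, with
    gap columns counting toward the length.
    """
    seq_a = a.sequence if isinstance(a, ProteinEntry) else a
    seq_b = b.sequence if isinstance(b, ProteinEntry) else b
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    alignment = _make_aligner().align(seq_a, seq_b)[0]
    col_a, col_b = alignment[0], alignment[1]
    matches = sum(x == y and x != "-" for x, y in zip(col_a, col_b))
    return 100.0 * matches / len(col_a)


@dataclass
class IdentitySummary:
    """All pairwise identities within a set of proteoforms, and their mean."""

    pair_identities: dict[tuple[str, str], float]
    mean_identity: float


def identity_summary(entries: Sequence[ProteinEntry]) -> IdentitySummary:
    """Pairwise percent identities among ``entries`` and their arithmetic mean."""
    pairs = {}
    for a, b in itertools.combinations(entries, 2):
        pairs[(a.accession, b.accession)] = pairwise_identity(a, b)
    if not pairs:
        raise ValueError("need at least two entries")
    mean = sum(pairs.values()) / len(pairs)
    return IdentitySummary(pairs, mean)
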