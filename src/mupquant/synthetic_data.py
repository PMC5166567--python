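"""Synthetic homologous-proteoform families and label-free quantification data.

No public raw data exist for the urinary-proteome study design this
package targets, so this module generates data with the same statistical
structure and a known ground truth:

* a family of proteoforms derived from one random base sequence, with
  central members (>97% identity to the family consensus) and peripheral
  members (82-94%), every member carrying at least one admissible
  proteotypic peptide in the family-only database context;
* a constant, non-homologous background proteome;
* a paired two-time-point study (13 individuals by default) in which a
  subset of family proteoforms is truly upregulated at t2, detection is
  genotype-like per individual, and the measured total protein
  concentration rises with family upregulation (1.4 -> ~2.6 ug/uL on
  average under the defaults);
* MS1 (peptide x sample) and MS2 (fragment x sample) peak-area matrices
  with multiplicative lognormal noise, per-peptide ionization-efficiency
  factors and per-peptide fragment-intensity patterns.

All randomness flows from a single seed; identical seed and settings
reproduce bit-identical matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_db import (
    DatabaseContext,
    DigestionParams,
    ProteinEntry,
    collapse_xle,
    map_proteotypic,
    tryptic_digest,
)

__all__ = [
    "FamilySpec",
    "StudyDesign",
    "GroundTruth",
    "SimulatedStudy",
    "DEFAULT_FREQUENCY_LADDER",
    "generate_family",
    "generate_background",
    "comprehensive_context",
    "make_long_form",
    "draw_detection",
    "simulate_study",
]

# residues used for random sequence construction; K/R are reserved for
# cleavage sites and P is excluded so the digest pattern stays fixed
_BODY_RESIDUES = "ACDEFGHILMNQSTVWY"
# substitution targets exclude K/R/P (cleavage control) and I/L
# (I<->L swaps are invisible under I/L-equivalent uniqueness)
_SUBSTITUTION_RESIDUES = "ACDEFGHMNQSTVWY"

#: detection frequencies spanning the ubiquitous/common/uncommon/rare
#: classes reported for urinary MUP proteoforms in a surveyed population
#: of 36 wild-derived house mice; reused as the generator default.
DEFAULT_FREQUENCY_LADDER = (
    1.00, 1.00, 0.70, 0.59, 0.54, 0.50, 0.48, 0.44, 0.41, 0.41,
    0.39, 0.35, 0.30, 0.09, 0.07, 0.07, 0.06, 0.02, 0.02,
)


@dataclass(frozen=True)
class FamilySpec:
    """Shape of the generated proteoform family.

    Identity bands are measured against the family base (consensus)
    sequence.  Defaults mirror a mature lipocalin-like family: 157
    residues, 14 central members above 97% identity and 5 peripheral
    members at 82-94%.
    """

    n_central: int = 14
    n_peripheral: int = 5
    central_identity_min: float = 97.0
    peripheral_identity_range: tuple[float, float] = (82.0, 94.0)
    base_length: int = 157

    def __post_init__(self) -> None:
        lo, hi = self.peripheral_identity_range
        if not (0 < lo <= hi <= 100) or not (0 < self.central_identity_min <= 100):
            raise ValueError("identity bands must lie in (0, 100]")
        if self.central_identity_min <= hi:
            raise ValueError("central identity minimum must exceed peripheral maximum")
        if self.n_central < 1 or self.n_peripheral < 0:
            raise ValueError("need at least one central proteoform")


@dataclass
class StudyDesign:
    """Paired two-time-point study with proteoform-specific upregulation.

    ``upregulated`` maps proteoform accession to its true t2/t1 fold
    change; when None, a subset of high-frequency proteoforms is chosen
    so that the family-driven rise of total protein matches the
    ``conc_t1_mean`` -> ``conc_t2_mean`` averages.  ``frequency_class``
    maps accession to the per-individual detection probability; when
    None, :data:`DEFAULT_FREQUENCY_LADDER` is assigned by decreasing
    abundance.  Coefficients of variation are for multiplicative
    lognormal noise with unit mean.
    """

    n_individuals: int = 13
    upregulated: dict[str, float] | None = None
    frequency_class: dict[str, float] | None = None
    conc_t1_mean: float = 1.4
    conc_t2_mean: float = 2.6
    default_fold: float = 3.0
    family_intensity_share: float = 0.85
    noise_cv: float = 0.25
    technical_cv: float = 0.10
    fragment_cv: float = 0.05
    individual_cv: float = 0.30
    concentration_cv: float = 0.05
    ionization_cv: float = 0.80
    replicates_t1: int = 2
    replicates_t2: int = 3
    n_fragments: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.upregulated is not None:
            for acc, f in self.upregulated.items():
                if f <= 0:
                    raise ValueError(f"fold change for {acc} must be positive")
        if self.frequency_class is not None:
            for acc, p in self.frequency_class.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"detection probability for {acc} not in [0,1]")
        if not 0 < self.family_intensity_share < 1:
            raise ValueError("family_intensity_share must lie in (0,1)")
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")


@dataclass
class GroundTruth:
    """Everything the simulator knows, kept for recovery tests."""

    baselines: dict[str, float]
    fold_changes: dict[str, float]
    frequencies: dict[str, float]
    detection: pd.DataFrame  # proteoform x individual booleans
    ionization_factors: dict[str, float]
    fragment_weights: dict[str, np.ndarray]
    family_accessions: list[str]
    family_intensity_share: float
    concentrations: pd.Series  # per sample, ug/uL


@dataclass
class SimulatedStudy:
    """Simulated matrices plus metadata and ground truth."""

    ms1: pd.DataFrame  # peptide x sample peak areas (NaN = not detected)
    ms2: pd.DataFrame | None  # "peptide.fN" x sample
    metadata: pd.DataFrame  # sample, individual, time_point, concentration
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Sequence generation


def _random_tryptic_sequence(rng: np.random.Generator, length: int) -> str:
    """Random protein whose tryptic peptides are mostly 6-12 residues long."""
    parts: list[str] = []
    total = 0
    while total < length:
        seg_len = int(rng.integers(6, 13))
        seg_len = min(seg_len, length - total)
        body = "".join(rng.choice(list(_BODY_RESIDUES), size=max(seg_len - 1, 1)))
        seg = body if seg_len == 1 else body + str(rng.choice(["K", "R"]))
        if total + seg_len >= length:  # C-terminal peptide need not end in K/R
            seg = seg[:seg_len].rstrip("KR") or seg[:seg_len]
            seg = seg + "".join(
                rng.choice(list(_BODY_RESIDUES), size=seg_len - len(seg))
            )
        parts.append(seg[: length - total])
        total += len(parts[-1])
    return "".join(parts)


def _eligible_positions(base: str, params: DigestionParams) -> list[int]:
    """Positions inside admissible fully-cleaved peptides, excluding K/R."""
    from .sequence_db import mz_admissible

    eligible: list[int] = []
    start = 0
    for rec in tryptic_digest(base, 0):
        n = len(rec.sequence)
        ok = (
            params.min_length <= n <= params.max_length
            and mz_admissible(
                rec.mono_mass, params.charge_candidates(n), params.mz_window
            )
        )
        if ok:
            eligible.extend(
                start + k for k in range(n) if base[start + k] not in "KR"
            )
        start += n
    return eligible


def _substitute(base: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    seq = list(base)
    for pos in positions:
        choices = [r for r in _SUBSTITUTION_RESIDUES if r != seq[pos]]
        seq[pos] = str(rng.choice(choices))
    return "".join(seq)


def generate_family(
    spec: FamilySpec = FamilySpec(),
    seed: int = 0,
    params: DigestionParams = DigestionParams(),
    max_retries: int = 25,
) -> DatabaseContext:
    """Generate a homologous proteoform family as a ``family_only`` context.

    Every proteoform derives from one random base sequence by point
    substitutions at positions unique to it, placed inside admissible
    tryptic peptides so that each member keeps at least one proteotypic
    peptide; K/R positions are never touched, so all members share the
    same digestion pattern.  Central members carry few substitutions
    (identity to base >= ``central_identity_min``), peripheral members
    carry many (identity to base within ``peripheral_identity_range``).
    The achieved family is audited with :func:`map_proteotypic` and
    substitutions are re-placed until every member is identifiable;
    an infeasible spec raises after ``max_retries`` attempts.

    The base sequence is recorded in ``context.metadata['base_sequence']``.
    """
    rng = np.random.default_rng(seed)
    L = spec.base_length
    d_central = max(1, math.floor(L * (1 - spec.central_identity_min / 100) / 2))
    lo_band, hi_band = spec.peripheral_identity_range
    d_peri_lo = max(1, math.ceil(L * (1 - hi_band / 100)))
    d_peri_hi = max(d_peri_lo, math.floor(L * (1 - lo_band / 100)))

    for _ in range(max_retries):
        base = _random_tryptic_sequence(rng, L)
        eligible = _eligible_positions(base, params)
        d_peri = [
            int(rng.integers(d_peri_lo, d_peri_hi + 1))
            for _ in range(spec.n_peripheral)
        ]
        needed = spec.n_central * d_central + sum(d_peri)
        if needed > len(eligible):
            continue
        order = rng.permutation(eligible)
        cursor = 0
        entries: list[ProteinEntry] = []
        for i in range(spec.n_central):
            pos = order[cursor : cursor + d_central]
            cursor += d_central
            entries.append(
                ProteinEntry(
                    accession=f"SYNC{i + 1:02d}",
                    sequence=_substitute(base, pos, rng),
                    gene_locus=f"locus{i + 1:02d}",
                    is_family_member=True,
                )
            )
        for j, d in enumerate(d_peri):
            pos = order[cursor : cursor + d]
            cursor += d
            entries.append(
                ProteinEntry(
                    accession=f"SYNP{j + 1:02d}",
                    sequence=_substitute(base, pos, rng),
                    gene_locus=f"locus{spec.n_central + j + 1:02d}",
                    is_family_member=True,
                )
            )
        ctx = DatabaseContext("family_only", entries)
        counts = {e.accession: 0 for e in entries}
        for rec in map_proteotypic(ctx, params):
            if rec.proteotypic_in["family_only"]:
                counts[rec.parent] += 1
        if all(c >= 1 for c in counts.values()):
            ctx.metadata["base_sequence"] = base
            return ctx
    raise RuntimeError(
        f"could not realize family spec {spec} within {max_retries} attempts"
    )


def generate_background(
    n: int,
    seed: int = 0,
    family: DatabaseContext | None = None,
    length_range: tuple[int, int] = (80, 250),
    params: DigestionParams = DigestionParams(),
    max_retries: int = 50,
) -> list[ProteinEntry]:
    """Random non-homologous background proteins sharing no tryptic peptide
    with the family (collisions are re-drawn)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    family_peps: set[str] = set()
    if family is not None:
        for e in family.entries:
            for rec in tryptic_digest(e.sequence, params.max_missed):
                family_peps.add(collapse_xle(rec.sequence))
    entries: list[ProteinEntry] = []
    for i in range(n):
        for _ in range(max_retries):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            seq = _random_tryptic_sequence(rng, length)
            peps = {
                collapse_xle(r.sequence)
                for r in tryptic_digest(seq, params.max_missed)
            }
            if not peps & family_peps:
                family_peps |= peps  # background entries must not collide either
                entries.append(
                    ProteinEntry(
                        accession=f"BKG{i + 1:03d}",
                        sequence=seq,
                        gene_locus=f"bglocus{i + 1:03d}",
                        is_family_member=False,
                    )
                )
                break
        else:
            raise RuntimeError("could not draw a collision-free background protein")
    return entries


def comprehensive_context(
    family: DatabaseContext,
    background: Sequence[ProteinEntry],
    name: str = "comprehensive",
) -> DatabaseContext:
    """Family entries plus background proteome as one superset context."""
    ctx = DatabaseContext(name, list(family.entries) + list(background))
    ctx.metadata.update(family.metadata)
    return ctx


def make_long_form(
    entry: ProteinEntry, extension: str, accession: str | None = None
) -> ProteinEntry:
    """C-terminally extended variant of ``entry`` flagged as a long form."""
    return ProteinEntry(
        accession=accession or f"{entry.accession}L",
        sequence=entry.sequence + extension,
        gene_locus=entry.gene_locus,
        is_family_member=entry.is_family_member,
        is_long_form=True,
    )


# ---------------------------------------------------------------------------
# Study simulation


def _lognormal_factors(
    rng: np.random.Generator, cv: float, size: tuple[int, ...] | int
) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise; exactly 1 when cv == 0."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def draw_detection(
    family_accessions: Sequence[str],
    frequencies: dict[str, float],
    n_individuals: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Bernoulli presence/absence per (proteoform, individual).

    A proteoform absent for an individual contributes no peptides at
    either time point, mimicking genotype-like expression differences.
    """
    individuals = [f"M{i + 1:02d}" for i in range(n_individuals)]
    data = {
        acc: rng.random(n_individuals) < frequencies[acc]
        for acc in family_accessions
    }
    return pd.DataFrame(data, index=individuals).T


def simulate_study(
    db: DatabaseContext,
    design: StudyDesign = StudyDesign(),
    params: DigestionParams | None = None,
    include_ms2: bool = True,
) -> SimulatedStudy:
    """Simulate MS1/MS2 quantification matrices for a paired study.

    Per sample, proteoform abundance = baseline x per-individual effect x
    (true fold change at t2) x lognormal biological noise averaged over
    pooled replicates; peptide MS1 area sums the abundances of its
    detected parents times a per-peptide ionization factor and technical
    noise; the MS2 matrix distributes each peptide area over
    ``design.n_fragments`` rows with per-peptide Dirichlet weights plus
    fragment noise (fragment rows sum exactly to the MS1 area when
    ``fragment_cv`` is zero).  Per-sample protein concentration scales
    with the true total protein amount (anchored so the t1 average equals
    ``conc_t1_mean``), so family upregulation raises concentration.

    Matrices contain fully cleaved peptides only (simulated digestion is
    complete); shared and proteotypic peptides are both present.
    """
    if params is None:
        params = DigestionParams(max_missed=0)
    family = [e.accession for e in db.family]
    if not family:
        raise ValueError("database context contains no family proteoforms")
    background = [e.accession for e in db.background]
    rng = np.random.default_rng(design.seed)
    n_ind = design.n_individuals

    # --- proteoform baselines; abundant family members get high frequency
    fam_base_draw = 100.0 * _lognormal_factors(rng, 1.0, len(family))
    order = np.argsort(-fam_base_draw)
    baselines = {family[i]: float(fam_base_draw[i]) for i in range(len(family))}
    ladder = list(DEFAULT_FREQUENCY_LADDER)
    if design.frequency_class is not None:
        freqs = dict(design.frequency_class)
        missing = [a for a in family if a not in freqs]
        if missing:
            raise ValueError(f"frequency_class missing proteoforms: {missing}")
    else:
        freqs = {}
        for rank, idx in enumerate(order):
            freqs[family[idx]] = ladder[rank % len(ladder)]

    # --- true fold changes: default subset of high-frequency proteoforms
    # covering just enough effective abundance that the family-driven total
    # rises from conc_t1_mean to ~conc_t2_mean
    effective = {a: baselines[a] * freqs[a] for a in family}
    fam_total = sum(effective.values())
    if design.upregulated is not None:
        folds = {a: design.upregulated.get(a, 1.0) for a in family}
    else:
        # choose upregulated proteoforms (most abundant first, at
        # default_fold) so the expected family-driven rise of the total
        # matches the conc_t1_mean -> conc_t2_mean averages; the last
        # member gets a partial fold to meet the target exactly
        conc_ratio = design.conc_t2_mean / design.conc_t1_mean
        # required sum of effective-share * (fold - 1) over the family
        lift_needed = (conc_ratio - 1.0) / design.family_intensity_share
        folds = {a: 1.0 for a in family}
        for a in sorted(family, key=lambda a: -effective[a]):
            if lift_needed <= 0:
                break
            share = effective[a] / fam_total
            fold = min(design.default_fold, 1.0 + lift_needed / share)
            folds[a] = fold
            lift_needed -= share * (fold - 1.0)
    # constant background: equal baselines sized to the family intensity share
    bkg_total = fam_total * (1 - design.family_intensity_share) / design.family_intensity_share
    for a in background:
        baselines[a] = bkg_total / len(background) if background else 0.0
        folds[a] = 1.0
        freqs[a] = 1.0

    detection = draw_detection(family, freqs, n_ind, rng)
    individuals = list(detection.columns)
    samples = [f"{ind}_t1" for ind in individuals] + [f"{ind}_t2" for ind in individuals]
    accessions = family + background
    n_prot, n_samp = len(accessions), len(samples)

    # --- per-sample true proteoform abundances
    indiv_eff = _lognormal_factors(rng, design.individual_cv, (n_prot, n_ind))
    abundance = np.zeros((n_prot, n_samp))
    for t_idx, (tp, reps) in enumerate(
        [("t1", design.replicates_t1), ("t2", design.replicates_t2)]
    ):
        bio = _lognormal_factors(rng, design.noise_cv, (n_prot, n_ind, reps)).mean(
            axis=2
        )
        for p, acc in enumerate(accessions):
            fold = folds[acc] if tp == "t2" else 1.0
            det = (
                detection.loc[acc].to_numpy(dtype=float)
                if acc in detection.index
                else np.ones(n_ind)
            )
            abundance[p, t_idx * n_ind : (t_idx + 1) * n_ind] = (
                baselines[acc] * indiv_eff[p] * fold * bio[p] * det
            )

    # --- peptide-level matrix
    peptides = map_proteotypic(db, params)
    pep_seqs = [r.sequence for r in peptides]
    acc_index = {a: i for i, a in enumerate(accessions)}
    membership = np.zeros((len(peptides), n_prot))
    for r_idx, rec in enumerate(peptides):
        for acc in rec.parents:
            membership[r_idx, acc_index[acc]] = 1.0
    raw = membership @ abundance
    ion = _lognormal_factors(rng, design.ionization_cv, len(peptides))
    tech = _lognormal_factors(rng, design.technical_cv, raw.shape)
    ms1_values = raw * ion[:, None] * tech
    ms1_values[raw == 0] = np.nan
    ms1 = pd.DataFrame(ms1_values, index=pep_seqs, columns=samples)

    # --- fragment-level matrix
    ms2 = None
    frag_weights: dict[str, np.ndarray] = {}
    if include_ms2:
        nf = design.n_fragments
        w = rng.dirichlet(np.full(nf, 5.0), size=len(peptides))
        frag_weights = {pep_seqs[i]: w[i] for i in range(len(peptides))}
        cum = np.cumsum(w, axis=1)
        cum[:, -1] = 1.0  # exact telescoping so fragments sum to the MS1 area
        lower = np.concatenate([np.zeros((len(peptides), 1)), cum[:, :-1]], axis=1)
        frag_rows = []
        frag_index = []
        fnoise = _lognormal_factors(
            rng, design.fragment_cv, (len(peptides), nf, n_samp)
        )
        for i, pep in enumerate(pep_seqs):
            base_row = ms1_values[i]
            for k in range(nf):
                frag = base_row * cum[i, k] - base_row * lower[i, k]
                frag_rows.append(frag * fnoise[i, k])
                frag_index.append(f"{pep}.f{k + 1}")
        ms2 = pd.DataFrame(np.vstack(frag_rows), index=frag_index, columns=samples)

    # --- total protein concentration coupled to the true total amount
    totals = abundance.sum(axis=0)
    t1_mean = totals[:n_ind].mean()
    conc_noise = _lognormal_factors(rng, design.concentration_cv, n_samp)
    conc = pd.Series(
        design.conc_t1_mean * totals / t1_mean * conc_noise, index=samples
    )

    metadata = pd.DataFrame(
        {
            "individual": individuals * 2,
            "time_point": ["t1"] * n_ind + ["t2"] * n_ind,
            "concentration": conc.to_numpy(),
        },
        index=pd.Index(samples, name="sample"),
    )
    truth = GroundTruth(
        baselines=baselines,
        fold_changes=folds,
        frequencies=freqs,
        detection=detection,
        ionization_factors={pep_seqs[i]: float(ion[i]) for i in range(len(pep_seqs))},
        fragment_weights=frag_weights,
        family_accessions=family,
        family_intensity_share=design.family_intensity_share,
        concentrations=conc,
    )
    return SimulatedStudy(ms1=ms1, ms2=ms2, metadata=metadata, truth=truth)
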