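"""Shared fixtures: toy databases and a small simulated study."""

from __future__ import annotations

import pytest

from mupquant.sequence_db import DatabaseContext, ProteinEntry
from mupquant.synthetic_data import (
    FamilySpec,
    StudyDesign,
    comprehensive_context,
    generate_background,
    generate_family,
    simulate_study,
)

# Two proteoforms sharing one tryptic peptide and differing inside another;
# all peptides are 6+ residues and admissible at z=1 or 2.
TOY_A = "AAADDDKGGGWWWK"
TOY_B = "AAADDDKGGGWWWR"


@pytest.fixture
def toy_pair() -> DatabaseContext:
    return DatabaseContext(
        "family_only",
        [
            ProteinEntry("P_A", TOY_A, gene_locus="locA"),
            ProteinEntry("P_B", TOY_B, gene_locus="locB"),
        ],
    )


@pytest.fixture(scope="session")
def small_family() -> DatabaseContext:
    return generate_family(
        FamilySpec(n_central=4, n_peripheral=2), seed=11
    )


@pytest.fixture(scope="session")
def small_comprehensive(small_family) -> DatabaseContext:
    background = generate_background(6, seed=12, family=small_family)
    return comprehensive_context(small_family, background)


@pytest.fixture(scope="session")
def noise_free_design() -> StudyDesign:
    return StudyDesign(
        n_individuals=6,
        noise_cv=0.0,
        technical_cv=0.0,
        fragment_cv=0.0,
        individual_cv=0.0,
        concentration_cv=0.0,
        ionization_cv=0.0,
        frequency_class=None,
        seed=5,
    )


@pytest.fixture(scope="session")
def noise_free_study(small_comprehensive, noise_free_design):
    return simulate_study(small_comprehensive, noise_free_design)


def brute_force_digest(sequence: str, max_missed: int) -> set[tuple[str, int]]:
    """Independent digestion oracle: scan every substring and keep those whose
    ends are valid tryptic boundaries and whose internal cleavage-site count
    does not exceed ``max_missed``."""
    n = len(sequence)

    def is_site(i: int) -> bool:  # cleavage between i-1 and i
        return 0 < i < n and sequence[i - 1] in "KR" and sequence[i] != "P"

    out = set()
    for start in range(n):
        if not (start == 0 or is_site(start)):
            continue
        for end in range(start + 1, n + 1):
            if not (end == n or is_site(end)):
                continue
            internal = sum(1 for i in range(start + 1, end) if is_site(i))
            if internal <= max_missed:
                out.add((sequence[start:end], internal))
    return out
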