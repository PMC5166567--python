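"""Digestion, masses, admissibility, proteotypic mapping and identity."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mupquant.sequence_db import (
    DatabaseContext,
    DigestionParams,
    ProteinEntry,
    compare_contexts,
    identity_summary,
    map_proteotypic,
    mz_admissible,
    pairwise_identity,
    peptide_mass,
    read_fasta,
    screen_long_forms,
    tryptic_digest,
)
from mupquant.synthetic_data import make_long_form

from conftest import TOY_A, TOY_B, brute_force_digest

SEQ_ALPHABET = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60)


# ---------------------------------------------------------------------------
# tryptic digestion


@pytest.mark.parametrize(
    "sequence, max_missed, expected",
    [
        ("AKRPGK", 0, {"AK", "RPGK"}),  # R before P does not cleave
        ("AAA", 0, {"AAA"}),
        ("AKEK", 1, {"AK", "EK", "AKEK"}),
    ],
)
def test_digest_examples(sequence, max_missed, expected):
    got = {r.sequence for r in tryptic_digest(sequence, max_missed)}
    assert got == expected


def test_digest_rejects_empty_sequence():
    with pytest.raises(ValueError):
        tryptic_digest("", 0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(sequence=SEQ_ALPHABET, max_missed=st.integers(0, 2))
def test_digest_matches_bruteforce_oracle(sequence, max_missed):
    got = {(r.sequence, r.missed_cleavages) for r in tryptic_digest(sequence, max_missed)}
    assert got == brute_force_digest(sequence, max_missed)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(sequence=SEQ_ALPHABET)
def test_zero_missed_products_reconstruct_parent(sequence):
    parts = [r.sequence for r in tryptic_digest(sequence, 0) if r.missed_cleavages == 0]
    assert "".join(parts) == sequence


# ---------------------------------------------------------------------------
# peptide masses and m/z admissibility


@pytest.mark.parametrize(
    "sequence, expected",
    [("ACK", 377.17328), ("G", 75.03203)],
)
def test_peptide_mass_examples(sequence, expected):
    assert peptide_mass(sequence) == pytest.approx(expected, abs=2e-5)


def test_peptide_mass_errors():
    with pytest.raises(ValueError):
        peptide_mass("")
    with pytest.raises(ValueError, match="position 2"):
        peptide_mass("ACXK")


@settings(max_examples=100, deadline=None, derandomize=True)
@given(s1=SEQ_ALPHABET, s2=SEQ_ALPHABET)
def test_mass_additivity_up_to_one_water(s1, s2):
    assert peptide_mass(s1 + s2) == pytest.approx(
        peptide_mass(s1) + peptide_mass(s2) - 18.01056, abs=1e-5
    )


def test_mz_admissible_examples():
    # z=2 would give m/z ~ 189.6, below the 250 lower bound
    assert mz_admissible(377.17328, {1, 2}) == {1}
    # boundary: m/z lands just inside the upper edge at z=1
    assert mz_admissible(1499.0 - 1.00728, {1}) == {1}
    assert mz_admissible(100.0, {1}) == frozenset()


def test_mz_admissible_rejects_nonpositive_mass():
    with pytest.raises(ValueError):
        mz_admissible(0.0, {2})


# ---------------------------------------------------------------------------
# FASTA reading and redundancy clearing


def test_read_fasta_collapses_identical_sequences(tmp_path):
    p = tmp_path / "db.fasta"
    p.write_text(">ACC1\nAAADDDK\n>ACC2\nAAADDDK\n>ACC3\nGGGWWWK\n")
    entries = read_fasta(p)
    assert [e.accession for e in entries] == ["ACC1", "ACC3"]
    assert entries[0].all_accessions == ("ACC1", "ACC2")


def test_read_fasta_empty_file(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    assert read_fasta(p) == []


def test_read_fasta_preserves_order(tmp_path):
    p = tmp_path / "db.fasta"
    p.write_text(">A\nAAAK\n>B\nCCCK\n>C\nDDDK\n")
    assert [e.accession for e in read_fasta(p)] == ["A", "B", "C"]


def test_read_fasta_rejects_bad_residue_and_garbage(tmp_path):
    bad = tmp_path / "bad.fasta"
    bad.write_text(">A\nAAB1K\n")
    with pytest.raises(ValueError, match="'A'"):
        read_fasta(bad)
    garbage = tmp_path / "garbage.fasta"
    garbage.write_text("not a fasta file\n")
    with pytest.raises(ValueError, match="not FASTA"):
        read_fasta(garbage)


def test_read_fasta_signal_peptide_trimming_merges_forms(tmp_path):
    p = tmp_path / "db.fasta"
    mature = "AAADDDKGGGWWWK"
    p.write_text(f">PRE\nMKT{mature}\n>MAT\n{mature}\n")
    entries = read_fasta(p, signal_peptide_lengths={"PRE": 3})
    assert len(entries) == 1
    assert entries[0].sequence == mature
    assert entries[0].all_accessions == ("PRE", "MAT")


def test_protein_entry_validation():
    with pytest.raises(ValueError):
        ProteinEntry("X", "")
    with pytest.raises(ValueError, match="position 1"):
        ProteinEntry("X", "AZA")
    with pytest.raises(ValueError, match="duplicate"):
        DatabaseContext("c", [ProteinEntry("X", "AAAK"), ProteinEntry("X", "CCCK")])


# ---------------------------------------------------------------------------
# proteotypic mapping


def test_single_residue_difference_yields_one_proteotypic_pair(toy_pair):
    records = map_proteotypic(toy_pair, DigestionParams(max_missed=0))
    by_parents = {}
    for r in records:
        by_parents.setdefault(frozenset(r.parents), []).append(r.sequence)
    assert sorted(by_parents[frozenset({"P_A"})]) == ["GGGWWWK"]
    assert sorted(by_parents[frozenset({"P_B"})]) == ["GGGWWWR"]
    shared = by_parents[frozenset({"P_A", "P_B"})]
    assert "AAADDDK" in shared


def test_single_protein_database_all_proteotypic():
    db = DatabaseContext("solo", [ProteinEntry("P", TOY_A)])
    records = map_proteotypic(db)
    assert records and all(r.proteotypic_in["solo"] for r in records)


def test_il_equivalent_proteins_are_indistinguishable():
    a = ProteinEntry("PI", "AAAIDDKGGGWWWK")
    b = ProteinEntry("PL", "AAALDDKGGGWWWK")
    db = DatabaseContext("ctx", [a, b])
    records = map_proteotypic(db, DigestionParams(max_missed=0, il_equivalent=True))
    assert not any(r.proteotypic_in["ctx"] for r in records if len(r.parents) == 1)
    records = map_proteotypic(db, DigestionParams(max_missed=0, il_equivalent=False))
    proteo = {r.sequence for r in records if r.proteotypic_in["ctx"]}
    assert proteo == {"AAAIDDK", "AAALDDK"}


def test_context_monotonicity_randomized():
    """Proteotypic counts can only shrink when the database grows."""
    rng = np.random.default_rng(42)
    residues = list("ACDEFGHIKLMNPQRSTVWY")
    for trial in range(30):
        n = int(rng.integers(2, 5))
        entries = [
            ProteinEntry(f"P{i}", "".join(rng.choice(residues, size=30)))
            for i in range(n)
        ]
        extra = [
            ProteinEntry(f"X{i}", "".join(rng.choice(residues, size=30)))
            for i in range(int(rng.integers(1, 4)))
        ]
        sub = DatabaseContext("sub", entries)
        sup = DatabaseContext("sup", entries + extra)
        counts_sub = {e.accession: 0 for e in entries}
        counts_sup = dict(counts_sub)
        for r in map_proteotypic(sub):
            if r.proteotypic_in["sub"]:
                counts_sub[r.parent] += 1
        for r in map_proteotypic(sup):
            if r.proteotypic_in["sup"] and r.parent in counts_sup:
                counts_sup[r.parent] += 1
        for acc in counts_sub:
            assert counts_sup[acc] <= counts_sub[acc]


# ---------------------------------------------------------------------------
# context comparison


def test_compare_identical_contexts_no_differences(toy_pair):
    other = DatabaseContext("other", list(toy_pair.entries))
    cmp = compare_contexts(toy_pair, other)
    assert cmp.counts_a == cmp.counts_b
    assert cmp.unidentifiable_in_b == []
    assert cmp.lost_peptides == {}


def test_background_copy_steals_proteotypic_status(toy_pair):
    thief = ProteinEntry("BKG", "GGGWWWK" + "AAACCCK", is_family_member=False)
    sup = DatabaseContext("sup", list(toy_pair.entries) + [thief])
    cmp = compare_contexts(toy_pair, sup, DigestionParams(max_missed=0))
    assert cmp.counts_a["P_A"] == 1 and cmp.counts_b["P_A"] == 0
    assert "GGGWWWK" in cmp.lost_peptides["P_A"]
    # P_A had a single proteotypic peptide, so it becomes unidentifiable
    assert cmp.unidentifiable_in_b == ["P_A"]


def test_compare_contexts_rejects_mismatched_families(toy_pair):
    altered = DatabaseContext(
        "alt",
        [ProteinEntry("P_A", TOY_B, gene_locus="locA"),
         ProteinEntry("P_B", TOY_A, gene_locus="locB")],
    )
    with pytest.raises(ValueError, match="family sequences differ"):
        compare_contexts(toy_pair, altered)


# ---------------------------------------------------------------------------
# long-form screening


def test_long_form_screening_verdicts(toy_pair):
    base = toy_pair.entries[0]
    supported = make_long_form(base, "NNNEEEQQQK", accession="LF1")
    db = DatabaseContext("ctx", list(toy_pair.entries) + [supported])
    params = DigestionParams(max_missed=0)
    reports = screen_long_forms(db, observed_peptides={"NNNEEEQQQK"}, params=params)
    assert reports[0].verdict == "supported"
    reports = screen_long_forms(db, observed_peptides={"AAADDDK"}, params=params)
    assert reports[0].verdict == "not supported at protein level"
    # extension with no admissible peptide in the window (too short)
    undecidable = make_long_form(base, "GG", accession="LF2")
    db2 = DatabaseContext("ctx2", list(toy_pair.entries) + [undecidable])
    reports = screen_long_forms(db2, observed_peptides=set(), params=params)
    assert reports[0].verdict == "undecidable"


def test_long_form_screening_without_long_forms_is_empty(toy_pair):
    assert screen_long_forms(toy_pair, set()) == []


# ---------------------------------------------------------------------------
# pairwise identity


def test_identity_of_identical_sequences_is_100():
    assert pairwise_identity(TOY_A, TOY_A) == pytest.approx(100.0)


def test_identity_single_substitution():
    assert pairwise_identity("ACD", "ACE") == pytest.approx(66.7, abs=0.05)


def test_identity_summary_mean():
    entries = [
        ProteinEntry("A", "AAADDDKGGGWWWK"),
        ProteinEntry("B", "AAADDDKGGGWWWR"),
        ProteinEntry("C", "AAADDDKGGGWWWK"[::-1]),
    ]
    summary = identity_summary(entries)
    assert len(summary.pair_identities) == 3
    assert summary.mean_identity == pytest.approx(
        sum(summary.pair_identities.values()) / 3
    )
    assert all(0 <= v <= 100 for v in summary.pair_identities.values())
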