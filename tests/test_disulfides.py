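"""Disulfide-linked species construction, hypothetical-pair enumeration, and
the scrambling check, with an atomic-composition oracle for the mass rule."""

import pytest
from pyteomics import mass as pyt_mass

from trapmap import (
    DimerAssembly,
    DisulfideBond,
    LinkedPeptideSpecies,
    PeakList,
    PeptideSpecies,
    ProteinChain,
    build_linked_species,
    detect_mispairing,
    enumerate_hypothetical_pairs,
    nonreduced_digest,
)
from trapmap.masses import DISULFIDE_DELTA_MONO, PROTON


def _pep(seq, start=1, chain="A"):
    return PeptideSpecies(chain, start, start + len(seq) - 1, seq)


def _oracle_linked_mass(sequences, n_bonds):
    """Independent atomic-composition route: sum compositions, remove 2H/bond."""
    comp = pyt_mass.Composition()
    for s in sequences:
        comp += pyt_mass.Composition(sequence=s)
    comp["H"] -= 2 * n_bonds
    return pyt_mass.calculate_mass(composition=comp)


@pytest.mark.parametrize(
    "sequences,bonds",
    [(["CK", "CR"], 1), (["ACDK", "GCR"], 1), (["TCPCK", "TCPCK"], 2), (["CGCK"], 1)],
)
def test_linked_mass_rule_equals_atomic_oracle(sequences, bonds):
    members = tuple(_pep(s, start=10 * i + 1) for i, s in enumerate(sequences))
    sp = LinkedPeptideSpecies(members, bonds)
    assert sp.mono_mass == pytest.approx(_oracle_linked_mass(sequences, bonds), abs=1e-4)


def test_two_bond_homopair_loses_four_hydrogens():
    pep = _pep("TCPCK")
    single = LinkedPeptideSpecies((pep, pep), 1)
    double = LinkedPeptideSpecies((pep, pep), 2)
    assert single.mono_mass - double.mono_mass == pytest.approx(
        DISULFIDE_DELTA_MONO, abs=1e-9
    )
    assert double.mono_mass == pytest.approx(2 * pep.mass() - 4.03130, abs=1e-4)


def test_assembly_validation():
    a = ProteinChain("A", "ACKGCR")
    b = ProteinChain("B", "ACKGCR")
    DimerAssembly((a, b), (DisulfideBond("A", 2, "B", 2),))
    with pytest.raises(ValueError, match="not a cysteine"):
        DimerAssembly((a, b), (DisulfideBond("A", 1, "B", 2),))
    with pytest.raises(ValueError, match="more than one bond"):
        DimerAssembly(
            (a, b),
            (DisulfideBond("A", 2, "B", 2), DisulfideBond("A", 2, "B", 5)),
        )
    with pytest.raises(ValueError, match="unknown chain"):
        DimerAssembly((a, b), (DisulfideBond("A", 2, "C", 2),))


def test_pool_conserves_cysteines(paper_fixture):
    pool = nonreduced_digest(paper_fixture.assembly)
    pool_cys = sum(p.sequence.count("C") for p in pool)
    chain_cys = sum(c.sequence.count("C") for c in paper_fixture.assembly.chains)
    assert pool_cys == chain_cys


def test_preset_topology_yields_five_species_with_hinge_double_bond(paper_fixture):
    species = paper_fixture.expected_linked_species()
    assert len(species) == 5
    double = [sp for sp in species if sp.bond_count == 2]
    assert len(double) == 1
    hinge = double[0]
    assert len(hinge.members) == 2
    assert hinge.members[0].sequence == hinge.members[1].sequence
    assert {sp.members[0].chain_id for sp in species} <= {"A", "B"}


def test_chain_without_cysteines_yields_no_linkable_peptides():
    a = ProteinChain("A", "GGKAAR")
    b = ProteinChain("B", "GGKAAR")
    assembly = DimerAssembly((a, b), ())
    pool = nonreduced_digest(assembly)
    assert enumerate_hypothetical_pairs(pool) == []


def test_hypothetical_pair_count():
    pool = [_pep("ACK", 1), _pep("GCR", 10), _pep("TTCK", 20)]
    pairs = enumerate_hypothetical_pairs(pool)
    assert len(pairs) == 6  # C(3,2) + 3 self-pairs
    single = enumerate_hypothetical_pairs([_pep("ACK")])
    assert len(single) == 1 and len(single[0].members) == 2


def test_expected_species_contained_in_hypothetical_enumeration(paper_fixture):
    pool = nonreduced_digest(paper_fixture.assembly)
    hyp = {sp.signature() for sp in enumerate_hypothetical_pairs(pool)}
    for sp in paper_fixture.expected_linked_species():
        assert sp.signature() in hyp


def test_homodimer_symmetry_invariance(paper_fixture):
    assembly = paper_fixture.assembly
    assert assembly.is_symmetric_homodimer()
    a, b = assembly.chains
    swapped = DimerAssembly(
        (ProteinChain("A", b.sequence), ProteinChain("B", a.sequence)),
        tuple(
            DisulfideBond(
                {"A": "B", "B": "A"}[x.chain_a], x.pos_a,
                {"A": "B", "B": "A"}[x.chain_b], x.pos_b,
            )
            for x in assembly.bonds
        ),
    )
    orig = build_linked_species(nonreduced_digest(assembly), assembly.bonds)
    swap = build_linked_species(nonreduced_digest(swapped), swapped.bonds)
    assert {sp.signature() for sp in orig} == {sp.signature() for sp in swap}


def test_intra_peptide_bond_gives_looped_species():
    a = ProteinChain("A", "TCPCKGGR")
    b = ProteinChain("B", "TCPCKGGR")
    bonds = (DisulfideBond("A", 2, "A", 4), DisulfideBond("B", 2, "B", 4))
    assembly = DimerAssembly((a, b), bonds)
    species = build_linked_species(nonreduced_digest(assembly), bonds)
    assert len(species) == 1
    assert len(species[0].members) == 1 and species[0].bond_count == 1
    assert species[0].mono_mass == pytest.approx(
        species[0].members[0].mass() - DISULFIDE_DELTA_MONO, abs=1e-9
    )


def test_missing_bond_endpoint_is_rejected_by_name():
    pool = [_pep("ACK", 1)]
    with pytest.raises(ValueError, match="A:99"):
        build_linked_species(pool, [DisulfideBond("A", 2, "A", 99)])


# ---------------------------------------------------------------------------
# scrambling


def test_exact_expected_peaks_give_no_scrambling(paper_fixture):
    expected = paper_fixture.expected_linked_species()
    pool = nonreduced_digest(paper_fixture.assembly)
    hyp = enumerate_hypothetical_pairs(pool)
    peaks = PeakList.from_values([sp.mh_plus for sp in expected])
    report = detect_mispairing(peaks, expected, hyp, 0.5)
    assert len(report.expected_matched) == 5
    assert not report.expected_unmatched
    assert not report.scrambling_detected


def test_non_native_pair_mass_is_flagged(paper_fixture):
    expected = paper_fixture.expected_linked_species()
    pool = nonreduced_digest(paper_fixture.assembly)
    hyp = enumerate_hypothetical_pairs(pool)
    expected_sigs = {sp.signature() for sp in expected}
    rogue = next(sp for sp in hyp if sp.signature() not in expected_sigs)
    peaks = PeakList.from_values([sp.mh_plus for sp in expected] + [rogue.mh_plus])
    report = detect_mispairing(peaks, expected, hyp, 0.1)
    assert len(report.scrambling_hits) == 1
    hit = report.scrambling_hits[0].candidate
    assert hit.signature() == rogue.signature()
    assert all("C" in p.sequence for p in hit.members)


def test_empty_peak_list_leaves_all_expected_unmatched(paper_fixture):
    expected = paper_fixture.expected_linked_species()
    report = detect_mispairing(PeakList(()), expected, [], 0.5)
    assert len(report.expected_unmatched) == 5 and not report.expected_matched
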