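"""Glycan composition arithmetic, 2-AA labeling, glycopeptide masses, and
the bounded-lattice composition search."""

import pytest
from pyteomics import mass as pyt_mass

from trapmap import (
    BUILTIN_GLYCAN_LIBRARY,
    GlycanComposition,
    PeakList,
    PeptideSpecies,
    assign_site_glycoforms,
    composition_mass,
    composition_search,
    glycan_residue_mass,
    glycopeptide_mass,
    label_2aa,
    peptide_mass,
)
from trapmap.masses import DEAMIDATION_MONO, WATER_MONO

_MONO_FORMULA = {
    "hex": "C6H10O5",
    "hexnac": "C8H13NO5",
    "deoxyhexose": "C6H10O4",
    "neuac": "C11H17NO8",
}


def _oracle_free_mass(comp: GlycanComposition) -> float:
    total = pyt_mass.calculate_mass(formula="H2O")
    for name, n in comp.counts().items():
        total += n * pyt_mass.calculate_mass(formula=_MONO_FORMULA[name])
    if comp.label == "2AA":
        total += (
            pyt_mass.calculate_mass(formula="C7H7NO2")
            - pyt_mass.calculate_mass(formula="H2O")
            + pyt_mass.calculate_mass(formula="H2")
        )
    return total


def test_core_only_mass_frozen_value():
    core = GlycanComposition()
    assert composition_mass(core).daltons == pytest.approx(910.32778, abs=1e-4)


def test_empty_composition_without_core_is_bare_water():
    empty = GlycanComposition(core=False)
    assert composition_mass(empty).daltons == pytest.approx(WATER_MONO, abs=1e-9)


@pytest.mark.parametrize("comp", BUILTIN_GLYCAN_LIBRARY, ids=lambda c: c.notation())
def test_library_masses_equal_atomic_oracle(comp):
    assert composition_mass(comp).daltons == pytest.approx(_oracle_free_mass(comp), abs=1e-4)


def test_composition_mass_linear_in_counts():
    a = GlycanComposition(1, 0, 1, 0, core=False)
    b = GlycanComposition(0, 2, 0, 1, core=False)
    merged = GlycanComposition(1, 2, 1, 1, core=False)
    assert composition_mass(merged).daltons - WATER_MONO == pytest.approx(
        (composition_mass(a).daltons - WATER_MONO)
        + (composition_mass(b).daltons - WATER_MONO),
        abs=1e-9,
    )


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        GlycanComposition(hex=-1)


# ---------------------------------------------------------------------------
# 2-AA labeling


def test_2aa_label_adds_constant_positive_delta():
    deltas = {
        label_2aa(c).daltons - composition_mass(c).daltons for c in BUILTIN_GLYCAN_LIBRARY
    }
    assert len({round(d, 6) for d in deltas}) == 1
    assert deltas.pop() > 0


def test_2aa_labeled_core_matches_oracle():
    core = GlycanComposition()
    from dataclasses import replace

    assert label_2aa(core).daltons == pytest.approx(
        _oracle_free_mass(replace(core, label="2AA")), abs=1e-4
    )


def test_double_labeling_rejected():
    labeled = GlycanComposition(label="2AA")
    with pytest.raises(ValueError, match="already labeled"):
        label_2aa(labeled)


# ---------------------------------------------------------------------------
# notation


@pytest.mark.parametrize("comp", BUILTIN_GLYCAN_LIBRARY, ids=lambda c: c.notation())
def test_notation_round_trip(comp):
    assert GlycanComposition.from_notation(comp.notation()) == comp


def test_parse_report_style_notation():
    comp = GlycanComposition.from_notation(
        "(Hex)2(HexNAc)2(Deoxyhexose)1(NeuAc)2+(Man)3(GlcNAc)2"
    )
    assert comp == GlycanComposition(2, 2, 1, 2, core=True)
    with pytest.raises(ValueError):
        GlycanComposition.from_notation("(Pentose)1")


# ---------------------------------------------------------------------------
# glycopeptides


def _pep(seq, start=1):
    return PeptideSpecies("A", start, start + len(seq) - 1, seq)


def test_fc_truncated_glycoform_mass_equals_oracle():
    pep = _pep("EEQYNSTYR")
    comp = GlycanComposition(0, 2, 0, 0)  # (HexNAc)2 + core
    expected = pyt_mass.calculate_mass(sequence="EEQYNSTYR") + (
        _oracle_free_mass(comp) - pyt_mass.calculate_mass(formula="H2O")
    )
    assert glycopeptide_mass(pep, comp).daltons == pytest.approx(expected, abs=1e-4)


def test_empty_glycan_leaves_peptide_mass_unchanged():
    pep = _pep("NSTFVR")
    comp = GlycanComposition(core=False)
    assert glycopeptide_mass(pep, comp).daltons == pytest.approx(pep.mass(), abs=1e-9)


def test_glycan_increment_identical_across_peptides():
    comp = GlycanComposition(2, 2, 1, 1)
    incs = {
        round(glycopeptide_mass(_pep(s), comp).daltons - _pep(s).mass(), 6)
        for s in ("NSTFVR", "EEQYNSTYR", "VTSPNITVTLK")
    }
    assert len(incs) == 1


def test_sequon_free_peptide_rejected():
    with pytest.raises(ValueError, match="sequon"):
        glycopeptide_mass(_pep("GGGGK"), GlycanComposition())


def test_glycopeptide_vs_deamidated_peptide_consistency(paper_fixture):
    # glycopeptide mass - deglycosylated(deamidated) peptide mass
    #   = glycan residue mass - deamidation delta, at every site
    from trapmap import apply_pngasef

    site_peps = paper_fixture.site_peptides()
    for pos, forms in paper_fixture.glycoform_table.items():
        pep = site_peps[pos]
        site = next(s for s in paper_fixture.sequons if s.position == pos)
        deam = apply_pngasef([pep], [site])[0]
        for comp in forms:
            diff = glycopeptide_mass(pep, comp).daltons - deam.mass()
            assert diff == pytest.approx(
                glycan_residue_mass(comp) - DEAMIDATION_MONO, abs=1e-9
            )


# ---------------------------------------------------------------------------
# composition search


@pytest.mark.parametrize("comp", BUILTIN_GLYCAN_LIBRARY, ids=lambda c: c.notation())
def test_search_round_trips_library_rank_one(comp):
    hits = composition_search(composition_mass(comp).daltons, tol=0.01)
    assert hits[0][0] == comp
    assert len(hits) == 1  # no degeneracy within 0.01 Da on this lattice


def test_search_zero_tolerance_on_non_matching_mass():
    assert composition_search(1234.5, tol=0.0) == []


def test_search_reports_near_degenerate_pairs_deterministically():
    target = composition_mass(GlycanComposition(2, 2, 1, 1)).daltons
    hits = composition_search(target, tol=150.0)
    assert len(hits) > 2
    assert hits == sorted(
        hits, key=lambda ce: (abs(ce[1]), ce[0].hex, ce[0].hexnac, ce[0].deoxyhexose, ce[0].neuac)
    )


# ---------------------------------------------------------------------------
# per-site assignment


def test_empty_group_yields_empty_table(paper_fixture):
    site_peps = paper_fixture.site_peptides()
    df = assign_site_glycoforms({33: PeakList(())}, site_peps, list(BUILTIN_GLYCAN_LIBRARY))
    assert df.empty


def test_assignment_rejects_sequon_free_peptide():
    with pytest.raises(ValueError, match="sequon"):
        assign_site_glycoforms(
            {1: PeakList.from_values([1000.0])},
            {1: _pep("GGGGK")},
            list(BUILTIN_GLYCAN_LIBRARY),
        )
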