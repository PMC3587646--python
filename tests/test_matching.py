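"""MH+/m/z arithmetic, PNGase F simulation, variant expansion, tolerance
matching against a brute-force oracle, coverage, and b/y fragment ions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trapmap import (
    DEAMIDATION_N,
    OXIDATION_M,
    Peak,
    PeakList,
    PeptideSpecies,
    ProteinChain,
    SequonSite,
    apply_pngasef,
    coverage,
    expand_variants,
    fragment_ions,
    mass_from_mz,
    match_peaks,
    mh_plus,
    mz,
)
from trapmap.masses import DEAMIDATION_MONO, ISOTOPE_SPACING, PROTON


def _pep(seq, start=1, chain="A"):
    return PeptideSpecies(chain, start, start + len(seq) - 1, seq)


# ---------------------------------------------------------------------------
# mass arithmetic


def test_mh_plus_and_mz_basics():
    assert mh_plus(0.0) == pytest.approx(1.007276)
    assert mz(1000.0, 1) == pytest.approx(1001.007276)
    assert mz(1000.0, 2) == pytest.approx(501.007276)
    assert mz(1000.0, 1) == mh_plus(1000.0)
    with pytest.raises(ValueError):
        mz(1000.0, 0)


@settings(deadline=None)
@given(st.floats(min_value=100, max_value=10000), st.integers(min_value=1, max_value=5))
def test_mz_round_trip(mass, z):
    assert mass_from_mz(mz(mass, z), z) == pytest.approx(mass, abs=1e-9)


# ---------------------------------------------------------------------------
# PNGase F


def test_pngasef_deamidates_occupied_sequon():
    pep = _pep("NSTFVR", start=193)
    out = apply_pngasef([pep], [SequonSite(193, "NST", occupied=True)])
    assert out[0].mass() - pep.mass() == pytest.approx(DEAMIDATION_MONO, abs=1e-9)
    assert out[0].mods[0].position == 1


def test_pngasef_leaves_sequon_free_peptides_unchanged():
    pep = _pep("GGGGK")
    out = apply_pngasef([pep], [])
    assert out[0] is pep


def test_pngasef_two_sequons_additive():
    pep = _pep("NSTANSTK", start=1)
    sites = [SequonSite(1, "NST", True), SequonSite(5, "NST", True)]
    out = apply_pngasef([pep], sites)
    assert out[0].mass() - pep.mass() == pytest.approx(2 * DEAMIDATION_MONO, abs=1e-9)


def test_pngasef_warns_on_uncovered_site():
    with pytest.warns(UserWarning, match="covered by no peptide"):
        apply_pngasef([_pep("GGGGK")], [SequonSite(50, "NST", True)])


# ---------------------------------------------------------------------------
# variable modification expansion


def test_expand_variants_counts_and_deltas():
    assert len(expand_variants(_pep("AAA"), [OXIDATION_M], 3)) == 1
    mam = expand_variants(_pep("MAM"), [OXIDATION_M], 2)
    assert len(mam) == 4  # none, M1, M3, both
    ng = expand_variants(_pep("NG"), [DEAMIDATION_N], 1)
    assert len(ng) == 2
    assert ng[1].mass() - ng[0].mass() == pytest.approx(DEAMIDATION_MONO, abs=1e-9)


# ---------------------------------------------------------------------------
# matching


def test_exact_peak_has_zero_error():
    cand = _pep("ELVIPCR")
    res = match_peaks(PeakList.from_values([cand.mass() + PROTON]), [cand], 0.5)
    assert res[0].candidate is cand and res[0].error_da == pytest.approx(0.0, abs=1e-12)


def test_empty_candidate_set_leaves_peaks_unmatched():
    res = match_peaks(PeakList.from_values([500.0]), [], 0.5)
    assert res[0].candidate is None


def test_isotope_offset_retry_flags_match():
    cand = _pep("ELVIPCR")
    peak = PeakList.from_values([cand.mass() + PROTON + ISOTOPE_SPACING + 0.1])
    miss = match_peaks(peak, [cand], 0.3)
    assert miss[0].candidate is None
    hit = match_peaks(peak, [cand], 0.3, check_isotope_offset=True)
    assert hit[0].candidate is cand and hit[0].isotope_offset


def _oracle_match(peaks, candidates, tol):
    # independent exhaustive all-pairs assignment with the documented tie-breaks
    out = []
    for peak in peaks:
        obs = peak.neutral_mass()
        scored = []
        for c in candidates:
            err = obs - c.mass()
            if abs(err) <= tol:
                scored.append((abs(err), len(c.mods), c.sequence, c, err))
        scored.sort(key=lambda t: t[:3])
        out.append(scored[0][3] if scored else None)
    return out


@pytest.mark.parametrize("seed", range(5))
def test_matching_equals_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    candidates = [
        _pep("".join(rng.choice(alphabet, size=rng.integers(5, 15))))
        for _ in range(200)
    ]
    peaks = PeakList.from_values(rng.uniform(400, 2000, size=50))
    got = [r.candidate for r in match_peaks(peaks, candidates, 0.5)]
    assert got == _oracle_match(peaks, candidates, 0.5)


def test_matching_order_invariance():
    cands = [_pep("GGGGK"), _pep("AAAAK")]
    peaks = PeakList.from_values([cands[0].mass() + PROTON])
    a = match_peaks(peaks, cands, 0.5)[0].candidate
    b = match_peaks(peaks, cands[::-1], 0.5)[0].candidate
    assert a is b


# ---------------------------------------------------------------------------
# coverage


def test_coverage_empty_and_full(paper_fixture):
    chain = paper_fixture.chain
    assert coverage([], chain).fraction == 0.0
    from trapmap import TRYPSIN, digest, match_peaks as mp

    peps = digest(chain, TRYPSIN, 0)
    res = mp(PeakList.from_values([p.mass() + PROTON for p in peps]), peps, 0.5)
    assert coverage(res, chain).fraction == pytest.approx(1.0)


def test_coverage_interval_union():
    chain = ProteinChain("A", "G" * 39 + "K")
    p1, p2 = PeptideSpecies("A", 1, 10, "G" * 10), PeptideSpecies("A", 5, 20, "G" * 16)
    res = match_peaks(
        PeakList.from_values([p1.mass() + PROTON, p2.mass() + PROTON]), [p1, p2], 0.5
    )
    rep = coverage(res, chain)
    assert rep.fraction == pytest.approx(0.5)
    assert rep.intervals == ((1, 20),)


# ---------------------------------------------------------------------------
# fragment ions


def test_gg_fragments_frozen_values():
    assert fragment_ions("GG", "b")[0] == pytest.approx(58.02874, abs=1e-4)
    assert fragment_ions("GG", "y")[0] == pytest.approx(76.03931, abs=1e-4)


@settings(deadline=None)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=20))
def test_b_y_complementarity(seq):
    pep = _pep(seq)
    b, y = fragment_ions(pep, "b"), fragment_ions(pep, "y")
    total = pep.mass() + 2 * PROTON
    for i in range(1, len(seq)):
        assert b[i - 1] + y[len(seq) - i - 1] == pytest.approx(total, abs=1e-6)


def test_fragment_ions_include_modification_mass():
    pep = _pep("NSTFVR")
    sites = [SequonSite(1, "NST", True)]
    mod = apply_pngasef([pep], sites)[0]
    b_plain, b_mod = fragment_ions(pep, "b"), fragment_ions(mod, "b")
    assert b_mod[0] - b_plain[0] == pytest.approx(DEAMIDATION_MONO, abs=1e-9)


def test_fragment_ions_rejections():
    with pytest.raises(ValueError):
        fragment_ions("G", "b")
    with pytest.raises(ValueError):
        fragment_ions("GG", "c")
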