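"""Theory-vs-observation matching: MH+/m/z arithmetic, PNGase F simulation,
variable-modification expansion, tolerance matching, coverage, b/y ions.

Observed peaks may be given as MH+ (``charge=None``) or as (m/z, z); the
matcher canonicalizes everything to neutral monoisotopic mass before
comparing.  Default tolerance is +/-0.5 Da, ion-trap scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .digestion import PeptideSpecies
from .masses import ISOTOPE_SPACING, MassValue, PROTON, WATER_MONO, residue_mass
from .proteoforms import (
    AppliedModification,
    Modification,
    PNGASEF_DEAMIDATION,
    ProteinChain,
    SequonSite,
    peptide_mass,
)

DEFAULT_TOL_DA = 0.5


def mh_plus(mass: MassValue | float) -> float:
    """Singly protonated mass MH+ = neutral mass + one proton."""
    m = mass.daltons if isinstance(mass, MassValue) else float(mass)
    if m < 0:
        raise ValueError("mass must be non-negative")
    return m + PROTON


def mz(mass: MassValue | float, z: int) -> float:
    """m/z of a z-protonated ion; ``mz(m, 1)`` equals ``mh_plus(m)``."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    m = mass.daltons if isinstance(mass, MassValue) else float(mass)
    return (m + z * PROTON) / z


def mass_from_mz(observed: float, z: int) -> float:
    """Neutral mass from an observed m/z at charge z (inverse of :func:`mz`)."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return observed * z - z * PROTON


@dataclass(frozen=True)
class Peak:
    """One observed peak.  ``charge=None`` means the value is already MH+."""

    observed: float
    charge: int | None = None
    retention_time: float | None = None
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.observed <= 0:
            raise ValueError("observed mass/mz must be positive")
        if self.charge is not None and self.charge < 1:
            raise ValueError("charge must be >= 1 when present")

    def neutral_mass(self) -> float:
        z = 1 if self.charge is None else self.charge
        return mass_from_mz(self.observed, z)


@dataclass(frozen=True)
class PeakList:
    entries: tuple[Peak, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_values(cls, mh_values: Iterable[float]) -> "PeakList":
        """Build from a flat list of MH+ values."""
        return cls(tuple(Peak(v) for v in mh_values))


@dataclass(frozen=True)
class MatchResult:
    """A peak with its best assignment, or unassigned (candidate None)."""

    peak: Peak
    candidate: object | None  # PeptideSpecies, LinkedPeptideSpecies, ...
    error_da: float | None
    error_ppm: float | None
    isotope_offset: bool = False


@dataclass(frozen=True)
class CoverageReport:
    chain_id: str
    intervals: tuple[tuple[int, int], ...]
    fraction: float


# ---------------------------------------------------------------------------


def apply_pngasef(
    peptides: Iterable[PeptideSpecies], occupied_sites: Sequence[SequonSite]
) -> list[PeptideSpecies]:
    """Simulate PNGase F: occupied sequon Asn -> Asp on overlapping peptides.

    Each occupied site inside a peptide adds one fixed deamidation
    (+0.98402 Da mono) at that Asn.  Sites covered by no peptide raise a
    warning, not an error.
    """
    peptides = list(peptides)
    covered = [False] * len(occupied_sites)
    out = []
    for pep in peptides:
        applied = []
        for i, site in enumerate(occupied_sites):
            if not site.occupied:
                continue
            if pep.start <= site.position <= pep.end:
                covered[i] = True
                applied.append(
                    AppliedModification(PNGASEF_DEAMIDATION, site.position - pep.start + 1)
                )
        out.append(pep.with_mods(applied) if applied else pep)
    for site, c in zip(occupied_sites, covered):
        if site.occupied and not c:
            warnings.warn(f"occupied sequon at {site.position} covered by no peptide")
    return out


def expand_variants(
    peptide: PeptideSpecies,
    variable_mods: Sequence[Modification],
    max_mods: int,
) -> list[PeptideSpecies]:
    """All placements of at most ``max_mods`` variable modifications.

    Eligible positions are target residues not already carrying a
    modification.  The unmodified form is always included first.
    """
    if max_mods < 0:
        raise ValueError("max_mods must be >= 0")
    taken = {m.position for m in peptide.mods}
    slots = [
        (i + 1, mod)
        for mod in variable_mods
        for i, aa in enumerate(peptide.sequence)
        if aa in mod.targets and (i + 1) not in taken
    ]
    out = [peptide]
    for k in range(1, max_mods + 1):
        for combo in combinations(slots, k):
            if len({pos for pos, _ in combo}) < k:
                continue  # two mods on one residue
            out.append(
                peptide.with_mods(AppliedModification(mod, pos) for pos, mod in combo)
            )
    return out


def _candidate_mass(candidate) -> float:
    if hasattr(candidate, "mono_mass"):
        return candidate.mono_mass
    return candidate.mass("monoisotopic")


def _n_mods(candidate) -> int:
    return len(getattr(candidate, "mods", ()))


def _cand_seq(candidate) -> str:
    if hasattr(candidate, "sequence"):
        return candidate.sequence
    return "+".join(sorted(p.sequence for p in getattr(candidate, "members", ())))


def match_peaks(
    peaks: PeakList | Iterable[Peak],
    candidates: Sequence,
    tol_da: float = DEFAULT_TOL_DA,
    tol_ppm: float | None = None,
    check_isotope_offset: bool = False,
) -> list[MatchResult]:
    """Assign each peak its best candidate within tolerance.

    Best = smallest |error in Da|; ties broken by fewer modifications, then
    lexicographic sequence.  With ``check_isotope_offset``, a peak matching
    nothing is retried with a -1.00335 Da shift (mis-picked +1 isotope) and
    flagged if that succeeds.  Equivalent to exhaustive all-pairs search.
    """
    if tol_da <= 0 and (tol_ppm is None or tol_ppm <= 0):
        raise ValueError("need a positive tol_da or tol_ppm")
    results = []
    for peak in peaks:
        obs = peak.neutral_mass()
        best = _best_candidate(obs, candidates, tol_da, tol_ppm)
        iso = False
        if best is None and check_isotope_offset:
            best = _best_candidate(obs - ISOTOPE_SPACING, candidates, tol_da, tol_ppm)
            iso = best is not None
        if best is None:
            results.append(MatchResult(peak, None, None, None))
        else:
            cand, err = best
            results.append(
                MatchResult(peak, cand, err, err / _candidate_mass(cand) * 1e6, iso)
            )
    return results


def _best_candidate(obs: float, candidates, tol_da, tol_ppm):
    best = None
    best_key = None
    for cand in candidates:
        theo = _candidate_mass(cand)
        err = obs - theo
        if tol_da is not None and tol_da > 0:
            within = abs(err) <= tol_da
        else:
            within = abs(err) / theo * 1e6 <= tol_ppm
        if tol_ppm is not None and tol_ppm > 0 and tol_da and tol_da > 0:
            within = within and abs(err) / theo * 1e6 <= tol_ppm
        if not within:
            continue
        key = (abs(err), _n_mods(cand), _cand_seq(cand))
        if best_key is None or key < best_key:
            best, best_key = (cand, err), key
    return best


def coverage(matches: Iterable[MatchResult], chain: ProteinChain) -> CoverageReport:
    """Fraction of the chain covered by the union of matched peptide intervals."""
    ivs = sorted(
        (m.candidate.start, m.candidate.end)
        for m in matches
        if m.candidate is not None
        and isinstance(m.candidate, PeptideSpecies)
        and m.candidate.chain_id == chain.chain_id
    )
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    covered = sum(e - s + 1 for s, e in merged)
    return CoverageReport(
        chain.chain_id,
        tuple((s, e) for s, e in merged),
        covered / len(chain.sequence),
    )


def fragment_ions(
    peptide: PeptideSpecies | str,
    series: str,
    z: int = 1,
    mods: Sequence[AppliedModification] = (),
) -> list[float]:
    """Singly charged (default) b- or y-ion m/z values, N->C / C->N ordered.

    b_i is the first i residues plus their mods plus z protons; y_j is the
    last j residues plus water plus z protons.  b_i + y_(n-i) = M + 2
    protons for every i (complementarity).
    """
    if isinstance(peptide, PeptideSpecies):
        seq, mods = peptide.sequence, peptide.mods
    else:
        seq = peptide
    if len(seq) < 2:
        raise ValueError("fragmentation needs a peptide of length >= 2")
    if series not in ("b", "y"):
        raise ValueError(f"series must be 'b' or 'y', got {series!r}")
    deltas = [0.0] * (len(seq) + 1)  # deltas[i]: mod mass on residue i (1-based)
    for am in mods:
        deltas[am.position] += am.mod.mono_delta
    residue_masses = [
        residue_mass(aa).daltons + deltas[i + 1] for i, aa in enumerate(seq)
    ]
    ions = []
    if series == "b":
        acc = 0.0
        for m in residue_masses[:-1]:
            acc += m
            ions.append((acc + z * PROTON) / z)
    else:
        acc = WATER_MONO
        for m in reversed(residue_masses[1:]):
            acc += m
            ions.append((acc + z * PROTON) / z)
    return ions
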