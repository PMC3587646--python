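"""Disulfide mapping: linked-peptide species from a non-reduced digest, the
exhaustive hypothetical-pair enumeration, and the scrambling check.

Every disulfide bond removes two hydrogens, so a linked species of b bonds
has mass sum(member masses) - b * 2.015650 Da (mono).  In a homodimer the
two chains carry identical intra-chain species; these collapse to a single
reported species, and the inter-chain hinge peptides form one species with
two bonds — the accounting that yields five di-peptides for a trap-type
fusion protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Sequence

import networkx as nx

from .digestion import PeptideSpecies, ProteaseRule, TRYPSIN, digest
from .masses import DISULFIDE_DELTA_MONO, PROTON, formula_mass
from .matching import MatchResult, Peak, PeakList, match_peaks
from .proteoforms import ProteinChain

_DISULFIDE_DELTA_AVG = formula_mass({"H": 2}, "average")


@dataclass(frozen=True)
class DisulfideBond:
    """One Cys-Cys bond between (chain_a, pos_a) and (chain_b, pos_b)."""

    chain_a: str
    pos_a: int
    chain_b: str
    pos_b: int

    def endpoints(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.chain_a, self.pos_a), (self.chain_b, self.pos_b))


@dataclass(frozen=True)
class DimerAssembly:
    """Two chains (identical sequence for a homodimer) plus bond topology."""

    chains: tuple[ProteinChain, ProteinChain]
    bonds: tuple[DisulfideBond, ...]

    def __post_init__(self) -> None:
        by_id = {c.chain_id: c for c in self.chains}
        if len(by_id) != 2:
            raise ValueError("assembly needs two chains with distinct ids")
        seen: set[tuple[str, int]] = set()
        for bond in self.bonds:
            for cid, pos in bond.endpoints():
                if cid not in by_id:
                    raise ValueError(f"bond references unknown chain {cid!r}")
                if by_id[cid].slice(pos, pos) != "C":
                    raise ValueError(
                        f"bond endpoint {cid}:{pos} is not a cysteine"
                    )
                if (cid, pos) in seen:
                    raise ValueError(f"cysteine {cid}:{pos} in more than one bond")
                seen.add((cid, pos))

    def chain(self, chain_id: str) -> ProteinChain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def is_symmetric_homodimer(self) -> bool:
        """True if both chains share a sequence and swapping chain labels
        maps the bond set onto itself."""
        a, b = self.chains
        if a.sequence != b.sequence:
            return False
        swap = {a.chain_id: b.chain_id, b.chain_id: a.chain_id}
        canon = {_canon_bond(x) for x in self.bonds}
        swapped = {
            _canon_bond(
                DisulfideBond(swap[x.chain_a], x.pos_a, swap[x.chain_b], x.pos_b)
            )
            for x in self.bonds
        }
        return canon == swapped


def _canon_bond(b: DisulfideBond) -> tuple:
    return tuple(sorted(b.endpoints()))


@dataclass(frozen=True)
class LinkedPeptideSpecies:
    """Peptides joined by ``bond_count`` disulfide bonds (size 1 = loop)."""

    members: tuple[PeptideSpecies, ...]
    bond_count: int
    bonds: tuple[DisulfideBond, ...] = ()

    def __post_init__(self) -> None:
        if not self.members or self.bond_count < 1:
            raise ValueError("linked species needs >=1 member and >=1 bond")

    @property
    def mono_mass(self) -> float:
        return (
            sum(p.mass("monoisotopic") for p in self.members)
            - self.bond_count * DISULFIDE_DELTA_MONO
        )

    @property
    def avg_mass(self) -> float:
        return (
            sum(p.mass("average") for p in self.members)
            - self.bond_count * _DISULFIDE_DELTA_AVG
        )

    @property
    def mh_plus(self) -> float:
        return self.mono_mass + PROTON

    def signature(self) -> tuple:
        """Chain-label-free identity: sorted member sequences + bond count.
        Symmetric homodimer copies share a signature and collapse."""
        return (tuple(sorted(p.sequence for p in self.members)), self.bond_count)


def nonreduced_digest(
    assembly: DimerAssembly,
    rule: ProteaseRule = TRYPSIN,
    max_missed: int = 0,
) -> list[PeptideSpecies]:
    """Digest both chains without reduction: no Cys blocking is applied and
    every peptide retains its global cysteine coordinates."""
    pool: list[PeptideSpecies] = []
    for chain in assembly.chains:
        pool.extend(digest(chain, rule, max_missed))
    return pool


def build_linked_species(
    pool: Sequence[PeptideSpecies],
    bonds: Sequence[DisulfideBond],
    collapse_symmetric: bool = True,
) -> list[LinkedPeptideSpecies]:
    """Connected components of the peptide-bond graph, one species each.

    Each bond endpoint must map to exactly one pool peptide; when the pool
    contains missed-cleavage variants, only the zero-missed peptides are
    used so the mapping stays unique.  With ``collapse_symmetric`` (default)
    species identical up to chain relabeling are reported once.
    """
    base = [p for p in pool if p.missed_cleavages == 0] or list(pool)
    by_cys: dict[tuple[str, int], PeptideSpecies] = {}
    for pep in base:
        for pos in pep.cys_positions():
            by_cys[(pep.chain_id, pos)] = pep

    graph = nx.MultiGraph()
    for bond in bonds:
        ends = []
        for cid, pos in bond.endpoints():
            pep = by_cys.get((cid, pos))
            if pep is None:
                raise ValueError(
                    f"bond endpoint {cid}:{pos} not found in the peptide pool"
                )
            ends.append((pep.chain_id, pep.start, pep.end))
            graph.add_node((pep.chain_id, pep.start, pep.end), peptide=pep)
        graph.add_edge(ends[0], ends[1], bond=bond)

    species = []
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        members = tuple(
            sorted(
                (graph.nodes[n]["peptide"] for n in comp),
                key=lambda p: (p.chain_id, p.start),
            )
        )
        comp_bonds = tuple(d["bond"] for _, _, d in sub.edges(data=True))
        species.append(LinkedPeptideSpecies(members, len(comp_bonds), comp_bonds))

    if collapse_symmetric:
        seen: dict[tuple, LinkedPeptideSpecies] = {}
        for sp in species:
            seen.setdefault(sp.signature(), sp)
        species = list(seen.values())
    species.sort(key=lambda s: s.signature())
    return species


def enumerate_hypothetical_pairs(
    pool: Sequence[PeptideSpecies],
) -> list[LinkedPeptideSpecies]:
    """Every hypothetical cysteine-linked di-peptide, for the scrambling check.

    Distinct Cys-bearing peptide species (by sequence) are paired in all
    unordered combinations including self-pairs: C(k,2) + k single-bond
    pairs, plus a two-bond variant wherever both members carry >=2
    cysteines.
    """
    uniq: dict[str, PeptideSpecies] = {}
    for pep in pool:
        if "C" in pep.sequence:
            uniq.setdefault(pep.sequence, pep)
    if len(uniq) < 1:
        return []
    peps = [uniq[s] for s in sorted(uniq)]
    out = []
    for a, b in combinations_with_replacement(peps, 2):
        out.append(LinkedPeptideSpecies((a, b), 1))
        if a.sequence.count("C") >= 2 and b.sequence.count("C") >= 2:
            out.append(LinkedPeptideSpecies((a, b), 2))
    return out


@dataclass(frozen=True)
class ScramblingReport:
    """Outcome of the mispairing check against observed peaks."""

    expected_matched: tuple[tuple[LinkedPeptideSpecies, MatchResult], ...]
    expected_unmatched: tuple[LinkedPeptideSpecies, ...]
    scrambling_hits: tuple[MatchResult, ...]
    unassigned_peaks: tuple[Peak, ...]

    @property
    def scrambling_detected(self) -> bool:
        return len(self.scrambling_hits) > 0


def detect_mispairing(
    peaks: PeakList | Iterable[Peak],
    expected: Sequence[LinkedPeptideSpecies],
    hypothetical: Sequence[LinkedPeptideSpecies],
    tol_da: float = 0.5,
) -> ScramblingReport:
    """Match peaks against expected species, then flag peaks explained only
    by a non-native (hypothetical but not expected) pairing."""
    if tol_da <= 0:
        raise ValueError("tolerance must be positive")
    peaks = list(peaks)
    expected_sigs = {sp.signature() for sp in expected}
    non_native = [sp for sp in hypothetical if sp.signature() not in expected_sigs]

    exp_results = match_peaks(peaks, expected, tol_da=tol_da)
    matched_sp: dict[tuple, MatchResult] = {}
    leftover: list[Peak] = []
    for res in exp_results:
        if res.candidate is not None:
            matched_sp.setdefault(res.candidate.signature(), res)
        else:
            leftover.append(res.peak)

    scram_results = match_peaks(leftover, non_native, tol_da=tol_da)
    hits = tuple(r for r in scram_results if r.candidate is not None)
    unassigned = tuple(r.peak for r in scram_results if r.candidate is None)

    matched = tuple(
        (sp, matched_sp[sp.signature()]) for sp in expected if sp.signature() in matched_sp
    )
    unmatched = tuple(sp for sp in expected if sp.signature() not in matched_sp)
    return ScramblingReport(matched, unmatched, hits, unassigned)
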