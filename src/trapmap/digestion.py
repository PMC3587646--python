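"""Rule-based in-silico protease digestion with coordinate-annotated peptides."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .masses import PROTON, WATER_MONO
from .proteoforms import AppliedModification, Modification, ProteinChain, peptide_mass


@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage specificity: cut after ``cut_after`` unless the next residue
    is in ``blocked_by_next``."""

    name: str
    cut_after: frozenset[str] = frozenset()
    blocked_by_next: frozenset[str] = frozenset()


TRYPSIN = ProteaseRule("trypsin", frozenset("KR"), frozenset("P"))
NO_PROTEASE = ProteaseRule("none")


@dataclass(frozen=True)
class PeptideSpecies:
    """A digested peptide: chain slice [start..end] plus applied mods."""

    chain_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int = 0
    mods: tuple[AppliedModification, ...] = ()

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end must be >= start")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length inconsistent with [start..end]")

    def with_mods(self, mods: Iterable[AppliedModification]) -> "PeptideSpecies":
        return PeptideSpecies(
            self.chain_id,
            self.start,
            self.end,
            self.sequence,
            self.missed_cleavages,
            self.mods + tuple(mods),
        )

    def mass(self, scale="monoisotopic") -> float:
        return peptide_mass(self.sequence, self.mods, scale).daltons

    def cys_positions(self) -> tuple[int, ...]:
        """Global 1-based positions of cysteines in this peptide."""
        return tuple(
            self.start + i for i, aa in enumerate(self.sequence) if aa == "C"
        )


def cleavage_sites(sequence: str, rule: ProteaseRule) -> list[int]:
    """1-based positions after which the protease cuts (excludes the C-term)."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in rule.cut_after and sequence[i + 1] not in rule.blocked_by_next
    ]


def digest(
    chain: ProteinChain, rule: ProteaseRule = TRYPSIN, max_missed: int = 0
) -> list[PeptideSpecies]:
    """All peptides with 0..``max_missed`` missed cleavages.

    Zero-missed peptides tile the chain exactly; a peptide with m missed
    cleavages is the concatenation of m+1 adjacent zero-missed peptides.
    Output is ordered by start position, then by missed cleavages.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    cuts = cleavage_sites(chain.sequence, rule)
    bounds = [0] + cuts + [len(chain.sequence)]  # segment i: bounds[i]+1..bounds[i+1]
    n_seg = len(bounds) - 1
    out = []
    for i in range(n_seg):
        for m in range(min(max_missed, n_seg - 1 - i) + 1):
            start, end = bounds[i] + 1, bounds[i + 1 + m]
            out.append(
                PeptideSpecies(
                    chain.chain_id, start, end, chain.slice(start, end), missed_cleavages=m
                )
            )
    out.sort(key=lambda p: (p.start, p.missed_cleavages))
    return out


def theoretical_peptide_table(
    chain: ProteinChain,
    rule: ProteaseRule = TRYPSIN,
    max_missed: int = 0,
    fixed_mods: Iterable[Modification] = (),
) -> pd.DataFrame:
    """Theoretical digest table: one row per peptide + modification state.

    Fixed modifications are applied at every eligible residue.  Columns:
    chain, start, end, sequence, missed, mods, mono_mass, avg_mass, mh_plus.
    """
    fixed_mods = tuple(fixed_mods)
    rows = []
    for pep in digest(chain, rule, max_missed):
        applied = [
            AppliedModification(mod, i + 1)
            for mod in fixed_mods
            for i, aa in enumerate(pep.sequence)
            if aa in mod.targets
        ]
        pep = pep.with_mods(applied)
        mono = pep.mass("monoisotopic")
        rows.append(
            {
                "chain": pep.chain_id,
                "start": pep.start,
                "end": pep.end,
                "sequence": pep.sequence,
                "missed": pep.missed_cleavages,
                "mods": ";".join(f"{m.mod.name}@{m.position}" for m in pep.mods),
                "mono_mass": mono,
                "avg_mass": pep.mass("average"),
                "mh_plus": mono + PROTON,
                "species": pep,
            }
        )
    return pd.DataFrame(rows)
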