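"""Core domain types: protein chains, modifications, sequons, and the pI model.

Coordinates are 1-based and intervals inclusive throughout, matching the
convention of peptide-map tables ("29-39 VTSPNITVTLK").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from scipy.optimize import brentq

from .masses import (
    CANONICAL_RESIDUES,
    CARBAMIDOMETHYL_AVG,
    CARBAMIDOMETHYL_MONO,
    DEAMIDATION_AVG,
    DEAMIDATION_MONO,
    MassScale,
    MassValue,
    OXIDATION_AVG,
    OXIDATION_MONO,
    residue_mass,
    water,
)

# ---------------------------------------------------------------------------
# Chains and annotations


@dataclass(frozen=True)
class DomainAnnotation:
    """A labelled interval on a chain, e.g. ("VR1 D2", 13, 28)."""

    label: str
    start: int
    end: int


@dataclass(frozen=True)
class ProteinChain:
    """A polypeptide chain with 1-based residue coordinates.

    Parameters
    ----------
    chain_id : str
        Identifier, e.g. ``"A"``.
    sequence : str
        Canonical one-letter residue codes, position 1 .. len(sequence).
    annotations : tuple of DomainAnnotation, optional
        Domain labels over inclusive intervals.
    """

    chain_id: str
    sequence: str
    annotations: tuple[DomainAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("chain sequence must be non-empty")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"non-canonical residue codes in chain: {sorted(bad)}")
        for ann in self.annotations:
            if not (1 <= ann.start <= ann.end <= len(self.sequence)):
                raise ValueError(f"annotation {ann.label!r} outside chain bounds")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Residues at 1-based inclusive positions ``start..end``."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(f"slice {start}..{end} outside 1..{len(self.sequence)}")
        return self.sequence[start - 1 : end]


# ---------------------------------------------------------------------------
# Modifications


@dataclass(frozen=True)
class Modification:
    """A covalent mass modification with a residue-level target rule."""

    name: str
    targets: str  # residue codes this mod may sit on, e.g. "C", "M", "NQ"
    mono_delta: float
    avg_delta: float
    mode: Literal["fixed", "variable"] = "variable"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mono_delta) and math.isfinite(self.avg_delta)):
            raise ValueError(f"modification {self.name!r} has non-finite delta")

    def delta(self, scale: MassScale) -> float:
        return self.mono_delta if scale == "monoisotopic" else self.avg_delta


@dataclass(frozen=True)
class AppliedModification:
    """A modification placed at a specific 1-based position within a peptide."""

    mod: Modification
    position: int  # local, 1-based within the peptide sequence


CARBAMIDOMETHYL_C = Modification(
    "carbamidomethyl", "C", CARBAMIDOMETHYL_MONO, CARBAMIDOMETHYL_AVG, "fixed"
)
DEAMIDATION_N = Modification("deamidation", "N", DEAMIDATION_MONO, DEAMIDATION_AVG)
DEAMIDATION_NQ = Modification("deamidation", "NQ", DEAMIDATION_MONO, DEAMIDATION_AVG)
OXIDATION_M = Modification("oxidation", "M", OXIDATION_MONO, OXIDATION_AVG)
#: PNGase F signature: the glycan-bearing Asn is released as Asp.
PNGASEF_DEAMIDATION = Modification(
    "pngasef_deamidation", "N", DEAMIDATION_MONO, DEAMIDATION_AVG, "fixed"
)

#: Modification registry for config-file lookup by name.
MODIFICATION_REGISTRY: dict[str, Modification] = {
    "carbamidomethyl": CARBAMIDOMETHYL_C,
    "deamidation": DEAMIDATION_NQ,
    "oxidation": OXIDATION_M,
    "pngasef_deamidation": PNGASEF_DEAMIDATION,
}


def peptide_mass(
    sequence: str,
    mods: Iterable[Modification | AppliedModification] = (),
    scale: MassScale = "monoisotopic",
) -> MassValue:
    """Neutral mass of a peptide: residue masses + one water + mod deltas.

    ``mods`` may mix bare :class:`Modification` instances (the sequence must
    contain an eligible target residue) and :class:`AppliedModification`
    instances (the residue at the stated position must be a target).
    """
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    total = water(scale)
    for aa in sequence:
        total = total + residue_mass(aa, scale)
    delta = 0.0
    for m in mods:
        if isinstance(m, AppliedModification):
            pos, mod = m.position, m.mod
            if not (1 <= pos <= len(sequence)):
                raise ValueError(
                    f"modification {mod.name!r} at position {pos} outside peptide"
                )
            if sequence[pos - 1] not in mod.targets:
                raise ValueError(
                    f"modification {mod.name!r} targets {mod.targets!r} but "
                    f"position {pos} is {sequence[pos - 1]!r}"
                )
        else:
            mod = m
            if not any(aa in mod.targets for aa in sequence):
                raise ValueError(
                    f"modification {mod.name!r} targets {mod.targets!r}, "
                    f"absent from {sequence!r}"
                )
        delta += mod.delta(scale)
    return MassValue(scale, total.daltons + delta)


# ---------------------------------------------------------------------------
# Sequons


@dataclass(frozen=True)
class SequonSite:
    """An N-X-(S|T) motif (X != P): a potential N-glycosylation site."""

    position: int  # 1-based position of the Asn
    motif: str
    occupied: bool = False

    def __post_init__(self) -> None:
        if len(self.motif) != 3 or self.motif[0] != "N":
            raise ValueError(f"sequon motif must be N-X-(S|T), got {self.motif!r}")
        if self.motif[1] == "P" or self.motif[2] not in "ST":
            raise ValueError(f"not a valid sequon motif: {self.motif!r}")


def find_sequons(chain: ProteinChain | str) -> list[SequonSite]:
    """All N-X-(S|T) sites with X != P, in ascending position."""
    seq = chain.sequence if isinstance(chain, ProteinChain) else chain
    sites = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST":
            sites.append(SequonSite(position=i + 1, motif=seq[i : i + 3]))
    return sites


# ---------------------------------------------------------------------------
# Isoelectric point model

#: Bjellqvist pKa values; sialic acid added for glycoprotein charge modeling.
BJELLQVIST_PKA: dict[str, float] = {
    "n_term": 7.5,
    "c_term": 3.55,
    "D": 4.05,
    "E": 4.45,
    "H": 5.98,
    "C": 9.0,
    "Y": 10.0,
    "K": 10.0,
    "R": 12.0,
    "sialic": 2.6,
}

_BASIC_GROUPS = ("n_term", "H", "K", "R")
_ACIDIC_GROUPS = ("c_term", "D", "E", "C", "Y", "sialic")


@dataclass(frozen=True)
class IonizableComposition:
    """Counts of ionizable groups, the input to the charge/pI model.

    Keys are residue codes ``D E C Y K R H`` plus ``n_term``, ``c_term`` and
    ``sialic`` (one per sialic-acid monosaccharide on attached glycans).
    """

    counts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(_BASIC_GROUPS) | set(_ACIDIC_GROUPS)
        bad = set(self.counts) - known
        if bad:
            raise ValueError(f"unknown ionizable groups: {sorted(bad)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("group counts must be non-negative")

    @classmethod
    def from_sequence(
        cls, sequence: str, *, sialic: float = 0.0, extra_asp: float = 0.0
    ) -> "IonizableComposition":
        """Composition of a single chain with free termini.

        ``extra_asp`` adds Asp equivalents (e.g. PNGase F-converted sequon
        Asn); ``sialic`` adds sialic-acid carboxylates from attached glycans.
        """
        counts: dict[str, float] = {"n_term": 1, "c_term": 1}
        for g in ("D", "E", "C", "Y", "K", "R", "H"):
            n = sequence.count(g)
            if n:
                counts[g] = n
        counts["D"] = counts.get("D", 0) + extra_asp
        if sialic:
            counts["sialic"] = sialic
        return cls(counts)

    def add(self, **deltas: float) -> "IonizableComposition":
        counts = dict(self.counts)
        for k, v in deltas.items():
            counts[k] = counts.get(k, 0) + v
        return IonizableComposition({k: v for k, v in counts.items() if v != 0})


def charge_at_pH(
    composition: IonizableComposition,
    pH: float,
    pka: Mapping[str, float] = BJELLQVIST_PKA,
) -> float:
    """Net charge from the Henderson-Hasselbalch sum over all groups.

    Basic groups contribute ``+n / (1 + 10**(pH - pKa))``, acidic groups
    ``-n / (1 + 10**(pKa - pH))``.
    """
    if not (0.0 <= pH <= 14.0):
        raise ValueError(f"pH must be in [0, 14], got {pH}")
    q = 0.0
    for g, n in composition.counts.items():
        if g in _BASIC_GROUPS:
            q += n / (1.0 + 10.0 ** (pH - pka[g]))
        else:
            q -= n / (1.0 + 10.0 ** (pka[g] - pH))
    return q


def isoelectric_point(
    composition: IonizableComposition,
    pka: Mapping[str, float] = BJELLQVIST_PKA,
    tol: float = 1e-4,
) -> float:
    """pH of zero net charge, solved on [0, 14].

    The charge curve is strictly decreasing in pH, so the root is unique
    when a sign change exists; compositions with no acidic or no basic
    group have none and are rejected.
    """
    q0 = charge_at_pH(composition, 0.0, pka)
    q14 = charge_at_pH(composition, 14.0, pka)
    if not (q0 > 0 > q14):
        raise ValueError(
            "charge curve has no sign change on [0, 14]; composition needs "
            "at least one acidic and one basic group"
        )
    root = brentq(lambda ph: charge_at_pH(composition, ph, pka), 0.0, 14.0, xtol=1e-10)
    assert abs(charge_at_pH(composition, root, pka)) < tol
    return float(root)
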