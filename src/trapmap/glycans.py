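"""Glycan composition arithmetic, 2-AA labeling, and glycopeptide assignment.

Compositions are written the way glycopeptide reports print them, antenna
counts separate from the invariant (Man)3(GlcNAc)2 core::

    (Hex)2(HexNAc)2(Deoxyhexose)1(NeuAc)2 + (Man)3(GlcNAc)2

Masses are residue (anhydro) monosaccharide masses; a free reducing glycan
additionally carries one water.  2-AA labeling (reductive amination with
anthranilic acid) adds a fixed delta to any free glycan.  A glycopeptide is
the peptide (sequon Asn intact, NOT deamidated) plus the glycan residue
mass — glycosidic attachment adds no extra water.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from itertools import product
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .digestion import PeptideSpecies
from .masses import MassScale, MassValue, PROTON, formula_mass
from .matching import Peak, PeakList
from .proteoforms import find_sequons

#: Elemental compositions of monosaccharide residues (anhydro).
MONOSACCHARIDE_FORMULAS: dict[str, dict[str, int]] = {
    "hex": {"C": 6, "H": 10, "O": 5},
    "hexnac": {"C": 8, "H": 13, "N": 1, "O": 5},
    "deoxyhexose": {"C": 6, "H": 10, "O": 4},
    "neuac": {"C": 11, "H": 17, "N": 1, "O": 8},
}

#: Net mass added by 2-AA reductive amination:
#: + anthranilic acid (C7H7NO2) - H2O (amine condensation) + H2 (reduction).
LABEL_2AA_DELTA_MONO = (
    formula_mass({"C": 7, "H": 7, "N": 1, "O": 2})
    - formula_mass({"H": 2, "O": 1})
    + formula_mass({"H": 2})
)
LABEL_2AA_DELTA_AVG = (
    formula_mass({"C": 7, "H": 7, "N": 1, "O": 2}, "average")
    - formula_mass({"H": 2, "O": 1}, "average")
    + formula_mass({"H": 2}, "average")
)


@dataclass(frozen=True)
class GlycanComposition:
    """Antenna monosaccharide counts plus the core flag and label state."""

    hex: int = 0
    hexnac: int = 0
    deoxyhexose: int = 0
    neuac: int = 0
    core: bool = True
    label: Literal["none", "2AA"] = "none"

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "deoxyhexose", "neuac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")

    def counts(self) -> dict[str, int]:
        """Total residue counts with the core folded in (core = 3 Hex + 2 HexNAc)."""
        return {
            "hex": self.hex + (3 if self.core else 0),
            "hexnac": self.hexnac + (2 if self.core else 0),
            "deoxyhexose": self.deoxyhexose,
            "neuac": self.neuac,
        }

    def notation(self) -> str:
        """Report-style string, e.g. ``(Hex)2(HexNAc)2(NeuAc)1+(Man)3(GlcNAc)2``."""
        names = [("Hex", self.hex), ("HexNAc", self.hexnac),
                 ("Deoxyhexose", self.deoxyhexose), ("NeuAc", self.neuac)]
        s = "".join(f"({n}){c}" for n, c in names if c > 0)
        if self.core:
            s += "+(Man)3(GlcNAc)2"
        return s or "(empty)"

    @classmethod
    def from_notation(cls, text: str) -> "GlycanComposition":
        """Parse report-style notation (whitespace-tolerant)."""
        text = re.sub(r"\s+", "", text)
        core = False
        m = re.search(r"\+\(?Man\)?3\(?GlcNAc\)?2$", text)
        if m:
            core = True
            text = text[: m.start()]
        counts = {"hex": 0, "hexnac": 0, "deoxyhexose": 0, "neuac": 0}
        key = {"hex": "hex", "hexnac": "hexnac", "deoxyhexose": "deoxyhexose",
               "fuc": "deoxyhexose", "neuac": "neuac"}
        pos = 0
        for mm in re.finditer(r"\(([A-Za-z]+)\)(\d+)", text):
            if mm.start() != pos:
                raise ValueError(f"cannot parse glycan notation at {text[pos:]!r}")
            pos = mm.end()
            name = mm.group(1).lower()
            if name not in key:
                raise ValueError(f"unknown monosaccharide {mm.group(1)!r}")
            counts[key[name]] += int(mm.group(2))
        if pos != len(text):
            raise ValueError(f"cannot parse glycan notation at {text[pos:]!r}")
        return cls(core=core, **counts)


def composition_mass(comp: GlycanComposition, scale: MassScale = "monoisotopic") -> MassValue:
    """Mass of the free reducing glycan: residue sum + one water (+ label)."""
    total = formula_mass({"H": 2, "O": 1}, scale)
    for name, n in comp.counts().items():
        total += n * formula_mass(MONOSACCHARIDE_FORMULAS[name], scale)
    if comp.label == "2AA":
        total += LABEL_2AA_DELTA_MONO if scale == "monoisotopic" else LABEL_2AA_DELTA_AVG
    return MassValue(scale, total)


def glycan_residue_mass(comp: GlycanComposition, scale: MassScale = "monoisotopic") -> float:
    """Mass the glycan adds when attached to a peptide (no water)."""
    if comp.label != "none":
        raise ValueError("attached glycans cannot carry a reducing-end label")
    return composition_mass(comp, scale).daltons - formula_mass({"H": 2, "O": 1}, scale)


def label_2aa(comp: GlycanComposition, scale: MassScale = "monoisotopic") -> MassValue:
    """Mass of the 2-AA-labeled free glycan.

    Raises if the composition is already labeled (double labeling is
    chemically impossible: the reducing end is consumed).
    """
    if comp.label != "none":
        raise ValueError("composition is already labeled")
    return composition_mass(replace(comp, label="2AA"), scale)


def glycopeptide_mass(
    peptide: PeptideSpecies, comp: GlycanComposition, scale: MassScale = "monoisotopic"
) -> MassValue:
    """Glycopeptide mass: intact-Asn peptide + glycan residue mass.

    The peptide must contain at least one sequon; the attachment Asn stays
    unmodified (deamidation is the signature of glycan *release*, not of a
    glycopeptide).
    """
    if not find_sequons(peptide.sequence):
        raise ValueError(f"peptide {peptide.sequence!r} has no N-X-(S/T) sequon")
    if any(m.mod.name.endswith("deamidation") for m in peptide.mods):
        raise ValueError("glycopeptide Asn must not be deamidated")
    return MassValue(scale, peptide.mass(scale) + glycan_residue_mass(comp, scale))


# ---------------------------------------------------------------------------
# Composition search and per-site assignment

#: Default search-lattice bounds, generous for biantennary complex glycans.
DEFAULT_BOUNDS: dict[str, int] = {"hex": 10, "hexnac": 8, "deoxyhexose": 3, "neuac": 4}


def composition_search(
    observed: float,
    tol: float,
    bounds: Mapping[str, int] | None = None,
    label: Literal["none", "2AA"] = "none",
    require_core: bool = True,
) -> list[tuple[GlycanComposition, float]]:
    """Exhaustive bounded-lattice search for compositions matching a mass.

    Returns ``(composition, signed error)`` pairs with |error| <= tol,
    sorted by |error| then by counts for a deterministic order.
    """
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    out = []
    for h, n, d, s in product(
        range(b["hex"] + 1), range(b["hexnac"] + 1),
        range(b["deoxyhexose"] + 1), range(b["neuac"] + 1),
    ):
        comp = GlycanComposition(h, n, d, s, core=require_core, label=label)
        err = observed - composition_mass(comp).daltons
        if abs(err) <= tol:
            out.append((comp, err))
    out.sort(key=lambda ce: (abs(ce[1]), ce[0].hex, ce[0].hexnac,
                             ce[0].deoxyhexose, ce[0].neuac))
    return out


def assign_site_glycoforms(
    peak_groups: Mapping[int, PeakList | Sequence[Peak]],
    site_peptides: Mapping[int, PeptideSpecies],
    library: Sequence[GlycanComposition] | None = None,
    tol: float = 0.5,
    top_k: int = 3,
) -> pd.DataFrame:
    """Per-site glycoform table from glycopeptide peak groups.

    ``peak_groups`` maps sequon position -> observed peaks for that site's
    glycopeptide cluster; ``site_peptides`` maps the same positions to the
    sequon-bearing tryptic peptide.  With a ``library``, each peak is
    matched against library glycopeptide masses; otherwise a de novo
    :func:`composition_search` runs on the peak-minus-peptide mass.  Ranking
    is by intensity when present, else by |error|; ``top_k`` rows per site.
    """
    rows = []
    for site, peaks in peak_groups.items():
        pep = site_peptides[site]
        if not find_sequons(pep.sequence):
            raise ValueError(f"site {site}: peptide {pep.sequence!r} has no sequon")
        pep_mass = pep.mass("monoisotopic")
        for peak in peaks:
            obs_neutral = peak.neutral_mass()
            if library is not None:
                cands = [
                    (comp, obs_neutral - glycopeptide_mass(pep, comp).daltons)
                    for comp in library
                ]
                cands = [(c, e) for c, e in cands if abs(e) <= tol]
                cands.sort(key=lambda ce: abs(ce[1]))
            else:
                cands = composition_search(
                    obs_neutral - pep_mass + formula_mass({"H": 2, "O": 1}), tol
                )
            if cands:
                comp, err = cands[0]
                rows.append(
                    {
                        "site": site,
                        "peptide": pep.sequence,
                        "composition": comp.notation(),
                        "observed": peak.observed,
                        "theoretical_mh": glycopeptide_mass(pep, comp).daltons + PROTON,
                        "error_da": err,
                        "intensity": peak.intensity,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["site", "peptide", "composition", "observed",
                 "theoretical_mh", "error_da", "intensity"],
    )
    if df.empty:
        return df
    if df["intensity"].notna().all():
        df = df.sort_values(["site", "intensity"], ascending=[True, False])
    else:
        df = df.sort_values(["site", "error_da"], key=lambda s: s.abs() if s.name == "error_da" else s)
    return df.groupby("site", group_keys=False).head(top_k).reset_index(drop=True)
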