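"""Synthetic fixtures and peak-list simulation.

The "paper topology" preset emulates the architecture of a homodimeric
VEGF-trap-type fusion protein (two receptor Ig-like domains fused to an
IgG1-style Fc): per chain, seven N-X-(S/T) sequons each on its own tryptic
peptide, one intra-chain disulfide spanning two peptides in each of the two
receptor domains, a hinge peptide carrying two inter-chain cysteines, and
two intra-chain disulfides spanning two peptides each in the Fc (CH2, CH3).
Non-reduced digestion of that topology yields exactly five distinct
disulfide-linked di-peptide species, one of them the two-bond hinge
homo-di-peptide.

Fixture sequences are generated, not copied from any real receptor or IgG1
sequence; only the architectural counts are reproduced.  The glycoform
table uses sialylated/fucosylated complex biantennary compositions on the
invariant Man3GlcNAc2 core, with a truncated-core series at the Fc-like
site, the pattern typical of CHO-expressed Fc fusions.

The noise model emulates ion-trap peak lists: Gaussian mass error (default
sigma 0.2 Da), occasional +1.00335 Da isotope mis-picks (default
probability 0.1), peak dropout, and uniform contaminant peaks over the
m/z 500-2000 scan range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digestion import PeptideSpecies, TRYPSIN, digest, theoretical_peptide_table
from .disulfides import (
    DimerAssembly,
    DisulfideBond,
    LinkedPeptideSpecies,
    build_linked_species,
    nonreduced_digest,
)
from .glycans import GlycanComposition, glycopeptide_mass
from .masses import ISOTOPE_SPACING, PROTON
from .matching import Peak, PeakList, apply_pngasef
from .proteoforms import (
    BJELLQVIST_PKA,
    CARBAMIDOMETHYL_C,
    DomainAnnotation,
    IonizableComposition,
    ProteinChain,
    SequonSite,
    find_sequons,
    isoelectric_point,
)

# ---------------------------------------------------------------------------
# Designed tryptic peptides of the paper-topology preset.  Filler peptides
# between them are seed-generated; the designed ones pin down the sequons
# and the disulfide architecture.  (domain, sequence); None domain = filler
# of the stated length.

_PRESET_LAYOUT: list[tuple[str | None, str | int]] = [
    (None, 12),
    ("VR1 D2", "ELVIPCR"),
    ("VR1 D2", "TGCIIMDSR"),
    ("VR1 D2", "VTSPNITVTLK"),       # sequon N33
    (None, 10),
    (None, 10),
    ("VR2 D3", "GFIISNATYK"),        # sequon N65
    ("VR2 D3", "YLAVPCSVK"),
    ("VR2 D3", "DGFTCEVSR"),
    (None, 10),
    (None, 10),
    (None, 9),
    ("VR2 D3", "LVLNCTAR"),          # sequon N120 (with an unbonded Cys)
    (None, 12), (None, 12), (None, 12), (None, 12), (None, 10), (None, 10),
    ("VR2 D4", "NSTFVR"),            # sequon N193
    (None, 11), (None, 11), (None, 11), (None, 10),
    ("VR2 D4", "NGIPLESNHTIK"),      # sequon N249
    (None, 13),
    ("VR2 D4", "DTGNYTVILTNPISK"),   # sequon N270
    ("Fc hinge", "THSCPVCPAEK"),     # inter-chain Cys 285, 288
    ("Fc CH2", "TPDVTCVVVAK"),
    ("Fc CH2", "ALPCPIEGK"),
    ("Fc CH3", "WQEGHVFSCSVK"),
    ("Fc CH3", "GQVSLTCLVK"),
    (None, 13), (None, 12), (None, 12),
    ("Fc CH3", "EEQYNSTYR"),         # sequon N376
    (None, 10), (None, 10),
]

#: Disulfide topology on the preset coordinates (per assembly, chains A/B):
#: intra-chain pairs in both chains, two inter-chain hinge bonds.
_PRESET_INTRA_BONDS = [(18, 22), (75, 83), (298, 307), (321, 331)]
_PRESET_HINGE_POSITIONS = [285, 288]

#: Per-site glycoform tables (three most abundant first), Table-2 style
#: complex biantennary compositions; all on the Man3GlcNAc2 core.
_PRESET_GLYCOFORMS: dict[int, list[GlycanComposition]] = {
    33: [GlycanComposition(2, 2, 1, 2), GlycanComposition(2, 2, 1, 1),
         GlycanComposition(2, 2, 1, 0)],
    65: [GlycanComposition(2, 2, 1, 2), GlycanComposition(2, 2, 1, 1),
         GlycanComposition(2, 2, 1, 0)],
    120: [GlycanComposition(2, 2, 0, 1), GlycanComposition(2, 0, 0, 0),
          GlycanComposition(2, 2, 0, 2)],
    193: [GlycanComposition(2, 2, 0, 1), GlycanComposition(2, 2, 1, 1),
          GlycanComposition(2, 2, 0, 0)],
    249: [GlycanComposition(2, 2, 1, 2), GlycanComposition(2, 2, 1, 1),
          GlycanComposition(2, 2, 1, 0)],
    270: [GlycanComposition(2, 2, 1, 2), GlycanComposition(2, 2, 1, 1),
          GlycanComposition(2, 2, 1, 0)],
    376: [GlycanComposition(1, 2, 1, 0), GlycanComposition(0, 2, 1, 0),
          GlycanComposition(0, 2, 0, 0)],
}

#: Relative abundance of a site's glycoforms by rank.
GLYCOFORM_RANK_WEIGHTS = (0.4, 0.35, 0.25)

#: Built-in glycan library: the distinct preset compositions.
BUILTIN_GLYCAN_LIBRARY: tuple[GlycanComposition, ...] = tuple(
    sorted(
        {c for forms in _PRESET_GLYCOFORMS.values() for c in forms},
        key=lambda c: (c.hex, c.hexnac, c.deoxyhexose, c.neuac),
    )
)

# Filler residue frequencies: no C, N, K or R in peptide bodies (cysteines,
# sequons and cleavage sites are placed by design, not chance); D/E/H rates
# keep the chain pI in the mildly-acidic-to-neutral range a CE run of such
# a fusion protein reports.
_FILLER_RESIDUES = list("ASTGVLIFPQMWYHDE")
_FILLER_PROBS = [0.09, 0.09, 0.08, 0.06, 0.09, 0.09, 0.08, 0.06,
                 0.06, 0.06, 0.03, 0.02, 0.03, 0.06, 0.05, 0.05]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic assembly generator."""

    seed: int = 0
    preset: str = "paper"
    glycoform_table: Mapping[int, Sequence[GlycanComposition]] | None = None
    max_retries: int = 20


@dataclass(frozen=True)
class NoiseModel:
    """Ion-trap observation model for simulated peak lists."""

    mass_sigma: float = 0.2
    isotope_pick_prob: float = 0.1
    dropout_prob: float = 0.0
    contaminant_rate: float = 0.0
    scan_range: tuple[float, float] = (500.0, 2000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.isotope_pick_prob, self.dropout_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        if self.mass_sigma < 0 or self.contaminant_rate < 0:
            raise ValueError("sigma and contaminant rate must be >= 0")


@dataclass(frozen=True)
class Fixture:
    """A synthetic assembly plus every ground-truth table the pipeline needs."""

    assembly: DimerAssembly
    sequons: tuple[SequonSite, ...]           # occupied, chain coordinates
    glycoform_table: dict[int, tuple[GlycanComposition, ...]]
    seed: int

    @property
    def chain(self) -> ProteinChain:
        return self.assembly.chains[0]

    # -- ground truth ------------------------------------------------------

    def reduced_candidates(self, pngasef: bool = True, max_missed: int = 0) -> list[PeptideSpecies]:
        """Tryptic peptides of one chain, Cys carbamidomethylated, with the
        PNGase F Asn->Asp signature at every occupied sequon when ``pngasef``."""
        table = theoretical_peptide_table(
            self.chain, TRYPSIN, max_missed, fixed_mods=[CARBAMIDOMETHYL_C]
        )
        peptides = list(table["species"])
        if pngasef:
            peptides = apply_pngasef(peptides, self.sequons)
        return peptides

    def peptide_map_truth(self, pngasef: bool = True) -> list[float]:
        """True MH+ values of the zero-missed reduced digest."""
        return [p.mass("monoisotopic") + PROTON for p in self.reduced_candidates(pngasef)]

    def expected_linked_species(self, max_missed: int = 0) -> list[LinkedPeptideSpecies]:
        pool = nonreduced_digest(self.assembly, TRYPSIN, max_missed)
        return build_linked_species(pool, self.assembly.bonds)

    def site_peptides(self) -> dict[int, PeptideSpecies]:
        """The sequon-bearing tryptic peptide for each site (Asn intact)."""
        peptides = digest(self.chain, TRYPSIN, 0)
        out = {}
        for site in self.sequons:
            for pep in peptides:
                if pep.start <= site.position <= pep.end:
                    out[site.position] = pep
                    break
        return out

    def glycopeptide_truth(self) -> dict[int, list[tuple[GlycanComposition, float, float]]]:
        """Per site: (composition, true MH+, relative abundance) by rank."""
        site_peps = self.site_peptides()
        out = {}
        for pos, forms in self.glycoform_table.items():
            pep = site_peps[pos]
            out[pos] = [
                (comp, glycopeptide_mass(pep, comp).daltons + PROTON, w)
                for comp, w in zip(forms, GLYCOFORM_RANK_WEIGHTS)
            ]
        return out

    def truth_tables(self) -> dict[str, pd.DataFrame]:
        """All ground truth as plain DataFrames (for TSV export)."""
        seq_df = pd.DataFrame(
            [{"position": s.position, "motif": s.motif, "occupied": s.occupied}
             for s in self.sequons]
        )
        link_df = pd.DataFrame(
            [{"members": "+".join(p.sequence for p in sp.members),
              "bonds": sp.bond_count, "mono_mass": sp.mono_mass,
              "mh_plus": sp.mh_plus}
             for sp in self.expected_linked_species()]
        )
        glyco_rows = []
        for pos, entries in self.glycopeptide_truth().items():
            for rank, (comp, mh, w) in enumerate(entries, 1):
                glyco_rows.append(
                    {"site": pos, "rank": rank, "composition": comp.notation(),
                     "mh_plus": mh, "abundance": w}
                )
        return {
            "sequons": seq_df,
            "linked_species": link_df,
            "glycoforms": pd.DataFrame(glyco_rows),
        }


def _random_filler(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(_FILLER_RESIDUES, size=length - 1, p=_FILLER_PROBS))
    return body + ("K" if rng.random() < 0.5 else "R")


def make_fixture(spec: FixtureSpec = FixtureSpec()) -> Fixture:
    """Build the preset assembly; deterministic under ``spec.seed``.

    Placement is re-drawn (bounded retries) if a random filler ever breaks
    a structural invariant — designed peptide coordinates, sequon count, or
    cysteine inventory.
    """
    if spec.preset != "paper":
        raise ValueError(f"unknown preset {spec.preset!r}")
    rng = np.random.default_rng(spec.seed)
    last_err: Exception | None = None
    for _ in range(spec.max_retries):
        try:
            return _build_preset(spec, rng)
        except AssertionError as err:  # invariant broke: re-draw fillers
            last_err = err
    raise ValueError(f"could not satisfy fixture constraints: {last_err}")


def _build_preset(spec: FixtureSpec, rng: np.random.Generator) -> Fixture:
    parts: list[str] = []
    annotations: list[DomainAnnotation] = []
    pos = 1
    for domain, item in _PRESET_LAYOUT:
        seq = _random_filler(rng, item) if isinstance(item, int) else item
        if domain is not None:
            annotations.append(DomainAnnotation(domain, pos, pos + len(seq) - 1))
        parts.append(seq)
        pos += len(seq)
    sequence = "".join(parts)

    # structural invariants of the preset
    assert len(sequence) == 400
    designed = [s for d, s in _PRESET_LAYOUT if not isinstance(s, int)]
    tiles = [p.sequence for p in digest(ProteinChain("A", sequence), TRYPSIN, 0)]
    assert all(s in tiles for s in designed), "designed peptides not cleanly cleaved"
    sequon_positions = [s.position for s in find_sequons(sequence)]
    assert sequon_positions == sorted(_PRESET_GLYCOFORMS), "unexpected sequon set"

    chain_a = ProteinChain("A", sequence, tuple(annotations))
    chain_b = ProteinChain("B", sequence, tuple(annotations))
    bonds = [
        DisulfideBond(cid, a, cid, b)
        for cid in "AB"
        for a, b in _PRESET_INTRA_BONDS
    ] + [DisulfideBond("A", p, "B", p) for p in _PRESET_HINGE_POSITIONS]
    assembly = DimerAssembly((chain_a, chain_b), tuple(bonds))

    glyco = {
        int(k): tuple(v)
        for k, v in (spec.glycoform_table or _PRESET_GLYCOFORMS).items()
    }
    sequons = tuple(
        SequonSite(s.position, s.motif, occupied=True) for s in find_sequons(sequence)
    )
    return Fixture(assembly, sequons, glyco, spec.seed)


# ---------------------------------------------------------------------------
# Peak-list simulation


def simulate_peaklist(
    truth_mh: Sequence[float],
    noise: NoiseModel = NoiseModel(),
    abundances: Sequence[float] | None = None,
) -> PeakList:
    """One peak per surviving species at MH+ + Gaussian error, plus
    contaminants uniform over the scan range.  Deterministic under
    ``noise.seed``."""
    if len(truth_mh) == 0:
        raise ValueError("truth species list must be non-empty")
    rng = np.random.default_rng(noise.seed)
    peaks = []
    for i, true in enumerate(truth_mh):
        if rng.random() < noise.dropout_prob:
            continue
        obs = true + rng.normal(0.0, noise.mass_sigma) if noise.mass_sigma else true
        if rng.random() < noise.isotope_pick_prob:
            obs += ISOTOPE_SPACING
        intensity = abundances[i] if abundances is not None else 1.0
        peaks.append(Peak(obs, intensity=intensity))
    n_cont = rng.poisson(noise.contaminant_rate)
    lo, hi = noise.scan_range
    for _ in range(int(n_cont)):
        peaks.append(Peak(float(rng.uniform(lo, hi)), intensity=0.1))
    return PeakList(tuple(peaks))


# ---------------------------------------------------------------------------
# PNGase F time course and the pI model


@dataclass(frozen=True)
class TimecoursePoint:
    """One sampling time: the glyco-state mixture and its pI profile."""

    time_h: float
    fraction_deglycosylated: float
    #: (n converted sites, total sialic count, probability, pI)
    states: tuple[tuple[int, int, float, float], ...]

    @property
    def mean_pi(self) -> float:
        return sum(w * pi for _, _, w, pi in self.states)

    @property
    def pi_range(self) -> tuple[float, float]:
        pis = [pi for _, _, _, pi in self.states]
        return (min(pis), max(pis))


def simulate_pngasef_timecourse(
    fixture: Fixture,
    hours: Sequence[float] = (0.0, 7.0, 48.0),
    rate: float = 0.05,
    pka: Mapping[str, float] = BJELLQVIST_PKA,
    min_weight: float = 1e-6,
) -> list[TimecoursePoint]:
    """Deglycosylation kinetics and the resulting pI distribution.

    Each site is released independently with probability
    ``1 - exp(-rate * t)``; an occupied site carries one of its glycoforms
    (rank weights :data:`GLYCOFORM_RANK_WEIGHTS`), contributing that form's
    sialic-acid carboxylates to the charge model, while a released site
    contributes one new Asp.  The state distribution over (converted sites,
    total sialic count) is computed exactly by convolution over sites; the
    pI of every state comes from :func:`~trapmap.proteoforms.isoelectric_point`.
    Mean pI strictly decreases with time: each conversion trades the site's
    mean sialic charge (below one for the preset mixture) for a full Asp.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    site_sialics = [
        [(comp.neuac, w) for comp, w in zip(forms, GLYCOFORM_RANK_WEIGHTS)]
        for forms in fixture.glycoform_table.values()
    ]
    base_seq = fixture.chain.sequence
    pi_cache: dict[tuple[int, int], float] = {}

    def state_pi(k: int, sialic: int) -> float:
        if (k, sialic) not in pi_cache:
            comp = IonizableComposition.from_sequence(
                base_seq, sialic=sialic, extra_asp=k
            )
            pi_cache[(k, sialic)] = isoelectric_point(comp, pka)
        return pi_cache[(k, sialic)]

    points = []
    for t in hours:
        f = 1.0 - float(np.exp(-rate * t))
        dist: dict[tuple[int, int], float] = {(0, 0): 1.0}
        for options in site_sialics:
            nxt: dict[tuple[int, int], float] = {}
            for (k, s), w in dist.items():
                if f > 0:
                    nxt[(k + 1, s)] = nxt.get((k + 1, s), 0.0) + w * f
                for sial, ww in options:
                    key = (k, s + sial)
                    nxt[key] = nxt.get(key, 0.0) + w * (1.0 - f) * ww
            dist = nxt
        states = tuple(
            sorted(
                (k, s, w, state_pi(k, s))
                for (k, s), w in dist.items()
                if w >= min_weight
            )
        )
        points.append(TimecoursePoint(t, f, states))
    return points
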