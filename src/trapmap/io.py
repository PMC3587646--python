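"""Readers and writers for the pipeline's plain-text formats.

FASTA for chains (Biopython), CSV for peak lists, TSV for digestion /
disulfide / glycoform tables and bond topologies, MGF (pyteomics) for
optional MS/MS confirmation, TOML for run configuration.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .disulfides import DisulfideBond
from .glycans import GlycanComposition
from .matching import Peak, PeakList
from .proteoforms import ProteinChain, SequonSite

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinChain]:
    return [
        ProteinChain(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(chains: Iterable[ProteinChain], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.chain_id, description="") for c in chains
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Peak lists

#: Documented peak-list CSV columns.
PEAK_COLUMNS = ("observed_mass_or_mz", "charge", "retention_time", "intensity")


def read_peaklist_csv(path: str | Path) -> PeakList:
    """Read a peak list; ``charge`` empty or missing means the value is MH+."""
    df = pd.read_csv(path)
    if "observed_mass_or_mz" not in df.columns:
        raise ValueError(f"{path}: missing required column 'observed_mass_or_mz'")
    peaks = []
    for row in df.itertuples(index=False):
        charge = getattr(row, "charge", None)
        charge = None if charge is None or (isinstance(charge, float) and math.isnan(charge)) else int(charge)
        rt = getattr(row, "retention_time", None)
        inten = getattr(row, "intensity", None)
        peaks.append(
            Peak(
                float(row.observed_mass_or_mz),
                charge,
                None if rt is None or (isinstance(rt, float) and math.isnan(rt)) else float(rt),
                None if inten is None or (isinstance(inten, float) and math.isnan(inten)) else float(inten),
            )
        )
    return PeakList(tuple(peaks))


def write_peaklist_csv(peaks: PeakList | Sequence[Peak], path: str | Path, extra: dict | None = None) -> None:
    rows = [
        {
            "observed_mass_or_mz": p.observed,
            "charge": p.charge,
            "retention_time": p.retention_time,
            "intensity": p.intensity,
            **(extra or {}),
        }
        for p in peaks
    ]
    pd.DataFrame(rows, columns=list(PEAK_COLUMNS) + list(extra or ())).to_csv(path, index=False)


def read_grouped_peaklist_csv(path: str | Path) -> dict[int, PeakList]:
    """Peak-list CSV with an extra ``site`` column, grouped by site."""
    df = pd.read_csv(path)
    if "site" not in df.columns:
        raise ValueError(f"{path}: glycopeptide peak list needs a 'site' column")
    out: dict[int, PeakList] = {}
    for site, sub in df.groupby("site"):
        peaks = tuple(
            Peak(
                float(r.observed_mass_or_mz),
                None if pd.isna(getattr(r, "charge", None)) else int(r.charge),
                None,
                None if pd.isna(getattr(r, "intensity", None)) else float(r.intensity),
            )
            for r in sub.itertuples(index=False)
        )
        out[int(site)] = PeakList(peaks)
    return out


# ---------------------------------------------------------------------------
# MGF (optional MS/MS confirmation)


def read_mgf(path: str | Path) -> list[dict]:
    """MS/MS spectra as dicts with ``pepmass``, ``mz_array``, ``intensity_array``."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            spectra.append(
                {
                    "pepmass": spec["params"].get("pepmass", (None,))[0],
                    "mz_array": spec["m/z array"],
                    "intensity_array": spec["intensity array"],
                    "params": spec["params"],
                }
            )
    return spectra


# ---------------------------------------------------------------------------
# Topology and glycan library TSV


def read_topology_tsv(path: str | Path) -> list[DisulfideBond]:
    df = pd.read_csv(path, sep="\t")
    return [
        DisulfideBond(str(r.chain_a), int(r.pos_a), str(r.chain_b), int(r.pos_b))
        for r in df.itertuples(index=False)
    ]


def write_topology_tsv(bonds: Iterable[DisulfideBond], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"chain_a": b.chain_a, "pos_a": b.pos_a, "chain_b": b.chain_b, "pos_b": b.pos_b}
            for b in bonds
        ]
    ).to_csv(path, sep="\t", index=False)


def read_glycan_library_tsv(path: str | Path) -> list[GlycanComposition]:
    df = pd.read_csv(path, sep="\t")
    return [
        GlycanComposition(
            int(r.hex), int(r.hexnac), int(r.deoxyhexose), int(r.neuac), bool(r.core)
        )
        for r in df.itertuples(index=False)
    ]


def write_glycan_library_tsv(library: Iterable[GlycanComposition], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"hex": c.hex, "hexnac": c.hexnac, "deoxyhexose": c.deoxyhexose,
             "neuac": c.neuac, "core": c.core}
            for c in library
        ]
    ).to_csv(path, sep="\t", index=False)


def write_sequon_table_tsv(sequons: Iterable[SequonSite], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"position": s.position, "motif": s.motif, "occupied": s.occupied}
            for s in sequons
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Config


def load_toml(path: str | Path) -> dict:
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)
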