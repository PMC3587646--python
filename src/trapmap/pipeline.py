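"""End-to-end characterization: digestion -> matching -> coverage, disulfide
mapping, per-site glycoform assignment, and the pI summary, bundled into a
single report with a provenance block.

Reports are deterministic given the same inputs and configuration (no
timestamps), so repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .digestion import TRYPSIN, theoretical_peptide_table
from .disulfides import (
    DimerAssembly,
    DisulfideBond,
    ScramblingReport,
    build_linked_species,
    detect_mispairing,
    enumerate_hypothetical_pairs,
    nonreduced_digest,
)
from .glycans import GlycanComposition, assign_site_glycoforms
from .io import (
    read_fasta,
    read_glycan_library_tsv,
    read_grouped_peaklist_csv,
    read_peaklist_csv,
    read_topology_tsv,
)
from .matching import (
    CoverageReport,
    PeakList,
    apply_pngasef,
    coverage,
    expand_variants,
    match_peaks,
)
from .proteoforms import (
    BJELLQVIST_PKA,
    CARBAMIDOMETHYL_C,
    DEAMIDATION_NQ,
    IonizableComposition,
    MODIFICATION_REGISTRY,
    OXIDATION_M,
    SequonSite,
    find_sequons,
    isoelectric_point,
)


@dataclass
class RunConfig:
    """Inputs and parameters of one characterization run."""

    fasta: str
    peptide_peaks: str | None = None
    disulfide_peaks: str | None = None
    glyco_peaks: str | None = None
    topology: str | None = None
    glycan_library: str | None = None
    tol_da: float = 0.5
    max_missed: int = 0
    nonreduced_max_missed: int = 0
    pngasef: bool = True
    check_isotope_offset: bool = True
    variable_mods: tuple[str, ...] = ()
    max_variable_mods: int = 2
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.tol_da <= 0:
            raise ValueError("tol_da must be positive")
        for attr in ("fasta", "peptide_peaks", "disulfide_peaks", "glyco_peaks",
                     "topology", "glycan_library"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config.{attr}: no such file: {p}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        from .io import load_toml

        data = load_toml(path)
        base = Path(path).parent
        kwargs = dict(data)
        for attr in ("fasta", "peptide_peaks", "disulfide_peaks", "glyco_peaks",
                     "topology", "glycan_library"):
            if kwargs.get(attr):
                kwargs[attr] = str(base / kwargs[attr])
        if "variable_mods" in kwargs:
            kwargs["variable_mods"] = tuple(kwargs["variable_mods"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CharacterizationReport:
    """Aggregated result of one run; every claim traces to a match table."""

    coverage: CoverageReport | None
    peptide_matches: pd.DataFrame | None
    sequon_table: pd.DataFrame
    disulfide: ScramblingReport | None
    disulfide_table: pd.DataFrame | None
    glycoforms: pd.DataFrame | None
    pi_summary: dict | None
    provenance: dict
    warnings: list[str] = field(default_factory=list)

    @property
    def anomalies(self) -> list[str]:
        out = []
        if self.disulfide is not None and self.disulfide.scrambling_detected:
            out.append("disulfide scrambling evidence")
        if self.disulfide is not None and self.disulfide.expected_unmatched:
            out.append("expected disulfide species unmatched")
        if not self.sequon_table.empty and not self.sequon_table["occupied"].all():
            out.append("unoccupied sequon(s)")
        return out

    def to_json(self) -> str:
        def df(d):
            return None if d is None else d.to_dict(orient="records")

        bundle = {
            "provenance": self.provenance,
            "coverage": None
            if self.coverage is None
            else {
                "chain_id": self.coverage.chain_id,
                "fraction": self.coverage.fraction,
                "intervals": [list(iv) for iv in self.coverage.intervals],
            },
            "sequons": df(self.sequon_table),
            "peptide_matches": df(self.peptide_matches),
            "disulfide": None
            if self.disulfide is None
            else {
                "expected_matched": len(self.disulfide.expected_matched),
                "expected_unmatched": len(self.disulfide.expected_unmatched),
                "scrambling_hits": len(self.disulfide.scrambling_hits),
            },
            "disulfide_table": df(self.disulfide_table),
            "glycoforms": df(self.glycoforms),
            "pi_summary": self.pi_summary,
            "warnings": self.warnings,
            "anomalies": self.anomalies,
        }
        return json.dumps(bundle, indent=2, sort_keys=True, default=float)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.sequon_table.to_csv(out / "sequons.tsv", sep="\t", index=False)
        if self.peptide_matches is not None:
            self.peptide_matches.to_csv(out / "peptide_matches.tsv", sep="\t", index=False)
        if self.disulfide_table is not None:
            self.disulfide_table.to_csv(out / "disulfides.tsv", sep="\t", index=False)
        if self.glycoforms is not None:
            self.glycoforms.to_csv(out / "glycoforms.tsv", sep="\t", index=False)


def _match_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        cand = r.candidate
        rows.append(
            {
                "observed": r.peak.observed,
                "assigned": cand is not None,
                "sequence": getattr(cand, "sequence", None) if cand is not None else None,
                "start": getattr(cand, "start", None) if cand is not None else None,
                "end": getattr(cand, "end", None) if cand is not None else None,
                "mods": ";".join(
                    f"{m.mod.name}@{m.position}" for m in getattr(cand, "mods", ())
                )
                if cand is not None
                else None,
                "error_da": r.error_da,
                "error_ppm": r.error_ppm,
                "isotope_offset": r.isotope_offset,
            }
        )
    return pd.DataFrame(rows)


def characterize(config: RunConfig) -> CharacterizationReport:
    """Run every configured stage and aggregate the report.

    Stages with missing inputs are skipped (reported as warnings); stage
    failures are re-raised with the stage name attached.
    """
    warnings_: list[str] = []
    chains = read_fasta(config.fasta)
    chain = chains[0]
    sequons = find_sequons(chain)

    # ---- peptide mapping --------------------------------------------------
    cov = None
    match_df = None
    occupied_flags = {s.position: False for s in sequons}
    if config.peptide_peaks:
        try:
            peaks = read_peaklist_csv(config.peptide_peaks)
            table = theoretical_peptide_table(
                chain, TRYPSIN, config.max_missed, fixed_mods=[CARBAMIDOMETHYL_C]
            )
            candidates = list(table["species"])
            if config.pngasef:
                occ = [SequonSite(s.position, s.motif, True) for s in sequons]
                candidates = apply_pngasef(candidates, occ)
            else:
                config_mods = [MODIFICATION_REGISTRY[m] for m in config.variable_mods] or [
                    DEAMIDATION_NQ,
                    OXIDATION_M,
                ]
                candidates = [
                    v
                    for pep in candidates
                    for v in expand_variants(pep, config_mods, config.max_variable_mods)
                ]
            results = match_peaks(
                peaks,
                candidates,
                tol_da=config.tol_da,
                check_isotope_offset=config.check_isotope_offset,
            )
            cov = coverage(results, chain)
            match_df = _match_table(results)
            if config.pngasef:
                for r in results:
                    if r.candidate is None:
                        continue
                    for m in r.candidate.mods:
                        if m.mod.name == "pngasef_deamidation":
                            occupied_flags[r.candidate.start + m.position - 1] = True
            if len(peaks) == 0 or not match_df["assigned"].any():
                warnings_.append("peptide mapping produced zero matches")
        except Exception as err:
            raise RuntimeError(f"stage peptide-mapping failed: {err}") from err
    else:
        warnings_.append("no peptide peak list configured; coverage not assessed")

    sequon_table = pd.DataFrame(
        [
            {"position": s.position, "motif": s.motif, "occupied": occupied_flags[s.position]}
            for s in sequons
        ],
        columns=["position", "motif", "occupied"],
    )

    # ---- disulfide mapping ------------------------------------------------
    scram = None
    disulfide_table = None
    if config.topology and config.disulfide_peaks and len(chains) >= 2:
        try:
            bonds = read_topology_tsv(config.topology)
            assembly = DimerAssembly((chains[0], chains[1]), tuple(bonds))
            pool = nonreduced_digest(assembly, TRYPSIN, config.nonreduced_max_missed)
            expected = build_linked_species(pool, bonds)
            hypothetical = enumerate_hypothetical_pairs(pool)
            ds_peaks = read_peaklist_csv(config.disulfide_peaks)
            scram = detect_mispairing(ds_peaks, expected, hypothetical, config.tol_da)
            rows = []
            for sp, res in scram.expected_matched:
                rows.append(
                    {
                        "members": "+".join(p.sequence for p in sp.members),
                        "bonds": sp.bond_count,
                        "theoretical_mh": sp.mh_plus,
                        "observed": res.peak.observed,
                        "error_da": res.error_da,
                        "status": "matched",
                    }
                )
            for sp in scram.expected_unmatched:
                rows.append(
                    {
                        "members": "+".join(p.sequence for p in sp.members),
                        "bonds": sp.bond_count,
                        "theoretical_mh": sp.mh_plus,
                        "observed": None,
                        "error_da": None,
                        "status": "unmatched",
                    }
                )
            for res in scram.scrambling_hits:
                rows.append(
                    {
                        "members": "+".join(p.sequence for p in res.candidate.members),
                        "bonds": res.candidate.bond_count,
                        "theoretical_mh": res.candidate.mh_plus,
                        "observed": res.peak.observed,
                        "error_da": res.error_da,
                        "status": "scrambling",
                    }
                )
            disulfide_table = pd.DataFrame(rows)
        except Exception as err:
            raise RuntimeError(f"stage disulfide-mapping failed: {err}") from err
    else:
        warnings_.append("disulfide stage skipped (needs topology, peaks, two chains)")

    # ---- glycoforms ---------------------------------------------------------
    glyco_df = None
    site_sialic: dict[int, float] = {}
    if config.glyco_peaks:
        try:
            groups = read_grouped_peaklist_csv(config.glyco_peaks)
            from .digestion import digest

            peptides = digest(chain, TRYPSIN, 0)
            site_peps = {}
            for s in sequons:
                for pep in peptides:
                    if pep.start <= s.position <= pep.end:
                        site_peps[s.position] = pep
                        break
            library = (
                read_glycan_library_tsv(config.glycan_library)
                if config.glycan_library
                else None
            )
            groups = {site: g for site, g in groups.items() if site in site_peps}
            glyco_df = assign_site_glycoforms(
                groups, site_peps, library, tol=config.tol_da
            )
            # abundance-weighted sialic content per site: the CE profile sees
            # the whole glycoform ensemble, not only the top form
            for site, sub in glyco_df.groupby("site"):
                neuac = sub["composition"].map(
                    lambda n: GlycanComposition.from_notation(n).neuac
                )
                if sub["intensity"].notna().all() and sub["intensity"].sum() > 0:
                    w = sub["intensity"] / sub["intensity"].sum()
                else:
                    w = pd.Series(1.0 / len(sub), index=sub.index)
                site_sialic[int(site)] = float((neuac * w).sum())
        except Exception as err:
            raise RuntimeError(f"stage glycoform-assignment failed: {err}") from err
    else:
        warnings_.append("glycopeptide stage skipped (no grouped peak list)")

    # ---- pI summary ---------------------------------------------------------
    pi_summary = None
    try:
        total_sialic = sum(site_sialic.values())
        glyco_comp = IonizableComposition.from_sequence(
            chain.sequence, sialic=total_sialic
        )
        degly_comp = IonizableComposition.from_sequence(
            chain.sequence, extra_asp=len(sequons)
        )
        pi_summary = {
            "pi_glycosylated_top_forms": isoelectric_point(glyco_comp),
            "pi_deglycosylated": isoelectric_point(degly_comp),
            "mean_sialic_acids_per_chain": total_sialic,
            "acidic_shift": isoelectric_point(glyco_comp) - isoelectric_point(degly_comp),
        }
    except ValueError as err:
        warnings_.append(f"pI model not applicable: {err}")

    provenance = {
        "package": "trapmap",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "pka_set": dict(BJELLQVIST_PKA),
    }
    return CharacterizationReport(
        coverage=cov,
        peptide_matches=match_df,
        sequon_table=sequon_table,
        disulfide=scram,
        disulfide_table=disulfide_table,
        glycoforms=glyco_df,
        pi_summary=pi_summary,
        provenance=provenance,
        warnings=warnings_,
    )
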