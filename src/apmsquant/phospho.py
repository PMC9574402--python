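"""Phosphosite mapping and occupancy estimation.

Localized phospho modifications on peptides are projected onto reference
protein coordinates (1-based), giving site labels like ``S408``. Occupancy
at a site within one run is the fraction of covering PSMs that carry a
phosphate at exactly that residue:

    occupancy = n_phos / n_total,

where n_total counts every PSM of the protein whose peptide spans the
residue and n_phos those with a phospho mapped to it. A PSM phosphorylated
at a *different* residue still counts as dephosphorylated at this one. A
site with no covering PSMs in a run is reported as not covered (no
occupancy), not as occupancy 0.

Counting is PSM-level by default (each spectrum is one unit of evidence);
distinct-peptide counting is available via ``count_mode="peptide"``.
Occupancies are compared across conditions with the pooled-variance unpaired
t-test on per-run values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AmbiguousPeptideError, ApmsError, UnmappablePeptideError
from .stoichiometry import PooledTResult, bait_recovery_test

PHOSPHO_KIND = "phospho"
PHOSPHO_RESIDUES = frozenset("STY")


def locate_peptide(peptide: str, sequence: str) -> int:
    """1-based start of ``peptide`` in ``sequence``; must occur exactly once."""
    pos = sequence.find(peptide)
    if pos < 0:
        raise UnmappablePeptideError(f"peptide {peptide!r} not found in reference sequence")
    if sequence.find(peptide, pos + 1) >= 0:
        raise AmbiguousPeptideError(f"peptide {peptide!r} occurs more than once in reference sequence")
    return pos + 1


@dataclass(frozen=True)
class MappedSite:
    residue_index: int  # 1-based on the reference sequence
    residue_letter: str

    @property
    def label(self) -> str:
        return f"{self.residue_letter}{self.residue_index}"


def map_modifications_to_sites(psm, proteome: Mapping[str, str]) -> list[MappedSite]:
    """Project a PSM's phospho modifications onto reference coordinates.

    ``psm`` is anything with ``protein``, ``peptide`` and ``modifications``
    attributes (a PsmRecord or a DataFrame row). Non-phospho modifications
    are ignored. Raises Unmappable/AmbiguousPeptideError when the peptide
    cannot be placed uniquely.
    """
    phospho_mods = [off for off, kind in psm.modifications if kind == PHOSPHO_KIND]
    if not phospho_mods:
        return []
    sequence = proteome[psm.protein]
    start = locate_peptide(psm.peptide, sequence)
    sites = []
    for offset in phospho_mods:
        residue_index = start + offset - 1
        sites.append(MappedSite(residue_index, sequence[residue_index - 1]))
    return sites


@dataclass(frozen=True)
class SiteOccupancy:
    protein: str
    residue_index: int
    residue_letter: str
    n_phos: int
    n_total: int

    @property
    def covered(self) -> bool:
        return self.n_total > 0

    @property
    def occupancy(self) -> float | None:
        return self.n_phos / self.n_total if self.covered else None

    @property
    def label(self) -> str:
        return f"{self.residue_letter}{self.residue_index}"


def site_occupancy(
    psms: pd.DataFrame,
    protein: str,
    residue_index: int,
    proteome: Mapping[str, str],
    count_mode: str = "psm",
) -> SiteOccupancy:
    """Occupancy of one residue in one run.

    Ambiguously located peptides are excluded with a warning. With
    ``count_mode="peptide"`` distinct peptide sequences are counted instead
    of spectra (a phosphorylated and an unphosphorylated version of the same
    sequence count as one each).
    """
    if count_mode not in ("psm", "peptide"):
        raise ApmsError(f"count_mode must be 'psm' or 'peptide', got {count_mode!r}")
    sequence = proteome[protein]
    if not 1 <= residue_index <= len(sequence):
        raise ApmsError(f"residue index {residue_index} outside {protein} (length {len(sequence)})")
    letter = sequence[residue_index - 1]
    sub = psms[psms["protein"] == protein]
    total_units: set | int = set() if count_mode == "peptide" else 0
    phos_units: set | int = set() if count_mode == "peptide" else 0
    for rec in sub.itertuples(index=False):
        try:
            start = locate_peptide(rec.peptide, sequence)
        except UnmappablePeptideError:
            raise
        except AmbiguousPeptideError:
            warnings.warn(
                f"excluding ambiguously located peptide {rec.peptide!r} of {protein}",
                stacklevel=2,
            )
            continue
        end = start + len(rec.peptide) - 1
        if not start <= residue_index <= end:
            continue
        has_phos = any(
            kind == PHOSPHO_KIND and start + off - 1 == residue_index
            for off, kind in rec.modifications
        )
        if count_mode == "peptide":
            total_units.add(rec.peptide)
            if has_phos:
                phos_units.add(rec.peptide)
        else:
            total_units += 1
            phos_units += int(has_phos)
    n_total = len(total_units) if count_mode == "peptide" else total_units
    n_phos = len(phos_units) if count_mode == "peptide" else phos_units
    return SiteOccupancy(protein, residue_index, letter, n_phos, n_total)


def discover_sites(psms: pd.DataFrame, protein: str, proteome: Mapping[str, str]) -> list[int]:
    """All residues of ``protein`` with at least one mapped phospho PSM."""
    found: set[int] = set()
    sub = psms[psms["protein"] == protein]
    for rec in sub.itertuples(index=False):
        try:
            for site in map_modifications_to_sites(rec, proteome):
                found.add(site.residue_index)
        except AmbiguousPeptideError:
            continue
    return sorted(found)


def occupancy_profile(
    psms: pd.DataFrame,
    protein: str,
    proteome: Mapping[str, str],
    residue_indices: Sequence[int] | None = None,
    count_mode: str = "psm",
) -> pd.DataFrame:
    """Per-run occupancy of every (given or discovered) site of a protein.

    Returns a long DataFrame with one row per (site, run): site_label,
    residue_index, residue_letter, run_id, condition, n_phos, n_total,
    occupancy (NaN when the run does not cover the site).
    """
    if residue_indices is None:
        residue_indices = discover_sites(psms, protein, proteome)
    rows = []
    for run_id, run_psms in psms.groupby("run_id", sort=False):
        condition = run_psms["condition"].iloc[0]
        for idx in residue_indices:
            occ = site_occupancy(run_psms, protein, idx, proteome, count_mode=count_mode)
            rows.append(
                {
                    "protein": protein,
                    "site_label": occ.label,
                    "residue_index": idx,
                    "residue_letter": occ.residue_letter,
                    "run_id": run_id,
                    "condition": condition,
                    "n_phos": occ.n_phos,
                    "n_total": occ.n_total,
                    "occupancy": occ.occupancy if occ.covered else np.nan,
                }
            )
    return pd.DataFrame(rows)


def summarize_profile(profile: pd.DataFrame) -> pd.DataFrame:
    """Mean occupancy +/- SEM per site over the runs that cover it."""
    rows = []
    for (protein, label, idx), group in profile.groupby(
        ["protein", "site_label", "residue_index"], sort=True
    ):
        occ = group["occupancy"].dropna()
        rows.append(
            {
                "protein": protein,
                "site_label": label,
                "residue_index": idx,
                "n_runs_covered": int(occ.size),
                "mean_occupancy": float(occ.mean()) if occ.size else np.nan,
                "sem_occupancy": float(occ.std(ddof=1) / np.sqrt(occ.size)) if occ.size > 1 else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("residue_index").reset_index(drop=True)


def compare_site_occupancy(occupancies_a, occupancies_b, site: str = "") -> PooledTResult:
    """Pooled-variance unpaired t-test on per-run occupancies of one site."""
    a = np.asarray(pd.Series(occupancies_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(occupancies_b).dropna(), dtype=float)
    where = f" at site {site}" if site else ""
    if a.size == 0 or b.size == 0:
        raise ApmsError(f"a condition has no covered runs{where}")
    if a.size < 2 or b.size < 2:
        raise ApmsError(f"need >= 2 covered runs per condition{where}, got {a.size} and {b.size}")
    return bait_recovery_test(a, b)
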