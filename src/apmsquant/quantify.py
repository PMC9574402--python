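"""Spectral-index quantification normalized to global intensity (SI_GI).

The central quantity of the pipeline: within one LC-MS/MS run, a protein's
raw spectral index is the sum of the intensities of all PSMs assigned to it,
and its SI_GI is that sum divided by the run's total over all detected
proteins. SI_GI is therefore compositional — each run's values sum to 1 —
which makes protein amounts comparable within and between runs regardless of
total ion current.

Detection and abundance are distinct: a protein whose PSMs all have zero
intensity is still *detected* in the run (it appears in the detection mask)
but has SI_GI 0. Undetected proteins have SI_GI exactly 0 and a False
detection flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ApmsError, DegenerateRunError

RUN_META_COLUMNS = ("condition", "bait_label", "genotype", "band")


def spectral_index(psms: pd.DataFrame) -> pd.Series:
    """Raw spectral index of every protein detected in one run.

    All PSMs must share a single ``run_id``; mixed runs are an error because
    global normalization is defined per run. Empty input yields an empty map.
    """
    if len(psms) == 0:
        return pd.Series(dtype=float, name="raw_index")
    run_ids = psms["run_id"].unique()
    if len(run_ids) > 1:
        raise ApmsError(f"spectral_index expects a single run, got {sorted(run_ids)}")
    raw = psms.groupby("protein", sort=True)["intensity"].sum()
    raw.name = "raw_index"
    return raw


def normalize_global(raw: pd.Series | Mapping[str, float]) -> pd.Series:
    """Normalize a raw spectral-index map to the run's total intensity."""
    raw = pd.Series(raw, dtype=float)
    total = raw.sum()
    if not total > 0:
        raise DegenerateRunError("degenerate run: total intensity is zero")
    si = raw / total
    si.name = "si_gi"
    return si


@dataclass
class QuantMatrix:
    """Per-protein, per-run SI_GI values plus run metadata.

    Attributes
    ----------
    values
        DataFrame proteins x runs; undetected entries are exactly 0 and each
        column over its detected proteins sums to 1.
    detected
        Boolean DataFrame of the same shape: protein observed in the run.
    runs
        Run metadata indexed by run_id with columns condition, bait_label,
        genotype, band; row order matches ``values.columns``.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    runs: pd.DataFrame

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.values.columns)

    def column_sums(self) -> pd.Series:
        return self.values.sum(axis=0)

    def run_ids_where(self, **criteria: str) -> list[str]:
        """Run ids whose metadata match all given column=value criteria."""
        mask = pd.Series(True, index=self.runs.index)
        for col, value in criteria.items():
            mask &= self.runs[col] == value
        return list(self.runs.index[mask])

    def select_runs(self, run_ids: list[str]) -> "QuantMatrix":
        return QuantMatrix(
            values=self.values[run_ids].copy(),
            detected=self.detected[run_ids].copy(),
            runs=self.runs.loc[run_ids].copy(),
        )

    def to_dir(self, out_dir: str | Path) -> None:
        """Serialize as TSV: si_gi.tsv, detected.tsv, runs.tsv."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        # %.17g round-trips float64 exactly, so staged re-runs are bit-identical
        self.values.rename_axis("protein").to_csv(out_dir / "si_gi.tsv", sep="\t", float_format="%.17g")
        self.detected.astype(int).rename_axis("protein").to_csv(out_dir / "detected.tsv", sep="\t")
        self.runs.rename_axis("run_id").to_csv(out_dir / "runs.tsv", sep="\t")

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "QuantMatrix":
        in_dir = Path(in_dir)
        values = pd.read_csv(
            in_dir / "si_gi.tsv", sep="\t", index_col="protein", float_precision="round_trip"
        )
        detected = pd.read_csv(in_dir / "detected.tsv", sep="\t", index_col="protein").astype(bool)
        values.columns.name = "run_id"
        detected.columns.name = "run_id"
        runs = pd.read_csv(
            in_dir / "runs.tsv", sep="\t", index_col="run_id", dtype=str, keep_default_na=False
        )
        return cls(values=values, detected=detected, runs=runs.loc[list(values.columns)])


def run_metadata(psms: pd.DataFrame) -> pd.DataFrame:
    """Extract per-run metadata, requiring consistency within each run."""
    meta = psms[["run_id", *RUN_META_COLUMNS]].drop_duplicates()
    counts = meta["run_id"].value_counts()
    inconsistent = counts[counts > 1]
    if len(inconsistent):
        run = inconsistent.index[0]
        raise ApmsError(f"inconsistent run metadata (condition/bait/genotype/band) within run {run!r}")
    return meta.set_index("run_id")


def build_quant_matrix(psms: pd.DataFrame) -> QuantMatrix:
    """Assemble the cross-run SI_GI matrix from an experiment's PSMs.

    Normalization is performed within each run independently, over all
    proteins detected in that run (background included). Run and protein
    order are lexicographic, so PSM row order never affects the matrix.
    """
    if len(psms) == 0:
        raise ApmsError("cannot build a quantification matrix from zero PSMs")
    runs = run_metadata(psms)
    run_order = sorted(psms["run_id"].unique())
    raw = psms.pivot_table(
        index="protein", columns="run_id", values="intensity", aggfunc="sum"
    ).reindex(columns=run_order)
    detected = raw.notna()
    raw = raw.fillna(0.0)
    totals = raw.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise DegenerateRunError(f"degenerate run {bad!r}: total intensity is zero")
    values = raw / totals
    values = values.sort_index()
    detected = detected.sort_index()
    return QuantMatrix(values=values, detected=detected, runs=runs.loc[run_order])


def by_band(psms: pd.DataFrame) -> dict[str, QuantMatrix]:
    """Build one quantification matrix per gel band present in the table."""
    return {
        band: build_quant_matrix(group)
        for band, group in psms.groupby("band", sort=True)
    }
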