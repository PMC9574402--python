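"""Input/output for PSM tables, reference FASTA files, and local network tables.

The pipeline consumes identification results at the PSM (peptide-spectrum
match) level: one row per matched spectrum, carrying the run it came from,
the experimental condition (bait purification or non-immune IgG control),
the protein it was assigned to, the matched peptide sequence, any localized
modifications, and a non-negative intensity in arbitrary units. Upstream
database searching (raw spectra -> identifications) is out of scope.

Modifications are encoded as semicolon-separated ``kind@offset`` tokens with
1-based offsets within the peptide, e.g. ``phospho@8;phospho@9``. Unknown
kinds are preserved verbatim and simply ignored by the phospho analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import (
    FastaError,
    PsmValidationError,
    SchemaError,
    TableFormatError,
)

#: Canonical column order of a PSM table.
PSM_COLUMNS = (
    "spectrum_id",
    "run_id",
    "condition",
    "bait_label",
    "genotype",
    "band",
    "protein",
    "peptide",
    "modifications",
    "intensity",
)

#: Columns that must be resolvable in every input table.
REQUIRED_COLUMNS = (
    "spectrum_id",
    "run_id",
    "condition",
    "protein",
    "peptide",
    "modifications",
    "intensity",
)

#: Optional columns and the default used when a table omits them.
OPTIONAL_COLUMN_DEFAULTS = {
    "bait_label": "",
    "genotype": "",
    "band": "unassigned",
}

CONDITIONS = frozenset({"bait", "control"})
BANDS = frozenset({"250kDa", "720kDa", "unassigned"})

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|")
_PEPTIDE_RE = re.compile(r"^[A-Z]+$")


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match."""

    spectrum_id: str
    run_id: str
    condition: str
    bait_label: str
    genotype: str
    band: str
    protein: str
    peptide: str
    modifications: tuple[tuple[int, str], ...]  # (1-based offset, kind)
    intensity: float


class ReferenceProteome(dict):
    """Mapping accession -> uppercase amino-acid sequence (1-based numbering)."""


def parse_modifications(text: str | None) -> tuple[tuple[int, str], ...]:
    """Parse ``kind@offset`` tokens; empty/missing field -> empty tuple."""
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return ()
    text = str(text).strip()
    if not text:
        return ()
    mods = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            kind, offset_str = token.rsplit("@", 1)
            offset = int(offset_str)
        except ValueError as exc:
            raise PsmValidationError(f"malformed modification token {token!r}") from exc
        mods.append((offset, kind.strip()))
    return tuple(mods)


def format_modifications(mods: Iterable[tuple[int, str]]) -> str:
    return ";".join(f"{kind}@{offset}" for offset, kind in mods)


def _resolve_columns(columns: Sequence[str], schema: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical column names to the table's actual column names."""
    schema = dict(schema or {})
    resolved: dict[str, str] = {}
    for name in PSM_COLUMNS:
        actual = schema.get(name, name)
        if actual in columns:
            resolved[name] = actual
        elif name in REQUIRED_COLUMNS:
            raise SchemaError(f"required column {actual!r} not found in PSM table")
    return resolved


def read_psm_table(path: str | Path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a tab-separated PSM table.

    Parameters
    ----------
    path
        UTF-8 TSV with a header row; ``#``-prefixed lines are ignored.
    schema
        Optional mapping from canonical column names to the table's column
        names, for tables produced by other tools.

    Returns
    -------
    DataFrame with the canonical :data:`PSM_COLUMNS`, the ``modifications``
    column parsed into tuples of ``(offset, kind)`` and ``intensity`` as float.

    Raises
    ------
    SchemaError
        If a required column is missing.
    PsmValidationError
        On the first invalid row (negative intensity, out-of-range
        modification offset, unknown condition/band), citing its row number.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    resolved = _resolve_columns(list(raw.columns), schema)
    df = pd.DataFrame({name: raw[actual] for name, actual in resolved.items()})
    for name, default in OPTIONAL_COLUMN_DEFAULTS.items():
        if name not in df.columns:
            df[name] = default
    df = df[list(PSM_COLUMNS)]
    return validate_psm_frame(df)


def validate_psm_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a PSM frame (parsed mods, float intensity)."""
    df = df.reset_index(drop=True).copy()
    try:
        intensity = pd.to_numeric(df["intensity"], errors="raise").astype(float)
    except (ValueError, TypeError):
        bad = pd.to_numeric(df["intensity"], errors="coerce")
        row = int(bad[bad.isna()].index[0]) + 1
        raise PsmValidationError("non-numeric intensity", row=row) from None
    mods_parsed = []
    for i, rec in enumerate(df.itertuples(index=False)):
        row = i + 1
        if intensity[i] < 0:
            raise PsmValidationError(f"negative intensity {intensity[i]}", row=row)
        if rec.condition not in CONDITIONS:
            raise PsmValidationError(f"unknown condition {rec.condition!r}", row=row)
        if rec.band not in BANDS:
            raise PsmValidationError(f"unknown band {rec.band!r}", row=row)
        peptide = str(rec.peptide)
        if not _PEPTIDE_RE.match(peptide):
            raise PsmValidationError(f"peptide {peptide!r} is not an uppercase residue string", row=row)
        try:
            mods = rec.modifications if isinstance(rec.modifications, tuple) else parse_modifications(rec.modifications)
        except PsmValidationError as exc:
            raise PsmValidationError(str(exc), row=row) from None
        for offset, kind in mods:
            if not 1 <= offset <= len(peptide):
                raise PsmValidationError(
                    f"modification offset {offset} outside peptide of length {len(peptide)}", row=row
                )
        mods_parsed.append(mods)
    df["modifications"] = mods_parsed
    df["intensity"] = intensity
    return df


def write_psm_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a PSM frame as canonical TSV (modifications re-serialized)."""
    out = df.copy()
    out["modifications"] = [
        format_modifications(m) if not isinstance(m, str) else m for m in out["modifications"]
    ]
    out = out[list(PSM_COLUMNS)]
    out.to_csv(path, sep="\t", index=False)


def psm_records(df: pd.DataFrame) -> list[PsmRecord]:
    """View a validated PSM frame as a list of :class:`PsmRecord`."""
    return [
        PsmRecord(
            spectrum_id=r.spectrum_id,
            run_id=r.run_id,
            condition=r.condition,
            bait_label=r.bait_label,
            genotype=r.genotype,
            band=r.band,
            protein=r.protein,
            peptide=r.peptide,
            modifications=tuple(r.modifications),
            intensity=float(r.intensity),
        )
        for r in df.itertuples(index=False)
    ]


def read_fasta(path: str | Path) -> ReferenceProteome:
    """Read reference sequences.

    The accession is the ``sp|ACC|NAME`` accession field of a UniProt-style
    header, otherwise the header's first whitespace-delimited token.
    """
    proteome = ReferenceProteome()
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            m = _UNIPROT_HEADER.match(record.id)
            accession = m.group(1) if m else record.id
            seq = str(record.seq).upper()
            if not seq:
                raise FastaError(f"empty sequence for {accession!r}")
            if accession in proteome:
                raise FastaError(f"duplicate accession {accession!r}")
            proteome[accession] = seq
    return proteome


def write_fasta(proteome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for accession in proteome:
            seq = proteome[accession]
            fh.write(f">{accession}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class ValidationReport:
    """Outcome of checking PSMs against a reference proteome."""

    n_psms: int
    mismatches: list[tuple[int, str, str, str]] = field(default_factory=list)  # (row, spectrum_id, protein, peptide)
    unknown_accessions: list[tuple[int, str, str]] = field(default_factory=list)  # (row, spectrum_id, protein)

    @property
    def ok(self) -> bool:
        return not self.mismatches and not self.unknown_accessions

    @property
    def bad_rows(self) -> set[int]:
        return {r for r, *_ in self.mismatches} | {r for r, *_ in self.unknown_accessions}

    def summary(self) -> str:
        return (
            f"{self.n_psms} PSMs checked: {len(self.unknown_accessions)} with unknown accession, "
            f"{len(self.mismatches)} whose peptide is absent from its protein"
        )


def validate_against_reference(
    psms: pd.DataFrame, proteome: Mapping[str, str]
) -> ValidationReport:
    """Flag PSMs whose protein is absent from the proteome or whose peptide
    is not a substring of its protein's sequence. Report-producing; never raises."""
    report = ValidationReport(n_psms=len(psms))
    for i, rec in enumerate(psms.itertuples(index=False)):
        row = i + 1
        seq = proteome.get(rec.protein)
        if seq is None:
            report.unknown_accessions.append((row, rec.spectrum_id, rec.protein))
        elif rec.peptide not in seq:
            report.mismatches.append((row, rec.spectrum_id, rec.protein, rec.peptide))
    return report


def drop_invalid(psms: pd.DataFrame, report: ValidationReport) -> pd.DataFrame:
    """Drop the rows a :class:`ValidationReport` flagged (drop-with-warning mode)."""
    bad = {r - 1 for r in report.bad_rows}
    keep = [i for i in range(len(psms)) if i not in bad]
    return psms.iloc[keep].reset_index(drop=True)


def read_interaction_table(path: str | Path) -> pd.DataFrame:
    """Local protein-protein interaction snapshot: TSV protein_a, protein_b, score."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in ("protein_a", "protein_b", "score"):
        if col not in df.columns:
            raise SchemaError(f"interaction table missing column {col!r}")
    score = pd.to_numeric(df["score"], errors="coerce")
    if score.isna().any():
        line = int(score[score.isna()].index[0]) + 2  # +1 header, +1 one-based
        raise TableFormatError("non-numeric interaction score", line=line)
    df = df.copy()
    df["score"] = score.astype(float)
    return df


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Local GO annotation snapshot: TSV protein, go_term [, score].

    Rows are assumed sorted best-first per protein when no score column is
    present; with a score column the highest-scoring term wins.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in ("protein", "go_term"):
        if col not in df.columns:
            raise SchemaError(f"annotation table missing column {col!r}")
    if "score" in df.columns:
        score = pd.to_numeric(df["score"], errors="coerce")
        if score.isna().any():
            line = int(score[score.isna()].index[0]) + 2
            raise TableFormatError("non-numeric annotation score", line=line)
        df = df.copy()
        df["score"] = score.astype(float)
    return df
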