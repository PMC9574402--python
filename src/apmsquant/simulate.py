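"""Synthetic AP-MS experiments with known ground truth.

The generator emulates the design of a bait-versus-IgG co-purification
study: a bait receptor complex whose member proteins co-purify at graded
abundances, a set of lower-abundance specific interactors enriched by a
configurable fold over the nonspecific background, background proteins that
bind bait and control beads alike, per-protein per-run detection dropout,
and phosphopeptides carrying localized modifications at defined per-site
occupancies. Defaults mirror the study conditions the pipeline was built
for: 5 bait-IP and 5 IgG-control replicates, a nine-subunit receptor
complex with abundances graded like a native pentameric receptor
purification, 30 interactors, and 100 background proteins.

Mechanics
---------
* Each protein has a condition weight: bait-complex members use their
  configured weights in bait runs (0 in controls by default), interactors
  use fold-enrichment x the background baseline in bait runs and a
  configurable fraction of baseline in controls, background proteins use a
  per-protein log-normal weight shared by both conditions.
* In each run, each non-dropped protein receives Poisson(psms_per_protein)
  PSMs (or exactly round(rate) with ``count_model="fixed"``); each PSM's
  intensity is weight x LogNormal(intensity_mu, intensity_sigma).
* Peptides are fixed-length windows over per-protein random reference
  sequences, unique to their protein with overwhelming probability; PSMs of
  a protein carrying a configured phosphosite are phosphorylated at that
  site with per-PSM probability equal to the true occupancy whenever the
  window covers the residue.
* Randomness: one stream per run derived from (seed, run_id), plus one
  structural stream for sequences and background weights — adding runs
  never perturbs existing ones, and a fixed seed reproduces outputs
  byte-identically.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ApmsError
from .io import ReferenceProteome, write_fasta, write_psm_table

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Graded bait-complex abundances (relative weights; background baseline = 1).
#: The profile follows a native receptor purification: one dominant target
#: subunit, partner subunits at 2--90x lower levels.
DEFAULT_BAIT_WEIGHTS = {
    "GABRA1": 8.7,
    "GABRB3": 3.5,
    "GABRG2": 2.4,
    "GABRB2": 1.4,
    "GABRA3": 0.7,
    "GABRB1": 0.6,
    "GABRD": 0.4,
    "GABRA2": 0.3,
    "GABRG3": 0.1,
}


def default_interactors(n: int = 30, fold_min: float = 2.0, fold_max: float = 50.0) -> dict[str, float]:
    """Graded specific interactors: fold-enrichments log-spaced over [min, max]."""
    folds = np.geomspace(fold_min, fold_max, n)
    return {f"INT{i + 1:03d}": float(f) for i, f in enumerate(folds[::-1])}


@dataclass(frozen=True)
class PhosphoSiteSpec:
    """A planted phosphosite: residue ``residue_index`` (1-based) of
    ``protein`` is fixed to ``residue_letter`` and phosphorylated on covering
    PSMs with probability ``occupancy``."""

    protein: str
    residue_index: int
    occupancy: float
    residue_letter: str = "S"

    def __post_init__(self):
        if not 0 <= self.occupancy <= 1:
            raise ApmsError(f"occupancy must be in [0, 1], got {self.occupancy}")
        if self.residue_letter not in "STY":
            raise ApmsError(f"phospho residue must be S, T or Y, got {self.residue_letter!r}")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_bait_runs: int = 5
    n_control_runs: int = 5
    bait_label: str = "Gabra1-IP"
    control_label: str = "IgG"
    genotype: str = "WT"
    band: str = "250kDa"
    bait_proteins: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BAIT_WEIGHTS))
    interactors: Mapping[str, float] = field(default_factory=default_interactors)
    interactor_control_level: float = 0.0  # fraction of background baseline in controls
    bait_control_level: float = 0.0  # fraction of the bait weight leaking into controls
    n_background: int = 100
    background_weight_sigma: float = 1.0  # log-normal spread of per-protein background weights
    intensity_mu: float = 0.0  # location of per-PSM log-intensity
    intensity_sigma: float = 0.3  # scale of per-PSM log-intensity
    psms_per_protein: float = 10.0  # mean PSM count per detected protein per run
    psm_rate_overrides: Mapping[str, float] = field(default_factory=dict)
    count_model: str = "poisson"  # or "fixed": exactly round(rate) PSMs
    dropout: float = 0.05  # per-protein per-run detection failure probability
    abundance_dependent_dropout: bool = False
    phospho_sites: tuple[PhosphoSiteSpec, ...] = ()
    peptide_length: int = 12
    protein_length: int = 120

    def __post_init__(self):
        if not 0 <= self.dropout <= 1:
            raise ApmsError(f"dropout must be in [0, 1], got {self.dropout}")
        if not 0 <= self.interactor_control_level:
            raise ApmsError("interactor_control_level must be >= 0")
        if self.count_model not in ("poisson", "fixed"):
            raise ApmsError(f"count_model must be 'poisson' or 'fixed', got {self.count_model!r}")
        if self.peptide_length > self.protein_length:
            raise ApmsError("peptide_length must not exceed protein_length")
        if not (self.bait_proteins or self.interactors or self.n_background):
            raise ApmsError("config defines zero proteins")
        for w in {**self.bait_proteins, **self.interactors}.values():
            if not w > 0:
                raise ApmsError(f"weights and fold-enrichments must be > 0, got {w}")
        for site in self.phospho_sites:
            if not 1 <= site.residue_index <= self.protein_length:
                raise ApmsError(
                    f"phosphosite {site.residue_index} outside sequence of length {self.protein_length}"
                )


@dataclass
class SimulationTruth:
    """Exact parameterization behind a simulated experiment."""

    interactors: set[str]  # bait-complex members + planted interactors
    background: set[str]
    true_mean_si_gi: pd.DataFrame  # proteins x {bait, control} expected shares
    occupancies: dict[tuple[str, int], float]  # (protein, residue_index) -> theta


@dataclass
class SimulatedExperiment:
    psms: pd.DataFrame
    proteome: ReferenceProteome
    truth: SimulationTruth
    run_meta: pd.DataFrame
    config: SimulationConfig


def _run_stream(seed: int, run_id: str) -> np.random.Generator:
    digest = hashlib.blake2s(run_id.encode(), digest_size=8).digest()
    return np.random.default_rng([int(seed), int.from_bytes(digest, "big")])


def _condition_weights(config: SimulationConfig, bg_weights: dict[str, float]):
    bait_w: dict[str, float] = {}
    control_w: dict[str, float] = {}
    for p, w in config.bait_proteins.items():
        bait_w[p] = float(w)
        control_w[p] = float(w) * config.bait_control_level
    for p, fold in config.interactors.items():
        bait_w[p] = float(fold)
        control_w[p] = config.interactor_control_level
    for p, w in bg_weights.items():
        bait_w[p] = w
        control_w[p] = w
    return bait_w, control_w


def _expected_shares(config, proteins, bait_w, control_w) -> pd.DataFrame:
    rates = {p: config.psm_rate_overrides.get(p, config.psms_per_protein) for p in proteins}
    rows = {}
    for cond, weights in (("bait", bait_w), ("control", control_w)):
        mass = np.array([weights[p] * rates[p] for p in proteins])
        total = mass.sum()
        rows[cond] = mass / total if total > 0 else mass
    return pd.DataFrame(rows, index=pd.Index(proteins, name="protein"))


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate PSM tables for every run plus the generating ground truth."""
    struct_rng = np.random.default_rng([int(config.seed), 0])

    proteins = (
        list(config.bait_proteins)
        + list(config.interactors)
        + [f"BG{i + 1:04d}" for i in range(config.n_background)]
    )
    if len(set(proteins)) != len(proteins):
        raise ApmsError("protein identifiers are not unique across bait/interactor/background sets")

    # reference sequences; planted phosphosite residues forced to their letter
    sites_by_protein: dict[str, list[PhosphoSiteSpec]] = {}
    for site in config.phospho_sites:
        if site.protein not in proteins:
            raise ApmsError(f"phosphosite protein {site.protein!r} not in the simulated protein set")
        sites_by_protein.setdefault(site.protein, []).append(site)
    proteome = ReferenceProteome()
    for p in proteins:
        letters = struct_rng.choice(_AMINO_ACIDS, size=config.protein_length)
        for site in sites_by_protein.get(p, ()):
            letters[site.residue_index - 1] = site.residue_letter
        proteome[p] = "".join(letters)

    bg_weights = {
        f"BG{i + 1:04d}": float(w)
        for i, w in enumerate(
            np.exp(struct_rng.normal(0.0, config.background_weight_sigma, config.n_background))
        )
    }
    bait_w, control_w = _condition_weights(config, bg_weights)

    runs = [
        (f"{config.bait_label}_r{i + 1}", "bait", config.bait_label)
        for i in range(config.n_bait_runs)
    ] + [
        (f"{config.control_label}_r{i + 1}", "control", config.control_label)
        for i in range(config.n_control_runs)
    ]

    frames = []
    pep_len = config.peptide_length
    n_starts = config.protein_length - pep_len + 1
    for run_id, condition, label in runs:
        rng = _run_stream(config.seed, run_id)
        weights = bait_w if condition == "bait" else control_w
        cols: dict[str, list] = {c: [] for c in ("protein", "peptide", "modifications", "intensity")}
        scan = 0
        for p in proteins:
            w = weights[p]
            if w <= 0:
                continue
            p_drop = _dropout_probability(config, p, w, bg_weights)
            if rng.random() < p_drop:
                continue
            rate = config.psm_rate_overrides.get(p, config.psms_per_protein)
            count = int(rng.poisson(rate)) if config.count_model == "poisson" else int(round(rate))
            if count == 0:
                continue
            if config.intensity_sigma > 0:
                intensities = w * np.exp(
                    rng.normal(config.intensity_mu, config.intensity_sigma, count)
                )
            else:
                intensities = np.full(count, w * np.exp(config.intensity_mu))
            starts = rng.integers(0, n_starts, size=count)  # 0-based window starts
            seq = proteome[p]
            peptides = [seq[s : s + pep_len] for s in starts]
            mods: list[tuple[tuple[int, str], ...]] = [()] * count
            for site in sites_by_protein.get(p, ()):
                covered = (starts + 1 <= site.residue_index) & (site.residue_index <= starts + pep_len)
                phos = covered & (rng.random(count) < site.occupancy)
                for j in np.nonzero(phos)[0]:
                    offset = int(site.residue_index - starts[j])
                    mods[j] = mods[j] + ((offset, "phospho"),)
            cols["protein"].extend([p] * count)
            cols["peptide"].extend(peptides)
            cols["modifications"].extend(mods)
            cols["intensity"].extend(intensities.tolist())
        n = len(cols["protein"])
        frame = pd.DataFrame(
            {
                "spectrum_id": [f"{run_id}:scan{i + 1:06d}" for i in range(n)],
                "run_id": run_id,
                "condition": condition,
                "bait_label": label,
                "genotype": config.genotype,
                "band": config.band,
                "protein": cols["protein"],
                "peptide": cols["peptide"],
                "modifications": cols["modifications"],
                "intensity": cols["intensity"],
            }
        )
        frames.append(frame)

    psms = pd.concat(frames, ignore_index=True)
    run_meta = pd.DataFrame(
        [
            {"run_id": r, "condition": c, "bait_label": l, "genotype": config.genotype, "band": config.band}
            for r, c, l in runs
        ]
    ).set_index("run_id")
    truth = SimulationTruth(
        interactors=set(config.bait_proteins) | set(config.interactors),
        background=set(bg_weights),
        true_mean_si_gi=_expected_shares(config, proteins, bait_w, control_w),
        occupancies={(s.protein, s.residue_index): s.occupancy for s in config.phospho_sites},
    )
    return SimulatedExperiment(psms=psms, proteome=proteome, truth=truth, run_meta=run_meta, config=config)


def _dropout_probability(config, protein, weight, bg_weights) -> float:
    if config.dropout == 0:
        return 0.0
    if not config.abundance_dependent_dropout:
        return config.dropout
    baseline = float(np.median(list(bg_weights.values()))) if bg_weights else 1.0
    return float(min(1.0, config.dropout * baseline / max(weight, 1e-12)))


def write_experiment(experiment: SimulatedExperiment, out_dir: str | Path) -> dict[str, Path]:
    """Emit psms.tsv, reference.fasta and truth.tsv into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "psms": out_dir / "psms.tsv",
        "fasta": out_dir / "reference.fasta",
        "truth": out_dir / "truth.tsv",
    }
    write_psm_table(experiment.psms, paths["psms"])
    write_fasta(experiment.proteome, paths["fasta"])
    truth = experiment.truth
    table = truth.true_mean_si_gi.copy()
    table["role"] = [
        "interactor" if p in truth.interactors else "background" for p in table.index
    ]
    table.to_csv(paths["truth"], sep="\t")
    return paths


@dataclass(frozen=True)
class RecoveryScore:
    sensitivity: float | None  # None when no interactors were planted
    false_positive_rate: float


def score_recovery(
    truth: SimulationTruth,
    records: pd.DataFrame,
    require_all_replicates: bool = False,
) -> RecoveryScore:
    """Recovery of the planted interactome from enrichment records.

    sensitivity = fraction of true interactors flagged significant (and, with
    ``require_all_replicates``, detected in every bait replicate); the false
    positive rate is the corresponding fraction over pure-background
    proteins. Interactors never reaching the record list count as missed.
    """
    known = truth.interactors | truth.background
    unknown = set(records["protein"]) - known
    if unknown:
        raise ApmsError(f"records contain proteins absent from the truth: {sorted(unknown)[:5]}")
    flagged = records["significant"]
    if require_all_replicates:
        flagged = flagged & records["detected_in_all"]
    flagged_set = set(records.loc[flagged, "protein"])
    fpr = (
        len(flagged_set & truth.background) / len(truth.background)
        if truth.background
        else 0.0
    )
    if not truth.interactors:
        return RecoveryScore(None, fpr)
    sens = len(flagged_set & truth.interactors) / len(truth.interactors)
    return RecoveryScore(sens, fpr)


def null_config(seed: int, n_background: int = 200) -> SimulationConfig:
    """Null experiment: background only, bait and control runs exchangeable."""
    return SimulationConfig(
        seed=seed,
        bait_proteins={},
        interactors={},
        n_background=n_background,
        dropout=0.0,
    )
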