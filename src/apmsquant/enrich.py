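"""Per-protein enrichment testing against the non-immune IgG control.

Each protein detected in at least one bait replicate is tested with Welch's
unequal-variance t-test: bait-replicate SI_GI values against control-replicate
values, undetected entries zero-filled by default so both group vectors have
full length (absence from a compositional profile is informative). The test
is two-tailed; no multiple-testing correction is applied by default, matching
the per-protein raw p-values this kind of study reports — Benjamini-Hochberg
can be switched on via :class:`EnrichConfig`.

A protein is *significant* when p < alpha and the test is non-degenerate; it
is *detected in all replicates* when it appears in every bait run. Downstream
analyses typically require both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ApmsError
from .quantify import QuantMatrix

ENRICHMENT_COLUMNS = (
    "protein",
    "mean_si_gi",
    "sem",
    "t",
    "df",
    "p",
    "detected_in_all",
    "significant",
    "enriched",
    "degenerate",
)


@dataclass(frozen=True)
class EnrichConfig:
    """Knobs for the enrichment test.

    alpha
        Two-tailed significance level (0.05, the convention of the
        ``*p < 0.05`` legends this analysis feeds).
    zero_fill
        Treat undetected entries as SI_GI 0 (default). When False, each
        protein's test uses only the runs where it was detected; groups left
        with fewer than 2 values are flagged degenerate.
    multiple_testing
        None (raw per-protein p-values, default) or ``"fdr_bh"`` for
        Benjamini-Hochberg adjustment of the significance calls.
    """

    alpha: float = 0.05
    zero_fill: bool = True
    multiple_testing: str | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.multiple_testing not in (None, "fdr_bh"):
            raise ValueError(f"unknown multiple_testing {self.multiple_testing!r}")


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool


def welch_test(x, y) -> WelchResult:
    """Welch's two-sample t-test.

    t = (mean x - mean y) / sqrt(s2x/nx + s2y/ny), with Welch-Satterthwaite
    degrees of freedom and a two-tailed p from Student's t. When one sample
    variance is zero the formula applies unchanged (s2y = 0 reduces df to
    nx - 1); when both are zero the result is degenerate: t, df, p are NaN
    and the protein can never be called significant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ApmsError(f"welch_test needs >= 2 values per group, got {x.size} and {y.size}")
    t, df, p, degen = _welch_arrays(x[None, :], y[None, :])
    return WelchResult(float(t[0]), float(df[0]), float(p[0]), bool(degen[0]))


def _welch_arrays(X: np.ndarray, Y: np.ndarray):
    """Row-wise Welch test on 2-D arrays (rows are proteins)."""
    nx, ny = X.shape[1], Y.shape[1]
    mx, my = X.mean(axis=1), Y.mean(axis=1)
    vx, vy = X.var(axis=1, ddof=1), Y.var(axis=1, ddof=1)
    se2 = vx / nx + vy / ny
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    t = np.where(degenerate, np.nan, t)
    df = np.where(degenerate, np.nan, df)
    p = np.where(degenerate, np.nan, p)
    return t, df, p, degenerate


def enrich_proteins(
    matrix: QuantMatrix,
    bait_label: str | None = None,
    config: EnrichConfig = EnrichConfig(),
) -> pd.DataFrame:
    """Test every protein seen in a bait purification against the IgG control.

    Parameters
    ----------
    matrix
        Quantification matrix holding both bait and control runs (already
        restricted to one gel band).
    bait_label
        Restrict the bait group to runs with this label; all
        ``condition == "control"`` runs form the comparison group.

    Returns
    -------
    One row per protein detected in >= 1 bait run, sorted by mean bait SI_GI
    descending, with columns :data:`ENRICHMENT_COLUMNS`.
    """
    bait_criteria = {"condition": "bait"}
    if bait_label is not None:
        bait_criteria["bait_label"] = bait_label
    bait_runs = matrix.run_ids_where(**bait_criteria)
    control_runs = matrix.run_ids_where(condition="control")
    if len(bait_runs) < 2 or len(control_runs) < 2:
        raise ApmsError(
            f"need >= 2 bait and >= 2 control runs, got {len(bait_runs)} and {len(control_runs)}"
        )

    bait_detected = matrix.detected[bait_runs]
    seen = bait_detected.any(axis=1)
    proteins = list(matrix.values.index[seen])
    X = matrix.values.loc[proteins, bait_runs].to_numpy(dtype=float)
    Y = matrix.values.loc[proteins, control_runs].to_numpy(dtype=float)

    nb = len(bait_runs)
    mean = X.mean(axis=1)
    sem = X.std(axis=1, ddof=1) / math.sqrt(nb)

    if config.zero_fill:
        t, df, p, degenerate = _welch_arrays(X, Y)
    else:
        t, df, p, degenerate = _welch_pairwise(
            X, Y,
            matrix.detected.loc[proteins, bait_runs].to_numpy(),
            matrix.detected.loc[proteins, control_runs].to_numpy(),
        )

    significant = np.zeros(len(proteins), dtype=bool)
    tested = ~degenerate & ~np.isnan(p)
    if config.multiple_testing == "fdr_bh" and tested.any():
        q = np.full(len(proteins), np.nan)
        q[tested] = stats.false_discovery_control(p[tested], method="bh")
        significant[tested] = q[tested] < config.alpha
    else:
        significant[tested] = p[tested] < config.alpha

    out = pd.DataFrame(
        {
            "protein": proteins,
            "mean_si_gi": mean,
            "sem": sem,
            "t": t,
            "df": df,
            "p": p,
            "detected_in_all": bait_detected.loc[proteins].all(axis=1).to_numpy(),
            "significant": significant,
            # significant in the bait direction: SI_GI is compositional, so a
            # strong pull-down *depletes* everything else and a two-tailed test
            # flags those too; "enriched" is the elevated-in-bait subset
            "enriched": significant & (np.nan_to_num(t) > 0),
            "degenerate": degenerate,
        }
    )
    out = out.sort_values(["mean_si_gi", "protein"], ascending=[False, True], kind="stable")
    return out.reset_index(drop=True)


def _welch_pairwise(X, Y, det_x, det_y):
    """Pairwise-deletion variant: only detected entries enter each group."""
    n = X.shape[0]
    t = np.full(n, np.nan)
    df = np.full(n, np.nan)
    p = np.full(n, np.nan)
    degenerate = np.zeros(n, dtype=bool)
    for i in range(n):
        x = X[i, det_x[i]]
        y = Y[i, det_y[i]]
        if x.size < 2 or y.size < 2:
            degenerate[i] = True
            continue
        res = welch_test(x, y)
        t[i], df[i], p[i], degenerate[i] = res.t, res.df, res.p, res.degenerate
    return t, df, p, degenerate


def filter_all_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only proteins detected in every bait replicate."""
    return records[records["detected_in_all"]].reset_index(drop=True)


def write_enrichment(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_enrichment(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("detected_in_all", "significant", "enriched", "degenerate"):
        df[col] = df[col].astype(bool)
    return df
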