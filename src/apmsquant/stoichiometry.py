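"""Composition summaries of enrichment results.

Three summaries this kind of study prints:

* subunit-class fractions — e.g. each alpha-isoform's share of the total
  alpha-subunit signal, computed over the significantly enriched members so
  the printed percentages sum to 100;
* relative-abundance pies, where proteins under a threshold share (2% by
  convention) are merged into a trailing "Other" bucket;
* bait-recovery comparisons between purifications, by pooled-variance
  unpaired Student's t-test — from printed summary statistics (mean, SEM, n)
  or from full replicate vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ApmsError


@dataclass
class CompositionTable:
    """class label -> fraction of summed mean SI_GI (fractions sum to 1)."""

    fractions: pd.Series
    provenance: dict = field(default_factory=dict)


@dataclass
class PieSummary:
    """Descending (label, fraction) pairs plus a trailing Other bucket."""

    entries: list[tuple[str, float]]
    other: float
    other_count: int
    other_threshold: float

    def as_series(self) -> pd.Series:
        labels = [l for l, _ in self.entries] + ["Other"]
        values = [f for _, f in self.entries] + [self.other]
        return pd.Series(values, index=labels, name="fraction")


def composition_fractions(
    records: pd.DataFrame,
    class_map: Mapping[str, str],
    only_significant: bool = True,
) -> CompositionTable:
    """Fraction of summed mean SI_GI contributed by each class.

    ``class_map`` assigns a class label (e.g. the alpha-isoform name) to the
    proteins of interest; proteins absent from the map are ignored. With
    ``only_significant`` (the convention of per-isoform stoichiometry
    figures) the denominator is restricted to significant records, so the
    shares sum to 100% over exactly the significant class members.
    """
    sel = records[records["protein"].isin(class_map)]
    if only_significant:
        sel = sel[sel["significant"]]
    if len(sel) == 0 or not (sel["mean_si_gi"] > 0).any():
        raise ApmsError("empty selection: no (significant) proteins with positive mean SI_GI")
    classes = sel["protein"].map(dict(class_map))
    sums = sel.groupby(classes)["mean_si_gi"].sum()
    fractions = sums / sums.sum()
    fractions.name = "fraction"
    return CompositionTable(
        fractions=fractions,
        provenance={
            "proteins": list(sel["protein"]),
            "only_significant": only_significant,
            "denominator": float(sums.sum()),
        },
    )


def pie_summary(records: pd.DataFrame, other_threshold: float = 0.02) -> PieSummary:
    """Relative abundance of each record's mean SI_GI, small slices merged.

    Fractions are over the summed mean SI_GI of all included records; labels
    whose fraction is below ``other_threshold`` are grouped into "Other".
    With threshold 0 the Other bucket is empty and the explicit entries
    reproduce the plain composition.
    """
    if other_threshold < 0:
        raise ApmsError(f"other_threshold must be >= 0, got {other_threshold}")
    if len(records) == 0:
        raise ApmsError("pie_summary needs at least one record")
    total = records["mean_si_gi"].sum()
    if not total > 0:
        raise ApmsError("pie_summary needs positive total mean SI_GI")
    frac = (records["mean_si_gi"] / total).to_numpy()
    labels = records["protein"].to_numpy()
    order = np.lexsort((labels, -frac))
    entries = []
    other = 0.0
    other_count = 0
    for i in order:
        if frac[i] < other_threshold:
            other += float(frac[i])
            other_count += 1
        else:
            entries.append((str(labels[i]), float(frac[i])))
    return PieSummary(entries=entries, other=other, other_count=other_count, other_threshold=other_threshold)


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class PooledTResult:
    t: float
    df: float
    p: float
    degenerate: bool


def _as_summary(values) -> SummaryStats:
    if isinstance(values, SummaryStats):
        return values
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ApmsError("replicate input must be one-dimensional")
    n = int(values.size)
    if n < 2:
        raise ApmsError(f"need n >= 2 replicates, got {n}")
    return SummaryStats(
        mean=float(values.mean()),
        sem=float(values.std(ddof=1) / math.sqrt(n)),
        n=n,
    )


def bait_recovery_test(a, b) -> PooledTResult:
    """Pooled-variance unpaired Student's t-test between two purifications.

    ``a`` and ``b`` are either ``SummaryStats``/``(mean, sem, n)`` printed
    summaries or full replicate vectors (summarized first; both paths agree
    exactly). Sample variance is recovered from the SEM as s^2 = n * sem^2;
    df = n_a + n_b - 2. Two identical zero-variance groups are degenerate.
    """
    if isinstance(a, tuple) and len(a) == 3:
        a = SummaryStats(float(a[0]), float(a[1]), int(a[2]))
    if isinstance(b, tuple) and len(b) == 3:
        b = SummaryStats(float(b[0]), float(b[1]), int(b[2]))
    sa, sb = _as_summary(a), _as_summary(b)
    if sa.sem < 0 or sb.sem < 0:
        raise ApmsError("SEM must be non-negative")
    if sa.n < 2 or sb.n < 2:
        raise ApmsError("need n >= 2 in each group")
    var_a = sa.n * sa.sem**2
    var_b = sb.n * sb.sem**2
    df = sa.n + sb.n - 2
    sp2 = ((sa.n - 1) * var_a + (sb.n - 1) * var_b) / df
    se = math.sqrt(sp2 * (1 / sa.n + 1 / sb.n))
    if se == 0:
        return PooledTResult(math.nan, float(df), math.nan, True)
    t = (sa.mean - sb.mean) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PooledTResult(t, float(df), p, False)


def write_composition(table: CompositionTable, path) -> None:
    table.fractions.rename_axis("label").to_csv(path, sep="\t")


def write_pie(summary: PieSummary, path) -> None:
    summary.as_series().rename_axis("label").to_csv(path, sep="\t")
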