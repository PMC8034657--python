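"""Intron-retention quantification and differential IR testing.

The IR ratio of one intron in one sample is

    IR = intronic_abundance / (intronic_abundance + spliced_abundance)

where intronic abundance is the trimmed-median per-base depth over the
intron's measurable region (per-base depth is already length-normalized) and
spliced abundance is the exon-exon junction read count, a point feature
commensurate with per-base depth.

Differential IR between two conditions pools (sums) counts across replicates
within each condition and applies the Audic-Claverie exact test to the
pooled intron read counts against the pooled intron + spliced totals, with
no multiple-testing correction at the primary threshold (BH q-values are
emitted additionally for convenience).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import CoverageTrack, Intron, JunctionCounts

WARN_LOW_COVER = "LowCover"
WARN_LOW_SPLICING = "LowSplicing"

#: an event is a reliable retained intron when clean and IR ratio > this
RELIABLE_IR_THRESHOLD = 0.1

#: default read length used to convert per-base depth back to read units
DEFAULT_READ_LENGTH = 100


# ---------------------------------------------------------------------------
# per-sample measurement
# ---------------------------------------------------------------------------


@dataclass
class IRMeasurement:
    intron_id: str
    sample_id: str
    compartment: str = "whole"
    gene_id: str = ""
    intronic_abundance: float = 0.0
    spliced_abundance: int = 0
    flank_support: int = 0
    intron_reads: int = 0
    intron_length: int = 0
    ir_ratio: float = float("nan")
    warnings: frozenset[str] = field(default_factory=frozenset)
    defined: bool = True

    @property
    def clean(self) -> bool:
        return self.defined and not self.warnings


def trimmed_median_depth(depths: Sequence[float]) -> float:
    """Median depth after discarding the lowest and highest 30% of positions.

    Positions are sorted by depth and floor(0.3 n) positions are removed from
    each end; the median of the remainder is returned.  If trimming would
    remove everything the plain median is returned instead.
    """
    values = np.sort(np.asarray(depths, dtype=float))
    n = values.size
    if n == 0:
        raise ValueError("trimmed_median_depth requires at least one position")
    k = int(math.floor(0.3 * n))
    core = values[k : n - k]
    if core.size == 0:
        core = values
    return float(np.median(core))


def classify_reliability(flank_support: int, intron_reads: int) -> frozenset[str]:
    """IRFinder-style warnings: LowCover unless flank + intron reads > 10,
    LowSplicing unless flank-spanning reads > 4."""
    warnings = set()
    if not (flank_support + intron_reads > 10):
        warnings.add(WARN_LOW_COVER)
    if not (flank_support > 4):
        warnings.add(WARN_LOW_SPLICING)
    return frozenset(warnings)


def compute_ir(
    intron: Intron,
    coverage: CoverageTrack,
    junctions: JunctionCounts,
    read_length: int = DEFAULT_READ_LENGTH,
) -> IRMeasurement:
    """Quantify IR for one intron in one sample.

    Raises ``ValueError`` for unusable introns (empty measurable region).
    Measurements with zero intronic and zero spliced signal are flagged
    undefined and must be excluded downstream.
    """
    if not intron.usable:
        raise ValueError(f"intron {intron.intron_id} has no measurable region")
    depths = np.concatenate(
        [coverage.depths(iv) for iv in intron.measurable_region]
    )
    intronic = trimmed_median_depth(depths)
    spliced, five, three = junctions.get(intron.intron_id)
    flank = five + three
    intron_reads = int(round(intronic * intron.measurable_length / read_length))
    measurement = IRMeasurement(
        intron_id=intron.intron_id,
        sample_id=coverage.sample_id,
        compartment=coverage.compartment,
        gene_id=intron.gene_id,
        intronic_abundance=intronic,
        spliced_abundance=spliced,
        flank_support=flank,
        intron_reads=intron_reads,
        intron_length=intron.length,
    )
    if intronic == 0 and spliced == 0:
        measurement.defined = False
        return measurement
    measurement.ir_ratio = intronic / (intronic + spliced)
    measurement.warnings = classify_reliability(flank, intron_reads)
    return measurement


def reliable_retained(measurement: IRMeasurement) -> bool:
    """True iff the measurement is clean and IR ratio strictly exceeds 0.1."""
    return (
        measurement.clean
        and measurement.defined
        and measurement.ir_ratio > RELIABLE_IR_THRESHOLD
    )


# ---------------------------------------------------------------------------
# Audic-Claverie test
# ---------------------------------------------------------------------------


def _ac_tails(x: int, big_n1: int, y: int, big_n2: int) -> tuple[float, float]:
    # P(Y = j | x) with r = N2/N1 is negative binomial:
    #   NB(number of successes x + 1, success probability 1/(1+r))
    r = big_n2 / big_n1
    dist = stats.nbinom(x + 1, 1.0 / (1.0 + r))
    lower = float(dist.cdf(y))
    upper = float(dist.sf(y - 1))
    return lower, upper


def audic_claverie_p(x: int, big_n1: int, y: int, big_n2: int) -> float:
    """Two-sided Audic-Claverie p-value for count x in a library of size N1
    against count y in a library of size N2.

    Uses the conditional distribution P(Y=y | x) = r^y (x+y)! /
    (x! y! (1+r)^(x+y+1)), r = N2/N1, evaluated through its
    negative-binomial form with regularized-incomplete-beta tails so that
    extreme tails remain accurate.  The two-sided p is min(1, 2 * smaller
    tail).  Arguments are canonically ordered first, so label symmetry
    p(x,N1,y,N2) == p(y,N2,x,N1) holds bit-exactly.
    """
    if big_n1 <= 0 or big_n2 <= 0:
        raise ValueError("library sizes must be positive")
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if x > big_n1 or y > big_n2:
        raise ValueError("count exceeds its library size")
    if (x, big_n1) > (y, big_n2):
        x, big_n1, y, big_n2 = y, big_n2, x, big_n1
    lower, upper = _ac_tails(x, big_n1, y, big_n2)
    return float(min(1.0, 2.0 * min(lower, upper)))


# ---------------------------------------------------------------------------
# differential IR
# ---------------------------------------------------------------------------


@dataclass
class DifferentialIREvent:
    intron_id: str
    gene_id: str
    contrast: tuple[str, str]
    intron_a: int
    spliced_a: int
    intron_b: int
    spliced_b: int
    ir_a: float
    ir_b: float
    delta_ir: float
    p_value: float
    significant: bool
    q_value: float = float("nan")
    intron_length: int = 0


def _pool(measurements: Iterable[IRMeasurement]) -> tuple[float, int, int, int]:
    abundance, spliced, reads, length = 0.0, 0, 0, 0
    for m in measurements:
        if not m.defined:
            continue
        abundance += m.intronic_abundance
        spliced += m.spliced_abundance
        reads += m.intron_reads
        length = max(length, m.intron_length)
    return abundance, spliced, reads, length


def differential_ir(
    measurements_a: Sequence[IRMeasurement],
    measurements_b: Sequence[IRMeasurement],
    contrast: tuple[str, str] = ("A", "B"),
    alpha: float = 0.05,
) -> list[DifferentialIREvent]:
    """Call differential IR for contrast A vs B (delta = ratio_A - ratio_B).

    Only introns with a clean measurement in at least one sample per
    condition enter.  Counts are pooled (summed) across replicates within
    each condition; the Audic-Claverie test is applied to pooled intron read
    counts against pooled intron + spliced totals.  Condition IR ratios use
    pooled abundances so they remain length-normalized.
    """
    by_intron_a: dict[str, list[IRMeasurement]] = {}
    by_intron_b: dict[str, list[IRMeasurement]] = {}
    for m in measurements_a:
        by_intron_a.setdefault(m.intron_id, []).append(m)
    for m in measurements_b:
        by_intron_b.setdefault(m.intron_id, []).append(m)

    events: list[DifferentialIREvent] = []
    for intron_id in sorted(set(by_intron_a) & set(by_intron_b)):
        group_a, group_b = by_intron_a[intron_id], by_intron_b[intron_id]
        if not any(m.clean for m in group_a) or not any(m.clean for m in group_b):
            continue
        abund_a, spliced_a, reads_a, length = _pool(group_a)
        abund_b, spliced_b, reads_b, _ = _pool(group_b)
        denom_a = abund_a + spliced_a
        denom_b = abund_b + spliced_b
        if denom_a == 0 or denom_b == 0:
            continue
        ir_a = abund_a / denom_a
        ir_b = abund_b / denom_b
        p = audic_claverie_p(
            reads_b, reads_b + spliced_b, reads_a, reads_a + spliced_a
        )
        events.append(
            DifferentialIREvent(
                intron_id=intron_id,
                gene_id=group_a[0].gene_id,
                contrast=contrast,
                intron_a=reads_a,
                spliced_a=spliced_a,
                intron_b=reads_b,
                spliced_b=spliced_b,
                ir_a=ir_a,
                ir_b=ir_b,
                delta_ir=ir_a - ir_b,
                p_value=p,
                significant=p < alpha,
            )
        )
    if events:
        from statsmodels.stats.multitest import multipletests

        qvals = multipletests([e.p_value for e in events], method="fdr_bh")[1]
        for event, q in zip(events, qvals):
            event.q_value = float(q)
    return events


# ---------------------------------------------------------------------------
# direction summaries
# ---------------------------------------------------------------------------


@dataclass
class DirectionSummary:
    contrast: tuple[str, str]
    n_events: int
    n_decreased: int
    n_increased: int
    percent_decreased: float
    t_statistic: float
    t_p_value: float
    wilcoxon_p_value: float


def summarize_directions(
    events: Sequence[DifferentialIREvent], alpha: float = 0.05
) -> DirectionSummary:
    """Count significant events by delta-IR direction (ties excluded) and
    test the delta-IR distribution against zero (one-sample t and Wilcoxon
    signed-rank)."""
    significant = [e for e in events if e.p_value < alpha]
    if not significant:
        raise ValueError("no significant events to summarize")
    deltas = np.array([e.delta_ir for e in significant])
    decreased = int(np.sum(deltas < 0))
    increased = int(np.sum(deltas > 0))
    n_events = decreased + increased
    percent = 100.0 * decreased / n_events if n_events else float("nan")
    t_stat, t_p = stats.ttest_1samp(deltas, 0.0)
    nonzero = deltas[deltas != 0]
    w_p = float(stats.wilcoxon(nonzero)[1]) if nonzero.size else float("nan")
    contrast = significant[0].contrast
    return DirectionSummary(
        contrast=contrast,
        n_events=n_events,
        n_decreased=decreased,
        n_increased=increased,
        percent_decreased=percent,
        t_statistic=float(t_stat),
        t_p_value=float(t_p),
        wilcoxon_p_value=w_p,
    )


# ---------------------------------------------------------------------------
# tabular conversions
# ---------------------------------------------------------------------------


def measurements_to_frame(measurements: Iterable[IRMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        rows.append(
            {
                "intron_id": m.intron_id,
                "gene_id": m.gene_id,
                "sample_id": m.sample_id,
                "compartment": m.compartment,
                "intronic_abundance": m.intronic_abundance,
                "spliced_abundance": m.spliced_abundance,
                "flank_support": m.flank_support,
                "intron_reads": m.intron_reads,
                "intron_length": m.intron_length,
                "ir_ratio": m.ir_ratio,
                "warnings": ";".join(sorted(m.warnings)),
                "clean": m.clean,
                "defined": m.defined,
            }
        )
    return pd.DataFrame(rows)


def events_to_frame(events: Iterable[DifferentialIREvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "intron_id": e.intron_id,
                "gene_id": e.gene_id,
                "condition_a": e.contrast[0],
                "condition_b": e.contrast[1],
                "intron_a": e.intron_a,
                "spliced_a": e.spliced_a,
                "intron_b": e.intron_b,
                "spliced_b": e.spliced_b,
                "ir_a": e.ir_a,
                "ir_b": e.ir_b,
                "delta_ir": e.delta_ir,
                "p_value": e.p_value,
                "q_value": e.q_value,
                "significant": e.significant,
            }
        )
    return pd.DataFrame(rows)


def frame_to_events(frame: pd.DataFrame) -> list[DifferentialIREvent]:
    events = []
    for row in frame.itertuples(index=False):
        events.append(
            DifferentialIREvent(
                intron_id=row.intron_id,
                gene_id=row.gene_id,
                contrast=(row.condition_a, row.condition_b),
                intron_a=int(row.intron_a),
                spliced_a=int(row.spliced_a),
                intron_b=int(row.intron_b),
                spliced_b=int(row.spliced_b),
                ir_a=float(row.ir_a),
                ir_b=float(row.ir_b),
                delta_ir=float(row.delta_ir),
                p_value=float(row.p_value),
                q_value=float(row.q_value),
                significant=bool(row.significant),
            )
        )
    return events
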