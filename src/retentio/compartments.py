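"""Nuclear versus cytoplasmic IR analysis.

Covers three questions: in which fraction are reliable retained introns
detected; per fraction, how does IR shift between conditions; and how
strongly are intron-retaining transcripts confined to the nucleus.
Confinement is quantified as delta-IR = cytoplasmic minus nuclear, so a
negative delta means nuclear enrichment; an intron is called nuclear
confined when the fraction contrast is significant with delta < 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ir_core import (
    DifferentialIREvent,
    DirectionSummary,
    IRMeasurement,
    differential_ir,
    summarize_directions,
)


@dataclass
class FractionSummary:
    n_whole: int
    n_nuclear: int  # reliable retained introns detected in the nuclear set
    n_cytoplasmic: int
    in_nuclear: int  # members of the whole-cell set seen in each fraction
    in_cytoplasmic: int
    in_both: int
    percent_nuclear: float
    percent_cytoplasmic: float
    percent_both: float


def fraction_summary(
    whole: set[str], nuclear: set[str], cytoplasmic: set[str]
) -> FractionSummary:
    """Detection overlap of reliable retained introns across fractions,
    with percentages relative to the whole-cell set."""
    if not whole:
        raise ValueError("whole-cell set is empty")
    in_nuc = whole & nuclear
    in_cyt = whole & cytoplasmic
    in_both = in_nuc & in_cyt
    n = len(whole)
    return FractionSummary(
        n_whole=n,
        n_nuclear=len(nuclear),
        n_cytoplasmic=len(cytoplasmic),
        in_nuclear=len(in_nuc),
        in_cytoplasmic=len(in_cyt),
        in_both=len(in_both),
        percent_nuclear=100.0 * len(in_nuc) / n,
        percent_cytoplasmic=100.0 * len(in_cyt) / n,
        percent_both=100.0 * len(in_both) / n,
    )


@dataclass
class ConfinementResult:
    events: list[DifferentialIREvent]  # delta = cytoplasmic - nuclear
    n_significant: int
    n_confined: int  # significant with delta < 0
    confined_fraction: float


def confinement_analysis(
    nuclear: Sequence[IRMeasurement],
    cytoplasmic: Sequence[IRMeasurement],
    condition: str = "",
    alpha: float = 0.05,
) -> ConfinementResult:
    """Per-intron Audic-Claverie contrast between fractions within one
    condition, pooling replicates per fraction."""
    label = f"{condition}:" if condition else ""
    events = differential_ir(
        cytoplasmic,
        nuclear,
        contrast=(f"{label}cytoplasmic", f"{label}nuclear"),
        alpha=alpha,
    )
    significant = [e for e in events if e.significant]
    confined = [e for e in significant if e.delta_ir < 0]
    fraction = len(confined) / len(significant) if significant else float("nan")
    return ConfinementResult(
        events=events,
        n_significant=len(significant),
        n_confined=len(confined),
        confined_fraction=fraction,
    )


def compare_confinement(
    result_a: ConfinementResult, result_b: ConfinementResult
) -> tuple[float, float]:
    """Rank-sum comparison of the confinement-delta distributions of two
    genotypes (e.g. mutant versus control)."""
    a = np.array([e.delta_ir for e in result_a.events])
    b = np.array([e.delta_ir for e in result_b.events])
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 events per genotype")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p)


@dataclass
class PerFractionDifferential:
    nuclear_events: list[DifferentialIREvent]
    cytoplasmic_events: list[DifferentialIREvent]
    nuclear_summary: DirectionSummary
    cytoplasmic_summary: DirectionSummary
    cross_fraction_statistic: float
    cross_fraction_p: float


def per_fraction_differential(
    nuclear_a: Sequence[IRMeasurement],
    nuclear_b: Sequence[IRMeasurement],
    cytoplasmic_a: Sequence[IRMeasurement],
    cytoplasmic_b: Sequence[IRMeasurement],
    contrast: tuple[str, str] = ("A", "B"),
    alpha: float = 0.05,
) -> PerFractionDifferential:
    """Condition contrast run separately in each fraction, plus a rank-sum
    comparison of the two significant delta-IR distributions."""
    nuclear_events = differential_ir(nuclear_a, nuclear_b, contrast, alpha)
    cyto_events = differential_ir(cytoplasmic_a, cytoplasmic_b, contrast, alpha)
    nuclear_summary = summarize_directions(nuclear_events, alpha)
    cyto_summary = summarize_directions(cyto_events, alpha)
    deltas_nuc = np.array(
        [e.delta_ir for e in nuclear_events if e.significant]
    )
    deltas_cyt = np.array([e.delta_ir for e in cyto_events if e.significant])
    stat, p = stats.mannwhitneyu(deltas_cyt, deltas_nuc, alternative="two-sided")
    return PerFractionDifferential(
        nuclear_events=nuclear_events,
        cytoplasmic_events=cyto_events,
        nuclear_summary=nuclear_summary,
        cytoplasmic_summary=cyto_summary,
        cross_fraction_statistic=float(stat),
        cross_fraction_p=float(p),
    )


def confinement_events_to_frame(result: ConfinementResult) -> pd.DataFrame:
    rows = []
    for e in result.events:
        rows.append(
            {
                "intron_id": e.intron_id,
                "gene_id": e.gene_id,
                "ir_cytoplasmic": e.ir_a,
                "ir_nuclear": e.ir_b,
                "confinement_delta": e.delta_ir,
                "p_value": e.p_value,
                "nuclear_confined": bool(e.significant and e.delta_ir < 0),
            }
        )
    return pd.DataFrame(rows)
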