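"""Sequence and track features of retained introns.

Covers GC content, length, mean conservation, RBP crosslink enrichment,
donor/acceptor splice-site strength and a rule-based nonsense-mediated
decay (NMD) prediction, plus rank-sum comparisons between intron sets
(e.g. IR-down versus IR-up events).

Splice-site strength is scored with a position-weight log-odds model over
the conventional windows: 9 bases for the donor (last 3 exonic + first 6
intronic) and 23 bases for the acceptor (last 20 intronic + first 3
exonic).  An externally supplied per-window score table can be dropped in
instead, preserving the same window contract.

NMD prediction applies the 50-nt rule: a transcript is a predicted NMD
substrate when, with the intron retained, translation terminates more than
50 nt upstream of the last exon-exon junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import CoverageTrack, GenomicInterval, Intron, Transcript

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DONOR_WINDOW = 9  # last 3 exonic + first 6 intronic bases
ACCEPTOR_WINDOW = 23  # last 20 intronic + first 3 exonic bases

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: minimum distance (nt) from stop codon to last junction that triggers NMD
NMD_MIN_DISTANCE = 50


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# simple per-intron features
# ---------------------------------------------------------------------------


def gc_content(sequence: str) -> float:
    """GC fraction over A/C/G/T; N bases are excluded from both numerator
    and denominator.  All-N (or empty informative) sequences return NaN."""
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in BASES}
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    return (counts["G"] + counts["C"]) / total


def mean_conservation(
    track: CoverageTrack, interval: GenomicInterval, min_cover: float = 0.5
) -> tuple[float, bool]:
    """Arithmetic mean conservation over the covered bases of the interval.

    Returns (mean, reliable); ``reliable`` is False when the track covers
    less than ``min_cover`` of the interval.  With no coverage at all the
    mean is NaN.
    """
    values, mask = track.depths_with_mask(interval)
    covered = int(mask.sum())
    if covered == 0:
        return float("nan"), False
    mean = float(values[mask].mean())
    return mean, covered >= min_cover * interval.length


def rbp_enrichment(
    crosslinks: pd.DataFrame,
    retained: Sequence[Intron],
    non_retained: Sequence[Intron],
    length_normalized: bool = True,
) -> pd.DataFrame:
    """Per-RBP crosslink enrichment of retained over non-retained introns.

    Enrichment is (events/kb in retained) / (events/kb in non-retained);
    with ``length_normalized=False`` the raw event-proportion ratio is used
    instead.  Callers should restrict both sets to introns of the same
    genes.  A zero denominator density yields NaN with ``defined=False``.
    """
    if not len(retained) or not len(non_retained):
        raise ValueError("both intron sets must be non-empty")

    def _assign(introns: Sequence[Intron]) -> tuple[pd.Series, float]:
        kb = sum(i.length for i in introns) / 1000.0
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for intron in introns:
            by_chrom.setdefault(intron.interval.chrom, []).append(
                (intron.interval.start, intron.interval.end)
            )
        hits = pd.Series(0, index=sorted(crosslinks["name"].unique()), dtype=int)
        for chrom, group in crosslinks.groupby("chrom"):
            spans = sorted(by_chrom.get(chrom, []))
            if not spans:
                continue
            starts = np.array([s for s, _ in spans])
            ends = np.array([e for _, e in spans])
            pos = group["start"].to_numpy()
            idx = np.searchsorted(starts, pos, side="right") - 1
            inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
            for rbp, count in group.loc[inside, "name"].value_counts().items():
                hits[rbp] += int(count)
        return hits, kb

    hits_ret, kb_ret = _assign(retained)
    hits_non, kb_non = _assign(non_retained)
    rows = []
    for rbp in hits_ret.index:
        if length_normalized:
            num = hits_ret[rbp] / kb_ret
            den = hits_non[rbp] / kb_non
        else:
            total = hits_ret[rbp] + hits_non[rbp]
            num = hits_ret[rbp] / total if total else 0.0
            den = hits_non[rbp] / total if total else 0.0
        defined = den > 0
        rows.append(
            {
                "rbp": rbp,
                "events_retained": int(hits_ret[rbp]),
                "events_non_retained": int(hits_non[rbp]),
                "enrichment": num / den if defined else float("nan"),
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# splice-site strength
# ---------------------------------------------------------------------------


@dataclass
class SpliceSiteModel:
    """Position-weight log-odds splice-site model.

    ``log2_fg`` is (window length x 4) per-position log2 probabilities of
    the trained site; ``log2_bg`` is the position-independent background
    log2 base frequencies.  Non-ACGT bases contribute 0 (scored with the
    background probability at that position).
    """

    kind: str  # "5ss" or "3ss"
    log2_fg: np.ndarray
    log2_bg: np.ndarray
    provenance: str = "trained-from-annotation"

    @property
    def window_length(self) -> int:
        return self.log2_fg.shape[0]

    def score(self, window: str) -> float:
        window = window.upper()
        if len(window) != self.window_length:
            raise ValueError(
                f"{self.kind} window must be {self.window_length} bases,"
                f" got {len(window)}"
            )
        total = 0.0
        for pos, base in enumerate(window):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                continue  # ambiguous base: foreground falls back to background
            total += self.log2_fg[pos, idx] - self.log2_bg[idx]
        return float(total)

    def max_score_window(self) -> str:
        return "".join(BASES[int(i)] for i in self.log2_fg.argmax(axis=1))


def _window_length_for(kind: str) -> int:
    if kind == "5ss":
        return DONOR_WINDOW
    if kind == "3ss":
        return ACCEPTOR_WINDOW
    raise ValueError("site kind must be '5ss' or '3ss'")


def train_splice_model(
    windows: Sequence[str],
    background_seqs: Sequence[str],
    kind: str,
    min_windows: int = 100,
) -> SpliceSiteModel:
    """Train a position-weight model from annotated junction windows.

    Foreground: per-position base frequencies with pseudocount 1.
    Background: position-independent base frequencies of the supplied
    background sequences (pseudocount 1).  Deterministic given inputs.
    """
    length = _window_length_for(kind)
    if len(windows) < min_windows:
        raise ValueError(f"need at least {min_windows} training windows")
    counts = np.ones((length, 4), dtype=float)  # pseudocount 1
    for window in windows:
        window = window.upper()
        if len(window) != length:
            raise ValueError(
                f"{kind} training window must be {length} bases, got {len(window)}"
            )
        for pos, base in enumerate(window):
            idx = _BASE_INDEX.get(base)
            if idx is not None:
                counts[pos, idx] += 1
    fg = counts / counts.sum(axis=1, keepdims=True)

    bg_counts = np.ones(4, dtype=float)
    for seq in background_seqs:
        seq = seq.upper()
        for base in BASES:
            bg_counts[_BASE_INDEX[base]] += seq.count(base)
    bg = bg_counts / bg_counts.sum()
    return SpliceSiteModel(kind=kind, log2_fg=np.log2(fg), log2_bg=np.log2(bg))


def splice_site_score(window: str, model: SpliceSiteModel) -> float:
    """log2-odds score of a window under a trained model (higher = stronger)."""
    return model.score(window)


def donor_window(intron: Intron, sequences: Mapping[str, str]) -> str:
    """Extract the 9-base donor window (last 3 exon + first 6 intron bases)
    in transcription orientation; minus-strand introns are reverse
    complemented from the plus-strand sequence."""
    chrom_seq = sequences[intron.interval.chrom]
    iv = intron.interval
    if iv.strand == "+":
        return chrom_seq[iv.start - 3 : iv.start + 6].upper()
    return reverse_complement(chrom_seq[iv.end - 6 : iv.end + 3]).upper()


def acceptor_window(intron: Intron, sequences: Mapping[str, str]) -> str:
    """Extract the 23-base acceptor window (last 20 intron + first 3 exon
    bases) in transcription orientation."""
    chrom_seq = sequences[intron.interval.chrom]
    iv = intron.interval
    if iv.strand == "+":
        return chrom_seq[iv.end - 20 : iv.end + 3].upper()
    return reverse_complement(chrom_seq[iv.start - 3 : iv.start + 20]).upper()


class ScoreTable:
    """Externally supplied per-window score table (e.g. published
    maximum-entropy parameters), mapping k-mer -> score."""

    def __init__(self, scores: Mapping[str, float], kind: str) -> None:
        self.kind = kind
        self.window_length = _window_length_for(kind)
        self.scores = {k.upper(): float(v) for k, v in scores.items()}
        self.provenance = "loaded-from-table"

    @classmethod
    def read(cls, path: str | Path, kind: str) -> "ScoreTable":
        table = pd.read_csv(path, sep="\t", header=None, names=["window", "score"])
        return cls(dict(zip(table["window"], table["score"])), kind)

    def score(self, window: str) -> float:
        window = window.upper()
        if len(window) != self.window_length:
            raise ValueError(f"window must be {self.window_length} bases")
        if window not in self.scores:
            raise KeyError(f"window {window} absent from score table")
        return self.scores[window]


# ---------------------------------------------------------------------------
# NMD prediction (50-nt rule)
# ---------------------------------------------------------------------------


@dataclass
class NMDCall:
    nmd_predicted: bool
    stop_position: int | None  # transcript coordinate of stop-codon end
    last_junction: int | None  # transcript coordinate of the last junction
    distance: int | None  # last_junction - stop end; > 50 triggers NMD
    defined: bool = True
    reason: str = ""


def _retained_blocks(
    exons: Sequence[GenomicInterval], intron: GenomicInterval
) -> list[GenomicInterval]:
    """Exon blocks of the intron-retained transcript: the two exons flanking
    the retained intron fuse into one contiguous block."""
    exons = sorted(exons, key=lambda e: e.start)
    blocks: list[GenomicInterval] = []
    i = 0
    while i < len(exons):
        exon = exons[i]
        if (
            i + 1 < len(exons)
            and exon.end == intron.start
            and exons[i + 1].start == intron.end
        ):
            blocks.append(
                GenomicInterval(exon.chrom, exon.start, exons[i + 1].end, exon.strand)
            )
            i += 2
        else:
            blocks.append(exon)
            i += 1
    return blocks


def _longest_orf_start(seq: str) -> int | None:
    best_start, best_len = None, -1
    for frame_start in range(len(seq) - 2):
        if seq[frame_start : frame_start + 3] != "ATG":
            continue
        length = 0
        for pos in range(frame_start, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            length += 3
            if codon in STOP_CODONS:
                break
        if length > best_len:
            best_start, best_len = frame_start, length
    return best_start


def predict_nmd(
    transcript: Transcript,
    retained_intron: Intron,
    sequences: Mapping[str, str],
    start_offset: int | None = None,
    min_distance: int = NMD_MIN_DISTANCE,
) -> NMDCall:
    """Apply the 50-nt rule to the intron-retained form of a transcript.

    The transcript sequence is rebuilt with the intron retained and
    translated from ``start_offset`` (transcript coordinate of the ATG) or,
    when absent, from the longest open reading frame.  The call is positive
    iff a stop codon ends more than ``min_distance`` nt upstream of the last
    exon-exon junction of the retained transcript; retention of the final
    intron therefore can never trigger NMD through its own stop codons.
    """
    intron_iv = retained_intron.interval
    blocks = _retained_blocks(transcript.exons, intron_iv)
    chrom_seq = sequences[intron_iv.chrom]
    plus_seq = "".join(chrom_seq[b.start : b.end] for b in blocks).upper()
    total = len(plus_seq)

    # exon-exon junction positions of the retained transcript, 5'->3'
    boundaries = np.cumsum([b.length for b in blocks])[:-1]
    if transcript.exons[0].strand == "-":
        seq = reverse_complement(plus_seq)
        junctions = sorted(int(total - b) for b in boundaries)
    else:
        seq = plus_seq
        junctions = sorted(int(b) for b in boundaries)

    if not junctions:
        return NMDCall(False, None, None, None, defined=True, reason="no junctions")

    start = start_offset if start_offset is not None else _longest_orf_start(seq)
    if start is None:
        return NMDCall(False, None, None, None, defined=False, reason="no ORF")

    stop_end: int | None = None
    for pos in range(start, len(seq) - 2, 3):
        if seq[pos : pos + 3] in STOP_CODONS:
            stop_end = pos + 3
            break
    if stop_end is None:
        return NMDCall(
            False, None, junctions[-1], None, defined=True, reason="no stop codon"
        )
    last_junction = junctions[-1]
    distance = last_junction - stop_end
    return NMDCall(
        nmd_predicted=distance > min_distance,
        stop_position=stop_end,
        last_junction=last_junction,
        distance=distance,
    )


# ---------------------------------------------------------------------------
# feature table + group comparison
# ---------------------------------------------------------------------------


@dataclass
class IntronFeatureRecord:
    intron_id: str
    length: int
    gc_fraction: float
    mean_conservation: float = float("nan")
    five_ss_score: float = float("nan")
    three_ss_score: float = float("nan")
    crosslink_density: float = float("nan")  # events/kb summed over RBPs
    nmd_predicted: bool = False


DEFAULT_FEATURES = (
    "length",
    "gc_fraction",
    "mean_conservation",
    "crosslink_density",
    "five_ss_score",
    "three_ss_score",
)


def compare_ir_sets(
    features_down: pd.DataFrame,
    features_up: pd.DataFrame,
    feature_columns: Sequence[str] = DEFAULT_FEATURES,
) -> pd.DataFrame:
    """Two-sided rank-sum test per feature between IR-down and IR-up intron
    sets, BH-adjusted across the feature family."""
    from statsmodels.stats.multitest import multipletests

    if len(features_down) < 3 or len(features_up) < 3:
        raise ValueError("both groups need at least 3 introns")
    rows = []
    for feature in feature_columns:
        a = features_down[feature].dropna().to_numpy()
        b = features_up[feature].dropna().to_numpy()
        if a.size < 3 or b.size < 3 or np.unique(np.concatenate([a, b])).size == 1:
            stat, p = float("nan"), 1.0
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "feature": feature,
                "n_down": int(a.size),
                "n_up": int(b.size),
                "statistic": float(stat),
                "p_value": float(p),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table
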