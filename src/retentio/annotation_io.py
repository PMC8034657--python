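"""Gene annotation I/O and measurable-intron derivation.

All in-memory coordinates are 0-based half-open.  GTF/GFF3 files, which are
1-based inclusive on disk, are converted at the I/O boundary and converted
back on write, so a read/write round trip is the identity on valid files.

Coverage inputs are assumed to be pre-filtered upstream (e.g. multi-mapping
reads already excluded by the aligner); this module does not re-implement
alignment-level filters.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

STRANDS = ("+", "-")

#: compartment labels accepted throughout the package
COMPARTMENTS = ("whole", "nuclear", "cytoplasmic")


class AnnotationError(ValueError):
    """Raised when an annotation file is malformed or violates invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise AnnotationError(f"negative start {self.start} on {self.chrom}")
        if self.strand not in STRANDS:
            raise AnnotationError(f"strand must be one of {STRANDS}: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Transcript:
    transcript_id: str
    exons: list[GenomicInterval]
    biotype: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )

    @property
    def span(self) -> GenomicInterval:
        first, last = self.exons[0], self.exons[-1]
        return GenomicInterval(first.chrom, first.start, last.end, first.strand)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)


@dataclass
class Intron:
    """An inter-exon gap with the sub-region in which IR can be measured.

    ``measurable_region`` is the gap minus the union of every annotated exon
    of any transcript overlapping it, so that exonic signal from alternative
    isoforms never contributes to intronic depth.  Identity is
    (gene_id, start, end, strand): identical gaps shared by several
    transcripts collapse to one intron.
    """

    intron_id: str
    interval: GenomicInterval
    gene_id: str
    five_prime_exon: GenomicInterval
    three_prime_exon: GenomicInterval
    measurable_region: list[GenomicInterval] = field(default_factory=list)

    @property
    def usable(self) -> bool:
        return len(self.measurable_region) > 0

    @property
    def measurable_length(self) -> int:
        return sum(iv.length for iv in self.measurable_region)

    @property
    def length(self) -> int:
        return self.interval.length


def intron_id_for(gene_id: str, interval: GenomicInterval) -> str:
    return f"{gene_id}:{interval.chrom}:{interval.start}-{interval.end}:{interval.strand}"


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------


def _attr_first(attrs: Mapping[str, Sequence[str]], *keys: str) -> str | None:
    for key in keys:
        if key in attrs:
            return attrs[key][0]
    return None


def _strip_prefix(value: str | None) -> str | None:
    if value is None:
        return None
    for prefix in ("transcript:", "gene:"):
        if value.startswith(prefix):
            return value[len(prefix):]
    return value


def load_annotation(path: str | Path) -> dict[str, GeneModel]:
    """Parse a GTF or GFF3 file into gene models keyed by gene_id.

    Disk coordinates (1-based inclusive) are converted to 0-based half-open.
    The Ensembl-style attributes ``gene_id``, ``transcript_id`` and
    ``transcript_biotype``/``biotype`` are honoured; GFF3 ``Parent`` chains
    are followed where GTF-style attributes are absent.
    """
    path = Path(path)
    try:
        import contextlib
        import warnings as _warnings

        # gffutils emits progress on stderr unconditionally; keep quiet
        with _warnings.catch_warnings(), contextlib.redirect_stderr(io.StringIO()):
            _warnings.simplefilter("ignore")
            db = gffutils.create_db(
                str(path),
                dbfn=":memory:",
                force=True,
                keep_order=True,
                merge_strategy="create_unique",
                verbose=False,
            )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise AnnotationError(f"failed to parse {path.name}: {exc}") from exc

    # transcript-level metadata (biotype, parent gene)
    tx_meta: dict[str, tuple[str | None, str | None]] = {}
    for kind in ("transcript", "mRNA"):
        for feat in db.features_of_type(kind):
            tid = _strip_prefix(
                _attr_first(feat.attributes, "transcript_id", "ID")
            )
            gid = _strip_prefix(_attr_first(feat.attributes, "gene_id", "Parent"))
            biotype = _attr_first(
                feat.attributes, "transcript_biotype", "biotype"
            )
            if tid is not None:
                tx_meta[tid] = (gid, biotype)

    gene_spans: dict[str, GenomicInterval] = {}
    for feat in db.features_of_type("gene"):
        gid = _strip_prefix(_attr_first(feat.attributes, "gene_id", "ID"))
        if gid is None:
            continue
        if feat.end < feat.start:
            raise AnnotationError(f"gene {gid}: end < start on line for {path.name}")
        gene_spans[gid] = GenomicInterval(
            feat.seqid, feat.start - 1, feat.end, feat.strand
        )

    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    for feat in db.features_of_type("exon"):
        tid = _strip_prefix(_attr_first(feat.attributes, "transcript_id", "Parent"))
        if tid is None:
            raise AnnotationError(
                f"exon without transcript_id/Parent at {feat.seqid}:{feat.start}"
            )
        gid = _strip_prefix(_attr_first(feat.attributes, "gene_id"))
        if gid is None:
            gid = tx_meta.get(tid, (None, None))[0]
        if gid is None:
            raise AnnotationError(f"cannot resolve gene for transcript {tid}")
        if feat.end < feat.start:
            raise AnnotationError(
                f"exon end < start at {feat.seqid}:{feat.start}-{feat.end}"
            )
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        span = gene_spans.get(gid)
        if span is not None and not span.contains(iv):
            raise AnnotationError(
                f"exon {iv.chrom}:{iv.start}-{iv.end} outside declared span of {gid}"
            )
        exons_by_tx.setdefault(tid, []).append(iv)
        tx_gene[tid] = gid

    genes: dict[str, GeneModel] = {}
    for tid, exons in exons_by_tx.items():
        gid = tx_gene[tid]
        biotype = tx_meta.get(tid, (None, None))[1]
        if gid not in genes:
            genes[gid] = GeneModel(gid, exons[0].chrom, exons[0].strand)
        genes[gid].transcripts.append(Transcript(tid, exons, biotype))
    if not genes:
        raise AnnotationError(f"no exon records found in {path.name}")
    return genes


def write_gtf(genes: Mapping[str, GeneModel], path: str | Path) -> None:
    """Write gene models as Ensembl-dialect GTF (1-based inclusive)."""
    lines: list[str] = []
    for gene in genes.values():
        span = gene.span
        lines.append(
            "\t".join(
                [
                    gene.chrom,
                    "retentio",
                    "gene",
                    str(span.start + 1),
                    str(span.end),
                    ".",
                    gene.strand,
                    ".",
                    f'gene_id "{gene.gene_id}";',
                ]
            )
        )
        for tx in gene.transcripts:
            tspan = tx.span
            attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
            if tx.biotype:
                attrs += f' transcript_biotype "{tx.biotype}";'
            lines.append(
                "\t".join(
                    [
                        gene.chrom,
                        "retentio",
                        "transcript",
                        str(tspan.start + 1),
                        str(tspan.end),
                        ".",
                        gene.strand,
                        ".",
                        attrs,
                    ]
                )
            )
            for exon in tx.exons:
                lines.append(
                    "\t".join(
                        [
                            gene.chrom,
                            "retentio",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            gene.strand,
                            ".",
                            attrs,
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# interval arithmetic + intron derivation
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def subtract_intervals(
    start: int, end: int, blockers: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Subtract merged blocker intervals from [start, end)."""
    pieces: list[tuple[int, int]] = []
    cursor = start
    for b_start, b_end in merge_intervals(blockers):
        if b_end <= cursor or b_start >= end:
            continue
        if b_start > cursor:
            pieces.append((cursor, b_start))
        cursor = max(cursor, b_end)
    if cursor < end:
        pieces.append((cursor, end))
    return pieces


def derive_introns(genes: Mapping[str, GeneModel]) -> dict[str, Intron]:
    """Derive one intron per unique (gene, inter-exon gap) across transcripts.

    The measurable region of each intron is the gap minus the union of all
    annotated exons (from any gene or transcript) overlapping it.  Introns
    whose measurable region is empty are still returned but flagged unusable.
    Deterministic and independent of transcript input order.
    """
    # global exon catalogue per chromosome for the exclusion mask
    exons_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for gene in genes.values():
        for tx in gene.transcripts:
            for exon in tx.exons:
                exons_by_chrom.setdefault(exon.chrom, []).append(
                    (exon.start, exon.end)
                )
    merged = {chrom: merge_intervals(ivs) for chrom, ivs in exons_by_chrom.items()}
    merged_arrays = {
        chrom: (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
        for chrom, ivs in merged.items()
    }

    introns: dict[str, Intron] = {}
    for gene_id in sorted(genes):
        gene = genes[gene_id]
        for tx in sorted(gene.transcripts, key=lambda t: t.transcript_id):
            for left, right in zip(tx.exons, tx.exons[1:]):
                if right.start <= left.end:
                    continue
                iv = GenomicInterval(gene.chrom, left.end, right.start, gene.strand)
                iid = intron_id_for(gene_id, iv)
                if iid in introns:
                    continue
                if gene.strand == "+":
                    five, three = left, right
                else:
                    five, three = right, left
                starts, ends = merged_arrays.get(gene.chrom, (np.array([]), np.array([])))
                lo = int(np.searchsorted(ends, iv.start, side="right"))
                hi = int(np.searchsorted(starts, iv.end, side="left"))
                blockers = [(int(starts[i]), int(ends[i])) for i in range(lo, hi)]
                region = [
                    GenomicInterval(gene.chrom, s, e, gene.strand)
                    for s, e in subtract_intervals(iv.start, iv.end, blockers)
                ]
                introns[iid] = Intron(
                    intron_id=iid,
                    interval=iv,
                    gene_id=gene_id,
                    five_prime_exon=five,
                    three_prime_exon=three,
                    measurable_region=region,
                )
    return introns


# ---------------------------------------------------------------------------
# coverage tracks
# ---------------------------------------------------------------------------


class CoverageTrack:
    """Per-base depth values stored as sorted non-overlapping runs per chrom.

    The declared universe is the union of the stored runs; positions outside
    any run are undefined (reported as depth 0 with a False mask).
    """

    def __init__(self, sample_id: str = "sample", compartment: str = "whole") -> None:
        if compartment not in COMPARTMENTS:
            raise ValueError(f"compartment must be one of {COMPARTMENTS}")
        self.sample_id = sample_id
        self.compartment = compartment
        self._runs: dict[str, list[tuple[int, int, float]]] = {}
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    def add_run(self, chrom: str, start: int, end: int, value: float) -> None:
        if value < 0:
            raise ValueError(f"negative depth {value} at {chrom}:{start}")
        if end <= start:
            raise ValueError(f"empty run at {chrom}:{start}-{end}")
        self._runs.setdefault(chrom, []).append((int(start), int(end), float(value)))
        self._arrays = None

    def add_values(self, chrom: str, start: int, values: Sequence[float]) -> None:
        """Add per-base values starting at ``start`` (run-length encoded)."""
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            return
        if np.any(values < 0):
            raise ValueError("negative depth values")
        change = np.flatnonzero(np.diff(values)) + 1
        boundaries = np.concatenate([[0], change, [values.size]])
        for lo, hi in zip(boundaries[:-1], boundaries[1:]):
            self.add_run(chrom, start + int(lo), start + int(hi), float(values[lo]))

    def _ensure_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        if self._arrays is None:
            arrays = {}
            for chrom, runs in self._runs.items():
                runs = sorted(runs)
                starts = np.array([r[0] for r in runs])
                ends = np.array([r[1] for r in runs])
                vals = np.array([r[2] for r in runs])
                if np.any(starts[1:] < ends[:-1]):
                    raise ValueError(f"overlapping coverage runs on {chrom}")
                arrays[chrom] = (starts, ends, vals)
            self._arrays = arrays
        return self._arrays

    def depths(self, interval: GenomicInterval) -> np.ndarray:
        """Per-base depth over the interval (0 where undefined)."""
        return self.depths_with_mask(interval)[0]

    def depths_with_mask(
        self, interval: GenomicInterval
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-base (depth, defined) arrays over the interval."""
        arrays = self._ensure_arrays()
        out = np.zeros(interval.length, dtype=float)
        mask = np.zeros(interval.length, dtype=bool)
        if interval.chrom not in arrays:
            return out, mask
        starts, ends, vals = arrays[interval.chrom]
        lo = int(np.searchsorted(ends, interval.start, side="right"))
        hi = int(np.searchsorted(starts, interval.end, side="left"))
        for i in range(lo, hi):
            a = max(int(starts[i]), interval.start) - interval.start
            b = min(int(ends[i]), interval.end) - interval.start
            out[a:b] = vals[i]
            mask[a:b] = True
        return out, mask

    @classmethod
    def read_bedgraph(
        cls, path: str | Path, sample_id: str | None = None, compartment: str = "whole"
    ) -> "CoverageTrack":
        path = Path(path)
        track = cls(sample_id or path.stem, compartment)
        table = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        if (table["value"] < 0).any():
            raise ValueError(f"negative depth in {path.name}")
        for row in table.itertuples(index=False):
            track.add_run(row.chrom, int(row.start), int(row.end), float(row.value))
        return track

    def write_bedgraph(self, path: str | Path) -> None:
        arrays = self._ensure_arrays()
        with open(path, "w") as handle:
            for chrom in sorted(arrays):
                starts, ends, vals = arrays[chrom]
                for s, e, v in zip(starts, ends, vals):
                    v = float(v)
                    rendered = f"{int(v)}" if v == int(v) else f"{v:.6g}"
                    handle.write(f"{chrom}\t{int(s)}\t{int(e)}\t{rendered}\n")


def read_coverage(
    path: str | Path, sample_id: str | None = None, compartment: str = "whole"
) -> CoverageTrack:
    return CoverageTrack.read_bedgraph(path, sample_id, compartment)


# ---------------------------------------------------------------------------
# junction counts
# ---------------------------------------------------------------------------

JUNCTION_COLUMNS = ["intron_id", "spliced", "five_prime", "three_prime"]


class JunctionCounts:
    """Per-intron junction-spanning read counts for one sample."""

    def __init__(self, table: pd.DataFrame, sample_id: str = "sample") -> None:
        missing = [c for c in JUNCTION_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"junction table missing columns {missing}")
        counts = table[JUNCTION_COLUMNS[1:]]
        if (counts.to_numpy() < 0).any():
            raise ValueError("junction counts must be non-negative")
        if not np.allclose(counts.to_numpy(), counts.to_numpy().astype(int)):
            raise ValueError("junction counts must be integers")
        self.table = table.set_index("intron_id").astype(
            {c: int for c in JUNCTION_COLUMNS[1:]}
        )
        self.sample_id = sample_id

    def get(self, intron_id: str) -> tuple[int, int, int]:
        """Return (spliced, five_prime, three_prime) counts; zeros if absent."""
        if intron_id not in self.table.index:
            return 0, 0, 0
        row = self.table.loc[intron_id]
        return int(row["spliced"]), int(row["five_prime"]), int(row["three_prime"])

    def __len__(self) -> int:
        return len(self.table)


def read_junctions(path: str | Path, sample_id: str | None = None) -> JunctionCounts:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    return JunctionCounts(table, sample_id or path.stem)


def write_junctions(junctions: JunctionCounts, path: str | Path) -> None:
    junctions.table.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic tables, FASTA, BED, GMT
# ---------------------------------------------------------------------------


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV so that ``read_table(write_table(x)) == x``."""
    records.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name in sequences:
            handle.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 file (e.g. crosslink events; ``name`` carries the RBP)."""
    table = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=BED6_COLUMNS,
        dtype={"chrom": str, "name": str},
    )
    if (table["end"] <= table["start"]).any():
        raise ValueError("BED intervals must satisfy end > start")
    return table


def write_bed(table: pd.DataFrame, path: str | Path) -> None:
    table[BED6_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name, description, members...."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, members in sets.items():
            handle.write("\t".join([name, name] + sorted(members)) + "\n")
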