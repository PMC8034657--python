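"""Ground-truthed synthetic datasets for the IR analysis pipeline.

The generator emits a toy genome (one contig per gene), Ensembl-dialect
annotation, per-base intron coverage, junction counts, a gene-level count
matrix and optional conservation/crosslink tracks, together with a truth
table mapping every simulated object to its generative parameters.

Statistical structure:

* Each intron carries a true retention level theta per condition (and per
  compartment when fractionation is enabled).  Retained-class introns draw
  theta from Beta(4, 6); non-retained from Beta(1, 40).
* Counts are gamma-Poisson (negative binomial; Poisson at dispersion 0).
  The gamma expression multiplier is shared between the intronic and
  spliced signal of a gene within one sample, so the IR *ratio* stays
  calibrated while totals are overdispersed.
* Spliced junction counts ~ NB(mean d*g*(1-theta)); intron per-base depth
  ~ Poisson(e*theta) given the multiplier e, so the IR ratio converges to
  theta with depth.  Flank junction counts emulate spliced support at each
  flanking junction (mean e*(1-theta) per side).
* A configurable fraction of genes carries coupled effects (delta-theta < 0
  with log2FC > 0), or alternatively a bivariate-normal mode targets a
  stated correlation between true delta-theta and log2FC.
* Compartments: nuclear retention odds are scaled up and cytoplasmic odds
  down relative to whole-cell theta, so nuclear theta >= cytoplasmic theta.
  The cytoplasmic PTC decay factor models mutant-enhanced NMD: in the
  mutant cytoplasm the retention odds of PTC-bearing introns are divided
  by the factor.
* Sequences are built codon-wise in phase 0 (exon and intron lengths are
  multiples of 3) with GT...AG intron boundaries; PTC-bearing introns carry
  an in-frame TAA, PTC-free introns contain no in-frame stop, and exonic
  frames are open from the ATG at transcript position 0 to a terminal TAA.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation_io import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Intron,
    JunctionCounts,
    Transcript,
    derive_introns,
    write_bed,
    write_fasta,
    write_gtf,
    write_junctions,
    write_table,
)

STOP_CODONS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """All generative parameters; defaults are the package's reference
    two-condition bulk RNA-seq study conditions (see docs/methods.md)."""

    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (3, 5)
    intron_length_log_mu: float = 5.4  # lognormal, median ~220 nt
    intron_length_log_sigma: float = 0.5
    intron_length_bounds: tuple[int, int] = (90, 3000)
    exon_length_bounds: tuple[int, int] = (90, 180)
    gc_retained: float = 0.55
    gc_background: float = 0.45
    gc_exon: float = 0.50

    conditions: tuple[str, str] = ("MUT", "CTRL")  # (treatment, reference)
    replicates: int = 3
    compartments: bool = False
    simulate_whole: bool = True  # set False for fractionation-only designs

    depth: float = 100.0  # expected junction-spanning reads at g = 1
    gene_expression_log_sigma: float = 0.5
    dispersion: float = 0.05  # NB dispersion; 0 = Poisson
    read_length: int = 100

    retained_fraction: float = 0.5
    theta_retained: tuple[float, float] = (4.0, 6.0)  # Beta(a, b)
    theta_background: tuple[float, float] = (1.0, 40.0)
    # fixed retention grid for parameter-recovery experiments; «None» draws
    # from the Beta priors above instead
    theta_values: tuple[float, ...] | None = None

    affected_fraction: float = 0.3  # of retained introns, differential in MUT
    delta_theta: float = -0.25
    # alternative effect scale: multiplicative on retention odds (symmetric
    # across compartments); overrides delta_theta when set
    delta_odds_ratio: float | None = None
    decreased_share: float = 0.8  # sign split among affected introns
    coupled_fraction: float = 0.15  # genes with delta-theta < 0 and LFC > 0
    coupled_log2fc: float = 1.5
    lfc_noise_sd: float = 0.2

    # bivariate mode: when set, (delta-theta, log2FC) are drawn jointly with
    # this correlation and the affected/coupled logic above is bypassed
    target_ir_lfc_correlation: float | None = None
    delta_theta_sd: float = 0.08
    lfc_sd: float = 0.5

    ptc_probability: float = 0.3
    cytoplasmic_ptc_decay: float = 1.0  # mutant-cytoplasm NMD enhancement
    nuclear_odds_factor: float = 3.0
    cytoplasmic_odds_factor: float = 0.3

    spike_fraction: float = 0.0  # positional coverage spikes (outlier test)
    spike_multiplier: float = 1000.0

    crosslink_base_rate: float = 0.02  # events per base, non-retained class
    crosslink_enrichment: float = 3.0
    rbps: tuple[str, ...] = ("RBP1", "RBP2")
    conservation_retained: float = 0.6
    conservation_background: float = 0.4
    conservation_noise_sd: float = 0.02

    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.cytoplasmic_ptc_decay < 1:
            raise ValueError("cytoplasmic_ptc_decay must be >= 1")
        for gc in (self.gc_retained, self.gc_background, self.gc_exon):
            if not 0.05 <= gc <= 0.95:
                raise ValueError(f"infeasible GC target {gc}")
        for p in (
            self.retained_fraction,
            self.affected_fraction,
            self.ptc_probability,
            self.coupled_fraction,
            self.decreased_share,
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of range: {p}")
        lo, hi = self.intron_length_bounds
        if lo < 30 or hi < lo:
            raise ValueError("infeasible intron length bounds")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, value in out.items():
            if isinstance(value, tuple):
                out[key] = list(value)
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        kwargs = dict(data)
        for key, value in kwargs.items():
            default = getattr(cls, key, None)
            if isinstance(value, list):
                kwargs[key] = tuple(value)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------


def _sample_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.array(list("ACGT")), size=n, p=probs)


def _sample_codons(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    """Sample n codons at the GC target, rejecting stop codons."""
    codons: list[str] = []
    while len(codons) < n:
        batch = _sample_bases(rng, 3 * (n - len(codons) + 4), gc)
        for i in range(0, len(batch) - 2, 3):
            codon = "".join(batch[i : i + 3])
            if codon not in STOP_CODONS:
                codons.append(codon)
                if len(codons) == n:
                    break
    return codons


def _intron_sequence(
    rng: np.random.Generator, length: int, gc: float, ptc: bool
) -> str:
    """Intron sequence: GT...AG ends, phase-0 codons free of in-frame stops,
    with an in-frame TAA near the middle when ptc is set."""
    assert length % 3 == 0 and length >= 12
    n_codons = length // 3
    first = "GT" + str(_sample_bases(rng, 1, gc)[0])
    last = str(rng.choice(["C", "G"] if rng.random() < gc else ["A"])) + "AG"
    middle = _sample_codons(rng, n_codons - 2, gc)
    if ptc:
        middle[len(middle) // 2] = "TAA"
    return first + "".join(middle) + last


# ---------------------------------------------------------------------------
# annotation simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedAnnotation:
    genes: dict[str, GeneModel]
    sequences: dict[str, str]
    introns: dict[str, Intron]
    truth_introns: pd.DataFrame  # structural truth (class, ptc, gc target)
    truth_genes: pd.DataFrame
    config: SimulationConfig


def simulate_annotation(config: SimulationConfig) -> SimulatedAnnotation:
    """Build the toy genome and annotation.  Deterministic under the seed:
    the same config yields byte-identical FASTA and GTF."""
    rng = np.random.default_rng([config.seed, 1])
    genes: dict[str, GeneModel] = {}
    sequences: dict[str, str] = {}
    intron_rows = []
    gene_rows = []

    for g in range(config.n_genes):
        gene_id = f"G{g:04d}"
        chrom = gene_id
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lengths = [
            3 * int(rng.integers(config.exon_length_bounds[0] // 3,
                                 config.exon_length_bounds[1] // 3 + 1))
            for _ in range(n_exons)
        ]
        lo, hi = config.intron_length_bounds
        intron_lengths = []
        for _ in range(n_exons - 1):
            raw = rng.lognormal(config.intron_length_log_mu, config.intron_length_log_sigma)
            intron_lengths.append(3 * int(np.clip(raw, lo, hi) // 3))

        retained_class = rng.random(n_exons - 1) < config.retained_fraction
        ptc_flags = rng.random(n_exons - 1) < config.ptc_probability
        ptc_flags[-1:] = False  # a PTC in the final intron cannot trigger NMD

        # assemble sequence left to right; transcription on + strand
        start = 200
        cursor = start
        parts: list[str] = ["N" * start]
        exon_ivs: list[GenomicInterval] = []
        intron_meta: list[tuple[GenomicInterval, bool, bool, float]] = []
        for i, exon_len in enumerate(exon_lengths):
            codons = _sample_codons(rng, exon_len // 3, config.gc_exon)
            if i == 0:
                codons[0] = "ATG"
            if i == n_exons - 1:
                codons[-1] = "TAA"
            parts.append("".join(codons))
            exon_ivs.append(GenomicInterval(chrom, cursor, cursor + exon_len, "+"))
            cursor += exon_len
            if i < n_exons - 1:
                gc = config.gc_retained if retained_class[i] else config.gc_background
                seq = _intron_sequence(rng, intron_lengths[i], gc, bool(ptc_flags[i]))
                parts.append(seq)
                intron_meta.append(
                    (
                        GenomicInterval(chrom, cursor, cursor + intron_lengths[i], "+"),
                        bool(retained_class[i]),
                        bool(ptc_flags[i]),
                        gc,
                    )
                )
                cursor += intron_lengths[i]
        parts.append("N" * 50)
        sequences[chrom] = "".join(parts)
        tx = Transcript(f"{gene_id}.t1", exon_ivs, biotype="protein_coding")
        genes[gene_id] = GeneModel(gene_id, chrom, "+", [tx])

        expression = float(rng.lognormal(0.0, config.gene_expression_log_sigma))
        gene_rows.append({"gene_id": gene_id, "expression": expression})
        for iv, retained, ptc, gc in intron_meta:
            intron_rows.append(
                {
                    "intron_id": f"{gene_id}:{chrom}:{iv.start}-{iv.end}:+",
                    "gene_id": gene_id,
                    "length": iv.length,
                    "retained_class": retained,
                    "ptc": ptc,
                    "gc_target": gc,
                }
            )

    introns = derive_introns(genes)
    return SimulatedAnnotation(
        genes=genes,
        sequences=sequences,
        introns=introns,
        truth_introns=pd.DataFrame(intron_rows),
        truth_genes=pd.DataFrame(gene_rows),
        config=config,
    )


# ---------------------------------------------------------------------------
# retention truth (theta per condition x compartment) and effects
# ---------------------------------------------------------------------------

_THETA_LO, _THETA_HI = 0.005, 0.95


def _odds(theta: np.ndarray) -> np.ndarray:
    return theta / (1.0 - theta)


def _from_odds(odds: np.ndarray) -> np.ndarray:
    return odds / (1.0 + odds)


def _draw_effects(
    annotation: SimulatedAnnotation, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign per-intron theta per condition and per-gene true log2FC."""
    config = annotation.config
    introns = annotation.truth_introns.copy()
    genes = annotation.truth_genes.copy()
    treatment, reference = config.conditions

    a_r, b_r = config.theta_retained
    a_b, b_b = config.theta_background
    n = len(introns)
    if config.theta_values is not None:
        theta_ref = np.resize(np.asarray(config.theta_values, dtype=float), n)
    else:
        theta_ref = np.where(
            introns["retained_class"],
            rng.beta(a_r, b_r, size=n),
            rng.beta(a_b, b_b, size=n),
        )
    theta_ref = np.clip(theta_ref, _THETA_LO, _THETA_HI)

    if config.target_ir_lfc_correlation is not None:
        rho = config.target_ir_lfc_correlation
        z = rng.standard_normal((len(genes), 2))
        # orthogonalize so the realized ensemble correlation equals the
        # configured target exactly, not just in expectation
        z1 = (z[:, 0] - z[:, 0].mean()) / z[:, 0].std()
        resid = z[:, 1] - np.dot(z[:, 1], z1) / np.dot(z1, z1) * z1
        resid = (resid - resid.mean()) / resid.std()
        z2 = rho * z1 + np.sqrt(1.0 - rho**2) * resid
        gene_delta = dict(zip(genes["gene_id"], config.delta_theta_sd * z1))
        genes["true_log2fc"] = config.lfc_sd * z2
        genes["coupled"] = False
        delta = introns["gene_id"].map(gene_delta).to_numpy()
    else:
        retained_idx = introns.index[introns["retained_class"]].to_numpy()
        affected = rng.random(retained_idx.size) < config.affected_fraction
        signs = np.where(
            rng.random(retained_idx.size) < config.decreased_share, -1.0, 1.0
        )
        delta = np.zeros(n)
        if config.delta_odds_ratio is not None:
            odds = _odds(theta_ref)
            factor = np.ones(n)
            factor[retained_idx[affected]] = config.delta_odds_ratio ** signs[affected]
            delta = _from_odds(odds * factor) - theta_ref
        else:
            delta[retained_idx[affected]] = (
                np.abs(config.delta_theta) * signs[affected]
            )

        genes_with_retained = introns.loc[introns["retained_class"], "gene_id"].unique()
        n_coupled = int(round(config.coupled_fraction * genes_with_retained.size))
        coupled = set(
            rng.choice(genes_with_retained, size=n_coupled, replace=False)
            if n_coupled
            else []
        )
        genes["coupled"] = genes["gene_id"].isin(coupled)
        genes["true_log2fc"] = np.where(
            genes["coupled"],
            config.coupled_log2fc,
            rng.normal(0.0, config.lfc_noise_sd, size=len(genes)),
        )
        coupled_introns = introns["gene_id"].isin(coupled) & introns["retained_class"]
        delta[coupled_introns.to_numpy()] = -abs(config.delta_theta)

    theta_trt = np.clip(theta_ref + delta, _THETA_LO, _THETA_HI)
    introns[f"theta_{reference}"] = theta_ref
    introns[f"theta_{treatment}"] = theta_trt
    introns["delta_theta"] = theta_trt - theta_ref

    if config.compartments:
        for cond, theta in ((reference, theta_ref), (treatment, theta_trt)):
            odds = _odds(theta)
            nuc = _from_odds(odds * config.nuclear_odds_factor)
            cyt_odds = odds * config.cytoplasmic_odds_factor
            if cond == treatment and config.cytoplasmic_ptc_decay > 1:
                ptc = introns["ptc"].to_numpy()
                cyt_odds = np.where(
                    ptc, cyt_odds / config.cytoplasmic_ptc_decay, cyt_odds
                )
            introns[f"theta_{cond}_nuclear"] = np.clip(nuc, _THETA_LO, _THETA_HI)
            introns[f"theta_{cond}_cytoplasmic"] = np.clip(
                _from_odds(cyt_odds), _THETA_LO, _THETA_HI
            )
    return introns, genes


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    annotation: SimulatedAnnotation
    coverage: dict[tuple[str, int, str], CoverageTrack]  # (cond, rep, comp)
    junctions: dict[tuple[str, int, str], JunctionCounts]
    gene_counts: pd.DataFrame  # genes x samples, whole-cell
    truth_introns: pd.DataFrame
    truth_genes: pd.DataFrame

    @property
    def config(self) -> SimulationConfig:
        return self.annotation.config

    def sample_names(self, condition: str) -> list[str]:
        return [
            f"{condition}_rep{r}" for r in range(1, self.config.replicates + 1)
        ]


def simulate_counts(annotation: SimulatedAnnotation) -> SimulatedDataset:
    """Simulate coverage, junction counts and the gene count matrix."""
    config = annotation.config
    rng = np.random.default_rng([config.seed, 2])
    truth_introns, truth_genes = _draw_effects(annotation, rng)
    treatment, reference = config.conditions
    if config.compartments:
        comps = ["nuclear", "cytoplasmic"]
        if config.simulate_whole:
            comps = ["whole"] + comps
    else:
        comps = ["whole"]

    gene_expr = dict(zip(truth_genes["gene_id"], truth_genes["expression"]))
    gene_lfc = dict(zip(truth_genes["gene_id"], truth_genes["true_log2fc"]))
    introns_by_gene: dict[str, list[Intron]] = {}
    for intron in annotation.introns.values():
        introns_by_gene.setdefault(intron.gene_id, []).append(intron)
    theta_cols = {
        (cond, comp): (
            f"theta_{cond}" if comp == "whole" else f"theta_{cond}_{comp}"
        )
        for cond in config.conditions
        for comp in comps
    }
    theta_lookup = {
        key: dict(zip(truth_introns["intron_id"], truth_introns[col]))
        for key, col in theta_cols.items()
    }

    coverage: dict[tuple[str, int, str], CoverageTrack] = {}
    junctions: dict[tuple[str, int, str], JunctionCounts] = {}
    count_columns: dict[str, dict[str, int]] = {}

    for cond in config.conditions:
        for rep in range(1, config.replicates + 1):
            sample = f"{cond}_rep{rep}"
            counts_col: dict[str, int] = {}
            tracks = {
                comp: CoverageTrack(sample, comp) for comp in comps
            }
            junction_rows: dict[str, list[dict]] = {comp: [] for comp in comps}
            for gene_id, gene in annotation.genes.items():
                mu = config.depth * gene_expr[gene_id]
                if cond == treatment:
                    mu *= 2.0 ** gene_lfc[gene_id]
                if config.dispersion > 0:
                    e = float(
                        rng.gamma(1.0 / config.dispersion, mu * config.dispersion)
                    )
                else:
                    e = mu
                counts_col[gene_id] = int(rng.poisson(10.0 * e))
                for intron in introns_by_gene.get(gene_id, []):
                    for comp in comps:
                        theta = theta_lookup[(cond, comp)][intron.intron_id]
                        iv = intron.interval
                        depths = rng.poisson(e * theta, size=iv.length).astype(float)
                        if config.spike_fraction > 0:
                            n_spike = int(config.spike_fraction * iv.length)
                            if n_spike:
                                pos = rng.choice(iv.length, size=n_spike, replace=False)
                                depths[pos] *= config.spike_multiplier
                        tracks[comp].add_values(iv.chrom, iv.start, depths)
                        junction_rows[comp].append(
                            {
                                "intron_id": intron.intron_id,
                                "spliced": int(rng.poisson(e * (1 - theta))),
                                "five_prime": int(rng.poisson(e * (1 - theta))),
                                "three_prime": int(rng.poisson(e * (1 - theta))),
                            }
                        )
            count_columns[sample] = counts_col
            for comp in comps:
                coverage[(cond, rep, comp)] = tracks[comp]
                junctions[(cond, rep, comp)] = JunctionCounts(
                    pd.DataFrame(junction_rows[comp]), sample
                )

    gene_counts = pd.DataFrame(count_columns)
    gene_counts.index.name = "gene_id"
    return SimulatedDataset(
        annotation=annotation,
        coverage=coverage,
        junctions=junctions,
        gene_counts=gene_counts,
        truth_introns=truth_introns,
        truth_genes=truth_genes,
    )


# ---------------------------------------------------------------------------
# conservation and crosslink tracks
# ---------------------------------------------------------------------------


def simulate_tracks(
    dataset: SimulatedDataset,
) -> tuple[CoverageTrack, pd.DataFrame]:
    """Conservation bedGraph-style track plus crosslink events (BED6 frame).

    Crosslink event rate per base differs by the configured enrichment
    factor between retained-class and non-retained-class introns;
    conservation values are clipped to [0, 1].
    """
    config = dataset.config
    rng = np.random.default_rng([config.seed, 3])
    conservation = CoverageTrack("conservation", "whole")
    crosslink_rows = []
    truth = dataset.truth_introns.set_index("intron_id")
    for intron_id, intron in dataset.annotation.introns.items():
        retained = bool(truth.loc[intron_id, "retained_class"])
        iv = intron.interval
        level = (
            config.conservation_retained
            if retained
            else config.conservation_background
        )
        values = np.clip(
            level + rng.normal(0.0, config.conservation_noise_sd, iv.length),
            0.0,
            1.0,
        )
        conservation.add_values(iv.chrom, iv.start, values)

        rate = config.crosslink_base_rate * (
            config.crosslink_enrichment if retained else 1.0
        )
        for rbp in config.rbps:
            n_events = int(rng.poisson(rate * iv.length))
            positions = rng.integers(iv.start, iv.end, size=n_events)
            for pos in positions:
                crosslink_rows.append(
                    {
                        "chrom": iv.chrom,
                        "start": int(pos),
                        "end": int(pos) + 1,
                        "name": rbp,
                        "score": 1,
                        "strand": iv.strand,
                    }
                )
    crosslinks = pd.DataFrame(
        crosslink_rows,
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    return conservation, crosslinks


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Convenience wrapper: annotation + counts (tracks drawn separately)."""
    return simulate_counts(simulate_annotation(config))


# ---------------------------------------------------------------------------
# on-disk output
# ---------------------------------------------------------------------------


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> Path:
    """Write all simulated inputs in their standard text formats, plus a
    JSON manifest recording the seed and config hash."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = dataset.annotation
    write_gtf(annotation.genes, outdir / "annotation.gtf")
    write_fasta(annotation.sequences, outdir / "genome.fa")
    for (cond, rep, comp), track in dataset.coverage.items():
        track.write_bedgraph(outdir / f"coverage_{cond}_rep{rep}_{comp}.bedgraph")
    for (cond, rep, comp), junc in dataset.junctions.items():
        write_junctions(junc, outdir / f"junctions_{cond}_rep{rep}_{comp}.tsv")
    dataset.gene_counts.reset_index().to_csv(
        outdir / "gene_counts.tsv", sep="\t", index=False
    )
    write_table(dataset.truth_introns, outdir / "truth_introns.tsv")
    write_table(dataset.truth_genes, outdir / "truth_genes.tsv")

    conservation, crosslinks = simulate_tracks(dataset)
    conservation.write_bedgraph(outdir / "conservation.bedgraph")
    write_bed(crosslinks, outdir / "crosslinks.bed")

    # synthetic reactivity panel: the coupled genes stand in for the
    # pan-reactive marker list; A1/A2 split the remainder of the panel
    coupled = sorted(
        dataset.truth_genes.loc[dataset.truth_genes["coupled"], "gene_id"]
    )
    panels = {
        "pan": coupled[: max(1, len(coupled) // 2)] if coupled else [],
        "A1": coupled[max(1, len(coupled) // 2):] if coupled else [],
        "A2": [],
    }
    (outdir / "panels.yaml").write_text(yaml.safe_dump(panels))

    manifest = {
        "seed": dataset.config.seed,
        "config_hash": dataset.config.config_hash(),
        "config": dataset.config.to_dict(),
    }
    (outdir / "simulation_manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def worked_example(seed: int = 7) -> SimulatedDataset:
    """Tiny deterministic dataset used in documentation examples."""
    config = SimulationConfig(
        n_genes=8,
        exons_per_gene=(3, 3),
        replicates=2,
        depth=300.0,
        dispersion=0.02,
        coupled_fraction=0.25,
        seed=seed,
    )
    return simulate_dataset(config)
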