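"""Synthetic ChIP-seq study generator with recoverable ground truth.

Emulates the study design the pipeline targets: two liver samples (patient
and control) assayed for three histone marks (H3K4me1, H3K4me3, H3K27ac)
and one transcription factor (USF1), on a small random genome. Planted
truth covers TF peaks (a chosen fraction carrying an E-box near the
summit), histone peaks with planted differential or sample-exclusive
effects, input-chromatin artifact regions, simple repeats, genes, and a
variant set with known dbSNP/GWAS/LD/depth/quality classes.

Read model: background read starts are per-base Poisson; within a planted
peak, fragments of the configured length are drawn so that every fragment
covers the planted summit (as sonicated ChIP fragments cover the bound
site), at a rate that makes the total in-peak start rate ``multiplier``
times the background. Reads are fixed-length single-end; the 5' read of a
+ fragment and the 3' read of a - fragment are reported, so downstream
fragment extension reconstructs the fragment. Patient libraries are deeper
than control by ``patient_depth_factor``, mirroring the asymmetric library
sizes of real two-sample designs.

Everything is deterministic under a fixed seed: each stage draws from its
own ``numpy`` generator seeded from (seed, stage index), so re-running any
stage reproduces its output byte-identically.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .io_formats import (
    AlignedRead,
    GeneModel,
    GenomicInterval,
    VariantRecord,
    write_fasta,
    write_gene_table,
    write_intervals,
    write_reads,
    write_variants,
)

HM_MARKS = ("H3K4me1", "H3K4me3", "H3K27ac")
TF_MARK = "USF1"
SAMPLES = ("control", "patient")
PLANTABLE_EBOXES = ("CACGTG", "CACATG")  # CA[C/T]GTG family, forward spellings

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Shape and rates of the synthetic study.

    Counts are per mark where applicable. ``background_rate`` is read starts
    per bp; a planted peak multiplies the local start rate by
    ``peak_read_multiplier`` over a ``peak_width_mean`` footprint.
    ``differential_fraction`` of each histone mark's peaks get an asymmetric
    effect: either the designated sample has ``differential_fold`` times the
    other's rate, or (for the ``exclusive_fraction`` subset of differential
    peaks) the peak is absent from the other sample entirely.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 300_000
    n_genes: int = 80
    n_tf_peaks: int = 40
    n_hm_peaks: int = 40
    n_false_peaks: int = 3  # TF peaks also enriched in input chromatin
    peak_width_mean: int = 300
    fragment_length: int = 170
    read_length: int = 50
    background_rate: float = 0.01
    peak_base_rate: Optional[float] = None  # rate under planted peaks; defaults
    # to background_rate, but can be set so peaks carry reads even with a
    # read-free background
    peak_read_multiplier: float = 20.0
    motif_fraction: float = 0.6
    differential_fraction: float = 0.3
    differential_fold: float = 5.0
    exclusive_fraction: float = 0.25
    patient_depth_factor: float = 1.7
    protein_coding_fraction: float = 0.85
    n_repeats: int = 20
    repeat_length: int = 200
    n_variants: int = 300
    in_peak_fraction: float = 0.5
    known_129_fraction: float = 0.5
    known_132_only_fraction: float = 0.2
    high_depth_fraction: float = 0.10
    low_depth_fraction: float = 0.15
    low_quality_fraction: float = 0.15
    gwas_fraction: float = 0.10
    ld_fraction: float = 0.10
    ld_block_size: int = 3

    def __post_init__(self) -> None:
        for name in (
            "n_chrom", "chrom_length", "n_genes", "n_tf_peaks", "n_hm_peaks",
            "peak_width_mean", "fragment_length", "read_length", "n_variants",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "motif_fraction", "differential_fraction", "exclusive_fraction",
            "in_peak_fraction", "known_129_fraction", "known_132_only_fraction",
            "gwas_fraction", "ld_fraction",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.chrom_length <= self.peak_width_mean:
            raise ValueError("chrom_length must exceed peak_width_mean")

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chrom)}


@dataclass
class TruthTable:
    """Planted ground truth, one row per planted object."""

    peaks: pd.DataFrame
    motifs: pd.DataFrame
    genes: list
    repeats: list
    chrom_sizes: Dict[str, int]
    variants: Dict[str, pd.DataFrame] = field(default_factory=dict)

    def tf_peaks(self, include_artifacts: bool = False) -> pd.DataFrame:
        sel = self.peaks[self.peaks["mark"] == TF_MARK]
        if not include_artifacts:
            sel = sel[~sel["is_artifact"]]
        return sel

    def hm_peaks(self, mark: Optional[str] = None) -> pd.DataFrame:
        sel = self.peaks[self.peaks["mark"] != TF_MARK]
        if mark is not None:
            sel = sel[sel["mark"] == mark]
        return sel

    def peak_intervals(
        self, mark: Optional[str] = None, sample: Optional[str] = None,
        differential_only: bool = False,
    ) -> list[GenomicInterval]:
        sel = self.peaks if mark is None else self.peaks[self.peaks["mark"] == mark]
        if sample is not None:
            col = f"multiplier_{sample}"
            sel = sel[sel[col] > 0]
        if differential_only:
            sel = sel[sel["differential"]]
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in sel.itertuples(index=False)
        ]


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _place_summits(config: SimulationConfig, rng: np.random.Generator, n: int):
    """Non-overlapping summit positions across the genome, away from edges."""
    margin = config.fragment_length + config.peak_width_mean
    spacing = 2 * (config.fragment_length + config.peak_width_mean)
    slots = []
    for chrom, size in config.chrom_sizes.items():
        pos = margin
        while pos < size - margin:
            slots.append((chrom, pos))
            pos += spacing
    if n > len(slots):
        raise ValueError(
            f"genome too small: {n} peaks requested but only {len(slots)} "
            "non-overlapping slots available"
        )
    chosen = rng.choice(len(slots), size=n, replace=False)
    jitter = rng.integers(-spacing // 8, spacing // 8 + 1, size=n)
    return [(slots[i][0], int(slots[i][1] + j)) for i, j in zip(chosen, jitter)]


def simulate_genome(config: SimulationConfig):
    """Random genome with planted peaks, motifs, genes and repeats.

    Returns ``(genome, truth)`` where genome is a dict of uppercase
    chromosome sequences and truth records every planted object. The peak
    table fixes summits and per-sample rate multipliers; reads are drawn
    from it by :func:`simulate_reads`.
    """
    rng = _rng(config, 0)
    L = config.fragment_length

    # 1. plan peaks -------------------------------------------------------
    n_total = (
        config.n_tf_peaks + config.n_false_peaks + len(HM_MARKS) * config.n_hm_peaks
    )
    summits = _place_summits(config, rng, n_total)
    rows = []
    cursor = 0

    def take(k):
        nonlocal cursor
        out = summits[cursor : cursor + k]
        cursor += k
        return out

    for chrom, s in take(config.n_tf_peaks):
        rows.append(
            dict(chrom=chrom, summit=s, mark=TF_MARK, is_artifact=False,
                 differential=False, exclusive=False, direction=".",
                 multiplier_control=config.peak_read_multiplier,
                 multiplier_patient=config.peak_read_multiplier)
        )
    for chrom, s in take(config.n_false_peaks):
        rows.append(
            dict(chrom=chrom, summit=s, mark=TF_MARK, is_artifact=True,
                 differential=False, exclusive=False, direction=".",
                 multiplier_control=config.peak_read_multiplier,
                 multiplier_patient=config.peak_read_multiplier)
        )
    base_m = config.peak_read_multiplier
    for mark in HM_MARKS:
        placed = take(config.n_hm_peaks)
        n_diff = int(round(config.differential_fraction * len(placed)))
        n_excl = int(round(config.exclusive_fraction * n_diff))
        for i, (chrom, s) in enumerate(placed):
            differential = i < n_diff
            exclusive = i < n_excl
            direction = "."
            mc = mp = base_m
            if differential:
                direction = (
                    "higher_in_patient" if i % 2 == 0 else "higher_in_control"
                )
                if direction == "higher_in_patient":
                    mp = base_m * config.differential_fold
                    mc = 0.0 if exclusive else base_m
                else:
                    mc = base_m * config.differential_fold
                    mp = 0.0 if exclusive else base_m
            rows.append(
                dict(chrom=chrom, summit=s, mark=mark, is_artifact=False,
                     differential=differential, exclusive=exclusive,
                     direction=direction, multiplier_control=mc,
                     multiplier_patient=mp)
            )
    peaks = pd.DataFrame(rows)
    peaks["start"] = peaks["summit"] - (L - 1)
    peaks["end"] = peaks["summit"] + L

    # 2. motifs near TF summits ------------------------------------------
    tf_real = peaks[(peaks["mark"] == TF_MARK) & ~peaks["is_artifact"]]
    n_motif = int(round(config.motif_fraction * len(tf_real)))
    motif_rows = []
    has_motif = np.zeros(len(peaks), dtype=bool)
    tf_idx = list(tf_real.index)
    for j, idx in enumerate(tf_idx[:n_motif]):
        offset = int(rng.integers(-40, 41))
        pattern = PLANTABLE_EBOXES[int(rng.integers(0, len(PLANTABLE_EBOXES)))]
        pos = int(peaks.at[idx, "summit"]) + offset
        motif_rows.append(dict(chrom=peaks.at[idx, "chrom"], pos=pos,
                               pattern=pattern))
        has_motif[idx] = True
    peaks["has_motif"] = has_motif
    motifs = pd.DataFrame(motif_rows, columns=["chrom", "pos", "pattern"])

    # 3. genes, non-overlapping ------------------------------------------
    genes = []
    occupied: Dict[str, list] = {c: [] for c in config.chrom_sizes}
    attempts = 0
    while len(genes) < config.n_genes:
        attempts += 1
        if attempts > 50 * max(1, config.n_genes):
            raise ValueError("genome too small to place the requested genes")
        chrom = f"chr{int(rng.integers(1, config.n_chrom + 1))}"
        size = config.chrom_sizes[chrom]
        length = int(rng.integers(2_000, 8_001))
        start = int(rng.integers(2_000, size - length - 2_000))
        end = start + length
        if any(start < e and s < end for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = (
            "protein_coding"
            if rng.random() < config.protein_coding_fraction
            else "lincRNA"
        )
        tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
        genes.append(
            GeneModel(f"GENE{len(genes):04d}", chrom, strand, tss, tes, biotype)
        )

    # 4. repeats, kept clear of peak footprints ---------------------------
    peak_spans: Dict[str, list] = {c: [] for c in config.chrom_sizes}
    for r in peaks.itertuples(index=False):
        peak_spans[r.chrom].append((int(r.start), int(r.end)))
    repeats = []
    attempts = 0
    while len(repeats) < config.n_repeats:
        attempts += 1
        if attempts > 50 * max(1, config.n_repeats):
            break
        chrom = f"chr{int(rng.integers(1, config.n_chrom + 1))}"
        size = config.chrom_sizes[chrom]
        start = int(rng.integers(0, size - config.repeat_length))
        end = start + config.repeat_length
        if any(start < e and s < end for s, e in peak_spans[chrom]):
            continue
        repeats.append(
            GenomicInterval(chrom, start, end, name=f"rpt{len(repeats)}")
        )

    # 5. sequence with planted hexamers ----------------------------------
    genome = {}
    for chrom, size in config.chrom_sizes.items():
        seq = rng.integers(0, 4, size=size)
        genome[chrom] = _BASES[seq].tobytes().decode()
    for m in motifs.itertuples(index=False):
        s = genome[m.chrom]
        genome[m.chrom] = s[: m.pos] + m.pattern + s[m.pos + len(m.pattern):]

    truth = TruthTable(
        peaks=peaks, motifs=motifs, genes=genes, repeats=repeats,
        chrom_sizes=dict(config.chrom_sizes),
    )
    return genome, truth


def _sample_depth(config: SimulationConfig, sample: str) -> float:
    return config.patient_depth_factor if sample == "patient" else 1.0


def _base_rate(config: SimulationConfig) -> float:
    return (
        config.peak_base_rate
        if config.peak_base_rate is not None
        else config.background_rate
    )


def expected_read_count(
    config: SimulationConfig, truth: TruthTable, sample: str, mark: str
) -> float:
    """Closed-form expected read count for one sample/mark library."""
    df = _sample_depth(config, sample)
    total = config.background_rate * df * sum(truth.chrom_sizes.values())
    col = f"multiplier_{sample}"
    for r in truth.peaks[truth.peaks["mark"] == mark].itertuples(index=False):
        m = getattr(r, col)
        if m > 0:
            total += (m - 1) * _base_rate(config) * df * config.peak_width_mean
    return total


def _draw_background(config, rng, depth_factor) -> list[AlignedRead]:
    reads = []
    for chrom, size in config.chrom_sizes.items():
        n = rng.poisson(config.background_rate * depth_factor * size)
        starts = rng.integers(0, size - config.read_length, size=n)
        strands = rng.random(n) < 0.5
        for s, plus in zip(np.sort(starts), strands):
            reads.append(
                AlignedRead(chrom, int(s), int(s) + config.read_length,
                            "+" if plus else "-")
            )
    return reads


def _draw_peak_reads(config, rng, chrom, summit, multiplier, depth_factor):
    """Fragments covering the summit; report the sequenced end per strand."""
    if multiplier <= 1:
        return []
    L, rl = config.fragment_length, config.read_length
    lam = (multiplier - 1) * _base_rate(config) * depth_factor * config.peak_width_mean
    n = rng.poisson(lam)
    frag_starts = rng.integers(summit - L + 1, summit + 1, size=n)
    strands = rng.random(n) < 0.5
    reads = []
    for f, plus in zip(frag_starts, strands):
        f = int(f)
        if plus:
            reads.append(AlignedRead(chrom, f, f + rl, "+"))
        else:
            reads.append(AlignedRead(chrom, f + L - rl, f + L, "-"))
    return reads


def simulate_reads(config: SimulationConfig, truth: TruthTable):
    """Per-sample/mark ChIP read sets plus per-sample input chromatin.

    Returns ``(chip, inputs)``: ``chip[(sample, mark)]`` is a read list and
    ``inputs[sample]`` the input-chromatin reads. Input libraries carry pure
    background plus the planted artifact regions (enriched in both ChIP and
    input), which the input filter is expected to remove.
    """
    rng = _rng(config, 1)
    chip: Dict[tuple, list] = {}
    for sample in SAMPLES:
        df = _sample_depth(config, sample)
        col = f"multiplier_{sample}"
        for mark in (TF_MARK,) + HM_MARKS:
            reads = _draw_background(config, rng, df)
            for r in truth.peaks[truth.peaks["mark"] == mark].itertuples(index=False):
                reads.extend(
                    _draw_peak_reads(
                        config, rng, r.chrom, int(r.summit), getattr(r, col), df
                    )
                )
            reads.sort(key=lambda x: (x.chrom, x.start, x.end, x.strand))
            chip[(sample, mark)] = reads
    inputs: Dict[str, list] = {}
    for sample in SAMPLES:
        df = _sample_depth(config, sample)
        reads = _draw_background(config, rng, df)
        for r in truth.peaks[
            (truth.peaks["mark"] == TF_MARK) & truth.peaks["is_artifact"]
        ].itertuples(index=False):
            reads.extend(
                _draw_peak_reads(
                    config, rng, r.chrom, int(r.summit),
                    config.peak_read_multiplier, df,
                )
            )
        reads.sort(key=lambda x: (x.chrom, x.start, x.end, x.strand))
        inputs[sample] = reads
    return chip, inputs


_GWAS_KEYWORD_TRAITS = (
    "Type 2 diabetes",
    "LDL cholesterol",
    "Liver enzyme levels",
    "Triglycerides",
    "Fasting plasma glucose",
    "Obesity",
    "Hepatocellular carcinoma",
    "Insulin resistance",
)
_GWAS_NEUTRAL_TRAITS = ("Height", "Hair color", "Bone mineral density")


def simulate_variants(config: SimulationConfig, truth: TruthTable):
    """Variant sets with known cascade classes, plus the lookup tables.

    Returns a dict with per-sample VariantRecord lists, dbSNP build-129 and
    -132 id sets, the GWAS catalogue and LD DataFrames; per-sample truth
    frames (with the expected outcome of every cascade stage) are stored on
    ``truth.variants``.
    """
    rng = _rng(config, 2)
    diff_regions = truth.peak_intervals(differential_only=True)
    diff_regions = [iv for iv in diff_regions]
    all_hm = truth.peak_intervals()
    hm_rows = truth.hm_peaks()

    def peak_presence(chrom, pos0):
        hit = hm_rows[
            (hm_rows["chrom"] == chrom)
            & (hm_rows["start"] <= pos0)
            & (pos0 < hm_rows["end"])
        ]
        if hit.empty:
            return False, False, False
        r = hit.iloc[0]
        return (r["multiplier_control"] > 0, r["multiplier_patient"] > 0,
                bool(r["differential"]))

    dbsnp129: set[str] = set()
    dbsnp132: set[str] = set()
    gwas_rows = []
    ld_rows = []
    out_records: Dict[str, list] = {}
    rs_counter = 1000

    hm_spans: Dict[str, list] = {}
    for iv in all_hm:
        hm_spans.setdefault(iv.chrom, []).append((iv.start, iv.end))

    # positions unique across BOTH samples: the dbSNP id lists are shared,
    # so a positional collision would leak one sample's known/novel class
    # into the other's
    used_pos = set()
    for sample in SAMPLES:
        n = config.n_variants if sample == "patient" else config.n_variants // 2
        records = []
        truth_rows = []
        for i in range(n):
            in_peak = rng.random() < config.in_peak_fraction and diff_regions
            for _ in range(200):
                if in_peak:
                    iv = diff_regions[int(rng.integers(0, len(diff_regions)))]
                    pos0 = int(rng.integers(iv.start, iv.end))
                    chrom = iv.chrom
                else:
                    chrom = f"chr{int(rng.integers(1, config.n_chrom + 1))}"
                    pos0 = int(rng.integers(0, config.chrom_sizes[chrom]))
                    if any(s <= pos0 < e for s, e in hm_spans.get(chrom, ())):
                        continue
                if (chrom, pos0) not in used_pos:
                    used_pos.add((chrom, pos0))
                    break
            u = rng.random()
            if u < config.high_depth_fraction:
                depth = int(rng.integers(101, 201))
            elif u < config.high_depth_fraction + config.low_depth_fraction:
                depth = int(rng.integers(1, 10))
            else:
                depth = int(rng.integers(10, 101))
            quality = (
                float(rng.uniform(10, 49.99))
                if rng.random() < config.low_quality_fraction
                else float(rng.uniform(50, 99))
            )
            v = rng.random()
            known129 = v < config.known_129_fraction
            known132 = known129 or (
                v < config.known_129_fraction + config.known_132_only_fraction
            )
            pos = pos0 + 1
            vid = f"{chrom}:{pos}"
            if known129:
                dbsnp129.add(vid)
            if known132:
                dbsnp132.add(vid)

            gwas_here = rng.random() < config.gwas_fraction
            gwas_keyword = False
            if gwas_here:
                rs_counter += 1
                gwas_keyword = rng.random() < 0.5
                trait = (
                    _GWAS_KEYWORD_TRAITS[int(rng.integers(0, len(_GWAS_KEYWORD_TRAITS)))]
                    if gwas_keyword
                    else _GWAS_NEUTRAL_TRAITS[int(rng.integers(0, len(_GWAS_NEUTRAL_TRAITS)))]
                )
                gwas_rows.append(
                    dict(snp_id=f"rs{rs_counter}", chrom=chrom, pos=pos, trait=trait)
                )

            ld_proxy = False
            if not (gwas_here and gwas_keyword) and rng.random() < config.ld_fraction:
                # anchor catalogue SNP elsewhere; alternate pass/fail edges
                rs_counter += 1
                anchor = f"rs{rs_counter}"
                a_pos = min(
                    config.chrom_sizes[chrom] - 1,
                    pos + int(rng.integers(1_000, 400_000)),
                )
                gwas_rows.append(
                    dict(
                        snp_id=anchor, chrom=chrom, pos=a_pos,
                        trait=_GWAS_KEYWORD_TRAITS[
                            int(rng.integers(0, len(_GWAS_KEYWORD_TRAITS)))
                        ],
                    )
                )
                edge_kind = int(rng.integers(0, 3))
                if edge_kind == 0:
                    r2, dist = float(rng.uniform(0.8, 1.0)), abs(a_pos - pos)
                    ld_proxy = True
                elif edge_kind == 1:
                    r2, dist = float(rng.uniform(0.2, 0.79)), abs(a_pos - pos)
                else:
                    r2, dist = float(rng.uniform(0.8, 1.0)), 500_001 + int(
                        rng.integers(0, 100_000)
                    )
                a, b = sorted([vid, anchor])
                ld_rows.append(dict(snp_a=a, snp_b=b, r2=round(r2, 3), distance=dist))

            records.append(
                VariantRecord(
                    chrom=chrom, pos=pos, ref_allele="A", alt_allele="G",
                    quality=round(quality, 2), depth=depth, sample_id=sample,
                )
            )
            in_c, in_p, in_diff = peak_presence(chrom, pos0)
            retained = depth <= 100 and quality >= 50
            novel = retained and not known129 and not known132
            truth_rows.append(
                dict(
                    chrom=chrom, pos=pos, depth=depth, quality=round(quality, 2),
                    known_129=known129, known_132=known132,
                    in_diff_region=bool(in_diff and in_peak),
                    expect_retained=retained,
                    expect_known=retained and known129,
                    expect_novel=novel,
                    expect_novel_in_peak=(
                        novel and bool(in_diff and in_peak) and depth >= 10
                    ),
                    expect_gwas_match=(
                        retained and not (not known129 and known132)
                        and gwas_here and gwas_keyword
                    ),
                    expect_ld_proxy=(
                        retained and not (not known129 and known132)
                        and not (gwas_here and gwas_keyword) and ld_proxy
                    ),
                    expect_hm_overlap=(
                        {
                            (True, True): "both",
                            (True, False): "control_only",
                            (False, True): "patient_only",
                            (False, False): "none",
                        }[(in_c, in_p)]
                    ),
                )
            )
        records.sort(key=lambda r: (r.chrom, r.pos))
        out_records[sample] = records
        tdf = pd.DataFrame(truth_rows).sort_values(["chrom", "pos"])
        truth.variants[sample] = tdf.reset_index(drop=True)

    gwas_df = pd.DataFrame(
        gwas_rows, columns=["snp_id", "chrom", "pos", "trait"]
    ).drop_duplicates("snp_id")
    ld_df = pd.DataFrame(
        ld_rows, columns=["snp_a", "snp_b", "r2", "distance"]
    ).drop_duplicates(["snp_a", "snp_b"])
    return {
        "records": out_records,
        "dbsnp129": dbsnp129,
        "dbsnp132": dbsnp132,
        "gwas": gwas_df,
        "ld": ld_df,
    }


@dataclass
class SimulatedStudy:
    """Everything one synthetic run produced, in memory."""

    config: SimulationConfig
    genome: Dict[str, str]
    truth: TruthTable
    chip_reads: Dict[tuple, list]
    input_reads: Dict[str, list]
    variant_data: dict


def simulate_all(
    config: SimulationConfig, outdir: Optional[str] = None
) -> SimulatedStudy:
    """Run every stage; optionally write the full file set to ``outdir``."""
    genome, truth = simulate_genome(config)
    chip, inputs = simulate_reads(config, truth)
    vdata = simulate_variants(config, truth)
    study = SimulatedStudy(config, genome, truth, chip, inputs, vdata)
    if outdir is not None:
        write_study(study, outdir)
    return study


def write_study(study: SimulatedStudy, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    j = lambda name: os.path.join(outdir, name)
    write_fasta(study.genome, j("genome.fa"))
    with open(j("chrom.sizes"), "w") as fh:
        for chrom, size in study.truth.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    write_gene_table(study.truth.genes, j("genes.tsv"))
    write_intervals(study.truth.repeats, j("repeats.bed"))
    for (sample, mark), reads in sorted(study.chip_reads.items()):
        write_reads(reads, j(f"reads_{sample}_{mark}.bed"))
    for sample, reads in sorted(study.input_reads.items()):
        write_reads(reads, j(f"input_{sample}.bed"))
    contigs = list(study.truth.chrom_sizes.items())
    for sample, records in sorted(study.variant_data["records"].items()):
        write_variants(records, j(f"variants_{sample}.vcf"), contigs=contigs)
    for build in ("dbsnp129", "dbsnp132"):
        with open(j(f"{build}.tsv"), "w") as fh:
            fh.write("id\n")
            for vid in sorted(study.variant_data[build]):
                fh.write(vid + "\n")
    study.variant_data["gwas"].to_csv(j("gwas_catalog.tsv"), sep="\t", index=False)
    study.variant_data["ld"].to_csv(j("ld_table.tsv"), sep="\t", index=False)
    study.truth.peaks.to_csv(j("truth_peaks.tsv"), sep="\t", index=False)
    study.truth.motifs.to_csv(j("truth_motifs.tsv"), sep="\t", index=False)
    for sample, tdf in sorted(study.truth.variants.items()):
        tdf.to_csv(j(f"truth_variants_{sample}.tsv"), sep="\t", index=False)
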