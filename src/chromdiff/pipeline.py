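"""End-to-end orchestration: simulate -> call peaks -> differential ->
footprints -> classification -> SNP cascade -> qPCR, with a JSON manifest.

In synthetic mode the pipeline generates its own inputs from a
:class:`~chromdiff.synthetic_data.SimulationConfig` and runs every stage,
writing all tabular outputs plus a manifest recording the seed and
per-stage row counts so cascade conservation is auditable.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .chromatin_diff import (
    DifferentialConfig,
    count_rpm,
    filter_simple_repeats,
    merge_peak_regions,
    nearest_tss,
    normalize_footprints,
    peak_gene_presence,
    rank_differential,
    tally_categories,
    tss_footprint,
    tss_peak_agreement,
)
from .io_formats import read_variants
from .peakcalling import (
    PeakCallConfig,
    add_rpm_heights,
    call_peaks,
    deduplicate_reads,
    extend_and_pileup,
    filter_by_input,
    peaks_to_intervals,
    scan_ebox,
    select_top_peaks,
)
from .synthetic_data import (
    HM_MARKS,
    SAMPLES,
    TF_MARK,
    SimulationConfig,
    simulate_all,
)
from .variants import VariantFilterConfig, annotated_to_frame, run_cascade

logger = logging.getLogger("chromdiff")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (synthetic mode)."""

    outdir: str
    seed: int = 0
    simulation: SimulationConfig = None
    peakcall: PeakCallConfig = field(default_factory=PeakCallConfig)
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)
    variant_filter: VariantFilterConfig = field(default_factory=VariantFilterConfig)
    n_top: Optional[int] = None  # override scaled to the synthetic region count

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic study and write every stage output.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    os.makedirs(config.outdir, exist_ok=True)
    j = lambda name: os.path.join(config.outdir, name)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    logger.info("stage simulate: generating synthetic study")
    study = simulate_all(config.simulation, outdir=j("inputs"))
    truth = study.truth
    chrom_sizes = truth.chrom_sizes
    genome = study.genome

    # --- TF peak calling with input filtering and motif scan -------------
    sample_peaks: Dict[str, list] = {}
    motif_summary: Dict[str, dict] = {}
    for sample in SAMPLES:
        reads = study.chip_reads[(sample, TF_MARK)]
        deduped = deduplicate_reads(
            reads, strand_blind=config.peakcall.strand_blind_dedup
        )
        cov = extend_and_pileup(deduped, config.peakcall, chrom_sizes)
        peaks = call_peaks(cov, config.peakcall, sample_id=sample, mark=TF_MARK)
        add_rpm_heights(peaks, total_mapped=len(reads))
        inp = deduplicate_reads(study.input_reads[sample])
        inp_cov = extend_and_pileup(inp, config.peakcall, chrom_sizes)
        peaks, n_removed = filter_by_input(peaks, inp_cov, config.peakcall)
        peaks, summary = scan_ebox(peaks, genome, config.peakcall)
        sample_peaks[sample] = peaks
        motif_summary[sample] = summary
        manifest["stages"][f"callpeaks_{sample}"] = {
            "n_reads": len(reads),
            "n_dedup": len(deduped),
            "n_peaks": len(peaks),
            "n_input_filtered": n_removed,
            "n_with_motif": summary["n_with_motif"],
        }
        from .io_formats import write_intervals

        write_intervals(
            peaks_to_intervals(peaks), j(f"peaks_{sample}_{TF_MARK}.narrowPeak"),
            dialect="narrowPeak",
        )

    # --- HM peak calling + differential analysis per mark ---------------
    diff_frames = []
    differential_by_mark: Dict[str, list] = {}
    hm_peaks_by = {}
    for mark in HM_MARKS:
        per_sample = {}
        totals = {}
        for sample in SAMPLES:
            reads = study.chip_reads[(sample, mark)]
            deduped = deduplicate_reads(reads)
            cov = extend_and_pileup(deduped, config.peakcall, chrom_sizes)
            peaks = call_peaks(cov, config.peakcall, sample_id=sample, mark=mark)
            add_rpm_heights(peaks, total_mapped=len(reads))
            per_sample[sample] = peaks
            totals[sample] = len(reads)
            hm_peaks_by[(sample, mark)] = peaks
        regions = merge_peak_regions(per_sample["control"], per_sample["patient"])
        regions, n_repeat_removed = filter_simple_repeats(
            regions, truth.repeats, config.differential
        )
        rpm_c = count_rpm(regions, study.chip_reads[("control", mark)],
                          totals["control"])
        rpm_p = count_rpm(regions, study.chip_reads[("patient", mark)],
                          totals["patient"])
        n_top = config.n_top or config.differential.n_top
        diff_cfg = DifferentialConfig(
            n_top=min(n_top, max(1, len(regions))),
            tss_window=config.differential.tss_window,
            footprint_halfwidth=config.differential.footprint_halfwidth,
            repeat_overlap_max=config.differential.repeat_overlap_max,
            tss_corr_dist=config.differential.tss_corr_dist,
            peak_match_dist=config.differential.peak_match_dist,
        )
        up, down = rank_differential(regions, rpm_c, rpm_p, diff_cfg, mark=mark)
        differential_by_mark[mark] = up + down
        for dr in up + down:
            try:
                gene, dist = nearest_tss(dr.region, truth.genes)
            except ValueError:
                gene, dist = None, None
            dr.nearest_gene, dr.tss_distance = gene, dist
            diff_frames.append(
                {
                    "mark": mark,
                    "chrom": dr.region.chrom,
                    "start": dr.region.start,
                    "end": dr.region.end,
                    "rpm_control": dr.rpm_control,
                    "rpm_patient": dr.rpm_patient,
                    "delta": dr.delta,
                    "direction": dr.direction,
                    "rank": dr.rank,
                    "nearest_gene": gene,
                    "tss_distance": dist,
                }
            )
        manifest["stages"][f"differential_{mark}"] = {
            "n_regions": len(regions),
            "n_repeat_removed": n_repeat_removed,
            "n_top_per_direction": diff_cfg.n_top,
        }
    pd.DataFrame(diff_frames).to_csv(j("differential.tsv"), sep="\t", index=False)

    # --- TSS footprints (patient libraries) ------------------------------
    profiles = []
    for mark in HM_MARKS:
        profiles.append(
            tss_footprint(
                study.chip_reads[("patient", mark)],
                truth.genes,
                config.differential,
                mark=mark,
                chrom_sizes=chrom_sizes,
            )
        )
    normalized = normalize_footprints(profiles)
    hw = config.differential.footprint_halfwidth
    fp = pd.DataFrame({"offset": np.arange(-hw, hw + 1)})
    for p in normalized:
        fp[p.mark] = p.values
    fp.to_csv(j("footprints.tsv"), sep="\t", index=False)
    manifest["stages"]["footprints"] = {
        "n_positions": 2 * hw + 1,
        "global_max": max(float(p.values.max()) for p in normalized),
    }

    # --- genomic classification + gene presence --------------------------
    tally = tally_categories(differential_by_mark, truth.genes, config.differential)
    pd.DataFrame(tally).to_csv(j("classification.tsv"), sep="\t", index=False)
    presence = {
        mark: peak_gene_presence(
            hm_peaks_by[("control", mark)],
            hm_peaks_by[("patient", mark)],
            truth.genes,
            config.differential,
        )
        for mark in HM_MARKS
    }
    pd.DataFrame(presence).T.rename_axis("mark").reset_index().to_csv(
        j("gene_presence.tsv"), sep="\t", index=False
    )
    agreement = tss_peak_agreement(
        sample_peaks["patient"], sample_peaks["control"], truth.genes,
        config.differential,
    )
    manifest["stages"]["tss_agreement"] = agreement

    # --- SNP cascade ------------------------------------------------------
    diff_intervals = truth.peak_intervals(differential_only=True)
    control_hm = truth.peak_intervals(sample="control")
    patient_hm = truth.peak_intervals(sample="patient")
    for sample in SAMPLES:
        records = read_variants(
            j(os.path.join("inputs", f"variants_{sample}.vcf")), sample_id=sample
        )
        result = run_cascade(
            records,
            study.variant_data["dbsnp129"],
            study.variant_data["dbsnp132"],
            diff_intervals,
            control_hm,
            patient_hm,
            study.variant_data["gwas"],
            study.variant_data["ld"],
            config.variant_filter,
        )
        annotated_to_frame(result["annotated"]).to_csv(
            j(f"variants_annotated_{sample}.tsv"), sep="\t", index=False
        )
        manifest["stages"][f"snps_{sample}"] = result["counts"]

    with open(j("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
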