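"""SNP filtering cascade and regulatory annotation.

Variants called on the pooled histone-mark alignments are passed through the
study's cascade: drop sites with depth > 100 (repeat-prone) or quality < 50;
split known from possibly-novel using a dbSNP build-129 id list, then prune
the novel set against build 132; keep novel sites with >= 10 reads inside
the differential peak regions; flag sites matching GWAS-catalogue SNPs whose
trait contains a disease keyword, expand through an LD table (r^2 >= 0.8
within 500 kb), and annotate every variant with its histone-peak overlap
category (control only / patient only / both / none).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, VariantRecord

DEFAULT_GWAS_KEYWORDS = (
    "diabetes",
    "fasting plasma glucose",
    "hepatitis",
    "hepatocellular carcinoma",
    "insulin",
    "ldl cholesterol",
    "lipid metabolism",
    "liver",
    "obesity",
    "triglycerides",
)


@dataclass(frozen=True)
class VariantFilterConfig:
    """Cascade thresholds.

    max_depth: sites with depth strictly above this are removed (repeat
    avoidance). min_quality: sites with quality strictly below are removed.
    min_peak_reads: novel sites need at least this depth inside a peak
    region. ld_r2_min / ld_dist_max: inclusive LD-proxy bounds. Keywords are
    matched case-insensitively as substrings of the GWAS trait.
    """

    max_depth: int = 100
    min_quality: float = 50.0
    min_peak_reads: int = 10
    ld_r2_min: float = 0.8
    ld_dist_max: int = 500_000
    gwas_keywords: tuple[str, ...] = DEFAULT_GWAS_KEYWORDS
    check_alleles: bool = False

    def __post_init__(self) -> None:
        if min(self.max_depth, self.min_quality, self.min_peak_reads) <= 0:
            raise ValueError("thresholds must be positive")
        if not self.gwas_keywords:
            raise ValueError("gwas_keywords must be non-empty")
        object.__setattr__(
            self, "gwas_keywords", tuple(k.lower() for k in self.gwas_keywords)
        )


@dataclass
class AnnotatedVariant:
    """A variant with its cascade flags and annotations."""

    base: VariantRecord
    known_129: bool = False
    known_132: bool = False
    novelty: str = "known"  # known | novel
    in_peak: bool = False
    in_peak_reads: int = 0
    gwas_match: Optional[dict] = None  # {snp_id, trait, keyword}
    ld_proxy_of: Optional[dict] = None  # {snp_id, r2, distance}
    hm_overlap: str = "none"  # control_only | patient_only | both | none


def _variant_key(v: VariantRecord, check_alleles: bool):
    if check_alleles:
        return (v.chrom, v.pos, v.ref_allele, v.alt_allele)
    return (v.chrom, v.pos)


def _ids_for(v: VariantRecord) -> set[str]:
    ids = {f"{v.chrom}:{v.pos}"}
    if v.variant_id and v.variant_id != ".":
        ids.add(v.variant_id)
    return ids


def filter_variants(
    variants: Sequence[VariantRecord], config: VariantFilterConfig
) -> tuple[list[VariantRecord], dict]:
    """Depth/quality filter: retain iff depth <= max_depth AND quality >= min.

    Records missing either field are routed to a ``missing_fields`` bucket.
    Returns (retained, removal log) where the log tallies every removal
    reason so that input = retained + sum(removals).
    """
    retained = []
    log = {"high_depth": 0, "low_quality": 0, "missing_fields": 0}
    for v in variants:
        if v.depth is None or v.quality is None:
            log["missing_fields"] += 1
        elif v.depth > config.max_depth:
            log["high_depth"] += 1
        elif v.quality < config.min_quality:
            log["low_quality"] += 1
        else:
            retained.append(v)
    return retained, log


def split_known_novel(
    variants: Sequence[VariantRecord],
    dbsnp129_ids: set[str],
    dbsnp132_ids: set[str],
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Split into known (present in build 129) and candidate-novel sets.

    Candidate-novel sites are absent from BOTH builds: a site in 132 but not
    129 is dropped from the novel set by the newer build, and (not being in
    129) is not part of the known output either.
    """
    known, novel = [], []
    for v in variants:
        ids = _ids_for(v)
        in129 = bool(ids & dbsnp129_ids)
        in132 = bool(ids & dbsnp132_ids)
        av = AnnotatedVariant(
            base=v,
            known_129=in129,
            known_132=in132,
            novelty="known" if in129 else "novel",
        )
        if in129:
            known.append(av)
        elif not in132:
            novel.append(av)
    return known, novel


def _point_in_any(
    pos0: int, chrom: str, intervals_by_chrom: Dict[str, np.ndarray]
) -> bool:
    arr = intervals_by_chrom.get(chrom)
    if arr is None or not len(arr):
        return False
    i = np.searchsorted(arr[:, 0], pos0, "right") - 1
    # intervals may overlap after merging differently; scan back while starts
    # could still cover pos0 (arrays here are merged, so one check suffices)
    return i >= 0 and pos0 < arr[i, 1]


def _index_intervals(
    intervals: Iterable[GenomicInterval],
) -> Dict[str, np.ndarray]:
    by_chrom: Dict[str, list] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        merged = []
        for s, e in pairs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged, dtype=np.int64)
    return out


def restrict_novel_to_peaks(
    novel: Sequence[AnnotatedVariant],
    hm_peaks: Iterable[GenomicInterval],
    config: VariantFilterConfig,
) -> list[AnnotatedVariant]:
    """Keep novel variants inside a peak region with depth >= min_peak_reads."""
    idx = _index_intervals(hm_peaks)
    kept = []
    for av in novel:
        inside = _point_in_any(av.base.pos0, av.base.chrom, idx)
        av.in_peak = inside
        av.in_peak_reads = av.base.depth if (inside and av.base.depth) else 0
        if inside and (av.base.depth or 0) >= config.min_peak_reads:
            kept.append(av)
    return kept


def gwas_overlap(
    variants: Sequence[AnnotatedVariant],
    catalogue: pd.DataFrame,
    config: VariantFilterConfig,
) -> list[AnnotatedVariant]:
    """Flag variants coinciding with keyword-matched GWAS catalogue SNPs.

    A match requires the variant position (or rsID) to equal a catalogue
    entry whose lowercase trait contains at least one keyword as a
    substring. Returns the matched subset; ``gwas_match`` is set in place.
    """
    for col in ("snp_id", "chrom", "pos", "trait"):
        if col not in catalogue.columns:
            raise ValueError(f"GWAS catalogue missing column {col!r}")
    by_pos: Dict[tuple, list] = {}
    by_id: Dict[str, list] = {}
    for row in catalogue.itertuples(index=False):
        trait = str(row.trait).lower()
        keyword = next((k for k in config.gwas_keywords if k in trait), None)
        if keyword is None:
            continue
        entry = {"snp_id": str(row.snp_id), "trait": str(row.trait), "keyword": keyword}
        by_pos.setdefault((str(row.chrom), int(row.pos)), []).append(entry)
        by_id.setdefault(str(row.snp_id), []).append(entry)
    matched = []
    for av in variants:
        entry = None
        hits = by_pos.get((av.base.chrom, av.base.pos))
        if hits:
            entry = hits[0]
        elif av.base.variant_id and av.base.variant_id in by_id:
            entry = by_id[av.base.variant_id][0]
        if entry is not None:
            av.gwas_match = entry
            matched.append(av)
    return matched


def ld_expand(
    variants: Sequence[AnnotatedVariant],
    catalogue: pd.DataFrame,
    ld_table: pd.DataFrame,
    config: VariantFilterConfig,
) -> list[AnnotatedVariant]:
    """Mark variants that are LD proxies of keyword-matched catalogue SNPs.

    A variant is a proxy when the LD table links it to a catalogue SNP with
    r^2 >= ld_r2_min and |distance| <= ld_dist_max (both bounds inclusive).
    Variants already matched directly are skipped. The strongest-r^2 partner
    is recorded.
    """
    for col in ("snp_a", "snp_b", "r2", "distance"):
        if col not in ld_table.columns:
            raise ValueError(f"LD table missing column {col!r}")
    keyword_snps = set()
    for row in catalogue.itertuples(index=False):
        if any(k in str(row.trait).lower() for k in config.gwas_keywords):
            keyword_snps.add(str(row.snp_id))
    partners: Dict[str, list] = {}
    for row in ld_table.itertuples(index=False):
        if row.r2 < config.ld_r2_min or abs(int(row.distance)) > config.ld_dist_max:
            continue
        a, b = str(row.snp_a), str(row.snp_b)
        for x, y in ((a, b), (b, a)):
            if y in keyword_snps:
                partners.setdefault(x, []).append(
                    {"snp_id": y, "r2": float(row.r2), "distance": int(row.distance)}
                )
    proxies = []
    for av in variants:
        if av.gwas_match is not None:
            continue
        hits = []
        for vid in _ids_for(av.base):
            hits.extend(partners.get(vid, ()))
        if hits:
            av.ld_proxy_of = max(hits, key=lambda h: h["r2"])
            proxies.append(av)
    return proxies


def hm_overlap_category(
    variants: Sequence[AnnotatedVariant],
    peaks_control: Iterable[GenomicInterval],
    peaks_patient: Iterable[GenomicInterval],
) -> list[AnnotatedVariant]:
    """Four-way histone-peak overlap category per variant (marks pooled)."""
    idx_c = _index_intervals(peaks_control)
    idx_p = _index_intervals(peaks_patient)
    for av in variants:
        in_c = _point_in_any(av.base.pos0, av.base.chrom, idx_c)
        in_p = _point_in_any(av.base.pos0, av.base.chrom, idx_p)
        av.hm_overlap = {
            (True, True): "both",
            (True, False): "control_only",
            (False, True): "patient_only",
            (False, False): "none",
        }[(in_c, in_p)]
    return list(variants)


def run_cascade(
    variants: Sequence[VariantRecord],
    dbsnp129_ids: set[str],
    dbsnp132_ids: set[str],
    hm_peaks: Sequence[GenomicInterval],
    peaks_control: Sequence[GenomicInterval],
    peaks_patient: Sequence[GenomicInterval],
    gwas_catalogue: pd.DataFrame,
    ld_table: pd.DataFrame,
    config: Optional[VariantFilterConfig] = None,
) -> dict:
    """Run the full cascade and return all stage outputs plus a count log."""
    config = config or VariantFilterConfig()
    retained, removal_log = filter_variants(variants, config)
    known, novel = split_known_novel(retained, dbsnp129_ids, dbsnp132_ids)
    novel_in_peaks = restrict_novel_to_peaks(novel, hm_peaks, config)
    everything = known + novel
    gwas_matched = gwas_overlap(everything, gwas_catalogue, config)
    ld_proxies = ld_expand(everything, gwas_catalogue, ld_table, config)
    hm_overlap_category(everything, peaks_control, peaks_patient)
    counts = {
        "input": len(variants),
        "removed_high_depth": removal_log["high_depth"],
        "removed_low_quality": removal_log["low_quality"],
        "removed_missing_fields": removal_log["missing_fields"],
        "retained": len(retained),
        "known_129": len(known),
        "candidate_novel": len(novel),
        "dropped_by_132": len(retained) - len(known) - len(novel),
        "novel_in_peaks": len(novel_in_peaks),
        "gwas_matched": len(gwas_matched),
        "ld_proxies": len(ld_proxies),
    }
    return {
        "retained": retained,
        "known": known,
        "novel": novel,
        "novel_in_peaks": novel_in_peaks,
        "gwas_matched": gwas_matched,
        "ld_proxies": ld_proxies,
        "annotated": everything,
        "counts": counts,
    }


def annotated_to_frame(variants: Sequence[AnnotatedVariant]) -> pd.DataFrame:
    """Flatten annotated variants into the output TSV schema."""
    rows = []
    for av in variants:
        rows.append(
            {
                "chrom": av.base.chrom,
                "pos": av.base.pos,
                "ref": av.base.ref_allele,
                "alt": av.base.alt_allele,
                "quality": av.base.quality,
                "depth": av.base.depth,
                "variant_id": av.base.variant_id or ".",
                "known_129": av.known_129,
                "known_132": av.known_132,
                "novelty": av.novelty,
                "in_peak": av.in_peak,
                "in_peak_reads": av.in_peak_reads,
                "gwas_snp": av.gwas_match["snp_id"] if av.gwas_match else ".",
                "gwas_trait": av.gwas_match["trait"] if av.gwas_match else ".",
                "gwas_keyword": av.gwas_match["keyword"] if av.gwas_match else ".",
                "ld_partner": av.ld_proxy_of["snp_id"] if av.ld_proxy_of else ".",
                "ld_r2": av.ld_proxy_of["r2"] if av.ld_proxy_of else np.nan,
                "ld_distance": av.ld_proxy_of["distance"] if av.ld_proxy_of else np.nan,
                "hm_overlap": av.hm_overlap,
            }
        )
    return pd.DataFrame(rows)
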