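"""Fragment-extension pileup peak calling for single-end ChIP-seq.

The caller mirrors the classic pre-MACS recipe for transcription-factor
ChIP-seq on single-end reads: keep one read per start position, extend each
read in silico to the mean sonication fragment length (170 bp by default),
count overlapping fragments per base, and report maximal runs of coverage
strictly above a threshold. The summit is the leftmost position attaining
the run maximum. Downstream annotation adds input-chromatin filtering,
per-sample peak-count capping, and E-box motif scanning around summits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np

from .io_formats import AlignedRead, GenomicInterval, fetch_sequence

# E-box family recognized by USF1: CA[C/T]GTG and its reverse complements
# CAC[G/A]TG. The four strings below are closed under reverse complement,
# so a forward-strand scan is equivalent to scanning both strands.
EBOX_PATTERNS = ("CACGTG", "CACATG", "CATGTG")


@dataclass(frozen=True)
class PeakCallConfig:
    """Parameters of the fragment-extension caller.

    fragment_length
        Mean fragment length the reads are extended to, bp.
    min_height
        Pileup threshold; coverage must be STRICTLY greater to be in a peak
        (the study used 10 for the control and 5 for the deeper-noise ASH
        library). Set ``min_height_inclusive`` to use >= instead.
    input_ratio
        A peak is discarded when the input-chromatin pileup at its summit is
        at least this fraction of the peak height.
    motif_window
        Half-width, bp, of the summit-centred window scanned for E-boxes.
    """

    fragment_length: int = 170
    min_height: int = 10
    min_height_inclusive: bool = False
    input_ratio: float = 0.25
    motif_window: int = 50
    motif_patterns: tuple[str, ...] = EBOX_PATTERNS
    strand_blind_dedup: bool = False

    def __post_init__(self) -> None:
        if self.fragment_length <= 0:
            raise ValueError("fragment_length must be positive")
        if self.min_height < 1:
            raise ValueError("min_height must be >= 1")
        if not 0 <= self.input_ratio < 1:
            raise ValueError("input_ratio must be in [0, 1)")
        if self.motif_window < 0:
            raise ValueError("motif_window must be >= 0")


@dataclass
class Peak:
    """A called enrichment region with its summit and height."""

    interval: GenomicInterval
    summit: int
    height: int
    height_rpm: Optional[float] = None
    motif_hit_count: int = 0
    sample_id: str = ""
    mark: str = ""
    score: Optional[float] = None  # ranking score for imported peak lists

    def __post_init__(self) -> None:
        if not self.interval.start <= self.summit < self.interval.end:
            raise ValueError("summit must lie within the peak interval")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def deduplicate_reads(
    reads: Iterable[AlignedRead], strand_blind: bool = False
) -> list[AlignedRead]:
    """Retain one read per start position.

    The dedup key is (chrom, start, strand), start being the leftmost
    aligned position; with ``strand_blind`` the strand is dropped from the
    key. Output is sorted for determinism.
    """
    seen: dict = {}
    for r in reads:
        key = (r.chrom, r.start) if strand_blind else (r.chrom, r.start, r.strand)
        if key not in seen:
            seen[key] = r
    return sorted(seen.values(), key=lambda r: (r.chrom, r.start, r.end, r.strand))


def extend_and_pileup(
    reads: Iterable[AlignedRead],
    config: PeakCallConfig,
    chrom_sizes: Mapping[str, int],
) -> Dict[str, np.ndarray]:
    """Extend reads to fragments and count per-base fragment overlap.

    A ``+`` read becomes the fragment [start, start+L); a ``-`` read becomes
    [end-L, end). Fragments are clipped at chromosome edges. Returns one
    int32 coverage array per chromosome.
    """
    L = config.fragment_length
    # difference-array accumulation: O(reads + genome)
    delta = {c: np.zeros(n + 1, dtype=np.int32) for c, n in chrom_sizes.items()}
    for r in reads:
        if r.chrom not in delta:
            continue
        n = chrom_sizes[r.chrom]
        if r.strand == "+":
            s, e = r.start, r.start + L
        else:
            s, e = r.end - L, r.end
        s, e = max(0, s), min(n, e)
        if s >= e:
            continue
        delta[r.chrom][s] += 1
        delta[r.chrom][e] -= 1
    return {c: np.cumsum(d[:-1]).astype(np.int32) for c, d in delta.items()}


def call_peaks(
    coverage: Mapping[str, np.ndarray],
    config: PeakCallConfig,
    sample_id: str = "",
    mark: str = "",
) -> list[Peak]:
    """Extract maximal runs of coverage above the threshold.

    Each peak is a maximal run of positions with coverage > min_height
    (>= when ``min_height_inclusive``); its summit is the leftmost position
    attaining the run maximum and its height that maximum.
    """
    peaks: list[Peak] = []
    for chrom in sorted(coverage):
        cov = np.asarray(coverage[chrom])
        if config.min_height_inclusive:
            above = cov >= config.min_height
        else:
            above = cov > config.min_height
        if not above.any():
            continue
        # vectorized run extraction on the boolean mask
        padded = np.concatenate(([0], above.view(np.int8), [0]))
        d = np.diff(padded)
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        for s, e in zip(run_starts, run_ends):
            seg = cov[s:e]
            off = int(np.argmax(seg))  # np.argmax returns the first maximum
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, int(s), int(e)),
                    summit=int(s) + off,
                    height=int(seg[off]),
                    sample_id=sample_id,
                    mark=mark,
                )
            )
    return peaks


def add_rpm_heights(peaks: Sequence[Peak], total_mapped: int) -> list[Peak]:
    """Attach RPM-normalized heights: height x 1e6 / total mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    for p in peaks:
        p.height_rpm = p.height * 1e6 / total_mapped
    return list(peaks)


def filter_by_input(
    peaks: Sequence[Peak],
    input_coverage: Mapping[str, np.ndarray],
    config: PeakCallConfig,
) -> tuple[list[Peak], int]:
    """Drop peaks enriched in input chromatin.

    A peak is removed when the input pileup at its summit is at least
    ``input_ratio`` x its ChIP height. Returns (retained peaks, n removed).
    """
    kept = []
    removed = 0
    for p in peaks:
        cov = input_coverage.get(p.chrom)
        at_summit = int(cov[p.summit]) if cov is not None and p.summit < len(cov) else 0
        if at_summit >= config.input_ratio * p.height:
            removed += 1
        else:
            kept.append(p)
    return kept, removed


def select_top_peaks(
    peak_sets: Mapping[str, Sequence[Peak]],
    round_to: int = 1000,
    score_key: str = "height_rpm",
    descending: bool = True,
) -> dict[str, list[Peak]]:
    """Cap every sample's peak list at a common rounded count.

    N = floor(min sample peak count / round_to) * round_to; each sample keeps
    its N best-ranked peaks (by ``score_key``, default RPM height; imported
    MACS lists rank by their score/p-value column). Ties break by genomic
    order.
    """
    if not peak_sets:
        raise ValueError("no peak sets supplied")
    n_min = min(len(v) for v in peak_sets.values())
    n_keep = (n_min // round_to) * round_to
    if n_keep == 0:
        raise ValueError(
            f"fewest peaks ({n_min}) rounds down to 0 at round_to={round_to}; "
            "use a smaller round_to"
        )

    def sort_key(p: Peak):
        score = getattr(p, score_key, None)
        if score is None:
            score = p.score if p.score is not None else p.height
        primary = -score if descending else score
        return (primary, p.chrom, p.interval.start, p.interval.end)

    return {
        sample: sorted(peaks, key=sort_key)[:n_keep]
        for sample, peaks in peak_sets.items()
    }


def _count_pattern_hits(seq: str, patterns: Sequence[str]) -> int:
    """Count (possibly overlapping) occurrences of any pattern."""
    rx = re.compile("(?=(" + "|".join(patterns) + "))")
    return sum(1 for _ in rx.finditer(seq))


def scan_ebox(
    peaks: Sequence[Peak], genome, config: PeakCallConfig
) -> tuple[list[Peak], dict]:
    """Annotate peaks with E-box hits within ``motif_window`` of the summit.

    The scanned window is [summit - w, summit + w + 6) so a hexamer starting
    anywhere within +/- w of the summit is counted. The pattern set is closed
    under reverse complement, so the forward-strand scan covers both strands.
    Returns the annotated peaks and a summary dict with ``n_with_motif`` and
    ``fraction``.
    """
    w = config.motif_window
    motif_len = max(len(p) for p in config.motif_patterns)
    for p in peaks:
        window = GenomicInterval(
            p.chrom, max(0, p.summit - w), p.summit + w + motif_len
        )
        seq = fetch_sequence(genome, window)
        p.motif_hit_count = _count_pattern_hits(seq, config.motif_patterns)
    n_hit = sum(1 for p in peaks if p.motif_hit_count > 0)
    summary = {
        "n_peaks": len(peaks),
        "n_with_motif": n_hit,
        "fraction": n_hit / len(peaks) if peaks else float("nan"),
    }
    return list(peaks), summary


def peaks_to_intervals(peaks: Sequence[Peak]) -> list[GenomicInterval]:
    return [
        GenomicInterval(
            p.chrom,
            p.interval.start,
            p.interval.end,
            name=f"{p.sample_id}:{p.mark}" if p.sample_id or p.mark else None,
            score=p.height_rpm if p.height_rpm is not None else float(p.height),
            summit_offset=p.summit - p.interval.start,
        )
        for p in peaks
    ]


def intervals_to_peaks(
    intervals: Sequence[GenomicInterval], sample_id: str = "", mark: str = ""
) -> list[Peak]:
    """Lift imported (e.g. MACS narrowPeak) intervals to Peak objects.

    The narrowPeak signal column becomes the ranking score; a missing summit
    offset falls back to the interval midpoint.
    """
    peaks = []
    for iv in intervals:
        if iv.summit_offset is not None and iv.summit_offset >= 0:
            summit = iv.start + iv.summit_offset
        else:
            summit = iv.midpoint
        score = iv.score if iv.score is not None else 0.0
        peaks.append(
            Peak(
                interval=iv,
                summit=min(max(summit, iv.start), iv.end - 1),
                height=int(score) if score == int(score) else 1,
                height_rpm=score,
                score=score,
                sample_id=sample_id,
                mark=mark,
            )
        )
    return peaks
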