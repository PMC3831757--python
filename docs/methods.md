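# Methods

This note documents the models, rules and numerical choices behind
`chromdiff`, in the order the pipeline applies them.

## Peak calling by fragment extension

The caller targets single-end transcription-factor ChIP-seq. Reads are
first deduplicated to one read per (chromosome, start, strand) key — the
classic guard against PCR amplification artifacts; a strand-blind mode
(one read per position regardless of strand) is available behind
`strand_blind_dedup`. Each surviving read is extended in silico to the mean
sonication fragment length `fragment_length` (default 170 bp): a `+` read
becomes the fragment `[start, start+L)`, a `-` read `[end-L, end)`, clipped
at chromosome edges rather than discarded. Coverage is the per-base count
of overlapping fragments, accumulated with a difference array in
O(reads + genome).

Peaks are maximal runs of coverage strictly above `min_height`
(`min_height_inclusive` switches to >=; "more than N reads" is read as a
strict bound). The summit is the leftmost position attaining the run
maximum — a deterministic tie-break on plateaus — and the height is that
maximum, also reported depth-normalized as RPM (height x 10^6 / mapped
reads). Threshold choice is per-library: it should sit well above the
background coverage mean (background rate x fragment length) and below
expected peak heights; the synthetic study uses 10 for both samples, where
background coverage averages 2–3 and planted peaks ~55.

Input-chromatin filtering is intentionally simple: a peak is dropped when
the input pileup at its summit is at least `input_ratio` (default 0.25)
times the peak height. The ratio is a knob because no universally agreed
criterion exists for "enriched also in input"; 0.25 removes regions whose
apparent enrichment is a quarter or more explainable by input signal.

To compare samples of very different sequencing depth on an equal footing,
`select_top_peaks` keeps the same number of best-ranked peaks from every
sample: N is the smallest per-sample peak count rounded down to a multiple
of `round_to` (default 1000). Rank is RPM height for the built-in caller,
or the score column for imported narrowPeak lists; ties break by genomic
order.

## E-box motif annotation

USF1 binds the degenerate E-box CA[C/T]GTG, whose reverse-complement
family is CAC[G/A]TG. The scanner searches the forward strand for the set
{CACGTG, CACATG, CATGTG}, which is closed under reverse complement, so a
single-strand scan is equivalent to a two-strand scan; overlapping
occurrences are counted as distinct start sites (a palindromic CACGTG is
one site). The window is `[summit - w, summit + w + 6)` with w = 50 bp, so
any hexamer starting within 50 bp of the summit is caught. The summary
reports the count and fraction of peaks with at least one hit.

## Differential histone-mark enrichment

Per mark, the two samples' peak sets are union-merged (overlapping or
book-ended intervals collapse) so no genomic region is counted twice, and
each region records whether it came from control, patient or both. Regions
with more than 80% of their bases covered by the simple-repeat track
(strictly > 0.8; union coverage, not summed) are removed as
repeat-dominated. Read counts per region are overlap counts normalized to
RPM, because the two libraries differ severalfold in depth; the difference
patient - control on the RPM scale ranks the regions, and the top `n_top`
per direction are the differentially enriched regions. No distributional
model or skew correction is applied — the statistic is deliberately the
plain ranked difference. Each region is assigned the gene with the TSS
closest to the region midpoint (summit when available), with the signed
distance negative when the TSS lies upstream of the anchor in the gene's
own orientation, and distance ties broken on the smaller gene id.

Classification uses two independent axes: TSS-proximal (any overlap with
TSS +/- 2 kb of any annotated gene, all biotypes) vs non-TSS, and
intragenic (any overlap with a gene body) vs intergenic. The six-category
tally crosses the three marks with the two differential directions.

## TSS footprints

Footprints aggregate full read-interval coverage (not 5' ends) at offsets
-1000..+1000 from the TSS of every protein-coding gene — 2001 positions —
with minus-strand genes flipped so positive offsets point in the direction
of transcription (`flip_minus_strand=False` reproduces unoriented
aggregation; fragment extension before aggregation is available by
piping extended reads in). Normalization is two-step: each mark's profile
is scaled to a common total sum S over the 2001 positions, then all marks
are divided by the single global maximum, so the maximal enrichment over
all marks equals exactly 1 while between-mark ratios from step 1 are
preserved. S = 2001 (mean 1 per position) — any constant yields the same
final output, this one makes the intermediate interpretable. The procedure
is idempotent, and a profile that is identically zero is an error rather
than a silent NaN.

## SNP cascade

Variants (one VCF per individual, called upstream on the pooled
histone-mark alignments) pass through, in order:

1. **Depth/quality filter** — retain iff depth <= 100 and quality >= 50.
   Depth above 100 flags collapsed repeats; both bounds retain at
   equality because the removal rules ("> 100", "< 50") are strict. Depth
   is the site DP (INFO, else summed FORMAT). Records missing either field
   go to an explicit missing-fields bucket; every stage's removals are
   tallied so input = retained + removals.
2. **Known/novel split** — known iff present in the build-129 id list;
   candidate-novel iff absent from both 129 and 132. Sites only in 132 are
   dropped from the novel set (the newer build knows them) without joining
   the known output. Identity is (chrom, pos) or rsID; an allele-checking
   flag exists for id lists that carry alleles.
3. **Peak restriction** — novel sites are kept when they fall inside a
   differential peak region with depth >= 10 (the "peak regions" default is
   the differential regions; a flag widens it to all peaks).
4. **GWAS overlap** — a variant matches when its position (or rsID)
   coincides with a catalogue SNP whose trait, lowercased, contains one of
   the liver/metabolic keywords (diabetes, fasting plasma glucose,
   hepatitis, hepatocellular carcinoma, insulin, LDL cholesterol, lipid
   metabolism, liver, obesity, triglycerides) as a substring — transparent,
   no stemming.
5. **LD expansion** — a non-matched variant is a proxy when the LD table
   links it to a keyword-matched catalogue SNP with r^2 >= 0.8 and
   |distance| <= 500 kb, both bounds inclusive ("threshold"/"limit" read as
   attained); the strongest-r^2 partner is recorded.
6. **Histone-peak category** — each variant is labelled control_only /
   patient_only / both / none by point membership in the two samples'
   pooled peak intervals; the four labels partition the set.

## qPCR enrichment call

The background level is mean + 2 x SD of the negative-control regions
(sample SD, ddof = 1 — the conservative choice when the divisor is
unspecified; a population-SD flag exists), and a region is called positive
only when its enrichment strictly exceeds two-fold that background.
Agreement between ChIP-seq heights and qPCR enrichment is the squared
Pearson correlation over paired regions, reported as missing when either
vector is constant or fewer than three pairs exist.

## Synthetic study

The generator emulates the target study design — patient and control
samples, three histone marks plus one TF — at desk scale: by default two
300 kb chromosomes, 80 genes, 40 TF peaks (60% with a planted E-box within
40 bp of the summit), 40 peaks per histone mark of which 30% are
differential (fold 5, half per direction; a quarter of those are
sample-exclusive), 3 input artifact regions, 20 repeats, and 300/150
variants (patient/control) with planted depth, quality, dbSNP, GWAS and LD
classes. Patient libraries are 1.7x deeper than control, mirroring the
asymmetric library sizes typical of two-sample designs; RPM normalization
is what absorbs that asymmetry downstream.

Reads are 50 bp single-end. Background read starts are per-base Poisson at
`background_rate` (0.01/bp). A planted peak draws
Poisson((multiplier - 1) x rate x width) fragments whose 170 bp extent
always covers the planted summit — fragment starts uniform on
[summit-169, summit] — so the pileup maximum sits at the summit, as
sonicated ChIP fragments do around a bound site; the sequenced read is the
5' 50 bp of a + fragment or the 3' 50 bp of a - fragment, so fragment
extension reconstructs the fragment exactly. `peak_base_rate` decouples
peak read density from the background rate when a read-free background is
wanted. Every stage draws from its own generator seeded from (seed, stage),
making outputs byte-identical under a fixed seed and stages independently
reproducible.

What the generator does **not** model: sequencing errors, mappability and
GC bias, paired-end inserts, chromatin accessibility structure, overlap
between peaks of different marks, or genes co-located with peaks by
design. Passing recovery tests therefore demonstrate the correctness of
the pipeline's logic under its stated read model, not robustness to real
library artifacts.

## Problem sizes and expected recovery

At the default scale the complete pipeline runs in a few seconds. Under
the default rates (multiplier 20 over 0.01 reads/bp), planted TF peaks are
recovered at 100% with mean summit error under 2 bp, all planted
differential regions land in the correct direction's top list when the
per-direction list length equals the planted per-direction count (the
desk-scale analogue of the fixed top-1000), and the SNP cascade reproduces
the planted class counts exactly. The per-direction list length for
recovery checks is taken from the planted truth because the claim under
test is exact recovery of the planted set.

## Known limitations

- The input-chromatin filter criterion (summit ratio 0.25) is one
  reasonable operationalization among several; real analyses may prefer a
  local-lambda test.
- `nearest_tss` is exhaustive per chromosome and `count_reads_in_regions`
  sorts once per read set; both are comfortable at desk scale and up to a
  few million reads, but a production genome-scale run would want an
  interval index.
- The caller reports no significance estimate (no FDR); thresholds are
  absolute pileup heights by design.
- Two-strand dedup keyed on the leftmost coordinate treats a +/- pair at
  the same position as two observations; libraries with severe strand
  imbalance may prefer the strand-blind mode.
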