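# chromdiff

Differential ChIP-seq analysis of histone modifications and
transcription-factor binding between a diseased and a normal tissue
sample — built for the two-sample, no-replicate designs typical of
biobank tissue studies (e.g. alcoholic steatohepatitis vs normal liver),
where standard replicate-based differential tools do not apply.

The package implements, as a tested and reusable library plus CLI:

- a **fragment-extension pileup peak caller** for single-end TF ChIP-seq:
  one read per start position, in-silico extension to the mean fragment
  length L (default 170 bp), per-base fragment-overlap coverage, peaks as
  maximal runs with coverage > h, summit at the leftmost run maximum,
  heights in RPM (height x 10^6 / mapped reads), input-chromatin
  filtering, and equal-depth capping of peak lists (top N, N = smallest
  sample count rounded to thousands);
- **E-box motif annotation** — occurrences of CA[C/T]GTG (scanning the
  reverse-complement-closed set {CACGTG, CACATG, CATGTG}) within 50 bp of
  each summit;
- **differential histone-mark ranking**: union-merged peak regions,
  repeat-dominated regions (> 80% simpleRepeat coverage) removed,
  per-region RPM in both samples, regions ranked by
  Delta = RPM_patient - RPM_control, top n per direction kept, each
  region assigned the gene with the closest TSS;
- **TSS footprints**: strand-oriented mean coverage over 2001 positions
  (TSS +/- 1 kb) across protein-coding genes, each mark normalized to a
  common total and all marks scaled so the global maximum is 1;
- **genomic classification** of regions (TSS +/- 2 kb vs non-TSS,
  intragenic vs intergenic) and per-gene peak presence (both samples /
  one sample only);
- a **regulatory SNP cascade**: depth <= 100 and quality >= 50 filters, a
  known/novel split against dbSNP-style build lists (129, then 132),
  restriction of novel sites to peak regions with >= 10 reads, GWAS
  catalogue overlap by disease keyword, LD-proxy expansion (r^2 >= 0.8
  within 500 kb), and histone-peak overlap categories;
- the **qPCR enrichment call**: background = mean + 2 SD of negative
  controls, positive iff enrichment > 2 x background, plus the squared
  Pearson agreement between ChIP-seq and qPCR;
- a **synthetic-data generator** that plants peaks, motifs, differential
  effects, repeats and variant classes with a full truth table, so every
  stage is testable without any download.

## Worked example

Generate a synthetic two-sample study and run the whole pipeline:

```sh
chromdiff run --seed 1 --outdir demo --n-top 12
```

The run writes per-sample USF1 peak lists (narrowPeak), differential
region tables, footprint matrices, classification tallies, annotated
variant tables and a `manifest.json`. With seed 1 the manifest reports,
among others:

```
callpeaks_control:   n_reads 8533, n_peaks 42, n_with_motif 24
callpeaks_patient:   n_reads 14344, n_peaks 43, n_with_motif 24
footprints:          n_positions 2001, global_max 1.0
snps_patient:        input 300 = retained 229 + removed 23+48+0
```

Reading: the caller finds 42/43 USF1 peaks (the generator planted 40 real
peaks plus 3 input artifacts, which the input filter removes), ~56% of
called peaks carry an E-box within 50 bp of the summit (60% were planted;
the rest of the calls sit on background), footprint normalization leaves
2001 positions with a global maximum of exactly 1, and the SNP cascade's
counts are conserved: every removed variant is accounted for by a reason.

The same stages run on real data via the other subcommands
(`chromdiff callpeaks|differential|footprint|classify|snps|qpcr --help`).

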