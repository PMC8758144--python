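# clipscope

Tools for two downstream analyses of protein–RNA crosslinking studies:

1. **PAR-CLIP crosslink analysis.** PAR-CLIP reads out direct protein–RNA
   contacts: 4-thiouridine incorporated into nascent RNA crosslinks to the
   bound protein under UV, and reverse transcription leaves a diagnostic
   T→C substitution at the crosslinked uridine. `clipscope` deduplicates
   reads by their random 3'-adapter barcode, classifies each mismatch as a
   T→C conversion versus noise, calls conversion-supported clusters with a
   kernel-density decision rule, builds metagene profiles on a common
   relative-position axis (5'-UTR → [−1, 0], CDS → [0, 1], 3'-UTR → [1, 2]),
   and classifies each mRNA as **5'-UTR enriched** (length-normalized 5'-UTR
   read density ≥ 20× the 3'-UTR density) or **pan-mRNA** (crosslinking
   spread along the transcript). Genes with ≥ 100 reads, ranked by 5'-UTR
   read density, form the input list for pathway analysis.

2. **Bead-registered colocalization.** For multi-channel 3D fluorescence
   stacks, multi-spectral beads imaged beside each cell calibrate the
   chromatic shift: each bead channel is registered to a reference by
   subvoxel cross-correlation, the same translation is applied to the cell
   stack, channels are background-thresholded (Otsu), and colocalization is
   quantified per channel pair as the Pearson correlation coefficient (PCC)
   of raw intensities. Samples whose bead channels correlate below 0.45 in
   any pair are excluded (insufficient dynamic range). Groups of PCCs are
   compared with an exact two-sided Wilcoxon rank-sum test (enumerated null
   for small samples, e.g. p = 2/252 ≈ 0.0079 for complete separation at
   n = 5 per group).

A synthetic-data module generates all inputs — transcript annotation (GTF),
abundance tables (TPM), reads (table or SAM with MD tags), and bead/cell
TIFF z-stacks — with ground-truth bookkeeping, so every stage can be
exercised and scored without external data.

## Worked example

Simulate 12 genes (half 5'-UTR-peaked, half pan-mRNA; 150 reads each with a
40 % PCR-duplication rate), deduplicate, and classify:

```sh
clipscope simulate reads --seed 5 --n-genes 12 --reads-per-gene 150 --outdir demo
# 2535 reads over 12 genes -> demo
clipscope dedup demo/reads.tsv --out demo/dedup.tsv
# retained 1800 reads
clipscope classify demo/dedup.tsv --gtf demo/annotation.gtf \
    --abundance demo/abundance.tsv --out demo/summary.tsv
```

The 2535 simulated reads collapse to exactly the 12 × 150 = 1800 unique
molecules. `demo/summary.tsv` then holds one row per gene:

```
gene_id  reads5  readsC  reads3  total  dens5   densC   dens3    ratio   label
G0000    133     10      7       150    1.900   0.0158  0.0129   147.66  utr5_enriched
G0001    138     8       4       150    1.408   0.0092  0.0136   103.50  utr5_enriched
...
G0006    21      75      54      150    0.208   0.1761  0.1298   1.60    pan_mRNA
G0007    39      67      44      150    0.109   0.1354  0.1406   0.77    pan_mRNA
```

`reads5/readsC/reads3` are reads assigned (by majority overlap) to the
5'-UTR + start codon, CDS + stop codon, and 3'-UTR; `dens*` divides each by
the region length in nt; `ratio = dens5/dens3` drives the label: the six
genes simulated with 5'-UTR-concentrated crosslinks land at ratios of
100–290 (≥ 20 → `utr5_enriched`), the six pan-mRNA genes at 0.8–1.8
(< 20 → `pan_mRNA`).

The same library API is available in Python (`clipscope.preprocess_reads`,
`clipscope.call_clusters_for_reads`, `clipscope.summarize_gene`,
`clipscope.analyze_sample`, `clipscope.ranksum_exact`, …); `clipscope
simulate stacks` plus `clipscope coloc` run the imaging pipeline on TIFFs.

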