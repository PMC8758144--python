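# Methods

## Transcript models and isoform selection

A transcript is represented in transcript coordinates (exons already
spliced; 0-based, half-open) by its 5'-UTR, coding span and 3'-UTR lengths.
The start and stop codons are the first and last 3 nt of the coding span,
the standard GTF convention, so `lenC` includes both and must be ≥ 6 nt.
Zero-length UTRs are legal; genes whose chosen isoform lacks a 5'- or
3'-UTR cannot support the density-ratio classifier and are flagged
`unclassifiable` rather than dropped, mirroring the treatment of transcripts
whose annotation is too complex to normalize.

Because crosslinking reads are short, the bound isoform is ambiguous; each
gene is represented by its most abundant isoform (highest TPM). Ties break
deterministically: longest transcript, then lexicographically smallest
transcript id. All-zero TPMs fall back to the longest transcript with a
warning. GTF input is GENCODE-dialect with the seqname naming the
transcript; parsing is line-based (via gffutils' feature parser) so
malformed input errors carry the line number. Genome-space exon-chain
projection is out of scope: reads are expected in transcript space.

## Read processing

* **Deduplication.** PCR duplicates share the random 3'-adapter barcode and
  the alignment coordinates. The collapse key is
  (transcript, start, end, strand, barcode) — not the barcode alone, which
  would merge distinct loci that happen to draw the same barcode. The
  representative is the first read in sorted order, making the operation
  deterministic and idempotent.
* **Conversion calling.** On '+' strand reads a T→C substitution (in
  reference orientation) is a conversion; on '−' strand reads the
  transcript-space appearance is A→G. The conversion pair is a parameter
  (`--conversion T,C`). Any substitution, including incidental sequencing
  errors that happen to read T→C, is classified by this rule alone — the
  caller cannot distinguish provenance, only pattern.
* **Filters.** Reads shorter than 20 nt or with more than 1 non-conversion
  mismatch are removed; conversions are exempt from the mismatch cap.
* **SAM ingestion** derives mismatches from the MD tag (via pysam's aligned
  pairs); a record without MD is a hard error — there is no reference-FASTA
  fallback. Barcodes ride in the read-name suffix after the last underscore.

## Cluster calling

A deliberately simplified conversion-aware caller, not a reimplementation of
a full two-state-HMM peak caller:

1. **Groups**: maximal intervals of transitively overlapping reads
   (overlap ≥ 1 nt); groups with < 5 reads are discarded.
2. **Smoothing**: per-position conversion events and non-conversion
   coverage events (coverage minus conversions) are each smoothed with a
   discrete Gaussian kernel, σ = 3 nt by default, truncated at 4σ and
   evaluated at integer positions. Positions covered by < 3 reads are
   masked (both tracks zeroed) and can never join a cluster.
3. **Decision rule**: each smoothed track is normalized to unit mass and a
   candidate cluster is a maximal unmasked run where the normalized
   conversion density is ≥ the normalized non-conversion density. The
   normalization is essential, and is the same comparison-of-likelihoods
   idea used by kernel-density CLIP peak callers: conversions are always a
   minority of raw coverage (at a 20–30 % conversion rate the raw conversion
   track can never exceed the raw coverage track anywhere), but conversions
   *concentrate* at crosslink sites while coverage is diffuse, so the
   normalized comparison finds exactly the locally over-converted region.
   Ties fall inside the run, so a conversion-only singleton can seed one. A
   group with zero conversions yields no candidates.
4. **Thresholds**: retained clusters need length ≥ 11 nt, ≥ 7 overlapping
   reads (any read overlapping by ≥ 1 nt counts), ≥ 2 distinct conversion
   locations and ≥ 2 conversion events, all applied to the final run
   boundaries.

With these defaults the caller recovers a planted crosslink site in ≈ 98 %
of 200 synthetic transcripts at sequencing depth 20 and conversion rate 0.3
(the packaged acceptance test).

## Metagene scale and classifier

Reads are assigned to 5'-UTR + start codon, CDS + stop codon, or 3'-UTR by
majority overlap of aligned bases, ties to the 5'-most region; the read
midpoint then sets the relative position. The axis is continuous by
construction: −(len5 − m)/len5 on the 5'-UTR (cap = −1, start codon = 0),
(m − len5)/lenC on the CDS, 1 + (m − len5 − lenC)/len3 on the 3'-UTR
(terminus = 2), each clamped to its segment. The orientation of the 5'-UTR
segment (cap at −1, not 0) is the only reading under which the three
segments abut continuously.

Per-gene region counts divided by region lengths give densities in
reads/nt; the enrichment statistic is `ratio = dens5/dens3`, and
`ratio ≥ 20` (inclusive — the cutoff is a soft boundary and a parameter)
labels the gene 5'-UTR enriched. `dens3 = 0` with 5'-UTR reads present maps
to ratio +∞ (enriched); a gene with no reads, or no 5'- or 3'-UTR, is
unclassifiable. Reads — not conversion events — are the counting unit
throughout. Gene ranking for pathway input keeps genes with ≥ 100 total
reads, sorts by dens5 (ties: total reads, then gene id) and truncates to
500.

ECDFs over pooled relative positions are plain right-continuous empirical
CDFs with multiset semantics. Note that for pan-mRNA (uniform-in-nt) reads
the pooled ECDF is piecewise linear with slopes proportional to the mean
region-length fractions, not globally diagonal; the tests compare it
against that mixture form computed from the generator's own geometry.

## Colocalization

* **Registration** is translation-only (chromatic shift is translational to
  first order at this field size): each bead channel is registered to the
  reference channel by cross-correlation with subvoxel (upsampled) peak
  refinement, in voxel units; voxel size (default 35 × 35 × 190 nm) is
  metadata for physical-unit reporting only. The estimated vector is the
  channel's feature displacement; applying a registration translates by its
  negation with linear interpolation, and out-of-frame voxels join an
  invalidity mask excluded from all correlations.
* **Thresholding** is two-class Otsu per channel (deterministic, standard
  for background removal; exposed as a parameter). A channel whose two Otsu
  classes are separated by less than 4 background standard deviations is
  treated as all-background: warning plus empty mask. A constant channel is
  an error.
* **PCC** is computed on raw intensities over the union of the two
  channels' masks intersected with the validity region (union, so that
  signal present in only one channel correctly depresses the coefficient);
  a whole-image mode is available for sensitivity analysis. Degenerate
  evaluation sets (< 2 voxels or zero variance) are errors.
* **QC**: a sample is excluded iff any off-diagonal bead-channel PCC is
  strictly below 0.45; the boundary value itself passes.
* **Rank-sum test**: for n1 + n2 ≤ 20 the two-sided p-value is exact — the
  rank-sum statistic (midranks under ties) is evaluated over every
  assignment of pooled values to groups, and the two-sided p is twice the
  smaller one-sided tail, capped at 1. Larger samples use the tie-corrected
  normal approximation. Identical pooled values give p = 1.

## Synthetic data

The read generator emulates the statistical structure the analysis assumes,
not a sequencing instrument. Feature lengths are gamma-distributed
(shape 4) around means of 150/900/450 nt for 5'-UTR/CDS/3'-UTR — typical
human mRNA proportions — floored at 20/60/30 nt, with the CDS rounded to
codons. Each gene has 1–3 isoforms with gamma-distributed TPMs; the maximum
defines the true primary isoform. Crosslink positions follow the gene's
class: pan-mRNA genes are uniform along the transcript; 5'-UTR-peaked genes
draw from a Beta(2,2) hump across the 5'-UTR with a 10 % uniform leak over
the whole transcript, which keeps 3'-UTR counts nonzero so the ratio
statistic stays finite and exercisable near its threshold. Reads
(25–35 nt) cover their crosslink position at a uniform offset. Conversions
are planted at covered Ts within ±3 nt of the crosslink position at the
configured rate (default 0.25) — the PAR-CLIP signature of conversions
concentrating at the crosslinked uridine; a `per_t` mode instead converts
every covered T independently, for distribution-level checks. Substitution
noise hits each covered nt at rate 0.002 with a uniformly random alternate
base (so a small fraction of noise is indistinguishable from conversion, as
in real data). Each molecule gets a random 8-mer barcode (collisions
allowed; truth tracks molecules, not barcodes) and is PCR-duplicated as an
exact copy with probability 0.4. Site-planting mode fixes one or more
crosslink sites per gene (forcing Ts at the site) for cluster-recovery
scoring. Not modeled: fragment-length bias, indels, quality scores,
alignment ambiguity.

The image generator renders spots as anisotropic 3D Gaussians at the
effective deconvolved resolution (σ ≈ 64 nm lateral, ≈ 212 nm axial,
i.e. ≈ 150/500 nm FWHM) in (z, y, x) stacks of 24 × 96 × 96 voxels by
default — a field cropped well below acquisition size to keep simulation
and registration fast while leaving ≥ 4σ margins. Beads are one spot field
rendered identically in all channels; cell channels share a fraction ρ of
spot positions (the planted colocalized fraction) with the remainder
independent. Each channel is displaced by its chromatic shift at render
time (continuous coordinates, hence exactly band-limited), so subvoxel
shifts are well defined. Noise is Poisson shot noise on signal plus
background (10 counts) plus a Gaussian read-noise floor (σ = 2). Not
modeled: real PSFs, depth-dependent aberrations, bleaching, or detector
artifacts — so passing tests demonstrate correctness of the registration
and correlation machinery, not robustness to microscope pathology.

## Numerical conventions and limitations

* All randomness flows from a mandatory config seed through
  `numpy.random.default_rng`; generators are bit-reproducible.
* Boundary conventions are half-open throughout; book-ended reads do not
  overlap; region-assignment ties go 5'-wards; the classification threshold
  and QC threshold are inclusive/exclusive exactly as stated above.
* The cluster caller is a simplification: no HMM, no genome-space merging,
  bandwidth fixed per run (σ = 3 nt default, exposed). Its thresholds are
  applied after run boundaries are fixed.
* Registration assumes deconvolved input and pure translation; rotation or
  scaling chromatic terms are not corrected.
* The read simulator draws each read independently; it does not model
  crosslink-site competition or per-gene abundance-dependent depth, so
  classifier accuracy on it bounds, but does not guarantee, accuracy on
  real libraries.
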