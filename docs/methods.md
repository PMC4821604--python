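# Methods

`nucshift` analyses paired wild-type (WT) / remodeler-mutant MNase-seq
mononucleosome libraries to locate nucleosomes whose positioning depends on an
ISWI-family sliding remodeler. This note records the models, the parameters
that matter, the synthetic data the tests run on, and the numerical choices
made where the design was genuinely open.

## Dyad density model

Each mononucleosome fragment protects ~147 bp of DNA centred on the nucleosome
dyad, so the dyad is estimated as the fragment midpoint, `floor((start+end)/2)`.
Fragments outside the mononucleosome size band are discarded first; the gate
defaults to [120, 180] bp (a tight gel-excision band around 147 bp).

Dyad counts per bp are smoothed with a Gaussian kernel into a continuous
per-bp signal interpreted as the relative probability of a dyad at each base.

* **Bandwidth** — 20 bp (Gaussian sd), default. It must resolve a ~10 bp
  difference in +1 position between conditions while suppressing per-bp
  sampling noise; 20 bp leaves two dyads 200 bp apart fully resolved and
  merges dyads closer than ~2 sd into one mode.
* **Kernel truncation** — ±4 sd, giving bounded compute and <1e-4 relative
  mass loss; mass is conserved before normalization up to truncation and
  chromosome-edge loss.
* **Normalization** — tracks are scaled so the genome-wide sum is exactly
  1e6 ("per-million"), making libraries of different depth comparable. The
  scaling factor is retained on the track; normalization is idempotent.

## Window shift calling

Chromosomes are tiled into non-overlapping 50-bp windows (a `step` option
supports sliding windows) and dyad counts per window are depth-normalized.
Both libraries are scaled to their geometric-mean total; this preserves the
mutant/WT count ratio of the usual one-sided scaling but makes the statistic
exactly antisymmetric under swapping the conditions, which the one-sided
scaling is not once the pseudocount enters. With a pseudocount of 1,

    log2fc = log2((n_mut_norm + 1) / (n_wt_norm + 1))

and a window is a *shift* when |log2fc| > 2 (two-sided by default: a
repositioned nucleosome necessarily produces a paired loss/gain; a
`one_sided` flag restricts to gains). The pseudocount stabilizes empty
windows; duplicating every fragment of one library can move log2fc only
through the pseudocount (by < 0.5). Runs of consecutive shifted windows
merge into regions. The fraction of genomic nucleosomes affected is
`100 * n_regions / (G / NRL)` for genome size G and genome-wide repeat
length NRL.

Merged regions are assigned to gene-feature classes by their midpoint with
fixed precedence upstream-1.5 kb > 5'UTR > 3'UTR > CDS exon > intron >
terminator flank (500 bp) > intergenic; enrichment over the genomic footprint
of each class is tested per class with a binomial test against the genome
fraction, Benjamini–Hochberg adjusted. UTR and exon extents come from
optional annotation columns; without them a gene is treated as a single exon.
For whole-chromosome views, region midpoints are binned into 4^order equal
bins and laid on the standard Hilbert curve (default order 9, 512×512, sub-kb
bins for a ~25 Mb chromosome arm); the mapping is bijective and consecutive
bins land in adjacent cells.

## Nucleosome arrays: +1 and NRL

The strand-oriented density averaged over a set of TSSs shows a ladder of
peaks. The +1 nucleosome is the first local maximum at offset ≥ +40 bp (the
search start skips the NDR shoulder; the search ends at +1300 bp because
condition differences fade ~1.2 kb into gene bodies). Peaks need prominence
≥ 5% of the profile maximum over the search range; up to six are kept. The
nucleosome repeat length (NRL) is the least-squares slope of peak offset on
nucleosome index over peaks +1..+5 — later peaks may mix positioning regimes
(arrays reset after roughly six nucleosomes) and are excluded from the
regression. The reported +1 is the first detected peak itself, not the
regression value at index 1. On a noise-free lattice the fit is exact
(slope to machine precision, r² = 1). Condition comparison reports per-index
dyad shifts (mut − wt), the NRL difference, and the first index at which the
shift falls below a 5-bp resolution floor.

Gene-level groupings reuse one machinery: activity (a gene is active iff its
mean promoter H3K4me3 over a strand-oriented 500-bp window exceeds 2× the
genome-wide mean — a scale-invariant rule that is exact on the synthetic
track), expression quintiles (descending stable sort, earlier bins take the
remainder), and core-promoter classes (genes with several element labels
contribute to each).

## Site classification

Around a point site (TF motif hit, insulator summit) three ratio-type scores
are computed per condition from the density: an occupancy ratio (mean over
summit ± 73 bp over the mean of the remaining ±1000 bp window), the distance
and prominence of the nearest density peak (peaks gated at 20% of the local
window maximum), and a phasing score (maximum over lags 150–200 bp of the
flank density autocorrelation, averaged over the two flank sides; a pure
185-bp cosine scores 1 at lag 185). The decision cascade is:

1. WT occupancy ratio < 0.5 → depleted branch: **V (barrier)** when the
   flanks are phased (score ≥ 0.3) in *both* conditions, else **IV
   (depleted)**. Requiring phasing in both conditions reflects the biology —
   barrier arrays persist in the mutant, merely migrating inward, while
   depleted domains fill in and lose periodicity — and is statistically
   necessary: the per-site autocorrelation over a ~930-bp flank has noise sd
   ~0.2, so a single-condition rule misroutes a large fraction of depleted
   sites.
2. Otherwise **I (occupied, remodeler-independent)** when the WT occupancy
   ratio exceeds 1.2, the nearest WT peak is within 40 bp, and the mutant
   peak persists within 20 bp of it.
3. Otherwise **III (entry/exit)** for a WT nearest-peak distance in
   [50, 90] bp, or **II (adjacent)** for (90, 160] bp, in each case only when
   the position is *lost* in the mutant: the mutant's nearest peak drifts by
   more than 30 bp or its prominence collapses below half the WT value.
4. Unresolvable sites default to I with a low-confidence flag.

All cut-offs derive from nucleosome geometry (±73 bp core, ~185 bp repeat
linkers) and are exposed in a thresholds dataclass. Because every score is a
ratio, the classification is invariant under genome-wide rescaling.

The NDR half-width estimator scans outward from the summit in 10-bp shells
and reports the largest extent over which the shell mean stays below
`threshold_frac` × a flank reference (the mean over the outer 40% of the
±1000 bp window). The default `threshold_frac` is 0.25: with a 20-bp
smoothing bandwidth the rising Gaussian edge of the boundary nucleosome
crosses a quarter of the flank level ~55 bp before its dyad, which places
the crossing close to the NDR boundary for boundary nucleosomes whose dyad
sits one nucleosome half-width beyond the open DNA. On hard-edged synthetic
tracks (zero density inside, uniform flanks) the estimator recovers the
constructed half-width to the scan step at any threshold.

## Synthetic data generator

The generator emulates the study conditions on a toy chromosome; every dyad
comes from an explicit emission component, and the component list is kept so
expected per-window counts — and hence analytically true shifted windows at
the caller's own statistic — are available independently of sampling.

* **Gene presets** (per-condition +1 / NRL in bp): WT active 132/175, mutant
  active 123/170; WT and mutant inactive identical at 185 (no printed +1; the
  generator uses 132 with larger fuzz so only the NRL is a recovery target);
  paused (INR/MTE/DPE) 142/175 in both conditions; expression quintiles with
  +1 interpolated from 136 (highest) to 125 (lowest), mutants shifted −9 bp
  at NRL 170. Eight nucleosomes per array, 30 dyads per nucleosome.
* **Positional fuzz** — 15 bp (active), 25 bp (inactive). Active arrays must
  support ±3 bp recovery of +1 and NRL at 200 genes; inactive arrays are
  visibly less well defined yet still yield a regression NRL.
* **Fragment model** — length ~ Normal(147, 10) truncated to [120, 180],
  start = dyad − floor(L/2). The gel band motivates a tight distribution; the
  exact law is this package's choice.
* **NDR** — genes: open DNA over [TSS − 150, +1 dyad − 73]. Sites: the NDR
  parameter is the distance from the summit to the boundary of nucleosomal
  DNA; phased flank dyads start one nucleosome half-width (73 bp) beyond it.
  Insulator/barrier presets use half-width 200 bp (WT) vs 125 bp (mutant)
  with 185-bp phased flanks of five nucleosomes per side.
* **Site classes I–III** sit in ambient fuzzy chromatin at 0.12 dyads/bp with
  a positioned nucleosome dyad at 0 / 70 / 120 bp from the summit (class
  I / III / II); in the mutant the class II/III nucleosome is removed. Class
  IV flanks carry uniform fuzzy coverage at one nucleosome per 185 bp
  (0.162 dyads/bp) and the mutant NDR fills in to the same level. These
  rates are geometry-derived defaults of this package.
* **Background** — 5% of dyads, uniform over the chromosome, with equal
  expected counts in both conditions.
* Genes alternate strands on a 6-kb grid (4-kb bodies, three exons, 200/300
  bp UTRs); sites sit on a 4-kb grid. The H3K4me3 track is 1 over active
  promoters' [TSS, TSS+500] and 0 elsewhere, so activity calls can be checked
  exactly. A seed fixes the complete output byte-for-byte.

**What the generator does not emulate:** sequence (no FASTA/FASTQ), MNase
sequence bias, ChIP immunoprecipitation noise, replicate structure, copy
number, or the mixture of architectures real loci show. Passing recovery
tests therefore demonstrates the estimators are unbiased and appropriately
precise under the stated architectures — not that real libraries meet those
assumptions.

## Problem sizes and determinism

Recovery runs use 200 genes × 8 nucleosomes × 30 dyads (~50k fragments per
condition) on a ~1.2-Mb chromosome, and 100 sites per class (~175k fragments)
for classification; both finish in seconds and give sub-bp standard errors on
the averaged-profile peaks. All randomness flows through one
`numpy.random.default_rng(seed)`; identical configurations reproduce
byte-identical outputs.

## Known limitations

* Shift calling has no replicate-aware dispersion model; libraries are
  treated as pooled counts (two replicates per genotype pooled upstream).
* Per-site classification needs adequate local coverage (~150 dyads per
  flank); at lower depth the phasing score becomes uninformative, and sites
  whose scores are undefined are reported unclassified rather than guessed.
* The 132→123 bp lattice change on active genes moves window occupancies by
  well under 4-fold, so individual gene-body windows do not exceed the
  |log2fc| > 2 threshold; array-level changes are the domain of the +1/NRL
  fits, while window shift calling targets wholesale losses, gains and
  migrations at regulatory elements.
* The NDR estimator's threshold-crossing logic is calibrated for
  kernel-smoothed tracks; on unsmoothed tracks it remains consistent but
  conservative near soft edges.
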