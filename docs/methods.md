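# Methods

This note documents the models, conventions and numerical choices behind
`ribotrans`, in the order data flows through the pipeline, and states
what the synthetic validation does and does not show about real data.

## Coordinates and gene models

All coordinates are 0-based, half-open (BED convention). A gene model is
four transcript landmarks in genomic coordinates — TSS, CDS start, CDS
end (start codon to stop codon), 3′UTR end — increasing on the plus
strand and mirrored on the minus strand, so each field keeps its
transcript meaning on both strands. The CDS length must be a multiple of
3. Transcript position of a genomic coordinate p is `p − tss` (plus) or
`tss − 1 − p` (minus).

## Counting

* **P-site offset (default 15 nt).** A footprint's 5′ end sits a fixed
  distance upstream of the ribosome's decoding site; shifting by 15 nt
  towards the 3′ end of the transcript places the assigned position at
  the P-site. On the minus strand the 5′ end is `end − 1` and the shift
  runs towards lower coordinates. mRNA reads are not shifted. An offset
  not smaller than the read length is a contract violation.
* **TSS exclusion (default 50 nt).** A read contributes to CDS abundance
  only if its assigned position is ≥ 50 nt from the TSS in *transcript*
  coordinates, so the window clips the CDS only when the 5′UTR is
  shorter than 50 nt. The window is anchored at the TSS; anchoring at
  the start codon instead can be had by passing `tss_exclusion=0` and
  trimming models, but is not a first-class flag because the abundance
  definition used throughout anchors at the TSS. UTR occupancy counts
  never apply the window: it is a bias correction for abundance
  estimation, whereas 5′UTR occupancy is itself the signal of interest.
* **Ambiguity and strand.** Positions inside two overlapping same-strand
  loci count for neither gene (tallied `ambiguous`); reads over a locus
  on the opposite strand are ignored (`wrong_strand` tally); positions
  in no annotated region are `unassigned`. Synthetic genes never
  overlap, so these paths matter only for real annotations.
* The vectorized counter (sorted positions + cumulative weights +
  boundary search) is checked exactly against a transcript-coordinate
  brute-force oracle and against the generator's own tallies in the test
  suite.

## Fold changes and the local σ

Per assay, genes with < 128 combined raw CDS reads (both conditions) are
excluded. The fold change is the library-normalized count ratio with a
symmetric pseudocount of 0.5 (bounded shrinkage for zeros that survive
the filter), rescaled so the median over analysed genes is exactly 1
(midpoint convention for even counts — exactness is asserted to 1e−12
for odd counts).

σ_i is the sample standard deviation (about the neighborhood mean, n−1
denominator) of log2 fold changes over gene i plus the k = 100 genes
with the nearest combined read count; read-count ties break by gene-id
order, making the neighborhood deterministic. A floor of 0.05 log2 units
prevents infinite z in degenerate neighborhoods. Zero-centered σ is
available via `center="zero"`. z = log2(F)/σ is invariant to the log
base as long as numerator and σ share it; log2 is used for all reported
columns. p-values are two-sided normal; a Benjamini–Hochberg column
(`q_bh`) is emitted as a convenience extra, not used by any downstream
rule.

On null simulations (5000 genes, depth 200, dispersion slope 0.5) the
fraction of |z| > 2 lands near the nominal 4.6% (measured ≈ 4.3–4.8%),
which is what the read-depth-local σ is for: a global σ would be
mis-calibrated at both coverage extremes.

## Translational efficiency

TE change = footprint F ÷ mRNA F for genes passing the 128-read filter
in **both** assays independently. The TE z divides log2(TE) by the
global sample SD of log2(TE) without mean-centering: the two fold
changes are already median-centered, so log2(TE) sits near zero, and
this reading matches the definition of normalizing the efficiency change
by its standard deviation. A centering flag and a read-depth-local SD
variant (`local_k`) exist for sensitivity analyses. If the SD is
numerically zero all z are zero.

Note one consequence of a global SD: planted (or real) TE outliers
inflate the denominator, so the threshold te_z > 2 becomes conservative
exactly when many genes change — at 4% of genes shifted 4-fold the
effective log2-TE threshold rises from ≈1.2 to ≈1.46, which together
with filter losses puts planted-effect sensitivity at ≈0.78–0.84 per
seed at depth 200 (false-positive rate ≈ 1%).

## Module scores

Signed WMW rank-sum z: U for members vs non-members, normal
approximation with tie-corrected variance and no continuity correction
(accurate for universes of thousands of genes; exact-permutation
agreement on ≤ 10-gene instances is part of the validation). The scored
universe is the set of genes passing the relevant assay's read filter;
memberships outside it are dropped before the ≥ 15-member check. A
module equal to the whole universe is reported as unscorable, not an
exception. Because the statistic is rank-based, scoring raw or log fold
changes is identical.

## 5′UTR loading classes

Per gene and condition the occupancy ratio is 5′UTR footprints / CDS
footprints (undefined when the CDS count is 0; such genes are excluded
from ratio summaries). Region fold changes between conditions use the
same per-library totals as gene-level fold changes and a 0.5
pseudocount; they are **not** re-median-centered per region, since both
regions share the library. Classes use d = log2(fc_CDS) − log2(fc_5′UTR)
with a diagonal band of half-width delta = 1 log2 unit (two-fold): the
class boundary is not a published constant, so delta is a first-class
parameter. Classification requires ≥ 16 footprints (5′UTR + CDS) per
condition; by default only TE-up genes are classified
(`classify_all=True` evaluates the classifier on every gene, which is
how the planted-class recovery is measured). Group summaries report both
the pooled ratio (Σ5′UTR/ΣCDS) and the median of per-gene ratios, with
an explicit outlier-exclusion id list for mechanistically distinct genes
of the GCN4 kind.

## Codon analysis

Codons are read in frame from the CDS; the terminal stop codon is
excluded from numerator and denominator (an `include_stop` flag exists);
codons containing N are dropped from both; internal stops and
non-multiple-of-3 lengths are errors naming the gene. K = AAA/AAG,
Q = CAA/CAG, E = GAA/GAG, M = ATG. Pearson r between a frequency and
log2 TE (raw-ratio flag available) uses the t-distribution p with n−2
df; a constant frequency vector is a degenerate-input error, not r = 0.
The gene-set contrast reuses the rank-sum machinery on freq_KQE and on
log2 TE and reports member-only and complement-only correlations, the
latter reproducing exclusion analyses ("is the global correlation
carried by this category?").

## Synthetic data generator

The generator emulates a yeast-like experiment; its defaults are the
study conditions used throughout the validation.

* **Architecture.** Geometric UTR lengths (5′ mean 60 nt, 3′ mean
  120 nt), log-normal CDS lengths (median ≈ 446 codons, log2 SD 0.6,
  ≥ 10 codons), genes laid head-to-tail with 200-nt gaps (no overlap);
  all plus strand by default, `minus_strand_fraction` mirrors a random
  subset to exercise strand handling.
* **Sequences.** ATG start, uniform stop, middle codons drawn KQE with
  per-gene probability from a Beta with mean 0.18 and SD 0.05 (total
  K+Q+E codon usage in yeast is ≈ 16–18%), no internal stops.
* **Counts.** Negative binomial with variance μ + φμ², φ =
  dispersion_slope/√μ (default slope 0.5) — dispersion decays with
  coverage, which is the regime the local-σ estimator is designed for.
  Per-gene expression is log-normal with log2 SD 0.75: this emulates the
  dynamic range of the *detected* gene population that survives a
  128-read filter at depth ~200, not the full transcriptome (whose wider
  spread would simply move most of the tail below the filter).
  `mean_depth` is the mean reads per gene per library.
* **Effects.** Transcriptional folds multiply both assays' MetR means;
  TE folds multiply only the footprint MetR mean; loading classes
  override the per-condition 5′UTR read fraction (defaults 0.30→0.05,
  0.05→0.40, 0.10→0.10 for classes 1/2/3, against a background of 0.008
  in both conditions) and carry the TE effect; `kqe_slope` s decrements
  log2(TE fold) by s·freq_KQE for the designated set (all genes when
  unset) — s = 2 gives the documented mean deficit of 0.5 log2 units at
  freq 0.25. Effect gene sets are drawn disjointly; class planting
  samples only genes with a 5′UTR ≥ 20 nt (a class needs somewhere to
  put the reads), and the class-recovery study generates models with
  `utr5_min=25` so all 300 planted genes qualify.
* **Reads.** mRNA 5′ ends uniform over the CDS; footprint P-sites
  uniform over CDS/5′UTR per the gene's fraction; emitted BED intervals
  are fixed-length (28 nt footprints, 50 nt mRNA) positioned so the
  counting rules recover the intended P-site exactly. Identical
  positions collapse into one BED line with the weight in the score
  column (flag to emit one line per read). The generator also returns
  its own per-region tallies, which downstream counting must (and does)
  reproduce exactly.
* **Determinism.** Everything derives from one integer seed;
  re-simulation is byte-identical, and so is a full pipeline rerun.

**What the simulations do not emulate:** sequencing error, alignment
ambiguity, rRNA/tRNA contamination, splice junctions, positional bias
within regions (beyond the TSS window the pipeline corrects for), codon-
level pausing, replicate structure, or correlated biological covariance
between mRNA and footprint noise. Passing recovery tests therefore
demonstrates correctness and calibration of the estimators under the
assumed noise model, not robustness to every artifact of real libraries.

## Validation scales and known limitations

The validation suite and `scripts/acceptance.py` use 5000 genes at depth
200 for calibration and TE recovery, 300 planted genes at depth 500 for
loading classes, 2000 genes for the KQE correlation (20 seeded runs in
the test suite), and 50 exhaustively enumerated rank-sum instances;
heavier statistical loops run on the generator's count tallies directly,
since the file-based counting path is verified exactly and separately.

Known limitations: TE sensitivity at depth 200 sits near the 80% mark
per seed (see the TE section above) — deeper libraries or fewer/larger
planted effects move it well clear; the rank-sum normal approximation is
compared against enumeration for modules of 2–4 members, as a
single-member "module" deviates by ≈ 0.2 z-units from the discrete exact
law regardless of implementation; and no multiple-testing control is
applied anywhere in the core pipeline (the `q_bh` column is advisory).
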