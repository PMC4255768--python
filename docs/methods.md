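# Methods

## The problem setting

A tandemly repeated, multiallelic CNV cannot be genotyped or fine-mapped
the way biallelic deletions and duplications are. Three features break the
standard toolchain: (i) the repeat unit sits inside flanking sequence that
is itself copy-number variable, so segmentation methods keyed to a
diploid-to-variable intensity transition misplace the boundaries; (ii) no
single assay is both precise and accurate enough for integer diploid
genotypes in the 2–7 copy range; (iii) with several near-identical copies
per haplotype, coding variation mixes paralogous sequence variants with
allelic SNPs, which must be separated before any selection inference.
`cnvblock` addresses each in turn.

## Boundary mapping

For probe *i* and samples *s*, the per-probe statistic is the squared
Pearson correlation between the probe's log₂(test/reference) intensities
and an independently assayed copy number. Pearson (not rank) correlation is
used because probe response is modeled as linear in log copy-number ratio;
*r²* is invariant to affine rescaling of either variable, so neither the
assay scale nor array normalization offsets matter. Probes with zero
intensity variance are assigned *r² = 0* — they carry no supporting
evidence — rather than treated as missing; probes with fewer than three
informative samples are missing.

Blocks are maximal runs of probes with *r² ≥ 0.5*, tolerating up to 20
consecutive sub-threshold probes inside a run, keeping at least 10
supporting probes. The gap tolerance exists because a real block can
embed a low-correlation section (a core duplicon shared with unrelated
loci elsewhere in the genome, whose probes cross-hybridize); the defaults
keep such a dip inside one call while never bridging to decoy CNVs
separated by more than the gap. All three thresholds are CLI-exposed.
Block edges snap to the outermost qualifying probe, so a recovered block
underestimates the true extent by up to one probe spacing per edge; edge
uncertainty is therefore always reported as the flanking probe-gap
interval, never a point estimate.

The HMM segmenter is a univariate Gaussian-emission chain over an ordered
log₂ track with states loss/neutral/gain (default means −1, 0, log₂ 1.5;
equal sds) and a symmetric transition probability of 10⁻⁶ between distinct
states. That deliberately conservative value means a state switch must be
supported by roughly 28 nats of emission evidence — single outlier probes
never open a segment. Decoding is exact Viterbi (verified in the test
suite against brute-force enumeration over all state paths on short
tracks). Breakpoints are reported as the genomic interval from the last
probe of the left state to the first probe of the right state. The model
is intentionally simpler than published bivariate breakpoint HMMs that
add sequence-feature emissions; with the correlation track carrying the
block evidence, the HMM only needs to localize state changes.

The dropout scan looks for internal heterogeneity inside a called block —
the signature of a polymorphic insertion (e.g. an endogenous retrovirus
present in the reference but absent in a subset of individuals). Per-sample
deviations from the sample's own block-wide median remove the copy-number
signal; probes where between 2 and half the cohort deviate below −0.5 log₂
units are flagged, and runs of at least two flagged probes are reported
with their carrier samples.

## Assay quantification

* **PRT**: copy number = reference_cn × mean over replicate peak-area
  ratios, reference_cn = 2 because the co-amplified reference locus lies
  outside any common CNV. Replicates with a zero reference peak are
  rejected individually.
* **ddPCR**: Poisson inversion λ = −ln(negatives/total) per channel;
  cn = 2 λ_test/λ_ref; reads with ≤ 10,000 droplets fail QC (the threshold
  is a strict inequality); a sample's value averages its QC-passing
  replicate reads. The Poisson estimator, unlike the naive
  positives-ratio, stays unbiased as loading saturates — the quantitative
  basis for anchoring integer calls on ddPCR.
* **qPCR**: per-amplicon standard curves (Ct vs log₁₀ quantity) give
  efficiencies E = 10^(−1/slope); relative quantity is E^(−Ct); the
  test/reference ratio is normalized by the same ratio measured on a
  calibrator sample of asserted diploid copy number. Without a calibrator
  the raw ratio is returned with an explicit un-calibrated flag.
* An optional affine calibration maps any method's continuous values onto
  anchor samples with asserted integer copy numbers (least squares;
  identity with a warning when fewer than two distinct anchors exist).

## Integer copy-number calling

PC1 of the block-restricted probe × sample matrix (probes as variables,
probe-mean imputation, sign oriented along per-sample mean intensity)
summarizes the array evidence. Methods are then standardized per column —
making the integration invariant to each assay's scale and offset, since
whether the original study standardized before its joint PCA is not
stated, we standardize and record the choice — and PC1 of the
sample × method matrix is the fused score, sign-anchored to the ddPCR
column. The fused score is affine-mapped onto the anchor method's scale by
least squares and rounded to the nearest integer, replacing the original
study's manual integer assignment with a reproducible rule; ties round
half away from zero. Confidence is 1 − 2·|mapped − round(mapped)| ∈ [0,1];
in simulation, wrong calls have systematically lower confidence than
correct ones, so the value is usable as a per-sample QC score.

## Selection between paralogs and alleles

Input is a set of phase-resolved haplotypes (in practice, fully sequenced
large-insert clones), each carrying the coding sequence of both tandem
copies. Divergence cells of the McDonald–Kreitman table are the
nonsynonymous/synonymous difference counts between the proximal and distal
copy within each haplotype, averaged over haplotypes; diversity cells are
the counts between haplotypes at the same copy, averaged over haplotype
pairs and summed over the two copies. Note one consequence of this
declared convention: a site polymorphic on a single haplotype at a single
copy contributes ½ to divergence as well as 1 to diversity.

Codon differences are classified Nei–Gojobori style: multi-difference
codons average over all minimal substitution pathways (pathways through
stop codons are excluded when an alternative exists), contributing
fractional counts. Site denominators are per-codon degeneracy tallies on
the reference haplotype's proximal sequence, with mutations to stop codons
counted as nonsynonymous. Each cell is Jukes–Cantor corrected on its own
class denominator, d = −(3/4)ln(1 − (4/3)p) scaled back to a count (the
correction is exposed as a flag, since applying it per-cell rather than to
distances only is a package choice); corrected cells are rounded half away
from zero to integers because the exact test requires counts. The test is
a two-sided Fisher exact test (summing hypergeometric probabilities ≤ the
observed table's); the neutrality index
NI = (diversity_N/diversity_S)/(divergence_N/divergence_S) is reported
with NI < 1 flagged as positive selection on paralog divergence. Tables
with an empty row or column return p = 1 and an uninformative flag.

Variant naming translates both sequences and emits reference-first labels
with 1-based residue numbers from the initiator Met ("G45R"); premature
stops are labelled "X" at their position with a warning. Percent identity
comes from a global affine-gap alignment (match/mismatch/open/extend
= +1/−1/−5/−1, a gap of length k costing 5 + (k−1)); identity = matched
columns / aligned columns, gap columns counting as non-matches, to one
decimal place.

## Insertion dating

Each diagnostic marker's insertion window is [max divergence among
lineages sharing it, min divergence among lineages lacking it]; a presence
older than an absence raises a homoplasy error. A marker absent from every
surveyed lineage but present in the focal species has a window starting at
0. Lineages in which a marker segregates polymorphically count as present
— presence anywhere in the lineage establishes the marker's age — with the
polymorphism kept as metadata. Unknown statuses are skipped, never
imputed. The duplication bracket takes the max of window lower bounds
(every insertion postdates the duplication-distinguishing state) and, for
the upper bound, the minimum published subfamily age among markers (the
element cannot predate its subfamily), falling back to window upper bounds
when no subfamily age is supplied. The tension inherent in using a
subfamily age as an "earliest origin" for a duplication whose insertions
postdate it is preserved as stated, not resolved.

## Synthetic cohorts

The generator emulates exactly the statistical structure the analysis
assumes. Probes tile a region at jittered mean spacing. Each probe's
expected log₂ ratio is attenuation × log₂(cn_s/cn_ref) inside the true
block (pseudocount 0.05 on a zero copy number, since arrays saturate
rather than report −∞), the same formula with independently drawn copy
numbers inside decoy intervals, and 0 elsewhere, plus i.i.d. Gaussian
noise. PRT replicates are the true ratio times unit-mean lognormal noise
of configured CV; ddPCR reads draw channel positives binomially under
Poisson loading with λ_test = λ_ref·cn/2. Haplotype sets place paralog
substitutions on the distal copy of both haplotypes (fixed divergence) and
allelic substitutions on one haplotype's proximal copy (polymorphism, the
arrangement observed in real phase-resolved clone pairs), one substitution
per codon, each class drawn Bernoulli(nonsyn_fraction) with realized truth
labels returned. All randomness flows from one seed through named
substreams; identical seed and config reproduce a cohort bit-exactly.

Packaged study conditions: the human-like configuration is 68 samples,
copy numbers 2–7, a 322-kb block in a 1.2-Mb region at 412-bp probe
spacing (the published tiling density at desk scale), noise sd 0.15, decoy
CNVs in both flanks, and a 2-kb dropout carried by 12 of 68; the
macaque-like configuration is 16 samples, copy numbers 3–6, a 20-kb unit
in a 982-kb region at 667-bp spacing (~1.5 probes/kb) and noise sd 0.25,
reflecting that platform's higher background. Neither platform's true
noise magnitude is published; the sds are tunable configuration, not
claims. Assay defaults (PRT CV 0.05, ddPCR λ_ref 0.8 with 15,000 droplets,
4 replicate reads) are typical bench values. What the generator omits —
dye bias, GC waves, spatial artifacts, real sequence context, gene
conversion between copies — bounds what passing tests show: recovery
results demonstrate the estimators and calling logic are correct under the
declared generative model, not that real arrays meet that model.

## Numerical and reporting conventions

Coordinates are 0-based half-open internally and in BED/bedgraph outputs;
human-readable logs additionally print 1-based inclusive coordinates,
labelled. Every tabular output opens with a comment header carrying tool
version, config hash and seed. Viterbi runs in log space with a uniform
initial distribution. Degenerate inputs fail loudly: equal HMM state
means, zero-variance PC1 input, saturated ddPCR reads (no negative
droplets), Jukes–Cantor proportions ≥ 3/4, and presence/absence patterns
incompatible with a single insertion origin each raise a typed error.

The acceptance script reports block-recovery sizes as the median over 11
replicate cohorts: a single cohort's largest call occasionally jumps when
a chance high-r² probe lands within the gap tolerance of a block edge
(an event visible mainly at the 16-sample configuration, where the null
r² distribution is wide), and the median of a modest replicate set is the
stable summary of what the method recovers. The test suite verifies the
distributional claims directly: ≥90% of 50 human-config cohorts recover
the block within ±2 probe spacings, and macaque-config integer calls are
≥95% accurate over 100 cohorts (exact at half noise).

## Known limitations

Probe-level r² needs tens of samples for a crisp boundary; at 16 samples
the threshold crossing is noisy and boundary intervals should be read
together with the HMM output. Divergence/diversity partitioning assumes
zero homoplasy and free recombination between the sampled haplotypes; the
MK construction here uses two haplotypes and small counts, so the Fisher
test is conservative. Dating inherits the published subfamily ages and
divergence times as fixed inputs and provides no uncertainty beyond the
bracket itself. No pedigree-based validation of integer calls is
implemented.
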