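# Methods

This note documents the statistical model behind `ovisweep`, the
numerical conventions it commits to, what its synthetic-data generator
does and does not emulate, and the design choices that were genuinely
open.

## The scan

The pipeline detects recent positive selection in a *selected*
population against a *reference* population from phased diploid
genotypes. It combines three complementary signals:

**Allele-frequency differentiation.** Per site, the Hudson estimator of
F<sub>ST</sub> is computed from its numerator and denominator
components,

    num = (p1 − p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1)

with `p_i` the ALT frequency and `n_i` the called allele count.
Components are aggregated as a *ratio of averages* (Σnum/Σden) over
windows and the genome; per-site values are never clamped, since
negative noise cancels in the aggregate and clamping biases windows
upward. Windowed "weighted" F<sub>ST</sub> follows the Weir &
Cockerham (1984) variance components a, b, c with the two-population
estimate Σa/Σ(a+b+c) — the quantity VCFtools prints for windowed scans.
Both estimators are consistent for the same parameter; on balanced
Balding–Nichols data they agree within 0.03 (tested).

**Haplotype length.** EHH at distance x from a core site is the
probability that two random haplotypes from the population are
identical at every site between the core and x. The curve starts at 1
at the core; the core's own alleles do not partition the sample (the
convention of selscan's XP-EHH, whose whole-sample EHH this follows).
iHH is the trapezoidal integral of the curve over physical distance,
both directions summed, truncated at the first extension site whose
EHH falls below the cutoff (default 0.05); the sub-cutoff segment is
excluded entirely. XP-EHH(raw) = ln iHH_sel − ln iHH_ref, written as a
difference of logs so that swapping the populations negates the score
bit-exactly. Raw scores are standardized genome-wide in a single bin
(mean 0, sd 1, population sd); frequency-binned normalization is an
iHS-ism that cross-population scores do not need. Scores are undefined
when either curve reaches a chromosome end before decaying below the
cutoff (edge truncation; retention switchable), crosses an inter-site
gap above 200 kb (selscan's guard), or integrates to zero. Scores are
computed at every site with pooled minor-allele frequency strictly
above 0.05. No genetic map is used: physical distance is the
integration axis.

**Diversity loss.** Per window and population: nucleotide diversity π
as the sum over sites of unbiased heterozygosity 2p(1−p)·n/(n−1)
(identical to the mean pairwise Hamming distance, which the tests
verify by enumeration), Watterson's θ, and Tajima's D with the
standard constants. The π-ratio is oriented π_ref/π_sel, so values
above 1 indicate diversity loss in the selected population; log2 is
also emitted. Undefined statistics are NaN-masked, never zero-filled —
zero-filling would distort the empirical quantiles that the outlier
rules depend on.

### Windows, outliers, sweep calls

The genome is tiled with consecutive non-overlapping 50,000-bp windows
anchored at position 1, so a 1-based position p belongs to window
⌊(p−1)/50000⌋ and reported bounds read like `90,600,001–90,650,000`.
Windows with fewer than `min_snps` (default 10) filtered SNPs are
masked and excluded from quantile computation. Upper-tail thresholds
use the empirical (1−f) quantile with "higher" interpolation; an item
is an outlier iff value ≥ cutoff, so ties at the cutoff are all
included. Window enrichment of high-F<sub>ST</sub> SNPs (per-site
Hudson F<sub>ST</sub> in the genome-wide top 5%) is scored with the
one-sided hypergeometric tail (Fisher's exact test), compared to raw
α = 0.05 by default; a Benjamini–Hochberg mode is available but off,
to reproduce the conventional raw-p rule.

A window is called a sweep candidate under the default **intersect**
rule when it is simultaneously in the top 5% of weighted
F<sub>ST</sub>, the top 5% of the window statistic max|XP-EHH z|, and
Fisher-significant; the alternative **xpehh_1pct** rule takes the 1%
right tail of the window XP-EHH statistic alone. Flagged windows at a
gap ≤ 50,000 bp (inclusive) are merged transitively; merged regions
carry member-window maxima as peak statistics and are annotated with
every gene whose half-open interval overlaps by at least 1 bp.
Fine-mapping re-evaluates max|z|, Tajima's D and the π-ratio in
sliding sub-windows (any size/step; 50-kb and 1-kb grids both
supported) re-using the genome-wide z standardization.

### SNP filtering

Sites enter the scan when they are biallelic, have missing rate **not
higher than** 10% (a site at exactly 10% survives), and pooled minor
allele frequency **strictly higher than** 5% (a site at exactly 0.05
is removed). Rates are computed on the samples of the current analysis
subset, since each scan pair re-subsets the cohort; per-population MAF
filtering is available behind a flag. The rules are independent
per-site predicates, so their order cannot change the surviving set
(asserted in tests); removals are reported per rule in the order
biallelic → missingness → MAF.

### Population structure

Breed-level differentiation uses Hudson ratio-of-averages
F<sub>ST</sub> on pooled breed samples; negative pairwise estimates
are clamped to 0 (count logged) to form a distance matrix. The tree is
classical neighbor joining (Saitou–Nei with the Studier–Keppler
Q-criterion), lexicographic tie-breaking for determinism, negative
branch lengths clamped to zero with the deficit moved to the sibling
edge so path lengths are preserved; on additive matrices the output
reproduces all pairwise path lengths to machine precision (tested, and
cross-checked against scikit-bio's independent implementation). PCA
normalizes each site by subtracting 2p̂ and dividing by √(2p̂(1−p̂)),
mean-imputes missing dosages (0 after centering), eigendecomposes the
sample×sample covariance, and fixes signs so each component's
largest-magnitude entry is positive. LD decay bins pairwise r² by
physical distance within each population; the half-decay distance is
the smallest bin midpoint where mean r² falls to half the binned
maximum.

## The synthetic-data generator

Two modes, chosen by what each statistic needs:

* **Balding–Nichols** (unlinked): ancestral p ~ U(0.05, 0.95),
  population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes
  Binomial(2, p_i). E[F<sub>ST</sub>] ≈ F, making it the calibration
  oracle for the F<sub>ST</sub> estimators and PCA. No LD, so it says
  nothing about haplotype statistics.
* **Forward Wright–Fisher** (linked): one ancestral diploid population
  seeded from the neutral stationary frequency spectrum (P(k) ∝ 1/k),
  burned in for 4N generations so haplotype structure equilibrates on
  the coalescent time scale, then split into two populations evolved
  independently with Poisson mutation (new biallelic sites at uniform
  positions), Poisson(rL) crossovers per transmitted haplotype, and
  multinomial resampling. A hard sweep introduces one focal copy in
  the target population at a stated time with fitnesses 1 : 1+hs :
  1+s, conditioned on survival to sampling by restarting from the
  introduction state (restart count recorded in the truth file).

### Rescaling

A desk-scale simulation cannot run at a realistic effective size, so
the generator works in a rescaled parameter family with λ = 100:
N = 100–200 diploids stands in for N_e ≈ 10,000–20,000, and per-bp
rates are scaled up accordingly — recombination 1e-6 (≈ 1 cM/Mb at
real scale), mutation 5e-7 per bp per haplotype per generation, and
selection coefficients multiplied by λ (s = 1.5 ↔ s_real ≈ 0.015).
This keeps the population-scaled quantities 4Nr, 4Nμ and 2Ns — which
are what every statistic here responds to — at realistic values.
Without rescaling, EHH would not decay below the 0.05 cutoff within a
desk-scale chromosome (every XP-EHH score edge-truncated) and a
sweep's haplotype footprint would cover a large fraction of the
simulated genome, breaking genome-wide standardization.

### Named validation scenarios

The test battery and `scripts/acceptance.py` run three frozen
scenarios (factories in `ovisweep.synthetic_data`):

* `sweep_scenario` — 4-Mb chromosome, N = 100/population, split 25
  generations before sampling (F<sub>ST</sub> ≈ 0.12–0.2), 40 diploids
  sampled per population; sweep s = 1.5, h = 0.9, introduced 20
  generations before sampling at position 2,025,000 (mid-window, so
  window-grid boundary effects do not confound locus containment).
  This is the classic XP-EHH target: a strong, young, nearly complete
  sweep. The near-dominant fitness is deliberate twice over: escape
  from low copy number is fast, so survival-conditioned replicates
  cluster tightly at high final frequency (0.8–0.97) instead of
  leaving an undetectable low-frequency tail; and the late phase
  stalls just below fixation, so the core window keeps the
  polymorphism that per-site F<sub>ST</sub> and the Fisher enrichment
  rule score (a fully fixed core is monomorphic in the selected
  population at most retained sites and pushes those signals onto the
  shoulders). ~6,000 SNPs per replicate; roughly 20 s per
  simulated-and-scanned replicate on one core.
* `neutral_scan_scenario` — the same without selection; measures the
  false-flag rate of the intersect rule.
* `exchangeable_scenario` — split_time 0: two random halves of one
  panmictic pool, the strict null for XP-EHH sign symmetry.

Problem sizes (replicate counts of 20, chromosome lengths, sample
sizes) are the package's choice of a desk-scale experiment that a
laptop reproduces in minutes.

### What the generator does not emulate

Genotyping error, missingness patterns of real sequencing, more than
two populations, migration after the split, variable recombination
maps, background selection, and genome-scale numbers of windows. The
last point matters most for interpretation: with ~80 windows per
replicate, empirical 5% tails contain only ~4 windows, so sweep
detection is intrinsically noisier than in a multi-gigabase genome
where the same rules select thousands of windows. Passing the
recovery tests shows the machinery ranks and intersects signals
correctly at small scale; it does not measure power on real genomes.

## Numerical conventions and degenerate inputs

* Internal coordinates 0-based half-open everywhere; VCF (1-based) and
  GFF3 (1-based inclusive) converted at the boundary; reports are
  1-based inclusive.
* Chromosome names match by exact string; an explicit rename map is
  the only normalization.
* Ploidy is fixed at 2; haploid or polyploid records are rejected.
* Missing genotypes are a distinct sentinel (−1), excluded from both
  numerator and denominator of every frequency.
* All-missing sites, monomorphic LD pairs, S = 0 windows (Tajima's D),
  zero or truncated iHH: NaN, masked downstream.
* Empirical quantiles warn (but still answer) when fewer than 1/f
  values are defined. Tail fractions accept 1.0 as the degenerate
  flag-everything limit.
* Sweep-region merging is idempotent and order-independent; equality
  at the 50-kb gap merges.
* All randomness flows from one integer seed per run
  (`numpy.random.default_rng`); identical configuration ⇒
  byte-identical outputs.

## Open design choices, resolved

* The window rule is stated two ways in the scan literature this
  design follows (top-5% intersection vs 1% right tail of the window
  statistic); both are implemented, `intersect` is the default, a flag
  switches.
* "Significant SNPs" for the Fisher test are per-site Hudson
  F<sub>ST</sub> top-5% outliers — the SNP-level threshold defined
  immediately before the enrichment rule.
* π-ratio orientation (reference/selected) is a convention choice;
  values > 1 mean diversity loss in the selected population.
* The NJ-vs-Fitch–Margoliash naming ambiguity in this family of scans
  is resolved as NJ; least-squares tree fitting is out of scope.
* Edge-truncated XP-EHH scores are excluded by default (retention
  flag provided); min_snps = 10 per 50-kb window.
* Fine-mapping supports both the 1,000-bp and the 50,000-bp sliding
  grids; neither is asserted as canonical.

## Known limitations

EHH walks are O(sites × haplotypes) per core site in Python/numpy —
fine for desk-scale validation, slow for whole genomes (a compiled
scanner like selscan or hapbin is the right tool there). The forward
simulator tracks the full haplotype matrix densely; memory grows with
N × segregating sites. Fisher enrichment treats SNPs as exchangeable
draws, ignoring LD between them, exactly as the conventional rule
does. Single-bin XP-EHH standardization assumes sweeps are rare in
the scanned genome; the generator's rescaling keeps that assumption
honest at desk scale.
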