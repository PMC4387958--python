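# Methods

This note documents the models and procedures implemented in `caprapop`, the
choices made where the design was genuinely open, and what the synthetic-data
harness does and does not establish about real data.

## Two-stage variant filtering

Per-caller call sets (VCF, one file per caller) are merged by `(chrom, pos)`.
A site passes **stage 1** when at least two different callers report it, each
with phred-scaled site quality strictly greater than 30; among passing sites
an alternate allele survives when any one caller calls it with at least one
non-reference genotype carrying it. Callers disagreeing on the reference
allele at a position is an error, not a silent merge. Failing sites are
flagged, never deleted, so the filter is auditable.

**Stage 2** is a Gaussian recalibration. The training set is the
highest-confidence subset: sites called by all callers with quality > 100,
biallelic after merging, with minor allele count ≥ 3 counting only genotypes
with GQ > 30 (genotypes taken from a designated primary caller — a CLI flag,
defaulting to the first caller file, since nothing in the merged record
decides this). A multivariate Gaussian is fitted to the training sites'
annotation vectors (QD, HaplotypeScore, MQRankSum, ReadPosRankSum, FS, DP,
InbreedingCoefficient) and a second Gaussian to all candidate sites; each
site's score is the log odds

    VQSLOD = ln N(x; μ_T, Σ_T) − ln N(x; μ_B, Σ_B).

Missing annotation values are imputed with the training median of that
annotation, in both fitting and scoring; covariances carry a small ridge
(1e−6) and a singular pair is reported by name rather than silently
regularized away. The cutoff is

    median(VQSLOD_training) − 3 × MAD(VQSLOD_training)

with the **unscaled** MAD (no 1.4826 consistency factor — the rule names the
raw median absolute deviation). A site at exactly the cutoff is retained;
only `VQSLOD < cutoff` fails. Genotypes with posterior probability
(FORMAT GP) strictly below 0.95 are masked to missing, never recoded as
reference. The positive model here is a single Gaussian against an all-site
background rather than a mixture-of-Gaussians machine: the contract the rest
of the pipeline uses is the log-odds score plus the MAD cutoff, and a single
Gaussian keeps that contract transparent and testable.

## Diversity and differentiation statistics

All estimators work on alternate-allele dosages (0/1/2, −1 missing).

* **π** per site is `2j(n−j)/(n(n−1))` for alternate count `j` of `n`
  chromosomes, averaged over biallelic variant sites with no missing
  genotype. The mean is per *variant site*, not per bp — values around 0.2
  are expected on polymorphic panels.
* **Ho** is the fraction of heterozygous genotypes per individual over
  biallelic SNPs with no missing call in any sample.
* **F** uses the method-of-moments homozygosity-excess form
  `F = (O_hom − E_hom)/(S − E_hom)` with expected homozygosity
  `1 − 2p(1−p)·n/(n−1)` from whole-sample frequencies; the `n/(n−1)` factor
  is the small-sample correction. The exact estimator had to be pinned here;
  this form is the standard one consistent with per-individual reporting.
* **IBS** similarity is the mean shared-allele proportion per pair (1, 0.5,
  0 per site), missing sites excluded pairwise; the distance is
  1 − similarity and both are exposed, because "IBS distance" is used for
  the shared proportion in parts of the literature.
* **ts/tv** counts A↔G and C↔T as transitions per alternate allele; a zero
  transversion count yields an infinite-ratio sentinel.
* **Rare variants** are MAF strictly below 0.05 over all samples.
* The **polymorphism partition** assigns each site to the subset of
  populations in which ≥ 2 alleles segregate among called genotypes; a
  lone heterozygote already segregates.
* **FST** is the Weir & Cockerham (1984) variance-components estimator:
  per-site components `a` (among populations), `b` (among individuals
  within), `c` (within individuals), per-site θ̂ = a/(a+b+c), and the
  genome-wide weighted value Σa/Σ(a+b+c). Sites where any population has
  fewer than two called genotypes are skipped and counted; overall
  monomorphic sites are excluded.

## LD and structure

r² is the squared Pearson correlation of dosage vectors over samples with
both genotypes called (genotype r², valid on unphased data; the estimator on
phased haplotypes is a different quantity and is not implemented). The decay
curve averages r² within the seven distance classes 0–0.2, 0.2–1, 1–2, 2–10,
10–30, 30–60 and 60–120 kb; the crossing distance of a level is interpolated
linearly between consecutive bin mean distances, with a NaN sentinel when
the level is never crossed. Pruning slides non-overlapping 50-marker blocks
per chromosome (the step is configurable; the window phrase alone does not
fix it) and removes the later-positioned marker of every pair with
r² > 0.95 — later-positioned, because the tie-break must be deterministic.
PCA centers dosages per site, scales by √(p(1−p)), imputes missing with the
site mean, and orders components by explained variance.

## XP-CLR sweep scan

The scan contrasts two models of the test population's allele frequency
`p1` given the pooled-reference frequency `p2` at each SNP:

* *neutral*: `p1 ~ TN(p2, ω·p2(1−p2) + v_s)` — a normal truncated and
  renormalized to [0, 1], where ω is a genome-wide drift scale and `v_s`
  the binomial sampling variance of the observed frequency;
* *sweep of strength s at map distance d*: each lineage escapes with
  probability `c(d, s) = 1 − exp(−d/s)` (d in Morgans). Unescaped lineages
  carry the beneficial haplotype's allele, so the distribution becomes the
  mixture `p2·TN(1 − c(1−p2), c²v + v_s) + (1−p2)·TN(c·p2, c²v + v_s)`:
  mass pushed toward fixation of either allele, drift variance shrunk by
  c². As s → 0, c → 1 and the sweep model collapses onto the neutral one,
  so null scores floor near zero by construction.

The grid score is `2 × max_s Σ_i w_i [ln f_sweep(p1_i) − ln f_neutral(p1_i)]`,
floored at 0. The s-grid is logarithmic with 10 points per decade over
[1e−4, 0.316]. ω is estimated once per chromosome by method of moments from
`(p1−p2)²/(p2(1−p2))` on a thinned SNP set, after subtracting both sample
frequencies' binomial sampling variances.

Windowing and assembly follow fixed rules: grid points every 2500 bp; at
most 250 variants per 0.5 cM window (thinned deterministically by even
spacing — reproducibility over randomness); weights 1/k from single-linkage
clusters of reference-group r² > 0.95; physical-to-map conversion at 1 cM
per Mb. Chromosomes are scanned in segments of at most 27 cM stepping by
25 cM; interior kept-span boundaries sit at the midpoint of each overlap
(1 cM trimmed from each side of the standard 2 cM overlap), chromosome ends
are never trimmed, and kept spans tile the chromosome exactly — the
midpoint rule also covers short terminal segments whose overlap is below
2 cM. Candidate regions are maximal runs of grid points at or above the
genome-wide 99.9th-percentile score (ties included, single-grid-step gaps
bridged); genes hit a region when their interval extended by 1500 bp on
both sides intersects it. Population sizes can be equalized by seeded
random subsampling before scanning.

The likelihood internals above are an operational rendering of the
cross-population composite-likelihood idea; they are validated behaviorally
(null scores near zero, localization of injected sweeps, linearity in the
weights), not by numeric identity to any external implementation.

## mtDNA statistics

Segregating sites are columns with ≥ 2 distinct states among A/C/G/T —
variation carried only by gaps or ambiguity codes does not count. Haplotype
collapsing merges sequences identical over their mutually unambiguous
positions (an N matches either state), greedily in input order with the
representative refined as ambiguous positions resolve. Region extraction is
1-based inclusive; the region share report gives segregating sites inside
the region over all segregating sites, next to the region's length share.

## The synthetic-data generator

`simulate_genotypes` combines Balding–Nichols differentiation with a
founder-mosaic haplotype layer:

* ancestral frequency `p ~ Beta(α, α)` per site, α = 0.1 by default — the
  near-neutral-SFS limit, giving a large rare-variant fraction;
* population frequency `p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` with
  `f_div = 0.0025` by default (three weakly differentiated populations of
  22 + 14 + 8 diploids);
* K = 30 founder haplotypes per population drawn from `p_k` via a uniform
  field *shared across populations* (comonotone founders), so
  founder-sampling noise largely cancels from the among-population variance
  instead of inflating realized FST roughly by 1/K;
* individual haplotypes are founder mosaics with switch probability
  1 − exp(−ρ·gap) per inter-site gap, ρ = 1e−4 per bp by default, so r²
  decays on a ~10 kb scale; diploids pair consecutive haplotypes;
* `n_founders=None` switches to the pure Balding–Nichols draw (genotypes
  binomial in `p_k`): no LD, but the divergence parameter is realized
  exactly — the right mode for differentiation-calibrated experiments,
  while the mosaic mode is the right one for LD-dependent experiments.

Realized genome-wide FST in mosaic mode exceeds `f_div` by a residual
founder term (about 3–5 × 10⁻³ at the defaults); transitions are drawn with
probability 0.71 per SNP, matching a ts/tv ratio near 2.4; 5% of sites are
labelled indels.

`inject_sweep` drags carrier haplotypes (a fraction `final_freq` of the
target population) toward one template haplotype with probability
`exp(−d/σ_s)` at distance d, i.e. escape probability `c(d) = 1 − exp(−d/σ_s)`;
the template carries the alternate allele at the sweep site. This is a test
harness for scan localization, not a model of sweep dynamics: it operates on
pseudo-haplotypes split from dosages and leaves other populations untouched
bit for bit.

`emit_caller_vcfs` re-emits true sites through three caller error channels
(false-negative and false-positive rates, quality and GQ/GP noise) plus a
shared artifact pool emitted by ≥ 2 callers so that some artifacts survive
the consensus stage and exercise the recalibration. True-site annotations
are Gaussian per key; artifact sites displace each annotation independently
by ~2 SD with random sign and probability 0.7. The random error modes
matter: a single stereotyped artifact class displaces every artifact along
one direction in annotation space, making the background covariance
inflation rank-one and the median−3·MAD cutoff behave like a 1-dof
chi-square tail (retaining only ~83% of true sites); heterogeneous modes
spread the inflation over all annotation dimensions, which is both closer
to how real caller failures look and restores the intended ~93% retention.

`simulate_mtdna` applies independent substitutions on a random reference
with a rate multiplier inside a hypervariable window; back-mutations are
possible and the truth table lists every mutated position.

### What passing tests do and do not show

The generator realizes the statistical *structure* the analysis assumes —
weak differentiation, rare-variant-rich SFS, distance-decaying LD, private
sweeps, class-separated caller noise — at desk scale, with known truth.
Passing tests show the estimators and the scan are correct *under that
model*. They do not show performance on real goat genomes: the mosaic model
has an effective population size of order K (= 30), so neutral founder
segments drift to high local frequency far more often than in real
populations. Such segments are locally indistinguishable from soft sweeps,
and the scan correctly assigns them elevated scores; in neutral simulations
the top-0.1% grid points therefore cluster into short runs (up to ~7
consecutive points observed) rather than scattering as they would under an
independent-sites null. No single K reconciles the first-bin r² magnitude
of dense real data (wanting K ≈ 5), genome-wide FST near 10⁻³ (wanting
K ≳ 30) and a clean neutral score tail (wanting K ≳ 100); K = 30 is the
fixed compromise and the limitation is intrinsic to the model family.
The headline real-data numbers (24 M variants, π = 0.180, FST = 0.0024,
r² < 0.2 at 5.4 kb, the candidate-gene lists) require the archived WGS data
and are not reproducible at desk scale.

## Numerical choices

* Strict inequalities fail, boundaries pass: site quality must exceed 30
  (exactly 30 fails), GP ≥ 0.95 is kept, VQSLOD = cutoff is retained, MAF
  exactly 0.05 is not rare.
* Truncated-normal normalizers are floored at 1e−300; sweep-model variance
  always includes the binomial sampling floor, so boundary frequencies
  (p1 ∈ {0, 1}) score finitely.
* Degenerate inputs raise named errors rather than returning silent
  defaults: zero divergence, all-tied scan scores, empty training sets,
  monomorphic-only π input, ragged alignments.
* Problem sizes in the shipped tests and the acceptance script (5–50 k
  sites, 4–50 Mb single chromosomes, 10 scan replicates of 10 Mb) were
  chosen so every experiment has clear statistical resolution while the
  whole suite runs in minutes on one CPU.

## Known limitations

No indel left-normalization (caller outputs are assumed
position-consistent, which the generator guarantees); no haplotype-phased
r²; no mixture-of-Gaussians recalibration or tranche sensitivity targets;
no coalescent realism in the generator; mtDNA network construction,
haplogroup assignment and substitution-model selection are out of scope.
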