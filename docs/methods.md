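# Methods

`rohscan` implements a runs-of-homozygosity (ROH) association pipeline
for dense biallelic SNP-array cohorts, together with an EHH/REHH
selection-sweep scan and a synthetic-cohort generator that plants every
signal the pipeline is meant to detect. This note records the models,
the defaults and their units, the numerical choices, and what the
synthetic data does and does not establish about real data.

## ROH calling

An ROH is a maximal stretch of consecutive non-heterozygous genotype
calls on one chromosome of one individual. A run is broken by

* a heterozygous call,
* an inter-SNP gap larger than `max_gap_bp` (default 100 kb), or
* a chromosome boundary.

Missing calls neither break a run nor count toward its SNP tally; an
optional `max_missing` cap (default unlimited) discards runs diluted by
too many no-calls. A run is emitted when it spans at least
`min_length_bp` (default 500,000 bp) **or** contains at least
`min_snps` homozygous calls (default 50). The OR combination follows
the definition the pipeline reproduces; `combine_rule="AND"` is offered
because several array pipelines require both criteria. Segment bounds
are the first and last SNP positions of the run, 1-based inclusive;
BED export converts to 0-based half-open at the boundary.

The caller is verified against a deliberately naive streaming
re-derivation (plain Python, one genotype at a time) on hundreds of
random matrices spanning both rules, gap sizes and missingness.

## Consensus core regions and carriers

Per-SNP coverage counts the distinct individuals whose ROH covers the
SNP. `core_regions(mode="span")` returns each maximal run of SNPs with
coverage ≥ `min_share` (default 10). An individual **carries** a region
only when one of its ROHs covers the region entirely: a core is the
shared interval, and partial overlap would re-admit the individuals
whose ragged segment ends defined the boundary.

These two rules interact badly on real (and realistic synthetic) data:
segment edges are ragged, so a coverage run can extend beyond any
interval a single individual covers, leaving a "consensus" region with
no carriers at all. `mode="plateau"` therefore refines each coverage
run to its maximal-coverage plateau(s) — the interval genuinely shared
by the covering individuals — which guarantees at least `min_share`
carriers per region. The pipeline and all association stages use
plateau regions; the span semantics remain available and are what the
coverage-counting equivalence tests exercise.

Regions whose carrier prevalence among controls falls below
`min_control_prev` (default 1%) are dropped before testing.

## Association testing

Each surviving region is a binary marker tested three ways:

* **Case-control:** Fisher's exact test on the 2×2 carrier × status
  table. Two-sided p by the probability-mass rule (sum of
  hypergeometric probabilities of tables no more likely than the
  observed one, with a 1 + 1e-7 relative tolerance for ties, the
  convention scipy also uses). Odds ratio ad/bc with a
  Haldane–Anscombe 0.5 added to every cell when any cell is zero
  (flagged).
* **Quantitative trait:** ordinary least squares of age of first
  phrase (AFP, months) on carrier status plus covariates (default sex,
  maternal/paternal education, SCQ; configurable). Missing phenotype
  or covariates are listwise-deleted per test and the complete-case n
  is reported; listwise deletion is this package's choice and the
  reported n makes it auditable.
* **Dichotomised trait:** logistic regression of the late/early AFP
  label on carrier plus covariates, Wald p. Perfect separation is
  detected (non-convergence, |coefficient| > 15, or non-finite SE) and
  the fit falls back to Firth's penalised likelihood (Newton iteration
  on the Jeffreys-prior-corrected score), flagged in the output.

AFP is dichotomised by exact one-dimensional 2-means: optimal 1-D
clusters are contiguous in sorted order, so every sorted split is
scored by within-cluster sum of squares and the minimum taken — no
random initialisation, hence fully deterministic. The cutoff is the
midpoint between the largest early and smallest late value; when the
optimum would split tied values the boundary moves right so the
early < cutoff ≤ late invariant always holds.

Multiple testing uses Bonferroni over the number of regions tested for
that phenotype (p·N capped at 1; threshold 0.05/N). Cross-cohort
evidence combines by Stouffer's method, z_i = Φ⁻¹(1−p_i); both the
unweighted and the √n-weighted ("z trend") variants are reported, since
either weighting is defensible and sources rarely say which they used.
Boundary p-values (0 or 1) are rejected rather than silently clipped.

## Burden statistics

* **Froh**: sum of an individual's segment lengths divided by the
  SNP-mappable length (default: last − first SNP + 1 summed over
  chromosomes; overridable). Overlapping segments for one individual
  violate the segment invariant and raise.
* **Inbreeding F**: method-of-moments excess homozygosity,
  F = (O − E)/(L − E) with E = Σ(1 − 2pq) over the individual's
  non-missing polymorphic SNPs and sample allele frequencies.
* **Length comparison**: two-sample z and Welch t on segment lengths
  by case status, reported one- and two-sided. Both the per-segment
  and per-individual (mean length) units of analysis are available
  because published comparisons are ambiguous about the unit.

## Hardy–Weinberg QC

SNPs are removed when the exact Hardy–Weinberg test (Levene's
conditional distribution of heterozygote counts, full enumeration,
probability-mass two-sided rule) gives p < 5×10⁻⁵. Counts are taken
from controls only by default — case ascertainment can distort HWE —
with an option to use everyone; monomorphic SNPs are retained (p = 1).

## EHH / REHH sweep scan

Core haplotypes are the distinct allele strings over a user-supplied
contiguous SNP span of the phased window. For a focal core with n_c
carriers, EHH at flanking SNP x is

EHH(x) = Σ_g C(n_g, 2) / C(n_c, 2),

grouping carriers by their allele string from the core edge through x.
EHH is 1 at the core and non-increasing outward (asserted exactly in
tests and checked against an all-pairs identity oracle). REHH divides
the focal EHH by the combined decay of all other cores,
Σ_s Σ_g C(n_{s,g},2) / Σ_s C(n_s,2). Distances are physical bp from
the nearer core-edge SNP; no genetic map is used, matching the kb/Mb
scale on which the criterion is stated. Cores with a single carrier are
excluded from both sides of the ratio (they contribute no pairs but
would distort denominators).

Where the combined-others EHH reaches exactly zero the ratio diverges:
REHH is reported as +inf while the focal EHH is still positive, and NaN
once both have decayed. A region is flagged as a candidate sweep when
REHH ≥ 2 at a marker more than 200 kb from the core on either side,
counting only markers where the focal EHH is still informative
(≥ 0.05, the conventional decay cutoff below which the ratio is noise).
A profile that never reaches 200 kb returns "inconclusive" rather than
a verdict. The haplotype-bifurcation tree (distinct extensions per SNP
step, counts conserved at every depth) is exported as JSON for
plotting; D′ and r² between SNP pairs come directly from phased
haplotype counts with the standard sign-dependent D_max.

The phased-haplotype container admits only 0/1 alleles, so flank
missingness cannot arise in-memory; VCFs with missing genotypes are
rejected when phased input is required.

## Synthetic cohorts

The generator emulates an Affymetrix-6.0-like panel on one chromosome
(multi-chromosome cohorts are concatenations):

* **Haplotype pool with LD.** Positions uniform then sorted/deduped;
  per-site alt frequencies uniform on the configured MAF range
  (default 0.05–0.5). LD comes from a founder-copying process: a small
  set of latent founder haplotypes (default 8) drawn at the site
  frequencies; each sample haplotype copies its current founder and
  switches to a fresh one with probability 1 − ρ per step (default
  ρ = 0.85). This yields positive adjacent D′ and realistic
  core-haplotype diversity at a single tunable knob; it is *not* a
  demographic or coalescent model.
* **Cohort assembly.** Each individual draws two pool haplotypes. With
  probability `autozygosity_rate` a background autozygous segment
  (length uniform on the configured bounds, default 0.5–2 Mb) is
  planted by copying one haplotype onto the other — a true ROH by
  construction. Carriers of a planted trait region (fixed SNP span)
  are created the same way at the configured frequency. An optional
  per-SNP error rate (default 0) flips sites to heterozygous so the
  zero-het rule's fragility can be probed.
* **Phenotype.** AFP = μ + β·carrier + Σγ·covariate + N(0, σ²),
  truncated below at 1 month; defaults μ = 39.6, σ = 18.29 months —
  the cohort moments the pipeline emulates — with β = 0 unless an
  effect is planted. Covariates: sex Bernoulli(0.5), parental
  education ordinal 1–5 concentrated on 4, SCQ/VIQ/PIQ normal at the
  emulated cohort's moments.
* **Sweep.** One pool haplotype's core + flank (default 300 kb each
  side) is copied onto the configured fraction of haplotypes, so the
  swept core's carriers share extended flanking homozygosity.

Everything is reproducible from (config, seed), and a truth record
(planted intervals, carrier status, phenotype parameters, sweep
carriers) accompanies every cohort.

What passing tests on this generator do **not** show: robustness to
array ascertainment bias, genotyping error beyond the simple flip
model, population structure or relatedness, recombination-map
heterogeneity, or multi-allelic/CNV complications. The generator
exists to verify the pipeline's logic against planted truth, not to
claim power estimates for any real cohort.

## Evaluation protocols and problem sizes

`rohscan.evaluation` packages four seeded protocols, used by the test
suite and by `scripts/acceptance.py`. The problem sizes are desk-scale
choices: cohorts of 300–500 individuals on a 10–15 Mb chromosome with
1,200–2,000 SNPs, 50–100 replicates per summary.

* **Type-I calibration:** ≥ 1,000 null region tests (β = 0, background
  autozygosity 0.6 so consensus regions form); the linear-regression
  rejection rate at 0.05 should sit in the 3σ binomial band. The
  continuous-outcome test is used because Fisher's exact test is
  conservative under discreteness at realistic carrier counts, making
  a symmetric band uninformative for it (its conservatism is asserted
  separately in the unit suite).
* **Effect recovery:** planted β = 30 months at 10% carrier prevalence,
  n = 300, σ = 18.29; the recovered carrier coefficient should lie
  within ±2 SE of 30 in ≈95% of replicates.
* **Froh recovery:** one planted segment per individual averaging 5% of
  the map; mean Froh over 500 individuals tracks 0.05 (slightly above,
  since chance homozygosity extends segment edges by a few SNPs).
* **Sweep detection:** planted 300-kb flank at frequency 0.4 versus
  matched neutral pools; the flag should fire for most swept replicates
  and rarely for neutral ones.

## Known limitations

* `max_het > 0` (allowing isolated heterozygotes inside a run, as some
  callers do) is not implemented; the zero-het rule is strict.
* The sweep scan takes user-supplied core spans; it does not locate
  candidate cores genome-wide, and REHH significance is judged by the
  fixed REHH ≥ 2 / 200 kb rule rather than a simulated genome-wide
  null distribution.
* Genetic-map (cM) distances, X-chromosome handling and CNV-aware
  hemizygosity checks are out of scope.
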