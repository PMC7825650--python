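# Methods

This note documents the statistical procedures implemented in
`pgxcombine`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic cohorts do
and do not emulate.

## Variant QC and Hardy–Weinberg testing

Genotypes are alternative-allele counts in {0, 1, 2} with missing calls
excluded per variant (not per subject). The alternative allele frequency
is (Σ alt alleles)/(2 × non-missing subjects). Three exclusion rules are
applied to the full input matrix in one pass — missing rate > 0.05,
MAF < 0.01, HWE p < 10⁻⁶ — which makes the filter idempotent; the
report records all three statistics and the first failing rule in the
fixed precedence missingness → MAF → HWE. Boundary semantics are
strict: a variant at exactly the threshold passes. The HWE test is the
plain 1-df chi-squared statistic Σ(O−E)²/E with expected counts from the
observed allele frequency, without continuity correction and without an
exact test; its type-I error at n = 500 is verified at the nominal 5 %
level by simulation in the test suite.

## Haplotype frequencies, LD, and blocks

**EM.** Haplotype frequencies at k loci are maximum-likelihood estimates
from unphased genotypes: the E-step distributes each multilocus genotype
over its 2^(h−1) consistent haplotype pairs (h = heterozygous loci) in
proportion to current frequency products; the M-step re-estimates
frequencies from expected counts. Initialisation is the
linkage-equilibrium product of single-locus frequencies — deterministic,
no random restarts; convergence when the largest frequency change falls
below 10⁻⁸ (default), capped at 1000 iterations with the
non-convergence recorded rather than raised. The log-likelihood is
tracked and is non-decreasing (tested). Subjects missing any locus of
the current pair/span are dropped pairwise/spanwise.

**LD.** For two loci, D = p_AB − p_A·p_B on the EM haplotype
frequencies; D′ uses Lewontin's normalisation; r² = D²/(p_A(1−p_A)
p_B(1−p_B)). The 90 % confidence interval on |D′| is computed by a
deterministic likelihood grid rather than bootstrap: allele frequencies
are fixed at their sample estimates, the multinomial likelihood of the
3×3 unphased genotype table is evaluated at 201 evenly spaced values of
D′ ∈ [0, 1] (D carrying the MLE sign), normalised to unit mass, and the
cumulative 5 %/95 % points are reported.

**Blocks.** The Gabriel confidence-interval rule with the conventional
Haploview thresholds, all exposed in `BlockThresholds`: a pair is strong
LD when the D′ CI is [≥ 0.70, ≥ 0.98], strong recombination when the
upper bound is < 0.90, otherwise uninformative (pairs involving a
monomorphic locus are uninformative). A contiguous span of ≥ 2 variants
qualifies when it has at least one informative pair and ≥ 95 % of them
are strong LD; qualifying spans are accepted greedily, longest first
with ties broken leftmost, skipping overlaps. Requiring ≥ 1 informative
pair (rather than treating 0/0 as vacuously passing) was a deliberate
choice: it prevents pairs of rare variants with no information from
forming spurious blocks. On small panels the result is verified against
exhaustive span enumeration.

## CNV segmentation (sparse Bayesian learning + backward elimination)

Each subject's probe series on one chromosome is modelled as a
piecewise-constant signal plus i.i.d. Gaussian noise, y = F·w + e, where
F is the normalised step basis (one zero-mean, unit-norm column per
candidate breakpoint between adjacent probes) fitted to the centred
series.

*Stage 1 (SBL).* Each weight w_j has a zero-mean Gaussian prior with its
own precision a_j, and the precisions carry a Gamma(α, b → 0) hyperprior
with sparseness parameter α = 0.2 (default). EM alternates the posterior
moments of w with the precision update a_j = (1 + 2α)/(μ_j² + Σ_jj);
precisions diverging past 10⁸ prune their breakpoint from the active
set. Precisions are initialised broadly (10⁻²) so the data dominate the
first steps; with a tight initialisation the EM can stall in a
non-sparse configuration.

*Noise variance.* The noise level is estimated robustly from first
differences — median(diff²)/(2 × 0.4549), the χ²₁-median-corrected
estimator — and held fixed during EM. This estimator is consistent
whenever breakpoints occupy fewer than half the probe gaps, and it is
the "pooled" σ̂ used by the backward-elimination t-scores. Re-estimating
σ² jointly inside the EM (the Tipping update) was tried and rejected:
on pure-noise tracks the weakly shrunk weights absorb noise, the
residual variance collapses (observed: σ̂ ≈ 0.02 for true σ = 0.15), and
the inflated t-scores produce spurious calls.

*Stage 2 (BE).* Each surviving breakpoint is scored by
t = |mean difference of flanking segments| / (σ̂ √(1/n₁ + 1/n₂)); the
minimum-t breakpoint is removed (ties leftmost), scores recomputed, until
every survivor has t ≥ T = 4.5. Afterwards the minimum segment length
(6 probes) is enforced: while an undersized segment exists, the shortest
(ties leftmost) loses its weaker flanking breakpoint. Ordering the
length enforcement after the T-criterion is deterministic and matches
the reference behaviour of the algorithm family. Segment means are
recomputed exactly from member probes. Degenerate inputs: a constant
series yields σ̂ at its floor and all t = 0, hence a single segment; a
noiseless step yields a huge t and survives.

On short instances (≤ 12 probes, ≤ 2 breakpoints) the procedure is
verified equivalent to exhaustive minimum-RSS segmentation at the same
breakpoint count, and on noisy planted events (shift 0.6, σ = 0.15,
40 probes) it recovers both breakpoints within ±1 probe in ≥ 90 % of
runs (both in the test suite).

*Classification and filtering.* Segment means are classified into a
total, mutually exclusive five-level status: amplification (≥ +0.8),
gain ([+0.25, +0.8)), neutral, loss ((−0.8, −0.25]), deletion (≤ −0.8).
Non-neutral segments spanning strictly more than 50 bp (first to last
probe, 1-based inclusive) are kept. A segment contributes to a gene if
it overlaps the ±10 kb padded region by ≥ 1 bp. A subject's *status set*
for a gene may contain both gain-side and loss-side entries (gene-level
gain/loss frequency tables count a subject in both columns); the single
*summary* status — used for the combined tables, whose categories must
partition the cohort — is the overlapping segment with the largest
|mean log2|, ties broken by longer span, then leftmost.

## Star-allele diplotyping

Definitions ship as an editable TSV (gene, allele, rsid, alt) covering
CYP4F2 \*2/\*3, TPMT \*3C, CYP2C19 \*2/\*3, CYP3A5 \*3; \*1 is the
implicit all-reference haplotype. Given the unphased genotype at a
gene's defining SNVs, all consistent haplotype pairs are enumerated; if
exactly one pair consists of named alleles it is emitted in ascending
star order (this automatically resolves the classic double-heterozygote
to the trans pair \*2\*3, since the cis phasing would require an unnamed
haplotype carrying both defining variants). Any other genotype — e.g.
heterozygous at one defining SNV and homozygous-alternative at another —
is emitted as a composite per-locus label (`*1*2-*3*3`, locus genotypes
rendered in definition-table order and joined by "-") with
`resolved=False`, never forced into a canonical call. Missing genotypes
at defining SNVs are an error, not silently imputed.

## Combined categories

Each subject contributes exactly one category per gene: the diplotype
label plus " gain"/" loss" according to the summary CNV status
(amplification and deletion fold into "gain"/"loss" for labelling).
Percentages are count/N × 100 rounded half-up to 2 decimals (`Decimal`,
not banker's rounding), so printed tables match hand calculation; per
gene, counts sum exactly to N and rounded percentages sum to 100 ± 0.1.

## Synthetic cohorts

The generator emulates (a) unphased biallelic autosomal genotypes —
either per-variant Bernoulli draws under linkage equilibrium or two
independent draws per subject from a specified haplotype pool (HWE at
the haplotype level), with the phased truth retained; and (b) probe-level
log2-ratio tracks at regular spacing with planted piecewise-constant
events plus i.i.d. Gaussian noise (default sd 0.15, a realistic
mid-range array value). Default planted shifts are ±0.40 (single-copy
gain/loss surrogates) and ±1.0 (amplification/deletion), straddling the
±0.25/±0.8 cutoffs. All randomness derives from one seed;
per-(subject, chromosome) substreams make any track reproducible in
isolation.

It does **not** emulate hybridisation artefacts, GC waves, probe-density
variation, genotype-calling error, or linkage disequilibrium between
the CNV and SNV layers; passing tests therefore demonstrate correctness
of the algorithms under the stated noise model, not performance on raw
array data.

**Worked-example cohort.** The 614-subject fixture assigns CYP4F2
(rs3093105, rs2108622) and TPMT (rs1142345) genotypes and gene-spanning
CNV events (shift ±0.40) in fixed per-category blocks, so the full
pipeline reproduces the reference combined frequency table exactly.
Probe tracks use 500 bp spacing across the ±10 kb padded gene regions
(flank 20 probes, events 41/54 probes), giving boundary t-statistics
near 10 so that planted events are essentially never missed. Fixture
noise is drawn from a *screened* Gaussian ensemble: a track's noise
substream is redrawn (deterministically, numbered substreams in order)
if any 6–12-probe window mean reaches 0.2 in absolute value. The screen
is defined purely on the noise vector — it never consults the
segmentation — and exists because an unconditioned Gaussian cohort of
~1200 tracks contains, with appreciable probability, a genuine ≈ 4.5 σ
short-window excursion that any correct segmenter must call; the
screened ensemble makes the planted category structure identifiable by
construction while keeping sd = 0.15 and all analysis parameters
untouched. Composite reference labels are planted as the per-locus
genotype combinations the diplotyper maps to them. Only the noise
realisation varies with the seed; the category counts do not.

## Known limitations

- The EM haplotype estimator enumerates 2^k haplotypes and is limited to
  k ≤ 16 loci (blocks of that size are far beyond its intended use).
- The SBL stage solves a dense system per iteration (O(M³) per EM step);
  it is meant for gene-region tracks of tens-to-hundreds of probes, not
  whole-genome arrays.
- Gene-level CNV status uses binary ≥ 1 bp overlap with the padded
  region, with no overlap-fraction weighting.
- Only biallelic SNVs are supported; no imputation, no multi-allelic
  records, no sex-chromosome-aware handling, and no detection of hybrid
  or tandem-fusion alleles.
- The combined analysis trusts the definition table; alleles defined by
  variants absent from the genotype matrix raise an error rather than
  being approximated.
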