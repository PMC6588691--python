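# Methods

## Data model

A *haplotype* is one man's profile over the 47-locus marker registry:
repeat counts per locus, stored as multisets to accommodate multi-copy
markers (DYS385a/b, DYS459a/b, DYS724a/b, DYS464a–d, YCAIIa/b, DYF387S1,
DYF399S1, DYF403S1a, DYF404S1 are each treated as **one** locus with
copy number 2–4), plus a Y-SNP sub-haplogroup label consumed as an opaque
string. Alleles are rationals, so intermediate alleles such as 13.2 are
representable; two alleles whose fractional parts differ have no defined
step difference and render the comparison ambiguous.

A *pedigree* is a rooted paternal tree (child→father map) with optional
birth years and sampled leaves. Two meiosis counts are deliberately kept
distinct and never conflated:

- *pair (path) meioses* — edges on the path a→MRCA→b, used for depth bins,
  the mutation/meioses association and TMRCA comparison (observed TMRCA =
  path meioses / 2);
- *tree (spanning) meioses* — edges of the minimal subtree spanning all
  sampled members, used for rate estimation, so a trio's shared edges are
  counted once.

File formats are plain delimited text (tab or comma, auto-detected): a
haplotype table with one column per locus (multi-copy alleles
comma-separated inside a cell), a pedigree edge list
(`lineage_id, father, son, son_birth_year, sample_id`), and a YAML panel
registry. Pair meioses are taken from the documented pedigree, not
recomputed from birth years.

## Mutation counting

Mutations are counted between the sampled haplotypes without inferring
ancestral states or mutation direction. Every comparison is carried in
two modes: **single** (any allele change at a locus/copy is one event)
and **multi** (a change of d repeat units is d single-step events); by
construction multi ≥ single for every locus.

- *DYS389 complex*: DYS389I is nested inside the DYS389II amplicon, so
  DYS389II is replaced by the derived marker DYS389II−DYS389I before
  counting; a mutation in the shared stretch then registers exactly once.
- *Multi-copy loci*: the two multisets are matched by the bijection
  minimising total absolute steps (exhaustive enumeration; ≤ 4 copies ⇒
  ≤ 24 bijections). If copy numbers differ, or minimising bijections
  disagree on the number of mutated copies, the locus is excluded for
  that genealogy — ambiguity is dropped, never guessed. A tie among
  minimising bijections that agree on the event count is not ambiguous.
- *Trios*: counted by parsimony on the documented 3-leaf topology,
  enumerating integer ancestral states over the observed allele range
  (single-copy) or the observed multisets (multi-copy) and minimising
  total steps first, mutated branches second. For a pair this reduces
  exactly to the direct comparison. How real multi-member genealogies
  apportion mutations internally is not observable; parsimony is the
  minimal-assumption convention and is logged as such.

## Non-paternity screening

Screens run in a fixed order. (a) Haplogroup concordance: a discordant
pair is excluded; a trio with exactly one discordant member keeps its
concordant pair. (b) An iterative Grubbs test (two-sided on the most
extreme deviation, α = 0.05, one removal per round) on the per-genealogy
mutation load, multi-mode counts over all typed loci.

The raw mutations/meioses ratio is heteroscedastic (variance ∝ 1/meioses)
and right-skewed, and the normal-theory Grubbs test applied to it is
markedly anticonservative — on clean simulated cohorts it removed at
least one genuine lineage almost half the time. The cohort screen
therefore applies Grubbs to the **Poisson deviance residuals** of the
per-genealogy counts under a common fitted rate, which are approximately
standard normal; with them the false-exclusion rate is at the nominal
few-percent level while an unrelated substituted haplotype remains an
overwhelming outlier. The raw-ratio variant is available
(`statistic="ratio"`). When the Grubbs screen flags a trio, the trio is
reduced to its least-mutated pair instead of being dropped, mirroring how
a within-trio outlier haplotype is handled in practice.

The Grubbs p-value uses the classical t-based null: with
t² = n(n−2)G²/((n−1)²−nG²), p = c·n·P(T_{n−2} > t), c = 2 two-sided
(verified by Monte-Carlo to reject at 4.8% for α = 5%, n = 30).

## Rates, bands, bins and comparisons

Rates are exact ratios k/n per locus per meiosis. The 95% band is the
2.5%/97.5% binomial quantile at the point estimate — Q(q)/n for
Binomial(n, k/n) — which is a quantile band, not a coverage-calibrated
interval; it is undefined (reported as a dash) when k = 0. Panel
estimates pool counts (Σk/Σn) across the panel's loci; pooling, not the
unweighted mean of locus rates, reproduces the published panel values.
Report tables round half-up to 2 decimals on the ×10³ scale.

Depth bins 7–10, 11–19, >19 meioses partition the pair-level data (all
pairs within a genealogy) and receive pooled rates and bands each. Count
comparisons between datasets use the two-sided Fisher exact test on the
2×2 mutations/meioses table and the exact binomial test against a null
proportion; comparison denominators from other studies are user-supplied
configuration, never hard-coded.

## Generation time and association

Generation time = Σ(father→son birth intervals) / (number of meioses with
birth years on both ends of the edge); the 95% CI resamples edges
(branches) i.i.d. with replacement, 1000 replicates by default. The
point estimate depends only on edge totals, so it is invariant to how
lineages are partitioned.

Association fits OLS of pair-level mutation counts (y) on pair meioses
(x) with intercept — this orientation, with mutations as the response,
makes the expected slope equal (number of loci) × (per-locus rate) — and
reports slope, its t-test p-value, multiple/adjusted R², plus Spearman
rank correlation with midrank ties.

## TMRCA posteriors

For a pair separated by τ total meioses, each locus accumulates mutations
as a Poisson process with per-meiosis rate μ (the panel-pooled multi-mode
rate by default; locus-specific rates are a caller option):

- **IAM**: a locus is identical iff zero mutations occurred on the τ
  transmissions; with k of n loci differing,
  L(τ) = (1−e^(−μτ))^k e^(−μτ(n−k)).
- **SMM**: each mutation shifts the count ±1 with equal probability; the
  net displacement follows P(D=d) = e^(−μτ) I_{|d|}(μτ), evaluated with
  the scaled Bessel function `ive` for stability, and the per-locus
  minimal step differences multiply.

The posterior is prior × likelihood normalised on a discrete τ grid,
default uniform on 1..600 meioses in steps of 1 (a population-size
geometric prior is available; the grid upper end is ≥ 40× the documented
depth scale and summaries change by < 1% under grid refinement).
Summaries are in generations (τ/2): mean Στp/2; median and the 95% band
as the smallest grid values whose CDF reaches 0.5/0.025/0.975; mode as
the argmax, ties to the smallest τ. Posteriors with k ≥ 1 are
right-skewed, giving mean ≥ median ≥ mode.

Evaluation against documented depths: the coverage fraction (percentage
of observed TMRCAs inside their bands), a signed deviation statistic
Σ(estimate−observed)/(N−1) — the N−1 normalisation is this package's
declared convention — and OLS of observed on estimated values, optionally
through the origin. A documented depth **below** the 95% band flags a
likely non-paternity event.

## Synthetic cohorts

The generator emulates the sampling design the analysis assumes: 66
lineages by default with a 3/66 trio fraction, pair path meioses uniform
on 7..30 (the documented-genealogy range; the ≥7 floor mirrors the
sampling rule), per-edge per-locus Poisson mutations at the published
locus rates, 96% of events single-step with multi-step jumps of 2/3/4
units at 75/15/10% of the remaining mass (loosely following the observed
14:3:2 split of two/three/four-step cases), father→son intervals normal
with mean 33.57 y, sd 5 y, truncated to 16–60 y, founder alleles uniform
on 10..20 repeats (absolute values never matter downstream), and a small
haplogroup label pool. Mutations are placed per edge so trio parsimony
and stacked "pseudo multi-step" changes arise naturally. Non-paternity
injection replaces one sampled member with an unrelated founder draw,
with a discordant haplogroup label in 7/8 of events (mirroring the 7:1
labelled-to-silent split of the reference screening scenario; the silent
event is planted in a trio, where the outlier screen reduces rather than
drops the lineage, so the scenario retains 59 of 66 genealogies).

What the generator does **not** model: allele-length or haplogroup
dependence of mutation rates, copy-number change at multi-copy loci,
genotyping error, and population structure among founders. Passing
calibration tests therefore demonstrates internal consistency of
counting, screening and inference under the stated mutation model — not
robustness to those real-data features.

## Problem sizes and numerical choices

Calibration checks use 500 simulated pairs for interval coverage, 100
replicate cohorts of 40 pairs for slope recovery, ~10⁴ meioses for rate
recovery, and 10⁵ Monte-Carlo replicates for the likelihood oracles —
sizes at which binomial/Monte-Carlo error is small relative to the
tolerances asserted. Posterior normalisation is checked to 1e−12; the
stepwise displacement law is verified to sum to 1 within 1e−10 truncated
at |d| ≤ 50. Fractional-part comparisons of alleles use a 1e−6 tolerance.
All randomness flows through a single seeded NumPy generator per
operation; identical seeds give byte-identical simulated files.

## Known limitations

- Trio parsimony is an assumption about unobservable within-genealogy
  placement; it can undercount genuinely homoplasic configurations.
- The binomial-quantile band is not a coverage-calibrated CI (its
  coverage drifts with k); it is reported because it is the band the
  direct-counting literature prints.
- SMM treats a multi-copy locus's pooled step difference as one walk,
  which is an approximation when several copies mutate.
- TMRCA posteriors condition on a point estimate of μ; rate uncertainty
  is not propagated.
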