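# Methods

## Branching-process model of arm-level copy-number evolution

Tumour history is divided into `N` arbitrary time periods.  Within each
period every extant copy of every chromosome arm independently undergoes a
deletion with probability `α`, no change with probability `β`, or a
duplication with probability `γ`, with `α + β + γ = 1`.  The per-copy
offspring probability generating function is `f(s) = α + βs + γs²`, and a
lineage started from one copy has, after `N` periods, the copy-number
distribution whose pgf is the `N`-fold composition `F_N = f ∘ … ∘ f`.  The
aneuploidy+WGD model adds one synchronous doubling of all extant copies
after period `M` (`1 ≤ M ≤ N`), giving `G(s) = F_M([F_{N−M}(s)]²)`.
`M = 0` is excluded because doubling before any evolution is
indistinguishable from a changed starting state.

Generating functions are stored as coefficient vectors and composed by
Horner-scheme polynomial arithmetic on floats.  For `N = 6` the per-allele
degree is at most `2^(N+1) = 128`, the coefficient arithmetic is exact to
roughly 1e-12, and the probability mass is checked to sum to 1 within
1e-9 on every evaluation.  No symbolic algebra system is needed.  Above
`N = 8` the degree growth (`2^(N+1)`) makes the composition and the
downstream grid search expensive; `N` is configurable but 6 is the
default working resolution.

### Likelihood

The observation unit is the allele: each determined arm contributes two
independent single-copy lineages, one for the major and one for the minor
allele, each scored against the per-allele distribution.  This choice is
consistent with the model capacity of 256 total copies per arm
(2 alleles × 2^(6+1)).  Whole-chromosome gains and losses are treated as
two independent arm events; focal amplifications and complex events are
outside the model.  Undetermined arms are skipped.  An observed per-allele
count with probability zero yields a log-likelihood of −∞ (held as a large
negative sentinel during optimisation and never handed to the refiner);
a count beyond the support raises an explicit error suggesting a larger
`N`.

Arm-level observations are produced from segment tables by
`summarize_arms`: the length-weighted modal (major, minor) pair among
determined overlapping segments, with the arm set to undetermined when
determined coverage is below 50% of the arm length.  Ties in the modal
weight break deterministically to the numerically smallest pair.

### Fitting and model selection

By default the symmetric constraint `α = γ = r` is imposed and `r` is
searched over `[0, 0.5]` with a deterministic 0.005-step grid followed by
golden-section refinement to 1e-5; the WGD model additionally enumerates
`M ∈ {1, …, N}` and keeps the argmax (ties to the smallest `M`).  The
unconstrained mode optimises `(α, γ)` on a 0.02-step simplex grid with
Nelder–Mead refinement from the best grid point.  Both paths are free of
stochastic search, so fits are bit-for-bit reproducible.

Free-parameter counts are `(k_WGD, k_non-WGD) = (3, 2)` in general and
`(2, 1)` under the symmetric constraint.  Each `FitResult` carries the AIC
`2k − 2·logL` with its own counting; the model comparison applies the
general counting to both sides uniformly, which adds a constant +2 to both
constrained AICs and leaves `ΔAIC = AIC_non-WGD − AIC_WGD` unchanged.
`ΔAIC > 0` selects WGD; ties resolve to the non-WGD model by parsimony.

### Arm definitions

Arms are derived from UCSC cytoBand-format files by splitting each
chromosome at the junction of its two `acen` centromere bands.  The
acrocentric short arms 13p, 14p, 15p, 21p and 22p are excluded by default
(no reliably assayable sequence), and the sex chromosomes are parsed but
excluded from model fitting because copy-number interpretation there
depends on sex; this leaves 39 modelled autosomal arms.  A bundled hg19
arm table (chromosome lengths and centromere bands at the 100-kb
resolution of the cytogenetic band table) is used when no file is given.

## Allelic-imbalance and LOH summarisation

A segment with integer allele-specific copy numbers is *balanced* when
`major = minor`, *AI without LOH* when `major > minor > 0`, and *LOH* when
`minor = 0`.  Homozygous deletions `(0, 0)` are counted as LOH, since loss
of heterozygosity is implied by the absent minor allele.  Genome state
fractions are length-weighted over a stated genome length, with uncovered
or CN-missing territory reported as undetermined rather than dropped;
mean ploidy is the length-weighted mean total copy number over determined
segments only.

Acquired LOH between an early and a late sample is the interval
intersection of late LOH segments with early-determined non-LOH segments;
early-undetermined territory is excluded (conservative: LOH that may have
pre-existed is never called acquired).  Overlapping acquired-LOH segments
across a patient's late samples are merged into events by single linkage
with a ≥1 bp overlap criterion (adjacency does not merge).

Mirrored allelic imbalance between two lesions is scored over shared
heterozygous SNPs in a region as the negated Pearson correlation of
`BAF − 0.5`; a call requires at least 10 shared SNPs, mean `|BAF − 0.5|`
above 0.1 in both samples, and a score above 0.5.  Both thresholds are
package choices (the phenomenon is qualitative) and are exposed as
function arguments.  When a noise-free track makes the correlation
degenerate, the score falls back to the sign of the product of mean
deviations, preserving the reflection antisymmetry of the statistic.

CCFs of lost mutations are reported descriptively (medians per group,
inside versus outside acquired LOH); no hypothesis test is attached.

## Sculpting statistics

`p_ns` — the probability that a random coding single-nucleotide change is
non-synonymous — is computed by enumerating, for each sense codon, its 9
single-nucleotide neighbours under the standard genetic code, classifying
each change (stop-gains count as non-synonymous), and weighting codons by
a usage table (uniform substitution across the 9 neighbours; a
trinucleotide-spectrum weighting could be slotted in at the same
interface).  Under uniform usage `p_ns ≈ 0.756` (415/549 changes).

A segment with `n_syn` synonymous mutations is expected to carry
`n_syn · p_ns/p_s` non-synonymous ones; the segment *exceeds* expectation
when `n_nonsyn` is strictly greater, which is algebraically equivalent to
`n_nonsyn > m·p_ns` for `m` total mutations.  Only segments strictly
longer than 10 Mb enter the aggregate test, discarding small fragments
prone to over-segmentation.  The aggregate test is an exact one-sided
binomial tail `P(X ≥ k)` for `k` exceeding segments out of `n`, with two
null modes: `half` (`p₀ = 0.5`) and the default `per_segment`, where `p₀`
is the mean over segments of `P(Binomial(m, p_ns) > m·p_ns)` — the
segment's own exceedance probability when consequences are assigned
independently of position.  The per-segment null accounts for the
asymmetry of small-count binomials, where the exceedance probability can
sit well away from one half; under null-generated cohorts its p-values
are uniform (verified by a KS check in the test suite).

Neoantigen losses are counted per merged LOH event: a predicted
neoantigenic mutation (optionally restricted to expressed genes) is lost
to an event when its position lies in the event interval and it is absent
from every member late sample; patient totals de-duplicate mutations
shared between events.  For the mutual-exclusivity question, events are
median-split into high/low predicted neo-antigenicity and high/low
non-synonymous count (ties to low) and the resulting 2×2 table is tested
with a two-sided unconditional exact test: columns are treated as
independent binomials with a common nuisance success probability π, the
statistic is the pooled Wald score, and the p-value is the maximum over a
999-point uniform π grid of the probability of outcomes at least as
extreme as observed.  Coarser grids move the p-value only in the third
decimal at these table sizes.  Degenerate pooled proportions (all
successes or all failures) are assigned a statistic of zero.

## Synthetic cohorts

The generator emulates the structure of a multi-sample autopsy series:
per patient, near-diploid early lesions and late metastases whose
arm-level copy numbers are forward-simulated from the same branching
process the inference fits (default rate 0.05 per copy per period, `N = 6`,
doubling after period 3 when WGD is configured, 39 autosomal arms on hg19
geometry).  Acquired LOH is planted by forcing `minor = 0` on randomly
chosen early-heterozygous arms until a target genome fraction (default
20%, in the range observed in heavily LOH-affected late disease) is
reached, shared across the patient's late samples so that merging
recovers one event per arm.  Mutations (default 400 per patient, 75%
non-synonymous, matching the coding expectation) are placed uniformly
within arms; a quarter are lost between early and late disease, 80% of
losses inside the planted LOH territory.  Lost-in-LOH mutations get high
early CCFs (0.9) and other losses low CCFs (0.35), mimicking the
subclonal explanation for losses outside LOH.  Planted per-event
neoantigen losses are realised as dedicated lost non-synonymous mutations
with attached expressed-neoantigen records; retained mutations carry
background neoantigens.  BAF tracks put one late sample at `0.5 + 0.3`
and a second at `0.5 − 0.3` (mirrored) with Gaussian noise (sd 0.03,
truncated to [0, 1]).

Segment boundaries are jittered inward by up to 1 Mb to exercise interval
logic; mutation positions keep a jitter-sized margin so planted
attributions survive the jitter.  `PatientConfig.noise_free()` switches
off the branching noise, jitter, CCF and BAF noise, making every planted
quantity exactly recoverable — the basis for the end-to-end recovery
tests.  One RNG substream per patient is derived from the master seed, so
cohorts are stable under appending patients, and identical seeds yield
byte-identical output bundles.

What the generator does **not** emulate: subclonal/non-integer copy
number, cellularity and purity effects, focal amplifications,
over-segmentation noise, mutational-signature-specific spectra, read-level
data, or realistic linkage between mutation density and genomic features.
Passing recovery tests therefore demonstrate correctness of the
algorithms under the model's own assumptions, not robustness to the full
messiness of sequencing-derived inputs.

## Problem sizes and numerical checks

The test suite verifies: exact agreement of the generating-function
distribution with exhaustive rational-arithmetic tree enumeration for
`N ≤ 3` (with and without WGD); total-variation distance below 0.01
between the `N = 6` distribution and 10⁵ forward-simulated lineages; AIC
model selection choosing the generating condition in ≥90% of 100
simulated 39-arm profiles per condition at rate 0.05; mean absolute rate
recovery error below 0.02 over 200 replicates; exact equality of the
binomial excess test with closed-form tails and KS-uniformity of its
p-values over 500 null cohorts of 194 segments; agreement of the
unconditional exact test with a brute-force enumeration oracle and with
an independent library implementation; and exact ground-truth recovery on
noise-free synthetic patients.  These replicate counts keep the default
suite in the tens of seconds while leaving the statistical assertions
comfortably powered.

## Known limitations

* The likelihood's observation unit (per-allele lineages) is a modelling
  choice; a total-copy-number variant would weight arms differently.
* Integer allele-specific copy numbers are required; subclonal states
  must be rounded upstream.
* Only a single WGD event is modelled; repeated doublings are outside the
  model and will be absorbed into inflated duplication rates.
* The binomial excess test treats segments as independent, ignoring
  shared lineage among a patient's samples.
* Expressed-neoantigen accounting relies entirely on upstream binding
  prediction and a configured expressed-gene list; no immunogenicity
  claim is implied.
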