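# wgdevolve

Inference of whole-genome doubling (WGD) from arm-level allele-specific
copy number, together with allelic-imbalance/LOH genome summarisation and
"sculpting" statistics that ask whether loss of heterozygosity
preferentially deletes non-synonymous mutations or predicted neoantigens.
The package targets multi-sample tumour series — early lesions (primaries,
regional metastases) paired with late distant metastases of the same
patient — of the kind produced by rapid-autopsy programmes, with
melanoma-scale mutation loads in mind.

## The model

Tumour history is divided into `N` discrete time periods.  In each period
every extant copy of every chromosome arm is independently

* deleted with probability `α`,
* left unchanged with probability `β`,
* duplicated with probability `γ`,  with `α + β + γ = 1`.

Starting from one copy, the copy-number distribution after `N` periods is
obtained from the offspring probability generating function
`f(s) = α + βs + γs²` by `N`-fold composition, `F_N = f ∘ … ∘ f`.  A single
whole-genome doubling after `M ≤ N` periods doubles every extant copy
synchronously:

```
G(s) = F_M( [F_{N−M}(s)]² )
```

Generating functions are represented as coefficient vectors and composed
by exact polynomial arithmetic, so with `N = 6` the model represents total
arm copy numbers up to `2 · 2^(6+1) = 256`.  Each arm contributes two
independent single-copy lineages (its major and minor allele) to the
likelihood.  The aneuploidy-only and aneuploidy+WGD models are fitted by
maximum likelihood (deterministic grid plus golden-section refinement,
with `α = γ` imposed by default) and compared by the Akaike Information
Criterion using the general parameter counting (3 vs 2 free parameters):

```
ΔAIC = AIC_non-WGD − AIC_WGD        ΔAIC > 0 supports genome doubling
```

Downstream, segments are classified as balanced (`major = minor`),
allelic imbalance without LOH (`major > minor > 0`) or LOH (`minor = 0`);
acquired LOH is the territory that is LOH in a late sample but determined
and heterozygous in the early sample.  Sculpting statistics compare each
large (>10 Mb) acquired-LOH segment's non-synonymous count against the
codon-usage expectation `n_syn · p_ns/p_s`, aggregate the excess flags
with an exact one-sided binomial test, count predicted expressed
neoantigens deleted per merged LOH event, and test mutual exclusivity of
neo-antigenicity and non-synonymous load with a two-sided unconditional
exact (Barnard) test.

## Worked example

Simulate one patient (one near-diploid early lesion, two post-WGD
metastases drawn from the branching process at rate 0.05 with doubling
after period 3) and run the model comparison on every sample:

```python
from wgdevolve.cn_model import fit_model, select_model, summarize_arms
from wgdevolve.synthetic import (PatientConfig, default_arm_definitions,
                                 simulate_patient)

bundle = simulate_patient(PatientConfig(patient_id="DEMO"), seed=42)
arms = default_arm_definitions()
for sample_id in bundle.early_samples + bundle.late_samples:
    profile = summarize_arms(bundle.segment_tables[sample_id], arms)
    sel = select_model(fit_model(profile, with_wgd=True),
                       fit_model(profile, with_wgd=False))
    rate = (sel.fit_wgd if sel.selected == "wgd" else sel.fit_non_wgd).params.alpha
    print(f"{sample_id}: selected={sel.selected:8s} "
          f"dAIC={sel.delta_aic:+9.2f} rate={rate:.4f} "
          f"M={sel.fit_wgd.params.wgd_time}")
```

Output:

```
DEMO-E1: selected=non_wgd  dAIC=  -221.07 rate=0.0000 M=1
DEMO-L1: selected=wgd      dAIC=   +57.12 rate=0.0519 M=4
DEMO-L2: selected=wgd      dAIC=   +35.95 rate=0.0742 M=3
```

The diploid early lesion strongly rejects WGD (large negative ΔAIC: the
doubling model would have to undo the doubling with deletions), while both
simulated metastases support it, with per-period event-rate estimates near
the generating value of 0.05.

The same analyses are available from the shell:

```sh
wgd-evolve simulate --seed 42 --patients 1 --out cohort/
wgd-evolve fit-wgd --segments cohort/DEMO1/DEMO1-L1.segments.tsv --n-periods 6
wgd-evolve run --config config.yaml --out results/
```

Segment TSVs use 1-based closed coordinates (Sequenza dialect); internal
processing and emitted BED-like tables are 0-based half-open.

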