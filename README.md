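# qstratify

Sensory-profile stratification for peripheral neuropathic pain.

Patients with neuropathic pain of very different etiologies (diabetic
polyneuropathy, peripheral nerve injury, postherpetic neuralgia, ...) fall
into three recurring somatosensory phenotypes: **sensory loss (SL)**,
**thermal hyperalgesia (TH)**, and **mechanical hyperalgesia (MH)**.
Stratifying trial populations by phenotype — rather than etiology — is a
promising route to less noisy treatment effects.  `qstratify` implements
the individual-patient allocation algorithm for these phenotypes from a
13-parameter quantitative sensory testing (QST) z-profile, plus everything
needed to plan a phenotype-stratified trial around it: ROC/Youden cutoff
derivation for the healthy-profile probability, agreement statistics,
phenotype-frequency summaries, sample-size and screening-population
arithmetic, and a synthetic cohort generator so every step can be exercised
without patient data.

## The algorithm

Each subject is a vector of QST z-values $z_i$, $i = 1,\dots,13$ (eleven
continuous parameters normalized to healthy mean 0 / SD 1; paradoxical heat
sensation coded 0/+2 and dynamic mechanical allodynia coded 0/+2/+3).  A
phenotype $m$ is summarized by its centroid — per-parameter mean
$\mu_i^{(m)}$ and SD $\sigma_i^{(m)}$.  The per-parameter similarity is the
Gaussian density normalized to its own maximum:

$$F_i^{(m)}(z_i) = 100 \cdot \exp\!\left(-\frac{(z_i - \mu_i^{(m)})^2}{2\,\sigma_i^{(m)2}}\right)\ \%$$

so a value exactly at the centroid mean scores 100 % regardless of the
cluster's spread.  The **phenotype probability** is the arithmetic mean of
$F_i^{(m)}$ over the *non-missing* parameters — missing values are simply
left out, which is the point of using densities instead of centroid
distances (no imputation, no exclusion of incomplete profiles).  A fourth
probability, "healthy", uses $\mu_i = 0,\ \sigma_i = 1$ for every
parameter.

Two allocation modes:

- **deterministic** — assign the single phenotype with the highest
  probability (ties broken SL > TH > MH > HEALTHY and flagged);
- **probabilistic** — assign *every* phenotype whose probability strictly
  exceeds a cutoff (default 64 %, the Youden-optimal threshold of the
  healthy-profile probability); a subject with no exceedance, or whose only
  exceedance is "healthy", is excluded.

A **simplified protocol** uses only warm detection threshold (WDT) and
mechanical pain sensitivity (MPS), the two parameters that explain most of
the between-phenotype variance.

**Centroid table.** The packaged default
(`src/qstratify/data/centroids_synthetic.csv`) is a *synthetic* stand-in
constructed from the published qualitative phenotype descriptions — the
defining cohort's numeric table is not redistributable here.  Every entry
point accepts a user table (`--centroids`, `CentroidTable.from_csv`) with
columns `phenotype,parameter,mu,sigma`; z-value signs are taken as given
(no re-signing is performed), so your table must use the same
loss/gain sign convention as your profiles.

## Worked example

```python
import qstratify as q

centroids = q.CentroidTable.load_default()

# simulate a labelled cohort: 200 per phenotype plus 200 healthy subjects
cohort = q.generate_cohort(q.CohortSpec(
    n_per_group={g: 200 for g in q.Phenotype}, seed=12345, sd_scale=1.0,
))

# deterministic allocation, healthy profile competing as a fourth label
result = q.allocate_cohort(cohort.profiles, centroids, mode="deterministic")
report = q.truth_recovery_report(cohort.truth_labels, result.allocations)
print(f"recovered {report.accuracy:.1%} of true labels, kappa = {report.kappa:.2f}")
for m in ("SL", "TH", "MH"):
    print(f"  {m}: recall {report.recall[m]:.1%}")

# screening plan: crossover trial powered at 80% for d = 0.5,
# phenotype present in 30% of the etiology of interest
n = q.required_n(q.PowerSpec(effect_size=q.cohen_d(2, 4), design=q.Design.CROSSOVER))
print(f"subgroup n = {n}, screen {q.screening_size(n, 0.30)} patients")
```

prints

```
recovered 77.1% of true labels, kappa = 0.69
  SL: recall 96.5%
  TH: recall 61.5%
  MH: recall 88.0%
subgroup n = 34, screen 114 patients
```

At the default noise level the allocator recovers the generating phenotype far
above the 33 % chance level; TH is hardest because its centroid sits close
to the healthy reference — exactly the overlap the probabilistic mode and
its 64 % cutoff are designed to surface.  A crossover trial detecting a
mean effect of 2 NRS points against a response SD of 4 (Cohen's d = 0.5)
needs 34 subjects of the target phenotype, hence 34/0.30 → 114 patients
screened with QST.

The same flows are available from the shell:

```
qstratify simulate --n-sl 200 --n-th 200 --n-mh 200 --n-healthy 200 --seed 7 --out sim/
qstratify allocate --input sim/profiles.csv --mode probabilistic --cutoff 64 --out alloc/
qstratify plan --frequencies freq.json --design crossover --out plan/
```

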