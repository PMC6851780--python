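# spirosim

Monte Carlo simulation of spirometric FEV₁ testing protocols: how
repeatability criteria (RC) and early test termination create measurement
error, plus the auxiliary analytics that go with the question — survey
exclusion-rate arithmetic, inference of the population intratest
coefficient of variation (CVm), and minimum-detectable-difference (MDD)
thresholds.

## Model

A single subject's predicted normal FEV₁ is a deterministic function of
height and age (default 173 cm, 59 yr → 3.55 L/sec). Each simulated test
draws a session mean from Normal(μ, σt²) (intertest variability, default
CVt = 3%, σt = 0.11 L/sec) and eight i.i.d. maneuvers from
Normal(test mean, σm²) (intratest variability, default CVm = 6%,
σm = 0.21 L/sec). The conventional protocol qualifies a test once the
highest and second-highest maneuvers so far differ by ≤ RC (default
0.15 L/sec, minimum three maneuvers) and reports the maximum seen at that
point; the unconstrained alternative reports the maximum of all eight
maneuvers. Measurement error is the gap between the two reported
distributions.

## Library

```python
import spirosim as ss

subject = ss.SubjectProfile()                      # 173 cm, 59 yr
var = ss.derive_sigmas(subject, cv_t=0.03, cv_m=0.06)   # sigma_t=0.11, sigma_m=0.21
cohort = ss.simulate_cohort(ss.SimulationConfig(subject, var, seed=1))

protocol = ss.ProtocolConfig(rc=0.15, stop_rule=ss.StopRule.fixed(3))
summary = ss.measurement_error_summary(cohort, protocol)
print(summary.mean_error, summary.mean_error_pct)   # ~0.19 L/sec, ~5.1 %

curve = ss.rejection_curve(cv_m=0.06, seed=1)       # ~49% at m=3, ~15% at m=8
ss.mdd_paired_difference(0.11).threshold            # ~0.4 L/sec
```

Measurement error supports two bases: `population` (default; difference
between the unconstrained and protocol-reported distributions — the basis
on which the published sensitivity table is reproducible) and
`within_test` (per-test paired difference). See each module's docstring.

## CLI

One subcommand per exhibit; each run writes CSV/JSON outputs plus a
manifest (config echo, seed, version, wall time) so results are
regenerable bit-identically:

```bash
spirosim --seed 1 --out out table2    # two-maneuver exclusion vs CVm 1-10%
spirosim --seed 1 --out out table4    # mean-error grid: RC x CVm
spirosim --seed 1 --out out fig1      # rejection curves by maneuver count
spirosim --seed 1 --out out cdf       # paired CDFs + error at each quantile
spirosim --seed 1 --out out mdd       # minimum detectable differences (JSON)
spirosim --seed 1 --out out nhanes    # exclusion-rate table + CVm fit
spirosim --seed 1 --out out simulate  # raw cohort CSV
```

Configuration is YAML or JSON (`--config cfg.yaml`); an empty file means
full defaults, unknown keys are rejected by name:

```yaml
subject: {height: 173, age: 59}
variability: {cv_t: 0.03, cv_m: 0.06}
protocol: {rc: 0.15, min_maneuvers: 3, max_maneuvers: 8}
simulation: {n_tests: 20902, seed: 1}
```

## Data

`src/spirosim/data/nhanes_maneuver_counts.csv` reproduces a published
survey maneuver-count table verbatim, including its internal
inconsistencies; loading it raises `CountConsistencyWarning`s rather than
failing, and the printed excluded counts take precedence for the rates.
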