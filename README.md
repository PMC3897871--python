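# explorebandit

Behavioral modelling and second-level statistics for restless multi-armed
bandit experiments on exploration/exploitation, built for studies that
compare expert groups (e.g. entrepreneurs vs managers) on *decision-making
efficiency* — task performance divided by decision time — and relate it to
regional brain activity.

The package provides, as a tested and reusable pipeline:

* **Task simulation** — the restless four-armed bandit whose latent mean
  payoffs follow a decaying Gaussian random walk
  μ<sub>i,t+1</sub> = λμ<sub>i,t</sub> + (1 − λ)θ + ν,
  ν ~ N(0, σ²_d), with integer payoffs drawn N(μ<sub>i,t</sub>, σ_o) and
  kept in [1, 100] (defaults: λ = 0.9836, θ = 50, σ_d = 2.8, σ_o = 4,
  300 trials in 4 runs of 75, 1.5 s response window).
* **Choice model** — a Kalman filter tracking a Gaussian belief
  (mean, variance) per arm with gain κ = σ²<sub>pre</sub>/(σ²<sub>pre</sub> + σ²_o)
  and AR(1) diffusion between trials, combined with a softmax rule
  P(i) ∝ exp(β μ̂<sub>i</sub>); β is the per-subject exploration
  (inverse-temperature) parameter.
* **Maximum-likelihood fitting** — learning parameters
  (λ, θ, σ_d, σ_o, μ₀, σ²₀) shared across all subjects, β per subject
  (profiled out exactly by a convex Newton step), bounded L-BFGS-B with
  seeded multistarts; plus the pooled t-test comparing group betas.
* **Explore/exploit labelling** — a trial is *exploitative* when the chosen
  arm is the one currently believed best, *explorative* otherwise.
* **Behavioral statistics** — per-subject efficiency (total payoff / mean
  RT, points/s), explore and exploit efficiency cells, descriptive cohort
  summaries, and 2 × 2 mixed-design ANOVAs (choice type within, group
  between; all effects F(1, n − 2)).
* **ROI statistics** — explore-vs-exploit contrasts (pooled t, df = 2n − 2),
  the frontopolar choice-by-group interaction ANOVA, and the OLS regression
  of efficiency on group membership plus 7 ROIs × 2 conditions
  (F(15, n − 16)).
* **Synthetic cohort generator** — a seeded two-group study (24 + 26
  subjects) with per-group exploration parameters, lognormal response
  times, missed trials, and ROI tables with planted condition effects, a
  frontopolar interaction and efficiency coupling, so the whole pipeline
  runs end to end with no external data.

## Worked example

```python
from explorebandit import (CohortConfig, generate_cohort, fit,
                           compare_group_betas, label_trials,
                           efficiency_table, mixed_anova)

sessions, groups = generate_cohort(CohortConfig(), seed=7)
result = fit(sessions, restarts=2, seed=0)
test = compare_group_betas(result, groups)
labels = {s.subject: label_trials(s, result.params) for s in sessions}
table = efficiency_table(sessions, labels)
```

Running the full example (`fit`, group comparison, efficiency ANOVA and the
ROI statistics on a matched synthetic activity table) prints:

```
fitted decay lambda = 0.8985, center theta = 54.77
total NLL = 12431 nats ({'entrepreneur': 5847, 'manager': 6584})
group betas: 0.161 vs 0.156, t(48) = 0.24, p = 0.81
efficiency group        F(1, 48) =   6.052, p = 0.0175
efficiency condition    F(1, 48) = 158.986, p = 0.0000
efficiency interaction  F(1, 48) =   1.463, p = 0.2323
mean RT: entrepreneurs 0.387 s, managers 0.434 s
rIPS contrast: t(98) = 4.85, explore > exploit
rFPC_switch choice-by-group interaction: F(1, 48) = 28.00, p = 0.000
efficiency regression: R2 = 0.42, adj R2 = 0.16, F(15, 34) = 1.64
```

Reading the output: the cohort-level fit recovers the learning parameters
the agents were generated with (decay 0.8985 vs 0.8941 generating); the
group difference in exploration parameters is null, as planted; the
efficiency ANOVA shows the choice-type main effect (exploit cells carry
most of the payoff) and the group main effect driven by the
entrepreneur-like group's faster responses at equal payoff; the ROI
statistics recover the planted explore > exploit parietal effect, the
frontopolar interaction, and an efficiency regression of the expected
magnitude. Numbers vary with the seed.

The same pipeline is available from the shell:

```sh
explorebandit synth --seed 7 --outdir data/
explorebandit fit   --sessions data/sessions.csv --out data/fit.json
explorebandit label --sessions data/sessions.csv --fit data/fit.json --out data/labels.csv
explorebandit stats --sessions data/sessions.csv --labels data/labels.csv --out data/stats.json
explorebandit roi   --betas data/betas.csv --efficiency data/stats.csv --out data/roi.json
```

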