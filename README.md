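# ddmeta

Analysis pipeline for studies that dissociate **decision-making** from
**post-decisional confidence** in two-alternative forced-choice (2AFC) tasks,
using an extreme-group design: participants are screened on a trait
questionnaire (here, the 24 combined Hesitation + Preoccupation items of an
action-control scale), the high and low tails become the two groups, and the
question is whether the groups differ in how they *decide* (drift-diffusion
parameters) or only in how they *evaluate* their decisions (confidence bias
and meta-d′ sensitivity).

The package is aimed at cognitive scientists who want the complete chain —
trial preprocessing, hierarchical Bayesian drift-diffusion fitting with
two-stage DIC model selection, type-2 signal detection (meta-d′), LISAS
efficiency scores, mixed-design ANOVA with Greenhouse–Geisser correction and
generalized η², calibration of dot-motion difficulty, and a power simulation
for the extreme-group design — as tested, reusable code.  A synthetic-data
module generates populations and behavioural datasets with the structure such
a study assumes (decision parameters drawn from *identical* hyper-distributions
in both groups; a ~6-point group gap in the confidence read-out), so every
stage runs end-to-end with no external data.

## The models at the core

**Drift-diffusion model (DDM).** Evidence `x(t)` accumulates at drift `v`
(unit diffusion) between absorbing boundaries 0 and `a`, starting at `z·a`;
observed RT is the first-passage time plus non-decision time `Ter`.  The
defective first-passage density is evaluated with the dual small-time /
large-time series expansion (truncation error ≤ 1e−7).  Subjects are
partially pooled: on transformed scales (raw `v`, `log a`, `logit z`,
`log Ter`), subject parameters are Normal(group mean, group SD), sampled by
an adaptive Metropolis-within-Gibbs sampler (jit-compiled) with conjugate
Gibbs updates for the group means and between-group offsets.  Model
comparison uses DIC = D̄ + p_D with p_D = D̄ − D(θ̄), a ΔDIC > 10 significance
rule, and Gelman–Rubin R̂ < 1.1 as the convergence criterion over chains.

**Two-stage model selection.** Stage 1 compares within-subject structures
only (8 models for the speed/accuracy task: `v`, `a`, `Ter` each constant or
by emphasis; 16 for the cued task: `z` by cue, `v` by cue and/or stimulus,
`Ter` by cue — the start point can never depend on the upcoming stimulus).
Stage 2 freezes the winner and adds the 7 non-empty subsets of between-group
effects; a group effect is "supported" only if some stage-2 model beats the
refitted no-trait baseline by more than 10 DIC points.

**meta-d′.** Metacognitive sensitivity in type-1 units: the d′ an SDT
observer would need for its confidence ratings to discriminate its own
correct from incorrect responses as well as the observed ratings do.
Estimated per subject by maximum likelihood on the 2×2×K rating table with
the type-1 criterion carried over scaled by meta-d′/d′; it is bias-free
(invariant to shifting all ratings), so it dissociates *sensitivity* from
confidence *magnitude* (bias), which is simply the mean rated confidence.

**Proportional-rate calibration.** In the dot-motion task drift is
proportional to coherence, `v = k·c`, bounds at ±A′, giving
`P(correct|c) = 1/(1+exp(−2kA′c))` and
`E[RT|c] = (A′/kc)·tanh(A′kc) + t_R`; the fitted psychometric curve is
inverted at 65% to pick each subject's coherence.

**LISAS.** `L = meanRT_correct + PE · S_RT/S_PE` — mean correct RT plus the
error rate weighted by the subject's RT-to-error spread ratio; a single
speed–accuracy efficiency number per condition (lower is better).

## Worked example

```python
import warnings
from ddmeta.synthetic_data import gen_population, gen_subject_params, simulate_dataset
from ddmeta.data_model import preprocess_trials, summarize_cells
from ddmeta.stats import mixed_anova

with warnings.catch_warnings():
    warnings.simplefilter("ignore")           # bound-relaxation notes
    pop = gen_population(seed=1)              # 724 screenees, two tails of 30
print(f"group separation: {pop.separation_sd:.2f} pool SDs")

subjects = gen_subject_params(pop, seed=2)    # equal decision params, 6-pt bias gap
ds = preprocess_trials(simulate_dataset(subjects[:10] + subjects[-10:], task="RDM", seed=3))
print(ds.filter_log)

cells = summarize_cells(ds)
print(cells.groupby("group")[["accuracy", "mean_confidence"]].mean().round(3))
tab = mixed_anova(cells, "mean_confidence", within=["emphasis"], between="group")
print(tab[["effect", "df1", "df2", "F", "p", "eta_g_sq"]].round(4).to_string(index=False))
```

Output from this exact run:

```
group separation: 3.43 pool SDs
{'input': 2756, 'rt_floor': 0, 'reversals': 0, 'sd_outliers': 7, 'output': 2749}
        accuracy  mean_confidence
group
action     0.622           79.508
state      0.676           74.890
          effect  df1  df2       F      p  eta_g_sq
           group    1   18 53.8805 0.0000    0.6786
        emphasis    1   18  0.4668 0.5032    0.0076
emphasis * group    1   18  0.2394 0.6306    0.0039
```

Read: the two groups are statistically indistinguishable in accuracy (the
small difference is sampling noise — both draw decision parameters from one
hyper-distribution) but differ by ~4.6 points in mean confidence, and the
mixed ANOVA calls only the group effect on confidence.  The DDM side of the
question is answered by

```python
from ddmeta.model_selection import two_stage_select
sel = two_stage_select(ds, "RDM",
                       mcmc={"n_samples": 1500, "n_burn": 500, "n_chains": 3}, seed=0)
sel.winning_stage1, sel.verdict   # -> winning within-structure, "no group effect"
```

which fits the 8-model within-subject space, freezes the winner, fits the 7
between-group extensions, and (on this data, where no group effect exists by
construction) reports `"no group effect"`: no stage-2 model improves the
no-trait baseline DIC by more than 10.

The same stages are exposed on the command line (`ddmeta simulate`,
`preprocess`, `fit-ddm`, `select-model`, `fit-metad`, `lisas`, `anova`,
`power`, `calibrate`, `pairs`, `report`); `ddmeta report` runs the whole
pipeline and writes every table plus a hypothesis-verdict summary.

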