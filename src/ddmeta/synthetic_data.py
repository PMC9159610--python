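"""Synthetic populations, task designs and behavioural datasets.

This module emulates the statistical structure of an extreme-group study of
action control and decision confidence so that the full analysis pipeline can
run without any external data:

* a screening population answering 24 binary questionnaire items (Hesitation
  + Preoccupation of the ACS-90), generated from a one-factor latent model,
  from which extreme action-/state-oriented groups are selected;
* per-subject drift-diffusion parameters drawn from group hyper-distributions
  that are *identical across groups* — the groups differ, by construction,
  only in the confidence read-out bias (about 6 percentage points) and
  optionally in read-out noise;
* the three task designs: random-dot motion with a speed/accuracy emphasis
  factor (3 blocks x 54 trials), cued face/house discrimination (5 blocks x
  96 trials, congruent/incongruent/neutral at 53.33/13.33/33.33%), and the
  2 x 2 x 2 interrogation design (160 trials, 20 per cell) built on
  value-distance choice pairs;
* trial-level simulation: free-response tasks diffuse to a boundary
  (deadline-censored), interrogation trials draw an evidence sample at the
  response beep; confidence is a noisy, biased, monotone read-out of
  post-decisional evidence mapped onto the task's rating scale.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .data_model import EXP1_SCALE, EXP2_SCALE, ConfidenceScale, Dataset
from .ddm.wfpt import DDMParams, simulate_ddm

# ---------------------------------------------------------------------------
# Screening population and extreme groups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    """Screening-phase generative model.

    24 binary items load on one latent orientation factor; the combined score
    is the item sum (0..24).  ``inter_item_corr`` is the latent (tetrachoric)
    correlation between items, chosen so that the implied score SD and
    internal consistency match a typical two-subscale combined score
    (alpha ~ 0.85).  ``selection_bounds`` are the (action minimum, state
    maximum) combined-score bounds; a bound above the 24-point maximum is
    accepted verbatim but clamped with a warning, and a bound too strict to
    yield ``n_per_group`` screenees is relaxed to the n-th most extreme score.
    """

    n_screen: int = 724
    n_per_group: int = 30
    acs_item_count: int = 24
    item_endorsement: float = 0.5
    inter_item_corr: float = 0.26
    selection_bounds: tuple[float, float] = (25.0, 6.0)


@dataclass
class ScreeningResult:
    scores: np.ndarray                     # all combined scores (n_screen,)
    subscale_scores: np.ndarray            # (n_screen, 2) Hesitation/Preoccupation
    action_idx: np.ndarray
    state_idx: np.ndarray
    separation_sd: float                   # group-mean separation in pool SD units
    warnings: list[str] = field(default_factory=list)


def _simulate_acs_items(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    lam = np.sqrt(spec.inter_item_corr)
    f = rng.standard_normal((spec.n_screen, 1))
    e = rng.standard_normal((spec.n_screen, spec.acs_item_count))
    latent = lam * f + np.sqrt(1.0 - lam**2) * e
    tau = norm.ppf(1.0 - spec.item_endorsement)
    return (latent > tau).astype(np.int32)


def gen_population(spec: PopulationSpec = PopulationSpec(), seed: int = 0) -> ScreeningResult:
    """Simulate the screening phase and select the two extreme groups.

    Selection respects ``selection_bounds`` where feasible (sampling
    ``n_per_group`` at random among qualifiers) and otherwise relaxes to the
    n most extreme scorers, with every relaxation logged.  Selected subjects
    must additionally fall on the proper side of the subscale medians, the
    standard guard against subjects extreme on one subscale only; when the
    guard leaves too few candidates it is dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    items = _simulate_acs_items(spec, rng)
    half = spec.acs_item_count // 2
    sub = np.stack([items[:, :half].sum(axis=1), items[:, half:].sum(axis=1)], axis=1)
    scores = sub.sum(axis=1)
    msgs: list[str] = []

    action_min, state_max = spec.selection_bounds
    max_score = spec.acs_item_count
    if action_min > max_score:
        msgs.append(
            f"action bound {action_min} exceeds the scale maximum {max_score}; clamped"
        )
        action_min = float(max_score)
    if state_max < 0:
        msgs.append(f"state bound {state_max} below 0; clamped")
        state_max = 0.0

    med = np.median(sub, axis=0)

    def select(side: str, bound: float) -> np.ndarray:
        if side == "action":
            ok = scores >= bound
            guard = (sub[:, 0] > med[0]) & (sub[:, 1] > med[1])
            extreme_order = np.argsort(-scores, kind="stable")
        else:
            ok = scores <= bound
            guard = (sub[:, 0] < med[0]) & (sub[:, 1] < med[1])
            extreme_order = np.argsort(scores, kind="stable")
        cand = np.flatnonzero(ok & guard)
        if len(cand) < spec.n_per_group:
            cand = np.flatnonzero(ok)
            if len(cand) < spec.n_per_group:
                msgs.append(
                    f"{side} bound {bound} leaves {len(cand)} qualifier(s); "
                    f"relaxed to the {spec.n_per_group} most extreme scores"
                )
                cand = extreme_order[: spec.n_per_group]
            else:
                msgs.append(f"{side} group: subscale-median guard dropped (too strict)")
        if len(cand) == spec.n_per_group:
            return np.sort(cand)
        return np.sort(rng.choice(cand, spec.n_per_group, replace=False))

    if np.all(scores == scores[0]):
        raise ValueError(
            "degenerate screening pool (all scores equal); extreme groups are "
            "infeasible — increase n_screen or item variability"
        )
    action_idx = select("action", action_min)
    state_idx = select("state", state_max)

    pool_sd = float(np.std(scores, ddof=1))
    sep = float(
        (scores[action_idx].mean() - scores[state_idx].mean()) / pool_sd
    )
    for m in msgs:
        warnings.warn(m)
    return ScreeningResult(scores, sub, action_idx, state_idx, sep, msgs)


def acs_pool_sampler(spec: PopulationSpec = PopulationSpec()):
    """Return a ``pool_sampler(n, rng)`` closure for :func:`ddmeta.stats.power_simulation`."""

    def sample(n: int, rng: np.random.Generator) -> np.ndarray:
        lam = np.sqrt(spec.inter_item_corr)
        f = rng.standard_normal((n, 1))
        e = rng.standard_normal((n, spec.acs_item_count))
        tau = norm.ppf(1.0 - spec.item_endorsement)
        return ((lam * f + np.sqrt(1 - lam**2) * e) > tau).sum(axis=1).astype(float)

    return sample


# ---------------------------------------------------------------------------
# Subject-level generative parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectConfig:
    """Hyper-parameters for per-subject generative parameters.

    The decision-parameter hyper-distributions are shared between groups;
    the only group-dependent quantities are the confidence read-out bias gap
    (``conf_bias_gap``, percent points, action minus state) and optionally
    the read-out noise.  Drift/threshold/non-decision means are typical
    2AFC-perceptual values; per-condition modulations (threshold and
    non-decision time higher under accuracy emphasis; drift modulated by cue
    congruence and stimulus category in the cued task) mirror the effects the
    free-response designs are built to elicit.
    """

    skill_mean: float = 1.0            # multiplicative drift skill, shared across tasks
    skill_sd: float = 0.15
    drift_rdm: float = 0.45            # base drift of the coherence-calibrated RDM (~65-67% correct)
    drift_fhd: float = 1.5             # base drift of the easy face/house task (~90% correct)
    a_mean: float = 1.6
    a_sd: float = 0.2
    a_emphasis_delta: float = 0.4      # a(accuracy) - a(speed)
    ter_mean: float = 0.35
    ter_sd: float = 0.05
    ter_emphasis_delta: float = 0.08
    z_mean: float = 0.5
    z_sd: float = 0.04
    z_cue_delta: float = 0.08          # congruent-cue shift of the start point
    meta_noise_sd: float = 1.0         # sigma_m of the post-decisional read-out
    evidence_gain: float = 12.0        # confidence points per unit of read-out evidence
    conf_bias_action: float = 20.0     # percent-point shift of the read-out map
    conf_bias_gap: float = 6.0         # action minus state bias
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.a_mean <= 0 or self.ter_mean <= 0:
            raise ValueError("threshold and non-decision hyper-means must be positive")


@dataclass
class GenerativeSubject:
    subject_id: str
    group: str                         # "action" | "state"
    acs_score: float
    skill: float
    v_rdm: float
    v_fhd: float
    a: float
    ter: float
    z: float
    a_delta: float
    ter_delta: float
    z_cue_delta: float
    meta_noise: float
    conf_gain: float
    conf_bias: float
    lapse: float

    def ddm_params(self, emphasis: str | None = None, task: str = "RDM") -> DDMParams:
        a = self.a + (self.a_delta / 2 if emphasis == "accuracy" else -self.a_delta / 2 if emphasis == "speed" else 0)
        ter = self.ter + (
            self.ter_delta / 2 if emphasis == "accuracy" else -self.ter_delta / 2 if emphasis == "speed" else 0
        )
        v = self.v_rdm if task == "RDM" else self.v_fhd
        return DDMParams(v=v, a=max(a, 0.3), z=self.z, ter=max(ter, 0.1))


def gen_subject_params(
    pop: ScreeningResult,
    config: SubjectConfig = SubjectConfig(),
    seed: int = 0,
) -> list[GenerativeSubject]:
    """Draw per-subject parameters for the selected extreme groups.

    Decision parameters come from one shared hyper-distribution, so any group
    difference in accuracy or RT is sampling noise; confidence read-out bias
    differs by ``conf_bias_gap`` percent points.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for group, idx in (("action", pop.action_idx), ("state", pop.state_idx)):
        bias = config.conf_bias_action - (0.0 if group == "action" else config.conf_bias_gap)
        for j, i in enumerate(idx):
            skill = float(max(rng.normal(config.skill_mean, config.skill_sd), 0.3))
            subjects.append(
                GenerativeSubject(
                    subject_id=f"{group[:2]}{j:02d}",
                    group=group,
                    acs_score=float(pop.scores[i]),
                    skill=skill,
                    v_rdm=skill * config.drift_rdm,
                    v_fhd=skill * config.drift_fhd,
                    a=float(max(rng.normal(config.a_mean, config.a_sd), 0.5)),
                    ter=float(max(rng.normal(config.ter_mean, config.ter_sd), 0.1)),
                    z=float(np.clip(rng.normal(config.z_mean, config.z_sd), 0.2, 0.8)),
                    a_delta=config.a_emphasis_delta,
                    ter_delta=config.ter_emphasis_delta,
                    z_cue_delta=config.z_cue_delta,
                    meta_noise=config.meta_noise_sd,
                    conf_gain=config.evidence_gain,
                    conf_bias=bias,
                    lapse=config.lapse_rate,
                )
            )
    return subjects


# ---------------------------------------------------------------------------
# Choice pairs (interrogation experiment)
# ---------------------------------------------------------------------------


def gen_item_values(
    n_items: int = 71,
    mean: float = 42.05,
    sd: float = 16.46,
    lo: float = 22.77,
    hi: float = 90.05,
    seed: int = 0,
) -> np.ndarray:
    """Item values (e.g. stimulus sizes in % of image area) from a truncated normal."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n_items, random_state=np.random.default_rng(seed))


def build_choice_pairs(
    values: np.ndarray | pd.Series,
    n_per_group: int = 40,
    seed: int = 0,
) -> dict[str, list[tuple[int, int]]]:
    """Value-distance pair construction for the two-item choice task.

    1) enumerate all unordered item pairs and their absolute value distance,
    2) stratify: *easy* pairs have distance greater than half the maximum
       distance; *difficult* pairs have positive distance below one eighth of
       the maximum (ties excluded),
    3) sample ``n_per_group`` pairs from each stratum.

    Raises with the stratum counts when either stratum is too small.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two items")
    pairs = list(itertools.combinations(range(len(values)), 2))
    dist = np.array([abs(values[i] - values[j]) for i, j in pairs])
    dmax = dist.max()
    easy = [p for p, d in zip(pairs, dist) if d > dmax / 2]
    difficult = [p for p, d in zip(pairs, dist) if 0 < d < dmax / 8]
    if len(easy) < n_per_group or len(difficult) < n_per_group:
        raise ValueError(
            f"not enough eligible pairs: easy={len(easy)}, difficult={len(difficult)}, "
            f"need {n_per_group} per stratum"
        )
    rng = np.random.default_rng(seed)
    return {
        "easy": [easy[i] for i in rng.choice(len(easy), n_per_group, replace=False)],
        "difficult": [difficult[i] for i in rng.choice(len(difficult), n_per_group, replace=False)],
        "n_pairs_total": len(pairs),
        "n_easy": len(easy),
        "n_difficult": len(difficult),
    }


# ---------------------------------------------------------------------------
# Task designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignSpec:
    """Per-task trial-schedule constants.

    Free-response deadlines are 1.5 s (dot motion) and 1.25 s (face/house);
    the interrogation beep sounds 2 s after stimulus onset and the confidence
    probe appears after 0.05 s (short) or 7 s (long).
    """

    task: str                                   # "RDM" | "FHD" | "EXP2"
    blocks: int = 3
    trials_per_block: int = 54
    deadline_s: float = 1.5
    cue_validity: float = 0.8
    cued_fraction: float = 2.0 / 3.0
    beep_s: float = 2.0
    intervals_s: tuple[float, float] = (0.05, 7.0)


RDM_DESIGN = DesignSpec(task="RDM", blocks=3, trials_per_block=54, deadline_s=1.5)
FHD_DESIGN = DesignSpec(task="FHD", blocks=5, trials_per_block=96, deadline_s=1.25)
EXP2_DESIGN = DesignSpec(task="EXP2", blocks=1, trials_per_block=160)


def gen_design(
    spec: DesignSpec,
    pairs: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate one subject's randomized trial schedule.

    RDM: 162 trials, emphasis (speed/accuracy) balanced 81/81, stimulus
    direction balanced within emphasis.  FHD: 480 trials; per block of 96,
    64 carry an 80%-valid cue and 32 a neutral cue, with fixed per-block
    counts so the congruent/incongruent/neutral proportions are exactly
    53.33/13.33/33.33%.  EXP2: 160 trials, each sampled pair used exactly
    once, counterbalanced over confidence interval and left/right display.
    Randomization permutes trial order only; the counts are deterministic.
    """
    rng = np.random.default_rng(seed)
    if spec.task == "RDM":
        n = spec.blocks * spec.trials_per_block
        half = n // 2
        emphasis = np.array(["speed"] * half + ["accuracy"] * (n - half))
        stim = np.tile(["left", "right"], n // 2 + 1)[:n]
        order = rng.permutation(n)
        return pd.DataFrame(
            {
                "block": np.repeat(np.arange(spec.blocks), spec.trials_per_block),
                "emphasis": emphasis[order],
                "stimulus": stim[order],
            }
        )
    if spec.task == "FHD":
        frames = []
        per_block = spec.trials_per_block
        n_cued = int(round(per_block * spec.cued_fraction))        # 64
        n_valid = int(round(n_cued * spec.cue_validity))           # 51.2 -> 51
        # exact per-block counts for 53.33/13.33/33.33 over the task require
        # 80% of cued trials congruent: with 64 cued, that is 51.2; use a
        # 5-block cycle of (51,51,51,51,52)... simpler: counts per block pair
        frames = []
        total_cued = spec.blocks * n_cued                          # 320
        total_valid = int(round(total_cued * spec.cue_validity))   # 256
        valid_flags = np.array([True] * total_valid + [False] * (total_cued - total_valid))
        valid_flags = valid_flags[rng.permutation(total_cued)]
        vi = 0
        for b in range(spec.blocks):
            cue_side = np.tile(["face", "house"], n_cued // 2)
            rows = []
            for cs in cue_side:
                valid = valid_flags[vi]
                vi += 1
                stim = cs if valid else ("house" if cs == "face" else "face")
                rows.append((b, f"80% {cs}", stim, "congruent" if valid else "incongruent"))
            n_neutral = per_block - n_cued
            neut_stim = np.tile(["face", "house"], n_neutral // 2)
            rows += [(b, "neutral", s, "neutral") for s in neut_stim]
            bdf = pd.DataFrame(rows, columns=["block", "cue_label", "stimulus", "cue"])
            frames.append(bdf.sample(frac=1.0, random_state=int(rng.integers(2**31 - 1))))
        return pd.concat(frames, ignore_index=True)
    if spec.task == "EXP2":
        if pairs is None:
            raise ValueError("the interrogation design requires sampled choice pairs")
        rows = []
        for domain in ("value", "perceptual"):
            for difficulty in ("easy", "difficult"):
                ps = pairs[domain][difficulty]
                n_cell_pairs = len(ps)  # 40 pairs -> 20 per 2x2x2 cell via interval split
                intervals = np.tile(["short", "long"], n_cell_pairs // 2)
                sides = np.tile(["left", "right"], n_cell_pairs // 2)
                sides = sides[rng.permutation(n_cell_pairs)]
                for (i, j), interval, side in zip(ps, intervals, sides):
                    rows.append((domain, difficulty, interval, i, j, side))
        df = pd.DataFrame(
            rows, columns=["domain", "difficulty", "interval", "item_a", "item_b", "larger_side"]
        )
        return df.sample(frac=1.0, random_state=int(rng.integers(2**31 - 1))).reset_index(
            drop=True
        )
    raise ValueError(f"unknown task {spec.task!r}")


# ---------------------------------------------------------------------------
# Behavioural simulation
# ---------------------------------------------------------------------------


#: Percent-scale gain of the confidence read-out: one unit of decision-variable
#: evidence maps to this many confidence points before thresholding.
EVIDENCE_GAIN = 18.0


def _confidence_from_evidence(
    evidence: np.ndarray,
    bias_pct: np.ndarray | float,
    noise_sd: float,
    rng: np.random.Generator,
    scale: ConfidenceScale,
    evidence_gain: float = EVIDENCE_GAIN,
) -> np.ndarray:
    """Map choice-congruent evidence to rating keys.

    The read-out is percent-scale: 50 + gain * evidence + bias + noise,
    thresholded midway between the scale's level values — a monotone map by
    construction.  The read-out noise sigma_m lives on the evidence scale and
    is mapped through the same gain, so the signal-to-noise ratio of the
    read-out (what meta-d' measures) does not depend on the gain.  Read-outs
    below the bottom cut land on the lowest rating, or on the reversal key
    where the scale has one.
    """
    noise = rng.normal(0.0, noise_sd * evidence_gain, size=np.shape(evidence))
    pct = 50.0 + evidence_gain * np.asarray(evidence, dtype=float) + np.asarray(bias_pct) + noise
    vals = np.asarray(scale.level_values)
    cut = (vals[:-1] + vals[1:]) / 2.0
    rating = 1 + np.sum(np.atleast_1d(pct)[:, None] > cut[None, :], axis=1)
    if scale.reversal_level is not None:
        reversal_cut = vals[0] - (vals[1] - vals[0]) / 2.0
        rating = np.where(np.atleast_1d(pct) < reversal_cut, scale.reversal_level, rating)
    return rating.astype(int)


def _congruent_margins(
    correct: np.ndarray, d_eff: float, rng: np.random.Generator
) -> np.ndarray:
    """Choice-congruent decision-variable magnitudes, SDT-consistent.

    The type-1 decision variable is x ~ Normal(d/2, 1) (stimulus coded to the
    positive side); a correct choice observed x > 0, an error x < 0.  The
    confidence system reads the magnitude |x|, so with zero read-out noise
    the ratings reproduce the ideal observer (meta-d' = d') and errors get
    systematically smaller margins than correct choices.
    """
    n = len(correct)
    u = rng.random(n)
    mu = d_eff / 2.0
    p_pos = norm.cdf(mu)
    x = np.empty(n)
    pos = np.asarray(correct, dtype=bool)
    # inverse-CDF sampling of the truncated normal on each side
    x[pos] = mu + norm.ppf(norm.cdf(-mu) + u[pos] * p_pos)
    x[~pos] = mu + norm.ppf(u[~pos] * (1.0 - p_pos))
    return np.abs(x)


def simulate_dataset(
    subjects: list[GenerativeSubject],
    task: str = "RDM",
    pairs_per_subject: bool = True,
    seed: int = 0,
    design_spec: DesignSpec | None = None,
) -> Dataset:
    """Simulate one full task for every subject; returns a :class:`Dataset`.

    Free-response tasks (RDM/FHD) diffuse to a boundary with the task
    deadline; post-decisional confidence evidence is the (signed) choice-
    congruent state, approximated by the distance-to-threshold margin at the
    boundary plus fresh post-decisional accumulation, then read out with the
    subject's bias and noise.  Interrogation trials (EXP2) draw the
    accumulated evidence at the beep from the equivalent SDT model
    (evidence ~ Normal(±d/2, 1)); long-interval trials add a second,
    independent evidence sample before the read-out.
    """
    rng = np.random.default_rng(seed)
    spec = design_spec or {"RDM": RDM_DESIGN, "FHD": FHD_DESIGN, "EXP2": EXP2_DESIGN}[task]
    if spec.deadline_s is not None and task in ("RDM", "FHD"):
        min_ter = min(s.ter for s in subjects)
        if spec.deadline_s <= min_ter:
            raise ValueError("response deadline is shorter than the non-decision time")
    rows: list[dict] = []
    scale = EXP2_SCALE if task == "EXP2" else EXP1_SCALE

    for subj in subjects:
        sseed = int(rng.integers(2**31 - 1))
        srng = np.random.default_rng(sseed)
        if task == "RDM":
            rows += _simulate_free_response(
                subj, gen_design(spec, seed=sseed), "RDM", ["emphasis"], spec, srng, scale
            )
        elif task == "FHD":
            rows += _simulate_free_response(
                subj, gen_design(spec, seed=sseed), "FHD", ["cue"], spec, srng, scale
            )
        elif task == "EXP2":
            values = {
                "value": gen_item_values(seed=sseed),
                "perceptual": gen_item_values(seed=sseed + 1),
            }
            pairs = {
                dom: build_choice_pairs(values[dom], seed=sseed + k)
                for k, dom in enumerate(values)
            }
            design = gen_design(spec, pairs=pairs, seed=sseed)
            rows += _simulate_interrogation(subj, design, values, spec, srng, scale)
        else:
            raise ValueError(f"unknown task {task!r}")

    df = pd.DataFrame(rows)
    meta = {"seed": seed, "task": task, "n_subjects": len(subjects)}
    return Dataset(df, scale, meta)


def _simulate_free_response(subj, design, task, factors, spec, rng, scale):
    from .ddm.wfpt import _upper_prob

    rows = []
    group_cols = factors if task == "RDM" else ["cue_label", "stimulus"]
    for factor_vals, sub in design.groupby(group_cols, sort=False):
        factor_vals = factor_vals if isinstance(factor_vals, tuple) else (factor_vals,)
        cond = dict(zip(group_cols, factor_vals))
        n = len(sub)
        if task == "RDM":
            p = subj.ddm_params(emphasis=cond.get("emphasis"), task="RDM")
            p_correct = _upper_prob(p.v, p.a, p.z)
        else:
            # stimulus coding: upper boundary = face response
            stim = cond["stimulus"]
            z = subj.z + (
                subj.z_cue_delta if cond["cue_label"] == "80% face"
                else -subj.z_cue_delta if cond["cue_label"] == "80% house"
                else 0.0
            )
            p = DDMParams(
                v=subj.v_fhd if stim == "face" else -subj.v_fhd,
                a=subj.a,
                z=float(np.clip(z, 0.05, 0.95)),
                ter=subj.ter,
            )
            up = _upper_prob(p.v, p.a, p.z)
            p_correct = up if stim == "face" else 1.0 - up
        ch, rt = simulate_ddm(p, n, deadline=spec.deadline_s, seed=int(rng.integers(2**31 - 1)))
        responded = ch >= 0
        if task == "RDM":
            correct = ch == 1
        else:
            correct = (ch == 1) == (cond["stimulus"] == "face")
        d_eff = 2.0 * norm.ppf(np.clip(p_correct, 0.55, 0.995))
        margins = _congruent_margins(correct, d_eff, rng)
        lapse = rng.random(n) < subj.lapse
        rating = _confidence_from_evidence(
            margins, subj.conf_bias, subj.meta_noise, rng, scale, subj.conf_gain
        )
        rating[lapse] = rng.integers(1, scale.n_levels + 1, int(lapse.sum()))
        trial_rows = sub.reset_index(drop=True)
        for i in range(n):
            if not responded[i]:
                continue  # censored at the deadline: no response recorded
            trial = trial_rows.iloc[i]
            if task == "RDM":
                resp = "correct" if ch[i] == 1 else "error"
            else:
                resp = "face" if ch[i] == 1 else "house"
            rows.append(
                dict(
                    subject=subj.subject_id,
                    group=subj.group,
                    task=task,
                    **{f: trial[f] for f in factors},
                    stimulus=trial["stimulus"],
                    response=resp,
                    correct=bool(correct[i]),
                    rt=float(rt[i]),
                    rating=int(rating[i]),
                )
            )
    return rows


def _simulate_interrogation(subj, design, values, spec, rng, scale):
    rows = []
    # discriminability of the evidence sample at the beep is a compressive
    # power function of the normalized value distance (a linear map cannot
    # produce high easy-choice accuracy together with clearly-above-chance
    # difficult choices, which is the regime this design operates in)
    d_scale, d_exponent = 3.6, 0.4
    for _, trial in design.iterrows():
        vals = values[trial["domain"]]
        va, vb = vals[trial["item_a"]], vals[trial["item_b"]]
        dist = abs(va - vb) / (vals.max() - vals.min())
        d = d_scale * dist**d_exponent
        better_is_a = va > vb
        ev = rng.normal(d / 2.0, 1.0)          # evidence for the better item
        choose_better = ev > 0
        correct = bool(choose_better)
        conf_ev = abs(ev)
        if trial["interval"] == "long":
            # a second, independent post-decisional sample, choice-congruent
            ev2 = rng.normal(d / 2.0, 1.0)
            conf_ev = (abs(ev) + (ev2 if choose_better else -ev2)) / 2.0
        rating = _confidence_from_evidence(
            np.array([conf_ev]), subj.conf_bias, subj.meta_noise, rng, scale, subj.conf_gain
        )[0]
        rt = float(spec.beep_s + max(rng.normal(0.35, 0.08), 0.15))
        rows.append(
            dict(
                subject=subj.subject_id,
                group=subj.group,
                task="EXP2",
                domain=trial["domain"],
                difficulty=trial["difficulty"],
                interval=trial["interval"],
                stimulus="a_better" if better_is_a else "b_better",
                response="chose_better" if choose_better else "chose_worse",
                correct=correct,
                rt=rt,
                rating=int(rating),
            )
        )
    return rows


def perceptual_reward(accuracy_pct: float) -> int:
    """Reward rule of the interrogation task: items won from perceptual accuracy."""
    if accuracy_pct >= 95.0:
        return 3
    if accuracy_pct > 90.0:
        return 2
    return 1
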