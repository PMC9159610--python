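"""Hierarchical Bayesian estimation of DDM parameters.

Subject-level parameters are sampled on unconstrained scales (drift raw,
log-threshold, logit start point, log non-decision time) and partially pooled
toward group-level means with group-level SDs — the shrinkage structure that
makes hierarchical estimation efficient at modest trial counts.  A model
specification decides which parameters vary over which within-subject factors
(each factor-level combination gets its own "slot") and which parameters may
carry a between-group offset.

The sampler is adaptive Metropolis-within-Gibbs, jit-compiled: random-walk
updates for each subject x slot (with only that slot's trials entering the
likelihood), conjugate Gibbs draws for group means and group offsets, and a
random-walk on log group SDs.  Several independent chains feed the
Gelman-Rubin convergence diagnostic; DIC is computed from the cached
trial-likelihood deviance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from numba import njit

from ..data_model import Dataset
from .wfpt import DDMParams, _wfpt_logpdf, simulate_ddm

if TYPE_CHECKING:  # pragma: no cover
    from ..model_selection import ModelSpec

_PTYPES = ("v", "a", "z", "ter")
# prior means/SDs and group-SD half-normal scales on the transformed scales
_PRIOR_M0 = {"v": 0.5, "a": np.log(1.5), "z": 0.0, "ter": np.log(0.3)}
_PRIOR_S0 = {"v": 2.0, "a": 0.5, "z": 0.7, "ter": 0.5}
_SIGMA_SCALE = {"v": 0.5, "a": 0.3, "z": 0.5, "ter": 0.3}


@dataclass
class SlotInfo:
    param: str          # v | a | z | ter
    label: str          # e.g. "a(accuracy)" or "v"
    transform: int      # 0 raw, 1 log, 2 logit
    free: bool
    group_free: bool


@dataclass
class DesignMatrices:
    """Trial-to-slot index arrays and slot metadata for one model spec."""

    rt: np.ndarray
    upper: np.ndarray
    subj_start: np.ndarray
    subj_end: np.ndarray
    slot_idx: np.ndarray          # (n_trials, 4) global slot id per parameter
    slots: list[SlotInfo]
    subjects: list
    gsign: np.ndarray             # (+0.5 action / -0.5 state / 0)
    row_order: np.ndarray         # original-row index of each sorted trial
    n_censored: int


@dataclass
class PosteriorFit:
    """Traces and diagnostics of one hierarchical fit."""

    model: object
    design: DesignMatrices
    traces: dict[str, np.ndarray]          # name -> (chains, draws)
    subject_traces: np.ndarray             # (chains, draws, S, J) transformed scale
    deviance: np.ndarray                   # (chains, draws)
    n_chains: int
    n_samples: int
    n_burn: int
    dic: float = np.nan
    pd_eff: float = np.nan
    rhat: dict[str, float] = field(default_factory=dict)

    def stacked(self, name: str) -> np.ndarray:
        return self.traces[name].reshape(-1)

    @property
    def param_names(self) -> list[str]:
        return list(self.traces)


@dataclass
class PosteriorContrast:
    name: str
    p: float
    significant: bool


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def build_design(ds: Dataset, model: "ModelSpec") -> DesignMatrices:
    """Map a trial table onto sampler arrays for one model specification."""
    df = ds.trials
    order = np.argsort(df["subject"].to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    subjects = list(pd.unique(df["subject"]))
    subj_codes = df["subject"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    n = len(df)

    if model.coding == "accuracy":
        upper = df["correct"].to_numpy().astype(np.int8)
    else:
        upper = (df["response"] == model.upper_label).to_numpy().astype(np.int8)

    varying = dict(model.varying)
    slots: list[SlotInfo] = []
    slot_idx = np.zeros((n, 4), dtype=np.int32)
    for pi, param in enumerate(_PTYPES):
        factors = list(varying.get(param, ()))
        for f in factors:
            nlev = df[f].nunique()
            if nlev < 2:
                raise ValueError(
                    f"parameter {param!r} marked varying by {f!r}, which has "
                    f"{nlev} level(s); the model is not identifiable"
                )
        free = model.free_params is None or param in model.free_params
        transform = {"v": 0, "a": 1, "z": 2, "ter": 1}[param]
        if factors:
            combos = (
                df[factors].astype(str).agg("|".join, axis=1)
                if len(factors) > 1
                else df[factors[0]].astype(str)
            )
            levels = sorted(combos.unique())
            base = len(slots)
            for lev in levels:
                slots.append(
                    SlotInfo(param, f"{param}({lev})", transform, free, param in model.group_effects)
                )
            lut = {lev: base + k for k, lev in enumerate(levels)}
            slot_idx[:, pi] = combos.map(lut).to_numpy()
        else:
            slots.append(
                SlotInfo(param, param, transform, free, param in model.group_effects)
            )
            slot_idx[:, pi] = len(slots) - 1

    starts = np.searchsorted(subj_codes, np.arange(len(subjects)))
    ends = np.append(starts[1:], n)

    gsign = np.zeros(len(subjects))
    if "group" in df.columns:
        gmap = df.groupby("subject")["group"].first()
        gsign = np.array([0.5 if gmap[s] == "action" else -0.5 for s in subjects])

    return DesignMatrices(
        rt=df["rt"].to_numpy(float),
        upper=upper,
        subj_start=starts.astype(np.int64),
        subj_end=ends.astype(np.int64),
        slot_idx=slot_idx,
        slots=slots,
        subjects=subjects,
        gsign=gsign,
        row_order=order,
        n_censored=0,
    )


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


@njit(cache=True)
def _natural(th: float, transform: int) -> float:
    if transform == 0:
        return th
    if transform == 1:
        return np.exp(th)
    return 1.0 / (1.0 + np.exp(-th))


@njit(cache=True)
def _trial_ll(i, theta_s, slot_idx, trans, rt, upper) -> float:
    v = _natural(theta_s[slot_idx[i, 0]], trans[slot_idx[i, 0]])
    a = _natural(theta_s[slot_idx[i, 1]], trans[slot_idx[i, 1]])
    z = _natural(theta_s[slot_idx[i, 2]], trans[slot_idx[i, 2]])
    ter = _natural(theta_s[slot_idx[i, 3]], trans[slot_idx[i, 3]])
    return _wfpt_logpdf(rt[i], upper[i] == 1, v, a, z, ter)


@njit(cache=True)
def _run_chain(
    rt,
    upper,
    subj_start,
    subj_end,
    slot_idx,
    trans,
    free,
    gfree,
    ptype,
    gsign,
    m0,
    s0,
    sig_scale,
    theta0,
    n_iter,
    n_burn,
    seed,
):
    np.random.seed(seed)
    S = len(subj_start)
    J = len(trans)
    n = len(rt)

    theta = theta0.copy()
    mu = np.empty(J)
    for j in range(J):
        acc = 0.0
        for s in range(S):
            acc += theta[s, j]
        mu[j] = acc / S
    delta = np.zeros(J)
    sigma = 0.2 * np.ones(J)

    # cached per-trial log-likelihoods
    ll = np.empty(n)
    for s in range(S):
        for i in range(subj_start[s], subj_end[s]):
            ll[i] = _trial_ll(i, theta[s], slot_idx, trans, rt, upper)

    step = 0.15 * np.ones((S, J))
    step_ls = 0.25 * np.ones(J)
    acc_theta = np.zeros((S, J))
    acc_sig = np.zeros(J)
    adapt_win = 50

    kept = n_iter - n_burn
    mu_tr = np.empty((kept, J))
    de_tr = np.empty((kept, J))
    si_tr = np.empty((kept, J))
    th_tr = np.empty((kept, S, J))
    dev_tr = np.empty(kept)

    tmp = np.empty(n)

    for it in range(n_iter):
        # ---- subject-slot random walks
        for s in range(S):
            for j in range(J):
                if not free[j]:
                    continue
                old = theta[s, j]
                prop = old + step[s, j] * np.random.randn()
                pt = ptype[j]
                dll = 0.0
                bad = False
                for i in range(subj_start[s], subj_end[s]):
                    if slot_idx[i, pt] == j:
                        theta[s, j] = prop
                        lnew = _trial_ll(i, theta[s], slot_idx, trans, rt, upper)
                        theta[s, j] = old
                        tmp[i] = lnew
                        if lnew == -np.inf:
                            bad = True
                            break
                        dll += lnew - ll[i]
                if bad:
                    continue
                m = mu[j] + delta[j] * gsign[s]
                dprior = (-0.5 * ((prop - m) / sigma[j]) ** 2) - (
                    -0.5 * ((old - m) / sigma[j]) ** 2
                )
                if np.log(np.random.rand()) < dll + dprior:
                    theta[s, j] = prop
                    for i in range(subj_start[s], subj_end[s]):
                        if slot_idx[i, pt] == j:
                            ll[i] = tmp[i]
                    acc_theta[s, j] += 1.0

        # ---- group means: conjugate Gibbs
        for j in range(J):
            if not free[j]:
                continue
            prec = S / sigma[j] ** 2 + 1.0 / s0[j] ** 2
            summ = 0.0
            for s in range(S):
                summ += theta[s, j] - delta[j] * gsign[s]
            mean = (summ / sigma[j] ** 2 + m0[j] / s0[j] ** 2) / prec
            mu[j] = mean + np.random.randn() / np.sqrt(prec)

        # ---- group offsets (between-group effects): conjugate Gibbs
        for j in range(J):
            if not (free[j] and gfree[j]):
                continue
            sg2 = 0.0
            sr = 0.0
            for s in range(S):
                sg2 += gsign[s] ** 2
                sr += gsign[s] * (theta[s, j] - mu[j])
            prec = sg2 / sigma[j] ** 2 + 1.0
            mean = (sr / sigma[j] ** 2) / prec
            delta[j] = mean + np.random.randn() / np.sqrt(prec)

        # ---- group SDs: random walk on log sigma, half-normal prior
        for j in range(J):
            if not free[j]:
                continue
            olds = sigma[j]
            props = olds * np.exp(step_ls[j] * np.random.randn())
            lo = 0.0
            for s in range(S):
                r = theta[s, j] - mu[j] - delta[j] * gsign[s]
                lo += (-0.5 * (r / props) ** 2 - np.log(props)) - (
                    -0.5 * (r / olds) ** 2 - np.log(olds)
                )
            lo += -0.5 * (props / sig_scale[j]) ** 2 + 0.5 * (olds / sig_scale[j]) ** 2
            lo += np.log(props) - np.log(olds)  # Jacobian of the log walk
            if np.log(np.random.rand()) < lo:
                sigma[j] = props
                acc_sig[j] += 1.0

        # ---- adaptation during burn-in
        if it < n_burn and (it + 1) % adapt_win == 0:
            for s in range(S):
                for j in range(J):
                    rate = acc_theta[s, j] / adapt_win
                    step[s, j] *= np.exp(1.2 * (rate - 0.35))
                    step[s, j] = min(max(step[s, j], 1e-3), 3.0)
                    acc_theta[s, j] = 0.0
            for j in range(J):
                rate = acc_sig[j] / adapt_win
                step_ls[j] *= np.exp(1.2 * (rate - 0.35))
                step_ls[j] = min(max(step_ls[j], 1e-3), 3.0)
                acc_sig[j] = 0.0

        if it >= n_burn:
            k = it - n_burn
            for j in range(J):
                mu_tr[k, j] = mu[j]
                de_tr[k, j] = delta[j]
                si_tr[k, j] = sigma[j]
            for s in range(S):
                for j in range(J):
                    th_tr[k, s, j] = theta[s, j]
            dtot = 0.0
            for i in range(n):
                dtot += ll[i]
            dev_tr[k] = -2.0 * dtot

    return mu_tr, de_tr, si_tr, th_tr, dev_tr


@njit(cache=True)
def _total_ll(theta, rt, upper, subj_start, subj_end, slot_idx, trans):
    tot = 0.0
    for s in range(len(subj_start)):
        for i in range(subj_start[s], subj_end[s]):
            tot += _trial_ll(i, theta[s], slot_idx, trans, rt, upper)
    return tot


def fit_hierarchical(
    ds: Dataset,
    model: "ModelSpec",
    n_samples: int = 5000,
    n_burn: int = 1000,
    n_chains: int = 5,
    seed: int = 0,
) -> PosteriorFit:
    """Fit the hierarchical DDM given a model specification.

    ``n_samples`` is the per-chain total; the first ``n_burn`` are discarded
    (and used for proposal adaptation).  Chains are independent apart from
    deterministic seed offsets.
    """
    dm = build_design(ds, model)
    S, J = len(dm.subjects), len(dm.slots)
    trans = np.array([s.transform for s in dm.slots], dtype=np.int8)
    free = np.array([s.free for s in dm.slots], dtype=np.bool_)
    gfree = np.array([s.group_free for s in dm.slots], dtype=np.bool_)
    ptype = np.zeros(J, dtype=np.int8)
    for j, s in enumerate(dm.slots):
        ptype[j] = _PTYPES.index(s.param)
    m0 = np.array([_PRIOR_M0[s.param] for s in dm.slots])
    s0 = np.array([_PRIOR_S0[s.param] for s in dm.slots])
    sig_scale = np.array([_SIGMA_SCALE[s.param] for s in dm.slots])

    # data-informed initial values keep the first likelihoods finite
    theta0 = np.tile(m0, (S, 1))
    for si in range(S):
        min_rt = dm.rt[dm.subj_start[si] : dm.subj_end[si]].min()
        for j, sl in enumerate(dm.slots):
            if sl.param == "ter":
                theta0[si, j] = np.log(max(0.6 * min_rt, 0.05))
            elif sl.param == "z":
                theta0[si, j] = 0.0

    rng = np.random.default_rng(seed)
    chain_seeds = rng.integers(1, 2**31 - 1, size=n_chains)

    mu_c, de_c, si_c, th_c, dev_c = [], [], [], [], []
    for c in range(n_chains):
        t0 = theta0 + 0.05 * rng.standard_normal(theta0.shape)
        mu_tr, de_tr, si_tr, th_tr, dev_tr = _run_chain(
            dm.rt,
            dm.upper,
            dm.subj_start,
            dm.subj_end,
            dm.slot_idx,
            trans,
            free,
            gfree,
            ptype,
            dm.gsign,
            m0,
            s0,
            sig_scale,
            t0,
            int(n_samples),
            int(n_burn),
            int(chain_seeds[c]),
        )
        mu_c.append(mu_tr)
        de_c.append(de_tr)
        si_c.append(si_tr)
        th_c.append(th_tr)
        dev_c.append(dev_tr)

    traces: dict[str, np.ndarray] = {}
    for j, sl in enumerate(dm.slots):
        if not sl.free:
            continue
        traces[f"{sl.label}_mu"] = np.stack([m[:, j] for m in mu_c])
        traces[f"{sl.label}_sd"] = np.stack([m[:, j] for m in si_c])
        if sl.group_free:
            traces[f"{sl.label}_delta"] = np.stack([m[:, j] for m in de_c])

    fit = PosteriorFit(
        model=model,
        design=dm,
        traces=traces,
        subject_traces=np.stack(th_c),
        deviance=np.stack(dev_c),
        n_chains=n_chains,
        n_samples=n_samples,
        n_burn=n_burn,
    )
    compute_dic(fit)
    compute_rhat(fit)
    return fit


# ---------------------------------------------------------------------------
# diagnostics and inference
# ---------------------------------------------------------------------------


def compute_dic(fit: PosteriorFit) -> float:
    """Deviance information criterion: DIC = mean deviance + pD, with
    pD = mean deviance - deviance at the posterior-mean subject parameters."""
    dm = fit.design
    dbar = float(fit.deviance.mean())
    theta_bar = fit.subject_traces.mean(axis=(0, 1))
    trans = np.array([s.transform for s in dm.slots], dtype=np.int8)
    dhat = -2.0 * _total_ll(
        theta_bar, dm.rt, dm.upper, dm.subj_start, dm.subj_end, dm.slot_idx, trans
    )
    pd_eff = dbar - dhat
    if fit.deviance.std() < 1e-9:
        warnings.warn("degenerate (zero-variance) posterior; pD set to 0")
        pd_eff = 0.0
    fit.dic = dbar + pd_eff
    fit.pd_eff = pd_eff
    return fit.dic


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic Gelman-Rubin potential-scale-reduction for (chains, draws).

    Ratios are floored at 1.0 (between-chain variance cannot meaningfully be
    negative, and identical chains should read exactly 1.0)."""
    m, n = chains.shape
    if m < 2:
        raise ValueError("R-hat needs at least two chains")
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return max(1.0, float(np.sqrt(var_plus / w)))


def compute_rhat(fit: PosteriorFit) -> dict[str, float]:
    """Gelman-Rubin R-hat for every group-level parameter (< 1.1 converged)."""
    fit.rhat = {name: gelman_rubin(tr) for name, tr in fit.traces.items()}
    return fit.rhat


def converged(fit: PosteriorFit, threshold: float = 1.1) -> bool:
    return max(fit.rhat.values()) < threshold


def posterior_compare(
    fit: PosteriorFit, name_a: str, name_b: str | None = None, value_b: float = 0.0
) -> PosteriorContrast:
    """P(A > B) over aligned posterior samples; ties count one half.

    With ``name_b=None`` the comparison is against the constant ``value_b``
    (useful for group offsets, where P(delta > 0) is the group contrast).
    Significance at P >= .95, the posterior analogue of a one-sided test.
    """
    a = fit.stacked(name_a)
    if name_b is not None:
        b = fit.stacked(name_b)
        if len(a) != len(b):
            raise ValueError("traces must have equal lengths for sample-wise comparison")
        label = f"{name_a} > {name_b}"
    else:
        b = value_b
        label = f"{name_a} > {value_b:g}"
    p = float(np.mean(a > b) + 0.5 * np.mean(a == b))
    return PosteriorContrast(name=label, p=p, significant=p >= 0.95)


def posterior_predictive_check(
    fit: PosteriorFit,
    ds: Dataset,
    n_draws: int = 50,
    quantiles: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9),
    seed: int = 0,
) -> pd.DataFrame:
    """Observed vs simulated accuracy and RT quantiles per condition cell.

    For ``n_draws`` random posterior draws the model simulates every
    subject's trials in each condition; the table reports the observed
    statistic, the 95% posterior-predictive interval and a coverage flag.
    Condition cells with no observed trials are skipped with a note.
    """
    rng = np.random.default_rng(seed)
    dm = fit.design
    df = ds.trials
    factor_cols = [c for c in ds.factor_columns]
    trans = [s.transform for s in dm.slots]
    draws_c = rng.integers(0, fit.subject_traces.shape[0], n_draws)
    draws_k = rng.integers(0, fit.subject_traces.shape[1], n_draws)

    coding = getattr(fit.model, "coding", "accuracy")
    upper_label = getattr(fit.model, "upper_label", None)
    cell_cols = factor_cols + (["stimulus"] if coding == "stimulus" else [])
    # positions of the original rows inside the subject-sorted design arrays
    inv = np.empty(len(df), dtype=np.int64)
    inv[dm.row_order] = np.arange(len(df))

    rows = []
    for cell, cdf in df.groupby(cell_cols, observed=True, sort=True):
        cell = cell if isinstance(cell, tuple) else (cell,)
        if len(cdf) == 0:
            rows.append(dict(zip(cell_cols, cell), note="empty cell"))
            continue
        obs_acc = cdf["correct"].mean()
        obs_q = np.quantile(cdf["rt"], quantiles)
        sim_acc = np.empty(n_draws)
        sim_q = np.empty((n_draws, len(quantiles)))
        # slot ids for this cell (identical for all its trials by construction)
        sidx = dm.slot_idx[inv[df.index.get_loc(cdf.index[0])]]
        counts = cdf.groupby("subject").size()
        sim_is_correct_upper = (
            True if coding == "accuracy" else cell[-1] == upper_label
        )
        for d in range(n_draws):
            theta = fit.subject_traces[draws_c[d], draws_k[d]]
            rts_all, cors_all = [], []
            for si, subj in enumerate(dm.subjects):
                n_sub = int(counts.get(subj, 0))
                if n_sub == 0:
                    continue
                th = theta[si]
                p = DDMParams(
                    v=float(_nat(th[sidx[0]], trans[sidx[0]])),
                    a=float(_nat(th[sidx[1]], trans[sidx[1]])),
                    z=float(np.clip(_nat(th[sidx[2]], trans[sidx[2]]), 0.02, 0.98)),
                    ter=float(_nat(th[sidx[3]], trans[sidx[3]])),
                )
                ch, rt = simulate_ddm(p, n_sub, seed=int(rng.integers(2**31 - 1)))
                keep = ch >= 0
                rts_all.append(rt[keep])
                cors_all.append((ch[keep] == 1) == sim_is_correct_upper)
            rt_cat = np.concatenate(rts_all)
            cor_cat = np.concatenate(cors_all)
            sim_acc[d] = cor_cat.mean()
            sim_q[d] = np.quantile(rt_cat, quantiles)
        row = dict(zip(cell_cols, cell))
        lo, hi = np.quantile(sim_acc, [0.025, 0.975])
        row.update(
            observed_accuracy=obs_acc,
            acc_lo=lo,
            acc_hi=hi,
            acc_covered=bool(lo <= obs_acc <= hi),
        )
        for qi, q in enumerate(quantiles):
            lo, hi = np.quantile(sim_q[:, qi], [0.025, 0.975])
            row[f"rt_q{int(q*100)}_obs"] = obs_q[qi]
            row[f"rt_q{int(q*100)}_lo"] = lo
            row[f"rt_q{int(q*100)}_hi"] = hi
            row[f"rt_q{int(q*100)}_covered"] = bool(lo <= obs_q[qi] <= hi)
        rows.append(row)
    return pd.DataFrame(rows)


def _nat(th: float, transform: int) -> float:
    if transform == 0:
        return th
    if transform == 1:
        return np.exp(th)
    return 1.0 / (1.0 + np.exp(-th))
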