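"""Efficiency scores, mixed-design ANOVA, scale reliability, and the
extreme-group power simulation.

The ANOVA implements the classical univariate repeated-measures decomposition
for fully balanced designs (one between-subject factor, any number of
within-subject factors, one cell mean per subject x cell), via orthonormal
contrasts.  Rotating each subject's cell-mean vector by a full orthonormal
basis (Kronecker products of per-factor contrasts and normalized constants)
preserves sums of squares, so the per-stratum SS obtained from the rotated
columns equal the classical ones exactly; Greenhouse-Geisser epsilon comes
from the pooled covariance of each effect's contrast scores, and generalized
eta squared follows Olejnik & Algina (effect SS over effect SS plus all
subject-error SS).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


# --------------------------------------------------------------------------
# LISAS
# --------------------------------------------------------------------------

def lisas(
    rt_correct_mean: float,
    prop_error: float,
    s_rt: float,
    s_pe: float,
) -> float:
    """Linear integrated speed-accuracy score for one subject x condition.

    L = mean correct RT + PE * (S_RT / S_PE), where S_RT is the SD of the
    subject's correct RTs and S_PE the SD of the subject's trial-level error
    indicator, both computed across all of the subject's trials.  Lower is
    more efficient.  A subject who never errs has S_PE = 0; the score then
    reduces to the mean correct RT (flagged by the caller via ``lisas_table``).
    """
    if s_pe == 0:
        return float(rt_correct_mean)
    return float(rt_correct_mean + prop_error * (s_rt / s_pe))


def lisas_table(trials: pd.DataFrame, condition_cols: list[str]) -> pd.DataFrame:
    """Per subject x condition LISAS scores from a trial table.

    Needs columns ``subject``, ``correct`` (bool), ``rt`` (s).  The spread
    terms S_RT and S_PE are per-subject, pooled across conditions, so the
    ratio weights errors identically for all of a subject's conditions.
    """
    rows = []
    for subj, sdf in trials.groupby("subject", sort=True):
        err = 1.0 - sdf["correct"].to_numpy(float)
        s_pe = float(np.std(err, ddof=1)) if len(err) > 1 else 0.0
        rts_c = sdf.loc[sdf["correct"], "rt"]
        s_rt = float(rts_c.std(ddof=1)) if len(rts_c) > 1 else 0.0
        for cond, cdf in sdf.groupby(condition_cols, sort=True):
            cond = cond if isinstance(cond, tuple) else (cond,)
            corr = cdf.loc[cdf["correct"], "rt"]
            pe = 1.0 - cdf["correct"].mean()
            rows.append(
                dict(
                    zip(condition_cols, cond),
                    subject=subj,
                    lisas=lisas(corr.mean() if len(corr) else np.nan, pe, s_rt, s_pe),
                    zero_error_flag=s_pe == 0,
                )
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Mixed-design ANOVA
# --------------------------------------------------------------------------

def _orthonormal_contrast(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast matrix (orthogonal to the constant)."""
    basis = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(basis)
    return q[:, : k - 1]


@dataclass
class AnovaEffect:
    effect: str
    ss: float
    df1: float
    df2: float
    f: float
    p: float
    eps: float
    p_gg: float
    ges: float


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "subject",
    between: str | None = None,
) -> pd.DataFrame:
    """Mixed-design ANOVA on per-subject cell means (aggregate-then-test).

    ``data`` holds one row per subject x within-cell (extra replicates are
    averaged).  Subjects missing any cell are dropped listwise with a
    warning.  Returns a table with uncorrected F/p, Greenhouse-Geisser
    epsilon and corrected p (identical to the uncorrected p when the effect
    has a single numerator contrast), and generalized eta squared.
    """
    df = data.copy()
    levels = {w: sorted(df[w].unique()) for w in within}
    cells = list(itertools.product(*[levels[w] for w in within]))
    cell_index = {c: i for i, c in enumerate(cells)}
    n_cells = len(cells)

    agg = df.groupby([subject] + within, observed=True, sort=False)[dv].mean().reset_index()
    wide = {}
    groups = {}
    for subj, sdf in agg.groupby(subject, sort=True):
        vec = np.full(n_cells, np.nan)
        for _, row in sdf.iterrows():
            vec[cell_index[tuple(row[w] for w in within)]] = row[dv]
        if np.isnan(vec).any():
            continue
        wide[subj] = vec
        groups[subj] = df.loc[df[subject] == subj, between].iloc[0] if between else "_all"
    n_dropped = agg[subject].nunique() - len(wide)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} subject(s) with incomplete cells")

    subjects = sorted(wide)
    X = np.array([wide[s] for s in subjects])          # n_subj x n_cells
    glabels = np.array([groups[s] for s in subjects])
    gnames = sorted(set(glabels))
    G = len(gnames)
    n = len(subjects)
    if between and G < 2:
        raise ValueError("between factor needs at least two groups")

    contrasts = {w: _orthonormal_contrast(len(levels[w])) for w in within}
    consts = {w: np.ones((len(levels[w]), 1)) / np.sqrt(len(levels[w])) for w in within}

    def kron_cols(subset: tuple[str, ...]) -> np.ndarray:
        mats = [contrasts[w] if w in subset else consts[w] for w in within]
        out = np.array([[1.0]])
        for m in mats:
            out = np.kron(out, m)
        return out

    # between stratum (empty within subset): subject scores on the constant
    y0 = X @ kron_cols(())                              # n x 1
    gmeans0 = np.array([y0[glabels == g].mean() for g in gnames])
    grand0 = y0.mean()
    ss_between = float(sum((glabels == g).sum() * (gm - grand0) ** 2 for g, gm in zip(gnames, gmeans0)))
    ss_subj = float(sum(((y0[glabels == g] - gm) ** 2).sum() for g, gm in zip(gnames, gmeans0)))
    df_subj = n - G

    strata = []
    ss_errors_total = ss_subj
    for r in range(1, len(within) + 1):
        for subset in itertools.combinations(within, r):
            M = kron_cols(subset)
            Y = X @ M                                   # n x q
            q = Y.shape[1]
            gm = np.array([Y[glabels == g].mean(axis=0) for g in gnames])  # G x q
            grand = Y.mean(axis=0)
            ngs = np.array([(glabels == g).sum() for g in gnames])
            ss_eff = float(n * np.sum(grand**2))
            ss_int = float(np.sum(ngs[:, None] * (gm - grand) ** 2))
            resid = Y - gm[[gnames.index(g) for g in glabels]]
            ss_err = float(np.sum(resid**2))
            # GG epsilon from the pooled within-group covariance of contrast scores
            if q > 1 and n - G > q - 0:
                S = resid.T @ resid / (n - G)
                tr, tr2 = np.trace(S), np.trace(S @ S)
                eps = float(tr**2 / (q * tr2)) if tr2 > 0 else 1.0
                eps = min(max(eps, 1.0 / q), 1.0)
            else:
                eps = 1.0
            strata.append((subset, ss_eff, ss_int, ss_err, q, eps))
            ss_errors_total += ss_err

    # scale-relative floor: SS at numerical-noise level count as exactly zero
    ss_floor = 1e-12 * max(float(np.sum(X**2)), 1.0)

    def make_row(name: str, ss: float, df1: float, ss_err: float, df2: float, eps: float) -> AnovaEffect:
        if ss < ss_floor:
            ss = 0.0
        if ss_err < ss_floor:
            ss_err = 0.0
        if ss_err <= 0 or df2 <= 0:
            f = 0.0 if ss == 0 else np.inf
            p = 1.0 if ss == 0 else 0.0
            p_gg = p
        else:
            ms, mse = ss / df1, ss_err / df2
            f = ms / mse if mse > 0 else (0.0 if ms == 0 else np.inf)
            p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
            p_gg = float(sps.f.sf(f, df1 * eps, df2 * eps)) if np.isfinite(f) else 0.0
        ges = ss / (ss + ss_errors_total) if (ss + ss_errors_total) > 0 else 0.0
        return AnovaEffect(name, ss, df1, df2, f, p, eps, p_gg, ges)

    rows = []
    if between:
        rows.append(make_row(between, ss_between, G - 1, ss_subj, df_subj, 1.0))
    for subset, ss_eff, ss_int, ss_err, q, eps in strata:
        name = " * ".join(subset)
        rows.append(make_row(name, ss_eff, q, ss_err, q * (n - G), eps))
        if between:
            rows.append(make_row(f"{name} * {between}", ss_int, q * (G - 1), ss_err, q * (n - G), eps))

    return pd.DataFrame([r.__dict__ for r in rows]).rename(
        columns={"f": "F", "eps": "gg_eps", "ges": "eta_g_sq"}
    )


# --------------------------------------------------------------------------
# Reliability
# --------------------------------------------------------------------------

def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha of an (respondents x items) matrix."""
    X = np.asarray(items, dtype=float)
    if X.shape[1] < 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 items and 2 respondents")
    k = X.shape[1]
    total_var = np.var(X.sum(axis=1), ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance; alpha undefined")
    item_var = np.var(X, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


# --------------------------------------------------------------------------
# Extreme-group power simulation
# --------------------------------------------------------------------------

@dataclass
class PowerCurve:
    """Simulated power of the extreme-group design over a grid of latent
    correlations between the screening score and the variable of interest."""

    r_grid: np.ndarray
    power: np.ndarray
    power_minus_alpha: np.ndarray
    mc_se: np.ndarray
    n_sims: int
    alpha: float
    bounds: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r": self.r_grid,
                "power": self.power,
                "power_minus_alpha": self.power_minus_alpha,
                "mc_se": self.mc_se,
            }
        )


def _t_pvalues_welch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Welch t-test p-values for (reps x n) samples."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * sps.t.sf(np.abs(t), df)


def power_simulation(
    pool_sampler,
    r_grid: np.ndarray | list[float],
    n_sims: int = 10_000,
    n_per_group: int = 30,
    bounds: tuple[float, float] = (25.0, 6.0),
    alpha: float = 0.05,
    seed: int = 0,
    chunk: int = 500,
) -> PowerCurve:
    """Monte-Carlo power of the extreme-group two-sample t-test.

    Per replicate: draw a fresh screening pool of combined scores from
    ``pool_sampler(n, rng) -> scores``, generate a latent variable of
    interest correlated ``r`` with the score, select ``n_per_group`` subjects
    per tail by the score ``bounds`` (action minimum, state maximum; a bound
    that fewer than ``n_per_group`` screenees clear is relaxed to the n-th
    most extreme score), and run a two-sided Welch t-test on the variable of
    interest.  Power is the rejection rate at ``alpha``; the
    false-positive-subtracted variant (rate minus alpha) is reported
    alongside, never blended.
    """
    rng = np.random.default_rng(seed)
    r_grid = np.asarray(r_grid, dtype=float)
    action_min, state_max = bounds
    power = np.zeros(len(r_grid))

    # sample one pool to sanity-check feasibility of the relaxed selection
    probe = np.asarray(pool_sampler(724, rng), dtype=float)
    if len(probe) < 2 * n_per_group:
        raise ValueError("screening pool smaller than the two extreme groups")

    for ir, r in enumerate(r_grid):
        n_sig = 0
        done = 0
        while done < n_sims:
            reps = min(chunk, n_sims - done)
            scores = np.empty((reps, len(probe)))
            for j in range(reps):
                scores[j] = pool_sampler(len(probe), rng)
            z = (scores - scores.mean(axis=1, keepdims=True)) / scores.std(
                axis=1, keepdims=True
            )
            y = r * z + np.sqrt(1.0 - r**2) * rng.standard_normal(z.shape)
            order = np.argsort(scores, axis=1)
            hi_pool = order[:, -n_per_group:]
            lo_pool = order[:, :n_per_group]
            # respect the stated bounds where they are feasible: among
            # qualifying screenees pick n at random, else take the n most extreme
            y_hi = np.empty((reps, n_per_group))
            y_lo = np.empty((reps, n_per_group))
            for j in range(reps):
                hi_ok = np.flatnonzero(scores[j] >= action_min)
                if len(hi_ok) >= n_per_group:
                    pick = rng.choice(hi_ok, n_per_group, replace=False)
                else:
                    pick = hi_pool[j]
                y_hi[j] = y[j, pick]
                lo_ok = np.flatnonzero(scores[j] <= state_max)
                if len(lo_ok) >= n_per_group:
                    pick = rng.choice(lo_ok, n_per_group, replace=False)
                else:
                    pick = lo_pool[j]
                y_lo[j] = y[j, pick]
            p = _t_pvalues_welch(y_hi, y_lo)
            n_sig += int((p < alpha).sum())
            done += reps
        power[ir] = n_sig / n_sims

    mc_se = np.sqrt(power * (1 - power) / n_sims)
    return PowerCurve(
        r_grid=r_grid,
        power=power,
        power_minus_alpha=power - alpha,
        mc_se=mc_se,
        n_sims=n_sims,
        alpha=alpha,
        bounds=(action_min, state_max),
    )
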