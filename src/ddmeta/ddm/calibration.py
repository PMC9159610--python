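"""Proportional-rate diffusion calibration for the random-dot-motion task.

Before the main task every subject runs a 200-trial calibration block with
motion coherences of 10/20/40/80%.  Drift is assumed proportional to
coherence, ``v = k·c``, with symmetric bounds at ±A′ (Palmer, Huk & Shadlen
forms), giving closed-form psychometric and chronometric curves::

    P(correct | c)  = 1 / (1 + exp(-2 k A' c))
    E[RT | c]       = (A' / (k c)) tanh(A' k c) + tR

The fitted psychometric curve is inverted at a target accuracy (65% in this
design) to pick the per-subject coherence for the main blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .wfpt import DDMParams, simulate_ddm

#: Calibration-block coherence levels, in percent.
CALIBRATION_COHERENCES = (10.0, 20.0, 40.0, 80.0)


@dataclass(frozen=True)
class PropRateFit:
    """Fitted proportional-rate model.

    k  : sensitivity, drift per unit coherence (coherence as a fraction)
    A  : bound height A′ (evidence units; boundary separation is 2A′)
    tr : residual (non-decision) time in seconds
    """

    k: float
    A: float
    tr: float
    converged: bool = True
    warning: str | None = None

    def psychometric(self, coherence_pct: np.ndarray | float) -> np.ndarray | float:
        c = np.asarray(coherence_pct, dtype=float) / 100.0
        return 1.0 / (1.0 + np.exp(-2.0 * self.k * self.A * c))

    def chronometric(self, coherence_pct: np.ndarray | float) -> np.ndarray | float:
        c = np.asarray(coherence_pct, dtype=float) / 100.0
        kc = self.k * c
        with np.errstate(divide="ignore", invalid="ignore"):
            dt = np.where(kc > 0, self.A / np.maximum(kc, 1e-12) * np.tanh(self.A * kc), self.A**2)
        return dt + self.tr

    def observer_params(self, coherence_pct: float) -> DDMParams:
        """Equivalent symmetric DDM at one coherence (a = 2A′, z = 1/2)."""
        return DDMParams(v=self.k * coherence_pct / 100.0, a=2.0 * self.A, z=0.5, ter=self.tr)


def calibration_summary(
    coherence_pct: np.ndarray, correct: np.ndarray, rt: np.ndarray
) -> pd.DataFrame:
    """Collapse raw calibration trials to per-coherence accuracy and mean RT."""
    df = pd.DataFrame({"coherence": coherence_pct, "correct": correct, "rt": rt})
    out = (
        df.groupby("coherence")
        .agg(n=("correct", "size"), n_correct=("correct", "sum"), mean_rt=("rt", "mean"))
        .reset_index()
    )
    return out


def fit_proportional_rate(summary: pd.DataFrame) -> PropRateFit:
    """Fit (k, A′, tR) to per-coherence accuracy and mean RT.

    ``summary`` needs columns ``coherence`` (percent), ``n``, ``n_correct``,
    ``mean_rt``.  The objective is the binomial negative log-likelihood of
    accuracy plus a Gaussian mean-RT term with its variance profiled out; this
    weighs both curves without a hand-tuned trade-off constant.  Accuracy at
    ceiling everywhere leaves ``k·A′`` unbounded; the fit then carries a
    warning rather than failing.
    """
    c = summary["coherence"].to_numpy(float) / 100.0
    n = summary["n"].to_numpy(float)
    nc = summary["n_correct"].to_numpy(float)
    rt = summary["mean_rt"].to_numpy(float)

    warn = None
    if np.all(nc == n):
        warn = "accuracy at ceiling for every coherence; k*A' is unbounded"
        warnings.warn(warn)
    acc = nc / n
    if not np.all(np.diff(acc[np.argsort(c)]) >= -0.15):
        warn = "grossly non-monotone accuracy over coherence; model likely misspecified"
        warnings.warn(warn)

    def nll(x: np.ndarray) -> float:
        k, A = np.exp(x[0]), np.exp(x[1])
        tr = x[2]
        p = 1.0 / (1.0 + np.exp(-2.0 * k * A * c))
        p = np.clip(p, 1e-9, 1 - 1e-9)
        ll_acc = nc * np.log(p) + (n - nc) * np.log1p(-p)
        kc = np.maximum(k * c, 1e-12)
        pred = A / kc * np.tanh(A * kc) + tr
        sse = float(np.sum((rt - pred) ** 2))
        return -float(np.sum(ll_acc)) + 0.5 * len(rt) * np.log(max(sse, 1e-12))

    best = None
    for k0, a0 in [(5.0, 0.8), (10.0, 0.5), (2.0, 1.5), (20.0, 1.0)]:
        res = minimize(
            nll,
            x0=np.array([np.log(k0), np.log(a0), float(np.min(rt)) * 0.8]),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    k, A = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    tr = float(max(best.x[2], 0.0))
    return PropRateFit(k=k, A=A, tr=tr, converged=bool(best.success), warning=warn)


def interpolate_coherence(fit: PropRateFit, target_accuracy: float) -> float:
    """Invert the fitted psychometric curve; returns coherence in percent.

    c* solves P(correct | c*) = target:  c* = logit(target) / (2 k A′).
    """
    if not 0.5 < target_accuracy < 1.0:
        raise ValueError("target accuracy must lie strictly between 0.5 and 1")
    logit = np.log(target_accuracy / (1.0 - target_accuracy))
    return 100.0 * logit / (2.0 * fit.k * fit.A)


def simulate_calibration_block(
    k: float,
    A: float,
    tr: float,
    n_trials: int = 200,
    coherences: tuple[float, ...] = CALIBRATION_COHERENCES,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a calibration block from a known proportional-rate observer.

    Trials are split evenly over the coherence levels (50 each for the
    standard 200-trial block) and simulated from the equivalent DDM, giving
    binomially noisy accuracies and noisy mean RTs like a real block.
    """
    rng = np.random.default_rng(seed)
    per = n_trials // len(coherences)
    rows = []
    truth = PropRateFit(k=k, A=A, tr=tr)
    for c in coherences:
        p = truth.observer_params(c)
        ch, rt = simulate_ddm(p, per, seed=int(rng.integers(2**31 - 1)))
        rows.append(
            pd.DataFrame({"coherence": c, "correct": ch == 1, "rt": rt})
        )
    return pd.concat(rows, ignore_index=True)
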