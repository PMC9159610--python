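"""Type-1 signal detection, confidence bias, and meta-d' estimation.

meta-d' expresses metacognitive sensitivity in type-1 units: it is the d' an
ideal SDT observer would need so that its confidence ratings, thresholded on
the same decision axis, reproduce the observed response-conditional rating
distributions.  meta-d' = d' for an observer who rates confidence directly on
the decision variable; post-decisional read-out noise pushes meta-d' below
d'.  Because the construction conditions on the response, a global shift of
all ratings (a bias change) leaves meta-d' essentially untouched.

Estimation is single-subject maximum likelihood on the 2 (stimulus) x
2 (response) x K (rating) count table, with the type-1 criterion carried over
scaled by meta-d'/d' (the standard construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .data_model import ConfidenceScale, Dataset


@dataclass
class MetacogResult:
    """Per subject×condition metacognitive summary."""

    d1: float
    c1: float
    meta_d: float
    mean_conf: float | None = None
    type2_criteria: np.ndarray | None = None
    m_ratio: float = float("nan")
    counts: np.ndarray | None = None
    flag: str | None = None

    def __post_init__(self) -> None:
        if np.isnan(self.m_ratio) and self.d1 != 0:
            self.m_ratio = self.meta_d / self.d1


def type1_sdt(stimulus: np.ndarray, response: np.ndarray) -> tuple[float, float]:
    """Type-1 d' and criterion c from binary stimulus/response vectors.

    d' = Phi^-1(H) - Phi^-1(F),  c = -(Phi^-1(H) + Phi^-1(F)) / 2, where
    "signal" is stimulus class 1.  Counts get the log-linear +0.5 correction,
    which keeps both statistics finite for perfect or empty cells.
    """
    stimulus = np.asarray(stimulus).astype(int)
    response = np.asarray(response).astype(int)
    if len(np.unique(stimulus)) < 2:
        raise ValueError("both stimulus classes must be present for type-1 SDT")
    n_sig = np.sum(stimulus == 1)
    n_noise = np.sum(stimulus == 0)
    hits = np.sum((stimulus == 1) & (response == 1))
    fas = np.sum((stimulus == 0) & (response == 1))
    h = (hits + 0.5) / (n_sig + 1.0)
    f = (fas + 0.5) / (n_noise + 1.0)
    zh, zf = norm.ppf(h), norm.ppf(f)
    return float(zh - zf), float(-(zh + zf) / 2.0)


def trials_to_counts(
    stimulus: np.ndarray, response: np.ndarray, rating: np.ndarray, n_levels: int
) -> np.ndarray:
    """Build the 2x2xK rating count table (stimulus, response, rating 1..K)."""
    counts = np.zeros((2, 2, n_levels), dtype=float)
    for s, r, k in zip(
        np.asarray(stimulus).astype(int),
        np.asarray(response).astype(int),
        np.asarray(rating).astype(int),
    ):
        counts[s, r, k - 1] += 1
    return counts


def _rating_areas(meta_d: float, c_prime: float, t2c: np.ndarray, s: int, r: int) -> np.ndarray:
    """Probabilities of each rating for stimulus s, response r under the
    meta-d' observer (decision axis ~ N(±meta_d/2, 1), criteria c' and t2c)."""
    mu = meta_d / 2.0 if s == 1 else -meta_d / 2.0
    K = len(t2c) // 2 + 1
    if r == 1:
        edges = np.concatenate([[c_prime], t2c[K - 1 :], [np.inf]])
        areas = norm.cdf(edges[1:] - mu) - norm.cdf(edges[:-1] - mu)
    else:
        edges = np.concatenate([[-np.inf], t2c[: K - 1], [c_prime]])
        areas = norm.cdf(edges[1:] - mu) - norm.cdf(edges[:-1] - mu)
        areas = areas[::-1]  # most extreme (lowest) evidence = highest rating
    return areas


def fit_meta_d(counts: np.ndarray, d1: float | None = None, c1: float | None = None) -> MetacogResult:
    """Maximum-likelihood meta-d' from a 2x2xK rating count table.

    Every response-conditional cell is padded by 1/(2K) before fitting, the
    standard regularization for sparse tables.  The type-1 operating point is
    taken from the (padded) counts unless supplied; the meta-level criterion
    is c' = c1 * meta_d / d1.  Degenerate tables (all mass in one rating
    level) return meta_d = 0 with a flag.
    """
    counts = np.asarray(counts, dtype=float)
    _, _, K = counts.shape
    padded = counts + 1.0 / (2.0 * K)

    if d1 is None or c1 is None:
        n_sig = padded[1].sum()
        n_noise = padded[0].sum()
        h = padded[1, 1].sum() / n_sig
        f = padded[0, 1].sum() / n_noise
        d1 = float(norm.ppf(h) - norm.ppf(f))
        c1 = float(-(norm.ppf(h) + norm.ppf(f)) / 2.0)

    rating_tot = counts.sum(axis=(0, 1))
    if np.sum(rating_tot > 0) <= 1:
        return MetacogResult(d1=d1, c1=c1, meta_d=0.0, counts=counts, flag="degenerate ratings")
    if d1 == 0:
        d1 = 1e-6

    def unpack(x: np.ndarray) -> tuple[float, np.ndarray]:
        meta_d = x[0]
        c_prime = c1 * meta_d / d1
        lo = c_prime - np.cumsum(np.exp(x[1:K]))[::-1]  # K-1 decreasing below c'
        hi = c_prime + np.cumsum(np.exp(x[K : 2 * K - 1]))  # K-1 increasing above c'
        return meta_d, np.concatenate([lo, hi])

    def nll(x: np.ndarray) -> float:
        meta_d, t2c = unpack(x)
        ll = 0.0
        for s in (0, 1):
            for r in (0, 1):
                areas = np.clip(_rating_areas(meta_d, c1 * meta_d / d1, t2c, s, r), 1e-12, None)
                # response-conditional: rating probabilities given (stimulus, response)
                areas = areas / areas.sum()
                ll += float(np.sum(padded[s, r] * np.log(areas)))
        return -ll

    best = None
    rng = np.random.default_rng(0)
    for trial in range(5):
        x0 = np.concatenate([[d1], np.full(2 * K - 2, np.log(0.4))])
        if trial:
            x0 = x0 + rng.normal(0, 0.2, size=x0.shape)
        res = minimize(nll, x0, method="L-BFGS-B", options={"ftol": 1e-12, "gtol": 1e-10})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    meta_d, t2c = unpack(best.x)
    return MetacogResult(
        d1=float(d1), c1=float(c1), meta_d=float(meta_d), type2_criteria=t2c, counts=counts
    )


def confidence_summary(ds: Dataset, scale: ConfidenceScale | None = None) -> pd.DataFrame:
    """Per subject×condition confidence bias and calibration curve.

    Returns one row per subject×condition×rating level with the level's
    percent value, its observed accuracy (the calibration curve), plus the
    cell's mean confidence, accuracy and over/under-confidence (mean
    confidence minus accuracy, in points).  Empty rating levels are omitted
    and flagged by ``level_present``.
    """
    scale = scale or ds.scale
    df = ds.trials.copy()
    df["conf_pct"] = scale.to_percent(df["rating"].to_numpy())
    keys = ["subject"] + ds.factor_columns
    rows = []
    for cell_key, cell in df.groupby(keys, observed=True, sort=True):
        cell_key = cell_key if isinstance(cell_key, tuple) else (cell_key,)
        rated = cell.dropna(subset=["conf_pct"])
        mean_conf = rated["conf_pct"].mean()
        acc = cell["correct"].mean()
        for lvl, val in enumerate(scale.level_values, start=1):
            at = cell[cell["rating"] == lvl]
            rows.append(
                dict(
                    zip(keys, cell_key),
                    rating_level=lvl,
                    rating_pct=val,
                    level_present=len(at) > 0,
                    level_accuracy=at["correct"].mean() if len(at) else np.nan,
                    level_n=len(at),
                    mean_confidence=mean_conf,
                    accuracy=acc,
                    overconfidence=mean_conf - 100.0 * acc,
                )
            )
    return pd.DataFrame(rows)
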