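import numpy as np
import pytest

from ddmeta.data_model import EXP1_SCALE, Dataset
from ddmeta.ddm.hierarchical import (
    PosteriorFit,
    build_design,
    compute_dic,
    fit_hierarchical,
    gelman_rubin,
    posterior_compare,
    posterior_predictive_check,
)
from ddmeta.model_selection import ModelSpec

from conftest import make_trials, simulate_flat_rdm

RDM_CONST = ModelSpec(task="RDM", coding="accuracy", free_params=("v", "a", "ter"))


def _dummy_fit(traces: dict, deviance=None) -> PosteriorFit:
    some = next(iter(traces.values()))
    return PosteriorFit(
        model=RDM_CONST,
        design=None,
        traces=traces,
        subject_traces=np.zeros((some.shape[0], some.shape[1], 1, 1)),
        deviance=deviance if deviance is not None else np.zeros(some.shape),
        n_chains=some.shape[0],
        n_samples=some.shape[1],
        n_burn=0,
    )


class TestGelmanRubin:
    def test_identical_chains_read_exactly_one(self, rng):
        x = rng.standard_normal(2000)
        assert gelman_rubin(np.stack([x, x, x])) == 1.0

    def test_iid_chains_read_near_one(self, rng):
        chains = rng.standard_normal((5, 5000))
        assert gelman_rubin(chains) < 1.01

    def test_shifted_chains_flag_nonconvergence(self, rng):
        chains = rng.standard_normal((2, 2000))
        chains[1] += 3.0
        assert gelman_rubin(chains) > 1.1

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(rng.standard_normal((1, 100)))

    def test_agrees_with_arviz(self, rng):
        az = pytest.importorskip("arviz")
        chains = rng.standard_normal((4, 1000)).cumsum(axis=1) * 0.01 + rng.standard_normal((4, 1000))
        mine = gelman_rubin(chains)
        ref = float(az.rhat(az.convert_to_dataset(chains))["x"])
        assert mine == pytest.approx(ref, abs=0.05)


class TestPosteriorCompare:
    def test_identical_traces_tie_to_half(self, rng):
        tr = rng.standard_normal((2, 100))
        fit = _dummy_fit({"A": tr, "B": tr.copy()})
        assert posterior_compare(fit, "A", "B").p == 0.5

    def test_strict_dominance_gives_one(self, rng):
        tr = rng.standard_normal((2, 100))
        fit = _dummy_fit({"A": tr + 1.0, "B": tr})
        res = posterior_compare(fit, "A", "B")
        assert res.p == 1.0 and res.significant

    def test_symmetry_sums_to_one(self, rng):
        fit = _dummy_fit({"A": rng.standard_normal((2, 500)), "B": rng.standard_normal((2, 500))})
        assert posterior_compare(fit, "A", "B").p + posterior_compare(fit, "B", "A").p == pytest.approx(1.0)

    def test_mismatched_lengths_rejected(self, rng):
        fit = _dummy_fit({"A": rng.standard_normal((2, 100)), "B": rng.standard_normal((2, 99))})
        with pytest.raises(ValueError):
            posterior_compare(fit, "A", "B")


class TestDic:
    def test_point_mass_posterior_is_plain_deviance(self, rng):
        ds = simulate_flat_rdm(2, trials_per_cell=30, seed=0)
        fit = fit_hierarchical(ds, RDM_CONST, n_samples=60, n_burn=30, n_chains=2, seed=0)
        fit.deviance = np.full_like(fit.deviance, fit.deviance.flat[0])
        fit.subject_traces = np.broadcast_to(
            fit.subject_traces[:1, :1], fit.subject_traces.shape
        ).copy()
        with pytest.warns(UserWarning, match="degenerate"):
            dic = compute_dic(fit)
        assert dic == pytest.approx(fit.deviance.flat[0])


class TestFitting:
    def test_nonidentifiable_spec_rejected_before_sampling(self):
        ds = Dataset(make_trials(40, emphasis="speed"), EXP1_SCALE)
        spec = ModelSpec(
            task="RDM", coding="accuracy", free_params=("v", "a", "ter"),
            varying=(("a", ("emphasis",)),),
        )
        with pytest.raises(ValueError, match="identifiable"):
            build_design(ds, spec)

    def test_single_subject_few_trials_still_runs(self):
        ds = simulate_flat_rdm(1, trials_per_cell=5, seed=1)
        fit = fit_hierarchical(ds, RDM_CONST, n_samples=120, n_burn=40, n_chains=2, seed=0)
        assert set(fit.rhat) == set(fit.traces)
        assert np.isfinite(fit.dic)

    def test_group_mean_recovery_within_ten_percent(self):
        """20 subjects x 200 trials from known v/a/Ter: posterior group means
        recover the truth with < 10% relative bias and converged chains."""
        ds = simulate_flat_rdm(20, trials_per_cell=100, seed=2, v=1.5, a=1.8, ter=0.3)
        fit = fit_hierarchical(ds, RDM_CONST, n_samples=1200, n_burn=400, n_chains=2, seed=0)
        v = fit.stacked("v_mu").mean()
        a = np.exp(fit.stacked("a_mu")).mean()
        ter = np.exp(fit.stacked("ter_mu")).mean()
        assert abs(v - 1.5) / 1.5 < 0.10
        assert abs(a - 1.8) / 1.8 < 0.10
        assert abs(ter - 0.3) / 0.3 < 0.10
        assert max(fit.rhat.values()) < 1.1

    def test_delta_contrast_detects_planted_threshold_gap(self):
        """a(accuracy) > a(speed) planted in the generator: the posterior
        contrast should call it with P >= .95."""
        ds = simulate_flat_rdm(14, trials_per_cell=81, a_delta=0.4, seed=3)
        spec = ModelSpec(
            task="RDM", coding="accuracy", free_params=("v", "a", "ter"),
            varying=(("a", ("emphasis",)),),
        )
        fit = fit_hierarchical(ds, spec, n_samples=900, n_burn=300, n_chains=2, seed=0)
        res = posterior_compare(fit, "a(accuracy)_mu", "a(speed)_mu")
        assert res.p >= 0.95


class TestPosteriorPredictive:
    def test_self_consistency_coverage(self):
        ds = simulate_flat_rdm(8, trials_per_cell=60, seed=4)
        fit = fit_hierarchical(ds, RDM_CONST, n_samples=500, n_burn=200, n_chains=2, seed=0)
        tab = posterior_predictive_check(fit, ds, n_draws=40, seed=0)
        cov_cols = [c for c in tab.columns if c.endswith("_covered")]
        frac = tab[cov_cols].to_numpy().astype(float).mean()
        assert frac >= 0.8

    def test_wrong_start_point_breaks_accuracy_coverage(self):
        # data generated with strong start-point bias, fitted with z fixed at 1/2
        ds = simulate_flat_rdm(8, trials_per_cell=80, seed=5, v=0.0)
        df = ds.trials.copy()
        from ddmeta.ddm.wfpt import DDMParams, simulate_ddm

        rows = []
        rng = np.random.default_rng(11)
        for s, sub in df.groupby("subject"):
            ch, rt = simulate_ddm(DDMParams(0.2, 1.6, 0.85, 0.3), len(sub), seed=int(rng.integers(2**31 - 1)))
            sub = sub.copy()
            sub["correct"] = ch == 1
            sub["rt"] = rt
            rows.append(sub)
        import pandas as pd

        biased = Dataset(pd.concat(rows, ignore_index=True), EXP1_SCALE)
        fit = fit_hierarchical(biased, RDM_CONST, n_samples=500, n_burn=200, n_chains=2, seed=0)
        tab = posterior_predictive_check(fit, biased, n_draws=40, seed=0)
        cov_cols = [c for c in tab.columns if c.endswith("_covered")]
        assert not tab[cov_cols].to_numpy().all()
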