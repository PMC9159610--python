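import warnings

import numpy as np
import pytest

from ddmeta.data_model import summarize_cells
from ddmeta.metacognition import fit_meta_d, trials_to_counts
from ddmeta.synthetic_data import (
    EXP2_DESIGN,
    FHD_DESIGN,
    RDM_DESIGN,
    DesignSpec,
    PopulationSpec,
    SubjectConfig,
    build_choice_pairs,
    gen_design,
    gen_item_values,
    gen_population,
    gen_subject_params,
    perceptual_reward,
    simulate_dataset,
)


class TestPopulation:
    def test_deterministic_unanimous_items_are_degenerate(self):
        spec = PopulationSpec(item_endorsement=1.0 - 1e-12, n_screen=100)
        with pytest.raises(ValueError, match="degenerate"):
            gen_population(spec, seed=0)

    def test_group_separation_at_least_two_sd(self):
        seps = []
        for seed in range(15):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pop = gen_population(seed=seed)
            seps.append(pop.separation_sd)
        assert min(seps) >= 2.0

    def test_out_of_range_bound_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            pop = gen_population(PopulationSpec(selection_bounds=(25.0, 6.0)), seed=1)
        assert any("clamped" in m for m in pop.warnings)
        assert len(pop.action_idx) == 30 and len(pop.state_idx) == 30

    def test_groups_respect_bounds_after_relaxation(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pop = gen_population(seed=2)
        assert pop.scores[pop.action_idx].min() > pop.scores[pop.state_idx].max()


class TestSubjectParams:
    def test_zero_gap_leaves_groups_equal_in_bias(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pop = gen_population(seed=3)
        subs = gen_subject_params(pop, SubjectConfig(conf_bias_gap=0.0), seed=0)
        biases = {g: {s.conf_bias for s in subs if s.group == g} for g in ("action", "state")}
        assert biases["action"] == biases["state"]

    def test_decision_hyperparameters_shared_between_groups(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pop = gen_population(seed=3)
        subs = gen_subject_params(pop, seed=1)
        v_a = np.mean([s.v_rdm for s in subs if s.group == "action"])
        v_s = np.mean([s.v_rdm for s in subs if s.group == "state"])
        # same hyper-distribution: difference is pure sampling noise
        assert abs(v_a - v_s) < 0.1

    def test_invalid_hypermeans_rejected(self):
        with pytest.raises(ValueError):
            SubjectConfig(a_mean=-1.0)

    def test_realized_confidence_gap_tracks_configured_gap(self):
        """Configured 6-point read-out gap should appear in mean rated
        confidence within ~2 points (averaged over replicates)."""
        gaps = []
        for seed in range(3):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pop = gen_population(seed=seed)
                subs = gen_subject_params(pop, seed=seed + 10)
                ds = simulate_dataset(subs[:10] + subs[-10:], task="RDM", seed=seed + 20)
            m = summarize_cells(ds).groupby("group")["mean_confidence"].mean()
            gaps.append(m["action"] - m["state"])
        assert abs(np.mean(gaps) - 6.0) < 2.0

    def test_accuracy_gap_near_zero_by_construction(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pop = gen_population(seed=4)
            subs = gen_subject_params(pop, seed=5)
            ds = simulate_dataset(subs, task="RDM", seed=6)
        m = summarize_cells(ds).groupby("group")["accuracy"].mean()
        assert abs(m["action"] - m["state"]) < 0.04


class TestChoicePairs:
    def test_seventy_one_items_give_2485_pairs(self):
        res = build_choice_pairs(gen_item_values(seed=0), seed=0)
        assert res["n_pairs_total"] == 2485

    def test_hand_enumerated_three_items(self):
        # values {0, 10, 20}: max distance 20; easy = {(0,20)} only;
        # difficult needs 0 < d < 2.5 -> none
        with pytest.raises(ValueError, match="difficult=0"):
            build_choice_pairs(np.array([0.0, 10.0, 20.0]), n_per_group=1)

    def test_hand_enumerated_strata_with_ties(self):
        values = np.array([0.0, 1.0, 1.0, 40.0])
        res = build_choice_pairs(values, n_per_group=1, seed=0)
        assert res["n_easy"] == 3          # 40 vs each of {0,1,1}
        assert res["n_difficult"] == 2     # (0,1) twice; the 1-1 tie excluded
        assert len(res["easy"]) == 1 and len(res["difficult"]) == 1

    def test_both_strata_usually_feasible_for_rated_items(self):
        ok = 0
        for seed in range(200):
            try:
                build_choice_pairs(gen_item_values(seed=seed), seed=seed)
                ok += 1
            except ValueError:
                pass
        assert ok >= 0.95 * 200

    def test_single_item_rejected(self):
        with pytest.raises(ValueError, match="two items"):
            build_choice_pairs(np.array([1.0]))


class TestDesigns:
    def test_rdm_design_counts(self):
        d = gen_design(RDM_DESIGN, seed=0)
        assert len(d) == 162
        assert (d["emphasis"].value_counts() == 81).all()

    def test_fhd_design_exact_congruency_proportions(self):
        d = gen_design(FHD_DESIGN, seed=1)
        assert len(d) == 480
        counts = d["cue"].value_counts()
        assert counts["congruent"] == 256   # 53.33%
        assert counts["incongruent"] == 64  # 13.33%
        assert counts["neutral"] == 160     # 33.33%

    def test_fhd_counts_deterministic_across_seeds(self):
        c1 = gen_design(FHD_DESIGN, seed=2)["cue"].value_counts()
        c2 = gen_design(FHD_DESIGN, seed=99)["cue"].value_counts()
        assert (c1 == c2).all()

    def test_exp2_design_counts_and_pair_usage(self):
        pairs = {
            dom: build_choice_pairs(gen_item_values(seed=k), seed=k)
            for k, dom in enumerate(("value", "perceptual"))
        }
        d = gen_design(EXP2_DESIGN, pairs=pairs, seed=3)
        assert len(d) == 160
        cells = d.groupby(["domain", "difficulty", "interval"]).size()
        assert (cells == 20).all() and len(cells) == 8
        assert not d.duplicated(subset=["domain", "difficulty", "item_a", "item_b"]).any()

    def test_exp2_without_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            gen_design(EXP2_DESIGN, seed=0)

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            gen_design(DesignSpec(task="NOPE"), seed=0)


class TestSimulation:
    @pytest.fixture(scope="class")
    def subjects(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pop = gen_population(seed=7)
            return gen_subject_params(pop, seed=8)

    def test_deadline_shorter_than_ter_rejected(self, subjects):
        spec = DesignSpec(task="RDM", deadline_s=0.05)
        with pytest.raises(ValueError, match="deadline"):
            simulate_dataset(subjects[:2], task="RDM", seed=0, design_spec=spec)

    def test_bias_shift_moves_confidence_not_accuracy(self, subjects):
        from dataclasses import replace

        subj = subjects[0]
        ds_lo = simulate_dataset([subj], task="RDM", seed=42)
        ds_hi = simulate_dataset([replace(subj, conf_bias=subj.conf_bias + 10)], task="RDM", seed=42)
        s_lo = summarize_cells(ds_lo)
        s_hi = summarize_cells(ds_hi)
        assert s_hi["mean_confidence"].mean() > s_lo["mean_confidence"].mean() + 2
        assert abs(s_hi["accuracy"].mean() - s_lo["accuracy"].mean()) < 0.03

    def test_pure_noise_readout_kills_metacognition(self, subjects):
        from dataclasses import replace

        subj = replace(subjects[0], meta_noise=50.0, lapse=0.0)
        ds = simulate_dataset([subj] * 8, task="RDM", seed=1)
        df = ds.trials
        stim = (df["stimulus"] == "right").astype(int)
        resp = (df["correct"].astype(int) == stim).astype(int)
        res = fit_meta_d(trials_to_counts(stim, resp, df["rating"], 6))
        assert abs(res.meta_d) < 0.25 and res.d1 > 0.3

    def test_noiseless_readout_approaches_ideal_observer(self, subjects):
        from dataclasses import replace

        subj = replace(subjects[0], meta_noise=0.0, conf_bias=0.0, lapse=0.0)
        ds = simulate_dataset([subj] * 12, task="RDM", seed=2)
        df = ds.trials
        stim = (df["stimulus"] == "right").astype(int)
        resp = (df["correct"].astype(int) == stim).astype(int)
        res = fit_meta_d(trials_to_counts(stim, resp, df["rating"], 6))
        # thresholded ratings lose a little information; near-equality is the contract
        assert res.meta_d > 0.75 * res.d1

    def test_reward_rule_bands(self):
        assert perceptual_reward(89.0) == 1
        assert perceptual_reward(90.0) == 1
        assert perceptual_reward(93.0) == 2
        assert perceptual_reward(96.0) == 3
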