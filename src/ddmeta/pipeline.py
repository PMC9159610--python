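"""End-to-end analysis pipeline on synthetic data.

Mirrors the analysis flow of an extreme-group confidence study: generate the
screening population and behavioural data, preprocess, score efficiency
(LISAS) and metacognition (meta-d'), run the mixed ANOVAs, the two-stage DDM
model selection, and the design power simulation, and write every table plus
a hypothesis-verdict summary to the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import Dataset, FilterRules, preprocess_trials, summarize_cells, write_trials
from .metacognition import fit_meta_d, trials_to_counts
from .model_selection import two_stage_select
from .stats import lisas_table, mixed_anova, power_simulation
from .synthetic_data import (
    PopulationSpec,
    SubjectConfig,
    acs_pool_sampler,
    gen_population,
    gen_subject_params,
    simulate_dataset,
)

log = logging.getLogger("ddmeta")


@dataclass
class RunConfig:
    """Fully serializable run configuration; a run is reproducible from
    config + seed alone."""

    seed: int = 0
    tasks: tuple[str, ...] = ("RDM",)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    subjects: SubjectConfig = field(default_factory=SubjectConfig)
    n_subjects_per_group: int | None = 10
    filters: FilterRules = field(default_factory=FilterRules)
    mcmc: dict = field(default_factory=lambda: {"n_samples": 1200, "n_burn": 400, "n_chains": 2})
    run_ddm_selection: bool = True
    power_r_grid: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    power_n_sims: int = 2000
    out_dir: str = "ddmeta_out"

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = json.loads(self.to_json())
        payload.pop("out_dir", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "population" in raw:
            raw["population"] = PopulationSpec(**{
                k: tuple(v) if k == "selection_bounds" else v for k, v in raw["population"].items()
            })
        if "subjects" in raw:
            raw["subjects"] = SubjectConfig(**raw["subjects"])
        if "filters" in raw:
            raw["filters"] = FilterRules(**raw["filters"])
        for key in ("tasks", "power_r_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs stay on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stamp(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = config.config_hash
    df["seed"] = config.seed
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the summary report (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "stages": {},
        "hypotheses": {},
    }
    t_start = time.time()

    def run_stage(name: str, fn):
        t0 = time.time()
        log.info("stage %s ...", name)
        try:
            result = fn()
        except Exception as e:  # noqa: BLE001 - halt with stage name
            report["stages"][name] = {"status": "failed", "error": str(e)}
            (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
            raise StageError(name, e) from e
        report["stages"][name] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
        return result

    if config.n_subjects_per_group is not None and config.n_subjects_per_group <= 0:
        raise StageError("generate", ValueError("n_subjects_per_group must be positive"))

    def _screen():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return gen_population(config.population, seed=config.seed)

    pop = run_stage("screen", _screen)

    subjects = gen_subject_params(pop, config.subjects, seed=config.seed + 1)
    if config.n_subjects_per_group:
        k = config.n_subjects_per_group
        subjects = [s for s in subjects if s.group == "action"][:k] + [
            s for s in subjects if s.group == "state"
        ][:k]

    def _simulate(task: str) -> Dataset:
        raw = simulate_dataset(subjects, task=task, seed=config.seed + 2)
        filtered = preprocess_trials(
            raw,
            FilterRules(
                rt_floor_s=config.filters.rt_floor_s,
                sd_cut=config.filters.sd_cut,
                drop_reversals=task == "EXP2",
            ),
        )
        write_trials(filtered, out / f"trials_{task}.csv")
        return filtered

    datasets = {
        task: run_stage(f"simulate[{task}]", lambda task=task: _simulate(task))
        for task in config.tasks
    }

    def _summaries(task: str, ds: Dataset):
        factor = ds.factor_columns
        cells = summarize_cells(ds)
        _stamp(cells, config).to_csv(out / f"cells_{task}.csv", index=False)
        lt = lisas_table(ds.trials, factor)
        lt = lt.merge(ds.trials.groupby("subject")["group"].first().reset_index())
        _stamp(lt, config).to_csv(out / f"lisas_{task}.csv", index=False)

        meta_rows = []
        for (subj, *cond), cdf in ds.trials.groupby(["subject"] + factor, sort=True):
            classes = sorted(cdf["stimulus"].unique())
            if len(classes) < 2 or len(cdf) < 10:
                continue
            stim = (cdf["stimulus"] == classes[-1]).astype(int)
            if stim.nunique() < 2:
                continue
            if task == "FHD":
                # stimulus-labelled responses (face/house)
                resp = (cdf["response"] == classes[-1]).astype(int)
            else:
                # responses coded by correctness: infer the chosen class
                resp = (cdf["correct"].astype(int) == stim).astype(int)
            counts = trials_to_counts(stim, resp, cdf["rating"].clip(lower=1), ds.scale.n_levels)
            r = fit_meta_d(counts)
            meta_rows.append(
                dict(
                    subject=subj,
                    group=cdf["group"].iloc[0],
                    **dict(zip(factor, cond)),
                    d1=r.d1,
                    meta_d=r.meta_d,
                    m_ratio=r.m_ratio,
                )
            )
        meta = pd.DataFrame(meta_rows)
        if len(meta):
            _stamp(meta, config).to_csv(out / f"metad_{task}.csv", index=False)
        return cells, lt, meta

    summaries = {
        task: run_stage(f"summaries[{task}]", lambda task=task, ds=ds: _summaries(task, ds))
        for task, ds in datasets.items()
    }

    def _anovas(task, cells, lt, meta):
        factor = datasets[task].factor_columns
        tabs = {}
        for dv, frame in (
            ("mean_confidence", cells),
            ("accuracy", cells),
            ("mean_rt_correct", cells),
            ("lisas", lt),
            ("meta_d", meta if len(meta) else None),
        ):
            if frame is None or dv not in getattr(frame, "columns", []):
                continue
            try:
                tabs[dv] = mixed_anova(frame.dropna(subset=[dv]), dv, within=factor, between="group")
            except Exception as e:  # degenerate cells should not kill the run
                log.warning("ANOVA for %s failed: %s", dv, e)
        combined = pd.concat([t.assign(dv=dv) for dv, t in tabs.items()], ignore_index=True)
        _stamp(combined, config).to_csv(out / f"anova_{task}.csv", index=False)
        return tabs

    anovas = {
        task: run_stage(
            f"anova[{task}]",
            lambda task=task, s=s: _anovas(task, *s),
        )
        for task, s in summaries.items()
    }

    for task, (cells, lt, meta) in summaries.items():
        conf = anovas[task].get("mean_confidence")
        if conf is None:
            continue
        row = conf[conf["effect"] == "group"]
        gm = cells.groupby("group")["mean_confidence"].mean()
        direction = "state < action" if gm.get("action", 0) > gm.get("state", 0) else "action < state"
        sig = bool(row["p"].iloc[0] < 0.05) if len(row) else False
        report["hypotheses"][f"confidence_bias[{task}]"] = {
            "direction": direction,
            "p": float(row["p"].iloc[0]) if len(row) else None,
            "verdict": f"{direction} supported" if sig else "no group difference",
            "group_means": {k: float(v) for k, v in gm.items()},
        }

    if config.run_ddm_selection and "RDM" in datasets:

        def _select():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return two_stage_select(datasets["RDM"], "RDM", mcmc=config.mcmc, seed=config.seed + 3)

        sel = run_stage("ddm_selection[RDM]", _select)
        _stamp(sel.stage1, config).to_csv(out / "dic_stage1_RDM.csv", index=False)
        _stamp(sel.stage2, config).to_csv(out / "dic_stage2_RDM.csv", index=False)
        report["hypotheses"]["ddm_group_effect[RDM]"] = {
            "winning_no_trait_model": sel.winning_stage1.name,
            "baseline_dic": sel.baseline_dic,
            "verdict": sel.verdict,
        }

    pc = run_stage(
        "power",
        lambda: power_simulation(
            acs_pool_sampler(config.population),
            r_grid=list(config.power_r_grid),
            n_sims=config.power_n_sims,
            n_per_group=config.population.n_per_group,
            bounds=config.population.selection_bounds,
            seed=config.seed + 4,
        ),
    )
    _stamp(pc.to_frame(), config).to_csv(out / "power_curve.csv", index=False)
    report["power"] = {str(r): float(p) for r, p in zip(pc.r_grid, pc.power)}

    report["seconds_total"] = round(time.time() - t_start, 2)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
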