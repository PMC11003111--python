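"""End-to-end orchestration: simulate -> diary -> fit -> associate -> report.

Each stage persists its artifacts under the run directory so stages can be
rerun in isolation; one global seed is fanned out to per-stage child seeds
through ``numpy.random.SeedSequence`` so the whole run is reproducible.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from adhertraj import association, diary, gbtm, simulate

log = logging.getLogger("adhertraj")

_STAGE_SEEDS = {"simulate": 0, "fit": 1, "impute": 2}


def _child_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(seed), _STAGE_SEEDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    seed: int
    simulation: simulate.SimulationConfig | None = None  # None -> external input
    input_dir: str | None = None
    interval_len_days: int = diary.INTERVAL_DAYS
    cap_days: int = diary.CARRY_FORWARD_CAP
    j_range: tuple[int, int] = (2, 7)
    n_restarts: int = 5
    tol: float = 1e-8
    max_iter: int = 500
    specs: list[association.ExposureModelSpec] | None = None
    impute_m: int = 50
    make_figures: bool = True

    def validate(self) -> None:
        if self.simulation is None and self.input_dir is None:
            raise ValueError("either a simulation config or input_dir is required")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise ValueError(f"input_dir {self.input_dir} does not exist")


@dataclass
class RunReport:
    """Summary of a completed pipeline run."""

    exclusions: dict
    model: dict
    selection_trace: dict
    group_shares: dict
    diagnostics: dict
    or_tables: pd.DataFrame
    figure_paths: list[str]
    seed: int
    version: str
    timings: dict = field(default_factory=dict)


def _load_inputs(path: Path):
    patients = pd.read_csv(path / "patients.csv")
    visits = pd.read_csv(path / "visits.csv")
    cens_file = path / "censoring.csv"
    if cens_file.exists() and cens_file.stat().st_size > 0:
        censoring = pd.read_csv(cens_file)
        if censoring.empty:
            censoring = pd.DataFrame(columns=["patient_id", "event_date", "reason"])
    else:
        censoring = pd.DataFrame(columns=["patient_id", "event_date", "reason"])
    return patients, visits, censoring


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages; persists every intermediate artifact."""
    from adhertraj import __version__

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}

    # ---- stage 1: cohort data ------------------------------------------
    t0 = time.time()
    if config.simulation is not None:
        sim = config.simulation
        sim = simulate.SimulationConfig(**{**sim.to_dict(), "seed": _child_seed(config.seed, "simulate")})
        patients, truth = simulate.generate_cohort(sim)
        visits, censoring = simulate.generate_follow_up(patients, truth, sim)
        patients = simulate.inject_missingness(patients, sim)
        simulate.write_cohort(out, patients, truth, visits, censoring, sim)
    else:
        patients, visits, censoring = _load_inputs(Path(config.input_dir))
    timings["simulate"] = time.time() - t0
    log.info("stage simulate done: %d patients, %d visits", len(patients), len(visits))

    # ---- stage 2: eligibility + diaries + PDC panel --------------------
    t0 = time.time()
    eligible, excl = diary.apply_eligibility(patients, visits, censoring)
    panel = diary.panels_from_visits(
        patients, visits, censoring, eligible,
        interval_len_days=config.interval_len_days, cap_days=config.cap_days,
    )
    panel.to_csv(out / "panel.csv", index=False)
    (out / "exclusions.json").write_text(json.dumps(excl.to_dict(), indent=2))
    timings["diary"] = time.time() - t0
    log.info("stage diary done: %d eligible, %d panel rows", len(eligible), len(panel))

    # ---- stage 3: trajectory model -------------------------------------
    t0 = time.time()
    fit_seed = _child_seed(config.seed, "fit")
    if panel["pdc"].std() < 1e-9:
        warnings.warn(
            "degenerate panel: PDC has no variation; fitting a single-group model",
            RuntimeWarning,
        )
        model = gbtm.fit_gbtm(panel, 1, 0, seed=fit_seed, n_restarts=1)
        trace = gbtm.SelectionTrace(chosen={"J": 1, "orders": [0], "bic": gbtm.bic(model)})
    else:
        model, trace = gbtm.select_model(
            panel, j_range=range(config.j_range[0], config.j_range[1] + 1),
            seed=fit_seed, n_restarts=config.n_restarts, tol=config.tol,
            max_iter=config.max_iter,
        )
    assignments = gbtm.posterior_assign(model, panel)
    diag = gbtm.diagnostics(model, assignments, panel=panel)
    assignments.to_csv(out / "assignments.csv", index=False)
    model_doc = {
        "model": model.to_dict(),
        "selection_trace": {"step1": trace.step1, "step2": trace.step2, "chosen": trace.chosen},
        "diagnostics": {
            "appa": diag.appa.tolist(),
            "occ": diag.occ.tolist(),
            "shares": diag.shares.tolist(),
            "flagged_groups": diag.flagged.tolist(),
        },
    }
    (out / "model.json").write_text(json.dumps(model_doc, indent=2))
    timings["fit"] = time.time() - t0
    log.info("stage fit done: J=%d orders=%s", model.J, model.orders)

    # ---- stage 4: associations -----------------------------------------
    t0 = time.time()
    elig_patients = patients[patients["patient_id"].isin(eligible)].reset_index(drop=True)
    completed = association.impute_missing(
        elig_patients, m=config.impute_m, seed=_child_seed(config.seed, "impute")
    )
    specs = config.specs if config.specs is not None else association.default_specs()
    tables = association.run_association_suite(assignments, completed, specs)
    or_long = association.combined_or_table(tables)
    or_long.to_csv(out / "or_table.csv", index=False)
    (out / "specs.json").write_text(json.dumps([s.to_dict() for s in specs], indent=2))
    timings["associate"] = time.time() - t0
    log.info("stage associate done: %d exposures", len(tables))

    # ---- stage 5: report -----------------------------------------------
    t0 = time.time()
    shares = {
        f"group_{j + 1}": float((assignments["assigned_group"] == j + 1).mean())
        for j in range(model.J)
    }
    report = RunReport(
        exclusions=excl.to_dict(),
        model=model.to_dict(),
        selection_trace=model_doc["selection_trace"],
        group_shares=shares,
        diagnostics=model_doc["diagnostics"],
        or_tables=or_long,
        figure_paths=[],
        seed=config.seed,
        version=__version__,
        timings=timings,
    )
    if config.make_figures:
        from adhertraj import report as report_mod

        report.figure_paths = report_mod.render_report(
            report, model, panel, assignments, out
        )
    timings["report"] = time.time() - t0
    return report
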