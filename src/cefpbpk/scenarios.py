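"""Packaged study designs and scenario execution.

Loads the shipped study-design tables (the clinical designs each drug's
model was checked against, plus the four prospective caesarean-prophylaxis
scenarios: 750/1500 mg cefuroxime in obese and morbidly obese pregnant
populations), turns them into population specs, runs replicated virtual
trials, and writes the profile/endpoint/report artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .compound import load_compound
from .engine import DosingRegimen
from .evaluation import TwoFoldReport, evaluate_study, load_observed
from .physiology import PopulationSpec
from .population import MicGrid, TrialResult, incision_offset_analysis, run_trials, time_above_threshold

__all__ = [
    "ScenarioConfig",
    "load_study_designs",
    "spec_for_study",
    "run_study",
    "run_scenario",
    "run_evaluation_suite",
    "endpoint_rows",
]

log = logging.getLogger("cefpbpk")

DEFAULT_N_TRIALS = 20
DEFAULT_OFFSETS_MIN = (15.0, 30.0, 60.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """One runnable scenario (a packaged study or a custom design)."""

    scenario_id: str
    drug: str
    dose_mg: float
    infusion_min: float = 1.0
    population_class: str = "lean"
    pregnant: bool = False
    ga_weeks: float = 0.0
    pre_pregnancy_weight: float | None = None
    target_mean_weight: float | None = None
    proportion_female: float = 1.0
    age_range: tuple[float, float] = (20.0, 40.0)
    n: int = 10
    n_trials: int = DEFAULT_N_TRIALS
    incision_offsets_min: tuple[float, ...] = DEFAULT_OFFSETS_MIN
    mic_grid: tuple[float, ...] = (2.0, 4.0, 8.0)
    seed: int = 0

    def population_spec(self) -> PopulationSpec:
        return PopulationSpec(
            population_class=self.population_class,
            pregnant=self.pregnant,
            gestational_age=self.ga_weeks,
            n_subjects=self.n,
            proportion_female=self.proportion_female,
            age_range=self.age_range,
            target_mean_weight=self.target_mean_weight,
            pre_pregnancy_weight=self.pre_pregnancy_weight,
            seed=self.seed,
        )

    def regimen(self) -> DosingRegimen:
        return DosingRegimen(dose=self.dose_mg,
                             infusion_duration=self.infusion_min)


def load_study_designs(drug: str) -> pd.DataFrame:
    path = resources.files("cefpbpk.data").joinpath(f"studies_{drug}.csv")
    with path.open() as fh:
        return pd.read_csv(fh, comment="#", dtype={"study_code": str}
                           ).set_index("study_code")


def spec_for_study(drug: str, study_code: str, seed: int = 0,
                   n_subjects: int | None = None) -> ScenarioConfig:
    """Build the scenario config of one packaged study design."""
    designs = load_study_designs(drug)
    try:
        row = designs.loc[study_code]
    except KeyError as exc:
        raise KeyError(f"no packaged study {study_code!r} for {drug}") from exc
    return ScenarioConfig(
        scenario_id=study_code,
        drug=drug,
        dose_mg=float(row.dose_mg),
        infusion_min=float(row.infusion_min),
        population_class=row.population_class,
        pregnant=bool(row.pregnant),
        ga_weeks=float(row.ga_weeks) if pd.notna(row.ga_weeks) else 0.0,
        pre_pregnancy_weight=(float(row.pre_pregnancy_weight_kg)
                              if pd.notna(row.pre_pregnancy_weight_kg) else None),
        target_mean_weight=(float(row.weight_target_kg)
                            if pd.notna(row.weight_target_kg) else None),
        proportion_female=float(row.prop_female),
        age_range=(float(row.age_min), float(row.age_max)),
        n=int(n_subjects if n_subjects is not None else row.n_subjects),
        seed=seed,
    )


def run_study(drug: str, study_code: str, seed: int = 0,
              n_trials: int = DEFAULT_N_TRIALS,
              n_subjects: int | None = None) -> TrialResult:
    """Run one packaged study design as a replicated virtual trial."""
    config = spec_for_study(drug, study_code, seed=seed,
                            n_subjects=n_subjects)
    compound = load_compound(drug)
    spec = config.population_spec()
    log.info("study %s/%s: n=%d trials=%d seed=%d", drug, study_code,
             spec.n_subjects, n_trials, seed)
    return run_trials(spec, compound, config.regimen(), n_trials=n_trials,
                      seed=seed)


def endpoint_rows(trial: TrialResult, mic_grid: tuple[float, ...],
                  study_code: str) -> pd.DataFrame:
    """Endpoint table: AUC/Cmax/CL summaries plus T>MIC per output series."""
    rows = []
    ep = trial.endpoint_table()
    for name, col in (("auc_inf", "auc_inf"), ("cmax_plasma", "cmax_plasma"),
                      ("cl", "cl")):
        for stat, value in (("mean", ep[col].mean()),
                            ("p5", ep[col].quantile(0.05)),
                            ("p95", ep[col].quantile(0.95))):
            rows.append({"study_code": study_code, "output": name,
                         "statistic": stat, "threshold": None,
                         "value": float(value), "reached": True})
    for output in ("plasma_total", "plasma_unbound", "adipose_total",
                   "adipose_isf_unbound"):
        summ = trial.summary(output)
        for thr in mic_grid:
            for stat in ("mean", "p5", "p95"):
                t_above = time_above_threshold(summ["time_h"].values,
                                               summ[stat].values, thr)
                rows.append({"study_code": study_code,
                             "output": f"t_above_{output}",
                             "statistic": stat, "threshold": thr,
                             "value": t_above, "reached": t_above > 0})
    return pd.DataFrame(rows)


def run_scenario(config: ScenarioConfig, out_dir: str | Path | None = None,
                 ) -> dict[str, pd.DataFrame]:
    """Run one scenario end to end and (optionally) write its artifacts.

    Returns the profile summary, endpoint table, and incision-offset table;
    outputs are deterministic under the config's seed.
    """
    compound = load_compound(config.drug)
    spec = config.population_spec()
    config_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:12]
    log.info("scenario %s: config_hash=%s seed=%d", config.scenario_id,
             config_hash, config.seed)
    trial = run_trials(spec, compound, config.regimen(),
                       n_trials=config.n_trials, seed=config.seed)

    profile_frames = []
    for output in ("plasma_total", "plasma_unbound", "adipose_total",
                   "adipose_isf_unbound"):
        summ = trial.summary(output)
        summ.insert(0, "output", output)
        profile_frames.append(summ)
    profiles = pd.concat(profile_frames, ignore_index=True)
    endpoints = endpoint_rows(trial, config.mic_grid, config.scenario_id)
    offsets = incision_offset_analysis(
        trial, offsets_min=config.incision_offsets_min,
        thresholds=MicGrid(tuple(config.mic_grid)))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = f"{config.drug}_{config.scenario_id}"
        profiles.to_csv(out / f"{stem}_profiles.csv", index=False)
        endpoints.to_csv(out / f"{stem}_endpoints.csv", index=False)
        offsets.to_csv(out / f"{stem}_incision_offsets.csv", index=False)
    return {"profiles": profiles, "endpoints": endpoints, "offsets": offsets}


def run_evaluation_suite(drug: str, seed: int = 0,
                         n_trials: int = DEFAULT_N_TRIALS,
                         study_codes: list[str] | None = None) -> TwoFoldReport:
    """Simulate every packaged study of a drug and evaluate it two-fold."""
    observed = load_observed(drug)
    designs = load_study_designs(drug)
    codes = study_codes if study_codes is not None else [
        c for c in designs.index if c in observed]
    frames = []
    for code in codes:
        trial = run_study(drug, code, seed=seed, n_trials=n_trials)
        report = evaluate_study(trial, observed[code])
        frames.append(report.rows)
    return TwoFoldReport(rows=pd.concat(frames, ignore_index=True))
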