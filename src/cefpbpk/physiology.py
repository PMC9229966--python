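"""Virtual-subject physiology.

Generates the demographics, tissue volumes, regional blood flows and renal
function of virtual subjects for the lean, obese and morbidly obese
non-pregnant baselines, and applies gestational scaling on a chosen
baseline to produce pregnant variants (the obese-pregnant populations use
the obese non-pregnant tissue flows as the pre-pregnancy starting point).

Conventions: volumes L, flows L/h, time h, weight kg, GFR L/h,
serum creatinine mg/dL, adipose density 0.916 kg/L, other tissues unit
density. Lean body weight via the Janmahasatian equations; body surface
area via DuBois; blood volume via Nadler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .compound import PERFUSION_TISSUES

__all__ = [
    "PopulationSpec",
    "SubjectPhysiology",
    "AdiposeGeometry",
    "mdrd_egfr",
    "mdrd_gfr",
    "build_baseline",
    "build_population",
    "apply_pregnancy",
    "adipose_water_partition",
    "reference_adult",
]

ADIPOSE_DENSITY = 0.916  # kg/L
ISF_FRACTION = 0.141  # interstitial water, fraction of adipose volume
IW_FRACTION = 0.039  # intracellular water, fraction of adipose volume

#: BMI sampling ranges by population class (kg/m^2)
BMI_RANGES = {
    "lean": (18.5, 24.99),
    "obese": (30.0, 40.0),
    "morbidly_obese": (40.0, 50.0),
}

# height distributions per sex (cm): mean, SD
HEIGHT_DIST = {"female": (163.0, 6.0), "male": (176.0, 7.0)}
# serum creatinine medians per sex (mg/dL), healthy adults
CREATININE_MEDIAN = {"female": 0.70, "male": 0.80}
BASE_HEMATOCRIT = {"female": 0.40, "male": 0.45}
CARDIAC_INDEX = 3.2  # L/min per m^2 BSA

# between-subject lognormal CVs (scaled by PopulationSpec.bsv_scale)
CV_FLOWS = 0.20
CV_VOLUMES = 0.20
CV_GFR = 0.25
CV_CREATININE = 0.15
CV_CARDIAC = 0.15


def _load_reference_tables():
    path = resources.files("cefpbpk.data").joinpath("population_reference.csv")
    with path.open() as fh:
        ref = pd.read_csv(fh, comment="#").set_index("tissue")
    path = resources.files("cefpbpk.data").joinpath("pregnancy_scaling.csv")
    with path.open() as fh:
        preg = pd.read_csv(fh, comment="#").set_index("parameter")
    return ref, preg


_REF_TABLE, _PREG_TABLE = _load_reference_tables()


@dataclass(frozen=True)
class PopulationSpec:
    """Definition of one virtual population / study arm."""

    population_class: str = "lean"
    pregnant: bool = False
    gestational_age: float = 0.0  # weeks
    n_subjects: int = 1
    proportion_female: float = 1.0
    age_range: tuple[float, float] = (20.0, 40.0)
    target_mean_weight: float | None = None  # kg, at study time (term if pregnant)
    pre_pregnancy_weight: float | None = None  # kg, mean pre-pregnancy weight
    seed: int = 0
    bsv_scale: float = 1.0  # 0 disables between-subject variability

    def __post_init__(self) -> None:
        if self.population_class not in BMI_RANGES:
            raise ValueError(f"unknown population class {self.population_class!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.pregnant:
            if not 0 < self.gestational_age <= 42:
                raise ValueError("gestational_age must be in (0, 42] weeks")
            if self.proportion_female != 1.0:
                raise ValueError("pregnant populations must be all female")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (min, max)")


@dataclass(frozen=True)
class SubjectPhysiology:
    """One virtual subject's anatomy and renal function."""

    age: float
    sex: str
    weight: float  # kg
    height: float  # cm
    bmi: float
    gestational_age: float  # weeks, 0 if not pregnant
    cardiac_output: float  # L/h
    hematocrit: float
    serum_creatinine: float  # mg/dL
    gfr: float  # L/h, absolute
    tissue_volumes: dict[str, float]  # L, includes 'adipose'
    tissue_flows: dict[str, float]  # L/h, includes 'adipose'; sums to CO
    plasma_volume: float  # L
    red_cell_volume: float  # L
    population_class: str = "lean"
    flow_fractions: dict[str, float] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.gfr <= 0:
            raise ValueError("gfr must be > 0")
        if any(v <= 0 for v in self.tissue_volumes.values()):
            raise ValueError("all tissue volumes must be > 0")
        if sum(self.tissue_flows.values()) > self.cardiac_output * (1 + 1e-9):
            raise ValueError("tissue flows exceed cardiac output")
        bmi = self.weight / (self.height / 100.0) ** 2
        if abs(bmi - self.bmi) > 0.01 * bmi:
            raise ValueError("bmi inconsistent with weight and height")

    @property
    def blood_volume(self) -> float:
        return self.plasma_volume + self.red_cell_volume

    @property
    def bsa(self) -> float:
        return dubois_bsa(self.weight, self.height)


@dataclass(frozen=True)
class AdiposeGeometry:
    """Water sub-compartment volumes of the adipose depot."""

    v_adipose: float  # L
    v_isf: float  # L
    v_iw: float  # L
    f_isf: float = ISF_FRACTION
    f_iw: float = IW_FRACTION


def adipose_water_partition(v_adipose: float) -> AdiposeGeometry:
    """Split an adipose volume into its interstitial and intracellular water."""
    if v_adipose <= 0:
        raise ValueError("adipose volume must be > 0")
    return AdiposeGeometry(
        v_adipose=v_adipose,
        v_isf=ISF_FRACTION * v_adipose,
        v_iw=IW_FRACTION * v_adipose,
    )


def dubois_bsa(weight: float, height: float) -> float:
    """DuBois body surface area (m^2) from weight (kg) and height (cm)."""
    return 0.007184 * weight ** 0.425 * height ** 0.725


def janmahasatian_lbw(weight: float, bmi: float, sex: str) -> float:
    """Lean body weight (kg)."""
    if sex == "male":
        return 9270.0 * weight / (6680.0 + 216.0 * bmi)
    return 9270.0 * weight / (8780.0 + 244.0 * bmi)


def nadler_blood_volume(weight: float, height: float, sex: str) -> float:
    """Total blood volume (L)."""
    h_m = height / 100.0
    if sex == "male":
        return 0.3669 * h_m ** 3 + 0.03219 * weight + 0.6041
    return 0.3561 * h_m ** 3 + 0.03308 * weight + 0.1833


def mdrd_egfr(age: float, sex: str, serum_creatinine: float) -> float:
    """MDRD estimated GFR, mL/min/1.73 m^2 (binary sex coefficient form)."""
    if serum_creatinine <= 0:
        raise ValueError("serum creatinine must be > 0")
    if age < 18:
        raise ValueError("MDRD applies to adults (age >= 18)")
    egfr = 175.0 * serum_creatinine ** -1.154 * age ** -0.203
    if sex == "female":
        egfr *= 0.742
    return egfr


def mdrd_gfr(age: float, sex: str, serum_creatinine: float,
             body_surface_area: float) -> float:
    """Absolute MDRD GFR in L/h, de-normalised by BSA/1.73."""
    egfr = mdrd_egfr(age, sex, serum_creatinine)
    ml_min = egfr * body_surface_area / 1.73
    return ml_min * 60.0 / 1000.0


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Median-1 lognormal multiplier truncated at +/-3 SD in log space."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    z = rng.standard_normal()
    z = min(max(z, -3.0), 3.0)
    return math.exp(sigma * z)


def _flow_column(population_class: str) -> pd.Series:
    return _REF_TABLE[f"flow_frac_{population_class}"].dropna()


def build_baseline(spec: PopulationSpec, rng: np.random.Generator,
                   weight_override: float | None = None) -> SubjectPhysiology:
    """Sample one non-pregnant subject of the spec's baseline class.

    Demographics are drawn within the stated ranges; organ volumes scale
    with lean body weight, adipose with fat mass, and regional flows follow
    the class flow-fraction table (obese classes route more of an elevated
    cardiac output to the enlarged adipose depot). When the spec carries a
    weight target the weight sampling is centred on it; ``weight_override``
    pins the weight exactly (used for population-level mean matching).
    """
    bsv = spec.bsv_scale
    sex = "female" if rng.random() < spec.proportion_female else "male"
    if bsv > 0:
        age = rng.uniform(*spec.age_range)
    else:
        age = 0.5 * (spec.age_range[0] + spec.age_range[1])
    h_mean, h_sd = HEIGHT_DIST[sex]
    height = h_mean + min(max(rng.standard_normal(), -3.0), 3.0) * h_sd * bsv

    lo, hi = BMI_RANGES[spec.population_class]
    if bsv > 0:
        bmi = rng.uniform(lo, hi)
    else:
        bmi = 0.5 * (lo + hi)
    weight = bmi * (height / 100.0) ** 2

    target = spec.pre_pregnancy_weight if spec.pregnant else spec.target_mean_weight
    if weight_override is not None:
        weight = weight_override
    elif target is not None:
        # centre the class weight distribution on the study target
        mid_bmi = 0.5 * (lo + hi)
        weight = target * (bmi / mid_bmi) * (height / h_mean) ** 2
    bmi = weight / (height / 100.0) ** 2
    if not 15.0 <= bmi <= 65.0:
        raise ValueError(
            f"weight target unreachable for class {spec.population_class!r}: "
            f"implied BMI {bmi:.1f}")

    lbw = janmahasatian_lbw(weight, bmi, sex)
    fat_mass = max(weight - lbw, 1.0)

    blood_volume = nadler_blood_volume(weight, height, sex)
    hematocrit = BASE_HEMATOCRIT[sex] * _lognormal_factor(rng, 0.05 * bsv)
    hematocrit = min(max(hematocrit, 0.25), 0.55)
    plasma_volume = blood_volume * (1.0 - hematocrit)
    red_cell_volume = blood_volume * hematocrit

    volumes: dict[str, float] = {}
    organ_total = 0.0
    for tissue in PERFUSION_TISSUES:
        if tissue == "rest":
            continue
        v = _REF_TABLE.loc[tissue, "vol_per_kg_lbw"] * lbw
        v *= _lognormal_factor(rng, CV_VOLUMES * bsv)
        volumes[tissue] = v
        organ_total += v
    volumes["adipose"] = fat_mass / ADIPOSE_DENSITY
    # carcass closure keeps sum(tissue masses) + blood == body weight
    volumes["rest"] = max(lbw - organ_total - blood_volume, 0.5)

    cardiac_output = (CARDIAC_INDEX * dubois_bsa(weight, height) * 60.0
                      * _lognormal_factor(rng, CV_CARDIAC * bsv))

    fracs_raw = _flow_column(spec.population_class).to_dict()
    perturbed = {t: f * _lognormal_factor(rng, CV_FLOWS * bsv)
                 for t, f in fracs_raw.items()}
    norm = sum(perturbed.values())
    flow_fractions = {t: f / norm for t, f in perturbed.items()}
    flows = {t: f * cardiac_output for t, f in flow_fractions.items()}

    serum_creatinine = (CREATININE_MEDIAN[sex]
                        * _lognormal_factor(rng, CV_CREATININE * bsv))
    gfr = mdrd_gfr(age, sex, serum_creatinine, dubois_bsa(weight, height))
    gfr *= _lognormal_factor(rng, CV_GFR * bsv)

    return SubjectPhysiology(
        age=age, sex=sex, weight=weight, height=height, bmi=bmi,
        gestational_age=0.0, cardiac_output=cardiac_output,
        hematocrit=hematocrit, serum_creatinine=serum_creatinine, gfr=gfr,
        tissue_volumes=volumes, tissue_flows=flows,
        plasma_volume=plasma_volume, red_cell_volume=red_cell_volume,
        population_class=spec.population_class,
        flow_fractions=flow_fractions,
    )


def _preg_multiplier(parameter: str, ga: float) -> float:
    row = _PREG_TABLE.loc[parameter]
    assert row.kind == "exp_sat"
    return 1.0 + row.a * (1.0 - math.exp(-ga / row.b))


def _preg_mass(parameter: str, ga: float) -> float:
    row = _PREG_TABLE.loc[parameter]
    assert row.kind == "power"
    return row.a * (ga / 40.0) ** row.b


def nonadipose_gestational_gain(base: SubjectPhysiology, ga: float) -> float:
    """Gestational weight gain (kg) excluding maternal fat: products of
    conception, extracellular fluid, and blood expansion."""
    masses = (_preg_mass("fetus", ga) + _preg_mass("conceptus_other", ga)
              + _preg_mass("ecf_expansion", ga))
    d_pv = base.plasma_volume * (_preg_multiplier("plasma_volume", ga) - 1.0)
    d_rcv = base.red_cell_volume * (_preg_multiplier("red_cell_volume", ga) - 1.0)
    return masses + d_pv + d_rcv


def apply_pregnancy(base: SubjectPhysiology, ga: float,
                    term_weight: float | None = None) -> SubjectPhysiology:
    """Apply gestational scaling to a non-pregnant female baseline.

    Cardiac output, GFR, plasma and red-cell volume follow smooth saturating
    gestational curves; products of conception and extracellular fluid are
    added to the carcass compartment; maternal fat gain is the residual
    needed to reach ``term_weight`` at this gestational age (or a default
    gain curve when no target is given). At ga=0 the subject is returned
    unchanged.
    """
    if base.sex != "female":
        raise ValueError("pregnancy scaling requires a female subject")
    if ga < 0:
        raise ValueError("gestational age must be >= 0")
    if ga == 0:
        return base

    nonadipose = nonadipose_gestational_gain(base, ga)
    if term_weight is not None:
        fat_gain = max(term_weight - base.weight - nonadipose, 0.0)
    else:
        fat_gain = _preg_mass("fat_default", ga)
    weight = base.weight + nonadipose + fat_gain

    plasma_volume = base.plasma_volume * _preg_multiplier("plasma_volume", ga)
    red_cell_volume = base.red_cell_volume * _preg_multiplier("red_cell_volume", ga)
    hematocrit = red_cell_volume / (plasma_volume + red_cell_volume)
    cardiac_output = base.cardiac_output * _preg_multiplier("cardiac_output", ga)
    gfr = base.gfr * _preg_multiplier("gfr", ga)
    # observable only; the GFR above already carries the gestational renal
    # effect, so MDRD is not re-evaluated on the lowered creatinine
    serum_creatinine = base.serum_creatinine * (
        1.0 - 0.2 * (1.0 - math.exp(-ga / 10.0)))

    volumes = dict(base.tissue_volumes)
    volumes["adipose"] = base.tissue_volumes["adipose"] + fat_gain / ADIPOSE_DENSITY
    volumes["rest"] = base.tissue_volumes["rest"] + (
        _preg_mass("fetus", ga) + _preg_mass("conceptus_other", ga)
        + _preg_mass("ecf_expansion", ga))
    flows = {t: f * cardiac_output for t, f in base.flow_fractions.items()}

    bmi = weight / (base.height / 100.0) ** 2
    return replace(
        base, weight=weight, bmi=bmi, gestational_age=ga,
        cardiac_output=cardiac_output, hematocrit=hematocrit,
        serum_creatinine=serum_creatinine, gfr=gfr, tissue_volumes=volumes,
        tissue_flows=flows, plasma_volume=plasma_volume,
        red_cell_volume=red_cell_volume,
    )


def build_population(spec: PopulationSpec) -> list[SubjectPhysiology]:
    """Build the full subject list for a spec, with exact mean-weight matching.

    Non-pregnant: sampled weights are recentred so the population mean hits
    the target (within the +/-5 kg adjustment convention the packaged study
    designs assume). Pregnant: the non-pregnant baseline is built first
    (centred on the pre-pregnancy weight when given, otherwise backed out of
    the term-weight target), then gestational scaling is applied per subject
    so the mean term weight lands on the target.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = [build_baseline(spec, rng) for _ in range(spec.n_subjects)]

    if spec.pregnant:
        ga = spec.gestational_age
        pre_target = spec.pre_pregnancy_weight
        if pre_target is None and spec.target_mean_weight is not None:
            # back out a mean pre-pregnancy weight using the default gain
            probe = subjects[0]
            default_gain = (nonadipose_gestational_gain(probe, ga)
                            + _preg_mass("fat_default", ga))
            pre_target = spec.target_mean_weight - default_gain
        if pre_target is not None:
            subjects = _recentre_weights(spec, subjects, pre_target)
        if spec.target_mean_weight is not None:
            mean_w0 = float(np.mean([s.weight for s in subjects]))
            gain = spec.target_mean_weight - mean_w0
            out = [apply_pregnancy(s, ga, term_weight=s.weight + gain)
                   for s in subjects]
        else:
            out = [apply_pregnancy(s, ga) for s in subjects]
        return out

    if spec.target_mean_weight is not None:
        subjects = _recentre_weights(spec, subjects, spec.target_mean_weight)
    return subjects


def _recentre_weights(spec: PopulationSpec, subjects: list[SubjectPhysiology],
                      target_mean: float) -> list[SubjectPhysiology]:
    mean_w = float(np.mean([s.weight for s in subjects]))
    factor = target_mean / mean_w
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    rebuilt = []
    for s in subjects:
        sub_spec = spec
        rebuilt.append(build_baseline(sub_spec, rng,
                                      weight_override=s.weight * factor))
    return rebuilt


def reference_adult() -> SubjectPhysiology:
    """Deterministic lean reference adult (male, 70 kg, 176 cm, 30 y)."""
    spec = PopulationSpec(population_class="lean", proportion_female=0.0,
                          n_subjects=1, bsv_scale=0.0,
                          target_mean_weight=70.0, seed=0)
    rng = np.random.default_rng(0)
    return build_baseline(spec, rng, weight_override=70.0)
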