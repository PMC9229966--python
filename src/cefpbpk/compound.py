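"""Drug constants and tissue partitioning.

Holds the compound parameter sets (physicochemistry, plasma binding,
tissue-to-plasma partition overrides, renal transporter intrinsic
clearances) and computes the steady-state distribution quantities the
whole-body model needs: ionized fractions, Rodgers–Rowland tissue:plasma
partition coefficients for monoprotic acids, intracellular unbound
fractions, and the steady-state volume of distribution.

Both packaged drugs are hydrophilic monoprotic acids that are >99.9%
ionized at physiological pH, so the moderate-to-strong acid equation
family (extracellular-protein binding term, no acidic-phospholipid
association) is used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

__all__ = [
    "CompoundParams",
    "RenalTransporterSet",
    "TissueComposition",
    "load_compound",
    "load_tissue_composition",
    "ionized_fraction",
    "predict_kp_set",
    "fu_intracellular",
    "compute_vss",
]

#: tissues modeled as perfusion-limited compartments (adipose is handled by
#: the permeability-limited sub-model and excluded from Kp-based transport,
#: but still carries a predicted Kp for Vss bookkeeping).
PERFUSION_TISSUES = (
    "bone", "brain", "gut", "heart", "kidney", "liver", "lung",
    "muscle", "pancreas", "skin", "spleen", "rest",
)
ALL_TISSUES = ("adipose",) + PERFUSION_TISSUES

PLASMA_PH = 7.4


@dataclass(frozen=True)
class RenalTransporterSet:
    """Per-cell kidney transport constants (uL/min/1e6 cells unless noted)."""

    clint_oat1_uptake: float
    clint_oat3_uptake: float
    clint_mrp4_efflux: float
    clpd_basal: float  # mL/min/1e6 cells
    clpd_apical: float  # mL/min/1e6 cells
    fu_kidney_cell: float
    fu_urine: float

    def __post_init__(self) -> None:
        for name in ("clint_oat1_uptake", "clint_oat3_uptake",
                     "clint_mrp4_efflux", "clpd_basal", "clpd_apical"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fu_kidney_cell", "fu_urine"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class CompoundParams:
    """One drug's physicochemical and kinetic constants."""

    name: str
    molecular_weight: float  # g/mol
    log_p: float
    acid_pka: float
    compound_type: str
    blood_to_plasma: float
    fu_plasma: float
    kp_scalar: float
    kp_overrides: dict[str, float]
    adipose_clpd: float  # L/h, passive ISF<->IW diffusion clearance
    renal: RenalTransporterSet
    field_metadata: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not 0 < self.fu_plasma <= 1:
            raise ValueError("fu_plasma must be in (0, 1]")
        if self.blood_to_plasma <= 0:
            raise ValueError("blood_to_plasma must be > 0")
        if self.adipose_clpd < 0:
            raise ValueError("adipose_clpd must be >= 0")
        if any(v < 0 for v in self.kp_overrides.values()):
            raise ValueError("Kp overrides must be >= 0")
        if self.compound_type != "monoprotic_acid":
            raise ValueError("only monoprotic acids are supported")


@dataclass(frozen=True)
class TissueComposition:
    """Fractional tissue composition table for the partitioning method."""

    table: pd.DataFrame  # indexed by tissue

    def __post_init__(self) -> None:
        frac_cols = ["f_water_ec", "f_water_ic", "f_nl", "f_np"]
        t = self.table
        if (t[frac_cols] < 0).any().any():
            raise ValueError("composition fractions must be >= 0")
        if (t[frac_cols].sum(axis=1) > 1.0 + 1e-9).any():
            raise ValueError("composition fractions within a tissue exceed 1")

    def row(self, tissue: str) -> pd.Series:
        try:
            return self.table.loc[tissue]
        except KeyError as exc:
            raise KeyError(f"no composition data for tissue {tissue!r}") from exc


def _data_path(name: str):
    return resources.files("cefpbpk.data").joinpath(name)


def load_compound(name_or_path: str) -> CompoundParams:
    """Load a compound file (packaged name like ``"cefazolin"`` or a path)."""
    if name_or_path in ("cefazolin", "cefuroxime"):
        text = _data_path(f"{name_or_path}.yaml").read_text()
    else:
        with open(name_or_path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    renal = RenalTransporterSet(**raw.pop("renal"))
    return CompoundParams(
        name=raw["name"],
        molecular_weight=float(raw["molecular_weight"]),
        log_p=float(raw["log_p"]),
        acid_pka=float(raw["acid_pka"]),
        compound_type=raw["compound_type"],
        blood_to_plasma=float(raw["blood_to_plasma"]),
        fu_plasma=float(raw["fu_plasma"]),
        kp_scalar=float(raw["kp_scalar"]),
        kp_overrides={k: float(v) for k, v in (raw.get("kp_overrides") or {}).items()},
        adipose_clpd=float(raw["adipose_clpd_l_per_h"]),
        renal=renal,
    )


def load_tissue_composition() -> TissueComposition:
    """Load the packaged tissue composition table."""
    with _data_path("tissue_composition.csv").open() as fh:
        table = pd.read_csv(fh, comment="#").set_index("tissue")
    return TissueComposition(table=table)


def ionized_fraction(pka: float, ph: float) -> float:
    """Fraction of a monoprotic acid present in the ionized form at ``ph``.

    Henderson–Hasselbalch: ionized/total = 1 - 1/(1 + 10**(ph - pka)).
    Monotone increasing in pH; 0.5 at pH == pKa.
    """
    if not (math.isfinite(pka) and math.isfinite(ph)):
        raise ValueError("pka and ph must be finite")
    return 1.0 - 1.0 / (1.0 + 10.0 ** (ph - pka))


def _x_term(pka: float, ph: float) -> float:
    # 1 + 10^(pH - pKa): reciprocal of the neutral fraction of an acid.
    return 1.0 + 10.0 ** (ph - pka)


def predict_kp_set(compound: CompoundParams,
                   composition: TissueComposition) -> dict[str, float]:
    """Tissue:plasma partition coefficients for every modeled tissue.

    Rodgers–Rowland moderate-to-strong acid form: partitioning into tissue
    water (with intracellular ionization shift), neutral lipid/phospholipid
    of the neutral species only, and binding to extracellular albumin scaled
    by the tissue:plasma albumin ratio. The prediction is multiplied by the
    global Kp scalar, then replaced by any explicit override.
    """
    p = 10.0 ** compound.log_p
    fu = compound.fu_plasma
    plasma = composition.row("plasma")
    y_plasma = _x_term(compound.acid_pka, PLASMA_PH)
    lipid_p = (p * plasma.f_nl + (0.3 * p + 0.7) * plasma.f_np) / y_plasma
    albumin_binding = 1.0 / fu - 1.0 - lipid_p  # bound:unbound via albumin

    kps: dict[str, float] = {}
    for tissue in ALL_TISSUES:
        row = composition.row(tissue)
        x_iw = _x_term(compound.acid_pka, row.ph_ic)
        kpu = (
            row.f_water_ec
            + (x_iw / y_plasma) * row.f_water_ic
            + (p * row.f_nl + (0.3 * p + 0.7) * row.f_np) / y_plasma
            + albumin_binding * row.albumin_ratio
        )
        kps[tissue] = max(kpu * fu, 0.0) * compound.kp_scalar
    for tissue, value in compound.kp_overrides.items():
        if tissue not in kps:
            raise KeyError(f"override for unmodeled tissue {tissue!r}")
        kps[tissue] = value
    return kps


def fu_intracellular(compound: CompoundParams, tissue: str,
                     composition: TissueComposition) -> float:
    """Predicted unbound fraction in the intracellular water of ``tissue``.

    Composition-based: only the neutral species (Henderson–Hasselbalch at
    intracellular pH) associates with neutral lipid and phospholipid;
    binding capacity is expressed per volume of cell water:

        fuIW = 1 / (1 + (P*f_nl + (0.3P + 0.7)*f_np) / (f_iw * X))

    with X = 1 + 10**(pH_ic - pKa). The interstitial unbound fraction is
    not computed here — it is taken equal to plasma fu by assumption.
    """
    row = composition.row(tissue)
    if row.f_water_ic <= 0:
        raise ValueError(f"tissue {tissue!r} has no intracellular water")
    p = 10.0 ** compound.log_p
    x_iw = _x_term(compound.acid_pka, row.ph_ic)
    binding = (p * row.f_nl + (0.3 * p + 0.7) * row.f_np) / (row.f_water_ic * x_iw)
    return 1.0 / (1.0 + binding)


def compute_vss(kps: dict[str, float], volumes: dict[str, float],
                plasma_volume: float, blood_to_plasma: float,
                hematocrit: float, body_weight: float | None = None) -> float:
    """Steady-state volume of distribution (L/kg).

    Vss = [V_plasma + V_ery * E:P + sum_t Kp_t * V_t] / body weight, where
    the erythrocyte:plasma ratio E:P is derived from B/P and hematocrit via
    B/P = (1 - Hct) + Hct * E:P. Body weight defaults to the sum of tissue
    volumes plus blood (unit density).
    """
    if not 0 < hematocrit < 1:
        raise ValueError("hematocrit must be in (0, 1)")
    if any(v < 0 for v in volumes.values()) or plasma_volume < 0:
        raise ValueError("volumes must be >= 0")
    missing = set(volumes) - set(kps)
    if missing:
        raise KeyError(f"no Kp for tissues: {sorted(missing)}")
    e_to_p = max((blood_to_plasma - (1.0 - hematocrit)) / hematocrit, 0.0)
    v_ery = plasma_volume * hematocrit / (1.0 - hematocrit)
    if body_weight is None:
        body_weight = sum(volumes.values()) + plasma_volume + v_ery
    tissue_term = sum(kps[t] * v for t, v in volumes.items())
    return (plasma_volume + v_ery * e_to_p + tissue_term) / body_weight
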