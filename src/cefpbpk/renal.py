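"""Renal elimination.

Both packaged drugs are cleared exclusively by the kidney: glomerular
filtration of the unbound drug (fu * GFR) plus transporter-mediated tubular
secretion. Secretion is modeled at the whole-organ level: the per-cell
basolateral uptake intrinsic clearances (OAT1 + OAT3) are scaled by the
proximal-tubule cellularity and kidney mass, and folded into a well-stirred
organ model bounded by kidney blood flow. Renal OAT3 activity rises during
pregnancy following a published cubic in gestational age; OAT1 and MRP4 are
left unchanged. Apical efflux (MRP4) exceeds uptake for both drugs and
passive back-diffusion across the kidney cell is negligible, so uptake is
rate-limiting; an efflux-competition correction activates only in the
opposite regime. No tubular reabsorption (fu_urine = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

from .compound import CompoundParams
from .physiology import SubjectPhysiology

__all__ = [
    "KidneyScaling",
    "default_kidney_scaling",
    "oat3_pregnancy_fold",
    "secretion_clearance",
    "renal_clearance_total",
]


@dataclass(frozen=True)
class KidneyScaling:
    """Whole-organ scaling constants for per-cell intrinsic clearances."""

    proximal_tubule_cells_per_g: float = 60e6  # cells per g kidney
    kidney_mass: float = 300.0  # g, both kidneys
    q_kidney: float = 60.0  # L/h, kidney blood flow

    def __post_init__(self) -> None:
        if min(self.proximal_tubule_cells_per_g, self.kidney_mass,
               self.q_kidney) <= 0:
            raise ValueError("kidney scaling constants must be > 0")


def default_kidney_scaling(subject: SubjectPhysiology | None = None) -> KidneyScaling:
    """Standard scaling; kidney flow taken from the subject when given."""
    if subject is None:
        return KidneyScaling()
    return KidneyScaling(q_kidney=subject.tissue_flows["kidney"])


def oat3_pregnancy_fold(ga: float) -> float:
    """Fold-change in renal OAT3 activity at gestational age ``ga`` (weeks).

    1 * (1 + 0.195*GA - 0.0093*GA^2 + 0.0001154*GA^3); equals 1 at GA=0,
    peaks near the end of the first trimester (~2.2x) and relaxes to ~1.3x
    at term.
    """
    if ga < 0:
        raise ValueError("gestational age must be >= 0")
    return 1.0 * (1.0 + 0.195 * ga - 0.0093 * ga ** 2 + 0.0001154 * ga ** 3)


def _organ_clint(clint_ul_min_per_mcells: float, scaling: KidneyScaling) -> float:
    """Scale a per-cell intrinsic clearance (uL/min/1e6 cells) to L/h."""
    n_mcells = scaling.proximal_tubule_cells_per_g * scaling.kidney_mass / 1e6
    ul_min = clint_ul_min_per_mcells * n_mcells
    return ul_min * 60.0 / 1e6  # uL/min -> L/h


def secretion_clearance(compound: CompoundParams, scaling: KidneyScaling,
                        fu: float, ga: float = 0.0) -> float:
    """Tubular secretion clearance (L/h), well-stirred in kidney blood flow.

    Basolateral uptake = OAT1 + fold(ga) * OAT3 (the gestational fold applies
    to OAT3 only). When efflux capacity falls below uptake, secretion is
    attenuated by the efflux : (efflux + basolateral passive return)
    competition ratio.
    """
    renal = compound.renal
    uptake_percell = (renal.clint_oat1_uptake
                      + oat3_pregnancy_fold(ga) * renal.clint_oat3_uptake)
    if uptake_percell == 0:
        return 0.0
    clint_organ = _organ_clint(uptake_percell, scaling)
    efflux_percell = renal.clint_mrp4_efflux
    uptake_raw = renal.clint_oat1_uptake + renal.clint_oat3_uptake
    if efflux_percell < uptake_raw:
        clpd_basal_percell = renal.clpd_basal * 1000.0  # mL -> uL
        clint_organ *= efflux_percell / (efflux_percell + clpd_basal_percell)
    q = scaling.q_kidney
    return q * fu * clint_organ / (q + fu * clint_organ)


def renal_clearance_total(subject: SubjectPhysiology,
                          compound: CompoundParams) -> float:
    """Total renal (and systemic) clearance: fu*GFR + secretion, L/h."""
    scaling = default_kidney_scaling(subject)
    fu = compound.fu_plasma
    return fu * subject.gfr + secretion_clearance(
        compound, scaling, fu, ga=subject.gestational_age)
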