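"""Conversion of Vt and plasma tracer activity into tissue boron-10 (ppm).

The chain, linear throughout, is:

    T = P * Vt                     tissue tracer activity, kBq/ml
    M = T / S                      molar tracer concentration, mol/ml
    B = MW_B * M * 1e6             boron ppm at the tracer dose (1 g/ml tissue)
    H = B * (dose / I) * (MW_fbpa / MW_bpa)
                                   boron ppm at the therapeutic BPA-fructose dose

With the default constants (I = 0.00102 g, dose = 30 g, MW 226.9 / 389.3)
the H/B multiplier is ~17142.4, so the tissue ppm at the therapeutic dose is
simply Vt times the plasma ppm at the same time.
"""

from __future__ import annotations

from dataclasses import dataclass

from .input_function import PlasmaInput, evaluate_plasma
from .tac_data import StudyConfig, ValidationError

__all__ = [
    "BoronEstimate",
    "tissue_activity",
    "activity_to_molar",
    "molar_to_ppm",
    "scale_to_therapeutic",
    "therapeutic_multiplier",
    "ppm_to_activity",
    "estimate_tissue_boron",
]


@dataclass(frozen=True)
class BoronEstimate:
    """Boron-10 concentration in one VOI at one time point."""

    voi_name: str
    time_min: float
    tissue_activity_kBq_ml: float  # T
    molar_mol_ml: float  # M
    tracer_ppm: float  # B, at the tracer dose
    therapeutic_ppm: float  # H, at the therapeutic dose


def tissue_activity(P: float, V: float) -> float:
    """Tissue tracer activity T = P * Vt (kBq/ml)."""
    if P < 0 or V < 0:
        raise ValidationError("plasma activity and Vt must be non-negative")
    return P * V


def activity_to_molar(T: float, S: float) -> float:
    """Molar concentration M = T / S (mol/ml), S in kBq/mol."""
    if S <= 0:
        raise ValidationError("specific activity must be positive")
    return T / S


def molar_to_ppm(M: float, MW_B: float = 10.0) -> float:
    """Boron ppm B = MW_B * M * 1e6 (one boron atom per tracer molecule, 1 g/ml)."""
    if MW_B <= 0:
        raise ValidationError("boron molecular weight must be positive")
    return MW_B * M * 1e6


def scale_to_therapeutic(B: float, config: StudyConfig | None = None) -> float:
    """Scale tracer-dose ppm to the therapeutic dose: H = B * (dose/I) * (MWfbpa/MWbpa)."""
    config = config or StudyConfig()
    return B * therapeutic_multiplier(config)


def therapeutic_multiplier(config: StudyConfig | None = None) -> float:
    config = config or StudyConfig()
    return (config.therapeutic_dose_g / config.injected_dose_g) * (
        config.mw_fbpa / config.mw_bpa
    )


def ppm_to_activity(H: float, config: StudyConfig | None = None) -> float:
    """Invert the chain: therapeutic-dose ppm back to tracer activity (kBq/ml)."""
    config = config or StudyConfig()
    B = H / therapeutic_multiplier(config)
    M = B / (config.mw_boron * 1e6)
    return M * config.specific_activity_kBq_mol


def estimate_tissue_boron(
    vt: float,
    plasma,
    t: float,
    config: StudyConfig | None = None,
    voi_name: str = "",
) -> BoronEstimate:
    """Boron-10 ppm in a tissue with distribution volume ``vt`` at time ``t``.

    ``plasma`` is either a :class:`~fbpakin.input_function.PlasmaInput`
    (evaluated at ``t`` in kBq/ml) or a plasma boron ppm value at the
    therapeutic dose, in which case the linearity of the chain gives
    H_tissue = Vt * H_plasma directly.
    """
    config = config or StudyConfig()
    if t < 0:
        raise ValidationError("time must be non-negative")
    if vt < 0:
        raise ValidationError("Vt must be non-negative")
    if isinstance(plasma, PlasmaInput):
        P = evaluate_plasma(plasma, t)
    else:
        P = ppm_to_activity(float(plasma), config)
    T = tissue_activity(P, vt)
    M = activity_to_molar(T, config.specific_activity_kBq_mol)
    B = molar_to_ppm(M, config.mw_boron)
    H = scale_to_therapeutic(B, config)
    return BoronEstimate(voi_name, float(t), T, M, B, H)
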