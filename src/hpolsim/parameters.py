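"""Typed registry of the HPOL model parameters.

Every rate constant, clearance, volume of distribution, threshold, stage
boundary and delay of the model lives here as a named field with units.
Field names are ASCII normalisations of the published notation (e.g.
``alpha_mLH_E2`` for the stimulatory factor of delayed E2 on mLH synthesis,
``Cl_E2_S4`` for the stage-4 E2 secretion clearance); the ``UNITS`` and
``NOTATION`` tables record the unit string and the original symbol for
each field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

__all__ = [
    "ModelParameters",
    "ParameterPerturbation",
    "default_parameters",
    "apply_perturbation",
    "load_parameters",
    "save_parameters",
    "parameter_names",
    "UNITS",
    "NOTATION",
]


# name -> (default value, units, original symbol, description)
_TABLE: dict[str, tuple[float, str, str, str]] = {
    # --- pituitary ---
    "ks_mFSH": (0.05895, "(pg/ug RNA)/hr", "k_s,mFSH", "basal mFSH synthesis rate"),
    "alpha_mFSH_GnRH": (2.0917, "unitless", "alpha_mFSH,GnRH", "GnRH stimulation of mFSH synthesis"),
    "kd_mFSH": (0.2446, "1/hr", "k_d,mFSH", "mFSH degradation rate"),
    "ks_mLH": (0.0512, "(pg/ug RNA)/hr", "k_s,mLH", "basal mLH synthesis rate"),
    "alpha_mLH_GnRH": (0.01, "unitless", "alpha_mLH,GnRH", "GnRH stimulation of mLH synthesis"),
    "alpha_mLH_E2": (4.15, "ml/ng", "alpha_mLH,E2", "delayed-E2 stimulation of mLH synthesis"),
    "kd_mLH": (0.1046, "1/hr", "k_d,mLH", "mLH degradation rate"),
    "ks_LH": (1.004, "(pg/ug RNA)^-1 ng/mg pituitary/hr", "k_s,LH", "LH synthesis rate from mLH"),
    "kd_LH": (0.06, "1/hr", "k_d,LH", "pituitary LH degradation rate"),
    "kr_LH": (66700.0, "1/hr", "k_r,LH", "LH release rate from pituitary into blood"),
    "T_E2_LH": (23.0, "ng/ml", "T_E2,LH", "E2 threshold permitting LH release"),
    "n_E2_LH": (9.0, "unitless", "n_E2", "Hill exponent of the E2 gate on LH release"),
    "N_E2": (36.78, "ml/mg pituitary", "N_E2", "E2-to-D2-receptor conversion in the release block"),
    "N_DHP": (2.8, "ml/mg pituitary", "N_DHP", "DHP-to-D2-receptor conversion in the release block"),
    "w_Pit": (15.0, "mg/kg", "w_Pit", "pituitary weight"),
    # --- plasma pharmacokinetics ---
    "V_FSH": (156.0, "ml/kg", "V_FSH", "FSH volume of distribution"),
    "ks_FSH": (0.0138, "(pg/ug RNA)^-1 ng/mg pituitary/hr", "k_s,FSH", "FSH appearance rate in blood"),
    "Cl_FSH": (1.7372, "ml/hr/kg", "Cl_FSH", "FSH plasma clearance"),
    "V_LH": (156.0, "ml/kg", "V_LH", "LH volume of distribution"),
    "Cl_LH": (1.7372, "ml/hr/kg", "Cl_LH", "LH plasma clearance"),
    "V_E2": (261.0, "ml/kg", "V_E2", "E2 volume of distribution"),
    "Cl_E2": (22.0, "ml/hr/kg", "Cl_E2", "E2 plasma clearance"),
    "V_DHP": (261.0, "ml/kg", "V_DHP", "DHP volume of distribution"),
    "Cl_DHP": (57.0, "ml/hr/kg", "Cl_DHP", "DHP plasma clearance"),
    "V_VTGP": (240.0, "ml/kg", "V_VTGP", "plasma VTG volume of distribution"),
    "Cl_VTG_trans": (42.2, "ml/hr/kg", "Cl_VTG,trans", "plasma<->peripheral VTG transfer clearance"),
    "Cl_VTG_Seq": (170.0, "ml/hr/kg", "Cl_VTG,Seq", "basal ovarian VTG sequestration clearance"),
    "T_Seq_FSH": (13.7, "ng/ml", "T_Seq,FSH", "FSH threshold stimulating VTG sequestration"),
    "Cl_VTG": (29.3, "ml/hr/kg", "Cl_VTG", "total-body VTG clearance"),
    "V_VTGN": (318.0, "ml/kg", "V_VTGN", "peripheral VTG volume of distribution"),
    # --- ovary ---
    "k_E2": (0.0053, "ng/hr/follicle", "k_E2", "basal per-follicle E2 production"),
    "n_oocyte": (2500.0, "follicle/kg", "n_oocyte", "oocyte follicles per kg of fish"),
    "Cl_E2_S2": (0.00057, "ml/hr/follicle", "Cl_E2,S2", "FSH-driven E2 secretion clearance, stage 2"),
    "Cl_E2_S3": (0.00057, "ml/hr/follicle", "Cl_E2,S3", "FSH-driven E2 secretion clearance, stage 3"),
    "Cl_E2_S4": (0.0027, "ml/hr/follicle", "Cl_E2,S4", "FSH-driven E2 secretion clearance, stage 4"),
    "Cl_E2_S5": (0.0561, "ml/hr/follicle", "Cl_E2,S5", "FSH-driven E2 secretion clearance, stage 5"),
    "Cl_E2_S6": (0.0617, "ml/hr/follicle", "Cl_E2,S6", "FSH-driven E2 secretion clearance, stage 6"),
    "Cl_DHP_S2": (0.0003, "ml/hr/follicle", "Cl_DHP,S2", "LH-driven DHP secretion clearance, stage 2"),
    "Cl_DHP_S3": (0.0003, "ml/hr/follicle", "Cl_DHP,S3", "LH-driven DHP secretion clearance, stage 3"),
    "Cl_DHP_S4": (0.0003, "ml/hr/follicle", "Cl_DHP,S4", "LH-driven DHP secretion clearance, stage 4"),
    "Cl_DHP_S5": (0.0003, "ml/hr/follicle", "Cl_DHP,S5", "LH-driven DHP secretion clearance, stage 5"),
    "Cl_DHP_S6": (0.3, "ml/hr/follicle", "Cl_DHP,S6", "LH-driven DHP secretion clearance, stage 6"),
    "Cl_DHP_SFOM": (0.79, "ml/hr/follicle", "Cl_DHP,SFOM", "LH-driven DHP secretion clearance, FOM"),
    "k_NV_OAvg": (0.00067, "mm/hr", "k_NV,OAvg", "non-vitellogenic follicle growth rate"),
    "k_V_OAvg": (2.19e-7, "mm/mg", "k_V,OAvg", "growth per mg VTG sequestered per follicle"),
    "alpha_OVar_S1": (0.0214, "mm^2", "alpha_OVar,S1", "maximal diameter variance, stage 1"),
    "alpha_OVar_S2": (0.0433, "mm^2", "alpha_OVar,S2", "maximal diameter variance, stage 2"),
    "alpha_OVar_S3": (0.0748, "mm^2", "alpha_OVar,S3", "maximal diameter variance, stage 3"),
    "alpha_OVar_S4": (0.0907, "mm^2", "alpha_OVar,S4", "maximal diameter variance, stage 4"),
    "alpha_OVar_S5": (0.0338, "mm^2", "alpha_OVar,S5", "maximal diameter variance, stage 5"),
    "alpha_OVar_S6": (0.014, "mm^2", "alpha_OVar,S6", "maximal diameter variance, stage 6"),
    "alpha_OVar_SFOM": (0.0067, "mm^2", "alpha_OVar,SFOM", "maximal diameter variance, FOM"),
    "s_1": (0.2, "mm", "s_1", "diameter dividing stages 1 and 2"),
    "s_2": (0.6, "mm", "s_2", "diameter dividing stages 2 and 3 (VTG uptake begins)"),
    "s_3": (1.17, "mm", "s_3", "diameter dividing stages 3 and 4"),
    "s_4": (1.69, "mm", "s_4", "diameter dividing stages 4 and 5"),
    "s_5": (3.4, "mm", "s_5", "diameter dividing stages 5 and 6"),
    "s_6": (5.3, "mm", "s_6", "diameter dividing stage 6 and FOM"),
    "FOM_final": (0.98, "unitless", "FOM_final", "FOM proportion required for ovulation"),
    "DHP_final": (120.0, "ng/ml", "DHP_final", "DHP concentration required for ovulation"),
    # --- liver ---
    "w_L": (15.0, "g/kg", "w_L", "liver weight"),
    "ks_mR": (30.0, "(pg/ug RNA)/hr", "k_s,mR", "basal mR synthesis rate"),
    "alpha_mR_ER": (0.0667, "g liver/fmol", "alpha_mR,ER", "ER stimulation of mR synthesis"),
    "kd_mR": (0.5, "1/hr", "k_d,mR", "mR degradation rate"),
    "ks_R": (0.0113, "(pg/ug RNA)^-1 fmol/g liver/hr", "k_s,R", "receptor synthesis rate from mR"),
    "kd_R": (0.466, "1/hr", "k_d,R", "free receptor degradation rate"),
    "kon_ER": (0.826, "(ng/ml)^-1 1/hr", "k_on,ER", "E2-receptor association rate"),
    "koff_ER": (0.347, "1/hr", "k_off,ER", "E2-receptor dissociation rate"),
    "kd_ER": (0.0766, "1/hr", "k_d,ER", "E2-receptor complex degradation rate"),
    "ks_mVTG": (6.93e-5, "(pg/ug RNA)/hr", "k_s,mVTG", "basal mVTG synthesis rate"),
    "alpha_mVTG_ER": (5.456e6, "g liver/fmol", "alpha_mVTG,ER", "ER stimulation of mVTG synthesis"),
    "kd_mVTG": (0.00462, "1/hr", "k_d,mVTG", "mVTG degradation rate"),
    "ks_VTG": (9.02e-6, "mg/g liver/hr", "k_s,VTG", "VTG synthesis rate"),
    "N_mVTG": (1000.0, "pg/ug RNA", "N_mVTG", "nondimensionalising scale for mVTG"),
    "gamma": (2.48, "unitless", "gamma", "translational amplification exponent for VTG"),
    "kr_VTG": (7.87, "1/hr", "k_r,VTG", "VTG release rate from liver into plasma"),
    # --- transit-compartment delays ---
    "D_FSH_E2": (875.0, "hr", "D_FSH,E2", "delay of E2 synthesis behind plasma FSH"),
    "D_E2_mLH": (240.0, "hr", "D_E2,mLH", "delay of mLH synthesis behind plasma E2"),
    "D_LH_DHP": (72.0, "hr", "D_LH,DHP", "delay of DHP synthesis behind plasma LH"),
}

UNITS: Mapping[str, str] = {k: v[1] for k, v in _TABLE.items()}
NOTATION: Mapping[str, str] = {k: v[2] for k, v in _TABLE.items()}
DESCRIPTIONS: Mapping[str, str] = {k: v[3] for k, v in _TABLE.items()}

_STAGE_BOUNDS = ("s_1", "s_2", "s_3", "s_4", "s_5", "s_6")


def parameter_names() -> tuple[str, ...]:
    """All parameter field names, in registry order."""
    return tuple(_TABLE)


@dataclass(frozen=True)
class ModelParameters:
    """Immutable container of the full parameter set.

    Construct with :func:`default_parameters` for the published values, or
    ``dataclasses.replace`` / :func:`apply_perturbation` for variants.
    Validation enforces positivity of every entry, strict ordering of the
    stage boundaries and a FOM_final proportion in (0, 1].
    """

    # fields are generated below to keep one source of truth

    def validate(self) -> None:
        for name in _TABLE:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ValueError(f"parameter {name} must be a positive number, got {v!r}")
        bounds = [getattr(self, s) for s in _STAGE_BOUNDS]
        if not all(a < b for a, b in zip(bounds, bounds[1:])):
            raise ValueError(f"stage boundaries must be strictly increasing, got {bounds}")
        if not 0 < self.FOM_final <= 1:
            raise ValueError(f"FOM_final must lie in (0, 1], got {self.FOM_final}")

    def __post_init__(self) -> None:
        self.validate()

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in _TABLE}

    def stage_boundaries(self) -> tuple[float, ...]:
        """(s_1, ..., s_6) in mm."""
        return tuple(getattr(self, s) for s in _STAGE_BOUNDS)

    def stage_variances(self) -> tuple[float, ...]:
        """Maximal diameter variances (stage 1..6, FOM) in mm^2."""
        return (
            self.alpha_OVar_S1,
            self.alpha_OVar_S2,
            self.alpha_OVar_S3,
            self.alpha_OVar_S4,
            self.alpha_OVar_S5,
            self.alpha_OVar_S6,
            self.alpha_OVar_SFOM,
        )

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.to_dict().items())


# attach the generated fields (single source of truth is _TABLE)
ModelParameters = dataclass(frozen=True)(
    type(
        "ModelParameters",
        (ModelParameters,),
        {"__annotations__": {name: float for name in _TABLE}},
    )
)
ModelParameters.__doc__ = ModelParameters.__mro__[1].__doc__
ModelParameters.__module__ = __name__


@dataclass(frozen=True)
class ParameterPerturbation:
    """Multiplicative perturbation: parameter name -> positive factor."""

    multipliers: Mapping[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.multipliers) - set(_TABLE)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        bad = {k: v for k, v in self.multipliers.items() if not v > 0}
        if bad:
            raise ValueError(f"perturbation factors must be positive: {bad}")


def default_parameters() -> ModelParameters:
    """The published baseline parameter set."""
    return ModelParameters(**{name: v[0] for name, v in _TABLE.items()})


def apply_perturbation(
    base: ModelParameters, pert: ParameterPerturbation | Mapping[str, float]
) -> ModelParameters:
    """Return a new parameter set with each named entry scaled by its factor.

    The base is untouched; invariants are re-validated on construction, so
    a perturbation that, e.g., re-orders the stage boundaries raises.
    """
    if not isinstance(pert, ParameterPerturbation):
        pert = ParameterPerturbation(dict(pert))
    values = base.to_dict()
    for name, factor in pert.multipliers.items():
        values[name] = values[name] * factor
    return ModelParameters(**values)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a tab-separated parameter file: name, value, units, note."""
    path = Path(path)
    lines = ["name\tvalue\tunits\tnote"]
    for name in _TABLE:
        lines.append(
            f"{name}\t{getattr(params, name)!r}\t{UNITS[name]}\t{DESCRIPTIONS[name]}"
        )
    path.write_text("\n".join(lines) + "\n")


def load_parameters(path: str | Path) -> ModelParameters:
    """Read a parameter file written by :func:`save_parameters`.

    Every registry entry must be present exactly once with matching units;
    errors name the offending row.
    """
    path = Path(path)
    values: dict[str, float] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["name", "value", "units"]:
            raise ValueError(f"{path}: expected columns name/value/units, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            name, raw, units = parts[0], parts[1], parts[2]
            if name not in _TABLE:
                raise ValueError(f"{path}:{lineno}: unknown parameter {name!r}")
            if name in values:
                raise ValueError(f"{path}:{lineno}: duplicate parameter {name!r}")
            if units != UNITS[name]:
                raise ValueError(
                    f"{path}:{lineno}: unit mismatch for {name}: file says {units!r}, "
                    f"expected {UNITS[name]!r}"
                )
            try:
                values[name] = float(raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable value {raw!r} for {name}") from exc
    missing = set(_TABLE) - set(values)
    if missing:
        raise ValueError(f"{path}: missing parameter(s): {sorted(missing)}")
    return ModelParameters(**values)


def packaged_parameter_file() -> Path:
    """Path of the parameter table shipped with the package."""
    return Path(resources.files("hpolsim").joinpath("data/parameters.tsv"))
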