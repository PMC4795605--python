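"""Model parameters and persistent-AF (PeAF) ionic remodeling.

The cell model is the Courtemanche–Ramirez–Nattel (CRN) human atrial
action-potential model (Am J Physiol 1998, 275:H301–H321).  Twenty of its
parameters — the maximal conductances, pump/exchanger rates and SR-handling
constants that the sensitivity analysis perturbs — live in
:class:`ParameterSet`; everything else (temperatures, external ion
concentrations, cell geometry, buffer constants) is a fixed model constant
in this module.

PeAF electrical remodeling is expressed as a small set of multiplicative
factors on those parameters (:class:`RemodelingSpec`): I_CaL down 50% or
70%, I_K1 up 100%, I_to down 70%, I_Kur down 50%, I_Na down 10%, NCX up
40% and the maximal SR-uptake-compartment Ca2+ down 20%.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np

# ---------------------------------------------------------------------------
# Fixed physical and model constants (CRN 1998, Table 1 of that paper)
# ---------------------------------------------------------------------------

R_GAS = 8.3143          # J / (mol K)
TEMP = 310.0            # K
FARADAY = 96.4867       # C / mmol
RTF = R_GAS * TEMP / FARADAY  # mV

CM = 100.0              # pF, whole-cell capacitance
CM_SPECIFIC = 1.0       # uF/cm^2, membrane capacitance per unit area (tissue)

V_CELL = 20100.0        # um^3
V_I = 13668.0           # um^3, intracellular (myoplasm) volume
V_UP = 1109.52          # um^3, SR uptake compartment (network SR)
V_REL = 96.48           # um^3, SR release compartment (junctional SR)

NA_O = 140.0            # mM extracellular Na+
K_O = 5.4               # mM extracellular K+
CA_O = 1.8              # mM extracellular Ca2+

K_Q10 = 3.0             # temperature scaling of Ito / IKur gate kinetics

# Na+/K+ pump half-saturation constants
K_M_NAI = 10.0          # mM, intracellular Na+
K_M_KO = 1.5            # mM, extracellular K+

# Sarcolemmal Ca pump half-saturation
K_M_PCA = 0.0005        # mM

# Ca2+ buffers
CMDN_MAX = 0.05         # mM calmodulin
TRPN_MAX = 0.07         # mM troponin
CSQN_MAX = 10.0         # mM calsequestrin
KM_CMDN = 0.00238       # mM
KM_TRPN = 0.0005        # mM
KM_CSQN = 0.8           # mM

TAU_TR = 180.0          # ms, uptake->release transfer time constant
TAU_U = 8.0             # ms
TAU_F_CA = 2.0          # ms

#: Canonical ordering of the 20 perturbable parameters (conductance table order).
PARAM_NAMES: tuple[str, ...] = (
    "G_Na", "G_bNa", "G_CaL", "G_bCa", "G_to", "G_K1", "G_Kr", "G_Ks",
    "G_Kur_scale", "I_NaK_max", "I_NaCa_max", "K_mCa", "K_mNa", "gamma",
    "K_sat", "Ca_up_max", "I_up_max", "k_rel", "K_up", "I_pCa_max",
)


@dataclass(frozen=True)
class ParameterSet:
    """The 20 perturbable CRN model parameters.

    Units: conductances in nS/pF; I_NaK_max and I_pCa_max in pA/pF;
    I_NaCa_max in pA/pF; half-saturation constants in mM; gamma and K_sat
    dimensionless; Ca_up_max in mM; I_up_max in mM/ms; k_rel in 1/ms.

    Note on the NCX constants: K_mNa = 87.5 mM is the extracellular-Na+
    half-saturation and K_mCa = 1.38 mM the extracellular-Ca2+
    half-saturation, following the original CRN assignment (the two labels
    are occasionally seen swapped in the secondary literature; the values
    themselves are unambiguous).
    """

    G_Na: float = 7.8
    G_bNa: float = 0.0006744375
    G_CaL: float = 0.1238
    G_bCa: float = 0.00113
    G_to: float = 0.1652
    G_K1: float = 0.09
    G_Kr: float = 0.0294
    G_Ks: float = 0.129
    G_Kur_scale: float = 1.0
    I_NaK_max: float = 0.60
    I_NaCa_max: float = 1600.0
    K_mCa: float = 1.38
    K_mNa: float = 87.5
    gamma: float = 0.35
    K_sat: float = 0.1
    Ca_up_max: float = 15.0
    I_up_max: float = 0.005
    k_rel: float = 30.0
    K_up: float = 0.00092
    I_pCa_max: float = 0.275

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"parameter {name} is not finite: {value!r}")
        positive = [n for n in PARAM_NAMES if n != "gamma"]
        for name in positive:
            if getattr(self, name) <= 0.0:
                raise ValueError(f"parameter {name} must be strictly positive")

    def to_vector(self) -> np.ndarray:
        """Parameter values as a float array in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ParameterSet":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected shape ({len(PARAM_NAMES)},), got {vec.shape}")
        return cls(**dict(zip(PARAM_NAMES, vec.tolist())))

    def scaled(self, factors: Mapping[str, float] | np.ndarray) -> "ParameterSet":
        """Return a copy with parameters multiplied by the given factors.

        ``factors`` is either a name->factor mapping (missing names are
        untouched) or a length-20 vector in :data:`PARAM_NAMES` order.
        """
        if isinstance(factors, Mapping):
            unknown = set(factors) - set(PARAM_NAMES)
            if unknown:
                raise KeyError(f"unknown parameter names: {sorted(unknown)}")
            updates = {n: getattr(self, n) * f for n, f in factors.items()}
            return dataclasses.replace(self, **updates)
        return ParameterSet.from_vector(self.to_vector() * np.asarray(factors, dtype=float))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ParameterSet":
        return cls(**{k: float(v) for k, v in d.items()})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# PeAF remodeling
# ---------------------------------------------------------------------------

#: Fractional change of each remodeled parameter in the full PeAF condition.
#: G_CaL is -50% in PeAF1 and -70% in PeAF2.
PEAF_FRACTIONS: dict[str, float] = {
    "G_Na": -0.10,
    "G_to": -0.70,
    "G_Kur_scale": -0.50,
    "Ca_up_max": -0.20,
    "G_K1": +1.00,
    "I_NaCa_max": +0.40,
}

#: variant tag -> name -> fractional change
VARIANT_FRACTIONS: dict[str, dict[str, float]] = {
    "control": {},
    "ICaL50": {"G_CaL": -0.50},
    "ICaL70": {"G_CaL": -0.70},
    "IK1x2": {"G_K1": +1.00},
    "PeAF1": {**PEAF_FRACTIONS, "G_CaL": -0.50},
    "PeAF2": {**PEAF_FRACTIONS, "G_CaL": -0.70},
}

VARIANTS: tuple[str, ...] = tuple(VARIANT_FRACTIONS)


@dataclass(frozen=True)
class RemodelingSpec:
    """Named multiplicative remodeling of a :class:`ParameterSet`."""

    variant: str = "control"

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_FRACTIONS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )

    @property
    def fractions(self) -> dict[str, float]:
        return dict(VARIANT_FRACTIONS[self.variant])

    def to_dict(self) -> dict[str, object]:
        return {"variant": self.variant, "fractions": self.fractions}


def apply_remodeling(base: ParameterSet, spec: RemodelingSpec | str) -> ParameterSet:
    """Apply a PeAF remodeling variant: each named parameter is multiplied
    by (1 + fractional change); everything else is untouched."""
    if isinstance(spec, str):
        spec = RemodelingSpec(spec)
    return base.scaled({n: 1.0 + f for n, f in spec.fractions.items()})
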