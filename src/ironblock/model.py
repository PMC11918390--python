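"""Core reaction network: species, compartments, rate laws and the ODE RHS.

The model tracks 13 chemical species in five compartments (lumen, cytoplasm
and blood are three-dimensional; the apical and basal membranes are
two-dimensional) connected by 19 reactions:

* DMT1 apical iron import and its LIP-sensitive endocytic cycling,
* a six-reaction ferritin module (oxidation of labile iron to a di-ferric
  intermediate, its reduction, nucleation and mineralization into the ferritin
  core, and release/degradation tied to ferritin turnover),
* FPN basolateral export and its inactivation by plasma iron (the model's
  stand-in for hepcidin-driven FPN degradation),
* IRPs interconversion and IRPs-repressed ferritin expression,
* mass-action plasma sequestration, basal uptake and paracellular leak.

The ODE state is the vector of extensive species *amounts* (mol).  Each rate
law is evaluated on intensive values (mol/L, or mol/cm^2 for the membrane
transporters) and converted to an extensive flux (mol/s) by the size of the
compartment whose species leads the rate law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig

__all__ = [
    "SPECIES", "N_SPECIES", "REACTIONS", "SPECIES_COMPARTMENT",
    "IRON_ATOMS", "STOICHIOMETRY", "Model", "RateLawError",
]

#: canonical species ordering of the state vector
SPECIES = (
    "Fe_lumen", "LIP", "DFP", "core", "FT",
    "DMT1_active", "DMT1_cytoplasm", "FPN_active", "FPN_inactive",
    "IRPs_active", "IRPs_inactive", "Fe_blood", "Fe_body",
)
N_SPECIES = len(SPECIES)
IDX = {name: i for i, name in enumerate(SPECIES)}

SPECIES_COMPARTMENT = {
    "Fe_lumen": "lumen",
    "LIP": "cytoplasm",
    "DFP": "cytoplasm",
    "core": "cytoplasm",
    "FT": "cytoplasm",
    "DMT1_active": "apical_membrane",
    "DMT1_cytoplasm": "cytoplasm",
    "FPN_active": "basal_membrane",
    "FPN_inactive": "cytoplasm",
    "IRPs_active": "cytoplasm",
    "IRPs_inactive": "cytoplasm",
    "Fe_blood": "blood",
    "Fe_body": "blood",   # sink pool accounted in the blood compartment
}

#: iron atoms carried per molecule (DFP is a di-ferric intermediate)
IRON_ATOMS = {
    "Fe_lumen": 1, "LIP": 1, "DFP": 2, "core": 1, "FT": 0,
    "DMT1_active": 0, "DMT1_cytoplasm": 0, "FPN_active": 0, "FPN_inactive": 0,
    "IRPs_active": 0, "IRPs_inactive": 0, "Fe_blood": 1, "Fe_body": 1,
}

REACTIONS = (
    "dmt1_endocytosis_free", "dmt1_endocytosis_lip", "dmt1_fusion",
    "dmt1_iron_transport",
    "oxidation", "reduction", "nucleation", "mineralization",
    "ft_core_release", "ft_degradation",
    "fpn_inactivation", "fpn_activation", "fpn_iron_transport",
    "irps_inactivation", "irps_activation", "ft_expression",
    "body_sequestration", "basal_uptake", "paracellular",
)
RIDX = {name: i for i, name in enumerate(REACTIONS)}

# species x reaction stoichiometry.  Iron bookkeeping: oxidation consumes
# 2 LIP per DFP; nucleation consumes 2 DFP and produces 4 core;
# mineralization converts one DFP into 2 core.
_STOICH = {
    "dmt1_endocytosis_free": {"DMT1_active": -1, "DMT1_cytoplasm": +1},
    "dmt1_endocytosis_lip": {"DMT1_active": -1, "DMT1_cytoplasm": +1},
    "dmt1_fusion": {"DMT1_cytoplasm": -1, "DMT1_active": +1},
    "dmt1_iron_transport": {"Fe_lumen": -1, "LIP": +1},
    "oxidation": {"LIP": -2, "DFP": +1},
    "reduction": {"DFP": -1, "LIP": +2},
    "nucleation": {"DFP": -2, "core": +4},
    "mineralization": {"DFP": -1, "core": +2},
    "ft_core_release": {"core": -1, "LIP": +1},
    "ft_degradation": {"FT": -1},
    "fpn_inactivation": {"FPN_active": -1, "FPN_inactive": +1},
    "fpn_activation": {"FPN_inactive": -1, "FPN_active": +1},
    "fpn_iron_transport": {"LIP": -1, "Fe_blood": +1},
    "irps_inactivation": {"IRPs_active": -1, "IRPs_inactive": +1},
    "irps_activation": {"IRPs_inactive": -1, "IRPs_active": +1},
    "ft_expression": {"FT": +1},
    "body_sequestration": {"Fe_blood": -1, "Fe_body": +1},
    "basal_uptake": {"Fe_blood": -1, "LIP": +1},
    "paracellular": {"Fe_lumen": -1, "Fe_blood": +1},
}

STOICHIOMETRY = np.zeros((N_SPECIES, len(REACTIONS)))
for _r, _changes in _STOICH.items():
    for _s, _c in _changes.items():
        STOICHIOMETRY[IDX[_s], RIDX[_r]] = _c


class RateLawError(RuntimeError):
    """A rate law produced a non-finite flux; carries the reaction name."""


def _hill(x: float, K: float, n: float) -> float:
    """Saturating Hill fraction x^n / (K^n + x^n), safe at x = 0."""
    if x <= 0.0:
        return 0.0
    xn = x ** n
    return xn / (K ** n + xn)


@dataclass
class Model:
    """Compiled model: rate constants and compartment sizes bound to arrays.

    Parameters are taken from a :class:`~ironblock.config.ModelConfig`; the
    instance is immutable in use (rebuild after changing the config).
    """

    config: ModelConfig

    def __post_init__(self) -> None:
        c = self.config
        self.sizes = dict(c.compartments)
        #: per-species compartment size, for amount <-> intensive conversion
        self.species_size = np.array(
            [self.sizes[SPECIES_COMPARTMENT[s]] for s in SPECIES])
        r = c.rates
        self._p = {k: dict(v) for k, v in r.items()}
        # scaling compartment size per reaction (leading-species convention)
        self._scale = np.array([
            self.sizes["apical_membrane"],   # dmt1_endocytosis_free
            self.sizes["apical_membrane"],   # dmt1_endocytosis_lip
            self.sizes["cytoplasm"],         # dmt1_fusion
            self.sizes["apical_membrane"],   # dmt1_iron_transport
            self.sizes["cytoplasm"],         # oxidation
            self.sizes["cytoplasm"],         # reduction
            self.sizes["cytoplasm"],         # nucleation
            self.sizes["cytoplasm"],         # mineralization
            self.sizes["cytoplasm"],         # ft_core_release
            self.sizes["cytoplasm"],         # ft_degradation
            self.sizes["basal_membrane"],    # fpn_inactivation
            self.sizes["cytoplasm"],         # fpn_activation
            self.sizes["basal_membrane"],    # fpn_iron_transport
            self.sizes["cytoplasm"],         # irps_inactivation
            self.sizes["cytoplasm"],         # irps_activation
            self.sizes["cytoplasm"],         # ft_expression
            self.sizes["blood"],             # body_sequestration
            self.sizes["blood"],             # basal_uptake
            1.0,                             # paracellular (handled per term)
        ])

    # -- state helpers ---------------------------------------------------

    def initial_amounts(self) -> np.ndarray:
        """Initial state vector (mol) from the configured intensive values."""
        x = np.array([self.config.initial[s] for s in SPECIES])
        return x * self.species_size

    def intensive(self, amounts: np.ndarray) -> np.ndarray:
        """Intensive values (M or mol/cm^2) from amounts."""
        return np.asarray(amounts) / self.species_size

    def amounts_from_intensive(self, intensive: np.ndarray) -> np.ndarray:
        return np.asarray(intensive) * self.species_size

    def atoms_per_core(self, amounts: np.ndarray) -> float:
        """Average iron atoms per ferritin cage, clipped to [0, capacity]."""
        ft = amounts[IDX["FT"]]
        if ft <= 0.0:
            return 0.0
        cap = self._p["mineralization"]["capacity"]
        return float(np.clip(amounts[IDX["core"]] / ft, 0.0, cap))

    def total_iron(self, amounts: np.ndarray) -> float:
        """Total iron atoms (mol of Fe) across all species."""
        w = np.array([IRON_ATOMS[s] for s in SPECIES], dtype=float)
        return float(np.dot(w, amounts))

    # -- rate laws -------------------------------------------------------

    def fluxes(self, amounts: np.ndarray) -> np.ndarray:
        """All 19 extensive reaction fluxes (mol/s) at the given state.

        Species amounts are clipped at zero before evaluating the rate laws,
        so small negative integrator excursions do not produce spurious
        negative fluxes.
        """
        x = np.maximum(np.asarray(amounts, dtype=float), 0.0) / self.species_size
        p = self._p
        fe_lum = x[IDX["Fe_lumen"]]
        lip = x[IDX["LIP"]]
        dfp = x[IDX["DFP"]]
        core = x[IDX["core"]]
        ft = x[IDX["FT"]]
        d_act = x[IDX["DMT1_active"]]
        d_cyt = x[IDX["DMT1_cytoplasm"]]
        f_act = x[IDX["FPN_active"]]
        f_in = x[IDX["FPN_inactive"]]
        i_act = x[IDX["IRPs_active"]]
        i_in = x[IDX["IRPs_inactive"]]
        fe_b = x[IDX["Fe_blood"]]

        v = np.empty(len(REACTIONS))

        q = p["dmt1_endocytosis_free"]
        v[0] = q["k_cat"] * d_act
        q = p["dmt1_endocytosis_lip"]
        v[1] = q["k_cat"] * d_act * _hill(lip, q["K_m"], q["n"])
        q = p["dmt1_fusion"]
        v[2] = q["k_cat"] * d_cyt
        q = p["dmt1_iron_transport"]
        v[3] = q["k_cat"] * d_act * fe_lum / (q["K_m"] + fe_lum)

        q = p["oxidation"]
        v[4] = (q["k_cat"] * (q["H"] + q["rO"]) / (24.0 + q["rO"])
                * ft * _hill(lip, q["K_m"], q["n"]))
        v[5] = p["reduction"]["k_deg"] * dfp
        q = p["nucleation"]
        v[6] = (q["k_cat"] * dfp * dfp * ft
                * (q["L"] + q["rN"]) / (24.0 + q["rN"])
                * (1.0 - _hill(core, q["K_i"], q["n"])))
        q = p["mineralization"]
        cap = q["capacity"]
        apc = min(core / ft, cap) if ft > 0.0 else 0.0
        v[7] = (q["k_cat"] * core * dfp / (q["K_m"] + dfp)
                * (1.0 - _hill(core, q["K_i"], q["n"]))
                * (cap ** q["m"] - apc ** q["m"]) / cap ** q["m"])
        # core release: k_deg * (core/FT) * FT, which reduces to k_deg * core
        # including in the FT -> 0 limit
        v[8] = p["ft_core_release"]["k_deg"] * core
        v[9] = p["ft_degradation"]["k_deg"] * ft

        q = p["fpn_inactivation"]
        v[10] = q["k_cat"] * f_act * _hill(fe_b, q["K_m"], q["n"])
        v[11] = p["fpn_activation"]["k_cat"] * f_in
        q = p["fpn_iron_transport"]
        v[12] = q["k_cat"] * f_act * lip / (q["K_m"] + lip)

        v[13] = p["irps_inactivation"]["k_cat"] * i_act * lip
        v[14] = p["irps_activation"]["k_cat"] * i_in
        q = p["ft_expression"]
        v[15] = q["k_cat"] * (1.0 - _hill(i_act, q["K_m"], q["n"]))

        v[16] = p["body_sequestration"]["k_cat"] * fe_b
        v[17] = p["basal_uptake"]["k_cat"] * fe_b

        q = p["paracellular"]
        v[18] = (q["k_for"] * fe_lum * self.sizes["lumen"]
                 - q["k_rev"] * fe_b * self.sizes["blood"])

        v *= self._scale
        return v

    def rhs(self, t: float, amounts: np.ndarray,
            clamp_mask: np.ndarray | None = None) -> np.ndarray:
        """Amount derivatives (mol/s); clamped species get derivative zero."""
        v = self.fluxes(amounts)
        if not np.all(np.isfinite(v)):
            bad = [REACTIONS[i] for i in np.flatnonzero(~np.isfinite(v))]
            raise RateLawError(f"non-finite flux in reaction(s) {bad} at t={t}")
        dx = STOICHIOMETRY @ v
        if clamp_mask is not None:
            dx = np.where(clamp_mask, 0.0, dx)
        return dx
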