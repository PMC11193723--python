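"""Reduced kinetic model of single-neuron energy metabolism.

The model tracks the central ATP-producing pathways of a neuron in two
compartments (cytosol, mitochondrion): glucose uptake (GLUT), glycolysis
lumped into an ATP-investing and an ATP/NADH-producing stage, reversible
lactate dehydrogenase (LDHA/LDHB), H+-coupled lactate exchange with the
extracellular space (MCT2), pyruvate oxidation plus the citric acid cycle
as one Ca2+-modulated flux, the malate-aspartate and glycerol-3-phosphate
shuttles coupling the cytosolic and mitochondrial NAD pools, NADH- and
FADH2-fed proton pumping by the respiratory chain with saturable O2
dependence, the proton-motive-force-driven ATP synthase, the adenine
nucleotide translocator, a proton leak, and mitochondrial Ca2+
uniporter/exchanger dynamics.  Energy demand enters as a Michaelis-Menten
ATPase, v = k*ATP/(ATP + Km); raising the rate constant k emulates raised
neuronal activity.

Units: concentrations mM (mitochondrial Ca2+ in uM), time s, membrane
potential mV, extracellular O2 in mmHg.  Cytosolic ATP is the model's
proxy for neuronal energy fitness; a steady state below 1 mM is read as
energy deficit.

All conserved pools (adenine and NAD per compartment, total FAD) are exact
by construction: the integrator works on a reduced state vector and the
partner species are reconstructed from the pool totals.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields, asdict, replace
from typing import Iterable, Literal, NamedTuple

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "ExternalConditions",
    "DemandSpec",
    "MetabolicState",
    "ModelParameters",
    "FluxVector",
    "BalanceResiduals",
    "SteadyStateError",
    "atpase_rate",
    "default_parameters",
    "demand_level",
    "rhs",
    "reaction_rates",
    "fluxes_from_state",
    "steady_state",
    "balance_residuals",
    "params_to_yaml",
    "params_from_yaml",
]

DEMAND_LEVELS = ("low", "intermediate", "high")


@dataclass(frozen=True)
class ExternalConditions:
    """Extracellular substrate and oxygen availability.

    po2 defaults to 60 mmHg, a saturating oxygen level for the respiratory
    chain (Km,O2 << 60 mmHg), so phase diagrams probe only the
    lactate/glucose axes.  ph_ext enters the H+-coupled MCT2 carrier.
    """

    glc_ext: float
    lac_ext: float
    po2: float = 60.0
    ph_ext: float = 7.3

    def __post_init__(self) -> None:
        if self.glc_ext < 0:
            raise ValueError(f"glc_ext must be >= 0, got {self.glc_ext}")
        if self.lac_ext < 0:
            raise ValueError(f"lac_ext must be >= 0, got {self.lac_ext}")
        if not self.po2 > 0:
            raise ValueError(f"po2 must be > 0, got {self.po2}")


@dataclass(frozen=True)
class DemandSpec:
    """ATP-hydrolysis load: v_ATPase = k * ATP / (ATP + km_atp)."""

    k: float
    km_atp: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if not self.km_atp > 0:
            raise ValueError(f"km_atp must be > 0, got {self.km_atp}")


def atpase_rate(atp: float, demand: DemandSpec) -> float:
    """ATP consumption rate k*ATP/(ATP+Km) in mM/s.

    Monotone increasing in ATP and bounded by the rate constant k.
    """
    if atp < 0:
        raise ValueError(f"atp must be >= 0, got {atp}")
    return demand.k * atp / (atp + demand.km_atp)


# Order of the full state vector; the reduced vector drops the four
# pool partners (adp_cyt, nad_cyt, adp_mit, nad_mit).
_STATE_FIELDS = (
    "glc_cyt", "pyr_cyt", "lac_cyt",
    "atp_cyt", "adp_cyt", "nadh_cyt", "nad_cyt",
    "atp_mit", "adp_mit", "nadh_mit", "nad_mit",
    "fadh2_equiv_mit", "dpsi", "dph", "ca_mit",
)
_REDUCED_FIELDS = (
    "glc_cyt", "pyr_cyt", "lac_cyt", "atp_cyt", "nadh_cyt",
    "atp_mit", "nadh_mit", "fadh2_equiv_mit", "dpsi", "dph", "ca_mit",
)


@dataclass
class MetabolicState:
    """Concentrations and potentials of the two-compartment neuron model.

    Conserved pools: atp_cyt+adp_cyt, atp_mit+adp_mit, nadh_cyt+nad_cyt,
    nadh_mit+nad_mit and fadh2_equiv_mit + (free FAD) are set by the
    parameter totals.  ca_mit is in uM; everything else in mM, dpsi in mV.
    """

    glc_cyt: float
    pyr_cyt: float
    lac_cyt: float
    atp_cyt: float
    adp_cyt: float
    nadh_cyt: float
    nad_cyt: float
    atp_mit: float
    adp_mit: float
    nadh_mit: float
    nad_mit: float
    fadh2_equiv_mit: float
    dpsi: float
    dph: float
    ca_mit: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "MetabolicState":
        return cls(**{f: float(v) for f, v in zip(_STATE_FIELDS, y)})

    def reduced(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _REDUCED_FIELDS], dtype=float)

    def validate(self, params: "ModelParameters", atol: float = 1e-6) -> None:
        y = self.as_array()
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite entries in MetabolicState")
        conc = [self.glc_cyt, self.pyr_cyt, self.lac_cyt, self.atp_cyt,
                self.adp_cyt, self.nadh_cyt, self.nad_cyt, self.atp_mit,
                self.adp_mit, self.nadh_mit, self.nad_mit,
                self.fadh2_equiv_mit, self.ca_mit]
        if min(conc) < -atol:
            raise ValueError("negative concentration in MetabolicState")
        if not (-atol <= self.dpsi <= 220.0 + atol):
            raise ValueError(f"dpsi out of range [0, 220] mV: {self.dpsi}")
        pools = {
            "adenine (cytosol)": (self.atp_cyt + self.adp_cyt, params.a_cyt),
            "adenine (mito)": (self.atp_mit + self.adp_mit, params.a_mit),
            "NAD (cytosol)": (self.nadh_cyt + self.nad_cyt, params.n_cyt),
            "NAD (mito)": (self.nadh_mit + self.nad_mit, params.n_mit),
        }
        for name, (total, expect) in pools.items():
            if abs(total - expect) > atol * max(1.0, expect):
                raise ValueError(
                    f"{name} pool violated: {total} != {expect}")


def _state_from_reduced(u: np.ndarray, params: "ModelParameters") -> MetabolicState:
    (glc, pyr, lac, atp_c, nadh_c, atp_m, nadh_m, fadh2, dpsi, dph, ca) = u
    return MetabolicState(
        glc_cyt=float(glc), pyr_cyt=float(pyr), lac_cyt=float(lac),
        atp_cyt=float(atp_c), adp_cyt=float(params.a_cyt - atp_c),
        nadh_cyt=float(nadh_c), nad_cyt=float(params.n_cyt - nadh_c),
        atp_mit=float(atp_m), adp_mit=float(params.a_mit - atp_m),
        nadh_mit=float(nadh_m), nad_mit=float(params.n_mit - nadh_m),
        fadh2_equiv_mit=float(fadh2), dpsi=float(dpsi), dph=float(dph),
        ca_mit=float(ca),
    )


@dataclass
class ModelParameters:
    """Rate constants, half-saturations, pool totals and stoichiometry.

    Capacities (v_*) are mM/s referred to cytosolic volume; half-saturations
    mM unless noted.  Stoichiometric constants are canonical textbook
    values: net 2 ATP and 2 NADH per glucose in glycolysis (2 invested /
    4 produced), 4 NADH + 1 FADH2 per pyruvate through pyruvate
    dehydrogenase plus the citric acid cycle, 10 and 6 protons pumped per
    NADH and FADH2, 3 protons per synthase ATP with the translocator
    contributing one further charge per exported ATP, and half an O2 per
    reducing equivalent.
    """

    # conserved pool totals (mM)
    a_cyt: float = 2.6
    a_mit: float = 5.0
    n_cyt: float = 0.5
    n_mit: float = 2.0
    f_mit: float = 1.0

    # glucose transport (GLUT3-like reversible carrier)
    v_glut: float = 0.07
    km_glut: float = 7.0

    # lumped glycolysis: upper (glucose-, ATP-dependent) x lower
    # (ADP-, NAD+-dependent) saturations, intermediate at quasi-steady state
    v_gly: float = 0.5
    km_gly_glc: float = 0.2
    km_gly_atp: float = 0.1
    km_gly_adp: float = 0.3
    km_gly_nad: float = 0.05

    # lactate dehydrogenase, reversible mass action toward equilibrium
    k_ldh: float = 500.0      # mM^-1 s^-1
    keq_ldh: float = 1.0e4    # ([lac][NAD+])/([pyr][NADH]) at cytosolic pH

    # MCT2, H+-coupled reversible lactate carrier
    v_mct: float = 0.10
    km_mct: float = 1.0
    ph_cyt: float = 7.0

    # pyruvate oxidation + citric acid cycle (lumped, Ca2+-modulated)
    v_tca: float = 0.40
    km_tca_pyr: float = 0.02
    km_tca_nad: float = 0.2
    km_tca_fad: float = 0.05
    a_ca: float = 1.0
    km_ca: float = 0.5        # uM

    # NADH shuttles
    v_mas: float = 0.40
    km_mas_nadh: float = 0.01
    km_mas_nad: float = 0.2
    v_g3p: float = 0.08
    km_g3p_nadh: float = 0.01
    km_g3p_fad: float = 0.1

    # respiratory chain (NADH- and FADH2-fed proton pumping)
    v_c1: float = 0.9
    km_c1: float = 0.1
    v_c2: float = 0.3
    km_c2: float = 0.05
    km_o2: float = 0.5        # mmHg
    pmf_pump: float = 185.0   # mV, back-pressure midpoint
    slope_pump: float = 10.0  # mV

    # ATP synthase
    v_syn: float = 2.0
    km_syn_adp: float = 0.3
    pmf_syn: float = 100.0    # mV, activation midpoint
    slope_syn: float = 15.0

    # adenine nucleotide translocator
    v_ant: float = 3.0
    km_ant_atp: float = 0.5
    km_ant_adp: float = 0.1

    # proton leak (charge-equivalent conductance)
    k_leak: float = 1.0e-4    # mM charge / s / mV

    # mitochondrial Ca2+ handling (uM/s)
    v_uni: float = 0.05
    psi_uni: float = 150.0
    s_uni: float = 20.0
    v_ncx: float = 0.10
    km_ncx: float = 1.0

    # membrane / pH coupling
    c_mito: float = 0.02      # mM charge per mV
    z_ph: float = 61.5        # mV per pH unit (2.303 RT/F at 35 C)
    ph_frac: float = 0.2      # Delta-pH share of the proton-motive force
    tau_ph: float = 1.0       # s, relaxation of dph toward its share

    # stoichiometry (canonical; do not tune)
    n_h_c1: float = 10.0
    n_h_c2: float = 6.0
    n_h_syn: float = 3.0
    nadh_per_glc: float = 2.0
    atp_per_glc: float = 2.0
    nadh_per_pyr: float = 4.0
    fadh2_per_pyr: float = 1.0
    o2_per_equiv: float = 0.5

    # demand model
    km_atp: float = 0.1
    # frozen by calibration: maximal steady ATP turnover on 5 mM glucose /
    # 0 lactate, and the named demand levels as fractions of it
    turnover_max: float = float("nan")
    demand_fractions: dict = field(
        default_factory=lambda: {"low": 0.10, "intermediate": 0.45, "high": 0.85})
    k_demand: dict = field(default_factory=dict)

    # documentation constants
    henry_o2_um_per_mmhg: float = 1.3  # dissolved O2, uM per mmHg

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and f.name not in ("turnover_max",):
                if not v > 0:
                    raise ValueError(f"parameter {f.name} must be > 0, got {v}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)


def params_to_yaml(params: ModelParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)


def params_from_yaml(path) -> ModelParameters:
    with open(path) as fh:
        return ModelParameters.from_dict(yaml.safe_load(fh))


_DEFAULTS_CACHE: ModelParameters | None = None


def default_parameters() -> ModelParameters:
    """The frozen default calibration.

    Calibrated once so that the 5 mM glucose / 0 lactate steady state at
    low demand sits at ~2.5 mM cytosolic ATP, the three demand levels are
    fixed fractions (10/45/85%) of the maximal steady ATP turnover on
    5 mM glucose, and the MCT2 capacity is scaled so the glucose-fitness
    thresholds emerge at their observed values.  Stored in
    data/default_params.yaml; stable across releases.
    """
    global _DEFAULTS_CACHE
    if _DEFAULTS_CACHE is None:
        res = importlib.resources.files("neuroenergetics").joinpath(
            "data/default_params.yaml")
        with res.open() as fh:
            _DEFAULTS_CACHE = ModelParameters.from_dict(yaml.safe_load(fh))
    return replace(_DEFAULTS_CACHE,
                   demand_fractions=dict(_DEFAULTS_CACHE.demand_fractions),
                   k_demand=dict(_DEFAULTS_CACHE.k_demand))


def demand_level(level: Literal["low", "intermediate", "high"],
                 params: ModelParameters) -> DemandSpec:
    """Map a named energy-demand level to its ATPase rate constant.

    Levels are frozen fractions of the model's maximal steady ATP turnover
    on 5 mM glucose / 0 lactate (see calibration), stored on the parameter
    set, so the mapping is pure.
    """
    if level not in DEMAND_LEVELS:
        raise ValueError(f"unknown demand level {level!r}; "
                         f"expected one of {DEMAND_LEVELS}")
    if level in params.k_demand:
        k = params.k_demand[level]
    else:
        if not np.isfinite(params.turnover_max):
            raise ValueError(
                "parameters carry no calibrated turnover_max or k_demand")
        k = params.demand_fractions[level] * params.turnover_max
    return DemandSpec(k=float(k), km_atp=params.km_atp)


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    # overflow-safe logistic
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def reaction_rates(state: MetabolicState, params: ModelParameters,
                   cond: ExternalConditions, demand: DemandSpec) -> dict:
    """All reaction velocities (mM/s cytosolic; Ca2+ terms uM/s).

    Positive directions: glut = influx; gly = glucose consumed; ldh =
    pyruvate -> lactate; mct = lactate uptake; tca = pyruvate oxidized;
    mas/g3p = cytosolic NADH moved to the matrix (as NADH resp. FADH2);
    c1/c2 = matrix NADH resp. FADH2 oxidized; syn = matrix ATP made;
    ant = ATP exported to the cytosol; atpase = cytosolic ATP consumed.
    """
    p = params
    s = state
    fad = max(p.f_mit - s.fadh2_equiv_mit, 0.0)
    pmf = s.dpsi + p.z_ph * s.dph

    v_glut = p.v_glut * (cond.glc_ext / (cond.glc_ext + p.km_glut)
                         - s.glc_cyt / (s.glc_cyt + p.km_glut))
    v_gly = (p.v_gly
             * s.glc_cyt / (s.glc_cyt + p.km_gly_glc)
             * s.atp_cyt / (s.atp_cyt + p.km_gly_atp)
             * s.adp_cyt / (s.adp_cyt + p.km_gly_adp)
             * s.nad_cyt / (s.nad_cyt + p.km_gly_nad))
    v_ldh = p.k_ldh * (s.pyr_cyt * s.nadh_cyt
                       - s.lac_cyt * s.nad_cyt / p.keq_ldh)
    # carrier equilibrium at lac_cyt = lac_ext * [H+]_ext/[H+]_cyt
    r_h = 10.0 ** (p.ph_cyt - cond.ph_ext)
    v_mct = p.v_mct * (cond.lac_ext * r_h - s.lac_cyt) / (
        p.km_mct + cond.lac_ext + s.lac_cyt)
    f_ca = (1.0 + p.a_ca * s.ca_mit / (s.ca_mit + p.km_ca)) / (1.0 + p.a_ca)
    v_tca = (p.v_tca * f_ca
             * s.pyr_cyt / (s.pyr_cyt + p.km_tca_pyr)
             * s.nad_mit / (s.nad_mit + p.km_tca_nad)
             * fad / (fad + p.km_tca_fad))
    v_mas = (p.v_mas
             * s.nadh_cyt / (s.nadh_cyt + p.km_mas_nadh)
             * s.nad_mit / (s.nad_mit + p.km_mas_nad))
    v_g3p = (p.v_g3p
             * s.nadh_cyt / (s.nadh_cyt + p.km_g3p_nadh)
             * fad / (fad + p.km_g3p_fad))
    f_o2 = cond.po2 / (cond.po2 + p.km_o2)
    f_back = _sigmoid((p.pmf_pump - pmf) / p.slope_pump)
    v_c1 = p.v_c1 * f_o2 * f_back * s.nadh_mit / (s.nadh_mit + p.km_c1)
    v_c2 = p.v_c2 * f_o2 * f_back * s.fadh2_equiv_mit / (
        s.fadh2_equiv_mit + p.km_c2)
    f_pmf_syn = _sigmoid((pmf - p.pmf_syn) / p.slope_syn)
    v_syn = p.v_syn * f_pmf_syn * s.adp_mit / (s.adp_mit + p.km_syn_adp)
    v_ant = (p.v_ant
             * s.atp_mit / (s.atp_mit + p.km_ant_atp)
             * s.adp_cyt / (s.adp_cyt + p.km_ant_adp))
    v_leak = p.k_leak * pmf
    v_atpase = demand.k * s.atp_cyt / (s.atp_cyt + demand.km_atp)
    v_uni = p.v_uni * _sigmoid((s.dpsi - p.psi_uni) / p.s_uni)
    v_ncx = p.v_ncx * s.ca_mit / (s.ca_mit + p.km_ncx)

    return {
        "glut": v_glut, "gly": v_gly, "ldh": v_ldh, "mct": v_mct,
        "tca": v_tca, "mas": v_mas, "g3p": v_g3p, "c1": v_c1, "c2": v_c2,
        "syn": v_syn, "ant": v_ant, "leak": v_leak, "atpase": v_atpase,
        "uni": v_uni, "ncx": v_ncx, "pmf": pmf,
    }


def _reduced_rhs(u: np.ndarray, params: ModelParameters,
                 cond: ExternalConditions, demand: DemandSpec) -> np.ndarray:
    p = params
    s = _state_from_reduced(u, p)
    r = reaction_rates(s, p, cond, demand)

    d_glc = r["glut"] - r["gly"]
    d_pyr = 2.0 * r["gly"] - r["ldh"] - r["tca"]
    d_lac = r["ldh"] + r["mct"]
    d_atp_c = p.atp_per_glc * r["gly"] + r["ant"] - r["atpase"]
    d_nadh_c = p.nadh_per_glc * r["gly"] - r["ldh"] - r["mas"] - r["g3p"]
    d_atp_m = r["syn"] - r["ant"]
    d_nadh_m = p.nadh_per_pyr * r["tca"] + r["mas"] - r["c1"]
    d_fadh2 = p.fadh2_per_pyr * r["tca"] + r["g3p"] - r["c2"]
    charge = (p.n_h_c1 * r["c1"] + p.n_h_c2 * r["c2"]
              - p.n_h_syn * r["syn"] - r["ant"] - r["leak"]
              - 2.0e-3 * r["uni"])
    d_dpsi = charge / p.c_mito
    dph_target = p.ph_frac * s.dpsi / p.z_ph
    d_dph = (dph_target - s.dph) / p.tau_ph
    d_ca = r["uni"] - r["ncx"]

    return np.array([d_glc, d_pyr, d_lac, d_atp_c, d_nadh_c,
                     d_atp_m, d_nadh_m, d_fadh2, d_dpsi, d_dph, d_ca])


def rhs(state: MetabolicState, params: ModelParameters,
        cond: ExternalConditions, demand: DemandSpec) -> MetabolicState:
    """Time derivative of every state field.

    Conserved-pool derivatives cancel exactly by construction
    (d(ATP)+d(ADP) = 0 per compartment, likewise the NAD pools).
    """
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite entries in state")
    du = _reduced_rhs(state.reduced(), params, cond, demand)
    (d_glc, d_pyr, d_lac, d_atp_c, d_nadh_c,
     d_atp_m, d_nadh_m, d_fadh2, d_dpsi, d_dph, d_ca) = du
    return MetabolicState(
        glc_cyt=d_glc, pyr_cyt=d_pyr, lac_cyt=d_lac,
        atp_cyt=d_atp_c, adp_cyt=-d_atp_c,
        nadh_cyt=d_nadh_c, nad_cyt=-d_nadh_c,
        atp_mit=d_atp_m, adp_mit=-d_atp_m,
        nadh_mit=d_nadh_m, nad_mit=-d_nadh_m,
        fadh2_equiv_mit=d_fadh2, dpsi=d_dpsi, dph=d_dph, ca_mit=d_ca,
    )


@dataclass(frozen=True)
class FluxVector:
    """Steady fluxes in mM/s.  j_lac is signed: negative = lactate uptake,
    positive = lactate release."""

    j_glc: float
    j_lac: float
    j_o2: float
    j_atpase: float
    j_synthase: float
    j_glycolysis: float
    j_tca: float
    j_shuttle: float
    j_leak: float


def fluxes_from_state(state: MetabolicState, params: ModelParameters,
                      cond: ExternalConditions, demand: DemandSpec) -> FluxVector:
    r = reaction_rates(state, params, cond, demand)
    return FluxVector(
        j_glc=float(r["glut"]),
        j_lac=float(-r["mct"]),
        j_o2=float(params.o2_per_equiv * (r["c1"] + r["c2"])),
        j_atpase=float(r["atpase"]),
        j_synthase=float(r["syn"]),
        j_glycolysis=float(r["gly"]),
        j_tca=float(r["tca"]),
        j_shuttle=float(r["mas"] + r["g3p"]),
        j_leak=float(r["leak"]),
    )


class BalanceResiduals(NamedTuple):
    carbon: float
    redox: float
    phosphate: float


def balance_residuals(fluxes: FluxVector) -> BalanceResiduals:
    """Steady-state mass/electron/phosphate closure (mM/s).

    carbon:    6*j_glc - 3*j_lac - 3*j_tca  (glucose C6, lactate/pyruvate C3)
    redox:     2*j_glycolysis + 5*j_tca - 2*j_o2 - j_lac
               (reducing-equivalent pairs: 2 per glucose in glycolysis,
               4 NADH + 1 FADH2 per pyruvate oxidized; the chain consumes
               two equivalents per O2; net lactate release exports one
               equivalent per lactate)
    phosphate: j_synthase + 2*j_glycolysis - j_atpase

    All three vanish identically at a converged steady state.
    """
    carbon = 6.0 * fluxes.j_glc - 3.0 * fluxes.j_lac - 3.0 * fluxes.j_tca
    redox = (2.0 * fluxes.j_glycolysis + 5.0 * fluxes.j_tca
             - 2.0 * fluxes.j_o2 - fluxes.j_lac)
    phosphate = fluxes.j_synthase + 2.0 * fluxes.j_glycolysis - fluxes.j_atpase
    return BalanceResiduals(carbon=carbon, redox=redox, phosphate=phosphate)


class SteadyStateError(RuntimeError):
    """Raised when the steady-state solver fails to converge.

    Carries the last state reached so callers can inspect or warm-start.
    """

    def __init__(self, message: str, last_state: MetabolicState | None = None):
        super().__init__(message)
        self.last_state = last_state


def initial_state(params: ModelParameters,
                  kind: Literal["energized", "deenergized"] = "energized",
                  ) -> MetabolicState:
    """The two documented starting points for the steady-state search.

    "energized": ATP-rich, polarized mitochondria; "deenergized": ATP-poor,
    depolarized.  A converged steady state must not depend on the choice.
    """
    p = params
    if kind == "energized":
        u = np.array([1.0, 0.05, 0.5, 0.9 * p.a_cyt, 0.02 * p.n_cyt,
                      0.8 * p.a_mit, 0.3 * p.n_mit, 0.1 * p.f_mit,
                      150.0, 0.5, 0.3])
    elif kind == "deenergized":
        u = np.array([0.05, 0.005, 0.05, 0.1 * p.a_cyt, 0.005 * p.n_cyt,
                      0.1 * p.a_mit, 0.02 * p.n_mit, 0.01 * p.f_mit,
                      20.0, 0.05, 0.05])
    else:
        raise ValueError(f"unknown initial condition {kind!r}")
    return _state_from_reduced(u, p)


def _integrate(u0: np.ndarray, params, cond, demand, t_end: float) -> np.ndarray:
    sol = solve_ivp(
        lambda t, y: _reduced_rhs(y, params, cond, demand),
        (0.0, t_end), u0, method="LSODA", rtol=1e-10, atol=1e-12,
        dense_output=False)
    if not sol.success:
        raise SteadyStateError(
            f"stiff integration failed: {sol.message}",
            _state_from_reduced(sol.y[:, -1], params))
    return sol.y[:, -1]


def steady_state(params: ModelParameters, cond: ExternalConditions,
                 demand: DemandSpec, *,
                 initial: Literal["energized", "deenergized"] | MetabolicState
                 = "energized",
                 tol: float = 1e-9,
                 ) -> tuple[MetabolicState, FluxVector]:
    """Steady state by stiff integration followed by root refinement.

    Integrates the reduced system far past its slowest relaxation, then
    polishes with a damped Newton (scipy.optimize.root) and verifies that
    the full right-hand side satisfies ||rhs||_inf < tol in native units
    (mM/s; mV/s for the membrane potential).  Raises SteadyStateError with
    the last state on failure -- never returns a silent partial result.
    """
    if isinstance(initial, MetabolicState):
        u = initial.reduced()
    else:
        u = initial_state(params, initial).reduced()

    last = u
    for t_end in (2000.0, 20000.0, 200000.0):
        u_int = _integrate(last, params, cond, demand, t_end)
        last = u_int
        scale = np.maximum(np.abs(u_int), 1e-3)
        sol = root(
            lambda v: _reduced_rhs(v * scale, params, cond, demand),
            u_int / scale, method="hybr", options={"xtol": 1e-13})
        u_ref = sol.x * scale
        # clip solver excursions just below the positivity boundary
        u_ref = np.where((u_ref < 0) & (u_ref > -1e-10), 0.0, u_ref)
        du = _reduced_rhs(u_ref, params, cond, demand)
        if np.max(np.abs(du)) < tol and np.min(u_ref) >= 0:
            state = _state_from_reduced(u_ref, params)
            return state, fluxes_from_state(state, params, cond, demand)
        if np.max(np.abs(_reduced_rhs(u_int, params, cond, demand))) < tol:
            state = _state_from_reduced(u_int, params)
            return state, fluxes_from_state(state, params, cond, demand)

    raise SteadyStateError(
        f"no steady state within tolerance {tol} at glc={cond.glc_ext}, "
        f"lac={cond.lac_ext}, k={demand.k}",
        _state_from_reduced(last, params))
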