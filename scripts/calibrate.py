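"""Regenerate the frozen default calibration of the kinetic model.

Protocol (see docs/methods.md):

1. Start from the structural defaults of ModelParameters (rate-law forms,
   pool totals, stoichiometry, all half-saturations).
2. Compute the maximal steady ATP turnover on 5 mM glucose / 0 lactate
   (demand rate constant driven far above capacity) and define the named
   demand levels as 10% / 45% / 85% of it.
3. Scale the MCT2 capacity (the single free calibration parameter) by
   bisection so that the glucose-fitness threshold at intermediate demand
   with 5 mM extracellular lactate lands at 0.25 mM glucose.
4. Freeze everything, including the turnover ceiling and the per-level
   ATPase rate constants, into src/neuroenergetics/data/default_params.yaml.

Run from the repository root:  python scripts/calibrate.py
"""
from dataclasses import replace
from pathlib import Path

from neuroenergetics.kinetics import (DemandSpec, ExternalConditions,
                                      ModelParameters, params_to_yaml,
                                      steady_state)

TARGET_INT_THRESHOLD_MM = 0.25
LAC_REF_MM = 5.0
FRACTIONS = {"low": 0.10, "intermediate": 0.45, "high": 0.85}


def max_turnover(p: ModelParameters) -> float:
    _, fl = steady_state(p, ExternalConditions(5.0, 0.0),
                         DemandSpec(4.0, p.km_atp))
    return fl.j_atpase


def atp_at(p: ModelParameters, glc: float, lac: float, k: float) -> float:
    st, _ = steady_state(p, ExternalConditions(glc, lac),
                         DemandSpec(k, p.km_atp))
    return st.atp_cyt


def glucose_threshold(p: ModelParameters, k: float, lac: float,
                      tol: float = 0.005) -> float:
    if atp_at(p, 0.0, lac, k) >= 1.0:
        return 0.0
    lo, hi = 0.0, 5.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        (lo, hi) = (lo, mid) if atp_at(p, mid, lac, k) >= 1.0 else (mid, hi)
    return 0.5 * (lo + hi)


def main() -> None:
    base = ModelParameters()
    lo, hi = 0.005, 0.2  # v_mct bracket; threshold decreasing in v_mct
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        p = replace(base, v_mct=mid)
        k_int = FRACTIONS["intermediate"] * max_turnover(p)
        t_int = glucose_threshold(p, k_int, LAC_REF_MM)
        (lo, hi) = (mid, hi) if t_int > TARGET_INT_THRESHOLD_MM else (lo, mid)
    v_mct = round(0.5 * (lo + hi), 5)

    p = replace(base, v_mct=v_mct)
    turnover = max_turnover(p)
    k_demand = {name: round(f * turnover, 6) for name, f in FRACTIONS.items()}
    p = replace(p, turnover_max=round(turnover, 6),
                demand_fractions=dict(FRACTIONS), k_demand=k_demand)

    out = Path(__file__).resolve().parents[1] / "src" / "neuroenergetics" \
        / "data" / "default_params.yaml"
    params_to_yaml(p, out)
    print(f"v_mct = {v_mct}, turnover_max = {turnover:.6f}")
    for name, k in k_demand.items():
        print(f"k({name}) = {k}")
    for name in ("low", "intermediate", "high"):
        t = glucose_threshold(p, k_demand[name], LAC_REF_MM)
        print(f"glucose threshold ({name}, lac={LAC_REF_MM}) = {t:.3f} mM")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
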