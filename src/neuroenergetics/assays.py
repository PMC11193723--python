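"""Quantitative bench-data reductions for slice-culture experiments.

Covers the standard wet-lab quantification steps around the imaging and
electrophysiology pipelines: serial-dilution standard curves for plate
assays (linear for nitrite/lactate, quadratic for the IL-6 ELISA) with
monotone inversion of unknowns; three-point oxygen-microsensor
calibration, probe depth geometry and slice-core localization; relative
gene expression by the comparative Ct method (2^-ddCt against a
reference gene and a control group); normalization of metabolite tables
to the control group and pairwise row ratios; and row z-scoring with
Ward hierarchical clustering for expression heatmaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "StandardCurve", "SensorCalibration", "O2Profile", "CoreLocation",
    "ExpressionMatrix",
    "dilution_series", "fit_standard_curve", "concentration_from_signal",
    "calibrate_o2", "calibration_drift", "depth_axis", "locate_slice_core",
    "ddct_expression", "normalize_to_control", "row_ratio", "zscore_cluster",
]


# --------------------------------------------------------------------------
# plate-assay standard curves

def dilution_series(top: float, factor: float = 2.0, n: int = 8) -> np.ndarray:
    """Concentrations of an n-point serial dilution: top / factor**i.

    An 8-point two-fold series from 8000 pg/mL runs 8000 ... 62.5; a
    9-point series from 80 uM bottoms out at 0.3125 uM.
    """
    if not factor > 1:
        raise ValueError(f"dilution factor must be > 1, got {factor}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not top > 0:
        raise ValueError(f"top standard must be > 0, got {top}")
    return top / factor ** np.arange(n)


@dataclass
class StandardCurve:
    """Fitted signal = f(concentration) mapping for one assay.

    coefficients are ascending powers (c0 + c1*x [+ c2*x^2]).  Inversion
    is restricted to the fitted concentration domain and the curve is
    required to be monotone there.
    """

    assay: str
    model: Literal["linear", "quadratic"]
    coefficients: np.ndarray
    concentration_domain: tuple
    signal_domain: tuple
    fit_stats: dict = field(default_factory=dict)

    def predict(self, conc):
        return np.polyval(self.coefficients[::-1], conc)


def fit_standard_curve(standards: Sequence[tuple],
                       model: Literal["linear", "quadratic"] = "linear",
                       assay: str = "") -> StandardCurve:
    """Least-squares fit of signal on concentration.

    Requires at least one point more than the polynomial degrees of
    freedom and verifies monotonicity over the standard range (a
    non-monotone curve cannot be inverted for unknowns).
    """
    degree = {"linear": 1, "quadratic": 2}.get(model)
    if degree is None:
        raise ValueError(f"unknown model {model!r}")
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("standards must be (concentration, signal) pairs")
    conc, sig = arr[:, 0], arr[:, 1]
    if len(conc) < degree + 2:
        raise ValueError(
            f"{model} fit needs at least {degree + 2} standards, "
            f"got {len(conc)}")
    coeffs = np.polyfit(conc, sig, degree)[::-1]

    lo, hi = float(conc.min()), float(conc.max())
    grid = np.linspace(lo, hi, 256)
    deriv = np.polyval(np.polyder(coeffs[::-1]), grid)
    if not (np.all(deriv > 0) or np.all(deriv < 0)):
        raise ValueError(
            "fitted curve is not monotone over the standard range; "
            "unusable for inversion")

    pred = np.polyval(coeffs[::-1], conc)
    ss_res = float(np.sum((sig - pred) ** 2))
    ss_tot = float(np.sum((sig - sig.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    sig_lo, sig_hi = np.polyval(coeffs[::-1], [lo, hi])
    return StandardCurve(
        assay=assay, model=model, coefficients=coeffs,
        concentration_domain=(lo, hi),
        signal_domain=(min(sig_lo, sig_hi), max(sig_lo, sig_hi)),
        fit_stats={"r2": r2, "n": len(conc)})


def concentration_from_signal(curve: StandardCurve, signal: float,
                              dilution_factor: float = 1.0) -> float:
    """Invert the fitted curve and undo the sample dilution.

    Interpolation only: signals outside the fitted signal range raise,
    as does a quadratic with two in-domain roots.
    """
    lo_s, hi_s = curve.signal_domain
    span = hi_s - lo_s
    if not (lo_s - 1e-9 * abs(span) <= signal <= hi_s + 1e-9 * abs(span)):
        raise ValueError(
            f"signal {signal} outside the curve's range "
            f"[{lo_s}, {hi_s}]; refusing to extrapolate")
    c = curve.coefficients
    if curve.model == "linear":
        conc = (signal - c[0]) / c[1]
    else:
        roots = np.roots([c[2], c[1], c[0] - signal])
        roots = roots[np.abs(roots.imag) < 1e-9].real
        lo, hi = curve.concentration_domain
        tol = 1e-9 * max(1.0, hi - lo)
        inside = roots[(roots >= lo - tol) & (roots <= hi + tol)]
        inside = np.unique(np.round(inside, 12))
        if len(inside) == 0:
            raise ValueError("no in-domain root for this signal")
        if len(inside) > 1:
            raise ValueError("two in-domain roots; curve not invertible "
                             "at this signal")
        conc = float(inside[0])
    return float(conc) * dilution_factor


# --------------------------------------------------------------------------
# oxygen microsensor

@dataclass
class SensorCalibration:
    """Linear raw-signal -> O2 map from a three-point saturation series."""

    points: np.ndarray       # (o2_level, raw_signal) rows
    slope: float
    intercept: float
    r2: float


def calibrate_o2(points: Sequence[tuple]) -> SensorCalibration:
    """Least-squares line through (raw signal, O2 level) calibration points.

    The classic series uses ACSF saturated at 0%, 20% and 95% O2.  Warns
    (does not fail) when r^2 < 0.99 -- a nonlinear electrode.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("need >= 3 (o2_level, raw_signal) points")
    levels, raw = arr[:, 0], arr[:, 1]
    if len(np.unique(levels)) < len(levels):
        raise ValueError("duplicate saturation levels in calibration")
    slope, intercept = np.polyfit(raw, levels, 1)
    pred = slope * raw + intercept
    ss_tot = float(np.sum((levels - levels.mean()) ** 2))
    r2 = 1.0 - float(np.sum((levels - pred) ** 2)) / ss_tot
    if r2 < 0.99:
        warnings.warn(f"sensor calibration r2 = {r2:.4f} < 0.99",
                      stacklevel=2)
    return SensorCalibration(points=arr, slope=float(slope),
                             intercept=float(intercept), r2=r2)


def calibration_drift(pre: SensorCalibration, post: SensorCalibration,
                      rel_tol: float = 0.10) -> bool:
    """True when the sensor sensitivity drifted by more than rel_tol
    between the pre- and post-experiment calibrations."""
    return abs(post.slope - pre.slope) > rel_tol * abs(pre.slope)


def depth_axis(n_steps: int, step_advance_um: float = 20.0,
               angle_deg: float = 55.0) -> np.ndarray:
    """Vertical depth after each probe advance along a tilted track.

    depth_i = i * advance * sin(angle); a 20 um advance at 55 degrees is
    ~16 um of vertical depth per step, so 6 steps reach ~98 um.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if not step_advance_um > 0:
        raise ValueError("step_advance_um must be > 0")
    if not 0 < angle_deg <= 90:
        raise ValueError(f"angle_deg must be in (0, 90], got {angle_deg}")
    return (np.arange(1, n_steps + 1) * step_advance_um
            * np.sin(np.deg2rad(angle_deg)))


@dataclass
class O2Profile:
    """Calibrated O2 concentration versus probe step / vertical depth."""

    step_index: np.ndarray
    depth_um: np.ndarray
    concentration: np.ndarray
    core_index: int | None = None

    def __post_init__(self) -> None:
        self.step_index = np.asarray(self.step_index)
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if len(self.depth_um) != len(self.concentration):
            raise ValueError("depth and concentration lengths differ")
        if len(self.depth_um) > 1 and np.any(np.diff(self.depth_um) <= 0):
            raise ValueError("depth_um must be strictly increasing")


@dataclass(frozen=True)
class CoreLocation:
    """Slice-core call: index of the O2 minimum plus quality flags."""

    index: int
    degenerate: bool = False
    note: str = ""


def locate_slice_core(profile: O2Profile) -> CoreLocation:
    """The slice core is the profile point of lowest O2 concentration.

    Ties resolve to the shallowest point (flagged degenerate); a minimum
    at the deepest point is flagged as a core possibly not reached.
    """
    conc = profile.concentration
    if len(conc) == 0:
        raise ValueError("empty profile")
    idx = int(np.argmin(conc))  # first minimum = shallowest
    n_min = int(np.sum(conc == conc[idx]))
    if n_min > 1:
        return CoreLocation(idx, degenerate=True,
                            note=f"{n_min} tied minima; shallowest reported")
    if idx == len(conc) - 1 and len(conc) > 1:
        return CoreLocation(idx, degenerate=True,
                            note="minimum at deepest step; core possibly "
                                 "not reached")
    return CoreLocation(idx)


# --------------------------------------------------------------------------
# relative expression

@dataclass
class ExpressionMatrix:
    """Genes x samples table of relative expression or metabolite content
    with per-sample group labels."""

    values: pd.DataFrame           # index = genes/metabolites, columns = samples
    groups: pd.Series              # sample -> group label
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")


def ddct_expression(ct: pd.DataFrame, reference_gene: str = "ACTB",
                    control_group: str = "CTL") -> ExpressionMatrix:
    """Comparative Ct relative expression, 2^-ddCt.

    ``ct`` is long-format with columns (sample, group, gene, ct).
    dCt = Ct_gene - Ct_reference per sample; ddCt references each gene's
    dCt to the control-group mean; relative expression = 2^-ddCt.
    Samples lacking the reference gene are dropped with a warning.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"ct table needs columns {sorted(required)}")
    if reference_gene not in set(ct["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} absent")
    if control_group not in set(ct["group"]):
        raise ValueError(f"control group {control_group!r} absent")

    wide = ct.pivot_table(index="gene", columns="sample", values="ct",
                          aggfunc="mean")
    groups = ct.drop_duplicates("sample").set_index("sample")["group"]

    ref = wide.loc[reference_gene]
    bad = ref.index[ref.isna()]
    if len(bad):
        warnings.warn(f"dropping samples without reference-gene Ct: "
                      f"{list(bad)}", stacklevel=2)
        wide = wide.drop(columns=bad)
        groups = groups.drop(bad)
        ref = ref.drop(bad)

    dct = wide.sub(ref, axis=1)
    control_cols = groups.index[groups == control_group]
    ddct = dct.sub(dct[control_cols].mean(axis=1), axis=0)
    rel = 2.0 ** (-ddct)
    return ExpressionMatrix(values=rel, groups=groups.loc[rel.columns])


def normalize_to_control(em: ExpressionMatrix,
                         control_group: str = "CTL") -> ExpressionMatrix:
    """Divide each row by its control-group mean (control mean -> 1)."""
    control_cols = em.groups.index[em.groups == control_group]
    if len(control_cols) == 0:
        raise ValueError(f"no samples in control group {control_group!r}")
    ctrl_mean = em.values[control_cols].mean(axis=1)
    if (ctrl_mean <= 0).any():
        bad = list(ctrl_mean.index[ctrl_mean <= 0])
        raise ValueError(f"non-positive control mean for rows {bad}")
    return ExpressionMatrix(values=em.values.div(ctrl_mean, axis=0),
                            groups=em.groups)


def row_ratio(em: ExpressionMatrix, numerator: str,
              denominator: str) -> pd.Series:
    """Per-sample ratio of two rows of the un-normalized matrix
    (e.g. alpha-ketoglutarate / citrate)."""
    for name in (numerator, denominator):
        if name not in em.values.index:
            raise ValueError(f"row {name!r} not in matrix")
    den = em.values.loc[denominator]
    if (den == 0).any():
        raise ValueError(f"zero denominator entries in {denominator!r}")
    return em.values.loc[numerator] / den


# --------------------------------------------------------------------------
# heatmap z-scores + Ward clustering

def _ward_d_linkage(x: np.ndarray) -> np.ndarray:
    """Classic Ward linkage on unsquared Euclidean distances (R's ward.D).

    scipy's 'ward' applies the Lance-Williams update to squared
    distances (ward.D2 semantics); feeding it sqrt(d) makes the internal
    squares reproduce the update on d itself, and squaring the resulting
    heights recovers the ward.D merge heights.
    """
    d = pdist(x, metric="euclidean")
    z = hierarchy.linkage(np.sqrt(d), method="ward")
    z = z.copy()
    z[:, 2] = z[:, 2] ** 2
    return z


def zscore_cluster(em: ExpressionMatrix):
    """Row-wise z-scores plus Ward.D/Euclidean leaf orders.

    z = (x - row mean) / row sd with the sample (n-1) sd convention;
    constant rows are set to zero and flagged.  Returns the z-scored
    matrix and the row and column leaf orders of agglomerative Ward
    clustering on unsquared Euclidean distances.
    """
    vals = em.values
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    constant = sd == 0
    safe_sd = sd.mask(constant, 1.0)
    z = vals.sub(mean, axis=0).div(safe_sd, axis=0)
    z[constant] = 0.0
    flags = {"constant_rows": list(vals.index[constant])}

    row_order = hierarchy.leaves_list(_ward_d_linkage(z.to_numpy()))
    col_order = hierarchy.leaves_list(_ward_d_linkage(z.to_numpy().T))
    zm = ExpressionMatrix(values=z, groups=em.groups, flags=flags)
    return zm, row_order, col_order
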