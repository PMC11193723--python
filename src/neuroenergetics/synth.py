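"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its spec (including the seed): the
same spec yields bitwise-identical output.  With noise set to zero the
downstream estimators recover the planted parameters exactly, which is
what the test suite exploits.

Generators:

- :func:`gen_lfp` -- 10 kHz field-potential traces: an amplitude-
  modulated gamma-band sinusoid over a 1/f^alpha background.
- :func:`gen_plate` -- microplate optical densities for a two-fold
  standard dilution series plus unknowns, under a known signal model.
- :func:`gen_ct_table` -- qPCR Ct tables for the six-group transient-
  inflammation design (CTL, LPS, RES24..RES96), with per-sample loading
  offsets that the comparative Ct method must cancel.
- :func:`gen_image_stack` -- two-channel confocal-like stacks with
  planted nuclei and ramified microglia at known positions.
- :func:`gen_o2_profile` -- oxygen microsensor depth profiles with a
  planted concentration minimum at the slice core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .assays import O2Profile, depth_axis, dilution_series
from .imaging import ImageStack
from .lfp import LfpTrace

__all__ = [
    "LfpSpec", "PlateSpec", "CtDesign", "ImageSpec", "O2ProfileSpec",
    "PlateData", "GroundTruth",
    "gen_lfp", "gen_plate", "gen_ct_table", "gen_image_stack",
    "gen_o2_profile",
    "save_plate", "load_plate", "save_ct", "load_ct",
    "save_image_stack", "load_image_stack", "save_o2_profile",
    "load_o2_profile",
]

CT_GROUPS = ("CTL", "LPS", "RES24", "RES48", "RES72", "RES96")


# --------------------------------------------------------------------------
# LFP

@dataclass(frozen=True)
class LfpSpec:
    """Carbachol-type gamma oscillation riding on a 1/f background.

    The oscillation is an amplitude-modulated sinusoid: a slow random
    envelope (bandwidth ``env_bandwidth_hz``) gives the spectral peak a
    realistic finite width while keeping the center frequency exact.
    Default amplitudes put the peak power around 1e-3 mV^2/Hz, an order
    of magnitude above the 1e-4 gamma classification threshold.
    """

    duration_s: float
    sample_rate_hz: float = 10_000.0
    osc_freq_hz: float = 40.0
    osc_amp_mv: float = 0.1
    noise_exponent: float = 1.0
    noise_amp_mv: float = 0.02
    env_bandwidth_hz: float = 4.0
    env_depth: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.sample_rate_hz <= 2 * self.osc_freq_hz:
            raise ValueError(
                f"sample_rate_hz ({self.sample_rate_hz}) must exceed twice "
                f"osc_freq_hz ({self.osc_freq_hz})")
        if self.osc_amp_mv < 0:
            raise ValueError(f"osc_amp_mv must be >= 0, got {self.osc_amp_mv}")
        if self.noise_amp_mv < 0:
            raise ValueError(
                f"noise_amp_mv must be >= 0, got {self.noise_amp_mv}")


def _one_over_f_noise(n: int, fs: float, alpha: float, rms: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped Gaussian noise with PSD proportional to 1/f^alpha."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-alpha / 2.0)
    shape[0] = 0.0
    shaped = np.fft.irfft(spec * shape, n=n)
    cur = shaped.std()
    return shaped * (rms / cur) if cur > 0 else shaped


def gen_lfp(spec: LfpSpec) -> LfpTrace:
    """Synthesize one trace of length duration_s * sample_rate_hz."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    t = np.arange(n) / spec.sample_rate_hz

    # slow positive envelope: low-pass-shaped noise around 1
    env_noise = rng.standard_normal(n)
    spec_f = np.fft.rfft(env_noise)
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sample_rate_hz)
    spec_f[freqs > spec.env_bandwidth_hz] = 0.0
    slow = np.fft.irfft(spec_f, n=n)
    sd = slow.std()
    if sd > 0:
        slow = slow / sd
    envelope = np.clip(1.0 + spec.env_depth * slow, 0.0, None)

    phase = rng.uniform(0, 2 * np.pi)
    osc = spec.osc_amp_mv * envelope * np.sin(
        2 * np.pi * spec.osc_freq_hz * t + phase)
    noise = _one_over_f_noise(n, spec.sample_rate_hz, spec.noise_exponent,
                              spec.noise_amp_mv, rng)
    return LfpTrace(samples=osc + noise,
                    sample_rate_hz=spec.sample_rate_hz)


# --------------------------------------------------------------------------
# plate assays

@dataclass(frozen=True)
class PlateSpec:
    """A standards-plus-unknowns plate under a known signal model.

    curve_truth holds ascending-power coefficients of the true
    signal(concentration) polynomial (2 for linear, 3 for quadratic).
    The canonical IL-6 plate is an 8-point two-fold series from
    8000 pg/mL.
    """

    assay: str = "IL6_ELISA"
    top_standard: float = 8000.0
    n_standards: int = 8
    dilution_factor: float = 2.0
    curve_truth: tuple = (0.05, 2.5e-4)
    noise_sd: float = 0.0
    unknowns_truth: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.top_standard > 0:
            raise ValueError(
                f"top_standard must be > 0, got {self.top_standard}")
        if not self.dilution_factor > 1:
            raise ValueError(
                f"dilution_factor must be > 1, got {self.dilution_factor}")
        if self.n_standards < 3:
            raise ValueError(
                f"n_standards must be >= 3, got {self.n_standards}")
        if len(self.curve_truth) not in (2, 3):
            raise ValueError("curve_truth must be linear (2 coefficients) "
                             "or quadratic (3)")


@dataclass
class PlateData:
    """Well table (well, role, conc, signal) plus the generating spec."""

    wells: pd.DataFrame
    spec: PlateSpec

    def standards(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == "standard"]

    def unknowns(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == "unknown"]


def gen_plate(spec: PlateSpec) -> PlateData:
    """Standard wells at top/factor^i plus unknown wells; signals follow
    the true curve plus additive Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    concs = dilution_series(spec.top_standard, spec.dilution_factor,
                            spec.n_standards)
    truth = np.asarray(spec.curve_truth, dtype=float)

    def signal(c):
        return np.polyval(truth[::-1], c)

    rows = []
    for i, c in enumerate(concs):
        rows.append({"well": f"S{i + 1}", "role": "standard",
                     "conc": float(c),
                     "signal": float(signal(c)
                                     + rng.normal(0, spec.noise_sd))})
    for i, c in enumerate(spec.unknowns_truth):
        rows.append({"well": f"U{i + 1}", "role": "unknown",
                     "conc": float(c),
                     "signal": float(signal(c)
                                     + rng.normal(0, spec.noise_sd))})
    return PlateData(wells=pd.DataFrame(rows), spec=spec)


# --------------------------------------------------------------------------
# qPCR

@dataclass(frozen=True)
class CtDesign:
    """Six-group transient-inflammation qPCR design.

    effect_logfc maps gene -> {group -> log2 fold change vs CTL}; the
    reference gene must have zero effect everywhere, and the RES96
    (fully resolved) group is forced to zero effect so the resolution
    pattern is reproducible.  Per-sample loading offsets (same shift for
    every gene of a sample) emulate pipetting differences; the
    comparative Ct method must cancel them.
    """

    groups: tuple = CT_GROUPS
    genes: tuple = ("IL6", "TNF", "ACTB")
    reference_gene: str = "ACTB"
    baseline_ct: float = 22.0
    effect_logfc: dict = field(default_factory=dict)
    ct_noise_sd: float = 0.0
    loading_offset_sd: float = 0.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_gene not in self.genes:
            raise ValueError(
                f"reference gene {self.reference_gene!r} missing from genes")
        if self.replicates < 2:
            raise ValueError(
                f"replicates must be >= 2, got {self.replicates}")
        ref_effects = self.effect_logfc.get(self.reference_gene, {})
        if any(v != 0 for v in ref_effects.values()):
            raise ValueError("reference gene must have zero effect_logfc "
                             "in every group")


def gen_ct_table(design: CtDesign) -> pd.DataFrame:
    """Long-format Ct table (sample, group, gene, ct).

    Ct = baseline - effect_logfc + loading offset + noise: one PCR cycle
    less per two-fold expression increase.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for group in design.groups:
        for rep in range(design.replicates):
            sample = f"{group}_{rep + 1}"
            offset = rng.normal(0, design.loading_offset_sd) \
                if design.loading_offset_sd > 0 else 0.0
            for gene in design.genes:
                logfc = design.effect_logfc.get(gene, {}).get(group, 0.0)
                if group == "RES96" and "RES96" in design.groups:
                    logfc = 0.0  # resolved state
                noise = rng.normal(0, design.ct_noise_sd) \
                    if design.ct_noise_sd > 0 else 0.0
                rows.append({"sample": sample, "group": group, "gene": gene,
                             "ct": design.baseline_ct - logfc + offset
                             + noise})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# image stacks

@dataclass(frozen=True)
class ImageSpec:
    """Planted two-channel stack: nuclei blobs plus ramified microglia.

    Microglial somata are disks of ``soma_radius_px`` with ``n_arms``
    line ramifications of ``arm_len_px``; each soma overlaps exactly one
    nucleus.  The default soma radius (12 px, area ~452 px) is sized to
    clear the 400-pixel particle cutoff after DAPI gating.  Intensities
    are 8-bit.
    """

    shape: tuple = (320, 320)
    n_slices: int = 6
    n_microglia: int = 10
    n_other_nuclei: int = 15
    soma_radius_px: int = 12
    n_arms: int = 4
    arm_len_px: int = 25
    background_level: float = 10.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_slices <= 16:
            raise ValueError(f"n_slices must be in [1, 16], "
                             f"got {self.n_slices}")
        if self.n_microglia < 0 or self.n_other_nuclei < 0:
            raise ValueError("object counts must be >= 0")
        if not 3 <= self.n_arms <= 5:
            raise ValueError(f"n_arms must be in [3, 5], got {self.n_arms}")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("intensities must be >= 0")


@dataclass
class GroundTruth:
    """Planted object geometry of a synthetic stack."""

    microglia_centers: list
    nuclei_centers: list

    @property
    def n_microglia(self) -> int:
        return len(self.microglia_centers)


class OvercrowdedError(RuntimeError):
    """Objects could not be placed without overlap within the retry
    budget."""


DILATION_MARGIN = 5  # matches the default DAPI-selection dilation radius


def _place_centers(n: int, shape: tuple, margin: float, min_dist: float,
                   rng: np.random.Generator,
                   existing: list | None = None) -> list:
    centers = list(existing) if existing else []
    placed = []
    h, w = shape
    tries = 0
    budget = 400 * max(n, 1)
    while len(placed) < n:
        if tries > budget:
            raise OvercrowdedError(
                f"could not place {n} objects of exclusion radius "
                f"{min_dist / 2:.0f}px in a {h}x{w} frame")
        tries += 1
        c = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if all(np.hypot(c[0] - o[0], c[1] - o[1]) >= min_dist
               for o in centers):
            centers.append(c)
            placed.append(c)
    return placed


def _add_gaussian_blob(img: np.ndarray, center: tuple, sigma: float,
                       peak: float) -> None:
    h, w = img.shape
    r = int(np.ceil(4 * sigma))
    y0, x0 = int(round(center[0])), int(round(center[1]))
    ys = slice(max(0, y0 - r), min(h, y0 + r + 1))
    xs = slice(max(0, x0 - r), min(w, x0 + r + 1))
    yy, xx = np.mgrid[ys, xs]
    img[ys, xs] += peak * np.exp(
        -((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma ** 2))


def _add_disk(img: np.ndarray, center: tuple, radius: float,
              value: float) -> None:
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2
    img[mask] = np.maximum(img[mask], value)


def _add_arm(img: np.ndarray, center: tuple, angle: float, start: float,
             length: float, value: float, width: int = 1) -> None:
    h, w = img.shape
    steps = int(length * 2)
    for s in np.linspace(start, start + length, steps):
        y = int(round(center[0] + s * np.sin(angle)))
        x = int(round(center[1] + s * np.cos(angle)))
        for dy in range(-width, width + 1):
            for dx in range(-width, width + 1):
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w:
                    img[yy, xx] = max(img[yy, xx], value)


def gen_image_stack(spec: ImageSpec) -> tuple:
    """Render the stack and return it with its ground truth.

    Channel 1 (DAPI) contains n_microglia + n_other_nuclei nuclei;
    channel 2 (Iba1) contains the microglial somata (each overlapping
    its nucleus) and their ramifications.  Object intensity is spread
    over slices with a Gaussian profile around a random center slice so
    that a maximum projection recovers the full brightness.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    margin = spec.soma_radius_px + spec.arm_len_px + 2
    min_dist = 2 * (spec.soma_radius_px + DILATION_MARGIN) + 4

    mg_centers = _place_centers(spec.n_microglia, spec.shape, margin,
                                min_dist, rng)
    nuc_margin = 2 * spec.soma_radius_px + 2  # keep whole blob in frame
    other_centers = _place_centers(spec.n_other_nuclei, spec.shape,
                                   nuc_margin, min_dist, rng,
                                   existing=mg_centers)

    dapi_flat = np.zeros((h, w))
    iba1_flat = np.zeros((h, w))
    nuc_sigma = spec.soma_radius_px / 2.0
    for c in mg_centers + other_centers:
        _add_gaussian_blob(dapi_flat, c, nuc_sigma, 180.0)
    for c in mg_centers:
        _add_disk(iba1_flat, c, spec.soma_radius_px, 200.0)
        angles = rng.uniform(0, 2 * np.pi) + \
            np.arange(spec.n_arms) * 2 * np.pi / spec.n_arms
        for a in angles:
            _add_arm(iba1_flat, c, a, spec.soma_radius_px - 1,
                     spec.arm_len_px, 150.0)

    # spread across slices with per-object focus profiles
    z_centers = rng.uniform(1, spec.n_slices - 2 if spec.n_slices > 2
                            else spec.n_slices - 1,
                            size=max(len(mg_centers) + len(other_centers), 1))
    z_profile = np.exp(-0.5 * ((np.arange(spec.n_slices)
                                - z_centers.mean()) / 1.5) ** 2)
    z_profile /= z_profile.max()

    dapi = np.empty((spec.n_slices, h, w))
    iba1 = np.empty((spec.n_slices, h, w))
    for k in range(spec.n_slices):
        dapi[k] = spec.background_level + z_profile[k] * dapi_flat
        iba1[k] = spec.background_level + z_profile[k] * iba1_flat
        if spec.noise_sd > 0:
            dapi[k] += rng.normal(0, spec.noise_sd, size=(h, w))
            iba1[k] += rng.normal(0, spec.noise_sd, size=(h, w))

    dapi = np.clip(dapi, 0, 255).astype(np.uint8)
    iba1 = np.clip(iba1, 0, 255).astype(np.uint8)
    stack = ImageStack(dapi=dapi, iba1=iba1)
    truth = GroundTruth(microglia_centers=mg_centers,
                        nuclei_centers=mg_centers + other_centers)
    return stack, truth


# --------------------------------------------------------------------------
# oxygen profiles

@dataclass(frozen=True)
class O2ProfileSpec:
    """Depth profile with a planted concentration minimum at the core."""

    n_steps: int = 8
    step_advance_um: float = 20.0
    angle_deg: float = 55.0
    surface_conc: float = 150.0
    core_conc: float = 60.0
    core_step_index: int = 5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.core_conc > self.surface_conc:
            raise ValueError(
                f"core_conc ({self.core_conc}) must not exceed "
                f"surface_conc ({self.surface_conc})")
        if not 0 <= self.core_step_index < self.n_steps:
            raise ValueError(
                f"core_step_index {self.core_step_index} outside "
                f"[0, {self.n_steps})")


def gen_o2_profile(spec: O2ProfileSpec) -> O2Profile:
    """Quadratic descent to the core with partial symmetric recovery.

    Before noise, the profile has its unique minimum exactly at
    core_step_index (flat if surface_conc == core_conc).  The depth axis
    follows the tilted-probe geometry.
    """
    rng = np.random.default_rng(spec.seed)
    i = np.arange(spec.n_steps, dtype=float)
    c = spec.core_step_index
    amp = spec.surface_conc - spec.core_conc
    denom_left = max(c, 1)
    denom_right = max(spec.n_steps - 1 - c, 1)
    rel = np.where(i <= c, (c - i) / denom_left, (i - c) / denom_right)
    conc = spec.core_conc + amp * np.clip(rel, 0, 1) ** 2
    if spec.noise_sd > 0:
        conc = conc + rng.normal(0, spec.noise_sd, size=spec.n_steps)
    return O2Profile(step_index=np.arange(spec.n_steps),
                     depth_um=depth_axis(spec.n_steps, spec.step_advance_um,
                                         spec.angle_deg),
                     concentration=conc)


# --------------------------------------------------------------------------
# serialization (plain-text and TIFF formats)

def save_plate(plate: PlateData, path) -> None:
    plate.wells.to_csv(path, index=False)


def load_plate(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_ct(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, index=False)


def load_ct(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_image_stack(stack: ImageStack, path) -> None:
    """Multi-page TIFF: all DAPI slices, then all Iba1 slices."""
    pages = np.concatenate([stack.dapi, stack.iba1], axis=0)
    tifffile.imwrite(path, pages,
                     metadata={"n_slices": int(stack.dapi.shape[0]),
                               "channels": "dapi,iba1"})


def load_image_stack(path, n_slices: int | None = None) -> ImageStack:
    pages = tifffile.imread(path)
    if n_slices is None:
        n_slices = pages.shape[0] // 2
    return ImageStack(dapi=pages[:n_slices], iba1=pages[n_slices:])


def save_o2_profile(profile: O2Profile, path) -> None:
    pd.DataFrame({"step_index": profile.step_index,
                  "depth_um": profile.depth_um,
                  "concentration": profile.concentration}).to_csv(
        path, index=False)


def load_o2_profile(path) -> O2Profile:
    df = pd.read_csv(path)
    return O2Profile(step_index=df["step_index"].to_numpy(),
                     depth_um=df["depth_um"].to_numpy(),
                     concentration=df["concentration"].to_numpy())
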