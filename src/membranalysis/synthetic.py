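"""Synthetic SAXS curves, DSC endotherms and GUV image stacks.

Each generator draws from the forward model of its analysis stage with a
known ground truth and a conventional instrument noise model:

* SAXS — multiplicative Gaussian noise (relative uncertainty roughly
  constant over the measured range), sigma_I = noise_fraction * I_model;
* DSC — a two-state van't Hoff endotherm plus a linear instrumental
  baseline and additive Gaussian noise;
* GUV imaging — channels built by inverting the GP definition from a known
  GP map, with per-pixel Poisson (photon-counting) noise.

Noiseless output is exactly invertible by the corresponding analysis
operation, which anchors the recovery tests.  The presets pin the
generators to the regimes of a ternary DOPC/DPPC/cholesterol (23:47:30)
suspension at 30 °C: a partly multilamellar control (about half
unilamellar vesicles, d-spacing ≈ 66 Å, d_B ≈ 50 Å), the same system
shifted by 10 mol% artepillin C (≈ 87 % unilamellar, thinner bilayer,
larger d-spacing), broad endotherms with Tm between 32.6 and 36.5 °C, and
phase-separated giant vesicles with distinct l_o / l_d GP levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dsc import TWO_STATE_FWHM_COEFF
from .formats_io import GAS_CONSTANT_CAL, ScatteringCurve, Thermogram, TwoChannelImage
from .saxs import BilayerModel, model_intensity

#: the factor-4 van't Hoff rule over-reports a two-state enthalpy by this
#: much; presets quoting a factor-4 value are de-biased by its inverse so
#: the analysis chain reproduces the quoted number.
VANT_HOFF_BIAS = 4.0 / TWO_STATE_FWHM_COEFF


@dataclass
class GroundTruth:
    """Generating parameters embedded in every synthetic record."""

    kind: str
    params: dict
    seed: int


def default_q_grid(n: int = 400) -> np.ndarray:
    """q grid matching the instrument window 0.15–4.47 nm⁻¹ (in Å⁻¹)."""
    return np.linspace(0.015, 0.447, n)


def simulate_saxs_curve(
    truth: BilayerModel,
    q_grid: np.ndarray | None = None,
    noise_fraction: float = 0.01,
    seed: int = 0,
) -> tuple[ScatteringCurve, GroundTruth]:
    """Simulate a vesicle-suspension SAXS curve from a known bilayer model.

    I = I_model * (1 + eps) with eps ~ Normal(0, noise_fraction);
    sigma_I = noise_fraction * I_model.  With noise_fraction = 0 the curve
    equals the model exactly (sigma_I is then floored at a vanishingly
    small positive value to keep uncertainties usable as weights).
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    i_model = model_intensity(q, truth)
    rng = np.random.default_rng(seed)
    if noise_fraction > 0:
        eps = rng.normal(0.0, noise_fraction, size=q.shape)
        intensity = i_model * (1.0 + eps)
        sigma = noise_fraction * i_model
    else:
        intensity = i_model.copy()
        sigma = 1e-9 * i_model
    curve = ScatteringCurve(q=q, I=intensity, sigma_I=sigma)
    gt = GroundTruth(
        kind="saxs",
        params={"model": truth, "noise_fraction": noise_fraction},
        seed=seed,
    )
    return curve, gt


def simulate_thermogram(
    Tm: float,
    dH_cal: float,
    dH_vH_true: float,
    T_grid: np.ndarray | None = None,
    baseline_slope: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    R: float = GAS_CONSTANT_CAL,
) -> tuple[Thermogram, GroundTruth]:
    """Simulate a two-state excess heat-capacity endotherm.

    K(T) = exp[-(dH_vH/R)(1/T - 1/Tm)] and
    Cp(T) = dH_cal * dH_vH / (R T^2) * K/(1+K)^2, in kcal/mol/K, plus a
    linear baseline ``baseline_slope * T`` and additive Gaussian noise.
    The grid must cover Tm ± 5 half-widths or the integral would miss
    enthalpy.
    """
    r_kcal = R / 1000.0
    fwhm = TWO_STATE_FWHM_COEFF * r_kcal * Tm**2 / dH_vH_true
    if T_grid is None:
        T = np.arange(Tm - 6.0 * fwhm, Tm + 6.0 * fwhm, 0.01)
    else:
        T = np.asarray(T_grid, dtype=float)
    if T[0] > Tm - 5.0 * fwhm or T[-1] < Tm + 5.0 * fwhm:
        raise ValueError(
            f"grid too narrow: need coverage of Tm ± {5 * fwhm:.2f} K around {Tm} K"
        )
    ln_k = -(dH_vH_true / r_kcal) * (1.0 / T - 1.0 / Tm)
    k = np.exp(ln_k)
    theta_prime = k / (1.0 + k) ** 2
    cp = dH_cal * dH_vH_true / (r_kcal * T**2) * theta_prime
    cp = cp + baseline_slope * T
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        cp = cp + rng.normal(0.0, noise_sd, size=T.shape)
    tg = Thermogram(T=T, Cp=cp, scan_rate=0.5)
    gt = GroundTruth(
        kind="dsc",
        params={
            "Tm": Tm,
            "dH_cal": dH_cal,
            "dH_vH_true": dH_vH_true,
            "baseline_slope": baseline_slope,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return tg, gt


def simulate_guv_frames(
    image_size_px: int = 128,
    radius_px: float = 40.0,
    ring_width_px: float = 5.0,
    arc_fraction_lo: float = 1.0 / 3.0,
    gp_lo: float = 0.45,
    gp_ld: float = 0.05,
    mean_counts: float = 500.0,
    g_factor: float = 1.0,
    background_counts: float = 2.0,
    n_frames: int = 1,
    step_frame: int | None = None,
    step_delta_gp: float = 0.0,
    poisson_noise: bool = True,
    seed: int = 0,
) -> tuple[list[TwoChannelImage], GroundTruth]:
    """Simulate equatorial GUV frames with coexisting l_o / l_d domains.

    The vesicle is an annulus of mean total intensity ``mean_counts`` on a
    dim background; an arc covering ``arc_fraction_lo`` of the ring carries
    GP ``gp_lo`` and the remainder ``gp_ld``.  Channels follow from
    inverting the GP definition: I440 = S*(1+GP)/2 and
    I490 = S*(1-GP)/(2*g_factor), then per-pixel Poisson noise.  From
    ``step_frame`` on, both phase GPs are raised by ``step_delta_gp``
    (mimicking a dehydrating additive reaching the membrane).  Timestamps
    count minutes, one per frame.
    """
    if radius_px + ring_width_px >= image_size_px / 2.0:
        raise ValueError("ring does not fit in the frame")
    if not 0.0 <= arc_fraction_lo <= 1.0:
        raise ValueError("arc_fraction_lo must lie in [0, 1]")

    c = (image_size_px - 1) / 2.0
    yy, xx = np.indices((image_size_px, image_size_px))
    r = np.hypot(yy - c, xx - c)
    theta = np.mod(np.arctan2(yy - c, xx - c), 2.0 * math.pi)
    ring = np.abs(r - radius_px) <= ring_width_px / 2.0
    lo_arc = ring & (theta < 2.0 * math.pi * arc_fraction_lo)

    rng = np.random.default_rng(seed)
    frames: list[TwoChannelImage] = []
    for t in range(n_frames):
        delta = step_delta_gp if (step_frame is not None and t >= step_frame) else 0.0
        gp_map = np.zeros((image_size_px, image_size_px))
        gp_map[ring] = gp_ld + delta
        gp_map[lo_arc] = gp_lo + delta
        if np.any(np.abs(gp_map) >= 1.0):
            raise ValueError("generated |GP| must stay below 1")
        s = np.where(ring, mean_counts, background_counts)
        i440 = s * (1.0 + gp_map) / 2.0
        i490 = s * (1.0 - gp_map) / (2.0 * g_factor)
        if poisson_noise:
            i440 = rng.poisson(i440).astype(float)
            i490 = rng.poisson(i490).astype(float)
        frames.append(TwoChannelImage(I440=i440, I490=i490, timestamp=float(t)))

    gt = GroundTruth(
        kind="guv",
        params={
            "radius_px": radius_px,
            "ring_width_px": ring_width_px,
            "arc_fraction_lo": arc_fraction_lo,
            "gp_lo": gp_lo,
            "gp_ld": gp_ld,
            "mean_counts": mean_counts,
            "g_factor": g_factor,
            "step_frame": step_frame,
            "step_delta_gp": step_delta_gp,
        },
        seed=seed,
    )
    return frames, gt


# ---------------------------------------------------------------------------
# presets pinning the generators to the studied regimes


def _bilayer(**kw) -> BilayerModel:
    return BilayerModel(**kw)


SAXS_PRESETS: dict[str, BilayerModel] = {
    # control suspension: ~half unilamellar, d_B = 2*(20.1 + 2*2.5) = 50.2 Å
    "control": _bilayer(
        z_H=20.1, sigma_H=2.5, rho_C=-1.2, sigma_C=4.0,
        d=65.8, N_layers=5, eta=0.1, N_UV=0.52, scale=1e-3, background=0.01,
    ),
    # +10 mol% artepillin C: mostly unilamellar, thinner bilayer
    # (d_B = 2*(19.6 + 2*2.2) = 48.0 Å), swollen d-spacing
    "artepillin_10molpct": _bilayer(
        z_H=19.6, sigma_H=2.2, rho_C=-1.2, sigma_C=4.0,
        d=71.4, N_layers=3, eta=0.15, N_UV=0.87, scale=1e-3, background=0.01,
    ),
}

# DSC presets quote factor-4 van't Hoff values; the underlying two-state
# enthalpy is that value times 3.5255/4, so that the analysis chain
# (FWHM measurement + factor-4 rule) returns the quoted number.
DSC_PRESETS: dict[str, dict] = {
    "dsc_control": {"Tm": 305.75, "dH_cal": 1.4, "dH_vH_true": 75.8 / VANT_HOFF_BIAS},
    "dsc_artepillin_5molpct": {"Tm": 308.05, "dH_cal": 1.3, "dH_vH_true": 54.1 / VANT_HOFF_BIAS},
    "dsc_artepillin_10molpct": {"Tm": 309.65, "dH_cal": 1.4, "dH_vH_true": 41.2 / VANT_HOFF_BIAS},
}

GUV_PRESETS: dict[str, dict] = {
    "guv_phase_step": {
        "image_size_px": 128,
        "radius_px": 40.0,
        "ring_width_px": 5.0,
        "arc_fraction_lo": 1.0 / 3.0,
        "gp_lo": 0.45,
        "gp_ld": 0.05,
        "mean_counts": 500.0,
        "g_factor": 1.0,
        "n_frames": 6,
        "step_frame": 3,
        "step_delta_gp": 0.05,
    },
}
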