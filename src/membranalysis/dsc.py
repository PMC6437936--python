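"""Thermotropic analysis of DSC endotherms.

Extracts, from a baseline-subtracted excess heat-capacity trace, the main
transition temperature ``Tm``, the full width at half maximum ``T_1/2``,
the calorimetric enthalpy ``dH_cal`` (peak area) and the van't Hoff
enthalpy via the classic approximation

    dH_vH ≈ 4 * R * Tm^2 / T_1/2.

The cooperative unit CU = dH_vH / dH_cal estimates how many lipids melt
together; it tends to infinity for a perfectly cooperative first-order
transition and to zero for a non-cooperative one.

Note on the factor 4: for an exact two-state transition the half-width
obeys T_1/2 = 4*ln(3+2*sqrt(2)) * R * Tm^2 / dH_vH ≈ 3.5255*R*Tm^2/dH_vH,
so the factor-4 approximation over-reports dH_vH by 4/3.5255 ≈ 1.134.
The approximation is the field's convention and is kept as is; the bias is
characterised by the test suite rather than corrected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .formats_io import GAS_CONSTANT_CAL, Thermogram

logger = logging.getLogger("membranalysis")

#: 2*ln(3 + 2*sqrt(2)) ≈ 3.5255 — exact two-state FWHM coefficient in
#: T_1/2 = c * R * Tm^2 / dH_vH; the half-maximum points of K/(1+K)^2
#: sit at K = 3 ± 2*sqrt(2), i.e. ln K = ±1.7627.
TWO_STATE_FWHM_COEFF = 2.0 * math.log(3.0 + 2.0 * math.sqrt(2.0))


@dataclass
class TransitionParams:
    """Extracted thermodynamic parameters of one endotherm."""

    Tm: float  # K
    T_half: float  # full width at half maximum, K
    dH_cal: float  # calorimetric enthalpy, kcal/mol
    dH_vH: float  # van't Hoff enthalpy, kcal/mol
    CU: float  # cooperative unit, dimensionless


@dataclass
class ReplicateSummary:
    """Mean ± sample SD of transition parameters over repeated scans."""

    mean: TransitionParams
    sd: TransitionParams
    n_scans: int
    n_excluded: int


def subtract_baseline(
    tg: Thermogram, T_low: float, T_high: float, anchor_window_K: float = 0.0
) -> Thermogram:
    """Subtract a linear chord through (T_low, Cp) and (T_high, Cp).

    Cp outside [T_low, T_high] is zeroed; the output is flagged
    baseline-subtracted.  Both anchors must lie inside the scan range.

    ``anchor_window_K`` > 0 averages Cp over a window of that width around
    each anchor instead of reading a single (possibly noisy) point; on a
    noisy scan a single-point anchor error integrates into a proportional
    enthalpy error over the whole window.
    """
    if not (tg.T[0] <= T_low < T_high <= tg.T[-1]):
        raise ValueError(
            f"baseline anchors [{T_low}, {T_high}] outside scan range "
            f"[{tg.T[0]}, {tg.T[-1]}]"
        )

    def anchor(t0: float) -> float:
        if anchor_window_K > 0:
            sel = np.abs(tg.T - t0) <= anchor_window_K / 2.0
            if sel.any():
                return float(tg.Cp[sel].mean())
        return float(np.interp(t0, tg.T, tg.Cp))

    cp_low = anchor(T_low)
    cp_high = anchor(T_high)
    slope = (cp_high - cp_low) / (T_high - T_low)
    chord = cp_low + slope * (tg.T - T_low)
    cp = tg.Cp - chord
    cp[(tg.T < T_low) | (tg.T > T_high)] = 0.0
    return Thermogram(T=tg.T.copy(), Cp=cp, scan_rate=tg.scan_rate, baseline_subtracted=True)


def _parabolic_refine(T: np.ndarray, Cp: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through the three points around index i.

    Fitted in coordinates centred on the middle point: absolute kelvin
    values (~300) with millikelvin spacing would otherwise lose the vertex
    to cancellation.
    """
    if i == 0 or i == len(T) - 1:
        return float(T[i]), float(Cp[i])
    x0, x2 = T[i - 1] - T[i], T[i + 1] - T[i]
    y0, y1, y2 = Cp[i - 1], Cp[i], Cp[i + 1]
    # y = y1 + b*x + a*x^2 through (x0, y0) and (x2, y2)
    a = ((y0 - y1) / x0 - (y2 - y1) / x2) / (x0 - x2)
    b = ((y0 - y1) * x2 / x0 - (y2 - y1) * x0 / x2) / (x2 - x0)
    if a >= 0:  # not a maximum; keep the discrete point
        return float(T[i]), float(y1)
    xv = -b / (2.0 * a)
    return float(T[i] + xv), float(y1 + b * xv + a * xv**2)


def transition_parameters(
    tg: Thermogram, T_low: float, T_high: float, smooth_window_K: float = 0.0
) -> tuple[float, float, float]:
    """Extract (Tm, T_half, dH_cal) from a baseline-subtracted endotherm.

    Tm comes from a three-point parabolic refinement of the discrete
    maximum; T_half from linearly interpolated half-maximum crossings on
    either side of the peak; dH_cal from the trapezoidal integral of Cp
    over [T_low, T_high].

    ``smooth_window_K`` > 0 applies a quadratic Savitzky-Golay filter of
    that temperature width to the curve used for peak location and width
    (point noise otherwise triggers the half-maximum crossings early on
    densely sampled scans); the enthalpy integral always uses the raw
    trace.  The window should stay well below the transition width.
    """
    if not tg.baseline_subtracted:
        raise ValueError("thermogram must be baseline-subtracted first")
    sel = (tg.T >= T_low) & (tg.T <= T_high)
    T, Cp_raw = tg.T[sel], tg.Cp[sel]
    if T.size < 5:
        raise ValueError("analysis window contains too few points")

    Cp = Cp_raw
    if smooth_window_K > 0:
        from scipy.signal import savgol_filter

        step = float(np.median(np.diff(T)))
        wl = max(5, int(round(smooth_window_K / step)) | 1)
        if wl < T.size:
            Cp = savgol_filter(Cp_raw, window_length=wl, polyorder=2)

    i_max = int(np.argmax(Cp))
    Tm, cp_max = _parabolic_refine(T, Cp, i_max)
    half = cp_max / 2.0

    below_left = np.where(Cp[:i_max] < half)[0]
    below_right = np.where(Cp[i_max:] < half)[0]
    if below_left.size == 0 or below_right.size == 0:
        raise ValueError("peak truncated: half maximum not crossed on both sides")
    iL = below_left[-1]  # last point below half on the left flank
    t_left = T[iL] + (half - Cp[iL]) * (T[iL + 1] - T[iL]) / (Cp[iL + 1] - Cp[iL])
    iR = i_max + below_right[0]  # first point below half on the right flank
    t_right = T[iR - 1] + (half - Cp[iR - 1]) * (T[iR] - T[iR - 1]) / (Cp[iR] - Cp[iR - 1])
    t_half = float(t_right - t_left)

    dh_cal = float(np.trapezoid(Cp_raw, T))
    return float(Tm), t_half, dh_cal


def vant_hoff_enthalpy(Tm: float, T_half: float, R: float = GAS_CONSTANT_CAL) -> float:
    """van't Hoff enthalpy 4*R*Tm^2/T_half in kcal/mol (R in cal/mol/K)."""
    if not Tm > 0:
        raise ValueError("Tm must be positive (kelvin)")
    if not T_half > 0:
        raise ValueError("T_half must be positive")
    return 4.0 * R * Tm**2 / T_half / 1000.0


def cooperative_unit(dH_vH: float, dH_cal: float) -> float:
    """Cooperative unit dH_vH/dH_cal (both in the same enthalpy units)."""
    if not dH_cal > 0:
        raise ValueError("dH_cal must be positive")
    return dH_vH / dH_cal


def analyze_scan(
    tg: Thermogram, T_low: float, T_high: float, R: float = GAS_CONSTANT_CAL,
    smooth_window_K: float = 0.0, anchor_window_K: float = 0.0,
) -> TransitionParams:
    """Full single-scan chain: baseline, peak parameters, dH_vH, CU."""
    work = (
        tg
        if tg.baseline_subtracted
        else subtract_baseline(tg, T_low, T_high, anchor_window_K)
    )
    tm, t_half, dh_cal = transition_parameters(work, T_low, T_high, smooth_window_K)
    dh_vh = vant_hoff_enthalpy(tm, t_half, R)
    cu = cooperative_unit(dh_vh, dh_cal)
    return TransitionParams(Tm=tm, T_half=t_half, dH_cal=dh_cal, dH_vH=dh_vh, CU=cu)


def analyze_replicates(
    scans: list[Thermogram], T_low: float, T_high: float, R: float = GAS_CONSTANT_CAL,
    smooth_window_K: float = 0.0, anchor_window_K: float = 0.0,
) -> ReplicateSummary:
    """Run the full chain on each scan and summarise as mean ± sample SD.

    Scans that fail (e.g. truncated peaks) are excluded with a logged
    reason; at least two must survive.  CU's spread comes from the
    per-scan CU values, not from the ratio of the mean enthalpies.
    """
    if len(scans) < 2:
        raise ValueError("at least 2 scans required")
    results: list[TransitionParams] = []
    n_excluded = 0
    for i, tg in enumerate(scans):
        try:
            results.append(
                analyze_scan(tg, T_low, T_high, R, smooth_window_K, anchor_window_K)
            )
        except ValueError as exc:
            n_excluded += 1
            logger.warning("scan %d excluded: %s", i, exc)
    if len(results) < 2:
        raise ValueError(f"only {len(results)} scans analyzable; at least 2 required")

    fields = ("Tm", "T_half", "dH_cal", "dH_vH", "CU")
    cols = {f: np.array([getattr(r, f) for r in results]) for f in fields}
    mean = TransitionParams(**{f: float(np.mean(cols[f])) for f in fields})
    sd = TransitionParams(**{f: float(np.std(cols[f], ddof=1)) for f in fields})
    return ReplicateSummary(mean=mean, sd=sd, n_scans=len(results), n_excluded=n_excluded)


def round_for_report(params: TransitionParams) -> dict:
    """Presentation rounding: CU to nearest integer, enthalpies to 3 s.f."""

    def sig3(x: float) -> float:
        if x == 0:
            return 0.0
        return float(f"{x:.3g}")

    return {
        "Tm_C": round(params.Tm - 273.15, 1),
        "T_half_K": sig3(params.T_half),
        "dH_cal_kcal_mol": sig3(params.dH_cal),
        "dH_vH_kcal_mol": sig3(params.dH_vH),
        "CU": int(round(params.CU)),
    }
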