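"""Small-angle X-ray scattering of vesicle suspensions.

A suspension of extruded phospholipid vesicles generally contains both
unilamellar vesicles, which scatter diffusely, and residual multilamellar
(oligolamellar) stacks, which produce quasi-Bragg peaks.  The measured
intensity is modelled as the incoherent mixture

    I(q) = scale * [ (1 - N_UV) * S(q) * |F(q)|^2 / q^2
                     + N_UV * |F(q)|^2 / q^2 ] + background,

where ``N_UV`` is the fraction of positionally non-correlated (unilamellar)
scatterers, ``F(q)`` the bilayer form factor and ``S(q)`` the inter-bilayer
structure factor of the lamellar stacks.

The transverse electron-density contrast of the bilayer is a symmetric
three-Gaussian profile: two positive headgroup Gaussians at ``±z_H`` of
width ``sigma_H`` and one (normally negative) methyl/chain Gaussian of
relative amplitude ``rho_C`` and width ``sigma_C`` at the centre.  Its
Fourier transform is analytic::

    F(q) = sqrt(2*pi) * [ 2*sigma_H*exp(-sigma_H^2 q^2/2)*cos(q z_H)
                          + rho_C*sigma_C*exp(-sigma_C^2 q^2/2) ].

``S(q)`` follows modified Caillé theory for a stack of ``N`` bilayers with
repeat distance ``d`` and bending-fluctuation parameter ``eta``.

The membrane (Luzzati-style steric) thickness is derived from the
headgroup parameters as ``d_B = 2*(z_H + 2*sigma_H)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import lmfit

from .formats_io import ScatteringCurve

EULER_GAMMA = 0.5772156649
_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass
class BilayerModel:
    """Electron-density and lamellar-stack parameters of one bilayer system.

    Lengths are in Å; ``rho_C`` is the chain-region amplitude relative to
    the headgroup amplitude (negative for phosphatidylcholines, since the
    terminal-methyl region is electron poor relative to water).
    """

    z_H: float  # headgroup position from bilayer centre, Å
    sigma_H: float  # headgroup Gaussian width, Å
    rho_C: float  # chain amplitude relative to headgroup (dimensionless)
    sigma_C: float  # chain Gaussian width, Å
    d: float  # lamellar repeat (d-spacing), Å
    N_layers: int  # mean bilayers per correlated stack
    eta: float  # Caillé bending-fluctuation parameter
    N_UV: float  # unilamellar (diffuse) fraction, in [0, 1]
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if not self.z_H > 0:
            raise ValueError("z_H must be positive")
        if not self.sigma_H > 0:
            raise ValueError("sigma_H must be positive")
        if not self.sigma_C > 0:
            raise ValueError("sigma_C must be positive")
        if not 0.0 <= self.N_UV <= 1.0:
            raise ValueError("N_UV must lie in [0, 1]")
        if not self.d > 2.0 * self.z_H:
            raise ValueError("d must exceed 2*z_H (bilayers cannot interpenetrate)")
        if int(self.N_layers) != self.N_layers or self.N_layers < 1:
            raise ValueError("N_layers must be an integer >= 1")
        self.N_layers = int(self.N_layers)
        if not self.eta >= 0:
            raise ValueError("eta must be >= 0")
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        if self.background < 0:
            raise ValueError("background must be >= 0")


@dataclass
class SAXSFit:
    """Point estimate, uncertainties and derived quantities of one fit."""

    model: BilayerModel
    uncertainties: dict
    chi2_reduced: float
    d_B: float  # 2*(z_H + 2*sigma_H), Å
    n_uv_percent: float
    d_B_err: float | None = None
    at_bounds: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# forward model


def form_factor(q, model: BilayerModel):
    """Bilayer form factor F(q): analytic FT of the three-Gaussian profile.

    Even in q; F(0) = sqrt(2*pi)*(2*sigma_H + rho_C*sigma_C).
    """
    q = np.asarray(q, dtype=float)
    head = 2.0 * model.sigma_H * np.exp(-0.5 * model.sigma_H**2 * q**2) * np.cos(q * model.z_H)
    chain = model.rho_C * model.sigma_C * np.exp(-0.5 * model.sigma_C**2 * q**2)
    return _SQRT_2PI * (head + chain)


def _structure_factor_raw(q, d: float, n_layers: int, eta: float):
    """Modified Caillé structure factor of an N-bilayer stack (unfloored)."""
    q = np.asarray(q, dtype=float)
    if n_layers < 1:
        raise ValueError("N_layers must be >= 1")
    if n_layers == 1:
        return np.ones_like(q)
    # Caillé exponent (d/2pi)^2 q^2 eta, shared by the damping and the
    # algebraic (pi*k)^-x peak-shape term
    x = (d / (2.0 * math.pi)) ** 2 * q**2 * eta
    k = np.arange(1, n_layers)
    # outer products: shape (nq, nk)
    cos_term = np.cos(np.outer(q * d, k))
    damping = np.exp(-x * EULER_GAMMA)[:, None] * np.power(math.pi * k[None, :], -x[:, None])
    s = n_layers + 2.0 * np.sum((n_layers - k)[None, :] * cos_term * damping, axis=1)
    return s


def structure_factor(q, model: BilayerModel):
    """Inter-bilayer structure factor S(q) by modified Caillé theory.

    The truncated sum can ring slightly negative; callers mixing it into
    the intensity must floor it at zero (``model_intensity`` does).
    """
    return _structure_factor_raw(q, model.d, model.N_layers, model.eta)


def model_intensity(q, model: BilayerModel):
    """Mixture intensity of unilamellar and multilamellar scatterers."""
    q = np.asarray(q, dtype=float)
    if np.any(q == 0):
        raise ValueError("q = 0 is singular (1/q^2 factor)")
    f2 = form_factor(q, model) ** 2
    s = np.maximum(structure_factor(q, model), 0.0)
    diffuse = f2 / q**2
    return model.scale * ((1.0 - model.N_UV) * s * diffuse + model.N_UV * diffuse) + model.background


def bilayer_thickness(z_H: float, sigma_H: float) -> float:
    """Membrane thickness d_B = 2*(z_H + 2*sigma_H), Å."""
    if z_H < 0 or sigma_H < 0:
        raise ValueError("z_H and sigma_H must be non-negative")
    return 2.0 * (z_H + 2.0 * sigma_H)


def electron_density_profile(model: BilayerModel, z_grid):
    """Relative electron-density contrast rho(z) across the bilayer.

    The grid must be symmetric about z = 0 so the evenness of the profile
    is representable on it.
    """
    z = np.asarray(z_grid, dtype=float)
    if not np.allclose(z + z[::-1], 0.0, atol=1e-9 * max(1.0, float(np.max(np.abs(z))))):
        raise ValueError("z_grid must be symmetric about 0")
    head = np.exp(-0.5 * ((z - model.z_H) / model.sigma_H) ** 2)
    head += np.exp(-0.5 * ((z + model.z_H) / model.sigma_H) ** 2)
    chain = model.rho_C * np.exp(-0.5 * (z / model.sigma_C) ** 2)
    return head + chain


def bragg_positions(d: float, orders) -> np.ndarray:
    """Quasi-Bragg peak positions k*2*pi/d (Å⁻¹) for the given orders."""
    if not d > 0:
        raise ValueError("d must be positive")
    orders = np.asarray(orders)
    if np.any(orders <= 0):
        raise ValueError("diffraction orders must be positive integers")
    return orders * 2.0 * math.pi / d


# ---------------------------------------------------------------------------
# fitting

_DEFAULT_BOUNDS = {
    "z_H": (5.0, 40.0),
    "sigma_H": (0.5, 8.0),
    "rho_C": (-5.0, -0.01),
    "sigma_C": (0.5, 12.0),
    "d": (40.0, 110.0),
    "eta": (0.0, 1.0),
    "N_UV": (0.0, 1.0),
    "scale": (1e-12, np.inf),
    "background": (0.0, np.inf),
}

_DEFAULT_FIT_OPTIONS = {
    "d_starts": (55.0, 60.0, 65.0, 70.0, 75.0, 80.0),
    "nuv_starts": (0.3, 0.7),
    "n_layers_range": (1, 2, 3, 4, 5, 6, 7),
    "scout_max_nfev": 200,  # bounded first pass over the full start grid
    "n_polish": 8,  # best starts refined to full precision
    "q_min": None,
    "q_max": None,
}

_FLOAT_PARAMS = ("z_H", "sigma_H", "rho_C", "sigma_C", "d", "eta", "N_UV", "scale", "background")


def _residual(params, q, I_obs, sigma, n_layers):
    p = params.valuesdict()
    f2 = (
        _SQRT_2PI
        * (
            2.0 * p["sigma_H"] * np.exp(-0.5 * p["sigma_H"] ** 2 * q**2) * np.cos(q * p["z_H"])
            + p["rho_C"] * p["sigma_C"] * np.exp(-0.5 * p["sigma_C"] ** 2 * q**2)
        )
    ) ** 2
    s = np.maximum(_structure_factor_raw(q, p["d"], n_layers, p["eta"]), 0.0)
    diffuse = f2 / q**2
    model = p["scale"] * ((1.0 - p["N_UV"]) * s * diffuse + p["N_UV"] * diffuse) + p["background"]
    return (model - I_obs) / sigma


def _make_params(init: BilayerModel, bounds: dict, d0: float, nuv0: float,
                 q, I_obs, sigma, n_layers) -> lmfit.Parameters:
    params = lmfit.Parameters()
    values = {
        "z_H": init.z_H,
        "sigma_H": init.sigma_H,
        "rho_C": init.rho_C,
        "sigma_C": init.sigma_C,
        "d": d0,
        "eta": init.eta,
        "N_UV": nuv0,
        "scale": init.scale,
        "background": init.background,
    }
    for name in _FLOAT_PARAMS:
        lo, hi = bounds[name]
        val = float(np.clip(values[name], lo if np.isfinite(lo) else None, hi if np.isfinite(hi) else None))
        params.add(name, value=val, min=lo, max=hi)
    # linear projection of the overall scale onto the data: with all shape
    # parameters held at their starts this is the weighted least-squares
    # optimum and makes the start grid scale-free
    params["scale"].value = 1.0
    resid0 = _residual(params, q, I_obs, sigma, n_layers) * sigma + I_obs  # model at scale 1
    m = resid0 - params["background"].value
    w = 1.0 / sigma**2
    denom = float(np.sum(w * m * m))
    if denom > 0:
        s0 = float(np.sum(w * m * (I_obs - params["background"].value)) / denom)
        lo, hi = bounds["scale"]
        params["scale"].value = float(np.clip(s0, max(lo, 1e-12), hi))
    return params


def fit_curve(
    curve: ScatteringCurve,
    init: BilayerModel,
    bounds: dict | None = None,
    fit_options: dict | None = None,
) -> SAXSFit:
    """Fit the vesicle-mixture model to a measured curve.

    Weighted least squares (weights 1/sigma_I^2) with a multi-start grid in
    the lamellar repeat and the unilamellar fraction, and an exhaustive
    loop over the integer stack size ``N_layers``.  The supplied ``init``
    provides the starting values of the remaining parameters and is itself
    included as a start.  Ties between stack sizes are broken by the lower
    reduced chi-square, then by the smaller ``N_layers``.

    Returns the best fit with per-parameter standard errors from the local
    quadratic approximation at the optimum.  Parameters that finish on a
    bound are listed in ``at_bounds``.
    """
    opts = dict(_DEFAULT_FIT_OPTIONS)
    opts.update(fit_options or {})
    bnds = dict(_DEFAULT_BOUNDS)
    bnds.update(bounds or {})

    work = curve.trim(opts["q_min"], opts["q_max"])
    q, I_obs, sigma = work.q, work.I, work.sigma_I
    if q.size < 50:
        raise ValueError(f"curve has {q.size} points; at least 50 required")
    if q[-1] / q[0] < 10.0:
        raise ValueError("curve must span at least one decade in q")

    starts = [(float(init.d), float(init.N_UV))]
    starts += [(d0, n0) for d0 in opts["d_starts"] for n0 in opts["nuv_starts"]]
    n_range = sorted(set(list(opts["n_layers_range"]) + [init.N_layers]))

    # scouting pass: bounded-iteration minimisation from every start
    scouted = []
    errors = []
    for n_layers in n_range:
        for d0, nuv0 in starts:
            params = _make_params(init, bnds, d0, nuv0, q, I_obs, sigma, n_layers)
            try:
                res = lmfit.minimize(
                    _residual,
                    params,
                    args=(q, I_obs, sigma, n_layers),
                    method="leastsq",
                    max_nfev=opts["scout_max_nfev"],
                )
            except Exception as exc:  # singular steps etc.: skip this start
                errors.append((n_layers, d0, nuv0, repr(exc)))
                continue
            scouted.append((float(res.redchi), n_layers, res))
    if not scouted:
        raise RuntimeError(f"SAXS fit failed from every start; last errors: {errors[-3:]}")

    # polish the best scouted starts to full precision
    scouted.sort(key=lambda t: (t[0], t[1]))
    finished = []
    for redchi0, n_layers, res0 in scouted[: opts["n_polish"]]:
        params = res0.params.copy()
        try:
            res = lmfit.minimize(
                _residual, params, args=(q, I_obs, sigma, n_layers), method="leastsq"
            )
        except Exception:
            continue
        finished.append((float(res.redchi), n_layers, res))
    if not finished:
        raise RuntimeError("SAXS fit polish failed from every scouted start")
    finished.sort(key=lambda t: (t[0], t[1]))
    redchi, n_layers, best = finished[0]

    p = best.params.valuesdict()
    model = BilayerModel(
        z_H=p["z_H"],
        sigma_H=p["sigma_H"],
        rho_C=p["rho_C"],
        sigma_C=p["sigma_C"],
        d=p["d"],
        N_layers=n_layers,
        eta=p["eta"],
        N_UV=p["N_UV"],
        scale=p["scale"],
        background=p["background"],
    )
    uncertainties = {
        name: (best.params[name].stderr if best.params[name].stderr is not None else float("nan"))
        for name in _FLOAT_PARAMS
    }

    d_b = bilayer_thickness(model.z_H, model.sigma_H)
    d_b_err = None
    if best.covar is not None and "z_H" in best.var_names and "sigma_H" in best.var_names:
        iz = best.var_names.index("z_H")
        isig = best.var_names.index("sigma_H")
        var = (
            4.0 * best.covar[iz, iz]
            + 16.0 * best.covar[isig, isig]
            + 16.0 * best.covar[iz, isig]
        )
        d_b_err = math.sqrt(var) if var > 0 else None

    at_bounds = []
    for name in _FLOAT_PARAMS:
        par = best.params[name]
        span = (par.max - par.min) if np.isfinite(par.max) and np.isfinite(par.min) else 1.0
        tol = 1e-6 * span
        if (np.isfinite(par.min) and par.value - par.min <= tol) or (
            np.isfinite(par.max) and par.max - par.value <= tol
        ):
            at_bounds.append(name)

    return SAXSFit(
        model=model,
        uncertainties=uncertainties,
        chi2_reduced=redchi,
        d_B=d_b,
        n_uv_percent=100.0 * model.N_UV,
        d_B_err=d_b_err,
        at_bounds=at_bounds,
    )
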