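"""Signal models for multi-b DWI and their voxelwise inverse problems.

Three decay models are fitted per voxel:

* mono-exponential        S(b) = S0 · exp(−b·ADC)
* biexponential IVIM      S(b) = S0 [(1−f)·exp(−b·D) + f·exp(−b·(D+D*))]
* stretched exponential   S(b) = S0 · exp(−(b·DDC)^α)

In the IVIM model ``f`` is the vascular volume fraction and the fast
(vascular) pool decays at rate D + D*, so the pseudo-diffusion
coefficient D* is the decay-rate *excess* of the vascular pool over
tissue.  The stretched exponent α ∈ (0, 1] is the diffusion
heterogeneity index; α = 1 recovers mono-exponential decay.

Virtual MR elastography maps a two-point attenuation log-ratio to a
surrogate shear stiffness (kPa):

    μ_diff = α_scale · ln(S_low / S_high) + β_shift

with calibration constants α_scale = −9.8 kPa and β_shift = 14 kPa and
key b-values 200 / 800 s/mm².  With the negative scale, stronger
attenuation between the two b-values (freer diffusion) maps to *lower*
stiffness.

All fits are deterministic: no randomness, fixed initialisation rules.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize

from .io import DWISeries, ParameterMap, ROIMask

__all__ = [
    "PROTOCOL_BVALUES",
    "BOUNDS",
    "MonoFit",
    "IVIMFit",
    "StretchedFit",
    "VMREConfig",
    "mono_signal",
    "biexp_signal",
    "stretched_signal",
    "fit_adc",
    "fit_ivim_segmented",
    "fit_ivim_full",
    "fit_stretched",
    "compute_vmre",
    "fit_volume",
]

#: Acquisition protocol diffusion weightings, s/mm².
PROTOCOL_BVALUES = (0.0, 50.0, 100.0, 150.0, 200.0, 500.0, 800.0)

#: Physiological fitting bounds (mm²/s for diffusivities).
BOUNDS = {
    "f": (0.0, 1.0),
    "D": (1e-5, 5e-3),
    "Dstar": (5e-3, 0.5),
    "DDC": (1e-5, 1e-2),
    "Alpha": (0.01, 1.0),
}


@dataclasses.dataclass
class MonoFit:
    ADC: float
    S0: float
    rss: float = 0.0
    converged: bool = True


@dataclasses.dataclass
class IVIMFit:
    f: float
    D: float
    Dstar: float
    S0: float
    rss: float = 0.0
    method: str = "segmented"
    converged: bool = True


@dataclasses.dataclass
class StretchedFit:
    DDC: float
    Alpha: float
    S0: float
    rss: float = 0.0
    converged: bool = True


@dataclasses.dataclass
class VMREConfig:
    """Calibration of the DWI-to-stiffness mapping."""

    alpha_scale: float = -9.8  # kPa per unit log-attenuation-ratio
    beta_shift: float = 14.0   # kPa
    b_low: float = 200.0       # s/mm²
    b_high: float = 800.0      # s/mm²

    def __post_init__(self) -> None:
        if not self.b_high > self.b_low > 0:
            raise ValueError("require b_high > b_low > 0")


# ---------------------------------------------------------------------------
# Forward models


def _check(name: str, value: float) -> None:
    lo, hi = BOUNDS[name]
    if not (lo <= value <= hi):
        raise ValueError(f"{name}={value} outside bounds [{lo}, {hi}]")


def mono_signal(ADC: float, S0: float, bvalues) -> np.ndarray:
    b = np.asarray(bvalues, dtype=float)
    if ADC < 0:
        raise ValueError("ADC must be non-negative")
    return S0 * np.exp(-b * ADC)


def biexp_signal(f: float, D: float, Dstar: float, S0: float, bvalues) -> np.ndarray:
    """Biexponential IVIM signal; the fast pool decays at rate D + D*."""
    _check("f", f)
    _check("D", D)
    if Dstar < 0:
        raise ValueError("Dstar must be non-negative")
    b = np.asarray(bvalues, dtype=float)
    return S0 * ((1 - f) * np.exp(-b * D) + f * np.exp(-b * (D + Dstar)))


def stretched_signal(DDC: float, Alpha: float, S0: float, bvalues) -> np.ndarray:
    """Stretched-exponential signal S0·exp(−(b·DDC)^α).

    Note the exponent applies to the *product* b·DDC; taking the power
    outside the exponential would collapse to a mono-exponential with
    rate α·DDC and make α unidentifiable.
    """
    _check("DDC", DDC)
    _check("Alpha", Alpha)
    b = np.asarray(bvalues, dtype=float)
    return S0 * np.exp(-np.power(b * DDC, Alpha))


# ---------------------------------------------------------------------------
# Scalar fits


def fit_adc(signal, bvalues) -> MonoFit:
    """Log-linear least-squares ADC over all b-values."""
    s = np.asarray(signal, dtype=float)
    b = np.asarray(bvalues, dtype=float)
    if np.unique(b).size < 2:
        raise ValueError("need at least 2 distinct b-values for an ADC fit")
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        return MonoFit(ADC=np.nan, S0=np.nan, rss=np.nan, converged=False)
    slope, intercept = np.polyfit(b, np.log(s), 1)
    adc, s0 = -slope, float(np.exp(intercept))
    rss = float(np.sum((s - mono_signal(max(adc, 0.0), s0, b)) ** 2))
    return MonoFit(ADC=float(adc), S0=s0, rss=rss, converged=True)


def _ivim_residual(params, s, b):
    s0, f, d, dstar = params
    return s0 * ((1 - f) * np.exp(-b * d) + f * np.exp(-b * (d + dstar))) - s


def fit_ivim_segmented(signal, bvalues, b_threshold: float = 200.0) -> IVIMFit:
    """Segmented IVIM fit.

    1. log-linear fit on b ≥ b_threshold (vascular pool fully attenuated)
       gives D and the tissue-compartment intercept;
    2. f = 1 − intercept / S(b_min);
    3. D* by bounded 1-D least squares on the full curve with f, D fixed.

    A non-positive step-2 intercept excess is treated as a perfusion-free
    voxel (f = 0, D* undefined) rather than an error.
    """
    s = np.asarray(signal, dtype=float)
    b = np.asarray(bvalues, dtype=float)
    hi = b >= b_threshold
    lo = ~hi
    if hi.sum() < 2 or lo.sum() < 2:
        raise ValueError(
            f"need >=2 b-values on each side of the threshold {b_threshold}"
        )
    if np.any(s <= 0):
        return IVIMFit(np.nan, np.nan, np.nan, np.nan, np.nan, "segmented", False)

    slope, intercept = np.polyfit(b[hi], np.log(s[hi]), 1)
    d = float(np.clip(-slope, *BOUNDS["D"]))
    s0_ref = float(s[b == b.min()].mean())
    f = 1.0 - float(np.exp(intercept)) / s0_ref

    if f <= 0:
        # noise pushed the tissue intercept above S0: perfusion-free voxel
        fit = fit_adc(s, b)
        return IVIMFit(0.0, float(np.clip(fit.ADC, *BOUNDS["D"])), np.nan,
                       s0_ref, fit.rss, "segmented", True)
    clipped = f > 1.0
    f = min(f, 1.0)

    def rss_of(dstar):
        return float(np.sum(_ivim_residual((s0_ref, f, d, dstar), s, b) ** 2))

    res = optimize.minimize_scalar(rss_of, bounds=BOUNDS["Dstar"], method="bounded")
    dstar = float(res.x)
    return IVIMFit(f, d, dstar, s0_ref, rss_of(dstar), "segmented",
                   bool(res.success) and not clipped)


def fit_ivim_full(signal, bvalues, init: IVIMFit | None = None) -> IVIMFit:
    """Bounded nonlinear least squares over (S0, f, D, D*).

    Initialised from the segmented fit unless ``init`` is given;
    deterministic for identical input and init.
    """
    s = np.asarray(signal, dtype=float)
    b = np.asarray(bvalues, dtype=float)
    if np.unique(b).size < 4:
        raise ValueError("need at least 4 distinct b-values for a full IVIM fit")
    if np.any(s <= 0):
        return IVIMFit(np.nan, np.nan, np.nan, np.nan, np.nan, "full", False)

    if init is None:
        init = fit_ivim_segmented(s, b)
    lb = [1e-12, BOUNDS["f"][0], BOUNDS["D"][0], BOUNDS["Dstar"][0]]
    ub = [np.inf, BOUNDS["f"][1], BOUNDS["D"][1], BOUNDS["Dstar"][1]]
    x0 = np.array([
        init.S0 if np.isfinite(init.S0) else float(s.max()),
        init.f if np.isfinite(init.f) else 0.1,
        init.D if np.isfinite(init.D) else 1.5e-3,
        init.Dstar if np.isfinite(init.Dstar) else 50e-3,
    ])
    x0 = np.clip(x0, np.asarray(lb) * 1.000001 + 1e-15, np.asarray(ub))
    res = optimize.least_squares(
        _ivim_residual, x0, args=(s, b), bounds=(lb, ub),
        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    s0, f, d, dstar = res.x
    return IVIMFit(float(f), float(d), float(dstar), float(s0),
                   float(np.sum(res.fun ** 2)), "full", bool(res.success))


def fit_stretched(signal, bvalues) -> StretchedFit:
    """Bounded NLLS over (S0, DDC, α); DDC initialised at the fitted ADC,
    α at 0.8."""
    s = np.asarray(signal, dtype=float)
    b = np.asarray(bvalues, dtype=float)
    if np.unique(b).size < 3:
        raise ValueError("need at least 3 distinct b-values for a stretched fit")
    if np.any(s <= 0):
        return StretchedFit(np.nan, np.nan, np.nan, np.nan, False)

    adc = fit_adc(s, b)
    ddc0 = float(np.clip(adc.ADC, BOUNDS["DDC"][0] * 1.01, BOUNDS["DDC"][1] * 0.99))

    def resid(params):
        s0, ddc, alpha = params
        return s0 * np.exp(-np.power(b * ddc, alpha)) - s

    lb = [1e-12, BOUNDS["DDC"][0], BOUNDS["Alpha"][0]]
    ub = [np.inf, BOUNDS["DDC"][1], BOUNDS["Alpha"][1]]
    res = optimize.least_squares(
        resid, [adc.S0, ddc0, 0.8], args=(), bounds=(lb, ub),
        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    s0, ddc, alpha = res.x
    return StretchedFit(float(ddc), float(alpha), float(s0),
                        float(np.sum(res.fun ** 2)), bool(res.success))


def compute_vmre(signal, bvalues, config: VMREConfig | None = None) -> float:
    """Virtual-MRE stiffness from the signals at the two key b-values.

    Multiple volumes at a key b-value are averaged.  Returns NaN when
    either key signal is non-positive.
    """
    config = config or VMREConfig()
    s = np.asarray(signal, dtype=float)
    b = np.asarray(bvalues, dtype=float)
    lo = np.isclose(b, config.b_low)
    hi = np.isclose(b, config.b_high)
    if not lo.any() or not hi.any():
        raise ValueError(
            f"b-values {config.b_low} and {config.b_high} must both be acquired"
        )
    s_low, s_high = float(s[lo].mean()), float(s[hi].mean())
    if s_low <= 0 or s_high <= 0:
        return float("nan")
    return config.alpha_scale * np.log(s_low / s_high) + config.beta_shift


# ---------------------------------------------------------------------------
# Volume-level fitting


def _maps_for(model: str) -> dict:
    units_d = "mm^2/s"
    table = {
        "adc": {"ADC": units_d, "S0": "a.u."},
        "ivim_segmented": {"f": "fraction", "D": units_d, "Dstar": units_d, "S0": "a.u."},
        "ivim_full": {"f": "fraction", "D": units_d, "Dstar": units_d, "S0": "a.u."},
        "stretched": {"DDC": units_d, "Alpha": "", "S0": "a.u."},
        "vmre": {"mu_diff": "kPa"},
    }
    return table[model]


def fit_volume(series: DWISeries, mask: ROIMask, model: str,
               config=None) -> dict:
    """Fit every masked voxel independently; returns parameter maps.

    ``model`` is one of adc / ivim_segmented / ivim_full / stretched /
    vmre.  Unmasked and failed voxels are NaN.  ``config`` is a
    :class:`VMREConfig` for vmre, or the segmented b-threshold for
    ivim_segmented.
    """
    if mask.mask.shape != series.spatial_shape:
        raise ValueError("mask grid does not match the DWI grid")
    if model not in ("adc", "ivim_segmented", "ivim_full", "stretched", "vmre"):
        raise ValueError(f"unknown model {model!r}")

    spec = _maps_for(model)
    out = {name: np.full(series.spatial_shape, np.nan) for name in spec}
    b = series.bvalues

    for idx in np.argwhere(mask.mask):
        i, j, k = idx
        s = series.signal[i, j, k, :]
        try:
            if model == "adc":
                fit = fit_adc(s, b)
                vals = {"ADC": fit.ADC, "S0": fit.S0}
            elif model == "ivim_segmented":
                kw = {} if config is None else {"b_threshold": config}
                fit = fit_ivim_segmented(s, b, **kw)
                vals = {"f": fit.f, "D": fit.D, "Dstar": fit.Dstar, "S0": fit.S0}
            elif model == "ivim_full":
                fit = fit_ivim_full(s, b)
                vals = {"f": fit.f, "D": fit.D, "Dstar": fit.Dstar, "S0": fit.S0}
            elif model == "stretched":
                fit = fit_stretched(s, b)
                vals = {"DDC": fit.DDC, "Alpha": fit.Alpha, "S0": fit.S0}
            else:  # vmre
                vals = {"mu_diff": compute_vmre(s, b, config)}
        except ValueError:
            raise  # contract violations (bad b-table) abort the volume
        for name, v in vals.items():
            out[name][i, j, k] = v

    return {
        name: ParameterMap(arr, name, spec[name], series.affine)
        for name, arr in out.items()
    }
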