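"""Action-spectrum construction and visual-pigment template fitting.

A heterologous bioassay reports light-evoked luminescence per wavelength and
irradiance dose.  The analysis chain is:

1. ``peak_response`` — baseline-subtracted peak luminescence per trace;
2. ``fit_dose_response`` — a four-parameter logistic (variable slope, bottom
   fixed at the measured baseline) on log10 irradiance, yielding the EC50
   (irradiance for a half-maximal response) per wavelength;
3. ``relative_sensitivity`` — sensitivities s(λ) = EC50_min / EC50(λ),
   normalized so the most sensitive wavelength is exactly 1;
4. ``fit_lambda_max`` — a least-squares grid scan of the Govardovskii
   A1-pigment absorbance template over candidate λ_max values, returning the
   λ_max whose template best matches the action spectrum.

The Govardovskii template is the standard parametric absorbance curve for
opsin:retinaldehyde (A1) pigments, fully determined by λ_max: an α-band
with a λ_max-dependent shape plus a Gaussian β-band in the near-UV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "LuminescenceTrace",
    "DoseResponseFit",
    "ActionSpectrum",
    "TemplateFit",
    "peak_response",
    "four_param_logistic",
    "fit_dose_response",
    "relative_sensitivity",
    "govardovskii_template",
    "fit_lambda_max",
    "analyze_action_spectrum",
]

ASSAY_WAVELENGTHS = (420, 442, 458, 480, 500, 520, 540, 568, 600)


@dataclass(frozen=True)
class LuminescenceTrace:
    """A raw luminescence time series with a defined pre-stimulus baseline."""

    times: np.ndarray  # s
    values: np.ndarray  # arbitrary luminescence units
    stimulus_onset: float  # s
    baseline_window: tuple[float, float]  # s, entirely before onset

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape:
            raise ValueError("times and values must have equal length")
        if times.size and (np.diff(times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        lo, hi = self.baseline_window
        if hi > self.stimulus_onset:
            raise ValueError("baseline window must end before stimulus onset")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class DoseResponseFit:
    """A 4PL fit with the bottom asymptote fixed at the assay baseline."""

    bottom: float
    top: float
    hill: float
    log_ec50: float  # log10 photons cm^-2 s^-1
    sse: float
    converged: bool
    flag: str | None = None  # diagnostic when the fit is unusable

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log_ec50

    @property
    def ok(self) -> bool:
        return self.converged and self.flag is None


@dataclass(frozen=True)
class ActionSpectrum:
    """Relative spectral sensitivities, normalized to a maximum of 1."""

    wavelengths: tuple[float, ...]
    relative_sensitivity: tuple[float, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.relative_sensitivity, dtype=float)
        if s.size != len(self.wavelengths):
            raise ValueError("wavelengths and sensitivities must align")
        if (s <= 0).any():
            raise ValueError("sensitivities must be positive")
        if not np.isclose(s.max(), 1.0):
            raise ValueError("maximum relative sensitivity must be 1")


@dataclass(frozen=True)
class TemplateFit:
    """Result of the λ_max grid scan: minimizer plus the full SS profile."""

    lambda_max: float  # nm
    min_ss: float
    ss_profile: tuple[tuple[float, float], ...]  # (candidate λ_max, ss)
    grid_step: float
    flag: str | None = None


def peak_response(trace: LuminescenceTrace) -> float:
    """Peak post-stimulus luminescence minus mean baseline (unclamped)."""
    lo, hi = trace.baseline_window
    base = trace.values[(trace.times >= lo) & (trace.times <= hi)]
    post = trace.values[trace.times > trace.stimulus_onset]
    if base.size == 0:
        raise ValueError("no samples in the baseline window")
    if post.size == 0:
        raise ValueError("no samples after stimulus onset")
    return float(post.max() - base.mean())


def four_param_logistic(
    x: np.ndarray, bottom: float, top: float, hill: float, log_ec50: float
) -> np.ndarray:
    """R(x) = B + (T - B) / (1 + 10^(h (logEC50 - x))), x in log10 units."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - x)))


def fit_dose_response(
    log_irradiance: Sequence[float],
    response: Sequence[float],
    baseline: float,
) -> DoseResponseFit:
    """Least-squares 4PL fit with the bottom fixed to ``baseline``.

    Starting values: top = max response, hill = 1, logEC50 = median dose.
    A non-convergent optimization or a non-positive fitted slope is returned
    flagged rather than raised, so callers can exclude the wavelength.
    """
    x = np.asarray(log_irradiance, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dose and response vectors must have equal length")
    if np.unique(x).size < 4:
        raise ValueError("at least 4 distinct dose levels are required")

    def model(xx, top, hill, log_ec50):
        return four_param_logistic(xx, baseline, top, hill, log_ec50)

    p0 = (float(y.max()), 1.0, float(np.median(x)))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, x, y, p0=p0, maxfev=20_000)
    except RuntimeError as exc:
        return DoseResponseFit(
            bottom=baseline, top=float(y.max()), hill=np.nan, log_ec50=np.nan,
            sse=np.nan, converged=False, flag=f"optimization failed: {exc}",
        )
    top, hill, log_ec50 = (float(v) for v in popt)
    sse = float(np.sum((model(x, *popt) - y) ** 2))
    flag = None
    if hill <= 0:
        flag = "non-positive Hill slope (no activating dose dependence)"
    elif top <= baseline:
        flag = "fitted top does not exceed the baseline"
    return DoseResponseFit(
        bottom=baseline, top=top, hill=hill, log_ec50=log_ec50,
        sse=sse, converged=True, flag=flag,
    )


def relative_sensitivity(fits: Mapping[float, DoseResponseFit]) -> ActionSpectrum:
    """s(λ) = EC50_min / EC50(λ); the most sensitive wavelength gets 1.

    Flagged fits are excluded with a warning; fewer than two usable
    wavelengths leave the spectrum undefined.
    """
    usable = {w: f for w, f in fits.items() if f.ok}
    dropped = sorted(set(fits) - set(usable))
    if dropped:
        warnings.warn(
            f"excluding flagged dose-response fits at {dropped} nm", stacklevel=2
        )
    if not usable:
        raise ValueError("all dose-response fits are flagged; no spectrum")
    if len(usable) < 2:
        raise ValueError("a spectrum needs at least two usable wavelengths")
    wl = sorted(usable)
    ec50 = np.array([usable[w].ec50 for w in wl])
    s = ec50.min() / ec50
    s[np.argmin(ec50)] = 1.0  # exact at the most sensitive wavelength
    return ActionSpectrum(wavelengths=tuple(float(w) for w in wl),
                          relative_sensitivity=tuple(float(v) for v in s))


def govardovskii_template(
    wavelength, lambda_max: float, beta_band: bool = True
):
    """A1 visual-pigment absorbance template, normalized to ~1 at λ_max.

    α-band: S_α(x) = 1 / (e^{A(a-x)} + e^{B(b-x)} + e^{C(c-x)} + D) with
    x = λ_max/λ, A=69.7, B=28, C=-14.9, D=0.674, b=0.922, c=1.104 and
    a = 0.8795 + 0.0459 e^{-(λ_max-300)^2/11940}.  β-band: Gaussian with
    amplitude 0.26, center 189 + 0.315 λ_max, width -40.5 + 0.195 λ_max.
    Accepts a scalar or array wavelength; both inputs restricted to
    300–700 nm.
    """
    wl = np.asarray(wavelength, dtype=float)
    if np.any(wl < 300) or np.any(wl > 700):
        raise ValueError("wavelength must be within 300-700 nm")
    if not 300 <= lambda_max <= 700:
        raise ValueError("lambda_max must be within 300-700 nm")

    def raw(w):
        x = lambda_max / w
        a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
        alpha = 1.0 / (
            np.exp(69.7 * (a - x))
            + np.exp(28.0 * (0.922 - x))
            + np.exp(-14.9 * (1.104 - x))
            + 0.674
        )
        if not beta_band:
            return alpha
        lam_b = 189.0 + 0.315 * lambda_max
        width = -40.5 + 0.195 * lambda_max
        return alpha + 0.26 * np.exp(-(((w - lam_b) / width) ** 2))

    # the raw curve tops out ~0.1% above 1 a hair off lambda_max; renormalize
    # to the lambda_max value so the peak is exactly 1 at lambda_max
    out = np.minimum(raw(wl) / raw(np.float64(lambda_max)), 1.0)
    return float(out) if np.isscalar(wavelength) else out


def fit_lambda_max(
    spectrum: ActionSpectrum,
    scan_lo: float = 400.0,
    scan_hi: float = 550.0,
    step: float = 1.0,
    beta_band: bool = True,
) -> TemplateFit:
    """Grid scan of template λ_max minimizing Σ (s(λ) − template(λ, λ_max))²."""
    if len(spectrum.wavelengths) < 3:
        raise ValueError("template fitting needs at least 3 wavelengths")
    wl = np.asarray(spectrum.wavelengths)
    s = np.asarray(spectrum.relative_sensitivity)
    flag = None
    if np.allclose(s, s[0]):
        flag = "degenerate spectrum: all sensitivities equal"
    candidates = np.arange(scan_lo, scan_hi + 0.5 * step, step)
    profile = []
    for lm in candidates:
        ss = float(np.sum((s - govardovskii_template(wl, float(lm), beta_band=beta_band)) ** 2))
        profile.append((float(lm), ss))
    best = min(profile, key=lambda p: p[1])
    return TemplateFit(
        lambda_max=best[0], min_ss=best[1],
        ss_profile=tuple(profile), grid_step=float(step), flag=flag,
    )


def analyze_action_spectrum(
    points,
    baselines: Mapping[float, float] | float,
    scan_lo: float = 400.0,
    scan_hi: float = 550.0,
    step: float = 1.0,
) -> tuple[dict[float, DoseResponseFit], ActionSpectrum, TemplateFit]:
    """Dose-response table -> per-wavelength fits -> spectrum -> λ_max.

    ``points`` is a DataFrame with columns wavelength_nm, log_irradiance,
    response (replicates pooled).  ``baselines`` is a per-wavelength map or
    a single value.
    """
    fits: dict[float, DoseResponseFit] = {}
    for wl, grp in points.groupby("wavelength_nm"):
        base = baselines[wl] if isinstance(baselines, Mapping) else float(baselines)
        fits[float(wl)] = fit_dose_response(
            grp["log_irradiance"].to_numpy(), grp["response"].to_numpy(), base
        )
    spectrum = relative_sensitivity(fits)
    template = fit_lambda_max(spectrum, scan_lo=scan_lo, scan_hi=scan_hi, step=step)
    return fits, spectrum, template
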