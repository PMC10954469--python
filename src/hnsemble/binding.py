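"""Binding analyses: Hill fits, 1:1 reference isotherms, derivative-based
apparent dissociation constants, coupling free energies and the
intensity-averaged emission wavenumber.

A polydisperse self-associating protein cannot be analysed with a single
mechanistic binding model — different oligomers bind ligand with
different stoichiometries, and the oligomer distribution itself shifts
with concentration.  The pragmatic toolkit implemented here therefore
comprises:

* the empirical Hill equation, f = c^n / (K_1/2^n + c^n), fitted with
  free signal amplitudes (anisotropy/fluorescence baselines are
  arbitrary);
* the exact 1:1 ligand-depletion isotherm as the non-cooperative
  reference expectation;
* inflection-point detection on the first derivative of an isotherm in
  log-concentration space, yielding apparent dissociation constants when
  no closed-form model applies;
* coupling free energies from ratios of dissociation constants,
  dG = R T ln(K_a / K_b);
* the intensity-averaged wavenumber, a robust scalar tracking combined
  intensity and wavelength shifts of an emission spectrum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

from .core_thermo import R

__all__ = [
    "BindingIsotherm",
    "HillFitResult",
    "EmissionSpectrum",
    "intensity_avg_wavenumber",
    "hill_fit",
    "one_to_one_isotherm",
    "apparent_kd_from_derivative",
    "coupling_dG_from_K_ratio",
]


@dataclass
class BindingIsotherm:
    """A titration: signal versus increasing titrant concentration (M)."""

    titrant_conc: np.ndarray
    signal: np.ndarray
    fixed_conc: float = float("nan")
    temperature: float = float("nan")
    ionic_strength_label: str = ""

    def __post_init__(self):
        self.titrant_conc = np.asarray(self.titrant_conc, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.titrant_conc.shape != self.signal.shape:
            raise ValueError("concentration and signal must have equal lengths")
        if np.any(self.titrant_conc <= 0):
            raise ValueError("titrant concentrations must be positive")
        if not np.all(np.diff(self.titrant_conc) > 0):
            raise ValueError("titrant concentrations must be increasing")


@dataclass
class EmissionSpectrum:
    """Fluorescence emission intensities on an increasing wavelength grid (nm)."""

    wavelength: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity must have equal lengths")
        if np.any(self.wavelength <= 0) or not np.all(np.diff(self.wavelength) > 0):
            raise ValueError("wavelengths must be positive and increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


def intensity_avg_wavenumber(spec: EmissionSpectrum) -> float:
    """Intensity-averaged wavenumber of an emission spectrum.

    nu_av = 1e4 * sum(I/lambda) / sum(I) with lambda in nm, in units of
    1e3 cm^-1.  Blue shifts of a fixed-shape spectrum strictly increase
    the value.
    """
    total = spec.intensity.sum()
    if total <= 0:
        raise ValueError("spectrum carries no intensity")
    return float(1e4 * np.sum(spec.intensity / spec.wavelength) / total)


@dataclass(frozen=True)
class HillFitResult:
    """Hill-equation fit: midpoint, cooperativity and free amplitudes."""

    K_half: float
    n_H: float
    signal_min: float
    signal_max: float
    stderr: dict[str, float]
    ci68: dict[str, tuple[float, float]]
    midpoint_in_range: bool

    def fraction_bound(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        return c**self.n_H / (self.K_half**self.n_H + c**self.n_H)


def _hill_signal(logc, smin, smax, logK, n):
    f = 1.0 / (1.0 + 10 ** (n * (logK - logc)))
    return smin + (smax - smin) * f


def hill_fit(iso: BindingIsotherm, seed: int = 0) -> HillFitResult:
    """Least-squares Hill fit with free amplitudes.

    Concentrations are handled in log10 space (titrations span decades),
    with the midpoint parameterized as log10 K_1/2.  Reported ``ci68`` is
    the 68% confidence interval, i.e. estimate +/- one standard error
    from the least-squares covariance.  A warning flag is set when the
    fitted midpoint falls outside the data range (transition not
    spanned).  ``seed`` only perturbs the start point on retries and does
    not affect a converged fit.
    """
    if iso.titrant_conc.size < 6:
        raise ValueError("need at least 6 points spanning the transition")
    logc = np.log10(iso.titrant_conc)
    y = iso.signal

    smin0, smax0 = float(y[0]), float(y[-1])
    # midpoint start: concentration closest to half-amplitude
    half = 0.5 * (smin0 + smax0)
    logK0 = float(logc[np.argmin(np.abs(y - half))])
    p0 = [smin0, smax0, logK0, 1.0]
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for attempt in range(5):
        try:
            popt, pcov = curve_fit(
                _hill_signal, logc, y, p0=p0, maxfev=20000,
                bounds=([-np.inf, -np.inf, logc[0] - 3, 1e-3],
                        [np.inf, np.inf, logc[-1] + 3, 50.0]),
            )
            break
        except RuntimeError as err:  # non-convergence: jitter the start
            last_err = err
            p0 = [smin0, smax0, logK0 + rng.normal(0, 0.3), 10 ** rng.normal(0, 0.2)]
    else:
        raise RuntimeError(f"Hill fit did not converge: {last_err}")

    smin, smax, logK, n = popt
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    K = 10**logK
    # propagate SE of log10 K to K (first order)
    se_K = K * math.log(10) * se[2]
    stderr = {"signal_min": se[0], "signal_max": se[1], "K_half": se_K, "n_H": se[3]}
    ci68 = {
        "signal_min": (smin - se[0], smin + se[0]),
        "signal_max": (smax - se[1], smax + se[1]),
        "K_half": (10 ** (logK - se[2]), 10 ** (logK + se[2])),
        "n_H": (n - se[3], n + se[3]),
    }
    in_range = bool(logc[0] <= logK <= logc[-1])
    if not in_range:
        warnings.warn("fitted K_half lies outside the measured range", stacklevel=2)
    return HillFitResult(
        K_half=float(K), n_H=float(n), signal_min=float(smin),
        signal_max=float(smax), stderr=stderr, ci68=ci68,
        midpoint_in_range=in_range,
    )


def one_to_one_isotherm(K_D: float, titrant_conc, fixed_conc: float) -> np.ndarray:
    """Fraction of the fixed component bound under 1:1 equilibrium.

    Exact ligand-depletion solution of P + L <-> PL: the complex
    concentration is the stable root of the binding quadratic, evaluated
    in the numerically safe form 2 P L / (b + sqrt(b^2 - 4 P L)) with
    b = P + L + K_D.  Monotone increasing in titrant, bounded by [0, 1].
    """
    if K_D <= 0:
        raise ValueError("K_D must be positive")
    if fixed_conc <= 0:
        raise ValueError("fixed component concentration must be positive")
    L = np.asarray(titrant_conc, dtype=float)
    P = fixed_conc
    b = P + L + K_D
    disc = np.sqrt(b * b - 4.0 * P * L)
    complex_conc = 2.0 * P * L / (b + disc)
    return complex_conc / P


def apparent_kd_from_derivative(
    iso: BindingIsotherm, smoothing_window: int = 7
) -> list[float]:
    """Apparent dissociation constants from isotherm inflection points.

    The signal is re-gridded onto an even log10-concentration axis,
    smoothed by a local quadratic (Savitzky-Golay) over
    ``smoothing_window`` points, and differentiated; interior maxima of
    d(signal)/d(log10 c) are returned in ascending concentration order.
    For a Hill curve the derivative peaks exactly at K_1/2.  The result
    is invariant to affine transformations of the signal.  A flat signal
    yields an empty list (with a warning).
    """
    if iso.titrant_conc.size < 10:
        raise ValueError("need at least 10 points for derivative analysis")
    if smoothing_window % 2 == 0 or smoothing_window < 5:
        raise ValueError("smoothing window must be odd and >= 5")
    logc = np.log10(iso.titrant_conc)
    grid = np.linspace(logc[0], logc[-1], logc.size)
    y = np.interp(grid, logc, iso.signal)

    amp = float(np.ptp(y))
    if amp == 0:
        warnings.warn("flat signal: no inflection points", stacklevel=2)
        return []
    y = (y - y.min()) / amp  # affine invariance
    dx = grid[1] - grid[0]
    window = min(smoothing_window, y.size if y.size % 2 else y.size - 1)
    deriv = savgol_filter(y, window_length=window, polyorder=2, deriv=1, delta=dx)
    dmax = float(np.max(np.abs(deriv)))
    idx, _ = find_peaks(deriv, height=0.1 * dmax, prominence=0.1 * dmax)
    if idx.size == 0:
        warnings.warn("no interior derivative maximum found", stacklevel=2)
        return []
    return [float(10 ** grid[i]) for i in idx]


def coupling_dG_from_K_ratio(K_a: float, K_b: float, T: float) -> float:
    """Coupling free energy R T ln(K_a / K_b), in kJ/mol (signed).

    Quantifies the thermodynamic linkage revealed by a perturbation that
    changes a dissociation constant from ``K_a`` to ``K_b``; swapping the
    arguments flips the sign, equal constants give zero.
    """
    if K_a <= 0 or K_b <= 0 or T <= 0:
        raise ValueError("constants and temperature must be positive")
    return R * T * math.log(K_a / K_b) / 1000.0
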