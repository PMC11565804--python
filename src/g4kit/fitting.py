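"""Nonlinear fits for the two binding/kinetics models used throughout:

* one-site specific binding, ``Y = baseline + Bmax * X / (KD + X)`` — the
  standard saturation model behind fluorescence-polarization titrations,
  reporting the dissociation constant KD (µM);
* one-phase association, ``Y = Y0 + (Plateau - Y0) * (1 - exp(-K t))`` — the
  single-exponential FRAP recovery model, reporting the rate K and the
  derived halftime ``t_half = ln 2 / K``.

Both use Levenberg-Marquardt least squares (lmfit) with positivity of
KD / K enforced through a log-parameterization, unweighted by default.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit

__all__ = [
    "TitrationCurve",
    "RecoveryCurve",
    "FitResult",
    "one_site_model",
    "one_phase_association_model",
    "fit_one_site",
    "fit_one_phase_association",
    "normalize_frap",
]

_LN2 = float(np.log(2.0))


@dataclass
class TitrationCurve:
    """(concentration µM, signal) pairs of one binding titration."""

    concentrations: np.ndarray
    signal: np.ndarray
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.concentrations.shape != self.signal.shape:
            raise ValueError("concentrations and signal length mismatch")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")


@dataclass
class RecoveryCurve:
    """Post-bleach FRAP recovery: times (s, 0 at first post-bleach point),
    normalized intensity."""

    times: np.ndarray
    intensity: np.ndarray
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.shape != self.intensity.shape:
            raise ValueError("times and intensity length mismatch")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and increasing")


@dataclass
class FitResult:
    parameters: dict[str, float]
    stderr: dict[str, float | None]
    derived: dict[str, float]
    converged: bool
    rss: float

    def __getitem__(self, name: str) -> float:
        if name in self.parameters:
            return self.parameters[name]
        return self.derived[name]


def one_site_model(x: np.ndarray, KD: float, Bmax: float, baseline: float = 0.0):
    return baseline + Bmax * x / (KD + x)


def one_phase_association_model(t: np.ndarray, K: float, plateau: float, Y0: float = 0.0):
    return Y0 + (plateau - Y0) * (1.0 - np.exp(-K * t))


def _result(out: lmfit.minimizer.MinimizerResult, names: Sequence[str],
            transform: Mapping[str, str]) -> tuple[dict, dict, bool, float]:
    params, stderr = {}, {}
    for name in names:
        p = out.params[transform.get(name, name)]
        if name in transform:  # log-parameterized: value = exp(log_value)
            params[name] = float(np.exp(p.value))
            stderr[name] = float(params[name] * p.stderr) if p.stderr else None
        else:
            params[name] = float(p.value)
            stderr[name] = float(p.stderr) if p.stderr is not None else None
    rss = float(np.sum(out.residual**2))
    return params, stderr, bool(out.success), rss


def fit_one_site(curve: TitrationCurve, with_baseline: bool = True,
                 nonspecific: bool = False, weights_inv_y2: bool = False) -> FitResult:
    """Fit the one-site specific binding model; reports KD, Bmax, baseline.

    Initialization is derivative-free: KD starts at the concentration whose
    signal is nearest half the signal span.  ``nonspecific`` adds a linear
    ``NS * X`` term; ``weights_inv_y2`` switches on 1/Y^2 weighting.  Fewer
    than (parameters + 1) distinct points is an error; non-convergence is
    reported through the ``converged`` flag, not an exception.
    """
    x, y = curve.concentrations, curve.signal
    n_par = 2 + int(with_baseline) + int(nonspecific)
    if len(np.unique(x)) < n_par + 1:
        raise ValueError(f"need at least {n_par + 1} distinct concentrations")

    span = float(y.max() - y.min())
    half = y.min() + 0.5 * span
    kd0 = float(x[np.argmin(np.abs(y - half))])
    pars = lmfit.Parameters()
    pars.add("log_KD", value=np.log(max(kd0, 1e-12)))
    pars.add("Bmax", value=span if span > 0 else 1.0)
    pars.add("baseline", value=float(y.min()), vary=with_baseline)
    pars.add("NS", value=0.0, vary=nonspecific)

    def residual(p):
        model = (p["baseline"] + p["Bmax"] * x / (np.exp(p["log_KD"]) + x)
                 + p["NS"] * x)
        r = y - model
        if weights_inv_y2:
            r = r / np.maximum(np.abs(y), 1e-12)
        return r

    out = lmfit.minimize(residual, pars, method="leastsq",
                         max_nfev=1000 * (n_par + 1), xtol=1e-10, ftol=1e-10)
    names = ["KD", "Bmax", "baseline"] + (["NS"] if nonspecific else [])
    params, stderr, ok, rss = _result(out, names, {"KD": "log_KD"})
    return FitResult(params, stderr, {}, ok, rss)


def fit_one_phase_association(curve: RecoveryCurve) -> FitResult:
    """Fit the one-phase association model; reports K, Y0, Plateau and the
    derived halftime ``t_half = ln 2 / K`` (exact identity in every result).

    The rate is initialized at ``ln 2 / t`` for the time point nearest half
    recovery, and the mobile fraction ``Plateau - Y0`` is included in
    ``derived`` (meaningful when intensities are full-scale normalized).
    """
    t, y = curve.times, curve.intensity
    if len(t) < 4:
        raise ValueError("need at least 4 time points")

    y0_0, plat0 = float(y[0]), float(y[-1])
    half = y0_0 + 0.5 * (plat0 - y0_0)
    t_half0 = float(t[np.argmin(np.abs(y - half))])
    k0 = _LN2 / t_half0 if t_half0 > 0 else _LN2 / max(t[1], 1e-12)

    pars = lmfit.Parameters()
    pars.add("log_K", value=np.log(max(k0, 1e-12)))
    pars.add("plateau", value=plat0)
    pars.add("Y0", value=y0_0)

    def residual(p):
        return y - one_phase_association_model(t, np.exp(p["log_K"]),
                                               p["plateau"], p["Y0"])

    out = lmfit.minimize(residual, pars, method="leastsq",
                         max_nfev=4000, xtol=1e-10, ftol=1e-10)
    params, stderr, ok, rss = _result(out, ["K", "plateau", "Y0"], {"K": "log_K"})
    derived = {
        "t_half": _LN2 / params["K"],
        "mobile_fraction": params["plateau"] - params["Y0"],
    }
    return FitResult(params, stderr, derived, ok, rss)


def normalize_frap(
    times: np.ndarray,
    raw_intensity: np.ndarray,
    prebleach_window: slice | Sequence[int],
    bleach_index: int,
) -> RecoveryCurve:
    """Full-scale FRAP normalization.

    ``(I(t) - I_bleach) / (I_pre - I_bleach)`` with ``I_pre`` the mean over
    the pre-bleach window and ``I_bleach`` the intensity at ``bleach_index``;
    the clock is re-zeroed at the first post-bleach point.  An unbleached
    series (``I_pre == I_bleach``) is degenerate and raises.
    """
    times = np.asarray(times, dtype=float)
    raw = np.asarray(raw_intensity, dtype=float)
    if not (0 <= bleach_index < len(raw)):
        raise ValueError("bleach_index outside the series")
    pre = raw[prebleach_window] if isinstance(prebleach_window, slice) \
        else raw[np.asarray(prebleach_window)]
    if pre.size == 0:
        raise ValueError("prebleach window selects no points")
    i_pre = float(np.mean(pre))
    i_bleach = float(raw[bleach_index])
    if i_pre == i_bleach:
        raise ValueError("degenerate series: prebleach equals bleach intensity")
    post = slice(bleach_index, None)
    return RecoveryCurve(times[post] - times[bleach_index],
                         (raw[post] - i_bleach) / (i_pre - i_bleach))
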