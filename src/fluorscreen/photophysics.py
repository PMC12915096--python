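"""Assay curve fitting: viscosity response, saturation binding, Hill, inhibition.

* Förster–Hoffmann: a molecular rotor's fluorescence intensity follows
  ``log10 I = C + x · log10 η`` in solvent viscosity η; ``x`` is the probe's
  viscosity sensitivity.  Fit by ordinary least squares in log–log space.
* One-site saturation binding: ``I([L]) = F0 + Bmax·[L] / (Kd + [L])``; the
  dissociation constant Kd is the ligand concentration at half-maximal
  specific signal.  Fit by multi-start nonlinear least squares.
* Hill model: ``I = F0 + Bmax·[L]^h / (Kd^h + [L]^h)``; ``h = 1`` reduces to
  the one-site model.
* Drug-screen statistic: inhibition rate (%) = (FI_mean_max − FI_drug) /
  FI_mean_max × 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DataError, DegenerateFitError, DomainError, FitFailureError

#: the standard probe titration grid (nM) used for dissociation-constant assays
TITRATION_GRID_NM = (0, 1, 2, 5, 8, 10, 20, 50, 80, 100, 200, 500, 800, 1000)


@dataclass
class AssaySeries:
    """An (x, intensity) dose/viscosity–response series."""

    x: np.ndarray
    intensity: np.ndarray
    replicate_id: object = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.x.shape != self.intensity.shape:
            raise DataError("x and intensity must have equal length")
        if self.x.size and (self.x < 0).any():
            raise DomainError("x values must be non-negative")


@dataclass
class FitResult:
    model: str
    params: dict
    rss: float
    r2: float
    ci: dict = field(default_factory=dict)


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def fit_forster_hoffmann(series: AssaySeries) -> FitResult:
    """OLS of log10 intensity on log10 viscosity; returns C, x and r²."""
    eta, inten = series.x, series.intensity
    if (eta <= 0).any():
        raise DomainError("viscosities must be positive (log undefined at 0)")
    if (inten <= 0).any():
        raise DomainError("intensities must be positive (log undefined)")
    if np.unique(eta).size < 2:
        raise DataError("need at least 2 distinct viscosities")
    lx, ly = np.log10(eta), np.log10(inten)
    x_sens, c = np.polyfit(lx, ly, 1)
    yhat = c + x_sens * lx
    rss = float(np.sum((ly - yhat) ** 2))
    return FitResult("forster_hoffmann", {"C": float(c), "x": float(x_sens)},
                     rss, _r2(ly, yhat))


def _one_site(L, f0, bmax, kd):
    return f0 + bmax * L / (kd + L)


def _hill(L, f0, bmax, kd, h):
    Lh = np.power(L, h, where=L > 0, out=np.zeros_like(L, dtype=float))
    return f0 + bmax * Lh / (kd ** h + Lh)


def _multistart_fit(func, x, y, starts, bounds, names):
    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(func, x, y, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - func(x, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise FitFailureError(
            f"no start converged (tried {len(starts)} initializations)"
        )
    popt, rss = best
    return dict(zip(names, (float(v) for v in popt))), rss


def _check_titration(series: AssaySeries):
    if np.unique(series.x).size < 4:
        raise DataError("need at least 4 distinct concentrations")
    spread = float(series.intensity.max() - series.intensity.min())
    scale = max(abs(float(np.mean(series.intensity))), 1e-12)
    if spread < 1e-9 * scale or spread == 0.0:
        raise DegenerateFitError("flat titration series carries no binding signal")


def _kd_starts(x, y):
    pos = x[x > 0]
    f0 = float(np.min(y))
    bmax = float(np.max(y) - np.min(y))
    return [
        (f0, bmax, kd0)
        for kd0 in (float(np.median(pos)), float(np.max(pos)) / 10.0, float(np.max(pos)))
    ]


def fit_saturation_kd(series: AssaySeries) -> FitResult:
    """One-site specific-binding fit; Kd reported in the units of x."""
    _check_titration(series)
    x, y = series.x, series.intensity
    eps = 1e-12
    params, rss = _multistart_fit(
        _one_site, x, y, _kd_starts(x, y),
        bounds=([-np.inf, eps, eps], [np.inf, np.inf, np.inf]),
        names=("F0", "Bmax", "Kd"),
    )
    yhat = _one_site(x, *params.values())
    return FitResult("saturation_kd", params, rss, _r2(y, yhat))


def fit_hill(series: AssaySeries, fix_h: float | None = None) -> FitResult:
    """Hill specific-binding fit; ``fix_h=1`` reproduces the one-site model."""
    if series.x.size == 0:
        raise DataError("empty series")
    _check_titration(series)
    x, y = series.x, series.intensity
    eps = 1e-12
    if fix_h is not None:
        def model(L, f0, bmax, kd, _h=float(fix_h)):
            return _hill(L, f0, bmax, kd, _h)

        params, rss = _multistart_fit(
            model, x, y, _kd_starts(x, y),
            bounds=([-np.inf, eps, eps], [np.inf, np.inf, np.inf]),
            names=("F0", "Bmax", "Kd"),
        )
        params["h"] = float(fix_h)
    else:
        starts = [s + (h0,) for s in _kd_starts(x, y) for h0 in (0.5, 1.0, 2.0)]
        params, rss = _multistart_fit(
            _hill, x, y, starts,
            bounds=([-np.inf, eps, eps, 0.1], [np.inf, np.inf, np.inf, 10.0]),
            names=("F0", "Bmax", "Kd", "h"),
        )
    yhat = _hill(x, params["F0"], params["Bmax"], params["Kd"], params["h"])
    return FitResult("hill", params, rss, _r2(y, yhat))


def inhibition_rate(fi_mean_max: float, fi_drug: float) -> float:
    """Inhibition rate (%) = (FI_mean_max − FI_drug) / FI_mean_max × 100.

    May be negative for signal enhancers; not clipped.
    """
    if fi_mean_max <= 0:
        raise DomainError("FI_mean_max must be positive")
    return (fi_mean_max - fi_drug) / fi_mean_max * 100.0


def bootstrap_ci(series: AssaySeries, fitter, n_boot: int = 1000, seed: int = 0,
                 level: float = 0.95) -> dict:
    """Case-resampling bootstrap percentile CIs for a fit's parameters."""
    rng = np.random.default_rng(seed)
    n = series.x.size
    draws: dict[str, list] = {}
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            res = fitter(AssaySeries(series.x[idx], series.intensity[idx]))
        except (FitFailureError, DataError, DomainError):
            continue
        for k, v in res.params.items():
            draws.setdefault(k, []).append(v)
    lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    return {
        k: (float(np.percentile(v, lo)), float(np.percentile(v, hi)))
        for k, v in draws.items()
        if v
    }
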