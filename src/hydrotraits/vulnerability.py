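"""Sigmoid xylem vulnerability curves.

The loss of xylem function with declining water potential is modelled with a
two-parameter logistic curve,

    PE(psi) = 100 - 100 / (1 + exp(a * (psi - b))),

where ``PE`` is percent embolism, ``a`` (MPa^-1, negative) sets the sensitivity
to declining water potential (proportional to the slope at the midpoint) and
``b`` (MPa, negative) is the water potential at 50% embolism (P50).  Reference
points P12 and P88 — onset of embolism and severe hydraulic impairment — are
obtained by inverting the curve.

Sign convention: water potentials are stored negative throughout; ``a`` is
negative on any physically meaningful fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit


class FitError(RuntimeError):
    """Raised when a vulnerability-curve fit fails or is non-physical."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


def sigmoid_pe(psi, a: float, b: float):
    """Percent embolism at water potential ``psi`` (MPa).

    Strictly decreasing in ``psi`` for ``a < 0``; returns values in (0, 100).
    Accepts scalars or arrays.
    """
    psi = np.asarray(psi, dtype=float)
    out = 100.0 - 100.0 / (1.0 + np.exp(a * (psi - b)))
    return out.item() if out.ndim == 0 else out


def px(a: float, b: float, x: float) -> float:
    """Water potential (MPa) at which ``x`` percent embolism occurs.

    Closed-form inverse of :func:`sigmoid_pe`:  Psi_x = b + ln(x/(100-x)) / a.
    ``x`` must lie strictly inside (0, 100); x=50 returns ``b`` exactly.
    """
    if not 0.0 < x < 100.0:
        raise ValueError(f"x must be in (0, 100), got {x}")
    return b + np.log(x / (100.0 - x)) / a


@dataclass(frozen=True)
class SigmoidFit:
    """Per-leaf vulnerability-curve fit.

    ``b_se`` is the sampling standard error of the P50 estimate.  When the
    total number of embolism events behind the trace is known it is the
    asymptotic SE of the median of ``n`` logistic draws, 2/(|a|*sqrt(n));
    otherwise it falls back to the (conditional, typically anti-conservative
    on cumulative traces) nonlinear-LS covariance estimate.
    """

    a: float
    b: float
    a_se: float
    b_se: float
    rss: float
    n_points: int
    converged: bool
    poorly_constrained: bool = False

    def __post_init__(self):
        if self.converged and self.a >= 0:
            raise FitError("non-physical fit: a >= 0")


@dataclass(frozen=True)
class SpeciesCurve:
    """Species-mean vulnerability curve: arithmetic means of per-leaf (a, b)."""

    species: str
    a_mean: float
    a_se: float
    b_mean: float
    b_se: float
    p12: float
    p50: float
    p88: float
    n_individuals: int


def _initial_guess(psi: np.ndarray, pct: np.ndarray) -> tuple[float, float]:
    """b0 = psi at first crossing of 50%; a0 from the empirical 20-80% spread."""
    above = pct >= 50.0
    b0 = float(psi[np.argmax(above)]) if above.any() else float(np.median(psi))
    psi20 = psi[np.argmax(pct >= 20.0)] if (pct >= 20.0).any() else psi[0]
    psi80 = psi[np.argmax(pct >= 80.0)] if (pct >= 80.0).any() else psi[-1]
    spread = float(psi20 - psi80)
    if spread <= 0:
        spread = max(1e-3, float(psi.max() - psi.min()) / 4.0)
    a0 = np.log(0.12 / 0.88) * 2.0 / spread
    return a0, b0


def fit_sigmoid(
    psi: Sequence[float],
    cum_pct: Sequence[float],
    n_events: int | None = None,
    n_restarts: int = 5,
) -> SigmoidFit:
    """Fit the sigmoid vulnerability model to a cumulative embolism trace.

    Parameters
    ----------
    psi, cum_pct
        Per-frame water potential (MPa) and cumulative percent embolism.
    n_events
        Total embolism events underlying the trace; enables the
        sampling-based ``b_se`` (see :class:`SigmoidFit`).
    n_restarts
        Deterministic jittered re-initialisations before giving up.

    Raises
    ------
    FitError
        On non-convergence after all restarts (``best`` carries the best
        iterate) or when the fitted ``a`` is non-negative.
    """
    psi = np.asarray(psi, dtype=float)
    pct = np.asarray(cum_pct, dtype=float)
    if psi.shape != pct.shape or psi.ndim != 1:
        raise ValueError("psi and cum_pct must be 1-D arrays of equal length")
    if len(psi) < 5:
        raise FitError(f"need >= 5 points to fit, got {len(psi)}")

    # the curve is only identifiable if the trace spans both tails
    poorly_constrained = not (pct.min() < 20.0 and pct.max() > 80.0)

    a0, b0 = _initial_guess(psi, pct)
    jitter_rng = np.random.default_rng(0)  # fixed: restarts are deterministic

    def model(p, a, b):
        return 100.0 - 100.0 / (1.0 + np.exp(np.clip(a * (p - b), -500, 500)))

    best = None
    for trial in range(n_restarts):
        if trial == 0:
            p0 = (a0, b0)
        else:
            p0 = (
                a0 * float(jitter_rng.uniform(0.3, 3.0)),
                b0 + float(jitter_rng.normal(0, 0.5)),
            )
        try:
            popt, pcov = curve_fit(model, psi, pct, p0=p0, maxfev=20000)
        except RuntimeError:
            continue
        rss = float(np.sum((model(psi, *popt) - pct) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
        if rss < 1e10:
            break
    if best is None:
        raise FitError("sigmoid fit did not converge after restarts", best=(a0, b0))

    (a_hat, b_hat), pcov, rss = best
    if a_hat >= 0:
        raise FitError(
            f"non-physical fit: a = {a_hat:.3g} >= 0", best=(a_hat, b_hat)
        )
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (np.nan, np.nan)
    if n_events is not None and n_events > 0:
        b_se = 2.0 / (abs(a_hat) * np.sqrt(n_events))
    else:
        b_se = float(perr[1])
    return SigmoidFit(
        a=float(a_hat),
        b=float(b_hat),
        a_se=float(perr[0]),
        b_se=float(b_se),
        rss=rss,
        n_points=len(psi),
        converged=True,
        poorly_constrained=poorly_constrained,
    )


def species_curve(fits: Sequence[SigmoidFit], species: str = "") -> SpeciesCurve:
    """Species-mean curve from individual-leaf fits.

    The species curve averages fitted parameters (not pooled raw traces):
    a_mean and b_mean are arithmetic means across leaves, with SE = sd/sqrt(n)
    (reported as NaN for a single leaf).  P12/P50/P88 are evaluated at the
    mean parameters; P50 equals b_mean by construction.
    """
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("species_curve requires at least one converged fit")
    a = np.array([f.a for f in fits])
    b = np.array([f.b for f in fits])
    n = len(fits)
    a_se = float(a.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    b_se = float(b.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    a_m, b_m = float(a.mean()), float(b.mean())
    return SpeciesCurve(
        species=species,
        a_mean=a_m,
        a_se=a_se,
        b_mean=b_m,
        b_se=b_se,
        p12=px(a_m, b_m, 12.0),
        p50=b_m,
        p88=px(a_m, b_m, 88.0),
        n_individuals=n,
    )
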