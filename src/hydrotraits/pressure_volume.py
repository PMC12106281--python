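"""Pressure-Volume curve analysis: turgor loss point, osmotic potential, elasticity.

A bench-drying series records leaf water potential and fresh mass as a leaf
dries.  In transformed coordinates — inverse water potential (1/psi) against
water deficit d = 1 - RWC — the post-turgor-loss portion is a straight line
(pure osmometer behaviour, psi = -psi_osm_ft / RWC), while the pre-turgor
portion bends away from it.  The analysis:

1. estimate turgid mass (regression of mass on psi over the wettest points,
   extrapolated to psi = 0),
2. convert masses to relative water content,
3. find the linear dry-end tail of the 1/psi vs d plot (the largest dry-end
   suffix whose OLS fit reaches a configurable r^2 — a deterministic
   surrogate for the visual inflection between the linear and nonlinear
   portions),
4. read off the traits: psi_osm_ft from the tail intercept, the turgor loss
   point as the wettest tail datum (or the model intersection, by flag), and
   the bulk elastic modulus eps = dP/(dV/V) as the OLS slope of turgor
   pressure against RWC over the pre-turgor points.

Apoplastic water is assumed negligible (symplast = total leaf water), so
turgor pressure at each pre-turgor point is psi - psi_s with
psi_s = -psi_osm_ft / RWC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

_PSI_ZERO_TOL = 1e-9


def closed_form_tlp(psi_osm_ft: float, eps: float) -> float:
    """Analytic turgor loss point of the linear-elasticity symplastic model.

    TLP = -psi_osm_ft / (1 - psi_osm_ft / eps).  Requires
    ``eps > psi_osm_ft > 0``; in the rigid-wall limit (eps -> inf) the TLP
    tends to the osmotic potential at full turgor.
    """
    if not psi_osm_ft > 0:
        raise ValueError("psi_osm_ft must be > 0 (magnitude)")
    if not eps > psi_osm_ft:
        raise ValueError("eps must exceed psi_osm_ft, else turgor is never lost")
    return -psi_osm_ft / (1.0 - psi_osm_ft / eps)


@dataclass(frozen=True)
class TailFit:
    """Linear dry-end region of the 1/psi vs water-deficit plot."""

    n: int
    slope: float
    intercept: float
    r2: float


@dataclass(frozen=True)
class PVTraits:
    tlp: float  # MPa, negative
    psi_osm_ft: float  # MPa, positive magnitude
    eps: float  # MPa; NaN when < 3 pre-turgor points
    tail_n: int
    tail_r2: float

    def __post_init__(self):
        if not self.tlp < 0:
            raise ValueError("TLP must be negative")
        if not self.psi_osm_ft > 0:
            raise ValueError("psi_osm_ft must be positive (magnitude)")


def estimate_turgid_mass(fresh_mass, psi) -> float:
    """Saturated (full-turgor) mass from the wet end of the series.

    If a point at psi = 0 exists its mass is taken directly.  Otherwise the
    fresh masses of points wetter than -1 MPa (at least 3 required) are
    regressed on psi and extrapolated to psi = 0.  Falls back to the maximum
    fresh mass, and never returns less than it.
    """
    fresh = np.asarray(fresh_mass, dtype=float)
    psi = np.asarray(psi, dtype=float)
    max_fresh = float(fresh.max())
    at_zero = psi >= -_PSI_ZERO_TOL
    if at_zero.any():
        return max(float(fresh[at_zero].max()), max_fresh)
    wet = psi > -1.0
    if wet.sum() >= 3:
        res = _sps.linregress(psi[wet], fresh[wet])
        return max(float(res.intercept), max_fresh)
    return max_fresh


def compute_rwc(fresh_mass, dry_mass: float, turgid_mass: float):
    """Relative water content (fresh - dry) / (turgid - dry), clipped to (0, 1]."""
    if not turgid_mass > dry_mass:
        raise ValueError("turgid_mass must exceed dry_mass")
    fresh = np.asarray(fresh_mass, dtype=float)
    rwc = (fresh - dry_mass) / (turgid_mass - dry_mass)
    return np.clip(rwc, np.finfo(float).tiny, 1.0)


def find_linear_tail(rwc, psi, r2_min: float = 0.99) -> TailFit:
    """Largest genuinely linear dry-end suffix of the transformed plot.

    Points are taken in drying order (as given) on (d, 1/psi) with
    d = 1 - RWC.  Two passes locate the inflection deterministically:

    1. the largest suffix of size >= 3 whose ordinary least-squares fit
       reaches ``r2_min`` is taken as a candidate;
    2. the candidate is trimmed from its wet end while the wettest point is
       an outlier against the fit of the remaining points (residual beyond
       3x their RMSE) — r^2 alone is scale-blind and can absorb a few
       pre-turgor points at high leverage, which would bias the osmotic
       intercept.

    On noiseless model data the surviving tail is exactly the post-turgor
    region.  Points at psi = 0 (full turgor) can never belong to the tail.
    """
    rwc = np.asarray(rwc, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n = len(rwc)
    if n < 6:
        raise ValueError("need >= 6 points for tail detection")
    d = 1.0 - rwc
    usable = psi < -_PSI_ZERO_TOL  # 1/psi undefined at full turgor
    inv = np.where(usable, 1.0 / np.where(usable, psi, -1.0), np.nan)

    def suffix_fit(k):
        dd, ii = d[n - k:], inv[n - k:]
        slope, intercept, r, _, _ = _sps.linregress(dd, ii)
        resid = ii - (slope * dd + intercept)
        return TailFit(n=k, slope=float(slope), intercept=float(intercept),
                       r2=float(r * r)), resid

    best = None
    for k in range(3, n + 1):
        if not usable[n - k:].all():
            break
        fit, _ = suffix_fit(k)
        if fit.r2 >= r2_min:
            best = fit
    if best is None:
        raise ValueError(
            f"no linear region: no dry-end suffix of >= 3 points reaches "
            f"r2 >= {r2_min}"
        )

    k = best.n
    while k > 3:
        rest, resid = suffix_fit(k - 1)
        rmse = float(np.sqrt(np.sum(resid**2) / max(k - 3, 1)))
        wettest_resid = inv[n - k] - (rest.slope * d[n - k] + rest.intercept)
        if abs(wettest_resid) > max(3.0 * rmse, 1e-10):
            k -= 1
        else:
            break
    fit, _ = suffix_fit(k)
    return fit


def extract_pv_traits(
    fresh_mass,
    psi,
    dry_mass: float,
    turgid_mass: float | None = None,
    r2_min: float = 0.99,
    tlp_rule: str = "breakpoint",
) -> PVTraits:
    """Full PV trait extraction from one leaf's drying series.

    Parameters
    ----------
    fresh_mass, psi
        The series in drying order (psi non-increasing, MPa <= 0).
    dry_mass
        Oven-dry mass (g).
    turgid_mass
        Saturated mass (g); estimated from the wet end when omitted.
    tlp_rule
        ``"breakpoint"`` (default) reports the water potential of the
        wettest tail datum; ``"intersection"`` reports the analytic
        intersection of the fitted osmotic line and turgor model,
        -psi_osm/(1 - psi_osm/eps).
    """
    fresh = np.asarray(fresh_mass, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if turgid_mass is None:
        turgid_mass = estimate_turgid_mass(fresh, psi)
    rwc = compute_rwc(fresh, dry_mass, turgid_mass)
    tail = find_linear_tail(rwc, psi, r2_min=r2_min)

    if tail.intercept >= 0:
        raise ValueError(
            "invalid osmotic intercept: the tail line extrapolates to a "
            "non-negative 1/psi at full hydration"
        )
    psi_osm_ft = -1.0 / tail.intercept  # magnitude, MPa

    tlp_breakpoint = float(psi[len(psi) - tail.n])

    # pre-turgor-loss points: everything before the tail
    pre = slice(0, len(psi) - tail.n)
    rwc_pre, psi_pre = rwc[pre], psi[pre]
    if len(rwc_pre) >= 3:
        psi_s = -psi_osm_ft / rwc_pre
        turgor = psi_pre - psi_s
        eps_slope, *_ = _sps.linregress(rwc_pre, turgor)
        eps = float(eps_slope)
    else:
        eps = float("nan")

    if tlp_rule == "breakpoint":
        tlp = tlp_breakpoint
    elif tlp_rule == "intersection":
        if not np.isfinite(eps) or eps <= psi_osm_ft:
            tlp = tlp_breakpoint
        else:
            tlp = closed_form_tlp(psi_osm_ft, eps)
    else:
        raise ValueError(f"unknown tlp_rule {tlp_rule!r}")

    return PVTraits(
        tlp=tlp,
        psi_osm_ft=psi_osm_ft,
        eps=eps,
        tail_n=tail.n,
        tail_r2=tail.r2,
    )


def pv_traits_table(
    pv: pd.DataFrame,
    dry_mass: float | dict,
    r2_min: float = 0.99,
    tlp_rule: str = "breakpoint",
) -> pd.DataFrame:
    """Per-leaf trait extraction over a tidy PV table.

    ``pv`` needs columns (leaf_id, step, fresh_mass_g, psi_mpa); ``dry_mass``
    is a scalar or a per-leaf mapping.  Returns one row per leaf:
    (leaf_id, tlp, psi_osm_ft, eps, tail_n, tail_r2).
    """
    rows = []
    for leaf_id, grp in pv.groupby("leaf_id", sort=False):
        grp = grp.sort_values("step")
        dm = dry_mass[leaf_id] if isinstance(dry_mass, dict) else dry_mass
        traits = extract_pv_traits(
            grp["fresh_mass_g"], grp["psi_mpa"], dry_mass=dm,
            r2_min=r2_min, tlp_rule=tlp_rule,
        )
        rows.append(
            (leaf_id, traits.tlp, traits.psi_osm_ft, traits.eps,
             traits.tail_n, traits.tail_r2)
        )
    return pd.DataFrame(
        rows, columns=["leaf_id", "tlp", "psi_osm_ft", "eps", "tail_n", "tail_r2"]
    )
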