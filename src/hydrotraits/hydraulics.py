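"""Safety margins, predicted percent embolism, and morphological traits.

Hydraulic safety margin (HSM) is the buffer between the water potentials a
plant actually experiences and those that embolise its xylem:
``psi_min - Px`` for an embolism threshold Px (P12, P50 or P88).  Positive
values mean the plant operates safely above the threshold; the margin from
P12 is always the narrowest (P12 > P50 > P88 on the water-potential axis).

Stomatal safety margin (SSM) is the buffer between stomatal closure (proxied
by the turgor loss point) and xylem failure: ``TLP - Px``.  It is the same
arithmetic as HSM with the TLP standing in for psi_min.

Predicted percent embolism (PPE) evaluates the species-mean vulnerability
curve at each individual's minimum water potential and averages across
individuals.  Because the curve is nonlinear, this differs from evaluating
the curve at the mean water potential — substantially so for steep curves —
which is why the individual-level average is used.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .vulnerability import SpeciesCurve, px, sigmoid_pe

PX_LEVELS = (12, 50, 88)


def hsm(psi_min: float, px_value: float) -> float:
    """Hydraulic safety margin psi_min - Px (MPa); positive = safe."""
    return psi_min - px_value


def ssm(tlp: float, px_value: float) -> float:
    """Stomatal safety margin TLP - Px (MPa); positive = stomata close first."""
    return tlp - px_value


def ppe(psi_min_individuals, a_mean: float, b_mean: float) -> tuple[float, float]:
    """Predicted percent embolism: mean +/- SE across individuals.

    Each individual's minimum water potential is pushed through the
    species-mean sigmoid curve; the nonlinear transform is averaged at the
    individual level.  SE is NaN for a single individual.
    """
    psi = np.asarray(psi_min_individuals, dtype=float)
    if psi.size == 0:
        raise ValueError("ppe requires at least one individual")
    vals = sigmoid_pe(psi, a_mean, b_mean)
    vals = np.atleast_1d(vals)
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else float("nan")
    return mean, se


def lma(dry_mass: float, projected_area: float) -> float:
    """Leaf mass per area (g m^-2) = dry mass (g) / projected area (m^2).

    For a batch of leaves, pass the summed mass and summed area (the ratio of
    totals, not the mean of per-leaf ratios).
    """
    if dry_mass <= 0 or projected_area <= 0:
        raise ValueError("dry_mass and projected_area must be positive")
    return dry_mass / projected_area


def sapwood_area_from_diameter(diameter: float) -> float:
    """Sapwood cross-sectional area from stem diameter, pi d^2 / 4."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return math.pi * diameter**2 / 4.0


def huber(sapwood_area: float, leaf_area: float) -> float:
    """Huber value: sapwood area / subtended leaf area (same units, unitless)."""
    if sapwood_area <= 0 or leaf_area <= 0:
        raise ValueError("sapwood_area and leaf_area must be positive")
    return sapwood_area / leaf_area


def safety_margin_table(
    curves: dict[str, SpeciesCurve] | pd.DataFrame,
    pv_means: pd.DataFrame,
    field: pd.DataFrame,
) -> pd.DataFrame:
    """Species x period table of safety margins and PPE.

    Parameters
    ----------
    curves
        Species-mean vulnerability curves: mapping species ->
        :class:`~hydrotraits.vulnerability.SpeciesCurve`, or a DataFrame with
        columns (species, a_mean, b_mean).
    pv_means
        Species-mean PV traits with columns (species, tlp) and optionally
        (tlp_se); extra columns are ignored.
    field
        Long-format water potentials (species, individual, period,
        psi_md_mpa).

    Returns one row per species x period with hsm12/50/88 (from the mean
    minimum water potential of that period), ssm12/50/88 (period-independent,
    repeated per row), ppe_mean/ppe_se and n (individuals).
    """
    if isinstance(curves, pd.DataFrame):
        curve_params = {
            r["species"]: (float(r["a_mean"]), float(r["b_mean"]))
            for _, r in curves.iterrows()
        }
    else:
        curve_params = {s: (c.a_mean, c.b_mean) for s, c in curves.items()}
    tlp_by_species = pv_means.set_index("species")["tlp"].to_dict()

    rows = []
    for (species, period), grp in field.groupby(["species", "period"], sort=True):
        if species not in curve_params:
            raise KeyError(f"no vulnerability curve for species {species!r}")
        if species not in tlp_by_species:
            raise KeyError(f"no PV traits for species {species!r}")
        a_m, b_m = curve_params[species]
        tlp = float(tlp_by_species[species])
        psi = grp["psi_md_mpa"].to_numpy(dtype=float)
        psi_min_mean = float(psi.mean())
        thresholds = {x: px(a_m, b_m, float(x)) for x in PX_LEVELS}
        ppe_mean, ppe_se = ppe(psi, a_m, b_m)
        rows.append(
            {
                "species": species,
                "period": period,
                **{f"hsm{x}": hsm(psi_min_mean, thresholds[x]) for x in PX_LEVELS},
                **{f"ssm{x}": ssm(tlp, thresholds[x]) for x in PX_LEVELS},
                "ppe_mean": ppe_mean,
                "ppe_se": ppe_se,
                "n": len(psi),
            }
        )
    return pd.DataFrame(rows)
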