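"""Published species-mean traits for six woody Albany Subtropical Thicket trees.

Trait means (± SE where available) for six dominant evergreen woody species of
South Africa's Albany Subtropical Thicket (Eastern Cape), as reported from
laboratory vulnerability-curve and Pressure-Volume measurements and field
water-potential campaigns during a protracted dry period (spring 2020) and a
subsequent wetter period (November 2022):

* ``tlp``       turgor loss point (MPa, negative)
* ``psi_osm``   osmotic potential at full turgor (MPa, positive magnitude)
* ``eps``       bulk elastic modulus (MPa)
* ``p50``       leaf xylem water potential at 50% embolism (MPa)
* ``slope_a``   sigmoid steepness parameter a (MPa^-1)
* ``ssm``       published stomatal safety margin TLP - P50 (MPa)
* ``hsm_2020`` / ``hsm_2022``  hydraulic safety margins from P50 (MPa)
* ``psi_min_2020`` / ``psi_min_2022``  per-period mean minimum water
  potential, back-computed as HSM + P50, with sd = SE * sqrt(n)
* ``lma`` (g m^-2), ``height`` (m), ``huber`` (sapwood/leaf area)

Missing entries in the source tables are filled with mid-range synthetic
values and marked in ``SYNTHETIC_FILLS`` (Boscia dry-period Ψ_min and Huber
value were not reported).
"""

from __future__ import annotations

import pandas as pd

# fmt: off
_ROWS = [
    # species,  tlp,   psi_osm, eps,   p50,   slope_a, ssm,  hsm20, hsm22, psi20,  sd20, psi22, sd22, lma,   height, huber
    ("Boscia",   -1.95, 1.37,  4.61,  -6.39, -3.34, 4.44, None,  2.39, -4.50, 0.45, -4.00, 0.45, 346.1, 3.6, 0.150),
    ("Searsia",  -3.69, 2.17,  6.14,  -8.09, -10.07, 4.40, 2.06,  3.78, -6.03, 0.82, -4.31, 0.50, 106.1, 2.2, 0.144),
    ("Euclea",   -3.82, 2.92, 12.43,  -8.02, -2.23, 4.20, 2.18,  3.14, -5.84, 1.49, -4.88, 0.48, 265.9, 2.4, 0.136),
    ("Pappea",   -2.33, 1.45,  3.88,  -5.61, -2.93, 3.28, 0.06,  0.84, -5.55, 1.42, -4.77, 0.56, 136.5, 3.7, 0.379),
    ("Schotia",  -1.33, 0.93,  3.87,  -4.64, -4.03, 3.31, 0.82,  1.53, -3.82, 0.70, -3.11, 0.85, 218.0, 2.6, 0.114),
    ("Polygala", -1.67, 1.02,  3.48,  -4.87, -0.77, 3.20, -0.46, 1.08, -5.33, 1.04, -3.79, 0.40, 144.0, 1.4, 0.127),
]
# fmt: on

REFERENCE_TRAITS = pd.DataFrame(
    _ROWS,
    columns=[
        "species", "tlp", "psi_osm", "eps", "p50", "slope_a", "ssm",
        "hsm_2020", "hsm_2022",
        "psi_min_2020", "psi_min_2020_sd", "psi_min_2022", "psi_min_2022_sd",
        "lma", "height", "huber",
    ],
).set_index("species")

#: entries not present in the published tables, filled with plausible values
SYNTHETIC_FILLS = {
    ("Boscia", "psi_min_2020"): "no dry-period water potentials were reported; "
    "set to -4.5 MPa (drier than the 2022 value)",
    ("Boscia", "huber"): "not reported; mid-range of the other five species",
}

PERIODS = ("2020-dry", "2022-wet")
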