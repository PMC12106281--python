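"""Standardized Precipitation Index (SPI).

The SPI characterises meteorological drought by transforming rolling
precipitation totals to standard-normal units: a gamma distribution is fitted
to the positive rolling sums, zeros are handled by a mixed distribution
``H(x) = q + (1 - q) * GammaCDF(x)`` with ``q`` the zero fraction, and
``SPI = Phi^-1(H(x))``.  Negative SPI indicates drier-than-usual conditions;
-1.5 to -2 is conventionally a severe drought.

By default a single gamma is fitted to all windows pooled ("long-term" SPI
trace); fitting per ending calendar month — the strict standard when
seasonality matters — is available with ``per_month=True``.  The gamma is
fitted by maximum likelihood with the location pinned at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps


@dataclass(frozen=True)
class GammaFit:
    shape: float
    scale: float
    zero_prob: float


def rolling_sum(mm, window: int = 12) -> np.ndarray:
    """Trailing sums over ``window`` months, aligned to the window end.

    Output length is ``n - window + 1``; raises on series shorter than the
    window.  ``window=1`` is the identity.
    """
    mm = np.asarray(mm, dtype=float)
    if len(mm) < window:
        raise ValueError(f"series of {len(mm)} months is shorter than window {window}")
    c = np.concatenate([[0.0], np.cumsum(mm)])
    return c[window:] - c[:-window]


def fit_spi(sums) -> tuple[np.ndarray, GammaFit]:
    """SPI values for a set of rolling sums, with the fitted gamma.

    Gamma parameters come from maximum likelihood on the positive sums
    (location fixed at 0); ``q`` is the fraction of zero sums.  Warns below
    30 sums (too short a record for a stable fit); raises on zero variance.
    """
    sums = np.asarray(sums, dtype=float)
    if sums.std() <= 0:
        raise ValueError("zero variance in rolling sums; SPI undefined")
    if len(sums) < 30:
        warnings.warn(
            f"only {len(sums)} sums; >= 30 recommended for a stable SPI fit",
            stacklevel=2,
        )
    positive = sums[sums > 0]
    q = 1.0 - len(positive) / len(sums)
    shape, _, scale = _sps.gamma.fit(positive, floc=0)
    h = np.where(
        sums > 0,
        q + (1.0 - q) * _sps.gamma.cdf(sums, shape, scale=scale),
        q if q > 0 else 1e-9,
    )
    h = np.clip(h, 1e-9, 1 - 1e-9)
    spi = _sps.norm.ppf(h)
    return spi, GammaFit(shape=float(shape), scale=float(scale), zero_prob=float(q))


def spi_series(
    precip: pd.DataFrame, window: int = 12, per_month: bool = False
) -> pd.DataFrame:
    """SPI trace from a monthly precipitation table (year, month, mm).

    Returns one row per complete trailing window: (year, month, sum_mm, spi),
    with (year, month) the window's ending month.  ``per_month=True`` fits a
    separate gamma for each ending calendar month instead of one pooled fit.
    """
    precip = precip.sort_values(["year", "month"]).reset_index(drop=True)
    mm = precip["mm"].to_numpy(dtype=float)
    if (mm < 0).any():
        raise ValueError("negative precipitation")
    sums = rolling_sum(mm, window=window)
    tail = precip.iloc[window - 1:].reset_index(drop=True)
    out = pd.DataFrame(
        {"year": tail["year"], "month": tail["month"], "sum_mm": sums}
    )
    if per_month:
        spi = np.empty(len(out))
        for m, grp in out.groupby("month"):
            vals, _ = fit_spi(grp["sum_mm"].to_numpy())
            spi[grp.index] = vals
        out["spi"] = spi
    else:
        out["spi"], _ = fit_spi(sums)
    return out
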