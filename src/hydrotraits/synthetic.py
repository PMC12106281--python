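"""Synthetic data generator for the whole drought-physiology pipeline.

Emulates all five raw-data kinds with known ground truth:

1. optical-vulnerability campaigns (per-frame embolism-event tables plus a
   psychrometer water-potential log, optionally rendered to an image stack),
2. Pressure-Volume bench-drying series,
3. field campaigns of per-individual midday/minimum water potentials,
4. canopy drought-damage surveys, and
5. monthly precipitation series.

Each generator takes a :class:`SpeciesParams` (the biological ground truth)
and a :class:`GeneratorConfig` (sampling/noise settings) and returns tidy
pandas tables plus a metadata dict recording the truth, so every downstream
stage can be tested by parameter recovery without any external data.

All generators are deterministic given (params, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .vulnerability import px
from .pressure_volume import closed_form_tlp


@dataclass(frozen=True)
class SpeciesParams:
    """Ground-truth physiological parameters for one species.

    ``a``/``b`` parameterise the sigmoid vulnerability curve (both negative,
    MPa^-1 and MPa); ``psi_osm_ft`` is the magnitude of the osmotic potential
    at full turgor (MPa, positive) and ``eps`` the bulk elastic modulus (MPa);
    turgor loss requires ``eps > psi_osm_ft``.  ``psi_min_by_period`` maps a
    period label to the (mean, sd) of individual minimum water potentials;
    ``damage_coefs`` maps a damage metric to its log-scale linear-predictor
    coefficients on trait columns (key ``"intercept"`` for the constant).
    """

    name: str
    a: float
    b: float
    psi_osm_ft: float
    eps: float
    apoplastic_fraction: float = 0.0
    psi_min_by_period: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    damage_coefs: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    lma: float | None = None
    height: float | None = None
    huber: float | None = None

    def __post_init__(self):
        if not self.a < 0:
            raise ValueError(f"{self.name}: sigmoid steepness a must be < 0")
        if not self.b < 0:
            raise ValueError(f"{self.name}: P50 parameter b must be < 0")
        if not self.psi_osm_ft > 0:
            raise ValueError(f"{self.name}: psi_osm_ft must be > 0 (magnitude)")
        if not self.eps > self.psi_osm_ft:
            raise ValueError(
                f"{self.name}: eps ({self.eps}) must exceed psi_osm_ft "
                f"({self.psi_osm_ft}); otherwise turgor is never lost"
            )
        if not 0.0 <= self.apoplastic_fraction < 1.0:
            raise ValueError(f"{self.name}: apoplastic_fraction must be in [0, 1)")
        for period, (_, sd) in self.psi_min_by_period.items():
            if sd < 0:
                raise ValueError(f"{self.name}/{period}: sd must be >= 0")

    @property
    def tlp_true(self) -> float:
        return closed_form_tlp(self.psi_osm_ft, self.eps)


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling and noise settings shared by the generators.

    Defaults emulate the bench and field protocols: images every 5 min,
    psychrometer log every 10 min, slow bench drying at 0.06 MPa h^-1
    (so a full curve takes ~2-6 days depending on xylem resistance),
    15-point PV series, and site-like rainfall (gamma-distributed monthly
    totals with mean 28 mm, i.e. ~338 mm yr^-1).
    """

    seed: int = 0
    # optical-vulnerability campaign
    n_pixels: int = 2000
    event_size: int = 1
    frame_interval: float = 5.0  # min
    log_interval: float = 10.0  # min
    psi_start: float = -0.1  # MPa at t=0
    drying_rate: float = 0.06  # MPa per hour, linear by default
    drying: str = "linear"  # or "exponential"
    # pressure-volume series
    n_pv_points: int = 15
    pv_overdry: float = 1.5  # dry down to |psi| = pv_overdry * |TLP|
    dry_mass: float = 0.2  # g
    water_mass_max: float = 0.3  # g of water at full turgor
    mass_noise_sd: float = 0.0  # g
    psi_noise_sd: float = 0.0  # MPa
    # field campaign
    n_individuals: int = 8
    # precipitation
    n_years: int = 60
    gamma_shape: float = 2.0
    gamma_scale: float = 14.0  # mm; mean monthly rainfall = shape*scale

    def __post_init__(self):
        for name in ("n_pixels", "n_pv_points", "n_individuals", "n_years", "event_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("mass_noise_sd", "psi_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def logistic_threshold(u, a: float, b: float):
    """Embolism water potential for quantile ``u``: Psi_u = b + ln(u/(1-u))/a.

    Closed-form inverse of the sigmoid curve — the threshold at which a
    conduit drawn at cumulative fraction ``u`` of the population embolises.
    The median (u = 0.5) is exactly ``b``.
    """
    u = np.asarray(u, dtype=float)
    out = b + np.log(u / (1.0 - u)) / a
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# optical-vulnerability campaign
# ---------------------------------------------------------------------------

def gen_embolism_campaign(
    params: SpeciesParams,
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate one leaf's optical-vulnerability drydown.

    The leaf dries from ``cfg.psi_start`` down past the point where >99.5% of
    conduits have embolised; water potential declines linearly in time by
    default (exponential decay optional) and is logged every
    ``cfg.log_interval`` minutes.  Each of ``cfg.n_pixels`` embolism events
    has its threshold drawn from the logistic implied by (a, b) and is
    assigned to the imaging frame whose water potential is closest.

    Returns ``(events, psychrometer, meta)`` where ``events`` has columns
    (frame_idx, time_min, n_pixels) for frames with at least one event,
    ``psychrometer`` has (time_min, psi_mpa) and ``meta`` records the truth.
    """
    if rng is None:
        rng = cfg.rng()
    if cfg.n_pixels < 10:
        raise ValueError("n_pixels < 10: too few events to fit a curve")

    psi_end = px(params.a, params.b, 99.5) - 0.25
    duration_min = (cfg.psi_start - psi_end) / cfg.drying_rate * 60.0
    frame_t = np.arange(0.0, duration_min + cfg.frame_interval, cfg.frame_interval)
    log_t = np.arange(0.0, duration_min + cfg.log_interval, cfg.log_interval)

    if cfg.drying == "linear":
        def psi_of_t(t):
            return cfg.psi_start - cfg.drying_rate / 60.0 * t
    elif cfg.drying == "exponential":
        # relaxes towards psi_end with the same initial rate as the linear trace
        tau = (psi_end - cfg.psi_start) / (-cfg.drying_rate / 60.0)

        def psi_of_t(t):
            return psi_end + (cfg.psi_start - psi_end) * np.exp(-t / tau)
    else:
        raise ValueError(f"unknown drying mode {cfg.drying!r}")

    frame_psi = psi_of_t(frame_t)
    u = rng.uniform(size=cfg.n_pixels)
    psi_u = logistic_threshold(u, params.a, params.b)
    # nearest-psi frame; monotone trace, so searchsorted on the descending grid
    idx = np.searchsorted(-frame_psi, -psi_u)
    idx = np.clip(idx, 1, len(frame_t) - 1)
    left_closer = np.abs(frame_psi[idx - 1] - psi_u) <= np.abs(frame_psi[idx] - psi_u)
    idx = np.where(left_closer, idx - 1, idx)
    idx = np.clip(idx, 1, len(frame_t) - 1)  # diff series starts at frame 1

    counts = np.bincount(idx, minlength=len(frame_t)) * cfg.event_size
    nz = np.nonzero(counts)[0]
    events = pd.DataFrame(
        {"frame_idx": nz, "time_min": frame_t[nz], "n_pixels": counts[nz]}
    )
    psych = pd.DataFrame({"time_min": log_t, "psi_mpa": psi_of_t(log_t)})
    meta = {
        "species": params.name,
        "a_true": params.a,
        "b_true": params.b,
        "n_events": int(cfg.n_pixels),
        "total_pixels": int(counts.sum()),
        "n_frames": len(frame_t),
        "frame_interval": cfg.frame_interval,
        "psi_start": cfg.psi_start,
        "psi_end": float(frame_psi[-1]),
    }
    return events, psych, meta


def gen_image_stack(
    events: pd.DataFrame,
    frame_shape: tuple[int, int],
    n_frames: int,
    background: int = 20,
    embolized: int = 220,
) -> np.ndarray:
    """Render an event table to a synthetic grayscale image stack.

    Each event flips a disjoint block of pixels from ``background`` to
    ``embolized`` intensity at its frame index (and they stay flipped), so
    differencing the stack recovers the event table exactly.  Raises if the
    total pixel count overflows the frame area.
    """
    h, w = frame_shape
    if h < 8 or w < 8:
        raise ValueError("frame_shape must be at least 8x8")
    total = int(events["n_pixels"].sum())
    if total > h * w:
        raise ValueError(
            f"events need {total} pixels but the frame holds only {h * w}"
        )
    stack = np.full((n_frames, h, w), background, dtype=np.uint8)
    flat = stack.reshape(n_frames, -1)
    offset = 0
    for frame_idx, n_px in zip(events["frame_idx"], events["n_pixels"]):
        if frame_idx >= n_frames:
            raise ValueError(f"event frame {frame_idx} outside stack of {n_frames}")
        flat[int(frame_idx):, offset:offset + int(n_px)] = embolized
        offset += int(n_px)
    return stack


# ---------------------------------------------------------------------------
# pressure-volume series
# ---------------------------------------------------------------------------

def pv_forward(rel_water, psi_osm_ft: float, eps: float):
    """Water potential of the symplastic linear-elasticity model at RWC ``rel_water``.

    psi = psi_s + psi_p with psi_s = -psi_osm_ft / R (osmometer behaviour)
    and psi_p = max(0, psi_osm_ft - eps * (1 - R)) (linear turgor decline).
    At full turgor (R = 1) the two components cancel and psi = 0.
    """
    r = np.asarray(rel_water, dtype=float)
    psi_s = -psi_osm_ft / r
    psi_p = np.maximum(0.0, psi_osm_ft - eps * (1.0 - r))
    out = psi_s + psi_p
    return out.item() if out.ndim == 0 else out


def gen_pv_series(
    params: SpeciesParams,
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
    leaf_id: str = "leaf1",
) -> tuple[pd.DataFrame, dict]:
    """Simulate one leaf's bench-drying Pressure-Volume series.

    Symplastic relative water content declines on a grid from full turgor
    (R = 1, psi = 0) through the turgor-loss point (included as a grid point)
    down to ``|psi| = cfg.pv_overdry * |TLP|``; roughly half the points lie
    beyond turgor loss.  Fresh mass is dry mass plus
    ``water_mass_max * (af + (1 - af) * R)``.  Gaussian noise on masses and
    water potentials is optional (off by default).

    Returns ``(table, meta)`` with table columns
    (leaf_id, step, fresh_mass_g, psi_mpa) and meta carrying dry mass, true
    turgid mass and the ground-truth (TLP, psi_osm_ft, eps).
    """
    if rng is None:
        rng = cfg.rng()
    n = cfg.n_pv_points
    if n < 8:
        raise ValueError("n_pv_points must be >= 8 (need >= 3 points beyond TLP)")
    po, e, af = params.psi_osm_ft, params.eps, params.apoplastic_fraction
    tlp = closed_form_tlp(po, e)
    r_tlp = 1.0 - po / e
    r_min = po / (cfg.pv_overdry * abs(tlp))
    pre_n = n // 2
    post_n = n - pre_n
    r_pre = np.linspace(1.0, r_tlp, pre_n + 1)[:-1]
    r_post = np.linspace(r_tlp, r_min, post_n)
    rel = np.concatenate([r_pre, r_post])

    psi = pv_forward(rel, po, e)
    fresh = cfg.dry_mass + cfg.water_mass_max * (af + (1.0 - af) * rel)
    if cfg.mass_noise_sd > 0:
        fresh = fresh + rng.normal(0.0, cfg.mass_noise_sd, size=n)
    if cfg.psi_noise_sd > 0:
        psi = np.minimum(psi + rng.normal(0.0, cfg.psi_noise_sd, size=n), 0.0)

    table = pd.DataFrame(
        {
            "leaf_id": leaf_id,
            "step": np.arange(n),
            "fresh_mass_g": fresh,
            "psi_mpa": psi,
        }
    )
    meta = {
        "species": params.name,
        "dry_mass": cfg.dry_mass,
        "turgid_mass": cfg.dry_mass + cfg.water_mass_max,
        "tlp_true": tlp,
        "psi_osm_ft_true": po,
        "eps_true": e,
        "apoplastic_fraction": af,
        "n_post_tlp": int(post_n),
    }
    return table, meta


# ---------------------------------------------------------------------------
# field campaign, damage survey, precipitation
# ---------------------------------------------------------------------------

def gen_field_campaign(
    params_list: Sequence[SpeciesParams],
    periods: Sequence[str],
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-individual midday water potentials by species and period.

    Draws Normal(mean, sd) per species x period (from
    ``params.psi_min_by_period``) truncated from above at -0.01 MPa so no
    non-physical positive potential is emitted.  Long format:
    (species, individual, period, psi_md_mpa).
    """
    if rng is None:
        rng = cfg.rng()
    if cfg.n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    rows = []
    for params in params_list:
        for period in periods:
            if period not in params.psi_min_by_period:
                raise KeyError(
                    f"{params.name} has no psi_min distribution for period "
                    f"{period!r}; available: {sorted(params.psi_min_by_period)}"
                )
            mean, sd = params.psi_min_by_period[period]
            draws = np.minimum(
                rng.normal(mean, sd, size=cfg.n_individuals), -0.01
            )
            for i, psi in enumerate(draws, start=1):
                rows.append((params.name, i, period, float(psi)))
    return pd.DataFrame(
        rows, columns=["species", "individual", "period", "psi_md_mpa"]
    )


DAMAGE_METRICS = ("crown_extent", "foliage", "dead_leaves", "discoloration")


def gen_damage_survey(
    traits: pd.DataFrame,
    damage_coefs: Mapping[str, Mapping[str, float]],
    noise_sd: float,
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
    n_observers: int = 2,
) -> pd.DataFrame:
    """Canopy damage metrics generated from a trait-based log-linear model.

    For each metric the expected value is ``clip(exp(intercept + X @ beta),
    0, 100)`` — matching the Gaussian log-link GLM used in the analysis —
    and each of ``n_observers`` replicates adds Gaussian observer noise;
    replicates are averaged and the result clipped to [0, 100].

    ``traits`` must contain every coefficient name (other than
    ``"intercept"``) as a column; unknown names raise with the available
    columns listed.
    """
    if rng is None:
        rng = cfg.rng()
    out = traits.copy()
    for metric, coefs in damage_coefs.items():
        lp = np.full(len(traits), float(coefs.get("intercept", 0.0)))
        for name, beta in coefs.items():
            if name == "intercept":
                continue
            if name not in traits.columns:
                raise KeyError(
                    f"unknown trait {name!r} in coefficients for {metric!r}; "
                    f"available traits: {sorted(traits.columns)}"
                )
            lp = lp + beta * traits[name].to_numpy(dtype=float)
        expected = np.clip(np.exp(lp), 0.0, 100.0)
        obs = expected[None, :] + rng.normal(
            0.0, noise_sd, size=(n_observers, len(traits))
        )
        out[metric] = np.clip(obs.mean(axis=0), 0.0, 100.0)
    return out


def gen_precip(
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
    drought_block: tuple[int, int] | None = None,
    drought_factor: float = 0.5,
) -> pd.DataFrame:
    """Monthly precipitation: i.i.d. Gamma(shape, scale) totals.

    ``drought_block = (start_month_index, length)`` multiplies the gamma
    scale by ``drought_factor`` over that span, emulating a protracted
    meteorological drought.  Returns (year, month, mm).
    """
    if rng is None:
        rng = cfg.rng()
    if cfg.n_years < 3:
        raise ValueError("n_years must be >= 3 (>= 30 recommended for SPI)")
    n_months = cfg.n_years * 12
    scale = np.full(n_months, float(cfg.gamma_scale))
    if drought_block is not None:
        start, length = drought_block
        scale[start:start + length] *= drought_factor
    mm = rng.gamma(cfg.gamma_shape, scale) if cfg.gamma_scale > 0 else np.zeros(n_months)
    years = np.repeat(np.arange(cfg.n_years) + 1960, 12)
    months = np.tile(np.arange(1, 13), cfg.n_years)
    return pd.DataFrame({"year": years, "month": months, "mm": mm})


__all__ = [
    "SpeciesParams",
    "GeneratorConfig",
    "logistic_threshold",
    "gen_embolism_campaign",
    "gen_image_stack",
    "pv_forward",
    "gen_pv_series",
    "gen_field_campaign",
    "gen_damage_survey",
    "gen_precip",
    "DAMAGE_METRICS",
]
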