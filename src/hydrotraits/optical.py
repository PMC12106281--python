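"""Optical embolism quantification.

Embolism events appear as abrupt pixel-intensity changes between sequential
images of a dehydrating leaf.  This module turns an image stack (or a
pre-computed per-frame changed-pixel event table) plus a psychrometer log of
water potential versus time into a cumulative percent-embolism trace:

    diff_stack -> filter_events -> align_psi -> cumulate

The changed-pixel series is a tidy frame-difference table with columns
(frame_idx, time_min, changed_pixels, kept); ``frame_idx`` k refers to the
change between frames k-1 and k.  Cumulative embolism is the running sum of
kept pixels expressed as a percentage of the total, so a complete drydown
always ends at exactly 100%.

Filtering replaces the manual removal of leaf-movement artefacts with a
deterministic rule: drop events smaller than ``min_size`` pixels (shot
noise) and larger than a high quantile of nonzero event sizes (whole-frame
shifts).  Both thresholds are configurable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def read_stack(path: str | Path) -> np.ndarray:
    """Load a multi-page grayscale TIFF as a (frames, height, width) array."""
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None, ...]
    if stack.ndim != 3:
        raise ValueError(f"{path}: expected a grayscale stack, got shape {stack.shape}")
    return stack


def write_stack(stack: np.ndarray, path: str | Path) -> Path:
    """Write a (frames, height, width) array as a multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack))
    return path


def diff_stack(
    stack: np.ndarray,
    binarize_threshold: float = 0.0,
    frame_interval: float = 5.0,
) -> pd.DataFrame:
    """Per-frame changed-pixel counts from a grayscale image stack.

    For each consecutive frame pair, counts pixels whose absolute intensity
    change exceeds ``binarize_threshold``.  ``stack`` must be a (frames,
    height, width) array with at least two frames.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be a 3-D (frames, height, width) array")
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 frames to difference")
    diffs = np.abs(np.diff(stack.astype(np.int64), axis=0))
    counts = (diffs > binarize_threshold).sum(axis=(1, 2))
    idx = np.arange(1, stack.shape[0])
    return pd.DataFrame(
        {
            "frame_idx": idx,
            "time_min": idx * frame_interval,
            "changed_pixels": counts,
            "kept": True,
        }
    )


def series_from_events(events: pd.DataFrame) -> pd.DataFrame:
    """Frame-difference series from a sparse event table (frame_idx, time_min, n_pixels)."""
    return pd.DataFrame(
        {
            "frame_idx": events["frame_idx"].to_numpy(),
            "time_min": events["time_min"].to_numpy(dtype=float),
            "changed_pixels": events["n_pixels"].to_numpy(),
            "kept": True,
        }
    )


def filter_events(
    series: pd.DataFrame,
    min_size: int = 2,
    max_size_quantile: float = 0.995,
) -> pd.DataFrame:
    """Flag putative artefacts in a frame-difference series.

    Nonzero events with fewer than ``min_size`` changed pixels, or more than
    the ``max_size_quantile`` quantile of nonzero event sizes, have their
    ``kept`` flag cleared.  The input is not modified.  Raises when nothing
    survives ("no embolism signal").
    """
    if len(series) == 0:
        raise ValueError("empty frame-difference series")
    out = series.copy()
    sizes = out["changed_pixels"].to_numpy(dtype=float)
    nonzero = sizes > 0
    kept = nonzero & (sizes >= min_size)
    if nonzero.any():
        cutoff = np.quantile(sizes[nonzero], max_size_quantile)
        kept &= sizes <= cutoff
    out["kept"] = kept | ~nonzero  # zero rows stay kept (they carry no signal)
    if not (kept & nonzero).any():
        raise ValueError("no embolism signal: every event was filtered out")
    return out


def align_psi(
    series: pd.DataFrame,
    psychrometer: pd.DataFrame,
    isotonic: bool = False,
) -> np.ndarray:
    """Water potential per frame, linearly interpolated from the psychrometer log.

    The log (time_min, psi_mpa) is sampled more coarsely than the image
    series; linear interpolation in time bridges the two.  Extrapolation is
    allowed up to one log interval past either end (constant-endpoint);
    frames further out raise.  With ``isotonic=True`` the result is made
    monotone non-increasing by a running minimum (off by default).
    """
    t = series["time_min"].to_numpy(dtype=float)
    log_t = psychrometer["time_min"].to_numpy(dtype=float)
    log_psi = psychrometer["psi_mpa"].to_numpy(dtype=float)
    if len(log_t) < 2:
        raise ValueError("psychrometer log needs at least 2 samples")
    interval = float(np.median(np.diff(log_t)))
    if t.min() < log_t[0] - interval or t.max() > log_t[-1] + interval:
        raise ValueError(
            "psychrometer log does not span the image series (beyond one "
            f"log interval): frames cover [{t.min()}, {t.max()}] min, "
            f"log covers [{log_t[0]}, {log_t[-1]}] min"
        )
    psi = np.interp(t, log_t, log_psi)
    if isotonic:
        psi = np.minimum.accumulate(psi)
    return psi


def cumulate(series: pd.DataFrame, psi: np.ndarray) -> pd.DataFrame:
    """Cumulative percent embolism trace from kept events.

    cum_pct at frame k is 100 x (kept pixels up to k) / (total kept pixels);
    by construction it is non-decreasing and ends at exactly 100.  Returns a
    trace table (frame_idx, time_min, psi_mpa, cum_pct) with the total pixel
    count stored in ``trace.attrs["total_pixels"]``.
    """
    psi = np.asarray(psi, dtype=float)
    if len(psi) != len(series):
        raise ValueError("psi must have one value per frame in the series")
    pixels = np.where(
        series["kept"].to_numpy(), series["changed_pixels"].to_numpy(dtype=float), 0.0
    )
    total = pixels.sum()
    if total <= 0:
        raise ValueError("zero total embolized pixels: nothing to cumulate")
    cum = 100.0 * np.cumsum(pixels) / total
    trace = pd.DataFrame(
        {
            "frame_idx": series["frame_idx"].to_numpy(),
            "time_min": series["time_min"].to_numpy(dtype=float),
            "psi_mpa": psi,
            "cum_pct": cum,
        }
    )
    trace.attrs["total_pixels"] = float(total)
    return trace


def trace_from_events(
    events: pd.DataFrame,
    psychrometer: pd.DataFrame,
    min_size: int = 0,
    max_size_quantile: float = 1.0,
    isotonic: bool = False,
) -> pd.DataFrame:
    """Convenience pipeline: event table + psychrometer log -> embolism trace.

    Defaults apply no artefact filtering (synthetic event tables are clean);
    pass ``min_size=2, max_size_quantile=0.995`` for the standard artefact
    rule on real differenced stacks.
    """
    series = series_from_events(events)
    if min_size > 0 or max_size_quantile < 1.0:
        series = filter_events(series, min_size, max_size_quantile)
    psi = align_psi(series, psychrometer, isotonic=isotonic)
    return cumulate(series, psi)
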