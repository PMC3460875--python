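"""Amplification-curve processing: baseline, efficiency, threshold, CT.

Implements window-of-linearity analysis of raw qPCR fluorescence: a
constant background is subtracted, log10 signal is regressed on cycle in a
sliding window, the best-fitting window's slope gives the per-reaction
amplification efficiency (E = 10**slope, fold per cycle), and CT values are
read off at an amplicon-wide fluorescence threshold by log-linear
interpolation.

Fixed choices: constant (not sloped) baseline; window length 5 by default
(4-7 supported); fits with R^2 below 0.99 flag the reaction as low quality
but keep it; the amplicon threshold is the geometric mean of each curve's
corrected signal at its window midpoint. During baseline estimation the
window search is confined to the early exponential phase (raw signal within
about two decades of the curve's noise floor), where a mis-set baseline
visibly bends the log-linear fit; high-signal cycles carry no baseline
information.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "AmpCurve",
    "FlatReactionError",
    "correct_baseline",
    "fit_efficiency",
    "amplicon_group",
    "read_curves",
    "write_fits",
]

R2_QUALITY_GATE = 0.99
MIN_WINDOW = 4
_TIE = 1e-12  # R^2 ties within this margin resolve to the earliest window


class FlatReactionError(ValueError):
    """Raised when no baseline leaves a usable exponential phase."""


@dataclass
class AmpCurve:
    """One well's amplification curve and its fitted quantities.

    ``cycles``/``signal`` are the raw trace (cycles strictly increasing);
    the remaining fields are populated by :func:`correct_baseline`,
    :func:`fit_efficiency` and :func:`amplicon_group`.
    """

    well_id: str
    amplicon_id: str
    cycles: np.ndarray
    signal: np.ndarray
    baseline: float | None = None
    corrected: np.ndarray | None = None
    window: tuple[int, int] | None = None  # inclusive cycle interval
    efficiency: float | None = None
    r_squared: float | None = None
    low_quality: bool = False
    ct: float | None = None

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.cycles.shape != self.signal.shape:
            raise ValueError("cycles and signal lengths differ")
        if not (np.diff(self.cycles) > 0).all():
            raise ValueError("cycles must be strictly increasing")
        if (self.signal < 0).any():
            raise ValueError("fluorescence must be non-negative")


def _window_fits(
    corrected: np.ndarray,
    cycles: np.ndarray,
    wlen: int,
    window_mask: np.ndarray | None = None,
) -> tuple[float, float, tuple[int, int]] | None:
    """Best sliding-window log-linear fit: (r2, slope, window) or None.

    A window qualifies when every corrected signal in it is positive, the
    fitted slope is positive, and the log signal is not flat. Ties in R^2
    (within 1e-12) resolve to the earliest window. ``window_mask`` can
    additionally disqualify windows (True = allowed).
    """
    n = len(cycles)
    if n < wlen:
        return None
    pos = corrected > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        logs = np.where(pos, np.log10(np.where(pos, corrected, 1.0)), np.nan)
    yw = sliding_window_view(logs, wlen)
    xw = sliding_window_view(cycles, wlen)
    valid = sliding_window_view(pos, wlen).all(axis=1)
    if window_mask is not None:
        valid &= window_mask
    if not valid.any():
        return None
    xm = xw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    sxx = ((xw - xm) ** 2).sum(axis=1)
    syy = ((yw - ym) ** 2).sum(axis=1)
    sxy = ((xw - xm) * (yw - ym)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(sxx > 0, sxy / sxx, np.nan)
        r2 = np.where((sxx > 0) & (syy > 0), sxy**2 / (sxx * syy), np.nan)
    ok = valid & np.isfinite(r2) & (slope > 0) & (syy > 0)
    if not ok.any():
        return None
    r2 = np.where(ok, r2, -np.inf)
    best = r2.max()
    i = int(np.argmax(r2 >= best - _TIE))
    return float(r2[i]), float(slope[i]), (int(cycles[i]), int(cycles[i + wlen - 1]))


def _early_phase_mask(signal: np.ndarray, wlen: int, span: float = 100.0) -> np.ndarray:
    """Windows confined to the early exponential phase (low raw signal).

    Allowed windows have every raw signal at most ``span`` times the noise
    floor (the smallest positive signal). The bound is relaxed by decades
    until at least one full window qualifies.
    """
    floor = signal[signal > 0].min() if (signal > 0).any() else 0.0
    if floor == 0.0:
        return np.ones(len(signal) - wlen + 1, dtype=bool)
    wmax = sliding_window_view(signal, wlen).max(axis=1)
    bound = span * floor
    mask = wmax <= bound
    while not mask.any() and bound < signal.max():
        bound *= 10.0
        mask = wmax <= bound
    if not mask.any():
        mask = np.ones_like(mask, dtype=bool)
    return mask


def correct_baseline(curve: AmpCurve, window_len: int = 5) -> AmpCurve:
    """Subtract the constant background that best linearises the log signal.

    The baseline is grid-searched on [0, min signal) and refined by staged
    grid zooming; the objective is the R^2 of the best early-phase
    log-linear window on the corrected signal (a wrong constant bends the
    log curve exactly where the signal is comparable to the background).
    Raises :class:`FlatReactionError` when no baseline leaves a window of
    ``window_len`` positive, rising cycles.
    """
    if len(curve.cycles) < 15:
        raise ValueError("need at least 15 cycles for baseline correction")
    mask = _early_phase_mask(curve.signal, window_len)
    smin = float(curve.signal.min())
    b_hi = max(smin * (1.0 - 1e-12), smin - 1e-12, 0.0)

    def objective(b: float) -> float:
        q = _window_fits(curve.signal - b, curve.cycles, window_len, mask)
        return q[0] if q is not None else -np.inf

    lo, hi = 0.0, b_hi
    grid = np.linspace(lo, hi, 129)
    scores = np.array([objective(b) for b in grid])
    if not np.isfinite(scores).any():
        raise FlatReactionError(
            f"well {curve.well_id!r}: no baseline leaves >= {window_len} "
            "positive rising cycles in any window (flat/failed reaction)"
        )
    best_i = int(np.argmax(scores))
    best_b, best_s = float(grid[best_i]), float(scores[best_i])
    step = grid[1] - grid[0] if len(grid) > 1 else b_hi
    # staged zoom: shrink the bracket around the incumbent until ~1e-13 wide
    while step > 1e-13:
        lo = max(best_b - step, 0.0)
        hi = min(best_b + step, b_hi)
        grid = np.linspace(lo, hi, 17)
        scores = np.array([objective(b) for b in grid])
        i = int(np.argmax(scores))
        if scores[i] > best_s:
            best_b, best_s = float(grid[i]), float(scores[i])
        step = (hi - lo) / 8.0
    corrected = curve.signal - best_b
    return replace(curve, baseline=float(best_b), corrected=corrected)


def fit_efficiency(curve: AmpCurve, window_len: int = 5) -> AmpCurve:
    """Estimate amplification efficiency from the window of linearity.

    Slides a ``window_len``-cycle window over the baseline-corrected
    signal, regresses log10 signal on cycle, keeps the window with maximal
    R^2 (ties -> earliest). Efficiency is ``10**slope``. An R^2 below 0.99
    flags the curve as low quality; it is retained but excluded from group
    efficiency averaging.

    Windows whose corrected signal falls below ~3x the estimated
    background are excluded when possible: any residual error in the
    baseline estimate dominates the log signal there and biases the slope
    low. If no window clears the floor, all windows are considered.
    """
    if not MIN_WINDOW <= window_len <= 7:
        raise ValueError("window_len must be between 4 and 7")
    if curve.corrected is None:
        raise ValueError("run correct_baseline first")
    q = None
    if curve.baseline is not None and curve.baseline > 0:
        wmin = sliding_window_view(curve.corrected, window_len).min(axis=1)
        floor = wmin >= 3.0 * curve.baseline
        if floor.any():
            q = _window_fits(curve.corrected, curve.cycles, window_len, floor)
            if q is not None and q[0] < R2_QUALITY_GATE:
                q = None  # floor leaves no clean window (e.g. abuts the plateau)
    if q is None:
        q = _window_fits(curve.corrected, curve.cycles, window_len)
    if q is None:
        raise FlatReactionError(
            f"well {curve.well_id!r}: no rising log-linear window of length {window_len}"
        )
    r2, slope, window = q
    eff = float(10.0**slope)
    return replace(
        curve,
        window=window,
        efficiency=eff,
        r_squared=float(r2),
        low_quality=bool(r2 < R2_QUALITY_GATE),
    )


def _signal_at(curve: AmpCurve, cycle: float) -> float:
    idx = int(np.argmin(np.abs(curve.cycles - cycle)))
    return float(curve.corrected[idx])


def _interpolate_ct(curve: AmpCurve, threshold: float) -> float | None:
    """Fractional cycle where the corrected signal first crosses threshold.

    Log-linear interpolation between the bracketing cycles; None when the
    curve never reaches the threshold.
    """
    s = curve.corrected
    c = curve.cycles
    above = s >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(c[0])
    s0, s1 = s[i - 1], s[i]
    if s0 <= 0:
        return float(c[i])
    return float(
        c[i - 1]
        + (c[i] - c[i - 1])
        * (np.log10(threshold) - np.log10(s0))
        / (np.log10(s1) - np.log10(s0))
    )


def amplicon_group(curves: list[AmpCurve]) -> tuple[float, float, list[AmpCurve]]:
    """Amplicon-level efficiency, threshold and per-well CTs.

    All curves must share one amplicon_id and be fitted. Group efficiency
    is the arithmetic mean over non-flagged curves; the shared threshold is
    the geometric mean of each curve's corrected signal at its window
    midpoint; each curve's CT is interpolated at that threshold (missing
    when never crossed).

    Returns ``(efficiency, threshold, curves_with_ct)``.
    """
    if not curves:
        raise ValueError("no curves supplied")
    amplicons = {c.amplicon_id for c in curves}
    if len(amplicons) != 1:
        raise ValueError(f"curves span multiple amplicons: {sorted(amplicons)}")
    if any(c.efficiency is None or c.window is None for c in curves):
        raise ValueError("all curves must be fitted (correct_baseline + fit_efficiency)")
    good = [c for c in curves if not c.low_quality]
    if not good:
        raise ValueError(
            f"amplicon {curves[0].amplicon_id!r}: every curve is flagged low-quality"
        )
    efficiency = float(np.mean([c.efficiency for c in good]))
    midpoints = [_signal_at(c, 0.5 * (c.window[0] + c.window[1])) for c in curves]
    threshold = float(np.exp(np.mean(np.log(midpoints))))
    out = [replace(c, ct=_interpolate_ct(c, threshold)) for c in curves]
    return efficiency, threshold, out


def read_curves(path: str | os.PathLike) -> list[AmpCurve]:
    """Read raw curves from long delimited text (well_id, amplicon_id, cycle, fluorescence)."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep)
    need = {"well_id", "amplicon_id", "cycle", "fluorescence"}
    if not need <= set(df.columns):
        raise ValueError(f"curve file needs columns {sorted(need)}")
    out = []
    for (well, amp), grp in df.groupby(["well_id", "amplicon_id"], sort=False):
        grp = grp.sort_values("cycle")
        out.append(
            AmpCurve(
                well_id=str(well),
                amplicon_id=str(amp),
                cycles=grp["cycle"].to_numpy(dtype=float),
                signal=grp["fluorescence"].to_numpy(dtype=float),
            )
        )
    return out


def write_fits(curves: list[AmpCurve], path: str | os.PathLike) -> None:
    """Write fitted per-well results as delimited text."""
    rows = []
    for c in curves:
        rows.append(
            {
                "well_id": c.well_id,
                "amplicon_id": c.amplicon_id,
                "baseline": c.baseline,
                "window_start": c.window[0] if c.window else None,
                "window_end": c.window[1] if c.window else None,
                "efficiency": c.efficiency,
                "r_squared": c.r_squared,
                "low_quality": c.low_quality,
                "ct": c.ct,
            }
        )
    sep = "\t" if str(path).endswith(".tsv") else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
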