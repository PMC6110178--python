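"""TOF mass-spectral preprocessing: from a timed run of scans to one binned
feature vector per sampled cell.

The acquisition window is m/z 700–1000. Cell-capture events appear as
transient bursts in the total-ion chronogram; each event's scans are summed,
baseline-subtracted, optionally mass-recalibrated against lock masses, then
total-ion normalized and binned onto the fixed 0.1 m/z grid (3,000 bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.stats import median_abs_deviation

MZ_MIN = 700.0
MZ_MAX = 1000.0
BIN_WIDTH = 0.1
N_BINS = 3000  # (MZ_MAX - MZ_MIN) / BIN_WIDTH
DEFAULT_ACCUMULATION = 0.05  # s per scan


@dataclass
class SpectrumRecord:
    """One TOF scan: m/z axis, intensities, and the scan's start time in seconds."""

    mz: np.ndarray
    intensity: np.ndarray
    timestamp: float = 0.0
    accumulation: float = DEFAULT_ACCUMULATION

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def tic(self) -> float:
        """Total ion current of this scan."""
        return float(self.intensity.sum())


@dataclass
class CellEvent:
    """A detected cell-capture transient in the chronogram."""

    cell_id: int
    t_start: float
    t_end: float
    apex_time: float
    apex_tic: float

    def __post_init__(self) -> None:
        if not (self.t_start < self.apex_time < self.t_end):
            raise ValueError("event apex must lie strictly inside its window")

    @property
    def window(self) -> tuple[float, float]:
        return (self.t_start, self.t_end)


@dataclass
class BinnedSpectrum:
    """A spectrum resampled onto the fixed 3,000-bin grid [700, 1000) at 0.1 m/z.

    Bin i covers the half-open interval [700 + 0.1*i, 700 + 0.1*(i+1)).
    """

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_BINS,):
            raise ValueError(f"binned spectrum must have exactly {N_BINS} values")
        if np.any(self.values < 0):
            raise ValueError("binned values must be non-negative")
        if self.normalized and self.values.sum() > 0:
            if abs(self.values.sum() - 1.0) > 1e-9:
                raise ValueError("normalized spectrum must sum to 1 within 1e-9")

    @staticmethod
    def bin_edges() -> np.ndarray:
        return MZ_MIN + BIN_WIDTH * np.arange(N_BINS + 1)

    @staticmethod
    def bin_centers() -> np.ndarray:
        return MZ_MIN + BIN_WIDTH * (np.arange(N_BINS) + 0.5)


@dataclass
class RecalibrationReport:
    """Bookkeeping from a lock-mass recalibration."""

    matches: list[tuple[float, float]] = field(default_factory=list)  # (observed, reference)
    slope: float = 1.0
    offset: float = 0.0
    warning: bool = False  # True when no lock mass matched and the spectrum is unchanged


def total_ion_chronogram(run: Sequence[SpectrumRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Per-scan TIC time series (timestamps, TIC), order preserved.

    Raises ``ValueError`` on an empty run or decreasing timestamps.
    """
    if len(run) == 0:
        raise ValueError("cannot compute a chronogram of an empty run")
    times = np.array([s.timestamp for s in run], dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("run timestamps must be non-decreasing")
    tic = np.array([s.intensity.sum() for s in run], dtype=float)
    return times, tic


def detect_cell_events(
    chronogram: tuple[np.ndarray, np.ndarray],
    k_mad: float = 5.0,
    min_gap: float = 1.0,
) -> list[CellEvent]:
    """Find cell-capture transients as contiguous regions where the TIC exceeds
    median + k_mad * MAD of the whole chronogram.

    Regions whose edges are closer than ``min_gap`` seconds are merged; the apex
    is the maximum-TIC scan of each region. Event windows are padded by half a
    scan interval on each side so that single-scan events have nonzero width.
    """
    if k_mad <= 0:
        raise ValueError("k_mad must be positive")
    times, tic = chronogram
    thr = np.median(tic) + k_mad * median_abs_deviation(tic)
    above = tic > thr
    if not above.any():
        return []
    # contiguous True regions
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    # merge regions separated by less than min_gap
    merged: list[list[int]] = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if times[s] - times[merged[-1][1]] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    dt = float(np.median(np.diff(times))) if len(times) > 1 else DEFAULT_ACCUMULATION
    events = []
    for cell_id, (s, e) in enumerate(merged):
        apex = s + int(np.argmax(tic[s : e + 1]))
        events.append(
            CellEvent(
                cell_id=cell_id,
                t_start=times[s] - 0.5 * dt,
                t_end=times[e] + 0.5 * dt,
                apex_time=float(times[apex]),
                apex_tic=float(tic[apex]),
            )
        )
    return events


def baseline_spectrum(
    run: Sequence[SpectrumRecord], events: Sequence[CellEvent] = ()
) -> np.ndarray | None:
    """Per-channel median over scans outside every given event window."""
    out = [
        s
        for s in run
        if not any(ev.t_start <= s.timestamp <= ev.t_end for ev in events)
    ]
    if not out:
        return None
    stacked = np.stack([s.intensity for s in out])
    return np.median(stacked, axis=0, overwrite_input=True)


def extract_cell_spectrum(
    run: Sequence[SpectrumRecord],
    event: CellEvent,
    baseline: np.ndarray | None = None,
) -> SpectrumRecord:
    """Sum all scans inside the event window and subtract the per-channel
    baseline estimated from out-of-event scans.

    The baseline defaults to the per-channel median over scans outside this
    event's window (pass a precomputed :func:`baseline_spectrum` when
    extracting many events from one run); it is subtracted once per summed
    scan and the result floored at zero. The output timestamp is the event
    apex time.
    """
    in_win = [s for s in run if event.t_start <= s.timestamp <= event.t_end]
    if not in_win:
        raise ValueError(
            f"event window ({event.t_start:.3f}, {event.t_end:.3f}) s contains no scans"
        )
    mz = in_win[0].mz
    summed = np.zeros(mz.size, dtype=float)
    for s in in_win:
        summed += s.intensity
    if baseline is None:
        baseline = baseline_spectrum(run, [event])
    if baseline is not None:
        summed -= len(in_win) * baseline
    np.maximum(summed, 0.0, out=summed)
    return SpectrumRecord(
        mz=mz.copy(),
        intensity=summed,
        timestamp=event.apex_time,
        accumulation=in_win[0].accumulation,
    )


def _peak_centroids(spectrum: SpectrumRecord, prominence_frac: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Intensity-weighted centroids of local maxima, for lock-mass matching."""
    y = np.asarray(spectrum.intensity, dtype=float)
    if y.max() <= 0:
        return np.empty(0), np.empty(0)
    peaks, _ = signal.find_peaks(y, prominence=prominence_frac * y.max())
    centroids = np.empty(peaks.size)
    heights = np.empty(peaks.size)
    half = 10  # +-10 samples ~ two FWHM at the default grid; keeps truncation bias small
    for j, p in enumerate(peaks):
        lo, hi = max(0, p - half), min(y.size, p + half + 1)
        w = y[lo:hi]
        centroids[j] = float(np.average(spectrum.mz[lo:hi], weights=w))
        heights[j] = y[p]
    return centroids, heights


def mass_recalibrate(
    spectrum: SpectrumRecord,
    lock_masses: Sequence[float],
    tolerance: float = 0.2,
) -> tuple[SpectrumRecord, RecalibrationReport]:
    """Correct the m/z axis against known reference ions (lock masses).

    Each lock mass is matched to the nearest observed peak centroid within
    ``tolerance``. With two or more matches a linear map observed -> reference
    is least-squares fitted; with exactly one, a constant offset; with none the
    spectrum is returned unchanged and the report's warning flag is set.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    centroids, _ = _peak_centroids(spectrum)
    matches: list[tuple[float, float]] = []
    for ref in lock_masses:
        if centroids.size == 0:
            continue
        j = int(np.argmin(np.abs(centroids - ref)))
        if abs(centroids[j] - ref) <= tolerance:
            matches.append((float(centroids[j]), float(ref)))
    if not matches:
        return replace(spectrum, mz=spectrum.mz.copy()), RecalibrationReport(warning=True)
    obs = np.array([m[0] for m in matches])
    ref = np.array([m[1] for m in matches])
    if len(matches) >= 2:
        slope, offset = np.polyfit(obs, ref, 1)
    else:
        slope, offset = 1.0, float(ref[0] - obs[0])
    corrected = replace(spectrum, mz=offset + slope * spectrum.mz)
    return corrected, RecalibrationReport(
        matches=matches, slope=float(slope), offset=float(offset)
    )


def normalize_and_bin(spectrum: SpectrumRecord, normalize: bool = True) -> BinnedSpectrum:
    """Sum intensities onto the fixed half-open 0.1 m/z grid over [700, 1000),
    then total-ion normalize (divide by the grand total).

    m/z values outside [700, 1000) are excluded by the half-open grid. An
    all-zero spectrum yields an all-zero vector with ``normalized=False``.
    """
    idx = np.floor((spectrum.mz - MZ_MIN) / BIN_WIDTH).astype(int)
    ok = (idx >= 0) & (idx < N_BINS)
    values = np.bincount(idx[ok], weights=np.asarray(spectrum.intensity, dtype=float)[ok], minlength=N_BINS)
    total = values.sum()
    if normalize and total > 0:
        values = values / total
        return BinnedSpectrum(values=values, normalized=True)
    return BinnedSpectrum(values=values, normalized=False)
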