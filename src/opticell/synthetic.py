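"""Ground-truthed synthetic data: bright-field slide images, class-specific
single-cell TOF spectra, and timed acquisition runs.

The generators emulate the two study systems: small pigmented algae
(Euglena gracilis ~10 µm, Phacus ~10 µm) dispersed on a membrane slide, and
large elliptical onion (Allium cepa) epidermis cells (~100-150 µm) in
connected tissue. Cells are rendered dark-on-bright, as absorbing bodies
appear in bright-field microscopy. Spectra place Gaussian peaks at the
species' marker-lipid and pigment ion m/z values (computed from elemental
formulas in :mod:`opticell.masses`).

All randomness flows through one ``numpy.random.Generator`` seeded explicitly;
identical seeds and parameters give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely.affinity
from shapely.geometry import Point

from . import masses
from .msproc import MZ_MAX, MZ_MIN, SpectrumRecord, DEFAULT_ACCUMULATION

MZ_GRID_STEP = 0.01  # dense simulation grid, finer than the 0.1 analysis bins
DEFAULT_PEAK_FWHM = 0.05
_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class CellGroundTruth:
    """True position, shape and class of one simulated cell (stage frame, µm)."""

    cell_id: int
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float = 0.0  # radians, major axis vs. +x
    class_label: str = "euglena"

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")

    def polygon(self, n_vertices: int = 64):
        """Shapely polygon of the ellipse outline."""
        circle = Point(0.0, 0.0).buffer(1.0, quad_segs=max(4, n_vertices // 4))
        ell = shapely.affinity.scale(circle, self.semi_axes[0], self.semi_axes[1])
        ell = shapely.affinity.rotate(ell, self.orientation, use_radians=True)
        return shapely.affinity.translate(ell, self.center[0], self.center[1])


@dataclass
class SpeciesProfile:
    """Ion peak list of one cell type: (m/z centroid, relative abundance) pairs.

    Abundances are fractions of total signal and must sum to 1; all centroids
    must sit inside the m/z 700-1000 acquisition window.
    """

    name: str
    peaks: list[tuple[float, float]]
    peak_fwhm: float = DEFAULT_PEAK_FWHM

    def __post_init__(self) -> None:
        for mz, _ in self.peaks:
            if not (MZ_MIN <= mz < MZ_MAX):
                raise ValueError(
                    f"peak m/z {mz:.4f} outside acquisition range [{MZ_MIN}, {MZ_MAX})"
                )
        total = sum(a for _, a in self.peaks)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"abundances must sum to 1 (got {total:.6f})")
        if self.peak_fwhm <= 0:
            raise ValueError("peak FWHM must be positive")


def default_profiles() -> dict[str, SpeciesProfile]:
    """Default Euglena gracilis and Phacus marker-ion profiles.

    Euglena: 34:7 and 36:7 MGDG, 34:4 DGDG and 30:8 PC; Phacus: 34:6 and
    36:8 MGDG and 30:9 PC. Both carry protonated chlorophyll a, chlorophyll b
    and pyropheophytin a, with chlorophyll b markedly stronger in Phacus.
    Relative abundances are free simulation parameters.
    """
    euglena = SpeciesProfile(
        name="euglena",
        peaks=[
            (masses.lipid_mz("MGDG", 34, 7), 0.20),
            (masses.lipid_mz("MGDG", 36, 7), 0.15),
            (masses.lipid_mz("DGDG", 34, 4), 0.12),
            (masses.lipid_mz("PC", 30, 8), 0.10),
            (masses.pigment_mz("chlorophyll a"), 0.22),
            (masses.pigment_mz("chlorophyll b"), 0.06),
            (masses.pigment_mz("pyropheophytin a"), 0.15),
        ],
    )
    phacus = SpeciesProfile(
        name="phacus",
        peaks=[
            (masses.lipid_mz("MGDG", 34, 6), 0.20),
            (masses.lipid_mz("MGDG", 36, 8), 0.15),
            (masses.lipid_mz("PC", 30, 9), 0.12),
            (masses.pigment_mz("chlorophyll a"), 0.20),
            (masses.pigment_mz("chlorophyll b"), 0.18),
            (masses.pigment_mz("pyropheophytin a"), 0.15),
        ],
    )
    return {"euglena": euglena, "phacus": phacus}


def pigment_lock_masses() -> list[float]:
    """m/z of the three pigment ions shared by both classes (recalibration refs)."""
    return [
        masses.pigment_mz("chlorophyll a"),
        masses.pigment_mz("chlorophyll b"),
        masses.pigment_mz("pyropheophytin a"),
    ]


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def generate_image(
    scene: list[CellGroundTruth],
    pixel_size: float,
    image_shape: tuple[int, int],
    noise_sd: float = 0.0,
    seed: int = 0,
    background: float = 3000.0,
    contrast: float = 1800.0,
    allow_overlap: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a bright-field slide image of elliptical cells.

    Cells appear as regions darker than the background by ``contrast`` counts;
    Gaussian pixel noise of ``noise_sd`` counts is added and the image clipped
    into the 16-bit range. Returns the uint16 image and the ground-truth table
    (cell_id, x_um, y_um, a_um, b_um, theta_rad, label), echoed unchanged.

    Overlapping cells raise a placement error unless ``allow_overlap`` is set.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    ids = [c.cell_id for c in scene]
    if len(set(ids)) != len(ids):
        raise ValueError("cell_id values must be unique within a scene")
    if not allow_overlap and len(scene) > 1:
        polys = [c.polygon() for c in scene]
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                if polys[i].intersects(polys[j]):
                    raise ValueError(
                        f"cells {scene[i].cell_id} and {scene[j].cell_id} overlap; "
                        "set allow_overlap=True to permit"
                    )
    h, w = image_shape
    img = np.full((h, w), background, dtype=float)
    for cell in scene:
        cx, cy = cell.center[0] / pixel_size, cell.center[1] / pixel_size
        a, b = cell.semi_axes[0] / pixel_size, cell.semi_axes[1] / pixel_size
        r_max = max(a, b)
        r0 = max(0, int(np.floor(cy - r_max)) - 1)
        r1 = min(h, int(np.ceil(cy + r_max)) + 2)
        c0 = max(0, int(np.floor(cx - r_max)) - 1)
        c1 = min(w, int(np.ceil(cx + r_max)) + 2)
        if r0 >= r1 or c0 >= c1:
            continue
        rows, cols = np.mgrid[r0:r1, c0:c1]
        # pixel centers at integer indices; rotate into the ellipse frame
        dx = cols - cx
        dy = rows - cy
        ct, st = np.cos(cell.orientation), np.sin(cell.orientation)
        u = (dx * ct + dy * st) / a
        v = (-dx * st + dy * ct) / b
        inside = u * u + v * v <= 1.0
        patch = img[r0:r1, c0:c1]
        patch[inside] = background - contrast
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0, 65535)
    truth = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in scene],
            "x_um": [c.center[0] for c in scene],
            "y_um": [c.center[1] for c in scene],
            "a_um": [c.semi_axes[0] for c in scene],
            "b_um": [c.semi_axes[1] for c in scene],
            "theta_rad": [c.orientation for c in scene],
            "label": [c.class_label for c in scene],
        }
    )
    return img.astype(np.uint16), truth


def random_scene(
    n_cells: int,
    region: tuple[float, float],
    radius_range: tuple[float, float] = (4.0, 6.0),
    aspect_range: tuple[float, float] = (1.0, 1.8),
    margin: float = 12.0,
    min_separation: float = 6.0,
    labels: list[str] | None = None,
    seed: int = 0,
) -> list[CellGroundTruth]:
    """Place non-overlapping elliptical cells uniformly inside a region (µm),
    keeping ``margin`` off the borders and ``min_separation`` between outlines.
    """
    rng = np.random.default_rng(seed)
    w, h = region
    cells: list[CellGroundTruth] = []
    attempts = 0
    while len(cells) < n_cells:
        attempts += 1
        if attempts > 200 * max(n_cells, 1):
            raise RuntimeError("could not place all cells; region too crowded")
        b = rng.uniform(*radius_range)
        a = b * rng.uniform(*aspect_range)
        cx = rng.uniform(margin + a, w - margin - a)
        cy = rng.uniform(margin + a, h - margin - a)
        theta = rng.uniform(0, np.pi)
        label = labels[len(cells)] if labels else "euglena"
        cand = CellGroundTruth(len(cells), (cx, cy), (a, b), theta, label)
        poly = cand.polygon().buffer(min_separation / 2.0)
        if any(poly.intersects(c.polygon().buffer(min_separation / 2.0)) for c in cells):
            continue
        cells.append(cand)
    return cells


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def mz_grid(step: float = MZ_GRID_STEP) -> np.ndarray:
    """The dense simulation m/z axis covering [700, 1000)."""
    n = int(round((MZ_MAX - MZ_MIN) / step))
    return MZ_MIN + step * np.arange(n)


def generate_spectrum(
    profile: SpeciesProfile,
    total_intensity: float = 5e4,
    noise_sd: float = 0.0,
    seed: int = 0,
    timestamp: float = 0.0,
    grid_step: float = MZ_GRID_STEP,
    abundance_jitter: float = 0.0,
) -> SpectrumRecord:
    """Simulate one single-cell TOF spectrum from a species profile.

    Each profile peak becomes a Gaussian of FWHM ``profile.peak_fwhm`` centred
    at its m/z, carrying ``abundance * total_intensity`` counts. Optional
    log-normal ``abundance_jitter`` (sigma of log-abundance) models cell-to-cell
    compositional variation; Gaussian detector noise of ``noise_sd`` counts is
    added per channel and the result floored at zero.
    """
    if total_intensity <= 0:
        raise ValueError("total_intensity must be positive")
    rng = np.random.default_rng(seed)
    mz = mz_grid(grid_step)
    intensity = np.zeros(mz.size)
    abundances = np.array([a for _, a in profile.peaks], dtype=float)
    if abundance_jitter > 0:
        abundances = abundances * rng.lognormal(0.0, abundance_jitter, abundances.size)
        abundances /= abundances.sum()
    sigma = profile.peak_fwhm * _SIGMA_PER_FWHM
    for (center, _), ab in zip(profile.peaks, abundances):
        g = np.exp(-0.5 * ((mz - center) / sigma) ** 2)
        intensity += ab * total_intensity * g / g.sum()
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, mz.size)
        np.maximum(intensity, 0.0, out=intensity)
    return SpectrumRecord(mz=mz, intensity=intensity, timestamp=timestamp)


def noise_sd_for_snr(
    profile: SpeciesProfile,
    total_intensity: float = 5e4,
    snr: float = 10.0,
    grid_step: float = MZ_GRID_STEP,
) -> float:
    """Channel noise SD giving the requested apex signal-to-noise ratio."""
    noiseless = generate_spectrum(profile, total_intensity, 0.0, grid_step=grid_step)
    return float(noiseless.intensity.max() / snr)


def contaminate(
    primary: SpectrumRecord, contaminant: SpectrumRecord, fraction: float
) -> SpectrumRecord:
    """Convex combination (1 - fraction)*primary + fraction*contaminant,
    emulating co-capture of a previously microdissected cell of the other type.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if primary.mz.shape != contaminant.mz.shape or not np.array_equal(
        primary.mz, contaminant.mz
    ):
        raise ValueError("spectra must share the same m/z grid")
    mixed = (1.0 - fraction) * np.asarray(primary.intensity, dtype=float) + (
        fraction
    ) * np.asarray(contaminant.intensity, dtype=float)
    return SpectrumRecord(
        mz=primary.mz.copy(),
        intensity=mixed,
        timestamp=primary.timestamp,
        accumulation=primary.accumulation,
    )


# ---------------------------------------------------------------------------
# Timed runs
# ---------------------------------------------------------------------------

def generate_run(
    cell_events: list[tuple[float, SpectrumRecord]],
    baseline: float = 50.0,
    scan_period: float = DEFAULT_ACCUMULATION,
    seed: int = 0,
    noise_sd: float = 0.0,
    envelope_sigma: float | None = None,
    pad: float = 1.0,
) -> list[SpectrumRecord]:
    """Simulate a timed acquisition: baseline scans plus one transient burst
    per cell event.

    Each event's spectrum is spread over scans with a Gaussian time envelope of
    sigma ``envelope_sigma`` (default 2 scan periods), truncated at +-6 sigma,
    scaled so the apex scan carries the full event spectrum. ``baseline`` is
    the per-scan baseline TIC, spread uniformly over channels.
    """
    if envelope_sigma is None:
        envelope_sigma = 2.0 * scan_period
    times = [t for t, _ in cell_events]
    if any(t < 0 for t in times):
        raise ValueError("event times must be non-negative")
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("event times must be strictly increasing")
    width = 12.0 * envelope_sigma  # full truncated envelope width
    if any(t2 - t1 <= width for t1, t2 in zip(times, times[1:])):
        raise ValueError("events must be separated by more than one event width")
    rng = np.random.default_rng(seed)
    mz = cell_events[0][1].mz if cell_events else mz_grid()
    for _, spec in cell_events:
        if not np.array_equal(spec.mz, mz):
            raise ValueError("all event spectra must share one m/z grid")
    t_total = (times[-1] if times else 0.0) + pad
    n_scans = int(np.ceil(t_total / scan_period)) + 1
    base_level = baseline / mz.size
    run: list[SpectrumRecord] = []
    for i in range(n_scans):
        t = i * scan_period
        intensity = np.full(mz.size, base_level, dtype=np.float32)
        for t0, spec in cell_events:
            if abs(t - t0) <= 6.0 * envelope_sigma:
                w = np.exp(-0.5 * ((t - t0) / envelope_sigma) ** 2)
                intensity += (w * np.asarray(spec.intensity)).astype(np.float32)
        if noise_sd > 0:
            intensity += rng.normal(0.0, noise_sd, mz.size).astype(np.float32)
            np.maximum(intensity, 0.0, out=intensity)
        run.append(SpectrumRecord(mz=mz, intensity=intensity, timestamp=t))
    return run
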