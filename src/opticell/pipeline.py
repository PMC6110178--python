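"""End-to-end orchestration: image -> recognized cells -> laser paths ->
(simulated or parsed) MS run -> per-cell binned features -> classification.

`simulate_experiment` builds a fully ground-truthed virtual experiment (slide
image + timed run whose capture events follow the planned sampling order);
`run_pipeline` executes the analysis chain on it (or on externally supplied
image + run files) and returns a `RunManifest` joining every stage's output
per cell. Identical config + seed give an identical manifest hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import FeatureMatrix, PcaLda, PcaLdaResults
from .msproc import (
    SpectrumRecord,
    detect_cell_events,
    extract_cell_spectrum,
    mass_recalibrate,
    normalize_and_bin,
    total_ion_chronogram,
)
from .pathplan import cut_contour, order_cells, raster_path
from .recognition import PRESETS, CellBoundary, OpticalImage, filter_isolated, segment_cells
from .synthetic import (
    CellGroundTruth,
    contaminate,
    default_profiles,
    generate_image,
    generate_run,
    generate_spectrum,
    noise_sd_for_snr,
    pigment_lock_masses,
    random_scene,
)


@dataclass
class PipelineConfig:
    """One document holding every tunable of the pipeline, with defaults."""

    mode: str = "cnd"  # "raster" | "cnd"
    preset: str = "algae"
    min_area: float | None = None  # override preset when set
    max_area: float | None = None
    min_circularity: float | None = None
    isolation_margin: float = 3.0  # µm, CnD single-cell guarantee
    spacing: float = 5.0  # raster line spacing, µm
    inset: float = 2.0  # raster stand-off, µm
    cut_margin: float = 3.0  # CnD contour clearance, µm
    n_passes: int = 2
    pixel_size: float = 0.5  # µm/px
    lock_masses: list[float] = field(default_factory=pigment_lock_masses)
    lock_tolerance: float = 0.2
    k_mad: float = 5.0
    min_gap: float = 1.0
    k_components: int = 2
    class_names: list[str] = field(default_factory=lambda: ["euglena", "phacus"])
    seed: int = 0
    output_dir: str | None = None

    def filters(self) -> tuple[float, float, float]:
        p = PRESETS[self.preset]
        return (
            self.min_area if self.min_area is not None else p["min_area"],
            self.max_area if self.max_area is not None else p["max_area"],
            self.min_circularity if self.min_circularity is not None else p["min_circularity"],
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SimulatedExperiment:
    """A ground-truthed virtual slide + acquisition run."""

    image: np.ndarray
    pixel_size: float
    truth: pd.DataFrame  # cell geometry, label, contamination fraction
    run: list[SpectrumRecord]
    sampling_order: list[int]  # ground-truth cell_ids in capture order
    dwell: float


@dataclass
class RunManifest:
    """Per-cell join of every pipeline stage, plus provenance."""

    records: list[dict]
    config: dict
    config_hash: str
    software_version: str
    loocv_accuracy: float | None = None
    n_cells: int = 0

    def __post_init__(self) -> None:
        self.n_cells = len(self.records)

    def hash(self) -> str:
        """Deterministic digest of the manifest content (provenance included)."""
        doc = json.dumps(
            {
                "records": self.records,
                "config_hash": self.config_hash,
                "version": self.software_version,
            },
            sort_keys=True,
        )
        return hashlib.sha256(doc.encode()).hexdigest()

    def to_json(self, path=None) -> str:
        doc = json.dumps(
            {
                "records": self.records,
                "config": self.config,
                "config_hash": self.config_hash,
                "software_version": self.software_version,
                "loocv_accuracy": self.loocv_accuracy,
                "n_cells": self.n_cells,
                "manifest_hash": self.hash(),
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc


def simulate_experiment(
    n_class_a: int,
    n_class_b: int,
    contamination: list[tuple[int, float]] | None = None,
    seed: int = 0,
    profiles: dict | None = None,
    snr: float = 10.0,
    total_intensity: float = 5e4,
    dwell: float = 2.0,
    image_noise_sd: float = 120.0,
    pixel_size: float = 0.5,
    abundance_jitter: float = 0.15,
) -> SimulatedExperiment:
    """Simulate a two-class single-cell experiment end to end.

    ``n_class_a`` cells of the first default profile (Euglena) and
    ``n_class_b`` of the second (Phacus) are scattered on a virtual slide;
    the MS run contains one capture burst per cell, in planned sampling order
    (greedy nearest-neighbour from the slide origin) at a fixed inter-cell
    ``dwell``. ``contamination`` lists (truth-table index, fraction) pairs:
    those cells' spectra become convex mixtures with the *other* class,
    emulating co-capture of a previously cut cell.

    The truth table records intended class and contamination per cell.
    """
    if n_class_a < 0 or n_class_b < 0:
        raise ValueError("cell counts must be non-negative")
    contamination = list(contamination or [])
    n = n_class_a + n_class_b
    for idx, frac in contamination:
        if not 0 <= idx < n:
            raise ValueError(f"contamination index {idx} out of range [0, {n})")
        if not 0.0 <= frac <= 1.0:
            raise ValueError("contamination fraction must lie in [0, 1]")
    profiles = profiles or default_profiles()
    names = list(profiles)
    rng = np.random.default_rng(seed)
    labels = [names[0]] * n_class_a + [names[1]] * n_class_b
    rng.shuffle(labels)
    # slide sized for ~1 cell / (30 µm)^2
    side = max(100.0, 30.0 * float(np.ceil(np.sqrt(max(n, 1)))) + 40.0)
    scene = random_scene(n, (side, side), labels=labels, seed=int(rng.integers(2**31)))
    shape = (int(np.ceil(side / pixel_size)), int(np.ceil(side / pixel_size)))
    image, truth = generate_image(
        scene, pixel_size, shape, noise_sd=image_noise_sd, seed=int(rng.integers(2**31))
    )
    contam_by_id = {idx: frac for idx, frac in contamination}
    truth["contaminated_fraction"] = [contam_by_id.get(c.cell_id, 0.0) for c in scene]
    # planned sampling order over ground-truth outlines (greedy tour)
    paths = [
        cut_contour(CellBoundary(cell_id=c.cell_id, polygon=c.polygon()))
        for c in scene
    ]
    order = [p.cell_id for p in order_cells(paths, start=(0.0, 0.0))]
    by_id = {c.cell_id: c for c in scene}
    noise = {
        name: noise_sd_for_snr(profiles[name], total_intensity, snr) for name in names
    }
    events = []
    for i, cell_id in enumerate(order):
        cell = by_id[cell_id]
        other = names[1] if cell.class_label == names[0] else names[0]
        spec = generate_spectrum(
            profiles[cell.class_label],
            total_intensity,
            noise_sd=noise[cell.class_label],
            seed=int(rng.integers(2**31)),
            abundance_jitter=abundance_jitter,
        )
        frac = contam_by_id.get(cell_id, 0.0)
        if frac > 0:
            contaminant = generate_spectrum(
                profiles[other],
                total_intensity,
                noise_sd=noise[other],
                seed=int(rng.integers(2**31)),
                abundance_jitter=abundance_jitter,
            )
            # fraction = share of the *other* class in the captured material
            spec = contaminate(spec, contaminant, frac)
        events.append((2.0 + i * dwell, spec))
    run = generate_run(
        events,
        baseline=total_intensity / 100.0,
        seed=int(rng.integers(2**31)),
        noise_sd=total_intensity / 3e6,
    ) if events else []
    return SimulatedExperiment(
        image=image,
        pixel_size=pixel_size,
        truth=truth,
        run=run,
        sampling_order=order,
        dwell=dwell,
    )


def extract_features(
    run: list[SpectrumRecord], config: PipelineConfig
) -> tuple[np.ndarray, list[dict]]:
    """Detect events, extract + recalibrate per-cell spectra, bin to 3,000 features."""
    from .msproc import baseline_spectrum

    chrono = total_ion_chronogram(run)
    events = detect_cell_events(chrono, k_mad=config.k_mad, min_gap=config.min_gap)
    baseline = baseline_spectrum(run, events)
    rows, meta = [], []
    for ev in events:
        spec = extract_cell_spectrum(run, ev, baseline=baseline)
        spec, report = mass_recalibrate(spec, config.lock_masses, config.lock_tolerance)
        binned = normalize_and_bin(spec)
        rows.append(binned.values)
        meta.append(
            {
                "event_id": ev.cell_id,
                "window_s": [ev.t_start, ev.t_end],
                "apex_time_s": ev.apex_time,
                "apex_tic": ev.apex_tic,
                "recalibration_matches": len(report.matches),
                "recalibration_warning": report.warning,
            }
        )
    matrix = np.vstack(rows) if rows else np.empty((0, 3000))
    return matrix, meta


def run_pipeline(
    config: PipelineConfig,
    image: np.ndarray | None = None,
    run: list[SpectrumRecord] | None = None,
    experiment: SimulatedExperiment | None = None,
    model: PcaLdaResults | None = None,
    output_dir: str | None = None,
) -> RunManifest:
    """Execute the full chain: detect -> isolate -> plan -> extract -> bin ->
    classify, and join everything per sampled cell into a manifest.

    Inputs are either a ``SimulatedExperiment`` (image + run + ground truth;
    enables training and truth columns in the manifest) or an ``image`` array
    plus an optional parsed ``run``. With ground-truth labels a PCA-LDA model
    is fitted on the extracted features and its LOOCV accuracy recorded; with
    a pre-fitted ``model`` the features are apportioned instead.
    """
    if experiment is not None:
        image = experiment.image
        run = experiment.run
        pixel_size = experiment.pixel_size
    else:
        pixel_size = config.pixel_size
    if image is None:
        raise ValueError("run_pipeline needs an image (directly or via experiment)")
    optical = OpticalImage(data=image, pixel_size=pixel_size)
    min_area, max_area, min_circ = config.filters()
    cells = segment_cells(optical, min_area, max_area, min_circ)
    if config.mode == "cnd":
        cells = filter_isolated(cells, config.isolation_margin)
        paths = [cut_contour(c, config.cut_margin, config.n_passes) for c in cells]
    elif config.mode == "raster":
        paths = [raster_path(c, config.spacing, config.inset) for c in cells]
    else:
        raise ValueError(f"unknown sampling mode {config.mode!r}")
    paths = order_cells(paths, start=(0.0, 0.0))
    by_id = {c.cell_id: c for c in cells}

    matrix, event_meta = (
        extract_features(run, config) if run else (np.empty((0, 3000)), [])
    )

    # join: i-th capture event <-> i-th planned cell
    records = []
    n_join = min(len(paths), matrix.shape[0]) if matrix.shape[0] else 0
    truth_lookup = {}
    if experiment is not None:
        for _, row in experiment.truth.iterrows():
            truth_lookup[int(row["cell_id"])] = row
    for i in range(len(paths)):
        cell = by_id[paths[i].cell_id]
        rec = {
            "cell_id": int(cell.cell_id),
            "centroid_um": [round(v, 6) for v in cell.centroid],
            "area_um2": round(cell.area, 6),
            "circularity": round(cell.circularity, 6),
            "mode": paths[i].mode,
            "n_waypoints": len(paths[i].waypoints),
            "sampling_index": i,
            "feature_row": i if i < n_join else None,
        }
        if i < n_join:
            rec.update(event_meta[i])
        if experiment is not None and i < len(experiment.sampling_order):
            true_id = experiment.sampling_order[i]
            t = truth_lookup.get(true_id)
            if t is not None:
                rec["true_label"] = str(t["label"])
                rec["contaminated_fraction"] = float(t["contaminated_fraction"])
        records.append(rec)

    loocv_acc = None
    if n_join:
        labels = [r.get("true_label") for r in records[:n_join]]
        have_truth = all(l is not None for l in labels) and len(set(labels)) == 2
        if model is not None:
            fm = FeatureMatrix(values=matrix[:n_join])
            predicted = model.predict(fm)
            for r, p in zip(records[:n_join], predicted):
                r["predicted_label"] = p
        elif have_truth and min(labels.count(c) for c in set(labels)) >= 2 and n_join >= 4:
            fitted = PcaLda(matrix[:n_join], labels=labels).fit(k=config.k_components)
            loocv = fitted.loocv()
            loocv_acc = loocv.accuracy
            for r, p in zip(records[:n_join], loocv.predicted):
                r["predicted_label"] = p

    manifest = RunManifest(
        records=records,
        config=config.to_dict(),
        config_hash=config.hash(),
        software_version=__version__,
        loocv_accuracy=loocv_acc,
    )
    if output_dir or config.output_dir:
        out = Path(output_dir or config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        from . import io as _io

        manifest.to_json(out / "manifest.json")
        if matrix.size:
            ids = [r["cell_id"] for r in records[:n_join]]
            labels = [r.get("true_label") for r in records[:n_join]]
            _io.write_matrix(
                out / "features.csv",
                matrix[:n_join],
                ids=ids,
                labels=labels if all(l is not None for l in labels) else None,
            )
    return manifest
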