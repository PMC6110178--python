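"""File formats: slide images (TIFF/PNG), ground truth and summaries (CSV),
species profiles (YAML), cell boundaries (GeoJSON), laser paths (JSON),
timed runs (mzML or CSV-per-scan + JSON manifest), and feature matrices (CSV).

All coordinates on disk are stage-frame µm, x right / y down; m/z axes cover
the 700-1000 acquisition window. The mzML writer emits a minimal mzML 1.1.0
document (64-bit little-endian floats, no compression); the reader is a
standard-library XML parse that also accepts zlib-compressed 32/64-bit float
arrays from other producers.
"""

from __future__ import annotations

import base64
import json
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
import yaml

from .msproc import SpectrumRecord
from .pathplan import LaserPath
from .recognition import CellBoundary
from .synthetic import SpeciesProfile

# ---------------------------------------------------------------------------
# Images & ground truth
# ---------------------------------------------------------------------------

def write_image(path, image: np.ndarray, pixel_size: float, png_preview: bool = True) -> None:
    """Write a 16-bit grayscale TIFF (resolution tags in µm) plus a PNG preview."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(
        path,
        np.asarray(image, dtype=np.uint16),
        resolution=(1.0 / pixel_size, 1.0 / pixel_size),
        metadata={"unit": "um", "pixel_size_um": pixel_size},
    )
    if png_preview:
        import imageio.v3 as iio

        img = np.asarray(image, dtype=float)
        lo, hi = img.min(), img.max()
        scaled = np.zeros_like(img) if hi <= lo else (img - lo) / (hi - lo)
        iio.imwrite(path.with_suffix(".png"), (255 * scaled).astype(np.uint8))


def read_image(path) -> np.ndarray:
    """Read an 8/16-bit grayscale TIFF or PNG as a 2-D array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim == 3:  # collapse an RGB(A) preview to grayscale
        data = data[..., :3].mean(axis=-1)
    return data


def write_ground_truth(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, index=False)


def read_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Species profiles (YAML)
# ---------------------------------------------------------------------------

def write_profiles(path, profiles: dict[str, SpeciesProfile]) -> None:
    doc = {
        name: {
            "peaks": [[float(mz), float(ab)] for mz, ab in p.peaks],
            "peak_fwhm": float(p.peak_fwhm),
        }
        for name, p in profiles.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_profiles(path) -> dict[str, SpeciesProfile]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {
        name: SpeciesProfile(
            name=name,
            peaks=[(float(mz), float(ab)) for mz, ab in spec["peaks"]],
            peak_fwhm=float(spec.get("peak_fwhm", 0.05)),
        )
        for name, spec in doc.items()
    }


# ---------------------------------------------------------------------------
# Cell boundaries (GeoJSON-style) and summaries (CSV)
# ---------------------------------------------------------------------------

def write_boundaries(path, cells: list[CellBoundary]) -> None:
    """GeoJSON FeatureCollection of cell outlines; coordinates in stage µm."""
    features = []
    for cell in cells:
        coords = [[float(x), float(y)] for x, y in cell.polygon.exterior.coords]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [coords]},
                "properties": {
                    "cell_id": cell.cell_id,
                    "centroid_um": list(cell.centroid),
                    "area_um2": cell.area,
                    "equivalent_diameter_um": cell.equivalent_diameter,
                    "circularity": cell.circularity,
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "crs_note": "stage frame, micrometres, x right / y down",
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_boundaries(path) -> list[CellBoundary]:
    from shapely.geometry import Polygon

    with open(path) as fh:
        doc = json.load(fh)
    cells = []
    for feat in doc["features"]:
        poly = Polygon(feat["geometry"]["coordinates"][0])
        cells.append(CellBoundary(cell_id=int(feat["properties"]["cell_id"]), polygon=poly))
    return cells


def write_cell_summary(path, cells: list[CellBoundary]) -> None:
    pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "centroid_x_um": [c.centroid[0] for c in cells],
            "centroid_y_um": [c.centroid[1] for c in cells],
            "area_um2": [c.area for c in cells],
            "equivalent_diameter_um": [c.equivalent_diameter for c in cells],
            "circularity": [c.circularity for c in cells],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Laser paths (JSON)
# ---------------------------------------------------------------------------

def write_paths(path, paths: list[LaserPath]) -> None:
    doc = {
        "frame": "stage micrometres, x right / y down",
        "paths": [
            {
                "cell_id": p.cell_id,
                "mode": p.mode,
                "spacing_um": p.line_spacing,
                "n_passes": p.n_passes,
                "puncture": list(p.puncture_point) if p.puncture_point else None,
                "eject": list(p.eject_point) if p.eject_point else None,
                "waypoints": [[float(x), float(y)] for x, y in p.waypoints],
            }
            for p in paths
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_paths(path) -> list[LaserPath]:
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for rec in doc["paths"]:
        out.append(
            LaserPath(
                cell_id=int(rec["cell_id"]),
                mode=rec["mode"],
                waypoints=[tuple(p) for p in rec["waypoints"]],
                puncture_point=tuple(rec["puncture"]) if rec["puncture"] else None,
                eject_point=tuple(rec["eject"]) if rec["eject"] else None,
                n_passes=int(rec["n_passes"]),
                line_spacing=rec["spacing_um"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Timed runs: mzML and CSV-per-scan
# ---------------------------------------------------------------------------

def _encode_array(values: np.ndarray) -> str:
    raw = np.asarray(values, dtype="<f8").tobytes()
    return base64.b64encode(raw).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000294" name="mass spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{npts}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000294" name="mass spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_run_mzml(path, run: list[SpectrumRecord], run_id: str = "synthetic_run") -> None:
    """Write a timed run as minimal mzML 1.1.0 (one spectrum per scan,
    scan start times in seconds, uncompressed 64-bit float arrays)."""
    with open(path, "w") as fh:
        fh.write(_MZML_HEADER.format(run_id=escape(run_id), count=len(run)))
        for i, scan in enumerate(run):
            mz_b64 = _encode_array(scan.mz)
            int_b64 = _encode_array(scan.intensity)
            fh.write(
                _MZML_SPECTRUM.format(
                    index=i,
                    scan=i + 1,
                    npts=scan.mz.size,
                    rt=repr(float(scan.timestamp)),
                    mz_len=len(mz_b64),
                    mz_b64=mz_b64,
                    int_len=len(int_b64),
                    int_b64=int_b64,
                )
            )
        fh.write(_MZML_FOOTER)


def _decode_binary(elem, ns: str) -> np.ndarray:
    """Decode one <binaryDataArray>: base64, optional zlib, 32/64-bit float."""
    import zlib

    accessions = {cv.get("accession") for cv in elem.findall(f"{ns}cvParam")}
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    raw = base64.b64decode((elem.findtext(f"{ns}binary") or "").strip())
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_run_mzml(path) -> list[SpectrumRecord]:
    """Read an MS1 mzML file (as written by :func:`write_run_mzml`, or any
    uncompressed/zlib float mzML) with a standard-library XML parse."""
    import xml.etree.ElementTree as ET

    root = ET.parse(str(path)).getroot()
    ns = root.tag[: root.tag.index("}") + 1] if root.tag.startswith("{") else ""
    run = []
    for spec in root.iter(f"{ns}spectrum"):
        t = 0.0
        for cv in spec.iter(f"{ns}cvParam"):
            if cv.get("accession") == "MS:1000016":  # scan start time
                t = float(cv.get("value"))
                if cv.get("unitName", "").startswith("minute"):
                    t *= 60.0
        arrays = {}
        for bda in spec.iter(f"{ns}binaryDataArray"):
            accessions = {cv.get("accession") for cv in bda.findall(f"{ns}cvParam")}
            if "MS:1000514" in accessions:
                arrays["mz"] = _decode_binary(bda, ns)
            elif "MS:1000515" in accessions:
                arrays["intensity"] = _decode_binary(bda, ns)
        if "mz" in arrays and "intensity" in arrays:
            run.append(
                SpectrumRecord(mz=arrays["mz"], intensity=arrays["intensity"], timestamp=t)
            )
    run.sort(key=lambda s: s.timestamp)
    return run


def write_run_csv(directory, run: list[SpectrumRecord]) -> None:
    """Write one CSV per scan plus a JSON run manifest into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"format": "csv-per-scan", "scans": []}
    for i, scan in enumerate(run):
        name = f"scan_{i:05d}.csv"
        pd.DataFrame({"mz": scan.mz, "intensity": scan.intensity}).to_csv(
            directory / name, index=False
        )
        manifest["scans"].append(
            {"file": name, "timestamp_s": float(scan.timestamp), "accumulation_s": scan.accumulation}
        )
    with open(directory / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_run_csv(directory) -> list[SpectrumRecord]:
    directory = Path(directory)
    with open(directory / "run_manifest.json") as fh:
        manifest = json.load(fh)
    run = []
    for rec in manifest["scans"]:
        df = pd.read_csv(directory / rec["file"])
        run.append(
            SpectrumRecord(
                mz=df["mz"].to_numpy(),
                intensity=df["intensity"].to_numpy(),
                timestamp=rec["timestamp_s"],
                accumulation=rec.get("accumulation_s", 0.05),
            )
        )
    run.sort(key=lambda s: s.timestamp)
    return run


def read_run(path) -> list[SpectrumRecord]:
    """Read a run from mzML (file) or CSV-per-scan (directory)."""
    path = Path(path)
    if path.is_dir():
        return read_run_csv(path)
    return read_run_mzml(path)


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------

def write_matrix(path, values: np.ndarray, ids=None, labels=None) -> None:
    """Per-cell binned feature matrix as CSV: rows = cells, 3,000 bin columns
    named by bin lower edge, with cell_id and optional label columns."""
    from .msproc import BIN_WIDTH, MZ_MIN, N_BINS

    values = np.atleast_2d(values)
    cols = [f"mz_{MZ_MIN + BIN_WIDTH * i:.1f}" for i in range(N_BINS)]
    df = pd.DataFrame(values, columns=cols)
    df.insert(0, "cell_id", ids if ids is not None else range(values.shape[0]))
    if labels is not None:
        df.insert(1, "label", list(labels))
    df.to_csv(path, index=False, float_format="%.10g")


def read_matrix(path):
    """Read a feature matrix CSV back as (values, ids, labels)."""
    df = pd.read_csv(path)
    ids = df.pop("cell_id").tolist()
    labels = df.pop("label").tolist() if "label" in df.columns else None
    return df.to_numpy(dtype=float), ids, labels
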