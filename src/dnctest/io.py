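"""Readers and writers for the on-disk exchange formats.

Plain-text formats throughout: TSV for emission-frame series (with a
JSON metadata sidecar), CSV for chromatograms, basis spectra, traces and
cohort tables; TIFF for section images; JSON for ROI polygons, standard
curves and diagnostic results.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import polygon as draw_polygon

from .dnc import COHORT_COLUMNS, DNCResult
from .hplc import Chromatogram, PeakWindow, StandardCurve
from .histology import HistologyImage
from .photometry import CoefficientTrace, DffTrace, EmissionFrameSeries, SpectralBasis

__all__ = [
    "write_frame_series",
    "read_frame_series",
    "read_basis_csv",
    "write_basis_csv",
    "write_chromatogram",
    "read_chromatogram",
    "read_windows",
    "write_curve",
    "read_curve",
    "write_cohort",
    "read_cohort",
    "write_trace",
    "write_dff",
    "write_image",
    "read_image",
    "read_roi_mask",
    "write_dnc_result",
]


def write_frame_series(series: EmissionFrameSeries, tsv_path, meta_path=None) -> None:
    """TSV with wavelength_nm plus one frame_<i> column per frame; JSON sidecar."""
    tsv_path = Path(tsv_path)
    df = pd.DataFrame({"wavelength_nm": series.wavelengths})
    for i in range(series.n_frames):
        df[f"frame_{i}"] = series.frames[i]
    df.to_csv(tsv_path, sep="\t", index=False)
    meta_path = Path(meta_path) if meta_path else tsv_path.with_suffix(".json")
    meta_path.write_text(
        json.dumps(
            {"frame_rate": series.frame_rate, "timestamps": series.timestamps.tolist()}
        )
    )


def read_frame_series(tsv_path, meta_path=None) -> EmissionFrameSeries:
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t")
    meta_path = Path(meta_path) if meta_path else tsv_path.with_suffix(".json")
    meta = json.loads(meta_path.read_text())
    frame_cols = [c for c in df.columns if c.startswith("frame_")]
    frame_cols.sort(key=lambda c: int(c.split("_")[1]))
    return EmissionFrameSeries(
        wavelengths=df["wavelength_nm"].to_numpy(),
        frames=df[frame_cols].to_numpy().T,
        timestamps=np.asarray(meta["timestamps"], dtype=float),
        frame_rate=float(meta["frame_rate"]),
    )


def write_basis_csv(basis: SpectralBasis, directory) -> list[Path]:
    """One two-column CSV (wavelength_nm, intensity) per fluorophore."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in basis.names:
        p = directory / f"{name.replace('/', '_')}.csv"
        pd.DataFrame(
            {"wavelength_nm": basis.wavelengths, "intensity": basis.column(name)}
        ).to_csv(p, index=False)
        paths.append(p)
    return paths


def read_basis_csv(paths, reference: str | None = None) -> SpectralBasis:
    """Assemble a basis from per-fluorophore CSVs (name taken from the stem)."""
    frames = []
    names = []
    for p in paths:
        p = Path(p)
        df = pd.read_csv(p)
        frames.append(df)
        names.append(p.stem)
    grid = frames[0]["wavelength_nm"].to_numpy()
    for name, df in zip(names[1:], frames[1:]):
        if not np.array_equal(df["wavelength_nm"].to_numpy(), grid):
            raise ValueError(f"basis file {name!r} is on a different wavelength grid")
    spectra = np.column_stack([df["intensity"].to_numpy() for df in frames])
    reference = reference or ("tdTomato" if "tdTomato" in names else names[-1])
    return SpectralBasis(
        wavelengths=grid, spectra=spectra, names=tuple(names), reference=reference
    )


def write_chromatogram(chrom: Chromatogram, path) -> None:
    pd.DataFrame({"time_s": chrom.time_s, "signal": chrom.signal}).to_csv(path, index=False)


def read_chromatogram(path) -> Chromatogram:
    df = pd.read_csv(path)
    return Chromatogram(time_s=df["time_s"].to_numpy(), signal=df["signal"].to_numpy())


def read_windows(path) -> list[PeakWindow]:
    """Peak windows from YAML or JSON: list of {analyte, start, end[, baseline_mode]}."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return [PeakWindow(**w) for w in raw]


def write_curve(curve: StandardCurve, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "slope": curve.slope,
                "intercept": curve.intercept,
                "r_squared": curve.r_squared,
                "calibration_points": [list(p) for p in curve.calibration_points],
            },
            indent=2,
        )
    )


def read_curve(path) -> StandardCurve:
    d = json.loads(Path(path).read_text())
    return StandardCurve(
        slope=d["slope"],
        intercept=d["intercept"],
        r_squared=d["r_squared"],
        calibration_points=tuple(tuple(p) for p in d.get("calibration_points", [])),
    )


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    return df


def write_trace(trace: CoefficientTrace, path) -> None:
    df = pd.DataFrame({"timestamp_s": trace.timestamps})
    for name in trace.names:
        df[name] = trace.channel(name)
    df["residual_norm"] = trace.residual_norm
    df.to_csv(path, index=False)


def write_dff(dff: DffTrace, path) -> None:
    pd.DataFrame(
        {
            "timestamp_s": dff.timestamps,
            "dff_percent": dff.dff_percent,
            "f0": dff.baseline_f0,
        }
    ).to_csv(path, index=False)


def write_image(image: HistologyImage, path) -> None:
    tifffile.imwrite(path, image.pixels)


def read_image(path, pixel_size_um: float | None = None) -> HistologyImage:
    return HistologyImage(pixels=tifffile.imread(path), pixel_size_um=pixel_size_um)


def read_roi_mask(path, shape) -> np.ndarray:
    """ROI from a mask TIFF or a polygon JSON {"vertices": [[row, col], ...]}."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        return tifffile.imread(path).astype(bool)
    d = json.loads(path.read_text())
    verts = np.asarray(d["vertices"], dtype=float)
    rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def write_dnc_result(result: DNCResult, path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2))
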