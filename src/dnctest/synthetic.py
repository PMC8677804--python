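"""Synthetic-data generators for every pipeline input.

No raw measurements from the mouse study were deposited, so each stage
of the pipeline is exercised on synthetic inputs that carry the
statistical structure the analysis assumes and return their latent
ground truth alongside:

* emission-frame series — two-Gaussian fluorophore mixtures with linear
  photobleaching of the dopamine-sensor coefficient, an exponentially
  decaying drug-evoked transient, and additive Gaussian noise;
* chromatograms — Gaussian peaks on a linear baseline drift with noise
  (true area of a Gaussian peak is amplitude * width * sqrt(2*pi));
* cohort tables — i.i.d. Normal(mean, SEM * sqrt(n)) draws per
  (group, state, analyte) cell, parameterised by published summaries;
* histology images — dark disk-like somata on a light textured
  background (the inverted-green-channel convention of DAB scans),
  with per-cell ground-truth masks.

Every generator takes an explicit integer seed and is bit-reproducible;
no global random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hplc import Chromatogram
from .photometry import EmissionFrameSeries, SpectralBasis
from .histology import HistologyImage
from . import studyparams

__all__ = [
    "FluorophoreSpec",
    "SessionParams",
    "CohortSpec",
    "ImageSpec",
    "SessionTruth",
    "SyntheticHistology",
    "DLIGHT",
    "TDTOMATO",
    "default_wavelength_grid",
    "make_basis",
    "simulate_session",
    "simulate_chromatogram",
    "simulate_cohort",
    "simulate_histology",
]


@dataclass(frozen=True)
class FluorophoreSpec:
    """Single-Gaussian approximation of a fluorophore emission spectrum."""

    name: str
    peak_wavelength: float  # nm
    bandwidth: float  # nm, Gaussian SD of the emission shape
    brightness: float = 1.0

    def __post_init__(self):
        if self.bandwidth <= 0:
            raise ValueError(f"{self.name}: bandwidth must be positive")
        if self.brightness < 0:
            raise ValueError(f"{self.name}: brightness must be nonnegative")

    def shape(self, grid: np.ndarray) -> np.ndarray:
        return self.brightness * np.exp(
            -0.5 * ((grid - self.peak_wavelength) / self.bandwidth) ** 2
        )


#: green dopamine sensor and red reference fluorophore used in the study
DLIGHT = FluorophoreSpec("dLight1.1", peak_wavelength=510.0, bandwidth=20.0, brightness=1.0)
TDTOMATO = FluorophoreSpec("tdTomato", peak_wavelength=581.0, bandwidth=18.0, brightness=1.0)


def default_wavelength_grid(start: float = 450.0, stop: float = 700.0, step: float = 2.0):
    return np.arange(start, stop + step / 2, step)


def make_basis(
    flspecs: list[FluorophoreSpec],
    grid: np.ndarray,
    reference: str | None = None,
    condition_flag_threshold: float = 1e8,
) -> SpectralBasis:
    """Build a spectral basis from fluorophore specs on a wavelength grid.

    All columns are scaled by the reference channel's peak so that the
    reference spectrum (tdTomato by default) has unit peak, as in
    peak-normalised published spectra.  Near-identical specs yield an
    ill-conditioned basis; the returned object carries the condition
    number and a flag rather than failing, so callers can decide.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if len(flspecs) < 1:
        raise ValueError("at least one fluorophore required")
    for fs in flspecs:
        if not (grid[0] <= fs.peak_wavelength <= grid[-1]):
            raise ValueError(f"{fs.name}: peak {fs.peak_wavelength} nm outside the grid")
    names = tuple(fs.name for fs in flspecs)
    if len(set(names)) != len(names):
        raise ValueError("fluorophore names must be unique")
    reference = reference or (TDTOMATO.name if TDTOMATO.name in names else names[-1])
    columns = np.column_stack([fs.shape(grid) for fs in flspecs])
    ref_peak = columns[:, names.index(reference)].max()
    if ref_peak <= 0:
        raise ValueError(f"reference channel {reference!r} has zero peak on the grid")
    columns = columns / ref_peak
    cond = float(np.linalg.cond(columns)) if len(flspecs) > 1 else 1.0
    return SpectralBasis(
        wavelengths=grid,
        spectra=columns,
        names=names,
        reference=reference,
        condition_number=cond,
        ill_conditioned=bool(cond > condition_flag_threshold),
    )


@dataclass(frozen=True)
class SessionParams:
    """Photometry-session generator parameters.

    Defaults match the acquisition protocol (25 Hz triggering); the
    bleach slope applies to the signal channel as a linear fractional
    loss per minute, reference-channel bleaching is separate (0 by
    default).  The transient is a fractional step of the signal-channel
    coefficient decaying exponentially after onset.
    """

    frame_rate: float = 25.0  # Hz
    duration: float = 1200.0  # s
    bleach_slope: float = 0.01  # fraction/min on the signal channel
    reference_bleach_slope: float = 0.0  # fraction/min on the reference channel
    transient_onset: float = 900.0  # s
    transient_amplitude: float = 0.5  # fractional increase of the signal coefficient
    transient_decay: float = 120.0  # s, exponential decay constant
    noise_sd: float = 0.01  # fraction of the peak clean signal
    seed: int = 0
    signal_channel: str = DLIGHT.name

    def __post_init__(self):
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("frame_rate and duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.transient_onset >= self.duration:
            raise ValueError("transient_onset must precede the end of the session")
        if self.transient_decay <= 0:
            raise ValueError("transient_decay must be positive")


@dataclass(frozen=True)
class SessionTruth:
    """Latent coefficient traces used to synthesise a session."""

    timestamps: np.ndarray
    coefficients: np.ndarray  # (n_frames, n_fluorophores)
    names: tuple[str, ...]

    def channel(self, name: str) -> np.ndarray:
        return self.coefficients[:, self.names.index(name)]


def simulate_session(
    basis: SpectralBasis, params: SessionParams
) -> tuple[EmissionFrameSeries, SessionTruth]:
    """Synthesise a photometry recording from a basis and session params.

    Frame t has expected spectrum sum_k c_k(t) * S_k(lambda) with

        c_sig(t) = (1 - bleach_slope * t / 60) * (1 + transient(t))
        transient(t) = A * exp(-(t - onset) / decay) for t >= onset

    plus additive white Gaussian noise of SD ``noise_sd`` times the peak
    of the clean t=0 spectrum.  The latent coefficient traces are
    returned as ground truth.
    """
    n_frames = int(round(params.duration * params.frame_rate))
    t = np.arange(n_frames) / params.frame_rate
    coeffs = np.ones((n_frames, basis.n_fluorophores))
    sig = basis.index(params.signal_channel)
    transient = np.where(
        t >= params.transient_onset,
        params.transient_amplitude * np.exp(-(t - params.transient_onset) / params.transient_decay),
        0.0,
    )
    coeffs[:, sig] = (1.0 - params.bleach_slope * t / 60.0) * (1.0 + transient)
    ref = basis.index(basis.reference)
    if ref != sig:
        coeffs[:, ref] = 1.0 - params.reference_bleach_slope * t / 60.0
    clean = coeffs @ basis.spectra.T
    rng = np.random.default_rng(params.seed)
    noise_scale = params.noise_sd * float(np.max(clean[0])) if n_frames else 0.0
    frames = clean + rng.normal(0.0, noise_scale, clean.shape) if noise_scale > 0 else clean
    series = EmissionFrameSeries(
        wavelengths=basis.wavelengths,
        frames=frames,
        timestamps=t,
        frame_rate=params.frame_rate,
    )
    return series, SessionTruth(timestamps=t, coefficients=coeffs, names=basis.names)


def simulate_chromatogram(
    peaks: list[tuple[str, float, float, float]],
    noise_sd: float = 0.0,
    drift_slope: float = 0.0,
    seed: int = 0,
    duration: float | None = None,
    dt: float = 0.1,
) -> Chromatogram:
    """Synthesise a chromatogram from (analyte, retention time s, amplitude, width s) peaks.

    signal(t) = drift_slope * t + sum_i A_i * exp(-(t - rt_i)^2 / (2 w_i^2)) + noise.

    True areas (A * w * sqrt(2 pi)) are attached per analyte.  Peaks
    closer than 3 sigma are flagged via ``overlapping_peaks`` rather
    than rejected.
    """
    for name, rt, amp, width in peaks:
        if width <= 0:
            raise ValueError(f"peak {name!r}: width must be positive")
    if duration is None:
        duration = max((rt + 6 * w for _, rt, _, w in peaks), default=60.0)
    t = np.arange(0.0, duration + dt / 2, dt)
    signal = drift_slope * t
    true_areas = {}
    for name, rt, amp, width in peaks:
        signal = signal + amp * np.exp(-0.5 * ((t - rt) / width) ** 2)
        true_areas[name] = amp * width * math.sqrt(2 * math.pi)
    overlapping = any(
        abs(p1[1] - p2[1]) < 3 * (p1[3] + p2[3])
        for i, p1 in enumerate(peaks)
        for p2 in peaks[i + 1 :]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, t.shape)
    return Chromatogram(
        time_s=t, signal=signal, true_areas=true_areas, overlapping_peaks=overlapping
    )


@dataclass(frozen=True)
class CohortSpec:
    """Normal population parameters per (group, state, analyte) cell.

    ``cells`` maps (group, state, analyte, matrix) to a
    :class:`~dnctest.studyparams.GroupStats`; draws within a cell are
    i.i.d. Normal(mean, SEM * sqrt(n)) — the only dispersion model
    reconstructible from published mean/SEM/n summaries.
    """

    cells: dict[tuple[str, str, str, str], studyparams.GroupStats]
    seed: int = 0

    def validate_complete(self) -> None:
        """Require every analyte to have all group x state cells; name gaps."""
        analytes = {(a, m) for (_, _, a, m) in self.cells}
        missing = [
            (g, s, a, m)
            for (a, m) in sorted(analytes)
            for g in studyparams.GROUPS
            for s in studyparams.STATES
            if (g, s, a, m) not in self.cells
        ]
        if missing:
            raise ValueError(f"cohort spec is missing cells: {missing}")
        for key, cell in self.cells.items():
            if cell.n < 2:
                raise ValueError(f"cell {key}: n must be >= 2")
            if cell.sem <= 0:
                raise ValueError(f"cell {key}: SEM must be positive")

    @classmethod
    def from_study(cls, stage: str, seed: int = 0) -> "CohortSpec":
        """Cohort spec at the published group parameters of one disease stage."""
        if stage not in studyparams.STAGES:
            raise ValueError(f"unknown stage {stage!r}; expected one of {studyparams.STAGES}")
        cells = {
            (g, s, a, studyparams.ANALYTE_MATRIX[a]): stats
            for (st, a, g, s), stats in studyparams.COHORT_STATS.items()
            if st == stage
        }
        return cls(cells=cells, seed=seed)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a long-format cohort table from a :class:`CohortSpec`.

    Columns: subject_id, genotype_group, state, matrix, analyte, value.
    Subject IDs are unique per cell (CSF and blood samples came from
    different animals, so no within-subject linkage is modelled).
    """
    spec.validate_complete()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for key in sorted(spec.cells):
        group, state, analyte, matrix = key
        cell = spec.cells[key]
        draws = rng.normal(cell.mean, cell.sd, cell.n)
        for i, v in enumerate(draws):
            rows.append(
                {
                    "subject_id": f"{group}_{state}_{matrix}_{analyte}_{i:03d}",
                    "genotype_group": group,
                    "state": state,
                    "matrix": matrix,
                    "analyte": analyte,
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of a synthetic DAB-stained section image.

    Dark disk-like somata on a light background with Gaussian texture,
    mimicking the inverted-green-channel appearance of DAB scans.  A
    ``min_separation`` margin between cell borders keeps the
    ground-truth count unambiguous; set it to a negative value to allow
    deliberate overlaps (for watershed stress tests).
    """

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 12
    cell_radius_range: tuple[float, float] = (8.0, 10.0)
    cell_intensity: float = 60.0
    background_level: float = 200.0
    texture_sd: float = 3.0
    min_separation: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        if self.cell_radius_range[0] > self.cell_radius_range[1] or self.cell_radius_range[0] <= 0:
            raise ValueError("invalid cell_radius_range")
        for v in (self.cell_intensity, self.background_level):
            if not (0 <= v <= 255):
                raise ValueError("intensities must lie within 8-bit depth")


@dataclass(frozen=True)
class SyntheticHistology:
    """Synthetic section image with its latent ground truth."""

    image: HistologyImage
    label_mask: np.ndarray  # int labels, one per generated cell
    count: int
    centers: np.ndarray  # (n_cells, 2) row, col
    radii: np.ndarray


def simulate_histology(
    spec: ImageSpec,
    centers: list[tuple[float, float]] | None = None,
    radii: list[float] | None = None,
) -> SyntheticHistology:
    """Generate a DAB-like section image with ground-truth cell masks.

    Cells are placed by rejection sampling with the requested border
    separation; an infeasible packing raises rather than silently
    dropping cells.  Explicit ``centers``/``radii`` override random
    placement (e.g. to construct deliberately overlapping pairs for
    watershed stress tests); the texture still follows the seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    if centers is not None:
        if radii is None or len(radii) != len(centers):
            raise ValueError("explicit placement requires one radius per center")
        return _render_histology(spec, rng, list(centers), list(radii))
    centers = []
    radii = []
    max_tries = 10000
    tries = 0
    while len(centers) < spec.n_cells:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {spec.n_cells} cells of radius "
                f"{spec.cell_radius_range} with separation {spec.min_separation} "
                f"in a {spec.shape} image"
            )
        tries += 1
        r = rng.uniform(*spec.cell_radius_range)
        margin = r + max(spec.min_separation, 0.0) + 1
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        ok = all(
            math.hypot(cy - oy, cx - ox) >= r + orr + spec.min_separation
            for (oy, ox), orr in zip(centers, radii)
        )
        if ok:
            centers.append((cy, cx))
            radii.append(r)
    return _render_histology(spec, rng, centers, radii)


def _render_histology(
    spec: ImageSpec, rng: np.random.Generator, centers: list, radii: list
) -> SyntheticHistology:
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]
    image = rng.normal(spec.background_level, spec.texture_sd, (h, w))
    labels = np.zeros((h, w), dtype=np.int32)
    for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        image[inside] = spec.cell_intensity
        labels[inside] = i
    image = np.clip(image, 0, 255).astype(np.uint8)
    return SyntheticHistology(
        image=HistologyImage(pixels=image),
        label_mask=labels,
        count=len(centers),
        centers=np.array(centers) if centers else np.zeros((0, 2)),
        radii=np.array(radii),
    )
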