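"""Spectrally resolved fiber-photometry analysis.

A single blue laser excites both the green dopamine sensor (dLight1.1)
and a dopamine-insensitive red reference fluorophore (tdTomato); the
emitted spectrum of every frame is a linear mixture of the two reference
emission shapes.  The stages implemented here:

1. per-frame linear unmixing of the measured spectrum into fluorophore
   coefficients (ordinary least squares; optional nonnegativity);
2. photobleaching ("fading") correction — an ordinary least-squares line
   fitted to the first minutes of a coefficient trace serves as the
   theoretical baseline F0, from which dF/F0% is computed;
3. the challenge-agent ranking metric: percent increase of the
   dLight/tdTomato coefficient ratio after a drug injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "SpectralBasis",
    "EmissionFrameSeries",
    "CoefficientTrace",
    "DffTrace",
    "unmix_frame",
    "unmix_series",
    "fit_fading_baseline",
    "percent_ratio_increase",
    "moving_average",
]

#: condition numbers above this default cap mark a basis as ill-conditioned
DEFAULT_CONDITION_CAP = 1e8


@dataclass(frozen=True)
class SpectralBasis:
    """Reference emission spectra of the fluorophores on a common grid.

    Spectra are stored column-wise: ``spectra[:, k]`` is the emission
    shape of fluorophore ``names[k]`` sampled on ``wavelengths`` (nm).
    By convention all columns are scaled so that the reference channel
    (tdTomato) peaks at 1, preserving relative brightness.
    """

    wavelengths: np.ndarray
    spectra: np.ndarray
    names: tuple[str, ...]
    reference: str
    condition_number: float = field(default=np.nan)
    ill_conditioned: bool = False

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        sp = np.asarray(self.spectra, dtype=float)
        if wl.ndim != 1 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be 1-D and strictly increasing")
        if sp.shape != (wl.size, len(self.names)):
            raise ValueError(
                f"spectra shape {sp.shape} does not match grid length {wl.size} "
                f"x {len(self.names)} fluorophores"
            )
        if np.any(sp < 0):
            raise ValueError("reference spectra must be nonnegative")
        if self.reference not in self.names:
            raise ValueError(f"reference channel {self.reference!r} not among {self.names}")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "spectra", sp)
        if np.isnan(self.condition_number):
            cond = float(np.linalg.cond(sp)) if min(sp.shape) > 1 else 1.0
            object.__setattr__(self, "condition_number", cond)

    @property
    def n_fluorophores(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def column(self, name: str) -> np.ndarray:
        return self.spectra[:, self.index(name)]


@dataclass(frozen=True)
class EmissionFrameSeries:
    """Time-ordered measured emission spectra from one recording.

    ``frames`` has shape (n_frames, n_wavelengths); ``timestamps`` are
    the acquisition-trigger times in seconds (integration time is
    metadata only).
    """

    wavelengths: np.ndarray
    frames: np.ndarray
    timestamps: np.ndarray
    frame_rate: float

    def __post_init__(self):
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, dtype=float))
        object.__setattr__(self, "frames", np.asarray(self.frames, dtype=float))
        object.__setattr__(self, "timestamps", np.asarray(self.timestamps, dtype=float))
        if self.frames.ndim != 2 or self.frames.shape[1] != self.wavelengths.size:
            raise ValueError("frames must be (n_frames, n_wavelengths)")
        if self.timestamps.size != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class CoefficientTrace:
    """Per-frame unmixing coefficients and residual norms."""

    timestamps: np.ndarray
    coefficients: np.ndarray  # (n_frames, n_fluorophores)
    names: tuple[str, ...]
    residual_norm: np.ndarray

    def channel(self, name: str) -> np.ndarray:
        return self.coefficients[:, self.names.index(name)]

    @property
    def frame_rate(self) -> float:
        dt = np.median(np.diff(self.timestamps)) if self.timestamps.size > 1 else 1.0
        return 1.0 / float(dt)


@dataclass(frozen=True)
class DffTrace:
    """Fading-corrected fractional fluorescence change, in percent."""

    timestamps: np.ndarray
    dff_percent: np.ndarray
    baseline_f0: np.ndarray
    fit_window_s: float
    channel: str


def unmix_frame(
    measured: np.ndarray,
    basis: SpectralBasis,
    *,
    nonnegative: bool = False,
    condition_cap: float = DEFAULT_CONDITION_CAP,
) -> tuple[np.ndarray, float]:
    """Least-squares decomposition of one spectrum into basis coefficients.

    Returns ``(coefficients, residual_norm)`` where the coefficients
    minimise ``||measured - spectra @ c||_2``.  With ``nonnegative=True``
    the minimisation is constrained to c >= 0.
    """
    measured = np.asarray(measured, dtype=float)
    if measured.shape != basis.wavelengths.shape:
        raise ValueError(
            f"measured spectrum length {measured.size} does not match "
            f"basis grid length {basis.wavelengths.size}"
        )
    if basis.condition_number > condition_cap:
        raise ValueError(
            f"basis {basis.names} is ill-conditioned "
            f"(condition number {basis.condition_number:.3g} > cap {condition_cap:.3g})"
        )
    if nonnegative:
        coeffs, rnorm = nnls(basis.spectra, measured)
        return coeffs, float(rnorm)
    coeffs, _, _, _ = np.linalg.lstsq(basis.spectra, measured, rcond=None)
    resid = measured - basis.spectra @ coeffs
    return coeffs, float(np.linalg.norm(resid))


def unmix_series(
    series: EmissionFrameSeries,
    basis: SpectralBasis,
    *,
    nonnegative: bool = False,
    condition_cap: float = DEFAULT_CONDITION_CAP,
) -> CoefficientTrace:
    """Unmix every frame of a recording.

    The unconstrained path solves all frames in a single vectorised
    least-squares call; results are identical to frame-by-frame
    :func:`unmix_frame`.
    """
    if series.n_frames < 1:
        raise ValueError("series must contain at least one frame")
    if not np.array_equal(series.wavelengths, basis.wavelengths):
        raise ValueError("frame series and basis are on different wavelength grids")
    if basis.condition_number > condition_cap:
        raise ValueError(
            f"basis {basis.names} is ill-conditioned "
            f"(condition number {basis.condition_number:.3g} > cap {condition_cap:.3g})"
        )
    if nonnegative:
        rows = []
        for i, frame in enumerate(series.frames):
            try:
                c, _ = unmix_frame(frame, basis, nonnegative=True, condition_cap=condition_cap)
            except ValueError as exc:  # pragma: no cover - re-raise with context
                raise ValueError(f"frame {i}: {exc}") from exc
            rows.append(c)
        coeffs = np.array(rows)
    else:
        coeffs, _, _, _ = np.linalg.lstsq(basis.spectra, series.frames.T, rcond=None)
        coeffs = coeffs.T
    resid = series.frames - coeffs @ basis.spectra.T
    return CoefficientTrace(
        timestamps=series.timestamps,
        coefficients=coeffs,
        names=basis.names,
        residual_norm=np.linalg.norm(resid, axis=1),
    )


def fit_fading_baseline(
    trace: CoefficientTrace,
    channel: str,
    fit_window_s: float = 600.0,
) -> DffTrace:
    """Correct photobleaching by a linear baseline fitted to early frames.

    An ordinary least-squares line is fitted to the coefficient trace on
    frames with ``t <= fit_window_s`` (boundary inclusive) and
    extrapolated over the whole recording as the theoretical baseline
    F0(t); dF/F0% = (F - F0)/F0 * 100 per frame.  The fit window must
    precede any evoked transient for the baseline to represent pure
    fading.
    """
    t = trace.timestamps
    f = trace.channel(channel)
    if t[-1] < fit_window_s:
        raise ValueError(
            f"trace spans {t[-1]:.1f} s, shorter than the {fit_window_s:.1f} s fit window"
        )
    mask = t <= fit_window_s
    slope, intercept = np.polyfit(t[mask], f[mask], deg=1)
    f0 = slope * t + intercept
    if np.any(f0 <= 0):
        raise ValueError(
            "fitted baseline F0 crosses zero within the recording; "
            "the linear fading model is invalid for this trace"
        )
    return DffTrace(
        timestamps=t,
        dff_percent=(f - f0) / f0 * 100.0,
        baseline_f0=f0,
        fit_window_s=float(fit_window_s),
        channel=channel,
    )


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered boxcar smoother; width clipped to [1, len(x)], edges renormalised."""
    width = int(max(1, min(width, x.size)))
    if width == 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(width)
    return np.convolve(x, kernel, mode="same") / np.convolve(np.ones_like(x), kernel, mode="same")


def percent_ratio_increase(
    trace: CoefficientTrace,
    injection_time: float,
    pre_window_s: float = 300.0,
    post_window_s: float = 1800.0,
    smoothing_s: float = 5.0,
    signal: str = "dLight1.1",
    reference: str = "tdTomato",
) -> float:
    """Percent increase of the signal/reference coefficient ratio after a drug.

    r(t) = c_signal(t) / c_reference(t).  Returns
    ``(max over smoothed post-injection window of r - mean pre-injection r)
    / (mean pre-injection r) * 100``.  This is the summary used to rank
    challenge agents (e.g. methylphenidate + haloperidol co-administration
    produces the largest rise).
    """
    t = trace.timestamps
    ref = trace.channel(reference)
    pre = (t >= injection_time - pre_window_s) & (t < injection_time)
    post = (t > injection_time) & (t <= injection_time + post_window_s)
    if not pre.any():
        raise ValueError("pre-injection window contains no frames")
    if not post.any():
        raise ValueError("post-injection window contains no frames")
    used = pre | post
    if np.any(ref[used] <= 0):
        raise ValueError("reference-channel coefficient <= 0 within the analysis windows")
    ratio = trace.channel(signal) / ref
    width = max(1, int(round(smoothing_s * trace.frame_rate)))
    smoothed = moving_average(ratio, width)
    baseline = float(np.mean(ratio[pre]))
    peak = float(np.max(smoothed[post]))
    return (peak - baseline) / baseline * 100.0
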