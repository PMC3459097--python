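"""Pre-statistics processing: temporal highpass, spatial smoothing,
intensity normalization and motion-block censoring.

The highpass filter regresses time series against a discrete-cosine
low-frequency subspace (periods longer than the cutoff) and restores the
series mean, matching the cutoff semantics of standard fMRI highpass
filtering deterministically. Censoring removes whole peristimulus epochs
whose volumes (including the 2 s pre-stimulus baseline) touch a corrupted
span; a run is rejected outright unless more than 40% of the acquisition
survives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from neohrf.synth import StimulusDesign

__all__ = [
    "CensoringReport",
    "highpass_filter",
    "spatial_smooth",
    "normalize_intensity",
    "censor_epochs",
    "NORMALIZATION_TARGET",
]

#: global 4D mean after intensity normalization (arbitrary units)
NORMALIZATION_TARGET = 10000.0

#: fraction of the acquisition that must survive censoring (strict: exactly
#: 40% retained rejects)
RETENTION_THRESHOLD = 0.40

#: pre-stimulus baseline window counted toward an epoch's integrity (s)
BASELINE_WINDOW = 2.0

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


def _dct_basis(n: int, k: int) -> np.ndarray:
    """First k DCT-II components (excluding the constant), columns of an
    (n, k) matrix. Component j has period 2n/j samples."""
    t = np.arange(n)
    j = np.arange(1, k + 1)
    return np.cos(np.pi * np.outer(t + 0.5, j) / n)


def highpass_filter(series: np.ndarray, tr: float, cutoff: float = 50.0) -> np.ndarray:
    """Remove fluctuations slower than ``cutoff`` seconds; restore the mean.

    Operates on the last axis. Components with period > cutoff are projected
    out via regression on a discrete-cosine subspace; faster fluctuations
    (period <= cutoff/2) pass essentially unattenuated.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if n < 2:
        raise ValueError("series must have at least 2 time points")
    if cutoff <= 2 * tr:
        raise ValueError(
            f"cutoff ({cutoff} s) must exceed twice the sampling interval ({2 * tr} s)"
        )
    # DCT component j spans period 2*n*tr/j seconds; drop all with period > cutoff
    k = int(np.floor(2.0 * n * tr / cutoff))
    mean = series.mean(axis=-1, keepdims=True)
    if k < 1:
        return series.copy()
    basis = _dct_basis(n, k)
    basis /= np.linalg.norm(basis, axis=0, keepdims=True)
    centered = series - mean
    coeffs = centered @ basis
    return centered - coeffs @ basis.T + mean


def spatial_smooth(
    volume: np.ndarray,
    voxel_sizes: tuple[float, float, float],
    fwhm: float = 5.0,
) -> np.ndarray:
    """Gaussian spatial smoothing with the stated FWHM in mm per axis.

    Anisotropic voxels are handled through per-axis sigmas; 4D input is
    smoothed volume-by-volume (no temporal blurring). Reflect boundary mode
    conserves the image sum.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    volume = np.asarray(volume, dtype=float)
    if volume.ndim not in (3, 4):
        raise ValueError("expected a 3D or 4D volume")
    if fwhm == 0:
        return volume.copy()
    sigmas = [fwhm * FWHM_TO_SIGMA / vs for vs in voxel_sizes]
    if volume.ndim == 4:
        sigmas = sigmas + [0.0]
    return ndimage.gaussian_filter(volume, sigma=sigmas, mode="reflect")


def normalize_intensity(
    volume: np.ndarray, target: float = NORMALIZATION_TARGET
) -> tuple[np.ndarray, float]:
    """Scale a 4D run by a single factor so its global mean equals ``target``.

    Returns the scaled volume and the factor applied.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ValueError("expected a 4D volume")
    mean = float(volume.mean())
    if mean == 0 or not np.isfinite(mean):
        raise ValueError("global mean is zero or non-finite; cannot normalize")
    factor = target / mean
    return volume * factor, factor


@dataclass(frozen=True)
class CensoringReport:
    """Outcome of motion-block censoring for one run."""

    total_epochs: int
    retained_epochs: int
    retained_fraction: float
    rejected: bool
    corrupted_spans: tuple[tuple[int, int], ...]
    retained_onsets: tuple[float, ...]


def censor_epochs(
    design: StimulusDesign,
    corrupted_spans: list[tuple[int, int]] | tuple[tuple[int, int], ...],
    baseline_window: float = BASELINE_WINDOW,
) -> tuple[CensoringReport, StimulusDesign]:
    """Drop peristimulus epochs whose volumes intersect a corrupted span.

    An epoch's integrity window is its peristimulus analysis window: from
    the pre-stimulus baseline (clipped at the acquisition start) through the
    epoch end minus the baseline width, so consecutive epoch windows tile
    the acquisition without overlap and each epoch owns exactly
    epoch_duration/tr volumes. Spans are half-open 0-based volume intervals.
    The run is flagged rejected when the retained fraction of the
    acquisition is <= 40%; rejection is a reported state, not an exception.
    """
    spans = []
    for start, end in corrupted_spans:
        start, end = int(start), int(end)
        if start < 0 or end > design.n_volumes or end <= start:
            raise ValueError(f"corrupted span ({start}, {end}) outside the acquisition")
        spans.append((start, end))

    epoch_vols = int(round(design.epoch_duration / design.tr))
    retained = []
    for onset in design.onsets:
        v_start = int(round((onset - baseline_window) / design.tr))
        v0 = max(v_start, 0)
        v1 = min(v_start + epoch_vols, design.n_volumes)
        clean = all(end <= v0 or start >= v1 for start, end in spans)
        if clean:
            retained.append(onset)

    fraction = len(retained) * epoch_vols / design.n_volumes
    report = CensoringReport(
        total_epochs=len(design.onsets),
        retained_epochs=len(retained),
        retained_fraction=fraction,
        rejected=fraction <= RETENTION_THRESHOLD,
        corrupted_spans=tuple(spans),
        retained_onsets=tuple(retained),
    )
    retained_design = replace(design, onsets=tuple(retained))
    return report, retained_design
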