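"""Synthetic acquisitions: stimulus designs, 4D BOLD runs and vessel flow.

The generator emulates the study conditions the analysis pipeline assumes:
an event-related run sampling the BOLD response every 500 ms with a 1 s
stimulus and a 40.5 s inter-stimulus interval (12 complete epochs in 1000
volumes over 6 axial slices), a block paradigm of 24 s stimulation / 24 s
rest, and pulsatile phase-contrast velocity waveforms for the two internal
carotid arteries and the basilar artery.

Noise components (white Gaussian, polynomial drift, pseudo-physiological
sinusoids, corrupted "motion" volume spans) are individually configurable
and, except for white noise, off by default. All randomness flows through a
single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre

from neohrf.cbf import (
    FlowMeasurement,
    NEONATAL_BRAIN_DENSITY,
    VELOCITY_AREA_TO_ML_MIN,
)
from neohrf.hrf import HRFParams, evaluate_hrf, DEFAULT_HORIZON

__all__ = [
    "StimulusDesign",
    "Geometry",
    "NoiseSpec",
    "SyntheticBold",
    "make_event_design",
    "make_block_design",
    "convolved_regressor",
    "simulate_bold",
    "simulate_pc_flow",
]

#: baseline intensity of synthetic voxels (arbitrary scanner units);
#: % signal change is defined relative to it
BASELINE_INTENSITY = 1000.0

VESSELS = ("left_ica", "right_ica", "basilar")


@dataclass(frozen=True)
class StimulusDesign:
    """Stimulus onsets on an acquisition clock.

    onsets are seconds from acquisition start; epoch_duration is stimulus
    duration plus the following rest (inter-stimulus interval for event
    designs, off-block for block designs).
    """

    tr: float
    n_volumes: int
    onsets: tuple[float, ...]
    stim_duration: float
    epoch_duration: float

    def __post_init__(self) -> None:
        if not self.tr > 0:
            raise ValueError("tr must be positive (s)")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be >= 1")
        onsets = tuple(float(o) for o in self.onsets)
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("onsets must be strictly increasing")
        total = self.n_volumes * self.tr
        if onsets and onsets[-1] + self.epoch_duration > total + 1e-9:
            raise ValueError("last epoch extends beyond the acquisition")
        object.__setattr__(self, "onsets", onsets)

    @property
    def total_duration(self) -> float:
        return self.n_volumes * self.tr

    @property
    def volume_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr

    def durations(self) -> np.ndarray:
        return np.full(len(self.onsets), self.stim_duration)


def _align_to_volume(t: float, tr: float) -> float:
    """Snap a time down to a volume start (stimuli are synchronized to the
    acquisition; flooring keeps every epoch inside the run)."""
    return math.floor(t / tr + 1e-9) * tr


def make_event_design(
    tr: float, n_volumes: int, stim_duration: float, isi: float
) -> StimulusDesign:
    """Event-related design: brief stimuli separated by a fixed
    inter-stimulus interval, first stimulus at the start of epoch 1.

    The number of complete epochs is floor(total_time / (stim + isi)).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    if stim_duration <= 0:
        raise ValueError("stim_duration must be positive")
    if isi < 0:
        raise ValueError("isi must be >= 0")
    epoch = stim_duration + isi
    if epoch < tr:
        raise ValueError("epoch shorter than one volume cannot be sampled")
    total = n_volumes * tr
    n_epochs = int(math.floor(total / epoch + 1e-9))
    if n_epochs < 1:
        raise ValueError(
            f"no complete stimulation+rest epoch fits: epoch duration {epoch} s "
            f"exceeds the {total} s acquisition"
        )
    onsets = tuple(_align_to_volume(k * epoch, tr) for k in range(n_epochs))
    return StimulusDesign(
        tr=tr,
        n_volumes=n_volumes,
        onsets=onsets,
        stim_duration=stim_duration,
        epoch_duration=epoch,
    )


def make_block_design(
    tr: float,
    n_volumes: int,
    on_duration: float,
    off_duration: float,
    stimulation_first: bool = True,
) -> StimulusDesign:
    """Block design: alternating stimulation and rest blocks.

    The first epoch starts with stimulation unless ``stimulation_first`` is
    False, in which case a rest block leads.
    """
    if on_duration <= 0 or off_duration <= 0:
        raise ValueError("block durations must be positive")
    if tr <= 0:
        raise ValueError("tr must be positive")
    cycle = on_duration + off_duration
    total = n_volumes * tr
    lead = 0.0 if stimulation_first else off_duration
    n_cycles = int(math.floor((total - lead) / cycle + 1e-9))
    if n_cycles < 1:
        raise ValueError(
            f"fewer than one complete on+off cycle fits in the {total} s acquisition"
        )
    onsets = tuple(_align_to_volume(lead + k * cycle, tr) for k in range(n_cycles))
    return StimulusDesign(
        tr=tr,
        n_volumes=n_volumes,
        onsets=onsets,
        stim_duration=on_duration,
        epoch_duration=cycle,
    )


def convolved_regressor(
    design: StimulusDesign,
    hrf: HRFParams | tuple[np.ndarray, np.ndarray],
    oversample: int = 10,
    unit_peak: bool = True,
    impulse: bool | None = None,
) -> np.ndarray:
    """Stimulus train convolved with an HRF, sampled at volume times.

    ``hrf`` is either double-gamma parameters (evaluated with unit peak) or a
    ``(times, values)`` waveform pair which is linearly resampled. With
    ``unit_peak`` the regressor is scaled to unit maximum absolute value so
    GLM effect sizes read directly in % signal change.

    Brief stimuli sample the impulse response directly: when ``impulse`` is
    None it defaults to True for stimuli no longer than two volumes, in
    which case each event contributes a unit-area impulse (the regressor at
    the volume grid is exactly the HRF shifted to the onsets). Sustained
    blocks use the boxcar convolution integral.
    """
    dt = design.tr / oversample
    n_fine = design.n_volumes * oversample
    if impulse is None:
        impulse = design.stim_duration <= 2.0 * design.tr
    u = np.zeros(n_fine)
    for onset in design.onsets:
        i0 = int(round(onset / dt))
        if impulse:
            if i0 < n_fine:
                u[i0] += 1.0 / dt
            continue
        i1 = int(round((onset + design.stim_duration) / dt))
        u[i0 : min(i1, n_fine)] = 1.0
    if isinstance(hrf, HRFParams):
        t_h = np.arange(0.0, DEFAULT_HORIZON + dt, dt)
        h = evaluate_hrf(hrf.with_amplitude(1.0), t_h)
    else:
        t_w, v_w = hrf
        t_h = np.arange(0.0, float(np.max(t_w)) + dt, dt)
        h = np.interp(t_h, np.asarray(t_w, float), np.asarray(v_w, float))
    s = np.convolve(u, h)[:n_fine] * dt
    s = s[::oversample]
    if unit_peak:
        peak = np.max(np.abs(s))
        if peak == 0:
            raise ValueError("design produces an all-zero regressor")
        s = s / peak
    return s


@dataclass(frozen=True)
class Geometry:
    """Volume geometry and the active cluster (a sphere in voxel space)."""

    shape: tuple[int, int, int] = (32, 32, 6)
    voxel_sizes: tuple[float, float, float] = (3.125, 3.125, 4.0)
    active_center: tuple[int, int, int] | None = None
    active_radius: float = 2.0  # voxels

    def active_mask(self) -> np.ndarray:
        center = self.active_center
        if center is None:
            center = tuple(s // 2 for s in self.shape)
        idx = np.indices(self.shape)
        d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
        mask = d2 <= self.active_radius**2
        if not mask[center]:
            raise ValueError("active cluster does not fit inside the volume")
        return mask


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise components in raw intensity units.

    white_sd: per-voxel, per-volume Gaussian sd. drift_coefficients: Legendre
    polynomial amplitudes (orders 1, 2, ...) over the run. oscillations:
    (amplitude, frequency_hz) sinusoids with per-voxel random phase, standing
    in for aliased cardiac/respiratory fluctuations. corrupted_spans:
    half-open volume intervals where the signal carries large global jumps,
    emulating motion-corrupted stretches.
    """

    white_sd: float = 10.0
    drift_coefficients: tuple[float, ...] = ()
    oscillations: tuple[tuple[float, float], ...] = ()
    corrupted_spans: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        vals = [self.white_sd, *self.drift_coefficients]
        vals += [x for pair in self.oscillations for x in pair]
        if not np.all(np.isfinite(vals)):
            raise ValueError("noise parameters must be finite")
        if self.white_sd < 0:
            raise ValueError("white_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticBold:
    """A synthetic 4D acquisition with ground truth."""

    volumes: np.ndarray  # (x, y, z, t), raw intensity
    voxel_sizes: tuple[float, float, float]
    tr: float
    truth_mask: np.ndarray  # (x, y, z) bool
    truth_amplitude: float  # % signal change at active voxels
    noise_spec: NoiseSpec
    seed: int

    def __post_init__(self) -> None:
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be 4D (x, y, z, t)")
        if self.truth_amplitude > 0 and not self.truth_mask.any():
            raise ValueError("truth_mask empty despite positive amplitude")


def simulate_bold(
    design: StimulusDesign,
    hrf: HRFParams,
    geometry: Geometry = Geometry(),
    noise_spec: NoiseSpec = NoiseSpec(),
    truth_amplitude: float = 1.0,
    seed: int = 0,
) -> SyntheticBold:
    """Simulate a 4D BOLD run with a spherical active cluster.

    Active voxels follow ``baseline * (1 + s(t)/100)`` where s(t) is the
    design convolved with the unit-peak HRF and rescaled so its maximum is
    ``truth_amplitude`` (% signal change). Inactive voxels carry baseline
    plus noise only. Identical seed and spec give identical output.
    """
    if len(design.onsets) == 0:
        raise ValueError("design has no stimuli")
    mask = geometry.active_mask()
    rng = np.random.default_rng(seed)
    T = design.n_volumes
    shape = geometry.shape

    # brief stimuli sample the unit-calibrated impulse response directly,
    # so the active time course equals the HRF curve at the volume grid;
    # sustained blocks are convolved and rescaled to the target peak
    impulse = design.stim_duration <= 2.0 * design.tr
    s = (
        convolved_regressor(design, hrf, unit_peak=not impulse, impulse=impulse)
        * truth_amplitude
    )

    data = np.full(shape + (T,), BASELINE_INTENSITY, dtype=np.float64)
    data[mask] *= 1.0 + s / 100.0

    ns = noise_spec
    if ns.white_sd > 0:
        data += rng.normal(0.0, ns.white_sd, size=shape + (T,))
    if ns.drift_coefficients:
        x = np.linspace(-1.0, 1.0, T)
        drift = np.zeros(T)
        for order, coeff in enumerate(ns.drift_coefficients, start=1):
            c = np.zeros(order + 1)
            c[order] = coeff
            drift += legendre.legval(x, c)
        data += drift
    if ns.oscillations:
        t = design.volume_times
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(len(ns.oscillations),) + shape)
        for (amp, freq), phase in zip(ns.oscillations, phases):
            data += amp * np.sin(
                2.0 * np.pi * freq * t[None, None, None, :] + phase[..., None]
            )
    for start, end in ns.corrupted_spans:
        start, end = max(int(start), 0), min(int(end), T)
        if end <= start:
            continue
        jumps = rng.normal(0.0, 0.05 * BASELINE_INTENSITY, size=end - start)
        data[..., start:end] += jumps[None, None, None, :]

    return SyntheticBold(
        volumes=data,
        voxel_sizes=geometry.voxel_sizes,
        tr=design.tr,
        truth_mask=mask,
        truth_amplitude=truth_amplitude,
        noise_spec=ns,
        seed=seed,
    )


def simulate_pc_flow(
    target_cbf: float,
    brain_volume: float,
    split: tuple[float, float, float] = (0.4, 0.4, 0.2),
    heart_rate: float = 120.0,
    n_phases: int = 20,
    pulsatility: float = 0.3,
    areas: tuple[float, float, float] = (5.0, 5.0, 4.0),
    density: float = NEONATAL_BRAIN_DENSITY,
    seed: int = 0,
) -> list[FlowMeasurement]:
    """Pulsatile per-vessel velocity waveforms consistent with a target CBF.

    The total brain-feeding flow implied by ``target_cbf`` (ml/100 g/min)
    and ``brain_volume`` (ml) is divided across the left/right internal
    carotid and basilar arteries per ``split``; each vessel's mean velocity
    is modulated by a cosine pulse whose cycle mean is exactly the required
    mean, so the flow computation recovers ``target_cbf`` to rounding.
    """
    if target_cbf <= 0:
        raise ValueError("target_cbf must be positive")
    if brain_volume <= 0:
        raise ValueError("brain_volume must be positive")
    if len(split) != 3 or len(areas) != 3:
        raise ValueError("need split fractions and areas for exactly 3 vessels")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {sum(split)}")
    if n_phases < 2:
        raise ValueError("need at least 2 cardiac phases")
    if pulsatility < 0:
        raise ValueError("pulsatility must be >= 0")

    total_flow = target_cbf * density * brain_volume / 100.0  # ml/min
    rng = np.random.default_rng(seed)
    p = np.arange(n_phases)
    measurements = []
    for vessel, frac, area in zip(VESSELS, split, areas):
        flow = total_flow * frac
        v_mean = flow / (area * VELOCITY_AREA_TO_ML_MIN)
        phase0 = rng.uniform(0.0, 2.0 * np.pi)
        waveform = np.cos(2.0 * np.pi * p / n_phases + phase0)
        waveform -= waveform.mean()  # exact zero cycle mean
        v = v_mean * (1.0 + pulsatility * waveform)
        measurements.append(
            FlowMeasurement(
                vessel=vessel,
                phase_velocities=tuple(v),
                area=area,
                heart_rate=heart_rate,
            )
        )
    return measurements
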