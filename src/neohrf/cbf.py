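"""Global cerebral blood flow (CBF) from phase-contrast vessel flow.

Per-vessel instantaneous flux is mean lumen velocity times lumen area;
vessel flow is the cardiac-cycle mean of the flux; global CBF is the summed
flow of the two internal carotid arteries and the basilar artery divided by
brain mass (volume x density), reported in ml/100 g/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FlowMeasurement",
    "CBFResult",
    "VELOCITY_AREA_TO_ML_MIN",
    "NEONATAL_BRAIN_DENSITY",
    "instantaneous_flux",
    "vessel_flow",
    "global_cbf",
]

#: cm/s * mm^2 -> ml/min: 1 cm/s = 10 mm/s, so 10 mm^3/s = 0.01 ml/s = 0.6 ml/min
VELOCITY_AREA_TO_ML_MIN = 0.6

#: neonatal brain density, g/ml
NEONATAL_BRAIN_DENSITY = 1.05


@dataclass(frozen=True)
class FlowMeasurement:
    """Phase-contrast measurement for one brain-feeding vessel.

    phase_velocities are mean lumen-ROI velocities (cm/s), one per cardiac
    phase; area is the lumen area in mm^2 (a per-phase vector is averaged,
    matching the convention of multiplying one area by the mean velocity).
    """

    vessel: str
    phase_velocities: tuple[float, ...]
    area: float
    heart_rate: float = float("nan")

    def __post_init__(self) -> None:
        v = np.asarray(self.phase_velocities, dtype=float)
        if v.size < 2:
            raise ValueError("need velocities for at least 2 cardiac phases")
        if not np.all(np.isfinite(v)):
            raise ValueError("phase velocities must be finite")
        area = np.mean(np.asarray(self.area, dtype=float))
        if not area > 0:
            raise ValueError("vessel area must be positive (mm^2)")
        object.__setattr__(self, "phase_velocities", tuple(float(x) for x in v))
        object.__setattr__(self, "area", float(area))


@dataclass(frozen=True)
class CBFResult:
    vessel_flows: dict[str, float] = field(default_factory=dict)  # ml/min
    total_flow: float = 0.0  # ml/min
    brain_volume: float = 0.0  # ml
    brain_density: float = NEONATAL_BRAIN_DENSITY  # g/ml
    global_cbf: float = 0.0  # ml/100 g/min


def instantaneous_flux(measurement: FlowMeasurement) -> np.ndarray:
    """Per-cardiac-phase flux in ml/min (mean velocity x lumen area)."""
    v = np.asarray(measurement.phase_velocities, dtype=float)
    return v * measurement.area * VELOCITY_AREA_TO_ML_MIN


def vessel_flow(flux_per_phase: np.ndarray) -> float:
    """Vessel flow = arithmetic mean of instantaneous flux across the cycle."""
    flux = np.asarray(flux_per_phase, dtype=float)
    if flux.size < 2:
        raise ValueError("need flux for at least 2 cardiac phases")
    return float(flux.mean())


def global_cbf(
    vessel_flows: dict[str, float] | list[float],
    brain_volume: float,
    density: float = NEONATAL_BRAIN_DENSITY,
) -> CBFResult:
    """Global CBF in ml/100 g/min from the three brain-feeding vessel flows.

    global_cbf = total_flow / (brain_volume * density) * 100.
    """
    if isinstance(vessel_flows, dict):
        flows = dict(vessel_flows)
    else:
        flows = {f"vessel_{i}": float(f) for i, f in enumerate(vessel_flows)}
    if len(flows) != 3:
        raise ValueError(
            "expected exactly three vessel flows (left ICA, right ICA, basilar); "
            f"got {len(flows)}"
        )
    if not brain_volume > 0:
        raise ValueError("brain volume must be positive (ml)")
    if not density > 0:
        raise ValueError("brain density must be positive (g/ml)")
    total = float(sum(flows.values()))
    cbf = total / (brain_volume * density) * 100.0
    return CBFResult(
        vessel_flows=flows,
        total_flow=total,
        brain_volume=float(brain_volume),
        brain_density=float(density),
        global_cbf=cbf,
    )


def cbf_from_measurements(
    measurements: list[FlowMeasurement],
    brain_volume: float,
    density: float = NEONATAL_BRAIN_DENSITY,
) -> CBFResult:
    """Convenience chain: flux -> vessel flow -> global CBF."""
    flows = {
        m.vessel: vessel_flow(instantaneous_flux(m)) for m in measurements
    }
    return global_cbf(flows, brain_volume, density=density)
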