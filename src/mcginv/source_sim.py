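"""Epicardial potential time series for normal and infarcted hearts.

Each epicardial node carries a monophasic action-potential-like waveform
(resting level, fast sigmoid depolarization, plateau, smooth repolarization)
shifted by a per-node activation delay.  Two myocardial-infarction (MI)
morphologies are simulated over a circular epicardial patch:

* ``st_elevated`` — the waveform's deviation from the resting level is
  scaled down (default factor 0.52, i.e. a 48% amplitude reduction),
  producing an ST-segment shift in the forward field;
* ``increased_t`` — the repolarization phase is shortened (default factor
  0.6), moving and sharpening the T peak.

Amplitudes are millivolts, times milliseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import TriMesh

__all__ = [
    "WaveformParams",
    "MIScenario",
    "SourceTimeSeries",
    "template_waveform",
    "lesion_patch",
    "simulate_sources",
]


@dataclass
class WaveformParams:
    """Parameters of the per-node action-potential surrogate (ms / mV).

    With the defaults the plateau spans roughly 40-110 ms and repolarization
    110-190 ms, so the analysis instants t = 85 ms (mid-ST) and t = 125 ms
    (T wave) fall in the plateau and repolarization phases respectively.
    """

    T_total: float = 250.0
    dt: float = 1.0
    resting_level: float = -0.5
    plateau_amplitude: float = 4.0
    depol_time: float = 30.0
    depol_rise: float = 10.0
    plateau_duration: float = 70.0
    repol_duration: float = 80.0
    delay_scale: float = 8.0  # ms of activation delay per cm from the apex node

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if min(self.depol_rise, self.plateau_duration, self.repol_duration) < 0:
            raise ValueError("durations must be non-negative")
        if self.T_total < self.depol_time + self.plateau_duration + self.repol_duration:
            raise ValueError("T_total too short for the waveform phases")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.T_total + 0.5 * self.dt, self.dt)


@dataclass
class MIScenario:
    """Infarction scenario applied to a circular patch of nodes.

    ``lesion_radius`` is the Euclidean spread from the center node (cm,
    default 1.5).  ``amplitude_factor`` multiplies the deviation from rest
    inside the patch for ``st_elevated`` (default 0.52 = 1 - 0.48);
    ``repol_shortening_factor`` rescales the repolarization duration for
    ``increased_t``.
    """

    type: str = "none"  # none | st_elevated | increased_t
    lesion_center_node: int = 0
    lesion_radius: float = 1.5
    amplitude_factor: float = 0.52
    repol_shortening_factor: float = 0.6

    def validate(self) -> None:
        if self.type not in ("none", "st_elevated", "increased_t"):
            raise ValueError(f"unknown scenario type {self.type!r}")
        if self.lesion_radius <= 0:
            raise ValueError("lesion_radius must be positive")
        if not 0 < self.amplitude_factor <= 1:
            raise ValueError("amplitude_factor must be in (0, 1]")
        if not 0 < self.repol_shortening_factor <= 1:
            raise ValueError("repol_shortening_factor must be in (0, 1]")


@dataclass
class SourceTimeSeries:
    """Q x T epicardial potentials (mV) with a uniform time axis (ms)."""

    values: np.ndarray
    times: np.ndarray
    mesh_label: str = ""
    scenario: MIScenario | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("source values must be finite")
        dts = np.diff(self.times)
        if len(dts) and (np.any(dts <= 0) or np.ptp(dts) > 1e-9 * dts[0]):
            raise ValueError("time axis must be strictly increasing and uniform")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def index_of_time(self, t_ms: float) -> int:
        idx = int(np.argmin(np.abs(self.times - t_ms)))
        if abs(self.times[idx] - t_ms) > 1e-6:
            raise ValueError(f"instant {t_ms} ms not on the time axis")
        return idx


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """C1 sigmoid ramp: exactly 0 for x <= 0 and 1 for x >= 1."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def template_waveform(
    params: WaveformParams,
    delay: float = 0.0,
    repol_duration: float | None = None,
) -> np.ndarray:
    """Single-node waveform sampled on ``params.times``, shifted by ``delay``.

    The value is exactly ``resting_level`` before ``depol_time + delay`` and
    after repolarization completes; phases are joined by smooth cubic ramps,
    so the series is bounded by [min, max] of resting and plateau levels.
    """
    params.validate()
    repol = params.repol_duration if repol_duration is None else repol_duration
    t = params.times - delay
    up_end = params.depol_time + params.depol_rise
    plateau_end = up_end + params.plateau_duration
    shape = np.where(
        t < up_end,
        _smoothstep((t - params.depol_time) / max(params.depol_rise, 1e-12)),
        1.0 - _smoothstep((t - plateau_end) / max(repol, 1e-12)),
    )
    return params.resting_level + (params.plateau_amplitude - params.resting_level) * shape


def lesion_patch(mesh: TriMesh, center_node: int, radius: float) -> np.ndarray:
    """Indices of nodes within Euclidean ``radius`` cm of the center node."""
    if not 0 <= center_node < mesh.n_nodes:
        raise ValueError(f"lesion center node {center_node} out of range")
    d = np.linalg.norm(
        mesh.node_positions - mesh.node_positions[center_node], axis=1
    )
    return np.flatnonzero(d <= radius)


def activation_delays(mesh: TriMesh, params: WaveformParams) -> np.ndarray:
    """Per-node activation delay: delay_scale x distance from the apex node.

    The apex is the node of lowest z, a crude stand-in for an activation
    origin; delay_scale = 0 disables the activation spread entirely.
    """
    if params.delay_scale == 0.0:
        return np.zeros(mesh.n_nodes)
    apex = int(np.argmin(mesh.node_positions[:, 2]))
    d = np.linalg.norm(mesh.node_positions - mesh.node_positions[apex], axis=1)
    return params.delay_scale * d


def simulate_sources(
    mesh: TriMesh,
    params: WaveformParams,
    scenario: MIScenario | None = None,
    seed: int | None = None,
) -> SourceTimeSeries:
    """Per-node epicardial potentials under the given scenario.

    Nodes outside the lesion patch are bit-identical to the normal case;
    ``st_elevated`` scales each patch node's deviation from rest by
    ``amplitude_factor``, ``increased_t`` shortens its repolarization.
    ``seed`` is unused unless delay jitter is requested (reserved hook).
    """
    scenario = scenario or MIScenario()
    params.validate()
    scenario.validate()
    delays = activation_delays(mesh, params)
    values = np.stack([template_waveform(params, d) for d in delays])
    if scenario.type != "none":
        patch = lesion_patch(mesh, scenario.lesion_center_node, scenario.lesion_radius)
        if len(patch) == 1:
            warnings.warn(
                "lesion radius captures only the center node; applying to it alone"
            )
        for q in patch:
            if scenario.type == "st_elevated":
                dev = values[q] - params.resting_level
                values[q] = params.resting_level + scenario.amplitude_factor * dev
            else:  # increased_t
                values[q] = template_waveform(
                    params,
                    delays[q],
                    repol_duration=params.repol_duration
                    * scenario.repol_shortening_factor,
                )
    return SourceTimeSeries(values, params.times, mesh.label, scenario)
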