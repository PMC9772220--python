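"""Biot-Savart forward model and SNR-controlled noise injection.

The lead field maps a unit current-dipole source at heart node q, oriented
along the outward normal ``a_q``, to the magnetic field at detector m:

    L(m, q, :) = (mu0 / 4 pi) * [(r_m - r'_q) / ||r_m - r'_q||^3] x a_q

with the cross-product operand order written exactly as above (the negative
of the textbook dipole form ``a x r / r^3``; the sign is a convention and
cancels in every inverse computation).  Geometry is in cm and sources in mV;
``unit_scale`` is the single explicit constant converting the mV * cm^-2
products to picotesla at the detectors.

For inversion, the M x Q x 3 tensor is flattened component-major to a
(3M) x Q design matrix: all x-component rows, then y, then z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SensorArray, TriMesh
from .source_sim import SourceTimeSeries

__all__ = [
    "LeadField",
    "FieldTimeSeries",
    "NoiseRecord",
    "MU0_OVER_4PI",
    "DEFAULT_UNIT_SCALE",
    "compute_lead_field",
    "forward_field",
    "add_noise",
    "measured_snr",
]

MU0_OVER_4PI = 1e-7  # magnetostatic constant, symbolic SI value
#: maps mV sources at cm-scale distances to pT-scale fields, so that a few-mV
#: epicardial distribution at ~10-20 cm yields fields of tens of pT
DEFAULT_UNIT_SCALE = 1e9


@dataclass
class LeadField:
    """M x Q x 3 spatial sensitivity tensor (pT per mV unit source)."""

    tensor: np.ndarray
    source_label: str = ""
    sensor_label: str = ""
    mu0_over_4pi: float = MU0_OVER_4PI
    unit_scale: float = DEFAULT_UNIT_SCALE

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3 or self.tensor.shape[2] != 3:
            raise ValueError("lead field tensor must be M x Q x 3")
        if not np.all(np.isfinite(self.tensor)):
            raise ValueError("lead field entries must be finite")

    @property
    def n_sensors(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_sources(self) -> int:
        return self.tensor.shape[1]

    def design_matrix(self, component: str = "all") -> np.ndarray:
        """Flatten to a real design matrix for inversion.

        ``component='all'`` stacks the three Cartesian components
        component-major into a (3M) x Q matrix; ``'x'/'y'/'z'`` restricts to
        a single scalar channel per detector (M x Q), as used for map-style
        exports.
        """
        if component == "all":
            return np.concatenate(
                [self.tensor[:, :, k] for k in range(3)], axis=0
            )
        k = {"x": 0, "y": 1, "z": 2}[component]
        return self.tensor[:, :, k]

    @staticmethod
    def unflatten(matrix: np.ndarray, n_sensors: int) -> np.ndarray:
        """Inverse of ``design_matrix('all')``: (3M) x Q -> M x Q x 3."""
        if matrix.shape[0] != 3 * n_sensors:
            raise ValueError("row count is not 3 x n_sensors")
        return np.stack(
            [matrix[k * n_sensors : (k + 1) * n_sensors] for k in range(3)],
            axis=2,
        )


@dataclass
class FieldTimeSeries:
    """M x T x 3 magnetic field samples (pT) on the detector array."""

    values: np.ndarray
    times: np.ndarray
    sensor_label: str = ""
    provenance: str = "clean"  # clean | noisy
    snr_db: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("field values must be M x T x 3")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")
        if self.values.shape[1] != len(self.times):
            raise ValueError("time axis length mismatch")

    @property
    def n_sensors(self) -> int:
        return self.values.shape[0]

    def stacked(self) -> np.ndarray:
        """Component-major (3M) x T measurement matrix (matches design_matrix)."""
        return np.concatenate([self.values[:, :, k] for k in range(3)], axis=0)

    @staticmethod
    def from_stacked(
        b: np.ndarray, times: np.ndarray, **kwargs
    ) -> "FieldTimeSeries":
        m = b.shape[0] // 3
        values = np.stack([b[k * m : (k + 1) * m] for k in range(3)], axis=2)
        return FieldTimeSeries(values, times, **kwargs)


@dataclass
class NoiseRecord:
    """Provenance of one additive-noise realization."""

    requested_snr_db: float
    realized_snr_db: float
    seed: int
    noise_amplitude: float  # P_n: std-dev of the added Gaussian noise
    noise: np.ndarray


def compute_lead_field(
    mesh: TriMesh,
    sensors: SensorArray,
    unit_scale: float = DEFAULT_UNIT_SCALE,
) -> LeadField:
    """Biot-Savart lead-field tensor between mesh nodes and detectors."""
    r = sensors.positions[:, None, :] - mesh.node_positions[None, :, :]  # M,Q,3
    dist = np.linalg.norm(r, axis=2)
    if dist.min() <= 1e-6:
        m, q = np.unravel_index(np.argmin(dist), dist.shape)
        raise ValueError(
            f"sensor {m} coincides with source node {q} "
            f"(distance {dist[m, q]:.2e} cm): lead field is singular"
        )
    tensor = (
        MU0_OVER_4PI
        * unit_scale
        * np.cross(r / dist[:, :, None] ** 3, mesh.node_normals[None, :, :])
    )
    return LeadField(
        tensor,
        source_label=mesh.label,
        sensor_label=sensors.label,
        unit_scale=unit_scale,
    )


def forward_field(L: LeadField, s: SourceTimeSeries) -> FieldTimeSeries:
    """Linear forward map B_f = L s (exact linearity in the sources)."""
    if L.n_sources != s.n_nodes:
        raise ValueError(
            f"lead field has {L.n_sources} sources but series has {s.n_nodes} nodes"
        )
    values = np.einsum("mqc,qt->mtc", L.tensor, s.values)
    return FieldTimeSeries(values, s.times, sensor_label=L.sensor_label)


def signal_power(values: np.ndarray) -> float:
    """Mean squared value over all channels, components and samples."""
    return float(np.mean(np.square(values)))


def measured_snr(clean: np.ndarray, noise: np.ndarray) -> float:
    """SNR (dB) = 10 log10(P_s / P_n) with powers as mean squared values."""
    clean = np.asarray(clean, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if clean.shape != noise.shape:
        raise ValueError("clean signal and noise shapes differ")
    p_n = signal_power(noise)
    if p_n == 0.0:
        return np.inf
    return 10.0 * np.log10(signal_power(clean) / p_n)


def add_noise(
    B: FieldTimeSeries, snr_db: float, seed: int
) -> tuple[FieldTimeSeries, NoiseRecord]:
    """Additive i.i.d. Gaussian noise calibrated to a requested SNR.

    The noise amplitude P_n = sqrt(P_s / 10^(SNR/10)) is the standard
    deviation multiplying standard-normal samples of the field's shape, so
    the realized SNR matches the request in expectation.
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite (use the clean field directly)")
    p_s = signal_power(B.values)
    if p_s == 0.0:
        raise ValueError("all-zero field: SNR is undefined")
    p_n = float(np.sqrt(p_s / 10.0 ** (snr_db / 10.0)))
    rng = np.random.default_rng(seed)
    noise = p_n * rng.standard_normal(B.values.shape)
    noisy = FieldTimeSeries(
        B.values + noise,
        B.times,
        sensor_label=B.sensor_label,
        provenance="noisy",
        snr_db=snr_db,
        seed=seed,
    )
    record = NoiseRecord(snr_db, measured_snr(B.values, noise), seed, p_n, noise)
    return noisy, record
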