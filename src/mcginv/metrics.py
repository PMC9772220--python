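"""Reconstruction quality metrics: spatial/temporal RMSE and correlation.

Spatial RMSE compares true and estimated potentials across nodes at one
instant; temporal RMSE compares them across time at one node.  When truth
and estimate live on different meshes, the truth is transported onto the
estimate's nodes through a nearest-node correspondence before comparison
("the same spatial points").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import NodeMap
from .source_sim import SourceTimeSeries

__all__ = ["EvalReport", "srmse", "trmse", "pearson_cc", "transport", "evaluate"]


@dataclass
class EvalReport:
    """Evaluation of one reconstruction against the (transported) truth."""

    srmse_per_instant: dict[float, float]  # instant (ms) -> mV
    trmse_per_node: np.ndarray  # mV, one per estimate-mesh node
    cc_temporal: float  # Pearson CC of the time courses at the focus node
    cc_spatial: dict[float, float]  # instant (ms) -> Pearson CC across nodes
    focus_node: int
    solver: str = ""
    snr_db: float | None = None
    seed: int | None = None


def srmse(s_true: np.ndarray, s_est: np.ndarray) -> float:
    """Spatial RMSE sqrt(sum_q (s_q - s_hat_q)^2 / Q) in mV."""
    s_true = np.asarray(s_true, dtype=float)
    s_est = np.asarray(s_est, dtype=float)
    if s_true.shape != s_est.shape:
        raise ValueError("length mismatch between true and estimated potentials")
    return float(np.sqrt(np.mean((s_true - s_est) ** 2)))


def trmse(s_true: np.ndarray, s_est: np.ndarray) -> float:
    """Temporal RMSE sqrt(sum_t (s_t - s_hat_t)^2 / T) in mV."""
    return srmse(s_true, s_est)


def pearson_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; NaN sentinel for constant input.

    A constant series has no defined correlation; the NaN is reported as
    missing downstream, never silently coerced to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D with equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def transport(truth: SourceTimeSeries, node_map: NodeMap) -> np.ndarray:
    """Truth values re-indexed onto the estimate mesh via the node map.

    ``node_map`` maps estimate-mesh nodes (source side) to truth-mesh nodes
    (target side); row j of the result is the truth series at the node
    nearest to estimate node j.
    """
    if node_map.indices.max() >= truth.n_nodes:
        raise ValueError("node map indexes beyond the truth mesh")
    return truth.values[node_map.indices]


def evaluate(
    truth: SourceTimeSeries,
    estimate: SourceTimeSeries,
    node_map: NodeMap,
    instants: list[float],
    focus_node: int,
    solver: str = "",
    snr_db: float | None = None,
    seed: int | None = None,
) -> EvalReport:
    """Full evaluation of an estimate against transported truth.

    ``node_map`` carries one truth-mesh index per estimate-mesh node;
    ``focus_node`` indexes the *estimate* mesh (e.g. the node nearest the
    lesion center) and anchors the temporal CC.
    """
    if len(node_map.indices) != estimate.n_nodes:
        raise ValueError("node map is inconsistent with the estimate mesh")
    if not 0 <= focus_node < estimate.n_nodes:
        raise ValueError("focus_node out of range for the estimate mesh")
    true_on_est = transport(truth, node_map)
    s_inst: dict[float, float] = {}
    cc_inst: dict[float, float] = {}
    for t_ms in instants:
        idx = estimate.index_of_time(t_ms)
        s_inst[t_ms] = srmse(true_on_est[:, idx], estimate.values[:, idx])
        cc_inst[t_ms] = pearson_cc(true_on_est[:, idx], estimate.values[:, idx])
    t_per_node = np.sqrt(np.mean((true_on_est - estimate.values) ** 2, axis=1))
    cc_t = pearson_cc(true_on_est[focus_node], estimate.values[focus_node])
    return EvalReport(
        s_inst, t_per_node, cc_t, cc_inst, focus_node, solver, snr_db, seed
    )
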