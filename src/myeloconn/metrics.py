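"""Node centralities and hub detection.

Two centralities are compared across weightings:

* NOS strength  ``S_i = sum_j w_ij`` — row sums of the streamline-count matrix.
* Scalar-weighted average  ``S_i = sum_j w_ij v_ij / sum_j w_ij`` — the
  NOS-weighted mean of the incident scalar (R1) edge values, deliberately
  insensitive to how many connections a node has.

Hubs are nodes whose metric is at least ``k`` sample standard deviations above
the mean (k = 2, or 3 for the conservative definition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import WeightedConnectome

logger = logging.getLogger(__name__)

__all__ = ["NodeMetricVector", "nos_strength", "weighted_average", "detect_hubs"]


@dataclass
class NodeMetricVector:
    """Per-node metric values; NaN marks nodes where the metric is undefined."""

    nodes: np.ndarray
    values: np.ndarray
    metric_kind: str

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.nodes) != len(self.values):
            raise ValueError("nodes and values length mismatch")

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def nos_strength(connectome: WeightedConnectome) -> NodeMetricVector:
    """Streamline-count strength: row sums of the NOS matrix."""
    if connectome.kind != "nos":
        raise ValueError("nos_strength expects a NOS-weighted connectome")
    return NodeMetricVector(connectome.nodes, connectome.weights.sum(axis=1),
                            metric_kind="nos_strength")


def weighted_average(nos: WeightedConnectome,
                     scalar: WeightedConnectome) -> NodeMetricVector:
    """NOS-weighted average of incident scalar edge values.

    Undefined (NaN) for isolated nodes; invariant to global rescaling of the
    NOS weights and bounded by the incident scalar min/max.
    """
    if not np.array_equal(nos.nodes, scalar.nodes):
        raise ValueError("connectomes must share the same node list")
    if not np.array_equal(nos.support(), scalar.support()):
        raise ValueError("NOS and scalar connectomes must share support")
    den = nos.weights.sum(axis=1)
    num = (nos.weights * scalar.weights).sum(axis=1)
    values = np.full(len(den), np.nan)
    connected = den > 0
    values[connected] = num[connected] / den[connected]
    if np.any(~connected):
        logger.warning("%d isolated node(s): weighted average undefined",
                       int((~connected).sum()))
    return NodeMetricVector(nos.nodes, values, metric_kind="weighted_average")


def detect_hubs(metric: NodeMetricVector, k_sd: float = 2.0) -> np.ndarray:
    """Nodes with value >= mean + k_sd * SD (sample SD, n-1 denominator).

    A constant metric (SD = 0) yields no hubs rather than declaring all nodes
    hubs. Undefined nodes are ignored.
    """
    vals = metric.values[metric.defined()]
    if len(vals) < 2:
        raise ValueError("need at least 2 defined values")
    sd = vals.std(ddof=1)
    if sd == 0:
        return np.asarray([], dtype=metric.nodes.dtype)
    threshold = vals.mean() + k_sd * sd
    keep = metric.defined() & (metric.values >= threshold)
    return metric.nodes[keep]
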