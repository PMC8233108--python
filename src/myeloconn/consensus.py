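"""Group-consensus connectomes and edge-weight agreement between weightings.

An edge enters the group network when it is present (nonzero) in at least
``ceil(prevalence * n_subjects)`` subjects; its consensus weight is the median
of its weights over the subjects in which it is present (zeros excluded, so a
consensus weight can never undercut every observed weight).  Shared variance
between two weightings is summarised by ordinary least squares over the edges
nonzero in both.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import Cohort, WeightedConnectome

__all__ = [
    "consensus_mask",
    "consensus_weights",
    "edge_regression",
    "EdgeRegressionResult",
]


def consensus_mask(cohort: Cohort, prevalence: float = 0.5) -> np.ndarray:
    """Boolean edge mask: kept iff present in >= ceil(prevalence * n) subjects."""
    if not (0 < prevalence <= 1):
        raise ValueError("prevalence must lie in (0, 1]")
    stack = cohort.nos_stack()
    threshold = math.ceil(prevalence * len(cohort))
    counts = (stack != 0).sum(axis=0)
    mask = counts >= threshold
    np.fill_diagonal(mask, False)
    return mask


def _presence_median(stack: np.ndarray, mask: np.ndarray,
                     exclude_zeros: bool) -> np.ndarray:
    n = stack.shape[1]
    out = np.zeros((n, n))
    if exclude_zeros:
        data = np.where(stack != 0, stack, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-absent edges
            med = np.nanmedian(data, axis=0)
        med = np.nan_to_num(med)
    else:
        med = np.median(stack, axis=0)
    out[mask] = med[mask]
    return out


def consensus_weights(cohort: Cohort, mask: np.ndarray,
                      exclude_zeros: bool = True):
    """Median-across-subjects consensus (NOS, scalar) connectome pair.

    ``exclude_zeros`` (default) takes the median only over subjects in which
    the edge is present; set False for a plain median including absences.
    """
    nos_w = _presence_median(cohort.nos_stack(), mask, exclude_zeros)
    sca_w = _presence_median(cohort.scalar_stack(), mask, exclude_zeros)
    prov = dict(prevalence_mask_edges=int(mask.sum() // 2),
                exclude_zeros=exclude_zeros, n_subjects=len(cohort),
                median_across_subjects=True)
    nos = WeightedConnectome(cohort.nodes, nos_w, kind="nos",
                             provenance=dict(prov))
    sca = WeightedConnectome(cohort.nodes, sca_w, kind="scalar",
                             provenance=dict(prov))
    return nos, sca


@dataclass
class EdgeRegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_edges: int


def edge_regression(a: WeightedConnectome,
                    b: WeightedConnectome) -> EdgeRegressionResult:
    """OLS of a's edge weights on b's over common-support upper-triangle edges."""
    if not np.array_equal(a.nodes, b.nodes):
        raise ValueError("connectomes must share the same node list")
    iu = np.triu_indices(a.n_nodes, k=1)
    ya, xb = a.weights[iu], b.weights[iu]
    common = (ya != 0) & (xb != 0)
    if common.sum() < 3:
        raise ValueError("need at least 3 common edges for regression")
    x, y = xb[common], ya[common]
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: predictor weights have zero variance")
    if np.ptp(y) == 0:
        # constant response: nothing to explain
        return EdgeRegressionResult(slope=0.0, intercept=float(y[0]),
                                    r_squared=0.0, p_value=1.0,
                                    n_edges=int(common.sum()))
    fit = stats.linregress(x, y)
    return EdgeRegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2), p_value=float(fit.pvalue),
        n_edges=int(common.sum()),
    )
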