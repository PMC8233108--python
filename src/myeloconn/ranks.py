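"""Rank-difference comparison of the two weightings across node classes.

Nodes are ranked within each connectome (rank 1 = highest value, ties get
average ranks).  The per-node difference ``d_i = rank_scalar_i - rank_nos_i``
is z-scored across nodes and summarised per functional and per
cytoarchitectonic class by its median.

Sign convention: because rank 1 is the *highest*, a class whose scalar
(R1-weighted) centrality outranks its streamline-count centrality has
negative ``d`` (its scalar ranks are numerically smaller).  ``flip_sign=True``
negates z for plotting conventions that draw "overrepresented" upward.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .metrics import NodeMetricVector
from .modularity import Partition

logger = logging.getLogger(__name__)

__all__ = [
    "rank_nodes",
    "rank_difference_z",
    "class_median_z",
    "module_class_composition",
]


def rank_nodes(metric: NodeMetricVector) -> np.ndarray:
    """Descending ranks (1 = largest value); ties take the average rank."""
    values = np.asarray(getattr(metric, "values", metric), dtype=float)
    if np.any(np.isnan(values)):
        raise ValueError("undefined metric values present: exclude isolated "
                         "nodes before ranking")
    return rankdata(-values, method="average")


def rank_difference_z(rank_scalar: np.ndarray, rank_nos: np.ndarray):
    """Per-node rank difference and its z-score.

    Returns ``(d, z)`` with ``d = rank_scalar - rank_nos`` and
    ``z = (d - mean(d)) / sd(d)`` (sample SD).  An all-zero difference vector
    (identical orderings) yields an all-zero z.
    """
    rank_scalar = np.asarray(rank_scalar, dtype=float)
    rank_nos = np.asarray(rank_nos, dtype=float)
    if rank_scalar.shape != rank_nos.shape:
        raise ValueError("rank vectors must cover the same nodes")
    if len(rank_scalar) < 2:
        raise ValueError("need at least 2 nodes")
    d = rank_scalar - rank_nos
    sd = d.std(ddof=1)
    if sd == 0:
        return d, np.zeros_like(d)
    return d, (d - d.mean()) / sd


def class_median_z(z: np.ndarray, classes: pd.DataFrame, scheme: str,
                   flip_sign: bool = False) -> pd.Series:
    """Median z per node class under the given scheme.

    ``classes`` is a DataFrame with ``functional`` and ``cytoarchitectonic``
    columns, row-aligned with ``z``.
    """
    if scheme not in ("functional", "cytoarchitectonic"):
        raise ValueError(f"unknown scheme {scheme!r}")
    z = np.asarray(z, dtype=float)
    if len(z) != len(classes):
        raise ValueError("z and class table must cover the same nodes")
    if flip_sign:
        z = -z
    labels = classes[scheme].to_numpy()
    out = (pd.Series(z, index=labels).groupby(level=0).median()
           .rename(f"median_z_{scheme}"))
    missing = set(pd.unique(classes[scheme])) - set(out.index)
    if missing:
        logger.warning("empty classes omitted: %s", sorted(missing))
    return out


def module_class_composition(partition: Partition, classes: pd.DataFrame,
                             scheme: str) -> pd.DataFrame:
    """Module-by-class contingency table of node counts.

    Row sums equal module sizes; the grand total equals the node count.
    """
    if scheme not in ("functional", "cytoarchitectonic"):
        raise ValueError(f"unknown scheme {scheme!r}")
    assignment = np.asarray(getattr(partition, "assignment", partition), int)
    if len(assignment) != len(classes):
        raise ValueError("partition and class table must cover the same nodes")
    table = pd.crosstab(pd.Series(assignment, name="module"),
                        pd.Series(classes[scheme].to_numpy(), name=scheme))
    return table
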