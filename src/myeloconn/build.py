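"""Build one subject's NOS- and scalar-median-weighted connectomes from a
tractogram, a parcellation and a scalar map.

The scalar weight of an edge is the median over the *pooled* samples of every
streamline in the bundle ("one median per bundle"); the even-count median is
the midpoint of the two central order statistics.  Pairs supported by fewer
than ``min_streamlines`` streamlines are zeroed in BOTH matrices, so the NOS
and scalar connectomes always share their support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import LabelVolume, ScalarVolume, Tractogram, WeightedConnectome
from .tracts import assign_endpoints, filter_by_length, sample_scalar

logger = logging.getLogger(__name__)

__all__ = ["EdgeBundle", "build_connectome"]


@dataclass
class EdgeBundle:
    """All streamlines connecting one region pair, with pooled scalar samples."""

    pair: tuple
    streamline_ids: list = field(default_factory=list)
    pooled_samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        i, j = self.pair
        if i == j:
            raise ValueError("bundle endpoints must differ")
        self.pair = (min(i, j), max(i, j))


def build_connectome(
    tractogram: Tractogram,
    labels: LabelVolume,
    scalar: ScalarVolume,
    min_streamlines: int = 2,
    length_bounds: tuple = (20.0, 250.0),
    radius_mm: float = 2.0,
    mode: str = "trilinear",
    pooling: str = "pooled",
):
    """Return ``(nos_connectome, scalar_connectome)`` for one subject.

    Parameters
    ----------
    min_streamlines
        Edges with fewer streamlines are removed from both outputs (default 2;
        5 is the conservative robustness setting).
    length_bounds
        Inclusive keep-range in mm applied before assignment.
    radius_mm, mode
        Endpoint-assignment search radius and scalar sampling mode.
    pooling
        ``"pooled"`` (default): one median over all samples of the bundle.
        ``"per_streamline"``: median of per-streamline medians, kept for
        sensitivity analysis.
    """
    if min_streamlines < 1:
        raise ValueError("min_streamlines must be >= 1")
    if pooling not in ("pooled", "per_streamline"):
        raise ValueError(f"unknown pooling {pooling!r}")

    kept = filter_by_length(tractogram, *length_bounds)
    bundles: dict = {}
    for sid, s in enumerate(kept.streamlines):
        pair = assign_endpoints(s, labels, radius_mm=radius_mm)
        if pair is None:
            continue
        key = (min(pair), max(pair))
        bundle = bundles.setdefault(key, EdgeBundle(key))
        bundle.streamline_ids.append(sid)
        samples = sample_scalar(s, scalar, mode=mode)
        if len(samples):
            bundle.pooled_samples.append(np.asarray(samples, dtype=float))

    nodes = np.asarray(labels.labels)
    index = {lab: k for k, lab in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    v = np.zeros((n, n))
    for (a, b), bundle in bundles.items():
        count = len(bundle.streamline_ids)
        if count < min_streamlines:
            continue
        if not bundle.pooled_samples:
            logger.warning("bundle (%s, %s): no scalar samples; dropped", a, b)
            continue
        if pooling == "pooled":
            med = float(np.median(np.concatenate(bundle.pooled_samples)))
        else:
            med = float(np.median([np.median(s) for s in bundle.pooled_samples]))
        ia, ib = index[a], index[b]
        w[ia, ib] = w[ib, ia] = count
        v[ia, ib] = v[ib, ia] = med

    if not np.any(w):
        logger.warning("no assignable streamlines: connectomes are empty")

    prov = dict(min_streamlines=min_streamlines, length_bounds=tuple(length_bounds),
                radius_mm=radius_mm, mode=mode, pooling=pooling,
                n_streamlines_in=len(tractogram), n_streamlines_kept=len(kept))
    nos = WeightedConnectome(nodes, w, kind="nos", provenance=dict(prov))
    sca = WeightedConnectome(nodes, v, kind="scalar", provenance=dict(prov))
    return nos, sca
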