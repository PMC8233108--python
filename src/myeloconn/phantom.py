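"""Synthetic phantom cohorts with known planted structure.

The generator stands in for an MRI cohort: it produces per-subject pairs of
streamline-count (NOS) and scalar (R1-like, 1/s) connectomes whose modular
organisation, class-dependent scalar gradient and inter-subject variability
are all planted and therefore recoverable as ground truth.

Model
-----
* A population *template* decides once, per region pair, whether an edge
  exists (Bernoulli, with different probabilities for within- vs
  between-module pairs under the planted partition).  Each subject then keeps
  each template edge independently with probability ``subject_edge_keep`` —
  so the 50%-prevalence group-consensus rule has both kept and rejected edges
  to work with.
* Streamline counts on existing edges are Poisson(lambda) truncated to >= 1,
  with different rates within vs between modules.
* Scalar edge values are ``scalar_base + mean(class offsets of the two
  endpoints) + subject offset + edge noise``, clipped to the physiological
  envelope (0, 3) 1/s.  Class offsets act through the *functional* class of
  each node, planting a transmodal > unimodal scalar gradient that the
  rank-based analysis should recover.
* Geometry mode additionally lays the regions out as compact blocks on a 3-D
  lattice, paints each bundle's planted scalar value along a straight
  (slightly jittered) 1-mm-step corridor, and emits polyline streamlines
  whose endpoints sit inside their intended regions.

Defaults emulate the study conditions this package targets: 35 subjects,
scalar base 1.1 1/s, +0.05 1/s on transmodal functional classes, and a
4-module planted partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Cohort, LabelVolume, ScalarVolume, Tractogram, WeightedConnectome

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "default_class_map",
    "generate_cohort_matrices",
    "generate_phantom_geometry",
    "FUNCTIONAL_CLASSES",
    "CYTOARCHITECTONIC_CLASSES",
    "TRANSMODAL_FUNCTIONAL",
]

#: Yeo-style functional classes (7 canonical resting-state networks).
FUNCTIONAL_CLASSES = ("VIS", "SM", "DA", "VA", "LIM", "FP", "DMN")
#: von Economo-style cytoarchitectonic classes.
CYTOARCHITECTONIC_CLASSES = (
    "primary_motor", "association_1", "association_2",
    "secondary_sensory", "primary_sensory", "limbic", "insular",
)
#: Higher-order (integrative) functional classes; VIS and SM are unimodal.
TRANSMODAL_FUNCTIONAL = frozenset({"DA", "VA", "LIM", "FP", "DMN"})

_SCALAR_LO, _SCALAR_HI = 1e-3, 3.0 - 1e-3


def default_class_map(n_regions: int) -> pd.DataFrame:
    """Cyclic node-class assignment, orthogonal to contiguous module blocks.

    Functional classes cycle with period 7 and cytoarchitectonic classes with
    period 49, so neither aligns with the planted modules.
    """
    nodes = np.arange(1, n_regions + 1)
    fun = [FUNCTIONAL_CLASSES[i % 7] for i in range(n_regions)]
    cyt = [CYTOARCHITECTONIC_CLASSES[(i // 7) % 7] for i in range(n_regions)]
    return pd.DataFrame(
        {"functional": fun, "cytoarchitectonic": cyt}, index=pd.Index(nodes, name="node")
    )


def _default_scalar_effect() -> dict:
    return {c: (0.05 if c in TRANSMODAL_FUNCTIONAL else 0.0)
            for c in FUNCTIONAL_CLASSES}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic cohort; see module docstring for the model."""

    n_regions: int = 60
    n_subjects: int = 35
    planted_partition: np.ndarray = None  # module labels, contiguous from 1
    lambda_within: float = 20.0
    lambda_between: float = 2.0
    edge_prob_within: float = 0.9
    edge_prob_between: float = 0.1
    subject_edge_keep: float = 0.8
    scalar_base: float = 1.1            # 1/s
    scalar_class_effect: dict = field(default_factory=_default_scalar_effect)
    scalar_noise_sd: float = 0.05       # 1/s, per edge per subject
    subject_noise_sd: float = 0.02      # relative global scalar shift per subject
    class_map: pd.DataFrame = None
    n_modules: int = 4                  # used only to build a default partition
    grid_shape: tuple = (64, 64, 64)    # geometry mode
    voxel_size: float = 2.0             # mm, isotropic (geometry mode)
    region_extent: int = 3              # voxels per region block side
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_partition is None:
            if self.n_regions % self.n_modules:
                raise ValueError("n_regions must divide evenly into n_modules "
                                 "when no explicit partition is given")
            size = self.n_regions // self.n_modules
            self.planted_partition = np.repeat(
                np.arange(1, self.n_modules + 1), size)
        self.planted_partition = np.asarray(self.planted_partition, dtype=int)
        if self.class_map is None:
            self.class_map = default_class_map(self.n_regions)
        self.validate()

    def validate(self) -> None:
        if self.n_regions < 2 or self.n_subjects < 1:
            raise ValueError("need >= 2 regions and >= 1 subject")
        if len(self.planted_partition) != self.n_regions:
            raise ValueError("planted_partition length != n_regions")
        labs = np.unique(self.planted_partition)
        if labs[0] != 1 or not np.array_equal(labs, np.arange(1, len(labs) + 1)):
            raise ValueError("planted module labels must be contiguous from 1")
        if not (self.lambda_within > self.lambda_between >= 0):
            raise ValueError("require lambda_within > lambda_between >= 0")
        for p in (self.edge_prob_within, self.edge_prob_between,
                  self.subject_edge_keep):
            if not (0 <= p <= 1):
                raise ValueError("edge probabilities must lie in [0, 1]")
        if self.scalar_noise_sd < 0 or self.subject_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if len(self.class_map) != self.n_regions:
            raise ValueError("class_map must cover every node")
        for col in ("functional", "cytoarchitectonic"):
            if col not in self.class_map.columns:
                raise ValueError(f"class_map missing column {col!r}")

    @property
    def nodes(self) -> np.ndarray:
        return np.arange(1, self.n_regions + 1)

    def node_scalar_offsets(self) -> np.ndarray:
        """Per-node additive scalar offset from its functional class."""
        return np.array([
            self.scalar_class_effect.get(c, 0.0)
            for c in self.class_map["functional"].to_numpy()
        ])


def _truncated_poisson(rng: np.random.Generator, lam: np.ndarray) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1; a zero rate degenerates to count 1."""
    lam = np.asarray(lam, dtype=float)
    out = rng.poisson(lam)
    zero = out == 0
    while np.any(zero):
        out[zero] = np.where(lam[zero] <= 0, 1, rng.poisson(lam[zero]))
        zero = out == 0
    return out


def _pair_structure(spec: PhantomSpec):
    """Upper-triangle pair indices with per-pair rates and probabilities."""
    iu, ju = np.triu_indices(spec.n_regions, k=1)
    within = spec.planted_partition[iu] == spec.planted_partition[ju]
    lam = np.where(within, spec.lambda_within, spec.lambda_between)
    prob = np.where(within, spec.edge_prob_within, spec.edge_prob_between)
    return iu, ju, lam, prob


def _planted_pair_values(spec: PhantomSpec, iu, ju) -> np.ndarray:
    offs = spec.node_scalar_offsets()
    return spec.scalar_base + 0.5 * (offs[iu] + offs[ju])


def _square(n: int, iu, ju, vals: np.ndarray) -> np.ndarray:
    m = np.zeros((n, n), dtype=float)
    m[iu, ju] = vals
    m[ju, iu] = vals
    return m


def generate_cohort_matrices(spec: PhantomSpec, seed: int | None = None) -> Cohort:
    """Generate a multi-subject cohort of (NOS, scalar) connectome pairs.

    Bit-identical output for identical ``(spec, seed)``.  ``seed`` overrides
    ``spec.seed`` when given.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_regions
    iu, ju, lam, prob = _pair_structure(spec)
    planted = _planted_pair_values(spec, iu, ju)

    template = rng.random(len(iu)) < prob
    subjects = []
    for _ in range(spec.n_subjects):
        keep = template & (rng.random(len(iu)) < spec.subject_edge_keep)
        counts = np.zeros(len(iu))
        if np.any(keep):
            counts[keep] = _truncated_poisson(rng, lam[keep])
        subj_shift = rng.normal(0.0, spec.subject_noise_sd) * spec.scalar_base
        noise = rng.normal(0.0, spec.scalar_noise_sd, size=len(iu))
        scal = np.where(
            keep,
            np.clip(planted + subj_shift + noise, _SCALAR_LO, _SCALAR_HI),
            0.0,
        )
        nos = WeightedConnectome(spec.nodes, _square(n, iu, ju, counts),
                                 kind="nos")
        sca = WeightedConnectome(spec.nodes, _square(n, iu, ju, scal),
                                 kind="scalar")
        subjects.append((nos, sca))
    return Cohort(subjects)


# ---------------------------------------------------------------------------
# geometry mode


def _region_centres(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Voxel-index centres of region blocks on a jittered coarse 3-D lattice.

    Lattice spacing is chosen so that any two block centres stay far enough
    apart for every streamline to exceed the 20 mm minimum length.  Centres
    are perturbed off-lattice (+-3 voxels per axis) so that no three regions
    are colinear: colinear triples would let one bundle's corridor run almost
    on top of another's, corrupting the planted scalar values.
    """
    shape = np.asarray(spec.grid_shape)
    per_axis = int(np.ceil(spec.n_regions ** (1 / 3)))
    perturb = 3
    # keep blocks (with their perturbation and bowed corridors) off the faces
    margin = spec.region_extent + 4 + perturb
    usable = shape - 2 * margin
    if np.any(usable < per_axis):
        raise ValueError("regions cannot fit in grid")
    axes = [np.linspace(margin, s - 1 - margin, per_axis) for s in shape]
    min_gap = min((ax[1] - ax[0]) if len(ax) > 1 else np.inf for ax in axes)
    min_dist_mm = (min_gap - 2 * perturb) * spec.voxel_size
    # endpoints are jittered by well under half a block from the centres
    if min_dist_mm < 20 + spec.region_extent * spec.voxel_size:
        raise ValueError(
            "grid too small: adjacent regions would allow streamlines "
            "shorter than the 20 mm bound")
    centres = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    centres = centres[: spec.n_regions]
    centres = centres + rng.integers(-perturb, perturb + 1,
                                     size=centres.shape)
    return np.rint(centres).astype(int)


def generate_phantom_geometry(spec: PhantomSpec, seed: int | None = None):
    """Generate (label volume, scalar volume, tractogram) phantom geometry.

    The scalar volume equals ``scalar_base`` everywhere except along bundle
    corridors, where it carries the bundle's planted value; Gaussian noise of
    SD ``scalar_noise_sd`` is added on top.  Streamlines are straight lines
    with sub-voxel jitter, sampled at 1 mm steps, endpoints strictly inside
    their region blocks, lengths within [20, 250] mm by construction.

    Returns ``(labels, scalar, tractogram, truth)`` where ``truth`` is a
    DataFrame of per-bundle planted values and streamline counts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    affine = np.diag([spec.voxel_size] * 3 + [1.0])

    centres = _region_centres(spec, rng)
    half = spec.region_extent // 2
    labels_grid = np.zeros(shape, dtype=np.int32)
    for lab, c in enumerate(centres, start=1):
        sl = tuple(slice(int(v) - half, int(v) + half + 1) for v in c)
        labels_grid[sl] = lab
    labels = LabelVolume(labels_grid, affine)

    scalar_grid = np.full(shape, spec.scalar_base, dtype=float)

    iu, ju, lam, prob = _pair_structure(spec)
    planted = _planted_pair_values(spec, iu, ju)
    template = rng.random(len(iu)) < prob
    counts = np.zeros(len(iu), dtype=int)
    counts[template] = _truncated_poisson(rng, lam[template])

    centres_mm = centres * spec.voxel_size
    jitter_mm = 0.45 * half * spec.voxel_size  # endpoints stay inside blocks
    streamlines, bundle_of = [], []
    records = []
    for p in np.flatnonzero(template):
        i, j = int(iu[p]), int(ju[p])
        # bundle-specific lateral bow so corridors between colinear regions
        # do not coincide (otherwise one bundle would overpaint another)
        chord = centres_mm[j] - centres_mm[i]
        perp = np.cross(chord, rng.normal(size=3))
        norm = np.linalg.norm(perp)
        while norm < 1e-9:
            perp = np.cross(chord, rng.normal(size=3))
            norm = np.linalg.norm(perp)
        bow = (perp / norm) * 6.0  # mm at mid-path
        for _ in range(counts[p]):
            a = centres_mm[i] + rng.uniform(-jitter_mm, jitter_mm, 3)
            b = centres_mm[j] + rng.uniform(-jitter_mm, jitter_mm, 3)
            dist = np.linalg.norm(b - a)
            n_pts = max(int(np.ceil(dist)) + 1, 2)
            t = np.linspace(0.0, 1.0, n_pts)[:, None]
            line = a + t * (b - a) + np.sin(np.pi * t) * bow
            # sub-voxel wobble on top; endpoints pinned inside their blocks
            wob = rng.normal(0.0, 0.25, size=line.shape)
            wob[0] = wob[-1] = 0.0
            line = line + wob
            streamlines.append(line)
            bundle_of.append(p)
        records.append({"i": i + 1, "j": j + 1, "n_streamlines": int(counts[p]),
                        "planted_value": planted[p]})

    # paint corridors: each vertex's nearest voxel takes the bundle value.
    # Where corridors overlap (near shared endpoint regions, at crossings)
    # only one bundle can own a voxel.  Ownership starts first-painted-wins,
    # then a repair pass re-claims voxels for any bundle left without a
    # strict majority of its own samples — the strict majority is what makes
    # the pooled *median* along every bundle exactly its planted value.
    inv_vox = 1.0 / spec.voxel_size
    flat_shape = int(np.prod(shape))
    owner = np.full(flat_shape, -1, dtype=int)
    bundle_voxels: dict = {}
    for sl, p in zip(streamlines, bundle_of):
        idx = np.rint(sl * inv_vox).astype(int)
        idx = np.clip(idx, 0, np.asarray(shape) - 1)
        flat = np.ravel_multi_index(tuple(idx.T), shape)
        bundle_voxels.setdefault(p, []).append(flat)
        free = owner[flat] == -1
        owner[flat[free]] = p
    bundle_voxels = {p: np.concatenate(v) for p, v in bundle_voxels.items()}

    def _own_fraction(p):
        return float(np.mean(owner[bundle_voxels[p]] == p))

    for _ in range(10):  # resolve contested overlaps
        failing = sorted((p for p in bundle_voxels if _own_fraction(p) <= 0.55),
                         key=_own_fraction)
        if not failing:
            break
        for p in failing:
            owner[bundle_voxels[p]] = p
    else:
        weakest = min(bundle_voxels, key=_own_fraction)
        logger.warning("corridor overlap unresolved for bundle pair (%d, %d)",
                       int(iu[weakest]) + 1, int(ju[weakest]) + 1)

    painted = owner >= 0
    scalar_grid.ravel()[painted] = planted[owner[painted]]

    if spec.scalar_noise_sd > 0:
        scalar_grid = scalar_grid + rng.normal(0.0, spec.scalar_noise_sd, shape)
    scalar = ScalarVolume(np.clip(scalar_grid, _SCALAR_LO, _SCALAR_HI)
                          if spec.scalar_noise_sd > 0 else scalar_grid, affine)

    tract = Tractogram(streamlines)
    for s in tract.streamlines:
        length = np.sum(np.linalg.norm(np.diff(s, axis=0), axis=1))
        if not (20.0 <= length <= 250.0):
            raise RuntimeError(f"generated streamline length {length:.1f} mm "
                               "outside [20, 250]")
    truth = pd.DataFrame.from_records(records)
    logger.info("phantom geometry: %d regions, %d bundles, %d streamlines",
                spec.n_regions, len(records), len(streamlines))
    return labels, scalar, tract, truth
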