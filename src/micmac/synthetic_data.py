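"""Ground-truthed synthetic fixtures for every pipeline stage.

Four generators emulate the data the pipeline was built for, at desk scale:

* :func:`sample_tree` — random branching trees in µm coordinates standing in
  for ramified Iba1-stained microglia; the planted simplified graph
  (junctions, endpoints, branch lengths) is the oracle for skeleton-graph
  recovery.
* :func:`render_scene` — rasterizes trees as tubes into a 3D stack with PSF
  blur, uneven illumination and Gaussian noise, keeping the pre-corruption
  label volume as ground truth.
* :func:`make_pathology_stack` — high-contrast blobs planted to a known
  volume fraction, the oracle for the volumetric load score.
* :func:`simulate_cohort` — hierarchical (case + cell) sampling of feature
  vectors and per-case marker loads with planted group shifts and
  load–feature couplings, the oracle for the statistics layer.

Every generator takes one explicit seed and is bit-reproducible. Cells are
placed without contact: merged-cell accumulations are deliberately not
modelled (the pipeline discards them in real data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi

from .morphograph import FEATURE_NAMES
from .stack_io import ImageStack

__all__ = [
    "CellSpec",
    "SceneSpec",
    "PlantedTree",
    "GroundTruth",
    "CohortEffects",
    "sample_tree",
    "render_scene",
    "make_pathology_stack",
    "simulate_cohort",
    "sample_archetypes",
]

SUBFIELDS = ("CA1", "CA3", "DG/CA4")
MARKERS = ("pTau", "Abeta", "pSyn")


@dataclass(frozen=True)
class CellSpec:
    """Stochastic grammar of one branched cell.

    Branches grow as straight segments; at each segment end the process
    bifurcates with ``branch_probability`` (until ``max_depth``), otherwise
    terminates. Defaults give mid-complexity ramified morphologies whose
    skeletons are unambiguous at a 1 µm voxel pitch.
    """

    n_primary_branches: int = 3
    branch_probability: float = 0.4
    segment_length_mean: float = 14.0  # µm
    segment_length_sd: float = 2.0
    radius: float = 3.0  # µm tube radius
    max_depth: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0.0 <= self.branch_probability <= 1.0):
            raise ValueError("branch_probability must be in [0, 1]")


@dataclass(frozen=True)
class SceneSpec:
    """Layout and corruption model of one rendered stack."""

    shape: tuple[int, int, int] = (64, 192, 192)  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # µm
    n_cells: int = 5
    min_separation: float = 8.0  # µm gap between tube surfaces
    noise_sd: float = 0.05
    background_gradient: float = 0.1  # amplitude of the illumination ramp
    psf_sigma: float = 1.0  # voxels, isotropic blur
    foreground: float = 0.8
    seed: int = 0


@dataclass
class PlantedTree:
    """A sampled tree and its simplified branch-graph ground truth."""

    segments: list[tuple[np.ndarray, np.ndarray]]  # (start, end) µm
    n_nodes: int
    n_edges: int
    n_endpoints: int
    edge_lengths: list[float]

    @property
    def points(self) -> np.ndarray:
        pts = [s for s, _ in self.segments] + [e for _, e in self.segments]
        return np.asarray(pts)

    @property
    def total_length(self) -> float:
        return float(sum(np.linalg.norm(e - s) for s, e in self.segments))


@dataclass
class GroundTruth:
    """Planted truth of a rendered scene."""

    labels: np.ndarray  # int volume, 0 background
    trees: list[PlantedTree]
    volumes: list[float]  # µm³ of each rasterized mask
    voxel_size: tuple[float, float, float]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * np.dot(axis, v) * (1 - np.cos(angle))
    )


def _child_directions(direction: np.ndarray, rng: np.random.Generator) -> list[np.ndarray]:
    """Two bifurcation directions at ±~40° from the parent, well separated."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, direction)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp = _unit(np.cross(direction, ref))
    spin = rng.uniform(0, 2 * np.pi)
    perp = _unit(_rotate_about(perp, direction, spin))
    angle = np.deg2rad(rng.uniform(35.0, 50.0))
    return [
        _unit(_rotate_about(direction, perp, angle)),
        _unit(_rotate_about(direction, perp, -angle)),
    ]


def sample_tree(spec: CellSpec, rng: np.random.Generator | None = None) -> PlantedTree:
    """Sample one random branching tree; reproducible under ``spec.seed``.

    The planted graph counts are those of the *simplified* tree (degree-2
    pass-through nodes contracted), matching what skeleton-graph recovery
    should return.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    g = nx.Graph()
    origin = np.zeros(3)
    g.add_node(0, coord=origin)
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    next_id = 1

    n_primary = max(spec.n_primary_branches, 1)
    # primary directions spread on the sphere with jitter, biased laterally
    # so shallow stacks still contain the cell
    dirs = []
    for i in range(n_primary):
        phi = 2 * np.pi * (i + rng.uniform(-0.15, 0.15)) / n_primary
        theta = np.deg2rad(rng.uniform(60.0, 120.0))
        dirs.append(
            np.array(
                [np.cos(theta), np.sin(theta) * np.sin(phi), np.sin(theta) * np.cos(phi)]
            )
        )

    # compress growth in z: thick-section acquisitions are laterally extended
    flatten = np.array([0.5, 1.0, 1.0])

    # distinct branches closer than a tube diameter would merge when
    # rasterized and falsify the planted topology; reject such segments
    clearance = 2.0 * spec.radius + 6.0
    # (start node, end node, sampled µm points) per placed segment
    seg_points: list[tuple[int, int, np.ndarray]] = []

    def _collides(start_node: int, start: np.ndarray, end: np.ndarray) -> bool:
        n = max(int(np.linalg.norm(end - start)), 2)
        ts = np.linspace(0.0, 1.0, n)[:, None]
        pts = start * (1 - ts) + end * ts
        for s_node, e_node, other_pts in seg_points:
            if start_node in (s_node, e_node):
                continue  # parent and sibling segments legitimately meet here
            d = np.linalg.norm(pts[:, None, :] - other_pts[None, :, :], axis=2)
            if d.min() < clearance:
                return True
        return False

    frontier = [(0, origin, _unit(d * flatten), 0) for d in dirs]
    while frontier:
        parent, pos, direction, depth = frontier.pop()
        direction = _unit(direction * flatten)
        placed = False
        base_direction = direction
        # segments never shrink below ~0.8x the mean: very short terminal
        # branches disappear inside the parent tube once rasterized
        min_length = max(6.0, 0.8 * spec.segment_length_mean)
        for _ in range(8):
            length = max(rng.normal(spec.segment_length_mean, spec.segment_length_sd), min_length)
            end = pos + length * direction
            if not _collides(parent, pos, end):
                placed = True
                break
            # resample a jittered direction, rejecting fold-backs that would
            # bring the tube onto its own parent branch
            jitter = rng.normal(0.0, 0.35, size=3)
            cand = _unit(_unit(direction + jitter) * flatten)
            if np.dot(cand, base_direction) >= np.cos(np.deg2rad(60.0)):
                direction = cand
        if not placed:
            continue  # drop this branch; simplification absorbs the dead end
        node = next_id
        next_id += 1
        g.add_node(node, coord=end)
        g.add_edge(parent, node, length=float(length))
        segments.append((pos.copy(), end.copy()))
        n = max(int(length), 2)
        ts = np.linspace(0.0, 1.0, n)[:, None]
        seg_points.append((parent, node, pos * (1 - ts) + end * ts))
        if depth < spec.max_depth and rng.random() < spec.branch_probability:
            for child_dir in _child_directions(direction, rng):
                frontier.append((node, end, child_dir, depth + 1))

    simplified = _simplify_tree(g)
    degrees = dict(simplified.degree())
    return PlantedTree(
        segments=segments,
        n_nodes=simplified.number_of_nodes(),
        n_edges=simplified.number_of_edges(),
        n_endpoints=sum(1 for d in degrees.values() if d == 1),
        edge_lengths=[d["length"] for _, _, d in simplified.edges(data=True)],
    )


def _simplify_tree(g: nx.Graph) -> nx.Graph:
    """Contract degree-2 chains, summing edge lengths."""
    simplified = g.copy()
    changed = True
    while changed:
        changed = False
        for node in list(simplified.nodes):
            if simplified.degree(node) == 2:
                (u, _, d1), (v, _, d2) = [
                    (nbr, node, simplified.edges[node, nbr]) for nbr in simplified.neighbors(node)
                ]
                if u == v:
                    continue
                simplified.remove_node(node)
                simplified.add_edge(u, v, length=d1["length"] + d2["length"])
                changed = True
    return simplified


def _tree_radius(tree: PlantedTree) -> float:
    pts = tree.points
    return float(np.linalg.norm(pts, axis=1).max())


def _rasterize_tube(
    tree: PlantedTree,
    center_um: np.ndarray,
    shape,
    voxel_size,
    radius: float,
) -> np.ndarray:
    """Binary tube mask: voxels within ``radius`` µm of the tree polyline."""
    vs = np.asarray(voxel_size)
    seed = np.zeros(shape, dtype=bool)
    step = 0.4 * float(vs.min())
    for start, end in tree.segments:
        seg_len = float(np.linalg.norm(end - start))
        n = max(int(np.ceil(seg_len / step)) + 1, 2)
        ts = np.linspace(0.0, 1.0, n)[:, None]
        pts = (center_um + start) * (1 - ts) + (center_um + end) * ts
        idx = np.round(pts / vs).astype(int)
        valid = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
        seed[tuple(idx[valid].T)] = True
    if not seed.any():
        return seed
    dist = ndi.distance_transform_edt(~seed, sampling=tuple(vs))
    return dist <= radius


def render_scene(
    scene: SceneSpec, cell_specs: list[CellSpec] | None = None, max_retries: int = 500
) -> tuple[ImageStack, GroundTruth]:
    """Rasterize separated tube cells into a noisy, unevenly lit stack.

    Ground-truth labels are stored pre-corruption. Raises ``RuntimeError``
    when the cells cannot be placed with the required separation.
    """
    rng = np.random.default_rng(scene.seed)
    if cell_specs is None:
        cell_specs = [
            CellSpec(seed=int(rng.integers(0, 2**31 - 1))) for _ in range(scene.n_cells)
        ]
    if len(cell_specs) != scene.n_cells:
        raise ValueError("need one CellSpec per cell")
    trees = [sample_tree(spec, np.random.default_rng(spec.seed)) for spec in cell_specs]
    extent_um = np.asarray(scene.shape) * np.asarray(scene.voxel_size)

    labels = np.zeros(scene.shape, dtype=np.int32)
    voxel_volume = float(np.prod(scene.voxel_size))
    forbidden = np.zeros(scene.shape, dtype=bool)
    # place the most extended trees first: packing succeeds far more often
    extents = [float((t.points.max(0) - t.points.min(0)).max()) for t in trees]
    order = sorted(range(len(trees)), key=lambda i: -extents[i])
    masks: dict[int, np.ndarray] = {}
    for i in order:
        lab, tree, spec = i + 1, trees[i], cell_specs[i]
        pts = tree.points
        pad = spec.radius + 1.0
        lo = -(pts.min(axis=0)) + pad  # admissible center range per axis
        hi = extent_um - pts.max(axis=0) - pad
        if np.any(hi <= lo):
            extent = (pts.max(axis=0) - pts.min(axis=0)).max()
            raise RuntimeError(f"cell {lab} (extent {extent:.1f} µm) does not fit the stack")
        for _ in range(max_retries):
            center = rng.uniform(lo, hi)
            mask = _rasterize_tube(tree, center, scene.shape, scene.voxel_size, spec.radius)
            if mask.any() and not (mask & forbidden).any():
                break
        else:
            raise RuntimeError(f"failed to place cell {lab} with required separation")
        labels[mask] = lab
        masks[i] = mask
        dist = ndi.distance_transform_edt(labels == 0, sampling=tuple(scene.voxel_size))
        forbidden = dist <= scene.min_separation
    volumes = [
        float(np.count_nonzero(masks[i])) * voxel_volume for i in range(len(trees))
    ]

    img = np.where(labels > 0, scene.foreground, 0.0)
    if scene.psf_sigma > 0:
        img = ndi.gaussian_filter(img, scene.psf_sigma, mode="nearest")
    if scene.background_gradient > 0:
        ramp_y = np.linspace(0.0, 1.0, scene.shape[1])[None, :, None]
        ramp_x = np.linspace(0.0, 1.0, scene.shape[2])[None, None, :]
        img = img + scene.background_gradient * 0.5 * (ramp_y + ramp_x)
    if scene.noise_sd > 0:
        img = img + rng.normal(0.0, scene.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    stack = ImageStack(voxels=img, voxel_size=scene.voxel_size, channel="Iba1")
    truth = GroundTruth(
        labels=labels, trees=trees, volumes=volumes, voxel_size=scene.voxel_size
    )
    return stack, truth


def make_pathology_stack(
    target_fraction: float,
    shape: tuple[int, int, int] = (32, 128, 128),
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    blob_radius_mean: float = 4.0,
    blob_radius_sd: float = 1.0,
    seed: int = 0,
    tolerance: float = 0.002,
    max_attempts: int = 20000,
) -> tuple[ImageStack, float]:
    """Plant high-contrast blobs to a known positive-volume fraction.

    Blobs are added until the positive fraction is within ``tolerance``
    (0.2 percentage points) of ``target_fraction``; the exact achieved
    fraction is returned as the stored truth. Raises ``RuntimeError`` when
    the fraction is unreachable with the given blob sizes.
    """
    if not (0.0 < target_fraction < 1.0):
        raise ValueError("target_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=bool)
    total = mask.size
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    vs = np.asarray(voxel_size)

    attempts = 0
    while True:
        fraction = np.count_nonzero(mask) / total
        if fraction >= target_fraction - tolerance:
            break
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("could not reach target fraction with given blob sizes")
        radius = float(np.clip(rng.normal(blob_radius_mean, blob_radius_sd), 1.5, None))
        center = rng.uniform([0, 0, 0], np.asarray(shape) - 1)
        for r in (radius, radius / 1.5, radius / 2.5, 1.5):
            d2 = (
                ((zz - center[0]) * vs[0]) ** 2
                + ((yy - center[1]) * vs[1]) ** 2
                + ((xx - center[2]) * vs[2]) ** 2
            )
            blob = d2 <= r**2
            new = np.count_nonzero(blob & ~mask)
            if (np.count_nonzero(mask) + new) / total <= target_fraction + tolerance:
                mask |= blob
                break

    true_fraction = np.count_nonzero(mask) / total
    img = np.where(mask, 0.9, 0.05) + rng.normal(0.0, 0.02, size=shape)
    img = np.clip(img, 0.0, 1.0)
    stack = ImageStack(voxels=img, voxel_size=tuple(float(v) for v in voxel_size))
    return stack, float(true_fraction)


@dataclass
class CohortEffects:
    """Planted effects of a simulated cohort.

    ``feature_shifts`` maps a condition (or ``(condition, subfield)``) to
    per-feature standardized mean shifts relative to the control baseline.
    ``load_coupling`` maps a marker to per-feature coefficients linking the
    case-level feature deviation to that case's load. ``case_sd`` is the
    case-level random effect, ``cell_sd`` the within-case cell noise, both
    in standardized feature units.
    """

    feature_shifts: dict = field(default_factory=dict)
    load_coupling: dict = field(default_factory=dict)
    case_sd: float = 0.3
    cell_sd: float = 1.0
    load_base: float = 10.0
    load_sd: float = 1.0

    def shift_for(self, condition: str, subfield: str) -> dict:
        if (condition, subfield) in self.feature_shifts:
            return self.feature_shifts[(condition, subfield)]
        return self.feature_shifts.get(condition, {})


def simulate_cohort(
    effects: CohortEffects,
    n_cases: dict[str, int] | None = None,
    cells_per_case: int = 50,
    subfields: tuple[str, ...] = SUBFIELDS,
    markers: tuple[str, ...] = MARKERS,
    feature_names: list[str] | None = None,
    seed: int = 0,
):
    """Hierarchical simulation of a cell table and a per-case load table.

    Per case × subfield × feature: a case-level random effect around the
    planted condition shift; cells add independent noise. Marker loads are
    the base plus the coupled case-level feature deviations plus noise,
    clipped to [0, 100]. Returns ``(cells, loads)`` DataFrames shaped like
    the real pipeline outputs.

    Default group sizes mirror the analyzed cohort: 11 CTL, 10 AD, 8 DLB.
    """
    if n_cases is None:
        n_cases = {"CTL": 11, "AD": 10, "DLB": 8}
    if feature_names is None:
        feature_names = list(FEATURE_NAMES)
    if not isinstance(effects, CohortEffects):
        raise TypeError("effects must be a CohortEffects instance")
    rng = np.random.default_rng(seed)
    nf = len(feature_names)
    cell_rows = []
    load_rows = []
    case_counter = 0
    for condition, n in n_cases.items():
        for _ in range(n):
            case_counter += 1
            case_id = f"sim{case_counter:03d}"
            for subfield in subfields:
                shift = effects.shift_for(condition, subfield)
                mu = np.array([shift.get(f, 0.0) for f in feature_names])
                case_eff = mu + rng.normal(0.0, effects.case_sd, size=nf)
                cells = case_eff + rng.normal(0.0, effects.cell_sd, size=(cells_per_case, nf))
                for row in cells:
                    cell_rows.append(
                        {"case_id": case_id, "condition": condition, "subfield": subfield}
                        | dict(zip(feature_names, row))
                    )
                for marker in markers:
                    coupling = effects.load_coupling.get(marker, {})
                    coef = np.array([coupling.get(f, 0.0) for f in feature_names])
                    load = (
                        effects.load_base
                        + float(coef @ case_eff)
                        + rng.normal(0.0, effects.load_sd)
                    )
                    load_rows.append(
                        {
                            "case_id": case_id,
                            "condition": condition,
                            "subfield": subfield,
                            "marker": marker,
                            "percent": float(np.clip(load, 0.0, 100.0)),
                        }
                    )
    import pandas as pd

    return pd.DataFrame(cell_rows), pd.DataFrame(load_rows)


def sample_archetypes(
    n_archetypes: int = 7,
    cells_per_archetype: int = 100,
    n_features: int = 16,
    separation: float = 6.0,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Well-separated morphology archetypes in feature space.

    Archetype centres are drawn on a hypersphere of radius ``separation``
    (rejecting close pairs); cells scatter isotropically around them. The
    oracle for cluster-recovery checks. Returns ``(X, labels)``.
    """
    rng = np.random.default_rng(seed)
    centers = []
    while len(centers) < n_archetypes:
        cand = rng.normal(size=n_features)
        cand = separation * cand / np.linalg.norm(cand)
        if all(np.linalg.norm(cand - c) > separation for c in centers):
            centers.append(cand)
    X = np.vstack(
        [c + rng.normal(0.0, noise_sd, size=(cells_per_archetype, n_features)) for c in centers]
    )
    labels = np.repeat(np.arange(1, n_archetypes + 1), cells_per_archetype)
    return X, labels
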