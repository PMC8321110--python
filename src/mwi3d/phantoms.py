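"""Randomized three-tissue breast phantoms and their prior backgrounds.

A phantom is a voxel label map with an outer ellipsoidal fat layer, an
interior fibroglandular region, and one or two tumors grown at random
inside the fibroglandular tissue.  Tissue labels map to the complex
relative permittivities of the standard table (air 1-0.001j, fat 3-0.6j,
fibroglandular 20-21.6j, tumor 56.3-30j), with the e^{+j omega t} sign
convention eps = eps' - j eps''.  The permittivity of each tissue is
treated as frequency independent.

The prior background used by the inversion is the same phantom with the
tumors relabeled as fibroglandular tissue, optionally with a fractional
error applied to the fibroglandular permittivity (imperfect prior).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grids import VoxelGrid

__all__ = [
    "AIR",
    "FAT",
    "FIBRO",
    "TUMOR",
    "TissueTable",
    "TissueMap",
    "PhantomSpec",
    "PermittivityVolume",
    "make_breast_geometry",
    "grow_tumor",
    "sample_phantom",
    "assign_permittivity",
    "make_prior_background",
    "generate_dataset",
]

AIR, FAT, FIBRO, TUMOR = 0, 1, 2, 3
_LABEL_NAMES = {AIR: "air", FAT: "fat", FIBRO: "fibroglandular", TUMOR: "tumor"}


@dataclass(frozen=True)
class TissueTable:
    """Complex relative permittivity per tissue, eps = eps' - j eps''."""

    air: complex = 1 - 0.001j
    fat: complex = 3 - 0.6j
    fibro: complex = 20 - 21.6j
    tumor: complex = 56.3 - 30j

    def __post_init__(self):
        for name in ("air", "fat", "fibro", "tumor"):
            v = complex(getattr(self, name))
            if not v.real > 0:
                raise ValueError(f"{name}: real permittivity must be > 0, got {v}")
            if v.imag > 0:
                raise ValueError(
                    f"{name}: imaginary part must be <= 0 under eps = eps' - j eps'', got {v}"
                )

    def lookup(self) -> dict:
        return {AIR: complex(self.air), FAT: complex(self.fat),
                FIBRO: complex(self.fibro), TUMOR: complex(self.tumor)}


@dataclass
class TissueMap:
    """Integer tissue-label volume on a voxel grid."""

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int8)
        if self.labels.shape != self.grid.shape:
            raise ValueError("label array shape does not match grid")
        bad = set(np.unique(self.labels)) - {AIR, FAT, FIBRO, TUMOR}
        if bad:
            raise ValueError(f"unknown tissue labels {sorted(bad)}")

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    def tumor_components(self) -> int:
        """Number of face-connected tumor components."""
        structure = ndimage.generate_binary_structure(self.grid.ndim, 1)
        _, n = ndimage.label(self.labels == TUMOR, structure=structure)
        return int(n)

    def interior_mask(self) -> np.ndarray:
        """Breast interior (everything that is not air)."""
        return self.labels != AIR

    def copy(self) -> "TissueMap":
        return TissueMap(self.grid, self.labels.copy())


@dataclass
class PermittivityVolume:
    """Complex relative permittivity per voxel.

    Ground-truth volumes respect the air floor Re(eps) >= 1; set
    ``check_floor=False`` for reconstructed volumes, whose artifacts may
    undershoot it.
    """

    grid: VoxelGrid
    values: np.ndarray
    check_floor: bool = True

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=np.complex128)
        if self.values.shape != self.grid.shape:
            raise ValueError("permittivity array shape does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("permittivity volume contains non-finite values")
        if self.check_floor and np.min(self.values.real) < 1 - 1e-9:
            raise ValueError("real permittivity below the air floor of 1")

    def copy(self) -> "PermittivityVolume":
        return PermittivityVolume(self.grid, self.values.copy())


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and sampling parameters for one random phantom.

    Default dimensions follow the physical three-region phantom: fat and
    fibroglandular diameters of 10 cm and 8 cm, as axis-aligned
    ellipsoids centered in the grid.  Tumor maximum diameters are drawn
    uniformly from ``diameter_range_cm`` (default 1.1-1.5 cm).
    ``fibro_height_delta`` shrinks the vertical extent of the
    fibroglandular region by that many meters (geometry-robustness
    variant).
    """

    grid: VoxelGrid = field(default_factory=VoxelGrid)
    fat_semiaxes: tuple = None  # type: ignore[assignment]
    fibro_semiaxes: tuple = None  # type: ignore[assignment]
    fat_center: tuple = None  # type: ignore[assignment]
    fibro_center: tuple = None  # type: ignore[assignment]
    n_tumors: int = 1
    diameter_range_cm: tuple = (1.1, 1.5)
    fibro_height_delta: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        d = self.grid.ndim
        if self.fat_semiaxes is None:
            object.__setattr__(self, "fat_semiaxes", (0.05,) * d)
        if self.fibro_semiaxes is None:
            object.__setattr__(self, "fibro_semiaxes", (0.04,) * d)
        if self.fat_center is None:
            object.__setattr__(self, "fat_center", (0.0,) * d)
        if self.fibro_center is None:
            object.__setattr__(self, "fibro_center", (0.0,) * d)
        for name in ("fat_semiaxes", "fibro_semiaxes", "fat_center", "fibro_center"):
            v = tuple(float(x) for x in getattr(self, name))
            if len(v) != d:
                raise ValueError(f"{name} must have {d} components")
            object.__setattr__(self, name, v)
        if self.n_tumors not in (0, 1, 2):
            raise ValueError("n_tumors must be 0, 1 or 2")
        lo, hi = self.diameter_range_cm
        if not (0 < lo <= hi):
            raise ValueError("diameter_range_cm must satisfy 0 < min <= max")
        if self.fibro_height_delta < 0:
            raise ValueError("fibro_height_delta must be >= 0")


def _ellipsoid_mask(grid: VoxelGrid, center, semiaxes) -> np.ndarray:
    if any(a <= 0 for a in semiaxes):
        raise ValueError(f"degenerate ellipsoid semi-axes {tuple(semiaxes)}")
    coords = grid.coords()
    q = np.zeros(grid.shape)
    for d in range(grid.ndim):
        q += ((coords[..., d] - center[d]) / semiaxes[d]) ** 2
    return q <= 1.0


def make_breast_geometry(spec: PhantomSpec) -> TissueMap:
    """Tumor-free breast: air background, fat ellipsoid, fibro interior.

    The fibroglandular vertical semi-axis (last grid axis) is reduced by
    ``fibro_height_delta / 2`` so the region's height shrinks by the full
    delta.  Raises if the geometry leaves the grid or the fibro region
    would be empty or poke out of the fat.
    """
    grid = spec.grid
    for c, a, ext, o in zip(spec.fat_center, spec.fat_semiaxes,
                            grid.extent, grid.origin):
        if c - a < o - grid.spacing / 2 or c + a > o + ext - grid.spacing / 2:
            raise ValueError("fat region exceeds grid bounds")
    fibro_axes = list(spec.fibro_semiaxes)
    fibro_axes[-1] -= spec.fibro_height_delta / 2.0
    if fibro_axes[-1] <= 0:
        raise ValueError("fibro_height_delta removes the fibroglandular region")
    fat = _ellipsoid_mask(grid, spec.fat_center, spec.fat_semiaxes)
    fibro = _ellipsoid_mask(grid, spec.fibro_center, fibro_axes)
    if np.any(fibro & ~fat):
        raise ValueError("fibroglandular region is not strictly inside the fat")
    if not np.any(fibro):
        raise ValueError("fibroglandular region is empty on this grid")
    labels = np.full(grid.shape, AIR, dtype=np.int8)
    labels[fat] = FAT
    labels[fibro] = FIBRO
    return TissueMap(grid, labels)


def _component_diameter(points: np.ndarray, spacing: float) -> float:
    """Physical diameter: max pairwise center distance plus one voxel.

    The extra spacing accounts for the voxels' own extent, so a single
    voxel has diameter ``spacing`` rather than zero.
    """
    if len(points) < 2:
        return float(spacing)
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max()) * spacing + spacing


def grow_tumor(tissue: TissueMap, rng: np.random.Generator,
               d_max: float, forbidden: np.ndarray | None = None) -> TissueMap:
    """Grow one tumor by random accretion inside the fibroglandular region.

    Starting from a uniformly random fibroglandular voxel, a uniformly
    random face-connected fibroglandular neighbor of the current
    component is converted to tumor on each step, until the component's
    physical diameter (max pairwise voxel-center distance plus one voxel
    extent) reaches ``d_max`` (meters) or no candidates remain.  Voxels
    in ``forbidden`` (and their faces) are never used, which keeps a
    second tumor disjoint from the first.
    """
    if d_max <= 0:
        raise ValueError("d_max must be > 0")
    grid = tissue.grid
    labels = tissue.labels.copy()
    allowed = labels == FIBRO
    if forbidden is not None:
        structure = ndimage.generate_binary_structure(grid.ndim, 1)
        allowed &= ~ndimage.binary_dilation(forbidden, structure=structure)
    seeds = np.argwhere(allowed)
    if len(seeds) == 0:
        raise ValueError("no fibroglandular voxels available to seed a tumor")
    start = seeds[rng.integers(len(seeds))]
    component = [tuple(start)]
    labels[tuple(start)] = TUMOR
    offsets = []
    for d in range(grid.ndim):
        for s in (-1, 1):
            off = [0] * grid.ndim
            off[d] = s
            offsets.append(tuple(off))
    while True:
        pts = np.asarray(component)
        if _component_diameter(pts, grid.spacing) >= d_max:
            break
        frontier = set()
        for p in component:
            for off in offsets:
                q = tuple(p[d] + off[d] for d in range(grid.ndim))
                if all(0 <= q[d] < grid.shape[d] for d in range(grid.ndim)) \
                        and allowed[q] and labels[q] == FIBRO:
                    frontier.add(q)
        if not frontier:
            break
        frontier = sorted(frontier)
        pick = frontier[rng.integers(len(frontier))]
        labels[pick] = TUMOR
        component.append(pick)
    return TissueMap(grid, labels)


def sample_phantom(spec: PhantomSpec) -> TissueMap:
    """Random phantom with ``spec.n_tumors`` tumors (0, 1 or 2).

    Each tumor gets an independently sampled maximum-diameter threshold
    from ``diameter_range_cm``.  Deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    tissue = make_breast_geometry(spec)
    lo, hi = (d * 1e-2 for d in spec.diameter_range_cm)
    first_tumor = None
    for i in range(spec.n_tumors):
        d_max = rng.uniform(lo, hi)
        tissue = grow_tumor(tissue, rng, d_max, forbidden=first_tumor)
        if i == 0 and spec.n_tumors > 1:
            first_tumor = tissue.labels == TUMOR
    return tissue


def assign_permittivity(tissue: TissueMap, table: TissueTable | None = None) -> PermittivityVolume:
    """Per-voxel tissue-to-permittivity lookup (frequency independent)."""
    table = table or TissueTable()
    lut = np.zeros(4, dtype=np.complex128)
    for label, value in table.lookup().items():
        lut[label] = value
    return PermittivityVolume(tissue.grid, lut[tissue.labels])


def make_prior_background(tissue: TissueMap, table: TissueTable | None = None,
                          fibro_error_frac: float = 0.0) -> PermittivityVolume:
    """Inhomogeneous background eps_n for the inversion.

    Tumor voxels are relabeled fibroglandular (the prior does not know
    about tumors) and the fibroglandular permittivity is scaled by
    ``1 + fibro_error_frac`` to emulate imperfect prior knowledge.
    """
    if not 0 <= fibro_error_frac < 1:
        raise ValueError("fibro_error_frac must be in [0, 1)")
    table = table or TissueTable()
    bg_table = TissueTable(
        air=table.air,
        fat=table.fat,
        fibro=complex(table.fibro) * (1 + fibro_error_frac),
        tumor=complex(table.fibro) * (1 + fibro_error_frac),
    )
    return assign_permittivity(tissue, bg_table)


def generate_dataset(n: int, spec_template: PhantomSpec, seed: int,
                     table: TissueTable | None = None,
                     fibro_error_frac: float = 0.0,
                     n_tumors: int | None = None):
    """Generate ``n`` phantoms: ceil(n/2) one-tumor then floor(n/2) two-tumor.

    ``n_tumors`` overrides the half/half split with a fixed tumor count
    per phantom (0 for the tumor-free robustness scenario).  Returns
    ``(items, manifest)`` where each item is a dict with keys ``tissue``
    (TissueMap), ``eps`` (true PermittivityVolume) and ``background``
    (prior PermittivityVolume); the manifest records the child seed and
    tumor count per phantom so any run can be reproduced.
    """
    if n < 1:
        raise ValueError("dataset size must be >= 1")
    table = table or TissueTable()
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in np.random.SeedSequence(seed).spawn(n)]
    items, records = [], []
    for i in range(n):
        if n_tumors is None:
            k_tumors = 1 if i < (n + 1) // 2 else 2
        else:
            k_tumors = n_tumors
        spec = replace(spec_template, n_tumors=k_tumors, rng_seed=child_seeds[i])
        tissue = sample_phantom(spec)
        items.append({
            "tissue": tissue,
            "eps": assign_permittivity(tissue, table),
            "background": make_prior_background(tissue, table, fibro_error_frac),
        })
        records.append({"index": i, "seed": child_seeds[i], "n_tumors": k_tumors,
                        "tumor_voxels": tissue.count(TUMOR)})
    manifest = {"n": n, "seed": int(seed), "fibro_error_frac": fibro_error_frac,
                "phantoms": records}
    return items, manifest


def manifest_json(manifest: dict) -> str:
    return json.dumps(manifest, indent=2, sort_keys=True)
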