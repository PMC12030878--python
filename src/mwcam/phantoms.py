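"""Procedural anthropomorphic breast phantom database.

The database combines a small catalog of parametric solids: three fat+skin
shells, five glandular inclusions and five tumor shapes (labels A-E, sizes
0.5-2 cm).  Glandular cavity 5 is deliberately too large for the smallest
fat shell, so 3*5 - 1 = 14 tumor-free models exist; four tumor cases (none /
adipose / glandular / both) give 56 models, and mirroring plus 16 rotations
about the vertical axis give 1792 samples.  A distinct held-out phantom
(separate shell, gland and tumor never used in the training combinatorics,
with the tumor in the fatty region on the observation plane) provides the
32-sample test set.

Tissues are piecewise constant.  Dielectric properties are the 2.45 GHz
table values (fat 5/0.1, glandular 44/1.5, skin 42/1.6, tumor 53/1.8,
water 73/1.0) with an optional uniform +/-5% per-tissue jitter; water, the
known coupling medium used for calibration, is never jittered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .geometry import CameraGeometry

# ---------------------------------------------------------------------------
# Dielectrics
# ---------------------------------------------------------------------------

TISSUES = ("fat", "glandular", "skin", "tumor", "water")

#: Nominal (eps_r, sigma [S/m]) at 2.45 GHz.
NOMINAL_PROPERTIES: Dict[str, Tuple[float, float]] = {
    "fat": (5.0, 0.1),
    "glandular": (44.0, 1.5),
    "skin": (42.0, 1.6),
    "tumor": (53.0, 1.8),
    "water": (73.0, 1.0),
}

#: Integer voxel labels, in precedence order tumor > gland > fat > skin > water.
LABELS = {"water": 0, "skin": 1, "fat": 2, "glandular": 3, "tumor": 4}
LABEL_NAMES = {v: k for k, v in LABELS.items()}


@dataclass(frozen=True)
class TissueDielectrics:
    """Per-tissue (eps_r, sigma) table at a given frequency."""

    properties: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(NOMINAL_PROPERTIES)
    )
    frequency: float = 2.45e9

    def __post_init__(self) -> None:
        for tissue, (eps_r, sigma) in self.properties.items():
            if eps_r <= 1.0:
                raise ValueError(f"{tissue}: eps_r must exceed 1, got {eps_r}")
            if sigma < 0.0:
                raise ValueError(f"{tissue}: sigma must be >= 0, got {sigma}")

    def eps_r(self, tissue: str) -> float:
        return self.properties[tissue][0]

    def sigma(self, tissue: str) -> float:
        return self.properties[tissue][1]

    def complex_permittivity(self, tissue: str, geometry: CameraGeometry) -> complex:
        eps_r, sigma = self.properties[tissue]
        return geometry.complex_permittivity(eps_r, sigma)


def jitter_dielectrics(
    nominal: TissueDielectrics, seed: int, amplitude: float = 0.05
) -> TissueDielectrics:
    """Draw one uniform multiplicative jitter per tissue property.

    Each non-water tissue receives two independent Uniform(1-a, 1+a) factors
    (one for eps_r, one for sigma).  Water is the known coupling medium and
    is left untouched.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    jittered: Dict[str, Tuple[float, float]] = {}
    for tissue in TISSUES:
        eps_r, sigma = nominal.properties[tissue]
        if tissue == "water":
            jittered[tissue] = (eps_r, sigma)
            continue
        f_eps, f_sig = rng.uniform(1.0 - amplitude, 1.0 + amplitude, size=2)
        jittered[tissue] = (eps_r * f_eps, sigma * f_sig)
    return TissueDielectrics(properties=jittered, frequency=nominal.frequency)


# ---------------------------------------------------------------------------
# Parametric solids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Superellipsoid:
    """Implicit solid sum(|(p - c)/a|^e) <= 1; e = 2 is an ellipsoid."""

    center: Tuple[float, float, float]
    semiaxes: Tuple[float, float, float]
    exponent: float = 2.0

    def contains(self, pts: np.ndarray) -> np.ndarray:
        q = np.abs((pts - np.asarray(self.center)) / np.asarray(self.semiaxes))
        return (q ** self.exponent).sum(axis=-1) <= 1.0

    def shrunk(self, margin: float) -> "Superellipsoid":
        """Same solid with every semiaxis reduced by ``margin`` (m)."""
        return replace(self, semiaxes=tuple(a - margin for a in self.semiaxes))

    def surface_points(self, n: int = 24) -> np.ndarray:
        """Points on the boundary, for numeric containment checks."""
        th = np.linspace(0.0, np.pi, n)
        ph = np.linspace(0.0, 2.0 * np.pi, 2 * n, endpoint=False)
        th, ph = np.meshgrid(th, ph, indexing="ij")
        u = np.stack(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)], axis=-1
        ).reshape(-1, 3)
        # scale unit directions onto the superellipsoid surface
        q = (np.abs(u / np.asarray(self.semiaxes)) ** self.exponent).sum(axis=-1)
        r = q ** (-1.0 / self.exponent)
        return np.asarray(self.center) + u * r[:, None]


@dataclass(frozen=True)
class SolidUnion:
    """Union of solids (used for lobulated glands and tumors)."""

    parts: Tuple[Superellipsoid, ...]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        mask = self.parts[0].contains(pts)
        for part in self.parts[1:]:
            mask |= part.contains(pts)
        return mask

    def surface_points(self, n: int = 24) -> np.ndarray:
        return np.concatenate([p.surface_points(n) for p in self.parts], axis=0)


def fits_inside(inner, outer, n: int = 24) -> bool:
    """Numeric nesting test: every boundary point of ``inner`` lies in ``outer``."""
    return bool(outer.contains(inner.surface_points(n)).all())


# ---------------------------------------------------------------------------
# Cavity catalog (surrogate geometry; sizes in meters)
# ---------------------------------------------------------------------------

SKIN_THICKNESS = 0.002

#: Outer skin surfaces of the three fat+skin shells, smallest first.
FAT_SHELLS: Dict[int, Superellipsoid] = {
    1: Superellipsoid((0.0, 0.0, 0.0), (0.040, 0.035, 0.045), 2.0),
    2: Superellipsoid((0.0, 0.0, 0.0), (0.050, 0.040, 0.055), 2.5),
    3: Superellipsoid((0.0, 0.0, 0.0), (0.060, 0.045, 0.065), 2.0),
}

#: Glandular inclusions.  Number 5 does not fit inside shell 1.
GLANDS: Dict[int, object] = {
    1: Superellipsoid((-0.008, -0.005, 0.000), (0.018, 0.014, 0.020), 2.0),
    2: SolidUnion(
        (
            Superellipsoid((-0.010, -0.004, 0.008), (0.016, 0.012, 0.014), 2.0),
            Superellipsoid((-0.004, 0.004, -0.008), (0.014, 0.011, 0.013), 2.0),
        )
    ),
    3: Superellipsoid((-0.006, 0.002, 0.004), (0.022, 0.016, 0.024), 2.5),
    4: Superellipsoid((-0.010, -0.006, -0.006), (0.020, 0.015, 0.026), 2.0),
    5: Superellipsoid((-0.002, 0.000, 0.002), (0.037, 0.026, 0.040), 2.0),
}

#: Tumor shapes A-E; characteristic diameters 0.5 cm .. 2 cm (centered at origin,
#: translated at placement time).
TUMOR_SHAPES: Dict[str, object] = {
    "A": Superellipsoid((0.0, 0.0, 0.0), (0.0025, 0.0025, 0.0025), 2.0),  # 0.5 cm
    "B": Superellipsoid((0.0, 0.0, 0.0), (0.0050, 0.0040, 0.0040), 2.0),  # 1.0 cm
    "C": Superellipsoid((0.0, 0.0, 0.0), (0.0075, 0.0075, 0.0075), 2.0),  # 1.5 cm
    "D": Superellipsoid((0.0, 0.0, 0.0), (0.0100, 0.0060, 0.0050), 2.0),  # 2.0 cm
    "E": SolidUnion(  # lobulated, ~1.4 cm
        (
            Superellipsoid((-0.0030, 0.0, 0.0), (0.0040, 0.0040, 0.0040), 2.0),
            Superellipsoid((0.0030, 0.0, 0.0), (0.0040, 0.0040, 0.0040), 2.0),
        )
    ),
}

#: Tumor-shape assignment: each shape is associated with a cavity exactly once,
#: and no valid (fat, gland) combination yields the same shape twice in one
#: phantom (shell 1 pairs with gland 5 only in the excluded combination).
ADIPOSE_TUMOR_SHAPE: Dict[int, str] = {1: "A", 2: "B", 3: "C"}
GLAND_TUMOR_SHAPE: Dict[int, str] = {1: "D", 2: "E", 3: "D", 4: "E", 5: "A"}

#: Relative adipose-tumor position: fraction of the inner fat semiaxes, on the
#: +x side (glands sit on the -x side) in the observation plane.
ADIPOSE_TUMOR_REL = (0.55, 0.0, 0.10)

# Held-out test phantom: a distinct shell/gland/tumor surrogate of the
# reference physical phantom, with the tumor in the fatty region exactly on
# the observation plane y=0.
HELDOUT_SHELL = Superellipsoid((0.0, 0.0, 0.0), (0.055, 0.042, 0.050), 3.0)
HELDOUT_GLAND = SolidUnion(
    (
        Superellipsoid((-0.012, -0.002, 0.006), (0.020, 0.014, 0.018), 2.0),
        Superellipsoid((-0.006, 0.004, -0.010), (0.016, 0.012, 0.014), 2.0),
        Superellipsoid((-0.016, -0.008, -0.002), (0.012, 0.010, 0.012), 2.0),
    )
)
HELDOUT_TUMOR = Superellipsoid((0.022, 0.000, 0.004), (0.005, 0.005, 0.005), 2.0)


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

TUMOR_CASES = (1, 2, 3, 4)  # none / adipose / glandular / both


@dataclass(frozen=True)
class PhantomConfig:
    """One entry of the combinatorial database.

    ``rotation`` indexes the angle 2*pi*k/n_rotations about the vertical
    (z) axis; ``mirror`` reflects x -> -x (a genuine reflection, not a
    180-degree rotation: propagation along y breaks that symmetry).
    ``family`` is "combinatorial" for the training cavities and "heldout"
    for the dedicated test phantom.
    """

    fat_id: int
    gland_id: int
    tumor_case: int = 1
    mirror: bool = False
    rotation: int = 0
    n_rotations: int = 16
    jitter_seed: int = 0
    family: str = "combinatorial"

    def __post_init__(self) -> None:
        if self.family == "combinatorial":
            if self.fat_id not in FAT_SHELLS:
                raise ValueError(f"unknown fat cavity {self.fat_id}")
            if self.gland_id not in GLANDS:
                raise ValueError(f"unknown glandular cavity {self.gland_id}")
            if (self.fat_id, self.gland_id) == (1, 5):
                raise ValueError(
                    "glandular cavity 5 does not fit inside the smallest fat "
                    "cavity; the (fat=1, gland=5) combination is rejected"
                )
        if self.tumor_case not in TUMOR_CASES:
            raise ValueError(f"tumor_case must be in {TUMOR_CASES}")
        if not 0 <= self.rotation < self.n_rotations:
            raise ValueError("rotation index out of range")

    @property
    def rotation_angle(self) -> float:
        return 2.0 * np.pi * self.rotation / self.n_rotations

    @property
    def has_adipose_tumor(self) -> bool:
        return self.tumor_case in (2, 4)

    @property
    def has_glandular_tumor(self) -> bool:
        return self.tumor_case in (3, 4)


def valid_cavity_pairs() -> List[Tuple[int, int]]:
    """The 14 nesting (fat, gland) pairs, sorted."""
    return [
        (f, g)
        for f in sorted(FAT_SHELLS)
        for g in sorted(GLANDS)
        if (f, g) != (1, 5)
    ]


def enumerate_configs(
    include_tumors: bool = True,
    include_mirrors: bool = True,
    n_rotations: int = 16,
    jitter_base_seed: int = 20_000,
) -> List[PhantomConfig]:
    """Deterministic, sorted enumeration of the combinatorial database.

    Counts: 14 tumor-free models; 56 with the four tumor cases; 1792 with
    mirrors and 16 rotations.  The jitter seed is drawn once per model
    (fat, gland, tumor-case combination): mirrors and rotations of a model
    share its jittered tissue properties.
    """
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    cases = TUMOR_CASES if include_tumors else (1,)
    mirrors = (False, True) if include_mirrors else (False,)
    configs: List[PhantomConfig] = []
    model_index = 0
    for fat_id, gland_id in valid_cavity_pairs():
        for case in cases:
            seed = jitter_base_seed + model_index
            model_index += 1
            for mirror in mirrors:
                for rot in range(n_rotations):
                    configs.append(
                        PhantomConfig(
                            fat_id=fat_id,
                            gland_id=gland_id,
                            tumor_case=case,
                            mirror=mirror,
                            rotation=rot,
                            n_rotations=n_rotations,
                            jitter_seed=seed,
                        )
                    )
    return configs


def enumerate_heldout_configs(
    n_rotations: int = 16, include_mirrors: bool = True, jitter_seed: int = 99_000
) -> List[PhantomConfig]:
    """The held-out test phantom's views (16 rotations x mirror = 32)."""
    mirrors = (False, True) if include_mirrors else (False,)
    return [
        PhantomConfig(
            fat_id=1,
            gland_id=1,
            tumor_case=2,
            mirror=m,
            rotation=r,
            n_rotations=n_rotations,
            jitter_seed=jitter_seed,
            family="heldout",
        )
        for m in mirrors
        for r in range(n_rotations)
    ]


def split_dataset(
    configs: Sequence[PhantomConfig],
    train_fraction: float = 0.8,
    shuffle_seed: int = 7,
) -> Tuple[List[PhantomConfig], List[PhantomConfig], List[PhantomConfig]]:
    """Shuffle and split the combinatorial configs; append the held-out test set.

    The train count is floor(train_fraction * N): 1792 samples at 0.8 give
    1433 train / 359 validation, and the held-out phantom contributes its
    32 views as the test set.  Purely a function of ``shuffle_seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    if any(c.family == "heldout" for c in configs):
        raise ValueError("held-out configs must be excluded before splitting")
    order = np.random.default_rng(shuffle_seed).permutation(len(configs))
    shuffled = [configs[i] for i in order]
    n_train = math.floor(train_fraction * len(configs))
    n_rot = configs[0].n_rotations if configs else 16
    test = enumerate_heldout_configs(n_rotations=n_rot)
    return shuffled[:n_train], shuffled[n_train:], test


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel grid centered on the camera axis.

    The transverse (x, z) sampling matches the retina; ``ny`` depth slabs of
    thickness ``spacing`` are centered on the observation plane y = 0.
    """

    n_transverse: int = 64
    ny: int = 27
    spacing: float = CameraGeometry().spacing

    def x_coords(self) -> np.ndarray:
        n = self.n_transverse
        return (np.arange(n) - n // 2) * self.spacing

    def y_coords(self) -> np.ndarray:
        return (np.arange(self.ny) - self.ny // 2) * self.spacing

    z_coords = x_coords


@dataclass
class VoxelPhantom:
    """Voxelized phantom: tissue labels and complex relative permittivity.

    Arrays are indexed ``[ix, iy, iz]``; ``eps[v] = eps' - i eps''`` with
    eps'' = sigma/(w eps0).  Background voxels carry the water properties.
    """

    labels: np.ndarray
    eps: np.ndarray
    grid: GridSpec
    config: PhantomConfig
    dielectrics: TissueDielectrics
    geometry: CameraGeometry


def _model_solids(config: PhantomConfig):
    """Canonical (unrotated, unmirrored) solids for a configuration."""
    if config.family == "heldout":
        outer = HELDOUT_SHELL
        inner = outer.shrunk(SKIN_THICKNESS)
        gland = HELDOUT_GLAND
        tumors = [HELDOUT_TUMOR] if config.has_adipose_tumor else []
        if config.has_glandular_tumor:
            raise ValueError("the held-out phantom carries an adipose tumor only")
        return outer, inner, gland, tumors

    outer = FAT_SHELLS[config.fat_id]
    inner = outer.shrunk(SKIN_THICKNESS)
    gland = GLANDS[config.gland_id]
    tumors = []
    if config.has_adipose_tumor:
        shape = TUMOR_SHAPES[ADIPOSE_TUMOR_SHAPE[config.fat_id]]
        center = tuple(r * a for r, a in zip(ADIPOSE_TUMOR_REL, inner.semiaxes))
        tumors.append(_translate(shape, center))
    if config.has_glandular_tumor:
        shape = TUMOR_SHAPES[GLAND_TUMOR_SHAPE[config.gland_id]]
        tumors.append(_translate(shape, _gland_center(gland)))
    return outer, inner, gland, tumors


def _translate(shape, offset):
    off = tuple(offset)
    if isinstance(shape, SolidUnion):
        return SolidUnion(tuple(_translate(p, off) for p in shape.parts))
    return replace(
        shape, center=tuple(c + o for c, o in zip(shape.center, off))
    )


def _gland_center(gland) -> Tuple[float, float, float]:
    if isinstance(gland, SolidUnion):
        return gland.parts[0].center
    return gland.center


def _canonical_points(pts: np.ndarray, config: PhantomConfig) -> np.ndarray:
    """Map lab-frame points into the canonical frame of the model solids.

    The phantom is rotate(mirror(canonical)); the inverse transform is
    mirror(rotate^-1(p)).  Rotation is about the vertical z axis.
    """
    th = config.rotation_angle
    c, s = np.cos(th), np.sin(th)
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    xr = c * x + s * y
    yr = -s * x + c * y
    if config.mirror:
        xr = -xr
    return np.stack([xr, yr, z], axis=-1)


def build_phantom(
    config: PhantomConfig,
    dielectrics: TissueDielectrics,
    grid: GridSpec,
    geometry: CameraGeometry | None = None,
) -> VoxelPhantom:
    """Voxelize a configuration onto ``grid``.

    Label precedence is tumor > gland > fat > skin > water.  The mirror is a
    geometric reflection of the solid applied before any field simulation;
    the rotation acts about the vertical axis.  Deterministic.
    """
    geometry = geometry or CameraGeometry()
    outer, inner, gland, tumors = _model_solids(config)

    x = grid.x_coords()
    y = grid.y_coords()
    z = grid.z_coords()
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    pts = _canonical_points(np.stack([X, Y, Z], axis=-1), config)

    labels = np.zeros(X.shape, dtype=np.int8)
    in_outer = outer.contains(pts)
    in_inner = inner.contains(pts)
    labels[in_outer] = LABELS["skin"]
    labels[in_inner] = LABELS["fat"]
    labels[in_inner & gland.contains(pts)] = LABELS["glandular"]
    for tumor in tumors:
        labels[in_inner & tumor.contains(pts)] = LABELS["tumor"]

    eps = np.empty(labels.shape, dtype=np.complex128)
    for name, lab in LABELS.items():
        eps[labels == lab] = dielectrics.complex_permittivity(name, geometry)
    return VoxelPhantom(labels, eps, grid, config, dielectrics, geometry)


# ---------------------------------------------------------------------------
# Contrast slice
# ---------------------------------------------------------------------------


@dataclass
class ContrastMap:
    """Complex contrast C(x, z) on an observation plane plus its support mask.

    ``C = (eps' - eps'_water) - i (eps'' - eps''_water)``; exactly zero on
    water pixels, with Re(C) <= 0 for all catalog tissues.
    """

    values: np.ndarray
    mask: np.ndarray
    plane_y: float
    grid: GridSpec


def contrast_slice(phantom: VoxelPhantom, plane_y: float = 0.0) -> ContrastMap:
    """Extract the complex contrast on the plane nearest to ``plane_y``."""
    y = phantom.grid.y_coords()
    half = phantom.grid.spacing / 2.0
    if plane_y < y[0] - half or plane_y > y[-1] + half:
        raise ValueError(f"plane_y={plane_y} lies outside the voxel grid")
    iy = int(np.argmin(np.abs(y - plane_y)))
    eps_w = phantom.geometry.complex_permittivity(
        phantom.dielectrics.eps_r("water"), phantom.dielectrics.sigma("water")
    )
    values = phantom.eps[:, iy, :] - eps_w
    mask = phantom.labels[:, iy, :] != LABELS["water"]
    values = np.where(mask, values, 0.0 + 0.0j)
    return ContrastMap(values, mask, float(y[iy]), phantom.grid)
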