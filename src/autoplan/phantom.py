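"""Synthetic voxel phantoms for automated-planning experiments.

Builds deterministic head-and-neck-like geometries on a regular voxel grid:
three nested target volumes (a central primary CTV plus one or two lateral
nodal levels), a posterior serial organ-at-risk surrogate (spinal-cord-like)
with a safety-margin PRV, paired lateral parallel organs (parotid-like), an
elliptical body contour, and the "rind" shells used as dummy optimization
structures around each PTV.

All geometry lives in millimetres.  Masks follow a voxel-centre membership
convention: a voxel belongs to a structure iff its centre satisfies the
geometric predicate, and margin expansions include a voxel iff its centre
lies within the margin (Euclidean, honouring anisotropic spacing) of some
already-included voxel centre.  Both 2D single-slice and 3D grids are
supported; the 2D mode is the default experimental surface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

ROLES = ("target", "serial_oar", "parallel_oar", "rind", "body", "external")

#: default three-level simultaneous-integrated-boost prescription (Gy)
DEFAULT_PRESCRIPTIONS = (70.0, 63.0, 56.0)
DEFAULT_FRACTIONS = 33


@dataclass(frozen=True)
class Grid:
    """Regular voxel grid: counts, spacing (mm) and origin (mm) per axis."""

    shape: tuple[int, ...]
    spacing: tuple[float, ...]
    origin: tuple[float, ...]

    def __post_init__(self):
        if len(self.shape) != len(self.spacing) or len(self.shape) != len(self.origin):
            raise ValueError("shape, spacing and origin must have equal length")
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape entries must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacings must be positive")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (mm) along one axis."""
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.spacing[axis]

    def centers(self) -> np.ndarray:
        """All voxel centres, shape ``(size, ndim)``, C-order flattening."""
        axes = [self.axis_centers(a) for a in range(self.ndim)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)


@dataclass
class Structure:
    """A named region of interest: a boolean mask on a grid plus its role."""

    name: str
    role: str
    mask: np.ndarray
    prescription: float | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for structure {self.name!r}")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class PhantomSpec:
    """Parametric description of a synthetic head-and-neck-like phantom.

    Geometry is given as ellipse/ellipsoid primitives (centres and semi-axes,
    mm) in a patient-like frame: axis 0 is left-right (+x to the patient's
    left), axis 1 is posterior-anterior (+y anterior); a 3D spec appends a
    superior-inferior axis.  The nodal target levels are lateral lobes whose
    placement follows ``laterality``: ``"bilateral"`` mirrors the lobes on
    both sides, ``"unilateral"`` places them on +x only.
    """

    shape: tuple[int, ...] = (88, 96)
    spacing_mm: tuple[float, ...] = (2.5, 2.5)
    origin_mm: tuple[float, ...] | None = None  # None -> grid centred on 0

    body_radii_mm: tuple[float, ...] = (90.0, 105.0)
    body_center_mm: tuple[float, ...] = (0.0, 0.0)

    ctv1_center_mm: tuple[float, ...] = (0.0, 20.0)
    ctv1_radius_mm: float = 24.0
    # nodal lobes: CTV2 = CTV1 plus high-risk lobes, CTV3 = CTV2 plus
    # lower-risk lobes (nested dose levels)
    node2_offset_mm: tuple[float, ...] = (42.0, 0.0)
    node2_radius_mm: float = 16.0
    node3_offset_mm: tuple[float, ...] = (52.0, -28.0)
    node3_radius_mm: float = 14.0
    laterality: str = "bilateral"

    serial_oar_center_mm: tuple[float, ...] = (0.0, -20.0)
    serial_oar_radius_mm: float = 5.0
    parotid_offset_mm: tuple[float, ...] = (60.0, -28.0)
    parotid_radius_mm: float = 12.0

    ctv_to_ptv_margin_mm: float = 3.0
    prv_margin_mm: float = 5.0
    rind_thickness_mm: float = 10.0

    prescriptions_gy: tuple[float, float, float] = DEFAULT_PRESCRIPTIONS
    fractions: int = DEFAULT_FRACTIONS

    #: allowed overlap (voxels) between the serial OAR and CTV1
    oar_ctv_overlap_tol: int = 0
    #: crop PTVs at the body surface (default: no cropping)
    crop_ptv_to_body: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.laterality not in ("unilateral", "bilateral"):
            raise ValueError("laterality must be 'unilateral' or 'bilateral'")
        for name in ("ctv_to_ptv_margin_mm", "prv_margin_mm", "rind_thickness_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def grid(self) -> Grid:
        origin = self.origin_mm
        if origin is None:
            origin = tuple(
                -0.5 * n * s for n, s in zip(self.shape, self.spacing_mm)
            )
        return Grid(tuple(self.shape), tuple(self.spacing_mm), tuple(origin))


@dataclass
class Phantom:
    """A voxel grid plus named structures and the prescription levels."""

    grid: Grid
    structures: dict[str, Structure]
    prescriptions_gy: tuple[float, float, float] = DEFAULT_PRESCRIPTIONS
    fractions: int = DEFAULT_FRACTIONS
    spec: PhantomSpec | None = None

    def mask(self, name: str) -> np.ndarray:
        try:
            return self.structures[name].mask
        except KeyError:
            raise KeyError(
                f"phantom has no structure named {name!r}; "
                f"available: {sorted(self.structures)}"
            ) from None

    def flat_mask(self, name: str) -> np.ndarray:
        return self.mask(name).ravel()

    def by_role(self, role: str) -> list[Structure]:
        return [s for s in self.structures.values() if s.role == role]

    def __contains__(self, name: str) -> bool:
        return name in self.structures


# ---------------------------------------------------------------------------
# mask primitives


def ellipsoid_mask(grid: Grid, center_mm, radii_mm) -> np.ndarray:
    """Voxels whose centre lies inside an axis-aligned ellipse/ellipsoid."""
    center = np.asarray(center_mm, dtype=float)
    radii = np.atleast_1d(np.asarray(radii_mm, dtype=float))
    if radii.size == 1:
        radii = np.full(grid.ndim, radii[0])
    if radii.size != grid.ndim or center.size != grid.ndim:
        raise ValueError("center/radii dimensionality does not match grid")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    q = np.zeros(grid.shape)
    for a in range(grid.ndim):
        coord = (grid.axis_centers(a) - center[a]) / radii[a]
        shp = [1] * grid.ndim
        shp[a] = grid.shape[a]
        q = q + coord.reshape(shp) ** 2
    return q <= 1.0


def expand_margin(mask: np.ndarray, margin_mm: float, grid: Grid) -> np.ndarray:
    """Isotropic margin expansion of a voxel mask.

    A voxel is included iff its centre lies within ``margin_mm`` (Euclidean,
    with anisotropic spacing honoured) of the centre of some voxel of the
    input mask.  Expansion is clipped at the grid boundary.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match grid")
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=grid.spacing)
    # tolerance so that centres at exactly margin_mm are included
    return dist <= margin_mm * (1.0 + 1e-12) + 1e-9


def make_rind(ptv_mask: np.ndarray, thickness_mm: float, grid: Grid) -> np.ndarray:
    """Shell of given thickness around a PTV, disjoint from the PTV itself."""
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    if not ptv_mask.any():
        raise ValueError("cannot build a rind around an empty PTV mask")
    return expand_margin(ptv_mask, thickness_mm, grid) & ~ptv_mask


# ---------------------------------------------------------------------------
# phantom assembly


def _lobe_centers(base, offset, laterality):
    """Mirror a lateral lobe offset according to the laterality flag."""
    base = np.asarray(base, dtype=float)
    offset = np.asarray(offset, dtype=float)
    plus = base + offset
    minus = base + offset * np.array([-1.0] + [1.0] * (len(offset) - 1))
    if laterality == "bilateral":
        return [plus, minus]
    return [plus]


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Assemble the full structure set from a :class:`PhantomSpec`.

    Deterministic for a fixed spec.  Raises if a structure extends outside
    the body contour or if the serial OAR overlaps the primary CTV by more
    than the configured tolerance.
    """
    grid = spec.grid()
    body = ellipsoid_mask(grid, spec.body_center_mm, spec.body_radii_mm)
    if not body.any():
        raise ValueError("body contour is empty on this grid")

    ctv1 = ellipsoid_mask(grid, spec.ctv1_center_mm, spec.ctv1_radius_mm)
    ctv2 = ctv1.copy()
    for c in _lobe_centers(spec.ctv1_center_mm, spec.node2_offset_mm, spec.laterality):
        ctv2 |= ellipsoid_mask(grid, c, spec.node2_radius_mm)
    ctv3 = ctv2.copy()
    for c in _lobe_centers(spec.ctv1_center_mm, spec.node3_offset_mm, spec.laterality):
        ctv3 |= ellipsoid_mask(grid, c, spec.node3_radius_mm)

    ptvs = {}
    for k, ctv in enumerate((ctv1, ctv2, ctv3), start=1):
        ptv = expand_margin(ctv, spec.ctv_to_ptv_margin_mm, grid)
        if spec.crop_ptv_to_body:
            ptv &= body
        ptvs[k] = ptv

    oar = ellipsoid_mask(grid, spec.serial_oar_center_mm, spec.serial_oar_radius_mm)
    prv = expand_margin(oar, spec.prv_margin_mm, grid)
    par_l = ellipsoid_mask(grid, np.asarray(spec.parotid_offset_mm), spec.parotid_radius_mm)
    mirror = np.array([-1.0] + [1.0] * (grid.ndim - 1))
    par_r = ellipsoid_mask(grid, np.asarray(spec.parotid_offset_mm) * mirror, spec.parotid_radius_mm)

    overlap = int((oar & ctv1).sum())
    if overlap > spec.oar_ctv_overlap_tol:
        raise ValueError(
            f"serial OAR overlaps CTV1 by {overlap} voxels "
            f"(tolerance {spec.oar_ctv_overlap_tol})"
        )

    structures: dict[str, Structure] = {
        "body": Structure("body", "body", body),
        "ctv1": Structure("ctv1", "target", ctv1, spec.prescriptions_gy[0]),
        "ctv2": Structure("ctv2", "target", ctv2, spec.prescriptions_gy[1]),
        "ctv3": Structure("ctv3", "target", ctv3, spec.prescriptions_gy[2]),
        "ptv1": Structure("ptv1", "target", ptvs[1], spec.prescriptions_gy[0]),
        "ptv2": Structure("ptv2", "target", ptvs[2], spec.prescriptions_gy[1]),
        "ptv3": Structure("ptv3", "target", ptvs[3], spec.prescriptions_gy[2]),
        "cord": Structure("cord", "serial_oar", oar),
        "cord_prv": Structure("cord_prv", "serial_oar", prv),
        "parotid_l": Structure("parotid_l", "parallel_oar", par_l),
        "parotid_r": Structure("parotid_r", "parallel_oar", par_r),
    }
    for k in (1, 2, 3):
        rind = make_rind(ptvs[k], spec.rind_thickness_mm, grid)
        structures[f"rind{k}"] = Structure(f"rind{k}", "rind", rind)

    for name, s in structures.items():
        if name == "body":
            continue
        if s.role in ("target", "serial_oar", "parallel_oar") and not s.mask.any():
            raise ValueError(f"structure {name!r} is empty on this grid")
        outside = int((s.mask & ~body).sum())
        if s.role in ("serial_oar", "parallel_oar", "target") and outside:
            # rinds may legitimately spill outside; anatomy must not
            raise ValueError(
                f"structure {name!r} extends outside the body contour "
                f"({outside} voxels)"
            )

    return Phantom(
        grid=grid,
        structures=structures,
        prescriptions_gy=tuple(spec.prescriptions_gy),
        fractions=spec.fractions,
        spec=replace(spec),
    )
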