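"""Synthetic voxel lung phantoms with analytic/voxel ground truth.

The phantom is a fully labelled 3D voxel block standing in for a fixed,
resin-embedded neonatal lung.  Parenchyma is modelled as a septal-tissue
matrix carved with spherical cavities on a jittered cubic lattice: a
fraction of lattice sites are individually identified alveoli, the rest
are ductal airspace.  Spheres are used because every quantity the
downstream estimators target (volume, surface, number, thickness,
intercept length) has a closed form, and because an isotropic cavity
population makes single-orientation test-line counting unbiased.
Nonparenchyma is a tissue block threaded by near-axial cylindrical
vessels with concentric wall and perivascular shells.

Every phantom carries a :class:`GroundTruth` record so each estimator in
the pipeline can be validated against brute-force voxel tallies rather
than against another stereological estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq


class Label(IntEnum):
    """Integer compartment labels used by all phantom rasters."""

    BACKGROUND = 0
    SEPTUM = 1
    ALVEOLAR_AIR = 2
    DUCT_AIR = 3
    EDEMA = 4
    INFLAMMATORY = 5
    VESSEL_LUMEN = 6
    VESSEL_WALL = 7
    PERIVASCULAR = 8
    AIRWAY = 9


#: Gas-exchange region: septa plus alveolar and ductal airspace.
PARENCHYMA_LABELS = frozenset(
    {Label.SEPTUM, Label.ALVEOLAR_AIR, Label.DUCT_AIR, Label.EDEMA, Label.INFLAMMATORY}
)
#: Conducting airways, >25 um vessels and the peribronchovascular sheath.
NONPARENCHYMA_LABELS = frozenset(
    {Label.VESSEL_LUMEN, Label.VESSEL_WALL, Label.PERIVASCULAR, Label.AIRWAY}
)
#: Total parenchymal airspace.  Intra-alveolar edema and inflammatory
#: material are measured *within* the airspace, so they belong to the
#: airspace reference volume.
AIRSPACE_LABELS = frozenset(
    {Label.ALVEOLAR_AIR, Label.DUCT_AIR, Label.EDEMA, Label.INFLAMMATORY}
)
#: Alveolar airspace inclusive of its edema/inflammatory content.
ALVEOLAR_AIRSPACE_LABELS = frozenset({Label.ALVEOLAR_AIR, Label.EDEMA, Label.INFLAMMATORY})

_GAP_VOXELS = 2.0  # minimum septal separation between cavities, in voxels
_MIN_RADIUS_VOXELS = 3.0


class PackingError(ValueError):
    """Requested cavity population cannot be packed into the block."""


class UnknownLabelError(ValueError):
    """A raster contains a label outside the phantom label set."""


@dataclass
class GroundTruth:
    """Exact (voxel-tally or analytic) quantities for one phantom.

    Volumes are in um^3, surfaces in um^2, thicknesses/diameters in um.
    ``septal_surface_um2`` counts every airspace-facing septal face
    (both-sided sheet convention); ``luminal_surface_um2`` is the
    one-sided endothelial surface of the vessel lumen.
    """

    volumes_um3: dict[str, float]
    septal_surface_um2: float = 0.0
    alveolus_count: int = 0
    mean_septal_thickness_um: float = float("nan")
    luminal_volume_um3: float = 0.0
    luminal_surface_um2: float = 0.0
    wall_volume_um3: float = 0.0
    perivascular_volume_um3: float = 0.0
    vessel_diameter_um: float = float("nan")
    block_volume_um3: float = 0.0

    def volume(self, labels: Iterable[Label]) -> float:
        return sum(self.volumes_um3.get(lab.name, 0.0) for lab in labels)

    @property
    def parenchyma_volume_um3(self) -> float:
        return self.volume(PARENCHYMA_LABELS)

    @property
    def nonparenchyma_volume_um3(self) -> float:
        return self.volume(NONPARENCHYMA_LABELS)

    @property
    def airspace_volume_um3(self) -> float:
        return self.volume(AIRSPACE_LABELS)

    @property
    def alveolar_airspace_volume_um3(self) -> float:
        return self.volume(ALVEOLAR_AIRSPACE_LABELS)

    @property
    def mean_linear_intercept_um(self) -> float:
        return 4.0 * self.airspace_volume_um3 / self.septal_surface_um2

    @property
    def mean_alveolar_volume_um3(self) -> float:
        return self.alveolar_airspace_volume_um3 / self.alveolus_count


@dataclass
class Phantom3D:
    """Voxel-labelled synthetic lung block.

    ``labels`` is a (z, y, x) uint8 raster of :class:`Label` values;
    ``alveolus_id`` assigns a positive integer to every alveolar-airspace
    voxel (0 elsewhere).  Intra-alveolar edema/inflammatory voxels keep
    the identity of their host alveolus.
    """

    labels: np.ndarray
    alveolus_id: np.ndarray
    voxel_um: float
    seed: int | None = None
    ground_truth: GroundTruth | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.voxel_um <= 0:
            raise ValueError("voxel edge length must be positive")
        if self.labels.shape != self.alveolus_id.shape:
            raise ValueError("label and identity grids must share a shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def depth_um(self) -> float:
        return self.labels.shape[0] * self.voxel_um

    @property
    def block_volume_um3(self) -> float:
        return float(np.prod(self.labels.shape)) * self.voxel_um**3


@dataclass
class SectionImage:
    """A 2D labelled physical section through a phantom or real raster."""

    labels: np.ndarray
    alveolus_id: np.ndarray | None
    z_um: float
    thickness_um: float
    pixel_um: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def height_um(self) -> float:
        return self.labels.shape[0] * self.pixel_um

    @property
    def width_um(self) -> float:
        return self.labels.shape[1] * self.pixel_um


@dataclass
class DisectorPair:
    """Two aligned sections a known axial distance apart.

    ``h_um`` is the centre-to-centre axial separation entering the
    number estimator's denominator (frame area x h).
    """

    reference: SectionImage
    lookup: SectionImage
    h_um: float

    def __post_init__(self) -> None:
        if self.h_um <= 0:
            raise ValueError("disector height must be positive")
        if self.reference.shape != self.lookup.shape:
            raise ValueError("disector sections must share a pixel grid")


@dataclass
class GroupPreset:
    """Named parameter bundle describing one experimental group.

    All geometric parameters are at phantom scale (the block is a
    miniature lung ~1e5 times smaller than a neonatal rabbit lung);
    cavity-lattice values were chosen so the *contrasts* between the
    normoxia and hyperoxia presets track the reference group means in
    direction and relative magnitude.  Vessel dimensions are absolute
    (um), since individual vessels are resolvable at phantom scale.

    ``variability`` maps field names to per-animal coefficients of
    variation used when a cohort is simulated.
    """

    name: str
    lung_volume_um3: float
    parenchymal_fraction: float
    alveolar_number_density_per_um3: float
    septal_thickness_um: float
    duct_site_fraction: float
    edema_airspace_fraction: float
    inflammatory_edema_fraction: float
    vessel_diameter_um: float
    vessel_wall_thickness_um: float
    perivascular_thickness_um: float
    vessels_per_lung: int = 3
    variability: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "lung_volume_um3",
            "parenchymal_fraction",
            "alveolar_number_density_per_um3",
            "septal_thickness_um",
            "vessel_diameter_um",
            "vessel_wall_thickness_um",
            "perivascular_thickness_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"preset field {name!r} must be positive")
        if not 0 < self.parenchymal_fraction < 1:
            raise ValueError("parenchymal_fraction must be in (0, 1)")
        if not 0 <= self.duct_site_fraction < 1:
            raise ValueError("duct_site_fraction must be in [0, 1)")

    def jittered(self, rng: np.random.Generator) -> "GroupPreset":
        """Draw one animal's parameters around the group means.

        Each field listed in ``variability`` is multiplied by an
        independent lognormal factor whose CV matches the stated
        between-animal coefficient of variation.
        """
        updates: dict[str, float] = {}
        for name, cv in self.variability.items():
            base = getattr(self, name)
            sigma = math.sqrt(math.log(1.0 + cv * cv))
            updates[name] = base * float(rng.lognormal(-0.5 * sigma**2, sigma))
        if "parenchymal_fraction" in updates:
            updates["parenchymal_fraction"] = min(updates["parenchymal_fraction"], 0.95)
        return replace(self, variability=self.variability, **updates)


# ---------------------------------------------------------------------------
# voxel helpers
# ---------------------------------------------------------------------------


def _carve_ball(
    labels: np.ndarray,
    ident: np.ndarray | None,
    center_vox: Sequence[float],
    radius_vox: float,
    label: int,
    ident_value: int = 0,
) -> None:
    """Assign ``label`` to all voxels whose centre lies within the ball."""
    shape = labels.shape
    lo = [max(int(math.floor(c - radius_vox)), 0) for c in center_vox]
    hi = [min(int(math.ceil(c + radius_vox)) + 1, s) for c, s in zip(center_vox, shape)]
    zz, yy, xx = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    mask = (
        (zz - center_vox[0]) ** 2 + (yy - center_vox[1]) ** 2 + (xx - center_vox[2]) ** 2
    ) <= radius_vox**2
    view = labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    view[mask] = label
    if ident is not None and ident_value:
        ident[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]][mask] = ident_value


def _carve_capsule(
    labels: np.ndarray,
    ident: np.ndarray | None,
    p0: np.ndarray,
    p1: np.ndarray,
    radius_vox: float,
    label: int,
    ident_value: int = 0,
) -> None:
    """Assign ``label`` within a finite cylinder (with flat caps) from p0 to p1."""
    shape = labels.shape
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius_vox).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius_vox).astype(int) + 1, shape)
    axis = np.asarray(p1, float) - np.asarray(p0, float)
    length2 = float(axis @ axis)
    if length2 == 0:
        return
    zz = (np.arange(lo[0], hi[0], dtype=np.float32) - p0[0])[:, None, None]
    yy = (np.arange(lo[1], hi[1], dtype=np.float32) - p0[1])[None, :, None]
    xx = (np.arange(lo[2], hi[2], dtype=np.float32) - p0[2])[None, None, :]
    t = (zz * axis[0] + yy * axis[1] + xx * axis[2]) / length2
    d2 = zz * zz + yy * yy + xx * xx - t * t * length2
    # flat caps: require projection strictly within the segment
    inside = (d2 <= radius_vox**2) & (t > 0) & (t < 1)
    view = labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    view[inside] = label
    if ident is not None and ident_value:
        ident[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]][inside] = ident_value


def interface_area_um2(
    labels: np.ndarray,
    class_a: Iterable[int],
    class_b: Iterable[int],
    voxel_um: float,
    method: str = "crofton",
) -> float:
    """Area of the interface between two disjoint label classes.

    ``crofton`` counts label transitions along the three grid axes and
    applies the Cauchy relation S = 2 * I_L * V (the measurement theory
    of intercept-counting stereology); it is asymptotically exact for
    isotropic interfaces such as the sphere populations used here.
    ``faces`` counts boundary voxel faces, which is exact for
    axis-aligned plates but overestimates curved isotropic surfaces by
    up to 50%.
    """
    in_a = np.isin(labels, list(class_a))
    in_b = np.isin(labels, list(class_b))
    cls = np.zeros(labels.shape, np.int8)
    cls[in_a] = 1
    cls[in_b] = 2
    transitions = []
    for ax in range(labels.ndim):
        lo = [slice(None)] * labels.ndim
        hi = [slice(None)] * labels.ndim
        lo[ax] = slice(None, -1)
        hi[ax] = slice(1, None)
        a, b = cls[tuple(lo)], cls[tuple(hi)]
        transitions.append(int(np.count_nonzero(a * b == 2)))  # 1*2: one side each class
    if method == "crofton":
        return (2.0 / 3.0) * float(sum(transitions)) * voxel_um**2
    if method == "faces":
        return float(sum(transitions)) * voxel_um**2
    raise ValueError(f"unknown surface method {method!r}")


def compute_ground_truth(phantom: Phantom3D, surface_method: str = "crofton") -> GroundTruth:
    """Brute-force oracle: exhaustive voxel tallies for every compartment.

    Volumes are voxel counts times the voxel volume; the septal surface
    is the septum<->airspace interface area; the alveolus count is the
    number of distinct identity labels; mean thicknesses and diameters
    use the same volume/surface identities the estimators apply, but on
    true totals.
    """
    labels = phantom.labels
    known = {int(v) for v in Label}
    counts = np.bincount(labels.ravel(), minlength=max(known) + 1)
    present = set(np.nonzero(counts)[0].tolist())
    unknown = present - known
    if unknown:
        raise UnknownLabelError(f"raster contains unknown label(s): {sorted(unknown)}")

    vv = phantom.voxel_um**3
    volumes = {Label(i).name: float(counts[i]) * vv for i in range(len(counts)) if counts[i]}
    gt = GroundTruth(volumes_um3=volumes, block_volume_um3=phantom.block_volume_um3)

    gt.alveolus_count = int(np.count_nonzero(np.unique(phantom.alveolus_id)))

    sept_air = interface_area_um2(
        labels, [Label.SEPTUM], sorted(AIRSPACE_LABELS), phantom.voxel_um, surface_method
    )
    gt.septal_surface_um2 = sept_air
    v_sept = volumes.get(Label.SEPTUM.name, 0.0)
    if sept_air > 0:
        gt.mean_septal_thickness_um = 2.0 * v_sept / sept_air

    gt.luminal_volume_um3 = volumes.get(Label.VESSEL_LUMEN.name, 0.0)
    gt.wall_volume_um3 = volumes.get(Label.VESSEL_WALL.name, 0.0)
    gt.perivascular_volume_um3 = volumes.get(Label.PERIVASCULAR.name, 0.0)
    if gt.luminal_volume_um3:
        lum_surf = interface_area_um2(
            labels, [Label.VESSEL_LUMEN], [Label.VESSEL_WALL], phantom.voxel_um, surface_method
        )
        gt.luminal_surface_um2 = lum_surf
        if lum_surf > 0:
            gt.vessel_diameter_um = 4.0 * gt.luminal_volume_um3 / lum_surf
    return gt


# ---------------------------------------------------------------------------
# parenchyma
# ---------------------------------------------------------------------------


def _solve_cavity_radius(
    cell_volume_um3: float,
    septal_thickness_um: float,
    r_max_um: float,
    r_min_um: float,
) -> float:
    """Cavity radius reproducing the target mean septal thickness.

    With every lattice cell holding one sphere of radius r,
    tau = 2 V_sept / S = 2 (V_cell - 4/3 pi r^3) / (4 pi r^2),
    monotone decreasing in r on the packable range.
    """

    def tau(r: float) -> float:
        v = (4.0 / 3.0) * math.pi * r**3
        s = 4.0 * math.pi * r**2
        return 2.0 * (cell_volume_um3 - v) / s

    if tau(r_max_um) > septal_thickness_um:
        raise PackingError(
            "requested number density too high for the requested septal "
            f"thickness: even at the maximum packable radius ({r_max_um:.1f} um) "
            f"the mean septal thickness is {tau(r_max_um):.1f} um "
            f"> target {septal_thickness_um:.1f} um"
        )
    if tau(r_min_um) < septal_thickness_um:
        raise PackingError(
            "requested septal thickness too large for the requested number "
            f"density: at the minimum resolvable radius ({r_min_um:.1f} um) the "
            f"mean septal thickness is only {tau(r_min_um):.1f} um"
        )
    return float(brentq(lambda r: tau(r) - septal_thickness_um, r_min_um, r_max_um))


def max_edema_airspace_fraction(preset: GroupPreset) -> float:
    """Largest airspace fraction the concentric edema balls can hold."""
    return 0.75**3 * (1.0 - preset.duct_site_fraction)


def min_packable_septal_thickness_um(preset: GroupPreset, voxel_um: float = 1.5) -> float:
    """Thinnest mean septum a sphere lattice at this density can realize.

    At the largest packable radius the cavities nearly touch; requesting
    a thinner septum than this is an infeasible packing.
    """
    pitch_um = lattice_pitch_um(preset)
    jitter = 1.0
    r_max_um = (0.99 * pitch_um / voxel_um - 2.0 * jitter - _GAP_VOXELS) / 2.0 * voxel_um
    v = (4.0 / 3.0) * math.pi * r_max_um**3
    s = 4.0 * math.pi * r_max_um**2
    return 2.0 * (pitch_um**3 - v) / s


def build_parenchyma_phantom(
    preset: GroupPreset,
    mode: str = "closed_cell",
    seed: int = 0,
    shape: tuple[int, int, int] | None = None,
    voxel_um: float = 1.5,
    target_extent_vox: int = 256,
    ground_truth: bool = True,
) -> Phantom3D:
    """Generate a parenchymal block: septal matrix with cavity lattice.

    Cavities sit on a jittered cubic lattice; a ``duct_site_fraction``
    of sites are ductal airspace (no identity), the rest individually
    identified alveoli.  In ``closed_cell`` mode every cavity is a
    disjoint sphere fully separated by septum, so the block is
    topologically countable by disector island events alone.  In
    ``duct_open`` mode each alveolus additionally receives one
    cylindrical mouth opening into its nearest duct (experimental for
    number estimation; see package docs).

    The cavity radius is solved from the preset's septal-thickness and
    number-density targets on the *nominal* lattice cell, so mean cavity
    size is a pure function of the preset.  With ``shape=None`` the
    block is snapped to whole lattice cells near ``target_extent_vox``
    and the realized septal thickness matches its target; an explicit
    ``shape`` stretches the lattice to tile the block, shifting the
    realized thickness by the cell-volume residual (never the cavity
    size).

    Edema is modelled as a concentric fluid ball inside a random subset
    of alveoli, with an optional inflammatory-cell core, reaching the
    preset's target fraction of total airspace volume.
    """
    if mode not in ("closed_cell", "duct_open"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    a = voxel_um

    pitch_um = lattice_pitch_um(preset)
    if shape is None:
        n_cells = max(1, int(round(target_extent_vox * a / pitch_um)))
        extent = int(round(n_cells * pitch_um / a))
        shape = (extent, extent, extent)
    if min(shape) < 64:
        raise ValueError("block must be at least 64^3 voxels")

    # the per-axis pitch is stretched so whole cells tile the block;
    # otherwise a dead septal shell at the faces would bias the realized
    # septal thickness, and differently so for different presets.  The
    # cell count is floored so the stretch only widens cells and can
    # never tighten the packing below the nominal pitch (the 0.1 slack
    # absorbs the rounding of a near-integer extent).
    n_ax = [max(1, int(n * a / pitch_um + 0.1)) for n in shape]
    pitch_ax = [n / k for n, k in zip(shape, n_ax)]  # voxels per cell, per axis

    jitter = 1.0  # voxels; the feasibility bound keeps the septal gap intact
    r_max_um = (0.99 * pitch_um / a - 2.0 * jitter - _GAP_VOXELS) / 2.0 * a
    r_min_um = _MIN_RADIUS_VOXELS * a
    if r_max_um <= r_min_um:
        raise PackingError(
            f"lattice pitch {pitch_um:.1f} um leaves no room for cavities of "
            f"radius >= {r_min_um:.1f} um"
        )
    r_um = _solve_cavity_radius(
        pitch_um**3, preset.septal_thickness_um, r_max_um, r_min_um
    )
    r = r_um / a

    # each (y, x) column of cells carries an independent uniform z phase:
    # a fully coherent cubic lattice would make thin sections alias with
    # the lattice period, inflating between-section variance far beyond
    # anything a real cavity population shows.  Lateral spacing alone
    # already guarantees the septal gap, so the stagger cannot create
    # contacts between columns.
    pitch_z = pitch_ax[0]
    z_lo, z_hi = r + 2.0, shape[0] - r - 2.0
    ys = (np.arange(n_ax[1]) + 0.5) * pitch_ax[1]
    xs = (np.arange(n_ax[2]) + 0.5) * pitch_ax[2]
    site_list = []
    for y in ys:
        for x in xs:
            phase = rng.uniform(0.0, pitch_z)
            zs = z_lo + np.arange(phase, z_hi - z_lo, pitch_z)
            for z in zs:
                site_list.append((z, y, x))
    sites = np.asarray(site_list)
    if len(sites) == 0:
        raise PackingError("block too shallow for a single cavity at this density")
    sites[:, 1:] += rng.uniform(-jitter, jitter, (len(sites), 2))
    # cavities must stay strictly inside the block (disector exactness
    # needs both poles of every cavity on interior planes)
    sites = np.clip(sites, r + 2.0, np.array(shape) - r - 2.0)

    n_duct = int(round(preset.duct_site_fraction * len(sites)))
    duct_idx = rng.choice(len(sites), size=n_duct, replace=False) if n_duct else np.array([], int)
    is_duct = np.zeros(len(sites), bool)
    is_duct[duct_idx] = True
    n_alv = int(len(sites) - n_duct)
    if n_alv == 0:
        raise PackingError("block too small for a single alveolus at this density")

    labels = np.full(shape, Label.SEPTUM, np.uint8)
    ident = np.zeros(shape, np.int32)

    alv_centers = []
    next_id = 0
    for site, duct in zip(sites, is_duct):
        if duct:
            _carve_ball(labels, None, site, r, Label.DUCT_AIR)
        else:
            next_id += 1
            _carve_ball(labels, ident, site, r, Label.ALVEOLAR_AIR, next_id)
            alv_centers.append(site)
    alv_centers = np.asarray(alv_centers)

    # edema: concentric fluid balls in a random subset of alveoli
    edema_ids: np.ndarray = np.array([], int)
    ball_factor = 0.75  # edema ball radius as a fraction of the cavity radius
    if preset.edema_airspace_fraction > 0 and n_alv:
        per_ball = ball_factor**3  # fraction of one cavity volume
        total_air = (n_alv + n_duct) * (4.0 / 3.0) * math.pi * r_um**3
        need = preset.edema_airspace_fraction * total_air
        p_sel = need / (per_ball * (4.0 / 3.0) * math.pi * r_um**3 * n_alv)
        if p_sel > 1.0:
            raise PackingError(
                f"edema fraction {preset.edema_airspace_fraction:.3f} exceeds what "
                f"concentric balls of relative radius {ball_factor} can hold"
            )
        sel = rng.random(n_alv) < p_sel
        edema_ids = np.nonzero(sel)[0]
        core = preset.inflammatory_edema_fraction ** (1.0 / 3.0) * ball_factor * r
        for i in edema_ids:
            _carve_ball(labels, None, alv_centers[i], ball_factor * r, Label.EDEMA)
            if core >= 1.0:
                _carve_ball(labels, None, alv_centers[i], core, Label.INFLAMMATORY)
        # edema keeps the host alveolus identity; _carve_ball(None) left ident intact

    if mode == "duct_open" and n_duct:
        duct_centers = sites[is_duct]
        mouth_r = max(0.35 * r, 2.0)
        for i, c in enumerate(alv_centers):
            d2 = np.sum((duct_centers - c) ** 2, axis=1)
            j = int(np.argmin(d2))
            if d2[j] <= (2.2 * max(pitch_ax)) ** 2:
                _carve_capsule(
                    labels, ident, c, duct_centers[j], mouth_r, Label.ALVEOLAR_AIR, i + 1
                )
                # restore the duct interior (the capsule end may poke into it)
                _carve_ball(labels, None, duct_centers[j], r, Label.DUCT_AIR)

    phantom = Phantom3D(
        labels=labels,
        alveolus_id=ident,
        voxel_um=voxel_um,
        seed=seed,
        meta={
            "kind": "parenchyma",
            "mode": mode,
            "preset": preset.name,
            "cavity_radius_um": r_um,
            "lattice_pitch_um": pitch_um,
            "n_alveoli": n_alv,
            "n_ducts": n_duct,
            "analytic": {
                "cavity_volume_um3": (4.0 / 3.0) * math.pi * r_um**3,
                "cavity_surface_um2": 4.0 * math.pi * r_um**2,
            },
        },
    )
    if ground_truth:
        phantom.ground_truth = compute_ground_truth(phantom)
    return phantom


# ---------------------------------------------------------------------------
# nonparenchyma
# ---------------------------------------------------------------------------


def _place_vessels(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    voxel_um: float,
    n_vessels: int,
    lumen_radius_um: float,
    wall_radius_um: float,
    outer_radius_um: float,
    diameter_cv: float,
    max_tilt_rad: float = 0.12,
    max_tries: int = 200,
) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Sample near-axial vessel axes, stratified along y.

    Lumen+wall tubes must not intersect; perivascular shells may touch
    (they are the same connective-tissue compartment).  Infeasible
    geometry fails explicitly after bounded retries.
    """
    nz, ny, nx = shape
    placed: list[tuple[np.ndarray, np.ndarray, float]] = []
    sigma = math.sqrt(math.log(1.0 + diameter_cv**2)) if diameter_cv > 0 else 0.0
    # a vessel wider than the bronchovascular column cannot exist there:
    # the calibre (nominal and per-vessel draws) is capped at the fitting
    # maximum
    shell_um = outer_radius_um - lumen_radius_um
    r_l_max = (min(nx, ny) / 2.0 - 3.0) * voxel_um - shell_um
    if r_l_max < 2.0 * voxel_um:
        raise PackingError(
            f"block cross-section {ny}x{nx} voxels cannot hold a vessel with a "
            f"{shell_um:.0f} um wall+perivascular shell"
        )
    lumen_radius_um = min(lumen_radius_um, r_l_max)
    outer_radius_um = lumen_radius_um + shell_um
    pad_nom = outer_radius_um / voxel_um + 2.0
    y_lo, y_hi = pad_nom, ny - pad_nom
    strata = np.linspace(y_lo, y_hi, n_vessels + 1)
    # in a narrow bronchovascular column a tilted axis would leave the
    # block laterally; cap the tilt by the available lateral slack
    slack_x = max((nx - 2.0 * pad_nom) / 2.0, 0.2)
    max_tilt_rad = min(max_tilt_rad, slack_x / max(nz / 2.0, 1.0))
    wall_r_placed: list[float] = []
    for i in range(n_vessels):
        r_l = lumen_radius_um * (float(rng.lognormal(-0.5 * sigma**2, sigma)) if sigma else 1.0)
        r_l = min(r_l, r_l_max)
        r_wall = r_l + (wall_radius_um - lumen_radius_um)
        r_out = r_l + (outer_radius_um - lumen_radius_um)
        for _try in range(max_tries):
            tilt = rng.uniform(0.0, max_tilt_rad)
            azim = rng.uniform(0.0, 2.0 * math.pi)
            direction = np.array(
                [math.cos(tilt), math.sin(tilt) * math.sin(azim), math.sin(tilt) * math.cos(azim)]
            )
            pad = r_out / voxel_um + 2.0
            cy = rng.uniform(strata[i], strata[i + 1])
            cx = rng.uniform(pad, nx - pad)
            mid = np.array([nz / 2.0, cy, cx])
            half = (nz / 2.0 - 2.0) / max(direction[0], 1e-6)
            p0 = mid - half * direction
            p1 = mid + half * direction
            if not (
                pad <= min(p0[1], p1[1])
                and max(p0[1], p1[1]) <= ny - pad
                and pad <= min(p0[2], p1[2])
                and max(p0[2], p1[2]) <= nx - pad
            ):
                continue
            ok = True
            for (q0, q1, _q_out), q_wall in zip(placed, wall_r_placed):
                # exact minimum in-plane distance between the two axes
                # over the block depth (linear in z, so the minimum of
                # the quadratic |delta(t)|^2 is taken on [0, 1])
                d0 = (p0 - q0)[1:]
                d1 = (p1 - q1)[1:]
                dd = d1 - d0
                denom = float(dd @ dd)
                t_star = -float(d0 @ dd) / denom if denom > 0 else 0.0
                t_star = min(max(t_star, 0.0), 1.0)
                gap2 = float(np.sum((d0 + t_star * dd) ** 2))
                min_sep = (r_wall + q_wall) / voxel_um + 2.0
                if gap2 < min_sep**2:
                    ok = False
                    break
            if ok:
                placed.append((p0, p1, r_out))
                wall_r_placed.append(r_wall)
                break
        else:
            raise PackingError(
                f"could not place vessel {len(placed) + 1}/{n_vessels} after {max_tries} tries"
            )
    return placed


def _carve_vessels(
    labels: np.ndarray, preset: GroupPreset, rng: np.random.Generator, voxel_um: float
) -> dict:
    """Carve the preset's vessel population into ``labels``; returns the
    analytic bookkeeping (volumes, lateral surfaces, diameters)."""
    shape = labels.shape
    r_l = preset.vessel_diameter_um / 2.0
    r_w = r_l + preset.vessel_wall_thickness_um
    r_p = r_w + preset.perivascular_thickness_um
    vessels = _place_vessels(
        rng,
        shape,  # type: ignore[arg-type]
        voxel_um,
        preset.vessels_per_lung,
        r_l,
        r_w,
        r_p,
        diameter_cv=preset.variability.get("vessel_diameter_um", 0.0),
    )
    t_wall = r_w - r_l
    t_peri = r_p - r_w
    # carve in passes so one vessel's perivascular shell can never
    # overwrite another vessel's wall or lumen
    for p0, p1, r_out in vessels:
        rl = (r_out - (r_p - r_l)) / voxel_um
        _carve_capsule(
            labels, None, p0, p1, rl + (t_wall + t_peri) / voxel_um, Label.PERIVASCULAR
        )
    for p0, p1, r_out in vessels:
        rl = (r_out - (r_p - r_l)) / voxel_um
        _carve_capsule(labels, None, p0, p1, rl + t_wall / voxel_um, Label.VESSEL_WALL)
    analytic: dict = {"luminal_volume_um3": 0.0, "luminal_surface_um2": 0.0, "diameters_um": []}
    for p0, p1, r_out in vessels:
        rl = (r_out - (r_p - r_l)) / voxel_um  # this vessel's lumen radius, voxels
        length_um = float(np.linalg.norm(p1 - p0)) * voxel_um
        # flat end caps: shorten the lumen so wall covers the ends
        axis = (p1 - p0) / np.linalg.norm(p1 - p0)
        cap = t_wall / voxel_um
        _carve_capsule(labels, None, p0 + cap * axis, p1 - cap * axis, rl, Label.VESSEL_LUMEN)
        d_um = 2.0 * rl * voxel_um
        lum_len = length_um - 2.0 * t_wall
        analytic["luminal_volume_um3"] += math.pi * (d_um / 2.0) ** 2 * lum_len
        analytic["luminal_surface_um2"] += math.pi * d_um * lum_len
        analytic["diameters_um"].append(d_um)
    return analytic


def build_nonparenchyma_phantom(
    preset: GroupPreset,
    seed: int = 0,
    shape: tuple[int, int, int] = (256, 192, 192),
    voxel_um: float = 1.5,
    ground_truth: bool = True,
) -> Phantom3D:
    """Generate a nonparenchymal block: vessels in peribronchial tissue.

    Vessels are near-axial cylinders (lumen, concentric wall shell,
    concentric perivascular shell) embedded in a conducting-airway
    tissue filler, with flat wall caps so the lumen surface is entirely
    endothelial.  Overlapping vessels are re-sampled with bounded
    retries.  The attached ground truth stores both the voxel tallies
    and the analytic cylinder values in ``meta``.
    """
    rng = np.random.default_rng(seed)
    labels = np.full(shape, Label.AIRWAY, np.uint8)
    analytic = _carve_vessels(labels, preset, rng, voxel_um)
    phantom = Phantom3D(
        labels=labels,
        alveolus_id=np.zeros(shape, np.int32),
        voxel_um=voxel_um,
        seed=seed,
        meta={"kind": "nonparenchyma", "preset": preset.name, "analytic": analytic},
    )
    if ground_truth:
        phantom.ground_truth = compute_ground_truth(phantom)
    return phantom


def lattice_pitch_um(preset: GroupPreset) -> float:
    """Nominal cavity-lattice pitch implied by the preset's density."""
    density = preset.alveolar_number_density_per_um3 / max(
        1.0 - preset.duct_site_fraction, 1e-9
    )
    return density ** (-1.0 / 3.0)


def build_lung_phantom(
    preset: GroupPreset,
    seed: int = 0,
    nx: int = 256,
    ny: int = 256,
    voxel_um: float = 1.5,
    mode: str = "closed_cell",
    ground_truth: bool = True,
) -> Phantom3D:
    """Compose one whole miniature lung: parenchyma beside nonparenchyma.

    The block depth realizes the preset's (possibly jittered) target
    lung volume; a bronchovascular column occupying ``1 -
    parenchymal_fraction`` of the cross-section holds the vessels.
    ``nx``/``ny`` are nominal: the cross-section is snapped to whole
    cavity-lattice cells so the realized cell volume — and with it the
    realized septal thickness and mean cavity size — does not depend on
    how the preset's pitch happens to divide an arbitrary block size.
    """
    a = voxel_um
    pitch_vox = lattice_pitch_um(preset) / a
    # parenchymal cross-section snapped to whole lattice cells
    par_w = int(round(round(preset.parenchymal_fraction * nx / pitch_vox) * pitch_vox))
    par_w = max(par_w, int(math.ceil(pitch_vox)))
    ny = int(round(round(ny / pitch_vox) * pitch_vox))
    w_nonpar = int(round(par_w * (1.0 - preset.parenchymal_fraction)
                         / preset.parenchymal_fraction))
    nx = par_w + w_nonpar
    nz = int(round(preset.lung_volume_um3 / (nx * ny * a**3)))
    nz = max(nz, 64)

    rng = np.random.default_rng(seed)
    par_seed, nonpar_seed = rng.integers(0, 2**31 - 1, 2)

    par = build_parenchyma_phantom(
        preset,
        mode=mode,
        seed=int(par_seed),
        shape=(nz, ny, par_w),
        voxel_um=a,
        ground_truth=False,
    )
    labels = np.full((nz, ny, nx), Label.AIRWAY, np.uint8)
    ident = np.zeros((nz, ny, nx), np.int32)
    labels[:, :, w_nonpar:] = par.labels
    ident[:, :, w_nonpar:] = par.alveolus_id

    region = labels[:, :, :w_nonpar]
    nonpar_rng = np.random.default_rng(int(nonpar_seed))
    _carve_vessels(region, preset, nonpar_rng, a)

    phantom = Phantom3D(
        labels=labels,
        alveolus_id=ident,
        voxel_um=a,
        seed=seed,
        meta={
            "kind": "lung",
            "preset": preset.name,
            "nonpar_width_vox": w_nonpar,
            "parenchyma_meta": par.meta,
        },
    )
    if ground_truth:
        phantom.ground_truth = compute_ground_truth(phantom)
    return phantom


# ---------------------------------------------------------------------------
# analytic primitives (oracles for the estimator identities)
# ---------------------------------------------------------------------------


def build_sphere_phantom(
    radius_um: float, voxel_um: float = 1.0, pad_um: float = 6.0, seed: int = 0
) -> Phantom3D:
    """Single alveolar cavity in septum, analytic V and S in ``meta``."""
    n = int(math.ceil(2 * (radius_um + pad_um) / voxel_um)) | 1
    labels = np.full((n, n, n), Label.SEPTUM, np.uint8)
    ident = np.zeros((n, n, n), np.int32)
    c = (n - 1) / 2.0
    _carve_ball(labels, ident, (c, c, c), radius_um / voxel_um, Label.ALVEOLAR_AIR, 1)
    ph = Phantom3D(
        labels,
        ident,
        voxel_um,
        seed,
        meta={
            "kind": "sphere",
            "analytic": {
                "volume_um3": (4.0 / 3.0) * math.pi * radius_um**3,
                "surface_um2": 4.0 * math.pi * radius_um**2,
            },
        },
    )
    ph.ground_truth = compute_ground_truth(ph)
    return ph


def build_plate_phantom(
    thickness_um: float, extent_vox: int = 64, voxel_um: float = 1.0
) -> Phantom3D:
    """Axis-aligned septal plate between two half-space airspaces.

    Plate identity: 2 V / S = thickness exactly (with the face-count
    surface, which is exact for axis-aligned interfaces).
    """
    t = int(round(thickness_um / voxel_um))
    if t < 1:
        raise ValueError("plate thinner than one voxel")
    n = extent_vox
    labels = np.full((n, n, n), Label.ALVEOLAR_AIR, np.uint8)
    z0 = (n - t) // 2
    labels[z0 : z0 + t] = Label.SEPTUM
    ident = np.zeros_like(labels, np.int32)
    area = (n * voxel_um) ** 2
    ph = Phantom3D(
        labels,
        ident,
        voxel_um,
        meta={
            "kind": "plate",
            "analytic": {
                "septal_volume_um3": area * t * voxel_um,
                "septal_surface_um2": 2.0 * area,  # both airspace-facing sides
            },
        },
    )
    ph.ground_truth = compute_ground_truth(ph, surface_method="faces")
    return ph


def build_cylinder_phantom(
    lumen_diameter_um: float,
    wall_thickness_um: float = 0.0,
    perivascular_thickness_um: float = 0.0,
    length_um: float | None = None,
    voxel_um: float = 1.0,
) -> Phantom3D:
    """Single axial vessel with analytic cylinder identities in ``meta``.

    For the lumen, 4V/S equals the diameter exactly; a thin wall shell
    satisfies V_wall / S_lumen ~ thickness.
    """
    r_l = lumen_diameter_um / 2.0
    r_out = r_l + wall_thickness_um + perivascular_thickness_um
    if length_um is None:
        length_um = 4.0 * lumen_diameter_um
    nz = int(math.ceil(length_um / voxel_um)) + 8
    nxy = int(math.ceil(2 * (r_out + 4.0) / voxel_um)) | 1
    labels = np.full((nz, nxy, nxy), Label.AIRWAY, np.uint8)
    c = (nxy - 1) / 2.0
    p0 = np.array([4.0, c, c])
    p1 = np.array([4.0 + length_um / voxel_um, c, c])
    if perivascular_thickness_um:
        _carve_capsule(labels, None, p0, p1, r_out / voxel_um, Label.PERIVASCULAR)
    if wall_thickness_um:
        _carve_capsule(
            labels, None, p0, p1, (r_l + wall_thickness_um) / voxel_um, Label.VESSEL_WALL
        )
    _carve_capsule(labels, None, p0, p1, r_l / voxel_um, Label.VESSEL_LUMEN)
    d, L = lumen_diameter_um, length_um
    ph = Phantom3D(
        labels,
        np.zeros_like(labels, np.int32),
        voxel_um,
        meta={
            "kind": "cylinder",
            "analytic": {
                "luminal_volume_um3": math.pi * (d / 2.0) ** 2 * L,
                "luminal_surface_um2": math.pi * d * L,
                "wall_volume_um3": math.pi
                * ((r_l + wall_thickness_um) ** 2 - r_l**2)
                * L,
                "diameter_um": d,
            },
        },
    )
    ph.ground_truth = compute_ground_truth(ph)
    return ph


# ---------------------------------------------------------------------------
# sectioning
# ---------------------------------------------------------------------------


def _dominant_label_slab(labels_slab: np.ndarray) -> np.ndarray:
    """Per-pixel dominant label across the slab's planes (first-max tie-break)."""
    n_lab = int(labels_slab.max()) + 1
    counts = np.zeros((n_lab,) + labels_slab.shape[1:], np.int16)
    for k in range(labels_slab.shape[0]):
        plane = labels_slab[k]
        np.add.at(counts, (plane,) + tuple(np.indices(plane.shape)), 1)
    return counts.argmax(axis=0).astype(np.uint8)


def extract_section(phantom: Phantom3D, z_um: float, thickness_um: float = 1.5) -> SectionImage:
    """Cut one physical section; finite thickness uses a dominant-label
    projection over the voxel planes the slab covers (deterministic,
    no sub-voxel interpolation)."""
    a = phantom.voxel_um
    depth = phantom.depth_um
    if not 0.0 <= z_um <= depth:
        raise ValueError(f"section position {z_um} um outside block depth {depth} um")
    # the slab covers round(t/a) whole voxel planes centred on z; a nominal
    # thickness at or below one voxel maps to exactly one plane, so thin
    # sections never mix two planes through the projection tie-break
    n_planes = max(1, int(round(thickness_um / a)))
    k_mid = min(int(z_um / a), phantom.labels.shape[0] - 1)
    k0 = max(k_mid - (n_planes - 1) // 2, 0)
    k1 = min(k0 + n_planes, phantom.labels.shape[0])
    k0 = min(k0, k1 - 1)
    slab = phantom.labels[k0:k1]
    if k1 - k0 == 1:
        lab2d = slab[0].copy()
        id2d = phantom.alveolus_id[k0].copy()
    else:
        lab2d = _dominant_label_slab(slab)
        # identity: first plane in the slab whose label matches the projection
        id2d = np.zeros(lab2d.shape, np.int32)
        unset = np.ones(lab2d.shape, bool)
        for k in range(k0, k1):
            match = unset & (phantom.labels[k] == lab2d)
            id2d[match] = phantom.alveolus_id[k][match]
            unset &= ~match
    center_um = (k0 + (k1 - k0) / 2.0) * a
    return SectionImage(
        labels=lab2d,
        alveolus_id=id2d,
        z_um=center_um,
        thickness_um=(k1 - k0) * a,
        pixel_um=a,
    )


def extract_disector_pairs(
    phantom: Phantom3D,
    pair_positions_um: Sequence[float],
    spacing_within_pair_um: float = 4.5,
    section_thickness_um: float = 1.5,
) -> list[DisectorPair]:
    """Extract aligned section pairs; ``h`` is the realized plane-centre
    distance (equal to the requested spacing whenever the spacing is an
    integer number of voxel planes)."""
    if spacing_within_pair_um <= 0:
        raise ValueError("pair spacing must be positive")
    pairs = []
    for z in pair_positions_um:
        ref = extract_section(phantom, z, section_thickness_um)
        look = extract_section(phantom, z + spacing_within_pair_um, section_thickness_um)
        h = look.z_um - ref.z_um
        if h <= 0:
            raise ValueError(f"pair at z={z} um collapses onto one plane")
        pairs.append(DisectorPair(reference=ref, lookup=look, h_um=h))
    return pairs
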