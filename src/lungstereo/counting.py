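"""Raw stereological counts on labelled rasters.

Everything here is a counting rule, not an estimator: points landing on
labels, test-line/boundary intersections, disector island/bridge events
between paired sections, and vessel-profile measurements with the
>25 um calibre cutoff.  All rules operate on integer-labelled rasters
and are deterministic given the realized grids.

Conventions (validated against the phantom oracle):

* airspace profiles use 8-connectivity (septa are then implicitly
  4-connected — the standard complementary pairing);
* counting-frame rule: profiles touching the left or bottom frame edge
  are rejected, others accepted;
* component correspondence across a disector pair: nonzero pixel
  overlap (the disector height is small against the cavity calibre);
* a k-fold merge counts k - 1 bridge events (Euler additivity);
* intersections are label transitions along the line's pixel trace.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .phantom import ALVEOLAR_AIRSPACE_LABELS, DisectorPair, Label, SectionImage
from .sampling import RealizedGrid

_EIGHT = np.ones((3, 3), dtype=int)


class CountingError(RuntimeError):
    pass


@dataclass
class TallySheet:
    """Accumulated raw counts for one lung and one sampling stage."""

    point_counts: dict[int, int] = field(default_factory=dict)
    intersections: int = 0
    ref_points: int = 0
    accounted_length_um: float = 0.0
    islands: int = 0
    bridges: int = 0
    frames: int = 0
    disector_volume_um3: float = 0.0
    fields: int = 0

    def add_points(self, counts: dict[int, int]) -> None:
        for lab, n in counts.items():
            self.point_counts[lab] = self.point_counts.get(lab, 0) + n
        self.fields += 1

    def points_on(self, labels: Iterable[int]) -> int:
        return sum(self.point_counts.get(int(lab), 0) for lab in labels)

    def to_row(self) -> dict:
        row = {f"P_{Label(lab).name}": n for lab, n in sorted(self.point_counts.items())}
        row.update(
            I=self.intersections,
            P_ref=self.ref_points,
            L_um=self.accounted_length_um,
            islands=self.islands,
            bridges=self.bridges,
            frames=self.frames,
            disector_volume_um3=self.disector_volume_um3,
            fields=self.fields,
        )
        return row


def _points_to_pixels(
    grid: RealizedGrid,
    origin_um: tuple[float, float],
    raster_shape: tuple[int, int],
    pixel_um: float,
) -> np.ndarray:
    """Absolute pixel indices of grid points; off-raster points dropped
    (fields may be clipped by the section border)."""
    pts = grid.points_um + np.asarray(origin_um)
    px = np.floor(pts / pixel_um).astype(int)
    keep = (
        (px[:, 0] >= 0)
        & (px[:, 0] < raster_shape[0])
        & (px[:, 1] >= 0)
        & (px[:, 1] < raster_shape[1])
    )
    return px[keep]


def count_points(
    raster: np.ndarray,
    points_px: np.ndarray,
) -> dict[int, int]:
    """Label tally under test points given as (row, col) pixel indices."""
    if len(points_px) == 0:
        return {}
    if (
        points_px.min() < 0
        or points_px[:, 0].max() >= raster.shape[0]
        or points_px[:, 1].max() >= raster.shape[1]
    ):
        raise CountingError("test point outside the raster (grid placement bug)")
    labs = raster[points_px[:, 0], points_px[:, 1]]
    vals, counts = np.unique(labs, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts)}


def count_points_on_field(
    section: SectionImage,
    grid: RealizedGrid,
    origin_um: tuple[float, float],
    raster: np.ndarray | None = None,
) -> dict[int, int]:
    """Convenience wrapper: realize grid points on a field of a section."""
    raster = section.labels if raster is None else raster
    px = _points_to_pixels(grid, origin_um, raster.shape, section.pixel_um)
    return count_points(raster, px)


def count_line_intersections(
    section: SectionImage,
    grid: RealizedGrid,
    origin_um: tuple[float, float],
    class_a: Iterable[int],
    class_b: Iterable[int],
    ref_labels: Iterable[int],
    raster: np.ndarray | None = None,
) -> tuple[int, int, float]:
    """Count boundary intersections of the line grid with a label-pair.

    Returns ``(I, P_ref, L_um)``: transitions between the two classes
    along each line's pixel trace, grid points landing in the reference
    space, and the accounted test-line length ``P_ref x l/p``.
    """
    if grid.lines_um is None:
        raise ValueError("grid carries no lines")
    raster = section.labels if raster is None else raster
    a = section.pixel_um
    labs_a, labs_b = list(class_a), list(class_b)

    intersections = 0
    for y_um, x0_um, x1_um in grid.lines_um:
        row = int((y_um + origin_um[0]) // a)
        if not 0 <= row < raster.shape[0]:
            continue
        c0 = max(int((x0_um + origin_um[1]) // a), 0)
        c1 = min(int(np.ceil((x1_um + origin_um[1]) / a)), raster.shape[1])
        if c1 - c0 < 2:
            continue
        line = raster[row, c0:c1]
        trace = np.zeros(line.shape, np.int16)
        trace[np.isin(line, labs_a)] = 1
        trace[np.isin(line, labs_b)] = 2
        prod = trace[:-1] * trace[1:]
        intersections += int(np.count_nonzero(prod == 2))  # 1*2: one pixel each class

    px = _points_to_pixels(grid, origin_um, raster.shape, a)
    if len(px):
        labs = raster[px[:, 0], px[:, 1]]
        p_ref = int(np.count_nonzero(np.isin(labs, list(ref_labels))))
    else:
        p_ref = 0
    length_um = p_ref * grid.lp_um
    # a single field may legitimately see intersections while no grid
    # point hits the reference space; only a grid with no points at all
    # can never account for its length
    if intersections and len(grid.points_um) == 0:
        raise CountingError("intersections counted with a grid that carries no points")
    return intersections, p_ref, length_um


# ---------------------------------------------------------------------------
# disector
# ---------------------------------------------------------------------------


def _frame_crop(
    shape: tuple[int, int], frame_um: tuple[float, float, float, float], pixel_um: float
) -> tuple[slice, slice]:
    y0 = int(frame_um[0] // pixel_um)
    x0 = int(frame_um[1] // pixel_um)
    y1 = int(np.ceil(frame_um[2] / pixel_um))
    x1 = int(np.ceil(frame_um[3] / pixel_um))
    if y0 < 0 or x0 < 0 or y1 > shape[0] or x1 > shape[1]:
        raise CountingError("counting frame extends outside the section")
    return slice(y0, y1), slice(x0, x1)


class _ComponentSelector:
    """Unbiased counting-frame selection over a labelled component raster.

    Implements the classic frame rule — two forbidden edges (left,
    bottom) plus their extensions — in its exact set form: a component
    is counted by frame (y0, x0, y1, x1) iff it intersects the frame,
    has no pixel on or below the bottom line (y >= y1), and no pixel
    left of the left line within the upper half-plane (x < x0, y < y1).
    Over a tiling of frames every component is counted exactly once, so
    the sampling probability of any profile equals the frame area over
    the tile area.
    """

    def __init__(self, lab: np.ndarray):
        self.lab = lab
        ids = np.unique(lab)
        self.ids = ids[ids > 0]
        n = len(self.ids)
        h, w = lab.shape
        yy, xx = np.nonzero(lab > 0)
        if n:
            k = np.searchsorted(self.ids, lab[yy, xx])
            self.max_y = np.full(n, -1, np.int64)
            np.maximum.at(self.max_y, k, yy)
            min_x_by_row = np.full((n, h), w + 1, np.int64)
            np.minimum.at(min_x_by_row, (k, yy), xx)
            # prefix_min_x[c, y] = leftmost pixel of component c in rows <= y
            self.prefix_min_x = np.minimum.accumulate(min_x_by_row, axis=1)
        else:
            self.max_y = np.empty(0, np.int64)
            self.prefix_min_x = np.empty((0, h), np.int64)

    def select(self, frame_px: tuple[int, int, int, int] | None) -> np.ndarray:
        if frame_px is None:
            return self.ids
        fy0, fx0, fy1, fx1 = frame_px
        h, w = self.lab.shape
        # the frame may extend past the raster (empty slide canvas); only
        # the candidate crop needs clipping, the rule tests use the raw
        # frame coordinates
        cand = np.unique(self.lab[max(fy0, 0) : min(fy1, h), max(fx0, 0) : min(fx1, w)])
        cand = cand[cand > 0]
        if cand.size == 0 or fy1 < 1:
            return cand[:0]
        k = np.searchsorted(self.ids, cand)
        ok = self.max_y[k] < fy1
        ok &= self.prefix_min_x[k, min(fy1, h) - 1] >= fx0
        return cand[ok]


@dataclass
class DisectorEvents:
    """Island/bridge tallies for one disector frame, per direction."""

    islands_ab: int
    bridges_ab: int
    islands_ba: int
    bridges_ba: int
    frame_area_um2: float
    h_um: float

    @property
    def net_events(self) -> int:
        """Sum over both directions of (islands - bridges)."""
        return self.islands_ab - self.bridges_ab + self.islands_ba - self.bridges_ba

    @property
    def disector_volume_um3(self) -> float:
        return self.frame_area_um2 * self.h_um


def _overlap_counts(look_lab: np.ndarray, ref_lab: np.ndarray) -> dict[int, int]:
    """For every look-up component id, the number of distinct reference
    components it overlaps (pixelwise, over the full sections)."""
    sel = look_lab > 0
    pairs = np.stack([look_lab[sel], ref_lab[sel]])
    uniq = np.unique(pairs, axis=1)
    counts: dict[int, int] = {}
    for b, r in uniq.T:
        counts.setdefault(int(b), 0)
        if r:
            counts[int(b)] += 1
    return counts


def _directional_events(
    overlap: dict[int, int], counted_ids: np.ndarray
) -> tuple[int, int]:
    """Islands and bridges seen going from the reference to the look-up.

    Correspondence is judged on the full sections (a profile clipped by
    the frame must still find its counterpart outside it); ``counted_ids``
    restricts which look-up components contribute events.  An island is
    a counted component with no pixel overlap in the reference; a
    component overlapping k reference components contributes k - 1
    bridge events.
    """
    islands = bridges = 0
    for b in counted_ids:
        k = overlap.get(int(b), 0)
        if k == 0:
            islands += 1
        else:
            bridges += k - 1
    return islands, bridges


def disector_frame_events(
    pair: DisectorPair,
    frames_um: Sequence[tuple[float, float, float, float] | None],
    labels_of_interest: Iterable[int] = tuple(sorted(ALVEOLAR_AIRSPACE_LABELS)),
) -> list[DisectorEvents]:
    """Euler-characteristic event counting for many frames on one pair.

    Component labelling and the frame-rule geometry are computed once
    per pair; each entry of ``frames_um`` is (y0, x0, y1, x1) in section
    coordinates, or ``None`` for the whole image with the frame rule
    disabled (exhaustive mode).  Frames may extend beyond the raster:
    the slide canvas around the specimen is empty, and allowing such
    placements keeps the acceptance measure of border profiles intact.
    """
    sec_a, sec_b = pair.reference, pair.lookup
    a = sec_a.pixel_um
    labs = list(labels_of_interest)
    lab_a, _ = ndimage.label(np.isin(sec_a.labels, labs), structure=_EIGHT)
    lab_b, _ = ndimage.label(np.isin(sec_b.labels, labs), structure=_EIGHT)
    sel_a = _ComponentSelector(lab_a)
    sel_b = _ComponentSelector(lab_b)
    overlap_b = _overlap_counts(lab_b, lab_a)
    overlap_a = _overlap_counts(lab_a, lab_b)
    out = []
    for frame_um in frames_um:
        if frame_um is None:
            frame_px = None
            area = sec_a.height_um * sec_a.width_um
        else:
            fy0 = int(math.floor(frame_um[0] / a))
            fx0 = int(math.floor(frame_um[1] / a))
            fy1 = int(math.ceil(frame_um[2] / a))
            fx1 = int(math.ceil(frame_um[3] / a))
            frame_px = (fy0, fx0, fy1, fx1)
            # the realized (pixel-snapped) frame is the acceptance region
            # the counting rule uses, so it defines the disector volume
            area = (fy1 - fy0) * (fx1 - fx0) * a * a
        isl_ab, br_ab = _directional_events(overlap_b, sel_b.select(frame_px))
        isl_ba, br_ba = _directional_events(overlap_a, sel_a.select(frame_px))
        out.append(
            DisectorEvents(
                islands_ab=isl_ab,
                bridges_ab=br_ab,
                islands_ba=isl_ba,
                bridges_ba=br_ba,
                frame_area_um2=area,
                h_um=pair.h_um,
            )
        )
    return out


def count_disector_events(
    pair: DisectorPair,
    frame_um: tuple[float, float, float, float] | None = None,
    labels_of_interest: Iterable[int] = tuple(sorted(ALVEOLAR_AIRSPACE_LABELS)),
) -> DisectorEvents:
    """Euler-characteristic event counting between paired sections.

    ``frame_um`` is (y0, x0, y1, x1) in section coordinates; ``None``
    uses the full image as the frame with the edge rule disabled
    (exhaustive mode).  Alveolar cavities are counted from events in
    the alveolar-airspace label class.
    """
    return disector_frame_events(pair, [frame_um], labels_of_interest)[0]


def count_alveoli_by_identity(
    pair: DisectorPair,
    frame_um: tuple[float, float, float, float] | None = None,
) -> int:
    """Brute-force oracle for disector islands using identity labels.

    Counts alveolus identities whose frame-accepted profile is present
    in one section of the pair with no pixel of the same identity in
    the other, summed over both directions.  Only available on phantom
    data.
    """
    if pair.reference.alveolus_id is None or pair.lookup.alveolus_id is None:
        raise CountingError("identity raster missing: oracle needs phantom sections")
    a = pair.reference.pixel_um
    if frame_um is None:
        frame_px = None
    else:
        frame_px = (
            int(math.floor(frame_um[0] / a)),
            int(math.floor(frame_um[1] / a)),
            int(math.ceil(frame_um[2] / a)),
            int(math.ceil(frame_um[3] / a)),
        )
    events = 0
    id_a = pair.reference.alveolus_id
    id_b = pair.lookup.alveolus_id
    for look, ref in ((id_b, id_a), (id_a, id_b)):
        counted = set(_ComponentSelector(look).select(frame_px).tolist())
        other = set(np.unique(ref).tolist()) - {0}
        events += len(counted - other)
    return events


# ---------------------------------------------------------------------------
# vessel profiles
# ---------------------------------------------------------------------------


@dataclass
class VesselProfile:
    """One vessel profile on a section."""

    lumen_area_um2: float
    boundary_length_um: float
    wall_area_um2: float
    perivascular_area_um2: float
    short_axis_um: float
    included: bool
    centroid_px: tuple[float, float]


@dataclass
class VesselProfileSet:
    profiles: list[VesselProfile]
    #: pixel mask of lumen+wall+perivascular tissue belonging to included profiles
    included_mask: np.ndarray

    def __iter__(self):
        return iter(self.profiles)

    @property
    def n_included(self) -> int:
        return sum(p.included for p in self.profiles)

    def to_rows(self) -> list[dict]:
        return [
            {
                "lumen_area_um2": p.lumen_area_um2,
                "boundary_length_um": p.boundary_length_um,
                "wall_area_um2": p.wall_area_um2,
                "perivascular_area_um2": p.perivascular_area_um2,
                "short_axis_um": p.short_axis_um,
                "included": p.included,
            }
            for p in self.profiles
        ]


def _min_feret_um(mask: np.ndarray, pixel_um: float) -> float:
    """Minimum caliper (Feret) diameter via rotating the convex hull."""
    ys, xs = np.nonzero(mask)
    if len(ys) < 3:
        return float(np.sqrt(len(ys))) * pixel_um
    # pixel corners so single-pixel-wide shapes keep finite width
    pts = np.concatenate(
        [
            np.stack([ys - 0.5, xs - 0.5], 1),
            np.stack([ys - 0.5, xs + 0.5], 1),
            np.stack([ys + 0.5, xs - 0.5], 1),
            np.stack([ys + 0.5, xs + 0.5], 1),
        ]
    )
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return float(np.sqrt(mask.sum())) * pixel_um
    verts = pts[hull.vertices]
    n = len(verts)
    best = np.inf
    for i in range(n):
        p, q = verts[i], verts[(i + 1) % n]
        edge = q - p
        norm = np.linalg.norm(edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        width = np.ptp((verts - p) @ normal)
        best = min(best, width)
    return float(best) * pixel_um


def _perimeter_um(mask: np.ndarray, pixel_um: float) -> float:
    """2D Cauchy (rotation-averaged intercept) boundary length."""
    t = 0
    for ax in (0, 1):
        t += int(np.abs(np.diff(mask.astype(np.int8), axis=ax)).sum())
    return float(np.pi / 4.0 * t) * pixel_um


def classify_vessel_profiles(
    section: SectionImage,
    min_diameter_um: float = 25.0,
) -> VesselProfileSet:
    """Measure vessel profiles and apply the calibre cutoff.

    The profile diameter is the short-axis caliper of the lumen, which
    for a cylinder is invariant to cut obliquity, matching the intent
    of a true-diameter cutoff.  Wall and perivascular pixels are
    attributed to their nearest lumen profile; wall fragments with no
    lumen in the field are logged and excluded.
    """
    raster = section.labels
    a = section.pixel_um
    lumen = raster == Label.VESSEL_LUMEN
    wall = raster == Label.VESSEL_WALL
    peri = raster == Label.PERIVASCULAR

    lum_lab, n_lum = ndimage.label(lumen, structure=_EIGHT)
    profiles: list[VesselProfile] = []
    included_mask = np.zeros(raster.shape, bool)
    if n_lum == 0:
        if wall.any():
            warnings.warn("vessel wall without any lumen profile in field; excluded")
        return VesselProfileSet(profiles=profiles, included_mask=included_mask)

    # attribute wall/perivascular pixels to the nearest lumen profile
    _dist, (iy, ix) = ndimage.distance_transform_edt(lum_lab == 0, return_indices=True)
    owner = lum_lab[iy, ix]
    wall_areas = ndimage.sum_labels(wall, owner, np.arange(1, n_lum + 1))
    peri_areas = ndimage.sum_labels(peri, owner, np.arange(1, n_lum + 1))
    centroids = ndimage.center_of_mass(lumen, lum_lab, np.arange(1, n_lum + 1))

    for i in range(1, n_lum + 1):
        comp = lum_lab == i
        area = float(comp.sum()) * a * a
        short_axis = _min_feret_um(comp, a)
        inc = short_axis > min_diameter_um
        profiles.append(
            VesselProfile(
                lumen_area_um2=area,
                boundary_length_um=_perimeter_um(comp, a),
                wall_area_um2=float(wall_areas[i - 1]) * a * a,
                perivascular_area_um2=float(peri_areas[i - 1]) * a * a,
                short_axis_um=short_axis,
                included=inc,
                centroid_px=tuple(centroids[i - 1]),
            )
        )
        if inc:
            included_mask |= comp
            included_mask |= (owner == i) & (wall | peri)
    return VesselProfileSet(profiles=profiles, included_mask=included_mask)
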