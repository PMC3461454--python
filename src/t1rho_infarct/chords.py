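"""Chord segmentation of the myocardial annulus.

Each short-axis slice is divided into circumferential wedges (default 20,
18° each) and radial sections (default 5) about the cardiac centroid, here
taken as the area centroid of the epicardial contour.  Wedge index comes
from the polar angle of a pixel about the centroid; radial index from its
normalized transmural depth between the endocardial and epicardial contours
along the centroid ray (section 1 = subendocardial, section 5 =
subepicardial, so "mid-myocardium" is literally sections 2-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon


@dataclass
class ContourPair:
    """Epicardial and endocardial polygons for one slice.

    Polygons are ordered counterclockwise, closed (last vertex repeats the
    first) and expressed in pixel-center coordinates (x = column, y = row);
    ``pixel_spacing`` converts vertex distances to mm.
    """

    slice_index: int
    epicardium: np.ndarray  # (N+1, 2), closed
    endocardium: np.ndarray
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.epicardium = np.asarray(self.epicardium, dtype=float)
        self.endocardium = np.asarray(self.endocardium, dtype=float)
        for name, poly in (("epicardium", self.epicardium),
                           ("endocardium", self.endocardium)):
            if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 4:
                raise ValueError(f"{name} must be a closed (N+1, 2) polygon")
            if not np.allclose(poly[0], poly[-1]):
                raise ValueError(f"{name} polygon is not closed")

    def validate(self) -> None:
        """Check simplicity and strict nesting (endo inside epi)."""
        epi = Polygon(self.epicardium)
        endo = Polygon(self.endocardium)
        if not epi.is_valid or not endo.is_valid:
            raise ValueError(
                f"slice {self.slice_index}: self-intersecting contour"
            )
        if not epi.contains(endo):
            raise ValueError(
                f"slice {self.slice_index}: endocardium not strictly inside "
                "epicardium"
            )

    def endocardial_perimeter_mm(self) -> float:
        seg = np.diff(self.endocardium, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum() * self.pixel_spacing)


@dataclass
class ChordGrid:
    """Per-pixel wedge/radial assignment for a slice stack.

    wedge, radial : int arrays shaped like the mask; 0 marks unassigned
                    pixels, assigned pixels carry 1-based sector indices.
    centroids     : per-slice (x, y) cardiac centroid, pixel coordinates.
    n_fallback    : pixels whose depth fell outside [0, 1) and were clamped
                    into the nearest section.
    """

    wedge: np.ndarray
    radial: np.ndarray
    centroids: dict[int, tuple[float, float]]
    n_wedges: int = 20
    n_radial: int = 5
    reference_angle_deg: float = 0.0
    n_fallback: int = 0
    contours: dict[int, ContourPair] = field(default_factory=dict)

    @property
    def assigned(self) -> np.ndarray:
        return self.wedge > 0

    def sector_mask(self, slice_index: int, wedge: int, radial: int) -> np.ndarray:
        m = np.zeros_like(self.wedge, dtype=bool)
        m[slice_index] = (self.wedge[slice_index] == wedge) & \
                         (self.radial[slice_index] == radial)
        return m


@dataclass
class SectorTable:
    """Per-sector mean signal plus the normalized mid-myocardial profile.

    table : one row per (slice, wedge, radial) sector: pixel count, mean
            signal, and mean normalized by the maximum over nonempty sectors.
    midwall : per (slice, wedge) mean over radial sections 2-4 (the
            mid-myocardium), normalized to the maximum value.
    """

    table: pd.DataFrame
    midwall: pd.DataFrame


# ---------------------------------------------------------------------------

def polygon_area_centroid(polygon: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Signed shoelace area and area centroid of a closed polygon."""
    x, y = polygon[:-1, 0], polygon[:-1, 1]
    xn, yn = polygon[1:, 0], polygon[1:, 1]
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-12:
        raise ValueError("degenerate polygon: area is (near) zero")
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return float(area), (float(cx), float(cy))


def cardiac_centroid(contours: ContourPair) -> tuple[float, float]:
    """Cardiac centroid of a slice: area centroid of the epicardial polygon."""
    _, centroid = polygon_area_centroid(contours.epicardium)
    return centroid


def _polar_radius_interpolator(polygon: np.ndarray,
                               centroid: tuple[float, float]):
    """Radius-vs-angle interpolator for a star-shaped contour."""
    cx, cy = centroid
    pts = polygon[:-1]
    theta = np.degrees(np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx)) % 360.0
    r = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    order = np.argsort(theta)
    theta, r = theta[order], r[order]
    # pad for periodic interpolation
    theta_p = np.concatenate([[theta[-1] - 360.0], theta, [theta[0] + 360.0]])
    r_p = np.concatenate([[r[-1]], r, [r[0]]])

    def radius_at(query_deg: np.ndarray) -> np.ndarray:
        return np.interp(np.mod(query_deg, 360.0), theta_p, r_p)

    return radius_at


def build_chord_grid(contours: list[ContourPair], mask: np.ndarray,
                     n_wedges: int = 20, n_radial: int = 5,
                     reference_angle_deg: float = 0.0) -> ChordGrid:
    """Assign every masked myocardial pixel to one (wedge, radial) sector.

    Wedge 1 starts at ``reference_angle_deg`` (degrees CCW from +x) and
    wedges advance counterclockwise.  Transmural depth d ∈ [0, 1) along the
    centroid ray maps to radial section floor(n_radial·d) + 1; pixels whose
    depth falls outside [0, 1) (contour discretization) are clamped into the
    nearest section and counted in ``n_fallback``.
    """
    if mask.ndim != 3:
        raise ValueError("mask must be (n_slices, ny, nx)")
    wedge = np.zeros(mask.shape, dtype=np.int16)
    radial = np.zeros(mask.shape, dtype=np.int16)
    centroids: dict[int, tuple[float, float]] = {}
    contour_map = {c.slice_index: c for c in contours}
    wedge_width = 360.0 / n_wedges
    n_fallback = 0

    for z in range(mask.shape[0]):
        yy, xx = np.nonzero(mask[z])
        if len(yy) == 0:
            continue
        if z not in contour_map:
            raise ValueError(f"no contours supplied for masked slice {z}")
        pair = contour_map[z]
        centroid = cardiac_centroid(pair)
        centroids[z] = centroid
        endo_r = _polar_radius_interpolator(pair.endocardium, centroid)
        epi_r = _polar_radius_interpolator(pair.epicardium, centroid)

        dx, dy = xx - centroid[0], yy - centroid[1]
        theta = np.degrees(np.arctan2(dy, dx)) % 360.0
        r = np.hypot(dx, dy)
        w = (np.floor(((theta - reference_angle_deg) % 360.0) / wedge_width)
             .astype(np.int16) % n_wedges) + 1

        r_in, r_out = endo_r(theta), epi_r(theta)
        depth = (r - r_in) / np.maximum(r_out - r_in, 1e-9)
        out_of_wall = (depth < 0) | (depth >= 1.0)
        n_fallback += int(out_of_wall.sum())
        depth = np.clip(depth, 0.0, np.nextafter(1.0, 0.0))
        rad = np.floor(n_radial * depth).astype(np.int16) + 1

        wedge[z, yy, xx] = w
        radial[z, yy, xx] = rad

    return ChordGrid(wedge=wedge, radial=radial, centroids=centroids,
                     n_wedges=n_wedges, n_radial=n_radial,
                     reference_angle_deg=reference_angle_deg,
                     n_fallback=n_fallback, contours=contour_map)


def sector_signal(grid: ChordGrid, image: np.ndarray) -> SectorTable:
    """Per-sector mean signal, normalized to the maximum over the table.

    The mid-myocardial profile averages radial sections 2-4 per wedge, the
    wall interior where partial-volume contamination from blood and
    epicardial fat is least, and is likewise normalized to its maximum.
    """
    if image.shape != grid.wedge.shape:
        raise ValueError(
            f"image shape {image.shape} does not match grid {grid.wedge.shape}"
        )
    assigned = grid.assigned
    z, yy, xx = np.nonzero(assigned)
    df = pd.DataFrame({
        "slice": z,
        "wedge": grid.wedge[assigned],
        "radial": grid.radial[assigned],
        "signal": image[assigned],
    })
    table = (df.groupby(["slice", "wedge", "radial"], as_index=False)
               .agg(n_pixels=("signal", "size"), mean=("signal", "mean")))
    if len(table):
        table["normalized"] = table["mean"] / table["mean"].max()
    else:
        table["normalized"] = pd.Series(dtype=float)

    mid = df[(df["radial"] >= 2) & (df["radial"] <= 4)]
    midwall = (mid.groupby(["slice", "wedge"], as_index=False)
                 .agg(n_pixels=("signal", "size"), mean=("signal", "mean")))
    if len(midwall):
        midwall["normalized"] = midwall["mean"] / midwall["mean"].max()
    else:
        midwall["normalized"] = pd.Series(dtype=float)
    return SectorTable(table=table, midwall=midwall)
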