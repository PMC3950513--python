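"""Per-cell pixel meshes and long-axis geometry.

Every downstream statistic in this package (focus localization, random
placement nulls, line profiles, axial tracking) consumes only two things
per cell: the set of member pixels and a principal long axis.  This module
produces both, either by segmenting a phase-contrast image with a
threshold/label approach or by ingesting a label image from an external
segmenter.  Subpixel active-contour outlines are deliberately not
attempted; masks from any dedicated tool can be injected via
:func:`load_masks` and honour the same contract.

Conventions
-----------
Coordinates are 0-based ``(row, col)`` with the pixel-center convention:
the pixel at index ``(r, c)`` occupies the unit square centred on the
continuous point ``(r, c)``.  All distances are computed in continuous
pixel coordinates; conversion to nanometres is a multiplication by the
pixel size downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology


class InputError(ValueError):
    """Raised when an input image violates a precondition."""


@dataclass
class CellMesh:
    """One segmented cell: pixel membership, boundary and long axis.

    Attributes
    ----------
    cell_id : int
        Label of the cell, unique within one field of view.
    pixels : ndarray, shape (N, 2), int
        Member pixel coordinates ``(row, col)``, stored in row-major order
        (this ordering defines the tie-break for brightest-pixel search).
    boundary : ndarray, shape (M, 2), float
        Closed polygon tracing the mask outline at the half-intensity
        level, in continuous pixel coordinates.
    centroid : ndarray, shape (2,)
        Mean of the member pixel coordinates.
    long_axis : ndarray, shape (2,)
        Unit vector along the principal axis of the pixel coordinates.
    axial_extent_px : float
        Peak-to-peak extent of pixel-center projections onto the long
        axis; the origin of :func:`project_long_axis` sits at the minimum.
    length_px, width_px : float
        Pixel-footprint lengths along the major/minor axes
        (``extent + 1`` so a single pixel has length 1).
    """

    cell_id: int
    pixels: np.ndarray
    boundary: np.ndarray
    centroid: np.ndarray
    long_axis: np.ndarray
    axial_extent_px: float
    length_px: float
    width_px: float
    axial_min: float = field(default=0.0, repr=False)  # min projection rel. to centroid

    @property
    def area_px(self) -> int:
        return len(self.pixels)

    def contains(self, point) -> bool:
        r, c = int(round(point[0])), int(round(point[1]))
        return bool(np.any((self.pixels[:, 0] == r) & (self.pixels[:, 1] == c)))


def _principal_axis(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit eigenvectors (major, minor) of the pixel-coordinate covariance."""
    if len(pixels) == 1:
        return np.array([1.0, 0.0]), np.array([0.0, 1.0])
    cov = np.cov(pixels.astype(float).T)
    vals, vecs = np.linalg.eigh(cov)
    major = vecs[:, np.argmax(vals)]
    minor = vecs[:, np.argmin(vals)]
    # deterministic sign: first nonzero component positive
    for v in (major, minor):
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            v *= -1.0
    return major, minor


def _trace_boundary(pixels: np.ndarray) -> np.ndarray:
    rmin, cmin = pixels.min(axis=0)
    rmax, cmax = pixels.max(axis=0)
    mask = np.zeros((rmax - rmin + 3, cmax - cmin + 3), dtype=float)
    mask[pixels[:, 0] - rmin + 1, pixels[:, 1] - cmin + 1] = 1.0
    contours = measure.find_contours(mask, 0.5)
    boundary = max(contours, key=len)
    return boundary + np.array([rmin - 1, cmin - 1], dtype=float)


def mesh_from_pixels(cell_id: int, pixels: np.ndarray) -> CellMesh:
    """Build a :class:`CellMesh` (centroid, axes, boundary) from raw pixels.

    ``pixels`` is re-sorted row-major so the brightest-pixel tie-break is
    independent of the caller's ordering.
    """
    pixels = np.asarray(pixels, dtype=int).reshape(-1, 2)
    if len(pixels) == 0:
        raise InputError("cell mesh needs at least one pixel")
    order = np.lexsort((pixels[:, 1], pixels[:, 0]))
    pixels = pixels[order]
    centroid = pixels.mean(axis=0)
    major, minor = _principal_axis(pixels)
    proj = (pixels - centroid) @ major
    perp = (pixels - centroid) @ minor
    extent = float(proj.max() - proj.min())
    length = extent + 1.0
    width = float(perp.max() - perp.min()) + 1.0
    if width > length:  # eigen-order can flip for near-isotropic blobs
        major, minor = minor, major
        proj, perp = perp, proj
        extent = float(proj.max() - proj.min())
        length, width = width, length
    return CellMesh(
        cell_id=int(cell_id),
        pixels=pixels,
        boundary=_trace_boundary(pixels),
        centroid=centroid,
        long_axis=major,
        axial_extent_px=extent,
        length_px=length,
        width_px=width,
        axial_min=float(proj.min()),
    )


def segment_cells(
    phase_image: np.ndarray,
    min_area_px: int = 30,
    max_area_px: int = 100_000,
    cells_dark: bool | None = None,
) -> list[CellMesh]:
    """Segment cells from a phase-contrast (or fluorescence-mask) image.

    Otsu-thresholds the image, keeps the minority class as foreground
    (phase-contrast cells are dark on a bright background; synthetic mask
    images are bright on dark — ``cells_dark`` overrides the automatic
    choice), fills holes, applies a 3x3 morphological opening, labels
    4-connected components and discards those outside
    ``[min_area_px, max_area_px]``.

    Returns an empty list (not an error) when nothing survives.  Touching
    cells are not split; crowded fields should be segmented externally and
    supplied through :func:`load_masks`.
    """
    phase_image = np.asarray(phase_image)
    if phase_image.ndim != 2:
        raise InputError(f"expected a 2-D image, got ndim={phase_image.ndim}")
    if min_area_px < 1:
        raise InputError("min_area_px must be >= 1")
    if phase_image.size == 0 or np.ptp(phase_image) == 0:
        return []
    thr = filters.threshold_otsu(phase_image)
    dark = phase_image < thr
    if cells_dark is None:
        cells_dark = dark.mean() <= 0.5  # cells are the minority class
    fg = dark if cells_dark else ~dark
    fg = ndimage.binary_fill_holes(fg)
    fg = morphology.opening(fg, footprint=np.ones((3, 3), dtype=bool))
    labels, n = ndimage.label(fg)  # 4-connectivity
    meshes = []
    cell_id = 0
    for lab in range(1, n + 1):
        pix = np.argwhere(labels == lab)
        if not (min_area_px <= len(pix) <= max_area_px):
            continue
        cell_id += 1
        meshes.append(mesh_from_pixels(cell_id, pix))
    return meshes


def load_masks(label_image: np.ndarray, min_area_px: int = 1) -> list[CellMesh]:
    """Build meshes from an integer label image (0 = background)."""
    label_image = np.asarray(label_image)
    if label_image.ndim != 2:
        raise InputError(f"expected a 2-D label image, got ndim={label_image.ndim}")
    if not np.issubdtype(label_image.dtype, np.integer):
        raise InputError(f"label image must have integer dtype, got {label_image.dtype}")
    meshes = []
    for lab in np.unique(label_image):
        if lab == 0:
            continue
        pix = np.argwhere(label_image == lab)
        if len(pix) < min_area_px:
            continue
        meshes.append(mesh_from_pixels(int(lab), pix))
    return meshes


def rasterize_meshes(meshes: list[CellMesh], shape: tuple[int, int]) -> np.ndarray:
    """Paint meshes back into a uint16 label image."""
    out = np.zeros(shape, dtype=np.uint16)
    for m in meshes:
        out[m.pixels[:, 0], m.pixels[:, 1]] = m.cell_id
    return out


def project_long_axis(mesh: CellMesh, point_px) -> float:
    """Axial coordinate of ``point_px`` along the cell's long axis.

    The origin sits at the axial minimum of the mesh (old-pole-agnostic),
    so the centroid of a symmetric cell projects to half the axial extent.
    The map is affine: moving a point by ``t * long_axis`` changes the
    result by exactly ``t``.
    """
    point = np.asarray(point_px, dtype=float)
    return float((point - mesh.centroid) @ mesh.long_axis - mesh.axial_min)
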