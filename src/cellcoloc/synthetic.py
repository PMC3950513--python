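"""Synthetic multi-channel fluorescence scenes with known ground truth.

Emulates the imaging regime the analysis is built for: rod-shaped
(capsule) *E. coli* cells on a dark background, 0-4 diffraction-limited
foci per cell in a reference channel rendered as 2-D Gaussians, and a
target channel whose signal is partly diffuse (a condensin-interacting
protein such as TopoIV shows a high intracellular background outside
foci) and whose single underlying point is tethered to a reference focus
with a controllable probability.  Every scene carries its ground truth,
so each pipeline stage has a parameter-recovery test surface.

The generator is deterministic given the config seed: one RNG
sub-stream per cell (spawned by counter) plus one for rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CellMesh, mesh_from_pixels

DEFAULT_PIXEL_SIZE_NM = 129.0


class SceneError(ValueError):
    """Raised for invalid scene configurations or out-of-bounds cells."""


@dataclass
class SceneConfig:
    """Parameters of one synthetic field of view.

    ``cell_length_um`` / ``cell_width_um`` are (mean, sd) of truncated
    normals; ``foci_per_cell_ref`` maps reference-focus count to
    probability; ``coloc_prob`` is the probability that the target point
    is tethered to a reference focus (Gaussian offset of sd
    ``tether_offset_sd_px``); ``diffuse_fraction`` of the target
    intensity is spread uniformly over the cell mask.
    """

    n_cells: int = 50
    cell_length_um: tuple[float, float] = (3.0, 0.4)
    cell_width_um: tuple[float, float] = (1.0, 0.05)
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    foci_per_cell_ref: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1}
    )
    coloc_prob: float = 0.75
    tether_offset_sd_px: float = 1.0
    min_ref_separation_px: float = 6.0
    diffuse_fraction: float = 0.3
    psf_sigma_px: float = 1.3
    amplitude: float = 500.0
    background: float = 50.0
    noise: str = "poisson"  # {"none", "poisson"}
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.coloc_prob <= 1.0:
            raise SceneError("coloc_prob must lie in [0, 1]")
        if not 0.0 <= self.diffuse_fraction <= 1.0:
            raise SceneError("diffuse_fraction must lie in [0, 1]")
        for name in ("pixel_size_nm", "psf_sigma_px"):
            if getattr(self, name) <= 0:
                raise SceneError(f"{name} must be > 0")
        if self.cell_length_um[0] <= 0 or self.cell_width_um[0] <= 0:
            raise SceneError("cell dimensions must be > 0")
        if self.noise not in ("none", "poisson"):
            raise SceneError(f"unknown noise model {self.noise!r}")
        total = sum(self.foci_per_cell_ref.values())
        if total <= 0 or any(p < 0 for p in self.foci_per_cell_ref.values()):
            raise SceneError("foci_per_cell_ref must be a non-negative distribution")


@dataclass
class TrueCell:
    """Ground-truth capsule geometry of one cell (continuous px)."""

    cell_id: int
    center: np.ndarray
    axis: np.ndarray  # unit vector
    length_px: float
    width_px: float
    mesh: CellMesh

    def _seg_dist(self, points: np.ndarray) -> np.ndarray:
        """Distance from points (…, 2) to the capsule's axis segment."""
        a = max((self.length_px - self.width_px) / 2.0, 0.0)
        d = np.asarray(points, dtype=float) - self.center
        t = np.clip(d @ self.axis, -a, a)
        closest = self.center + t[..., None] * self.axis
        return np.linalg.norm(np.asarray(points, float) - closest, axis=-1)

    def contains(self, points: np.ndarray, margin_px: float = 0.0) -> np.ndarray:
        return self._seg_dist(points) <= self.width_px / 2.0 - margin_px

    def sample_interior(self, rng, n: int = 1, margin_px: float = 0.0) -> np.ndarray:
        """Uniform continuous points inside the capsule, inset by margin."""
        half_diag = self.length_px / 2.0
        out = np.empty((n, 2))
        got = 0
        while got < n:
            cand = self.center + rng.uniform(-half_diag, half_diag, size=(4 * n, 2))
            ok = cand[self.contains(cand, margin_px)]
            take = min(len(ok), n - got)
            out[got : got + take] = ok[:take]
            got += take
        return out


@dataclass
class GroundTruth:
    """Per-cell true geometry, reference foci, target point, tether flag."""

    cells: list[TrueCell]
    ref_foci: list[np.ndarray]  # per cell (k, 2) continuous px
    target: list[np.ndarray]  # per cell (2,) continuous px
    tethered: list[bool]
    config: SceneConfig
    image_shape: tuple[int, int]

    def coloc_fraction(self, threshold_px: float = 4.0) -> float:
        """Realized fraction of cells whose true target point lies within
        ``threshold_px`` of the nearest true reference focus (cells with
        no reference focus count as not colocalized)."""
        hits = 0
        for foci, tgt in zip(self.ref_foci, self.target):
            if len(foci) and np.min(np.linalg.norm(foci - tgt, axis=1)) <= threshold_px:
                hits += 1
        return hits / len(self.cells)


def _cell_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def make_cell(
    length_um: float,
    width_um: float,
    center_px,
    orientation_rad: float,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    image_shape: tuple[int, int] | None = None,
    cell_id: int = 1,
) -> TrueCell:
    """Rasterize one capsule (rectangle with semicircular caps) cell.

    A pixel belongs to the cell when its center lies within ``width/2``
    of the capsule's axis segment.  Raises :class:`SceneError` when the
    cell would leave the image bounds.
    """
    if not length_um >= width_um > 0:
        raise SceneError("need length >= width > 0")
    length_px = length_um * 1000.0 / pixel_size_nm
    width_px = width_um * 1000.0 / pixel_size_nm
    center = np.asarray(center_px, dtype=float)
    axis = np.array([np.sin(orientation_rad), np.cos(orientation_rad)])
    cell = TrueCell(cell_id, center, axis, length_px, width_px, mesh=None)

    half = length_px / 2.0
    lo = np.floor(center - half - 1).astype(int)
    hi = np.ceil(center + half + 1).astype(int)
    if image_shape is not None:
        if lo[0] < 0 or lo[1] < 0 or hi[0] >= image_shape[0] or hi[1] >= image_shape[1]:
            raise SceneError(
                f"cell at {center} (length {length_px:.1f} px) exceeds image bounds {image_shape}"
            )
    rr, cc = np.mgrid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1]
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
    inside = cell.contains(pts)
    if not inside.any():
        raise SceneError("degenerate cell rasterizes to zero pixels")
    cell.mesh = mesh_from_pixels(cell_id, pts[inside])
    return cell


def capsule_area_px(length_px: float, width_px: float) -> float:
    """Analytic capsule area: w*(l - w) + pi*(w/2)^2."""
    return width_px * (length_px - width_px) + np.pi * (width_px / 2.0) ** 2


def _scene_layout(config: SceneConfig) -> tuple[np.ndarray, int, tuple[int, int]]:
    """Grid of non-touching cell slots; returns slot centers and image shape."""
    lmax_px = (config.cell_length_um[0] + 3 * config.cell_length_um[1]) * 1000.0 / config.pixel_size_nm
    slot = int(np.ceil(lmax_px)) + 10
    ncol = int(np.ceil(np.sqrt(config.n_cells)))
    nrow = int(np.ceil(config.n_cells / ncol))
    centers = np.array(
        [
            [(i // ncol) * slot + slot / 2.0, (i % ncol) * slot + slot / 2.0]
            for i in range(config.n_cells)
        ]
    )
    return centers, slot, (nrow * slot, ncol * slot)


def effective_focus_separation(
    length_px: float, n_foci: int, min_sep_px: float, margin_px: float = 1.0
) -> float:
    """Largest enforceable pairwise focus separation in a cell.

    ``min_sep_px`` is capped by what the cell's axial extent can host:
    n foci strung along an axis of usable length ``length - 2*margin``
    can be at most that length over ``n - 1`` apart (with a 10% slack
    for the rejection sampler to have room to succeed).
    """
    if n_foci <= 1:
        return min_sep_px
    usable = max(length_px - 2.0 * margin_px, 1.0)
    return float(min(min_sep_px, max(0.9 * usable / (n_foci - 1), 1.0)))


def _place_separated_foci(
    cell: TrueCell, n: int, rng, margin_px: float, min_sep_px: float
) -> np.ndarray:
    """Uniform interior foci kept pairwise separated by rejection.

    Distinct condensin-like clusters occupy separate chromosomal
    positions and are optically resolvable; foci closer than the
    diffraction limit would be one cluster, not two.  The separation is
    ``min_sep_px`` capped by the cell's capacity (see
    :func:`effective_focus_separation`).  If rejection fails (short cell,
    many foci), the foci fall back to evenly spaced axial stations with
    radial jitter, which meets the separation by construction.
    """
    if n == 0:
        return np.empty((0, 2))
    sep = effective_focus_separation(cell.length_px, n, min_sep_px, margin_px)
    placed: list[np.ndarray] = []
    for _ in range(n):
        for _try in range(500):
            cand = cell.sample_interior(rng, 1, margin_px=margin_px)[0]
            if all(np.linalg.norm(cand - p) >= sep for p in placed):
                placed.append(cand)
                break
        else:  # evenly spaced along the axis, symmetric about mid-cell
            a = max((cell.length_px - 2.0 * margin_px) / 2.0, 0.0)
            a_cyl = max((cell.length_px - cell.width_px) / 2.0, 0.0)
            r_in = max(cell.width_px / 2.0 - margin_px, 0.0)
            radial = np.array([-cell.axis[1], cell.axis[0]])
            placed = []
            for s in np.linspace(-a, a, n) if n > 1 else [0.0]:
                over = max(abs(s) - a_cyl, 0.0)
                rmax = np.sqrt(max(r_in**2 - over**2, 0.0))
                placed.append(
                    cell.center + s * cell.axis + rng.uniform(-rmax, rmax) * radial
                )
            break
    return np.array(placed)


def sample_truth(config: SceneConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw ground truth for one scene.

    Reference foci are uniform in the mask interior (>= 1 px from the
    boundary).  The target point is, with probability ``coloc_prob``, a
    randomly chosen reference focus plus an isotropic Gaussian offset
    (re-sampled up to 100 times if it falls outside the mask, then
    clipped to the capsule interior); otherwise a uniform random interior
    point.  A cell with zero reference foci cannot tether; its flag is
    recorded False.
    """
    centers, slot, shape = _scene_layout(config)
    counts = np.array(sorted(config.foci_per_cell_ref))
    probs = np.array([config.foci_per_cell_ref[k] for k in counts], dtype=float)
    probs /= probs.sum()

    cells, ref_foci, targets, tethered = [], [], [], []
    for i in range(config.n_cells):
        crng = _cell_rng(config.seed, i)
        lmean, lsd = config.cell_length_um
        wmean, wsd = config.cell_width_um
        width = float(np.clip(crng.normal(wmean, wsd), 0.5 * wmean, wmean + 3 * wsd))
        length = float(np.clip(crng.normal(lmean, lsd), width, lmean + 3 * lsd))
        orientation = crng.uniform(0.0, np.pi)
        cell = make_cell(
            length, width, centers[i], orientation,
            pixel_size_nm=config.pixel_size_nm, image_shape=shape, cell_id=i + 1,
        )
        n_ref = int(crng.choice(counts, p=probs))
        margin = min(1.0, cell.width_px / 2.0 - 0.25)  # keep feasible for thin cells
        foci = _place_separated_foci(
            cell, n_ref, crng, margin, config.min_ref_separation_px
        )

        # a target position must also round to an in-mask pixel so the
        # ground truth stays comparable to pixel-level localizations
        def _in_mask(p):
            return cell.contains(p[None])[0] and cell.contains(np.round(p)[None])[0]

        tether = bool(crng.random() < config.coloc_prob) and n_ref > 0
        if tether:
            anchor = foci[crng.integers(n_ref)]
            point = None
            for _ in range(100):
                cand = anchor + crng.normal(0.0, config.tether_offset_sd_px, size=2)
                if _in_mask(cand):
                    point = cand
                    break
            if point is None:  # clip to the nearest safely-interior position
                off = cand - cell.center
                t = np.clip(off @ cell.axis, -(cell.length_px - cell.width_px) / 2,
                            (cell.length_px - cell.width_px) / 2)
                closest = cell.center + t * cell.axis
                radial = cand - closest
                point = closest + radial / np.linalg.norm(radial) * (cell.width_px / 2 - 0.75)
        else:
            point = cell.sample_interior(crng, 1)[0]
            while not _in_mask(point):
                point = cell.sample_interior(crng, 1)[0]

        cells.append(cell)
        ref_foci.append(foci)
        targets.append(np.asarray(point))
        tethered.append(tether)
    return GroundTruth(cells, ref_foci, targets, tethered, config, shape)


def _add_gaussian(img: np.ndarray, pos: np.ndarray, amplitude: float, sigma: float):
    """Add an isotropic Gaussian spot sampled at pixel centers, in place."""
    r0, c0 = pos
    w = int(np.ceil(5 * sigma))
    rlo, rhi = max(0, int(r0) - w), min(img.shape[0] - 1, int(r0) + w)
    clo, chi = max(0, int(c0) - w), min(img.shape[1] - 1, int(c0) + w)
    rr, cc = np.mgrid[rlo : rhi + 1, clo : chi + 1]
    img[rlo : rhi + 1, clo : chi + 1] += amplitude * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2)
    )


def render_scene(
    truth: GroundTruth, config: SceneConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Render phase, reference and target channel images from ground truth.

    Reference foci are isotropic Gaussians of sd ``psf_sigma_px`` and the
    configured amplitude.  In the target channel ``diffuse_fraction`` of
    the point's total intensity (amplitude * 2*pi*sigma^2) is spread
    uniformly over the cell mask and the remainder forms the spot.  A
    constant background is added to the fluorescence channels and Poisson
    shot noise is applied when configured.  The phase channel is bright
    background / dark cells.
    """
    config = config or truth.config
    if rng is None:
        rng = _cell_rng(config.seed, config.n_cells)  # render stream after cell streams
    shape = truth.image_shape
    ref = np.full(shape, config.background, dtype=float)
    target = np.full(shape, config.background, dtype=float)
    phase = np.full(shape, 1000.0)

    spot_total = config.amplitude * 2.0 * np.pi * config.psf_sigma_px**2
    for cell, foci, tgt in zip(truth.cells, truth.ref_foci, truth.target):
        pix = cell.mesh.pixels
        phase[pix[:, 0], pix[:, 1]] = 300.0
        for f in foci:
            _add_gaussian(ref, f, config.amplitude, config.psf_sigma_px)
        if config.diffuse_fraction < 1.0:
            _add_gaussian(
                target, tgt, config.amplitude * (1.0 - config.diffuse_fraction),
                config.psf_sigma_px,
            )
        if config.diffuse_fraction > 0.0:
            target[pix[:, 0], pix[:, 1]] += (
                config.diffuse_fraction * spot_total / len(pix)
            )

    images = {"phase": phase, "ref": ref, "target": target}
    if config.noise == "poisson":
        images = {k: rng.poisson(v).astype(float) for k, v in images.items()}
    return images


def simulate_scene(config: SceneConfig) -> tuple[GroundTruth, dict[str, np.ndarray]]:
    """Convenience: sample ground truth and render it."""
    truth = sample_truth(config)
    return truth, render_scene(truth, config)
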