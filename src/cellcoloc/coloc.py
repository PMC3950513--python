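"""Nearest-distance colocalization statistics with random-placement nulls.

The central statistic of the package: per cell, the Euclidean distance
between one target localization (a brightest pixel or single centroid)
and the nearest reference-focus centroid, compared against matched
in-cell random-placement controls.  Distances are accumulated into a
cumulative distribution over *all* cells; its value at a threshold
(default 4 px, i.e. 516 nm at 129 nm/px) is the colocalization fraction,
reported with a 95% Wilson score interval.  Cells without any reference
focus contribute an ABSENT record — they can never colocalize, so the
cumulative curve plateaus at the fraction of cells that possess at least
one reference focus (the asymptote) rather than at 1.

Two null models are provided, mirroring the two measurement directions:

* :func:`random_null_distances` — a pixel placed uniformly at random in
  the cell, measured against the cell's real reference foci (the control
  for a brightest-pixel target).
* :func:`random_null_focus_set` — the cell's reference foci replaced by
  an equal number of uniform random in-cell points, measured against the
  cell's fixed target (the control when the reference channel has
  multiple foci per cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .geometry import CellMesh

DEFAULT_THRESHOLD_PX = 4.0


@dataclass
class DistanceRecord:
    """One measured or null target-to-nearest-reference distance.

    ``distance_px`` is ``None`` (ABSENT) iff the cell has no accepted
    reference focus.
    """

    cell_id: int
    kind: str  # {"measured", "random"}
    distance_px: float | None
    distance_nm: float | None

    @property
    def absent(self) -> bool:
        return self.distance_px is None


@dataclass
class ColocResult:
    threshold_px: float
    threshold_nm: float
    comparator: str  # {"le", "lt"}
    n_cells: int
    n_cells_with_ref_focus: int
    coloc_fraction: float
    ci_low: float
    ci_high: float
    asymptote: float
    curve: np.ndarray = field(repr=False)  # (K, 2): distance_px, cumulative fraction
    n_draws: int = 1
    kind: str = "measured"


def _record(cell_id, kind, d_px, pixel_size_nm) -> DistanceRecord:
    if d_px is None:
        return DistanceRecord(cell_id, kind, None, None)
    return DistanceRecord(cell_id, kind, float(d_px), float(d_px) * pixel_size_nm)


def _nearest(point: np.ndarray, refs: np.ndarray) -> float | None:
    if len(refs) == 0:
        return None
    return float(np.min(np.linalg.norm(np.asarray(refs, float) - np.asarray(point, float), axis=1)))


def measured_distances(
    targets: dict[int, np.ndarray],
    refs: dict[int, np.ndarray],
    pixel_size_nm: float,
) -> list[DistanceRecord]:
    """Per cell, distance from the single target point to the nearest
    reference focus (continuous px, pixel-center convention).

    ``targets`` maps cell_id to one (row, col) point; ``refs`` maps
    cell_id to a (k, 2) array of accepted focus centroids (k may be 0).
    The two tables must cover identical cell ids.
    """
    if set(targets) != set(refs):
        raise ValueError(
            f"cell-id mismatch: targets {sorted(set(targets) ^ set(refs))} unmatched"
        )
    return [
        _record(cid, "measured", _nearest(targets[cid], refs[cid]), pixel_size_nm)
        for cid in sorted(targets)
    ]


def random_null_distances(
    meshes: list[CellMesh],
    refs: dict[int, np.ndarray],
    n_draws: int,
    rng: np.random.Generator,
    pixel_size_nm: float,
) -> list[DistanceRecord]:
    """Null distances from uniformly random in-cell pixels to the nearest
    reference focus; ABSENT propagated for focus-less cells.

    ``n_draws = 1`` gives the classic one-random-pixel-per-cell control;
    larger values reduce null variance (draws are averaged per cell
    before the cumulative curve).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    out = []
    for mesh in meshes:
        cell_refs = refs.get(mesh.cell_id, np.empty((0, 2)))
        if len(cell_refs) == 0:
            out.extend(_record(mesh.cell_id, "random", None, pixel_size_nm) for _ in range(n_draws))
            continue
        idx = rng.integers(len(mesh.pixels), size=n_draws)
        pts = mesh.pixels[idx].astype(float)
        dmat = np.linalg.norm(pts[:, None, :] - np.asarray(cell_refs, float)[None, :, :], axis=2)
        for d in dmat.min(axis=1):
            out.append(_record(mesh.cell_id, "random", d, pixel_size_nm))
    return out


def random_null_focus_set(
    meshes: list[CellMesh],
    n_foci_per_cell: dict[int, int],
    targets: dict[int, np.ndarray],
    n_draws: int,
    rng: np.random.Generator,
    pixel_size_nm: float,
) -> list[DistanceRecord]:
    """Equal-count random focus-set null: per draw, each cell's reference
    foci are replaced by that many uniform random in-cell pixels, and the
    distance from the cell's fixed target to the nearest random point is
    recorded.  Cells with zero foci yield ABSENT."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    out = []
    for mesh in meshes:
        k = int(n_foci_per_cell.get(mesh.cell_id, 0))
        if k == 0:
            out.extend(_record(mesh.cell_id, "random", None, pixel_size_nm) for _ in range(n_draws))
            continue
        tgt = np.asarray(targets[mesh.cell_id], float)
        idx = rng.integers(len(mesh.pixels), size=(n_draws, k))
        pts = mesh.pixels[idx].astype(float)  # (n_draws, k, 2)
        d = np.linalg.norm(pts - tgt[None, None, :], axis=2).min(axis=1)
        out.extend(_record(mesh.cell_id, "random", di, pixel_size_nm) for di in d)
    return out


def _cell_weights(records: list[DistanceRecord]) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Finite distances with per-cell weights 1/n_records(cell).

    Averaging a cell's draws before aggregation makes a multi-draw null
    directly comparable to single-draw measured records.
    Returns (distances, weights, n_cells_seen, n_cells_with_focus).
    """
    per_cell: dict[int, int] = {}
    for r in records:
        per_cell[r.cell_id] = per_cell.get(r.cell_id, 0) + 1
    dist, wt = [], []
    with_focus = set()
    for r in records:
        if r.absent:
            continue
        with_focus.add(r.cell_id)
        dist.append(r.distance_px)
        wt.append(1.0 / per_cell[r.cell_id])
    return np.asarray(dist), np.asarray(wt), len(per_cell), len(with_focus)


def cumulative_curve(records: list[DistanceRecord], n_cells_total: int) -> np.ndarray:
    """Cumulative distribution F(d) = weighted #(distance <= d) / n_cells_total.

    Random draws are averaged per cell first, so F is a per-cell average
    regardless of n_draws.  F is non-decreasing and plateaus at the
    asymptote (fraction of cells with >= 1 reference focus); ABSENT
    records never enter the numerator.  Returns an array of
    (distance, F) step-function vertices.
    """
    dist, wt, n_seen, _ = _cell_weights(records)
    if n_cells_total < n_seen:
        raise ValueError("n_cells_total smaller than the number of cells in records")
    if len(dist) == 0:
        return np.zeros((0, 2))
    order = np.argsort(dist)
    d_sorted, w_sorted = dist[order], wt[order]
    cum = np.cumsum(w_sorted) / n_cells_total
    # collapse ties: keep the last cumulative value at each distinct distance
    uniq, last = np.unique(d_sorted[::-1], return_index=True)
    return np.column_stack([uniq, cum[::-1][last]])


def coloc_fraction(
    records: list[DistanceRecord],
    n_cells_total: int,
    threshold_px: float = DEFAULT_THRESHOLD_PX,
    comparator: str = "le",
    pixel_size_nm: float = 129.0,
    ci_method: str = "wilson",
    kind: str = "measured",
) -> ColocResult:
    """Colocalization fraction at a distance threshold, over ALL cells.

    ``comparator="le"`` implements the snapshot rule (within the
    threshold, boundary included); ``"lt"`` the strict time-lapse rule.
    ABSENT cells count as not colocalized.  The 95% CI is a Wilson score
    interval by default (``ci_method="beta"`` gives Clopper-Pearson);
    for multi-draw nulls the per-cell averaged colocalization weight is
    used as an effective count.
    """
    if threshold_px <= 0:
        raise ValueError("threshold_px must be > 0")
    if comparator not in ("le", "lt"):
        raise ValueError(f"comparator must be 'le' or 'lt', got {comparator!r}")
    dist, wt, n_seen, n_with = _cell_weights(records)
    if n_cells_total < n_seen:
        raise ValueError("n_cells_total smaller than the number of cells in records")
    if n_cells_total == 0:
        raise ValueError("n_cells_total must be >= 1")
    hit = dist <= threshold_px if comparator == "le" else dist < threshold_px
    count = float(wt[hit].sum())
    frac = count / n_cells_total
    lo, hi = proportion_confint(count, n_cells_total, alpha=0.05, method=ci_method)
    n_draws = max(round(1.0 / wt.min()), 1) if len(wt) else 1
    return ColocResult(
        threshold_px=threshold_px,
        threshold_nm=threshold_px * pixel_size_nm,
        comparator=comparator,
        n_cells=n_cells_total,
        n_cells_with_ref_focus=n_with,
        coloc_fraction=frac,
        ci_low=float(lo),
        ci_high=float(hi),
        asymptote=n_with / n_cells_total,
        curve=cumulative_curve(records, n_cells_total),
        n_draws=n_draws,
        kind=kind,
    )


def compare_to_random(measured: ColocResult, random: ColocResult) -> tuple[float, bool]:
    """Two-proportion z-test of measured vs. random colocalized counts.

    Returns ``(p_value, significant)``.  The significance flag requires
    both p < 0.05 and non-overlap of the two 95% confidence intervals
    (the stricter visual criterion used when comparing error bars).
    """
    if measured.n_cells == 0 or random.n_cells == 0:
        raise ValueError("cannot compare results over zero cells")
    if measured.threshold_px != random.threshold_px:
        raise ValueError("results were computed at different thresholds")
    p1, p2 = measured.coloc_fraction, random.coloc_fraction
    n1, n2 = measured.n_cells, random.n_cells
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        p_value = 1.0 if p1 == p2 else 0.0
    else:
        from scipy.stats import norm

        z = (p1 - p2) / se
        p_value = 2.0 * norm.sf(abs(z))
    disjoint = measured.ci_low > random.ci_high or measured.ci_high < random.ci_low
    return float(p_value), bool(p_value < 0.05 and disjoint)
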