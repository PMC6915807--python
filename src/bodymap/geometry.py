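"""Rasterize concern outlines into binary pixel masks on the manikin grid.

The fill rule is pinned precisely so that masks are reproducible across
platforms: a pixel belongs to a polygon iff its *center* ``(col + 0.5,
row + 0.5)`` lies inside the implicitly-closed outline under the even-odd
(crossing-parity) rule; pixel centers lying exactly on an edge are included.
Even-odd makes the result independent of vertex orientation and gives the
intuitive two-triangle fill for self-intersecting "bow-tie" traces.
"""

from __future__ import annotations

import numpy as np

from .cohort import ConcernEntry

__all__ = ["rasterize_outline", "subject_concern_mask", "union_masks"]

_EDGE_EPS = 1e-9


class DegeneratePolygonError(ValueError):
    pass


class BoundsError(ValueError):
    pass


def _check_polygon(polygon, dims):
    w, h = dims
    if len(polygon) < 3:
        raise DegeneratePolygonError(
            f"polygon needs >= 3 vertices, got {len(polygon)}"
        )
    pts = np.asarray(polygon, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DegeneratePolygonError("polygon must be a sequence of (x, y) pairs")
    if (pts[:, 0] < 0).any() or (pts[:, 0] > w).any() or (pts[:, 1] < 0).any() or (pts[:, 1] > h).any():
        bad = pts[
            (pts[:, 0] < 0) | (pts[:, 0] > w) | (pts[:, 1] < 0) | (pts[:, 1] > h)
        ][0]
        raise BoundsError(
            f"vertex ({bad[0]}, {bad[1]}) outside raster bounds {w}x{h}"
        )
    return pts


def rasterize_outline(polygon, dims: tuple[int, int]) -> np.ndarray:
    """Fill a closed outline on a (width, height) raster.

    Parameters
    ----------
    polygon
        Ordered (x, y) vertices; the last vertex connects back to the first.
    dims
        Raster (width, height) in pixels.

    Returns
    -------
    ndarray of uint8, shape (height, width), entries in {0, 1}.
    """
    w, h = dims
    pts = _check_polygon(polygon, dims)

    grid = np.zeros((h, w), dtype=np.uint8)
    # restrict work to the polygon's pixel bounding box
    c0 = max(int(np.floor(pts[:, 0].min() - 0.5)), 0)
    c1 = min(int(np.ceil(pts[:, 0].max() + 0.5)), w)
    r0 = max(int(np.floor(pts[:, 1].min() - 0.5)), 0)
    r1 = min(int(np.ceil(pts[:, 1].max() + 0.5)), h)
    if c1 <= c0 or r1 <= r0:
        return grid

    cx = np.arange(c0, c1) + 0.5            # pixel-center x, shape (W',)
    cy = np.arange(r0, r1) + 0.5            # pixel-center y, shape (H',)
    PX = cx[None, :, None]                  # (1, W', 1)
    PY = cy[:, None, None]                  # (H', 1, 1)

    x1, y1 = pts[:, 0], pts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)

    # crossing-parity ray cast toward +x; half-open vertex rule avoids
    # double-counting shared endpoints
    cond = (y1[None, None, :] > PY) != (y2[None, None, :] > PY)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = x1 + (PY - y1) * (x2 - x1) / np.where(y2 == y1, np.inf, y2 - y1)
    inside = (cond & (PX < xint)).sum(axis=2) % 2 == 1

    # boundary rule: a center exactly on an edge segment counts as inside
    dx, dy = x2 - x1, y2 - y1
    seglen2 = dx * dx + dy * dy
    vx = PX - x1[None, None, :]
    vy = PY - y1[None, None, :]
    cross = vx * dy[None, None, :] - vy * dx[None, None, :]
    dot = vx * dx[None, None, :] + vy * dy[None, None, :]
    scale = np.sqrt(np.where(seglen2 > 0, seglen2, 1.0))
    on_edge = (
        (np.abs(cross) / scale[None, None, :] <= _EDGE_EPS)
        & (dot >= -_EDGE_EPS)
        & (dot <= seglen2[None, None, :] + _EDGE_EPS)
        & (seglen2[None, None, :] > 0)
    ).any(axis=2)

    grid[r0:r1, c0:c1] = (inside | on_edge).astype(np.uint8)
    return grid


def union_masks(masks, dims: tuple[int, int] | None = None) -> np.ndarray:
    """Pixel-wise logical OR of binary masks (empty input -> zero mask;
    then ``dims`` is required)."""
    masks = list(masks)
    if not masks:
        if dims is None:
            raise ValueError("dims required for an empty mask list")
        w, h = dims
        return np.zeros((h, w), dtype=np.uint8)
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise ValueError(f"mask dims mismatch: {m.shape} vs {shape}")
    if dims is not None and shape != (dims[1], dims[0]):
        raise ValueError(f"mask dims {shape} do not match raster {dims}")
    out = np.zeros(shape, dtype=np.uint8)
    for m in masks:
        np.logical_or(out, m, out=out)
    return out.astype(np.uint8)


def subject_concern_mask(entries: list[ConcernEntry] | list, dims: tuple[int, int]) -> np.ndarray:
    """Collapse a subject's concern outlines into one binary mask.

    The union means a subject contributes at most 1 to any pixel of the
    group proportion map regardless of how many overlapping concerns they
    outlined.  An empty entry list yields the all-zero mask.
    """
    polys = [e.polygon if isinstance(e, ConcernEntry) else e for e in entries]
    return union_masks([rasterize_outline(p, dims) for p in polys], dims=dims)
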