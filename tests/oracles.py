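"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (ray casting, O(points x edges)
distance scans, raster counting, grid searches) and shares no code with
the package implementation.
"""

from __future__ import annotations

import numpy as np


def _rings(poly) -> list[np.ndarray]:
    """Exterior + interior rings of a shapely polygon as coordinate arrays."""
    rings = [np.asarray(poly.exterior.coords)]
    rings.extend(np.asarray(r.coords) for r in poly.interiors)
    return rings


def points_in_ring(pts: np.ndarray, ring: np.ndarray) -> np.ndarray:
    """Even-odd ray casting; boundary points are resolved arbitrarily."""
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    x0, y0 = ring[:-1, 0], ring[:-1, 1]
    x1, y1 = ring[1:, 0], ring[1:, 1]
    for ax, ay, bx, by in zip(x0, y0, x1, y1):
        cross = (ay > y) != (by > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xin = ax + (y - ay) * (bx - ax) / (by - ay)
        inside ^= cross & (x < xin)
    return inside


def points_in_polygon(pts: np.ndarray, poly) -> np.ndarray:
    rings = _rings(poly)
    inside = points_in_ring(pts, rings[0])
    for hole in rings[1:]:
        inside &= ~points_in_ring(pts, hole)
    return inside


def dist_to_segments(pts: np.ndarray, ring: np.ndarray) -> np.ndarray:
    """Min distance from each point to any segment of the ring."""
    a = ring[:-1]  # (m, 2)
    b = ring[1:]
    ab = b - a
    denom = (ab ** 2).sum(1)
    denom = np.where(denom == 0, 1.0, denom)
    # (n, m) projections
    ap = pts[:, None, :] - a[None, :, :]
    t = np.clip((ap * ab[None, :, :]).sum(-1) / denom[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]
    d = np.sqrt(((pts[:, None, :] - proj) ** 2).sum(-1))
    return d.min(axis=1)


def dist_to_polygon(pts: np.ndarray, poly) -> np.ndarray:
    """0 inside the polygon, else min distance to any boundary ring."""
    d = np.min([dist_to_segments(pts, r) for r in _rings(poly)], axis=0)
    return np.where(points_in_polygon(pts, poly), 0.0, d)


def wells_within_buffer_bruteforce(poly, wells, buffer_m: float) -> set[str]:
    if not wells:
        return set()
    pts = np.array([[w.location.x, w.location.y] for w in wells])
    d = dist_to_polygon(pts, poly)
    return {w.id for w, di in zip(wells, d) if di <= buffer_m}


def mc_area_km2(poly, n: int = 1_000_000, seed: int = 0) -> float:
    """Rejection-sampling area estimate (hit rate in the bounding box)."""
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = poly.bounds
    pts = np.column_stack([
        rng.uniform(minx, maxx, n), rng.uniform(miny, maxy, n),
    ])
    hit = points_in_polygon(pts, poly).mean()
    return hit * (maxx - minx) * (maxy - miny) / 1e6


def raster_intersection_weights(nbhd_poly, tracts, cell_m: float = 10.0):
    """Raster counting oracle for (w_ext, w_int) on a metric grid."""
    minx, miny, maxx, maxy = nbhd_poly.bounds
    pad = cell_m
    xs = np.arange(minx - pad, maxx + pad, cell_m) + cell_m / 2
    ys = np.arange(miny - pad, maxy + pad, cell_m) + cell_m / 2
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    in_nb = points_in_polygon(pts, nbhd_poly)
    out = {}
    for tid, tg in tracts:
        in_t = points_in_polygon(pts, tg)
        inter_cells = int((in_nb & in_t).sum())
        if inter_cells == 0:
            continue
        w_int = inter_cells * cell_m ** 2
        out[tid] = (w_int / tg.area, w_int)
    return out


def quantile_trim_oracle(scores: np.ndarray, lower_pct: float, upper_pct: float):
    """Sort-based linear-interpolation quantiles + strict exclusion."""
    s = np.sort(np.asarray(scores, dtype=float))
    n = len(s)

    def q(p):
        h = (n - 1) * p / 100.0
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    p1, p99 = q(lower_pct), q(upper_pct)
    return (scores >= p1) & (scores <= p99)


def grid_fluctuation_oracle(Qbar, g, A, Y_star, weights=None,
                            lo=-10.0, hi=10.0, step=1e-4) -> float:
    """Grid-search maximizer of the weighted Bernoulli log-likelihood."""
    Qbar = np.clip(np.asarray(Qbar, float), 1e-12, 1 - 1e-12)
    A = np.asarray(A, float)
    Y = np.asarray(Y_star, float)
    w = np.ones(len(A)) if weights is None else np.asarray(weights, float)
    H = A / g - (1 - A) / (1 - g)
    off = np.log(Qbar / (1 - Qbar))
    eps = np.arange(lo, hi + step, step)
    # chunk to keep memory modest
    best_eps, best_ll = 0.0, -np.inf
    for chunk in np.array_split(eps, 40):
        q = 1.0 / (1.0 + np.exp(-(off[None, :] + chunk[:, None] * H[None, :])))
        q = np.clip(q, 1e-12, 1 - 1e-12)
        ll = (w[None, :] * (Y[None, :] * np.log(q) + (1 - Y)[None, :] * np.log1p(-q))).sum(1)
        j = int(np.argmax(ll))
        if ll[j] > best_ll:
            best_ll, best_eps = float(ll[j]), float(chunk[j])
    return best_eps
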