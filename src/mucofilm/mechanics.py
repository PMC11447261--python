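"""Steric relaxation: pairwise shoving and solid-wall constraints.

Growth and division leave circular agents overlapping one another and,
near the substratum, intruding into solid blocks.  Overlap is relieved
by a Jacobi-style shoving scheme: every overlapping pair contributes a
displacement of half the overlap to each partner, directed along the
center line, and all candidate positions are computed from the same
pre-update state.  Movement toward solids is truncated at the first
point of contact of the swept circle with the block boundary.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .scenario_config import SubstratumLattice

CONTACT_TOL = 1e-6  # um, circle-solid contact tolerance


# ---------------------------------------------------------------------------
# solid geometry


def distance_to_solid(x, y, lattice: SubstratumLattice, return_direction=False):
    """Distance from point(s) to the nearest solid-block boundary.

    Exact within the 3x3 block neighborhood of each point (sufficient for
    clearances below one block size); points farther from any solid than
    that report the block size as a lower bound.  Periodic in x.  With
    ``return_direction`` also returns the unit vector pointing away from
    the nearest solid (zero for points on/inside solid).
    """
    b = lattice.block_size
    x = np.atleast_1d(np.asarray(x, dtype=float)) % lattice.width
    y = np.atleast_1d(np.asarray(y, dtype=float))
    ix = np.floor(x / b).astype(int)
    iy = np.floor(y / b).astype(int)
    best = np.full(x.shape, b)
    away = np.zeros((x.size, 2))
    for ox in (-1, 0, 1):
        jx = (ix + ox) % lattice.nx
        x0 = (ix + ox) * b  # unwrapped coordinates adjacent to the point
        for oy in (-1, 0, 1):
            jy = iy + oy
            valid = (jy >= 0) & (jy < lattice.ny)
            solid = np.zeros(x.shape, dtype=bool)
            solid[valid] = lattice.solid[jx[valid], jy[valid]]
            if not solid.any():
                continue
            y0 = jy * b
            ex = np.clip(x, x0, x0 + b)  # nearest point on the rect
            ey = np.clip(y, y0, y0 + b)
            dx = x - ex
            dy = y - ey
            d = np.hypot(dx, dy)
            closer = solid & (d < best)
            best = np.where(closer, d, best)
            if return_direction:
                with np.errstate(invalid="ignore", divide="ignore"):
                    ux = np.where(d > 0, dx / np.maximum(d, 1e-300), 0.0)
                    uy = np.where(d > 0, dy / np.maximum(d, 1e-300), 0.0)
                away[closer, 0] = ux[closer]
                away[closer, 1] = uy[closer]
    if return_direction:
        return best, away
    return best if best.size > 1 else float(best[0])


def is_feasible(x, y, radius, lattice: SubstratumLattice, tol: float = CONTACT_TOL):
    """True where a circle of given radius does not penetrate solid."""
    return distance_to_solid(x, y, lattice) >= np.asarray(radius) - tol


def _segment_blocks(start, end, radius, lattice):
    """Solid blocks (unwrapped rects) within reach of a swept circle."""
    b = lattice.block_size
    pad = radius + b * 0.5
    xlo = min(start[0], end[0]) - pad
    xhi = max(start[0], end[0]) + pad
    ylo = max(min(start[1], end[1]) - pad, 0.0)
    yhi = min(max(start[1], end[1]) + pad, lattice.height)
    rects = []
    for ix in range(int(np.floor(xlo / b)), int(np.floor(xhi / b)) + 1):
        jx = ix % lattice.nx
        for iy in range(int(np.floor(ylo / b)), int(np.floor(yhi / b)) + 1):
            if 0 <= iy < lattice.ny and lattice.solid[jx, iy]:
                rects.append((ix * b, iy * b, (ix + 1) * b, (iy + 1) * b))
    return rects


def _rect_distance(px, py, rect):
    x0, y0, x1, y1 = rect
    dx = max(x0 - px, 0.0, px - x1)
    dy = max(y0 - py, 0.0, py - y1)
    return float(np.hypot(dx, dy))


def _first_contact_rect(start, d, radius, rect):
    """Smallest t in [0, 1] at which |p(t) - rect| == radius, else None.

    The swept circle touches the rectangle where the center crosses the
    rectangle dilated by the radius: four offset edges plus four corner
    circles, each solvable in closed form.
    """
    x0, y0, x1, y1 = rect
    sx, sy = start
    dx, dy = d
    candidates = []
    # offset edges (axis-aligned lines limited to the edge span)
    for xline, lo, hi in ((x0 - radius, y0, y1), (x1 + radius, y0, y1)):
        if abs(dx) > 1e-300:
            t = (xline - sx) / dx
            if 0.0 <= t <= 1.0 and lo <= sy + t * dy <= hi:
                candidates.append(t)
    for yline, lo, hi in ((y0 - radius, x0, x1), (y1 + radius, x0, x1)):
        if abs(dy) > 1e-300:
            t = (yline - sy) / dy
            if 0.0 <= t <= 1.0 and lo <= sx + t * dx <= hi:
                candidates.append(t)
    # corner circles
    for cx, cy in ((x0, y0), (x0, y1), (x1, y0), (x1, y1)):
        fx, fy = sx - cx, sy - cy
        a = dx * dx + dy * dy
        if a <= 1e-300:
            continue
        bq = 2 * (fx * dx + fy * dy)
        c = fx * fx + fy * fy - radius * radius
        disc = bq * bq - 4 * a * c
        if disc < 0:
            continue
        sq = np.sqrt(disc)
        for t in ((-bq - sq) / (2 * a), (-bq + sq) / (2 * a)):
            if 0.0 <= t <= 1.0:
                candidates.append(t)
    # keep only true boundary crossings of the dilated rectangle
    valid = [t for t in candidates
             if abs(_rect_distance(sx + t * dx, sy + t * dy, rect) - radius) < 1e-9]
    return min(valid) if valid else None


def wall_constrain(start, candidate, radius, lattice: SubstratumLattice):
    """Move a circle from ``start`` toward ``candidate``, halting at the
    first contact with a solid-block boundary.

    Returns the final center position.  ``start`` must itself be feasible.
    """
    start = (float(start[0]), float(start[1]))
    candidate = (float(candidate[0]), float(candidate[1]))
    if lattice.is_solid_at(*start):
        raise ValueError("wall_constrain called with center inside solid")
    # a cell whose surface was left slightly embedded (e.g. it grew while
    # resting on the wall) may still slide, but no deeper: shrink the
    # swept radius to its current clearance
    d0 = distance_to_solid(*start, lattice)
    r_eff = min(radius, d0 - CONTACT_TOL) if d0 < radius else radius
    if r_eff <= 0:
        return np.array(start)
    d = (candidate[0] - start[0], candidate[1] - start[1])
    if d[0] == 0.0 and d[1] == 0.0:
        return np.array(start)
    tmin = 1.0
    for rect in _segment_blocks(start, candidate, radius, lattice):
        t = _first_contact_rect(start, d, r_eff, rect)
        if t is not None and t < tmin:
            tmin = t
    return np.array([start[0] + tmin * d[0], start[1] + tmin * d[1]])


# ---------------------------------------------------------------------------
# shoving


def overlap_pairs(x, y, radius, width: float, height: float):
    """Index pairs (i, j) of overlapping circles and their overlaps.

    Positions are periodic in x with period ``width``.
    """
    n = x.size
    if n < 2:
        return (np.empty((0, 2), dtype=int), np.empty(0), np.empty(0), np.empty(0))
    ybox = max(2 * height, np.max(y) + 1.0)
    tree = cKDTree(np.column_stack([x % width, y]), boxsize=[width, ybox])
    pairs = tree.query_pairs(r=2 * float(np.max(radius)), output_type="ndarray")
    if pairs.size == 0:
        return (np.empty((0, 2), dtype=int), np.empty(0), np.empty(0), np.empty(0))
    i, j = pairs[:, 0], pairs[:, 1]
    dx = (x[i] - x[j] + width / 2) % width - width / 2
    dy = y[i] - y[j]
    dist = np.hypot(dx, dy)
    ov = radius[i] + radius[j] - dist
    keep = ov > 0
    return pairs[keep], dx[keep], dy[keep], dist[keep]


def shove_iteration(x, y, radius, width: float, height: float,
                    rng: np.random.Generator | None = None):
    """One parallel shoving pass; returns per-agent candidate displacements.

    Every overlapping pair pushes both members apart by half the overlap
    along the center-to-center direction; contributions from all partners
    are summed from the same pre-update positions.  Coincident centers
    are separated along a random direction (requires ``rng``).
    """
    disp = np.zeros((x.size, 2))
    pairs, dx, dy, dist = overlap_pairs(x, y, radius, width, height)
    if pairs.shape[0] == 0:
        return disp, 0.0
    zero = dist < 1e-12
    if zero.any():
        if rng is None:
            rng = np.random.default_rng(0)
        ang = rng.uniform(0, 2 * np.pi, size=int(zero.sum()))
        dx[zero] = np.cos(ang) * 1e-12
        dy[zero] = np.sin(ang) * 1e-12
        dist[zero] = 1e-12
    ov = radius[pairs[:, 0]] + radius[pairs[:, 1]] - dist
    ux, uy = dx / dist, dy / dist
    half = 0.5 * ov
    np.add.at(disp[:, 0], pairs[:, 0], ux * half)
    np.add.at(disp[:, 1], pairs[:, 0], uy * half)
    np.add.at(disp[:, 0], pairs[:, 1], -ux * half)
    np.add.at(disp[:, 1], pairs[:, 1], -uy * half)
    return disp, float(ov.max())


def _batch_wall_contact(x0, y0, x1, y1, r, lattice):
    """Vectorized exact first wall contact for short segments.

    Considers the 3x3 block neighborhood of each start point (sufficient
    for displacements below one block size) and intersects each segment
    with the solid rectangles dilated by the swept radius: four offset
    edges plus four corner circles per rectangle, all in closed form.
    Returns the constrained end points.
    """
    b = lattice.block_size
    n = x0.size
    xw = x0 % lattice.width
    ix = np.floor(xw / b).astype(int)
    iy = np.floor(y0 / b).astype(int)
    dx = x1 - x0
    dy = y1 - y0
    tmin = np.ones(n)
    big = 2.0
    for ox in (-1, 0, 1):
        jx = (ix + ox) % lattice.nx
        rx0 = x0 + ((ix + ox) * b - xw)  # rect left edge, unwrapped
        for oy in (-1, 0, 1):
            jy = iy + oy
            valid = (jy >= 0) & (jy < lattice.ny)
            solid = np.zeros(n, dtype=bool)
            solid[valid] = lattice.solid[jx[valid], jy[valid]]
            if not solid.any():
                continue
            ry0 = jy * b
            rx1, ry1 = rx0 + b, ry0 + b
            ts = np.full((12, n), big)
            with np.errstate(divide="ignore", invalid="ignore"):
                # offset edges
                for slot, (edge, delta, s, lo, hi, other) in enumerate((
                        (rx0 - r, dx, x0, ry0, ry1, None),
                        (rx1 + r, dx, x0, ry0, ry1, None),
                        (ry0 - r, dy, y0, rx0, rx1, "x"),
                        (ry1 + r, dy, y0, rx0, rx1, "x"))):
                    t = (edge - s) / delta
                    if other is None:
                        oth = y0 + t * dy
                    else:
                        oth = x0 + t * dx
                    ok = (t >= 0) & (t <= 1) & (oth >= lo) & (oth <= hi)
                    ts[slot] = np.where(ok, t, big)
                # corner circles
                a = dx * dx + dy * dy
                slot = 4
                for left, bottom in ((True, True), (True, False),
                                     (False, True), (False, False)):
                    cx = rx0 if left else rx1
                    cy = ry0 if bottom else ry1
                    fx = x0 - cx
                    fy = y0 - cy
                    bq = 2 * (fx * dx + fy * dy)
                    c = fx * fx + fy * fy - r * r
                    disc = bq * bq - 4 * a * c
                    sq = np.sqrt(np.maximum(disc, 0.0))
                    for root in ((-bq - sq), (-bq + sq)):
                        t = np.where((disc >= 0) & (a > 0), root / (2 * a), big)
                        px = x0 + t * dx
                        py = y0 + t * dy
                        # contact point must lie in the corner quadrant
                        okx = (px <= cx) if left else (px >= cx)
                        oky = (py <= cy) if bottom else (py >= cy)
                        ok = (t >= 0) & (t <= 1) & okx & oky
                        ts[slot] = np.where(ok, t, big)
                        slot += 1
            t_rect = ts.min(axis=0)
            tmin = np.where(solid, np.minimum(tmin, t_rect), tmin)
    return x0 + tmin * dx, y0 + tmin * dy


def relax(pop, lattice: SubstratumLattice, max_iters: int = 50,
          tol: float = 1e-2, rng: np.random.Generator | None = None):
    """Alternate shoving and wall constraints until overlap falls below tol.

    Only attached agents participate.  Returns (iterations, residual
    maximum overlap); non-convergence is reported, not fatal.
    """
    att = np.flatnonzero(pop.attached)
    if att.size == 0:
        return 0, 0.0
    x = pop.x[att].copy()
    y = pop.y[att].copy()
    radius = pop.radius[att]
    residual = 0.0
    iters = 0
    from .motility import solid_top

    top = solid_top(lattice)
    rmax = float(radius.max())
    for iters in range(1, max_iters + 1):
        disp, residual = shove_iteration(x, y, radius, pop.width, pop.height, rng)
        # only agents close to the substratum can interact with it
        near = np.flatnonzero(y < top + rmax + 1.0)
        d2s = np.full(x.size, np.inf)
        if near.size:
            d2s_n, away = distance_to_solid(x[near], y[near], lattice,
                                            return_direction=True)
            d2s[near] = d2s_n
            # the substratum shoves too: cells embedded in a wall (they grow
            # while resting on it) are pushed out along the outward normal
            wall_ov = radius[near] - d2s_n
            wmask = wall_ov > 0
            if wmask.any():
                disp[near[wmask]] += away[wmask] * wall_ov[wmask, None]
                residual = max(residual, float(wall_ov[wmask].max()))
        if residual < tol:
            break
        cx = x + disp[:, 0]
        cy = np.minimum(y + disp[:, 1], pop.height)
        moved = np.flatnonzero(((disp[:, 0] != 0) | (disp[:, 1] != 0))
                               & (d2s < np.inf))
        if moved.size:
            r_eff = np.minimum(radius[moved], np.maximum(d2s[moved], 0.0))
            bad = np.atleast_1d(distance_to_solid(cx[moved], cy[moved], lattice)
                                < r_eff - CONTACT_TOL)
            if bad.any():
                sub = moved[bad]
                tx, ty = _batch_wall_contact(x[sub], y[sub], cx[sub], cy[sub],
                                             r_eff[bad], lattice)
                cx[sub] = tx
                cy[sub] = ty
        free = (disp[:, 0] != 0) | (disp[:, 1] != 0)
        x[free] = cx[free] % pop.width
        y[free] = cy[free]
    pop.x[att] = x
    pop.y[att] = y
    pop.invalidate_index()
    return iters, residual
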