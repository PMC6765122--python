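"""Writhe, twist and linking-number bookkeeping for polygonal DNA paths.

The writhe of a space curve is the signed crossing number averaged over all
projection directions.  For a polygonal curve it decomposes into a sum over
non-adjacent segment pairs, each term being the fraction of the viewing
sphere from which the pair is seen to cross, computed from the solid angle
enclosed by four planes (Levitt's construction):

    Omega_ij = A + B + C + D - 2*pi,     W_ij = +/- Omega_ij / (2*pi)

with A..D the angles between the four plane normals

    a = (r_i - r_{j+1}) x (r_i - r_j)
    b = (r_i - r_{j+1}) x (r_{i+1} - r_{j+1})
    c = (r_{i+1} - r_j) x (r_{i+1} - r_{j+1})
    d = (r_{i+1} - r_j) x (r_i - r_j)

and the sign that of [(r_{i+1} - r_i) x (r_{j+1} - r_j)] . (r_i - r_j), the
Gauss-integral convention under which a left-handed (negatively supercoiled)
superhelix has negative writhe.

A numerical Gauss double-integral evaluator is provided as an independent
cross-check (test oracle); it is not the production path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PolygonalCurve",
    "TwistModel",
    "segment_pair_writhe",
    "writhe_levitt",
    "writhe_gauss_numeric",
    "twist_change",
    "linking_change_per_nucleosome",
    "per_nucleosome_writhe",
]


@dataclass(frozen=True)
class PolygonalCurve:
    """Ordered vertices (Angstrom) of an open or closed polygonal curve."""

    vertices: np.ndarray
    closed: bool = False

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 3:
            raise ValueError("need an (n>=3, 3) vertex array")
        if np.any(np.linalg.norm(np.diff(v, axis=0), axis=1) <= 1e-9):
            raise ValueError("consecutive vertices must be distinct")
        object.__setattr__(self, "vertices", v)


@dataclass(frozen=True)
class TwistModel:
    """Helical repeats (bp/turn) of linker DNA, relaxed vs in the compact fibre."""

    repeat_relaxed: float = 10.5
    repeat_fibre: float = 10.0
    nucleosome_core_bp: int = 147

    def __post_init__(self):
        if self.repeat_relaxed <= 0 or self.repeat_fibre <= 0:
            raise ValueError("helical repeats must be positive")


def segment_pair_writhe(r_i, r_i1, r_j, r_j1) -> float:
    """Directional writhe contribution W_ij of two non-adjacent segments.

    Returns 0 for coplanar or degenerate (collinear-triple) configurations.
    """
    r_i, r_i1, r_j, r_j1 = (np.asarray(x, float) for x in (r_i, r_i1, r_j, r_j1))
    a = np.cross(r_i - r_j1, r_i - r_j)
    b = np.cross(r_i - r_j1, r_i1 - r_j1)
    c = np.cross(r_i1 - r_j, r_i1 - r_j1)
    d = np.cross(r_i1 - r_j, r_i - r_j)
    na, nb, nc, nd = (np.linalg.norm(x) for x in (a, b, c, d))
    if min(na, nb, nc, nd) < 1e-12:
        return 0.0
    A = np.arccos(np.clip(a @ d / (na * nd), -1, 1))
    B = np.arccos(np.clip(b @ a / (nb * na), -1, 1))
    C = np.arccos(np.clip(c @ b / (nc * nb), -1, 1))
    D = np.arccos(np.clip(d @ c / (nd * nc), -1, 1))
    omega = A + B + C + D - 2 * np.pi
    sign = np.dot(np.cross(r_i1 - r_i, r_j1 - r_j), r_i - r_j)
    return float(np.copysign(omega / (2 * np.pi), sign)) if omega > 1e-15 else 0.0


def _pair_sum_numpy(seg_a: np.ndarray, seg_b: np.ndarray) -> float:
    """Vectorized Levitt pair sum over all j >= i+2 (upper triangle), tiled."""
    n = seg_a.shape[0]
    total = 0.0
    block = 256
    for i0 in range(0, n - 2, block):
        i1 = min(i0 + block, n - 2)
        ri = seg_a[i0:i1, None, :]
        ri1 = seg_b[i0:i1, None, :]
        rj = seg_a[None, i0 + 2 :, :]
        rj1 = seg_b[None, i0 + 2 :, :]
        a = np.cross(ri - rj1, ri - rj)
        b = np.cross(ri - rj1, ri1 - rj1)
        c = np.cross(ri1 - rj, ri1 - rj1)
        d = np.cross(ri1 - rj, ri - rj)
        na = np.linalg.norm(a, axis=-1)
        nb = np.linalg.norm(b, axis=-1)
        nc = np.linalg.norm(c, axis=-1)
        nd = np.linalg.norm(d, axis=-1)
        ok = np.minimum(np.minimum(na, nb), np.minimum(nc, nd)) > 1e-12
        # mask the lower-triangle part of the tile (j < i+2)
        jj = np.arange(i0 + 2, n)[None, :]
        ii = np.arange(i0, i1)[:, None]
        ok &= jj >= ii + 2
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.arccos(np.clip(np.sum(a * d, -1) / (na * nd), -1, 1))
            B = np.arccos(np.clip(np.sum(b * a, -1) / (nb * na), -1, 1))
            C = np.arccos(np.clip(np.sum(c * b, -1) / (nc * nb), -1, 1))
            D = np.arccos(np.clip(np.sum(d * c, -1) / (nd * nc), -1, 1))
        omega = A + B + C + D - 2 * np.pi
        sign = np.sum(np.cross(ri1 - ri, rj1 - rj) * (ri - rj), -1)
        w = np.where(ok & (omega > 1e-15), np.copysign(omega, sign) / (2 * np.pi), 0.0)
        total += float(w.sum())
    return total


_numba_kernel = None


def _get_numba_kernel():
    global _numba_kernel
    if _numba_kernel is None:
        try:
            import numba
        except ImportError:
            _numba_kernel = False
            return _numba_kernel

        @numba.njit(cache=True, fastmath=False)
        def kernel(sa, sb):  # pragma: no cover - exercised via writhe_levitt
            n = sa.shape[0]
            total = 0.0
            for i in range(n - 2):
                rix, riy, riz = sa[i, 0], sa[i, 1], sa[i, 2]
                ri1x, ri1y, ri1z = sb[i, 0], sb[i, 1], sb[i, 2]
                tix, tiy, tiz = ri1x - rix, ri1y - riy, ri1z - riz
                for j in range(i + 2, n):
                    rjx, rjy, rjz = sa[j, 0], sa[j, 1], sa[j, 2]
                    rj1x, rj1y, rj1z = sb[j, 0], sb[j, 1], sb[j, 2]
                    # p = r_i - r_{j+1}, q = r_i - r_j
                    px, py, pz = rix - rj1x, riy - rj1y, riz - rj1z
                    qx, qy, qz = rix - rjx, riy - rjy, riz - rjz
                    # s = r_{i+1} - r_{j+1}, t = r_{i+1} - r_j
                    sx, sy, sz = ri1x - rj1x, ri1y - rj1y, ri1z - rj1z
                    tx, ty, tz = ri1x - rjx, ri1y - rjy, ri1z - rjz
                    ax, ay, az = py * qz - pz * qy, pz * qx - px * qz, px * qy - py * qx
                    bx, by, bz = py * sz - pz * sy, pz * sx - px * sz, px * sy - py * sx
                    cx, cy, cz = ty * sz - tz * sy, tz * sx - tx * sz, tx * sy - ty * sx
                    dx, dy, dz = ty * qz - tz * qy, tz * qx - tx * qz, tx * qy - ty * qx
                    na = (ax * ax + ay * ay + az * az) ** 0.5
                    nb = (bx * bx + by * by + bz * bz) ** 0.5
                    nc = (cx * cx + cy * cy + cz * cz) ** 0.5
                    nd = (dx * dx + dy * dy + dz * dz) ** 0.5
                    if na < 1e-12 or nb < 1e-12 or nc < 1e-12 or nd < 1e-12:
                        continue
                    ca = (ax * dx + ay * dy + az * dz) / (na * nd)
                    cb = (bx * ax + by * ay + bz * az) / (nb * na)
                    cc = (cx * bx + cy * by + cz * bz) / (nc * nb)
                    cd = (dx * cx + dy * cy + dz * cz) / (nd * nc)
                    ca = min(1.0, max(-1.0, ca))
                    cb = min(1.0, max(-1.0, cb))
                    cc = min(1.0, max(-1.0, cc))
                    cd = min(1.0, max(-1.0, cd))
                    omega = (
                        np.arccos(ca) + np.arccos(cb) + np.arccos(cc) + np.arccos(cd)
                        - 2 * np.pi
                    )
                    if omega <= 1e-15:
                        continue
                    tjx, tjy, tjz = rj1x - rjx, rj1y - rjy, rj1z - rjz
                    crx = tiy * tjz - tiz * tjy
                    cry = tiz * tjx - tix * tjz
                    crz = tix * tjy - tiy * tjx
                    sgn = crx * qx + cry * qy + crz * qz
                    if sgn < 0:
                        total -= omega / (2 * np.pi)
                    else:
                        total += omega / (2 * np.pi)
            return total

        _numba_kernel = kernel
    return _numba_kernel


def _segments(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, PolygonalCurve):
        v, closed = curve.vertices, curve.closed
    else:
        v, closed = np.asarray(curve, float), False
    if v.shape[0] < 3:
        raise ValueError("curve needs at least 3 vertices")
    sa, sb = v[:-1], v[1:]
    if closed:
        sa = np.vstack([sa, v[-1]])
        sb = np.vstack([sb, v[0]])
    return np.ascontiguousarray(sa), np.ascontiguousarray(sb)


def writhe_levitt(curve, engine: str = "auto") -> float:
    """Total directional writhe of a polygonal curve (Levitt pair sum).

    ``curve`` may be a PolygonalCurve or an (n, 3) vertex array (treated as
    open).  The sum runs over all non-adjacent segment pairs; for a closed
    curve the wrap-around segment is included and its adjacency respected.
    ``engine`` is "numba", "numpy" or "auto" (numba when available).
    """
    sa, sb = _segments(curve)
    if engine == "auto":
        kernel = _get_numba_kernel()
        engine = "numba" if kernel else "numpy"
    if engine == "numba":
        total = float(_get_numba_kernel()(sa, sb))
    elif engine == "numpy":
        total = _pair_sum_numpy(sa, sb)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    # for a closed curve the (first, wrap) pair shares a vertex and is
    # coplanar, hence contributes exactly 0 in the sum: no correction needed
    return total


def writhe_gauss_numeric(curve, order: int = 24) -> float:
    """Gauss double integral over segment pairs by fixed-order quadrature.

    Independent numerical cross-check of the closed-form pair sum; O(n^2 *
    order^2), intended for small curves in tests.
    """
    sa, sb = _segments(curve)
    closed = isinstance(curve, PolygonalCurve) and curve.closed
    n = sa.shape[0]
    x, wq = np.polynomial.legendre.leggauss(order)
    x = 0.5 * (x + 1.0)
    wq = 0.5 * wq
    total = 0.0
    for i in range(n - 2):
        di = sb[i] - sa[i]
        pi = sa[i][None, :] + x[:, None] * di[None, :]
        jmax = n if not (closed and i == 0) else n - 1
        for j in range(i + 2, jmax):
            dj = sb[j] - sa[j]
            cr = np.cross(di, dj)
            diff = pi[:, None, :] - (sa[j][None, None, :] + x[None, :, None] * dj[None, None, :])
            r3 = np.sum(diff * diff, axis=-1) ** 1.5
            integrand = (diff @ cr) / r3
            total += float(wq @ integrand @ wq)
    return total / (2 * np.pi)


def twist_change(linker_bp: float, model: TwistModel = TwistModel()) -> float:
    """Linker twist change (turns): positive when over-twisting toward the fibre repeat."""
    if linker_bp < 0:
        raise ValueError("linker length must be non-negative")
    return linker_bp * (1.0 / model.repeat_fibre - 1.0 / model.repeat_relaxed)


def linking_change_per_nucleosome(
    wr_per_nuc: float, linker_bp: float, model: TwistModel = TwistModel()
) -> float:
    """Linking-number change per nucleosome: dL = dWr + dTw."""
    return wr_per_nuc + twist_change(linker_bp, model)


def per_nucleosome_writhe(wr_total: float, n_nuc: int) -> float:
    """Total writhe divided by the nucleosome count (end effects accepted)."""
    if n_nuc < 1:
        raise ValueError("need at least one nucleosome")
    return wr_total / n_nuc
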