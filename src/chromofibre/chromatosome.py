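"""Chromatosome DNA path: superhelical core, straight arms, disc normal.

The chromatosome is treated purely as a space curve of base-pair midpoints:
a 167 bp path whose central 129 bp (bp 20-148) wind ~1.65 left-handed turns
around the histone octamer and whose two flanking 19 bp segments (the
entering and leaving DNAs, bp 1-19 and 149-167) are straight.  The canonical
frame puts the superhelical axis on z and the dyad axis on y, with the core
centred at the Cartesian origin.

The parametric core is

    x' = a sin(w n),  y' = a cos(w n),  z' = q w n,   n = -64 .. +64

with radius ``a`` (Angstrom), angular advance per bp ``w`` (rad) and rise per
radian ``q`` (Angstrom/rad); q > 0 gives a left-handed superhelix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BasePairPath",
    "SuperhelixFit",
    "ArmFit",
    "ChromatosomeTemplate",
    "PairingError",
    "StructureFormatError",
    "SuperhelixFitError",
    "DegenerateGeometryError",
    "BASE_STEP",
    "DEFAULT_A",
    "DEFAULT_OMEGA",
    "DEFAULT_Q",
    "extract_basepair_midpoints",
    "fit_superhelix",
    "fit_arm",
    "fit_chromatosome",
    "adjust_arms",
    "extend_arms",
    "disc_normal",
    "generate_ideal_chromatosome",
    "rot_x",
    "rot_z",
    "rot_y_paper",
    "translation",
]

#: canonical B-DNA base-step rise used throughout (Angstrom per bp)
BASE_STEP = 3.405

# Canonical superhelix defaults for the synthetic chromatosome: radius from
# nucleosome crystallography, angular advance giving ~1.64 left-handed turns
# over the 129 bp core, and a rise giving a superhelical pitch of ~26 A/turn.
DEFAULT_A = 41.9
DEFAULT_OMEGA = 0.0807
DEFAULT_Q = 4.2

MAX_ARM_ADJUST = np.pi / 36  # 5 degrees


class PairingError(ValueError):
    """Two DNA chains cannot be paired base-by-base."""


class StructureFormatError(ValueError):
    """Structure lacks the atoms needed to trace the DNA path."""


class SuperhelixFitError(RuntimeError):
    """Superhelix fit failed to converge; carries the best residual."""

    def __init__(self, message: str, rmsd: float):
        super().__init__(message)
        self.rmsd = rmsd


class DegenerateGeometryError(ValueError):
    """Input geometry has no spatial extent / is collinear where it must not be."""


# ---------------------------------------------------------------------------
# elementary homogeneous transforms (4x4), matching the composition
# conventions used by the model equations


def rot_x(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    m = np.eye(4)
    m[1, 1], m[1, 2], m[2, 1], m[2, 2] = c, -s, s, c
    return m


def rot_z(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    m = np.eye(4)
    m[0, 0], m[0, 1], m[1, 0], m[1, 1] = c, -s, s, c
    return m


def rot_y_paper(t: float) -> np.ndarray:
    """y-rotation in the convention used by the model equations.

    Note the sign placement: this equals a standard right-handed y-rotation
    by ``-t``.
    """
    c, s = np.cos(t), np.sin(t)
    m = np.eye(4)
    m[0, 0], m[0, 2], m[2, 0], m[2, 2] = c, -s, s, c
    return m


def translation(v) -> np.ndarray:
    m = np.eye(4)
    m[:3, 3] = v
    return m


def apply_transform(m: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 4x4 homogeneous transform to an (n, 3) point array."""
    return points @ m[:3, :3].T + m[:3, 3]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class BasePairPath:
    """Ordered base-pair midpoints tracing a DNA segment.

    ``coords`` is (n, 3) in Angstrom; ``index_offset`` is the 1-based label of
    the first base pair (bp 1..167 numbering of the chromatosome).
    """

    coords: np.ndarray
    index_offset: int = 1

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
            raise ValueError("coords must be an (n>=2, 3) array")
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def indices(self) -> np.ndarray:
        return np.arange(len(self)) + self.index_offset

    def spacings(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    def is_physical(self) -> bool:
        s = self.spacings()
        return bool(np.all((s >= 2.5) & (s <= 4.5)))


@dataclass(frozen=True)
class SuperhelixFit:
    """Least-squares alignment of a DNA core onto the parametric superhelix."""

    a: float
    omega: float
    q: float
    theta1: float
    theta2: float
    theta3: float
    xv: float
    yv: float
    zv: float
    rmsd: float

    def transform(self) -> np.ndarray:
        """4x4 transform A mapping input coordinates onto the canonical frame."""
        return (
            rot_z(self.theta1)
            @ rot_y_paper(self.theta2)
            @ rot_x(self.theta3)
            @ translation([self.xv, self.yv, self.zv])
        )

    def curve(self, n: np.ndarray) -> np.ndarray:
        """Parametric superhelix points at bp offsets ``n`` (0 at the dyad)."""
        n = np.asarray(n, dtype=float)
        t = self.omega * n
        return np.column_stack([self.a * np.sin(t), self.a * np.cos(t), self.q * t])


@dataclass(frozen=True)
class ArmFit:
    """Straight-line fit of an entering or leaving DNA segment."""

    base_point: np.ndarray  # core-proximal fitted point (3,)
    step_vector: np.ndarray  # per-bp step along genomic direction (3,)
    n_bp: int
    side: str  # "entry" | "exit"
    rmsd: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "base_point", np.asarray(self.base_point, float))
        object.__setattr__(self, "step_vector", np.asarray(self.step_vector, float))


@dataclass(frozen=True)
class ChromatosomeTemplate:
    """Fitted chromatosome DNA path in the canonical frame.

    ``path`` holds the full (167 + u + v, 3) base-pair path in genomic order;
    bp labels run 1 .. 167+u+v.  Arm adjustments (delta, phi) and extensions
    (u, v) already applied are recorded.
    """

    path: np.ndarray
    a: float
    omega: float
    q: float
    entry_arm: ArmFit
    exit_arm: ArmFit
    delta: float = 0.0
    phi: float = 0.0
    u: int = 0
    v: int = 0
    superhelix: SuperhelixFit | None = field(default=None, compare=False)

    def __post_init__(self):
        path = np.asarray(self.path, float)
        if path.shape != (167 + self.u + self.v, 3):
            raise ValueError(
                f"path must have 167+u+v={167 + self.u + self.v} points, got {path.shape[0]}"
            )
        object.__setattr__(self, "path", path)

    def __len__(self) -> int:
        return self.path.shape[0]

    # index helpers (0-based into ``path``)
    @property
    def entry_anchor_idx(self) -> int:
        return self.u + 18  # bp 19 of the unextended numbering

    @property
    def exit_anchor_idx(self) -> int:
        return self.u + 148  # bp 149

    @property
    def core(self) -> np.ndarray:
        """The 129 bp superhelical core (bp 20-148)."""
        return self.path[self.u + 19 : self.u + 148]

    @property
    def disc_normal(self) -> np.ndarray:
        return disc_normal(self.a, self.q)

    def as_path(self) -> BasePairPath:
        return BasePairPath(self.path, index_offset=1)


# ---------------------------------------------------------------------------
# operations


def extract_basepair_midpoints(structure, chain_pair) -> BasePairPath:
    """Trace a DNA duplex as midpoints between opposing phosphorus atoms.

    ``structure`` is a biotite AtomArray (or stack; the first model is used);
    ``chain_pair`` names the two complementary DNA chains.  Residues are
    paired antiparallel index-complementary: the i-th P of the first chain
    (5'->3') with the i-th-from-last P of the second.
    """
    import biotite.structure as struc

    if hasattr(structure, "stack_depth"):
        structure = structure[0]
    c1, c2 = chain_pair
    coords = []
    for chain in (c1, c2):
        mask = (structure.chain_id == chain) & (structure.element == "P")
        sub = structure[mask]
        if sub.array_length() == 0:
            raise StructureFormatError(f"no phosphorus atoms found in chain {chain!r}")
        order = np.argsort(sub.res_id, kind="stable")
        coords.append(sub.coord[order])
    p1, p2 = coords
    if len(p1) != len(p2):
        raise PairingError(
            f"chains {c1!r} and {c2!r} have {len(p1)} vs {len(p2)} phosphates; "
            "cannot pair antiparallel index-complementary strands"
        )
    mid = 0.5 * (p1 + p2[::-1])
    return BasePairPath(mid, index_offset=1)


def fit_superhelix(core: BasePairPath | np.ndarray, n_starts: int = 4) -> SuperhelixFit:
    """Fit the 129 bp core to the parametric superhelix by least squares.

    Minimizes the summed squared residuals between ``A @ p_i`` and the
    parametric curve at n = -64..+64, over the nine unknowns
    (theta1..3, xv, yv, zv, a, omega, q).  Multi-start quasi-Newton with a
    PCA-seeded initial frame; solutions normalized to a > 0, omega > 0.
    """
    pts = core.coords if isinstance(core, BasePairPath) else np.asarray(core, float)
    if pts.shape != (129, 3):
        raise ValueError("superhelix fit expects exactly 129 points (bp 20-148)")
    n = np.arange(-64, 65, dtype=float)

    def residuals(x):
        th1, th2, th3, xv, yv, zv, a, w, q = x
        A = rot_z(th1) @ rot_y_paper(th2) @ rot_x(th3) @ translation([xv, yv, zv])
        moved = apply_transform(A, pts)
        t = w * n
        curve = np.column_stack([a * np.sin(t), a * np.cos(t), q * t])
        return (moved - curve).ravel()

    starts = _superhelix_starts(pts, n, n_starts)
    best = None
    for x0 in starts:
        sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    rmsd = float(np.sqrt(np.mean(np.sum(residuals(best.x).reshape(-1, 3) ** 2, axis=1))))
    fit = _normalize_superhelix(best.x, rmsd)
    # guard: a fit worse than the point cloud scale means no superhelix was found
    scale = float(np.linalg.norm(pts - pts.mean(axis=0), axis=1).mean())
    if rmsd > 0.5 * scale:
        raise SuperhelixFitError(f"superhelix fit did not converge (rmsd={rmsd:.3g} A)", rmsd)
    return fit


def _superhelix_starts(pts, n, n_starts):
    """PCA-style initial frames: plane normal to z, phase/radius/pitch from data."""
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    starts = []
    for normal in (vt[2], -vt[2]):
        # rotation taking the plane normal to +z
        z = np.array([0.0, 0.0, 1.0])
        vperp = np.cross(normal, z)
        s = np.linalg.norm(vperp)
        c = float(np.dot(normal, z))
        if s < 1e-12:
            R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            k = vperp / s
            K = np.array([
                [0.0, -k[2], k[1]],
                [k[2], 0.0, -k[0]],
                [-k[1], k[0], 0.0],
            ])
            R = np.eye(3) + s * K + (1 - c) * (K @ K)
        local = centered @ R.T
        phi = np.unwrap(np.arctan2(local[:, 0], local[:, 1]))
        w0 = float(np.polyfit(n, phi, 1)[0])
        if w0 < 0:
            # try the mirrored frame instead; handled by the -normal start
            w0 = abs(w0)
        a0 = float(np.linalg.norm(local[:, :2], axis=1).mean())
        t = w0 * n
        q0 = float(np.polyfit(t, local[:, 2], 1)[0]) if np.ptp(t) > 0 else 1.0
        phi0 = float(np.polyfit(n, phi, 1)[1])
        M = rot_z(-phi0)[:3, :3] @ R
        th1, th2, th3 = _decompose_rotation(M)
        tvec = M.T @ (-M @ centroid)
        starts.append([th1, th2, th3, *tvec, a0, w0, q0])
        if len(starts) >= n_starts:
            break
    # jittered extras if requested
    rng = np.random.default_rng(0)
    while len(starts) < n_starts:
        base = starts[len(starts) % 2]
        jit = np.array(base, float)
        jit[:3] += rng.normal(scale=0.2, size=3)
        starts.append(list(jit))
    return starts


def _decompose_rotation(R):
    """Angles (theta1, theta2, theta3) with R = Rz(t1) @ Ry_paper(t2) @ Rx(t3)."""
    # Ry_paper(t) == standard Ry(-t); standard ZYX decomposition, pitch negated
    sy = -R[2, 0]
    sy = np.clip(sy, -1.0, 1.0)
    b_std = np.arcsin(sy)
    if abs(abs(sy) - 1.0) > 1e-9:
        a = np.arctan2(R[1, 0], R[0, 0])
        c = np.arctan2(R[2, 1], R[2, 2])
    else:  # gimbal lock
        a = np.arctan2(-R[0, 1], R[1, 1])
        c = 0.0
    return a, -b_std, c


def _normalize_superhelix(x, rmsd) -> SuperhelixFit:
    th1, th2, th3, xv, yv, zv, a, w, q = [float(v) for v in x]
    R = (rot_z(th1) @ rot_y_paper(th2) @ rot_x(th3))[:3, :3]
    flip = np.eye(3)
    if a < 0:
        a = -a
        flip = rot_z(np.pi)[:3, :3] @ flip
    if w < 0:
        w, q = -w, -q
        flip = rot_y_paper(-np.pi)[:3, :3] @ flip
    if not np.allclose(flip, np.eye(3)):
        th1, th2, th3 = _decompose_rotation(flip @ R)
    return SuperhelixFit(a, w, q, th1, th2, th3, xv, yv, zv, rmsd)


def fit_arm(points: BasePairPath | np.ndarray, side: str) -> ArmFit:
    """Total-least-squares line fit of an arm segment.

    ``points`` are the observed arm base pairs in genomic order (for the
    entry arm bp 2..19, for the exit arm bp 149..166).  The fitted
    ``base_point`` is anchored at the core-proximal end; ``step_vector``
    points along the genomic direction.
    """
    pts = points.coords if isinstance(points, BasePairPath) else np.asarray(points, float)
    if pts.shape[0] < 3:
        raise ValueError("arm fit needs at least 3 points")
    if side not in ("entry", "exit"):
        raise ValueError("side must be 'entry' or 'exit'")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.linalg.norm(centered, axis=1).max() < 1e-9:
        raise DegenerateGeometryError("arm points have no spatial extent")
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    k = np.arange(pts.shape[0], dtype=float)
    s = centered @ d
    slope, intercept = np.polyfit(k, s, 1)
    if slope < 0:  # orient along genomic order
        d, slope, intercept = -d, -slope, -intercept

    def fitted(i):
        return centroid + (intercept + slope * i) * d

    resid = centered - np.outer(s, d)
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    step = slope * d
    base = fitted(pts.shape[0] - 1) if side == "entry" else fitted(0.0)
    return ArmFit(base_point=base, step_vector=step, n_bp=19, side=side, rmsd=rmsd)


def _arm_points(arm: ArmFit, n_total: int) -> np.ndarray:
    """Arm path in genomic order including the one-step extrapolated terminus."""
    if arm.side == "entry":
        # base point is bp 19; bp j = base - (19 - j) * step, j = 1..19
        offsets = np.arange(-(n_total - 1), 1, dtype=float)
    else:
        # base point is bp 149; bp 149+k = base + k*step
        offsets = np.arange(0, n_total, dtype=float)
    return arm.base_point + np.outer(offsets, arm.step_vector)


def fit_chromatosome(path: BasePairPath) -> ChromatosomeTemplate:
    """Fit superhelix + arms to a 167 bp midpoint path and build the template.

    Input bp 1 and 167 (if present) are ignored and re-derived by one-step
    extrapolation of the arm fits, so the template is uniform regardless of
    missing terminal phosphates.
    """
    pts = path.coords
    if pts.shape[0] != 167:
        raise ValueError("expected a 167 bp chromatosome path")
    fit = fit_superhelix(pts[19:148])
    A = fit.transform()
    aligned = apply_transform(A, pts)
    entry = fit_arm(aligned[1:19], side="entry")
    exit_ = fit_arm(aligned[148:166], side="exit")
    n = np.arange(-64, 65, dtype=float)
    full = np.vstack([_arm_points(entry, 19), fit.curve(n), _arm_points(exit_, 19)])
    return ChromatosomeTemplate(
        path=full, a=fit.a, omega=fit.omega, q=fit.q,
        entry_arm=entry, exit_arm=exit_, superhelix=fit,
    )


def disc_normal(a: float, q: float) -> np.ndarray:
    """Unit normal to the nucleosomal disc in the canonical frame.

    The disc's bisecting plane is tilted from the xy plane by the superhelical
    climb over half a turn; the normal is (0,0,1) rotated about y by
    -arctan(q pi / 2a).
    """
    if a <= 0:
        raise DegenerateGeometryError("superhelix radius must be positive")
    t = np.arctan(q * np.pi / (2.0 * a))
    m = rot_y_paper(-t)
    return m[:3, :3] @ np.array([0.0, 0.0, 1.0])


def _arm_alignment(anchor: np.ndarray, tip: np.ndarray) -> np.ndarray:
    """Transform C taking the arm to the +y axis with its anchor at the origin."""
    d = tip - anchor
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise DegenerateGeometryError("arm has zero length")
    lam2 = np.arctan2(d[0], d[1])
    rho = np.hypot(d[0], d[1])
    lam1 = np.arctan2(d[2], rho)
    return rot_x(-lam1) @ rot_z(lam2) @ translation(-anchor)


def adjust_arms(template: ChromatosomeTemplate, delta: float, phi: float) -> ChromatosomeTemplate:
    """Rigidly swivel both arms about their core-proximal anchors.

    Each arm is aligned to +y with its anchor at the origin, rotated by
    (-delta about z, -phi about x) for the entry arm and (+delta, +phi) for
    the exit arm, then mapped back.  |delta|, |phi| <= 5 degrees.
    """
    if abs(delta) > MAX_ARM_ADJUST + 1e-12 or abs(phi) > MAX_ARM_ADJUST + 1e-12:
        raise ValueError("arm adjustments delta, phi must be within 5 degrees")
    path = template.path.copy()
    ea, xa = template.entry_anchor_idx, template.exit_anchor_idx

    # entry arm: anchor bp19, tip bp1 (outermost)
    C = _arm_alignment(path[ea], path[0])
    B = rot_x(-phi) @ rot_z(-delta)
    M = np.linalg.inv(C) @ B @ C
    path[: ea + 1] = apply_transform(M, path[: ea + 1])
    entry = replace(
        template.entry_arm,
        base_point=M[:3, :3] @ template.entry_arm.base_point + M[:3, 3],
        step_vector=M[:3, :3] @ template.entry_arm.step_vector,
    )

    # exit arm: anchor bp149, tip bp 167+u+v
    C = _arm_alignment(path[xa], path[-1])
    B = rot_x(phi) @ rot_z(delta)
    M = np.linalg.inv(C) @ B @ C
    path[xa:] = apply_transform(M, path[xa:])
    exit_ = replace(
        template.exit_arm,
        base_point=M[:3, :3] @ template.exit_arm.base_point + M[:3, 3],
        step_vector=M[:3, :3] @ template.exit_arm.step_vector,
    )
    return replace(
        template, path=path, entry_arm=entry, exit_arm=exit_,
        delta=template.delta + delta, phi=template.phi + phi,
    )


def extend_arms(template: ChromatosomeTemplate, u: int, v: int) -> ChromatosomeTemplate:
    """Append u (entry) and v (exit) extra base pairs along each arm's line.

    New points continue the arm trajectories at the arm's uniform base-step
    spacing; extension is additive: extending by u1 then u2 equals extending
    by u1+u2.
    """
    if u < 0 or v < 0 or int(u) != u or int(v) != v:
        raise ValueError("arm extensions u, v must be non-negative integers")
    u, v = int(u), int(v)
    path = template.path
    step_en = path[0] - path[1]
    step_ex = path[-1] - path[-2]
    pre = path[0] + np.outer(np.arange(u, 0, -1, dtype=float), step_en)
    post = path[-1] + np.outer(np.arange(1, v + 1, dtype=float), step_ex)
    new_path = np.vstack([pre, path, post]) if (u or v) else path
    return replace(template, path=new_path, u=template.u + u, v=template.v + v)


def generate_ideal_chromatosome(
    a: float = DEFAULT_A, omega: float = DEFAULT_OMEGA, q: float = DEFAULT_Q,
) -> ChromatosomeTemplate:
    """Synthetic canonical chromatosome: exact superhelical core + tangent arms.

    The 129 bp core lies exactly on the parametric superhelix; each 19 bp arm
    continues the core tangent at its junction with uniform base-step spacing.
    """
    if a <= 0:
        raise ValueError("superhelix radius a must be positive")
    if omega == 0:
        raise ValueError("angular advance omega must be nonzero")
    fit = SuperhelixFit(a, omega, q, 0, 0, 0, 0, 0, 0, rmsd=0.0)
    n = np.arange(-64, 65, dtype=float)
    core = fit.curve(n)

    def tangent(n0):
        t = omega * n0
        d = np.array([a * omega * np.cos(t), -a * omega * np.sin(t), q * omega])
        return d / np.linalg.norm(d)

    t_en = tangent(-64.0)  # genomic direction at the entry junction
    t_ex = tangent(64.0)
    entry = ArmFit(
        base_point=core[0] - BASE_STEP * t_en,  # bp 19 sits one step before bp 20
        step_vector=BASE_STEP * t_en, n_bp=19, side="entry",
    )
    exit_ = ArmFit(
        base_point=core[-1] + BASE_STEP * t_ex,  # bp 149, one step after bp 148
        step_vector=BASE_STEP * t_ex, n_bp=19, side="exit",
    )
    full = np.vstack([_arm_points(entry, 19), core, _arm_points(exit_, 19)])
    return ChromatosomeTemplate(
        path=full, a=a, omega=omega, q=q, entry_arm=entry, exit_arm=exit_, superhelix=fit,
    )
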