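"""Fibre assembly: place chromatosomes on 1-start/2-start helical stacks.

Nucleosomes are numbered 1..n in genomic order.  Odd and even nucleosomes
form two series.  Both series wind around a common left-handed fibre axis
(z): the k-th member of a series relates to its first by a screw of
rotation -k*alpha and rise h*k*alpha.  The first members are placed by the
rigid transforms D_n1 / D_n2 which put the chromatosome origin at radius r,
tilt its superhelical axis tangent to the helical path (by -arctan(h/r))
and roll the disc by +theta (series 1) or -theta (series 2).

The even series is phased ahead of the odd by beta (rotation beta, rise
h*beta).  The spacing alpha and the ratio beta/alpha fix the architecture.
2-start: alpha is small and beta ~ pi, so each series forms its own steep
stack (face-to-face contacts i +- 2) diametrically opposite the other, and
every linker crosses the fibre interior.  1-start: alpha is larger and
beta ~ (m + 1/2)*alpha with m = int(beta/alpha) >= 4, so the two series
interdigitate into one low-pitch stack where nucleosome i packs against
i +- (2m-1) and i +- (2m+1).  In both regimes the nucleosomes n_{2m+1} and
n_{2m+3} are the series-1 members flanking n2 in angle, and their
centre-to-centre distances to n2 are the closed forms below.

Straight linker DNA bridges the exit base pair of each nucleosome to the
entry base pair of the next.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .chromatosome import (
    BASE_STEP,
    ChromatosomeTemplate,
    DegenerateGeometryError,
    adjust_arms,
    apply_transform,
    extend_arms,
    rot_x,
    rot_y_paper,
    rot_z,
    translation,
)

__all__ = [
    "FibreParams",
    "FibreModel",
    "ConstraintReport",
    "FibreMetrics",
    "GeometryError",
    "placement_matrix",
    "place_nucleosome",
    "build_fibre",
    "adjacent_nucleosome_distances",
    "linker_line_distance",
    "evaluate_linker_clearances",
    "relative_twist_geometric",
    "relative_twist_geometric_signed",
    "relative_twist_from_linker",
    "fold_twist",
    "wrap_angle",
    "packing_density",
    "min_nonlocal_approach",
    "stacking_distance",
    "nuc_per_11nm",
    "connectivity_pattern",
    "compute_metrics",
    "BASELINE_TWIST_DEG",
    "NUCLEOSOME_DISC_RADIUS",
]

#: empirical twist baseline (degrees) between stacked cores at zero linker length
BASELINE_TWIST_DEG = 51.52
#: radius of the nucleosomal disc (Angstrom), used for the fibre envelope
NUCLEOSOME_DISC_RADIUS = 55.0


class GeometryError(ValueError):
    """Physically impossible fibre geometry (e.g. overlapping nucleosomes)."""


@dataclass(frozen=True)
class FibreParams:
    """The nine geometric variables of a fibre model plus bookkeeping.

    Angles in radians, lengths in Angstrom.  ``r``: stack-helix radius;
    ``h``: rise per radian (fibre pitch = 2*pi*h); ``alpha``: angular spacing
    of consecutive same-series nucleosomes; ``beta``: phase of the even
    series; ``theta``: disc roll about the helical tangent; ``delta``,
    ``phi``: arm swivels; ``u``, ``v``: integer arm extensions (bp).
    ``u2``/``v2`` optionally give even-numbered nucleosomes different arm
    extensions (alternating-NRL fibres).
    """

    r: float
    h: float
    alpha: float
    beta: float
    theta: float
    delta: float = 0.0
    phi: float = 0.0
    u: int = 0
    v: int = 0
    start_mode: str = "2-start"
    n_nuc: int = 32
    u2: int | None = None
    v2: int | None = None

    def __post_init__(self):
        if self.r <= 0 or self.h <= 0:
            raise ValueError("r and h must be positive")
        if not (0 < self.alpha < 2 * np.pi):
            raise ValueError("alpha must lie in (0, 2*pi)")
        if not (0 <= self.beta < 2 * np.pi):
            raise ValueError("beta must lie in [0, 2*pi)")
        if self.n_nuc < 4:
            raise ValueError("need at least 4 nucleosomes")
        if self.start_mode not in ("1-start", "2-start"):
            raise ValueError("start_mode must be '1-start' or '2-start'")

    @property
    def m(self) -> int:
        """Interdigitation index int(beta/alpha)."""
        return int(self.beta / self.alpha)

    def extensions(self, index: int) -> tuple[int, int]:
        """(u, v) for nucleosome ``index`` (1-based; even series may differ)."""
        if index % 2 == 0 and self.u2 is not None:
            return int(self.u2), int(self.v2 if self.v2 is not None else self.u2)
        return int(self.u), int(self.v)


def placement_matrix(params: FibreParams, index: int) -> np.ndarray:
    """Rigid 4x4 transform placing nucleosome ``index`` (1-based) on the fibre."""
    if index < 1:
        raise ValueError("nucleosome index is 1-based")
    r, h, alpha, beta, theta = params.r, params.h, params.alpha, params.beta, params.theta
    tilt = rot_y_paper(-np.arctan(h / r))
    if index % 2 == 1:
        D = (
            translation([-r, 0.0, 0.0])
            @ rot_z(-np.pi / 2)
            @ tilt
            @ rot_x(theta)
            @ rot_y_paper(-np.pi / 2)
        )
        k = (index - 1) // 2
    else:
        D = (
            translation([-r * np.cos(beta), r * np.sin(beta), h * beta])
            @ rot_z(3 * np.pi / 2 - beta)
            @ tilt
            @ rot_x(-theta)
            @ rot_y_paper(np.pi / 2)
        )
        k = (index - 2) // 2
    screw = rot_z(-k * alpha)
    screw[2, 3] = h * k * alpha
    return screw @ D


def place_nucleosome(
    template: ChromatosomeTemplate, params: FibreParams, index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Placed bp path and unit disc normal of nucleosome ``index``."""
    M = placement_matrix(params, index)
    return apply_transform(M, template.path), M[:3, :3] @ template.disc_normal


@dataclass
class FibreModel:
    """A placed n-mer fibre: nucleosome paths, linkers, normals."""

    params: FibreParams
    template: ChromatosomeTemplate  # base template (unadjusted, unextended)
    nucleosome_paths: list[np.ndarray]
    nucleosome_normals: list[np.ndarray]
    linker_paths: list[np.ndarray]  # interior linker bp (may be empty arrays)
    centres: np.ndarray = field(default=None)

    @cached_property
    def full_path(self) -> np.ndarray:
        """All bp positions in genomic order (nucleosomes + linker interiors)."""
        parts = []
        for i, nuc in enumerate(self.nucleosome_paths):
            parts.append(nuc)
            if i < len(self.linker_paths) and len(self.linker_paths[i]):
                parts.append(self.linker_paths[i])
        return np.vstack(parts)

    @property
    def n_nuc(self) -> int:
        return len(self.nucleosome_paths)

    def linker_gap(self, i: int) -> float:
        """Exit-to-entry straight gap (Angstrom) between nucleosomes i, i+1 (1-based i)."""
        return float(
            np.linalg.norm(self.nucleosome_paths[i][0] - self.nucleosome_paths[i - 1][-1])
        )

    def linker_line(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Point + direction of linker Lk_i (between nucleosomes i and i+1)."""
        p = self.nucleosome_paths[i - 1][-1]
        d = self.nucleosome_paths[i][0] - p
        return p, d

    def linker_bp(self, i: int) -> float:
        """Equivalent linker length N (bp, fractional) for linker Lk_i."""
        u, _ = self.params.extensions(i + 1)  # entry extension of nucleosome i+1
        _, v = self.params.extensions(i)  # exit extension of nucleosome i
        return self.linker_gap(i) / BASE_STEP + 19 + u + v


def build_fibre(template: ChromatosomeTemplate, params: FibreParams) -> FibreModel:
    """Assemble an n-mer fibre from a base template and fibre parameters.

    The template's arms are swiveled by (delta, phi) and extended by (u, v)
    before placement; interior linker base pairs are laid at uniform spacing
    along each straight exit-to-entry segment.
    """
    if template.u or template.v or template.delta or template.phi:
        raise ValueError("build_fibre expects an unadjusted, unextended base template")
    adjusted = adjust_arms(template, params.delta, params.phi)
    templates = {}
    for parity in (1, 2):
        u, v = params.extensions(parity)
        templates[parity % 2] = extend_arms(adjusted, u, v)

    paths, normals = [], []
    for i in range(1, params.n_nuc + 1):
        tpl = templates[i % 2]
        M = placement_matrix(params, i)
        paths.append(apply_transform(M, tpl.path))
        normals.append(M[:3, :3] @ tpl.disc_normal)

    centres = np.array(
        [placement_matrix(params, i)[:3, 3] for i in range(1, params.n_nuc + 1)]
    )
    d_consec = np.linalg.norm(np.diff(centres, axis=0), axis=1)
    if np.any(d_consec < 20.0):
        raise GeometryError(
            f"overlapping consecutive nucleosomes (min centre distance {d_consec.min():.1f} A)"
        )

    linkers = []
    for i in range(params.n_nuc - 1):
        a, b = paths[i][-1], paths[i + 1][0]
        gap = np.linalg.norm(b - a)
        nstep = max(int(round(gap / BASE_STEP)), 1)
        frac = np.arange(1, nstep)[:, None] / nstep
        linkers.append(a + frac * (b - a))

    return FibreModel(
        params=params, template=template, nucleosome_paths=paths,
        nucleosome_normals=normals, linker_paths=linkers, centres=centres,
    )


# ---------------------------------------------------------------------------
# closed-form geometric quantities


def adjacent_nucleosome_distances(params: FibreParams) -> tuple[float, float]:
    """Centre-to-centre distances between a nucleosome and its two adjacent neighbours.

    The closed forms for nucleosome n2 (phase beta) against the series-1
    members at angles m*alpha and (m+1)*alpha, with m = int(beta/alpha) —
    i.e. against nucleosomes n_{2m+1} and n_{2m+3}.  For the 2-start regime
    (beta < alpha) these are n1 and n3, the cross-start neighbours.
    """
    r, h, alpha, beta = params.r, params.h, params.alpha, params.beta
    m = params.m
    d1 = np.sqrt(
        (-r * np.cos(beta) + r * np.cos(m * alpha)) ** 2
        + (r * np.sin(beta) - r * np.sin(m * alpha)) ** 2
        + (beta * h - m * alpha * h) ** 2
    )
    d2 = np.sqrt(
        (-r * np.cos((m + 1) * alpha) + r * np.cos(beta)) ** 2
        + (r * np.sin((m + 1) * alpha) - r * np.sin(beta)) ** 2
        + ((m + 1) * alpha * h - beta * h) ** 2
    )
    return float(d1), float(d2)


def linker_line_distance(p1, d1, p2, d2, parallel_tol: float = 1e-9) -> float:
    """Minimal distance between two infinite lines (point + direction).

    Solves the two-parameter closed form; near-parallel lines (normal-equation
    determinant below ``parallel_tol`` relative to scale) fall back to
    point-to-line distance.
    """
    p1, d1, p2, d2 = (np.asarray(x, float) for x in (p1, d1, p2, d2))
    n1, n2 = np.linalg.norm(d1), np.linalg.norm(d2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("line directions must be nonzero")
    w = p2 - p1
    a = float(d1 @ d1)
    b = float(d1 @ d2)
    c = float(d2 @ d2)
    den = b * b - a * c
    if abs(den) < parallel_tol * a * c:
        u = d1 / n1
        return float(np.linalg.norm(w - (w @ u) * u))
    s = (b * float(d2 @ w) - c * float(d1 @ w)) / den
    t = (a * float(d2 @ w) - b * float(d1 @ w)) / den
    return float(np.linalg.norm(w + t * d2 - s * d1))


def _arm_lines(model: FibreModel, index: int):
    """Infinite lines through the entry and exit 19 bp arm segments of a nucleosome."""
    path = model.nucleosome_paths[index - 1]
    u, v = model.params.extensions(index)
    en_a, en_b = path[0], path[u + 18]
    ex_a, ex_b = path[-(v + 19)], path[-1]
    return [(en_a, en_b - en_a), (ex_a, ex_b - ex_a)]


def evaluate_linker_clearances(model: FibreModel) -> list[tuple[str, float]]:
    """Labelled clearance distances among interior linkers and interface arms.

    Interior pairs (Lk1,Lk2), (Lk2,Lk3), (Lk1,Lk3), (Lk2,Lk4), plus the
    entering/leaving-arm interface pair between nucleosomes n_{2m+1} and n_2
    selected by m = int(beta/alpha), when the stacking partner is not itself
    linker-connected to n_2 (m >= 2) and the model is long enough.
    """
    if model.n_nuc < 5:
        raise ValueError("need at least 5 nucleosomes (4 linkers) for clearances")
    out = []
    for i, j in [(1, 2), (2, 3), (1, 3), (2, 4)]:
        d = linker_line_distance(*model.linker_line(i), *model.linker_line(j))
        out.append((f"Lk{i}-Lk{j}", d))
    m = model.params.m
    partner = 2 * m + 1
    if m >= 2 and partner <= model.n_nuc:
        dmin = min(
            linker_line_distance(*la, *lb)
            for la in _arm_lines(model, partner)
            for lb in _arm_lines(model, 2)
        )
        out.append((f"n{partner}/n2", float(dmin)))
    return out


def relative_twist_geometric(model: FibreModel, i: int) -> float:
    """Structural relative twist (rad) between consecutive nucleosomes i, i+1.

    Angle between the in-plane reference vectors V_b = V_nm x V_Lk of the two
    discs, where V_Lk is the straight linker trajectory between them.
    """
    if not (1 <= i < model.n_nuc):
        raise ValueError("need consecutive nucleosomes i, i+1 inside the model")
    v_lk = model.nucleosome_paths[i][0] - model.nucleosome_paths[i - 1][-1]
    b1 = np.cross(model.nucleosome_normals[i - 1], v_lk)
    b2 = np.cross(model.nucleosome_normals[i], v_lk)
    n1, n2 = np.linalg.norm(b1), np.linalg.norm(b2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise DegenerateGeometryError("disc normal parallel to linker trajectory")
    return float(np.arccos(np.clip(b1 @ b2 / (n1 * n2), -1.0, 1.0)))


def relative_twist_from_linker(model: FibreModel, i: int, helical_repeat: float = 10.0) -> float:
    """Relative twist (rad) dictated by the linker DNA's helical winding.

    N is the fractional linker length in bp; the result is
    2*pi*(1 - frac(N/repeat + 1 - 51.52/360)) with frac(x) = x - floor(x).
    """
    if helical_repeat <= 0:
        raise ValueError("helical repeat must be positive")
    n_bp = model.linker_bp(i)
    x = n_bp / helical_repeat + 1.0 - BASELINE_TWIST_DEG / 360.0
    return float(2 * np.pi * (1.0 - (x - np.floor(x))))


def fold_twist(angle: float) -> float:
    """Fold an angle in [0, 2*pi) to the unsigned equivalent in [0, pi]."""
    a = angle % (2 * np.pi)
    return float(min(a, 2 * np.pi - a))


def wrap_angle(angle: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    return float(-((-angle + np.pi) % (2 * np.pi) - np.pi))


def relative_twist_geometric_signed(model: FibreModel, i: int) -> float:
    """Signed structural twist in (-pi, pi], right-handed about the linker.

    Magnitude as relative_twist_geometric; the sign is that of
    (V_b1 x V_b2) . V_Lk, i.e. positive when the disc reference vector
    rotates right-handedly about the linker direction from nucleosome i to
    i+1.  The sign disambiguates the two chiral registers that the unsigned
    angle cannot distinguish.
    """
    v_lk = model.nucleosome_paths[i][0] - model.nucleosome_paths[i - 1][-1]
    b1 = np.cross(model.nucleosome_normals[i - 1], v_lk)
    b2 = np.cross(model.nucleosome_normals[i], v_lk)
    ang = relative_twist_geometric(model, i)
    s = np.dot(np.cross(b1, b2), v_lk)
    return float(np.copysign(ang, s) if s != 0 else ang)


def packing_density(model: FibreModel) -> float:
    """Fibre packing density D_fibre in bp per cubic Angstrom.

    bp content of a two-nucleosome repeating unit (two full chromatosome
    paths plus the two bridging linker gaps) over the enclosing cylinder
    volume of radius r+55 and axial extent alpha*h.
    """
    if model.n_nuc < 3:
        raise ValueError("need at least 3 nucleosomes")
    p = model.params
    n_bp_nuc = 167 + p.u + p.v
    numer = (model.linker_gap(1) + model.linker_gap(2)) / BASE_STEP + 2 * (n_bp_nuc - 1)
    denom = p.alpha * p.h * np.pi * (p.r + NUCLEOSOME_DISC_RADIUS) ** 2
    return float(numer / denom)


def min_nonlocal_approach(model: FibreModel, genomic_exclusion_bp: int = 10,
                          cap: float = 28.0) -> float:
    """Closest DNA-DNA approach (Angstrom) between distinct structural units.

    Considers base-pair point pairs belonging to different nucleosomes (or a
    linker and anything it does not join onto) that are at least
    ``genomic_exclusion_bp`` apart along the path; distances beyond ``cap``
    are reported as ``cap``.  Two touching B-DNA duplexes have an axial
    separation of ~20 A, so values below that signal a sterically impossible
    (self-intersecting) placement that the plain clearance list cannot see.
    """
    from scipy.spatial import cKDTree

    parts, unit, genomic = [], [], []
    g = 0
    for i, nuc in enumerate(model.nucleosome_paths):
        parts.append(nuc)
        unit.append(np.full(len(nuc), 2 * i))
        genomic.append(np.arange(g, g + len(nuc)))
        g += len(nuc)
        if i < len(model.linker_paths) and len(model.linker_paths[i]):
            lk = model.linker_paths[i]
            parts.append(lk)
            unit.append(np.full(len(lk), 2 * i + 1))
            genomic.append(np.arange(g, g + len(lk)))
            g += len(lk)
    pts = np.vstack(parts)
    unit = np.concatenate(unit)
    genomic = np.concatenate(genomic)
    tree = cKDTree(pts, balanced_tree=False, compact_nodes=False)
    pairs = tree.query_pairs(cap, output_type="ndarray")
    if len(pairs) == 0:
        return cap
    a, b = pairs[:, 0], pairs[:, 1]
    keep = (unit[a] != unit[b]) & (np.abs(genomic[a] - genomic[b]) >= genomic_exclusion_bp)
    if not np.any(keep):
        return cap
    d = np.linalg.norm(pts[a[keep]] - pts[b[keep]], axis=1)
    return float(min(cap, d.min()))


def stacking_distance(params: FibreParams) -> float:
    """Centre-to-centre distance of same-series neighbours (i, i+2)."""
    r, h, alpha = params.r, params.h, params.alpha
    return float(np.sqrt(2 * r * r * (1 - np.cos(alpha)) + (h * alpha) ** 2))


def nuc_per_11nm(model: FibreModel) -> float:
    """Nucleosomes per 11 nm of fibre length.

    Each series contributes one nucleosome per h*alpha of axial rise, so the
    bulk rise per nucleosome is h*alpha/2 in both architectures; the finite
    fibre's single-series end runs are excluded from the conversion.
    """
    p = model.params
    rise = p.h * p.alpha / 2.0
    if rise <= 0:
        raise GeometryError("degenerate axial extent")
    return 110.0 / rise


def connectivity_pattern(params: FibreParams) -> str:
    """Stacking-neighbour labels: 'i ± 2' for 2-start, interdigitation labels for 1-start."""
    if params.start_mode == "2-start":
        return "i ± 2"
    m = params.m
    return f"i ± {2 * m - 1}, i ± {2 * m + 1}"


@dataclass(frozen=True)
class ConstraintReport:
    """All constraint quantities of a fibre, with signed slacks."""

    d_gyre: float
    d_n1n2: float
    d_n2n3: float
    linker_clearances: list[tuple[str, float]]
    tw_str: tuple[float, float]
    tw_ll: tuple[float, float]
    m: int
    connectivity: str
    slacks: dict[str, float]
    feasible: bool


@dataclass(frozen=True)
class FibreMetrics:
    """Summary quantities of a fibre model (Angstrom / nm / bp / turns)."""

    nrl_bp: float
    linker_bp: float
    diameter_nm: float
    nuc_per_11nm: float
    packing_density: float
    wr_total: float | None = None
    wr_per_nuc: float | None = None
    dtw_per_nuc: float | None = None
    dl_per_nuc: float | None = None
    connectivity: str = ""
    start_mode: str = ""


def compute_metrics(model: FibreModel, wr_total: float | None = None,
                    repeat_relaxed: float = 10.5, repeat_fibre: float = 10.0) -> FibreMetrics:
    """Fibre metrics; if ``wr_total`` is given, per-nucleosome topology too."""
    p = model.params
    linker = float(np.mean([model.linker_bp(i) for i in (1, 2)]))
    out = dict(
        nrl_bp=147.0 + linker,
        linker_bp=linker,
        diameter_nm=2 * (p.r + NUCLEOSOME_DISC_RADIUS) / 10.0,
        nuc_per_11nm=nuc_per_11nm(model),
        packing_density=packing_density(model),
        connectivity=connectivity_pattern(p),
        start_mode=p.start_mode,
    )
    if wr_total is not None:
        wr_nuc = wr_total / p.n_nuc
        dtw = linker * (1.0 / repeat_fibre - 1.0 / repeat_relaxed)
        out.update(
            wr_total=wr_total, wr_per_nuc=wr_nuc, dtw_per_nuc=dtw, dl_per_nuc=wr_nuc + dtw,
        )
    return FibreMetrics(**out)


def compute_metrics_with_writhe(model: FibreModel, **kw) -> FibreMetrics:
    from .topology import writhe_levitt

    return compute_metrics(model, wr_total=writhe_levitt(model.full_path), **kw)
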