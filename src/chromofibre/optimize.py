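"""Constrained maximization of fibre packing density and NRL-space scans.

The objective is D_fibre / (d_n1-n2 + d_n2-n3): packing density (bp per unit
enclosed fibre volume) divided by the sum of the two stacking centre-to-centre
distances, maximized over the continuous variables (r, h, alpha, beta, theta,
delta, phi) with the integer arm extensions (u, v) enumerated exhaustively
over a small box.  Constraints (native units, Angstrom and radians):

    d_gyre = 2*pi*h           >= 110
    11 deg <= theta <= 15 deg   (relative rotation of adjacent discs = 2*theta)
    d_n1-n2, d_n2-n3          >= 57.6
    |delta|, |phi| <= 5 deg
    all linker clearances     >= 20
    |Tw_str - Tw_LL|          <= twist_tol   (both consecutive pairs)

The twist-consistency band is what quantizes the nucleosome repeat length:
feasible local maxima only exist where the structural inter-nucleosome twist
matches the winding of the linker DNA at ~10 bp/turn, i.e. at discrete
"islands" of NRL roughly one helical repeat apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .chromatosome import BASE_STEP, ChromatosomeTemplate
from .fibre import (
    ConstraintReport,
    FibreMetrics,
    FibreModel,
    FibreParams,
    adjacent_nucleosome_distances,
    build_fibre,
    compute_metrics,
    connectivity_pattern,
    evaluate_linker_clearances,
    packing_density,
    relative_twist_from_linker,
    min_nonlocal_approach,
    relative_twist_geometric_signed,
    stacking_distance,
    wrap_angle,
)

__all__ = [
    "OptimizerOptions",
    "OptimizationResult",
    "InfeasibleError",
    "constraint_report",
    "optimize_fibre",
    "scan_nrl",
    "default_initial_params",
]

logger = logging.getLogger(__name__)

THETA_LO = 11 * np.pi / 180
THETA_HI = np.pi / 12
ARM_HI = np.pi / 36
D_GYRE_MIN = 110.0
D_STACK_MIN = 57.6
CLEARANCE_MIN = 20.0
STERIC_MIN = 20.0  # DNA duplex diameter: minimum non-adjacent path approach


@dataclass(frozen=True)
class OptimizerOptions:
    """Tunables of the packing optimizer.

    ``twist_tol``: half-width (rad) of the twist-consistency band; default 1
    degree.  ``nrl_window``: half-width (bp) of the NRL window around a
    target.  ``n_starts``: jittered multi-starts per (u, v) cell.
    ``helical_repeat``: linker repeat (bp/turn) used for Tw_LL.
    """

    n_starts: int = 32
    seed: int = 0
    twist_tol: float = np.deg2rad(1.0)
    nrl_window: float = 5.0
    helical_repeat: float = 10.0
    max_iter: int = 120
    twist_sign: int = -1  # chiral register of the linker-twist match (+1 flips)
    n_eval_nuc: int | None = None  # nucleosomes used during evaluation
    feas_tol: float = 1e-6
    r_bounds: tuple[float, float] = (40.0, 260.0)
    h_bounds: tuple[float, float] = (110.0 / (2 * np.pi), 120.0)
    alpha_bounds: tuple[float, float] = (0.15, 2.2)


@dataclass
class OptimizationResult:
    """A feasible local maximum of the packing objective."""

    params: FibreParams
    objective_value: float
    nrl_bp: float
    metrics: FibreMetrics | None = None
    report: ConstraintReport | None = None
    trace: list[float] = field(default_factory=list)
    n_starts: int = 0
    seed: int = 0
    wr_per_nuc: float | None = None


class InfeasibleError(RuntimeError):
    """No feasible point found; carries the least-violating report."""

    def __init__(self, message: str, report: ConstraintReport | None = None):
        super().__init__(message)
        self.report = report


# ---------------------------------------------------------------------------
# evaluation


def _eval_n_nuc(params: FibreParams, options: OptimizerOptions) -> int:
    if options.n_eval_nuc:
        return options.n_eval_nuc
    return max(6, 2 * params.m + 2)


def _eval_model(template: ChromatosomeTemplate, params: FibreParams, n_nuc: int) -> FibreModel:
    p = replace(params, n_nuc=n_nuc)
    return build_fibre(template, p)


def _twist_pair(model: FibreModel, i: int, repeat: float, sign: int = -1) -> tuple[float, float]:
    """Signed structural twist and signed linker-dictated twist (rad).

    The raw linker angle lies in [0, 2*pi); with the default right-handed
    register (sign = -1) it is mapped to wrap(N*2*pi/repeat - baseline), the
    rotation a right-handed duplex accumulates over the linker.
    """
    tw_str = relative_twist_geometric_signed(model, i)
    tw_ll = wrap_angle(sign * relative_twist_from_linker(model, i, repeat))
    return tw_str, tw_ll


def constraint_report(
    params: FibreParams,
    template: ChromatosomeTemplate,
    options: OptimizerOptions = OptimizerOptions(),
) -> ConstraintReport:
    """Evaluate every constraint of the packing problem with signed slacks."""
    model = _eval_model(template, params, _eval_n_nuc(params, options))
    d1, d2 = adjacent_nucleosome_distances(params)
    clearances = evaluate_linker_clearances(model)
    tw = [_twist_pair(model, i, options.helical_repeat, options.twist_sign) for i in (1, 2)]
    d_gyre = 2 * np.pi * params.h
    slacks = {
        "d_gyre": d_gyre - D_GYRE_MIN,
        "theta_lo": params.theta - THETA_LO,
        "theta_hi": THETA_HI - params.theta,
        "d_n1n2": d1 - D_STACK_MIN,
        "d_n2n3": d2 - D_STACK_MIN,
        "d_stack": stacking_distance(params) - D_STACK_MIN,
        "delta_mag": ARM_HI - abs(params.delta),
        "phi_mag": ARM_HI - abs(params.phi),
    }
    for label, dist in clearances:
        slacks[f"clearance[{label}]"] = dist - CLEARANCE_MIN
    slacks["steric"] = min_nonlocal_approach(model) - STERIC_MIN
    for k, (ts, tl) in enumerate(tw, start=1):
        slacks[f"twist[n{k}-n{k + 1}]"] = options.twist_tol - abs(wrap_angle(ts - tl))
    feasible = all(v >= -1e-6 for v in slacks.values())
    return ConstraintReport(
        d_gyre=float(d_gyre), d_n1n2=d1, d_n2n3=d2,
        linker_clearances=clearances, tw_str=(tw[0][0], tw[1][0]),
        tw_ll=(tw[0][1], tw[1][1]), m=params.m,
        connectivity=connectivity_pattern(params), slacks=slacks, feasible=feasible,
    )


class _Evaluator:
    """Objective/constraint functions over x = (r, h, alpha, beta, theta, delta, phi)."""

    def __init__(self, template, base_params: FibreParams, options: OptimizerOptions,
                 nrl_target: float | None, m_cell: int | None):
        self.template = template
        self.base = base_params
        self.opt = options
        self.nrl_target = nrl_target
        self.m_cell = m_cell
        self.n_eval = max(6, 2 * (m_cell or 1) + 2)
        self._cache = {}

    def params(self, x) -> FibreParams:
        r, h, alpha, beta, theta, delta, phi = [float(t) for t in x]
        return replace(self.base, r=r, h=h, alpha=alpha, beta=beta, theta=theta,
                       delta=delta, phi=phi)

    def _quantities(self, x):
        key = tuple(float(t) for t in x)
        if key in self._cache:
            return self._cache[key]
        p = self.params(x)
        try:
            model = _eval_model(self.template, p, self.n_eval)
            d1, d2 = adjacent_nucleosome_distances(p)
            dens = packing_density(model)
            clear = [d for _, d in evaluate_linker_clearances(model)]
            tw = [_twist_pair(model, i, self.opt.helical_repeat, self.opt.twist_sign)
                  for i in (1, 2)]
            nrl = 147.0 + 0.5 * (model.linker_bp(1) + model.linker_bp(2))
            steric = min_nonlocal_approach(model)
            out = dict(obj=dens / (d1 + d2), d1=d1, d2=d2, clear=clear, tw=tw,
                       nrl=nrl, steric=steric)
        except (ValueError, FloatingPointError):
            out = dict(obj=1e-30, d1=0.0, d2=0.0, clear=[-1e3] * 5,
                       tw=[(0.0, np.pi)] * 2, nrl=0.0, steric=0.0)
        if len(self._cache) > 4096:
            self._cache.clear()
        self._cache[key] = out
        return out

    def neg_log_objective(self, x) -> float:
        return -np.log(max(self._quantities(x)["obj"], 1e-30))

    def constraints(self, x) -> np.ndarray:
        q = self._quantities(x)
        p = self.params(x)
        g = [
            (2 * np.pi * p.h - D_GYRE_MIN) / 10.0,
            (q["d1"] - D_STACK_MIN) / 10.0,
            (q["d2"] - D_STACK_MIN) / 10.0,
            (stacking_distance(p) - D_STACK_MIN) / 10.0,
        ]
        g += [(c - CLEARANCE_MIN) / 10.0 for c in q["clear"]]
        g.append((q["steric"] - STERIC_MIN) / 10.0)
        for ts, tl in q["tw"]:
            d = wrap_angle(ts - tl)
            g.append(self.opt.twist_tol - d)
            g.append(self.opt.twist_tol + d)
        if self.nrl_target is not None:
            g.append((self.opt.nrl_window - (q["nrl"] - self.nrl_target)) / 5.0)
            g.append((self.opt.nrl_window + (q["nrl"] - self.nrl_target)) / 5.0)
        if self.m_cell is not None:
            # keep beta inside the (m, m+1) interdigitation cell
            g.append((p.beta - (self.m_cell + 0.05) * p.alpha))
            g.append(((self.m_cell + 0.95) * p.alpha - p.beta))
        return np.asarray(g)

    def bounds(self):
        o = self.opt
        beta_b = (0.02, 2 * np.pi - 0.05)
        return [o.r_bounds, o.h_bounds, o.alpha_bounds, beta_b,
                (THETA_LO, THETA_HI), (-ARM_HI, ARM_HI), (-ARM_HI, ARM_HI)]

    def min_slack(self, x) -> float:
        return float(np.min(self.constraints(x)))


# ---------------------------------------------------------------------------
# defaults and starts


def default_initial_params(start_mode: str, nrl_target: float, m: int | None = None,
                           n_nuc: int = 32) -> FibreParams:
    """Documented per-mode starting geometry for a target repeat length.

    The stack radius starts at roughly half the linker contour length plus
    the disc radius (crossed linkers span the fibre interior); 2-start stacks
    start steep (high pitch), 1-start stacks start near the minimum gyre
    spacing (low pitch) with the even series phased (m + 1/2) spacings ahead.
    """
    linker_len = (nrl_target - 147.0) * BASE_STEP
    if start_mode == "2-start":
        if m is None or m >= 4:
            # steep twin stacks diametrically opposed: small alpha, beta ~ pi
            m = 5 if m is None else m
            alpha0 = 0.55
            r0 = 55.0 + 0.33 * linker_len
            return FibreParams(r=max(r0, 60.0), h=57.0, alpha=alpha0,
                               beta=(m + 0.5) * alpha0,
                               theta=np.deg2rad(13), delta=np.deg2rad(2),
                               phi=np.deg2rad(2), start_mode="2-start", n_nuc=n_nuc)
        # tightly phased twin stacks (beta < alpha): the regime the synthetic
        # template packs best in.  Its shortest sterically feasible repeat is
        # ~194 bp, so the radius start assumes at least that repeat.
        alpha0 = 2.0
        eff_linker = (max(nrl_target, 194.0) - 147.0) * BASE_STEP
        r0 = 60.0 + 0.65 * eff_linker
        return FibreParams(r=r0, h=27.5, alpha=alpha0, beta=0.594 * alpha0,
                           theta=np.deg2rad(11.1), delta=np.deg2rad(4.9),
                           phi=np.deg2rad(-3.1), start_mode="2-start", n_nuc=n_nuc)
    r0 = 55.0 + 0.45 * linker_len
    if m is None:
        m = 4 if nrl_target <= 210 else 5
    alpha0 = 0.9
    return FibreParams(r=max(r0, 80.0), h=20.0, alpha=alpha0, beta=(m + 0.5) * alpha0,
                       theta=np.deg2rad(13), delta=np.deg2rad(2), phi=np.deg2rad(2),
                       start_mode="1-start", n_nuc=n_nuc)


def _jittered_starts(ev: _Evaluator, x0: np.ndarray, n: int, rng: np.random.Generator):
    """Deterministic diversified starts first, random jitter for the rest."""
    lo = np.array([b[0] for b in ev.bounds()])
    hi = np.array([b[1] for b in ev.bounds()])

    def cell_beta(x, frac):
        if ev.m_cell is not None:
            x[3] = (ev.m_cell + frac) * x[2]
        return x

    starts = [x0.copy()]
    for fa, fh, fr in [(0.85, 1.0, 1.0), (1.2, 1.0, 1.0), (1.0, 0.78, 1.0),
                       (1.0, 1.3, 1.0), (0.9, 0.85, 1.1), (1.1, 1.2, 0.9)]:
        x = x0.copy()
        x[0] *= fr
        x[1] *= fh
        x[2] *= fa
        starts.append(cell_beta(x, 0.5))
        if len(starts) >= n:
            break
    while len(starts) < n:
        x = x0.copy()
        x[0] *= rng.uniform(0.85, 1.15)  # r
        x[1] *= rng.uniform(0.75, 1.35)  # h
        x[2] *= rng.uniform(0.85, 1.15)  # alpha
        if ev.m_cell is not None:
            x[3] = (ev.m_cell + rng.uniform(0.2, 0.8)) * x[2]
        else:
            x[3] = x0[3] + rng.uniform(-0.4, 0.4)
        x[4] = rng.uniform(THETA_LO, THETA_HI)
        x[5] = rng.uniform(-ARM_HI, ARM_HI)
        x[6] = rng.uniform(-ARM_HI, ARM_HI)
        starts.append(x)
    return [np.clip(x, lo, hi) for x in starts[:n]]


def _uv_cells(ev: _Evaluator, x0, nrl_target: float, max_cells: int = 4):
    """Integer (u, v) cells consistent with the target NRL at the start point."""
    q = ev._quantities(x0)
    gap_bp = (q["nrl"] - 147.0) - 19 - ev.base.u - ev.base.v
    want = (nrl_target - 147.0) - 19 - gap_bp
    w = max(0, int(round(want)))
    cells, seen = [], set()
    for dw in (0, -1, 1, -2, 2, -3, 3):
        tot = w + dw
        if tot < 0:
            continue
        u, v = tot - tot // 2, tot // 2
        if (u, v) not in seen:
            seen.add((u, v))
            cells.append((u, v))
        if len(cells) >= max_cells:
            break
    return cells


# ---------------------------------------------------------------------------
# main entry points


def optimize_fibre(
    template: ChromatosomeTemplate,
    start_mode: str,
    nrl_target: float | None = None,
    initial_params: FibreParams | None = None,
    options: OptimizerOptions = OptimizerOptions(),
    m: int | None = None,
    n_nuc: int = 32,
) -> OptimizationResult:
    """Multi-start constrained local maximization of the packing objective.

    For each integer (u, v) cell near the target NRL, runs ``n_starts``
    SLSQP maximizations from jittered documented defaults and returns the
    best feasible solution.  Raises InfeasibleError when nothing feasible
    converges.
    """
    if initial_params is None and nrl_target is None:
        raise ValueError("give either nrl_target or initial_params")
    if initial_params is None and start_mode == "2-start" and m is None:
        # enumerate both 2-start regimes (diametric m~5 and tightly phased m=0)
        best_res, last_err = None, None
        for m_cell in (0, 5):
            try:
                res = optimize_fibre(template, start_mode, nrl_target=nrl_target,
                                     options=options, m=m_cell, n_nuc=n_nuc)
            except InfeasibleError as exc:
                last_err = exc
                continue
            if best_res is None or res.objective_value > best_res.objective_value:
                best_res = res
        if best_res is None:
            raise last_err
        return best_res
    if initial_params is None:
        initial_params = default_initial_params(start_mode, nrl_target, m=m, n_nuc=n_nuc)
    base = replace(initial_params, start_mode=start_mode, n_nuc=n_nuc)
    if m is None:
        m = base.m
    rng = np.random.default_rng(options.seed)

    ev0 = _Evaluator(template, base, options, nrl_target, m)
    x0 = np.array([base.r, base.h, base.alpha, base.beta, base.theta, base.delta, base.phi])
    cells = _uv_cells(ev0, x0, nrl_target) if nrl_target is not None else [(base.u, base.v)]

    best = None
    best_report = None
    trace: list[float] = []
    relax_opts = replace(options, twist_tol=max(options.twist_tol, np.deg2rad(6.0)))
    for (u, v) in cells:
        cell_base = replace(base, u=u, v=v)
        ev = _Evaluator(template, cell_base, options, nrl_target, m)
        ev_relax = _Evaluator(template, cell_base, relax_opts, nrl_target, m)

        def _feas_polish(e, x):
            pre = minimize(
                lambda t: float(np.sum(np.minimum(e.constraints(t), 0.0) ** 2)),
                x, method="SLSQP", bounds=e.bounds(),
                options={"maxiter": 80, "ftol": 1e-14},
            )
            return pre.x

        def _maximize(e, x):
            return minimize(
                e.neg_log_objective, x, method="SLSQP", bounds=e.bounds(),
                constraints=[{"type": "ineq", "fun": e.constraints}],
                options={"maxiter": options.max_iter, "ftol": 1e-10},
            )

        starts = _jittered_starts(ev, x0, options.n_starts, rng)
        for xs in starts:
            try:
                # homotopy: converge inside a widened twist band first, then
                # repair feasibility and re-maximize under the strict band
                if ev_relax.min_slack(xs) < -0.05:
                    xs = _feas_polish(ev_relax, xs)
                x1 = _maximize(ev_relax, xs).x
                if ev_relax.min_slack(x1) < -0.3:
                    continue  # not even the relaxed problem is satisfiable here
                if ev.min_slack(x1) < -options.feas_tol:
                    x1 = _feas_polish(ev, x1)
                    if ev.min_slack(x1) < -0.05:
                        continue
                sol = _maximize(ev, x1)
            except (ValueError, FloatingPointError):  # pragma: no cover
                continue
            slack = ev.min_slack(sol.x)
            obj = ev._quantities(sol.x)["obj"]
            logger.info("start u=%d v=%d: obj=%.4g min_slack=%.3g status=%s",
                        u, v, obj, slack, sol.status)
            if slack < -options.feas_tol:
                continue
            if best is None or obj > best[0]:
                best = (obj, ev.params(sol.x), ev)
                trace.append(obj)
        if best is None:
            # remember the least-violating report for diagnostics
            try:
                best_report = constraint_report(ev.params(x0), template, options)
            except Exception:  # pragma: no cover
                pass
    if best is None:
        raise InfeasibleError(
            f"no feasible optimum found for {start_mode} NRL~{nrl_target}", best_report
        )
    obj, params, ev = best
    model = _eval_model(template, params, ev.n_eval)
    nrl = 147.0 + 0.5 * (model.linker_bp(1) + model.linker_bp(2))
    report = constraint_report(params, template, options)
    metrics = compute_metrics(_eval_model(template, params, max(params.n_nuc, ev.n_eval)))
    return OptimizationResult(
        params=params, objective_value=float(obj), nrl_bp=float(nrl),
        metrics=metrics, report=report, trace=trace,
        n_starts=options.n_starts, seed=options.seed,
    )


def scan_nrl(
    template: ChromatosomeTemplate,
    nrl_range: tuple[float, float] = (172.0, 242.0),
    mode_policy: str = "paper",
    options: OptimizerOptions = OptimizerOptions(),
    step: float = 5.0,
    n_nuc: int = 32,
    writhe_n_nuc: int | None = None,
) -> list[OptimizationResult]:
    """Scan NRL space for feasible packing optima ("islands of stability").

    Overlapping NRL windows (centres every ``step`` bp) are optimized
    independently; converged solutions are clustered by NRL (single linkage,
    3 bp) and deduplicated to one representative per cluster.  ``mode_policy``
    is "paper" (2-start for NRL <= 197, 1-start >= 197), "1-start" or
    "2-start".  When ``writhe_n_nuc`` is set, each representative gets its
    writhe per nucleosome computed on a fibre of that size.
    """
    lo, hi = nrl_range
    if hi <= lo:
        raise ValueError("empty NRL range")
    if lo < 150 or hi > 260:
        raise ValueError("NRL range should lie within ~167-247 bp")
    solutions: list[OptimizationResult] = []
    centres = np.arange(lo, hi + 1e-9, step)
    for i, target in enumerate(centres):
        modes = []
        if mode_policy in ("paper", "2-start") and (mode_policy != "paper" or target <= 197):
            modes.append("2-start")
        if mode_policy in ("paper", "1-start") and (mode_policy != "paper" or target >= 197):
            modes.append("1-start")
        for mode in modes:
            opt_i = replace(options, seed=options.seed + 1000 * i + (mode == "1-start"))
            try:
                res = optimize_fibre(template, mode, nrl_target=float(target),
                                     options=opt_i, n_nuc=n_nuc)
            except InfeasibleError:
                logger.info("no feasible solution near NRL %.0f (%s)", target, mode)
                continue
            solutions.append(res)
    solutions = _dedup_by_nrl(solutions)
    if writhe_n_nuc:
        from .topology import per_nucleosome_writhe, writhe_levitt

        for res in solutions:
            model = build_fibre(template, replace(res.params, n_nuc=writhe_n_nuc))
            res.wr_per_nuc = per_nucleosome_writhe(
                writhe_levitt(model.full_path), writhe_n_nuc
            )
    return solutions


def _dedup_by_nrl(solutions, threshold: float = 3.0):
    """Single-linkage clustering on NRL; keep the best objective per cluster."""
    if not solutions:
        return []
    per_mode: dict[str, list[OptimizationResult]] = {}
    for s in solutions:
        per_mode.setdefault(s.params.start_mode, []).append(s)
    out = []
    for mode_solutions in per_mode.values():
        mode_solutions.sort(key=lambda s: s.nrl_bp)
        cluster = [mode_solutions[0]]
        for s in mode_solutions[1:]:
            if s.nrl_bp - cluster[-1].nrl_bp <= threshold:
                cluster.append(s)
            else:
                out.append(max(cluster, key=lambda t: t.objective_value))
                cluster = [s]
        out.append(max(cluster, key=lambda t: t.objective_value))
    out.sort(key=lambda s: (s.nrl_bp, s.params.start_mode))
    return out
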