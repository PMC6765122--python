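# Methods

## The model

`chromofibre` models a compact chromatin fibre as a rigid-body assembly of
chromatosome DNA paths on a left-handed helical scaffold, with straight
linker DNA bridging consecutive nucleosomes. Only the DNA path is
represented — a space curve with one point per base pair (bp), in Angstrom.
No protein atoms, no base-step parameters, no energetics.

### Chromatosome template

The template is a 167 bp path: a 129 bp superhelical core (bp 20–148)

    x' = a sin(ωn),  y' = a cos(ωn),  z' = qωn,    n = −64 … +64,

flanked by two straight 19 bp arms (the entering and leaving DNAs, bp 1–19
and 149–167). With q > 0 the core is left-handed; the canonical frame puts
the superhelical axis on z and the dyad axis on y. The disc normal is
(0, 0, 1) rotated about y by −arctan(qπ/2a), accounting for the superhelical
climb across the bisecting plane.

Template parameters and defaults:

| symbol | meaning | default | unit |
|---|---|---|---|
| a | superhelix radius | 41.9 | Å |
| ω | angular advance per bp | 0.0807 | rad/bp |
| q | rise per radian | 4.2 | Å/rad |

The defaults give a 1.64-turn left-handed core of ~26 Å pitch — canonical
nucleosome crystallography values. A template can instead be fitted from any
chromatosome structure (PDB/mmCIF): bp midpoints are taken between opposing
phosphorus atoms, the core is aligned to the parametric superhelix by
nine-parameter least squares (three rotations, translation, a, ω, q), and
each arm is fitted as a straight line (total-least-squares direction, step
length from the projection-vs-index slope). Terminal base pairs 1 and 167
are always rebuilt by one-step extrapolation of the arm fit, whether or not
the structure resolves them.

The synthetic generator continues the core tangents into the arms at a
uniform 3.405 Å base step. This is the one place where the synthetic
template knowingly departs from a linker-histone-bound chromatosome: real
entering/leaving DNAs converge toward the linker-histone stem and cross,
whereas tangent-continued arms splay outward (tips ~76 Å from the
chromatosome origin). The consequences are quantified under *Limitations*.

### Fibre assembly

Nucleosomes are numbered genomically 1…n; odd and even nucleosomes form two
series. Placement of the first member of each series is a fixed composition
of rigid transforms: translate to radius r on the fibre axis, orient the
superhelical axis tangent to the helical path (tilt −arctan(h/r)), and roll
the disc by +θ (odd) or −θ (even) about the tangent. Subsequent members
follow by the screw (rotation −α, rise hα) — a left-handed stack. The even
series is phased ahead by β (rotation β, rise hβ).

One parametrization covers both canonical architectures:

* **2-start** — two regimes, both enumerated by the optimizer: β ≈ π with
  small α (each series a steep stack diametrically opposite the other) and
  the tightly-phased β < α regime (the one the synthetic template can
  actually pack in). In both, nucleosomes stack face-to-face within a series
  (connectivity i ± 2) and every linker crosses between the starts.
* **1-start** — α larger (~0.8–1.1 rad), β ≈ (m + ½)α with m = int(β/α) ≥ 4:
  the two series interdigitate into a single low-pitch stack; nucleosome i
  packs against i ± (2m−1) and i ± (2m+1).

Linkers are straight segments from the exit bp of nucleosome i to the entry
bp of nucleosome i+1, with interior bp laid at uniform spacing (count =
round(gap/3.405)). The fractional linker length N = gap/3.405 + 19 + u + v
is kept for twist and NRL bookkeeping (NRL = 147 + N); the linker is
modelled as continuous even though real linkers are integer bp.

### Constraint set and objective

The packing objective is D_fibre/(d_n1–n2 + d_n2–n3), where D_fibre is bp per
unit volume of the enclosing cylinder of radius r + 55 Å over axial extent
αh per two nucleosomes, and the denominator holds the two adjacent-neighbour
centre distances (closed forms in `fibre.py`). Constraints:

* gyre spacing 2πh ≥ 110 Å;
* disc roll 11π/180 ≤ θ ≤ π/12 (the relative rotation between adjacent
  nucleosomes is 2θ, i.e. 22°–30°);
* adjacent-neighbour distances d_n1–n2, d_n2–n3 ≥ 57.6 Å, and same-series
  stacking distance √(2r²(1−cos α) + (hα)²) ≥ 57.6 Å;
* arm swivels |δ|, |φ| ≤ 5°;
* linker–linker clearances (Lk1–Lk2, Lk2–Lk3, Lk1–Lk3, Lk2–Lk4) ≥ 20 Å and,
  for m ≥ 2, the entering/leaving-arm interface clearance of the stacking
  pair (n_{2m+1}, n_2) ≥ 20 Å;
* a steric floor: minimum approach ≥ 20 Å between path points of different
  nucleosomes/linkers at least 10 bp apart along the path. This
  excluded-volume *feasibility bound* (not an energy) uses the same DNA
  contact distance as the clearance list; without it the optimizer can
  thread one nucleosome's arm through a neighbouring coil, which no physical
  fibre can do;
* twist consistency: the structural inter-nucleosome twist must match the
  twist dictated by the linker length, |Tw_str − Tw_LL| ≤ 1° (band
  configurable), for both the (n1, n2) and (n2, n3) pairs.

Twist consistency is the quantization mechanism: Tw_LL = 2π(1 − frac(N/c +
1 − 51.52°/360°)) with helical repeat c = 10 bp/turn and a 51.52° empirical
baseline at zero linker length, so feasible solutions only exist where N
sits at discrete registers ~one repeat apart. Both angles are compared
*signed*: Tw_str is signed right-handed about the linker direction, and
Tw_LL is mapped to wrap(N·2π/c − baseline), the rotation a right-handed
duplex accumulates along the linker. The unsigned angle cannot distinguish
the two chiral registers, and the wrong register yields compact fibres of
the wrong handedness (positive writhe). A configuration flag
(`twist_sign`) exposes the alternative register.

### Optimization

SLSQP local maximization of log D_fibre/(d₁+d₂) over (r, h, α, β, θ, δ, φ),
with (u, v) enumerated over a small integer box matched to the target NRL
and m = int(β/α) held fixed per run (β constrained inside its cell, which
keeps the constraint set smooth; different m cells are separate runs — for
2-start both the β≈π and β<α regimes are enumerated). Each start runs a
homotopy: converge inside a widened (6°) twist band, repair feasibility,
then re-maximize under the strict band. Starts are a deterministic
diversified set around documented per-mode defaults plus seeded random
jitter; all randomness flows from a single integer seed, and repeated runs
are bit-identical. A returned optimum is feasible (all slacks ≥ −10⁻⁶) and
stationary.

The NRL scan covers a target range with overlapping windows, optimizes each
independently, clusters converged solutions by NRL (single linkage, 3 bp),
and keeps the best-objective representative per cluster.

### Topology

Writhe is computed by the polygonal solid-angle method: for every
non-adjacent segment pair, W_ij = ±Ω_ij/2π with Ω_ij = A + B + C + D − 2π
built from the four plane normals, and the sign of
[(r_{i+1}−r_i)×(r_{j+1}−r_j)]·(r_i−r_j) — the Gauss-integral convention, under
which left-handed coiling is negative. The O(n²) pair sum runs through a
numba kernel (tiled numpy fallback); a 7,000-vertex path takes seconds. An
independent Gauss double-integral evaluator (fixed-order Gauss–Legendre per
segment pair) serves as the test oracle and is not the production path.
arccos arguments are clamped to [−1, 1]; degenerate (collinear-triple) pairs
contribute 0.

Twist bookkeeping: ΔTw = N·(1/10 − 1/10.5) turns for a linker of N bp
over-twisting from the relaxed 10.5 bp/turn to the compact-fibre 10 bp/turn,
and ΔL/nuc = Wr/nuc + ΔTw/nuc, with Wr/nuc the 32-mer total divided by 32
(end effects accepted; a 16-mer vs 32-mer comparison bounds them below 0.03
per nucleosome).

## Numerical choices

* Superhelix fit: `scipy.optimize.least_squares` (LM), multi-start from a
  PCA frame (plane normal → z, phase/radius/pitch from the projected cloud,
  both normal orientations tried). Solutions are normalized to a > 0, ω > 0
  by folding compensating π-rotations into the alignment; q's sign carries
  the handedness.
* Near-parallel line-distance fallback: when the normal-equation determinant
  falls below 10⁻⁹ relative to scale, point-to-line distance is used.
* frac(x) = x − floor(x), always in [0, 1), keeping the twist formula
  continuous and periodic for any argument.
* nuc/11 nm = 220/(hα): each series contributes one nucleosome per hα of
  axial rise, so the bulk rise per nucleosome is hα/2 in both architectures.
  Measuring the axial extent of a finite 32-mer instead would inflate the
  apparent rise by the single-series end runs (~20 % for a 1-start), which
  is why the bulk value is used.
* Alternating-NRL fibres (two-NRL repeating unit) are built by giving even
  nucleosomes their own (u, v); the optimizer itself covers uniform NRLs.

## Problem sizes

The acceptance script optimizes with 10 starts per (u, v) cell and measures
writhe on 32-mers (~6,000–7,600 vertices). The test suite uses scaled-down
versions of the same computations: 3–6 starts, 16-mers for the scan trend,
a 10 bp scan step, Gauss-oracle curves of 30–150 vertices and 3×30,000
Monte-Carlo projection directions. The methods and tolerances are identical;
only the sampling effort differs.

## Limitations

* **Template geometry bounds the reachable writhe.** The synthetic
  tangent-arm template has an isolated writhe of −1.05 per chromatosome;
  published compact-fibre values (−1.58 … −1.78 per nucleosome) imply a
  template closer to −1.5 (the real chromatosome's arms converge and cross
  at the stem, adding roughly a full negative crossing). Optimized fibre
  writhe with the synthetic template lands near −0.5 … −0.95 per nucleosome:
  macroscopic observables (diameter, nuc/11 nm) reproduce published values
  closely, but per-nucleosome writhe magnitudes do not. Fitting the template
  from an actual chromatosome structure removes this gap at the source.
* **A steric floor on the synthetic template forbids the shortest compact
  2-start repeats.** At the 57.6 Å stacking distance the splayed arm tips of
  stacked neighbours approach ~19 Å, so 2-start optima below NRL ≈ 193 bp
  are infeasible even with signed arm swivels; the 2-start target is
  therefore optimized inside a widened NRL window and converges near the
  shortest feasible repeat (~194 bp, 6.4 nucleosomes/11 nm). For the same
  reason the arm-swivel band is symmetric (|δ|, |φ| ≤ 5°): the beneficial
  swing direction depends on the template frame, and the synthetic
  template needs the opposite sign on one arm.
* **NRL islands shift off the 10n lattice for the synthetic template.** The
  51.52° twist baseline was measured for stacked real core particles; with
  tangent-continued arms the feasible islands land 2–4 bp away from the
  147 + 10n lattice points (e.g. the shortest 2-start island at 193.8 bp).
* Linkers are straight by construction; no linker writhing, no
  sequence-dependent twist, no electrostatics, no linker-histone placement.
* The optimizer guarantees local, not global, maxima — by design: the
  published solutions are themselves local maxima of the same objective.
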