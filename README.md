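# chromofibre

Geometric modelling of compact chromatin fibres and the topology of their
DNA.

The 30-nm chromatin fibre coils a string of nucleosomes into one (1-start)
or two (2-start) helical stacks, with straight linker DNA crossing the fibre
interior. `chromofibre` builds such crossed-linker fibre models from a
chromatosome DNA path — fitted from a structure or generated synthetically —
searches for the most compact geometry permitted by physical constraints,
and computes the writhe (Wr) and linking-number change (ΔL) of the fibre
DNA. It is aimed at structural biologists and biophysicists studying
chromatin compaction and DNA supercoiling.

## The model in brief

A chromatosome is reduced to a 167 bp space curve: a 129 bp left-handed
superhelical core, x′ = a·sin(ωn), y′ = a·cos(ωn), z′ = qωn (n = −64…64),
plus two straight 19 bp arms. Copies are placed rigidly on a left-handed
helix of radius r and rise h per radian: same-series neighbours relate by a
screw (−α rotation, hα rise), the even series is phased ahead by β, and each
disc is rolled ±θ about the helical tangent. Fibre packing density

    D_fibre = [bp content of a 2-nucleosome unit] / [α·h·π(r+55)²]

is maximized over (r, h, α, β, θ, δ, φ, u, v) subject to, among others,
gyre spacing 2πh ≥ 110 Å, stacking distances ≥ 57.6 Å, linker–linker
clearances ≥ 20 Å, and consistency of the structural inter-nucleosome twist
with the winding of the linker DNA at ~10 bp/turn. The twist constraint
quantizes the nucleosome repeat length (NRL): feasible optima appear only on
a ~10 bp lattice ("islands of stability"). Writhe is computed by the
polygonal solid-angle method, summed over all non-adjacent segment pairs of
the ~7,000-point DNA path, and combined with the linker twist change
ΔTw = N·(1/10 − 1/10.5) into ΔL = ΔWr + ΔTw. Details, conventions and known
limitations are in [docs/methods.md](docs/methods.md).

## Worked example

Optimize a 1-start 32-mer fibre at a target NRL of 197 bp and measure its
topology (about three minutes on one CPU):

```python
from dataclasses import replace
from chromofibre import (OptimizerOptions, build_fibre,
                         generate_ideal_chromatosome, optimize_fibre,
                         twist_change, writhe_levitt)

template = generate_ideal_chromatosome()          # a=41.9 A, 1.64 turns
result = optimize_fibre(template, "1-start", nrl_target=197.0, m=4,
                        options=OptimizerOptions(n_starts=8, seed=1))
model = build_fibre(template, replace(result.params, n_nuc=32))
wr_per_nuc = writhe_levitt(model.full_path) / 32
linker = result.nrl_bp - 147.0
print(f"NRL {result.nrl_bp:.1f} bp, {result.metrics.nuc_per_11nm:.1f} nuc/11nm, "
      f"diameter {result.metrics.diameter_nm:.1f} nm")
print(f"Wr/nuc {wr_per_nuc:.3f}, dTw/nuc {twist_change(linker):+.3f}, "
      f"dL/nuc {wr_per_nuc + twist_change(linker):.3f}")
```

prints

```
NRL 201.2 bp, 11.2 nuc/11nm, diameter 38.6 nm
Wr/nuc -0.548, dTw/nuc +0.258, dL/nuc -0.290
```

i.e. the packing optimizer settles on a 201 bp island with ~11 nucleosomes
per 11 nm of fibre; each nucleosome constrains about half a negative turn of
writhe, partly offset by the overtwisting of its 54 bp linker. (With a
template fitted from an actual chromatosome structure the writhe per
nucleosome is substantially more negative; see the limitations section of
the methods note.)

The same pipeline is available from the shell:

```
chromofibre optimize --mode 1-start --nrl 197 --seed 1 -o params.yaml
chromofibre build --params params.yaml -o path.txt --pdb path.pdb
chromofibre writhe path.txt --n-nuc 32 --linker-bp 54.3
chromofibre scan -o summary.tsv          # NRL islands, Table-style summary
```

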