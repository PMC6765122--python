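"""Deterministic synthetic fixtures with known ground-truth properties.

Every fixture is generated from a ``FixtureSpec`` (kind + parameters + seed)
and is bit-reproducible for a given spec.  Fixtures cover: ideal and noisy
chromatosome geometry, toy polygonal curves with known writhe, and small
prebuilt fibres, so the full test suite runs without any external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chromatosome import (
    DEFAULT_A,
    DEFAULT_OMEGA,
    DEFAULT_Q,
    ChromatosomeTemplate,
    generate_ideal_chromatosome,
)
from .fibre import FibreModel, FibreParams, build_fibre

__all__ = ["FixtureSpec", "make_fixture", "KINDS"]

KINDS = (
    "ideal_chromatosome",
    "noisy_superhelix",
    "planar_polygon",
    "helical_curve",
    "trefoil_like_curve",
    "random_smooth_curve",
    "mini_fibre",
)


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def make_fixture(spec: FixtureSpec):
    """Build the object described by ``spec`` (identical spec -> identical output)."""
    if spec.kind not in KINDS:
        raise ValueError(f"unknown fixture kind {spec.kind!r}; known: {KINDS}")
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    if spec.kind == "ideal_chromatosome":
        return generate_ideal_chromatosome(
            a=p.get("a", DEFAULT_A), omega=p.get("omega", DEFAULT_OMEGA),
            q=p.get("q", DEFAULT_Q),
        )
    if spec.kind == "noisy_superhelix":
        tpl = generate_ideal_chromatosome(
            a=p.get("a", DEFAULT_A), omega=p.get("omega", DEFAULT_OMEGA),
            q=p.get("q", DEFAULT_Q),
        )
        sigma = p.get("sigma", 0.5)
        return tpl.core + rng.normal(scale=sigma, size=tpl.core.shape)
    if spec.kind == "planar_polygon":
        n = p.get("n", 20)
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        radius = p.get("radius", 50.0)
        return np.column_stack([radius * np.cos(t), radius * np.sin(t), np.zeros(n)])
    if spec.kind == "helical_curve":
        # ``turns`` turns of a helix; handedness left for pitch > 0 with this
        # parametrization (matches the chromatosome core convention)
        turns = p.get("turns", 3.0)
        n = p.get("n", 200)
        radius = p.get("radius", 40.0)
        pitch = p.get("pitch", 25.0)  # rise per turn
        t = np.linspace(0, 2 * np.pi * turns, n)
        return np.column_stack(
            [radius * np.sin(t), radius * np.cos(t), pitch * t / (2 * np.pi)]
        )
    if spec.kind == "trefoil_like_curve":
        n = p.get("n", 120)
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        x = np.sin(t) + 2 * np.sin(2 * t)
        y = np.cos(t) - 2 * np.cos(2 * t)
        z = -np.sin(3 * t)
        return 20.0 * np.column_stack([x, y, z])
    if spec.kind == "random_smooth_curve":
        # low-order Fourier arc: smooth and open (span < 1 period so the
        # endpoints stay apart)
        n = p.get("n", 60)
        harmonics = p.get("harmonics", 4)
        scale = p.get("scale", 10.0)
        t = np.linspace(0, 0.85, n)
        pts = np.zeros((n, 3))
        for k in range(1, harmonics + 1):
            amp = rng.normal(size=(3, 2)) / k
            pts += amp[:, 0] * np.sin(2 * np.pi * k * t)[:, None]
            pts += amp[:, 1] * np.cos(2 * np.pi * k * t)[:, None]
        return scale * pts
    if spec.kind == "mini_fibre":
        tpl: ChromatosomeTemplate = p.get("template") or generate_ideal_chromatosome()
        params = p.get("params") or default_mini_fibre_params(
            start_mode=p.get("start_mode", "2-start"), n_nuc=p.get("n_nuc", 8)
        )
        return build_fibre(tpl, params)
    raise AssertionError  # pragma: no cover


def default_mini_fibre_params(start_mode: str = "2-start", n_nuc: int = 8) -> FibreParams:
    """Geometrically sane (loose, clash-free) fibre parameters for tests."""
    if start_mode == "2-start":
        return FibreParams(r=90.0, h=30.0, alpha=1.4, beta=0.7,
                           theta=np.deg2rad(13), start_mode="2-start", n_nuc=n_nuc)
    return FibreParams(r=130.0, h=20.0, alpha=1.0, beta=4.5,
                       theta=np.deg2rad(13), start_mode="1-start", n_nuc=n_nuc)


def mini_fibre(start_mode: str = "2-start", n_nuc: int = 8) -> FibreModel:
    return make_fixture(FixtureSpec("mini_fibre", {"start_mode": start_mode, "n_nuc": n_nuc}))
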