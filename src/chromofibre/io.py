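"""Readers/writers for path files, templates, parameter files and summaries.

The shared path format is columnar text: one row per base pair, columns
``x y z`` in Angstrom (whitespace- or comma-separated), with an optional
leading integer index column and ``#`` comments.  All writers embed the
sha256 digest of the active configuration so outputs are traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .chromatosome import ArmFit, BasePairPath, ChromatosomeTemplate
from .fibre import FibreParams

__all__ = [
    "PathParseError",
    "read_path_file",
    "write_path_file",
    "read_template",
    "write_template",
    "read_params",
    "write_params",
    "write_summary_table",
    "export_pdb",
    "config_digest",
]


class PathParseError(ValueError):
    """Malformed path file; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def config_digest(obj) -> str:
    """Short sha256 digest of a JSON-serializable configuration object."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def read_path_file(path, index_offset: int = 1) -> BasePairPath:
    """Read a columnar x,y,z path file (3 or 4 columns, '#' comments)."""
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if ncols is None:
                if len(parts) not in (3, 4):
                    raise PathParseError(
                        f"expected 3 or 4 columns, got {len(parts)}", lineno
                    )
                ncols = len(parts)
            if len(parts) != ncols:
                raise PathParseError(
                    f"inconsistent column count ({len(parts)} vs {ncols})", lineno
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise PathParseError(str(exc), lineno) from None
            rows.append(vals[-3:])
    if len(rows) < 2:
        raise PathParseError("need at least two data rows", 0)
    return BasePairPath(np.asarray(rows), index_offset=index_offset)


def write_path_file(path, bp_path: BasePairPath, digest: str | None = None,
                    indexed: bool = True) -> None:
    """Write a path file at full float precision (lossless round-trip)."""
    with open(path, "w") as fh:
        if digest:
            fh.write(f"# config digest: {digest}\n")
        fh.write("# columns: " + ("index x y z" if indexed else "x y z") + " (Angstrom)\n")
        for i, (x, y, z) in zip(bp_path.indices, bp_path.coords):
            prefix = f"{i}\t" if indexed else ""
            fh.write(f"{prefix}{float(x)!r}\t{float(y)!r}\t{float(z)!r}\n")


def write_template(path, template: ChromatosomeTemplate, digest: str | None = None) -> None:
    doc = {
        "a": template.a, "omega": template.omega, "q": template.q,
        "delta": template.delta, "phi": template.phi,
        "u": template.u, "v": template.v,
        "entry_arm": {
            "base_point": template.entry_arm.base_point.tolist(),
            "step_vector": template.entry_arm.step_vector.tolist(),
            "n_bp": template.entry_arm.n_bp, "rmsd": template.entry_arm.rmsd,
        },
        "exit_arm": {
            "base_point": template.exit_arm.base_point.tolist(),
            "step_vector": template.exit_arm.step_vector.tolist(),
            "n_bp": template.exit_arm.n_bp, "rmsd": template.exit_arm.rmsd,
        },
        "path": template.path.tolist(),
    }
    if digest:
        doc["config_digest"] = digest
    Path(path).write_text(json.dumps(doc, indent=1))


def read_template(path) -> ChromatosomeTemplate:
    doc = json.loads(Path(path).read_text())
    entry = ArmFit(side="entry", **doc["entry_arm"])
    exit_ = ArmFit(side="exit", **doc["exit_arm"])
    return ChromatosomeTemplate(
        path=np.asarray(doc["path"]), a=doc["a"], omega=doc["omega"], q=doc["q"],
        entry_arm=entry, exit_arm=exit_, delta=doc.get("delta", 0.0),
        phi=doc.get("phi", 0.0), u=doc.get("u", 0), v=doc.get("v", 0),
    )


_ANGLE_KEYS = ("alpha", "beta", "theta", "delta", "phi")


def read_params(path) -> FibreParams:
    """Read fibre parameters from flat key-value / YAML text (angles in degrees)."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError("parameter file must be a flat key: value mapping")
    kwargs = dict(doc)
    for key in _ANGLE_KEYS:
        if key in kwargs:
            kwargs[key] = float(np.deg2rad(kwargs[key]))
    return FibreParams(**kwargs)


def write_params(path, params: FibreParams, digest: str | None = None) -> None:
    doc = asdict(params)
    for key in _ANGLE_KEYS:
        doc[key] = float(np.rad2deg(doc[key]))
    lines = [f"# angles in degrees, lengths in Angstrom"]
    if digest:
        lines.append(f"# config digest: {digest}")
    for k, v in doc.items():
        if v is not None:
            lines.append(f"{k}: {v}")
    Path(path).write_text("\n".join(lines) + "\n")


SUMMARY_COLUMNS = ["nrl_bp", "linker_bp", "diameter_nm", "nuc_per_11nm",
                   "connectivity", "model", "wr_per_nuc", "dl_per_nuc"]


def write_summary_table(path, rows: list[dict], digest: str | None = None) -> str:
    """Write a TSV summary (one row per fibre solution); returns the text."""
    lines = []
    if digest:
        lines.append(f"# config digest: {digest}")
    lines.append("\t".join(SUMMARY_COLUMNS))
    for row in rows:
        cells = []
        for col in SUMMARY_COLUMNS:
            val = row.get(col)
            if val is None:
                cells.append("NA")
            elif isinstance(val, float):
                cells.append(f"{val:.3f}" if col not in ("nrl_bp",) else f"{val:.1f}")
            else:
                cells.append(str(val))
        lines.append("\t".join(cells))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def export_pdb(path, bp_path: BasePairPath) -> None:
    """Export a DNA path as pseudo-atom records (one P per bp; non-chemical)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = len(bp_path)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(bp_path.coords, dtype=np.float32)
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = np.asarray(bp_path.indices)
    atoms.res_name = np.full(n, "DN")
    atoms.atom_name = np.full(n, "P")
    atoms.element = np.full(n, "P")
    atoms.hetero = np.full(n, True)
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def load_structure(path):
    """Read a PDB/mmCIF structure file into a biotite AtomArray."""
    import biotite.structure.io as strucio

    return strucio.load_structure(str(path))
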