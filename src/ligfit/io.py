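"""Readers and writers for the pipeline's plain-text formats.

Curves travel as two-column CSV (``stretch,stress_mpa``), parameters and
fit reports as JSON, FE step tables as CSV and FE fields as legacy ASCII
VTK (readable by ParaView).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import CharacteristicPoints, StressStretchCurve
from .fem import FEResult

__all__ = [
    "CurveParseError",
    "read_curve_csv",
    "write_curve_csv",
    "points_to_json",
    "points_from_json",
    "write_step_table",
    "write_vtk",
    "write_cohort",
]

CURVE_HEADER = ("stretch", "stress_mpa")


class CurveParseError(ValueError):
    pass


def read_curve_csv(path) -> StressStretchCurve:
    """Read a stress-stretch curve, validating the header and invariants."""
    path = Path(path)
    df = pd.read_csv(path)
    if tuple(df.columns[:2]) != CURVE_HEADER:
        raise CurveParseError(
            f"{path}: expected header 'stretch,stress_mpa', got {','.join(df.columns[:2])}"
        )
    lam = df["stretch"].to_numpy(dtype=float)
    P = df["stress_mpa"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(lam) <= 0)
    if bad.size:
        # +2: one for the header line, one for 0- vs 1-based rows
        raise CurveParseError(f"{path}: stretch not increasing at data row {bad[0] + 2}")
    try:
        return StressStretchCurve(lam, P, specimen_id=path.stem)
    except ValueError as e:
        raise CurveParseError(f"{path}: {e}") from e


def write_curve_csv(curve: StressStretchCurve, path) -> None:
    """Write a curve losslessly (round-trips to 1e-12 via repr precision)."""
    df = pd.DataFrame({"stretch": curve.lam, "stress_mpa": curve.P})
    df.to_csv(path, index=False, float_format="%.17g")


def points_to_json(points: CharacteristicPoints) -> str:
    return json.dumps(
        {"ptI": list(points.ptI), "ptII": list(points.ptII), "fail": list(points.fail)},
        indent=1,
    )


def points_from_json(text: str) -> CharacteristicPoints:
    d = json.loads(text)
    return CharacteristicPoints(tuple(d["ptI"]), tuple(d["ptII"]), tuple(d["fail"]))


def write_step_table(result: FEResult, A0: float, path) -> None:
    """FE step table CSV: ``step,lambda,reaction_n,p_mpa``."""
    df = pd.DataFrame({
        "step": np.arange(1, len(result.lam) + 1),
        "lambda": result.lam,
        "reaction_n": result.reaction,
        "p_mpa": result.reaction / A0,
    })
    df.to_csv(path, index=False, float_format="%.10g")


def write_vtk(result: FEResult, path, step: int = -1) -> None:
    """Legacy ASCII VTK with point displacements and cell stresses."""
    model = result.model
    u = result.u_steps[step]
    sig = result.stress_steps[step]
    nn, ne = model.n_nodes, model.n_elements
    lines = [
        "# vtk DataFile Version 3.0",
        "ligament membrane tension",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {nn} double",
    ]
    for x, y in model.nodes:
        lines.append(f"{x:.10g} {y:.10g} 0")
    lines.append(f"CELLS {ne} {5 * ne}")
    for e in model.elements:
        lines.append("4 " + " ".join(str(n) for n in e))
    lines.append(f"CELL_TYPES {ne}")
    lines.extend(["9"] * ne)  # VTK_QUAD
    lines.append(f"POINT_DATA {nn}")
    lines.append("VECTORS displacement double")
    for ux, uy in u:
        lines.append(f"{ux:.10g} {uy:.10g} 0")
    lines.append(f"CELL_DATA {ne}")
    for name, col in (("sigma11", 0), ("sigma22", 1)):
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.10g}" for v in sig[:, col])
    Path(path).write_text("\n".join(lines) + "\n")


def write_cohort(cohort, out_dir) -> Path:
    """Write one CSV per specimen plus a manifest JSON; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for curve, geom, pts in cohort:
        fname = f"{curve.specimen_id or 'specimen'}.csv"
        write_curve_csv(curve, out_dir / fname)
        manifest.append({
            "file": fname,
            "ligament": curve.ligament,
            "geometry": {"L0": geom.L0, "b": geom.b, "t": geom.t, "A0": geom.A0},
            "true_points": json.loads(points_to_json(pts)),
        })
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath
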