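"""Reading and writing point patterns, distance sequences and curve outputs.

Point patterns travel as TSV with an ``x_um<TAB>y_um`` header (a third
column, e.g. a section z coordinate, is accepted and dropped with a
warning — all analyses are planar).  The analysis window rides along either
as a ``#window: {...json...}`` comment line or a sidecar ``<path>.window.json``;
absent both, the bounding box plus a 2% margin is used with a warning.
Distance sequences are single-column TSV ``distance_um`` (ordered), with an
optional ``block`` column for multi-block files.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .distance import DistanceSequence
from .patterns import PointPattern, Window

log = logging.getLogger("bundlemap.io")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".window.json")


def read_point_pattern(path) -> PointPattern:
    """Read a pattern TSV; see module docstring for the format contract."""
    path = Path(path)
    window = None
    header = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#window:"):
                window = Window.from_dict(json.loads(line[len("#window:"):]))
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                if header[:2] != ["x_um", "y_um"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header 'x_um<TAB>y_um', "
                        f"got {fields!r}"
                    )
                if len(header) > 2:
                    warnings.warn(
                        f"{path}: extra column(s) {header[2:]} dropped "
                        "(analyses are planar)"
                    )
                continue
            try:
                rows.append((float(fields[0]), float(fields[1])))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
    pts = np.array(rows, dtype=float).reshape(-1, 2)
    if window is None and _sidecar(path).exists():
        window = Window.from_dict(json.loads(_sidecar(path).read_text()))
    if window is None:
        if pts.size == 0:
            raise ValueError(f"{path}: empty pattern and no window declared")
        warnings.warn(
            f"{path}: no window declared; using bounding box + 2% margin"
        )
        mx = 0.02 * np.ptp(pts[:, 0]) or 1.0
        my = 0.02 * np.ptp(pts[:, 1]) or 1.0
        window = Window(
            pts[:, 0].min() - mx,
            pts[:, 0].max() + mx,
            pts[:, 1].min() - my,
            pts[:, 1].max() + my,
        )
    n_dup = len(pts) - len(np.unique(pts, axis=0)) if pts.size else 0
    if n_dup:
        log.info("%s: %d duplicate coordinate(s)", path, n_dup)
    return PointPattern(pts, window, label=path.stem)


def write_point_pattern(pattern: PointPattern, path) -> None:
    """Write TSV with an inline ``#window:`` comment (lossless round trip)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#window: " + json.dumps(pattern.window.to_dict()) + "\n")
        fh.write("x_um\ty_um\n")
        for x, y in pattern.points:
            fh.write(f"{float(x)!r}\t{float(y)!r}\n")


def read_distances(path, block: str | None = None) -> DistanceSequence:
    """Read an ordered distance sequence; ``block`` selects one block's rows."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if "distance_um" not in df.columns:
        raise ValueError(f"{path}: expected a 'distance_um' column")
    if block is not None:
        if "block" not in df.columns:
            raise ValueError(f"{path}: no 'block' column to select {block!r} from")
        df = df[df["block"].astype(str) == block]
    return DistanceSequence(df["distance_um"].to_numpy(), block=block or "")


def write_distances(seq: DistanceSequence, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("distance_um\n")
        for v in seq.values:
            fh.write(f"{float(v)!r}\n")


def write_curve_tsv(path, columns: dict) -> None:
    """Write named columns (equal length) as TSV."""
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False)


def write_density_map(dmap, path_prefix) -> None:
    """Matrix TSV (row-major, origin top-left: first row = largest y) + JSON meta."""
    prefix = Path(path_prefix)
    np.savetxt(
        prefix.with_suffix(".tsv"), dmap.values[::-1], delimiter="\t", fmt="%.6g"
    )
    meta = {
        "bandwidth_sigma_um": dmap.bandwidth_sigma,
        "grid_spacing_um": dmap.grid_spacing,
        "window": dmap.window.to_dict(),
        "units": "bundles/mm^2",
        "orientation": "row-major, origin top-left (first row = y_max edge)",
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))
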