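"""File formats and configuration.

Panel CSV dialect: a single comma-separated file with ``#``-prefixed
metadata header lines, then the columns

    label, distance_kb, count, cells        (or ``probability`` for cells)

one row per (line, mRNA count).  ``distance_kb`` is NaN for a
promoter-only line.  Counts within a line must be unique and sorted;
missing counts are treated as zero cells.  BED intervals are interpreted
0-based half-open; the genomic distance between an enhancer and a promoter
interval is the distance between their midpoints, in kb.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InputError
from .inference import CellLine, CellLinePanel, coarse_grain_distance

__all__ = [
    "read_panel",
    "write_panel",
    "bed_to_genomic_distance",
    "load_config",
]


def write_panel(panel: CellLinePanel, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# eptx cell-line panel\n")
        fh.write(f"# monomer_kb: {panel.monomer_kb}\n")
        fh.write("label,distance_kb,count,cells\n")
        for line in panel:
            if line.n_cells is None:
                raise InputError(
                    f"line {line.label} has probabilities only; write requires cell "
                    "counts (generate without exact=True)"
                )
            cells = np.rint(line.q * line.n_cells).astype(int)
            for x, c in enumerate(cells):
                fh.write(f"{line.label},{line.distance_kb},{x},{c}\n")


def _parse_lines(df: pd.DataFrame, path, monomer_kb: float) -> list[CellLine]:
    has_cells = "cells" in df.columns
    has_prob = "probability" in df.columns
    if not (has_cells or has_prob):
        raise InputError(f"{path}: need a 'cells' or 'probability' column")
    lines = []
    for label, grp in df.groupby("label", sort=False):
        counts = grp["count"].to_numpy()
        if np.any(counts < 0):
            row = int(grp.index[counts < 0][0]) + 2
            raise InputError(f"{path} row {row}: negative mRNA count")
        if np.any(np.diff(counts) <= 0):
            row = int(grp.index[1:][np.diff(counts) <= 0][0]) + 2
            raise InputError(
                f"{path} row {row}: counts must be unique and sorted within line {label}"
            )
        dist = grp["distance_kb"].to_numpy(dtype=float)
        if np.unique(dist[~np.isnan(dist)]).size > 1:
            raise InputError(f"{path}: inconsistent distance for line {label}")
        distance_kb = float(dist[0])
        dense = np.zeros(int(counts[-1]) + 1)
        if has_cells:
            cells = grp["cells"].to_numpy(dtype=float)
            if np.any(cells < 0) or np.any(cells != np.rint(cells)):
                row = int(grp.index[(cells < 0) | (cells != np.rint(cells))][0]) + 2
                raise InputError(f"{path} row {row}: cells must be non-negative integers")
            total = cells.sum()
            if total <= 0:
                raise InputError(f"{path}: line {label} has zero cells")
            dense[counts] = cells / total
            n_cells = int(total)
        else:
            prob = grp["probability"].to_numpy(dtype=float)
            if np.any(prob < 0):
                row = int(grp.index[prob < 0][0]) + 2
                raise InputError(f"{path} row {row}: negative probability")
            if abs(prob.sum() - 1.0) > 1e-6:
                raise InputError(
                    f"{path}: line {label} probabilities sum to {prob.sum():.6f}, not 1"
                )
            dense[counts] = prob
            n_cells = None
        dg = coarse_grain_distance(distance_kb, monomer_kb)
        dg = None if isinstance(dg, float) and math.isnan(dg) else int(dg)
        lines.append(
            CellLine(label=str(label), distance_kb=distance_kb, d_G=dg, q=dense,
                     n_cells=n_cells)
        )
    return lines


def read_panel(path, monomer_kb: float = 5.0) -> CellLinePanel:
    """Read a panel CSV (or several per-line CSVs) into a CellLinePanel."""
    paths = [path] if isinstance(path, (str, Path)) else list(path)
    lines: list[CellLine] = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise InputError(f"panel file not found: {p}")
        try:
            df = pd.read_csv(p, comment="#")
        except Exception as exc:  # noqa: BLE001 - report file context
            raise InputError(f"{p}: cannot parse as panel CSV ({exc})") from exc
        required = {"label", "distance_kb", "count"}
        if not required.issubset(df.columns):
            raise InputError(
                f"{p}: missing columns {sorted(required - set(df.columns))}"
            )
        lines.extend(_parse_lines(df, p, monomer_kb))
    labels = [ln.label for ln in lines]
    if len(set(labels)) != len(labels):
        raise InputError(f"duplicate line labels across files: {labels}")
    return CellLinePanel(lines=tuple(lines), monomer_kb=monomer_kb)


def _as_interval(value) -> tuple[str, int, int]:
    """Accept 'chr1:100-200', (chrom, start, end), or a BED file path."""
    if isinstance(value, tuple) and len(value) == 3:
        chrom, start, end = value
        return str(chrom), int(start), int(end)
    text = str(value)
    if ":" in text and "-" in text:
        chrom, span = text.split(":", 1)
        start, end = span.split("-", 1)
        return chrom, int(start), int(end)
    path = Path(text)
    if not path.exists():
        raise InputError(f"cannot interpret interval {value!r}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise InputError(f"{path}: BED needs at least 3 columns")
    row = df.iloc[0]
    return str(row[0]), int(row[1]), int(row[2])


def bed_to_genomic_distance(enhancer, promoter) -> float:
    """Midpoint-to-midpoint distance between two intervals, in kb.

    Intervals are 0-based half-open; the result is rounded to 4 decimals.
    Overlapping intervals get no special-casing.
    """
    ce, se, ee = _as_interval(enhancer)
    cp, sp, ep = _as_interval(promoter)
    if se >= ee or sp >= ep:
        raise InputError("intervals must have start < end (0-based half-open)")
    if ce != cp:
        raise InputError(f"intervals on different chromosomes: {ce} vs {cp}")
    mid_e = (se + ee) / 2.0
    mid_p = (sp + ep) / 2.0
    return round(abs(mid_e - mid_p) / 1000.0, 4)


def load_config(path) -> dict:
    """Load a YAML configuration file; missing file is an input error."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    with path.open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: top level of the config must be a mapping")
    return cfg
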