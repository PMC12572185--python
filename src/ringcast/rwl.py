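"""Tucson/rwl ring-width file reader and writer.

Supports the two common dialects: precision 0.01 mm (end-of-series marker
999) and 0.001 mm (marker -9999). Zero values inside a series denote
missing rings and are mapped to NaN with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .containers import TreeRingSeries

__all__ = ["read_rwl", "write_rwl"]

_STOP_001 = -9999  # 0.001 mm dialect
_STOP_01 = 999  # 0.01 mm dialect


def read_rwl(path) -> list[TreeRingSeries]:
    """Parse a Tucson/rwl file into per-tree ring-width series (mm)."""
    path = Path(path)
    raw: dict[str, dict[int, float]] = {}
    scale: dict[str, float] = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        series_id = line[:8].strip()
        rest = line[8:].split()
        if not series_id or len(rest) < 2:
            continue
        try:
            decade = int(rest[0])
            values = [int(v) for v in rest[1:]]
        except ValueError:
            continue  # header line
        store = raw.setdefault(series_id, {})
        for offset, val in enumerate(values):
            if val == _STOP_001:
                scale[series_id] = 0.001
                break
            if val == _STOP_01:
                scale[series_id] = 0.01
                break
            store[decade + offset] = val
    out = []
    for series_id, store in raw.items():
        if not store:
            continue
        unit = scale.get(series_id, 0.01)
        years = np.array(sorted(store))
        width = np.array([store[y] for y in years], dtype=float) * unit
        if np.any(width == 0.0):
            warnings.warn(
                f"series {series_id}: zero ring widths read as missing rings", stacklevel=2
            )
            width[width == 0.0] = np.nan
        out.append(TreeRingSeries(tree_id=series_id, years=years, width=width))
    return out


def write_rwl(trees: list[TreeRingSeries], path, precision: float = 0.01) -> None:
    """Write series in Tucson format at ``precision`` mm (0.01 or 0.001)."""
    if precision not in (0.01, 0.001):
        raise ValueError("precision must be 0.01 or 0.001 mm")
    stop = _STOP_01 if precision == 0.01 else _STOP_001
    short_ids = [t.tree_id[:8] for t in trees]
    if len(set(short_ids)) != len(short_ids):
        raise ValueError("tree ids collide after truncation to the 8-character Tucson field")
    lines = []
    for tree in trees:
        tid = tree.tree_id[:8]
        first, last = int(tree.years[0]), int(tree.years[-1])
        lookup = dict(zip(tree.years.tolist(), tree.width.tolist()))
        year = first
        while year <= last:
            decade_end = (year // 10) * 10 + 9
            row_years = range(year, min(decade_end, last) + 1)
            vals = []
            for y in row_years:
                v = lookup.get(y, np.nan)
                vals.append(0 if not np.isfinite(v) else int(round(v / precision)))
            line = f"{tid:<8}{year:>4}" + "".join(f"{v:>6}" for v in vals)
            if row_years[-1] == last:
                line += f"{stop:>6}"
            lines.append(line)
            year = decade_end + 1
    Path(path).write_text("\n".join(lines) + "\n")
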