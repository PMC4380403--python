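"""Tucson/rwl decadal ring-width file reader and writer.

The Tucson format stores one series per block: each line carries a
series id, the decade-start year, and up to ten ring widths in 0.01 mm
units, terminated by a ``999`` or ``-9999`` sentinel.  The reader
tolerates either terminator, blank cells and header lines; the writer
emits the conventional 8-character id / 4-digit year layout.
"""

from __future__ import annotations

import numpy as np

from .chronology import RingWidthCore

__all__ = ["read_rwl", "write_rwl"]

_TERMINATORS = {999, -9999}


def read_rwl(path, pith_offsets: dict | None = None) -> list[RingWidthCore]:
    """Parse an rwl file into :class:`RingWidthCore` records.

    ``pith_offsets`` optionally maps core id -> estimated missing
    radius in mm (the format itself cannot carry pith offsets).
    Core ids of the form ``<tree>_<core>`` (or ``<tree>a``/``b``)
    yield the tree id by stripping the final token; otherwise the tree
    id equals the core id.
    """
    series: dict[str, dict[int, float]] = {}
    order: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                continue
            sid = line[:8].strip() or parts[0]
            rest = line[8:].split()
            try:
                year = int(rest[0])
            except (ValueError, IndexError):
                continue  # header line
            vals = rest[1:]
            if sid not in series:
                series[sid] = {}
                order.append(sid)
            for k, tok in enumerate(vals):
                try:
                    v = int(tok)
                except ValueError:
                    continue
                if v in _TERMINATORS:
                    break
                series[sid][year + k] = v / 100.0

    cores = []
    for sid in order:
        data = series[sid]
        if not data:
            continue
        years = sorted(data)
        first, last = years[0], years[-1]
        if set(years) != set(range(first, last + 1)):
            missing = sorted(set(range(first, last + 1)) - set(years))
            raise ValueError(f"series {sid}: non-contiguous years, missing {missing[:5]}")
        widths = np.array([data[y] for y in range(first, last + 1)])
        tree_id = sid.rsplit("_", 1)[0] if "_" in sid else sid
        cores.append(
            RingWidthCore(
                tree_id=tree_id,
                core_id=sid,
                first_year=first,
                widths=widths,
                pith_offset=(pith_offsets or {}).get(sid, 0.0),
            )
        )
    return cores


def write_rwl(cores, path) -> None:
    """Write cores in decadal Tucson layout (0.01 mm, 999 terminator)."""
    with open(path, "w") as fh:
        for core in cores:
            sid = core.core_id[:8]
            vals = [int(round(w * 100)) for w in core.widths]
            year = core.first_year
            last = year + len(vals) - 1
            pos = year
            while pos <= last:
                decade_end = (pos // 10) * 10 + 9
                chunk_years = range(pos, min(decade_end, last) + 1)
                cells = [f"{vals[y - year]:6d}" for y in chunk_years]
                if chunk_years[-1] == last:
                    cells.append(f"{999:6d}")
                fh.write(f"{sid:<8}{pos:4d}{''.join(cells)}\n")
                pos = min(decade_end, last) + 1
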