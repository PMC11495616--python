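"""Edge-list input and JSON report output."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

from .graphs import DirectedGraph

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = ["read_edge_list", "write_report", "read_report", "write_edge_list"]

_HEADER_WORDS = {"source", "target", "from", "to", "pre", "post", "src", "dst"}


def read_edge_list(
    path: str | Path,
    drop_self_loops: bool = False,
    header: bool | None = None,
) -> DirectedGraph:
    """Read a two-column (source, target) TSV/CSV edge list.

    Node labels are arbitrary strings, mapped to dense integer ids in
    first-appearance order.  Duplicate rows are deduplicated (logged);
    self-loop rows are dropped (logged) when ``drop_self_loops`` is set
    and rejected otherwise.  ``header=None`` auto-detects a header row by
    its column names.
    """
    path = Path(path)
    text = path.read_text()
    rows: list[tuple[str, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sep = "\t" if "\t" in line else ","
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise ValueError(f"{path}:{lineno}: malformed edge row {line!r}")
        rows.append((parts[0], parts[1]))
    if not rows:
        raise ValueError(f"{path}: empty edge list")
    if header is None:
        header = rows[0][0].lower() in _HEADER_WORDS and rows[0][1].lower() in _HEADER_WORDS
    if header:
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: no data rows after header")

    ids: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    n_loops = n_dup = 0
    for a, b in rows:
        if a == b:
            if not drop_self_loops:
                raise ValueError(
                    f"{path}: self-loop on {a!r}; pass drop_self_loops=True to drop"
                )
            n_loops += 1
            if a not in ids:
                ids[a] = len(ids)
            continue
        for x in (a, b):
            if x not in ids:
                ids[x] = len(ids)
        e = (ids[a], ids[b])
        if e in edges:
            n_dup += 1
        edges.add(e)
    if n_loops:
        logger.warning("%s: dropped %d self-loop rows", path, n_loops)
    if n_dup:
        logger.warning("%s: deduplicated %d repeated edges", path, n_dup)
    if not ids:
        raise ValueError(f"{path}: no nodes after filtering")
    return DirectedGraph(len(ids), edges, labels=tuple(ids))


def write_edge_list(g: DirectedGraph, path: str | Path) -> None:
    """Write the graph as a tab-separated edge list with original labels."""
    path = Path(path)
    with path.open("w") as fh:
        for i, j in sorted(g.edges):
            fh.write(f"{g.label(i)}\t{g.label(j)}\n")


def write_report(report: Any, path: str | Path, **extra: Any) -> None:
    """Serialize a report (anything with ``to_dict``, or a plain mapping)
    as JSON with a schema version and the configuration echo."""
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    payload["schema_version"] = SCHEMA_VERSION
    if extra:
        payload["config"] = extra
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def _jsonable(obj: Any):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return list(obj)
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"cannot serialize {type(obj)!r}")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
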