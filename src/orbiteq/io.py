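"""Edge-list parsing and deterministic serialization.

The edge-list dialect: two whitespace-separated vertex identifiers per line,
``#`` starts a comment, blank lines are ignored.  Graphs are undirected and
loop-free; duplicate edges warn by default and raise under strict mode.
All writers sort keys and fix column orders so identical inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .counting import ExploredGraph, OrbitCountTable
from .errors import InputError

logger = logging.getLogger("orbiteq")


def read_edge_list(path, *, strict: bool = False) -> ExploredGraph:
    """Parse an edge-list file into an :class:`ExploredGraph`.

    Errors carry line numbers.  With ``strict=True`` a duplicate edge is an
    error instead of a warning.
    """
    g = ExploredGraph()
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise InputError(
                f"{path}:{lineno}: expected two vertex identifiers, got {len(tokens)}"
            )
        u, v = tokens
        if u == v:
            raise InputError(f"{path}:{lineno}: self-loop on vertex {u!r}")
        if g.has_edge(u, v):
            msg = f"{path}:{lineno}: duplicate edge {u!r} -- {v!r}"
            if strict:
                raise InputError(msg)
            logger.warning(msg)
            continue
        g.add_edge(u, v)
    return g


def write_json(obj: dict, path=None) -> str:
    text = json.dumps(obj, indent=2, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_count_table(table: OrbitCountTable, fmt: str = "tsv", path=None) -> str:
    if fmt == "tsv":
        text = table.to_tsv()
    elif fmt == "json":
        text = json.dumps(table.to_json(), indent=2, sort_keys=True) + "\n"
    else:
        raise InputError(f"unknown count-table format: {fmt!r}")
    if path is not None:
        Path(path).write_text(text)
    return text
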