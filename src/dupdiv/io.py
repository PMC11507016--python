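"""Readers and writers: edge-list TSV, STRING-style score files, result tables.

Edge lists are one edge per line, ``node_a<TAB>node_b<TAB>weight`` with an
optional header; weights round-trip exactly (written with ``repr``). An
optional node-universe file (one node id per line) carries nodes with no
edges, so isolated proteins survive serialisation.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import DataFormatError
from .graph import WeightedGraph

__all__ = [
    "write_graph_tsv",
    "read_graph_tsv",
    "read_string_edges",
    "write_trajectories_tsv",
    "read_trajectories_tsv",
    "SCORE_SCALES",
]

logger = logging.getLogger(__name__)

SCORE_SCALES = ("int_0_1000", "float_0_1")


def write_graph_tsv(
    G: WeightedGraph,
    edges_path: str | Path,
    nodes_path: str | Path | None = None,
    header: bool = True,
) -> None:
    """Write the edge list (and optionally the node universe) of ``G``.

    Without a nodes file, isolated nodes are not representable in the edge
    list and will be lost on re-reading.
    """
    with open(edges_path, "w") as fh:
        if header:
            fh.write("node_a\tnode_b\tweight\n")
        for a, b, w in G.edges():
            fh.write(f"{a}\t{b}\t{w!r}\n")
    if nodes_path is not None:
        with open(nodes_path, "w") as fh:
            for v in G.nodes:
                fh.write(f"{v}\n")


def read_graph_tsv(
    edges_path: str | Path,
    nodes_path: str | Path | None = None,
) -> WeightedGraph:
    """Read an edge-list TSV (header auto-detected) into a WeightedGraph."""
    edges = []
    with open(edges_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataFormatError(f"{edges_path}:{ln}: expected at least 2 columns")
            if ln == 1 and not _is_number(parts[0]) and parts[0].lower() in ("node_a", "source", "a"):
                continue
            try:
                a, b = int(parts[0]), int(parts[1])
                w = float(parts[2]) if len(parts) > 2 else 1.0
            except ValueError as exc:
                raise DataFormatError(f"{edges_path}:{ln}: {exc}") from None
            edges.append((a, b, w))
    if nodes_path is not None:
        with open(nodes_path) as fh:
            nodes = [int(line.strip()) for line in fh if line.strip()]
    else:
        nodes = sorted({v for a, b, _ in edges for v in (a, b)})
    return WeightedGraph.from_edges(nodes, edges)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_string_edges(
    path: str | Path,
    threshold: float,
    score_scale: str,
    node_universe_path: str | Path | None = None,
) -> WeightedGraph:
    """Load a STRING-style scored link file and threshold it into a unit-weight graph.

    The file holds ``protein_a  protein_b  score`` rows (tab- or
    whitespace-separated; header auto-detected). Edges with score >=
    ``threshold`` are kept and given weight 1. The node universe defaults to
    every protein appearing in the file *before* thresholding, so
    thresholding can create isolated nodes; an explicit universe file (one
    id per line) overrides this. Duplicate pairs collapse to their maximum
    score; self-loops are dropped with a logged warning.

    ``score_scale`` declares whether scores are STRING integers (0-1000) or
    floats in [0, 1]; the threshold must be on the declared scale.
    """
    if score_scale not in SCORE_SCALES:
        raise DataFormatError(f"score_scale must be one of {SCORE_SCALES}, got {score_scale!r}")
    if score_scale == "int_0_1000" and threshold <= 1.0:
        raise DataFormatError(
            f"threshold {threshold} looks like a 0-1 score but score_scale is int_0_1000"
        )
    if score_scale == "float_0_1" and threshold > 1.0:
        raise DataFormatError(
            f"threshold {threshold} exceeds 1 but score_scale is float_0_1"
        )
    try:
        df = pd.read_csv(path, sep=r"\s+", engine="python", header=None, comment="#")
    except Exception as exc:
        raise DataFormatError(f"cannot parse {path}: {exc}") from None
    if df.shape[1] < 3:
        raise DataFormatError(f"{path}: expected columns protein_a, protein_b, score")
    df = df.iloc[:, :3]
    df.columns = ["a", "b", "score"]
    if not _is_number(str(df.iloc[0]["score"])):
        df = df.iloc[1:]
    df["score"] = df["score"].astype(float)

    best: dict[tuple[str, str], float] = {}
    universe: set[str] = set()
    for a, b, s in df.itertuples(index=False):
        a, b = str(a), str(b)
        if a == b:
            logger.warning("dropping self-loop on %s", a)
            continue
        universe.update((a, b))
        key = (a, b) if a < b else (b, a)
        best[key] = max(best.get(key, -1.0), float(s))

    if node_universe_path is not None:
        with open(node_universe_path) as fh:
            universe = {line.strip() for line in fh if line.strip()}

    names = sorted(universe)
    ids = {name: i + 1 for i, name in enumerate(names)}
    kept = [
        (ids[a], ids[b], 1.0)
        for (a, b), s in sorted(best.items())
        if s >= threshold and a in ids and b in ids
    ]
    return WeightedGraph.from_edges(ids.values(), kept)


# ---------------------------------------------------------------------------
# result tables


def write_trajectories_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy trajectory table with full float precision."""
    frame.to_csv(path, sep="\t", index=False, float_format=None)


def read_trajectories_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
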