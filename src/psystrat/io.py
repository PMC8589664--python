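"""Reading and writing cohort tables and analysis artifacts.

CSV is the interchange format: one row per patient, PANSS columns named
exactly P1..P7, N1..N7, G1..G16, missing values as empty cells.  Boolean
outcomes are serialized as ``True``/``False``.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import OUTCOME_BINARY, PANSS_ITEMS, Cohort, CohortValidationError


class CohortParseError(ValueError):
    pass


def read_cohort(path: str | Path, schema: dict[str, str] | None = None) -> Cohort:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path : path to a CSV file with a header row.
    schema : optional mapping from column names found in the file to the
        canonical names (e.g. ``{"subject": "patient_id"}``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message carries the line
        raise CohortParseError(f"malformed CSV {path}: {exc}") from exc
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in PANSS_ITEMS if c not in df.columns]
    if missing:
        raise CohortParseError(f"{path}: missing PANSS columns {missing}")
    for col in OUTCOME_BINARY:
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False, True: True, False: False})
    df["patient_id"] = df["patient_id"].astype(str)
    try:
        return Cohort(df)
    except CohortValidationError as exc:
        raise CohortValidationError(f"{path}: {exc}") from exc


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV; floats keep full round-trip precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = cohort.df.copy()
    for col in PANSS_ITEMS:
        df[col] = df[col].astype(int)
    df.to_csv(path, index=False)


def write_assignment(labels: pd.Series, path: str | Path) -> None:
    out = labels.rename("group").rename_axis("patient_id").reset_index()
    out.to_csv(path, index=False)


def read_assignment(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, dtype={"patient_id": str})
    return df.set_index("patient_id")["group"]


def _node_key(node) -> str:
    return f"{node[0]}:{node[1]}" if isinstance(node, tuple) else str(node)


def graph_to_json(graph: nx.Graph) -> dict:
    """Mapper graph as a JSON-serializable dict (nodes with members, edges
    with shared-member counts)."""
    nodes = []
    for node, data in sorted(graph.nodes(data=True), key=lambda kv: _node_key(kv[0])):
        nodes.append(
            {
                "id": _node_key(node),
                "rectangle": data.get("rectangle"),
                "members": sorted(int(i) for i in data["members"]),
                "patient_ids": sorted(map(str, data.get("patient_ids", []))),
            }
        )
    edges = [
        {"source": _node_key(u), "target": _node_key(v), "shared": int(d.get("shared", 1))}
        for u, v, d in sorted(graph.edges(data=True), key=lambda e: (_node_key(e[0]), _node_key(e[1])))
    ]
    return {"nodes": nodes, "edges": edges}


def write_graph(graph: nx.Graph, path_json: str | Path, path_graphml: str | Path | None = None) -> None:
    Path(path_json).parent.mkdir(parents=True, exist_ok=True)
    with open(path_json, "w") as fh:
        json.dump(graph_to_json(graph), fh, indent=1)
    if path_graphml is not None:
        g = nx.Graph()
        for node, data in graph.nodes(data=True):
            g.add_node(_node_key(node), members=",".join(str(i) for i in sorted(data["members"])))
        for u, v, d in graph.edges(data=True):
            g.add_edge(_node_key(u), _node_key(v), shared=int(d.get("shared", 1)))
        nx.write_graphml(g, path_graphml)


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
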