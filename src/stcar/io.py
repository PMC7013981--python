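"""Plain-text I/O: GeoJSON polygons, edge-list CSVs, panel CSVs, truth sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

from .spatial import AdjacencyMatrix, build_adjacency_from_edges
from .synthetic import PanelData, SyntheticTruth

__all__ = [
    "read_geojson",
    "read_adjacency_csv",
    "write_adjacency_csv",
    "write_adjacency_matrix_csv",
    "read_panel_csv",
    "write_panel_csv",
    "write_truth",
    "read_truth",
]


def read_geojson(
    path: str | Path, id_field: str = "id"
) -> tuple[list[BaseGeometry], list[str]]:
    """Polygons + unit ids from a GeoJSON FeatureCollection.

    ``id_field`` names the property carrying the unit identifier; a
    top-level feature "id" member is used as a fallback.
    """
    with open(path) as fh:
        gj = json.load(fh)
    polygons, ids = [], []
    for i, feat in enumerate(gj["features"]):
        props = feat.get("properties") or {}
        uid = props.get(id_field, feat.get("id", i))
        polygons.append(shape(feat["geometry"]))
        ids.append(str(uid))
    return polygons, ids


def read_adjacency_csv(path: str | Path, unit_ids: list[str] | None = None) -> AdjacencyMatrix:
    """Adjacency from a two-column edge list (id_a, id_b).

    If ``unit_ids`` is omitted the roster is the sorted set of ids seen in
    the edge list (isolated units then cannot be represented).
    """
    df = pd.read_csv(path, dtype=str)
    edges = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if unit_ids is None:
        unit_ids = sorted({u for e in edges for u in e})
    return build_adjacency_from_edges(edges, list(unit_ids))


def write_adjacency_csv(adj: AdjacencyMatrix, path: str | Path) -> None:
    pd.DataFrame(adj.edges(), columns=["id_a", "id_b"]).to_csv(path, index=False)


def write_adjacency_matrix_csv(adj: AdjacencyMatrix, path: str | Path) -> None:
    """Dense 0/1 matrix with unit ids as header and index, for inspection."""
    pd.DataFrame(
        adj.W.astype(int), index=adj.unit_ids, columns=adj.unit_ids
    ).to_csv(path)


def read_panel_csv(path: str | Path, **kw) -> PanelData:
    return PanelData.from_frame(pd.read_csv(path), **kw)


def write_panel_csv(panel: PanelData, path: str | Path) -> None:
    panel.to_frame().to_csv(path, index=False)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth.as_dict(), fh)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    out["beta"] = np.asarray(out["beta"], dtype=float)
    return out
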