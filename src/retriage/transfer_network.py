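"""Sending-to-receiving transfer graphs with proportion-weighted edges.

Nodes are hospitals (level, location, region); a directed edge aggregates
all re-triages between one ordered facility pair in the selected year, with
weight equal to that pair's share of the year's re-triages. Edge categories
follow the map legend convention: optimal (to level I/II), suboptimal into a
nontrauma center, and suboptimal into a level III/IV center.
"""

from __future__ import annotations

import json

import networkx as nx
import numpy as np
import pandas as pd

from . import vocab
from .hospitals import HospitalDirectory

GEOGRAPHIC = "GEOGRAPHIC"
FORCE_DIRECTED = "FORCE_DIRECTED"

CATEGORY_OPTIMAL = "OPTIMAL"
CATEGORY_SUBOPT_NONTRAUMA = "SUBOPT_TO_NONTRAUMA"
CATEGORY_SUBOPT_III_IV = "SUBOPT_TO_III_IV"

FR_ITERATIONS = 500


def edge_category(receiving_level: str) -> str:
    if receiving_level in vocab.HIGH_LEVELS:
        return CATEGORY_OPTIMAL
    if receiving_level == vocab.NONTRAUMA:
        return CATEGORY_SUBOPT_NONTRAUMA
    return CATEGORY_SUBOPT_III_IV


def build_transfer_graph(
    events, directory: HospitalDirectory, year: int | None = None
) -> nx.DiGraph:
    """Aggregate labeled events into a weighted directed graph.

    ``year`` restricts to one calendar year (weights normalize over that
    year's re-triage count); ``None`` pools the whole period. A year with no
    events yields an empty graph.
    """
    ev = events if year is None else events[events["year"] == year]
    g = nx.DiGraph()
    total = len(ev)
    if total == 0:
        return g
    for (s, r), grp in ev.groupby(["facility_id", "recv_facility_id"], sort=True):
        recv_level = grp["receiving_level"].iloc[0]
        for fid in (s, r):
            if not g.has_node(fid):
                lat, lon = directory.coordinates(fid)
                g.add_node(
                    fid,
                    latitude=lat,
                    longitude=lon,
                    rtcc_id=str(directory.attribute_for(pd.Series([fid]), "rtcc_id").iloc[0]),
                )
        g.add_edge(
            s, r,
            count=int(len(grp)),
            weight=len(grp) / total,
            category=edge_category(recv_level),
        )
    return g


def layout_graph(graph: nx.DiGraph, mode: str = GEOGRAPHIC, seed: int = 0) -> dict:
    """Node coordinates: geographic (lon/lat as x/y) or a seeded
    Fruchterman-Reingold spring embedding with a fixed iteration count."""
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot lay out an empty graph")
    if mode == GEOGRAPHIC:
        pos = {}
        for node, data in graph.nodes(data=True):
            if "longitude" not in data or "latitude" not in data:
                raise ValueError(f"node {node!r} lacks coordinates for geographic layout")
            pos[node] = (data["longitude"], data["latitude"])
        return pos
    if mode == FORCE_DIRECTED:
        return nx.spring_layout(graph, iterations=FR_ITERATIONS, seed=seed)
    raise ValueError(f"unknown layout mode {mode!r}")


def write_graphml(graph: nx.DiGraph, path) -> None:
    nx.write_graphml(graph, path)


def to_geojson(graph: nx.DiGraph) -> dict:
    """Nodes as points and edges as great-circle chords (straight lon/lat
    segments; adequate at intrastate scale)."""
    features = []
    for node, d in graph.nodes(data=True):
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [d["longitude"], d["latitude"]]},
                "properties": {"facility_id": node, **{k: d[k] for k in d if k not in
                                                       ("latitude", "longitude")}},
            }
        )
    for s, r, d in graph.edges(data=True):
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        [graph.nodes[s]["longitude"], graph.nodes[s]["latitude"]],
                        [graph.nodes[r]["longitude"], graph.nodes[r]["latitude"]],
                    ],
                },
                "properties": {"sending": s, "receiving": r, **d},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(graph: nx.DiGraph, path) -> None:
    with open(path, "w") as fh:
        json.dump(to_geojson(graph), fh)


EDGE_COLORS = {
    CATEGORY_OPTIMAL: "tab:blue",
    CATEGORY_SUBOPT_NONTRAUMA: "tab:red",
    CATEGORY_SUBOPT_III_IV: "tab:green",
}


def plot_graph(graph: nx.DiGraph, pos: dict, path) -> None:
    """Static rendering: line width encodes transfer volume, color the edge
    category."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8))
    weights = np.array([d["weight"] for _, _, d in graph.edges(data=True)])
    widths = 0.5 + 8 * weights / weights.max() if len(weights) else []
    colors = [EDGE_COLORS[d["category"]] for _, _, d in graph.edges(data=True)]
    nx.draw_networkx_nodes(graph, pos, node_size=30, node_color="black", ax=ax)
    nx.draw_networkx_edges(graph, pos, width=widths, edge_color=colors, ax=ax, arrows=False)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
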