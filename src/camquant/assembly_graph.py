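"""Centroid-level assembly statistics: contact graphs and probability tables.

Cell-cell contacts are inferred from segmented-cell centroids: an edge
joins cells *i* and *j* when their centre distance is at most a fixed
threshold, or at most ``k * (radius_i + radius_j)`` when per-cell radii are
available (inclusive boundary in both cases).  The interaction-probability
table normalizes the edge counts of each unordered type pair by the total
edge count, producing one probability distribution over contact types (the
"probability box" heat map); a row-normalized variant is exposed as a
flag.

`area_ratio_series` covers the intercalation time course: per timepoint,
max-project, binarize both channels, and report the footprint-area ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import CamquantError
from .imaging import ImageStack, binarize, max_projection

__all__ = [
    "ContactGraph",
    "build_contact_graph",
    "interaction_probability",
    "area_ratio_series",
    "read_centroids",
    "write_centroids",
]

POSITION_COLUMNS = ("x_um", "y_um", "z_um")


@dataclass
class ContactGraph:
    """Undirected typed contact graph with its threshold-rule record."""

    graph: nx.Graph = field(repr=False)
    rule: str = ""

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


def _positions(cells: pd.DataFrame) -> np.ndarray:
    if "x_um" not in cells.columns or "y_um" not in cells.columns:
        raise CamquantError("centroid table needs x_um and y_um columns")
    cols = [c for c in POSITION_COLUMNS if c in cells.columns]
    pos = cells[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(pos)):
        raise CamquantError("centroid positions must be finite")
    return pos


def build_contact_graph(
    cells: pd.DataFrame,
    rule: str = "radius_scaled",
    tau: float | None = None,
    k: float = 1.1,
) -> ContactGraph:
    """Build the typed contact graph of a centroid set.

    ``rule='fixed'`` joins cells within ``tau`` µm; ``rule='radius_scaled'``
    joins cells within ``k * (radius_i + radius_j)`` and requires a
    ``radius_um`` column.  Both thresholds are inclusive.
    """
    pos = _positions(cells)
    ids = cells["id"].to_numpy()
    if len(set(ids)) != len(ids):
        raise CamquantError("centroid ids must be unique")

    g = nx.Graph()
    for cid, ctype in zip(ids, cells["type"]):
        g.add_node(int(cid), type=str(ctype))

    if rule == "fixed":
        if tau is None or tau <= 0:
            raise CamquantError("fixed rule needs tau > 0")
        pairs = cKDTree(pos).query_pairs(tau)  # inclusive upper bound
        for i, j in pairs:
            g.add_edge(int(ids[i]), int(ids[j]))
        desc = f"fixed(tau={tau})"
    elif rule == "radius_scaled":
        if "radius_um" not in cells.columns:
            raise CamquantError("radius_scaled rule needs a radius_um column")
        if k <= 0:
            raise CamquantError("radius_scaled rule needs k > 0")
        radii = cells["radius_um"].to_numpy(dtype=float)
        r_max = 2 * k * radii.max()
        pairs = cKDTree(pos).query_pairs(r_max)
        for i, j in pairs:
            if np.linalg.norm(pos[i] - pos[j]) <= k * (radii[i] + radii[j]):
                g.add_edge(int(ids[i]), int(ids[j]))
        desc = f"radius_scaled(k={k})"
    else:
        raise CamquantError(f"unknown rule {rule!r}")
    return ContactGraph(graph=g, rule=desc)


def interaction_probability(
    graph: ContactGraph,
    cells: pd.DataFrame | None = None,
    row_normalized: bool = False,
) -> pd.DataFrame:
    """Interaction-probability table over unordered type pairs.

    With the default global normalization, entries over unordered pairs
    (including same-type contacts) sum to 1; heterotypic probabilities are
    mirrored across the diagonal for heat-map display.
    ``row_normalized=True`` instead normalizes each row to the conditional
    contact distribution of that type.

    Raises
    ------
    CamquantError
        If the graph has no edges.
    """
    g = graph.graph
    if g.number_of_edges() == 0:
        raise CamquantError("no contacts: cannot form a probability table")
    if cells is not None:
        types = sorted(set(cells["type"].astype(str)))
    else:
        types = sorted({d["type"] for _, d in g.nodes(data=True)})
    counts = pd.DataFrame(0.0, index=types, columns=types)
    for u, v in g.edges:
        a, b = sorted((g.nodes[u]["type"], g.nodes[v]["type"]))
        counts.loc[a, b] += 1
        if a != b:
            counts.loc[b, a] += 1
    if row_normalized:
        row_sums = counts.sum(axis=1)
        return counts.div(row_sums.replace(0, np.nan), axis=0).fillna(0.0)
    return counts / g.number_of_edges()


def area_ratio_series(
    stacks: list[tuple[float, ImageStack]],
    channel_num: str,
    channel_den: str,
    scope: str = "per-slice",
    method: str = "otsu",
    threshold: float | None = None,
) -> pd.DataFrame:
    """Footprint-area ratio of two channels over time.

    Per timepoint the stack is max-projected, each channel binarized, and
    ``ratio = area(channel_num) / area(channel_den)`` computed from
    foreground pixel counts times the pixel area.  A zero denominator
    flags the ratio as NaN (undefined) at that timepoint without failing.
    """
    rows = []
    for t, stack in stacks:
        proj = max_projection(stack)
        areas = {}
        for name in (channel_num, channel_den):
            bw = binarize(proj, name, scope=scope, method=method, threshold=threshold)
            areas[name] = bw.area()
        den = areas[channel_den]
        rows.append(
            {
                "t": t,
                "area_num": areas[channel_num],
                "area_den": den,
                "ratio": areas[channel_num] / den if den > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def read_centroids(path) -> pd.DataFrame:
    """Read a centroid CSV (columns id, x_um, y_um[, z_um], type[, radius_um])."""
    df = pd.read_csv(path)
    missing = {"id", "x_um", "y_um", "type"} - set(df.columns)
    if missing:
        raise CamquantError(f"centroid CSV lacks columns {sorted(missing)}")
    return df


def write_centroids(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)
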