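"""Detection and classification of tertiary lymphoid structures (TLS).

Lymphoid infiltrates are defined as contact-connected conglomerates of T
and B lymphocytes: an undirected graph links lymphocytes whose centers lie
within a contact radius (~one lymphocyte diameter, i.e. physically
touching), and connected components with at least ``min_cells`` members
containing both lineages are infiltrates.  An infiltrate is scored as a
TLS when it shows organized structure: separate B and T cell zones
(k-nearest-neighbor class segregation above a threshold for both classes)
and/or a germinal center (a compact disk that is a dense, nearly pure
B-cell focus relative to the component's typical local density).  Venules,
an alternative scoring criterion in the source workflow, are not modeled:
the adaptive panel carries no endothelial marker.

Distances from a TLS centroid to the media/adventitia boundary quantify
where in the adventitia the structures sit.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import AnalysisParams
from .geometry import LayerGeometry
from .panels import T_CELL_LEAVES


@dataclass
class TLSRecord:
    tls_id: str
    slide_id: str
    member_ids: tuple[str, ...]
    n_t: int
    n_b: int
    centroid_x_um: float
    centroid_y_um: float
    zone_segregation_t: float
    zone_segregation_b: float
    has_zones: bool
    has_germinal_center: bool
    is_tls: bool
    distance_to_media_um: float = np.nan

    def to_row(self) -> dict:
        return {
            "tls_id": self.tls_id,
            "slide_id": self.slide_id,
            "n_members": len(self.member_ids),
            "n_t": self.n_t,
            "n_b": self.n_b,
            "centroid_x_um": self.centroid_x_um,
            "centroid_y_um": self.centroid_y_um,
            "zone_segregation_t": self.zone_segregation_t,
            "zone_segregation_b": self.zone_segregation_b,
            "has_zones": self.has_zones,
            "has_germinal_center": self.has_germinal_center,
            "is_tls": self.is_tls,
            "distance_to_media_um": self.distance_to_media_um,
        }


def lymphocyte_mask(cells: pd.DataFrame, layers: tuple[str, ...], layer_labels: np.ndarray) -> np.ndarray:
    """T or B cells (adaptive-panel leaves) within the given layers."""
    phen = cells["phenotype_adaptive"]
    is_lymph = phen.isin(T_CELL_LEAVES + ("b_cell",)).to_numpy()
    return is_lymph & np.isin(layer_labels, layers)


def build_contact_graph(lymphocytes: pd.DataFrame, contact_radius_um: float) -> nx.Graph:
    """Undirected graph on lymphocytes: edge iff center distance <= radius."""
    g = nx.Graph()
    ids = lymphocytes["cell_id"].to_numpy()
    g.add_nodes_from(ids)
    if len(lymphocytes) >= 2:
        xy = lymphocytes[["x_um", "y_um"]].to_numpy()
        tree = cKDTree(xy)
        for i, j in tree.query_pairs(contact_radius_um):  # pairs with distance <= r
            g.add_edge(ids[i], ids[j])
    return g


def find_lymphoid_infiltrates(
    graph: nx.Graph, lymphocytes: pd.DataFrame, min_cells: int
) -> list[pd.DataFrame]:
    """Connected components with >= min_cells members and both lineages,
    ordered deterministically by centroid (x, then y)."""
    by_id = lymphocytes.set_index("cell_id", drop=False)
    comps = []
    for comp in nx.connected_components(graph):
        if len(comp) < min_cells:
            continue
        members = by_id.loc[sorted(comp)]
        is_b = (members["phenotype_adaptive"] == "b_cell").to_numpy()
        if is_b.all() or not is_b.any():
            continue  # must mix T and B
        comps.append(members.reset_index(drop=True))
    comps.sort(key=lambda m: (float(m["x_um"].mean()), float(m["y_um"].mean())))
    return comps


def _zone_segregation(xy: np.ndarray, is_b: np.ndarray, k: int) -> tuple[float, float]:
    """Mean same-class fraction of the k nearest within-component neighbors,
    per class.  Components smaller than k+1 use the neighbors available."""
    n = len(xy)
    kk = min(k, n - 1)
    if kk < 1:
        return 1.0, 1.0
    tree = cKDTree(xy)
    _, idx = tree.query(xy, k=kk + 1)
    nbr = idx[:, 1:]  # drop self
    same = is_b[nbr] == is_b[:, None]
    frac_same = same.mean(axis=1)
    seg_b = float(frac_same[is_b].mean()) if is_b.any() else np.nan
    seg_t = float(frac_same[~is_b].mean()) if (~is_b).any() else np.nan
    return seg_t, seg_b


def _has_germinal_center(
    xy: np.ndarray, is_b: np.ndarray, radius: float, fold: float, max_t_fraction: float
) -> bool:
    """A disk of ``radius`` centered on some member that is B-dense
    (>= fold x the component's median local member density) and nearly
    B-pure (T fraction <= max_t_fraction)."""
    tree = cKDTree(xy)
    area = np.pi * radius**2
    counts = tree.query_ball_point(xy, radius, return_length=True)  # includes self
    median_local_density = float(np.median(counts)) / area
    if median_local_density == 0:
        return False
    neighbors = tree.query_ball_point(xy, radius)
    for i in range(len(xy)):
        idx = np.asarray(neighbors[i])
        n_b = int(is_b[idx].sum())
        n_t = len(idx) - n_b
        if len(idx) == 0:
            continue
        b_density = n_b / area
        t_fraction = n_t / len(idx)
        if b_density >= fold * median_local_density and t_fraction <= max_t_fraction:
            return True
    return False


def classify_tls(
    members: pd.DataFrame,
    analysis: AnalysisParams,
    tls_id: str = "tls0",
    geometry: LayerGeometry | None = None,
) -> TLSRecord:
    """Score one infiltrate: zones, germinal center, TLS flag, media distance."""
    xy = members[["x_um", "y_um"]].to_numpy()
    is_b = (members["phenotype_adaptive"] == "b_cell").to_numpy()
    seg_t, seg_b = _zone_segregation(xy, is_b, analysis.k_neighbors)
    has_zones = (
        not np.isnan(seg_t)
        and not np.isnan(seg_b)
        and seg_t >= analysis.zone_segregation_threshold
        and seg_b >= analysis.zone_segregation_threshold
    )
    has_gc = _has_germinal_center(
        xy, is_b, analysis.gc_radius_um, analysis.gc_fold, analysis.gc_max_t_fraction
    )
    cx, cy = float(xy[:, 0].mean()), float(xy[:, 1].mean())
    rec = TLSRecord(
        tls_id=tls_id,
        slide_id=str(members["slide_id"].iloc[0]) if len(members) else "",
        member_ids=tuple(members["cell_id"]),
        n_t=int((~is_b).sum()),
        n_b=int(is_b.sum()),
        centroid_x_um=cx,
        centroid_y_um=cy,
        zone_segregation_t=seg_t,
        zone_segregation_b=seg_b,
        has_zones=has_zones,
        has_germinal_center=has_gc,
        is_tls=has_zones or has_gc,
    )
    if geometry is not None:
        rec.distance_to_media_um = tls_media_distance(rec, geometry)
    return rec


def tls_media_distance(record: TLSRecord, geometry: LayerGeometry) -> float:
    """Euclidean distance from the TLS centroid to the nearest point of the
    media/adventitia boundary."""
    from shapely.geometry import Point

    return float(
        geometry.media_adventitia_boundary().distance(
            Point(record.centroid_x_um, record.centroid_y_um)
        )
    )


def detect_tls(
    cells: pd.DataFrame, geometry: LayerGeometry, analysis: AnalysisParams
) -> list[TLSRecord]:
    """Full per-slide detection: contact graph on adventitial lymphocytes,
    infiltrate filtering, TLS classification, media distances."""
    layer_labels = geometry.assign_layers(cells["x_um"].to_numpy(), cells["y_um"].to_numpy())
    lymph = cells[lymphocyte_mask(cells, analysis.tls_layers, layer_labels)]
    graph = build_contact_graph(lymph, analysis.contact_radius_um)
    comps = find_lymphoid_infiltrates(graph, lymph, analysis.min_infiltrate_cells)
    slide = str(cells["slide_id"].iloc[0]) if len(cells) else "slide"
    return [
        classify_tls(m, analysis, tls_id=f"{slide}_det{i}", geometry=geometry)
        for i, m in enumerate(comps)
    ]


def tls_group_stats(records_per_slide: dict[str, list[TLSRecord]]) -> dict:
    """Group-level TLS statistics over quantifiable slides.

    prevalence: fraction of slides with >= 1 TLS; mean count reported both
    per TLS-positive slide (primary) and per all slides (alternative, since
    the per-slide basis of the published mean is ambiguous); mean centroid
    distance to the media over all detected TLS.
    """
    n_slides = len(records_per_slide)
    counts = {s: sum(r.is_tls for r in recs) for s, recs in records_per_slide.items()}
    positive = [c for c in counts.values() if c > 0]
    distances = [
        r.distance_to_media_um
        for recs in records_per_slide.values()
        for r in recs
        if r.is_tls and not np.isnan(r.distance_to_media_um)
    ]
    return {
        "n_slides": n_slides,
        "prevalence": (len(positive) / n_slides) if n_slides else np.nan,
        "mean_tls_per_positive_slide": float(np.mean(positive)) if positive else np.nan,
        "mean_tls_per_slide": float(np.mean(list(counts.values()))) if counts else np.nan,
        "mean_distance_to_media_um": float(np.mean(distances)) if distances else np.nan,
    }
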