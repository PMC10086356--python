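"""Synthetic whole-slide single-cell generator with known ground truth.

Emulates post-segmentation single-cell tables from whole-slide multiplex
IHC of the aortic wall: each slide is a rectangular strip with intima /
media / adventitia bands, homogeneous-Poisson cell placement per layer and
phenotype, vasa-vasorum endothelial clusters, one or more excluded blood
regions densely packed with circulating leukocytes, planted tertiary
lymphoid structures (TLS) with a compact B-cell core (germinal-center
proxy) and a T-cell rim, and per-marker log-normal intensities with
overlapping positive/negative distributions for the gradual markers.

TLS members are *relocated* from the slide's background lymphocyte pool
rather than added on top, so planting does not alter the slide's per-layer
phenotype composition (only its spatial arrangement); if the realized pool
is too small the shortfall is synthesized and recorded in ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point

from .config import AnalysisParams, CohortConfig, GroupParams, IntensityModel, TLSParams
from .geometry import LAYERS, ExcludedRegion, GeometryError, LayerGeometry
from .panels import ALL_MARKERS, PHENOTYPE_MARKERS

TILE_W_UM = 600.0
TILE_H_UM = 450.0

#: composition of circulating cells inside blood (hematoma) regions
BLOOD_COMPOSITION = {
    "helper_t": 0.30,
    "cytotoxic_t": 0.15,
    "b_cell": 0.10,
    "neutrophil": 0.35,
    "stromal": 0.10,
}

CELL_COLUMNS = ["cell_id", "slide_id", "tile_id", "x_um", "y_um"] + list(ALL_MARKERS) + [
    "true_phenotype",
    "layer",
]


@dataclass(frozen=True)
class PlantedTLS:
    tls_id: str
    slide_id: str
    center_x_um: float
    center_y_um: float
    n_b: int
    n_t: int
    member_ids: tuple[str, ...]
    has_germinal_center: bool = True

    def to_dict(self) -> dict:
        return {
            "tls_id": self.tls_id,
            "slide_id": self.slide_id,
            "center_x_um": self.center_x_um,
            "center_y_um": self.center_y_um,
            "n_b": self.n_b,
            "n_t": self.n_t,
            "member_ids": list(self.member_ids),
            "has_germinal_center": self.has_germinal_center,
        }


@dataclass
class GroundTruth:
    """Per-slide ground truth: planted TLS records (per-cell phenotype and
    layer truth live in the cell table itself)."""

    slide_id: str
    tls: list[PlantedTLS] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"slide_id": self.slide_id, "tls": [t.to_dict() for t in self.tls]}


@dataclass
class SlideData:
    slide_id: str
    group: str
    cells: pd.DataFrame
    geometry: LayerGeometry
    truth: GroundTruth


# --------------------------------------------------------------------------
# placement helpers
def _uniform_in_band(geometry: LayerGeometry, layer: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """n points uniform over the layer band minus excluded regions."""
    if n == 0:
        return np.empty((0, 2))
    y0, y1 = geometry.layer_band(layer)
    out = []
    need = n
    while need > 0:
        m = max(need * 2, 16)
        x = rng.uniform(0.0, geometry.slide_width_um, m)
        y = rng.uniform(y0, y1, m)
        keep = np.ones(m, dtype=bool)
        for reg in geometry.excluded_regions:
            keep &= ~shapely.intersects_xy(reg.polygon, x, y)
        pts = np.column_stack([x[keep], y[keep]])[:need]
        out.append(pts)
        need -= len(pts)
    return np.concatenate(out)


def _clustered_in_band(
    geometry: LayerGeometry,
    layer: str,
    expected: float,
    rng: np.random.Generator,
    cluster_size_mean: float,
    cluster_radius_um: float,
) -> np.ndarray:
    """Matérn-style cluster process: expected total intensity ``expected``."""
    n_clusters = rng.poisson(expected / cluster_size_mean)
    if n_clusters == 0:
        return np.empty((0, 2))
    centers = _uniform_in_band(geometry, layer, n_clusters, rng)
    sizes = 1 + rng.poisson(max(cluster_size_mean - 1.0, 0.0), n_clusters)
    y0, y1 = geometry.layer_band(layer)
    pts = []
    for c, s in zip(centers, sizes):
        r = cluster_radius_um * np.sqrt(rng.uniform(0, 1, s))
        a = rng.uniform(0, 2 * np.pi, s)
        x = np.clip(c[0] + r * np.cos(a), 0.0, geometry.slide_width_um)
        y = np.clip(c[1] + r * np.sin(a), y0 + 1e-6, y1 - 1e-6)
        pts.append(np.column_stack([x, y]))
    out = np.concatenate(pts)
    keep = np.ones(len(out), dtype=bool)
    for reg in geometry.excluded_regions:
        keep &= ~shapely.intersects_xy(reg.polygon, out[:, 0], out[:, 1])
    return out[keep]


def _ring_points(n: int, spacing: float, r_start: float, rng: np.random.Generator) -> np.ndarray:
    """Points on concentric rings ``0.87*spacing`` apart, ``spacing`` along
    each ring, from radius ``r_start`` outward, ordered by radius."""
    dr = 0.87 * spacing
    pts: list[tuple[float, float]] = []
    r = r_start
    if r_start == 0.0:
        pts.append((0.0, 0.0))
        r = dr
    while len(pts) < n:
        k = max(1, int(round(2 * np.pi * r / spacing)))
        phase = rng.uniform(0, 2 * np.pi)
        ang = phase + 2 * np.pi * np.arange(k) / k
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
        r += dr
    return np.asarray(pts[:n])


def _jitter(pts: np.ndarray, jitter_um: float, rng: np.random.Generator) -> np.ndarray:
    if jitter_um <= 0 or len(pts) == 0:
        return pts
    r = jitter_um * np.sqrt(rng.uniform(0, 1, len(pts)))
    a = rng.uniform(0, 2 * np.pi, len(pts))
    return pts + np.column_stack([r * np.cos(a), r * np.sin(a)])


def tls_template(tls_params: TLSParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Member positions of one TLS relative to its center: B core then T rim."""
    b_xy = _ring_points(tls_params.n_b, tls_params.b_spacing_um, 0.0, rng)
    core_r = float(np.max(np.hypot(b_xy[:, 0], b_xy[:, 1]))) if len(b_xy) > 1 else 0.0
    t_xy = _ring_points(tls_params.n_t, tls_params.t_spacing_um, core_r + tls_params.zone_gap_um, rng)
    return _jitter(b_xy, tls_params.jitter_um, rng), _jitter(t_xy, tls_params.jitter_um, rng)


# --------------------------------------------------------------------------
def place_tls(
    cells: pd.DataFrame,
    geometry: LayerGeometry,
    tls_params: TLSParams,
    rng: np.random.Generator,
    n_tls: int,
    contact_radius_um: float = 12.0,
    slide_id: str = "slide",
) -> tuple[pd.DataFrame, list[PlantedTLS]]:
    """Plant ``n_tls`` TLS in the adventitia by relocating background B and
    helper-T cells into B-core/T-rim disks at sampled offsets from the
    media/adventitia boundary.

    Member spacing is bounded by construction so each planted TLS forms a
    single contact-connected component at ``contact_radius_um``.
    """
    if n_tls == 0:
        return cells, []
    worst = max(tls_params.t_spacing_um * 1.1, tls_params.zone_gap_um) + 2 * tls_params.jitter_um
    if worst > contact_radius_um:
        raise ValueError(
            f"TLS spacing ({worst:.1f} um worst-case) exceeds contact radius {contact_radius_um} um; "
            "planted cells would not be guaranteed to touch"
        )

    templates = [tls_template(tls_params, rng) for _ in range(n_tls)]
    r_out = max(
        float(np.max(np.hypot(np.concatenate([b, t])[:, 0], np.concatenate([b, t])[:, 1])))
        for b, t in templates
    )
    y_ma = geometry.media_adventitia_y
    adv_thickness = geometry.adventitia_thickness_um
    lo, hi = r_out + 10.0, adv_thickness - r_out - 10.0
    if lo >= hi:
        raise GeometryError("TLS disk does not fit inside the adventitia")

    centers: list[tuple[float, float]] = []
    for _ in range(n_tls):
        for attempt in range(tls_params.max_tries):
            offset = rng.normal(tls_params.offset_mean_um, tls_params.offset_sd_um)
            if not lo <= offset <= hi:
                continue
            cx = rng.uniform(r_out + 20.0, geometry.slide_width_um - r_out - 20.0)
            cy = y_ma + offset
            if any(np.hypot(cx - px, cy - py) < tls_params.min_separation_um for px, py in centers):
                continue
            if any(reg.polygon.distance(Point(cx, cy)) < r_out + 10.0 for reg in geometry.excluded_regions):
                continue
            centers.append((cx, cy))
            break
        else:
            raise GeometryError(
                f"could not place TLS in the adventitia after {tls_params.max_tries} tries"
            )

    cells = cells.reset_index(drop=True)
    planted: list[PlantedTLS] = []
    used: set[int] = set()
    next_cell = len(cells)
    new_rows: list[dict] = []

    def _take(phenotype: str, k: int) -> list[int]:
        nonlocal next_cell
        pool = cells.index[
            (cells["true_phenotype"] == phenotype)
            & (cells["layer"] == "adventitia")
            & (~cells.index.isin(list(used)))
        ].to_numpy()
        chosen = list(rng.permutation(pool)[:k])
        shortfall = k - len(chosen)
        for _ in range(shortfall):  # rare: realized pool smaller than demand
            new_rows.append(
                {
                    "cell_id": f"{slide_id}_c{next_cell:05d}",
                    "slide_id": slide_id,
                    "x_um": 0.0,
                    "y_um": 0.0,
                    "true_phenotype": phenotype,
                    "layer": "adventitia",
                }
            )
            chosen.append(-len(new_rows))  # negative sentinel -> new_rows index
            next_cell += 1
        used.update(i for i in chosen if i >= 0)
        return chosen

    for j, ((cx, cy), (b_xy, t_xy)) in enumerate(zip(centers, templates)):
        member_ids = []
        for phenotype, xy in (("b_cell", b_xy), ("helper_t", t_xy)):
            idx = _take(phenotype, len(xy))
            for i, (dx, dy) in zip(idx, xy):
                if i >= 0:
                    cells.at[i, "x_um"] = cx + dx
                    cells.at[i, "y_um"] = cy + dy
                    member_ids.append(cells.at[i, "cell_id"])
                else:
                    row = new_rows[-i - 1]
                    row["x_um"], row["y_um"] = cx + dx, cy + dy
                    member_ids.append(row["cell_id"])
        planted.append(
            PlantedTLS(
                tls_id=f"{slide_id}_tls{j}",
                slide_id=slide_id,
                center_x_um=cx,
                center_y_um=cy,
                n_b=len(b_xy),
                n_t=len(t_xy),
                member_ids=tuple(member_ids),
            )
        )
    if new_rows:
        cells = pd.concat([cells, pd.DataFrame(new_rows)], ignore_index=True)
    return cells, planted


# --------------------------------------------------------------------------
def sample_intensities(
    phenotypes,
    intensity_model: IntensityModel,
    rng: np.random.Generator,
    markers: tuple[str, ...] = ALL_MARKERS,
) -> pd.DataFrame:
    """Draw per-marker intensities for cells of the given true phenotypes.

    A marker listed for the phenotype in :data:`~aortamihc.panels.PHENOTYPE_MARKERS`
    is drawn from that marker's positive log-normal, every other marker from
    its negative log-normal (which doubles as the autofluorescence floor).
    """
    phen = np.asarray(phenotypes, dtype=object)
    unknown = set(np.unique(phen)) - set(PHENOTYPE_MARKERS)
    if unknown:
        raise ValueError(f"unknown phenotypes: {sorted(unknown)}")
    out = {}
    for m in markers:
        if m not in intensity_model.params:
            raise KeyError(f"no intensity distribution for marker {m!r}")
        p = intensity_model.params[m]
        positive_for = [ph for ph, ms in PHENOTYPE_MARKERS.items() if m in ms]
        pos = np.isin(phen, positive_for)
        vals = rng.lognormal(p.neg_mu, p.neg_sigma, len(phen))
        if pos.any():
            vals[pos] = rng.lognormal(p.pos_mu, p.pos_sigma, int(pos.sum()))
        out[m] = vals
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
def _make_geometry(config: CohortConfig, rng: np.random.Generator) -> LayerGeometry:
    g = config.geometry
    regions = []
    y_ma = g.intima_thickness_um + g.media_thickness_um
    r = g.blood_region_radius_um
    for _ in range(g.n_blood_regions):
        cx = rng.uniform(r + 50.0, g.slide_width_um - r - 50.0)
        cy = rng.uniform(y_ma + r + 20.0, y_ma + g.adventitia_thickness_um - r - 20.0)
        regions.append(ExcludedRegion("blood", Point(cx, cy).buffer(r, quad_segs=32)))
    return LayerGeometry(
        slide_width_um=g.slide_width_um,
        intima_thickness_um=g.intima_thickness_um,
        media_thickness_um=g.media_thickness_um,
        adventitia_thickness_um=g.adventitia_thickness_um,
        excluded_regions=regions,
    )


def _tile_ids(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    ix = (np.asarray(x) // TILE_W_UM).astype(int)
    iy = (np.asarray(y) // TILE_H_UM).astype(int)
    return np.char.add(np.char.add("t", ix.astype(str)), np.char.add("_", iy.astype(str)))


def generate_slide(
    group: GroupParams,
    geometry: LayerGeometry,
    rng: np.random.Generator,
    intensity_model: IntensityModel,
    analysis: AnalysisParams,
    slide_id: str = "slide",
    blood_cell_density_mm2: float = 2500.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """One synthetic slide: background cells per layer, vasa-vasorum
    endothelial clusters, blood-region cells, planted TLS, intensities."""
    xs, ys, phenos, layers = [], [], [], []
    for layer in LAYERS:
        area = geometry.layer_area_mm2(layer)
        comp = dict(group.composition.get(layer, {}))
        comp["stromal"] = max(0.0, 1.0 - sum(comp.values()))
        total = group.layer_density.get(layer, 0.0)
        for pheno, frac in comp.items():
            expected = total * frac * area
            if expected == 0:
                continue
            if pheno == "endothelium":
                pts = _clustered_in_band(
                    geometry, layer, expected, rng,
                    analysis.vasa_cluster_size_mean, analysis.vasa_cluster_radius_um,
                )
            else:
                pts = _uniform_in_band(geometry, layer, rng.poisson(expected), rng)
            xs.append(pts[:, 0])
            ys.append(pts[:, 1])
            phenos.extend([pheno] * len(pts))
            layers.extend([layer] * len(pts))

    # circulating cells inside excluded blood regions
    for reg in geometry.excluded_regions:
        if reg.label != "blood":
            continue
        n = rng.poisson(reg.polygon.area / 1e6 * blood_cell_density_mm2)
        if n == 0:
            continue
        minx, miny, maxx, maxy = reg.polygon.bounds
        got = 0
        while got < n:
            m = max((n - got) * 2, 16)
            x = rng.uniform(minx, maxx, m)
            y = rng.uniform(miny, maxy, m)
            inside = shapely.intersects_xy(reg.polygon, x, y)
            x, y = x[inside][: n - got], y[inside][: n - got]
            ph = rng.choice(
                list(BLOOD_COMPOSITION), size=len(x), p=list(BLOOD_COMPOSITION.values())
            )
            xs.append(x)
            ys.append(y)
            phenos.extend(ph)
            layers.extend(["excluded"] * len(x))
            got += len(x)

    x_all = np.concatenate(xs) if xs else np.empty(0)
    y_all = np.concatenate(ys) if ys else np.empty(0)
    cells = pd.DataFrame(
        {
            "cell_id": [f"{slide_id}_c{i:05d}" for i in range(len(x_all))],
            "slide_id": slide_id,
            "x_um": x_all,
            "y_um": y_all,
            "true_phenotype": phenos,
            "layer": layers,
        }
    )

    truth = GroundTruth(slide_id=slide_id)
    if group.tls is not None and rng.uniform() < group.tls.prevalence:
        n_tls = 1 + rng.poisson(group.tls.extra_count_mean)
        cells, planted = place_tls(
            cells, geometry, group.tls, rng, n_tls,
            contact_radius_um=analysis.contact_radius_um, slide_id=slide_id,
        )
        truth.tls = planted

    cells["tile_id"] = _tile_ids(cells["x_um"], cells["y_um"]) if len(cells) else []
    intens = sample_intensities(cells["true_phenotype"], intensity_model, rng)
    cells = pd.concat([cells.reset_index(drop=True), intens], axis=1)
    return cells[CELL_COLUMNS], truth


def generate_cohort(config: CohortConfig) -> list[SlideData]:
    """Generate the full cohort; deterministic in ``config.master_seed``."""
    config.validate()
    n_total = sum(g.n_slides for g in config.groups)
    seeds = np.random.SeedSequence(config.master_seed).spawn(n_total)
    out: list[SlideData] = []
    k = 0
    for group in config.groups:
        for i in range(group.n_slides):
            rng = np.random.default_rng(seeds[k])
            k += 1
            slide_id = f"{group.name}_{i + 1:02d}"
            geometry = _make_geometry(config, rng)
            cells, truth = generate_slide(
                group, geometry, rng, config.intensity_model, config.analysis, slide_id,
                blood_cell_density_mm2=config.geometry.blood_cell_density_mm2,
            )
            out.append(SlideData(slide_id=slide_id, group=group.name, cells=cells, geometry=geometry, truth=truth))
    return out
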