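"""Slide geometry: tissue layers and excluded regions.

A slide is a rectangular strip of aortic wall in µm coordinates, origin
bottom-left, intima at the bottom, media in the middle, adventitia on top
(the v1 geometry uses horizontal layer boundaries; the curvature of a real
cross-section adds nothing to layer-stratified counting).  Excluded regions
(surgical hematoma / blood, background) are polygons; cells inside them are
dropped from every quantitative summary, mirroring the tissue-segmentation
step that excludes blood and background from analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon, box

LAYERS = ("intima", "media", "adventitia")
EXCLUDED = "excluded"


class GeometryError(ValueError):
    pass


@dataclass
class ExcludedRegion:
    label: str  # "blood" | "background"
    polygon: Polygon

    def to_dict(self) -> dict:
        return {"label": self.label, "exterior": list(map(list, self.polygon.exterior.coords))}

    @classmethod
    def from_dict(cls, d: dict) -> "ExcludedRegion":
        return cls(label=d["label"], polygon=Polygon(d["exterior"]))


@dataclass
class LayerGeometry:
    """Per-slide layer extents (µm) and excluded regions.

    Layer bands (bottom to top): intima [0, t_i), media [t_i, t_i+t_m),
    adventitia [t_i+t_m, t_i+t_m+t_a].  A cell exactly on a boundary is
    assigned to the inner (lower) layer.
    """

    slide_width_um: float
    intima_thickness_um: float
    media_thickness_um: float
    adventitia_thickness_um: float
    excluded_regions: list[ExcludedRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("slide_width_um", "intima_thickness_um", "media_thickness_um", "adventitia_thickness_um"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0, got {getattr(self, name)}")
        bounds = box(0, 0, self.slide_width_um, self.total_thickness_um)
        for reg in self.excluded_regions:
            if reg.label not in ("blood", "background"):
                raise GeometryError(f"excluded region label must be blood|background, got {reg.label!r}")
            if not bounds.contains(reg.polygon):
                raise GeometryError("excluded region lies outside slide bounds")

    # --- derived extents -------------------------------------------------
    @property
    def total_thickness_um(self) -> float:
        return self.intima_thickness_um + self.media_thickness_um + self.adventitia_thickness_um

    @property
    def intima_media_y(self) -> float:
        return self.intima_thickness_um

    @property
    def media_adventitia_y(self) -> float:
        return self.intima_thickness_um + self.media_thickness_um

    def layer_band(self, layer: str) -> tuple[float, float]:
        if layer == "intima":
            return (0.0, self.intima_media_y)
        if layer == "media":
            return (self.intima_media_y, self.media_adventitia_y)
        if layer == "adventitia":
            return (self.media_adventitia_y, self.total_thickness_um)
        raise GeometryError(f"unknown layer {layer!r}")

    def media_adventitia_boundary(self) -> LineString:
        y = self.media_adventitia_y
        return LineString([(0.0, y), (self.slide_width_um, y)])

    # --- areas -----------------------------------------------------------
    def layer_area_mm2(self, layer: str, analyzed: bool = True) -> float:
        """Band area in mm²; ``analyzed`` subtracts excluded-region overlap."""
        y0, y1 = self.layer_band(layer)
        band = box(0, y0, self.slide_width_um, y1)
        area = band.area
        if analyzed:
            for reg in self.excluded_regions:
                area -= band.intersection(reg.polygon).area
        if area <= 0:
            raise GeometryError(f"analyzed area of {layer} is not positive")
        return area / 1e6

    # --- point classification --------------------------------------------
    def assign_layer(self, x_um: float, y_um: float) -> str:
        """Layer label for one point; excluded polygons and out-of-bounds
        points map to ``excluded``.  Boundary points go to the inner layer."""
        labels = self.assign_layers(np.asarray([x_um]), np.asarray([y_um]))
        return labels[0]

    def assign_layers(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        x = np.asarray(x_um, dtype=float)
        y = np.asarray(y_um, dtype=float)
        out = np.full(x.shape, EXCLUDED, dtype=object)
        inside = (x >= 0) & (x <= self.slide_width_um) & (y >= 0) & (y <= self.total_thickness_um)
        # boundary convention: y <= upper bound of the inner layer
        out[inside & (y <= self.intima_media_y)] = "intima"
        out[inside & (y > self.intima_media_y) & (y <= self.media_adventitia_y)] = "media"
        out[inside & (y > self.media_adventitia_y)] = "adventitia"
        if self.excluded_regions:
            import shapely

            for reg in self.excluded_regions:
                hit = shapely.intersects_xy(reg.polygon, x, y)  # boundary counts as inside
                out[hit] = EXCLUDED
        return out.astype(str)

    # --- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "slide_width_um": self.slide_width_um,
            "intima_thickness_um": self.intima_thickness_um,
            "media_thickness_um": self.media_thickness_um,
            "adventitia_thickness_um": self.adventitia_thickness_um,
            "excluded_regions": [r.to_dict() for r in self.excluded_regions],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "LayerGeometry":
        return cls(
            slide_width_um=d["slide_width_um"],
            intima_thickness_um=d["intima_thickness_um"],
            media_thickness_um=d["media_thickness_um"],
            adventitia_thickness_um=d["adventitia_thickness_um"],
            excluded_regions=[ExcludedRegion.from_dict(r) for r in d.get("excluded_regions", [])],
        )

    @classmethod
    def from_json(cls, path) -> "LayerGeometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
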