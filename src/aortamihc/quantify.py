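"""Layer-stratified quantification of gated cells.

Cells are assigned to intima / media / adventitia (or excluded) by the
slide geometry; per slide and layer the module reports count, fraction of
all cells, and density (cells/mm² of analyzed area) per leaf phenotype of
each panel, plus the derived quantities the cohort comparisons run on:
the CD4/CD8 ratio (helper T over cytotoxic T, on total CD3+CD8− counts
including the memory and regulatory subsets) and fold changes between
groups computed as ratios of group medians of the per-slide fraction.

Fractions use all analyzed cells of the layer as the denominator,
including ``other`` and ``ambiguous`` cells, matching "% of all cells"
reporting; ``ambiguous`` doublets are never counted toward any phenotype.
Masked-marker phenotypes (FoxP3-dependent labels in post-mortem material)
are reported as missing, not zero.  Slides whose adventitia is flagged
non-quantifiable (dissections) are excluded from group aggregation for
that layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import LAYERS, LayerGeometry
from .panels import AMBIGUOUS, LEAF_PANEL, OTHER, PANELS, MarkerPanel, expand_phenotype


class QuantifyError(ValueError):
    pass


#: labels whose rule requires the masked marker positive
def _masked_labels(panel: MarkerPanel, markers_masked: tuple[str, ...]) -> set[str]:
    return {r.label for r in panel.rules if set(markers_masked) & r.positive}


@dataclass
class SlideSummary:
    """Tidy per-slide quantification: one row per layer x panel x phenotype."""

    slide_id: str
    group: str
    table: pd.DataFrame  # columns: layer, panel, phenotype, count, fraction, density, area_mm2
    adventitia_quantifiable: bool = True
    markers_masked: tuple[str, ...] = ()

    def _rows(self, layer: str, phenotype: str, panel: str | None) -> pd.DataFrame:
        leaves = expand_phenotype(phenotype)
        sub = self.table[(self.table["layer"] == layer) & (self.table["phenotype"].isin(leaves))]
        if panel is not None:
            return sub[sub["panel"] == panel]
        # leaf labels are unique to their panel; `other`/`ambiguous` exist in
        # both and default to the adaptive panel unless a panel is named
        keep = []
        for _, row in sub.iterrows():
            owner = LEAF_PANEL.get(row["phenotype"], "adaptive")
            keep.append(row["panel"] == owner)
        return sub[np.asarray(keep, dtype=bool)] if len(sub) else sub

    def count(self, layer: str, phenotype: str, panel: str | None = None) -> float:
        """Count for a leaf phenotype or aggregate in one layer (NaN if masked)."""
        sub = self._rows(layer, phenotype, panel)
        if sub.empty or sub["count"].isna().all():
            return np.nan  # masked label: unavailable, not zero
        return float(sub["count"].sum())

    def fraction(self, layer: str, phenotype: str, panel: str | None = None) -> float:
        sub = self._rows(layer, phenotype, panel)
        if sub.empty or sub["fraction"].isna().all():
            return np.nan
        return float(sub["fraction"].sum())

    def layer_total(self, layer: str) -> float:
        sub = self.table[self.table["layer"] == layer]
        return float(sub["total_cells"].iloc[0]) if len(sub) else 0.0


def assign_layer(cell, geometry: LayerGeometry) -> str:
    """Layer label for a single cell (mapping-like with x_um/y_um)."""
    return geometry.assign_layer(float(cell["x_um"]), float(cell["y_um"]))


def summarize_slide(
    cells: pd.DataFrame,
    geometry: LayerGeometry,
    group: str = "",
    adventitia_quantifiable: bool = True,
    markers_masked: tuple[str, ...] = (),
    panels: dict[str, MarkerPanel] | None = None,
) -> SlideSummary:
    """Per-layer composition of one gated slide.

    ``cells`` must carry ``phenotype_<panel>`` columns (see
    :func:`aortamihc.gating.gate_cells`) and µm coordinates; the layer is
    (re)derived from the geometry, and excluded-region cells are dropped
    from every count and denominator.
    """
    panels = panels or PANELS
    if len(cells) == 0:
        slide_id = ""
    else:
        slide_id = str(cells["slide_id"].iloc[0])
    for p in panels.values():
        if f"phenotype_{p.name}" not in cells.columns:
            raise QuantifyError(f"cells not gated for panel {p.name!r}")

    layer = geometry.assign_layers(cells["x_um"].to_numpy(), cells["y_um"].to_numpy()) if len(cells) else np.array([], dtype=str)
    rows = []
    for ly in LAYERS:
        in_layer = cells[layer == ly]
        area = geometry.layer_area_mm2(ly)
        total = len(in_layer)
        for p in panels.values():
            masked = _masked_labels(p, markers_masked)
            lab = in_layer[f"phenotype_{p.name}"]
            for phen in p.labels + (OTHER, AMBIGUOUS):
                if phen in masked:
                    count: float = np.nan  # unavailable, not zero
                else:
                    count = int((lab == phen).sum())
                rows.append(
                    {
                        "slide_id": slide_id,
                        "group": group,
                        "layer": ly,
                        "panel": p.name,
                        "phenotype": phen,
                        "count": count,
                        "total_cells": total,
                        "fraction": (count / total) if total > 0 else np.nan,
                        "density": count / area,
                        "area_mm2": area,
                    }
                )
    return SlideSummary(
        slide_id=slide_id,
        group=group,
        table=pd.DataFrame(rows),
        adventitia_quantifiable=adventitia_quantifiable,
        markers_masked=markers_masked,
    )


def _quantifiable(summaries: list[SlideSummary], layer: str) -> list[SlideSummary]:
    if layer == "adventitia":
        return [s for s in summaries if s.adventitia_quantifiable]
    return list(summaries)


def group_fold_change(
    summaries_a: list[SlideSummary],
    summaries_b: list[SlideSummary],
    phenotype: str,
    layer: str,
    measure: str = "fraction",
) -> float:
    """Ratio (B over A) of group medians of the per-slide measure.

    ``measure`` is ``fraction`` (of all cells; the reported basis) or
    ``density``.  Non-quantifiable slides are excluded; a zero denominator
    median yields ``inf`` with a warning.
    """
    if measure not in ("fraction", "density"):
        raise QuantifyError(f"measure must be fraction|density, got {measure!r}")

    def med(summaries: list[SlideSummary]) -> float:
        vals = []
        for s in _quantifiable(summaries, layer):
            v = s.fraction(layer, phenotype) if measure == "fraction" else (
                s.count(layer, phenotype) / s.table[s.table["layer"] == layer]["area_mm2"].iloc[0]
            )
            if not np.isnan(v):
                vals.append(v)
        if not vals:
            raise QuantifyError(f"no quantifiable slides for {phenotype!r} in {layer!r}")
        return float(np.median(vals))

    a, b = med(summaries_a), med(summaries_b)
    if a == 0:
        warnings.warn(f"denominator group median is 0 for {phenotype!r} in {layer!r}; fold change infinite")
        return np.inf
    return b / a


def cd4_cd8_ratio(summary: SlideSummary, layer: str) -> float:
    """Helper-T (CD3+CD8−, all subsets) over cytotoxic-T (CD3+CD8+) count."""
    helper = summary.count(layer, "helper_t_total")
    cytotoxic = summary.count(layer, "cytotoxic_t")
    if np.isnan(helper) or np.isnan(cytotoxic):
        return np.nan
    if cytotoxic == 0:
        warnings.warn(f"no cytotoxic T cells in {layer!r} of {summary.slide_id}; CD4/CD8 undefined")
        return np.nan
    return helper / cytotoxic


def group_median_fraction(summaries: list[SlideSummary], phenotype: str, layer: str) -> float:
    """Group median of the per-slide fraction-of-all-cells."""
    vals = [
        s.fraction(layer, phenotype)
        for s in _quantifiable(summaries, layer)
        if not np.isnan(s.fraction(layer, phenotype))
    ]
    if not vals:
        return np.nan
    return float(np.median(vals))


def group_median_cd4_cd8(summaries: list[SlideSummary], layer: str) -> float:
    vals = [cd4_cd8_ratio(s, layer) for s in _quantifiable(summaries, layer)]
    vals = [v for v in vals if not np.isnan(v)]
    if not vals:
        return np.nan
    return float(np.median(vals))


def pooled_fraction(
    gated_slides: list[tuple[pd.DataFrame, LayerGeometry]],
    layer: str,
    leaves: tuple[str, ...],
    panels: dict[str, MarkerPanel] | None = None,
) -> float:
    """Fraction of pooled cells of ``layer`` (across slides) whose leaf
    label in *any* panel is one of ``leaves``.

    Used for pooled intima statistics (combined immune fraction, M1-like
    fraction) where the slides are pooled before dividing.
    """
    panels = panels or PANELS
    num = 0
    den = 0
    for cells, geometry in gated_slides:
        lay = geometry.assign_layers(cells["x_um"].to_numpy(), cells["y_um"].to_numpy())
        sub = cells[lay == layer]
        den += len(sub)
        hit = np.zeros(len(sub), dtype=bool)
        for p in panels.values():
            hit |= sub[f"phenotype_{p.name}"].isin(leaves).to_numpy()
        num += int(hit.sum())
    return num / den if den else np.nan
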