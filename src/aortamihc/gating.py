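"""Flow-style phenotype gating of segmented cells.

Bimodal markers are binarized against fixed per-marker thresholds (the
stand-in for manual flow-style gates, which the source workflow set by
hand).  The gradual markers CD45RO and MMP9 have no separated positive
mode, so their thresholds are computed per slide set as a high quantile of
the marker's intensity in the *negative-control* population — cells
negative for every lineage marker of the panel (non-immune cells).  A cell
is positive iff its intensity is strictly greater than the threshold
(equality is negative; deterministic tie-break).

Leaf labels are assigned by ordered most-specific-first rules; cells
positive for mutually exclusive lineage markers (CD3 & CD20, CD68 & CD15)
are segmentation doublets, labeled ``ambiguous`` and excluded from
phenotype counts; cells matching no rule are ``other``.  Masked markers
(e.g. FoxP3 in post-mortem material) are treated as unavailable: rules
requiring them positive are skipped and they are ignored as negativity
requirements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisParams, IntensityModel
from .panels import AMBIGUOUS, OTHER, MarkerPanel, PhenotypeRule


class GatingError(ValueError):
    pass


def compute_gradual_threshold(
    cells: pd.DataFrame,
    marker: str,
    negative_mask: np.ndarray,
    quantile: float,
    min_negative: int = 50,
) -> float:
    """Quantile threshold for a gradual marker from its negative-control cells.

    ``negative_mask`` selects the negative-control population (all lineage
    markers negative).  Raises :class:`GatingError` if that population is
    smaller than ``min_negative``; callers should then fall back to the
    fixed threshold from the configuration.
    """
    if marker not in cells.columns:
        raise GatingError(f"marker {marker!r} not in cell table")
    neg = cells.loc[np.asarray(negative_mask, dtype=bool), marker].to_numpy()
    if len(neg) < min_negative:
        raise GatingError(
            f"only {len(neg)} negative-control cells for {marker!r} (need >= {min_negative}); "
            "use the fixed fallback threshold from the configuration"
        )
    return float(np.quantile(neg, quantile, method="inverted_cdf"))  # nearest rank


def binarize_markers(
    cells: pd.DataFrame, thresholds: dict[str, float], markers: tuple[str, ...]
) -> pd.DataFrame:
    """Boolean positivity per marker: intensity strictly above the threshold."""
    out = {}
    for m in markers:
        if m not in cells.columns:
            raise GatingError(f"marker {m!r} missing from cell table")
        if m not in thresholds:
            raise GatingError(f"no threshold for marker {m!r}")
        vals = cells[m]
        if vals.isna().any():
            raise GatingError(f"marker {m!r} has missing values")
        out[m] = vals.to_numpy() > thresholds[m]
    return pd.DataFrame(out, index=cells.index)


def panel_thresholds(
    cells: pd.DataFrame,
    panel: MarkerPanel,
    intensity_model: IntensityModel,
    analysis: AnalysisParams,
) -> dict[str, float]:
    """All thresholds for one panel: fixed for bimodal markers, negative-
    control quantile for gradual markers (fixed fallback when the control
    population is too small)."""
    thresholds = {
        m: intensity_model.fixed_thresholds[m]
        for m in panel.markers
        if m not in panel.gradual_markers
    }
    lineage = [m for m in panel.negative_control_markers]
    lineage_pos = binarize_markers(cells, thresholds, tuple(lineage))
    negative_mask = ~lineage_pos.any(axis=1).to_numpy()
    for m in panel.gradual_markers:
        try:
            thresholds[m] = compute_gradual_threshold(
                cells, m, negative_mask, analysis.gradual_quantile, analysis.min_negative_control
            )
        except GatingError:
            thresholds[m] = intensity_model.fallback_thresholds[m]
    return thresholds


def _effective_rules(panel: MarkerPanel, masked: tuple[str, ...]) -> list[PhenotypeRule]:
    rules = []
    for rule in panel.rules:
        if set(masked) & rule.positive:
            continue  # rule requires an unavailable marker
        rules.append(
            PhenotypeRule(rule.label, rule.positive, rule.negative - frozenset(masked))
        )
    return rules


def gate_panel(
    cells: pd.DataFrame,
    panel: MarkerPanel,
    thresholds: dict[str, float],
    markers_masked: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Assign one leaf label per cell for the panel.

    Returns a DataFrame with the per-marker positivity booleans and a
    ``phenotype_<panel>`` column.
    """
    usable = tuple(m for m in panel.markers if m not in markers_masked)
    pos = binarize_markers(cells, thresholds, usable)
    for m in markers_masked:
        if m in panel.markers:
            pos[m] = False  # unavailable: treated as not callable positive
    labels = np.full(len(cells), OTHER, dtype=object)

    ambiguous = np.zeros(len(cells), dtype=bool)
    for a, b in panel.lineage_exclusive:
        if a in usable and b in usable:
            ambiguous |= (pos[a] & pos[b]).to_numpy()

    unassigned = ~ambiguous
    for rule in _effective_rules(panel, markers_masked):
        m = unassigned.copy()
        for mk in rule.positive:
            m &= pos[mk].to_numpy()
        for mk in rule.negative:
            m &= ~pos[mk].to_numpy()
        labels[m] = rule.label
        unassigned &= ~m
    labels[ambiguous] = AMBIGUOUS

    out = pos.add_suffix("_pos")  # intensity columns keep the bare marker name
    out[f"phenotype_{panel.name}"] = labels
    return out


def gate_cells(
    cells: pd.DataFrame,
    panels: dict[str, MarkerPanel],
    intensity_model: IntensityModel,
    analysis: AnalysisParams,
    markers_masked: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Gate every panel and append positivity booleans + per-panel labels."""
    extra = []
    for panel in panels.values():
        thresholds = panel_thresholds(cells, panel, intensity_model, analysis)
        extra.append(gate_panel(cells, panel, thresholds, markers_masked))
    return pd.concat([cells.reset_index(drop=True)] + [e.reset_index(drop=True) for e in extra], axis=1)
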