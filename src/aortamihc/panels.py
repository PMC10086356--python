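"""Marker panels and phenotype gating rules.

Two eight-color panels are modeled, mirroring the study design for the
aortic wall: an *adaptive* panel (CD3, CD8, CD20, CD1c, FoxP3, CD45RO)
resolving T-cell subsets, B cells and type-2 classical dendritic cells,
and an *innate* panel (CD68, CD206, CD15, CD31, MMP9, GM-CSF) resolving
macrophage polarization, neutrophils, endothelium and MMP9 expression.

A phenotype rule is a conjunction of required-positive and
required-negative markers.  Rules are ordered most-specific-first so that
every cell receives exactly one leaf label per panel (``other`` if no rule
matches, ``ambiguous`` if it is positive for mutually exclusive lineage
markers — a segmentation-doublet artifact).  The published rule table
leaves some pairs of rules overlapping (e.g. a CD31+ MMP9+ cell); the
ordered rules with explicit required-negatives below are the disjoint
closure of that table.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PhenotypeRule:
    """One gating rule: ``label`` requires all of ``positive`` and none of ``negative``."""

    label: str
    positive: frozenset[str]
    negative: frozenset[str] = frozenset()

    def matches(self, positivity: dict[str, bool]) -> bool:
        return all(positivity.get(m, False) for m in self.positive) and not any(
            positivity.get(m, False) for m in self.negative
        )


@dataclass(frozen=True)
class MarkerPanel:
    """A panel: its markers, ordered leaf rules, and marker semantics.

    ``gradual_markers`` have continuous expression with no separated
    positive mode and are thresholded against a negative-control cell
    population; all other markers are bimodal and use fixed thresholds.
    ``lineage_exclusive`` pairs mark segmentation doublets ("ambiguous").
    ``negative_control_markers`` define the non-immune control population
    (all of them negative) used for gradual-marker thresholding.
    """

    name: str
    markers: tuple[str, ...]
    rules: tuple[PhenotypeRule, ...]
    gradual_markers: frozenset[str] = frozenset()
    lineage_exclusive: tuple[tuple[str, str], ...] = ()
    negative_control_markers: frozenset[str] = frozenset()
    parents: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.markers)
        labels = [r.label for r in self.rules]
        if len(labels) != len(set(labels)):
            raise ValueError(f"panel {self.name!r}: duplicate rule labels")
        for rule in self.rules:
            unknown = (rule.positive | rule.negative) - known
            if unknown:
                raise ValueError(
                    f"panel {self.name!r}: rule {rule.label!r} uses unknown markers {sorted(unknown)}"
                )
        if not self.gradual_markers <= known:
            raise ValueError(f"panel {self.name!r}: gradual markers outside panel")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.rules)


OTHER = "other"
AMBIGUOUS = "ambiguous"

#: leaf phenotype -> markers it is truly positive for (used by the generator)
PHENOTYPE_MARKERS: dict[str, tuple[str, ...]] = {
    "helper_t": ("CD3",),
    "memory_helper_t": ("CD3", "CD45RO"),
    "regulatory_t": ("CD3", "FoxP3"),
    "cytotoxic_t": ("CD3", "CD8"),
    "b_cell": ("CD20",),
    "cdc2": ("CD1c",),
    "m1_macrophage": ("CD68",),
    "m2_macrophage": ("CD68", "CD206"),
    "neutrophil": ("CD15",),
    "endothelium": ("CD31",),
    "mmp9_cell": ("MMP9",),
    "stromal": (),
}

ADAPTIVE_PANEL = MarkerPanel(
    name="adaptive",
    markers=("CD3", "CD8", "CD20", "CD1c", "FoxP3", "CD45RO"),
    rules=(
        PhenotypeRule("regulatory_t", frozenset({"CD3", "FoxP3"}), frozenset({"CD8", "CD20"})),
        PhenotypeRule(
            "memory_helper_t", frozenset({"CD3", "CD45RO"}), frozenset({"CD8", "CD20", "FoxP3"})
        ),
        PhenotypeRule("cytotoxic_t", frozenset({"CD3", "CD8"}), frozenset({"CD20"})),
        PhenotypeRule("helper_t", frozenset({"CD3"}), frozenset({"CD8", "CD20"})),
        PhenotypeRule("b_cell", frozenset({"CD20"}), frozenset({"CD3"})),
        PhenotypeRule("cdc2", frozenset({"CD1c"}), frozenset({"CD3", "CD20"})),
    ),
    gradual_markers=frozenset({"CD45RO"}),
    lineage_exclusive=(("CD3", "CD20"),),
    negative_control_markers=frozenset({"CD3", "CD20", "CD1c"}),
    parents={
        "regulatory_t": "helper_t_total",
        "memory_helper_t": "helper_t_total",
        "helper_t": "helper_t_total",
    },
)

INNATE_PANEL = MarkerPanel(
    name="innate",
    markers=("CD68", "CD206", "CD15", "CD31", "MMP9", "GMCSF"),
    rules=(
        PhenotypeRule("m2_macrophage", frozenset({"CD68", "CD206"}), frozenset({"CD15"})),
        PhenotypeRule("m1_macrophage", frozenset({"CD68"}), frozenset({"CD206", "CD15"})),
        PhenotypeRule("neutrophil", frozenset({"CD15"}), frozenset({"CD68"})),
        PhenotypeRule("endothelium", frozenset({"CD31"}), frozenset({"CD68", "CD15"})),
        PhenotypeRule("mmp9_cell", frozenset({"MMP9"}), frozenset({"CD68", "CD15", "CD31"})),
    ),
    gradual_markers=frozenset({"MMP9"}),
    lineage_exclusive=(("CD68", "CD15"),),
    negative_control_markers=frozenset({"CD68", "CD15", "CD31"}),
    parents={"m1_macrophage": "macrophage", "m2_macrophage": "macrophage"},
)

PANELS: dict[str, MarkerPanel] = {"adaptive": ADAPTIVE_PANEL, "innate": INNATE_PANEL}

ALL_MARKERS: tuple[str, ...] = ADAPTIVE_PANEL.markers + INNATE_PANEL.markers

# Aggregate phenotype groups used for reporting.  "lymphocyte" (CD3+ or CD20+)
# and "immune" are reporting conveniences; the rule table itself only defines
# leaf labels.
T_CELL_LEAVES = ("helper_t", "memory_helper_t", "regulatory_t", "cytotoxic_t")
HELPER_T_LEAVES = ("helper_t", "memory_helper_t", "regulatory_t")
LYMPHOCYTE_LEAVES = T_CELL_LEAVES + ("b_cell",)
MACROPHAGE_LEAVES = ("m1_macrophage", "m2_macrophage")
#: immune leaves per panel (endothelium and MMP9+ non-immune cells excluded)
IMMUNE_LEAVES_ADAPTIVE = LYMPHOCYTE_LEAVES + ("cdc2",)
IMMUNE_LEAVES_INNATE = MACROPHAGE_LEAVES + ("neutrophil",)

AGGREGATES: dict[str, tuple[str, ...]] = {
    "t_cell": T_CELL_LEAVES,
    "helper_t_total": HELPER_T_LEAVES,
    "lymphocyte": LYMPHOCYTE_LEAVES,
    "macrophage": MACROPHAGE_LEAVES,
    "immune": IMMUNE_LEAVES_ADAPTIVE + IMMUNE_LEAVES_INNATE,
}


#: leaf label -> the panel that defines it
LEAF_PANEL: dict[str, str] = {
    **{r.label: "adaptive" for r in ADAPTIVE_PANEL.rules},
    **{r.label: "innate" for r in INNATE_PANEL.rules},
}


def expand_phenotype(name: str) -> tuple[str, ...]:
    """Resolve a phenotype or aggregate name to its leaf labels."""
    if name in AGGREGATES:
        return AGGREGATES[name]
    if name in PHENOTYPE_MARKERS or name in (OTHER, AMBIGUOUS):
        return (name,)
    raise KeyError(f"unknown phenotype {name!r}")
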