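import numpy as np
import pandas as pd
import pytest

from aortamihc.config import default_intensity_model
from aortamihc.gating import (
    GatingError,
    binarize_markers,
    compute_gradual_threshold,
    gate_cells,
    gate_panel,
    panel_thresholds,
)
from aortamihc.panels import (
    ADAPTIVE_PANEL,
    AMBIGUOUS,
    INNATE_PANEL,
    OTHER,
    PANELS,
    MarkerPanel,
    PhenotypeRule,
)

HI, LO = 100.0, 0.1  # far above / below every default threshold


def _cells(rows: list[dict], panel: MarkerPanel) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    for m in panel.markers:
        if m not in df.columns:
            df[m] = LO
    return df


def _gate(rows, panel, masked=()):
    cells = _cells(rows, panel)
    thresholds = {m: 7.0 for m in panel.markers}
    return gate_panel(cells, panel, thresholds, markers_masked=masked)[
        f"phenotype_{panel.name}"
    ].tolist()


class TestPanelRules:
    """The published rule table, exercised cell by cell."""

    @pytest.mark.parametrize(
        "markers,expected",
        [
            ({"CD3": HI}, "helper_t"),
            ({"CD3": HI, "CD8": HI}, "cytotoxic_t"),
            ({"CD3": HI, "FoxP3": HI}, "regulatory_t"),
            ({"CD3": HI, "CD45RO": HI}, "memory_helper_t"),
            ({"CD3": HI, "CD8": HI, "CD45RO": HI}, "cytotoxic_t"),  # memory requires CD8-
            ({"CD20": HI}, "b_cell"),
            ({"CD1c": HI}, "cdc2"),
            ({"CD1c": HI, "CD20": HI}, "b_cell"),  # cDC2 requires CD20-; falls through
            ({}, OTHER),
            ({"CD45RO": HI}, OTHER),  # gradual marker alone is no lineage
            ({"CD3": HI, "CD20": HI}, AMBIGUOUS),  # exclusive lineage doublet
        ],
    )
    def test_adaptive_rules(self, markers, expected):
        assert _gate([markers], ADAPTIVE_PANEL) == [expected]

    @pytest.mark.parametrize(
        "markers,expected",
        [
            ({"CD68": HI}, "m1_macrophage"),
            ({"CD68": HI, "CD206": HI}, "m2_macrophage"),
            ({"CD15": HI}, "neutrophil"),
            ({"CD31": HI}, "endothelium"),
            ({"MMP9": HI}, "mmp9_cell"),
            ({"CD31": HI, "MMP9": HI}, "endothelium"),  # disjoint closure
            ({"CD68": HI, "CD15": HI}, AMBIGUOUS),
            ({}, OTHER),
        ],
    )
    def test_innate_rules(self, markers, expected):
        assert _gate([markers], INNATE_PANEL) == [expected]

    def test_masked_marker_skips_rules_requiring_it(self):
        # FoxP3 masked (post-mortem): the FoxP3+ rule is unavailable and the
        # cell falls through to the next most specific match
        cell = {"CD3": HI, "FoxP3": HI}
        assert _gate([cell], ADAPTIVE_PANEL, masked=("FoxP3",)) == ["helper_t"]

    def test_partition_sums_to_total(self, gated_dilated_slide):
        gated, _, _ = gated_dilated_slide
        for panel in PANELS.values():
            labels = gated[f"phenotype_{panel.name}"]
            valid = set(panel.labels) | {OTHER, AMBIGUOUS}
            assert labels.isin(valid).all()
            assert labels.value_counts().sum() == len(gated)


class TestBinarize:
    def test_equality_is_negative(self):
        cells = pd.DataFrame({"CD3": [7.0, 7.0001, 0.0]})
        pos = binarize_markers(cells, {"CD3": 7.0}, ("CD3",))
        assert pos["CD3"].tolist() == [False, True, False]

    def test_threshold_minus_inf_makes_all_positive(self):
        cells = pd.DataFrame({"CD3": [0.0, 1e-12]})
        pos = binarize_markers(cells, {"CD3": -np.inf}, ("CD3",))
        assert pos["CD3"].all()

    def test_missing_marker_value_errors(self):
        cells = pd.DataFrame({"CD3": [1.0, np.nan]})
        with pytest.raises(GatingError, match="missing"):
            binarize_markers(cells, {"CD3": 7.0}, ("CD3",))

    def test_missing_threshold_errors(self):
        cells = pd.DataFrame({"CD3": [1.0]})
        with pytest.raises(GatingError, match="threshold"):
            binarize_markers(cells, {}, ("CD3",))


class TestGradualThreshold:
    def test_nearest_rank_quantile(self):
        cells = pd.DataFrame({"CD45RO": np.arange(1.0, 101.0)})
        thr = compute_gradual_threshold(cells, "CD45RO", np.ones(100, bool), 0.95)
        assert thr == 95.0

    def test_identical_negatives_give_their_value(self):
        cells = pd.DataFrame({"CD45RO": np.full(60, 3.5)})
        thr = compute_gradual_threshold(cells, "CD45RO", np.ones(60, bool), 0.995)
        assert thr == 3.5
        # any intensity strictly above is then positive
        pos = binarize_markers(pd.DataFrame({"CD45RO": [3.5, 3.6]}), {"CD45RO": thr}, ("CD45RO",))
        assert pos["CD45RO"].tolist() == [False, True]

    def test_too_few_negatives_instructs_fallback(self):
        cells = pd.DataFrame({"CD45RO": np.arange(10.0)})
        with pytest.raises(GatingError, match="fallback"):
            compute_gradual_threshold(cells, "CD45RO", np.ones(10, bool), 0.995)

    def test_false_positive_rate_bounded_on_synthetic_slide(self, config, gated_dilated_slide):
        """At quantile q, at most 1-q (+1%) of true CD45RO- cells are called positive."""
        gated, _, _ = gated_dilated_slide
        truly_negative = ~gated["true_phenotype"].isin(["memory_helper_t"])
        fp = gated.loc[truly_negative, "CD45RO_pos"].mean()
        assert fp <= (1 - config.analysis.gradual_quantile) + 0.01


class TestGatingAccuracy:
    def test_per_phenotype_accuracy(self, gated_dilated_slide):
        """With well-separated bimodal markers, gating recovers the true
        phenotype for >= 99.5% of cells of every bimodal-defined phenotype."""
        gated, _, _ = gated_dilated_slide
        expected_adaptive = {
            "helper_t": "helper_t",
            "regulatory_t": "regulatory_t",
            "cytotoxic_t": "cytotoxic_t",
            "b_cell": "b_cell",
            "cdc2": "cdc2",
            "m1_macrophage": OTHER,
            "stromal": OTHER,
        }
        for true, want in expected_adaptive.items():
            sub = gated[gated["true_phenotype"] == true]
            if len(sub) < 50:
                continue
            acc = (sub["phenotype_adaptive"] == want).mean()
            assert acc >= 0.995, f"{true}: {acc}"
        expected_innate = {
            "m1_macrophage": "m1_macrophage",
            "m2_macrophage": "m2_macrophage",
            "neutrophil": "neutrophil",
            "endothelium": "endothelium",
            "helper_t": OTHER,
        }
        for true, want in expected_innate.items():
            sub = gated[gated["true_phenotype"] == true]
            if len(sub) < 50:
                continue
            acc = (sub["phenotype_innate"] == want).mean()
            assert acc >= 0.995, f"{true}: {acc}"

    def test_hierarchy_consistency(self, gated_dilated_slide):
        """helper-T total >= its subsets; T = helper total + cytotoxic."""
        gated, _, _ = gated_dilated_slide
        counts = gated["phenotype_adaptive"].value_counts()
        helper_total = sum(counts.get(k, 0) for k in ("helper_t", "memory_helper_t", "regulatory_t"))
        assert helper_total >= counts.get("regulatory_t", 0) + counts.get("memory_helper_t", 0)
        t_total = helper_total + counts.get("cytotoxic_t", 0)
        leaves_t = gated["phenotype_adaptive"].isin(
            ["helper_t", "memory_helper_t", "regulatory_t", "cytotoxic_t"]
        ).sum()
        assert t_total == leaves_t


class TestPanelValidation:
    def test_rule_with_unknown_marker_rejected(self):
        with pytest.raises(ValueError, match="unknown markers"):
            MarkerPanel(
                name="bad",
                markers=("CD3",),
                rules=(PhenotypeRule("x", frozenset({"CD99"})),),
            )

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            MarkerPanel(
                name="bad",
                markers=("CD3", "CD8"),
                rules=(
                    PhenotypeRule("x", frozenset({"CD3"})),
                    PhenotypeRule("x", frozenset({"CD8"})),
                ),
            )


def test_gate_cells_appends_both_panels(config, dilated_slide):
    cells, _, _ = dilated_slide
    gated = gate_cells(cells.head(200), PANELS, config.intensity_model, config.analysis)
    assert "phenotype_adaptive" in gated and "phenotype_innate" in gated
    assert "CD3_pos" in gated and "MMP9_pos" in gated
    assert len(gated) == 200


def test_panel_thresholds_fall_back_when_controls_scarce(config):
    """A tiny slide of pure lymphocytes has no negative-control population;
    gradual markers then use the configured fallback threshold."""
    model = default_intensity_model()
    rng = np.random.default_rng(0)
    n = 60
    cells = pd.DataFrame({m: rng.lognormal(0.4, 0.4, n) for m in ADAPTIVE_PANEL.markers})
    cells["CD3"] = 100.0  # everything is a T cell
    thr = panel_thresholds(cells, ADAPTIVE_PANEL, model, config.analysis)
    assert thr["CD45RO"] == model.fallback_thresholds["CD45RO"]
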