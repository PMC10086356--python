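import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from aortamihc.config import (
    AnalysisParams,
    CohortConfig,
    ConfigError,
    GeometryParams,
    GroupParams,
    TLSParams,
    default_cohort_config,
    default_intensity_model,
)
from aortamihc.geometry import GeometryError, LayerGeometry
from aortamihc.simulate import (
    _make_geometry,
    generate_cohort,
    generate_slide,
    place_tls,
    sample_intensities,
)


def _sparse_config(adv_b_fraction=0.02, n_slides=1, tls=None, seed=0):
    """A light one-group cohort: B cells in the adventitia only."""
    group = GroupParams(
        name="g",
        n_slides=n_slides,
        layer_density={"adventitia": 200.0},
        composition={"adventitia": {"b_cell": adv_b_fraction, "helper_t": 0.05}},
        tls=tls,
    )
    return CohortConfig(
        groups=(group,),
        geometry=GeometryParams(slide_width_um=4000.0, n_blood_regions=0),
        intensity_model=default_intensity_model(),
        analysis=AnalysisParams(),
        master_seed=seed,
    )


class TestCohortGeneration:
    def test_zero_slides_gives_empty_cohort(self):
        cfg = _sparse_config(n_slides=0)
        assert generate_cohort(cfg) == []

    def test_slide_counts_match_config(self):
        cfg = _sparse_config(n_slides=3)
        cohort = generate_cohort(cfg)
        assert len(cohort) == 3
        assert {s.group for s in cohort} == {"g"}

    def test_seed_determinism(self):
        cfg = _sparse_config(n_slides=2, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for sa, sb in zip(a, b):
            pd.testing.assert_frame_equal(sa.cells, sb.cells)
            assert sa.geometry.to_dict() == sb.geometry.to_dict()

    def test_different_seeds_differ(self):
        a = generate_cohort(_sparse_config(seed=1))
        b = generate_cohort(_sparse_config(seed=2))
        assert not a[0].cells["x_um"].equals(b[0].cells["x_um"])

    def test_poisson_counts(self):
        """B-cell count per slide ~ Poisson(density x area): empirical mean
        over 50 slides within 3 SE, and dispersion consistent with Poisson."""
        cfg = _sparse_config(adv_b_fraction=0.5, n_slides=50, seed=3)
        cohort = generate_cohort(cfg)
        counts = np.array([(s.cells["true_phenotype"] == "b_cell").sum() for s in cohort])
        area = cohort[0].geometry.layer_area_mm2("adventitia")
        lam = 200.0 * 0.5 * area
        se = np.sqrt(lam / 50)
        assert abs(counts.mean() - lam) <= 3 * se
        # chi-square dispersion index test, alpha = 0.01
        disp = (50 - 1) * counts.var(ddof=1) / counts.mean()
        lo, hi = sps.chi2.ppf([0.005, 0.995], df=49)
        assert lo < disp < hi


class TestSlideGeneration:
    def test_zero_density_empty_table(self):
        cfg = _sparse_config(adv_b_fraction=0.0)
        group = dataclasses.replace(cfg.groups[0], composition={"adventitia": {}}, layer_density={})
        rng = np.random.default_rng(0)
        geom = _make_geometry(cfg, rng)
        cells, truth = generate_slide(group, geom, rng, cfg.intensity_model, cfg.analysis)
        assert len(cells) == 0 and truth.tls == []

    def test_single_layer_density_confines_cells(self):
        cfg = _sparse_config()
        rng = np.random.default_rng(0)
        geom = _make_geometry(cfg, rng)
        cells, _ = generate_slide(cfg.groups[0], geom, rng, cfg.intensity_model, cfg.analysis)
        y0, y1 = geom.layer_band("adventitia")
        assert (cells["y_um"] > y0).all() and (cells["y_um"] <= y1).all()
        assert (cells["layer"] == "adventitia").all()

    def test_conservation_of_counts(self, dilated_slide):
        """Total cells = layer cells + excluded-region cells (+ relocated
        TLS members, who keep their adventitia label)."""
        cells, geometry, truth = dilated_slide
        by_layer = cells["layer"].value_counts()
        assert by_layer.sum() == len(cells)
        assert set(by_layer.index) <= {"intima", "media", "adventitia", "excluded"}
        member_ids = {m for t in truth.tls for m in t.member_ids}
        assert member_ids <= set(cells["cell_id"])

    def test_blood_cells_confined_to_excluded_regions(self, dilated_slide):
        cells, geometry, _ = dilated_slide
        blood = cells[cells["layer"] == "excluded"]
        assert len(blood) > 0
        relabel = geometry.assign_layers(blood["x_um"].to_numpy(), blood["y_um"].to_numpy())
        assert (relabel == "excluded").all()


class TestPlaceTLS:
    def _base(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        geom = LayerGeometry(4000, 150, 1200, 800)
        y0, y1 = geom.layer_band("adventitia")
        cells = pd.DataFrame(
            {
                "cell_id": [f"s_c{i:05d}" for i in range(n)],
                "slide_id": "s",
                "x_um": rng.uniform(0, 4000, n),
                "y_um": rng.uniform(y0, y1, n),
                "true_phenotype": ["b_cell"] * (n // 2) + ["helper_t"] * (n - n // 2),
                "layer": "adventitia",
            }
        )
        return cells, geom, rng

    def test_zero_count_unchanged(self):
        cells, geom, rng = self._base()
        out, planted = place_tls(cells, geom, TLSParams(), rng, n_tls=0)
        pd.testing.assert_frame_equal(out, cells)
        assert planted == []

    def test_planted_centroid_offset(self):
        """With a degenerate offset distribution at 242 µm, the planted
        center sits 242 µm above the media/adventitia boundary."""
        cells, geom, rng = self._base()
        params = TLSParams(offset_mean_um=242.0, offset_sd_um=0.0)
        out, planted = place_tls(cells, geom, params, rng, n_tls=1)
        assert len(planted) == 1
        t = planted[0]
        assert t.center_y_um - geom.media_adventitia_y == pytest.approx(242.0)
        # member centroid is close to the sampled center
        members = out[out["cell_id"].isin(t.member_ids)]
        assert members["y_um"].mean() - geom.media_adventitia_y == pytest.approx(242.0, abs=5)

    def test_relocation_preserves_composition(self):
        cells, geom, rng = self._base()
        before = cells["true_phenotype"].value_counts()
        out, planted = place_tls(cells, geom, TLSParams(), rng, n_tls=1)
        after = out["true_phenotype"].value_counts()
        pd.testing.assert_series_equal(before, after)

    def test_members_mutually_touching(self):
        """Every planted TLS is one connected component at the contact radius."""
        import networkx as nx
        from scipy.spatial import cKDTree

        cells, geom, rng = self._base()
        out, planted = place_tls(cells, geom, TLSParams(), rng, n_tls=2, contact_radius_um=12.0)
        for t in planted:
            xy = out.set_index("cell_id").loc[list(t.member_ids), ["x_um", "y_um"]].to_numpy()
            g = nx.Graph()
            g.add_nodes_from(range(len(xy)))
            g.add_edges_from(cKDTree(xy).query_pairs(12.0))
            assert nx.number_connected_components(g) == 1

    def test_too_large_tls_raises(self):
        cells, geom, rng = self._base()
        params = TLSParams(n_b=40, n_t=110, offset_mean_um=5000.0, offset_sd_um=1.0, max_tries=5)
        with pytest.raises(GeometryError):
            place_tls(cells, geom, params, rng, n_tls=1)

    def test_spacing_wider_than_contact_radius_rejected(self):
        cells, geom, rng = self._base()
        params = TLSParams(t_spacing_um=20.0)
        with pytest.raises(ValueError, match="contact radius"):
            place_tls(cells, geom, params, rng, n_tls=1, contact_radius_um=12.0)


class TestIntensities:
    def test_phenotype_determines_positive_markers(self):
        model = default_intensity_model()
        rng = np.random.default_rng(0)
        df = sample_intensities(["helper_t"] * 500, model, rng)
        # CD3 from the positive distribution, CD8/CD20/CD1c from the negative
        assert df["CD3"].median() > 10 * df["CD8"].median()
        assert df["CD20"].median() < 7.0
        assert df["CD1c"].median() < 7.0

    def test_zero_variance_degenerate(self):
        model = default_intensity_model()
        params = {
            m: dataclasses.replace(p, neg_sigma=0.0, pos_sigma=0.0)
            for m, p in model.params.items()
        }
        model = dataclasses.replace(model, params=params)
        rng = np.random.default_rng(0)
        df = sample_intensities(["b_cell"] * 10, model, rng)
        assert df["CD20"].nunique() == 1
        assert df["CD3"].nunique() == 1

    def test_unknown_phenotype_errors(self):
        with pytest.raises(ValueError, match="unknown phenotypes"):
            sample_intensities(["martian"], default_intensity_model(), np.random.default_rng(0))

    def test_gradual_marker_quantile_bound(self):
        """By the log-normal closed form, the 99.5th percentile of the
        negative CD45RO distribution misclassifies <= 0.5% of true negatives."""
        model = default_intensity_model()
        p = model.params["CD45RO"]
        thr = float(np.exp(p.neg_mu + sps.norm.ppf(0.995) * p.neg_sigma))
        rng = np.random.default_rng(1)
        negatives = rng.lognormal(p.neg_mu, p.neg_sigma, 200_000)
        assert (negatives > thr).mean() <= 0.005 + 0.001


class TestConfigValidation:
    def test_negative_density_names_field(self):
        cfg = _sparse_config()
        bad = dataclasses.replace(cfg.groups[0], layer_density={"adventitia": -1.0})
        with pytest.raises(ConfigError, match="layer_density"):
            dataclasses.replace(cfg, groups=(bad,)).validate()

    def test_prevalence_out_of_range_names_field(self):
        cfg = _sparse_config()
        bad = dataclasses.replace(cfg.groups[0], tls=TLSParams(prevalence=1.5))
        with pytest.raises(ConfigError, match="prevalence"):
            dataclasses.replace(cfg, groups=(bad,)).validate()

    def test_fraction_sum_above_one_rejected(self):
        cfg = _sparse_config()
        bad = dataclasses.replace(cfg.groups[0], composition={"adventitia": {"b_cell": 0.7, "helper_t": 0.4}})
        with pytest.raises(ConfigError, match="sum"):
            dataclasses.replace(cfg, groups=(bad,)).validate()

    def test_default_config_validates(self):
        default_cohort_config().validate()
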