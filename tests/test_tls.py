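import networkx as nx
import numpy as np
import pandas as pd
import pytest

from aortamihc.config import AnalysisParams, TLSParams
from aortamihc.geometry import LayerGeometry
from aortamihc.simulate import place_tls, tls_template
from aortamihc.tls import (
    TLSRecord,
    build_contact_graph,
    classify_tls,
    detect_tls,
    find_lymphoid_infiltrates,
    tls_group_stats,
    tls_media_distance,
)

ANALYSIS = AnalysisParams()
GEOM = LayerGeometry(4000, 150, 1200, 800)


def _lymph(xy, labels, slide="s"):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "cell_id": [f"{slide}_c{i:04d}" for i in range(len(xy))],
            "slide_id": slide,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "phenotype_adaptive": labels,
        }
    )


class TestContactGraph:
    def test_close_pair_has_edge(self):
        cells = _lymph([(0, 0), (3, 4)], ["helper_t", "b_cell"])  # 5 um apart
        g = build_contact_graph(cells, 12.0)
        assert g.number_of_edges() == 1

    def test_boundary_pair_within_radius_counts(self):
        cells = _lymph([(0, 0), (12.0, 0)], ["helper_t", "b_cell"])
        assert build_contact_graph(cells, 12.0).number_of_edges() == 1

    def test_pair_beyond_radius_has_no_edge(self):
        cells = _lymph([(0, 0), (12.1, 0)], ["helper_t", "b_cell"])
        assert build_contact_graph(cells, 12.0).number_of_edges() == 0

    def test_edges_equal_all_pairs_oracle(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 200, size=(300, 2))
        cells = _lymph(xy, ["b_cell"] * 150 + ["helper_t"] * 150)
        g = build_contact_graph(cells, 12.0)
        ids = cells["cell_id"].to_numpy()
        brute = set()
        for i in range(300):
            for j in range(i + 1, 300):
                if np.hypot(*(xy[i] - xy[j])) <= 12.0:
                    brute.add(frozenset((ids[i], ids[j])))
        assert {frozenset(e) for e in g.edges} == brute

    def test_no_self_loops(self):
        cells = _lymph([(0, 0), (1, 0)], ["b_cell", "b_cell"])
        g = build_contact_graph(cells, 12.0)
        assert all(u != v for u, v in g.edges)


class TestInfiltrates:
    def test_pure_t_cluster_is_no_infiltrate(self):
        xy = [(i * 5.0, 0) for i in range(30)]
        cells = _lymph(xy, ["helper_t"] * 30)
        g = build_contact_graph(cells, 12.0)
        assert find_lymphoid_infiltrates(g, cells, min_cells=20) == []

    def test_min_cells_filter(self):
        xy = [(i * 5.0, 0) for i in range(10)]
        cells = _lymph(xy, ["helper_t"] * 5 + ["b_cell"] * 5)
        g = build_contact_graph(cells, 12.0)
        assert find_lymphoid_infiltrates(g, cells, min_cells=20) == []
        assert len(find_lymphoid_infiltrates(g, cells, min_cells=10)) == 1

    def test_two_separated_clusters_found_separately(self):
        xy = [(i * 5.0, 0) for i in range(20)] + [(1000 + i * 5.0, 0) for i in range(20)]
        cells = _lymph(xy, (["helper_t"] * 10 + ["b_cell"] * 10) * 2)
        g = build_contact_graph(cells, 12.0)
        comps = find_lymphoid_infiltrates(g, cells, min_cells=20)
        assert len(comps) == 2
        assert [len(c) for c in comps] == [20, 20]
        # deterministic ordering by centroid x
        assert comps[0]["x_um"].mean() < comps[1]["x_um"].mean()


class TestClassification:
    def test_checkerboard_mixing_has_no_zones(self):
        """A perfectly interleaved T/B lattice segregates far below the 0.7
        zone threshold and has no B-pure dense focus."""
        pts, labels = [], []
        for i in range(12):
            for j in range(12):
                pts.append((i * 8.0, j * 8.0))
                labels.append("b_cell" if (i + j) % 2 == 0 else "helper_t")
        # lattice neighbors are mostly opposite-class: segregation well below 0.7
        rec = classify_tls(_lymph(pts, labels), ANALYSIS)
        assert rec.zone_segregation_b < 0.6
        assert rec.zone_segregation_t < 0.6
        assert not rec.has_zones
        assert not rec.has_germinal_center
        assert not rec.is_tls

    def test_planted_core_rim_structure_is_tls(self):
        rng = np.random.default_rng(0)
        b_xy, t_xy = tls_template(TLSParams(), rng)
        pts = np.vstack([b_xy, t_xy]) + 500.0
        labels = ["b_cell"] * len(b_xy) + ["helper_t"] * len(t_xy)
        rec = classify_tls(_lymph(pts, labels), ANALYSIS)
        assert rec.zone_segregation_b >= 0.7
        assert rec.zone_segregation_t >= 0.7
        assert rec.has_zones
        assert rec.has_germinal_center
        assert rec.is_tls

    def test_two_cell_component_is_not_tls(self):
        rec = classify_tls(_lymph([(0, 0), (5, 0)], ["helper_t", "b_cell"]), ANALYSIS)
        assert not rec.has_zones and not rec.has_germinal_center and not rec.is_tls

    def test_invariant_to_ordering_and_translation(self):
        rng = np.random.default_rng(1)
        b_xy, t_xy = tls_template(TLSParams(), rng)
        pts = np.vstack([b_xy, t_xy]) + 300.0
        labels = ["b_cell"] * len(b_xy) + ["helper_t"] * len(t_xy)
        rec1 = classify_tls(_lymph(pts, labels), ANALYSIS)
        perm = rng.permutation(len(pts))
        rec2 = classify_tls(
            _lymph(pts[perm] + np.array([1234.5, -77.0]), [labels[i] for i in perm]), ANALYSIS
        )
        assert rec1.has_zones == rec2.has_zones
        assert rec1.has_germinal_center == rec2.has_germinal_center
        assert rec1.zone_segregation_b == pytest.approx(rec2.zone_segregation_b)
        assert rec1.zone_segregation_t == pytest.approx(rec2.zone_segregation_t)


class TestMediaDistance:
    def _record(self, x, y):
        return TLSRecord(
            tls_id="t", slide_id="s", member_ids=(), n_t=1, n_b=1,
            centroid_x_um=x, centroid_y_um=y,
            zone_segregation_t=1, zone_segregation_b=1,
            has_zones=True, has_germinal_center=True, is_tls=True,
        )

    def test_vertical_offset(self):
        assert tls_media_distance(self._record(2000, GEOM.media_adventitia_y + 100), GEOM) == pytest.approx(100.0)

    def test_on_boundary(self):
        assert tls_media_distance(self._record(2000, GEOM.media_adventitia_y), GEOM) == 0.0

    def test_matches_sampled_boundary_oracle(self):
        rng = np.random.default_rng(0)
        samples = np.linspace(0, GEOM.slide_width_um, 200_001)
        for _ in range(10):
            x, y = rng.uniform(0, 4000), rng.uniform(1350, 2150)
            d = tls_media_distance(self._record(x, y), GEOM)
            brute = np.min(np.hypot(samples - x, GEOM.media_adventitia_y - y))
            assert d == pytest.approx(brute, abs=1e-3)


class TestDetection:
    def test_monotonicity_in_contact_radius(self, gated_dilated_slide):
        """Growing the contact radius never shrinks any detected component."""
        gated, geometry, _ = gated_dilated_slide
        import dataclasses

        small = detect_tls(gated, geometry, ANALYSIS)
        big = detect_tls(gated, geometry, dataclasses.replace(ANALYSIS, contact_radius_um=16.0))
        assert sum(len(r.member_ids) for r in big) >= sum(len(r.member_ids) for r in small)
        for rec in small:
            members = set(rec.member_ids)
            assert any(members <= set(r.member_ids) for r in big)

    def test_round_trip_recovers_planted_members(self):
        """A planted 40B+40T structure comes back as one component holding
        every planted cell."""
        rng = np.random.default_rng(5)
        n = 200
        y0, y1 = GEOM.layer_band("adventitia")
        cells = pd.DataFrame(
            {
                "cell_id": [f"s_c{i:04d}" for i in range(n)],
                "slide_id": "s",
                "x_um": rng.uniform(0, 4000, n),
                "y_um": rng.uniform(y0, y1, n),
                "true_phenotype": ["b_cell"] * 100 + ["helper_t"] * 100,
                "layer": "adventitia",
            }
        )
        params = TLSParams(n_b=40, n_t=40)
        out, planted = place_tls(cells, GEOM, params, rng, n_tls=1)
        out["phenotype_adaptive"] = out["true_phenotype"]
        recs = detect_tls(out, GEOM, ANALYSIS)
        planted_ids = set(planted[0].member_ids)
        match = [r for r in recs if planted_ids <= set(r.member_ids)]
        assert len(match) == 1


class TestGroupStats:
    def _tls(self, slide, dist=100.0):
        return TLSRecord(
            tls_id="t", slide_id=slide, member_ids=("a",), n_t=1, n_b=1,
            centroid_x_um=0, centroid_y_um=0,
            zone_segregation_t=1, zone_segregation_b=1,
            has_zones=True, has_germinal_center=True, is_tls=True,
            distance_to_media_um=dist,
        )

    def test_no_tls_prevalence_zero(self):
        stats = tls_group_stats({"s1": [], "s2": []})
        assert stats["prevalence"] == 0.0
        assert np.isnan(stats["mean_tls_per_positive_slide"])

    def test_half_prevalence_and_counts(self):
        stats = tls_group_stats(
            {"s1": [self._tls("s1"), self._tls("s1")], "s2": [], "s3": [self._tls("s3", 200.0)], "s4": []}
        )
        assert stats["prevalence"] == 0.5
        assert stats["mean_tls_per_positive_slide"] == pytest.approx(1.5)
        assert stats["mean_tls_per_slide"] == pytest.approx(0.75)
        assert stats["mean_distance_to_media_um"] == pytest.approx((100 + 100 + 200) / 3)
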