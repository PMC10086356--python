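#!/usr/bin/env python
"""Group comparisons across the simulated cohort.

Runs the statistical battery on the per-slide summaries: two-group
Kolmogorov-Smirnov on adventitial fractions (non-dilated vs dilated),
three-group Kruskal-Wallis with Bonferroni-adjusted pairwise tests on
media fractions, a Fisher exact test on TLS presence, and Kendall's tau
(bootstrap CI) for the helper-T / B-cell association in the dilated
adventitia.  Writes results/group_tests.csv.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from aortamihc import default_cohort_config
from aortamihc.quantify import summarize_slide
from aortamihc.stats import (
    fisher_exact_2x2,
    kendall_tau_ci,
    kruskal_wallis_pairwise,
    ks_two_sample,
)
from aortamihc.tls import detect_tls

sys.path.insert(0, str(Path(__file__).parent))
from _cohort import load_gated_cohort  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=0, help="bootstrap seed for the tau CI")
    args = ap.parse_args()

    config = default_cohort_config()
    summaries: dict[str, list] = {}
    tls_positive: dict[str, int] = {}
    n_slides: dict[str, int] = {}
    for slide_id, group, gated, geometry, _ in load_gated_cohort(args.cohort_dir):
        g = config.group(group)
        s = summarize_slide(
            gated, geometry, group=group,
            adventitia_quantifiable=g.adventitia_quantifiable,
            markers_masked=g.markers_masked,
        )
        summaries.setdefault(group, []).append(s)
        n_slides[group] = n_slides.get(group, 0) + 1
        recs = detect_tls(gated, geometry, config.analysis)
        tls_positive[group] = tls_positive.get(group, 0) + bool(any(r.is_tls for r in recs))

    rows = []
    nd, dl = summaries["non_dilated"], summaries["dilated"]
    for pheno in ("lymphocyte", "b_cell", "helper_t_total", "memory_helper_t", "macrophage"):
        a = [v for v in (s.fraction("adventitia", pheno) for s in nd) if not np.isnan(v)]
        b = [v for v in (s.fraction("adventitia", pheno) for s in dl) if not np.isnan(v)]
        cmp = ks_two_sample(a, b, names=("non_dilated", "dilated"))
        rows.append({**cmp.to_row(), "phenotype": pheno, "layer": "adventitia"})
        print(f"KS adventitia {pheno}: D = {cmp.statistic:.2f}, p = {cmp.p_raw:.4f}")

    for pheno in ("helper_t_total", "cdc2", "m1_macrophage"):
        groups = {
            g: [v for v in (s.fraction("media", pheno) for s in ss) if not np.isnan(v)]
            for g, ss in summaries.items()
        }
        overall, pairwise = kruskal_wallis_pairwise(groups)
        rows.append({**overall.to_row(), "phenotype": pheno, "layer": "media"})
        rows.extend({**c.to_row(), "phenotype": pheno, "layer": "media"} for c in pairwise)
        print(f"KW media {pheno}: H = {overall.statistic:.2f}, p = {overall.p_raw:.4f}")

    table = [
        [tls_positive["dilated"], n_slides["dilated"] - tls_positive["dilated"]],
        [tls_positive["non_dilated"], n_slides["non_dilated"] - tls_positive["non_dilated"]],
    ]
    cmp = fisher_exact_2x2(table)
    rows.append({**cmp.to_row(), "phenotype": "tls_presence", "layer": "adventitia"})
    print(f"Fisher TLS presence dilated vs non-dilated: p = {cmp.p_raw:.4f}")

    ht = [s.count("adventitia", "helper_t_total") for s in dl]
    bc = [s.count("adventitia", "b_cell") for s in dl]
    corr = kendall_tau_ci(ht, bc, seed=args.seed)
    if corr is not None:
        rows.append(
            {
                "test": "kendall_tau",
                "groups": "dilated",
                "statistic": corr.tau,
                "p_raw": corr.p,
                "phenotype": "helper_t_total~b_cell",
                "layer": "adventitia",
            }
        )
        print(
            f"Kendall tau helper T ~ B (dilated adventitia): "
            f"tau = {corr.tau:.3f} (CI {corr.ci_low:.3f}-{corr.ci_high:.3f}), p = {corr.p:.4f}"
        )

    args.outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.outdir / "group_tests.csv", index=False)


if __name__ == "__main__":
    main()
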