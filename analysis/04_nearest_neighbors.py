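#!/usr/bin/env python
"""Nearest-neighbor analysis: M1-like macrophages to endothelium.

For every slide, computes the median minimal distance from CD68+CD206-
macrophages to CD31+CD68- endothelial cells in the media and adventitia
(tiles merged; slides with < 150 cells of either phenotype excluded) and
compares the per-slide medians across groups with the Kruskal-Wallis
test.  Writes results/nn_results.csv and prints the comparison.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from aortamihc import default_cohort_config
from aortamihc.neighbors import cohort_nn_comparison, median_min_distance

sys.path.insert(0, str(Path(__file__).parent))
from _cohort import load_gated_cohort  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--from-phenotype", default="CD68+CD206-")
    ap.add_argument("--to-phenotype", default="CD31+CD68-")
    args = ap.parse_args()

    config = default_cohort_config()
    rows = []
    by_group: dict[str, list] = {}
    for slide_id, group, gated, geometry, _ in load_gated_cohort(args.cohort_dir):
        res = median_min_distance(
            gated, geometry,
            from_rule=args.from_phenotype, to_rule=args.to_phenotype,
            layers=config.analysis.nn_layers, min_count=config.analysis.nn_min_count,
        )
        by_group.setdefault(group, []).append(res)
        rows.append(res.to_row())
        tag = f"excluded ({res.exclusion_reason})" if res.excluded else f"{res.median_min_distance_um:.1f} um"
        print(f"{slide_id}: {tag}")

    args.outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.outdir / "nn_results.csv", index=False)

    out = cohort_nn_comparison(by_group)
    if out["computable"]:
        print(
            f"Kruskal-Wallis on per-slide medians: H = {out['statistic']:.3f}, "
            f"p = {out['p']:.3f} ({'not ' if out['p'] >= 0.05 else ''}significant at 0.05)"
        )
    else:
        print(f"comparison not computable: {out['reason']}")


if __name__ == "__main__":
    main()
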