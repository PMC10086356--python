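#!/usr/bin/env python
"""Gate the simulated cohort and quantify per-layer composition.

Writes the tidy per-slide x layer x phenotype summary table and the
adventitial fold changes (dilated over non-dilated) to results/, and
prints the headline numbers: the lymphocyte and B-cell fold changes, the
dilated-group helper-T percentage and the CD4/CD8 ratios.
"""

import argparse
from pathlib import Path

import pandas as pd

from aortamihc import default_cohort_config
from aortamihc.quantify import (
    group_fold_change,
    group_median_cd4_cd8,
    group_median_fraction,
    summarize_slide,
)

import sys

sys.path.insert(0, str(Path(__file__).parent))
from _cohort import load_gated_cohort  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    config = default_cohort_config()
    summaries: dict[str, list] = {}
    for slide_id, group, gated, geometry, _ in load_gated_cohort(args.cohort_dir):
        g = config.group(group)
        s = summarize_slide(
            gated, geometry, group=group,
            adventitia_quantifiable=g.adventitia_quantifiable,
            markers_masked=g.markers_masked,
        )
        summaries.setdefault(group, []).append(s)

    args.outdir.mkdir(parents=True, exist_ok=True)
    table = pd.concat([s.table for ss in summaries.values() for s in ss], ignore_index=True)
    table.to_csv(args.outdir / "slide_summaries.csv", index=False)

    nd, dl = summaries["non_dilated"], summaries["dilated"]
    rows = []
    for pheno in ("lymphocyte", "b_cell", "helper_t_total", "macrophage", "m1_macrophage"):
        fc = group_fold_change(nd, dl, pheno, "adventitia")
        rows.append({"phenotype": pheno, "layer": "adventitia", "fold_change": fc})
        print(f"adventitia {pheno}: dilated / non-dilated fold change = {fc:.2f}")
    pd.DataFrame(rows).to_csv(args.outdir / "fold_changes.csv", index=False)

    print(
        "dilated adventitia helper T: "
        f"{100 * group_median_fraction(dl, 'helper_t_total', 'adventitia'):.2f}% of all cells"
    )
    print(f"CD4/CD8 dilated: {group_median_cd4_cd8(dl, 'adventitia'):.2f}")
    print(f"CD4/CD8 non-dilated: {group_median_cd4_cd8(nd, 'adventitia'):.2f}")


if __name__ == "__main__":
    main()
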