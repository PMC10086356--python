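"""Shared loader for the analysis scripts: read the simulated cohort from
results/cohort/ and gate every slide with the default panels."""

from pathlib import Path

from aortamihc import default_cohort_config
from aortamihc.gating import gate_cells
from aortamihc.geometry import LayerGeometry
from aortamihc.io import read_cell_table, read_ground_truth
from aortamihc.panels import PANELS


def load_gated_cohort(cohort_dir: Path):
    """Yield (slide_id, group, gated cells, geometry, truth) per slide."""
    config = default_cohort_config()
    paths = sorted(cohort_dir.glob("*.cells.csv"))
    if not paths:
        raise SystemExit(
            f"no slides found in {cohort_dir}; run analysis/01_simulate_cohort.py first"
        )
    for path in paths:
        slide_id = path.name.removesuffix(".cells.csv")
        group = slide_id.rsplit("_", 1)[0]
        cells = read_cell_table(path)
        geometry = LayerGeometry.from_json(cohort_dir / f"{slide_id}.geometry.json")
        truth = read_ground_truth(cohort_dir / f"{slide_id}.truth.json")
        gated = gate_cells(
            cells, PANELS, config.intensity_model, config.analysis,
            markers_masked=config.group(group).markers_masked,
        )
        yield slide_id, group, gated, geometry, truth
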