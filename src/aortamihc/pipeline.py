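"""End-to-end orchestration: synthetic cohort -> gating -> layer
quantification -> TLS detection -> nearest-neighbor analysis -> group
statistics, with every artifact written as CSV/JSON carrying a provenance
header (run id, config hash, seed, stage).

`calibration_statistics` condenses one full run into the summary
statistics the default cohort is calibrated to (fold changes, helper-T
percentage, CD4/CD8 ratios, TLS prevalence/count/distance, pooled intima
fractions); `run_pipeline` executes the whole battery and optionally
writes the result bundle to disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .config import CohortConfig
from .gating import gate_cells
from .neighbors import cohort_nn_comparison, median_min_distance
from .panels import IMMUNE_LEAVES_ADAPTIVE, IMMUNE_LEAVES_INNATE, PANELS
from .quantify import (
    SlideSummary,
    group_fold_change,
    group_median_cd4_cd8,
    group_median_fraction,
    pooled_fraction,
    summarize_slide,
)
from .simulate import SlideData, generate_cohort
from .stats import fisher_exact_2x2, kendall_tau_ci, kruskal_wallis_pairwise, ks_two_sample
from .tls import detect_tls, tls_group_stats


class PipelineError(RuntimeError):
    pass


def config_hash(config: CohortConfig) -> str:
    """Stable hash of the full configuration (provenance)."""
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class RunManifest:
    run_id: str
    config: CohortConfig
    seed: int
    outdir: str | None = None

    @property
    def hash(self) -> str:
        return config_hash(self.config.with_seed(self.seed))


def _gate_slide(slide: SlideData, config: CohortConfig) -> pd.DataFrame:
    group = config.group(slide.group)
    return gate_cells(
        slide.cells, PANELS, config.intensity_model, config.analysis,
        markers_masked=group.markers_masked,
    )


@dataclass
class ResultBundle:
    """Everything one run produces, as in-memory tables."""

    run_id: str
    seed: int
    config_hash: str
    summaries: list[SlideSummary]
    summary_table: pd.DataFrame
    fold_changes: pd.DataFrame
    tls_records: pd.DataFrame
    tls_stats: dict
    nn_results: pd.DataFrame
    nn_comparison: dict
    group_tests: pd.DataFrame
    calibration: dict


def run_pipeline(manifest: RunManifest) -> ResultBundle:
    """Execute simulate -> gate -> quantify -> TLS -> NN -> stats.

    Any stage failure is re-raised naming the stage and offending slide.
    """
    config = manifest.config.with_seed(manifest.seed)
    config.validate()
    if sum(g.n_slides for g in config.groups) == 0:
        raise PipelineError("manifest has zero slides")

    stage = "simulate"
    try:
        cohort = generate_cohort(config)
    except Exception as e:  # pragma: no cover - passthrough with context
        raise PipelineError(f"stage {stage} failed: {e}") from e

    gated: dict[str, pd.DataFrame] = {}
    summaries: dict[str, list[SlideSummary]] = {g.name: [] for g in config.groups}
    tls_by_slide: dict[str, dict[str, list]] = {g.name: {} for g in config.groups}
    nn_by_group: dict[str, list] = {g.name: [] for g in config.groups}
    tls_rows, nn_rows = [], []

    for slide in cohort:
        group = config.group(slide.group)
        try:
            stage = "gate"
            cells = _gate_slide(slide, config)
            gated[slide.slide_id] = cells
            stage = "quantify"
            summary = summarize_slide(
                cells, slide.geometry, group=slide.group,
                adventitia_quantifiable=group.adventitia_quantifiable,
                markers_masked=group.markers_masked,
            )
            summaries[slide.group].append(summary)
            stage = "tls"
            recs = detect_tls(cells, slide.geometry, config.analysis)
            tls_by_slide[slide.group][slide.slide_id] = recs
            tls_rows.extend(r.to_row() for r in recs)
            stage = "neighbors"
            nn = median_min_distance(
                cells, slide.geometry,
                layers=config.analysis.nn_layers, min_count=config.analysis.nn_min_count,
            )
            nn_by_group[slide.group].append(nn)
            nn_rows.append(nn.to_row())
        except Exception as e:
            raise PipelineError(f"stage {stage} failed on slide {slide.slide_id}: {e}") from e

    stage = "stats"
    # TLS group statistics: quantifiable (adventitia) slides only
    quantifiable_tls = {
        s: recs
        for g in config.groups
        if g.adventitia_quantifiable
        for s, recs in tls_by_slide[g.name].items()
    }
    dilated_tls = tls_by_slide.get("dilated", {})
    t_stats = tls_group_stats(dilated_tls if dilated_tls else quantifiable_tls)

    fold_rows = []
    if "non_dilated" in summaries and "dilated" in summaries:
        for pheno in ("lymphocyte", "b_cell", "helper_t_total", "macrophage", "m1_macrophage"):
            fold_rows.append(
                {
                    "phenotype": pheno,
                    "layer": "adventitia",
                    "comparison": "dilated_vs_non_dilated",
                    "fold_change": group_fold_change(
                        summaries["non_dilated"], summaries["dilated"], pheno, "adventitia"
                    ),
                }
            )

    test_rows = []
    if "non_dilated" in summaries and "dilated" in summaries:
        for pheno in ("lymphocyte", "b_cell", "helper_t_total", "memory_helper_t", "macrophage"):
            a = [s.fraction("adventitia", pheno) for s in summaries["non_dilated"]]
            b = [s.fraction("adventitia", pheno) for s in summaries["dilated"]]
            a = [v for v in a if not np.isnan(v)]
            b = [v for v in b if not np.isnan(v)]
            if len(a) >= 2 and len(b) >= 2:
                cmp = ks_two_sample(a, b, names=("non_dilated", "dilated"))
                row = cmp.to_row()
                row.update(phenotype=pheno, layer="adventitia")
                test_rows.append(row)
    if len(summaries) >= 2:
        for pheno in ("helper_t_total", "cdc2", "m1_macrophage"):
            groups_vals = {
                g: [v for v in (s.fraction("media", pheno) for s in ss) if not np.isnan(v)]
                for g, ss in summaries.items()
            }
            groups_vals = {g: v for g, v in groups_vals.items() if len(v) >= 2}
            if len(groups_vals) >= 2:
                overall, pairwise = kruskal_wallis_pairwise(groups_vals)
                for cmp in [overall] + pairwise:
                    row = cmp.to_row()
                    row.update(phenotype=pheno, layer="media")
                    test_rows.append(row)
    # helper T / B cell correlation in the dilated adventitia
    if "dilated" in summaries and len(summaries["dilated"]) >= 3:
        ht = [s.count("adventitia", "helper_t_total") for s in summaries["dilated"]]
        bc = [s.count("adventitia", "b_cell") for s in summaries["dilated"]]
        corr = kendall_tau_ci(ht, bc, seed=manifest.seed)
        if corr is not None:
            row = {"test": "kendall_tau", "groups": "dilated", "statistic": corr.tau,
                   "p_raw": corr.p, "p_adjusted": None, "adjustment": None,
                   "phenotype": "helper_t_total~b_cell", "layer": "adventitia"}
            test_rows.append(row)
    # TLS presence: dilated vs non-dilated (binary -> Fisher exact)
    if "non_dilated" in summaries and "dilated" in summaries:
        pos_d = sum(1 for recs in tls_by_slide["dilated"].values() if any(r.is_tls for r in recs))
        pos_n = sum(1 for recs in tls_by_slide["non_dilated"].values() if any(r.is_tls for r in recs))
        n_d, n_n = len(tls_by_slide["dilated"]), len(tls_by_slide["non_dilated"])
        cmp = fisher_exact_2x2([[pos_d, n_d - pos_d], [pos_n, n_n - pos_n]])
        row = cmp.to_row()
        row.update(phenotype="tls_presence", layer="adventitia")
        test_rows.append(row)

    nn_cmp = cohort_nn_comparison(nn_by_group)

    calibration = _calibration_from_results(config, cohort, gated, summaries, tls_by_slide)

    bundle = ResultBundle(
        run_id=manifest.run_id,
        seed=manifest.seed,
        config_hash=manifest.hash,
        summaries=[s for ss in summaries.values() for s in ss],
        summary_table=pd.concat([s.table for ss in summaries.values() for s in ss], ignore_index=True),
        fold_changes=pd.DataFrame(fold_rows),
        tls_records=pd.DataFrame(tls_rows),
        tls_stats=t_stats,
        nn_results=pd.DataFrame(nn_rows),
        nn_comparison=nn_cmp,
        group_tests=pd.DataFrame(test_rows),
        calibration=calibration,
    )
    if manifest.outdir is not None:
        _write_bundle(bundle, manifest)
    return bundle


def _calibration_from_results(config, cohort, gated, summaries, tls_by_slide) -> dict:
    """The calibrated summary statistics, on the scales they are reported on."""
    out: dict[str, float] = {}
    nd = summaries.get("non_dilated", [])
    dl = summaries.get("dilated", [])
    if nd and dl:
        out["adventitia_lymphocyte_fold"] = group_fold_change(nd, dl, "lymphocyte", "adventitia")
        out["adventitia_b_cell_fold"] = group_fold_change(nd, dl, "b_cell", "adventitia")
        out["adventitia_macrophage_fold"] = group_fold_change(nd, dl, "macrophage", "adventitia")
    if dl:
        out["adventitia_helper_t_pct_dilated"] = 100 * group_median_fraction(dl, "helper_t_total", "adventitia")
        out["adventitia_cd4_cd8_dilated"] = group_median_cd4_cd8(dl, "adventitia")
    if nd:
        out["adventitia_cd4_cd8_non_dilated"] = group_median_cd4_cd8(nd, "adventitia")
    dilated_tls = tls_by_slide.get("dilated", {})
    if dilated_tls:
        ts = tls_group_stats(dilated_tls)
        out["tls_prevalence_dilated_pct"] = 100 * ts["prevalence"]
        out["tls_per_positive_slide"] = ts["mean_tls_per_positive_slide"]
        out["tls_distance_to_media_um"] = ts["mean_distance_to_media_um"]
    pooled = [(gated[s.slide_id], s.geometry) for s in cohort]
    out["intima_immune_pct"] = 100 * pooled_fraction(
        pooled, "intima", IMMUNE_LEAVES_ADAPTIVE + IMMUNE_LEAVES_INNATE
    )
    out["intima_m1_pct"] = 100 * pooled_fraction(pooled, "intima", ("m1_macrophage",))
    return out


def _write_bundle(bundle: ResultBundle, manifest: RunManifest) -> None:
    outdir = Path(manifest.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {
        "run_id": bundle.run_id,
        "seed": bundle.seed,
        "config_hash": bundle.config_hash,
    }
    for name, df in (
        ("slide_summaries", bundle.summary_table),
        ("fold_changes", bundle.fold_changes),
        ("tls_records", bundle.tls_records),
        ("nn_results", bundle.nn_results),
        ("group_tests", bundle.group_tests),
    ):
        with open(outdir / f"{name}.csv", "w") as fh:
            for k, v in {**prov, "stage": name}.items():
                fh.write(f"# {k}: {v}\n")
            df.to_csv(fh, index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(
            {
                **prov,
                "tls_stats": _jsonable(bundle.tls_stats),
                "nn_comparison": _jsonable(bundle.nn_comparison),
                "calibration": _jsonable(bundle.calibration),
            },
            fh,
            indent=1,
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def calibration_statistics(config: CohortConfig, seed: int | None = None) -> dict:
    """Run the full pipeline for one master seed and return the recovered
    calibration statistics (see `_calibration_from_results`)."""
    if seed is None:
        seed = config.master_seed
    manifest = RunManifest(run_id=f"calib_{seed}", config=config, seed=seed)
    return run_pipeline(manifest).calibration
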