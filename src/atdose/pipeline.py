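"""End-to-end orchestration: simulate -> dose -> de -> screen -> profile.

A :class:`PipelineConfig` carries every threshold (defaults are the
analysis cutoffs: |FC| >= 1.5, adjusted p < 0.01 for differential
expression, p < 0.05 for GO enrichment, 3% near-tie rule), the exposure
grid, the seed and the output directory.  :func:`run_pipeline` executes
the stages in order, writes every table as TSV, and finishes with a
manifest (seed, thresholds, package versions, sha256 checksums of all
outputs) so a run can be audited and reproduced.  A stage failure
aborts with the stage name and leaves partial outputs under a
``FAILED`` marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from atdose import dosimetry
from atdose.diffexpr import call_all_conditions, de_summary
from atdose.dosimetry import AT211_SPECTRUM, OrganGeometry, dose_table
from atdose.profiles import enrich, profile, profile_heatmap_table
from atdose.screen import ExposureGrid, collapse_by_gene, screen, screen_table
from atdose.simulate import SimulationDesign, simulate_study
from atdose import io as aio

log = logging.getLogger("atdose.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run."""

    out_dir: str = "atdose_out"
    seed: int = 211
    fc_threshold: float = 1.5
    alpha_de: float = 0.01
    alpha_go: float = 0.05
    tie_threshold: float = 0.03
    floor_quantile: float = 0.2
    de_method: str = "moderated"
    grid: ExposureGrid = field(default_factory=ExposureGrid)
    windows: list = field(
        default_factory=lambda: [(1.7, 1.0), (1.7, 6.0), (1.7, 168.0),
                                 (105.0, 1.0), (7.5, 6.0)]
    )
    # input paths; None means "generate synthetically with `seed`"
    curves: str | None = None
    nuclide: str | None = None
    organs: str | None = None
    matrix: str | None = None
    samples: str | None = None
    annotation: str | None = None
    category_map: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        grid = doc.pop("grid", None)
        windows = doc.pop("windows", None)
        cfg = cls(**doc)
        if grid is not None:
            cfg.grid = ExposureGrid(
                reference_activity_kbq=grid["reference_activity_kbq"],
                reference_times_h=tuple(grid["reference_times_h"]),
                elevated=tuple(tuple(e) for e in grid["elevated"]),
            )
        if windows is not None:
            cfg.windows = [tuple(w) for w in windows]
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dictionary.

    Inputs not supplied as paths are generated from the synthetic design
    seeded with ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    outputs: list[Path] = []
    stage = "setup"
    try:
        # ---------------------------------------------------- simulate/load
        stage = "simulate"
        log.info("stage=%s seed=%s", stage, config.seed)
        design = SimulationDesign(seed=config.seed, grid=config.grid)
        synth_curves, synth_study, synth_amap, truth = simulate_study(design)

        curves = (aio.read_curves_tsv(config.curves)
                  if config.curves else synth_curves)
        spectrum = (aio.read_nuclide_yaml(config.nuclide)
                    if config.nuclide else AT211_SPECTRUM)
        if config.organs:
            geometries = aio.read_organs_tsv(config.organs)
        else:
            geometries = [OrganGeometry(organ=name, mass_kg=k.mass_kg)
                          for name, k in design.organs.items()]
        if config.matrix and config.samples:
            study = aio.read_expression_study(config.matrix, config.samples)
        else:
            study = synth_study
            p = out / "matrix.tsv"
            aio.write_expression_study(study, p, out / "samples.tsv",
                                       out / "probe_gene.tsv")
            outputs += [p, out / "samples.tsv", out / "probe_gene.tsv"]
            aio.write_curves_tsv(curves, out / "curves.tsv")
            outputs.append(out / "curves.tsv")
            truth.to_json(out / "truth.json")
            outputs.append(out / "truth.json")
        # --------------------------------------------------------- dosimetry
        stage = "dose"
        log.info("stage=%s organs=%d windows=%d", stage, len(geometries),
                 len(config.windows))
        doses = dose_table(curves, geometries, spectrum, config.windows,
                           reference_activity_kbq=config.grid.reference_activity_kbq)
        doses.to_csv(out / "dose_table.tsv", sep="\t", index=False)
        outputs.append(out / "dose_table.tsv")

        # ---------------------------------------------------------------- DE
        stage = "de"
        log.info("stage=%s conditions=%s", stage, study.conditions())
        calls = call_all_conditions(
            study, config.fc_threshold, config.alpha_de,
            config.floor_quantile, config.de_method,
        )
        outputs += aio.write_de_calls(calls, out / "de")
        summary = pd.DataFrame(
            [
                {"activity_kbq": c[0], "time_h": c[1],
                 "n_up": de_summary(df)[0], "n_down": de_summary(df)[1]}
                for c, df in sorted(calls.items())
            ]
        )
        summary.to_csv(out / "de_summary.tsv", sep="\t", index=False)
        outputs.append(out / "de_summary.tsv")

        # ------------------------------------------------------------ screen
        stage = "screen"
        log.info("stage=%s", stage)
        biomarkers = screen(calls, config.grid, study.probe_gene,
                            config.tie_threshold)
        screen_table(biomarkers, config.grid).to_csv(
            out / "biomarkers.tsv", sep="\t", index=False)
        collapse_by_gene(biomarkers).to_csv(
            out / "biomarkers_by_gene.tsv", sep="\t", index=False)
        outputs += [out / "biomarkers.tsv", out / "biomarkers_by_gene.tsv"]

        # ----------------------------------------------------------- profile
        stage = "profile"
        log.info("stage=%s", stage)
        if config.annotation:
            amap = aio.read_annotation(config.annotation, config.category_map)
        else:
            amap = synth_amap
            aio.write_annotation_tsv(amap, out / "annotation.tsv",
                                     out / "category_map.tsv")
            outputs += [out / "annotation.tsv", out / "category_map.tsv"]
        from atdose.diffexpr import filter_probes

        universe = set(filter_probes(study.matrix, config.floor_quantile))
        profiles_by_condition = {}
        for cond, df in sorted(calls.items()):
            significant = set(df.index[df["significant"]])
            enr = enrich(significant, universe, amap, config.alpha_go)
            profiles_by_condition[aio.condition_slug(cond)] = profile(enr, amap)
        long, matrix = profile_heatmap_table(profiles_by_condition)
        long.to_csv(out / "profiles_long.tsv", sep="\t", index=False)
        matrix.to_csv(out / "profiles_matrix.tsv", sep="\t")
        outputs += [out / "profiles_long.tsv", out / "profiles_matrix.tsv"]

        # ---------------------------------------------------------- manifest
        stage = "manifest"
        import numpy, scipy, statsmodels
        import atdose

        manifest = {
            "seed": config.seed,
            "thresholds": {
                "fc": config.fc_threshold,
                "alpha_de": config.alpha_de,
                "alpha_go": config.alpha_go,
                "tie": config.tie_threshold,
                "floor_quantile": config.floor_quantile,
                "de_method": config.de_method,
            },
            "versions": {
                "atdose": atdose.__version__,
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "statsmodels": statsmodels.__version__,
            },
            "outputs": {
                str(p.relative_to(out)): _sha256(p) for p in sorted(set(outputs))
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        failed_marker.write_text(f"stage: {stage}\ncause: {exc}\n")
        raise StageError(stage, exc) from exc
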