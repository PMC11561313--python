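"""End-to-end pipeline: occurrences + rasters -> surfaces, fuzzy statistics, reports.

Stages run in the order thin -> select predictors -> build tables -> fit
models -> predict surfaces -> favourability -> pairwise fuzzy comparison ->
evaluation, writing every artifact to disk and recording it in a JSON
manifest stamped with the seed and a hash of the configuration, so a rerun
with the same inputs is reproducible artifact-for-artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, fuzzy, io, preprocess, sdm, synthetic
from .grids import EnvGrid, MembershipSurface, OccurrenceSet

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]

log = logging.getLogger("fuzzysdm")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; YAML-serializable."""

    out_dir: str = "fuzzysdm_out"
    # inputs: either a rasters directory + occurrence CSVs, or simulate
    raster_dir: str | None = None
    occurrence_csvs: dict[str, str] = field(default_factory=dict)  # species -> csv path
    simulate: dict | None = None  # kwargs for synthetic.default_study
    # preprocessing
    thin: bool = True
    min_dist_km: float = 10.0
    thin_reps: int = 100
    corr_threshold: float = 0.8
    # sdm
    algorithms: list[str] = field(default_factory=lambda: ["glm", "gam", "brt", "maxent_like"])
    cv_k: int = 5
    cv_reps: int = 10
    seed: int = 0
    sdm_params: dict = field(default_factory=dict)  # per-algorithm fit kwargs
    # fuzzy comparison
    n_bins: int = 10
    confidence: float = 0.95
    binary_threshold: float = 0.5
    # evaluation
    threshold_rule: str = "prevalence"
    hl_bins: int = 10

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def demo_config(out_dir: str = "fuzzysdm_out", seed: int = 0,
                scale: float = 1.0) -> PipelineConfig:
    """The built-in two-species virtual demo study.

    ``scale`` < 1 shrinks the landscape and the background sample together
    (model structure and prevalences are unchanged) for quick runs.
    """
    rows = max(int(round(100 * np.sqrt(scale))), 20)
    n_back = max(int(round(synthetic.DEFAULT_N_BACKGROUND * scale)), 400)
    return PipelineConfig(
        out_dir=out_dir, seed=seed,
        simulate={"n_rows": rows, "n_cols": rows, "n_background": n_back},
        thin=False,  # cell-center virtual records need no bias correction
        sdm_params={"brt": {"max_trees": 300}},
    )


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        grid, _, _, occ_a, occ_b, background = synthetic.default_study(seed=cfg.seed, **sim)
        occs = {occ_a.species_id: occ_a, occ_b.species_id: occ_b}
        return grid, occs, background
    if cfg.raster_dir is None or not cfg.occurrence_csvs:
        raise ValueError("config must provide either 'simulate' or raster_dir + occurrence_csvs")
    grid = io.read_raster_stack(cfg.raster_dir)
    occs = {sp: io.read_occurrences(path, species=sp)
            for sp, path in cfg.occurrence_csvs.items()}
    background = synthetic.sample_background(grid, seed=cfg.seed,
                                             replace=grid.n_valid < synthetic.DEFAULT_N_BACKGROUND)
    return grid, occs, background


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the output manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                      "stages": {}, "artifacts": {}}
    stage = "load"
    try:
        grid, occs, background = _load_inputs(cfg)
        manifest["stages"]["load"] = {"species": sorted(occs),
                                      "n_layers": len(grid.layer_names),
                                      "n_background": len(background)}

        stage = "thin"
        if cfg.thin:
            for sp in list(occs):
                before = len(occs[sp])
                occs[sp] = preprocess.thin_occurrences(
                    occs[sp], cfg.min_dist_km, cfg.thin_reps, seed=cfg.seed)
                log.info("thinning %s: %d -> %d records", sp, before, len(occs[sp]))
                manifest["stages"].setdefault("thin", {})[sp] = {
                    "before": before, "after": len(occs[sp])}

        stage = "select_predictors"
        corr = preprocess.pearson_matrix(grid)
        report = preprocess.select_predictors(corr, threshold=cfg.corr_threshold)
        log.info("predictor pruning: %d -> %d variables", len(corr), len(report.kept))
        io.write_report(report.to_dict(), out / "correlation_report.json")
        manifest["stages"]["select_predictors"] = {
            "before": len(corr), "kept": report.kept, "dropped": report.dropped}
        manifest["artifacts"]["correlation_report"] = "correlation_report.json"
        kept = report.kept

        stage = "fit"
        surfaces: dict[tuple[str, str], MembershipSurface] = {}
        fav: dict[tuple[str, str], MembershipSurface] = {}
        for sp, occ in sorted(occs.items()):
            table = sdm.build_table(grid, occ, background, layer_names=kept)
            for algo in cfg.algorithms:
                params = dict(cfg.sdm_params.get(algo, {}))
                model = sdm.fit(table, algo, **params)
                surf = sdm.predict_surface(model, grid)
                name = f"{sp}_{algo}_{'suitability' if model.output_kind != 'probability' else 'probability'}.asc"
                io.write_surface(surf, out / name)
                manifest["artifacts"][f"{sp}/{algo}/{surf.kind}"] = name
                surfaces[(sp, algo)] = surf

                if model.output_kind == "probability":
                    fsurf = fuzzy.favourability_surface(surf, model.n1, model.n0)
                    fname = f"{sp}_{algo}_favourability.asc"
                    io.write_surface(fsurf, out / fname)
                    manifest["artifacts"][f"{sp}/{algo}/favourability"] = fname
                    fav[(sp, algo)] = fsurf

                stage = "crossvalidate"
                cv = sdm.crossvalidate(table, algo, k=cfg.cv_k, reps=cfg.cv_reps,
                                       seed=cfg.seed, threshold_rule=cfg.threshold_rule,
                                       **params)
                cv_name = f"{sp}_{algo}_cv.csv"
                cv.to_csv(out / cv_name, index=False)
                manifest["artifacts"][f"{sp}/{algo}/cv"] = cv_name

                stage = "evaluate"
                rpt, hl, reason = evaluation.evaluate_model(
                    model, table, threshold_rule=cfg.threshold_rule, hl_bins=cfg.hl_bins)
                payload = {"full_data": rpt.to_dict(),
                           "cv_mean": cv[["AUC", "TSS", "CCR", "Sensitivity",
                                          "Specificity"]].mean().to_dict()}
                if hl is not None:
                    payload["HL"] = hl.to_dict()
                else:
                    payload["HL_skipped_reason"] = reason
                ev_name = f"{sp}_{algo}_evaluation.json"
                io.write_report(payload, out / ev_name)
                manifest["artifacts"][f"{sp}/{algo}/evaluation"] = ev_name
                stage = "fit"

        stage = "compare"
        species = sorted(occs)
        if len(species) >= 2:
            for algo in cfg.algorithms:
                pair = [(sp, algo) for sp in species if (sp, algo) in fav]
                if len(pair) < 2:
                    continue  # relative-suitability output stays out of fuzzy comparison
                f_a, f_b = fav[pair[0]], fav[pair[1]]
                inter = fuzzy.fuzzy_intersection(f_a, f_b)
                iname = f"intersection_{algo}.asc"
                io.write_surface(inter, out / iname)
                manifest["artifacts"][f"pair/{algo}/intersection"] = iname

                profile = fuzzy.shared_favourability_profile(
                    f_a, f_b, n_bins=cfg.n_bins, confidence=cfg.confidence)
                comp = {
                    "FOvI": fuzzy.fuzzy_overlap_index(f_a, f_b),
                    "fuzzy_similarity": fuzzy.similarity_matrix(
                        [f_a, f_b], mode="fuzzy", labels=species[:2]),
                    "binary_similarity": fuzzy.similarity_matrix(
                        [f_a, f_b], mode="binary", labels=species[:2],
                        binary_threshold=cfg.binary_threshold),
                    "fuzzy_entropy": {species[0]: fuzzy.fuzzy_entropy(f_a),
                                      species[1]: fuzzy.fuzzy_entropy(f_b)},
                    "shared_profile": profile.table.reset_index(),
                }
                cname = f"comparison_{algo}.json"
                io.write_report(comp, out / cname)
                manifest["artifacts"][f"pair/{algo}/comparison"] = cname

                ax = fuzzy.plot_shared_favourability(profile, labels=species[:2])
                pname = f"shared_favourability_{algo}.png"
                ax.figure.savefig(out / pname, dpi=120)
                import matplotlib.pyplot as plt
                plt.close(ax.figure)
                manifest["artifacts"][f"pair/{algo}/shared_plot"] = pname
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        io.write_report(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    io.write_report(manifest, out / "manifest.json")
    return manifest
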