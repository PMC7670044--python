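"""End-to-end orchestration: simulate -> behavior -> PLS -> report.

Each stage is a plain function over the library; :func:`run_pipeline` wires
them together, splits the master seed into per-stage streams by fixed
offsets, and writes a manifest recording every seed and parameter so a
fixed configuration regenerates every numeric output identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from . import design as dg
from .grid import VoxelGrid
from .imagesim import (ConditionImageSet, default_planted_model,
                       select_conditions)
from .io import save_condition_images, save_map
from .peaks import find_peaks
from .resampling import (ResamplingConfig, bootstrap_reliability,
                         permutation_test, task_matrix)
from .seedpls import SeedSpec, extract_seed_values, seed_correlation_maps
from .taskpls import build_datamat, compute_brain_scores, pls_svd

log = logging.getLogger(__name__)

# fixed offsets splitting the master seed into independent stage streams
STAGE_SEED_OFFSETS = {"behavior": 11, "images": 23, "resampling": 37}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; JSON-round-trippable."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    analyses: tuple[str, ...] = (
        "repetition", "targetness", "seed:target_seed")
    pooling: str = "pooled"
    n_subjects: int = 14
    sdt_mode: str = "rate"
    n_perm: int = 500
    n_boot: int = 100
    bsr_threshold: float = 3.0
    min_sep_mm: float = 10.0
    #: mm center per seed analysis label
    seed_centers: dict = field(default_factory=lambda: {
        "target_seed": (-5.0, -1.0, -3.0)})

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        if "seed_centers" in raw:
            raw["seed_centers"] = {k: tuple(v)
                                   for k, v in raw["seed_centers"].items()}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analyses"] = list(d["analyses"])
        d["seed_centers"] = {k: list(v) for k, v in d["seed_centers"].items()}
        return d


def stage_seed(cfg: PipelineConfig, stage: str) -> int:
    return (cfg.seed * 1000003 + STAGE_SEED_OFFSETS[stage]) % (2 ** 31)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def stage_behavior(cfg: PipelineConfig, out: Path) -> dict:
    """Simulate the cohort and compute the behavioral statistics."""
    out.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(cfg, "behavior")
    params = dg.DesignParams(n_subjects=cfg.n_subjects, rng_seed=seed)
    sdt = dg.SdtParams(mode=cfg.sdt_mode)
    responses = dg.simulate_cohort(params, sdt, rng_seed=seed)
    _write_tsv(responses, out / "responses.tsv")

    pool = dg.generate_word_pool(params)
    design = dg.generate_design(pool, params)
    dg.write_events_tsv(design, out / "events_sub-01.tsv")

    rates = bh.score_responses(responses)
    _write_tsv(rates, out / "rates.tsv")
    sdt_tab = bh.sdt_summary(rates)
    _write_tsv(sdt_tab, out / "sdt.tsv")

    wide = sdt_tab.pivot(index="subject", columns="run_type")
    c_old = wide[("c", "incentivize-old")].to_numpy()
    c_new = wide[("c", "incentivize-new")].to_numpy()
    d_old = wide[("d_prime", "incentivize-old")].to_numpy()
    d_new = wide[("d_prime", "incentivize-new")].to_numpy()
    t_c, df_c, p_c, dz_c = bh.paired_t(c_old, c_new)
    t_d, df_d, p_d, dz_d = bh.paired_t(d_old, d_new)
    n = len(c_old)
    tost = {f"bound_{b:.2f}": dataclasses.asdict(
        bh.tost_paired(dz_d, n, b)) for b in (0.50, 0.80)}
    anova_acc = bh.rm_anova_2way(bh.accuracy_anova_table(rates))
    anova_rt = bh.rm_anova_2way(bh.rt_anova_table(rates))
    summary = {
        "criterion_t": {"t": t_c, "df": df_c, "p": p_c, "dz": dz_c},
        "sensitivity_t": {"t": t_d, "df": df_d, "p": p_d, "dz": dz_d},
        "tost_sensitivity": tost,
        "anova_accuracy": anova_acc.to_dict(orient="records"),
        "anova_rt": anova_rt.to_dict(orient="records"),
        "group_means": {
            "d_prime": {rt: float(sdt_tab[sdt_tab.run_type == rt]
                                  .d_prime.mean()) for rt in dg.RUN_TYPES},
            "c": {rt: float(sdt_tab[sdt_tab.run_type == rt].c.mean())
                  for rt in dg.RUN_TYPES},
        },
    }
    with open(out / "behavior_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return {"seed": seed, "n_subjects": cfg.n_subjects,
            "files": sorted(p.name for p in out.iterdir())}


def stage_images(cfg: PipelineConfig, out: Path) -> tuple[ConditionImageSet, dict]:
    """Simulate condition beta images from the default planted model."""
    out.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(cfg, "images")
    grid, model = default_planted_model()
    from .imagesim import simulate_condition_images
    images = simulate_condition_images(
        cfg.n_subjects, dg.MODELED_CONDITIONS, grid, model, rng_seed=seed)
    save_condition_images(images, out)
    return images, {"seed": seed, "grid_shape": list(grid.shape),
                    "n_conditions": images.n_conditions}


def _analysis_matrix_fn(analysis: str, cfg: PipelineConfig):
    """Return (condition-selection fn, matrix fn, label) for an analysis."""
    if analysis in ("repetition", "targetness"):
        def select(images):
            return select_conditions(images, analysis, cfg.pooling)
        return select, task_matrix, analysis
    if analysis.startswith("seed:"):
        label = analysis.split(":", 1)[1]
        center = tuple(cfg.seed_centers[label])
        spec = SeedSpec(center_mm=center, label=label)

        def select(images):
            return select_conditions(images, "targetness", "unpooled")

        def matrix_fn(images):
            return seed_correlation_maps(
                extract_seed_values(images, spec), images)
        return select, matrix_fn, f"seed_{label}"
    raise KeyError(f"unknown analysis {analysis!r}")


def stage_analysis(cfg: PipelineConfig, analysis: str,
                   images: ConditionImageSet, out: Path) -> dict:
    """One PLS analysis: decomposition, permutation, bootstrap, peaks."""
    select, matrix_fn, label = _analysis_matrix_fn(analysis, cfg)
    adir = out / label
    adir.mkdir(parents=True, exist_ok=True)
    sel = select(images)
    rcfg = ResamplingConfig(
        n_perm=cfg.n_perm, n_boot=cfg.n_boot,
        bsr_threshold=cfg.bsr_threshold,
        rng_seed=stage_seed(cfg, "resampling"))

    M = matrix_fn(sel)
    lvs = pls_svd(M)
    perm_p = permutation_test(sel, matrix_fn, rcfg)
    rels = bootstrap_reliability(sel, matrix_fn, rcfg, lvs)

    total = sum(lv.singular_value ** 2 for lv in lvs)
    lv_rows = []
    peak_frames = []
    for lv, rel in zip(lvs, rels):
        lv_rows.append((lv.index, lv.singular_value,
                        100.0 * lv.singular_value ** 2 / total if total else 0.0,
                        float(perm_p[lv.index])))
        save_map(lv.voxel_saliences, sel.grid,
                 adir / f"lv{lv.index}_salience.nii")
        save_map(np.nan_to_num(rel.bsr, posinf=1e6, neginf=-1e6),
                 sel.grid, adir / f"lv{lv.index}_bsr.nii")
        peak_frames.append(find_peaks(rel, sel.grid,
                                      min_sep_mm=cfg.min_sep_mm))
    _write_tsv(pd.DataFrame(
        lv_rows, columns=["lv", "singular_value", "pct_covariance", "perm_p"]
    ), adir / "lv_table.tsv")
    _write_tsv(pd.DataFrame(
        {f"lv{lv.index}": lv.task_saliences for lv in lvs}
    ).assign(condition=sel.conditions), adir / "task_saliences.tsv")
    if analysis in ("repetition", "targetness"):
        dm = build_datamat(sel)
        scores = {f"lv{lv.index}_{c}": compute_brain_scores(dm, lv)[:, ci]
                  for lv in lvs for ci, c in enumerate(sel.conditions)}
        _write_tsv(pd.DataFrame(scores).assign(subject=sel.subjects),
                   adir / "brain_scores.tsv")
    _write_tsv(pd.concat(peak_frames, ignore_index=True),
               adir / "peaks.tsv")
    return {"conditions": list(sel.conditions),
            "n_lvs": len(lvs),
            "perm_p": [float(p) for p in perm_p[:len(lvs)]],
            "files": sorted(p.name for p in adir.iterdir())}


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage and write the manifest; idempotent per config."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest(),
        "stage_seeds": {s: stage_seed(cfg, s) for s in STAGE_SEED_OFFSETS},
        "stages": {},
    }
    log.info("stage: behavior")
    manifest["stages"]["behavior"] = stage_behavior(cfg, out / "behavior")
    log.info("stage: images")
    images, rec = stage_images(cfg, out / "images")
    manifest["stages"]["images"] = rec
    for analysis in cfg.analyses:
        log.info("stage: analysis %s", analysis)
        manifest["stages"][analysis] = stage_analysis(
            cfg, analysis, images, out)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
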