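"""End-to-end orchestration of the release-from-adaptation pipeline.

Stages: similarity norms -> binning -> experiment design -> (simulate or
load) BOLD runs -> FIR adaptation GLM and 4th>7th-bin mask -> HRF release
GLM -> voxel-wise similarity regression -> sign-flip TFCE permutation ->
positive-slope release mask -> leave-one-out tuning-curve clustering and
cluster comparison -> behavioral RT analysis.  A manifest records the
configuration, every seed, per-stage wall time and SHA-256 hashes of the
written artifacts, so a rerun with the same configuration is bit-for-bit
traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .behavior import behavioral_report
from .clusters import (compare_clusters, consensus_mask, loo_cluster_rois,
                       select_k_calinski_harabasz, zscore_rows)
from .design import (build_behavioral_design, build_fmri_run, design_summary,
                     read_events_tsv, write_events_tsv)
from .glm import adaptation_contrast, build_fir_design, build_hrf_design, fit_glm
from .niftiio import read_mask, read_nifti, write_mask, write_nifti
from .norms import (assign_bins, cosine_similarity_matrix, load_feature_norms,
                    synthetic_feature_norms, write_binning_tsv, write_similarity_csv)
from .release import (TFCEParams, permutation_one_sample, positive_slope_mask,
                      voxelwise_release_regression)
from .simulate import (NoiseParams, RTGenParams, default_tuning_grid,
                       simulate_bold_run, simulate_rt_dataset)

logger = logging.getLogger(__name__)

STAGES = ("design", "behavior", "simulate", "glm", "release", "clusters")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "adaptune_out"
    # inputs
    norms_csv: str | None = None          # None -> bundled synthetic norms
    n_adaptors: int = 10
    # acquisition / simulation
    n_subjects: int = 20
    tr: float = 1.0
    grid_shape: tuple[int, int, int] = (12, 12, 8)
    noise: dict = field(default_factory=dict)         # NoiseParams overrides
    amplitude_subject_sd: float = 0.1
    subjects: list[dict] | None = None    # load mode: bold/mask/events/nuisance paths
    # adaptation GLM
    adaptation_alpha: float = 0.001
    adaptation_bins: tuple[int, int] = (4, 7)
    # release inference
    n_perm: int = 1000
    fwe_alpha: float = 0.001
    stat: str = "r2"                      # "r2" (conventional) or "slope"
    tfce: dict = field(default_factory=dict)          # TFCEParams overrides
    # clustering
    k_range: tuple[int, int] = (2, 6)
    fixed_k: int | None = None
    consensus_threshold: float = 0.75
    # behavior
    run_behavioral: bool = True
    rt: dict = field(default_factory=dict)            # RTGenParams overrides

    def __post_init__(self) -> None:
        for a in (self.adaptation_alpha, self.fwe_alpha):
            if not 0 < a < 1:
                raise ValueError(f"alpha {a} outside (0, 1)")
        if self.stat not in ("r2", "slope"):
            raise ValueError("stat must be 'r2' or 'slope'")
        if self.norms_csv is not None and not Path(self.norms_csv).exists():
            raise FileNotFoundError(f"norms CSV not found: {self.norms_csv}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("grid_shape", "adaptation_bins", "k_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def demo_config(out_dir: str = "adaptune_out", seed: int = 0, **overrides) -> PipelineConfig:
    """A small, fast configuration exercising every stage on synthetic data."""
    defaults = dict(
        seed=seed, out_dir=out_dir, n_subjects=12, n_perm=1000,
        fwe_alpha=0.001, rt={"n_subjects": 12},
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: PipelineConfig, until: str = "clusters") -> dict:
    """Execute the pipeline through ``until`` and write artifacts + manifest."""
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; choose from {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    results: dict = {}
    stage_times: dict[str, float] = {}
    outputs: list[Path] = []

    def stage(name):
        class _Timer:
            def __enter__(self):
                logger.info("stage %s ...", name)
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                stage_times[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                else:
                    logger.info("stage %s done in %.2fs", name, stage_times[name])
        return _Timer()

    # --- design -----------------------------------------------------------
    with stage("design"):
        norms = (load_feature_norms(config.norms_csv) if config.norms_csv
                 else synthetic_feature_norms(seed=config.seed))
        sim = cosine_similarity_matrix(norms)
        adaptors = [norms.object_ids[i * (len(norms.object_ids) // config.n_adaptors)]
                    for i in range(config.n_adaptors)]
        binnings = assign_bins(sim, adaptors, seed=config.seed)
        write_similarity_csv(sim, out / "similarity.csv")
        write_binning_tsv(binnings, sim, out / "binning.tsv")
        outputs += [out / "similarity.csv", out / "binning.tsv"]
        behavioral_trials = build_behavioral_design(binnings, seed=config.seed + 1)
        results["design_summary"] = design_summary(behavioral_trials)
    if until == "design":
        return _finish(config, results, stage_times, outputs, out)

    # --- behavior ---------------------------------------------------------
    if config.run_behavioral:
        with stage("behavior"):
            rt_params = RTGenParams(**{"seed": config.seed + 2, **config.rt})
            rt_table = simulate_rt_dataset(behavioral_trials, rt_params)
            rt_table.to_csv(out / "rt_trials.csv", index=False)
            outputs.append(out / "rt_trials.csv")
            results["behavior"] = behavioral_report(rt_table)
    if until == "behavior":
        return _finish(config, results, stage_times, outputs, out)

    # --- simulate / load --------------------------------------------------
    with stage("simulate"):
        runs = []
        if config.subjects:  # load mode
            for sub in config.subjects:
                vol = read_nifti(sub["bold"], sub.get("mask"))
                events = read_events_tsv(sub["events"])
                nuis = None
                if sub.get("nuisance"):
                    import pandas as pd
                    nuis = pd.read_csv(sub["nuisance"], sep="\t")
                runs.append((events, vol, nuis))
            grid = None
        else:
            grid = default_tuning_grid(config.grid_shape)
            noise = NoiseParams(**config.noise)
            for s in range(config.n_subjects):
                events = build_fmri_run(binnings, seed=config.seed + 100 + s)
                scale = float(1.0 + config.amplitude_subject_sd * rng.standard_normal())
                vol, nuis = simulate_bold_run(
                    events, grid, noise=noise, tr=config.tr,
                    seed=config.seed + 1000 + s, amplitude_scale=max(scale, 0.1),
                )
                runs.append((events, vol, nuis))
            write_events_tsv(runs[0][0], out / "events_example.tsv")
            outputs.append(out / "events_example.tsv")
        results["n_runs"] = len(runs)
    if until == "simulate":
        return _finish(config, results, stage_times, outputs, out)

    # --- GLMs and adaptation mask ----------------------------------------
    with stage("glm"):
        fir_betas, hrf_betas = [], []
        for events, vol, nuis in runs:
            Xf = build_fir_design(events, vol.n_vols, config.tr, nuis)
            fir_betas.append(fit_glm(vol, Xf))
            Xh = build_hrf_design(events, vol.n_vols, config.tr, nuis)
            hrf_betas.append(fit_glm(vol, Xh))
        fmap, adapt_mask = adaptation_contrast(
            fir_betas, alpha=config.adaptation_alpha, bins=config.adaptation_bins)
        if not adapt_mask.any():
            raise RuntimeError("glm stage produced an empty adaptation mask")
        affine = runs[0][1].affine
        write_mask(adapt_mask, out / "adaptation_mask.nii.gz", affine)
        outputs.append(out / "adaptation_mask.nii.gz")
        results["adaptation_mask_voxels"] = int(adapt_mask.sum())
    if until == "glm":
        return _finish(config, results, stage_times, outputs, out)

    # --- release inference ------------------------------------------------
    with stage("release"):
        rel = [voxelwise_release_regression(b, adapt_mask) for b in hrf_betas]
        stat_maps = [(r.r2 if config.stat == "r2" else r.slope) for r in rel]
        perm = permutation_one_sample(
            [np.nan_to_num(m) for m in stat_maps], adapt_mask,
            n_perm=config.n_perm, params=TFCEParams(**config.tfce),
            alpha=config.fwe_alpha, seed=config.seed + 5,
        )
        mean_slope = np.full(adapt_mask.shape, np.nan)
        mean_slope[adapt_mask] = np.mean(
            np.stack([r.slope[adapt_mask] for r in rel]), axis=0)
        release_mask = positive_slope_mask(perm.significant, mean_slope)
        if not release_mask.any():
            raise RuntimeError("release stage produced an empty release mask")
        write_mask(release_mask, out / "release_mask.nii.gz", affine)
        np.savetxt(out / "null_max_tfce.csv", perm.null_max, delimiter=",")
        outputs += [out / "release_mask.nii.gz", out / "null_max_tfce.csv"]
        results["release_mask_voxels"] = int(release_mask.sum())
        results["_release_mask"] = release_mask
        results["_adaptation_mask"] = adapt_mask
    if until == "release":
        return _finish(config, results, stage_times, outputs, out)

    # --- tuning clusters --------------------------------------------------
    with stage("clusters"):
        subject_betas = np.stack(
            [np.stack([b.beta(c)[release_mask] for c in ("SC", "C", "D", "SD")])
             for b in hrf_betas])
        group_curves = zscore_rows(subject_betas.mean(axis=0).T)
        sel = select_k_calinski_harabasz(
            group_curves, k_range=range(config.k_range[0], config.k_range[1] + 1),
            seed=config.seed + 6)
        k = config.fixed_k or sel.k
        sols = loo_cluster_rois(subject_betas, k, seed=config.seed + 7)
        cons = consensus_mask(sols, config.consensus_threshold)
        identity = np.stack([
            [b.beta("I")[release_mask][sols[s].labels == c].mean()
             if (sols[s].labels == c).any() else np.nan for c in range(1, k + 1)]
            for s, b in enumerate(hrf_betas)])
        heldout = np.stack([s.heldout_curves for s in sols])
        comparison = compare_clusters(heldout, identity=identity)
        for c, m in cons.items():
            full = np.zeros(release_mask.shape, bool)
            full[release_mask] = m
            write_mask(full, out / f"cluster_{c}_consensus.nii.gz", affine)
            outputs.append(out / f"cluster_{c}_consensus.nii.gz")
        if k >= 2:
            from .viz import plot_tuning_curves
            plot_tuning_curves(comparison, out / "tuning_curves.png")
            outputs.append(out / "tuning_curves.png")
        results["k_selected"] = sel.k
        results["k_used"] = k
        results["ch_scores"] = sel.scores
        results["cluster_comparison"] = {
            "excluded_subjects": comparison.excluded_subjects,
            "slope_means": comparison.slopes.mean(axis=0).tolist(),
            "slope_t": comparison.slope_t,
            "slope_p_one_tailed": comparison.slope_p_one_tailed,
            "wilcoxon_p": comparison.wilcoxon_p,
        }
        results["_solutions"] = sols
        results["_consensus"] = cons
        results["_comparison"] = comparison
    return _finish(config, results, stage_times, outputs, out)


def _finish(config, results, stage_times, outputs, out: Path) -> dict:
    report = {k: _to_jsonable(v) for k, v in results.items() if not k.startswith("_")}
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    manifest = {
        "package_version": __version__,
        "config": _to_jsonable(asdict(config)),
        "stages_seconds": stage_times,
        "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    results["report"] = report
    return results
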