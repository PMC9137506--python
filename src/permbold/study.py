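"""End-to-end study orchestration.

One configuration drives the whole analysis: simulate a two-group
cohort, fit every subject's GLM, smooth and median the maps, build the
permutation null (B runs; together with the true analysis that is B + 1
group-map computations), derive the six FWER thresholds, extract
significant clusters, and run the PCA / sparse-PCA group comparison.
Every output is reachable from a manifest keyed by the master seed, and
a fixed configuration reproduces every file bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .difference import (ResponsePCA, build_response_matrix,
                         eigenimage_to_volume)
from .errors import ConfigurationError
from .glm import gamma_hrf
from .permutation import (DEFAULT_ALPHAS, PermutationEngine,
                          compute_thresholds, extract_clusters, threshold_map)
from .simulate import (GROUPS, TaskConfig, default_cohort_spec,
                       generate_cohort, write_cohort)
from .summary_stats import t_from_samples, variant_select, summarize

logger = logging.getLogger("permbold")

__all__ = ["StudyConfig", "StudyReport", "validate_config", "run_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Complete, serialisable description of one simulated study."""

    # task
    n_trials: int = 200
    nogo_fraction: float = 0.20
    tr_seconds: float = 2.0
    # cohort
    n_per_group: int = 15
    effect: float = 0.5
    noise_sd: float = 1.0
    base_amplitude: float = 1.0
    grid_shape: tuple[int, int, int] = (16, 16, 12)
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 3.5)
    # subject GLM
    hrf_peak_seconds: float = 6.0
    hrf_dispersion: float = 0.7
    hrf_kernel_length: int = 16
    mask_fraction: float = 0.4
    # group / permutation
    smoothing_sd_mm: float = 3.0
    B: int = 1000
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    min_cluster_mm3: float = 100.0
    connectivity: int = 18
    # group difference
    K: int = 10
    sparsity: float = 0.5          # target nonzero fraction for sparse PCA
    # bookkeeping
    master_seed: int = 0
    output_dir: str = "study_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        d["alphas"] = list(self.alphas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key in ("grid_shape", "voxel_size_mm", "alphas"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def validate_config(cfg: StudyConfig) -> list[dict]:
    """Blocking errors and advisory warnings for a study configuration."""
    findings: list[dict] = []

    def err(msg):
        findings.append({"level": "error", "message": msg})

    def warn(msg):
        findings.append({"level": "warning", "message": msg})

    if cfg.n_trials < 1:
        err("n_trials must be >= 1")
    if not 0 <= cfg.nogo_fraction <= 1:
        err("nogo_fraction must be in [0, 1]")
    if cfg.noise_sd < 0:
        err("noise_sd must be non-negative")
    if cfg.n_per_group < 1:
        err("n_per_group must be >= 1")
    if cfg.B < 1:
        err("B must be >= 1")
    if any(not 0 < a < 1 for a in cfg.alphas):
        err("alphas must lie in (0, 1)")
    if cfg.connectivity not in (6, 18, 26):
        err("connectivity must be 6, 18 or 26")
    if cfg.min_cluster_mm3 < 0:
        err("min_cluster_mm3 must be non-negative")
    if cfg.K > 2 * cfg.n_per_group - 1:
        err(f"K={cfg.K} exceeds the n-1 limit for {2 * cfg.n_per_group} subjects")
    if not 0 < cfg.sparsity <= 1:
        err("sparsity (target nonzero fraction) must be in (0, 1]")
    if cfg.alphas and cfg.B >= 1:
        amin = min(cfg.alphas)
        if cfg.B < np.ceil(1.0 / amin):
            warn(
                f"B={cfg.B} permutations resolve map-wide exceedance "
                f"probabilities only down to 1/B={1 / cfg.B:.3g}; the "
                f"requested alpha={amin} needs B >= {int(np.ceil(1 / amin))} "
                "for the empirical tail probability to fall strictly below "
                "alpha")
    return findings


@dataclass(frozen=True)
class StudyReport:
    """Paths and headline numbers of one completed study."""

    config: StudyConfig
    paths: dict
    n_group_maps: int
    thresholds: dict
    n_clusters: int
    n_significant_voxels: int
    cluster_table: pd.DataFrame
    component_tests: pd.DataFrame
    pc1_variance: float
    sparse_nnz: int
    report_hash: str = ""


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-18s %6.2f s", name, t1 - t0)
    return t1


def run_study(cfg: StudyConfig) -> StudyReport:
    """Execute every stage in pipeline order and write all outputs."""
    import nibabel as nib

    findings = validate_config(cfg)
    errors = [f["message"] for f in findings if f["level"] == "error"]
    if errors:
        raise ConfigurationError("invalid study config: " + "; ".join(errors))
    for f in findings:
        logger.warning("config: %s", f["message"])

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(cfg.voxel_size_mm) + [1.0])
    t0 = time.perf_counter()

    # 1. simulate -----------------------------------------------------------
    task = TaskConfig(n_trials=cfg.n_trials, nogo_fraction=cfg.nogo_fraction,
                      tr_seconds=cfg.tr_seconds, seed=cfg.master_seed)
    spec = default_cohort_spec(
        n_per_group=cfg.n_per_group, effect=cfg.effect, noise_sd=cfg.noise_sd,
        base_amplitude=cfg.base_amplitude, grid_shape=cfg.grid_shape,
        voxel_size_mm=cfg.voxel_size_mm, seed=cfg.master_seed)
    cohort = generate_cohort(spec, task)
    manifest_path = write_cohort(cohort, spec, out / "cohort")
    t0 = _stage("simulate", t0)

    # 2-3. subject maps -> smoothed -> true group median --------------------
    hrf = gamma_hrf(cfg.hrf_peak_seconds, cfg.hrf_dispersion,
                    cfg.tr_seconds, cfg.hrf_kernel_length)
    engine = PermutationEngine(cohort, hrf=hrf, mask_fraction=cfg.mask_fraction,
                               smoothing_sd_mm=cfg.smoothing_sd_mm,
                               voxel_size_mm=cfg.voxel_size_mm)
    subject_maps = engine.subject_maps()
    group = engine.group_map()
    nib.save(nib.Nifti1Image(group.median_map.astype(np.float32), affine),
             out / "group_median.nii")
    t0 = _stage("subject+group map", t0)

    # 4. permutation null and thresholds ------------------------------------
    null = engine.null_distribution(cfg.B, cfg.master_seed)
    thresholds = compute_thresholds(null, cfg.alphas)
    (out / "null_distribution.json").write_text(json.dumps({
        "B": null.B, "master_seed": null.master_seed,
        "maxima": null.maxima.tolist(), "minima": null.minima.tolist(),
    }, sort_keys=True))
    thr_dict = {"upper": {str(a): thresholds.upper[a] for a in cfg.alphas},
                "lower": {str(a): thresholds.lower[a] for a in cfg.alphas}}
    (out / "thresholds.json").write_text(json.dumps(thr_dict, sort_keys=True,
                                                    indent=2))
    t0 = _stage("permutation null", t0)

    # 5. threshold + clusters ------------------------------------------------
    sig = threshold_map(group.median_map, thresholds)
    sig[~engine.group_mask] = 0
    nib.save(nib.Nifti1Image(sig.astype(np.int16), affine),
             out / "significance.nii")
    clusters = extract_clusters(sig, cfg.voxel_size_mm,
                                connectivity=cfg.connectivity,
                                min_size_mm3=cfg.min_cluster_mm3,
                                stat_map=group.median_map, affine=affine)
    cluster_table = pd.DataFrame([{
        "sign": c.sign, "size_voxels": c.size_voxels,
        "size_mm3": round(c.size_mm3, 3),
        "peak_i": c.peak_coord[0], "peak_j": c.peak_coord[1],
        "peak_k": c.peak_coord[2],
        "peak_x_mm": c.peak_mm[0], "peak_y_mm": c.peak_mm[1],
        "peak_z_mm": c.peak_mm[2],
        "peak_value": c.peak_value, "tier": c.tier, "label": c.label,
    } for c in clusters])
    cluster_table.to_csv(out / "clusters.tsv", sep="\t", index=False)
    t0 = _stage("clusters", t0)

    # 6. group difference ----------------------------------------------------
    n_sig = int(np.count_nonzero(sig))
    pca_summary: dict = {"n_significant_voxels": n_sig}
    component_tests = pd.DataFrame()
    pc1_var = float("nan")
    sparse_nnz = 0
    if n_sig > 0:
        groups = [ds.group for ds in cohort]
        R = build_response_matrix(subject_maps, sig, groups)
        K = min(cfg.K, R.n_subjects - 1, R.p_voxels)
        results = ResponsePCA(R, groups=GROUPS).fit(K=K)
        component_tests = results.component_tests
        pc1_var = float(results.pcs.explained_variance_ratio[0])
        sp = results.sparse(target_nnz_fraction=cfg.sparsity)
        sparse_nnz = sp.nnz
        scores = pd.DataFrame(results.pcs.scores,
                              columns=[f"u{k + 1}" for k in range(K)])
        scores.insert(0, "subject_id", [ds.subject_id for ds in cohort])
        scores.insert(1, "group", groups)
        scores.to_csv(out / "pc_scores.tsv", sep="\t", index=False)
        component_tests.to_csv(out / "component_tests.tsv", sep="\t",
                               index=False)
        nib.save(nib.Nifti1Image(
            eigenimage_to_volume(results.pcs.loadings[:, 0], R.voxel_index,
                                 cfg.grid_shape).astype(np.float32), affine),
            out / "eigenimage1.nii")
        nib.save(nib.Nifti1Image(
            eigenimage_to_volume(sp.v, R.voxel_index,
                                 cfg.grid_shape).astype(np.float32), affine),
            out / "sparse_eigenimage1.nii")
        pca_summary.update({
            "pc1_explained_variance": pc1_var,
            "u1_U": float(component_tests.iloc[0]["U"]),
            "u1_p": float(component_tests.iloc[0]["p"]),
            "sparse_nnz": sparse_nnz,
            "sparse_c": sp.c,
            "sparse_reduction_pct": 100.0 * (1 - sparse_nnz / R.p_voxels),
        })
    t0 = _stage("group difference", t0)

    # 7. behavioural stats on the simulated cohort ---------------------------
    perf_rows = []
    for ds in cohort:
        go_total = ds.Z[:, 0].sum() + ds.Z[:, 2].sum()
        nogo_total = ds.Z[:, 1].sum() + ds.Z[:, 3].sum()
        perf_rows.append({
            "subject_id": ds.subject_id, "group": ds.group,
            "go_accuracy": ds.Z[:, 0].sum() / max(go_total, 1),
            "nogo_accuracy": ds.Z[:, 1].sum() / max(nogo_total, 1),
        })
    perf = pd.DataFrame(perf_rows)
    perf.to_csv(out / "performance.tsv", sep="\t", index=False)
    behaviour = {}
    for var in ("go_accuracy", "nogo_accuracy"):
        x1 = perf.loc[perf.group == GROUPS[0], var]
        x2 = perf.loc[perf.group == GROUPS[1], var]
        variant = variant_select(summarize(x1), summarize(x2))
        res = t_from_samples(x1, x2, variant)
        behaviour[var] = {"t": res.t, "df": res.df, "p": res.p,
                          "variant": res.variant}
    t0 = _stage("behaviour stats", t0)

    # report -----------------------------------------------------------------
    paths = {
        "manifest": str(manifest_path),
        "group_median": str(out / "group_median.nii"),
        "null_distribution": str(out / "null_distribution.json"),
        "thresholds": str(out / "thresholds.json"),
        "significance": str(out / "significance.nii"),
        "clusters": str(out / "clusters.tsv"),
        "performance": str(out / "performance.tsv"),
    }
    if n_sig > 0:
        paths.update({
            "pc_scores": str(out / "pc_scores.tsv"),
            "component_tests": str(out / "component_tests.tsv"),
            "eigenimage1": str(out / "eigenimage1.nii"),
            "sparse_eigenimage1": str(out / "sparse_eigenimage1.nii"),
        })
    report = {
        "config": cfg.to_dict(),
        "n_group_maps": cfg.B + 1,
        "thresholds": thr_dict,
        "n_clusters": len(clusters),
        "n_significant_voxels": n_sig,
        "clusters": cluster_table.to_dict(orient="records"),
        "pca": pca_summary,
        "behaviour": behaviour,
        "component_tests": component_tests.to_dict(orient="records"),
        "paths": {k: str(Path(v).name) for k, v in paths.items()},
    }
    text = json.dumps(report, sort_keys=True, indent=2, default=float)
    (out / "report.json").write_text(text)
    digest = hashlib.sha256(text.encode()).hexdigest()
    return StudyReport(
        config=cfg, paths=paths, n_group_maps=cfg.B + 1,
        thresholds=thr_dict, n_clusters=len(clusters),
        n_significant_voxels=n_sig, cluster_table=cluster_table,
        component_tests=component_tests, pc1_variance=pc1_var,
        sparse_nnz=sparse_nnz, report_hash=digest)
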