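"""End-to-end orchestration: config, the full pipeline, and the phantom study.

``run_pipeline`` executes skeletonization -> feature extraction -> PCA ->
clustering (k-means or hybrid, fixed k or elbow-selected) -> semantic
ordering -> lesion calling on a CT volume + vessel mask, and writes a
label volume, a calls JSON and a run manifest.  ``run_phantom_study``
generates a battery of synthetic diseased cases, runs both clustering
algorithms on each, scores them at the plaque level against the planted
truth, and compares their per-case F1 scores with a paired t test.

A single user seed fans out to per-stage seeds through a stable
blake2-based hash, so stage-level reruns are reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .volume_io import (CTVolume, VesselMask, read_ct_volume, read_mask,
                        quantize_hu, write_label_volume)
from .phantom import (PhantomCase, default_diseased_spec, generate_phantom)
from .skeleton import extract_skeleton, local_frames
from .texture_features import extract_feature_table
from .clustering import (pca_reduce, kmeans_cluster, hybrid_cluster,
                         select_k_elbow, order_clusters_semantic)
from .lesion_calling import (CallingParams, call_lesions, calls_to_json,
                             calls_to_label_volume, expected_radius_profile)
from .evaluation import (match_calls_to_truth, detection_metrics,
                         ffr_concordance, matched_hausdorff_mm, paired_compare)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "run_phantom_study", "derive_stage_seed"]

log = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, serializable to/from YAML."""

    schema_version: int = CONFIG_SCHEMA_VERSION
    # quantization
    n_levels: int = 32
    hu_min: float = -1000.0
    hu_max: float = 3000.0
    # skeleton
    prune_length_mm: float = 3.0
    # features
    max_assign_mm: float = 10.0
    # PCA / clustering
    variance_fraction: float = 0.95
    algorithm: str = "hybrid"          # "kmeans" | "hybrid"
    k: int | str = 5                   # int or "auto" (elbow selection)
    k_min: int = 2
    k_max: int = 10
    k_pre: int = 50
    seed: int = 0
    # lesion calling
    calcified_hu_threshold: float = 500.0
    min_lesion_mm: float = 2.0
    soft_deviation_min: float = 0.25
    merge_gap_mm: float = 2.0
    sig_severity_min: float = 0.50
    # evaluation
    min_overlap_mm: float = 1.0
    tile_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.algorithm not in ("kmeans", "hybrid"):
            raise ValueError("algorithm must be 'kmeans' or 'hybrid'")
        if self.k != "auto" and (not isinstance(self.k, int) or self.k < 1):
            raise ValueError("k must be a positive integer or 'auto'")
        if self.schema_version != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema_version {self.schema_version}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def calling_params(self) -> CallingParams:
        return CallingParams(
            min_lesion_mm=self.min_lesion_mm,
            soft_deviation_min=self.soft_deviation_min,
            merge_gap_mm=self.merge_gap_mm,
            sig_severity_min=self.sig_severity_min,
            calcified_hu_threshold=self.calcified_hu_threshold,
        )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def derive_stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    h = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "big") % (2 ** 31)


@dataclass
class PipelineResult:
    labels_volume: np.ndarray
    calls: list
    labeling: object
    table: object
    skel: object
    profile: object
    selected_k: int
    wcss: dict | None
    manifest: dict


def run_pipeline(ct, mask, config: PipelineConfig | None = None,
                 out_dir=None) -> PipelineResult:
    """Run the full lesion-characterization pipeline.

    ``ct`` / ``mask`` may be paths to NIfTI files or in-memory
    :class:`CTVolume` / :class:`VesselMask` objects.
    """
    config = config or PipelineConfig()
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    times = manifest["stages"]

    def _stage(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, exc_type, exc, tb):
                times[name] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None:
                    manifest["failed_stage"] = name
                return False
        return _T()

    try:
        with _stage("read"):
            if not isinstance(ct, CTVolume):
                ct = read_ct_volume(ct)
            if not isinstance(mask, VesselMask):
                mask = read_mask(mask, ct)
            if mask.is_empty:
                raise ValueError("empty mask")
        with _stage("quantize"):
            quant = quantize_hu(ct, n_levels=config.n_levels,
                                hu_min=config.hu_min, hu_max=config.hu_max)
        with _stage("skeleton"):
            skel = extract_skeleton(mask, prune_length_mm=config.prune_length_mm)
            local_frames(skel)
        with _stage("profile"):
            profile = expected_radius_profile(
                skel.arc_mm, skel.radius_mm,
                point_index=np.arange(skel.n_points))
        with _stage("features"):
            expected = np.empty(skel.n_points)
            expected[profile.point_index] = profile.expected_mm
            table = extract_feature_table(
                ct, quant, mask, skel,
                max_assign_mm=config.max_assign_mm,
                expected_radius=expected)
        with _stage("pca"):
            red = pca_reduce(table, variance_fraction=config.variance_fraction)
        with _stage("cluster"):
            seed = derive_stage_seed(config.seed, "cluster")
            wcss = None
            if config.k == "auto":
                k, wcss = select_k_elbow(red, k_min=config.k_min,
                                         k_max=config.k_max, seed=seed)
            else:
                k = int(config.k)
            if config.algorithm == "kmeans":
                labeling = kmeans_cluster(red, k, seed=seed)
            else:
                k_pre = min(config.k_pre, red.n_rows)
                labeling = hybrid_cluster(red, k_pre=max(k_pre, k),
                                          k_final=k, seed=seed)
            labeling = order_clusters_semantic(
                labeling, table,
                calcified_hu_threshold=config.calcified_hu_threshold)
        with _stage("call"):
            calls = call_lesions(labeling, table, skel, profile,
                                 params=config.calling_params(),
                                 grid_shape=mask.shape)
            labels_volume = calls_to_label_volume(calls, mask.shape)
    finally:
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            (out_dir / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True))

    manifest["selected_k"] = int(k)
    if wcss is not None:
        manifest["wcss"] = {str(kk): v for kk, v in wcss.items()}
    manifest["semantic"] = {str(l): r for l, r in labeling.semantic.items()}
    manifest["explained_variance"] = [
        float(v) for v in red.explained_variance_fractions]
    manifest["n_calls"] = len(calls)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "calls.json").write_text(calls_to_json(calls))
        write_label_volume(labels_volume, ct, out_dir / "calls.nii.gz")
        # cluster label map: 0 background, 1..k clusters in semantic order
        order = sorted(labeling.semantic,
                       key=lambda l: (labeling.semantic[l] != "calcified",
                                      labeling.semantic[l]))
        rank_of = {lab: i + 1 for i, lab in enumerate(order)}
        cl_vol = np.zeros(mask.shape, dtype=np.int16)
        coords = table[["x", "y", "z"]].to_numpy(dtype=np.int64)
        cl_vol[tuple(coords.T)] = [rank_of[l] for l in labeling.labels]
        write_label_volume(cl_vol, ct, out_dir / "clusters.nii.gz",
                           semantic={str(rank_of[l]): r
                                     for l, r in labeling.semantic.items()})
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(labels_volume=labels_volume, calls=calls,
                          labeling=labeling, table=table, skel=skel,
                          profile=profile, selected_k=int(k), wcss=wcss,
                          manifest=manifest)


def _evaluate_case(result: PipelineResult, case: PhantomCase,
                   config: PipelineConfig) -> dict:
    cc = match_calls_to_truth(result.calls, case.truth,
                              min_overlap_mm=config.min_overlap_mm,
                              tile_mm=config.tile_mm)
    metrics = detection_metrics(cc)
    hd = matched_hausdorff_mm(result.calls, case.truth, cc, case.ct.spacing)
    conc = ffr_concordance(result.calls, case.truth, case.ffr,
                           min_overlap_mm=config.min_overlap_mm)
    return {"metrics": metrics, "hausdorff_mm": hd, "ffr": conc}


def run_phantom_study(n_cases: int = 10, seed: int = 1,
                      config: PipelineConfig | None = None,
                      spec_factory=default_diseased_spec) -> dict:
    """Generate ``n_cases`` phantoms and compare k-means vs hybrid.

    Both algorithms run on the same features per case; the per-case
    pooled and per-type F1 scores feed a paired t test.
    """
    if n_cases < 2:
        raise ValueError("paired comparison needs >= 2 cases")
    config = config or PipelineConfig()
    per_algo: dict[str, list] = {"kmeans": [], "hybrid": []}
    ffr_totals = {a: {"tp": 0, "fn": 0, "fp": 0, "tn": 0} for a in per_algo}
    hausdorff = {a: [] for a in per_algo}
    cases_meta = []
    for i in range(n_cases):
        case_seed = seed + i
        case = generate_phantom(spec_factory(seed=case_seed))
        for algo in ("kmeans", "hybrid"):
            cfg = dataclasses.replace(config, algorithm=algo, seed=case_seed)
            try:
                result = run_pipeline(case.ct, case.mask, cfg)
            except Exception as exc:
                raise RuntimeError(f"case {i} ({algo}) failed: {exc}") from exc
            ev = _evaluate_case(result, case, cfg)
            per_algo[algo].append(ev)
            for kk in ffr_totals[algo]:
                ffr_totals[algo][kk] += ev["ffr"][kk]
            hausdorff[algo].extend(ev["hausdorff_mm"].values())
        cases_meta.append({"seed": case_seed,
                           "n_lesions": len(case.truth.lesions)})

    report: dict = {"n_cases": n_cases, "seed": seed, "cases": cases_meta,
                    "algorithms": {}, "comparison": {}}
    for algo, evs in per_algo.items():
        agg: dict = {}
        for ptype in ("calcified", "soft", "mixed", "all"):
            vals = {m: float(np.mean([e["metrics"][ptype][m] for e in evs]))
                    for m in ("sensitivity", "specificity", "precision", "f1")}
            agg[ptype] = vals
        report["algorithms"][algo] = {
            "mean_metrics_pct": agg,
            "ffr_concordance": ffr_totals[algo],
            "mean_hausdorff_mm": (float(np.mean(hausdorff[algo]))
                                  if hausdorff[algo] else None),
        }
    for ptype in ("calcified", "soft", "mixed", "all"):
        f1_h = [e["metrics"][ptype]["f1"] for e in per_algo["hybrid"]]
        f1_k = [e["metrics"][ptype]["f1"] for e in per_algo["kmeans"]]
        cmp_ = paired_compare(f1_h, f1_k)
        report["comparison"][ptype] = {
            "t": cmp_.t, "p": cmp_.p, "df": cmp_.df,
            "mean_f1_diff_hybrid_minus_kmeans": cmp_.mean_diff,
            "ci95": list(cmp_.ci95), "degenerate": cmp_.degenerate,
        }
    return report
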