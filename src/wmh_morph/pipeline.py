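"""End-to-end orchestration: threshold, extract, features, cluster, PGI, ANOVA.

``run`` takes an intensity volume and a co-registered lesion mask (or
lesion-probability map), extracts per-slice lesion components, links them
into 3D lesions, computes Zernike shape features and fuzzy texture
histograms per lesion image, selects cluster counts with the gap
statistic, clusters (Euclidean for shape, Manhattan for texture), computes
the per-lesion potential growth index, and closes with one-way ANOVAs of
PGI across shape and texture clusters — including repeated-trial P-value
ranges over re-seeded K-means runs.

All randomness is derived from one master seed, so identical inputs and
configuration reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster_gap, lesion_io, pgi, shape_zernike, texture_fuzzy

__all__ = ["RunConfig", "RunReport", "run", "run_from_paths"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable parameters of a full analysis run.

    Defaults follow the reference protocol: probability threshold 0.5,
    components of more than 10 connected voxels, a 60x60 shape canvas with
    Zernike order <= 5 (12 magnitudes), 5 texture bins, gap statistic with
    N = 20 and B = 10, gamma = 1.02 with 3 layers for PGI, and 1000
    re-seeded clustering trials for the ANOVA stability check.
    """

    probability_threshold: float = 0.5
    min_voxels: int = 10
    connectivity: int = 8
    slice_axis: int = 2
    shape_canvas: int = 60
    shape_max_order: int = 5
    texture_bins: int = 5
    texture_per_component: bool = True
    shape_metric: str = "euclidean"
    texture_metric: str = "manhattan"
    gap_max_k: int = 20
    gap_n_ref: int = 10
    kmeans_n_init: int = 10
    gamma: float = 1.02
    n_layers: int = 3
    trials: int = 1000
    master_seed: int = 0
    probability_input: bool | None = None  # None: auto-detect binary vs probability

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)


@dataclass
class RunReport:
    config: RunConfig
    components: list
    lesions3d: list
    components_df: pd.DataFrame
    lesions3d_df: pd.DataFrame
    shape_features: pd.DataFrame
    texture_features: pd.DataFrame
    shape_gap: cluster_gap.GapCurve
    texture_gap: cluster_gap.GapCurve
    clusters: pd.DataFrame
    pgi_df: pd.DataFrame
    shape_anova: pgi.AnovaResult | None
    texture_anova: pgi.AnovaResult | None
    trial_summary: dict
    written: dict = field(default_factory=dict)


def _resolve_mask(mask_or_pmap: np.ndarray, config: RunConfig) -> np.ndarray:
    arr = np.asarray(mask_or_pmap)
    is_prob = config.probability_input
    if is_prob is None:
        vals = np.unique(arr)
        is_prob = not (arr.dtype == bool or np.isin(vals, (0, 1)).all())
    if is_prob:
        return lesion_io.threshold_probability_map(arr, config.probability_threshold)
    return arr.astype(bool)


def _anova_filtered(values: np.ndarray, labels: np.ndarray) -> pgi.AnovaResult | None:
    """ANOVA dropping clusters with fewer than two members; None if < 2 remain."""
    labels = np.asarray(labels)
    keep_labels = [lab for lab in np.unique(labels) if (labels == lab).sum() >= 2]
    if len(keep_labels) < 2:
        return None
    keep = np.isin(labels, keep_labels)
    return pgi.anova_pgi_by_cluster(values[keep], labels[keep])


def run(
    volume: np.ndarray | lesion_io.IntensityVolume,
    mask_or_pmap: np.ndarray,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    subject_id: str = "subject",
) -> RunReport:
    """Full analysis of one study volume; optionally writes a report bundle."""
    config = config or RunConfig()
    if isinstance(volume, lesion_io.IntensityVolume):
        vol = volume.voxels
        slice_axis = volume.slice_axis
    else:
        vol = np.asarray(volume, dtype=np.float64)
        slice_axis = config.slice_axis
    mask_arr = np.asarray(mask_or_pmap)
    if mask_arr.shape != vol.shape:
        raise ValueError(
            f"volume grid {vol.shape} does not match mask grid {mask_arr.shape}"
        )
    mask = _resolve_mask(mask_arr, config)

    components = lesion_io.extract_lesions_volume(
        mask,
        min_voxels=config.min_voxels,
        connectivity=config.connectivity,
        slice_axis=slice_axis,
    )
    if not components:
        raise ValueError("no lesion components above the size filter; nothing to analyze")
    logger.info("extracted %d 2D components", len(components))
    lesions3d = lesion_io.build_lesions_3d(components, vol, slice_axis=slice_axis)
    logger.info("linked into %d 3D lesions", len(lesions3d))
    parent = {}
    for les in lesions3d:
        for comp in les.components:
            parent[comp.lesion_id] = les

    # --- shape features (per 2D lesion image) ---
    shape_cols = shape_zernike.feature_names(config.shape_max_order)
    shape_rows = []
    for comp in components:
        norm = shape_zernike.normalize_shape(comp, side=config.shape_canvas)
        vec = shape_zernike.shape_feature_vector(
            shape_zernike.zernike_moments(norm, max_order=config.shape_max_order)
        )
        shape_rows.append([comp.lesion_id, *vec])
    shape_features = pd.DataFrame(shape_rows, columns=["component_id", *shape_cols])
    shape_x = shape_features[shape_cols].to_numpy()

    # --- texture features ---
    tex_cols = [f"bin_{j}" for j in range(config.texture_bins)]
    tex_rows = []
    if config.texture_per_component:
        for les in lesions3d:
            hists = texture_fuzzy.texture_histograms_by_component(les, n=config.texture_bins)
            for comp, hist in zip(les.components, hists):
                tex_rows.append([comp.lesion_id, *hist.normalized])
        texture_features = (
            pd.DataFrame(tex_rows, columns=["component_id", *tex_cols])
            .sort_values("component_id", ignore_index=True)
        )
        tex_ids = texture_features["component_id"].to_numpy()
    else:
        for les in lesions3d:
            hist = texture_fuzzy.texture_histogram(les, n=config.texture_bins)
            tex_rows.append([les.lesion_id, *hist.normalized])
        texture_features = pd.DataFrame(tex_rows, columns=["lesion3d_id", *tex_cols])
        tex_ids = texture_features["lesion3d_id"].to_numpy()
    texture_x = texture_features[tex_cols].to_numpy()

    # --- cluster-count selection and clustering ---
    seeds = np.random.default_rng(config.master_seed).integers(0, 2**31 - 1, size=6)
    shape_gap = cluster_gap.gap_statistic(
        shape_x, n_max=config.gap_max_k, n_ref=config.gap_n_ref,
        seed=int(seeds[0]), metric=config.shape_metric, n_init=config.kmeans_n_init,
    )
    texture_gap = cluster_gap.gap_statistic(
        texture_x, n_max=config.gap_max_k, n_ref=config.gap_n_ref,
        seed=int(seeds[1]), metric=config.texture_metric, n_init=config.kmeans_n_init,
    )
    logger.info("gap statistic: shape k_opt=%d, texture k_opt=%d",
                shape_gap.k_opt, texture_gap.k_opt)
    shape_labels = cluster_gap.kmeans(
        shape_x, shape_gap.k_opt, seed=int(seeds[2]), metric=config.shape_metric,
        n_init=config.kmeans_n_init,
    ).labels
    texture_labels_rows = cluster_gap.kmeans(
        texture_x, texture_gap.k_opt, seed=int(seeds[3]), metric=config.texture_metric,
        n_init=config.kmeans_n_init,
    ).labels

    comp_ids = np.array([c.lesion_id for c in components])
    if config.texture_per_component:
        tex_label_by_comp = dict(zip(tex_ids, texture_labels_rows))
    else:
        by_lesion = dict(zip(tex_ids, texture_labels_rows))
        tex_label_by_comp = {
            comp.lesion_id: by_lesion[les.lesion_id]
            for les in lesions3d
            for comp in les.components
        }
    texture_labels = np.array([tex_label_by_comp[i] for i in comp_ids])
    clusters = pd.DataFrame(
        {
            "component_id": comp_ids,
            "shape_cluster": shape_labels,
            "texture_cluster": texture_labels,
        }
    )

    # --- potential growth index per 2D lesion image ---
    grid2d = np.take(vol, 0, axis=slice_axis).shape
    all_mask_by_slice: dict[int, np.ndarray] = {}
    for comp in components:
        sl_mask = all_mask_by_slice.setdefault(comp.slice_index, np.zeros(grid2d, dtype=bool))
        sl_mask[comp.voxels[:, 0], comp.voxels[:, 1]] = True
    pgi_rows = []
    for comp in components:
        les = parent[comp.lesion_id]
        own = comp.mask(grid2d)
        forbidden = all_mask_by_slice[comp.slice_index] & ~own
        result = pgi.pgi_for_lesion(
            own,
            np.take(vol, comp.slice_index, axis=slice_axis),
            gmax=les.gmax,
            gmin=les.gmin,
            gamma=config.gamma,
            n_layers=config.n_layers,
            forbidden=forbidden,
        )
        row = {"component_id": comp.lesion_id, "lesion3d_id": les.lesion_id}
        for i in range(config.n_layers):
            row[f"gv_{i + 1}"] = int(result.growth_per_layer[i])
            row[f"layer_size_{i + 1}"] = int(result.layer_sizes[i])
        row["p_g"] = result.p_g
        pgi_rows.append(row)
    pgi_df = pd.DataFrame(pgi_rows)
    pgi_values = pgi_df["p_g"].to_numpy()

    # --- ANOVA: PGI across clusters, plus re-seeded trial stability ---
    shape_anova = _anova_filtered(pgi_values, shape_labels)
    texture_anova = _anova_filtered(pgi_values, texture_labels)
    trial_summary = {}
    for name, x, k, metric, seed in (
        ("shape", shape_x, shape_gap.k_opt, config.shape_metric, int(seeds[4])),
        ("texture", texture_x, texture_gap.k_opt, config.texture_metric, int(seeds[5])),
    ):
        trial_labels = cluster_gap.stability_trials(
            x, k, trials=config.trials, seed=seed, metric=metric
        )
        ps, fs = [], []
        for t in range(trial_labels.shape[0]):
            if name == "texture" and not config.texture_per_component:
                by_lesion = dict(zip(tex_ids, trial_labels[t]))
                labels_t = np.array(
                    [by_lesion[parent[i].lesion_id] for i in comp_ids]
                )
            else:
                labels_t = trial_labels[t]
            res = _anova_filtered(pgi_values, labels_t)
            if res is not None and np.isfinite(res.p):
                ps.append(res.p)
                fs.append(res.f)
        trial_summary[name] = {
            "trials": int(config.trials),
            "valid_trials": len(ps),
            "p_min": float(np.min(ps)) if ps else float("nan"),
            "p_max": float(np.max(ps)) if ps else float("nan"),
            "f_min": float(np.min(fs)) if fs else float("nan"),
            "f_max": float(np.max(fs)) if fs else float("nan"),
        }

    report = RunReport(
        config=config,
        components=components,
        lesions3d=lesions3d,
        components_df=lesion_io.components_table(components, subject_id),
        lesions3d_df=lesion_io.lesions3d_table(lesions3d, subject_id),
        shape_features=shape_features,
        texture_features=texture_features,
        shape_gap=shape_gap,
        texture_gap=texture_gap,
        clusters=clusters,
        pgi_df=pgi_df,
        shape_anova=shape_anova,
        texture_anova=texture_anova,
        trial_summary=trial_summary,
    )
    if out_dir is not None:
        report.written = _write_report(report, Path(out_dir))
    return report


def _anova_payload(res: pgi.AnovaResult | None) -> dict | None:
    if res is None:
        return None
    return {"F": res.f, "P": res.p, "clusters": res.table.to_dict(orient="records")}


def _write_report(report: RunReport, out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    def _csv(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, index=False)
        written[name] = path

    def _json(name: str, payload) -> None:
        path = out_dir / name
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        written[name] = path

    report.config.to_json(out_dir / "config.json")
    written["config.json"] = out_dir / "config.json"
    _csv("lesions_2d.csv", report.components_df)
    _csv("lesions_3d.csv", report.lesions3d_df)
    _csv("size_histogram.csv", lesion_io.size_histogram(report.components))
    _csv("shape_features.csv", report.shape_features)
    _csv("texture_features.csv", report.texture_features)
    _csv("clusters.csv", report.clusters)
    _csv("pgi.csv", report.pgi_df)
    _json("gap_shape.json", report.shape_gap.as_dict())
    _json("gap_texture.json", report.texture_gap.as_dict())
    _json(
        "anova.json",
        {
            "shape": _anova_payload(report.shape_anova),
            "texture": _anova_payload(report.texture_anova),
            "trials": report.trial_summary,
        },
    )
    return written


def run_from_paths(
    volume_path: str | Path,
    mask_path: str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    subject_id: str = "subject",
) -> RunReport:
    """Load NIfTI inputs and run the full analysis."""
    config = config or RunConfig()
    volume = lesion_io.load_volume(volume_path, slice_axis=config.slice_axis)
    mask_img = lesion_io.load_volume(mask_path, slice_axis=config.slice_axis)
    return run(volume, mask_img.voxels, config=config, out_dir=out_dir, subject_id=subject_id)
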