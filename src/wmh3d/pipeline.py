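"""End-to-end lesion morphometry pipeline.

Stages: extract connected lesions from volume/mask pairs -> split into
small/large size groups -> (optional) size-screening shape clustering ->
volume-normalise and embed each group -> Zernike descriptors -> PCA ->
multi-restart K-means with gap-statistic cluster-count selection -> fuzzy
texture histograms and their clustering -> per-lesion PGI -> one-way ANOVA
of PGI (and size) across the shape and texture clusters.

Every stage draws randomness from sub-streams of one master seed, so a rerun
with the same configuration and inputs reproduces the report bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as clu
from . import lesions as lp
from . import pgi as pgimod
from . import synth, texture, zernike
from .stats import AnovaResult, anova_by_cluster

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "desk_config"]


@dataclass
class PipelineConfig:
    """Analysis parameters; defaults are the study's reference settings."""

    manifest: list = field(default_factory=list)  # (subject_id, volume_path, mask_path)
    min_volume_mm3: float = 30.0
    size_cutoff_voxels: int = 250
    # (target volume, cube side, zernike order) per size group
    small_norm: tuple = (80, 36, 100)
    large_norm: tuple = (1500, 90, 250)
    screening: tuple = (150, 150)  # (cube side, order)
    run_screening: bool = False
    pca_variance: float = 0.998
    kmeans_trials: int = 1000
    gap_N: int = 20
    gap_B: int = 30
    gap_trials: int = 10
    texture_bins: int = 10
    texture_discard: float = 0.01
    pgi_gamma: float = 2.5
    pgi_layers: int = 5
    connectivity: int = 26
    shape_k: int | None = None  # override gap-selected k
    texture_k: int | None = None
    seed: int = 0


def desk_config(**overrides) -> PipelineConfig:
    """A scaled-down configuration for laptop-speed runs: reduced Zernike
    orders and cube sides, modest restart budgets."""
    cfg = PipelineConfig(
        small_norm=(80, 24, 16),
        large_norm=(400, 32, 20),
        screening=(48, 12),
        kmeans_trials=20,
        gap_N=6,
        gap_B=10,
        gap_trials=5,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class AnalysisReport:
    lesion_table: pd.DataFrame
    shape_descriptors: dict
    shape_clusters: dict
    shape_gap: dict
    texture_table: pd.DataFrame
    texture_clusters: pd.DataFrame | None
    texture_gap: object
    pgi_table: pd.DataFrame
    anova: dict
    screening_clusters: pd.DataFrame | None
    config: PipelineConfig

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.lesion_table.to_csv(out / "lesions.csv", index=False)
        for grp, df in self.shape_descriptors.items():
            df.to_csv(out / f"shape_descriptors_{grp}.csv", index=False)
        for grp, df in self.shape_clusters.items():
            df.to_csv(out / f"shape_clusters_{grp}.csv", index=False)
        self.texture_table.to_csv(out / "texture_features.csv", index=False)
        if self.texture_clusters is not None:
            self.texture_clusters.to_csv(out / "texture_clusters.csv", index=False)
        self.pgi_table.to_csv(out / "pgi.csv", index=False)
        if self.screening_clusters is not None:
            self.screening_clusters.to_csv(out / "screening_clusters.csv", index=False)
        gaps = {}
        for name, g in [*self.shape_gap.items(), ("texture", self.texture_gap)]:
            if g is not None:
                gaps[name] = {
                    "k": g.ks.tolist(),
                    "W_k": g.W_k.tolist(),
                    "gap": g.gap.tolist(),
                    "s_k": g.s_k.tolist(),
                    "k_hat": g.k_hat,
                }
        anova_out = {}
        for name, res in self.anova.items():
            if res is None:
                continue
            anova_out[name] = {
                "F": res.F,
                "p": res.p,
                "bonferroni_threshold": res.bonferroni_threshold,
                "pairwise": res.pairwise.to_dict(orient="records"),
            }
        manifest = {
            "config": _config_dict(self.config),
            "gap_curves": gaps,
            "anova": anova_out,
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["manifest"] = [[str(x) for x in entry] for entry in d["manifest"]]
    return d


def _descriptor_frame(ids, descriptors) -> pd.DataFrame:
    cols = [f"d_{n}_{l}" for n, l in descriptors[0].pairs] if descriptors else []
    data = np.array([d.values for d in descriptors]) if descriptors else np.zeros((0, 0))
    df = pd.DataFrame(data, columns=cols)
    df.insert(0, "lesion", ids)
    return df


def _cluster_features(feats: np.ndarray, cfg: PipelineConfig, rng, k_override):
    """Gap-selected (or overridden) K-means clustering of a feature matrix."""
    n = feats.shape[0]
    gap = None
    if k_override is not None:
        k = min(k_override, n)
    else:
        if n < 3 or np.ptp(feats, axis=0).max() == 0:
            return np.zeros(n, dtype=int), None, 1
        gap = clu.gap_statistic(
            feats, N=min(cfg.gap_N, n), B=cfg.gap_B, seed=rng, trials_per_fit=cfg.gap_trials
        )
        k = gap.k_hat
    model = clu.kmeans_best_of(feats, k, trials=cfg.kmeans_trials, seed=rng)
    return model.assignments, gap, k


def run_pipeline(config: PipelineConfig, data=None) -> AnalysisReport:
    """Run all stages.  ``data`` may carry in-memory
    ``(subject_id, volume, mask)`` triples; otherwise volumes and masks are
    loaded from the NIfTI paths in ``config.manifest``."""
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ["screening", "shape_small", "shape_large", "texture"], ss.spawn(4)
        )
    }

    if data is None:
        data = []
        for subject_id, vol_path, mask_path in cfg.manifest:
            vol, spacing, _ = synth.load_nifti(vol_path)
            msk, _, _ = synth.load_nifti(mask_path)
            data.append((subject_id, np.asarray(vol, float), (np.asarray(msk) > 0.5)))

    # --- extraction and PGI (per subject, pooled intensity stats) ---
    all_lesions: list[lp.Lesion3D] = []
    pgi_rows = []
    for subject_id, vol, msk in data:
        les = lp.extract_lesions(
            vol,
            msk.astype(np.uint8),
            min_volume_mm3=cfg.min_volume_mm3,
            connectivity=cfg.connectivity,
            subject_id=str(subject_id),
        )
        results = pgimod.pgi_for_lesions(
            vol, les, gamma=cfg.pgi_gamma, l=cfg.pgi_layers, connectivity=cfg.connectivity
        )
        for le, res in zip(les, results):
            row = {
                "lesion": f"{le.subject_id}:{le.lesion_id}",
                "subject_id": le.subject_id,
                "lesion_id": le.lesion_id,
                "PGI": res.pgi,
                "gamma": res.gamma,
                "l": res.l,
            }
            row.update({f"V_{i+1}": int(v) for i, v in enumerate(res.sizes)})
            row.update({f"GV_{i+1}": int(g) for i, g in enumerate(res.growth)})
            pgi_rows.append(row)
        all_lesions.extend(les)
    pgi_table = pd.DataFrame(pgi_rows)

    groups = lp.split_by_size(all_lesions, cutoff_voxels=cfg.size_cutoff_voxels)
    lesion_df = lp.lesion_table(all_lesions, groups)

    # --- optional size-screening clustering on raw (unscaled) shapes ---
    screening_df = None
    if cfg.run_screening and len(all_lesions) >= 3:
        side, order = cfg.screening
        grid = zernike.build_unit_ball_grid(side, "cube_in_ball")
        descs = []
        for le in all_lesions:
            cube = _embed_raw(le, side)
            mom = zernike.forward_transform(cube.astype(float), grid, order)
            descs.append(zernike.compute_descriptor(mom).values)
        feats = clu.pca_reduce(np.array(descs), cfg.pca_variance)
        labels, _, _ = _cluster_features(feats, cfg, streams["screening"], None)
        screening_df = pd.DataFrame(
            {
                "lesion": [f"{le.subject_id}:{le.lesion_id}" for le in all_lesions],
                "volume_voxels": [le.volume_voxels for le in all_lesions],
                "cluster": labels,
            }
        )

    # --- per-size-group shape features and clustering ---
    shape_descriptors, shape_clusters, shape_gap = {}, {}, {}
    for grp_name, lesions_grp, (target, side, order) in [
        ("small", groups.group_small, cfg.small_norm),
        ("large", groups.group_large, cfg.large_norm),
    ]:
        ids = [f"{le.subject_id}:{le.lesion_id}" for le in lesions_grp]
        if not lesions_grp:
            shape_descriptors[grp_name] = pd.DataFrame({"lesion": []})
            shape_clusters[grp_name] = pd.DataFrame({"lesion": [], "cluster": []})
            shape_gap[grp_name] = None
            continue
        grid = zernike.build_unit_ball_grid(side, "cube_in_ball")
        descs = []
        for le in lesions_grp:
            shape = lp.rescale_to_target_volume(le, target)
            cube = lp.embed_in_cube(shape, side)
            mom = zernike.forward_transform(cube.astype(float), grid, order)
            descs.append(zernike.compute_descriptor(mom))
        shape_descriptors[grp_name] = _descriptor_frame(ids, descs)
        mat = np.array([d.values for d in descs])
        if len(lesions_grp) >= 3:
            feats = clu.pca_reduce(mat, cfg.pca_variance)
            labels, gap, _ = _cluster_features(
                feats, cfg, streams[f"shape_{grp_name}"], cfg.shape_k
            )
        else:
            labels, gap = np.zeros(len(lesions_grp), dtype=int), None
        shape_clusters[grp_name] = pd.DataFrame({"lesion": ids, "cluster": labels})
        shape_gap[grp_name] = gap

    # --- texture features and clustering over all lesions ---
    tex_rows, tex_ids = [], []
    for le in all_lesions:
        try:
            s = texture.normalize_intensities(le, cfg.texture_discard)
        except texture.DegenerateIntensityError:
            continue
        h = texture.fuzzy_histogram(s, cfg.texture_bins)
        tex_ids.append(f"{le.subject_id}:{le.lesion_id}")
        tex_rows.append(h.frequencies)
    texture_table = pd.DataFrame(
        tex_rows, columns=[f"bin_{j}" for j in range(cfg.texture_bins)]
    )
    texture_table.insert(0, "lesion", tex_ids)
    texture_clusters, texture_gap = None, None
    if len(tex_rows) >= 3:
        feats = np.array(tex_rows)
        labels, texture_gap, _ = _cluster_features(
            feats, cfg, streams["texture"], cfg.texture_k
        )
        texture_clusters = pd.DataFrame({"lesion": tex_ids, "cluster": labels})

    # --- ANOVA of PGI (and size) across cluster groupings ---
    anova: dict[str, AnovaResult | None] = {}
    if len(lesion_df):
        lesion_df.insert(
            0,
            "lesion",
            [f"{s}:{i}" for s, i in zip(lesion_df.subject_id, lesion_df.lesion_id)],
        )
    else:
        lesion_df = pd.DataFrame(columns=["lesion", "subject_id", "lesion_id", "volume_voxels"])
    for name, cl_df in [
        ("shape_small", shape_clusters.get("small")),
        ("shape_large", shape_clusters.get("large")),
        ("texture", texture_clusters),
    ]:
        anova[f"pgi_{name}"] = None
        anova[f"size_{name}"] = None
        if cl_df is None or len(cl_df) == 0 or len(pgi_table) == 0:
            continue
        merged = cl_df.merge(pgi_table[["lesion", "PGI"]], on="lesion").merge(
            lesion_df[["lesion", "volume_voxels"]], on="lesion"
        )
        for prefix, col in [("pgi", "PGI"), ("size", "volume_voxels")]:
            try:
                anova[f"{prefix}_{name}"] = anova_by_cluster(
                    merged[col].to_numpy(), merged["cluster"].to_numpy()
                )
            except ValueError:
                pass

    return AnalysisReport(
        lesion_table=lesion_df,
        shape_descriptors=shape_descriptors,
        shape_clusters=shape_clusters,
        shape_gap=shape_gap,
        texture_table=texture_table,
        texture_clusters=texture_clusters,
        texture_gap=texture_gap,
        pgi_table=pgi_table,
        anova=anova,
        screening_clusters=screening_df,
        config=cfg,
    )


def _embed_raw(lesion: lp.Lesion3D, side: int) -> np.ndarray:
    coords = lesion.coords - lesion.coords.min(axis=0)
    shape = np.zeros(tuple(coords.max(axis=0) + 1), dtype=bool)
    shape[tuple(coords.T)] = True
    return lp.embed_in_cube(shape, side)
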