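"""End-to-end workflow: simulate -> GLM -> spatial model -> ROS -> temporal
CNN -> VOS -> kernel analysis -> acoustics -> recovery report.

A pipeline run is driven by a single config (YAML/JSON or dict) and a single
global seed that fans out deterministically to per-stage seeds. Each stage
writes its artifacts under the run directory together with a completion marker
holding content hashes; completed stages are skipped (and their outputs
reloaded) unless forced. Two runs with the same config and seed produce
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acoustic_features import AudioClip, spectral_centroid
from .kernel_analysis import (
    aggregate_shape_counts,
    analyze_model,
    frequency_ratios,
    shape_counts,
)
from .predictive_model import (
    bootstrap_feature_test,
    confusion_and_roc,
    fit_svm_loso,
    rfe_select,
    SignificanceMap,
)
from .ros_selection import default_k, region_feature_ratio, scores_to_frame, select_ros
from .spatial_activation import build_design, feature_matrix
from .synthetic_data import (
    Atlas,
    GroundTruth,
    SimConfig,
    Volume4D,
    block_design_timing,
    generate_dataset,
    save_atlas_nifti,
    save_ground_truth,
    save_nifti,
    save_wav,
    synthesize_audio,
)
from .temporal_cnn import (
    CNNSpec,
    extract_voxel_signals,
    identify_vos,
    train_eval_loocv,
    VoxelPredictionTable,
)

logger = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "glm",
    "fit-spatial",
    "select-ros",
    "fit-temporal",
    "identify-vos",
    "analyze-kernels",
    "acoustics",
    "report",
]

#: Demo-scale defaults: a small toy brain so the whole pipeline runs on one CPU
#: in minutes. The CNN uses a larger SGD step and fewer epochs than the
#: desk-scale CNNSpec defaults so training converges at this problem size.
CONFIG_DEFAULTS = {
    "sim": {
        "n_subjects": 4,
        "n_excerpts_per_category": 4,
        "categories": ["CLA", "SPE"],
        "n_volumes": 60,
        "tr_seconds": 1.5,
        "volume_shape": [8, 8, 8],
        "n_regions": 12,
        "planted_region_ids": [1, 2, 3, 4],
        "planted_voxel_fraction": 0.5,
        "effect_amplitude": 1.0,
        "class_freq_hz": {"CLA": 0.06, "SPE": 0.25},
        "ar_coefficient": 0.3,
        "noise_sd": 0.5,
        "block_on_s": 15.0,
        "block_off_s": 15.0,
    },
    "glm": {"drift_order": 1},
    "svm": {"C": 1.0},
    "bootstrap": {"B": 200, "alpha": 0.05},
    # demo n_keep matched to the planted activation extent (4 regions of ~16
    # in-mask voxels); at whole-brain scale the library default (1% of mask)
    # applies instead
    "rfe": {"step_fraction": 0.1, "n_keep": 64},
    # demo k matched to the planted design: 4 planted regions split evenly
    # between positive and negative signs -> 2 per (sign x method) list
    "ros": {"k": 2, "rank_by": "r"},
    "cnn": {
        "epochs": 10,
        "learning_rate": 0.05,
        "batch_size": 64,
        "max_regions": 2,
    },
    "vos": {"threshold": 0.6},
    "audio": {"duration_s": 90.0, "sample_rate": 22050},
    "seed": 0,
}


class ConfigError(ValueError):
    """Raised with the exhaustive list of config schema violations."""


@dataclasses.dataclass
class PipelineConfig:
    sim: SimConfig
    glm: dict
    svm: dict
    bootstrap: dict
    rfe: dict
    ros: dict
    cnn: dict
    vos: dict
    audio: dict
    seed: int
    raw: dict

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:16]


def _deep_merge(base: dict, override: dict) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = {**out[k], **v}
        else:
            out[k] = v
    return out


def validate_config(source) -> PipelineConfig:
    """Fill defaults and check cross-field constraints, reporting every
    violation at once.

    ``source`` is a mapping, or a path to a YAML/JSON file.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        user = yaml.safe_load(text) or {}
    else:
        user = dict(source or {})

    errors: list[str] = []
    known = set(CONFIG_DEFAULTS)
    for key in user:
        if key not in known:
            errors.append(f"unknown config section {key!r}")
    merged = _deep_merge(CONFIG_DEFAULTS, {k: v for k, v in user.items() if k in known})

    sim_raw = merged["sim"]
    cats = list(sim_raw["categories"])
    if len(set(cats)) != len(cats):
        errors.append(f"duplicate category names: {cats}")
    freq = dict(sim_raw["class_freq_hz"])
    for cat in freq:
        if cat not in cats:
            errors.append(f"class_freq_hz names unknown category {cat!r}")
    nyquist = 1.0 / (2.0 * float(sim_raw["tr_seconds"]))
    for cat, f in freq.items():
        if cat in cats and not 0 < f < nyquist:
            errors.append(
                f"class_freq_hz[{cat!r}] = {f} violates 0 < f < Nyquist = "
                f"1/(2*TR) = {nyquist:.4g} Hz"
            )
    thr = merged["vos"]["threshold"]
    if not 0 < thr <= 1:
        errors.append(f"vos.threshold = {thr} must lie in (0, 1]")
    if merged["bootstrap"]["B"] < 100:
        errors.append("bootstrap.B must be >= 100")
    if merged["audio"]["duration_s"] <= 0:
        errors.append("audio.duration_s must be positive")

    sim = None
    if not errors:
        try:
            sim = SimConfig(
                n_subjects=int(sim_raw["n_subjects"]),
                n_excerpts_per_category=int(sim_raw["n_excerpts_per_category"]),
                categories=tuple(cats),
                n_volumes=int(sim_raw["n_volumes"]),
                tr_seconds=float(sim_raw["tr_seconds"]),
                volume_shape=tuple(sim_raw["volume_shape"]),
                n_regions=int(sim_raw["n_regions"]),
                planted_region_ids=tuple(sim_raw["planted_region_ids"]),
                planted_voxel_fraction=float(sim_raw["planted_voxel_fraction"]),
                effect_amplitude=float(sim_raw["effect_amplitude"]),
                class_freq_hz=freq,
                ar_coefficient=float(sim_raw["ar_coefficient"]),
                noise_sd=float(sim_raw["noise_sd"]),
                block_on_s=float(sim_raw["block_on_s"]),
                block_off_s=float(sim_raw["block_off_s"]),
                seed=_stage_seed(int(merged["seed"]), 0),
            )
        except ValueError as e:
            errors.append(str(e))
    if errors:
        raise ConfigError("invalid config:\n- " + "\n- ".join(errors))

    return PipelineConfig(
        sim=sim,
        glm=merged["glm"],
        svm=merged["svm"],
        bootstrap=merged["bootstrap"],
        rfe=merged["rfe"],
        ros=merged["ros"],
        cnn=merged["cnn"],
        vos=merged["vos"],
        audio=merged["audio"],
        seed=int(merged["seed"]),
        raw=merged,
    )


def _stage_seed(global_seed: int, index: int) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    return int(np.random.SeedSequence([global_seed, index]).generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


class PipelineRun:
    """Executes the stages in order into a run directory, with skip/force."""

    def __init__(self, config: PipelineConfig, outdir, force: bool = False):
        self.cfg = config
        self.outdir = Path(outdir)
        self.force = force
        self.outdir.mkdir(parents=True, exist_ok=True)
        (self.outdir / "stages").mkdir(exist_ok=True)
        self.state: dict = {}
        _write_json(self.outdir / "config.json", config.raw)

    # -- marker/manifest machinery -------------------------------------------

    def _marker(self, stage: str) -> Path:
        return self.outdir / "stages" / f"{stage}.json"

    def _complete(self, stage: str, artifacts: list[Path]) -> None:
        payload = {
            str(p.relative_to(self.outdir)): _sha256(p) for p in sorted(artifacts)
        }
        _write_json(self._marker(stage), payload)
        manifest_path = self.outdir / "manifest.json"
        manifest = (
            json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
        )
        manifest.update(payload)
        _write_json(manifest_path, manifest)

    def _done(self, stage: str) -> bool:
        if self.force or not self._marker(stage).exists():
            return False
        recorded = json.loads(self._marker(stage).read_text())
        return all((self.outdir / rel).exists() for rel in recorded)

    def run(self, upto: str = "report") -> dict:
        if upto not in STAGES:
            raise ValueError(f"unknown stage {upto!r}; stages are {STAGES}")
        for stage in STAGES[: STAGES.index(upto) + 1]:
            method = getattr(self, "stage_" + stage.replace("-", "_"))
            if self._done(stage):
                logger.info("stage %s: outputs present, skipping", stage)
                method(load_only=True)
            else:
                logger.info("stage %s: running", stage)
                try:
                    method(load_only=False)
                except Exception as e:
                    raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
        return self.state.get("report", {})

    # -- stages ---------------------------------------------------------------

    def stage_simulate(self, load_only: bool = False):
        cfg = self.cfg
        d = self.outdir / "data"
        d.mkdir(exist_ok=True)
        atlas_p, mask_p = d / "atlas.nii", d / "mask.nii"
        truth_p, manifest_p = d / "ground_truth.json", d / "runs.csv"

        if load_only and manifest_p.exists():
            import nibabel as nib

            labels = np.asarray(nib.load(str(atlas_p)).dataobj).astype(np.int32)
            names = {int(i): f"region_{int(i):03d}" for i in np.unique(labels) if i}
            atlas = Atlas(labels=labels, names=names)
            mask = np.asarray(nib.load(str(mask_p)).dataobj) > 0.5
            gt = json.loads(truth_p.read_text())
            truth = GroundTruth(
                spatial_regions=frozenset(gt["spatial_regions"]),
                temporal_voxels=frozenset(tuple(v) for v in gt["temporal_voxels"]),
                class_signatures=gt["class_signatures"],
                region_preference={int(k): v for k, v in gt["region_preference"].items()},
            )
            runs = []
            for row in pd.read_csv(manifest_p).itertuples():
                data = np.moveaxis(
                    np.asarray(nib.load(str(d / row.path)).dataobj, dtype=np.float64),
                    -1, 0,
                )
                runs.append(
                    Volume4D(
                        data=data,
                        tr_seconds=float(row.tr_seconds),
                        subject_id=int(row.subject_id),
                        excerpt_id=int(row.excerpt_id),
                        category=str(row.category),
                    )
                )
            self.state.update(atlas=atlas, mask=mask, truth=truth, runs=runs)
            return

        atlas, mask, truth, runs = generate_dataset(cfg.sim)
        if not load_only:
            save_atlas_nifti(atlas_p, atlas)
            save_nifti(mask_p, mask.astype(np.float32))
            save_ground_truth(truth_p, truth)
            rows = []
            for i, run in enumerate(runs):
                p = d / f"run_{i:03d}.nii"
                save_nifti(p, run.data)
                rows.append(
                    {
                        "path": p.name,
                        "subject_id": run.subject_id,
                        "excerpt_id": run.excerpt_id,
                        "category": run.category,
                        "tr_seconds": run.tr_seconds,
                    }
                )
            pd.DataFrame(rows).to_csv(manifest_p, index=False)
            arts = [atlas_p, mask_p, truth_p, manifest_p] + [
                d / f"run_{i:03d}.nii" for i in range(len(runs))
            ]
            self._complete("simulate", arts)
        self.state.update(atlas=atlas, mask=mask, truth=truth, runs=runs)

    def stage_glm(self, load_only: bool = False):
        cfg = self.cfg
        d = self.outdir / "glm"
        d.mkdir(exist_ok=True)
        feat_p = d / "features.npz"
        if load_only and feat_p.exists():
            z = np.load(feat_p, allow_pickle=False)
            self.state.update(
                features=z["features"],
                labels=z["labels"],
                subjects=z["subjects"],
                index_map=z["index_map"],
            )
            return
        sim = cfg.sim
        onsets, durations = block_design_timing(sim)
        design = build_design(
            onsets, durations, sim.n_volumes, sim.tr_seconds,
            drift_order=int(cfg.glm["drift_order"]),
        )
        pd.DataFrame(design.matrix, columns=design.names).to_csv(
            d / "design_matrix.csv", index=False
        )
        features, labels, subjects, index_map = feature_matrix(
            self.state["runs"], design, self.state["mask"]
        )
        np.savez(
            feat_p,
            features=features,
            labels=labels.astype(str),
            subjects=subjects,
            index_map=index_map,
        )
        self.state.update(
            features=features, labels=labels, subjects=subjects, index_map=index_map
        )
        self._complete("glm", [feat_p, d / "design_matrix.csv"])

    def stage_fit_spatial(self, load_only: bool = False):
        cfg = self.cfg
        d = self.outdir / "spatial"
        d.mkdir(exist_ok=True)
        sig_p, met_p = d / "significance.npz", d / "classification_metrics.json"
        if load_only and sig_p.exists():
            z = np.load(sig_p, allow_pickle=False)
            classes = tuple(z["classes"])
            self.state["sig_maps"] = {
                m: SignificanceMap(
                    statistic=z[f"{m}_statistic"],
                    selected=z[f"{m}_selected"],
                    sign=z[f"{m}_sign"],
                    method=m,
                    classes=classes,
                )
                for m in ("bootstrap", "RFE")
            }
            self.state["classification_metrics"] = json.loads(met_p.read_text())
            return
        X, y, subj = self.state["features"], self.state["labels"], self.state["subjects"]
        cv = fit_svm_loso(X, y, subj, C=float(cfg.svm["C"]))
        metrics = confusion_and_roc(cv)
        pd.DataFrame({"fpr": metrics.fpr, "tpr": metrics.tpr}).to_csv(
            d / "roc_points.csv", index=False
        )
        met = {
            "accuracy": metrics.accuracy,
            "sensitivity": metrics.S_N,
            "specificity": metrics.S_P,
            "auc": metrics.auc,
            "confusion": {
                "TP": metrics.TP, "FN": metrics.FN,
                "FP": metrics.FP, "TN": metrics.TN,
            },
            "positive_class": str(cv.classes[1]),
        }
        _write_json(met_p, met)

        boot = bootstrap_feature_test(
            X, y,
            B=int(cfg.bootstrap["B"]),
            alpha=float(cfg.bootstrap["alpha"]),
            seed=_stage_seed(cfg.seed, 2),
            C=float(cfg.svm["C"]),
        )
        n_keep = cfg.rfe["n_keep"]
        n_keep = int(n_keep) if n_keep else max(1, X.shape[1] // 100)
        rfe = rfe_select(
            X, y,
            step_fraction=float(cfg.rfe["step_fraction"]),
            n_keep=n_keep,
            C=float(cfg.svm["C"]),
        )
        np.savez(
            sig_p,
            classes=np.asarray(boot.classes, dtype=str),
            **{
                f"{s.method}_{f}": getattr(s, f)
                for s in (boot, rfe)
                for f in ("statistic", "selected", "sign")
            },
        )
        self.state["sig_maps"] = {"bootstrap": boot, "RFE": rfe}
        self.state["classification_metrics"] = met
        self._complete(
            "fit-spatial", [sig_p, met_p, d / "roc_points.csv"]
        )

    def stage_select_ros(self, load_only: bool = False):
        cfg = self.cfg
        d = self.outdir / "ros"
        d.mkdir(exist_ok=True)
        ros_p = d / "ros.json"
        atlas, mask = self.state["atlas"], self.state["mask"]
        scores_by_method = {
            m: region_feature_ratio(s, atlas, self.state["index_map"], mask)
            for m, s in self.state["sig_maps"].items()
        }
        k = cfg.ros["k"]
        k = int(k) if k else default_k(cfg.sim.n_regions)
        ros = select_ros(scores_by_method, k=k, rank_by=cfg.ros["rank_by"])
        if not load_only:
            pd.concat(
                [scores_to_frame(s) for s in scores_by_method.values()]
            ).to_csv(d / "region_scores.csv", index=False)
            _write_json(
                ros_p,
                {
                    "regions": {
                        str(rid): info for rid, info in sorted(ros.regions.items())
                    },
                    "top_lists": {
                        f"{sign}|{method}": ids
                        for (sign, method), ids in sorted(ros.top_lists.items())
                    },
                    "intersection": ros.intersection,
                    "k": k,
                },
            )
            self._complete("select-ros", [ros_p, d / "region_scores.csv"])
        self.state["ros"] = ros
        self.state["region_scores"] = scores_by_method

    def _temporal_regions(self) -> list[int]:
        """ROS regions ordered by best feature ratio, capped at cnn.max_regions."""
        ros = self.state["ros"]
        best_r: dict[int, float] = {}
        for scores in self.state["region_scores"].values():
            for s in scores:
                if s.region_id in ros.regions:
                    best_r[s.region_id] = max(best_r.get(s.region_id, 0.0), s.r)
        ordered = sorted(ros.regions, key=lambda rid: (-best_r.get(rid, 0.0), rid))
        return ordered[: int(self.cfg.cnn["max_regions"])]

    def _cnn_spec(self) -> CNNSpec:
        c = self.cfg.cnn
        return CNNSpec(
            epochs=int(c["epochs"]),
            learning_rate=float(c["learning_rate"]),
            batch_size=int(c["batch_size"]),
            seed=_stage_seed(self.cfg.seed, 4),
        )

    def stage_fit_temporal(self, load_only: bool = False):
        d = self.outdir / "temporal"
        d.mkdir(exist_ok=True)
        regions = self._temporal_regions()
        tables: dict[int, VoxelPredictionTable] = {}
        arts: list[Path] = []
        for rid in regions:
            pred_p = d / f"region_{rid:03d}_predictions.csv"
            sigset = extract_voxel_signals(
                self.state["runs"], self.state["atlas"], rid, self.state["mask"]
            )
            if load_only and pred_p.exists():
                table = pd.read_csv(pred_p)
                tables[rid] = VoxelPredictionTable(
                    table=table,
                    coords=sigset.coords,
                    region_id=rid,
                    classes=tuple(np.unique(sigset.categories)),
                )
                continue
            result = train_eval_loocv(sigset, self._cnn_spec(), keep_models=True)
            result.table.to_csv(pred_p, index=False)
            kernels_p = d / f"region_{rid:03d}_kernels.npz"
            np.savez(
                kernels_p,
                **{
                    f"fold{f}_{name}": arr
                    for f, model in enumerate(result.models)
                    for name, arr in (
                        ("last_conv_W", model.conv_W[-1]),
                        ("dense_W", model.dense_W),
                    )
                },
            )
            tables[rid] = result
            arts += [pred_p, kernels_p]
        if not load_only:
            self._complete("fit-temporal", arts)
        self.state["prediction_tables"] = tables

    def stage_identify_vos(self, load_only: bool = False):
        d = self.outdir / "temporal"
        vos_p = d / "vos.json"
        threshold = float(self.cfg.vos["threshold"])
        payload = {}
        vos_state = {}
        for rid, table in self.state["prediction_tables"].items():
            vos_idx, proportion = identify_vos(table, threshold)
            coords = table.coords[vos_idx]
            payload[str(rid)] = {
                "threshold": threshold,
                "n_voxels": int(len(table.coords)),
                "n_vos": int(len(vos_idx)),
                "proportion": proportion,
                "vos_coords": [[int(v) for v in c] for c in coords],
            }
            vos_state[rid] = {tuple(int(v) for v in c) for c in coords}
        if not load_only:
            _write_json(vos_p, payload)
            self._complete("identify-vos", [vos_p])
        self.state["vos"] = vos_state

    def stage_analyze_kernels(self, load_only: bool = False):
        d = self.outdir / "kernels"
        d.mkdir(exist_ok=True)
        ratios_p = d / "frequency_ratios.csv"
        if load_only and ratios_p.exists():
            self.state["kernel_ratios"] = pd.read_csv(ratios_p)
            return
        frames = []
        for rid, table in self.state["prediction_tables"].items():
            if not table.models:
                # models were not retained (e.g. resumed run): reload weights
                frames.append(self._kernel_counts_from_disk(rid, table.classes))
                continue
            per_fold = [
                shape_counts(analyze_model(m, table.classes), rid, table.classes)
                for m in table.models
            ]
            frames.append(aggregate_shape_counts(per_fold))
        counts = pd.concat(frames, ignore_index=True)
        ratios = frequency_ratios(counts)
        counts.to_csv(d / "shape_counts.csv", index=False)
        ratios.to_csv(ratios_p, index=False)
        self.state["kernel_ratios"] = ratios
        self._complete("analyze-kernels", [ratios_p, d / "shape_counts.csv"])

    def _kernel_counts_from_disk(self, rid: int, classes: tuple) -> pd.DataFrame:
        from .kernel_analysis import classify_shape, kernel_spectrum, SHAPE_LABELS

        z = np.load(self.outdir / "temporal" / f"region_{rid:03d}_kernels.npz")
        n_folds = len([k for k in z.files if k.endswith("last_conv_W")])
        rows = {cat: {s: 0 for s in SHAPE_LABELS} for cat in classes}
        for f in range(n_folds):
            W_last, dense_W = z[f"fold{f}_last_conv_W"], z[f"fold{f}_dense_W"]
            n_kernels, n_pos = W_last.shape[0], dense_W.shape[1] // W_last.shape[0]
            agg = dense_W.reshape(2, n_kernels, n_pos).sum(axis=2)
            for k in range(n_kernels):
                if agg[0, k] == agg[1, k]:
                    continue
                cat = classes[int(np.argmax(agg[:, k]))]
                rows[cat][classify_shape(kernel_spectrum(W_last[k]))] += 1
        return pd.DataFrame(
            [{"region_id": rid, "category": c, **rows[c]} for c in classes]
        )

    def stage_acoustics(self, load_only: bool = False):
        cfg = self.cfg
        d = self.outdir / "acoustics"
        d.mkdir(exist_ok=True)
        summary_p = d / "acoustic_summary.json"
        if load_only and summary_p.exists():
            self.state["acoustics"] = json.loads(summary_p.read_text())
            return
        sr = int(cfg.audio["sample_rate"])
        duration = float(cfg.audio["duration_s"])
        seed = _stage_seed(cfg.seed, 7)
        summary = {}
        arts = []
        for cat in cfg.sim.categories:
            samples = synthesize_audio(cat, duration, sr, seed=seed)
            wav_p = d / f"{cat}.wav"
            save_wav(wav_p, samples, sr)
            cent = spectral_centroid(AudioClip(samples=samples, sample_rate=sr))
            summary[cat] = {
                "centroid_mean_hz": float(np.nanmean(cent)),
                "centroid_sd_hz": float(np.nanstd(cent)),
            }
            arts.append(wav_p)
        _write_json(summary_p, summary)
        self.state["acoustics"] = summary
        self._complete("acoustics", arts + [summary_p])

    def stage_report(self, load_only: bool = False):
        report_p = self.outdir / "report.json"
        if load_only and report_p.exists():
            self.state["report"] = json.loads(report_p.read_text())
            return
        truth: GroundTruth = self.state["truth"]
        ros = self.state["ros"]
        planted = set(truth.spatial_regions)

        def set_metrics(selected: set, reference: set) -> dict:
            tp = len(selected & reference)
            precision = tp / len(selected) if selected else 0.0
            recall = tp / len(reference) if reference else 0.0
            union = len(selected | reference)
            return {
                "precision": precision,
                "recall": recall,
                "jaccard": tp / union if union else 0.0,
            }

        per_method = {}
        for method in self.state["region_scores"]:
            sel = {
                rid
                for (sign, m), ids in ros.top_lists.items()
                if m == method
                for rid in ids
            }
            per_method[method] = set_metrics(sel, planted)

        analyzed = list(self.state["prediction_tables"])
        analyzed_coords = {
            tuple(int(v) for v in c)
            for rid in analyzed
            for c in self.state["prediction_tables"][rid].coords
        }
        planted_vox = set(truth.temporal_voxels) & analyzed_coords
        vos_all = set().union(*self.state["vos"].values()) if self.state["vos"] else set()
        temporal = set_metrics(vos_all, planted_vox)
        vos_proportions = {
            str(rid): len(self.state["vos"][rid])
            / len(self.state["prediction_tables"][rid].coords)
            for rid in analyzed
        }

        ratios = self.state["kernel_ratios"]
        kernel_table = [
            {
                "region_id": int(r.region_id),
                "category": r.category,
                "gamma_ratio": None if pd.isna(r.gamma_ratio) else float(r.gamma_ratio),
                "l_ratio": None if pd.isna(r.l_ratio) else float(r.l_ratio),
            }
            for r in ratios.itertuples()
        ]

        report = {
            "spatial": {
                "per_method": per_method,
                "ros_regions": ros.region_ids,
                "planted_regions": sorted(planted),
            },
            "temporal": {
                **temporal,
                "vos_proportion_per_region": vos_proportions,
                "analyzed_regions": analyzed,
            },
            "classification": self.state["classification_metrics"],
            "kernel_ratios": kernel_table,
            "acoustics": self.state["acoustics"],
            "provenance": {
                "config_hash": self.cfg.config_hash(),
                "seed": self.cfg.seed,
                "version": __version__,
            },
        }
        _write_json(report_p, report)
        self.state["report"] = report
        self._complete("report", [report_p])


def run_pipeline(
    config, outdir, force: bool = False, upto: str = "report"
) -> dict:
    """Validate ``config`` (mapping or path) and execute the pipeline."""
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    return PipelineRun(cfg, outdir, force=force).run(upto=upto)
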