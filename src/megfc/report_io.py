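"""Run configuration, serialization, and the end-to-end pipeline driver.

A single :class:`RunConfig` carries every stage parameter; its canonical
YAML serialization is hashed (sha256) and stamped into every output so a
run is reproducible from one file plus one root seed.  All randomness is
derived from the root seed via per-stage ``numpy.random.SeedSequence``
spawning.

Artifacts written by :func:`run_pipeline`:

* ``folds_<scheme>.csv``   — per-fold validation accuracy and selection sizes;
* ``stable_edges_<scheme>.csv`` — the stable feature set with atlas labels,
  overlap counts, mean F-scores and strong-edge flags;
* ``edges_<scheme>.csv``   — plain ``i,j,weight`` list for brain-plot tools;
* ``metrics.json``         — test accuracy / sensitivity / specificity and
  run provenance (config hash, seed, counts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import classify as cl
from .atlas import default_atlas
from .connectivity import ImaginaryCoherency
from .features import feature_index_map
from .preprocess import Segment, preprocess_recording
from .simulate import CPS, CohortConfig, CouplingSpec, generate_cohort

__all__ = [
    "RunConfig",
    "config_hash",
    "load_config",
    "save_config",
    "save_segments",
    "load_segments",
    "save_recordings",
    "load_recordings",
    "edge_report",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Every stage parameter of one pipeline run."""
    # cohort
    n_subjects_per_group: int = 16
    n_parcels: int = 74
    segments_per_subject_range: tuple[int, int] = (33, 169)
    noise_sd: float = 0.1
    mode: str = "segments"                      # "segments" | "raw"
    # raw-mode acquisition scale
    sample_rate_hz: float = 1200.0
    n_blocks: int = 20
    block_duration_s: float = 120.0
    spike_rate_per_min: float = 1.0
    # coupling (the planted group difference)
    edges: tuple[tuple[int, int], ...] = ()
    lag_ms: float = 20.0
    strength: float = 0.6
    coupling_group: str = CPS
    # preprocessing (raw mode)
    pad_s: float = 10.0
    cut_len_s: float = 10.0
    min_keep_s: float = 4.0
    trim_len_s: float = 4.0
    amp_z_max: float = 6.0
    grad_z_max: float = 6.0
    # connectivity
    band_hz: tuple[float, float] = (1.0, 40.0)
    window_s: float = 1.0
    overlap: float = 0.5
    # selection + classification
    k_fraction: float = 0.01
    C: float = 1.2
    gamma: float = 5.0
    overlap_threshold: int = 12
    strong_fraction: float = 0.75
    n_reps: int = 14
    train_frac: float = 0.9
    n_test_subsets: int = 2
    test_subsets: tuple[int, ...] | None = None  # pin instead of seeded draw
    schemes: tuple[str, ...] = ("subsets", "random")
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.segments_per_subject_range
        if not 1 <= lo <= hi:
            raise ValueError("segments_per_subject_range must be [min, max]")
        if self.mode not in ("segments", "raw"):
            raise ValueError("mode must be 'segments' or 'raw'")
        if "subsets" in self.schemes:
            n_folds = self.n_subjects_per_group - self.n_test_subsets
            if self.overlap_threshold > n_folds:
                raise ValueError(
                    f"overlap_threshold {self.overlap_threshold} exceeds the "
                    f"{n_folds} leave-one-subset-out folds"
                )
        if "random" in self.schemes and self.overlap_threshold > self.n_reps:
            raise ValueError("overlap_threshold exceeds n_reps")
        for s in self.schemes:
            if s not in ("subsets", "random"):
                raise ValueError(f"unknown scheme {s!r}")

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_subjects_per_group=self.n_subjects_per_group,
            n_parcels=self.n_parcels,
            segments_per_subject_range=tuple(self.segments_per_subject_range),
            noise_sd=self.noise_sd,
            sample_rate_hz=self.sample_rate_hz,
            n_blocks=self.n_blocks,
            block_duration_s=self.block_duration_s,
            spike_rate_per_min=self.spike_rate_per_min,
            seed=self.seed,
        )

    def coupling_spec(self) -> CouplingSpec:
        return CouplingSpec(edges=tuple(tuple(e) for e in self.edges),
                            lag_ms=self.lag_ms, strength=self.strength,
                            group=self.coupling_group)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def config_hash(config: RunConfig) -> str:
    """sha256 of the canonical YAML serialization (first 12 hex digits)."""
    text = yaml.safe_dump(_to_plain(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=True))


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("segments_per_subject_range", "band_hz", "schemes",
                "test_subsets"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    if raw.get("edges"):
        raw["edges"] = tuple(tuple(e) for e in raw["edges"])
    return RunConfig(**raw)


# ---------------------------------------------------------------- HDF5 I/O

def save_segments(path, segments: list[Segment], attrs: dict | None = None):
    """Stack segments into one HDF5 container (/signals + provenance)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signals",
                         data=np.stack([s.signals for s in segments]).astype(
                             np.float32))
        str_dt = h5py.string_dtype()
        f.create_dataset("subject_id",
                         data=[s.subject_id for s in segments], dtype=str_dt)
        f.create_dataset("group_label",
                         data=[s.group_label for s in segments], dtype=str_dt)
        f.create_dataset("origin",
                         data=np.array([[s.origin[0], s.origin[1]]
                                        for s in segments]))
        f.attrs["sample_rate_hz"] = segments[0].sample_rate_hz
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_segments(path) -> list[Segment]:
    with h5py.File(path, "r") as f:
        signals = f["signals"][()]
        subjects = [s.decode() for s in f["subject_id"][()]]
        groups = [g.decode() for g in f["group_label"][()]]
        origins = f["origin"][()]
        fs = float(f.attrs["sample_rate_hz"])
    return [
        Segment(subject_id=subjects[k], group_label=groups[k],
                signals=signals[k], sample_rate_hz=fs,
                origin=(int(origins[k, 0]), float(origins[k, 1])))
        for k in range(signals.shape[0])
    ]


def save_recordings(path, recordings):
    with h5py.File(path, "w") as f:
        for rec in recordings:
            g = f.create_group(f"subjects/{rec.subject_id}")
            g.create_dataset("signals", data=rec.signals)
            g.create_dataset("events",
                             data=np.array(rec.events, dtype=float).reshape(-1, 2))
            g.attrs["group_label"] = rec.group_label
            g.attrs["sample_rate_hz"] = rec.sample_rate_hz
            g.attrs["block_duration_s"] = rec.block_duration_s
            g.attrs["n_blocks"] = rec.n_blocks


def load_recordings(path):
    from .simulate import Recording
    out = []
    with h5py.File(path, "r") as f:
        for sid, g in f["subjects"].items():
            ev = [(int(b), float(t)) for b, t in g["events"][()]]
            out.append(Recording(
                subject_id=sid, group_label=g.attrs["group_label"],
                signals=g["signals"][()],
                sample_rate_hz=float(g.attrs["sample_rate_hz"]),
                block_duration_s=float(g.attrs["block_duration_s"]),
                n_blocks=int(g.attrs["n_blocks"]), events=ev))
    return out


# ------------------------------------------------------------------ report

def edge_report(stability: cl.StabilityResult, atlas: pd.DataFrame,
                n_parcels: int,
                coincident_with: set[int] | None = None) -> pd.DataFrame:
    """Stable-feature table with atlas labels, Table-style layout.

    One row per stable feature, ordered by descending mean F-score, with
    the two parcel labels, the overlap count, the mean F-score and the
    strong-edge flag.  ``coincident_with`` (feature indices stable under
    the other scheme) adds a ``coincident`` marker column.
    """
    idx_map = feature_index_map(n_parcels)
    labels = atlas["label"].tolist()
    rows = []
    flags = (stability.strong_flags if stability.strong_flags.size
             else np.zeros(stability.stable_features.size, bool))
    for rank, (feat, mf, strong) in enumerate(
            zip(stability.stable_features, stability.mean_fscores, flags),
            start=1):
        i, j = idx_map[feat]
        if feat >= idx_map.shape[0]:
            raise ValueError(f"feature index {feat} outside the feature space")
        row = {
            "rank": rank,
            "feature_index": int(feat),
            "roi_1": labels[i],
            "roi_2": labels[j],
            "overlap_count": int(stability.occurrence_counts[int(feat)]),
            "mean_fscore": float(mf),
            "strong": bool(strong),
        }
        if coincident_with is not None:
            row["coincident"] = int(feat) in coincident_with
        rows.append(row)
    cols = ["rank", "feature_index", "roi_1", "roi_2", "overlap_count",
            "mean_fscore", "strong"]
    if coincident_with is not None:
        cols.append("coincident")
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------- pipeline

@dataclass
class PipelineResult:
    """In-memory result of one full run (also written to disk)."""
    config: RunConfig
    models: dict                    # scheme -> StabilitySelectedSVC
    reports: dict                   # scheme -> EvalReport
    edge_tables: dict               # scheme -> DataFrame
    metrics: dict
    ground_truth_edges: tuple = ()


def _segments_to_samples(segments, band_hz, window_s, overlap):
    X_ts = np.stack([s.signals for s in segments])
    fc = ImaginaryCoherency(sample_rate_hz=segments[0].sample_rate_hz,
                            band_hz=tuple(band_hz), window_s=window_s,
                            overlap=overlap)
    X = fc.fit(X_ts).transform(X_ts)
    y = np.array([1 if s.group_label == CPS else 0 for s in segments])
    subj = np.array([s.subject_id for s in segments])
    return X, y, subj


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    """simulate -> (preprocess) -> connectivity -> features -> classify.

    Runs every scheme in ``config.schemes`` on the same cohort and
    train/test partition, writes the artifact files into ``out_dir``
    (when given) and returns the in-memory results.
    """
    rng_root = np.random.SeedSequence(config.seed)
    s_partition, s_random = rng_root.spawn(2)

    cohort = generate_cohort(config.cohort_config(), config.coupling_spec(),
                             mode=config.mode)
    if config.mode == "raw":
        segments = []
        for rec in cohort.recordings:
            segments.extend(preprocess_recording(
                rec, pad_s=config.pad_s, cut_len_s=config.cut_len_s,
                min_keep_s=config.min_keep_s, trim_len_s=config.trim_len_s,
                amp_z_max=config.amp_z_max, grad_z_max=config.grad_z_max))
    else:
        segments = cohort.segments

    X, y, subj = _segments_to_samples(segments, config.band_hz,
                                      config.window_s, config.overlap)

    uniq, counts = np.unique(subj, return_counts=True)
    groups = np.array([CPS if s.startswith("cps") else "SPS" for s in uniq])
    partition = cl.build_subset_partition(
        uniq, groups, counts, seed=s_partition,
        n_test=config.n_test_subsets, test_subsets=config.test_subsets)
    subset_of = partition.subset_of_subject()
    sample_subset = np.array([subset_of[s] for s in subj])
    test_mask = np.isin(sample_subset, partition.test_subsets)

    X_tr, y_tr, sub_tr = X[~test_mask], y[~test_mask], sample_subset[~test_mask]
    X_te, y_te = X[test_mask], y[test_mask]

    models, reports, tables, fold_frames = {}, {}, {}, {}
    for scheme in config.schemes:
        model = cl.StabilitySelectedSVC(
            scheme=scheme, select_fraction=config.k_fraction,
            overlap_threshold=config.overlap_threshold, C=config.C,
            gamma=config.gamma, n_reps=config.n_reps,
            train_frac=config.train_frac,
            strong_fraction=config.strong_fraction,
            random_state=s_random)
        model.fit(X_tr, y_tr, subset_ids=sub_tr)
        models[scheme] = model
        reports[scheme] = model.evaluate(X_te, y_te,
                                         subject_ids=subj[test_mask])
        fold_frames[scheme] = pd.DataFrame([
            {"fold": fr.fold_id + 1,
             "validation_accuracy_pct": 100 * fr.validation_accuracy,
             "n_selected": fr.selected_features.size}
            for fr in model.fold_results_])
    for scheme in config.schemes:
        other = [s for s in config.schemes if s != scheme]
        coincident = (set(models[other[0]].selected_features_.tolist())
                      if other else None)
        tables[scheme] = edge_report(models[scheme].stability_,
                                     default_atlas(config.n_parcels),
                                     config.n_parcels,
                                     coincident_with=coincident)

    chash = config_hash(config)
    metrics = {"config_hash": chash, "seed": config.seed,
               "n_segments": int(len(segments)),
               "n_test_segments": int(test_mask.sum()),
               "schemes": {}}
    for scheme in config.schemes:
        accs = fold_frames[scheme]["validation_accuracy_pct"]
        rep = reports[scheme]
        metrics["schemes"][scheme] = {
            "validation_mean_pct": float(accs.mean()),
            "validation_min_pct": float(accs.min()),
            "validation_max_pct": float(accs.max()),
            "test_accuracy_pct": 100 * rep.accuracy,
            "test_sensitivity_pct": 100 * rep.sensitivity,
            "test_specificity_pct": 100 * rep.specificity,
            "subject_majority_accuracy": rep.subject_majority_accuracy,
            "n_stable_features": int(
                models[scheme].selected_features_.size),
        }

    result = PipelineResult(config=config, models=models, reports=reports,
                            edge_tables=tables, metrics=metrics,
                            ground_truth_edges=cohort.ground_truth_edges)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_config(config, out / "config.yaml")
        idx_map = feature_index_map(config.n_parcels)
        for scheme in config.schemes:
            fold_frames[scheme].assign(config_hash=chash).to_csv(
                out / f"folds_{scheme}.csv", index=False)
            tables[scheme].assign(config_hash=chash).to_csv(
                out / f"stable_edges_{scheme}.csv", index=False)
            stab = models[scheme].stability_
            pd.DataFrame({
                "i": idx_map[stab.stable_features, 0],
                "j": idx_map[stab.stable_features, 1],
                "weight": stab.mean_fscores,
            }).to_csv(out / f"edges_{scheme}.csv", index=False)
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    return result
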