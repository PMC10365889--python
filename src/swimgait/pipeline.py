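"""End-to-end pipeline: simulate -> pose -> behavior -> metrics -> embedding
-> tensor components -> outcome statistics.

Each stage reads its inputs from and writes its outputs to a results
directory, records a completion marker carrying the config hash and seed,
and is skipped on re-runs unless forced.  Stage failures halt with the stage
name and offending assay.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, capacity, embedding, gait, stats, tca
from .core import N_ANGLES, PoseSequence, week_index
from .io import (config_hash, read_pose_table, read_stamped_csv,
                 write_manifest, write_pose_table, write_stamped_csv)
from .pose import process_assay
from .simulate import SimConfig, outcomes_frame, simulate_cohort

STAGES = ("simulate", "pose", "train", "classify", "metrics",
          "embed", "tca", "stats")


@dataclass
class PipelineConfig:
    """Analysis knobs layered over the simulator configuration."""

    sim: SimConfig = field(default_factory=SimConfig)
    activity_threshold: float = 2.0       # px/frame, above the tracking noise
    scoliosis_cutoff: float = embedding.SCOLIOSIS_CUTOFF
    max_windows_per_class: int = 300
    tca_ranks: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    tca_replicates: int = 4
    min_cluster_size: int = 3
    max_cruises_per_assay: int = 8

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _marker(out: Path, stage: str) -> Path:
    return out / "log" / f"{stage}.done.json"


def _stage_done(out: Path, stage: str, chash: str) -> bool:
    m = _marker(out, stage)
    if not m.exists():
        return False
    try:
        return json.loads(m.read_text()).get("config_hash") == chash
    except json.JSONDecodeError:
        return False


def _mark(out: Path, stage: str, chash: str, **info) -> None:
    m = _marker(out, stage)
    m.parent.mkdir(parents=True, exist_ok=True)
    m.write_text(json.dumps({"stage": stage, "config_hash": chash, **info}))


def _assay_paths(out: Path) -> list[tuple[str, str, Path]]:
    rows = []
    for p in sorted((out / "poses").glob("*.csv")):
        fish_id, week = p.stem.rsplit("_", 1)
        rows.append((fish_id, week, p))
    return rows


def run_pipeline(out_dir: str | Path, config: PipelineConfig | None = None,
                 force: bool = False) -> Path:
    """Run all stages; returns the results directory."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cdict = config.to_dict()
    chash = config_hash(cdict)
    seed = config.sim.rng_seed

    for stage in STAGES:
        if not force and _stage_done(out, stage, chash):
            continue
        try:
            _STAGE_FUNCS[stage](out, config, cdict, seed)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        _mark(out, stage, chash, seed=seed)
    return out


# ---------------------------------------------------------------------------
# stages

def stage_simulate(out: Path, config: PipelineConfig, cdict: dict,
                   seed: int) -> None:
    records = simulate_cohort(config.sim.n_fish, config.sim)
    (out / "poses").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    fish_entries = []
    for rec in records:
        entry = {"fish_id": rec.phenotype.fish_id, "sex": rec.phenotype.sex,
                 "survived": rec.survived, "assays": {}}
        for week, assay in rec.assays.items():
            name = f"{rec.phenotype.fish_id}_{week}.csv"
            write_pose_table(assay.poses, out / "poses" / name,
                             assay_id=f"{rec.phenotype.fish_id}:{week}")
            truth = pd.DataFrame({
                "frame": np.arange(len(assay.truth.labels)),
                "label": assay.truth.labels.astype(str),
                "corrupt": assay.truth.corrupt.astype(int)
                if assay.truth.corrupt is not None else 0})
            truth.attrs = {}
            write_stamped_csv(truth, out / "truth" / name, cdict, seed)
            entry["assays"][week] = f"poses/{name}"
        fish_entries.append(entry)
    write_stamped_csv(outcomes_frame(records), out / "outcomes.csv", cdict, seed)
    write_manifest(out / "manifest.yaml", fish_entries, "outcomes.csv", cdict)


def _processed_path(out: Path, fish_id: str, week: str) -> Path:
    return out / "processed" / f"{fish_id}_{week}.csv"


def stage_pose(out: Path, config: PipelineConfig, cdict: dict,
               seed: int) -> None:
    for fish_id, week, p in _assay_paths(out):
        seq = read_pose_table(p)
        proc = process_assay(seq)
        df = pd.DataFrame({"frame": np.arange(seq.n_frames),
                           "valid": proc["valid"].astype(int),
                           "reason": proc["quality"]["reason"]})
        for a in range(N_ANGLES):
            df[f"angle_{a}"] = proc["angles"][:, a]
        for k in range(10):
            df[f"c{k}_x"] = proc["centerline"][:, k, 0]
            df[f"c{k}_y"] = proc["centerline"][:, k, 1]
        df["tail_x"] = proc["tail_tip"][:, 0]
        df["tail_y"] = proc["tail_tip"][:, 1]
        write_stamped_csv(df, _processed_path(out, fish_id, week), cdict, seed)


def _load_processed(out: Path, fish_id: str, week: str):
    df = read_stamped_csv(_processed_path(out, fish_id, week))
    angles = df[[f"angle_{a}" for a in range(N_ANGLES)]].to_numpy()
    centerline = np.stack(
        [df[[f"c{k}_x", f"c{k}_y"]].to_numpy() for k in range(10)], axis=1)
    tail = df[["tail_x", "tail_y"]].to_numpy()
    valid = df["valid"].to_numpy().astype(bool)
    return angles, centerline, tail, valid


def stage_train(out: Path, config: PipelineConfig, cdict: dict,
                seed: int) -> None:
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    for fish_id, week, p in _assay_paths(out):
        truth = read_stamped_csv(out / "truth" / p.name)
        angles, _, _, valid = _load_processed(out, fish_id, week)
        labels = truth["label"].to_numpy(dtype=object)
        wins, centers, y = behavior.build_pose_windows(angles, valid, labels)
        if len(centers) == 0:
            continue
        # keep windows whose full span shares one annotated behavior
        span = np.array([len(set(labels[c - 6:c + 7])) == 1 for c in centers])
        X_parts.append(wins[span])
        y_parts.append(y[span])
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    keep_idx = []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        if len(idx) > config.max_windows_per_class:
            idx = rng.choice(idx, size=config.max_windows_per_class,
                             replace=False)
        keep_idx.append(idx)
    keep = np.sort(np.concatenate(keep_idx))
    clf = behavior.train_behavior_classifier(X[keep], y[keep], rng_seed=seed)
    import joblib
    (out / "model").mkdir(exist_ok=True)
    joblib.dump(clf, out / "model" / "behavior_classifier.joblib")
    (out / "model" / "training_report.json").write_text(
        json.dumps(clf.report_, indent=2))


def stage_classify(out: Path, config: PipelineConfig, cdict: dict,
                   seed: int) -> None:
    import joblib
    clf = joblib.load(out / "model" / "behavior_classifier.joblib")
    (out / "labels").mkdir(exist_ok=True)
    ep_rows = []
    for fish_id, week, p in _assay_paths(out):
        seq = read_pose_table(p)
        angles, _, _, valid = _load_processed(out, fish_id, week)
        labels = behavior.annotate_frames(angles, valid, clf)
        write_stamped_csv(pd.DataFrame({"frame": np.arange(len(labels)),
                                        "label": labels.astype(str)}),
                          out / "labels" / p.name, cdict, seed)
        eps = behavior.segment_episodes(labels, angles, seq.frame_rate,
                                        seq.flow_velocity())
        for ep in eps:
            ep_rows.append({"assay_id": f"{fish_id}:{week}", "fish_id": fish_id,
                            "week": week, "label": ep.label, "start": ep.start,
                            "end": ep.end, "flow_cm_s": ep.flow_cm_s,
                            "n_extrema": ep.n_extrema})
    write_stamped_csv(pd.DataFrame(ep_rows), out / "episodes.csv", cdict, seed)


def _episodes_for(episodes_df: pd.DataFrame, fish_id: str, week: str):
    from .core import BehaviorEpisode
    sel = episodes_df[(episodes_df["fish_id"] == fish_id)
                      & (episodes_df["week"].astype(str) == str(week))]
    return [BehaviorEpisode(label=r.label, start=int(r.start), end=int(r.end),
                            flow_cm_s=float(r.flow_cm_s),
                            n_extrema=int(r.n_extrema))
            for r in sel.itertuples()]


def stage_metrics(out: Path, config: PipelineConfig, cdict: dict,
                  seed: int) -> None:
    episodes_df = read_stamped_csv(out / "episodes.csv")
    assays = _assay_paths(out)

    # pass 1: cruise profiles (for the control profile) and control poses
    profiles: dict[tuple[str, str], gait.CruiseCurvatureProfile | None] = {}
    control_angles = []
    cached = {}
    for fish_id, week, p in assays:
        angles, centerline, tail, valid = _load_processed(out, fish_id, week)
        eps = _episodes_for(episodes_df, fish_id, week)
        cached[(fish_id, week)] = (angles, centerline, tail, valid, eps, p)
        cruises = gait.episode_angles(angles, eps, "cruise")
        profiles[(fish_id, week)] = gait.cruise_curvature_profile(
            cruises, (fish_id, week))
        if week == "control":
            control_angles.append(angles[valid])
    control_profs = [pr for (f, w), pr in profiles.items()
                     if w == "control" and pr is not None]
    control = gait.control_profile(control_profs)
    pd.DataFrame({"position": np.arange(1, N_ANGLES + 1),
                  "amplitude": control}).to_csv(
        out / "control_profile.csv", index=False)

    novelty = gait.PostureNoveltyScorer(random_state=seed)
    rng = np.random.default_rng(seed)
    sub = [a if len(a) <= 3000 else a[rng.choice(len(a), 3000, replace=False)]
           for a in control_angles if len(a) >= 12]
    novelty_ok = bool(sub)
    if novelty_ok:
        novelty.fit(sub)

    rows = []
    for (fish_id, week), (angles, centerline, tail, valid, eps, p) in cached.items():
        seq = read_pose_table(p)
        track = capacity.CentroidTrack.from_centerline(centerline, valid)
        frame_labels = np.full(len(angles), "", dtype=object)
        for ep in eps:
            frame_labels[ep.start:ep.end] = ep.label
        cap = capacity.compute_capacity_metrics(
            track, frame_labels, seq, config.activity_threshold)
        gm = gait.compute_gait_metrics(angles, centerline, tail, eps, seq,
                                       control=control, valid=valid,
                                       assay_key=(fish_id, week))
        prof = gm.pop("profile")
        row = {"fish_id": fish_id, "week": week, **cap, **gm}
        if prof is not None:
            for a in range(N_ANGLES):
                row[f"profile_{a + 1}"] = prof.amplitudes[a]
        row["posture_novelty"] = (novelty.score_assay(angles[valid])
                                  if novelty_ok else float("nan"))
        rows.append(row)
    write_stamped_csv(pd.DataFrame(rows), out / "metrics.csv", cdict, seed)


MEASUREMENTS = ("distance", "activity", "centroid_burst_frequency",
                "pose_burst_frequency", "time_against_flow", "mean_y",
                "rostral_compensation", "summed_rostral_amplitude",
                "cruise_angular_frequency", "tail_beat_frequency",
                "scoliosis", "posture_novelty")


def stage_embed(out: Path, config: PipelineConfig, cdict: dict,
                seed: int) -> None:
    metrics = read_stamped_csv(out / "metrics.csv")
    episodes_df = read_stamped_csv(out / "episodes.csv")
    # omit fish with late scoliosis above the cutoff
    late = metrics[metrics["week"].astype(str) == "8"]
    bad_fish = set(late[late["scoliosis"] > config.scoliosis_cutoff]["fish_id"])
    cruise_sets, keys = [], []
    for fish_id, week, p in _assay_paths(out):
        if fish_id in bad_fish:
            continue
        angles, _, _, valid = _load_processed(out, fish_id, week)
        eps = [e for e in _episodes_for(episodes_df, fish_id, week)
               if e.label == "cruise"][:config.max_cruises_per_assay]
        for k, e in enumerate(eps):
            cruise_sets.append(angles[e.start:e.end])
            keys.append((fish_id, week, k))
    if len(cruise_sets) < 4:
        warnings.warn("too few cruises to embed; stage skipped")
        write_stamped_csv(pd.DataFrame(
            columns=["fish_id", "week", "episode", "umap_1", "umap_2", "umap_3"]),
            out / "embedding.csv", cdict, seed)
        return
    traces, _ = embedding.decompose_cruises(cruise_sets)
    exemplar_idx = []
    by_assay: dict[tuple[str, str], list[int]] = {}
    for i, (fish_id, week, k) in enumerate(keys):
        by_assay.setdefault((fish_id, week), []).append(i)
    for assay, idxs in by_assay.items():
        sel = embedding.select_exemplars([traces[i] for i in idxs],
                                         random_state=seed)
        exemplar_idx.extend(idxs[i] for i in sel)
    exemplar_idx = sorted(exemplar_idx)
    D = embedding.dtw_matrix([traces[i] for i in exemplar_idx])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = embedding.embed_cruises(D, random_state=seed)
    rows = []
    for row_i, i in enumerate(exemplar_idx):
        fish_id, week, k = keys[i]
        rows.append({"fish_id": fish_id, "week": week, "episode": k,
                     "umap_1": coords[row_i, 0], "umap_2": coords[row_i, 1],
                     "umap_3": coords[row_i, 2]})
    emb_df = pd.DataFrame(rows)
    write_stamped_csv(emb_df, out / "embedding.csv", cdict, seed)
    dens = embedding.density_by_week(coords, emb_df["week"].to_numpy())
    means = pd.DataFrame([{"week": wk, "n": v["n"],
                           **{f"mean_umap_{c + 1}": v["mean"][c]
                              for c in range(coords.shape[1])}}
                          for wk, v in dens.items()])
    write_stamped_csv(means, out / "embedding_week_means.csv", cdict, seed)


def _drop_sparse_measurements(df: pd.DataFrame, meas: list[str],
                              max_nan_frac: float = 0.25) -> list[str]:
    """Keep measurements defined in most assays; sparse ones (e.g. Strouhal
    at desk scale, when short still-water periods yield no usable cruise)
    would otherwise exclude every fish."""
    return [m for m in meas if df[m].isna().mean() <= max_nan_frac]


def stage_tca(out: Path, config: PipelineConfig, cdict: dict,
              seed: int) -> None:
    metrics = read_stamped_csv(out / "metrics.csv")
    meas = _drop_sparse_measurements(
        metrics, [m for m in MEASUREMENTS if m in metrics.columns],
        max_nan_frac=0.1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tensor = tca.assemble_tensor(metrics, meas)
    ranks = [r for r in config.tca_ranks
             if r <= min(np.prod(np.delete(tensor.values.shape, i))
                         for i in range(3))]
    models = tca.fit_cp_models(tensor, ranks, config.tca_replicates, seed)
    best, curves = tca.select_model(models)
    write_stamped_csv(curves, out / "tca_selection.csv", cdict, seed)
    for mode, names in (("fish", tensor.fish_ids), ("assay", tensor.weeks),
                        ("measurement", tensor.measurements)):
        i = ("fish", "assay", "measurement").index(mode)
        df = pd.DataFrame(best.factors[i],
                          columns=[f"component_{c + 1}" for c in range(best.rank)])
        df.insert(0, mode, names)
        write_stamped_csv(df, out / f"tca_factors_{mode}.csv", cdict, seed)
    labels, thr, report = tca.cluster_fish_factors(
        best, min_cluster_size=config.min_cluster_size)
    outcomes = read_stamped_csv(out / "outcomes.csv")
    summary = tca.summarize_clusters(labels, tensor.fish_ids, outcomes)
    write_stamped_csv(pd.DataFrame({"fish_id": tensor.fish_ids,
                                    "cluster": labels}),
                      out / "tca_clusters.csv", cdict, seed)
    write_stamped_csv(summary, out / "tca_cluster_summary.csv", cdict, seed)


def stage_stats(out: Path, config: PipelineConfig, cdict: dict,
                seed: int) -> None:
    metrics = read_stamped_csv(out / "metrics.csv")
    outcomes = read_stamped_csv(out / "outcomes.csv")
    metrics["week"] = metrics["week"].astype(str)
    meas = [m for m in MEASUREMENTS if m in metrics.columns]
    meas = _drop_sparse_measurements(metrics[metrics["week"] == "8"], meas)

    wk8 = metrics[metrics["week"] == "8"].set_index("fish_id")[meas]
    table = wk8.join(outcomes.set_index("fish_id")[
        ["glial_bridging", "axon_proximal", "axon_distal"]], how="inner")
    ctrl_means = metrics[metrics["week"] == "control"][meas].mean()
    wk1_means = metrics[metrics["week"] == "1"][meas].mean()
    aligned, flipped = stats.sign_align_metrics(table, ctrl_means, wk1_means)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corr, pvals = stats.spearman_matrix(aligned)
        clusters = stats.cluster_metrics(corr)
    corr.to_csv(out / "correlation_rs.csv")
    pvals.to_csv(out / "correlation_p.csv")
    pd.DataFrame({"metric": clusters["labels"].index,
                  "cluster": clusters["labels"].to_numpy()}).to_csv(
        out / "correlation_clusters.csv", index=False)

    sexes = outcomes.set_index("fish_id")["sex"]
    early = metrics[metrics["week"].isin(["1", "2"])][
        ["fish_id", "week", "distance", "rostral_compensation"]].copy()
    early["sex"] = early["fish_id"].map(sexes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wellness = stats.wellness_scores(early)
        report = stats.evaluate_prediction(wellness, outcomes)
    write_stamped_csv(wellness, out / "wellness.csv", cdict, seed)
    write_stamped_csv(report, out / "prediction_report.csv", cdict, seed)


_STAGE_FUNCS = {"simulate": stage_simulate, "pose": stage_pose,
                "train": stage_train, "classify": stage_classify,
                "metrics": stage_metrics, "embed": stage_embed,
                "tca": stage_tca, "stats": stage_stats}
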