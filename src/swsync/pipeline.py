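"""End-to-end orchestration: preprocess -> detect -> cluster -> GLM -> PMI.

The functions here glue the stage modules together for multi-run analyses,
including the surrogate-based PMI significance test (detection and labeling
re-run on every phase-randomized dataset) and ground-truth evaluation
helpers for simulated runs.
"""

from __future__ import annotations

import json
import os


import numpy as np

from . import io as sio
from .cluster import (ClusterModel, center_unit, fit_kmeans_corr,
                      occurrence_timecourse, pair_subclusters, transition_matrix)
from .config import PipelineConfig, get_logger
from .detect import detect_ts, swpca
from .glm import build_design, group_stats, run_glm
from .pmi import pmi_decompositions, pmi_significance
from .preprocess import (RoiTimeseries, bandpass, framewise_displacement,
                         scrub_mask, trim_frames)
from .surrogates import phase_randomize


def preprocess_run(ts: RoiTimeseries, config: PipelineConfig, motion=None):
    """Band-pass, trim, and derive the scrub mask for one run.

    Returns (trimmed_ts, scrub_mask_or_None); the mask is trimmed to the same
    frame space as the data.
    """
    filtered = bandpass(ts, config.band_low, config.band_high)
    trimmed = trim_frames(filtered, config.trim, config.trim)
    mask = None
    if motion is not None:
        fd = framewise_displacement(motion, config.head_radius)
        full = scrub_mask(fd, config.fd_threshold, config.scrub_after)
        full.mask = full.mask[config.trim:ts.n_frames - config.trim]
        mask = full
    return trimmed, mask


def detect_run(ts: RoiTimeseries, config: PipelineConfig, mask=None):
    """Sliding-window PCA plus TS event detection for one (preprocessed) run."""
    res = swpca(ts, config.window_size)
    return detect_ts(res, mask, smooth=config.var_smooth), res


def label_events(events, model: ClusterModel, inplace: bool = True):
    """Assign each event the sub-cluster of its most correlated centroid."""
    if not events:
        return events
    V = center_unit(np.stack([ev.tsp for ev in events]))
    labels = np.argmax(V @ model.centroids.T, axis=1)
    for ev, lab in zip(events, labels):
        ev.sub_cluster = int(lab)
    return events


def cluster_runs(events_per_run, config: PipelineConfig):
    """Fit the sub-cluster model on pooled events and pair sub-clusters.

    Events are labeled in place with their fitted sub-cluster. Returns
    (model, transitions); ``model.pairing`` maps sub-cluster -> cluster.
    """
    pooled = [ev for events in events_per_run for ev in events]
    if len(pooled) < config.k:
        raise ValueError(f"only {len(pooled)} events pooled; need >= k={config.k}")
    tsps = np.stack([ev.tsp for ev in pooled])
    model = fit_kmeans_corr(tsps, k=config.k, n_init=config.n_init,
                            seed=config.seed)
    i = 0
    for events in events_per_run:
        for ev in events:
            ev.sub_cluster = int(model.labels[i])
            i += 1
    sequences = [[ev.sub_cluster for ev in events] for events in events_per_run
                 if len(events) >= 2]
    transitions = transition_matrix(sequences, model.k)
    pair_subclusters(model, transitions)
    return model, transitions


def occurrences_per_run(events_per_run, n_frames: int, model: ClusterModel,
                        smooth_w: int = 50):
    return [occurrence_timecourse(events, n_frames, model.pairing, smooth_w)
            for events in events_per_run]


def pmi_null_test(runs, config: PipelineConfig, n_surrogates: int = 100,
                  tau_max: int = None, t_stride: int = 1, tau_stride: int = 1,
                  seed: int = 0, preprocess: bool = False):
    """PMI decomposition of a dataset with surrogate-based FWE p-values.

    The detection + clustering + occurrence + PMI chain runs on the given
    runs; the identical chain (with sub-cluster labels transferred by nearest
    centroid from the fitted model) runs on ``n_surrogates`` common-phase
    randomized copies of the dataset; family-wise p-values per coefficient
    type come from the per-surrogate maximum statistic.

    Returns (real_decomps, pvals).
    """
    if preprocess:
        runs = [preprocess_run(ts, config)[0] for ts in runs]
    n_frames = runs[0].n_frames
    if tau_max is None:
        tau_max = n_frames // 2
    events_per_run = [detect_run(ts, config)[0] for ts in runs]
    model, _ = cluster_runs(events_per_run, config)
    n_clusters = len(set(model.pairing.values()))

    def decomps_for(events_lists):
        occs = occurrences_per_run(events_lists, n_frames, model,
                                   config.pmi_smooth)
        return pmi_decompositions(occs, n_clusters, tau_max,
                                  t_stride=t_stride, tau_stride=tau_stride,
                                  t_trim=config.pmi_t_trim,
                                  tau_min=config.pmi_tau_min,
                                  on_insufficient="skip")

    real = decomps_for(events_per_run)
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_surrogates):
        sur_events = []
        for ts in runs:
            sur = phase_randomize(ts, int(rng.integers(2 ** 31)))
            events, _ = detect_run(sur, config)
            label_events(events, model)
            sur_events.append(events)
        null.append(decomps_for(sur_events))
    pvals = pmi_significance(real, null)
    return real, pvals


# ---------------------------------------------------------------------------
# Ground-truth evaluation helpers for synthetic runs
# ---------------------------------------------------------------------------

def match_events(true_frames, detected_frames, tol: int = 3,
                 false_radius: int = None):
    """Greedy one-to-one matching of detected to true event frames.

    A true event is recovered when a detection lies within ``tol`` frames of
    it (one-to-one). A detection counts as false when it lies farther than
    ``false_radius`` from every true event, i.e. when no event can account
    for it; ``false_radius`` defaults to ``tol``, but an attribution radius
    of half the analysis window separates mislocalization from genuinely
    spurious maxima.

    Returns (n_matched, n_false).
    """
    if false_radius is None:
        false_radius = tol
    true_arr = np.asarray(sorted(int(f) for f in true_frames))
    detected = sorted(int(f) for f in detected_frames)
    used = [False] * len(true_arr)
    n_matched = 0
    n_false = 0
    for d in detected:
        best, best_dist = None, tol + 1
        for i, t in enumerate(true_arr):
            if not used[i] and abs(d - t) <= tol and abs(d - t) < best_dist:
                best, best_dist = i, abs(d - t)
        if best is not None:
            used[best] = True
            n_matched += 1
        elif true_arr.size == 0 or np.abs(true_arr - d).min() > false_radius:
            n_false += 1
    return n_matched, n_false


def recovered_pairs(model: ClusterModel, patterns, r_thresh: float = 0.9):
    """Count designed anti-correlated pattern pairs recovered by the model.

    A designed pair counts as recovered when some fitted sub-cluster pair's
    two centroids correlate (r >= ``r_thresh``) with the pair's two patterns,
    one-to-one. Returns (n_recovered, details).
    """
    if model.pairing is None:
        raise ValueError("model has no pairing; run pair_subclusters first")
    P = center_unit(patterns.patterns)
    corr = model.centroids @ P.T               # (k, n_patterns)
    by_cluster = {}
    for sub, cid in model.pairing.items():
        by_cluster.setdefault(cid, []).append(sub)
    truth_pairs = {frozenset((i, patterns.pairing[i]))
                   for i in range(patterns.n_patterns)}
    recovered = set()
    details = []
    for cid, (a, b) in sorted((c, tuple(sorted(s))) for c, s in by_cluster.items()):
        pa = int(np.argmax(corr[a]))
        pb = int(np.argmax(corr[b]))
        ra, rb = corr[a, pa], corr[b, pb]
        pair = frozenset((pa, pb))
        ok = (pair in truth_pairs and ra >= r_thresh and rb >= r_thresh
              and pa != pb)
        if ok:
            recovered.add(pair)
        details.append({"cluster": cid, "subclusters": (a, b),
                        "patterns": (pa, pb), "r": (float(ra), float(rb)),
                        "recovered": ok})
    return len(recovered), details


# ---------------------------------------------------------------------------
# File-based end-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, inputs: dict, out_dir) -> dict:
    """Execute the full file-based pipeline and write an artifact directory.

    ``inputs`` must contain ``roi_tsv`` (list of ROI TSV paths) and may
    contain ``motion`` (parallel list of motion text paths) and
    ``voxel_nifti`` (parallel list of 4-D NIfTI paths for SAP maps). Each
    stage writes its outputs under ``out_dir``; a JSON provenance record
    (config, seeds, stage manifest) is always written, and a stage failure
    aborts with the stage name after dumping the partial manifest.
    """
    log = get_logger()
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"config": config.to_dict(), "config_hash": config.hash(),
                "stages": [], "outputs": []}

    def fail(stage, exc):
        manifest["failed_stage"] = stage
        with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    try:
        runs = [sio.read_roi_tsv(p, tr=config.tr) for p in inputs["roi_tsv"]]
        motions = [sio.read_motion(p) for p in inputs.get("motion", [])] or \
            [None] * len(runs)
    except Exception as exc:
        fail("load", exc)

    try:
        pre = [preprocess_run(ts, config, m) for ts, m in zip(runs, motions)]
        trimmed = [p[0] for p in pre]
        masks = [p[1] for p in pre]
        manifest["stages"].append("preprocess")
    except Exception as exc:
        fail("preprocess", exc)

    try:
        events_per_run = []
        for ts, mask in zip(trimmed, masks):
            events, _ = detect_run(ts, config, mask)
            events_per_run.append(events)
        manifest["stages"].append("detect")
    except Exception as exc:
        fail("detect", exc)

    try:
        model, transitions = cluster_runs(events_per_run, config)
        for i, (ts, events) in enumerate(zip(trimmed, events_per_run)):
            path = os.path.join(out_dir, f"events_run{i}.tsv")
            sio.write_events_tsv(events, path, frame_offset=ts.frame_offset)
            manifest["outputs"].append(path)
        model_path = os.path.join(out_dir, "cluster_model.tsv")
        sio.write_cluster_model(model, model_path)
        np.savetxt(os.path.join(out_dir, "transitions.tsv"), transitions,
                   fmt="%d", delimiter="\t")
        manifest["outputs"] += [model_path, os.path.join(out_dir, "transitions.tsv")]
        manifest["stages"].append("cluster")
    except Exception as exc:
        fail("cluster", exc)

    if inputs.get("voxel_nifti"):
        try:
            betas_by_subject = {}
            for i, (ts, events, path) in enumerate(zip(trimmed, events_per_run,
                                                       inputs["voxel_nifti"])):
                matrix, affine, shape = sio.read_nifti4d(path)
                design = build_design(events, ts.n_frames, config.tr,
                                      n_subclusters=config.k,
                                      glm_trim=config.glm_trim)
                betas, _, _ = run_glm(matrix, design)
                subj = ts.subject_id or f"subj{i}"
                betas_by_subject.setdefault(subj, []).append(betas.T[:-1])
                for sc, name in enumerate(design.names[:-1]):
                    out = os.path.join(out_dir, f"beta_run{i}_{name}.nii.gz")
                    sio.write_nifti_map(betas[:, sc], affine, shape, out)
                    manifest["outputs"].append(out)
            if len(betas_by_subject) >= 2:
                z, report = group_stats(betas_by_subject)
                np.savetxt(os.path.join(out_dir, "group_z.tsv"), z,
                           delimiter="\t")
                manifest["outputs"].append(os.path.join(out_dir, "group_z.tsv"))
            manifest["stages"].append("sap_glm")
        except Exception as exc:
            fail("sap_glm", exc)

    try:
        n_frames = trimmed[0].n_frames
        occs = occurrences_per_run(events_per_run, n_frames, model,
                                   config.pmi_smooth)
        n_clusters = len(set(model.pairing.values()))
        decs = pmi_decompositions(occs, n_clusters, tau_max=n_frames // 2,
                                  t_trim=config.pmi_t_trim,
                                  tau_min=config.pmi_tau_min)
        rows = ["pair_a\tpair_b\tlag_coef\ttime_coef\tconst"]
        for (a, b), d in sorted(decs.items()):
            rows.append(f"{a}\t{b}\t{d.lag_coef:.8g}\t{d.time_coef:.8g}\t{d.const:.8g}")
        pmi_path = os.path.join(out_dir, "pmi_decomposition.tsv")
        with open(pmi_path, "w") as fh:
            fh.write("\n".join(rows) + "\n")
        manifest["outputs"].append(pmi_path)
        manifest["stages"].append("pmi")
    except Exception as exc:
        fail("pmi", exc)

    with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("pipeline complete: %d stage(s), %d output file(s)",
             len(manifest["stages"]), len(manifest["outputs"]))
    return manifest
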