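"""End-to-end pipeline: simulate -> preprocess -> FC -> states -> stats -> classify.

One :class:`RunConfig` drives every stage; a single master seed derives all
stage seeds deterministically, so reruns with the same config produce
byte-identical artifacts (verified via the manifest's content hashes).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import clustering as clus
from . import cohort as coh
from . import connectivity as conn
from . import dynamics as dyn
from . import stats as gstats
from .preprocess import SubjectTimecourses, preprocess_subject

__all__ = ["RunConfig", "run_pipeline", "subject_window_vectors", "report"]


@dataclass
class RunConfig:
    """Flat configuration for a full run; defaults follow the study settings."""

    seed: int = 0
    # cohort
    n_group_a: int = 20
    n_group_b: int = 20
    C: int = 20
    T: int = 255
    TR: float = 2.25
    k_true: int = 4
    effect_pairs: list = field(default_factory=lambda: [(1, (4, 19), -0.3)])
    noise_sd: float = 0.1
    # preprocessing
    detrend_order: int = 3
    cutoff_hz: float = 0.15
    fd_thresh: float = 0.5
    # windows / clustering
    window_width: int = 30
    window_step: int = 1
    count_convention: str = "n_minus_w"
    k: int = 4
    kmeans_replicates: int = 100
    elbow_range: tuple[int, int] = (2, 8)
    elbow_replicates: int = 5
    run_elbow: bool = False
    # stats
    n_perm: int = 10000
    q: float = 0.05
    # classification
    grid_size: int = 25
    inner_folds: int = 5
    run_classifier: bool = True
    network_filter: tuple[str, ...] = ("VIS", "FPN", "DMN")

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31)


def subject_window_vectors(
    subject_data: np.ndarray, spec: conn.WindowSpec
) -> np.ndarray:
    """Windowed FC for one subject as (n_windows x P) Fisher-z pair vectors."""
    mats = conn.windowed_fc(subject_data, spec)
    return conn.fisher_z(conn.vectorize_upper(mats))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 cohort: coh.Cohort | None = None) -> dict:
    """Execute all stages and write artifacts plus a hash manifest.

    Returns a results dict with the in-memory objects of every stage.
    ``cohort`` may be supplied to skip simulation (e.g. loaded from disk).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- simulate ----------------------------------------------------------
    if cohort is None:
        cfg = coh.CohortConfig(
            n_group_a=config.n_group_a, n_group_b=config.n_group_b,
            C=config.C, T=config.T, TR=config.TR, k_true=config.k_true,
            effect_pairs=list(config.effect_pairs), noise_sd=config.noise_sd,
            seed=config.stage_seed("simulate"),
        )
        cohort = coh.generate_cohort(cfg)
    network_map = cohort.config.network_map
    C = cohort.config.C
    groups = {s.subject_id: s.group for s in cohort}

    # -- preprocess --------------------------------------------------------
    processed: dict[str, np.ndarray] = {}
    spike_rows = []
    for subj in cohort:
        ts = SubjectTimecourses(
            data=subj.timecourses, tr=cohort.config.TR, motion=subj.motion,
            fd_trace=subj.fd_trace, subject_id=subj.subject_id,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clean, mask = preprocess_subject(
                ts, detrend_order=config.detrend_order,
                cutoff_hz=config.cutoff_hz, fd_thresh=config.fd_thresh)
        processed[subj.subject_id] = clean.data
        spike_rows.append({"subject_id": subj.subject_id,
                           "n_spikes": int(mask.sum())})
    pd.DataFrame(spike_rows).to_csv(out / "spike_counts.csv", index=False)

    # -- connectivity ------------------------------------------------------
    spec = conn.WindowSpec(config.window_width, config.window_step,
                           config.count_convention)
    static_vecs = {
        sid: conn.vectorize_upper(conn.static_fc(data))
        for sid, data in processed.items()
    }
    window_vecs = {sid: subject_window_vectors(data, spec)
                   for sid, data in processed.items()}

    # -- cluster -----------------------------------------------------------
    data, index = clus.concat_windows(window_vecs)
    elbow = None
    if config.run_elbow:
        elbow = clus.elbow_select(
            data, range(config.elbow_range[0], config.elbow_range[1] + 1),
            n_replicates=config.elbow_replicates,
            seed=config.stage_seed("elbow"))
        pd.DataFrame({"k": elbow.k_values, "validity": elbow.validity}).to_csv(
            out / "elbow.csv", index=False)
    model = clus.kmeans_states(data, config.k, index,
                               n_replicates=config.kmeans_replicates,
                               seed=config.stage_seed("cluster"))
    model.labels.to_csv(out / "labels.csv", index=False)
    iu, ju = conn.pair_index(C)
    cent_rows = []
    for s in range(config.k):
        for p, (i, j) in enumerate(zip(iu, ju)):
            cent_rows.append({"state": s + 1, "comp_i": int(i),
                              "comp_j": int(j), "z": model.centroids[s, p]})
    pd.DataFrame(cent_rows).to_csv(out / "centroids.csv", index=False)

    # -- dynamics ----------------------------------------------------------
    metrics = [dyn.compute_dynamics(sid, model.labels_for(sid), config.k)
               for sid in model.subject_ids]
    dyn.dynamics_table(metrics, config.k).to_csv(out / "dynamics.csv", index=False)

    # -- stats -------------------------------------------------------------
    meta = cohort.metadata.set_index("subject_id")
    covs = {
        sid: np.array([meta.loc[sid, "age"],
                       1.0 if meta.loc[sid, "sex"] == "F" else 0.0,
                       meta.loc[sid, "mean_fd"]])
        for sid in processed
    }
    stats_out: dict = {"states": {}}
    label_seqs = {sid: model.labels_for(sid) for sid in model.subject_ids}

    def _name_pairs(res):
        if res is not None:
            for r, i, j in zip(res, iu, ju):
                r.unit = f"pair({i},{j})"
        return res
    for state in range(1, config.k + 1):
        visitors = {
            sid: _state_mean_vector(window_vecs[sid], label_seqs[sid], state)
            for sid in label_seqs if np.any(label_seqs[sid] == state)
        }
        res = _name_pairs(gstats.statewise_fc_test(
            visitors, groups, covariates={s: covs[s] for s in visitors},
            n_perm=config.n_perm, q=config.q,
            seed=config.stage_seed(f"stats_state{state}")))
        stats_out["states"][state] = res
        if res is not None:
            pd.DataFrame([vars(r) for r in res]).to_csv(
                out / f"stats_state{state}.csv", index=False)
    static_res = _name_pairs(gstats.statewise_fc_test(
        static_vecs, groups, covariates=covs, n_perm=config.n_perm,
        q=config.q, seed=config.stage_seed("stats_static")))
    stats_out["static"] = static_res
    if static_res is not None:
        pd.DataFrame([vars(r) for r in static_res]).to_csv(
            out / "stats_static.csv", index=False)

    # dynamics ANOVAs (dwell on visited states; fraction on all)
    stats_out["anova"] = {}
    for metric in ("dwell", "fraction"):
        vals, gf, sf = [], [], []
        for m in metrics:
            for s in range(1, config.k + 1):
                v = m.dwell.get(s) if metric == "dwell" else m.fraction[s]
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    continue
                vals.append(v)
                gf.append(groups[m.subject_id])
                sf.append(s)
        stats_out["anova"][metric] = gstats.twoway_anova(vals, gf, sf)
    anova_rows = [
        {"metric": met, "factor": a.factor, "F": a.F, "p": a.p}
        for met, res in stats_out["anova"].items() for a in res
    ]
    pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)

    # -- classify ----------------------------------------------------------
    stats_out["classify"] = {}
    if config.run_classifier:
        targets: dict[str, dict[str, np.ndarray]] = {"static": static_vecs}
        for state in range(1, config.k + 1):
            targets[f"state{state}"] = {
                sid: _state_mean_vector(window_vecs[sid], label_seqs[sid], state)
                for sid in label_seqs if np.any(label_seqs[sid] == state)
            }
        for name, fc in targets.items():
            counts = pd.Series([groups[s] for s in fc]).value_counts()
            if len(fc) < 10 or counts.min() < 5:
                stats_out["classify"][name] = None
                continue
            feats = clf.build_features(fc, groups, network_map,
                                       set(config.network_filter))
            result = clf.loocv_l1_logreg(
                feats, n_grid=config.grid_size,
                inner_folds=config.inner_folds,
                seed=config.stage_seed(f"classify_{name}"))
            stats_out["classify"][name] = {
                "result": result,
                "confusion": clf.confusion_measures(result),
            }
            with open(out / f"confusion_{name}.json", "w") as fh:
                json.dump(clf.confusion_measures(result), fh, indent=1)

    # -- report + manifest -------------------------------------------------
    rep = report(stats_out, metrics, groups, config)
    with open(out / "report.json", "w") as fh:
        json.dump(rep, fh, indent=1, default=str)
    cfg_dict = asdict(config)
    with open(out / "config.json", "w") as fh:
        json.dump(cfg_dict, fh, indent=1, default=str)
    manifest = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return {
        "cohort": cohort, "processed": processed, "window_vecs": window_vecs,
        "static_vecs": static_vecs, "model": model, "elbow": elbow,
        "metrics": metrics, "stats": stats_out, "report": rep,
        "manifest": manifest,
    }


def _state_mean_vector(win_vecs: np.ndarray, labels: np.ndarray, state: int) -> np.ndarray:
    return win_vecs[labels == state].mean(axis=0)


def report(stats_out: dict, metrics: list, groups: dict, config: RunConfig) -> dict:
    """Summary of group differences, dynamics tests and classification."""
    rep: dict = {"states": {}, "classification": {}}
    for state, res in stats_out["states"].items():
        if res is None:
            rep["states"][str(state)] = {"status": "skipped"}
            continue
        sig = [r for r in res if r.significant]
        top = max(res, key=lambda r: abs(r.cohens_d))
        rep["states"][str(state)] = {
            "status": "ok",
            "n_fdr_significant": len(sig),
            "top_effect_pair": top.unit,
            "top_effect_d": round(top.cohens_d, 3),
        }
    rep["anova"] = {
        met: {a.factor: {"F": round(a.F, 3), "p": round(a.p, 5)} for a in res}
        for met, res in stats_out.get("anova", {}).items()
    }
    for name, entry in stats_out.get("classify", {}).items():
        if entry is None:
            rep["classification"][name] = {"status": "skipped"}
        else:
            c = entry["confusion"]
            rep["classification"][name] = {
                "status": "ok", "accuracy": round(c["accuracy"], 3),
                "TPR": round(c["TPR"], 3) if np.isfinite(c["TPR"]) else None,
                "TNR": round(c["TNR"], 3) if np.isfinite(c["TNR"]) else None,
            }
    return rep
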