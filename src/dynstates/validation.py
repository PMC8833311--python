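"""Recovery and calibration studies on synthetic cohorts.

Because the pipeline's scientific claims rest on what it can recover from
data with known ground truth, this module packages the standard validation
experiments as first-class, reusable drivers:

* :func:`run_recovery_study` — replicate cohorts with four separated state
  templates and injected group effects; measures elbow k-selection,
  window-label recovery (ARI over unambiguously labelled windows),
  matched-centroid fidelity, detection of the injected connectivity
  offset (and its specificity to the right state), and sign recovery of
  the dwell-time shift and transition volatility.
* :func:`null_fdr_study` — false-discovery calibration of the pairwise
  permutation-test + Benjamini-Hochberg pipeline on null cohorts.
* :func:`ttest_type1_study` / :func:`anova_type1_study` — type-I error
  calibration of the permutation t-test and the two-way ANOVA group
  effect.
* :func:`classifier_sanity` — LOOCV accuracy on separable features and
  chance-level behaviour under label permutation (leakage guard).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import classify as clf
from . import clustering as clus
from . import cohort as coh
from . import connectivity as conn
from . import dynamics as dyn
from . import stats as gstats
from .pipeline import subject_window_vectors

__all__ = [
    "CohortRecovery",
    "RecoveryStudy",
    "analyze_cohort_recovery",
    "run_recovery_study",
    "null_fdr_study",
    "ttest_type1_study",
    "anova_type1_study",
    "classifier_sanity",
]


@dataclass
class CohortRecovery:
    """Recovery measurements for one synthetic cohort."""

    seed: int
    chosen_k: int
    ari: float
    matched_r: list[float]
    effect_hit: bool
    effect_t: float
    effect_p_fdr: float
    other_state_flags: int  # injected pair flagged in non-effect states
    n_other_states_tested: int
    dwell_sign_ok: bool  # patient-like dwell lower in the dominant state
    shift_sign_ok: bool  # dwell pattern shifts from state 1 toward state 2
    transition_sign_ok: bool  # patient-like group transitions more
    severity_r: float  # corr(severity, total transitions) within group B


@dataclass
class RecoveryStudy:
    cohorts: list[CohortRecovery]

    @property
    def n(self) -> int:
        return len(self.cohorts)

    @property
    def elbow_k4_count(self) -> int:
        return sum(c.chosen_k == 4 for c in self.cohorts)

    @property
    def min_ari(self) -> float:
        return min(c.ari for c in self.cohorts)

    @property
    def min_matched_r(self) -> float:
        return min(min(c.matched_r) for c in self.cohorts)

    @property
    def effect_hit_count(self) -> int:
        return sum(c.effect_hit for c in self.cohorts)

    @property
    def other_state_flag_rate(self) -> float:
        flags = sum(c.other_state_flags for c in self.cohorts)
        tested = sum(c.n_other_states_tested for c in self.cohorts)
        return flags / max(tested, 1)

    @property
    def dwell_sign_count(self) -> int:
        return sum(c.dwell_sign_ok for c in self.cohorts)

    @property
    def shift_sign_count(self) -> int:
        return sum(c.shift_sign_ok for c in self.cohorts)

    @property
    def transition_sign_count(self) -> int:
        return sum(c.transition_sign_ok for c in self.cohorts)

    @property
    def severity_positive_count(self) -> int:
        return sum(c.severity_r > 0 for c in self.cohorts)


def analyze_cohort_recovery(
    seed: int,
    n_group_a: int = 50,
    n_group_b: int = 50,
    C: int = 20,
    T: int = 255,
    effect_pair: tuple[int, int] = (4, 19),
    effect_delta: float = -0.3,
    effect_state: int = 1,
    kmeans_replicates: int = 10,
    elbow_replicates: int = 5,
    run_elbow: bool = True,
    n_perm: int = 10000,
    q: float = 0.05,
) -> CohortRecovery:
    """Generate one cohort, run the pipeline, and score recovery.

    The model state corresponding to each generator template is identified
    by Hungarian matching of centroids to the template Fisher-z vectors,
    so scores are invariant to the arbitrary k-means state numbering.
    """
    cfg = coh.CohortConfig(
        n_group_a=n_group_a, n_group_b=n_group_b, C=C, T=T,
        effect_pairs=[(effect_state, effect_pair, effect_delta)], seed=seed,
    )
    cohort = coh.generate_cohort(cfg)
    spec = conn.WindowSpec(30, 1)
    wv = {s.subject_id: subject_window_vectors(s.timecourses, spec)
          for s in cohort}
    data, index = clus.concat_windows(wv)
    model = clus.kmeans_states(data, 4, index,
                               n_replicates=kmeans_replicates, seed=seed + 1)

    # window-label recovery over unambiguous windows
    true_labels = np.concatenate(
        [coh.true_window_labels(s.true_state_seq) for s in cohort])
    defined = true_labels > 0
    ari = adjusted_rand_score(true_labels[defined],
                              model.labels["state"].to_numpy()[defined])

    # template <-> model-state correspondence
    tpl_vecs = np.vstack([conn.fisher_z(conn.vectorize_upper(t.covariance))
                          for t in cohort.templates])
    perm = clus.match_states(tpl_vecs, model.centroids)
    matched_r = [
        float(np.corrcoef(tpl_vecs[i], model.centroids[perm[i]])[0, 1])
        for i in range(4)
    ]

    chosen_k = 4
    if run_elbow:
        elbow = clus.elbow_select(data, range(2, 9),
                                  n_replicates=elbow_replicates, seed=seed + 2)
        chosen_k = elbow.chosen_k

    # state-wise group test at the injected pair
    iu, ju = conn.pair_index(C)
    pidx = int(np.flatnonzero((iu == effect_pair[0]) & (ju == effect_pair[1]))[0])
    groups = {s.subject_id: s.group for s in cohort}
    labels = {sid: model.labels_for(sid) for sid in model.subject_ids}
    effect_model_state = perm[effect_state - 1] + 1

    def state_test(model_state: int):
        fc = {sid: wv[sid][labels[sid] == model_state].mean(axis=0)
              for sid in labels if np.any(labels[sid] == model_state)}
        return gstats.statewise_fc_test(fc, groups, n_perm=n_perm, q=q,
                                        seed=seed + 3)

    res = state_test(effect_model_state)
    effect_hit = bool(res is not None and res[pidx].significant
                      and res[pidx].t_stat > 0)
    effect_t = float(res[pidx].t_stat) if res else float("nan")
    effect_p_fdr = float(res[pidx].p_fdr) if res else float("nan")
    other_flags, other_tested = 0, 0
    for ms in range(1, 5):
        if ms == effect_model_state:
            continue
        r = state_test(ms)
        if r is not None:
            other_tested += 1
            other_flags += int(r[pidx].significant)

    # dynamics sign recovery
    metrics = [dyn.compute_dynamics(sid, labels[sid], 4) for sid in labels]
    s1 = perm[0] + 1
    s2 = perm[1] + 1

    def group_mean_dwell(state: int, group: str) -> float:
        vals = [m.dwell.get(state, np.nan) for m in metrics
                if groups[m.subject_id] == group]
        return float(np.nanmean(vals))

    dwell_sign_ok = group_mean_dwell(s1, "A") > group_mean_dwell(s1, "B")
    shift = ((group_mean_dwell(s2, "B") - group_mean_dwell(s1, "B"))
             - (group_mean_dwell(s2, "A") - group_mean_dwell(s1, "A")))
    trans_a = np.mean([m.total_transitions for m in metrics
                       if groups[m.subject_id] == "A"])
    trans_b = np.mean([m.total_transitions for m in metrics
                       if groups[m.subject_id] == "B"])
    sev = np.array([s.severity for s in cohort if s.group == "B"], dtype=float)
    tr_b = np.array([m.total_transitions for m in metrics
                     if groups[m.subject_id] == "B"], dtype=float)
    sev_r, _ = gstats.severity_correlation(tr_b, sev)

    return CohortRecovery(
        seed=seed, chosen_k=chosen_k, ari=float(ari), matched_r=matched_r,
        effect_hit=effect_hit, effect_t=effect_t, effect_p_fdr=effect_p_fdr,
        other_state_flags=other_flags, n_other_states_tested=other_tested,
        dwell_sign_ok=bool(dwell_sign_ok), shift_sign_ok=bool(shift > 0),
        transition_sign_ok=bool(trans_a < trans_b), severity_r=float(sev_r),
    )


def run_recovery_study(n_cohorts: int = 20, seed: int = 0, **kwargs) -> RecoveryStudy:
    """Replicate :func:`analyze_cohort_recovery` over ``n_cohorts`` seeds."""
    base = np.random.SeedSequence(seed).generate_state(n_cohorts) % (2**31 - 1)
    return RecoveryStudy(
        [analyze_cohort_recovery(int(s), **kwargs) for s in base])


def null_fdr_study(
    n_cohorts: int = 20,
    n_per_group: int = 40,
    C: int = 39,
    T: int = 255,
    n_perm: int = 10000,
    q: float = 0.05,
    seed: int = 0,
) -> tuple[float, list[int]]:
    """False discoveries of the pairwise perm-test + BH pipeline under the null.

    Each replicate draws two equal groups of subjects from the same state
    template (no group effect), computes their static Fisher-z FC vectors
    (C(C-1)/2 pairs), runs the pairwise permutation test with BH at ``q``,
    and counts FDR discoveries.  Returns (mean count, per-cohort counts).
    """
    rng = np.random.default_rng(seed)
    template = coh.make_state_templates(C, k_true=4, seed=seed)[0]
    counts = []
    for _ in range(n_cohorts):
        vecs = []
        for _s in range(2 * n_per_group):
            data = coh.simulate_subject(np.ones(T, dtype=int), [template],
                                        noise_sd=0.1, seed=rng)
            vecs.append(conn.fisher_z(conn.vectorize_upper(conn.static_fc(data))))
        X = np.vstack(vecs)
        _t, p = gstats.perm_ttest(X[:n_per_group], X[n_per_group:],
                                  n_perm=n_perm, seed=int(rng.integers(2**31)))
        _p_adj, reject = gstats.fdr_bh(p, q=q)
        counts.append(int(reject.sum()))
    return float(np.mean(counts)), counts


def ttest_type1_study(
    n_reps: int = 1000,
    n_per_group: int = 20,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error rate of the permutation t-test on normal null data."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_per_group, n_reps))
    y = rng.standard_normal((n_per_group, n_reps))
    _t, p = gstats.perm_ttest(x, y, n_perm=n_perm, seed=seed + 1)
    return float(np.mean(p <= alpha))


def anova_type1_study(
    n_reps: int = 500,
    n_per_cell: int = 20,
    k_states: int = 4,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error rate of the two-way ANOVA group effect on null data."""
    rng = np.random.default_rng(seed)
    group = np.repeat(["A", "B"], k_states * n_per_cell)
    state = np.tile(np.repeat(np.arange(1, k_states + 1), n_per_cell), 2)
    rejections = 0
    for _ in range(n_reps):
        values = rng.standard_normal(group.size)
        res = gstats.twoway_anova(values, group, state)
        p_group = next(a.p for a in res if a.factor == "group")
        rejections += p_group <= alpha
    return rejections / n_reps


def classifier_sanity(
    n_subjects: int = 60,
    n_features: int = 3,
    shift: float = 2.0,
    n_permuted_runs: int = 20,
    seed: int = 0,
) -> dict:
    """LOOCV sanity checks: separable accuracy and permuted-label chance.

    Separable features are two Gaussian clouds shifted by ``shift`` SD per
    feature; permuted-label runs re-fit the whole LOOCV on shuffled labels
    and should stay at chance (any excess signals information leakage).
    """
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n_subjects // 2)
    X = rng.standard_normal((n_subjects, n_features)) + shift * y[:, None]
    feats = clf.FeatureMatrix(
        values=X, labels=y,
        subject_ids=[f"s{i}" for i in range(n_subjects)],
        feature_pairs=[(0, i + 1) for i in range(n_features)],
    )
    result = clf.loocv_l1_logreg(feats, seed=seed)
    separable_accuracy = result.accuracy

    permuted_acc = []
    for run in range(n_permuted_runs):
        yp = rng.permutation(y)
        fp = clf.FeatureMatrix(
            values=X, labels=yp, subject_ids=feats.subject_ids,
            feature_pairs=feats.feature_pairs,
        )
        permuted_acc.append(clf.loocv_l1_logreg(fp, seed=seed + run).accuracy)

    recomputed = result.fold_nonzero.mean(axis=0)
    bookkeeping_max_err = float(
        np.max(np.abs(recomputed - result.selection_frequency)))
    return {
        "separable_accuracy": float(separable_accuracy),
        "permuted_mean_accuracy": float(np.mean(permuted_acc)),
        "permuted_accuracies": [float(a) for a in permuted_acc],
        "bookkeeping_max_err": bookkeeping_max_err,
    }
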