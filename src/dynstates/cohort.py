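"""Synthetic resting-state cohort generator with known brain-state structure.

Real ICA time courses from patient cohorts are rarely deposited, so every
downstream stage of the pipeline (windowed connectivity, state clustering,
dynamics metrics, group statistics, classification) is validated against
cohorts simulated here, where the state sequence, the state covariance
templates, and the injected group effects are all known exactly.

The generative model is deliberately simple: a first-order Markov chain over
``k_true`` states at TR resolution drives, at each time point, a draw from a
zero-mean multivariate normal whose covariance is the active state's
template (plus optional isotropic observation noise).  Group differences are
injected as (a) connectivity offsets on named component pairs within named
states and (b) a separate transition matrix for the patient-like group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StateTemplate",
    "CohortConfig",
    "SyntheticSubject",
    "Cohort",
    "make_state_templates",
    "simulate_state_sequence",
    "simulate_subject",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
    "DEFAULT_NETWORKS",
]

# Seven canonical resting-state networks used throughout: sensorimotor,
# visual, subcortical, cerebellar, default-mode, dorsal attention,
# fronto-parietal.
DEFAULT_NETWORKS = ("SM", "VIS", "SB", "CB", "DMN", "dATT", "FPN")

#: The four state characters, in state-id order.  State 1 is the dominant,
#: weakly connected state resembling static FC; states 2 and 4 are strongly
#: segregated (high modularity); state 3 is densely connected with little
#: modular structure.
PROFILE_TAGS = (
    "low-conn/mid-modular",
    "high-conn/high-modular",
    "high-conn/low-modular",
    "low-conn/high-modular",
)

# (within-network r, between-network r) per profile tag.  Chosen so that
# overall connectivity is higher for the "high-conn" tags and the
# within/between contrast (hence modularity) orders 2 ~ 4 > 1 > 3.  The
# strongly segregated state 4 carries mild between-network anticorrelation.
_PROFILE_LEVELS = {
    "low-conn/mid-modular": (0.30, 0.10),
    "high-conn/high-modular": (0.75, 0.12),
    "high-conn/low-modular": (0.42, 0.30),
    "low-conn/high-modular": (0.45, -0.04),
}

#: Amplitude of the state-specific random off-diagonal pattern that makes
#: the templates mutually distinguishable beyond their block profile.
_STATE_PATTERN_SD = 0.15

#: SD of the per-state, per-network variation in block levels: states
#: differ in *which* networks engage, not just in the mean level.
_NETWORK_LEVEL_SD = 0.12


@dataclass(frozen=True)
class StateTemplate:
    """One recurrent connectivity state: a C x C correlation-scale covariance."""

    state_id: int
    covariance: np.ndarray
    profile_tag: str

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if not np.allclose(np.diag(cov), 1.0, atol=1e-8):
            raise ValueError("covariance must have unit diagonal")
        # positive definiteness is the hard contract
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"state {self.state_id}: covariance not positive definite"
            ) from exc


@dataclass
class CohortConfig:
    """Study-scale configuration for a two-group synthetic cohort.

    Defaults mirror the study conditions: ~57 patient-like and ~61
    control-like subjects, 39 components over 7 networks, 255 time points at
    TR = 2.25 s, and 4 recurrent states.
    """

    n_group_a: int = 61
    n_group_b: int = 57
    C: int = 39
    T: int = 255
    TR: float = 2.25
    k_true: int = 4
    transition_a: np.ndarray | None = None
    transition_b: np.ndarray | None = None
    effect_pairs: list[tuple[int, tuple[int, int], float]] = field(default_factory=list)
    noise_sd: float = 0.1
    seed: int = 0
    network_map: pd.DataFrame | None = None
    initial_dist: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.transition_a is None:
            self.transition_a = default_transition_matrix("A", self.k_true)
        if self.transition_b is None:
            self.transition_b = default_transition_matrix("B", self.k_true)
        for name in ("transition_a", "transition_b"):
            mat = np.asarray(getattr(self, name), dtype=float)
            _check_row_stochastic(mat)
            if mat.shape != (self.k_true, self.k_true):
                raise ValueError(f"{name} must be {self.k_true}x{self.k_true}")
            setattr(self, name, mat)
        if self.network_map is None:
            self.network_map = default_network_map(self.C)
        if self.initial_dist is None:
            # state 1 is the dominant state: scans preferentially start there
            w = np.full(self.k_true, 0.6 / max(self.k_true - 1, 1))
            w[0] = 0.4
            self.initial_dist = w / w.sum()
        self.initial_dist = np.asarray(self.initial_dist, dtype=float)


@dataclass
class SyntheticSubject:
    subject_id: str
    timecourses: np.ndarray  # T x C
    true_state_seq: np.ndarray  # length T, labels 1..k
    group: str  # "A" (control-like) or "B" (patient-like)
    age: float
    sex: str  # "F" / "M"
    motion: np.ndarray  # T x 12 realignment-parameter stand-ins
    fd_trace: np.ndarray  # length T, framewise displacement (mm)
    severity: float  # ordinal 0..4 severity score (group B); 0 for group A

    @property
    def mean_fd(self) -> float:
        return float(np.mean(self.fd_trace))


@dataclass
class Cohort:
    subjects: list[SyntheticSubject]
    templates: list[StateTemplate]
    config: CohortConfig
    ground_truth: dict

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
                "mean_fd": [s.mean_fd for s in self.subjects],
                "severity": [s.severity for s in self.subjects],
            }
        )


def default_network_map(C: int, networks: tuple[str, ...] = DEFAULT_NETWORKS) -> pd.DataFrame:
    """Assign C components to networks in near-equal contiguous blocks."""
    sizes = np.full(len(networks), C // len(networks))
    sizes[: C % len(networks)] += 1
    assignment: list[str] = []
    for net, size in zip(networks, sizes):
        assignment.extend([net] * int(size))
    return pd.DataFrame({"component_id": np.arange(C), "network": assignment[:C]})


def default_transition_matrix(group: str, k: int = 4) -> np.ndarray:
    """Per-group state transition matrices encoding the group effects.

    State runs must be long relative to the 30-TR analysis window for the
    windowed correlations to reflect a single state, as they do in resting
    scans; group A (control-like) therefore dwells ~80 TR per state.
    Group B (patient-like) leaves the dominant state 1 sooner, stays longer
    in the segregated state 2, and is overall more volatile, with its extra
    transitions biased toward the 1<->2 and 3<->4 pairs.
    """
    if k == 4:
        if group == "A":
            # dominant state 1 dwells ~130 TR, the rest ~100 TR
            P = np.array(
                [
                    [0.99231, 0.00256, 0.00256, 0.00257],
                    [0.00333, 0.99000, 0.00333, 0.00334],
                    [0.00333, 0.00333, 0.99000, 0.00334],
                    [0.00333, 0.00333, 0.00334, 0.99000],
                ]
            )
        else:
            P = np.array(
                [
                    [0.98462, 0.01038, 0.00250, 0.00250],
                    [0.00400, 0.99400, 0.00100, 0.00100],
                    [0.00400, 0.00300, 0.98000, 0.01300],
                    [0.00400, 0.00300, 0.01300, 0.98000],
                ]
            )
        return P
    # generic fallback for other k: uniform off-diagonal
    self_p = 0.99 if group == "A" else 0.98
    P = np.full((k, k), (1 - self_p) / (k - 1))
    np.fill_diagonal(P, self_p)
    return P


def _check_row_stochastic(mat: np.ndarray, atol: float = 1e-8) -> None:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(mat < -atol):
        raise ValueError("transition probabilities must be non-negative")
    sums = mat.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=atol):
        raise ValueError(f"transition rows must sum to 1 (got {sums})")


def _nearest_correlation_pd(mat: np.ndarray, min_eig: float = 0.1) -> np.ndarray:
    """Nearest unit-diagonal positive-definite correlation matrix.

    Eigenvalues are clipped at ``min_eig`` and the diagonal rescaled.  The
    floor is deliberately generous (0.1): templates must stay positive
    definite under subsequent pair-level connectivity offsets of up to
    ~0.3, which a near-singular matrix would not survive.  Falls back to a
    small shrinkage toward the identity if the clipped matrix is still
    numerically singular; raises if even that fails.
    """
    from statsmodels.stats.correlation_tools import corr_clipped

    out = (mat + mat.T) / 2.0
    np.fill_diagonal(out, 1.0)
    # alternate eigenvalue clipping and diagonal rescaling until the floor
    # holds; each corr_clipped call is one clip + rescale
    for _ in range(100):
        out = np.asarray(corr_clipped(out, threshold=min_eig))
        out = (out + out.T) / 2.0
        np.fill_diagonal(out, 1.0)
        if np.linalg.eigvalsh(out)[0] >= 0.95 * min_eig:
            break
    for shrink in (0.0, 1e-3, 1e-2):
        cand = (1.0 - shrink) * out + shrink * np.eye(len(out))
        try:
            np.linalg.cholesky(cand)
            return cand
        except np.linalg.LinAlgError:
            continue
    raise RuntimeError("could not repair covariance to positive definite")


def _profile_orderings_ok(templates: list[StateTemplate]) -> bool:
    """Check the character orderings of the four canonical profiles.

    Overall connectivity: the densely connected state 3 is the strongest
    and state 2 exceeds the weak states 1 and 4.  Modularity: the
    segregated states 2 and 4 exceed state 1, which exceeds state 3.
    (Absolute-value semantics of overall connectivity keep states 2 and 4
    from being strictly ordered against each other.)
    """
    from .connectivity import modularity, overall_connectivity

    oc = [overall_connectivity(t.covariance) for t in templates]
    q = [modularity(t.covariance, n_runs=5)[0] for t in templates]
    return (
        oc[2] == max(oc)
        and oc[1] > oc[0]
        and min(q[1], q[3]) > q[0] > q[2]
    )


def make_state_templates(
    C: int,
    network_map: pd.DataFrame | None = None,
    k_true: int = 4,
    seed: int = 0,
    profile_tags: tuple[str, ...] | None = None,
    pattern_sd: float = _STATE_PATTERN_SD,
    network_level_sd: float = _NETWORK_LEVEL_SD,
    max_attempts: int = 20,
) -> list[StateTemplate]:
    """Build ``k_true`` positive-definite correlation templates.

    Each template is a network-block matrix whose within- and
    between-network levels are set by its profile tag, with per-state,
    per-network variation (states differ in which networks engage) and a
    state-specific random symmetric perturbation, repaired to the nearest
    unit-diagonal positive-definite matrix.  For the four canonical
    profiles the construction is retried with derived seeds until the
    overall-connectivity and modularity orderings match the tags.

    Parameters
    ----------
    C : number of components (>= 4).
    network_map : DataFrame with ``component_id`` and ``network`` columns;
        defaults to a near-equal split over the seven canonical networks.
    k_true : number of states; tags cycle through the four canonical
        profiles if ``k_true != 4``.
    seed : RNG seed for the state-specific patterns.
    pattern_sd : SD of the component-pair-level perturbation.
    network_level_sd : SD of the per-network block-level variation.
    """
    if C < 4:
        raise ValueError("need at least 4 components")
    if network_map is None:
        network_map = default_network_map(C)
    nets = np.asarray(network_map["network"])
    if len(nets) != C:
        raise ValueError("network_map must assign every component")
    uniq = sorted(set(nets))
    if len(uniq) < 2:
        raise ValueError("network_map must define at least 2 networks")
    if profile_tags is None:
        profile_tags = tuple(PROFILE_TAGS[i % 4] for i in range(k_true))
    block = np.array([uniq.index(n) for n in nets])
    same_net = block[:, None] == block[None, :]
    check_order = tuple(profile_tags) == PROFILE_TAGS and k_true == 4

    last_error: Exception | None = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        templates = []
        try:
            for s in range(k_true):
                tag = profile_tags[s]
                within, between = _PROFILE_LEVELS[tag]
                w_net = np.clip(
                    rng.normal(within, network_level_sd, len(uniq)), 0.05, 0.85)
                b_blk = rng.normal(between, network_level_sd,
                                   (len(uniq), len(uniq)))
                b_blk = (b_blk + b_blk.T) / 2.0
                base = b_blk[block[:, None], block[None, :]].copy()
                base[same_net] = w_net[block[:, None].repeat(C, 1)][same_net]
                if pattern_sd > 0:
                    noise = rng.normal(0.0, pattern_sd, size=(C, C))
                    base = base + (noise + noise.T) / 2.0
                np.fill_diagonal(base, 1.0)
                cov = _nearest_correlation_pd(base)
                templates.append(
                    StateTemplate(state_id=s + 1, covariance=cov, profile_tag=tag))
        except RuntimeError as exc:
            last_error = exc
            continue
        if not check_order or _profile_orderings_ok(templates):
            return templates
    if last_error is not None:
        raise RuntimeError("template construction failed") from last_error
    raise RuntimeError(
        f"could not realize profile orderings in {max_attempts} attempts")


def simulate_state_sequence(
    T: int,
    transition_matrix: np.ndarray,
    initial_dist: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample a length-T first-order Markov chain; labels are 1..k."""
    if T < 1:
        raise ValueError("T must be >= 1")
    P = np.asarray(transition_matrix, dtype=float)
    _check_row_stochastic(P)
    k = P.shape[0]
    if initial_dist is None:
        initial_dist = np.full(k, 1.0 / k)
    initial_dist = np.asarray(initial_dist, dtype=float)
    if not np.isclose(initial_dist.sum(), 1.0, atol=1e-8):
        raise ValueError("initial distribution must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # inverse-CDF sampling against precomputed row CDFs
    cdf = np.cumsum(P, axis=1)
    u = rng.random(T)
    seq = np.empty(T, dtype=int)
    seq[0] = np.searchsorted(np.cumsum(initial_dist), u[0], side="right")
    for t in range(1, T):
        seq[t] = np.searchsorted(cdf[seq[t - 1]], u[t], side="right")
    return seq + 1


def simulate_subject(
    state_seq: np.ndarray,
    templates: list[StateTemplate],
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw a T x C series; each time point is MVN(0, cov[state]) + noise.

    The same standard-normal innovations are rotated through each state's
    Cholesky factor, so the series is continuous in distribution and exactly
    reproducible from the seed.
    """
    state_seq = np.asarray(state_seq, dtype=int)
    by_id = {t.state_id: t for t in templates}
    missing = set(np.unique(state_seq)) - set(by_id)
    if missing:
        raise ValueError(f"state_seq contains labels without templates: {sorted(missing)}")
    C = next(iter(by_id.values())).covariance.shape[0]
    T = len(state_seq)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((T, C))
    out = np.empty((T, C))
    for sid, tpl in by_id.items():
        mask = state_seq == sid
        if not mask.any():
            continue
        try:
            L = np.linalg.cholesky(tpl.covariance)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"state {sid}: covariance factorization failed") from exc
        out[mask] = z[mask] @ L.T
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=(T, C))
    return out


def true_window_labels(
    state_seq: np.ndarray,
    width_tr: int = 30,
    step_tr: int = 1,
    n_windows: int | None = None,
    min_majority: float = 2.0 / 3.0,
) -> np.ndarray:
    """Ground-truth state label per sliding window; 0 where ambiguous.

    A window is labelled with a state only when that state occupies at
    least ``min_majority`` of its frames; windows straddling a transition
    without such a majority have no single true state and get label 0.
    Recovery scores should be computed over the labelled windows only.
    """
    seq = np.asarray(state_seq, dtype=int)
    T = len(seq)
    n = T - width_tr if n_windows is None else n_windows
    starts = np.arange(0, n * step_tr, step_tr)
    out = np.zeros(len(starts), dtype=int)
    for w, s in enumerate(starts):
        counts = np.bincount(seq[s:s + width_tr])
        if counts.max() >= min_majority * width_tr:
            out[w] = int(counts.argmax())
    return out


def _pin_effect_pair_baselines(
    templates: list[StateTemplate],
    effect_pairs: list[tuple[int, tuple[int, int], float]],
    network_map: pd.DataFrame,
) -> list[StateTemplate]:
    """Fix each effect pair's value to its profile base level in all states.

    The random per-state structure would otherwise convolve with the
    injected group offset, making the realized contrast (and the
    contamination from neighbouring states in windowed estimates) vary
    from seed to seed.  Pinning keeps the ground-truth contrast exactly
    interpretable.
    """
    if not effect_pairs:
        return templates
    nets = np.asarray(network_map["network"])
    out = []
    for t in templates:
        cov = t.covariance.copy()
        within, between = _PROFILE_LEVELS[t.profile_tag]
        for _state, (i, j), _delta in effect_pairs:
            cov[i, j] = cov[j, i] = within if nets[i] == nets[j] else between
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"state {t.state_id}: pinning effect-pair baseline broke "
                "positive definiteness"
            ) from exc
        out.append(StateTemplate(t.state_id, cov, t.profile_tag))
    return out


def _apply_effect_pairs(
    templates: list[StateTemplate],
    effect_pairs: list[tuple[int, tuple[int, int], float]],
) -> list[StateTemplate]:
    """Return templates with pairwise connectivity offsets applied (group B)."""
    if not effect_pairs:
        return templates
    covs = {t.state_id: t.covariance.copy() for t in templates}
    for state_id, (i, j), delta in effect_pairs:
        if state_id not in covs:
            raise ValueError(f"effect names unknown state {state_id}")
        cov = covs[state_id]
        cov[i, j] += delta
        cov[j, i] += delta
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"effect delta {delta:+.3f} on pair ({i},{j}) in state "
                f"{state_id} breaks positive definiteness"
            ) from exc
    return [
        StateTemplate(t.state_id, covs[t.state_id], t.profile_tag) for t in templates
    ]


def _simulate_metadata(rng: np.random.Generator, group: str) -> tuple[float, str, float]:
    """Age ~ N(26, 8), sex Bernoulli(0.88 female), severity 0..4 (group B)."""
    age = float(np.clip(rng.normal(26.0, 8.0), 18.0, 65.0))
    sex = "F" if rng.random() < 0.88 else "M"
    severity = float(rng.binomial(4, 0.5)) if group == "B" else 0.0
    return age, sex, severity


def _simulate_motion(rng: np.random.Generator, T: int, spike_prob: float = 0.02):
    """Realignment-parameter stand-ins and a lognormal FD trace with spikes."""
    drift = np.cumsum(rng.normal(0.0, 0.01, size=(T, 6)), axis=0)
    params = drift + rng.normal(0.0, 0.02, size=(T, 6))
    derivs = np.vstack([np.zeros(6), np.diff(params, axis=0)])
    motion = np.hstack([params, derivs])
    fd = rng.lognormal(mean=np.log(0.12), sigma=0.5, size=T)
    spikes = rng.random(T) < spike_prob
    fd[spikes] += rng.uniform(0.5, 1.5, size=int(spikes.sum()))
    return motion, fd


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full two-group cohort plus its ground-truth record.

    Group B subjects receive the configured connectivity offsets
    (``effect_pairs``) and their own transition matrix.  To give severity a
    real association with transition volatility, each group-B subject's
    transition matrix interpolates between the group-A and an exaggerated
    group-B matrix with a weight that increases with the subject's severity
    score; the interpolation weights average ~1 so the group mean matches
    ``transition_b``.
    """
    rng = np.random.default_rng(config.seed)
    # retry template construction if an injected delta breaks positive
    # definiteness for a particular random template realization; an
    # infeasible delta still errors after the attempts are exhausted
    last_exc: Exception | None = None
    for _ in range(20):
        templates_a = make_state_templates(
            config.C, config.network_map, config.k_true,
            seed=int(rng.integers(2**31)),
        )
        try:
            templates_a = _pin_effect_pair_baselines(
                templates_a, config.effect_pairs, config.network_map)
            templates_b = _apply_effect_pairs(templates_a, config.effect_pairs)
            break
        except ValueError as exc:
            last_exc = exc
    else:
        raise ValueError(str(last_exc)) from last_exc

    # exaggerated B matrix for severity linkage: P_ex = A + 2 (B - A),
    # clipped/renormalized to stay a proper stochastic matrix
    P_a, P_b = config.transition_a, config.transition_b
    P_ex = np.clip(P_a + 2.0 * (P_b - P_a), 1e-4, None)
    P_ex = P_ex / P_ex.sum(axis=1, keepdims=True)

    subjects = []
    seqs: dict[str, list[int]] = {}
    n_total = config.n_group_a + config.n_group_b
    for idx in range(n_total):
        group = "A" if idx < config.n_group_a else "B"
        sid = f"sub-{idx + 1:03d}"
        age, sex, severity = _simulate_metadata(rng, group)
        if group == "A":
            P_subj = P_a
            templates = templates_a
        else:
            w = severity / 4.0  # 0 -> group-A-like, 1 -> exaggerated
            P_subj = (1.0 - w) * P_a + w * P_ex
            templates = templates_b
        seq = simulate_state_sequence(config.T, P_subj,
                                      initial_dist=config.initial_dist, seed=rng)
        data = simulate_subject(seq, templates, noise_sd=config.noise_sd, seed=rng)
        motion, fd = _simulate_motion(rng, config.T)
        subjects.append(
            SyntheticSubject(
                subject_id=sid, timecourses=data, true_state_seq=seq,
                group=group, age=age, sex=sex, motion=motion,
                fd_trace=fd, severity=severity,
            )
        )
        seqs[sid] = seq.tolist()

    ground_truth = {
        "note": (
            "Fully synthetic stand-in cohort; all distributional choices are "
            "simulator conventions, not estimates from any real dataset."
        ),
        "k_true": config.k_true,
        "profile_tags": [t.profile_tag for t in templates_a],
        "templates_group_a": [t.covariance.tolist() for t in templates_a],
        "effect_pairs": [
            {"state": s, "pair": list(p), "delta": d} for s, p, d in config.effect_pairs
        ],
        "transition_a": P_a.tolist(),
        "transition_b": P_b.tolist(),
        "true_state_sequences": seqs,
        "seed": config.seed,
    }
    return Cohort(subjects=subjects, templates=templates_a, config=config,
                  ground_truth=ground_truth)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write per-subject time courses, subjects.csv, networks.csv, ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tc_dir = out / "timecourses"
    tc_dir.mkdir(exist_ok=True)
    for subj in cohort.subjects:
        np.savetxt(tc_dir / f"{subj.subject_id}.tsv", subj.timecourses,
                   delimiter="\t", fmt="%.6f")
        np.savetxt(tc_dir / f"{subj.subject_id}_motion.tsv", subj.motion,
                   delimiter="\t", fmt="%.6f")
        np.savetxt(tc_dir / f"{subj.subject_id}_fd.tsv", subj.fd_trace,
                   delimiter="\t", fmt="%.6f")
    cohort.metadata.to_csv(out / "subjects.csv", index=False)
    cohort.config.network_map.rename(
        columns={"network": "network_label"}).to_csv(out / "networks.csv", index=False)
    gt = dict(cohort.ground_truth)
    gt["timecourse_dir"] = "timecourses"
    gt["TR"] = cohort.config.TR
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt, fh)


def load_cohort(in_dir: str | Path) -> Cohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    root = Path(in_dir)
    meta = pd.read_csv(root / "subjects.csv")
    networks = pd.read_csv(root / "networks.csv")
    with open(root / "ground_truth.json") as fh:
        gt = json.load(fh)
    tc_dir = root / gt.get("timecourse_dir", "timecourses")
    subjects = []
    for row in meta.itertuples(index=False):
        sid = row.subject_id
        data = np.loadtxt(tc_dir / f"{sid}.tsv", delimiter="\t")
        motion = np.loadtxt(tc_dir / f"{sid}_motion.tsv", delimiter="\t")
        fd = np.loadtxt(tc_dir / f"{sid}_fd.tsv", delimiter="\t")
        seq = np.asarray(gt["true_state_sequences"][sid], dtype=int)
        subjects.append(
            SyntheticSubject(
                subject_id=sid, timecourses=data, true_state_seq=seq,
                group=row.group, age=row.age, sex=row.sex, motion=motion,
                fd_trace=fd, severity=row.severity,
            )
        )
    templates = [
        StateTemplate(i + 1, np.asarray(c), gt["profile_tags"][i])
        for i, c in enumerate(gt["templates_group_a"])
    ]
    config = CohortConfig(
        n_group_a=int((meta["group"] == "A").sum()),
        n_group_b=int((meta["group"] == "B").sum()),
        C=subjects[0].timecourses.shape[1],
        T=subjects[0].timecourses.shape[0],
        TR=float(gt.get("TR", 2.25)),
        k_true=int(gt["k_true"]),
        transition_a=np.asarray(gt["transition_a"]),
        transition_b=np.asarray(gt["transition_b"]),
        effect_pairs=[
            (e["state"], tuple(e["pair"]), e["delta"]) for e in gt["effect_pairs"]
        ],
        seed=int(gt["seed"]),
        network_map=networks.rename(columns={"network_label": "network"}),
    )
    return Cohort(subjects=subjects, templates=templates, config=config, ground_truth=gt)
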