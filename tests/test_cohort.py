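"""Synthetic cohort generator: templates, Markov chains, subject simulation."""

import numpy as np
import pytest

from dynstates import cohort as coh
from dynstates.connectivity import modularity, overall_connectivity
from dynstates.dynamics import run_lengths


class TestStateTemplates:
    def test_profile_orderings_hold(self):
        """Overall connectivity and modularity follow the four state characters."""
        for C in (20, 39):
            tpls = coh.make_state_templates(C, k_true=4, seed=3)
            oc = [overall_connectivity(t.covariance) for t in tpls]
            q = [modularity(t.covariance, n_runs=5)[0] for t in tpls]
            assert oc[2] == max(oc)  # densely connected state 3
            assert oc[1] > oc[0]  # state 2 stronger than the weak state 1
            assert min(q[1], q[3]) > q[0] > q[2]  # segregation 2,4 > 1 > 3

    def test_all_templates_positive_definite_unit_diagonal(self):
        tpls = coh.make_state_templates(20, k_true=4, seed=11)
        for t in tpls:
            np.linalg.cholesky(t.covariance)  # raises if not PD
            assert np.allclose(np.diag(t.covariance), 1.0)
            assert np.allclose(t.covariance, t.covariance.T)

    def test_within_network_exceeds_between_for_modular_template(self):
        """At C=6 with 2 networks a high-modularity template has block contrast."""
        import pandas as pd
        nm = pd.DataFrame({"component_id": range(6),
                           "network": ["a"] * 3 + ["b"] * 3})
        tpls = coh.make_state_templates(
            6, network_map=nm, k_true=1, seed=0,
            profile_tags=("high-conn/high-modular",))
        cov = tpls[0].covariance
        within = [cov[i, j] for i in range(6) for j in range(6)
                  if i < j and (i < 3) == (j < 3)]
        between = [cov[i, j] for i in range(3) for j in range(3, 6)]
        assert np.mean(within) > np.mean(between)

    def test_identity_like_matrix_modularity_degenerate(self):
        """An all-nonpositive off-diagonal matrix yields Q=0 without crashing."""
        mat = np.eye(6)
        with pytest.warns(UserWarning):
            q, labels = modularity(mat - np.full((6, 6), 0.01) + 0.01 * np.eye(6))
        assert q == 0.0
        assert len(set(labels)) == 1

    def test_too_few_components_rejected(self):
        with pytest.raises(ValueError):
            coh.make_state_templates(3, k_true=4, seed=0)


class TestStateSequence:
    def test_absorbing_chain_stays_put(self):
        seq = coh.simulate_state_sequence(10, np.eye(2), [0.0, 1.0], seed=0)
        assert (seq == 2).all()

    def test_mean_run_length_matches_geometric_dwell(self):
        """Self-transition p gives mean dwell 1/(1-p), checked by run counting."""
        P = np.array([[0.9, 0.1], [0.1, 0.9]])
        seq = coh.simulate_state_sequence(10000, P, seed=1)
        runs = [length for _state, length in run_lengths(seq)]
        assert np.mean(runs) == pytest.approx(10.0, rel=0.05)

    def test_uniform_chain_occupancy(self):
        P = np.full((4, 4), 0.25)
        seq = coh.simulate_state_sequence(40000, P, seed=2)
        occ = np.bincount(seq, minlength=5)[1:] / len(seq)
        assert np.allclose(occ, 0.25, atol=0.01)

    def test_bad_rows_rejected(self):
        with pytest.raises(ValueError):
            coh.simulate_state_sequence(10, np.array([[0.5, 0.4], [0.1, 0.9]]))

    def test_deterministic_given_seed(self):
        P = np.array([[0.8, 0.2], [0.3, 0.7]])
        a = coh.simulate_state_sequence(500, P, seed=9)
        b = coh.simulate_state_sequence(500, P, seed=9)
        assert (a == b).all()


class TestSimulateSubject:
    def test_single_state_empirical_correlation_matches_template(self):
        tpls = coh.make_state_templates(8, k_true=1, seed=4,
                                        profile_tags=("low-conn/mid-modular",))
        seq = np.ones(20000, dtype=int)
        data = coh.simulate_subject(seq, tpls, noise_sd=0.0, seed=0)
        emp = np.corrcoef(data.T)
        assert np.max(np.abs(emp - tpls[0].covariance)) < 0.05

    def test_identity_templates_give_independent_components(self):
        tpl = coh.StateTemplate(1, np.eye(6), "low-conn/mid-modular")
        data = coh.simulate_subject(np.ones(5000, dtype=int), [tpl], seed=1)
        emp = np.corrcoef(data.T)
        off = emp[np.triu_indices(6, 1)]
        assert np.mean(np.abs(off)) < 0.05

    def test_seed_contract(self):
        tpl = coh.StateTemplate(1, np.eye(4), "low-conn/mid-modular")
        seq = np.ones(50, dtype=int)
        a = coh.simulate_subject(seq, [tpl], seed=3)
        b = coh.simulate_subject(seq, [tpl], seed=3)
        c = coh.simulate_subject(seq, [tpl], seed=4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_missing_template_rejected(self):
        tpl = coh.StateTemplate(1, np.eye(4), "low-conn/mid-modular")
        with pytest.raises(ValueError, match="labels without templates"):
            coh.simulate_subject(np.array([1, 2, 1]), [tpl])


class TestGenerateCohort:
    def test_cohort_is_reproducible(self):
        cfg = dict(n_group_a=3, n_group_b=3, C=14, T=80, seed=7)
        a = coh.generate_cohort(coh.CohortConfig(**cfg))
        b = coh.generate_cohort(coh.CohortConfig(**cfg))
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.timecourses, sb.timecourses)
            assert np.array_equal(sa.true_state_seq, sb.true_state_seq)
            assert sa.severity == sb.severity

    def test_metadata_and_shapes(self, small_cohort):
        meta = small_cohort.metadata
        assert len(meta) == 12
        assert set(meta["group"]) == {"A", "B"}
        for s in small_cohort:
            assert s.timecourses.shape == (160, 14)
            assert s.motion.shape == (160, 12)
            assert (s.fd_trace >= 0).all()
            assert s.true_state_seq.min() >= 1
            assert s.true_state_seq.max() <= 4

    def test_severity_zero_for_controls(self, small_cohort):
        for s in small_cohort:
            if s.group == "A":
                assert s.severity == 0.0

    def test_infeasible_delta_errors_naming_pair(self):
        cfg = coh.CohortConfig(n_group_a=2, n_group_b=2, C=14, T=40,
                               effect_pairs=[(1, (0, 1), -1.5)], seed=0)
        with pytest.raises(ValueError, match=r"\(0,1\)|\(0, 1\)"):
            coh.generate_cohort(cfg)

    def test_volatile_group_transitions_more_on_average(self):
        """Lower self-transition probabilities yield more observed switches."""
        cfg = coh.CohortConfig(n_group_a=25, n_group_b=25, C=14, T=255, seed=21)
        c = coh.generate_cohort(cfg)
        counts = {"A": [], "B": []}
        for s in c:
            n_runs = len(run_lengths(s.true_state_seq))
            counts[s.group].append(n_runs - 1)
        assert np.mean(counts["B"]) > np.mean(counts["A"])

    def test_severity_links_to_transition_volatility(self):
        """Higher severity means a more volatile chain, by construction."""
        cfg = coh.CohortConfig(n_group_a=2, n_group_b=200, C=14, T=255, seed=31)
        c = coh.generate_cohort(cfg)
        sev, trans = [], []
        for s in c:
            if s.group != "B":
                continue
            sev.append(s.severity)
            trans.append(len(run_lengths(s.true_state_seq)) - 1)
        r = np.corrcoef(sev, trans)[0, 1]
        assert r > 0.1

    def test_roundtrip_io(self, small_cohort, tmp_path):
        coh.write_cohort(small_cohort, tmp_path)
        loaded = coh.load_cohort(tmp_path)
        assert len(loaded) == len(small_cohort)
        for a, b in zip(small_cohort, loaded):
            assert a.subject_id == b.subject_id
            assert a.group == b.group
            assert np.allclose(a.timecourses, b.timecourses, atol=1e-5)
            assert np.array_equal(a.true_state_seq, b.true_state_seq)


class TestTrueWindowLabels:
    def test_constant_sequence_fully_labelled(self):
        seq = np.ones(60, dtype=int)
        lab = coh.true_window_labels(seq, width_tr=30)
        assert lab.shape == (30,)
        assert (lab == 1).all()

    def test_transition_windows_marked_ambiguous(self):
        seq = np.concatenate([np.ones(60, dtype=int), np.full(60, 2)])
        lab = coh.true_window_labels(seq, width_tr=30)
        # windows with 10..20 frames of each state have no 2/3 majority
        assert (lab == 0).sum() > 0
        assert set(lab) <= {0, 1, 2}
        assert lab[0] == 1 and lab[-1] == 2
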