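"""Moderated one-vs-group testing, BH, panel curation, call filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epivar.outlier import (
    DMCpGCaller,
    bh_adjust,
    call_dmcpgs,
    classify_status,
    fit_ebayes_prior,
    moderated_one_vs_group,
    panel_frequency,
)


class TestClassifyStatus:
    @pytest.mark.parametrize(
        "beta,status",
        [
            (0.891, "hyper"),
            (0.597, "intermediate"),
            (0.30, "intermediate"),  # boundaries belong to intermediate
            (0.70, "intermediate"),
            (0.0, "hypo"),
            (1.0, "hyper"),
            (0.2999, "hypo"),
            (0.7001, "hyper"),
        ],
    )
    def test_bins(self, beta, status):
        assert classify_status(beta) == status

    def test_vectorised(self):
        out = classify_status(np.array([0.1, 0.5, 0.9]))
        assert list(out) == ["hypo", "intermediate", "hyper"]


class TestEbayesPrior:
    def test_identical_variances_give_infinite_prior_df(self):
        d0, s02 = fit_ebayes_prior(np.full(20, 0.03), df=9)
        assert np.isinf(d0)
        assert s02 == pytest.approx(0.03, rel=1e-6)

    def test_two_equal_probes(self):
        d0, s02 = fit_ebayes_prior(np.array([1.0, 1.0]), df=9)
        assert s02 == pytest.approx(1.0)

    def test_recovery_from_scaled_f_prior(self):
        # simulation oracle: s2 ~ s0^2 * F(d_g, d0) with d0=4, d_g=9
        rng = np.random.default_rng(0)
        s2 = 0.04 * stats.f.rvs(9, 4, size=10_000, random_state=rng)
        d0, s02 = fit_ebayes_prior(s2, df=9)
        assert abs(d0 - 4) / 4 < 0.2
        assert abs(s02 - 0.04) / 0.04 < 0.2

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_ebayes_prior(np.zeros(5), df=9)


class TestModeratedT:
    def test_case_at_control_mean_is_null(self):
        t, p = moderated_one_vs_group(0.8, np.full(10, 0.8), d0=np.inf, s02=0.01)
        assert t == 0.0 and p == 1.0

    def test_no_moderation_equals_ordinary_t(self, tight_controls):
        t, p = moderated_one_vs_group(0.5, tight_controls, d0=0.0, s02=123.0)
        x = tight_controls
        se = x.std(ddof=1) * np.sqrt(1 + 1 / x.size)
        t_ref = (0.5 - x.mean()) / se
        p_ref = 2 * stats.t.sf(abs(t_ref), x.size - 1)
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)

    def test_infinite_prior_df_closed_form(self):
        # sd fixed at 0.02 by the prior: |t| = 0.45 / (0.02 sqrt(1.1))
        t, p = moderated_one_vs_group(0.45, np.full(10, 0.90), d0=np.inf, s02=0.02**2)
        assert abs(t) == pytest.approx(0.45 / (0.02 * np.sqrt(1.1)), rel=1e-6)
        assert abs(t) == pytest.approx(21.45, abs=0.01)

    def test_huge_prior_df_approaches_z_statistic(self, tight_controls):
        t_big, p_big = moderated_one_vs_group(0.5, tight_controls, d0=1e9, s02=4e-4)
        z = (0.5 - tight_controls.mean()) / np.sqrt(
            4e-4 * (1 + 1 / tight_controls.size)
        )
        assert t_big == pytest.approx(z, rel=1e-3)
        assert p_big == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-2)

    def test_too_few_controls(self):
        with pytest.raises(ValueError, match="3 control"):
            moderated_one_vs_group(0.5, np.array([0.8, 0.9]))


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=1, max_size=50)
    )
    def test_q_dominates_p_and_is_permutation_stable(self, ps):
        p = np.array(ps)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(np.sort(bh_adjust(p[perm])), np.sort(q))


class TestPanelFrequency:
    def _panel(self, values):
        return pd.DataFrame([values], index=pd.Index(["cgX"], name="probe_id"))

    def test_three_of_757_is_rare(self):
        vals = np.full(757, 0.9)
        vals[:3] = 0.45  # same hyper->intermediate drop as the case call
        f = panel_frequency("cgX", self._panel(vals), 0.9, "hypo")
        assert f == pytest.approx(3 / 757)
        assert f < 0.005

    def test_four_of_757_is_common(self):
        vals = np.full(757, 0.9)
        vals[:4] = 0.45
        f = panel_frequency("cgX", self._panel(vals), 0.9, "hypo")
        assert f == pytest.approx(4 / 757)
        assert f > 0.005

    def test_no_altered_samples(self):
        f = panel_frequency("cgX", self._panel(np.full(100, 0.9)), 0.9, "hypo")
        assert f == 0.0

    def test_direction_must_match(self):
        vals = np.full(100, 0.5)
        vals[:10] = 0.95  # hyper-direction moves
        assert panel_frequency("cgX", self._panel(vals), 0.5, "hypo") == 0.0
        assert panel_frequency("cgX", self._panel(vals), 0.5, "hyper") == pytest.approx(0.1)


def _study_matrix(seed=0, n_probes=400, n_ctrl=10, n_case=2):
    """Tight hyper probes with named samples, as a beta DataFrame."""
    rng = np.random.default_rng(seed)
    probes = pd.Index([f"cg{i:05d}" for i in range(n_probes)], name="probe_id")
    cols = [f"ASD_{i+1}" for i in range(n_case)] + [f"CTL_{i+1}" for i in range(n_ctrl)]
    vals = rng.beta(0.85 * 300, 0.15 * 300, size=(n_probes, n_case + n_ctrl))
    return pd.DataFrame(vals, index=probes, columns=cols)


class TestCaller:
    def test_retained_call_for_large_drop(self):
        beta = _study_matrix(seed=1)
        beta.at["cg00007", "ASD_1"] = 0.462  # vs control mean ~0.85: big drop
        controls = [c for c in beta.columns if c.startswith("CTL")]
        calls = call_dmcpgs("ASD_1", beta, controls)
        assert "cg00007" in set(calls["probe_id"])
        row = calls.set_index("probe_id").loc["cg00007"]
        assert row["status_from"] == "hyper" and row["status_to"] == "intermediate"
        assert row["q_value"] < 0.01 and row["delta_beta"] < -0.18

    def test_small_delta_rejected_despite_significance(self):
        beta = _study_matrix(seed=2)
        ctrl_mean = beta.loc["cg00007", [c for c in beta.columns if "CTL" in c]].mean()
        beta.at["cg00007", "ASD_1"] = ctrl_mean - 0.10  # significant but small
        controls = [c for c in beta.columns if c.startswith("CTL")]
        cand = call_dmcpgs("ASD_1", beta, controls, keep_candidates=True)
        sub = cand[cand["probe_id"] == "cg00007"]
        if len(sub):  # may or may not reach q<0.01; if it does, delta must fail
            assert not sub.iloc[0]["pass_delta"]
        calls = call_dmcpgs("ASD_1", beta, controls)
        assert "cg00007" not in set(calls["probe_id"])

    def test_control_altered_probe_discarded(self):
        beta = _study_matrix(seed=3)
        beta.at["cg00010", "ASD_1"] = 0.40
        beta.at["cg00010", "CTL_3"] = 0.40  # a control shows the same event
        controls = [c for c in beta.columns if c.startswith("CTL")]
        cand = call_dmcpgs("ASD_1", beta, controls, keep_candidates=True)
        row = cand[cand["probe_id"] == "cg00010"]
        assert len(row) == 1 and not row.iloc[0]["pass_control_altered"]

    def test_panel_filter_discards_common_variants(self):
        beta = _study_matrix(seed=4)
        beta.at["cg00020", "ASD_1"] = 0.40
        controls = [c for c in beta.columns if c.startswith("CTL")]
        panel_vals = np.full((1, 200), 0.85)
        panel_vals[0, :10] = 0.40  # 5% of the panel carries the same change
        panel = pd.DataFrame(
            np.vstack([np.full((len(beta), 200), np.nan)]),
            index=beta.index,
            columns=[f"P{i}" for i in range(200)],
        )
        rng = np.random.default_rng(0)
        panel.iloc[:, :] = rng.beta(0.85 * 300, 0.15 * 300, size=panel.shape)
        panel.loc["cg00020"] = panel_vals[0]
        calls = call_dmcpgs("ASD_1", beta, controls, panel=panel)
        assert "cg00020" not in set(calls["probe_id"])
        cand = call_dmcpgs("ASD_1", beta, controls, panel=panel, keep_candidates=True)
        row = cand[cand["probe_id"] == "cg00020"]
        assert len(row) == 1 and not row.iloc[0]["pass_panel"]

    def test_case_listed_as_control_rejected(self):
        beta = _study_matrix(seed=5)
        with pytest.raises(ValueError, match="among the controls"):
            call_dmcpgs("CTL_1", beta, [c for c in beta.columns if "CTL" in c])

    def test_filters_only_remove(self):
        beta = _study_matrix(seed=6)
        beta.at["cg00031", "ASD_1"] = 0.45
        controls = [c for c in beta.columns if c.startswith("CTL")]
        cand = call_dmcpgs("ASD_1", beta, controls, keep_candidates=True)
        calls = call_dmcpgs("ASD_1", beta, controls)
        assert set(calls["probe_id"]) <= set(cand["probe_id"])
        assert (cand["q_value"] < 0.01).all()

    def test_sklearn_param_interface(self):
        caller = DMCpGCaller(delta_min=0.2)
        assert caller.get_params()["delta_min"] == 0.2
        caller.set_params(q_max=0.05)
        assert caller.q_max == 0.05


class TestRecoveryOnStudy:
    def test_spiked_mesnvs_recovered_no_false_calls(self, small_study):
        from epivar.qc import run_qc

        st_ = small_study
        surviving, _ = run_qc(
            st_.detection_p, st_.annotation, beta_index=st_.betas.values.index
        )
        beta = st_.betas.values.loc[surviving]
        caller = DMCpGCaller().fit(
            beta[st_.control_ids].T, panel=st_.panel.values.loc[surviving]
        )
        calls = caller.predict(beta[st_.case_ids].T)
        truth = {(t.sample_id, t.probe_ids[0]) for t in st_.truth if t.kind == "meSNV"}
        got = set(zip(calls["sample_id"], calls["probe_id"]))
        assert len(truth & got) >= len(truth) - 1  # >= 5/6 here; full-scale suite covers 0.95
        truth_probes = {
            p for t in st_.truth if t.kind in ("meSNV", "epimutation") for p in t.probe_ids
        }
        false_calls = [g for g in got if g[1] not in truth_probes]
        assert len(false_calls) <= 1
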