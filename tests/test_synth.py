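"""Generator contracts: value ranges, determinism, spike semantics."""

import numpy as np
import pandas as pd
import pytest

from epivar.outlier import classify_status
from epivar.synth import (
    DEFAULT_ARCHETYPES,
    ProbeArchetype,
    betas_for_assignment,
    revert_spike,
    simulate_allele_counts,
    simulate_control_betas,
    simulate_expression,
    spike_dmr,
    spike_mesnv,
)


class TestControlBetas:
    def test_values_in_unit_interval_and_archetypes_recorded(self):
        m = simulate_control_betas(
            500, 10, {"hyper": 0.5, "intermediate": 0.3, "hypo": 0.2}, seed=1
        )
        v = m.values.to_numpy()
        assert ((v >= 0) & (v <= 1)).all()
        assert set(m.archetypes.unique()) <= {"hypo", "intermediate", "hyper"}
        assert len(m.archetypes) == 500

    def test_hyper_probe_means_exceed_bin_threshold(self):
        # Monte-Carlo check: at the default concentration, sample means of
        # hyper-assigned probes stay above 0.7 for at least 95% of probes
        m = simulate_control_betas(
            1000, 10, {"hyper": 0.5, "intermediate": 0.3, "hypo": 0.2}, seed=1
        )
        hyper = m.values[m.archetypes == "hyper"]
        frac = (hyper.mean(axis=1) > 0.7).mean()
        assert frac >= 0.95

    def test_determinism_same_seed(self):
        a = simulate_control_betas(1, 2, {"hyper": 1.0}, seed=7)
        b = simulate_control_betas(1, 2, {"hyper": 1.0}, seed=7)
        assert a.values.equals(b.values)
        assert ((a.values.to_numpy() > 0) & (a.values.to_numpy() < 1)).all()

    def test_archetype_means_map_to_status_bins(self):
        assert classify_status(DEFAULT_ARCHETYPES["hypo"].mean_beta) == "hypo"
        assert (
            classify_status(DEFAULT_ARCHETYPES["intermediate"].mean_beta)
            == "intermediate"
        )
        assert classify_status(DEFAULT_ARCHETYPES["hyper"].mean_beta) == "hyper"

    def test_non_summing_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_control_betas(10, 5, {"hyper": 0.5, "hypo": 0.2}, seed=0)

    def test_archetype_invariants(self):
        with pytest.raises(ValueError):
            ProbeArchetype("hypo", 0.4, 50.0)  # hypo mean must be < 0.3
        with pytest.raises(ValueError):
            ProbeArchetype("hyper", 0.85, -1.0)

    def test_shared_assignment_matches_archetypes(self):
        m = simulate_control_betas(200, 5, seed=3)
        panel = betas_for_assignment(m.archetypes, 8, seed=4)
        assert panel.archetypes.equals(m.archetypes)
        hyper = panel.values[panel.archetypes == "hyper"]
        assert (hyper.mean(axis=1) > 0.7).all()


class TestSpikeMesnv:
    def test_het_on_hyper_probe_lands_intermediate(self):
        m = simulate_control_betas(50, 6, {"hyper": 1.0}, seed=2)
        probe = str(m.probe_ids[0])
        sample = str(m.sample_ids[0])
        m.values.at[probe, sample] = 0.90
        spiked, rec = spike_mesnv(m, probe, sample, "het", seed=0)
        v = float(spiked.values.at[probe, sample])
        assert 0.35 <= v <= 0.55  # one unmethylated allele halves the signal
        assert rec.kind == "meSNV" and rec.expected_direction == "hypo"
        # all other cells untouched
        other = spiked.values.drop(columns=[sample])
        assert other.equals(m.values.drop(columns=[sample]))

    def test_hom_reads_near_zero(self):
        m = simulate_control_betas(10, 4, {"hyper": 1.0}, seed=3)
        spiked, _ = spike_mesnv(m, str(m.probe_ids[1]), str(m.sample_ids[1]), "hom", seed=1)
        assert float(spiked.values.iat[1, 1]) < 0.15

    def test_revert_round_trip(self):
        m = simulate_control_betas(10, 4, {"hyper": 1.0}, seed=4)
        spiked, rec = spike_mesnv(m, str(m.probe_ids[2]), str(m.sample_ids[0]), "het", seed=2)
        assert revert_spike(spiked, rec).values.equals(m.values)

    def test_unknown_probe_or_sample_rejected(self):
        m = simulate_control_betas(5, 4, {"hyper": 1.0}, seed=5)
        with pytest.raises(KeyError):
            spike_mesnv(m, "cg_nope", str(m.sample_ids[0]))
        with pytest.raises(KeyError):
            spike_mesnv(m, str(m.probe_ids[0]), "nobody")


class TestSpikeDmr:
    def test_shift_and_truth_direction(self):
        m = simulate_control_betas(30, 4, {"hypo": 1.0}, seed=6)
        probes = [str(p) for p in m.probe_ids[:5]]
        spiked, rec = spike_dmr(m, probes, str(m.sample_ids[0]), +0.30, seed=1)
        assert rec.expected_direction == "hyper"
        deltas = (
            spiked.values.loc[probes, m.sample_ids[0]]
            - m.values.loc[probes, m.sample_ids[0]]
        )
        assert (deltas > 0.15).all()  # shifted up, modulo Beta noise

    def test_zero_delta_rejected_matrix_unchanged(self):
        m = simulate_control_betas(10, 4, {"hypo": 1.0}, seed=7)
        before = m.values.copy()
        with pytest.raises(ValueError):
            spike_dmr(m, [str(m.probe_ids[0]), str(m.probe_ids[1])], str(m.sample_ids[0]), 0.0)
        assert m.values.equals(before)

    def test_single_probe_run_rejected(self):
        m = simulate_control_betas(10, 4, {"hypo": 1.0}, seed=8)
        with pytest.raises(ValueError, match=">=2"):
            spike_dmr(m, [str(m.probe_ids[0])], str(m.sample_ids[0]), 0.3)

    def test_saturating_delta_clips_to_one(self):
        m = simulate_control_betas(10, 4, {"intermediate": 1.0}, seed=9)
        probes = [str(p) for p in m.probe_ids[:3]]
        sample = str(m.sample_ids[0])
        m.values.loc[probes, sample] = 0.5
        spiked, _ = spike_dmr(m, probes, sample, +1.0, seed=1)
        assert (spiked.values.loc[probes, sample] == 1.0).all()


class TestExpression:
    def test_null_links_preserve_type_one_error(self):
        # with lfc=0 everywhere, a two-sample t between arbitrary halves of
        # the cohort rejects at ~5%: Monte-Carlo bound <= 7% over 1000 genes
        from scipy import stats

        expr, _ = simulate_expression(1000, [f"S{i}" for i in range(20)], seed=1)
        a = expr.iloc[:, :10].to_numpy()
        b = expr.iloc[:, 10:].to_numpy()
        _, p = stats.ttest_ind(a, b, axis=1)
        assert (p < 0.05).mean() <= 0.07

    def test_carrier_outlier_zscore_recall(self):
        # a 4x (lfc=2) single-carrier effect at CV 0.2 gives z > 2 in >=90%
        from epivar.integrate import expression_zscore

        hits = 0
        for seed in range(30):
            expr, _ = simulate_expression(
                1,
                [f"S{i}" for i in range(29)],
                links={"gene00000": {"lfc": 2.0, "carriers": ["S0"]}},
                seed=seed,
                cv=0.2,
            )
            if expression_zscore("gene00000", "S0", expr) > 2:
                hits += 1
        assert hits >= 27

    def test_empty_gene_set(self):
        expr, truths = simulate_expression(0, ["S1", "S2"], seed=0)
        assert expr.empty and truths == []

    def test_values_nonnegative(self):
        expr, _ = simulate_expression(50, [f"S{i}" for i in range(5)], seed=2)
        assert (expr.to_numpy() >= 0).all()


class TestAlleleCounts:
    def test_zero_maf_gives_zero_minor_alleles(self):
        t = simulate_allele_counts(100, 200, 0.0, 0.0, seed=0)
        assert t["a"] == 0 and t["c"] == 0
        assert t["b"] == 200 and t["d"] == 400

    def test_binomial_expectation(self):
        # mean case minor-allele count over many draws ~ 2*447*0.0067 = 5.99
        tot = 0
        n_rep = 3000
        for seed in range(n_rep):
            tot += simulate_allele_counts(447, 1349, 0.0067, 0.0019, seed=seed)["a"]
        assert abs(tot / n_rep - 5.99) < 0.15

    def test_seed_reproducibility_and_margins(self):
        t1 = simulate_allele_counts(50, 60, 0.1, 0.05, seed=9)
        t2 = simulate_allele_counts(50, 60, 0.1, 0.05, seed=9)
        assert t1 == t2
        assert t1["a"] + t1["b"] == 100 and t1["c"] + t1["d"] == 120


class TestStudy:
    def test_study_determinism_and_truth(self, small_study):
        from conftest import small_config

        from epivar.synth import simulate_study

        again = simulate_study(small_config(), seed=11)
        assert small_study.betas.values.equals(again.betas.values)
        assert small_study.panel.values.equals(again.panel.values)
        kinds = {t.kind for t in small_study.truth}
        assert {"meSNV", "epimutation", "expression_effect", "assoc_variant"} <= kinds

    def test_written_study_round_trips(self, small_study, tmp_path):
        small_study.write(tmp_path)
        beta = pd.read_csv(tmp_path / "beta.tsv", sep="\t", index_col=0)
        assert np.allclose(beta.to_numpy(), small_study.betas.values.to_numpy())
        assert (tmp_path / "manifest.json").exists()
        controls = (tmp_path / "controls.txt").read_text().split()
        assert controls == small_study.control_ids
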