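"""Synthetic cohort generator: calibration, marginals, determinism."""

import numpy as np
import pandas as pd
import pytest

from apoescore.genotypes import GROUP_CASE, GROUP_CONTROL, SNPDef
from apoescore.io import write_cohort_tsv
from apoescore.ld import em_haplotypes, ld_stats
from apoescore.simulate import (
    GROUP_MAFS,
    LD_TARGETS,
    SimulationConfig,
    calibrate_pool,
    default_config,
    simulate_cohort,
)

pytestmark = pytest.mark.filterwarnings("ignore::FutureWarning")


@pytest.fixture(scope="module")
def big_control_cohort():
    """Large control arm for law-of-large-numbers checks (50 000 controls)."""
    return simulate_cohort(default_config(n_case=110, n_control=50_000, seed=19))


class TestDefaultConfig:
    def test_control_pool_rs429358_marginal(self, default_cfg):
        assert default_cfg.pool_marginal(GROUP_CONTROL, "rs429358") == \
            pytest.approx(0.091, abs=1e-9)

    def test_case_pool_rs405509_marginal(self, default_cfg):
        assert default_cfg.pool_marginal(GROUP_CASE, "rs405509") == \
            pytest.approx(0.398, abs=1e-9)

    def test_all_published_marginals_reproduced(self, default_cfg):
        # every realized (post-rejection) frequency matches the published MAF
        for group, mafs in GROUP_MAFS.items():
            for rsid, maf in mafs.items():
                got = default_cfg.expected_allele_freq(group, rsid)
                tol = 1e-9 if rsid == "rs7412" else 1e-3
                assert got == pytest.approx(maf, abs=tol), (group, rsid)

    def test_pools_are_proper_distributions(self, default_cfg):
        for pool in (default_cfg.haplotype_pool_case,
                     default_cfg.haplotype_pool_control):
            assert sum(pool.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(f > 0 for f in pool.values())

    def test_e1_haplotype_absent_from_pools(self, default_cfg):
        # rs429358-C together with rs7412-T never occurs
        for pool in (default_cfg.haplotype_pool_case,
                     default_cfg.haplotype_pool_control):
            for hap in pool:
                assert not (hap[4] == "C" and hap[5] == "T")

    def test_e2e2_probability_zero_in_simulated_cohorts(self):
        cohort = simulate_cohort(default_config(n_case=5000, n_control=5000,
                                                seed=23))
        eps = cohort.epsilon_genotypes().map(str)
        assert (eps == "E2/E2").sum() == 0
        assert (eps == "E2/E3").sum() > 0  # E2 itself does occur

    def test_invalid_pool_rejected(self, default_cfg):
        bad = dict(default_cfg.haplotype_pool_case)
        first = next(iter(bad))
        bad[first] += 0.1
        with pytest.raises(Exception):
            SimulationConfig(
                n_case=10, n_control=10, haplotype_pool_case=bad,
                haplotype_pool_control=default_cfg.haplotype_pool_control,
                rare_mafs=default_cfg.rare_mafs,
                apoe_level_params=default_cfg.apoe_level_params,
                covariates=default_cfg.covariates)


class TestCalibratePool:
    def _loci(self, n=2):
        defs = [SNPDef("L1", "L1", "A", "T", "T"), SNPDef("L2", "L2", "C", "G", "G"),
                SNPDef("L3", "L3", "A", "G", "G")]
        return defs[:n]

    def test_complete_ld_gives_two_haplotypes(self):
        loci = self._loci()
        pool, diag = calibrate_pool({"L1": 0.5, "L2": 0.5},
                                    [("L1", "L2", 1.0)], forbidden=(),
                                    loci=loci)
        assert set(pool) == {"TG", "AC"}
        assert pool["TG"] == pytest.approx(0.5, abs=1e-9)
        assert diag.max_dprime_error < 1e-9

    def test_zero_ld_gives_product_of_marginals(self):
        loci = self._loci()
        pool, _ = calibrate_pool({"L1": 0.3, "L2": 0.2},
                                 [("L1", "L2", 0.0)], forbidden=(), loci=loci)
        assert pool["TG"] == pytest.approx(0.3 * 0.2, abs=1e-12)
        assert pool["AC"] == pytest.approx(0.7 * 0.8, abs=1e-12)

    def test_six_locus_targets_self_consistent(self):
        # recompute D' from the returned pools: within 0.02 of targets
        for group in (GROUP_CASE, GROUP_CONTROL):
            pool, diag = calibrate_pool(GROUP_MAFS[group], LD_TARGETS)
            assert diag.margin_error < 1e-9
            for pair, target in diag.target_dprime.items():
                assert diag.achieved_dprime[pair] == \
                    pytest.approx(abs(target), abs=0.02), (group, pair)

    def test_marginals_matched_exactly(self):
        pool, diag = calibrate_pool(GROUP_MAFS[GROUP_CASE], LD_TARGETS)
        for i, (rsid, maf) in enumerate(
                [("rs449647", 0.150), ("rs769446", 0.059), ("rs405509", 0.398),
                 ("rs440446", 0.335), ("rs429358", 0.289), ("rs7412", 0.039)]):
            minor = {"rs449647": "T", "rs769446": "C", "rs405509": "G",
                     "rs440446": "C", "rs429358": "C", "rs7412": "T"}[rsid]
            got = sum(f for h, f in pool.items() if h[i] == minor)
            assert got == pytest.approx(maf, abs=1e-9), rsid


class TestSimulatedCohorts:
    def test_same_seed_byte_identical_tsv(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_cohort_tsv(simulate_cohort(default_config(seed=42)), p1)
        write_cohort_tsv(simulate_cohort(default_config(seed=42)), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        c1 = simulate_cohort(default_config(seed=1))
        c2 = simulate_cohort(default_config(seed=2))
        assert not c1.data["rs405509"].equals(c2.data["rs405509"])

    def test_realized_frequency_converges(self, big_control_cohort):
        # rs405509-G among 50 000 controls: within 3 binomial SE of 0.559
        d = big_control_cohort.minor_dosage("rs405509")[
            big_control_cohort.group_mask(GROUP_CONTROL)]
        freq = d.sum() / (2 * len(d))
        se = np.sqrt(0.559 * 0.441 / (2 * len(d)))
        assert abs(freq - 0.559) < 3 * se

    def test_serum_level_conditional_means(self, big_control_cohort):
        eps = big_control_cohort.epsilon_genotypes().map(
            lambda e: None if e is None else str(e))
        apoe = big_control_cohort.data["apoe_level"]
        for genotype, mean, sd in [("E4/E4", 3.72, 0.8), ("E3/E3", 6.38, 1.48)]:
            values = apoe[eps == genotype]
            assert len(values) > 50
            assert abs(values.mean() - mean) < 3 * sd / np.sqrt(len(values))

    def test_epsilon_distribution_follows_pool(self, big_control_cohort,
                                               default_cfg):
        # E4 allele frequency among subjects tracks the configured value
        eps = big_control_cohort.epsilon_genotypes()
        controls = big_control_cohort.group_mask(GROUP_CONTROL)
        count_e4 = sum((str(e).count("E4")) for e in eps[controls])
        n = int(controls.sum())
        freq = count_e4 / (2 * n)
        expected = default_cfg.expected_allele_freq(GROUP_CONTROL, "rs429358")
        se = np.sqrt(expected * (1 - expected) / (2 * n))
        assert abs(freq - expected) < 3 * se

    def test_covariate_marginals(self, big_control_cohort):
        controls = big_control_cohort.data[
            big_control_cohort.data["group"] == GROUP_CONTROL]
        assert controls["sex"].eq("F").mean() == pytest.approx(85 / 110, abs=0.02)
        assert controls["age"].mean() == pytest.approx(66.8, abs=0.5)
        assert controls["age"].between(40, 100).all()
        assert controls["age_at_onset"].isna().all()
        edu = controls["education"].value_counts(normalize=True)
        assert edu[4] == pytest.approx(64 / 110, abs=0.02)

    def test_cases_have_onset_before_interview(self, study_cohort):
        cases = study_cohort.data[study_cohort.data["group"] == GROUP_CASE]
        assert cases["age_at_onset"].notna().all()
        assert (cases["age_at_onset"] <= cases["age"]).all()

    def test_serum_levels_nonnegative(self, study_cohort):
        assert (study_cohort.data["apoe_level"] >= 0).all()

    def test_panel_has_fourteen_markers(self, study_cohort):
        assert len(study_cohort.panel) == 14


class TestGeneratorEstimatorRoundTrip:
    def test_dprime_recovered_from_large_simulation(self):
        # estimate rs440446-rs429358 D' from 50 000 simulated controls
        cohort = simulate_cohort(default_config(n_case=110, n_control=50_000,
                                                seed=31))
        mask = cohort.group_mask(GROUP_CONTROL)
        g1 = cohort.minor_dosage("rs440446")[mask].to_numpy()
        g2 = cohort.minor_dosage("rs429358")[mask].to_numpy()
        h = em_haplotypes(g1, g2)
        st = ld_stats(h, int(mask.sum()))
        assert st.D_prime == pytest.approx(0.956, abs=0.02)

    def test_yaml_round_trip(self, tmp_path, default_cfg):
        path = tmp_path / "config.yaml"
        default_cfg.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back.n_case == default_cfg.n_case
        assert back.haplotype_pool_case.keys() == \
            default_cfg.haplotype_pool_case.keys()
        for k, v in default_cfg.haplotype_pool_control.items():
            assert back.haplotype_pool_control[k] == pytest.approx(v)
        c1 = simulate_cohort(back)
        c2 = simulate_cohort(default_cfg)
        assert c1.data["rs405509"].equals(c2.data["rs405509"])
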