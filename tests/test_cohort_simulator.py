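import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from genrisksim import (
    SNPSpec,
    StudySpec,
    ScoreSet,
    assign_status,
    auc_mann_whitney,
    hwe_genotype_freqs,
    posterior_risks,
    sample_genotypes,
    simulate_cohort,
    solve_baseline_risk,
)
from genrisksim.cohort_simulator import cohort_to_frame


class TestHWEFreqs:
    @pytest.mark.parametrize(
        "raf,expected",
        [
            (0.5, (0.25, 0.50, 0.25)),
            (0.0, (1.0, 0.0, 0.0)),
            (1.0, (0.0, 0.0, 1.0)),
            (0.3, (0.49, 0.42, 0.09)),
        ],
    )
    def test_known_values(self, raf, expected):
        assert hwe_genotype_freqs(raf) == pytest.approx(expected, abs=1e-15)

    @given(raf=st.floats(0.0, 1.0))
    @settings(max_examples=50, derandomize=True)
    def test_sums_to_one(self, raf):
        assert sum(hwe_genotype_freqs(raf)) == pytest.approx(1.0, abs=1e-12)


class TestSampleGenotypes:
    def test_empirical_proportions_within_binomial_error(self):
        n = 100_000
        specs = [SNPSpec("s", 0.5, 1.2)]
        gm = sample_genotypes(specs, n, 7)
        props = np.bincount(gm.counts[:, 0], minlength=3) / n
        for p_hat, p in zip(props, (0.25, 0.5, 0.25)):
            assert abs(p_hat - p) < 4 * math.sqrt(p * (1 - p) / n)

    def test_allele_frequency_recovery(self, small_panel):
        n = 100_000
        gm = sample_genotypes(small_panel, n, 11)
        for j, spec in enumerate(small_panel):
            raf_hat = gm.counts[:, j].mean() / 2
            se = math.sqrt(spec.raf * (1 - spec.raf) / (2 * n))
            assert abs(raf_hat - spec.raf) < 4 * se

    def test_same_seed_reproduces_matrix(self, small_panel):
        a = sample_genotypes(small_panel, 500, 3)
        b = sample_genotypes(small_panel, 500, 3)
        assert np.array_equal(a.counts, b.counts)
        assert a.snp_ids == b.snp_ids

    def test_values_are_genotype_counts(self, small_panel):
        gm = sample_genotypes(small_panel, 1000, 5)
        assert set(np.unique(gm.counts)) <= {0, 1, 2}


class TestSolveBaselineRisk:
    def test_null_snp_gives_flat_risks(self):
        prof = solve_baseline_risk(SNPSpec("s", 0.4, 1.0), 0.2)
        assert prof.geno_risks == pytest.approx((0.2, 0.2, 0.2), abs=1e-10)
        assert prof.lrs == pytest.approx((1.0, 1.0, 1.0), abs=1e-9)

    def test_matches_independent_brentq_oracle(self):
        # dual route: package bisection vs scipy brentq on the same prevalence equation
        spec, d = SNPSpec("s", 0.5, 2.0), 0.2
        g = np.array(hwe_genotype_freqs(spec.raf))
        orp = spec.or_allele ** np.arange(3)
        f = lambda o0: float((g * o0 * orp / (1 + o0 * orp)).sum()) - d
        o0 = brentq(f, 1e-12, 1e6, xtol=1e-15)
        expected_p = o0 * orp / (1 + o0 * orp)

        prof = solve_baseline_risk(spec, d)
        assert prof.geno_risks == pytest.approx(tuple(expected_p), abs=1e-9)
        # frozen values from the pre-build oracle run
        assert prof.geno_risks == pytest.approx((0.104320, 0.188931, 0.317817), abs=1e-5)
        assert prof.lrs == pytest.approx((0.465882, 0.931765, 1.863530), abs=1e-5)

    @given(
        raf=st.floats(0.02, 0.98),
        orv=st.floats(1.0, 6.0),
        d=st.floats(0.002, 0.5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_algebraic_identities(self, raf, orv, d):
        prof = solve_baseline_risk(SNPSpec("s", raf, orv), d)
        g = np.array(prof.geno_freqs)
        p = np.array(prof.geno_risks)
        lr = np.array(prof.lrs)
        assert g.sum() == pytest.approx(1.0, abs=1e-12)
        assert float(g @ p) == pytest.approx(d, abs=1e-10)  # prevalence constraint
        assert lr[1] / lr[0] == pytest.approx(orv, rel=1e-9)
        assert lr[2] / lr[0] == pytest.approx(orv**2, rel=1e-9)
        # control-genotype-weighted mean LR is 1
        ctrl_freqs = g * (1 - p) / (1 - d)
        assert float(ctrl_freqs @ lr) == pytest.approx(1.0, abs=1e-9)


class TestPosteriorRisks:
    def test_single_snp_posterior_equals_genotype_risk(self):
        spec, d = SNPSpec("s", 0.5, 2.0), 0.2
        prof = solve_baseline_risk(spec, d)
        gm = sample_genotypes([spec], 50, 13)
        risks = posterior_risks(gm, [prof], d)
        for i, geno in enumerate(gm.counts[:, 0]):
            assert risks[i] == pytest.approx(prof.geno_risks[geno], abs=1e-12)

    def test_null_panel_posterior_is_prior(self, null_panel):
        d = 0.2
        profiles = [solve_baseline_risk(s, d) for s in null_panel]
        gm = sample_genotypes(null_panel, 200, 17)
        assert posterior_risks(gm, profiles, d) == pytest.approx(
            np.full(200, d), abs=1e-9
        )

    def test_mean_posterior_risk_matches_prevalence(self, small_panel):
        d, n = 0.2, 100_000
        profiles = [solve_baseline_risk(s, d) for s in small_panel]
        gm = sample_genotypes(small_panel, n, 19)
        risks = posterior_risks(gm, profiles, d)
        mc_se = risks.std() / math.sqrt(n)
        assert abs(risks.mean() - d) < 4 * mc_se
        assert np.all((risks > 0) & (risks < 1))


class TestAssignStatus:
    def test_extreme_risks(self):
        n = 2000
        assert assign_status(np.full(n, 1 - 1e-12), 1).mean() == 1.0
        assert assign_status(np.full(n, 1e-12), 1).mean() == 0.0

    def test_constant_risk_prevalence_bound(self):
        r, n = 0.3, 100_000
        status = assign_status(np.full(n, r), 23)
        assert abs(status.mean() - r) < 4 * math.sqrt(r * (1 - r) / n)


class TestSimulateCohort:
    def test_same_seed_is_bit_identical(self, small_study):
        a = simulate_cohort(small_study, 42)
        b = simulate_cohort(small_study, 42)
        assert np.array_equal(a.genotypes.counts, b.genotypes.counts)
        assert np.array_equal(a.posterior_risk, b.posterior_risk)
        assert np.array_equal(a.status, b.status)
        assert a.seed == b.seed == 42

    def test_null_panel_has_no_discrimination(self, null_panel):
        study = StudySpec(
            study_id="null", disease="test", d=0.2, model_type="bayes",
            snps=tuple(null_panel), n_sim=50_000, n_iter=1,
        )
        cohort = simulate_cohort(study, 7)
        # posterior risk is constant d -> rank AUC of any tie-broken score is 0.5;
        # use the unweighted allele count, which is independent of status here
        score = ScoreSet(
            scores=cohort.genotypes.counts.sum(axis=1).astype(float),
            status=cohort.status, model_type="unweighted",
        )
        assert auc_mann_whitney(score).auc == pytest.approx(0.5, abs=0.01)

    def test_prevalence_recovery(self, small_study):
        d, n = small_study.d, small_study.n_sim
        cohort = simulate_cohort(small_study, 3)
        assert abs(cohort.status.mean() - d) < 4 * math.sqrt(d * (1 - d) / n)

    def test_or_recovery_from_simulated_alleles(self, small_panel):
        # the allelic OR re-estimated from the 2x2 allele-by-status table
        # matches its exact population value (computed by enumerating the
        # joint genotype space) within the Woolf 95% CI.  For strong effects
        # at common disease risk the allele-table OR sits slightly below the
        # per-allele genotype OR (odds-ratio non-collapsibility), so the
        # enumerated value — not the input — is the recovery target here.
        import itertools

        from genrisksim import ci_from_counts

        d = 0.2
        profiles = [solve_baseline_risk(s, d) for s in small_panel]
        G = len(small_panel)
        combos = np.array(list(itertools.product(range(3), repeat=G)))
        freqs = np.array([p.geno_freqs for p in profiles])
        loglrs = np.log([p.lrs for p in profiles])
        idx = np.arange(G)
        prob = freqs[idx, combos].prod(axis=1)
        log_odds = math.log(d / (1 - d)) + loglrs[idx, combos].sum(axis=1)
        risk = 1 / (1 + np.exp(-log_odds))
        dbar = float(prob @ risk)
        expected_or = []
        for j in range(G):
            pa = float((prob * risk * combos[:, j]).sum()) / (2 * dbar)
            pu = float((prob * (1 - risk) * combos[:, j]).sum()) / (2 * (1 - dbar))
            expected_or.append(pa * (1 - pu) / ((1 - pa) * pu))

        study = StudySpec(
            study_id="rec", disease="test", d=d, model_type="bayes",
            snps=tuple(small_panel), n_sim=100_000, n_iter=1,
        )
        cohort = simulate_cohort(study, 31)
        cases = cohort.status == 1
        for j, spec in enumerate(small_panel):
            geno = cohort.genotypes.counts[:, j]
            a = int(geno[cases].sum())
            b = int(2 * cases.sum() - a)
            c = int(geno[~cases].sum())
            e = int(2 * (~cases).sum() - c)
            orv, _, _ = ci_from_counts(a, b, c, e)
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / e)
            assert abs(math.log(orv) - math.log(expected_or[j])) < 4 * se
            # the enumerated value stays close to the input even at OR = 2
            assert expected_or[j] == pytest.approx(spec.or_allele, rel=0.02)

    def test_export_frame_shape(self, small_study):
        cohort = simulate_cohort(small_study, 5)
        df = cohort_to_frame(cohort)
        assert list(df.columns) == ["a", "b", "c", "posterior_risk", "status"]
        assert len(df) == small_study.n_sim
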