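import numpy as np
import pandas as pd
import pytest

from subjectds import simulate
from subjectds.io import CellAnnotation, CellCounts, SubjectDesign, ValidationError


def make_params(alpha, sigma2, q1, n_cells=20, sjc=1.0, n_subjects=2, genes=None):
    """One-coefficient params: q_ij = q1 for every subject."""
    genes = genes or ["g1"]
    g = len(genes)
    subjects = [f"S{j + 1}" for j in range(n_subjects)]
    design = SubjectDesign(subjects, np.ones((n_subjects, 1)), ["intercept"])
    beta = np.full((g, 1), np.log(q1))
    return simulate.HierarchicalParams(
        genes,
        design,
        beta,
        np.full(g, alpha),
        np.full((g, n_subjects), sigma2),
        [np.full(n_cells, sjc) for _ in subjects],
    )


class TestTheoreticalMoments:
    def test_nb_variance_when_no_cell_level_variance(self):
        # sigma2 = 0: variance reduces to mu + alpha mu^2
        p = make_params(alpha=0.3, sigma2=0.0, q1=2.0, n_cells=10, sjc=1.5)
        mean, var = simulate.theoretical_moments(p, 0, 0)
        mu = 15.0 * 2.0
        assert mean == pytest.approx(mu)
        assert var == pytest.approx(mu + 0.3 * mu**2)

    def test_poisson_identity_when_all_variances_zero(self):
        p = make_params(alpha=0.0, sigma2=0.0, q1=0.7, n_cells=4, sjc=2.0)
        mean, var = simulate.theoretical_moments(p, 0, 0)
        assert mean == pytest.approx(var)

    def test_general_formula_terms(self):
        alpha, sigma2, q = 0.2, 0.5, 3.0
        sjc = np.array([1.0, 2.0, 3.0])
        p = make_params(alpha=alpha, sigma2=sigma2, q1=q, n_cells=3)
        p.cell_size_factors[0] = sjc
        mean, var = simulate.theoretical_moments(p, 0, 0)
        sj = sjc.sum()
        assert mean == pytest.approx(sj * q)
        expected = sj**2 * q**2 * alpha + sigma2 * (1 + alpha) * q**2 * (sjc**2).sum() + sj * q
        assert var == pytest.approx(expected)


@pytest.mark.parametrize(
    "alpha,sigma2",
    [(0.0, 0.0), (0.0, 1.0), (0.5, 0.0), (0.1, 0.2), (0.5, 1.0)],
)
def test_simulated_moments_match_oracle(alpha, sigma2):
    """Monte-Carlo mean/variance of aggregated counts vs the exact formulas."""
    n_draws = 30_000
    q, n_cells, sjc = 0.5, 15, 2.0
    p = make_params(alpha=alpha, sigma2=sigma2, q1=q, n_cells=n_cells, sjc=sjc, n_subjects=1)
    rng = np.random.default_rng(123)
    theta = rng.gamma(1 / alpha, q * alpha, size=n_draws) if alpha > 0 else np.full(n_draws, q)
    if sigma2 > 0:
        lam = rng.gamma(1 / sigma2, (theta * sigma2)[:, None] * np.ones(n_cells))
    else:
        lam = np.repeat(theta[:, None], n_cells, axis=1)
    k = rng.poisson(sjc * lam).sum(axis=1)
    mean, var = simulate.theoretical_moments(p, 0, 0)
    se_mean = k.std(ddof=1) / np.sqrt(n_draws)
    m4 = np.mean((k - k.mean()) ** 4)
    se_var = np.sqrt(max(m4 - k.var(ddof=1) ** 2, 0) / n_draws)
    assert abs(k.mean() - mean) < 3 * se_mean
    assert abs(k.var(ddof=1) - var) < 3 * se_var


class TestSimulateCounts:
    def test_pure_poisson_limit(self):
        # alpha = sigma2 = 0: counts are Poisson(sjc * q) exactly
        p = make_params(alpha=0.0, sigma2=0.0, q1=0.25, n_cells=20_000, sjc=3.0, n_subjects=1)
        counts, _, _ = simulate.simulate_counts(p, rng=7)
        k = counts.counts[0]
        lam = 3.0 * 0.25
        assert abs(k.mean() - lam) < 3 * np.sqrt(lam / k.size)
        assert abs(k.var(ddof=1) - lam) < 4 * np.sqrt(2 * lam**2 / k.size + lam / k.size)

    def test_absent_gene_all_zero(self):
        p = make_params(alpha=0.2, sigma2=0.5, q1=1.0, genes=["g1", "g2"])
        p.beta[1, 0] = -np.inf  # q = 0: gene absent
        counts, _, _ = simulate.simulate_counts(p, rng=0)
        assert counts.counts[1].sum() == 0

    def test_aggregated_mean_matches_mu(self):
        p = make_params(alpha=0.1, sigma2=0.4, q1=0.8, n_cells=10, sjc=1.0, n_subjects=1)
        rng = np.random.default_rng(5)
        agg = np.array(
            [simulate.simulate_counts(p, rng=rng)[0].counts.sum() for _ in range(3000)], float
        )
        mean, var = simulate.theoretical_moments(p, 0, 0)
        assert abs(agg.mean() - mean) < 3 * np.sqrt(var / agg.size)

    def test_sigma2_zero_makes_cell_expression_constant_within_subject(self):
        # large size factors: normalized expression varies only via Poisson noise
        p = make_params(alpha=0.5, sigma2=0.0, q1=0.5, n_cells=30, sjc=1e6, genes=["g1", "g2"])
        counts, _, _ = simulate.simulate_counts(p, rng=11)
        e = counts.counts[:, :30] / counts.counts[:, :30].sum(axis=0, keepdims=True)
        assert e.std(axis=1).max() < 1e-3

    def test_non_finite_q_names_gene(self):
        p = make_params(alpha=0.1, sigma2=0.1, q1=1.0, genes=["g1", "gBAD"])
        p.beta[1, 0] = 1e4  # overflow
        with pytest.raises(ValidationError, match="gBAD"):
            simulate.simulate_counts(p, rng=0)


class TestDrawEffects:
    def test_pde_zero_all_null(self):
        t = simulate.draw_effects(100, 0.0, 1.0, seed=1)
        assert not t.is_de.any() and (t.beta2 == 0).all()

    def test_effect_sd_matches_tau(self):
        t = simulate.draw_effects(100_000, 1.0, 1.0, seed=2)
        assert t.is_de.all()
        assert t.beta2.std(ddof=1) == pytest.approx(1.0, rel=0.01)

    def test_same_seed_identical(self):
        a = simulate.draw_effects(500, 0.3, 0.8, seed=9)
        b = simulate.draw_effects(500, 0.3, 0.8, seed=9)
        np.testing.assert_array_equal(a.beta2, b.beta2)

    def test_flag_consistency_enforced(self):
        t = simulate.draw_effects(1000, 0.5, 1.5, seed=3)
        assert ((t.beta2 != 0) == t.is_de).all()

    def test_truth_round_trip_via_frame(self):
        t = simulate.draw_effects(50, 0.4, 1.0, seed=4)
        back = simulate.TruthTable.from_frame(
            pd.read_csv(__import__("io").StringIO(t.to_frame().to_csv(sep="\t", index=False)), sep="\t")
        )
        np.testing.assert_allclose(back.beta2, t.beta2, rtol=1e-12)
        np.testing.assert_array_equal(back.is_de, t.is_de)


class TestMatchMoments:
    def test_hand_calculated_alpha(self):
        # two subjects with E_ij = {0.1, 0.2}: m=0.15, v=0.005, alpha=0.2222
        counts = CellCounts(
            ["g1", "g2"],
            ["a1", "a2", "b1", "b2"],
            np.array([[10, 10, 20, 20], [90, 90, 80, 80]]),
        )
        ann = CellAnnotation(
            pd.DataFrame(
                {
                    "cell_id": ["a1", "a2", "b1", "b2"],
                    "subject_id": ["S1", "S1", "S2", "S2"],
                    "cell_type": "t",
                }
            )
        )
        est = simulate.match_moments(counts, ann)
        assert est.alpha[0] == pytest.approx(0.005 / 0.0225, rel=1e-12)

    def test_identical_subject_expression_floors_alpha(self):
        counts = CellCounts(
            ["g1", "g2"], ["a1", "a2", "b1", "b2"], np.array([[5, 5, 5, 5], [5, 5, 5, 5]])
        )
        ann = CellAnnotation(
            pd.DataFrame(
                {
                    "cell_id": ["a1", "a2", "b1", "b2"],
                    "subject_id": ["S1", "S1", "S2", "S2"],
                    "cell_type": "t",
                }
            )
        )
        est = simulate.match_moments(counts, ann)
        assert est.alpha[0] == 0.0 and not est.floored_alpha[0]

    def test_monopoly_gene_has_unit_exp_beta1(self):
        counts = CellCounts(["g1", "g2"], ["a1", "a2", "b1", "b2"], np.array([[3, 4, 5, 6], [0, 0, 0, 0]]))
        ann = CellAnnotation(
            pd.DataFrame(
                {
                    "cell_id": ["a1", "a2", "b1", "b2"],
                    "subject_id": ["S1", "S1", "S2", "S2"],
                    "cell_type": "t",
                }
            )
        )
        est = simulate.match_moments(counts, ann)
        assert est.exp_beta1[0] == pytest.approx(1.0)
        assert est.exp_beta1[1] == 0.0

    def test_all_zero_gene_flagged_and_floored(self):
        counts = CellCounts(["g1", "g2"], ["a1", "a2", "b1", "b2"], np.array([[3, 4, 5, 6], [0, 0, 0, 0]]))
        ann = CellAnnotation(
            pd.DataFrame(
                {
                    "cell_id": ["a1", "a2", "b1", "b2"],
                    "subject_id": ["S1", "S1", "S2", "S2"],
                    "cell_type": "t",
                }
            )
        )
        est = simulate.match_moments(counts, ann)
        assert est.alpha[1] == 0.0 and est.floored_alpha[1]

    def test_round_trip_recovers_alpha_and_expression(self):
        """Simulate from known parameters, re-estimate by moment matching."""
        rng = np.random.default_rng(17)
        g, n_subj, n_cells = 60, 30, 300
        subjects = [f"S{j}" for j in range(n_subj)]
        design = SubjectDesign(subjects, np.ones((n_subj, 1)), ["intercept"])
        w = rng.lognormal(0, 1.5, g)
        beta1 = np.log(w / w.sum())
        alpha = np.full(g, 0.15)
        sigma2 = np.full((g, n_subj), 0.8)
        params = simulate.HierarchicalParams(
            [f"g{i}" for i in range(g)], design, beta1[:, None], alpha, sigma2,
            [np.full(n_cells, 3000.0)] * n_subj,
        )
        counts, ann, _ = simulate.simulate_counts(params, rng=rng)
        est = simulate.match_moments(counts, ann)
        expressed = counts.counts.sum(axis=1) > 500
        rel_a = np.abs(est.alpha[expressed] - 0.15) / 0.15
        rel_b = np.abs(est.exp_beta1[expressed] - np.exp(beta1[expressed])) / np.exp(beta1[expressed])
        assert np.median(rel_a) < 0.35  # variance estimate from 30 subjects
        assert np.median(rel_b) < 0.10

    def test_all_zero_subject_errors(self):
        counts = CellCounts(["g1"], ["a1", "a2", "b1", "b2"], np.array([[1, 2, 0, 0]]))
        ann = CellAnnotation(
            pd.DataFrame(
                {
                    "cell_id": ["a1", "a2", "b1", "b2"],
                    "subject_id": ["S1", "S1", "S2", "S2"],
                    "cell_type": "t",
                }
            )
        )
        with pytest.raises(ValidationError, match="S2"):
            simulate.match_moments(counts, ann)


class TestReproducibility:
    def test_replicates_are_independent_streams(self):
        cfg = simulate.SimulationConfig(n_genes=50, cells_per_subject=10, seed=1)
        c0 = simulate.simulate_dataset(cfg, 0)[0]
        c1 = simulate.simulate_dataset(cfg, 1)[0]
        c0b = simulate.simulate_dataset(cfg, 0)[0]
        np.testing.assert_array_equal(c0.counts, c0b.counts)
        assert not np.array_equal(c0.counts, c1.counts)

    def test_config_grid_defaults_match_study_conditions(self):
        cfg = simulate.SimulationConfig()
        assert cfg.n_genes == 21731
        assert cfg.group_sizes == (4, 3)
        assert cfg.n_replicates == 100
        assert simulate.DEFAULT_PDE_GRID == (0.01, 0.3, 0.6)
        assert simulate.DEFAULT_TAU_GRID == (0.5, 1.0, 1.5)

    def test_config_flat_round_trip(self):
        cfg = simulate.SimulationConfig(n_genes=123, p_de=0.6, tau=1.5, seed=9)
        back = simulate.SimulationConfig.from_flat_dict(
            {k: str(v) for k, v in cfg.to_flat_dict().items()}
        )
        assert back == cfg
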