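"""Canned simulation-study runs at desk scale.

These functions reproduce the design of the full simulation study — two
groups of 4 and 3 subjects, a grid of DE proportions and effect-size spreads,
the *subject* and *wilcox* methods compared replicate by replicate — at sizes
a single CPU handles in minutes (2000 genes, 200 cells per subject, 20
replicates) rather than the full 21 731-gene, 100-replicate grid.  They back
the reproduction script and the acceptance-style tests; all randomness flows
from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import baseline, calibrate, ds_test, evaluate, simulate

STUDY_N_GENES = 2000
STUDY_CELLS_PER_SUBJECT = 200
STUDY_N_REPLICATES = 20
STUDY_GRID = ((0.3, 1.0), (0.3, 1.5), (0.6, 1.0), (0.6, 1.5))


@dataclass
class MethodComparison:
    """Replicate-averaged metrics for one (pDE, tau) setting."""

    p_de: float
    tau: float
    n_replicates: int
    subject: pd.DataFrame  # per-replicate metric rows + mean row
    wilcox: pd.DataFrame

    def mean(self, method: str, metric: str) -> float:
        table = getattr(self, method)
        return float(table.loc[table["replicate"] == "mean", metric].iloc[0])


def compare_methods(
    p_de: float,
    tau: float,
    seed: int,
    n_replicates: int = STUDY_N_REPLICATES,
    n_genes: int = STUDY_N_GENES,
    cells_per_subject: int = STUDY_CELLS_PER_SUBJECT,
    cutoff: float = 0.05,
) -> MethodComparison:
    """Run both DS methods on ``n_replicates`` simulated datasets and collect
    detection metrics against the simulation truth."""
    cfg = simulate.SimulationConfig(
        n_genes=n_genes,
        cells_per_subject=cells_per_subject,
        p_de=p_de,
        tau=tau,
        seed=seed,
        n_replicates=n_replicates,
    )
    rows = {"subject": [], "wilcox": []}
    for r in range(n_replicates):
        counts, ann, design, truth, _ = simulate.simulate_dataset(cfg, r)
        for name, runner in (
            ("subject", ds_test.run_subject_method),
            ("wilcox", baseline.run_wilcox_method),
        ):
            res = runner(counts, ann, design)
            padj = res.set_index("gene").reindex(truth.genes)["padj"].to_numpy(float)
            rows[name].append(evaluate.summarize_replicate(padj, truth.is_de, r, cutoff))
    return MethodComparison(
        p_de, tau, n_replicates,
        evaluate.summary_table(rows["subject"]),
        evaluate.summary_table(rows["wilcox"]),
    )


def moment_oracle_errors(
    seed: int,
    n_draws: int = 100_000,
    settings: tuple[tuple[float, float], ...] = ((0.0, 0.0), (0.0, 1.0), (0.1, 0.2), (0.5, 0.0), (0.5, 1.0)),
    q: float = 0.5,
    n_cells: int = 15,
    sjc: float = 2.0,
) -> pd.DataFrame:
    """Monte-Carlo check of the aggregated-count moment formulas.

    For each (alpha, sigma2) setting, draws ``n_draws`` aggregated counts
    K_j = sum_c K_jc from the three-stage model and reports the deviation of
    the empirical mean and variance from the closed forms, in units of the
    Monte-Carlo standard error.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 9001)))
    out = []
    for alpha, sigma2 in settings:
        theta = rng.gamma(1 / alpha, q * alpha, n_draws) if alpha > 0 else np.full(n_draws, q)
        if sigma2 > 0:
            lam = rng.gamma(1 / sigma2, (theta * sigma2)[:, None] * np.ones(n_cells))
        else:
            lam = np.repeat(theta[:, None], n_cells, axis=1)
        k = rng.poisson(sjc * lam).sum(axis=1).astype(float)

        sj = sjc * n_cells
        mean = sj * q
        var = sj**2 * q**2 * alpha + sigma2 * (1 + alpha) * q**2 * n_cells * sjc**2 + sj * q
        se_mean = k.std(ddof=1) / np.sqrt(n_draws)
        m4 = np.mean((k - k.mean()) ** 4)
        se_var = np.sqrt(max(m4 - k.var(ddof=1) ** 2, 1e-12) / n_draws)
        out.append(
            {
                "alpha": alpha,
                "sigma2": sigma2,
                "mean_z": (k.mean() - mean) / se_mean,
                "var_z": (k.var(ddof=1) - var) / se_var,
                "nb_variance_exact": (
                    abs(var - (mean + alpha * mean**2)) < 1e-9 * max(var, 1.0) if sigma2 == 0 else np.nan
                ),
            }
        )
    return pd.DataFrame(out)


def calibration_gap_comparison(
    seed: int, n_genes: int = 500, cells_per_subject: int = 200
) -> dict[str, float]:
    """Max CDF gap (method vs permutation P-values on [0, 0.2]) for both
    methods on one null dataset with subject-level variance present."""
    cfg = simulate.SimulationConfig(
        n_genes=n_genes, cells_per_subject=cells_per_subject, p_de=0.0, tau=0.0, seed=seed
    )
    counts, ann, design, _, _ = simulate.simulate_dataset(cfg, 0)
    gaps = {}
    for name, runner in (
        ("subject", ds_test.run_subject_method),
        ("wilcox", baseline.run_wilcox_method),
    ):
        result = calibrate.permutation_pvalues(
            lambda d, runner=runner: runner(counts, ann, d), design
        )
        _, gaps[name] = calibrate.cdf_compare(result)
    return gaps


def parameter_recovery_errors(
    seed: int,
    n_genes: int = 200,
    n_subjects: int = 40,
    n_cells: int = 500,
    alpha_true: float = 0.2,
    sigma2_true: float = 0.8,
) -> dict[str, float]:
    """Median relative errors of moment matching on data simulated from known
    (alpha_i, exp(beta_i1)) with many subjects and cells per subject."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 9002)))
    subjects = [f"S{j}" for j in range(n_subjects)]
    design = simulate.SubjectDesign(subjects, np.ones((n_subjects, 1)), ["intercept"])
    w = rng.lognormal(0.0, 1.5, n_genes)
    exp_beta1 = w / w.sum()
    params = simulate.HierarchicalParams(
        [f"g{i}" for i in range(n_genes)],
        design,
        np.log(exp_beta1)[:, None],
        np.full(n_genes, alpha_true),
        np.full((n_genes, n_subjects), sigma2_true),
        [np.full(n_cells, 5000.0)] * n_subjects,
    )
    counts, ann, _ = simulate.simulate_counts(params, rng=rng)
    est = simulate.match_moments(counts, ann)
    expressed = counts.counts.sum(axis=1) >= 100  # moments need observable counts
    rel_alpha = np.abs(est.alpha[expressed] - alpha_true) / alpha_true
    rel_expr = np.abs(est.exp_beta1[expressed] - exp_beta1[expressed]) / exp_beta1[expressed]
    return {
        "alpha_median_rel_err": float(np.median(rel_alpha)),
        "exp_beta1_median_rel_err": float(np.median(rel_expr)),
        "n_genes_used": int(expressed.sum()),
    }
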