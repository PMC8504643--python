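"""Hierarchical gamma-Poisson simulator for multi-subject scRNA-seq counts.

The generative model for one cell type has three stages.  For gene *i*,
subject *j* and cell *c*:

1. subject-level expression
   ``theta_ij ~ Gamma(shape 1/alpha_i, scale q_ij * alpha_i)`` with
   ``log q_ij = sum_r x_jr beta_ir``; mean ``q_ij``, squared coefficient of
   variation ``alpha_i`` (the *subject-level variance*);
2. cell-level expression
   ``lambda_ijc | theta_ij ~ Gamma(shape 1/sigma2_ij, scale theta_ij * sigma2_ij)``;
   mean ``theta_ij``, squared CV ``sigma2_ij`` (the *cell-level variance*);
3. observed counts ``K_ijc | lambda_ijc ~ Poisson(s_jc * lambda_ijc)`` with
   per-cell size factor ``s_jc`` (total UMIs).

``alpha_i = 0`` or ``sigma2_ij = 0`` degenerate the corresponding gamma stage
to a point mass at its mean (the shape -> infinity limit), so the model
continuously covers the pure-Poisson and negative-binomial special cases.

Summed over a subject's cells, ``K_ij = sum_c K_ijc`` has mean
``mu_ij = s_j q_ij`` and exact variance

    s_j^2 q_ij^2 alpha_i + sigma2_ij (1 + alpha_i) q_ij^2 sum_c s_jc^2 + s_j q_ij

(:func:`theoretical_moments`).  As cells per subject grow, the middle term is
dominated by the first, leaving the negative-binomial variance
``mu + alpha mu^2`` that bulk RNA-seq engines assume — the justification for
testing on pseudobulk counts with subjects as the units of analysis.

:func:`match_moments` runs the reverse direction: given real gene-by-cell
counts it matches ``alpha_i``, ``sigma2_ij`` and ``exp(beta_i1)`` to sample
moments of normalized expression so simulations mimic an empirical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CellAnnotation, CellCounts, SubjectDesign, ValidationError

# Full-scale study conditions for the simulation grid.
DEFAULT_N_GENES = 21731
DEFAULT_GROUP_SIZES = (4, 3)
DEFAULT_PDE_GRID = (0.01, 0.3, 0.6)
DEFAULT_TAU_GRID = (0.5, 1.0, 1.5)
DEFAULT_N_REPLICATES = 100


def replicate_rng(seed: int, replicate: int = 0) -> np.random.Generator:
    """Independent, individually reproducible stream for one replicate.

    A single root seed spawns per-replicate streams through
    ``SeedSequence((seed, replicate))`` so replicate *r* can be regenerated
    without drawing the first *r - 1*.
    """
    return np.random.default_rng(np.random.SeedSequence((seed, replicate)))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class HierarchicalParams:
    """Complete parameterization of the three-stage model.

    ``beta`` is (G, R) aligned to ``design.covariates`` columns; ``alpha`` is
    (G,); ``sigma2`` is (G, n_subjects); ``cell_size_factors`` holds one
    positive array of s_jc per subject, its length fixing that subject's cell
    count.
    """

    genes: list[str]
    design: SubjectDesign
    beta: np.ndarray
    alpha: np.ndarray
    sigma2: np.ndarray
    cell_size_factors: list[np.ndarray]

    def __post_init__(self) -> None:
        g = len(self.genes)
        n = self.design.n_subjects
        self.beta = np.atleast_2d(np.asarray(self.beta, float))
        self.alpha = np.asarray(self.alpha, float)
        self.sigma2 = np.atleast_2d(np.asarray(self.sigma2, float))
        if self.beta.shape != (g, self.design.covariates.shape[1]):
            raise ValidationError(f"beta must be (genes, R) = ({g}, {self.design.covariates.shape[1]})")
        if self.alpha.shape != (g,):
            raise ValidationError("alpha must be one value per gene")
        if self.sigma2.shape != (g, n):
            raise ValidationError(f"sigma2 must be (genes, subjects) = ({g}, {n})")
        if np.any(self.alpha < 0) or np.any(self.sigma2 < 0):
            raise ValidationError("variance parameters must be >= 0")
        if len(self.cell_size_factors) != n:
            raise ValidationError("one size-factor vector per subject required")
        for j, sjc in enumerate(self.cell_size_factors):
            self.cell_size_factors[j] = np.asarray(sjc, float)
            if np.any(self.cell_size_factors[j] <= 0):
                raise ValidationError(f"subject {self.design.subject_ids[j]}: size factors must be > 0")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def q(self) -> np.ndarray:
        """Mean expression q_ij = exp(sum_r x_jr beta_ir), shape (G, n)."""
        logq = self.beta @ self.design.covariates.T
        with np.errstate(over="ignore"):
            q = np.exp(logq)
        bad = ~np.isfinite(q).all(axis=1)
        if bad.any():
            names = [self.genes[i] for i in np.flatnonzero(bad)[:5]]
            raise ValidationError(f"non-finite q_ij for genes {names}")
        return q

    def with_effects(self, truth: "TruthTable", coef_index: int = 1) -> "HierarchicalParams":
        """Return params whose group coefficient column is truth.beta2."""
        beta = self.beta.copy()
        beta[:, coef_index] = truth.beta2
        return replace(self, beta=beta)


@dataclass
class TruthTable:
    """Per-gene differential-expression flag and group effect beta_i2."""

    genes: list[str]
    is_de: np.ndarray
    beta2: np.ndarray

    def __post_init__(self) -> None:
        self.is_de = np.asarray(self.is_de, bool)
        self.beta2 = np.asarray(self.beta2, float)
        if not (len(self.genes) == self.is_de.size == self.beta2.size):
            raise ValidationError("truth fields must align with genes")
        if np.any((self.beta2 != 0) != self.is_de):
            raise ValidationError("beta2 must be 0 exactly for non-DE genes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "is_de": self.is_de.astype(int), "beta2": self.beta2})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TruthTable":
        return cls(list(df["gene"].astype(str)), df["is_de"].to_numpy(bool), df["beta2"].to_numpy(float))


@dataclass
class SimulationConfig:
    """Study conditions for one simulation setting.

    Defaults follow the two-group design the model was studied under: groups
    of 4 and 3 subjects, 21 731 genes, and per-setting grids
    pDE in {0.01, 0.3, 0.6}, tau in {0.5, 1.0, 1.5} with 100 replicates.
    Cells per subject (200) and mean UMIs per cell (5000, log-normal with
    sigma 0.3) stand in for unpublished empirical vectors.
    """

    n_genes: int = DEFAULT_N_GENES
    group_sizes: tuple[int, int] = DEFAULT_GROUP_SIZES
    cells_per_subject: int = 200
    mean_umis: float = 5000.0
    umi_lognormal_sigma: float = 0.3
    p_de: float = 0.3
    tau: float = 1.0
    seed: int = 0
    n_replicates: int = DEFAULT_N_REPLICATES
    # baseline-parameter distributions (see docs/methods.md)
    log_expression_sigma: float = 2.0
    alpha_log_mean: float = float(np.log(0.1))
    alpha_log_sigma: float = 1.0
    sigma2_log_mean: float = 0.0
    sigma2_log_sigma: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.p_de <= 1:
            raise ValidationError("p_de must lie in [0, 1]")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")

    def to_flat_dict(self) -> dict:
        d = dict(self.__dict__)
        d["group_sizes"] = f"{self.group_sizes[0]},{self.group_sizes[1]}"
        return d

    @classmethod
    def from_flat_dict(cls, d: dict) -> "SimulationConfig":
        kw = dict(d)
        if "group_sizes" in kw and isinstance(kw["group_sizes"], str):
            a, b = kw["group_sizes"].split(",")
            kw["group_sizes"] = (int(a), int(b))
        fields_ = {f for f in cls.__dataclass_fields__}
        typed = {}
        for k, v in kw.items():
            if k not in fields_:
                raise ValidationError(f"unknown config key {k!r}")
            want = cls.__dataclass_fields__[k].type
            if k == "group_sizes":
                typed[k] = v
            elif want == "int":
                typed[k] = int(v)
            elif want == "float":
                typed[k] = float(v)
            else:
                typed[k] = v
        return cls(**typed)


# ---------------------------------------------------------------------------
# parameter generation
# ---------------------------------------------------------------------------

def sample_params(config: SimulationConfig, rng: np.random.Generator) -> HierarchicalParams:
    """Draw a realistic baseline parameterization for synthetic studies.

    Relative expression levels exp(beta_i1) are log-normal draws normalized to
    sum to 1 across genes (so q_ij is a composition, as in the moment-matched
    setting); alpha_i and sigma2_ij are log-normal with the configured
    location/spread; size factors s_jc are log-normal with the configured mean
    UMI count.
    """
    g = config.n_genes
    n1, n2 = config.group_sizes
    subjects = [f"S{k + 1}" for k in range(n1 + n2)]
    groups = ["group1"] * n1 + ["group2"] * n2
    design = SubjectDesign.from_groups(subjects, groups)

    w = rng.lognormal(mean=0.0, sigma=config.log_expression_sigma, size=g)
    beta1 = np.log(w / w.sum())
    beta = np.column_stack([beta1, np.zeros(g)])
    alpha = rng.lognormal(config.alpha_log_mean, config.alpha_log_sigma, size=g)
    sigma2 = rng.lognormal(config.sigma2_log_mean, config.sigma2_log_sigma, size=(g, n1 + n2))

    mu_log = np.log(config.mean_umis) - config.umi_lognormal_sigma**2 / 2
    sfs = [
        rng.lognormal(mu_log, config.umi_lognormal_sigma, size=config.cells_per_subject)
        for _ in subjects
    ]
    genes = [f"gene{k + 1}" for k in range(g)]
    return HierarchicalParams(genes, design, beta, alpha, sigma2, sfs)


def draw_effects(
    n_genes: int, p_de: float, tau: float, seed: int | np.random.Generator, genes: list[str] | None = None
) -> TruthTable:
    """Flag each gene DE with probability ``p_de``; flagged genes receive
    ``beta_i2 ~ Normal(0, tau^2)`` (natural-log fold change), others 0."""
    if not 0 <= p_de <= 1:
        raise ValidationError("p_de must lie in [0, 1]")
    if tau < 0:
        raise ValidationError("tau must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    is_de = rng.random(n_genes) < p_de
    beta2 = np.zeros(n_genes)
    draws = rng.normal(0.0, tau, size=int(is_de.sum()))
    # a DE gene drawn exactly at 0 would contradict the flag; nudge (prob ~0)
    draws[draws == 0.0] = np.finfo(float).tiny
    beta2[is_de] = draws
    if genes is None:
        genes = [f"gene{k + 1}" for k in range(n_genes)]
    return TruthTable(genes, is_de, beta2)


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def _gamma_or_mean(
    rng: np.random.Generator, mean: np.ndarray, cv2: np.ndarray, shape: tuple[int, ...] | None = None
) -> np.ndarray:
    """Independent gamma draws with given mean and squared CV, broadcast to
    ``shape``; entries with cv2 = 0 return the mean deterministically."""
    if shape is None:
        shape = np.broadcast_shapes(np.shape(mean), np.shape(cv2))
    out = np.array(np.broadcast_to(mean, shape), dtype=float)
    pos = np.broadcast_to(cv2 > 0, shape)
    if pos.any():
        cv2b = np.broadcast_to(cv2, shape)[pos]
        mb = np.broadcast_to(mean, shape)[pos]
        out[pos] = rng.gamma(shape=1.0 / cv2b, scale=mb * cv2b)
    return out


def simulate_counts(
    params: HierarchicalParams,
    truth: TruthTable | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[CellCounts, CellAnnotation, SubjectDesign]:
    """Draw a gene-by-cell count matrix from the three-stage model.

    When ``truth`` is given, its beta_i2 overwrites the group-coefficient
    column of ``params.beta`` first.  Degenerate stages (alpha_i = 0 or
    sigma2_ij = 0) contribute their mean deterministically.
    """
    if truth is not None:
        params = params.with_effects(truth)
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)

    q = params.q()  # (G, n)
    theta = _gamma_or_mean(rng, q, params.alpha[:, None])

    blocks: list[np.ndarray] = []
    cell_ids: list[str] = []
    rows = []
    for j, subj in enumerate(params.design.subject_ids):
        sjc = params.cell_size_factors[j]
        lam = _gamma_or_mean(rng, theta[:, [j]], params.sigma2[:, [j]], shape=(params.n_genes, sjc.size))
        k = rng.poisson(sjc[None, :] * lam)
        blocks.append(k)
        ids = [f"{subj}_c{c + 1}" for c in range(sjc.size)]
        cell_ids.extend(ids)
        rows.append(pd.DataFrame({"cell_id": ids, "subject_id": subj, "cell_type": "simulated", "size_factor": sjc}))

    counts = CellCounts(list(params.genes), cell_ids, np.concatenate(blocks, axis=1))
    annotation = CellAnnotation(pd.concat(rows, ignore_index=True))
    return counts, annotation, params.design


def simulate_dataset(
    config: SimulationConfig, replicate: int = 0
) -> tuple[CellCounts, CellAnnotation, SubjectDesign, TruthTable, HierarchicalParams]:
    """One replicate of a simulation setting, fully determined by
    (config.seed, replicate): baseline parameters, DE effects and counts."""
    rng = replicate_rng(config.seed, replicate)
    params = sample_params(config, rng)
    truth = draw_effects(config.n_genes, config.p_de, config.tau, rng, genes=params.genes)
    counts, annotation, design = simulate_counts(params, truth, rng)
    return counts, annotation, design, truth, params


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------

def theoretical_moments(params: HierarchicalParams, gene: int | str, subject: int | str) -> tuple[float, float]:
    """Exact mean and variance of the aggregated count K_ij = sum_c K_ijc.

    mean = s_j q_ij;
    variance = s_j^2 q_ij^2 alpha_i + sigma2_ij (1+alpha_i) q_ij^2 sum_c s_jc^2
               + s_j q_ij.
    With sigma2_ij = 0 this is the negative-binomial variance mu + alpha mu^2;
    with alpha_i = 0 as well, the Poisson identity variance = mean.
    """
    i = params.genes.index(gene) if isinstance(gene, str) else gene
    j = params.design.subject_ids.index(subject) if isinstance(subject, str) else subject
    q = params.q()[i, j]
    sjc = params.cell_size_factors[j]
    sj = sjc.sum()
    mean = sj * q
    var = (
        sj**2 * q**2 * params.alpha[i]
        + params.sigma2[i, j] * (1.0 + params.alpha[i]) * q**2 * np.sum(sjc**2)
        + sj * q
    )
    return float(mean), float(var)


@dataclass
class MomentEstimates:
    """Moment-matched parameters plus flags for genes floored at 0."""

    genes: list[str]
    subjects: list[str]
    alpha: np.ndarray  # (G,)
    sigma2: np.ndarray  # (G, n)
    exp_beta1: np.ndarray  # (G,)
    floored_alpha: np.ndarray = field(default=None)  # bool (G,)
    floored_sigma2: np.ndarray = field(default=None)  # bool (G, n)

    def to_params(
        self,
        design: SubjectDesign,
        cell_size_factors: list[np.ndarray],
        n_extra_coefs: int = 1,
    ) -> HierarchicalParams:
        """Promote to a full parameterization with zero effect coefficients."""
        beta = np.column_stack([np.log(np.where(self.exp_beta1 > 0, self.exp_beta1, np.finfo(float).tiny))]
                               + [np.zeros(len(self.genes))] * n_extra_coefs)
        return HierarchicalParams(list(self.genes), design, beta, self.alpha, self.sigma2, cell_size_factors)


def match_moments(cell_counts: CellCounts, annotation: CellAnnotation) -> MomentEstimates:
    """Match alpha_i, sigma2_ij and exp(beta_i1) to an empirical dataset.

    Normalized expressions: E_ijc = K_ijc / sum_i' K_i'jc per cell, and
    E_ij = sum_c K_ijc / sum_i' sum_c K_i'jc per subject.  With m_i, v_i the
    sample mean/variance of {E_ij} over subjects and m_ij, v_ij those of
    {E_ijc} over cells: alpha_i = v_i / m_i^2, sigma2_ij = v_ij / m_ij^2, and
    exp(beta_i1) = overall gene total / grand total.  Undefined or negative
    ratios are floored at 0 and flagged.
    """
    ann = annotation.aligned_to(cell_counts)
    subjects = ann.subject_ids
    if len(subjects) < 2:
        raise ValidationError("moment matching needs >= 2 subjects")
    K = cell_counts.counts.astype(float)
    subj_of = ann.table["subject_id"].to_numpy()

    g = cell_counts.n_genes
    n = len(subjects)
    E_subject = np.empty((g, n))
    sigma2 = np.zeros((g, n))
    floored_s = np.zeros((g, n), bool)
    for j, subj in enumerate(subjects):
        cols = np.flatnonzero(subj_of == subj)
        if cols.size < 2:
            raise ValidationError(f"subject {subj}: moment matching needs >= 2 cells")
        Kj = K[:, cols]
        cell_tot = Kj.sum(axis=0)
        if np.any(cell_tot == 0):
            Kj = Kj[:, cell_tot > 0]
            cell_tot = cell_tot[cell_tot > 0]
            if cell_tot.size < 2:
                raise ValidationError(f"subject {subj}: fewer than 2 non-empty cells")
        subj_tot = Kj.sum()
        if subj_tot == 0:
            raise ValidationError(f"subject {subj}: all-zero total count, normalization undefined")
        E_subject[:, j] = Kj.sum(axis=1) / subj_tot
        Ec = Kj / cell_tot[None, :]
        m_ij = Ec.mean(axis=1)
        v_ij = Ec.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            s2 = v_ij / m_ij**2
        bad = ~np.isfinite(s2) | (s2 < 0)
        s2[bad] = 0.0
        sigma2[:, j] = s2
        floored_s[:, j] = bad

    m_i = E_subject.mean(axis=1)
    v_i = E_subject.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = v_i / m_i**2
    floored_a = ~np.isfinite(alpha) | (alpha < 0)
    alpha[floored_a] = 0.0

    exp_beta1 = K.sum(axis=1) / K.sum()
    return MomentEstimates(list(cell_counts.genes), subjects, alpha, sigma2, exp_beta1, floored_a, floored_s)
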