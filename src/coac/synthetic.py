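"""Synthetic scRNA-seq matrices with planted, subpopulation-localized
co-expression modules.

The generator emulates the features of droplet scRNA-seq that matter for
localized co-expression inference: heavy dropout (a uniform Bernoulli zero
mask), log-normal-like expressed values, a rank-1 global nuisance factor
shared by all cells, and K disjoint gene modules that are co-expressed
only within a designated cell subpopulation and behave like background
noise everywhere else.

Correlation is planted on the latent (log) layer with a shared factor per
active cell, on top of the module's activation shift:

    L = mu + activation + sd * (sqrt(rho_L) * f_cell + sqrt(1 - rho_L) * eps),

where the latent correlation rho_L is solved so that the *value-scale*
(exp(L)) Pearson correlation hits the requested rho, inverting the
log-normal identity corr_X = (exp(rho_L sd^2) - 1) / (exp(sd^2) - 1).
Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix, Transform

__all__ = ["ModuleSpec", "SyntheticSpec", "GroundTruth", "generate", "generate_two_group"]


@dataclass(frozen=True)
class ModuleSpec:
    """One planted module: gene count, active-cell fraction, target
    within-module Pearson correlation (value scale, pre-dropout), and the
    activation shift.

    ``activation`` is the log-scale up-regulation of module genes in
    their active cells, emulating a cell-type expression program whose
    genes are expressed in the subpopulation running it and near-silent
    elsewhere.  It does not enter the within-active-cell correlation
    (a constant shift there); it is what localizes the module.
    """

    n_genes: int
    active_fraction: float
    rho: float
    activation: float = 4.0
    genes: tuple[int, ...] | None = None  # explicit gene indices (optional)

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("a module needs at least 2 genes")
        if not 0 < self.active_fraction <= 1:
            raise ValueError("active_fraction must be in (0, 1]")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")
        if self.activation < 0:
            raise ValueError("activation must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic matrix.

    Defaults describe the benchmark regime used throughout the test
    suite: 500 cells x 200 genes, three disjoint 20-gene modules each
    active in 30% of cells at rho = 0.8, with 60% dropout.
    """

    n_cells: int = 500
    n_genes: int = 200
    modules: tuple[ModuleSpec, ...] = (
        ModuleSpec(20, 0.3, 0.8, activation=3.5),
        ModuleSpec(20, 0.3, 0.8, activation=4.0),
        ModuleSpec(20, 0.3, 0.8, activation=4.5),
    )
    dropout_rate: float = 0.6
    dropout_steepness: float = 1.0
    noise_sd: float = 1.0
    global_factor_strength: float = 0.1
    mean_log: float = -2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        total = sum(m.n_genes for m in self.modules)
        if total > self.n_genes:
            raise ValueError(f"{total} module genes exceed {self.n_genes} genes")

    def module_gene_indices(self) -> list[np.ndarray]:
        """Disjoint gene-index blocks, explicit indices honoured."""
        blocks: list[np.ndarray] = []
        taken: set[int] = set()
        cursor = 0
        for mod in self.modules:
            if mod.genes is not None:
                idx = np.array(mod.genes, dtype=int)
                if len(idx) != mod.n_genes or idx.max() >= self.n_genes:
                    raise ValueError("explicit module gene indices invalid")
            else:
                idx = np.arange(cursor, cursor + mod.n_genes)
                cursor += mod.n_genes
            if taken & set(idx.tolist()):
                raise ValueError("module gene sets overlap")
            taken |= set(idx.tolist())
            blocks.append(idx)
        return blocks


@dataclass
class GroundTruth:
    """Planted structure: per-module gene/cell ids and per-cell labels."""

    module_genes: list[list[str]]
    module_cells: list[list[str]]
    cell_labels: dict[str, str] = field(default_factory=dict)


def _latent_rho(rho: float, sd: float) -> float:
    """Latent (log-layer) correlation giving value-scale correlation rho."""
    if rho >= 1.0:
        return 1.0
    s2 = sd**2
    return float(np.log1p(rho * np.expm1(s2)) / s2)


def _log_layer(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Latent log-expression plus module gene/cell index blocks."""
    L = spec.mean_log + spec.noise_sd * rng.standard_normal(
        (spec.n_cells, spec.n_genes)
    )
    if spec.global_factor_strength > 0:
        g = rng.standard_normal(spec.n_cells)
        h = rng.standard_normal(spec.n_genes)
        L += spec.global_factor_strength * np.outer(g, h)
    gene_blocks = spec.module_gene_indices()
    cell_blocks = []
    for mod, genes in zip(spec.modules, gene_blocks):
        n_active = max(1, int(round(mod.active_fraction * spec.n_cells)))
        active = np.sort(rng.choice(spec.n_cells, size=n_active, replace=False))
        cell_blocks.append(active)
        rho_l = _latent_rho(mod.rho, spec.noise_sd)
        f = rng.standard_normal(n_active)
        eps = rng.standard_normal((n_active, len(genes)))
        block = spec.mean_log + mod.activation + spec.noise_sd * (
            np.sqrt(rho_l) * f[:, None] + np.sqrt(1.0 - rho_l) * eps
        )
        L[np.ix_(active, genes)] = block
    return L, gene_blocks, cell_blocks


def _dropout_probabilities(X: np.ndarray, rate: float, steepness: float) -> np.ndarray:
    """Per-entry dropout probabilities, logistic in log expression.

    ``p = sigmoid(a - steepness * log1p(x))`` with the intercept ``a``
    calibrated (bisection) so the mean probability equals ``rate``; lowly
    expressed entries drop out more, as in real droplet data.  Steepness 0
    recovers uniform Bernoulli dropout.
    """
    u = np.log1p(X)

    def mean_p(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a - steepness * u)))))

    lo, hi = -60.0, 60.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < rate:
            lo = mid
        else:
            hi = mid
    a = 0.5 * (lo + hi)
    return 1.0 / (1.0 + np.exp(-(a - steepness * u)))


def _finalize(
    spec: SyntheticSpec, L: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    X = np.exp(L)
    if spec.dropout_rate > 0:
        p = _dropout_probabilities(X, spec.dropout_rate, spec.dropout_steepness)
        mask = rng.random(X.shape) >= p
        X = X * mask
    return X


def _truth(
    spec: SyntheticSpec,
    gene_blocks: list[np.ndarray],
    cell_blocks: list[np.ndarray],
    gene_ids: list[str],
    cell_ids: list[str],
) -> GroundTruth:
    labels = {}
    for c, cid in enumerate(cell_ids):
        active_in = [
            str(k) for k, cells in enumerate(cell_blocks) if c in set(cells.tolist())
        ]
        labels[cid] = "module_" + "+".join(active_in) if active_in else "background"
    return GroundTruth(
        module_genes=[[gene_ids[g] for g in blk] for blk in gene_blocks],
        module_cells=[[cell_ids[c] for c in blk] for blk in cell_blocks],
        cell_labels=labels,
    )


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """One synthetic expression matrix with its planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    L, gene_blocks, cell_blocks = _log_layer(spec, rng)
    X = _finalize(spec, L, rng)
    gene_ids = [f"gene_{i:04d}" for i in range(spec.n_genes)]
    cell_ids = [f"cell_{i:05d}" for i in range(spec.n_cells)]
    m = ExpressionMatrix(X, gene_ids=gene_ids, cell_ids=cell_ids, transform=Transform.RAW)
    return m, _truth(spec, gene_blocks, cell_blocks, gene_ids, cell_ids)


def generate_two_group(
    spec: SyntheticSpec, perturbed_module: int
) -> tuple[ExpressionMatrix, dict[str, str], GroundTruth]:
    """Matched control/case cell groups; in the case group the designated
    module's co-expression is abolished.

    Each case-group gene of the perturbed module has its latent values
    independently shuffled across the module's active cells, which
    destroys the shared factor (and hence the correlation) while leaving
    every per-gene marginal exactly as generated.
    """
    if not 0 <= perturbed_module < len(spec.modules):
        raise ValueError(f"no module {perturbed_module}")
    rng = np.random.default_rng(spec.seed)
    L_ctrl, gene_blocks, cell_blocks_ctrl = _log_layer(spec, rng)
    X_ctrl = _finalize(spec, L_ctrl, rng)
    L_case, gene_blocks_case, cell_blocks_case = _log_layer(spec, rng)
    active = cell_blocks_case[perturbed_module]
    for g in gene_blocks_case[perturbed_module]:
        L_case[active, g] = L_case[rng.permutation(active), g]
    X_case = _finalize(spec, L_case, rng)

    gene_ids = [f"gene_{i:04d}" for i in range(spec.n_genes)]
    ctrl_ids = [f"ctrl_{i:05d}" for i in range(spec.n_cells)]
    case_ids = [f"case_{i:05d}" for i in range(spec.n_cells)]
    X = np.vstack([X_ctrl, X_case])
    m = ExpressionMatrix(
        X, gene_ids=gene_ids, cell_ids=ctrl_ids + case_ids, transform=Transform.RAW
    )
    labels = {c: "control" for c in ctrl_ids} | {c: "case" for c in case_ids}
    truth = GroundTruth(
        module_genes=[[gene_ids[g] for g in blk] for blk in gene_blocks],
        module_cells=[
            [ctrl_ids[c] for c in blk_c] + [case_ids[c] for c in blk_k]
            for blk_c, blk_k in zip(cell_blocks_ctrl, cell_blocks_case)
        ],
        cell_labels=labels,
    )
    return m, labels, truth
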