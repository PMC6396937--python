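"""Matrix factorization, robust rank, gene projections, and ternarization.

The expression matrix ``A`` (cells x genes) is factored as ``A = U S V*``.
A gene's profile across cells is a linear combination of the left singular
vectors (components) ``P_j = U[:, j]``:

    A[:, i] = sum_j w_ij P_j,   w_ij = sigma_j V[i, j].

The projection of gene ``i`` onto component ``j`` is the cosine
``D(i, j) = w_ij / ||A[:, i]||``, in [-1, 1].  For each component the bulk
of projections behaves like noise around its mean; genes in the tails are
the ones the component actually organizes.  They are marked by an
F-distribution outlier rule: the statistic ``(x - m)^2 / s^2`` of a
projection ``x`` against the component's mean ``m`` and variance ``s^2``
is referred to F(1, N-1) (N genes), and projections whose upper-tail
p-value falls below ``alpha`` become +1 (Gain, upper tail) or -1 (Loss,
lower tail); everything else is 0 (Non-effect).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg
from scipy import stats

from .matrix import ExpressionMatrix

__all__ = [
    "Decomposition",
    "ProjectionMatrix",
    "ComponentThresholds",
    "TernaryMatrix",
    "compute_svd",
    "estimate_robust_rank",
    "projection_matrix",
    "component_thresholds",
    "ternary_map",
]

RANK_METHODS = ("permutation", "energy", "elbow")


@dataclass
class Decomposition:
    """Top-k singular triplets of a cells x genes matrix.

    ``U`` is cells x k (components as columns), ``sigma`` nonincreasing,
    ``V`` genes x k.  ``rank_r`` is the retained (robust) rank, set by
    :func:`estimate_robust_rank` or explicitly.
    """

    U: np.ndarray
    sigma: np.ndarray
    V: np.ndarray
    rank_r: int | None = None
    centered: bool = False
    col_norms: np.ndarray | None = None  # gene norms of the factored matrix

    def __post_init__(self) -> None:
        if np.any(np.diff(self.sigma) > 1e-12):
            raise ValueError("singular values must be nonincreasing")

    @property
    def k(self) -> int:
        return len(self.sigma)

    def weights(self) -> np.ndarray:
        """Genes x k matrix of component weights w_ij = sigma_j V(i,j)."""
        return self.V * self.sigma[np.newaxis, :]


@dataclass
class ProjectionMatrix:
    """Genes x rank_r matrix of normalized loadings D(i,j) in [-1, 1]."""

    D: np.ndarray
    gene_ids: list[str]
    zero_genes: np.ndarray  # boolean mask: genes with zero expression norm

    def __post_init__(self) -> None:
        if self.D.shape[0] != len(self.gene_ids):
            raise ValueError("row count must match gene_ids")


@dataclass
class ComponentThresholds:
    """Per-component ternarization cutoffs from the F(1, N-1) outlier rule.

    ``threshold_pos[j] = m_j + sqrt(s2_j * F_crit)`` and
    ``threshold_neg[j] = m_j - sqrt(s2_j * F_crit)`` where ``F_crit`` is the
    (1 - alpha) quantile of F(1, N-1).  Inert components (zero variance)
    get infinite thresholds so no gene is ever marked.
    """

    threshold_pos: np.ndarray
    threshold_neg: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    alpha: float
    n_genes: int
    inert: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.inert is None:
            self.inert = np.zeros(len(self.mean), dtype=bool)
        if np.any(self.threshold_neg >= self.threshold_pos):
            raise ValueError("negative threshold must lie below positive")


@dataclass
class TernaryMatrix:
    """Components x genes matrix with entries in {-1, 0, +1} (sparse)."""

    M: sp.spmatrix
    gene_ids: list[str]
    alpha: float

    @property
    def presence(self) -> sp.csr_matrix:
        """|M| collapsed to 0/1 — the mining substrate."""
        p = sp.csr_matrix(abs(self.M))
        p.data = np.ones_like(p.data)
        return p


def compute_svd(
    m: ExpressionMatrix, k: int, center: bool = False, seed: int = 0
) -> Decomposition:
    """Top-k SVD of the (optionally column-centered) expression matrix.

    Dense matrices, or k equal to the full rank, use LAPACK; large sparse
    matrices use ARPACK (``svds``) with a deterministic start vector
    derived from ``seed``.
    """
    n_cells, n_genes = m.values.shape
    if not 1 <= k <= min(n_cells, n_genes):
        raise ValueError(f"k={k} must be in [1, {min(n_cells, n_genes)}]")
    use_dense = (not sp.issparse(m.values)) or center or k >= min(n_cells, n_genes) - 1
    if use_dense:
        a = m.dense()
        if center:
            a = a - a.mean(axis=0, keepdims=True)
        norms = np.linalg.norm(a, axis=0)
        U, s, Vt = np.linalg.svd(a, full_matrices=False)
        return Decomposition(
            U[:, :k], s[:k], Vt[:k].T, centered=center, col_norms=norms
        )
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(m.values.shape))
    try:
        U, s, Vt = scipy.sparse.linalg.svds(
            m.values.astype(float), k=k, v0=v0, maxiter=5000
        )
    except scipy.sparse.linalg.ArpackNoConvergence as exc:
        raise RuntimeError(
            "sparse SVD did not converge; retry with a smaller k or "
            "densify the matrix"
        ) from exc
    order = np.argsort(s)[::-1]
    norms = np.sqrt(np.asarray(m.values.multiply(m.values).sum(axis=0)).ravel())
    return Decomposition(
        U[:, order], s[order], Vt[order].T, centered=False, col_norms=norms
    )


def _column_null_shuffle(col: np.ndarray, master_seed: int, perm_index: int) -> np.ndarray:
    # Seed from the sorted column values so the null matrix is invariant to
    # row and column permutations of the input at a fixed master seed.
    sorted_col = np.sort(col)
    h = hashlib.blake2b(sorted_col.tobytes(), digest_size=8)
    h.update(master_seed.to_bytes(8, "little", signed=True))
    h.update(perm_index.to_bytes(4, "little"))
    rng = np.random.default_rng(int.from_bytes(h.digest(), "little"))
    return rng.permutation(sorted_col)


def estimate_robust_rank(
    d: Decomposition,
    m: ExpressionMatrix,
    method: str = "permutation",
    n_perm: int = 10,
    seed: int = 0,
    energy_fraction: float = 0.9,
    quantile: float = 1.0,
    comparison: str = "max",
) -> int:
    """Number of components to retain as signal above the noise floor.

    permutation (default)
        Independently shuffle each gene column and compare the observed
        spectrum against the shuffled one, aggregated over ``n_perm``
        replicates at ``quantile`` (1.0 = max).  With
        ``comparison="max"`` r counts singular values above the largest
        shuffled singular value — a conservative floor that retains all
        structure implied by the column marginals (for nonnegative data
        the shared positive mean alone reaches the top shuffled value, so
        this variant rarely certifies more than the leading component).
        ``comparison="per_rank"`` is parallel analysis: r is the longest
        prefix with sigma_j above the j-th shuffled singular value.
    energy
        Smallest r whose cumulative squared singular values reach
        ``energy_fraction`` of the total.
    elbow
        Position of the largest relative gap in the singular spectrum.

    Always clipped to [1, k]; a constant (zero-variance) matrix is
    rejected.
    """
    if method not in RANK_METHODS:
        raise ValueError(f"method must be one of {RANK_METHODS}")
    dense = m.dense()
    if np.allclose(dense, dense.flat[0]):
        raise ValueError("constant matrix has no signal rank")
    sigma = d.sigma
    if method == "energy":
        if not 0 < energy_fraction <= 1:
            raise ValueError("energy_fraction must be in (0, 1]")
        frac = np.cumsum(sigma**2) / np.sum(sigma**2)
        r = int(np.searchsorted(frac, energy_fraction - 1e-12) + 1)
    elif method == "elbow":
        if d.k == 1:
            return 1
        safe = np.where(sigma[:-1] > 0, sigma[:-1], 1.0)
        gaps = (sigma[:-1] - sigma[1:]) / safe
        r = int(np.argmax(gaps) + 1)
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if comparison not in ("max", "per_rank"):
            raise ValueError("comparison must be 'max' or 'per_rank'")
        null_spectra = np.empty((n_perm, d.k))
        for t in range(n_perm):
            shuffled = np.column_stack(
                [_column_null_shuffle(dense[:, i], seed, t) for i in range(dense.shape[1])]
            )
            null_spectra[t] = np.linalg.svd(shuffled, compute_uv=False)[: d.k]
        if comparison == "max":
            floor = np.quantile(null_spectra[:, 0], quantile)
            r = int(np.sum(sigma > floor))
        else:
            floors = np.quantile(null_spectra, quantile, axis=0)
            above = sigma > floors
            r = int(np.argmin(above)) if not above.all() else d.k
    return int(np.clip(r, 1, d.k))


def projection_matrix(d: Decomposition, m: ExpressionMatrix) -> ProjectionMatrix:
    """Normalized gene loadings on the retained components.

    Row i is gene i's cosine against each retained component:
    ``w_ij / ||A[:, i]||``, with the gene norm taken from the actual
    expression column (so rows have norm <= 1 under truncation).
    Zero-expression genes get an all-zero row and are flagged.
    """
    if d.rank_r is None or d.rank_r < 1:
        raise ValueError("decomposition has no retained rank; set rank_r first")
    r = d.rank_r
    w = d.weights()[:, :r]
    if d.col_norms is not None:
        norms = np.asarray(d.col_norms, dtype=float)
    elif sp.issparse(m.values):
        norms = np.sqrt(np.asarray(m.values.multiply(m.values).sum(axis=0)).ravel())
    else:
        norms = np.linalg.norm(m.dense(), axis=0)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    D = w / safe[:, np.newaxis]
    D[zero] = 0.0
    D = np.clip(D, -1.0, 1.0)
    return ProjectionMatrix(D=D, gene_ids=list(m.gene_ids), zero_genes=zero)


def component_thresholds(
    p: ProjectionMatrix,
    alpha: float = 0.05,
    strict_alpha_bounds: bool = True,
) -> ComponentThresholds:
    """Closed-form per-component outlier cutoffs at p-value ``alpha``.

    A projection x is extreme for component j when
    ``(x - m_j)^2 / s2_j > F_crit(1 - alpha; 1, N - 1)``, i.e. beyond
    ``m_j +/- sqrt(s2_j * F_crit)``.  Degenerate (zero-norm) genes are
    excluded from the collection and from N.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if strict_alpha_bounds and not 0.01 <= alpha <= 0.05:
        raise ValueError(
            f"alpha={alpha} outside the allowed [0.01, 0.05] range "
            "(pass strict_alpha_bounds=False to override)"
        )
    rows = p.D[~p.zero_genes]
    n = rows.shape[0]
    if n < 3:
        raise ValueError("need at least 3 non-degenerate genes")
    mean = rows.mean(axis=0)
    var = rows.var(axis=0, ddof=1)
    # loadings live in [-1,1]; anything this small is numerically constant
    inert = var <= 1e-24
    f_crit = stats.f.ppf(1.0 - alpha, 1, n - 1)
    half = np.sqrt(np.where(inert, np.inf, var) * f_crit)
    return ComponentThresholds(
        threshold_pos=mean + half,
        threshold_neg=mean - half,
        mean=mean,
        variance=var,
        alpha=alpha,
        n_genes=n,
        inert=inert,
    )


def ternary_map(p: ProjectionMatrix, t: ComponentThresholds) -> TernaryMatrix:
    """Map projections to {-1, 0, +1} per component (strict inequalities).

    Output rows are components, columns are genes; a projection exactly at
    a threshold maps to 0.
    """
    if p.D.shape[1] != len(t.mean):
        raise ValueError("thresholds were computed for a different projection")
    gain = p.D > t.threshold_pos[np.newaxis, :]
    loss = p.D < t.threshold_neg[np.newaxis, :]
    m = gain.astype(np.int8) - loss.astype(np.int8)
    return TernaryMatrix(
        M=sp.csr_matrix(m.T), gene_ids=list(p.gene_ids), alpha=t.alpha
    )
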