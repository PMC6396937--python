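"""Eigenvector features, F-score selection, and sample stratification.

A subnetwork is summarized by the eigensystem of its gene-gene Pearson
correlation matrix (an eigengene-style representation).  A cell's or bulk
sample's expression over the subnetwork genes, S, is scored as

    feature = sum_t (sigma_t / sigma_1) * (S . F_t) / ||S||_2,

where F_t are the retained unit eigenvectors and the ratios
sigma_t/sigma_1 <= 1 are attenuation coefficients (the leading term has
coefficient 1).  With a single eigenvector this is a cosine in [-1, 1] and
is invariant to positive rescaling of S, which is what makes the score
comparable across cells with different library sizes and across
single-cell and bulk profiles.

Features are ranked for case/control separation by an F-score; the
default form is the classic one-way ANOVA F statistic (between-group
mean square over within-group mean square), with bounded
between-over-merged and variance-difference variants available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .mining import Subnetwork

__all__ = [
    "SubnetworkEigensystem",
    "FeatureScore",
    "subnetwork_eigensystem",
    "feature_value",
    "feature_matrix",
    "f_score",
    "select_features",
    "rank_by_group_difference",
    "stratify_samples",
    "label_drug_response",
]


@dataclass
class SubnetworkEigensystem:
    """Retained eigenpairs of a subnetwork's gene correlation matrix.

    Eigenvalues are nonincreasing; eigenvectors are unit columns of
    ``eigenvectors`` with the sign fixed so each one's largest-magnitude
    loading is positive.
    """

    gene_ids: tuple[str, ...]
    eigenvalues: np.ndarray  # length v, nonincreasing
    eigenvectors: np.ndarray  # genes x v
    name: str = ""

    @property
    def v(self) -> int:
        return len(self.eigenvalues)


@dataclass
class FeatureScore:
    feature: str
    f_score: float
    kept: bool


def subnetwork_eigensystem(
    s: Subnetwork,
    training: ExpressionMatrix,
    v: int | str = "auto",
    name: str = "",
) -> SubnetworkEigensystem:
    """Eigendecomposition of the giant-component genes' correlation matrix.

    Correlations use the genes' full training profiles.  ``v="auto"``
    keeps all eigenvalues >= 1 (at least one); an integer keeps exactly
    that many leading eigenpairs.
    """
    genes = s.giant_genes
    if len(genes) < 2:
        raise ValueError("eigensystem needs at least 2 genes")
    idx = training.gene_index(list(genes))
    profiles = training.dense()[:, idx]
    sd = profiles.std(axis=0)
    if np.any(sd == 0):
        bad = [g for g, s_ in zip(genes, sd) if s_ == 0]
        raise ValueError(f"constant gene(s) in training data: {bad}")
    corr = np.corrcoef(profiles, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    if v == "auto":
        keep = max(1, int(np.sum(evals >= 1.0)))
    else:
        keep = int(v)
        if not 1 <= keep <= len(evals):
            raise ValueError(f"v={v} out of range [1, {len(evals)}]")
    evals, evecs = evals[:keep], evecs[:, :keep]
    # sign convention: largest-magnitude loading positive
    for t in range(keep):
        col = evecs[:, t]
        if col[np.argmax(np.abs(col))] < 0:
            evecs[:, t] = -col
    return SubnetworkEigensystem(
        gene_ids=tuple(genes), eigenvalues=evals, eigenvectors=evecs, name=name
    )


def feature_value(S: np.ndarray, e: SubnetworkEigensystem) -> float:
    """Score one expression vector (aligned to ``e.gene_ids``) against the
    eigensystem; a zero vector scores 0 by convention."""
    S = np.asarray(S, dtype=float)
    if S.shape != (len(e.gene_ids),):
        raise ValueError(
            f"expression vector has length {S.shape}, expected {len(e.gene_ids)}"
        )
    norm = np.linalg.norm(S)
    if norm == 0:
        return 0.0
    atten = e.eigenvalues / e.eigenvalues[0] if e.eigenvalues[0] > 0 else np.ones(e.v)
    return float(np.sum(atten * (S @ e.eigenvectors)) / norm)


def feature_matrix(
    m: ExpressionMatrix,
    eigensystems: list[SubnetworkEigensystem],
    missing: str = "skip",
) -> pd.DataFrame:
    """Samples x features table of feature values.

    Works identically for single-cell and bulk matrices.  Eigensystems
    whose genes are absent from ``m`` are skipped with a warning
    (``missing="skip"``) or scored with the absent genes zero-filled
    (``missing="zero"``).
    """
    if not eigensystems:
        raise ValueError("no eigensystems given")
    dense = m.dense()
    lookup = {g: i for i, g in enumerate(m.gene_ids)}
    cols: dict[str, np.ndarray] = {}
    for n, e in enumerate(eigensystems):
        fname = e.name or f"subnetwork_{n}"
        absent = [g for g in e.gene_ids if g not in lookup]
        if absent:
            if missing == "skip":
                warnings.warn(
                    f"feature {fname}: genes {absent[:3]} missing; skipped",
                    stacklevel=2,
                )
                continue
            sub = np.zeros((m.n_cells, len(e.gene_ids)))
            present = [i for i, g in enumerate(e.gene_ids) if g in lookup]
            sub[:, present] = dense[:, [lookup[e.gene_ids[i]] for i in present]]
        else:
            sub = dense[:, [lookup[g] for g in e.gene_ids]]
        norms = np.linalg.norm(sub, axis=1)
        safe = np.where(norms == 0, 1.0, norms)
        atten = (
            e.eigenvalues / e.eigenvalues[0]
            if e.eigenvalues[0] > 0
            else np.ones(e.v)
        )
        cols[fname] = (sub @ e.eigenvectors) @ atten / safe
    if not cols:
        raise ValueError("every eigensystem was skipped (missing genes)")
    return pd.DataFrame(cols, index=list(m.cell_ids))


def _two_groups(
    values: pd.Series | np.ndarray, labels: dict[str, str], index=None
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(values, pd.Series):
        index = values.index
        values = values.to_numpy(dtype=float)
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    a = np.array([v for v, i in zip(values, index) if labels.get(i) == groups[0]])
    b = np.array([v for v, i in zip(values, index) if labels.get(i) == groups[1]])
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    return a, b


def f_score(values: pd.Series, labels: dict[str, str], mode: str = "anova") -> float:
    """Discriminative score of one feature between two cell groups.

    mode="anova" (default)
        Classic one-way F statistic: between-group mean square over
        within-group mean square.  Unbounded; under the null it follows
        F(1, n-2), which makes a fixed critical point such as 2.4
        meaningful.
    mode="ratio"
        Between-group variance (n-weighted, around the grand mean) over
        the population variance of the merged values.  Bounded by 1.
    mode="var_diff"
        Absolute difference of the two group variances over the merged
        population variance.

    All modes are invariant to shifting all values by a constant and to
    scaling them by a nonzero constant.
    """
    if mode not in ("anova", "ratio", "var_diff"):
        raise ValueError("mode must be 'anova', 'ratio' or 'var_diff'")
    a, b = _two_groups(values, labels)
    merged = np.concatenate([a, b])
    m = merged.mean()
    background = merged.var()
    if background == 0:
        raise ValueError("zero background variance: feature is constant")
    if mode == "ratio":
        differential = (
            len(a) * (a.mean() - m) ** 2 + len(b) * (b.mean() - m) ** 2
        ) / len(merged)
        return float(differential / background)
    if mode == "var_diff":
        return float(abs(a.var() - b.var()) / background)
    msb = len(a) * (a.mean() - m) ** 2 + len(b) * (b.mean() - m) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    n = len(merged)
    if ssw == 0:
        return float("inf") if msb > 0 else 0.0
    return float(msb / (ssw / (n - 2)))


def select_features(
    fm: pd.DataFrame,
    labels: dict[str, str],
    threshold: float = 2.4,
    mode: str = "anova",
) -> list[FeatureScore]:
    """Score every feature column and mark those with F-score strictly
    above ``threshold``; ordered by descending score, ties by name."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    scores = []
    for col in fm.columns:
        try:
            fs = f_score(fm[col], labels, mode=mode)
        except ValueError:
            fs = 0.0
        scores.append(FeatureScore(feature=col, f_score=fs, kept=fs > threshold))
    scores.sort(key=lambda s: (-s.f_score, s.feature))
    return scores


def rank_by_group_difference(
    fm: pd.DataFrame, labels: dict[str, str], combine: str = "product"
) -> list[str]:
    """Order features by between-group |mean difference| and |variance
    difference|, combined by rank product (default) or rank sum; the
    strongest feature comes first."""
    if combine not in ("product", "sum"):
        raise ValueError("combine must be 'product' or 'sum'")
    d_mean, d_var = {}, {}
    for col in fm.columns:
        a, b = _two_groups(fm[col], labels)
        d_mean[col] = abs(a.mean() - b.mean())
        d_var[col] = abs(a.var() - b.var())
    cols = list(fm.columns)
    # rank 1 = largest difference; ties share the better (smaller) rank
    mean_rank = pd.Series(d_mean).rank(ascending=False, method="min")
    var_rank = pd.Series(d_var).rank(ascending=False, method="min")
    if combine == "product":
        score = mean_rank * var_rank
    else:
        score = mean_rank + var_rank
    return sorted(cols, key=lambda c: (score[c], c))


def stratify_samples(
    values: pd.Series, k: int = 32
) -> tuple[list[str], list[str]]:
    """Top-k and bottom-k sample ids by feature value (ties by id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(values)
    if 2 * k > n:
        raise ValueError(f"2k={2 * k} exceeds the {n} available samples")
    order = sorted(values.index, key=lambda i: (-values[i], i))
    return list(order[:k]), list(order[-k:])


def label_drug_response(
    ic50: pd.Series, cutoff: float = 10.0
) -> pd.Series:
    """Binary resistant/sensitive labels from IC50 values in uM.

    Resistant iff IC50 strictly exceeds the cutoff (default 10 uM).
    """
    vals = ic50.astype(float)
    if (vals <= 0).any():
        raise ValueError("IC50 values must be positive")
    return pd.Series(
        np.where(vals > cutoff, "resistant", "sensitive"), index=ic50.index
    )
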