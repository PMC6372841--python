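"""Distance, ordination and permutation statistics.

Self-contained implementations of the statistics layer used to compare
the two omic layers as whole communities: Bray-Curtis dissimilarity,
classical principal-coordinate analysis (PCoA), Procrustes
superimposition, the Mantel test, distance-based PERMANOVA (pseudo-F)
and the Friedman rank test.  Permutation p-values use the
``(1 + count) / (n_perm + 1)`` estimator; all randomness flows through an
explicit seed so results are bitwise reproducible.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import FeatureTable

DEFAULT_N_PERM = 999


class OrdinationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with zero diagonal."""

    ids: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.data = np.asarray(self.data, float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise OrdinationError(
                f"matrix shape {self.data.shape} does not match {n} ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise OrdinationError("distance matrix is not symmetric")
        if np.any(np.diag(self.data) != 0):
            raise OrdinationError("distance matrix diagonal must be zero")
        if (self.data < 0).any():
            raise OrdinationError("distances must be nonnegative")

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) entries, row-major."""
        iu = np.triu_indices(len(self), k=1)
        return self.data[iu]

    def write_tsv(self, path) -> None:
        out = pd.DataFrame(self.data, index=self.ids, columns=self.ids)
        out.index.name = "sample"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(df.index), df.to_numpy(float))


@dataclass
class OrdinationResult:
    """PCoA coordinates with eigenvalues and variance explained."""

    ids: tuple[str, ...]
    coordinates: np.ndarray          # samples x positive axes
    eigenvalues: np.ndarray          # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues

    def write_tsv(self, path) -> None:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        out = pd.DataFrame(self.coordinates, index=self.ids, columns=cols)
        out.index.name = "sample"
        out.to_csv(path, sep="\t")


@dataclass
class PermutationTestResult:
    """Outcome of a permutation (or asymptotic rank) test."""

    method: str
    statistic: float
    p_value: float
    n_perm: int | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"method": self.method, "statistic": self.statistic,
               "p_value": self.p_value, "n_perm": self.n_perm,
               "seed": self.seed}
        out.update(self.extras)
        return out


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    ``d(i, j) = 1 - 2 * sum(min(x_i, x_j)) / (sum(x_i) + sum(x_j))``.
    Missing cells are disallowed (use complete-case tables); a pair of
    all-zero samples has undefined dissimilarity and raises.
    """
    if table.n_missing:
        raise OrdinationError(
            "table has missing cells; apply filter_complete_features first")
    X = table.values.to_numpy(float).T  # samples x features
    sums = X.sum(axis=1)
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = sums[i] + sums[j]
            if denom == 0:
                raise OrdinationError(
                    f"samples {table.sample_ids[i]!r} and "
                    f"{table.sample_ids[j]!r} are both all-zero")
            d[i, j] = d[j, i] = 1.0 - 2.0 * np.minimum(X[i], X[j]).sum() / denom
    return DistanceMatrix(tuple(table.sample_ids), d)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical metric scaling of a distance matrix.

    Double-centers ``-0.5 * D**2``, eigendecomposes, and keeps the
    positive-eigenvalue axes scaled by the square root of their
    eigenvalue.  Negative eigenvalues (non-Euclidean input) are reported
    unchanged, without Lingoes/Cailliez correction.
    """
    n = len(dm)
    d2 = dm.data ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigval[0]), 1.0))
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pos_sum = eigval[pos].sum()
    prop = eigval[pos] / pos_sum if pos_sum > 0 else eigval[pos]
    if not pos.any():
        coords = np.zeros((n, 1))
        prop = np.zeros(1)
    return OrdinationResult(dm.ids, coords, eigval, prop)


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------


def procrustes(X: np.ndarray, Y: np.ndarray
               ) -> tuple[float, np.ndarray]:
    """Optimal superimposition of configuration Y onto X.

    Both configurations (rows = corresponding samples) are centered and
    scaled to unit trace (Frobenius norm 1); Y is then optimally rotated/
    reflected and scaled onto X.  Returns ``(M2, aligned_Y)`` where
    ``M2 = sum of squared residuals`` lies in ``[0, 1]``.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape[0] != Y.shape[0]:
        raise OrdinationError("configurations must have equal sample counts")
    k = max(X.shape[1], Y.shape[1])
    X = np.pad(X, ((0, 0), (0, k - X.shape[1])))
    Y = np.pad(Y, ((0, 0), (0, k - Y.shape[1])))
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    nx, ny = np.linalg.norm(X), np.linalg.norm(Y)
    if nx == 0 or ny == 0:
        raise OrdinationError("degenerate (zero-variance) configuration")
    X, Y = X / nx, Y / ny
    U, s, Vt = np.linalg.svd(Y.T @ X)
    R = U @ Vt
    scale = s.sum()
    aligned = scale * (Y @ R)
    m2 = float(((X - aligned) ** 2).sum())
    return m2, aligned


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------


def _permutations(n: int, n_perm: int | None, seed: int | None):
    """Yield permutation index arrays; ``n_perm=None`` = exhaustive."""
    if n_perm is None:
        for p in itertools.permutations(range(n)):
            yield np.array(p)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            yield rng.permutation(n)


def mantel(d1: DistanceMatrix, d2: DistanceMatrix,
           n_perm: int | None = DEFAULT_N_PERM,
           seed: int | None = 0) -> PermutationTestResult:
    """Mantel test: Pearson correlation of two distance matrices.

    Rows/columns of ``d2`` are permuted jointly; the one-sided p-value
    counts permuted correlations at least as large as the observed one.
    ``n_perm=None`` enumerates all permutations (small n only), and the
    p-value is then the exact fraction over all relabelings.
    """
    if d1.ids != d2.ids:
        raise OrdinationError("distance matrices must share sample ids/order")
    n = len(d1)
    if n < 4:
        raise OrdinationError("Mantel test needs at least 4 samples")
    x = d1.condensed()
    iu = np.triu_indices(n, k=1)

    def corr(mat: np.ndarray) -> float:
        y = mat[iu]
        return float(np.corrcoef(x, y)[0, 1])

    observed = corr(d2.data)
    count = 0
    total = 0
    for perm in _permutations(n, n_perm, seed):
        total += 1
        if corr(d2.data[np.ix_(perm, perm)]) >= observed - 1e-12:
            count += 1
    if n_perm is None:
        p = count / total
    else:
        p = (1 + count) / (n_perm + 1)
    return PermutationTestResult("mantel", observed, p,
                                 n_perm if n_perm is not None else total, seed)


def permanova(dm: DistanceMatrix, grouping: dict[str, str] | pd.Series,
              n_perm: int | None = DEFAULT_N_PERM,
              seed: int | None = 0) -> PermutationTestResult:
    """Distance-based PERMANOVA pseudo-F with a permutation p-value.

    ``pseudo-F = (SS_among / (a - 1)) / (SS_within / (n - a))`` from sums
    of squared distances; group labels are permuted.  Requires at least
    two groups with two samples each.  ``n_perm=None`` enumerates all
    label permutations exactly.
    """
    if isinstance(grouping, pd.Series):
        grouping = dict(grouping)
    labels = np.array([grouping[s] for s in dm.ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise OrdinationError("PERMANOVA needs at least two groups")
    if counts.min() < 2:
        small = uniq[counts < 2]
        raise OrdinationError(f"singleton group(s): {list(small)}")
    n = len(dm)
    a = len(uniq)
    d2 = dm.data ** 2

    def pseudo_f(lab: np.ndarray) -> float:
        ss_total = d2[np.triu_indices(n, k=1)].sum() / n
        ss_within = 0.0
        for g in uniq:
            idx = np.nonzero(lab == g)[0]
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
        ss_among = ss_total - ss_within
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    observed = pseudo_f(labels)
    count = 0
    total = 0
    for perm in _permutations(n, n_perm, seed):
        total += 1
        if pseudo_f(labels[perm]) >= observed - 1e-12:
            count += 1
    if n_perm is None:
        p = count / total
    else:
        p = (1 + count) / (n_perm + 1)
    return PermutationTestResult("permanova", observed, p,
                                 n_perm if n_perm is not None else total, seed)


# ---------------------------------------------------------------------------
# Friedman test
# ---------------------------------------------------------------------------


def friedman(blocks: np.ndarray | pd.DataFrame) -> PermutationTestResult:
    """Friedman rank test over a blocks x treatments table.

    Average ranks within each block, tie-corrected chi-square statistic,
    asymptotic chi-square p-value with ``k - 1`` degrees of freedom.
    Used here to ask whether taxon compositions differ between samples
    (blocks = samples/dates, treatments = taxa, or vice versa).
    """
    data = np.asarray(blocks, float)
    n, k = data.shape
    if n < 3 or k < 2:
        raise OrdinationError("need >= 3 blocks and >= 2 treatments")
    if np.isnan(data).any():
        raise OrdinationError("Friedman test disallows missing cells")
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    ssbn = (ranks.sum(axis=0) ** 2).sum()
    chisq = 12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)
    ties = 0.0
    for row in data:
        _, t = np.unique(row, return_counts=True)
        ties += (t ** 3 - t).sum()
    c = 1.0 - ties / (k * (k * k - 1) * n)
    if c == 0:
        warnings.warn("all blocks constant; Friedman statistic undefined, "
                      "reporting 0")
        return PermutationTestResult("friedman", 0.0, 1.0, None, None,
                                     {"df": k - 1})
    chisq /= c
    p = float(stats.chi2.sf(chisq, k - 1))
    return PermutationTestResult("friedman", float(chisq), p, None, None,
                                 {"df": k - 1})
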