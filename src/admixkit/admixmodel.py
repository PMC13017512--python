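"""qpWave-style rank tests and qpAdm-style admixture-weight estimation.

The machinery works on the matrix of f4 statistics

    X[i, j] = f4(left_i, left_last; right_j, right_last),

for i, j short of the basis (last-listed) populations, together with the
block-jackknife covariance of vec(X). A target population is modelled as a
mixture of source populations: since f4 is bilinear in allele frequencies,
``target = Σ_s w_s · source_s`` with ``Σ w_s = 1`` implies that the target's
f4 row is the same weighted combination of the source rows against any set of
"right" reference populations unadmixed with the left set. The residual
quadratic form under the jackknife covariance is referred to a chi-squared
distribution with (n_right − n_left + 1) degrees of freedom; weight standard
errors come from refitting on delete-one-block f4 matrices.

Model-selection rules: a model is rejected when its residual p-value is below
0.01 or any fitted weight is negative (infeasible); period means aggregate
only accepted dual-source fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, stats

from .errors import ConfigurationError, EstimationError
from .fstats import BlockSpec, weighted_jackknife
from .genodata import GenotypePanel

__all__ = [
    "F4Matrix",
    "RankTestResult",
    "QpAdmResult",
    "f4_matrix",
    "qpwave_rank",
    "qpadm_fit",
    "rank_models",
    "period_aggregate",
]


@dataclass
class F4Matrix:
    """f4 matrix with its jackknife covariance and per-block leave-one-out copies."""

    left: list[str]
    right: list[str]
    X: np.ndarray            # (m, J)
    covariance: np.ndarray   # (m*J, m*J), covariance of vec(X), column-major
    loo: np.ndarray          # (g, m, J) delete-one-block matrices
    block_weights: np.ndarray  # (g,) mean SNP count per block across cells
    n_snps_used: int
    allsnps: bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


@dataclass
class RankTestResult:
    rank: int
    statistic: float
    dof: int
    p_value: float
    regularized: bool = False


@dataclass
class QpAdmResult:
    target: str
    sources: list[str]
    references: list[str]
    weights: np.ndarray
    weight_se: np.ndarray
    p_value: float
    feasible: bool
    allsnps: bool
    n_snps_used: int
    statistic: float = np.nan
    dof: int = 0
    period: str | None = None

    def to_record(self) -> dict:
        return {
            "target": self.target,
            "sources": list(self.sources),
            "references": list(self.references),
            "weights": [float(w) for w in self.weights],
            "weight_se": [float(s) for s in self.weight_se],
            "p_value": float(self.p_value),
            "feasible": bool(self.feasible),
            "allsnps": bool(self.allsnps),
            "n_snps": int(self.n_snps_used),
        }


def f4_matrix(
    panel: GenotypePanel,
    left: Sequence[str],
    right: Sequence[str],
    blocks: BlockSpec,
    allsnps: bool = True,
) -> F4Matrix:
    """Compute X[i,j] = f4(left_i, left_last; right_j, right_last) and its covariance.

    With ``allsnps`` each cell uses its own complete-case site set (the
    behaviour used throughout the analyses here); otherwise one common
    intersected site set is used for every cell. The covariance of vec(X) is
    the delete-one-block jackknife covariance.
    """
    left = list(left)
    right = list(right)
    if len(left) < 2 or len(right) < 2:
        raise ConfigurationError("need at least two left and two right populations")
    pops = left + right
    freq, _ = panel.population_frequencies(pops)
    fr = {p: freq[:, k] for k, p in enumerate(pops)}
    m, J = len(left) - 1, len(right) - 1
    g = blocks.n_blocks
    ids = blocks.block_ids

    common = np.isfinite(freq).all(axis=1) if not allsnps else None

    num = np.zeros((g, m, J))
    cnt = np.zeros((g, m, J))
    used = np.zeros(len(ids), dtype=bool)
    lbase, rbase = fr[left[-1]], fr[right[-1]]
    for i in range(m):
        li = fr[left[i]]
        for j in range(J):
            rj = fr[right[j]]
            cols = np.column_stack([li, lbase, rj, rbase])
            mask = np.isfinite(cols).all(axis=1)
            if common is not None:
                mask &= common
            if not mask.any():
                raise EstimationError(
                    f"f4 cell ({left[i]}, {right[j]}): zero usable sites"
                )
            used |= mask
            terms = (li - lbase) * (rj - rbase)
            bid = ids[mask]
            num[:, i, j] = np.bincount(bid, weights=terms[mask], minlength=g)
            cnt[:, i, j] = np.bincount(bid, minlength=g)

    tot_num = num.sum(axis=0)
    tot_cnt = cnt.sum(axis=0)
    X = tot_num / tot_cnt
    loo_cnt = tot_cnt[np.newaxis] - cnt
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = np.where(loo_cnt > 0, (tot_num[np.newaxis] - num) / np.maximum(loo_cnt, 1), X[np.newaxis])
    v = np.stack([loo[b].flatten(order="F") for b in range(g)])
    vbar = v.mean(axis=0)
    dv = v - vbar
    Q = (g - 1) / g * dv.T @ dv
    weights = cnt.reshape(g, -1).mean(axis=1)
    return F4Matrix(
        left=left,
        right=right,
        X=X,
        covariance=Q,
        loo=loo,
        block_weights=weights,
        n_snps_used=int(used.sum()),
        allsnps=allsnps,
    )


def _regularize(Q: np.ndarray) -> tuple[np.ndarray, bool]:
    d = Q.shape[0]
    eig = np.linalg.eigvalsh(Q)
    if eig.min() > 1e-12 * max(eig.max(), 1e-300):
        return Q, False
    eps = 1e-9 * np.trace(Q) / d
    if eps <= 0:
        eps = 1e-15
    return Q + eps * np.eye(d), True


def _chi2_form(v: np.ndarray, Qc) -> float:
    y = linalg.cho_solve(Qc, v)
    return float(v @ y)


def qpwave_rank(X: np.ndarray, covariance: np.ndarray, rank: int) -> RankTestResult:
    """Test whether X is consistent with the given rank.

    Finds the best rank-``rank`` approximation minimising the
    covariance-weighted quadratic form (by alternating generalised least
    squares) and refers the residual statistic to chi-squared with
    (rows − rank)(cols − rank) degrees of freedom.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m, n = X.shape
    if rank >= min(m, n):
        raise ConfigurationError("rank must be smaller than both matrix dimensions")
    dof = (m - rank) * (n - rank)
    Q, regularized = _regularize(np.asarray(covariance, dtype=float))
    Qc = linalg.cho_factor(Q)
    v = X.flatten(order="F")
    if rank == 0:
        stat = _chi2_form(v, Qc)
        return RankTestResult(0, stat, dof, float(stats.chi2.sf(stat, dof)), regularized)

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    A = U[:, :rank] * s[:rank]
    B = Vt[:rank].T
    Qinv = linalg.cho_solve(Qc, np.eye(m * n))
    prev = np.inf
    stat = np.inf
    for _ in range(300):
        # update A given B
        D = np.kron(B, np.eye(m))            # (mn, m*rank)
        M = D.T @ Qinv @ D
        rhs = D.T @ (Qinv @ v)
        a = np.linalg.lstsq(M, rhs, rcond=None)[0]
        A = a.reshape(m, rank, order="F")
        # update B given A
        D = np.kron(np.eye(n), A)            # (mn, n*rank)
        M = D.T @ Qinv @ D
        rhs = D.T @ (Qinv @ v)
        b = np.linalg.lstsq(M, rhs, rcond=None)[0]
        B = b.reshape(rank, n, order="F").T
        resid = v - (A @ B.T).flatten(order="F")
        stat = float(resid @ (Qinv @ resid))
        if abs(prev - stat) < 1e-12 * (1 + abs(stat)):
            break
        prev = stat
    return RankTestResult(rank, stat, dof, float(stats.chi2.sf(stat, dof)), regularized)


def _solve_weights(X: np.ndarray, Q4: np.ndarray) -> tuple[np.ndarray, float]:
    """Fit mixture weights for the target row (row 0) of an f4 matrix.

    Rows 1..m-1 are sources (short of the basis source, whose row is
    identically zero and absorbed by the sum-to-one constraint). Returns the
    full weight vector (length = number of sources) and the residual
    chi-squared statistic.
    """
    m, J = X.shape[0], X.shape[1]
    xt = X[0]
    Bmat = X[1:].T  # (J, m-1)
    k_free = m - 1

    def cov_of_resid(w_free: np.ndarray) -> np.ndarray:
        c = np.concatenate([[1.0], -w_free])
        V = np.einsum("p,q,pjqk->jk", c, c, Q4)
        return V

    if k_free == 0:
        w_free = np.empty(0)
        V = cov_of_resid(w_free)
        V, _ = _regularize(V)
        stat = float(xt @ np.linalg.solve(V, xt))
        return np.array([1.0]), stat

    w_free = np.linalg.lstsq(Bmat, xt, rcond=None)[0]
    for _ in range(50):
        V = cov_of_resid(w_free)
        V, _ = _regularize(V)
        Vc = linalg.cho_factor(V)
        M = Bmat.T @ linalg.cho_solve(Vc, Bmat)
        rhs = Bmat.T @ linalg.cho_solve(Vc, xt)
        w_new = np.linalg.lstsq(M, rhs, rcond=None)[0]
        if np.allclose(w_new, w_free, atol=1e-12, rtol=0):
            w_free = w_new
            break
        w_free = w_new
    V = cov_of_resid(w_free)
    V, _ = _regularize(V)
    e = xt - Bmat @ w_free
    stat = float(e @ np.linalg.solve(V, e))
    weights = np.concatenate([w_free, [1.0 - w_free.sum()]])
    return weights, stat


def qpadm_fit(
    panel: GenotypePanel,
    target: str,
    sources: Sequence[str],
    references: Sequence[str],
    blocks: BlockSpec,
    allsnps: bool = True,
) -> QpAdmResult:
    """Model ``target`` as a mixture of ``sources`` against a right set.

    Weights solve the condition that the target's f4 row is the weighted
    combination of the source rows (weights summing to one), estimated by
    iterated generalised least squares under the jackknife covariance.
    Weight SEs come from a weighted block jackknife of the whole fit; the
    p-value is the chi-squared tail of the residual statistic with
    ``len(references) − len(sources) − 1 + 1`` degrees of freedom.
    """
    sources = list(sources)
    references = list(references)
    if target in sources or target in references:
        raise ConfigurationError("target must not appear among sources or references")
    if len(references) < len(sources) + 1:
        raise ConfigurationError(
            "need at least len(sources)+1 reference populations"
        )
    left = [target] + sources
    fm = f4_matrix(panel, left, references, blocks, allsnps=allsnps)
    m, J = fm.shape
    # covariance is over vec(X) column-major (index i + m*j); unfold so that
    # Q4[p, j, q, k] = Cov(X[p, j], X[q, k])
    Q4 = fm.covariance.reshape((m, J, m, J), order="F")

    weights, stat = _solve_weights(fm.X, Q4)
    dof = J - (m - 1)
    if dof < 1:
        raise ConfigurationError("no residual degrees of freedom; add references")
    p_value = float(stats.chi2.sf(stat, dof))

    g = fm.loo.shape[0]
    loo_w = np.empty((g, len(sources)))
    for b in range(g):
        loo_w[b], _ = _solve_weights(fm.loo[b], Q4)
    se = np.empty(len(sources))
    for k in range(len(sources)):
        _, se[k] = weighted_jackknife(weights[k], loo_w[:, k], fm.block_weights)

    return QpAdmResult(
        target=target,
        sources=sources,
        references=references,
        weights=weights,
        weight_se=se,
        p_value=p_value,
        feasible=bool((weights >= 0).all()),
        allsnps=allsnps,
        n_snps_used=fm.n_snps_used,
        statistic=stat,
        dof=dof,
    )


def rank_models(results: Sequence[QpAdmResult], p_threshold: float = 0.01) -> list[tuple[QpAdmResult, bool]]:
    """Accept/reject and order qpAdm models.

    A model is rejected iff its p-value is below ``p_threshold`` or any
    weight is negative. Accepted models are sorted by p descending, ties
    broken by fewer sources then lexical source names; rejected models follow
    in the same order.
    """
    def accepted(r: QpAdmResult) -> bool:
        return r.p_value >= p_threshold and r.feasible

    def key(r: QpAdmResult):
        return (-r.p_value, len(r.sources), tuple(sorted(r.sources)))

    acc = sorted([r for r in results if accepted(r)], key=key)
    rej = sorted([r for r in results if not accepted(r)], key=key)
    return [(r, True) for r in acc] + [(r, False) for r in rej]


def period_aggregate(
    results: Sequence[QpAdmResult],
    period_labels: Sequence[str],
    p_threshold: float = 0.01,
) -> dict[str, np.ndarray]:
    """Mean weights per period over accepted fits (p > threshold, feasible).

    Periods with no accepted model are absent from the result rather than
    reported as zero.
    """
    if len(results) != len(period_labels):
        raise ConfigurationError("results and period_labels must align")
    acc: dict[str, list[np.ndarray]] = {}
    for r, period in zip(results, period_labels):
        if r.p_value > p_threshold and r.feasible:
            acc.setdefault(period, []).append(np.asarray(r.weights, dtype=float))
    return {k: np.mean(v, axis=0) for k, v in acc.items()}
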