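"""f-statistics (outgroup-f3, f4, D, F4-ratio) with weighted block jackknife.

Estimates are computed from population allele frequencies as per-site terms,
aggregated as ratio statistics over jackknife blocks. Standard errors use the
weighted delete-one-block jackknife of Busing, Meijer & van der Leeden (1999),
with block SNP counts as weights so that short terminal blocks are handled
correctly. Z scores are estimate / SE.

Missing data: each statistic is computed over its own complete-case site set
(sites with a defined frequency in every population entering that statistic).

Single-sample pseudo-haploid populations have frequencies of 0/1 and no
within-population heterozygosity correction is attempted; this is the analogue
of treating pseudo-haploid genotypes as inbred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EstimationError
from .genodata import GenotypePanel

__all__ = [
    "BlockSpec",
    "FStatResult",
    "make_blocks",
    "weighted_jackknife",
    "f3",
    "f4",
    "d_stat",
    "f4_ratio",
    "outgroup_f3_matrix",
]


@dataclass(frozen=True)
class BlockSpec:
    """Partition of sites into contiguous jackknife blocks."""

    mode: str
    size: int
    block_ids: np.ndarray  # per-site block id, consecutive integers from 0

    @property
    def n_blocks(self) -> int:
        return int(self.block_ids.max()) + 1 if self.block_ids.size else 0


@dataclass
class FStatResult:
    """An f-statistic estimate with jackknife SE and Z score."""

    statistic_name: str
    populations: tuple
    estimate: float
    jackknife_se: float
    z_score: float
    n_blocks: int
    n_snps_used: int
    degenerate: bool = False
    warning: str | None = None

    def to_record(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "populations": list(self.populations),
            "estimate": self.estimate,
            "se": self.jackknife_se,
            "z": self.z_score,
            "n_blocks": self.n_blocks,
            "n_snps": self.n_snps_used,
            "degenerate": self.degenerate,
            "warning": self.warning,
        }


def make_blocks(sites: pd.DataFrame, mode: str = "span", size: int = 5_000_000) -> BlockSpec:
    """Assign each site to a contiguous block.

    ``span`` mode groups by ``floor(pos / size)`` keyed by chromosome (blocks
    never join chromosomes); ``count`` mode takes consecutive runs of ``size``
    sites in panel order.
    """
    if size <= 0:
        raise ConfigurationError("block size must be positive")
    n = len(sites)
    if n == 0:
        return BlockSpec(mode, size, np.empty(0, dtype=np.int64))
    if mode == "span":
        chrom = sites["chrom"].to_numpy()
        bin_ = sites["pos"].to_numpy() // size
        keys = pd.Series(list(zip(chrom, bin_)))
        ids = pd.factorize(keys)[0].astype(np.int64)
    elif mode == "count":
        ids = np.arange(n, dtype=np.int64) // size
    else:
        raise ConfigurationError(f"unknown block mode {mode!r}")
    return BlockSpec(mode, size, ids)


def weighted_jackknife(
    full: float, loo: np.ndarray, weights: np.ndarray
) -> tuple[float, float]:
    """Weighted delete-one jackknife (Busing et al. 1999).

    ``loo`` are the delete-one-block estimates and ``weights`` the block
    weights (SNP counts). Returns ``(bias_corrected_estimate, se)``.
    """
    w = np.asarray(weights, dtype=float)
    loo = np.asarray(loo, dtype=float)
    g = len(w)
    if g < 2:
        return full, 0.0
    n = w.sum()
    h = n / w
    theta_j = g * full - np.sum((1.0 - w / n) * loo)
    tau = h * full - (h - 1.0) * loo
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g
    return theta_j, float(np.sqrt(max(var, 0.0)))


def _block_ratio_result(
    name: str,
    pops: tuple,
    num: np.ndarray,
    den: np.ndarray,
    counts: np.ndarray,
) -> FStatResult:
    """Full-data ratio Σnum/Σden with delete-one-block jackknife SE."""
    keep = counts > 0
    num, den, counts = num[keep], den[keep], counts[keep]
    tot_n, tot_d = num.sum(), den.sum()
    if tot_d == 0:
        raise EstimationError(f"{name}: denominator sum is zero")
    full = tot_n / tot_d
    loo_d = tot_d - den
    ok = loo_d != 0
    loo = np.where(ok, (tot_n - num) / np.where(ok, loo_d, 1.0), full)
    _, se = weighted_jackknife(full, loo, counts)
    degenerate = se == 0.0
    z = full / se if se > 0 else 0.0
    return FStatResult(
        statistic_name=name,
        populations=pops,
        estimate=float(full),
        jackknife_se=se,
        z_score=float(z),
        n_blocks=int(keep.sum()),
        n_snps_used=int(counts.sum()),
        degenerate=bool(degenerate),
    )


def _terms_to_blocks(
    terms: np.ndarray, mask: np.ndarray, blocks: BlockSpec
) -> tuple[np.ndarray, np.ndarray]:
    g = blocks.n_blocks
    ids = blocks.block_ids[mask]
    sums = np.bincount(ids, weights=terms[mask], minlength=g)
    counts = np.bincount(ids, minlength=g).astype(float)
    return sums, counts


def _complete_mask(freq: np.ndarray) -> np.ndarray:
    return np.isfinite(freq).all(axis=1)


def f3(
    panel: GenotypePanel, a: str, b: str, c: str, blocks: BlockSpec
) -> FStatResult:
    """f3(A, B; C) with vertex population C: per-site term (c−a)(c−b).

    With C an outgroup this is the outgroup-f3 shared-drift statistic.
    Symmetric in A and B.
    """
    freq, _ = panel.population_frequencies([a, b, c])
    mask = _complete_mask(freq)
    if not mask.any():
        raise EstimationError(f"f3({a},{b};{c}): zero sites non-missing in all populations")
    fa, fb, fc = freq[:, 0], freq[:, 1], freq[:, 2]
    terms = (fc - fa) * (fc - fb)
    sums, counts = _terms_to_blocks(terms, mask, blocks)
    return _block_ratio_result("f3", (a, b, c), sums, counts, counts)


def f4(
    panel: GenotypePanel, a: str, b: str, c: str, d: str, blocks: BlockSpec
) -> FStatResult:
    """f4(A, B; C, D): per-site term (a−b)(c−d)."""
    freq, _ = panel.population_frequencies([a, b, c, d])
    mask = _complete_mask(freq)
    if not mask.any():
        raise EstimationError(f"f4({a},{b};{c},{d}): zero usable sites")
    terms = (freq[:, 0] - freq[:, 1]) * (freq[:, 2] - freq[:, 3])
    sums, counts = _terms_to_blocks(terms, mask, blocks)
    return _block_ratio_result("f4", (a, b, c, d), sums, counts, counts)


def d_stat(
    panel: GenotypePanel, w: str, x: str, y: str, z: str, blocks: BlockSpec
) -> FStatResult:
    """D(P1, P2, P3, P4) = Σ(p1−p2)(p3−p4) / Σ(p1+p2−2·p1·p2)(p3+p4−2·p3·p4).

    Jackknifed as a ratio statistic over blocks. |Z| > 3 is the conventional
    evidence threshold for gene flow.
    """
    freq, _ = panel.population_frequencies([w, x, y, z])
    mask = _complete_mask(freq)
    if not mask.any():
        raise EstimationError(f"D({w},{x},{y},{z}): zero usable sites")
    fw, fx, fy, fz = (freq[:, i] for i in range(4))
    num = (fw - fx) * (fy - fz)
    den = (fw + fx - 2 * fw * fx) * (fy + fz - 2 * fy * fz)
    num_b, counts = _terms_to_blocks(num, mask, blocks)
    den_b, _ = _terms_to_blocks(den, mask, blocks)
    return _block_ratio_result("D", (w, x, y, z), num_b, den_b, counts)


def f4_ratio(
    panel: GenotypePanel,
    a: str,
    o: str,
    x: str,
    b: str,
    c: str,
    blocks: BlockSpec,
) -> FStatResult:
    """Admixture-proportion estimator α = f4(A,O;X,C) / f4(A,O;B,C).

    Under a topology where X is a mixture α·B' + (1−α)·C' with B', C' on the
    lineages of B and C respectively, α estimates the B-related ancestry
    fraction of X. Both f4s are computed over the common complete-case site
    set and jackknifed as a block ratio. When the denominator f4 is not
    significantly nonzero (|Z| < 3) the result carries a warning flag.
    """
    freq, _ = panel.population_frequencies([a, o, x, b, c])
    mask = _complete_mask(freq)
    if not mask.any():
        raise EstimationError("f4_ratio: zero usable sites")
    fa, fo, fx, fb, fc = (freq[:, i] for i in range(5))
    left = fa - fo
    num = left * (fx - fc)
    den = left * (fb - fc)
    num_b, counts = _terms_to_blocks(num, mask, blocks)
    den_b, _ = _terms_to_blocks(den, mask, blocks)
    result = _block_ratio_result("f4_ratio", (a, o, x, b, c), num_b, den_b, counts)
    den_result = _block_ratio_result("f4", (a, o, b, c), den_b, counts, counts)
    if abs(den_result.z_score) < 3:
        result.warning = "denominator_not_significant"
    return result


def outgroup_f3_matrix(
    panel: GenotypePanel,
    populations: Sequence[str],
    vertex: str,
    blocks: BlockSpec,
    min_coverage: float = 0.0,
) -> pd.DataFrame:
    """Symmetric matrix of outgroup-f3 estimates f3(X, Y; vertex).

    Samples with coverage below ``min_coverage`` are excluded (samples with
    unknown coverage are kept); populations left with no samples are dropped.
    The diagonal is left undefined (NaN).
    """
    if vertex in populations:
        raise ConfigurationError("vertex population must be disjoint from the list")
    cov = panel.samples["coverage"].to_numpy()
    keep = np.isnan(cov) | (cov >= min_coverage)
    keep |= (panel.samples["population"] == vertex).to_numpy()  # vertex always kept
    sub = panel.take_samples(keep)
    retained = [p for p in populations if (sub.samples["population"] == p).any()]
    mat = pd.DataFrame(np.nan, index=retained, columns=retained, dtype=float)
    for i, p in enumerate(retained):
        for q in retained[i + 1:]:
            est = f3(sub, p, q, vertex, blocks).estimate
            mat.loc[p, q] = est
            mat.loc[q, p] = est
    return mat
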