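"""READ-style pairwise-mismatch kinship with median normalization.

For each pair of (pseudo-)haploid samples, P0 is the fraction of co-covered
sites at which the two calls differ, computed per genomic window (default
5 Mb). The per-pair mean P0 is normalized by the median over all pairs — the
median pair standing proxy for an unrelated pair — and relatedness is
reported as theta = 1 − normalized P0, so the median pair has theta = 0 by
construction. Standard errors come from a delete-one-window jackknife of the
normalized statistic (the median is recomputed for each deletion).

Diploid samples are pseudo-haploidized on the fly by drawing one random
allele per site (seeded), so all comparisons are symmetric haploid–haploid.
Windows with fewer than ``min_sites`` co-covered sites are dropped to keep
degenerate windows from dominating the jackknife.

theta here is a relative statistic; mapping onto an absolute kinship
coefficient scale (with degree-classification cutoffs) is a documented
convention left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, EstimationError
from .fstats import make_blocks
from .genodata import MISSING, GenotypePanel

__all__ = ["KinshipResult", "window_mismatch", "estimate_theta"]


@dataclass
class KinshipResult:
    pair: tuple[str, str]
    p0_mean: float
    p0_norm: float
    theta: float
    jackknife_se: float
    n_windows: int

    def to_record(self) -> dict:
        return {
            "sample_a": self.pair[0],
            "sample_b": self.pair[1],
            "p0_mean": self.p0_mean,
            "p0_norm": self.p0_norm,
            "theta": self.theta,
            "se": self.jackknife_se,
            "n_windows": self.n_windows,
        }


def _haploid_calls(panel: GenotypePanel, rng: np.random.Generator) -> np.ndarray:
    """Haploid 0/1/MISSING call matrix; diploids get one random allele."""
    calls = panel.calls.astype(np.int8).copy()
    ploidy = panel.samples["ploidy"].to_numpy()
    for j in np.flatnonzero(ploidy == 2):
        col = calls[:, j]
        het = col == 1
        out = col.copy()
        out[col == 2] = 1
        out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
        out[col == MISSING] = MISSING
        calls[:, j] = out
    return calls


def _pair_window_p0(
    hap: np.ndarray,
    ia: int,
    ib: int,
    window_ids: np.ndarray,
    n_windows: int,
    min_sites: int,
) -> tuple[np.ndarray, np.ndarray]:
    a, b = hap[:, ia], hap[:, ib]
    co = (a != MISSING) & (b != MISSING)
    mis = co & (a != b)
    n_co = np.bincount(window_ids[co], minlength=n_windows).astype(float)
    n_mis = np.bincount(window_ids[mis], minlength=n_windows).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = np.where(n_co >= min_sites, n_mis / np.maximum(n_co, 1), np.nan)
    return p0, n_co


def window_mismatch(
    panel: GenotypePanel,
    sample_a: str,
    sample_b: str,
    window_bp: int = 5_000_000,
    min_sites: int = 10,
    seed: int | None = None,
) -> np.ndarray:
    """Per-window pairwise mismatch rate P0 (NaN where under-covered)."""
    rng = np.random.default_rng(seed)
    hap = _haploid_calls(panel, rng)
    ids = {s: i for i, s in enumerate(panel.samples["sample_id"])}
    blocks = make_blocks(panel.sites, "span", window_bp)
    p0, _ = _pair_window_p0(
        hap, ids[sample_a], ids[sample_b], blocks.block_ids, blocks.n_blocks, min_sites
    )
    if not np.isfinite(p0).any():
        raise EstimationError(f"no co-covered windows for pair ({sample_a}, {sample_b})")
    return p0


def estimate_theta(
    panel: GenotypePanel,
    pairs: Sequence[tuple[str, str]] | None = None,
    window_bp: int = 5_000_000,
    seed: int | None = None,
    min_sites: int = 10,
) -> list[KinshipResult]:
    """Median-normalized relatedness for sample pairs.

    ``pairs`` defaults to all unordered sample pairs. At least three pairs
    are required for the median normalization to be meaningful.
    """
    ids = list(panel.samples["sample_id"])
    if pairs is None:
        pairs = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ConfigurationError("need at least 3 pairs for median normalization")
    rng = np.random.default_rng(seed)
    hap = _haploid_calls(panel, rng)
    index = {s: i for i, s in enumerate(ids)}
    blocks = make_blocks(panel.sites, "span", window_bp)
    W = blocks.n_blocks

    p0 = np.full((len(pairs), W), np.nan)
    for k, (a, b) in enumerate(pairs):
        p0[k], _ = _pair_window_p0(
            hap, index[a], index[b], blocks.block_ids, W, min_sites
        )
    valid = np.isfinite(p0)
    if not valid.any(axis=1).all():
        bad = [pairs[k] for k in np.flatnonzero(~valid.any(axis=1))]
        raise EstimationError(f"pairs with zero co-covered windows: {bad}")

    sums = np.where(valid, p0, 0.0).sum(axis=1)
    counts = valid.sum(axis=1).astype(float)
    p0_mean = sums / counts
    med = np.median(p0_mean)
    if med == 0:
        raise EstimationError("median P0 is zero; cannot normalize")
    theta_full = 1.0 - p0_mean / med

    # delete-one-window jackknife, recomputing the median per deletion
    loo_sum = sums[:, None] - np.where(valid, p0, 0.0)
    loo_cnt = counts[:, None] - valid
    with np.errstate(invalid="ignore", divide="ignore"):
        loo_mean = np.where(loo_cnt > 0, loo_sum / np.maximum(loo_cnt, 1), p0_mean[:, None])
    loo_med = np.median(loo_mean, axis=0)
    loo_theta = 1.0 - loo_mean / loo_med[None, :]

    results = []
    for k, pair in enumerate(pairs):
        w = np.flatnonzero(valid[k])
        th_w = loo_theta[k, w]
        g = len(w)
        if g > 1:
            se = float(np.sqrt((g - 1) / g * np.sum((th_w - th_w.mean()) ** 2)))
        else:
            se = 0.0
        results.append(
            KinshipResult(
                pair=pair,
                p0_mean=float(p0_mean[k]),
                p0_norm=float(p0_mean[k] / med),
                theta=float(theta_full[k]),
                jackknife_se=se,
                n_windows=int(g),
            )
        )
    return results
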