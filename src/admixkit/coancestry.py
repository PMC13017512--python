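"""Human–dog co-ancestry: distance matrices, MRM, partial Mantel, outliers.

The procedure asks whether dog–dog genetic similarity (outgroup-f3) at a set
of archaeological sites tracks human–human similarity at the same sites,
beyond what shared geography and time explain. Spatial distance is the
great-circle (haversine) distance between sites; temporal distance is the
absolute difference of site midpoint ages. All matrices are z-standardised
over their off-diagonal entries before modelling.

Significance of matrix correlations uses joint row-and-column permutations,
with p = (b + 1) / (n + 1) so that p is never zero. The partial Mantel test
follows the classic residual-correlation formulation: both matrices are
regressed on the covariate matrices over lower-triangle entries, the
residuals are correlated, and the null distribution comes from permuting the
residual matrix of one side. The default significance threshold of 0.0045 is
a conservative correction for spatially autocorrelated similarity matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateError, DimensionError, InputError

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "SitePairFrame",
    "MantelResult",
    "MRMResult",
    "haversine_km",
    "distance_matrices",
    "standardize_offdiag",
    "build_pair_frame",
    "mrm",
    "partial_mantel",
    "paired_f3_outliers",
]


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between decimal-degree coordinates."""
    arrs = [np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2)]
    la1, lo1, la2, lo2 = arrs
    if (np.abs(la1) > 90).any() or (np.abs(la2) > 90).any():
        raise InputError("latitude out of [-90, 90]")
    if (np.abs(lo1) > 180).any() or (np.abs(lo2) > 180).any():
        raise InputError("longitude out of [-180, 180]")
    p1, p2 = np.radians(la1), np.radians(la2)
    dphi = np.radians(la2 - la1)
    dlam = np.radians(lo2 - lo1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


def distance_matrices(site_meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Spatial (km) and temporal (years) distance matrices over sites.

    ``site_meta`` needs columns latitude, longitude, age_bp (midpoint ages).
    """
    lat = site_meta["latitude"].to_numpy(dtype=float)
    lon = site_meta["longitude"].to_numpy(dtype=float)
    age = site_meta["age_bp"].to_numpy(dtype=float)
    spatial = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    temporal = np.abs(age[:, None] - age[None, :])
    return spatial, temporal


def standardize_offdiag(M: np.ndarray) -> np.ndarray:
    """z-transform a square matrix over its off-diagonal entries (diag set 0)."""
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = M[off]
    sd = vals.std()
    if sd == 0:
        raise DegenerateError("matrix is constant off the diagonal; cannot standardize")
    Z = (M - vals.mean()) / sd
    np.fill_diagonal(Z, 0.0)
    return Z


@dataclass
class SitePairFrame:
    """Per-site-pair view of standardized similarity and distance matrices."""

    sites: list[str]
    frame: pd.DataFrame  # one row per unordered pair
    matrices: dict[str, np.ndarray]  # standardized square matrices


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    alpha: float = 0.0045

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class MRMResult:
    coefficients: pd.Series
    p_values: pd.Series
    r_squared: float
    residual_matrix: np.ndarray
    outlier_pairs: pd.DataFrame
    n_permutations: int


def build_pair_frame(
    f3_human: pd.DataFrame, f3_dog: pd.DataFrame, site_meta: pd.DataFrame
) -> SitePairFrame:
    """Standardize matrices over off-diagonal pairs and tabulate unordered pairs.

    The two f3 matrices must be indexed by the same site list as
    ``site_meta['site']``.
    """
    sites = list(site_meta["site"])
    for name, m in (("human", f3_human), ("dog", f3_dog)):
        if list(m.index) != sites or list(m.columns) != sites:
            raise DimensionError(f"{name} f3 matrix is not aligned with the site list")
    spatial, temporal = distance_matrices(site_meta)
    mats = {
        "human_f3": standardize_offdiag(f3_human.to_numpy(dtype=float)),
        "dog_f3": standardize_offdiag(f3_dog.to_numpy(dtype=float)),
        "spatial": standardize_offdiag(spatial),
        "temporal": standardize_offdiag(temporal),
    }
    n = len(sites)
    iu = np.triu_indices(n, k=1)
    frame = pd.DataFrame(
        {
            "site_i": [sites[i] for i in iu[0]],
            "site_j": [sites[j] for j in iu[1]],
            "spatial_km": spatial[iu],
            "temporal_years": temporal[iu],
            "spatial_z": mats["spatial"][iu],
            "temporal_z": mats["temporal"][iu],
            "human_f3": mats["human_f3"][iu],
            "dog_f3": mats["dog_f3"][iu],
        }
    )
    return SitePairFrame(sites=sites, frame=frame, matrices=mats)


def _check_square(M: np.ndarray, n: int | None = None) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DimensionError("matrix must be square")
    if n is not None and M.shape[0] != n:
        raise DimensionError("matrices have mismatched dimensions")
    if not np.allclose(M, M.T, atol=1e-8):
        raise DimensionError("matrix must be symmetric")
    return M


def _tril_vec(M: np.ndarray) -> np.ndarray:
    il = np.tril_indices(M.shape[0], k=-1)
    return M[il]


def mrm(
    response_matrix: np.ndarray,
    predictor_matrices: Mapping[str, np.ndarray],
    n_permutations: int = 999,
    seed: int | None = None,
    outlier_sd: float = 4.0,
) -> MRMResult:
    """Multiple regression on distance matrices with permutation p-values.

    OLS of the vectorized lower triangle of the response on the predictors;
    significance per coefficient by jointly permuting rows and columns of the
    response ``n_permutations`` times. Pairs with |residual| exceeding
    ``outlier_sd`` standard deviations are flagged.
    """
    if n_permutations < 99:
        raise ConfigurationError("n_permutations must be at least 99")
    R = _check_square(response_matrix)
    n = R.shape[0]
    names = list(predictor_matrices)
    preds = [_check_square(predictor_matrices[k], n) for k in names]
    y = _tril_vec(R)
    design = np.column_stack([np.ones(len(y))] + [_tril_vec(P) for P in preds])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan

    pinv = np.linalg.pinv(design)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(beta))
    for _ in range(n_permutations):
        p = rng.permutation(n)
        y_p = _tril_vec(R[np.ix_(p, p)])
        beta_p = pinv @ y_p
        exceed += np.abs(beta_p) >= np.abs(beta) - 1e-15
    p_values = (exceed + 1.0) / (n_permutations + 1.0)

    resid_mat = np.zeros((n, n))
    il = np.tril_indices(n, k=-1)
    resid_mat[il] = resid
    resid_mat = resid_mat + resid_mat.T

    sd = resid.std()
    # an exact fit leaves only floating-point noise: nothing to flag
    flags = np.abs(resid) > outlier_sd * sd if sd > 1e-12 else np.zeros(len(resid), bool)
    outliers = pd.DataFrame(
        {
            "i": il[0][flags],
            "j": il[1][flags],
            "residual": resid[flags],
        }
    )
    labels = ["intercept"] + names
    return MRMResult(
        coefficients=pd.Series(beta, index=labels),
        p_values=pd.Series(p_values, index=labels),
        r_squared=float(r2),
        residual_matrix=resid_mat,
        outlier_pairs=outliers,
        n_permutations=n_permutations,
    )


def partial_mantel(
    A: np.ndarray,
    B: np.ndarray,
    covariates: Sequence[np.ndarray] = (),
    n_permutations: int = 999,
    seed: int | None = None,
    alpha: float = 0.0045,
) -> MantelResult:
    """Partial Mantel test of A vs B controlling for covariate matrices.

    r is the Pearson correlation of lower-triangle residuals after each
    matrix is regressed on the covariates (with an empty covariate set this
    is exactly the simple Mantel statistic). The one-sided p-value permutes
    rows and columns of A's residual matrix jointly.
    """
    if n_permutations < 99:
        raise ConfigurationError("n_permutations must be at least 99")
    A = _check_square(A)
    n = A.shape[0]
    B = _check_square(B, n)
    covs = [_check_square(C, n) for C in covariates]
    il = np.tril_indices(n, k=-1)
    ya, yb = A[il], B[il]
    design = np.column_stack([np.ones(len(ya))] + [C[il] for C in covs])
    pinv = np.linalg.pinv(design)
    ra = ya - design @ (pinv @ ya)
    rb = yb - design @ (pinv @ yb)
    denom = np.sqrt(np.sum(ra**2) * np.sum(rb**2))
    if denom == 0:
        raise DegenerateError("zero residual variance in partial Mantel")
    r_obs = float(np.sum(ra * rb) / denom)

    RA = np.zeros((n, n))
    RA[il] = ra
    RA = RA + RA.T
    rbc = rb / np.sqrt(np.sum(rb**2))
    rng = np.random.default_rng(seed)
    b_count = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        rap = RA[np.ix_(p, p)][il]
        nrm = np.sqrt(np.sum(rap**2))
        r_p = float(rap @ rbc / nrm) if nrm > 0 else 0.0
        if r_p >= r_obs - 1e-15:
            b_count += 1
    p_value = (b_count + 1.0) / (n_permutations + 1.0)
    return MantelResult(r=r_obs, p_value=p_value, n_permutations=n_permutations, alpha=alpha)


def paired_f3_outliers(
    human_f3: np.ndarray,
    dog_f3: np.ndarray,
    z_threshold: float = 3.0,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Flag site pairs whose human/dog similarity difference is an outlier.

    Per pair, the difference (human − dog) is converted to a robust Z score
    against the median and 1.4826·MAD of all pairs; |Z| above the threshold
    is flagged. Invariant to adding a constant to both matrices.
    """
    H = _check_square(human_f3)
    D = _check_square(dog_f3, H.shape[0])
    n = H.shape[0]
    il = np.tril_indices(n, k=-1)
    diff = H[il] - D[il]
    med = np.median(diff)
    mad = np.median(np.abs(diff - med))
    if mad == 0:
        if np.allclose(diff, med):
            z = np.zeros(len(diff))
        else:
            raise DegenerateError("zero MAD with non-constant differences")
    else:
        z = (diff - med) / (1.4826 * mad)
    if labels is None:
        labels = [str(i) for i in range(n)]
    return pd.DataFrame(
        {
            "site_i": [labels[i] for i in il[0]],
            "site_j": [labels[j] for j in il[1]],
            "difference": diff,
            "z": z,
            "flagged": np.abs(z) > z_threshold,
        }
    )
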