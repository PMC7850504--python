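"""Matrix-correlation machinery for spatial population structure.

Isolation by distance is tested by correlating linearized genetic
differentiation F_ST/(1-F_ST) against geographic distance with a Mantel
permutation test; multiple regression on distance matrices (MRM) separates
geographic from climatic predictors; and clinal structure is read off as
the Pearson correlation between an ordination axis and longitude or
latitude.  The climatic distance is the absolute difference of scores on
the first principal component of the 12 growing-season climate variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distances import DistanceMatrix

__all__ = [
    "MantelResult",
    "MrmResult",
    "mantel_test",
    "mrm",
    "axis_gradient_correlation",
    "climate_pc1_distance",
]


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    seed: int | None


@dataclass
class MrmResult:
    coefficients: pd.Series        # intercept + one slope per predictor
    r_squared: float
    p_values: pd.Series            # permutation p per slope
    r_squared_p: float
    n_perm: int
    seed: int | None


def _aligned_condensed(*mats: DistanceMatrix) -> list[np.ndarray]:
    first = mats[0]
    for m in mats[1:]:
        if m.ids != first.ids:
            raise ValueError("distance matrices must share labels in the same order")
    return [m.condensed() for m in mats]


def _triu_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def mantel_test(D1: DistanceMatrix, D2: DistanceMatrix, n_perm: int = 9999,
                seed: int | None = None) -> MantelResult:
    """Two-sided Mantel test of matrix correlation.

    r is the Pearson correlation over the n(n-1)/2 unordered pairs;
    permutations relabel the rows and columns of D2 jointly and
    p = (#{|r_perm| >= |r_obs|} + 1)/(n_perm + 1).
    """
    if D1.n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    v1, v2_check = _aligned_condensed(D1, D2)
    if np.std(v1) == 0 or np.std(v2_check) == 0:
        raise ValueError("constant distance matrix; correlation undefined")
    n = D1.n
    iu, ju = _triu_indices(n)
    z1 = (v1 - v1.mean()) / v1.std()
    M2 = D2.values
    v2 = M2[iu, ju]
    z2 = (v2 - v2.mean()) / v2.std()
    r_obs = float(np.mean(z1 * z2))

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = M2[perm[iu], perm[ju]]
        zp = (vp - vp.mean()) / vp.std()
        if abs(np.mean(z1 * zp)) >= abs(r_obs) - 1e-15:
            count += 1
    return MantelResult(r_obs, (count + 1) / (n_perm + 1), n_perm, seed)


def mrm(response_D: DistanceMatrix, predictor_Ds: dict[str, DistanceMatrix],
        n_perm: int = 9999, seed: int | None = None) -> MrmResult:
    """Multiple regression of one distance matrix on several others.

    Ordinary least squares on the vectorized upper triangles; significance
    of each slope and of R^2 by jointly permuting the rows and columns of
    the RESPONSE matrix and refitting.  Collinear predictors are rejected
    with the offending pair named.
    """
    if not predictor_Ds:
        raise ValueError("need at least one predictor matrix")
    names = list(predictor_Ds)
    mats = [predictor_Ds[k] for k in names]
    for m in mats:
        if m.ids != response_D.ids:
            raise ValueError("predictor labels must match the response matrix")
    X = np.column_stack([np.ones(len(response_D.condensed()))]
                        + [m.condensed() for m in mats])
    corr = np.corrcoef(X[:, 1:].T) if len(names) > 1 else None
    if corr is not None:
        off = np.abs(corr - np.eye(len(names)))
        if off.max() > 0.999:
            i, j = np.unravel_index(np.argmax(off), off.shape)
            raise ValueError(f"collinear predictors: {names[i]!r} and {names[j]!r}")

    n = response_D.n
    iu, ju = _triu_indices(n)
    M = response_D.values
    y = M[iu, ju]

    XtX_inv_Xt = np.linalg.pinv(X)

    def fit(yv):
        beta = XtX_inv_Xt @ yv
        resid = yv - X @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yv - yv.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        return beta, r2

    beta_obs, r2_obs = fit(y)
    rng = np.random.default_rng(seed)
    count_beta = np.zeros(len(names))
    count_r2 = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = M[perm[iu], perm[ju]]
        beta_p, r2_p = fit(yp)
        count_beta += np.abs(beta_p[1:]) >= np.abs(beta_obs[1:]) - 1e-15
        count_r2 += r2_p >= r2_obs - 1e-15
    p_beta = (count_beta + 1) / (n_perm + 1)
    return MrmResult(
        coefficients=pd.Series(beta_obs, index=["intercept"] + names),
        r_squared=r2_obs,
        p_values=pd.Series(p_beta, index=names),
        r_squared_p=(count_r2 + 1) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
    )


def axis_gradient_correlation(axis_values, coordinate_values) -> tuple[float, float]:
    """Pearson correlation between ordination scores and a map coordinate.

    Returns (r, two-sided t-test p).  Used for the longitude / latitude
    clines of the first PCoA axis.
    """
    a = np.asarray(axis_values, dtype=float)
    c = np.asarray(coordinate_values, dtype=float)
    if a.shape != c.shape or a.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.isnan(a).any() or np.isnan(c).any():
        raise ValueError("missing values in paired vectors")
    if np.std(a) == 0 or np.std(c) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(a, c)
    return float(r), float(p)


def climate_pc1_distance(climate: pd.DataFrame, scale: bool = True
                         ) -> tuple[DistanceMatrix, float]:
    """Distance on the first principal component of the climate block.

    ``climate`` has one row per landrace and 12 growing-season variables;
    variables are centred and (by default) unit-scaled, since temperatures
    and precipitations are incommensurable.  Rows with missing values must
    be excluded beforehand (PassportTable.climate does so).  Returns the
    |PC1_i - PC1_j| matrix and the percent variance PC1 explains.
    """
    X = climate.to_numpy(dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 complete climate rows")
    if np.isnan(X).any():
        raise ValueError("missing climate values; drop incomplete rows first")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        Xc = Xc[:, keep] / sd[keep]
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    pc1 = U[:, 0] * S[0]
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    pct = float(100.0 * S[0] ** 2 / np.sum(S ** 2))
    D = np.abs(pc1[:, None] - pc1[None, :])
    ids = [str(x) for x in climate.index]
    return DistanceMatrix(ids, D, "climate_pc1"), pct
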