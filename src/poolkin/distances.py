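"""Pairwise distance and differentiation statistics on frequency vectors.

Implements the modified Rogers distance (Euclidean distance between
allele-frequency vectors normalised to [0, 1]), Nei's Gst form of F_ST with
a landrace-permutation significance test, Rousset's F_ST/(1-F_ST)
linearization for isolation-by-distance regressions, and great-circle
geographic distances by the spherical law of cosines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_core import FrequencyMatrix, PassportTable, ValidationError

__all__ = [
    "DistanceMatrix",
    "FstResult",
    "modified_rogers",
    "pairwise_matrix",
    "fst_nei",
    "fst_permutation_test",
    "linearize_fst",
    "geographic_distance",
    "geographic_matrix",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.ids = [str(x) for x in self.ids]
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValidationError("duplicate ids in distance matrix")
        if not np.allclose(v, v.T, atol=1e-10, equal_nan=False):
            raise ValidationError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValidationError("diagonal is not zero")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        return squareform(self.values, checks=False)

    def submatrix(self, ids) -> "DistanceMatrix":
        index = {x: i for i, x in enumerate(self.ids)}
        idx = [index[x] for x in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.metric_name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_csv(self, path, metadata: dict | None = None) -> None:
        with open(path, "w") as fh:
            for key, val in (metadata or {}).items():
                fh.write(f"# {key}={val}\n")
            self.to_dataframe().to_csv(fh, index_label="id")

    @classmethod
    def read_csv(cls, path, metric_name: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, comment="#", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float), metric_name)

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per unordered pair."""
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                rows.append((self.ids[i], self.ids[j], self.values[i, j]))
        return pd.DataFrame(rows, columns=["id1", "id2", "value"])


@dataclass
class FstResult:
    """Nei's Gst between two groups of landrace frequency vectors.

    Hs is the mean of the two group expected heterozygosities (each from
    its mean member frequency), Ht the heterozygosity of their unweighted
    pooled mean; multilocus Gst aggregates as a ratio of sums.
    """

    Hs: float
    Ht: float
    Fst: float
    p_value: float | None = None


def modified_rogers(p1, p2) -> float:
    """Modified Rogers distance between two biallelic frequency vectors.

    d = sqrt( sum_l 2 (p1_l - p2_l)^2 / (2 L) ), i.e. the Euclidean
    distance between frequency vectors divided by sqrt(L); lies in [0, 1].
    """
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("frequency vectors must be 1-D, non-empty and equal length")
    return float(np.sqrt(np.sum((a - b) ** 2) / a.size))


def _check_complete(fm: FrequencyMatrix) -> None:
    if fm.has_missing:
        raise ValidationError("distance computations require a complete matrix; "
                              "apply filter_missing_loci first")


def _pairwise_fst_values(P: np.ndarray) -> np.ndarray:
    """Square matrix of pairwise Nei Gst between rows of P (vectorized).

    Uses the identity Ht_l - Hs_l = (p_i - p_j)^2 / 2 for the two-population
    unweighted-pool case, so the numerator is half the squared Euclidean
    distance and the denominator needs only row sums and a Gram matrix.
    """
    num = squareform(pdist(P, metric="sqeuclidean")) / 2.0
    s = P.sum(axis=1)                       # sum_l p_i
    G = P @ P.T                             # sum_l p_i p_j
    sq = np.diag(G)
    # sum_l 2 pbar (1 - pbar) with pbar = (p_i + p_j)/2
    denom = (s[:, None] + s[None, :]) - 0.5 * (sq[:, None] + 2.0 * G + sq[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(denom > 0, num / denom, np.nan)
    np.fill_diagonal(fst, 0.0)
    return fst


def pairwise_matrix(fm: FrequencyMatrix, metric: str = "modified_rogers") -> DistanceMatrix:
    """All-pairs distance matrix over landraces.

    metric 'modified_rogers' or 'fst_nei' (pairwise Gst treating each
    landrace as a population frequency vector).
    """
    _check_complete(fm)
    if fm.n_landraces < 2:
        raise ValueError("need at least 2 landraces")
    if metric == "modified_rogers":
        d = squareform(pdist(fm.values, metric="euclidean") / np.sqrt(fm.n_loci))
    elif metric == "fst_nei":
        d = _pairwise_fst_values(fm.values)
        if np.isnan(d).any():
            raise ValidationError("pairwise Gst undefined for a pair of identical "
                                  "fully monomorphic landraces")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(list(fm.landrace_ids), d, metric)


def _gst_from_group_means(pA: np.ndarray, pB: np.ndarray) -> tuple[float, float, float]:
    heA = 2.0 * pA * (1.0 - pA)
    heB = 2.0 * pB * (1.0 - pB)
    hs_l = 0.5 * (heA + heB)
    pbar = 0.5 * (pA + pB)
    ht_l = 2.0 * pbar * (1.0 - pbar)
    ht_sum = float(ht_l.sum())
    hs_sum = float(hs_l.sum())
    if ht_sum <= 0.0:
        raise ValidationError("Gst undefined: total heterozygosity is zero "
                              "(all loci monomorphic and identical)")
    L = pA.size
    return hs_sum / L, ht_sum / L, (ht_sum - hs_sum) / ht_sum


def fst_nei(groupA_rows, groupB_rows) -> FstResult:
    """Nei's Gst between two groups given as stacked landrace frequency rows.

    Each group enters as its mean frequency vector (bulk semantics); loci
    with zero total heterozygosity contribute to neither sum.
    """
    A = np.atleast_2d(np.asarray(groupA_rows, dtype=float))
    B = np.atleast_2d(np.asarray(groupB_rows, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("both groups must be non-empty")
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups genotyped at different numbers of loci")
    hs, ht, fst = _gst_from_group_means(A.mean(axis=0), B.mean(axis=0))
    return FstResult(hs, ht, fst)


def fst_permutation_test(
    fm: FrequencyMatrix,
    labelsA,
    labelsB,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[FstResult, float]:
    """Permutation test of group differentiation.

    Landrace group labels are permuted ``n_perm`` times, the two-group Gst
    recomputed each time, and p = (#{Gst_perm >= Gst_obs} + 1)/(n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    labelsA, labelsB = list(labelsA), list(labelsB)
    if not labelsA or not labelsB:
        raise ValueError("degenerate groups")
    _check_complete(fm)
    rowsA = fm.rows(labelsA)
    rowsB = fm.rows(labelsB)
    obs = fst_nei(rowsA, rowsB)
    pool = np.vstack([rowsA, rowsB])
    nA = len(labelsA)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool.shape[0])
        f = fst_nei(pool[perm[:nA]], pool[perm[nA:]]).Fst
        if f >= obs.Fst:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return FstResult(obs.Hs, obs.Ht, obs.Fst, p), p


def linearize_fst(fst):
    """Rousset's linearization F_ST / (1 - F_ST), elementwise on arrays."""
    f = np.asarray(fst, dtype=float)
    if np.any(f >= 1.0):
        raise ValueError("linearization undefined at F_ST = 1")
    out = f / (1.0 - f)
    return float(out) if np.isscalar(fst) or out.ndim == 0 else out


def geographic_distance(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km by the spherical law of cosines.

    The arccos argument is clamped to [-1, 1] so antipodal or identical
    points survive floating-point rounding.
    """
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(lon2 - lon1)
    arg = np.sin(phi1) * np.sin(phi2) + np.cos(phi1) * np.cos(phi2) * np.cos(dlam)
    return float(EARTH_RADIUS_KM * np.arccos(np.clip(arg, -1.0, 1.0)))


def geographic_matrix(passport: PassportTable) -> DistanceMatrix:
    """Pairwise great-circle km over the georeferenced landraces only."""
    coords = passport.coordinates()
    if len(coords) < 2:
        raise ValueError("need at least 2 georeferenced landraces")
    phi = np.radians(coords["latitude"].to_numpy())
    lam = np.radians(coords["longitude"].to_numpy())
    arg = (np.sin(phi)[:, None] * np.sin(phi)[None, :]
           + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.cos(lam[:, None] - lam[None, :]))
    d = EARTH_RADIUS_KM * np.arccos(np.clip(arg, -1.0, 1.0))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(coords.index), d, "geographic_km")
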