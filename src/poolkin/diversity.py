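"""Per-landrace and per-group diversity statistics for biallelic frequency data.

For a biallelic SNP with reference-allele frequency p, expected
heterozygosity (Nei's gene diversity) is He = 2p(1-p), at most 0.5, and a
locus contributes 2 alleles to allelic richness when 0 < p < 1 and 1 when
fixed — hence the identity Ar = 1 + proportion of polymorphic loci.
Group-level He is computed from group mean frequencies (each landrace is a
bulk frequency vector), and allelic richness is compared across groups of
unequal size by rarefaction over landraces: repeated subsampling of g
landraces without replacement, counting alleles present in the subsample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .io_core import FrequencyMatrix

__all__ = [
    "DiversityRecord",
    "GroupDiversity",
    "landrace_stats",
    "diversity_table",
    "group_he",
    "rarefied_group_ar",
    "paired_rank_test",
]


@dataclass
class DiversityRecord:
    landrace_id: str
    Ar: float          # mean alleles per locus, in [1, 2]
    He: float          # mean 2p(1-p), in [0, 0.5]
    prop_poly: float   # fraction of loci with 0 < p < 1


@dataclass
class GroupDiversity:
    group_label: str
    n_landraces: int
    He_group: float
    Ar_rarefied: float
    Ar_sd: float
    rarefaction_g: int
    n_resamples: int
    exhaustive: bool


def landrace_stats(freqs: np.ndarray, landrace_id: str = "", eps: float = 0.0) -> DiversityRecord:
    """Allelic richness, gene diversity and polymorphism rate of one landrace.

    ``eps`` widens the fixation call: a locus counts as polymorphic when
    eps < p < 1 - eps.
    """
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if np.isnan(p).any():
        raise ValueError("missing values; filter loci first")
    he = float(np.mean(2.0 * p * (1.0 - p)))
    poly = (p > eps) & (p < 1.0 - eps)
    prop_poly = float(np.mean(poly))
    return DiversityRecord(landrace_id, 1.0 + prop_poly, he, prop_poly)


def diversity_table(fm: FrequencyMatrix, eps: float = 0.0) -> list[DiversityRecord]:
    return [landrace_stats(row, lid, eps) for lid, row in zip(fm.landrace_ids, fm.values)]


def group_he(fm: FrequencyMatrix, members) -> float:
    """Group gene diversity from frequencies averaged over member landraces.

    By concavity of 2p(1-p) this is at least the mean of the members'
    individual He values.
    """
    members = list(members)
    if not members:
        raise ValueError("empty member list")
    pbar = fm.rows(members).mean(axis=0)
    return float(np.mean(2.0 * pbar * (1.0 - pbar)))


def _allele_counts(rows: np.ndarray, eps: float) -> np.ndarray:
    """Per-locus allele count (1 or 2) of a set of landrace frequency rows.

    The reference allele is present when any member has p > eps; the
    alternate when any member has p < 1 - eps.
    """
    has_ref = (rows > eps).any(axis=0)
    has_alt = (rows < 1.0 - eps).any(axis=0)
    counts = has_ref.astype(int) + has_alt.astype(int)
    # a column of exact 0.5-eps ties cannot zero out: one allele is always seen
    return np.maximum(counts, 1)


def rarefied_group_ar(
    fm: FrequencyMatrix,
    members,
    g: int = 9,
    n_resamples: int = 1000,
    seed: int | None = None,
    eps: float = 0.0,
) -> GroupDiversity:
    """Rarefied allelic richness of a group by resampling g landraces.

    Each resample draws ``g`` member landraces without replacement and
    averages the per-locus allele count over loci; the rarefied Ar is the
    mean over resamples.  When the number of distinct subsets C(n, g) does
    not exceed ``n_resamples`` every subset is enumerated exactly — e.g. a
    group of 12 has only 220 possible draws of 9.
    """
    members = list(members)
    n = len(members)
    if g < 1:
        raise ValueError("g must be >= 1")
    if g > n:
        raise ValueError(f"subsample size g={g} exceeds group size {n}")
    rows = fm.rows(members)
    if np.isnan(rows).any():
        raise ValueError("missing values; filter loci first")

    n_subsets = comb(n, g)
    exhaustive = n_subsets <= n_resamples
    if exhaustive:
        subsets = combinations(range(n), g)
        n_used = n_subsets
    else:
        rng = np.random.default_rng(seed)
        subsets = (rng.choice(n, size=g, replace=False) for _ in range(n_resamples))
        n_used = n_resamples

    ars = np.empty(n_used)
    for k, idx in enumerate(subsets):
        ars[k] = _allele_counts(rows[list(idx)], eps).mean()
    he = group_he(fm, members)
    return GroupDiversity(
        group_label="",
        n_landraces=n,
        He_group=he,
        Ar_rarefied=float(ars.mean()),
        Ar_sd=float(ars.std(ddof=1)) if n_used > 1 else 0.0,
        rarefaction_g=g,
        n_resamples=n_used,
        exhaustive=exhaustive,
    )


def paired_rank_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-locus statistics.

    Zero differences are dropped (Wilcoxon's original treatment); the
    normal approximation is used for large samples.  If every difference
    is zero the test is vacuous: returns (0, 1) with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("paired vectors must be non-empty and equal length")
    if np.all(a == b):
        warnings.warn("all paired differences are zero; test is vacuous")
        return 0.0, 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method="auto")
    return float(res.statistic), float(res.pvalue)
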