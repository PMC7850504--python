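"""Three-population admixture tests on group mean allele frequencies.

For a focal group X and references Y and W, the f3 statistic is the mean
over loci of (x_l - y_l)(x_l - w_l).  If X arose by mixing relatives of Y
and W, intermediate frequencies make the two factors systematically
opposite in sign and f3 goes negative; drift specific to X pushes it back
up.  Standard errors come from a delete-one block jackknife over
contiguous map-ordered blocks of loci, robust to local correlation along
the genome, and Z = f3/sd with Z < -2 flagged as significant admixture.

The plain product form is used by default; the small-sample bias
correction applied by sequence-based implementations needs within-
population sample sizes that DNA bulks obscure, so it is exposed as an
option (subtracting hX/(2n) with n the number of landraces in the focal
group) but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io_core import FrequencyMatrix, MarkerPanel

__all__ = ["F3Result", "group_frequencies", "f3_with_jackknife",
           "scan_admixture_scenarios"]

Z_THRESHOLD = -2.0


@dataclass
class F3Result:
    focal: str
    ref1: str
    ref2: str
    f3: float
    sd: float
    Z: float
    n_blocks: int
    n_loci: int

    @property
    def significant(self) -> bool:
        """The Z < -2 admixture decision rule."""
        return self.Z < Z_THRESHOLD


def group_frequencies(fm: FrequencyMatrix, members) -> np.ndarray:
    """Unweighted per-locus mean frequency over member landraces."""
    members = list(members)
    if not members:
        raise ValueError("empty member list")
    rows = fm.rows(members)
    if np.isnan(rows).any():
        raise ValueError("missing values; filter loci first")
    return rows.mean(axis=0)


def _block_bounds(n_loci: int, block_size: int) -> list[tuple[int, int]]:
    starts = range(0, n_loci, block_size)
    return [(s, min(s + block_size, n_loci)) for s in starts]


def f3_with_jackknife(
    x,
    y,
    w,
    block_size_loci: int = 500,
    labels: tuple[str, str, str] = ("X", "Y", "W"),
    bias_correct_n: int | None = None,
) -> F3Result:
    """f3(X; Y, W) with a delete-one-block jackknife standard error.

    Loci must already be in genetic-map order; they are partitioned into
    contiguous blocks of ``block_size_loci`` (the last block may be short).
    ``bias_correct_n`` optionally subtracts the heterozygosity-based
    within-focal correction hX/(2 n) per locus.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.shape == y.shape == w.shape) or x.ndim != 1:
        raise ValueError("frequency vectors must be 1-D and equal length")
    L = x.size
    terms = (x - y) * (x - w)
    if bias_correct_n is not None:
        terms = terms - x * (1.0 - x) / (2.0 * bias_correct_n)
    bounds = _block_bounds(L, block_size_loci)
    B = len(bounds)
    if B < 2:
        raise ValueError(
            f"{L} loci give {B} block(s) of {block_size_loci}; the jackknife "
            "sd needs at least 2"
        )
    total = terms.sum()
    f3 = total / L
    loo = np.empty(B)
    for b, (s, e) in enumerate(bounds):
        nb = e - s
        loo[b] = (total - terms[s:e].sum()) / (L - nb)
    sd = float(np.sqrt((B - 1) / B * np.sum((loo - loo.mean()) ** 2)))
    if sd == 0.0:
        # only reachable when every block agrees exactly, e.g. the focal
        # group IS one of the references and every term is zero
        if f3 == 0.0:
            return F3Result(labels[0], labels[1], labels[2], 0.0, 0.0, 0.0, B, L)
        raise ValueError("degenerate jackknife: all leave-one-block estimates equal")
    return F3Result(labels[0], labels[1], labels[2], float(f3), sd,
                    float(f3 / sd), B, L)


def scan_admixture_scenarios(
    fm: FrequencyMatrix,
    group_membership: dict[str, list[str]],
    focal_groups,
    reference_groups,
    block_size_loci: int = 500,
    panel: MarkerPanel | None = None,
    bias_correct: bool = False,
) -> pd.DataFrame:
    """f3 tests for every focal group against each unordered reference pair.

    ``group_membership`` maps labels to landrace ids (when derived from a
    structure run, membership should already be restricted to landraces
    with top ancestry >= the purity cutoff).  If a marker panel is given,
    loci are re-ordered along the genetic map before blocking.  Rows are
    sorted by Z ascending; the ``significant`` column applies Z < -2 to
    negative-f3 rows.
    """
    work = fm
    if panel is not None:
        order = [lid for lid in panel.locus_ids if lid in set(fm.locus_ids)]
        work = fm.select_loci(order)
    means = {}
    for g in set(focal_groups) | set(reference_groups):
        members = group_membership.get(g, [])
        if not members:
            raise ValueError(f"group {g!r} is empty after cutoff filtering")
        means[g] = group_frequencies(work, members)

    rows = []
    for focal in focal_groups:
        n_focal = len(group_membership[focal])
        for r1, r2 in combinations([r for r in reference_groups if r != focal], 2):
            res = f3_with_jackknife(
                means[focal], means[r1], means[r2], block_size_loci,
                labels=(focal, r1, r2),
                bias_correct_n=n_focal if bias_correct else None,
            )
            rows.append({
                "focal": focal, "ref1": r1, "ref2": r2,
                "f3": res.f3, "sd": res.sd, "Z": res.Z,
                "n_blocks": res.n_blocks,
                "negative_f3": res.f3 < 0.0,
                "significant": res.significant,
            })
    return pd.DataFrame(rows).sort_values("Z", kind="stable").reset_index(drop=True)
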