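"""Ancestry-cluster inference for bulk frequency panels.

Model-based clustering software for individual genotypes cannot consume a
bulk frequency matrix directly, so the pipeline (i) thins the SNP panel to
one marker per genetic-map window to limit linkage disequilibrium,
(ii) simulates a few haploid genotypes per landrace from its allele
frequencies under Hardy-Weinberg equilibrium, and (iii) fits the standard
K-cluster admixture likelihood to those haploids:

    log L = sum_i sum_l log( sum_k q_ik [ g_il p_kl + (1-g_il)(1-p_kl) ] )

with q_ik the ancestry fraction of haploid i in cluster k and p_kl the
cluster allele frequency.  The likelihood is maximised by EM (monotone by
construction); the optimiser differs from the quasi-Newton block relaxation
of the ADMIXTURE program but targets the same model.  Model choice across
K uses the Evanno delta-K heuristic on replicate runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import FrequencyMatrix, MarkerPanel

__all__ = [
    "HaploidPanel",
    "AncestryResult",
    "LikelihoodTable",
    "thin_by_windows",
    "simulate_haploids",
    "admixture_em",
    "structure_scan",
    "evanno_deltak",
    "assign_groups",
]


@dataclass
class HaploidPanel:
    """Binary pseudo-haploid genotypes, n_rep rows per source landrace."""

    sample_ids: list[str]           # "<landrace>#<replicate>"
    landrace_of: list[str]          # source landrace per row
    genotypes: np.ndarray           # samples x loci in {0, 1}
    locus_ids: list[str]

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if not np.isin(g, (0, 1)).all():
            raise ValueError("haploid genotypes must be binary")
        self.genotypes = g.astype(np.int8)

    @property
    def landrace_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for lid in self.landrace_of:
            seen.setdefault(lid, None)
        return list(seen)


@dataclass
class AncestryResult:
    K: int
    sample_ids: list[str]
    Q: np.ndarray                     # samples x K, rows sum to 1
    P: np.ndarray                     # K x loci, in [0, 1]
    loglik: float
    n_iter: int
    converged: bool
    seed: int | None
    landrace_ids: list[str] = field(default_factory=list)
    Q_landrace: np.ndarray | None = None
    loglik_trace: np.ndarray | None = None


@dataclass
class LikelihoodTable:
    """Replicate-run log-likelihoods per K, feeding the Evanno computation."""

    table: pd.DataFrame               # columns: K, replicate, loglik, seed

    def mean_sd(self) -> pd.DataFrame:
        g = self.table.groupby("K")["loglik"]
        return pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1)})


def thin_by_windows(panel: MarkerPanel, n_windows: int = 2500,
                    seed: int | None = None) -> list[str]:
    """One randomly chosen SNP per non-empty equal-cM map window.

    The total map length is divided into ``n_windows`` contiguous windows
    allocated to chromosomes proportionally to their map length (largest
    remainder rounding, at least one window per chromosome); within each
    chromosome, windows are equal-width in cM.  Returns locus ids in map
    order; empty windows contribute nothing.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    rng = np.random.default_rng(seed)
    t = panel.table
    chroms = t["chromosome"].unique()
    spans = {}
    for c in chroms:
        pos = t.loc[t["chromosome"] == c, "position_cM"].to_numpy()
        spans[c] = max(pos.max() - pos.min(), 0.0)
    total = sum(spans.values())
    if total <= 0:
        # degenerate map (all loci colocated): a single window per chromosome
        alloc = {c: 1 for c in chroms}
    else:
        raw = {c: n_windows * spans[c] / total for c in chroms}
        alloc = {c: max(int(np.floor(raw[c])), 1) for c in chroms}
        remainder = n_windows - sum(alloc.values())
        if remainder > 0:
            order = sorted(chroms, key=lambda c: raw[c] - np.floor(raw[c]), reverse=True)
            for c in order[:remainder]:
                alloc[c] += 1

    chosen: list[str] = []
    for c in chroms:
        sub = t[t["chromosome"] == c]
        pos = sub["position_cM"].to_numpy()
        ids = sub["locus_id"].to_numpy()
        k = alloc[c]
        lo, hi = pos.min(), pos.max()
        if hi == lo:
            chosen.append(str(rng.choice(ids)))
            continue
        edges = np.linspace(lo, hi, k + 1)
        bins = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, k - 1)
        for w in range(k):
            members = ids[bins == w]
            if members.size:
                chosen.append(str(rng.choice(members)))
    order = {lid: i for i, lid in enumerate(panel.locus_ids)}
    chosen.sort(key=order.__getitem__)
    return chosen


def simulate_haploids(fm: FrequencyMatrix, n_rep: int = 5,
                      seed: int | None = None) -> HaploidPanel:
    """Draw pseudo-haploid genotypes from landrace frequencies.

    Each of the ``n_rep`` haploids per landrace carries allele 1 at locus l
    independently with probability p_l (Hardy-Weinberg, no linkage).
    """
    if fm.has_missing:
        raise ValueError("haploid simulation requires a complete matrix")
    rng = np.random.default_rng(seed)
    n, L = fm.values.shape
    G = (rng.random((n, n_rep, L)) < fm.values[:, None, :]).astype(np.int8)
    sample_ids = [f"{lid}#{r}" for lid in fm.landrace_ids for r in range(n_rep)]
    landrace_of = [lid for lid in fm.landrace_ids for _ in range(n_rep)]
    return HaploidPanel(sample_ids, landrace_of, G.reshape(n * n_rep, L),
                        list(fm.locus_ids))


def _loglik(G: np.ndarray, Q: np.ndarray, P: np.ndarray) -> float:
    F = Q @ P                       # samples x loci: P(allele 1)
    lik = np.where(G == 1, F, 1.0 - F)
    return float(np.log(np.clip(lik, 1e-300, None)).sum())


def admixture_em(
    hp: HaploidPanel,
    K: int,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> AncestryResult:
    """Fit the K-cluster admixture likelihood to haploid genotypes by EM.

    ``tol`` is the relative log-likelihood gain below which iteration
    stops.  Per-landrace ancestry (Q_landrace) is the mean of the
    landrace's replicate haploid rows.  K = 1 is solved in closed form
    (P = genotype column means, Q = 1).
    """
    G = hp.genotypes.astype(float)
    n, L = G.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the {n} haploid samples")
    rng = np.random.default_rng(seed)

    if K == 1:
        P = G.mean(axis=0, keepdims=True)
        Q = np.ones((n, 1))
        ll = _loglik(G, Q, P)
        return _finish(hp, K, Q, P, ll, 0, True, seed, np.array([ll]))

    Q = rng.dirichlet(np.ones(K), size=n)
    P = np.clip(rng.random((K, L)) * 0.8 + 0.1, 1e-6, 1 - 1e-6)

    trace = []
    prev = -np.inf
    converged = False
    eps = 1e-12
    for it in range(1, max_iter + 1):
        # E-step responsibilities r_ilk computed implicitly via two moments
        F = Q @ P                               # n x L
        F = np.clip(F, eps, 1 - eps)
        # A_ilk = q_ik p_kl / F_il   (for g=1), q_ik (1-p_kl)/(1-F_il) (g=0)
        W1 = G / F                              # n x L
        W0 = (1.0 - G) / (1.0 - F)
        # expected counts for Q update: sum_l r_ilk
        R = Q * ((W1 @ P.T) + (W0 @ (1.0 - P).T))     # n x K
        Qn = R / L
        # P update numerator: sum_i r_ilk g_il = p_kl (Q^T W1)_kl
        Pnum = P * (Q.T @ W1)
        Pden = Pnum + (1.0 - P) * (Q.T @ W0)
        Pn = np.clip(Pnum / np.clip(Pden, eps, None), eps, 1 - eps)
        Q = Qn / Qn.sum(axis=1, keepdims=True)
        P = Pn
        ll = _loglik(G, Q, P)
        trace.append(ll)
        if prev > -np.inf and ll - prev <= tol * abs(prev):
            converged = True
            break
        prev = ll
    return _finish(hp, K, Q, P, trace[-1], len(trace), converged, seed,
                   np.asarray(trace))


def _finish(hp, K, Q, P, ll, n_iter, converged, seed, trace) -> AncestryResult:
    landraces = hp.landrace_ids
    lid_arr = np.asarray(hp.landrace_of)
    Ql = np.vstack([Q[lid_arr == lid].mean(axis=0) for lid in landraces])
    return AncestryResult(K, list(hp.sample_ids), Q, np.clip(P, 0.0, 1.0),
                          ll, n_iter, converged, seed, landraces, Ql, trace)


def structure_scan(
    hp: HaploidPanel,
    k_values,
    n_replicates: int = 5,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> tuple[dict[int, AncestryResult], LikelihoodTable]:
    """Replicate EM runs over a contiguous K range.

    Returns the best run (highest log-likelihood) per K plus the full
    replicate log-likelihood table used for delta-K.
    """
    k_values = sorted(k_values)
    ss = np.random.SeedSequence(seed)
    rows = []
    best: dict[int, AncestryResult] = {}
    for K in k_values:
        for rep in range(n_replicates):
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            res = admixture_em(hp, K, seed=sub_seed, tol=tol, max_iter=max_iter)
            rows.append({"K": K, "replicate": rep, "loglik": res.loglik,
                         "seed": sub_seed})
            if K not in best or res.loglik > best[K].loglik:
                best[K] = res
    return best, LikelihoodTable(pd.DataFrame(rows))


def evanno_deltak(lt: LikelihoodTable) -> pd.DataFrame:
    """Evanno's delta-K from replicate log-likelihoods.

    delta K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)), the absolute second
    difference of the mean log-likelihood scaled by the replicate standard
    deviation; undefined at the boundary K values and flagged NaN where
    the replicate sd is zero.
    """
    ms = lt.mean_sd()
    ks = np.asarray(sorted(ms.index))
    if len(ks) < 3 or np.any(np.diff(ks) != 1):
        raise ValueError("delta-K needs a contiguous range of at least 3 K values")
    counts = lt.table.groupby("K").size()
    if (counts < 2).any():
        raise ValueError("delta-K needs >= 2 replicate runs per K")
    out = []
    for k in ks[1:-1]:
        second = abs(ms.loc[k + 1, "mean"] - 2.0 * ms.loc[k, "mean"]
                     + ms.loc[k - 1, "mean"])
        sd = ms.loc[k, "sd"]
        if sd == 0:
            warnings.warn(f"replicate sd is zero at K={k}; delta-K undefined there")
            dk = np.nan
        else:
            dk = second / sd
        out.append({"K": int(k), "mean_loglik": ms.loc[k, "mean"],
                    "sd_loglik": sd, "delta_k": dk})
    return pd.DataFrame(out)


def best_k(deltak: pd.DataFrame) -> int:
    """K maximising delta-K (NaN rows ignored)."""
    valid = deltak.dropna(subset=["delta_k"])
    if valid.empty:
        raise ValueError("delta-K undefined at every interior K")
    return int(valid.loc[valid["delta_k"].idxmax(), "K"])


def assign_groups(ar: AncestryResult, cutoff: float = 0.7) -> pd.DataFrame:
    """Assign each landrace to its majority cluster.

    ``is_pure`` marks landraces whose top ancestry fraction reaches the
    cutoff (default 0.7); ties go to the lowest cluster index with a
    warning.
    """
    if ar.Q_landrace is None:
        raise ValueError("ancestry result lacks per-landrace Q")
    Q = ar.Q_landrace
    if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("ancestry rows do not sum to 1")
    top = Q.argmax(axis=1)
    rows = []
    for i, lid in enumerate(ar.landrace_ids):
        q = Q[i]
        ties = np.flatnonzero(q == q[top[i]])
        if ties.size > 1:
            warnings.warn(f"ancestry tie for landrace {lid!r}; "
                          f"assigned to cluster {int(ties[0])}")
        k = int(ties[0])
        rows.append({"landrace_id": lid, "cluster": k,
                     "max_ancestry": float(q[k]),
                     "is_pure": bool(q[k] >= cutoff)})
    return pd.DataFrame(rows)
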