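"""Ordination and tree building: PCoA, PCA with supplementary rows, NJ.

PCoA follows Gower: double-centre -D^2/2, eigendecompose, scale
eigenvectors by sqrt(eigenvalue); percent inertia is taken over positive
eigenvalues only.  PCA centres columns by the active-set means (no
variance scaling by default) and projects supplementary rows onto the
active axes — the device used to place European landraces relative to the
American reference groups without letting them shape the axes.
Neighbor joining is the Saitou-Nei agglomeration with the
Studier-Keppler Q criterion and deterministic lowest-index tie-breaking.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .distances import DistanceMatrix
from .io_core import FrequencyMatrix

__all__ = [
    "OrdinationResult",
    "pcoa",
    "pca_with_supplementary",
    "neighbor_joining",
    "write_newick",
    "read_newick",
    "tree_path_distances",
]


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray          # samples x axes
    eigenvalues: np.ndarray          # descending
    percent_inertia: np.ndarray      # per retained axis
    supplementary_ids: list[str] = field(default_factory=list)
    supplementary_coordinates: np.ndarray | None = None
    negative_eigenvalues: np.ndarray | None = None


def _orient_axes(coords: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Sign convention: flip each axis so its largest-|entry| is positive.

    Returns the per-axis sign vector; ``reference`` (e.g. loadings) can
    supply the entries used for orientation instead of the scores.
    """
    ref = coords if reference is None else reference
    signs = np.ones(ref.shape[1])
    for k in range(ref.shape[1]):
        col = ref[:, k]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            signs[k] = -1.0
    return signs


def pcoa(D: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinate analysis of a distance matrix.

    Negative eigenvalues (non-Euclidean input) are excluded from the
    inertia denominator and reported separately; for the modified Rogers
    distance none arise because it embeds in Euclidean space.
    """
    d = D.values
    n = D.n
    B = -0.5 * d ** 2
    B = B - B.mean(axis=0, keepdims=True) - B.mean(axis=1, keepdims=True) + B.mean()
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(1e-10, 1e-10 * max(abs(evals[0]), 1.0))
    pos = evals > tol
    n_pos = int(pos.sum())
    if n_axes is None:
        n_axes = n_pos
    if n_axes > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating from {n_axes}")
        n_axes = n_pos
    lam = evals[:n_axes]
    coords = evecs[:, :n_axes] * np.sqrt(lam)
    coords = coords * _orient_axes(coords)
    inertia = 100.0 * lam / evals[pos].sum() if n_pos else np.zeros(0)
    return OrdinationResult(
        sample_ids=list(D.ids),
        coordinates=coords,
        eigenvalues=lam,
        percent_inertia=inertia,
        negative_eigenvalues=evals[evals < -tol],
    )


def pca_with_supplementary(
    active: FrequencyMatrix,
    supplementary: FrequencyMatrix | None = None,
    scale: bool = False,
    n_axes: int | None = None,
) -> OrdinationResult:
    """PCA of the active rows; supplementary rows projected onto its axes.

    Columns are centred (and optionally unit-scaled) using ACTIVE-set
    statistics only, for both active scores and supplementary projections;
    percent variance comes from the active eigenvalues.
    """
    if supplementary is not None and supplementary.locus_ids != active.locus_ids:
        raise ValueError("active and supplementary panels must share loci in order")
    X = active.values
    if np.isnan(X).any() or (supplementary is not None and supplementary.has_missing):
        raise ValueError("PCA requires complete matrices")
    mu = X.mean(axis=0)
    Xc = X - mu
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    max_axes = int(np.sum(S > 1e-12 * max(S[0], 1.0))) if S.size else 0
    k = max_axes if n_axes is None else min(n_axes, max_axes)
    signs = _orient_axes(Vt[:k].T)
    scores = (U[:, :k] * S[:k]) * signs
    evals = S ** 2 / X.shape[0]
    inertia = 100.0 * evals[:k] / evals.sum()

    sup_ids: list[str] = []
    sup_coords = None
    if supplementary is not None:
        Y = supplementary.values - mu
        if scale:
            Y = Y / sd
        sup_coords = (Y @ Vt[:k].T) * signs
        sup_ids = list(supplementary.landrace_ids)
    return OrdinationResult(
        sample_ids=list(active.landrace_ids),
        coordinates=scores,
        eigenvalues=evals[:k],
        percent_inertia=inertia,
        supplementary_ids=sup_ids,
        supplementary_coordinates=sup_coords,
    )


def _clamp_branch_pair(li: float, lj: float) -> tuple[float, float]:
    # transfer any negative length to the sibling edge; the path li+lj is kept
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted scikit-bio tree.

    Ties in the Q criterion are broken by the lexicographically smallest
    (i, j) index pair, making the topology deterministic.  Negative branch
    lengths are set to zero with the deficit moved to the sibling edge.
    """
    if D.n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = D.values.astype(float).copy()
    nodes = [TreeNode(name=name) for name in D.ids]

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        Q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie break: argmin of flattened array scans row-major
        i, j = divmod(int(np.argmin(Q)), n)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        li, lj = _clamp_branch_pair(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # final star: three remaining nodes joined at an unrooted trifurcation
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    la, lb = _clamp_branch_pair(la, lb)
    lc = max(lc, 0.0)
    a.length, b.length, c.length = la, lb, lc
    root = TreeNode(children=[a, b, c])
    return root


_NEWICK_SPECIAL = set(" ()[]{}:;,'\t\n")


def _newick_label(name: str | None) -> str:
    if not name:
        return ""
    if set(name) & _NEWICK_SPECIAL:
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to a Newick string (branch lengths, ';' terminated).

    Labels containing spaces or other Newick metacharacters are quoted.
    """
    def render(node: TreeNode) -> str:
        if node.children:
            body = "(" + ",".join(render(c) for c in node.children) + ")"
        else:
            body = _newick_label(node.name)
        if node.length is not None:
            body += f":{node.length:.10g}"
        return body

    return render(tree) + ";"


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), format="newick",
                         convert_underscores=False)


def tree_path_distances(tree: TreeNode, ids) -> np.ndarray:
    """Patristic (path-length) distance matrix over the named leaves."""
    dm = tree.tip_tip_distances()
    idx = [list(map(str, dm.ids)).index(str(x)) for x in ids]
    return dm.data[np.ix_(idx, idx)]
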