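"""Reference Felsenstein pruning without repeat detection.

Conditional likelihood vectors (CLVs) are stored per inner node as an
array of shape ``(n_sites, n_categories, 4)``.  Tip CLVs follow directly
from the bitmask encoding: entry ``s`` is 1 iff state ``s`` is compatible
with the observed character.  Per-site scaling guards against underflow on
deep trees: whenever every entry of a site's CLV drops below 2**-256 the
site is multiplied by 2**256 and a per-site exponent counter is
incremented; the counters are folded back in when the log-likelihood is
assembled.  Rate categories carry equal weights 1/k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .models import SubstModel
from .trees import Node, Tree, TreeView, root_at_edge, root_at_terminal_edge

SCALE_THRESHOLD = 2.0 ** -256
SCALE_FACTOR = 2.0 ** 256
LOG_SCALE_STEP = 256.0 * np.log(2.0)

#: tip CLV for every encoded state 0..15 (row 0 unused)
TIP_CLV_TABLE = np.array(
    [[(code >> s) & 1 for s in range(4)] for code in range(16)], dtype=float
)


class UnderflowError(ArithmeticError):
    """A per-site likelihood evaluated to zero (or below)."""


def tip_clv(code: int) -> np.ndarray:
    """0/1 state vector for an encoded character: bit s set -> entry s is 1."""
    if not 1 <= code <= 15:
        raise ValueError(f"encoded state must lie in [1, 15], got {code}")
    return TIP_CLV_TABLE[code].copy()


@dataclass
class LikelihoodResult:
    """Log-likelihood (natural log) with its per-pattern decomposition."""

    log_likelihood: float
    per_site: np.ndarray      # per-pattern log-likelihood
    weights: np.ndarray       # pattern multiplicities


class CLVStore:
    """Per-inner-node CLV arrays plus per-site scaling exponents."""

    def __init__(self) -> None:
        self.clv: dict[int, np.ndarray] = {}     # node.index -> (n, k, 4)
        self.scale: dict[int, np.ndarray] = {}   # node.index -> (n,) int

    def set(self, node: Node, clv: np.ndarray, scale: np.ndarray) -> None:
        self.clv[node.index] = clv
        self.scale[node.index] = scale

    def get(self, node: Node) -> tuple[np.ndarray, np.ndarray]:
        return self.clv[node.index], self.scale[node.index]


def _check_taxa(view: TreeView, alignment: Alignment) -> dict[str, int]:
    rows = {t: i for i, t in enumerate(alignment.taxa)}
    missing = [t for t in view.taxa if t not in rows]
    if missing:
        raise ValueError(f"alignment lacks taxa {missing}")
    if len(view.taxa) != alignment.n_taxa:
        raise ValueError(
            f"tree has {len(view.taxa)} taxa but alignment has {alignment.n_taxa}"
        )
    return rows


def inner_clv(clv_v: np.ndarray, p_v: np.ndarray,
              clv_w: np.ndarray, p_w: np.ndarray) -> np.ndarray:
    """Combine two children into a parent CLV.

    ``clv_v``/``clv_w`` have shape ``(n, k, 4)`` (use :data:`TIP_CLV_TABLE`
    broadcast over categories for a tip child) and ``p_v``/``p_w`` are the
    per-category transition matrices ``(k, 4, 4)`` for the child edges.
    Returns the elementwise product of the two propagated terms.
    """
    left = np.einsum("kab,nkb->nka", p_v, clv_v)
    right = np.einsum("kab,nkb->nka", p_w, clv_w)
    return left * right


def _child_term(child: Node, P: np.ndarray, codes: np.ndarray | None,
                store: CLVStore) -> tuple[np.ndarray, np.ndarray | None]:
    """(sum_s' P[s,s'] L_child(s')) for all sites/categories: (n, k, 4)."""
    if child.is_tip:
        L = TIP_CLV_TABLE[codes]                      # (n, 4)
        return np.einsum("kab,nb->nka", P, L), None
    L, scale = store.get(child)
    return np.einsum("kab,nkb->nka", P, L), scale


def _rescale(clv: np.ndarray, scale: np.ndarray) -> None:
    site_max = clv.max(axis=(1, 2))
    mask = (site_max < SCALE_THRESHOLD) & (site_max > 0.0)
    if mask.any():
        clv[mask] *= SCALE_FACTOR
        scale[mask] += 1


def compute_clvs(view: TreeView, alignment: Alignment, model: SubstModel,
                 scaling: bool = True) -> CLVStore:
    """Post-order CLV computation for every inner node of ``view``."""
    rows = _check_taxa(view, alignment)
    store = CLVStore()
    n = alignment.n_sites
    for u in view.postorder_inner():
        terms = []
        scale = np.zeros(n, dtype=np.int64)
        for child in u.children:
            P = model.transition_matrices(child.edge_length)
            codes = alignment.data[rows[child.label]] if child.is_tip else None
            term, child_scale = _child_term(child, P, codes, store)
            terms.append(term)
            if child_scale is not None:
                scale += child_scale
        clv = terms[0] * terms[1]
        if scaling:
            _rescale(clv, scale)
        store.set(u, clv, scale)
    return store


def _assemble(site_like: np.ndarray, scale: np.ndarray,
              weights: np.ndarray) -> LikelihoodResult:
    if (site_like <= 0).any():
        bad = int(np.argmax(site_like <= 0))
        raise UnderflowError(
            f"per-site likelihood is not positive at site {bad + 1}"
        )
    per_site = np.log(site_like) - scale * LOG_SCALE_STEP
    return LikelihoodResult(
        log_likelihood=float((weights * per_site).sum()),
        per_site=per_site,
        weights=weights.copy(),
    )


def likelihood_rooted(view: TreeView, alignment: Alignment, model: SubstModel,
                      clvs: CLVStore | None = None) -> LikelihoodResult:
    """Likelihood of a rooted view: per site, the root CLV is averaged over
    rate categories (equal weights) and contracted with the stationary
    frequencies; site weights and scaling exponents are honoured in
    log space."""
    if clvs is None:
        clvs = compute_clvs(view, alignment, model)
    clv, scale = clvs.get(view.root)
    site_like = (clv @ model.frequencies).mean(axis=1)
    return _assemble(site_like, scale, alignment.weights)


def likelihood_edge(tree: Tree, edge, alignment: Alignment,
                    model: SubstModel) -> LikelihoodResult:
    """Likelihood of an unrooted tree evaluated at one of its edges.

    ``edge`` is either a taxon label (the pendant edge of that taxon) or a
    pair of vertex ids of :meth:`Tree.edges`.  Internally the tree is
    virtually rooted on the edge, which reproduces the edge evaluation
    exactly: the u-side subtree sits at distance 0 from the root, the
    v-side at the full edge length.
    """
    if isinstance(edge, str):
        view = root_at_terminal_edge(tree, edge)
    else:
        a, b = edge
        view = root_at_edge(tree, a, b)
    return likelihood_rooted(view, alignment, model)
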