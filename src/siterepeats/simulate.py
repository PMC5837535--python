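"""Synthetic alignments and random trees for experiments and tests.

The simulator draws root states from the stationary frequencies and evolves
them down the tree with the model's transition probabilities, one discrete
rate category per site.  Gaps and ambiguities are then injected i.i.d. by
masking: a gap replaces the character by complete uncertainty (15), an
ambiguity widens it to a random IUPAC superset containing the true base.
This emulates the gap/ambiguity content of empirical alignments but not
their block structure (indels are not modelled).  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .alignment import Alignment
from .models import SubstModel
from .trees import DirtySet, Tree, TreeView, mark_dirty, root_at_terminal_edge

#: for each true base bit, the ambiguity masks (>= 2 bits) containing it
_SUPERSETS = {
    bit: [m for m in range(3, 15) if (m & bit) and bin(m).count("1") >= 2]
    for bit in (1, 2, 4, 8)
}


@dataclass
class SimConfig:
    """Conditions for one synthetic data set."""

    n_taxa: int = 20
    n_sites: int = 300
    gap_fraction: float = 0.05
    ambiguity_fraction: float = 0.01
    mean_branch_length: float = 0.1
    seed: int = 0
    model: SubstModel = field(default_factory=lambda: SubstModel.jc(alpha=1.0,
                                                                    n_categories=4))

    def __post_init__(self) -> None:
        for name in ("gap_fraction", "ambiguity_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.n_taxa < 2 or self.n_sites < 1:
            raise ValueError("need at least 2 taxa and 1 site")

    def describe(self) -> dict:
        d = asdict(self)
        d["model"] = {
            "frequencies": list(map(float, self.model.frequencies)),
            "exchangeabilities": list(map(float, self.model.exchangeabilities)),
            "alpha": self.model.alpha,
            "n_categories": self.model.n_categories,
        }
        return d


def random_tree(n_taxa: int, seed=0, mean_branch_length: float = 0.1) -> Tree:
    """Random unrooted binary tree via sequential attachment of tips to a
    uniformly chosen edge; branch lengths are i.i.d. exponential."""
    if n_taxa < 3:
        raise ValueError("an unrooted binary tree needs at least 3 taxa")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    labels = {}
    adj: dict[int, set[int]] = {}

    def add(label=None):
        vid = len(labels)
        labels[vid] = label
        adj[vid] = set()
        return vid

    def link(a, b):
        adj[a].add(b)
        adj[b].add(a)

    center = add()
    for t in range(3):
        link(center, add(f"t{t + 1}"))
    edges = [(center, v) for v in list(adj[center])]
    for t in range(3, n_taxa):
        a, b = edges[rng.integers(len(edges))]
        adj[a].discard(b)
        adj[b].discard(a)
        x = add()
        tip = add(f"t{t + 1}")
        link(a, x)
        link(x, b)
        link(x, tip)
        edges.remove((a, b))
        edges.extend([(a, x), (x, b), (x, tip)])
    full_adj = {}
    lengths = {}
    for v in adj:
        full_adj[v] = []
    for v in adj:
        for w in adj[v]:
            if v < w:
                lengths[(v, w)] = float(rng.exponential(mean_branch_length))
    for (v, w), l in lengths.items():
        full_adj[v].append((w, l))
        full_adj[w].append((v, l))
    return Tree(labels, full_adj, base=center, is_rooted=False)


def simulate_alignment(cfg: SimConfig, tree: Tree | TreeView) -> Alignment:
    """Evolve sequences along ``tree`` under ``cfg`` (see module docstring)."""
    rng = np.random.default_rng(cfg.seed)
    if isinstance(tree, TreeView):
        view = tree
    elif tree.is_rooted:
        view = tree.view()
    else:
        view = root_at_terminal_edge(tree, tree.taxa[0])
    model = cfg.model
    n = cfg.n_sites
    k = model.n_categories
    cats = rng.integers(k, size=n)
    states: dict[int, np.ndarray] = {
        view.root.index: rng.choice(4, size=n, p=model.frequencies)
    }
    # pre-order: parents before children
    for nd in reversed(view.nodes):
        if nd.parent is None:
            continue
        P = model.transition_matrices(nd.edge_length)  # (k, 4, 4)
        parent = states[nd.parent.index]
        out = np.empty(n, dtype=np.int64)
        for c in range(k):
            for s in range(4):
                mask = (cats == c) & (parent == s)
                cnt = int(mask.sum())
                if cnt:
                    out[mask] = rng.choice(4, size=cnt, p=P[c, s])
        states[nd.index] = out

    taxa = view.taxa
    data = np.empty((len(taxa), n), dtype=np.int64)
    for r, tip in enumerate(view.tips):
        codes = np.left_shift(1, states[tip.index])
        amb = rng.random(n) < cfg.ambiguity_fraction
        for i in np.nonzero(amb)[0]:
            options = _SUPERSETS[int(codes[i])]
            codes[i] = options[rng.integers(len(options))]
        gap = rng.random(n) < cfg.gap_fraction
        codes[gap] = 15
        data[r] = codes
    return Alignment(taxa=list(taxa), data=data)


def simulate_dataset(cfg: SimConfig) -> tuple[Tree, Alignment]:
    """Random tree plus an alignment evolved on it, from one seed."""
    tree = random_tree(cfg.n_taxa, seed=cfg.seed,
                       mean_branch_length=cfg.mean_branch_length)
    return tree, simulate_alignment(cfg, tree)


def random_walk_dirty(view: TreeView, rng, p_continue: float = 0.95) -> DirtySet:
    """Dirty set from a random walk over adjacent inner nodes.

    Starts from a random pair of adjacent inner nodes and keeps extending
    the selection to unvisited adjacent inner nodes with probability
    ``p_continue`` (default 0.95), then closes the set upward.  This is the
    update pattern produced by local topological rearrangements during tree
    search.
    """
    inner = view.postorder_inner()
    if len(inner) < 2:
        return mark_dirty(view, [view.root])

    def neighbours(nd):
        out = [c for c in nd.children if not c.is_tip]
        if nd.parent is not None:
            out.append(nd.parent)
        return out

    candidates = [nd for nd in inner if any(not n.is_tip for n in neighbours(nd))]
    start = candidates[rng.integers(len(candidates))]
    nbrs = [n for n in neighbours(start) if not n.is_tip]
    second = nbrs[rng.integers(len(nbrs))]
    visited = {start.index: start, second.index: second}
    frontier = [start, second]
    while frontier and rng.random() < p_continue:
        new_frontier = []
        for nd in frontier:
            options = [n for n in neighbours(nd)
                       if not n.is_tip and n.index not in visited]
            if options:
                pick = options[rng.integers(len(options))]
                visited[pick.index] = pick
                new_frontier.append(pick)
        frontier = new_frontier[:2]
    return mark_dirty(view, list(visited.values()))
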