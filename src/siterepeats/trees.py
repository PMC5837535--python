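"""Phylogenetic trees and rooted binary traversal views.

A parsed :class:`Tree` keeps the topology as an undirected graph so the
likelihood can be evaluated from any virtual rooting.  A :class:`TreeView`
is a strictly binary rooted orientation of that graph: every inner node has
exactly two children, nodes are enumerated in post-order (children before
parents, so traversals always start at a cherry), and a rooted tree over
``m`` tips has exactly ``2m - 1`` nodes.

Virtual rooting convention: rooting "on an edge (a, b)" places the root at
the a-side end of the edge, i.e. the root's two children are the a-side
subtree at distance 0 and the b-side subtree at the full edge length.  For
a reversible substitution model the likelihood does not depend on this
choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy


class TreeError(ValueError):
    """Raised for malformed trees or invalid tree operations."""


class Node:
    """One node of a rooted binary view."""

    __slots__ = ("index", "label", "vid", "parent", "children", "edge_length")

    def __init__(self, label=None, vid=None, edge_length=0.0):
        self.index: int = -1          # post-order position within the view
        self.label = label            # taxon label for tips, optional otherwise
        self.vid = vid                # vertex id in the underlying graph
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.edge_length: float = edge_length  # length of the edge to parent

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else "inner"
        return f"<Node {self.index} {kind} {self.label or ''}>"


class TreeView:
    """Rooted binary traversal view: post-order node list plus tip mapping."""

    def __init__(self, root: Node):
        self.root = root
        self.nodes: list[Node] = []
        self._index_postorder()
        self.tips = [nd for nd in self.nodes if nd.is_tip]
        self.inner = [nd for nd in self.nodes if not nd.is_tip]
        labels = [t.label for t in self.tips]
        if None in labels or len(set(labels)) != len(labels):
            raise TreeError("tips must carry unique labels")
        self.taxon_to_tip = {t.label: t for t in self.tips}

    def _index_postorder(self) -> None:
        order: list[Node] = []
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            nd, done = stack.pop()
            if done:
                order.append(nd)
                continue
            stack.append((nd, True))
            for child in reversed(nd.children):
                child.parent = nd
                stack.append((child, False))
        self.root.parent = None
        for i, nd in enumerate(order):
            nd.index = i
            if nd.children and len(nd.children) != 2:
                raise TreeError("inner nodes of a view must have two children")
        self.nodes = order

    @property
    def n_taxa(self) -> int:
        return len(self.tips)

    @property
    def taxa(self) -> list[str]:
        return [t.label for t in self.tips]

    def postorder_inner(self) -> list[Node]:
        """Inner nodes in post-order (both children precede each node)."""
        return self.inner

    def subtree_tips(self, node: Node) -> list[str]:
        """Tip labels below ``node`` in post-order."""
        out = []
        stack = [node]
        while stack:
            nd = stack.pop()
            if nd.is_tip:
                out.append(nd.label)
            else:
                stack.extend(reversed(nd.children))
        return out

    def find_clade(self, labels) -> Node:
        """The node whose subtree tips are exactly ``labels``."""
        want = set(labels)
        for nd in self.nodes:
            if set(self.subtree_tips(nd)) == want:
                return nd
        raise TreeError(f"no node with tip set {sorted(want)}")

    def newick(self) -> str:
        return _subtree_newick(self.root) + ";"


def _subtree_newick(node: Node) -> str:
    # iterative so deep caterpillar trees do not exhaust the stack
    out: list[str] = []
    stack: list[tuple] = [("enter", node)]
    while stack:
        op, nd = stack.pop()
        if op == "lit":
            out.append(nd)
            continue
        suffix = (
            f":{format(nd.edge_length, '.10g')}" if nd.parent is not None else ""
        )
        if op == "enter":
            if nd.is_tip:
                out.append((nd.label or "") + suffix)
            else:
                out.append("(")
                stack.append(("exit", nd))
                for i, child in enumerate(reversed(nd.children)):
                    stack.append(("enter", child))
                    if i < len(nd.children) - 1:
                        stack.append(("lit", ","))
        else:  # exit an inner node
            out.append(")" + (nd.label or "") + suffix)
    return "".join(out)


class Tree:
    """A parsed tree: undirected graph plus the rooting state of the input.

    ``adj`` maps vertex id -> list of ``(neighbour_vid, edge_length)``;
    ``labels`` maps vertex id -> label (taxon label for tips).  ``base`` is
    the vertex the Newick string was written from: with two neighbours the
    input is a rooted binary tree, with three it is unrooted.
    """

    def __init__(self, labels, adj, base, is_rooted):
        self.labels: dict[int, str | None] = labels
        self.adj: dict[int, list[tuple[int, float]]] = adj
        self.base: int = base
        self.is_rooted: bool = is_rooted
        self.tip_vids: dict[str, int] = {
            labels[v]: v for v in adj if len(adj[v]) == 1
        }

    @property
    def taxa(self) -> list[str]:
        return list(self.tip_vids)

    @property
    def n_taxa(self) -> int:
        return len(self.tip_vids)

    def _unrooted_adj(self) -> dict[int, list[tuple[int, float]]]:
        """Adjacency with a degree-2 base (rooted input) suppressed."""
        if not self.is_rooted or len(self.adj[self.base]) != 2:
            return self.adj
        adj = {v: list(nbrs) for v, nbrs in self.adj.items()}
        (a, la), (b, lb) = adj.pop(self.base)
        adj[a] = [(x, l) for x, l in adj[a] if x != self.base] + [(b, la + lb)]
        adj[b] = [(x, l) for x, l in adj[b] if x != self.base] + [(a, la + lb)]
        return adj

    def edges(self) -> list[tuple[int, int, float]]:
        """Undirected edges (a, b, length) of the unrooted topology."""
        adj = self._unrooted_adj()
        out = []
        for v, nbrs in adj.items():
            for w, l in nbrs:
                if v < w:
                    out.append((v, w, l))
        return out

    def view(self) -> TreeView:
        """Rooted view at the input's own root (rooted input only)."""
        if not self.is_rooted:
            raise TreeError(
                "tree is unrooted; choose a rooting with root_at_terminal_edge"
            )
        root = _orient(self.adj, self.labels, self.base, parent_vid=None)
        return TreeView(root)

    def newick(self) -> str:
        root = _orient(self.adj, self.labels, self.base, parent_vid=None)
        root.parent = None
        return _subtree_newick(root) + ";"


def _orient(adj, labels, start, parent_vid, edge_length=0.0) -> Node:
    """Build an oriented Node subtree from ``start`` away from ``parent_vid``."""
    root = Node(label=labels.get(start), vid=start, edge_length=edge_length)
    stack = [(root, parent_vid)]
    while stack:
        node, pvid = stack.pop()
        for nbr, length in adj[node.vid]:
            if nbr == pvid:
                continue
            child = Node(label=labels.get(nbr), vid=nbr, edge_length=length)
            child.parent = node
            node.children.append(child)
            stack.append((child, node.vid))
    return root


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Multifurcations are resolved deterministically (leftmost pairing) by
    inserting zero-length edges; a trifurcating base is kept as the marker
    of an unrooted tree.  Missing branch lengths default to 0.0 with a
    warning.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeError(f"malformed Newick: {exc}") from None

    missing = [False]

    def length_of(edge) -> float:
        if edge.length is None:
            missing[0] = True
            return 0.0
        return float(edge.length)

    # nested (label, length, children) structure, built iteratively so deep
    # (caterpillar) trees do not exhaust the interpreter stack
    def make_rec(dnode, is_base=False):
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        length = 0.0 if is_base else length_of(dnode.edge)
        return [label, length, []]

    base = make_rec(dtree.seed_node, is_base=True)
    stack = [(dtree.seed_node, base)]
    while stack:
        dnode, rec = stack.pop()
        for c in dnode.child_nodes():
            crec = make_rec(c)
            rec[2].append(crec)
            stack.append((c, crec))
    if missing[0]:
        warnings.warn("missing branch lengths default to 0.0", stacklevel=2)

    def resolve(rec, keep: int) -> None:
        work = [(rec, keep)]
        while work:
            r, k = work.pop()
            children = r[2]
            while len(children) > k:
                merged = [None, 0.0, children[:2]]
                children = [merged] + children[2:]
            r[2] = children
            for c in r[2]:
                if c[2]:
                    work.append((c, 2))

    n_base_children = len(base[2])
    if n_base_children == 0:
        raise TreeError("tree has a single node")
    if n_base_children == 1:
        # degenerate outer parentheses; descend
        inner = base[2][0]
        inner[1] = 0.0
        base = inner
        n_base_children = len(base[2])
        if n_base_children == 0:
            raise TreeError("tree has fewer than two taxa")
    is_rooted = n_base_children == 2
    resolve(base, 2 if is_rooted else 3)

    # flatten to the undirected graph
    labels: dict[int, str | None] = {}
    adj: dict[int, list[tuple[int, float]]] = {}
    counter = [0]

    def add_vertex(label):
        vid = counter[0]
        counter[0] += 1
        labels[vid] = label
        adj[vid] = []
        return vid

    def build(rec, parent_vid):
        work = [(rec, parent_vid)]
        top_vid = None
        while work:
            r, pvid = work.pop()
            label, length, children = r
            vid = add_vertex(label)
            if top_vid is None:
                top_vid = vid
            if pvid is not None:
                adj[vid].append((pvid, length))
                adj[pvid].append((vid, length))
            for c in reversed(children):
                work.append((c, vid))
        return top_vid

    base_vid = build(base, None)
    tree = Tree(labels, adj, base_vid, is_rooted)
    tip_labels = [labels[v] for v in adj if len(adj[v]) == 1]
    if None in tip_labels:
        raise TreeError("unlabeled tip")
    if len(set(tip_labels)) != len(tip_labels):
        raise TreeError("duplicate taxon labels")
    if len(tip_labels) < 2:
        raise TreeError("tree needs at least two taxa")
    return tree


def read_tree(path: str) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def root_at_edge(tree: Tree, a: int, b: int) -> TreeView:
    """Virtual rooting on the edge (a, b): root children are the a-side
    subtree at distance 0 and the b-side subtree at the full edge length."""
    adj = tree._unrooted_adj()
    length = None
    for nbr, l in adj.get(a, ()):
        if nbr == b:
            length = l
    if length is None:
        raise TreeError(f"no edge between vertices {a} and {b}")
    root = Node(label=None, vid=None)
    left = _orient(adj, tree.labels, a, parent_vid=b, edge_length=0.0)
    right = _orient(adj, tree.labels, b, parent_vid=a, edge_length=length)
    root.children = [left, right]
    left.parent = right.parent = root
    return TreeView(root)


def root_at_terminal_edge(tree: Tree, taxon: str) -> TreeView:
    """Virtual rooting on the pendant edge of ``taxon`` (tip-side end)."""
    try:
        tv = tree.tip_vids[taxon]
    except KeyError:
        raise TreeError(f"unknown taxon {taxon!r}") from None
    adj = tree._unrooted_adj()
    (nbr, _), = adj[tv]
    return root_at_edge(tree, tv, nbr)


@dataclass
class DirtySet:
    """Upward-closed set of inner nodes whose CLVs must be recomputed."""

    nodes: list[Node] = field(default_factory=list)  # post-order restricted

    def __post_init__(self) -> None:
        self._indices = {nd.index for nd in self.nodes}

    def __contains__(self, node: Node) -> bool:
        return node.index in self._indices

    def __len__(self) -> int:
        return len(self.nodes)

    def is_upward_closed(self) -> bool:
        for nd in self.nodes:
            if nd.parent is not None and nd.parent.index not in self._indices:
                return False
        return True


def mark_dirty(view: TreeView, nodes) -> DirtySet:
    """Upward closure of ``nodes``: the marked inner nodes plus all their
    ancestors, returned in post-order."""
    closure: set[int] = set()
    for nd in nodes:
        if nd.is_tip:
            raise TreeError("only inner nodes can be marked dirty")
        while nd is not None and nd.index not in closure:
            closure.add(nd.index)
            nd = nd.parent
    ordered = [nd for nd in view.postorder_inner() if nd.index in closure]
    return DirtySet(nodes=ordered)
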