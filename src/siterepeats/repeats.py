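"""Site-repeat detection and repeat-aware likelihood computation.

Two alignment sites are *repeats* at a node ``u`` when their columns,
restricted to the tips below ``u``, are identical: the conditional
likelihoods of the two sites at ``u`` are then equal, so only one needs to
be computed and stored.  The engine assigns each site a per-node integer
*identifier* so that two sites share an identifier at ``u`` iff they are
repeats at ``u``:

* at a tip, the identifier of a site is its encoded character (1..15);
* at an inner node with children ``v`` and ``w``, sites are repeats iff
  their identifier *pairs* ``(phi_v, phi_w)`` coincide.  Pairs are deduced
  through a bounded flat lookup table ``M`` of ``tsize`` unsigned-integer
  slots indexed by ``(phi_v - 1) * wmax + (phi_w - 1)``.  A first
  occurrence mints the next identifier from a counter; later occurrences
  inherit the stored identifier.  A *clean* record per identifier marks
  which table slots are valid for the current assignment pass, so the one
  table is reused by every node without clearing.

When ``vmax * wmax`` exceeds the table bound, repeat detection is skipped
for that node (FALLBACK): each site becomes its own class, which in turn
forces fallback at every ancestor.  Identifiers are minted densely in
first-occurrence order, so each inner node stores exactly ``maxid``
conditional likelihood entries (the LH array) instead of one per site —
the source of both the operation savings and the memory savings.

Engine modes: ``srdt`` (dynamic topologies) recomputes identifiers on every
call; ``srct`` (constant topology) computes them once and reuses them when
only model parameters or branch lengths change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .models import SubstModel
from .plf import (
    LOG_SCALE_STEP,
    TIP_CLV_TABLE,
    CLVStore,
    LikelihoodResult,
    UnderflowError,
    _assemble,
    _check_taxa,
    _rescale,
)
from .trees import DirtySet, Node, Tree, TreeView, root_at_terminal_edge

#: identifiers a tip can take (the 15 possible encoded states); also the
#: indexing base used for a tip child in the flat table.
TIP_MAXID = 15

#: default table bound: 50 million uint32 entries = 200 MB at 4 bytes/entry
DEFAULT_TABLE_ENTRIES = 50_000_000

BYTES_PER_TABLE_ENTRY = 4


class _Fallback:
    def __repr__(self) -> str:
        return "FALLBACK"


#: sentinel returned when the table bound would be exceeded at a node
FALLBACK = _Fallback()


def table_entries_for_mb(mb: float) -> int:
    """Table entries that fit in ``mb`` megabytes at 4 bytes per entry."""
    return int(mb * 1_000_000 / BYTES_PER_TABLE_ENTRY)


def tau(a: int, b: int, base: int) -> int:
    """Bijective pairing (a, b) -> (a-1)*base + b on {1..} x {1..base}."""
    return (a - 1) * base + b


def assign_identifiers_cherry(xv: np.ndarray, xw: np.ndarray) -> tuple[np.ndarray, int]:
    """Identifiers for a cherry from its two encoded tip rows.

    Sites with equal (state, state) pairs share an identifier; identifiers
    are minted densely in first-occurrence order, so ``maxid`` equals the
    number of distinct pairs.
    """
    xv = np.asarray(xv)
    xw = np.asarray(xw)
    if xv.shape != xw.shape:
        raise ValueError("tip rows must have equal length")
    seen: dict[int, int] = {}
    phi = np.empty(len(xv), dtype=np.int64)
    for i in range(len(xv)):
        code = tau(int(xv[i]), int(xw[i]), TIP_MAXID + 1)
        ident = seen.get(code)
        if ident is None:
            ident = len(seen) + 1
            seen[code] = ident
        phi[i] = ident
    return phi, len(seen)


class RepeatTable:
    """The bounded flat lookup buffer ``M`` with clean-list validity records.

    The buffer is allocated lazily and grown only up to ``max_entries``
    (``None`` means unbounded).  Validity of a slot is tracked per minted
    identifier as a (slot, pass-token) pair, where the token increments once
    per node assignment; a stored identifier is trusted only when its clean
    record matches the queried slot and the current pass.  This reuses one
    buffer across all nodes and all traversals without ever clearing it.
    """

    def __init__(self, max_entries: int | None, n_sites: int):
        self.max_entries = max_entries
        self.n_sites = n_sites
        self.buf = np.zeros(0, dtype=np.int64)
        self.clean_slot = np.full(n_sites + 1, -1, dtype=np.int64)
        self.clean_pass = np.full(n_sites + 1, -1, dtype=np.int64)
        self._pass = 0
        self.high_water = 0          # largest vmax*wmax actually indexed
        self.max_pair_product = 0    # largest vmax*wmax requested (incl. fallbacks)

    def assign(self, phi_v: np.ndarray, vmax: int, phi_w: np.ndarray,
               wmax: int):
        """Identifiers for a parent from its children's identifier arrays.

        Returns ``(phi_u, maxid_u)``, or :data:`FALLBACK` when
        ``vmax * wmax`` exceeds the bound.
        """
        need = vmax * wmax
        self.max_pair_product = max(self.max_pair_product, need)
        if self.max_entries is not None and need > self.max_entries:
            return FALLBACK
        if need > len(self.buf):
            new = np.zeros(need, dtype=np.int64)
            new[: len(self.buf)] = self.buf
            self.buf = new
        self.high_water = max(self.high_water, need)
        self._pass += 1
        p = self._pass
        buf = self.buf
        clean_slot = self.clean_slot
        clean_pass = self.clean_pass
        n = len(phi_v)
        phi_u = np.empty(n, dtype=np.int64)
        ident = 0
        for i in range(n):
            d = (phi_v[i] - 1) * wmax + (phi_w[i] - 1)
            val = buf[d]
            if val > 0 and clean_slot[val] == d and clean_pass[val] == p:
                phi_u[i] = val
            else:
                ident += 1
                buf[d] = ident
                clean_slot[ident] = d
                clean_pass[ident] = p
                phi_u[i] = ident
        return phi_u, ident


def assign_identifiers_inner(phi_v, vmax, phi_w, wmax, table: RepeatTable):
    """Functional wrapper over :meth:`RepeatTable.assign` (spec surface)."""
    return table.assign(np.asarray(phi_v), vmax, np.asarray(phi_w), wmax)


@dataclass
class NodeIdentifiers:
    phi: np.ndarray     # per-site identifiers, 1..maxid in first-occurrence order
    maxid: int
    fallback: bool = False


class IdentifierMap:
    """Per-inner-node identifier arrays phi and their maxima (maxid)."""

    def __init__(self) -> None:
        self.entries: dict[int, NodeIdentifiers] = {}

    def phi(self, node: Node) -> np.ndarray:
        return self.entries[node.index].phi

    def maxid(self, node: Node) -> int:
        return self.entries[node.index].maxid

    def is_fallback(self, node: Node) -> bool:
        return self.entries[node.index].fallback

    def partition(self, node: Node) -> list[list[int]]:
        """Sites grouped by identifier, classes in first-occurrence order."""
        phi = self.entries[node.index].phi
        groups: list[list[int]] = [[] for _ in range(self.entries[node.index].maxid)]
        for i, ident in enumerate(phi):
            groups[ident - 1].append(i)
        return groups

    def maxids(self) -> dict[int, int]:
        return {idx: rec.maxid for idx, rec in self.entries.items()}


def _child_identifiers(child: Node, idmap: IdentifierMap, tip_codes):
    """(phi, base) for a child: raw encoded states with base 15 for a tip,
    the stored identifiers with base maxid for an inner node."""
    if child.is_tip:
        return tip_codes[child.index], TIP_MAXID
    rec = idmap.entries[child.index]
    return rec.phi, rec.maxid


def compute_identifiers(view: TreeView, alignment: Alignment,
                        table: RepeatTable, idmap: IdentifierMap | None = None,
                        dirty: DirtySet | None = None) -> IdentifierMap:
    """Post-order identifier assignment for (a dirty subset of) inner nodes."""
    rows = _check_taxa(view, alignment)
    tip_codes = {
        tip.index: alignment.data[rows[tip.label]] for tip in view.tips
    }
    if idmap is None:
        idmap = IdentifierMap()
    n = alignment.n_sites
    targets = view.postorder_inner() if dirty is None else dirty.nodes
    for u in targets:
        phi_v, vbase = _child_identifiers(u.children[0], idmap, tip_codes)
        phi_w, wbase = _child_identifiers(u.children[1], idmap, tip_codes)
        result = table.assign(phi_v, vbase, phi_w, wbase)
        if result is FALLBACK:
            idmap.entries[u.index] = NodeIdentifiers(
                phi=np.arange(1, n + 1, dtype=np.int64), maxid=n, fallback=True
            )
        else:
            phi_u, maxid = result
            idmap.entries[u.index] = NodeIdentifiers(phi=phi_u, maxid=maxid)
    return idmap


class CompressedCLVStore:
    """Per-node LH arrays: exactly ``maxid`` CLV entries, no duplicates.

    The entry for site ``i`` at node ``u`` is ``lh[u][phi_u(i) - 1]``.
    """

    def __init__(self) -> None:
        self.lh: dict[int, np.ndarray] = {}     # node.index -> (maxid, k, 4)
        self.scale: dict[int, np.ndarray] = {}  # node.index -> (maxid,)

    def site_clv(self, node: Node, idmap: IdentifierMap) -> np.ndarray:
        """Expand the LH array back to per-site CLVs (for inspection)."""
        return self.lh[node.index][idmap.phi(node) - 1]


class RepeatEngine:
    """Repeat-aware PLF evaluation over a fixed rooted view.

    Parameters
    ----------
    view
        Rooted binary traversal view; taxa must match the alignment.
    alignment
        Encoded alignment (pattern-compressed or raw; weights are honoured).
    model
        Substitution model used for CLVs and the likelihood.
    table_entries
        Bound on the lookup table (entries).  ``None`` means unbounded,
        0 forces fallback everywhere.
    mode
        ``"srdt"`` recomputes identifiers at every call (changing
        topologies); ``"srct"`` assigns them once and reuses them across
        calls (fixed topology, e.g. when optimising model parameters).
    """

    def __init__(self, view: TreeView, alignment: Alignment, model: SubstModel,
                 table_entries: int | None = DEFAULT_TABLE_ENTRIES,
                 mode: str = "srdt"):
        if mode not in ("srdt", "srct"):
            raise ValueError(f"mode must be 'srdt' or 'srct', got {mode!r}")
        self.view = view
        self.alignment = alignment
        self.model = model
        self.mode = mode
        self.rows = _check_taxa(view, alignment)
        self.table = RepeatTable(table_entries, alignment.n_sites)
        self.idmap: IdentifierMap | None = None
        self.store = CompressedCLVStore()
        self.result: LikelihoodResult | None = None
        self._tip_codes = {
            tip.index: alignment.data[self.rows[tip.label]] for tip in view.tips
        }
        self.counters: dict[str, int] = {}

    # -- public API --------------------------------------------------------
    def set_model(self, model: SubstModel) -> None:
        """Swap model parameters (identifiers stay valid; SRCT reuses them)."""
        self.model = model

    def run(self) -> LikelihoodResult:
        """Full traversal: assign identifiers, compute one CLV per unique
        identifier, return the likelihood."""
        self._reset_counters()
        if self.mode == "srdt" or self.idmap is None:
            self.idmap = compute_identifiers(
                self.view, self.alignment, self.table
            )
        for u in self.view.postorder_inner():
            self._compute_node_lh(u)
        self.result = self._likelihood()
        return self.result

    def partial_update(self, dirty: DirtySet) -> LikelihoodResult:
        """Recompute identifiers (SRDT) and LH entries for dirty nodes only."""
        if self.result is None:
            raise RuntimeError("partial_update requires a prior full run()")
        if not dirty.is_upward_closed():
            raise ValueError("dirty set is not upward-closed")
        self._reset_counters()
        if len(dirty) == 0:
            return self.result
        if self.mode == "srdt":
            compute_identifiers(
                self.view, self.alignment, self.table, self.idmap, dirty
            )
        for u in dirty.nodes:
            self._compute_node_lh(u)
        self.result = self._likelihood()
        return self.result

    @property
    def plain_clv_computations(self) -> int:
        """CLV computations a per-site traversal would need: n * (m - 1)."""
        return self.alignment.n_sites * len(self.view.inner)

    # -- internals ---------------------------------------------------------
    def _reset_counters(self) -> None:
        self.counters = {"clv_computations": 0, "fallback_nodes": 0,
                         "nodes_processed": 0}

    def _compute_node_lh(self, u: Node) -> None:
        rec = self.idmap.entries[u.index]
        # identifiers are dense in first-occurrence order, so the sorted
        # unique values are 1..maxid and their first indices line up
        _, first = np.unique(rec.phi, return_index=True)
        terms = []
        scale = np.zeros(rec.maxid, dtype=np.int64)
        for child in u.children:
            P = self.model.transition_matrices(child.edge_length)
            if child.is_tip:
                L = TIP_CLV_TABLE[self._tip_codes[child.index][first]]
                terms.append(np.einsum("kab,mb->mka", P, L))
            else:
                crec = self.idmap.entries[child.index]
                sel = crec.phi[first] - 1
                L = self.store.lh[child.index][sel]
                terms.append(np.einsum("kab,mkb->mka", P, L))
                scale += self.store.scale[child.index][sel]
        lh = terms[0] * terms[1]
        _rescale(lh, scale)
        self.store.lh[u.index] = lh
        self.store.scale[u.index] = scale
        self.counters["clv_computations"] += rec.maxid
        self.counters["nodes_processed"] += 1
        if rec.fallback:
            self.counters["fallback_nodes"] += 1

    def _likelihood(self) -> LikelihoodResult:
        root = self.view.root
        rec = self.idmap.entries[root.index]
        lh = self.store.lh[root.index]
        unique_like = (lh @ self.model.frequencies).mean(axis=1)
        if (unique_like <= 0).any():
            bad_ident = int(np.argmax(unique_like <= 0))
            bad_site = int(np.argmax(rec.phi == bad_ident + 1))
            raise UnderflowError(
                f"per-site likelihood is not positive at site {bad_site + 1}"
            )
        site_like = unique_like[rec.phi - 1]
        scale = self.store.scale[root.index][rec.phi - 1]
        return _assemble(site_like, scale, self.alignment.weights)


def repeats_full_traversal(view: TreeView, alignment: Alignment,
                           model: SubstModel,
                           table_entries: int | None = DEFAULT_TABLE_ENTRIES,
                           mode: str = "srdt"):
    """One-shot full traversal; returns (IdentifierMap, CompressedCLVStore,
    LikelihoodResult).  For repeated evaluation keep a :class:`RepeatEngine`."""
    engine = RepeatEngine(view, alignment, model, table_entries, mode)
    result = engine.run()
    return engine.idmap, engine.store, result


def _as_view(tree_or_view, root_taxon: str | None) -> TreeView:
    if isinstance(tree_or_view, TreeView):
        return tree_or_view
    tree: Tree = tree_or_view
    if root_taxon is not None:
        return root_at_terminal_edge(tree, root_taxon)
    if tree.is_rooted:
        return tree.view()
    return root_at_terminal_edge(tree, tree.taxa[0])


def unbounded_table_entries(alignment: Alignment) -> int:
    """A table bound large enough that no node ever falls back."""
    n = alignment.n_sites
    return max((TIP_MAXID + 1) ** 2, n * n, (TIP_MAXID + 1) * n)


def repeat_fraction(tree_or_view, alignment: Alignment,
                    root_taxon: str | None = None) -> float:
    """Percentage of (site, inner node) pairs that are repeats of an
    earlier site at the same node: ``100 * sum_u (n - maxid_u) / (n * #inner)``.

    Uses an unbounded table so every repeat is found.  The statistic is
    defined on the sites of the alignment as given (apply it to the raw,
    uncompressed alignment to count all columns).
    """
    view = _as_view(tree_or_view, root_taxon)
    table = RepeatTable(None, alignment.n_sites)
    idmap = compute_identifiers(view, alignment, table)
    n = alignment.n_sites
    inner = view.postorder_inner()
    saved = sum(n - idmap.maxid(u) for u in inner)
    return 100.0 * saved / (n * len(inner))


def memory_estimate(n_taxa: int, n_sites: int, idmap: IdentifierMap,
                    n_categories: int = 4,
                    table: RepeatTable | None = None) -> dict:
    """Memory report for CLV storage with and without repeat compression.

    ``standard_clv_bytes`` follows the conventional accounting for an
    unrooted tree (8-byte doubles x 4 states x k categories for each of the
    ``n_taxa - 2`` inner-node CLV arrays of ``n_sites`` sites).
    ``view_clv_bytes`` is the same quantity for the rooted view actually
    stored (one more inner node).  ``compressed_clv_bytes`` counts only the
    ``maxid`` unique entries kept per node.  A CLV entry holds
    ``4 * n_categories`` doubles whereas a site identifier is one unsigned
    integer, so the per-site value-count ratio of CLV storage to the
    identifier list is ``clv_values_per_identifier``.
    """
    entry_bytes = 8 * 4 * n_categories
    n_inner = len(idmap.entries)
    total_maxid = sum(rec.maxid for rec in idmap.entries.values())
    report = {
        "standard_clv_bytes": entry_bytes * (n_taxa - 2) * n_sites,
        "view_clv_bytes": entry_bytes * n_inner * n_sites,
        "compressed_clv_bytes": entry_bytes * total_maxid,
        "identifier_bytes": 4 * (n_sites * n_inner + (2 * n_taxa - 1)),
        "clv_values_per_identifier": 4 * n_categories,
        "n_inner_nodes": n_inner,
        "total_unique_entries": total_maxid,
    }
    if table is not None:
        report["table_bytes"] = BYTES_PER_TABLE_ENTRY * table.high_water
        report["table_entries_used"] = table.high_water
    return report
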