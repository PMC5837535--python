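"""Independent brute-force oracles for testing the engine.

These reimplement repeat detection and the pruning likelihood by the most
direct route possible — string comparison of restricted columns, and plain
nested scalar loops with scipy's generic matrix exponential — sharing
nothing with the production code paths beyond the input containers.  They
are intended for small instances only.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import gamma as _gamma_dist

from .alignment import Alignment
from .models import SubstModel
from .trees import Node, TreeView

_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def brute_force_repeats(view: TreeView, alignment: Alignment,
                        node: Node) -> list[list[int]]:
    """Partition of site indices into repeat classes at ``node``.

    Sites are grouped by exact equality of their columns restricted to the
    tips below ``node`` (string comparison); classes appear in order of
    first occurrence.
    """
    rows = {t: i for i, t in enumerate(alignment.taxa)}
    tip_rows = [rows[t] for t in view.subtree_tips(node)]
    groups: dict[str, list[int]] = {}
    for i in range(alignment.n_sites):
        key = ",".join(str(int(alignment.data[r, i])) for r in tip_rows)
        groups.setdefault(key, []).append(i)
    return list(groups.values())


def _oracle_gamma_rates(alpha: float, k: int) -> list[float]:
    """Category means by direct numerical quadrature of the gamma density."""
    if k == 1:
        return [1.0]
    dist = _gamma_dist(a=alpha, scale=1.0 / alpha)
    cuts = [0.0] + [float(dist.ppf(j / k)) for j in range(1, k)] + [math.inf]
    rates = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        val, _ = quad(lambda x: x * dist.pdf(x), lo, hi, limit=200)
        rates.append(val * k)
    return rates


def _oracle_pmatrix(model: SubstModel, t: float, rate: float) -> list[list[float]]:
    """exp(Q t r) via scipy's generic expm on a loop-built generator."""
    pi = model.frequencies
    Q = [[0.0] * 4 for _ in range(4)]
    for s, (i, j) in zip(model.exchangeabilities, _PAIRS):
        Q[i][j] = float(s * pi[j])
        Q[j][i] = float(s * pi[i])
    for i in range(4):
        Q[i][i] = -sum(Q[i][j] for j in range(4) if j != i)
    mu = -sum(pi[i] * Q[i][i] for i in range(4))
    M = np.array(Q) * (t * rate / mu)
    return expm(M).tolist()


def scalar_plf_oracle(view: TreeView, alignment: Alignment,
                      model: SubstModel):
    """Plain nested-loop pruning likelihood: per site, per category, per
    state, with no vectorisation, no compression and no scaling.

    Returns a ``LikelihoodResult``-compatible object (log-likelihood plus
    per-site log-likelihoods honouring site weights).
    """
    from .plf import LikelihoodResult  # container only

    rows = {t: i for i, t in enumerate(alignment.taxa)}
    rates = (
        _oracle_gamma_rates(model.alpha, model.n_categories)
        if model.alpha is not None
        else [1.0] * model.n_categories
    )
    pi = [float(p) for p in model.frequencies]
    pmats: dict[tuple[int, int], list[list[float]]] = {}
    for nd in view.nodes:
        if nd.parent is not None:
            for c in range(len(rates)):
                pmats[(nd.index, c)] = _oracle_pmatrix(model, nd.edge_length, rates[c])

    def clv(node: Node, site: int, cat: int) -> list[float]:
        if node.is_tip:
            code = int(alignment.data[rows[node.label], site])
            return [1.0 if (code >> s) & 1 else 0.0 for s in range(4)]
        out = []
        child_clvs = [clv(c, site, cat) for c in node.children]
        for s in range(4):
            prod = 1.0
            for child, cc in zip(node.children, child_clvs):
                P = pmats[(child.index, cat)]
                acc = 0.0
                for s2 in range(4):
                    acc += P[s][s2] * cc[s2]
                prod *= acc
            out.append(prod)
        return out

    per_site = []
    for i in range(alignment.n_sites):
        total = 0.0
        for c in range(len(rates)):
            root_clv = clv(view.root, i, c)
            total += sum(pi[s] * root_clv[s] for s in range(4)) / len(rates)
        per_site.append(math.log(total))
    per_site = np.array(per_site)
    return LikelihoodResult(
        log_likelihood=float((alignment.weights * per_site).sum()),
        per_site=per_site,
        weights=alignment.weights.copy(),
    )
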