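# Methods

## Model and likelihood

The package evaluates the phylogenetic likelihood of a DNA alignment on a
binary tree under a general time-reversible (GTR) substitution model with
optional discrete-Γ rate heterogeneity. The generator is
`q_ij = s_ij π_j` (i ≠ j), normalised to one expected substitution per unit
branch length at stationarity; transition probabilities
`P(t, r) = exp(Q t r)` come from the eigendecomposition of the symmetrised
generator `diag(√π) Q diag(1/√π)`, the standard stable route for
reversible matrices. `P(0)` is returned as the exact identity: the
eigendecomposition reconstruction carries ~1e-17 residue, which would turn
structurally impossible site patterns (probability zero across zero-length
branches) into tiny positive numbers and defeat the underflow diagnostics.

Rate heterogeneity follows Yang's discrete gamma: `k` equal-probability
categories of Gamma(α, α), each represented by its category *mean*
(computed in closed form from the regularised incomplete gamma function),
with equal weights `1/k`. Mean-vs-median discretisation is not forced by
anything upstream; mean keeps the average rate exactly 1 and is the common
default. The per-site likelihood averages the root CLV over categories
before contracting with π.

Characters are encoded as 4-bit masks (A=1, C=2, G=4, T=8; IUPAC
ambiguities OR their constituents; `-`, `?` and `N` all map to 15). Tip
conditional likelihoods are the bit indicators of the mask. Unifying gap,
`?` and `N` keeps the observed-state alphabet at 15 values and matches how
production PLF implementations treat missing data; nothing downstream
distinguishes "gap" from "completely ambiguous".

## Repeat detection

Two sites are repeats at node `u` iff their columns restricted to the tips
of `u`'s subtree are equal; equivalently (and this is what makes a
linear-time pass possible) iff their identifier pairs at `u`'s children
coincide. The engine assigns identifiers in post-order:

* **Tips** contribute their raw encoded states as identifiers, with
  indexing base 15 (the number of possible observed states).
* **Inner nodes** query a flat buffer `M` of `tsize` unsigned integers at
  slot `(φ_v − 1)·wmax + (φ_w − 1)`. An empty/invalid slot means a new
  repeat class: the node's counter mints the next identifier (so
  identifiers are dense, `1..maxid`, in first-occurrence order) and the
  slot records it. A valid slot yields the earlier site's identifier.
* **Validity** is tracked by a *clean* list with one record per possible
  identifier (≤ number of sites): minting identifier `i` at slot `d`
  stores `(d, pass-token)` under `i`, and a stored identifier is trusted
  only if its record matches the queried slot and the current pass. The
  token increments once per node assignment, so the single buffer is
  reused by every node — and, unlike a per-node tag, also stays correct
  across *partial* re-assignments of a subset of nodes in later
  traversals, where records minted for the same node in a previous
  traversal must not be trusted either.
* **Fallback**: if `vmax·wmax > tsize` the node skips detection and uses
  per-site identifiers (`maxid = n`). That choice propagates naturally:
  the node's ancestors see `maxid = n` and (for any table bounded below
  `15·n` resp. `n²`) fall back too, with no extra state. With very small
  alignments an ancestor can still satisfy the bound and resume detection;
  the resulting partition is then finer than true column equality but
  never coarser, so the likelihood is unaffected. The buffer is grown
  lazily up to the bound (default 50 million entries = 200 MB at 4 bytes
  per entry) and `maxid` is kept per node, so finding the children's
  maxima costs O(1).

Correctness rests on two directions: equal child pairs imply equal
restricted columns (induction down the subtree), and distinct pairs map to
distinct slots because the pairing `(a−1)·base + b` is bijective on
`{1..} × {1..base}`. Both are exercised against a brute-force
string-comparison oracle over random trees and alignments with gaps and
ambiguities.

## Compressed CLV storage and traversal

Each inner node stores an LH array of exactly `maxid` CLV entries (shape
`maxid × k × 4`), one per repeat class; the entry for site `i` is
`LH[φ_u(i) − 1]`. Child entries are fetched through the children's
identifiers, so duplicates are never computed *or stored* — the memory
footprint drops from `n` to `maxid` entries per node, while the identifier
list costs one unsigned integer per site against the `4·k` doubles of a
CLV entry (16 values per entry at `k = 4`; in bytes the ratio is 32× for
8-byte doubles vs 4-byte integers — both numbers are reported by
`memory_estimate`, which also quotes the conventional
`8·4·k·(m−2)·n`-byte accounting for an unrooted tree of `m` taxa and `n`
sites).

The engine counts one "CLV computation" per LH entry it evaluates, i.e.
`Σ_u maxid[u]` per full traversal (`n·(m−1)` under total fallback, which is
exactly the plain per-site count for a rooted view with `m−1` inner
nodes). These counters are the basis of the operation-saving checks; no
wall-clock claims are made, since the implementation is vectorised Python
rather than tuned C.

**Modes.** SRDT recomputes identifiers on every call (the tables above
make this cheap and it is required when topologies change); SRCT assigns
them once and reuses them across calls while branch lengths or model
parameters vary. Both produce identical identifiers and likelihoods on a
fixed topology.

**Partial updates.** After a local tree modification, only an
upward-closed set of inner nodes needs new identifiers (SRDT) and LH
entries. The dirty set is validated for upward closure; non-dirty nodes'
arrays are reused as-is. Test coverage perturbs branch lengths inside
random walk regions (adjacent inner nodes, continuation probability 0.95,
mirroring the update pattern of local rearrangement moves) and compares
against a fresh full traversal.

## Numerical safeguards

Underflow scaling is per site (per LH entry in the compressed store): when
every entry of a site's CLV falls below 2⁻²⁵⁶ it is multiplied by 2²⁵⁶ and
a per-site exponent counter increments; log-likelihood assembly subtracts
`256·ln 2` per increment. The threshold triggers only on deep trees
(hundreds of nodes on a path), leaves shallow computations bit-identical
to the unscaled path, and is invisible to repeat detection, which operates
on identifiers, not values. A site whose likelihood is exactly zero
(impossible pattern, e.g. conflicting states across zero-length branches)
raises an error naming the site rather than returning −inf.

Likelihood evaluation of unrooted trees virtually roots the tree on an
edge, placing the root at the near end: the two root children sit at
distances 0 and the full edge length. This reproduces the edge-likelihood
sum exactly and, for reversible models, makes the result independent of
the edge chosen (verified over all edges and all terminal-edge rootings).
Multifurcations are resolved to binary by leftmost pairing with zero-length
edges; missing branch lengths default to 0 with a warning; both choices
keep toy inputs runnable and deterministic.

## Synthetic data

The simulator draws root states from π, evolves them down the tree with
the model's `P(t, r)` using one fixed rate category per site, then injects
missing data i.i.d.: gaps replace a character by full uncertainty,
ambiguities widen it to a random IUPAC superset containing the true base.
Defaults (20 taxa, 300 sites, JC+Γ₄ with α = 1, exponential branch lengths
of mean 0.1, 5% gaps, 1% ambiguities) are chosen as a moderate, realistic
regime for the property suites; the oracle-agreement suite varies taxa
3–12 and sites 1–50 with 10% gaps / 5% ambiguities to stress edge cases.
The generator reproduces the *amount* of gaps/ambiguity of empirical
alignments but not their block (indel) structure, lineage-specific rates,
or alignment error — so passing tests demonstrate algorithmic correctness
and the repeat statistics of i.i.d.-site data, not the (typically higher)
repeat fractions of real gappy alignments. Random trees come from
sequential attachment of tips to a uniformly chosen edge. Everything is
byte-reproducible from a single integer seed.

## Problem sizes

The test and acceptance suites run the worked example (4 taxa × 5 sites),
100 random instances of 3–12 taxa × 1–50 sites for oracle agreement (each
under 2 modes × 3 table bounds), 40 instances for the operation-saving
bounds, and 20-taxon × 150-site simulations for the partial-update and
rooting-invariance checks; a 560-taxon caterpillar exercises the scaler.
These sizes keep the whole suite under a minute while covering every code
path; the engine itself is routinely used at tens of thousands of sites
(the identifier pass is linear in sites × nodes given the table).

## Known limitations

* DNA only (4-state); the data structures do not preclude codon or
  protein alphabets but no such models are provided.
* No branch-length or model-parameter optimisation — the package computes
  likelihoods, it does not fit them.
* No SIMD/tuned kernels; operation counters, not timings, quantify the
  savings.
* The bounded-table fallback can, on very small alignments, resume
  detection above a fallback node with a finer-than-true partition (see
  above); likelihoods are unaffected.
* Partitioned runs split a global table budget evenly across partitions,
  each with its own table and identifier maps.
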