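"""Plain vs repeat-aware likelihood on simulated data.

Simulates 20 sequences of 300 sites under JC+Gamma(4), then evaluates the
same likelihood three ways: the reference per-site pruning, the SRDT engine
(identifiers recomputed per call, for changing topologies) and the SRCT
engine (identifiers computed once, for fixed topologies).  All three agree
to machine precision; the engines do far fewer CLV computations.
"""

import siterepeats as sr

cfg = sr.SimConfig(n_taxa=20, n_sites=300, seed=42)
tree, aln = sr.simulate_dataset(cfg)
view = sr.root_at_terminal_edge(tree, "t1")
model = cfg.model

plain = sr.likelihood_rooted(view, aln, model)
print(f"plain pruning    logL = {plain.log_likelihood:.6f}  "
      f"({aln.n_sites * len(view.inner)} CLV computations)")

for mode in ("srdt", "srct"):
    engine = sr.RepeatEngine(view, aln, model, mode=mode)
    res = engine.run()
    print(f"{mode} engine      logL = {res.log_likelihood:.6f}  "
          f"({engine.counters['clv_computations']} CLV computations)")

# SRCT reuses its identifier maps when only model parameters change:
engine = sr.RepeatEngine(view, aln, model, mode="srct")
engine.run()
engine.set_model(sr.SubstModel.jc(alpha=0.3, n_categories=4))
res2 = engine.run()
print(f"srct, alpha=0.3  logL = {res2.log_likelihood:.6f}  "
      "(identifiers reused, only CLVs recomputed)")
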