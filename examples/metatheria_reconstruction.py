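"""Parsimony vs maximum likelihood in Metatheria.

Marsupials are the hard case: most have only a fibrocartilaginous
patelloid, yet bandicoots, marsupial moles, the honey possum, shrew
opossums and the extinct borhyaenoids have true bony patellae.  This
script reconstructs the character both ways and prints the nodes the
two methods disagree or hedge on.
"""

import patevol as pv

fx = pv.load_fixture("metatheria_fig6")
tree = fx.tree
sm = tree.mrca(fx.clades["sparassodonta_marsupialia"].members)

for scheme in ("unordered", "ordered"):
    res = pv.sankoff(tree, fx.matrix, pv.make_step_matrix(scheme, 3))
    states = "/".join(str(s) for s in sorted(res.state_sets[sm]))
    print(f"{scheme:>9} parsimony: {res.total:g} steps; "
          f"Sparassodonta+Marsupialia ancestor = {{{states}}}")
    equivocal = sum(1 for n in tree.preorder()
                    if not n.is_tip and len(res.state_sets[n]) > 1)
    print(f"           {equivocal} internal nodes equivocal")

fit = pv.fit_rate(tree, fx.matrix)
recon = pv.marginal_probs(tree, fx.matrix, fit.model)
mapped = pv.map_states(recon)
lo, hi = pv.ml_transition_bracket(tree, mapped)
losses = pv.ml_transition_bracket(tree, mapped, *pv.LOSS)

print()
print(f"ML: fitted rate q = {fit.model.q:.4g} /Myr, "
      f"log-likelihood {fit.loglik:.2f}")
p = recon[sm]
print(f"ML marginal at the Sparassodonta+Marsupialia ancestor: "
      f"absent {p[0]:.2f}, patelloid {p[1]:.2f}, ossified {p[2]:.2f}")
print(f"ML origins of the ossified patella in Metatheria: {lo}"
      + ("" if lo == hi else f"-{hi}"))
print(f"ML losses (reduction to patelloid/absent): {losses[0]}-{losses[1]}")
print()
print("Reading: one origin in the ancestor of borhyaenoids + crown")
print("marsupials, followed by reduction to a patelloid in several")
print("lineages — parsimony leaves the basal crown nodes equivocal")
print("between patelloid and ossified, ML comes down on ossified.")
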