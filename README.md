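# patevol

Ancestral-state reconstruction of the mammalian patella (kneecap) as a
reusable, tested Python library.

The ossified patella is scattered oddly across tetrapods: present in most
birds, most lizards, monotremes and nearly all placental mammals, absent in
most marsupials and many fossil mammal relatives, with a fibrocartilaginous
"patelloid" standing in for it in several groups. `patevol` codes the organ
as a three-state character —

* `0` — patella absent,
* `1` — soft-tissue patelloid (fibrocartilaginous),
* `2` — ossified patella, with `?` for unknown/inapplicable —

maps it onto composite, time-calibrated phylogenies (in Mya, polytomies and
fossil tips included), and answers the question the coding exists for: *how
many times did the bony patella evolve, and how often was it lost?*

It is aimed at comparative morphologists and methods-minded phylogeneticists
who want the full accounting — not one arbitrary reconstruction but the
bracket of answers over every most-parsimonious history, under both ordered
and unordered costs, across alternative topologies, cross-checked against a
likelihood model.

## What is inside

| module | contents |
|---|---|
| `patevol.tree` | rooted trees with ages/branch lengths, traversals, MRCA, subtree extraction |
| `patevol.nexusio` | Nexus (Mesquite-dialect) and Newick reading; deterministic writers |
| `patevol.characters` | the 3-state space, character matrices, ordered/unordered step matrices |
| `patevol.supertree` | declarative composite-tree builder, even-spacing date interpolation, named topology variants |
| `patevol.parsimony` | Sankoff dynamic programme, Hartigan/MPR state sets, exhaustive MPR enumeration |
| `patevol.mk` | symmetric Mk likelihood (closed-form transitions), rate fitting, marginal ancestral probabilities |
| `patevol.origins` | gain/loss edge counting, exact min/max brackets over all MPRs, scenario sweeps |
| `patevol.fixtures` | transcribed study trees and codings (tetrapods, Mammaliaformes, Metatheria, Eutheria) with per-taxon provenance |
| `patevol.simulate` | Yule trees and exact jump-chain trait simulation for calibration |
| `patevol.cli` | `patevol reconstruct / count-origins / sweep / simulate / fixtures` |

The core statistics, in the field's notation: generalized parsimony uses the
Sankoff recursion

    S_v(i) = sum over children c of min_j [ step(i, j) + S_c(j) ]

with step(i,j) = 1 for any change (unordered) or |i − j| (ordered, forcing
absent → patelloid → ossified). A matching outside pass marks every state a
node takes in *some* minimum-cost history, and a min/max dynamic programme
brackets the number of gain edges (parent in {0,1}, child 2 — so
re-ossification of a patelloid counts as an origin) over all such histories.
The likelihood route is the k-state symmetric Markov ("Mk") model,
p_ij(t) = (1 − e^(−kqt))/k for i ≠ j, fitted by maximising the Felsenstein
pruning likelihood over the single rate q (per Myr), with marginal node
posteriors from the standard inside/outside combination.

## Worked example

```python
import patevol as pv

fx = pv.load_fixture("metatheria_fig6")       # marsupials and kin
tree = fx.tree                                 # dated, validated
res = pv.sankoff(tree, fx.matrix, pv.make_step_matrix("unordered", 3))
sm = tree.mrca(fx.clades["sparassodonta_marsupialia"].members)
print(res.total, sorted(res.state_sets[sm]))

fit = pv.fit_rate(tree, fx.matrix)
mapped = pv.map_states(pv.marginal_probs(tree, fx.matrix, fit.model))
print(pv.ml_transition_bracket(tree, mapped))
```

prints

```
4.0 [2]
(1, 1)
```

— the most-parsimonious length is 4 steps, the ancestor of borhyaenoids +
crown marsupials reconstructs unambiguously as ossified, and under the
fitted Mk model (q ≈ 0.0062 /Myr) the ossified patella originates exactly
once within Metatheria, with subsequent reductions to a patelloid. The
scripts in `examples/` walk through each capability the same way
(`python examples/mesozoic_origin_counts.py` prints the variant × cost-
scheme sweep whose crown-Mammalia origin bracket spans 4–6).

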