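# Methods

## The character and its coding

The patellar organ is coded as one ordered-by-anatomy, three-state
character: 0 = no patella, 1 = fibrocartilaginous patelloid, 2 = ossified
patella. `?` means the state is unknown *or inapplicable* and is treated
everywhere as the full state set {0,1,2}; in particular, taxa whose entire
hindlimb is lost (crown Cetacea, crown Sirenia) are `?`, because limb loss
carries no information about patellar ossification. The suprapatella is not
coded (its homology is unsettled), and "patelloid present" is a state of the
same character, not a different organ.

## Trees

Trees are rooted, may contain hard polytomies (e.g. Juramaia + Eomaia +
crown Placentalia), and carry absolute node ages in Mya (present = 0) from
which branch lengths in Myr are derived — ages are the single source of
truth, and zero-length branches (identical dates) are legal; no algorithm
divides by a branch length. Composite trees are described declaratively
(`CladeSpec`): nested topology, stated ages where a source gives them, tip
ages for fossils (last appearance; 0 for extant terminals).

Undated internal nodes are interpolated by even spacing: a chain of m
undated nodes between a dated ancestor (age a) and dated descendant (age d)
receives ages a − i(a−d)/(m+1). Where an undated node has several dated
descendants reachable through undated nodes, the *oldest* evenly-spaced
candidate is taken; this tie-break is the only rule that keeps every
root-to-tip path free of age inversions, and processing nodes in preorder
makes the chain case exactly even-spaced. Interpolated ages affect only the
likelihood analyses (parsimony is length-free), and only mildly: the true
ages the original analyses used for undated nodes are not recoverable, so
likelihood results on the fixtures are approximate by construction.

Topology variants are declarative rewirings (detach a clade, re-attach as
sister to another, with a stated new node age) applied to a copy, so tip
codings are shared across variants and cannot drift.

## Parsimony

Generalized (Sankoff) parsimony with an explicit step matrix: uniform costs
("unordered", any change = 1 step, so absent → ossified directly is one
step) or linear costs ("ordered", |i − j|, so absent → ossified must pay for
passing through the patelloid state). Tips observed as a set contribute cost
0 for each allowed state and an arithmetic-safe infinity otherwise; the
root score is the plain minimum over root states (no stationary weighting).

Beyond the score, the package reports per-node *MPR state sets* — the states
a node takes in at least one minimum-cost history — via an outside pass that
mirrors the inside recursion; for uniform costs this is exactly Hartigan's
up/down construction generalized to polytomies, and with step matrices it
gives the step-matrix analogue. Full enumeration of MPRs is available with a
cap (default 10^6) and an explicit "truncated" signal; enumeration order is
deterministic (state tuples ascending in postorder node order).

Origins and losses are edge counts on reconstructions: a gain is an edge
whose parent is 0 or 1 and child is 2 (so re-acquisition after reduction
counts as an origin, and gains from 0 and from 1 are also reported
separately); a loss is the reverse. The [min, max] bracket over *all* MPRs
is computed by a dynamic programme that exploits the fact that an
assignment is globally optimal iff every child choice is locally optimal
given its parent's state — so per node and state the min/max achievable
count among optimal subtree assignments is exact, and scales to trees where
enumeration would explode. Counts can be restricted to a clade; the clade's
stem edge is included by default (an origin "in the ancestor of
Sparassodonta and Marsupialia" belongs to Metatheria). The DP path and the
enumeration path are cross-checked against each other and against an
exhaustive assignment oracle in the tests.

## Likelihood

The likelihood model is the single-rate symmetric Mk chain with k = 3 and a
uniform root prior — the default model of the character-mapping software
the original analyses used; the sources name no model, so this is the
package's reconstruction of that default, and exact numerical agreement
with figure insets is not claimed. Transition probabilities use the closed
form p_ij(t) = (1 − e^(−kqt))/k (i ≠ j); q is in 1/Myr and absorbs the time
scale. Likelihoods use Felsenstein pruning with per-node rescaling (results
are independent of the rescaling; deep trees do not underflow). The rate is
fitted by bounded scalar maximisation on q ∈ [10⁻⁸, 10] /Myr, optimising
log q because the likelihood surface is far better conditioned on that
scale (on the raw scale a bounded search can stall on the saturation
plateau). Data with no variation land on the lower bound and are flagged,
not raised.

Marginal ancestral probabilities come from the standard inside/outside
combination and are cross-checked against brute-force enumeration at small
size. State maps take the argmax per node, but any state within 0.05
(configurable) of the maximum is kept, so near-ties surface as ambiguous
sets; ML origin/loss counts then come as [min, max] brackets in which an
edge counts toward the minimum only when every allowed state combination is
a transition. An ordered-rates variant (separate gain/loss rates on the
0↔1↔2 chain, numerical matrix exponential) is provided for simulation and
sensitivity work, not for headline numbers.

## Fixtures and their transcription

Four study trees are packaged, with every terminal an operational taxon of
the original analysis (collapsed families/orders for extant groups, genera
for fossils) and a per-taxon provenance note; notes beginning `inferred:`
mark codings reconstructed from context rather than stated outright (the
deposited data matrix is the authority for those where it is available).
Stated "~X Mya" dates are stored as X exactly; remaining dates are round
literature-consistent values, chosen once.

Two transcription choices deserve emphasis:

* **Eutherian polarization.** A tree of Eutheria alone has no stem edge, so
  "one origin within Eutheria" cannot register as a gain edge on it; and
  with a single outgroup terminal the gain can float onto the therian stem
  in a tied reconstruction. The eutherian fixture therefore carries the
  cladotherian/metatherian outgroup terminals (Henkelotherium, Vincelestes,
  Sinodelphys, Marsupialia) that polarize the stem, mirroring the enclosing
  mammal tree that polarized the original figure.
* **Conservative marsupial codings.** Within crown Marsupialia, state 1 is
  assigned only where the patelloid is explicitly documented (Didelphidae,
  Vombatidae, Pseudocheiridae); families whose patelloid is plausible but
  unverified are `?`. A short exchange argument shows that under uniform
  costs no coding can make the Sparassodonta+Marsupialia ancestor fixed at
  2 while the crown root itself is {1,2}-equivocal — the two reported
  patterns are only jointly realisable with the equivocal nodes on the
  basal crown backbone (here, the diprotodontian spine), which is what the
  conservative coding produces and what the "equally parsimonious between
  ossified and patelloid in basal lineages" reading refers to.

## Simulation

`yule_tree` grows pure-birth trees (per-lineage rate, clock stopped one
exponential waiting time after the n-th birth, so pendant edges are never
zero); `simulate_trait` evolves the character by exact exponential
waiting-time (jump-chain) simulation — no discretisation, hence no
tolerance knob — recording every jump, so the realised change count and
realised gains into state 2 are exact ground truth. One explicit integer
seed drives each run.

The simulator emulates the statistical structure the analyses assume: a
homogeneous Markov chain on an ultrametric or fixture tree. It does *not*
emulate fossilized sampling through time on random trees, correlated
characters, rate variation across branches, or coding error; green
calibration tests therefore show the machinery is correct under the model,
not that real patellar evolution followed it.

## Problem sizes and numerical choices

Exhaustive oracles run at 4–8 tips (where full enumeration over 3^nodes is
trivial); engine-vs-oracle agreement uses 100–200 random instances per
property and 1,000 for the Fitch-length and parsimony-lower-bound checks.
Rate recovery uses a fixed 200-tip Yule tree with q = 0.005/Myr and 100
replicates in the tests (20 in the acceptance script), asserting the median
fitted rate within a factor of 1.5 of truth. Likelihood agreement
tolerances are 10⁻¹⁰ absolute; probability-vector normalisation 10⁻⁹; age
arithmetic 10⁻⁶ Myr. The whole test suite runs in well under a minute on
one CPU.

## Known limitations

* Branch lengths on fixture trees are partly interpolated (above), so
  fitted rates and marginal probabilities are approximations to the
  originals; parsimony quantities are exact on the transcribed topology.
* The min/max origin brackets for ML maps are conservative (forced/possible
  edge counts), not an exact optimisation over the ambiguous-set product.
* MPR enumeration is exponential in the worst case; the capped enumerator
  signals truncation and the Pareto-style DP is the scalable path for
  brackets.
* Single character, single rate; no model selection is attempted between
  the symmetric and ordered-rates chains.
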