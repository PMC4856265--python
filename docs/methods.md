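# Methods

## Model

`msnc` performs Bayesian inference of a rooted phylogenetic network Ψ
(topology plus branch lengths in coalescent units) and inheritance
probabilities Γ from multi-locus gene-tree topology data under the
multispecies network coalescent (MSNC).  The posterior is

    p(Ψ, Γ | G) ∝ p(Ψ) p(Γ) ∏_i p(g_i | Ψ, Γ),

where `G = {g_1 … g_m}` are per-locus collections of rooted gene-tree
topology estimates.  Gene-tree uncertainty is handled by letting each locus
contribute a *set* of estimates (typically 100 bootstrap trees); the locus
likelihood is the unweighted arithmetic mean of the topology mass over that
set, computed after deduplicating the set with multiplicity weights (which
leaves the value unchanged and the computation much cheaper).  Gene-tree
branch lengths are deliberately ignored: estimated coalescence times in
real multi-locus data sets are severely underestimated and would force all
network nodes toward the leaves, so topology-only inference is both the
intended and the practically robust regime.

Networks are binary: internal tree nodes have one parent and two children,
reticulation nodes two parents and one child, the root two children.  Each
reticulation node carries one inheritance probability γ shared across loci;
the two incident parent edges receive γ and 1 − γ.

## The gene-tree topology mass function

`gene_tree_mass` computes P(topology | Ψ, λ, Γ) exactly.  Backward in
time, the alleles sampled at the leaves coalesce within each network
branch at rate C(k,2) per coalescent unit, and at each reticulation node
every surviving lineage independently follows a parent edge with that
edge's inheritance probability.  The implementation is a dynamic program
over *configurations* — the set of uncoalesced gene-tree clades present on
a branch, encoded as bitmasks:

* Within a branch with `u` entering and `v` leaving lineages, the
  transition weight is `g_{u,v}(t) · w / d_{u,v}` where `g_{u,v}(t)` is
  Tavaré's lineage-count transition probability, `d_{u,v} = ∏_{k=v+1}^u
  C(k,2)` counts all pairwise-merger sequences, and `w` counts the merger
  sequences consistent with the gene tree (linear extensions of the merger
  forest).
* At a reticulation node, the DP enumerates all 2^k subsets of the k
  arriving lineages with weight γ^a (1−γ)^b.
* Above the root every remaining lineage must coalesce (`t = ∞`).

The two parent edges of a reticulation carry *correlated* configurations,
so the DP tracks joint tables ("blocks") of mutually dependent open edges
and joins blocks lazily when their edges meet at a node; on a tree every
block holds a single edge and the DP reduces to the standard per-branch
recursion.  Per-branch transitions are memoized per evaluation, and the
combinatorial transition structure is cached per gene-tree topology.
Complexity is exponential in the reticulation count and the per-branch
lineage count; at the package's target scale (≤ 8 taxa, ≤ 3 reticulations)
one evaluation costs 0.1–50 ms.

`g_{u,v}(t)` is evaluated by the closed-form alternating sum with
compensated (`fsum`) accumulation, clamped to [0, 1], and refused beyond
u = 12 lineages rather than silently degraded; the test suite pins it to an
independent matrix-exponential of the pure-death generator.  The whole mass
function is pinned to (a) exact normalization over all rooted topologies,
(b) an independently coded coalescent-history enumeration on trees, and
(c) Monte-Carlo frequencies from the simulator.

## Priors

`p(Ψ)` factorizes into a Poisson(ν) prior on the reticulation count m
divided by T_{n,m} (the number of network topologies with n leaves and m
reticulations, so that topologies within a count class are equally
weighted), i.i.d. Exponential(δ) branch lengths, and an optional
Exponential(η) penalty on a length-coupled topology statistic.  The
implemented statistic is the *reticulation span* (summed length of the two
edges entering each reticulation node); η = 0 by default, which disables
the term — a deliberate choice, since the exponentially distributed
topology quantity is not identified further and a span penalty is the
reading most consistent with conditioning on the branch lengths.  The
statistic is pluggable.  `p(Γ)` is uniform on [0, 1] per reticulation
node.  A candidate graph violating the network definition (cycle, parallel
edge, extra root, degree or negative-length violation) receives prior
probability zero.

T_{n,m} is evaluated in one of three modes.  `enumerate` counts exactly by
exhaustive generation with canonical-key deduplication (guarded to n ≤ 5,
m ≤ 2; e.g. T(3,0) = 3, T(3,1) = 21, T(5,0) = 105).  `constant-1` drops
the factor.  The default `estimate` uses exact counts inside the guard and
extends beyond it with an insertion-count surrogate — each added
reticulation multiplies the class size by about (E+1)·E / m placements,
with E the current edge count, anchored at the last exact count.  The
surrogate matters: without the T factor the posterior at realistic sizes
spreads over many likelihood-equivalent states that differ only by a
spurious reticulation, because the Poisson alone penalizes an extra
reticulation by just log(ν/(m+1)).  The estimate restores the strong
class-size growth (log T(7, m) ≈ 9.2, 14.3, 19.1 for m = 0, 1, 2) at no
enumeration cost; it overestimates absolute counts by a factor ~2–3 per
level (calibrated against exact counts at small n), which only strengthens
the complexity penalty slightly.

## Proposal kernel

Seven moves, selected hierarchically: with probability κ a
dimension-changing move (Add-Reticulation with probability κ₁, else
Delete), otherwise with probability ω a non-topology move (Change-Length
with ω₁, else Change-Inheritance), otherwise a topology move (Move-Tail /
Move-Head / Flip-Reticulation with ξ₁ : ξ₂ : ξ₃).  On a tree the moves
requiring a reticulation are unavailable and their probability mass is
reabsorbed within the group (Add absorbs Delete's, Change-Length absorbs
Change-Inheritance's, Move-Tail the whole topology group).  Defaults:
κ = 0.2, κ₁ = 0.5, ω = 0.55, ω₁ = 0.7, ξ = (⅓, ⅓, ⅓); windows 0.5
(lengths, reflected at 0) and 0.1 (γ, reflected into [0,1]); the fresh
reticulation-edge length is proposed from the branch-length prior
Exponential(δ) so that part of the acceptance ratio cancels; the
reticulation count is capped at one less than the number of taxa.

Hastings ratios follow from uniform choices over eligible edge sets,
uniform attachment heights along destination edges, and the stated
densities for fresh parameters; eligible-set and destination counts enter
the ratio whenever they differ between the forward and reverse states.
With attachment heights as the auxiliary variables, the dimension-matching
map of Add/Delete-Reticulation is a permutation-plus-shear with |J| = 1,
so the Jacobian term is identically zero (it is still carried separately
in `ProposalResult`).  Delete-Reticulation is restricted to reticulation
edges whose tail is a non-root internal tree node — exactly the class Add
creates — so every delete has a well-defined reverse add; reticulation
edges with root or reticulation tails (reachable via Move-Head/Flip) are
simply not directly deletable, which only reshapes mixing, not the
stationary distribution.  Invalid candidates are returned and die at the
prior, as the three enumerated violation conditions prescribe; moves with
empty eligible sets are skipped and count as rejected iterations, keeping
the kernel well defined.

Every move records the random choices that produced it and the
deterministic choices that reverse it; the test suite replays the reverse
and asserts the state is restored and log-Hastings + log-Jacobian is
exactly antisymmetric, and prior-only chains are checked against the
truncated-Poisson reticulation-count marginal and the Exponential length
marginal.

A validation-only `freeze_lengths` mode pins all branch lengths at 1 and
attaches at edge midpoints, realizing a finite topology-only state space
on which chain frequencies are compared with an exhaustively computed
posterior (total variation < 0.02 at 10⁶ iterations).

## Sampler

Algorithm: standard Metropolis–Hastings over (Ψ, Γ) with log r =
Δlog-likelihood + Δlog-prior + log-Hastings (+ log-Jacobian), burn-in
discard (default 10% of the chain) and thinning (default keeps ~10⁴
records).  Runs are bit-reproducible given (data, config, seed).  The
default initial state is a greedy consensus tree of the input gene trees
(clades ranked by mean bootstrap support, completed randomly) — a
deliberate departure from a random start: it removes most of the
tree-search burn-in and is standard practice in Bayesian phylogenetics;
`init="random"` remains available, and prior-only runs always start
random.  The 95% credible set ranks distinct topology keys (lengths and γ
marginalized) by posterior frequency and returns the smallest prefix
reaching the level, ties broken lexicographically; the representative
network per key is the highest-posterior sample.  Likelihood-
indistinguishable credible-set members (best sampled log-likelihoods
within 1e-6) can be flagged via `MSNCResults.indistinguishable_keys`.

## Simulator and synthetic data

`simulate_gene_tree` draws genealogies by the same backward-in-time
process the likelihood integrates over, and the central cross-module check
of the package is that simulated topology frequencies match
`gene_tree_mass` within binomial error.  Sequences evolve i.i.d. per site
along the simulated gene tree; the expected number of substitutions per
site on a branch is (θ/2) × its coalescent-unit length (the θ = 4Nμ
convention with time in 2N-generation units — the dominant convention in
MSC simulation pipelines; configurable).  The substitution model defaults
to Jukes–Cantor with a full GTR hook.  Bootstrap gene trees are
re-estimated per locus by site resampling followed by a pluggable engine:
FastTree (approximate maximum likelihood, used when the executable is on
the PATH, mirroring how bootstrap gene trees are built in practice) or the
internal Jukes–Cantor + neighbor-joining fallback (scikit-bio), each
rooted at the designated outgroup.

The three bundled model networks (`fixtures/model_networks.enwk`) have
seven taxa with outgroup O, 1/2/3 reticulations, branch lengths between
0.5 and 1.5 coalescent units, and fixed inheritance probabilities.  They
were designed so that each reticulation displaces a whole cherry (or a
leaf between two such backbones) with balanced-to-strong inheritance —
the massive-introgression regime of the hybridizing species complexes
such data sets come from — because a reticulation that merely reroutes one
peripheral lineage with a short post-reticulation branch is provably
unidentifiable from ~10² loci of topology data (the best tree trails the
true network by only a few nats).  Under these networks, 50 loci of
1000-site alignments at θ = 0.036 give bootstrap trees that differ from
the true gene trees on ~9–16% of internal branches depending on the
engine and seed.

What the generator does *not* emulate: intra-locus recombination, indels,
rate heterogeneity across sites and loci, alignment error, and
non-identically-distributed loci.  Passing the validation study therefore
shows the inference machinery is correct and adequately powered under the
model's own assumptions, not that those assumptions hold for any
particular empirical data set.

## Problem sizes used by the test suite

Chosen as the package's validation scale: likelihood normalization and
simulator agreement on 3–4-taxon networks at 10⁵ replicates; prior
recovery over 2×10⁵ prior-only iterations (3 taxa, reticulations capped at
2, exact T counts); enumerable-posterior agreement over 10⁶ frozen-length
iterations; network recovery from 128 loci of exact gene-tree topologies
under the 1-reticulation model network with a 2×10⁴-iteration chain capped
at two reticulations (the cap follows the precedent of bounding
reticulation counts for computational reasons in published reanalyses);
estimation error at 50 loci × 100 bootstrap replicates.  The chain scale
is far below production runs (10⁶–5×10⁶ iterations); the posterior under
128 exact loci concentrates strongly enough that the reduced chain mixes
through the relevant region.

## Known limitations

* Likelihood cost grows exponentially with reticulation count and lineage
  count; ≥ 4 reticulations or ≥ 10 taxa per locus are impractical.
* One inheritance probability per reticulation node shared across loci
  (the usual simplification); per-locus Γ is not implemented.
* Topology-only likelihood: gene-tree branch lengths are never used.
* Credible sets can legitimately contain likelihood-indistinguishable
  topologies (e.g. different temporal orderings of reticulations between
  the same taxon pairs); the summary reports them as distinct.
* No multi-chain convergence diagnostics; trace inspection and per-move
  acceptance rates only.
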