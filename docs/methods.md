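# Methods

## Model and update semantics

The model is a classical synchronous Boolean network over a signed directed
graph. Node states are binary; at every step each free node j computes the
sum of ω_ij·σ_i(t) over its inputs and switches on iff the sum is at least
its threshold φ_j. All thresholds are 0, so the tie (equally many active
activators and repressors, or no active input at all) resolves to ON: the
rule is activation-dominant, and a node with no inputs is constitutively on
unless forced off. This tie-break is not a free choice — it is what makes
an input-free node active and is required by every quantitative result the
package reproduces.

Constitutive perturbations are modelled as rule-table overrides: a forced
node takes its forced value after every update, ignoring its inputs, but
its *current* state still feeds downstream threshold sums. The alternative
semantics (clamping the input state before evaluating the sums) was
considered and rejected: it changes the transient structure of the
statespace and is inconsistent with the basin sizes the model is known to
produce. One consequence adopted throughout: a transient bit-flip applied
*at* a forced node is reasserted by the override before it can propagate,
so noise at a clamped node never switches the steady state.

System states are encoded as integers with bit i holding node i's state.
Node order is fixed (AR, JUN, TP53, SP1, E2F1, MYCN, MXD1, RELA, MYC, FOS,
HIF1A, SP3, STAT3, NR2F2, TERT, then ETS2 in the extended model) so state
encodings are reproducible across runs and machines.

## The canonical network

The packaged 15-node network carries 92 interactions (50 activating, 42
repressive); every non-TERT node has exactly one direct signed edge to
TERT (7 activators, 7 repressors) and TERT has no outgoing edges. Two of
the 92 edges — RELA → STAT3 (activation) and TP53 → MYCN (repression) —
are not recoverable from the published interaction tables, which list 90;
they were reconstructed from the model's published invariants. The
reconstruction is over-determined: the activation/repression module edge
censuses (31 = 22+9 and 27 = 9+18), module node memberships and diameters,
the printed betweenness values, the basal basin sizes and transient lengths
(20156/12612, 9/8) and the inhibitor-modified basin sizes (26002/6766)
jointly admit exactly this one edge pair, and with it every other published
statespace fraction reproduces to the printed precision. Two textual
statements remain slightly inconsistent with the reconstructed model and
are treated as imprecision of the source rather than model error: the
ERK-inhibitor steady state also differs from basal state 1 at the FOS bit
(trivially — FOS is forced off by that ruleset), and the MYC+SP3 double
suppression leaves two TERT-on basins whose sizes sum to the quoted 8.9 %
rather than a single basin.

## Statespace analysis

All 2^N transitions are computed vectorised (chunked batches of 2^16
states, int8 matrix products), bounded by default at N = 24 to cap memory.
Cycles are located by pointer doubling — squaring the successor map N+1
times maps every state into its own attractor cycle — which is equivalent
to iteratively stripping never-reached leaf states until only the
input-degree core remains. Since the graph is functional, the weak
component of a state equals the set of states sharing its attractor, so
basins are assigned by attractor without building an undirected copy.
Transient lengths (steps to the first cycle state) come from a reverse BFS
over predecessor lists; the dominant-basin ordering breaks ties
deterministically by smallest cycle state. A limit cycle counts as
target-on only if the target bit is set in every cycle state.

## Perturbation protocols

*Single scans* force each non-target node in the direction that opposes the
target (activators off, repressors on); a companion generator forces every
node off (RNAi-style co-suppression), used for double scans on a
MYC-suppressed background. The published account of the double-scan
protocol is ambiguous between these conventions, so both are implemented
and labelled; the explicitly documented cases (AR and SP3 co-suppression)
use forced-off. The scan metric is the stable-on fraction: the proportion
of all 2^N states whose trajectory ends in a target-on attractor.

*Bit-flip noise* requires a fixed-point origin; flipping a node of a
limit-cycle attractor is left undefined and raises an error. The target
gene is excluded from flipping (denominators of 14 on the 15-node model).

*Rule-set shifts* evolve an attractor state of one ruleset under another,
modelling treatment onset/wear-off applied to each network state.

## Module extraction and metrics

Self-loops are removed, nodes are partitioned by the sign of their direct
target edge, and the four edge sets (positive edges within the activator
set, activator→target, negative activator→repressor, repressor→target) are
united; the repression module mirrors this. Iterative deletion of nodes
with total (in+out) degree < 2 then leaves exactly the overlapping system
of complete coherent feedforward triads (types I/IV for activation, II/III
for repression); the reduction is confluent, so deletion order is
irrelevant. Betweenness is directed geodesic betweenness with endpoints
excluded, normalised by (n−1)(n−2), with fractional credit over tied
geodesics. Diameter is the longest finite directed shortest path
(unreachable pairs ignored). Flow betweenness is optionally reported as the
raw Freeman max-flow form (Σ over ordered pairs of the max-flow drop when
the node is removed, unit capacities); the original analysis tool's scaling
convention is unknown, so these values are for qualitative comparison only.
The AM/RM edge ratio is undefined (NaN, excluded from medians with a count)
when the repression module is empty.

## Ensembles

The attack series deletes module edges independently with probability
p ∈ {0.10, 0.15, …, 0.70}, targeting the AM alone or AM and RM, never
touching target-incident edges (so the activator/repressor partition is
invariant). The published total of 600 networks is allocated as 13
probabilities × 2 modes × 23 replicates = 598 plus one extra replicate per
mode at p = 0.10; the allocation is configurable and recorded per record.
Per-record seeds derive from the master seed via `SeedSequence([seed, i])`,
making every record independently reproducible. Semi-random panels place
one fully downstream regulated node (mandatory signed edge from every
regulator) and seed every ordered regulator pair, self-loops included, with
probability equal to the density parameter; signs are Bernoulli(0.5).
Defaults follow the published panel: 100 networks at each density 0.1,
0.15, 0.2, 15 nodes. Edge-ratio populations grouped by stable-on count
{0, 1, 2, ≥3} are compared with the Wilcoxon rank-sum test (scipy
`ranksums`).

At the default 600-network allocation the group medians land within a few
hundredths of 0.78 / 1.04 / 1.14 / 1.36 across master seeds, with adjacent
group differences far below p = 0.01; the test suite asserts a ±0.15 band
plus strict monotone ordering, reflecting sampling variation of medians
over 600 draws, and additionally checks that a reduced 150-network series
preserves the ordering. The semi-random panel shows the same association
qualitatively (the zero-on-state group has the lowest median ratio); its
medians are not asserted numerically because the panel's topology space is
much broader.

## Synthetic screens

The generator emulates the *summary* output of a reporter screen: one
(factor, promoter) record per ordered node pair with a fold-change and a
p-value. True edges draw log-normal fold-changes centred at 2.5
(activation) or 0.4 (repression) with log-sd 0.15 — comfortably beyond the
1.5 / 0.667 cutoffs, matching the clearly separated effects the screen
reports; non-edges fluctuate multiplicatively around 1 (log-sd 0.1).
P-values are drawn directly (uniform on (0, 0.005) for true effects,
(0.05, 1) for nulls) rather than simulated from replicate-level assays,
because the construction stage consumes only the FC/p summary; the
replicate count is metadata. What passing tests show: the cutoff filter and
the downstream pipeline behave correctly on tables with this structure,
including exact recovery in the zero-noise limit and graceful degradation
as null fold-change noise grows (when null p-values straddle the
significance cutoff). What they do not show: robustness to correlated
replicate noise, transfection-efficiency artefacts or promoter
cross-talk, none of which the generator models.

## Numerical and interface choices

Percentages are rounded to one decimal where reported quantities are
percentages of statespace. Edge-list files carry the node order and target
in header comments so round-trips are lossless even for isolated nodes.
Pajek exports use 1-based vertex numbering (0-based indices internally).
CSV outputs are byte-stable for fixed config and seed; timestamps are
confined to the run log, which goes to standard error / a log file so
stdout remains pipeable.

## Limitations

The framework is qualitative: synchronous updates, unit weights and zero
thresholds cannot express dose dependence, and constitutive overrides are
an idealisation of knockdown/overexpression. Statespace enumeration is
exponential in N and intentionally capped. Asynchronous or probabilistic
updating, pre-image computation and general motif censuses (beyond the
coherent FFL modules) are out of scope.
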