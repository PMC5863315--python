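# Methods

## Model

The network is four simple undirected Newman–Watts graphs with a fixed
global node order (left-LGN, left-VC, right-LGN, right-VC; global index
= component × N² + row-major local index). Each component is an N × N
lattice with von Neumann (cross-like) adjacency and open boundaries —
2N(N−1) regular edges; corner degree 2, edge degree 3, interior degree
4 — plus m shortcut edges drawn uniformly **without replacement from
the node pairs not already joined**. Shortcuts therefore never
duplicate a lattice edge and never form self-loops, and each of the
four components draws its shortcuts independently. Thalamocortical
edges (m_tc per hemisphere) are sampled uniformly without replacement
over all (LGN node, VC node) pairs of the hemisphere and are directed
LGN → VC in the main model (`tc_directed=False` makes them undirected,
the comparison variant). Callosal edges (m_cc) are sampled the same
way over (left-VC, right-VC) pairs and are always undirected. All
synaptic weights are 1; the data model accepts other weights but no
learning rule exists.

Node dynamics are a refractory-excitable chain S, A₁…A_d, R in
discrete time with synchronous update. The input of node i is
Σⱼ wᵢⱼ oⱼ(t) + Iᵢ(t) with oⱼ = 1 iff j is in an active stage.
Transitions: S→A₁ iff input ≥ T; Aⱼ→Aⱼ₊₁ (j < d) iff input ≥ T, else
→S; A_d→R and R→S unconditionally. The R→S step is unconditional; a
recovered node simply obeys the ordinary S rule on the next step. The
forced A_d→R transition is the model's only inhibitory mechanism: a
node active d consecutive steps is silenced for one step regardless of
drive. d = 2 reproduces the classic four-state (S/Y/Z/R) automaton.

The retina is represented purely as the input signal: a single-step
pulse of amplitude 1 delivered at t ≡ phase (mod P) to the stimulated
first-row LGN nodes (phase 0 by default, identical in both
hemispheres). A sustained-over-P stimulus would pin the stimulated
node to the three-step fire–fire–recover cycle rather than the drive
period, so the pulse-train reading is the one consistent with a
P-periodic drive.

## Parameters

| name | meaning | default | why |
|---|---|---|---|
| N | lattice side; N² nodes per graph | 10 | standard study scale (400 nodes total) |
| m | shortcuts per component | grid {3,9,27,81} | spans near-lattice to strongly small-world |
| m_tc (m′) | thalamocortical edges/hemisphere | grid | at m=m′=m″=27 the cortical wiring fractions (≈11% thalamocortical, ≈5% callosal) match mammalian estimates |
| m_cc (m″) | callosal edges | grid | — |
| T | firing threshold | 1 | one active neighbor (or the pulse) suffices |
| P | drive period (steps ≡ ms) | 10 | a 100 Hz pulse train, the retinal band |
| d | max consecutive active steps | 2 | stronger inhibition than larger d; the canonical choice |
| amplitude | pulse height | 1 | unit-magnitude stimulus |
| horizon / window | steps simulated / trailing analysis window | 200 / 100 | the dynamics reach their permanent regime well before t = 100 (the sweep counts are bit-identical for transients 100, 200 and 400) |
| phase | pulse offset | 0 | shift-invariant for classification; configurable |

Initial condition: all nodes susceptible at t = 0 — the unique
quiescent state, making every run reproducible with no burn-in draw.

## Period detection and classification

Activity is stored as exact integer active-node counts per component
(percentages are derived views), so recurrence can be tested by exact
equality — no tolerance to tune. The detected period is the smallest
p ∈ [1, window/2] with x(t) = x(t+p) for every valid t in the trailing
window; the window/2 cap means every reported period is confirmed by at
least two full cycles, and anything longer counts as aperiodic *within
the window*. A constant series (e.g. a silent cortex) has period 1 and
therefore classifies as OTHER_SYNC, not ETA1/ETA2, since its period is
not P. When all four components are periodic the minimal integer
ratios rᵢ = pᵢ / gcd(p₁…p₄) are reported; the general "synchronized"
notion (all four periodic with integer ratios) is the OTHER_SYNC
umbrella, while ETA1/ETA2 are the two operational categories the
campaign counts.

## Sweep protocol and seeding

For each grid triplet, `n_networks` networks are generated; in
single-site mode all N² (left site × right site) input combinations
are simulated per network, in full-row mode one run per network. The
full protocol is 64 triplets × 100 networks × 100 inputs = 6.4 × 10⁵
single-site runs, and 64 × 10 000 × 1 full-row runs; `n_networks` is
the scale knob for reduced sweeps. Fresh networks are drawn per
triplet. Child generators derive deterministically as
`SeedSequence(master_seed, spawn_key=(triplet_index, replicate))`, so
any sub-sweep can be recomputed in isolation and identical configs give
byte-identical tables. Marginal tables are computed from the stored
per-triplet counts, never re-simulated.

## Numerical implementation

Stepping is array-vectorized: states live in an int8 matrix (batch ×
nodes), the input sum is one sparse in-adjacency product per step, and
the transition rules are branchless `where` chains. Single-site mode
batches all N² schedules of a network; full-row mode batches networks
through a block-diagonal adjacency. A two-buffer pure-Python reference
update and a brute-force recurrence scanner serve as independent
oracles in the test suite; structural metrics (all-pairs BFS distances)
are cross-checked against networkx.

The acceptance script reports reduced-scale sweeps — 10 networks per
triplet (single-site) and 625 per triplet (full-row), i.e. 16 000 and
10 000 simulations per marginal — scaled to the full campaign's
160 000-run cells. At these sizes the binomial standard error of a
marginal fraction is ≲ 0.01, small against the ±0.05 band used for
comparisons.

## What the generator does and does not emulate

The synthetic networks realize exactly the study's topology family:
independent shortcut draws, uniform cross-edge sampling, unit weights.
They do not emulate spatially organized (retinotopic) thalamocortical
maps, weighted or plastic synapses, conduction delays, stochastic
firing, or a modeled retina — so passing tests demonstrate properties
of the wiring-vs-synchronization mechanism, not quantitative
predictions for biological tissue.

## Known limitations and open choices

* Whether shortcut sampling may duplicate an existing edge is not
  uniquely determined by the model family; this implementation forbids
  duplicates (simple-graph convention). The alternative yields
  slightly fewer distinct shortcuts and hence marginally longer path
  lengths and can shift sweep fractions by a few percentage points at
  intermediate m.
* The subharmonic-cortex (ETA2) fraction at intermediate m is the
  quantity most sensitive to such micro-conventions; drive-locked
  (ETA1) fractions at extreme m are robust.
* The η₂-vs-m″ trend is a "tends to increase": adjacent-cell gaps in a
  marginal are ~0.007 in fraction, below Monte-Carlo resolution at
  reduced scale, so tests assert the endpoint increase and a positive
  trend slope rather than strict adjacent ordering.
* Asynchronous update schemes, noisy dynamics and spectral period
  estimation are out of scope by design.
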