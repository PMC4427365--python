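# Methods

This note documents the model behind `trajmap`, the algorithmic choices
made where the method leaves room, the synthetic systems used to test it,
and the known limitations.  Notation: q denotes the conformational
coordinates (here backbone torsion angles), τ a trajectory-piece length,
and ps the time unit used throughout.

## Trajectory mapping

A trajectory piece i of length τ is mapped to

    v_i = (1, ⟨Â_1⟩_i, …, ⟨Â_n⟩_i),     ⟨Â_μ⟩_i = (1/τ) ∫ Â_μ(q_i(t)) dt,

with basis functions orthonormalized under a reference sample,
⟨Â_μ Â_ν⟩_ref = δ_μν, and Â_0 ≡ 1 carried implicitly as component 0.
Time averages are plain frame means (rectangle rule).  Because
P_i(q)/P_ref(q) expands in the orthonormal basis with coefficients
⟨Â_μ⟩_i, the inner product v_i·v_j estimates the overlap integral
∫ P_i P_j / P_ref dq, and the scaled inner product (SIP) — the cosine of
the two mapped vectors — is ≈1 for pieces equilibrated in one metastable
state and ≈0 for pieces in disjoint regions.  Small negative SIPs from
finite samples are reported unclamped.

The covariance of mapped vectors ties the method to time-correlation
analyses: with C_μν(t) the feature cross-correlation at lag t, the sample
second moment of the mapped vectors equals the lag-weighted sum
(1/L) Σ_{δ=0}^{L−1} w_δ (1 − δ/L)[C(δ) + C(δ)ᵀ], w_0 = ½, w_δ = 1
otherwise — an exact discrete identity that the test suite checks to
numerical precision.

### Basis functions

For D sequential backbone angles the raw basis contains sin(kx), cos(kx)
per angle (k ≤ max_order, default 2) and all products
{sin,cos}(m·x_i)·{sin,cos}(n·x_{i+1}) with m, n ≥ 1, m+n ≤ max_order for
adjacent pairs — only sequential-neighbour correlations are modelled.  For
D = 22 and max_order = 2 this yields 172 functions (88 single, 84 pair).
Orthonormalization is symmetric whitening: centre the raw features over
the reference, eigendecompose the second-moment matrix, discard
eigendirections below `rank_tolerance` (10⁻¹⁰ relative) and scale by
1/√eigenvalue.  Whitening was preferred over Gram–Schmidt for
order-independence and numerical stability; centring makes every feature
orthogonal to Â_0.  Eigenvector signs are fixed deterministically (largest
component positive) so identical inputs give bit-identical transforms.

### Clustering and refinement

Clustering is greedy and seeded: the unassigned vector with the most
unassigned neighbours at SIP > r_l (default 0.95) seeds a provisional
cluster of itself plus those neighbours; the cluster representative — the
mapped vector of the pooled member frames, equivalently the length-weighted
mean of member components — is recomputed, and members failing
SIP > r_l against it are dropped.  If nothing survives the re-check, the
seed is kept as a singleton so the loop always terminates; ties break to
the lowest piece index.  Clusters strictly larger than `min_cluster`
(default 5) become metastable states; everything else returns to the
unassigned pool.

Refinement drives distinct states toward mutual orthogonality
(SIP < `state_orthogonality`, default 0.01).  For the most-overlapping
pair: if SIP > r_l the two are one state split by noise and are merged;
otherwise defining pieces whose SIP to the partner representative exceeds
`overlap_exclusion` (default 0.5) are stripped — from the *smaller* state
only.  The asymmetry is deliberate: an overlapping pair is typically a
genuine state versus a smaller cluster of mixed pieces straddling it, and
cluster size is the method's confidence proxy; symmetric stripping lets a
mixed cluster eat a genuine state's pieces.  A pair whose overlap has no
individually responsible piece carries an irreducible finite-basis /
finite-sample floor and is kept with the residual logged.  States falling
to `min_cluster` pieces or fewer dissolve back to the pool, mirroring the
strictly-greater identification rule.

### The top-down hierarchy

For each τ in a decreasing schedule: re-orthonormalize the basis on the
current working sample (default; a fixed level-0 basis is a switch), cut
the working stretches into τ-length pieces discarding remainders, map,
exclude pieces whose SIP to any existing state representative exceeds
`overlap_exclusion` (they belong to known states), cluster, identify, then
refine the *entire* state inventory.  Unassigned pieces' frames form the
next level's working stretches.  The per-level reference pools the working
frames **and** the defining frames of all states found so far: a basis
whitened on a sample that misses two disjoint states cannot distinguish
them, so refining old states in a working-sample-only basis fails.

Truly nested sub-states cannot surface in this pass — their pieces overlap
the parent state and are correctly excluded.  `find_substates` implements
the focused alternative: re-analyse one state's own sample (preferably its
indicator-derived dwell segments, which are purer than the defining
pieces) in isolation at shorter τ.

### Indicators, assignment, events

The state-indicator curve f_α(t) is the SIP between the window
[t−Δt, t+Δt] (clipped at the ends) and state α's unit representative.  The
half-window Δt is per-state: "auto" uses max(25, level_τ/40) frames,
because a state identified from τ-length pieces can take up to ~τ to
equilibrate internally, while short-τ states need only the noise floor.  A
frame is assigned to the argmax state when the summed indicators exceed
0.9, else left unassigned; ties break to the lowest state.  Maximal
constant-label runs are dwell segments; transitions are recorded between
consecutive distinct-state segments (unassigned gaps in between do not
cancel an event).  Two opt-in cleanups exist: `bridge_gap` absorbs short
unassigned gaps flanked by the same state, and `min_segment` demotes
assigned runs shorter than the indicator window (which cannot resolve
them) to unassigned.  Both default to 0.

### Kinetics

τ_life per state is the mean duration of its continuous stays.  Two
estimators are provided: the dwell-segment mean (used to report per-state
τ_life with its standard error, omitted below 3 stays) and the
event-to-event residence mean, which the pipeline uses for the rate
network because it includes the unassigned boundary gaps symmetrically and
is immune to brief mid-stay indicator dips — dwell-segment durations carry
a boundary-blur bias that propagates directly into rates.

τ_eq per state averages per-piece estimates: the relaxation curve —
SIP between the piece's growing prefix [0, u] and the state
representative, on 50 log-spaced prefix lengths — is fitted with
c{1 − exp[−(a·u)^b]} and τ_eq^est = Γ(1/b)/(a·b) (equivalently
Γ(1+1/b)/a).  The fit is bounded (a > 0, 0.1 ≤ b ≤ 4, 0 < c ≤ 1.2),
initialized at b = 1, c = the final value, a = 1/u_half, with five
jittered restarts on failure.  Fits pinned to a parameter bound
(b ≤ 0.12, c ≥ 1.19) or with RMS residual > 0.08 have not converged to
the model and are excluded with a warning.

Observed rates follow k_ij = N_ij / (τ_life^i · Σ_j N_ij), so each state's
outgoing rates sum to 1/τ_life^i exactly.  The network is kept as
observed: single-directional edges are preserved and detailed balance is
not imposed, since finite sampling need not satisfy it.

### The overlap-relaxation diagnostic

A discrete reversible generator matrix stands in for the Fokker–Planck
operator: with stationary law π, the symmetrized propagator has
orthonormal modes φ_n, rates λ_n ≥ 0 (λ_0 = 0, φ_0 = √π), and an initial
distribution with coefficients C_n relaxes such that the self-overlap of
its time-averaged distribution obeys

    ⟨P_avr(t)|P_avr(t)⟩ = 1 + (1/t²) Σ_{n>0} (C_n/λ_n)² (e^{−λ_n t} − 1)²,

decaying as 1/t² once the exponentials die.  The same quantity is
estimated by Monte-Carlo: jump paths are simulated, each path's [0, t]
occupancies give its time-averaged features in the exact eigenmode basis,
and the squared norm of the ensemble-averaged vector estimates the
overlap.  Agreement of the two routes (and the −2 log-log tail slope)
validates the sample inner-product estimator that the whole method rests
on.  `pavr_overlap_curve` applies the same construction to real trajectory
ensembles.

## The synthetic generator

The generator emulates a peptide's torsional dynamics as a continuous-time
Markov jump process over hidden states (Gillespie simulation of a rate
matrix Q, discretized at the frame interval) with, per state and angle, a
von Mises emission around a state-specific mean.  Within a dwell each
angle follows an Ornstein–Uhlenbeck recursion on its deviation from the
mean, wrapped on output; the stationary marginal is a wrapped normal with
σ² = 1/κ, a good von Mises approximation for concentrations κ ≥ 2 (all
built-in specs use κ = 8).  Dwell starts draw the deviation from the exact
von Mises.  Everything is reproducible from a single seed.

What it does **not** emulate: anharmonic basin shapes, concerted
multi-angle transition paths (jumps are instantaneous in the emission
means), solvent memory, and intra-basin slow modes beyond a single
autocorrelation time.  Passing tests therefore demonstrate the machinery's
correctness on exactly-specified kinetics, not performance on real MD
landscapes.

### Study conditions and their rationale

A signal-to-noise analysis fixes the regime in which the default fixtures
operate.  After whitening, the total between-state variance of mapped
vectors is bounded by n_states − 1 (the between-scatter has rank
n_states − 1 with eigenvalues ≤ 1), while the piece-average noise scales
as rank · τ_corr / τ_piece frames.  Intra-state SIP ≈
(1+S)/(1+S+N) with S ≲ n_states − 1 and N the noise power, so r_l = 0.95
requires N ≲ 0.15.  The default 3-state system therefore uses 2 angles
(order-2 basis of rank 12), sub-frame angular decorrelation (0.4 ps at
1 ps/frame), dwells of 300 ps and 10⁵ frames, with jumps on a cycle
(0→1→2→0) so that every generator entry is identifiable from lifetimes
alone, free of branching noise.  τ = 150 ps sits inside
τ_eq ≪ τ ≤ τ_life.

τ_eq estimation needs the opposite regime: the relaxation curve only
resolves equilibration when a short prefix covers the state poorly, i.e.
when the basis is rich relative to the state count and the internal
correlation time spans many frames.  The kinetics fixture uses 4 angles
(rank 28), 10 ps mixing, 9 ns dwells, τ = 3 ns and 4·10⁵ frames; there
τ_eq comes out at 0.3–2 ns with τ_life ≈ 8–15 ns, comfortably satisfying
τ_eq < τ_life.  On the fast-mixing fixtures τ_eq is genuinely below one
frame and the estimate instead reflects the sampling-noise floor — such
fixtures are outside the estimator's valid regime by construction and are
not used to test it.

The multi-timescale fixture places slow (5 ns) and fast (300 ps) states in
*different* regions of angle space on a nearest-neighbour ring, exercising
the top-down schedule exactly as intended (slow states at τ = 2 ns, fast
ones at τ = 150 ps from the remainder).  The nested fixture (2 super-states
× 2 sub-states, sub dwell 400 ps, super dwell 32 ns, 10⁶ frames) exercises
super-state discovery top-down and sub-state discovery via the focused
search.  The diffusive fixture interleaves metastable states with a
corridor of states whose dwell equals their mixing time (κ = 1) on a ring;
stationary occupancy is proportional to dwell, so the corridor carries a
chosen fraction of frames that the method should leave unassigned.

Problem sizes throughout (10⁵–10⁶ frames, 2–4 angles) were chosen so each
fixture has ≥ ~100 of the events its assertions count while remaining
quick to simulate and analyse.

## Numerical conventions

- Angles in radians, wrapped to (−π, π]; −π maps to +π.
- Torsions by the atan2 two-plane construction; cis = 0, trans = +π;
  collinear atom triples raise an error naming frame and quadruple.
- φ_i = (C′_{i−1}, N_i, Cα_i, C′_i) for residues i ≥ 2 and
  ψ_i = (N_i, Cα_i, C′_i, N_{i+1}) for i ≤ R−1, interleaved N→C:
  2(R−1) angles for an R-residue chain.
- Remainder frames at piece cutting are discarded, matching the
  segmentation arithmetic (52 pieces of 100 ns recut at 30 ns give 156).
- Tie-breaks everywhere to the lowest index; randomness enters only
  through the synthetic generator's seed, so the analysis path is
  deterministic given fixed inputs.
- Time unit ps in all files and APIs; the CLI accepts `ns`/`ps` suffixes.

## Known limitations

- Inter-state SIP after refinement carries a floor (~0.03 on the default
  fixture) from retained pieces with slight admixture; only a much more
  aggressive strip threshold would remove it, at the cost of discarding
  genuine pieces.
- Dwells shorter than the indicator window are unresolvable; their jumps
  are attributed to bridging edges (e.g. a short visit to B inside A→B→C
  may register as A→C), slightly deflating branching fractions.
- `min_cluster`-sized coincidental clusters of mixed pieces can transiently
  become states at τ beyond the slowest lifetime; refinement dissolves
  them, but schedules should start at or below the slowest expected
  τ_life.
- The τ_eq estimate saturates at a sampling-noise floor proportional to
  basis rank; states whose true equilibration is faster than a few frames
  report the floor, not the dynamics.
- Jump-process transitions are instantaneous, so the generator cannot test
  behaviour on gradual (diffusive) barrier crossings.
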