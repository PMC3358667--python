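# Methods

## Degradation model

Serum proteolysis is modelled as a continuous-time Markov jump process
on a bipartite cleavage graph. Peptide nodes hold particle counts; each
event node consumes one particle of its substrate and produces one
particle of the prefix and one of the suffix (Petri-net semantics), at a
per-particle rate ρλ_p — the product of the site/enzyme affinity ρ and
the enzyme activity λ_p. Sources (nodes never produced inside the graph,
in practice the sequenced precursors) gain particles at constant rate
φ*; leaves (nodes never cleaved) lose particles at per-particle rate φ⊥.
Creation and complete degradation stand in for everything outside the
modelled network: upstream proteolysis producing the precursors, and the
disappearance of short fragments.

All reactions are zeroth- or first-order, so the stationary *means* of
the stochastic process satisfy the deterministic balance equations
exactly; no moment closure is needed. Only those first moments are used
for inference. The Gillespie simulator in `pepflux.synth` is an
independent stochastic oracle of this fact, not part of the inference
path.

Since both products of a cleavage are strictly shorter than the
substrate, peptide nodes ordered by decreasing length (lexicographic
within a length) are in topological order, and the balance system is
solved by a single forward sweep: sources as φ*/outflow-rate, interior
nodes as inflow/outflow-rate, leaves as inflow/φ⊥. A dense linear solve
of the same system is kept in the test suite as a second, independent
route.

## Affinity scores

A peptidase's specificity is a column-stochastic 21×8 frequency matrix
(20 residues + terminal-gap symbol × loci P4…P1,P1′…P4′). A candidate
site is scored by the product of the matched per-locus frequencies
raised to 8/(k+l), where k and l (each 1–4) are the residues actually
available on either side of the bond. The exponent makes truncated
windows commensurate with full windows: for a constant-frequency profile
the score is independent of window length. Loci beyond a terminus are
excluded from the product rather than scored against the gap row; the
gap row exists only because curated cleavage records themselves contain
terminal gaps. Cleavage detection is thresholding of this same score, so
detection and rate both derive from one quantity and detection is
monotone in the threshold. The global scale γ (default 1.0) is pure
gauge: it multiplies every ρ and is absorbed by the activity
normalisation.

## Graph construction and filling

In-silico digestion applies detection recursively to every generated
product until closure (a `max_depth` safety cap exists for pathological
thresholds). Fragments are identified by sequence alone: the same
subsequence reached through different lineages, or from different
precursors, is one node — mass spectrometry observes sequences, not
provenance.

Peptides are located in LC-MS data by monoisotopic mass (standard
residue masses via pyteomics), m/z over charges 1–8, and retention time
predicted by ordinary least squares on amino-acid composition (21
coefficients; the design must have full rank). Expected coordinates are
matched to same-charge peaks under the tolerance-scaled distance
d = √((Δmz/(mz·tol_ppm))² + (Δrt/tol_rt)²) with one dimensionless
cut-off (defaults: 10 ppm, 2 min, d ≤ 1). Assignment is greedy in
ascending d and one-to-one in peaks, so a feature is never counted
twice; intensities of one peptide's charge states are summed. After
filling, empty sources and empty leaves are pruned recursively (interior
empty nodes stay; a node with amount 0 counts as empty).

## Fitting

The parameter vector z stacks φ* (one per source), φ⊥ (one per leaf) and
λ (one per peptidase); the objective is Φ_v(z) − y_v over observed nodes,
well-posed for m ≥ n (enforced). Positivity is obtained by optimising
θ = log z with unconstrained Levenberg–Marquardt (MINPACK via
`scipy.optimize.least_squares(method="lm")`, ftol = xtol = gtol = 1e-10);
the scale-gauge rank deficiency is left to LM damping rather than fixed
during optimisation. Seven starts are drawn log-uniformly from
[1e-2, 1e2]; each run is capped at `max_iter`·(n+1) function
evaluations, i.e. roughly `max_iter` (default 200) LM iterations under
forward-difference Jacobians; the start with the lowest final rse wins
and everything is deterministic given the seed. Inside the residual
function θ is clipped to ±46 and non-finite residuals are replaced by a
large finite penalty, so wandering starts retreat instead of aborting;
unproductive starts are reported in the diagnostics rather than hidden.

Activities are identified only up to the joint scale of (φ*, φ⊥, λ) and
are reported as a composition (sum-to-one simplex) and through the
centred log-ratio. A sharper fact, found while validating: interior-node
balances are the *only* constraints on λ once the amounts are known —
each is linear and homogeneous in λ — so an enzyme whose cuts never
touch an interior node (every cut maps a source straight to leaves) is
structurally unidentifiable, its activity absorbed by the free φ*/φ⊥.
`infer.activity_constraint_matrix` exposes this diagnostic; activities
are fully identified up to gauge exactly when that matrix has rank
|P|−1.

## Significance and cross-sample reporting

The permutation null keeps the graph topology and randomly reassigns the
multiset of observed amounts over the observed nodes; the p-value is the
literal count fraction |{i : rse(ζ_i) ≤ rse(x)}| / n_perm (no add-one
correction, so p = 0 is possible). When no baseline rse is supplied, the
baseline fit uses the same fit options and the same per-fit seeding
stream as the refits, which makes the observed dataset exchangeable with
its permutations under the null — the property that yields uniform
p-values on null data. Permutation refits default to the baseline's
settings but accept reduced ones (e.g. 1–2 starts) for tractability at
n_perm = 1000.

The cross-sample activity matrix (samples × peptidases, clr values) uses
the intersection of detected enzymes by default; a union mode imputes a
sample's absent enzymes at its minimum observed normalised activity
before renormalising and re-transforming.

## Synthetic study conditions

The generator emulates the validation design of the method itself:
noisy observations are drawn per node from N(φ_v, (σ·φ_v)²), redrawn
until positive, at σ ∈ {0.1, 0.01, 0.001} for weak/moderate/good model
agreement. σ is read as *relative* noise because the observed amounts
are in arbitrary intensity units; `simulate_amounts(..., absolute=True)`
restores the literal absolute-σ reading.

Default conditions: 4 peptidases, 3 precursors of length 10–14, fully
observed graphs. Generated profiles give each enzyme a one-designated
dominant P1 residue (weight 1 − 1/s, s = 200) with near-uniform flanking
columns (Dirichlet, concentration 2.5·s per residue); distinct enzymes
get distinct P1 residues. With γ = 5·10¹⁰ the full-window score of a
matching site is order 1–100 while non-matching sites fall below 0.03,
so the detection threshold 0.15 separates the two populations with an
order-of-magnitude margin on both sides for any seed. True rates are
drawn as φ* ∈ U[5, 20], φ⊥ ∈ U[0.5, 2], λ log-uniform in [0.5, 2].
Precursor pools are resampled deterministically until the graph is well
posed: every precursor is a cleaved true source, every enzyme drives at
least one event, no node is simultaneously source and leaf, m ≥ n, and
the activity constraint matrix has rank |P|−1 with smallest retained
singular value ≥ 1e-4 of the largest (so recovery is not just formally
possible but well conditioned).

What the generator does *not* emulate: isotope envelopes and
chromatographic peak shape (one monoisotopic stick per peptide, at the
heaviest charge whose m/z fits a 100–2000 Th scan window), missing
observations (real graphs are mostly empty; benchmarks are fully
observed), shared peptidase specificities, and modification-carrying
peptides. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated conditions, not
performance on real serum data, where partial observation and correlated
specificities will loosen identifiability.

## Numerical choices and problem sizes

Frequency-matrix columns must sum to 1 within 1e-9; clr outputs sum to 0
within 1e-9; the linear-solve cross-check is required to agree with the
recursion to 1e-10 relative. Gillespie standard errors use 20
batch-means over the post-burn-in window. Validation problem sizes were
chosen so the whole battery runs in minutes on one core: benchmark
graphs of ~25–50 nodes, 50 graphs for the oracle sweep, 10 replicates
per noise level, 20 null datasets × 100 permutations (with single-start
refits) for p-value calibration, and a 6-node network for the
stochastic oracle.

## Known limitations

- Per-precursor provenance of identical fragments is deliberately not
  tracked.
- The consensus-matching rule is score thresholding; curated detection
  rules from specificity databases may differ.
- Exopeptidase ladders are treated as generic prefix/suffix events, not
  as a special ladder kinetics.
- rse weights absolute residuals, so high-abundance nodes dominate;
  with wide dynamic range the small-amount nodes contribute little to
  the fit.
- MINPACK reports function evaluations, not LM iterations;
  `iterations_per_start` records evaluations.
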