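# pepflux

Inference of serum peptidase activities from LC-MS peptide abundances by
modelling *ex vivo* proteolytic degradation as a first-order reaction
network on a **cleavage graph**.

Blood-serum peptidomes are shaped by ongoing proteolysis: endopeptidases
cut circulating peptides into shorter fragments, which are cut again or
degraded completely. The relative abundances of a precursor peptide and
its fragments therefore encode the activities of the enzymes doing the
cutting. `pepflux` turns a set of tandem-MS-sequenced precursor peptides,
a set of peptidase cleavage-specificity profiles (MEROPS-style frequency
matrices) and an LC-MS monoisotopic peak list into per-sample estimates
of peptidase activities, with permutation-based significance and
compositional (clr) reporting suitable for cross-sample clustering or
PCA. It is aimed at computational proteomics groups studying serum
degradomics.

## The model

The cleavage graph is a bipartite digraph: *peptide nodes* are all
subsequences reachable by cleavage, and each *event node* represents one
peptidase p cutting one substrate u at one bond into a prefix v and a
suffix w (written u = v † w). An event carries an affinity coefficient

ρ<sup>p</sup><sub>vw</sub> = γ ( ∏<sub>j∈J′</sub> f<sup>p</sup><sub>j,a<sub>j</sub></sub> )<sup>8/(k+l)</sup>

scoring the site context a<sub>P_k</sub>…a<sub>P1</sub>a<sub>P1′</sub>…a<sub>P_l′</sub>
against the enzyme's frequency matrix f<sup>p</sup> over the eight loci
P4…P1|P1′…P4′ (windows truncate near termini; the 8/(k+l) exponent is a
geometric-mean normalisation). Particles are created at source nodes S
(rate φ*), consumed from a substrate at per-particle rate ρλ<sub>p</sub>
by each event, and completely degraded at leaf nodes L (rate φ⊥). At
stationarity every node obeys the balance equation

φ*<sub>v</sub> + Σ<sub>u=v†w</sub> x<sub>u</sub>ρλ + Σ<sub>u=q†v</sub> x<sub>u</sub>ρλ
= x<sub>v</sub>( φ⊥<sub>v</sub> + Σ<sub>v=x†y</sub> ρλ )

whose solution Φ(z) is computed by a three-case recursion in topological
order. The parameter vector z = (φ*, φ⊥, λ) is estimated by multi-start
Levenberg–Marquardt least squares on the residuals Φ<sub>v</sub>(z) − y<sub>v</sub>
over the m observed nodes (solvable for m ≥ n = |S|+|L|+|P|; positivity
is enforced by optimising log z). Because Φ is invariant under joint
rescaling of all rates, activities λ are identified only up to scale and
are reported on the simplex and through the centred log-ratio transform.
Fit quality is the relative squared error (rse), and its significance is
the fraction of topology-preserving amount permutations that refit at
least as well.

## Worked example

Everything needed to exercise the pipeline can be generated
synthetically with a seed:

```python
import pepflux as pf

bench = pf.make_benchmark(pf.SynthConfig(seed=1))       # graph + ground truth
model = pf.ProteolysisModel(bench.truth.graph, bench.datasets[0.001])
res = model.fit(n_starts=7, max_iter=200, seed=0)
print(res.summary())
```

```
Proteolysis activity model
==========================================================
observed nodes (m):        35
parameters (n):            19  (S=3, L=12, P=4)
relative squared error:    3.21281e-11
starts / best / converged: 7 / 1 / True
seed:                      0

Peptidase activities (identified up to scale)
----------------------------------------------------------
peptidase               normalized           clr
pep00                     0.156112       -0.4224
pep01                     0.199892       -0.1752
pep02                     0.297995        0.2241
pep03                     0.346001        0.3735
----------------------------------------------------------
```

The data were simulated at relative noise σ = 0.001 from true normalised
activities (0.155887, 0.199777, 0.298077, 0.346260); the fit recovers
them to three decimals, and the rse ≈ 3×10⁻¹¹ says the stationary model
reproduces the observed amounts to noise level.
`res.permutation_test(n_perm=100, seed=0, n_starts=2, max_iter=100)`
gives p = 0.0: none of 100 permuted datasets fits as well.

The same stages are available as a CLI pipeline with inspectable
intermediate artifacts:

```bash
pepflux simulate --seed 1 --out bench/
pepflux digest  --matrices bench/matrices --precursors bench/precursors.fasta \
                --threshold 0.15 --gamma 5e10 --out graph.json
pepflux match   --graph graph.json --peaks bench/peaks.tsv \
                --rt-train rt_train.tsv --out filled.json
pepflux fit     --graph filled.json --seed 0 --out fit.json
pepflux permute --graph filled.json --fit-json fit.json --n-perm 1000 \
                --seed 0 --out permutation.json
```

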