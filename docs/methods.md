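# Methods

## Model and assumptions

The pipeline estimates interactions among `n` unmeasured signaling
components from the expression of `m` early genes under `n + 1`
conditions: an unperturbed baseline and one condition per perturbed
component.  Three assumptions carry the whole construction:

1. **Early-time linearity.** Early genes are transcribed by pre-formed
   factors, so over the first ~hour transcript accumulation is linear in
   upstream signaling activity.  Gene activity is therefore modelled as an
   (unknown) linear readout of component activities, and a weighted gene
   sum is a legitimate estimator of a component's activity.
2. **Log-normal replicate noise.** Expression measurements are treated as
   approximately log-normal; all significance statistics run on natural
   logs of the replicate values.
3. **Linear response regime.** Components operate near the linear range of
   their stimulus–response curves, so modular response analysis (MRA) —
   exact for linearised systems near steady state — applies to the
   estimated responses.

Natural log is used throughout; the entropy bound `ln n` of the
information score fixes that choice.

## Scoring (weight-matrix construction)

For gene `k` and perturbation `j`, with baseline mean `A_k`, perturbed
mean `G_jk`, log-means `LogA_k`, `LogG_jk` and log standard errors `dA_k`,
`dG_jk` (sample SD of logs over replicates divided by `√n_rep`):

- change matrix `C_jk = A_k − G_jk`;
- activity score `D_jk = s_j C_jk / ‖C_·k‖₂` with perturbation sign
  `s_j ∈ {−1, +1}`; the Euclidean norm over perturbations gives the
  invariant `Σ_j D_jk² ∈ {0, 1}` and makes all downstream quantities
  invariant to per-gene rescaling (an L1 option exists in config);
- Z statistic `Z_jk = (LogA_k − LogG_jk)/√(dA_k² + dG_jk²)`; P-score
  `P_jk = erf(|Z_jk|/√2)`, i.e. twice the standard-normal CDF from 0 to
  `|Z|` (a Student-t option with Welch–Satterthwaite degrees of freedom is
  available; the normal form is the default);
- information score `I_k = ln n − H(z̃_·k)` with `z̃_jk = Z_jk²/Σ_j Z_jk²`
  and `H` the Shannon entropy (`0·ln 0 = 0`); `I_k = 0` iff the gene
  changes equally significantly under every perturbation, `I_k = ln n`
  iff it changes under exactly one;
- weights `W_ik = D_ik P_ik I_k / A_k`.  Division by `A_k` stops highly
  expressed genes from dominating the weighted sums.

Degenerate cases are defined explicitly: an all-zero Z column scores
`I = 0` and `W = 0` (an uninformative gene); zero replicate variance with
differing means yields a ±∞ Z sentinel with `P = 1` ("certainly
changed").  When a column holds such sentinels — the regime of noise-free
synthetic data, where every real change has zero variance — `z̃` is
evaluated in its analytic limit: as all standard errors shrink at a
common rate, `z̃_jk → Δlog_jk²/Σ Δlog²` over the zero-variance entries.
This keeps the specificity score informative in the limit rather than
collapsing every changed gene to a uniform profile.  Equality of means
under zero variance is judged at 1e-9 relative tolerance so that float
residue from the simulator's linear solves does not masquerade as change.

## Inference

Estimated activities are `S = W Gᵀ`, `S0 = W A`, and the global response
matrix is `R = S − S0·1ᵀ`.  MRA inverts it:

    r = −[dg(R⁻¹)]⁻¹ R⁻¹,

giving local interaction coefficients with diagonal exactly −1;
`r_ij` is the linearised effect of component `j` on component `i`.
Inversion refuses matrices whose reciprocal condition number falls below
1e-10 (MRA amplifies estimation noise through the inverse), or whose
inverse has a zero diagonal entry.

Because each weight row carries an unknown positive scale, coefficient
magnitudes are not comparable across datasets and no magnitude cutoff is
applied.  Instead, genes are resampled: the leave-one-out (jackknife)
scheme recomputes the full pipeline with each gene removed, giving `m`
coefficient samples per ordered pair.  Every score is a per-gene quantity
taken across perturbations, so rerunning the scoring on a gene subset
equals dropping the gene's column of `W`; the implementation exploits
this (rank-one downdates of `R`, batched MRA) and a test asserts the
equivalence against the definitional per-subset recomputation.  A
bootstrap resampler (sampling `m` genes with replacement) is available
behind config for larger panels.

An edge is **significant** when `|μ|/σ ≥ Φ⁻¹(1 − α)` over its resamples
(`α = 0.05`, one-sided — the hypothesis is "one consistent sign"; a
two-sided variant is in config; `σ = 0` with `μ ≠ 0` counts as
significant; the boundary is inclusive).  `σ` is the plain sample SD over
resamples, with no jackknife variance inflation.  Pairs losing more than
20% of their resamples to singular subproblems are flagged unresolvable
and never significant.

With `E` independent experiments, the **consensus** keeps an ordered pair
iff it is significant *with the same sign* in at least `K` experiments
(default 4 of 5; the synthetic robustness study uses 3 of 5).  For
`K ≤ E/2` both signs could reach `K`; such conflicts are dropped and
reported.  `K = 1` equals the union of significant edges and retention is
monotone non-increasing in `K`.

Per-edge **gene contributions** decompose a response entry exactly:
`R_ji = Σ_k W_jk (G_ik − A_k)`; the table ranks genes by their term times
the sign of the total response, so the genes driving the observed edge
come first.  For an inhibitory perturbation of the source, a top-ranked
positive term marks a gene whose hyper-induction carries the inferred
inhibition.

## Synthetic benchmark

The simulator realises a known signed component network linearly:
interaction weights `M` (zero diagonal, spectral radius < 1 enforced) and
basal inputs `b` define the fixed point `S* = (I − M)⁻¹ b`; a perturbation
multiplies one component's basal input by a fold factor (0.2 by default —
an ~80% inhibition) and the network settles to a new fixed point.  The
true local coefficient matrix of this system is exactly `M − I`, which is
what the full pipeline should recover up to positive per-component
scaling.  Gene means respond linearly to relative activity changes,
`mean_jk = base_k (1 + Σ_i reg_ki ΔS_ij / S*_i)`, floored at a small
positive epsilon; replicates add truncated-Gaussian noise with SD equal
to `noise_fraction · mean` (a log-normal option with matched coefficient
of variation exists, since the scoring assumes near-log-normal data).
Four replicates per condition are simulated, matching the replicate count
of the motivating qPCR experiments.

The benchmark network has four components and ten genes: a mutually
activating S1↔S2 pair, S2 ⊣ S3, and a bi-fan inhibition of S4 by S1 and
S2; S3 and S4 are sinks.  G1, G2 and G4 read the S1/S2 pair, G6–G9 read
S3 (G6 is also the one good S2 reporter in that set; G7 also reads S2 and
S4), G3/G5 read S4, G10 is a single-component S1 reporter, and G4 carries
a strong S4 exception — the route by which the S2 ⊣ S4 signal is
detected.  The gene-regulation weights mix activation and repression and
are deliberately asymmetric between S1 and S2: identifiability of the
mutually coupled pair cannot rest on a single gene, or leave-one-out
resampling becomes unstable, and the mixed signs are what keep the
foreign-row leakage of multi-component reporters below the jackknife
significance threshold.  The source text describing this benchmark fixes its topology
and reporter sets but not its numerical constants; the constants here
were chosen, once, so that the reconstruction reproduces the documented
behaviour of the original study — exact noise-free recovery of the true
signed edges and consensus robustness to replicate noise up to ~20% of
the mean — and are part of the model definition, not user-tunable dials.

What the simulator does *not* emulate: saturation and other
nonlinearities of real dose–response curves, correlated noise across
genes or conditions (e.g. plate effects), feedback from genes onto
components, secondary transcription, and panel sizes beyond ten genes.
Passing benchmarks therefore demonstrate correctness of the inference
machinery in its assumed regime, not performance guarantees on real data.

Reconstruction quality is scored as **sign-similarity**: the fraction of
ordered component pairs whose status (absent / positive / negative)
matches the generating network; a value score (Pearson correlation of
coefficients over true edges, absences counted as zero) accompanies it.
A noise sweep simulates `E` experiments per level and repetition, runs
the pipeline per experiment, forms the K-of-E consensus, and scores
against truth.  All randomness derives from a single seed through a named
spawn schedule (level, repetition, experiment), so every sweep is exactly
reproducible; identical (model, seed) pairs give byte-identical datasets.

## Numerical choices

- Condition-mean snapping: simulated means within 1e-9 relative of
  baseline are set to baseline exactly, so zero-noise data produce exact
  `Z = 0` for unaffected genes.
- Information-score values within 1e-12 of 0 snap to exactly 0 (the
  equal-response endpoint is an exact statement).
- Jackknife requires `m ≥ n + 1` genes so each subproblem can still span
  the component space; singular subproblems are recorded as missing
  rather than aborting the run.
- Ties at the significance boundary are kept (inclusive `≥`).
- Reported runs: the robustness study uses 5 experiments per level,
  noise levels 5–30% of the mean, 3-of-5 consensus and 10 repetitions per
  level, the size at which level means are stable to well under one
  similarity increment (1/12).

## Known limitations

- Only coefficient signs are interpretable; magnitudes carry unknown
  per-component scales (a direct consequence of estimating activities
  from weighted gene sums).
- The one-experiment pipeline is vulnerable to systematic leakage when a
  gene reports several components; the consensus stage exists precisely
  to suppress such edges, and single-experiment edge lists should be read
  with that caveat.
- Gonadotrope-scale panels (6 components, ~20 genes) are well within the
  method's regime, but data-degenerate panels — many genes with identical
  response profiles — reduce the effective gene count toward the
  `m ≥ n + 1` floor.
- The entropy specificity score is scale-free across perturbation counts
  but saturates for genes specific to two or more components; such genes
  contribute weight to several rows by design.
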