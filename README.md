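# placa

Reverse engineering of **functional signaling networks** from early-gene
expression measured under systematic single-component perturbations.

## The problem

Many signaling components — scaffold proteins, transcription factors,
kinases with poorly characterised activity states — cannot be assayed
directly in high throughput.  Their downstream *early genes* can: genes
transcribed without de-novo protein synthesis accumulate transcript
approximately linearly in upstream signaling activity during the first
hour after stimulation, so an early-gene panel read at an early time point
is a set of quantitative sensors for the signaling layer above it.

`placa` turns a panel of `m` early genes measured under `n + 1` conditions
(one unperturbed baseline, one condition per inhibited/activated signaling
component) into a signed, directed network of functional interactions
among the `n` unmeasured components, along with the genes that support
each inferred edge.

## The method

With baseline mean activities `A_k` and post-perturbation means `G_jk`,
each gene is scored per perturbation:

- **activity score** `D_jk = s_j (A_k − G_jk) / ‖A_k − G_·k‖₂` — the signed
  relative response, normalised across perturbations;
- **P-score** `P_jk = erf(|Z_jk|/√2)` with
  `Z_jk = (log A_k − log G_jk)/√(dA_k² + dG_jk²)` — the probability that the
  change is real rather than replicate noise (expression is near
  log-normal, so the test runs in log space);
- **information score** `I_k = ln n − H(z̃_k)`, `z̃_jk = Z_jk²/Σ_j Z_jk²` —
  an entropy-based specificity in `[0, ln n]`, maximal for a gene that
  responds to exactly one perturbation.

The weight matrix `W_ik = D_ik · P_ik · I_k / A_k` estimates component
activities `S = W Gᵀ`, `S0 = W A`; the global response matrix
`R = S − S0·1ᵀ` is inverted by modular response analysis,

    r = −[dg(R⁻¹)]⁻¹ R⁻¹,

into local interaction coefficients (diagonal −1).  Because the activity
estimates carry unknown per-component scale factors, only coefficient
*signs* are interpreted: each gene is left out in turn (jackknife), the
full pipeline reruns, and an edge is kept only when its coefficient keeps
one sign at 95% one-sided confidence.  With several independent
experiments, a K-of-E consensus (default 4-of-5) removes residual false
edges.  Inferred edges are *functional*: the two components demonstrably
regulate a shared gene set, whether or not they touch biochemically.

A synthetic benchmark — four components wired from standard motifs
(a mutually activating S1↔S2 pair, S2 ⊣ S3, a bi-fan inhibition of S4 by
S1 and S2) read out by ten genes with mixed shared/specific, activating/
repressing regulation — generates ground-truth datasets with log-normal or
truncated-Gaussian replicate noise for validation.

## Worked example

Simulate one noisy benchmark experiment, infer its network, and inspect
the genes behind one edge:

```
$ placa simulate --noise 0.1 --seed 5 --out-prefix demo
wrote demo.expression.tsv / demo.panel.tsv

$ placa infer demo.expression.tsv demo.panel.tsv --out-prefix demo_run
6 significant edges -> demo_run.edges.tsv

$ placa contributions demo.expression.tsv demo.panel.tsv \
      --source S2 --target S3 | head -4
gene    contribution
G7      -0.4119725959693984
G1      -0.09877668229703825
G8      -0.06890153708793971
```

The edge list marks all five true edges significant — S1→S2 and S2→S1
positive, S2⊣S3, S1⊣S4, S2⊣S4 — plus one spurious edge (S4⊣S3), a typical
single-experiment false positive; rerunning with other seeds and combining
via `placa consensus exp1.tsv ... exp5.tsv --panel panel.tsv -k 4` removes
it, which is exactly why the consensus stage exists.  Each row carries the
jackknife mean coefficient, its SD, the sign-consistency z-ratio and the
top supporting genes.  The contributions table decomposes the estimated
response of S3 to the S2 perturbation gene by gene (the terms sum exactly
to the response-matrix entry); here the S3 reporters G7 and G8 and the
shared S2 readout G1 carry the edge.

`placa benchmark` sweeps reconstruction quality against noise.

The same pipeline applies unchanged to real perturbation panels (e.g. six
kinase inhibitors in GnRH-stimulated gonadotrope cells with an 18–24
early-gene qPCR panel): export the replicate table to TSV/CSV, list the
conditions in a panel table, and run `placa infer` / `placa consensus`.

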