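# Methods

## Model

Each gene's expression is modeled as a linear structural equation over the
other genes and a panel of SNP genotypes:

    y_i = b_i Y + f_i X + mu_i + eps_i,        eps_i ~ N(0, sigma^2 I)

with `Y` (genes x samples) and `X` (SNPs x samples, genotypes coded
{1, 2, 3} = minor-allele count + 1). The row `b_i` of the square matrix `B`
carries directed gene-gene regulation (`b_ii = 0`: no self-loops); the row
`f_i` of `F` carries SNP-to-gene (eQTL) effects. SNPs are exogenous — they
may regulate genes but are never targets. Row-centering `Y` and `X`
eliminates the intercepts `mu_i`, so all fitting happens on centered data.
The package assumes each gene has at most one eQTL in the final output and
that the gene network is sparse; it does not assume the eQTL map is known.

Identification of edge *directions* rests on the genotypic perturbations:
a SNP acts as an instrument anchoring its gene, which is why recovering the
per-gene eQTL correctly is the single most important determinant of network
accuracy (a gene with a wrongly assigned SNP is typically fitted "in
reverse", through a child gene, losing its true parents).

## Inference pipeline

Two modes: **IAL1** is given the gene-to-SNP map and runs only the final
stage; **IAL2** infers the map first. All per-gene subproblems are solved
independently; every regression excludes the target gene's own expression
row, which enforces `b_ii = 0` structurally.

**Step 1-1 — ridge.** Per gene, the doubly ell2-penalized least squares has
a closed-form joint minimizer obtained by eliminating the gene block (see
`screening.ridge_fit_gene`). The two penalty levels are chosen per gene by
5-fold cross-validated held-out squared error over a 20-point log grid on
[1e-3, 1e3] (CV-minimizing; ridge does not select support, so the
parsimony correction below is not applied here).

**Step 1-2 — elastic-net SNP screen.** The mixed penalty (ell2 on genes,
ell1 on SNPs) is reduced, by profiling the ridge-penalized gene block out
in closed form, to a lasso in the SNP coefficients alone, solved by cyclic
soft-threshold coordinate descent on the profiled Gram system. The gene
penalty reuses Step 1-1's level; the SNP penalty is chosen per gene by
5-fold CV with the **one-standard-error rule** (strongest penalty within
one SE of the minimal held-out error). A CV-minimizing ell1 level
systematically overselects, which pollutes the candidate sets this step
exists to produce; with the 1-SE rule candidate sets average ~3 SNPs per
gene and contain the true simulated eQTL essentially always. Surviving
SNPs are truncated to the `n_k = 5` largest |coefficients|.

**Step 2 — lasso-path eQTL finalization.** The other genes' expression
rows and the candidate SNP rows are stacked into one design; an ell1 path
of 50 log-spaced penalties is traced from the empty model (the path top is
the exact threshold at which all coefficients are zero) down to 1% of it,
warm-starting each solve. The gene's eQTL is the candidate SNP whose
coefficient becomes nonzero *earliest* along the path; gene coefficients
are fitted but never compete for the slot. Ties at one path point break to
the larger |coefficient|. Rows of the stacked design are standardized to
unit variance first — the default convention for lasso solvers — because
expression rows accumulate the variance of their regulators and otherwise
enter the path far too eagerly, dragging their own eQTLs in ahead of the
target's true SNP. If no candidate enters before the path floor (or only
one candidate exists), the strongest screened SNP is assigned and the gene
is flagged as a fallback in the diagnostics.

**Step 3 — iterative adaptive lasso.** `B` and `F` are re-initialized by a
*restricted* ridge: per gene, ell2 on the gene block (level by 5-fold CV)
and the single retained SNP fitted without penalty. The adaptive lasso
then minimizes

    ||y_i - b_i Y - f_i X||^2 + lambda1 * sum_j w^b_ij |b_ij|
                              + lambda2 * sum_j w^f_ij |f_ij|

by joint cyclic coordinate descent, with weights `w = |previous
estimate|^-exponent`; a zero previous estimate gives an infinite weight,
implemented as a frozen-coordinate mask (a pruned edge can never return).
The per-gene `(lambda1, lambda2)` pair is estimated once, before the
pruning loop, by 5-fold CV of the adaptive lasso itself with weights from
the ridge refit, again with the one-SE rule (most parsimonious qualifying
pair, largest `lambda1` first): this CV sets the sparsity of the final
network, and CV-minimizing it leaves occasional genes with the grid-bottom
penalty and a halo of tiny false edges that the exponent sweep then cannot
remove.

The outer loop raises the gene-weight exponent `alpha` from 0 in steps of
0.5 up to 3 (the SNP exponent `beta` stays at 0.5); at each `alpha` an
inner loop refits with weights from the previous pass until the selected
edge count N_e(B) stops changing. The first pass of the first inner loop
uses the dense ridge-refit weights, so its collapse to a sparse network
registers as a change and the sweep proceeds. The loop terminates when an
entire inner loop leaves N_e(B) unchanged; hitting the `alpha` cap is
recorded as a distinct termination reason. Because supports only shrink,
N_e(B) is non-increasing across passes, and termination is guaranteed.

## Numerical choices

* Coordinate updates are the exact single-coordinate minimizers
  `soft(c_j, t_j/2) / G_jj` of the Gram-form objective (the half-threshold
  follows from writing the squared loss without a 1/2 factor); sweeps are
  cyclic in fixed ascending order, gene block before SNP block, and any
  order converges since the objectives are convex. Convergence: max
  coordinate change < 1e-6, cap 10^4 sweeps (a non-converged solve is
  returned flagged, not raised).
* A coefficient is a selected edge when its magnitude exceeds 1e-8.
* All CV folds and any randomized order derive from a single integer seed;
  the screening stages and Step 3 use independent derived streams so that
  IAL1 and IAL2 draw identical Step-3 folds — with the same seed, the two
  modes produce bit-identical results whenever Steps 1-2 recover exactly
  the map supplied to IAL1, and any run repeats bit-for-bit.
* The coordinate-descent kernel is JIT-compiled (numba); tests cross-check
  it against an independent L-BFGS-B solver on the split-variable
  reformulation of each objective and against scikit-learn's lasso.

## Synthetic benchmark generator

The generator emulates genetic-perturbation experiments on a directed
acyclic regulatory network:

* topology: a uniform random permutation fixes a topological order; each
  admissible (later -> earlier) slot becomes an edge independently with
  probability set so the expected edge count is `edges_per_gene * n_genes`;
* coefficients (gene-gene and eQTL alike) are uniform on ±[0.5, 1];
* one eQTL per gene: `F` is diagonal with a full diagonal, so the SNP
  panel has the gene panel's size;
* genotypes are i.i.d. {1, 2, 3} with probabilities (0.25, 0.5, 0.25)
  (Hardy-Weinberg at allele frequency 1/2);
* expression solves `Y = (I - B)^-1 (F X + E)` with `E_ij ~ N(0, 0.01)`;
  the noise realization is stored so tests can verify the SEM residual
  `(I - B) Y - F X` recovers it exactly.

What this does *not* emulate — and what passing benchmarks therefore do
not certify for real data: linkage disequilibrium or any SNP-SNP
correlation, cyclic regulation or feedback, genes with zero or several
eQTLs, non-Gaussian or gene-specific noise scales, measurement error in
genotypes, and hidden confounders. The very high signal-to-noise ratio
(effect sizes ≥ 0.5 against noise variance 0.01) is the regime of the
benchmark protocol, not of typical expression data.

## Evaluation

Supports are compared over all directed off-diagonal gene-gene slots:
TPR = TP/(TP+FN), FDR = FP/(TP+FP), with FDR defined as 0 when nothing is
predicted; sign and magnitude are ignored beyond the zero tolerance. eQTL
assignments are scored per gene (correct SNP = TP; wrong SNP = FP + FN;
missing = FN). The benchmark harness runs simulate-infer-score grids with
replicate seeds `base_seed + replicate`, records failures per replicate
rather than aborting, and reports per-cell means in the layout of the
reference table. Default study conditions are 10 replicates per condition;
the test suite's smoke checks use 3 to keep the default run short, at
correspondingly widened tolerances.

## Known limitations

* The step-2 first-entry rule fails for roughly 1% of genes under the
  benchmark's denser settings (E_g = 2): when a target has several parents
  and at least one child, the child's expression row enters the path first
  and its eQTL can precede the target's own. The error is structural (it
  does not vanish at N = 500 and is insensitive to path resolution), and
  one wrong eQTL typically costs the affected gene its parent edges, which
  is visible as the IAL2-vs-IAL1 accuracy gap growing with network size.
* Per-gene penalties are estimated once, not re-tuned per pruning
  iteration (cost); the `alpha` schedule (start 0, step 0.5, cap 3) is a
  fixed design choice.
* Genes whose screen yields no candidate SNP proceed without an eQTL;
  nothing attempts multiple eQTLs per gene.
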