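# clonedd

Clonal division-destiny analysis for multiplex division-tracking lymphocyte
data.

When a T or B cell is activated, it divides a number of times and then
returns to quiescence; the generation at which it stops is its **division
destiny (DD)**. Multiplex division-tracking assays recover the progeny of
many individual founder cells (clonal families) and record, for each
detected cell, its generation and whether it has returned to quiescence.
`clonedd` answers two questions about such data:

1. **How concordant is DD within a family?**  The within-family
   correlation ρ of DD decisions is estimated by maximum likelihood under
   a beta-binomial branching model, accounting for incomplete cell
   recovery, and the model's predicted distribution of the clonal *range*
   (max − min generation of detected progeny) is compared with the data.
2. **Do costimulatory signals add independently at clone level?**  Clone
   expansion statistics (maxDD and the cohort-normalized mean DD, mDD) are
   *additive* under concatenation of family trees, so independent signal
   integration implies the distribution for a signal combination is the
   convolution of the single-signal distributions.  A dedicated χ² test
   compares two convolved categorical distributions.

## Model

Within a family, of the `c_k` cells alive in generation `k`, the number
progressing past `k` is beta-binomial(`c_k`, `p_k`, ρ): at ρ = 0 each cell
decides independently with probability `p_k`; at ρ = 1 the family shares a
single decision.  The progression profile is estimated from pooled,
cohort-corrected counts (`n_j` DD cells in generation `j` weighted by
`2^−j`):

    p_k = Σ_{j>k} n_j 2^−j / Σ_{j≥k} n_j 2^−j,

which is invariant to ρ.  Every full tree `T = (t_0, …, t_D)` (DD cells
per generation) has likelihood `Π_k B(c_k, c_k − t_k | p_k, ρ)`; observed
clones are binomial thinnings of full trees with per-condition recovery
probability `r`, and the sampled-range distribution follows by summing
over trees and subtrees.

For signal addition, a family's DD vector `x` (`x_i` quiescent cells in
generation `i`) is the coefficient vector of the leaf generating function
of its tree.  Concatenating a second tree into the first — at *any*
partition of cells — multiplies generating functions, i.e. convolves the
DD vectors, so `maxDD(x*y) = maxDD(x) + maxDD(y)` and likewise for mDD.
The equality of convolved distributions is tested with a quadratic-form
statistic `S = V' Σ⁺ V`, where `V` is the difference of convolved
empirical distributions and Σ its delta-method covariance;
`S ~ χ²_rank(Σ)` under the null.

## Worked example

```sh
clonedd simulate --seed 1 --out clones.tsv
clonedd summarize clones.tsv --out summary.tsv
clonedd fit-concordance clones.tsv --condition N4 --out fit_n4.json
clonedd test-addition clones.tsv --stat maxdd \
    --pair1 "N4,N4+aCD28+IL-2" --pair2 "N4+aCD28,N4+IL-2" \
    --seed 0 --out addition.json
```

`simulate` writes a four-condition clone table (N4, N4+aCD28, N4+IL-2,
N4+aCD28+IL-2; founder inputs 96/224/96/224, harvests at 54/62/72 h).
`fit-concordance` reports, for the N4 condition of the seed-1 table:

```
clonedd: condition N4: rho_hat=0.869 (57 clones)
```

and writes the fitted progression profile, the profile-likelihood curve
over ρ, and the predicted range distribution with 95% binomial envelopes.
The estimate is close to the generator's true within-family correlation
of 0.9: family fate is strongly lineage-imprinted in these data, far from
the independent-decision model ρ = 0.  `test-addition` prints

```
clonedd: maxdd test: S=2.237 dof=2 p=0.327
```

a non-significant result, as expected when the combined-stimulus families
are statistically indistinguishable from convolutions of the
single-stimulus families.  The same library functions are available in
Python (`clonedd.fit_rho`, `clonedd.convolution_equality_test`, …).

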