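# insulreg

Sparse insulation regression for Hi-C contact maps: identification of
topologically associating domain (TAD) borders **and facilitators**,
differential border detection between two conditions, and prediction of
contact maps after chromosomal deletions or inversions.

## The problem and the model

Hi-C assays produce, per chromosome, a symmetric matrix of contact counts
between genomic bins. TAD borders are bins that *insulate*: their presence
between two loci lowers the loci's contact frequency. Classical insulation
scores aggregate contacts crossing each bin and therefore smear borders
over wide valleys. `insulreg` instead estimates a **sparse, per-bin
regression coefficient** whose sign and magnitude are directly
interpretable as a multiplicative effect on contact frequency.

For a pair of bins (i, j) with contact count *y* and log genomic distance
*d*, the polymer (distance-decay) background is removed first with a
negative-binomial spline regression,

    log E[y | d] = β₀ + f(d),

and log-scale residuals *z* are regressed on binary indicator variables
x₁…x_p, where x_k = 1 iff bin k lies strictly between i and j:

    E[z | X] = β₀ + X β_X,   minimizing  (1/N) Σ (z − β₀ − Xβ_X)² + λ‖β_X‖₀.

The L0 (best-subset) penalty yields exactly-sparse profiles: β̂_k < 0 marks
a TAD border (insulator), β̂_k > 0 a TAD *facilitator*, β̂_k = 0 no effect.
λ is selected by 10-fold cross-validation. Three pipelines share this core:

- **SIM** (sparse insulation model): border/facilitator calling with
  strength tiers (strong β̂ < −2, moderate −2 < β̂ < −1.2, weak otherwise).
- **DIM** (differential insulation model): stacks residuals from two
  experiments and tests bin×experiment interaction terms by OLS,
  E[z | S, e] = β₀ + Sβ_S + β_e e + Σ_j β_{s_j e} s_j e, with
  Benjamini–Hochberg adjustment; β̂_{s_j e} < 0 means a border gained in
  experiment 2.
- **PIM** (prediction insulation model): a Poisson GLM
  log E[y | d, X] = β₀ + β_d d + Xβ_X trained on wild-type data; after a
  deletion the distance variable shrinks by the deleted length and the
  deleted bins' indicators vanish, after an inversion the bin order flips,
  and the trained coefficients predict the rearranged map.

A synthetic Hi-C generator (power-law decay, log-additive planted
border/facilitator effects, Poisson or negative-binomial noise) provides
ground truth for every statistical claim, plus matched wild-type/mutant
pairs for prediction scoring with Pearson-on-log-counts, Spearman, and the
stratum-adjusted correlation (SCC).

## Worked example

Generate the default synthetic chromosome (200 bins at 25 kb, 8 planted
borders with β ∈ [−2.5, −1.0], 2 facilitators, ≈100 counts at gap 1) and
call borders:

```bash
$ insulreg simulate --seed 3 --out fixture
wrote fixture/matrix.triplet
$ insulreg sim --matrix fixture/matrix.triplet --p 200 --out sim_out
selected 8 border bin(s), 2 facilitator(s)
```

`sim_out/sim_bins.tsv` then contains one row per bin; the nonzero rows:

```
 chrom   start     end  bin      beta       class        tier
chrSyn  500000  525000   21 -2.076823      border      strong
chrSyn 1125000 1150000   46 -2.005949      border      strong
chrSyn 1375000 1400000   56  1.483781 facilitator facilitator
chrSyn 1750000 1775000   71 -1.664680      border    moderate
chrSyn 2375000 2400000   96 -1.338495      border    moderate
chrSyn 3000000 3025000  121 -1.272270      border    moderate
chrSyn 3250000 3275000  131  1.016683 facilitator facilitator
chrSyn 3625000 3650000  146 -1.114173      border        weak
chrSyn 4250000 4275000  171 -1.015178      border        weak
chrSyn 4625000 4650000  186 -0.891824      border        weak
```

Every planted effect is recovered within one bin of its true position
(truth in `fixture/truth.json`: borders at bins 21, 46, 71, 96, 121, 146,
171, 186 in 1-based coordinates; facilitators at 56 and 131), with the
correct sign, tier and no false positives. `beta` is the estimated
log-scale effect: bin 21's β̂ = −2.08 means contacts spanning it are
attenuated ≈ e^(−2.08) ≈ 8-fold.

Other subcommands: `insulreg score` (classical insulation score),
`insulreg dim` (two-condition differential borders), `insulreg pim`
(train/predict rearranged maps, `--rearrangement` TSV of
`kind chrom start end`), `insulreg enrich` (feature fold-change at borders
stratified by strength). The same functionality is available as a library
(`import insulreg`).

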