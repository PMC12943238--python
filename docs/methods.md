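# Methods note

This note records the statistical model behind each stage of `equisea`,
the default parameters and why they were chosen, what the synthetic-data
generator does and does not capture, and the numerical conventions that
make runs reproducible.

## Cohort phenotyping

A BALF cytology profile (neutrophil, eosinophil, mast-cell percentages
plus two clinical flags) is classified with inclusive thresholds:

- **HEALTHY** iff neutrophils ≤ 6 ∧ mast cells ≤ 2 ∧ eosinophils ≤ 1 ∧ no
  signs of illness;
- **SEA** iff neutrophils ≥ 20 ∧ respiratory signs present;
- **EXCLUDED** otherwise.

Thresholds live in `PhenotypeConfig` and are validated so the healthy
ceiling stays below the SEA floor. Applied to the bundled 12-horse
enrollment table this yields 8 healthy and 4 SEA animals; those group
sizes (8 vs 4) are the design the rest of the package is tuned for.

## Alpha diversity

Per sample, from relative abundances `p_i` (all-zero samples are
rejected): richness (count of non-zero taxa), Shannon entropy `H` in
nats, `hill1 = exp(H)`, and a phylogenetic Hill number. With branch set
`b`, branch lengths `L_b`, and `a_b` the summed relative abundance of
tips below branch `b`:

```
T = Σ_b L_b a_b          (mean pairwise-path "tree depth")
phylo_hill1    = exp( − Σ_b (L_b a_b / T) · ln a_b )
phylo_hill1_pd = T · phylo_hill1
```

`phylo_hill1` is the mean-diversity (per-unit-branch-length) form; on a
star tree it reduces exactly to `hill1`, which the suite verifies. The
`_pd` variant restores the branch-length scale for users who want an
effective-PD reading. Group contrasts use two-sided Welch *t*-tests; the
degenerate equal-constant case is reported as (t = 0, p = 1).

## Beta diversity

**Unweighted UniFrac** is computed from presence sets via a precomputed
branch × tip boolean mask matrix: `d = Σ L_b [branch unique to one
sample] / Σ L_b [branch in either]`. It is validated against a
brute-force branch-enumeration oracle and scikit-bio on random trees.

**PCoA** uses Gower centering `B = −½ J D² J`, a symmetric
eigendecomposition, retention of eigenvalues above `1e-10 ×` the largest,
and a deterministic sign convention (largest-magnitude loading of each
axis made positive). Euclidean configurations are reproduced to 1e-8.

**PERMANOVA** follows Anderson's partition: `SS_total = (1/N) Σ_{i<j}
d_ij²`, within-group sums analogously per group, pseudo-F =
`(SS_among/(a−1)) / (SS_within/(N−a))`. The Monte-Carlo p-value is
`(1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` with a seeded
`np.random.default_rng`; `exhaustive=True` enumerates the distinct
relabelings instead (p = hits / #distinct, identity included), with a
1e-12 tie tolerance. Note the permutation floor at small N: for 3 vs 3
there are only 20 distinct splits, so no p below 0.1 is attainable.

## Differential abundance

1. Collapse counts to the requested rank (lineage-prefix pooling;
   unmapped features pool into an `unclassified` bin, totals conserved).
2. Prevalence filter: keep taxa present in ≥ 20% of samples (inclusive
   boundary). At n = 12 that means ≥ 3 samples — below that a *t*-test is
   meaningless.
3. `y_ij = ln(count_ij + 1)`.
4. Per-sample offsets `o_j = median_i (y_ij − mean_j' y_ij')`, i.e. the
   median across taxa of the sample's deviation from the taxon means;
   `y_ij − o_j` corrects for sample-specific sampling fractions under the
   assumption that most taxa are not differential. On simulated tables
   with known fractions the offsets track the true log fractions with
   mean Spearman correlation ≈ 0.91.
5. Vectorized two-sided Welch *t* per taxon; candidates are taxa with
   unadjusted p < α (default 0.05), reported with direction (group with
   the higher corrected mean) and sorted by p. P-values are deliberately
   left unadjusted — this is a screen feeding the resampling stage, not a
   discovery claim.

**Calibration, measured on the generator:** a planted log2FC = 3 effect
on a common taxon is recovered with the correct direction in ≈ 98% of
200 simulated 8-vs-4 cohorts. Under the global null the per-taxon flag
rate is ≈ 0.054 — a small (< 0.005) excess over the nominal 0.05 that is
intrinsic to *t*-screens on zero-inflated log counts at n = 12, not a
bug; treat screen p-values accordingly.

### Combination resampling

For each candidate, all 3-subject subsets of each group are enumerated —
C(8,3) = 56 and C(4,3) = 4 — and the mean relative abundance of each
subset computed. Two contrasts of the 56 vs 4 subset means are reported:

- `p_t`: a naive Welch *t*-test on the subset means. Because subsets
  overlap, these means are strongly dependent and the test is
  **anticonservative** (measured ≈ 45% null rejection). It is retained
  only as the descriptive statistic of the original design.
- `p_perm`: a subject-level permutation test — group labels are permuted
  over the 12 subjects, subset means recomputed, and |Welch t| compared —
  which respects the dependence and is approximately valid (measured ≈ 3%
  null rejection at α = 0.05). **Use `p_perm` for inference.**

## Synthetic data generator

Per kingdom (defaults: bacteria 500 taxa, archaea 30, fungi 120):

- Base composition: sorted log-normal(0, sd = 1.5) relative abundances —
  a steep, realistic rank-abundance curve.
- Planted effects multiply chosen taxa by `2^log2FC` in one group, then
  the composition is renormalized (so ground-truth ratios are slightly
  below the nominal fold change — the package reports both).
- Structural zeros: taxon *i* (rarity rank `r_i`) is zeroed in a sample
  with probability `clip(2 · sparsity · r_i/(n−1), 0, 0.95)` — rare taxa
  drop out often, dominant taxa essentially never, matching the
  occupancy-abundance relationship of real surveys (a uniform-dropout
  variant was rejected: knocking common taxa to zero 20% of the time is
  both unrealistic and destroys power).
- Sequencing depth: `10^N(4.5, 0.2)` reads, multiplied by a sample
  sampling-fraction bias `exp(N(0, 0.5))` that affects **counts only**,
  never the true composition — exactly the nuisance the median-offset
  correction targets.
- Counts: Dirichlet-multinomial with precision θ = 100 (θ = ∞ gives a
  plain multinomial).
- Trees: Yule process (uniform random tip splitting), exponential(0.1)
  branch lengths; taxonomies are nested random lineages with ~10% missing
  genus/species labels.

**Limits.** The generator has no ecological interactions or taxon
correlations, no phylogenetic signal in abundances (tree and composition
are independent), no batch structure beyond the scalar fraction bias, and
taxonomies are synthetic strings. Power and calibration numbers above are
statements about this model, not about real fecal microbiomes; on real
data, library-prep artifacts, compositional correlation and phylogenetic
conservation of habitat preference can all widen error rates.

## Numerical and reproducibility conventions

- All randomness flows through `np.random.default_rng` with explicit
  seeds; per-kingdom streams derive as `(seed·10007 + 101·offset) mod
  2^31`, keeping every derived seed below 2^31.
- Reports are JSON with sorted keys; `report.json` embeds a SHA-256 of
  the canonical config (output location excluded) so the same analysis
  written anywhere is byte-identical — the suite asserts this.
- Eigenvalue cutoff 1e-10 (relative), PERMANOVA tie tolerance 1e-12,
  pseudocount 1, α = 0.05 throughout unless configured otherwise.
- Problem sizes: the full default study (650 taxa across three kingdoms,
  12 samples, 999 permutations) runs end-to-end in a few seconds; the
  whole validation suite, including 2,000-replicate PERMANOVA type-I and
  500 differential-abundance simulations, runs in well under a minute.
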