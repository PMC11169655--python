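# Methods

## Attribution model

The quantity at the core of the package is the attribution fraction

    x[i, j] = nTPM[i, j] / Σ_j nTPM[i, j]

for gene *i* and cell type *j*, computed on a reference atlas of sorted
leukocyte subtypes whose normalization (nTPM) is designed to make
expression comparable across cell types.  Attribution is a property of
the reference atlas alone: it involves no bulk mixture, no estimate of
cell-type proportions, and no deconvolution.  It is row-stochastic and
invariant to any positive rescaling of a gene's nTPM row, which is why
the synthetic generator models specificity at the composition level
only.

The denominator is the sum over exactly the atlas's subtype columns (18
in the reference use case); no aggregate column enters it.  Genes whose
nTPM row sums to zero have no defined attribution; they are excluded
from gene sets and background alike and their count is logged — this is
a reported outcome, not an error.  Medians use the midpoint convention
for even counts.  Attribution is a fraction internally and a percentage
with two decimals in outputs.

## Enrichment testing

For a gene set S and cell type j, the set's attribution values
{x[i, j] : i ∈ S} are compared with the genome-wide background — all
retained genes, S included, matching the "all protein coding genes"
reference population.  Two variants ship, selectable per run:

- **signed_rank_vs_background_median** (default): one-sample Wilcoxon
  signed-rank of (set values − background median), two-sided.  Zero
  differences are dropped (classic Wilcoxon rather than Pratt), ties
  take mid-ranks.  The exact null distribution is used when n ≤ 25 and
  the absolute differences are tie-free; otherwise the normal
  approximation with continuity correction (and tie correction) is
  used.  Two caveats are inherent to this test and documented here
  deliberately.  First, it tests *symmetry about* the background
  median, so on a skewed background (attribution fractions are
  Beta-like and strongly right-skewed) it is anti-conservative on
  random gene sets — we measure ≈0.10 rejection at α = 0.05; a
  dedicated test pins this behaviour.  Second, its p-values are floored
  at 2/2ⁿ (≈1.9e-6 at n = 20), so very small published p-values for
  20-gene sets cannot arise from it.
- **rank_sum_vs_background**: two-sample Wilcoxon rank-sum
  (Mann–Whitney) of set versus background, normal approximation with
  tie and continuity correction.  This variant is calibrated on random
  gene sets drawn from the background (empirically 0.047 at α = 0.05)
  and supports p-values at the 1e-11 scale for strongly shifted 20-gene
  sets.  Consequently the calibration and planted-recovery checks in
  the test suite and acceptance script exercise this variant.

P-values across the 18 cell types of one table are adjusted by the
Benjamini–Hochberg step-up procedure (statsmodels implementation,
cross-checked against hand-computed step-up values); significance stars
(\*, \*\*, \*\*\*) are assigned from adjusted p-values at 0.05 / 0.01 /
0.001.  Both raw and adjusted columns are emitted.  The per-row fold
change is set median / background median.

## Gene sets, curves and direction tests

Gene sets are cut from the ranked list by rank (`top:k`), by the
half-maximum score rule (`frac:0.5`: every gene scoring at least half
the top gene — the rule that yields the 20-gene headline set), by
direction then rank (`top:k:increase`), or not at all (`all`).
Selection happens before atlas mapping; the enrichment table uses the
mapped subset, the direction test uses the full selected set.

The cumulative median curve reports, for each k, the median combined
attribution (default subset: the two naïve T-cell columns) of the top-k
*mapped* genes — ranks whose genes failed to map are skipped, so k
counts mapped genes.  k_min defaults to 5 because medians of fewer than
five values are dominated by single genes.  The curve's endpoint equals
the full-set median computed on the enrichment side; a cross-module
test asserts this.

Direction-of-change counts are tested with the exact two-tailed
binomial test using the minimum-likelihood convention (sum the
probabilities of all outcomes no more likely than the observed count);
at null 0.5 — the only null used in practice — this coincides with
doubling the smaller tail, capped at 1.  The convention is fixed so the
asymmetric-null behaviour is deterministic.  Reports always print the
integer count alongside the proportion, because a proportion alone does
not identify the count at these sample sizes.

## Identifier mapping

Ranked-list entries are matched to atlas rows by stable gene id first
(exact), then by symbol (case-insensitive exact).  A symbol carried by
several atlas genes is ambiguous; the entry is reported unmatched with
reason `ambiguous_symbol` rather than guessed.  Several list entries
may legitimately map to one atlas gene.  Mapping totals always satisfy
n_mapped + n_unmapped = n_input, and the report is written as TSV with
a one-line summary in the run log.

Long-format atlas files may omit zero-expression (gene, cell type)
pairs; these are zero-filled with a counted warning.  Duplicated pairs
are an error — never silently aggregated.  Column names follow the
public download's header (`Gene`, `Gene name`, `Immune cell`, `nTPM`)
and are renameable because that header has varied across releases.

## Synthetic data generator

The generator emulates the two real inputs so the pipeline is fully
exercisable offline:

- **Atlas**: each background gene's cell-type composition is drawn from
  a symmetric Dirichlet(1.0) over the 18 subtype labels; each of the
  `n_planted` planted genes places `specificity_weight` (default 0.85)
  of its composition on the two naïve T columns, split evenly, with the
  remainder Dirichlet-spread over the other 16 subtypes.  Per-gene
  total expression is log-normal (meanlog 3, sdlog 1.5, in nTPM units);
  nTPM is total × composition.  The 18 labels are the subtype names of
  the reference atlas, so synthetic outputs are drop-in for the
  real-data path.
- **Ranked list**: each of the top 20 ranks is filled from the planted
  pool with probability 0.9 (without replacement), otherwise from the
  background; lower ranks draw background genes.  Direction is
  "decrease" with probability 0.85 inside the top 20 (expectation 17 of
  20) and 0.58 below it (so the full list sits near the ~60% decrease
  proportion of real meta-analysis lists).  Scores decrease strictly
  with rank and are laid out so the rank-20 score is exactly half the
  rank-1 score, making the `frac:0.5` rule select exactly the top 20.

Defaults the generator fixes where the emulated inputs leave them open:
`n_genes = 2000` and `n_planted = 40` (large enough for a stable
background median and a planted pool comfortably exceeding the top-20
window, small enough that multi-seed checks stay cheap), and
`list_length = 200` (a ranked list an order of magnitude longer than
the headline set, so threshold and direction-filtered selections are
exercised away from boundary effects).

One seed drives atlas and list through independent sub-streams
(`numpy` SeedSequence spawning), so regenerating the list never
perturbs the atlas, and identical (config, seed) pairs yield
byte-identical TSV output.

What the generator does **not** emulate: donor-level bulk mixtures, an
age variable, measurement noise or replicate structure, correlated gene
modules, and the long-tailed symbol/id mismatch patterns of real
annotation.  Passing the planted-recovery checks therefore demonstrates
that the pipeline detects composition-level specificity signals of the
planted kind; it does not validate the biological claim on real data,
which requires the public atlas and ranked-list downloads (a skipped
integration test covers those when the files are supplied).

## Numerical and design choices

- Exact signed-rank path verified against full 2ⁿ sign-assignment
  enumeration for n ≤ 10; the exact binomial verified against direct
  tail summation and a 10⁶-draw Monte-Carlo estimate.
- Atlas values are written with full `repr` precision so read∘write
  round-trips are bit-exact; canonical (sorted) gene and cell-type
  ordering makes parsing independent of file row order.
- Enrichment tables are sorted by descending set median — the reading
  order of the published-table shape this output mirrors.
- Pipeline outputs are deterministic given inputs and config; all
  stochastic checks are confined to the test suite and acceptance
  script, which take explicit seeds.
- Problem sizes in the test suite and acceptance script (2000-gene
  atlases, 50-seed recovery sweeps, 1000-draw calibration) are chosen
  as the smallest sizes at which the Monte-Carlo bands quoted in the
  checks are meaningful.

## Known limitations

- Attribution measures where expression comes from in the *reference*
  atlas, not how much a cell type contributes to a given bulk sample;
  blood composition varies across donors and with age.
- The signed-rank variant's symmetry assumption rarely holds for
  attribution fractions; prefer the rank-sum variant when calibration
  on random sets matters (its p-values, not the signed-rank's, are
  comparable to published two-sample-scale values).
- Symbol-based mapping is exact-match only; no alias or history
  resolution is attempted, so real-data mapping rates depend on the
  annotation vintage of the inputs.
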