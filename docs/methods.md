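# Methods

## Problem setting

Two purification strategies are applied to the same cell population
(here CD11b⁺ brain microglia): bead-based enrichment (MACS-like), which
retains protein-rich acellular debris, and flow-cytometric isolation
(FACS-like), which gates debris out.  Each strategy contributes five
replicate samples to one 10-plex TMT experiment; the input to the
pipeline is the protein-level reporter-abundance matrix.  The analysis
asks (i) which proteins differ between the strategies, (ii) whether
those differences follow cell-type marker structure (contamination
signature), and (iii) which proteins are highly abundant under *both*
strategies (the consensus core of the purified cell type).

## Inclusion filtering

A protein is retained when quantified (nonzero reporter abundance) in at
least `min_per_group` (default 3) replicates of both groups.  A protein
quantified in *every* replicate of one group and *no* replicate of the
other is biologically interesting (strategy-exclusive) but statistically
fragile, so it is admitted only when its protein-level FDR confidence
grade is `high`; it is flagged `exclusive` in the inclusion report, and
dropped with reason `low_confidence_exclusive` otherwise.  All other
insufficiently covered proteins drop with reason `low_coverage`.  The
filter is monotone in the threshold and preserves input order.

## Imputation and transforms

Zeros encode "not quantified".  After filtering, every zero is replaced
by the smallest nonzero value of the retained matrix — a deliberate
floor-imputation that mimics reporting at the detection limit.  "The
dataset" over which that minimum is taken is by default the *filtered*
matrix, since that is the analyzed dataset; `impute_scope=full` computes
it over the unfiltered matrix instead (the difference is rarely more
than one protein's worth of floor value).  Values are then log2
transformed.  The row-geometric-mean form
`log2(abundance / row geomean)` (each row summing to zero) is provided
for relative-abundance bar plots only; no test statistic is computed on
it.

Imputation can create constant or near-constant rows, which is why the
differential stage must tolerate zero-variance comparisons (below).

## Differential enrichment

Per protein, an unpaired two-sample t-test on log2 abundances,
comparison minus reference.  The default flavor is the pooled-variance
Student test (df = n₁ + n₂ − 2): an "unpaired t-test" without further
qualification conventionally denotes the equal-variance test, and with
five replicates per group variance estimates are too noisy for Welch to
be clearly preferable; `flavor="welch"` is available.  The tests run on
log2 values, the scale on which such tables are normally shipped and on
which multiplicative reporter noise is approximately additive.

Significance is strict `p < alpha` (default 0.05); `alpha_inclusive`
switches to `≤` for replication of analyses that used the inclusive
rule.  BH adjustment is applied across all tested proteins.  The ≥ 2-fold
classes require *both* significance and |log2FC| ≥ `fold_log2`
(default 1.0), matching the usual definition of over-representation
input lists.

Degenerate comparisons — both groups constant after imputation — return
p = 1 when the constants are equal and p = 0 with a `degenerate` flag
when they differ, keeping the pipeline total; consumers can exclude
flagged rows.  The flag rather than an error is the right behavior
because floor-imputation makes all-missing-in-one-group patterns
produce exactly this case.

## Cell-type enrichment

Marker references map uppercased gene symbols to one of
{microglia, neuron, astrocyte, oligodendrocyte, endothelial}; a symbol
claimed by several cell types is demoted to `none` deterministically
(order-independent).  Annotation is a pure lookup; unmatched symbols are
reported as "No cell-type".

For each cell type the significantly increased and decreased proteins
are counted (percentages within the cell type's significant set).
Over-representation of a cell type within the increased (resp.
decreased) list is a one-tailed Fisher exact test — the hypergeometric
upper tail P(X ≥ r) — with the background equal to **all quantified
proteins in the analyzed dataset**, not the genome: the dataset itself
defines the only self-consistent sampling universe for a
protein-detection experiment.  BH correction is applied across the
cell-type × direction family; the "No cell-type" row is reported but
not tested.  `reference_concordance` reports per-cell-type Venn counts
(A-only / B-only / shared) between two marker references.

## Consensus core

Within each group, proteins are ranked by their group-mean log2
abundance; percentiles use the midpoint convention
`100·(rank − 0.5)/N` with average ranks for ties — symmetric (mean 50),
tie-robust, and dependent only on the ordering, so core membership is
invariant to any strictly increasing transformation of abundances.
Membership requires percentile ≥ threshold in both groups; the default
threshold is the 90th percentile, but it is an explicit parameter and
`threshold_grid` reports set size over a grid so a target core size can
be located empirically — the convention behind any particular published
core-set count is not uniquely determined by a percentile cutoff alone.
Members are ordered by the smaller of their two group percentiles,
descending, with accession as the deterministic tie-break;
`top_marker_selection` restricts to members labelled with the purified
cell type.

## GO over-representation

Flat gene sets (GMT) only; no ontology-graph traversal or term pruning.
Each term is intersected with the background first and skipped when
fewer than `min_genes` (default 5) background members remain.  With
background size N, term size R, input size n and overlap r, the score is
the exact Fisher upper-tail p together with the hypergeometric-moment
normal approximation

    z = (r − nR/N) / sqrt( n · (R/N) · (1 − R/N) · (1 − (n−1)/(N−1)) ),

whose numerator and denominator are the exact mean and standard
deviation of the hypergeometric overlap.  A term passes at p < 0.05 and
z > 1.96 (the two-sided normal 5% point, making the two criteria
consistent by construction).  No multiple-testing correction is applied
across terms by default — these lists are used descriptively — but a BH
column is available.  The default input lists are the significant
≥ 2-fold increased and decreased sets, run separately.

## Synthetic data

The simulator emulates the phenomenon end to end with closed-form
truth.  Each protein draws a baseline log2 abundance from
N(10, 2) (arbitrary log2 intensity units).  A configurable fraction of
proteins is assigned as markers of each cell type (defaults: 8%
microglia, 8% neuron, 8% astrocyte, 8% oligodendrocyte, 4% endothelial,
the remaining 64% a shared pool), and a marker is enriched by
`marker_log2_enrichment` (default 3, i.e. 8-fold) in its own cell type's
profile only.

Samples are **linear-intensity mixtures**: sample intensity =
Σ_c w_c·2^(profile_c) with per-group mixing weights summing to 1.
Mixing in intensity space, not log space, is the physical model —
reporter-ion signal adds across co-isolated material, which is exactly
how acellular debris contaminates an enriched preparation.  Defaults:
MACS-like weights {microglia 0.85, neuron 0.07, astrocyte 0.045,
oligodendrocyte 0.03, endothelial 0.005}; FACS-like {microglia 0.97,
neuron 0.01, astrocyte 0.01, oligodendrocyte 0.005, endothelial 0.005}
— two groups × 5 replicates, ~1800 proteins, the study shape.  On top of
the mixture each value receives multiplicative log-normal noise
(`noise_sigma` = 0.3 log2 units, a typical between-replicate reporter
CV) and logistic dropout on log2 abundance (midpoint 4.0, slope 1.0:
p(missing) = 0.5 at log2 intensity 4, negligible at the mean — TMT
missingness is low and abundance-dependent).  Expected log2 fold changes
are recorded in closed form per protein:
`log2(Σ w_FACS 2^profile) − log2(Σ w_MACS 2^profile)`.

### What the mixing model implies for recovery metrics

For a marker of the purified cell type the achievable contrast is
bounded: as the marker's own-type enrichment grows, the expected log2FC
tends to `log2(w_FACS,microglia / w_MACS,microglia)` ≈ log2(0.97/0.85)
≈ 0.19.  With noise σ = 0.3 and 5 + 5 replicates the fold-change
estimator has SD σ√(2/5) ≈ 0.19, so the *sign* of the estimate for an
arbitrary microglial marker is correct only ~80–85% of the time — an
intrinsic property of purity-ratio contrasts, not an implementation
artifact.  Direction recovery is therefore assessed where the method
makes calls: among purified-cell markers reaching significance, the
fraction classified `increased` must be ≥ 95% (empirically 100% at the
defaults), and the cell-type table must concentrate those markers in
the increased column with a significant one-tailed Fisher test.  This
matches how such contamination analyses report their marker structure
(direction splits of *significant* proteins).  Contaminant-type markers
have much larger expected contrasts (e.g. neurons:
log2(1.07/1.49) ≈ −0.48) and are recovered broadly.

### What the simulator does not model

No spectral-level effects (co-isolation interference, isotopic
impurity, ratio compression), no peptide-to-protein roll-up, no
batch/channel effects (inputs are assumed channel-normalized), no
protein–protein abundance correlation, and marker enrichment is uniform
within a cell type.  Passing tests on synthetic data therefore validate
the statistical machinery and the contamination logic, not robustness
to those real-data artifacts.

## Numerical and design choices

- BH adjustment delegates to statsmodels' step-up implementation;
  tests verify it against a direct implementation of the definition on
  exhaustive permutations.
- Fisher tail probabilities come from `scipy.stats.hypergeom.sf`;
  tests verify against exact binomial-coefficient enumeration for all
  margins with background ≤ 25.
- t p-values use `scipy.stats.t` on hand-computed statistics (so that
  degenerate variances can be handled explicitly); cross-checked
  against `scipy.stats.ttest_ind`.
- Table writers serialize floats with `repr`, making write→read
  round-trips bit-exact and pipeline outputs byte-reproducible (no
  timestamps anywhere).
- Problem sizes in the test suite and the reproduction script are the
  study shape itself (~1800 proteins × 10 samples) or smaller; a null
  calibration uses 1000 proteins, enough for the ±3-binomial-SE band
  around α to be discriminating.

## Known limitations

- The floor-imputation rule is the only missing-value strategy offered;
  model-based imputation is deliberately out of scope.
- Strategy-exclusive proteins receive p = 0 + flag rather than a
  principled presence/absence test.
- GO analysis consumes flat GMT sets; redundancy among nested GO terms
  is not pruned, so passing term lists should be read as descriptive.
- Symbol-keyed marker matching cannot resolve one-to-many protein-group
  to gene mappings; accession and symbol are both carried so either
  keying is possible upstream.
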