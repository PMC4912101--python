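# Methods

## Data model

Alu insertion polymorphisms are treated as stable biallelic presence/absence
loci: the insertion (+) allele and its absence (−), with diploid genotypes
II, ID, DD. No mutation model is applied anywhere — new insertion alleles are
not generated and the ancestral state (absence) is known, which is what makes
these markers attractive for population comparisons.

Two carriers cover the two kinds of published data. `GenotypeTable` holds
individual-level calls (TSV: `population, individual, locus, genotype`, with
`+/+`-style and `II`-style tokens accepted interchangeably and `NA` as the
missing code). `FrequencyMatrix` holds population × locus insertion-allele
frequencies with optional per-cell diploid sample sizes — the form in which
comparative data are usually published. Only the insertion frequency is ever
stored; the deletion frequency is always derived as 1 − p, which prevents the
internal p/q inconsistencies that plague transcribed tables. Sample sizes are
carried per locus rather than per population because published typing counts
at individual loci often differ from the declared recruitment size.

Missing calls simply reduce a cell's n (complete-case counting, the only
choice consistent with estimating frequencies by direct counting); there is
no imputation. A cell with no typed individuals has no defined frequency and
is an error rather than a silent zero.

## Single-population statistics

Allele frequency by direct counting, p = (2·n_II + n_ID)/2n. Observed
heterozygosity is the heterozygote fraction n_ID/n; expected heterozygosity
is the Hardy–Weinberg value 2pq, uncorrected for sample size (the published
tables this package re-analyses match plain 2pq; the 2n/(2n−1) unbiased
variant was considered and deliberately left out of the defaults). Multi-locus
averages are unweighted arithmetic means over loci; the caller selects whether
the observed or expected series is averaged (default observed, which is the
series the survey's per-population summary table prints).

Hardy–Weinberg equilibrium is tested per cell with the plain χ² goodness-of-
fit statistic Σ(O−E)²/E over the three genotype classes, E = (np̂², 2np̂q̂,
nq̂²), on 1 degree of freedom (three classes, one estimated allele frequency),
no continuity correction. Monomorphic cells (p̂ ∈ {0,1}) have no test; they
are flagged and skipped. Bonferroni correction multiplies each p-value by the
family size m, clamped at 1; the default family is every testable cell in the
run (populations × loci), configurable to per-locus or none, since surveys
rarely state their family explicitly.

Calibration: at n = 100 and p = 0.3 the test's type-I error at α = 0.05 is
verified by simulation (10⁴ HWE cells) to lie within 0.05 ± 0.01.

## Gene-diversity decomposition

Per locus, across K populations with frequencies p_j:
Hs = (1/K) Σ 2p_j(1−p_j), p̄ = (1/K) Σ p_j, Ht = 2p̄(1−p̄),
Gst = (Ht − Hs)/Ht. Populations enter unweighted: the decomposition then
needs no sample sizes (often unavailable for previously published
populations), and the printed decomposition tables this package reproduces
are consistent with the unweighted rule. An n-weighted variant is available
(`weighted=True`). Ht ≥ Hs by concavity of 2p(1−p), so Gst ∈ [0,1]; a locus
fixed for the same allele everywhere (Ht = 0) has undefined Gst and is
excluded from aggregation with a warning.

Multi-locus aggregation defaults to **mean-of-ratios**: Ht, Hs and Gst are
each unweighted means of their per-locus values. This is not Nei's classical
convention (ratio of mean Ht and Hs), but it is the rule that reproduces
every "All loci" cell of the published decomposition tables, so it is the
default here; `convention="ratio-of-means"` gives the classical aggregate and
every output is tagged with the convention used.

## Distances and neighbor joining

The survey names only the tree method, not its distance; the package defaults
to Nei's (1972) standard genetic distance D = −ln(J_ab/√(J_a J_b)) with
per-locus gene identities averaged before the ratio, and offers Da (1983),
1 − (1/L) Σ (√(p_a p_b) + √(q_a q_b)), as an alternative. The choice is
surfaced in configuration and recorded in output metadata. D is infinite when
the pair shares no alleles (J_ab = 0), reported as an error naming the pair.

Neighbor joining is the standard Saitou–Nei agglomeration: join the pair
minimising Q(i,j) = (r−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), attach with
rate-corrected branch lengths, replace with d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2;
the last three nodes are resolved by the exact three-point formulas. Ties in
Q are broken by the lexicographically smallest index pair, making runs
deterministic. Negative branch lengths, which can arise on non-additive
input, are clamped to zero with the deficit moved to the sibling branch
(preserving the pair's summed length) and a warning. The result is an
unrooted tree (trifurcating root) held as a `skbio.TreeNode`, so Newick
serialisation and leaf-to-leaf path lengths come from the standard container.
Correctness is property-tested: on additive matrices generated from random
trees, NJ must recover every path length to 1e-9 (which pins down the
topology), and the implementation is cross-checked against an independent NJ
implementation.

## PCA

The population × locus frequency matrix is column-centered only — the
frequencies already share one scale, and the analysis is meant to run on raw
allele frequencies — and decomposed by SVD; a `scale=True` flag standardises
columns for sensitivity analysis, since which variant the original
NTSYS-based analysis used is unknowable. Variance fractions are σ_k²/Σσ²
over the min(K−1, L) non-trivial components; they are non-negative,
non-increasing and sum to 1 (checked to 1e-9 against an independent
covariance-eigendecomposition oracle). Sign convention: each loading vector
is flipped so its largest-magnitude entry is positive, making scores
reproducible across platforms. PCA of the full comparative 48-population
matrix is not reproducible here because the 36 external populations'
frequencies were never printed; validation of this stage is therefore
property-based.

## Synthetic data

The Balding–Nichols island model maps the simulation parameter F directly
onto the Gst estimand: per locus an ancestral frequency p₀ ~ U[0.1, 0.9]
(bounds avoid near-fixed, uninformative loci), then each population draws
p_j ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F), so E[p_j] = p₀ and
Var(p_j) = F·p₀(1−p₀). Genotypes are multinomial (p², 2pq, q²) within
populations — HWE holds by construction, which is what makes the generator a
valid null for the HWE calibration check. Loci are independent (matching the
independence implicitly assumed by averaging over loci) and there is no
linkage, mutation, migration or admixture: passing parameter-recovery tests
shows the estimators are correct under the island model, not that real
caste/tribe data meet its assumptions.

Defaults mirror the survey design (K = 12, L = 7, n = 50, F = 0.036 — the
overall differentiation the survey reports). Parameter recovery is checked
at K = 20, L = 50, n = 100, F = 0.10 over 100 seeds: the pipeline's
multi-locus Gst must land in [0.07, 0.13] in at least 95 runs. The interval
absorbs two small, opposite-signed distortions that are tolerated rather
than corrected: a downward (K−1)/K bias from estimating the across-population
mean frequency from finitely many populations, and upward noise from
estimating frequencies with n = 100 diploids. Identical config + seed yields
byte-identical serialised datasets.

## Published-table handling

The bundled survey tables are stored verbatim, including their internal
inconsistencies, which are documented in `alupopdiv.datasets` and excluded
from identity checks rather than silently "fixed": the pooled-decomposition
FXIIIB row prints Hs > Ht and its CD4 row does not satisfy Gst = (Ht−Hs)/Ht
(presumably transposition errors), and one tribal bold heterozygosity
(0.5918) exceeds the biallelic expected maximum of 0.5, marking that row as
observed heterozygosity — which is also the only reading under which the
tables' arithmetic is self-consistent (the "+/−" rows are exactly 2pq of the
flanking frequency rows). Identity and aggregation checks use the
arithmetically consistent rows; the multi-locus "All loci" means use all
printed per-locus values, as the published aggregates do.

## Numerical and design notes

- Frequencies are validated to [0,1] on construction; TSV output uses
  4-decimal frequencies by default (configurable), matching the precision of
  the published tables.
- `Gst` at Ht → 0 is never computed by limit; the locus is excluded.
- Pipeline outputs are deterministic byte-for-byte given a config: label
  orders are canonicalised on file input (sorted), manifests contain no
  timestamps, and all stochastic code takes explicit integer seeds.
- Problem sizes in the test suite (e.g. 100 recovery replicates at
  K = 20 × L = 50 × n = 100, 10⁴ HWE cells, 100 additive NJ matrices of 5–10
  leaves) were chosen to give Monte-Carlo error comfortably inside the
  asserted bands while keeping the whole suite fast.
- Out of scope by design: multi-allelic loci, linkage statistics,
  hierarchical F-statistics (Fis/Fit), AMOVA, bootstrap supports, tree/PCA
  plotting, and VCF/PLINK ingestion (these markers are presence/absence
  calls, not coordinate-anchored sequence variants).
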