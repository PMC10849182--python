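# Methods

## The question and the statistic

Synonymous codon usage bias (CUB) in fast-growing bacteria is largely
attributed to translational selection, strongest in highly expressed genes.
If that selection is comparable in strength to the selection on an
amino-acid change itself, it should also bias *non-synonymous* variation:
mutations that move a codon from unpreferred to preferred should segregate
and fix more readily than the reverse. `codonsel` quantifies this with a
codon-level odds ratio per directed amino-acid change.

For a directed pair A→B connected by a single nucleotide change, the
single-step codon mutations are ranked by the ratio
RSCU(derived)/RSCU(ancestral) computed on highly expressed genes; the
largest ("max") and smallest ("min") define the contrast:

    Y = (N_max_events / N_max_ancestral_sites)
      / (N_min_events / N_min_ancestral_sites)

Events are polarized polymorphisms (`Y_pol`) or fixed differences
(`Y_div`); opportunity sites are ingroup-monomorphic codons
(polymorphism level) or three-species-identical codons (divergence level).
Per-gene 2×2 tables are pooled with the Cochran–Mantel–Haenszel (CMH)
estimator so between-gene heterogeneity cannot manufacture an aggregate
association (Simpson's paradox). Natural logarithms are used throughout;
the base only rescales and never changes a sign or a test.

Key conventions, chosen where the procedure was genuinely open:

- **Ratio, not difference.** "Biggest increase in RSCU" is read as the
  largest RSCU *ratio*, consistent with ΔRSCU being a ratio of ratios; a
  `criterion="difference"` switch exists. Ties are broken
  lexicographically on the codon pair and logged.
- **No pseudocounts.** A pooled numerator or denominator of zero leaves
  log Y undefined (NaN); undefined pairs are dropped from downstream
  means, mirroring the shrinking pair counts at the divergence level.
  Single-stratum CMH is then *exactly* the simple odds ratio.
- **Wobble-connected 2-fold pairs.** Families like Asn/Lys (AAT,AAC vs
  AAA,AAG) are connected by third-position changes and have four
  single-step codon mutations, not two; the max/min contrast handles this
  uniformly. (First/second-position-connected 2-fold pairs have exactly
  two.)
- **ΔRSCU profiles.** At the polymorphism level both RSCU values come from
  the focal species' highly expressed genes; at the divergence level the
  ancestral-codon RSCU comes from the closest outgroup's profile on the
  same gene set.

## Site filters

Biallelism is assessed at the **codon** level (exactly two codon
haplotypes), since the statistic is a codon-state statistic. A codon
column enters the analysis only if ≥95% of ingroup strains have an
unambiguous, gap-free codon (gaps and ambiguity characters count as
missing; the threshold applies to the ingroup only, while a missing
outgroup codon discards the site). Retained polymorphisms must be
biallelic, one nucleotide apart, non-synonymous, and polarizable: the
outgroup codon must equal one of the two states, which is then called
ancestral. Fixed differences additionally require a monomorphic ingroup
and two agreeing outgroups. Every column receives exactly one call;
discards carry a reason tag (low-coverage, triallelic, multi-nucleotide,
synonymous-only, outgroup-mismatch/-missing/-conflict, stop-codon,
ingroup-polymorphic), so column accounting is exact.

Synonymous divergence d_S uses unweighted Nei–Gojobori (1986) counting:
per-position synonymous site fractions (changes to stops count as
non-synonymous), multi-hit codons averaged over minimal mutational
pathways excluding those through stops, and no multiple-hit correction by
default (`jukes_cantor=True` applies −3/4·ln(1−4p/3)). The choice of
dialect is a documented default, not a claim about the original analysis.

## Codon usage machinery

RSCU is the observed codon count divided by the count expected under equal
synonymous usage; families are the full synonymous sets (6-fold families
kept whole, the seqinr convention). Reference profiles pool counts across
the gene set (not per-gene averages). Relative adaptiveness w is RSCU over
the family maximum; CAI is the geometric mean of w over a gene's codons
excluding Met, Trp and stops, with a floor of w = 0.01 (configurable) for
codons absent from the reference set so one unobserved codon cannot zero
the index.

Highly expressed genes are identified by correspondence analysis of the
genes × codons matrix — CA on RSCU (CA-RSCU), CA on absolute frequencies
(CA-AF), or within-amino-acid-group CA (WCA-CA-AF, the default, which
removes amino-acid composition differences between genes before the
chi-square SVD). The implementation reproduces ade4's `dudi.coa` row
coordinates to 1e-8 on a frozen fixture. Axis 1 is oriented by marker
genes (e.g. ribosomal proteins) when given, else by correlation with
expression, else left unoriented with a warning; the top decile
(ceil(0.10·n)) on the oriented axis is the reference set. Gene categories
use quantile bins with near-equal occupancy (defaults: 4 CAI bins, 5
expression bins — the two figures/methods conventions — both
configurable), and the category × slope interaction model recomputes RSCU
per category by default (`per_category_rscu=False` reuses the global
profile).

## Mutation–selection–drift model and power

With scaled selection S = 4·Ne·s for the preferred codon of a 2-fold
family and Ne·u ≪ 1, the equilibrium preferred fraction is
f = e^S/(e^S+1), invertible as S = log(f/(1−f)). The expected number of
segregating polymorphisms of selective effect S in n chromosomes is the
selected-SFS integral P(S, n) (neutral limit H_{n−1}). Numerics: the
integrand's endpoint singularities are removable (→ n at x=0, → 0 at
x=1) and are evaluated by their limits; `expm1` avoids cancellation; for
|S| < 1e-8 the neutral integrand is substituted; adaptive quadrature runs
at absolute tolerance 1e-10 and is verified against a 10⁶-point trapezoid
rule to 1e-6 over S ∈ [−5, 5].

Assuming the amino-acid change itself is neutral, a mutation into the
derived amino acid's preferred codon has advantage S_derived and the
min-path mutation is disfavoured by S_ancestral, so
E[Y] = P(S_derived, n)/P(−S_ancestral, n); `solve_S_for_expected_y`
inverts the symmetric case by bracketed root-finding.

The power simulation draws, per amino-acid pair and replicate, Poisson
counts with means (1+α)·p̄·N_low and (1−α)·p̄·N_high, where
α = (Ŷ−1)/(Ŷ+1), recomputes log Y per pair (zero cells drop the pair),
and applies a one-sided one-sample t-test across pairs at the 5% level;
power is the rejection fraction over replicates (default 10,000).
Randomness uses one root seed with per-replicate child streams, so results
are bit-for-bit reproducible. With small per-cell means the log-ratio is
skewed and the test runs conservative (size ≈ 0.04 at ~6 events per
cell); with well-populated cells (≈100 events) the size sits at the
nominal 5%.

**Per-pair count table.** p̄, N_low and N_high are inputs (TSV or Python),
never hard-coded results. Because the original per-pair supplementary
counts are not redistributable, the package ships a *synthetic* stand-in
(`synthetic_ecoli_twofold_pair_table`): an *E. coli*-like core genome
(1,316 genes × ~310 codons), round literature codon frequencies for the
nine 2-fold families, and events distributed over the 30 directed pairs in
proportion to ancestral amino-acid abundance. The table's one free scale —
total polymorphism events — is pinned by `calibrate_synthetic_pair_table`
to reproduce a *different* published operating point (≈30% power at
Ŷ = 1.10), leaving power at other Ŷ values as out-of-sample predictions;
at Ŷ = 1.4 the calibrated table predicts ≈99% power, close to the ≈95%
reported for the real counts. This validates the machinery at realistic
scale; it is not a reconstruction of the real table.

## The synthetic generator

`generate_dataset` emulates the structure of bacterial core-genome
alignment data: hundreds of genes, tens of strains, two outgroups at
synonymous divergence ~0.15–0.27, ≤5% missing data. Per codon site:

1. amino acid drawn from a configurable composition (default: *E. coli*-like);
2. ancestral codon from the within-family Boltzmann equilibrium
   p(c) ∝ e^{S_c} (exactly f = e^S/(e^S+1) for 2-folds);
3. a biallelic polymorphism planted with per-path probability
   θ_scale · bias(b→b′) · P(S_{c′}−S_c, n)/P(0, n) toward single-nucleotide
   sense neighbours (θ is approximately the neutral polymorphic fraction of
   codon sites; a path-level normalizer keeps up/down contrasts exactly
   P(ΔS)-proportional), derived counts from the neutral spectrum p(k) ∝ 1/k;
4. focal-branch and outgroup-branch substitutions with synonymous rate set
   by the divergence parameter and non-synonymous paths scaled by a dN/dS
   factor (default 0.05) times the relative fixation rate ΔS/(1−e^{−ΔS}),
   so realized d_S matches the configured value without saturating
   non-synonymous sites;
5. per-strain missing-data masking, optional triallelic noise injection to
   exercise the discard paths.

Ground truth records, for every column, the planted states *and* the
status each caller should assign given the realized outgroups and masking;
with `missing_rate=0` the callers reconcile exactly (statuses, reasons and
polarization, site by site). `expected_log_y_truth` returns the planted
per-pair expectation from the configured S values, mutation bias and the
extremes the pipeline would choose at equilibrium.

**Preferred-codon geometry.** The default preferred-codon map maximizes
the number of pairs with a full unpreferred→preferred contrast. A
limitation is structural, not a bug: with a binary per-family fitness
(preferred = S, others = 0), two adjacent families whose preferred codons
share the third-position nucleotide have only preferred→preferred and
unpreferred→unpreferred connecting paths, so their planted contrast is
exactly zero — and for mutually adjacent family triples (e.g. Gln/Lys/Glu)
at least one such null pair is unavoidable under *any* codon-fitness
assignment. The defaults leave 34 of 42 directed pairs at full contrast;
the parameter-recovery checks therefore pool the full-contrast pairs
against log E[Y] and verify the null pairs separately.

What a green test establishes: the pipeline recovers planted odds ratios
and classifies sites exactly under a site-independent, free-recombination,
equilibrium model. What it does not: linkage, recombination tracts, gene
conversion, demography, alignment error, or selection on the amino-acid
changes themselves — all present in real data and outside scope.

## Known limitations

- The CMH estimate on very sparse strata is noisy for individual pairs;
  standard errors (Robins–Breslow–Greenland, cross-checked against
  statsmodels) are reported and pooling across pairs is preferred for
  calibration checks.
- Outgroup synonymous substitutions in the generator ignore codon
  selection (rate set by the divergence parameter alone); this slightly
  relaxes outgroup codon frequencies toward uniform and is irrelevant to
  the Y contrasts, which condition on the ingroup ancestral codon.
- `d_S` has no site-pattern weighting and the Jukes–Cantor option treats
  all substitutions exchangeably; at d_S ≳ 0.3 both dialects undercount.
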