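# Methods

## The question and the design

When a gene duplicates, the two copies may both keep the ancestral job
(gene conservation), split it between them (subfunctionalization), or one
copy may drift toward a new function or toward decay (neofunctionalization
/ unfinished pseudogenization).  These retention modes make different
predictions about how *asymmetrically* the two copies accumulate amino-acid
substitutions, and about which copy loses expression and accumulates
non-synonymous polymorphism.  `dupasym` implements a genome-scale version
of this analysis for reconciled gene families: each eligible duplication is
compared against its phylogenetically nearest *singleton* ortholog, using
the ancestral reconstruction at the speciation node directly preceding the
duplication as the common reference.  Referencing the pre-duplication
speciation node (rather than the duplication node itself) matches each
paralog pair to its closest never-duplicated relative and lets concerted
evolution show up as substitutions shared by both paralog clades; the cost
is a conservative bias, since part of each "paralog" branch was actually
spent as a single-copy gene.

## Input masking

Alignment regions around indels are unreliable, so every gap run longer
than 1 residue is excluded together with 5 flanking columns on each side
(both knobs configurable).  Masking is column-wise for the whole family: a
bad region in any sequence removes the column everywhere.  Terminal gap
runs are treated like internal ones with the flank clipped at the
alignment bounds — the conservative reading where the rule is ambiguous.
The per-sequence usable length (unmasked, ungapped columns) is the
denominator L of all rate calculations.

## Ancestral reconstruction and posterior tie resolution

Per divergent column, ancestral states are reconstructed by unit-cost
parsimony (Sankoff dynamic programming; gaps and ambiguity codes are
missing data, costing nothing in any state).  Ties between equally
parsimonious reconstructions are resolved probabilistically: 20×20
matrices of (ancestral → derived) substitution frequencies are first
estimated from the *unambiguous* sites, binned into 10 classes of
phylogeny depth (Ks units, synonymous substitutions per 4-fold degenerate
site) spanning the full tree depth, because exchange propensities drift
with evolutionary time.  The depth of a substitution is the Ks depth of
the child node of its edge; duplication nodes inherit the depth of the
nearest preceding speciation node (the upper-bound age estimate — the true
age of a duplication is unknowable more precisely than its flanking
speciations).

Each tied reconstruction is weighted by the product, over its implied
substitutions, of the bin frequency of that amino-acid pair; normalising
over the alternatives gives each reconstruction — and hence each
hypothesised substitution — a posterior probability.  A unique
reconstruction has posterior exactly 1, and posteriors over a site's
alternatives always sum to 1.  Numerical choices: bin matrices expose pure
empirical frequencies (so a degenerate corpus yields a degenerate matrix,
and frequency ratios are exactly what the counts say); a 0.5 pseudo-count
floor replaces a required cell only when it was never observed, so weights
are never zero; empty bins fall back to the pooled matrix; tie enumeration
is exhaustive up to a cap of 64 alternatives per site, beyond which the
truncated set gets uniform posteriors (bounded runtime on pathological
columns; such sites are rare and carry little signal anyway).

## Selecting duplications

Only duplications directly preceded by a speciation event in a singleton
gene are analysed, so that a clean triplet exists: the speciation
ancestor, the two paralog clades, and the singleton outgroup.  Three
filters enforce this: duplications ancestral to the whole species set are
dropped (no outgroup exists); of nested duplications only the outermost is
kept; and a duplication whose nearest outgroup is the remaining paralog of
a lost duplication is dropped.  Gene types (paralog / true singleton /
remaining paralog) are taken from the reconciler's leaf annotations when
present and otherwise derived structurally from the duplication nodes; the
reconciler annotations matter for the third filter, because a fully lost
duplication leaves no node in the gene tree and is only knowable from
reconciliation against the species tree.  Several triplets per family are
allowed when duplications sit in parallel orthologous clades.
Duplication ages are classed young / mid / old on the upper-bound Ks
depth; the young boundary defaults to Ks = 0.051 and the upper boundary to
the cohort tertile, keeping three usable classes while honouring the one
externally fixed cut-off.

## Rates, radicality, asymmetry

For each clade of a triplet, Ka is the posterior mass of substitutions on
the ancestor→leaf paths divided by the summed usable lengths of those
paths.  Remaining paralogs are excluded from paralog clades.  Events on
the speciation→duplication stem lie on every paralog path and are counted
in both paralog clades — deliberately, since concerted evolution is
expected to manifest exactly there.  relKa = Ka / Ks-depth normalises by
the upper-bound age, so a clade evolving at the synonymous clock has relKa
≈ 1 (the synthetic generator reproduces this calibration).

Radicality of a clade's substitutions is the posterior-weighted mean of
(i) the absolute polarity difference between ancestral and derived residue
(Grantham 1974 polarity scale, replaceable) and (ii) the directional
exchangeability EX of the change.  Posterior weights only — no length
weighting — per the definition of these as averages over substitutions.
The shipped EX table is a deterministic synthetic stand-in with the
published schema (directional, [0, 1]); real analyses should supply the
published matrix as a TSV.  All EX unit tests use controlled fixture
matrices, so correctness never rests on the shipped values.

Asymmetry between the two paralog clades with counts N1, N2 over lengths
L1, L2 is

    Z² = (p1 − p2)² / [ p (1 − p) (1/L1 + 1/L2) ],   p_i = N_i/L_i,
    p = (N1+N2)/(L1+L2),

the squared normal deviate of the two-proportion comparison.  Its null
expectation is 1 under equal rates and near-uniform site rates, and —
unlike the classical A = (N1−N2)²/(N1+N2), to which it reduces as
Z² = A/(1−p) at equal lengths — it is independent of divergence and of
target size.  Z² (the uncorrected statistic) is the asymmetry *measure*;
*significance* uses the Yates-corrected chi-square of the 2×2 table
[sites with/without substitutions × lineage], since the continuity
correction is defined on counts: posterior-weighted counts are rounded
half-to-even to form the table.  Multiple testing across duplications uses
Bonferroni (α = 0.05) and Benjamini–Yekutieli FDR (q = 0.1; valid under
arbitrary dependence).  For log-scale analyses, Z² = 0 datapoints (exactly
equal counts) are removed before taking log10.

## The simulated null of Z²

`pair_simulator` evolves a pair of homologs with *equal* per-copy
substitution probabilities as a discrete event process: each event picks a
(copy, site) proportionally to current rates until total events per site
reach the target Ka.  Ka counts events (multiple hits included); N_i for
Z² counts distinct substituted sites.  Site rates are gamma distributed
with mean 1; by default the draw is *shared* between the two copies —
the rate is a property of the homologous site, not of the copy.  This
choice is load-bearing: shared fast sites saturate in both copies, making
the counts correlate beyond the binomial model and driving the null
expectation of Z² below 1 for leptokurtic rate distributions (shape 0.5),
while near-uniform rates (shape 20) keep it at 1 at any divergence.  With
independent per-copy draws (available via `shared_site_rates=False`) the
below-1 drift disappears, which is inconsistent with the behaviour the
analysis corrects for; hence the default.  Unequal lengths (500 vs 400
codons) have no effect under near-uniform rates and partially reverse the
drift under leptokurtic rates, because the unshared tail of the longer
copy decorrelates the counts.  Optional epistatic sites multiply all other
rates in their copy once substituted; even 5 such sites at factor 2 push
the null mean of Z² far above 1 at small Ka — so an observed Z² > 1 can
reflect either true rate asymmetry or epistasis, and the analysis reports
it as rate difference without asserting the cause.  Null curves report
log10 of the mean Z² as the headline (`log10_mean_z2`; 0 under the null)
alongside the mean and SE of log10 Z²; the mean of log10 of a χ²(1)
variable is ≈ −0.55 even under a perfect null, so the two scales must not
be conflated.

## Expression, polymorphism, location

Per-gene expression over n tissues (default 26) is summarised as log10
mean, coefficient of variation (non-uniformity) and Shannon evenness
H(shares)/ln(n) — the evenness formula is a provisional standard choice,
isolated behind one function, satisfying the property that its conclusions
mirror CV with opposite sign.  Pair-level quantities are polarized by
divergence: dE = E(faster copy) − E(slower copy), direction set by the
clade Ka; pairs with exactly equal Ka carry no direction and are excluded,
consistently with the Z² = 0 removal.  Pairs whose two members resolve to
one expression record (one gene under two identifiers) are dropped.
Polymorphism Ka/Ks per gene is (non-synonymous SNPs per non-synonymous
site)/(synonymous SNPs per synonymous site); genes need ≥ 3 SNPs of each
class to be eligible, because the ratio is noise-dominated below that.
Paralog pair placement is classed as different arms / same arm over 5 kb /
tandem collinear / tandem inverted, with distance measured as the gap
between gene spans (overlap counts as 0 and falls to tandem by
orientation); gap-vs-midpoint was an open choice and the gap is
implemented.  The statistical battery runs one-sample two-tailed t-tests,
sign tests and Fisher exact tests on the polarized differences (all pairs,
Z² > 1 pairs, FDR-significant pairs), regressions of log10 Z² on
expression summaries and of the polarized differences on log10 Z², binned
means (0.5 log10-unit bins), and a linear model of log10 Z² on mean
expression, CV and location with a type-II ANOVA table.  Tests with fewer
than 3 usable records are skipped with a logged reason.

## The synthetic-data generator

The generator is first-class, tested code: it emulates the statistical
structure of the real inputs (reconciled 12-genome families, tissue
expression, population SNP tables, chromosomal locations) with full ground
truth, not their biological detail.  Sequence evolution is uniform
20-state exchange with per-site gamma multipliers, events Poisson per
branch at the Ks clock scaled by `ka_ks_scale` (1 = neutral calibration,
relKa ≈ 1; cohort defaults use 0.15, a typical purifying-selection rate).
A duplication planted on a species-tree edge (midpoint of the edge in Ks)
doubles the subtree below; `rate_ratio` accelerates copy 1;
`concerted_until` mirrors the first stretch of post-duplication evolution
into both copies; programmed losses delete copy-2 leaves in chosen species
and mark survivors as remaining paralogs; `indel_rate` plants 2–5 residue
gaps for the masking stage.  Expression is log-normal per tissue around a
gene mean; a signed coupling shifts the faster copy's log-mean (negative =
faster copy lower), and paralogs share a family tissue profile so
within-pair tissue correlation is realistic.  SNP tables draw Poisson
counts at per-site densities (defaults 0.05 synonymous, 0.015
non-synonymous per site — a few SNPs per gene, so the ≥3 filter bites
occasionally, as in real population data); a positive coupling raises the
faster copy's non-synonymous density.  What the generator does *not*
emulate: codon-level evolution and realistic dN/dS, real tissue
correlation structure, linkage, and reconciliation errors — so passing
tests demonstrate correctness of the analysis machinery and recoverability
of imposed effects, not biological conclusions about real genomes.

## Problem sizes and reproducibility

Every stage is a pure function of inputs plus a single integer seed;
reruns are byte-identical.  Default test and acceptance problem sizes are
chosen so the full battery runs in seconds to a couple of minutes on one
CPU: 2000 replicate pairs for null calibration, 500 replicates per
grid point for the null curves, and paired 50-family cohorts (6 taxa, 150
codons) for parameter recovery — large enough that the imposed effects
(rate ratio 4, expression coupling −1, SNP coupling +1) are recovered with
conventional significance, and that zero-coupling cohorts stay null.

## Known limitations

Parsimony undercounts multiple hits, so Ka is biased downward at high
divergence (the generator's ground truth quantifies this; recovery tests
run at moderate divergence).  The posterior weighting of tied
reconstructions is a simple per-substitution product — a likelihood-
flavoured use of the depth-binned matrices, not a full ML reconstruction.
The shipped EX matrix is synthetic (see above).  Ks depths are inputs, not
estimated from sequence.  The duplication age is only bounded above;
everything age-related inherits that coarseness.
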