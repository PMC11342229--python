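# Methods

## The reciprocal ABBA-BABA construction

A single ABBA-BABA (Patterson's D) test on four taxa (P1, P2, P3, O)
polarizes each biallelic site with the outgroup and contrasts the two
discordant patterns: ABBA (derived allele shared by P2 and P3) against
BABA (shared by P1 and P3). Incomplete lineage sorting (ILS) produces
both in equal expectation; introgression between P2 and P3 inflates
ABBA only.

In an allotetraploid the five available taxa are the two subgenomes
(E_SUB maternal, C_SUB paternal), the two diploid progenitors (E_DIP,
C_DIP) and an outgroup. `hgflow` runs the test twice, once per
direction of homoeologous gene flow (HGF), excluding the *donor*
subgenome from the quartet each time:

| direction | P1 | P2 | P3 | excluded donor | detects |
|-----------|----|----|----|----------------|---------|
| MAT | C_DIP | C_SUB | E_DIP | E_SUB | E subgenome overwriting C |
| PAT | E_DIP | E_SUB | C_DIP | C_SUB | C subgenome overwriting E |

If the donor has overwritten the tested subgenome, that subgenome
shares derived alleles with the *opposing* diploid (ABBA); the BABA
count estimates how often the same pattern arises by chance. Each test
is therefore read one-tailed: only D > 0 indicates HGF in that
direction.

### Site usability rules

A column enters the tally only when all four quartet bases are
unambiguous nucleotides (A/C/G/T after U→T normalization) and at most
two states are present. Gaps, N, and IUPAC ambiguity codes make a
column unusable rather than being resolved probabilistically — a
deliberate choice keeping the count strictly binary; there is no
frequency-weighted variant here because each taxon contributes a single
haplotype. Columns with three or more states are discarded as
unpolarizable. The excluded donor's state — including a gap — never
affects a column's usability; that convention is a documented decision
point for sensitivity analysis, since conversion tracts in the donor
could in principle carry gaps. Counting is nucleotide-level across all
codon positions.

### Inference

D is computed on site totals summed over genes (concatenated D). The
exchangeable unit for uncertainty is the gene — sites within a gene
share one genealogy — so resampling is a gene-level bootstrap:
each replicate redraws n genes with replacement (realized as
multinomial weights, which is distribution-identical and vectorizes),
recomputes D, and the defaults take 10,000 replicates. Reported are the
percentile 95% CI, boot sd, Z = D/sd, and the upper-tail normal
p-value. Replicates whose resample has no informative sites are
dropped and counted (`n_failed_reps`) rather than redrawn. A replicate
distribution that collapses to a point (e.g. a single gene) yields
sd = 0; Z is then flagged undefined instead of being reported as
infinite. If extreme bootstrap skew ever places the point estimate
outside its own CI, the result is flagged, not silently adjusted.

Two estimates from the *same* genes (the two directions, or one
direction in two categories over a shared gene set) are compared by a
paired bootstrap: one resample of gene indices is applied to both
series per replicate, Δ = D_a − D_b, Z = mean(Δ)/sd(Δ), upper-tail p.

All randomness flows from a single integer seed through one numpy
Generator; identical seeds give bit-identical output.

## Gene-tree topologies

Rooting a five-taxon binary tree at the outgroup leaves a four-leaf
ingroup with exactly 15 possible rooted shapes. Topology identity is a
canonical serialization of the ingroup as nested sets with sorted
children, so leaf order, branch lengths and supports are irrelevant.
Display letters A–O are cosmetic and remappable; categories attach to
shapes:

* A = ((E_SUB,E_DIP),(C_SUB,C_DIP)) — species tree;
* L = (((E_SUB,C_SUB),E_DIP),C_DIP) — E-overwrites-C;
* M = (((E_SUB,C_SUB),C_DIP),E_DIP) — C-overwrites-E;
* F = ((E_SUB,C_DIP),(C_SUB,E_DIP)) — reciprocal exchange;
* K = ((E_SUB,C_SUB),(E_DIP,C_DIP)) — tetraploids and diploids sister;
* N, H — a subgenome sister to the opposing diploid; I, O — diploids-
  sister caterpillars; the remaining six shapes are "other".

Under ILS, a tetraploids-sister arrangement is no likelier than its
counterparts, so HGF is inferred from the excess of L, M and F over the
paired ILS topologies. The default pairing is L:N, M:H, F:K and is a
configuration (YAML via the CLI), because reasonable alternative
counterpart sets exist (e.g. including the diploids-sister shapes); the
statistics are computed per pairing, with binomial, chi-square
goodness-of-fit and Fisher 2×2 tests, Holm-corrected within each test
family. Binomial tests are two-sided by default with a one-sided
option.

Support filtering: a tree is counted only when *all* ingroup internal
supports meet the threshold, and the comparison is inclusive (≥). Both
choices were genuinely open — a single weakest-node rule and a strict
(>) comparison are defensible — and are exposed as parameters; trees
without support labels fail any positive threshold.

## Gene categories and enrichment

Categories follow the CyMIRA scheme: NOT, MTNI, MTI, MTEC, PTNI, PTI,
PTEC, with the enzyme-complex sets nested inside the interacting sets
(MTEC ⊆ MTI, PTEC ⊆ PTI); category tables store the most specific
label, and the interacting analyses include their enzyme-complex
subset. Genes absent from the table default to NOT with a warning,
since NOT is defined as the complement of the organelle-targeted sets.
Per-category bootstrap D values (both directions) are Holm-corrected as
one family spanning all reported category × direction tests; the family
boundary is itself a documented configuration choice.

Topology enrichment asks whether a focal category's *ratio of
directional-HGF trees to species-trees* differs from the
non-organelle-targeted baseline: the 2×2 table is
[[focal HGF-topology count, focal species-tree count],
[baseline HGF count, baseline species-tree count]], tested with the
two-sided probability-mass Fisher rule. Normalizing by the species-tree
count rather than the category remainder makes the test insensitive to
how many ILS/other trees a category happens to contain. On the
published coffee gene-tree counts this construction reproduces all four
printed enzyme-complex p-values (0.274 and 1.0 for plastid, 0.752 and
0.737 for mitochondrial). Note the source reports some quantities
inconsistently between text and tables (e.g. genome-wide D_MAT 0.538
vs 0.514; plastid enzyme-complex D_MAT 0.750 vs 0.888); this package
documents, and does not adjudicate, those discrepancies.

## The simulator

`simulate` emulates the five-taxon per-gene data the tests consume, and
provides exact truth for validation. Per gene: (1) a genealogy class is
drawn — species arrangement, or with probability `p_ils` (split evenly)
one of the two discordant arrangements K and F. These two are the
symmetric pair under the reciprocal quartets: K produces BABA and F
produces ABBA in *both* directions, so the no-HGF background satisfies
E[D_MAT] = E[D_PAT] = 0 by construction. (2) Sequences evolve from a
uniform random root by Jukes–Cantor along the genealogy. (3) With
probability `f_mat`/`f_pat`/`f_recip` a conversion event copies the
donor's final sequence over the recipient (whole gene, or a uniformly
placed tract), then residual divergence accrues.

Parameters (defaults are the emulated study conditions):

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 1000 | genes per data set |
| `gene_length` | 300 | alignment columns (bp, multiple of 3) |
| `diploid_divergence` | 0.026 | expected subs/site between diploids (≈2.6% dS) |
| `outgroup_divergence` | 0.15 | expected subs/site to the outgroup |
| `polyploid_age_fraction` | 0.1 | subgenome–progenitor split as a fraction of diploid divergence (young polyploid) |
| `p_ils` | 0.05 | per-gene probability of a discordant genealogy |
| `f_mat`, `f_pat`, `f_recip` | 0 | per-gene HGF probabilities by direction |
| `tract_mode` | whole_gene | conversion span; `tract` uses `tract_length` |
| `tract_length` | 200 | bp, the expected scale of gene-conversion tracts |

Residual post-conversion divergence is
`polyploid_age_fraction × diploid_divergence / 2` applied to each
overwritten segment (conversion is treated as having happened at the
polyploid origin; with age fraction 0 the copy is exact). Discordant
genealogies place their cherries at the species-crown depth with the
discordant root midway to the tree root — deep coalescence happens
above the species split, and the exact depth only scales the ILS
signal, not its symmetry. Each gene's generator is keyed by
(seed, gene index), and the genealogy and HGF draws precede all
sequence randomness, so raising an HGF rate at fixed seed converts a
superset of genes: D responds monotonically, which the tests exploit.

What the simulator does *not* model: an explicit multispecies
coalescent (ILS is a per-gene genealogy class), recombination within
genes, codon structure or selection, rate variation among lineages,
alignment or assembly error, and gaps/ambiguity codes (simulated
alignments are gap-free; the usability rules are exercised by
constructed fixtures instead). Passing calibration here therefore shows
the statistical machinery is correct under the stated model, not that
real data are free of the assembly, alignment and rate-variation
caveats that apply to any D-statistic analysis.

## Numerical and interface choices

* One-tailed upper-normal p-values for D (gene flow can only push the
  tested D positive); the Z-vs-p pairs this convention implies (e.g.
  Z = 2.375 → p = 0.0088, Z = 3.27 → p = 0.0005) match the reference
  analyses this package reproduces.
* Percentile bootstrap CI (not BCa): simple, matches the quantity the
  replicate distribution directly estimates.
* Holm step-down for every multiple-testing family; Fisher's exact test
  uses the two-sided probability-mass rule (ties included).
* The ≥99 bp gene-length filter is inclusive and applied to
  post-trimming alignment length; alignments are consumed pre-trimmed.
* Alignment columns are 0-based internally (truth-table tract
  coordinates are 0-based half-open); user-facing reports are 1-based.
* Genes failing validation are skipped with structured reasons and the
  run continues; results files embed tool version, config hash and
  seed.

## Problem sizes

The shipped validation runs the calibration at 1000 genes × 300 bp with
1000 bootstrap replicates and 100 independent runs per condition, and
the site-pattern oracle at 1000 random alignments; these sizes give the
coverage/power margins quoted in the tests while keeping the whole
suite fast. The genome-scale configuration (6672 genes, 10,000
replicates) is the library default and is exercised by the optional
integration test against the public coffee deposit.
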