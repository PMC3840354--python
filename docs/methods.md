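# Methods

`mpnpipe` re-implements, as a tested pipeline over alignment hit tables, the
comparative metagenomic/metatranscriptomic analysis of a methylphosphonate
(MPn) amendment experiment: seawater microcosms amended with glucose +
nitrate (Glc+N) or glucose + nitrate + MPn (Glc+N+MPn) against an unamended
control, sampled as paired DNA and RNA libraries over 48 h.  Every stage is
exercised end-to-end on a synthetic community simulator with known ground
truth, because the original sequencing data and the database versions they
were searched against are not reproducible at desk scale.

## Input model

All computation begins at alignment hit tables in the 12-column BLAST
tabular layout (`qseqid sseqid pident length mismatch gapopen qstart qend
sstart send evalue bitscore`); extra trailing columns are ignored.  Only
column 1 (read), 2 (subject), 3 (percent identity) and 12 (bit score) are
consumed.  Reference catalogs are TSVs mapping each subject to an explicit
taxonomic lineage (domain → phylum → class → order → species), an optional
KEGG ortholog (KO), a protein length in amino acids, a gene-family tag
(e.g. `phnJ`, `recA`, `csrB`), and an entry class (rRNA / sRNA / protein).
Storing lineages per entry keeps the artifact free of any external
taxonomy service.  The universal significance gate is a bit score of 50,
applied inclusively (`>= 50`): the source methods state the cutoff both as
"50" and as ">50", so the inclusive reading was fixed once and the
comparison operator left configurable.

## Read partitioning

Each read belongs to exactly one class, assigned by precedence
rRNA → sRNA → protein → unassigned: any qualifying rRNA hit wins regardless
of other matches, then sRNA, then protein (hits against either the
protein/taxonomy catalog or the KEGG catalog count as protein evidence).
The precedence order is made explicit here because a read can legitimately
hit several catalogs; it reflects the parsing order of the original
workflow (rRNA parsed out first).  Reads present in the library manifest
but absent from every hit table are unassigned; class counts always sum to
the manifest total.

## Taxonomic profiles

A read's taxon is its top-bit-score hit's taxon.  If several hits tie at
the top score, the read counts only when all of them agree on one taxon id
("uniquely assigned"); ties among genes of a single organism do not
disqualify it, cross-taxon ties are excluded and counted.  Bit-score ties
use exact float equality — BLAST reports scores at fixed precision, so no
epsilon is warranted.  Assignment always happens at the taxon-id level and
the requested lineage rank only aggregates for reporting, which makes
rank-aggregation exactly consistent (a species profile summed by lineage
equals the order profile).  Abundance is percent of assigned reads; taxa
below a report cutoff (1% or 3% in the original figures) can be pooled
into "other".

## KO and pathway profiles

For each non-rRNA, non-sRNA read, the top-bit-score KEGG hits define its
KO assignment; each of the k KO-bearing tied hits contributes weight 1/k
(same-KO ties accumulate), so every KEGG-assigned read contributes total
weight exactly 1 — a conservation law asserted in the tests.  KO percents
are normalized to the number of KEGG-assigned reads.  Pathway abundance is
the sum of member-KO percents; a KO in several pathways counts fully in
each (no cross-pathway splitting), so pathway columns may sum above 100% —
this matches counting "sequences assigned to KO annotations within that
pathway" and is documented rather than hidden.  Three custom pathways are
carried alongside the standard ones: alkylphosphonate metabolism (the C-P
lyase KOs), phosphate metabolism, and polyhydroxyalkanoate biosynthesis.

Sample clustering uses unweighted average linkage on d = 1 − Pearson r
over pathways retained at >1% in at least one library.  The agglomeration
is implemented in-package because deterministic tie-breaking is part of
the contract: among equidistant candidate merges, the lexicographically
smallest pair of member-id sets is merged, making the tree invariant to
input column order.  scipy's UPGMA serves as an independent oracle in the
tests (cophenetic distances agree on tie-free inputs).  The row-normalized
display matrix is a per-row z-score; since Pearson distance is
scale-invariant this choice affects display only, and rows of zero
variance are an explicit error naming the offending library.

sRNA family abundance uses a deliberately different denominator: percent
of all non-rRNA reads of the library (not the KEGG-assigned subset),
matching how csrB abundance was reported.

## Differential abundance

Two libraries' KO counts are compared with the Audic–Claverie conditional
test.  Given count x in a library of size N1, the count y in a library of
size N2 follows

    p(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

i.e. y | x ~ NegativeBinomial(x+1, N1/(N1+N2)).  Tail masses are evaluated
in log space with log-gamma and `logsumexp`, accurate far beyond
floating-point factorials; the tests check agreement with direct summation
to 1e-10 for all x, y ≤ 50 and with scipy's negative-binomial CDF.

Tail convention: with L(y) = Σ_{k≤y} p(k|x), the one-sided p-value is L(y)
when the observed rate y/N2 falls below x/N1, the complement 1 − L(y) (the
strict upper tail) when above, and 1 when the rates are exactly equal (the
least extreme observation possible).  This is the unique completion that
makes the test exactly exchangeable, p(x,y,N1,N2) = p(y,x,N2,N1): summing
both tails inclusively double-counts the boundary term p(y|x) under the
swap, which is easy to verify at x=5, y=0, N1=N2 (1/64 vs 1/32).  The
two-sided p-value doubles the one-sided value, capped at 1, and is the
default; the one-sided variant is exposed.

Tie-split weights are rounded to integers before testing (the statistic is
defined on counts); half-up rounding is the default with floor available.
Features at zero in both libraries are skipped — they would contribute
p = 1 while inflating the correction burden.  Benjamini–Hochberg q-values
come from statsmodels' step-up implementation, cross-checked against a
literal step-up oracle in the tests.  The headline summary is the fraction
of tested KOs with q < 0.05.  Fold changes are ratios of normalized
percents with an explicit `inf` for zero denominators.  Testing defaults
to the KO level (pathway-level comparison is available through the same
interface by aggregating first).

## Gene-family abundance (percent of bacteria)

For family f with reference protein length L_f and qualifying-hit count
c_f, and recA as the single-copy reference (length 353 aa — the E. coli
RecA protein; the reference length is configurable since the original
value was not stated),

    percent_of_bacteria(f) = 100 · (c_f / L_f) / (c_recA / L_recA).

Length normalization cancels the longer-gene-more-reads bias, and dividing
by the recA rate converts to "fraction of genomes carrying f" under the
single-copy assumption.  The reference normalizes itself to exactly 100 in
every library with ≥1 recA hit.  A read hitting two families counts only
for its best-scoring family (no double counting; equal-score cross-family
ties go to the alphabetically first family for determinism).  Taxonomic
attribution of family hits uses the single top-scoring hit per read, with
cross-taxon exact ties sent to an explicit "ambiguous" bucket rather than
assigned arbitrarily.  An optional percent-identity gate (95%) supports
assigning gDNA reads to near-identical recovered clusters.  In the
simulation, the multinomial read model makes the estimator exactly unbiased
for the true carriage fraction, which the calibration test verifies at
carriage 0.05/0.3/0.5 over 20 seeds within 3 propagated binomial standard
errors.

## Expression ratios

Per gene on a recovered cluster, ratio = (RNA reads per gene / total
non-rRNA non-sRNA RNA reads) / (gDNA reads per gene / total gDNA reads),
counting only hits at bit score ≥ 50 and identity ≥ 95%.  "Total gDNA
reads" is taken literally as the library total.  Zero-DNA genes are
explicitly undefined, excluded from group means, and counted.  Groups
(C-P lyase vs other genes) are compared by arithmetic means of defined
ratios (the reported statistic), with medians also emitted for robustness.

## Cluster annotation

Roles follow the canonical phn nomenclature: phnC/D/E transporter, phnG–M
catalytic core, phnF regulatory, phnN/O/P and the phnP-analogous rcsF
phosphoesterase accessory; unknown genes are kept with role "novel"
(duplicated components like phnM1/phnE2 included).  Completeness is
assessed on three axes — catalytic core (all of phnG–M), transporter
(phnC–E), PRcP hydrolysis (phnP or rcsF).  Substrate predictions are a
pure function of gene content: a catalytically complete, PRcP-capable
cluster grows on MPn, ethylphosphonate, 2-aminoethylphosphonate,
3-phosphonopropionate and 3-aminophosphonopropionate; the
1-aminoalkylphosphonates (AMPn, 1-AEPn) additionally require the phnO
N-acetyltransferase.  Substrates with no cluster-intrinsic rule
(phosphonoacetate, phosphonoalanine, phosphite, hypophosphite, phosphate,
no-P) are reported indeterminate rather than guessed — the observed
differences among the recovered clusters on those substrates have no
stated genetic basis, and fitting a rule to them would be fabrication.
The bundled gene lists of the three recovered marine clusters are
reconstructions from their published descriptions (ordered lists were not
printed); the growth-panel agreement test covers only the rule-covered
substrates.

## The synthetic community

The simulator emits hit tables directly — the pipeline's computation
begins there, and simulating sequences would add nothing the tests could
check.  A scenario is a set of taxa with genomes (gene catalogs), per-arm
abundance trajectories, and regulons (gene-family sets with induction
multipliers per treatment and timepoint).  Per library:

* DNA read counts per gene are multinomial with weights ∝ taxon abundance
  × gene length (rRNA and sRNA genes included — genomes contain them).
* RNA reads are first split into rRNA/sRNA/other classes at fixed scenario
  fractions (defaults 40% rRNA, 5% sRNA); within the sRNA and protein
  classes, weights are additionally scaled by regulon induction.  This is
  how treatment-specific physiology enters: induction changes composition
  within a class while class totals stay put.
* With probability `ambiguity_rate` (default 0.05) a protein read receives
  two equal-bit-score top hits to same-KO genes of two distinct taxa:
  KO-assignable but taxonomically ambiguous, exactly the contrast between
  tie-split KO counting and unique-taxon profiling.  The realized tie
  count is recorded in the ground truth and equals the taxonomic
  exclusion count by construction.
* With probability `unassigned_rate` (default 0.10) a read gets only
  sub-threshold hits (b < 50); a further 30% of reads carry a weaker
  secondary hit to exercise top-hit selection.
* Scores and identities are simple uniform/normal draws (primary identity
  ~N(96.5, 2), as for reads aligned to a matched reference) — only
  thresholded and tied comparisons matter downstream.

Each library has its own pseudo-random stream derived from
(seed, sha256(library_id)), so libraries regenerate independently and the
whole simulation is byte-reproducible.

The default "microcosm succession" scenario has six taxa — two oligotrophs
(Prochlorococcus-like, Pelagibacter-like), a V. splendidus-like
opportunist, two C-P lyase carriers (V. nigripulchritudo-like and a
Rhodobacterales representative), and an Alteromonadales background — over
0/12/24/36/48 h in the three arms, 20,000 reads per library (a realistic
pyrosequencing-scale desk size; depth is a free parameter).  Trajectories
and inductions were set once to mirror the observed succession: the
opportunist blooms to 59% at 24 h in both amended arms with PTS (×5 peak),
PHA (×3) and csrB (×60, from a 0.02 repressed baseline) responses;
P-starvation (Pho regulon ×3→×5 from 24 h) follows in both amended arms;
only the MPn arm ends with the carriers at a combined 46% of cells and the
alkylphosphonate regulon induced ×12 at 48 h from a 0.05 repressed
baseline.  The ×12 endpoint induction makes the C-P lyase expression-ratio
fold over carrier housekeeping genes exceed 10 by construction; the
repressed baselines keep phn transcription near zero elsewhere, so the
alkylphosphonate pathway is the top fold-change pathway only in the MPn
arm.  The carriers' phn gene complements differ deliberately: the
Vibrio-like carrier has phnC–N + phnP, the Rhodobacterales carrier lacks
phnP and carries rcsF (which, having no KO, also exercises the
KEGG-unassigned path).

What the simulator does *not* model — and hence what passing tests do not
show about real data: sequencing error and chimeras, homopolymer
artifacts, genome-size variation (abundances are read-generating weights,
not cell counts), multi-copy rRNA operons, strain-level diversity within a
taxon, database incompleteness (every simulated read has a true subject),
phage dynamics, and diel expression cycling in the controls.  Conclusions
about statistical calibration (type-I error, carriage recovery) hold under
multinomial sampling, which real libraries only approximate.

## Numerical and degenerate-input choices

* AC tail sums: log-space `logsumexp`; absolute error vs direct summation
  ≤ 1e-10 over the tested grid.  p = 1 at exact rate equality.
* Zero reference (recA) hits: explicit error — the statistic is undefined,
  never silently zero.
* Pearson distance on a zero-variance profile: explicit error naming the
  library.
* Clustering merge ties: lexicographically smallest member-id pair, within
  a 1e-12 distance tolerance.
* Pathways with no observed member KO: kept at zero (excluded from the
  clustering view by the 1% rule) by default; a strict mode raises.
* Weight rounding for the count test: half-up (not banker's), configurable
  to floor.
* Empty hit tables, empty libraries, all-sub-threshold reads: all yield
  well-defined empty/zero results rather than exceptions, except where a
  denominator genuinely vanishes.

## Problem sizes

The bundled analyses and tests run the default scenario at 20,000 reads ×
30 libraries, the null calibration at 2,000 features × 50,000 depth, and
carriage recovery at 6,000 reads × 20 seeds × 3 carriage levels — sizes
chosen so the full suite completes in well under a minute while leaving
every statistical check adequately powered.
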