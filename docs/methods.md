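# Methods

## The model

The pipeline asks, for each protein domain (or gene), whether it carries
more somatic mutations across a patient cohort than its length alone
would predict. The null model assumes mutations are mutually independent
and land uniformly over the tested universe of sequence. For region *i*
with residue length *l<sub>i</sub>* out of a universe of total length *L*,
each mutation hits the region with probability *p<sub>i</sub> = l<sub>i</sub>/L*,
so the region's count among *n* total mutations is
Binomial(*n*, *p<sub>i</sub>*). A region is a **candidate** when its
upper-tail probability P(X ≥ k) falls below the Bonferroni-corrected
level α/m, with α = 0.05 by default and *m* the number of hypotheses in
the family — (number of regions) × (number of cohorts), where the
pan-cancer union cohort always counts as one additional cohort.

Two universes are used:

* **Domain level** — *l<sub>i</sub>* sums every occurrence of domain *i*
  across the proteome (a Pfam family or CATH superfamily may occur on
  many proteins and repeatedly on one protein); *L* sums all domains of
  that source (Pfam and CATH are tested as separate families); *n*
  counts only hits landing on that source's domains, one per
  (mutation, domain id) pair. Overlapping occurrences of the *same*
  domain id contribute a single hit per mutation, so self-overlap never
  inflates a count.
* **Gene level** — *l<sub>i</sub>* is the gene's coding length in
  residues and *L* the total coding length of **all** genes, even when
  only a restricted gene set (e.g. DNA-repair genes) is tested; *m*
  scales with the set size instead. Group-level tests (e.g. organelle
  complexes) sum member lengths and counts against the same genome-wide
  *L*.

The strict lower-tail convention P(X < k) = Σ<sub>j&lt;k</sub> Pr(X = j)
is used throughout; the candidate criterion is its complement
P(X ≥ k) < α/m. The boundary case (mass exactly at k) is resolved by the
strict form; at realistic *n* the distinction never changes a call.

## Numerical evaluation

All probabilities are computed in log space:
log Pr(X = k) = log C(n,k) + k·log p + (n−k)·log(1−p), with
log-factorials from the Stirling asymptotic series
(n+½)log n − n + ½log 2π + 1/(12n) − 1/(360n³) + 1/(1260n⁵) and an exact
table below n = 64 (where the series is weakest and exact values are
cheap). The series meets 1e-10 relative accuracy across [1, 1e7]; the
test suite checks this on a log-spaced grid against exact big-integer
factorials and lgamma.

Tail sums use log-sum-exp. When k exceeds the mean n·p — the regime of
every interesting candidate — the upper tail is summed **directly** from
j = k upward, truncating once terms fall 40 log-units below the running
maximum (relative contribution < 1e-17); computing 1 − P(X < k) there
would cancel to exactly zero in double precision. Below the mean the
complement of the lower tail is well-conditioned and is used instead.
The suite cross-checks both tails against 60-digit decimal direct
summation and scipy's independent incomplete-beta implementation.

## Coordinate mapping

Genomic positions are converted to protein residues through the spliced,
strand-oriented CDS of one canonical transcript per gene: the 1-based
CDS offset of the position gives residue ⌈offset/3⌉. Positions outside
the CDS map to nothing (a valid result, not an error). Indels are
assigned to the residue containing their start position — a single-point
rule that keeps counts well defined when an indel spans a domain
boundary. Variant classes are trusted from the input table; consequence
calling from alleles is out of scope. Synonymous mutations and records
that do not map to a residue are removed before any counting.

## Coverage, specificity, overlap

* **Coverage** of a domain in a cohort: percent of patients with ≥ 1
  mutation inside any of its occurrences. Cumulative coverage of a
  domain set is the union over patients, never the sum.
* A candidate domain is **specific** to a cancer type when no other
  individual cancer type also flags it; the pan-cancer cohort is a
  union, not a disease, and is excluded from the exclusivity count.
* A protein is a **specific protein** of a cancer type when it carries
  at least one mutated candidate domain there and every candidate domain
  annotated on it is specific to that type.
* **Pfam-vs-CATH overlap** per protein: each source's occurrences are
  merged into a union of disjoint residue intervals; the two unions are
  intersected; the intersection length is reported as a percent of each
  union (rounded half-up for display, raw ratios kept). Union-then-
  intersect is the only reading under which nested occurrences (such as
  a CATH superfamily at residues 1–176 containing another at 102–176) are
  not double-counted. Averages over proteins are unweighted
  (protein-weighted); a length-weighted mean is the obvious alternative
  but would let a handful of huge multidomain proteins dominate.

## Synthetic data

The generator emulates the statistical structure of a multi-cancer
exome study at desk scale: genes laid end to end on one synthetic
chromosome with fixed 100-nt intergenic gaps and 30–90-nt introns,
exon lengths in whole codons (so every CDS is a whole number of
codons), Pfam-style and CATH-style domain ids placed 1–3 times each on
random proteins, and per-patient mutation counts drawn Poisson.
Background mutations are uniform over coding positions; planted
enrichment multiplies the per-position mass inside a chosen domain's
occurrences by a fold factor (rejection-free mixture, so the fold is
controlled exactly; folds multiply where planted domains overlap).
Variant class is Bernoulli with 25 % synonymous by default — enough
material for the synonymous filter to remove. Defaults (4 cancer types,
50 patients per type, Poisson mean 20 mutations per patient, 200 genes)
are one deliberate desk-scale choice; error-control and recovery suites
instead use the configurations stated with those checks (e.g. 1000
regions of 100 residues, L = 1e5, ≈ 5000 in-universe mutations,
100-fold enrichment; 200 null families of 50 regions × 3 cohorts).

What the generator does **not** emulate: trinucleotide mutational
signatures, regional mutation-rate covariates (replication timing,
expression), germline variation, copy number, multiple isoforms, or
real domain architecture. Passing tests therefore demonstrate the
statistical machinery — error control, power against planted folds,
bookkeeping — under the model's own assumptions, not robustness to the
rate heterogeneity of real tumor genomes, where a uniform background is
known to be anticonservative.

`sample_region_counts` draws per-region hit counts directly as a
multinomial over (length × fold) mass. Uniform placement followed by
domain assignment induces exactly this distribution, so the FWER and
recovery suites use it to avoid materialising positions; the full
position-level path is exercised end-to-end separately.

## Degenerate inputs and tie-breaks

* k = 0 gives P(X ≥ k) = 1: never a candidate.
* A single-domain universe has l = L, p = 1, forcing k = n and
  P(X ≥ k) = 1: degenerate, never a candidate.
* Empty cohorts and empty mutation tables produce empty result tables
  and a warning, not an error; an empty patient set makes coverage
  undefined and raises.
* Genes absent from the models are skipped with a counted warning
  during domain assignment, and raise when explicitly requested in a
  gene universe.

## Known limitations

* One transcript per gene; isoform choice is upstream.
* The uniform background is the model's central simplification; on real
  cohorts it overstates significance in late-replicating, lowly
  expressed regions.
* Gene-level and domain-level families are corrected separately, as in
  the underlying design; no correction spans both.
* The external causal-list comparison and the bipartite export are
  bookkeeping over the candidate sets; protein-interaction enrichment
  and impact annotation belong to external services and are not
  computed here beyond exporting protein lists.
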