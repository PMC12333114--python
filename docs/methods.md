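# Methods

## The chromosome-quotient model

`cqscan` locates hemizygous, male-specific sequence — a candidate
male-determining (M) locus — from whole-genome sequencing of pooled males
and pooled females aligned to the same reference.  The reference is tiled
with contiguous windows (default 500 bp, half-open coordinates, the final
window of a chromosome may be short), and each window S receives the
chromosome quotient

    CQ_S = F_S / (M_S + c)

where F_S and M_S are the female and male read counts attributed to S
(each read to the window containing its leftmost aligned base) and
c = 0.01 is a pseudocount that keeps the quotient finite on male-only
sequence.  With balanced sequencing depth, autosomal windows concentrate
near CQ = 1; sequence present on only the male-carried homolog draws
essentially no female reads and collapses toward CQ = 0.

Windows are classified as:

| class | rule |
|---|---|
| `male_biased` | CQ ≤ 0.05 (at least a ~20-fold male excess) |
| `grey` | 0.05 < CQ ≤ 0.50 |
| `unbiased` | CQ > 0.50 |
| `filtered_low_male` | M_S ≤ 20 (no CQ computed) |
| `filtered_masked` | masked fraction ≥ `masked_exclude_fraction` (no CQ) |

The male-hit filter is strict (a window with exactly 20 male hits is
excluded), so every reported CQ rests on real alignment signal.  The
male-bias bound is inclusive by default (`male_bias_inclusive=True`):
the boundary value 0.05 corresponds exactly to F=1 against M=20, i.e.
the 20-fold correspondence, and the inclusive rule defines the plotted
male-biased set that delimits the locus.  An exclusive variant is a
config switch.

Calibration (`calibrate`) summarises mean and median CQ per autosome
over all retained windows (including the `unbiased` class — "ignored" is
a display decision, not an exclusion from statistics) and flags
`near_one` when both lie within ±0.2 of 1.  When they do not,
`CQConfig(normalize=True)` rescales CQ by total-male / total-female
mapped counts.  Normalisation is off by default: balanced libraries need
none, and an unconditional rescale would silently absorb genuine global
asymmetries.

The M-locus call is the minimal interval covering every male-biased
window on the target chromosome.  An optional `max_outlier_distance`
prunes male-biased windows isolated from the largest cluster — an
extension for noisy or synthetic data, off by default so the span is
exactly the male-biased span.

## Repeat contrast

`repeat_fraction` measures the merged (overlap-collapsed) coverage of a
region by annotation intervals matching a label; a label matches the
repeat class, the family, or the full `class/family` string.  Merging
first makes the measure invariant under splitting annotation records.
`repeat_contrast` reports, per label, the fraction inside the locus, the
genome-wide fraction and their ratio (enrichment, undefined and flagged
when the background is zero).  The genome-wide background includes the
locus itself by default, matching the usual "x% genome-wide" phrasing;
`include_locus_in_background=False` excludes it.

RepeatMasker `.out` files are parsed with the whitespace dialect and its
three header lines; 1-based inclusive coordinates become 0-based
half-open and the complement marker `C` becomes `-`.

## EVE refinement

The endogenous-viral-element arm consumes two precomputed translated
homology tables — a forward search of the genome against viral proteins
and a reciprocal search of extracted candidate regions against a broad
protein database — in extended outfmt-6 (the 12 standard columns plus
subject species/family/superkingdom).  It never runs searches itself,
so database-version-dependent absolute counts are out of scope.

1. **Load & filter**: rows with e-value > 1e-6 are dropped; reversed
   query coordinates are swapped and recorded as minus strand.
2. **Cluster**: hits overlapping or book-ended on one chromosome form a
   cluster (transitive closure; bedtools-merge default semantics, i.e.
   a gap of ≥ 1 bp separates).  The upstream convention is plain
   sort-and-merge BED processing with no distance flag, hence
   distance 0.
3. **Best hit**: highest bitscore; ties broken by lowest e-value, then
   longest alignment, then lexicographic subject id, making the result
   order-invariant.
4. **Reciprocal filter**: a candidate whose best reciprocal hit is
   non-viral is a host-derived false positive (`rejected_host`); best
   viral hit confirms.  "Best hit non-viral ⇒ reject" was chosen over
   "any eukaryotic hit rejects", which would discard genuine EVEs with
   incidental low-scoring host similarity; the policy for candidates
   with no reciprocal row is configurable and defaults to reject.
5. **Join**: confirmed integrations on the same chromosome from the
   same viral species with gap `start₂ − end₁` strictly below 100 bp
   are joined transitively (gap 99 joins, gap 100 does not); the joined
   record spans all members and inherits the highest-bitscore hit.
   Joining is idempotent.
6. **Family assignment & summary**: each integration takes the family
   of its best hit's species from the taxonomy map, `unclassified` when
   absent — so the classified/unclassified split reflects taxonomy-map
   completeness, which is exactly how it arises in practice.  The
   summary reports per-family counts, total bp and min/median/max span
   (even-count median = mean of the central pair).

## The synthetic-data generator

`simulate` emulates the statistical structure the analyses assume, at
window level, not read level: the statistic consumes per-window counts,
so read-level simulation would add cost without test power.

* **Genome**: configurable chromosome lengths; the default test genomes
  use two autosomes plus one sex chromosome with a window-aligned
  planted M locus.
* **Counts**: independent Poisson draws per window and sex.  The default
  depth is 100 reads per sex per 500-bp window, the balanced ~100×/100×
  short-read design of the study the package models.  Inside the locus
  the female mean drops to `female_leak_rate` (default 0 — the residual
  female coverage of a real M locus is unreported, so perfect
  hemizygosity is the default and leak is an explicit parameter).  The
  Poisson mean scales linearly with window length and unmasked fraction
  (masked reference attracts no alignments; partial overlap reduces
  alignment opportunity linearly).
* **Repeats**: per family, intervals of uniform length 200–1500 bp are
  drawn until the merged coverage meets the target density, separately
  inside the locus (locus density) and outside (genome density);
  realised densities converge within ±0.02 at the 10-Mb scale.
* **Viral hits**: each planted integration is 1–3 fragments with gaps
  drawn from [20, 99] bp (strictly below the join distance, so ground
  truth is one joined integration per plant); each fragment carries one
  spanning hit plus 0–2 overlapping weaker same-species hits.  Host
  false positives are isolated forward hits whose best reciprocal hit
  is a eukaryotic protein (with a weaker viral reciprocal hit included
  to exercise best-hit selection).  Plants are spaced ≥ 500 bp apart so
  distinct integrations never join.
* **Determinism**: all draws flow from one seed through named child
  streams (`layout` / `counts` / `viral` via CRC-derived child keys), so
  enabling one component never perturbs another and identical configs
  give byte-identical files.

What the generator does **not** model: read-level artefacts (sequencing
error, mapping quality, multi-mapping, GC bias), over-dispersion beyond
Poisson, correlated coverage along the chromosome, and reference
assembly error.  Passing tests therefore demonstrate correctness of the
statistics and procedures under the stated count model, not robustness
to every real-data pathology; on real data the masking step and the
male-hit filter carry that burden.

## Numerical and interface choices

* Coordinates are 0-based half-open everywhere internally and in files;
  locus reports add 1-based inclusive companion fields.
* CQ is computed in double precision; against exact rational arithmetic
  (CQ = 100F/(100M+1) for the default pseudocount) the relative error
  is ≤ 1e-12 (checked over 10⁶ random pairs).
* Reads are attributed to the window containing the leftmost aligned
  base — totals are conserved and boundary behaviour is exact.  Only
  primary mapped alignments count; MAPQ threshold defaults to 0 since
  repetitive mis-hits are controlled by masking upstream.
* Problem sizes in the test and acceptance suites (genomes of 1–10 Mb,
  1000-window calibrations, 20-seed recovery sweeps, 10⁶-pair oracle
  checks) were chosen as the smallest scales at which the stochastic
  properties are comfortably resolved.

## Known limitations

* The count-ingestion path trusts the (chrom, start, end) keys of a
  precomputed table; a table windowed at a different size silently
  yields zero-filled windows rather than an error.
* `call_locus` assumes a single locus per chromosome; two genuine
  distant loci would be spanned (default) or the smaller one reported
  as outliers (with pruning on).
* Frame information of translated searches is reduced to a strand flag
  derived from coordinate orientation.
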