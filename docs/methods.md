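# Methods

This note records the statistical conventions, simulation model and
design choices behind `asmeval`, in the spirit of a package vignette:
what is computed, under which assumptions, and what the synthetic
validation does and does not demonstrate about real data.

## Contiguity statistics

All length statistics are computed on the record set remaining after a
minimum-length filter, strict `>1000` bp by default (an `inclusive`
flag switches to `≥` for comparison against tools that filter that
way).  Both the numerator and denominator of "% of genome in ≥25 kb
scaffolds" use the filtered set, so the quantity is a property of the
reported assembly, not of discarded debris.  The 25 kb default
approximates the average vertebrate gene length; threshold counts
(defaults 100 kb, 1 Mb, 39 Mb — the last a chromosome-scale marker for
a mid-sized mammalian karyotype) use strict `>`.

**Nx convention.**  Sort lengths descending, accumulate, and return the
element at which the running sum first reaches x% of the total (the
Assemblathon convention).  The returned value is always a member of the
length set; an exact-half tie resolves to the element that achieves the
bound.  Nx is non-increasing in x, so N90 ≤ N50 always.

**Contig breaking.**  Scaffolds are split at every maximal run of
≥25 consecutive N (case-insensitive; ambiguity codes are normalised to
N on load precisely so that gap detection cannot miss masked or
lower-case gaps).  Sub-threshold N runs stay inside contigs.  Contigs
produced by splitting are *not* re-filtered at 1 kb before contig N50
(a `refilter_contigs` flag enables it); splitting is idempotent.

**Fold changes** are reported rounded half-up to one decimal, the
convention used for the printed values they summarise.

## Accuracy model

The error-free criterion is per-base coverage ≥5 by perfectly and
uniquely mapped reads.  This package does not map reads: coverage
tracks are ingested (per-base or BedGraph-like TSV) or simulated.

The breakpoint detector flags maximal runs of ≥`min_run` (default 100)
consecutive bases with coverage <`min_cov` (default 5).  This is a
declared simplification of fragment-coverage-distribution (FCD)
evaluators such as REAPR, which model the expected fragment depth
profile; `min_run=100` is a package default, not a value inferred from
any external tool.  FCD error counts and before/after sequence counts
from such a tool can be ingested and are carried through reports
unchanged, labelled as ingested.

Breaking drops the flagged interval content (the junction sequence is
the suspect part).  Because that shrinks the assembly total, the N50
of the broken set can exceed the original by a few bases even though
every fragment is no longer than its parent; `accuracy_report` clamps
broken N50 at the original (with a warning) to keep the invariant
`broken_n50 ≤ original_n50` that the downstream percent-reduction and
summary-score formulas assume.  Percent reduction is rounded half-up to
an integer.  Excess breaks relative to a baseline may be negative when
scaffolding merges sequences; that is a warning, not an error.

## k-mer spectra

Canonical counting (each k-mer folded to the lexicographic minimum of
itself and its reverse complement) at k=31 by default; windows
containing non-ACGT characters are skipped, so N runs partition
sequences into independent stretches.  The comparison spectrum is the
joint histogram of distinct read k-mers over assembly copy number
d ∈ {0..10} and read multiplicity m ∈ {1..200}; both axes clip into
their final bucket rather than dropping mass, matching how spectra
plots clip axes.  "Solid" read content missing from the assembly is the
d=0 mass at m ≥ 3; the value 3 is a package default for the
error/genuine boundary, which in real data depends on coverage and
error rate and is therefore exposed as a parameter.  Counting is plain
in-memory hashing; the contract is desk-scale input (tens of Mb), not
whole-lane counting.

## Completeness and repeats

Ortholog status tables use the conventional four categories; "Complete"
maps to `single`.  Percentages round half-up to integers, so the four
percentages of one table can sum to 100 ± small rounding slack.
Cross-assembly intersections require a shared ortholog-id universe.

Repeat summaries compute the percent masked from the union of hit
intervals per sequence; per-class percentages use independent per-class
unions, so overlapping annotations can make class percentages sum above
the total masked percentage (the behaviour of standard repeat-annotation
summaries).  Mean divergence is the unweighted mean over hits of
`mismatches/(matches+mismatches)` (a `length_weighted` flag is
provided); stored as a fraction, displayed ×100.  When a tool-reported
percent-divergence column is present in ingested tables it takes
precedence over the matches/mismatches ratio.

## Ranking

Rank scores use tie-average ranking (via `scipy.stats.rankdata`), so
each metric's scores always sum to n(n+1)/2.  z-scores use the sample
(n−1) standard deviation by default (a population-sd flag exists); a
zero-spread metric standardises to all zeros with a warning and simply
stops contributing.  Leave-one-metric-out bounds are the min and max of
the cumulative score over dropping each single metric; note the
interval need not bracket the cumulative point (dropping a metric can
only raise the sum of a uniformly negative row), which is why the plot
draws a min–max segment rather than symmetric error bars.  Rank totals
are invariant to monotone rescaling of any metric; z totals are not —
the reason both orderings are reported.

Costs must be supplied explicitly (YAML: per-data-type USD plus fixed
overhead).  The shipped examples use placeholder prices; no real
project costs are bundled.  How shared data types are apportioned
across assemblies is a per-run modelling decision the config must make
explicit.

## Synthetic-data model

The generator plants known truth at every stage:

* **Genome** — IID bases at a target GC (default 0.42, mammal-like).
  No repeats, no heterozygosity.
* **Assembly** — the genome is cut into contigs (uniform lengths,
  [0.5, 1.5]× the mean, default mean 5 kb) and re-joined into scaffolds
  (default 8 contigs) with N-gap runs uniform on [25, 500] so every
  join is visible to contig breaking (a sub-25 mode tests the unbroken
  branch).  A misassembly is an incorrect join — a non-adjacent or
  cross-chromosome contig spliced in — either at an exact planted count
  (spread sequential-uniformly over join opportunities) or per-join
  Bernoulli.  Scaffolds never cross a chromosome boundary except
  through a planted error, and a scaffold ends one contig after a
  splice, so planted junctions sit at least half a fragment from each
  other and from scaffold ends.  Every junction is recorded in a truth
  table with its realized correctness.  Inversions and indels are out
  of scope: an incorrect join is the minimal structure the
  break-accounting machinery exercises.
* **Coverage** — Poisson around the mean (default 30×) everywhere,
  collapsed to zero within ±200 bp of each incorrect join.  Gap (N)
  bases receive the same Poisson coverage as sequence: real
  perfect-unique coverage over Ns would be zero, but the informative
  signal being emulated is the collapse at bad joins, and zero-coverage
  gaps would turn every ≥100 bp gap into a false breakpoint.  At 30×,
  P(coverage < 5) ≈ 6×10⁻⁹ per base, so a false 100-base dropout run is
  effectively impossible — which is what makes exact break recovery a
  sharp test of the detector rather than of luck.
* **Reads** — uniform single-end reads with IID substitution errors;
  read placements are drawn before error draws so the same seed gives
  the same layout at any error rate.
* **Status/repeat tables** — per-ortholog categorical draws with a
  per-assembly single-copy probability (the remainder split 20/40/40
  over duplicated/fragmented/missing); repeat hits with
  Beta-distributed divergences around a target mean.

**Gradient study.**  Five assemblies of one 400 kb genome (2 × 200 kb
chromosomes) with strictly improving conditions: mean fragment length
(3, 4.5, 7, 11, 18 kb), misassembly rate (0.25 → 0.015) and single-copy
probability (0.90 → 0.975, the range seen in practice for draft mammal
assemblies).  All five share one provenance and cost, so the
value-for-money metric is a scaled broken N50; real studies would vary
costs per strategy, which the config supports.  Validation runs 100
seeded replicates and requires the cumulative-z ordering to match the
planted order in ≥95; break recovery runs 50 seeded replicates with
k ∈ {1..20} planted errors on 1 Mb genomes and requires exact recovery
in all of them.  These sizes were chosen as the smallest at which the
planted effects dominate sampling noise by a comfortable margin.

**What passing does not show.**  The simulated genome is repeat-free
and haploid, coverage noise is independent Poisson, and misassemblies
are clean joins with total signal collapse.  Real assemblies fail in
correlated ways — repeat-driven collapses, heterozygosity-driven
duplications, partial coverage dips — that this generator does not
emulate.  The synthetic validation demonstrates that the accounting,
detection and ranking machinery is correct, not that the simplified
dropout detector matches an FCD evaluator on real data; for real
studies, ingest the evaluator's outputs.

## Numerical conventions

Half-up rounding (`decimal`) wherever integer or one-decimal
percentages are reported, because the printed conventions these mirror
round half-up; float `round()` would round half-even.  Coordinates are
0-based half-open everywhere internally.  Degenerate inputs (empty
assemblies after filtering, empty length sets, zero costs, mismatched
track lengths) raise typed errors (`ConfigError`, `InputError`,
`ConsistencyError`) that the CLI maps to distinct exit codes; empty
FASTA files load as empty assemblies with a warning, since an empty
candidate is a data problem, not a usage error.
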