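# Methods

## Model and procedure

The pipeline treats the genome purely as coordinate space. A *locus* is a
half-open interval `[start, end)` on a named chromosome with a strand, an
E-value and the identifier of the matching reference element. Loci come
from two sources:

* **BLAST tabular (outfmt 6)** hits of reference HERV elements against the
  genome, with the genome as BLAST subject. Subject coordinates are 1-based
  inclusive and are converted to 0-based half-open; `sstart > send` marks a
  minus-strand hit, `sstart == send` a valid 1-bp locus. Hits are retained
  up to an inclusive E-value ceiling (default 1e-10, the threshold used to
  build HERV-similarity databases).
* **RepeatMasker `.out`** rows whose repeat class starts with a prefix
  (default `LTR`). RepeatMasker reports no E-value, so these loci carry
  `evalue = 0` and pass every E-value ceiling — they are an alternative
  locus source, not an E-value-bearing one. Strand `C` maps to minus.

Loci go into a per-chromosome interval tree. The tree is an implementation
detail: by contract, any query result equals a brute-force linear scan
under the same predicate, and the test suite enforces this with an
independently coded oracle. Duplicate hits are kept as distinct records —
the report lists every stored hit with its own E-value, and merging
overlapping hits from different reference elements would silently change
the statistics.

A *neighborhood query* takes a region and a predicate `(max_distance,
max_evalue, min_length, max_length)`. The distance between a region and a
locus is the gap between nearest edges, `max(0, locus.start − region.end,
region.start − locus.end)`: 0 means overlapping or abutting. All
comparisons are inclusive; strand never enters the distance; both strands
are always searched. A chromosome absent from the store yields an empty
result, not an error.

The *quantile fold-change filter* declares a probe set up-regulated when
its median signal in the first group is at least `fold` (default 10) times
the 75th percentile of the second group, and symmetrically for
down-regulation. Quantiles interpolate linearly between order statistics
(the numpy default; the rule's original software does not pin down a
definition, and the configurable quantiles make the choice explicit). A
zero denominator passes iff the numerator is positive, so all-zero probes
never pass; with `fold > 1` this makes the up and down sets provably
disjoint. Signals are used raw: no log transform, no multiple-testing
correction — the filter is deliberately a plain ratio rule.

Probe sets are mapped to coordinates through a TSV table; unmapped probes
are counted and excluded, and **all association percentages use the mapped
regions as denominator**.

Association curves evaluate the associated fraction of an up and a down
region set over a strictly increasing grid of distances (default 1 bp to
10 kb, 17 log-spaced points) or E-value ceilings. The per-point ratio
f_up/f_down is reported as missing (NaN in memory, `.` in TSV) when
f_down = 0, never as infinity, so downstream files stay finite. The random
baseline samples probe sets without replacement from the mapped population
under a fixed seed.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| build `max_evalue` | 1e-10 | ceiling for ingesting BLAST hits (bp-free) |
| query `max_distance` | 1000 bp | largest allowed edge gap; 1 kb is a compromise between the ~200 bp scale at which regulatory enrichment tends to peak and the saturation regime |
| query `max_evalue` | ∞ | inclusive ceiling; 1e-100 restricts to near-identical HERV copies, 1e-10 admits diverged ones |
| `min_length`/`max_length` | none | stored-locus length bounds in bp |
| filter `fold` | 10 | ratio threshold k (must exceed 1) |
| filter quantiles | 0.50 / 0.75 | numerator (median) and denominator quantiles |
| distance grid | 1–10,000 bp | sweep range; fractions provably reach 100% and the ratio 1.0 once the distance covers the chromosomes, so wider grids add nothing |

## Synthetic data: what it emulates, what it does not

`SimParams` defaults describe a small but structurally realistic study: a
4.5 Mb genome in three chromosomes; 250 loci with log-uniform lengths on
300–7,000 bp (solo LTRs up to near-complete proviruses) and E-value
exponents uniform on [−200, −10], matching the range the store and query
ceilings operate in; 2,000 probe sets per region set with a 120 bp
footprint; and 5 vs 11 samples, echoing a small case group against a
larger normal panel.

Enrichment is planted geometrically: a fraction π of a probe population is
placed at a gap drawn uniformly on [D/2, 3D/2] from a random locus
(defaults π_up = 0.5, π_down = 0.05, D = 200 bp); the remainder is uniform.
The narrow gap distribution makes the ratio-curve peak identifiable; with a
target offset of 200 bp the recovered peak is expected within a factor of
two (100–400 bp), because background loci near planted probes and the
discreteness of the grid shift the argmax. Expression is log-normal
(baseline mean log 5, noise sigma 0.4 on the log scale) with a
multiplicative effect of 50 on the planted population in its group; 50 sits
far enough above the fold threshold of 10 that recovery is essentially
complete at these sample sizes.

The generator does **not** simulate sequence content, BLAST score
statistics, probe chemistry, cross-hybridization, correlated noise between
samples, chromosome-scale features (centromeres, gene deserts), or the
>10⁸-hit scale of a real HERV-similarity database. Passing tests therefore
demonstrate the correctness of the arithmetic, the filters and the
statistics, and identifiability under the planted model — not biological
conclusions about real arrays or genomes.

## Numerical and design choices

* Coordinates are internally 0-based half-open; BED is taken as-is, BLAST
  tabular and RepeatMasker are converted from 1-based inclusive.
* All threshold comparisons (E-value, distance, fold change) are inclusive;
  "at least k times" reads literally as ≥.
* Query results are sorted by (gap, locus start, locus end, source id) so
  outputs are byte-reproducible.
* Sweep grids must be strictly increasing and nonempty; a single-point grid
  is allowed.
* The pipeline is deterministic given its config: the only randomness (the
  baseline sample) derives from the config seed, and a rerun produces
  byte-identical outputs.
* Degenerate inputs: empty region lists are an error for fractions (a
  proportion of nothing is meaningless); empty stores are valid and yield
  fraction 0; `sstart == send` BLAST hits are 1-bp loci.
* Problem sizes in the test suite (hundreds of loci, a few thousand probe
  sets, 100-instance oracle sweeps) were chosen so each property is checked
  at a scale where its statistics are stable while the whole suite runs in
  seconds.

## Known limitations

* The store is in-memory; it is meant for catalogues up to a few million
  loci, not the >4×10⁸ hits of a full-genome HERV-similarity database
  (which motivated a dedicated disk-based store in the original web
  server — out of scope here).
* No statistical significance is attached to the enrichment curves; the
  pipeline reports raw fractions and ratios, with the random baseline as
  the calibration reference.
* The filter assumes exactly two groups and nonnegative intensity-scale
  signals; count data (RNA-seq) should be normalized before use.
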