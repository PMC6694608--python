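# Methods

## Statistics model

Each FASTQ file is summarized by an exact-integer accumulator over its
records: read count, base count, length min/max/sum, summed decoded Phred
scores, and the count of high-quality bases. A base is high quality when
its decoded score is **strictly greater** than the threshold Q (default
25, i.e. error probability below 10^-2.5); an inclusive (`>=`) mode is
available as a flag. Derived metrics are ratios of tallies: mean length =
len_sum / n_reads, mean quality = qual_sum / n_bases, hq% = 100 ·
hq_bases / n_bases. Quality encoding defaults to Phred+33 (the universal
modern Illumina convention) with a Phred+64 option; a quality character
below the declared offset is a hard error rather than a clamped value.

Accumulators form a commutative monoid under componentwise merge (sums
add, min/max combine, the empty accumulator is the identity), with one
guard: accumulators computed under different Q cannot be merged, since
their high-quality tallies are not comparable. This merge law is the load-
bearing design choice — it makes segment-parallel execution provably
equivalent to a serial pass, which the test suite checks directly
(segmentation independence over random record-aligned splits, worker-count
invariance of the executor).

Malformed input (length mismatch, missing `+` separator, truncated final
record) is a hard per-file error naming the record ordinal; a QC tool must
not silently truncate corrupt data. Failures are isolated per file: one
corrupt file costs only its own result.

## Allocation planning

Inputs: F files with byte sizes, C cores, M bytes of memory, and
`max_core` (default 55) — the per-file core count beyond which parallel
overhead outweighs the added cores.

* **Iterations.** F > C: floor(F/C) groups of exactly C files (one core
  each) followed by a remainder group; F <= C: a single group with the
  cores divided as evenly as possible (counts differ by at most one before
  the `max_core` cap). Files are ordered lexicographically by path so
  plans are deterministic; the grouping does not attempt size balancing.
* **Passes.** If a group's total bytes exceed M, each pass processes the
  fraction f = M / total of every file — so one pass over the whole group
  fills memory exactly — for floor(1/f) full passes plus one remainder
  pass of 1 − floor(1/f)·f. Fractions are exact rationals
  (`fractions.Fraction`) over byte counts; floating point would break the
  sum-to-1 and never-exceed-M invariants. The remainder pass is kept as a
  distinct final pass (the greedy rule) rather than rebalanced into equal
  passes.
* **Policy.** When both cores and memory are limited the composition above
  yields one core per file with splits, which empirically beats multi-core
  whole-file reads: file-split overhead is smaller than core-assignment
  overhead.
* Heterogeneous sizes are handled by planning passes from each
  iteration's actual total bytes; every file contributes the same fraction
  of its own size per pass, degenerating to the uniform-size rule when
  sizes are equal. Gzip files use their compressed on-disk size as the
  memory proxy — the decompressed size is unknown without a full scan, so
  this is conservative only in expectation (documented limitation).

## Execution

Pass fractions are realized as byte budgets rounded down to record
boundaries (a segment never splits a 4-line record; budgets are advanced
to the next record start, since a `@` may legitimately begin a quality
line and content alone cannot identify record starts). The final pass
absorbs rounding remainders. A file assigned k cores is further cut into k
contiguous record chunks per pass, balanced by record count. Plain files
are read by byte range; gzip files cannot be random-accessed, so their
units carry record-count ranges and workers stream from the file start.
Workers own disjoint units and return immutable partial accumulators;
assembly is a pure fold in fixed (file, pass, chunk) order, so the result
is byte-identical for any worker budget and completion order — there is no
shared mutable state to lock. Pass p+1 I/O is not overlapped with pass p
computation.

Parallel efficiency is reported as PG = t1 / (C · tC); PG = 1 is ideal
C-fold speedup.

## Aggregation and comparison

Lanes merge into samples per (dataset, sample, mate); mates are never
merged across R1/R2. Experiment level is computed at lane resolution
(pooled over lane units) and sample resolution (pooled over sample
units); the pooled tallies coincide by associativity, while the attached
dispersion summaries — unweighted mean and population standard deviation
of each derived metric — average over lane units versus sample units and
differ under unbalanced designs.

Two datasets covering identical (sample, mate, lane) key sets are
compared per metric; unmatched units are warned about and excluded. The
difference is relative by default, 100·(B−A)/A with dataset A the
baseline and NA on a zero baseline; an absolute mode (plain difference,
percentage points for percent metrics) is provided because a difference
shown on a secondary chart axis is readable either way.

## Flagging

Per metric, units are standardized within their peer group — all units of
the same dataset, mate, and level — using the population standard
deviation (divisor n): the peer group *is* the complete population of
units in the experiment. The unit's own value stays in the group mean and
deviation (no leave-one-out). |z| > cutoff (default 1.5) flags the unit.
Groups with fewer than 3 units or zero deviation yield undefined z and no
flags. Flagged metrics: read count, mean length, mean quality, hq% — one
summary per statistic family. No multiple-testing correction and no
robust (MAD-type) variant: plain z-scores are the contract, and with a
1.5σ cutoff occasional flags among perfectly healthy peers are expected
false positives, visible in the README example.

## Synthetic data generator

Emulates the shape of a multi-lane Illumina experiment at desk scale:
defaults of 2 samples × 4 lanes × paired-end, 500 reads per lane at 75 bp
(the reference workload is 10^7 reads at ~75 bp; tests stay under 10^5
reads total), quality mean 30 / sd 3 on integer Phred scores obtained by
rounding a normal and clipping to [0, 41], bases uniform over ACGT. Each
(sample, lane, mate) unit derives its own seed stream from the dataset
seed and the unit labels, so the same spec and seed reproduce
byte-identical files (gzip members are written with mtime=0) and
regenerating one unit with a shifted quality mean — the outlier-injection
hook — leaves every other file untouched.

The generator does **not** model per-cycle quality decay, adapter or
k-mer content, GC bias, or indel error profiles. Passing tests therefore
demonstrate the correctness of the bookkeeping, planning, merging, and
flagging machinery on well-formed data of realistic shape — not robustness
to real-instrument artifacts, which per-position profilers (FastQC
territory) address and this package deliberately does not.

## Numerical and interface choices

* Planner arithmetic is exact (integers and rationals); statistics are
  exact integer tallies, so every cross-route equality in the tests is
  bit-exact, not approximate.
* TSV output is byte-deterministic: fixed column order, rows sorted by
  (level, dataset, sample, mate, lane), counts as integers, fractional
  values to two decimals, undefined values as `NA`.
* Input discovery uses the folder convention
  `<dir>/<sample>/<sample>_L<lane>_R<1|2>.fastq[.gz]` (single-end files
  omit `_R<n>`); unrecognized names warn and are skipped, duplicate unit
  keys are an error.
* Resource probing reads `os.cpu_count()` and `/proc/meminfo`
  (MemAvailable), with explicit `--cores` / `--memory` overrides winning
  and a (1 core, 1 GB) fallback when probing fails.
* The acceptance script evaluates the planner on the three canonical
  configurations (30 files/100 cores/128 GB; 250/40/128 GB;
  250/100/60 GB with 2 GB files) and the PG definition; these are
  closed-form plan reads, so problem size is the configuration itself.
  Its pipeline self-check uses 2 samples × 4 lanes × 200 single-end reads
  of 75 bp.

## Known limitations

* No dynamic re-planning mid-run, NUMA placement, or multi-node
  scheduling.
* Compressed inputs are streamed serially per worker from the file start;
  for deep splits of large gzip files this repeats decompression work.
* Experiment-level z-flagging across more than two datasets is not
  defined (input is capped at two datasets).
* Wall-clock performance claims are hardware-dependent and are not
  asserted anywhere; only the algebraic PG definition is.
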