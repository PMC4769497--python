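# Methods

## Data model and FAST5 dialect

`poremap` targets the classic 2014–2016 single-read FAST5 layout: one
HDF5 file per sequencer read, basecalls under
`/Analyses/Basecall_2D_<NNN>/BaseCalled_{template,complement,2D}` (a
`Fastq` string dataset holding a standard 4-line Phred+33 record, and an
`Events` compound dataset with `mean, stdv, start, length, model_state,
move` columns), channel attributes under `/UniqueGlobalKey/channel_id`
and run metadata under `/UniqueGlobalKey/tracking_id`. Multi-read FAST5
(post-2017) and POD5 are out of scope, as is any interpretation of the
basecaller's HMM model tables — those travel through the archive as
opaque bytes.

Files often contain several `Basecall_*` groups from re-basecalling; the
reader takes the highest numeric suffix as the most recent, with an
explicit `analysis_group` override. The read start time is taken from the
`start_time` attribute (in samples at the channel's sampling rate) of the
event-detection read group, falling back to the first event's start; a
missing `run_id` degrades to the literal run key `unknown_run` rather
than failing, so statistics never lose files over absent metadata. A 2D
read without a template violates the chemistry (2D is the combination of
both strands) but is accepted with a warning. Parsing is total: any
input, however corrupt, produces either a parsed record, a format error,
or an uncalled/unrecognized error — never an unhandled crash.

`read_fast5(..., load_events=False)` skips decoding event tables; the
sequence-level statistics never touch events and the tables dominate
both file size and parse time.

## Archive format

The archive is a portable re-implementation of a sorted, indexed
key-value sequence file. Two files, all integers little-endian and
unsigned: `<name>.data` is `"NPKV"`, u16 version, u8 codec (0 = none,
1 = deflate), then per record `u32 key_len | key | u64 raw_len |
u64 stored_len | value`; `<name>.index` is `"NPKI"`, u16 version,
u64 record_count, then sorted entries `u32 key_len | key | u64 offset |
u64 stored_len | u64 raw_len`. Design choices:

* **keys are import-root-relative paths** (`/` separators), which keeps
  identical basenames in different subfolders unique without renaming;
* **compression is per-record deflate**, preserving random access by key
  (whole-file compression would not);
* **the format contains no timestamps**, so importing the same folder
  twice is byte-identical — archives are reproducible artifacts;
* archives are **write-once**; there is no append or delete.

Lookup is a binary search over the in-memory index (≤ ⌈log₂ n⌉ + 1
probes); scans are restartable from any index position, which is what
lets workers take contiguous key ranges.

## Statistics

Every reported quantity derives from a per-read-type accumulator that
forms a commutative monoid under component-wise merge: counts,
nucleotide totals, min/max/sum of lengths, pooled base counts,
histograms, per-position profiles, per-channel tallies and a multiset of
(start-second, read-length) yield events. Definitions that upstream
tools disagree on, stated explicitly:

* **mean read quality** is the arithmetic mean of per-base Phred scores;
  the run-level figure is the mean over reads of per-read means (not the
  mean over all bases);
* **%GC** is 100·(G+C)/(A+C+G+T); N is excluded from numerator and
  denominator so no-calls do not bias composition. An all-N read has
  undefined GC; it contributes 0 to the GC histogram and is counted in a
  flag field;
* **histogram bins**: read length in 500-nt bins, per-read GC in 101
  integer-percent bins, read quality in width-1 bins of the rounded
  per-read mean;
* **yield** uses the experiment start as time origin and a 60 s default
  bin width; the curve is cumulative and its final value equals the
  nucleotide total by construction;
* per-position profiles are truncated at 10⁶ positions with an overflow
  tally, bounding memory against pathological lengths;
* files with no basecalls are counted as **uncalled** and reported as a
  separate summary line, never entering any read-type statistic.

Integer accumulators merge exactly, so partition invariance is exact for
them; the only floating-point sum whose value depends on merge order is
the per-read mean-quality total, which agrees across orders to ~1e-15
relative and is printed rounded (2 decimals in `summary.txt`, 4 in the
TSV dumps), giving byte-identical reports for every worker count in
practice. Per-position quality sums are sums of integers and therefore
exact in any order.

## Execution engine

Jobs are (map, merge, identity, workers) quadruples over an ordered
key-value stream. The source is materialized, split into contiguous
near-equal index ranges, and each range is folded in a separate process
(`fork` start method on POSIX); chunk results merge in chunk order, so
the final fold equals the sequential left fold whenever the merge is
associative — a property the test suite verifies rather than assumes.
Per-pair map failures are collected as (key, error) pairs and reported
alongside the result (with `pairs_processed + pairs_failed ==
pairs_seen`); a fail-fast switch converts the first failure into an
abort. The `--hadoop` flag of the original command line is retained as a
deprecated alias selecting this local pool; the `JobSpec` seam is where
a cluster backend would plug in.

## Synthetic data generator

The simulator emulates the on-disk shape of a small early-chemistry
MinION run, with every quantity a test might check drawn from a known
law:

| parameter | default | meaning |
|---|---|---|
| `length_median`, `length_sigma` | 1000 nt, 0.5 | log-normal read length, rounded, truncated to [1, 50 000] |
| `gc_fraction` | 0.5 | i.i.d. bases, P(G)=P(C)=gc/2 |
| `q0`, `quality_slope`, `quality_sd` | 12, −1/kb, 2 | per-base Phred ~ N(q0 + slope·pos/1000, sd), clipped [0, 40], rounded |
| `n_channels` | 512 | channel uniform over the flowcell |
| `run_duration` | 3600 s | read start uniform, drawn on the 5 kHz sample grid |
| `p_complement`, `p_2d` | 0.7, 0.5 | every read has a template; 2D requires the complement |
| `events_per_base` | 1.5 | events per basecalled strand; log-normal durations |
| `uncalled_fraction` | 0 | fraction of files written without basecalls |

The defaults give ~1.1 kb mean reads, mean quality ≈ 11.4 and a 2D rate
of 35%, in the range of early MinION chemistry. One seeded NumPy
generator drives everything and HDF5 timestamp tracking is disabled, so
identical config + seed reproduces the dataset byte-for-byte.
`expected_summary` provides closed-form recovery targets: the truncated
log-normal mean length (via normal CDFs), %GC = 100·g with binomial
standard error 100·√(g(1−g)/total bases), and mean quality
q0 + slope·(E[L]−1)/2000 with a standard error combining between-read
length variance and within-read noise. Quality expectations ignore the
[0, 40] clipping, negligible for profiles several sd inside the bounds.

What the simulator does **not** model: real pore-current physics, basecall
error profiles (sequences are i.i.d., not error-corrupted copies of a
genome), strand-consensus 2D reads (the 2D sequence is drawn
independently — no statistic here compares strands), channel death over
time, or multi-run folders from a single flowcell. Passing tests
therefore demonstrate correct accounting, merging, storage and
extraction on structurally faithful inputs — not robustness to every
dialect quirk of real basecaller output.

## Verification design

The test suite checks the pipeline against independent recomputation,
not against itself: a flat-list oracle recounts every summary number
from the generator manifest with plain Python; monoid laws
(commutativity, associativity, identity) are property-tested over ~200
randomized cases, exactly on integer fields; partition invariance is
asserted byte-for-byte on rendered reports across 1/2/4/8 workers;
archive round-trips compare raw bytes exhaustively; parameter recovery
uses 3-standard-error bounds from the closed forms (pooled %GC at
gc ∈ {0.3, 0.5, 0.7} with 500 reads of median 1 kb; quality slope via a
count-weighted least-squares fit over positions with ≥ 30 observations).
End-to-end checks run on seeded datasets of 50–1000 reads; the
acceptance script uses 400 reads, sizes at which binomial standard
errors are small enough for 3-SE bounds to be discriminating while a
full run stays in the tens of seconds.

## Known limitations

* The archive is write-once; updating a run means re-importing.
* Only the `Basecall_2D_<NNN>` group family is scanned; 1D-only layouts
  (`Basecall_1D_<NNN>`) of later chemistry are not recognized.
* `summary.txt` equality across worker counts relies on rounded printing
  of the one order-sensitive float; the underlying monoid is exact only
  on integer fields.
* Plots are data-faithful but make no attempt to reproduce any
  particular tool's styling; the TSV dumps are the contract.
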