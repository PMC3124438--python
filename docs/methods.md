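# Methods

This note documents the models, algorithms and numerical choices behind
`fessurvey`, and what the synthetic-data tests do and do not demonstrate
about real survey data.

## Synthetic fosmid-end reads

The generator emulates a clone-end survey of a large genome. Read lengths
follow a truncated normal with the survey's observed minimum/mean/maximum
(100/531/861 bp) and SD = (max − min)/6, redrawn until inside the bounds;
only those three summary statistics of the real length distribution are
modelled. Background bases are i.i.d. at the configured GC (default
45.88%); no dinucleotide or higher-order composition is simulated, so
background self-similarity is at the random-sequence floor — real genomes
have low-complexity structure that produces more marginal detector calls
than the simulator does.

Planted features replace background bases in place (read lengths are
preserved, plants never overlap). A microsatellite plant is `motif`
repeated `copies` times with independent per-base substitutions and
indels at the configured rates. A family plant draws a random consensus
(≥100 bp), then emits copies mutated at the configured divergence
(substitutions per site, measured from the consensus — two copies are
therefore ~2× that divergent from each other), reverse-complemented with
probability 0.5, and optionally 5′/3′-truncated (truncated copies keep
40–80% of the consensus, at least 100 bp). Every planted interval is
recorded with its template coordinates, orientation and the exact
mutation operations, so truth round-trips base-for-base. All randomness
derives from one seed; identical configurations are byte-identical.

## Tandem-repeat detection

Candidates: for each distance d in 1..max_unit, positions where the
k-mer (k = min(d, 5)) recurs at distance d are collected; runs separated
by gaps ≤ d + k + 2 become candidate windows when they span at least
max(min_array_length, 1.9 d) bp and the match density clears a 10%
trigger. Perfect arrays ≥ 12 bp are guaranteed a covering candidate.
Candidates never span runs of ≥ 2 N; a single N scores as a mismatch.

Each candidate yields a consensus unit (majority base per phase class,
ties A<C<G<T, reduced to its shortest period), which is aligned to the
window by wraparound dynamic programming: the DP table has one column per
motif position, the in-row dependency wraps cyclically (rows are relaxed
to a fixed point; gap costs are strictly negative so this terminates),
row 0 is free at every phase, and local (Smith–Waterman-style) resets
find the best-scoring array substring. The window grows by 100-bp steps
whenever the alignment presses against its edge, because candidate runs
fragment on diverged arrays. Weights are the classic tandem-finder set
{match +2, mismatch −3, indel −5}; retention requires score ≥ 50 AND
length ≥ 12 bp AND purity (matches / aligned columns) strictly > 0.55 AND
copy number ≥ 1.9. Note the score and length floors are deliberately
independent: with these weights a perfect 12-bp array scores only 24, so
the effective floor for perfect arrays is 25 bp; setting `min_score=24`
realizes a literal 12-bp floor.

Array boundaries are then refined by a phase-anchored changepoint walk:
a rotation of the unit is fitted at the array's centre, and the boundary
walks base-by-base outward scoring +1 for a base matching the expected
phase and −p otherwise, stopping at the innermost strict peak of the
cumulative score (x-drop 10). The penalty p interpolates between 2.5 for
clean arrays and 1.9 for diverged ones (estimated from the array's own
mismatch fraction) — the maximum-a-posteriori trade between shedding a
mutated terminal unit and annexing chance-matching flank depends on the
divergence. If the fixed-phase walk loses more than 40% of the aligned
span (heavy indel drift), the alignment span is kept instead. Reported
score/purity are recomputed on the final span, so every reported array
re-scores to its reported values.

Boundary accuracy has an information-theoretic ceiling: a flank that
happens to continue the repeat's phase is indistinguishable from a
mutated terminal unit. A Monte-Carlo oracle (a MAP changepoint decoder
given the true divergence and both generative models) locates a boundary
within one unit with probability ≈0.92 for dinucleotides and ≈0.955 for
trinucleotides at divergences up to 10%; with two boundaries per locus
that caps whole-locus sharp recovery near 85–91%, and the detector
operates essentially at that ceiling (~88–90% over di-/tri-nucleotide
mixes). Detection itself (right class, ≥80% span overlap) is ≥99%.

Overlap resolution keeps the highest score (ties: smaller period, then
leftmost start); accepted arrays may overlap by at most one unit, and
adjacent distinct-motif arrays (compound repeats) are reported separately.
Purity here is matches over aligned columns of the array-vs-cyclic-unit
alignment — simpler than the adjacent-copy percent-matches some tools
report, and documented as such.

## Canonical motif classes

The class label of a unit is the lexicographic minimum (A<C<G<T) over all
rotations of the unit and all rotations of its reverse complement; units
that are repetitions of a shorter unit are first reduced to that period.
Class counts by exhaustive partition of all 4^k strings: 2, 4, 10, 33,
102, 350 for k = 1..6.

## Landscape statistics

Per-class rows carry counts, reads-with-a-locus (a read counts once per
class regardless of how many loci it has), summed bases, max/mean/SD
length (population SD), mean repeat number (mean length / unit), RA
(class bp / total microsatellite bp × 100) and RF (class loci / total
loci × 100); RA and RF each sum to 100 by construction. Density is
surveyed bp / loci / 1000, reported to 2 decimals. Length-class bins are
L1 (12–20 bp), L2 (21–40) … L10 (181–200), L11 (>201). Partition
comparison reports per-class RA within each partition and microsatellite
bp per Mb. Full precision is kept internally; report output rounds to 2
decimals.

## Repeat-family discovery

Input reads should be tandem-masked (detected arrays to N); a warning is
logged if >20% of hits fall inside known tandem intervals. The all-vs-all
search indexes exact 11-mers, groups shared seeds between a read pair by
diagonal band (band width = endpoint tolerance, adjacent bands merged to
absorb indel drift), chains seeds with gaps ≤150 bp into candidate boxes,
and verifies each box by global alignment (edlib) trimmed to the
maximal-scoring run of columns (match +1, mismatch/indel −2); hits need
≥100 aligned bp at ≥80% identity (matches/columns of the trimmed
alignment) and are emitted symmetrically in both orientations.

Elements: per read, hit intervals whose endpoints both agree within 30 bp
are single-linkage grouped and become one element at the median
endpoints; a group whose span is contained (within tolerance) in a wider
group's span is absorbed as a partial view of the same element; residual
overlapping elements are trimmed at the overlap midpoint so no base pair
is double-counted. Families are the connected components of the
element graph (edges = supporting hits); orientations propagate along a
BFS tree by hit-orientation parity, with odd-cycle conflicts resolved by
majority vote and logged.

Consensus is a star alignment: every element, reoriented to the family's
forward strand, is infix-aligned into the longest element; per-column
base counts take the majority (ties alphabetically), and columns covered
by fewer than two elements are trimmed from the ends. Curation iterates
to a fixed point (≤5 rounds): families whose consensi align at ≥80%
identity over the full shorter consensus are merged transitively and
rebuilt; families whose mean member-to-consensus identity falls below
0.60 are re-clustered at hit identity + 0.1. Families with fewer than 20
elements are dropped, and families matching an exclusion set (≥80%
identity over ≥100 bp, either orientation) are set aside. The internal
tandem scan reuses the tandem detector with the unit ceiling raised to
consensus length / 1.9. Accounting reports per-family genome fraction
(element bp / surveyed bp) and extrapolated genome copies
(count / sampling fraction), plus category grand totals.

The search parameters (word 11, ≥100 bp, ≥80% identity, 30-bp endpoint
tolerance) are configurable defaults chosen to match the length/identity
floors a BLAST-based protocol would use at this read length. With them,
family recovery is reliable for families whose members are pairwise ≤
~18% divergent; at ≥20% pairwise divergence hits fall below the identity
floor and families fragment — real, ancient repeat families are harder
than anything the simulator plants.

## Genome sizing and survey calculators

Flow histograms are two-column channel/count text. The G1 peak is the
mode of a moving-average-smoothed histogram (window 5 bins), refined to a
sub-bin position as the count-weighted centroid over the peak's FWHM
region; if a second local maximum outside that region reaches 95% of the
peak height the histogram is declared ambiguous and an explicit gate is
required. Genome size is ratio × standard (3.50 pg per human-lymphocyte
nucleus). Base-pair conversion defaults to ratio × 3.0 Gb (the human
reference length), which keeps pg and bp mutually consistent with a
72.2% ratio giving ≈2.17 Gb; the physical 0.978 × 10⁹ bp/pg conversion is
available as `pg_conversion=True` and gives ≈2.47 Gb from the same
picogram value — the two conventions disagree by ~14% and the choice is
exposed rather than hidden. Coverage uses the nominal 40-kb insert by
default (a measured mean, e.g. 40.8 kb, can be passed instead). The
sampling fraction computed from a configured genome size (11.1 Mb of a
2.17-Gb genome → 0.51%) differs from the 0.45% a pg-converted genome
would give; the copy-number extrapolation takes the sampling fraction as
an explicit argument for exactly this reason.

## Problem sizes in the test suite

The bundled suites run at desk scale by design: simulations use 60–400
reads (≈30–200 kb), 400 planted tandem loci for the recovery property,
two planted families of 25–30 copies, 100 histogram pairs for sizing
recovery, and 500 random instances for the DP-vs-oracle identity. These
sizes give stable statistics for every property tested while keeping the
whole suite under a minute.

## Known limitations

- No sequencing-error or quality model; no chimeric clones.
- The background is i.i.d.; real low-complexity sequence will produce
  more borderline tandem calls than the simulator suggests.
- Purity is defined against the cyclic consensus unit, not between
  adjacent copies; arrays with systematic copy-to-copy variants score
  lower than an adjacent-copy definition would give.
- Family discovery assumes members are ≲18% pairwise divergent at the
  default floors; orientation assignment is majority-based and can be
  wrong for small, conflict-rich families.
- The curation merge step can chain families transitively through a
  shared segment (the biological "composite family" problem); merged ids
  are concatenated so such events are visible.
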