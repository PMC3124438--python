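"""Tandem-repeat (microsatellite) detection.

Detection runs in two stages.  A fast k-mer self-match scan proposes
candidate windows and periods: a position ``i`` supports period ``d`` when
the k-mer starting at ``i`` recurs at ``i + d`` (k = min(d, 5)), and dense
runs of such support become candidates.  Each candidate is then resolved by
wraparound dynamic programming: the window is aligned against an unbounded
cyclic repetition of a consensus unit, scoring +2 per match, -3 per
mismatch and -5 per indel column, with the unit free to enter at any phase.
The best-scoring local segment of that alignment defines the array; arrays
are retained when they score at least ``min_score`` (default 50), span at
least ``min_array_length`` bp (default 12), and have purity -- the fraction
of aligned columns that are matches -- strictly above ``min_purity``
(default 0.55).

With the default weights a perfect 12-bp array scores only 24, so the score
floor, not the length floor, is what binds for short perfect arrays; the
effective perfect-array floor is 25 bp.  Both thresholds are independent
AND-filters and either can be relaxed (``min_score=24`` realizes a literal
12-bp floor).

Coordinates are 0-based half-open throughout; GFF3 output converts to
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from fessurvey.motifs import canonical_motif, shortest_period

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class DetectorParams:
    """Alignment weights and retention thresholds for the tandem scan."""

    match_weight: int = 2
    mismatch_penalty: int = 3
    indel_penalty: int = 5
    min_score: int = 50
    min_array_length: int = 12
    min_purity: float = 0.55  # strictly-greater retention
    max_unit: int = 6
    min_copy_number: float = 1.9
    trigger_fraction: float = 0.1  # k-mer support density that opens a candidate

    def __post_init__(self) -> None:
        if min(self.match_weight, self.mismatch_penalty, self.indel_penalty) <= 0:
            raise ValueError("alignment weights and penalties must be positive")
        if not 0.0 < self.min_purity < 1.0:
            raise ValueError(f"min_purity must be in (0,1), got {self.min_purity}")
        if self.max_unit < 1:
            raise ValueError(f"max_unit must be >= 1, got {self.max_unit}")


@dataclass
class TandemArray:
    """One detected tandem array on a read."""

    read_id: str
    start: int
    end: int
    period: int
    motif: str
    canonical_motif: str
    copy_number: float
    score: int
    purity: float
    indel_fraction: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    if not seq:
        raise ValueError("sequence is empty")
    extra = set(seq) - _VALID_BASES
    if extra:
        raise ValueError(f"sequence contains non-IUPAC characters: {sorted(extra)}")
    return seq


# ---------------------------------------------------------------------------
# Wraparound dynamic programming
# ---------------------------------------------------------------------------

_NEG = -(10**9)


def _wdp(seg: str, motif: str, params: DetectorParams, local: bool):
    """Wraparound DP of ``seg`` against the cyclic repetition of ``motif``.

    Returns ``(score, end_i, end_j, D, ptr)``.  ``D[i][j]`` is the best
    score of an alignment consuming ``seg[:i]`` whose last pattern column
    is ``motif[j]``; row 0 is free at every ``j`` (free entry phase).  In
    local mode every cell may additionally restart at 0 and the best cell
    anywhere is returned; in global mode the segment is consumed entirely
    and the best cell of the last row is returned.

    The in-row dependency (a gap in the segment consumes a pattern
    character, moving ``j -> j+1`` cyclically within one row) wraps around
    the motif, so each row is relaxed repeatedly until a fixed point; gap
    costs are strictly negative, so this terminates within two sweeps.
    """
    n, m = len(seg), len(motif)
    mw, mp, ip = params.match_weight, params.mismatch_penalty, params.indel_penalty
    base = 0 if local else _NEG
    D = [[0] * m] + [[base] * m for _ in range(n)]
    # ptr codes: 0 = origin, 1 = diagonal, 2 = up (gap in pattern), 3 = left
    # (gap in segment, cyclic within row)
    ptr = [[0] * m] + [[0] * m for _ in range(n)]
    for i in range(1, n + 1):
        c = seg[i - 1]
        row, prev, prow = D[i], D[i - 1], ptr[i]
        if local:
            for j in range(m):
                row[j] = 0
        for _sweep in range(m + 2):
            changed = False
            for j in range(m):
                sub = mw if c == motif[j] else -mp  # N scores as mismatch
                best = prev[(j - 1) % m] + sub
                bp = 1
                up = prev[j] - ip
                if up > best:
                    best, bp = up, 2
                left = row[(j - 1) % m] - ip
                if left > best:
                    best, bp = left, 3
                if local and best < 0:
                    best, bp = 0, 0
                if best > row[j]:
                    row[j], prow[j] = best, bp
                    changed = True
            if not changed:
                break
    if local:
        score = end_i = end_j = None
        for i in range(n + 1):
            for j in range(m):
                if score is None or D[i][j] > score:
                    score, end_i, end_j = D[i][j], i, j
    else:
        end_i = n
        end_j = max(range(m), key=lambda j: D[n][j])
        score = D[n][end_j]
    return score, end_i, end_j, D, ptr


def _traceback(end_i: int, end_j: int, ptr) -> tuple[int, int, int, int]:
    """Follow backpointers; returns (start_i, matches+mismatch, matches, gaps)."""
    i, j, aligned, matches, gaps = end_i, end_j, 0, 0, 0
    m = len(ptr[0])
    while i > 0 and ptr[i][j] != 0:
        code = ptr[i][j]
        aligned += 1
        if code == 1:
            i, j = i - 1, (j - 1) % m
        elif code == 2:
            gaps += 1
            i -= 1
        else:
            gaps += 1
            j = (j - 1) % m
    return i, aligned, gaps, j


def wraparound_align(
    segment: str, motif: str, params: DetectorParams | None = None
) -> tuple[int, float, float, tuple[int, int]]:
    """Align ``segment`` globally against an unbounded tandem of ``motif``.

    Returns ``(score, purity, indel_fraction, (start, end))`` where purity
    is matches over aligned columns and the span covers the whole segment
    (the cyclic pattern absorbs any phase).

    >>> wraparound_align("AGAGAG", "AG")[:2]
    (12, 1.0)
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    params = params or DetectorParams()
    seg = _validate_sequence(segment)
    motif = motif.upper()
    score, ei, ej, D, ptr = _wdp(seg, motif, params, local=False)
    _, aligned, gaps, _ = _traceback(ei, ej, ptr)
    # recount matches from the score identity: score = 2*M - 3*X - 5*G
    # with aligned = M + X + G
    subs = aligned - gaps
    matches = round(
        (score + params.mismatch_penalty * subs + params.indel_penalty * gaps)
        / (params.match_weight + params.mismatch_penalty)
    )
    purity = matches / aligned if aligned else 0.0
    indel_fraction = gaps / aligned if aligned else 0.0
    return score, purity, indel_fraction, (0, len(seg))


def _best_local_array(seq: str, motif: str, params: DetectorParams):
    """Best-scoring substring of ``seq`` against cyclic ``motif``.

    Returns ``(score, start, end)`` of the maximal local wraparound
    alignment, or ``None`` when nothing scores above 0.
    """
    score, ei, ej, D, ptr = _wdp(seq, motif, params, local=True)
    if not score or score <= 0:
        return None
    si, _, _, _ = _traceback(ei, ej, ptr)
    return score, si, ei


# ---------------------------------------------------------------------------
# Candidate discovery
# ---------------------------------------------------------------------------


def _nn_run_spans(seq: str) -> list[tuple[int, int]]:
    """Half-open spans of runs of >= 2 consecutive N."""
    spans, i, n = [], 0, len(seq)
    while i < n:
        if seq[i] == "N":
            j = i
            while j < n and seq[j] == "N":
                j += 1
            if j - i >= 2:
                spans.append((i, j))
            i = j
        else:
            i += 1
    return spans


def _split_at_nn(start: int, end: int, nn_spans) -> list[tuple[int, int]]:
    pieces, cur = [], start
    for ns, ne in nn_spans:
        if ne <= start or ns >= end:
            continue
        if ns > cur:
            pieces.append((cur, ns))
        cur = max(cur, ne)
    if cur < end:
        pieces.append((cur, end))
    return pieces


def find_candidate_periods(
    sequence: str, params: DetectorParams | None = None
) -> list[tuple[tuple[int, int], int]]:
    """Propose (window, period) candidates from k-mer self-matches.

    For every distance ``d`` in 1..max_unit, positions where the
    k-mer (k = min(d, 5)) recurs at distance ``d`` are tallied; runs of
    support separated by gaps of at most ``d + k + 2`` become candidate
    windows.  Any perfect array of length >= ``min_array_length`` is
    guaranteed a covering candidate.  Windows never span runs of two or
    more N.
    """
    params = params or DetectorParams()
    seq = _validate_sequence(sequence)
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    not_n = arr != ord("N")
    nn_spans = _nn_run_spans(seq)
    candidates: list[tuple[tuple[int, int], int]] = []
    for d in range(1, params.max_unit + 1):
        if n < d + 1:
            break
        k = min(d, 5)
        if n < d + k:
            continue
        eq = (arr[: n - d] == arr[d:]) & not_n[: n - d] & not_n[d:]
        if k > 1:
            kernel = np.ones(k, dtype=np.int32)
            support = np.convolve(eq.astype(np.int32), kernel, mode="valid") == k
        else:
            support = eq
        idx = np.flatnonzero(support)
        if idx.size == 0:
            continue
        gap_tol = d + k + 2
        run_start = prev = int(idx[0])
        runs = []
        for pos in idx[1:]:
            pos = int(pos)
            if pos - prev > gap_tol:
                runs.append((run_start, prev))
                run_start = pos
            prev = pos
        runs.append((run_start, prev))
        min_span = max(params.min_array_length, int(np.ceil(params.min_copy_number * d)))
        for rs, re_ in runs:
            start, end = rs, min(n, re_ + d + k)
            for ps, pe in _split_at_nn(start, end, nn_spans):
                span = pe - ps
                n_support = int(np.count_nonzero(support[ps : max(ps, pe - d - k) + 1]))
                dens = n_support / max(1, span - d - k + 1)
                if span >= min_span and dens >= params.trigger_fraction:
                    candidates.append(((ps, pe), d))
    candidates.sort(key=lambda c: (c[0][0], c[1]))
    return candidates


# ---------------------------------------------------------------------------
# Array calling
# ---------------------------------------------------------------------------


def _consensus_unit(seq: str, start: int, end: int, d: int) -> str | None:
    """Majority base per phase class over window [start, end); ties A<C<G<T."""
    unit = []
    for p in range(d):
        counts: dict[str, int] = {}
        for pos in range(start + p, end, d):
            b = seq[pos]
            if b != "N":
                counts[b] = counts.get(b, 0) + 1
        if not counts:
            return None
        best = max(counts.values())
        unit.append(min(b for b, c in counts.items() if c == best))
    return "".join(unit)


def _best_rotation(seq: str, pos: int, motif: str, window_end: int) -> str:
    """Rotation of ``motif`` best matching ``seq[pos:window_end]`` in phase."""
    best, best_rot = -1, motif
    for r in range(len(motif)):
        rot = motif[r:] + motif[:r]
        matches = sum(
            1
            for x in range(pos, window_end)
            if seq[x] == rot[(x - pos) % len(rot)]
        )
        if matches > best:
            best, best_rot = matches, rot
    return best_rot


def _polish_boundaries(
    seq: str, start: int, end: int, motif: str
) -> tuple[int, int]:
    """Snap array boundaries to unit granularity.

    The score-optimal local alignment extends over any positive-scoring
    flank run and trims any negative-scoring array end, which biases
    boundaries by a few bases around mutations.  Here the boundary moves
    in whole units: a flanking unit is annexed only when a strict majority
    of its bases continues the phase, and a terminal unit is shed when a
    majority of its bases does not.
    """
    p = len(motif)
    n = len(seq)
    mid = (start + end) // 2
    anchor = max(start, min(mid - (5 * p) // 2, end - 5 * p))
    anchor = max(0, anchor)
    rot = _best_rotation(seq, anchor, motif, min(end, anchor + 5 * p))

    def expected(x: int) -> str:
        return rot[(x - anchor) % p]

    # Estimate the array's own divergence from the anchor neighbourhood;
    # the boundary rule below trades a missed mutated terminal unit
    # against annexed chance-matching flank, and the right trade depends
    # on how diverged the array is (maximum-a-posteriori changepoint).
    est_lo = max(start + p, anchor - 90)
    est_hi = min(end - p, anchor + 90)
    if est_hi <= est_lo:
        est_lo, est_hi = start, end
    mismatch_frac = sum(
        1 for x in range(est_lo, est_hi) if seq[x] != expected(x)
    ) / max(1, est_hi - est_lo)
    # clean array -> strict boundary (2.5); diverged array -> lenient (1.9)
    penalty = float(np.clip(2.5 - (mismatch_frac - 0.03) * 15.0, 1.9, 2.5))

    # Walk base-by-base from the anchor outward, +1 for a base matching
    # the expected phase and -penalty otherwise; the boundary sits at the
    # innermost strict peak of the cumulative score.  Inside the array the
    # drift is strongly positive, so mutation clusters are dips the walk
    # recovers from (it gives up 10 below the peak); in random flank the
    # drift is strongly negative and chance matches rarely assemble a new
    # peak more than one unit out.
    def walk(step: int) -> int:
        x = anchor if step > 0 else anchor - 1
        best_x, best_s, s = anchor, 0.0, 0.0
        while 0 <= x < n:
            s += 1.0 if seq[x] == expected(x) else -penalty
            if s > best_s:
                best_s, best_x = s, x
            if s < best_s - 10:
                break
            x += step
        return best_x

    new_end = min(n, walk(+1) + 1)
    new_start = max(0, walk(-1))
    # a heavily indel-shifted array defeats the fixed-phase walk; fall back
    # to the alignment span rather than truncate at the phase break
    if (new_end - new_start) < 0.6 * (end - start) or new_end <= new_start:
        return start, end
    return new_start, new_end


def call_tandem_arrays(
    read: str,
    params: DetectorParams | None = None,
    read_id: str = "read",
) -> list[TandemArray]:
    """Detect, score and filter tandem arrays in one read.

    Each candidate window yields a consensus unit (majority base per phase
    class), the array is grown to the maximal-scoring local wraparound
    alignment of that unit, and arrays passing the score, length, purity
    and copy-number floors are retained.  Overlapping calls are resolved by
    keeping the highest score, ties broken by smaller period then leftmost
    start; adjacent distinct-motif arrays are reported separately.
    """
    params = params or DetectorParams()
    seq = _validate_sequence(read)
    n = len(seq)
    nn_spans = _nn_run_spans(seq)
    raw: list[TandemArray] = []
    seen: set[tuple[int, int, str]] = set()
    for (cs, ce), d in find_candidate_periods(seq, params):
        unit = _consensus_unit(seq, cs, ce, d)
        if unit is None or "N" in unit:
            continue
        unit = shortest_period(unit)
        margin = 2 * len(unit) + 10
        ws, we = max(0, cs - margin), min(n, ce + margin)
        for ws, we in _split_at_nn(ws, we, nn_spans):
            if not (ws <= cs < we or ws < ce <= we or (cs <= ws and we <= ce)):
                continue
            cur = unit
            span = None
            for _round in range(10):
                hit = _best_local_array(seq[ws:we], cur, params)
                if hit is None:
                    break
                _, ls, le = hit
                span = (ws + ls, ws + le)
                # grow the window when the array presses against its edge:
                # candidate runs fragment on diverged arrays and the true
                # span can extend well beyond the trigger window
                grew = False
                if span[0] - ws <= len(cur) and ws > 0:
                    new_ws = max(0, ws - 100)
                    pieces = [
                        p for p in _split_at_nn(new_ws, we, nn_spans)
                        if p[0] <= span[0] < p[1]
                    ]
                    if pieces and pieces[0][0] < ws:
                        ws, grew = pieces[0][0], True
                if we - span[1] <= len(cur) and we < n:
                    new_we = min(n, we + 100)
                    pieces = [
                        p for p in _split_at_nn(ws, new_we, nn_spans)
                        if p[0] < span[1] <= p[1]
                    ]
                    if pieces and pieces[0][1] > we:
                        we, grew = pieces[0][1], True
                refined = _consensus_unit(seq, span[0], span[1], len(cur))
                if refined is not None:
                    refined = shortest_period(refined)
                if not grew and (refined is None or refined == cur):
                    break
                if refined is not None:
                    cur = refined
            if span is None:
                continue
            start, end = _polish_boundaries(seq, span[0], span[1], cur)
            period = len(cur)
            key = (start, end, cur)
            if key in seen or end - start < period:
                continue
            seen.add(key)
            score, purity, indel_fraction, _ = wraparound_align(
                seq[start:end], cur, params
            )
            copy_number = (end - start) / period
            if (
                end - start >= params.min_array_length
                and score >= params.min_score
                and purity > params.min_purity
                and copy_number >= params.min_copy_number
                and period <= params.max_unit
            ):
                raw.append(
                    TandemArray(
                        read_id=read_id,
                        start=start,
                        end=end,
                        period=period,
                        motif=cur,
                        canonical_motif=(
                            canonical_motif(cur).label if period <= 6 else cur
                        ),
                        copy_number=copy_number,
                        score=score,
                        purity=purity,
                        indel_fraction=indel_fraction,
                    )
                )
    return _resolve_overlaps(raw)


def _resolve_overlaps(arrays: list[TandemArray]) -> list[TandemArray]:
    """Keep highest score among overlapping calls; ties -> smaller period,
    then leftmost.  Accepted arrays may overlap by at most one unit."""
    order = sorted(arrays, key=lambda a: (-a.score, a.period, a.start, a.motif))
    kept: list[TandemArray] = []
    for a in order:
        ok = True
        for b in kept:
            overlap = min(a.end, b.end) - max(a.start, b.start)
            if overlap > min(a.period, b.period):
                ok = False
                break
        if ok:
            kept.append(a)
    kept.sort(key=lambda a: a.start)
    return kept


def filter_by_purity(
    arrays: Iterable[TandemArray], params: DetectorParams | None = None
) -> list[TandemArray]:
    """Retain arrays whose purity strictly exceeds ``min_purity``.

    An array at exactly the floor (55% matches by default) is removed;
    output order follows input order.
    """
    params = params or DetectorParams()
    return [a for a in arrays if a.purity > params.min_purity]


# ---------------------------------------------------------------------------
# Read-set level helpers and output
# ---------------------------------------------------------------------------


def scan_reads(
    reads: Mapping[str, str], params: DetectorParams | None = None
) -> list[TandemArray]:
    """Run the tandem caller over a read set (mapping id -> sequence)."""
    params = params or DetectorParams()
    out: list[TandemArray] = []
    for read_id, seq in reads.items():
        out.extend(call_tandem_arrays(seq, params, read_id=read_id))
    return out


def mask_tandem_arrays(
    reads: Mapping[str, str], arrays: Sequence[TandemArray]
) -> dict[str, str]:
    """Replace detected tandem intervals with N (input untouched)."""
    masked = {rid: list(seq) for rid, seq in reads.items()}
    for a in arrays:
        if a.read_id in masked:
            for i in range(a.start, a.end):
                masked[a.read_id][i] = "N"
    return {rid: "".join(chars) for rid, chars in masked.items()}


def arrays_to_gff3(arrays: Sequence[TandemArray]) -> str:
    """Render arrays as GFF3 (type tandem_repeat, 1-based inclusive)."""
    lines = ["##gff-version 3"]
    for a in arrays:
        attrs = (
            f"period={a.period};motif={a.motif};canonical={a.canonical_motif};"
            f"copies={a.copy_number:.2f};score={a.score};purity={a.purity:.4f}"
        )
        lines.append(
            "\t".join(
                [
                    a.read_id,
                    "fessurvey",
                    "tandem_repeat",
                    str(a.start + 1),
                    str(a.end),
                    str(a.score),
                    "+",
                    ".",
                    attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def arrays_to_tsv(arrays: Sequence[TandemArray]) -> str:
    """Flat TSV mirroring the GFF attributes (0-based half-open)."""
    header = (
        "read_id\tstart\tend\tperiod\tmotif\tcanonical\tcopies\tscore\t"
        "purity\tindel_fraction"
    )
    rows = [header]
    for a in arrays:
        rows.append(
            f"{a.read_id}\t{a.start}\t{a.end}\t{a.period}\t{a.motif}\t"
            f"{a.canonical_motif}\t{a.copy_number:.2f}\t{a.score}\t"
            f"{a.purity:.4f}\t{a.indel_fraction:.4f}"
        )
    return "\n".join(rows) + "\n"
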