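"""De novo interspersed-repeat family discovery.

Works on tandem-masked reads (microsatellites replaced by N so they cannot
seed spurious homology).  The stages mirror the classic survey-sequence
workflow: an all-vs-all seeded local alignment finds pairwise homologies
between reads; overlapping hit intervals on a read whose endpoints agree
within a tolerance are aggregated into repeat *elements*; single-linkage
clustering of elements connected by hits yields candidate *families*, with
element orientations propagated along hit-orientation parity; a star
alignment against the longest element builds each family consensus; an
automated merge/split curation pass replaces manual inspection (families
whose consensi align well are merged, families whose members fit their own
consensus poorly are re-clustered at a stricter identity); families with
fewer than ``min_family_count`` members (default 20) are dropped, and
families matching an exclusion set (e.g. rRNA screens) set aside.  The
accounting stage converts element counts and lengths into genome-fraction
and genome-copy-number extrapolations.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx
import numpy as np
import pandas as pd

from fessurvey.motifs import reverse_complement
from fessurvey.tandem import DetectorParams, call_tandem_arrays

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FamilyParams:
    word_size: int = 11
    min_hit_length: int = 100
    min_hit_identity: float = 0.80
    endpoint_tolerance: int = 30
    min_family_count: int = 20
    merge_identity: float = 0.80
    merge_coverage: float = 0.50
    split_identity_floor: float = 0.60
    max_chain_gap: int = 150

    def __post_init__(self) -> None:
        if self.min_family_count < 1:
            raise ValueError("min_family_count must be >= 1")
        for name in ("min_hit_identity", "merge_identity", "merge_coverage",
                     "split_identity_floor"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0,1], got {v}")


@dataclass
class PairwiseHit:
    read_a: str
    read_b: str
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    orientation: str  # "same" | "opposite"
    identity: float
    score: int

    def mirrored(self) -> "PairwiseHit":
        return PairwiseHit(
            self.read_b, self.read_a, self.interval_b, self.interval_a,
            self.orientation, self.identity, self.score,
        )


@dataclass
class RepeatElement:
    read_id: str
    start: int
    end: int
    orientation: str = "+"  # relative to the family reference

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatFamily:
    family_id: str
    elements: list[RepeatElement]
    consensus: str = ""
    internal_tandems: list[tuple[int, float]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.elements)

    @property
    def consensus_length(self) -> int:
        return len(self.consensus)

    @property
    def total_length(self) -> int:
        return sum(e.length for e in self.elements)

    @property
    def gc_pct(self) -> float:
        gc = sum(1 for b in self.consensus if b in "GC")
        n = sum(1 for b in self.consensus if b in "ACGT")
        return gc / n * 100 if n else float("nan")


# ---------------------------------------------------------------------------
# Seeded all-vs-all search
# ---------------------------------------------------------------------------


def _identity_nw(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def _chain_matches(
    matches: list[tuple[int, int]], params: FamilyParams
) -> list[tuple[int, int, int, int]]:
    """Group seed matches (pos_a, pos_b) by diagonal band and chain them
    into candidate interval pairs (sa, ea, sb, eb)."""
    w = params.word_size
    by_band: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for pa, pb in matches:
        by_band[(pa - pb) // params.endpoint_tolerance].append((pa, pb))
    merged: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for band, pts in by_band.items():
        merged[band].extend(pts)
        # neighbouring bands belong to the same alignment when indels drift
        if band + 1 in by_band:
            merged[band].extend(by_band[band + 1])
    boxes = []
    for pts in merged.values():
        pts = sorted(set(pts))
        cur = [pts[0]]
        for p in pts[1:]:
            if p[0] - cur[-1][0] <= params.max_chain_gap:
                cur.append(p)
            else:
                boxes.append(cur)
                cur = [p]
        boxes.append(cur)
    out = []
    for chain in boxes:
        sa = min(p[0] for p in chain)
        ea = max(p[0] for p in chain) + w
        sb = min(p[1] for p in chain)
        eb = max(p[1] for p in chain) + w
        out.append((sa, ea, sb, eb))
    # drop boxes nested in a larger one
    out.sort(key=lambda t: (t[1] - t[0]), reverse=True)
    kept: list[tuple[int, int, int, int]] = []
    for box in out:
        if not any(
            box[0] >= k[0] and box[1] <= k[1] and box[2] >= k[2] and box[3] <= k[3]
            for k in kept
        ):
            kept.append(box)
    return kept


def _trim_local(sub_a: str, sub_b: str) -> tuple[int, int, int, int, int, int] | None:
    """Globally align two substrings and keep the maximal-scoring run of
    columns (match +1, mismatch/indel -2), trimming noisy ends.

    Returns (a_start, a_end, b_start, b_end, matches, columns) as offsets
    into the substrings, or None when nothing aligns positively.
    """
    res = edlib.align(sub_a, sub_b, mode="NW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    cols: list[tuple[int, int, int]] = []  # (weight, da, db) per column
    for n, op in _walk_cigar(res["cigar"]):
        if op in "=M":
            cols.extend([(1, 1, 1)] * n)
        elif op == "X":
            cols.extend([(-2, 1, 1)] * n)
        elif op == "I":  # consumes query (sub_a)
            cols.extend([(-2, 1, 0)] * n)
        else:  # D: consumes target (sub_b)
            cols.extend([(-2, 0, 1)] * n)
    # Kadane: best-scoring contiguous column run
    best = run = 0
    best_span = (0, 0)
    run_start = 0
    for i, (w, _, _) in enumerate(cols):
        run += w
        if run <= 0:
            run, run_start = 0, i + 1
        elif run > best:
            best, best_span = run, (run_start, i + 1)
    if best <= 0:
        return None
    lo, hi = best_span
    a0 = sum(da for _, da, _ in cols[:lo])
    b0 = sum(db for _, _, db in cols[:lo])
    a1 = a0 + sum(da for _, da, _ in cols[lo:hi])
    b1 = b0 + sum(db for _, _, db in cols[lo:hi])
    matches = sum(1 for w, _, _ in cols[lo:hi] if w > 0)
    return a0, a1, b0, b1, matches, hi - lo


def _verify_box(
    seq_a: str, seq_b: str, box, params: FamilyParams
) -> tuple[tuple[int, int], tuple[int, int], float, int] | None:
    sa, ea, sb, eb = box
    m = params.word_size
    sa, sb = max(0, sa - m), max(0, sb - m)
    ea, eb = min(len(seq_a), ea + m), min(len(seq_b), eb + m)
    if ea - sa < params.min_hit_length or eb - sb < params.min_hit_length:
        return None
    trimmed = _trim_local(seq_a[sa:ea], seq_b[sb:eb])
    if trimmed is None:
        return None
    a0, a1, b0, b1, matches, columns = trimmed
    if a1 - a0 < params.min_hit_length or b1 - b0 < params.min_hit_length:
        return None
    ident = matches / columns if columns else 0.0
    if ident < params.min_hit_identity:
        return None
    return (sa + a0, sa + a1), (sb + b0, sb + b1), ident, matches


def _kmer_positions(seq: str, w: int):
    for i in range(len(seq) - w + 1):
        kmer = seq[i : i + w]
        if "N" not in kmer:
            yield kmer, i


def pairwise_local_hits(
    id_a: str, seq_a: str, id_b: str, seq_b: str, params: FamilyParams
) -> list[PairwiseHit]:
    """Seeded local alignments between two sequences, both orientations."""
    hits: list[PairwiseHit] = []
    index: dict[str, list[int]] = defaultdict(list)
    for kmer, i in _kmer_positions(seq_a, params.word_size):
        index[kmer].append(i)
    for orientation, query in (
        ("same", seq_b),
        ("opposite", reverse_complement(seq_b)),
    ):
        matches = [
            (pa, pb)
            for kmer, pb in _kmer_positions(query, params.word_size)
            for pa in index.get(kmer, ())
        ]
        if not matches:
            continue
        for box in _chain_matches(matches, params):
            got = _verify_box(seq_a, query, box, params)
            if got is None:
                continue
            (sa, ea), (sb, eb), ident, score = got
            if orientation == "opposite":
                sb, eb = len(seq_b) - eb, len(seq_b) - sb
            hits.append(
                PairwiseHit(id_a, id_b, (sa, ea), (sb, eb), orientation, ident, score)
            )
    return hits


def allpairs_search(
    reads: Mapping[str, str], params: FamilyParams | None = None,
    known_tandems: Sequence | None = None,
) -> list[PairwiseHit]:
    """All-vs-all seeded local alignment over a (tandem-masked) read set.

    Exact ``word_size``-mers shared between two distinct reads (either
    orientation) are chained along diagonals into candidate interval pairs
    and verified by global alignment of the boxed substrings; pairs passing
    the length and identity floors become hits.  Output is symmetric:
    every hit is emitted in both (a, b) and (b, a) forms.

    When ``known_tandems`` (an iterable with read_id/start/end attributes)
    is given and more than 20% of hit intervals fall inside those spans, a
    warning is logged -- the input was probably not masked.
    """
    params = params or FamilyParams()
    ids = sorted(reads)
    index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for ai, rid in enumerate(ids):
        for kmer, pos in _kmer_positions(reads[rid], params.word_size):
            index[kmer].append((ai, pos))
    hits: list[PairwiseHit] = []
    for bi, rid_b in enumerate(ids):
        seq_b_fwd = reads[rid_b]
        for orientation in ("same", "opposite"):
            query = seq_b_fwd if orientation == "same" else reverse_complement(seq_b_fwd)
            per_partner: dict[int, list[tuple[int, int]]] = defaultdict(list)
            for kmer, pb in _kmer_positions(query, params.word_size):
                for ai, pa in index.get(kmer, ()):
                    if ai < bi:
                        per_partner[ai].append((pa, pb))
            for ai, matches in per_partner.items():
                rid_a, seq_a = ids[ai], reads[ids[ai]]
                for box in _chain_matches(matches, params):
                    got = _verify_box(seq_a, query, box, params)
                    if got is None:
                        continue
                    (sa, ea), (sb, eb), ident, score = got
                    if orientation == "opposite":
                        sb, eb = len(seq_b_fwd) - eb, len(seq_b_fwd) - sb
                    hit = PairwiseHit(
                        rid_a, rid_b, (sa, ea), (sb, eb), orientation, ident, score
                    )
                    hits.append(hit)
                    hits.append(hit.mirrored())
    if known_tandems:
        spans = defaultdict(list)
        for t in known_tandems:
            spans[t.read_id].append((t.start, t.end))
        inside = sum(
            1
            for h in hits
            if any(
                h.interval_a[0] >= s and h.interval_a[1] <= e
                for s, e in spans.get(h.read_a, ())
            )
        )
        if hits and inside / len(hits) > 0.20:
            logger.warning(
                "%.0f%% of hits fall inside known tandem intervals; "
                "was the input tandem-masked?", 100 * inside / len(hits),
            )
    return hits


# ---------------------------------------------------------------------------
# Element definition and clustering
# ---------------------------------------------------------------------------


def define_elements(
    hits: Sequence[PairwiseHit], params: FamilyParams | None = None
) -> list[RepeatElement]:
    """Aggregate hit intervals on each read into repeat elements.

    Intervals whose start and end both agree within ``endpoint_tolerance``
    are single-linkage grouped; each group becomes one element at the
    majority (median) endpoints.  Elements that still overlap after
    grouping are trimmed at the midpoint of their overlap so no base pair
    is counted twice.
    """
    params = params or FamilyParams()
    by_read: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for h in hits:
        by_read[h.read_a].append(h.interval_a)
    elements: list[RepeatElement] = []
    tol = params.endpoint_tolerance
    for rid in sorted(by_read):
        ivs = sorted(by_read[rid])
        groups: list[list[tuple[int, int]]] = []
        for iv in ivs:
            placed = False
            for g in groups:
                if any(abs(iv[0] - s) <= tol and abs(iv[1] - e) <= tol for s, e in g):
                    g.append(iv)
                    placed = True
                    break
            if not placed:
                groups.append([iv])
        spans = []
        for g in groups:
            start = int(np.median([s for s, _ in g]))
            end = int(np.median([e for _, e in g]))
            spans.append((start, end))
        # fragment groups contained in a longer group's span are absorbed:
        # they are partial views of the same element, not a distinct boundary
        spans.sort(key=lambda iv: iv[0] - iv[1])  # widest first
        made: list[RepeatElement] = []
        for start, end in spans:
            if any(
                start >= e.start - tol and end <= e.end + tol for e in made
            ):
                continue
            made.append(RepeatElement(rid, start, end))
        made.sort(key=lambda e: e.start)
        for prev, cur in zip(made, made[1:]):
            if cur.start < prev.end:  # trim overlap at the midpoint
                mid = (cur.start + prev.end) // 2
                prev.end, cur.start = mid, mid
        elements.extend(e for e in made if e.length > 0)
    return elements


def _element_lookup(elements: Sequence[RepeatElement]):
    by_read: dict[str, list[int]] = defaultdict(list)
    for i, e in enumerate(elements):
        by_read[e.read_id].append(i)
    return by_read


def _find_element(
    by_read, elements, read_id: str, interval: tuple[int, int]
) -> int | None:
    s, e = interval
    best, best_ov = None, 0
    for i in by_read.get(read_id, ()):
        el = elements[i]
        ov = min(e, el.end) - max(s, el.start)
        if ov > best_ov:
            best, best_ov = i, ov
    if best is not None and best_ov >= 0.5 * (e - s):
        return best
    return None


def cluster_families(
    elements: Sequence[RepeatElement],
    hits: Sequence[PairwiseHit],
    params: FamilyParams | None = None,
) -> list[RepeatFamily]:
    """Single-linkage clustering of elements into families.

    An edge joins the two elements a hit connects; connected components
    become families.  Orientations are propagated from an arbitrary
    reference element by hit-orientation parity (same-strand hits imply
    equal orientation); parity conflicts on odd cycles are resolved by a
    majority vote over incident edges and logged.
    """
    params = params or FamilyParams()
    elements = list(elements)
    by_read = _element_lookup(elements)
    G = nx.Graph()
    G.add_nodes_from(range(len(elements)))
    for h in hits:
        ia = _find_element(by_read, elements, h.read_a, h.interval_a)
        ib = _find_element(by_read, elements, h.read_b, h.interval_b)
        if ia is None or ib is None or ia == ib:
            continue
        parity = 0 if h.orientation == "same" else 1
        if G.has_edge(ia, ib):
            G[ia][ib]["votes"].append(parity)
        else:
            G.add_edge(ia, ib, votes=[parity])
    families = []
    for comp_idx, comp in enumerate(
        sorted(nx.connected_components(G), key=lambda c: (-len(c), min(c)))
    ):
        comp = sorted(comp)
        # edge parity = majority vote of its supporting hits
        parity = {}
        ref = comp[0]
        orient = {ref: 0}
        for u, v in nx.bfs_edges(G.subgraph(comp), ref):
            p = round(np.mean(G[u][v]["votes"]))
            orient[v] = orient[u] ^ p
        conflicts = 0
        for u, v, data in G.subgraph(comp).edges(data=True):
            p = round(np.mean(data["votes"]))
            if orient[u] ^ orient[v] != p:
                conflicts += 1
        if conflicts:
            # majority re-vote per node
            for node in comp[1:]:
                votes = []
                for nb in G.neighbors(node):
                    if nb in orient:
                        p = round(np.mean(G[node][nb]["votes"]))
                        votes.append(orient[nb] ^ p)
                if votes:
                    orient[node] = round(np.mean(votes))
            logger.info(
                "family %d: %d orientation-parity conflicts resolved by majority",
                comp_idx, conflicts,
            )
        fam_elements = []
        for i in comp:
            e = elements[i]
            fam_elements.append(
                RepeatElement(e.read_id, e.start, e.end, "-" if orient[i] else "+")
            )
        families.append(RepeatFamily(f"FAM{comp_idx + 1}", fam_elements))
    return families


def filter_families(
    families: Iterable[RepeatFamily], params: FamilyParams | None = None
) -> list[RepeatFamily]:
    """Retain families with at least ``min_family_count`` elements."""
    params = params or FamilyParams()
    return [f for f in families if f.count >= params.min_family_count]


# ---------------------------------------------------------------------------
# Consensus building
# ---------------------------------------------------------------------------


def _element_seq(e: RepeatElement, reads: Mapping[str, str]) -> str:
    seq = reads[e.read_id][e.start : e.end]
    return reverse_complement(seq) if e.orientation == "-" else seq


_CIGAR_OPS = frozenset("=XIDM")


def _walk_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch in _CIGAR_OPS:
            yield int(num), ch
            num = ""
        else:
            num += ch


def build_consensus(family: RepeatFamily, reads: Mapping[str, str]) -> str:
    """Star-alignment majority consensus of a family.

    Every element (reoriented to the family's + strand) is aligned into the
    longest element with an infix alignment; per-column base counts are
    tallied and the majority base taken (ties alphabetically, A<C<G<T).
    Columns covered by fewer than two elements are trimmed from the ends.
    Single-element families return the element itself.
    """
    if not family.elements:
        raise ValueError("cannot build a consensus for an empty family")
    seqs = [_element_seq(e, reads) for e in family.elements]
    if len(seqs) == 1:
        logger.info("family %s has a single element; consensus = element", family.family_id)
        return seqs[0]
    ref_i = max(range(len(seqs)), key=lambda i: len(seqs[i]))
    ref = seqs[ref_i]
    L = len(ref)
    counts = np.zeros((L, 4), dtype=np.int32)
    coverage = np.zeros(L, dtype=np.int32)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for b_i, base in enumerate(ref):
        if base in base_idx:
            counts[b_i, base_idx[base]] += 1
    coverage += 1
    for s_i, seq in enumerate(seqs):
        if s_i == ref_i:
            continue
        res = edlib.align(seq, ref, mode="HW", task="path")
        if res["editDistance"] < 0 or not res.get("cigar"):
            continue
        start = res["locations"][0][0]
        qpos, tpos = 0, start
        for n, op in _walk_cigar(res["cigar"]):
            if op in "=XM":
                for _ in range(n):
                    b = seq[qpos]
                    if b in base_idx and tpos < L:
                        counts[tpos, base_idx[b]] += 1
                    qpos += 1
                    tpos += 1
            elif op == "I":  # insertion in the element; not in star columns
                qpos += n
            else:  # deletion: element skips reference columns
                tpos += n
        coverage[start : min(tpos, L)] += 1
    cons = []
    for i in range(L):
        col = counts[i]
        if col.sum() == 0:
            cons.append(ref[i])
            continue
        best = col.max()
        cons.append("ACGT"[int(np.flatnonzero(col == best)[0])])
    covered = np.flatnonzero(coverage >= 2)
    if covered.size == 0:
        return "".join(cons)
    return "".join(cons[covered[0] : covered[-1] + 1])


def build_all_consensi(
    families: Sequence[RepeatFamily], reads: Mapping[str, str]
) -> None:
    for fam in families:
        fam.consensus = build_consensus(fam, reads)


# ---------------------------------------------------------------------------
# Curation: automated merge / split
# ---------------------------------------------------------------------------


def _infix_identity(query: str, target: str) -> float:
    """Identity of the best infix alignment of ``query`` within ``target``."""
    if not query or not target or len(query) > len(target):
        return 0.0
    res = edlib.align(query, target, mode="HW", task="distance")
    return 1.0 - res["editDistance"] / len(query)


def _consensus_pair_identity(a: str, b: str) -> tuple[float, str]:
    """Best identity of the shorter consensus within the longer, either
    orientation; returns (identity, orientation)."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    fwd = _infix_identity(short, long_)
    rev = _infix_identity(reverse_complement(short), long_)
    return (fwd, "same") if fwd >= rev else (rev, "opposite")


def _mean_member_identity(fam: RepeatFamily, reads: Mapping[str, str]) -> float:
    idents = []
    for e in fam.elements:
        seq = _element_seq(e, reads)
        target = fam.consensus
        if len(seq) <= len(target):
            idents.append(_infix_identity(seq, target))
        else:
            idents.append(_infix_identity(target, seq))
    return float(np.mean(idents)) if idents else 0.0


def _split_family(
    fam: RepeatFamily, reads: Mapping[str, str], threshold: float
) -> list[list[RepeatElement]]:
    seqs = [_element_seq(e, reads) for e in fam.elements]
    G = nx.Graph()
    G.add_nodes_from(range(len(seqs)))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            a, b = seqs[i], seqs[j]
            short, long_ = (a, b) if len(a) <= len(b) else (b, a)
            if _infix_identity(short, long_) >= threshold:
                G.add_edge(i, j)
    return [
        [fam.elements[i] for i in sorted(comp)]
        for comp in sorted(nx.connected_components(G), key=lambda c: (-len(c), min(c)))
    ]


def curate_families(
    families: Sequence[RepeatFamily],
    reads: Mapping[str, str],
    params: FamilyParams | None = None,
) -> list[RepeatFamily]:
    """Automated merge/split curation, iterated to a fixed point (<= 5 rounds).

    Merge: families whose consensi align at >= ``merge_identity`` over
    >= ``merge_coverage`` of the shorter consensus are unioned
    (transitively) and their consensus rebuilt.  Split: families whose mean
    element-to-consensus identity falls below ``split_identity_floor`` are
    re-clustered at ``min_hit_identity + 0.1``.
    """
    params = params or FamilyParams()
    fams = [RepeatFamily(f.family_id, list(f.elements), f.consensus) for f in families]
    for fam in fams:
        if not fam.consensus:
            fam.consensus = build_consensus(fam, reads)
    for _iteration in range(5):
        changed = False
        # ---- merge pass (transitive, via graph components)
        G = nx.Graph()
        G.add_nodes_from(range(len(fams)))
        flip: dict[tuple[int, int], str] = {}
        for i in range(len(fams)):
            for j in range(i + 1, len(fams)):
                a, b = fams[i].consensus, fams[j].consensus
                if not a or not b:
                    continue
                # infix alignment always covers the full shorter consensus,
                # so merge_coverage is satisfied whenever identity passes
                ident, orientation = _consensus_pair_identity(a, b)
                if ident >= params.merge_identity:
                    G.add_edge(i, j)
                    flip[(i, j)] = orientation
        merged: list[RepeatFamily] = []
        for comp in sorted(nx.connected_components(G), key=min):
            comp = sorted(comp)
            if len(comp) == 1:
                merged.append(fams[comp[0]])
                continue
            changed = True
            ref_i = comp[0]
            orient = {ref_i: "same"}
            sub = G.subgraph(comp)
            for u, v in nx.bfs_edges(sub, ref_i):
                o = flip.get((min(u, v), max(u, v)), "same")
                orient[v] = o if orient[u] == "same" else (
                    "same" if o == "opposite" else "opposite"
                )
            elements: list[RepeatElement] = []
            for i in comp:
                for e in fams[i].elements:
                    if orient[i] == "opposite":
                        e = RepeatElement(
                            e.read_id, e.start, e.end,
                            "+" if e.orientation == "-" else "-",
                        )
                    elements.append(e)
            fam = RepeatFamily("&".join(fams[i].family_id for i in comp), elements)
            fam.consensus = build_consensus(fam, reads)
            merged.append(fam)
        fams = merged
        # ---- split pass
        result: list[RepeatFamily] = []
        for fam in fams:
            if fam.count >= 2 and _mean_member_identity(fam, reads) < params.split_identity_floor:
                parts = _split_family(
                    fam, reads, min(0.99, params.min_hit_identity + 0.1)
                )
                if len(parts) > 1:
                    changed = True
                    for k, part in enumerate(parts, start=1):
                        nf = RepeatFamily(f"{fam.family_id}.{k}", part)
                        nf.consensus = build_consensus(nf, reads)
                        result.append(nf)
                    continue
            result.append(fam)
        fams = result
        if not changed:
            break
    else:
        logger.warning("curation did not converge within 5 iterations")
    return fams


# ---------------------------------------------------------------------------
# Exclusion screening, internal tandems, accounting
# ---------------------------------------------------------------------------


def screen_exclusion(
    families: Sequence[RepeatFamily],
    exclusion: Mapping[str, str] | None,
    params: FamilyParams | None = None,
) -> tuple[list[RepeatFamily], list[RepeatFamily]]:
    """Set aside families matching an exclusion set (e.g. rRNA screens).

    A family is excluded when its consensus aligns to any exclusion
    sequence at >= 80% identity over >= 100 bp (seeded local alignment,
    both orientations).  Returns (kept, excluded); with no exclusion set,
    everything is kept.
    """
    if exclusion is None:
        return list(families), []
    params = params or FamilyParams()
    screen = FamilyParams(
        word_size=params.word_size,
        min_hit_length=100,
        min_hit_identity=0.80,
        endpoint_tolerance=params.endpoint_tolerance,
        min_family_count=1,
    )
    kept, excluded = [], []
    for fam in families:
        hit = any(
            pairwise_local_hits("x", xseq, fam.family_id, fam.consensus, screen)
            for xseq in exclusion.values()
        )
        (excluded if hit else kept).append(fam)
    return kept, excluded


def internal_tandem_scan(
    consensus: str, detector: DetectorParams | None = None
) -> list[tuple[int, float]]:
    """Tandem structure inside a family consensus.

    Reuses the tandem caller with the unit ceiling raised to
    ``len(consensus) / 1.9`` (so a unit must still repeat ~2x) and reports
    each internal array as (unit bp, copies to one decimal).
    """
    if len(consensus) < 24:
        raise ValueError("consensus too short to scan (< 24 bp)")
    base = detector or DetectorParams()
    from dataclasses import replace

    params = replace(base, max_unit=max(base.max_unit, int(len(consensus) / 1.9)))
    arrays = call_tandem_arrays(consensus, params)
    return [(a.period, round(a.copy_number, 1)) for a in arrays]


def family_accounting(
    families: Sequence[RepeatFamily],
    surveyed_bp: int,
    sampling_fraction: float,
) -> pd.DataFrame:
    """Per-family abundance table with genome extrapolations.

    Columns: family_id, count, consensus_kb, gc_pct, total_length,
    genome_fraction_pct (total element bp / surveyed bp x 100) and
    extrapolated_genome_copies (count / sampling_fraction).  A TOTAL row
    sums lengths and fractions.
    """
    if not 0 < sampling_fraction <= 1:
        raise ValueError(f"sampling_fraction must be in (0,1], got {sampling_fraction}")
    rows = []
    for fam in families:
        rows.append(
            {
                "family_id": fam.family_id,
                "count": fam.count,
                "consensus_kb": fam.consensus_length / 1000,
                "gc_pct": fam.gc_pct,
                "total_length": fam.total_length,
                "genome_fraction_pct": fam.total_length / surveyed_bp * 100,
                "extrapolated_genome_copies": fam.count / sampling_fraction,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "family_id", "count", "consensus_kb", "gc_pct", "total_length",
            "genome_fraction_pct", "extrapolated_genome_copies",
        ],
    )
    total = {
        "family_id": "TOTAL",
        "count": df["count"].sum() if len(df) else 0,
        "consensus_kb": float("nan"),
        "gc_pct": float("nan"),
        "total_length": df["total_length"].sum() if len(df) else 0,
        "genome_fraction_pct": (
            df["genome_fraction_pct"].sum() if len(df) else 0.0
        ),
        "extrapolated_genome_copies": float("nan"),
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def category_totals(category_bp: Mapping[str, float], surveyed_bp: int) -> pd.DataFrame:
    """Grand-total accounting over repeat categories.

    Given summed lengths per category, returns per-category percentages of
    the surveyed length plus a TOTAL row (combined bp and percentage).
    """
    rows = [
        {"category": k, "length_bp": v, "pct": v / surveyed_bp * 100}
        for k, v in category_bp.items()
    ]
    total_bp = sum(category_bp.values())
    rows.append(
        {"category": "TOTAL", "length_bp": total_bp, "pct": total_bp / surveyed_bp * 100}
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# One-call pipeline
# ---------------------------------------------------------------------------


def discover_families(
    masked_reads: Mapping[str, str],
    params: FamilyParams | None = None,
    exclusion: Mapping[str, str] | None = None,
) -> list[RepeatFamily]:
    """Full family pipeline: search, define, cluster, consensus, curate,
    count-filter, screen, internal tandem scan."""
    params = params or FamilyParams()
    hits = allpairs_search(masked_reads, params)
    elements = define_elements(hits, params)
    families = cluster_families(elements, hits, params)
    build_all_consensi(families, masked_reads)
    families = curate_families(families, masked_reads, params)
    families = filter_families(families, params)
    families, _ = screen_exclusion(families, exclusion, params)
    for fam in families:
        if len(fam.consensus) >= 24:
            fam.internal_tandems = internal_tandem_scan(fam.consensus)
    return families
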