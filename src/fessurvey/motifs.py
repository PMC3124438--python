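"""Canonical microsatellite motif classes.

A tandem-repeat unit read off a sequence is an arbitrary representative of
its equivalence class: the same locus can be written starting at any phase
of the unit and on either strand, so e.g. TC, CT, GA and AG all name one
dinucleotide class.  The canonical label of a motif is the lexicographically
smallest string (A < C < G < T) among all rotations of the motif and all
rotations of its reverse complement; under this rule the four dinucleotide
classes are AC, AG, AT and CG, and the arthropod telomere unit TTAGG
canonicalizes to AACCT.

Motifs whose repetition is itself periodic (e.g. ATAT, unit 4 but period 2)
are reduced to their shortest period before canonicalization, so no class
label is a repetition of a shorter unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class CanonicalMotif:
    """A motif class representative: its label and unit length in bp."""

    label: str
    unit: int

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def shortest_period(motif: str) -> str:
    """Smallest repeating unit of ``motif`` (``motif`` itself if aperiodic)."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return motif[:p]
    return motif


def _rotations(s: str):
    return (s[i:] + s[:i] for i in range(len(s)))


@lru_cache(maxsize=65536)
def _canonical_label(motif: str) -> str:
    motif = shortest_period(motif)
    rc = reverse_complement(motif)
    return min(min(_rotations(motif)), min(_rotations(rc)))


def canonical_motif(motif: str) -> CanonicalMotif:
    """Map a repeat unit to its canonical class.

    Parameters
    ----------
    motif:
        Repeat unit over {A,C,G,T}, 1-6 bp.  Lower case accepted.

    Returns
    -------
    CanonicalMotif
        The class label (invariant under rotation and reverse
        complementation, reduced to the shortest period) and its unit
        length.

    Examples
    --------
    >>> canonical_motif("TC").label
    'AG'
    >>> canonical_motif("TTAGG").label
    'AACCT'
    """
    motif = motif.upper()
    if not motif or len(motif) > 6:
        raise ValueError(f"motif length must be 1-6 bp, got {len(motif)}")
    if not set(motif) <= _VALID:
        bad = sorted(set(motif) - _VALID)
        raise ValueError(f"motif contains non-ACGT characters: {bad}")
    label = _canonical_label(motif)
    return CanonicalMotif(label=label, unit=len(label))


def enumerate_classes(unit: int) -> list[CanonicalMotif]:
    """All canonical motif classes of exactly ``unit`` bp.

    Classes whose label has a shorter period (e.g. the would-be
    tetranucleotide ATAT) belong to the shorter unit and are excluded.
    There are 2 mononucleotide classes (A, C), 4 dinucleotide classes
    (AC, AG, AT, CG) and 10 trinucleotide classes.
    """
    if not 1 <= unit <= 6:
        raise ValueError(f"unit must be in 1..6, got {unit}")
    labels = set()
    for idx in range(4**unit):
        s, k = [], idx
        for _ in range(unit):
            s.append("ACGT"[k % 4])
            k //= 4
        motif = "".join(s)
        if shortest_period(motif) != motif:
            continue
        label = _canonical_label(motif)
        if len(label) == unit:
            labels.add(label)
    return [CanonicalMotif(label=l, unit=unit) for l in sorted(labels)]
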