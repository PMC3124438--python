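"""Synthetic fosmid-end read simulator with ground-truth annotations.

Emulates a genome-survey read set: reads of 100-861 bp (mean ~531 bp, a
truncated-normal length model), i.i.d. background bases at a configurable
GC content, and planted features of two kinds -- microsatellite arrays
(a unit of 1-6 bp repeated a configurable number of times, with per-base
substitution and indel rates) and interspersed repeat families (copies of a
family consensus mutated at a configurable divergence, reverse-complemented
with probability 0.5, optionally truncated).  Every planted interval is
recorded in a truth set with enough detail (template coordinates,
orientation, and the exact mutation operations applied) to reconstruct the
pristine repeat, so detector and clustering stages can be scored against
known answers.

All randomness flows from the single config seed; identical configs produce
byte-identical FASTA and truth output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from fessurvey.motifs import reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SsrPlant:
    """A microsatellite to plant: ``motif`` repeated ``copies`` times."""

    motif: str
    copies: float
    per_base_mutation: float = 0.0
    per_base_indel: float = 0.0
    n_loci: int = 1

    def __post_init__(self) -> None:
        if not 1 <= len(self.motif) <= 6 or set(self.motif) - set("ACGT"):
            raise ValueError(f"SsrPlant.motif must be 1-6 bp over ACGT: {self.motif!r}")
        if self.copies * len(self.motif) < 12:
            raise ValueError(
                f"SsrPlant: copies x unit must give an array >= 12 bp "
                f"({self.copies} x {len(self.motif)} bp)"
            )
        if self.n_loci < 1:
            raise ValueError("SsrPlant.n_loci must be >= 1")

    @property
    def length(self) -> int:
        return round(self.copies * len(self.motif))


@dataclass(frozen=True)
class FamilyPlant:
    """An interspersed repeat family: ``n_copies`` of a random consensus."""

    family_id: str
    consensus_length: int
    n_copies: int
    divergence: float = 0.0
    truncation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError("FamilyPlant.n_copies must be >= 1")
        if not 0 <= self.divergence <= 0.4:
            raise ValueError(f"FamilyPlant.divergence must be in [0, 0.4]: {self.divergence}")
        if self.consensus_length < 100:
            raise ValueError("FamilyPlant.consensus_length must be >= 100 bp")
        if not 0 <= self.truncation_fraction <= 1:
            raise ValueError("FamilyPlant.truncation_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    n_reads: int = 1000
    length_min: int = 100
    length_max: int = 861
    length_mean: int = 531
    gc_background: float = 0.4588
    seed: int = 0
    planted_ssrs: tuple[SsrPlant, ...] = ()
    planted_families: tuple[FamilyPlant, ...] = ()

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError(f"n_reads must be positive, got {self.n_reads}")
        if not 0 < self.length_min <= self.length_mean <= self.length_max:
            raise ValueError(
                "length_min/length_mean/length_max must satisfy "
                f"0 < min <= mean <= max, got {self.length_min}/"
                f"{self.length_mean}/{self.length_max}"
            )
        if not 0 <= self.gc_background <= 1:
            raise ValueError(f"gc_background must be in [0,1], got {self.gc_background}")


@dataclass
class TruthRecord:
    """One planted interval: 0-based half-open coordinates on its read."""

    read_id: str
    start: int
    end: int
    kind: str  # "ssr" | "family"
    label: str
    params: dict


@dataclass
class TruthSet:
    records: list[TruthRecord] = field(default_factory=list)
    family_consensi: dict[str, str] = field(default_factory=dict)


def _draw_lengths(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Truncated normal: SD = (max-min)/6, redrawn until inside [min, max]."""
    lo, hi, mu = config.length_min, config.length_max, config.length_mean
    if lo == hi:
        return np.full(config.n_reads, lo, dtype=np.int64)
    sd = (hi - lo) / 6.0
    out = np.empty(config.n_reads, dtype=np.int64)
    filled = 0
    while filled < config.n_reads:
        draw = rng.normal(mu, sd, size=2 * (config.n_reads - filled))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, config.n_reads - filled)
        out[filled : filled + take] = np.round(ok[:take]).astype(np.int64)
        filled += take
    return out


def _random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def generate_background(config: SimulationConfig) -> dict[str, str]:
    """Generate the background read set (no planted features).

    Reads are named read00001..; bases are i.i.d. at the configured GC.
    """
    rng = np.random.default_rng(config.seed)
    lengths = _draw_lengths(config, rng)
    width = max(5, len(str(config.n_reads)))
    return {
        f"read{i + 1:0{width}d}": _random_seq(int(L), config.gc_background, rng)
        for i, L in enumerate(lengths)
    }


# ---------------------------------------------------------------------------
# Mutation machinery (replayable operation lists)
# ---------------------------------------------------------------------------


def mutate_sequence(
    template: str,
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> tuple[str, list]:
    """Mutate ``template``; return (realized, ops).

    Ops reference template positions and replay deterministically through
    :func:`apply_ops`: ("sub", pos, new_base), ("del", pos),
    ("ins", pos, base) -- insertion after template position ``pos``.
    """
    out: list[str] = []
    ops: list = []
    for pos, base in enumerate(template):
        if indel_rate and rng.random() < indel_rate:
            if rng.random() < 0.5:
                ops.append(("del", pos))
                continue
            ins = str(rng.choice(_BASES))
            if sub_rate and rng.random() < sub_rate:
                new = str(rng.choice([b for b in "ACGT" if b != base]))
                ops.append(("sub", pos, new))
                base = new
            out.append(base)
            ops.append(("ins", pos, ins))
            out.append(ins)
            continue
        if sub_rate and rng.random() < sub_rate:
            new = str(rng.choice([b for b in "ACGT" if b != base]))
            ops.append(("sub", pos, new))
            base = new
        out.append(base)
    return "".join(out), ops


def apply_ops(template: str, ops: Sequence) -> str:
    """Replay a mutation op list against its template."""
    by_pos: dict[int, list] = {}
    for op in ops:
        by_pos.setdefault(op[1], []).append(op)
    out: list[str] = []
    for pos, base in enumerate(template):
        deleted = False
        ins_after: list[str] = []
        for op in by_pos.get(pos, ()):
            if op[0] == "del":
                deleted = True
            elif op[0] == "sub":
                base = op[2]
            else:
                ins_after.append(op[2])
        if not deleted:
            out.append(base)
        out.extend(ins_after)
    return "".join(out)


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------


def _place(
    occupied: dict[str, list[tuple[int, int]]],
    reads: dict[str, str],
    length: int,
    rng: np.random.Generator,
    what: str,
) -> tuple[str, int]:
    """Pick a read and start where a ``length``-bp plant fits without
    touching previous plants."""
    ids = list(reads)
    for _ in range(200):
        rid = ids[int(rng.integers(len(ids)))]
        room = len(reads[rid]) - length
        if room < 0:
            continue
        start = int(rng.integers(room + 1))
        end = start + length
        if all(end <= s or start >= e for s, e in occupied[rid]):
            occupied[rid].append((start, end))
            return rid, start
    raise ValueError(f"no read can accommodate plant: {what} ({length} bp)")


def plant_features(
    reads: dict[str, str], config: SimulationConfig
) -> tuple[dict[str, str], TruthSet]:
    """Plant the configured SSRs and family copies into a background set.

    Planted sequence replaces background bases in place (read lengths are
    preserved).  Returns the modified reads and the truth set.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    reads = dict(reads)
    truth = TruthSet()
    occupied: dict[str, list[tuple[int, int]]] = {rid: [] for rid in reads}

    for plant in config.planted_ssrs:
        unit = plant.motif
        template = (unit * (plant.length // len(unit) + 1))[: plant.length]
        for _ in range(plant.n_loci):
            realized, ops = mutate_sequence(
                template, plant.per_base_mutation, plant.per_base_indel, rng
            )
            rid, start = _place(occupied, reads, len(realized), rng, f"ssr {unit}")
            seq = reads[rid]
            reads[rid] = seq[:start] + realized + seq[start + len(realized):]
            truth.records.append(
                TruthRecord(
                    read_id=rid,
                    start=start,
                    end=start + len(realized),
                    kind="ssr",
                    label=unit,
                    params={
                        "motif": unit,
                        "copies": plant.copies,
                        "template_length": len(template),
                        "ops": ops,
                    },
                )
            )

    for fam in config.planted_families:
        consensus = _random_seq(fam.consensus_length, config.gc_background, rng)
        truth.family_consensi[fam.family_id] = consensus
        n_trunc = round(fam.truncation_fraction * fam.n_copies)
        for i in range(fam.n_copies):
            cs, ce = 0, fam.consensus_length
            if i < n_trunc:
                keep = 0.4 + 0.4 * rng.random()  # keep 40-80% of the consensus
                span = max(100, int(keep * fam.consensus_length))
                if rng.random() < 0.5:
                    ce = cs + span
                else:
                    cs = ce - span
            fragment = consensus[cs:ce]
            realized, ops = mutate_sequence(fragment, fam.divergence, 0.0, rng)
            orientation = "-" if rng.random() < 0.5 else "+"
            final = reverse_complement(realized) if orientation == "-" else realized
            rid, start = _place(
                occupied, reads, len(final), rng, f"family {fam.family_id}"
            )
            seq = reads[rid]
            reads[rid] = seq[:start] + final + seq[start + len(final):]
            truth.records.append(
                TruthRecord(
                    read_id=rid,
                    start=start,
                    end=start + len(final),
                    kind="family",
                    label=fam.family_id,
                    params={
                        "family_id": fam.family_id,
                        "orientation": orientation,
                        "cons_start": cs,
                        "cons_end": ce,
                        "divergence": fam.divergence,
                        "ops": ops,
                    },
                )
            )
    truth.records.sort(key=lambda r: (r.read_id, r.start))
    return reads, truth


def simulate_reads(config: SimulationConfig) -> tuple[dict[str, str], TruthSet]:
    """Background generation followed by feature planting."""
    reads = generate_background(config)
    return plant_features(reads, config)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def reads_to_fasta(reads: dict[str, str], width: int = 70) -> str:
    chunks = []
    for rid, seq in reads.items():
        chunks.append(f">{rid}")
        for i in range(0, len(seq), width):
            chunks.append(seq[i : i + width])
    return "\n".join(chunks) + "\n"


def truth_to_tsv(truth: TruthSet) -> str:
    """Tab-separated truth: read_id, start, end, kind, label, params JSON."""
    lines = ["read_id\tstart\tend\tkind\tlabel\tparams"]
    for r in truth.records:
        lines.append(
            f"{r.read_id}\t{r.start}\t{r.end}\t{r.kind}\t{r.label}\t"
            + json.dumps(r.params, separators=(",", ":"))
        )
    return "\n".join(lines) + "\n"


def truth_from_tsv(text: str) -> TruthSet:
    truth = TruthSet()
    for line in text.strip().splitlines()[1:]:
        rid, start, end, kind, label, params = line.split("\t")
        truth.records.append(
            TruthRecord(rid, int(start), int(end), kind, label, json.loads(params))
        )
    return truth
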