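"""Microsatellite landscape statistics.

Aggregates called tandem arrays into the survey-level characterization a
genome-survey study reports: per-motif-class counts, summed base pairs,
length statistics, relative abundance (RA, a class's bp as a percentage of
all microsatellite bp), relative frequency (RF, a class's locus count as a
percentage of all loci), overall microsatellite density (kb of surveyed
sequence per locus), length-class histograms (L1: 12-20 bp, L2: 21-40 bp,
... L11: >201 bp), and the genomic-vs-transcript partition comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from fessurvey.tandem import TandemArray

LENGTH_CLASS_EDGES = [
    (12, 20), (21, 40), (41, 60), (61, 80), (81, 100), (101, 120),
    (121, 140), (141, 160), (161, 180), (181, 200),
]  # L11 is > 201 bp (open-ended)
LENGTH_CLASS_LABELS = [f"L{i}" for i in range(1, 12)]


@dataclass
class LandscapeReport:
    per_motif: pd.DataFrame
    per_unit: pd.DataFrame
    total_loci: int
    total_bases: int
    surveyed_bp: int
    genome_pct: float
    density_kb: float
    mean_locus_length: float
    at_content_pct: float


def _arrays_frame(arrays: Iterable[TandemArray]) -> pd.DataFrame:
    rows = [
        {
            "read_id": a.read_id,
            "motif": a.canonical_motif,
            "unit": a.period,
            "length": a.end - a.start,
        }
        for a in arrays
    ]
    return pd.DataFrame(rows, columns=["read_id", "motif", "unit", "length"])


def summarize_by_motif(
    arrays: Sequence[TandemArray], total_reads: int, surveyed_bp: int
) -> pd.DataFrame:
    """Per-canonical-motif summary table.

    One row per motif class present, sorted by unit length then label, with
    columns: motif, unit, counts, n_fes (reads containing >= 1 locus of the
    class), pct_fes, bases, pct_bases, max_length, mean_length, std_length
    (population SD), mean_repeat_no (mean_length / unit), ra_pct, rf_pct.
    """
    if surveyed_bp <= 0:
        raise ValueError(f"surveyed_bp must be positive, got {surveyed_bp}")
    df = _arrays_frame(arrays)
    if df.empty:
        raise ValueError("no arrays to summarize")
    total_loci = len(df)
    total_bases = int(df["length"].sum())
    grouped = df.groupby("motif", sort=False)
    out = pd.DataFrame(
        {
            "unit": grouped["unit"].first(),
            "counts": grouped.size(),
            "n_fes": grouped["read_id"].nunique(),
            "bases": grouped["length"].sum(),
            "max_length": grouped["length"].max(),
            "mean_length": grouped["length"].mean(),
            "std_length": grouped["length"].std(ddof=0).fillna(0.0),
        }
    )
    out["pct_fes"] = out["n_fes"] / total_reads * 100
    out["pct_bases"] = out["bases"] / surveyed_bp * 100
    out["mean_repeat_no"] = out["mean_length"] / out["unit"]
    out["ra_pct"] = out["bases"] / total_bases * 100
    out["rf_pct"] = out["counts"] / total_loci * 100
    out = out.reset_index().sort_values(["unit", "motif"]).reset_index(drop=True)
    return out[
        [
            "motif", "unit", "counts", "n_fes", "pct_fes", "bases", "pct_bases",
            "max_length", "mean_length", "std_length", "mean_repeat_no",
            "ra_pct", "rf_pct",
        ]
    ]


def per_unit_aggregate(per_motif: pd.DataFrame) -> pd.DataFrame:
    """RF/RA aggregated over motif classes of each unit length."""
    agg = per_motif.groupby("unit")[["counts", "bases", "rf_pct", "ra_pct"]].sum()
    return agg.reset_index()


def density(total_loci: int, surveyed_bp: int) -> float:
    """Microsatellite density as kb of surveyed sequence per locus.

    >>> density(8441, 11114786)
    1.32
    """
    if total_loci <= 0:
        raise ValueError("density undefined for zero loci")
    return round(surveyed_bp / total_loci / 1000, 2)


def length_class(length: int) -> str:
    """Assign one locus length to its L1..L11 bin."""
    if length < 12:
        raise ValueError(f"locus length {length} below the 12-bp detection floor")
    for label, (lo, hi) in zip(LENGTH_CLASS_LABELS, LENGTH_CLASS_EDGES):
        if lo <= length <= hi:
            return label
    return "L11"


def length_class_histogram(arrays: Sequence[TandemArray]) -> pd.DataFrame:
    """Per-motif histogram over the L1..L11 length classes."""
    df = _arrays_frame(arrays)
    if df.empty:
        raise ValueError("no arrays to bin")
    df["length_class"] = df["length"].map(length_class)
    hist = (
        df.groupby(["motif", "length_class"]).size().unstack(fill_value=0)
        .reindex(columns=LENGTH_CLASS_LABELS, fill_value=0)
    )
    return hist.reset_index()


def at_content_of_arrays(
    arrays: Sequence[TandemArray], reads: Mapping[str, str]
) -> float:
    """A/T percentage of the bases inside detected microsatellite spans."""
    at = total = 0
    for a in arrays:
        span = reads[a.read_id][a.start : a.end].upper()
        for b in span:
            if b in "AT":
                at += 1
            if b in "ACGT":
                total += 1
    if total == 0:
        raise ValueError("no unambiguous bases inside arrays")
    return at / total * 100


def build_report(
    arrays: Sequence[TandemArray],
    total_reads: int,
    surveyed_bp: int,
    reads: Mapping[str, str] | None = None,
) -> LandscapeReport:
    """Full landscape report: per-motif table, unit aggregates, totals."""
    per_motif = summarize_by_motif(arrays, total_reads, surveyed_bp)
    total_loci = int(per_motif["counts"].sum())
    total_bases = int(per_motif["bases"].sum())
    return LandscapeReport(
        per_motif=per_motif,
        per_unit=per_unit_aggregate(per_motif),
        total_loci=total_loci,
        total_bases=total_bases,
        surveyed_bp=surveyed_bp,
        genome_pct=total_bases / surveyed_bp * 100,
        density_kb=density(total_loci, surveyed_bp),
        mean_locus_length=total_bases / total_loci,
        at_content_pct=(
            at_content_of_arrays(arrays, reads) if reads is not None else float("nan")
        ),
    )


def compare_partitions(
    arrays_a: Sequence[TandemArray],
    surveyed_a: int,
    arrays_b: Sequence[TandemArray],
    surveyed_b: int,
) -> pd.DataFrame:
    """Compare RA per motif between two sequence partitions.

    Typical use: genomic reads vs transcribed (EST-like) reads.  Returns a
    per-motif table of RA% in each partition plus a two-row totals block
    carried in ``DataFrame.attrs['bp_per_mb']``: microsatellite bp per Mb
    of each partition, (sum locus bp / surveyed bp) x 10^6.
    """
    if not arrays_a or not arrays_b:
        raise ValueError("both partitions must contain at least one array")
    tables = []
    for name, arrays, surveyed in (
        ("a", arrays_a, surveyed_a),
        ("b", arrays_b, surveyed_b),
    ):
        df = _arrays_frame(arrays)
        bases = df.groupby("motif")["length"].sum()
        tables.append((bases / bases.sum() * 100).rename(f"ra_pct_{name}"))
    out = pd.concat(tables, axis=1).fillna(0.0).reset_index()
    out["ra_diff"] = out["ra_pct_a"] - out["ra_pct_b"]
    out.attrs["bp_per_mb"] = {
        "a": sum(a.end - a.start for a in arrays_a) / surveyed_a * 1e6,
        "b": sum(a.end - a.start for a in arrays_b) / surveyed_b * 1e6,
    }
    return out
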