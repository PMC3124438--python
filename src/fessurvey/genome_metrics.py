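"""Genome sizing and survey-level extrapolation.

Flow-cytometry genome sizing works by ratio: nuclei of the study organism
and of a standard of known DNA content (human lymphocyte, 3.50 pg per
nucleus) are stained with an intercalating dye and the positions of their
G1 fluorescence peaks compared.  The ratio of peak positions is the ratio
of DNA contents, so ``pg = ratio x standard_pg``.  Conversion to base
pairs defaults to ``bp = ratio x reference_bp`` with a 3.0 Gb human
reference; the physical constant 0.978 x 10^9 bp/pg is available as an
alternative (``pg_conversion=True``).

The survey calculators turn a clone library and a sparse read sample into
genome-scale numbers: library coverage (clones x insert / genome), the
sampling fraction (surveyed bp / genome bp), and the gene count and density
implied by an observed coding fraction and an assumed mean gene size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

HUMAN_STANDARD_PG = 3.50
HUMAN_REFERENCE_BP = 3.0e9
BP_PER_PG = 0.978e9


@dataclass
class FlowHistogram:
    """Event counts per fluorescence channel."""

    channel: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        self.channel = np.asarray(self.channel, dtype=float)
        self.count = np.asarray(self.count, dtype=float)
        if self.channel.shape != self.count.shape:
            raise ValueError("channel and count must have equal length")
        if (self.count < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_events(self) -> int:
        return int(self.count.sum())

    @classmethod
    def from_text(cls, text: str) -> "FlowHistogram":
        """Parse two-column (channel, count) whitespace/CSV text."""
        ch, ct = [], []
        for line in text.strip().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            ch.append(float(parts[0]))
            ct.append(float(parts[1]))
        return cls(np.array(ch), np.array(ct))


@dataclass
class GenomeSizeEstimate:
    ratio: float
    pg_per_nucleus: float
    bp_haploid: float
    standard_pg: float
    reference_bp: float


def detect_g1_peak(
    hist: FlowHistogram,
    smoothing_window: int = 5,
    gate: tuple[float, float] | None = None,
) -> float:
    """Locate the G1 peak channel of a fluorescence histogram.

    The histogram is smoothed with a moving average, the modal bin found
    (within ``gate`` if given), and the sub-bin position refined as the
    count-weighted centroid over the peak's full-width-at-half-maximum
    region.  If a second local maximum reaches within 5% of the peak height
    outside the peak's FWHM region, the histogram is considered ambiguous
    and an explicit gate is required.
    """
    if hist.n_events < 500:
        raise ValueError(f"need >= 500 events, histogram has {hist.n_events}")
    counts = hist.count
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        smooth = np.convolve(counts, kernel, mode="same")
    else:
        smooth = counts.astype(float)
    mask = np.ones_like(smooth, dtype=bool)
    if gate is not None:
        mask = (hist.channel >= gate[0]) & (hist.channel <= gate[1])
        if not mask.any():
            raise ValueError("gate excludes every channel")
    gated = np.where(mask, smooth, -np.inf)
    peak_idx = int(np.argmax(gated))
    peak_h = smooth[peak_idx]
    # FWHM region around the modal bin
    half = peak_h / 2
    lo = peak_idx
    while lo > 0 and smooth[lo - 1] >= half:
        lo -= 1
    hi = peak_idx
    while hi < len(smooth) - 1 and smooth[hi + 1] >= half:
        hi += 1
    if gate is None:
        outside = smooth.copy()
        outside[lo : hi + 1] = -np.inf
        local_max = (
            (outside[1:-1] >= outside[:-2]) & (outside[1:-1] >= outside[2:])
        )
        rivals = outside[1:-1][local_max]
        if rivals.size and rivals.max() >= 0.95 * peak_h:
            raise ValueError(
                "multimodal histogram: two peaks within 5% height; "
                "pass an explicit gate=(lo, hi)"
            )
    region = slice(lo, hi + 1)
    weights = counts[region]
    if weights.sum() == 0:
        return float(hist.channel[peak_idx])
    return float(np.average(hist.channel[region], weights=weights))


def estimate_genome_size(
    sample_peak: float,
    standard_peak: float,
    standard_pg: float = HUMAN_STANDARD_PG,
    reference_bp: float = HUMAN_REFERENCE_BP,
    pg_conversion: bool = False,
) -> GenomeSizeEstimate:
    """Genome size from the G1 peak ratio against a standard.

    >>> est = estimate_genome_size(0.722, 1.0)
    >>> round(est.pg_per_nucleus, 2)
    2.53
    """
    if sample_peak <= 0 or standard_peak <= 0:
        raise ValueError("peak positions must be positive")
    ratio = sample_peak / standard_peak
    pg = ratio * standard_pg
    bp = pg * BP_PER_PG if pg_conversion else ratio * reference_bp
    return GenomeSizeEstimate(
        ratio=ratio,
        pg_per_nucleus=pg,
        bp_haploid=bp,
        standard_pg=standard_pg,
        reference_bp=reference_bp,
    )


def simulate_flow_histogram(
    peak_channel: float,
    cv: float = 0.03,
    n_events: int = 5000,
    n_channels: int = 1024,
    rng: np.random.Generator | int | None = None,
) -> FlowHistogram:
    """Synthetic single-population histogram: Gaussian G1 peak.

    Events are drawn from N(peak_channel, cv x peak_channel) and binned
    into integer channels; emulates a 3,000-10,000 event acquisition.
    """
    rng = np.random.default_rng(rng)
    events = rng.normal(peak_channel, cv * peak_channel, size=n_events)
    counts, _ = np.histogram(events, bins=np.arange(n_channels + 1))
    return FlowHistogram(np.arange(n_channels) + 0.5, counts.astype(float))


def library_coverage(n_clones: float, insert_bp: float, genome_bp: float) -> float:
    """Fold-coverage of a clone library: clones x insert / genome.

    >>> round(library_coverage(288000, 40000, 2.17e9), 1)
    5.3
    """
    if genome_bp <= 0:
        raise ValueError("genome size must be positive")
    if n_clones <= 0 or insert_bp <= 0:
        raise ValueError("clone count and insert size must be positive")
    return n_clones * insert_bp / genome_bp


def gene_metrics(
    coding_fraction: float,
    genome_bp: float,
    gene_size_lo: float,
    gene_size_hi: float,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Gene count and density ranges from a coding fraction.

    count = coding_fraction x genome_bp / gene_size, evaluated at both
    gene-size bounds; density = genome_bp / count (bp per gene).  Returns
    ((count_at_hi_size, count_at_lo_size), (density_lo, density_hi)) with
    counts ordered low-to-high.
    """
    if not 0 < coding_fraction < 1:
        raise ValueError("coding_fraction must be in (0,1)")
    if gene_size_lo <= 0 or gene_size_lo > gene_size_hi:
        raise ValueError("need 0 < gene_size_lo <= gene_size_hi")
    count_hi = coding_fraction * genome_bp / gene_size_lo
    count_lo = coding_fraction * genome_bp / gene_size_hi
    density_lo = genome_bp / count_hi
    density_hi = genome_bp / count_lo
    return (count_lo, count_hi), (density_lo, density_hi)


def gc_content(reads) -> float:
    """GC percentage over a read set; N excluded from the denominator."""
    seqs = reads.values() if hasattr(reads, "values") else reads
    gc = total = 0
    for seq in seqs:
        for b in seq.upper():
            if b in "GC":
                gc += 1
            if b in "ACGT":
                total += 1
    if total == 0:
        raise ValueError("no unambiguous bases in read set")
    return gc / total * 100


def sampling_fraction(surveyed_bp: float, genome_bp: float) -> float:
    if not 0 < surveyed_bp < genome_bp:
        raise ValueError("need 0 < surveyed_bp < genome_bp")
    return surveyed_bp / genome_bp


def mean_masked_fraction(masked_bp: Sequence[float], surveyed_bp: float) -> float:
    """Mean masked percentage over repeat databases: mean(bp_i / surveyed) x 100.

    Reproduces the ratio arithmetic of a masked-length table (e.g. the mean
    interspersed-repeat fraction over two reference databases).
    """
    if surveyed_bp <= 0:
        raise ValueError("surveyed_bp must be positive")
    fractions = [bp / surveyed_bp for bp in masked_bp]
    return float(np.mean(fractions)) * 100


def survey_summary(
    reads,
    genome_bp: float,
    n_clones: float,
    insert_bp: float,
    coding_fraction: float,
    gene_size_lo: float,
    gene_size_hi: float,
) -> dict:
    """Survey-level key-value summary (coverage, sampling, genes, GC)."""
    surveyed_bp = sum(len(s) for s in (reads.values() if hasattr(reads, "values") else reads))
    n_reads = len(reads)
    (count_lo, count_hi), (density_lo, density_hi) = gene_metrics(
        coding_fraction, genome_bp, gene_size_lo, gene_size_hi
    )
    return {
        "n_reads": n_reads,
        "surveyed_bp": surveyed_bp,
        "gc_pct": gc_content(reads),
        "coverage_fold": library_coverage(n_clones, insert_bp, genome_bp),
        "sampling_fraction": sampling_fraction(surveyed_bp, genome_bp),
        "gene_count_lo": count_lo,
        "gene_count_hi": count_hi,
        "gene_density_kb_lo": density_lo / 1000,
        "gene_density_kb_hi": density_hi / 1000,
    }
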