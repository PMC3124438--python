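"""Canonical motif classes and a survey-style microsatellite landscape.

A repeat unit read off either strand at any phase names the same class:
TC, CT, GA and AG are all the AG class, and the arthropod telomere unit
TTAGG canonicalizes to AACCT.  The landscape report aggregates detected
arrays into the per-class table a genome survey publishes: counts, summed
bases, length statistics, relative abundance (RA, % of microsatellite bp)
and relative frequency (RF, % of loci).
"""

from fessurvey.motifs import canonical_motif, enumerate_classes
from fessurvey.landscape import build_report, density
from fessurvey.simulate import SimulationConfig, SsrPlant, simulate_reads
from fessurvey.tandem import scan_reads

for raw in ("TC", "GA", "TTAGG", "GGC"):
    print(f"canonical({raw}) = {canonical_motif(raw).label}")
print("dinucleotide classes:", [c.label for c in enumerate_classes(2)])
print("trinucleotide classes:", len(enumerate_classes(3)))
print()

config = SimulationConfig(
    n_reads=150,
    seed=7,
    planted_ssrs=(
        SsrPlant("AG", 40, 0.03, n_loci=15),
        SsrPlant("AAT", 25, 0.03, n_loci=8),
        SsrPlant("AACCT", 30, 0.0, n_loci=3),
    ),
)
reads, _ = simulate_reads(config)
arrays = scan_reads(reads)
surveyed = sum(len(s) for s in reads.values())
report = build_report(arrays, len(reads), surveyed, reads)

cols = ["motif", "counts", "bases", "mean_length", "mean_repeat_no", "ra_pct", "rf_pct"]
print(report.per_motif[cols].round(2).to_string(index=False))
print()
print(f"total loci:        {report.total_loci}")
print(f"genome fraction:   {report.genome_pct:.2f}% of {surveyed} bp")
print(f"density:           1 locus per {density(report.total_loci, surveyed):.2f} kb")
print(f"A/T content of loci: {report.at_content_pct:.1f}%")
# RA and RF sum to 100% across classes; mean_repeat_no is mean length
# divided by the unit size.
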