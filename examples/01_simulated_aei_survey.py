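"""Simulate per-tissue AEI experiments and run the full calling pipeline.

Each preset emulates one gene/tissue condition of the survey: heterozygous
gDNA reference rows (expected 1:1, skewed only by assay bias) plus cDNA rows
drawn from that condition's imbalance archetype.  The pipeline standardises
every cDNA allelic ratio by the gene's mean gDNA ratio, applies the 60:40
rule, and summarises folded ratios per direction with a Welch t-test
against the gDNA folded ratios.
"""
import pandas as pd

from pyroaei import MeasurementTable, run_aei, simulate_experiment

tables = []
for preset in ["lep-liver", "igf2-pituitary", "ccl2-kidney", "null"]:
    table, _truth = simulate_experiment(preset, seed=5)
    tables.append(table)

measurements = MeasurementTable.concat(tables)
calls, summaries = run_aei(measurements)

pd.set_option("display.width", 140)
print(summaries.round(3).to_string(index=False))
print()
print(
    "Each row mirrors one gene/tissue: counts of samples imbalanced toward\n"
    "allele A or B, the per-direction mean +/- SD of folded (higher/lower)\n"
    "ratios, the overall mean folded ratio over ALL samples, and the Welch\n"
    "p-value vs gDNA.  Stars: * p<0.05, ** p<0.01, *** p<0.001.  Expect the\n"
    "IGF2 pituitary row near-monoallelic (mean ~30), LEP liver one-directional\n"
    "(~4 toward allele A = C), CCL2 kidney weak, and NULL balanced."
)
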