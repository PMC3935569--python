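"""Genome-wide eQTL mapping with cis/trans classification.

Maps every e-trait by composite interval mapping, classifies each eQTL by
whether the e-trait's own locus sits inside the 1.5-LOD-drop support
interval, and prints the per-chromosome summary with size-based
expectations and standardized residues.
"""

import eqtlnet as eq
from eqtlnet.pipeline import classify_catalog, summarize_by_chromosome

cfg = eq.SimConfig(
    n_lines=200, n_chromosomes=6, n_bins=150, genome_mb=150.0, genome_cm=700.0,
    n_etraits=250, n_cis=60, regulators=[eq.RegulatorSpec(n_targets=150)],
    n_traits=0, trait_specs=[], seed=3,
)
binmap, G, truth, E, P = eq.simulate_population(cfg)

catalog = eq.map_all_etraits(E, G, binmap, threshold=4.95)
classify_catalog(catalog, E.anchors)
total = len(catalog.records)
print(f"{total} eQTLs: {catalog.n_cis} cis ({catalog.n_cis/total*100:.1f}%), "
      f"{catalog.n_trans} trans ({catalog.n_trans/total*100:.1f}%)")

summary = summarize_by_chromosome(catalog, binmap)
print(summary[["chrom", "n_eqtl", "n_cis", "n_trans", "size_Mb", "expected_physical",
               "SR_physical"]].round(1).to_string(index=False))
print(f"chi2 (physical sizes) = {summary.attrs['chi2_physical']:.1f}")
# |SR| > 2.33 marks chromosomes with significantly more or fewer eQTLs than
# their physical size predicts (P < 0.01); the regulator's chromosome
# stands out because its hotspot collects the planted trans-eQTLs.
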