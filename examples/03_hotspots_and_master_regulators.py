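"""Trans-eQTL hotspot screen and master-regulator nomination.

Flags bins whose trans-eQTL count beats both the size-based expectation
(standardized residue) and the bin's cis content (hypergeometric test),
then nominates regulators: cis genes whose support interval captures many
co-expressed trans targets at permutation-calibrated correlation cuts.
"""

import eqtlnet as eq
from eqtlnet.pipeline import classify_catalog
from eqtlnet.network import regulators_to_frame

cfg = eq.SimConfig(
    n_lines=200, n_chromosomes=6, n_bins=150, genome_mb=150.0, genome_cm=700.0,
    n_etraits=250, n_cis=60, regulators=[eq.RegulatorSpec(n_targets=150)],
    n_traits=0, trait_specs=[], seed=3,
)
binmap, G, truth, E, P = eq.simulate_population(cfg)
catalog = eq.map_all_etraits(E, G, binmap, threshold=4.95)
classify_catalog(catalog, E.anchors)

hs = eq.hotspot_screen(catalog, binmap, alpha=0.01)
print("hotspot bins:", ", ".join(hs.hotspots["bin_id"]))
print("planted regulator bin:",
      binmap.bin_ids[truth.regulator_bin[truth.regulator_etraits[0]]])

cuts = eq.correlation_thresholds(E, n_group=100, alpha=0.01, seed=1)
print(f"correlation cuts from random pairs: {cuts.pos_cut:+.2f} / {cuts.neg_cut:+.2f}")
cands = eq.find_master_regulators(catalog, E, cuts, min_targets=100)
print(regulators_to_frame(cands).head(3).to_string(index=False))
# N is the number of co-expressed e-traits whose trans-eQTL peak falls in
# the regulator's cis support interval; N > 100 marks a master regulator.
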