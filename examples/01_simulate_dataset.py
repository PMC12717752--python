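"""Generate the synthetic study and inspect its planted ground truth.

Builds a toy two-chromosome genome with protein-coding genes, planted
lncRNAs of the three positional classes, deliberate filter-failures, a
12-sample NB expression design, miRNAs with planted binding sites, and a
term map with one over-represented term.  Everything is reproducible from
the seed, and the truth tables record what was planted.
"""

from beetlnc.synthetic import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(seed=0))

print("planted transcript classes:")
print(ds.truth.classes["clazz"].value_counts().to_string())
print(f"\ngenes: {len(ds.annotation.genes)}, miRNAs: {len(ds.mirnas)}")
print(f"expression: {ds.lnc_matrix.counts.shape[0]} lncRNAs x "
      f"{len(ds.lnc_matrix.samples)} samples "
      f"({ds.lnc_matrix.samples[0].name} .. {ds.lnc_matrix.samples[-1].name})")
print(f"planted DE features: {len(ds.truth.de)} "
      f"(per tissue: {ds.truth.de['tissue'].value_counts().to_dict()})")
print(f"planted binding sites: {len(ds.truth.sites)}, "
      f"expected ceRNA triads: {len(ds.truth.triads)}")

# The class counts above are what identification must recover; the DE and
# site tables are the targets for the DE caller and the site scanner.
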