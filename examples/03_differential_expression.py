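"""Call differentially expressed lncRNAs (DELs) per tissue.

Counts are normalised with trimmed-mean size factors, per-feature NB
dispersions are estimated by moments with shrinkage toward the common
value, and each feature gets a conditional NB exact test (LN vs CV, three
replicates each).  DELs are called at q < 0.05; mRNAs (DEGs) additionally
need |log2FC| >= 1.
"""

from beetlnc.diffexp import run_de
from beetlnc.synthetic import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(seed=0))

for tissue in ("foliage", "root"):
    de = run_de(ds.lnc_matrix, tissue, "lncRNA")
    called = de[de["call"] != "ns"]
    planted = set(
        ds.truth.de.query("kind == 'lncRNA' and tissue == @tissue")["feature"]
    )
    hit = len(set(called["feature"]) & planted)
    print(f"{tissue}: {len(called)} DELs "
          f"({(called['call'] == 'up').sum()} up, "
          f"{(called['call'] == 'down').sum()} down); "
          f"recovered {hit}/{len(planted)} planted")
    print(called.head(3)[["feature", "log2fc", "p", "q", "call"]]
          .to_string(index=False), "\n")

# log2FC is LN over CV; q is the BH-adjusted p-value.  The planted features
# carry |log2FC| = 2, so nearly all are recovered at these sample sizes.
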