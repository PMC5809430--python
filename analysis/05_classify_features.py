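"""Rank residue features by forward-stepwise logistic AUROC.

Trains significantly cleaved peptides against a size-matched random
draw of neutral peptides, in both feature modes: residue presence
anywhere (global) and residue at a defined position (positional).
Writes the selected-feature tables and prints the AUROC trajectories.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from phageprofiler import classify as clf

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "pipeline"
SEED = 17

records = pd.read_csv(OUTDIR / "enrichment.tsv", sep="\t", index_col="peptide")
positives = list(records.index[records["label"] == "cleaved"])
negatives = clf.sample_negatives(records, len(positives), np.random.default_rng(SEED))
print(f"{len(positives)} cleaved vs {len(negatives)} sampled neutral peptides")

for mode in ("global", "positional"):
    fm = clf.build_features(positives, negatives, mode=mode)
    result = clf.forward_stepwise(fm, tol=0.001, max_features=20)
    result.to_frame().to_csv(OUTDIR / f"stepwise_{mode}.tsv", sep="\t", index=False)
    final = result.auroc_path[-1] if result.auroc_path else 0.5
    steps = ", ".join(
        f"{f}({s})" for f, s in zip(result.features[:5], result.signs[:5])
    )
    print(f"{mode}: AUROC {final:.3f} after {len(result.features)} features; "
          f"first picks: {steps}")
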