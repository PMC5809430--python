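"""Build the substrate-recognition motif from the classified peptides.

Compares per-position residue frequencies of the cleaved pool against
the non-cleaved pool (differential logo with two-proportion z calls),
aligns Arg-containing peptides on the center-most Arg as P1, bins
peptides by p-value magnitude for frequency profiles, and writes the
residue-proportion comparison.  Outputs land in results/pipeline/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from phageprofiler import motif

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "pipeline"

records = pd.read_csv(OUTDIR / "enrichment.tsv", sep="\t", index_col="peptide")
cleaved = list(records.index[records["label"] == "cleaved"])
others = list(records.index[records["label"] != "cleaved"])
print(f"{len(cleaved)} cleaved vs {len(others)} non-cleaved peptides")

pfm_c = motif.position_frequencies(cleaved)
pfm_o = motif.position_frequencies(others)
pfm_c.to_tsv(OUTDIR / "pfm_cleaved.tsv")
logo = motif.differential_logo(pfm_c, pfm_o)
logo.to_tsv(OUTDIR / "differential_logo.tsv")
motif.plot_differential_heatmap(logo, OUTDIR / "differential_heatmap.png")
for pos in logo.diff.index:
    top = logo.diff.loc[pos].idxmax()
    print(f"  position {pos}: top enriched residue {top} "
          f"(diff {logo.diff.loc[pos, top]:+.3f}, call {logo.call.loc[pos, top] or 'none'})")

aligned_c = motif.align_on_anchor(cleaved, "R", "center_most")
print(f"anchored alignment: {len(aligned_c.peptides)} cleaved peptides carry Arg "
      f"({aligned_c.skipped} skipped)")
if aligned_c.peptides and others:
    aligned_o = motif.align_on_anchor(others, "R", "center_most")
    a_logo = motif.differential_logo(
        motif.position_frequencies(aligned_c), motif.position_frequencies(aligned_o)
    )
    a_logo.to_tsv(OUTDIR / "differential_logo_anchored.tsv")

profiles, bins = motif.pvalue_binned_profiles(records, min_bin=10)
profiles.join(bins).to_csv(OUTDIR / "binned_profiles.tsv", sep="\t")
print(f"p-value bins: {bins.groupby('arm')['n_peptides'].agg(list).to_dict()}")

props = motif.aa_proportion_comparison(records)
props.to_csv(OUTDIR / "aa_proportions.tsv", sep="\t")
print("residues most over-represented in cleaved vs depleted:",
      ", ".join(props.index[:3]))

nnk_freq, stop_mass = motif.nnk_expected_frequencies()
pd.DataFrame({"nnk_expected": nnk_freq}).to_csv(OUTDIR / "nnk_expected.tsv", sep="\t")
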