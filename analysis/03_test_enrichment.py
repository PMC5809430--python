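"""Call cleaved / depleted / neutral peptides with the NB Wald test.

Applies the minimum-4-combined-reads filter, median-of-ratios size
factors, trended dispersion shrinkage, the two-group negative-binomial
Wald test, and BH FDR at 0.05.  Writes enrichment.tsv and the rank-order
listing of significantly cleaved peptides under results/pipeline/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from phageprofiler.enrichment import run_enrichment
from phageprofiler.pipeline import rank_order_report
from phageprofiler.readproc import PeptideCountTable

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "pipeline"

table = PeptideCountTable.from_tsv(OUTDIR / "counts.tsv", OUTDIR / "design.tsv")
records = run_enrichment(table, alpha=0.05, min_total=4)
records.rename_axis("peptide").to_csv(OUTDIR / "enrichment.tsv", sep="\t")

ranked, _ = rank_order_report(records)
ranked.to_csv(OUTDIR / "rank_order.tsv", sep="\t", index=False)

counts = records["label"].value_counts()
print(f"{len(records)} peptides tested after the min-4-reads filter")
for label in ("cleaved", "depleted", "neutral"):
    print(f"  {label}: {int(counts.get(label, 0))}")
if len(ranked):
    top = ranked.iloc[0]
    print(f"top cleaved peptide: {top['peptide']} "
          f"(log2FC {top['log2fc']:.2f}, p_FDR {top['p_fdr']:.2e})")
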