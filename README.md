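# phageprofiler

Substrate phage display coupled to high-throughput sequencing is a way to
read out a protease's active-site specificity in one experiment: phage
displaying random hexapeptides (encoded by NNK degenerate codons) are
immobilised on beads, the protease of interest releases phage whose
peptide it can cleave, and deep sequencing of the selected and unselected
pools turns every clone into a count. Peptides enriched after selection
are substrates; peptides depleted are refractory. `phageprofiler`
implements that analysis end to end for hexapeptide libraries —
from paired-end FASTQ to a substrate-recognition motif — together with a
synthetic-data generator that plants a known cleavage motif, so the whole
pipeline is testable without any sequencing downloads.

It is aimed at people analysing (or planning) substrate phage display
screens of serine or metalloproteases such as thrombin or ADAMTS13, and
at anyone who wants a self-contained, tested reference implementation of
the count-based statistics behind such screens.

## What the pipeline computes

1. **Read filtering** (`readproc`). Each read pair is oriented by exact
   match of any of three 8-bp seed sequences in the forward-flank region
   (the redundancy tolerates sequencing errors); the sense and
   reverse-complemented antisense reads must agree perfectly across the
   18-nt variable region; and every variable-region base on both mates
   needs Phred ≥ 5. With a 1% per-read error rate, requiring both mates
   to err drives the post-filter error to ~0.01% (the rates multiply).
   Survivors are translated; stop-codon reads are tallied (only TAG is
   reachable in error-free NNK space) and excluded from the count table.

2. **Enrichment testing** (`enrichment`). Peptides with ≥ 4 reads
   combined across samples enter a negative-binomial Wald test of
   selected vs unselected counts: median-of-ratios size factors,
   method-of-moments dispersions α̂ = max(0, (s²−μ)/μ²) shrunk toward an
   a/μ + b trend, a two-group NB GLM with log link and size-factor
   offsets, and Benjamini–Hochberg FDR. Peptides with p_FDR < 0.05 are
   called *cleaved* (log₂FC > 0) or *depleted* (log₂FC < 0).

3. **Motif construction** (`motif`). Position frequency matrices for the
   cleaved and non-cleaved pools; differential logos with a
   two-proportion z significance call per position/residue
   (z = d/√(f̄(1−f̄)(1/n₁+1/n₂))) and a three-state
   enriched/depleted/unpopulated heatmap; Schechter–Berger anchoring of
   Arg-containing peptides (center-most Arg as P1, position 3 preferred
   over 4); p-value-binned residue-frequency profiles; and NNK
   codon-count expectations (e.g. Leu 3/32, Met 1/32) for normalisation.

4. **Feature ranking** (`classify`). Forward-stepwise logistic
   regression over binary residue-presence features — residue anywhere
   ("R") or residue at a position ("R@4") — trained on cleaved vs a
   size-matched random draw of neutral peptides, greedily maximising
   in-sample AUROC (Mann–Whitney, ties ½) with a small ridge penalty for
   separable pools.

The generator (`simulate`) produces the matching inputs: NNK libraries
with log-normal clone-abundance skew and zero display abundance for
stop-codon clones, a position-weight cleavage model
P(cleave) = logistic(b + Σₖ w[k, aaₖ]), one saturating selection round
(selected abundance ∝ input × cleavage probability), and paired 50-bp
reads with per-base substitution errors and Phred+33 qualities.

## Worked example

The numbered scripts under `analysis/` run a complete planted-truth
study (10,000 clones, 4 samples × 100,000 read pairs, thrombin-like
Arg-at-position-4 motif) and write their tables under `results/`:

```bash
python analysis/01_simulate_library.py
python analysis/02_extract_counts.py
python analysis/03_test_enrichment.py
python analysis/04_build_motif.py
python analysis/05_classify_features.py
```

Output from one run:

```
library: 10000 clones, 8341 displayed (16.6% stop-flagged, expected ~17.3%)
unselected_1: 96451/100000 passed (96.5%), 7949 unique peptides, stop fraction 0.00%
7865 peptides tested after the min-4-reads filter
  cleaved: 736
  depleted: 2
  neutral: 7127
  position 4: top enriched residue R (diff +0.995, call enriched)
global: AUROC 0.841 after 7 features; first picks: R(+), A(-), C(+), E(-), N(-)
positional: AUROC 0.999 after 1 features; first picks: R@4(+)
```

Reading this: ~17% of drawn NNK inserts carry a stop (1 − (31/32)⁶) but
they are flagged with zero display abundance, so passed reads contain
essentially none; 96.5% of pairs survive the three filters (losses are
almost entirely mate mismatches at the 0.1% per-base error rate); the
enrichment stage recovers 736 cleaved peptides, nearly all carrying the
planted Arg; the differential logo pins the motif to position 4; and the
stepwise classifier picks "R" first in global mode and "R@4" first in
positional mode, with positional features separating almost perfectly —
the same qualitative picture (one dominant anchor residue plus weaker
context preferences) that real thrombin screens show.

The same stages are available as a CLI
(`phageprofiler simulate|extract|enrich|motif|classify|all`) for running
on real per-sample FASTQ files with a template JSON describing the
amplicon flanks and seed sequences.

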