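# katalogkit

Quality control, annotation accounting, paralog detection and ageing-expression
analysis for *de novo* transcript catalogues — the situation of a non-model
species (such as the short-lived killifish *Nothobranchius furzeri*) whose
transcriptome was assembled from mixed-technology reads without a reference
genome, and whose only yardstick is the annotated proteome of a close relative.

The package implements the analysis stages that turn a raw contig set plus
tabular alignment hits into a curated, quantified catalogue:

* **Contig post-processing** — splitting large contigs into overlapping
  fixed-length pieces (default 2,000 bp with 300 bp overlap, i.e. step
  2,000 − 300 = 1,700 nt), greedy longest-first redundancy collapse (removed at
  ≥ 99 % identity over ≥ 90 % of the shorter sequence), and detection of the
  periodic length-histogram peaks such fragmentation leaves behind.
* **Reference-protein QC** — per-protein coverage from subject-interval unions,
  N-/C-terminal fragmentation classes, per-residue redundancy depth, chimera
  detection (two non-overlapping hits to different proteins, each with
  e ≤ 10⁻²⁰, subject coverage ≥ 75 % and identity ≥ 50 %), and contamination
  tagging (best hit non-fish with every fish hit at least 10 orders of
  magnitude weaker).
* **Annotation** — per-database filtered best-hit selection with strict
  database priority, gene-symbol grouping, CDS completeness (complete iff
  strictly > 90 % of the annotating entry), GO assignment with per-namespace
  count conservation, GO-Slim mapping (most-specific slim ancestors), and
  gene-family count comparison against reference species.
* **Paralogy** — shared (teleost) paralog families via reference gene-tree
  tables with an ortholog-replacement rule, species-specific duplicates via
  six-frame translation (≥ 100 aa) and 1-D divergence-gap clustering (minimum
  10 % gap between clusters), and catalogue-level accounting
  (e.g. collapsed genes = total − paralogs + families).
* **Expression** — RPKM (count / (length in kb × mapped reads in millions)),
  Spearman/PCA sample structure on log₁₀(RPKM + 1), an exact binomial test for
  directional DEG overlap between species, and a paired Wilcoxon comparison of
  per-strain fold changes after rescaling to a common chronological span
  (linear in level: fc′ = 1 + (fc − 1) · span_target/span_source).
* **Synthetic data** — seeded generators for reference proteomes with planted
  paralog families, contig catalogues with planted fragments / redundant copies
  / chimeras / contaminants, provenance-encoding hit tables, and
  negative-binomial count matrices with planted age effects; every planted
  feature carries a ground-truth label.

## Worked example

```python
import numpy as np
from collections import defaultdict
import katalogkit as kk

reference, _ = kk.generate_reference(300, {1: 0.8, 2: 0.15, 3: 0.05}, seed=7)
contigs, hits, truth = kk.generate_contigs(
    reference,
    {"fragment": 0.15, "redundant": 0.05, "chimera": 0.03, "contaminant": 0.02},
    seed=8,
)
print("contigs:", len(contigs), "planted:", truth.class_counts())

by_contig = defaultdict(list)
for h in hits:
    by_contig[h.query_id].append(h)
chimeras = {c for c, v in kk.detect_chimeras(by_contig).items() if v.is_chimeric}
contaminants = {c for c, v in kk.tag_contamination(by_contig).items() if v.is_contaminant}
print(f"flagged chimeric: {len(chimeras)}  contaminant: {len(contaminants)}")

fc = kk.time_normalize_fc(3.0, span_source=26, span_target=9)
print(f"fold change 3.0 over 26 weeks -> {fc:.3f} over 9 weeks")

spans = kk.TimeSpans({"GRZ": 9.0, "MZM-0403": 26.0})
degs = kk.simulate_strain_deg_fc(43, spans, down_fraction=32/43, seed=9)
raw = kk.compare_strain_fc(degs, spans, normalize=False)
norm = kk.compare_strain_fc(degs, spans, normalize=True)
print(f"paired Wilcoxon p: raw {raw.p_all:.3g}  time-normalized {norm.p_all:.3g}")
```

prints

```
contigs: 313 planted: {'clean': 244, 'fragment': 44, 'redundant_copy': 13, 'chimera': 6, 'contaminant': 6}
flagged chimeric: 6  contaminant: 6
fold change 3.0 over 26 weeks -> 1.692 over 9 weeks
paired Wilcoxon p: raw 0.000205  time-normalized 0.871
```

All 6 planted chimeras and all 6 contaminants are recovered with no false
positives.  The last two lines show why time normalization matters: 43 genes
changing at the *same rate per week* in a strain sampled over 9 weeks and one
sampled over 26 weeks look strongly different on raw fold changes
(p ≈ 2 × 10⁻⁴) but indistinguishable once the longer span is rescaled to the
shorter (p ≈ 0.87).

A command-line interface mirrors the main stages:

```sh
katalogkit simulate --genes 500 --rates 0.1,0.05,0.01,0.02 --seed 1 --out sim/
katalogkit qc --hits sim/hits.tsv --reference sim/reference.fa --out qc.json
katalogkit fragment sim/contigs.fa --out fragments.fa
katalogkit peaks sim/contigs.fa
katalogkit expr strain-compare --degs degs.tsv
```

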