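# ppikit

Confidence scoring and downstream analysis of predicted protein–protein
complexes. Given AlphaFold-Multimer/ColabFold outputs for two-chain
predictions (coordinates with pLDDT in the B-factor column, plus score
JSONs carrying the PAE matrix, pTM and ipTM), ppikit provides:

- **`ppikit.afm_io`** — readers for PDB/mmCIF coordinates and ColabFold
  score JSONs; Cβ-proxy contact maps (Cα fallback for glycine).
- **`ppikit.interface_metrics`** — pair-level confidence metrics: `lis`
  (mean inversely rescaled inter-chain PAE over the confident PAE ≤ 12 Å
  region), `clis` (restricted to Cβ–Cβ ≤ 8 Å contacts), `ilis`
  (geometric mean of the two), plus ifPAE, ifPAE_d8, model confidence and
  pDockQ; best-model and five-model-average scoring.
- **`ppikit.residue_profiles`** — per-residue interface flags (LIR/cLIR)
  and interface-frequency percentages across all predicted partners of a
  protein.
- **`ppikit.calibration`** — ROC analysis, FPR-level threshold calibration
  across pLDDT subgroups with bootstrap AUCs, and threshold-based PPI
  classification.
- **`ppikit.allele_enrichment`** — mapping missense mutations onto model
  sequences (exact match or Needleman–Wunsch transfer), interface-frequency
  binning, Cochran–Armitage trend tests, within-gene permutation nulls,
  conservation stratification and adjusted logistic regression.
- **`ppikit.ppi_network`** — evidence-filtered network construction and
  recursive, permutation-validated Leiden clustering with per-cluster
  resolution optimization and hypergeometric term enrichment.
- **`ppikit.synthetic_fixtures`** — seeded generators for every input
  dialect: toy dimer structures with planted contacts and known analytic
  scores, benchmark score tables, residue tables with a planted logit
  mutation model, and planted-partition graphs with evidence columns.

## CLI

```sh
# pair-level metrics for every rank_001..005 model/score set in a directory
ppikit score --models DIR --out scores.tsv

# per-residue LIR/cLIR percentages for one gene (pair ids look like A__B)
ppikit profile --gene Dsh --models DIR --out profile.tsv

# FPR threshold calibration and classification
ppikit calibrate --table bench.tsv --out thresholds.tsv
ppikit classify --scores scores.tsv --metric ilis_best --threshold 0.223 --out labels.tsv

# allele enrichment on a residue table
ppikit enrich --residue-table residues.tsv --n-perm 100000 --seed 42 --out report.json

# network clustering
ppikit cluster --edges edges.tsv --seed 42 --resolution 1.1 --out tree.json

# synthetic fixtures
ppikit simulate complex --spec spec.json --out DIR
```

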