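# phosdisplay

Phosphorylation of serine/threonine residues in intrinsically disordered
protein regions frequently tunes protein–protein interactions mediated by
short linear motifs (SLiMs). `phosdisplay` implements the computational
side of *phosphomimetic proteomic peptide-phage display*: a screening
strategy in which every confident phospho-S/T site in a proteome's
disordered regions is displayed on phage both as its wild-type 16-mer
peptides and as single S/T→E (phosphomimetic) mutants, so that one
selection experiment simultaneously discovers SLiM-based interactions and
indicates whether phosphorylation would enable or disable them.

The package is aimed at phage-display and interaction-proteomics groups and
covers the full workflow:

- **Library design** — phosphosite filtering (localization probability
  ≥ 0.75, functional score ≥ 0.4524, with per-protein best-site rescue),
  tiling of disordered regions into 16-mers with 12-residue overlap,
  single-mutant phosphomimetic variant generation, and deterministic
  reverse translation with ranked *E. coli* codons avoiding SmaI sites
  (including across display-vector flank junctions).
- **Selection NGS processing** — barcode demultiplexing, mean-Phred ≥ 20
  quality filtering, adapter trimming and translation, design matching,
  singleton removal, counts-per-million normalization, day merging, 0–4
  confidence levels, and naive-library coverage estimation.
- **Phosphomimetic enrichment scoring** — for each bait × phosphosite with
  n matched (wild-type, mutant) normalized-count datapoints over
  overlapping peptides and replicates,

      PES = Σᵢ ncᵢᵖᵐ/(ncᵢʷᵗ + ncᵢᵖᵐ) − Σᵢ ncᵢʷᵗ/(ncᵢʷᵗ + ncᵢᵖᵐ),

  bounded by ±n, with a two-sided Mann–Whitney p-value (exact for small
  tie-free groups) and enabling/disabling classification at |PES| ≥ 2,
  P ≤ 0.01.
- **Fluorescence-polarization affinity analysis** — quadratic
  (ligand-depletion) saturation fits, logistic displacement fits with IC50,
  exact competitive-equilibrium conversion of IC50 to K_i, active-protein
  back-calculation, and fold-change/direction calls that propagate "<x"
  bounds and "n.b." (no binding) cells.
- **Simulator** — seeded generators for proteomes, multinomial
  selection counts with per-round enrichment and wild-type-vs-mutant
  preference factors, error-free FASTQ, and noisy FP plates, so the whole
  pipeline is testable with known ground truth.

## Worked example

The package ships a 32-triplet validation panel of FP affinities
(wild-type, glutamate and phospho-peptide K_D values per bait–phosphosite
pair, with the corresponding display-derived PES and p-value). Running

```bash
phosdisplay concordance
```

prints

```json
{
  "n_records": 28,
  "n_pass": 18,
  "n_agree": 14,
  "agreement_fraction": 0.7777777777777778,
  "foldchange_spearman": {"rho": 0.6314529914529914, "n": 26},
  "pes_foldchange_spearman": {"rho": 0.5287477119416172, "n": 26}
}
```

meaning: of the 28 representative bait–phosphosite pairs (one binding
pocket per bait), 18 pass the screening cutoffs (P ≤ 0.01, |PES| ≥ 2), and
for 14 of those (78%) the sign of the PES matches the direction of an at
least twofold affinity change between the wild-type and phosphorylated
peptide. Across pairs with finite K_D on both axes, the phosphomimetic
and phosphorylated fold changes correlate with Spearman ρ ≈ 0.63, and the
PES itself tracks the phospho fold change with ρ ≈ 0.53 — the phage-derived
score is a useful, if slightly damped, proxy for the effect of real
phosphorylation.

A complete miniature screen with known ground truth can be generated and
analysed in a few seconds:

```bash
phosdisplay simulate --seed 1 --out scratch/study
```

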