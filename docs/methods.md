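# Methods

## Library design

The design models a phosphomimetic display library over a proteome's
intrinsically disordered regions. Candidate phospho-S/T sites are filtered
by mass-spectrometry localization probability (default ≥ 0.75) and a 0–1
functional-priority score (default ≥ 0.4524); both cutoffs are inclusive.
Two rescue rules keep biologically interesting sites that fail the scores:
every protein contributing any site to the input contributes at least its
best site (highest functional score; ties break to the lowest position) to
the output, and all sites of proteins on a user-supplied
proteins-of-interest list are kept. Sites kept despite failing the cutoffs
carry `rescued=True`; a site of a rescue-list protein that passes on its
own keeps `rescued=False`, so the invariant "non-rescued ⇒ passes both
cutoffs" always holds. Whether the localization cutoff should still apply
to rescued sites is genuinely open; we ignore both cutoffs for rescues,
which is the more permissive reading.

Regions are tiled with 16-mers every 4 residues (12-residue overlap).
Tiling step and end handling were open choices: we anchor one extra tile
at the region end whenever the last regular tile falls short, so every
region residue is covered, and regions shorter than 16 yield a single
short peptide rather than being padded (no padding scheme is assumed).
Each tile covering k sites yields one shared wild-type entry
(deduplicated by sequence) and k single-mutant S/T→E entries — never a
double mutant, so the mutation-centred analysis can attribute effects to
one site.

Reverse translation is deterministic greedy over a ranked *E. coli* codon
table: each residue takes its top-ranked codon; while the flanked
construct (5' flank + oligo + 3' flank) contains a forbidden motif
(SmaI's CCCGGG by default, since SmaI digestion removes unmutagenized
vector), the left-most codon overlapping the left-most occurrence is
swapped for the best-ranked alternative that moves the occurrence
rightward. Progress is strictly monotone, so the procedure terminates;
with ≥ 2 codons per amino acid involved in any CCCGGG window it cannot
fail for SmaI (asserted property-wise in the tests). Flanks are included
in the scan because a site can span the vector junction. Determinism means
identical inputs give byte-identical design files.

## Selection data processing

Demultiplexing requires exact matches of both the 5' and 3' barcode (a
mismatch-tolerant mode is deliberately not the default, for determinism).
Reads are kept when their mean Phred score is ≥ 20 (inclusive), adapters
are located by exact substring search, and inserts are translated with the
standard genetic code; off-frame or stop-containing inserts are rejected
with reason codes. Counts are tallied per exact peptide sequence
(synonymous DNA variants collapse), peptides absent from the design and
peptides with a read count of 1 are removed, and the remainder is scaled
to counts-per-million per experiment. The normalization constant is a
package choice; any per-experiment constant cancels in the enrichment
score. Selection days of one replicate are merged by averaging normalized
counts with implicit zeros, which makes the merge idempotent and
order-invariant.

Confidence levels are the sum of four binary criteria — occurrence in ≥ 2
replicates, an overlapping enriched designed peptide from the same protein
region, a match to the bait's consensus-motif regex, and a mean normalized
count at or above the median of the bait's enriched peptides — mapped to
none/low/medium/high at 0/1/2–3/4. The additive equal-weight form is a
package choice. Coverage of the design is estimated from naive-library
samples as the cumulative unique fraction, extrapolated (when ≥ 3 samples
are available) with a two-parameter saturating exponential
f_max·(1 − e^(−r·k)) fit to the accumulation curve; f_max is capped at 1
and never reported below the observed fraction.

## Enrichment scoring

For each bait × phosphosite, every wild-type peptide covering the site is
paired with its phosphomimetic variant, one datapoint per peptide per
replicate. Datapoints with both counts zero are excluded — the score's
per-datapoint fraction is undefined there — which reduces n (and hence the
score bound ±n) for sparsely observed sites. The PES is the sum over
datapoints of (nc_pm − nc_wt)/(nc_wt + nc_pm); it is antisymmetric under
swapping the two variants and invariant to rescaling any single datapoint.
The n datapoints are interpreted as exactly n terms (an index running
0..n would imply n+1, contradicting the ±n bound).

Significance uses the two-sided Mann–Whitney test on the wt vs pm count
vectors (scipy): the exact null distribution when both groups have ≤ 10
observations and no ties, otherwise the normal approximation with
mid-ranks, tie-corrected variance and continuity correction. Raw p-values
are reported; an optional Benjamini–Hochberg column is available but not
used in the default classification. Sites are called enabling
(PES ≥ +2, P ≤ 0.01) or disabling (PES ≤ −2, P ≤ 0.01); a stringent mode
uses P ≤ 0.001.

## Concordance with affinity data

The shipped validation panel contains 32 bait–phosphosite triplets of FP
affinities (wild-type, glutamate, phospho-peptide). For baits with two
binding pockets (KPNA4), only the pocket the selection probed (major) is
marked representative, and representative rows are the default analysis
set. A record passes at P ≤ 0.01 and |PES| ≥ 2 and agrees when the PES
sign matches the direction of a ≥ 2-fold wild-type-vs-phospho K_D change;
"<x" cells propagate as a fold of at least kd_wt/x and "n.b." as an
unbounded disabling change. Correlation analyses use signed
log2(K_D ratios) and drop rows lacking finite values on either axis
(Spearman is invariant to the log). On the shipped panel this yields
18 passing pairs, 14 agreements (78%), ρ ≈ 0.63 between phosphomimetic
and phospho fold changes, and ρ ≈ 0.53 between PES and the phospho fold
change — all recomputed, not stored, by `scripts/acceptance.py` and the
acceptance tests.

## Binding models

Saturation curves use the 1:1 ligand-depletion quadratic model
[PL] = ((P_T+L_T+K_d) − √((P_T+L_T+K_d)² − 4P_T·L_T))/2 with signal
S_free + (S_bound−S_free)[PL]/L_T; initial guesses come from the signal
extremes and the concentration nearest the half-signal. Displacement
curves are fit with a logistic in concentration (free Hill slope by
default, unit-slope option); curves whose signal span is below 20% of the
maximum signal are flagged "no binding" and return no IC50 (the threshold
is a package choice). IC50 is converted to K_i from the exact
three-species equilibrium: at 50% inhibition the probe complex is half its
competitor-free value, from which free probe, free protein,
competitor-bound protein and free competitor follow by mass balance and
K_i = [P]₅₀[I]₅₀/[PI]₅₀. This closed form is derived from the equilibria
directly (the free, not total, protein concentration enters), and the
tests verify it against the package's numeric root-finding equilibrium
solver to within 1% over a 5×5×5 grid of probe K_d, protein totals and
competitor K_i. Active protein concentration is back-calculated by
refitting the saturation model with a multiplicative active-fraction
parameter (K_d fixed), constrained to (0, 1.5]. All concentrations are
handled in μM; all fits are deterministic given the data (no random
restarts).

## Simulator

The simulator emulates: a tiled wild-type/phosphomimetic library over a
random proteome (sites placed per-residue at density 0.05, localization
and functional scores from Beta(8,2) and Beta(5,4)); serial phage panning
as per-round multiplicative fitness with multinomial resampling at a
sequencing depth of 30,000 reads per experiment (a realistic
per-experiment share of a multiplexed desktop sequencing run), four rounds
with rounds 3 and 4 sequenced, three replicates; phospho-modulation as a
multiplicative preference factor (default 4-fold, or its reciprocal) on
the mutant variants of affected sites; and FP plates as the exact binding
models plus Gaussian noise. It does **not** model sequencing errors,
display or amplification bias, phage growth kinetics, or
kinase-specificity structure, so passing tests demonstrate the correctness
and calibration of the analysis under the stated sampling model, not
robustness to those real-data artifacts. The reference scoring used for
fixture truth tables is an independent straight-line reimplementation that
shares no code with the analysis modules. All generators take explicit
seeds and are byte-reproducible.

The default miniature-screen size (40 proteins × 150 residues, ~150
designed sites, ~1,000 displayed peptides) was chosen as the smallest
scale at which the calibration properties (≥ 90% sign recovery for
strong effects, ≤ 2% significant calls under the null) are comfortably
measurable; the whole fixture builds and scores in about one second.

## Known limitations

- Obligate phospho-reader domains (14-3-3, polo-box, FHA, WW) are not
  expected to yield signal: a glutamate cannot replace the phosphate
  moiety those folds require, so absence of enrichment is uninformative
  for them.
- Exact-match demultiplexing and adapter search discard reads with any
  barcode/adapter sequencing error; with error-free simulated reads this
  is lossless, on real data it trades yield for specificity.
- The confidence-level weighting and the coverage extrapolation form are
  reasonable defaults, not fitted to data.
- Full-scale screen counts cannot be checked without the complete external
  result tables (see the README); the shipped panel covers the desk-scale
  analyses only.
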