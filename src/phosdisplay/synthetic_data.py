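"""Ground-truth-known simulators for every stage of the pipeline.

Generates toy proteomes with phospho-S/T sites, phage-selection sequencing
data under a per-round multiplicative enrichment model with multinomial
resampling, raw FASTQ reads with barcodes and adapters, and noisy FP
saturation/displacement curves drawn from the exact binding models.

The selection model: each displayed peptide has a fitness (its enrichment
factor per selection round); phosphomimetic variants of a phospho-modulated
site carry an extra multiplicative wild-type-vs-mutant preference factor.
Round r abundances are the multinomially resampled counts of round r-1
weighted by fitness, which is the simplest model consistent with serial
phage panning (amplification bias and phage growth effects are not
modeled).

The reference scoring path used to produce fixture truth tables
(:func:`reference_site_calls`) is written as straight-line loops and shares
no code with :mod:`phosdisplay.phospho_scoring`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from phosdisplay import binding_affinity
from phosdisplay.library_design import (
    PHOSPHOMIMETIC,
    WILD_TYPE,
    DisorderedRegion,
    LibraryEntry,
    PhosphositeRecord,
    design_library,
)
from phosdisplay.selection_processing import (
    STAGE_RAW,
    BarcodeMap,
    SelectionCounts,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror a miniature phosphomimetic display screen: four
    selection rounds with the last two sequenced, three replicate
    selections, and a per-experiment sequencing depth of 30,000 reads
    (a realistic per-experiment share of a multiplexed MiSeq run).
    """

    seed: int = 0
    n_proteins: int = 40
    protein_length: int = 150
    phosphosite_density: float = 0.05  # per disordered-region residue
    loc_prob_beta: tuple[float, float] = (8.0, 2.0)
    func_score_beta: tuple[float, float] = (5.0, 4.0)
    peptide_length: int = 16
    tiling_step: int = 4
    selection_rounds: int = 4
    sequenced_rounds: tuple[int, ...] = (3, 4)
    replicates: int = 3
    depth: int = 30_000


@dataclass(frozen=True)
class TrueEffect:
    """Ground-truth phospho-modulation of one site's peptides.

    ``base_enrichment`` multiplies the abundance of every peptide covering
    the site each selection round; ``pm_preference`` additionally
    multiplies the phosphomimetic variants (>1 = phosphomimetic preferred,
    <1 = wild-type preferred, 1 = no preference).
    """

    protein_ac: str
    position: int
    base_enrichment: float = 1.0
    pm_preference: float = 1.0

    @property
    def expected_sign(self) -> int:
        if self.pm_preference > 1.0:
            return 1
        if self.pm_preference < 1.0:
            return -1
        return 0


def simulate_proteome(
    config: SimConfig,
) -> tuple[dict[str, str], list[PhosphositeRecord], list[DisorderedRegion]]:
    """Random proteome with phospho-S/T sites in fully disordered proteins.

    Each protein is one disordered region.  Site positions are Bernoulli
    per residue at ``phosphosite_density``; chosen residues are set to S or
    T and receive localization / functional scores from the configured
    Beta distributions.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    proteome: dict[str, str] = {}
    sites: list[PhosphositeRecord] = []
    regions: list[DisorderedRegion] = []
    for i in range(config.n_proteins):
        ac = f"SIM{i:04d}"
        seq = list(rng.choice(list(AMINO_ACIDS), size=config.protein_length))
        hits = np.nonzero(rng.random(config.protein_length) < config.phosphosite_density)[0]
        for pos0 in hits:
            residue = "S" if rng.random() < 0.5 else "T"
            seq[pos0] = residue
            sites.append(
                PhosphositeRecord(
                    protein_ac=ac,
                    position=int(pos0) + 1,
                    residue=residue,
                    localization_prob=float(rng.beta(*config.loc_prob_beta)),
                    functional_score=float(rng.beta(*config.func_score_beta)),
                    kinases=("CDK1",) if rng.random() < 0.6 else (),
                )
            )
        proteome[ac] = "".join(seq)
        regions.append(DisorderedRegion(ac, 1, config.protein_length))
    return proteome, sites, regions


def _entry_fitness(
    entries: list[LibraryEntry], effects: list[TrueEffect]
) -> np.ndarray:
    by_site = {(e.protein_ac, e.position): e for e in effects}
    fitness = np.ones(len(entries))
    for i, entry in enumerate(entries):
        covered = [
            eff for (ac, pos), eff in by_site.items()
            if ac == entry.tile.protein_ac and entry.tile.covers(pos)
        ]
        if not covered:
            continue
        base = max(eff.base_enrichment for eff in covered)
        fitness[i] = base
        if entry.variant == PHOSPHOMIMETIC:
            key = (entry.phosphosite.protein_ac, entry.phosphosite.position)
            own = by_site.get(key)
            if own is not None:
                fitness[i] = own.base_enrichment * own.pm_preference
    return fitness


def simulate_selection(
    design: list[LibraryEntry],
    effects: list[TrueEffect],
    config: SimConfig,
) -> tuple[dict[tuple[str, int], SelectionCounts], pd.DataFrame]:
    """Simulate per-round sequencing counts for replicate selections.

    Returns ``(tables, truth)`` where tables maps ``(replicate_id, round)``
    to a raw-stage count table for the sequenced rounds, and truth is the
    effect table (one row per site with an assigned effect).
    """
    rng = np.random.default_rng(config.seed)
    peptides = [e.peptide_seq for e in design]
    fitness = _entry_fitness(design, effects)
    tables: dict[tuple[str, int], SelectionCounts] = {}
    for rep in range(1, config.replicates + 1):
        rep_id = f"rep{rep}"
        abundance = np.ones(len(design))
        for rnd in range(1, config.selection_rounds + 1):
            weights = abundance * fitness
            total = weights.sum()
            if total == 0 or config.depth == 0:
                counts = np.zeros(len(design), dtype=int)
            else:
                counts = rng.multinomial(config.depth, weights / total)
            abundance = counts.astype(float)
            if rnd in config.sequenced_rounds:
                table = {
                    pep: float(c) for pep, c in zip(peptides, counts) if c > 0
                }
                tables[(rep_id, rnd)] = SelectionCounts(
                    experiment_id=f"{rep_id}_day{rnd}",
                    bait_id="simbait",
                    replicate_id=rep_id,
                    selection_day=rnd,
                    stage=STAGE_RAW,
                    counts=table,
                )
    truth = pd.DataFrame(
        [
            {
                "protein_ac": e.protein_ac,
                "position": e.position,
                "base_enrichment": e.base_enrichment,
                "pm_preference": e.pm_preference,
                "expected_sign": e.expected_sign,
            }
            for e in effects
        ]
    )
    return tables, truth


def simulate_reads(
    table: SelectionCounts,
    oligos: dict[str, str],
    barcode_map: BarcodeMap,
    experiment_id: str,
    seed: int = 0,
    quality: int = 30,
):
    """Error-free FASTQ reads for one experiment's count table.

    Each read is 5'barcode + 5'adapter + oligo + 3'adapter + 3'barcode at
    uniform Phred quality.  Read order is shuffled deterministically.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(seed)
    b5, b3 = barcode_map.experiments[experiment_id]
    reads = []
    for pep in sorted(table.counts):
        oligo = oligos[pep]
        n = int(round(table.counts[pep]))
        dna = b5 + barcode_map.adapter_5prime + oligo + barcode_map.adapter_3prime + b3
        for k in range(n):
            rec = SeqRecord(Seq(dna), id=f"{experiment_id}:{pep[:6]}:{k}",
                            description="")
            rec.letter_annotations["phred_quality"] = [quality] * len(dna)
            reads.append(rec)
    rng.shuffle(reads)
    return reads


def simulate_fp(
    kind: str,
    params: dict,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy FP plate data from the exact binding models.

    ``kind="saturation"``: params need protein_total (array, uM),
    probe_total, kd, signal_free, signal_bound.
    ``kind="displacement"``: params need competitor_total (array, uM),
    protein_total, probe_total, probe_kd, ki, signal_free, signal_bound;
    the signal is computed from the full three-species equilibrium.
    """
    rng = np.random.default_rng(seed)
    if kind == "saturation":
        x = np.asarray(params["protein_total"], dtype=float)
        y = binding_affinity.saturation_signal(
            x, params["probe_total"], params["kd"],
            params["signal_free"], params["signal_bound"],
        )
        colname = "protein_total"
    elif kind == "displacement":
        x = np.asarray(params["competitor_total"], dtype=float)
        y = binding_affinity.displacement_signal(
            x, params["protein_total"], params["probe_total"],
            params["probe_kd"], params["ki"],
            params["signal_free"], params["signal_bound"],
        )
        colname = "competitor_total"
    else:
        raise ValueError(f"unknown FP curve kind: {kind!r}")
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return pd.DataFrame({colname: x, "signal_mp": y})


# --------------------------------------------------------------------------
# Independent reference scoring (fixture truth; straight-line, no shared code)
# --------------------------------------------------------------------------

def reference_site_calls(
    merged_by_replicate: dict[str, SelectionCounts],
    design: list[LibraryEntry],
    pes_min: float = 2.0,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Flat re-derivation of per-site enrichment calls for fixture truth."""
    rows = []
    site_keys = sorted(
        {
            (e.phosphosite.protein_ac, e.phosphosite.position)
            for e in design
            if e.variant == PHOSPHOMIMETIC
        }
    )
    for ac, pos in site_keys:
        wt_list: list[float] = []
        pm_list: list[float] = []
        for entry in design:
            if entry.variant != PHOSPHOMIMETIC:
                continue
            if entry.phosphosite.protein_ac != ac or entry.phosphosite.position != pos:
                continue
            for rep in sorted(merged_by_replicate):
                table = merged_by_replicate[rep].counts
                a = table.get(entry.tile.sequence, 0.0)
                b = table.get(entry.peptide_seq, 0.0)
                if a + b > 0:
                    wt_list.append(a)
                    pm_list.append(b)
        if not wt_list:
            continue
        score = 0.0
        for a, b in zip(wt_list, pm_list):
            score += b / (a + b) - a / (a + b)
        p = float(
            mannwhitneyu(wt_list, pm_list, alternative="two-sided").pvalue
        )
        if p <= p_max and score >= pes_min:
            call = "enabling"
        elif p <= p_max and score <= -pes_min:
            call = "disabling"
        else:
            call = "not_significant"
        rows.append(
            {"protein_ac": ac, "position": pos, "ref_pes": score,
             "ref_p": p, "ref_call": call, "n": len(wt_list)}
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# End-to-end fixture
# --------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    config: SimConfig
    proteome: dict[str, str]
    sites: list[PhosphositeRecord]
    regions: list[DisorderedRegion]
    design: list[LibraryEntry]
    effects: list[TrueEffect]
    tables: dict[tuple[str, int], SelectionCounts]
    truth: pd.DataFrame
    reference_calls: pd.DataFrame = field(default_factory=pd.DataFrame)


def end_to_end_fixture(
    config: SimConfig | None = None,
    n_enabling: int = 15,
    n_disabling: int = 15,
    enrichment: float = 3.0,
    pm_preference: float = 4.0,
) -> FixtureBundle:
    """A complete miniature screen with known phospho-modulated sites.

    The first ``n_enabling`` designed sites get a phosphomimetic
    preference of ``pm_preference``, the next ``n_disabling`` get its
    reciprocal, all on a ``enrichment``-fold per-round binder background;
    the remaining sites are unmodulated binders (preference 1).
    """
    config = config or SimConfig()
    proteome, sites, regions = simulate_proteome(config)
    design, _uncovered, _stats = design_library(
        proteome, sites, regions,
        length=config.peptide_length, step=config.tiling_step,
    )
    site_keys = sorted(
        {
            (e.phosphosite.protein_ac, e.phosphosite.position)
            for e in design
            if e.variant == PHOSPHOMIMETIC
        }
    )
    effects = []
    for i, (ac, pos) in enumerate(site_keys):
        if i < n_enabling:
            pref = pm_preference
        elif i < n_enabling + n_disabling:
            pref = 1.0 / pm_preference
        else:
            pref = 1.0
        effects.append(TrueEffect(ac, pos, base_enrichment=enrichment,
                                  pm_preference=pref))
    tables, truth = simulate_selection(design, effects, config)
    return FixtureBundle(
        config=config, proteome=proteome, sites=sites, regions=regions,
        design=design, effects=effects, tables=tables, truth=truth,
    )
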