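"""Processing of phage-selection NGS data into normalized count tables.

Reads are demultiplexed by exact 5'/3' barcode combinations, kept when the
mean Phred quality is >= 20, trimmed of adapters and translated.  Peptides
absent from the library design and singleton counts (read count 1) are
removed; surviving counts are normalized to counts-per-million, selection
days of the same replicate are averaged, and each peptide is assigned a
0-4 confidence level.  Naive (unchallenged) library sequencing is used to
estimate design coverage via a saturating accumulation curve.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq
from scipy.optimize import curve_fit

NORMALIZATION_CONSTANT = 1e6  # counts per million

STAGE_RAW = "raw"
STAGE_FILTERED = "filtered"
STAGE_NORMALIZED = "normalized"


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class BarcodeMap:
    """experiment_id -> (5' barcode, 3' barcode); plus adapter sequences."""

    experiments: dict[str, tuple[str, str]]
    adapter_5prime: str = ""
    adapter_3prime: str = ""

    def __post_init__(self) -> None:
        pairs = list(self.experiments.values())
        if len(set(pairs)) != len(pairs):
            raise ConfigError("duplicate 5'/3' barcode pair in barcode map")
        for exp, (b5, b3) in self.experiments.items():
            if not b5 or not b3:
                raise ConfigError(f"empty barcode for experiment {exp}")

    @classmethod
    def from_json(cls, path) -> "BarcodeMap":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            experiments={k: tuple(v) for k, v in raw["experiments"].items()},
            adapter_5prime=raw.get("adapter_5prime", ""),
            adapter_3prime=raw.get("adapter_3prime", ""),
        )


@dataclass
class SelectionCounts:
    """Per-experiment peptide -> count table with its processing stage."""

    experiment_id: str
    bait_id: str
    replicate_id: str
    selection_day: int
    stage: str
    counts: dict[str, float] = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(self.counts.values()))


@dataclass
class PeptideEvidence:
    peptide_seq: str
    bait_id: str
    n_replicates: int
    overlap_support: bool
    motif_match: bool
    count_rank: bool
    confidence_level: int

    @property
    def confidence_label(self) -> str:
        return {0: "none", 1: "low", 2: "medium", 3: "medium", 4: "high"}[
            self.confidence_level
        ]


@dataclass
class CoverageEstimate:
    n_designed: int
    n_observed: int
    observed_fraction: float
    estimated_max_coverage: float


def demultiplex(reads, barcode_map: BarcodeMap):
    """Assign reads to experiments by exact 5'+3' barcode match.

    ``reads`` is an iterable of Bio.SeqRecord (FASTQ).  Returns
    ``(assigned, n_unassigned)`` where assigned maps experiment_id to the
    list of reads carrying both its barcodes.
    """
    assigned: dict[str, list] = {exp: [] for exp in barcode_map.experiments}
    n_unassigned = 0
    items = [
        (exp, b5, b3) for exp, (b5, b3) in barcode_map.experiments.items()
    ]
    for read in reads:
        seq = str(read.seq)
        for exp, b5, b3 in items:
            if seq.startswith(b5) and seq.endswith(b3):
                assigned[exp].append(read)
                break
        else:
            n_unassigned += 1
    return assigned, n_unassigned


def quality_filter(read, min_mean_quality: float = 20.0) -> bool:
    """True iff the read's mean Phred score is >= the threshold (inclusive)."""
    quals = read.letter_annotations.get("phred_quality")
    if quals is None or len(quals) == 0:
        raise ValueError(f"read {read.id} has no per-base quality scores")
    return float(np.mean(quals)) >= min_mean_quality


def trim_translate(
    read, adapter_5prime: str, adapter_3prime: str
) -> tuple[str | None, str]:
    """Extract the peptide-coding insert between adapters and translate.

    Returns ``(peptide, "ok")`` on success, else ``(None, reason)`` with
    reason one of "adapter", "frame", "stop".
    """
    seq = str(read.seq) if hasattr(read, "seq") else str(read)
    start = seq.find(adapter_5prime)
    if start < 0:
        return None, "adapter"
    start += len(adapter_5prime)
    end = seq.find(adapter_3prime, start)
    if end < 0:
        return None, "adapter"
    insert = seq[start:end]
    if len(insert) == 0 or len(insert) % 3 != 0:
        return None, "frame"
    peptide = str(Seq(insert).translate())
    if "*" in peptide:
        return None, "stop"
    return peptide, "ok"


def count_and_filter(
    peptides, design_peptides: set[str], *, experiment_id: str = "",
    bait_id: str = "", replicate_id: str = "", selection_day: int = 0,
) -> SelectionCounts:
    """Tally peptides; drop non-design matches and singleton counts."""
    tally = Counter(peptides)
    counts = {
        pep: float(c)
        for pep, c in tally.items()
        if c > 1 and pep in design_peptides
    }
    return SelectionCounts(
        experiment_id, bait_id, replicate_id, selection_day,
        STAGE_FILTERED, counts,
    )


def filter_counts(sc: SelectionCounts, design_peptides: set[str]) -> SelectionCounts:
    """Apply the design-match and singleton filters to an existing table."""
    counts = {
        pep: float(c)
        for pep, c in sc.counts.items()
        if c > 1 and pep in design_peptides
    }
    return replace(sc, stage=STAGE_FILTERED, counts=counts)


def normalize(sc: SelectionCounts) -> SelectionCounts:
    """Scale counts so the experiment total equals one million."""
    total = sc.total()
    if total == 0:
        raise ValueError(
            f"experiment {sc.experiment_id}: zero total count, cannot normalize"
        )
    factor = NORMALIZATION_CONSTANT / total
    return replace(
        sc,
        stage=STAGE_NORMALIZED,
        counts={pep: c * factor for pep, c in sc.counts.items()},
    )


def merge_days(day_tables: list[SelectionCounts]) -> SelectionCounts:
    """Average normalized counts across selection days of one replicate.

    A peptide absent on a day contributes an implicit zero, so the result
    is invariant to the order of the day tables.
    """
    if not day_tables:
        raise ValueError("no day tables to merge")
    support: set[str] = set()
    for t in day_tables:
        support.update(t.counts)
    n = len(day_tables)
    merged = {
        pep: sum(t.counts.get(pep, 0.0) for t in day_tables) / n
        for pep in support
    }
    first = day_tables[0]
    return SelectionCounts(
        first.experiment_id, first.bait_id, first.replicate_id,
        selection_day=-1, stage=STAGE_NORMALIZED, counts=merged,
    )


def score_confidence(
    bait_id: str,
    replicate_tables: list[SelectionCounts],
    peptide_coords: dict[str, tuple[str, int, int]],
    motif_pattern: str | None = None,
) -> list[PeptideEvidence]:
    """Assign 0-4 confidence levels to enriched peptides of one bait.

    Four additive binary criteria per peptide: (1) present in >= 2
    replicate selections; (2) at least one other enriched designed peptide
    overlaps it (same protein, overlapping tile coordinates); (3) the
    peptide matches the bait's consensus-motif regex; (4) its mean
    normalized count is >= the median over all enriched peptides of the
    bait.  Levels 2-3 are "medium", 4 is "high" confidence.

    ``peptide_coords`` maps each designed peptide to
    ``(protein_ac, tile_start, tile_end)``.
    """
    occurrence: Counter[str] = Counter()
    mean_counts: dict[str, float] = {}
    for t in replicate_tables:
        for pep in t.counts:
            occurrence[pep] += 1
    n_rep = len(replicate_tables)
    for pep in occurrence:
        mean_counts[pep] = sum(t.counts.get(pep, 0.0) for t in replicate_tables) / n_rep

    median_count = float(np.median(list(mean_counts.values()))) if mean_counts else 0.0
    regex = re.compile(motif_pattern) if motif_pattern else None

    evidence = []
    for pep, n_occ in sorted(occurrence.items()):
        coords = peptide_coords.get(pep)
        overlap = False
        if coords is not None:
            ac, start, end = coords
            for other in occurrence:
                if other == pep:
                    continue
                oc = peptide_coords.get(other)
                if oc and oc[0] == ac and oc[1] <= end and start <= oc[2]:
                    overlap = True
                    break
        motif = bool(regex.search(pep)) if regex else False
        rank = mean_counts[pep] >= median_count
        level = int(n_occ >= 2) + int(overlap) + int(motif) + int(rank)
        evidence.append(
            PeptideEvidence(pep, bait_id, n_occ, overlap, motif, rank, level)
        )
    return evidence


def estimate_coverage(
    naive_samples: list[SelectionCounts], design_peptides: set[str]
) -> CoverageEstimate:
    """Estimate design coverage from naive-library sequencing samples.

    The observed fraction is the union of designed peptides seen across
    samples over the design size.  With >= 3 samples the per-sample
    accumulation curve (cumulative unique fraction vs number of samples)
    is fit to a two-parameter saturating exponential
    ``f(k) = f_max * (1 - exp(-r k))`` and ``f_max`` (capped at 1) is
    reported as the estimated maximum coverage; with fewer samples the
    observed fraction is returned unextrapolated.
    """
    n_designed = len(design_peptides)
    if n_designed == 0:
        raise ValueError("empty design")
    seen: set[str] = set()
    cumulative = []
    for sample in naive_samples:
        seen.update(p for p in sample.counts if p in design_peptides)
        cumulative.append(len(seen) / n_designed)
    observed_fraction = cumulative[-1] if cumulative else 0.0

    estimated_max = observed_fraction
    if len(cumulative) >= 3 and observed_fraction > 0:
        k = np.arange(1, len(cumulative) + 1, dtype=float)
        y = np.asarray(cumulative)

        def accum(x, f_max, rate):
            return f_max * (1.0 - np.exp(-rate * x))

        try:
            popt, _ = curve_fit(
                accum, k, y, p0=[observed_fraction, 1.0],
                bounds=([0.0, 1e-6], [1.0, np.inf]), maxfev=10000,
            )
            estimated_max = float(min(1.0, max(popt[0], observed_fraction)))
        except RuntimeError:
            pass  # saturation not identifiable; keep the observed fraction
    return CoverageEstimate(
        n_designed, len(seen), observed_fraction, estimated_max
    )


def process_count_tables(
    tables: dict[tuple[str, int], SelectionCounts],
    design_peptides: set[str],
) -> dict[str, SelectionCounts]:
    """Filter, normalize and day-merge raw tables keyed by (replicate, day).

    Returns one day-merged normalized table per replicate.  Experiments
    whose filtered table is empty are dropped from the merge.
    """
    by_replicate: dict[str, list[SelectionCounts]] = {}
    for (rep, _day), table in sorted(tables.items()):
        filtered = filter_counts(table, design_peptides)
        if filtered.total() > 0:
            by_replicate.setdefault(rep, []).append(normalize(filtered))
    return {rep: merge_days(days) for rep, days in by_replicate.items()}


def process_reads(
    reads,
    barcode_map: BarcodeMap,
    design_peptides: set[str],
    experiment_meta: dict[str, dict] | None = None,
) -> tuple[dict[str, SelectionCounts], dict[str, Counter]]:
    """Full raw-read pipeline: demultiplex, filter, translate, count.

    Returns per-experiment filtered count tables and per-experiment
    rejection-reason tallies.
    """
    assigned, n_unassigned = demultiplex(reads, barcode_map)
    tables: dict[str, SelectionCounts] = {}
    rejections: dict[str, Counter] = {"_unassigned": Counter({"barcode": n_unassigned})}
    for exp, exp_reads in assigned.items():
        peptides = []
        reasons: Counter[str] = Counter()
        b5, b3 = barcode_map.experiments[exp]
        for read in exp_reads:
            if not quality_filter(read):
                reasons["quality"] += 1
                continue
            pep, reason = trim_translate(
                read, b5 + barcode_map.adapter_5prime,
                barcode_map.adapter_3prime + b3,
            )
            if pep is None:
                reasons[reason] += 1
            else:
                peptides.append(pep)
        meta = (experiment_meta or {}).get(exp, {})
        tables[exp] = count_and_filter(
            peptides, design_peptides, experiment_id=exp,
            bait_id=meta.get("bait_id", exp),
            replicate_id=meta.get("replicate_id", "r1"),
            selection_day=meta.get("selection_day", 0),
        )
        rejections[exp] = reasons
    return tables, rejections
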