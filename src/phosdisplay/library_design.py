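"""Design of a wild-type + phosphomimetic peptide-phage display library.

The library tiles intrinsically disordered regions of a proteome with
overlapping 16-mer peptides (step 4, i.e. 12-residue overlap).  Confident
phospho-serine/threonine sites are mapped onto the tiles; every tile that
covers a site contributes a wild-type entry and one single-mutant
S/T->E (phosphomimetic) entry per covered site.  Peptides are reverse
translated with ranked E. coli codons while avoiding forbidden restriction
motifs (SmaI by default, whose site is used to eliminate unmutagenized
vector during library construction), including motifs spanning the
junctions with fixed display-vector flanks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

# SmaI recognition site; the cloning workflow digests with SmaI, so the
# designed inserts must never contain it (including across flank junctions).
SMAI_SITE = "CCCGGG"

# E. coli codons per amino acid, ranked by K-12 usage (most preferred first).
ECOLI_RANKED_CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCG", "GCC", "GCA", "GCT"),
    "R": ("CGT", "CGC", "CGG", "CGA", "AGA", "AGG"),
    "N": ("AAC", "AAT"),
    "D": ("GAT", "GAC"),
    "C": ("TGC", "TGT"),
    "Q": ("CAG", "CAA"),
    "E": ("GAA", "GAG"),
    "G": ("GGC", "GGT", "GGG", "GGA"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "L": ("CTG", "TTA", "TTG", "CTC", "CTT", "CTA"),
    "K": ("AAA", "AAG"),
    "M": ("ATG",),
    "F": ("TTT", "TTC"),
    "P": ("CCG", "CCA", "CCT", "CCC"),
    "S": ("AGC", "TCT", "AGT", "TCC", "TCG", "TCA"),
    "T": ("ACC", "ACA", "ACG", "ACT"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
    "V": ("GTG", "GTT", "GTC", "GTA"),
}

WILD_TYPE = "wild_type"
PHOSPHOMIMETIC = "phosphomimetic"


class DesignError(ValueError):
    """A design input contradicts the proteome or the design contract."""


@dataclass(frozen=True)
class PhosphositeRecord:
    """One candidate phospho-S/T site.

    ``localization_prob`` is the mass-spectrometry site-localization
    probability; ``functional_score`` is the 0-1 functional priority score
    of the site.  ``rescued`` marks sites kept despite failing the score
    cutoffs (per-protein best-site rescue, or protein-of-interest list).
    """

    protein_ac: str
    position: int  # 1-based residue index in the protein
    residue: str  # "S" or "T"
    localization_prob: float
    functional_score: float
    kinases: tuple[str, ...] = ()
    phosphatases: tuple[str, ...] = ()
    rescued: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.localization_prob <= 1.0:
            raise ValueError(
                f"localization_prob out of [0,1] for {self.protein_ac}:{self.position}"
            )
        if not 0.0 <= self.functional_score <= 1.0:
            raise ValueError(
                f"functional_score out of [0,1] for {self.protein_ac}:{self.position}"
            )


@dataclass(frozen=True)
class DisorderedRegion:
    protein_ac: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid region {self.protein_ac}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PeptideTile:
    protein_ac: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class LibraryEntry:
    """One displayed peptide: a tile in wild-type or single-E mutant form."""

    tile: PeptideTile
    variant: str  # WILD_TYPE or PHOSPHOMIMETIC
    peptide_seq: str
    phosphosite: PhosphositeRecord | None = None
    mutated_position: int | None = None  # 1-based index within the peptide
    oligo: str = ""


@dataclass
class LibraryStats:
    n_phosphosites: int = 0
    n_peptides: int = 0
    n_pairs: int = 0
    fraction_complete_pairs: float = 0.0
    site_coverage_histogram: dict[int, int] = field(default_factory=dict)
    mutated_position_histogram: dict[int, int] = field(default_factory=dict)


def filter_phosphosites(
    sites: list[PhosphositeRecord],
    loc_min: float = 0.75,
    func_min: float = 0.4524,
    rescue_accessions: set[str] | frozenset[str] = frozenset(),
) -> list[PhosphositeRecord]:
    """Filter sites by localization probability and functional score.

    A site passes when ``localization_prob >= loc_min`` and
    ``functional_score >= func_min`` (both inclusive).  Two rescue rules
    apply on top of the cutoffs:

    * for a protein none of whose sites pass, the single site with the
      highest functional score is kept (``rescued=True``; ties break to
      the lowest position);
    * every site of a protein listed in ``rescue_accessions`` is kept;
      those failing the cutoffs are flagged ``rescued=True``.

    Records whose residue is not S or T are rejected and reported in a
    :class:`DesignError` raised after the scan.
    """
    bad = [s for s in sites if s.residue not in ("S", "T")]
    if bad:
        listing = ", ".join(f"{s.protein_ac}:{s.position}({s.residue})" for s in bad)
        raise DesignError(f"non-S/T phosphosite records rejected: {listing}")

    by_protein: dict[str, list[PhosphositeRecord]] = {}
    for s in sites:
        by_protein.setdefault(s.protein_ac, []).append(s)

    kept: list[PhosphositeRecord] = []
    for ac, recs in by_protein.items():
        passing = [
            r for r in recs
            if r.localization_prob >= loc_min and r.functional_score >= func_min
        ]
        if ac in rescue_accessions:
            passing_set = {(r.protein_ac, r.position) for r in passing}
            for r in recs:
                if (r.protein_ac, r.position) in passing_set:
                    kept.append(replace(r, rescued=False))
                else:
                    kept.append(replace(r, rescued=True))
        elif passing:
            kept.extend(replace(r, rescued=False) for r in passing)
        else:
            best = max(recs, key=lambda r: (r.functional_score, -r.position))
            kept.append(replace(best, rescued=True))
    return kept


def tile_region(
    region: DisorderedRegion,
    proteome: dict[str, str],
    length: int = 16,
    step: int = 4,
) -> list[PeptideTile]:
    """Tile one disordered region into overlapping peptides.

    Regular tiles start at ``region.start, region.start+step, ...`` as long
    as a full-length tile fits.  If the last regular tile stops short of the
    region end, an extra tile anchored at the region end is added so every
    residue is covered.  A region shorter than ``length`` yields a single
    short tile spanning the whole region.
    """
    seq = proteome.get(region.protein_ac)
    if seq is None:
        raise DesignError(f"unknown protein {region.protein_ac}")
    if region.end > len(seq):
        raise DesignError(
            f"region {region.protein_ac}:{region.start}-{region.end} exceeds "
            f"protein length {len(seq)}"
        )

    def make(start: int, end: int) -> PeptideTile:
        return PeptideTile(region.protein_ac, start, end, seq[start - 1 : end])

    if region.length < length:
        return [make(region.start, region.end)]

    tiles = []
    start = region.start
    while start + length - 1 <= region.end:
        tiles.append(make(start, start + length - 1))
        start += step
    if tiles[-1].end < region.end:
        tiles.append(make(region.end - length + 1, region.end))
    return tiles


def tile_regions(
    regions: list[DisorderedRegion],
    proteome: dict[str, str],
    length: int = 16,
    step: int = 4,
) -> list[PeptideTile]:
    tiles: list[PeptideTile] = []
    for region in regions:
        tiles.extend(tile_region(region, proteome, length=length, step=step))
    return tiles


def generate_variants(
    tiles: list[PeptideTile],
    sites: list[PhosphositeRecord],
) -> tuple[list[LibraryEntry], list[PhosphositeRecord]]:
    """Map phosphosites onto tiles and emit wild-type/phosphomimetic entries.

    Each tile covering k sites yields one shared wild-type entry plus k
    single-mutant entries — only one S/T->E mutation per displayed peptide,
    even when several sites fall in the same tile.  Wild-type entries are
    deduplicated by peptide sequence.  Returns ``(entries, uncovered)``
    where ``uncovered`` lists sites not covered by any tile.
    """
    mismatches = []
    for s in sites:
        for t in tiles:
            if t.protein_ac == s.protein_ac and t.covers(s.position):
                if t.sequence[s.position - t.start] != s.residue:
                    mismatches.append(s)
                break
    if mismatches:
        listing = ", ".join(f"{s.protein_ac}:{s.position}{s.residue}" for s in mismatches)
        raise DesignError(f"phosphosite residue mismatch with proteome: {listing}")

    entries: list[LibraryEntry] = []
    seen_wt: set[str] = set()
    covered: set[tuple[str, int]] = set()
    for tile in tiles:
        tile_sites = [
            s for s in sites if s.protein_ac == tile.protein_ac and tile.covers(s.position)
        ]
        if not tile_sites:
            continue
        if tile.sequence not in seen_wt:
            seen_wt.add(tile.sequence)
            entries.append(LibraryEntry(tile, WILD_TYPE, tile.sequence))
        for s in tile_sites:
            covered.add((s.protein_ac, s.position))
            idx = s.position - tile.start  # 0-based within peptide
            mutant = tile.sequence[:idx] + "E" + tile.sequence[idx + 1 :]
            entries.append(
                LibraryEntry(tile, PHOSPHOMIMETIC, mutant, phosphosite=s,
                             mutated_position=idx + 1)
            )
    uncovered = [s for s in sites if (s.protein_ac, s.position) not in covered]
    return entries, uncovered


def _find_forbidden(seq: str, motifs: tuple[str, ...]) -> tuple[int, str] | None:
    """Leftmost occurrence of any forbidden motif, or None."""
    best: tuple[int, str] | None = None
    for m in motifs:
        pos = seq.find(m)
        if pos >= 0 and (best is None or pos < best[0]):
            best = (pos, m)
    return best


def reverse_translate(
    peptide: str,
    codon_table: dict[str, tuple[str, ...]] | None = None,
    forbidden_motifs: tuple[str, ...] = (SMAI_SITE,),
    flank_5prime: str = "",
    flank_3prime: str = "",
) -> str:
    """Reverse translate a peptide with ranked codons, avoiding motifs.

    Deterministic greedy: every residue gets its top-ranked codon; while the
    flanked construct contains a forbidden motif, the left-most codon
    overlapping the left-most occurrence is swapped for the best-ranked
    alternative that pushes the left-most occurrence rightward (or removes
    it).  Progress is strictly monotone so the loop terminates.
    """
    table = codon_table if codon_table is not None else ECOLI_RANKED_CODONS
    for aa in peptide:
        if aa not in table or not table[aa]:
            raise ValueError(f"no codon available for amino acid {aa!r}")

    codons = [table[aa][0] for aa in peptide]

    def construct() -> str:
        return flank_5prime + "".join(codons) + flank_3prime

    offset = len(flank_5prime)
    while True:
        hit = _find_forbidden(construct(), forbidden_motifs)
        if hit is None:
            return "".join(codons)
        pos, motif = hit
        # codon indices overlapping the motif occurrence
        lo = max(0, (pos - offset) // 3)
        hi = min(len(codons) - 1, (pos + len(motif) - 1 - offset) // 3)
        if pos + len(motif) <= offset or pos >= offset + 3 * len(codons):
            raise DesignError(
                f"forbidden motif {motif} lies entirely within the flanks; "
                "peptide codons cannot remove it"
            )
        fixed = False
        for i in range(lo, hi + 1):
            current = codons[i]
            for alt in table[peptide[i]]:
                if alt == current:
                    continue
                codons[i] = alt
                new_hit = _find_forbidden(construct(), forbidden_motifs)
                if new_hit is None or new_hit[0] > pos:
                    fixed = True
                    break
                codons[i] = current
            if fixed:
                break
        if not fixed:
            raise DesignError(
                f"cannot avoid forbidden motif {motif} while encoding peptide "
                f"{peptide!r}"
            )


def translate(oligo: str) -> str:
    """Standard-genetic-code translation (round-trip check helper)."""
    return str(Seq(oligo).translate())


def attach_oligos(
    entries: list[LibraryEntry],
    codon_table: dict[str, tuple[str, ...]] | None = None,
    forbidden_motifs: tuple[str, ...] = (SMAI_SITE,),
    flank_5prime: str = "",
    flank_3prime: str = "",
) -> list[LibraryEntry]:
    return [
        replace(
            e,
            oligo=reverse_translate(
                e.peptide_seq,
                codon_table=codon_table,
                forbidden_motifs=forbidden_motifs,
                flank_5prime=flank_5prime,
                flank_3prime=flank_3prime,
            ),
        )
        for e in entries
    ]


def compute_library_stats(entries: list[LibraryEntry]) -> LibraryStats:
    """Summarize a design: counts, pair completeness and position histograms."""
    stats = LibraryStats()
    if not entries:
        return stats
    pm = [e for e in entries if e.variant == PHOSPHOMIMETIC]
    wt_seqs = {e.peptide_seq for e in entries if e.variant == WILD_TYPE}

    sites = {(e.phosphosite.protein_ac, e.phosphosite.position) for e in pm}
    stats.n_phosphosites = len(sites)
    stats.n_peptides = len({(e.peptide_seq, e.variant) for e in entries})
    stats.n_pairs = len(pm)
    complete = sum(1 for e in pm if e.tile.sequence in wt_seqs)
    stats.fraction_complete_pairs = complete / len(pm) if pm else 0.0

    coverage = Counter(
        (e.phosphosite.protein_ac, e.phosphosite.position) for e in pm
    )
    stats.site_coverage_histogram = dict(Counter(coverage.values()))
    stats.mutated_position_histogram = dict(
        Counter(e.mutated_position for e in pm)
    )
    return stats


def design_library(
    proteome: dict[str, str],
    sites: list[PhosphositeRecord],
    regions: list[DisorderedRegion],
    length: int = 16,
    step: int = 4,
    loc_min: float = 0.75,
    func_min: float = 0.4524,
    rescue_accessions: set[str] | frozenset[str] = frozenset(),
    codon_table: dict[str, tuple[str, ...]] | None = None,
    forbidden_motifs: tuple[str, ...] = (SMAI_SITE,),
    flank_5prime: str = "",
    flank_3prime: str = "",
) -> tuple[list[LibraryEntry], list[PhosphositeRecord], LibraryStats]:
    """End-to-end design: filter, tile, mutate, reverse translate, summarize."""
    kept = filter_phosphosites(sites, loc_min, func_min, rescue_accessions)
    tiles = tile_regions(regions, proteome, length=length, step=step)
    entries, uncovered = generate_variants(tiles, kept)
    entries = attach_oligos(
        entries,
        codon_table=codon_table,
        forbidden_motifs=forbidden_motifs,
        flank_5prime=flank_5prime,
        flank_3prime=flank_3prime,
    )
    return entries, uncovered, compute_library_stats(entries)
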