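"""Readers and writers for the package's file interfaces.

Proteomes are FASTA (Biopython), phosphosites and disordered regions are
TSV, designs round-trip through a one-row-per-entry TSV plus an oligo
FASTA, count tables are two-column TSVs, and configuration is YAML/JSON.
All user-facing coordinates are 1-based inclusive.
"""

from __future__ import annotations

import json

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from phosdisplay.library_design import (
    DisorderedRegion,
    LibraryEntry,
    PeptideTile,
    PhosphositeRecord,
)
from phosdisplay.selection_processing import SelectionCounts


def read_proteome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_proteome_fasta(proteome: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=ac, description="") for ac, seq in proteome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _split_list(cell) -> tuple[str, ...]:
    if pd.isna(cell) or cell == "":
        return ()
    return tuple(str(cell).split(";"))


def read_phosphosites_tsv(path) -> list[PhosphositeRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    records = []
    for _, row in df.iterrows():
        records.append(
            PhosphositeRecord(
                protein_ac=str(row["protein_ac"]),
                position=int(row["position"]),
                residue=str(row["residue"]),
                localization_prob=float(row["localization_prob"]),
                functional_score=float(row["functional_score"]),
                kinases=_split_list(row.get("kinases", "")),
                phosphatases=_split_list(row.get("phosphatases", "")),
            )
        )
    return records


def write_phosphosites_tsv(sites: list[PhosphositeRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "protein_ac": s.protein_ac,
                "position": s.position,
                "residue": s.residue,
                "localization_prob": s.localization_prob,
                "functional_score": s.functional_score,
                "kinases": ";".join(s.kinases),
                "phosphatases": ";".join(s.phosphatases),
            }
            for s in sites
        ]
    ).to_csv(path, sep="\t", index=False)


def read_regions_tsv(path) -> list[DisorderedRegion]:
    df = pd.read_csv(path, sep="\t")
    return [
        DisorderedRegion(str(r["protein_ac"]), int(r["start"]), int(r["end"]))
        for _, r in df.iterrows()
    ]


def write_regions_tsv(regions: list[DisorderedRegion], path) -> None:
    pd.DataFrame(
        [{"protein_ac": r.protein_ac, "start": r.start, "end": r.end} for r in regions]
    ).to_csv(path, sep="\t", index=False)


def write_design_tsv(entries: list[LibraryEntry], path) -> None:
    rows = []
    for e in entries:
        rows.append(
            {
                "protein_ac": e.tile.protein_ac,
                "tile_start": e.tile.start,
                "tile_end": e.tile.end,
                "tile_seq": e.tile.sequence,
                "variant": e.variant,
                "site_position": (
                    e.phosphosite.position if e.phosphosite is not None else ""
                ),
                "mutated_position": e.mutated_position or "",
                "peptide": e.peptide_seq,
                "oligo": e.oligo,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_design_tsv(path) -> list[LibraryEntry]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    entries = []
    for _, r in df.iterrows():
        tile = PeptideTile(
            str(r["protein_ac"]), int(r["tile_start"]), int(r["tile_end"]),
            str(r["tile_seq"]),
        )
        site = None
        mut = None
        if str(r["variant"]) == "phosphomimetic":
            pos = int(r["site_position"])
            site = PhosphositeRecord(
                protein_ac=str(r["protein_ac"]), position=pos,
                residue=tile.sequence[pos - tile.start],
                localization_prob=1.0, functional_score=1.0,
            )
            mut = int(r["mutated_position"])
        entries.append(
            LibraryEntry(tile, str(r["variant"]), str(r["peptide"]),
                         phosphosite=site, mutated_position=mut,
                         oligo=str(r["oligo"]))
        )
    return entries


def write_oligo_fasta(entries: list[LibraryEntry], path) -> None:
    records = []
    for i, e in enumerate(entries):
        name = f"{e.tile.protein_ac}_{e.tile.start}_{e.tile.end}_{e.variant}_{i}"
        records.append(SeqRecord(Seq(e.oligo), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_counts_tsv(table: SelectionCounts, path) -> None:
    df = pd.DataFrame(
        sorted(table.counts.items()), columns=["peptide", "count"]
    )
    with open(path, "w") as fh:
        fh.write(
            f"# experiment={table.experiment_id} bait={table.bait_id} "
            f"replicate={table.replicate_id} day={table.selection_day} "
            f"stage={table.stage}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path) -> SelectionCounts:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip()
        meta = dict(kv.split("=") for kv in header.split())
        df = pd.read_csv(fh, sep="\t")
    return SelectionCounts(
        experiment_id=meta.get("experiment", ""),
        bait_id=meta.get("bait", ""),
        replicate_id=meta.get("replicate", ""),
        selection_day=int(meta.get("day", 0)),
        stage=meta.get("stage", "raw"),
        counts=dict(zip(df["peptide"], df["count"].astype(float))),
    )


def read_config(path) -> dict:
    text = open(path).read()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def read_fp_plate_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
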