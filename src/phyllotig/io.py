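"""File formats: FASTA (Biopython), flat TSV tables, and GFF3 export.

Canonical on-disk schemas used across the pipeline:

* contigs / trimmed contigs — plain FASTA;
* 16S reference DB — FASTA with a semicolon-delimited 6-rank lineage in the
  description (``>REF001 Phylum;Class;Order;Family;Genus;Species``);
* depths — 2-column TSV ``contig_id, mean_depth``;
* annotations — flat TSV with the closed label vocabulary plus nullable
  best-hit taxonomy columns (also exportable as GFF3);
* external scores — per-contig TSV ``contig_id, phage_score,
  viral_completeness, genome_completeness, contamination``;
* community profiles — TSV ``taxon, relative_abundance, n_genes, n_contigs``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .qc import Contig
from .ssu import RANKS, CommunityProfile, SSURecord
from .synthetic import ANNOTATION_COLUMNS


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_contigs(fasta_path: str | Path, depths: Mapping[str, float] | None = None) -> list[Contig]:
    contigs = [Contig(contig_id=name, sequence=seq) for name, seq in read_fasta(fasta_path).items()]
    if depths is not None:
        for contig in contigs:
            if contig.contig_id in depths:
                contig.mean_depth = float(depths[contig.contig_id])
    return contigs


def read_reference_db(path: str | Path) -> list[SSURecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        lineage = tuple(rec.description.split(maxsplit=1)[1].split(";")) if " " in rec.description else ()
        if len(lineage) != len(RANKS):
            raise ValueError(f"reference record {rec.id!r}: expected a 6-rank ';'-delimited lineage")
        records.append(SSURecord(ref_id=rec.id, lineage=lineage, sequence=str(rec.seq).upper()))
    return records


def write_reference_db(path: str | Path, records: Iterable[SSURecord]) -> None:
    seqs = {f"{r.ref_id} {';'.join(r.lineage)}": r.sequence for r in records}
    # SeqRecord splits id/description on the first space
    out = [
        SeqRecord(Seq(seq), id=header.split()[0], description=header.split(maxsplit=1)[1])
        for header, seq in seqs.items()
    ]
    with open(path, "w") as handle:
        SeqIO.write(out, handle, "fasta")


def read_depths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("contig_id")["mean_depth"].astype(float)


def write_depths(path: str | Path, depths: pd.Series | Mapping[str, float]) -> None:
    ser = pd.Series(depths, name="mean_depth").rename_axis("contig_id")
    ser.to_frame().to_csv(path, sep="\t")


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "gene_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df[ANNOTATION_COLUMNS]


def write_annotations(path: str | Path, annotations: pd.DataFrame) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def write_gff3(path: str | Path, annotations: pd.DataFrame, contig_lengths: Mapping[str, int]) -> None:
    """Export the annotation table as GFF3 (one `gene` feature per row)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, length in contig_lengths.items():
            fh.write(f"##sequence-region {cid} 1 {length}\n")
        for _, row in annotations.iterrows():
            attrs = [f"ID={row['gene_id']}", f"label={row['label']}"]
            if isinstance(row.get("hit_species"), str):
                attrs.append(f"hit_species={row['hit_species']}")
            fh.write(
                "\t".join(
                    [
                        str(row["contig_id"]),
                        "phyllotig",
                        "gene",
                        str(int(row["start"])),
                        str(int(row["end"])),
                        ".",
                        str(row["strand"]),
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_external_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("contig_id")


def write_external_scores(path: str | Path, scores: pd.DataFrame) -> None:
    df = scores.reset_index() if scores.index.name == "contig_id" else scores
    df.to_csv(path, sep="\t", index=False)


def write_profile(path: str | Path, profile: CommunityProfile) -> None:
    profile.table.rename_axis("taxon").to_csv(path, sep="\t")


def read_profile(path: str | Path) -> CommunityProfile:
    table = pd.read_csv(path, sep="\t").set_index("taxon")
    return CommunityProfile(table=table, weighting="per_contig")
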