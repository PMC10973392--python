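"""Generate the ground-truthed synthetic phyllosphere community.

Writes the inputs every later analysis step consumes: contig FASTA, per-contig
depth TSV, gene-annotation TSV (+GFF3), the 16S reference database with
lineages, external per-contig scores, the planted truth table, and an
amplicon-style companion profile.
"""

import argparse
from pathlib import Path

import phyllotig as pt
from phyllotig.io import (
    write_annotations,
    write_depths,
    write_external_scores,
    write_fasta,
    write_gff3,
    write_profile,
    write_reference_db,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--n-taxa", type=int, default=20)
    parser.add_argument("--n-contigs", type=int, default=80)
    parser.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    db = pt.generate_reference_db(n_taxa=args.n_taxa, seed=args.seed)
    config = pt.CommunityConfig(seed=args.seed, n_taxa=args.n_taxa, n_contigs=args.n_contigs)
    community = pt.generate_community(config, db)

    write_fasta(args.outdir / "contigs.fasta", community.contigs)
    write_depths(args.outdir / "depths.tsv", community.depths)
    write_annotations(args.outdir / "annotations.tsv", community.annotations)
    write_gff3(args.outdir / "annotations.gff3", community.annotations,
               {c: len(s) for c, s in community.contigs.items()})
    write_reference_db(args.outdir / "reference_16s.fasta", [t.as_ssu_record() for t in db])
    write_external_scores(args.outdir / "external_scores.tsv",
                          community.external_scores.set_index("contig_id"))
    community.truth.to_csv(args.outdir / "truth.tsv", sep="\t", index=False)
    write_profile(args.outdir / "amplicon_profile.tsv",
                  pt.make_amplicon_profile(community, seed=args.seed + 1))

    tally = community.truth["true_class"].value_counts()
    total_mb = sum(len(s) for s in community.contigs.values()) / 1e6
    print(f"community: {len(community.contigs)} contigs, {total_mb:.1f} Mbp, "
          f"{int(community.truth['circular'].sum())} circular")
    print("planted replicon classes:")
    print(tally.to_string())
    print(f"planted 16S copies: {int(community.truth['n_ssu_copies'].sum())} "
          f"on {(community.truth['n_ssu_copies'] > 0).sum()} contigs")
    print(f"inputs written to {args.outdir}/")


if __name__ == "__main__":
    main()
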