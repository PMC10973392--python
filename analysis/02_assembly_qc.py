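"""Assembly summary and high-quality contig filtering.

Prints an assembly-summary table (all contigs vs the depth-filtered
high-quality set) in the layout of a long-read metagenome study's headline
table, and writes it to results/assembly_stats.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

import phyllotig as pt
from phyllotig.io import read_annotations, read_contigs, read_depths


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/assembly_stats.tsv"))
    parser.add_argument("--min-depth", type=float, default=5.0)
    args = parser.parse_args()

    depths = read_depths(args.datadir / "depths.tsv")
    contigs = read_contigs(args.datadir / "contigs.fasta")
    annotations = read_annotations(args.datadir / "annotations.tsv")
    artifacts = [c for c in contigs if pt.detect_low_complexity(c)]
    clean = [c for c in contigs if c not in artifacts]
    hq = pt.filter_high_quality(clean, depths, min_depth=args.min_depth)

    n_cds_all = len(annotations[annotations["label"] != "SSU_RRNA"])
    hq_ids = {c.contig_id for c in hq}
    n_cds_hq = len(annotations[(annotations["label"] != "SSU_RRNA")
                               & annotations["contig_id"].isin(hq_ids)])

    rows = {}
    for label, subset, n_cds in (("Total contigs", contigs, n_cds_all),
                                 ("High quality contigs", hq, n_cds_hq)):
        s = pt.compute_stats(subset, n_cds=n_cds)
        rows[label] = {
            "Number of the contigs": s.n_contigs,
            "Total nucleotides (bp)": s.total_bp,
            "Number of nucleotides (bp, >=50 kbp)": s.bp_ge_50kbp,
            "Largest contig size (bp)": s.largest_bp,
            "Contig N50": s.n50,
            "Predicted CDS": s.n_cds,
            "Number of contigs >=1 Mbp": s.n_ge_1mbp,
        }
    table = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t")

    print(f"{len(artifacts)} low-complexity artifact contigs removed; "
          f"{len(hq)} of {len(contigs)} contigs have depth > {args.min_depth:g}")
    print(table.to_string())
    hq_frac = table.loc["Total nucleotides (bp)", "High quality contigs"] / \
        table.loc["Total nucleotides (bp)", "Total contigs"]
    print(f"high-quality contigs hold {100 * hq_frac:.1f}% of assembled bases "
          f"(summary: {args.out})")


if __name__ == "__main__":
    main()
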