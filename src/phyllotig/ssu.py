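"""Full-length 16S rRNA taxonomy: reference curation, tiered rank assignment,
and depth-weighted community profiling.

The reference set is curated the way full-length 16S databases are built:
short records (<=1400 bp) are discarded and the remainder greedily clustered
at 97% identity, longest sequence first, keeping cluster representatives.
Metagenome-derived 16S genes are aligned to the curated set (overlap
alignment; hits covering <95% of the query are dropped) and the top-hit
identity is mapped onto taxonomic-rank tiers: >=97% species, >=94.5% genus,
>=86.5% family, >=82% order, >=78% class, below that unresolved. A gene whose
best hit falls below the species tier is a candidate novel taxon at the rank
one step below its resolved tier (e.g. a 90% hit resolves to a known family
and flags a potentially novel genus).

Community profiles are depth-weighted: each 16S-bearing contig contributes
its mean read depth, so multi-copy operons on one replicon do not inflate a
species (per-contig weighting, the default); per-gene weighting is available
for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .align import align_overlap, pairwise_identity

logger = logging.getLogger(__name__)

RANKS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class SSURecord:
    """A full-length 16S reference sequence with a 6-rank lineage."""

    ref_id: str
    lineage: tuple[str, ...]
    sequence: str

    def __post_init__(self) -> None:
        if len(self.lineage) != len(RANKS) or not all(self.lineage):
            raise ValueError(f"{self.ref_id}: lineage must have 6 non-empty ranks")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def species(self) -> str:
        return self.lineage[-1]


@dataclass(frozen=True)
class SSUGene:
    """A 16S gene extracted from a metagenome contig."""

    gene_id: str
    contig_id: str
    sequence: str
    contig_depth: float | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Hit:
    gene_id: str
    ref_id: str
    identity: float
    query_coverage: float


@dataclass(frozen=True)
class RankTiers:
    """Identity thresholds (percent) mapping top-hit identity to rank tiers."""

    species: float = 97.0
    genus: float = 94.5
    family: float = 86.5
    order: float = 82.0
    class_: float = 78.0

    def __post_init__(self) -> None:
        vals = (self.species, self.genus, self.family, self.order, self.class_)
        if not all(a > b for a, b in zip(vals, vals[1:])):
            raise ValueError("rank tier thresholds must be strictly decreasing")


#: (tier attribute, resolved rank, novelty flag), highest tier first.
_TIER_TABLE = (
    ("species", "species", "known_species"),
    ("genus", "genus", "novel_species"),
    ("family", "family", "novel_genus"),
    ("order", "order", "novel_family"),
    ("class_", "class", "novel_order"),
)


@dataclass(frozen=True)
class RankAssignment:
    gene_id: str
    ref_id: str
    lineage: tuple[str, ...]
    identity: float
    query_coverage: float
    resolved_rank: str
    novelty_flag: str


@dataclass(frozen=True)
class CommunityProfile:
    """Per-taxon relative abundance (percent) with gene/contig tallies."""

    table: pd.DataFrame  # index taxon; columns relative_abundance, n_genes, n_contigs
    weighting: str

    @property
    def taxa(self) -> list[str]:
        return list(self.table.index)

    def abundance(self, taxon: str) -> float:
        if taxon not in self.table.index:
            return 0.0
        return float(self.table.loc[taxon, "relative_abundance"])


@dataclass(frozen=True)
class ProfileComparison:
    above_threshold_in_b: tuple[str, ...]
    n_present_in_a: int
    combined_abundance_a: float
    combined_abundance_b: float


def clustering_identity(query: str, ref: str, min_coverage: float = 90.0) -> float:
    """Coverage-gated percent identity for whole-sequence comparisons.

    Overlap alignment of two unrelated sequences can degenerate to a few
    perfectly matching terminal columns, which would read as spuriously high
    identity. For clustering and database curation — where both sequences are
    full-length genes of the same locus — identity is therefore only
    meaningful when the alignment covers most of the query; below
    ``min_coverage`` percent the pair is treated as unalignable (0.0).
    """
    identity, coverage = pairwise_identity(query, ref)
    return identity if coverage >= min_coverage else 0.0


def curate_reference_db(
    records: Sequence[SSURecord],
    min_len: int = 1400,
    cluster_identity: float = 97.0,
    min_absorb_coverage: float = 90.0,
) -> list[SSURecord]:
    """Length-filter then greedily cluster a 16S reference set.

    Records of length <= ``min_len`` are removed. Survivors are sorted by
    length descending (ties by ref_id) and clustered first-fit: each record
    joins the first existing representative it matches at
    >= ``cluster_identity`` percent identity over an alignment covering at
    least ``min_absorb_coverage`` percent of it (see
    :func:`clustering_identity`), otherwise it seeds a new cluster. Returns
    the representatives in seeding order.
    """
    if not records:
        raise ValueError("curate_reference_db requires at least one record")
    survivors = [r for r in records if r.length > min_len]
    if not survivors:
        logger.warning("all %d reference records removed by the %d bp length filter", len(records), min_len)
        return []
    survivors.sort(key=lambda r: (-r.length, r.ref_id))
    reps: list[SSURecord] = []
    for rec in survivors:
        for rep in reps:
            if clustering_identity(rec.sequence, rep.sequence, min_absorb_coverage) >= cluster_identity:
                break
        else:
            reps.append(rec)
    return reps


def search_top_hit(
    gene: SSUGene,
    db: Sequence[SSURecord],
    min_coverage: float = 95.0,
) -> Hit | None:
    """Best reference hit by identity among alignments covering >=95% of the gene.

    Ties on identity break toward higher coverage, then lexicographically
    smaller ref_id. Returns None when no alignment passes the coverage filter.
    """
    if gene.length < 1400:
        raise ValueError(f"gene {gene.gene_id!r} is {gene.length} bp; full-length (>=1400 bp) required")
    best: tuple[float, float, str] | None = None
    for ref in db:
        res = align_overlap(gene.sequence, ref.sequence)
        if res.query_coverage < min_coverage:
            continue
        key = (res.identity, res.query_coverage, ref.ref_id)
        if best is None or (key[0], key[1]) > (best[0], best[1]) or (
            (key[0], key[1]) == (best[0], best[1]) and key[2] < best[2]
        ):
            best = key
    if best is None:
        return None
    return Hit(gene_id=gene.gene_id, ref_id=best[2], identity=best[0], query_coverage=best[1])


def assign_rank(identity: float, tiers: RankTiers = RankTiers()) -> tuple[str, str]:
    """Map a top-hit identity onto (resolved_rank, novelty_flag).

    Tiers are lower-inclusive half-open intervals; identities below the class
    tier resolve to ("unresolved", "novel_class").
    """
    if not 0.0 < identity <= 100.0:
        raise ValueError(f"identity must be in (0, 100], got {identity}")
    for attr, rank, flag in _TIER_TABLE:
        if identity >= getattr(tiers, attr):
            return rank, flag
    return "unresolved", "novel_class"


def assign_taxonomy(
    genes: Iterable[SSUGene],
    db: Sequence[SSURecord],
    tiers: RankTiers = RankTiers(),
    min_coverage: float = 95.0,
) -> list[RankAssignment]:
    """Top-hit search plus tier assignment for each gene; hit-less genes are skipped."""
    ref_by_id = {r.ref_id: r for r in db}
    out: list[RankAssignment] = []
    for gene in genes:
        hit = search_top_hit(gene, db, min_coverage=min_coverage)
        if hit is None:
            continue
        rank, flag = assign_rank(hit.identity, tiers)
        out.append(
            RankAssignment(
                gene_id=gene.gene_id,
                ref_id=hit.ref_id,
                lineage=ref_by_id[hit.ref_id].lineage,
                identity=hit.identity,
                query_coverage=hit.query_coverage,
                resolved_rank=rank,
                novelty_flag=flag,
            )
        )
    return out


def tier_counts(assignments: Sequence[RankAssignment], genes: Sequence[SSUGene]) -> pd.DataFrame:
    """Genes and contigs per identity tier (the classic threshold table layout)."""
    contig_of = {g.gene_id: g.contig_id for g in genes}
    rows = []
    order = [t[1] for t in _TIER_TABLE] + ["unresolved"]
    by_rank: dict[str, list[RankAssignment]] = {r: [] for r in order}
    for a in assignments:
        by_rank[a.resolved_rank].append(a)
    thresholds = {"species": 97.0, "genus": 94.5, "family": 86.5, "order": 82.0, "class": 78.0, "unresolved": float("nan")}
    for rank in order:
        assigned = by_rank[rank]
        rows.append(
            {
                "identity_threshold": thresholds[rank],
                "taxonomic_rank": rank,
                "n_genes": len(assigned),
                "n_contigs": len({contig_of[a.gene_id] for a in assigned}),
            }
        )
    return pd.DataFrame(rows)


def profile_community(
    assignments: Sequence[RankAssignment],
    genes: Sequence[SSUGene],
    weighting: Literal["per_contig", "per_gene"] = "per_contig",
) -> CommunityProfile:
    """Species-level, depth-weighted community profile.

    Only genes at the species tier (identity >= species threshold, i.e.
    ``known_species``) enter the profile, mirroring species-level
    approximation from top hits. Under ``per_contig`` weighting a contig
    contributes its depth once per taxon regardless of how many 16S copies of
    that taxon it carries; under ``per_gene`` every copy contributes.
    Abundances are normalised to sum to 100.
    """
    if weighting not in ("per_contig", "per_gene"):
        raise ValueError(f"unknown weighting {weighting!r}")
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    for a in assignments:
        if a.novelty_flag != "known_species":
            continue
        gene = gene_by_id[a.gene_id]
        if gene.contig_depth is None:
            raise MissingDepthForGene(gene.gene_id)
        rows.append(
            {
                "taxon": a.lineage[-1],
                "contig_id": gene.contig_id,
                "gene_id": gene.gene_id,
                "depth": float(gene.contig_depth),
            }
        )
    if not rows:
        return CommunityProfile(
            table=pd.DataFrame(columns=["relative_abundance", "n_genes", "n_contigs"]),
            weighting=weighting,
        )
    df = pd.DataFrame(rows)
    if weighting == "per_contig":
        per = df.drop_duplicates(["taxon", "contig_id"]).groupby("taxon")["depth"].sum()
    else:
        per = df.groupby("taxon")["depth"].sum()
    table = pd.DataFrame(
        {
            "relative_abundance": 100.0 * per / per.sum(),
            "n_genes": df.groupby("taxon")["gene_id"].nunique(),
            "n_contigs": df.groupby("taxon")["contig_id"].nunique(),
        }
    ).sort_values("relative_abundance", ascending=False)
    return CommunityProfile(table=table, weighting=weighting)


class MissingDepthForGene(KeyError):
    def __init__(self, gene_id: str):
        super().__init__(gene_id)
        self.gene_id = gene_id

    def __str__(self) -> str:
        return f"gene {self.gene_id!r} has no contig depth"


def compare_profiles(
    a: CommunityProfile,
    b: CommunityProfile,
    threshold: float = 1.0,
) -> ProfileComparison:
    """Overlap of the dominant taxa of ``b`` with ``a``.

    Reports the taxa of ``b`` above the abundance threshold, how many of them
    occur in ``a`` at all, and the combined abundance of that taxon set
    evaluated in each profile separately.
    """
    above = tuple(t for t in b.taxa if b.abundance(t) > threshold)
    present = [t for t in above if t in a.taxa]
    return ProfileComparison(
        above_threshold_in_b=above,
        n_present_in_a=len(present),
        combined_abundance_a=float(sum(a.abundance(t) for t in above)),
        combined_abundance_b=float(sum(b.abundance(t) for t in above)),
    )
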