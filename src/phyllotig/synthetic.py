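"""Ground-truthed synthetic metagenome communities.

Emulates the structure of a PacBio-style long-read phyllosphere assembly so
every downstream stage can be tested against planted truth: a reference set of
full-length 16S sequences with consistent 6-rank lineages; contigs of mixed
replicon classes (chromosome, megaplasmid, repABC plasmid, putative plasmid,
bacteriophage, unclassified) with class-appropriate sizes and marker genes;
circular contigs emitted as linear strings with the first ``terminal_overlap_len``
bases duplicated at the end; multi-copy 16S genes spliced into chromosome and
megaplasmid sequences at controlled divergence from their source reference;
log-normal per-contig read depths; and per-contig external scores of the kind
produced by viral/completeness screens.

16S templates are random sequences flanked by fixed conserved 100-bp blocks
(so overlap alignments anchor end-to-end); real 16S secondary structure is not
modelled — identity arithmetic is the point. Divergence is substitution-only,
which makes the realized identity exactly controllable. Only the 16S rows
correspond to actual planted sequence; marker and filler gene rows are
annotation-level truth (coordinates are bookkeeping, not sequence content),
which is all the rule-based classifier consumes.

Determinism: every output is a pure function of (config, db, seed); one global
seed is split into independent per-purpose streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ssu import RANKS, CommunityProfile, SSURecord, clustering_identity
from .classify import REPLICON_CLASSES, T4SS_COMPONENTS, VIRB_COMPONENTS

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed conserved 16S end blocks shared by every reference template
_cons_rng = np.random.default_rng(16051962)
CONSERVED_5 = bytes(_BASES[_cons_rng.integers(0, 4, size=100)]).decode()
CONSERVED_3 = bytes(_BASES[_cons_rng.integers(0, 4, size=100)]).decode()
del _cons_rng

ANNOTATION_COLUMNS = [
    "contig_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "label",
    "hit_species",
    "hit_genus",
    "hit_phylum",
    "hit_identity",
    "hit_coverage",
]

#: class proportions of the default community, echoing the observed tally of
#: classified circular elements (repABC : putative plasmid : phage : unclassified
#: roughly 41 : 59 : 29 : 6) with chromosomes/megaplasmids included so that 16S
#: profiling has carriers.
DEFAULT_REPLICON_MIX = {
    "chromosome": 0.10,
    "megaplasmid": 0.05,
    "repABC_plasmid": 0.30,
    "putative_plasmid": 0.35,
    "bacteriophage": 0.15,
    "unclassified": 0.05,
}

#: default 16S divergence targets (percent identity to the source reference),
#: spanning the rank tiers from known species down to a potential novel class;
#: deliberately off the tier boundaries so a target maps to one tier only.
DEFAULT_DIVERGENCE_LEVELS = (99.5, 98.5, 97.5, 96.0, 90.0, 84.0, 80.0, 76.5)

_SIZE_RANGES = {
    "chromosome": (1_000_000, 5_000_000),
    "megaplasmid": (1_000_000, 2_500_000),
    "repABC_plasmid": (8_000, 500_000),
    "putative_plasmid": (8_000, 300_000),
    "bacteriophage": (10_000, 80_000),
    "unclassified": (8_000, 100_000),
}


@dataclass(frozen=True)
class ReferenceTaxon:
    """A reference organism: 6-rank lineage plus its full-length 16S sequence."""

    taxon_id: str
    lineage: tuple[str, ...]
    ssu_sequence: str

    def __post_init__(self) -> None:
        if len(self.lineage) != len(RANKS) or not all(self.lineage):
            raise ValueError(f"{self.taxon_id}: lineage must have 6 non-empty ranks")
        if len(self.ssu_sequence) < 1400:
            raise ValueError(f"{self.taxon_id}: 16S sequence shorter than 1400 bp")
        if set(self.ssu_sequence) - set("ACGT"):
            raise ValueError(f"{self.taxon_id}: 16S sequence has non-ACGT characters")

    @property
    def species(self) -> str:
        return self.lineage[-1]

    def as_ssu_record(self) -> SSURecord:
        return SSURecord(ref_id=self.taxon_id, lineage=self.lineage, sequence=self.ssu_sequence)


@dataclass(frozen=True)
class CommunityConfig:
    """Knobs of the synthetic community; defaults are the study conditions."""

    seed: int
    n_taxa: int = 20
    n_contigs: int = 40
    replicon_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REPLICON_MIX))
    ssu_copy_range: tuple[int, int] = (1, 4)
    divergence_levels: tuple[float, ...] = DEFAULT_DIVERGENCE_LEVELS
    depth_lognormal_params: tuple[float, float] = (2.0, 1.0)
    circular_fraction: float = 0.8
    terminal_overlap_len: int = 2000

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_contigs < 1:
            raise ValueError("n_taxa and n_contigs must be positive")
        if set(self.replicon_mix) - set(REPLICON_CLASSES):
            raise ValueError(f"unknown replicon classes in mix: {set(self.replicon_mix) - set(REPLICON_CLASSES)}")
        total = sum(self.replicon_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"replicon_mix proportions must sum to 1, got {total}")
        if not all(70.0 < d <= 100.0 for d in self.divergence_levels):
            raise ValueError("divergence levels must lie in (70, 100]")
        if self.terminal_overlap_len < 1:
            raise ValueError("terminal_overlap_len must be >= 1")
        if not 0.0 <= self.circular_fraction <= 1.0:
            raise ValueError("circular_fraction must be in [0, 1]")
        lo, hi = self.ssu_copy_range
        if lo < 1 or hi < lo:
            raise ValueError("ssu_copy_range must be a positive interval")


@dataclass
class SyntheticCommunity:
    """Generated inputs plus the planted truth table."""

    contigs: dict[str, str]
    annotations: pd.DataFrame
    depths: pd.Series
    truth: pd.DataFrame
    external_scores: pd.DataFrame


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def generate_reference_db(n_taxa: int, seed: int) -> list[ReferenceTaxon]:
    """Reference taxa with consistent lineages and mutually distinct 16S.

    Lineages form a hierarchy (shared genus implies shared family and so on
    up). Inter-species 16S identity is kept below the species threshold (97%)
    by construction, enforced by rejection sampling against the accepted set.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))

    # nested hierarchy: each level subdivides its parent
    genera: list[tuple[str, ...]] = []
    n_phyla = max(1, int(np.ceil(n_taxa / 8)))
    counters = {rank: 0 for rank in RANKS[:-1]}

    def _name(rank: str) -> str:
        counters[rank] += 1
        return f"{rank.capitalize()}_{counters[rank]:02d}"

    for _ in range(n_phyla):
        phylum = _name("phylum")
        for _ in range(int(rng.integers(1, 3))):
            klass = _name("class")
            for _ in range(int(rng.integers(1, 3))):
                order = _name("order")
                for _ in range(int(rng.integers(1, 3))):
                    family = _name("family")
                    for _ in range(int(rng.integers(1, 4))):
                        genera.append((phylum, klass, order, family, _name("genus")))

    taxa: list[ReferenceTaxon] = []
    for i in range(n_taxa):
        genus_path = genera[int(rng.integers(0, len(genera)))]
        for _attempt in range(100):
            core_len = int(rng.integers(1250, 1401))
            seq = CONSERVED_5 + bytes(_random_dna(rng, core_len)).decode() + CONSERVED_3
            if all(clustering_identity(seq, t.ssu_sequence) < 97.0 for t in taxa):
                break
        else:  # pragma: no cover - random sequences essentially never collide
            raise RuntimeError("could not generate a 16S template below 97% identity")
        taxa.append(
            ReferenceTaxon(
                taxon_id=f"TAX{i:04d}",
                lineage=(*genus_path, f"Species_{i:03d}"),
                ssu_sequence=seq,
            )
        )
    return taxa


def mutate_to_identity(seq: str, target_identity: float, seed: int) -> str:
    """Substitute bases to hit a target percent identity (no indels).

    The number of substituted positions is ``round((100 - target)/100 * len)``,
    drawn without replacement; each substitution picks one of the three other
    bases, so the realized identity is exact at the substitution level.
    """
    if not seq:
        raise ValueError("mutate_to_identity requires a non-empty sequence")
    if not 70.0 < target_identity <= 100.0:
        raise ValueError(f"target identity must be in (70, 100], got {target_identity}")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n_sub = int(round((100.0 - target_identity) / 100.0 * len(seq)))
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    offsets = rng.integers(1, 4, size=n_sub)
    base_index = np.searchsorted(_BASES, arr[positions])
    arr[positions] = _BASES[(base_index + offsets) % 4]
    return bytes(arr).decode()


def _draw_markers(klass: str, rng: np.random.Generator) -> list[str]:
    """Marker-gene labels for one contig of the given truth class.

    Multiplicities echo observed structure (e.g. ~1.5 repC genes per repABC
    plasmid) and keep the planted signal robust to moderate annotation loss.
    """
    if klass == "chromosome":
        return ["DNAA"]
    if klass == "megaplasmid":
        label = "REPA" if rng.random() < 0.5 else "REPAB"
        return [label] * int(rng.integers(1, 3))
    if klass == "repABC_plasmid":
        markers = ["REPC"] * int(rng.integers(1, 4))
        if rng.random() < 0.3:
            markers.append("PAR")
        return markers
    if klass == "putative_plasmid":
        variant = ("REPAB", "REPA", "TRAY", "PAR", "VIRB")[int(rng.integers(0, 5))]
        if variant == "VIRB":
            n = int(rng.integers(1, 10))
            return list(VIRB_COMPONENTS[:n])
        return [variant] * int(rng.integers(2, 4))
    if klass == "bacteriophage":
        return ["PHAGE_STRUCTURAL"] * int(rng.integers(2, 6))
    return []


def _draw_t4ss(rng: np.random.Generator) -> list[str]:
    """A T4SS gene set in operon order: complete, nearly complete, or partial,
    occasionally with a duplicated component."""
    u = rng.random()
    if u < 0.4:
        comps = list(T4SS_COMPONENTS)
    elif u < 0.7:
        drop = rng.choice(12, size=int(rng.integers(1, 3)), replace=False)
        comps = [c for i, c in enumerate(T4SS_COMPONENTS) if i not in set(drop.tolist())]
    else:
        n = int(rng.integers(3, 10))
        keep = np.sort(rng.choice(12, size=n, replace=False))
        comps = [T4SS_COMPONENTS[i] for i in keep]
    if rng.random() < 0.3:
        comps.insert(int(rng.integers(0, len(comps))), comps[int(rng.integers(0, len(comps)))])
    return comps


def generate_community(config: CommunityConfig, db: Sequence[ReferenceTaxon]) -> SyntheticCommunity:
    """Emit contigs, annotations, depths, and external scores with full truth."""
    if not db:
        raise ValueError("generate_community requires a non-empty reference db")
    root = np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    r_class, r_len, r_seq, r_depth, r_ssu, r_ann, r_score = (
        np.random.default_rng(s) for s in root.spawn(7)
    )

    classes = [
        REPLICON_CLASSES[i]
        for i in r_class.choice(
            len(REPLICON_CLASSES),
            size=config.n_contigs,
            p=[config.replicon_mix.get(c, 0.0) for c in REPLICON_CLASSES],
        )
    ]
    # chromosome/megaplasmid contigs cycle through distinct taxa so the
    # planted community has species diversity; others draw any taxon
    genome_taxon_order = r_class.permutation(len(db))
    genome_cursor = 0

    contigs: dict[str, str] = {}
    ann_rows: list[dict] = []
    truth_rows: list[dict] = []
    score_rows: list[dict] = []
    depths: dict[str, float] = {}
    ov = config.terminal_overlap_len

    for idx, klass in enumerate(classes):
        cid = f"CTG{idx + 1:05d}"
        if klass in ("chromosome", "megaplasmid"):
            taxon = db[int(genome_taxon_order[genome_cursor % len(db)])]
            genome_cursor += 1
        else:
            taxon = db[int(r_class.integers(0, len(db)))]
        lo, hi = _SIZE_RANGES[klass]
        core_len = int(r_len.integers(lo, hi + 1))
        circular = True if klass in ("chromosome", "megaplasmid") else bool(r_len.random() < config.circular_fraction)
        core = _random_dna(r_seq, core_len)

        gene_counter = 0

        def _add_row(label: str, start: int, end: int) -> dict:
            nonlocal gene_counter
            gene_counter += 1
            row = {
                "contig_id": cid,
                "gene_id": f"{cid}_g{gene_counter:04d}",
                "start": start,
                "end": end,
                "strand": "+",
                "label": label,
                "hit_species": None,
                "hit_genus": None,
                "hit_phylum": None,
                "hit_identity": np.nan,
                "hit_coverage": np.nan,
            }
            ann_rows.append(row)
            return row

        # 16S copies on chromosome-scale replicons, non-overlapping 2 kb slots
        ssu_identities: list[float] = []
        if klass in ("chromosome", "megaplasmid"):
            k = int(r_ssu.integers(config.ssu_copy_range[0], config.ssu_copy_range[1] + 1))
            slots = np.arange(ov, core_len - 1700, 2000)
            starts = np.sort(r_ssu.choice(slots, size=k, replace=False))
            for pos in starts:
                level = float(r_ssu.choice(config.divergence_levels))
                copy = mutate_to_identity(taxon.ssu_sequence, level, seed=int(r_ssu.integers(2**31)))
                carr = np.frombuffer(copy.encode("ascii"), dtype=np.uint8)
                core[int(pos) : int(pos) + carr.size] = carr
                _add_row("SSU_RRNA", int(pos) + 1, int(pos) + carr.size)
                ssu_identities.append(level)

        # marker genes near the back half of the replicon, 2 kb spacing
        markers = _draw_markers(klass, r_ann)
        if klass in ("repABC_plasmid", "putative_plasmid") and r_ann.random() < 0.25:
            markers = markers + _draw_t4ss(r_ann)
        pos = max(core_len // 2, core_len - 2000 * (len(markers) + 1))
        if markers:
            spacing = min(2000, max(200, (core_len - pos - 1600) // len(markers)))
            for label in markers:
                glen = int(r_ann.integers(600, 1501))
                _add_row(label, pos + 1, min(pos + glen, core_len))
                pos += spacing

        # filler genes with best-hit taxonomy on a planted fraction
        n_other = int(min(max(core_len // 1200, 3), 300)) - gene_counter
        for _ in range(max(n_other, 2)):
            start = int(r_ann.integers(1, max(core_len - 1500, 2)))
            _add_row("OTHER", start, start + int(r_ann.integers(300, 1501)))
        contig_rows = ann_rows[-gene_counter:]
        hit_fraction = float(r_ann.uniform(0.35, 0.6))
        n_hits = int(round(hit_fraction * gene_counter))
        for ri in r_ann.choice(gene_counter, size=n_hits, replace=False):
            row = contig_rows[int(ri)]
            row["hit_species"] = taxon.species
            row["hit_genus"] = taxon.lineage[4]
            row["hit_phylum"] = taxon.lineage[0]
            row["hit_identity"] = float(np.round(r_ann.uniform(85.0, 100.0), 2))
            row["hit_coverage"] = float(np.round(r_ann.uniform(85.0, 100.0), 2))

        seq = np.concatenate([core, core[:ov]]) if circular else core
        contigs[cid] = bytes(seq).decode()
        mu, sigma = config.depth_lognormal_params
        depths[cid] = float(np.round(max(r_depth.lognormal(mu, sigma), 0.1), 4))

        if klass == "bacteriophage":
            score_rows.append(
                {
                    "contig_id": cid,
                    "phage_score": float(np.round(r_score.uniform(0.85, 0.99), 3)),
                    "viral_completeness": float(np.round(r_score.uniform(14.3, 100.0), 1)),
                    "genome_completeness": np.nan,
                    "contamination": np.nan,
                }
            )
        elif klass == "chromosome":
            score_rows.append(
                {
                    "contig_id": cid,
                    "phage_score": np.nan,
                    "viral_completeness": np.nan,
                    "genome_completeness": float(np.round(r_score.uniform(80.0, 100.0), 2)),
                    "contamination": float(np.round(r_score.uniform(0.0, 3.0), 2)),
                }
            )
        elif r_score.random() < 0.3:  # low, sub-threshold viral signal on some contigs
            score_rows.append(
                {
                    "contig_id": cid,
                    "phage_score": float(np.round(r_score.uniform(0.0, 0.5), 3)),
                    "viral_completeness": np.nan,
                    "genome_completeness": np.nan,
                    "contamination": np.nan,
                }
            )

        truth_rows.append(
            {
                "contig_id": cid,
                "true_class": klass,
                "source_taxon": taxon.taxon_id,
                "source_species": taxon.species,
                "source_genus": taxon.lineage[4],
                "source_phylum": taxon.lineage[0],
                "circular": circular,
                "overlap_len": ov if circular else 0,
                "core_length": core_len,
                "emitted_length": core_len + (ov if circular else 0),
                "n_ssu_copies": len(ssu_identities),
                "ssu_identities": ";".join(f"{x:g}" for x in ssu_identities),
                "markers": ";".join(markers),
            }
        )

    annotations = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    scores = pd.DataFrame(
        score_rows,
        columns=["contig_id", "phage_score", "viral_completeness", "genome_completeness", "contamination"],
    )
    return SyntheticCommunity(
        contigs=contigs,
        annotations=annotations,
        depths=pd.Series(depths, name="mean_depth").rename_axis("contig_id"),
        truth=truth,
        external_scores=scores,
    )


def apply_annotation_dropout(annotations: pd.DataFrame, frac: float, seed: int) -> pd.DataFrame:
    """Drop each annotation row independently with probability ``frac``."""
    if not 0.0 <= frac < 1.0:
        raise ValueError("dropout fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(annotations)) >= frac
    return annotations.loc[keep].reset_index(drop=True)


def true_species_profile(
    community: SyntheticCommunity,
    species_identity: float = 97.0,
    min_depth: float = 0.0,
) -> pd.Series:
    """Planted depth-weighted species abundances (percent).

    Counts a contig toward its source species when it carries at least one 16S
    copy at or above the species-level identity threshold (and, optionally,
    passes the 16S depth-eligibility filter) — exactly what the metagenome
    species profile can see.
    """
    truth = community.truth
    rows = []
    for _, t in truth.iterrows():
        if t["n_ssu_copies"] == 0 or community.depths[t["contig_id"]] < min_depth:
            continue
        levels = [float(x) for x in str(t["ssu_identities"]).split(";") if x]
        if any(lv >= species_identity for lv in levels):
            rows.append((t["source_species"], community.depths[t["contig_id"]]))
    if not rows:
        return pd.Series(dtype=float)
    ser = pd.DataFrame(rows, columns=["species", "depth"]).groupby("species")["depth"].sum()
    return 100.0 * ser / ser.sum()


def make_amplicon_profile(
    community: SyntheticCommunity,
    seed: int,
    jitter_sigma: float = 0.15,
    n_extra_taxa: int = 4,
) -> CommunityProfile:
    """An amplicon-style companion profile of the same community.

    Takes the planted depth-weighted species abundances over all 16S-bearing
    contigs, perturbs them with a multiplicative log-normal jitter (primer and
    PCR bias stand-in), and adds a few low-abundance taxa seen only by the
    amplicon method. Returned as a CommunityProfile on the same species
    namespace so it can be compared against the metagenome profile.
    """
    rng = np.random.default_rng(seed)
    truth = community.truth
    rows = [
        (t["source_species"], community.depths[t["contig_id"]])
        for _, t in truth.iterrows()
        if t["n_ssu_copies"] > 0
    ]
    base = pd.DataFrame(rows, columns=["species", "depth"]).groupby("species")["depth"].sum()
    jittered = base * rng.lognormal(0.0, jitter_sigma, size=len(base))
    extras = pd.Series(
        rng.uniform(0.05, 0.8, size=n_extra_taxa),
        index=[f"AmpliconOnly_sp{i + 1:02d}" for i in range(n_extra_taxa)],
    )
    combined = pd.concat([jittered, extras])
    abundance = 100.0 * combined / combined.sum()
    table = pd.DataFrame(
        {
            "relative_abundance": abundance.sort_values(ascending=False),
            "n_genes": 0,
            "n_contigs": 0,
        }
    )
    return CommunityProfile(table=table, weighting="per_contig")
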