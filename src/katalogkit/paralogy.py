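"""Duplicated-gene detection and paralog family accounting.

Teleost genomes carry many paralogs from the fish-specific whole-genome
duplication.  Two complementary detectors are implemented: (1) shared
paralogs — two catalogue genes whose best cross-species hits are recorded
teleost-specific paralogs in a reference gene-tree table, with an ortholog
replacement step when the two hits land in different species; (2)
species-specific paralogs — redundant contigs of one gene whose translated
proteins fall into divergence clusters separated by a minimum gap,
indicating duplicates absent from the reference species.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import networkx as nx
from Bio.Seq import Seq

from .annotation import GeneEntry
from .contig_ops import default_identity_fn
from .formats_io import ConfigError, Contig

IdentityFn = Callable[[str, str], tuple[float, int]]


@dataclass(frozen=True)
class ClusteringParams:
    min_protein_length: int = 100  # aa
    min_alignment_length: int = 100  # aa
    min_cluster_distance: float = 0.10

    def __post_init__(self) -> None:
        if self.min_protein_length <= 0 or self.min_alignment_length <= 0:
            raise ConfigError("length filters must be positive")
        if not (0 < self.min_cluster_distance < 1):
            raise ConfigError("min_cluster_distance must be in (0, 1)")


@dataclass
class ParalogFamily:
    family_id: str
    members: frozenset[str]
    origin: str  # "teleost_shared" | "species_specific"

    def __post_init__(self) -> None:
        if self.origin not in ("teleost_shared", "species_specific"):
            raise ConfigError(f"unknown origin {self.origin!r}")
        if len(self.members) < 2:
            raise ConfigError("a paralog family needs >= 2 members")


def shared_paralog_families(
    best_hits: Mapping[str, tuple[str, str]],
    paralog_tables: Mapping[str, Mapping[str, frozenset[str] | set[str]]],
    ortholog_tables: Mapping[tuple[str, str], Mapping[str, str]],
) -> list[ParalogFamily]:
    """Teleost-shared paralog families from reference gene-tree tables.

    ``best_hits`` maps catalogue gene -> (species, reference gene id) of its
    best cross-species hit.  ``paralog_tables`` maps species -> {gene id ->
    set of recorded teleost-specific paralog gene ids}.  When two catalogue
    genes hit different species, the second gene's hit is replaced by its
    ortholog in the first gene's species (``ortholog_tables`` keyed by
    (from_species, to_species)); pairs whose ortholog lookup fails are
    skipped.  Families are connected components of the resulting paralogy
    relation; the symmetric closure of the tables is taken so the direction
    of replacement cannot change families.
    """
    graph = nx.Graph()
    graph.add_nodes_from(best_hits)
    genes = sorted(best_hits)
    skipped: list[tuple[str, str]] = []

    def are_paralogs(sp: str, a: str, b: str) -> bool:
        table = paralog_tables.get(sp, {})
        return b in table.get(a, ()) or a in table.get(b, ())

    for i, g1 in enumerate(genes):
        sp1, ref1 = best_hits[g1]
        for g2 in genes[i + 1 :]:
            sp2, ref2 = best_hits[g2]
            if sp1 == sp2:
                if are_paralogs(sp1, ref1, ref2):
                    graph.add_edge(g1, g2)
                continue
            # ortholog replacement: map the second gene's hit into the first
            # gene's species; fall back to the opposite direction.
            linked = False
            mapped = ortholog_tables.get((sp2, sp1), {}).get(ref2)
            if mapped is not None:
                linked = are_paralogs(sp1, ref1, mapped)
            if not linked:
                mapped_back = ortholog_tables.get((sp1, sp2), {}).get(ref1)
                if mapped_back is not None:
                    linked = are_paralogs(sp2, mapped_back, ref2)
                elif mapped is None:
                    skipped.append((g1, g2))
            if linked:
                graph.add_edge(g1, g2)

    families = []
    for idx, component in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]), start=1
    ):
        if len(component) >= 2:
            families.append(
                ParalogFamily(
                    family_id=f"shared{idx}",
                    members=frozenset(component),
                    origin="teleost_shared",
                )
            )
    return families


def _longest_orf(protein: str) -> str:
    return max(protein.split("*"), key=len) if protein else ""


def translate_contig(
    contig: Contig,
    frame_hint: tuple[int, int] | None = None,
    min_protein_length: int = 100,
) -> str | None:
    """Translate a contig into its protein, or ``None`` if too short.

    ``frame_hint`` is (frame offset 0-2, strand +1/-1), typically derived
    from the annotation hit: that single frame is translated and the longest
    stop-free stretch returned.  Without a hint all six frames are scanned
    for the longest stop-free ORF.  Proteins shorter than
    ``min_protein_length`` aa yield ``None``.
    """
    seq = Seq(contig.sequence)
    candidates: list[str] = []
    if frame_hint is not None:
        offset, strand = frame_hint
        s = seq if strand >= 0 else seq.reverse_complement()
        sub = s[offset:]
        sub = sub[: len(sub) - len(sub) % 3]
        candidates.append(_longest_orf(str(sub.translate())))
    else:
        for s in (seq, seq.reverse_complement()):
            for offset in range(3):
                sub = s[offset:]
                sub = sub[: len(sub) - len(sub) % 3]
                candidates.append(_longest_orf(str(sub.translate())))
    best = max(candidates, key=len) if candidates else ""
    return best if len(best) >= min_protein_length else None


def gap_cluster(divergences: Sequence[float], min_gap: float) -> list[list[float]]:
    """1-D single-linkage clustering: split sorted values at gaps >= min_gap."""
    values = sorted(divergences)
    if not values:
        return []
    clusters: list[list[float]] = [[values[0]]]
    for v in values[1:]:
        if v - clusters[-1][-1] >= min_gap:
            clusters.append([v])
        else:
            clusters[-1].append(v)
    return clusters


@dataclass
class ClusterResult:
    gene_symbol: str
    cluster_count: int
    divergences: dict[str, float]  # secondary contig id -> divergence
    assignments: dict[str, int]  # contig id -> cluster index (longest contig = 0)


def species_specific_clusters(
    gene_entry: GeneEntry,
    translations: Mapping[str, str],
    identity_fn: IdentityFn | None = None,
    params: ClusteringParams = ClusteringParams(),
) -> ClusterResult:
    """Divergence-gap clustering of one gene's redundant contigs.

    The longest contig's protein is aligned to each secondary contig's
    protein; divergence is 1 - identity, alignments shorter than
    ``min_alignment_length`` aa are discarded.  The value 0 (the longest
    contig against itself) is always included so a single distant secondary
    forms a second cluster.  Clusters are separated by gaps >=
    ``min_cluster_distance``; two or more clusters indicate a duplication
    private to the catalogue's species.
    """
    identity_fn = identity_fn or default_identity_fn
    longest = gene_entry.longest_contig_id
    ref_protein = translations.get(longest)
    if ref_protein is None or len(ref_protein) < params.min_protein_length:
        return ClusterResult(gene_entry.gene_symbol, 0, {}, {})
    divergences: dict[str, float] = {}
    for contig_id in gene_entry.members:
        if contig_id == longest:
            continue
        protein = translations.get(contig_id)
        if protein is None or len(protein) < params.min_protein_length:
            continue
        identity, aligned = identity_fn(ref_protein, protein)
        if aligned < params.min_alignment_length:
            continue
        divergences[contig_id] = 1.0 - identity

    values = {longest: 0.0, **divergences}
    clusters = gap_cluster(list(values.values()), params.min_cluster_distance)
    boundaries = [c[0] for c in clusters]
    assignments = {
        cid: max(i for i, b in enumerate(boundaries) if d >= b)
        for cid, d in values.items()
    }
    return ClusterResult(
        gene_symbol=gene_entry.gene_symbol,
        cluster_count=len(clusters),
        divergences=divergences,
        assignments=assignments,
    )


@dataclass
class ParalogSummary:
    shared_paralogs: int  # P_s: members of teleost-shared families
    shared_families: int  # F_s
    cluster_paralogs: int  # P_c: clusters over multi-cluster genes
    multi_cluster_genes: int  # F_c
    total_genes: int
    collapsed_genes: int
    mean_family_size: float | None
    pair_fraction: float | None
    total_paralogs: int

    def as_dict(self) -> dict[str, float | int | None]:
        return {
            "shared_paralogs": self.shared_paralogs,
            "shared_families": self.shared_families,
            "cluster_paralogs": self.cluster_paralogs,
            "multi_cluster_genes": self.multi_cluster_genes,
            "total_genes": self.total_genes,
            "collapsed_genes": self.collapsed_genes,
            "mean_family_size": self.mean_family_size,
            "pair_fraction": self.pair_fraction,
            "total_paralogs": self.total_paralogs,
        }


def paralog_summary(
    shared_families: Sequence[ParalogFamily],
    cluster_counts: Mapping[str, int],
    total_genes: int,
) -> ParalogSummary:
    """Catalogue-level paralog accounting.

    ``collapsed_genes`` counts each shared family once
    (total - members + families).  The pair fraction is the share of all
    paralogs (shared family members plus clusters of multi-cluster genes)
    sitting in size-2 groups.  Mean family size is members / families of the
    shared set, rounded to one decimal.
    """
    p_s = sum(len(f.members) for f in shared_families)
    f_s = len(shared_families)
    multi = {g: c for g, c in cluster_counts.items() if c >= 2}
    p_c = sum(multi.values())
    f_c = len(multi)
    pair_members = sum(len(f.members) for f in shared_families if len(f.members) == 2)
    pair_members += sum(2 for c in multi.values() if c == 2)
    total_paralogs = p_s + p_c
    return ParalogSummary(
        shared_paralogs=p_s,
        shared_families=f_s,
        cluster_paralogs=p_c,
        multi_cluster_genes=f_c,
        total_genes=total_genes,
        collapsed_genes=total_genes - p_s + f_s,
        mean_family_size=round(p_s / f_s, 1) if f_s else None,
        pair_fraction=pair_members / total_paralogs if total_paralogs else None,
        total_paralogs=total_paralogs,
    )
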