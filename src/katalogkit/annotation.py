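"""Multi-database best-hit annotation, CDS completeness, GO and gene families.

Each database carries its own filter thresholds and a priority rank.  Per
contig, hits are filtered per database (e-value, overlap, identity, a
description blacklist) and the contig is annotated from the best passing hit
of the highest-priority database with any passing hit.  Downstream steps
group contigs into genes by symbol, score CDS completeness against the
annotating entry, assign GO terms from association tables and map them to a
slim vocabulary, and compare per-family gene counts against reference
species.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .formats_io import ConfigError, GOGraph, HitRecord
from .reference_qc import merge_intervals

DEFAULT_BLACKLIST = ("bac", "fosmid", "shotgun")


@dataclass(frozen=True)
class DatabaseSpec:
    tag: str
    priority: int  # 1 = highest
    max_e_value: float = 1e-10
    min_overlap: int = 33  # alignment columns
    min_identity: float = 0.30
    kind: str = "protein"

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "nucleotide"):
            raise ConfigError(f"unknown database kind {self.kind!r}")
        if self.priority < 1:
            raise ConfigError("priority ranks start at 1")


@dataclass
class AnnotationRecord:
    contig_id: str
    database_tag: str
    subject_id: str
    gene_symbol: str
    species: str | None = None
    description: str = ""
    cds_fraction: float | None = None


@dataclass
class GeneEntry:
    gene_symbol: str
    members: list[str]
    longest_contig_id: str
    isoform_count: int = 1


def _hit_passes(h: HitRecord, spec: DatabaseSpec, blacklist: Sequence[str]) -> bool:
    if h.e_value > spec.max_e_value:
        return False
    if h.alignment_length < spec.min_overlap:
        return False
    if h.percent_identity / 100.0 < spec.min_identity:
        return False
    desc = h.description.lower()
    return not any(word in desc for word in blacklist)


def _best_hit(hits: Sequence[HitRecord]) -> HitRecord:
    # lowest e-value; ties by highest bit score then lexicographic subject id
    return min(hits, key=lambda h: (h.e_value, -h.bit_score, h.subject_id))


def select_best_hits(
    hit_tables: Mapping[str, Sequence[HitRecord]],
    specs: Mapping[str, DatabaseSpec],
    blacklist_words: Sequence[str] = DEFAULT_BLACKLIST,
) -> dict[str, AnnotationRecord]:
    """Annotate each contig from its best passing hit.

    Within each database, hits failing that database's thresholds or whose
    description contains a blacklisted word are dropped.  The annotating
    database is the passing database of highest priority (rank 1 first); the
    annotation copies subject id, gene symbol (subject id when no gene id is
    present), species and description from its best hit.  Contigs with no
    passing hit anywhere are left unannotated.
    """
    for tag in hit_tables:
        if tag not in specs:
            raise ConfigError(f"no DatabaseSpec for hit table {tag!r}")
    blacklist = [w.lower() for w in blacklist_words]
    per_contig: dict[str, dict[str, list[HitRecord]]] = defaultdict(lambda: defaultdict(list))
    for tag, hits in hit_tables.items():
        spec = specs[tag]
        for h in hits:
            if _hit_passes(h, spec, blacklist):
                per_contig[h.query_id][tag].append(h)

    annotations: dict[str, AnnotationRecord] = {}
    for contig_id, by_db in per_contig.items():
        tag = min(by_db, key=lambda t: specs[t].priority)
        best = _best_hit(by_db[tag])
        annotations[contig_id] = AnnotationRecord(
            contig_id=contig_id,
            database_tag=tag,
            subject_id=best.subject_id,
            gene_symbol=best.subject_gene_id or best.subject_id,
            species=best.subject_species,
            description=best.description,
        )
    return annotations


def build_gene_entries(
    annotations: Mapping[str, AnnotationRecord],
    contig_lengths: Mapping[str, int],
    isoform_counts: Mapping[str, int] | None = None,
) -> dict[str, GeneEntry]:
    """Group annotated contigs into genes by symbol.

    The representative contig is the longest member (ties broken by
    lexicographically smaller id).  Isoform counts come from
    ``isoform_counts`` (e.g. divergence clusters) when given, else from the
    number of distinct annotating subject entries per symbol.
    """
    members: dict[str, list[str]] = defaultdict(list)
    subjects: dict[str, set[str]] = defaultdict(set)
    for ann in annotations.values():
        members[ann.gene_symbol].append(ann.contig_id)
        subjects[ann.gene_symbol].add(ann.subject_id)
    entries: dict[str, GeneEntry] = {}
    for symbol, contigs in members.items():
        longest = min(contigs, key=lambda c: (-contig_lengths[c], c))
        iso = (
            isoform_counts.get(symbol, 1)
            if isoform_counts is not None
            else len(subjects[symbol])
        )
        entries[symbol] = GeneEntry(
            gene_symbol=symbol,
            members=sorted(contigs),
            longest_contig_id=longest,
            isoform_count=max(1, iso),
        )
    return entries


@dataclass
class CDSReport:
    per_gene_fraction: dict[str, float]
    complete_flags: dict[str, bool]
    decile_histogram: np.ndarray  # 10 bins: (0,0.1], ..., (0.9,1.0]
    aggregate_ratio: float
    threshold: float


def _covered_on_subject(hits: Sequence[HitRecord], subject_id: str) -> int:
    intervals = [h.subject_interval for h in hits if h.subject_id == subject_id]
    if not intervals:
        return 0
    return sum(e - s + 1 for s, e in merge_intervals(intervals))


def cds_completeness(
    gene_entries: Mapping[str, GeneEntry],
    annotations: Mapping[str, AnnotationRecord],
    hits: Sequence[HitRecord],
    complete_threshold: float = 0.90,
) -> CDSReport:
    """Fraction of the annotating entry's CDS recovered per gene.

    Per gene: the maximum over member contigs of the fraction of the
    annotation subject covered by that contig's hits; a gene is complete iff
    the fraction strictly exceeds ``complete_threshold``.  The aggregate
    ratio sums the longest contig's covered residues over the summed subject
    lengths.
    """
    hits_by_contig: dict[str, list[HitRecord]] = defaultdict(list)
    subject_lengths: dict[str, int] = {}
    for h in hits:
        hits_by_contig[h.query_id].append(h)
        if h.subject_length is not None:
            subject_lengths[h.subject_id] = h.subject_length

    fractions: dict[str, float] = {}
    flags: dict[str, bool] = {}
    agg_covered = 0
    agg_subject = 0
    for symbol, entry in gene_entries.items():
        subject = annotations[entry.longest_contig_id].subject_id
        if subject not in subject_lengths:
            raise ConfigError(f"missing subject_length for {subject}")
        slen = subject_lengths[subject]
        best = 0.0
        for contig in entry.members:
            covered = _covered_on_subject(hits_by_contig.get(contig, []), subject)
            best = max(best, covered / slen)
        fractions[symbol] = min(best, 1.0)
        flags[symbol] = fractions[symbol] > complete_threshold
        agg_covered += _covered_on_subject(hits_by_contig.get(entry.longest_contig_id, []), subject)
        agg_subject += slen

    histogram = np.zeros(10, dtype=int)
    for frac in fractions.values():
        # decile bins (0, 0.1], ..., (0.9, 1.0]; zero coverage falls in the first
        idx = min(9, int(np.ceil(frac * 10)) - 1) if frac > 0 else 0
        histogram[idx] += 1
    return CDSReport(
        per_gene_fraction=fractions,
        complete_flags=flags,
        decile_histogram=histogram,
        aggregate_ratio=agg_covered / agg_subject if agg_subject else 0.0,
        threshold=complete_threshold,
    )


@dataclass
class GOAssignment:
    terms_per_contig: dict[str, frozenset[str]]
    total_counts: int
    counts_per_namespace: dict[str, int]
    unique_terms: int
    skipped_terms: list[str] = field(default_factory=list)


def assign_go(
    annotations: Mapping[str, AnnotationRecord],
    association_tables: Mapping[str, Mapping[str, Sequence[str]]],
    go_graph: GOGraph,
) -> GOAssignment:
    """Assign GO terms to annotated contigs via subject-id associations.

    ``association_tables`` maps database tag -> {subject id -> GO term ids}.
    Terms reached through multiple databases are deduplicated per contig
    before counting; a GO count is one (contig, term) assignment.  Terms
    absent from the graph are skipped and reported.
    """
    skipped: list[str] = []
    per_contig: dict[str, frozenset[str]] = {}
    for contig_id, ann in annotations.items():
        terms: set[str] = set()
        for tag, table in association_tables.items():
            for term in table.get(ann.subject_id, ()):
                if term in go_graph:
                    terms.add(term)
                else:
                    skipped.append(term)
        if terms:
            per_contig[contig_id] = frozenset(terms)
    per_ns: dict[str, int] = defaultdict(int)
    unique: set[str] = set()
    total = 0
    for terms in per_contig.values():
        for term in terms:
            per_ns[go_graph.namespace(term)] += 1
            unique.add(term)
            total += 1
    return GOAssignment(
        terms_per_contig=per_contig,
        total_counts=total,
        counts_per_namespace=dict(per_ns),
        unique_terms=len(unique),
        skipped_terms=skipped,
    )


def map_to_slim(go_graph: GOGraph, term_id: str) -> frozenset[str]:
    """Most-specific slim ancestors of a term (map2slim semantics).

    A slim term is returned iff it is an ancestor-or-self of ``term_id``
    reachable by an upward is_a path that passes through no other slim term.
    A slim term maps to itself.
    """
    if term_id not in go_graph:
        raise ConfigError(f"term {term_id} not in graph")

    @lru_cache(maxsize=None)
    def climb(term: str) -> frozenset[str]:
        if term in go_graph.slim_set:
            return frozenset({term})
        out: set[str] = set()
        for parent in go_graph.parents[term]:
            out |= climb(parent)
        return frozenset(out)

    return climb(term_id)


@dataclass
class FamilyComparison:
    families_hit: int
    families_matching: int
    per_family_counts: dict[str, int]

    @property
    def matching_fraction(self) -> float:
        return self.families_matching / self.families_hit if self.families_hit else 0.0


def compare_gene_families(
    best_hits_per_gene: Mapping[str, Mapping[str, str]],
    family_tables: Mapping[str, Mapping[str, str]],
    family_sizes: Mapping[str, Mapping[str, int]],
) -> FamilyComparison:
    """Compare per-family catalogue gene counts to the reference species.

    ``best_hits_per_gene`` maps catalogue gene -> {species -> best-hit gene
    id}; ``family_tables`` maps species -> {gene id -> family id};
    ``family_sizes`` maps species -> {family id -> gene count}.  A family is
    hit iff some catalogue gene's best hit in some species maps to it; it
    matches iff the number of catalogue genes hitting it equals its gene
    count in at least one species.
    """
    catalogue_genes_per_family: dict[str, set[str]] = defaultdict(set)
    for gene, hits in best_hits_per_gene.items():
        for species, ref_gene in hits.items():
            family = family_tables.get(species, {}).get(ref_gene)
            if family is not None:
                catalogue_genes_per_family[family].add(gene)
    matching = 0
    counts: dict[str, int] = {}
    for family, genes in catalogue_genes_per_family.items():
        counts[family] = len(genes)
        sizes = {
            family_sizes[sp][family]
            for sp in family_sizes
            if family in family_sizes[sp]
        }
        if len(genes) in sizes:
            matching += 1
    return FamilyComparison(
        families_hit=len(catalogue_genes_per_family),
        families_matching=matching,
        per_family_counts=counts,
    )
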