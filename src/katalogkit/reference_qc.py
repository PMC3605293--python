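"""Reference-protein QC of a transcript catalogue.

A catalogue without a genome to compare against is assessed against a set of
experimentally supported reference proteins from a close relative: how many
proteins are represented, how completely each is covered, whether contigs are
fragments (N-terminal / C-terminal / internal) or span the whole protein,
how deeply each residue is covered, and two artefact screens — chimeric
contigs (two non-overlapping strong hits to different proteins) and
cross-taxon contamination (best hit outside fish with all fish hits many
orders of magnitude weaker).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import ConfigError, HitRecord, order_gap


@dataclass(frozen=True)
class ChimeraParams:
    max_e_value: float = 1e-20
    min_subject_coverage: float = 0.75
    min_identity: float = 0.50
    max_query_overlap: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_subject_coverage <= 1 and 0 < self.min_identity <= 1):
            raise ConfigError("coverage/identity thresholds must be in (0, 1]")
        if self.max_query_overlap < 0 or self.max_e_value <= 0:
            raise ConfigError("invalid chimera thresholds")


@dataclass(frozen=True)
class ContaminationParams:
    max_e_value: float = 1e-20
    min_order_gap: float = 10.0

    def __post_init__(self) -> None:
        if self.min_order_gap <= 0:
            raise ConfigError("min_order_gap must be > 0")


TERMINAL_CLASSES = ("n_terminal", "c_terminal", "internal", "complete", "complete_with_utr")


@dataclass
class ProteinQCReport:
    covered_fraction: dict[str, float]
    hit_flag: dict[str, bool]
    threshold_flag: dict[str, bool]
    single_contig_sufficient: dict[str, bool]
    depth: dict[str, np.ndarray]
    coverage_threshold: float


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(end - start + 1 for start, end in merge_intervals(intervals))


def protein_representation(
    hits: Sequence[HitRecord],
    reference: Mapping[str, int],
    coverage_threshold: float = 0.90,
) -> ProteinQCReport:
    """Per-protein representation and coverage report.

    ``reference`` maps protein id -> length (aa).  For each protein the
    union of subject intervals gives the covered fraction; a protein is
    single-contig-sufficient iff some one contig's own interval union covers
    at least ``coverage_threshold`` of it.
    """
    by_protein: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        if h.subject_id not in reference:
            raise ConfigError(f"hit subject {h.subject_id} absent from reference")
        by_protein[h.subject_id].append(h)

    covered: dict[str, float] = {}
    hit_flag: dict[str, bool] = {}
    threshold_flag: dict[str, bool] = {}
    single: dict[str, bool] = {}
    depth: dict[str, np.ndarray] = {}
    for protein, length in reference.items():
        phits = by_protein.get(protein, [])
        hit_flag[protein] = bool(phits)
        frac = _union_length(h.subject_interval for h in phits) / length if phits else 0.0
        covered[protein] = frac
        threshold_flag[protein] = frac >= coverage_threshold
        by_contig: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for h in phits:
            by_contig[h.query_id].append(h.subject_interval)
        single[protein] = any(
            _union_length(iv) / length >= coverage_threshold for iv in by_contig.values()
        )
        d = np.zeros(length, dtype=int)
        for contig_intervals in by_contig.values():
            for start, end in merge_intervals(contig_intervals):
                d[start - 1 : end] += 1
        depth[protein] = d
    return ProteinQCReport(
        covered_fraction=covered,
        hit_flag=hit_flag,
        threshold_flag=threshold_flag,
        single_contig_sufficient=single,
        depth=depth,
        coverage_threshold=coverage_threshold,
    )


def classify_terminal_coverage(
    contig_hits: Sequence[HitRecord],
    protein_length: int,
    contig_length: int | None = None,
    utr_margin: int = 30,
) -> str:
    """Terminal class of one contig's hits on one protein.

    n_terminal iff the interval union includes residue 1 but not the last
    residue; c_terminal symmetric; internal iff neither; complete iff both;
    complete_with_utr iff complete and the contig carries >= ``utr_margin``
    unaligned nt flanking the aligned region on both sides (requires
    ``contig_length``).
    """
    if not contig_hits:
        raise ConfigError("need at least one hit")
    merged = merge_intervals(h.subject_interval for h in contig_hits)
    has_n = merged[0][0] == 1
    has_c = merged[-1][1] == protein_length
    if has_n and has_c:
        if contig_length is not None:
            qstart = min(h.query_start for h in contig_hits)
            qend = max(h.query_end for h in contig_hits)
            left = qstart - 1
            right = contig_length - qend
            if left >= utr_margin and right >= utr_margin:
                return "complete_with_utr"
        return "complete"
    if has_n:
        return "n_terminal"
    if has_c:
        return "c_terminal"
    return "internal"


def per_residue_redundancy(
    hits: Sequence[HitRecord],
    reference: Mapping[str, int],
) -> tuple[float, float]:
    """(average depth, fraction of identified residues with depth >= 2).

    Depth counts distinct contigs covering each residue; both statistics are
    taken over residues with depth >= 1 (the identified protein sequence).
    """
    report = protein_representation(hits, reference, coverage_threshold=0.0)
    all_depth = np.concatenate(list(report.depth.values())) if report.depth else np.array([])
    identified = all_depth[all_depth >= 1]
    if identified.size == 0:
        return 0.0, 0.0
    return float(identified.mean()), float((identified >= 2).mean())


@dataclass
class ChimeraCall:
    contig_id: str
    is_chimeric: bool
    supporting_pair: tuple[HitRecord, HitRecord] | None = None


def _passes_chimera_hit(h: HitRecord, params: ChimeraParams) -> bool:
    if h.subject_length is None:
        raise ConfigError(f"hit {h.query_id}->{h.subject_id} lacks subject_length")
    coverage = (h.subject_end - h.subject_start + 1) / h.subject_length
    return (
        h.e_value <= params.max_e_value
        and coverage >= params.min_subject_coverage
        and h.percent_identity / 100.0 >= params.min_identity
    )


def _query_overlap(a: HitRecord, b: HitRecord) -> int:
    return min(a.query_end, b.query_end) - max(a.query_start, b.query_start) + 1


def detect_chimeras(
    hits_by_contig: Mapping[str, Sequence[HitRecord]],
    params: ChimeraParams = ChimeraParams(),
) -> dict[str, ChimeraCall]:
    """Flag contigs with two non-overlapping strong hits to different proteins.

    A contig is chimeric iff some hit pair targets two different subject
    proteins, the query intervals overlap by at most ``max_query_overlap``
    nt, and each hit individually satisfies the e-value, subject-coverage
    and identity thresholds.
    """
    calls: dict[str, ChimeraCall] = {}
    for contig_id, hits in hits_by_contig.items():
        passing = [h for h in hits if _passes_chimera_hit(h, params)]
        call = ChimeraCall(contig_id=contig_id, is_chimeric=False)
        for i in range(len(passing)):
            for j in range(i + 1, len(passing)):
                a, b = passing[i], passing[j]
                if a.subject_id == b.subject_id:
                    continue
                if _query_overlap(a, b) <= params.max_query_overlap:
                    call = ChimeraCall(contig_id, True, (a, b))
                    break
            if call.is_chimeric:
                break
        calls[contig_id] = call
    return calls


@dataclass
class ContaminationCall:
    contig_id: str
    is_contaminant: bool
    taxon_group: str | None = None
    fish_hit_present: bool = True


def tag_contamination(
    hits_by_contig: Mapping[str, Sequence[HitRecord]],
    params: ContaminationParams = ContaminationParams(),
) -> dict[str, ContaminationCall]:
    """Flag contigs whose best hit is non-fish with no comparable fish hit.

    A contig is tagged iff its best (lowest e-value) hit is non-fish and
    either no fish hit exists or the best fish e-value is at least
    ``10^min_order_gap`` times the best non-fish e-value.
    """
    calls: dict[str, ContaminationCall] = {}
    for contig_id, hits in hits_by_contig.items():
        usable = [h for h in hits if h.e_value <= params.max_e_value]
        if not usable:
            calls[contig_id] = ContaminationCall(contig_id, False)
            continue
        best = min(usable, key=lambda h: (h.e_value, -h.bit_score, h.subject_id))
        fish = [h for h in usable if h.subject_taxon_group == "fish"]
        if best.subject_taxon_group == "fish":
            calls[contig_id] = ContaminationCall(contig_id, False)
            continue
        if not fish:
            calls[contig_id] = ContaminationCall(
                contig_id, True, taxon_group=best.subject_taxon_group, fish_hit_present=False
            )
            continue
        best_fish = min(h.e_value for h in fish)
        if order_gap(best.e_value, best_fish) >= params.min_order_gap:
            calls[contig_id] = ContaminationCall(contig_id, True, taxon_group=best.subject_taxon_group)
        else:
            calls[contig_id] = ContaminationCall(contig_id, False)
    return calls


def qc_summary(
    report: ProteinQCReport,
    terminal_classes: Mapping[str, str],
    chimera_calls: Mapping[str, ChimeraCall],
    contamination_calls: Mapping[str, ContaminationCall],
) -> dict[str, float]:
    """Aggregate percentages over proteins and contigs."""
    n_prot = len(report.hit_flag)
    hit = [p for p, f in report.hit_flag.items() if f]
    summary = {
        "proteins_total": n_prot,
        "proteins_hit_pct": 100.0 * len(hit) / n_prot if n_prot else 0.0,
        "proteins_covered_pct": (
            100.0 * sum(report.threshold_flag[p] for p in hit) / len(hit) if hit else 0.0
        ),
        "single_contig_sufficient_pct": (
            100.0 * sum(report.single_contig_sufficient[p] for p in hit) / len(hit) if hit else 0.0
        ),
    }
    n_classified = len(terminal_classes)
    for cls in TERMINAL_CLASSES:
        count = sum(1 for c in terminal_classes.values() if c == cls)
        summary[f"class_{cls}_pct"] = 100.0 * count / n_classified if n_classified else 0.0
    n_contigs = len(chimera_calls)
    summary["chimeric_pct"] = (
        100.0 * sum(c.is_chimeric for c in chimera_calls.values()) / n_contigs if n_contigs else 0.0
    )
    n_tagged = len(contamination_calls)
    summary["contaminant_pct"] = (
        100.0 * sum(c.is_contaminant for c in contamination_calls.values()) / n_tagged
        if n_tagged
        else 0.0
    )
    return summary
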