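"""Contig-set post-processing: fragmentation, redundancy collapse, peak diagnostics.

The iterative assembly strategy that produced the catalogue splits large
contigs into fixed-length pieces with a fixed overlap before re-assembly.
Pieces that the assembler cannot extend survive as artefacts and show up as
periodic peaks in the contig length histogram, spaced by
``fragment_length - overlap``.  This module implements the splitting rule,
the CD-HIT-style redundancy collapse and a detector for those periodic
peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from Bio import Align

from .formats_io import ConfigError, Contig

IdentityFn = Callable[[str, str], tuple[float, int]]


@dataclass(frozen=True)
class FragmentationParams:
    fragment_length: int = 2000
    overlap: int = 300
    min_contig_length: int = 300

    def __post_init__(self) -> None:
        if not (0 < self.overlap < self.fragment_length):
            raise ConfigError("require 0 < overlap < fragment_length")

    @property
    def step(self) -> int:
        return self.fragment_length - self.overlap


@dataclass(frozen=True)
class RedundancyParams:
    min_identity: float = 0.99
    min_coverage_smaller: float = 0.90

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage_smaller"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name} must be in (0, 1]")


def fragment_contig(contig: Contig, params: FragmentationParams = FragmentationParams()) -> list[Contig]:
    """Split a contig into overlapping fixed-length fragments.

    Fragments start at 0, s, 2s, ... with step ``s = fragment_length -
    overlap``; every fragment has length ``fragment_length`` except possibly
    the last, which is truncated at the contig end (never discarded), so the
    union of fragments covers the contig exactly.
    """
    seq = contig.sequence
    length = len(seq)
    if length == 0:
        raise ConfigError(f"contig {contig.id} is empty")
    starts = [0]
    while starts[-1] + params.fragment_length < length:
        starts.append(starts[-1] + params.step)
    fragments = []
    for i, start in enumerate(starts, start=1):
        end = min(start + params.fragment_length, length)
        fragments.append(
            Contig(
                id=f"{contig.id}/frag{i}",
                sequence=seq[start:end],
                strain=contig.strain,
                meta={"source": contig.id, "start": str(start + 1), "end": str(end)},
            )
        )
    return fragments


def reassemble_fragments(fragments: Sequence[Contig], overlap: int = 300) -> str:
    """Overlap-aware concatenation inverting :func:`fragment_contig`."""
    pieces = [fragments[0].sequence]
    pieces.extend(f.sequence[overlap:] for f in fragments[1:])
    return "".join(pieces)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # free end gaps: a shorter sequence may sit inside a longer one
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


def default_identity_fn(seq_a: str, seq_b: str) -> tuple[float, int]:
    """(identity fraction, aligned length) from a banded-style global alignment.

    Scores: match +1, mismatch -1, gap -2, terminal gaps free.  Identity is
    matches / alignment columns within the aligned core (internal gaps count
    as columns, terminal overhangs do not); aligned length is that column
    count.
    """
    aligner = _make_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    a_row, b_row = str(alignment[0]), str(alignment[1])
    # trim terminal overhangs (columns where either row is a leading/trailing gap)
    first = 0
    last = len(a_row)
    while first < last and (a_row[first] == "-" or b_row[first] == "-"):
        first += 1
    while last > first and (a_row[last - 1] == "-" or b_row[last - 1] == "-"):
        last -= 1
    core_a, core_b = a_row[first:last], b_row[first:last]
    columns = len(core_a)
    if columns == 0:
        return 0.0, 0
    matches = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    return matches / columns, columns


def collapse_redundant(
    contigs: Sequence[Contig],
    params: RedundancyParams = RedundancyParams(),
    identity_fn: IdentityFn | None = None,
) -> tuple[list[Contig], dict[str, str]]:
    """Greedy longest-first redundancy collapse.

    Contigs are processed in descending length order (ties broken by id).
    Each contig is compared against the already-retained set and removed iff
    some retained contig aligns at identity >= ``min_identity`` over >=
    ``min_coverage_smaller`` of the shorter sequence.  Returns the retained
    contigs plus a map removed id -> surviving id.
    """
    identity_fn = identity_fn or default_identity_fn
    ordered = sorted(contigs, key=lambda c: (-c.length, c.id))
    retained: list[Contig] = []
    removed: dict[str, str] = {}
    for cand in ordered:
        survivor = None
        for kept in retained:
            identity, aligned = identity_fn(kept.sequence, cand.sequence)
            smaller = min(kept.length, cand.length)
            if identity >= params.min_identity and aligned >= params.min_coverage_smaller * smaller:
                survivor = kept.id
                break
        if survivor is None:
            retained.append(cand)
        else:
            removed[cand.id] = survivor
    return retained, removed


def filter_min_length(contigs: Sequence[Contig], min_length: int = 300) -> list[Contig]:
    """Keep contigs of at least ``min_length`` nt."""
    return [c for c in contigs if c.length >= min_length]


def collapse_and_filter(
    contigs: Sequence[Contig],
    redundancy: RedundancyParams = RedundancyParams(),
    min_length: int = 300,
    order: str = "filter_last",
    identity_fn: IdentityFn | None = None,
) -> tuple[list[Contig], dict[str, str]]:
    """Redundancy collapse combined with the minimum-length filter.

    ``order`` is ``"filter_last"`` (collapse, then drop short contigs; the
    default) or ``"filter_first"``.  The orders differ only when a
    below-threshold contig absorbs an even shorter redundant copy before
    being filtered out itself.
    """
    if order not in ("filter_first", "filter_last"):
        raise ConfigError(f"unknown order {order!r}")
    pool = filter_min_length(contigs, min_length) if order == "filter_first" else list(contigs)
    retained, removed = collapse_redundant(pool, redundancy, identity_fn)
    if order == "filter_last":
        retained = filter_min_length(retained, min_length)
    return retained, removed


def assembly_summary(contigs: Sequence[Contig], large_threshold: int = 1000) -> dict[str, float]:
    """Catalogue-level size metrics: counts, lengths and the large-contig share."""
    lengths = np.array([c.length for c in contigs])
    total = int(lengths.sum())
    large = lengths[lengths >= large_threshold]
    return {
        "n_contigs": int(len(lengths)),
        "total_length": total,
        "average_length": float(lengths.mean()) if len(lengths) else 0.0,
        "median_length": float(np.median(lengths)) if len(lengths) else 0.0,
        "max_length": int(lengths.max()) if len(lengths) else 0,
        "n_large_contigs": int(len(large)),
        "large_total_length": int(large.sum()),
        "large_contig_fraction": float(large.sum()) / total if total else 0.0,
    }


@dataclass
class PeakReport:
    bin_edges: np.ndarray
    counts: np.ndarray
    peak_bins: list[int]
    peak_centers: list[float]
    expected_spacing_flag: bool = False
    spacing_nt: int | None = None


def detect_artefact_peaks(
    contigs: Sequence[Contig],
    bin_width: int = 200,
    params: FragmentationParams = FragmentationParams(),
    peak_factor: float = 1.5,
) -> PeakReport:
    """Find periodic artefact peaks in the contig length histogram.

    Lengths are binned at ``bin_width``; a peak is a bin whose count exceeds
    both neighbours and exceeds a moving-median baseline (window 5) by
    ``peak_factor``.  The spacing flag is set when at least two peaks are
    separated by ``fragment_length - overlap`` within one bin width.
    """
    if not contigs:
        raise ConfigError("need at least one contig")
    lengths = np.array([c.length for c in contigs])
    n_bins = int(lengths.max() // bin_width) + 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)

    padded = np.pad(counts.astype(float), 2, mode="constant")
    baseline = np.array([np.median(padded[i : i + 5]) for i in range(len(counts))])

    peak_bins: list[int] = []
    for i in range(len(counts)):
        left = counts[i - 1] if i > 0 else -1
        right = counts[i + 1] if i + 1 < len(counts) else -1
        if counts[i] > left and counts[i] > right and counts[i] > peak_factor * max(baseline[i], 1e-9):
            peak_bins.append(i)

    centers = [float(edges[i] + bin_width / 2) for i in peak_bins]
    expected = params.step
    flag = False
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if abs(abs(centers[j] - centers[i]) - expected) <= bin_width:
                flag = True
    return PeakReport(
        bin_edges=edges,
        counts=counts,
        peak_bins=peak_bins,
        peak_centers=centers,
        expected_spacing_flag=flag,
        spacing_nt=expected,
    )
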