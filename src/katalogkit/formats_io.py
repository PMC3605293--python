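"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* Coordinates are 1-based inclusive throughout (the tabular-alignment
  convention); interval arithmetic converts to 0-based half-open internally
  and never exposes it.
* E-values are clamped to >= 1e-300 on ingest so "orders of magnitude"
  comparisons stay defined even when an aligner prints ``0.0``.
* Minus-strand nucleotide hits are normalized to ascending query coordinates
  with ``minus_strand=True`` retained.
* Readers reject malformed input instead of silently repairing it; every
  writer produces files its paired reader ingests losslessly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd
from Bio import SeqIO

E_VALUE_FLOOR = 1e-300

TAXON_GROUPS = ("fish", "mammal", "invertebrate", "plant", "other")

# species -> taxon group defaults covering the reference species used here
DEFAULT_TAXON_MAP = {
    "medaka": "fish",
    "stickleback": "fish",
    "tetraodon": "fish",
    "zebrafish": "fish",
    "human": "mammal",
    "mouse": "mammal",
    "drosophila": "invertebrate",
    "arabidopsis": "plant",
}


class FormatError(ValueError):
    """Malformed external file."""


class ConfigError(ValueError):
    """Invalid configuration or parameter set."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Contig:
    """A nucleotide sequence with optional ``key=value`` header metadata."""

    id: str
    sequence: str
    strain: str | None = None
    meta: dict[str, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class HitRecord:
    """One row of 12+-column tabular alignment output.

    ``query_start <= query_end`` always holds; the original orientation is
    kept in ``minus_strand``.  Subject coordinates are amino acids for
    translated searches.
    """

    query_id: str
    subject_id: str
    database_tag: str
    percent_identity: float
    alignment_length: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    e_value: float
    bit_score: float
    subject_length: int | None = None
    subject_species: str | None = None
    subject_gene_id: str | None = None
    subject_taxon_group: str = "other"
    description: str = ""
    minus_strand: bool = False

    def __post_init__(self) -> None:
        if self.query_start > self.query_end:
            self.query_start, self.query_end = self.query_end, self.query_start
            self.minus_strand = True
        if self.subject_start > self.subject_end:
            self.subject_start, self.subject_end = self.subject_end, self.subject_start
        self.e_value = max(float(self.e_value), E_VALUE_FLOOR)

    @property
    def subject_interval(self) -> tuple[int, int]:
        return (self.subject_start, self.subject_end)

    @property
    def query_interval(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)


@dataclass
class GOGraph:
    """is_a DAG over GO terms with an optional slim subset.

    ``terms`` maps a term id to ``(name, namespace)``; ``parents`` maps a
    term id to its direct is_a parents.  ``slim_set`` is a subset of term
    ids marking the reduced high-level vocabulary.
    """

    terms: dict[str, tuple[str, str]]
    parents: dict[str, frozenset[str]]
    slim_set: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        missing = self.slim_set - self.terms.keys()
        if missing:
            raise FormatError(f"slim terms absent from graph: {sorted(missing)}")

    def namespace(self, term_id: str) -> str:
        return self.terms[term_id][1]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    strain: str
    tissue: str
    age_weeks: float

    def __post_init__(self) -> None:
        if self.age_weeks <= 0:
            raise ConfigError(f"sample {self.sample_id}: age_weeks must be > 0")


@dataclass
class ExpressionMatrix:
    """Genes x samples unique-read counts with lengths, totals and metadata."""

    counts: pd.DataFrame
    gene_lengths: pd.Series
    sample_totals: pd.Series
    meta: dict[str, SampleMeta]

    def __post_init__(self) -> None:
        if (self.gene_lengths <= 0).any():
            raise ConfigError("gene lengths must be positive")
        for sample in self.counts.columns:
            if sample not in self.meta:
                raise FormatError(f"sample {sample} has no metadata")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a FASTA file into :class:`Contig` records, order preserved.

    The header token before the first whitespace is the id; the remainder
    is parsed as ``key=value`` metadata when present.  Duplicate ids and
    empty sequences are format errors.
    """
    records: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"empty sequence for FASTA id: {rec.id}")
        meta = {}
        for tok in rec.description.split()[1:]:
            if "=" in tok:
                key, _, val = tok.partition("=")
                meta[key] = val
        records.append(Contig(id=rec.id, sequence=seq, strain=meta.get("strain"), meta=meta))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[Contig], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for rec in records:
            meta = dict(rec.meta)
            if rec.strain is not None:
                meta.setdefault("strain", rec.strain)
            tail = "".join(f" {k}={v}" for k, v in meta.items())
            handle.write(f">{rec.id}{tail}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# tabular hit files
# ---------------------------------------------------------------------------

_HIT_NUMERIC = (
    ("percent_identity", float),
    ("alignment_length", int),
    ("mismatches", int),
    ("gap_opens", int),
    ("query_start", int),
    ("query_end", int),
    ("subject_start", int),
    ("subject_end", int),
    ("e_value", float),
    ("bit_score", float),
)


def read_hit_table(
    path: str | Path,
    database_tag: str,
    taxon_map: Mapping[str, str] | None = None,
) -> list[HitRecord]:
    """Read a 12+-column tabular alignment file.

    Columns 1-12 follow the standard tabular dialect; optional columns
    13-15 are subject_length, subject_species, subject_gene_id and an
    optional column 16 carries the subject description.  The taxon group is
    assigned by looking the subject species up in ``taxon_map``
    (default ``"other"``).
    """
    taxon_map = taxon_map or {}
    hits: list[HitRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: expected >=12 columns, got {len(cols)}")
            values: dict[str, float | int] = {}
            for (name, cast), raw in zip(_HIT_NUMERIC, cols[2:12]):
                try:
                    values[name] = cast(raw)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric value {raw!r} in column {name}"
                    ) from exc
            subject_length = None
            if len(cols) > 12 and cols[12] != "":
                try:
                    subject_length = int(cols[12])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad subject_length {cols[12]!r}") from exc
            species = cols[13] if len(cols) > 13 and cols[13] != "" else None
            gene_id = cols[14] if len(cols) > 14 and cols[14] != "" else None
            description = cols[15] if len(cols) > 15 else ""
            hits.append(
                HitRecord(
                    query_id=cols[0],
                    subject_id=cols[1],
                    database_tag=database_tag,
                    percent_identity=float(values["percent_identity"]),
                    alignment_length=int(values["alignment_length"]),
                    query_start=int(values["query_start"]),
                    query_end=int(values["query_end"]),
                    subject_start=int(values["subject_start"]),
                    subject_end=int(values["subject_end"]),
                    e_value=float(values["e_value"]),
                    bit_score=float(values["bit_score"]),
                    subject_length=subject_length,
                    subject_species=species,
                    subject_gene_id=gene_id,
                    subject_taxon_group=taxon_map.get(species or "", "other"),
                    description=description,
                )
            )
    return hits


def write_hit_table(hits: Sequence[HitRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for h in hits:
            qs, qe = (h.query_end, h.query_start) if h.minus_strand else (h.query_start, h.query_end)
            cols = [
                h.query_id,
                h.subject_id,
                f"{h.percent_identity:.2f}",
                str(h.alignment_length),
                "0",
                "0",
                str(qs),
                str(qe),
                str(h.subject_start),
                str(h.subject_end),
                f"{h.e_value:.3g}",
                f"{h.bit_score:.1f}",
                "" if h.subject_length is None else str(h.subject_length),
                h.subject_species or "",
                h.subject_gene_id or "",
                h.description,
            ]
            handle.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# OBO ontology
# ---------------------------------------------------------------------------


def read_obo(
    path: str | Path,
    slim_subset: str | None = None,
    slim_terms: Sequence[str] | None = None,
) -> GOGraph:
    """Parse an OBO v1.2 file into a :class:`GOGraph`.

    Only id, name, namespace, is_a and is_obsolete are used; obsolete terms
    are excluded.  The slim set is taken from ``subset:`` tags matching
    ``slim_subset`` or given explicitly via ``slim_terms``.  A cyclic is_a
    relation is a format error.
    """
    graph = obonet.read_obo(str(path))
    terms: dict[str, tuple[str, str]] = {}
    parents: dict[str, frozenset[str]] = {}
    slim: set[str] = set(slim_terms or ())
    for term_id, data in graph.nodes(data=True):
        terms[term_id] = (data.get("name", ""), data.get("namespace", ""))
        if slim_subset and slim_subset in data.get("subset", []):
            slim.add(term_id)
    # obonet edges point child -> parent for is_a
    isa = nx.DiGraph()
    isa.add_nodes_from(terms)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a" and parent in terms:
            isa.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(isa):
        raise FormatError(f"cyclic is_a relation in {path}")
    for term_id in terms:
        parents[term_id] = frozenset(isa.successors(term_id))
    return GOGraph(terms=terms, parents=parents, slim_set=frozenset(slim))


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------


def read_count_table(path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample count TSV plus its sample-metadata TSV.

    The count table has genes as rows, one ``length`` column (nt) and one
    integer column per sample.  Metadata rows are
    ``sample_id  strain  tissue  age_weeks`` and must cover every sample
    column.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    if "length" not in table.columns:
        raise FormatError(f"{path}: missing 'length' column")
    lengths = table["length"].astype(float)
    counts = table.drop(columns=["length"])
    for col in counts.columns:
        vals = counts[col]
        if not (vals == vals.round()).all() or (vals < 0).any():
            bad = vals[(vals != vals.round()) | (vals < 0)].index[0]
            raise FormatError(f"{path}: negative or non-integer count for gene {bad!r} in {col}")
    counts = counts.astype(int)

    meta_df = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    meta: dict[str, SampleMeta] = {}
    for row in meta_df.itertuples(index=False):
        meta[row.sample_id] = SampleMeta(
            sample_id=row.sample_id,
            strain=row.strain,
            tissue=row.tissue,
            age_weeks=float(row.age_weeks),
        )
    for col in counts.columns:
        if col not in meta:
            raise FormatError(f"sample {col} missing from {meta_path}")
    totals = counts.sum(axis=0)
    return ExpressionMatrix(counts=counts, gene_lengths=lengths, sample_totals=totals, meta=meta)


def write_count_table(matrix: ExpressionMatrix, path: str | Path, meta_path: str | Path) -> None:
    out = matrix.counts.copy()
    out.insert(0, "length", matrix.gene_lengths.astype(int))
    out.to_csv(path, sep="\t", index_label="gene")
    rows = [
        {
            "sample_id": m.sample_id,
            "strain": m.strain,
            "tissue": m.tissue,
            "age_weeks": m.age_weeks,
        }
        for m in matrix.meta.values()
    ]
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# key = value config
# ---------------------------------------------------------------------------


def read_config(path: str | Path) -> dict[str, str]:
    """Read a flat ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            out[key.strip()] = val.strip()
    return out


def order_gap(e_small: float, e_large: float) -> float:
    """Orders of magnitude between two clamped e-values (log10 ratio)."""
    return math.log10(max(e_large, E_VALUE_FLOOR)) - math.log10(max(e_small, E_VALUE_FLOOR))
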