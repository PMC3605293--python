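"""Synthetic reference proteomes, contig catalogues, hit tables and counts.

The generator emulates the statistical structure the downstream stages
assume, with ground-truth labels for every planted feature:

* a reference proteome with planted paralog families (a seed protein copied
  and mutated at a controlled fraction of residues);
* a contig catalogue derived from the proteome by reverse translation, with
  planted fragments, near-identical redundant copies, chimeric joins of two
  genes and contaminant contigs from a disjoint non-fish protein set;
* a tabular hit file encoding the known provenance, with identity
  ``100 x (1 - divergence)`` and a synthetic e-value heuristic
  ``10^(-round(2 x aligned_aa x identity / 100))`` clamped to >= 1e-300 —
  declared synthetic, not aligner statistics; downstream rules depend only
  on relative e-value magnitudes, which the heuristic preserves;
* negative-binomial count matrices with planted age/strain/tissue effects.

Every operation takes an explicit seed and uses a single private RNG
stream; identical seed and parameters give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .expression import DEGRecord, TimeSpans
from .formats_io import (
    ConfigError,
    Contig,
    E_VALUE_FLOOR,
    ExpressionMatrix,
    HitRecord,
    SampleMeta,
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

CONTIG_CLASSES = ("clean", "fragment", "redundant_copy", "chimera", "contaminant")

# disjoint "non-fish" sources for contaminant contigs
CONTAMINANT_SPECIES = {
    "human": "mammal",
    "drosophila": "invertebrate",
    "arabidopsis": "plant",
}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_SYNONYMS: dict[str, list[str]] = {}
for codon, aa in _STANDARD_TABLE.forward_table.items():
    _SYNONYMS.setdefault(aa, []).append(codon)
for aa in _SYNONYMS:
    _SYNONYMS[aa].sort()


@dataclass
class ReferenceProtein:
    id: str
    sequence: str
    species: str = "medaka"
    status: str = "known"
    family_id: str | None = None
    divergence: float = 0.0  # from its family seed

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic dataset."""

    seed: int
    contig_class: dict[str, str] = field(default_factory=dict)
    paralog_divergence: dict[str, list[float]] = field(default_factory=dict)
    deg_effect: dict[tuple[str, str], float] = field(default_factory=dict)
    family_members: dict[str, list[str]] = field(default_factory=dict)
    contig_source: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def class_counts(self) -> dict[str, int]:
        counts = {cls: 0 for cls in CONTIG_CLASSES}
        for cls in self.contig_class.values():
            counts[cls] += 1
        return counts


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def _mutate_protein(rng: np.random.Generator, sequence: str, divergence: float) -> str:
    n_mut = round(divergence * len(sequence))
    positions = rng.choice(len(sequence), size=n_mut, replace=False)
    chars = list(sequence)
    for pos in positions:
        options = [a for a in AA_ALPHABET if a != chars[pos]]
        chars[pos] = options[rng.integers(len(options))]
    return "".join(chars)


def reverse_translate(rng: np.random.Generator, protein: str) -> str:
    """Reverse-translate with the standard codon table, uniform synonym choice."""
    return "".join(_SYNONYMS[aa][rng.integers(len(_SYNONYMS[aa]))] for aa in protein)


def generate_reference(
    n_genes: int,
    family_size_dist: Mapping[int, float],
    divergence_range: tuple[float, float] = (0.15, 0.25),
    seed: int = 0,
    length_range: tuple[int, int] = (100, 1000),
) -> tuple[list[ReferenceProtein], SyntheticTruth]:
    """Generate a reference proteome with planted paralog families.

    Family sizes are drawn from ``family_size_dist`` until ``n_genes``
    proteins exist (the last family truncated to fit).  Each family copies
    a randomly generated seed protein and mutates a fraction of residues
    drawn uniformly from ``divergence_range``; truth records family
    membership and per-copy divergences.
    """
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    sizes = sorted(family_size_dist)
    probs = np.array([family_size_dist[s] for s in sizes], dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9 or any(s < 1 for s in sizes):
        raise ConfigError("family_size_dist must be a distribution over sizes >= 1")
    lo, hi = divergence_range
    if not (0 <= lo <= hi <= 1):
        raise ConfigError("divergence_range must satisfy 0 <= lo <= hi <= 1")

    rng = np.random.default_rng(seed)
    proteins: list[ReferenceProtein] = []
    truth = SyntheticTruth(seed=seed)
    gene_no = 0
    fam_no = 0
    while gene_no < n_genes:
        size = int(rng.choice(sizes, p=probs))
        size = min(size, n_genes - gene_no)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seed_seq = _random_protein(rng, length)
        family_id = None
        members: list[str] = []
        if size >= 2:
            fam_no += 1
            family_id = f"fam{fam_no:04d}"
        divergences: list[float] = []
        for copy in range(size):
            gene_no += 1
            gene_id = f"g{gene_no:05d}"
            if copy == 0:
                seq, div = seed_seq, 0.0
            else:
                div = float(rng.uniform(lo, hi))
                seq = _mutate_protein(rng, seed_seq, div)
                divergences.append(div)
            proteins.append(
                ReferenceProtein(id=gene_id, sequence=seq, family_id=family_id, divergence=div)
            )
            members.append(gene_id)
        if family_id is not None:
            truth.family_members[family_id] = members
            truth.paralog_divergence[members[0]] = divergences
    return proteins, truth


def _synthetic_e_value(aligned_aa: int, identity_pct: float) -> float:
    exponent = round(2 * aligned_aa * identity_pct / 100.0)
    return max(10.0 ** (-exponent), E_VALUE_FLOOR)


def _hit(
    contig_id: str,
    protein: ReferenceProtein,
    query_interval: tuple[int, int],
    subject_interval: tuple[int, int],
    identity_pct: float,
    taxon_group: str = "fish",
    e_value: float | None = None,
) -> HitRecord:
    aligned = subject_interval[1] - subject_interval[0] + 1
    ev = e_value if e_value is not None else _synthetic_e_value(aligned, identity_pct)
    return HitRecord(
        query_id=contig_id,
        subject_id=protein.id,
        database_tag="refprot",
        percent_identity=identity_pct,
        alignment_length=aligned,
        query_start=query_interval[0],
        query_end=query_interval[1],
        subject_start=subject_interval[0],
        subject_end=subject_interval[1],
        e_value=ev,
        bit_score=2.0 * aligned * identity_pct / 100.0,
        subject_length=protein.length,
        subject_species=protein.species,
        subject_gene_id=protein.id,
        subject_taxon_group=taxon_group,
    )


def generate_contigs(
    reference: Sequence[ReferenceProtein],
    rates: Mapping[str, float],
    seed: int = 0,
    utr_range: tuple[int, int] = (30, 80),
    cross_species_divergence: tuple[float, float] = (0.0, 0.05),
    id_prefix: str = "c",
) -> tuple[list[Contig], list[HitRecord], SyntheticTruth]:
    """Derive a contig catalogue with planted artefacts from a proteome.

    ``rates`` gives per-gene probabilities for the keys ``fragment``,
    ``redundant``, ``chimera`` and ``contaminant`` (remaining mass: clean).
    Contigs are reverse-translated gene sequences with UTR flanks; fragments
    truncate to an internal protein window; redundant copies are emitted
    alongside the clean contig at ~99.5% nucleotide identity over ~95% of
    its length; chimeras concatenate two genes' coding sequences;
    contaminants derive from a disjoint non-fish protein set.  The hit
    table encodes the known provenance.
    """
    keys = ("fragment", "redundant", "chimera", "contaminant")
    r = {k: float(rates.get(k, 0.0)) for k in keys}
    if any(v < 0 or v > 1 for v in r.values()) or sum(r.values()) > 1:
        raise ConfigError("rates must lie in [0,1] and sum to <= 1")

    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    contigs: list[Contig] = []
    hits: list[HitRecord] = []
    probs = [1.0 - sum(r.values()), r["fragment"], r["redundant"], r["chimera"], r["contaminant"]]
    classes = [rng.choice(5, p=probs) for _ in reference]
    cont_no = 0

    for idx, protein in enumerate(reference):
        cls = CONTIG_CLASSES[classes[idx]]
        contig_id = f"{id_prefix}{idx + 1:05d}"
        div = float(rng.uniform(*cross_species_divergence))
        identity = 100.0 * (1.0 - div)

        if cls == "contaminant":
            cont_no += 1
            species = sorted(CONTAMINANT_SPECIES)[rng.integers(len(CONTAMINANT_SPECIES))]
            length = int(rng.integers(100, 501))
            cont_protein = ReferenceProtein(
                id=f"cont{cont_no:04d}",
                sequence=_random_protein(rng, length),
                species=species,
                status="predicted",
            )
            cds = reverse_translate(rng, cont_protein.sequence)
            contigs.append(Contig(id=contig_id, sequence=cds, meta={"class": cls}))
            best = _hit(
                contig_id,
                cont_protein,
                (1, 3 * length),
                (1, length),
                identity,
                taxon_group=CONTAMINANT_SPECIES[species],
            )
            hits.append(best)
            if rng.random() < 0.5:
                # weak fish hit, always >= 10 orders of magnitude worse
                gap = float(rng.uniform(12, 40))
                weak_e = min(best.e_value * 10.0**gap, 1e-21)
                window = min(protein.length, 60)
                hits.append(
                    _hit(
                        contig_id,
                        protein,
                        (1, 3 * window),
                        (1, window),
                        35.0,
                        e_value=weak_e,
                    )
                )
            truth.contig_class[contig_id] = cls
            truth.contig_source[contig_id] = (cont_protein.id,)
            continue

        if cls == "fragment":
            length = protein.length
            start = int(rng.integers(2, max(3, length // 3)))
            end = int(rng.integers(min(length - 1, start + length // 3), length))
            window = protein.sequence[start - 1 : end]
            cds = reverse_translate(rng, window)
            contigs.append(Contig(id=contig_id, sequence=cds, meta={"class": cls}))
            hits.append(_hit(contig_id, protein, (1, len(cds)), (start, end), identity))
            truth.contig_class[contig_id] = cls
            truth.contig_source[contig_id] = (protein.id,)
            continue

        if cls == "chimera":
            partner = reference[(idx + 1 + int(rng.integers(len(reference) - 1))) % len(reference)]
            cds_a = reverse_translate(rng, protein.sequence)
            cds_b = reverse_translate(rng, partner.sequence)
            contigs.append(Contig(id=contig_id, sequence=cds_a + cds_b, meta={"class": cls}))
            hits.append(_hit(contig_id, protein, (1, len(cds_a)), (1, protein.length), identity))
            hits.append(
                _hit(
                    contig_id,
                    partner,
                    (len(cds_a) + 1, len(cds_a) + len(cds_b)),
                    (1, partner.length),
                    identity,
                )
            )
            truth.contig_class[contig_id] = cls
            truth.contig_source[contig_id] = (protein.id, partner.id)
            continue

        # clean (and the base copy of a redundant pair)
        utr5 = int(rng.integers(*utr_range))
        utr3 = int(rng.integers(*utr_range))
        cds = reverse_translate(rng, protein.sequence)
        flank5 = "".join(rng.choice(list("ACGT"), size=utr5))
        flank3 = "".join(rng.choice(list("ACGT"), size=utr3))
        sequence = flank5 + cds + flank3
        contigs.append(Contig(id=contig_id, sequence=sequence, meta={"class": "clean"}))
        hits.append(
            _hit(contig_id, protein, (utr5 + 1, utr5 + len(cds)), (1, protein.length), identity)
        )
        truth.contig_class[contig_id] = "clean"
        truth.contig_source[contig_id] = (protein.id,)

        if cls == "redundant_copy":
            copy_id = f"{contig_id}r"
            keep = int(0.95 * len(sequence))
            sub = sequence[:keep] if rng.random() < 0.5 else sequence[-keep:]
            chars = list(sub)
            n_mut = max(1, round(0.005 * len(chars)))
            for pos in rng.choice(len(chars), size=n_mut, replace=False):
                options = [b for b in "ACGT" if b != chars[pos]]
                chars[pos] = options[rng.integers(3)]
            contigs.append(Contig(id=copy_id, sequence="".join(chars), meta={"class": cls}))
            sub_end = max(1, protein.length - max(1, protein.length // 20))
            hits.append(_hit(copy_id, protein, (1, 3 * sub_end), (1, sub_end), identity))
            truth.contig_class[copy_id] = cls
            truth.contig_source[copy_id] = (protein.id,)

    return contigs, hits, truth


def default_aging_design() -> list[SampleMeta]:
    """The 8-sample two-strain, two-tissue, young/old design."""
    design = []
    for strain, ages in (("GRZ", (5.0, 14.0)), ("MZM-0403", (5.0, 31.0))):
        for age in ages:
            for tissue in ("skin", "brain"):
                tag = "young" if age == min(ages) else "old"
                design.append(
                    SampleMeta(
                        sample_id=f"{strain}_{tissue}_{tag}",
                        strain=strain,
                        tissue=tissue,
                        age_weeks=age,
                    )
                )
    return design


def simulate_counts(
    design: Sequence[SampleMeta],
    baseline_dispersion: float,
    deg_effects: SyntheticTruth,
    seed: int = 0,
    n_background_genes: int = 200,
    baseline_mean_range: tuple[float, float] = (50.0, 500.0),
    length_range: tuple[int, int] = (500, 3000),
    library_factor_range: tuple[float, float] = (0.8, 1.2),
) -> ExpressionMatrix:
    """Negative-binomial count matrix with planted age effects.

    Per gene and sample the mean is ``baseline x 2^(effect x old) x
    library-size factor`` where ``old`` is 1 for the later sampling point of
    the sample's strain; effects are applied per tissue from
    ``deg_effects.deg_effect``.  ``baseline_dispersion`` is the NB
    overdispersion (variance = m + a m^2); at 0 the counts are the
    deterministic rounded means.
    """
    if not design:
        raise ConfigError("design must be non-empty")
    if baseline_dispersion < 0:
        raise ConfigError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    effect_genes = sorted({g for g, _ in deg_effects.deg_effect})
    genes = effect_genes + [f"bg{i + 1:04d}" for i in range(n_background_genes)]
    lengths = pd.Series(
        rng.integers(length_range[0], length_range[1] + 1, size=len(genes)).astype(float),
        index=genes,
    )
    log_lo, log_hi = math.log(baseline_mean_range[0]), math.log(baseline_mean_range[1])
    baseline = np.exp(rng.uniform(log_lo, log_hi, size=len(genes)))
    lib = rng.uniform(*library_factor_range, size=len(design))

    young_age = {}
    for m in design:
        young_age[m.strain] = min(young_age.get(m.strain, m.age_weeks), m.age_weeks)

    counts = np.zeros((len(genes), len(design)), dtype=int)
    for j, meta in enumerate(design):
        old = meta.age_weeks > young_age[meta.strain]
        for i, gene in enumerate(genes):
            effect = deg_effects.deg_effect.get((gene, meta.tissue), 0.0) if old else 0.0
            mean = baseline[i] * (2.0**effect) * lib[j]
            if baseline_dispersion == 0:
                counts[i, j] = round(mean)
            else:
                shape = 1.0 / baseline_dispersion
                counts[i, j] = rng.poisson(rng.gamma(shape, mean / shape))
    frame = pd.DataFrame(counts, index=genes, columns=[m.sample_id for m in design])
    return ExpressionMatrix(
        counts=frame,
        gene_lengths=lengths,
        sample_totals=frame.sum(axis=0),
        meta={m.sample_id: m for m in design},
    )


def simulate_strain_deg_fc(
    n_genes: int,
    spans: TimeSpans,
    tissue: str = "skin",
    rate_range: tuple[float, float] = (0.005, 0.015),
    down_fraction: float = 0.5,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> list[DEGRecord]:
    """DEGs with equal planted per-week level-change rates in both strains.

    Each gene changes linearly in level at the same rate per week in every
    strain: ``fc = 1 + rate x span x eps`` with multiplicative noise ``eps =
    exp(N(0, noise_sd))`` truncated at 2.5 sd, drawn independently per
    strain.  Downregulated genes get a negative rate.  Under time
    normalization to the shorter span the two strains' fold changes are
    exchangeable, so a paired test holds its nominal level; without it the
    longer span inflates the apparent differences.
    """
    rng = np.random.default_rng(seed)
    records: list[DEGRecord] = []
    strains = sorted(spans.spans)
    for i in range(n_genes):
        down = rng.random() < down_fraction
        rate = float(rng.uniform(*rate_range)) * (-1.0 if down else 1.0)
        fc = {}
        for strain in strains:
            eps = math.exp(float(np.clip(rng.normal(0.0, noise_sd), -2.5 * noise_sd, 2.5 * noise_sd)))
            fc[strain] = 1.0 + rate * spans[strain] * eps
        records.append(
            DEGRecord(
                gene=f"deg{i + 1:04d}",
                tissue=tissue,
                fc_per_strain=fc,
                direction="down" if down else "up",
            )
        )
    return records


def generate_duplication_catalogue(
    n_genes: int = 200,
    dup_fraction: float = 0.5,
    dup_divergence: tuple[float, float] = (0.15, 0.25),
    noise_divergence: float = 0.01,
    n_secondary: int = 2,
    seed: int = 0,
    length_range: tuple[int, int] = (150, 400),
) -> tuple[dict[str, list[Contig]], dict[str, bool]]:
    """Per-gene contig sets for duplication-status recovery experiments.

    Every gene gets a primary contig (the reverse-translated protein) plus
    ``n_secondary`` secondaries.  For a planted duplicate one secondary
    derives from a paralogous copy mutated at a protein divergence drawn
    from ``dup_divergence``; all remaining secondaries are sequencing-noise
    copies at ``noise_divergence``.  Returns contigs per gene and the truth
    duplicated flag.
    """
    rng = np.random.default_rng(seed)
    catalogue: dict[str, list[Contig]] = {}
    truth: dict[str, bool] = {}
    for i in range(n_genes):
        gene = f"dup{i + 1:04d}"
        duplicated = bool(rng.random() < dup_fraction)
        length = int(rng.integers(*length_range))
        protein = _random_protein(rng, length)
        contigs = [Contig(id=f"{gene}_t1", sequence=reverse_translate(rng, protein))]
        for s in range(n_secondary):
            if duplicated and s == 0:
                div = float(rng.uniform(*dup_divergence))
            else:
                div = noise_divergence
            variant = _mutate_protein(rng, protein, div)
            contigs.append(
                Contig(id=f"{gene}_t{s + 2}", sequence=reverse_translate(rng, variant))
            )
        catalogue[gene] = contigs
        truth[gene] = duplicated
    return catalogue, truth


def write_truth_table(truth: SyntheticTruth, path: str) -> None:
    rows = [
        {"contig_id": cid, "contig_class": cls, "source": ";".join(truth.contig_source.get(cid, ()))}
        for cid, cls in truth.contig_class.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
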