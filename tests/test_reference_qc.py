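from collections import defaultdict

import numpy as np
import pytest

from katalogkit import (
    ChimeraParams,
    ContaminationParams,
    classify_terminal_coverage,
    detect_chimeras,
    generate_contigs,
    generate_reference,
    merge_intervals,
    per_residue_redundancy,
    protein_representation,
    tag_contamination,
)
from katalogkit.formats_io import ConfigError
from katalogkit.reference_qc import TERMINAL_CLASSES

from conftest import mk_hit


def _random_hits(rng, n_proteins=5, n_contigs=8, n_hits=15):
    lengths = {f"p{i}": int(rng.integers(80, 300)) for i in range(n_proteins)}
    hits = []
    for _ in range(n_hits):
        pid = f"p{rng.integers(n_proteins)}"
        length = lengths[pid]
        s = int(rng.integers(1, length))
        e = int(rng.integers(s, length + 1))
        hits.append(
            mk_hit(
                query_id=f"c{rng.integers(n_contigs)}",
                subject_id=pid,
                sstart=s,
                send=e,
                qstart=1,
                qend=3 * (e - s + 1),
                subject_length=length,
            )
        )
    return hits, lengths


def _oracle_coverage(hits, length):
    """Brute-force per-residue boolean array."""
    mask = np.zeros(length, dtype=bool)
    for h in hits:
        mask[h.subject_start - 1 : h.subject_end] = True
    return mask


class TestProteinRepresentation:
    def test_full_single_contig(self):
        hits = [mk_hit(subject_id="p1", sstart=1, send=200, subject_length=200)]
        report = protein_representation(hits, {"p1": 200})
        assert report.covered_fraction["p1"] == 1.0
        assert report.single_contig_sufficient["p1"]

    def test_two_half_contigs_not_single_sufficient(self):
        hits = [
            mk_hit(query_id="c1", subject_id="p1", sstart=1, send=100),
            mk_hit(query_id="c2", subject_id="p1", sstart=101, send=200),
        ]
        report = protein_representation(hits, {"p1": 200})
        assert report.covered_fraction["p1"] == 1.0
        assert not report.single_contig_sufficient["p1"]

    def test_matches_brute_force_interval_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            hits, lengths = _random_hits(rng)
            report = protein_representation(hits, lengths)
            by_protein = defaultdict(list)
            for h in hits:
                by_protein[h.subject_id].append(h)
            for pid, length in lengths.items():
                mask = _oracle_coverage(by_protein.get(pid, []), length)
                assert report.covered_fraction[pid] == pytest.approx(mask.mean())

    def test_unknown_subject_rejected(self):
        with pytest.raises(ConfigError):
            protein_representation([mk_hit(subject_id="mystery")], {"p1": 100})


class TestTerminalClassification:
    @pytest.mark.parametrize(
        "sstart,send,expected",
        [(1, 150, "n_terminal"), (50, 200, "c_terminal"), (50, 150, "internal"), (1, 200, "complete")],
    )
    def test_basic_classes(self, sstart, send, expected):
        hits = [mk_hit(sstart=sstart, send=send, subject_length=200)]
        assert classify_terminal_coverage(hits, 200) == expected

    def test_complete_with_utr_needs_both_flanks(self):
        hits = [mk_hit(sstart=1, send=200, qstart=31, qend=630, subject_length=200)]
        assert classify_terminal_coverage(hits, 200, contig_length=700) == "complete_with_utr"
        # right flank only 10 nt
        assert classify_terminal_coverage(hits, 200, contig_length=640) == "complete"

    def test_classes_partition_synthetic_catalogue(self):
        proteins, _ = generate_reference(80, {1: 1.0}, seed=22)
        contigs, hits, _ = generate_contigs(proteins, {"fragment": 0.4}, seed=23)
        contig_lengths = {c.id: c.length for c in contigs}
        by_pair = defaultdict(list)
        for h in hits:
            if h.subject_taxon_group == "fish":
                by_pair[(h.query_id, h.subject_id)].append(h)
        plen = {p.id: p.length for p in proteins}
        classes = [
            classify_terminal_coverage(hs, plen[pid], contig_lengths[cid])
            for (cid, pid), hs in by_pair.items()
        ]
        assert set(classes) <= set(TERMINAL_CLASSES)
        counts = {cls: classes.count(cls) for cls in TERMINAL_CLASSES}
        assert sum(counts.values()) == len(classes)

    def test_requires_hits(self):
        with pytest.raises(ConfigError):
            classify_terminal_coverage([], 200)


class TestPerResidueRedundancy:
    def test_single_full_contig(self):
        hits = [mk_hit(sstart=1, send=100, subject_length=100)]
        avg, frac2 = per_residue_redundancy(hits, {"p1": 100})
        assert avg == 1.0 and frac2 == 0.0

    def test_three_full_contigs(self):
        hits = [mk_hit(query_id=f"c{i}", sstart=1, send=100) for i in range(3)]
        avg, frac2 = per_residue_redundancy(hits, {"p1": 100})
        assert avg == 3.0 and frac2 == 1.0

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(24)
        hits, lengths = _random_hits(rng, n_hits=25)
        avg, frac2 = per_residue_redundancy(hits, lengths)
        depths = []
        for pid, length in lengths.items():
            per_contig = defaultdict(list)
            for h in hits:
                if h.subject_id == pid:
                    per_contig[h.query_id].append(h)
            depth = np.zeros(length)
            for chits in per_contig.values():
                depth += _oracle_coverage(chits, length)
            depths.append(depth)
        stacked = np.concatenate(depths)
        identified = stacked[stacked >= 1]
        assert avg == pytest.approx(identified.mean())
        assert frac2 == pytest.approx((identified >= 2).mean())


class TestChimeraDetection:
    def test_textbook_chimera(self):
        hits = {
            "c1": [
                mk_hit(subject_id="protA", qstart=1, qend=600, sstart=1, send=200,
                       identity=80.0, e_value=1e-50, subject_length=200),
                mk_hit(subject_id="protB", qstart=700, qend=1300, sstart=1, send=200,
                       identity=70.0, e_value=1e-40, subject_length=200),
            ]
        }
        calls = detect_chimeras(hits)
        assert calls["c1"].is_chimeric
        assert {h.subject_id for h in calls["c1"].supporting_pair} == {"protA", "protB"}

    def test_single_hit_not_chimeric(self):
        calls = detect_chimeras({"c1": [mk_hit()]})
        assert not calls["c1"].is_chimeric

    def test_overlapping_hits_not_chimeric(self):
        hits = {
            "c1": [
                mk_hit(subject_id="protA", qstart=1, qend=600, sstart=1, send=200,
                       identity=80.0, subject_length=200),
                mk_hit(subject_id="protB", qstart=400, qend=1000, sstart=1, send=200,
                       identity=70.0, subject_length=200),
            ]
        }
        assert not detect_chimeras(hits)["c1"].is_chimeric

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"e_value": 1e-10},  # too weak
            {"sstart": 1, "send": 100},  # 50% subject coverage
            {"identity": 40.0},  # below identity floor
        ],
    )
    def test_each_threshold_blocks_the_call(self, kwargs):
        good = mk_hit(subject_id="protA", qstart=1, qend=600, sstart=1, send=200,
                      identity=80.0, subject_length=200)
        bad = mk_hit(subject_id="protB", qstart=700, qend=1300, sstart=1, send=200,
                     identity=70.0, subject_length=200)
        for key, val in kwargs.items():
            mapping = {"e_value": "e_value", "sstart": "subject_start",
                       "send": "subject_end", "identity": "percent_identity"}
            setattr(bad, mapping[key], val)
        assert not detect_chimeras({"c1": [good, bad]})["c1"].is_chimeric

    def test_missing_subject_length_rejected(self):
        with pytest.raises(ConfigError):
            detect_chimeras({"c1": [mk_hit(subject_length=None),
                                    mk_hit(subject_id="p2", subject_length=None)]})


class TestContamination:
    def test_flagged_at_20_orders(self):
        hits = {"c1": [mk_hit(subject_id="m1", taxon="mammal", e_value=1e-80),
                       mk_hit(subject_id="f1", taxon="fish", e_value=1e-60)]}
        call = tag_contamination(hits)["c1"]
        assert call.is_contaminant and call.taxon_group == "mammal"

    def test_not_flagged_at_5_orders(self):
        hits = {"c1": [mk_hit(subject_id="m1", taxon="mammal", e_value=1e-80),
                       mk_hit(subject_id="f1", taxon="fish", e_value=1e-75)]}
        assert not tag_contamination(hits)["c1"].is_contaminant

    def test_best_fish_never_flagged(self):
        hits = {"c1": [mk_hit(subject_id="f1", taxon="fish", e_value=1e-90),
                       mk_hit(subject_id="m1", taxon="mammal", e_value=1e-60)]}
        assert not tag_contamination(hits)["c1"].is_contaminant

    def test_no_fish_hit_counts_as_gap_and_is_reported(self):
        hits = {"c1": [mk_hit(subject_id="m1", taxon="mammal", e_value=1e-40)]}
        call = tag_contamination(hits)["c1"]
        assert call.is_contaminant and not call.fish_hit_present


def test_merge_intervals_unions_adjacent_and_overlapping():
    assert merge_intervals([(5, 9), (1, 4), (20, 30), (8, 12)]) == [(1, 12), (20, 30)]
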