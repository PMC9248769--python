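from collections import Counter

import pandas as pd
import pytest
from Bio import SeqIO

from phagepan.clonotyping import (
    ClonotypeKey,
    Rearrangement,
    assign_genes,
    build_repertoire,
    cdrh3_from_junction,
    clonotype_key,
    read_airr,
    repertoire_from_airr,
    v_subgroup,
)
from phagepan.simulate import emit_reads


def _rearr(**overrides):
    base = dict(
        sequence_id="r1",
        v_call="IGHV1-1",
        j_call="IGHJ1",
        junction_nt="TGTGCTAGGCAGTGG",
        junction_aa="CARQW",
        v_3p_deletion=2,
        j_5p_deletion=1,
        ndn_length=4,
        productive=True,
        round_label="R1",
    )
    base.update(overrides)
    return Rearrangement(**base)


class TestJunctionConvention:
    @pytest.mark.parametrize(
        "junction_aa, cdrh3, length",
        [
            ("CARQKNGYVDYW", "ARQKNGYVDY", 10),
            ("CARRLRLDYW", "ARRLRLDY", 8),
        ],
    )
    def test_cdrh3_is_junction_minus_anchors(self, junction_aa, cdrh3, length):
        got = cdrh3_from_junction(junction_aa)
        assert got == cdrh3
        assert len(got) == length == len(junction_aa) - 2

    def test_out_of_frame_junction_is_non_productive(self, germline, small_library, tmp_path):
        # a 35-nt junction cannot translate; assign_genes flags non-productive
        _, truth, sample = small_library
        emit_reads(sample, truth, germline, 0.0, seed=1,
                   fasta_path=tmp_path / "r.fa", airr_path=tmp_path / "r.tsv")
        rec = next(SeqIO.parse(tmp_path / "r.fa", "fasta"))
        read = str(rec.seq)
        # delete one junction-interior nt to break the frame
        by_name = {g.name: g for g in germline}
        v = by_name[assign_genes(read, germline).v_call]
        broken = read[: v.anchor_offset + 4] + read[v.anchor_offset + 5 :]
        r = assign_genes(broken, germline)
        assert r is None or not r.productive


class TestAssignGenes:
    def test_error_free_round_trip_recovers_truth_key(
        self, germline, small_library, tmp_path
    ):
        _, truth, sample = small_library
        emit_reads(sample, truth, germline, 0.0, seed=1,
                   fasta_path=tmp_path / "r.fa", airr_path=tmp_path / "r.tsv")
        tsv = pd.read_csv(tmp_path / "r.tsv", sep="\t", keep_default_na=False)
        true_rows = {r.sequence_id: r for r in tsv.itertuples(index=False)}
        for rec in list(SeqIO.parse(tmp_path / "r.fa", "fasta"))[:300]:
            r = assign_genes(str(rec.seq), germline, sequence_id=rec.id)
            t = true_rows[rec.id]
            key = clonotype_key(r)
            assert key == ClonotypeKey(
                t.v_call, t.j_call, t.v_3p_deletion, t.j_5p_deletion,
                t.np_total_length, t.junction_aa,
            )

    def test_short_read_rejected(self, germline):
        with pytest.raises(ValueError):
            assign_genes("ACGT" * 10, germline)

    def test_requires_v_and_j_genes(self, germline):
        only_v = [g for g in germline if g.segment == "V"]
        with pytest.raises(ValueError):
            assign_genes("ACGT" * 100, only_v)

    def test_v_call_accuracy_at_one_percent_error(
        self, germline, small_library, tmp_path
    ):
        _, truth, sample = small_library
        emit_reads(sample, truth, germline, 0.01, seed=13,
                   fasta_path=tmp_path / "e.fa", airr_path=tmp_path / "e.tsv")
        tsv = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        true_v = dict(zip(tsv.sequence_id, tsv.v_call))
        correct = total = 0
        for rec in SeqIO.parse(tmp_path / "e.fa", "fasta"):
            r = assign_genes(str(rec.seq), germline)
            total += 1
            correct += r is not None and r.v_call == true_v[rec.id]
        assert total == 1000
        assert correct / total >= 0.95


class TestClonotypeKey:
    def test_synonymous_junction_changes_share_a_key(self):
        a = _rearr(junction_nt="TGTGCTAGGCAGTGG")
        b = _rearr(junction_nt="TGCGCAAGACAATGG")  # same aa, different codons
        assert clonotype_key(a) == clonotype_key(b)

    def test_same_junction_aa_different_segmentation_distinct_keys(self):
        # same CDRH3 string but different N-region lengths = different clone
        a = _rearr(v_call="IGHV14-3", junction_aa="CARRLRLDYW", ndn_length=6)
        b = _rearr(v_call="IGHV14-3", junction_aa="CARRLRLDYW", ndn_length=10)
        assert clonotype_key(a) != clonotype_key(b)

    def test_missing_field_names_the_field(self):
        with pytest.raises(ValueError, match="v_call"):
            clonotype_key(_rearr(v_call=None))

    def test_key_is_pure(self):
        assert clonotype_key(_rearr()) == clonotype_key(_rearr())

    def test_junction_length_bounds(self):
        with pytest.raises(ValueError):
            ClonotypeKey("IGHV1-1", "IGHJ1", 0, 0, 0, "CRW")


class TestBuildRepertoire:
    def test_single_clonotype_frequency_100(self):
        sample = build_repertoire([_rearr(sequence_id=f"r{i}") for i in range(10)], "R1")
        assert sample.n_clonotypes == 1
        (key,) = sample.counts
        assert sample.frequency_pct(key) == 100.0

    def test_frequencies_sum_to_100(self, small_campaign):
        _, _, samples = small_campaign
        for s in samples:
            assert sum(s.frequencies_pct().values()) == pytest.approx(100.0)

    def test_dominance_numerator_is_direct_count(self):
        rearrs = [_rearr(sequence_id=f"a{i}") for i in range(1235)]
        rearrs += [
            _rearr(sequence_id=f"b{i}", junction_aa="CGGGGW", junction_nt=None,
                   ndn_length=5 + (i % 99))
            for i in range(8765)
        ]
        sample = build_repertoire(rearrs, "R2")
        top = max(sample.counts.values())
        assert 100.0 * top / sample.total_identified == pytest.approx(12.35)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_repertoire([], "R1")

    def test_mixed_round_labels_rejected(self):
        with pytest.raises(ValueError):
            build_repertoire([_rearr(), _rearr(round_label="R2")], "R1")

    def test_non_productive_excluded_from_denominator(self):
        rearrs = [_rearr(sequence_id=f"r{i}") for i in range(8)]
        rearrs += [_rearr(sequence_id=f"n{i}", productive=False) for i in range(2)]
        sample = build_repertoire(rearrs, "R1")
        assert sample.total_identified == 8

    def test_partition_refinement(self, small_campaign):
        """Clonotype keys refine CDRH3 strings: #keys >= #distinct CDRH3."""
        _, _, samples = small_campaign
        for s in samples:
            assert s.n_clonotypes >= len({k.cdrh3_aa for k in s.counts})


class TestVSubgroup:
    @pytest.mark.parametrize(
        "name, subgroup",
        [
            ("IGHV5-9-3", "IGHV5"),
            ("IGHV14-3", "IGHV14"),
            ("IGKV1-110", "IGKV1"),
            ("IGHV1S81", "IGHV1"),
        ],
    )
    def test_parses_imgt_names(self, name, subgroup):
        assert v_subgroup(name) == subgroup

    @pytest.mark.parametrize("name", ["CD38", "IGH", "TRBV5-1", ""])
    def test_rejects_non_gene_names(self, name):
        with pytest.raises(ValueError):
            v_subgroup(name)


def test_airr_round_trip(germline, small_library, tmp_path):
    _, truth, sample = small_library
    emit_reads(sample, truth, germline, 0.0, seed=1,
               fasta_path=tmp_path / "r.fa", airr_path=tmp_path / "r.tsv")
    df = read_airr(tmp_path / "r.tsv")
    assert len(df) == sample.n_reads
    rebuilt = repertoire_from_airr(tmp_path / "r.tsv", "library")
    assert rebuilt.counts == sample.counts
    assert rebuilt.total_identified == sample.total_identified
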