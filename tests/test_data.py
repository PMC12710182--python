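"""Domain types, descriptors, target transform, splitting, and file I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanpqsar import (
    IFNB,
    IL6,
    NANPDataset,
    NANPRecord,
    NucleicType,
    Shape,
    Strand,
    compute_descriptors,
    infer_strand_type,
    log10_transform_targets,
    read_dataset,
    rna_base_ratio,
    split_dataset,
    write_dataset,
    write_fasta,
)
from nanpqsar.data import (
    AmbiguousStrandTypeError,
    CannotSplitError,
    FormatError,
    InvalidMeasurementError,
    SequenceError,
)

from conftest import make_record


class TestStrandValidation:
    def test_case_and_whitespace_normalized(self):
        s = Strand("s", " acg u\n", NucleicType.RNA)
        assert s.sequence == "ACGU"

    @pytest.mark.parametrize("seq", ["", "ACGX", "ACUT", "ACG-N"])
    def test_invalid_sequences_rejected(self, seq):
        with pytest.raises(SequenceError):
            Strand("s", seq, NucleicType.DNA if "T" in seq else NucleicType.RNA)

    def test_type_sequence_consistency(self):
        with pytest.raises(SequenceError):
            Strand("s", "ACGT", NucleicType.RNA)
        with pytest.raises(SequenceError):
            Strand("s", "ACGU", NucleicType.DNA)

    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGU", NucleicType.RNA), ("ACGT", NucleicType.DNA)],
    )
    def test_infer_strand_type(self, seq, expected):
        assert infer_strand_type(seq) is expected

    def test_infer_ambiguous_raises(self):
        with pytest.raises(AmbiguousStrandTypeError):
            infer_strand_type("ACGC")


class TestRecordInvariants:
    def test_minimum_two_strands(self):
        with pytest.raises(FormatError):
            NANPRecord("N", Shape.OTHER,
                       (Strand("a", "ACGU", NucleicType.RNA),))

    @pytest.mark.parametrize(
        "shape,count",
        [(Shape.TRIANGLE, 4), (Shape.SQUARE, 5), (Shape.PENTAGON, 6),
         (Shape.CUBE, 6)],
    )
    def test_shape_implies_strand_count(self, shape, count):
        strands = tuple(
            Strand(f"s{i}", "ACGUACGU", NucleicType.RNA) for i in range(count)
        )
        assert NANPRecord("N", shape, strands).strand_count == count
        with pytest.raises(FormatError):
            NANPRecord("N", shape, strands[:-1] if count > 2 else strands * 2)

    def test_duplicate_ids_rejected(self, toy_record):
        with pytest.raises(FormatError):
            NANPDataset([toy_record, toy_record])


class TestDescriptors:
    def test_rna_ratio_hand_count(self):
        # two RNA strands of 10 nt + two DNA strands of 30 nt -> 20/80
        rec = make_record(
            "N", Shape.OTHER,
            ("ACGUACGUAC", "ACGUACGUAC", "ACGT" * 7 + "AC", "ACGT" * 7 + "AC"),
        )
        assert rna_base_ratio(rec) == pytest.approx(20 / 80)

    def test_rna_ratio_extremes(self):
        assert rna_base_ratio(make_record("N", seqs=("ACGU", "GGUU"))) == 1.0
        assert rna_base_ratio(make_record("N", seqs=("ACGT", "GGTT"))) == 0.0

    def test_rna_ratio_order_invariant(self, triangle_record):
        rec = triangle_record
        flipped = NANPRecord("T1x", rec.shape, tuple(reversed(rec.strands)))
        assert rna_base_ratio(rec) == rna_base_ratio(flipped)

    def test_descriptor_hand_counts(self):
        rec = make_record("N", seqs=("ACGU", "ACGU"))
        d = compute_descriptors(rec)
        assert d.strand_count == 2
        assert d.total_length == 8
        assert d.gc_fraction == pytest.approx(0.5)
        assert d.purine_fraction == pytest.approx(0.5)
        assert sum(d.mono_freqs) == pytest.approx(1.0, abs=1e-9)

    def test_homopolymer_gc_zero(self):
        d = compute_descriptors(make_record("N", seqs=("AAAA", "AAAA")))
        assert d.gc_fraction == 0.0

    def test_determinism(self, triangle_record):
        a = compute_descriptors(triangle_record).to_array()
        b = compute_descriptors(triangle_record).to_array()
        np.testing.assert_array_equal(a, b)


class TestLogTransform:
    @pytest.mark.parametrize("value,expected", [(1000.0, 3.0), (1.0, 0.0),
                                                (0.0, -1.0)])
    def test_examples(self, value, expected):
        ds = NANPDataset([make_record("N", endpoints={IFNB: value})])
        out = log10_transform_targets(ds, floor=0.1)
        assert out.records[0].endpoints[IFNB] == pytest.approx(expected)

    def test_negative_measurement_rejected(self):
        ds = NANPDataset([make_record("N", endpoints={IFNB: -1.0})])
        with pytest.raises(InvalidMeasurementError):
            log10_transform_targets(ds)

    def test_floor_recorded_and_invertible(self):
        values = [0.5, 7.3, 123.4, 99999.0]
        ds = NANPDataset(
            [make_record(f"N{i}", endpoints={IFNB: v})
             for i, v in enumerate(values)]
        )
        out = log10_transform_targets(ds, floor=0.1)
        assert out.metadata["target_transform"] == {"type": "log10", "floor": 0.1}
        for rec, v in zip(out.records, values):
            assert 10 ** rec.endpoints[IFNB] == pytest.approx(v, rel=1e-12)


class TestSplit:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=2, max_value=300),
        f=st.sampled_from([0.5, 0.7, 0.9]),
        stratify=st.booleans(),
    )
    def test_partition_property(self, n, f, stratify):
        """train and test are disjoint, cover the dataset, and
        |train| = floor(f * n)."""
        shapes = [Shape.OTHER, Shape.TRIANGLE]
        records = []
        for i in range(n):
            shape = shapes[i % 2]
            seqs = ("ACGUACGUAC",) * (4 if shape is Shape.TRIANGLE else 2)
            records.append(make_record(f"N{i}", shape, seqs))
        ds = NANPDataset(records)
        train, test = split_dataset(ds, f, seed=1, stratify_by_shape=stratify)
        assert len(train) == math.floor(f * n)
        assert len(train) + len(test) == n
        assert set(train.ids()).isdisjoint(test.ids())
        assert set(train.ids()) | set(test.ids()) == set(ds.ids())

    def test_panel_split_sizes(self):
        records = [make_record(f"N{i}") for i in range(176)]
        train, test = split_dataset(NANPDataset(records), 0.7, seed=0)
        assert (len(train), len(test)) == (123, 53)

    def test_seed_reproducibility(self, small_library):
        a = split_dataset(small_library, 0.7, seed=5)
        b = split_dataset(small_library, 0.7, seed=5)
        assert a[0].ids() == b[0].ids() and a[1].ids() == b[1].ids()

    def test_too_small_raises(self, toy_record):
        with pytest.raises(CannotSplitError):
            split_dataset(NANPDataset([toy_record]), 0.7, seed=0)


class TestFileIO:
    def test_csv_round_trip(self, tmp_path, small_library):
        m, e = tmp_path / "m.csv", tmp_path / "e.csv"
        write_dataset(small_library, m, e)
        back = read_dataset(m, e)
        assert back.ids() == small_library.ids()
        for a, b in zip(back, small_library):
            assert a.shape == b.shape
            assert [s.sequence for s in a.strands] == [s.sequence for s in b.strands]
            for key in (IFNB, IL6):
                assert a.endpoints[key] == pytest.approx(b.endpoints[key])

    def test_duplicate_strand_index_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "nanp_id,shape,strand_index,strand_id,nucleic_type,sequence\n"
            "N1,other,1,a,RNA,ACGU\n"
            "N1,other,1,b,RNA,ACGU\n"
        )
        with pytest.raises(FormatError):
            read_dataset(path)

    def test_auto_nucleic_type(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "nanp_id,shape,strand_index,strand_id,nucleic_type,sequence\n"
            "N1,other,1,a,auto,ACGU\nN1,other,2,b,auto,ACGT\n"
        )
        ds = read_dataset(path)
        assert [s.nucleic_type for s in ds.records[0].strands] == [
            NucleicType.RNA, NucleicType.DNA,
        ]

    def test_unmatched_endpoint_collected_as_warning(self, tmp_path, toy_dataset):
        m, e = tmp_path / "m.csv", tmp_path / "e.csv"
        write_dataset(toy_dataset, m, e)
        e.write_text(e.read_text() + "GHOST,1.0,2.0\n")
        ds = read_dataset(m, e)
        assert any("GHOST" in w for w in ds.metadata["join_warnings"])

    def test_fasta_round_trip_preserves_strand_order(self, tmp_path, toy_dataset):
        path = tmp_path / "strands.fasta"
        write_fasta(toy_dataset, path)
        back = read_dataset(path)
        assert back.ids() == toy_dataset.ids()
        for a, b in zip(back, toy_dataset):
            assert [s.sequence for s in a.strands] == [s.sequence for s in b.strands]
            assert a.shape == b.shape
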