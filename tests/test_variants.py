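import numpy as np
import pytest
from conftest import aln

from panplastome.annotation import GeneFeature, GeneModel
from panplastome.errors import InputError
from panplastome.structure import QuadripartitePartition
from panplastome.variants import (
    COL_GAP,
    COL_INVARIANT,
    COL_SUBSTITUTION,
    AlignmentMatrix,
    annotate_events,
    call_variant_events,
    collapse_ir_events,
    percentage_shares,
    scan_columns,
    snv_matrix,
    summarize_variants,
)


class TestAlignmentMatrix:
    def test_unequal_rows_rejected(self):
        with pytest.raises(InputError):
            aln(("a", "ACGT"), ("b", "ACG"))

    def test_single_row_rejected(self):
        with pytest.raises(InputError):
            AlignmentMatrix.from_sequences([("a", "ACGT")])

    def test_column_to_ref_pos_with_ref_gaps(self):
        a = aln(("ref", "AC--GT"), ("s", "ACTTGT"))
        assert a.column_to_ref_pos.tolist() == [0, 1, 1, 1, 2, 3]
        assert a.reference_length == 4


class TestScanColumns:
    def test_states(self):
        a = aln(("a", "AAAG"), ("b", "AG-G"), ("c", "AAAG"))
        states = scan_columns(a)
        assert states.tolist() == [
            COL_INVARIANT, COL_SUBSTITUTION, COL_GAP, COL_INVARIANT,
        ]

    def test_ambiguity_only_variation_is_invariant(self):
        a = aln(("a", "ANR"), ("b", "AAA"))
        assert scan_columns(a).tolist() == [0, 0, 0]


class TestCallEvents:
    def test_single_snv(self):
        events = call_variant_events(aln(("a", "ACGT"), ("b", "ACAT")))
        assert len(events) == 1
        assert events[0].category == "SNV"
        assert events[0].columns == (2, 3)

    def test_block_substitution(self):
        events = call_variant_events(aln(("a", "AAGGAA"), ("b", "AATTAA")))
        assert [(e.category, e.columns) for e in events] == [("BlockSub", (2, 4))]

    def test_indel_run_merged(self):
        events = call_variant_events(aln(("a", "AAATTTAAA"), ("b", "AAA---AAA")))
        assert [(e.category, e.columns) for e in events] == [("InDel", (3, 6))]

    def test_mixed_event(self):
        events = call_variant_events(aln(("a", "AAGTAAA"), ("b", "AAC-AAA")))
        assert [(e.category, e.columns) for e in events] == [("Mixed", (2, 4))]

    def test_alleles_recorded(self):
        events = call_variant_events(aln(("a", "ACGT"), ("b", "AGGT"), ("c", "ACGT")))
        assert events[0].alleles == ("C", "G")

    def test_events_disjoint_with_invariant_separation(self, small_simulation):
        events = call_variant_events(small_simulation.alignment)
        for prev, nxt in zip(events, events[1:]):
            assert prev.columns[1] < nxt.columns[0]

    def test_row_permutation_invariance(self, small_simulation):
        base = small_simulation.alignment
        events = call_variant_events(base)
        perm = list(reversed(range(base.n_samples)))
        shuffled = AlignmentMatrix(
            [base.sample_ids[i] for i in perm], base.matrix[perm],
            ref_index=perm.index(base.ref_index),
        )
        events2 = call_variant_events(shuffled)
        assert [(e.columns, e.category) for e in events] == [
            (e.columns, e.category) for e in events2
        ]


class TestAnnotateEvents:
    PART = QuadripartitePartition(
        lsc=(0, 500), irb=(500, 620), ssc=(620, 710), ira=(710, 830)
    )
    MODEL = GeneModel(
        features=[GeneFeature("alpha", "PCG", "+", [(100, 140), (160, 200)])],
        genome_length=830,
        partition=PART,
    )

    def build(self, pos, alt="T"):
        ref = "A" * 830
        other = ref[:pos] + alt + ref[pos + 1:]
        return aln(("ref", ref), ("s", other))

    @pytest.mark.parametrize(
        "pos,region,context,gene",
        [
            (50, "LSC", "IGS", None),
            (120, "LSC", "CDS", "alpha"),
            (150, "LSC", "intron", "alpha"),
            (550, "IR", "IGS", None),
            (650, "SSC", "IGS", None),
        ],
    )
    def test_region_and_context(self, pos, region, context, gene):
        events = annotate_events(
            call_variant_events(self.build(pos, alt="T")), self.PART, self.MODEL
        )
        assert len(events) == 1
        ev = events[0]
        assert (ev.region, ev.context, ev.gene) == (region, context, gene)

    def test_without_partition_or_model(self):
        events = annotate_events(call_variant_events(self.build(10)))
        assert events[0].region is None and events[0].context is None

    def test_collapse_ir_mirrored_pair(self):
        ref = list("A" * 830)
        alt = list(ref)
        # mirrored positions in IRb and IRa: 510 <-> 710 + (620 - 511) = 819
        alt[510] = "T"
        alt[819] = "T"
        a = aln(("ref", "".join(ref)), ("s", "".join(alt)))
        events = annotate_events(call_variant_events(a), self.PART)
        assert len(events) == 2
        collapsed = collapse_ir_events(events, self.PART)
        assert len(collapsed) == 1
        assert collapsed[0].ref_start == 510
        assert collapsed[0].ir_collapsed is True

    def test_collapse_keeps_unmirrored(self):
        ref = "A" * 830
        alt = ref[:515] + "T" + ref[516:]
        a = aln(("ref", ref), ("s", alt))
        events = annotate_events(call_variant_events(a), self.PART)
        assert len(collapse_ir_events(events, self.PART)) == 1


class TestSummarize:
    def test_published_count_percentages(self):
        counts = {"SNV": 455, "InDel": 201, "BlockSub": 18, "Mixed": 8}
        shares = percentage_shares(counts)
        # oracle: direct arithmetic on 682 (note 201/682 rounds to 29.47)
        assert shares == {"SNV": 66.72, "InDel": 29.47, "BlockSub": 2.64,
                          "Mixed": 1.17}

    def test_region_and_context_shares(self):
        assert percentage_shares({"LSC": 474, "SSC": 161, "IR": 47})["LSC"] == 69.50
        assert percentage_shares({"IGS": 381}, total=682)["IGS"] == 55.87

    def test_counts_sum_to_total(self, small_simulation):
        aln_ = small_simulation.alignment
        events = annotate_events(
            call_variant_events(aln_),
            small_simulation.partition,
            small_simulation.gene_model,
        )
        summary = summarize_variants(events)
        assert sum(summary.by_category.values()) == summary.total
        assert sum(summary.by_region.values()) == summary.total
        assert sum(summary.by_context.values()) == summary.total

    def test_empty_summary(self):
        summary = summarize_variants([])
        assert summary.total == 0
        assert all(v == 0 for v in summary.by_category.values())


class TestSnvMatrix:
    def test_counts_substitution_columns(self):
        a = aln(("a", "ACGTAC"), ("b", "AGGTAC"), ("c", "ACGAAC"))
        sub, cols = snv_matrix(a)
        assert cols.tolist() == [1, 3]
        assert sub.shape == (3, 2)

    def test_monomorphic_warns_empty(self):
        a = aln(("a", "ACGT"), ("b", "ACGT"))
        with pytest.warns(UserWarning):
            sub, cols = snv_matrix(a)
        assert cols.size == 0

    def test_matches_planted_substitution_columns(self, small_simulation):
        truth = small_simulation.truth
        expected = sum(
            ev.columns[1] - ev.columns[0]
            for ev in truth.events
            if ev.category in ("SNV", "BlockSub")
        ) + sum(1 for ev in truth.events if ev.category == "Mixed")
        _, cols = snv_matrix(small_simulation.alignment)
        assert cols.size == expected
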