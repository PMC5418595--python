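from collections import Counter

import numpy as np
import pytest

from combilib import (
    AlignmentRecord,
    GeneUnit,
    LibraryDesign,
    PromoterPart,
    Slot,
    align_reads,
    chain_reads,
    classify_reads,
    identify_read,
    simulate_library,
    tabulate,
)
from combilib.read_classifier import ReadIdentification, UnknownRegionError

AMPR = "AmpRTerm_AmpR_AmpRProm"


def toy_design():
    """Names/roles only; constructed records carry their own region lengths."""
    parts = {
        "pX": PromoterPart("pX", "strong", "ACGT" * 5),
        "pY": PromoterPart("pY", "weak", "ACGT" * 5),
    }
    units = {g: GeneUnit(g, "ACGT" * 10) for g in ("gA", "gB", "gC")}
    slots = [Slot(g, ("pX", "pY")) for g in ("gA", "gB", "gC")]
    return LibraryDesign(slots, parts, units)


def rec(ref, ref_total, read_start, read_name="r1", read_total=10_000, score=100,
        ref_start=0, ref_len=None, read_len=None, strand="+"):
    ref_len = ref_total - ref_start if ref_len is None else ref_len
    read_len = ref_len if read_len is None else read_len
    return AlignmentRecord(
        score=score, ref_name=ref, ref_start=ref_start, ref_aln_len=ref_len,
        read_name=read_name, read_start=read_start, read_aln_len=read_len,
        read_strand=strand, read_total_len=read_total, ref_total_len=ref_total,
    )


class TestChainReads:
    def test_sorted_by_read_coordinate(self):
        d = toy_design()
        records = [rec("gA", 1500, 4000), rec("pX", 500, 10), rec("gB", 1200, 2000)]
        (chain,) = chain_reads(records, d)
        assert [s.read_start for s in chain.segments] == [10, 2000, 4000]

    def test_overlapping_duplicates_keep_highest_score(self):
        d = toy_design()
        records = [
            rec("gA", 1500, 100, score=90),
            rec("gA", 1500, 150, score=120),
        ]
        (chain,) = chain_reads(records, d)
        assert len(chain.segments) == 1
        assert chain.segments[0].score == 120

    def test_lambda_only_chain_flagged_decoy(self):
        d = toy_design()
        records = [rec("lambda", 4000, 0, read_total=4000)]
        (chain,) = chain_reads(records, d)
        assert chain.decoy

    def test_decoy_flag_by_best_alignment(self):
        # gene unit outscores the backbone hit: not a decoy chain
        d = toy_design()
        records = [rec("gA", 1500, 0, read_total=3000, score=1400),
                   rec(AMPR, 1200, 1500, read_total=3000, score=1000)]
        (chain,) = chain_reads(records, d)
        assert not chain.decoy

    def test_chains_grouped_per_read(self):
        d = toy_design()
        records = [rec("pX", 500, 0, read_name="a", read_total=2000),
                   rec("pX", 500, 0, read_name="b", read_total=2000)]
        chains = chain_reads(records, d)
        assert sorted(c.read_name for c in chains) == ["a", "b"]


def single_chain(design, read_total, first_start=0, stretch=0):
    """A digested-single chain [pX, gA] with Σ region lengths 2000."""
    segs = [
        rec("pX", 500, first_start, read_total=read_total, score=450,
            read_len=500 + stretch),
        rec("gA", 1500, first_start + 520 + stretch, read_total=read_total, score=1400,
            read_len=min(1500 + stretch, read_total - first_start - 520 - stretch)),
    ]
    (chain,) = chain_reads(segs, design)
    return chain


class TestIdentifyRead:
    def test_multigene_accepted_with_slot_assignments(self):
        d = toy_design()
        # Σ region lengths = 500+1500+500+1200+500+900 = 5100
        layout = [("pX", 500), ("gA", 1500), ("pY", 500), ("gB", 1200), ("pX", 500), ("gC", 900)]
        pos, segs = 0, []
        for name, total in layout:
            segs.append(rec(name, total, pos, read_total=5150, score=total))
            pos += total + 10
        (chain,) = chain_reads(segs, d)
        ident = identify_read(chain, d)
        assert ident.verdict == "multigene"
        assert ident.slot_promoters == {"gA": "pX", "gB": "pY", "gC": "pX"}
        assert ident.reasons == []

    def test_length_boundary_inclusive_at_15_percent(self):
        d = toy_design()
        # read 15 % longer than the 2000 bp region sum: accepted exactly at
        # the boundary...
        chain = single_chain(d, read_total=2300, stretch=280)
        ident = identify_read(chain, d)
        assert ident.verdict == "digested_single"
        assert ident.gene == "gA"
        assert ident.length_ratio == pytest.approx(1.15)
        # ...and rejected one base over
        chain = single_chain(d, read_total=2301, stretch=280)
        ident = identify_read(chain, d)
        assert ident.verdict == "unidentified"
        assert "length" in ident.reasons

    def test_end_anchor_rejects_60bp_overhang(self):
        d = toy_design()
        chain = single_chain(d, read_total=2080, first_start=60)
        ident = identify_read(chain, d)
        assert ident.verdict == "unidentified"
        assert "end_anchor" in ident.reasons

    def test_end_anchor_allows_exactly_50bp(self):
        d = toy_design()
        chain = single_chain(d, read_total=2070, first_start=50)
        ident = identify_read(chain, d)
        assert ident.verdict == "digested_single"

    def test_end_anchor_not_applied_to_multigene(self):
        d = toy_design()
        layout = [("pX", 500), ("gA", 1500), ("pY", 500), ("gB", 1200), ("pX", 500), ("gC", 900)]
        pos, segs = 60, []  # 60 bp unaligned read prefix
        for name, total in layout:
            segs.append(rec(name, total, pos, read_total=5220, score=total))
            pos += total + 10
        (chain,) = chain_reads(segs, d)
        assert identify_read(chain, d).verdict == "multigene"

    def test_two_promoters_before_unit_is_ambiguous(self):
        d = toy_design()
        segs = [rec("pX", 500, 0, read_total=2500, score=450),
                rec("pY", 500, 510, read_total=2500, score=440),
                rec("gA", 1500, 1000, read_total=2500, score=1400, read_len=1500)]
        (chain,) = chain_reads(segs, d)
        ident = identify_read(chain, d)
        assert ident.verdict == "unidentified"
        assert "ambiguous_promoter" in ident.reasons

    def test_undigested_single_recognised_via_backbone(self):
        d = toy_design()
        segs = [rec("pX", 500, 0, read_total=3300, score=450),
                rec("gA", 1500, 500, read_total=3300, score=1400),
                rec(AMPR, 1200, 2000, read_total=3300, score=1100)]
        (chain,) = chain_reads(segs, d)
        ident = identify_read(chain, d)
        assert ident.verdict == "undigested_single"
        assert ident.gene == "gA"
        assert ident.slot_promoters == {"gA": "pX"}

    def test_non_backbone_decoy_segment_unidentified(self):
        # partial lambda hit (not the chain's best alignment, so the chain is
        # not removed as a decoy read) blocks identification
        d = toy_design()
        segs = [rec("pX", 500, 0, read_total=2900, score=450),
                rec("gA", 1500, 500, read_total=2900, score=1400),
                rec("lambda", 4000, 2000, read_total=2900, score=800,
                    ref_len=900, read_len=900)]
        (chain,) = chain_reads(segs, d)
        ident = identify_read(chain, d)
        assert ident.verdict == "unidentified"
        assert "decoy_segment" in ident.reasons

    def test_minus_strand_chain_canonicalised(self):
        d = toy_design()
        segs = [rec("gA", 1500, 0, read_total=2000, score=1400, strand="-"),
                rec("pX", 500, 1500, read_total=2000, score=450, strand="-")]
        (chain,) = chain_reads(segs, d)
        assert chain.orientation == "-"
        ident = identify_read(chain, d)
        assert ident.verdict == "digested_single"
        assert ident.slot_promoters == {"gA": "pX"}

    def test_decoy_chain_refused(self):
        d = toy_design()
        (chain,) = chain_reads([rec("lambda", 4000, 0, read_total=4000)], d)
        with pytest.raises(ValueError):
            identify_read(chain, d)

    def test_unknown_region_errors_when_known_set_given(self):
        d = toy_design()
        segs = [rec("pX", 500, 0, read_total=2100, score=450),
                rec("mystery", 100, 600, read_total=2100, score=90),
                rec("gA", 1500, 700, read_total=2100, score=1300, read_len=1400)]
        (chain,) = chain_reads(segs, d)
        with pytest.raises(UnknownRegionError):
            identify_read(chain, d, known_regions={AMPR, "lambda"})


class TestTabulate:
    def test_multigene_counts_per_slot(self):
        d = toy_design()
        idents = [
            ReadIdentification("r1", "multigene",
                               slot_promoters={"gA": "pX", "gB": "pY", "gC": "pX"},
                               length_ratio=1.0),
            ReadIdentification("r2", "multigene",
                               slot_promoters={"gA": "pX", "gB": "pX", "gC": "pY"},
                               length_ratio=1.0),
        ]
        table = tabulate(idents, d, "multi")
        assert table.counts[("gA", "pX")] == 2
        assert table.counts[("gB", "pY")] == 1
        assert table.category_counts[("gA", "strong")] == 2

    def test_slot_observation_conservation(self):
        d = toy_design()
        idents = [
            ReadIdentification("r1", "multigene",
                               slot_promoters={"gA": "pX", "gB": "pY", "gC": "pX"},
                               length_ratio=1.0),
            ReadIdentification("r2", "digested_single", gene="gB",
                               slot_promoters={"gB": "pY"}, length_ratio=1.0),
            ReadIdentification("r3", "unidentified", length_ratio=0.5),
        ]
        table = tabulate(idents, d, "pooled")
        assert sum(table.counts.values()) == 3 + 1
        assert sum(table.category_counts.values()) == 4

    def test_empty_input_all_zero(self):
        d = toy_design()
        table = tabulate([], d, "empty")
        assert sum(table.counts.values()) == 0
        assert set(table.counts) == {(s.gene, p) for s in d.slots
                                     for p in s.candidate_promoters}

    def test_tsv_round_trip(self, tmp_path):
        d = toy_design()
        idents = [ReadIdentification("r1", "digested_single", gene="gA",
                                     slot_promoters={"gA": "pY"}, length_ratio=1.0)]
        table = tabulate(idents, d, "s1")
        path = tmp_path / "counts.tsv"
        table.to_tsv(path)
        loaded = type(table).from_tsv(path, d)
        assert loaded.counts == table.counts
        assert loaded.category_counts == table.category_counts
        assert loaded.stage == "s1"


@pytest.fixture(scope="module")
def pipeline(design, decoys, reference_db, min_score):
    sim = simulate_library(design, 120, seed=21, decoys=decoys)
    records = align_reads(sim.reads, reference_db, min_score=min_score)
    return sim, records


class TestPipelineProperties:
    def test_every_read_gets_exactly_one_verdict(self, pipeline, design):
        sim, records = pipeline
        idents = classify_reads(records, design)
        aligned_reads = {r.read_name for r in records}
        assert len(idents) == len(aligned_reads)
        assert len({i.read_name for i in idents}) == len(idents)
        non_decoy = [i for i in idents if i.verdict != "decoy"]
        counts = Counter(i.verdict for i in non_decoy)
        assert sum(counts.values()) == len(non_decoy)
        assert set(counts) <= {"multigene", "digested_single",
                               "undigested_single", "unidentified"}

    def test_tightening_tolerances_never_gains_reads(self, pipeline, design):
        sim, records = pipeline

        def identified(length_tol, end_tol):
            idents = classify_reads(records, design,
                                    length_tol=length_tol, end_tol=end_tol)
            return sum(i.identified for i in idents)

        base = identified(0.15, 50)
        assert identified(0.10, 50) <= base
        assert identified(0.15, 25) <= base
        assert identified(0.05, 10) <= identified(0.10, 25) <= base

    def test_simulated_truth_recovered(self, pipeline, design):
        sim, records = pipeline
        idents = {i.read_name: i for i in classify_reads(records, design)}
        truth = {r.read_id: r for r in sim.reads}
        correct = 0
        multi = 0
        for read_id, tr in truth.items():
            if tr.kind != "multigene":
                continue
            multi += 1
            ident = idents.get(read_id)
            if ident and ident.verdict == "multigene" and \
                    ident.slot_promoters == dict(tr.promoter_choice):
                correct += 1
        assert multi > 0
        assert correct / multi >= 0.95
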