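"""Annotation merging and priority-rule read assignment."""

import numpy as np
import pytest

from evbiomark import (
    AlignmentRecord,
    FeatureAnnotation,
    assign_read,
    build_toy_annotation,
    count_matrix_from_alignments,
    load_annotations,
    simulate_alignments,
)
from evbiomark.annotation import AnnotationError, write_bed6, write_gtf
from evbiomark.quantify import PRIORITY_ORDER
from conftest import small_config


def _feat(fid, biotype, chrom="chr1", start=0, end=100, strand="+"):
    return FeatureAnnotation(fid, biotype, chrom, start, end, strand)


def _read(start, end, chrom="chr1", strand="+", rid="r1"):
    return AlignmentRecord(rid, chrom, start, end, strand)


# --- load_annotations -------------------------------------------------------


def test_single_gtf_roundtrip(tmp_path):
    feats = [_feat(f"f{i}", "miRNA", start=i * 200, end=i * 200 + 50) for i in range(5)]
    path = tmp_path / "mirbase_like.gtf"
    write_gtf(feats, path)
    loaded = load_annotations([path])
    assert len(loaded) == 5
    assert {f.feature_id for f in loaded} == {f"f{i}" for i in range(5)}
    assert all(f.start == i * 200 for f, i in zip(sorted(loaded, key=lambda f: f.start), range(5)))


def test_duplicate_ids_across_sources_are_suffixed(tmp_path):
    a = tmp_path / "dbA.gtf"
    b = tmp_path / "dbB.gtf"
    write_gtf([_feat("shared", "piRNA", start=0, end=50)], a)
    write_gtf([_feat("shared", "piRNA", start=500, end=560)], b)
    loaded = load_annotations([a, b])
    assert len(loaded) == 2
    assert {f.feature_id for f in loaded} == {"shared__dbA", "shared__dbB"}


def test_identical_interval_same_biotype_collapsed(tmp_path):
    a = tmp_path / "dbA.gtf"
    b = tmp_path / "dbB.gtf"
    write_gtf([_feat("x1", "lncRNA", start=10, end=90)], a)
    write_gtf([_feat("x2", "lncRNA", start=10, end=90)], b)
    loaded = load_annotations([a, b])
    assert len(loaded) == 1


def test_bed6_with_biotype_column_and_unknown_biotype_error(tmp_path):
    good = tmp_path / "pirna.bed"
    good.write_text("chr1\t10\t40\tp1\tpiRNA\t+\n")
    assert load_annotations([good])[0].biotype == "piRNA"
    with pytest.raises(AnnotationError, match="miRNA"):  # message lists vocabulary
        load_annotations([good], source_biotypes={"pirna": "bogotype"})


def test_malformed_bed_line_reports_line_number(tmp_path):
    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t10\t40\tp1\tpiRNA\t+\nchr1\t50\n")
    with pytest.raises(AnnotationError, match="line 2"):
        load_annotations([bad])


# --- assign_read ------------------------------------------------------------


def test_mirna_beats_lncrna():
    m1 = _feat("m1", "miRNA", start=10, end=32)
    l1 = _feat("l1", "lncRNA", start=0, end=500)
    assert assign_read(_read(12, 30), [l1, m1]) == "m1"


def test_single_overlap_is_identity():
    mr = _feat("g1", "mRNA", start=0, end=200)
    assert assign_read(_read(50, 75), [mr]) == "g1"


def test_equal_priority_ties_resolved_by_overlap_then_id():
    l1 = _feat("l1", "lncRNA", start=0, end=20)  # 20 nt overlap
    l2 = _feat("l2", "lncRNA", start=5, end=40)  # 15 nt overlap
    assert assign_read(_read(0, 20), [l2, l1]) == "l1"
    # equal overlaps -> lexicographically smallest id
    l3 = _feat("l3", "lncRNA", start=0, end=20)
    assert assign_read(_read(0, 20), [l3, l1]) == "l1"


def test_empty_candidate_list_unassigned():
    assert assign_read(_read(0, 20), []) is None


def test_min_overlap_excludes_grazing_hits():
    f = _feat("f", "mRNA", start=0, end=10)
    assert assign_read(_read(9, 30), [f], min_overlap=1) == "f"
    assert assign_read(_read(9, 30), [f], min_overlap=2) is None


def test_assign_read_matches_bruteforce_oracle():
    """Randomized instances against stable-sort by (priority, -overlap, id)."""
    rng = np.random.default_rng(123)
    biotypes = list(PRIORITY_ORDER)
    for _ in range(2000):
        n = rng.integers(1, 6)
        feats = []
        for j in range(n):
            s = int(rng.integers(0, 50))
            feats.append(
                _feat(f"f{rng.integers(0, 4)}", biotypes[rng.integers(0, 10)], start=s, end=s + int(rng.integers(5, 60)))
            )
        rs = int(rng.integers(0, 60))
        read = _read(rs, rs + int(rng.integers(5, 40)))
        keyed = [
            (PRIORITY_ORDER[f.biotype], -(min(read.end, f.end) - max(read.start, f.start)), f.feature_id)
            for f in feats
            if min(read.end, f.end) - max(read.start, f.start) >= 1
        ]
        expected = min(keyed)[2] if keyed else None
        assert assign_read(read, feats) == expected


# --- count_matrix_from_alignments ------------------------------------------


def test_counts_equal_simulated_truth():
    config = small_config(n_reads_per_sample=400, overlap_fraction=0.4)
    annotation = build_toy_annotation(config)
    alignments, truth = simulate_alignments(config, annotation)
    cm, unassigned = count_matrix_from_alignments(alignments, annotation)
    assert cm.counts.equals(truth)
    for s, records in alignments.items():
        assert cm.counts[s].sum() + unassigned[s] == len(records)


def test_zero_alignments_give_zero_matrix_with_full_index():
    annotation = build_toy_annotation(small_config())
    cm, unassigned = count_matrix_from_alignments({"s1": []}, annotation)
    assert cm.counts.shape == (len(annotation), 1)
    assert (cm.counts == 0).all().all()
    assert unassigned["s1"] == 0


def test_alignment_order_invariance():
    config = small_config(n_reads_per_sample=200)
    annotation = build_toy_annotation(config)
    alignments, _ = simulate_alignments(config, annotation)
    shuffled = {s: list(reversed(records)) for s, records in alignments.items()}
    cm1, _ = count_matrix_from_alignments(alignments, annotation)
    cm2, _ = count_matrix_from_alignments(shuffled, annotation)
    assert cm1.counts.equals(cm2.counts)


def test_unknown_chromosome_counts_as_unassigned():
    annotation = [_feat("f1", "miRNA", start=0, end=100)]
    reads = [_read(10, 30, chrom="chrMystery")]
    cm, unassigned = count_matrix_from_alignments({"s": reads}, annotation)
    assert unassigned["s"] == 1
    assert cm.counts["s"].sum() == 0


def test_strand_mismatch_unassigned_unless_unstranded():
    annotation = [_feat("f1", "miRNA", start=0, end=100, strand="+")]
    reads = [_read(10, 30, strand="-")]
    cm, unassigned = count_matrix_from_alignments({"s": reads}, annotation)
    assert unassigned["s"] == 1
    cm2, un2 = count_matrix_from_alignments({"s": reads}, annotation, stranded=False)
    assert cm2.counts.loc["f1", "s"] == 1 and un2["s"] == 0


def test_duplicate_read_ids_rejected():
    annotation = [_feat("f1", "miRNA", start=0, end=100)]
    reads = [_read(10, 30, rid="dup"), _read(40, 60, rid="dup")]
    with pytest.raises(ValueError, match="duplicate read id"):
        count_matrix_from_alignments({"s": reads}, annotation)


def test_sam_and_bed_roundtrip(tmp_path):
    from evbiomark.alignments import (
        load_alignments,
        write_bed6_alignments,
        write_sam_alignments,
    )
    from evbiomark.simdata import toy_chrom_sizes

    config = small_config(n_reads_per_sample=50)
    annotation = build_toy_annotation(config)
    alignments, _ = simulate_alignments(config, annotation, sample_ids=["sA"])
    records = alignments["sA"]
    sam, bed = tmp_path / "sA.sam", tmp_path / "sA.bed"
    write_sam_alignments(records, sam, toy_chrom_sizes(annotation))
    write_bed6_alignments(records, bed)
    assert load_alignments(sam) == records
    assert load_alignments(bed) == records
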