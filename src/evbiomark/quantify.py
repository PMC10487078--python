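"""Biotype-prioritized read counting.

Small-RNA annotations overlap heavily: a miRNA hairpin may sit inside a
lncRNA intron, a tRNA fragment inside a pseudogene.  Rather than counting a
read once per overlapping feature, each read is assigned to exactly one
feature using a fixed biotype priority hierarchy:

    miRNA > tRNA > rRNA > mRNA > pseudogene > snRNA > snoRNA > piRNA
    > lncRNA > miscRNA

Among equal-priority features the read goes to the one with the largest
overlap; remaining ties break to the lexicographically smallest feature id,
so assignment is a deterministic, order-independent function of the read
and the annotation.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .alignments import AlignmentRecord
from .annotation import BIOTYPES, FeatureAnnotation
from .countmatrix import CountMatrix

logger = logging.getLogger(__name__)

#: Assignment priority of each biotype (lower rank wins).
PRIORITY_ORDER: dict[str, int] = {b: i for i, b in enumerate(BIOTYPES)}

UNASSIGNED = None


def overlap_length(read_start: int, read_end: int, feat: FeatureAnnotation) -> int:
    return max(0, min(read_end, feat.end) - max(read_start, feat.start))


def assign_read(
    read: AlignmentRecord,
    overlapping: Sequence[FeatureAnnotation],
    min_overlap: int = 1,
) -> str | None:
    """Assign a read to one feature among its same-strand overlaps.

    ``overlapping`` should contain candidate features on the read's strand;
    features overlapping by fewer than ``min_overlap`` bases are ignored.
    Returns the winning ``feature_id`` or ``None`` if no feature qualifies.
    """
    best: tuple[int, int, str] | None = None
    best_feat = None
    for feat in overlapping:
        ov = overlap_length(read.start, read.end, feat)
        if ov < min_overlap:
            continue
        key = (PRIORITY_ORDER[feat.biotype], -ov, feat.feature_id)
        if best is None or key < best:
            best = key
            best_feat = feat.feature_id
    return best_feat


class _AnnotationIndex:
    """Interval index over features, keyed by (chrom, strand)."""

    def __init__(self, features: Sequence[FeatureAnnotation], stranded: bool = True):
        self.stranded = stranded
        self.trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        self.chroms = set()
        for f in features:
            self.chroms.add(f.chrom)
            self.trees[(f.chrom, f.strand if stranded else ".")].addi(f.start, f.end, f)

    def query(self, read: AlignmentRecord) -> list[FeatureAnnotation]:
        strand = read.strand if self.stranded else "."
        tree = self.trees.get((read.chrom, strand))
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(read.start, read.end)]


def count_matrix_from_alignments(
    alignments_by_sample: Mapping[str, Sequence[AlignmentRecord]],
    annotation: Sequence[FeatureAnnotation],
    min_overlap: int = 1,
    stranded: bool = True,
) -> tuple[CountMatrix, pd.Series]:
    """Count reads per feature per sample under the priority rule.

    Parameters
    ----------
    alignments_by_sample
        Mapping sample id -> alignment records for that sample.
    annotation
        Merged feature set; every feature appears in the output matrix even
        if no read is assigned to it.
    stranded
        Require read strand to match feature strand (small-RNA libraries
        are stranded); pass ``False`` for unstranded counting.

    Returns
    -------
    (CountMatrix, unassigned)
        The count matrix over the full feature index, and a per-sample
        Series of reads left unassigned.  Per sample, assigned + unassigned
        equals the number of input reads.
    """
    index = _AnnotationIndex(annotation, stranded=stranded)
    feature_ids = [f.feature_id for f in annotation]
    biotypes = pd.Series(
        [f.biotype for f in annotation], index=pd.Index(feature_ids, name="feature_id")
    )
    samples = list(alignments_by_sample)
    counts = pd.DataFrame(
        np.zeros((len(feature_ids), len(samples)), dtype=np.int64),
        index=pd.Index(feature_ids, name="feature_id"),
        columns=samples,
    )
    unassigned = pd.Series(0, index=pd.Index(samples, name="sample_id"), dtype=np.int64)
    for sample, records in alignments_by_sample.items():
        seen_ids = set()
        col = counts[sample].to_dict()
        n_unassigned = 0
        for read in records:
            if read.read_id in seen_ids:
                raise ValueError(
                    f"sample {sample}: duplicate read id {read.read_id!r} "
                    "(multi-mapped input is not supported)"
                )
            seen_ids.add(read.read_id)
            if read.chrom not in index.chroms:
                logger.warning(
                    "sample %s: read %s on unknown chromosome %s counted as unassigned",
                    sample,
                    read.read_id,
                    read.chrom,
                )
                n_unassigned += 1
                continue
            fid = assign_read(read, index.query(read), min_overlap=min_overlap)
            if fid is None:
                n_unassigned += 1
            else:
                col[fid] += 1
        counts[sample] = pd.Series(col)
        unassigned[sample] = n_unassigned
        logger.info(
            "sample %s: %d reads assigned, %d unassigned",
            sample,
            len(records) - n_unassigned,
            n_unassigned,
        )
    return CountMatrix(counts, biotypes), unassigned
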