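"""Feature annotations for small-RNA quantification.

Annotations for extracellular-vesicle small RNA-seq come from many
databases (miRBase-style miRNA sets, tRNA/piRNA/lncRNA catalogues, the
reference gene build), each contributing intervals tagged with one of ten
RNA biotypes.  This module merges such multi-source annotation files
(GTF/GFF3 or BED6) into a single deduplicated feature set with 0-based
half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pyranges as pr

#: The ten-level RNA biotype vocabulary used throughout the pipeline.
BIOTYPES = (
    "miRNA",
    "tRNA",
    "rRNA",
    "mRNA",
    "pseudogene",
    "snRNA",
    "snoRNA",
    "piRNA",
    "lncRNA",
    "miscRNA",
)


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated RNA feature on the genome.

    Coordinates are 0-based half-open (BED convention); GTF input/output is
    converted at the boundary.
    """

    feature_id: str
    biotype: str
    chrom: str
    start: int
    end: int
    strand: str
    source_db: str = "unknown"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"feature {self.feature_id}: start {self.start} >= end {self.end}"
            )
        if self.biotype not in BIOTYPES:
            raise AnnotationError(
                f"feature {self.feature_id}: unknown biotype {self.biotype!r}; "
                f"valid biotypes are {', '.join(BIOTYPES)}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"feature {self.feature_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _features_to_frame(features: Sequence[FeatureAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in features],
            "biotype": [f.biotype for f in features],
            "chrom": [f.chrom for f in features],
            "start": [f.start for f in features],
            "end": [f.end for f in features],
            "strand": [f.strand for f in features],
            "source_db": [f.source_db for f in features],
        }
    )


def annotation_to_frame(features: Sequence[FeatureAnnotation]) -> pd.DataFrame:
    """Tabular view of a feature set (one row per feature)."""
    return _features_to_frame(features)


def _read_gtf(path: Path, biotype_override: str | None) -> list[FeatureAnnotation]:
    try:
        df = pr.read_gtf(str(path)).df
    except Exception as exc:  # pragma: no cover - depends on parser internals
        raise AnnotationError(f"{path}: failed to parse as GTF/GFF ({exc})") from exc
    if df.empty:
        return []
    feats = []
    for i, row in enumerate(df.itertuples(index=False)):
        biotype = biotype_override or getattr(row, "biotype", None)
        if biotype is None or (isinstance(biotype, float)):
            raise AnnotationError(
                f"{path} record {i + 1}: no 'biotype' attribute and no per-source override"
            )
        fid = getattr(row, "gene_id", None) or getattr(row, "transcript_id", None)
        if fid is None:
            raise AnnotationError(f"{path} record {i + 1}: no gene_id/transcript_id")
        feats.append(
            FeatureAnnotation(
                feature_id=str(fid),
                biotype=str(biotype),
                chrom=str(row.Chromosome),
                start=int(row.Start),
                end=int(row.End),
                strand=str(row.Strand),
                source_db=path.stem,
            )
        )
    return feats


def _read_bed6(path: Path, biotype_override: str | None) -> list[FeatureAnnotation]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise AnnotationError(
                    f"{path} line {lineno}: expected >=6 tab-separated BED fields, got {len(parts)}"
                )
            chrom, start, end, name, score, strand = parts[:6]
            # BED score column doubles as the biotype carrier in our BED-like
            # sources when it is non-numeric; otherwise an override is required.
            biotype = biotype_override
            if biotype is None and score in BIOTYPES:
                biotype = score
            if biotype is None and len(parts) >= 7 and parts[6] in BIOTYPES:
                biotype = parts[6]
            if biotype is None:
                raise AnnotationError(
                    f"{path} line {lineno}: cannot resolve a biotype; valid biotypes "
                    f"are {', '.join(BIOTYPES)}"
                )
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path} line {lineno}: non-integer coordinates") from exc
            feats.append(
                FeatureAnnotation(
                    feature_id=name,
                    biotype=biotype,
                    chrom=chrom,
                    start=s,
                    end=e,
                    strand=strand,
                    source_db=path.stem,
                )
            )
    return feats


def load_annotations(
    paths: Iterable[str | Path],
    source_biotypes: Mapping[str, str] | None = None,
) -> list[FeatureAnnotation]:
    """Merge annotation files from several databases into one feature set.

    Parameters
    ----------
    paths
        GTF/GFF3 (``.gtf``/``.gff``/``.gff3``) or BED6 files.  GTF records
        must carry a ``biotype`` attribute unless an override is supplied.
    source_biotypes
        Optional mapping from file stem (or full path string) to a biotype
        applied to every record of that source, for databases that are
        single-biotype by construction (e.g. a piRNA catalogue).

    Returns
    -------
    list of FeatureAnnotation
        Duplicate ids across sources are disambiguated by suffixing the
        source name; records with identical (chrom, start, end, strand,
        biotype) are collapsed to a single feature.
    """
    source_biotypes = dict(source_biotypes or {})
    all_feats: list[FeatureAnnotation] = []
    for p in paths:
        path = Path(p)
        override = source_biotypes.get(str(path), source_biotypes.get(path.stem))
        if override is not None and override not in BIOTYPES:
            raise AnnotationError(
                f"override biotype {override!r} for {path} not in vocabulary "
                f"{', '.join(BIOTYPES)}"
            )
        suffix = path.suffix.lower()
        if suffix in (".gtf", ".gff", ".gff3"):
            all_feats.extend(_read_gtf(path, override))
        elif suffix in (".bed", ".bed6"):
            all_feats.extend(_read_bed6(path, override))
        else:
            raise AnnotationError(f"{path}: unrecognised annotation format {suffix!r}")

    # Collapse identical-interval same-biotype duplicates (keep first source).
    seen_interval: dict[tuple, FeatureAnnotation] = {}
    for f in all_feats:
        key = (f.chrom, f.start, f.end, f.strand, f.biotype)
        if key not in seen_interval:
            seen_interval[key] = f
    merged = list(seen_interval.values())

    # Disambiguate remaining id clashes across sources.
    by_id: dict[str, int] = {}
    for f in merged:
        by_id[f.feature_id] = by_id.get(f.feature_id, 0) + 1
    out = []
    for f in merged:
        if by_id[f.feature_id] > 1:
            f = FeatureAnnotation(
                feature_id=f"{f.feature_id}__{f.source_db}",
                biotype=f.biotype,
                chrom=f.chrom,
                start=f.start,
                end=f.end,
                strand=f.strand,
                source_db=f.source_db,
            )
        out.append(f)
    ids = [f.feature_id for f in out]
    if len(set(ids)) != len(ids):
        raise AnnotationError("feature ids not unique after source-suffix disambiguation")
    return out


def write_gtf(features: Sequence[FeatureAnnotation], path: str | Path) -> None:
    """Write features as GTF (1-based inclusive) with a ``biotype`` attribute."""
    with open(path, "w") as fh:
        for f in features:
            attrs = f'gene_id "{f.feature_id}"; biotype "{f.biotype}";'
            fh.write(
                f"{f.chrom}\t{f.source_db}\texon\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


def write_bed6(features: Sequence[FeatureAnnotation], path: str | Path) -> None:
    """Write features as BED6 with the biotype in the score column."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t{f.biotype}\t{f.strand}\n")
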