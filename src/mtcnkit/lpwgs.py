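"""mtDNA copy number from low-pass WGS coverage.

A diploid cell carries two copies of each autosome, so the mean depth ratio
of the mitochondrial contig to the autosomes, doubled, estimates copies of
mtDNA per cell:

    mtDNAcn = (mito mean depth / autosomal mean depth) * 2

At 0.5-1X autosomal depth the mitochondrial genome is typically covered at
100-1000X, so the ratio is well determined even from shallow data.  Depth
here means aligned reference bases per reference position; the streaming
pass sums each kept read's M/=/X reference span per contig, which equals a
per-base pileup average without holding per-position arrays.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pysam

LOW_MITO_COVERAGE = "LOW_MITO_COVERAGE"

_MITO_NAMES = {"chrM", "MT", "M", "NC_012920.1", "chrMT"}
_AUTOSOME_NAMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}
_SEX_NAMES = {"chrX", "chrY", "X", "Y"}

# CIGAR ops counted as aligned reference bases (M, =, X)
_ALIGNED_OPS = frozenset((0, 7, 8))
# ops that consume reference without being coverage (D, N)
_REF_GAP_OPS = frozenset((2, 3))


@dataclass(frozen=True)
class ContigClassification:
    contig_name: str
    contig_class: str  # autosome | sex | mitochondrial | other
    length: int


@dataclass(frozen=True)
class ReadFilterPolicy:
    """Which alignment records contribute to depth.

    Defaults drop duplicates (they inflate depth at low pass), secondary/
    supplementary records (double counting), unmapped reads, and MAPQ 0
    (multi-mappers, including NUMT cross-mapping).  Set everything off and
    min_mapq=0 to reproduce unfiltered behavior.
    """

    min_mapq: int = 1
    drop_duplicates: bool = True
    drop_secondary: bool = True
    drop_supplementary: bool = True
    drop_unmapped: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")

    def rejection(self, read: pysam.AlignedSegment) -> str | None:
        """Name of the first filter the read fails, or None if kept."""
        if self.drop_unmapped and read.is_unmapped:
            return "unmapped"
        if self.drop_secondary and read.is_secondary:
            return "secondary"
        if self.drop_supplementary and read.is_supplementary:
            return "supplementary"
        if self.drop_duplicates and read.is_duplicate:
            return "duplicate"
        if read.mapping_quality < self.min_mapq:
            return "low_mapq"
        return None


@dataclass
class ContigDepth:
    length: int
    aligned_bases: int = 0

    @property
    def mean_depth(self) -> float:
        return self.aligned_bases / self.length


@dataclass
class CoverageSummary:
    per_contig: dict[str, ContigDepth]
    autosomal_mean_depth: float
    mito_mean_depth: float
    reads_kept: int
    reads_filtered: dict[str, int]
    mito_read_count: int


@dataclass(frozen=True)
class LpwgsCnResult:
    sample_id: str
    mtdnacn: float
    mito_mean_depth: float
    autosomal_mean_depth: float
    mito_read_count: int
    qc_flags: frozenset[str] = frozenset()


def classify_contigs(
    header_contigs: Sequence[tuple[str, int]],
    overrides: Mapping[str, str] | None = None,
) -> list[ContigClassification]:
    """Classify every contig of an alignment header.

    Recognizes the common naming dialects for human references (chrM/MT/M/
    NC_012920.1 mitochondrial; chr1-22 or bare 1-22 autosomes; X/Y sex);
    anything else is "other" and excluded from the autosomal mean.
    ``overrides`` (contig -> class) win over recognition.  Exactly one
    mitochondrial contig must result.
    """
    overrides = dict(overrides or {})
    names = [n for n, _ in header_contigs]
    if len(names) != len(set(names)):
        raise ValueError("contig names must be unique")
    out = []
    for name, length in header_contigs:
        if name in overrides:
            cls = overrides[name]
            if cls not in ("autosome", "sex", "mitochondrial", "other"):
                raise ValueError(f"invalid override class {cls!r} for {name}")
        elif name in _MITO_NAMES:
            cls = "mitochondrial"
        elif name in _AUTOSOME_NAMES:
            cls = "autosome"
        elif name in _SEX_NAMES:
            cls = "sex"
        else:
            cls = "other"
        out.append(ContigClassification(name, cls, length))
    n_mito = sum(1 for c in out if c.contig_class == "mitochondrial")
    if n_mito != 1:
        raise ValueError(f"need exactly one mitochondrial contig, found {n_mito}")
    return out


def _class_map(classification: Sequence[ContigClassification]) -> dict[str, ContigClassification]:
    return {c.contig_name: c for c in classification}


def aligned_reference_bases(read: pysam.AlignedSegment) -> int:
    """Reference bases covered by a read: CIGAR M/=/X lengths (not D/N/clips)."""
    if read.cigartuples is None:
        return 0
    return sum(length for op, length in read.cigartuples if op in _ALIGNED_OPS)


def _iter_reads(
    alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
) -> tuple[Iterable[pysam.AlignedSegment], pysam.AlignmentFile | None]:
    if isinstance(alignments, (str, Path)):
        af = pysam.AlignmentFile(str(alignments), check_sq=False)
        return af, af
    if isinstance(alignments, pysam.AlignmentFile):
        return alignments, None
    return alignments, None


def _finalize(
    contigs: dict[str, ContigDepth],
    cmap: dict[str, ContigClassification],
    kept: int,
    filtered: dict[str, int],
    mito_reads: int,
) -> CoverageSummary:
    auto_bases = sum(d.aligned_bases for n, d in contigs.items()
                     if cmap[n].contig_class == "autosome")
    auto_len = sum(d.length for n, d in contigs.items()
                   if cmap[n].contig_class == "autosome")
    mito_name = next(n for n, c in cmap.items() if c.contig_class == "mitochondrial")
    return CoverageSummary(
        per_contig=contigs,
        autosomal_mean_depth=auto_bases / auto_len if auto_len else 0.0,
        mito_mean_depth=contigs[mito_name].mean_depth,
        reads_kept=kept,
        reads_filtered=filtered,
        mito_read_count=mito_reads,
    )


def mean_depth(
    alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    classification: Sequence[ContigClassification],
    policy: ReadFilterPolicy = ReadFilterPolicy(),
) -> CoverageSummary:
    """Single streaming pass over a SAM/BAM: per-contig mean depth.

    Order-independent and constant memory in genome size.  The autosomal
    mean is length-weighted (total autosomal aligned bases over total
    autosomal length); sex and unplaced contigs never enter it.
    """
    cmap = _class_map(classification)
    contigs = {c.contig_name: ContigDepth(c.length) for c in classification}
    kept = 0
    filtered: dict[str, int] = {}
    mito_reads = 0
    reads, handle = _iter_reads(alignments)
    try:
        for read in reads:
            reason = policy.rejection(read)
            if reason is not None:
                filtered[reason] = filtered.get(reason, 0) + 1
                continue
            name = read.reference_name
            if name not in contigs:
                raise ValueError(f"contig {name!r} in records but not in classification")
            contigs[name].aligned_bases += aligned_reference_bases(read)
            kept += 1
            if cmap[name].contig_class == "mitochondrial":
                mito_reads += 1
    finally:
        if handle is not None:
            handle.close()
    return _finalize(contigs, cmap, kept, filtered, mito_reads)


def pileup_depth_oracle(
    alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    classification: Sequence[ContigClassification],
    policy: ReadFilterPolicy = ReadFilterPolicy(),
) -> CoverageSummary:
    """Brute-force per-base depth counter (toy-scale test oracle).

    Walks every read's CIGAR and increments a per-position array for each
    M/=/X base, then averages.  Must match :func:`mean_depth` exactly on
    identical input and filters.
    """
    cmap = _class_map(classification)
    depth = {c.contig_name: np.zeros(c.length, dtype=np.int64) for c in classification}
    kept = 0
    filtered: dict[str, int] = {}
    mito_reads = 0
    reads, handle = _iter_reads(alignments)
    try:
        for read in reads:
            reason = policy.rejection(read)
            if reason is not None:
                filtered[reason] = filtered.get(reason, 0) + 1
                continue
            name = read.reference_name
            if name not in depth:
                raise ValueError(f"contig {name!r} in records but not in classification")
            pos = read.reference_start
            for op, length in read.cigartuples or ():
                if op in _ALIGNED_OPS:
                    depth[name][pos:pos + length] += 1
                    pos += length
                elif op in _REF_GAP_OPS:
                    pos += length
            kept += 1
            if cmap[name].contig_class == "mitochondrial":
                mito_reads += 1
    finally:
        if handle is not None:
            handle.close()
    contigs = {name: ContigDepth(len(arr), int(arr.sum())) for name, arr in depth.items()}
    return _finalize(contigs, cmap, kept, filtered, mito_reads)


def mtdnacn_from_coverage(
    summary: CoverageSummary,
    sample_id: str = "sample",
) -> LpwgsCnResult:
    """mtDNAcn = (mito mean depth / autosomal mean depth) * 2."""
    if summary.autosomal_mean_depth <= 0:
        raise ValueError("autosomal mean depth is zero; cannot form coverage ratio")
    flags = set()
    if summary.mito_mean_depth == 0:
        flags.add(LOW_MITO_COVERAGE)
    return LpwgsCnResult(
        sample_id=sample_id,
        mtdnacn=(summary.mito_mean_depth / summary.autosomal_mean_depth) * 2.0,
        mito_mean_depth=summary.mito_mean_depth,
        autosomal_mean_depth=summary.autosomal_mean_depth,
        mito_read_count=summary.mito_read_count,
        qc_flags=frozenset(flags),
    )


def classification_from_header(
    alignments: str | Path | pysam.AlignmentFile,
    overrides: Mapping[str, str] | None = None,
) -> list[ContigClassification]:
    """Read (name, length) pairs from a SAM/BAM header and classify them."""
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
            pairs = list(zip(af.references, af.lengths))
    else:
        pairs = list(zip(alignments.references, alignments.lengths))
    return classify_contigs(pairs, overrides)


def read_override_table(stream: IO[str]) -> dict[str, str]:
    """Contig-class override TSV: columns ``contig`` and ``class``."""
    rows = list(csv.DictReader(stream, delimiter="\t"))
    return {r["contig"]: r["class"] for r in rows}


def write_result_tsv(results: Sequence[LpwgsCnResult], stream: IO[str]) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(["sample_id", "mtdnacn", "mito_mean_depth",
                     "autosomal_mean_depth", "mito_reads", "qc_flags"])
    for r in sorted(results, key=lambda r: r.sample_id):
        writer.writerow([r.sample_id, f"{r.mtdnacn:.6g}", f"{r.mito_mean_depth:.6g}",
                         f"{r.autosomal_mean_depth:.6g}", r.mito_read_count,
                         ";".join(sorted(r.qc_flags))])


def write_per_contig_tsv(summary: CoverageSummary, stream: IO[str]) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(["contig", "length", "aligned_bases", "mean_depth"])
    for name in sorted(summary.per_contig):
        d = summary.per_contig[name]
        writer.writerow([name, d.length, d.aligned_bases, f"{d.mean_depth:.6g}"])
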