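"""Alignment ingestion: sample QC metrics, pair-level filtering, and
clipped-read / discordant-pair evidence extraction.

Reads are consumed as pysam records (SAM or BAM).  Before any metric is
computed, reads lacking a mate, duplicates, mapping-quality-zero reads and
records whose sequence and quality strings disagree in length are removed.
Chimeric pairs are those in unexpected orientation (same-strand or
outward-facing mates) or with insert size above 100 kb.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

log = logging.getLogger("l1recall")

MAX_INSERT = 100_000

# QC thresholds used for tumor/normal pair exclusion.
CHIMERIC_MAX = 0.02
TUMOR_MIN_DEPTH = 50.0
NORMAL_MIN_DEPTH = 20.0


@dataclass(frozen=True)
class SampleQC:
    chimeric_read_fraction: float
    clipped_base_fraction: float
    mean_read_length: float
    mean_base_quality: float
    coverage: float

    def as_dict(self) -> dict:
        return {
            "chimeric_read_fraction": self.chimeric_read_fraction,
            "clipped_base_fraction": self.clipped_base_fraction,
            "mean_read_length": self.mean_read_length,
            "mean_base_quality": self.mean_base_quality,
            "coverage": self.coverage,
        }


@dataclass(frozen=True)
class ClipEvidence:
    read_id: str
    chrom: str
    breakpoint: int          # 0-based reference coordinate of the clip
    side: str                # 'left' | 'right'
    clipped_seq: str
    reconstructed_from_supplementary: bool = False


@dataclass(frozen=True)
class DiscordantEvidence:
    read_id: str
    chrom: str
    position: int
    strand: str
    mate_class: str          # 'consensus-L1' | L1-copy id | 'other'


class EmptyInputError(ValueError):
    pass


def _passes_read_filters(rec: pysam.AlignedSegment) -> bool:
    """The read-level exclusion applied before any QC metric."""
    if not rec.is_paired:
        return False
    if rec.is_duplicate:
        return False
    if rec.mapping_quality == 0:
        return False
    seq = rec.query_sequence
    qual = rec.query_qualities
    if seq is None or qual is None or len(seq) != len(qual):
        return False
    return True


def iter_records(source) -> Iterable[pysam.AlignedSegment]:
    """Accept a path to SAM/BAM, an open AlignmentFile, or an iterable."""
    if isinstance(source, (str, Path)):
        with pysam.AlignmentFile(str(source), check_sq=False) as fh:
            yield from fh
    else:
        yield from source


def _is_chimeric(rec: pysam.AlignedSegment) -> bool:
    if rec.is_unmapped or rec.mate_is_unmapped:
        return False
    if rec.reference_name != rec.next_reference_name:
        return True
    if rec.is_reverse == rec.mate_is_reverse:
        return True   # same-strand mates
    if abs(rec.template_length) > MAX_INSERT:
        return True
    # outward-facing: reverse read upstream of its forward mate
    if not rec.is_reverse and rec.mate_is_reverse:
        if rec.next_reference_start < rec.reference_start:
            return True
    if rec.is_reverse and not rec.mate_is_reverse:
        if rec.reference_start < rec.next_reference_start:
            return True
    return False


def _clip_lengths(rec: pysam.AlignedSegment) -> tuple[int, int]:
    cig = rec.cigartuples or []
    left = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
    right = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
    return left, right


def compute_sample_qc(records, genome_length: float) -> SampleQC:
    """Five per-sample metrics over filtered primary reads.

    Coverage is filtered aligned bases divided by ``genome_length`` (the
    denominator of the source metric is not pinned down; this choice is
    reported in output metadata).
    """
    n_reads = 0
    n_chimeric = 0
    clip_bases = 0
    read_bases = 0
    qual_sum = 0.0
    aligned_bases = 0
    counts = {"unpaired": 0, "duplicate": 0, "mapq0": 0, "inconsistent": 0}
    for rec in iter_records(records):
        if rec.is_supplementary or rec.is_secondary:
            continue
        if not rec.is_paired:
            counts["unpaired"] += 1
            continue
        if rec.is_duplicate:
            counts["duplicate"] += 1
            continue
        if rec.mapping_quality == 0 and not rec.is_unmapped:
            counts["mapq0"] += 1
            continue
        seq, qual = rec.query_sequence, rec.query_qualities
        if seq is None or qual is None or len(seq) != len(qual):
            counts["inconsistent"] += 1
            continue
        n_reads += 1
        rl = len(seq)
        read_bases += rl
        qual_sum += float(sum(qual)) / rl
        if not rec.is_unmapped:
            left, right = _clip_lengths(rec)
            clip_bases += left + right
            aligned_bases += rl - left - right
            if _is_chimeric(rec):
                n_chimeric += 1
    if n_reads == 0:
        consumed = max(counts, key=counts.get)
        raise EmptyInputError(
            f"no reads left after filtering (largest filter: {consumed}, "
            f"counts={counts})"
        )
    return SampleQC(
        chimeric_read_fraction=n_chimeric / n_reads,
        clipped_base_fraction=clip_bases / read_bases,
        mean_read_length=read_bases / n_reads,
        mean_base_quality=qual_sum / n_reads,
        coverage=aligned_bases / genome_length,
    )


def filter_sample_pairs(
    pairs: Sequence[tuple[SampleQC, SampleQC]],
    chimeric_max: float = CHIMERIC_MAX,
    tumor_min_depth: float = TUMOR_MIN_DEPTH,
    normal_min_depth: float = NORMAL_MIN_DEPTH,
) -> list[dict]:
    """Apply the pair-level exclusion thresholds.

    A pair is dropped when tumor or normal chimeric fraction exceeds
    ``chimeric_max``, tumor depth falls below ``tumor_min_depth``, or normal
    depth falls below ``normal_min_depth``.  All violated reasons are listed.
    """
    out = []
    for i, pair in enumerate(pairs):
        if pair is None or len(pair) != 2 or any(p is None for p in pair):
            raise ValueError(f"pair {i}: both tumor and normal QC must be present")
        tumor, normal = pair
        reasons = []
        if tumor.chimeric_read_fraction > chimeric_max:
            reasons.append("chimeric_tumor")
        if normal.chimeric_read_fraction > chimeric_max:
            reasons.append("chimeric_normal")
        if tumor.coverage < tumor_min_depth:
            reasons.append("tumor_depth")
        if normal.coverage < normal_min_depth:
            reasons.append("normal_depth")
        out.append({"index": i, "kept": not reasons, "reasons": reasons})
    return out


def extract_clips(records, min_clip: int = 20) -> list[ClipEvidence]:
    """Clip evidence from soft-clipped primaries and hard-clipped supplementaries.

    For a hard-clipped supplementary, the clipped portion of the *aligned*
    span is absent from the record itself; the full read sequence is taken
    from the matching primary (same read name and first/second-of-pair flag)
    and the clipped tail of the primary is reported with
    ``reconstructed_from_supplementary=True``, breakpointed at the
    supplementary's genomic position.  Supplementaries without a primary in
    the input are skipped with a warning.
    """
    primaries: dict[tuple[str, bool], pysam.AlignedSegment] = {}
    supplementaries: list[pysam.AlignedSegment] = []
    emitted: set[tuple[str, bool, str]] = set()
    out: list[ClipEvidence] = []
    for rec in iter_records(records):
        if rec.is_unmapped or rec.is_duplicate or rec.is_secondary:
            continue
        if rec.is_supplementary:
            supplementaries.append(rec)
            continue
        if rec.mapping_quality == 0:
            continue
        primaries[(rec.query_name, rec.is_read1)] = rec
        seq = rec.query_sequence
        if seq is None:
            continue
        left, right = _soft_clips(rec)
        if left >= min_clip:
            emitted.add((rec.query_name, rec.is_read1, "left"))
            out.append(
                ClipEvidence(
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    "left",
                    seq[:left],
                )
            )
        if right >= min_clip:
            emitted.add((rec.query_name, rec.is_read1, "right"))
            out.append(
                ClipEvidence(
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_end,
                    "right",
                    seq[len(seq) - right :],
                )
            )
    for rec in supplementaries:
        cig = rec.cigartuples or []
        has_hard = any(op == 5 for op, _ in cig)
        if not has_hard:
            continue
        key = (rec.query_name, rec.is_read1)
        primary = primaries.get(key)
        if primary is None or primary.query_sequence is None:
            warnings.warn(
                f"supplementary {rec.query_name} has no primary in input; skipped"
            )
            continue
        # The supplementary's aligned span is the primary's clipped tail; the
        # reconstructed sequence is that tail, read off the primary record.
        pleft, pright = _soft_clips(primary)
        pseq = primary.query_sequence
        for side, clip_len in (("left", pleft), ("right", pright)):
            if clip_len < min_clip:
                continue
            if (rec.query_name, rec.is_read1, side) in emitted:
                continue  # primary soft clip already described this junction
            seq = pseq[:clip_len] if side == "left" else pseq[len(pseq) - clip_len :]
            bp = primary.reference_start if side == "left" else primary.reference_end
            out.append(
                ClipEvidence(
                    rec.query_name,
                    primary.reference_name,
                    bp,
                    side,
                    seq,
                    reconstructed_from_supplementary=True,
                )
            )
    return out


def _soft_clips(rec: pysam.AlignedSegment) -> tuple[int, int]:
    cig = rec.cigartuples or []
    left = cig[0][1] if cig and cig[0][0] == 4 else 0
    right = cig[-1][1] if cig and cig[-1][0] == 4 else 0
    return left, right


@dataclass(frozen=True)
class L1Interval:
    id: str
    chrom: str
    start: int
    end: int


def load_l1_annotation(path: str | Path) -> list[L1Interval]:
    """BED of genomic L1 copies: chrom, start, end[, name]."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed L1 annotation at line {lineno}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"malformed L1 annotation at line {lineno}: {line!r}"
                ) from exc
            name = parts[3] if len(parts) > 3 else f"L1_{lineno}"
            out.append(L1Interval(name, parts[0], start, end))
    return out


def extract_discordant(
    records,
    l1_intervals: Sequence[L1Interval],
    consensus_contigs: Sequence[str] = (),
) -> list[DiscordantEvidence]:
    """Anchors of non-proper pairs whose mate maps into annotated L1 sequence
    or onto a transposon consensus contig."""
    by_chrom: dict[str, list[L1Interval]] = {}
    for iv in l1_intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    consensus_contigs = set(consensus_contigs)
    out = []
    for rec in iter_records(records):
        if rec.is_unmapped or rec.is_supplementary or rec.is_secondary:
            continue
        if rec.is_duplicate or rec.mapping_quality == 0:
            continue
        if rec.is_proper_pair or rec.mate_is_unmapped:
            continue
        mate_chrom = rec.next_reference_name
        mate_pos = rec.next_reference_start
        mate_class = None
        if mate_chrom in consensus_contigs:
            mate_class = "consensus-L1"
        else:
            for iv in by_chrom.get(mate_chrom, ()):
                if iv.start <= mate_pos < iv.end:
                    mate_class = iv.id
                    break
        if mate_class is None:
            continue
        # skip anchors that are themselves inside annotated L1 sequence
        inside = any(
            iv.start <= rec.reference_start < iv.end
            for iv in by_chrom.get(rec.reference_name, ())
        )
        if inside:
            continue
        out.append(
            DiscordantEvidence(
                rec.query_name,
                rec.reference_name,
                rec.reference_start,
                "-" if rec.is_reverse else "+",
                mate_class,
            )
        )
    return out
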