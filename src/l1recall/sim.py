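"""Synthetic L1 insertion simulator with oracle alignments.

Generates random genomes with embedded full-length L1 source copies, applies
mechanistically faithful insertion haplotypes (5' truncation, target-site
duplication, twin-priming inversion, 3' transduction, poly(A) tail), simulates
paired-end reads, and emits the alignments a correct local aligner would
produce against the unmodified reference.  Because read provenance is known
exactly, the emitted SAM is an oracle: junction-spanning reads are soft-clipped
at the true breakpoint and insertion-interior reads are placed on a genomic L1
source copy, so the caller can be benchmarked without any external aligner.

Coordinates are 0-based half-open internally; SAM output is produced through
pysam which handles the 1-based dialect.
"""

from __future__ import annotations

import gzip
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")

# Phred 30 constant base quality (spec'd: no quality model by default).
DEFAULT_QUAL_CHAR = chr(30 + 33)


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase ACGTN string."""
    return seq.translate(_COMP)[::-1]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class L1Consensus:
    """The transposon consensus sequence clipped tails are realigned against.

    An intact element is about 6 kb; anything at least 1 kb is accepted so
    tests can run on shorter synthetic consensi.
    """

    id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1000:
            raise ValueError("consensus must be at least 1000 nt")
        if set(seq) - set("ACGT"):
            raise ValueError("consensus must contain only ACGT")

    @property
    def length(self) -> int:
        return len(self.sequence)


def random_consensus(length: int = 6000, seed: int = 0, id: str = "L1_consensus") -> L1Consensus:
    """A synthetic stand-in consensus (random ACGT) for self-contained tests."""
    rng = np.random.default_rng(seed)
    return L1Consensus(id=id, sequence=random_sequence(length, rng))


@dataclass(frozen=True)
class SourceLocus:
    """A genomic full-length L1 copy that can donate 3' transductions."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    downstream_unique_flank: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if len(self.downstream_unique_flank) < 200:
            raise ValueError("downstream flank must be >= 200 nt")


@dataclass(frozen=True)
class InsertionSpec:
    """Parameters of one simulated insertion (the Fig.-style mechanism).

    ``inserted_len`` is the length of the 3'-anchored consensus segment; a
    value below the consensus length models 5' truncation.  When
    ``inversion_junction`` is set (a consensus coordinate strictly inside the
    inserted interval) the 5'-ward fragment is inverted relative to the
    3'-ward fragment, modelling twin priming.  A transduction appends unique
    sequence from downstream of a source locus between the L1 3' end and the
    poly(A) tail.
    """

    target_chrom: str
    target_pos: int
    tsd_len: int
    strand: str
    inserted_len: int
    polyA_len: int = 12
    inversion_junction: int | None = None
    transduction_source: str | None = None
    transduction_len: int = 0

    def validate(self, consensus: L1Consensus) -> None:
        if self.tsd_len < 0 or self.polyA_len < 0:
            raise ValueError("tsd_len and polyA_len must be >= 0")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if not 1 <= self.inserted_len <= consensus.length:
            raise ValueError("inserted_len must be in [1, consensus length]")
        if self.inversion_junction is not None:
            lo = consensus.length - self.inserted_len
            if not lo < self.inversion_junction < consensus.length:
                raise ValueError(
                    "inversion_junction must lie strictly inside the inserted interval"
                )
        if (self.transduction_len > 0) != (self.transduction_source is not None):
            raise ValueError("transduction_len > 0 iff transduction_source present")


@dataclass(frozen=True)
class InsertionTruth:
    """Ground truth for one realized insertion, for benchmarking the caller."""

    insertion_id: str
    spec: InsertionSpec
    left_bp: int        # reference coordinate of the leftmost target-site base
    right_bp: int       # left_bp + tsd_len: where right-clip evidence accumulates
    hap_left: int       # haplotype coordinate where the cassette begins
    hap_right: int      # haplotype coordinate where reference sequence resumes
    inserted_seq: str   # full cassette (strand-appropriate orientation)

    @property
    def is_inversion(self) -> bool:
        return self.spec.inversion_junction is not None


@dataclass(frozen=True)
class ReadSimParams:
    read_len: int = 150
    frag_mean: float = 500.0
    frag_sd: float = 60.0
    coverage: float = 30.0
    base_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.read_len < 100:
            raise ValueError("read_len must be >= 100")
        if self.frag_mean <= 2 * self.read_len:
            raise ValueError("frag_mean must exceed 2 x read_len")


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------


class PlacementError(ValueError):
    pass


def build_reference(
    genome_len: int,
    n_sources: int,
    consensus: L1Consensus,
    seed: int,
    chrom: str = "chr1",
    flank_len: int = 300,
    margin: int = 2000,
) -> tuple[str, list[SourceLocus]]:
    """Random genome with ``n_sources`` embedded full-length consensus copies.

    Copies are written over the random background at non-overlapping
    positions (plus-strand), each followed by ``flank_len`` nt of the unique
    random background recorded as its downstream flank.  Deterministic given
    ``seed``.
    """
    if genome_len < 100_000:
        raise ValueError("genome_len must be >= 100 kb")
    if n_sources < 0:
        raise ValueError("n_sources must be >= 0")
    rng = np.random.default_rng(seed)
    genome = list(random_sequence(genome_len, rng))
    clen = consensus.length
    need = clen + flank_len
    lo, hi = margin, genome_len - margin - need
    if n_sources and hi <= lo:
        raise PlacementError("genome too short to place source copies")
    placed: list[int] = []
    for _ in range(n_sources):
        for _attempt in range(1000):
            pos = int(rng.integers(lo, hi))
            if all(abs(pos - p) >= need + flank_len for p in placed):
                placed.append(pos)
                break
        else:
            raise PlacementError("could not place source copies without overlap")
    placed.sort()
    sources = []
    for i, pos in enumerate(placed):
        genome[pos : pos + clen] = consensus.sequence
        flank = "".join(genome[pos + clen : pos + clen + flank_len])
        sources.append(
            SourceLocus(
                id=f"S{i}",
                chrom=chrom,
                start=pos,
                end=pos + clen,
                strand="+",
                downstream_unique_flank=flank,
            )
        )
    return "".join(genome), sources


# ---------------------------------------------------------------------------
# Cassette construction and haplotype application
# ---------------------------------------------------------------------------

# Cassette part kinds: L1 (consensus-derived), TD (transduced reference
# sequence downstream of a source), PA (poly(A)/poly(T) tract).


@dataclass(frozen=True)
class CassettePart:
    kind: str           # 'L1' | 'TD' | 'PA'
    length: int
    c_lo: int = 0       # L1: consensus interval; TD: reference interval
    c_hi: int = 0
    orient: int = 1     # +1: haplotype-forward follows consensus/reference-forward
    source_id: str | None = None


def build_cassette(
    spec: InsertionSpec, consensus: L1Consensus, sources: Sequence[SourceLocus]
) -> tuple[str, list[CassettePart]]:
    """The inserted sequence plus a piecewise map of where each base came from.

    In sense orientation the cassette is
    ``[inverted 5' fragment?][3'-anchored L1][transduction?][poly(A)]``;
    on the minus strand the whole cassette is reverse complemented so the
    reference top strand shows poly(T) 5'-ward.
    """
    spec.validate(consensus)
    L = consensus.length
    a = L - spec.inserted_len
    parts: list[tuple[str, str, CassettePart]] = []
    if spec.inversion_junction is not None:
        j = spec.inversion_junction
        parts.append(
            ("L1", revcomp(consensus.sequence[a:j]), CassettePart("L1", j - a, a, j, -1))
        )
        parts.append(("L1", consensus.sequence[j:L], CassettePart("L1", L - j, j, L, 1)))
    else:
        parts.append(("L1", consensus.sequence[a:L], CassettePart("L1", L - a, a, L, 1)))
    if spec.transduction_source is not None:
        src = next(s for s in sources if s.id == spec.transduction_source)
        if spec.transduction_len > len(src.downstream_unique_flank):
            raise ValueError("transduction_len exceeds recorded source flank")
        seq = src.downstream_unique_flank[: spec.transduction_len]
        parts.append(
            (
                "TD",
                seq,
                CassettePart(
                    "TD", len(seq), src.end, src.end + len(seq), 1, source_id=src.id
                ),
            )
        )
    if spec.polyA_len:
        parts.append(("PA", "A" * spec.polyA_len, CassettePart("PA", spec.polyA_len)))
    if spec.strand == "-":
        parts = [
            (kind, revcomp(seq), replace(meta, orient=-meta.orient))
            for kind, seq, meta in reversed(parts)
        ]
    seq = "".join(p[1] for p in parts)
    return seq, [p[2] for p in parts]


# Haplotype run kinds: REF plus the cassette part kinds above.


@dataclass(frozen=True)
class HapRun:
    hap_lo: int
    hap_hi: int
    kind: str                 # 'REF' | 'L1' | 'TD' | 'PA'
    ref_lo: int = 0           # REF/TD: reference coordinate of hap_lo (orient +1)
    c_lo: int = 0             # L1: consensus interval
    c_hi: int = 0
    orient: int = 1
    insertion_id: str | None = None
    source_id: str | None = None


@dataclass
class Haplotype:
    name: str
    seq: str
    chrom: str
    runs: list[HapRun]
    _starts: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self):
        self._starts = [r.hap_lo for r in self.runs]

    def decompose(self, s: int, e: int) -> list[HapRun]:
        """Sub-runs covering haplotype interval [s, e)."""
        out = []
        i = max(0, bisect_right(self._starts, s) - 1)
        while i < len(self.runs) and self.runs[i].hap_lo < e:
            r = self.runs[i]
            lo, hi = max(s, r.hap_lo), min(e, r.hap_hi)
            if lo < hi:
                out.append(_slice_run(r, lo, hi))
            i += 1
        return out


def _slice_run(r: HapRun, lo: int, hi: int) -> HapRun:
    off_lo, off_hi = lo - r.hap_lo, hi - r.hap_lo
    if r.kind == "REF":
        return replace(r, hap_lo=lo, hap_hi=hi, ref_lo=r.ref_lo + off_lo)
    if r.kind == "L1":
        if r.orient == 1:
            c_lo, c_hi = r.c_lo + off_lo, r.c_lo + off_hi
        else:
            c_lo, c_hi = r.c_hi - off_hi, r.c_hi - off_lo
        return replace(r, hap_lo=lo, hap_hi=hi, c_lo=c_lo, c_hi=c_hi)
    if r.kind == "TD":
        if r.orient == 1:
            ref_lo = r.ref_lo + off_lo
        else:
            ref_lo = r.ref_lo + (r.hap_hi - hi)
        return replace(r, hap_lo=lo, hap_hi=hi, ref_lo=ref_lo)
    return replace(r, hap_lo=lo, hap_hi=hi)


def reference_haplotype(genome: str, name: str = "ref", chrom: str = "chr1") -> Haplotype:
    return Haplotype(name, genome, chrom, [HapRun(0, len(genome), "REF", ref_lo=0)])


def apply_insertions(
    genome: str,
    specs: Sequence[InsertionSpec],
    consensus: L1Consensus,
    sources: Sequence[SourceLocus],
    name: str = "hap",
    chrom: str = "chr1",
    id_prefix: str = "ins",
) -> tuple[Haplotype, list[InsertionTruth]]:
    """Apply several insertions to one genome, left to right.

    Target positions must be strictly increasing and may not fall inside a
    source locus.  The modified haplotype carries, around each insertion,
    ``[target site][cassette][target site duplicate]``.
    """
    specs = sorted(specs, key=lambda s: s.target_pos)
    for prev, nxt in zip(specs, specs[1:]):
        if nxt.target_pos <= prev.target_pos + prev.tsd_len:
            raise ValueError("insertion target sites overlap")
    for s in specs:
        for src in sources:
            if src.start <= s.target_pos < src.end:
                raise ValueError(f"target_pos {s.target_pos} inside source {src.id}")
    pieces: list[str] = []
    runs: list[HapRun] = []
    truths: list[InsertionTruth] = []
    cursor = 0        # reference coordinate up to which we have copied
    hap_pos = 0
    for i, spec in enumerate(specs):
        ins_id = f"{id_prefix}{i}"
        tsd_end = spec.target_pos + spec.tsd_len
        ref_piece = genome[cursor:tsd_end]
        if ref_piece:
            pieces.append(ref_piece)
            runs.append(HapRun(hap_pos, hap_pos + len(ref_piece), "REF", ref_lo=cursor))
            hap_pos += len(ref_piece)
        cassette, parts = build_cassette(spec, consensus, sources)
        hap_left = hap_pos
        for p in parts:
            runs.append(
                HapRun(
                    hap_pos,
                    hap_pos + p.length,
                    p.kind,
                    ref_lo=p.c_lo if p.kind == "TD" else 0,
                    c_lo=p.c_lo,
                    c_hi=p.c_hi,
                    orient=p.orient,
                    insertion_id=ins_id,
                    source_id=p.source_id,
                )
            )
            hap_pos += p.length
        pieces.append(cassette)
        truths.append(
            InsertionTruth(
                insertion_id=ins_id,
                spec=spec,
                left_bp=spec.target_pos,
                right_bp=tsd_end,
                hap_left=hap_left,
                hap_right=hap_pos,
                inserted_seq=cassette,
            )
        )
        cursor = spec.target_pos   # re-copy the target site: duplication
    tail = genome[cursor:]
    pieces.append(tail)
    runs.append(HapRun(hap_pos, hap_pos + len(tail), "REF", ref_lo=cursor))
    return Haplotype(name, "".join(pieces), chrom, runs), truths


def apply_insertion(
    genome: str,
    spec: InsertionSpec,
    consensus: L1Consensus,
    sources: Sequence[SourceLocus] = (),
    name: str = "hap",
    chrom: str = "chr1",
) -> tuple[Haplotype, InsertionTruth]:
    hap, truths = apply_insertions(genome, [spec], consensus, sources, name, chrom)
    return hap, truths[0]


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimRead:
    """One simulated read: interval on its haplotype plus observed sequence."""

    hap_name: str
    start: int
    end: int
    hap_forward: bool   # True for R1 (sequenced left-to-right on the haplotype)
    seq: str            # observed sequence in original read orientation


@dataclass(frozen=True)
class SimFragment:
    name: str
    hap_name: str
    start: int
    end: int
    r1: SimRead
    r2: SimRead


def simulate_reads(
    haplotypes: Sequence[Haplotype], params: ReadSimParams
) -> list[SimFragment]:
    """Paired-end fragments: uniform starts, truncated-normal lengths, FR mates.

    Substitution errors are applied at ``base_error_rate`` per base.
    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    rl = params.read_len
    frags: list[SimFragment] = []
    for hap in haplotypes:
        n = len(hap.seq)
        if n < params.frag_mean + 4 * params.frag_sd:
            raise ValueError(f"haplotype {hap.name} shorter than frag_mean + 4*frag_sd")
        n_frag = int(round(params.coverage * n / (2 * rl)))
        lens = rng.normal(params.frag_mean, params.frag_sd, size=n_frag)
        lens = np.clip(np.rint(lens), 2 * rl, n).astype(int)
        starts = rng.integers(0, n - lens + 1)
        for i in range(n_frag):
            s, fl = int(starts[i]), int(lens[i])
            e = s + fl
            r1_seq = hap.seq[s : s + rl]
            r2_seq = revcomp(hap.seq[e - rl : e])
            if params.base_error_rate > 0:
                r1_seq = _mutate(r1_seq, params.base_error_rate, rng)
                r2_seq = _mutate(r2_seq, params.base_error_rate, rng)
            name = f"{hap.name}_frag{i:07d}"
            frags.append(
                SimFragment(
                    name,
                    hap.name,
                    s,
                    e,
                    SimRead(hap.name, s, s + rl, True, r1_seq),
                    SimRead(hap.name, e - rl, e, False, r2_seq),
                )
            )
    return frags


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    n = len(seq)
    hits = np.flatnonzero(rng.random(n) < rate)
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def write_fastq(frags: Sequence[SimFragment], prefix: str | Path) -> tuple[Path, Path]:
    """Untested glue for handing reads to an external aligner."""
    prefix = Path(prefix)
    p1, p2 = Path(f"{prefix}_R1.fastq.gz"), Path(f"{prefix}_R2.fastq.gz")
    with gzip.open(p1, "wt") as f1, gzip.open(p2, "wt") as f2:
        for fr in frags:
            q = DEFAULT_QUAL_CHAR * len(fr.r1.seq)
            f1.write(f"@{fr.name}/1\n{fr.r1.seq}\n+\n{q}\n")
            q = DEFAULT_QUAL_CHAR * len(fr.r2.seq)
            f2.write(f"@{fr.name}/2\n{fr.r2.seq}\n+\n{q}\n")
    return p1, p2


# ---------------------------------------------------------------------------
# Oracle alignment
# ---------------------------------------------------------------------------

MIN_ANCHOR = 20      # shortest reference run accepted as a primary anchor
MIN_INTERIOR = 30    # shortest L1/TD run placed when a read is cassette-interior
SUPPL_MIN = 30       # shortest clipped L1 tail that earns a supplementary record


@dataclass
class _Placement:
    mapped: bool
    ref_start: int = 0
    left_clip: int = 0
    right_clip: int = 0
    map_orient: int = 1      # haplotype-forward relative to reference-forward
    aligned_len: int = 0
    kind: str = "REF"        # 'REF' | 'L1' | 'TD' (placement provenance)
    suppl: tuple | None = None   # (ref_start, c_len, map_orient, left_hard, right_hard)


def _place_read(
    read: SimRead, hap: Haplotype, sources: Sequence[SourceLocus]
) -> _Placement:
    runs = hap.decompose(read.start, read.end)
    ref_runs = [r for r in runs if r.kind == "REF"]
    if ref_runs:
        best = max(ref_runs, key=lambda r: r.hap_hi - r.hap_lo)
        if best.hap_hi - best.hap_lo >= MIN_ANCHOR:
            pl = _Placement(
                True,
                ref_start=best.ref_lo,
                left_clip=best.hap_lo - read.start,
                right_clip=read.end - best.hap_hi,
                map_orient=1,
                aligned_len=best.hap_hi - best.hap_lo,
            )
            pl.suppl = _supplementary_for(read, runs, best, sources)
            return pl
    # cassette-interior (or too short an anchor): try L1 then transduction runs
    l1_runs = [r for r in runs if r.kind == "L1"]
    td_runs = [r for r in runs if r.kind == "TD"]
    if l1_runs and sources:
        best = max(l1_runs, key=lambda r: r.hap_hi - r.hap_lo)
        if best.hap_hi - best.hap_lo >= MIN_INTERIOR:
            src = sources[0]
            lc, rc = best.hap_lo - read.start, read.end - best.hap_hi
            if best.orient == -1:
                lc, rc = rc, lc
            return _Placement(
                True,
                ref_start=src.start + best.c_lo,
                left_clip=lc,
                right_clip=rc,
                map_orient=best.orient,
                aligned_len=best.hap_hi - best.hap_lo,
                kind="L1",
            )
    if td_runs:
        best = max(td_runs, key=lambda r: r.hap_hi - r.hap_lo)
        if best.hap_hi - best.hap_lo >= MIN_INTERIOR:
            lc, rc = best.hap_lo - read.start, read.end - best.hap_hi
            if best.orient == -1:
                lc, rc = rc, lc
            return _Placement(
                True,
                ref_start=best.ref_lo,
                left_clip=lc,
                right_clip=rc,
                map_orient=best.orient,
                aligned_len=best.hap_hi - best.hap_lo,
                kind="TD",
            )
    return _Placement(False)


def _supplementary_for(
    read: SimRead, runs: list[HapRun], primary: HapRun, sources: Sequence[SourceLocus]
) -> tuple | None:
    """Hard-clipped supplementary placement for a clipped L1 tail, if long enough."""
    if not sources:
        return None
    l1_runs = [
        r
        for r in runs
        if r.kind == "L1"
        and r.hap_hi - r.hap_lo >= SUPPL_MIN
        and (r.hap_hi <= primary.hap_lo or r.hap_lo >= primary.hap_hi)
    ]
    if not l1_runs:
        return None
    r = max(l1_runs, key=lambda x: x.hap_hi - x.hap_lo)
    src = sources[0]
    lh, rh = r.hap_lo - read.start, read.end - r.hap_hi
    if r.orient == -1:
        lh, rh = rh, lh
    return (src.start + r.c_lo, r.hap_hi - r.hap_lo, r.orient, lh, rh)


def oracle_align(
    frags: Sequence[SimFragment],
    haplotypes: Sequence[Haplotype],
    genome_len: int,
    sources: Sequence[SourceLocus],
    out_sam: str | Path,
    chrom: str = "chr1",
    sample: str = "sample",
    emit_supplementary: bool = True,
) -> Path:
    """Write oracle alignments for simulated fragments to a SAM file.

    Reads fully inside reference sequence map unclipped; junction-spanning
    reads map soft-clipped at the true breakpoint; cassette-interior reads map
    to a genomic source copy (for L1-derived bases) or to the transduced
    reference interval, and poly(A)-only reads are emitted unmapped with a
    mapped mate.  Pairs in which either mate is clipped, non-reference-placed
    or unmapped are flagged not-proper (discordant).
    """
    haps = {h.name: h for h in haplotypes}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": chrom, "LN": genome_len}],
            "RG": [{"ID": sample, "SM": sample}],
        }
    )
    out_sam = Path(out_sam)
    with pysam.AlignmentFile(out_sam, "w", header=header) as fh:
        for frag in frags:
            hap = haps[frag.hap_name]
            p1 = _place_read(frag.r1, hap, sources)
            p2 = _place_read(frag.r2, hap, sources)
            proper = _is_proper(p1, p2)
            a1 = _to_record(frag.name, frag.r1, p1, p2, True, proper, header, chrom)
            a2 = _to_record(frag.name, frag.r2, p2, p1, False, proper, header, chrom)
            _set_tlen(a1, a2)
            fh.write(a1)
            fh.write(a2)
            if emit_supplementary:
                for read, pl, mate in ((frag.r1, p1, p2), (frag.r2, p2, p1)):
                    if pl.suppl is not None:
                        fh.write(
                            _suppl_record(
                                frag.name, read, pl, mate,
                                read is frag.r1, header, chrom,
                            )
                        )
    return out_sam


def _is_proper(p1: _Placement, p2: _Placement) -> bool:
    for p in (p1, p2):
        if not p.mapped or p.left_clip or p.right_clip or p.map_orient != 1:
            return False
        if p.kind != "REF":
            return False   # a mate placed inside L1/transduced sequence is discordant
    lo = min(p1.ref_start, p2.ref_start)
    hi = max(p1.ref_start + p1.aligned_len, p2.ref_start + p2.aligned_len)
    return 0 < hi - lo <= 100_000


def _stored_seq(read: SimRead, pl: _Placement) -> str:
    # SAM stores the sequence in reference orientation.
    hap_fwd = read.seq if read.hap_forward else revcomp(read.seq)
    return hap_fwd if pl.map_orient == 1 else revcomp(hap_fwd)


def _is_reverse(read: SimRead, pl: _Placement) -> bool:
    r_hap = 1 if read.hap_forward else -1
    return r_hap * pl.map_orient == -1


def _to_record(
    name: str,
    read: SimRead,
    pl: _Placement,
    mate: _Placement,
    is_read1: bool,
    proper: bool,
    header: pysam.AlignmentHeader,
    chrom: str,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.is_paired = True
    a.is_read1 = is_read1
    a.is_read2 = not is_read1
    rl = len(read.seq)
    if pl.mapped:
        a.reference_name = chrom
        a.reference_start = pl.ref_start
        a.mapping_quality = 60
        a.is_reverse = _is_reverse(read, pl)
        a.query_sequence = _stored_seq(read, pl)
        cig = []
        if pl.left_clip:
            cig.append((4, pl.left_clip))
        cig.append((0, pl.aligned_len))
        if pl.right_clip:
            cig.append((4, pl.right_clip))
        a.cigartuples = cig
        a.is_proper_pair = proper
    else:
        a.is_unmapped = True
        a.query_sequence = read.seq
        a.mapping_quality = 0
        if mate.mapped:
            a.reference_name = chrom
            a.reference_start = mate.ref_start
    a.query_qualities = pysam.qualitystring_to_array(DEFAULT_QUAL_CHAR * rl)
    if mate.mapped:
        a.next_reference_name = chrom
        a.next_reference_start = mate.ref_start
        a.mate_is_reverse = _is_reverse_mate(mate)
    else:
        a.mate_is_unmapped = True
        if pl.mapped:
            a.next_reference_name = chrom
            a.next_reference_start = pl.ref_start
    return a


def _is_reverse_mate(mate: _Placement) -> bool:
    # mate orientation is recomputed from its own placement by the caller of
    # _to_record; here we only know map_orient, so reconstruct via the same rule
    # using the stored flag on the mate record when both are written.  For flag
    # purposes the mate's reverse bit equals (mate is R2) XOR (map_orient == -1)
    # which we cannot see; callers overwrite it via _set_tlen.
    return False


def _set_tlen(a1: pysam.AlignedSegment, a2: pysam.AlignedSegment) -> None:
    a1.mate_is_reverse = a2.is_reverse
    a2.mate_is_reverse = a1.is_reverse
    a1.mate_is_unmapped = a2.is_unmapped
    a2.mate_is_unmapped = a1.is_unmapped
    if a1.is_unmapped or a2.is_unmapped:
        a1.template_length = 0
        a2.template_length = 0
        return
    lo = min(a1.reference_start, a2.reference_start)
    hi = max(a1.reference_end, a2.reference_end)
    tlen = hi - lo
    if a1.reference_start <= a2.reference_start:
        a1.template_length, a2.template_length = tlen, -tlen
    else:
        a1.template_length, a2.template_length = -tlen, tlen


def _suppl_record(
    name: str,
    read: SimRead,
    pl: _Placement,
    mate: _Placement,
    is_read1: bool,
    header: pysam.AlignmentHeader,
    chrom: str,
) -> pysam.AlignedSegment:
    ref_start, c_len, orient, lh, rh = pl.suppl
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.is_paired = True
    a.is_read1 = is_read1
    a.is_read2 = not is_read1
    a.is_supplementary = True
    a.reference_name = chrom
    a.reference_start = ref_start
    a.mapping_quality = 60
    r_hap = 1 if read.hap_forward else -1
    a.is_reverse = r_hap * orient == -1
    hap_fwd = read.seq if read.hap_forward else revcomp(read.seq)
    seg = hap_fwd if orient == 1 else revcomp(hap_fwd)
    # hard clips: only the aligned span is stored
    a.query_sequence = seg[lh : lh + c_len]
    a.query_qualities = pysam.qualitystring_to_array(DEFAULT_QUAL_CHAR * c_len)
    cig = []
    if lh:
        cig.append((5, lh))
    cig.append((0, c_len))
    if rh:
        cig.append((5, rh))
    a.cigartuples = cig
    if mate.mapped:
        a.next_reference_name = chrom
        a.next_reference_start = mate.ref_start
    return a


# ---------------------------------------------------------------------------
# Truth table and random event generation
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "chrom",
    "start",
    "end",
    "class",
    "inserted_len",
    "tsd_len",
    "inversion_junction",
    "source_id",
    "transduction_len",
]


def write_truth_table(truths: Iterable[InsertionTruth], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            cls = "inversion" if t.is_inversion else "canonical"
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        t.spec.target_chrom,
                        t.left_bp,
                        t.right_bp,
                        cls,
                        t.spec.inserted_len,
                        t.spec.tsd_len,
                        t.spec.inversion_junction
                        if t.spec.inversion_junction is not None
                        else ".",
                        t.spec.transduction_source or ".",
                        t.spec.transduction_len,
                    )
                )
                + "\n"
            )
    return path


def random_insertion_specs(
    n: int,
    genome_len: int,
    consensus: L1Consensus,
    sources: Sequence[SourceLocus],
    seed: int,
    frac_inversion: float = 0.35,
    frac_transduction: float = 0.15,
    tsd_range: tuple[int, int] = (5, 20),
    trunc_range: tuple[int, int] = (100, 6000),
    transduction_range: tuple[int, int] = (100, 250),
    polyA_range: tuple[int, int] = (10, 25),
    margin: int = 3000,
    min_spacing: int = 4000,
    chrom: str = "chr1",
) -> list[InsertionSpec]:
    """Random event mix: canonical truncations, twin-priming inversions and
    transduction-bearing insertions, at well-spaced target sites that avoid
    embedded source copies."""
    rng = np.random.default_rng(seed)
    excluded = [(s.start - margin, s.end + len(s.downstream_unique_flank) + margin) for s in sources]
    positions: list[int] = []
    attempts = 0
    while len(positions) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise PlacementError("could not place insertion targets; genome too crowded")
        pos = int(rng.integers(margin, genome_len - margin))
        if any(lo <= pos < hi for lo, hi in excluded):
            continue
        if any(abs(pos - p) < min_spacing for p in positions):
            continue
        positions.append(pos)
    positions.sort()
    L = consensus.length
    specs = []
    for pos in positions:
        u = rng.random()
        tsd = int(rng.integers(tsd_range[0], tsd_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        polyA = int(rng.integers(polyA_range[0], polyA_range[1] + 1))
        lo, hi = trunc_range
        hi = min(hi, L)
        ins_len = int(rng.integers(lo, hi + 1))
        inv = None
        src = None
        td_len = 0
        if u < frac_inversion:
            ins_len = max(ins_len, 200)  # room for a junction strictly inside
            a = L - ins_len
            inv = int(rng.integers(a + 50, L - 50))
        elif u < frac_inversion + frac_transduction and sources:
            src = sources[int(rng.integers(0, len(sources)))].id
            td_len = int(rng.integers(transduction_range[0], transduction_range[1] + 1))
        specs.append(
            InsertionSpec(
                target_chrom=chrom,
                target_pos=pos,
                tsd_len=tsd,
                strand=strand,
                inserted_len=ins_len,
                polyA_len=polyA,
                inversion_junction=inv,
                transduction_source=src,
                transduction_len=td_len,
            )
        )
    return specs


def simulate_tumor_normal(
    outdir: str | Path,
    seed: int,
    n_somatic: int = 200,
    n_germline: int = 0,
    genome_len: int = 2_000_000,
    n_sources: int = 3,
    consensus_len: int = 6000,
    coverage: float = 30.0,
    read_len: int = 150,
    error_rate: float = 0.001,
    frac_inversion: float = 0.35,
    frac_transduction: float = 0.15,
    tsd_range: tuple[int, int] = (5, 20),
    trunc_range: tuple[int, int] = (100, 6000),
    transduction_range: tuple[int, int] = (100, 250),
) -> dict:
    """Build a complete tumor/normal benchmarking dataset on disk.

    Somatic insertions go only into the tumor haplotype; germline insertions
    go into both.  Returns paths to the oracle SAMs plus the in-memory truth
    needed for evaluation (genome, sources, somatic/germline truth lists).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    consensus = random_consensus(consensus_len, seed=seed)
    genome, sources = build_reference(genome_len, n_sources, consensus, seed=seed)
    specs = random_insertion_specs(
        n_somatic + n_germline,
        genome_len,
        consensus,
        sources,
        seed=seed + 1,
        frac_inversion=frac_inversion,
        frac_transduction=frac_transduction,
        tsd_range=tsd_range,
        trunc_range=trunc_range,
        transduction_range=transduction_range,
    )
    rng = np.random.default_rng(seed + 2)
    germline_idx = set(
        rng.choice(len(specs), size=n_germline, replace=False).tolist()
    )
    somatic_specs = [s for i, s in enumerate(specs) if i not in germline_idx]
    germline_specs = [s for i, s in enumerate(specs) if i in germline_idx]
    tumor_hap, tumor_truths = apply_insertions(
        genome, specs, consensus, sources, "tumor"
    )
    if germline_specs:
        normal_hap, normal_truths = apply_insertions(
            genome, germline_specs, consensus, sources, "normal"
        )
    else:
        normal_hap, normal_truths = reference_haplotype(genome, "normal"), []
    params_t = ReadSimParams(
        read_len=read_len, coverage=coverage, base_error_rate=error_rate, seed=seed + 3
    )
    params_n = ReadSimParams(
        read_len=read_len, coverage=coverage, base_error_rate=error_rate, seed=seed + 4
    )
    frags_t = simulate_reads([tumor_hap], params_t)
    frags_n = simulate_reads([normal_hap], params_n)
    tumor_sam = oracle_align(
        frags_t, [tumor_hap], genome_len, sources, outdir / "tumor.sam"
    )
    normal_sam = oracle_align(
        frags_n, [normal_hap], genome_len, sources, outdir / "normal.sam"
    )
    germline_pos = {s.target_pos for s in germline_specs}
    somatic_truths = [t for t in tumor_truths if t.left_bp not in germline_pos]
    germline_truths = [t for t in tumor_truths if t.left_bp in germline_pos]
    return {
        "consensus": consensus,
        "genome": genome,
        "sources": sources,
        "tumor_sam": tumor_sam,
        "normal_sam": normal_sam,
        "somatic_truths": somatic_truths,
        "germline_truths": germline_truths,
        "all_truths": tumor_truths,
    }


def write_fasta(entries: dict[str, str], path: str | Path, width: int = 80) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in entries.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path
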