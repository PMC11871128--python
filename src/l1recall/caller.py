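"""Core L1 retrotransposition caller.

Clustered clipped-read evidence is realigned against the transposon consensus
to infer orientation, inserted length and inversion status; poly(A)/poly(T)
tracts and target-site duplications are read directly off the junction
geometry; 3' transductions are traced back to registered genomic source loci;
and tumor calls are classified somatic vs pseudo-germline against evidence
extracted from the matched normal.

The central mechanistic idea: the clipped tail at the junction distal to the
poly(A) samples the 5'-most consensus coordinate reached by reverse
transcription, so for a canonical insertion the inserted length is the
consensus length minus that coordinate.  Twin-priming inversions betray
themselves by clip alignments of opposite orientation at the two junctions,
in which case only the second-priming coordinate is knowable from clips and
the length is reported unresolved with a lower bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np
from Bio import Align
from scipy import stats

from .evidence import ClipEvidence, DiscordantEvidence, L1Interval
from .sim import L1Consensus, SourceLocus, revcomp

log = logging.getLogger("l1recall")

# Clip realignment scoring regime (standard local-alignment parameters for
# 20-150 nt tails; all configurable through realign_clip arguments).
MATCH = 2
MISMATCH = -2
GAP_OPEN = -4
GAP_EXTEND = -1
SCORE_FRACTION = 0.6          # threshold = SCORE_FRACTION * (MATCH * clip length)
IDENTITY_FLOOR = 0.85

MIN_CLIP = 20
POLY_MIN_LEN = 8
POLY_PURITY = 0.8
MAX_SOURCE_DISTANCE = 10_000
SOURCE_GROUP_DISTANCE = 1000
INTERSECT_WINDOW = 50


def _make_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    return a


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class ClipAlignment:
    c_start: int
    c_end: int
    orientation: str      # '+': clip as given matches consensus; '-': its revcomp
    score: float
    identity: float
    query_start: int = 0  # aligned interval on the clip (in given orientation)
    query_end: int = 0


def _alignment_details(target: str, query: str) -> tuple[float, int, int, int, int, float]:
    alns = _ALIGNER.align(target, query)
    best = alns[0]
    (t0, t1), (q0, q1) = best.coordinates[0][[0, -1]], best.coordinates[1][[0, -1]]
    matches = 0
    length = 0
    tc, qc = best.coordinates
    for i in range(tc.shape[0] - 1):
        ta, tb = tc[i], tc[i + 1]
        qa, qb = qc[i], qc[i + 1]
        if tb - ta == qb - qa and tb > ta:  # aligned block
            seg_t = target[ta:tb]
            seg_q = query[qa:qb]
            matches += sum(x == y for x, y in zip(seg_t, seg_q))
            length += tb - ta
        else:
            length += max(tb - ta, qb - qa)
    identity = matches / length if length else 0.0
    return best.score, int(t0), int(t1), int(q0), int(q1), identity


def _infix_match(query: str, target: str) -> tuple[int, int, int] | None:
    """Fast whole-query infix alignment (edit distance); None when poor."""
    k = max(2, int(len(query) * (1 - IDENTITY_FLOOR)) + 1)
    res = edlib.align(query, target, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    t0, t1 = res["locations"][0]
    return res["editDistance"], t0, t1 + 1


def realign_clip(
    clip_seq: str,
    consensus: L1Consensus,
    score_fraction: float = SCORE_FRACTION,
    identity_floor: float = IDENTITY_FLOOR,
) -> ClipAlignment | None:
    """Best local alignment of a clipped tail (both strands) to the consensus.

    Returns None when the best score falls below
    ``score_fraction * MATCH * len(clip_seq)``, when identity is below the
    floor, or when the two strands tie exactly (ambiguous orientation).

    Implementation: clips that embed fully in the consensus (the vast
    majority) are resolved by a banded whole-query edit-distance search;
    chimeric tails that fail it fall back to Smith-Waterman local alignment.
    """
    if len(clip_seq) < MIN_CLIP:
        return None   # too short to map reliably
    n = len(clip_seq)
    rc = revcomp(clip_seq)
    fwd_hit = _infix_match(clip_seq, consensus.sequence)
    rev_hit = _infix_match(rc, consensus.sequence)
    if fwd_hit or rev_hit:
        d_f = fwd_hit[0] if fwd_hit else n
        d_r = rev_hit[0] if rev_hit else n
        if d_f == d_r:
            return None   # strand-ambiguous
        dist, t0, t1 = fwd_hit if d_f < d_r else rev_hit
        orientation = "+" if d_f < d_r else "-"
        identity = (n - dist) / n
        score = MATCH * (n - dist) + MISMATCH * dist
        if identity >= identity_floor and score >= score_fraction * MATCH * n:
            return ClipAlignment(t0, t1, orientation, float(score), identity, 0, n)
        return None
    # chimeric or degraded tail: full local alignment on both strands
    fwd = _ALIGNER.score(consensus.sequence, clip_seq)
    rev = _ALIGNER.score(consensus.sequence, rc)
    threshold = score_fraction * MATCH * n
    if max(fwd, rev) < threshold:
        return None
    if fwd == rev:
        return None   # strand-ambiguous
    orientation = "+" if fwd > rev else "-"
    query = clip_seq if orientation == "+" else rc
    score, t0, t1, q0, q1, identity = _alignment_details(consensus.sequence, query)
    if identity < identity_floor:
        return None
    return ClipAlignment(t0, t1, orientation, score, identity, q0, q1)


def detect_poly_tract(
    seq: str,
    min_len: int = POLY_MIN_LEN,
    purity: float = POLY_PURITY,
    end: str = "prefix",
) -> str:
    """Detect a terminal poly(A)/poly(T) tract at the given end of ``seq``.

    Returns 'polyA', 'polyT' or 'none'.  A tract qualifies when some terminal
    window of at least ``min_len`` bases is composed of at least ``purity``
    fraction of the tract base.  Total function: never raises.
    """
    if end == "suffix":
        seq = seq[::-1]
    best = "none"
    best_len = 0
    n = len(seq)
    for base, label in (("A", "polyA"), ("T", "polyT")):
        count = 0
        longest = 0
        for i in range(n):
            if seq[i] == base:
                count += 1
            if count / (i + 1) >= purity:
                longest = i + 1
        if longest >= min_len and longest > best_len:
            best, best_len = label, longest
    return best


# ---------------------------------------------------------------------------
# Evidence clustering
# ---------------------------------------------------------------------------


@dataclass
class BreakpointCluster:
    chrom: str
    left_bp: int | None            # left-clip breakpoint (leftmost target-site base)
    right_bp: int | None           # right-clip breakpoint (left_bp + TSD length)
    left_clips: list[ClipEvidence] = field(default_factory=list)
    right_clips: list[ClipEvidence] = field(default_factory=list)
    discordants: list[DiscordantEvidence] = field(default_factory=list)
    # realignment cache filled by resolve_call: clip -> (stripped tail, aln)
    clip_alignments: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def clip_support(self) -> int:
        return len(self.left_clips) + len(self.right_clips)

    @property
    def position(self) -> int:
        """Best estimate of the leftmost target-site coordinate (0-based)."""
        if self.left_bp is not None:
            return self.left_bp
        return self.right_bp


def _group_positions(
    clips: list[ClipEvidence], window: int
) -> list[tuple[int, list[ClipEvidence]]]:
    clips = sorted(clips, key=lambda c: c.breakpoint)
    groups: list[list[ClipEvidence]] = []
    for c in clips:
        if groups and c.breakpoint - groups[-1][-1].breakpoint <= window:
            groups[-1].append(c)
        else:
            groups.append([c])
    out = []
    for g in groups:
        bps = sorted(c.breakpoint for c in g)
        out.append((int(bps[len(bps) // 2]), g))
    return out


def cluster_evidence(
    clips: Sequence[ClipEvidence],
    discordants: Sequence[DiscordantEvidence] = (),
    window: int = 50,
    max_tsd: int = 30,
    discordant_window: int = 800,
) -> list[BreakpointCluster]:
    """Merge clip evidence into per-site clusters and pair the two junctions.

    Right-clip groups sit at the duplicated target site's right edge and
    left-clip groups at its left edge, so a right-clip group is paired with
    the nearest left-clip group no more than ``max_tsd`` bp to its left
    (small negative offsets, target-site deletions, are also paired).
    Discordant anchors within ``discordant_window`` are attached as
    corroboration.
    """
    by_chrom: dict[str, dict[str, list[ClipEvidence]]] = {}
    for c in clips:
        by_chrom.setdefault(c.chrom, {"left": [], "right": []})[c.side].append(c)
    clusters: list[BreakpointCluster] = []
    for chrom, sides in sorted(by_chrom.items()):
        lefts = _group_positions(sides["left"], window)
        rights = _group_positions(sides["right"], window)
        used_left: set[int] = set()
        for rbp, rgroup in rights:
            best_i, best_d = None, None
            for i, (lbp, _group) in enumerate(lefts):
                if i in used_left:
                    continue
                d = rbp - lbp
                if -5 <= d <= max_tsd:
                    if best_d is None or abs(d) < abs(best_d):
                        best_i, best_d = i, d
            if best_i is not None:
                used_left.add(best_i)
                lbp, lgroup = lefts[best_i]
                clusters.append(
                    BreakpointCluster(chrom, lbp, rbp, lgroup, rgroup)
                )
            else:
                clusters.append(BreakpointCluster(chrom, None, rbp, [], rgroup))
        for i, (lbp, lgroup) in enumerate(lefts):
            if i not in used_left:
                clusters.append(BreakpointCluster(chrom, lbp, None, lgroup, []))
    disc_by_chrom: dict[str, list[DiscordantEvidence]] = {}
    for d in discordants:
        disc_by_chrom.setdefault(d.chrom, []).append(d)
    for cl in clusters:
        pos = cl.position
        for d in disc_by_chrom.get(cl.chrom, ()):
            if abs(d.position - pos) <= discordant_window:
                cl.discordants.append(d)
    clusters.sort(key=lambda c: (c.chrom, c.position))
    return clusters


# ---------------------------------------------------------------------------
# Call resolution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransductionAnnotation:
    transduced_seq: str
    chrom: str
    start: int
    end: int
    source_id: str | None
    source_is_reference: bool = True
    multimap: bool = False


@dataclass
class RTCall:
    sample_id: str
    chrom: str
    position: int                  # 1-based leftmost target-site coordinate
    call_class: str                # 'canonical' | 'inversion'
    inserted_length: int | None    # None = unresolved (inversions)
    tsd_len: int | None
    polyA_support: bool
    clip_support: int
    discordant_support: int
    status: str = "unresolved"     # 'somatic' | 'pseudo-germline' | 'unresolved'
    transduction: TransductionAnnotation | None = None
    second_priming: int | None = None
    length_lower_bound: int | None = None
    tsd_deletion: bool = False
    notes: str = ""
    cluster: BreakpointCluster | None = field(default=None, repr=False, compare=False)

    @property
    def pos0(self) -> int:
        return self.position - 1


def _junction_proximal_poly(clip: ClipEvidence, min_len: int, purity: float) -> str:
    # right-clip tails read into the cassette start: junction-proximal end is
    # the prefix; left-clip tails are the cassette end: proximal end is suffix.
    end = "prefix" if clip.side == "right" else "suffix"
    return detect_poly_tract(clip.clipped_seq, min_len, purity, end=end)


def _strip_poly(seq: str, side: str, purity: float) -> str:
    """Remove the junction-proximal poly tract (if any) from a clipped tail."""
    work = seq if side == "right" else seq[::-1]
    for base in "AT":
        count = 0
        cut = 0
        for i, ch in enumerate(work):
            if ch == base:
                count += 1
            if count / (i + 1) >= purity:
                cut = i + 1
        if cut >= POLY_MIN_LEN:
            work = work[cut:]
            break
    return work if side == "right" else work[::-1]


def resolve_call(
    cluster: BreakpointCluster,
    consensus: L1Consensus,
    sample_id: str = "sample",
    min_support_clips: int = 2,
    min_support_mixed: tuple[int, int] = (1, 2),
    max_align_per_side: int = 16,
    poly_min_len: int = POLY_MIN_LEN,
    poly_purity: float = POLY_PURITY,
) -> RTCall | None:
    """Resolve one breakpoint cluster into a call, or None below min support.

    Support rule: at least ``min_support_clips`` clip evidences, or
    ``min_support_mixed`` = (clips, discordant anchors) jointly.
    """
    nclips = cluster.clip_support
    ndisc = len(cluster.discordants)
    if nclips < min_support_clips and not (
        nclips >= min_support_mixed[0] and ndisc >= min_support_mixed[1]
    ):
        return None

    L = consensus.length
    side_alns: dict[str, list[ClipAlignment]] = {"left": [], "right": []}
    poly_support = False
    for side, clips in (("left", cluster.left_clips), ("right", cluster.right_clips)):
        ranked = sorted(clips, key=lambda c: -len(c.clipped_seq))[:max_align_per_side]
        for clip in ranked:
            if _junction_proximal_poly(clip, poly_min_len, poly_purity) != "none":
                poly_support = True
            stripped = _strip_poly(clip.clipped_seq, clip.side, poly_purity)
            aln = realign_clip(stripped, consensus)
            cluster.clip_alignments[clip] = (stripped, aln)
            if aln is not None:
                side_alns[side].append(aln)

    def dominant(alns: list[ClipAlignment]) -> str | None:
        if not alns:
            return None
        plus = sum(1 for a in alns if a.orientation == "+")
        minus = len(alns) - plus
        if plus == minus:
            return None
        return "+" if plus > minus else "-"

    o_left = dominant(side_alns["left"])
    o_right = dominant(side_alns["right"])
    all_alns = side_alns["left"] + side_alns["right"]

    if not all_alns:
        # clips exist but none maps to the consensus: not an L1 call
        return None

    call_class = "canonical"
    inserted_length: int | None = None
    second_priming: int | None = None
    length_lb: int | None = None
    notes = ""

    if o_left is not None and o_right is not None and o_left != o_right:
        call_class = "inversion"
        # the junction whose alignments stay farther from the consensus 3' end
        # samples the inverted (second-priming) fragment
        max_end = {s: max(a.c_end for a in side_alns[s]) for s in ("left", "right")}
        inv_side = "left" if max_end["left"] < max_end["right"] else "right"
        other = "right" if inv_side == "left" else "left"
        second_priming = max_end[inv_side]
        length_lb = (second_priming - min(a.c_start for a in side_alns[inv_side])) + (
            L - min(a.c_start for a in side_alns[other])
        )
    else:
        if o_left is not None and o_right is not None and o_left == o_right:
            pass
        elif o_left is None and o_right is None:
            notes = "orientation ambiguous on both junctions"
        inserted_length = L - min(a.c_start for a in all_alns)

    tsd_len: int | None = None
    deletion = False
    if cluster.left_bp is not None and cluster.right_bp is not None:
        d = cluster.right_bp - cluster.left_bp
        if d >= 0:
            tsd_len = d
        else:
            tsd_len = 0
            deletion = True

    return RTCall(
        sample_id=sample_id,
        chrom=cluster.chrom,
        position=cluster.position + 1,
        call_class=call_class,
        inserted_length=inserted_length if call_class == "canonical" else None,
        tsd_len=tsd_len,
        polyA_support=poly_support,
        clip_support=nclips,
        discordant_support=ndisc,
        second_priming=second_priming,
        length_lower_bound=length_lb,
        tsd_deletion=deletion,
        notes=notes,
        cluster=cluster,
    )


# ---------------------------------------------------------------------------
# Transduction attribution
# ---------------------------------------------------------------------------


def _candidate_transduced_segments(
    call: RTCall, consensus: L1Consensus, min_len: int = 30
) -> list[str]:
    """Non-consensus, non-poly(A) junction-tail segments, longest first."""
    if call.cluster is None:
        return []
    segs = []
    cache = call.cluster.clip_alignments
    for clip in call.cluster.left_clips + call.cluster.right_clips:
        if clip in cache:
            stripped, aln = cache[clip]
        else:
            stripped = _strip_poly(clip.clipped_seq, clip.side, POLY_PURITY)
            aln = realign_clip(stripped, consensus) if len(stripped) >= min_len else None
        if len(stripped) < min_len:
            continue
        if aln is None:
            segs.append(stripped)
        else:
            # keep any junction-proximal residue beyond the consensus match
            if clip.side == "left":
                residue = stripped[aln.query_end :]
                if aln.orientation == "-":
                    residue = revcomp(stripped)[aln.query_end :]
            else:
                residue = stripped[: aln.query_start]
                if aln.orientation == "-":
                    residue = revcomp(stripped)[: aln.query_start]
            if len(residue) >= min_len:
                segs.append(residue)
    segs.sort(key=len, reverse=True)
    return segs


def attribute_transduction(
    call: RTCall,
    consensus: L1Consensus,
    genome: str,
    sources: Sequence[SourceLocus],
    l1_intervals: Sequence[L1Interval] = (),
    max_source_distance: int = MAX_SOURCE_DISTANCE,
    group_distance: int = SOURCE_GROUP_DISTANCE,
    min_segment: int = 30,
) -> RTCall:
    """Trace a transduced junction-tail segment back to a registered source.

    The segment is aligned within ``max_source_distance`` downstream of every
    registered source 3' end (both orientations); the best unique hit assigns
    the source.  Candidate sources whose 3' ends lie within
    ``group_distance`` of each other are merged into one grouped id.  A
    segment whose best placement falls in L1-annotated or consensus sequence
    leaves the call intact but unannotated (multimap flag set).
    """
    segs = _candidate_transduced_segments(call, consensus, min_segment)
    if not segs:
        return call
    seg = segs[0]
    # a segment that itself maps to the consensus is L1-multimapping
    if realign_clip(seg, consensus, score_fraction=0.5) is not None:
        call.transduction = TransductionAnnotation(
            seg, call.chrom, -1, -1, None, multimap=True
        )
        return call
    threshold = SCORE_FRACTION * MATCH * len(seg)
    hits = []  # (score, source, window_offset, t0, t1)
    for src in sources:
        window = genome[src.end : src.end + max_source_distance]
        if not window:
            continue
        for query in (seg, revcomp(seg)):
            sc = _ALIGNER.score(window, query)
            if sc >= threshold:
                score, t0, t1, _q0, _q1, ident = _alignment_details(window, query)
                if ident >= IDENTITY_FLOOR:
                    hits.append((score, src, t0, t1))
                break
    if not hits:
        return call
    hits.sort(key=lambda h: -h[0])
    best_score, best_src, t0, t1 = hits[0]
    # competing placements from sources farther than group_distance apart
    competing = [
        h
        for h in hits[1:]
        if h[0] >= best_score * 0.95 and abs(h[1].end - best_src.end) > group_distance
    ]
    start, end = best_src.end + t0, best_src.end + t1
    if competing:
        call.transduction = TransductionAnnotation(
            seg, best_src.chrom, start, end, None, multimap=True
        )
        return call
    for iv in l1_intervals:
        if iv.chrom == best_src.chrom and start < iv.end and end > iv.start:
            call.transduction = TransductionAnnotation(
                seg, best_src.chrom, start, end, None, multimap=True
            )
            return call
    group = sorted(
        s.id for s in sources if abs(s.end - best_src.end) <= group_distance
    )
    call.transduction = TransductionAnnotation(
        seg, best_src.chrom, start, end, "+".join(group)
    )
    return call


# ---------------------------------------------------------------------------
# Somatic classification
# ---------------------------------------------------------------------------


def classify_somatic(
    tumor_calls: Sequence[RTCall],
    normal_clips: Sequence[ClipEvidence],
    normal_discordants: Sequence[DiscordantEvidence] = (),
    normal_depth=None,
    window: int = 50,
    discordant_window: int = 500,
    min_normal_coverage: float = 8.0,
) -> list[RTCall]:
    """Label tumor calls somatic, pseudo-germline, or unresolved.

    Any qualifying normal clip within ``window`` (or discordant anchor within
    ``discordant_window``) of the call makes it pseudo-germline.  Otherwise,
    if ``normal_depth`` (a callable (chrom, pos) -> fold coverage) reports
    less than ``min_normal_coverage`` at the locus, the call is unresolved;
    with adequate normal coverage and no support it is somatic.
    """
    if normal_clips is None:
        raise ValueError("normal evidence is required for somatic classification")
    clip_pos: dict[str, list[int]] = {}
    for c in normal_clips:
        clip_pos.setdefault(c.chrom, []).append(c.breakpoint)
    disc_pos: dict[str, list[int]] = {}
    for d in normal_discordants:
        disc_pos.setdefault(d.chrom, []).append(d.position)
    for v in clip_pos.values():
        v.sort()
    for v in disc_pos.values():
        v.sort()

    def _any_within(positions: list[int], pos: int, w: int) -> bool:
        import bisect

        i = bisect.bisect_left(positions, pos - w)
        return i < len(positions) and positions[i] <= pos + w

    for call in tumor_calls:
        pos = call.pos0
        supported = _any_within(clip_pos.get(call.chrom, []), pos, window) or _any_within(
            disc_pos.get(call.chrom, []), pos, discordant_window
        )
        if supported:
            call.status = "pseudo-germline"
        elif normal_depth is not None and normal_depth(call.chrom, pos) < min_normal_coverage:
            call.status = "unresolved"
        else:
            call.status = "somatic"
    return list(tumor_calls)


def binned_depth(records, genome_len: int, bin_size: int = 100):
    """Coarse fold-coverage profile from primary alignments; returns a
    callable (chrom, pos) -> coverage."""
    from .evidence import iter_records

    nbins = genome_len // bin_size + 1
    depth = np.zeros(nbins)
    for rec in iter_records(records):
        if rec.is_unmapped or rec.is_supplementary or rec.is_secondary:
            continue
        s, e = rec.reference_start, rec.reference_end or rec.reference_start
        for b in range(s // bin_size, min(e // bin_size, nbins - 1) + 1):
            lo, hi = b * bin_size, (b + 1) * bin_size
            depth[b] += max(0, min(e, hi) - max(s, lo))
    depth /= bin_size

    def lookup(chrom: str, pos: int) -> float:
        b = pos // bin_size
        return float(depth[b]) if 0 <= b < nbins else 0.0

    return lookup


# ---------------------------------------------------------------------------
# Call-set intersection and inversion-rate CI
# ---------------------------------------------------------------------------


def intersect_callsets(
    set_a: Sequence[RTCall], set_b: Sequence[RTCall], window: int = INTERSECT_WINDOW
) -> dict:
    """Greedy nearest-neighbor matching of two call sets.

    Calls from the same sample and chromosome within ``window`` bp are
    considered shared; each call matches at most once; ties break to the
    smallest offset, then the lowest coordinate.  Swapping inputs swaps
    a_only and b_only.
    """
    for name, calls in (("a", set_a), ("b", set_b)):
        keys = [(c.sample_id, c.chrom, c.position) for c in calls]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate call ids in set {name}")
    index_b: dict[tuple[str, str], list[int]] = {}
    for j, c in enumerate(set_b):
        index_b.setdefault((c.sample_id, c.chrom), []).append(j)
    candidates = []
    for i, c in enumerate(set_a):
        for j in index_b.get((c.sample_id, c.chrom), ()):
            d = abs(c.position - set_b[j].position)
            if d <= window:
                candidates.append((d, min(c.position, set_b[j].position), i, j))
    candidates.sort()
    matched_a: set[int] = set()
    matched_b: set[int] = set()
    shared = []
    for d, _pos, i, j in candidates:
        if i in matched_a or j in matched_b:
            continue
        matched_a.add(i)
        matched_b.add(j)
        shared.append((set_a[i], set_b[j]))
    return {
        "shared": shared,
        "a_only": [c for i, c in enumerate(set_a) if i not in matched_a],
        "b_only": [c for j, c in enumerate(set_b) if j not in matched_b],
    }


def inversion_rate_ci(k: int, n: int, level: float = 0.99) -> tuple[float, float]:
    """Exact Clopper-Pearson confidence interval for an inversion proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


# ---------------------------------------------------------------------------
# End-to-end convenience pipeline
# ---------------------------------------------------------------------------


def mask_l1_regions(
    calls: Sequence[RTCall],
    l1_intervals: Sequence[L1Interval],
    margin: int = 500,
) -> list[RTCall]:
    """Drop calls whose breakpoint falls in or near an annotated genomic L1
    copy.  Clip pileups inside existing L1 sequence (and its immediate
    downstream flank, where transduced fragments land) are mapping artifacts
    of the repeat, not novel insertions."""
    out = []
    for c in calls:
        inside = any(
            iv.chrom == c.chrom and iv.start - margin <= c.pos0 < iv.end + margin
            for iv in l1_intervals
        )
        if not inside:
            out.append(c)
    return out


def call_sample(
    tumor_records,
    normal_records,
    consensus: L1Consensus,
    l1_intervals: Sequence[L1Interval],
    genome: str | None = None,
    sources: Sequence[SourceLocus] = (),
    genome_len: int | None = None,
    sample_id: str = "sample",
    min_clip: int = MIN_CLIP,
    window: int = 50,
    max_tsd: int = 30,
    l1_mask_margin: int = 500,
) -> list[RTCall]:
    """Full calling pass for one tumor/normal pair of alignment inputs.

    ``tumor_records`` / ``normal_records`` may be SAM/BAM paths or record
    iterables; they are read once each.  Transduction attribution runs only
    when ``genome`` and ``sources`` are provided.
    """
    from .evidence import extract_clips, extract_discordant, iter_records

    t_recs = list(iter_records(tumor_records))
    n_recs = list(iter_records(normal_records))
    clips_t = extract_clips(t_recs, min_clip=min_clip)
    disc_t = extract_discordant(t_recs, l1_intervals)
    clusters = cluster_evidence(clips_t, disc_t, window=window, max_tsd=max_tsd)
    calls = []
    for cl in clusters:
        call = resolve_call(cl, consensus, sample_id=sample_id)
        if call is not None:
            calls.append(call)
    calls = mask_l1_regions(calls, l1_intervals, margin=l1_mask_margin)
    if genome is not None and sources:
        for call in calls:
            attribute_transduction(call, consensus, genome, sources, l1_intervals)
    clips_n = extract_clips(n_recs, min_clip=min_clip)
    disc_n = extract_discordant(n_recs, l1_intervals)
    depth = None
    if genome_len is not None:
        depth = binned_depth(n_recs, genome_len)
    classify_somatic(calls, clips_n, disc_n, normal_depth=depth, window=window)
    return calls


TSV_COLUMNS = [
    "sample_id",
    "chrom",
    "position",
    "class",
    "inserted_length",
    "tsd_len",
    "polyA_support",
    "clip_support",
    "discordant_support",
    "status",
    "transduction_source",
    "second_priming",
]


def calls_to_rows(calls: Sequence[RTCall]) -> list[dict]:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "chrom": c.chrom,
                "position": c.position,
                "class": c.call_class,
                "inserted_length": c.inserted_length if c.inserted_length is not None else ".",
                "tsd_len": c.tsd_len if c.tsd_len is not None else ".",
                "polyA_support": int(c.polyA_support),
                "clip_support": c.clip_support,
                "discordant_support": c.discordant_support,
                "status": c.status,
                "transduction_source": (
                    c.transduction.source_id
                    if c.transduction and c.transduction.source_id
                    else "."
                ),
                "second_priming": c.second_priming if c.second_priming is not None else ".",
            }
        )
    return rows


def write_calls_tsv(calls: Sequence[RTCall], path) -> None:
    rows = calls_to_rows(calls)
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in TSV_COLUMNS) + "\n")


def write_calls_vcf(calls: Sequence[RTCall], path, contigs: dict[str, int]) -> None:
    """Minimal VCF with INS records (CLASS, SVLEN, TSD, POLYA, TDSRC, STATUS)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for key, desc in [
            ("CLASS", "canonical or inversion"),
            ("SVLEN", "inferred inserted length"),
            ("TSD", "target site duplication length"),
            ("POLYA", "poly(A) support flag"),
            ("TDSRC", "transduction source id"),
            ("STATUS", "somatic status"),
        ]:
            num_type = (
                'Number=0,Type=Flag' if key == "POLYA" else 'Number=1,Type=String'
            )
            fh.write(f'##INFO=<ID={key},{num_type},Description="{desc}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(sorted(calls, key=lambda x: (x.chrom, x.position))):
            info = [f"CLASS={c.call_class}"]
            if c.inserted_length is not None:
                info.append(f"SVLEN={c.inserted_length}")
            if c.tsd_len is not None:
                info.append(f"TSD={c.tsd_len}")
            if c.polyA_support:
                info.append("POLYA")
            if c.transduction and c.transduction.source_id:
                info.append(f"TDSRC={c.transduction.source_id}")
            info.append(f"STATUS={c.status}")
            fh.write(
                f"{c.chrom}\t{c.position}\tL1_{i}\tN\t<INS>\t.\tPASS\t{';'.join(info)}\n"
            )
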