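"""Telomere-aware contig finishing.

Quality trimming, anchored end extension from prioritised sources,
greedy overlap merging, chimera detection from unspanned paired-read
intervals, and split-and-trim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import dna, telomere

ANCHOR_LEN = 100
MIN_ANCHOR_IDENTITY = 0.94
END_ZONE = 400
TRIM_BP = 200
MIN_FRAGMENT = 100


# ---------------------------------------------------------------------------
# quality trimming


def longest_quality_run(qual: str, threshold: int = 20, offset: int = 33) -> tuple[int, int]:
    """[start, end) of the longest run of bases with phred >= threshold."""
    best = (0, 0)
    start = None
    for i, ch in enumerate(qual):
        if ord(ch) - offset >= threshold:
            if start is None:
                start = i
        else:
            if start is not None and i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if start is not None and len(qual) - start > best[1] - best[0]:
        best = (start, len(qual))
    return best


def quality_trim(
    reads: Iterable[tuple[str, str, str]],
    min_quality: int = 20,
    min_len: int = 100,
) -> list[tuple[str, str, str]]:
    """Keep the longest high-quality run per read; discard short results.

    *reads* yields (read_id, seq, qual) triples with Phred+33 qualities.
    """
    out = []
    for rid, seq, qual in reads:
        if len(seq) != len(qual):
            raise ValueError(f"malformed record {rid!r}: seq/qual length mismatch")
        s, e = longest_quality_run(qual, min_quality)
        if e - s >= min_len:
            out.append((rid, seq[s:e], qual[s:e]))
    return out


# ---------------------------------------------------------------------------
# end extension


@dataclass(frozen=True)
class ExtensionSource:
    priority: int  # 1 meta-assembly, 2 auxiliary assembly, 3 raw long reads
    source_id: str
    seq: str


@dataclass(frozen=True)
class ExtensionCandidate:
    contig_id: str
    end: str  # "5" or "3"
    source_priority: int
    source_id: str
    anchor_identity: float
    extension_sequence: str
    extension_length_bp: int


def _find_anchor(
    anchor: str, source_seq: str, k: int = 31, min_identity: float = MIN_ANCHOR_IDENTITY
) -> tuple[int, float] | None:
    """Best placement of the 100 bp anchor inside source_seq (forward)."""
    ac = dna.encode(anchor)
    sc = dna.encode(source_seq)
    n = len(anchor)
    if len(source_seq) < n:
        return None
    cand: set[int] = set()
    for off in (0, n // 2, n - k):
        if off < 0:
            continue
        kmer = anchor[off : off + k]
        start = 0
        while True:
            p = source_seq.find(kmer, start)
            if p < 0:
                break
            cand.add(p - off)
            start = p + 1
    best = None
    for pos in sorted(cand):
        if pos < 0 or pos + n > len(source_seq):
            continue
        ident = dna.matches(sc[pos : pos + n], ac) / n
        if ident >= min_identity and (best is None or ident > best[1]):
            best = (pos, ident)
    return best


def find_end_extensions(
    contig_id: str,
    seq: str,
    sources: Sequence[ExtensionSource],
    anchor_len: int = ANCHOR_LEN,
    min_identity: float = MIN_ANCHOR_IDENTITY,
    max_degenerate: int = telomere.DEFAULT_MAX_DEGENERATE,
) -> dict[str, ExtensionCandidate]:
    """Best extension candidate per non-telomeric contig end.

    Candidates rank by (source priority, anchor identity desc, extension
    length desc, source id); telomere-bearing ends are never extended.
    """
    if len(seq) < anchor_len:
        return {}
    spans = telomere.find_telomeres(seq, max_degenerate=max_degenerate)
    has5 = any(s.polarity == "5" and telomere.is_terminal(s, len(seq)) for s in spans)
    has3 = any(s.polarity == "3" and telomere.is_terminal(s, len(seq)) for s in spans)
    out: dict[str, ExtensionCandidate] = {}
    for end, has_tel in (("5", has5), ("3", has3)):
        if has_tel:
            continue
        anchor = seq[:anchor_len] if end == "5" else seq[-anchor_len:]
        cands: list[ExtensionCandidate] = []
        for src in sources:
            for oriented in (src.seq.upper(), dna.revcomp(src.seq.upper())):
                hit = _find_anchor(anchor, oriented, min_identity=min_identity)
                if hit is None:
                    continue
                pos, ident = hit
                ext = oriented[:pos] if end == "5" else oriented[pos + anchor_len :]
                if not ext:
                    continue
                cands.append(
                    ExtensionCandidate(
                        contig_id, end, src.priority, src.source_id,
                        ident, ext, len(ext),
                    )
                )
        if cands:
            cands.sort(
                key=lambda c: (
                    c.source_priority,
                    -c.anchor_identity,
                    -c.extension_length_bp,
                    c.source_id,
                )
            )
            out[end] = cands[0]
    return out


def apply_extensions(seq: str, candidates: dict[str, ExtensionCandidate]) -> str:
    """Append/prepend extension sequences; existing bases are untouched."""
    out = seq
    if "5" in candidates:
        out = candidates["5"].extension_sequence + out
    if "3" in candidates:
        out = out + candidates["3"].extension_sequence
    return out


def extend_contigs(
    contigs: Sequence[tuple[str, str]],
    sources: Sequence[ExtensionSource],
    rounds: int = 2,
    anchor_len: int = ANCHOR_LEN,
    min_identity: float = MIN_ANCHOR_IDENTITY,
) -> list[tuple[str, str]]:
    """Iterative end extension (default two rounds); an end stops
    extending once it carries a terminal telomere."""
    current = {cid: seq for cid, seq in contigs}
    for _ in range(rounds):
        for cid in sorted(current):
            cands = find_end_extensions(
                cid, current[cid], sources, anchor_len, min_identity
            )
            if cands:
                current[cid] = apply_extensions(current[cid], cands)
    return [(cid, current[cid]) for cid in sorted(current)]


# ---------------------------------------------------------------------------
# greedy overlap merging


def _overlap_candidates(a: str, b: str, k: int = 16, min_overlap: int = 1) -> set[int]:
    """Candidate suffix(a)/prefix(b) overlap lengths from shared k-mers."""
    cands: set[int] = set()
    if len(b) < k or len(a) < k:
        if b and a:
            cands.update(range(min_overlap, min(len(a), len(b)) + 1))
        return cands
    for j in (0, 8, 16, 24, 32):
        if j + k > len(b):
            break
        kmer = b[j : j + k]
        start = 0
        while True:
            p = a.find(kmer, start)
            if p < 0:
                break
            ell = len(a) - p + j
            if min_overlap <= ell <= min(len(a), len(b)):
                cands.add(ell)
            start = p + 1
    return cands


def _best_overlap(a: str, b: str, min_overlap: int, min_identity: float) -> tuple[int, float] | None:
    ac, bc = dna.encode(a), dna.encode(b)
    best = None
    for ell in sorted(_overlap_candidates(a, b, min_overlap=min_overlap), reverse=True):
        ident = dna.matches(ac[len(a) - ell :], bc[:ell]) / ell
        if ident >= min_identity and (best is None or ell > best[0]):
            best = (ell, ident)
            break  # longest qualifying overlap wins
    return best


def _merge_pair(a: str, b: str, ell: int) -> str:
    """Merge a and b over a suffix/prefix overlap of length ell; column
    ties resolve to the longer contig's base."""
    ov_a = a[len(a) - ell :]
    ov_b = b[:ell]
    longer_first = len(a) >= len(b)
    consensus = "".join(
        ca if ca == cb or longer_first else cb for ca, cb in zip(ov_a, ov_b)
    )
    return a[: len(a) - ell] + consensus + b[ell:]


def greedy_overlap_merge(
    contigs: Sequence[tuple[str, str]],
    min_overlap_bp: int = 40,
    min_identity: float = 0.99,
) -> list[tuple[str, str]]:
    """Repeatedly merge the highest-scoring qualifying suffix-prefix
    overlap (either strand) until none remains."""
    if min_overlap_bp < 1 or not 0 < min_identity <= 1:
        raise ValueError("bad merge parameters")
    pool = {cid: seq.upper() for cid, seq in contigs}
    while True:
        best = None  # (ell, ident, a_id, b_id, b_rc)
        ids = sorted(pool)
        for ia, aid in enumerate(ids):
            for bid in ids[ia + 1 :]:
                for a_id, b_id in ((aid, bid), (bid, aid)):
                    for rc in (False, True):
                        a = pool[a_id]
                        b = dna.revcomp(pool[b_id]) if rc else pool[b_id]
                        hit = _best_overlap(a, b, min_overlap_bp, min_identity)
                        if hit is None:
                            continue
                        ell, ident = hit
                        key = (ell, ident, a_id, b_id, rc)
                        if best is None or (ell, ident) > (best[0], best[1]):
                            best = key
        if best is None:
            return [(cid, pool[cid]) for cid in sorted(pool)]
        ell, _, a_id, b_id, rc = best
        a = pool[a_id]
        b = dna.revcomp(pool[b_id]) if rc else pool[b_id]
        merged_id = a_id if len(a) >= len(b) else b_id
        merged = _merge_pair(a, b, ell) if ell < len(b) else (
            a if len(a) >= len(b) else b
        )
        del pool[a_id], pool[b_id]
        pool[merged_id] = merged


# ---------------------------------------------------------------------------
# chimera detection and splitting


@dataclass(frozen=True)
class UnspannedInterval:
    contig_id: str
    start: int
    end: int
    reason: str  # "no-pair-span" | "zero-coverage-end"


def _union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals.sort()
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def detect_unspanned(
    contig_id: str,
    contig_len: int,
    alignments: Sequence,
    end_zone: int = END_ZONE,
) -> list[UnspannedInterval]:
    """Maximal intervals not covered by any inter-mate span, excluding
    the *end_zone* bp end regions, plus contig ends with no mapped reads.

    A span is the inter-PE-read region, the reads themselves excluded;
    only proper pairs with both mates on the contig contribute.
    """
    by_id = {a.read_id: a for a in alignments if a.contig_id == contig_id}
    spans: list[tuple[int, int]] = []
    read_cov: list[tuple[int, int]] = []
    seen = set()
    for a in by_id.values():
        read_cov.append((a.start, a.end))
        if not a.mate_id or a.read_id in seen:
            continue
        m = by_id.get(a.mate_id)
        if m is None:
            continue
        seen.add(a.read_id)
        seen.add(m.read_id)
        left, right = (a, m) if a.start <= m.start else (m, a)
        if right.start > left.end:
            spans.append((left.end, right.start))

    out: list[UnspannedInterval] = []
    cov = _union(read_cov)
    if not cov:
        return [UnspannedInterval(contig_id, 0, contig_len, "zero-coverage-end")]
    if cov[0][0] > 0:
        out.append(UnspannedInterval(contig_id, 0, cov[0][0], "zero-coverage-end"))
    if cov[-1][1] < contig_len:
        out.append(
            UnspannedInterval(contig_id, cov[-1][1], contig_len, "zero-coverage-end")
        )

    merged = _union(spans)
    gaps: list[tuple[int, int]] = []
    prev = 0
    for s, e in merged:
        if s > prev:
            gaps.append((prev, s))
        prev = max(prev, e)
    if prev < contig_len:
        gaps.append((prev, contig_len))
    for s, e in gaps:
        # splits near the ends are not trusted (subtelomeric coverage gap)
        if s < end_zone or e > contig_len - end_zone:
            continue
        out.append(UnspannedInterval(contig_id, s, e, "no-pair-span"))
    return sorted(out, key=lambda u: u.start)


def split_and_trim(
    contig_id: str,
    seq: str,
    intervals: Sequence[UnspannedInterval],
    trim_bp: int = TRIM_BP,
    min_len: int = MIN_FRAGMENT,
) -> list[tuple[str, str]]:
    """Cut at each no-pair-span midpoint, trim the new ends by *trim_bp*,
    drop zero-coverage end regions, discard fragments below *min_len*."""
    lo, hi = 0, len(seq)
    cuts = []
    for iv in sorted(intervals, key=lambda u: u.start):
        if iv.reason == "zero-coverage-end":
            if iv.start == 0:
                lo = max(lo, iv.end)
            if iv.end == len(seq):
                hi = min(hi, iv.start)
        else:
            cuts.append((iv.start + iv.end) // 2)

    bounds = [lo] + [c for c in cuts if lo < c < hi] + [hi]
    frags = []
    n = 0
    for i in range(len(bounds) - 1):
        s, e = bounds[i], bounds[i + 1]
        if i > 0:
            s += trim_bp  # new end created by the cut on the left
        if i < len(bounds) - 2:
            e -= trim_bp  # new end created by the cut on the right
        if e - s >= min_len:
            n += 1
            fid = contig_id if len(bounds) == 2 and lo == 0 and hi == len(seq) else f"{contig_id}.{n}"
            frags.append((fid, seq[s:e]))
    return frags
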