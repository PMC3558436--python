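"""Telomere-addition-site (TAS) calling, alternative-fragmentation
detection, isoform prediction and CDS-context enrichment.

Polarity convention: a 5' TAS retains sequence to its right, a 3' TAS
retains sequence to its left, in contig orientation.  TAS coordinates
are the first non-telomeric base of the supporting reads (0-based); a
3' TAS coordinate is the half-open end of the retained sequence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

WINDOW = 200
STRONG_MIN_READS = 10
TERMINAL_WINDOW = 100
LINK_BP = 100
MERGE_RADIUS = 50


@dataclass(frozen=True)
class TeloRead:
    """One telomeric read's junction evidence on a contig."""

    pos: int
    polarity: str  # "5" | "3"


@dataclass(frozen=True)
class TAS:
    contig_id: str
    pos: int
    polarity: str
    n_reads: int
    support: str  # "strong" | "weak"
    terminal: bool


@dataclass(frozen=True)
class Isoform:
    contig_id: str
    left_tas: TAS  # 5' site
    right_tas: TAS  # 3' site
    n_pairs: int


@dataclass
class AltFragStatus:
    contig_id: str
    fragmented: bool
    n_internal_sites: int
    internal_sites: list[TAS] = field(default_factory=list)


def telo_support_from_truth(truth, reads) -> dict[str, list[TeloRead]]:
    """Convert simulator telomeric reads to per-contig junction evidence.

    Reads whose telomeric end is the native contig terminus report the
    terminal junction; internally added telomeres report the cut site.
    """
    lengths = {lt.locus_id: lt.length for lt in truth.loci}
    tel = {lt.locus_id: lt.telomere_len for lt in truth.loci}
    out: dict[str, list[TeloRead]] = {}
    for r in reads:
        if r.telo_polarity is None or r.ref_start is None:
            continue
        L, t = lengths[r.locus_id], tel[r.locus_id]
        if r.telo_polarity == "5":
            pos = t if r.ref_start < t else r.ref_start
        else:
            pos = L - t if r.ref_end > L - t else r.ref_end
        out.setdefault(r.locus_id, []).append(TeloRead(pos, r.telo_polarity))
    return out


def telo_reads_from_alignments(alignments: Iterable, masked_sides: Mapping[str, tuple[bool, bool]]) -> dict[str, list[TeloRead]]:
    """Junction evidence from mapped telomere-masked reads.

    *masked_sides* maps read_id -> (lead, trail): whether the original
    read's left/right end was telomeric (telomere.mask_read).  The
    masked side, rotated by strand, fixes the polarity: masked side on
    the contig's left -> 5' TAS at the alignment start, on the right ->
    3' TAS at the alignment end.
    """
    out: dict[str, list[TeloRead]] = {}
    for a in alignments:
        sides = masked_sides.get(a.read_id)
        if sides is None or not (sides[0] or sides[1]):
            continue
        lead, trail = sides
        if a.strand == "-":
            lead, trail = trail, lead
        recs = out.setdefault(a.contig_id, [])
        if lead:
            recs.append(TeloRead(a.start, "5"))
        if trail:
            recs.append(TeloRead(a.end, "3"))
    return out


def call_tas(
    contig_id: str,
    contig_len: int,
    telo_reads: Sequence[TeloRead],
    window: int = WINDOW,
    strong_min_reads: int = STRONG_MIN_READS,
    terminal_window: int = TERMINAL_WINDOW,
) -> list[TAS]:
    """Greedy window calling per polarity: repeatedly take the position
    with maximal telomeric-read support (ties to the smaller
    coordinate), assign all same-polarity reads within +-window/2, and
    repeat until no reads remain.
    """
    half = window // 2
    out: list[TAS] = []
    for polarity in ("5", "3"):
        counts = Counter(tr.pos for tr in telo_reads if tr.polarity == polarity)
        while counts:
            pos, _ = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
            support = 0
            for p in [q for q in counts if abs(q - pos) <= half]:
                support += counts.pop(p)
            out.append(
                TAS(
                    contig_id,
                    pos,
                    polarity,
                    support,
                    "strong" if support >= strong_min_reads else "weak",
                    pos <= terminal_window or pos >= contig_len - terminal_window,
                )
            )
    return sorted(out, key=lambda t: (t.pos, t.polarity))


def detect_altfrag(
    contig_id: str,
    contig_len: int,
    tas_list: Sequence[TAS],
    end_margin: int = TERMINAL_WINDOW,
    strong_only: bool = True,
) -> AltFragStatus:
    """A contig is alternatively fragmented iff it carries >= 1 internal
    TAS beyond *end_margin* from either end (strong sites only by
    default)."""
    internal = [
        t
        for t in tas_list
        if end_margin < t.pos < contig_len - end_margin
        and (t.support == "strong" or not strong_only)
    ]
    return AltFragStatus(contig_id, bool(internal), len(internal), internal)


def merge_close_tas(tas_list: Sequence[TAS], radius: int = MERGE_RADIUS) -> list[TAS]:
    """Merge TASs within *radius* bp into the better-supported site
    (support sums; used for isoform prediction)."""
    merged: list[TAS] = []
    for t in sorted(tas_list, key=lambda t: (-t.n_reads, t.pos)):
        hit = next(
            (i for i, m in enumerate(merged)
             if m.polarity == t.polarity and abs(m.pos - t.pos) <= radius),
            None,
        )
        if hit is None:
            merged.append(t)
        else:
            m = merged[hit]
            n = m.n_reads + t.n_reads
            merged[hit] = TAS(m.contig_id, m.pos, m.polarity, n,
                              "strong" if n >= STRONG_MIN_READS else "weak",
                              m.terminal)
    return sorted(merged, key=lambda t: (t.pos, t.polarity))


def predict_isoforms(
    contig_id: str,
    tas_list: Sequence[TAS],
    pair_ends: Sequence[tuple[int, int]],
    link_bp: int = LINK_BP,
    merge_radius: int | None = MERGE_RADIUS,
) -> list[Isoform]:
    """Isoforms from telomere-paired read pairs.

    *pair_ends* gives (left_end, right_end) contig positions of each
    pair's two junctions.  A pair links the nearest 5' TAS within
    *link_bp* of its left end and the nearest 3' TAS within *link_bp* of
    its right end; every ordered (5', 3') TAS pair with >= 1 linking
    pair becomes an isoform.
    """
    sites = merge_close_tas(tas_list, merge_radius) if merge_radius else list(tas_list)
    tas5 = [t for t in sites if t.polarity == "5"]
    tas3 = [t for t in sites if t.polarity == "3"]
    counts: Counter[tuple[TAS, TAS]] = Counter()
    for left, right in pair_ends:
        l5 = min(tas5, key=lambda t: (abs(t.pos - left), t.pos), default=None)
        r3 = min(tas3, key=lambda t: (abs(t.pos - right), t.pos), default=None)
        if l5 is None or r3 is None:
            continue
        if abs(l5.pos - left) > link_bp or abs(r3.pos - right) > link_bp:
            continue
        if l5.pos < r3.pos:
            counts[(l5, r3)] += 1
    return sorted(
        (Isoform(contig_id, l, r, n) for (l, r), n in counts.items()),
        key=lambda iso: (iso.left_tas.pos, iso.right_tas.pos),
    )


def pair_ends_from_truth(reads1, reads2) -> dict[str, list[tuple[int, int]]]:
    """(left, right) junction coordinates for telomere-paired reads with
    truth placements (read1 5'-anchored, read2 3'-anchored)."""
    by_id = {r.read_id: r for r in reads2}
    out: dict[str, list[tuple[int, int]]] = {}
    for r1 in reads1:
        r2 = by_id.get(r1.mate_id)
        if r2 is None or r1.ref_start is None or r2.ref_end is None:
            continue
        out.setdefault(r1.locus_id, []).append((r1.ref_start, r2.ref_end))
    return out


# ---------------------------------------------------------------------------
# CDS context


@dataclass
class ContextSummary:
    mode: str  # "two_gene" | "single_gene"
    n_inter: int
    n_intra: int
    bp_inter: int
    bp_intra: int
    enrichment: float  # inter density / intra density; inf when intra empty
    enrichment_undefined: bool
    mean_reads_inter: float
    mean_reads_intra: float


def cds_context(
    sites_by_contig: Mapping[str, Sequence[TAS]],
    cds_by_contig: Mapping[str, Sequence[tuple[int, int]]],
    contig_lens: Mapping[str, int],
    mode: str = "two_gene",
) -> ContextSummary:
    """Label fragmentation sites inter-CDS vs intra-CDS (two-gene mode)
    or CDS vs non-CDS (single-gene mode) and compute the per-bp
    enrichment ratio (sites_inter/bp_inter) / (sites_intra/bp_intra)."""
    if mode not in ("two_gene", "single_gene"):
        raise ValueError(f"bad mode {mode!r}")
    n_inter = n_intra = bp_inter = bp_intra = 0
    reads_inter: list[int] = []
    reads_intra: list[int] = []
    for cid, length in contig_lens.items():
        cds = sorted(cds_by_contig.get(cid, ()))
        cds_bp = sum(e - s for s, e in cds)
        if mode == "two_gene":
            inter_bp = sum(
                max(0, cds[i + 1][0] - cds[i][1]) for i in range(len(cds) - 1)
            )
        else:
            inter_bp = length - cds_bp
        bp_intra += cds_bp
        bp_inter += inter_bp
        for t in sites_by_contig.get(cid, ()):
            in_cds = any(s <= t.pos < e for s, e in cds)
            if in_cds:
                n_intra += 1
                reads_intra.append(t.n_reads)
            elif mode == "single_gene" or any(
                cds[i][1] <= t.pos < cds[i + 1][0] for i in range(len(cds) - 1)
            ):
                n_inter += 1
                reads_inter.append(t.n_reads)
    if bp_inter == 0 or bp_intra == 0:
        raise ValueError("zero-length context: enrichment undefined")
    d_inter = n_inter / bp_inter
    d_intra = n_intra / bp_intra
    undefined = d_intra == 0
    enrichment = float("inf") if undefined else d_inter / d_intra
    return ContextSummary(
        mode, n_inter, n_intra, bp_inter, bp_intra, enrichment, undefined,
        float(np.mean(reads_inter)) if reads_inter else float("nan"),
        float(np.mean(reads_intra)) if reads_intra else float("nan"),
    )


# ---------------------------------------------------------------------------
# directionality


@dataclass
class DirectionalitySummary:
    by_site_count: dict[int, int]
    n_fragmented: int
    single_site_fraction: float  # "directional" share


def directionality_summary(site_counts: Sequence[int]) -> DirectionalitySummary:
    """Distribution of fragmented contigs by number of internal sites."""
    fragged = [n for n in site_counts if n >= 1]
    if not fragged:
        return DirectionalitySummary({}, 0, float("nan"))
    dist = dict(sorted(Counter(fragged).items()))
    return DirectionalitySummary(dist, len(fragged), dist.get(1, 0) / len(fragged))
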