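"""Minimal seeded read mapper, contig-contig matcher and SAM exchange.

The mapper is seed-and-verify: exact k-mer seeds (default k=21) propose
diagonals and an ungapped identity check scores them; the synthetic
divergence regime (substitutions only, <= ~6%) does not require gapped
verification.  SAM import accepts externally produced alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from . import dna

DEFAULT_MIN_IDENTITY = 0.94
DEFAULT_K = 21


@dataclass(slots=True)
class AlignmentRecord:
    """A read placement on a contig, forward-strand half-open coordinates.

    seq is the aligned (possibly clipped) read sequence oriented to the
    contig's forward strand.
    """

    read_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    identity: float
    seq: str = ""
    is_telomeric: bool = False
    mate_id: str | None = None
    multi: bool = False
    alt_contigs: tuple[str, ...] = ()


@dataclass(frozen=True)
class ContigMatch:
    query_id: str
    target_id: str
    length_bp: int
    identity: float
    strand: str = "+"


class ReferenceIndex:
    """Exact k-mer index over a contig set."""

    def __init__(self, contigs: Sequence[tuple[str, str]], k: int = DEFAULT_K):
        if not contigs:
            raise ValueError("empty contig index")
        self.k = k
        self.ids = [cid for cid, _ in contigs]
        self.seqs = {cid: seq.upper() for cid, seq in contigs}
        self.codes = {cid: dna.encode(seq) for cid, seq in self.seqs.items()}
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        for cid, seq in self.seqs.items():
            for i in range(0, len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self.kmers.setdefault(kmer, []).append((cid, i))


def _identity_at(index: ReferenceIndex, cid: str, start: int, qcodes: np.ndarray) -> float | None:
    ref = index.codes[cid]
    n = len(qcodes)
    if start < 0 or start + n > len(ref):
        return None
    return dna.matches(ref[start : start + n], qcodes) / n


def _seed_offsets(n: int, k: int) -> list[int]:
    # a handful of spread-out seeds: robust to ~6% substitution divergence
    offs = {0, max(0, n - k)}
    step = max(k // 2 + 1, (n - k) // 5 or 1)
    offs.update(range(0, n - k + 1, step))
    return sorted(offs)


def map_read(
    index: ReferenceIndex,
    seq: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[tuple[str, int, str, float]]:
    """All best-identity placements of *seq* (clipping terminal Ns):
    (contig_id, start, strand, identity), sorted deterministically."""
    seq = seq.upper()
    lead = len(seq) - len(seq.lstrip("N"))
    core = seq.strip("N")
    if len(core) < index.k:
        return []
    best: dict[tuple[str, int, str], float] = {}
    for dense in (False, True):
        for strand, s in (("+", core), ("-", dna.revcomp(core))):
            qcodes = dna.encode(s)
            offsets = (
                range(0, len(s) - index.k + 1, 4)
                if dense
                else _seed_offsets(len(s), index.k)
            )
            for off in offsets:
                kmer = s[off : off + index.k]
                for cid, pos in index.kmers.get(kmer, ()):
                    start = pos - off
                    key = (cid, start, strand)
                    if key in best:
                        continue
                    ident = _identity_at(index, cid, start, qcodes)
                    if ident is not None:
                        best[key] = ident
        if best:
            break  # dense pass only when sparse seeding found nothing
    if not best:
        return []
    top = max(best.values())
    if top < min_identity:
        return []
    hits = sorted(
        (cid, start, strand, ident)
        for (cid, start, strand), ident in best.items()
        if ident == top
    )
    return hits


def map_reads(
    reads: Iterable,
    contigs: Sequence[tuple[str, str]],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    k: int = DEFAULT_K,
    index: ReferenceIndex | None = None,
) -> list[AlignmentRecord]:
    """Best placement per read.  *reads* yields objects with read_id/seq
    (simgenome.SimRead works) or (read_id, seq) tuples.

    Multi-best placements resolve to the lexicographically smallest
    (contig, start, strand) and are flagged ``multi`` with the other
    contigs recorded in ``alt_contigs``.
    """
    idx = index or ReferenceIndex(contigs, k)
    out: list[AlignmentRecord] = []
    for r in reads:
        rid, seq = (r.read_id, r.seq) if hasattr(r, "read_id") else (r[0], r[1])
        mate = getattr(r, "mate_id", None)
        hits = map_read(idx, seq, min_identity)
        if not hits:
            continue
        cid, start, strand, ident = hits[0]
        core = seq.strip("N").upper()
        aln = core if strand == "+" else dna.revcomp(core)
        alt = tuple(sorted({h[0] for h in hits[1:]} - {cid}))
        out.append(
            AlignmentRecord(
                read_id=rid,
                contig_id=cid,
                start=start,
                end=start + len(core),
                strand=strand,
                identity=ident,
                seq=aln,
                is_telomeric="N" in seq.upper() or getattr(r, "is_telomeric", False),
                mate_id=mate,
                multi=len(hits) > 1,
                alt_contigs=alt,
            )
        )
    return out


def truth_alignments(reads: Iterable) -> list[AlignmentRecord]:
    """Noiseless AlignmentRecords straight from simulator ground truth."""
    out = []
    for r in reads:
        if r.ref_start is None:
            continue
        n = r.ref_end - r.ref_start
        ident = 1.0 - r.n_errors / max(n, 1)
        out.append(
            AlignmentRecord(
                read_id=r.read_id,
                contig_id=r.locus_id,
                start=r.ref_start,
                end=r.ref_end,
                strand=r.strand,
                identity=ident,
                seq=r.aln_seq or "",
                is_telomeric=r.is_telomeric,
                mate_id=r.mate_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# contig-contig matching


def _longest_good_segment(mism: np.ndarray, max_rate: float) -> tuple[int, int]:
    """Longest window with mismatch rate <= max_rate (two pointers);
    returns (start, end)."""
    best = (0, 0)
    lo = 0
    bad = 0
    for hi in range(len(mism)):
        bad += mism[hi]
        while bad > max_rate * (hi - lo + 1):
            bad -= mism[lo]
            lo += 1
        if hi - lo + 1 > best[1] - best[0]:
            best = (lo, hi + 1)
    return best


def nonself_matches(
    contigs: Sequence[tuple[str, str]],
    min_len: int = 100,
    min_identity: float = 0.90,
    k: int = DEFAULT_K,
) -> list[ContigMatch]:
    """All qualifying local matches between distinct contigs, both strands.

    Substitution-only matching along shared k-mer diagonals; the longest
    sufficiently identical diagonal segment is reported per pair/strand.
    """
    if len(contigs) < 2:
        raise ValueError("need >= 2 contigs")
    seqs = {cid: seq.upper() for cid, seq in contigs}
    codes = {cid: dna.encode(s) for cid, s in seqs.items()}
    index: dict[str, list[tuple[str, int]]] = {}
    for cid, seq in seqs.items():
        for i in range(0, len(seq) - k + 1, 8):
            index.setdefault(seq[i : i + k], []).append((cid, i))

    results: dict[tuple[str, str, str], ContigMatch] = {}
    for qid, qseq in seqs.items():
        for strand in ("+", "-"):
            q = qseq if strand == "+" else dna.revcomp(qseq)
            qc = dna.encode(q)
            diags: set[tuple[str, int]] = set()
            for i in range(0, len(q) - k + 1, 4):
                for tid, tpos in index.get(q[i : i + k], ()):
                    if tid == qid:
                        continue
                    diags.add((tid, tpos - i))
            for tid, d in diags:
                tc = codes[tid]
                q0 = max(0, -d)
                t0 = max(0, d)
                n = min(len(qc) - q0, len(tc) - t0)
                if n < min_len:
                    continue
                mism = (qc[q0 : q0 + n] != tc[t0 : t0 + n]).astype(np.int64)
                s, e = _longest_good_segment(mism, 1.0 - min_identity)
                if e - s < min_len:
                    continue
                ident = 1.0 - float(mism[s:e].sum()) / (e - s)
                key = tuple(sorted((qid, tid))) + (strand,)
                cur = results.get(key)
                if cur is None or (e - s) * ident > cur.length_bp * cur.identity:
                    a, b = sorted((qid, tid))
                    results[key] = ContigMatch(a, b, e - s, ident, strand)
    return sorted(results.values(), key=lambda m: (m.query_id, m.target_id, m.strand))


def matched_contigs(matches: Iterable[ContigMatch]) -> set[str]:
    """Contig ids having at least one qualifying non-self match."""
    out: set[str] = set()
    for m in matches:
        out.add(m.query_id)
        out.add(m.target_id)
    return out


def group_by_contig(alignments: Iterable[AlignmentRecord]) -> dict[str, list[AlignmentRecord]]:
    out: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        out.setdefault(a.contig_id, []).append(a)
    return out


def count_cross_mapped(contig_id: str, alignments: Iterable[AlignmentRecord]) -> int:
    """Reads placed on *contig_id* whose best placements also include
    another contig."""
    return sum(
        1 for a in alignments if a.contig_id == contig_id and a.alt_contigs
    )


# ---------------------------------------------------------------------------
# SAM exchange (minimal dialect)


def write_sam(
    path: str | Path,
    alignments: Iterable[AlignmentRecord],
    contigs: Sequence[tuple[str, str]],
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": cid, "LN": len(seq)} for cid, seq in contigs],
    }
    ref_ids = {cid: i for i, (cid, _) in enumerate(contigs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = a.read_id
            seg.flag = 16 if a.strand == "-" else 0
            seg.reference_id = ref_ids[a.contig_id]
            seg.reference_start = a.start
            seg.mapping_quality = 255
            if a.seq:
                seg.query_sequence = a.seq
                seg.cigartuples = [(0, len(a.seq))]
            else:
                seg.cigartuples = [(0, a.end - a.start)]
            nm = round((1.0 - a.identity) * (a.end - a.start))
            seg.set_tag("NM", nm)
            fh.write(seg)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            length = seg.reference_length or len(seg.query_sequence or "")
            nm = seg.get_tag("NM") if seg.has_tag("NM") else 0
            out.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    contig_id=seg.reference_name,
                    start=seg.reference_start,
                    end=seg.reference_start + length,
                    strand="-" if seg.is_reverse else "+",
                    identity=1.0 - nm / max(length, 1),
                    seq=seg.query_sequence or "",
                )
            )
    return out
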