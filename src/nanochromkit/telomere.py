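"""Detection, masking and classification of telomeric repeats.

Nanochromosomes carry C4A4-type telomeres: the 5' repeat core is
``CCCCAAAACCCC`` (optionally preceded by a run of A/C bases) and the 3'
core is its reverse complement ``GGGGTTTTGGGG`` (optionally followed by
a run of G/T bases).  The core tolerates a configurable number of
mismatched ("degenerate") bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import dna

TEL5_CORE = "CCCCAAAACCCC"
TEL3_CORE = "GGGGTTTTGGGG"
DEFAULT_MAX_DEGENERATE = 2
TERMINAL_WINDOW = 100

_CORE5 = dna.encode(TEL5_CORE)
_CORE3 = dna.encode(TEL3_CORE)
_PREFIX5 = frozenset("AC")
_SUFFIX3 = frozenset("GT")


@dataclass(frozen=True)
class TelomereSpan:
    """A telomeric repeat occurrence, 0-based half-open coordinates."""

    contig_id: str
    start: int
    end: int
    polarity: str  # "5" or "3"
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty telomere span")
        if self.polarity not in ("5", "3"):
            raise ValueError(f"bad polarity {self.polarity!r}")


@dataclass(frozen=True)
class TelomereClass:
    contig_id: str
    n5: int
    n3: int
    class_label: str  # zero | one | two | multi


@dataclass
class MaskedRead:
    """Result of masking a read: sequence plus which ends were masked."""

    seq: str
    lead: bool  # a telomeric span touched the read's left end
    trail: bool  # a telomeric span touched the read's right end


def _core_hits(codes: np.ndarray, core: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """(position, n_mismatch) of all core occurrences with <= max_mm mismatches."""
    n, k = len(codes), len(core)
    if n < k:
        return []
    mm = np.zeros(n - k + 1, dtype=np.int16)
    for j in range(k):
        col = codes[j : n - k + 1 + j]
        mm += (col != core[j]) | (col == 4)
    idx = np.nonzero(mm <= max_mm)[0]
    return [(int(i), int(mm[i])) for i in idx]


def _merge_spans(spans: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Merge overlapping/adjacent (start, end, n_deg) triples."""
    if not spans:
        return []
    spans.sort()
    merged = [spans[0]]
    for s, e, d in spans[1:]:
        ps, pe, pd = merged[-1]
        if s <= pe:
            merged[-1] = (ps, max(pe, e), max(pd, d))
        else:
            merged.append((s, e, d))
    return merged


def find_telomeres(
    sequence: str,
    contig_id: str = "",
    max_degenerate: int = DEFAULT_MAX_DEGENERATE,
) -> list[TelomereSpan]:
    """All non-overlapping telomeric spans in *sequence*.

    A 5' span is a core ``CCCCAAAACCCC`` occurrence (<= *max_degenerate*
    mismatches) together with the maximal run of A/C bases immediately
    preceding it; a 3' span is the reverse-complement core plus the
    maximal G/T run following it.  Overlapping occurrences of the same
    polarity (telomere tracts) are merged into a single span.
    """
    seq = sequence.upper()
    dna.check_dna(seq)
    codes = dna.encode(seq)

    spans5: list[tuple[int, int, int]] = []
    for pos, nmm in _core_hits(codes, _CORE5, max_degenerate):
        start = pos
        while start > 0 and seq[start - 1] in _PREFIX5:
            start -= 1
        spans5.append((start, pos + len(TEL5_CORE), nmm))

    spans3: list[tuple[int, int, int]] = []
    for pos, nmm in _core_hits(codes, _CORE3, max_degenerate):
        end = pos + len(TEL3_CORE)
        while end < len(seq) and seq[end] in _SUFFIX3:
            end += 1
        spans3.append((pos, end, nmm))

    out = [
        TelomereSpan(contig_id, s, e, "5", d) for s, e, d in _merge_spans(spans5)
    ] + [TelomereSpan(contig_id, s, e, "3", d) for s, e, d in _merge_spans(spans3)]
    out.sort(key=lambda t: (t.start, t.polarity))
    return out


def mask_telomeres(sequence: str, max_degenerate: int = DEFAULT_MAX_DEGENERATE) -> str:
    """Replace every telomeric span with a single ``N``.

    Iterates to a fixed point, so the operation is idempotent:
    ``mask(mask(x)) == mask(x)``.
    """
    seq = sequence.upper()
    while True:
        spans = find_telomeres(seq, max_degenerate=max_degenerate)
        if not spans:
            return seq
        parts = []
        prev = 0
        for sp in spans:
            parts.append(seq[prev : sp.start])
            parts.append("N")
            prev = sp.end
        parts.append(seq[prev:])
        seq = "".join(parts)


def mask_read(sequence: str, max_degenerate: int = DEFAULT_MAX_DEGENERATE) -> MaskedRead:
    """Mask a read and report whether its left/right end was telomeric."""
    seq = sequence.upper()
    spans = find_telomeres(seq, max_degenerate=max_degenerate)
    lead = any(sp.start == 0 for sp in spans)
    trail = any(sp.end == len(seq) for sp in spans)
    return MaskedRead(mask_telomeres(seq, max_degenerate), lead, trail)


def _classify_one(
    contig_id: str,
    seq: str,
    max_degenerate: int,
) -> tuple[TelomereClass, list[TelomereSpan]]:
    spans = find_telomeres(seq, contig_id, max_degenerate)
    n5 = sum(1 for s in spans if s.polarity == "5")
    n3 = sum(1 for s in spans if s.polarity == "3")
    if n5 >= 2 or n3 >= 2:
        label = "multi"
    elif n5 + n3 == 2:
        label = "two"
    elif n5 + n3 == 1:
        label = "one"
    else:
        label = "zero"
    return TelomereClass(contig_id, n5, n3, label), spans


def classify_contigs(
    contigs: Sequence[tuple[str, str]],
    max_degenerate: int = DEFAULT_MAX_DEGENERATE,
) -> list[TelomereClass]:
    """Assign every contig a telomere class (zero/one/two/multi)."""
    return [_classify_one(cid, seq, max_degenerate)[0] for cid, seq in contigs]


def n50(lengths: Iterable[int]) -> int:
    """Length L such that contigs >= L cover at least half the assembly.

    Ties resolve to the smaller qualifying length (the length at which
    the cumulative sum first reaches half the total).
    """
    ls = sorted(lengths, reverse=True)
    if not ls:
        raise ValueError("empty length set")
    half = sum(ls) / 2
    acc = 0
    for length in ls:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def is_terminal(span: TelomereSpan, contig_len: int, window: int = TERMINAL_WINDOW) -> bool:
    """True when the span lies within *window* bp of a contig end."""
    return span.start < window or span.end > contig_len - window


def assembly_stats(
    contigs: Sequence[tuple[str, str]],
    max_degenerate: int = DEFAULT_MAX_DEGENERATE,
    terminal_window: int = TERMINAL_WINDOW,
) -> dict:
    """Assembly summary: counts and mean lengths per telomere class,
    overall N50 and the terminal-telomere count.
    """
    if not contigs:
        raise ValueError("empty contig set")
    per_class: dict[str, list[int]] = {"zero": [], "one": [], "two": [], "multi": []}
    n_telomeres = 0
    lengths = []
    for cid, seq in contigs:
        tc, spans = _classify_one(cid, seq, max_degenerate)
        per_class[tc.class_label].append(len(seq))
        n_telomeres += sum(1 for sp in spans if is_terminal(sp, len(seq), terminal_window))
        lengths.append(len(seq))
    stats = {
        "n_contigs": len(contigs),
        "assembly_size_bp": int(sum(lengths)),
        "mean_contig_length_bp": float(np.mean(lengths)),
        "n50_bp": n50(lengths),
        "n_telomeres": n_telomeres,
    }
    for label, ls in per_class.items():
        stats[f"n_{label}_telomere_contigs"] = len(ls)
        stats[f"mean_{label}_telomere_contig_length_bp"] = (
            float(np.mean(ls)) if ls else float("nan")
        )
    return stats


def make_telomere(length_bp: int, polarity: str = "5") -> str:
    """A C4A4-pattern telomere of the requested length (>= core length)."""
    if length_bp < len(TEL5_CORE):
        raise ValueError("telomere shorter than repeat core")
    tel5 = ("CCCCAAAA" * (length_bp // 8 + 2))[:length_bp]
    return tel5 if polarity == "5" else dna.revcomp(tel5)
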