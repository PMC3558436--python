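"""Variant-site calling, heterozygosity classification and population
genetics.

Variant sites come from pileup columns of telomere-masked read
alignments (>= 20x coverage, >= 5% minor frequency, >= 40 bp from the
contig ends).  A nanochromosome is heterozygous when variants occupy
>= 0.5% of the examined positions.  Diversity at 4-fold synonymous
sites uses the ciliate nuclear genetic code (translation table 6,
TAA/TAG = Gln) and feeds the effective-population-size estimate
Ne = pi4s / (4 mu).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Data import CodonTable

from . import dna

MIN_COVERAGE = 20
MIN_VARIANT_FREQ = 0.05
END_MARGIN = 40
HET_THRESHOLD_PCT = 0.5
DEFAULT_MU = 1e-9
CILIATE_TABLE_ID = 6


# ---------------------------------------------------------------------------
# pileups and variant sites


def pileup_counts(contig_len: int, alignments: Iterable) -> np.ndarray:
    """Per-column A/C/G/T counts, shape (4, contig_len).

    Alignment records need start + seq (forward-strand oriented);
    N bases are skipped.
    """
    positions: list[np.ndarray] = []
    codes: list[np.ndarray] = []
    for a in alignments:
        if not a.seq:
            continue
        c = dna.encode(a.seq)
        n = min(len(c), contig_len - a.start)
        if n <= 0 or a.start < 0:
            continue
        codes.append(c[:n])
        positions.append(np.arange(a.start, a.start + n))
    counts = np.zeros((4, contig_len), dtype=np.int64)
    if not positions:
        return counts
    pos = np.concatenate(positions)
    cod = np.concatenate(codes).astype(np.int64)
    keep = cod < 4
    flat = np.bincount(cod[keep] * contig_len + pos[keep], minlength=4 * contig_len)
    return flat.reshape(4, contig_len)


@dataclass(frozen=True)
class VariantSite:
    contig_id: str
    pos: int
    coverage: int
    base_counts: tuple[int, int, int, int]
    minor_freq: float  # second-most-frequent base count / coverage


def _examined_mask(counts: np.ndarray, min_cov: int, end_margin: int) -> np.ndarray:
    cov = counts.sum(axis=0)
    mask = cov >= min_cov
    mask[:end_margin] = False
    if end_margin > 0:
        mask[-end_margin:] = False
    return mask


def call_variant_sites(
    counts: np.ndarray,
    contig_id: str = "",
    min_cov: int = MIN_COVERAGE,
    min_freq: float = MIN_VARIANT_FREQ,
    end_margin: int = END_MARGIN,
    min_var_reads: int = 2,
) -> list[VariantSite]:
    """Substitution variant sites from a pileup count matrix.

    *min_var_reads* is the absolute supporting-read floor (VarScan-style
    default of 2), which stops single sequencing errors at minimum-depth
    columns from passing the 5% frequency filter.
    """
    cov = counts.sum(axis=0)
    srt = np.sort(counts, axis=0)
    minor = srt[-2]  # second-most-frequent base
    mask = _examined_mask(counts, min_cov, end_margin)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(cov > 0, minor / np.maximum(cov, 1), 0.0)
    idx = np.nonzero(mask & (freq >= min_freq) & (minor >= min_var_reads))[0]
    return [
        VariantSite(
            contig_id,
            int(p),
            int(cov[p]),
            tuple(int(x) for x in counts[:, p]),
            float(freq[p]),
        )
        for p in idx
    ]


def n_examined_positions(
    counts: np.ndarray,
    min_cov: int = MIN_COVERAGE,
    end_margin: int = END_MARGIN,
) -> int:
    return int(_examined_mask(counts, min_cov, end_margin).sum())


# ---------------------------------------------------------------------------
# heterozygosity classification


@dataclass
class HetReport:
    contig_id: str
    match_status: str  # "matchless" | "matched"
    n_examined: int
    n_variant: int
    het_pct: float  # 100 * n_variant / n_examined, two decimals
    median_variant_freq: float | None
    classification: str | None  # "homozygous" | "heterozygous" | None
    unclassifiable: bool = False


def classify_het(
    contig_id: str,
    n_examined: int,
    n_variant: int,
    match_status: str = "matchless",
    median_variant_freq: float | None = None,
    threshold_pct: float = HET_THRESHOLD_PCT,
) -> HetReport:
    """Heterozygous iff variants occupy >= threshold (0.5%) of examined
    positions; matched contigs are treated as heterozygous downstream."""
    if match_status not in ("matchless", "matched"):
        raise ValueError(f"bad match_status {match_status!r}")
    if n_examined == 0:
        return HetReport(contig_id, match_status, 0, n_variant, float("nan"),
                         median_variant_freq, None, unclassifiable=True)
    het_pct = round(100.0 * n_variant / n_examined, 2)
    cls = "heterozygous" if het_pct >= threshold_pct else "homozygous"
    return HetReport(contig_id, match_status, n_examined, n_variant, het_pct,
                     median_variant_freq, cls)


def classify_het_from_pileup(
    contig_id: str,
    counts: np.ndarray,
    match_status: str = "matchless",
    min_cov: int = MIN_COVERAGE,
    min_freq: float = MIN_VARIANT_FREQ,
    end_margin: int = END_MARGIN,
) -> HetReport:
    sites = call_variant_sites(counts, contig_id, min_cov, min_freq, end_margin)
    med = float(np.median([s.minor_freq for s in sites])) if sites else None
    return classify_het(
        contig_id,
        n_examined_positions(counts, min_cov, end_margin),
        len(sites),
        match_status,
        med,
    )


def genome_homozygous_fraction(reports: Sequence[HetReport]) -> float:
    """Homozygous matchless contigs / all contigs; matched contigs count
    individually and are treated as heterozygous."""
    usable = [r for r in reports if not r.unclassifiable]
    if not usable:
        raise ValueError("no classifiable reports")
    n_hom = sum(
        1
        for r in usable
        if r.match_status == "matchless" and r.classification == "homozygous"
    )
    return n_hom / len(usable)


def variant_freq_profile(
    sites_by_contig: Mapping[str, Sequence[VariantSite]],
    bin_width: float = 0.05,
) -> tuple[dict[str, float], tuple[np.ndarray, np.ndarray]]:
    """Per-contig median minor-variant frequency plus a pooled histogram
    of those medians in 5% bins labelled by lower bound."""
    medians = {
        cid: float(np.median([s.minor_freq for s in sites]))
        for cid, sites in sites_by_contig.items()
        if sites
    }
    edges = np.arange(0.0, 0.5 + bin_width, bin_width)
    hist, _ = np.histogram(list(medians.values()), bins=edges)
    return medians, (edges[:-1], hist)


# ---------------------------------------------------------------------------
# pairwise-alignment heterozygosity


@dataclass(frozen=True)
class PairwiseHet:
    value: float | None
    excluded: bool
    reason: str | None = None
    n_columns: int = 0
    n_substitutions: int = 0


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -5
    al.extend_gap_score = -1
    return al


def pairwise_het(
    seq_a: str,
    seq_b: str,
    max_len_ratio: float = 1.1,
    max_diff: float = 0.15,
) -> PairwiseHet:
    """Substitutions per aligned non-gap column from a global alignment.

    Pairs whose length ratio exceeds *max_len_ratio* or whose difference
    fraction exceeds *max_diff* are excluded and flagged.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if max(len(a), len(b)) > max_len_ratio * min(len(a), len(b)):
        return PairwiseHet(None, True, "length-ratio")
    aln = _aligner().align(a, b)[0]
    subs = cols = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for ca, cb in zip(a[a0:a1], b[b0:b1]):
            cols += 1
            if ca != cb:
                subs += 1
    if cols == 0:
        return PairwiseHet(None, True, "no-aligned-columns")
    frac = subs / cols
    if frac > max_diff:
        return PairwiseHet(None, True, "divergence", cols, subs)
    return PairwiseHet(frac, False, None, cols, subs)


# ---------------------------------------------------------------------------
# 4-fold synonymous diversity


def fourfold_prefixes(table_id: int = CILIATE_TABLE_ID) -> frozenset[str]:
    """Codon prefixes whose third position is 4-fold degenerate."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    out = set()
    for b1 in "ACGT":
        for b2 in "ACGT":
            aas = set()
            ok = True
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                if codon in table.stop_codons:
                    ok = False
                    break
                aas.add(table.forward_table[codon])
            if ok and len(aas) == 1:
                out.add(b1 + b2)
    return frozenset(out)


_FOURFOLD = fourfold_prefixes()


@dataclass
class Pi4SResult:
    mean: float
    per_pair: list[float]
    n_pairs_used: int
    n_pairs_excluded: int


def pi4s(
    cds_pairs: Sequence[tuple[str, str]],
    table_id: int = CILIATE_TABLE_ID,
    max_gap_frac: float = 0.05,
) -> Pi4SResult:
    """Mean over codon-aware aligned CDS pairs of (differences at 4-fold
    degenerate third positions / number of such positions).

    A third position counts when the prefix is 4-fold degenerate in BOTH
    aligned codons; pairs with > 5% gaps or no qualifying site are
    excluded.
    """
    prefixes = _FOURFOLD if table_id == CILIATE_TABLE_ID else fourfold_prefixes(table_id)
    per_pair = []
    excluded = 0
    for a, b in cds_pairs:
        a, b = a.upper(), b.upper()
        if len(a) != len(b):
            raise ValueError("aligned CDS pair with unequal lengths")
        if min(len(a), len(b)) == 0:
            excluded += 1
            continue
        if a.count("-") / len(a) > max_gap_frac or b.count("-") / len(b) > max_gap_frac:
            excluded += 1
            continue
        n_sites = n_diff = 0
        for i in range(0, len(a) - 2, 3):
            ca, cb = a[i : i + 3], b[i : i + 3]
            if "-" in ca or "-" in cb:
                continue
            if ca[:2] in prefixes and cb[:2] in prefixes:
                n_sites += 1
                if ca[2] != cb[2]:
                    n_diff += 1
        if n_sites == 0:
            excluded += 1
            continue
        per_pair.append(n_diff / n_sites)
    if not per_pair:
        return Pi4SResult(float("nan"), [], 0, excluded)
    return Pi4SResult(float(np.mean(per_pair)), per_pair, len(per_pair), excluded)


# ---------------------------------------------------------------------------
# effective population size


@dataclass(frozen=True)
class PopGenEstimate:
    pi4s_raw: float
    correction_factor: float
    pi4s_corrected: float
    mu: float
    ne: float


def effective_pop_size(
    pi4s_raw: float,
    het_read_based: float,
    het_alignment_based: float,
    mu: float = DEFAULT_MU,
) -> PopGenEstimate:
    """Scale the raw 4-fold estimate by read-based/alignment-based
    heterozygosity, then Ne = pi4s_corrected / (4 mu)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if het_alignment_based == 0:
        raise ValueError("alignment-based heterozygosity of zero: factor undefined")
    factor = het_read_based / het_alignment_based
    corrected = pi4s_raw * factor
    ne = corrected / (4.0 * mu)
    if ne < 0 or math.isnan(ne):
        raise ValueError("invalid inputs produced a negative/NaN Ne")
    return PopGenEstimate(pi4s_raw, factor, corrected, mu, ne)
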