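"""Relative nanochromosome copy-number estimation and group comparisons.

Two estimators: interior read depth (telomere-less reads fully inside
the interval 600 bp from either end, normalised by interior length) and
telomeric-read counts per contig.  Relative copy number is reads/bp
scaled to mean 1 over the qualifying (>= 1,800 bp) contig set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

MIN_CONTIG_LEN = 1800
END_MARGIN = 600


@dataclass(frozen=True)
class CopyNumberEstimate:
    contig_id: str
    contig_len: int
    interior_reads: int
    interior_len_bp: int
    reads_per_bp: float
    telomeric_reads_5: int
    telomeric_reads_3: int
    relative_cn: float = float("nan")

    @property
    def telomeric_reads(self) -> int:
        return self.telomeric_reads_5 + self.telomeric_reads_3


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    D: float
    p: float
    mean_a: float
    mean_b: float
    ratio: float  # mean_a / mean_b
    n_a: int = 0
    n_b: int = 0


def estimate_cn(
    contig_id: str,
    contig_len: int,
    alignments: Iterable,
    telo_reads: Iterable | None = None,
    min_len: int = MIN_CONTIG_LEN,
    margin: int = END_MARGIN,
) -> CopyNumberEstimate | None:
    """Raw (un-normalised) estimate; returns None for short contigs.

    A read counts as interior when it is non-telomeric and its alignment
    lies entirely within [margin, contig_len - margin).  *telo_reads*
    yields objects with a ``polarity`` attribute ("5"/"3").
    """
    if contig_len < min_len:
        return None
    lo, hi = margin, contig_len - margin
    interior = sum(
        1
        for a in alignments
        if a.contig_id == contig_id
        and not a.is_telomeric
        and a.start >= lo
        and a.end <= hi
    )
    t5 = t3 = 0
    for tr in telo_reads or ():
        if tr.polarity == "5":
            t5 += 1
        else:
            t3 += 1
    interior_len = contig_len - 2 * margin
    return CopyNumberEstimate(
        contig_id, contig_len, interior, interior_len,
        interior / interior_len, t5, t3,
    )


def finalize_relative(estimates: Sequence[CopyNumberEstimate]) -> list[CopyNumberEstimate]:
    """Fill relative_cn = reads_per_bp / mean reads_per_bp (mean-1
    normalisation over the qualifying set)."""
    if not estimates:
        return []
    mean = float(np.mean([e.reads_per_bp for e in estimates]))
    if mean == 0:
        raise ValueError("zero mean reads_per_bp")
    return [replace(e, relative_cn=e.reads_per_bp / mean) for e in estimates]


@dataclass(frozen=True)
class CrossValidation:
    r_depth_vs_telomeric: float
    slope_5_vs_3: float
    r2_5_vs_3: float
    n: int


def cross_validate(estimates: Sequence[CopyNumberEstimate]) -> CrossValidation:
    """Pearson r between interior reads/bp and total telomeric reads,
    plus a through-origin regression of 5' on 3' telomeric reads."""
    if len(estimates) < 10:
        raise ValueError("need >= 10 estimates")
    depth = np.array([e.reads_per_bp for e in estimates])
    telo = np.array([e.telomeric_reads for e in estimates], dtype=float)
    if depth.std() == 0 or telo.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(stats.pearsonr(depth, telo).statistic)
    x = np.array([e.telomeric_reads_3 for e in estimates], dtype=float)
    y = np.array([e.telomeric_reads_5 for e in estimates], dtype=float)
    denom = float(np.sum(x * x))
    slope = float(np.sum(x * y) / denom) if denom > 0 else float("nan")
    resid = y - slope * x
    tot = float(np.sum(y**2))
    r2 = 1.0 - float(np.sum(resid**2)) / tot if tot > 0 else float("nan")
    return CrossValidation(r, slope, r2, len(estimates))


def ks_one_sided(
    values_a: Sequence[float],
    values_b: Sequence[float],
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """One-sided two-sample K-S with the alternative that *a* is
    stochastically greater than *b*.

    D+ = max over pooled points of ECDF_b(x) - ECDF_a(x); asymptotic
    p = exp(-2 D^2 m n / (m + n)).
    """
    a = np.sort(np.asarray(values_a, dtype=float))
    b = np.sort(np.asarray(values_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    ecdf_a = np.searchsorted(a, pooled, side="right") / len(a)
    ecdf_b = np.searchsorted(b, pooled, side="right") / len(b)
    d = float(max(np.max(ecdf_b - ecdf_a), 0.0))
    m, n = len(a), len(b)
    p = float(min(1.0, math.exp(-2.0 * d * d * m * n / (m + n))))
    mean_a, mean_b = float(a.mean()), float(b.mean())
    ratio = mean_a / mean_b if mean_b != 0 else float("inf")
    return GroupComparison(group_a, group_b, d, p, mean_a, mean_b, ratio, m, n)


def mean_ratio(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    return float(np.mean(values_a)) / float(np.mean(values_b))


def group_report(
    estimates: Sequence[CopyNumberEstimate],
    labels: Mapping[str, set[str]],
    metric: str = "relative_cn",
) -> list[dict]:
    """Per-label comparison of flagged vs unflagged contigs.

    *labels* maps contig_id -> set of flags (e.g. {"altfrag"},
    {"ribosomal"}).  For each flag the flagged group is compared against
    the complement with a one-sided K-S (alternative: flagged greater).
    Groups with < 2 members are skipped.
    """
    all_flags = sorted({f for fs in labels.values() for f in fs})
    rows = []
    for flag in all_flags:
        in_g = [e for e in estimates if flag in labels.get(e.contig_id, ())]
        out_g = [e for e in estimates if flag not in labels.get(e.contig_id, ())]
        if len(in_g) < 2 or len(out_g) < 2:
            continue
        va = [getattr(e, metric) for e in in_g]
        vb = [getattr(e, metric) for e in out_g]
        ks = ks_one_sided(va, vb, flag, f"non-{flag}")
        ta = [float(e.telomeric_reads) for e in in_g]
        tb = [float(e.telomeric_reads) for e in out_g]
        rows.append(
            {
                "group": flag,
                "n_in": len(in_g),
                "n_out": len(out_g),
                "mean_in": ks.mean_a,
                "sd_in": float(np.std(va)),
                "mean_out": ks.mean_b,
                "sd_out": float(np.std(vb)),
                "ratio": ks.ratio,
                "mean_telomeric_in": float(np.mean(ta)),
                "mean_telomeric_out": float(np.mean(tb)),
                "telomeric_ratio": float(np.mean(ta)) / float(np.mean(tb))
                if np.mean(tb) > 0
                else float("inf"),
                "ks_D": ks.D,
                "ks_p": ks.p,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# haploid genome size helpers


def haploid_genome_size_mb(n_nanochromosomes: float, mean_len_bp: float) -> float:
    """Haploid genome size in Mb = nanochromosome count x mean length."""
    if n_nanochromosomes <= 0 or mean_len_bp <= 0:
        raise ValueError("inputs must be positive")
    return n_nanochromosomes * mean_len_bp / 1e6


def estimate_haploid_count(
    n_two_telomere: int,
    n_multi_telomere: int,
    n_one_telomere: int,
    homozygous_fraction: float,
    collapsed_allele_fraction: float = 0.25,
) -> float:
    """Haploid nanochromosome count from telomere-class contig counts.

    Assumption-laden estimate over all telomere-bearing contigs: a
    homozygous nanochromosome contributes one contig while a
    heterozygous one contributes two, except for the fraction of
    heterozygous loci whose alleles collapsed during assembly (~1/4).
    """
    if not 0 <= homozygous_fraction <= 1:
        raise ValueError("homozygous_fraction outside [0, 1]")
    contig_equivalents = n_two_telomere + n_multi_telomere + n_one_telomere
    het = 1.0 - homozygous_fraction
    per_locus = homozygous_fraction + het * (2.0 - collapsed_allele_fraction)
    return contig_equivalents / per_locus
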