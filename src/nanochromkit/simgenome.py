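"""Synthetic nanochromosome genome and read simulator with ground truth.

Generates telomere-capped loci with a configurable homozygous /
heterozygous allele structure, alternative-fragmentation isoforms,
right-skewed relative copy number, paired-end / single-end reads with a
normal outer-distance model, an optional subtelomeric coverage gap, a
dedicated telomeric-read stream and a telomere-paired library whose two
reads start inside the two telomeres of one isoform.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dna, telomere

_MUT = {0: "CGT", 1: "AGT", 2: "ACT", 3: "ACG"}


@dataclass
class SimParams:
    """Simulation parameters; one global seed governs all randomness."""

    n_loci: int = 200
    length_mean_bp: float = 3200.0
    length_sd_bp: float = 1200.0
    het_locus_fraction: float = 0.58
    snp_rate: float = 0.04
    minor_allele_fraction: float = 0.5
    altfrag_fraction: float = 0.10
    altfrag_short_isoform_share: float = 0.35
    copy_number_lognormal_sigma: float = 0.5
    pe_outer_mean_bp: float = 362.0
    pe_outer_sd_bp: float = 52.0
    read_len_bp: int = 100
    coverage_x: float = 30.0
    gap_depletion_prob: float = 0.0
    gap_offset_bp: int = 100
    gap_len_bp: int = 160
    telomere_len_bp: int = 20
    base_error_rate: float = 0.002
    telo_read_depth: float = 20.0
    telo_pair_depth: float = 10.0
    noisy_quality: bool = False
    intra_cds_altfrag: bool = False
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "het_locus_fraction": self.het_locus_fraction,
            "snp_rate": self.snp_rate,
            "altfrag_fraction": self.altfrag_fraction,
            "altfrag_short_isoform_share": self.altfrag_short_isoform_share,
            "gap_depletion_prob": self.gap_depletion_prob,
            "base_error_rate": self.base_error_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if not 0.0 < self.minor_allele_fraction <= 0.5:
            raise ValueError("minor_allele_fraction must be in (0, 0.5]")
        for name in ("length_mean_bp", "length_sd_bp", "coverage_x",
                     "copy_number_lognormal_sigma", "pe_outer_mean_bp",
                     "pe_outer_sd_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.read_len_bp < 30:
            raise ValueError("read_len_bp too short")
        if self.telomere_len_bp < len(telomere.TEL5_CORE):
            raise ValueError("telomere_len_bp shorter than repeat core")
        if self.length_mean_bp < 2 * self.telomere_len_bp + 50:
            raise ValueError(
                "degenerate params: length_mean_bp < 2*telomere_len_bp + 50"
            )

    def __post_init__(self) -> None:
        self.validate()


@dataclass(frozen=True)
class FragSiteTruth:
    """An internal fragmentation site in reference (contig) coordinates."""

    pos: int
    polarity: str  # "5": retained sequence to the right; "3": to the left


@dataclass(frozen=True)
class IsoformTruth:
    """Retained reference interval [start, end) of one isoform.

    start == 0 / end == locus length means the native terminal telomere
    is retained; otherwise a telomere is appended at the cut.
    """

    start: int
    end: int
    weight: float


@dataclass
class LocusTruth:
    locus_id: str
    length: int
    alleles: list[str]
    allele_weights: list[float]
    copy_number: float
    frag_sites: list[FragSiteTruth]
    isoforms: list[IsoformTruth]
    cds: list[tuple[int, int]]
    telomere_len: int

    def isoform_seq(self, allele_idx: int, iso: IsoformTruth) -> str:
        ref = self.alleles[allele_idx]
        left = "" if iso.start == 0 else telomere.make_telomere(self.telomere_len, "5")
        right = "" if iso.end == self.length else telomere.make_telomere(self.telomere_len, "3")
        return left + ref[iso.start : iso.end] + right

    def tas_truth(self) -> list[tuple[int, str]]:
        """(position, polarity) of every telomere addition site, terminal
        sites included."""
        t = self.telomere_len
        sites = [(t, "5"), (self.length - t, "3")]
        sites += [(fs.pos, fs.polarity) for fs in self.frag_sites]
        return sorted(sites)


@dataclass
class SimTruth:
    params: SimParams
    loci: list[LocusTruth]

    def contigs(self) -> list[tuple[str, str]]:
        """The reference contig set: the primary allele of every locus."""
        return [(lt.locus_id, lt.alleles[0]) for lt in self.loci]

    def relative_copy_numbers(self) -> dict[str, float]:
        mean = float(np.mean([lt.copy_number for lt in self.loci]))
        return {lt.locus_id: lt.copy_number / mean for lt in self.loci}


@dataclass
class SimRead:
    """A simulated read with its ground-truth placement.

    ref_start/ref_end give the non-telomeric portion of the read on the
    source contig's forward strand (None when the read maps nowhere,
    e.g. it lies entirely in an appended telomere).  aln_seq is that
    portion, forward-strand oriented, with sequencing errors applied.
    """

    read_id: str
    seq: str
    qual: str
    locus_id: str
    ref_start: int | None
    ref_end: int | None
    strand: str
    n_errors: int = 0
    is_telomeric: bool = False
    telo_polarity: str | None = None
    mate_id: str | None = None
    aln_seq: str | None = None


@dataclass
class ReadSet:
    pe1: list[SimRead] = field(default_factory=list)
    pe2: list[SimRead] = field(default_factory=list)
    se: list[SimRead] = field(default_factory=list)
    telo: list[SimRead] = field(default_factory=list)
    tp1: list[SimRead] = field(default_factory=list)
    tp2: list[SimRead] = field(default_factory=list)

    def all_reads(self) -> list[SimRead]:
        return self.pe1 + self.pe2 + self.se + self.telo + self.tp1 + self.tp2


# ---------------------------------------------------------------------------
# genome simulation


_CORE5_CODES = dna.encode(telomere.TEL5_CORE)
_CORE3_CODES = dna.encode(telomere.TEL3_CORE)


def _scrub_telomere_like(seq_codes: np.ndarray, rng: np.random.Generator,
                         lo: int, hi: int) -> None:
    """Destroy accidental telomere-core lookalikes inside [lo, hi).

    Plants three mismatches-to-motif inside the detected 12 bp core so a
    2-mismatch-tolerant scan can never re-find it at the same offset.
    """
    while True:
        sub = dna.decode(seq_codes[lo:hi])
        spans = telomere.find_telomeres(sub)
        if not spans:
            return
        for sp in spans:
            # the core sits at the non-extended edge of the span
            core_start = lo + (sp.end - 12 if sp.polarity == "5" else sp.start)
            motif = _CORE5_CODES if sp.polarity == "5" else _CORE3_CODES
            for off in (2, 6, 10):
                p = core_start + off
                if not lo <= p < hi:
                    continue
                forbidden = {int(motif[off]), int(seq_codes[p])}
                options = [b for b in range(4) if b not in forbidden]
                seq_codes[p] = options[int(rng.integers(0, len(options)))]


def _gene_layout(rng: np.random.Generator, length: int, tel: int) -> list[tuple[int, int]]:
    """CDS intervals: subtelomeric margins ~100 bp, spacers ~200 bp."""
    margin = 100
    lo = tel + margin
    hi = length - tel - margin
    usable = hi - lo
    if usable < 300:
        return []
    spacer = 200
    n_genes = max(1, usable // 1200)
    if usable >= 900:
        n_genes = max(2, n_genes)
    while n_genes > 1 and usable - (n_genes - 1) * spacer < n_genes * 150:
        n_genes -= 1
    gene_len = (usable - (n_genes - 1) * spacer) // n_genes
    gene_len -= gene_len % 3
    cds = []
    pos = lo
    for _ in range(n_genes):
        cds.append((pos, pos + gene_len))
        pos += gene_len + spacer
    return cds


def _pick_frag_sites(
    rng: np.random.Generator,
    length: int,
    tel: int,
    cds: list[tuple[int, int]],
    intra_cds: bool,
) -> list[FragSiteTruth]:
    """1-2 internal sites, >= 300 bp from contig ends, >= 200 bp apart,
    placed in spacer (non-CDS) regions unless *intra_cds* is set."""
    end_margin = 300
    lo, hi = end_margin, length - end_margin
    if hi - lo < 50:
        return []
    if intra_cds:
        regions = [(max(s, lo), min(e, hi)) for s, e in cds]
    else:
        bounds = [tel] + [x for se in cds for x in se] + [length - tel]
        regions = []
        for i in range(0, len(bounds), 2):
            s, e = bounds[i], bounds[i + 1]
            regions.append((max(s + 10, lo), min(e - 10, hi)))
    regions = [(s, e) for s, e in regions if e - s > 10]
    if not regions:
        return []
    n_sites = 1 if rng.random() < 0.75 else 2
    sites: list[FragSiteTruth] = []
    for _ in range(n_sites):
        ok = [
            (s, e)
            for s, e in regions
            if all(not (s - 200 < fs.pos < e + 200) for fs in sites)
        ]
        if not ok:
            break
        s, e = ok[rng.integers(0, len(ok))]
        pos = int(rng.integers(s, e))
        if any(abs(pos - fs.pos) < 200 for fs in sites):
            continue
        polarity = "3" if rng.random() < 0.5 else "5"
        sites.append(FragSiteTruth(pos, polarity))
    return sorted(sites, key=lambda f: f.pos)


def _isoforms_from_sites(
    sites: list[FragSiteTruth], length: int, share: float
) -> list[IsoformTruth]:
    if not sites:
        return [IsoformTruth(0, length, 1.0)]
    per_site = min(share, 0.9) / len(sites)
    isos = []
    for fs in sites:
        if fs.polarity == "3":
            isos.append(IsoformTruth(0, fs.pos, per_site))
        else:
            isos.append(IsoformTruth(fs.pos, length, per_site))
    isos.append(IsoformTruth(0, length, 1.0 - per_site * len(sites)))
    return isos


def _locus_rng(seed: int, stream: int, idx: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, idx])


def simulate_genome(params: SimParams) -> tuple[SimTruth, list[tuple[str, str]]]:
    """Simulate *n_loci* telomere-capped loci with ground-truth tables.

    Returns the truth object and the reference contig set (the primary
    allele of each locus).
    """
    params.validate()
    tel = params.telomere_len_bp
    tel5 = telomere.make_telomere(tel, "5")
    tel3 = telomere.make_telomere(tel, "3")
    min_len = max(2 * tel + 50, 400)

    # log-normal length with the requested mean/SD
    m, s = params.length_mean_bp, params.length_sd_bp
    sigma2 = np.log(1.0 + (s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0

    loci: list[LocusTruth] = []
    for i in range(params.n_loci):
        rng = _locus_rng(params.seed, 1, i)
        length = int(rng.lognormal(mu, np.sqrt(sigma2)))
        length = int(np.clip(length, min_len, 12 * m))

        codes = np.empty(length, dtype=np.uint8)
        codes[:tel] = dna.encode(tel5)
        codes[length - tel :] = dna.encode(tel3)
        codes[tel : length - tel] = rng.integers(0, 4, length - 2 * tel, dtype=np.uint8)
        _scrub_telomere_like(codes, rng, tel, length - tel)
        ref = dna.decode(codes)

        cds = _gene_layout(rng, length, tel)

        alleles = [ref]
        weights = [1.0]
        if rng.random() < params.het_locus_fraction:
            alt = codes.copy()
            hit = np.nonzero(rng.random(length - 2 * tel) < params.snp_rate)[0] + tel
            for p in hit:
                alt[p] = (alt[p] + 1 + rng.integers(0, 3)) % 4
            _scrub_telomere_like(alt, rng, tel, length - tel)
            alleles = [ref, dna.decode(alt)]
            maf = params.minor_allele_fraction
            weights = [1.0 - maf, maf]

        frag_sites: list[FragSiteTruth] = []
        if rng.random() < params.altfrag_fraction:
            frag_sites = _pick_frag_sites(rng, length, tel, cds, params.intra_cds_altfrag)
        isoforms = _isoforms_from_sites(frag_sites, length, params.altfrag_short_isoform_share)

        cn = float(rng.lognormal(
            -params.copy_number_lognormal_sigma**2 / 2.0,
            params.copy_number_lognormal_sigma,
        ))

        loci.append(
            LocusTruth(
                locus_id=f"locus{i:05d}",
                length=length,
                alleles=alleles,
                allele_weights=weights,
                copy_number=cn,
                frag_sites=frag_sites,
                isoforms=isoforms,
                cds=cds,
                telomere_len=tel,
            )
        )
    truth = SimTruth(params, loci)
    return truth, truth.contigs()


# ---------------------------------------------------------------------------
# read simulation


def _iso_to_ref(lt: LocusTruth, iso: IsoformTruth, q0: int, q1: int) -> tuple[int | None, int | None]:
    """Map isoform-coordinate window [q0, q1) to reference coordinates,
    clipped to the retained non-appended interval."""
    off = 0 if iso.start == 0 else lt.telomere_len
    interior_len = iso.end - iso.start
    a = max(q0, off)
    b = min(q1, off + interior_len)
    if b <= a:
        return None, None
    return iso.start + (a - off), iso.start + (b - off)


def _apply_errors(window: str, rng: np.random.Generator, rate: float) -> tuple[str, int]:
    n_err = rng.binomial(len(window), rate) if rate > 0 else 0
    if n_err == 0:
        return window, 0
    chars = list(window)
    pos = rng.choice(len(chars), size=n_err, replace=False)
    for p in pos:
        c = chars[p]
        if c in "ACGT":
            chars[p] = _MUT["ACGT".index(c)][rng.integers(0, 3)]
    return "".join(chars), int(n_err)


def _qual(params: SimParams, n: int, rng: np.random.Generator) -> str:
    q30 = chr(33 + 30) * n
    if not params.noisy_quality:
        return q30
    if rng.random() < 0.3:
        tail = int(rng.integers(20, 41))
        tail = min(tail, n - 1)
        return chr(33 + 30) * (n - tail) + chr(33 + 8) * tail
    return q30


def _telomeric_overlap(q0: int, q1: int, iso_len: int, tel: int) -> bool:
    """Read window overlaps a telomere of the isoform by >= 12 bp."""
    left = min(q1, tel) - q0
    right = q1 - max(q0, iso_len - tel)
    return max(left, right) >= 12


def simulate_reads(truth: SimTruth, params: SimParams | None = None,
                   streams: tuple[str, ...] = ("pe", "se", "telo", "tp")) -> ReadSet:
    """Draw reads per locus proportional to copy number x allele weight x
    isoform weight.  *streams* selects which libraries to generate.
    """
    params = params or truth.params
    if params.coverage_x <= 0:
        raise ValueError("coverage_x must be > 0")
    rl = params.read_len_bp
    tel = params.telomere_len_bp
    cn_rel = truth.relative_copy_numbers()
    out = ReadSet()

    for li, lt in enumerate(truth.loci):
        rng = _locus_rng(params.seed, 7, li)
        for ai, aw in enumerate(lt.allele_weights):
            for fi, iso in enumerate(lt.isoforms):
                w = cn_rel[lt.locus_id] * aw * iso.weight
                iso_seq = lt.isoform_seq(ai, iso)
                iso_len = len(iso_seq)
                if iso_len < rl:
                    continue
                tag = f"{lt.locus_id}_a{ai}f{fi}"

                def emit(q0: int, q1: int, strand: str, rid: str,
                         telo_polarity: str | None = None,
                         mate_id: str | None = None) -> SimRead:
                    window, n_err = _apply_errors(iso_seq[q0:q1], rng, params.base_error_rate)
                    r0, r1 = _iso_to_ref(lt, iso, q0, q1)
                    aln = None
                    if r0 is not None:
                        off = 0 if iso.start == 0 else lt.telomere_len
                        a = (r0 - iso.start) + off - q0
                        b = (r1 - iso.start) + off - q0
                        aln = window[a:b]
                    seq = window if strand == "+" else dna.revcomp(window)
                    return SimRead(
                        read_id=rid,
                        seq=seq,
                        qual=_qual(params, len(seq), rng),
                        locus_id=lt.locus_id,
                        ref_start=r0,
                        ref_end=r1,
                        strand=strand,
                        n_errors=n_err,
                        is_telomeric=_telomeric_overlap(q0, q1, iso_len, tel),
                        telo_polarity=telo_polarity,
                        mate_id=mate_id,
                        aln_seq=aln,
                    )

                if "pe" in streams and iso_len >= 2 * rl:
                    n_pairs = rng.poisson(params.coverage_x * w * iso_len / (2 * rl))
                    frags = rng.normal(params.pe_outer_mean_bp, params.pe_outer_sd_bp, n_pairs)
                    frags = np.clip(frags, 2 * rl, iso_len).astype(np.int64)
                    starts = rng.integers(0, iso_len - frags + 1)
                    keep_u = rng.random(n_pairs)
                    g0 = tel + params.gap_offset_bp
                    g1 = g0 + params.gap_len_bp
                    h1 = iso_len - g0
                    h0 = iso_len - g1
                    for j in range(n_pairs):
                        s, f = int(starts[j]), int(frags[j])
                        e = s + f
                        if params.gap_depletion_prob > 0:
                            in_gap = (g0 <= s < g1) or (g0 <= e < g1) or \
                                     (h0 <= s < h1) or (h0 <= e < h1)
                            if in_gap and keep_u[j] < params.gap_depletion_prob:
                                continue
                        rid = f"{tag}_p{j}"
                        r1_ = emit(s, s + rl, "+", rid + "/1", mate_id=rid + "/2")
                        r2_ = emit(e - rl, e, "-", rid + "/2", mate_id=rid + "/1")
                        out.pe1.append(r1_)
                        out.pe2.append(r2_)

                if "se" in streams:
                    n_se = rng.poisson(params.coverage_x * w * iso_len / rl)
                    starts = rng.integers(0, iso_len - rl + 1, n_se)
                    strands = rng.random(n_se) < 0.5
                    for j in range(n_se):
                        s = int(starts[j])
                        out.se.append(
                            emit(s, s + rl, "+" if strands[j] else "-", f"{tag}_s{j}")
                        )

                if "telo" in streams:
                    # reads anchored inside each telomere (>= full core retained)
                    max_u = tel - len(telomere.TEL5_CORE)
                    n5 = rng.poisson(params.telo_read_depth * w)
                    for j in range(n5):
                        u = int(rng.integers(0, max_u + 1))
                        if u + rl <= iso_len:
                            out.telo.append(
                                emit(u, u + rl, "+", f"{tag}_t5{j}", telo_polarity="5")
                            )
                    n3 = rng.poisson(params.telo_read_depth * w)
                    for j in range(n3):
                        u = int(rng.integers(0, max_u + 1))
                        if iso_len - u - rl >= 0:
                            out.telo.append(
                                emit(iso_len - u - rl, iso_len - u, "-",
                                     f"{tag}_t3{j}", telo_polarity="3")
                            )

                if "tp" in streams and iso_len >= 2 * rl:
                    n_tp = rng.poisson(params.telo_pair_depth * w)
                    for j in range(n_tp):
                        rid = f"{tag}_q{j}"
                        out.tp1.append(
                            emit(0, rl, "+", rid + "/1",
                                 telo_polarity="5", mate_id=rid + "/2")
                        )
                        out.tp2.append(
                            emit(iso_len - rl, iso_len, "-", rid + "/2",
                                 telo_polarity="3", mate_id=rid + "/1")
                        )
    return out


# ---------------------------------------------------------------------------
# output

def write_fasta(path: str | Path, contigs: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str | Path, reads: list[SimRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


def write_truth_tables(outdir: str | Path, truth: SimTruth) -> None:
    """Ground-truth tables: loci TSV, fragmentation-site BED, isoform TSV,
    CDS GFF3, allele FASTA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "loci.tsv", "w") as fh:
        fh.write("locus_id\tlength\tn_alleles\tallele_weights\tcopy_number\tn_frag_sites\n")
        for lt in truth.loci:
            fh.write(
                f"{lt.locus_id}\t{lt.length}\t{len(lt.alleles)}\t"
                f"{','.join(f'{w:.4f}' for w in lt.allele_weights)}\t"
                f"{lt.copy_number:.6f}\t{len(lt.frag_sites)}\n"
            )
    with open(outdir / "frag_sites.bed", "w") as fh:
        for lt in truth.loci:
            for fs in lt.frag_sites:
                fh.write(f"{lt.locus_id}\t{fs.pos}\t{fs.pos + 1}\ttas_{fs.polarity}p\n")
    with open(outdir / "isoforms.tsv", "w") as fh:
        fh.write("locus_id\tstart\tend\tweight\n")
        for lt in truth.loci:
            for iso in lt.isoforms:
                fh.write(f"{lt.locus_id}\t{iso.start}\t{iso.end}\t{iso.weight:.4f}\n")
    with open(outdir / "cds.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for lt in truth.loci:
            for gi, (s, e) in enumerate(lt.cds):
                fh.write(
                    f"{lt.locus_id}\tsimgenome\tCDS\t{s + 1}\t{e}\t.\t+\t0\t"
                    f"ID=cds-{lt.locus_id}-{gi}\n"
                )
    alleles = [
        (f"{lt.locus_id}_allele{ai}", seq)
        for lt in truth.loci
        for ai, seq in enumerate(lt.alleles)
    ]
    write_fasta(outdir / "alleles.fasta", alleles)


def params_to_dict(params: SimParams) -> dict:
    return dataclasses.asdict(params)
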