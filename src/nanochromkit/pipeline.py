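"""End-to-end orchestration: simulate -> map -> classify -> report.

Every stage writes its reports into a run directory; a manifest records
parameters, package version and output checksums so reruns with the
same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, copynum, fragsites, hetvar, mapkit, simgenome, telomere

log = logging.getLogger("nanochromkit")


@dataclass
class PipelineConfig:
    """Stage toggles plus all module thresholds (defaults mirror the
    published pipeline's printed values)."""

    sim: simgenome.SimParams = field(default_factory=simgenome.SimParams)
    seed: int = 0

    run_mapping: bool = True  # False: use ground-truth placements
    run_hetvar: bool = True
    run_fragsites: bool = True
    run_copynum: bool = True

    map_min_identity: float = 0.94
    var_min_coverage: int = 20
    var_min_freq: float = 0.05
    var_end_margin: int = 40
    het_threshold_pct: float = 0.5
    match_min_len: int = 100
    match_min_identity: float = 0.90
    tas_window: int = 200
    tas_strong_min_reads: int = 10
    tas_terminal_window: int = 100
    altfrag_end_margin: int = 100
    isoform_link_bp: int = 100
    cn_min_len: int = 1800
    cn_margin: int = 600

    def validate(self) -> None:
        self.sim.validate()
        if not 0 < self.map_min_identity <= 1:
            raise ValueError("map_min_identity outside (0, 1]")
        if not 0 < self.match_min_identity <= 1:
            raise ValueError("match_min_identity outside (0, 1]")
        if not 0 <= self.var_min_freq <= 1:
            raise ValueError("var_min_freq outside [0, 1]")
        for name in ("var_min_coverage", "var_end_margin", "tas_window",
                     "tas_strong_min_reads", "tas_terminal_window",
                     "altfrag_end_margin", "isoform_link_bp", "cn_min_len",
                     "cn_margin", "match_min_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = simgenome.SimParams(**data.pop("sim", {}))
        cfg = cls(sim=sim, **data)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run all enabled stages; returns the run directory."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # stage: simulate -------------------------------------------------------
    log.info("simulating %d loci (seed %d)", config.sim.n_loci, config.sim.seed)
    params = dataclasses.replace(config.sim, seed=config.seed or config.sim.seed)
    truth, contigs = simgenome.simulate_genome(params)
    reads = simgenome.simulate_reads(truth, params)
    simgenome.write_fasta(out / "contigs.fasta", contigs)
    simgenome.write_fastq(out / "reads_pe1.fastq", reads.pe1)
    simgenome.write_fastq(out / "reads_pe2.fastq", reads.pe2)
    simgenome.write_fastq(out / "reads_se.fastq", reads.se)
    simgenome.write_fastq(out / "reads_telo.fastq", reads.telo)
    simgenome.write_fastq(out / "reads_tp1.fastq", reads.tp1)
    simgenome.write_fastq(out / "reads_tp2.fastq", reads.tp2)
    simgenome.write_truth_tables(out / "truth", truth)
    lengths = {cid: len(seq) for cid, seq in contigs}

    # stage: telomere stats -------------------------------------------------
    stats = telomere.assembly_stats(contigs)
    with open(out / "assembly_stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
    with open(out / "telomere_spans.bed", "w") as fh:
        for cid, seq in contigs:
            for sp in telomere.find_telomeres(seq, cid):
                fh.write(f"{cid}\t{sp.start}\t{sp.end}\ttel{sp.polarity}p\n")

    # stage: alignments -----------------------------------------------------
    if config.run_mapping:
        log.info("mapping %d reads", len(reads.pe1) + len(reads.pe2) + len(reads.se))
        masked = []
        sides: dict[str, tuple[bool, bool]] = {}
        for r in reads.pe1 + reads.pe2 + reads.se + reads.telo:
            mr = telomere.mask_read(r.seq)
            masked.append(
                simgenome.SimRead(r.read_id, mr.seq, r.qual, r.locus_id,
                                  None, None, r.strand,
                                  is_telomeric=mr.lead or mr.trail,
                                  mate_id=r.mate_id)
            )
            sides[r.read_id] = (mr.lead, mr.trail)
        alignments = mapkit.map_reads(masked, contigs, config.map_min_identity)
        telo_by_contig = fragsites.telo_reads_from_alignments(alignments, sides)
    else:
        log.info("using ground-truth placements")
        alignments = mapkit.truth_alignments(
            reads.pe1 + reads.pe2 + reads.se + reads.telo
        )
        telo_by_contig = fragsites.telo_support_from_truth(
            truth, reads.telo + reads.pe1 + reads.pe2 + reads.se
        )
    mapkit.write_sam(out / "alignments.sam", alignments, contigs)
    aln_by_contig: dict[str, list] = {cid: [] for cid, _ in contigs}
    for a in alignments:
        aln_by_contig[a.contig_id].append(a)

    # stage: heterozygosity -------------------------------------------------
    reports = []
    if config.run_hetvar:
        matches = mapkit.nonself_matches(
            contigs, config.match_min_len, config.match_min_identity
        ) if len(contigs) > 1 else []
        matched = mapkit.matched_contigs(matches)
        with open(out / "het_reports.tsv", "w") as fh:
            fh.write(
                "contig_id\tmatch_status\tn_examined\tn_variant\thet_pct\t"
                "median_variant_freq\tclassification\n"
            )
            for cid, seq in contigs:
                counts = hetvar.pileup_counts(lengths[cid], aln_by_contig[cid])
                rep = hetvar.classify_het_from_pileup(
                    cid, counts,
                    "matched" if cid in matched else "matchless",
                    config.var_min_coverage, config.var_min_freq,
                    config.var_end_margin,
                )
                reports.append(rep)
                med = "" if rep.median_variant_freq is None else f"{rep.median_variant_freq:.4f}"
                fh.write(
                    f"{rep.contig_id}\t{rep.match_status}\t{rep.n_examined}\t"
                    f"{rep.n_variant}\t{rep.het_pct:.2f}\t{med}\t{rep.classification}\n"
                )
        usable = [r for r in reports if not r.unclassifiable]
        summary = {
            "n_contigs": len(reports),
            "n_classifiable": len(usable),
            "homozygous_fraction": hetvar.genome_homozygous_fraction(usable)
            if usable else None,
        }
        with open(out / "het_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

    # stage: fragmentation --------------------------------------------------
    statuses: dict[str, fragsites.AltFragStatus] = {}
    if config.run_fragsites:
        tp_pairs = fragsites.pair_ends_from_truth(reads.tp1, reads.tp2)
        with open(out / "tas.bed", "w") as fh, \
             open(out / "altfrag.tsv", "w") as fh2, \
             open(out / "isoforms.tsv", "w") as fh3:
            fh2.write("contig_id\tfragmented\tn_internal_sites\n")
            fh3.write("contig_id\tleft_pos\tright_pos\tn_pairs\n")
            for cid, seq in contigs:
                tas = fragsites.call_tas(
                    cid, lengths[cid], telo_by_contig.get(cid, ()),
                    config.tas_window, config.tas_strong_min_reads,
                    config.tas_terminal_window,
                )
                for t in tas:
                    fh.write(
                        f"{cid}\t{t.pos}\t{t.pos + 1}\ttas{t.polarity}p\t{t.n_reads}\t"
                        f"{t.support}\n"
                    )
                st = fragsites.detect_altfrag(
                    cid, lengths[cid], tas, config.altfrag_end_margin
                )
                statuses[cid] = st
                fh2.write(f"{cid}\t{int(st.fragmented)}\t{st.n_internal_sites}\n")
                for iso in fragsites.predict_isoforms(
                    cid, tas, tp_pairs.get(cid, ()), config.isoform_link_bp
                ):
                    fh3.write(
                        f"{cid}\t{iso.left_tas.pos}\t{iso.right_tas.pos}\t{iso.n_pairs}\n"
                    )
        summary = fragsites.directionality_summary(
            [st.n_internal_sites for st in statuses.values()]
        )
        with open(out / "altfrag_summary.json", "w") as fh:
            json.dump(
                {
                    "n_fragmented": summary.n_fragmented,
                    "by_site_count": summary.by_site_count,
                    "single_site_fraction": None
                    if np.isnan(summary.single_site_fraction)
                    else summary.single_site_fraction,
                },
                fh, indent=2, sort_keys=True,
            )

    # stage: copy number ----------------------------------------------------
    if config.run_copynum:
        raw = []
        for cid, seq in contigs:
            est = copynum.estimate_cn(
                cid, lengths[cid], aln_by_contig[cid],
                telo_by_contig.get(cid, ()),
                config.cn_min_len, config.cn_margin,
            )
            if est is not None:
                raw.append(est)
        ests = copynum.finalize_relative(raw)
        with open(out / "copynum.tsv", "w") as fh:
            fh.write(
                "contig_id\tcontig_len\tinterior_reads\treads_per_bp\t"
                "telomeric_reads_5\ttelomeric_reads_3\trelative_cn\n"
            )
            for e in ests:
                fh.write(
                    f"{e.contig_id}\t{e.contig_len}\t{e.interior_reads}\t"
                    f"{e.reads_per_bp:.6f}\t{e.telomeric_reads_5}\t"
                    f"{e.telomeric_reads_3}\t{e.relative_cn:.4f}\n"
                )
        comparison = None
        if statuses:
            flags = {
                e.contig_id: ({"altfrag"} if statuses.get(e.contig_id)
                              and statuses[e.contig_id].fragmented else set())
                for e in ests
            }
            rows = copynum.group_report(ests, flags)
            comparison = rows[0] if rows else None
        with open(out / "copynum_comparison.json", "w") as fh:
            json.dump(comparison, fh, indent=2, sort_keys=True)

    # manifest --------------------------------------------------------------
    outputs = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
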