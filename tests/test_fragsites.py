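import numpy as np
import pytest

from nanochromkit import fragsites, simgenome


def make_locus_with_site(pos=2000, polarity="3", short_weight=0.7,
                         length=4000, seed=51, **kw):
    p = simgenome.SimParams(n_loci=1, length_mean_bp=length, length_sd_bp=1,
                            het_locus_fraction=0.0, altfrag_fraction=0.0,
                            seed=seed, **kw)
    truth, contigs = simgenome.simulate_genome(p)
    lt = truth.loci[0]
    lt.frag_sites = [simgenome.FragSiteTruth(pos, polarity)]
    if polarity == "3":
        short = simgenome.IsoformTruth(0, pos, short_weight)
    else:
        short = simgenome.IsoformTruth(pos, lt.length, short_weight)
    lt.isoforms = [short, simgenome.IsoformTruth(0, lt.length, 1 - short_weight)]
    return p, truth, lt


class TestCallTas:
    def test_all_reads_at_origin_terminal(self):
        reads = [fragsites.TeloRead(20, "5")] * 15
        tas = fragsites.call_tas("c", 3000, reads)
        assert len(tas) == 1
        t = tas[0]
        assert (t.pos, t.polarity, t.n_reads, t.support, t.terminal) == (
            20, "5", 15, "strong", True)

    def test_window_clustering(self, rng):
        # 12 reads ending at 2000 +- 30: one internal strong 3' TAS near 2000
        positions = [2000, 2000, 2000, 1995, 1995, 2010, 2010, 1970, 2030,
                     2000, 1985, 2025]
        reads = [fragsites.TeloRead(p, "3") for p in positions]
        tas = fragsites.call_tas("c", 5000, reads)
        assert len(tas) == 1
        assert tas[0].pos == 2000 and tas[0].n_reads == 12
        assert tas[0].support == "strong" and not tas[0].terminal

    def test_strong_weak_threshold(self):
        for n, support in ((9, "weak"), (10, "strong")):
            reads = [fragsites.TeloRead(1500, "3")] * n
            (t,) = fragsites.call_tas("c", 4000, reads)
            assert t.support == support

    def test_window_exclusivity(self):
        # two same-polarity clusters 250 bp apart stay separate sites
        reads = [fragsites.TeloRead(1000, "5")] * 12 + \
                [fragsites.TeloRead(1250, "5")] * 11
        tas = fragsites.call_tas("c", 4000, reads)
        assert [t.pos for t in tas] == [1000, 1250]
        assert all(
            abs(a.pos - b.pos) >= 200
            for a in tas for b in tas
            if a is not b and a.polarity == b.polarity
        )

    def test_ties_break_to_smaller_coordinate(self):
        reads = [fragsites.TeloRead(500, "5")] * 5 + \
                [fragsites.TeloRead(520, "5")] * 5
        (t,) = fragsites.call_tas("c", 2000, reads)
        assert t.pos == 500


class TestDetectAltfrag:
    def test_no_internal_site_not_fragmented(self):
        tas = [fragsites.TAS("c", 20, "5", 50, "strong", True),
               fragsites.TAS("c", 3980, "3", 50, "strong", True)]
        st = fragsites.detect_altfrag("c", 4000, tas)
        assert not st.fragmented and st.n_internal_sites == 0

    def test_margin_arithmetic(self):
        tas = [fragsites.TAS("c", 300, "3", 20, "strong", False)]
        assert fragsites.detect_altfrag("c", 4000, tas, end_margin=250).fragmented
        assert not fragsites.detect_altfrag("c", 4000, tas, end_margin=350).fragmented

    def test_weak_sites_ignored_in_strong_mode(self):
        tas = [fragsites.TAS("c", 2000, "3", 5, "weak", False)]
        assert not fragsites.detect_altfrag("c", 4000, tas).fragmented
        assert fragsites.detect_altfrag("c", 4000, tas, strong_only=False).fragmented

    def test_simulated_fraction_recovery(self):
        p = simgenome.SimParams(n_loci=400, altfrag_fraction=0.10,
                                altfrag_short_isoform_share=0.5,
                                telo_read_depth=60.0,
                                copy_number_lognormal_sigma=0.2,
                                length_sd_bp=600.0, seed=53)
        truth, _ = simgenome.simulate_genome(p)
        reads = simgenome.simulate_reads(truth, p, streams=("telo",))
        support = fragsites.telo_support_from_truth(truth, reads.telo)
        n_frag = 0
        for lt in truth.loci:
            tas = fragsites.call_tas(lt.locus_id, lt.length,
                                     support.get(lt.locus_id, []))
            if fragsites.detect_altfrag(lt.locus_id, lt.length, tas).fragmented:
                n_frag += 1
        sd = np.sqrt(400 * 0.10 * 0.90)
        assert abs(n_frag - 40) <= 3 * sd

    def test_positional_recovery_within_100bp(self):
        p = simgenome.SimParams(n_loci=100, altfrag_fraction=0.5,
                                altfrag_short_isoform_share=0.5,
                                telo_read_depth=60.0,
                                copy_number_lognormal_sigma=0.05,
                                length_sd_bp=600.0, seed=57)
        truth, _ = simgenome.simulate_genome(p)
        reads = simgenome.simulate_reads(truth, p, streams=("telo",))
        support = fragsites.telo_support_from_truth(truth, reads.telo)
        n_sites = n_found = 0
        for lt in truth.loci:
            tas = fragsites.call_tas(lt.locus_id, lt.length,
                                     support.get(lt.locus_id, []))
            emitted = {
                (tr.pos, tr.polarity): sum(
                    1 for x in support.get(lt.locus_id, [])
                    if x.pos == tr.pos and x.polarity == tr.polarity
                )
                for tr in support.get(lt.locus_id, [])
            }
            for fs in lt.frag_sites:
                if emitted.get((fs.pos, fs.polarity), 0) < 10:
                    continue  # claim holds at >= 10-read support
                n_sites += 1
                if any(
                    t.polarity == fs.polarity and abs(t.pos - fs.pos) <= 100
                    for t in tas if t.support == "strong"
                ):
                    n_found += 1
        assert n_sites >= 30
        assert n_found == n_sites  # recall 1.0 under noiseless placement


class TestPredictIsoforms:
    def test_terminal_only_single_isoform(self):
        tas = [fragsites.TAS("c", 20, "5", 50, "strong", True),
               fragsites.TAS("c", 3980, "3", 50, "strong", True)]
        isos = fragsites.predict_isoforms("c", tas, [(20, 3980)] * 5)
        assert len(isos) == 1
        assert isos[0].n_pairs == 5
        assert (isos[0].left_tas.pos, isos[0].right_tas.pos) == (20, 3980)

    def test_internal_site_two_isoforms_70_30(self):
        p, truth, lt = make_locus_with_site(short_weight=0.7,
                                            telo_pair_depth=200.0,
                                            telo_read_depth=50.0)
        reads = simgenome.simulate_reads(truth, p, streams=("telo", "tp"))
        support = fragsites.telo_support_from_truth(truth, reads.telo)
        tas = fragsites.call_tas(lt.locus_id, lt.length, support[lt.locus_id])
        pair_ends = fragsites.pair_ends_from_truth(reads.tp1, reads.tp2)
        isos = fragsites.predict_isoforms(lt.locus_id, tas,
                                          pair_ends[lt.locus_id])
        assert len(isos) == 2
        short = next(i for i in isos if i.right_tas.pos == 2000)
        full = next(i for i in isos if i.right_tas.pos == lt.length - 20)
        n = short.n_pairs + full.n_pairs
        sd = np.sqrt(n * 0.7 * 0.3)
        assert abs(short.n_pairs - 0.7 * n) <= 3 * sd
        # pair counts across the locus sum to the assigned pairs
        assert n == len(pair_ends[lt.locus_id])

    def test_site_without_linking_pairs_no_isoform(self):
        tas = [fragsites.TAS("c", 20, "5", 50, "strong", True),
               fragsites.TAS("c", 2000, "3", 20, "strong", False),
               fragsites.TAS("c", 3980, "3", 50, "strong", True)]
        isos = fragsites.predict_isoforms("c", tas, [(20, 3980)] * 4)
        assert len(isos) == 1
        assert isos[0].right_tas.pos == 3980

    def test_close_sites_merged(self):
        tas = [fragsites.TAS("c", 3762, "3", 30, "strong", False),
               fragsites.TAS("c", 3806, "3", 4, "weak", False),
               fragsites.TAS("c", 20, "5", 50, "strong", True)]
        merged = fragsites.merge_close_tas(tas, 50)
        assert len(merged) == 2
        m = next(t for t in merged if t.polarity == "3")
        assert m.pos == 3762 and m.n_reads == 34


class TestCdsContext:
    def test_all_sites_in_spacers_infinite_flag(self):
        sites = {"c": [fragsites.TAS("c", 1500, "3", 20, "strong", False)]}
        cds = {"c": [(200, 1400), (1600, 2800)]}
        summary = fragsites.cds_context(sites, cds, {"c": 3000})
        assert summary.enrichment_undefined
        assert summary.enrichment == float("inf")

    def test_density_arithmetic_18x(self):
        # 9 inter-CDS sites / 1,000 bp inter vs 1 intra site / 2,000 bp CDS
        cds = {"c": [(0, 1000), (2000, 3000)]}
        sites = {"c": [fragsites.TAS("c", 1000 + 100 * i, "3", 20, "strong", False)
                       for i in range(1, 10)]
                 + [fragsites.TAS("c", 500, "3", 20, "strong", False)]}
        summary = fragsites.cds_context(sites, cds, {"c": 3000})
        assert summary.n_inter == 9 and summary.n_intra == 1
        assert summary.enrichment == pytest.approx(18.0)

    def test_scaling_invariance(self):
        cds = {"c": [(0, 1000), (2000, 3000)]}
        sites = {"c": [fragsites.TAS("c", 1500, "3", 20, "strong", False),
                       fragsites.TAS("c", 500, "3", 20, "strong", False)]}
        e1 = fragsites.cds_context(sites, cds, {"c": 3000}).enrichment
        cds2 = {"c": [(0, 3000), (6000, 9000)]}
        sites2 = {"c": [fragsites.TAS("c", 4500, "3", 20, "strong", False),
                        fragsites.TAS("c", 1500, "3", 20, "strong", False)]}
        e2 = fragsites.cds_context(sites2, cds2, {"c": 9000}).enrichment
        assert e1 == pytest.approx(e2)

    def test_simulated_spacer_vs_intra_modes(self):
        for intra, seed in ((False, 61), (True, 62)):
            p = simgenome.SimParams(n_loci=150, altfrag_fraction=0.5,
                                    altfrag_short_isoform_share=0.5,
                                    telo_read_depth=50.0,
                                    copy_number_lognormal_sigma=0.1,
                                    intra_cds_altfrag=intra,
                                    length_sd_bp=400.0, seed=seed)
            truth, _ = simgenome.simulate_genome(p)
            reads = simgenome.simulate_reads(truth, p, streams=("telo",))
            support = fragsites.telo_support_from_truth(truth, reads.telo)
            sites = {}
            for lt in truth.loci:
                tas = fragsites.call_tas(lt.locus_id, lt.length,
                                         support.get(lt.locus_id, []))
                st = fragsites.detect_altfrag(lt.locus_id, lt.length, tas)
                if st.fragmented:
                    sites[lt.locus_id] = st.internal_sites
            cds = {lt.locus_id: lt.cds for lt in truth.loci}
            lens = {lt.locus_id: lt.length for lt in truth.loci}
            summary = fragsites.cds_context(sites, cds, lens)
            if intra:
                assert summary.n_intra > summary.n_inter
                assert summary.enrichment < 1.0
            else:
                assert summary.n_intra == 0
                assert summary.enrichment_undefined

    def test_zero_length_context_rejected(self):
        with pytest.raises(ValueError):
            fragsites.cds_context({}, {"c": []}, {"c": 1000}, mode="two_gene")


class TestDirectionality:
    def test_printed_counts_74_percent(self):
        counts = [1] * 1208 + [2] * (1622 - 1208)
        summary = fragsites.directionality_summary(counts)
        assert round(100 * summary.single_site_fraction) == 74

    def test_all_single_site(self):
        summary = fragsites.directionality_summary([1] * 25)
        assert summary.single_site_fraction == 1.0

    def test_simulated_distribution_exact(self):
        p = simgenome.SimParams(n_loci=200, altfrag_fraction=0.3,
                                altfrag_short_isoform_share=0.5,
                                telo_read_depth=80.0,
                                copy_number_lognormal_sigma=0.05,
                                length_sd_bp=400.0, seed=63)
        truth, _ = simgenome.simulate_genome(p)
        reads = simgenome.simulate_reads(truth, p, streams=("telo",))
        support = fragsites.telo_support_from_truth(truth, reads.telo)
        called = []
        for lt in truth.loci:
            tas = fragsites.call_tas(lt.locus_id, lt.length,
                                     support.get(lt.locus_id, []))
            st = fragsites.detect_altfrag(lt.locus_id, lt.length, tas)
            called.append(st.n_internal_sites)
        truth_counts = [len(lt.frag_sites) for lt in truth.loci]
        obs = fragsites.directionality_summary(called)
        exp = fragsites.directionality_summary(truth_counts)
        assert obs.by_site_count == exp.by_site_count
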