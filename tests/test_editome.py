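"""Pileup, AEI arithmetic, site calling with SNP masking, VCF round-trip —
checked against brute-force read-level oracles."""

import math

import numpy as np
import pytest

from aluedit import (
    CallParams,
    EditingSite,
    FilterParams,
    SimParams,
    UndefinedIndexError,
    accumulate_aei_components,
    build_pileup,
    call_editing_sites,
    compute_aei,
    make_reference,
    plant_truth,
    quantify_sample,
    read_sites_vcf,
    simulate_sample,
    write_sites_vcf,
)
from aluedit.editome import AEIComponents
from aluedit.readprep import (
    filter_alignments,
    mask_read_start,
    split_junction_segments,
)
from test_readprep import mkread, walk_cigar_oracle


def brute_force_pileup(reads, alu_intervals, reference, min_baseq, softclip_n=0):
    """Independent per-read recount: walk every read base-by-base and tally
    bases at Alu positions passing the quality filter."""
    counts = {}
    for read in reads:
        masked = mask_read_start(read, softclip_n) if softclip_n else read
        for pos, base, qual in walk_cigar_oracle(masked):
            if qual < min_baseq or qual < 0 or base == "N":
                continue
            in_alu = any(
                c == read.contig and s <= pos < e
                for c, s, e, _, _ in alu_intervals
            )
            if not in_alu:
                continue
            ref_base = reference[read.contig][pos]
            if ref_base == "N":
                continue
            counts.setdefault((read.contig, pos), {b: 0 for b in "ACGT"})[base] += 1
    return counts


class TestBuildPileup:
    def test_no_reads_empty(self, toy_ref):
        assert build_pileup([], toy_ref.alu_intervals, toy_ref.contigs) == []

    def test_single_read_ten_columns(self, toy_ref):
        contig, start, end, _, _ = toy_ref.alu_intervals[0]
        read = mkread(
            contig=contig, pos0=start - 40,
            cigar=[("M", 50)],
            seq=toy_ref.contigs[contig][start - 40 : start + 10],
        )
        cols = build_pileup(
            split_junction_segments(read), toy_ref.alu_intervals, toy_ref.contigs,
            min_baseq=25,
        )
        assert len(cols) == 10
        assert [c.pos0 for c in cols] == list(range(start, start + 10))
        assert all(c.depth == 1 for c in cols)

    def test_oracle_equivalence_on_simulated_reads(self, toy_ref, toy_truth):
        """Pileup counts equal a naive O(reads x positions) recount on a
        <=1000-read simulation, after the same filter cascade."""
        params = SimParams(depth=3, seed=42)
        rs = simulate_sample(toy_ref, toy_truth, "control", "d1", params)
        fp = FilterParams()
        filtered = filter_alignments(rs, fp)
        assert len(filtered) <= 1000
        segs = []
        for r in filtered:
            segs.extend(split_junction_segments(mask_read_start(r, fp.softclip_n)))
        cols = build_pileup(segs, toy_ref.alu_intervals, toy_ref.contigs, fp.min_baseq)
        oracle = brute_force_pileup(
            filtered.reads, toy_ref.alu_intervals, toy_ref.contigs,
            fp.min_baseq, fp.softclip_n,
        )
        got = {(c.contig, c.pos0): c.counts for c in cols}
        assert got == oracle
        assert [(c.contig, c.pos0) for c in cols] == sorted(got)


class TestAEI:
    def test_empty_pileup_zero_components(self):
        assert accumulate_aei_components([]) == AEIComponents()

    def test_single_column_tally(self):
        from aluedit.editome import PileupColumn

        col = PileupColumn("chrS", 5, "A", {"A": 8, "C": 0, "G": 2, "T": 0})
        c = accumulate_aei_components([col])
        assert (c.ag_mismatch, c.aa_match, c.tc_mismatch, c.tt_match) == (2, 8, 0, 0)

    @pytest.mark.parametrize(
        "comp,expected",
        [
            (AEIComponents(ag_mismatch=15, tc_mismatch=0, aa_match=85, tt_match=0), 15.0),
            (AEIComponents(ag_mismatch=0, tc_mismatch=0, aa_match=100, tt_match=50), 0.0),
            (AEIComponents(ag_mismatch=2, tc_mismatch=3, aa_match=45, tt_match=50), 5.0),
        ],
    )
    def test_aei_hand_arithmetic(self, comp, expected):
        assert compute_aei(comp) == expected

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedIndexError):
            compute_aei(AEIComponents())

    def test_components_match_read_level_tally(self, toy_ref, toy_truth):
        """AEI components over the pileup equal a brute-force tally over
        raw filtered reads."""
        rs = simulate_sample(toy_ref, toy_truth, "kd", "d2", SimParams(depth=3, seed=7))
        fp = FilterParams()
        filtered = filter_alignments(rs, fp)
        segs = []
        for r in filtered:
            segs.extend(split_junction_segments(mask_read_start(r, fp.softclip_n)))
        comp = accumulate_aei_components(
            build_pileup(segs, toy_ref.alu_intervals, toy_ref.contigs, fp.min_baseq)
        )
        oracle = brute_force_pileup(
            filtered.reads, toy_ref.alu_intervals, toy_ref.contigs,
            fp.min_baseq, fp.softclip_n,
        )
        ag = tc = aa = tt = 0
        for (contig, pos), counts in oracle.items():
            ref_base = toy_ref.contigs[contig][pos]
            if ref_base == "A":
                aa += counts["A"]
                ag += counts["G"]
            elif ref_base == "T":
                tt += counts["T"]
                tc += counts["C"]
        assert (comp.ag_mismatch, comp.tc_mismatch, comp.aa_match, comp.tt_match) == (
            ag, tc, aa, tt)

    def test_additivity_merged_samples(self, toy_ref, toy_truth):
        """Merging two samples' reads gives components equal to the sum of
        the per-sample components, hence the merged AEI is the AEI of the
        summed components."""
        a = simulate_sample(toy_ref, toy_truth, "control", "d1", SimParams(depth=4, seed=1))
        b = simulate_sample(toy_ref, toy_truth, "control", "d2", SimParams(depth=4, seed=2))
        qa = quantify_sample(a, toy_ref.contigs, toy_ref.alu_intervals, set(), "a")
        qb = quantify_sample(b, toy_ref.contigs, toy_ref.alu_intervals, set(), "b")
        # pool the two samples' (independently filtered) segments into one pileup
        fp = FilterParams()
        segs = []
        for rs in (a, b):
            for r in filter_alignments(rs, fp):
                segs.extend(split_junction_segments(mask_read_start(r, fp.softclip_n)))
        merged_comp = accumulate_aei_components(
            build_pileup(segs, toy_ref.alu_intervals, toy_ref.contigs, fp.min_baseq)
        )
        assert merged_comp == qa.components + qb.components
        merged_aei = compute_aei(merged_comp)
        assert merged_aei == compute_aei(qa.components + qb.components)
        assert 0.0 <= merged_aei <= 100.0

    def test_monotone_in_planted_frequency(self):
        """On a fixed seed and reference, AEI is nondecreasing over the
        planted-frequency grid {0, 0.05, 0.1, 0.2, 0.4}."""
        ref = make_reference(n_genes=2, alu_per_gene=2, alu_len=300, seed=33)
        aeis = []
        for f in (0.0, 0.05, 0.1, 0.2, 0.4):
            truth = plant_truth(ref, 40, {"c": f}, n_snps=0, seed=34)
            rs = simulate_sample(ref, truth, "c", "any", SimParams(depth=30, seed=35))
            ed = quantify_sample(rs, ref.contigs, ref.alu_intervals, set(), f"f{f}")
            aeis.append(ed.aei)
        # tolerance: binomial noise at this depth is well under 0.1 pp
        assert all(b >= a - 0.1 for a, b in zip(aeis, aeis[1:]))
        assert aeis[-1] > aeis[0] + 1.0


class TestCallSites:
    def _col(self, ref_base, counts, pos0=100):
        from aluedit.editome import PileupColumn

        full = {b: 0 for b in "ACGT"}
        full.update(counts)
        return PileupColumn("chrS", pos0, ref_base, full)

    def test_masked_position_not_called(self):
        col = self._col("A", {"A": 7, "G": 3})
        assert call_editing_sites([col], {("chrS", 100)}) == []
        assert len(call_editing_sites([col], set())) == 1

    def test_non_at_reference_not_called(self):
        col = self._col("C", {"C": 10, "T": 5})
        assert call_editing_sites([col], set()) == []

    def test_call_arithmetic_default_thresholds(self):
        col = self._col("A", {"A": 17, "G": 3})
        [site] = call_editing_sites([col], set(), sample_id="s1")
        assert (site.depth, site.edited_count) == (20, 3)
        assert site.freq == pytest.approx(0.15)
        assert (site.ref_base, site.edited_base, site.sample_id) == ("A", "G", "s1")

    @pytest.mark.parametrize(
        "counts,called",
        [
            ({"A": 3, "G": 2}, True),    # depth 5, support 2: at thresholds
            ({"A": 3, "G": 1}, False),   # support below min_edited_reads
            ({"A": 2, "G": 2}, False),   # depth below min_coverage
            ({"A": 14, "G": 3, "C": 3}, False),  # 15% non-canonical: artifact
        ],
    )
    def test_threshold_edges(self, counts, called):
        sites = call_editing_sites([self._col("A", counts)], set())
        assert bool(sites) is called

    def test_tc_antisense_called(self):
        [site] = call_editing_sites([self._col("T", {"T": 10, "C": 4})], set())
        assert (site.ref_base, site.edited_base) == ("T", "C")

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            CallParams(min_coverage=2, min_edited_reads=5)

    def test_no_calls_at_snp_positions_in_simulation(self, toy_ref, toy_truth):
        """Zero false calls at masked positions over a simulation with
        heterozygous SNPs (allele fraction 0.5 would otherwise look like a
        50%-edited site)."""
        rs = simulate_sample(toy_ref, toy_truth, "control", "d1", SimParams(depth=30, seed=55))
        ed = quantify_sample(
            rs, toy_ref.contigs, toy_ref.alu_intervals, toy_ref.snp_mask, "s"
        )
        called = {(s.contig, s.pos0) for s in ed.sites}
        assert called.isdisjoint(toy_truth.snp_positions())
        # and without the mask, at least one SNP would indeed be mis-called
        ed_nomask = quantify_sample(
            rs, toy_ref.contigs, toy_ref.alu_intervals, set(), "s2"
        )
        miscalls = {(s.contig, s.pos0) for s in ed_nomask.sites} & toy_truth.snp_positions()
        assert miscalls


class TestSitesVcf:
    def test_coordinate_convention(self, tmp_path):
        site = EditingSite("chrS", 999, "A", "G", 3, 10, "s")
        write_sites_vcf([site], tmp_path / "s.vcf", {"chrS": 2000})
        text = (tmp_path / "s.vcf").read_text()
        assert "\t1000\t" in text  # POS is 1-based

    def test_empty_site_list_header_only(self, tmp_path):
        write_sites_vcf([], tmp_path / "e.vcf", {"chrS": 2000}, sample_id="s")
        assert read_sites_vcf(tmp_path / "e.vcf") == []

    def test_round_trip_random_sites(self, tmp_path):
        rng = np.random.default_rng(5)
        positions = rng.choice(5000, size=100, replace=False)
        sites = []
        for pos in sorted(int(p) for p in positions):
            depth = int(rng.integers(5, 80))
            edited = int(rng.integers(2, min(depth, 20) + 1))
            ref = "A" if rng.random() < 0.5 else "T"
            sites.append(EditingSite(
                "chrS", pos, ref, "G" if ref == "A" else "C", edited, depth, "sampleX"))
        write_sites_vcf(sites, tmp_path / "r.vcf", {"chrS": 10000})
        assert read_sites_vcf(tmp_path / "r.vcf") == sites


class TestFrequencyRecovery:
    def test_mean_site_frequency_unbiased(self):
        """error_rate 0, depth 50, planted frequency f: the mean estimated
        frequency over >=100 sites lies within 3 standard errors of f."""
        ref = make_reference(n_genes=6, alu_per_gene=2, alu_len=300, seed=77)
        f = 0.25
        truth = plant_truth(ref, 120, {"c": f}, n_snps=0, seed=78)
        rs = simulate_sample(
            ref, truth, "c", "any",
            SimParams(depth=50, error_rate=0.0, seed=79),
        )
        ed = quantify_sample(rs, ref.contigs, ref.alu_intervals, set(), "s")
        truth_pos = truth.edit_positions()
        est = [s.freq for s in ed.sites if (s.contig, s.pos0) in truth_pos]
        assert len(est) >= 100
        tol = 3 * math.sqrt(f * (1 - f) / 50 / len(est))
        assert abs(np.mean(est) - f) <= tol
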