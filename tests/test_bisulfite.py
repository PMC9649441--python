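import numpy as np
import pytest
from scipy import stats as scipy_stats

from icrdesign.bisulfite import (
    METH,
    MISSING,
    UNMETH,
    AlignScoring,
    BisulfiteRead,
    MethylationCallMatrix,
    QCThresholds,
    align_bisulfite,
    call_matrix,
    convert_in_silico,
    summarize_methylation,
)
from icrdesign.core import GenomicSequence, cpg_positions, reverse_complement
from icrdesign.synthetic import EpialleleScenario, generate_reads


def nw_oracle(target, query, match=1.0, mismatch=-1.0, gap=-2.0):
    """Independent Needleman-Wunsch in collapsed space (Y matches C/T,
    R matches G/A), plain dynamic programming."""

    def sub(t, q):
        if t == "N" or q == "N":
            return 0.0
        if t == q or (t == "Y" and q in "CT") or (t == "R" and q in "GA"):
            return match
        return mismatch

    n, m = len(target), len(query)
    dp = np.zeros((n + 1, m + 1))
    dp[:, 0] = np.arange(n + 1) * gap
    dp[0, :] = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i, j] = max(
                dp[i - 1, j - 1] + sub(target[i - 1], query[j - 1]),
                dp[i - 1, j] + gap,
                dp[i, j - 1] + gap,
            )
    return dp[n, m]


class TestConvertInSilico:
    def test_full_conversion_all_meth(self, amplicon_ref):
        grid = cpg_positions(amplicon_ref)
        read = convert_in_silico(amplicon_ref, [METH] * len(grid),
                                 conversion_rate=1.0, strand="OT", seed=1)
        # C survives exactly at CpG-C positions
        c_positions = [i for i, b in enumerate(read.seq) if b == "C"]
        assert c_positions == grid

    def test_full_conversion_all_unmeth_no_c(self, amplicon_ref):
        grid = cpg_positions(amplicon_ref)
        read = convert_in_silico(amplicon_ref, [UNMETH] * len(grid),
                                 conversion_rate=1.0, strand="OT", seed=1)
        assert "C" not in read.seq

    def test_ob_strand_structure(self, amplicon_ref):
        grid = cpg_positions(amplicon_ref)
        read = convert_in_silico(amplicon_ref, [METH] * len(grid),
                                 conversion_rate=1.0, strand="OB", seed=1)
        # read is the converted bottom strand: its revcomp should show G at
        # the + strand CpG-G positions (preserved methylated C on bottom)
        plus = reverse_complement(read.seq)
        for p in grid:
            assert plus[p + 1] == "G"

    def test_rate_validation(self, amplicon_ref):
        grid = cpg_positions(amplicon_ref)
        with pytest.raises(ValueError):
            convert_in_silico(amplicon_ref, [METH] * len(grid),
                              conversion_rate=1.5)
        with pytest.raises(ValueError):
            convert_in_silico(amplicon_ref, [METH] * len(grid), error_rate=-0.1)

    def test_states_must_cover_grid(self, amplicon_ref):
        with pytest.raises(ValueError, match="covers"):
            convert_in_silico(amplicon_ref, [METH])

    def test_observed_conversion_rate_binomial(self):
        # aggregate converted fraction over many molecules ~ Binomial(n, 0.99)
        ref = GenomicSequence("r", "ACTCCTACTCCTACTCCT" * 4)  # C-rich, no CpG
        rate = 0.99
        total = converted = 0
        for seed in range(200):
            read = convert_in_silico(ref, [], conversion_rate=rate, seed=seed)
            total += ref.seq.count("C")
            converted += read.seq.count("T") - ref.seq.count("T")
        se = np.sqrt(rate * (1 - rate) / total)
        assert abs(converted / total - rate) < 3 * se


class TestAlignBisulfite:
    def test_perfect_meth_read(self, amplicon_ref):
        grid = cpg_positions(amplicon_ref)
        read = convert_in_silico(amplicon_ref, [METH] * len(grid),
                                 conversion_rate=1.0, strand="OT", seed=2)
        res = align_bisulfite(read, amplicon_ref, mode="directional")
        assert list(res.calls) == [METH] * len(grid)
        assert res.qc.conversion_rate == 1.0
        assert res.qc.identity == 1.0
        assert res.strand_form == "OT"

    def test_perfect_unmeth_read(self, amplicon_ref):
        grid = cpg_positions(amplicon_ref)
        read = convert_in_silico(amplicon_ref, [UNMETH] * len(grid),
                                 conversion_rate=1.0, strand="OT", seed=2)
        res = align_bisulfite(read, amplicon_ref, mode="directional")
        assert list(res.calls) == [UNMETH] * len(grid)

    @pytest.mark.parametrize("strand", ["OT", "OB"])
    @pytest.mark.parametrize("mode", ["directional", "non_directional"])
    def test_round_trip_both_strands_both_modes(self, amplicon_ref, strand, mode):
        grid = cpg_positions(amplicon_ref)
        rng = np.random.default_rng(77)
        states = [METH if x < 0.5 else UNMETH for x in rng.random(len(grid))]
        read = convert_in_silico(amplicon_ref, states, conversion_rate=1.0,
                                 strand=strand, error_rate=0.0, seed=5)
        res = align_bisulfite(read, amplicon_ref, mode=mode)
        assert list(res.calls) == states
        assert res.qc.passed

    def test_dp_oracle_30bp_read(self):
        ref = GenomicSequence("r", "ACGTTACGGATCCGTTAACGGTACGTTACCGGATCGTAAGGTTCCAATCGGATTACCGGA"[:60])
        grid = cpg_positions(ref)
        read = convert_in_silico(ref, [METH] * len(grid), conversion_rate=1.0,
                                 strand="OT", seed=9)
        # truncate to 30 bp and perturb to force a nontrivial alignment
        short = BisulfiteRead("t", read.seq[:30])
        res = align_bisulfite(short, ref, mode="directional")
        target = ref.seq.replace("C", "Y")
        assert res.score == pytest.approx(nw_oracle(target, short.seq))

    def test_dp_oracle_with_indel(self):
        ref = GenomicSequence("r", "ATTGGATCGTTAAGGTTAACCGGATTAAGGATTTAAGCGTTAGGATTAAGGCCATTAAGG")
        read_text = ref.seq.replace("C", "T")
        read_text = read_text[:20] + read_text[22:]  # 2 bp deletion
        read = BisulfiteRead("d", read_text)
        res = align_bisulfite(read, ref, mode="directional")
        assert res.score == pytest.approx(
            nw_oracle(ref.seq.replace("C", "Y"), read_text)
        )

    def test_non_directional_identifies_strand(self, amplicon_ref):
        grid = cpg_positions(amplicon_ref)
        for strand in ("OT", "OB"):
            read = convert_in_silico(amplicon_ref, [METH] * len(grid),
                                     conversion_rate=1.0, strand=strand, seed=3)
            res = align_bisulfite(read, amplicon_ref, mode="non_directional")
            assert res.strand_form == strand

    def test_ctot_form_recognized(self, amplicon_ref):
        grid = cpg_positions(amplicon_ref)
        read = convert_in_silico(amplicon_ref, [METH] * len(grid),
                                 conversion_rate=1.0, strand="OT", seed=3)
        flipped = BisulfiteRead("ctot", reverse_complement(read.seq))
        res = align_bisulfite(flipped, amplicon_ref, mode="non_directional")
        assert res.strand_form == "CTOT"
        assert list(res.calls) == [METH] * len(grid)

    def test_bad_mode_rejected(self, amplicon_ref):
        with pytest.raises(ValueError):
            align_bisulfite(BisulfiteRead("x", "ACGT" * 40), amplicon_ref,
                            mode="bogus")

    def test_unconverted_read_fails_conversion_qc(self, amplicon_ref):
        # raw reference as "read": nothing converted
        read = BisulfiteRead("raw", amplicon_ref.seq)
        res = align_bisulfite(read, amplicon_ref, mode="directional")
        assert res.qc.conversion_rate == 0.0
        assert not res.qc.passed
        assert "conversion" in res.qc.reason


class TestCallMatrix:
    def test_ten_perfect_meth_reads(self, amplicon_ref):
        grid = cpg_positions(amplicon_ref)
        reads = [
            convert_in_silico(amplicon_ref, [METH] * len(grid), 1.0, "OT", 0.0,
                              seed=s, read_id=f"r{s}")
            for s in range(10)
        ]
        m = call_matrix(reads, amplicon_ref)
        assert m.calls.shape == (10, len(grid))
        assert (m.calls == METH).all()

    def test_qc_failing_read_excluded(self, amplicon_ref):
        grid = cpg_positions(amplicon_ref)
        good = [
            convert_in_silico(amplicon_ref, [METH] * len(grid), 1.0, "OT", 0.0,
                              seed=s, read_id=f"g{s}")
            for s in range(3)
        ]
        bad = BisulfiteRead("unconverted", amplicon_ref.seq)
        m = call_matrix(good + [bad], amplicon_ref)
        assert m.calls.shape[0] == 3
        assert "unconverted" not in m.read_ids
        failing = [q for q in m.qc if not q.passed]
        assert len(failing) == 1 and failing[0].read_id == "unconverted"

    def test_zero_passing_reads_status(self, amplicon_ref):
        bad = BisulfiteRead("raw", amplicon_ref.seq)
        with pytest.warns(UserWarning, match="zero reads"):
            m = call_matrix([bad], amplicon_ref)
        assert m.status == "no_passing_reads"
        assert m.n_molecules == 0

    def test_empty_reads_rejected(self, amplicon_ref):
        with pytest.raises(ValueError):
            call_matrix([], amplicon_ref)

    def test_conservation_counts(self, amplicon_ref):
        reads, _ = generate_reads(
            amplicon_ref,
            EpialleleScenario(mode="disordered", n_molecules=40, p=0.4,
                              conversion_rate=0.98, error_rate=0.002, seed=8),
        )
        m = call_matrix(reads, amplicon_ref)
        counts = ((m.calls == METH) | (m.calls == UNMETH) | (m.calls == MISSING))
        assert counts.all()  # every entry is one of the three states
        per_site = (m.calls == METH).sum(0) + (m.calls == UNMETH).sum(0) + (
            m.calls == MISSING
        ).sum(0)
        assert (per_site == m.n_molecules).all()

    def test_disordered_p403_consistent(self, amplicon_ref):
        p = 0.403
        reads, states = generate_reads(
            amplicon_ref,
            EpialleleScenario(mode="disordered", n_molecules=300, p=p, seed=10),
        )
        m = call_matrix(reads, amplicon_ref)
        total = m.calls.size
        meth = int((m.calls == METH).sum())
        # joint binomial test over all calls at alpha = 0.01
        assert scipy_stats.binomtest(meth, total, p).pvalue > 0.01
        # and the matrix reproduces the simulated ground truth exactly
        assert np.array_equal(m.calls, states)


class TestSummarize:
    def _matrix(self, calls, sites=None):
        calls = np.asarray(calls, dtype=np.int8)
        sites = tuple(sites or range(calls.shape[1]))
        return MethylationCallMatrix("ref", sites, calls,
                                     tuple(f"m{i}" for i in range(calls.shape[0])),
                                     qc=())

    def test_all_meth(self):
        m = self._matrix(np.ones((4, 3)))
        s = summarize_methylation(m)
        assert s.fractions == (1.0, 1.0, 1.0)
        assert s.aggregate == 1.0

    def test_hand_tally_five_sites(self):
        calls = [
            [1, 0, 1, -1, 1],
            [1, 1, 0, 0, -1],
            [0, 0, -1, 1, 1],
        ]
        s = summarize_methylation(self._matrix(calls), min_coverage=2)
        # site coverages: 3,3,2,2,2 ; meth: 2,1,1,1,2
        assert s.sites == (0, 1, 2, 3, 4)
        assert s.fractions == pytest.approx((2 / 3, 1 / 3, 1 / 2, 1 / 2, 1.0))
        assert s.aggregate == pytest.approx(np.mean([2 / 3, 1 / 3, 0.5, 0.5, 1.0]))

    def test_499_coverage_excluded_at_500(self):
        calls = np.ones((499, 1))
        s = summarize_methylation(self._matrix(calls), min_coverage=500)
        assert s.excluded_sites == (0,)
        assert s.sites == ()
        calls = np.ones((500, 1))
        s = summarize_methylation(self._matrix(calls), min_coverage=500)
        assert s.sites == (0,)

    def test_missing_not_counted_as_coverage(self):
        calls = np.full((10, 1), MISSING)
        calls[:3, 0] = METH
        s = summarize_methylation(self._matrix(calls), min_coverage=4)
        assert s.excluded_sites == (0,)

    def test_all_excluded_flagged(self):
        calls = np.full((2, 2), MISSING)
        with pytest.warns(UserWarning, match="aggregate undefined"):
            s = summarize_methylation(self._matrix(calls), min_coverage=1)
        assert s.aggregate is None
        assert s.sites == ()

    def test_coverage_filter_monotonicity(self, rng):
        calls = rng.choice([METH, UNMETH, MISSING], size=(30, 8))
        m = self._matrix(calls)
        prev = None
        for mc in (1, 5, 10, 20, 31):
            retained = set(summarize_methylation(m, mc).sites)
            if prev is not None:
                assert retained <= prev
            prev = retained

    def test_min_coverage_validation(self):
        with pytest.raises(ValueError):
            summarize_methylation(self._matrix(np.ones((1, 1))), min_coverage=0)
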