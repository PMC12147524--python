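"""Generative model of the converted sequencing library."""

import numpy as np
import pandas as pd
import pytest

from f5cseq.simulate import (
    SimConfig,
    SpikeInDesign,
    enumerate_contexts,
    expected_ct_rate,
    make_truth_table,
    revcomp,
    simulate_library,
    simulate_rt_stop,
    simulate_site_counts,
    spike_in_reference,
)
from conftest import full_cover_config


def site_base_counts(sam_text: str, name: str, pos0: int) -> tuple[int, int]:
    """(n_T, coverage) at a site, counted straight off match-only SAM lines."""
    n_t = cov = 0
    for line in sam_text.splitlines():
        if line.startswith("@"):
            continue
        f = line.split("\t")
        if f[2] != name or "I" in f[5] or "D" in f[5] or "S" in f[5]:
            continue
        start = int(f[3]) - 1
        seq = f[9]
        if int(f[1]) & 0x10:
            continue  # forward evidence only in these tests
        if start <= pos0 < start + len(seq):
            base = seq[pos0 - start]
            if base != "N":
                cov += 1
                n_t += base == "T"
    return n_t, cov


class TestContexts:
    @pytest.mark.parametrize(
        "motif, expected",
        [("NNCNN", 256), ("NCN", 16), ("ACA", 1)],
    )
    def test_wildcard_expansion_count(self, motif, expected):
        got = enumerate_contexts(SpikeInDesign(motif=motif))
        assert len(got) == len(set(got)) == expected
        assert got == sorted(got)

    def test_motif_without_anchor_c_rejected(self):
        with pytest.raises(ValueError):
            SpikeInDesign(motif="NNANN")

    def test_spike_reference_realizes_design(self, spike_design):
        ref, truth = spike_in_reference(spike_design)
        assert len(ref) == 256 + len(spike_design.fractions)
        # every truth site sits on a C of its transcript
        for row in truth.itertuples():
            assert ref[row.ref][row.pos0] == "C"


class TestValidation:
    def test_truth_position_must_be_cytosine(self, toy_ref):
        truth = make_truth_table([("tx1", 0, "+", 0.5)])  # an A
        with pytest.raises(ValueError, match="requires 'C'"):
            simulate_library(toy_ref, truth, full_cover_config())

    def test_minus_strand_site_requires_reference_g(self, toy_ref):
        truth = make_truth_table([("tx1", 15, "-", 0.5)])  # C, not G
        with pytest.raises(ValueError):
            simulate_library(toy_ref, truth, full_cover_config())

    @pytest.mark.parametrize(
        "kw",
        [
            {"mode": "bogus"},
            {"conversion_efficiency": 1.2},
            {"background_ct_error": 1.0},
            {"reads_per_transcript": 0},
            {"rt_stop_prob": -0.1},
        ],
    )
    def test_config_range_checks(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)


class TestReadModel:
    def test_seed_makes_output_byte_identical(self, toy_ref, toy_truth):
        cfg = full_cover_config(seed=7, background_ct_error=0.01,
                                generic_seq_error=0.001)
        r1 = simulate_library(toy_ref, toy_truth, cfg)
        r2 = simulate_library(toy_ref, toy_truth, cfg)
        assert r1.fastq == r2.fastq and r1.sam == r2.sam
        pd.testing.assert_frame_equal(r1.truth, r2.truth)

    def test_fully_modified_fully_converted_site_is_all_T(self, toy_ref):
        truth = make_truth_table([("tx1", 15, "+", 1.0)])
        cfg = full_cover_config(conversion_efficiency=1.0)
        res = simulate_library(toy_ref, truth, cfg)
        n_t, cov = site_base_counts(res.sam, "tx1", 15)
        assert cov == 100 and n_t == cov

    def test_unmodified_clean_site_is_all_C(self, toy_ref):
        truth = make_truth_table([("tx1", 15, "+", 0.0)])
        res = simulate_library(toy_ref, truth, full_cover_config())
        n_t, cov = site_base_counts(res.sam, "tx1", 15)
        assert cov == 100 and n_t == 0

    def test_empirical_rate_matches_binomial_expectation(self, toy_ref):
        """f=0.5, eps=0.917, clean background: the site rate must land
        within 3 binomial sigma of 0.4585 at deep coverage."""
        truth = make_truth_table([("tx1", 15, "+", 0.5)])
        cfg = full_cover_config(
            seed=11, reads_per_transcript=200_000, conversion_efficiency=0.917
        )
        res = simulate_library(toy_ref, truth, cfg)
        n_t, cov = site_base_counts(res.sam, "tx1", 15)
        p = 0.5 * 0.917
        assert cov == 200_000
        assert abs(n_t / cov - p) < 3 * np.sqrt(p * (1 - p) / cov)

    def test_law_of_large_numbers_across_seeds(self, toy_ref):
        """|empirical - f*eps - (1-f*eps)*e0| < 4 binomial sigma at
        n=10,000 for every one of 50 seeds."""
        f, eps, e0 = 0.3, 0.9, 0.01
        truth = make_truth_table([("tx1", 15, "+", f)])
        p = expected_ct_rate(f, eps, e0)
        bound = 4 * np.sqrt(p * (1 - p) / 10_000)
        ok = 0
        for seed in range(50):
            cfg = full_cover_config(
                seed=seed,
                reads_per_transcript=10_000,
                conversion_efficiency=eps,
                background_ct_error=e0,
            )
            res = simulate_library(toy_ref, truth, cfg)
            n_t, cov = site_base_counts(res.sam, "tx1", 15)
            ok += abs(n_t / cov - p) < bound
        assert ok >= 50 * 0.99

    def test_expected_rate_column(self, toy_ref, toy_truth):
        cfg = full_cover_config(conversion_efficiency=0.9, background_ct_error=0.002)
        res = simulate_library(toy_ref, toy_truth, cfg)
        expected = 0.5 * 0.9 + (1 - 0.5 * 0.9) * 0.002
        assert res.expected_rates["expected_rate"].iloc[0] == pytest.approx(expected)

    def test_untreated_input_mode_suppresses_conversion(self, toy_ref):
        truth = make_truth_table([("tx1", 15, "+", 1.0)])
        cfg = full_cover_config(mode="untreated_input", conversion_efficiency=1.0)
        res = simulate_library(toy_ref, truth, cfg)
        n_t, cov = site_base_counts(res.sam, "tx1", 15)
        assert n_t == 0 and cov == 100

    def test_fastq_and_sam_agree_read_for_read(self, toy_ref, toy_truth):
        cfg = full_cover_config(seed=3)
        res = simulate_library(toy_ref, toy_truth, cfg)
        fq = res.fastq.splitlines()
        fq_reads = {fq[i][1:]: fq[i + 1] for i in range(0, len(fq), 4)}
        sam_lines = [l for l in res.sam.splitlines() if not l.startswith("@")]
        assert len(sam_lines) == len(fq_reads)
        for line in sam_lines:
            f = line.split("\t")
            seq = f[9] if not int(f[1]) & 0x10 else revcomp(f[9])
            assert fq_reads[f[0]] == seq

    def test_minus_strand_site_emits_g_to_a_in_reference_space(self):
        # reference G at 15 is the '-' strand modified C
        ref = {"tx1": "ATGATTAGGATTAGAGGGATTAGGATTAGA"}
        truth = make_truth_table([("tx1", 15, "-", 1.0)])
        cfg = full_cover_config(conversion_efficiency=1.0)
        res = simulate_library(ref, truth, cfg)
        body = [l.split("\t") for l in res.sam.splitlines() if not l.startswith("@")]
        assert all(int(f[1]) & 0x10 for f in body)
        bases = {f[9][15 - (int(f[3]) - 1)] for f in body}
        assert bases == {"A"}


class TestRtStop:
    def _run(self, f, tau, n, seed=0):
        ref = {"tx1": "ATGATTAGGATTAGACGGATTAGGATTAGA"}
        truth = make_truth_table([("tx1", 15, "+", f)])
        cfg = full_cover_config(
            seed=seed, reads_per_transcript=n, mode="malononitrile", rt_stop_prob=tau
        )
        return simulate_rt_stop(ref, truth, cfg).readthrough.iloc[0]

    def test_no_stop_probability_gives_full_readthrough(self):
        assert self._run(1.0, 0.0, 500)["readthrough"] == 1.0

    def test_certain_stop_truncates_every_read(self):
        row = self._run(1.0, 1.0, 500)
        assert row["readthrough"] == 0.0 and row["n_possible"] == 500

    def test_partial_stop_matches_binomial_expectation(self):
        row = self._run(1.0, 0.7, 100_000, seed=5)
        p = 0.3
        assert abs(row["readthrough"] - p) < 3 * np.sqrt(p * (1 - p) / 100_000)

    def test_wrapper_requires_malononitrile_mode(self, toy_ref, toy_truth):
        with pytest.raises(ValueError):
            simulate_rt_stop(toy_ref, toy_truth, full_cover_config())


class TestSiteCounts:
    def test_counts_level_marginal_matches_read_level_expectation(self, rng):
        df = simulate_site_counts([0.0, 0.5, 1.0], 200_000, eps=0.9, e0=0.002, rng=rng)
        for row in df.itertuples():
            se = np.sqrt(row.expected_rate * (1 - row.expected_rate) / row.coverage)
            assert abs(row.rate - row.expected_rate) <= 4 * se + 1e-12
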