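"""Motif extraction, PFM construction, MEME export and logos."""

import numpy as np
import pytest

from circrb import (
    CapsNetConfig,
    CapsuleNetwork,
    build_pfm,
    encode_sequence,
    export_meme,
    extract_subsequences,
    information_content,
    parse_meme,
    plot_logo,
)
from circrb.motifs import MotifPFM, discover_motifs


def net_with_filters(weights, bias, L=5):
    """A 1-layer net whose conv filters are set explicitly."""
    K, hc = weights.shape
    cfg = CapsNetConfig(input_length=L, n_filters=K, kernel_size=hc // 4, caps_dim=K)
    net = CapsuleNetwork(cfg, seed=0)
    net.params["conv_w"].data = weights.astype(float)
    net.params["conv_b"].data = np.asarray(bias, dtype=float)
    return net


class TestExtractSubsequences:
    def test_indicator_filter_recovers_motif(self):
        w = encode_sequence("ACG").matrix.reshape(1, -1)
        net = net_with_filters(w, [0.0])
        subs = extract_subsequences(net, ["TACGT"])
        assert subs[0] == ["ACG"]

    def test_never_firing_detector_contributes_nothing(self):
        w = -np.ones((1, 12))
        net = net_with_filters(w, [0.0])
        subs = extract_subsequences(net, ["TACGT", "AAAAA"])
        assert subs[0] == []

    def test_all_windows_have_detector_width(self):
        rng = np.random.default_rng(0)
        net = net_with_filters(rng.normal(size=(4, 12)), np.zeros(4), L=20)
        seqs = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(5)]
        for subs in extract_subsequences(net, seqs).values():
            assert all(len(s) == 3 for s in subs)


class TestBuildPfm:
    def test_simple_stack(self):
        pfm = build_pfm(["ACG", "ACG"], h=3)
        np.testing.assert_array_equal(pfm.counts[0], [2, 0, 0, 0])  # A
        np.testing.assert_array_equal(pfm.counts[1], [0, 2, 0, 0])  # C
        np.testing.assert_array_equal(pfm.counts[2], [0, 0, 2, 0])  # G

    def test_n_excluded_from_counts(self):
        pfm = build_pfm(["ANG", "ACG"], h=3)
        assert pfm.non_n_totals.tolist() == [2, 1, 2]
        np.testing.assert_array_equal(pfm.counts[1], [0, 1, 0, 0])

    def test_non_n_totals_bounded_by_subsequence_count(self):
        pfm = build_pfm(["ANG", "ACG", "NNN"], h=3)
        assert (pfm.non_n_totals <= pfm.n_subsequences).all()
        assert pfm.non_n_totals[2] == 2  # one N in column 3

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_pfm(["AC", "ACG"], h=3)

    def test_consensus(self):
        pfm = build_pfm(["ACG", "ACG", "ATG"], h=3)
        assert pfm.consensus() == "ACG"


class TestInformationContent:
    def test_pure_column_two_bits(self):
        pfm = build_pfm(["A" * 3] * 50, h=3)
        ic = information_content(pfm, pseudocount=0.0)
        np.testing.assert_allclose(ic, 2.0, atol=1e-12)

    def test_uniform_column_zero_bits(self):
        pfm = build_pfm(["AAA", "CCC", "GGG", "TTT"], h=3)
        np.testing.assert_allclose(information_content(pfm, pseudocount=0.0), 0.0, atol=1e-12)

    def test_half_half_column_one_bit(self):
        pfm = build_pfm(["A", "A", "C", "C"], h=1)
        np.testing.assert_allclose(information_content(pfm, pseudocount=0.0), 1.0, atol=1e-12)

    def test_all_n_column_flagged_zero(self):
        pfm = build_pfm(["NA", "NA"], h=2)
        ic = information_content(pfm)
        assert ic[0] == 0.0 and ic[1] > 0.0


class TestMeme:
    def _pfms(self):
        return [build_pfm(["ACG", "ACG", "ATG"], h=3, detector_id=7)]

    def test_minimal_format_structure(self):
        text = export_meme(self._pfms())
        assert text.startswith("MEME version 4")
        assert "ALPHABET= ACGT" in text
        assert "MOTIF detector_7" in text
        assert "w= 3" in text

    def test_probability_rows_sum_to_one(self):
        text = export_meme(self._pfms())
        _, mat = parse_meme(text)[0]
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-3)

    def test_roundtrip_recovers_probabilities(self):
        pfms = self._pfms()
        _, mat = parse_meme(export_meme(pfms))[0]
        np.testing.assert_allclose(mat, pfms[0].probabilities(), atol=1e-4)

    def test_empty_pfm_skipped_with_warning(self):
        pfms = self._pfms() + [MotifPFM(9, np.zeros((3, 4), int), np.zeros(3, int), 0)]
        with pytest.warns(UserWarning, match="detector 9"):
            text = export_meme(pfms)
        assert "detector_9" not in text

    def test_all_empty_rejected(self):
        empty = [MotifPFM(0, np.zeros((3, 4), int), np.zeros(3, int), 0)]
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            export_meme(empty)

    def test_bad_background_rejected(self):
        with pytest.raises(ValueError):
            export_meme(self._pfms(), background=np.array([0.5, 0.5, 0.5, 0.5]))

    def test_zero_count_column_uniform(self):
        pfm = build_pfm(["NA", "NA"], h=2)
        probs = pfm.probabilities()
        np.testing.assert_allclose(probs[0], 0.25)


def test_discovered_pfms_reproducible(tiny_fit):
    """Fixed checkpoint + fixed test pool -> bit-identical PFM counts."""
    pfms1 = tiny_fit.motifs(min_subsequences=5)
    pfms2 = tiny_fit.motifs(min_subsequences=5)
    assert len(pfms1) == len(pfms2) > 0
    for a, b in zip(pfms1, pfms2):
        np.testing.assert_array_equal(a.counts, b.counts)
        assert a.detector_id == b.detector_id


def test_logo_renders_to_file(tmp_path):
    pfm = build_pfm(["ACGTAA", "ACGTAC", "ACGAAT"], h=6, detector_id=1)
    out = tmp_path / "logo.png"
    plot_logo(pfm, out, rna=True)
    assert out.stat().st_size > 0
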