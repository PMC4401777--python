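import numpy as np
import pandas as pd
import pytest

from loregic import PWM, classify_binding, extract_promoters, read_pwms, scan_pwm
from loregic.motif import load_gene_coords, _window_scores

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def brute_force_hits(pwm: PWM, seq: str, frac: float) -> int:
    """Oracle: score every window on both strands by explicit summation."""
    s_max = sum(max(col) for col in pwm.matrix.T)
    s_min = sum(min(col) for col in pwm.matrix.T)
    span = s_max - s_min
    cutoff = s_min + frac * span if span > 0 else s_min
    hits = 0
    for strand_seq in (seq, revcomp(seq)):
        for i in range(len(strand_seq) - pwm.length + 1):
            window = strand_seq[i : i + pwm.length]
            if "N" in window:
                continue
            score = sum(
                pwm.matrix["ACGT".index(base), j] for j, base in enumerate(window)
            )
            if score >= cutoff:
                hits += 1
    return hits


@pytest.fixture
def toy_pwm():
    # consensus ACG
    return PWM(
        name="toy",
        matrix=np.array(
            [
                [10.0, 1.0, 0.0],
                [0.0, 8.0, 1.0],
                [0.0, 1.0, 9.0],
                [1.0, 0.0, 0.0],
            ]
        ),
    )


class TestScan:
    def test_consensus_always_hits(self, toy_pwm):
        assert toy_pwm.consensus == "ACG"
        assert scan_pwm(toy_pwm, "ACG", min_score_frac=1.0) >= 1

    def test_all_n_sequence_has_no_hits(self, toy_pwm):
        assert scan_pwm(toy_pwm, "N" * 30) == 0

    def test_short_sequence_has_no_hits(self, toy_pwm):
        assert scan_pwm(toy_pwm, "AC") == 0

    def test_matches_brute_force_oracle(self, toy_pwm):
        rng = np.random.default_rng(23)
        bases = np.array(list("ACGTN"))
        for _ in range(30):
            seq = "".join(rng.choice(bases, size=rng.integers(3, 40),
                                     p=[0.23, 0.23, 0.23, 0.23, 0.08]))
            for frac in (0.5, 0.8, 1.0):
                assert scan_pwm(toy_pwm, seq, frac) == brute_force_hits(
                    toy_pwm, seq, frac
                ), (seq, frac)

    def test_reverse_complement_invariance(self, toy_pwm):
        rng = np.random.default_rng(31)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=25))
            assert scan_pwm(toy_pwm, seq) == scan_pwm(toy_pwm, revcomp(seq))

    def test_threshold_monotonicity(self, toy_pwm):
        rng = np.random.default_rng(37)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        counts = [scan_pwm(toy_pwm, seq, f) for f in (0.2, 0.5, 0.8, 0.95, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_forward_only_strand(self, toy_pwm):
        # CGT is the reverse complement of the consensus ACG
        assert scan_pwm(toy_pwm, "CGT", min_score_frac=1.0, strand="forward") == 0
        assert scan_pwm(toy_pwm, "CGT", min_score_frac=1.0, strand="both") == 1

    def test_negative_weights_supported_by_minmax(self):
        pwm = PWM("logodds", np.array([[1.5, -2.0], [-2.0, 1.5],
                                       [-0.5, -0.5], [-0.5, -0.5]]))
        assert scan_pwm(pwm, "AC", min_score_frac=1.0) >= 1


class TestPwmIO:
    def test_jaspar_like_with_base_labels(self, tmp_path):
        path = tmp_path / "motifs.txt"
        path.write_text(
            ">M1\nA [ 4 19 0 ]\nC [ 16 0 20 ]\nG [ 0 1 0 ]\nT [ 0 0 0 ]\n"
            ">M2\n1 0\n0 1\n0 0\n0 0\n"
        )
        pwms = read_pwms(path)
        assert set(pwms) == {"M1", "M2"}
        assert pwms["M1"].length == 3
        assert pwms["M1"].consensus == "CAC"
        assert pwms["M2"].consensus == "AC"

    def test_wrong_row_count_errors(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(">M1\n1 0\n0 1\n")
        with pytest.raises(ValueError, match="4 rows"):
            read_pwms(path)


class TestPromoters:
    GENOME = {"chr1": "".join(
        np.random.default_rng(3).choice(list("ACGT"), size=200))}

    def coords(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "gene", "score", "strand"]
        )

    def test_plus_strand_window(self):
        coords = self.coords([("chr1", 100, 150, "g1", 0, "+")])
        promoters = extract_promoters(self.GENOME, coords, window=30)
        assert promoters["g1"] == self.GENOME["chr1"][70:100]

    def test_minus_strand_is_reverse_complemented(self):
        coords = self.coords([("chr1", 100, 150, "g2", 0, "-")])
        promoters = extract_promoters(self.GENOME, coords, window=30)
        assert promoters["g2"] == revcomp(self.GENOME["chr1"][150:180])

    def test_clipping_at_chromosome_start(self):
        coords = self.coords([("chr1", 20, 50, "g3", 0, "+")])
        promoters = extract_promoters(self.GENOME, coords, window=100)
        assert promoters["g3"] == self.GENOME["chr1"][0:20]

    def test_missing_chromosome_skipped(self):
        coords = self.coords([("chrX", 10, 20, "g4", 0, "+")])
        assert extract_promoters(self.GENOME, coords, window=10) == {}

    def test_fasta_roundtrip(self, tmp_path):
        fasta = tmp_path / "genome.fa"
        fasta.write_text(">chr1\n" + self.GENOME["chr1"] + "\n")
        coords = self.coords([("chr1", 100, 150, "g1", 0, "+")])
        promoters = extract_promoters(str(fasta), coords, window=25)
        assert promoters["g1"] == self.GENOME["chr1"][75:100]

    def test_bed_loader_validates_strand(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("chr1\t0\t10\tg1\t0\t*\n")
        with pytest.raises(ValueError, match="strand"):
            load_gene_coords(path)


class TestClassification:
    @pytest.mark.parametrize(
        "hits, expected",
        [
            ((3, 2), "both_direct"),
            ((5, 0), "rf2_indirect"),
            ((0, 4), "rf1_indirect"),
            ((0, 0), "both_missing"),
            ((None, 2), "unscorable"),
        ],
    )
    def test_categories(self, hits, expected):
        assert classify_binding(*hits) == expected
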