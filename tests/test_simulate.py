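import numpy as np
import pandas as pd
import pytest
from scipy import stats

import repquant as rq
from repquant.simulate import HMMConfig, stationary_high_occupancy


def degenerate_config():
    """Feature forces the high state, background forces the low state."""
    return HMMConfig(
        background_transition=np.array([[1.0, 0.0], [1.0, 0.0]]),
        feature_transition=np.array([[0.0, 1.0], [0.0, 1.0]]),
    )


@pytest.fixture(scope="module")
def flat_genome():
    rng = np.random.default_rng(5)
    return {"chr": "".join(rng.choice(list("ACGT"), 20_000))}


class TestEmissionProfile:
    def test_degenerate_transitions_recover_state_means(self):
        config = degenerate_config()
        profile = rq.simulate_emission_profile(10_000, [(4000, 6000)], config, seed=0)
        inside = profile.weights[4000:6000]
        outside = np.concatenate([profile.weights[:4000], profile.weights[6000:]])
        # Normal(3.0, 0.1) inside features, Normal(1.0, 0.1) outside
        assert inside.mean() == pytest.approx(3.0, abs=3 * 0.1 / np.sqrt(inside.size))
        assert outside.mean() == pytest.approx(1.0, abs=3 * 0.1 / np.sqrt(outside.size))
        assert (profile.states[4000:6000] == 1).all()

    def test_empty_features_follow_background(self):
        config = HMMConfig()
        profile = rq.simulate_emission_profile(200_000, [], config, seed=1)
        occ = profile.states.mean()
        expect = stationary_high_occupancy(config.background_transition)
        assert occ == pytest.approx(expect, abs=0.01)

    def test_stationary_occupancy_closed_form(self):
        # P(low->high)=a, P(high->low)=b inside a feature spanning 1 Mb
        a, b = 0.02, 0.05
        config = HMMConfig(
            feature_transition=np.array([[1 - a, a], [b, 1 - b]]),
        )
        profile = rq.simulate_emission_profile(
            1_000_000, [(0, 1_000_000)], config, seed=2
        )
        assert profile.states.mean() == pytest.approx(a / (a + b), abs=0.01 * a / (a + b) + 0.005)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError, match="row-stochastic"):
            HMMConfig(background_transition=np.array([[0.5, 0.2], [0.5, 0.5]]))

    def test_feature_outside_contig_rejected(self):
        with pytest.raises(ValueError, match="outside contig"):
            rq.simulate_emission_profile(100, [(50, 200)], HMMConfig(), seed=0)

    def test_weights_nonnegative_and_full_length(self):
        config = HMMConfig(emission_mean=(0.05, 3.0), emission_sd=(0.5, 0.1))
        profile = rq.simulate_emission_profile(5000, [], config, seed=3)
        assert profile.weights.size == 5000
        assert (profile.weights >= 0).all()


class TestSampleReads:
    def test_zero_weight_positions_never_sampled(self, flat_genome):
        profile = rq.simulate_emission_profile(20_000, [], HMMConfig(), seed=0)
        profile.weights[:10_000] = 0.0
        rs = rq.sample_reads(profile, flat_genome, 5000, 50, seed=1)
        assert (rs.truth["start"] >= 10_000).all()

    def test_uniform_profile_is_uniform(self, flat_genome):
        profile = rq.simulate_emission_profile(20_000, [], HMMConfig(), seed=0)
        profile.weights[:] = 1.0
        rs = rq.sample_reads(profile, flat_genome, 100_000, 50, seed=2)
        observed, _ = np.histogram(rs.truth["start"], bins=10, range=(0, 20_000 - 49))
        _chi2, p = stats.chisquare(observed)
        assert p > 0.01

    def test_feature_read_fraction_matches_emission_ratio(self, flat_genome):
        # feature covers 10% with mean weight 3 vs background 1:
        # expected in-feature fraction = 0.3/(0.3+0.9) = 0.25
        config = degenerate_config()
        profile = rq.simulate_emission_profile(
            20_000, [(9000, 11_000)], config, seed=4
        )
        n = 50_000
        rs = rq.sample_reads(profile, flat_genome, n, 50, seed=5)
        frac = ((rs.truth["start"] >= 9000) & (rs.truth["start"] < 11_000)).mean()
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) < 3 * se + 0.005  # small edge effect at read length

    def test_sequences_match_true_coordinates(self, flat_genome):
        profile = rq.simulate_emission_profile(20_000, [], HMMConfig(), seed=6)
        rs = rq.sample_reads(profile, flat_genome, 200, 40, seed=7)
        g = flat_genome["chr"]
        for (_, row), seq in zip(rs.truth.iterrows(), rs.sequences):
            expect = g[row["start"] : row["start"] + 40]
            if row["strand"] == "-":
                expect = rq.revcomp(expect)
            assert seq == expect

    def test_same_seed_identical_fasta(self, flat_genome, tmp_path):
        profile = rq.simulate_emission_profile(20_000, [], HMMConfig(), seed=8)
        a, b = tmp_path / "a.fa", tmp_path / "b.fa"
        rq.sample_reads(profile, flat_genome, 500, 50, seed=9).write_fasta(a)
        rq.sample_reads(profile, flat_genome, 500, 50, seed=9).write_fasta(b)
        assert a.read_bytes() == b.read_bytes()

    def test_all_zero_profile_rejected(self, flat_genome):
        profile = rq.simulate_emission_profile(20_000, [], HMMConfig(), seed=0)
        profile.weights[:] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            rq.sample_reads(profile, flat_genome, 10, 50, seed=0)


class TestTrueAbundance:
    instances = [
        rq.RepeatInstance("chr", 100, 400, "+", "AluY", "Alu", "SINE", 0),
        rq.RepeatInstance("chr", 600, 900, "+", "L1PA2", "L1", "LINE", 1),
    ]

    def test_read_inside_instance_counts(self):
        truth = pd.DataFrame({"chrom": ["chr"], "start": [150]})
        counts = rq.true_abundance(truth, 50, self.instances, ["AluY", "L1PA2"])
        assert counts.to_dict() == {"AluY": 1, "L1PA2": 0}

    def test_read_overlapping_nothing(self):
        truth = pd.DataFrame({"chrom": ["chr"], "start": [450]})
        counts = rq.true_abundance(truth, 50, self.instances, ["AluY", "L1PA2"])
        assert counts.sum() == 0

    def test_matches_unique_read_assignment(self, oracle_toy):
        rng = np.random.default_rng(11)
        starts = rng.integers(0, 29_950, size=500)
        truth = pd.DataFrame({"chrom": "chrT", "start": starts})
        subs = oracle_toy.hierarchy.subfamilies
        counts = rq.true_abundance(truth, 50, oracle_toy.instances, subs)
        uas = [
            rq.UniqueAlignment(f"r{i}", 0, "chrT", int(s), int(s) + 50)
            for i, s in enumerate(starts)
        ]
        rmap = rq.assign_unique_reads(uas, oracle_toy.instances)
        from repquant.counting import count_reads

        assert counts.equals(count_reads(rmap, subs)["total"])


class TestEvaluationMetrics:
    def test_r_squared_cases(self):
        x = np.array([1.0, 2.0, 3.0])
        assert rq.r_squared(x, x) == 1.0
        assert rq.r_squared(x, np.full(3, x.mean())) == 0.0
        assert rq.r_squared(x, np.array([1.0, 2.0, 4.0])) == pytest.approx(0.5)

    def test_r_squared_clamps_below_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert rq.r_squared(x, np.array([10.0, -5.0, 7.0])) == 0.0

    def test_distance_matrix(self):
        vecs = pd.DataFrame({"a": [0.0, 0.0], "b": [3.0, 4.0], "c": [0.0, 0.0]})
        d = rq.distance_matrix(vecs)
        assert d.loc["a", "b"] == pytest.approx(5.0)
        assert d.loc["a", "c"] == 0.0
        assert (d.values == d.values.T).all()
        assert (np.diag(d.values) == 0).all()

    def test_average_log2cpm_prior_handles_zeros(self):
        counts = pd.DataFrame({"r1": [0, 10], "r2": [0, 30]})
        lib = pd.Series({"r1": 1000, "r2": 1000})
        out = rq.average_log2cpm(counts, lib, prior_count=0.5)
        assert np.isfinite(out).all()
        assert out.iloc[0] == pytest.approx(np.log2(0.5 * 1e6 / 1000))


def test_fastq_output_constant_quality(flat_genome, tmp_path):
    profile = rq.simulate_emission_profile(20_000, [], HMMConfig(), seed=10)
    rs = rq.sample_reads(profile, flat_genome, 10, 30, seed=11)
    p = tmp_path / "reads.fastq"
    rs.write_fastq(p)
    from Bio import SeqIO

    records = list(SeqIO.parse(str(p), "fastq"))
    assert len(records) == 10
    assert [str(r.seq) for r in records] == rs.sequences
    assert set(records[0].letter_annotations["phred_quality"]) == {40}
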