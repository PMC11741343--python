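import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqdigest.hashing import revcomp, stream_hashes
from seqdigest.schemes import (
    DigestResult,
    SchemeParams,
    digest,
    digest_minimizer,
    digest_modimizer,
    digest_syncmer,
)
from seqdigest.window_min import BACKEND_KINDS

from conftest import random_dna
from oracles import brute_minimizer, brute_modimizer, brute_syncmer


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            SchemeParams("modimizer", k=4, mod=0)
        with pytest.raises(ValueError):
            SchemeParams("modimizer", k=4)  # modulus missing
        with pytest.raises(ValueError):
            SchemeParams("minimizer", k=4, w=0)
        with pytest.raises(ValueError):
            SchemeParams("syncmer", k=8, w=8)  # requires k < w
        with pytest.raises(ValueError):
            SchemeParams("minimizer", k=0, w=3)
        with pytest.raises(ValueError):
            SchemeParams("maximizer", k=4, w=3)

    def test_selected_length_and_window_entries(self):
        assert SchemeParams("minimizer", k=5, w=9).selected_length == 5
        assert SchemeParams("syncmer", k=5, w=9).selected_length == 9
        assert SchemeParams("syncmer", k=5, w=9).window_entries == 5
        assert SchemeParams("modimizer", k=5, mod=4).selected_length == 5


class TestModimizer:
    def test_modulus_one_selects_every_valid_kmer(self):
        res = digest_modimizer("ACGTACGT", SchemeParams("modimizer", k=4, mod=1))
        assert res.positions == [0, 1, 2, 3, 4]

    def test_all_ambiguous_yields_empty(self):
        res = digest_modimizer("NNNNN", SchemeParams("modimizer", k=3, mod=1))
        assert res.positions == []

    def test_matches_bruteforce_and_binomial_density(self, rng):
        seq = random_dna(rng, 10_000, n_rate=0.01)
        n = 16
        res = digest_modimizer(seq, SchemeParams("modimizer", k=9, mod=n))
        assert res.positions == brute_modimizer(seq, 9, n)
        total = stream_hashes(seq, 9)[0].size
        sd = np.sqrt(total * (1 / n) * (1 - 1 / n))
        assert abs(len(res) - total / n) < 5 * sd


class TestMinimizer:
    def test_window_of_one_selects_everything(self, rng):
        seq = random_dna(rng, 300, n_rate=0.02)
        res = digest_minimizer(seq, SchemeParams("minimizer", k=5, w=1))
        assert res.positions == stream_hashes(seq, 5)[0].tolist()

    def test_constant_sequence_picks_rightmost_per_window(self):
        res = digest_minimizer("AAAAAAAA", SchemeParams("minimizer", k=3, w=3))
        assert res.positions == [2, 3, 4, 5]

    def test_fewer_valid_kmers_than_window_yields_empty(self):
        assert digest_minimizer("ACGTA", SchemeParams("minimizer", k=4, w=3)).positions == []

    @pytest.mark.parametrize("w", [5, 11, 32])
    @pytest.mark.parametrize("n_rate", [0.0, 0.01])
    def test_matches_bruteforce_across_all_backends(self, rng, w, n_rate):
        seq = random_dna(rng, 20_000, n_rate=n_rate)
        params = SchemeParams("minimizer", k=15, w=w)
        expect = brute_minimizer(seq, 15, w)
        for kind in BACKEND_KINDS + ("auto",):
            res = digest_minimizer(seq, params, backend=kind)
            assert res.positions == expect, kind

    def test_window_coverage(self, rng):
        """Every window of w consecutive valid k-mers contains at least one
        selected position — the defining minimizer guarantee."""
        seq = random_dna(rng, 5000, n_rate=0.01)
        k, w = 11, 8
        res = digest_minimizer(seq, SchemeParams("minimizer", k=k, w=w))
        pos, _ = stream_hashes(seq, k)
        selected = np.isin(pos, res.positions)
        windows = np.lib.stride_tricks.sliding_window_view(selected, w)
        assert windows.any(axis=1).all()


class TestSyncmer:
    def test_two_kmer_windows_select_every_valid_window(self, rng):
        # with w = k+1 the minimum is necessarily at one end
        seq = random_dna(rng, 500, n_rate=0.02)
        k, w = 6, 7
        res = digest_syncmer(seq, SchemeParams("syncmer", k=k, w=w))
        valid = set(stream_hashes(seq, k)[0].tolist())
        expect = [j for j in range(len(seq) - w + 1) if j in valid and j + 1 in valid]
        assert res.positions == expect

    def test_sequence_shorter_than_window_yields_empty(self):
        assert digest_syncmer("ACGTAC", SchemeParams("syncmer", k=4, w=8)).positions == []

    @pytest.mark.parametrize("k,w", [(11, 21), (7, 13)])
    @pytest.mark.parametrize("n_rate", [0.0, 0.01])
    def test_matches_bruteforce(self, rng, k, w, n_rate):
        seq = random_dna(rng, 20_000, n_rate=n_rate)
        res = digest_syncmer(seq, SchemeParams("syncmer", k=k, w=w))
        assert res.positions == brute_syncmer(seq, k, w)

    def test_windows_never_straddle_ambiguous_runs(self):
        seq = "ACGTACGTAC" + "N" + "GTACGTACGT"
        res = digest_syncmer(seq, SchemeParams("syncmer", k=3, w=6))
        for j in res.positions:
            assert "N" not in seq[j : j + 6]


class TestDispatchAndInvariants:
    def test_dispatch_matches_scheme_functions(self, rng):
        seq = random_dna(rng, 2000)
        pm = SchemeParams("modimizer", k=8, mod=4)
        assert digest(seq, pm).positions == digest_modimizer(seq, pm).positions
        pw = SchemeParams("minimizer", k=8, w=5)
        assert digest(seq, pw).positions == digest_minimizer(seq, pw).positions
        ps = SchemeParams("syncmer", k=8, w=12)
        assert digest(seq, ps).positions == digest_syncmer(seq, ps).positions

    def test_minimizer_w1_equals_modimizer_n1(self, rng):
        seq = random_dna(rng, 1500, n_rate=0.02)
        a = digest(seq, SchemeParams("minimizer", k=6, w=1))
        b = digest(seq, SchemeParams("modimizer", k=6, mod=1))
        assert a.positions == b.positions

    def test_determinism(self, rng):
        seq = random_dna(rng, 3000, n_rate=0.01)
        p = SchemeParams("minimizer", k=9, w=7)
        assert digest(seq, p, with_hashes=True) == digest(seq, p, with_hashes=True)

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=200), st.data())
    @settings(max_examples=60)
    def test_positions_stay_in_bounds_and_pure(self, seq, data):
        """Fuzz: selected substrings never leave the sequence and never
        contain ambiguous characters; positions strictly increase."""
        scheme = data.draw(st.sampled_from(["modimizer", "minimizer", "syncmer"]))
        k = data.draw(st.integers(1, 8))
        if scheme == "modimizer":
            params = SchemeParams(scheme, k=k, mod=data.draw(st.integers(1, 8)))
        elif scheme == "minimizer":
            params = SchemeParams(scheme, k=k, w=data.draw(st.integers(1, 6)))
        else:
            params = SchemeParams(scheme, k=k, w=k + data.draw(st.integers(1, 6)))
        res = digest(seq, params)
        L = params.selected_length
        assert all(0 <= p <= len(seq) - L for p in res.positions)
        assert all(a < b for a, b in zip(res.positions, res.positions[1:]))
        for p in res.positions:
            assert set(seq[p : p + L]) <= set("ACGT")

    def test_canonical_digest_mirrors_under_reverse_complement(self, rng):
        """On tie-free input, digesting the reverse complement selects the
        mirror image of the forward selection.  k is chosen large enough
        that no window holds two equal hashes (repeated k-mers — e.g. at
        small k or in homopolymer runs — create genuine ties, where the
        rightmost rule breaks the symmetry); tie-freeness is verified."""
        seq = random_dna(rng, 20_000)
        n = len(seq)
        k = 16
        h = stream_hashes(seq, k, SchemeParams("minimizer", k=k, w=9, hash_bits=64).hash_config)[1]
        windows = np.lib.stride_tricks.sliding_window_view(h, 9)  # covers both window sizes
        assert all(len(set(w.tolist())) == w.size for w in windows)  # tie-free
        for params in (
            SchemeParams("minimizer", k=k, w=9, hash_bits=64),
            SchemeParams("syncmer", k=k, w=21, hash_bits=64),
            SchemeParams("modimizer", k=k, mod=8, hash_bits=64),
        ):
            L = params.selected_length
            fwd = digest(seq, params).positions
            rev = digest(revcomp(seq), params).positions
            assert sorted(n - L - p for p in fwd) == rev

    def test_hashes_attached_on_request(self, rng):
        seq = random_dna(rng, 2000)
        res = digest(seq, SchemeParams("minimizer", k=9, w=5), with_hashes=True)
        lookup = dict(zip(*[a.tolist() for a in stream_hashes(seq, 9)]))
        assert res.hashes == [lookup[p] for p in res.positions]
        assert digest(seq, SchemeParams("minimizer", k=9, w=5)).hashes is None
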