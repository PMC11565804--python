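import itertools
import warnings

import numpy as np
import pytest

from g4kit.enrichment import (PatternSpec, ReadPool, classify_pool, count_kmers,
                              forest_normalize, has_strong_g4, kmer_enrichment,
                              match_strong_g4, pattern_enrichment,
                              read_pool_fasta, write_pool_fasta)
from g4kit.synthetic import PoolSpec, generate_read_pools

TERRA23 = "UAGGGUUAGGGUUAGGGUUAGGG"
HIV_TAR = "GGCAGAUCUGAGCCUGGGAGCUCUCUGCC"
STXBP5 = "GGGAAGGGAAGGGGAGUGGG"


def oracle_match(seq, spec):
    """Exhaustive recursive matcher enumerating every run/loop decomposition."""
    n = len(seq)

    def runs_from(pos, runs_left):
        if runs_left == 0:
            return True
        for rl in range(spec.g_run_min, spec.g_run_max + 1):
            if pos + rl > n or any(c != "G" for c in seq[pos:pos + rl]):
                break
            if runs_left == 1:
                return True
            for loop in range(0, spec.loop_max + 1):
                nxt = pos + rl + loop
                if nxt >= n:
                    break
                if runs_from(nxt, runs_left - 1):
                    return True
        return False

    return any(runs_from(i, spec.n_runs) for i in range(n))


# ---------------------------------------------------------------------------
# k-mer counting and R statistic
# ---------------------------------------------------------------------------

def test_count_kmers_hand_counts():
    t = count_kmers(ReadPool(["GGGAAA"]), k=6)
    assert t.counts == {"GGGAAA": 1} and t.total == 1
    t2 = count_kmers(ReadPool(["GGGG"]), k=2)
    assert t2.counts == {"GG": 3} and t2.frequencies["GG"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        count_kmers(ReadPool(["AAA"]), k=4)


@pytest.mark.parametrize("seed", range(3))
def test_count_kmers_equals_naive_recount(seed):
    rng = np.random.default_rng(seed)
    reads = ["".join(rng.choice(list("ACGU"), size=15)) for _ in range(40)]
    pool = ReadPool(reads)
    table = count_kmers(pool, k=4)
    naive = {}
    for r in reads:
        for i in range(len(r) - 3):
            naive[r[i:i + 4]] = naive.get(r[i:i + 4], 0) + 1
    assert table.counts == naive


def test_identical_pools_give_unit_R_exactly():
    pool = ReadPool(["GGGAAAGGG", "UUACGUACG", "CCCGGGUUU"])
    table = kmer_enrichment(pool, pool, k=3)
    assert (table["R"] == 1.0).all()


def test_hand_built_double_frequency_gives_R_2():
    # bound pool holds the 6-mer twice as frequently (per instance) as input
    inp = ReadPool(["GGGGGG", "AAAAAA", "CCCCCC", "UUUUUU"])
    bound = ReadPool(["GGGGGG", "GGGGGG", "AAAAAA", "CCCCCC"])
    table = kmer_enrichment(bound, inp, k=6).set_index("kmer")
    assert table.loc["GGGGGG", "R"] == pytest.approx(2.0)


def test_generator_spike_tops_enrichment_table():
    motif, factor = "GGGUGG", 5.0
    inp, bound = generate_read_pools(
        PoolSpec(n_reads=30_000, enriched_motifs={motif: factor}, seed=5))
    table = kmer_enrichment(bound, inp, k=6)
    assert table.iloc[0]["kmer"] == motif
    assert table.iloc[0]["R"] == pytest.approx(factor, rel=0.15)


def test_adapters_participate_when_included():
    pool = ReadPool(["AAAA"], adapter_5p="GG", adapter_3p="CC")
    with_ad = count_kmers(pool, k=2, include_adapters=True)
    assert with_ad.counts["GG"] == 1 and with_ad.counts["GA"] == 1
    without = count_kmers(pool, k=2, include_adapters=False)
    assert "GG" not in without.counts


def test_dna_letters_and_case_normalized():
    pool = ReadPool(["ggtAcgT"])
    assert pool.reads == ["GGUACGU"]
    with pytest.raises(ValueError):
        ReadPool(["ACGX"])


# ---------------------------------------------------------------------------
# strong-G4 pattern
# ---------------------------------------------------------------------------

def test_printed_sequences_classify_as_expected():
    assert has_strong_g4(TERRA23)        # four GGG runs, UUA loops
    assert not has_strong_g4(HIV_TAR)    # a single GGG run only
    assert not has_strong_g4("A" * 10)
    assert has_strong_g4(STXBP5)         # GGG/GGG/GGGG/GGG with short loops
    spans = match_strong_g4(TERRA23)
    assert spans and spans[0] == (2, 23)


def test_matcher_equals_exhaustive_oracle_on_all_length_8():
    """Every 4^8 length-8 sequence, against the recursive decomposition
    oracle, for a compact run/loop family where matches actually occur."""
    spec = PatternSpec(g_run_min=2, g_run_max=3, loop_max=1, n_runs=2,
                       min_g_for_control=8)
    n_match = 0
    for tup in itertools.product("ACGU", repeat=8):
        seq = "".join(tup)
        got = bool(match_strong_g4(seq, spec))
        assert got == oracle_match(seq, spec), seq
        n_match += got
    assert 0 < n_match < 4**8


@pytest.mark.parametrize("seed", range(2))
def test_matcher_equals_oracle_on_random_20mers_default_pattern(seed):
    rng = np.random.default_rng(seed)
    spec = PatternSpec()
    # G-biased alphabet so the default pattern has real matches
    seqs = ["".join(rng.choice(list("ACGUGGG"), size=20)) for _ in range(3000)]
    for seq in seqs:
        assert bool(match_strong_g4(seq, spec)) == oracle_match(seq, spec), seq


def test_backtracking_beats_greedy_run_consumption():
    # 7 G's then a loop then GGG...: a greedy maximal first run (6) leaves
    # only one G and fails; the valid decomposition uses shorter runs
    seq = "GGGGGGGAAGGGAAGGGAAGGG"
    assert has_strong_g4(seq)


def test_classification_rules():
    labels, fractions = classify_pool(ReadPool(["A" * 40]))
    assert labels == ["other"]
    scattered = "AG" * 9 + "A" * 22  # 9 guanines, no run of 3
    labels, _ = classify_pool(ReadPool([scattered]))
    assert labels == ["non_g4_control"]
    embedded = ("A" * 8 + TERRA23 + "A" * 9)
    labels, _ = classify_pool(ReadPool([embedded]))
    assert labels == ["strong_g4"]
    assert sum(fractions.values()) == pytest.approx(1.0)


def test_classification_fractions_sum_to_one_on_random_pool():
    inp, _ = generate_read_pools(PoolSpec(n_reads=2000, seed=2))
    _, fractions = classify_pool(inp)
    assert sum(fractions.values()) == pytest.approx(1.0)


def test_adapters_extend_the_pattern_search_region():
    # the read alone lacks a 4th G-run (it still holds >= 8 guanines, so it
    # falls into the control class); the 3' adapter completes the pattern
    read = "GGGAAGGGAAGGGAAAAA"
    pool = ReadPool([read], adapter_3p="GGG")
    assert classify_pool(pool, include_adapters=True)[0] == ["strong_g4"]
    assert classify_pool(pool, include_adapters=False)[0] == ["non_g4_control"]


# ---------------------------------------------------------------------------
# pattern enrichment
# ---------------------------------------------------------------------------

def test_pattern_enrichment_identity_and_hand_ratio():
    pool = ReadPool([TERRA23, "A" * 23])
    assert pattern_enrichment(pool, pool) == pytest.approx(1.0)

    inp = ReadPool([TERRA23] + ["A" * 23] * 3)    # 25% strong_g4
    bound = ReadPool([TERRA23] * 2 + ["A" * 23] * 2)  # 50%
    assert pattern_enrichment(bound, inp) == pytest.approx(2.0)

    no_g4 = ReadPool(["A" * 23] * 4)
    with pytest.warns(UserWarning, match="absent"):
        assert pattern_enrichment(bound, no_g4) is None


@pytest.mark.parametrize("factor", [2.0, 5.0])
def test_end_to_end_pattern_recovery_from_generator(factor):
    """A structure-selective binder with weight f on strong-G4 reads yields a
    measured pattern enrichment within sampling error of the reweighting
    oracle (which is ~f, since strong-G4 reads are rare in uniform pools)."""
    n = 100_000
    inp, bound = generate_read_pools(
        PoolSpec(n_reads=n, pattern_enrichment=factor, seed=31))
    ratio = pattern_enrichment(bound, inp)
    is_g4 = np.array([has_strong_g4(r) for r in inp.reads])
    p = is_g4.mean()
    assert p > 0
    w = np.where(is_g4, factor, 1.0)
    q = (w * is_g4).sum() / w.sum()          # expected bound-pool g4 fraction
    expect = q / p
    se = np.sqrt(q * (1 - q) / n) / p        # binomial error on the bound draw
    assert abs(ratio - expect) < 4 * se
    assert expect == pytest.approx(factor, rel=0.02)


# ---------------------------------------------------------------------------
# FOREST normalization
# ---------------------------------------------------------------------------

def test_forest_normalization_hand_values():
    net = forest_normalize({"p1": 100.0}, {"p1": 40.0}, {"p1": "s1"})
    assert net == {"s1": pytest.approx(60.0)}
    net2 = forest_normalize({"a": 100.0, "b": 120.0}, {"a": 40.0, "b": 40.0},
                            {"a": "s", "b": "s"})
    assert net2 == {"s": pytest.approx(70.0)}
    neg = forest_normalize({"a": 10.0}, {"a": 50.0}, {"a": "s"})
    assert neg["s"] == pytest.approx(-40.0)
    with pytest.raises(KeyError, match="p9"):
        forest_normalize({"p9": 1.0}, {}, {"p9": "s"})


def test_fasta_round_trip(tmp_path):
    pool = ReadPool(["GGGAAACCC", "UUUACGUAC"], label="demo")
    path = tmp_path / "pool.fasta"
    write_pool_fasta(pool, path)
    back = read_pool_fasta(path)
    assert back.reads == pool.reads
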