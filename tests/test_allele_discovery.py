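"""Read-support rules, clustering, genotype tables, lineage assignment."""
import pytest

from mhchap._seq import canonical, revcomp
from mhchap.allele_discovery import (assign_lineage, build_genotype_table,
                                     call_novel_exonic, call_novel_fulllength,
                                     classify_expression, classify_transcript,
                                     cluster_identical, discover,
                                     extract_size_window, map_known)
from mhchap.model import (MAJOR, MINOR, AlleleSequence, GenotypeCall, Read,
                          ReadCluster, ReadSet)


def _rs(*seqs, sample="s1"):
    return ReadSet(reads=[Read(f"r{i}", s) for i, s in enumerate(seqs)],
                   sample_id=sample)


def _cluster(seq, size, orientations=("fwd", "rev")):
    return ReadCluster(representative=canonical(seq),
                       members=[("s1", f"r{i}") for i in range(size)],
                       orientations=frozenset(orientations))


# -- size window -------------------------------------------------------------

def test_size_window_closed_interval():
    rs = _rs("A" * 899, "A" * 900, "A" * 1200, "A" * 1201)
    kept = extract_size_window(rs, 900, 1200)
    assert sorted(len(r.sequence) for r in kept) == [900, 1200]
    assert len(extract_size_window(_rs(), 900, 1200)) == 0
    with pytest.raises(ValueError):
        extract_size_window(rs, 1200, 900)


# -- mapping to known --------------------------------------------------------

def test_map_known_exact_revcomp_and_mismatch():
    db = [AlleleSequence("al1", "ACGTACGTTT")]
    asg, res = map_known(_rs("ACGTACGTTT"), db)
    assert asg == {"r0": ["al1"]}
    asg, res = map_known(_rs(revcomp("ACGTACGTTT")), db)
    assert asg == {"r0": ["al1"]}
    asg, res = map_known(_rs("ACGTACGTTA"), db)   # one substitution
    assert not asg and len(res) == 1


def test_map_known_partial_containment():
    db = [AlleleSequence("part", "GTACG")]
    asg, res = map_known(_rs("ACGTACGTTT"), db)
    assert asg == {"r0": ["part"]}


def test_map_known_matches_brute_force():
    """Oracle equivalence on a random read x allele grid."""
    import numpy as np
    rng = np.random.default_rng(17)
    bases = "ACGT"
    alleles = []
    for i in range(20):
        L = int(rng.integers(30, 60))
        alleles.append(AlleleSequence(
            f"al{i}", "".join(bases[b] for b in rng.integers(0, 4, L))))
    reads = []
    for i in range(100):
        src = alleles[int(rng.integers(0, len(alleles)))].sequence
        s = src
        if rng.random() < 0.3:    # substring
            a = int(rng.integers(0, max(1, len(s) - 25)))
            s = s[a:a + 25]
        if rng.random() < 0.3:    # mutate
            pos = int(rng.integers(0, len(s)))
            s = s[:pos] + ("A" if s[pos] != "A" else "C") + s[pos + 1:]
        if rng.random() < 0.5:
            s = revcomp(s)
        reads.append(s)

    def brute(read, allele):
        shorter, longer = sorted((read, allele.sequence), key=len)
        return any(shorter in t or revcomp(shorter) in t for t in (longer,))

    asg, res = map_known(_rs(*reads), alleles)
    for i, s in enumerate(reads):
        expect = sorted(a.name for a in alleles if brute(s, a))
        assert asg.get(f"r{i}", []) == expect


# -- clustering ---------------------------------------------------------------

def test_cluster_identical_groups_and_conserves():
    rs = _rs("AAACGT", "AAACGT", revcomp("AAACGT"), "TTTTTA", "CCCCCA")
    clusters = cluster_identical(rs)
    assert sum(c.size for c in clusters) == 5
    sizes = sorted(c.size for c in clusters)
    assert sizes == [1, 1, 3]
    top = clusters[0]
    assert top.size == 3 and top.orientations == frozenset({"fwd", "rev"})


def test_cluster_all_distinct_singletons():
    rs = _rs("AAAAAA", "CCACCC", "GGTGGA")
    assert all(c.size == 1 for c in cluster_identical(rs))


# -- acceptance rules ---------------------------------------------------------

def test_fulllength_rule_three_read_boundary():
    accepted = call_novel_fulllength([_cluster("ACGTAA", 3)], min_reads=3)
    assert len(accepted) == 1 and accepted[0].support_reads == 3
    assert not call_novel_fulllength([_cluster("ACGTAA", 2)], min_reads=3)


def test_fulllength_extension_of_known_partial():
    known = [AlleleSequence("Paan-B*01:01", "ACGTACGTACGTACGTACGT")]
    extended = "TTTTT" + known[0].sequence + "GGGGG"
    out = call_novel_fulllength([_cluster(extended, 3)], known, min_reads=3)
    assert out[0].status == "extension"
    assert "Paan-B*01:01" in out[0].name
    novel = call_novel_fulllength([_cluster("A" * 30, 3)], known, min_reads=3)
    assert novel[0].status == "novel"


def test_exonic_rule_count_and_orientation():
    ok = call_novel_exonic([_cluster("ACGTAA", 10)], min_reads=10)
    assert len(ok) == 1
    assert not call_novel_exonic([_cluster("ACGTAA", 9)], min_reads=10)
    fwd_only = _cluster("ACGTAA", 25, orientations=("fwd",))
    assert not call_novel_exonic([fwd_only], min_reads=10)


def test_threshold_monotonicity():
    clusters = [_cluster("ACGTAA", k) for k in (2, 3, 5, 9, 12)]
    prev = None
    for mr in (1, 2, 3, 5, 10, 13):
        got = {c.support_reads for c in call_novel_fulllength(clusters, min_reads=mr)}
        if prev is not None:
            assert got <= prev
        prev = got


# -- transcript / expression classification ----------------------------------

def test_classify_transcript_rules():
    intact = "ATGAAACCCGGGTTTAAA"
    assert classify_transcript(intact) == "bona_fide"
    deleted = intact[:4] + intact[5:]          # 1-nt deletion: frameshift
    assert classify_transcript(deleted) == "pseudogene"
    early_stop = "ATGTAACCCGGGTTTAAA"          # in-frame premature stop
    assert classify_transcript(early_stop) == "pseudogene"
    with pytest.raises(ValueError):
        classify_transcript("AT")


def test_classify_expression_threshold():
    call = GenotypeCall("s1", counts={"X": 200.0, "Y": 6.0})
    classify_expression(call, tau=0.1)
    assert call.expression == {"X": MAJOR, "Y": MINOR}
    single = GenotypeCall("s1", counts={"X": 5.0})
    classify_expression(single, tau=0.1)
    assert single.expression == {"X": MAJOR}
    equal = GenotypeCall("s1", counts={"X": 7.0, "Y": 7.0})
    classify_expression(equal, tau=0.99)
    assert set(equal.expression.values()) == {MAJOR}


def test_classify_expression_is_per_locus():
    call = GenotypeCall("s1", counts={"a1": 100.0, "a2": 5.0,
                                      "b1": 10.0, "b2": 9.0})
    classify_expression(call, tau=0.1,
                        locus_of={"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    assert call.expression == {"a1": MAJOR, "a2": MINOR,
                               "b1": MAJOR, "b2": MAJOR}


# -- genotype table -----------------------------------------------------------

def test_genotype_table_counts_and_fractional_ambiguity():
    assignments = {"s1": {"r1": ["alA"], "r2": ["alA", "alB"]}}
    calls = build_genotype_table(["s1"], assignments, [], [])
    c = calls[0]
    assert c.counts == {"alA": 1.5, "alB": 0.5}
    assert c.ambiguous == {"alA", "alB"}


def test_genotype_table_includes_accepted_cluster_members():
    cl = _cluster("ACGTAA", 4)
    accepted = [AlleleSequence("novel1", cl.representative, status="novel")]
    calls = build_genotype_table(["s1"], {}, [cl], accepted)
    assert calls[0].counts == {"novel1": 4.0}


# -- lineage assignment --------------------------------------------------------

@pytest.fixture
def known_pool():
    return [
        AlleleSequence("Paan-B*02:01", "ACGTACGTACGTACGTACGT", locus="B",
                       lineage="B*02"),
        AlleleSequence("Paan-A*01:01", "TGCATGCATGCATGCATGCA", locus="A",
                       lineage="A*01"),
    ]


def test_assign_lineage_nearest_neighbour(known_pool):
    novel = AlleleSequence("q", "ACGTACGTACGTACGTACGA")   # 1/20 from B*02:01
    locus, lineage, name = assign_lineage(novel, known_pool, theta_lineage=0.1)
    assert locus == "B" and lineage == "B*02"


def test_assign_lineage_new_lineage_beyond_theta(known_pool):
    novel = AlleleSequence("q", "ACGTACGTACGTTGCAACGA")
    locus, lineage, _ = assign_lineage(novel, known_pool, theta_lineage=0.02)
    assert locus == "B" and lineage.startswith("B*nl")


def test_assign_lineage_tie_is_unassigned():
    pool = [AlleleSequence("a", "AAAA", locus="A", lineage="A*01"),
            AlleleSequence("b", "TTTT", locus="B", lineage="B*01")]
    novel = AlleleSequence("q", "AATT")
    locus, lineage, name = assign_lineage(novel, pool)
    assert locus == "unassigned"


def test_assign_lineage_exact_match_keeps_name(known_pool):
    novel = AlleleSequence("q", "ACGTACGTACGTACGTACGT")
    locus, lineage, name = assign_lineage(novel, known_pool)
    assert name == "Paan-B*02:01"


# -- end-to-end conservation ---------------------------------------------------

def test_discover_conserves_reads_per_sample():
    from mhchap.synthetic_data import SimConfig, simulate_cohort, simulate_cohort_reads
    cfg = SimConfig(seed=21, n_founders=4, n_generations=1, n_offspring_per_gen=3,
                    reads_per_animal=150)
    t = simulate_cohort(cfg)
    reads, _ = simulate_cohort_reads(t)
    known = [a for a in t.pool.alleles][:5]
    res = discover(reads, known, platform="full_length")
    for sid, rs in reads.items():
        c = res.conservation[sid]
        assert c["input"] == len(rs)
        assert c["discarded_size"] + c["assigned"] + c["residual"] == c["input"]
        total = sum(res.genotype_calls[[x.sample_id for x in
                                        res.genotype_calls].index(sid)].counts.values())
        assert total <= len(rs) + 1e-9
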