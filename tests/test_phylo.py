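"""Distance, NJ and clustering behaviour against closed forms and oracles."""
import itertools
import math
import random

import numpy as np
import pytest
import skbio

from mhchap.model import SaturationError
from mhchap.phylo import (CODON_TABLE, STOP_CODONS, DistanceMatrix,
                          distance_matrix, jc_distance, jc_from_p,
                          lineage_clusters, nei_gojobori, nei_gojobori_ds,
                          neighbor_joining, p_distance, pairwise_sites,
                          to_newick)

from oracles import ng_oracle


# -- pairwise deletion -------------------------------------------------------

def test_pairwise_sites_removes_ambiguity_per_pair():
    assert pairwise_sites("ACGT", "ACGT") == [0, 1, 2, 3]
    assert pairwise_sites("ANGT", "ACGT") == [0, 2, 3]
    assert pairwise_sites("AC-T", "ACGT") == [0, 1, 3]
    with pytest.raises(ValueError):
        pairwise_sites("AC", "ACG")
    with pytest.raises(ValueError):
        p_distance("NNNN", "ACGT")


# -- Jukes-Cantor ------------------------------------------------------------

def test_jc_closed_form():
    assert jc_from_p(0.0) == 0.0
    assert jc_from_p(0.1) == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))
    assert jc_from_p(0.1) == pytest.approx(0.10732, abs=1e-5)
    with pytest.raises(SaturationError):
        jc_from_p(0.75)


def test_jc_distance_monotone_in_p():
    ps = np.linspace(0.0, 0.74, 50)
    ds = [jc_from_p(p) for p in ps]
    assert all(b > a for a, b in zip(ds, ds[1:]))


def test_jc_distance_on_sequences():
    assert jc_distance("ACGTACGTAC", "ACGTACGTAC") == 0.0
    # one difference out of ten sites
    d = jc_distance("ACGTACGTAC", "ACGTACGTAA")
    assert d == pytest.approx(jc_from_p(0.1))


# -- Nei-Gojobori ------------------------------------------------------------

def test_ng_identical_is_zero():
    cds = "ATGAAACCCGGGTTT"
    res = nei_gojobori(cds, cds)
    assert res.ds == 0.0 and res.dn == 0.0


def test_ng_single_synonymous_third_position_change():
    # CCC -> CCA is synonymous (Pro); all other codons identical
    c1 = "ATGAAACCCGGGTTT"
    c2 = "ATGAAACCAGGGTTT"
    res = nei_gojobori(c1, c2)
    assert res.syn_diffs == pytest.approx(1.0)
    assert res.nonsyn_diffs == pytest.approx(0.0)
    assert res.ds == pytest.approx(jc_from_p(1.0 / res.s_sites))


def test_ng_stop_codon_is_an_error():
    with pytest.raises(ValueError, match="stop codon"):
        nei_gojobori("ATGTAA", "ATGAAA")


def test_ng_matches_exhaustive_pathway_oracle():
    rng = np.random.default_rng(42)
    codons = sorted(set(CODON_TABLE) - STOP_CODONS)
    n_checked = 0
    for _ in range(200):
        L = int(rng.integers(5, 31))
        c1 = [codons[i] for i in rng.integers(0, len(codons), L)]
        c2 = [codons[int(rng.integers(0, len(codons)))] if rng.random() < 0.3
              else c for c in c1]
        s1, s2 = "".join(c1), "".join(c2)
        S, Sd, ps = ng_oracle(s1, s2)
        if ps >= 0.75:
            continue
        try:
            res = nei_gojobori(s1, s2)
        except SaturationError:   # nonsynonymous side can saturate at small L
            continue
        assert res.s_sites == pytest.approx(S, abs=1e-9)
        assert res.syn_diffs == pytest.approx(Sd, abs=1e-9)
        assert res.ds == pytest.approx(jc_from_p(ps), abs=1e-12)
        n_checked += 1
    assert n_checked > 150


def test_ng_agrees_with_biopython_on_stop_free_pairs():
    """Cross-check against an independent NG86 implementation.

    Restricted to codon pairs whose substitution pathways never touch a
    stop codon -- the one convention the two implementations share.
    """
    from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    def stop_free(c1, c2):
        diff = [i for i in range(3) if c1[i] != c2[i]]
        for order in itertools.permutations(diff):
            cur = c1
            for pos in order:
                cur = cur[:pos] + c2[pos] + cur[pos + 1:]
                if cur in STOP_CODONS:
                    return False
        return True

    rng = np.random.default_rng(7)
    codons = sorted(set(CODON_TABLE) - STOP_CODONS)
    n = 0
    while n < 50:
        L = int(rng.integers(10, 25))
        c1 = [codons[i] for i in rng.integers(0, len(codons), L)]
        c2 = [codons[int(rng.integers(0, len(codons)))] if rng.random() < 0.25
              else c for c in c1]
        if not all(stop_free(a, b) for a, b in zip(c1, c2)):
            continue
        s1, s2 = "".join(c1), "".join(c2)
        try:
            mine = nei_gojobori(s1, s2)
            dn, ds = cal_dn_ds(CodonSeq(s1), CodonSeq(s2), method="NG86")
        except Exception:
            continue
        assert mine.ds == pytest.approx(ds, abs=1e-9)
        assert mine.dn == pytest.approx(dn, abs=1e-9)
        n += 1


def test_ng_symmetry_and_nonnegativity():
    rng = np.random.default_rng(3)
    codons = sorted(set(CODON_TABLE) - STOP_CODONS)
    for _ in range(25):
        c1 = [codons[i] for i in rng.integers(0, len(codons), 12)]
        c2 = [codons[int(rng.integers(0, len(codons)))] if rng.random() < 0.2
              else c for c in c1]
        s1, s2 = "".join(c1), "".join(c2)
        try:
            a, b = nei_gojobori(s1, s2), nei_gojobori(s2, s1)
        except SaturationError:
            continue
        assert a.ds == pytest.approx(b.ds) and a.ds >= 0.0


# -- neighbour joining -------------------------------------------------------

def _random_additive(seed, n):
    r = random.Random(seed)
    names = [f"t{i}" for i in range(n)]
    nodes = {nm: skbio.TreeNode(name=nm) for nm in names}
    active = list(names)
    while len(active) > 1:
        a, b = r.sample(active, 2)
        nodes[a].length = r.uniform(0.05, 1.0)
        nodes[b].length = r.uniform(0.05, 1.0)
        key = min(a, b)
        nodes[key] = skbio.TreeNode(children=[nodes[a], nodes[b]])
        active.remove(a)
        active.remove(b)
        active.append(key)
    dmat = nodes[active[0]].tip_tip_distances()
    taxa = sorted(names)
    order = [list(dmat.ids).index(t) for t in taxa]
    return taxa, dmat.data[np.ix_(order, order)]


@pytest.mark.parametrize("seed,n", [(s, n) for s in range(3) for n in (4, 5, 6, 7, 8)])
def test_nj_reproduces_additive_matrices(seed, n):
    taxa, d = _random_additive(seed, n)
    tree = neighbor_joining(DistanceMatrix(taxa=taxa, d=d))
    out = tree.tip_tip_distances()
    order = [list(out.ids).index(t) for t in taxa]
    assert np.abs(out.data[np.ix_(order, order)] - d).max() < 1e-9


def test_nj_three_taxa_closed_form():
    taxa = ["a", "b", "c"]
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    tree = neighbor_joining(DistanceMatrix(taxa=taxa, d=d))
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["a"] == pytest.approx(1.0)
    assert lengths["b"] == pytest.approx(2.0)
    assert lengths["c"] == pytest.approx(3.0)


def test_nj_matches_skbio_on_random_matrix():
    """Independent-route check: same additive matrix, same topology."""
    taxa, d = _random_additive(99, 7)
    mine = neighbor_joining(DistanceMatrix(taxa=taxa, d=d))
    ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=taxa))
    assert mine.compare_rfd(ref) == 0.0


def test_nj_requires_three_taxa_and_is_deterministic():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(taxa=["a", "b"], d=np.zeros((2, 2))))
    taxa = [f"t{i}" for i in range(5)]
    d = np.ones((5, 5)) - np.eye(5)
    t1 = to_newick(neighbor_joining(DistanceMatrix(taxa=taxa, d=d)))
    t2 = to_newick(neighbor_joining(DistanceMatrix(taxa=taxa, d=d)))
    assert t1 == t2


# -- lineage clustering ------------------------------------------------------

def test_lineage_clusters_thresholds():
    seqs = {"a": "AAAA", "b": "AAAT", "c": "TTTT"}
    dm = distance_matrix(seqs, method="p")
    assert lineage_clusters(dm, 1.0) == [["a", "b", "c"]]
    assert lineage_clusters(dm, 0.0) == [["a"], ["b"], ["c"]]
    assert lineage_clusters(dm, 0.3) == [["a", "b"], ["c"]]


def test_lineage_clusters_recover_simulated_lineages():
    from mhchap.synthetic_data import SimConfig, simulate_allele_pool
    cfg = SimConfig(seed=11, pseudogene_prob=0.0)
    pool = simulate_allele_pool(cfg)
    a_alleles = {al.name: al.sequence for al in pool.by_locus("A")}
    dm = distance_matrix(a_alleles, method="p")
    theta = (cfg.intra_lineage_divergence + cfg.inter_lineage_divergence) / 2
    clusters = lineage_clusters(dm, theta)
    truth = {}
    for al in pool.by_locus("A"):
        truth.setdefault(al.lineage, set()).add(al.name)
    assert {frozenset(c) for c in clusters} == {frozenset(v) for v in truth.values()}


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(taxa=["a", "b"], d=np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(taxa=["a", "b"], d=np.array([[0.0, -1.0], [-1.0, 0.0]]))
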