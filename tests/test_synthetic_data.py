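"""Generator properties: determinism, divergence structure, transmission."""
import numpy as np
import pytest

from mhchap._seq import canonical
from mhchap.model import MAJOR, MINOR
from mhchap.phylo import p_distance
from mhchap.synthetic_data import (SimConfig, build_haplotypes,
                                   simulate_allele_pool, simulate_cohort,
                                   simulate_cohort_reads, simulate_reads,
                                   within_b_crossover)


def test_seed_is_mandatory_and_config_validated():
    with pytest.raises(TypeError):
        SimConfig()
    with pytest.raises(ValueError):
        SimConfig(seed=1, per_base_error=1.5)
    with pytest.raises(ValueError):
        SimConfig(seed=1, a_genes_per_hap=(3, 1))
    with pytest.raises(ValueError):
        SimConfig(seed=1, n_founders=1)


def test_same_seed_identical_cohorts():
    a = simulate_cohort(SimConfig(seed=42))
    b = simulate_cohort(SimConfig(seed=42))
    assert a.diplotypes == b.diplotypes
    assert {h: t.allele_ids for h, t in a.haplotypes.items()} == \
        {h: t.allele_ids for h, t in b.haplotypes.items()}
    ra, ca = simulate_cohort_reads(a)
    rb, cb = simulate_cohort_reads(b)
    assert ca == cb
    for animal in ra:
        assert [(r.id, r.sequence) for r in ra[animal]] == \
            [(r.id, r.sequence) for r in rb[animal]]


def test_pool_divergence_structure():
    cfg = SimConfig(seed=2, pseudogene_prob=0.0)
    pool = simulate_allele_pool(cfg)
    by_lineage = {}
    for al in pool.alleles:
        by_lineage.setdefault((al.locus, al.lineage), []).append(al)
    intra, inter = [], []
    a_lins = [v for (loc, _), v in by_lineage.items() if loc == "A"]
    for lin in a_lins:
        for i in range(len(lin)):
            for j in range(i + 1, len(lin)):
                intra.append(p_distance(lin[i].sequence, lin[j].sequence)[0])
    for i in range(len(a_lins)):
        for j in range(i + 1, len(a_lins)):
            inter.append(p_distance(a_lins[i][0].sequence, a_lins[j][0].sequence)[0])
    assert max(intra, default=0.0) < min(inter)
    assert np.mean(inter) == pytest.approx(cfg.inter_lineage_divergence, rel=0.35)
    if intra:
        assert np.mean(intra) == pytest.approx(cfg.intra_lineage_divergence, rel=0.8)


def test_pool_sequences_are_coding_and_distinct():
    from mhchap.allele_discovery import classify_transcript
    pool = simulate_allele_pool(SimConfig(seed=3))
    seqs = [al.sequence for al in pool.alleles]
    assert len(set(seqs)) == len(seqs)
    for al in pool.alleles:
        if al.status == "pseudogene":
            assert classify_transcript(al.sequence) == "pseudogene"
            assert len(al.sequence) % 3 != 0
        else:
            assert len(al.sequence) % 3 == 0
            assert classify_transcript(al.sequence) == "bona_fide"


def test_pseudogene_prob_one_puts_pseudogene_on_every_haplotype():
    cfg = SimConfig(seed=4, pseudogene_prob=1.0)
    pool = simulate_allele_pool(cfg, np.random.default_rng((4, 0)))
    haps = build_haplotypes(cfg, pool, np.random.default_rng((4, 1)))
    assert all(len(h.pseudogenes) >= 1 for h in haps.values())


def test_recomb_off_every_offspring_hap_is_parental():
    cfg = SimConfig(seed=5, recomb_prob_AB=0.0, recomb_prob_withinB=0.0)
    t = simulate_cohort(cfg)
    for rec in t.pedigree:
        if rec.dam_id is None:
            continue
        hm, hp = t.diplotypes[rec.animal_id]
        assert hm in t.diplotypes[rec.dam_id]
        assert hp in t.diplotypes[t.true_sire[rec.animal_id]]
        # child's allele set within the union of its true parents' sets
        union = (t.allele_presence(rec.dam_id)
                 | t.allele_presence(t.true_sire[rec.animal_id]))
        assert t.allele_presence(rec.animal_id) <= union
    assert not t.recomb_events


def test_within_b_crossover_shares_proper_subsets():
    cfg = SimConfig(seed=6, n_haplotypes=4, disjoint_lineages=True,
                    pseudogene_prob=0.0)
    pool = simulate_allele_pool(cfg, np.random.default_rng((6, 0)))
    haps = build_haplotypes(cfg, pool, np.random.default_rng((6, 1)))
    ids = sorted(haps)
    h1 = next(h for h in ids if len(haps[h].b_alleles) >= 4)
    h2 = next(h for h in ids if h != h1)
    rec = within_b_crossover(haps[h1], haps[h2], np.random.default_rng(0), "R01")
    s1 = rec.b_alleles & haps[h1].b_alleles
    s2 = rec.b_alleles & haps[h2].b_alleles
    assert s1 and s2                                # mixes both parents
    assert s1 < haps[h1].b_alleles                  # proper subset of donor 1
    assert rec.a_alleles == haps[h1].a_alleles      # A block from one parent
    assert rec.str_d6s2854 == haps[h1].str_d6s2854  # STR travels with A


def test_sire_ambiguity_truth_always_among_candidates():
    cfg = SimConfig(seed=7, sire_ambiguity_frac=1.0)
    t = simulate_cohort(cfg)
    ambiguous = [r for r in t.pedigree if len(r.sire_ids) == 2]
    assert ambiguous
    for r in ambiguous:
        assert t.true_sire[r.animal_id] in r.sire_ids


def test_reads_error_free_match_some_transcript():
    cfg = SimConfig(seed=8, per_base_error=0.0, n_founders=2, n_generations=0,
                    n_offspring_per_gen=0, reads_per_animal=60)
    t = simulate_cohort(cfg)
    reads, counts = simulate_cohort_reads(t)
    truth = {canonical(s) for s in t.pool.sequences.values()}
    orientations = set()
    for rs in reads.values():
        for r in rs:
            assert canonical(r.sequence) in truth
            orientations.add(r.sequence == canonical(r.sequence))
    assert orientations == {True, False}    # both directions occur


def test_minor_weight_zero_silences_minors():
    cfg = SimConfig(seed=9, minor_expression_weight=0.0)
    t = simulate_cohort(cfg)
    reads, counts = simulate_cohort_reads(t)
    for animal, cnt in counts.items():
        for allele in cnt:
            assert t.pool.expression[allele] == MAJOR


def test_major_minor_read_ratio_tracks_weight():
    """Monte-Carlo: mean minor/major count ratio ~= configured weight."""
    cfg = SimConfig(seed=10, per_base_error=0.0, reads_per_animal=450)
    t = simulate_cohort(cfg)
    animal = next(a for a in t.animals
                  if {MAJOR, MINOR} <= {t.pool.expression[x]
                                        for x in t.allele_presence(a)})
    weights = t.expression_weights(animal)
    ratios = []
    for i in range(100):
        rng = np.random.default_rng((123, i))
        _, counts = simulate_reads(weights, t.pool.sequences, cfg, rng, "x")
        majors = [counts.get(al, 0) for al, w in weights.items() if w == 1.0]
        minors = [counts.get(al, 0) for al, w in weights.items() if w < 1.0]
        ratios.append(np.mean(minors) / np.mean(majors))
    mean = np.mean(ratios)
    se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
    assert abs(mean - cfg.minor_expression_weight) < 3 * se + 1e-3


def test_bona_fide_b_count_within_config_implied_range():
    cfg = SimConfig(seed=11)
    t = simulate_cohort(cfg)
    lo, hi = cfg.b_genes_per_hap
    for a in t.animals:
        n = sum(1 for x in t.allele_presence(a)
                if not x.endswith("ps") and x.split("*")[0].endswith("B"))
        assert lo <= n <= 2 * hi


def test_platform_window_lengths():
    cfg = SimConfig(seed=12, platform="long_exon23", per_base_error=0.0,
                    n_founders=2, n_generations=0, reads_per_animal=30)
    t = simulate_cohort(cfg)
    reads, _ = simulate_cohort_reads(t)
    lengths = {len(r.sequence) for rs in reads.values() for r in rs}
    assert lengths == {755}
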