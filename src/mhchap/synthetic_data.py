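"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a pedigreed Old World monkey breeding colony typed
for a copy-number-variable MHC class I region:

* an allele pool organised in deep-branched lineages (large inter-lineage
  divergence, little polymorphism within a lineage) for an *A*-like and a
  *B*-like locus group, with optional Bw4/Bw6 windows planted at mature
  positions 77-83 and frameshifted pseudogene transcripts;
* haplotypes carrying 1-3 A genes and 3-7 B genes (plus occasional
  pseudogenes) and a linked microsatellite signature (1-4 D6S2854 and 0-2
  D6S2859 fragment lengths);
* Mendelian transmission through a multi-generation pedigree with rare
  recombination between the A and B blocks or within the B block
  ("patchwork" haplotypes), and a fraction of offspring with two candidate
  sires;
* expression-weighted amplicon reads (majors >> minors, ~450 reads per
  animal) with optional per-base substitution error and random read
  orientation.

Every random draw flows from the mandatory ``SimConfig.seed``; identical
seeds give byte-for-byte identical cohorts.  Truth tables (haplotype
catalogue, diplotypes, per-allele read counts, recombination events) are
kept so every downstream module can be scored without recomputation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._seq import revcomp
from .model import (LOCUS_A, LOCUS_B, MAJOR, MARKER_D6S2854, MARKER_D6S2859,
                    MINOR, PLATFORM_FULL_LENGTH, PLATFORM_LONG_EXON23,
                    STATUS_KNOWN, STATUS_PSEUDOGENE, AlleleSequence,
                    PedigreeRecord, Read, ReadSet)
from .phylo import CODON_TABLE, STOP_CODONS

# transcript geometry: 366 codons (1098 nt) of coding sequence without the
# terminal stop; 24-codon signal peptide, so mature positions 77-83 sit at
# codons 100-106 (0-based).
CDS_CODONS = 366
CDS_LEN = CDS_CODONS * 3
SIGNAL_CODONS = 24
BW_WINDOW_CODONS = range(SIGNAL_CODONS + 76, SIGNAL_CODONS + 83)
# fixed exon 2-3 style amplicon window (0-based half-open slice, 755 nt)
EXON23_SLICE = (72, 827)

_MOTIF_AA = {
    "Bw4": "NLRIALR",
    "Bw6_identical": "SLRNLRG",
    "Bw6_canonical": "NLRNLRG",
}
_MOTIF_STRINGS = frozenset(_MOTIF_AA.values())

_NONSTOP_CODONS = sorted(set(CODON_TABLE) - STOP_CODONS)
_CODONS_FOR_AA: dict[str, list[str]] = {}
for _c, _a in CODON_TABLE.items():
    _CODONS_FOR_AA.setdefault(_a, []).append(_c)
for _a in _CODONS_FOR_AA:
    _CODONS_FOR_AA[_a].sort()


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    The seed is mandatory: the generator has no implicit entropy source.
    """

    seed: int
    n_haplotypes: int = 10
    n_founders: int = 10
    n_generations: int = 2
    n_offspring_per_gen: int = 15
    a_genes_per_hap: tuple[int, int] = (1, 3)
    b_genes_per_hap: tuple[int, int] = (3, 7)
    pseudogene_prob: float = 0.10
    missing_a_prob: float = 0.05
    n_lineages_a: int = 12
    n_lineages_b: int = 35
    alleles_per_lineage: tuple[int, int] = (1, 2)
    intra_lineage_divergence: float = 0.005
    inter_lineage_divergence: float = 0.06
    minor_expression_weight: float = 0.05
    reads_per_animal: int = 450
    per_base_error: float = 0.002
    recomb_prob_AB: float = 0.02
    recomb_prob_withinB: float = 0.02
    sire_ambiguity_frac: float = 0.15
    platform: str = PLATFORM_FULL_LENGTH
    # motif planting: fraction of lineages per class (rest get "other" windows);
    # Bw4 defaults to 0 -- no identical Bw4 motif is seen in this system.
    bw4_frac: float = 0.0
    bw6_identical_frac: float = 0.15
    bw6_canonical_frac: float = 0.25
    minor_a_lineages: int = 1
    minor_b_lineage_frac: float = 0.6
    d6s2854_grid: tuple[int, int, int] = (180, 260, 2)
    d6s2859_grid: tuple[int, int, int] = (140, 180, 2)
    chimera_rate: float = 0.0      # off by default; hook only
    disjoint_lineages: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("a_genes_per_hap", "b_genes_per_hap", "alleles_per_lineage"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name}: empty or negative range ({lo}, {hi})")
        for name in ("pseudogene_prob", "missing_a_prob", "minor_expression_weight",
                     "per_base_error", "recomb_prob_AB", "recomb_prob_withinB",
                     "sire_ambiguity_frac", "bw4_frac", "bw6_identical_frac",
                     "bw6_canonical_frac", "chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.recomb_prob_AB + self.recomb_prob_withinB > 1.0:
            raise ValueError("recombination probabilities sum above 1")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.platform not in (PLATFORM_FULL_LENGTH, PLATFORM_LONG_EXON23):
            raise ValueError(f"unknown platform {self.platform!r}")


@dataclass
class AllelePool:
    alleles: list[AlleleSequence]
    expression: dict[str, str]          # allele -> major/minor
    motif_class: dict[str, str]         # allele -> planted window class
    sequences: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.sequences = {a.name: a.sequence for a in self.alleles}

    def by_locus(self, locus: str) -> list[AlleleSequence]:
        return [a for a in self.alleles if a.locus == locus and
                a.status != STATUS_PSEUDOGENE]

    @property
    def pseudogenes(self) -> list[AlleleSequence]:
        return [a for a in self.alleles if a.status == STATUS_PSEUDOGENE]


@dataclass
class TrueHaplotype:
    hap_id: str
    a_alleles: frozenset[str]
    b_alleles: frozenset[str]
    pseudogenes: frozenset[str] = frozenset()
    str_d6s2854: frozenset[int] = frozenset()
    str_d6s2859: frozenset[int] = frozenset()
    recombinant: Optional[str] = None    # None, "A_B" or "within_B"

    @property
    def allele_ids(self) -> frozenset[str]:
        return self.a_alleles | self.b_alleles | self.pseudogenes


@dataclass
class RecombEvent:
    child: str
    parent: str
    kind: str                   # "A_B" or "within_B"
    hap_a_side: str             # donor of the A block (and STR)
    hap_b_side: str             # donor of (part of) the B block
    new_hap: str


@dataclass
class CohortTruth:
    config: SimConfig
    pool: AllelePool
    haplotypes: dict[str, TrueHaplotype]
    pedigree: list[PedigreeRecord]
    sex: dict[str, str]
    true_sire: dict[str, Optional[str]]
    diplotypes: dict[str, tuple[str, str]]     # animal -> (maternal, paternal)
    recomb_events: list[RecombEvent]

    @property
    def animals(self) -> list[str]:
        return [r.animal_id for r in self.pedigree]

    def carried_haplotypes(self) -> dict[str, list[str]]:
        """hap_id -> animals carrying it (support)."""
        out: dict[str, list[str]] = {}
        for a, (hm, hp) in self.diplotypes.items():
            for h in {hm, hp}:
                out.setdefault(h, []).append(a)
        return {h: sorted(v) for h, v in sorted(out.items())}

    def allele_presence(self, animal: str) -> frozenset[str]:
        hm, hp = self.diplotypes[animal]
        return self.haplotypes[hm].allele_ids | self.haplotypes[hp].allele_ids

    def expression_weights(self, animal: str) -> dict[str, float]:
        """Relative transcription weight per allele carried by the animal.

        Pseudogene transcripts are transcribed at minor-like levels.
        """
        w = {}
        cfg = self.config
        for name in sorted(self.allele_presence(animal)):
            if self.pool.expression.get(name, MINOR) == MAJOR:
                w[name] = 1.0
            else:
                w[name] = cfg.minor_expression_weight
        return w

    def str_observation(self, animal: str) -> dict[str, frozenset[int]]:
        hm, hp = self.diplotypes[animal]
        h1, h2 = self.haplotypes[hm], self.haplotypes[hp]
        return {
            MARKER_D6S2854: h1.str_d6s2854 | h2.str_d6s2854,
            MARKER_D6S2859: h1.str_d6s2859 | h2.str_d6s2859,
        }


# ---------------------------------------------------------------------------
# allele pool
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator) -> list[str]:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=CDS_CODONS)
    return [_NONSTOP_CODONS[i] for i in idx]


def _mutate(codons: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    """Jukes-Cantor style uniform substitutions at ``rate`` per site.

    The Bw window codons are never touched (planted motifs are lineage
    identity) and substitutions creating stop codons are reverted, keeping
    every sequence coding.
    """
    seq = list("".join(codons))
    protected = {3 * c + k for c in BW_WINDOW_CODONS for k in range(3)}
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for pos in hits:
        if pos in protected:
            continue
        old = seq[pos]
        alts = [b for b in "ACGT" if b != old]
        seq[pos] = alts[rng.integers(0, 3)]
        ci = pos // 3
        codon = "".join(seq[3 * ci:3 * ci + 3])
        if codon in STOP_CODONS:
            seq[pos] = old
    s = "".join(seq)
    return [s[i:i + 3] for i in range(0, len(s), 3)]


def _encode_window(aa7: str, rng: np.random.Generator) -> list[str]:
    return [_CODONS_FOR_AA[a][rng.integers(0, len(_CODONS_FOR_AA[a]))] for a in aa7]


def _window_aa(codons: list[str]) -> str:
    return "".join(CODON_TABLE[codons[c]] for c in BW_WINDOW_CODONS)


def simulate_allele_pool(config: SimConfig,
                         rng: Optional[np.random.Generator] = None) -> AllelePool:
    """Generate the lineage-structured allele pool.

    Lineage founders diverge from a per-locus ancestor by half the
    inter-lineage divergence each (so founder pairs sit at roughly the
    configured inter-lineage distance); alleles within a lineage diverge
    from their founder by half the intra-lineage divergence.
    """
    if rng is None:
        rng = np.random.default_rng((config.seed, 0))
    alleles: list[AlleleSequence] = []
    expression: dict[str, str] = {}
    motif_class: dict[str, str] = {}
    seen: set[str] = set()

    for locus, n_lin in ((LOCUS_A, config.n_lineages_a), (LOCUS_B, config.n_lineages_b)):
        ancestor = _random_cds(rng)
        # per-lineage motif classes, apportioned by the configured fractions
        n_bw4 = int(round(config.bw4_frac * n_lin))
        n_bw6i = int(round(config.bw6_identical_frac * n_lin))
        n_bw6c = int(round(config.bw6_canonical_frac * n_lin))
        if n_bw4 + n_bw6i + n_bw6c > n_lin:
            raise ValueError("motif fractions exceed the number of lineages")
        classes = (["Bw4"] * n_bw4 + ["Bw6_identical"] * n_bw6i +
                   ["Bw6_canonical"] * n_bw6c)
        classes += ["other"] * (n_lin - len(classes))
        rng.shuffle(classes)

        n_minor = (config.minor_a_lineages if locus == LOCUS_A
                   else int(round(config.minor_b_lineage_frac * n_lin)))
        minor_lineages = set(range(n_lin - n_minor, n_lin))

        for lin in range(n_lin):
            founder = _mutate(ancestor, config.inter_lineage_divergence / 2.0, rng)
            cls = classes[lin]
            if cls == "other":
                while _window_aa(founder) in _MOTIF_STRINGS or "*" in _window_aa(founder):
                    for c in BW_WINDOW_CODONS:
                        founder[c] = _NONSTOP_CODONS[rng.integers(0, len(_NONSTOP_CODONS))]
            else:
                win = _encode_window(_MOTIF_AA[cls], rng)
                for i, c in enumerate(BW_WINDOW_CODONS):
                    founder[c] = win[i]
            lineage = f"{locus}*{lin + 1:02d}"
            n_alleles = int(rng.integers(config.alleles_per_lineage[0],
                                         config.alleles_per_lineage[1] + 1))
            n_alleles = max(n_alleles, 1)
            for ai in range(n_alleles):
                codons = founder if ai == 0 else _mutate(
                    founder, config.intra_lineage_divergence / 2.0, rng)
                seq = "".join(codons)
                tries = 0
                while seq in seen:
                    codons = _mutate(founder, config.intra_lineage_divergence / 2.0, rng)
                    seq = "".join(codons)
                    tries += 1
                    if tries > 50:
                        raise ValueError("allele pool exhausts sequence space; "
                                         "raise divergence or lower allele counts")
                seen.add(seq)
                name = f"Paan-{locus}*{lin + 1:02d}:{ai + 1:02d}"
                alleles.append(AlleleSequence(name=name, sequence=seq,
                                              status=STATUS_KNOWN, locus=locus,
                                              lineage=lineage))
                expression[name] = MINOR if lin in minor_lineages else MAJOR
                motif_class[name] = cls

    # frameshifted pseudogene transcripts, derived from B alleles by a
    # single-nucleotide deletion inside the exon-2 region
    if config.pseudogene_prob > 0:
        b_names = [a.name for a in alleles if a.locus == LOCUS_B]
        for pi in range(2):
            donor_name = b_names[int(rng.integers(0, len(b_names)))]
            donor = next(a for a in alleles if a.name == donor_name)
            pos = int(rng.integers(100, 280))
            seq = donor.sequence[:pos] + donor.sequence[pos + 1:]
            name = f"Paan-B*{90 + pi}:01ps"
            alleles.append(AlleleSequence(name=name, sequence=seq,
                                          status=STATUS_PSEUDOGENE, locus=LOCUS_B,
                                          lineage=f"B*{90 + pi}"))
            expression[name] = MINOR
            motif_class[name] = "other"

    return AllelePool(alleles=alleles, expression=expression, motif_class=motif_class)


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

def _grid_values(grid: tuple[int, int, int]) -> list[int]:
    lo, hi, step = grid
    return list(range(lo, hi + 1, step))


def build_haplotypes(config: SimConfig, pool: AllelePool,
                     rng: np.random.Generator) -> dict[str, TrueHaplotype]:
    """Assemble the founder haplotype catalogue from the pool.

    Each haplotype draws at most one allele per lineage (a lineage stands
    for a locus here), keeps at least one major B transcript, and receives
    a linked STR signature drawn from a seeded length grid (collisions
    across haplotypes are allowed, as real STR lengths are homoplasic).
    With ``disjoint_lineages`` the lineage pool is partitioned so no two
    haplotypes share any allele (used for controlled recombination tests).
    """
    def split(allele_list, major):
        return [a for a in allele_list if (pool.expression[a.name] == MAJOR) == major]

    a_alleles = pool.by_locus(LOCUS_A)
    b_alleles = pool.by_locus(LOCUS_B)

    def by_lineage(allele_list):
        d: dict[str, list[str]] = {}
        for a in allele_list:
            d.setdefault(a.lineage, []).append(a.name)
        return {k: sorted(v) for k, v in sorted(d.items())}

    lin_a_major = by_lineage(split(a_alleles, True))
    lin_a_minor = by_lineage(split(a_alleles, False))
    lin_b_major = by_lineage(split(b_alleles, True))
    lin_b_minor = by_lineage(split(b_alleles, False))

    reserved: set[str] = set()   # alleles already used (disjoint mode)

    def draw(lin_map: dict[str, list[str]], k: int) -> list[str]:
        usable = {lin: [al for al in als if al not in reserved]
                  for lin, als in lin_map.items()}
        usable = {lin: als for lin, als in usable.items() if als}
        lins = sorted(usable)
        if len(lins) < k:
            raise ValueError(
                "not enough lineages to draw a haplotype; increase n_lineages "
                "or relax disjoint_lineages")
        chosen_lins = rng.choice(len(lins), size=k, replace=False)
        out = []
        for li in sorted(int(x) for x in chosen_lins):
            als = usable[lins[li]]
            al = als[int(rng.integers(0, len(als)))]
            out.append(al)
            if config.disjoint_lineages:
                reserved.update(lin_map[lins[li]])
        return out

    g2854 = _grid_values(config.d6s2854_grid)
    g2859 = _grid_values(config.d6s2859_grid)
    haplotypes: dict[str, TrueHaplotype] = {}
    ps_names = sorted(a.name for a in pool.pseudogenes)

    for h in range(config.n_haplotypes):
        a_lo, a_hi = config.a_genes_per_hap
        a_count = int(rng.integers(a_lo, a_hi + 1))
        if rng.random() < config.missing_a_prob:
            a_count = 0
        b_lo, b_hi = config.b_genes_per_hap
        b_count = int(rng.integers(b_lo, b_hi + 1))

        def avail(lin_map: dict[str, list[str]]) -> int:
            return sum(1 for als in lin_map.values()
                       if any(al not in reserved for al in als))

        # 1-2 majors per locus group; minors fill the rest, overflowing back
        # into majors when the minor lineage pool is too small
        n_a_major = min(a_count, 1 + int(rng.integers(0, 2)))
        n_a_minor = min(a_count - n_a_major, avail(lin_a_minor))
        n_a_major = a_count - n_a_minor
        n_b_major = max(1, min(b_count, 1 + int(rng.integers(0, 2))))  # >= 1 major B
        n_b_minor = min(b_count - n_b_major, avail(lin_b_minor))
        n_b_major = b_count - n_b_minor
        hap_a = draw(lin_a_major, n_a_major) + draw(lin_a_minor, n_a_minor)
        hap_b = draw(lin_b_major, n_b_major) + draw(lin_b_minor, n_b_minor)

        ps: list[str] = []
        if ps_names and rng.random() < config.pseudogene_prob:
            n_ps = 1 + int(rng.integers(0, 2))
            ps = list(rng.choice(ps_names, size=min(n_ps, len(ps_names)),
                                 replace=False))

        k2854 = 1 + int(rng.integers(0, 4))
        k2859 = int(rng.integers(0, 3))
        s2854 = frozenset(int(x) for x in rng.choice(g2854, size=k2854, replace=False))
        s2859 = frozenset(int(x) for x in rng.choice(g2859, size=k2859, replace=False))

        hap_id = f"H{h + 1:02d}"
        haplotypes[hap_id] = TrueHaplotype(
            hap_id=hap_id, a_alleles=frozenset(hap_a), b_alleles=frozenset(hap_b),
            pseudogenes=frozenset(str(p) for p in ps),
            str_d6s2854=s2854, str_d6s2859=s2859)
    return haplotypes


def within_b_crossover(h1: TrueHaplotype, h2: TrueHaplotype,
                       rng: np.random.Generator, new_id: str) -> TrueHaplotype:
    """A patchwork haplotype exchanging part of the B block.

    The A block (and its linked STR signature) comes from ``h1``; the B
    content mixes a subset of each parent's B genes.  When block sizes
    allow, at least two genes are kept and at least two dropped from each
    side, which is the content pattern observed for natural within-B
    patchworks.
    """
    b1, b2 = sorted(h1.b_alleles), sorted(h2.b_alleles)
    n1, n2 = len(b1), len(b2)
    # keep >= 2 and drop >= 2 of the first parent's block when it is large
    # enough, and take >= 2 from the second: the content signature of a
    # crossover between interior B loci
    k1 = int(rng.integers(2, n1 - 1)) if n1 >= 4 else int(rng.integers(1, n1))
    if n2 >= 3:
        k2 = int(rng.integers(2, n2))
    else:
        k2 = n2
    new_b = ({str(x) for x in rng.choice(b1, size=k1, replace=False)} |
             {str(x) for x in rng.choice(b2, size=k2, replace=False)})
    return TrueHaplotype(hap_id=new_id, a_alleles=h1.a_alleles,
                         b_alleles=frozenset(new_b), pseudogenes=h1.pseudogenes,
                         str_d6s2854=h1.str_d6s2854, str_d6s2859=h1.str_d6s2859,
                         recombinant="within_B")


def ab_crossover(h_a_side: TrueHaplotype, h_b_side: TrueHaplotype,
                 new_id: str) -> TrueHaplotype:
    """A haplotype joining the A block of one parent with the B block of
    the other (the STR signature travels with the A block; pseudogenes sit
    in the B region)."""
    return TrueHaplotype(hap_id=new_id, a_alleles=h_a_side.a_alleles,
                         b_alleles=h_b_side.b_alleles,
                         pseudogenes=h_b_side.pseudogenes,
                         str_d6s2854=h_a_side.str_d6s2854,
                         str_d6s2859=h_a_side.str_d6s2859,
                         recombinant="A_B")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> CohortTruth:
    """Pedigree + diplotypes + truth tables for one synthetic cohort."""
    rng = np.random.default_rng((config.seed, 1))
    pool = simulate_allele_pool(config, np.random.default_rng((config.seed, 0)))
    haplotypes = build_haplotypes(config, pool, rng)
    hap_ids = sorted(haplotypes)

    pedigree: list[PedigreeRecord] = []
    sex: dict[str, str] = {}
    true_sire: dict[str, Optional[str]] = {}
    diplotypes: dict[str, tuple[str, str]] = {}
    recomb_events: list[RecombEvent] = []
    n_recomb = 0

    for i in range(config.n_founders):
        aid = f"F{i + 1:02d}"
        sex[aid] = "F" if i % 2 == 0 else "M"
        pedigree.append(PedigreeRecord(animal_id=aid))
        true_sire[aid] = None
        pair = rng.integers(0, len(hap_ids), size=2)
        diplotypes[aid] = (hap_ids[int(pair[0])], hap_ids[int(pair[1])])

    def meiosis(parent: str, child: str) -> str:
        nonlocal n_recomb
        hm, hp = diplotypes[parent]
        pick = int(rng.integers(0, 2))
        chosen, other = (hm, hp) if pick == 0 else (hp, hm)
        u = rng.random()
        if u < config.recomb_prob_AB and chosen != other:
            n_recomb += 1
            new_id = f"R{n_recomb:02d}"
            new = ab_crossover(haplotypes[chosen], haplotypes[other], new_id)
            haplotypes[new_id] = new
            recomb_events.append(RecombEvent(child=child, parent=parent, kind="A_B",
                                             hap_a_side=chosen, hap_b_side=other,
                                             new_hap=new_id))
            return new_id
        if u < config.recomb_prob_AB + config.recomb_prob_withinB and chosen != other:
            n_recomb += 1
            new_id = f"R{n_recomb:02d}"
            new = within_b_crossover(haplotypes[chosen], haplotypes[other], rng, new_id)
            haplotypes[new_id] = new
            recomb_events.append(RecombEvent(child=child, parent=parent,
                                             kind="within_B", hap_a_side=chosen,
                                             hap_b_side=other, new_hap=new_id))
            return new_id
        return chosen

    for g in range(config.n_generations):
        females = [a for a in sorted(sex) if sex[a] == "F"]
        males = [a for a in sorted(sex) if sex[a] == "M"]
        if not females or not males:
            raise ValueError("cannot breed: need founders of both sexes")
        for k in range(config.n_offspring_per_gen):
            aid = f"G{g + 1}-{k + 1:02d}"
            # every dam is bred (round-robin), sires drawn at random -- the
            # usage pattern of a managed colony (few sires, all dams used)
            dam = females[k % len(females)]
            sire = males[int(rng.integers(0, len(males)))]
            sex[aid] = "F" if rng.random() < 0.5 else "M"
            hm = meiosis(dam, aid)
            hp = meiosis(sire, aid)
            diplotypes[aid] = (hm, hp)
            true_sire[aid] = sire
            sires = (sire,)
            if len(males) > 1 and rng.random() < config.sire_ambiguity_frac:
                others = [m for m in males if m != sire]
                decoy = others[int(rng.integers(0, len(others)))]
                sires = (sire, decoy) if rng.random() < 0.5 else (decoy, sire)
            pedigree.append(PedigreeRecord(animal_id=aid, dam_id=dam, sire_ids=sires))

    return CohortTruth(config=config, pool=pool, haplotypes=haplotypes,
                       pedigree=pedigree, sex=sex, true_sire=true_sire,
                       diplotypes=diplotypes, recomb_events=recomb_events)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _platform_sequence(seq: str, platform: str) -> str:
    if platform == PLATFORM_LONG_EXON23:
        lo, hi = EXON23_SLICE
        return seq[lo:hi]
    return seq


def simulate_reads(weights: dict[str, float], sequences: dict[str, str],
                   config: SimConfig, rng: np.random.Generator,
                   sample_id: str) -> tuple[ReadSet, dict[str, int]]:
    """Expression-weighted reads for one sample.

    Read counts are multinomial over ``reads_per_animal`` with per-allele
    probabilities proportional to the expression weights; each read gets
    independent per-base substitution errors and a random orientation.
    Returns the reads plus the true per-allele read counts.
    """
    names = sorted(weights)
    w = np.array([weights[n] for n in names], dtype=float)
    if w.sum() <= 0:
        return ReadSet(reads=[], sample_id=sample_id), {}
    counts = rng.multinomial(config.reads_per_animal, w / w.sum())
    reads: list[Read] = []
    true_counts: dict[str, int] = {}
    serial = 0
    for name, n in zip(names, counts):
        if n == 0:
            continue
        true_counts[name] = int(n)
        template = _platform_sequence(sequences[name], config.platform)
        L = len(template)
        n_err = rng.binomial(L, config.per_base_error, size=n)
        flips = rng.random(n) < 0.5
        for j in range(n):
            s = template
            if n_err[j] > 0:
                arr = list(s)
                pos = rng.choice(L, size=int(n_err[j]), replace=False)
                for p in pos:
                    alts = [b for b in "ACGT" if b != arr[p]]
                    arr[p] = alts[int(rng.integers(0, 3))]
                s = "".join(arr)
            if flips[j]:
                s = revcomp(s)
            serial += 1
            reads.append(Read(id=f"{sample_id}_r{serial:05d}", sequence=s))
    return ReadSet(reads=reads, sample_id=sample_id), true_counts


def simulate_cohort_reads(truth: CohortTruth,
                          config: Optional[SimConfig] = None,
                          ) -> tuple[dict[str, ReadSet], dict[str, dict[str, int]]]:
    """Reads for every animal; returns (readsets, true read counts).

    Each animal draws from its own seeded stream, so per-animal output is
    independent of cohort size and iteration order.
    """
    cfg = config or truth.config
    readsets: dict[str, ReadSet] = {}
    true_counts: dict[str, dict[str, int]] = {}
    for idx, animal in enumerate(truth.animals):
        rng = np.random.default_rng((cfg.seed, 2, idx))
        rs, tc = simulate_reads(truth.expression_weights(animal),
                                truth.pool.sequences, cfg, rng, animal)
        readsets[animal] = rs
        true_counts[animal] = tc
    return readsets, true_counts
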