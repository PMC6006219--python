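"""Distance-based lineage analysis for class I transcripts.

Implements the distance stack used to resolve allele lineages: proportion
distance with pairwise deletion of ambiguous positions, the Jukes-Cantor
correction, the Nei-Gojobori (unweighted pathway) synonymous distance dS,
neighbour-joining tree construction with deterministic tie-breaking, and
single-linkage lineage clustering at a distance threshold.

All distances are in substitutions per site; dS is in synonymous
substitutions per synonymous site.  Sequences are assumed pre-aligned
(same-locus transcripts on matching coordinates); a gap or IUPAC ambiguity
code makes a position ambiguous for that sequence pair only.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .model import SaturationError

_UNAMBIGUOUS = frozenset("ACGT")

_BASES = "TCAG"
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = dict(zip(_CODONS, _AA))
STOP_CODONS = frozenset(c for c, a in CODON_TABLE.items() if a == "*")


# ---------------------------------------------------------------------------
# pairwise site handling and simple distances
# ---------------------------------------------------------------------------

def pairwise_sites(seq1: str, seq2: str) -> list[int]:
    """Positions where both sequences carry an unambiguous A/C/G/T.

    Mirrors pairwise deletion: ambiguous positions are removed per sequence
    pair, not across the whole alignment.
    """
    if len(seq1) != len(seq2):
        raise ValueError(f"length mismatch: {len(seq1)} vs {len(seq2)}")
    s1, s2 = seq1.upper(), seq2.upper()
    return [i for i, (a, b) in enumerate(zip(s1, s2))
            if a in _UNAMBIGUOUS and b in _UNAMBIGUOUS]


def p_distance(seq1: str, seq2: str) -> tuple[float, int]:
    """(proportion of differing sites, number of sites compared)."""
    sites = pairwise_sites(seq1, seq2)
    if not sites:
        raise ValueError("no unambiguous positions shared by the pair")
    s1, s2 = seq1.upper(), seq2.upper()
    diffs = sum(s1[i] != s2[i] for i in sites)
    return diffs / len(sites), len(sites)


def jc_from_p(p: float) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p)."""
    if p < 0:
        raise ValueError("p must be non-negative")
    if p >= 0.75:
        raise SaturationError(f"p={p:.4f} >= 3/4: JC distance undefined (saturation)")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def jc_distance(seq1: str, seq2: str) -> float:
    p, _ = p_distance(seq1, seq2)
    return jc_from_p(p)


# ---------------------------------------------------------------------------
# Nei-Gojobori synonymous distance (NG86, unweighted pathways)
# ---------------------------------------------------------------------------

def _syn_site_fraction(codon: str) -> float:
    """Number of synonymous sites in a codon (sum over positions of the
    fraction of the three possible changes that are synonymous).

    Changes into stop codons count as nonsynonymous, the usual NG86
    convention for site counting.
    """
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if CODON_TABLE[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    with equal weight over all minimal substitution pathways.

    Pathways passing through a stop codon are discarded; if every pathway is
    blocked the average is taken over all pathways instead (degenerate case,
    only possible for 2-3 differences between rare codon pairs).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nsyn = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                hit_stop = True
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        (blocked if hit_stop else valid).append((syn, nsyn))
    pool = valid if valid else blocked
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


@dataclass(frozen=True)
class NgResult:
    ds: float
    dn: float
    s_sites: float
    n_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    codons_used: int


def nei_gojobori(cds1: str, cds2: str) -> NgResult:
    """Unweighted-pathway Nei-Gojobori estimates for an in-frame CDS pair.

    Codons containing an ambiguous base in either sequence are skipped
    pairwise.  A stop codon in either sequence is an error (inputs are
    expected to be coding sequence without the terminal stop).
    """
    if len(cds1) != len(cds2):
        raise ValueError("CDS length mismatch")
    if len(cds1) % 3:
        raise ValueError("CDS length not a multiple of 3")
    s1, s2 = cds1.upper(), cds2.upper()
    S = N = Sd = Nd = 0.0
    used = 0
    for k in range(0, len(s1), 3):
        c1, c2 = s1[k:k + 3], s2[k:k + 3]
        if set(c1) - _UNAMBIGUOUS or set(c2) - _UNAMBIGUOUS:
            continue
        for c in (c1, c2):
            if c in STOP_CODONS:
                raise ValueError(f"stop codon {c} at codon {k // 3 + 1}")
        S += (_syn_site_fraction(c1) + _syn_site_fraction(c2)) / 2.0
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
        used += 1
    if used == 0:
        raise ValueError("no unambiguous codons shared by the pair")
    N = 3.0 * used - S
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    return NgResult(ds=jc_from_p(ps), dn=jc_from_p(pn), s_sites=S, n_sites=N,
                    syn_diffs=Sd, nonsyn_diffs=Nd, codons_used=used)


def nei_gojobori_ds(cds1: str, cds2: str) -> float:
    return nei_gojobori(cds1, cds2).ds


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray
    method: str = "p"
    pairwise_positions_used: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


def distance_matrix(sequences: Mapping[str, str], method: str = "p") -> DistanceMatrix:
    """All-pairs distances. ``method``: 'p', 'jc' or 'ng-ds'."""
    taxa = sorted(sequences)
    n = len(taxa)
    d = np.zeros((n, n))
    used: dict[tuple[str, str], int] = {}
    for i, j in itertools.combinations(range(n), 2):
        s1, s2 = sequences[taxa[i]], sequences[taxa[j]]
        if method == "p":
            p, m = p_distance(s1, s2)
            d[i, j] = d[j, i] = p
        elif method == "jc":
            p, m = p_distance(s1, s2)
            d[i, j] = d[j, i] = jc_from_p(p)
        elif method == "ng-ds":
            res = nei_gojobori(s1, s2)
            d[i, j] = d[j, i] = res.ds
            m = res.codons_used * 3
        else:
            raise ValueError(f"unknown method {method!r}")
        used[(taxa[i], taxa[j])] = m
    return DistanceMatrix(taxa=taxa, d=d, method=method, pairwise_positions_used=used)


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Standard Q-criterion neighbour joining.

    Ties on Q are broken on the lexicographically smallest pair of node
    labels (a node is labelled by the smallest leaf name below it), which
    makes the output deterministic.  Negative branch lengths are clamped to
    zero with a warning unless ``clamp_negative`` is False.

    Returns an unrooted tree as a ``skbio.TreeNode`` with a trifurcating
    root (the usual convention for unrooted binary topologies).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")

    def _mklen(x: float) -> float:
        if x < 0:
            if clamp_negative:
                warnings.warn(f"negative branch length {x:.6g} clamped to 0")
                return 0.0
            return x
        return x

    # active nodes: label -> TreeNode; label = smallest leaf name below node
    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in dm.taxa}
    dist: dict[frozenset[str], float] = {}
    for i, j in itertools.combinations(range(n), 2):
        dist[frozenset((dm.taxa[i], dm.taxa[j]))] = float(dm.d[i, j])

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    active = sorted(nodes)
    while len(active) > 3:
        r = len(active)
        row = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (r - 2) * d(a, b) - row[a] - row[b]
            key = (q, min(a, b), max(a, b))
            if best is None or key < best:
                best = key
        _, a, b = best
        la = _mklen(0.5 * d(a, b) + (row[a] - row[b]) / (2.0 * (r - 2)))
        lb = _mklen(d(a, b) - (0.5 * d(a, b) + (row[a] - row[b]) / (2.0 * (r - 2))))
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = la, lb
        u = TreeNode(children=[na, nb])
        ulabel = min(a, b)
        nodes[ulabel] = u
        fresh = {}
        for c in active:
            if c in (a, b):
                continue
            fresh[frozenset((ulabel, c))] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        for c in active:
            dist.pop(frozenset((a, c)), None)
            dist.pop(frozenset((b, c)), None)
        dist.update(fresh)
        active = sorted(nodes)

    a, b, c = active
    la = _mklen(0.5 * (d(a, b) + d(a, c) - d(b, c)))
    lb = _mklen(0.5 * (d(a, b) + d(b, c) - d(a, c)))
    lc = _mklen(0.5 * (d(a, c) + d(b, c) - d(a, b)))
    for lbl, ln in ((a, la), (b, lb), (c, lc)):
        nodes[lbl].length = ln
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return root


def to_newick(tree: TreeNode) -> str:
    return str(tree).strip()


# ---------------------------------------------------------------------------
# lineage clustering
# ---------------------------------------------------------------------------

def lineage_clusters(dm: DistanceMatrix, theta: float) -> list[list[str]]:
    """Single-linkage clusters at threshold ``theta``.

    Equivalent to connected components of the graph joining pairs with
    d <= theta.  Deterministic: clusters sorted by their smallest member.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    parent = list(range(len(dm.taxa)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n = len(dm.taxa)
    for i, j in itertools.combinations(range(n), 2):
        if dm.d[i, j] <= theta:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[str]] = {}
    for i, t in enumerate(dm.taxa):
        groups.setdefault(find(i), []).append(t)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])
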