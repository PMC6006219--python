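"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration or via
third-party code paths, never by calling the implementation under test.
"""
from __future__ import annotations

import itertools
from typing import Mapping, Sequence

from Bio.Seq import Seq

from mhchap.model import PedigreeRecord


# ---------------------------------------------------------------------------
# exhaustive diplotype enumeration (tiny instances only)
# ---------------------------------------------------------------------------

def _splits(universe: frozenset):
    """All ordered pairs (H1, H2) with H1 | H2 == universe."""
    items = sorted(universe, key=repr)
    for choice in itertools.product((0, 1, 2), repeat=len(items)):
        h1, h2 = set(), set()
        for it, c in zip(items, choice):
            if c in (0, 2):
                h1.add(it)
            if c in (1, 2):
                h2.add(it)
        yield frozenset(h1), frozenset(h2)


def enumerate_minimal_catalogues(observations: Mapping[str, frozenset],
                                 pedigree: Sequence[PedigreeRecord],
                                 ) -> tuple[int, set[frozenset]]:
    """(minimal catalogue size, set of all minimal catalogues).

    Exhaustive search over every consistent assignment of ordered
    haplotype pairs; exponential, usable only for tiny instances
    (|observation| <= ~5, <= ~12 animals).
    """
    ped = {r.animal_id: r for r in pedigree}
    order = []
    placed: set[str] = set()
    remaining = set(observations)
    while remaining:
        progress = False
        for a in sorted(remaining):
            r = ped[a]
            parents = [p for p in (r.dam_id, *r.sire_ids) if p in observations]
            if all(p in placed for p in parents):
                order.append(a)
                placed.add(a)
                remaining.discard(a)
                progress = True
        if not progress:
            raise ValueError("pedigree not topologically orderable")

    best_size = [None]
    catalogues: set[frozenset] = set()

    def rec(i: int, assignment: dict):
        if i == len(order):
            cat = frozenset(h for pair in assignment.values() for h in pair)
            size = len(cat)
            if best_size[0] is None or size < best_size[0]:
                best_size[0] = size
                catalogues.clear()
                catalogues.add(cat)
            elif size == best_size[0]:
                catalogues.add(cat)
            return
        a = order[i]
        u = observations[a]
        r = ped[a]
        cur = frozenset(h for pair in assignment.values() for h in pair)
        if best_size[0] is not None and len(cur) > best_size[0]:
            return
        if r.dam_id in assignment:
            m_opts = set(assignment[r.dam_id])
        else:
            m_opts = None
        p_opts = set()
        has_sire = False
        for s in r.sire_ids:
            if s in assignment:
                has_sire = True
                p_opts |= set(assignment[s])
        for h1, h2 in _splits(u):
            if m_opts is not None and h1 not in m_opts:
                continue
            if has_sire and h2 not in p_opts:
                continue
            assignment[a] = (h1, h2)
            rec(i + 1, assignment)
            del assignment[a]

    rec(0, {})
    if best_size[0] is None:
        raise ValueError("no consistent solution")
    return best_size[0], catalogues


# ---------------------------------------------------------------------------
# exhaustive Nei-Gojobori pathway oracle
# ---------------------------------------------------------------------------

def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng_oracle(cds1: str, cds2: str) -> tuple[float, float, float]:
    """(S sites, Sd, pS) by direct enumeration, Biopython translation.

    Synonymous-site fractions count changes into stop codons as
    nonsynonymous; codon pathways are enumerated explicitly and those
    passing through a stop codon are dropped (equal weight over the rest).
    """
    assert len(cds1) == len(cds2) and len(cds1) % 3 == 0
    S = 0.0
    Sd = 0.0
    n_codons = 0
    for k in range(0, len(cds1), 3):
        c1, c2 = cds1[k:k + 3], cds2[k:k + 3]
        n_codons += 1
        for c in (c1, c2):
            syn = 0
            for pos in range(3):
                for b in "ACGT":
                    if b == c[pos]:
                        continue
                    alt = c[:pos] + b + c[pos + 1:]
                    if _aa(alt) != "*" and _aa(alt) == _aa(c):
                        syn += 1
            S += syn / 6.0      # averaged over the two codons
        diff = [i for i in range(3) if c1[i] != c2[i]]
        if not diff:
            continue
        path_syn = []
        for perm in itertools.permutations(diff):
            cur = c1
            syn = 0
            blocked = False
            for pos in perm:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if _aa(nxt) == "*":
                    blocked = True
                if _aa(nxt) == _aa(cur):
                    syn += 1
                cur = nxt
            if not blocked:
                path_syn.append(syn)
        if not path_syn:   # all pathways blocked: fall back to all
            for perm in itertools.permutations(diff):
                cur = c1
                syn = 0
                for pos in perm:
                    nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                    if _aa(nxt) == _aa(cur):
                        syn += 1
                    cur = nxt
                path_syn.append(syn)
        Sd += sum(path_syn) / len(path_syn)
    return S, Sd, (Sd / S if S else 0.0)
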