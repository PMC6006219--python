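"""Microsatellite (STR) haplotype inference from family segregation.

D6S2854 and D6S2859 flank the A region and show both length and copy
number variation: an animal displays one to several fragment lengths per
marker, and particular length combinations segregate together through
families, so haplotypes can be deduced.  A haplotype carries one to four
D6S2854 and zero to two D6S2859 lengths.

Lengths are treated as presence sets -- capillary patterns carry no
dosage, so two haplotypes sharing a length are separable only through the
pedigree (a documented limitation).  The minimal-catalogue objective
mirrors the analyst's parsimony; ties are broken on the lexicographic
order of the length sets for determinism.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._phasing import Phaser, PhasingSolution, check_solution
from .model import (MARKER_D6S2854, MARKER_D6S2859, PedigreeRecord, StrGenotype,
                    StrHaplotype)

MAX_D6S2854 = 4
MAX_D6S2859 = 2

Item = tuple[str, int]


def str_observations(genotypes: Sequence[StrGenotype]) -> dict[str, frozenset[Item]]:
    """Fold per-marker genotype rows into one token set per animal."""
    obs: dict[str, set[Item]] = {}
    for g in genotypes:
        obs.setdefault(g.animal_id, set()).update((g.marker, x) for x in g.lengths)
    return {a: frozenset(v) for a, v in obs.items()}


def _marker_counts(items: frozenset[Item]) -> tuple[int, int]:
    n54 = sum(1 for m, _ in items if m == MARKER_D6S2854)
    n59 = sum(1 for m, _ in items if m == MARKER_D6S2859)
    return n54, n59


def _partial_valid(items: frozenset[Item]) -> bool:
    n54, n59 = _marker_counts(items)
    return n54 <= MAX_D6S2854 and n59 <= MAX_D6S2859


@dataclass
class StrPhasingResult:
    catalogue: list[StrHaplotype]
    assignments: dict[str, Optional[tuple[str, str]]]   # animal -> (mat, pat) hap ids
    flagged: dict[str, str]
    incomplete: list[str] = field(default_factory=list)  # haps with no D6S2854 length
    n_optimal: int = 1
    raw: Optional[PhasingSolution] = None


def infer_str_haplotypes(pedigree: Sequence[PedigreeRecord],
                         genotypes: Sequence[StrGenotype],
                         allow_detach: bool = False) -> StrPhasingResult:
    """Deduce the STR haplotype catalogue and per-animal assignments.

    Each animal's observed length set must be the union of two haplotypes,
    each offspring haplotype must equal one haplotype of each (candidate)
    parent, and the catalogue is of minimal cardinality among consistent
    solutions.  Unresolvable animals are flagged, not forced; a family
    with no consistent partition raises :class:`MendelianError` naming it.
    """
    obs = str_observations(genotypes)
    solution = Phaser(obs, pedigree, partial_valid=_partial_valid,
                      allow_detach=allow_detach).solve()
    catalogue: list[StrHaplotype] = []
    incomplete: list[str] = []
    for i, items in enumerate(solution.catalogue):
        hid = f"S{i + 1:02d}"
        h = StrHaplotype(
            hap_id=hid,
            d6s2854=frozenset(x for m, x in items if m == MARKER_D6S2854),
            d6s2859=frozenset(x for m, x in items if m == MARKER_D6S2859))
        if not h.d6s2854:
            incomplete.append(hid)
        catalogue.append(h)
    assignments: dict[str, Optional[tuple[str, str]]] = {}
    for a, pair in solution.assignments.items():
        if pair is None:
            assignments[a] = None
        else:
            assignments[a] = (catalogue[pair[0]].hap_id, catalogue[pair[1]].hap_id)
            for idx in set(pair):
                catalogue[idx].support.append(a)
    for h in catalogue:
        h.support.sort()
    return StrPhasingResult(catalogue=catalogue, assignments=assignments,
                            flagged=solution.flagged, incomplete=incomplete,
                            n_optimal=solution.n_optimal, raw=solution)


def check_str_solution(pedigree: Sequence[PedigreeRecord],
                       genotypes: Sequence[StrGenotype],
                       result: StrPhasingResult) -> bool:
    """Independent union/transmission verification of an STR phasing."""
    obs = str_observations(genotypes)
    by_id = {h.hap_id: h.items() for h in result.catalogue}
    cat = [h.items() for h in result.catalogue]
    index = {h.hap_id: i for i, h in enumerate(result.catalogue)}
    assignments = {a: (index[p[0]], index[p[1]]) if p else None
                   for a, p in result.assignments.items()}
    del by_id
    return check_solution(obs, pedigree, cat, assignments)
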