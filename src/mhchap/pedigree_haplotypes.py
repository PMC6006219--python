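"""A-B haplotype deduction by co-segregation in families.

Genotype calls give each animal a presence set of A and B alleles (read
counts are deliberately not used as copy-number evidence: transcription
differences between majors and minors confound dosage).  Haplotypes --
the allele sets transmitted as units -- are deduced exactly as an analyst
does from families: each animal is the union of two haplotypes, each
offspring haplotype matches one haplotype of the dam and one of a
candidate sire, and the catalogue is minimal.  Alleles may recur on
several haplotypes.  Haplotypes lacking any A transcript are reported
with the caveat that primer dropout cannot be excluded.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from ._phasing import Phaser, PhasingSolution, check_solution
from .model import (LOCUS_A, LOCUS_B, AbHaplotype, GenotypeCall, MendelianError,
                    PedigreeRecord)

WARN_MAX_A = 3
WARN_MAX_B = 8

MISSING_A_CAVEAT = ("no A transcript assigned; absence of a functional A gene "
                    "cannot be distinguished from primer dropout")


def presence_sets(calls: Sequence[GenotypeCall]) -> dict[str, frozenset[str]]:
    return {c.sample_id: c.alleles for c in calls}


def _locus_lookup(locus_of: Optional[Mapping[str, str]], allele: str) -> str:
    if locus_of and allele in locus_of:
        return locus_of[allele]
    # fall back on IPD-style names: Prefix-A*... / Prefix-B*...
    head = allele.split("*")[0]
    if head.endswith("A"):
        return LOCUS_A
    if head.endswith("B"):
        return LOCUS_B
    return LOCUS_B


@dataclass
class AbPhasingResult:
    catalogue: list[AbHaplotype]
    assignments: dict[str, Optional[tuple[str, str]]]
    flagged: dict[str, str]
    sire_used: dict[str, Optional[str]]
    ambiguous_sires: set[str]
    recomb_suspects: list[tuple[str, str]]
    warnings: list[str] = field(default_factory=list)
    n_optimal: int = 1
    raw: Optional[PhasingSolution] = None


def infer_ab_haplotypes(pedigree: Sequence[PedigreeRecord],
                        genotype_calls: Sequence[GenotypeCall] | Mapping[str, frozenset[str]],
                        locus_of: Optional[Mapping[str, str]] = None,
                        pseudogenes: frozenset[str] = frozenset(),
                        allow_detach: bool = False) -> AbPhasingResult:
    """Deduce the A-B haplotype catalogue and per-animal diplotypes.

    ``genotype_calls`` may be GenotypeCall objects or ready presence sets.
    With ``allow_detach`` a transmission that cannot be explained by any
    parental haplotype is detached and surfaced as a recombination
    suspect instead of failing the family.
    """
    if isinstance(genotype_calls, Mapping):
        obs = {a: frozenset(v) for a, v in genotype_calls.items()}
    else:
        obs = presence_sets(genotype_calls)
    solution = Phaser(obs, pedigree, allow_detach=allow_detach).solve()

    catalogue: list[AbHaplotype] = []
    warns: list[str] = []
    for i, items in enumerate(solution.catalogue):
        hid = f"ha{i + 1}"
        ps = frozenset(a for a in items if a in pseudogenes)
        rest = set(items) - ps
        a_set = frozenset(a for a in rest if _locus_lookup(locus_of, a) == LOCUS_A)
        b_set = frozenset(rest) - a_set
        if len(a_set) > WARN_MAX_A:
            warns.append(f"{hid}: {len(a_set)} A alleles (expected <= {WARN_MAX_A})")
        if not 1 <= len(b_set) <= WARN_MAX_B:
            warns.append(f"{hid}: {len(b_set)} B alleles (expected 1..{WARN_MAX_B})")
        catalogue.append(AbHaplotype(hap_id=hid, a_alleles=a_set, b_alleles=b_set,
                                     pseudogenes=ps))

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
    return AbPhasingResult(catalogue=catalogue, assignments=assignments,
                           flagged=solution.flagged, sire_used=solution.sire_used,
                           ambiguous_sires=solution.ambiguous_sires,
                           recomb_suspects=solution.recomb_suspects,
                           warnings=warns, n_optimal=solution.n_optimal,
                           raw=solution)


def check_ab_solution(pedigree: Sequence[PedigreeRecord],
                      observations: Mapping[str, frozenset[str]],
                      result: AbPhasingResult) -> bool:
    """Independent union/transmission verification of an A-B phasing."""
    cat = [h.items() for h in result.catalogue]
    index = {h.hap_id: i for i, h in enumerate(result.catalogue)}
    assignments = {a: (index[p[0]], index[p[1]]) if p else None
                   for a, p in result.assignments.items()}
    return check_solution(dict(observations), pedigree, cat, assignments)


# ---------------------------------------------------------------------------
# sire resolution
# ---------------------------------------------------------------------------

def resolve_sire(record: PedigreeRecord,
                 observations: Mapping[str, frozenset[str]],
                 result: AbPhasingResult) -> str:
    """Pick the candidate sire whose haplotypes can supply the offspring's
    paternal haplotype.  Returns the sire id, or ``"ambiguous"`` when both
    candidates could; raises :class:`MendelianError` when neither can."""
    if len(record.sire_ids) < 2:
        raise ValueError("resolve_sire expects two candidate sires")
    pair = result.assignments.get(record.animal_id)
    if pair is None:
        raise MendelianError(f"{record.animal_id}: no diplotype assigned")
    paternal = pair[1]
    consistent = []
    for s in record.sire_ids:
        spair = result.assignments.get(s)
        if spair is not None and paternal in spair:
            consistent.append(s)
    if not consistent:
        raise MendelianError(
            f"{record.animal_id}: neither candidate sire {list(record.sire_ids)} "
            f"carries the paternal haplotype {paternal}")
    if len(consistent) > 1:
        return "ambiguous"
    return consistent[0]


# ---------------------------------------------------------------------------
# haplotypes without an A transcript
# ---------------------------------------------------------------------------

def detect_missing_a(haplotypes: Sequence[AbHaplotype]) -> list[tuple[str, str]]:
    """(hap_id, caveat) for every haplotype with an empty A set."""
    return [(h.hap_id, MISSING_A_CAVEAT) for h in haplotypes if not h.a_alleles]


# ---------------------------------------------------------------------------
# STR linkage
# ---------------------------------------------------------------------------

@dataclass
class StrLinkConflict:
    ab_hap: str
    str_hap: str
    animals: list[str]


def link_str(ab_result: AbPhasingResult, str_result,
             ) -> tuple[dict[str, str], list[StrLinkConflict]]:
    """Link A-B haplotypes to STR haplotypes by per-slot co-occurrence.

    An A-B haplotype links to an STR haplotype iff, in every animal (and
    chromosome slot) where either is assigned, the other occupies the same
    slot.  Partial co-occurrence is reported as a conflict, not a link.
    """
    ab_slots: dict[str, set[tuple[str, int]]] = {}
    str_slots: dict[str, set[tuple[str, int]]] = {}
    common = set(ab_result.assignments) & set(str_result.assignments)
    for a in sorted(common):
        abp = ab_result.assignments[a]
        stp = str_result.assignments[a]
        if abp is None or stp is None:
            continue
        for k in (0, 1):
            ab_slots.setdefault(abp[k], set()).add((a, k))
            str_slots.setdefault(stp[k], set()).add((a, k))
    links: dict[str, str] = {}
    conflicts: list[StrLinkConflict] = []
    for ab_h, slots in sorted(ab_slots.items()):
        partners = {s for s in str_slots if str_slots[s] & slots}
        if len(partners) == 1:
            s = partners.pop()
            if str_slots[s] == slots:
                links[ab_h] = s
                continue
            conflicts.append(StrLinkConflict(
                ab_hap=ab_h, str_hap=s,
                animals=sorted({a for a, _ in str_slots[s] ^ slots})))
        elif partners:
            for s in sorted(partners):
                conflicts.append(StrLinkConflict(
                    ab_hap=ab_h, str_hap=s,
                    animals=sorted({a for a, _ in (str_slots[s] ^ slots)})))
    for h in ab_result.catalogue:
        if h.hap_id in links:
            h.str_hap = links[h.hap_id]
    return links, conflicts
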