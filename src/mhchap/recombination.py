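"""Patchwork-haplotype detection.

Haplotype pairs whose allele content mixes blocks of one another are the
signature of historic recombination-like events: a swap between the A and
B regions, a crossover within the B region (part of the B genes shared,
part different), or a single switched gene (a gene-conversion candidate).
Gene order inside the B region is unknown from transcript data, so all
calls are allele-content statements, not positional breakpoints.
"""
from __future__ import annotations

from typing import Sequence

from .model import (CLASS_AB_RECOMBINANT, CLASS_NONE, CLASS_SINGLE_SWITCH,
                    CLASS_WITHIN_B, AbHaplotype, PatchworkCall)

DEFAULT_MIN_SHARED = 2
DEFAULT_MIN_UNIQUE = 2


def compare_haplotypes(h1: AbHaplotype, h2: AbHaplotype) -> PatchworkCall:
    """Shared/unique allele partitions per region; symmetric in arguments."""
    a1, a2 = h1.a_alleles, h2.a_alleles
    b1, b2 = h1.b_alleles | h1.pseudogenes, h2.b_alleles | h2.pseudogenes
    return PatchworkCall(
        hap_pair=(h1.hap_id, h2.hap_id),
        shared_a=frozenset(a1 & a2),
        unique_a=(frozenset(a1 - a2), frozenset(a2 - a1)),
        shared_b=frozenset(b1 & b2),
        unique_b=(frozenset(b1 - b2), frozenset(b2 - b1)),
        patch_class=CLASS_NONE)


def _identical_nonempty(shared, u1, u2) -> bool:
    return bool(shared) and not u1 and not u2


def _fully_different(shared, u1, u2) -> bool:
    return not shared and (bool(u1) or bool(u2))


def classify_patchwork(call: PatchworkCall,
                       min_shared: int = DEFAULT_MIN_SHARED,
                       min_unique: int = DEFAULT_MIN_UNIQUE) -> PatchworkCall:
    """Assign the recombination class from the shared/unique partitions.

    Precedence: A-B recombinant (one region identical, the other fully
    different) > within-B recombinant (at least ``min_shared`` shared and
    ``min_unique`` unique B genes on each side) > single-gene switch
    (exactly one allele differs overall; gene-conversion candidate).
    The defaults classify the field's worked examples as intended: a pair
    sharing 3 of 7 B genes with 4 different on each side is a within-B
    recombinant, a pair differing by one extra B gene is a single-gene
    switch candidate.
    """
    if min_shared < 1 or min_unique < 1:
        raise ValueError("thresholds must be >= 1")
    sa, (ua1, ua2) = call.shared_a, call.unique_a
    sb, (ub1, ub2) = call.shared_b, call.unique_b
    cls = CLASS_NONE
    if (_identical_nonempty(sa, ua1, ua2) and _fully_different(sb, ub1, ub2)) or \
       (_identical_nonempty(sb, ub1, ub2) and _fully_different(sa, ua1, ua2)):
        cls = CLASS_AB_RECOMBINANT
    elif (len(sb) >= min_shared and len(ub1) >= min_unique
          and len(ub2) >= min_unique):
        cls = CLASS_WITHIN_B
    elif len(ua1) + len(ua2) + len(ub1) + len(ub2) == 1:
        cls = CLASS_SINGLE_SWITCH
    return PatchworkCall(hap_pair=call.hap_pair, shared_a=sa,
                         unique_a=call.unique_a, shared_b=sb,
                         unique_b=call.unique_b, patch_class=cls)


_CLASS_ORDER = {CLASS_AB_RECOMBINANT: 0, CLASS_WITHIN_B: 1, CLASS_SINGLE_SWITCH: 2}


def scan_catalogue(haplotypes: Sequence[AbHaplotype],
                   min_shared: int = DEFAULT_MIN_SHARED,
                   min_unique: int = DEFAULT_MIN_UNIQUE) -> list[PatchworkCall]:
    """Classify every unordered haplotype pair; keep the non-trivial calls.

    Output is sorted by (class, haplotype ids) and is independent of the
    input order of the catalogue.
    """
    ordered = sorted(haplotypes, key=lambda h: h.hap_id)
    calls = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            call = classify_patchwork(compare_haplotypes(ordered[i], ordered[j]),
                                      min_shared=min_shared, min_unique=min_unique)
            if call.patch_class != CLASS_NONE:
                calls.append(call)
    calls.sort(key=lambda c: (_CLASS_ORDER[c.patch_class], c.hap_pair))
    return calls
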