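"""Low-level nucleotide helpers used throughout the package."""
from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Orientation-normalized form: lexicographically smaller of seq/revcomp.

    Deterministic and symmetric, so two reads of the same molecule sequenced
    in opposite directions map to the same key.
    """
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def orientation(seq: str) -> str:
    """'fwd' if the read already is its canonical form, else 'rev'."""
    return "fwd" if seq == canonical(seq) else "rev"


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def best_offset_p_distance(a: str, b: str) -> float:
    """p-distance over the best ungapped containment of the shorter in the longer.

    Orientation is normalized first.  For equal lengths this is plain
    Hamming/len; otherwise every offset of the shorter sequence along the
    longer one is scanned (both orientations) and the minimum mismatch
    fraction is returned.
    """
    if len(a) > len(b):
        a, b = b, a
    la = len(a)
    if la == 0:
        raise ValueError("empty sequence")
    best = la + 1
    for query in (b, revcomp(b)):
        if la == len(query):
            best = min(best, hamming(a, query))
            continue
        for off in range(len(query) - la + 1):
            d = hamming(a, query[off:off + la])
            if d < best:
                best = d
                if best == 0:
                    return 0.0
    return best / la


def contains_exact(longer: str, shorter: str) -> bool:
    """True if ``shorter`` occurs in ``longer`` in either orientation."""
    return shorter in longer or revcomp(shorter) in longer
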