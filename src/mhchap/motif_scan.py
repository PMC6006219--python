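"""Bw4/Bw6 KIR-ligand motif classification.

Bw4 and Bw6 are mutually exclusive 7-residue epitopes at positions 77-83 of
the mature class I alpha-1 domain and are ligands for NK-cell KIR
receptors.  Classification is an exact-string decision on that 7-mer:

* ``NLRIALR``  -> Bw4
* ``SLRNLRG``  -> Bw6 (identical to the HLA epitope)
* ``NLRNLRG``  -> canonical Bw6
* anything else -> other (reported verbatim for inspection)

Mature-protein numbering depends on the signal-peptide length; the default
of 24 residues is the classical class I leader.  Pseudogene transcripts
have no stable reading frame and are skipped with a notice.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import (BW4, BW6_CANONICAL, BW6_IDENTICAL, MOTIF_OTHER,
                    STATUS_PSEUDOGENE, AlleleSequence, MotifCall)
from .phylo import CODON_TABLE

DEFAULT_SIGNAL_LEN = 24
_WINDOW_START_MATURE = 77   # 1-based mature coordinates, inclusive
_WINDOW_END_MATURE = 83

_MOTIF_CLASSES = {
    "NLRIALR": BW4,
    "SLRNLRG": BW6_IDENTICAL,
    "NLRNLRG": BW6_CANONICAL,
}


@dataclass(frozen=True)
class Translation:
    aa: str                     # residues up to (not including) the first stop
    stop_codon_index: Optional[int]   # 0-based codon index of the first stop
    incomplete_codon: bool      # True when input length was not a multiple of 3


def translate_cds(nt: str) -> Translation:
    """Standard-code translation from the first base.

    Stops at the first stop codon and records its position.  A trailing
    partial codon is dropped and flagged.  Non-ACGT characters are an
    error naming the offending position (1-based).
    """
    seq = nt.upper()
    for i, ch in enumerate(seq):
        if ch not in "ACGT":
            raise ValueError(f"non-ACGT character {ch!r} at position {i + 1}")
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    aa = []
    stop_at = None
    n_codons = len(seq) // 3
    for k in range(n_codons):
        res = CODON_TABLE[seq[3 * k:3 * k + 3]]
        if res == "*":
            stop_at = k
            break
        aa.append(res)
    return Translation(aa="".join(aa), stop_codon_index=stop_at,
                       incomplete_codon=bool(len(seq) % 3))


def extract_bw_window(aa: str, signal_len: int = DEFAULT_SIGNAL_LEN) -> str:
    """Mature residues 77..83 (1-based; mature position 1 = residue
    ``signal_len + 1`` of the primary translation)."""
    if signal_len < 0:
        raise ValueError("signal_len must be >= 0")
    start = signal_len + _WINDOW_START_MATURE - 1
    end = signal_len + _WINDOW_END_MATURE
    if len(aa) < end:
        raise ValueError(
            f"translation of length {len(aa)} does not reach mature position "
            f"{_WINDOW_END_MATURE} (needs {end} residues with signal_len={signal_len})")
    return aa[start:end]


def classify_bw(window: str) -> str:
    if len(window) != 7:
        raise ValueError(f"window must be 7 residues, got {len(window)}")
    return _MOTIF_CLASSES.get(window, MOTIF_OTHER)


def scan_alleles(alleles: Sequence[AlleleSequence],
                 signal_len: int = DEFAULT_SIGNAL_LEN,
                 ) -> tuple[list[MotifCall], list[tuple[str, str]]]:
    """Classify every bona fide allele; returns (calls, skipped).

    ``skipped`` lists (allele, reason) for pseudogenes and for sequences
    whose translation does not reach the window.
    """
    calls: list[MotifCall] = []
    skipped: list[tuple[str, str]] = []
    for al in alleles:
        if al.status == STATUS_PSEUDOGENE:
            skipped.append((al.name, "pseudogene: no stable reading frame"))
            continue
        try:
            tr = translate_cds(al.sequence)
            window = extract_bw_window(tr.aa, signal_len=signal_len)
        except ValueError as exc:
            skipped.append((al.name, str(exc)))
            continue
        calls.append(MotifCall(allele=al.name, window_aa=window,
                               motif_class=classify_bw(window),
                               mature_offset_used=signal_len))
    return calls, skipped
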