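"""Read-support rules that turn amplicon reads into validated alleles.

Two acceptance rule sets are implemented, one per sequencing platform:

* ``full_length`` (CCS-style): reads of 900-1200 bp are extracted, mapped
  against a database of known full-length or partial transcripts at 100%
  identity, the residual reads are clustered by exact identity, and only
  clusters supported by at least three independent reads are retained.
  Candidates that exactly contain a known partial entry are labelled
  extensions of it, the rest are novel.
* ``long_exon23`` (454-style): a sequence is accepted as a new allele only
  if it was detected in both the forward and reverse direction and at
  least ten times with zero mismatches.

Identity is always evaluated after orientation normalization (canonical
form = lexicographically smaller of a sequence and its reverse
complement), so the rules are quality-score free and purely sequence
based.  Read counts are conserved at every step: assigned + clustered +
discarded equals the input, per sample.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from ._seq import best_offset_p_distance, canonical, contains_exact, orientation, revcomp
from .model import (LOCUS_UNASSIGNED, MAJOR, MINOR, PLATFORM_FULL_LENGTH,
                    PLATFORM_LONG_EXON23, STATUS_EXTENSION, STATUS_NOVEL,
                    STATUS_PSEUDOGENE, AlleleSequence, GenotypeCall, ReadCluster,
                    ReadSet)
from .phylo import CODON_TABLE, STOP_CODONS

DEFAULT_SIZE_WINDOW = (900, 1200)
DEFAULT_MIN_READS = {PLATFORM_FULL_LENGTH: 3, PLATFORM_LONG_EXON23: 10}
DEFAULT_TAU = 0.10
DEFAULT_THETA_LINEAGE = 0.02


# ---------------------------------------------------------------------------
# read-level operations
# ---------------------------------------------------------------------------

def extract_size_window(reads: ReadSet, min_len: int = DEFAULT_SIZE_WINDOW[0],
                        max_len: int = DEFAULT_SIZE_WINDOW[1]) -> ReadSet:
    """Keep reads whose length lies in the closed interval [min_len, max_len]."""
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    kept = [r for r in reads if min_len <= len(r.sequence) <= max_len]
    return ReadSet(reads=kept, sample_id=reads.sample_id)


def map_known(reads: ReadSet, known_db: Sequence[AlleleSequence],
              ) -> tuple[dict[str, list[str]], ReadSet]:
    """Assign reads that match a database entry at 100% identity.

    A read matches an entry when, after orientation normalization, the
    shorter of the two occurs in the longer with zero mismatches (exact
    containment -- partial database entries are legitimate).  A read
    matching several entries is assigned to all of them and later counted
    fractionally.  Unassigned reads form the residual.
    """
    full = {}
    for al in known_db:
        full.setdefault(canonical(al.sequence), []).append(al.name)
    partial = [(al.name, al.sequence) for al in known_db]

    assignments: dict[str, list[str]] = {}
    residual = []
    for r in reads:
        hits = list(full.get(canonical(r.sequence), []))
        for name, seq in partial:
            if name in hits:
                continue
            if len(seq) == len(r.sequence):
                continue    # equal length handled by the canonical lookup
            longer, shorter = ((r.sequence, seq) if len(r.sequence) > len(seq)
                               else (seq, r.sequence))
            if contains_exact(longer, shorter):
                hits.append(name)
        if hits:
            assignments[r.id] = sorted(set(hits))
        else:
            residual.append(r)
    return assignments, ReadSet(reads=residual, sample_id=reads.sample_id)


def cluster_identical(residual: Mapping[Optional[str], ReadSet] | ReadSet,
                      ) -> list[ReadCluster]:
    """Equivalence classes of residual reads under exact identity.

    Accepts either a single ReadSet or a mapping sample -> ReadSet (reads
    are pooled across samples but each member remembers its sample).
    Cluster sizes always sum to the residual size.
    """
    if isinstance(residual, ReadSet):
        residual = {residual.sample_id: residual}
    groups: dict[str, ReadCluster] = {}
    for sample in sorted(residual, key=lambda s: (s is None, s)):
        for r in residual[sample]:
            key = canonical(r.sequence)
            cl = groups.get(key)
            if cl is None:
                cl = ReadCluster(representative=key, members=[], orientations=frozenset())
                groups[cl.representative] = cl
            cl.members.append((sample, r.id))
            cl.orientations = cl.orientations | {orientation(r.sequence)}
    return sorted(groups.values(), key=lambda c: (-c.size, c.representative))


# ---------------------------------------------------------------------------
# acceptance rules
# ---------------------------------------------------------------------------

def _extension_of(candidate: str, known_db: Sequence[AlleleSequence]) -> Optional[str]:
    """Name of the longest known entry the candidate exactly extends."""
    best: Optional[AlleleSequence] = None
    for al in known_db:
        if len(al.sequence) < len(candidate) and contains_exact(candidate, al.sequence):
            if best is None or len(al.sequence) > len(best.sequence):
                best = al
    return best.name if best else None


def call_novel_fulllength(clusters: Sequence[ReadCluster],
                          known_db: Sequence[AlleleSequence] = (),
                          min_reads: int = 3) -> list[AlleleSequence]:
    """Full-length rule: clusters with >= min_reads identical reads become
    candidate alleles; a candidate containing a known partial entry as an
    exact substring is an extension of that entry, the rest are novel."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    out: list[AlleleSequence] = []
    serial = 0
    for cl in clusters:
        if cl.size < min_reads:
            continue
        serial += 1
        ext = _extension_of(cl.representative, known_db)
        if ext is not None:
            out.append(AlleleSequence(name=f"{ext}+ext{serial}",
                                      sequence=cl.representative,
                                      status=STATUS_EXTENSION,
                                      support_reads=cl.size))
        else:
            out.append(AlleleSequence(name=f"novel{serial}",
                                      sequence=cl.representative,
                                      status=STATUS_NOVEL,
                                      support_reads=cl.size))
    return out


def call_novel_exonic(clusters: Sequence[ReadCluster],
                      min_reads: int = 10) -> list[AlleleSequence]:
    """Exon 2-3 rule: accepted iff seen >= min_reads times with zero
    mismatches AND in both the forward and reverse direction."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    out = []
    serial = 0
    for cl in clusters:
        if cl.size >= min_reads and cl.orientations == frozenset({"fwd", "rev"}):
            serial += 1
            out.append(AlleleSequence(name=f"novel{serial}",
                                      sequence=cl.representative,
                                      status=STATUS_NOVEL,
                                      support_reads=cl.size))
    return out


# ---------------------------------------------------------------------------
# transcript and expression classification
# ---------------------------------------------------------------------------

def classify_transcript(seq: str, reference: Optional[str] = None) -> str:
    """'pseudogene' if the reading frame is disturbed, else 'bona_fide'.

    A frameshift shows as a length that is no multiple of 3 (relative to
    in-frame full transcripts) or as a stop codon before the end of the
    reference CDS (or before the final codon when no reference is given).
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    if len(seq) % 3 != 0:
        return STATUS_PSEUDOGENE
    limit = (len(reference) // 3 if reference is not None else len(seq) // 3) - 1
    for k in range(min(limit, len(seq) // 3)):
        codon = seq[3 * k:3 * k + 3]
        if codon in STOP_CODONS:
            return STATUS_PSEUDOGENE
    return "bona_fide"


def classify_expression(call: GenotypeCall, tau: float = DEFAULT_TAU,
                        locus_of: Optional[Mapping[str, str]] = None) -> GenotypeCall:
    """Label alleles major/minor within each locus of one sample.

    An allele is major iff its read count is at least ``tau`` times the
    count of the most-read allele of the same locus in the same sample.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    present = {a: c for a, c in call.counts.items() if c > 0}
    if not present:
        warnings.warn(f"sample {call.sample_id}: all-zero counts, no expression labels")
        return call
    buckets: dict[str, list[str]] = {}
    for a in present:
        loc = locus_of.get(a, LOCUS_UNASSIGNED) if locus_of else LOCUS_UNASSIGNED
        buckets.setdefault(loc, []).append(a)
    for loc, names in buckets.items():
        top = max(present[a] for a in names)
        for a in names:
            call.expression[a] = MAJOR if present[a] >= tau * top else MINOR
    return call


# ---------------------------------------------------------------------------
# genotype table
# ---------------------------------------------------------------------------

def build_genotype_table(sample_ids: Sequence[str],
                         assignments: Mapping[str, dict[str, list[str]]],
                         clusters: Sequence[ReadCluster],
                         accepted: Sequence[AlleleSequence]) -> list[GenotypeCall]:
    """Per-sample read counts per allele.

    Counts combine database-assigned reads and member reads of accepted
    clusters.  A read assigned to k alleles contributes 1/k to each and
    raises the ambiguity flag on those alleles.
    """
    accepted_by_seq = {al.sequence: al.name for al in accepted}
    calls = []
    for sid in sample_ids:
        counts: dict[str, float] = {}
        ambiguous: set[str] = set()
        for _read_id, names in assignments.get(sid, {}).items():
            share = 1.0 / len(names)
            for n in names:
                counts[n] = counts.get(n, 0.0) + share
                if len(names) > 1:
                    ambiguous.add(n)
        for cl in clusters:
            name = accepted_by_seq.get(cl.representative)
            if name is None:
                continue
            n_here = sum(1 for s, _ in cl.members if s == sid)
            if n_here:
                counts[name] = counts.get(name, 0.0) + n_here
        calls.append(GenotypeCall(sample_id=sid, counts=counts, ambiguous=ambiguous))
    return calls


# ---------------------------------------------------------------------------
# lineage assignment
# ---------------------------------------------------------------------------

def assign_lineage(novel: AlleleSequence, known_pool: Sequence[AlleleSequence],
                   theta_lineage: float = DEFAULT_THETA_LINEAGE,
                   new_lineage_serial: int = 1) -> tuple[str, str, str]:
    """(locus, lineage, provisional name) by nearest known allele.

    Locus comes from the nearest known allele under p-distance; the
    lineage is inherited when that distance is at most ``theta_lineage``,
    otherwise a new provisional lineage label is minted.  A tie between
    loci at equal distance leaves the allele unassigned for review.
    """
    if not known_pool:
        raise ValueError("known pool must be non-empty")
    best: dict[str, float] = {}
    nearest: dict[str, AlleleSequence] = {}
    for al in known_pool:
        d = best_offset_p_distance(novel.sequence, al.sequence)
        if al.locus not in best or d < best[al.locus] or (
                d == best[al.locus] and al.name < nearest[al.locus].name):
            best[al.locus] = d
            nearest[al.locus] = al
    ranked = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return (LOCUS_UNASSIGNED, "", f"unassigned:{novel.name}")
    locus, d = ranked[0]
    near = nearest[locus]
    if d == 0.0:
        return (locus, near.lineage, near.name)
    if d <= theta_lineage:
        lineage = near.lineage
    else:
        lineage = f"{locus}*nl{new_lineage_serial:02d}"
    prefix = near.name.split("*")[0] if "*" in near.name else locus
    return (locus, lineage, f"{prefix}-{lineage}:{novel.name}"
            if "*" not in lineage else f"{lineage}:{novel.name}")


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryResult:
    platform: str
    assignments: dict[str, dict[str, list[str]]]   # sample -> read -> alleles
    clusters: list[ReadCluster]
    accepted: list[AlleleSequence]                 # novel + extension calls
    genotype_calls: list[GenotypeCall]
    conservation: dict[str, dict[str, int]]        # sample -> stage counts
    log: list[str] = field(default_factory=list)

    @property
    def accepted_sequences(self) -> frozenset[str]:
        return frozenset(al.sequence for al in self.accepted)


def discover(sample_reads: Mapping[str, ReadSet],
             known_db: Sequence[AlleleSequence] = (),
             platform: str = PLATFORM_FULL_LENGTH,
             min_reads: Optional[int] = None,
             tau: float = DEFAULT_TAU,
             theta_lineage: float = DEFAULT_THETA_LINEAGE,
             size_window: tuple[int, int] = DEFAULT_SIZE_WINDOW) -> DiscoveryResult:
    """Run the full per-platform discovery pipeline over a cohort.

    Residual reads are pooled across samples for clustering (each member
    keeps its sample of origin), the platform's acceptance rule is applied,
    and a genotype table with per-sample read counts is built from the
    assignments plus the accepted clusters.
    """
    if min_reads is None:
        min_reads = DEFAULT_MIN_READS[platform]
    log: list[str] = [f"platform={platform} min_reads={min_reads} tau={tau}"]
    assignments: dict[str, dict[str, list[str]]] = {}
    residuals: dict[Optional[str], ReadSet] = {}
    conservation: dict[str, dict[str, int]] = {}

    for sid in sorted(sample_reads):
        rs = sample_reads[sid]
        windowed = (extract_size_window(rs, *size_window)
                    if platform == PLATFORM_FULL_LENGTH else rs)
        asg, residual = map_known(windowed, known_db)
        assignments[sid] = asg
        residuals[sid] = residual
        conservation[sid] = {
            "input": len(rs),
            "discarded_size": len(rs) - len(windowed),
            "assigned": len(asg),
            "residual": len(residual),
        }
        log.append(f"{sid}: {len(rs)} reads, {len(rs) - len(windowed)} outside "
                   f"size window, {len(asg)} mapped to known, {len(residual)} residual")

    clusters = cluster_identical(residuals)
    if platform == PLATFORM_FULL_LENGTH:
        accepted = call_novel_fulllength(clusters, known_db, min_reads=min_reads)
    else:
        accepted = call_novel_exonic(clusters, min_reads=min_reads)
    log.append(f"{len(clusters)} clusters, {len(accepted)} accepted "
               f"(novel/extension) at min_reads={min_reads}")

    # name + classify accepted calls
    serial_new_lineage = 1
    for al in accepted:
        al.status = (STATUS_PSEUDOGENE
                     if classify_transcript(al.sequence) == STATUS_PSEUDOGENE
                     and al.status == STATUS_NOVEL else al.status)
        if known_db:
            locus, lineage, name = assign_lineage(
                al, known_db, theta_lineage, new_lineage_serial=serial_new_lineage)
            if lineage.endswith(f"nl{serial_new_lineage:02d}"):
                serial_new_lineage += 1
            al.locus, al.lineage = locus, lineage

    calls = build_genotype_table(sorted(sample_reads), assignments, clusters, accepted)
    locus_of = {al.name: al.locus for al in list(known_db) + accepted}
    pseudo = {al.name for al in list(known_db) + accepted
              if al.status == STATUS_PSEUDOGENE or
              classify_transcript(al.sequence) == STATUS_PSEUDOGENE}
    for call in calls:
        if call.counts:
            classify_expression(call, tau=tau, locus_of=locus_of)
        bona: dict[str, int] = {}
        for a, c in call.counts.items():
            if c > 0 and a not in pseudo:
                loc = locus_of.get(a, LOCUS_UNASSIGNED)
                bona[loc] = bona.get(loc, 0) + 1
        call.bona_fide_count = bona

    return DiscoveryResult(platform=platform, assignments=assignments,
                           clusters=clusters, accepted=accepted,
                           genotype_calls=calls, conservation=conservation, log=log)
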