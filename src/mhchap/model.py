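"""Domain types shared across the pipeline.

The central objects mirror how multigene-family MHC class I data are
organised in practice: oriented amplicon reads per sample, a pool of named
allele sequences, per-animal genotype calls with read support, and
haplotypes -- sets of alleles (or STR fragment lengths) that are
transmitted through a pedigree as a unit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

# -- status / enum-like string constants ------------------------------------

STATUS_KNOWN = "known"
STATUS_NOVEL = "novel"
STATUS_EXTENSION = "extension"
STATUS_PSEUDOGENE = "pseudogene"

LOCUS_A = "A"
LOCUS_B = "B"
LOCUS_UNASSIGNED = "unassigned"

PLATFORM_FULL_LENGTH = "full_length"    # full-length transcript amplicons (CCS-style rule set)
PLATFORM_LONG_EXON23 = "long_exon23"    # exon 2-3 amplicons (454-style rule set)
PLATFORMS = (PLATFORM_FULL_LENGTH, PLATFORM_LONG_EXON23)

MAJOR = "major"
MINOR = "minor"

MARKER_D6S2854 = "D6S2854"
MARKER_D6S2859 = "D6S2859"
STR_MARKERS = (MARKER_D6S2854, MARKER_D6S2859)


class MhchapError(Exception):
    """Base class for all pipeline errors."""


class ParseError(MhchapError):
    pass


class PedigreeError(MhchapError):
    pass


class MendelianError(MhchapError):
    """Raised when no consistent segregation of haplotypes exists."""


class SaturationError(MhchapError):
    """Distance correction undefined (observed divergence at/above 3/4)."""


# -- reads -------------------------------------------------------------------


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str


@dataclass
class ReadSet:
    """Amplicon reads for one sample; orientation of each read is unknown."""

    reads: list[Read] = field(default_factory=list)
    sample_id: Optional[str] = None

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __getitem__(self, i: int) -> Read:
        return self.reads[i]


# -- manifests / pedigree / STR ----------------------------------------------


@dataclass(frozen=True)
class SampleManifest:
    sample_id: str
    read_path: str
    platform: str = PLATFORM_FULL_LENGTH

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal with its dam and one-or-more candidate sires.

    ``dam_id`` is None when unknown; ``sire_ids`` is empty when unknown and
    holds two entries when paternity is ambiguous between two males.
    """

    animal_id: str
    dam_id: Optional[str] = None
    sire_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.animal_id in self.sire_ids or self.animal_id == self.dam_id:
            raise PedigreeError(f"animal {self.animal_id} listed as its own parent")


@dataclass(frozen=True)
class StrGenotype:
    """Observed fragment lengths for one animal at one microsatellite marker."""

    animal_id: str
    marker: str
    lengths: frozenset[int]

    def __post_init__(self) -> None:
        if self.marker not in STR_MARKERS:
            raise ValueError(f"unknown STR marker {self.marker!r}")
        if self.marker == MARKER_D6S2854 and not self.lengths:
            raise ValueError(f"{self.animal_id}: D6S2854 genotype must be non-empty")


# -- alleles and genotype calls ----------------------------------------------


@dataclass
class AlleleSequence:
    """A named nucleotide transcript with its lineage and discovery status."""

    name: str
    sequence: str
    status: str = STATUS_KNOWN
    locus: str = LOCUS_UNASSIGNED
    lineage: str = ""
    support_reads: Optional[int] = None

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"allele {self.name}: non-ACGT characters {sorted(bad)}")


@dataclass
class ReadCluster:
    """An equivalence class of identical reads (after orientation normalization)."""

    representative: str
    members: list[tuple[Optional[str], str]]     # (sample_id, read_id)
    orientations: frozenset[str]                 # subset of {"fwd", "rev"}

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GenotypeCall:
    """Per-sample allele read counts plus transcription-class labels.

    Counts may be fractional when a read matched several database alleles
    (1/k to each of k alleles); such alleles carry an ambiguity flag.
    """

    sample_id: str
    counts: dict[str, float] = field(default_factory=dict)
    ambiguous: set[str] = field(default_factory=set)
    expression: dict[str, str] = field(default_factory=dict)   # allele -> major/minor
    bona_fide_count: dict[str, int] = field(default_factory=dict)  # locus -> n

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset(a for a, c in self.counts.items() if c > 0)


# -- haplotypes ---------------------------------------------------------------


@dataclass
class StrHaplotype:
    """Joint D6S2854/D6S2859 length pattern transmitted as a unit."""

    hap_id: str
    d6s2854: frozenset[int]
    d6s2859: frozenset[int] = frozenset()
    optional_lengths: frozenset[tuple[str, int]] = frozenset()
    support: list[str] = field(default_factory=list)   # animal ids

    def items(self) -> frozenset[tuple[str, int]]:
        out = {(MARKER_D6S2854, x) for x in self.d6s2854}
        out |= {(MARKER_D6S2859, x) for x in self.d6s2859}
        return frozenset(out)


@dataclass
class AbHaplotype:
    """A set of A and B alleles (plus pseudogenes) transmitted as a unit."""

    hap_id: str
    a_alleles: frozenset[str] = frozenset()
    b_alleles: frozenset[str] = frozenset()
    pseudogenes: frozenset[str] = frozenset()
    str_hap: Optional[str] = None
    support: list[str] = field(default_factory=list)

    def items(self) -> frozenset[str]:
        return self.a_alleles | self.b_alleles | self.pseudogenes


# -- recombination / motifs ---------------------------------------------------

CLASS_AB_RECOMBINANT = "A_B_recombinant"
CLASS_WITHIN_B = "within_B_recombinant"
CLASS_SINGLE_SWITCH = "single_gene_switch"
CLASS_NONE = "none"


@dataclass
class PatchworkCall:
    hap_pair: tuple[str, str]
    shared_a: frozenset[str]
    unique_a: tuple[frozenset[str], frozenset[str]]
    shared_b: frozenset[str]
    unique_b: tuple[frozenset[str], frozenset[str]]
    patch_class: str = CLASS_NONE


BW4 = "Bw4"
BW6_IDENTICAL = "Bw6_identical"
BW6_CANONICAL = "Bw6_canonical"
MOTIF_OTHER = "other"


@dataclass(frozen=True)
class MotifCall:
    allele: str
    window_aa: str
    motif_class: str
    mature_offset_used: int
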