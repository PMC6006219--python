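"""Readers and writers for every external representation the pipeline touches.

One dialect everywhere: UTF-8, tab-separated tables with a header line and
``#`` comments; FASTA/FASTQ for sequence data (via Biopython); newick for
trees.  Allele names follow the IPD-style ``Prefix-Locus*Lineage:Allele``
pattern; colon-less aliases (``B*0212`` for ``B*02:12``) are accepted on
input and normalized on output.
"""
from __future__ import annotations

import csv
import io
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (MARKER_D6S2854, MARKER_D6S2859, PLATFORMS, STR_MARKERS,
                    AlleleSequence, GenotypeCall, ParseError, PedigreeError,
                    PedigreeRecord, Read, ReadSet, SampleManifest, StrGenotype)

PathLike = Union[str, Path]

_MISSING = {"", ".", "na", "NA", "none", "None", "unknown", "0"}


# ---------------------------------------------------------------------------
# allele-name normalization
# ---------------------------------------------------------------------------

_COLONLESS = re.compile(r"^(?P<prefix>(?:[A-Za-z]+-)?[AB])\*(?P<digits>\d{4,6})(?P<tag>ps)?$")


def normalize_allele_name(name: str) -> str:
    """Insert the lineage:allele colon into colon-less aliases.

    ``Paan-B*0212`` -> ``Paan-B*02:12``; names that already carry a colon
    (or do not look like an allele designation) pass through unchanged.
    """
    m = _COLONLESS.match(name)
    if not m:
        return name
    digits = m.group("digits")
    lineage, allele = digits[:2], digits[2:]
    return f"{m.group('prefix')}*{lineage}:{allele}{m.group('tag') or ''}"


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def read_reads(path: PathLike, fmt: Optional[str] = None,
               sample_id: Optional[str] = None) -> ReadSet:
    """Parse FASTA/FASTQ reads; format inferred from the extension if omitted.

    Identical sequences are retained as separate records (no collapsing
    here); a malformed record raises a :class:`ParseError` naming the index
    of the record at which parsing failed.
    """
    path = Path(path)
    if fmt is None:
        ext = path.suffix.lower()
        fmt = "fastq" if ext in {".fastq", ".fq"} else "fasta"
    fmt = fmt.lower()
    if fmt not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported read format {fmt!r}")
    reads: list[Read] = []
    with open(path) as fh:
        parser = SeqIO.parse(fh, fmt)
        idx = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ParseError(f"{path}: malformed {fmt} record #{idx + 1}: {exc}") from exc
            reads.append(Read(id=rec.id, sequence=str(rec.seq).upper()))
            idx += 1
    return ReadSet(reads=reads, sample_id=sample_id)


def write_fastq(readset: ReadSet, path: PathLike, quality: int = 40) -> None:
    recs = [SeqRecord(Seq(r.sequence), id=r.id, description="",
                      letter_annotations={"phred_quality": [quality] * len(r.sequence)})
            for r in readset]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fastq")


# ---------------------------------------------------------------------------
# allele FASTA
# ---------------------------------------------------------------------------

def write_allele_fasta(alleles: Sequence[AlleleSequence], path: PathLike) -> None:
    """FASTA with ``status=<s> locus=<l> lineage=<lin>`` in the description."""
    recs = []
    for al in alleles:
        desc = f"status={al.status} locus={al.locus}"
        if al.lineage:
            desc += f" lineage={al.lineage}"
        if al.support_reads is not None:
            desc += f" reads={al.support_reads}"
        recs.append(SeqRecord(Seq(al.sequence), id=normalize_allele_name(al.name),
                              description=desc))
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_allele_fasta(path: PathLike) -> list[AlleleSequence]:
    out: list[AlleleSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(kv.split("=", 1) for kv in rec.description.split()
                      if "=" in kv)
        support = fields.get("reads")
        out.append(AlleleSequence(
            name=normalize_allele_name(rec.id),
            sequence=str(rec.seq).upper(),
            status=fields.get("status", "known"),
            locus=fields.get("locus", "unassigned"),
            lineage=fields.get("lineage", ""),
            support_reads=int(support) if support is not None else None,
        ))
    return out


# ---------------------------------------------------------------------------
# tables: pedigree, STR genotypes, sample manifest
# ---------------------------------------------------------------------------

def _read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")


def read_pedigree(path: PathLike) -> list[PedigreeRecord]:
    """Headered TSV with columns ``animal  dam  sire1  [sire2]``.

    Strict PED does not accommodate two candidate sires, hence the headered
    dialect.  Duplicate animals and pedigree cycles are errors (the cycle is
    listed in the message).
    """
    df = _read_tsv(path)
    required = {"animal", "dam", "sire1"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: pedigree needs columns {sorted(required)}")
    records: list[PedigreeRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        aid = row["animal"].strip()
        if not aid:
            continue
        if aid in seen:
            raise PedigreeError(f"duplicate animal_id {aid!r}")
        seen.add(aid)
        dam = row["dam"].strip()
        sires = [row.get(c, "").strip() for c in ("sire1", "sire2")]
        sires = tuple(s for s in sires if s not in _MISSING)
        records.append(PedigreeRecord(
            animal_id=aid,
            dam_id=None if dam in _MISSING else dam,
            sire_ids=sires,
        ))
    _check_acyclic(records)
    return records


def _check_acyclic(records: Sequence[PedigreeRecord]) -> None:
    parents = {r.animal_id: [p for p in (r.dam_id, *r.sire_ids) if p] for r in records}
    state: dict[str, int] = {}   # 1 = on current path, 2 = done

    def visit(node: str, trail: list[str]) -> None:
        state[node] = 1
        trail.append(node)
        for p in sorted(parents.get(node, [])):
            if p not in parents:
                continue        # parent outside the table: treated as founder
            s = state.get(p)
            if s == 1:
                cyc = trail[trail.index(p):] + [p]
                raise PedigreeError(f"pedigree cycle detected: {' -> '.join(cyc)}")
            if s is None:
                visit(p, trail)
        trail.pop()
        state[node] = 2

    for a in sorted(parents):
        if a not in state:
            visit(a, [])


def write_pedigree(records: Sequence[PedigreeRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["animal", "dam", "sire1", "sire2"])
        for r in records:
            sires = list(r.sire_ids) + ["", ""]
            w.writerow([r.animal_id, r.dam_id or "", sires[0], sires[1]])


def read_str_genotypes(path: PathLike) -> list[StrGenotype]:
    """TSV with columns ``animal  marker  lengths`` (comma-separated bp)."""
    df = _read_tsv(path)
    required = {"animal", "marker", "lengths"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: STR table needs columns {sorted(required)}")
    out: list[StrGenotype] = []
    for i, row in df.iterrows():
        marker = row["marker"].strip()
        if marker not in STR_MARKERS:
            raise ParseError(f"{path} row {i + 1}: unknown marker {marker!r}")
        raw = row["lengths"].strip()
        lengths = frozenset(int(x) for x in raw.split(",") if x.strip()) if raw else frozenset()
        out.append(StrGenotype(animal_id=row["animal"].strip(), marker=marker,
                               lengths=lengths))
    return out


def write_str_genotypes(genotypes: Sequence[StrGenotype], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["animal", "marker", "lengths"])
        for g in genotypes:
            w.writerow([g.animal_id, g.marker,
                        ",".join(str(x) for x in sorted(g.lengths))])


def read_sample_manifest(path: PathLike) -> list[SampleManifest]:
    df = _read_tsv(path)
    required = {"sample_id", "read_path", "platform"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: manifest needs columns {sorted(required)}")
    out: list[SampleManifest] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["sample_id"].strip()
        if sid in seen:
            raise ParseError(f"duplicate sample_id {sid!r}")
        seen.add(sid)
        platform = row["platform"].strip()
        if platform not in PLATFORMS:
            raise ParseError(f"sample {sid}: unknown platform {platform!r}")
        out.append(SampleManifest(sample_id=sid, read_path=row["read_path"].strip(),
                                  platform=platform))
    return out


# ---------------------------------------------------------------------------
# genotype table (alleles x samples matrix of read counts)
# ---------------------------------------------------------------------------

def _fmt_count(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_genotype_table(calls: Sequence[GenotypeCall], path: PathLike) -> None:
    """TSV matrix: rows = alleles, columns = samples, cells = read counts.

    Absent allele/sample combinations are structural zeros rendered as 0.
    """
    if not calls:
        raise ValueError("no genotype calls to write")
    samples = [c.sample_id for c in calls]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids in genotype calls")
    alleles = sorted({a for c in calls for a in c.counts if c.counts[a] > 0})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["allele", *samples])
        for al in alleles:
            w.writerow([al, *(_fmt_count(c.counts.get(al, 0.0)) for c in calls)])


def read_genotype_table(path: PathLike) -> list[GenotypeCall]:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    calls = []
    for sample in df.columns:
        counts = {str(al): float(v) for al, v in df[sample].items() if float(v) > 0}
        calls.append(GenotypeCall(sample_id=str(sample), counts=counts))
    return calls


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def write_run_manifest(params: dict, path: PathLike) -> None:
    """YAML log of the parameters (and package version) behind one run."""
    from . import __version__
    doc = {"mhchap_version": __version__, "parameters": params}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_run_manifest(path: PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
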