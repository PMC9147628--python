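"""Sequence and manifest input/output.

Reads and writes the plain-text formats the pipeline touches: FASTQ
(Phred+33 only), FASTA (aligned and unaligned), the TSV sample manifest and
its YAML species-roles companion.  Parsing of FASTA/FASTQ is delegated to
Biopython; this module adds the validation the downstream stages rely on
(quality range, pair-id agreement, equal alignment lengths, manifest
consistency).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, FormatError, ManifestError, PairingError

VALID_BASES = frozenset("ACGTN-")

#: Highest Phred score representable in Phred+33 within printable ASCII.
MAX_PHRED = 93

#: Scores above this are taken as evidence of a Phred+64 file read as +33
#: (a +64 'h' decodes to 71); such inputs are rejected rather than guessed at.
_PHRED64_SUSPECT = 62

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with optional per-base Phred scores.

    ``quals`` may be any integer sequence (tuple or ``bytes``; the latter is
    the compact form bulk generators use)."""

    id: str
    seq: str
    quals: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if self.quals is not None:
            if len(self.quals) != len(self.seq):
                raise FormatError(
                    f"record {self.id!r}: {len(self.quals)} quality scores "
                    f"for {len(self.seq)} bases"
                )
            if self.quals and (min(self.quals) < 0 or max(self.quals) > MAX_PHRED):
                raise FormatError(
                    f"record {self.id!r}: Phred scores outside [0, {MAX_PHRED}]"
                )

    def __len__(self) -> int:
        return len(self.seq)


def _from_bio(rec: SeqRecord, with_quals: bool) -> SequenceRecord:
    quals = None
    if with_quals:
        scores = rec.letter_annotations.get("phred_quality")
        if scores is None:
            raise FormatError(f"record {rec.id!r} has no quality scores")
        if scores and max(scores) > _PHRED64_SUSPECT:
            raise FormatError(
                f"record {rec.id!r}: quality {max(scores)} suggests a Phred+64 "
                "file; only Phred+33 input is accepted"
            )
        quals = tuple(scores)
    return SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), quals=quals)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file; sequences are upper-cased, '.' gaps rejected."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sr = _from_bio(rec, with_quals=False)
        if "." in sr.seq:
            raise FormatError(
                f"record {sr.id!r} uses '.' as a gap; only '-' is accepted"
            )
        records.append(sr)
    return records


def read_aligned_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read an aligned FASTA; all sequences must have identical length."""
    records = read_fasta(path)
    lengths = {len(r) for r in records}
    if len(lengths) > 1:
        raise AlignmentError(
            f"{path}: ragged alignment, sequence lengths {sorted(lengths)}"
        )
    return records


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTQ file decoded as Phred+33."""
    try:
        return [_from_bio(rec, with_quals=True) for rec in SeqIO.parse(str(path), "fastq")]
    except ValueError as exc:  # Biopython signals malformed FASTQ this way
        raise FormatError(f"{path}: {exc}") from exc


_PAIR_SUFFIXES = ("/1", "/2", ".1", ".2", "_1", "_2")


def _pair_key(read_id: str) -> str:
    key = read_id.split()[0]
    for suffix in _PAIR_SUFFIXES:
        if key.endswith(suffix):
            return key[: -len(suffix)]
    return key


def read_fastq_pairs(
    path_r1: str | Path, path_r2: str | Path
) -> list[tuple[SequenceRecord, SequenceRecord]]:
    """Read two mate FASTQ files in matching order.

    Raises :class:`PairingError` if record counts differ or ids disagree
    after stripping read-direction suffixes.
    """
    r1 = read_fastq(path_r1)
    r2 = read_fastq(path_r2)
    if len(r1) != len(r2):
        raise PairingError(
            f"{path_r1} has {len(r1)} records but {path_r2} has {len(r2)}"
        )
    for a, b in zip(r1, r2):
        if _pair_key(a.id) != _pair_key(b.id):
            raise PairingError(f"read ids {a.id!r} and {b.id!r} do not pair")
    return list(zip(r1, r2))


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.quals is None:
                raise FormatError(f"record {rec.id!r} has no qualities to write")
            if isinstance(rec.quals, (bytes, bytearray)):
                qline = bytes(q + 33 for q in rec.quals).decode("ascii")
            else:
                qline = "".join(chr(q + 33) for q in rec.quals)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qline}\n")


# ---------------------------------------------------------------------------
# Sample manifest


@dataclass(frozen=True)
class SpeciesRole:
    """Role of one species in the classification scheme."""

    group: str  # 'complex_member' or 'outgroup'
    is_tricolor: bool = False
    is_arvensis: bool = False
    is_kit_or_hym: bool = False


@dataclass(frozen=True)
class Sample:
    sample_id: str
    species: str
    group: str
    n_individuals: int


_GROUPS = ("complex_member", "outgroup")


@dataclass
class SampleManifest:
    """The sample sheet: which amplicon library belongs to which species.

    Species role flags (focal complex membership, named roles used by the
    variant classifier) come from a separate species-roles mapping so that
    the class scheme is configuration, not code.
    """

    samples: list[Sample]
    roles: dict[str, SpeciesRole] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        species_group: dict[str, str] = {}
        for s in self.samples:
            if s.sample_id in seen:
                raise ManifestError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)
            if s.group not in _GROUPS:
                raise ManifestError(
                    f"sample {s.sample_id!r}: unknown group {s.group!r} "
                    f"(expected one of {_GROUPS})"
                )
            if s.n_individuals < 1:
                raise ManifestError(
                    f"sample {s.sample_id!r}: n_individuals must be >= 1"
                )
            prev = species_group.setdefault(s.species, s.group)
            if prev != s.group:
                raise ManifestError(
                    f"species {s.species!r} assigned to both groups "
                    f"{prev!r} and {s.group!r}"
                )
        for sp, grp in species_group.items():
            role = self.roles.get(sp)
            if role is None:
                self.roles[sp] = SpeciesRole(group=grp)
            elif role.group != grp:
                raise ManifestError(
                    f"species {sp!r}: manifest group {grp!r} disagrees with "
                    f"roles group {role.group!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def species_list(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.species not in out:
                out.append(s.species)
        return out

    def species_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.species
        raise KeyError(sample_id)

    def samples_of(self, species: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.species == species]

    def role(self, species: str) -> SpeciesRole:
        return self.roles[species]

    def is_outgroup(self, species: str) -> bool:
        return self.roles[species].group == "outgroup"


def roles_from_species_names(
    species_groups: Mapping[str, str]
) -> dict[str, SpeciesRole]:
    """Derive role flags by pattern-matching species names.

    Convenience for datasets whose names contain 'tricolor', 'arvensis',
    'kitaibeliana' or 'hymettia'; anything else gets bare group membership.
    """
    roles = {}
    for sp, grp in species_groups.items():
        low = sp.lower()
        roles[sp] = SpeciesRole(
            group=grp,
            is_tricolor="tricolor" in low,
            is_arvensis="arvensis" in low,
            is_kit_or_hym=("kitaibeliana" in low or "hymettia" in low),
        )
    return roles


def load_roles(path: str | Path) -> dict[str, SpeciesRole]:
    """Load the YAML species-roles mapping.

    Expected layout::

        species:
          V_tricolor: {group: complex_member, is_tricolor: true}
          V_eugeniae: {group: outgroup}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "species" not in doc:
        raise ManifestError(f"{path}: expected a top-level 'species' mapping")
    roles = {}
    for sp, spec in doc["species"].items():
        spec = spec or {}
        grp = spec.get("group")
        if grp not in _GROUPS:
            raise ManifestError(f"{path}: species {sp!r} has unknown group {grp!r}")
        roles[sp] = SpeciesRole(
            group=grp,
            is_tricolor=bool(spec.get("is_tricolor", False)),
            is_arvensis=bool(spec.get("is_arvensis", False)),
            is_kit_or_hym=bool(spec.get("is_kit_or_hym", False)),
        )
    return roles


def load_manifest(
    path: str | Path,
    roles: str | Path | Mapping[str, SpeciesRole] | None = None,
) -> SampleManifest:
    """Load the TSV sample manifest (columns: sample_id, species, group,
    n_individuals) and attach species roles.

    ``roles`` may be a YAML path, a ready mapping, or None (in which case
    role flags are inferred from species names).
    """
    samples = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "species", "group", "n_individuals"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ManifestError(
                f"{path}: manifest must have columns {sorted(required)}"
            )
        for row in reader:
            try:
                n_ind = int(row["n_individuals"])
            except ValueError as exc:
                raise ManifestError(
                    f"{path}: bad n_individuals {row['n_individuals']!r}"
                ) from exc
            samples.append(
                Sample(
                    sample_id=row["sample_id"].strip(),
                    species=row["species"].strip(),
                    group=row["group"].strip(),
                    n_individuals=n_ind,
                )
            )
    if roles is None:
        role_map = roles_from_species_names({s.species: s.group for s in samples})
    elif isinstance(roles, (str, Path)):
        role_map = load_roles(roles)
    else:
        role_map = dict(roles)
    return SampleManifest(samples=samples, roles=role_map)
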