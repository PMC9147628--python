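"""Simple indel coding and two-partition NEXUS export.

Each distinct internal gap run observed in the alignment becomes one binary
presence/absence character.  A sequence scores 1 when its own gap run
exactly matches the character's interval, 0 when it has no such run, and
missing ('?') when a strictly longer gap run of that sequence contains the
interval (the shorter event is then unobservable).  Leading and trailing
gap runs are amplicon length artefacts, not indel events, and are treated
as missing data throughout.

The NEXUS writer emits the nucleotide matrix and the coded indel matrix as
two character blocks plus a sets block, the layout expected by partitioned
Bayesian dating analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import AlignmentError, IgsflowError
from .seqio import SequenceRecord

MISSING = -1  # state code for '?'


def _gap_runs(seq: str) -> tuple[list[tuple[int, int]], tuple[int, int] | None, tuple[int, int] | None]:
    """All gap runs of a sequence as 0-based half-open intervals, split into
    (internal runs, leading run, trailing run)."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, c in enumerate(seq):
        if c == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    leading = runs[0] if runs and runs[0][0] == 0 else None
    trailing = (
        runs[-1] if runs and runs[-1][1] == len(seq) and runs[-1] != leading else None
    )
    if leading is not None and leading[1] == len(seq):
        # all-gap sequence: a single terminal run
        return [], leading, None
    internal = [r for r in runs if r != leading and r != trailing]
    return internal, leading, trailing


@dataclass
class IndelCharacterMatrix:
    """Binary indel characters: intervals (0-based half-open) x sequences."""

    characters: list[tuple[int, int]]
    states: np.ndarray  # (n_sequences, n_characters), values {0, 1, MISSING}
    sequence_ids: list[str]

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def state_symbol(self, i: int, k: int) -> str:
        s = int(self.states[i, k])
        return "?" if s == MISSING else str(s)


def simple_indel_coding(alignment: Sequence[SequenceRecord]) -> IndelCharacterMatrix:
    """Code every distinct internal gap run as a binary character."""
    lengths = {len(r) for r in alignment}
    if len(lengths) > 1:
        raise AlignmentError("indel coding requires an alignment")
    per_seq = [_gap_runs(r.seq) for r in alignment]
    characters = sorted({run for internal, _, _ in per_seq for run in internal})
    states = np.zeros((len(alignment), len(characters)), dtype=np.int8)
    for i, (internal, leading, trailing) in enumerate(per_seq):
        own = set(internal)
        longer = [r for r in internal]
        terminals = [r for r in (leading, trailing) if r is not None]
        for k, (cs, ce) in enumerate(characters):
            if (cs, ce) in own:
                states[i, k] = 1
            elif any(rs <= cs and ce <= re and (rs, re) != (cs, ce) for rs, re in longer):
                states[i, k] = MISSING
            elif any(rs <= cs and ce <= re for rs, re in terminals):
                states[i, k] = MISSING
            else:
                states[i, k] = 0
    return IndelCharacterMatrix(
        characters=characters,
        states=states,
        sequence_ids=[r.id for r in alignment],
    )


def _nexus_name(name: str) -> str:
    if any(c in name for c in " \t()[]{}/\\,;:=*'\"`<>^"):
        return "'" + name.replace("'", "''") + "'"
    return name


def export_nexus(
    alignment: Sequence[SequenceRecord],
    matrix: IndelCharacterMatrix,
    path: str | Path,
) -> None:
    """Write nucleotide + binary indel partitions as a NEXUS file.

    Characters blocks use 1-based inclusive coordinates; binary states are
    0/1 with '?' for missing.
    """
    ids = [r.id for r in alignment]
    if ids != matrix.sequence_ids:
        raise IgsflowError("indel matrix was not derived from this alignment")
    nchar_nt = len(alignment[0].seq) if alignment else 0
    nchar_indel = matrix.n_characters
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\n")
        fh.write("BEGIN TAXA;\n")
        fh.write(f"    DIMENSIONS NTAX={len(alignment)};\n")
        fh.write(
            "    TAXLABELS " + " ".join(_nexus_name(i) for i in ids) + ";\n"
        )
        fh.write("END;\n\n")
        fh.write("BEGIN CHARACTERS;\n")
        fh.write("    TITLE nucleotides;\n")
        fh.write(f"    DIMENSIONS NCHAR={nchar_nt};\n")
        fh.write("    FORMAT DATATYPE=DNA GAP=- MISSING=?;\n")
        fh.write("    MATRIX\n")
        for rec in alignment:
            fh.write(f"        {_nexus_name(rec.id)}  {rec.seq}\n")
        fh.write("    ;\nEND;\n\n")
        fh.write("BEGIN CHARACTERS;\n")
        fh.write("    TITLE indels;\n")
        fh.write(f"    DIMENSIONS NCHAR={nchar_indel};\n")
        fh.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
        if nchar_indel:
            labels = " ".join(
                f"{k + 1} indel_{s + 1}_{e}" for k, (s, e) in enumerate(matrix.characters)
            )
            fh.write(f"    CHARSTATELABELS {labels};\n")
        fh.write("    MATRIX\n")
        for i, rec in enumerate(alignment):
            row = "".join(matrix.state_symbol(i, k) for k in range(nchar_indel))
            fh.write(f"        {_nexus_name(rec.id)}  {row}\n")
        fh.write("    ;\nEND;\n\n")
        fh.write("BEGIN SETS;\n")
        fh.write(
            f"    CHARPARTITION combined = nucleotides : 1-{max(nchar_nt, 1)}, "
            f"indels : 1-{max(nchar_indel, 1)};\n"
        )
        fh.write("END;\n")
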