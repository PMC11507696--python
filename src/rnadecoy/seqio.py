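"""On-disk formats: FASTA, structures, probability matrices, alignments,
reports and configuration files.

All file formats use 1-based indices; everything in memory is 0-based.
Dot-bracket is the canonical structure output; CT is accepted on input.
Probability matrices use a plain-text "i j prob" triplet dialect so fixtures
stay human-readable.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .consensus import MultipleAlignment
from .core import PairProbabilityMatrix, SecondaryStructure, SequenceGroup, SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_pair_probabilities",
    "write_pair_probabilities",
    "read_structure",
    "write_structure",
    "read_alignment",
    "write_alignment",
    "write_report",
    "parse_config",
    "setup_logging",
]

logger = logging.getLogger("rnadecoy")

PathLike = Union[str, Path]


def setup_logging(verbose: bool = False) -> None:
    """Log to stderr; results go only to files/stdout."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.WARNING)


def read_fasta(path: PathLike) -> SequenceGroup:
    """Read a FASTA file into a normalized sequence group.

    T is mapped to U and case folded; duplicate ids, non-nucleotide
    characters and empty files are rejected with the offending record named.
    """
    records = []
    seen = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            records.append(SequenceRecord(id=rec.id, residues=str(rec.seq)))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r} in {path}: {exc}") from exc
    if not records:
        raise ValueError(f"no sequences in {path}")
    return SequenceGroup(members=records)


def write_fasta(group: SequenceGroup, path: PathLike) -> None:
    recs = [_BioSeqRecord(Seq(m.residues), id=m.id, description="") for m in group]
    _BioSeqIO.write(recs, str(path), "fasta")


def read_pair_probabilities(path: PathLike, length: int) -> PairProbabilityMatrix:
    """Read a text probability matrix: one "i j prob" line per pair, 1-based.

    Unlisted pairs are zero. Rejects probabilities outside [0, 1], indices
    out of range, and per-position pairing marginals exceeding 1.
    """
    P = np.zeros((length, length))
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 'i j prob'")
            i, j = int(parts[0]), int(parts[1])
            p = float(parts[2])
            if not (1 <= i <= length and 1 <= j <= length) or i == j:
                raise ValueError(f"{path}:{ln}: index out of range for length {length}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{path}:{ln}: probability {p} outside [0, 1]")
            P[i - 1, j - 1] = p
            P[j - 1, i - 1] = p
    return PairProbabilityMatrix(P)  # marginal conservation checked on construction


def write_pair_probabilities(probs: PairProbabilityMatrix, path: PathLike,
                             precision: int = 6) -> None:
    """Write nonzero pairs as 1-based "i j prob" lines."""
    with open(path, "w") as fh:
        for i in range(probs.length):
            for j in range(i + 1, probs.length):
                if probs.P[i, j] > 0:
                    fh.write(f"{i + 1} {j + 1} {probs.P[i, j]:.{precision}f}\n")


def read_structure(path: PathLike) -> SecondaryStructure:
    """Read a secondary structure from dot-bracket (with optional FASTA-like
    header and sequence line) or CT format, auto-detected."""
    text = Path(path).read_text().strip()
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        raise ValueError(f"empty structure file {path}")
    first = lines[0].split()
    if first and first[0].isdigit():
        return _parse_ct(lines, path)
    db = None
    for line in lines:
        s = line.strip()
        if s.startswith(">"):
            continue
        if set(s) <= set("().-"):
            db = s.replace("-", ".")
            break
    if db is None:
        raise ValueError(f"no dot-bracket line found in {path}")
    return SecondaryStructure.from_dot_bracket(db)


def _parse_ct(lines: list[str], path: PathLike) -> SecondaryStructure:
    n = int(lines[0].split()[0])
    pairs = set()
    for line in lines[1:n + 1]:
        parts = line.split()
        idx, partner = int(parts[0]), int(parts[4])
        if partner > 0 and idx < partner:
            pairs.add((idx - 1, partner - 1))
    return SecondaryStructure(pairs=frozenset(pairs), length=n)


def write_structure(structure: SecondaryStructure, path: PathLike,
                    sequence: Optional[str] = None, name: str = "structure") -> None:
    """Write dot-bracket (the canonical output format)."""
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        if sequence is not None:
            fh.write(sequence + "\n")
        fh.write(structure.to_dot_bracket() + "\n")


def read_alignment(path: PathLike) -> MultipleAlignment:
    """Read an aligned-FASTA multiple alignment ('-' for gaps)."""
    ids, rows = [], []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper().replace("T", "U").replace(".", "-"))
    if not rows:
        raise ValueError(f"no alignment rows in {path}")
    return MultipleAlignment(rows, ids)


def write_alignment(msa: MultipleAlignment, path: PathLike) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")


def write_report(results, path: PathLike, header_lines: Sequence[str] = ()) -> None:
    """Write the per-sequence classification report as a TSV table.

    ``results`` is the DataFrame produced by ``classifier.classify_group``:
    id, the six features, decoy probability and verdict, in input order.
    """
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        results.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def parse_config(path: PathLike) -> dict:
    """Parse a flat key=value configuration file.

    Also accepts, best-effort, the external consensus-folding dialect where a
    sequence list appears as ``InSeq = {a.fasta;b.fasta}``; unknown brace
    values other than InSeq are kept verbatim with a warning. '#' starts a
    comment. Values are left as strings except the InSeq list.
    """
    conf: dict = {}
    text = Path(path).read_text()
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected key = value")
        key, value = (s.strip() for s in line.split("=", 1))
        if value.startswith("{") and value.endswith("}"):
            items = [v.strip() for v in value[1:-1].split(";") if v.strip()]
            if key.lower() == "inseq":
                conf["input_sequences"] = items
            else:
                logger.warning("config key %r with brace list kept verbatim", key)
                conf[key] = items
        else:
            conf[key] = value
    return conf
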