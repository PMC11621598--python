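"""Labeled 41-nt sequence windows: validation, I/O, encoding, redundancy filtering.

Every sample is a fixed 41-bp window centered on the putative
modification site (0-based sequence index 20): a central adenine for
N6-methyladenine classes, a central cytosine for the cytosine
modifications.  Before entering the model a classification token is
prepended, giving token sequences of length 42 in which the site sits
at token index 21.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

WINDOW_LENGTH = 41
SITE_INDEX = 20  # 0-based position of the modified base within the window
TOKEN_LENGTH = 42  # [CLS] + 41 nucleotides
SITE_TOKEN_INDEX = SITE_INDEX + 1

LABELS: tuple[str, ...] = ("4mC", "5hmC", "5mC", "6mA", "6mA-neg")
LABEL_TO_ID = {label: i for i, label in enumerate(LABELS)}
ADENINE_LABELS = frozenset({"6mA", "6mA-neg"})
CYTOSINE_LABELS = frozenset({"4mC", "5hmC", "5mC"})

CLS_TOKEN = "[CLS]"
VOCABULARY: dict[str, int] = {CLS_TOKEN: 0, "A": 1, "C": 2, "G": 3, "T": 4}
_ID_TO_TOKEN = {i: t for t, i in VOCABULARY.items()}
_VALID_BASES = frozenset("ACGT")


class RecordError(ValueError):
    """A sequence record violating the window invariants."""


@dataclass(frozen=True)
class SequenceRecord:
    """One labeled 41-nt window with a central modification site."""

    id: str
    sequence: str
    label: str
    species: str | None = None

    def __post_init__(self) -> None:
        validate_record(self)


def validate_record(record: SequenceRecord) -> None:
    if record.label not in LABEL_TO_ID:
        raise RecordError(
            f"record {record.id!r}: unknown label {record.label!r}; "
            f"valid labels are {', '.join(LABELS)}"
        )
    if len(record.sequence) != WINDOW_LENGTH:
        raise RecordError(
            f"record {record.id!r}: sequence length {len(record.sequence)} "
            f"violates the {WINDOW_LENGTH}-nt window invariant"
        )
    bad = set(record.sequence) - _VALID_BASES
    if bad:
        raise RecordError(
            f"record {record.id!r}: invalid characters {sorted(bad)}; "
            "only A, C, G, T are accepted (no ambiguity codes)"
        )
    center = record.sequence[SITE_INDEX]
    if record.label in ADENINE_LABELS and center != "A":
        raise RecordError(
            f"record {record.id!r}: central base {center!r} must be 'A' "
            f"for label {record.label}"
        )
    if record.label in CYTOSINE_LABELS and center != "C":
        raise RecordError(
            f"record {record.id!r}: central base {center!r} must be 'C' "
            f"for label {record.label}"
        )


@dataclass(frozen=True)
class TokenSequence:
    """Integer-encoded [CLS]+window sequence of length 42."""

    token_ids: tuple[int, ...]
    label_id: int
    vocabulary: dict[str, int] = field(default_factory=lambda: dict(VOCABULARY))

    def __post_init__(self) -> None:
        if len(self.token_ids) != TOKEN_LENGTH:
            raise RecordError(
                f"token sequence length {len(self.token_ids)} != {TOKEN_LENGTH}"
            )
        if self.token_ids[0] != self.vocabulary[CLS_TOKEN]:
            raise RecordError("token sequence must start with the [CLS] id")


def tokenize(record: SequenceRecord) -> TokenSequence:
    """Prepend [CLS] and integer-encode a validated record."""
    ids = [VOCABULARY[CLS_TOKEN]]
    for base in record.sequence:
        try:
            ids.append(VOCABULARY[base])
        except KeyError:
            raise RecordError(
                f"record {record.id!r}: character {base!r} outside the "
                "A/C/G/T alphabet"
            ) from None
    return TokenSequence(token_ids=tuple(ids), label_id=LABEL_TO_ID[record.label])


def detokenize(tokens: TokenSequence) -> str:
    """Recover the 41-nt string from a token sequence (drops [CLS])."""
    return "".join(_ID_TO_TOKEN[i] for i in tokens.token_ids[1:])


def encode_dataset(records: Sequence[SequenceRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized encoding: (n, 42) int token matrix and (n,) label ids."""
    tokens = np.empty((len(records), TOKEN_LENGTH), dtype=np.int64)
    labels = np.empty(len(records), dtype=np.int64)
    for i, rec in enumerate(records):
        ts = tokenize(rec)
        tokens[i] = ts.token_ids
        labels[i] = ts.label_id
    return tokens, labels


# ---------------------------------------------------------------------------
# redundancy filtering
# ---------------------------------------------------------------------------

def redundancy_filter(
    records: Sequence[SequenceRecord], threshold: float = 0.80
) -> list[SequenceRecord]:
    """Greedy input-order redundancy removal on ungapped identity.

    A record is kept iff its per-position identity fraction to every
    previously kept record is strictly below ``threshold`` (identity ≥
    threshold ⇒ removed; the 80% default mirrors the usual CD-HIT-style
    cutoff).  Exact per-position matching is appropriate because all
    windows share the same length; no alignment is needed.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not records:
        return []
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise RecordError("all records must have equal length")
    length = lengths.pop()

    kept: list[SequenceRecord] = []
    kept_matrix = np.empty((len(records), length), dtype=np.uint8)
    n_kept = 0
    for rec in records:
        row = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
        if n_kept:
            identity = (kept_matrix[:n_kept] == row).mean(axis=1)
            if (identity >= threshold).any():
                continue
        kept_matrix[n_kept] = row
        n_kept += 1
        kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# file I/O — FASTA and TSV, plain or gzip
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_fasta_header(description: str) -> tuple[str, str, str | None]:
    parts = description.split()
    rec_id = parts[0]
    label = None
    species = None
    for token in parts[1:]:
        if token.startswith("label="):
            label = token[len("label="):]
        elif token.startswith("species="):
            species = token[len("species="):]
    if label is None:
        raise RecordError(
            f"record {rec_id!r}: FASTA header missing the required "
            "'label=<class>' field"
        )
    return rec_id, label, species


def read_records(path: str | Path, format: str = "fasta") -> list[SequenceRecord]:
    """Read labeled windows from FASTA (``label=`` header fields) or TSV."""
    if format == "fasta":
        with _open_text(path) as handle:
            out = []
            for bio_rec in SeqIO.parse(handle, "fasta"):
                rec_id, label, species = _parse_fasta_header(bio_rec.description)
                out.append(SequenceRecord(
                    id=rec_id,
                    sequence=str(bio_rec.seq).upper(),
                    label=label,
                    species=species,
                ))
            return out
    if format == "tsv":
        with _open_text(path) as handle:
            frame = pd.read_csv(handle, sep="\t", dtype=str)
        missing = {"id", "sequence", "label"} - set(frame.columns)
        if missing:
            raise RecordError(f"TSV missing required columns: {sorted(missing)}")
        out = []
        for row in frame.itertuples(index=False):
            species = getattr(row, "species", None)
            if isinstance(species, float) and np.isnan(species):
                species = None
            out.append(SequenceRecord(
                id=str(row.id),
                sequence=str(row.sequence).upper(),
                label=str(row.label),
                species=species,
            ))
        return out
    raise ValueError(f"unknown format {format!r}; expected 'fasta' or 'tsv'")


def write_records(
    records: Iterable[SequenceRecord], path: str | Path, format: str = "fasta"
) -> None:
    """Write records to FASTA or TSV (gzip if the path ends in .gz)."""
    records = list(records)
    if format == "fasta":
        bio_records = []
        for rec in records:
            desc = f"label={rec.label}"
            if rec.species:
                desc += f" species={rec.species}"
            bio_records.append(
                BioSeqRecord(Seq(rec.sequence), id=rec.id, description=desc)
            )
        with _open_text(path, "wt") as handle:
            SeqIO.write(bio_records, handle, "fasta")
        return
    if format == "tsv":
        frame = pd.DataFrame(
            {
                "id": [r.id for r in records],
                "sequence": [r.sequence for r in records],
                "label": [r.label for r in records],
                "species": [r.species if r.species else "" for r in records],
            }
        )
        with _open_text(path, "wt") as handle:
            frame.to_csv(handle, sep="\t", index=False)
        return
    raise ValueError(f"unknown format {format!r}; expected 'fasta' or 'tsv'")
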