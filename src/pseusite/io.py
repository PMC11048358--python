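"""Reading, validating and writing fixed-length labeled RNA windows.

A training example is a ``λ``-nucleotide RNA window centred on a candidate
uridine; the binary label says whether that centre U carries a pseudouridine
(Ψ) modification.  Labels travel in the FASTA header as a trailing ``|1`` /
``|0`` token by default, or in a separate two-column TSV (``id<TAB>label``).
DNA-style ``T`` characters are silently normalised to ``U`` and lowercase is
uppercased, because public Ψ-site datasets mix DNA and RNA alphabets.

Positions are reported 1-based; offsets relative to the centre use the
``+1`` / ``-5`` convention common in site-preference analyses.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO

RNA_ALPHABET = "ACGU"
_VALID_CHARS = frozenset(RNA_ALPHABET)

LABEL_RULES = ("header-token", "paired-files", "unlabeled")


class FastaParseError(ValueError):
    """The input file is not parseable FASTA (or lacks a required label token)."""


class ValidationError(ValueError):
    """A record or dataset violates the fixed-window invariants."""


def normalize_sequence(raw: str) -> str:
    """Uppercase and map T -> U.  Does not validate the alphabet."""
    return raw.strip().upper().replace("T", "U")


@dataclass(frozen=True)
class RnaSequenceRecord:
    """One fixed-length RNA window with an optional binary label."""

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise ValidationError(
                f"record {self.id!r}: invalid characters {sorted(bad)} "
                f"(alphabet is A/C/G/U after T->U normalization)"
            )
        if self.label not in (None, 0, 1):
            raise ValidationError(f"record {self.id!r}: label must be 0, 1 or None")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceDataset:
    """An ordered collection of equal-length windows, all labeled or all not.

    Parameters
    ----------
    records:
        The windows, in input order.
    center_check:
        When True (training data), every window must have odd length and a
        ``U`` at the centre position ``(λ+1)/2`` (1-based).  When False
        (prediction input), a non-U centre only raises a warning.
    """

    records: list[RnaSequenceRecord] = field(default_factory=list)
    center_check: bool = True

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if not self.records:
            return
        lam = len(self.records[0])
        odd = [r.id for r in self.records if len(r) != lam]
        if odd:
            raise ValidationError(
                f"inconsistent window lengths: expected {lam} nt, offending ids {odd}"
            )
        labeled = [r.label is not None for r in self.records]
        if any(labeled) and not all(labeled):
            missing = [r.id for r, has in zip(self.records, labeled) if not has]
            raise ValidationError(f"labels must be all present or all absent; missing for {missing}")
        self._check_center(lam)

    def _check_center(self, lam: int) -> None:
        if lam % 2 == 0:
            if self.center_check:
                raise ValidationError(f"window length must be odd to have a centre U, got {lam}")
            return
        centre = (lam - 1) // 2  # 0-based
        off = [r.id for r in self.records if r.sequence[centre] != "U"]
        if off:
            msg = f"centre nucleotide (position {(lam + 1) // 2}, 1-based) is not U for {off}"
            if self.center_check:
                raise ValidationError(msg)
            warnings.warn(msg, stacklevel=3)

    # -- accessors ----------------------------------------------------------

    @property
    def window_length(self) -> int:
        if not self.records:
            raise ValidationError("empty dataset has no window length")
        return len(self.records[0])

    @property
    def labeled(self) -> bool:
        return bool(self.records) and self.records[0].label is not None

    @property
    def y(self) -> np.ndarray:
        if not self.labeled:
            raise ValidationError("dataset is unlabeled")
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[RnaSequenceRecord]:
        return iter(self.records)

    def subset(self, indices: Sequence[int]) -> "SequenceDataset":
        return SequenceDataset(
            [self.records[i] for i in indices], center_check=self.center_check
        )


def _read_label_table(path: str | Path) -> dict[str, int]:
    table: dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2 or row[1] not in ("0", "1"):
                raise FastaParseError(f"label table {path}: bad row {row!r} (want id<TAB>0|1)")
            table[row[0]] = int(row[1])
    return table


def read_fasta(
    path: str | Path,
    label_rule: str = "header-token",
    label_file: str | Path | None = None,
    center_check: bool = True,
) -> SequenceDataset:
    """Read a FASTA file of fixed-length RNA windows into a validated dataset.

    ``label_rule`` is one of ``header-token`` (a trailing ``|0`` / ``|1`` on
    each header id), ``paired-files`` (ids looked up in ``label_file``), or
    ``unlabeled``.
    """
    if label_rule not in LABEL_RULES:
        raise ValueError(f"label_rule must be one of {LABEL_RULES}, got {label_rule!r}")
    path = Path(path)
    text_head = path.read_text()[:4096].lstrip()
    if text_head and not text_head.startswith(">"):
        raise FastaParseError(f"{path}: not FASTA (does not start with '>')")

    table = _read_label_table(label_file) if label_rule == "paired-files" else None
    if label_rule == "paired-files" and label_file is None:
        raise ValueError("label_rule 'paired-files' requires label_file")

    records: list[RnaSequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, label = rec.id, None
        if label_rule == "header-token":
            base, sep, token = rid.rpartition("|")
            if not sep or token not in ("0", "1"):
                raise FastaParseError(
                    f"record {rid!r}: header lacks a trailing '|0' or '|1' label token"
                )
            rid, label = base, int(token)
        elif label_rule == "paired-files":
            if rid not in table:  # type: ignore[operator]
                raise ValidationError(f"record {rid!r}: no entry in label table")
            label = table[rid]  # type: ignore[index]
        seq = normalize_sequence(str(rec.seq))
        records.append(RnaSequenceRecord(id=rid, sequence=seq, label=label))
    return SequenceDataset(records, center_check=center_check)


def write_fasta(dataset: SequenceDataset, path: str | Path) -> None:
    """Write a dataset as FASTA; labels are appended to headers as ``|0``/``|1``.

    ``read_fasta(write_fasta(d))`` reproduces ids, sequences and labels.
    """
    with open(path, "w") as fh:
        for rec in dataset:
            header = rec.id if rec.label is None else f"{rec.id}|{rec.label}"
            fh.write(f">{header}\n{rec.sequence}\n")


def drop_exact_duplicates(dataset: SequenceDataset) -> SequenceDataset:
    """Optional filter removing records whose sequence was already seen.

    Off by default everywhere: the benchmark protocol does not specify a
    deduplication policy, so the first occurrence wins only when explicitly
    requested.
    """
    seen: set[str] = set()
    kept = []
    for rec in dataset:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            kept.append(rec)
    return SequenceDataset(kept, center_check=dataset.center_check)
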