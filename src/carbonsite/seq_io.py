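"""Reading and writing the formats the pipeline touches.

Coordinates are 1-based inclusive in every user-facing file (FASTA
positions, annotation tables, prediction tables); any 0-based arithmetic is
confined to this module and to in-memory indexing.  Sequences are
restricted to the 20 amino acids plus the padding symbol X; ambiguity codes
(B, Z, U, ...) are rejected with an explicit message rather than silently
remapped.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from carbonsite.alphabet import ALPHABET, CENTER_TYPES
from carbonsite.errors import DataValidationError

_ALPHABET_SET = frozenset(ALPHABET)

POSITIVE_LABEL = "positive"
NEGATIVE_LABEL = "negative"

ANNOTATION_COLUMNS = ["protein_id", "position", "residue", "label"]
PREDICTION_COLUMNS = ["protein_id", "position", "residue", "score", "call"]


@dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    ``sequence`` is uppercase over the 21-symbol alphabet (20 amino acids
    plus X).
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise DataValidationError("protein record with empty id")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise DataValidationError(f"protein {self.id!r} has an empty sequence")
        for offset, ch in enumerate(seq, start=1):
            if ch not in _ALPHABET_SET:
                raise DataValidationError(
                    f"protein {self.id!r}: illegal character {ch!r} at offset "
                    f"{offset} (allowed: 20 amino acids and X)"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= self.length:
            raise DataValidationError(
                f"position {position} outside protein {self.id!r} "
                f"(length {self.length})"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class SiteAnnotation:
    """An experimentally determined label for one candidate residue."""

    protein_id: str
    position: int  # 1-based
    residue: str  # one of K, P, R, T
    label: str = NEGATIVE_LABEL

    def __post_init__(self) -> None:
        if self.residue not in CENTER_TYPES:
            raise DataValidationError(
                f"annotation {self.protein_id}:{self.position}: residue "
                f"{self.residue!r} is not one of {', '.join(CENTER_TYPES)}"
            )
        if self.label not in (POSITIVE_LABEL, NEGATIVE_LABEL):
            raise DataValidationError(
                f"annotation {self.protein_id}:{self.position}: label must be "
                f"'{POSITIVE_LABEL}' or '{NEGATIVE_LABEL}', got {self.label!r}"
            )
        if self.position < 1:
            raise DataValidationError(
                f"annotation {self.protein_id}: position must be >= 1, "
                f"got {self.position}"
            )


@dataclass(frozen=True)
class PredictionRecord:
    """One scored candidate site.

    ``call`` is "carbonylation site" exactly when ``score`` reached the
    decision threshold of the predictor that produced it.
    """

    protein_id: str
    position: int
    residue: str
    score: float
    call: str

    POSITIVE_CALL = "carbonylation site"
    NEGATIVE_CALL = "non-carbonylation site"

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise DataValidationError(
                f"prediction {self.protein_id}:{self.position}: score "
                f"{self.score} outside [0, 1]"
            )
        if self.call not in (self.POSITIVE_CALL, self.NEGATIVE_CALL):
            raise DataValidationError(f"unknown call {self.call!r}")


def read_fasta(path: str | Path | io.TextIOBase) -> list[ProteinRecord]:
    """Parse a FASTA file into validated protein records.

    Order is preserved; ids (first header token) must be unique; characters
    outside the 21-symbol alphabet abort the parse with the protein id and
    the 1-based offset of the offending character.
    """
    handle = path if isinstance(path, io.TextIOBase) else open(path)
    try:
        records: list[ProteinRecord] = []
        seen: set[str] = set()
        for entry in SeqIO.parse(handle, "fasta"):
            if entry.id in seen:
                raise DataValidationError(f"duplicate FASTA id {entry.id!r}")
            seen.add(entry.id)
            records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq)))
        return records
    finally:
        if handle is not path:
            handle.close()


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as wrapped FASTA; inverse of :func:`read_fasta`."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for start in range(0, rec.length, width):
                fh.write(rec.sequence[start:start + width] + "\n")


def read_annotations(
    path: str | Path | io.TextIOBase,
    proteins: Sequence[ProteinRecord] | None = None,
) -> list[SiteAnnotation]:
    """Read the tab-separated site-annotation table.

    Requires a header row with columns protein_id, position, residue,
    label.  When ``proteins`` is given, each annotation is cross-checked:
    the position must lie inside the named protein and the residue there
    must equal the stated residue.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residue": str,
                                            "label": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(
            f"annotation file missing column(s): {', '.join(missing)}"
        )
    annotations = [
        SiteAnnotation(
            protein_id=row.protein_id,
            position=int(row.position),
            residue=row.residue,
            label=row.label,
        )
        for row in df.itertuples(index=False)
    ]
    if proteins is not None:
        validate_annotations(annotations, proteins)
    return annotations


def validate_annotations(
    annotations: Iterable[SiteAnnotation],
    proteins: Sequence[ProteinRecord],
) -> None:
    """Check every annotation against its protein sequence."""
    by_id = {p.id: p for p in proteins}
    for ann in annotations:
        protein = by_id.get(ann.protein_id)
        if protein is None:
            raise DataValidationError(
                f"annotation references unknown protein {ann.protein_id!r}"
            )
        found = protein.residue_at(ann.position)
        if found != ann.residue:
            raise DataValidationError(
                f"annotation {ann.protein_id}:{ann.position}: expected "
                f"residue {ann.residue!r} but sequence has {found!r}"
            )


def write_annotations(annotations: Iterable[SiteAnnotation],
                      path: str | Path) -> None:
    df = pd.DataFrame(
        [(a.protein_id, a.position, a.residue, a.label) for a in annotations],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_predictions(records: Sequence[PredictionRecord],
                      path: str | Path) -> None:
    """Write predictions as TSV, grouped by protein then ascending position.

    After the data rows, one comment line per protein summarizes how many
    candidate residues were scanned and how many were called sites, e.g.
    ``# p1: 9 K residues, 5 predicted sites``.
    """
    ordered = sorted(records, key=lambda r: (r.protein_id, r.position))
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for rec in ordered:
            fh.write(
                f"{rec.protein_id}\t{rec.position}\t{rec.residue}\t"
                f"{rec.score:.4f}\t{rec.call}\n"
            )
        for protein_id, residue, n_total, n_pos in summarize_predictions(ordered):
            fh.write(
                f"# {protein_id}: {n_total} {residue} residues, "
                f"{n_pos} predicted sites\n"
            )


def summarize_predictions(
    records: Sequence[PredictionRecord],
) -> list[tuple[str, str, int, int]]:
    """Per (protein, residue type): total candidates and positive calls."""
    counts: dict[tuple[str, str], list[int]] = {}
    for rec in records:
        key = (rec.protein_id, rec.residue)
        total_pos = counts.setdefault(key, [0, 0])
        total_pos[0] += 1
        if rec.call == PredictionRecord.POSITIVE_CALL:
            total_pos[1] += 1
    return [
        (pid, res, total, pos)
        for (pid, res), (total, pos) in sorted(counts.items())
    ]


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"protein_id": str, "residue": str, "call": str})
    return [
        PredictionRecord(
            protein_id=row.protein_id,
            position=int(row.position),
            residue=row.residue,
            score=float(row.score),
            call=row.call,
        )
        for row in df.itertuples(index=False)
    ]
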