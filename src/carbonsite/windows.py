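"""Peptide-window benchmark construction.

A candidate site is described by the (2ξ+1)-mer centered on it: ξ residues
upstream, the candidate residue ⊛ (K, P, R or T), and ξ residues
downstream.  Windows that run past a sequence terminus are padded with the
dummy residue X on the deficient side.  Windows whose center is an
experimentally annotated site form the positive subset; all other windows
of the same center type form the negative subset.  Each subset is then
screened with a greedy sequence-identity filter so that no kept window has
identity at or above the threshold with any other kept window of the same
subset.

The published procedure ran CD-HIT for this screen; because the samples
here are fixed-length ungapped peptides, identity reduces to a column
count and the screen is reimplemented directly as a deterministic
keep-first scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from carbonsite.alphabet import ALPHABET, CENTER_TYPES
from carbonsite.errors import DataValidationError
from carbonsite.seq_io import (
    POSITIVE_LABEL,
    NEGATIVE_LABEL,
    ProteinRecord,
    SiteAnnotation,
)

UNLABELED = "unlabeled"

_ALPHABET_SET = frozenset(ALPHABET)


@dataclass(frozen=True)
class WindowConfig:
    """Parameters of benchmark construction.

    ``xi`` is the flank length: a window spans ``2*xi + 1`` residues.  The
    default 7 (15-mer windows) gave the best preliminary performance in the
    original study and is the only length its benchmark used.
    ``identity_threshold`` is the fraction of identical columns at or above
    which a window is discarded as redundant.
    """

    xi: int = 7
    center_type: str = "K"
    identity_threshold: float = 0.30
    filter_enabled: bool = True

    def __post_init__(self) -> None:
        if self.xi < 1:
            raise ValueError(f"xi must be >= 1, got {self.xi}")
        if self.center_type not in CENTER_TYPES:
            raise ValueError(
                f"center_type must be one of {', '.join(CENTER_TYPES)}, "
                f"got {self.center_type!r}"
            )
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError(
                f"identity_threshold must be in (0, 1], "
                f"got {self.identity_threshold}"
            )

    @property
    def window_length(self) -> int:
        return 2 * self.xi + 1


@dataclass(frozen=True)
class PeptideWindow:
    """A (2ξ+1)-mer peptide sample centered on a candidate residue.

    ``center_position`` is 1-based in the source protein.  ``synthetic``
    marks Monte-Carlo-generated windows, which are always positive and must
    never appear in a test fold.
    """

    residues: str
    center_type: str
    protein_id: str
    center_position: int
    label: str = UNLABELED
    synthetic: bool = False

    def __post_init__(self) -> None:
        n = len(self.residues)
        if n < 3 or n % 2 == 0:
            raise ValueError(
                f"window length must be an odd number >= 3, got {n}"
            )
        if not _ALPHABET_SET.issuperset(self.residues):
            bad = sorted(set(self.residues) - _ALPHABET_SET)
            raise DataValidationError(
                f"window contains illegal residue(s) {bad} "
                f"({self.protein_id}:{self.center_position})"
            )
        if self.residues[n // 2] != self.center_type:
            raise ValueError(
                f"window center {self.residues[n // 2]!r} does not match "
                f"declared center type {self.center_type!r}"
            )
        if self.label not in (POSITIVE_LABEL, NEGATIVE_LABEL, UNLABELED):
            raise ValueError(f"unknown label {self.label!r}")
        if self.synthetic and self.label != POSITIVE_LABEL:
            raise ValueError("synthetic windows must be labeled positive")

    @property
    def xi(self) -> int:
        return len(self.residues) // 2

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_id, self.center_position)


@dataclass
class SampleSet:
    """The benchmark S(⊛) = S+(⊛) ∪ S−(⊛) for one center type."""

    center_type: str
    xi: int
    positives: list[PeptideWindow] = field(default_factory=list)
    negatives: list[PeptideWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        for w in self.positives:
            self._check_member(w, POSITIVE_LABEL)
        for w in self.negatives:
            self._check_member(w, NEGATIVE_LABEL)
        pos_keys = {w.key for w in self.positives if not w.synthetic}
        neg_keys = {w.key for w in self.negatives}
        overlap = pos_keys & neg_keys
        if overlap:
            raise ValueError(
                f"sites present in both subsets: {sorted(overlap)[:5]}"
            )

    def _check_member(self, w: PeptideWindow, expected_label: str) -> None:
        if w.center_type != self.center_type or w.xi != self.xi:
            raise ValueError(
                f"window {w.key} has center_type/xi "
                f"({w.center_type}, {w.xi}) inconsistent with sample set "
                f"({self.center_type}, {self.xi})"
            )
        if w.label != expected_label:
            raise ValueError(
                f"window {w.key} labeled {w.label!r} placed in the "
                f"{expected_label} subset"
            )

    @property
    def n_positive(self) -> int:
        return len(self.positives)

    @property
    def n_negative(self) -> int:
        return len(self.negatives)

    def has_synthetic(self) -> bool:
        return any(w.synthetic for w in self.positives)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (w.residues, w.label, w.protein_id, w.center_position, w.synthetic)
            for w in self.positives + self.negatives
        ]
        return pd.DataFrame(
            rows,
            columns=["peptide", "label", "protein_id", "center_position",
                     "synthetic"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, center_type: str | None = None
                 ) -> "SampleSet":
        df = pd.read_csv(path, sep="\t",
                         dtype={"peptide": str, "label": str,
                                "protein_id": str})
        if df.empty:
            raise DataValidationError(f"sample-set file {path} is empty")
        if "synthetic" not in df.columns:
            df["synthetic"] = False
        peptides = df["peptide"].tolist()
        xi = len(peptides[0]) // 2
        inferred = peptides[0][xi]
        center = center_type or inferred
        positives, negatives = [], []
        for row in df.itertuples(index=False):
            w = PeptideWindow(
                residues=row.peptide,
                center_type=center,
                protein_id=row.protein_id,
                center_position=int(row.center_position),
                label=row.label,
                synthetic=bool(row.synthetic),
            )
            (positives if w.label == POSITIVE_LABEL else negatives).append(w)
        return cls(center_type=center, xi=xi, positives=positives,
                   negatives=negatives)


def extract_windows(protein: ProteinRecord,
                    config: WindowConfig) -> list[PeptideWindow]:
    """Slide a (2ξ+1)-tuple window along the protein and collect every
    window centered on the configured residue type.

    A center at 1-based position ``pos`` lacks ``xi - (pos - 1)`` residues
    upstream when ``pos <= xi`` and ``xi - (L - pos)`` downstream when
    ``pos > L - xi``; missing residues are filled with X.
    """
    xi = config.xi
    padded = "X" * xi + protein.sequence + "X" * xi
    windows: list[PeptideWindow] = []
    for idx, residue in enumerate(protein.sequence):  # idx is 0-based
        if residue != config.center_type:
            continue
        # center at padded index idx + xi; take xi on each side
        segment = padded[idx:idx + 2 * xi + 1]
        windows.append(
            PeptideWindow(
                residues=segment,
                center_type=config.center_type,
                protein_id=protein.id,
                center_position=idx + 1,
            )
        )
    return windows


def label_windows(windows: Sequence[PeptideWindow],
                  annotations: Iterable[SiteAnnotation]
                  ) -> list[PeptideWindow]:
    """Assign positive/negative labels from experimental annotations.

    Windows whose (protein_id, center_position) matches a positive
    annotation become positive; every other window becomes negative.  A
    positive annotation with no matching window signals a flank-length or
    residue-type mismatch and is an error.
    """
    positive_keys = {
        (a.protein_id, a.position)
        for a in annotations
        if a.label == POSITIVE_LABEL
    }
    window_keys = {w.key for w in windows}
    orphans = positive_keys - window_keys
    if orphans:
        raise DataValidationError(
            "positive annotation(s) with no matching extracted window: "
            f"{sorted(orphans)[:5]} — check center residue type and xi"
        )
    return [
        replace(
            w,
            label=POSITIVE_LABEL if w.key in positive_keys else NEGATIVE_LABEL,
        )
        for w in windows
    ]


def pairwise_identity(a: PeptideWindow, b: PeptideWindow) -> float:
    """Ungapped identity: fraction of columns with identical symbols.

    X matches only X — two windows padded over the same terminus genuinely
    share that context.
    """
    if len(a.residues) != len(b.residues):
        raise ValueError(
            f"cannot compare windows of lengths {len(a.residues)} "
            f"and {len(b.residues)}"
        )
    matches = sum(x == y for x, y in zip(a.residues, b.residues))
    return matches / len(a.residues)


def redundancy_filter(samples: Sequence[PeptideWindow],
                      threshold: float) -> list[PeptideWindow]:
    """Greedy keep-first redundancy screen within one subset.

    Samples are scanned in input order; a sample is dropped when its
    identity with any already-kept sample reaches the threshold.  The
    result is deterministic for a fixed input order and is a fixed point:
    re-filtering the output changes nothing.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    kept: list[PeptideWindow] = []
    for sample in samples:
        if all(pairwise_identity(sample, k) < threshold for k in kept):
            kept.append(sample)
    return kept


def build_benchmark(proteins: Sequence[ProteinRecord],
                    annotations: Sequence[SiteAnnotation],
                    config: WindowConfig) -> SampleSet:
    """Extract, label and screen windows into a benchmark sample set.

    The redundancy filter runs on positives and negatives independently —
    a positive is never discarded for resembling a negative.
    """
    windows: list[PeptideWindow] = []
    for protein in proteins:
        windows.extend(extract_windows(protein, config))
    labeled = label_windows(windows, annotations)
    positives = [w for w in labeled if w.label == POSITIVE_LABEL]
    negatives = [w for w in labeled if w.label == NEGATIVE_LABEL]
    if config.filter_enabled:
        positives = redundancy_filter(positives, config.identity_threshold)
        negatives = redundancy_filter(negatives, config.identity_threshold)
    if not positives:
        raise DataValidationError(
            "no positive samples remain after benchmark construction; "
            "a model cannot be fit"
        )
    return SampleSet(center_type=config.center_type, xi=config.xi,
                     positives=positives, negatives=negatives)
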