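"""Labeled FASTA I/O, pairwise alignment, and ITS1/5.8S/ITS2 annotation.

The barcoding pipeline works on a pre-built multiple alignment of ITS
sequences (ITS1 + 5.8S + ITS2) whose headers carry a species label.  The
conserved 5.8S gene is excluded from diagnostics, so each sequence needs
an ITS annotation; annotations are transferred from a single annotated
reference by global pairwise alignment, and the per-member 5.8S
intervals are projected onto alignment columns to build a column mask.

Coordinates are 0-based half-open internally; reports are 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AnnotationError, SequenceFormatError

__all__ = [
    "ALPHABET",
    "GAP",
    "LabeledSequence",
    "LabeledAlignment",
    "ItsAnnotation",
    "PairwiseAlignment",
    "Scoring",
    "read_labeled_fasta",
    "write_labeled_fasta",
    "global_align",
    "transfer_annotation",
    "mask_58s",
    "load_annotations",
    "save_annotations",
]

GAP = "-"
IUPAC_AMBIGUOUS = set("RYSWKMBDHV")
ALPHABET = set("ACGTN") | IUPAC_AMBIGUOUS | {GAP}


@dataclass(frozen=True)
class LabeledSequence:
    """A (possibly gapped) nucleotide sequence with species metadata."""

    accession: str
    species: str
    residues: str
    geography: str | None = None

    def __post_init__(self):
        if not self.residues:
            raise SequenceFormatError(f"{self.accession}: empty sequence")
        up = self.residues.upper()
        bad = set(up) - ALPHABET
        if bad:
            raise SequenceFormatError(
                f"{self.accession}: illegal residue(s) {sorted(bad)}"
            )
        object.__setattr__(self, "residues", up)

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledAlignment:
    """Equal-length labeled sequences plus a boolean column mask.

    ``column_mask[j]`` is True when column ``j`` participates in
    diagnostics and distance computation (False marks e.g. 5.8S columns).
    """

    members: list[LabeledSequence]
    column_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        lengths = {len(m) for m in self.members}
        if len(lengths) > 1:
            raise SequenceFormatError(f"ragged member lengths: {sorted(lengths)}")
        n = lengths.pop() if lengths else 0
        if self.column_mask is None:
            self.column_mask = np.ones(n, dtype=bool)
        else:
            self.column_mask = np.asarray(self.column_mask, dtype=bool)
            if self.column_mask.size != n:
                raise SequenceFormatError("mask length != column count")

    @property
    def column_count(self) -> int:
        return len(self.members[0]) if self.members else 0

    @property
    def species(self) -> list[str]:
        """Distinct species in first-appearance order."""
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(m.species, None)
        return list(seen)

    def species_map(self) -> dict[str, str]:
        return {m.accession: m.species for m in self.members}

    def masked_columns(self) -> np.ndarray:
        """Indices of mask-true columns, in ascending order."""
        return np.flatnonzero(self.column_mask)

    def matrix(self) -> np.ndarray:
        """Residues as a (members x columns) array of single characters."""
        return np.array([list(m.residues) for m in self.members], dtype="U1")

    def subset_columns(self, columns: Sequence[int]) -> "LabeledAlignment":
        cols = list(columns)
        members = [
            replace(m, residues="".join(m.residues[c] for c in cols))
            for m in self.members
        ]
        return LabeledAlignment(members, np.ones(len(cols), dtype=bool))


@dataclass(frozen=True)
class ItsAnnotation:
    """ITS1 / 5.8S / ITS2 intervals, 0-based half-open, in ungapped
    sequence coordinates."""

    its1: tuple[int, int]
    r58s: tuple[int, int]
    its2: tuple[int, int]

    def __post_init__(self):
        for name, (s, e) in self.regions().items():
            if not (0 <= s < e):
                raise AnnotationError(f"empty or invalid {name} interval [{s}, {e})", name)
        if not (self.its1[1] <= self.r58s[0] and self.r58s[1] <= self.its2[0]):
            raise AnnotationError("regions must be ordered its1 < 5.8S < its2")

    def regions(self) -> dict[str, tuple[int, int]]:
        return {"its1": self.its1, "r58s": self.r58s, "its2": self.its2}


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise SequenceFormatError("gapped lengths differ")


@dataclass(frozen=True)
class Scoring:
    """Linear-gap alignment scoring; defaults suit near-identical ITS."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


def _parse_header(header: str, delimiter: str) -> tuple[str, str, str | None]:
    parts = [p.strip() for p in header.split(delimiter)]
    if len(parts) < 2 or not parts[0] or not parts[1]:
        raise SequenceFormatError(
            f"header {header!r} does not parse to accession{delimiter}species"
        )
    geography = parts[2] if len(parts) > 2 and parts[2] else None
    return parts[0], parts[1], geography


def read_labeled_fasta(
    path: str | Path, delimiter: str = "|"
) -> LabeledAlignment | list[LabeledSequence]:
    """Read a labeled FASTA; aligned input yields a :class:`LabeledAlignment`.

    Headers follow ``accession|species[|geography]``.  If all sequences
    have equal length the result is an alignment with an all-true mask;
    ragged input returns a plain list (check with ``isinstance``).
    """
    seqs: list[LabeledSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        accession, species, geography = _parse_header(header, delimiter)
        if accession in seen:
            raise SequenceFormatError(f"duplicate accession {accession}")
        seen.add(accession)
        seqs.append(LabeledSequence(accession, species, str(rec.seq), geography))
    if not seqs:
        raise SequenceFormatError(f"{path}: no sequences")
    if len({len(s) for s in seqs}) == 1:
        return LabeledAlignment(seqs)
    return seqs


def write_labeled_fasta(
    seqs: LabeledAlignment | Iterable[LabeledSequence],
    path: str | Path,
    delimiter: str = "|",
) -> None:
    members = seqs.members if isinstance(seqs, LabeledAlignment) else list(seqs)
    records = []
    for m in members:
        header = f"{m.accession}{delimiter}{m.species}"
        if m.geography:
            header += f"{delimiter}{m.geography}"
        records.append(SeqRecord(Seq(m.residues), id=header, description=""))
    SeqIO.write(records, str(path), "fasta-2line")


def global_align(
    a: LabeledSequence | str, b: LabeledSequence | str, scoring: Scoring = Scoring()
) -> PairwiseAlignment:
    """Needleman-Wunsch global alignment with linear gap costs.

    Tie-breaking during traceback is deterministic: diagonal
    (substitution) is preferred, then up (gap in ``b``), then left.
    """
    sa = a.residues if isinstance(a, LabeledSequence) else a.upper()
    sb = b.residues if isinstance(b, LabeledSequence) else b.upper()
    n, m = len(sa), len(sb)
    if n == 0 or m == 0:
        raise SequenceFormatError("cannot align empty sequences")
    F = np.empty((n + 1, m + 1), dtype=float)
    F[:, 0] = scoring.gap * np.arange(n + 1)
    F[0, :] = scoring.gap * np.arange(m + 1)
    ai = np.frombuffer(sa.encode(), dtype="S1")
    bi = np.frombuffer(sb.encode(), dtype="S1")
    for i in range(1, n + 1):
        sub = np.where(bi == ai[i - 1], scoring.match, scoring.mismatch)
        row, prev = F[i], F[i - 1]
        for j in range(1, m + 1):
            row[j] = max(prev[j - 1] + sub[j - 1], prev[j] + scoring.gap,
                         row[j - 1] + scoring.gap)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and F[i, j] == F[i - 1, j - 1] + (
            scoring.match if sa[i - 1] == sb[j - 1] else scoring.mismatch
        ):
            out_a.append(sa[i - 1]); out_b.append(sb[j - 1]); i -= 1; j -= 1
        elif i > 0 and F[i, j] == F[i - 1, j] + scoring.gap:
            out_a.append(sa[i - 1]); out_b.append(GAP); i -= 1
        else:
            out_a.append(GAP); out_b.append(sb[j - 1]); j -= 1
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                             float(F[n, m]))


def _coordinate_map(pair: PairwiseAlignment) -> list[int]:
    """For every position ``r`` of the degapped first sequence (0..len),
    the number of second-sequence residues strictly before it.

    Insertions in the second sequence (columns where the first is
    gapped) accrue to the nearest left boundary.
    """
    len_a = len(pair.aligned_a.replace(GAP, ""))
    mapping = [0] * (len_a + 1)
    r = t = 0
    for ca, cb in zip(pair.aligned_a, pair.aligned_b):
        if ca != GAP:
            mapping[r] = t
            r += 1
        if cb != GAP:
            t += 1
    mapping[len_a] = t
    return mapping


def transfer_annotation(
    reference: LabeledSequence,
    reference_annotation: ItsAnnotation,
    target: LabeledSequence,
    scoring: Scoring = Scoring(),
) -> ItsAnnotation:
    """Map ITS region boundaries from an annotated reference to a target.

    The two (ungapped) sequences are globally aligned and each half-open
    boundary is pushed through the induced coordinate map.  A region that
    collapses to an empty interval on the target raises
    :class:`AnnotationError` naming the region.
    """
    ref_len = len(reference.ungapped())
    for name, (s, e) in reference_annotation.regions().items():
        if e > ref_len:
            raise AnnotationError(f"{name} interval exceeds reference length", name)
    pair = global_align(reference.ungapped(), target.ungapped(), scoring)
    mapping = _coordinate_map(pair)
    transferred: dict[str, tuple[int, int]] = {}
    for name, (s, e) in reference_annotation.regions().items():
        ts, te = mapping[s], mapping[e]
        if ts >= te:
            raise AnnotationError(
                f"target {target.accession} lacks the {name} region "
                f"(transferred interval [{ts}, {te}) is empty)",
                name,
            )
        transferred[name] = (ts, te)
    return ItsAnnotation(transferred["its1"], transferred["r58s"], transferred["its2"])


def mask_58s(
    alignment: LabeledAlignment,
    annotations: Mapping[str, ItsAnnotation] | None,
) -> LabeledAlignment:
    """Mask out every alignment column touched by any member's 5.8S.

    ``annotations`` maps accession to that member's annotation in its own
    ungapped coordinates; each member's 5.8S interval is projected
    through its gaps onto a contiguous span of alignment columns and the
    union of spans is set False in the mask.  Passing ``None`` documents
    the skip-masking default and returns the alignment unchanged.
    """
    if annotations is None:
        return alignment
    mask = alignment.column_mask.copy()
    for m in alignment.members:
        if m.accession not in annotations:
            raise AnnotationError(f"no annotation for member {m.accession}")
        s, e = annotations[m.accession].r58s
        cols = []
        residue_idx = 0
        for col, ch in enumerate(m.residues):
            if ch != GAP:
                if s <= residue_idx < e:
                    cols.append(col)
                residue_idx += 1
        if residue_idx < e:
            raise AnnotationError(
                f"{m.accession}: 5.8S interval [{s}, {e}) exceeds ungapped length {residue_idx}"
            )
        if cols:
            mask[cols[0]: cols[-1] + 1] = False
    return LabeledAlignment(list(alignment.members), mask)


def load_annotations(path: str | Path) -> dict[str, ItsAnnotation]:
    """Read an annotation config: ``{accession: {its1: [s, e), ...}}``."""
    raw = json.loads(Path(path).read_text())
    out = {}
    for accession, regions in raw.items():
        out[accession] = ItsAnnotation(
            tuple(regions["its1"]), tuple(regions["r58s"]), tuple(regions["its2"])
        )
    return out


def save_annotations(annotations: Mapping[str, ItsAnnotation], path: str | Path) -> None:
    payload = {
        acc: {name: list(iv) for name, iv in ann.regions().items()}
        for acc, ann in annotations.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
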