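"""Sequence and motif file handling.

Reads FASTA window sets and MEME minimal-format motif files, builds labeled
datasets of fixed-length DNA windows, and provides the dataset hygiene steps
(exact deduplication, stratified train/test splitting) used throughout the
package.

Sequences are normalized on read: uppercased, with U mapped to T. Anything
else outside the A/C/G/T alphabet is handled per an explicit policy — either
a hard error (``strict``, the default) or dropping the offending record with
a warning (``drop``). Records are never silently altered.
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = "ACGT"
_NON_ACGT = re.compile(r"[^ACGT]")

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA window with an identifier and an optional class label."""

    id: str
    seq: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.label is not None and self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"record {self.id!r}: unknown label {self.label!r}")


@dataclass(frozen=True)
class MotifModel:
    """A sequence motif as a letter-probability matrix.

    ``probs`` has one row per motif column and four columns in A, C, G, T
    order; each row is a probability distribution over the four nucleotides.
    ``evalue`` is the motif's statistical significance as reported by the
    discovery tool (expected number of equally enriched motifs by chance).
    """

    name: str
    width: int
    probs: np.ndarray
    evalue: float

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if self.width < 1:
            raise ValueError(f"motif {self.name!r}: width must be >= 1")
        if probs.shape != (self.width, 4):
            raise ValueError(
                f"motif {self.name!r}: probability matrix shape {probs.shape} "
                f"does not match width {self.width} x 4"
            )
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError(f"motif {self.name!r}: probabilities outside [0, 1]")
        row_sums = probs.sum(axis=1)
        bad = np.flatnonzero(np.abs(row_sums - 1.0) > 1e-3)
        if bad.size:
            raise ValueError(
                f"motif {self.name!r}: row {bad[0] + 1} sums to "
                f"{row_sums[bad[0]]:.6f}, expected 1 within 1e-3"
            )
        if self.evalue < 0:
            raise ValueError(f"motif {self.name!r}: negative E-value")


@dataclass
class LabeledDataset:
    """An ordered collection of labeled fixed-length windows."""

    records: list[SequenceRecord]
    window_length: int

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.label is None:
                raise ValueError(f"record {rec.id!r} is unlabeled")
        bad = [r.id for r in self.records if len(r.seq) != self.window_length]
        if bad:
            raise ValueError(
                f"records with length != {self.window_length}: {', '.join(bad[:10])}"
                + ("..." if len(bad) > 10 else "")
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]  # type: ignore[misc]

    @property
    def n_positive(self) -> int:
        return sum(1 for r in self.records if r.label == POSITIVE)

    @property
    def n_negative(self) -> int:
        return sum(1 for r in self.records if r.label == NEGATIVE)


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U to T. Does not touch other letters."""
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path, policy: Literal["strict", "drop"] = "strict") -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Parameters
    ----------
    path:
        FASTA file (multi-record, wrapped or single-line).
    policy:
        ``strict`` raises on any record containing non-A/C/G/T letters after
        normalization; ``drop`` omits such records and logs how many were
        dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    if policy not in ("strict", "drop"):
        raise ValueError(f"unknown policy {policy!r}; expected 'strict' or 'drop'")

    with open(path) as handle:
        first = handle.read(1)
        if not first:
            raise ValueError(f"empty FASTA file: {path}")
        if first != ">":
            raise ValueError(f"{path}: line 1: expected '>' header, found {first!r}")
        handle.seek(0)
        raw = list(SeqIO.parse(handle, "fasta"))

    records: list[SequenceRecord] = []
    dropped = 0
    for entry in raw:
        seq = normalize_sequence(str(entry.seq))
        m = _NON_ACGT.search(seq)
        if m:
            if policy == "strict":
                raise ValueError(
                    f"record {entry.id!r} in {path} contains non-ACGT letter "
                    f"{m.group()!r} at position {m.start() + 1}"
                )
            dropped += 1
            continue
        records.append(SequenceRecord(id=entry.id, seq=seq))
    if dropped:
        logger.warning("dropped %d record(s) with non-ACGT letters from %s", dropped, path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA, one line per sequence, preserving order."""
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta-2line")


_LPM_HEADER = re.compile(
    r"letter-probability matrix:"
    r"(?:\s+alength=\s*(?P<alength>\d+))?"
    r"(?:\s+w=\s*(?P<w>\d+))?"
    r"(?:\s+nsites=\s*(?P<nsites>\S+))?"
    r"(?:\s+E=\s*(?P<evalue>\S+))?"
)


def read_meme_motifs(path: str | Path) -> list[MotifModel]:
    """Parse a MEME minimal-format motif file into :class:`MotifModel` objects.

    The minimal format is the plain-text exchange format written by MEME:
    ``MOTIF <name>`` blocks, each followed by a
    ``letter-probability matrix: alength= 4 w= <w> ... E= <e>`` header and
    ``w`` rows of four real numbers (A, C, G, T columns).

    The letter probabilities are taken verbatim from the file (no rounding
    through site counts), since downstream log-odds scores depend on them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"motif file not found: {path}")

    motifs: list[MotifModel] = []
    with open(path) as handle:
        lines = handle.readlines()

    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else f"motif_{len(motifs) + 1}"
            # find the letter-probability matrix header for this block
            j = i + 1
            header = None
            while j < n:
                stripped = lines[j].strip()
                if stripped.startswith("letter-probability matrix"):
                    header = _LPM_HEADER.match(stripped)
                    break
                if stripped.startswith("MOTIF"):
                    break
                j += 1
            if header is None:
                raise ValueError(
                    f"{path}: motif {name!r} has no letter-probability matrix block"
                )
            if header.group("w") is None:
                raise ValueError(f"{path}: motif {name!r}: matrix header lacks w=")
            width = int(header.group("w"))
            alength = int(header.group("alength") or 4)
            if alength != 4:
                raise ValueError(
                    f"{path}: motif {name!r}: alphabet length {alength} != 4 (DNA expected)"
                )
            evalue = float(header.group("evalue")) if header.group("evalue") else 0.0

            rows: list[list[float]] = []
            k = j + 1
            while k < n:
                stripped = lines[k].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL", "letter-probability")):
                    break
                fields = stripped.split()
                try:
                    row = [float(x) for x in fields]
                except ValueError:
                    break
                if len(row) != 4:
                    raise ValueError(
                        f"{path}: motif {name!r}: matrix row {len(rows) + 1} has "
                        f"{len(row)} columns, expected 4"
                    )
                rows.append(row)
                k += 1
            if len(rows) != width:
                raise ValueError(
                    f"{path}: motif {name!r}: found {len(rows)} matrix rows, "
                    f"header declares w= {width}"
                )
            try:
                motifs.append(
                    MotifModel(name=name, width=width, probs=np.array(rows), evalue=evalue)
                )
            except ValueError as exc:
                raise ValueError(f"{path}: {exc}") from exc
            i = k
        else:
            i += 1
    return motifs


def write_meme_motifs(motifs: Sequence[MotifModel], path: str | Path) -> None:
    """Write motifs in MEME minimal format (uniform background header)."""
    with open(path, "w") as handle:
        handle.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        handle.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            handle.write(f"MOTIF {m.name}\n")
            handle.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 20 E= {m.evalue:g}\n"
            )
            for row in m.probs:
                handle.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            handle.write("\n")


def filter_motifs_by_evalue(motifs: Sequence[MotifModel], threshold: float = 0.05) -> list[MotifModel]:
    """Keep motifs with E-value strictly below ``threshold``, order preserved."""
    if threshold <= 0:
        raise ValueError("E-value threshold must be > 0")
    return [m for m in motifs if m.evalue < threshold]


def load_labeled_dataset(
    pos_path: str | Path,
    neg_path: str | Path,
    window_length: int = 41,
    policy: Literal["strict", "drop"] = "strict",
) -> LabeledDataset:
    """Load positive and negative FASTA window files into one labeled dataset.

    Every record must have exactly ``window_length`` bases; otherwise the
    offending record ids are reported. Either class being empty is an error,
    since a single-class set cannot train or evaluate a classifier.
    """
    positives = read_fasta(pos_path, policy=policy)
    negatives = read_fasta(neg_path, policy=policy)
    if not positives:
        raise ValueError(f"empty class: no positive records in {pos_path}")
    if not negatives:
        raise ValueError(f"empty class: no negative records in {neg_path}")
    records = [SequenceRecord(r.id, r.seq, POSITIVE) for r in positives]
    records += [SequenceRecord(r.id, r.seq, NEGATIVE) for r in negatives]
    return LabeledDataset(records=records, window_length=window_length)


def stratified_split(
    data: LabeledDataset, test_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split into train/test preserving class proportions.

    Per class, ``round(class size * test_fraction)`` records go to the test
    set; membership is deterministic for a fixed seed. Original record order
    is preserved within each output.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    if data.n_positive == 0 or data.n_negative == 0:
        raise ValueError("both classes must be non-empty")

    rng = random.Random(seed)
    test_idx: set[int] = set()
    for label in (POSITIVE, NEGATIVE):
        idx = [i for i, r in enumerate(data.records) if r.label == label]
        n_test = round(len(idx) * test_fraction)
        test_idx.update(rng.sample(idx, n_test))

    train = [r for i, r in enumerate(data.records) if i not in test_idx]
    test = [r for i, r in enumerate(data.records) if i in test_idx]
    return (
        LabeledDataset(train, data.window_length),
        LabeledDataset(test, data.window_length),
    )


def deduplicate(data: LabeledDataset) -> LabeledDataset:
    """Remove exact duplicate sequences within each class (first kept).

    A sequence occurring in both classes is contradictory training signal:
    all its copies are removed and the conflict is logged.
    """
    pos_seqs = {r.seq for r in data.records if r.label == POSITIVE}
    neg_seqs = {r.seq for r in data.records if r.label == NEGATIVE}
    conflicts = pos_seqs & neg_seqs
    if conflicts:
        logger.warning(
            "label conflict: %d sequence(s) appear in both classes; removing all copies",
            len(conflicts),
        )

    seen: set[tuple[str, str]] = set()
    kept: list[SequenceRecord] = []
    for rec in data.records:
        if rec.seq in conflicts:
            continue
        key = (rec.label, rec.seq)  # type: ignore[assignment]
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    return LabeledDataset(kept, data.window_length)
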