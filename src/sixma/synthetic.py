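"""Synthetic 6mA benchmark generator.

Emulates balanced sets of fixed-length (default 41-nt) DNA windows in which
positives carry a planted sequence motif near the window center and
negatives are pure background. Motif strength is a continuous dial: each
planted column samples from ``strength * p_motif + (1 - strength) *
background``, so strength 0 makes the classes statistically exchangeable
(a null benchmark) and strength 1 plants the motif columns verbatim.

By default both classes have A forced at the center position, mirroring
real 6mA benchmarks where negatives are windows centered on unmethylated
adenines — the center base itself carries no class signal.

The default planted motif is a sharpened 9-column matrix with consensus
ACCGATCSA (S split evenly between C and G), echoing the kind of short
enriched motif that discovery tools report flanking 6mA sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .io import (
    DNA_ALPHABET,
    NEGATIVE,
    POSITIVE,
    LabeledDataset,
    MotifModel,
    SequenceRecord,
    write_fasta,
)


def default_planted_motif(sharpness: float = 0.91) -> MotifModel:
    """A 9-column matrix with consensus ACCGATCSA.

    Each consensus column puts ``sharpness`` on the consensus letter and the
    rest uniformly on the other three; the degenerate S column splits
    ``sharpness`` evenly between C and G.
    """
    if not (0.25 < sharpness <= 1.0):
        raise ValueError("sharpness must be in (0.25, 1]")
    off = (1.0 - sharpness) / 3.0
    rows = []
    consensus = "ACCGATCSA"
    for letter in consensus:
        if letter == "S":  # IUPAC S = C or G
            half = sharpness / 2.0
            pair_off = (1.0 - sharpness) / 2.0
            rows.append([pair_off, half, half, pair_off])
        else:
            row = [off] * 4
            row[DNA_ALPHABET.index(letter)] = sharpness
            rows.append(row)
    return MotifModel(name=consensus, width=9, probs=np.array(rows), evalue=0.029)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic benchmark.

    ``motif_offset`` is the 0-based start of the planted motif; by default
    the motif is centered on the window midpoint. ``center_a`` forces A at
    the center position of every window in both classes (windows represent
    candidate adenine sites, so the center base is constant by construction).
    """

    n_pos: int = 200
    n_neg: int = 200
    window_length: int = 41
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif_strength: float = 1.0
    motif_offset: Optional[int] = None
    center_a: bool = True
    seed: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "background_composition", tuple(self.background_composition)
        )
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        comp = np.asarray(self.background_composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("background_composition must be a non-negative 4-vector summing to 1")
        if not (0.0 <= self.motif_strength <= 1.0):
            raise ValueError("motif_strength must be in [0, 1]")

    @property
    def center_index(self) -> int:
        """0-based index of the window center, ceil(L/2) in 1-based terms."""
        return (self.window_length + 1) // 2 - 1

    def resolved_offset(self, motif_width: int) -> int:
        if self.motif_offset is not None:
            offset = self.motif_offset
        else:
            offset = (self.window_length - motif_width) // 2
        if offset < 0 or offset + motif_width > self.window_length:
            raise ValueError(
                f"motif of width {motif_width} at offset {offset} does not fit "
                f"in a {self.window_length}-nt window"
            )
        return offset

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def generate_dataset(
    spec: SyntheticSpec, motif: Optional[MotifModel] = None
) -> LabeledDataset:
    """Draw a labeled synthetic dataset.

    Positives are background windows overwritten across the motif span with
    letters sampled column-wise from the strength-mixed motif distribution;
    negatives are pure background. Deterministic for a fixed seed.
    """
    motif = motif if motif is not None else default_planted_motif()
    offset = spec.resolved_offset(motif.width)
    rng = np.random.default_rng(spec.seed)
    bg = np.asarray(spec.background_composition, dtype=float)
    letters = np.array(list(DNA_ALPHABET))

    mixed = spec.motif_strength * motif.probs + (1.0 - spec.motif_strength) * bg[None, :]
    mixed = mixed / mixed.sum(axis=1, keepdims=True)

    records: list[SequenceRecord] = []

    def draw_background() -> np.ndarray:
        return rng.choice(4, size=spec.window_length, p=bg)

    for i in range(spec.n_pos):
        idx = draw_background()
        for col in range(motif.width):
            idx[offset + col] = rng.choice(4, p=mixed[col])
        if spec.center_a:
            idx[spec.center_index] = 0
        records.append(
            SequenceRecord(f"pos_{i + 1:05d}", "".join(letters[idx]), POSITIVE)
        )
    for i in range(spec.n_neg):
        idx = draw_background()
        if spec.center_a:
            idx[spec.center_index] = 0
        records.append(
            SequenceRecord(f"neg_{i + 1:05d}", "".join(letters[idx]), NEGATIVE)
        )
    return LabeledDataset(records, spec.window_length)


def composition_report(data: LabeledDataset) -> dict[str, np.ndarray]:
    """Empirical A/C/G/T frequencies per class (generator calibration check)."""
    if not data.records:
        raise ValueError("empty dataset")
    out: dict[str, np.ndarray] = {}
    for label in (POSITIVE, NEGATIVE):
        seqs = [r.seq for r in data.records if r.label == label]
        if not seqs:
            continue
        joined = "".join(seqs)
        total = len(joined)
        out[label] = np.array([joined.count(c) / total for c in DNA_ALPHABET])
    return out


def write_dataset(
    data: LabeledDataset, spec: SyntheticSpec, outdir: str | Path
) -> tuple[Path, Path, Path]:
    """Write paired FASTA files plus a JSON sidecar recording the spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pos_path = outdir / "positives.fasta"
    neg_path = outdir / "negatives.fasta"
    spec_path = outdir / "synthetic_spec.json"
    write_fasta([r for r in data.records if r.label == POSITIVE], pos_path)
    write_fasta([r for r in data.records if r.label == NEGATIVE], neg_path)
    spec.to_json(spec_path)
    return pos_path, neg_path, spec_path
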