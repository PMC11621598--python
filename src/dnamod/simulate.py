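"""Synthetic planted-motif datasets for the 5-class methylation task.

Each class draws 41-nt windows from a background base composition,
plants a short class-specific motif at a fixed offset with a
configurable per-position fidelity, and finally forces the central
base to match the class chemistry (A for the 6mA classes, C for the
cytosine modifications) — so the site constraint always wins over the
motif.  The unmodified-adenine class (6mA-neg) carries no motif: it is
background plus the forced central A.

Defaults emulate the shape of curated multi-species benchmark sets:
500 windows for the well-populated classes and a deliberately
under-represented 5hmC class at 10% of that, which is what makes
focal-loss training meaningful.  The default motifs are 6-mers echoing
reported methylation-context motifs (e.g. CCGTA-like for 5hmC), planted
starting 2 nt downstream of the site so they overlap the ±5 window
used by attribution segment extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .records import (
    ADENINE_LABELS,
    LABELS,
    SITE_INDEX,
    WINDOW_LENGTH,
    SequenceRecord,
)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_COUNTS: dict[str, int] = {
    "4mC": 500,
    "5hmC": 50,
    "5mC": 500,
    "6mA": 500,
    "6mA-neg": 500,
}

DEFAULT_MOTIFS: dict[str, str | None] = {
    "4mC": "ATTTCC",
    "5hmC": "CCGTAA",
    "5mC": "CCTCAG",
    "6mA": "CGAGAA",
    "6mA-neg": None,
}

DEFAULT_MOTIF_OFFSET = SITE_INDEX + 2  # motif starts 2 nt downstream of the site


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset."""

    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    motifs: dict[str, str | None] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    motif_offset: int = DEFAULT_MOTIF_OFFSET
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif_fidelity: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(LABELS)
        if unknown:
            raise ValueError(f"unknown labels in counts: {sorted(unknown)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("class counts must be nonnegative")
        bg = np.asarray(self.background_composition, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or (bg < 0).any():
            raise ValueError("background_composition must be a probability 4-vector")
        if not 0.0 <= self.motif_fidelity <= 1.0:
            raise ValueError("motif_fidelity must lie in [0, 1]")
        for label, motif in self.motifs.items():
            if motif is None:
                continue
            if not 4 <= len(motif) <= 8 or set(motif) - set(BASES):
                raise ValueError(
                    f"motif for {label!r} must be 4-8 bases over A/C/G/T"
                )
            if not (0 <= self.motif_offset and
                    self.motif_offset + len(motif) <= WINDOW_LENGTH):
                raise ValueError(
                    f"motif for {label!r} at offset {self.motif_offset} falls "
                    f"outside the [0, {WINDOW_LENGTH}) window"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "background_composition" in raw:
            raw["background_composition"] = tuple(raw["background_composition"])
        return cls(**raw)


def generate_dataset(spec: SyntheticSpec) -> list[SequenceRecord]:
    """Draw a dataset with exact per-class counts, reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    bg = np.asarray(spec.background_composition, dtype=float)
    records: list[SequenceRecord] = []
    for label in LABELS:  # fixed label order keeps generation seed-stable
        n = spec.counts.get(label, 0)
        motif = spec.motifs.get(label)
        site_base = "A" if label in ADENINE_LABELS else "C"
        for i in range(n):
            seq = rng.choice(4, size=WINDOW_LENGTH, p=bg)
            if motif:
                for j, base in enumerate(motif):
                    if rng.random() < spec.motif_fidelity:
                        seq[spec.motif_offset + j] = _BASE_INDEX[base]
            # the site base is set last, so class chemistry always wins
            seq[SITE_INDEX] = _BASE_INDEX[site_base]
            records.append(SequenceRecord(
                id=f"{label}_{i:06d}",
                sequence="".join(BASES[b] for b in seq),
                label=label,
                species="synthetic",
            ))
    return records


def planted_pwm(spec: SyntheticSpec, label: str) -> np.ndarray:
    """Ground-truth per-position base probabilities of a planted motif.

    Column for motif position j puts ``motif_fidelity`` mass on the
    specified base plus ``(1 - motif_fidelity) * background`` on all
    four bases; columns sum to 1.  Shape (motif_length, 4) in A,C,G,T
    order.
    """
    motif = spec.motifs.get(label)
    if not motif:
        raise ValueError(f"label {label!r} has no planted motif")
    bg = np.asarray(spec.background_composition, dtype=float)
    pwm = np.tile((1.0 - spec.motif_fidelity) * bg, (len(motif), 1))
    for j, base in enumerate(motif):
        pwm[j, _BASE_INDEX[base]] += spec.motif_fidelity
    return pwm


def motif_span(spec: SyntheticSpec, label: str) -> tuple[int, int]:
    """Planted motif span as a 0-based half-open interval in window coordinates."""
    motif = spec.motifs.get(label)
    if not motif:
        raise ValueError(f"label {label!r} has no planted motif")
    return spec.motif_offset, spec.motif_offset + len(motif)
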