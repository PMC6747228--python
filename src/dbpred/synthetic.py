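"""Seeded synthetic datasets for offline testing of the whole pipeline.

Real benchmarks for this problem need curated structures and a PSI-BLAST
run against a large sequence database, neither of which belongs in a test
suite.  This module fabricates datasets with the same *shape* as the real
inputs — amino-acid sequences, integer L×20 log-odds-like profiles, ±1
labels — and a single knob, ``shift``, controlling how separable the two
classes are:

* class +1 sequences draw residues preferentially from a fixed 10-residue
  subset, class −1 from its complement; at ``shift=0`` both classes use the
  uniform distribution (no signal), at ``shift=1`` the two residue pools are
  disjoint (maximal compositional separation);
* each profile row carries a base log-odds score ``b`` at the observed
  residue plus rounded Gaussian noise elsewhere, clipped to [−10, 10], so
  the profile is correlated with the sequence the way a real evolutionary
  profile is.

Everything flows through one ``numpy.random.Generator`` seeded from the
spec, so a given spec reproduces its dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .io import (AA_ORDER, PSSMatrix, ProteinRecord, write_fasta,
                 write_labels, write_pssm_ascii)

#: Residues favored by the positive class at shift > 0 (the complement is
#: favored by the negative class).  An arbitrary fixed split of the alphabet.
POSITIVE_RESIDUES = frozenset("ARNDCQEGHI")

PSSM_BASE_SCORE = 5      # log-odds added at the observed residue's column
PSSM_CLIP = 10           # profiles clipped to [-PSSM_CLIP, PSSM_CLIP]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset."""

    n_per_class: int = 30
    length_range: tuple[int, int] = (50, 120)
    shift: float = 1.0
    pssm_noise: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")
        if not (20 <= lo <= hi):
            raise ValidationError(
                "length_range must satisfy 20 <= min <= max (every extractor "
                "needs at least 20 residues)"
            )
        if not (0.0 <= self.shift <= 1.0):
            raise ValidationError("shift must lie in [0, 1]")
        if self.pssm_noise < 0:
            raise ValidationError("pssm_noise must be non-negative")


def _class_probs(shift: float) -> tuple[np.ndarray, np.ndarray]:
    in_set = np.array([aa in POSITIVE_RESIDUES for aa in AA_ORDER])
    p_pos = np.where(in_set, 1.0 + shift, 1.0 - shift) / 20.0
    p_neg = np.where(in_set, 1.0 - shift, 1.0 + shift) / 20.0
    return p_pos, p_neg


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], dict[str, PSSMatrix]]:
    """Draw a labeled dataset of sequences and matching profiles."""
    rng = np.random.default_rng(spec.seed)
    p_pos, p_neg = _class_probs(spec.shift)
    alphabet = np.array(list(AA_ORDER))
    lo, hi = spec.length_range

    records: list[ProteinRecord] = []
    pssms: dict[str, PSSMatrix] = {}
    for label, probs, tag in ((+1, p_pos, "pos"), (-1, p_neg, "neg")):
        for i in range(spec.n_per_class):
            pid = f"{tag}{i:04d}"
            length = int(rng.integers(lo, hi + 1))
            residue_idx = rng.choice(20, size=length, p=probs)
            seq = "".join(alphabet[residue_idx])
            noise = np.rint(
                rng.normal(0.0, spec.pssm_noise, size=(length, 20))
            )
            scores = noise
            scores[np.arange(length), residue_idx] += PSSM_BASE_SCORE
            scores = np.clip(scores, -PSSM_CLIP, PSSM_CLIP)
            records.append(ProteinRecord(id=pid, sequence=seq, label=label))
            pssms[pid] = PSSMatrix(protein_id=pid, scores=scores)
    return records, pssms


DEFAULT_FIXTURES = {
    "easy": SyntheticSpec(shift=1.0, seed=11),
    "medium": SyntheticSpec(shift=0.4, seed=12),
    "null": SyntheticSpec(shift=0.0, seed=13),
}


def write_dataset(records, pssms, out_dir) -> None:
    """Write one dataset as FASTA + labels TSV + a directory of ASCII
    profiles, the exact on-disk layout the command-line tools consume."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(records, out_dir / "sequences.fasta")
    write_labels({r.id: r.label for r in records}, out_dir / "labels.tsv")
    pssm_dir = out_dir / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    for rec in records:
        write_pssm_ascii(pssms[rec.id], rec.sequence,
                         pssm_dir / f"{rec.id}.pssm")


def write_fixture_suite(out_dir, specs=None) -> dict[str, Path]:
    """Emit a suite of datasets (default: easy / medium / null) under
    ``out_dir``, one subdirectory each."""
    out_dir = Path(out_dir)
    specs = specs if specs is not None else DEFAULT_FIXTURES
    paths: dict[str, Path] = {}
    for name, spec in specs.items():
        records, pssms = generate_dataset(spec)
        target = out_dir / name
        write_dataset(records, pssms, target)
        paths[name] = target
    return paths
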