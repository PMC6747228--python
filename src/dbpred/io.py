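"""Reading and writing of external formats.

Handles FASTA sequences, PSI-BLAST ASCII PSSM profiles, label tables and
trained-model archives, validating everything into the package's domain
types on the way in.

The canonical amino-acid order used for all internal 20-column tables is
``ARNDCQEGHILKMFPSTWYV`` (the order PSI-BLAST prints its log-odds columns
in); profiles read from disk are remapped to it regardless of the column
order the file declares.
"""

from __future__ import annotations

import io as _stdio
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO

from .exceptions import FormatError, ValidationError

#: Canonical residue order for every 20-wide table in the package.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
AA_SET = frozenset(AA_ORDER)

#: Residue codes that are legal FASTA but outside the canonical alphabet.
NONCANONICAL = frozenset("BZXUOJ*")

MODEL_SCHEMA_VERSION = 1


@dataclass
class ProteinRecord:
    """One protein: identifier, amino-acid sequence, optional ±1 label."""

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record has an empty id")
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence):
            if ch not in AA_SET:
                raise ValidationError(
                    f"record {self.id!r}: illegal residue {ch!r} at position "
                    f"{pos + 1} (canonical alphabet is {AA_ORDER})"
                )
        if self.label is not None and self.label not in (+1, -1):
            raise ValidationError(
                f"record {self.id!r}: label must be +1 or -1, got {self.label}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PSSMatrix:
    """L×20 log-odds profile of one protein, columns in canonical order."""

    protein_id: str
    scores: np.ndarray
    column_order: str = AA_ORDER

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValidationError(
                f"PSSM for {self.protein_id!r}: expected L×20 matrix, "
                f"got shape {self.scores.shape}"
            )
        if sorted(self.column_order) != sorted(AA_ORDER):
            raise ValidationError(
                f"PSSM for {self.protein_id!r}: column_order must be a "
                "permutation of the 20 amino acids"
            )
        if self.column_order != AA_ORDER:
            perm = [self.column_order.index(aa) for aa in AA_ORDER]
            self.scores = self.scores[:, perm]
            self.column_order = AA_ORDER

    def __len__(self) -> int:
        return self.scores.shape[0]


def normalize_sequence(seq: str, *, policy: str = "reject") -> str:
    """Uppercase a raw sequence and apply the non-canonical-residue policy.

    ``policy="reject"`` (default) leaves non-canonical codes in place so the
    record constructor reports them; ``policy="mask"`` maps B/Z/U/O/J/* to X.
    Downstream extractors never accept X, so masked positions must be dropped
    by the caller (``drop_masked``).
    """
    seq = seq.strip().upper().replace(" ", "")
    if policy == "mask":
        table = str.maketrans({c: "X" for c in "BZUOJ*"})
        seq = seq.translate(table)
    elif policy != "reject":
        raise ValueError(f"unknown residue policy {policy!r}")
    return seq


def drop_masked(seq: str) -> str:
    """Remove X positions from a masked sequence."""
    return seq.replace("X", "")


def read_fasta(path, *, policy: str = "reject") -> list[ProteinRecord]:
    """Read a multi-record FASTA file into validated :class:`ProteinRecord`s.

    Order is preserved; duplicate ids and (under the default policy)
    non-canonical residues raise :class:`ValidationError`.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(entry.seq), policy=policy)
        if policy == "mask":
            seq = drop_masked(seq)
        if entry.id in seen:
            raise ValidationError(f"duplicate record id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path, *, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# --- PSI-BLAST ASCII PSSM -------------------------------------------------

def read_pssm_ascii(path, *, sequence: Optional[str] = None,
                    protein_id: Optional[str] = None) -> PSSMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Only the first block of 20 columns (the log-odds scores) is kept; the
    percentage block and the trailing statistics lines are ignored.  The
    header row of residue letters fixes the file's column order, which is
    remapped to :data:`AA_ORDER`.  If ``sequence`` is given, the residue
    column of every row is checked against it.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    header_cols: Optional[str] = None
    rows: list[list[int]] = []
    residues: list[str] = []
    expected_pos = 1
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        if header_cols is None:
            # the column-header line: 40 single-letter residue codes
            # (or 20 in a minimal dialect)
            if len(tokens) >= 20 and all(t in AA_SET for t in tokens[:20]):
                header_cols = "".join(tokens[:20])
            continue
        if not tokens[0].isdigit():
            break  # trailing K/lambda statistics – end of the matrix
        if int(tokens[0]) != expected_pos:
            raise FormatError(
                f"{path}:{lineno}: expected row for position {expected_pos}, "
                f"got {tokens[0]}"
            )
        if len(tokens) < 22:
            raise FormatError(
                f"{path}:{lineno}: truncated row, need position, residue and "
                f"20 log-odds integers, got {len(tokens)} fields"
            )
        residue = tokens[1]
        try:
            scores = [int(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise FormatError(
                f"{path}:{lineno}: non-integer value in log-odds block: {exc}"
            ) from None
        residues.append(residue)
        rows.append(scores)
        expected_pos += 1

    if header_cols is None or not rows:
        raise FormatError(f"{path}: no PSSM matrix found")

    if sequence is not None:
        if len(sequence) != len(rows):
            raise ValidationError(
                f"{path}: profile has {len(rows)} rows but the sequence has "
                f"{len(sequence)} residues"
            )
        for i, (r, s) in enumerate(zip(residues, sequence), start=1):
            if r != s:
                raise ValidationError(
                    f"{path}: residue mismatch at position {i}: profile has "
                    f"{r!r}, sequence has {s!r}"
                )

    pid = protein_id if protein_id is not None else path.stem
    return PSSMatrix(protein_id=pid, scores=np.array(rows, dtype=float),
                     column_order=header_cols)


def write_pssm_ascii(pssm: PSSMatrix, sequence: str, path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect read by
    :func:`read_pssm_ascii` (log-odds block only)."""
    if len(sequence) != len(pssm):
        raise ValidationError(
            f"PSSM for {pssm.protein_id!r}: {len(pssm)} rows vs sequence "
            f"length {len(sequence)}"
        )
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("    " + "  ".join(AA_ORDER) + "\n")
        for i, (res, row) in enumerate(zip(sequence, pssm.scores), start=1):
            cells = " ".join(f"{int(round(v)):3d}" for v in row)
            fh.write(f"{i:5d} {res} {cells}\n")
        fh.write("\n")


# --- label tables ---------------------------------------------------------

def read_labels(path, *, convention: str = "pm1") -> dict[str, int]:
    """Read a two-column id/label table.

    ``convention="pm1"`` accepts +1/-1; ``convention="01"`` accepts 1/0 and
    maps 0 to -1.  Internal representation is always ±1.
    """
    if convention not in ("pm1", "01"):
        raise ValueError(f"unknown label convention {convention!r}")
    path = Path(path)
    labels: dict[str, int] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'id<TAB>label'")
        pid, token = parts
        if convention == "pm1":
            if token in ("+1", "1"):
                lab = +1
            elif token == "-1":
                lab = -1
            else:
                raise ValidationError(
                    f"{path}:{lineno}: unknown ±1 label token {token!r}"
                )
        else:
            if token == "1":
                lab = +1
            elif token == "0":
                lab = -1
            else:
                raise ValidationError(
                    f"{path}:{lineno}: unknown 0/1 label token {token!r}"
                )
        if pid in labels:
            raise ValidationError(f"{path}:{lineno}: duplicate id {pid!r}")
        labels[pid] = lab
    if not labels:
        raise FormatError(f"{path}: empty label table")
    return labels


def write_labels(labels: dict[str, int], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for pid, lab in labels.items():
            fh.write(f"{pid}\t{lab:+d}\n")


# --- model archive --------------------------------------------------------

def save_model(model, path) -> None:
    """Serialize a trained model to a zip archive (JSON metadata + one
    ``.npy`` per array), with a schema-version field for forward safety."""
    path = Path(path)
    meta = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "C": model.C,
        "lam": model.lam,
        "views": list(model.views),
        "gammas": {v: model.gammas[v] for v in model.views},
        "omega": list(map(float, model.omega)),
        "train_ids": list(model.train_ids),
        "fuzzy": bool(model.fuzzy),
        "standardize_scores": bool(model.standardize_scores),
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for name, arr in [("alpha", model.alpha), ("D", model.D)]:
            buf = _stdio.BytesIO()
            np.save(buf, np.asarray(arr), allow_pickle=False)
            zf.writestr(f"{name}.npy", buf.getvalue())
        for view in model.views:
            buf = _stdio.BytesIO()
            np.save(buf, np.asarray(model.train_features[view]),
                    allow_pickle=False)
            zf.writestr(f"train_features/{view}.npy", buf.getvalue())


def load_model(path):
    """Inverse of :func:`save_model`; refuses newer schema versions and
    raises :class:`FormatError` on corrupted archives."""
    from .fkrr import FKRRModel  # deferred to avoid an import cycle

    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            version = meta.get("schema_version")
            if version != MODEL_SCHEMA_VERSION:
                raise FormatError(
                    f"{path}: model schema version {version} not supported "
                    f"(this build reads version {MODEL_SCHEMA_VERSION})"
                )

            def _load(name):
                return np.load(_stdio.BytesIO(zf.read(name)),
                               allow_pickle=False)

            alpha = _load("alpha.npy")
            D = _load("D.npy")
            train_features = {
                v: _load(f"train_features/{v}.npy") for v in meta["views"]
            }
    except FormatError:
        raise
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, ValueError) as exc:
        raise FormatError(f"{path}: corrupted or invalid model file: {exc}") from None

    return FKRRModel(
        alpha=alpha,
        D=D,
        C=meta["C"],
        lam=meta["lam"],
        omega=np.array(meta["omega"], dtype=float),
        views=tuple(meta["views"]),
        gammas={v: float(g) for v, g in meta["gammas"].items()},
        train_ids=tuple(meta["train_ids"]),
        train_features=train_features,
        fuzzy=meta["fuzzy"],
        standardize_scores=meta["standardize_scores"],
    )
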