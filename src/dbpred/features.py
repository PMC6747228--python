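"""The four multi-view sequence descriptors.

Two views are computed from the raw amino-acid sequence:

* **MCD** — multi-scale continuous/discontinuous composition, transition and
  distribution statistics of a 7-group residue alphabet over 14 sequence
  regions (882 dimensions).
* **NMBAC** — normalized Moreau–Broto autocorrelation of six standardized
  physicochemical properties over lags 1..lg (6·lg dimensions).

Two views are computed from the PSI-BLAST evolutionary profile (PSSM):

* **PSSM-AB** — per-column means over 20 consecutive sequence blocks
  (400 dimensions).
* **PsePSSM** — column means of the row-standardized profile plus lagged
  squared-difference terms (20 + 20·lag_max dimensions).

All output orderings are frozen: changing them is a breaking change for
serialized feature tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .exceptions import LengthError, ValidationError
from .io import AA_ORDER, PSSMatrix, ProteinRecord

VIEW_NAMES = ("mcd", "nmbac", "pssm_ab", "psepssm")

# --- physicochemical property table ----------------------------------------
# Six properties per residue: hydrophobicity (H), side-chain volume (VSC),
# polarity (P1), polarizability (P2), solvent-accessible surface area (SASA),
# net charge index of side chains (NCISC).
PROPERTY_NAMES = ("H", "VSC", "P1", "P2", "SASA", "NCISC")

_RAW_PROPERTIES = {
    #        H      VSC     P1     P2      SASA    NCISC
    "A": (0.62, 27.5, 8.1, 0.046, 1.181, 0.007187),
    "C": (0.29, 44.6, 5.5, 0.128, 1.461, -0.03661),
    "D": (-0.9, 40.0, 13.0, 0.105, 1.587, -0.02382),
    "E": (-0.74, 62.0, 12.3, 0.151, 1.862, 0.006802),
    "F": (1.19, 115.5, 5.2, 0.29, 2.228, 0.037552),
    "G": (0.48, 0.0, 9.0, 0.0, 0.881, 0.179052),
    "H": (-0.4, 79.0, 10.4, 0.23, 2.025, -0.01069),
    "I": (1.38, 93.5, 5.2, 0.186, 1.81, 0.021631),
    "K": (-1.5, 100.0, 11.3, 0.219, 2.258, 0.017708),
    "L": (1.06, 93.5, 4.9, 0.186, 1.931, 0.051672),
    "M": (0.64, 94.1, 5.7, 0.221, 2.034, 0.002683),
    "N": (-0.78, 58.7, 11.6, 0.134, 1.655, 0.005392),
    "P": (0.12, 41.9, 8.0, 0.131, 1.468, 0.239531),
    "Q": (-0.85, 80.7, 10.5, 0.18, 1.932, 0.049211),
    "R": (-2.53, 105.0, 10.5, 0.291, 2.56, 0.043587),
    "S": (-0.18, 29.3, 9.2, 0.062, 1.298, 0.004627),
    "T": (-0.05, 51.3, 8.6, 0.108, 1.525, 0.003352),
    "V": (1.08, 71.5, 5.9, 0.14, 1.645, 0.057004),
    "W": (0.81, 145.5, 5.4, 0.409, 2.663, 0.037977),
    "Y": (0.26, 117.3, 6.2, 0.298, 2.368, 0.023599),
}


def property_table(standardized: bool = False) -> np.ndarray:
    """20×6 property matrix, rows in canonical residue order.

    With ``standardized=True`` each property column is shifted/scaled to
    zero mean and unit (population) standard deviation over the 20 residues,
    which puts the six very differently scaled properties on a common
    footing before autocorrelation.
    """
    table = np.array([_RAW_PROPERTIES[aa] for aa in AA_ORDER], dtype=float)
    if standardized:
        table = (table - table.mean(axis=0)) / table.std(axis=0)
    return table


# --- MCD -------------------------------------------------------------------
# Seven physicochemical residue groups (dipole / side-chain volume clusters).
# The digit assigned to each group is fixed by the descriptor's reference
# encoding AVDCALSK -> 11321476.
MCD_GROUPS = {
    frozenset("AGV"): "1",
    frozenset("C"): "2",
    frozenset("DE"): "3",
    frozenset("FILP"): "4",
    frozenset("HNQW"): "5",
    frozenset("KR"): "6",
    frozenset("MSTY"): "7",
}
_GROUP_OF = {aa: digit for members, digit in MCD_GROUPS.items() for aa in members}
N_GROUPS = 7

# Region scheme: split the sequence into 4 equal parts (remainder to the
# leftmost parts), then take 10 contiguous part spans plus 4 discontinuous
# unions, 14 regions total. With 7 C + 21 T + 35 D statistics per region
# this yields the 63·14 = 882-dimensional vector.
MCD_REGIONS: tuple[tuple[int, ...], ...] = (
    (0,), (1,), (2,), (3,),          # quarters
    (0, 1), (1, 2), (2, 3),          # halves, sliding
    (0, 1, 2), (1, 2, 3),            # three-quarter spans
    (0, 1, 2, 3),                    # full sequence
    (0, 2), (1, 3), (0, 3), (0, 1, 3),  # discontinuous unions
)
MCD_DIM = len(MCD_REGIONS) * (N_GROUPS + N_GROUPS * (N_GROUPS - 1) // 2 + 5 * N_GROUPS)
MCD_MIN_LENGTH = 8  # every quarter must hold >=2 residues


def encode_mcd_groups(sequence: str) -> str:
    """Map a protein sequence to its 7-group digit string (e.g. ``AVDCALSK``
    encodes to ``11321476``)."""
    try:
        return "".join(_GROUP_OF[aa] for aa in sequence)
    except KeyError as exc:
        raise ValidationError(
            f"residue {exc.args[0]!r} is outside the 20-letter alphabet"
        ) from None


def _quarters(n: int) -> list[range]:
    """Split 0..n-1 into 4 contiguous parts, remainder to the leftmost."""
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    bounds = np.cumsum([0] + sizes)
    return [range(bounds[i], bounds[i + 1]) for i in range(4)]


def _ctd(region: str) -> list[float]:
    """Composition, transition and distribution statistics of one region.

    C: frequency of each group (7).  T: frequency of unordered adjacent
    pairs of distinct groups, over region length − 1 (21).  D: relative
    position of the first, 25%, 50%, 75% and last occurrence of each group,
    zero when absent (35).
    """
    m = len(region)
    out: list[float] = []
    # composition
    counts = [region.count(str(g)) for g in range(1, N_GROUPS + 1)]
    out.extend(c / m for c in counts)
    # transition (unordered distinct pairs, canonical pair order g<h)
    pair_counts = {}
    for a, b in zip(region, region[1:]):
        if a != b:
            key = (min(a, b), max(a, b))
            pair_counts[key] = pair_counts.get(key, 0) + 1
    for g in range(1, N_GROUPS + 1):
        for h in range(g + 1, N_GROUPS + 1):
            out.append(pair_counts.get((str(g), str(h)), 0) / (m - 1))
    # distribution
    for g in range(1, N_GROUPS + 1):
        positions = [i + 1 for i, ch in enumerate(region) if ch == str(g)]
        if not positions:
            out.extend([0.0] * 5)
            continue
        n_occ = len(positions)
        for frac in (None, 0.25, 0.5, 0.75, 1.0):
            idx = 1 if frac is None else max(1, math.ceil(frac * n_occ))
            out.append(positions[idx - 1] / m)
    return out


def mcd_features(sequence: str) -> np.ndarray:
    """882-dimensional multi-scale continuous/discontinuous descriptor."""
    if len(sequence) < MCD_MIN_LENGTH:
        raise LengthError(
            f"MCD needs a sequence of length >= {MCD_MIN_LENGTH}, "
            f"got {len(sequence)}"
        )
    encoded = encode_mcd_groups(sequence)
    parts = _quarters(len(encoded))
    feats: list[float] = []
    for region_parts in MCD_REGIONS:
        region = "".join(encoded[i] for p in region_parts for i in parts[p])
        feats.extend(_ctd(region))
    return np.array(feats, dtype=float)


# --- NMBAC -----------------------------------------------------------------

def nmbac_features(sequence: str, lg: int = 10) -> np.ndarray:
    """Normalized Moreau–Broto autocorrelation over six standardized
    physicochemical properties.

    Entry (property j, lag) is ``(1/(n-lag)) * sum_i X[i,j] * X[i+lag,j]``
    where ``X`` holds the standardized property values of the residues.
    Ordering is property-major: all lags of property 1, then property 2, ...
    """
    n = len(sequence)
    if n <= lg:
        raise LengthError(f"NMBAC with lg={lg} needs length > {lg}, got {n}")
    table = property_table(standardized=True)
    idx = np.fromiter((AA_ORDER.index(aa) for aa in sequence), dtype=int, count=n)
    X = table[idx]  # n×6
    feats = np.empty(6 * lg, dtype=float)
    for j in range(6):
        col = X[:, j]
        for lag in range(1, lg + 1):
            feats[j * lg + (lag - 1)] = (
                np.dot(col[: n - lag], col[lag:]) / (n - lag)
            )
    return feats


# --- PSSM-AB ---------------------------------------------------------------

def pssm_ab_features(pssm: PSSMatrix) -> np.ndarray:
    """Averaged-blocks profile descriptor: the sequence rows are cut into
    20 consecutive blocks and each of the 20 profile columns is averaged
    within each block, giving a 400-vector indexed k = j + 20·(i−1) for
    block i and column j.

    For L not divisible by 20, block i covers rows
    ⌊(i−1)·L/20⌋ .. ⌊i·L/20⌋−1, which reduces to equal blocks of L/20 rows
    in the divisible case.
    """
    L = len(pssm)
    if L < 20:
        raise LengthError(f"PSSM-AB needs a profile with L >= 20, got L={L}")
    scores = pssm.scores
    feats = np.empty(400, dtype=float)
    for i in range(1, 21):
        lo = (i - 1) * L // 20
        hi = i * L // 20
        block_means = scores[lo:hi].mean(axis=0)
        feats[20 * (i - 1) : 20 * i] = block_means
    return feats


# --- PsePSSM ---------------------------------------------------------------

def psepssm_features(pssm: PSSMatrix, lag_max: int = 15) -> np.ndarray:
    """Pseudo-PSSM descriptor of a profile.

    Each profile row is first standardized over its 20 entries (rows with
    zero spread standardize to all zeros rather than NaN).  The first 20
    features are the column means of the standardized profile; feature
    k = 20 + j + 20·(lag−1) is the mean squared difference between column j
    entries ``lag`` positions apart, for lag = 1..lag_max.
    """
    L = len(pssm)
    if L <= lag_max:
        raise LengthError(
            f"PsePSSM with lag_max={lag_max} needs L > {lag_max}, got L={L}"
        )
    scores = pssm.scores
    mean = scores.mean(axis=1, keepdims=True)
    std = scores.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(std > 0, (scores - mean) / std, 0.0)
    feats = np.empty(20 + 20 * lag_max, dtype=float)
    feats[:20] = P.mean(axis=0)
    for lag in range(1, lag_max + 1):
        diff = P[: L - lag] - P[lag:]
        feats[20 + 20 * (lag - 1) : 20 + 20 * lag] = (diff ** 2).mean(axis=0)
    return feats


# --- batch extraction ------------------------------------------------------

@dataclass
class FeatureMatrix:
    """One feature view over a dataset: N×d values with aligned row ids."""

    view: str
    values: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = tuple(self.ids)
        if self.values.ndim != 2:
            raise ValidationError(f"view {self.view!r}: values must be 2-D")
        if self.values.shape[0] != len(self.ids):
            raise ValidationError(
                f"view {self.view!r}: {self.values.shape[0]} rows vs "
                f"{len(self.ids)} ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"view {self.view!r}: non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def subset(self, indices) -> "FeatureMatrix":
        indices = np.asarray(indices)
        return FeatureMatrix(
            view=self.view,
            values=self.values[indices],
            ids=tuple(self.ids[i] for i in indices),
        )


def extract_all_views(
    records: Sequence[ProteinRecord],
    pssms: Optional[Mapping[str, PSSMatrix]] = None,
    *,
    views: Iterable[str] = VIEW_NAMES,
    lg: int = 10,
    lag_max: int = 15,
) -> dict[str, FeatureMatrix]:
    """Compute the requested feature views for a dataset, with identically
    ordered rows across views.  Records missing a profile are reported by id
    when a PSSM-based view is requested."""
    records = list(records)
    if not records:
        raise ValidationError("empty record list")
    views = tuple(views)
    unknown = set(views) - set(VIEW_NAMES)
    if unknown:
        raise ValidationError(f"unknown views: {sorted(unknown)}")

    needs_pssm = {"pssm_ab", "psepssm"} & set(views)
    if needs_pssm:
        pssms = pssms or {}
        missing = [r.id for r in records if r.id not in pssms]
        if missing:
            raise ValidationError(
                f"missing PSSM for records: {', '.join(missing)}"
            )
        for rec in records:
            if len(pssms[rec.id]) != len(rec.sequence):
                raise ValidationError(
                    f"record {rec.id!r}: PSSM has {len(pssms[rec.id])} rows "
                    f"but sequence length is {len(rec.sequence)}"
                )

    ids = tuple(r.id for r in records)
    out: dict[str, FeatureMatrix] = {}
    for view in views:
        if view == "mcd":
            rows = [mcd_features(r.sequence) for r in records]
        elif view == "nmbac":
            rows = [nmbac_features(r.sequence, lg=lg) for r in records]
        elif view == "pssm_ab":
            rows = [pssm_ab_features(pssms[r.id]) for r in records]
        else:  # psepssm
            rows = [psepssm_features(pssms[r.id], lag_max=lag_max) for r in records]
        out[view] = FeatureMatrix(view=view, values=np.vstack(rows), ids=ids)
    return out
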