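"""Feature encodings: square-root amino-acid composition, gapped dipeptide
compositions, and region-averaged property/profile tracks over the
length-conditional six-part sequence split.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import AA_INDEX, ALPHABET, AAindexTable, ProteinRecord, PSSMProfile

# Feature family identifiers and their fixed dimensions.
FAMILY_DIMS: dict[str, int] = {
    "OAAC": 20,
    "DIPEP0": 400,
    "DIPEP1": 400,
    "DIPEP2": 400,
    "DIPEP_ALL": 1200,
    "AAINDEX": 168,
    "PSSM": 120,
}

#: The six families that feed one model each in the voting ensemble.
MODEL_FAMILIES: tuple[str, ...] = (
    "OAAC", "DIPEP0", "DIPEP1", "DIPEP2", "AAINDEX", "PSSM",
)

REGION_NAMES: tuple[str, ...] = ("N1", "N2", "N3", "N4", "M", "C")

# Split geometry constants: N-terminal sub-part lengths for the long and
# intermediate cases, and the fixed C-terminal length.
_DN_LONG = 25
_DN_MID = 20
_DC = 10
_CASE_A_MIN = 4 * _DN_LONG + 20 + _DC  # 130
_CASE_B_MIN = 4 * _DN_MID + _DC  # 90
MIN_SPLIT_LENGTH = 12


@dataclass(frozen=True)
class SAAPartition:
    """Six half-open index ranges (N1..N4, M, C) tiling ``[0, L)``.

    In case ``C`` (short sequences) the N-terminal is not subdivided: the
    four N slots all alias the single undivided N range.
    """

    regions: tuple[tuple[int, int], ...]
    case: str

    def __post_init__(self) -> None:
        if len(self.regions) != 6:
            raise ValueError("exactly six regions required")
        if self.case not in {"A", "B", "C"}:
            raise ValueError(f"unknown case {self.case!r}")

    @property
    def length(self) -> int:
        return self.regions[-1][1]

    def distinct_regions(self) -> list[tuple[int, int]]:
        """The non-aliased ranges in order (3 in case C, 6 otherwise)."""
        seen: list[tuple[int, int]] = []
        for r in self.regions:
            if not seen or r != seen[-1]:
                seen.append(r)
        return seen


@dataclass
class FeatureVector:
    """A named real-valued feature vector of one family."""

    values: np.ndarray
    names: list[str]
    family: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.names):
            raise ValueError("values and names must be 1-D and equal length")
        expected = FAMILY_DIMS.get(self.family)
        if expected is not None and len(self.values) != expected:
            # Custom-size tables are allowed for AAINDEX.
            if self.family != "AAINDEX":
                raise ValueError(
                    f"family {self.family}: expected {expected} features, "
                    f"got {len(self.values)}"
                )


@dataclass
class FeatureMatrix:
    """Feature vectors for many proteins sharing one name layout."""

    ids: list[str]
    names: list[str]
    values: np.ndarray
    family: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.names)):
            raise ValueError(
                f"value matrix {self.values.shape} does not match "
                f"{len(self.ids)} ids x {len(self.names)} names"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite cells")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.names)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, family: str) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            ids=[str(i) for i in df.index],
            names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            family=family,
        )

    @classmethod
    def from_vectors(
        cls, ids: Sequence[str], vectors: Sequence[FeatureVector]
    ) -> "FeatureMatrix":
        if not vectors:
            raise ValueError("no feature vectors")
        names = vectors[0].names
        family = vectors[0].family
        for v in vectors[1:]:
            if v.names != names:
                raise ValueError("inconsistent feature name layouts")
        return cls(
            ids=list(ids),
            names=list(names),
            values=np.vstack([v.values for v in vectors]),
            family=family,
        )


def compute_oaac(record: ProteinRecord) -> FeatureVector:
    """Square-root amino-acid composition: ``sqrt(n_i / L)`` per residue.

    The squared values sum to exactly 1.
    """
    counts = np.zeros(20)
    for aa in record.sequence:
        counts[AA_INDEX[aa]] += 1
    freqs = counts / record.length
    return FeatureVector(
        values=np.sqrt(freqs),
        names=[f"OAAC_{aa}" for aa in ALPHABET],
        family="OAAC",
    )


def dipeptide_names(s: int) -> list[str]:
    return [f"DIPEP{s}_{a}{b}" for a in ALPHABET for b in ALPHABET]


def compute_dipeptide(record: ProteinRecord, s: int) -> FeatureVector:
    """Gapped dipeptide composition at interval ``s`` (0, 1 or 2).

    Counts ordered residue pairs at positions ``(t, t + s + 1)`` and divides
    by ``N - 1`` for every interval, so the 400 cells sum to
    ``(N - 1 - s) / (N - 1)`` (exactly 1 at ``s = 0``).
    """
    if s not in (0, 1, 2):
        raise ValueError(f"interval must be 0, 1 or 2, got {s}")
    n = record.length
    if n < s + 2:
        raise ValueError(
            f"record {record.id!r}: length {n} too short for interval {s} "
            f"(need at least {s + 2})"
        )
    counts = np.zeros((20, 20))
    seq = record.sequence
    gap = s + 1
    for t in range(n - gap):
        counts[AA_INDEX[seq[t]], AA_INDEX[seq[t + gap]]] += 1
    return FeatureVector(
        values=(counts / (n - 1)).ravel(),
        names=dipeptide_names(s),
        family=f"DIPEP{s}",
    )


def compute_dipeptide_all(record: ProteinRecord) -> FeatureVector:
    """Concatenated dipeptide compositions at intervals 0, 1 and 2 (1200-dim)."""
    parts = [compute_dipeptide(record, s) for s in (0, 1, 2)]
    return FeatureVector(
        values=np.concatenate([p.values for p in parts]),
        names=[n for p in parts for n in p.names],
        family="DIPEP_ALL",
    )


def saa_partition(length: int) -> SAAPartition:
    """Length-conditional six-part split (N1..N4, M, C) of ``[0, L)``.

    - case A (``L >= 130``): four N parts of 25, C of 10, M takes the rest;
    - case B (``90 < L < 130``): four N parts of 20, C of 10, M the rest;
    - case C (``12 <= L <= 90``): undivided N of ``(L - 10) // 2`` (aliased
      into all four N slots), C of 10, M the rest.

    The case-B lower bound is exclusive: at exactly ``L = 90`` the middle
    region would be empty and its mean undefined, so that length takes the
    undivided-N split instead.
    """
    if length < MIN_SPLIT_LENGTH:
        raise ValueError(
            f"sequence length {length} < {MIN_SPLIT_LENGTH}: cannot form "
            "non-empty N/M/C regions"
        )
    if length >= _CASE_A_MIN:
        dn, case = _DN_LONG, "A"
    elif length > _CASE_B_MIN:
        dn, case = _DN_MID, "B"
    else:
        dn, case = None, "C"
    c_start = length - _DC
    if case in ("A", "B"):
        bounds = [(i * dn, (i + 1) * dn) for i in range(4)]
        bounds.append((4 * dn, c_start))  # M
    else:
        n_len = (length - _DC) // 2
        n_range = (0, n_len)
        bounds = [n_range, n_range, n_range, n_range, (n_len, c_start)]
    bounds.append((c_start, length))
    return SAAPartition(regions=tuple(bounds), case=case)


def _region_means(track: np.ndarray, partition: SAAPartition) -> np.ndarray:
    """Mean of each column of ``track`` over each of the six regions.

    Returns shape (6, track.shape[1]).
    """
    return np.vstack(
        [track[start:end].mean(axis=0) for start, end in partition.regions]
    )


def encode_aaindex(
    record: ProteinRecord, table: AAindexTable
) -> FeatureVector:
    """Per-property region means over the six-part split.

    For each property and region, the arithmetic mean of the per-residue
    property values over that region. Ordered property-major then region:
    ``28 properties x 6 regions = 168`` values for the default table.
    """
    partition = saa_partition(record.length)
    idx = np.fromiter(
        (AA_INDEX[aa] for aa in record.sequence), dtype=int, count=record.length
    )
    track = table.values[:, idx].T  # L x n_properties
    means = _region_means(track, partition)  # 6 x n_properties
    values = means.T.ravel()  # property-major
    names = [
        f"AAINDEX_{pid}_{region}"
        for pid in table.property_ids
        for region in REGION_NAMES
    ]
    return FeatureVector(values=values, names=names, family="AAINDEX")


def encode_pssm(record: ProteinRecord, profile: PSSMProfile) -> FeatureVector:
    """Per-column region means of a PSSM profile over the six-part split.

    20 columns x 6 regions = 120 values, column-major then region.
    """
    if profile.length != record.length:
        raise ValueError(
            f"record {record.id!r}: profile has {profile.length} rows but "
            f"sequence has {record.length} residues"
        )
    partition = saa_partition(record.length)
    means = _region_means(profile.scores, partition)  # 6 x 20
    values = means.T.ravel()
    names = [
        f"PSSM_{aa}_{region}" for aa in ALPHABET for region in REGION_NAMES
    ]
    return FeatureVector(values=values, names=names, family="PSSM")


def build_family_matrix(
    records: Sequence[ProteinRecord],
    family: str,
    table: AAindexTable | None = None,
    profiles: Mapping[str, PSSMProfile] | None = None,
) -> FeatureMatrix:
    """Compute one family's feature matrix for a set of records."""
    vectors: list[FeatureVector] = []
    for rec in records:
        if family == "OAAC":
            vectors.append(compute_oaac(rec))
        elif family in ("DIPEP0", "DIPEP1", "DIPEP2"):
            vectors.append(compute_dipeptide(rec, int(family[-1])))
        elif family == "DIPEP_ALL":
            vectors.append(compute_dipeptide_all(rec))
        elif family == "AAINDEX":
            if table is None:
                raise ValueError("AAINDEX features require a property table")
            vectors.append(encode_aaindex(rec, table))
        elif family == "PSSM":
            if profiles is None or rec.id not in profiles:
                raise ValueError(f"no PSSM profile for record {rec.id!r}")
            vectors.append(encode_pssm(rec, profiles[rec.id]))
        else:
            raise ValueError(f"unknown feature family {family!r}")
    return FeatureMatrix.from_vectors([r.id for r in records], vectors)


def build_family_matrices(
    records: Sequence[ProteinRecord],
    families: Sequence[str] = MODEL_FAMILIES,
    table: AAindexTable | None = None,
    profiles: Mapping[str, PSSMProfile] | None = None,
) -> dict[str, FeatureMatrix]:
    """Compute feature matrices for several families at once."""
    return {
        fam: build_family_matrix(records, fam, table=table, profiles=profiles)
        for fam in families
    }
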