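"""Input/output and validation for sequences, labels, PSSM profiles and the
amino-acid property table.

All downstream code assumes the canonical residue ordering
:data:`ALPHABET` (alphabetical one-letter codes). Every matrix-like object
produced here (PSSM columns, property-table columns) is re-ordered to that
convention on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical ordering of the 20 standard amino acids (alphabetical).
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residue -> index in :data:`ALPHABET`.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

#: Column ordering used by NCBI PSI-BLAST ASCII PSSM files.
NCBI_PSSM_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

#: Class label strings.
LABEL_DSB = "DSB"
LABEL_SSB = "SSB"
VALID_LABELS = frozenset({LABEL_DSB, LABEL_SSB})


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its cleaned amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-standard residues {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Protein records paired one-to-one with binary class labels."""

    records: list[ProteinRecord]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise ValueError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        unknown = {l for l in self.labels} - VALID_LABELS
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def class_counts(self) -> dict[str, int]:
        counts = {LABEL_DSB: 0, LABEL_SSB: 0}
        for l in self.labels:
            counts[l] += 1
        return counts

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            records=[self.records[i] for i in indices],
            labels=[self.labels[i] for i in indices],
        )


@dataclass
class PSSMProfile:
    """Per-position substitution scores for one protein (L rows, 20 columns)."""

    id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"profile {self.id!r}: expected Lx20 matrix, got {self.scores.shape}"
            )
        if self.scores.shape[0] == 0:
            raise ValueError(f"profile {self.id!r}: zero rows")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class AAindexTable:
    """Numeric physicochemical properties, one row per accession.

    ``values[p, a]`` is property ``property_ids[p]`` for residue
    ``ALPHABET[a]``.
    """

    property_ids: list[str]
    values: np.ndarray
    descriptions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.property_ids), 20):
            raise ValueError(
                f"expected {(len(self.property_ids), 20)} value matrix, "
                f"got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            bad = [
                self.property_ids[i]
                for i in np.unique(np.nonzero(~np.isfinite(self.values))[0])
            ]
            raise ValueError(f"non-finite values for properties: {bad}")

    @property
    def n_properties(self) -> int:
        return len(self.property_ids)


#: The 28 default property accessions, in vendored-file order.
DEFAULT_AAINDEX_ACCESSIONS: tuple[str, ...] = (
    "CHOP780202", "GEIM800106", "PALJ810107", "ZIMJ680104",
    "CIDH920103", "KANM800102", "QIAN880123", "AURR980120",
    "CIDH920105", "KLEP840101", "RACS770103", "MUNV940103",
    "FAUJ880109", "KRIW710101", "RADA880108", "NADH010104",
    "FAUJ880111", "LIFS790101", "ROSM880102", "NADH010106",
    "FINA910104", "MEEJ800101", "SWER830101", "GUYH850105",
    "GEIM800104", "OOBM770102", "ZIMJ680102", "MIYS990104",
)

_NONSTANDARD = set("XBZUOJ*-.")


def clean_sequence(raw: str) -> str:
    """Uppercase ``raw`` and drop every non-standard character.

    Characters outside the 20 standard one-letter codes (X, B, Z, U, O, J,
    gap and stop symbols, whitespace, anything else) are removed. The number
    of removed characters is logged at WARNING level.

    Raises
    ------
    ValueError
        If ``raw`` is empty or nothing remains after cleaning.
    """
    if not raw:
        raise ValueError("empty sequence")
    upper = raw.upper()
    cleaned = "".join(c for c in upper if c in AA_INDEX)
    removed = len(upper) - len(cleaned)
    if removed:
        logger.warning("removed %d non-standard characters from sequence", removed)
    if not cleaned:
        raise ValueError("sequence empty after removing non-standard residues")
    return cleaned


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into cleaned :class:`ProteinRecord` objects.

    Record ids are the first whitespace-delimited token of each header.
    Sequences are passed through :func:`clean_sequence`.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        try:
            seq = clean_sequence(str(entry.seq))
        except ValueError as exc:
            raise FormatError(f"FASTA entry {entry.id!r}: {exc}") from exc
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrapping)."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def parse_pssm(
    path: str | Path, alphabet_order: str = ALPHABET
) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM file (``-out_ascii_pssm`` dialect).

    The first 20 numeric columns of each residue row (the log-odds block)
    are returned, with columns re-ordered from the file's header ordering to
    ``alphabet_order``. Trailing per-row statistics (information content,
    relative weight) are ignored.
    """
    path = Path(path)
    if sorted(alphabet_order) != sorted(ALPHABET):
        raise ValueError("alphabet_order must be a permutation of the 20 letters")

    file_order: str | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            # Column-header line: 40 single-letter tokens (log-odds block
            # then percentage block); take the first 20 as the file order.
            if file_order is None and all(
                len(t) == 1 and t in AA_INDEX for t in tokens
            ) and len(tokens) >= 20:
                file_order = "".join(tokens[:20])
                continue
            # Residue row: position, residue letter, then numeric fields.
            if (
                tokens[0].isdigit()
                and len(tokens) >= 2
                and len(tokens[1]) == 1
                and tokens[1].isalpha()
            ):
                numeric = tokens[2:]
                if not all(_is_number(t) for t in numeric):
                    continue  # trailing statistics lines (Lambda/K) etc.
                if len(numeric) < 40:
                    raise FormatError(
                        f"{path}:{lineno}: matrix row has {len(numeric)} numeric "
                        "fields, expected at least 40 (20 log-odds + 20 percentages)"
                    )
                rows.append([float(t) for t in numeric[:20]])
    if not rows:
        raise FormatError(f"{path}: no residue rows found in PSSM matrix block")
    if file_order is None:
        file_order = NCBI_PSSM_ORDER
    scores = np.asarray(rows, dtype=float)
    # Re-order columns from file order to the requested order.
    perm = [file_order.index(aa) for aa in alphabet_order]
    scores = scores[:, perm]
    return PSSMProfile(id=path.stem, scores=scores)


def load_aaindex_table(
    path: str | Path | None = None, strict: bool = True
) -> AAindexTable:
    """Load an amino-acid property table.

    With no ``path``, the vendored 28-property default table is loaded. With
    ``strict=True`` the accession set must equal the 28 defaults; with
    ``strict=False`` any non-empty accession set is accepted (e.g. small
    custom tables for testing).

    The file is tab-delimited: a header line naming the residue columns,
    then one line per property: accession, 20 values (in the header's
    residue order), optional free-text description.
    """
    if path is None:
        ref = resources.files("ssbdsb.data").joinpath("aaindex28.tsv")
        with resources.as_file(ref) as p:
            return load_aaindex_table(p, strict=strict)
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split("\t")
        header = [h.strip() for h in header]
        if len(header) < 21:
            raise FormatError(f"{path}: header must name 20 residue columns")
        residue_cols = header[1:21]
        if sorted(residue_cols) != sorted(ALPHABET):
            raise FormatError(
                f"{path}: residue columns are not the 20 standard letters"
            )
        perm = [residue_cols.index(aa) for aa in ALPHABET]
        ids: list[str] = []
        descriptions: list[str] = []
        values: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            if len(fields) < 21:
                raise FormatError(
                    f"{path}:{lineno}: expected accession + 20 values, "
                    f"got {len(fields)} fields"
                )
            ids.append(fields[0])
            try:
                row = [float(fields[1 + j]) for j in perm]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            values.append(row)
            descriptions.append(fields[21] if len(fields) > 21 else "")
    if not ids:
        raise FormatError(f"{path}: no property rows")
    if strict:
        missing = set(DEFAULT_AAINDEX_ACCESSIONS) - set(ids)
        extra = set(ids) - set(DEFAULT_AAINDEX_ACCESSIONS)
        if missing or extra:
            raise FormatError(
                f"{path}: accession set differs from the 28 defaults "
                f"(missing: {sorted(missing)}, unexpected: {sorted(extra)}); "
                "pass strict=False to allow a custom property set"
            )
    return AAindexTable(
        property_ids=ids, values=np.asarray(values), descriptions=descriptions
    )


def read_labels(
    path: str | Path, records: Sequence[ProteinRecord]
) -> LabeledDataset:
    """Read a two-column (id, label) table and pair it with ``records``.

    The delimiter may be tab or comma. Labels are case-insensitive DSB/SSB.
    Every record must have exactly one label and vice versa.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", "\t").split("\t")
            fields = [f.strip() for f in fields if f.strip()]
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected two columns (id, label)"
                )
            pid, label = fields
            label = label.upper()
            if label not in VALID_LABELS:
                raise FormatError(
                    f"{path}:{lineno}: unknown label {label!r} "
                    f"(expected one of {sorted(VALID_LABELS)})"
                )
            if pid in mapping:
                raise FormatError(f"{path}:{lineno}: duplicate id {pid!r}")
            mapping[pid] = label
    record_ids = [r.id for r in records]
    missing = [rid for rid in record_ids if rid not in mapping]
    extra = sorted(set(mapping) - set(record_ids))
    if missing or extra:
        raise FormatError(
            f"{path}: labels do not match records "
            f"(records without label: {missing[:10]}, "
            f"labels without record: {extra[:10]})"
        )
    return LabeledDataset(
        records=list(records), labels=[mapping[rid] for rid in record_ids]
    )


def write_labels(dataset: LabeledDataset, path: str | Path) -> None:
    """Write the (id, label) table for ``dataset`` as TSV."""
    with open(path, "w") as fh:
        for rec, label in zip(dataset.records, dataset.labels):
            fh.write(f"{rec.id}\t{label}\n")
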