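"""Synthetic fixture generators: labeled sequence datasets with a tunable
class-composition signal, PSI-BLAST-style ASCII PSSM files, and random
property tables. Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import (
    ALPHABET,
    AA_INDEX,
    AAindexTable,
    LABEL_DSB,
    LABEL_SSB,
    LabeledDataset,
    NCBI_PSSM_ORDER,
    ProteinRecord,
    PSSMProfile,
)

#: Residues enriched in the DSB class (positively charged side chains).
DSB_BIAS_RESIDUES: tuple[str, ...] = ("R", "K", "H")
#: Residues enriched in the SSB class.
SSB_BIAS_RESIDUES: tuple[str, ...] = ("N", "G", "F", "Y", "V")


@dataclass
class GeneratorConfig:
    """Settings for the labeled-dataset generator.

    Class sizes default to the 873:183 imbalance of the reference training
    collection. ``delta`` is the total probability mass moved onto each
    class's biased residue set (split evenly across the set, then the whole
    distribution is renormalized). Default lengths span all three split
    cases (A/B/C).
    """

    n_dsb: int = 873
    n_ssb: int = 183
    len_min: int = 60
    len_max: int = 400
    delta: float = 0.0
    dsb_residues: tuple[str, ...] = DSB_BIAS_RESIDUES
    ssb_residues: tuple[str, ...] = SSB_BIAS_RESIDUES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dsb < 1 or self.n_ssb < 1:
            raise ValueError("both class sizes must be >= 1")
        if not (1 <= self.len_min <= self.len_max):
            raise ValueError("need 1 <= len_min <= len_max")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")

    def class_distribution(self, label: str) -> np.ndarray:
        """Residue sampling distribution for one class, canonical order."""
        probs = np.full(20, 1.0 / 20)
        biased = self.dsb_residues if label == LABEL_DSB else self.ssb_residues
        for aa in biased:
            probs[AA_INDEX[aa]] += self.delta / len(biased)
        if (probs < 0).any():
            raise ValueError("delta produced a negative residue probability")
        return probs / probs.sum()


def generate_dataset(config: GeneratorConfig) -> LabeledDataset:
    """Draw i.i.d. sequences residue-by-residue from class distributions."""
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(ALPHABET))
    records: list[ProteinRecord] = []
    labels: list[str] = []
    specs = [(LABEL_DSB, config.n_dsb, "dsb"), (LABEL_SSB, config.n_ssb, "ssb")]
    for label, count, prefix in specs:
        probs = config.class_distribution(label)
        for i in range(count):
            length = int(rng.integers(config.len_min, config.len_max + 1))
            seq = "".join(rng.choice(alphabet, size=length, p=probs))
            records.append(ProteinRecord(id=f"{prefix}{i:05d}", sequence=seq))
            labels.append(label)
    return LabeledDataset(records=records, labels=labels)


def generate_pssm_profile(
    record: ProteinRecord,
    noise_scale: float = 0.0,
    seed: int = 0,
    match_score: int = 7,
    mismatch_score: int = -2,
) -> PSSMProfile:
    """Identity-dominated profile: the column matching each residue scores
    high, all others low, plus rounded Gaussian noise."""
    rng = np.random.default_rng(seed)
    scores = np.full((record.length, 20), float(mismatch_score))
    for row, aa in enumerate(record.sequence):
        scores[row, AA_INDEX[aa]] = match_score
    if noise_scale > 0:
        scores += np.round(rng.normal(0.0, noise_scale, size=scores.shape))
    return PSSMProfile(id=record.id, scores=scores)


def write_pssm_file(
    profile: PSSMProfile, record: ProteinRecord, path: str | Path
) -> None:
    """Write a profile in the PSI-BLAST ``-out_ascii_pssm`` ASCII dialect.

    Columns are emitted in NCBI order with a duplicated 20-letter header
    (log-odds block then a synthetic percentage block) and trailing
    statistics lines, matching what :func:`ssbdsb.seqio.parse_pssm` accepts.
    """
    if profile.length != record.length:
        raise ValueError("profile/sequence length mismatch")
    perm = [ALPHABET.index(aa) for aa in NCBI_PSSM_ORDER]
    ncbi_scores = profile.scores[:, perm]
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted, "
            "synthetic profile\n"
        )
        letters = "   ".join(NCBI_PSSM_ORDER)
        fh.write(f"            {letters}   {letters}\n")
        for row in range(profile.length):
            logodds = " ".join(
                f"{int(round(v)):3d}" for v in ncbi_scores[row]
            )
            # Synthetic percentage block: uniform occupancy.
            percents = " ".join("  5" for _ in range(20))
            fh.write(
                f"{row + 1:5d} {record.sequence[row]}  {logodds}  {percents}"
                f"  0.36 0.08\n"
            )
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1347     0.3179\n")


def generate_pssm_files(
    dataset: LabeledDataset,
    out_dir: str | Path,
    noise_scale: float = 0.0,
    seed: int = 0,
) -> dict[str, Path]:
    """One ``<id>.pssm`` file per protein; returns id -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}
    for record in dataset.records:
        profile = generate_pssm_profile(
            record, noise_scale=noise_scale, seed=int(rng.integers(2**31 - 1))
        )
        path = out_dir / f"{record.id}.pssm"
        write_pssm_file(profile, record, path)
        paths[record.id] = path
    return paths


def generate_pssm_profiles(
    dataset: LabeledDataset, noise_scale: float = 0.0, seed: int = 0
) -> dict[str, PSSMProfile]:
    """In-memory profiles for every protein (same scheme as the file writer)."""
    rng = np.random.default_rng(seed)
    return {
        record.id: generate_pssm_profile(
            record, noise_scale=noise_scale, seed=int(rng.integers(2**31 - 1))
        )
        for record in dataset.records
    }


def generate_aaindex_table(n_properties: int, seed: int = 0) -> AAindexTable:
    """Random finite property table with ids ``SYN0001``, ``SYN0002``, ..."""
    if n_properties < 1:
        raise ValueError("n_properties must be >= 1")
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, 1.0, size=(n_properties, 20))
    ids = [f"SYN{i + 1:04d}" for i in range(n_properties)]
    return AAindexTable(
        property_ids=ids,
        values=values,
        descriptions=["synthetic property"] * n_properties,
    )
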