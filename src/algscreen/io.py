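"""Standard-format I/O: FASTA records, metadata TSV, occurrence fixture.

FASTA reading/writing is delegated to biopython; sequences are
uppercased on read and wrapped at 70 columns on write, so a write/read
round trip preserves ids, descriptions and sequences exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "load_occurrence_fixture",
    "packaged_occurrence_path",
    "packaged_reference_path",
]

VALID_ORIGINS = ("SH-W", "SH-R", "SS-W", "SS-R")


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide or amino-acid sequence with sample provenance."""

    id: str
    sequence: str
    sample_id: str = ""
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, sample_id: str = "") -> list[SequenceRecord]:
    """Read a FASTA file into records; uppercases sequences, rejects duplicates."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(rec.id, str(rec.seq).upper(), sample_id, desc)
        )
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    """Write records as plain FASTA wrapped at 70 columns."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(seqs)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV with at least sample_id and group_label columns."""
    meta = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"sample_id", "group_label"} - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


@dataclass
class OccurrenceFixtureRow:
    phylotype_no: int
    origins: frozenset[str]
    closest_hit: str = ""
    pct_identity: float | None = None


def load_occurrence_fixture(
    path: str | Path, valid_origins: tuple[str, ...] = VALID_ORIGINS
) -> dict[str, frozenset[str]]:
    """Load a phylotype -> origin-set table (the published-table abstraction).

    Returns a mapping of phylotype id (as string) to its frozen origin
    set; unknown origin tokens are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"phylotype_no", "origins"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["phylotype_no"].duplicated().any():
        raise ValueError(f"{path}: duplicate phylotype numbers")
    occurrence: dict[str, frozenset[str]] = {}
    for _, row in df.iterrows():
        tokens = [t.strip() for t in str(row["origins"]).split(",") if t.strip()]
        if not tokens:
            raise ValueError(f"{path}: phylotype {row['phylotype_no']}: empty origin set")
        for t in tokens:
            if t not in valid_origins:
                raise ValueError(
                    f"{path}: phylotype {row['phylotype_no']}: unknown origin token {t!r}"
                )
        occurrence[str(row["phylotype_no"])] = frozenset(tokens)
    return occurrence


def packaged_occurrence_path() -> Path:
    """The packaged 50-phylotype occurrence fixture."""
    return Path(__file__).parent / "data" / "table2_occurrence.tsv"


def packaged_reference_path() -> Path:
    """The packaged synthetic PL7-like protein reference set."""
    return Path(__file__).parent / "data" / "pl7_reference_synthetic.faa"
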