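"""Amplicon filtering: six-frame translation, stop-codon exclusion,
reference-similarity screening, and equal-length trimming.

The screening step replaces a live protein-database homology search
with a local-alignment screen against a packaged reference protein set:
a query is kept iff its best local alignment to any reference reaches a
configurable identity over a configurable fraction of the query.
Defaults (identity >= 0.35 over >= 50% of the query) are deliberately
permissive, playing the role of a hit-existence criterion.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io import SequenceRecord, read_fasta, write_fasta

__all__ = [
    "TranslatedFrame",
    "ScreenResult",
    "six_frame_translate",
    "stop_codon_filter",
    "reference_screen",
    "screen_records",
    "align_identity",
    "trim_to_length",
]

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class TranslatedFrame:
    """One reading-frame translation of a nucleotide source sequence."""

    source_id: str
    frame: int
    aa_sequence: str

    @property
    def has_stop(self) -> bool:
        return "*" in self.aa_sequence


@dataclass(frozen=True)
class ScreenResult:
    source_id: str
    kept: bool
    best_reference_id: str | None
    identity: float
    aligned_length: int


def six_frame_translate(nt: str, source_id: str = "") -> list[TranslatedFrame]:
    """Translate a nucleotide sequence in all six frames (standard code).

    Frames +1..+3 read the plus strand at offsets 0..2; frames -1..-3
    read the reverse complement at offsets 0..2. Trailing partial codons
    are dropped.
    """
    nt = nt.upper()
    if len(nt) < 3:
        raise ValueError(f"{source_id or 'sequence'}: too short to translate ({len(nt)} nt)")
    bad = set(nt) - set("ACGT")
    if bad:
        raise ValueError(f"{source_id or 'sequence'}: non-ACGT characters {sorted(bad)}")
    rc = str(Seq(nt).reverse_complement())
    frames = []
    for frame in FRAMES:
        src = nt if frame > 0 else rc
        offset = abs(frame) - 1
        sub = src[offset:]
        sub = sub[: len(sub) - len(sub) % 3]
        frames.append(TranslatedFrame(source_id, frame, str(Seq(sub).translate())))
    return frames


def stop_codon_filter(frames: list[TranslatedFrame]) -> list[TranslatedFrame]:
    """Drop every frame containing a stop codon.

    An empty result means the source sequence is discarded outright
    (no stop-free reading frame exists).
    """
    return [f for f in frames if not f.has_stop]


def _protein_aligner(open_gap: float = -10.0, extend_gap: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def _alignment_identity_stats(alignment) -> tuple[float, int, int]:
    """(identity, aligned columns, aligned query residues) of one alignment.

    Identity is matching columns over alignment columns; local alignments
    carry no terminal gaps, so no further exclusion applies.
    """
    a, b = alignment[0], alignment[1]
    columns = len(a)
    if columns == 0:
        return 0.0, 0, 0
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    query_res = sum(1 for y in b if y != "-")
    return matches / columns, columns, query_res


def align_identity(seq_a: str, seq_b: str, alphabet: str = "aa") -> float:
    """Global-alignment identity, terminal gaps excluded from the denominator."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "aa":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -1.0
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    else:
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -2.0
        aligner.extend_gap_score = -1.0
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    alignment = aligner.align(seq_a, seq_b)[0]
    a, b = alignment[0], alignment[1]
    # strip terminal gap columns
    lo = 0
    hi = len(a)
    while lo < hi and (a[lo] == "-" or b[lo] == "-"):
        lo += 1
    while hi > lo and (a[hi - 1] == "-" or b[hi - 1] == "-"):
        hi -= 1
    if hi == lo:
        return 0.0
    matches = sum(1 for x, y in zip(a[lo:hi], b[lo:hi]) if x == y and x != "-")
    return matches / (hi - lo)


def reference_screen(
    aa_sequence: str,
    reference: list[SequenceRecord],
    min_identity: float = 0.35,
    min_coverage: float = 0.5,
    source_id: str = "",
) -> ScreenResult:
    """Screen one protein query against the reference set.

    Kept iff the best local alignment reaches ``min_identity`` over an
    alignment covering at least ``min_coverage`` of the query residues.
    """
    if not aa_sequence:
        raise ValueError("empty query sequence")
    if not reference:
        raise ValueError("empty reference set")
    aligner = _protein_aligner()
    best = (0.0, 0, None)  # identity, columns, ref id — best by identity among covering hits
    best_any = (0.0, 0, None)
    for ref in reference:
        alignments = aligner.align(ref.sequence, aa_sequence)
        if len(alignments) == 0:
            continue
        identity, columns, query_res = _alignment_identity_stats(alignments[0])
        covered = query_res / len(aa_sequence) >= min_coverage
        if identity > best_any[0]:
            best_any = (identity, columns, ref.id)
        if covered and identity > best[0]:
            best = (identity, columns, ref.id)
    identity, columns, ref_id = best if best[2] is not None else best_any
    kept = best[2] is not None and identity >= min_identity
    return ScreenResult(source_id, kept, ref_id, identity, columns)


def screen_records(
    queries: list[SequenceRecord],
    reference: list[SequenceRecord],
    min_identity: float = 0.35,
    min_coverage: float = 0.5,
) -> list[ScreenResult]:
    return [
        reference_screen(q.sequence, reference, min_identity, min_coverage, q.id)
        for q in queries
    ]


def _mafft_align(records: list[SequenceRecord], alphabet: str) -> list[SequenceRecord]:
    """Multiple alignment via the mafft CLI (auto strategy)."""
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH; cannot align unequal-length sequences")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fasta"
        write_fasta(records, inp)
        args = ["mafft", "--auto", "--quiet"]
        if alphabet == "aa":
            args.append("--amino")
        proc = subprocess.run(
            args + [str(inp)], capture_output=True, text=True, check=True
        )
        out = Path(tmp) / "out.fasta"
        out.write_text(proc.stdout)
        aligned = read_fasta(out)
    by_id = {r.id: r for r in records}
    return [
        SequenceRecord(r.id, r.sequence.upper(), by_id[r.id].sample_id, by_id[r.id].description)
        for r in aligned
    ]


def trim_to_length(
    records: list[SequenceRecord],
    target_len: int,
    alphabet: str = "aa",
) -> list[SequenceRecord]:
    """Trim sequences to a common length through a multiple alignment.

    The records are aligned (mafft; skipped when already equal-length
    and ungapped, in which case the alignment is the identity), and a
    contiguous window of ``target_len`` alignment columns is chosen to
    maximize the number of sequences with a full complement of residues
    (no gaps) inside it, ties broken leftmost. Sequences with fewer than
    ``target_len`` residues in the window are excluded; survivors are
    returned gap-free at exactly ``target_len``.
    """
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    if not records:
        raise ValueError("no sequences to trim")
    lengths = {len(r) for r in records}
    if lengths == {target_len}:
        return list(records)
    if len(lengths) == 1 and not any("-" in r.sequence for r in records):
        aligned = records
    else:
        aligned = _mafft_align(records, alphabet)
    width = len(aligned[0].sequence)
    if width < target_len:
        raise ValueError(
            f"alignment width {width} shorter than target {target_len}; 0/{len(records)} survive"
        )
    # prefix sums of gap counts per sequence for O(1) window queries
    import numpy as np

    gap = np.array(
        [[1 if c == "-" else 0 for c in r.sequence] for r in aligned], dtype=np.int32
    )
    cum = np.concatenate([np.zeros((gap.shape[0], 1), dtype=np.int32), gap.cumsum(axis=1)], axis=1)
    n_windows = width - target_len + 1
    survivors_per_window = [
        int(((cum[:, s + target_len] - cum[:, s]) == 0).sum()) for s in range(n_windows)
    ]
    best = max(range(n_windows), key=lambda s: (survivors_per_window[s], -s))
    if survivors_per_window[best] == 0:
        raise ValueError(
            f"no sequence survives trimming to {target_len}: 0/{len(records)} kept"
        )
    out = []
    for i, r in enumerate(aligned):
        if cum[i, best + target_len] - cum[i, best] == 0:
            out.append(
                SequenceRecord(
                    r.id,
                    r.sequence[best: best + target_len],
                    r.sample_id,
                    r.description,
                )
            )
    return out
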