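"""Phylotype clustering and occurrence summaries.

Reads are dereplicated, ordered by multiplicity (ties broken
lexicographically) and clustered by abundance-ordered greedy centroid
clustering: each unique sequence joins the first existing centroid whose
pairwise identity reaches the threshold, otherwise it founds a new
centroid. Identity is matching columns over alignment columns with
terminal gaps excluded; for equal-length inputs (the usual case after
equal-length trimming) this reduces to one minus the Hamming fraction
and is computed vectorized.

Phylotype occurrence across sample types (e.g. wild/reared hosts) is
summarized by set algebra: per-type phylotype counts, pairwise
intersections, type-specific counts and the reared-only tally.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filtering import align_identity
from .io import SequenceRecord

__all__ = [
    "PhylotypeTable",
    "dereplicate",
    "greedy_cluster",
    "cluster_records",
    "select_representatives",
    "build_occurrence",
    "overlap_summary",
]

_BASE_CODE = {c: i for i, c in enumerate("ACGTUMRWSYKVHDBN-*X")}


@dataclass
class Cluster:
    centroid: str
    members: list[tuple[str, int]] = field(default_factory=list)  # (sequence, multiplicity)

    @property
    def size(self) -> int:
        return sum(m for _, m in self.members)


@dataclass
class PhylotypeTable:
    """Samples x phylotypes count matrix with cluster bookkeeping."""

    counts: pd.DataFrame  # rows: samples, columns: phylotype ids
    representatives: dict[str, str]
    threshold: float
    alphabet: str
    clusters: dict[str, Cluster] = field(default_factory=dict)
    singleton_only: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts in phylotype table")
        if (self.counts.sum(axis=0) < 1).any():
            empty = self.counts.columns[self.counts.sum(axis=0) < 1].tolist()
            raise ValueError(f"phylotypes with zero total count: {empty}")

    @property
    def n_reads(self) -> int:
        return int(self.counts.values.sum())

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)

    def drop_singleton_phylotypes(self) -> "PhylotypeTable":
        """Stricter reading of the representative rule: discard phylotypes
        whose every member is a singleton."""
        keep = [p for p in self.counts.columns if p not in self.singleton_only]
        return PhylotypeTable(
            self.counts[keep].loc[self.counts[keep].sum(axis=1) > 0],
            {p: s for p, s in self.representatives.items() if p in keep},
            self.threshold,
            self.alphabet,
            {p: c for p, c in self.clusters.items() if p in keep},
            set(),
        )


def dereplicate(seqs: list[str]) -> list[tuple[str, int]]:
    """Unique sequences with multiplicities, multiplicity-descending order.

    Ties are broken by lexicographic sequence so downstream clustering is
    invariant to input read order. Mixed lengths are rejected (inputs are
    expected to be equal-length after trimming).
    """
    if not seqs:
        return []
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("dereplicate requires equal-length sequences")
    counts = Counter(seqs)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def _encode(seqs: list[str]) -> np.ndarray:
    return np.array(
        [[_BASE_CODE.get(c, len(_BASE_CODE)) for c in s] for s in seqs], dtype=np.uint8
    )


def greedy_cluster(
    uniques: list[tuple[str, int]],
    threshold: float,
    alphabet: str = "nt",
) -> list[Cluster]:
    """Abundance-ordered greedy centroid clustering of dereplicated input.

    ``uniques`` must already be in the declared order (multiplicity
    descending, ties lexicographic); each sequence recruits to the first
    centroid with identity >= ``threshold``, else becomes a new centroid.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    clusters: list[Cluster] = []
    if not uniques:
        return clusters
    equal_len = len({len(s) for s, _ in uniques}) == 1
    if equal_len:
        L = len(uniques[0][0])
        max_mm = int(np.floor((1.0 - threshold) * L + 1e-9))
        enc = _encode([s for s, _ in uniques])
        centroid_rows: list[np.ndarray] = []
        for i, (seq, mult) in enumerate(uniques):
            assigned = None
            if centroid_rows:
                mm = (np.vstack(centroid_rows) != enc[i]).sum(axis=1)
                hits = np.nonzero(mm <= max_mm)[0]
                if hits.size:
                    assigned = int(hits[0])
            if assigned is None:
                centroid_rows.append(enc[i])
                clusters.append(Cluster(seq, [(seq, mult)]))
            else:
                clusters[assigned].members.append((seq, mult))
    else:
        for seq, mult in uniques:
            assigned = None
            for c in clusters:
                if align_identity(c.centroid, seq, alphabet) >= threshold:
                    assigned = c
                    break
            if assigned is None:
                clusters.append(Cluster(seq, [(seq, mult)]))
            else:
                assigned.members.append((seq, mult))
    return clusters


def cluster_records(
    records: list[SequenceRecord],
    threshold: float,
    alphabet: str = "nt",
    id_prefix: str = "PT",
) -> PhylotypeTable:
    """Cluster reads from all samples jointly into a phylotype table.

    Dereplication pools reads across samples (cluster geometry must not
    depend on sample boundaries); per-sample counts are then tabulated
    from read provenance. Total table counts equal the number of input
    reads.
    """
    if not records:
        raise ValueError("no records to cluster")
    uniques = dereplicate([r.sequence for r in records])
    clusters = greedy_cluster(uniques, threshold, alphabet)
    seq_to_pt: dict[str, str] = {}
    ids = []
    for k, cl in enumerate(clusters):
        pid = f"{id_prefix}{k + 1:04d}"
        ids.append(pid)
        for seq, _ in cl.members:
            seq_to_pt[seq] = pid
    samples = sorted({r.sample_id for r in records})
    counts = pd.DataFrame(0, index=samples, columns=ids, dtype=int)
    for r in records:
        counts.loc[r.sample_id, seq_to_pt[r.sequence]] += 1
    cluster_map = {pid: cl for pid, cl in zip(ids, clusters)}
    table = PhylotypeTable(
        counts,
        {pid: cl.centroid for pid, cl in cluster_map.items()},
        threshold,
        alphabet,
        cluster_map,
    )
    select_representatives(table)
    return table


def select_representatives(
    table: PhylotypeTable, min_multiplicity: int = 2
) -> dict[str, tuple[str, bool]]:
    """Choose per-phylotype representatives from reads seen at least
    ``min_multiplicity`` times.

    A phylotype whose most-abundant member reaches the multiplicity bar
    gets that member (ties broken by lexicographically smaller sequence);
    phylotypes containing only rarer reads are retained but flagged
    ``singleton_only``. Updates the table in place and returns
    phylotype -> (representative, singleton_only).
    """
    out: dict[str, tuple[str, bool]] = {}
    table.singleton_only = set()
    for pid, cl in table.clusters.items():
        best_seq, best_mult = min(cl.members, key=lambda kv: (-kv[1], kv[0]))
        singleton = best_mult < min_multiplicity
        if singleton:
            table.singleton_only.add(pid)
        table.representatives[pid] = best_seq
        out[pid] = (best_seq, singleton)
    return out


def build_occurrence(
    table: PhylotypeTable, sample_types: dict[str, str]
) -> dict[str, frozenset[str]]:
    """Phylotype -> set of sample types in which it was observed."""
    unmapped = set(table.counts.index) - set(sample_types)
    if unmapped:
        raise ValueError(f"samples without a type mapping: {sorted(unmapped)}")
    occurrence: dict[str, frozenset[str]] = {}
    for pid in table.counts.columns:
        present = table.counts.index[table.counts[pid] > 0]
        types = frozenset(sample_types[s] for s in present)
        if not types:
            raise ValueError(f"phylotype {pid} has no occurrences")
        occurrence[pid] = types
    return occurrence


def overlap_summary(
    occurrence: dict[str, frozenset[str]],
    labels: tuple[str, ...] = ("SH-W", "SH-R", "SS-W", "SS-R"),
    reared_labels: tuple[str, ...] = ("SH-R", "SS-R"),
) -> dict[str, int]:
    """Set-algebra summary of an occurrence matrix.

    Returns per-type phylotype counts, all pairwise intersection counts,
    per-type specific counts (origin exactly one type), the reared-only
    tally (origin within the reared labels) and the total.
    """
    for pid, origins in occurrence.items():
        if not origins:
            raise ValueError(f"phylotype {pid}: empty origin set")
        unknown = origins - set(labels)
        if unknown:
            raise ValueError(f"phylotype {pid}: unknown origins {sorted(unknown)}")
    summary: dict[str, int] = {"total": len(occurrence)}
    for lab in labels:
        summary[lab] = sum(1 for o in occurrence.values() if lab in o)
        summary[f"{lab} only"] = sum(1 for o in occurrence.values() if o == {lab})
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            summary[f"{a} & {b}"] = sum(
                1 for o in occurrence.values() if a in o and b in o
            )
    reared = set(reared_labels)
    summary["reared only"] = sum(1 for o in occurrence.values() if o <= reared)
    return summary
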