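"""Pipeline driver: configuration and the stage graph gluing all steps.

The 16S branch mirrors an amplicon survey: reads -> equal-length trim
(280 nt) -> 97% phylotype clustering -> rarefied diversity indices,
per-phylotype differential tests, NJ tree, UniFrac distances, PCoA and
group-distance comparisons. The ALG branch mirrors a clone library:
in-silico PCR with the degenerate primer pool and 300-650 bp size
selection -> six-frame translation -> stop-codon filter -> reference
similarity screen -> 95 aa trim -> 90% amino-acid clustering ->
occurrence/overlap summaries.

Every stage writes plain-text outputs (TSV, FASTA, newick) under a run
directory together with a JSON manifest of the configuration and seeds,
so any stage can be re-run from intermediates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import differential_phylotypes, diversity_profile, rarefy_table
from .filtering import (
    screen_records,
    six_frame_translate,
    stop_codon_filter,
    trim_to_length,
)
from .io import (
    SequenceRecord,
    packaged_reference_path,
    read_fasta,
    read_metadata,
    write_fasta,
)
from .ordination import (
    group_distance_comparison,
    nj_tree,
    pairwise_distance,
    pcoa,
    unifrac_matrix,
)
from .pcr import amplify, load_primers, packaged_primers
from .phylotypes import PhylotypeTable, build_occurrence, cluster_records, overlap_summary

__all__ = ["PipelineConfig", "run_16s", "run_alg", "run_pipeline", "midpoint_root"]


@dataclass
class PipelineConfig:
    """All analysis constants, with the study's defaults."""

    seed: int = 0
    primer_file: str | None = None  # None -> packaged printed primers
    size_window: tuple[int, int] = (300, 650)
    max_mismatch: int = 0
    identity_16s: float = 0.97
    identity_alg: float = 0.90
    trim_len_16s: int = 280
    trim_len_alg: int = 95
    rarefaction_depth: int = 4000
    alpha: float = 0.05
    screen_min_identity: float = 0.35
    screen_min_coverage: float = 0.5
    drop_singleton_phylotypes: bool = False
    raw_weighted_unifrac: bool = False
    bh_correction: bool = False

    def __post_init__(self) -> None:
        for thr in (self.identity_16s, self.identity_alg):
            if not 0 < thr <= 1:
                raise ValueError(f"identity threshold {thr} outside (0, 1]")
        lo, hi = self.size_window
        if lo >= hi:
            raise ValueError(f"size window min {lo} >= max {hi}")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction depth must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "size_window" in raw:
            raw["size_window"] = tuple(raw["size_window"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size_window"] = list(d["size_window"])
        return d


def midpoint_root(tree):
    """Midpoint-root a tree for UniFrac traversal; no-op when impossible."""
    try:
        return tree.root_at_midpoint()
    except Exception:
        return tree


def _tree_from_representatives(reps: dict[str, str]):
    """NJ tree over phylotype representatives (p-distance)."""
    records = [SequenceRecord(pid, seq) for pid, seq in sorted(reps.items())]
    dist = pairwise_distance(records)
    return midpoint_root(nj_tree(dist))


def run_16s(
    records: list[SequenceRecord],
    groups: dict[str, str],
    config: PipelineConfig | None = None,
    group_a: str | None = None,
    group_b: str | None = None,
    rarefy_depth: int | None = None,
) -> dict:
    """16S branch on pooled per-sample reads.

    ``group_a``/``group_b`` default to the two labels present (wild
    first). ``rarefy_depth`` overrides the configured rarefaction depth;
    pass 0 to skip rarefaction.
    """
    config = config or PipelineConfig()
    trimmed = trim_to_length(records, config.trim_len_16s, alphabet="nt")
    table = cluster_records(trimmed, config.identity_16s, "nt")
    if config.drop_singleton_phylotypes:
        table = table.drop_singleton_phylotypes()
    labels = sorted(set(groups.values()))
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise ValueError(f"expected 2 group labels, found {labels}")
        wild = [g for g in labels if g.endswith("-W") or g.lower().startswith("wild")]
        group_a = wild[0] if wild else labels[0]
        group_b = next(g for g in labels if g != group_a)
    depth = config.rarefaction_depth if rarefy_depth is None else rarefy_depth
    counts = table.counts
    if depth:
        counts = rarefy_table(counts, depth, config.seed)
    diversity = diversity_profile(counts)
    diff = differential_phylotypes(
        table, groups, group_a, group_b, config.alpha, config.bh_correction
    )
    tree = _tree_from_representatives(table.representatives)
    uw = unifrac_matrix(tree, counts if depth else table.counts, "unweighted")
    ww = unifrac_matrix(
        tree,
        counts if depth else table.counts,
        "weighted",
        normalized=not config.raw_weighted_unifrac,
    )
    result = {
        "table": table,
        "rarefied_counts": counts,
        "diversity": diversity,
        "differential": diff,
        "tree": tree,
        "unweighted_unifrac": uw,
        "weighted_unifrac": ww,
        "pcoa_unweighted": pcoa(uw),
        "pcoa_weighted": pcoa(ww),
        "groupdist_unweighted": group_distance_comparison(
            uw, groups, group_a, group_b, config.alpha
        ),
        "groupdist_weighted": group_distance_comparison(
            ww, groups, group_a, group_b, config.alpha
        ),
        "groups": (group_a, group_b),
    }
    return result


def run_alg(
    records: list[SequenceRecord],
    groups: dict[str, str],
    config: PipelineConfig | None = None,
    reference: list[SequenceRecord] | None = None,
) -> dict:
    """ALG clone-library branch on pooled per-sample template sequences.

    Amplifies with the degenerate primer pool, size-selects, translates
    in six frames, drops frames with stop codons, screens the surviving
    frames against the reference protein set, trims survivors to a
    common 95 aa window and clusters at 90% amino-acid identity.
    """
    config = config or PipelineConfig()
    primers = (
        load_primers(config.primer_file)
        if config.primer_file
        else list(packaged_primers().values())
    )
    forwards = [p for p in primers if p.orientation == "forward" and p.name.startswith("ALG")]
    reverses = [p for p in primers if p.orientation == "reverse" and p.name.startswith("ALG")]
    if not forwards or not reverses:
        raise ValueError("primer set lacks ALG forward/reverse primers")
    reference = reference or read_fasta(packaged_reference_path())
    n_amplicons = 0
    kept_frames: list[SequenceRecord] = []
    screen_stats = []
    for rec in records:
        amps = amplify(
            rec.sequence,
            forwards,
            reverses,
            config.max_mismatch,
            config.size_window,
            template_id=rec.id,
        )
        for a_idx, amp in enumerate(amps):
            n_amplicons += 1
            frames = stop_codon_filter(
                six_frame_translate(amp.sequence, f"{rec.id}.amp{a_idx}")
            )
            for f in frames:
                kept_frames.append(
                    SequenceRecord(
                        f"{f.source_id}.f{f.frame:+d}", f.aa_sequence, rec.sample_id
                    )
                )
    screened = screen_records(
        kept_frames, reference, config.screen_min_identity, config.screen_min_coverage
    )
    screen_stats = pd.DataFrame(
        [(s.source_id, s.kept, s.best_reference_id, s.identity, s.aligned_length) for s in screened],
        columns=["source_id", "kept", "best_reference_id", "identity", "aligned_length"],
    )
    survivors = [r for r, s in zip(kept_frames, screened) if s.kept]
    if not survivors:
        raise ValueError("no amplicon frame survives the reference screen")
    trimmed = trim_to_length(survivors, config.trim_len_alg, alphabet="aa")
    table = cluster_records(trimmed, config.identity_alg, "aa")
    if config.drop_singleton_phylotypes:
        table = table.drop_singleton_phylotypes()
    occurrence = build_occurrence(table, groups)
    labels = tuple(sorted(set(groups.values())))
    reared = tuple(g for g in labels if g.endswith("-R"))
    summary = overlap_summary(occurrence, labels, reared or labels)
    return {
        "n_templates": len(records),
        "n_amplicons": n_amplicons,
        "n_stop_free_frames": len(kept_frames),
        "n_screened_in": len(survivors),
        "screen_report": screen_stats,
        "table": table,
        "occurrence": occurrence,
        "overlap": summary,
    }


def _write_table(table: PhylotypeTable, outdir: Path, prefix: str) -> None:
    table.counts.to_csv(outdir / f"{prefix}_phylotype_table.tsv", sep="\t")
    write_fasta(
        [SequenceRecord(pid, seq) for pid, seq in sorted(table.representatives.items())],
        outdir / f"{prefix}_representatives.fasta",
    )


def run_pipeline(
    config: PipelineConfig,
    fasta_by_sample: dict[str, str | Path],
    metadata_path: str | Path,
    outdir: str | Path,
    mode: str = "16s",
) -> dict:
    """End-to-end run from per-sample FASTA files to a result directory."""
    outdir = Path(outdir)
    meta_path = Path(metadata_path)
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata file not found: {meta_path}")
    meta = read_metadata(meta_path)
    groups = dict(zip(meta["sample_id"], meta["group_label"]))
    missing = set(fasta_by_sample) - set(groups)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    outdir.mkdir(parents=True, exist_ok=True)
    records: list[SequenceRecord] = []
    for sid in sorted(fasta_by_sample):
        records.extend(read_fasta(fasta_by_sample[sid], sample_id=sid))

    if mode == "16s":
        result = run_16s(records, groups, config)
        _write_table(result["table"], outdir, "16s")
        pd.DataFrame(
            [
                (d.sample_id, d.s_obs, d.f1, d.f2, d.chao1, d.shannon)
                for d in result["diversity"]
            ],
            columns=["sample_id", "s_obs", "f1", "f2", "chao1", "shannon"],
        ).to_csv(outdir / "16s_diversity.tsv", sep="\t", index=False)
        result["differential"].to_csv(outdir / "16s_differential.tsv", sep="\t")
        result["tree"].write(str(outdir / "16s_tree.nwk"))
        result["unweighted_unifrac"].to_frame().to_csv(
            outdir / "16s_unweighted_unifrac.tsv", sep="\t"
        )
        result["weighted_unifrac"].to_frame().to_csv(
            outdir / "16s_weighted_unifrac.tsv", sep="\t"
        )
        ordi = result["pcoa_unweighted"]
        pd.DataFrame(
            ordi.coordinates,
            index=ordi.labels,
            columns=[f"axis{k + 1}" for k in range(ordi.coordinates.shape[1])],
        ).to_csv(outdir / "16s_pcoa_unweighted.tsv", sep="\t")
        stage_counts = {
            "reads": len(records),
            "phylotypes": int(result["table"].counts.shape[1]),
        }
    elif mode == "alg":
        result = run_alg(records, groups, config)
        _write_table(result["table"], outdir, "alg")
        result["screen_report"].to_csv(outdir / "alg_screen_report.tsv", sep="\t", index=False)
        occ = pd.DataFrame(
            [(pid, ",".join(sorted(o))) for pid, o in sorted(result["occurrence"].items())],
            columns=["phylotype_id", "origins"],
        )
        occ.to_csv(outdir / "alg_occurrence.tsv", sep="\t", index=False)
        pd.Series(result["overlap"]).to_csv(
            outdir / "alg_overlap_summary.tsv", sep="\t", header=False
        )
        stage_counts = {
            "templates": result["n_templates"],
            "amplicons": result["n_amplicons"],
            "stop_free_frames": result["n_stop_free_frames"],
            "screened_in": result["n_screened_in"],
            "phylotypes": int(result["table"].counts.shape[1]),
        }
    else:
        raise ValueError(f"unknown mode {mode!r}")

    manifest = {
        "version": __version__,
        "mode": mode,
        "config": config.to_dict(),
        "samples": {s: str(p) for s, p in sorted(fasta_by_sample.items())},
        "metadata": str(meta_path),
        "stage_counts": stage_counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    result["manifest"] = manifest
    return result
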