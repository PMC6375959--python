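"""Replicate-level recovery checks of the synthetic feeding experiment.

Runs the full 16S branch on one simulated study and measures how well
the pipeline recovers the planted ground truth: which enriched
"degrader" taxa are flagged, whether reared richness drops below wild
richness, and whether reared individuals are more similar to each other
(weighted UniFrac) than wild individuals are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import PipelineConfig, run_16s
from .synthetic import StudyData, simulate_study

__all__ = ["ReplicateResult", "match_phylotypes_to_taxa", "run_replicate"]


@dataclass(frozen=True)
class ReplicateResult:
    seed: int
    n_enriched: int
    n_enriched_detected: int
    n_phylotypes: int
    chao1_wild_median: float
    chao1_reared_median: float
    unifrac_ww_median: float
    unifrac_rr_median: float
    rr_vs_ww_p: float

    @property
    def richness_dropped(self) -> bool:
        return self.chao1_reared_median < self.chao1_wild_median

    @property
    def reared_converged(self) -> bool:
        return (
            self.unifrac_rr_median < self.unifrac_ww_median and self.rr_vs_ww_p < 0.05
        )


def match_phylotypes_to_taxa(
    representatives: dict[str, str], genomes, min_identity: float = 0.97
) -> dict[str, str]:
    """Map each planted taxon to the phylotype whose representative is
    closest to its (equally trimmed) marker, if close enough."""
    out: dict[str, str] = {}
    for genome in genomes:
        best_pid, best_ident = None, 0.0
        for pid, rep in representatives.items():
            marker = genome.marker_16s[: len(rep)]
            if len(marker) != len(rep):
                continue
            ident = sum(a == b for a, b in zip(marker, rep)) / len(rep)
            if ident > best_ident:
                best_pid, best_ident = pid, ident
        if best_pid is not None and best_ident >= min_identity:
            out[genome.taxon_id] = best_pid
    return out


def run_replicate(seed: int, config: PipelineConfig | None = None, **study_kwargs) -> ReplicateResult:
    """Simulate one study and measure pipeline recovery of its truth."""
    study: StudyData = simulate_study(seed=seed, **study_kwargs)
    reads = [r for s in study.samples for r in s.records]
    groups = dict(zip(study.metadata.sample_id, study.metadata.group_label))
    cfg = config or PipelineConfig(seed=seed)
    result = run_16s(reads, groups, cfg, rarefy_depth=0)
    diff = result["differential"]
    taxon_to_pt = match_phylotypes_to_taxa(
        result["table"].representatives, study.genomes, cfg.identity_16s
    )
    detected = sum(
        1
        for t in study.enriched_taxa
        if t in taxon_to_pt and diff.loc[taxon_to_pt[t], "label"] == "enriched"
    )
    chao1 = {d.sample_id: d.chao1 for d in result["diversity"]}
    group_a, group_b = result["groups"]
    wild = [chao1[s] for s, g in groups.items() if g == group_a]
    reared = [chao1[s] for s, g in groups.items() if g == group_b]
    gd = result["groupdist_weighted"]
    return ReplicateResult(
        seed=seed,
        n_enriched=len(study.enriched_taxa),
        n_enriched_detected=detected,
        n_phylotypes=result["table"].counts.shape[1],
        chao1_wild_median=float(np.median(wild)),
        chao1_reared_median=float(np.median(reared)),
        unifrac_ww_median=float(np.median(gd["distances"]["within_a"])),
        unifrac_rr_median=float(np.median(gd["distances"]["within_b"])),
        rr_vs_ww_p=gd["tests"]["within_a_vs_within_b"].p_value,
    )
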