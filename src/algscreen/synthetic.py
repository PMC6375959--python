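"""Synthetic gut-metagenome generator.

Emulates the statistical structure the analysis pipeline assumes for a
controlled feeding experiment on algivorous gastropods:

* a **wild** community template with high taxon richness, log-normal
  rank abundances, and per-individual dispersion (wild animals forage on
  mixed algae, so individuals vary more);
* a **reared** community derived from the same template by multiplying a
  planted set of "degrader" taxa by an enrichment factor and everything
  else by a depletion factor, removing taxa that fall below an
  extinction floor (the richness drop), with smaller per-individual
  dispersion (a single controlled diet converges the microbiota);
* per-taxon marker genes: a 16S-like marker (~310 nt, V1-V2-like, primer
  cores at both ends) and zero or more alginate-lyase-like genes whose
  amplifiable region is framed by the conserved A3/A4 strand motifs the
  degenerate primers target, separated by a variable core of
  controllable length;
* reads drawn multinomially from community abundances with
  substitution-only sequencing error (no fragmentation, no quality
  scores, no homopolymer model).

Every stochastic operation takes an explicit seed; fixed seed implies
bit-identical output. Abundance vectors are always normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SequenceRecord, read_fasta, packaged_reference_path
from .pcr import _CODON_TABLE  # standard codon table, aa -> codons

__all__ = [
    "CommunitySpec",
    "TaxonGenome",
    "SampleReads",
    "A3_MOTIF_NT",
    "A4_MOTIF_NT",
    "sample_community",
    "apply_rearing_shift",
    "jitter_community",
    "evolve_marker_genes",
    "generate_reads",
    "make_reference_proteins",
    "simulate_study",
    "StudyData",
]

# Nucleotide realizations of the conserved primer-anchor strands, chosen
# inside the degenerate primer pools so a zero-mismatch forward/reverse
# site frames every planted amplicon.
#   A3 head codons: Y A R S E L R E  (matches ALG-f1 exactly)
A3_MOTIF_NT = "TACGCCCGTTCCGAACTGCGTGAA"
#   A4 tail codons: Y F K A G S Y   (matches the ALG-r site exactly)
A4_MOTIF_NT = "TACTTCAAAGCTGGTAGCTAC"
A3_MOTIF_AA = "YARSELRE"
A4_MOTIF_AA = "YFKAGSY"

# 16S V1-V2-like anchor cores: one concrete expansion of M27F and of the
# reverse complement of M338R.
_M27F_SITE = "AGAGTTTGATCATGGCTCAG"
_M338R_RC_SITE = "ACTTCTACGGAAGGCAGCAG"

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = sorted(
    c for aa, cs in _CODON_TABLE.items() if aa != "*" for c in cs
)
# residues available for random protein cores (no C/W to keep cores generic)
_CORE_AA = "ADEFGHIKLMNPQRSTVY"


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of one community draw."""

    n_taxa: int
    mu: float = 0.0
    sigma: float = 1.5
    enriched_taxa: frozenset[str] = frozenset()
    depletion_factor: float = 0.3
    enrichment_factor: float = 5.0
    extinction_floor: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if not 0 <= self.depletion_factor <= 1:
            raise ValueError("depletion_factor must be in [0, 1]")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")

    @property
    def taxa(self) -> list[str]:
        return [f"T{i + 1:03d}" for i in range(self.n_taxa)]


@dataclass(frozen=True)
class TaxonGenome:
    """Marker genes of one taxon."""

    taxon_id: str
    marker_16s: str
    alg_genes: tuple[str, ...] = ()


@dataclass
class SampleReads:
    """Reads of one sample with its group label."""

    sample_id: str
    group_label: str
    records: list[SequenceRecord]

    @property
    def depth(self) -> int:
        return len(self.records)


def _normalize(abund: dict[str, float]) -> dict[str, float]:
    total = sum(abund.values())
    if total <= 0:
        raise ValueError("community has zero total abundance")
    return {t: a / total for t, a in abund.items()}


def sample_community(spec: CommunitySpec) -> dict[str, float]:
    """Draw a log-normal community and normalize to relative abundances."""
    bad = set(spec.enriched_taxa) - set(spec.taxa)
    if bad:
        raise ValueError(f"enriched taxa not in community: {sorted(bad)}")
    rng = np.random.default_rng(spec.seed)
    raw = rng.lognormal(spec.mu, spec.sigma, spec.n_taxa)
    return _normalize(dict(zip(spec.taxa, raw)))


def apply_rearing_shift(
    community: dict[str, float], spec: CommunitySpec
) -> dict[str, float]:
    """Enrich planted degraders, deplete the rest, drop extinct taxa.

    Enriched taxa are multiplied by the enrichment factor and all others
    by the depletion factor; the vector is renormalized and taxa below
    the extinction floor are removed (renormalizing again), reproducing
    the richness decrease under rearing.
    """
    if not community:
        raise ValueError("empty community")
    shifted = {
        t: a * (spec.enrichment_factor if t in spec.enriched_taxa else spec.depletion_factor)
        for t, a in community.items()
    }
    shifted = _normalize(shifted)
    surviving = {t: a for t, a in shifted.items() if a >= spec.extinction_floor}
    if not surviving:
        raise ValueError("no taxon survives the extinction floor")
    return _normalize(surviving)


def jitter_community(
    community: dict[str, float], sigma: float, seed
) -> dict[str, float]:
    """Per-individual log-normal dispersion around a community template."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noisy = {t: a * rng.lognormal(0.0, sigma) for t, a in community.items()}
    return _normalize(noisy)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-base substitution at ``rate``; substitutions always change the base."""
    if rate == 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _random_nt(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous coding of a protein (stop-free by construction)."""
    out = []
    for aa in protein:
        codons = _CODON_TABLE[aa]
        out.append(codons[rng.integers(len(codons))])
    return "".join(out)


def _fix_stops_in_frame(seq: str, offset: int, rng: np.random.Generator) -> str:
    """Replace any stop codon in the frame starting at ``offset``."""
    arr = list(seq)
    for i in range(offset, len(seq) - 2, 3):
        codon = "".join(arr[i:i + 3])
        if codon in _STOPS:
            new = _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))]
            arr[i:i + 3] = list(new)
    return "".join(arr)


def make_reference_proteins(
    n: int = 16,
    core_len: int = 115,
    divergence: float = 0.3,
    seed: int = 0,
    id_prefix: str = "PL7REF",
) -> list[SequenceRecord]:
    """Synthetic PL7-like reference protein family.

    Members share the A3/A4 strand motifs and descend from one root
    core by residue substitution at ``divergence`` — a colinear
    homologous family (the generator's evolution model is
    substitution-only), so amplicons planted from these ancestors align
    into a common trimming window and reference screening behaves like
    a homology filter against a family the amplicons actually belong
    to. These are constructed sequences, not database entries.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(_CORE_AA))
    root = aa[rng.integers(0, len(aa), core_len)]
    records = []
    for k in range(n):
        core = root.copy()
        hits = np.nonzero(rng.random(core_len) < divergence)[0]
        core[hits] = aa[rng.integers(0, len(aa), len(hits))]
        records.append(
            SequenceRecord(
                f"{id_prefix}{k + 1:03d}",
                A3_MOTIF_AA + "".join(core) + A4_MOTIF_AA,
                description="synthetic PL7-like protein (A3/A4 scaffold family)",
            )
        )
    return records


def _ancestor_16s(core_len: int, rng: np.random.Generator) -> str:
    return _M27F_SITE + _random_nt(core_len, rng) + _M338R_RC_SITE


def _alg_gene_from_protein(
    protein: str, pad: int, rng: np.random.Generator
) -> tuple[str, int]:
    """Nucleotide ALG gene: 5' pad + amplifiable region + 3' pad.

    The amplifiable region reuses the canonical A3/A4 site codons (so
    the degenerate primers find zero-mismatch sites) around a random
    synonymous coding of the protein core. Returns (gene, amplicon
    start offset).
    """
    if not (protein.startswith(A3_MOTIF_AA) and protein.endswith(A4_MOTIF_AA)):
        raise ValueError("ALG protein must carry the A3/A4 scaffold")
    core = protein[len(A3_MOTIF_AA): len(protein) - len(A4_MOTIF_AA)]
    region = A3_MOTIF_NT + _reverse_translate(core, rng) + A4_MOTIF_NT
    gene = _random_nt(pad, rng) + region + _random_nt(pad, rng)
    return gene, pad


def evolve_marker_genes(
    n_taxa: int,
    seed: int = 0,
    rate: float = 0.05,
    motif_rate: float = 0.0,
    marker_core_len: int = 270,
    alg_core_len: tuple[int, int] = (90, 190),
    p_alg: float = 0.3,
    alg_taxa: frozenset[str] = frozenset(),
    pad: int = 60,
) -> list[TaxonGenome]:
    """Evolve per-taxon markers from shared ancestors by point mutation.

    All taxa descend from one 16S-like ancestor and (where they carry
    one) an ALG-like ancestor drawn from the packaged synthetic PL7
    scaffold set. Marker bodies mutate at ``rate``; primer-anchor motifs
    mutate at ``motif_rate`` (default 0, so planted amplifiability is
    exact). Taxa in ``alg_taxa`` always carry an ALG gene, others with
    probability ``p_alg``. Stop codons arising in the amplicon frame are
    re-drawn so planted genes survive the stop-codon filter the way real
    coding sequence would.
    """
    if not 0 <= rate < 0.75:
        raise ValueError("rate must be in [0, 0.75)")
    rng = np.random.default_rng(seed)
    ancestor_16s = _ancestor_16s(marker_core_len, rng)
    ancestors_alg = read_fasta(packaged_reference_path())
    taxa = [f"T{i + 1:03d}" for i in range(n_taxa)]
    genomes = []
    head = len(_M27F_SITE)
    tail = len(_M338R_RC_SITE)
    for t in taxa:
        body = _mutate(ancestor_16s[head:-tail], rate, rng)
        site_a = _mutate(ancestor_16s[:head], motif_rate, rng)
        site_b = _mutate(ancestor_16s[-tail:], motif_rate, rng)
        marker = site_a + body + site_b
        genes: list[str] = []
        if t in alg_taxa or rng.random() < p_alg:
            anc = ancestors_alg[rng.integers(len(ancestors_alg))]
            core_min, core_max = alg_core_len
            core = anc.sequence[len(A3_MOTIF_AA): -len(A4_MOTIF_AA)]
            L = int(min(max(len(core), core_min), core_max))
            protein = A3_MOTIF_AA + core[:L] + A4_MOTIF_AA
            gene, start = _alg_gene_from_protein(protein, pad, rng)
            region_end = len(gene) - pad
            # mutate pads+core body at `rate`, primer sites at `motif_rate`
            g = (
                _mutate(gene[:start], rate, rng)
                + _mutate(gene[start:start + len(A3_MOTIF_NT)], motif_rate, rng)
                + _mutate(gene[start + len(A3_MOTIF_NT): region_end - len(A4_MOTIF_NT)], rate, rng)
                + _mutate(gene[region_end - len(A4_MOTIF_NT): region_end], motif_rate, rng)
                + _mutate(gene[region_end:], rate, rng)
            )
            g = _fix_stops_in_frame(g, start, rng)
            genes.append(g)
        genomes.append(TaxonGenome(t, marker, tuple(genes)))
    return genomes


def generate_reads(
    communities: dict[str, dict[str, float]],
    genomes: list[TaxonGenome],
    depth: int,
    error_rate: float = 0.002,
    seed: int = 0,
    group_labels: dict[str, str] | None = None,
    gene: str = "16s",
) -> list[SampleReads]:
    """Draw reads multinomially from each sample's community.

    Each read is the taxon's whole marker (16S mode) or a random one of
    its ALG genes, with per-base substitution errors at ``error_rate``.
    Samples are processed in sorted id order from independent substreams
    of ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    by_id = {g.taxon_id: g for g in genomes}
    group_labels = group_labels or {}
    ss = np.random.SeedSequence(seed)
    sample_ids = sorted(communities)
    out = []
    for child, sid in zip(ss.spawn(len(sample_ids)), sample_ids):
        rng = np.random.default_rng(child)
        community = communities[sid]
        taxa = sorted(community)
        if gene == "alg":
            taxa = [t for t in taxa if by_id[t].alg_genes]
            if not taxa:
                raise ValueError(f"sample {sid}: no taxon carries an ALG gene")
        probs = np.array([community[t] for t in taxa])
        probs = probs / probs.sum()
        counts = rng.multinomial(depth, probs)
        records = []
        k = 0
        for t, c in zip(taxa, counts):
            genome = by_id[t]
            for _ in range(c):
                if gene == "16s":
                    template = genome.marker_16s
                else:
                    template = genome.alg_genes[rng.integers(len(genome.alg_genes))]
                records.append(
                    SequenceRecord(
                        f"{sid}_r{k:05d}",
                        _mutate(template, error_rate, rng),
                        sample_id=sid,
                    )
                )
                k += 1
        out.append(SampleReads(sid, group_labels.get(sid, ""), records))
    return out


@dataclass
class StudyData:
    """One synthetic feeding experiment for a single host."""

    samples: list[SampleReads]
    metadata: pd.DataFrame
    genomes: list[TaxonGenome]
    enriched_taxa: frozenset[str]
    wild_template: dict[str, float]
    reared_template: dict[str, float]
    communities: dict[str, dict[str, float]]


def simulate_study(
    n_taxa: int = 50,
    n_enriched: int = 5,
    enrichment_factor: float = 5.0,
    depletion_factor: float = 0.3,
    n_wild: int = 5,
    n_reared: int = 5,
    depth: int = 2000,
    error_rate: float = 0.002,
    marker_rate: float = 0.05,
    mu: float = 0.0,
    sigma: float = 1.5,
    wild_sigma: float = 0.5,
    reared_sigma: float = 0.15,
    extinction_floor: float = 1e-3,
    host: str = "SH",
    seed: int = 0,
) -> StudyData:
    """Simulate wild and reared individuals of one host species.

    A single wild community template is drawn per host population; a
    reared template is derived from it by the rearing shift. Individuals
    are log-normal jitters of their template — wider for wild animals
    (mixed natural diet) than for reared ones (one controlled diet) —
    and reads are drawn from each individual's community.
    """
    ss = np.random.SeedSequence(seed)
    s_comm, s_genomes, s_jitter, s_reads = ss.spawn(4)
    rng = np.random.default_rng(s_comm)
    taxa = [f"T{i + 1:03d}" for i in range(n_taxa)]
    enriched = frozenset(rng.choice(taxa, n_enriched, replace=False).tolist())
    spec = CommunitySpec(
        n_taxa,
        mu,
        sigma,
        enriched,
        depletion_factor,
        enrichment_factor,
        extinction_floor,
        seed=int(rng.integers(2**31)),
    )
    wild_template = sample_community(spec)
    reared_template = apply_rearing_shift(wild_template, spec)
    genomes = evolve_marker_genes(
        n_taxa, seed=int(np.random.default_rng(s_genomes).integers(2**31)),
        rate=marker_rate, alg_taxa=enriched,
    )
    communities: dict[str, dict[str, float]] = {}
    labels: dict[str, str] = {}
    jitters = s_jitter.spawn(n_wild + n_reared)
    for i in range(n_wild):
        sid = f"{host}W{i + 1:02d}"
        communities[sid] = jitter_community(wild_template, wild_sigma, jitters[i])
        labels[sid] = f"{host}-W"
    for i in range(n_reared):
        sid = f"{host}R{i + 1:02d}"
        communities[sid] = jitter_community(
            reared_template, reared_sigma, jitters[n_wild + i]
        )
        labels[sid] = f"{host}-R"
    samples = generate_reads(
        communities, genomes, depth, error_rate,
        seed=int(np.random.default_rng(s_reads).integers(2**31)),
        group_labels=labels,
    )
    meta = pd.DataFrame(
        {
            "sample_id": list(labels),
            "group_label": [labels[s] for s in labels],
            "host": host,
            "treatment": ["wild" if g.endswith("-W") else "reared" for g in labels.values()],
        }
    )
    return StudyData(
        samples, meta, genomes, enriched, wild_template, reared_template, communities
    )
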