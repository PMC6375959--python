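"""Degenerate-primer modelling and in-silico PCR.

Primers are written 5'->3' over the IUPAC nucleotide ambiguity alphabet
plus ``I`` (inosine). Inosine is treated as a universal-pairing residue:
it anneals to any template base but, unlike ``N``, it is a single
physical residue and therefore contributes a factor of 1 to the
degeneracy (number of distinct oligonucleotides) of a primer pool.

A forward primer anneals to the minus strand, so its site is its literal
sequence on the plus strand (strand ``+``). A reverse primer anneals to
the plus strand, so its site is its reverse complement on the plus
strand (strand ``-``). Amplification pairs a forward site with a
downstream reverse site and size-selects products, emulating gel
purification of products in a configured window (default 300-650 bp).
All coordinates are 0-based half-open on the plus strand; amplicons are
primer-inclusive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "IUPAC_SETS",
    "DegeneratePrimer",
    "PrimerSite",
    "Amplicon",
    "degeneracy",
    "expand_primer",
    "reverse_complement",
    "match_primer",
    "amplify",
    "design_degenerate_primers",
    "load_primers",
    "packaged_primers",
]

#: Concrete plus-strand bases each primer character can anneal to.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "I": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "I": "I",
}

# Bases -> minimal IUPAC code (inosine never emitted here; see
# design_degenerate_primers for the I-substitution rule).
_BASES_TO_CODE = {frozenset(v): k for k, v in IUPAC_SETS.items() if k != "I"}

# Standard genetic code, amino acid -> codons (code 1).
_CODON_TABLE = {
    "F": ["TTT", "TTC"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"],
    "M": ["ATG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "Y": ["TAT", "TAC"],
    "H": ["CAT", "CAC"],
    "Q": ["CAA", "CAG"],
    "N": ["AAT", "AAC"],
    "K": ["AAA", "AAG"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "C": ["TGT", "TGC"],
    "W": ["TGG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "*": ["TAA", "TAG", "TGA"],
}


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC+inosine primer with an annealing orientation."""

    name: str
    sequence: str
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"primer {self.name!r}: empty sequence")
        for i, c in enumerate(self.sequence):
            if c not in IUPAC_SETS:
                raise ValueError(
                    f"primer {self.name!r}: illegal character {c!r} at position {i}"
                )
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name!r}: bad orientation {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerSite:
    """A primer annealing site in plus-strand coordinates."""

    template_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    primer_name: str


@dataclass(frozen=True)
class Amplicon:
    """A primer-inclusive PCR product on the plus strand."""

    template_id: str
    start: int
    end: int
    sequence: str
    fwd_primer_name: str
    rev_primer_name: str

    @property
    def length(self) -> int:
        return self.end - self.start


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full degenerate alphabet (I self-pairs)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"cannot complement character {exc.args[0]!r}") from None


def degeneracy(primer: DegeneratePrimer | str) -> int:
    """Number of distinct oligonucleotides in the primer pool.

    Inosine counts as a single universal residue (factor 1); every other
    code contributes the size of its base set.
    """
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer
    n = 1
    for i, c in enumerate(seq):
        if c not in IUPAC_SETS:
            raise ValueError(f"illegal character {c!r} at position {i}")
        n *= 1 if c == "I" else len(IUPAC_SETS[c])
    return n


def expand_primer(primer: DegeneratePrimer | str) -> list[str]:
    """Enumerate the concrete oligonucleotides of the pool.

    Inosine is kept as ``I`` (one physical residue), so the enumeration
    size equals :func:`degeneracy`.
    """
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer
    choices = [["I"] if c == "I" else sorted(IUPAC_SETS[c]) for c in seq]
    return ["".join(p) for p in itertools.product(*choices)]


def _mismatches_at(pattern: str, template: str, pos: int, limit: int) -> int:
    """Mismatch count of ``pattern`` vs ``template[pos:]``; early exit past limit."""
    mm = 0
    for j, c in enumerate(pattern):
        if template[pos + j] not in IUPAC_SETS[c]:
            mm += 1
            if mm > limit:
                return mm
    return mm


def match_primer(
    primer: DegeneratePrimer,
    template: str,
    max_mismatch: int = 0,
    template_id: str = "",
) -> list[PrimerSite]:
    """All annealing sites of ``primer`` on ``template``.

    A forward primer is matched literally against the plus strand
    (strand ``+``); a reverse primer is matched as its reverse
    complement (strand ``-``). An IUPAC code matches a template base iff
    the base is in its denoted set; inosine matches any base. A primer
    longer than the template yields no sites.
    """
    template = template.upper()
    bad = set(template) - set("ACGT")
    if bad:
        raise ValueError(f"template contains non-ACGT characters: {sorted(bad)}")
    if primer.orientation == "forward":
        pattern, strand = primer.sequence, "+"
    else:
        pattern, strand = reverse_complement(primer.sequence), "-"
    L = len(pattern)
    sites = []
    for pos in range(len(template) - L + 1):
        mm = _mismatches_at(pattern, template, pos, max_mismatch)
        if mm <= max_mismatch:
            sites.append(
                PrimerSite(template_id, pos, pos + L, strand, mm, primer.name)
            )
    return sites


def amplify(
    template: str,
    forward_primers: list[DegeneratePrimer],
    reverse_primers: DegeneratePrimer | list[DegeneratePrimer],
    max_mismatch: int = 0,
    size_window: tuple[int, int] = (300, 650),
    template_id: str = "",
) -> list[Amplicon]:
    """Extract size-selected amplicons from one template.

    Every pairing of a forward site with a downstream reverse site
    yields a product iff the primer-inclusive span length falls inside
    ``size_window`` (inclusive). Any member of the forward pool may
    initiate (degenerate primer mixture semantics); multiple products
    per template are all reported.
    """
    lo, hi = size_window
    if lo > hi:
        raise ValueError(f"inverted size window ({lo}, {hi})")
    if isinstance(reverse_primers, DegeneratePrimer):
        reverse_primers = [reverse_primers]
    for p in forward_primers:
        if p.orientation != "forward":
            raise ValueError(f"primer {p.name!r} is not a forward primer")
    for p in reverse_primers:
        if p.orientation != "reverse":
            raise ValueError(f"primer {p.name!r} is not a reverse primer")
    template = template.upper()
    fwd_sites = [
        s for p in forward_primers
        for s in match_primer(p, template, max_mismatch, template_id)
    ]
    rev_sites = [
        s for p in reverse_primers
        for s in match_primer(p, template, max_mismatch, template_id)
    ]
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            if f.start < r.end and lo <= r.end - f.start <= hi:
                products.append(
                    Amplicon(
                        template_id,
                        f.start,
                        r.end,
                        template[f.start:r.end],
                        f.primer_name,
                        r.primer_name,
                    )
                )
    products.sort(key=lambda a: (a.start, a.end, a.fwd_primer_name))
    return products


def _minimal_code(bases: frozenset[str]) -> str:
    return _BASES_TO_CODE[frozenset(bases)]


def _window_codon_sets(block: list[str], window: tuple[int, int]) -> list[set[str]]:
    """Per-column codon sets for the aligned protein block over ``window``."""
    if not block:
        raise ValueError("empty alignment block")
    start, end = window
    sets = []
    for col in range(start, end):
        residues = {seq[col] for seq in block}
        if "-" in residues or "." in residues:
            raise ValueError(f"window column {col} contains gap characters")
        codons: set[str] = set()
        for aa in residues:
            try:
                codons.update(_CODON_TABLE[aa.upper()])
            except KeyError:
                raise ValueError(f"unknown residue {aa!r} at column {col}") from None
        sets.append(codons)
    return sets


def _primer_from_codon_sets(
    codon_sets: list[set[str]], inosine_third_position: bool
) -> str:
    out = []
    for codons in codon_sets:
        for pos in range(3):
            bases = frozenset(c[pos] for c in codons)
            code = _minimal_code(bases)
            if code == "N" and pos == 2 and inosine_third_position:
                code = "I"
            out.append(code)
    return "".join(out)


def design_degenerate_primers(
    block: list[str],
    window: tuple[int, int],
    name: str = "primer",
    orientation: str = "forward",
    max_degeneracy: int | None = None,
    inosine_third_position: bool = True,
) -> list[DegeneratePrimer]:
    """Back-translate a gap-free window of an aligned protein block.

    Each window column's observed residue set is expanded through the
    standard codon table; per codon position the minimal IUPAC code
    covering all observed bases is emitted, with ``I`` substituted where
    the cover would be ``N`` at a codon third position (the wobble
    position, where a universal residue is the conventional choice).

    When the pool degeneracy exceeds ``max_degeneracy`` the most
    degenerate column's codon set is bisected (grouping synonymous codon
    families together) and the design recurses on each half, emulating a
    forward-primer split such as ALG-f1/ALG-f2; the union of the
    returned primers' expansions covers every observed coding.
    """
    if not (0 <= window[0] < window[1] <= min(len(s) for s in block)):
        raise ValueError(f"window {window} out of range")
    codon_sets = _window_codon_sets(block, window)

    def build(sets: list[set[str]]) -> list[list[set[str]]]:
        seq = _primer_from_codon_sets(sets, inosine_third_position)
        if max_degeneracy is None or degeneracy(seq) <= max_degeneracy:
            return [sets]
        # Split the column whose codon set spans the most bases.
        def spread(cs: set[str]) -> int:
            return degeneracy(_primer_from_codon_sets([cs], False))

        worst = max(range(len(sets)), key=lambda i: spread(sets[i]))
        codons = sorted(sets[worst])
        if len(codons) < 2:
            return [sets]  # cannot split further
        # Group codons by first two bases so synonymous families stay together.
        families: dict[str, list[str]] = {}
        for c in codons:
            families.setdefault(c[:2], []).append(c)
        keys = sorted(families, key=lambda k: -len(families[k]))
        half_a: list[str] = []
        half_b: list[str] = []
        for k in keys:
            (half_a if sum(map(len, (half_a,))) <= sum(map(len, (half_b,))) else half_b).extend(
                families[k]
            )
        if not half_b:  # single family: split it in half
            half_a, half_b = codons[: len(codons) // 2], codons[len(codons) // 2:]
        out = []
        for half in (half_a, half_b):
            sub = [set(s) for s in sets]
            sub[worst] = set(half)
            out.extend(build(sub))
        return out

    variants = build(codon_sets)
    primers = []
    for i, sets in enumerate(variants):
        seq = _primer_from_codon_sets(sets, inosine_third_position)
        suffix = f"-{i + 1}" if len(variants) > 1 else ""
        primers.append(DegeneratePrimer(f"{name}{suffix}", seq, orientation))
    return primers


def load_primers(path: str | Path) -> list[DegeneratePrimer]:
    """Read primers from a TSV of (name, sequence, orientation); '#' comments."""
    primers = []
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                header_seen = True
                if fields[0].lower() == "name":
                    continue
            if len(fields) != 3:
                raise ValueError(f"malformed primer line: {line!r}")
            primers.append(DegeneratePrimer(fields[0], fields[1].upper(), fields[2]))
    if not primers:
        raise ValueError(f"no primers found in {path}")
    return primers


def packaged_primers() -> dict[str, DegeneratePrimer]:
    """The study's five printed primers, keyed by name."""
    path = Path(__file__).parent / "data" / "primers.tsv"
    return {p.name: p for p in load_primers(path)}
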