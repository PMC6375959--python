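"""Alpha diversity and nonparametric group tests.

Chao1 is the bias-corrected estimator S_obs + F1(F1-1)/(2(F2+1)),
well-defined when doubletons are absent; Shannon entropy is reported in
nats by default. Rarefaction subsamples reads without replacement
(multivariate hypergeometric) to a common depth to remove
sequencing-effort bias. The Mann-Whitney U test uses midranks for ties,
exact enumeration of all C(n1+n2, n1) group labelings for small
tie-free samples, and a tie- and continuity-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .phylotypes import PhylotypeTable

__all__ = [
    "DiversityResult",
    "GroupComparison",
    "rarefy",
    "rarefy_table",
    "chao1",
    "shannon",
    "diversity_profile",
    "mann_whitney_u",
    "differential_phylotypes",
]


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    s_obs: int
    f1: int
    f2: int
    chao1: float
    shannon: float


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n1: int
    n2: int
    u: float
    p_value: float
    method: str
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def rarefy(counts, depth: int = 4000, seed: int | None = None, sample_id: str = ""):
    """Subsample a count vector to ``depth`` reads without replacement."""
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("negative counts")
    total = int(counts.sum())
    if total < depth:
        raise ValueError(
            f"sample {sample_id or '<unnamed>'}: only {total} reads, cannot rarefy to {depth}"
        )
    if total == depth:
        return counts.copy()
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth).astype(np.int64)


def rarefy_table(table: pd.DataFrame, depth: int = 4000, seed: int | None = None) -> pd.DataFrame:
    """Rarefy every row of a samples x phylotypes count table.

    Per-sample substreams are spawned from ``seed`` so results do not
    depend on row order.
    """
    import zlib

    out = {}
    for sample, row in table.iterrows():
        # substream keyed to the sample name, so results are invariant to
        # the table's row order
        child = np.random.SeedSequence(
            [0 if seed is None else int(seed), zlib.crc32(str(sample).encode())]
        )
        out[sample] = rarefy(row.values, depth, np.random.default_rng(child), sample)
    return pd.DataFrame.from_dict(out, orient="index", columns=table.columns)


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness estimate."""
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("negative counts")
    s_obs = int((counts > 0).sum())
    if s_obs == 0:
        raise ValueError("all-zero count vector")
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts, base: float = math.e) -> float:
    """Shannon entropy of a count vector (nats by default)."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum() / math.log(base))


def diversity_profile(
    table: pd.DataFrame, depth: int | None = None, seed: int | None = None
) -> list[DiversityResult]:
    """Per-sample S_obs/F1/F2/Chao1/Shannon, optionally on rarefied counts."""
    if depth is not None:
        table = rarefy_table(table, depth, seed)
    out = []
    for sample, row in table.iterrows():
        counts = row.values
        out.append(
            DiversityResult(
                str(sample),
                int((counts > 0).sum()),
                int((counts == 1).sum()),
                int((counts == 2).sum()),
                chao1(counts),
                shannon(counts),
            )
        )
    return out


def _u_statistic(x: np.ndarray, ranks: np.ndarray, idx: tuple[int, ...]) -> float:
    n1 = len(idx)
    r1 = ranks[list(idx)].sum()
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney_u(
    x,
    y,
    alternative: str = "two-sided",
    alpha: float = 0.05,
    exact_max_n: int = 8,
    group_a: str = "x",
    group_b: str = "y",
) -> GroupComparison:
    """Mann-Whitney U test with midranks.

    Exact p-values enumerate all C(n1+n2, n1) labelings when the larger
    group has at most ``exact_max_n`` observations and the pooled data
    are tie-free; otherwise a normal approximation with tie correction
    and a 0.5 continuity correction is used. Two-sided p-values count
    labelings whose U is at least as far from the null mean n1*n2/2 as
    observed (the exact-null distribution is symmetric).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty group")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank(method="average").to_numpy()
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mean_u = n1 * n2 / 2.0
    has_ties = len(np.unique(pooled)) < n1 + n2

    if max(n1, n2) <= exact_max_n and not has_ties:
        method = "exact"
        us = np.array(
            [_u_statistic(pooled, ranks, idx) for idx in combinations(range(n1 + n2), n1)]
        )
        if alternative == "two-sided":
            p = float((np.abs(us - mean_u) >= abs(u - mean_u) - 1e-12).mean())
        elif alternative == "greater":
            p = float((us >= u - 1e-12).mean())
        else:
            p = float((us <= u + 1e-12).mean())
    else:
        method = "normal-approximation"
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sd = math.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term))
        if sd == 0:
            p = 1.0
        else:
            from scipy.stats import norm

            if alternative == "two-sided":
                z = (abs(u - mean_u) - 0.5) / sd
                p = float(2 * norm.sf(max(z, 0.0)))
            elif alternative == "greater":
                z = (u - mean_u - 0.5) / sd
                p = float(norm.sf(z))
            else:
                z = (u - mean_u + 0.5) / sd
                p = float(norm.cdf(z))
        p = min(p, 1.0)
    return GroupComparison(group_a, group_b, n1, n2, u, p, method, alpha)


def differential_phylotypes(
    table: PhylotypeTable | pd.DataFrame,
    groups: dict[str, str],
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-phylotype Mann-Whitney tests on relative abundances.

    Labels a phylotype ``enriched`` (higher in ``group_b``) or
    ``depleted`` by the direction of the median difference when
    p < alpha, else ``ns``. No multiple-testing correction by default;
    Benjamini-Hochberg optional.
    """
    counts = table.counts if isinstance(table, PhylotypeTable) else table
    rel = counts.div(counts.sum(axis=1), axis=0)
    a_samples = [s for s in counts.index if groups.get(s) == group_a]
    b_samples = [s for s in counts.index if groups.get(s) == group_b]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError(
            f"need >= 2 samples per group (got {len(a_samples)} {group_a!r}, "
            f"{len(b_samples)} {group_b!r})"
        )
    rows = []
    for pid in counts.columns:
        xa = rel.loc[a_samples, pid].to_numpy()
        xb = rel.loc[b_samples, pid].to_numpy()
        cmp = mann_whitney_u(xa, xb, alpha=alpha, group_a=group_a, group_b=group_b)
        delta = float(np.median(xb) - np.median(xa))
        rows.append((pid, cmp.u, cmp.p_value, cmp.method, delta))
    df = pd.DataFrame(rows, columns=["phylotype", "u", "p", "method", "median_diff"])
    pcol = "p"
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
        pcol = "p_adj"

    def label(row):
        if row[pcol] < alpha and row["median_diff"] > 0:
            return "enriched"
        if row[pcol] < alpha and row["median_diff"] < 0:
            return "depleted"
        return "ns"

    df["label"] = df.apply(label, axis=1)
    return df.set_index("phylotype")
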