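"""Set-level statistics on the shared homology universe.

Covers the pairwise hypergeometric overlap test with its enrichment ratio
(observed overlap divided by the independence expectation |A||B|/N), BH
adjustment across all tested pairs, the multi-set bootstrap for the joint
overlap of three (or more) significant-gene sets, the per-chromosome bias
test, extraction of the cross-tissue "core battery" with direction
classification, and one-sample proportion tests of direction consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffabund import adjust_fdr
from .homology import AlignedResults

__all__ = [
    "OverlapResult",
    "BootstrapResult",
    "CoreBattery",
    "DirectionTestResult",
    "enrichment_ratio",
    "pairwise_overlap",
    "all_pairwise",
    "adjust_pairwise",
    "bootstrap_multiset_overlap",
    "chromosome_bias",
    "core_battery",
    "direction_consistency_test",
]


def enrichment_ratio(observed: float, expected: float) -> float:
    """Observed overlap over its independence expectation (0 when observed 0)."""
    if observed == 0:
        return 0.0
    if expected == 0:
        return math.inf
    return observed / expected


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap of two sets on a universe of size N."""

    observed: int
    expected: float
    ratio: float
    p: float
    size_a: int
    size_b: int
    n: int
    label_a: str = "A"
    label_b: str = "B"
    q: float | None = None


def pairwise_overlap(
    a: Iterable, b: Iterable, n: int,
    label_a: str = "A", label_b: str = "B",
) -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap between two gene sets.

    ``expected = |A||B|/N``; ``p = P[X >= observed]`` with
    ``X ~ Hypergeometric(N, |A|, |B|)``.  The result is symmetric in A/B.
    """
    if n <= 0:
        raise ValueError("universe size N must be positive")
    a, b = set(a), set(b)
    if len(a) > n or len(b) > n:
        raise ValueError("set larger than the universe")
    observed = len(a & b)
    expected = len(a) * len(b) / n
    p = float(stats.hypergeom.sf(observed - 1, n, len(a), len(b)))
    return OverlapResult(
        observed=observed,
        expected=expected,
        ratio=enrichment_ratio(observed, expected),
        p=min(p, 1.0),
        size_a=len(a),
        size_b=len(b),
        n=n,
        label_a=label_a,
        label_b=label_b,
    )


def all_pairwise(sets: Mapping[str, set], n: int) -> pd.DataFrame:
    """Overlap tests for every pair of named sets, BH-adjusted as one family."""
    results = [
        pairwise_overlap(sets[ka], sets[kb], n, ka, kb)
        for ka, kb in combinations(sets, 2)
    ]
    return adjust_pairwise(results)


def adjust_pairwise(results: Sequence[OverlapResult]) -> pd.DataFrame:
    """BH over the family of tested pairs; returns a tidy table."""
    if not results:
        raise ValueError("no pair results to adjust")
    q = adjust_fdr([r.p for r in results])
    return pd.DataFrame(
        {
            "set_a": [r.label_a for r in results],
            "set_b": [r.label_b for r in results],
            "size_a": [r.size_a for r in results],
            "size_b": [r.size_b for r in results],
            "observed": [r.observed for r in results],
            "expected": [r.expected for r in results],
            "ratio": [r.ratio for r in results],
            "p": [r.p for r in results],
            "q": q,
        }
    )


# ---------------------------------------------------------------------------
# multi-set bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapResult:
    """Monte-Carlo null for the joint overlap of several sets.

    ``exceed_count`` counts replicates whose joint-overlap size is strictly
    greater than ``observed`` (the study's rule); ``p_estimate`` is
    ``exceed/reps`` and ``p_upper_bound`` the reportable bound ``1/reps``
    when no replicate exceeds.  ``p_pseudocount`` is the conventional
    ``(#{count >= observed} + 1)/(reps + 1)`` estimate.
    """

    observed: int
    reps: int
    exceed_count: int
    p_estimate: float
    p_upper_bound: float | None
    p_pseudocount: float
    perm_mean: float
    perm_var: float

    @property
    def p_report(self) -> str:
        if self.exceed_count == 0:
            return f"< {1.0 / self.reps:g}"
        return f"{self.p_estimate:g}"


def _compose_counts(
    sizes: Sequence[int], n: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Joint-overlap sizes by sequential hypergeometric composition.

    The intersection of independent uniform subsets can be built
    sequentially: the running intersection has some size c, and
    intersecting with the next subset of size n_i draws
    ``Hypergeometric(N, c, n_i)``.
    """
    counts = np.full(reps, sizes[0], dtype=np.int64)
    for size in sizes[1:]:
        positive = counts > 0
        new = np.zeros_like(counts)
        if positive.any():
            new[positive] = rng.hypergeometric(
                counts[positive], n - counts[positive], size
            )
        counts = new
    return counts


def _direct_counts(
    sizes: Sequence[int], n: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Joint-overlap sizes by explicit uniform set sampling (validation path)."""
    counts = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        joint = np.ones(n, dtype=bool)
        for size in sizes:
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=size, replace=False)] = True
            joint &= mask
        counts[r] = joint.sum()
    return counts


def bootstrap_multiset_overlap(
    sizes: Sequence[int],
    n: int,
    observed: int,
    reps: int = 10**6,
    seed: int | np.random.Generator | None = None,
    method: str = "auto",
) -> BootstrapResult:
    """Bootstrap p-value for the joint overlap of several gene sets.

    Under the null, each set is an independent uniform draw of its size from
    the universe.  ``method='composition'`` (default for large ``reps``)
    samples only the running intersection size and is exact in distribution;
    ``method='direct'`` samples the sets explicitly and serves as a
    cross-check.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if len(sizes) < 2:
        raise ValueError("need at least two sets")
    if any(s < 0 or s > n for s in sizes):
        raise ValueError("each set size must lie in [0, N]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if method == "auto":
        method = "composition" if reps >= 10**5 else "direct"
    if method == "composition":
        counts = _compose_counts(sizes, n, reps, rng)
    elif method == "direct":
        counts = _direct_counts(sizes, n, reps, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    exceed = int((counts > observed).sum())
    exceed_ge = int((counts >= observed).sum())
    return BootstrapResult(
        observed=observed,
        reps=reps,
        exceed_count=exceed,
        p_estimate=exceed / reps,
        p_upper_bound=(1.0 / reps) if exceed == 0 else None,
        p_pseudocount=(exceed_ge + 1) / (reps + 1),
        perm_mean=float(counts.mean()),
        perm_var=float(counts.var(ddof=1)) if reps > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# chromosome bias
# ---------------------------------------------------------------------------

def chromosome_bias(
    sig: Iterable,
    chrom_map: Mapping,
    universe: Iterable,
) -> pd.DataFrame:
    """Per-chromosome enrichment of significant genes, BH across chromosomes.

    For each chromosome, an upper-tail hypergeometric test of the number of
    significant genes assigned to it, against the chromosome's share of the
    universe.
    """
    universe = set(universe)
    sig = set(sig) & universe
    missing = universe - set(chrom_map)
    if missing:
        raise ValueError(
            f"chromosome map does not cover the universe "
            f"({len(missing)} genes missing)"
        )
    n, m = len(universe), len(sig)
    rows = []
    by_chrom: dict[str, set] = {}
    for gene in universe:
        by_chrom.setdefault(chrom_map[gene], set()).add(gene)
    for chrom in sorted(by_chrom):
        genes = by_chrom[chrom]
        k = len(genes & sig)
        expected = len(genes) * m / n
        p = float(stats.hypergeom.sf(k - 1, n, len(genes), m))
        rows.append(
            {
                "chrom": chrom,
                "n_universe": len(genes),
                "observed": k,
                "expected": expected,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = adjust_fdr(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# core battery
# ---------------------------------------------------------------------------

@dataclass
class CoreBattery:
    """Genes significant in at least ``min_studies`` studies.

    ``table`` is indexed by HID, ordered by decreasing mean |M| across
    studies, with columns ``n_significant``, ``direction_class``
    (``consistent`` / ``species_divergent`` / ``tissue_variable``),
    ``mean_abs_M`` and per-study ``M_<key>`` / ``q_<key>``.
    """

    table: pd.DataFrame
    q_threshold: float
    min_studies: int

    @property
    def genes(self) -> set[int]:
        return set(self.table.index)


def _classify_direction(
    sig_signs: Mapping[str, float], species: Mapping[str, str]
) -> str:
    values = list(sig_signs.values())
    if all(v == values[0] for v in values):
        return "consistent"
    by_species: dict[str, set[float]] = {}
    for key, sign in sig_signs.items():
        by_species.setdefault(species[key], set()).add(sign)
    if all(len(signs) == 1 for signs in by_species.values()):
        distinct = {next(iter(s)) for s in by_species.values()}
        if len(distinct) > 1:
            return "species_divergent"
    return "tissue_variable"


def core_battery(
    aligned: AlignedResults,
    q_threshold: float = 0.05,
    min_studies: int = 4,
) -> CoreBattery:
    """Extract genes whose abundance tracks genotype across most studies.

    A gene enters the battery when significant (q below threshold) in at
    least ``min_studies`` studies.  Direction classes: ``consistent`` when
    every significant M shares one sign; ``species_divergent`` when the sign
    is constant within species but differs between them; otherwise
    ``tissue_variable``.  Rows are ordered by decreasing mean |M| across all
    studies.
    """
    if len(aligned.results) < 2:
        raise ValueError("need at least two aligned studies")
    min_studies = max(min_studies, 2)
    keys = list(aligned.results)
    q_mat = pd.DataFrame({k: aligned.results[k]["q"] for k in keys})
    m_mat = pd.DataFrame({k: aligned.results[k]["M"] for k in keys})
    sig = q_mat < q_threshold
    n_sig = sig.sum(axis=1)
    hits = n_sig[n_sig >= min_studies].index
    rows = []
    for hid in hits:
        sig_signs = {
            k: float(np.sign(m_mat.loc[hid, k])) for k in keys if sig.loc[hid, k]
        }
        row: dict = {
            "hid": hid,
            "n_significant": int(n_sig[hid]),
            "direction_class": _classify_direction(sig_signs, aligned.species),
            "mean_abs_M": float(m_mat.loc[hid].abs().mean()),
        }
        for k in keys:
            row[f"M_{k}"] = float(m_mat.loc[hid, k])
            row[f"q_{k}"] = float(q_mat.loc[hid, k])
        rows.append(row)
    columns = (
        ["hid", "n_significant", "direction_class", "mean_abs_M"]
        + [f"M_{k}" for k in keys]
        + [f"q_{k}" for k in keys]
    )
    table = pd.DataFrame(rows, columns=columns)
    table = table.sort_values(
        "mean_abs_M", ascending=False, kind="mergesort"
    ).set_index("hid")
    return CoreBattery(table=table, q_threshold=q_threshold, min_studies=min_studies)


# ---------------------------------------------------------------------------
# direction consistency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectionTestResult:
    """One-sample, one-sided proportion test against 0.5.

    ``p_exact`` is the binomial tail; ``p_chisq`` the continuity-corrected
    chi-square variant; ``ci`` the one-sided 95% interval
    (Clopper-Pearson lower bound, 1.0).
    """

    n_expected: int
    n_total: int
    proportion: float
    p_exact: float
    p_chisq: float
    ci: tuple[float, float]


def direction_consistency_test(
    signs: Iterable[float],
    expected_direction: float = 1.0,
) -> DirectionTestResult:
    """Test whether observations fall in the expected direction more than half
    the time.

    ``signs`` are signed observations (e.g. the M of each significant
    (gene, study) pair); zeros are dropped.  Both the exact one-sided
    binomial test and the continuity-corrected chi-square variant are
    reported, with a one-sided exact 95% confidence interval.
    """
    values = [float(np.sign(s)) for s in signs if s != 0]
    if not values:
        raise ValueError("no non-zero observations")
    want = float(np.sign(expected_direction))
    k = sum(1 for v in values if v == want)
    n = len(values)
    p_exact = float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue)
    # chi-square with Yates continuity, one-sided
    correction = min(abs(k - n / 2.0), 0.5)
    chi2 = (abs(k - n / 2.0) - 0.5) ** 2 / (n / 4.0) if n > 0 else 0.0
    if abs(k - n / 2.0) <= 0.5:
        chi2 = 0.0
    p_two = float(stats.chi2.sf(chi2, df=1))
    p_chisq = p_two / 2.0 if k >= n / 2.0 else 1.0 - p_two / 2.0
    lower = float(stats.beta.ppf(0.05, k, n - k + 1)) if k > 0 else 0.0
    return DirectionTestResult(
        n_expected=k,
        n_total=n,
        proportion=k / n,
        p_exact=p_exact,
        p_chisq=p_chisq,
        ci=(lower, 1.0),
    )
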