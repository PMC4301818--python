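"""ChIP probe-level binding tests and gene-level binding fractions.

Replicate probe log-ratios near transcription start sites are tested for
enrichment (one-sample, one-sided t against zero — "preferential binding"),
probes are assigned to every gene whose TSS±1 kb interval they overlap, and
multiple probes per gene collapse liberally to the lowest p-value.  A gene
counts as bound when its best probe has p below the threshold (0.05 by
default), and the binding fraction of a gene set is the share of its genes
that are bound.  Fractions are compared across direction-of-regulation
strata and across constitutive/ligand-responsive conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffabund import DifferentialResult

__all__ = [
    "BindingSummary",
    "annotate_probes_to_genes",
    "probe_binding_test",
    "collapse_to_gene",
    "binding_fraction",
    "stratified_binding",
    "cross_condition_overlap",
    "gene_binding_summary",
]


def _replicate_columns(probes: pd.DataFrame) -> list[str]:
    cols = [c for c in probes.columns if c.startswith("rep")]
    if len(cols) < 2:
        raise ValueError("probe table needs >=2 replicate intensity columns")
    return cols


def annotate_probes_to_genes(
    probes: pd.DataFrame,
    tss_table: pd.DataFrame,
    window: int = 1000,
) -> pd.DataFrame:
    """Assign each probe to every gene whose TSS±window interval it overlaps.

    ``probes`` has columns (probe_id, chrom, start, end, rep*); ``tss_table``
    is BED-like with (chrom, start, end, gene, strand) where the TSS is the
    interval midpoint.  Probes overlapping no gene are dropped.  Returns the
    probe table with a ``gene`` column (one row per probe-gene pair).
    """
    if (probes["start"] >= probes["end"]).any():
        raise ValueError("probe intervals must satisfy start < end")
    tss_pos = ((tss_table["start"] + tss_table["end"]) // 2).to_numpy()
    genes = tss_table["gene"].to_numpy()
    chroms = tss_table["chrom"].to_numpy()
    out = []
    for chrom, grp in probes.groupby("chrom", sort=False):
        on_chrom = chroms == chrom
        if not on_chrom.any():
            continue
        lo = tss_pos[on_chrom] - window
        hi = tss_pos[on_chrom] + window
        g = genes[on_chrom]
        starts = grp["start"].to_numpy()[:, None]
        ends = grp["end"].to_numpy()[:, None]
        hit = (starts < hi[None, :]) & (ends > lo[None, :])
        probe_idx, gene_idx = np.nonzero(hit)
        if probe_idx.size:
            sub = grp.iloc[probe_idx].copy()
            sub["gene"] = g[gene_idx]
            out.append(sub)
    if not out:
        return probes.head(0).assign(gene=pd.Series(dtype=object))
    return pd.concat(out, ignore_index=True)


def probe_binding_test(intensities: Sequence[float] | np.ndarray) -> float:
    """One-sample, one-sided t-test of replicate log-ratios against zero.

    Degenerate cases: all replicates zero (or zero variance with zero mean)
    gives p = 1; zero variance with a positive mean is reported as the limit
    p = 0 with a warning; zero variance with a negative mean gives p = 1.
    """
    x = np.asarray(intensities, float)
    if x.size < 2:
        raise ValueError("need >=2 replicates")
    if np.allclose(x.std(ddof=1), 0.0):
        mean = x.mean()
        if mean > 0:
            warnings.warn(
                "zero replicate variance with non-zero mean: p reported as 0",
                stacklevel=2,
            )
            return 0.0
        return 1.0
    res = stats.ttest_1samp(x, 0.0, alternative="greater")
    return float(res.pvalue)


def collapse_to_gene(gene_probe_p: Mapping[str, Sequence[float]]) -> pd.Series:
    """Per-gene p as the minimum over the gene's probes (liberal rule)."""
    out = {}
    for gene, ps in gene_probe_p.items():
        ps = list(ps)
        if not ps:
            raise ValueError(f"gene {gene!r} has no probes")
        out[gene] = float(min(ps))
    return pd.Series(out, name="p").sort_index()


@dataclass
class BindingSummary:
    """Per-gene best-probe p-values and bound flags at a fixed threshold."""

    gene_p: pd.Series
    threshold: float = 0.05

    @property
    def bound(self) -> pd.Series:
        return self.gene_p < self.threshold

    @property
    def bound_genes(self) -> set[str]:
        return set(self.gene_p.index[self.bound])

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"p": self.gene_p, "bound": self.bound.astype(int)}
        ).rename_axis("gene").to_csv(path, sep="\t")


def gene_binding_summary(
    probes: pd.DataFrame,
    tss_table: pd.DataFrame,
    window: int = 1000,
    threshold: float = 0.05,
) -> BindingSummary:
    """Annotate, test and collapse a probe table into per-gene p-values."""
    annotated = annotate_probes_to_genes(probes, tss_table, window)
    reps = _replicate_columns(probes)
    if annotated.empty:
        return BindingSummary(gene_p=pd.Series(dtype=float), threshold=threshold)
    # vectorized one-sample one-sided t over all probes at once
    x = annotated[reps].to_numpy(float)
    k = x.shape[1]
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(k))
    pvals = stats.t.sf(t, df=k - 1)
    degenerate = np.isclose(sd, 0.0)
    pvals[degenerate & (mean > 0)] = 0.0
    pvals[degenerate & (mean <= 0)] = 1.0
    grouped = pd.DataFrame({"gene": annotated["gene"], "p": pvals})
    gene_p = grouped.groupby("gene")["p"].min().sort_index()
    return BindingSummary(gene_p=gene_p, threshold=threshold)


def binding_fraction(genes: Iterable[str], summary: BindingSummary) -> float:
    """Share of the gene set whose best probe passes the binding test.

    Genes absent from the summary must not occur; the caller restricts the
    set to genes with probe coverage first.
    """
    genes = set(genes)
    if not genes:
        raise ValueError("empty gene set")
    missing = genes - set(summary.gene_p.index)
    if missing:
        raise KeyError(
            f"{len(missing)} genes lack binding data (e.g. {sorted(missing)[:3]})"
        )
    return float(summary.bound.loc[sorted(genes)].mean())


def stratified_binding(
    result: DifferentialResult | pd.DataFrame,
    summary: BindingSummary,
    q_threshold: float = 0.05,
    gene_map=None,
) -> pd.DataFrame:
    """Binding fraction per direction-of-regulation stratum.

    The transcriptome splits into significantly up-regulated (q below
    threshold, M > 0), significantly down-regulated, and non-significant
    strata; the binding fraction of each stratum (restricted to genes with
    probe coverage) is reported with its size.  Empty strata are omitted
    with a note.
    """
    table = result.table if isinstance(result, DifferentialResult) else result
    genes = table.index.to_series().astype(str)
    if gene_map is not None:
        genes = genes.map(gene_map)
    covered = genes.isin(summary.gene_p.index).to_numpy()
    sig = (table["q"] < q_threshold).to_numpy()
    up = sig & (table["M"] > 0).to_numpy()
    down = sig & (table["M"] < 0).to_numpy()
    strata = {"up": up, "down": down, "non_significant": ~sig}
    rows = []
    for name, mask in strata.items():
        members = set(genes[mask & covered])
        if not members:
            rows.append(
                {"stratum": name, "size": 0, "fraction": np.nan,
                 "note": "empty stratum"}
            )
            continue
        rows.append(
            {
                "stratum": name,
                "size": len(members),
                "fraction": binding_fraction(members, summary),
                "note": "",
            }
        )
    return pd.DataFrame(rows)


def cross_condition_overlap(
    constitutive: Iterable[str],
    responsive: Iterable[str],
    universe: Iterable[str],
) -> pd.DataFrame:
    """2x2 contingency of ligand-responsive vs constitutively-variant genes.

    Rows: responsive / non-responsive (to ligand treatment); columns:
    constitutively variant / invariant.  Row proportions say what share of
    (non-)responsive genes also varies constitutively.
    """
    universe = set(universe)
    cset = set(constitutive) & universe
    rset = set(responsive) & universe
    rows = []
    for label, members in (
        ("responsive", rset),
        ("non_responsive", universe - rset),
    ):
        variant = len(members & cset)
        invariant = len(members) - variant
        total = len(members)
        rows.append(
            {
                "group": label,
                "constitutively_variant": variant,
                "constitutively_invariant": invariant,
                "n": total,
                "variant_proportion": variant / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)
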