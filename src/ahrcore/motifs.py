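"""AHR response element (AHRE) motif scanning and conservation scoring.

The receptor recognises degenerate DNA elements in promoter regions.  Four
patterns are scanned here, written in a small pattern grammar (exact bases,
``N`` for any base, ``[X|Y]`` alternatives, ``{Nk}`` fixed-length gaps):

====================  =======================  ======
name                  pattern                  length
====================  =======================  ======
AHRE-I_core           ``GCGTG``                5
AHRE-I_extended       ``TNGCGTG``              7
AHRE-I_full           ``[T|G]NGCGTG[A|C][G|C]A``  10
AHRE-II               ``CATG{N6}C[T|A]TG``     14
====================  =======================  ======

Windows are TSS-centred, ±3 kbp by default, 0-based half-open
``[-L/2, +L/2)`` in TSS-relative coordinates.  Both strands are scanned
(minus-strand matches use the reverse complement); overlapping matches all
count.  Each hit is scored by the mean per-base conservation (a track of
values in [0, 1], e.g. a phylogenetic-HMM score) over its footprint,
gap positions included.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AHRE_PATTERNS",
    "MotifDef",
    "MotifHit",
    "PromoterSet",
    "compile_motif",
    "default_motifs",
    "scan_window",
    "scan_promoters",
    "hit_counts",
    "score_summary",
    "class_fractions",
]

#: The four canonical AHRE patterns (name -> pattern string).
AHRE_PATTERNS: dict[str, str] = {
    "AHRE-I_core": "GCGTG",
    "AHRE-I_extended": "TNGCGTG",
    "AHRE-I_full": "[T|G]NGCGTG[A|C][G|C]A",
    "AHRE-II": "CATG{N6}C[T|A]TG",
}

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class MotifParseError(ValueError):
    pass


@dataclass(frozen=True)
class MotifDef:
    """A compiled motif: one allowed-base set per footprint position."""

    name: str
    classes: tuple[frozenset, ...]

    def __len__(self) -> int:
        return len(self.classes)

    def reverse_complement(self) -> "MotifDef":
        rc = tuple(
            frozenset(_COMPLEMENT[b] for b in cls)
            for cls in reversed(self.classes)
        )
        return MotifDef(name=self.name, classes=rc)

    def matches(self, sequence: str, pos: int = 0) -> bool:
        """True when the motif matches ``sequence`` starting at ``pos``."""
        if pos < 0 or pos + len(self) > len(sequence):
            return False
        return all(
            sequence[pos + j] in cls for j, cls in enumerate(self.classes)
        )

    def realize(self, rng: np.random.Generator) -> str:
        """One concrete instance, degenerate positions drawn uniformly."""
        return "".join(
            sorted(cls)[rng.integers(len(cls))] for cls in self.classes
        )


_TOKEN = re.compile(r"\[([ACGT](?:\|[ACGT])+)\]|\{N(\d+)\}|([ACGTN])")


def compile_motif(pattern: str, name: str | None = None) -> MotifDef:
    """Compile a pattern string into a positional class list.

    Grammar: ``A/C/G/T`` exact base, ``N`` any base, ``[X|Y]`` alternatives,
    ``{Nk}`` a run of k unconstrained positions.
    """
    classes: list[frozenset] = []
    pos = 0
    while pos < len(pattern):
        m = _TOKEN.match(pattern, pos)
        if m is None:
            raise MotifParseError(
                f"malformed motif pattern {pattern!r} at position {pos}"
            )
        alt, gap, base = m.groups()
        if alt is not None:
            classes.append(frozenset(alt.split("|")))
        elif gap is not None:
            classes.extend([_BASES] * int(gap))
        elif base == "N":
            classes.append(_BASES)
        else:
            classes.append(frozenset(base))
        pos = m.end()
    if not classes:
        raise MotifParseError("empty motif pattern")
    return MotifDef(name=name or pattern, classes=tuple(classes))


def default_motifs() -> list[MotifDef]:
    """The four AHRE motifs, compiled."""
    return [compile_motif(pat, name) for name, pat in AHRE_PATTERNS.items()]


@dataclass(frozen=True)
class MotifHit:
    """A located motif instance in a TSS-centred window.

    ``start`` is the 0-based TSS-relative coordinate of the leftmost
    footprint base on the forward strand; ``score`` is the mean per-base
    conservation over the footprint.
    """

    gene: str
    motif: str
    start: int
    strand: str
    score: float


@dataclass
class PromoterSet:
    """TSS-centred promoter windows with aligned conservation tracks.

    ``sequences``/``conservation`` map gene -> window sequence / per-base
    conservation array (both of length ``window``); ``tss`` is a BED-like
    table with columns (chrom, start, end, gene, strand).
    """

    sequences: dict[str, str]
    conservation: dict[str, np.ndarray]
    tss: pd.DataFrame
    window: int = 6000

    def __post_init__(self) -> None:
        for gene, seq in self.sequences.items():
            if len(seq) != self.window:
                raise ValueError(
                    f"promoter of {gene} has length {len(seq)} != {self.window}"
                )
            cons = np.asarray(self.conservation[gene], float)
            if cons.shape != (self.window,):
                raise ValueError(f"conservation track of {gene} misaligned")
            if cons.min() < 0 or cons.max() > 1:
                raise ValueError("conservation values must lie in [0, 1]")
            self.conservation[gene] = cons

    def write(self, fasta: str | Path, cons_tsv: str | Path, tss_tsv: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=gene, description="")
            for gene, seq in self.sequences.items()
        ]
        with open(fasta, "w") as fh:
            SeqIO.write(records, fh, "fasta")
        half = self.window // 2
        rows = []
        for gene, cons in self.conservation.items():
            rows.append(
                pd.DataFrame(
                    {
                        "gene": gene,
                        "offset": np.arange(-half, half),
                        "score": np.round(cons, 4),
                    }
                )
            )
        pd.concat(rows).to_csv(cons_tsv, sep="\t", index=False)
        self.tss.to_csv(tss_tsv, sep="\t", index=False)

    @classmethod
    def read(cls, fasta: str | Path, cons_tsv: str | Path, tss_tsv: str | Path,
             window: int = 6000) -> "PromoterSet":
        from Bio import SeqIO

        sequences = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")
        }
        cons = pd.read_csv(cons_tsv, sep="\t")
        half = window // 2
        conservation = {}
        for gene, grp in cons.groupby("gene", sort=False):
            track = np.full(window, np.nan)
            track[grp["offset"].to_numpy() + half] = grp["score"].to_numpy()
            conservation[str(gene)] = track
        tss = pd.read_csv(tss_tsv, sep="\t")
        return cls(sequences=sequences, conservation=conservation,
                   tss=tss, window=window)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _match_positions(seq_arr: np.ndarray, motif: MotifDef) -> np.ndarray:
    """0-based window positions where the motif matches the forward text."""
    n = seq_arr.size - len(motif) + 1
    if n <= 0:
        return np.empty(0, dtype=int)
    ok = np.ones(n, dtype=bool)
    for j, cls in enumerate(motif.classes):
        if cls == _BASES:
            continue
        allowed = np.frombuffer("".join(sorted(cls)).encode(), dtype="S1")
        ok &= np.isin(seq_arr[j:j + n], allowed)
    return np.nonzero(ok)[0]


def scan_window(
    sequence: str,
    conservation: Sequence[float] | np.ndarray,
    motifs: Iterable[MotifDef] | None = None,
    strands: Sequence[str] = ("+", "-"),
    gene: str = "",
) -> list[MotifHit]:
    """Scan one TSS-centred window for motif instances on both strands.

    Every position/strand whose footprint matches yields one hit; a
    minus-strand hit is a forward-text match of the motif's reverse
    complement, reported at its forward-strand footprint start.  Offsets are
    TSS-relative (window midpoint = TSS).
    """
    cons = np.asarray(conservation, float)
    if cons.shape != (len(sequence),):
        raise ValueError(
            f"conservation track length {cons.shape} does not match "
            f"sequence length {len(sequence)}"
        )
    if motifs is None:
        motifs = default_motifs()
    half = len(sequence) // 2
    seq_arr = np.frombuffer(sequence.upper().encode(), dtype="S1")
    csum = np.concatenate([[0.0], np.cumsum(cons)])
    hits: list[MotifHit] = []
    for motif in motifs:
        L = len(motif)
        for strand in strands:
            target = motif if strand == "+" else motif.reverse_complement()
            for pos in _match_positions(seq_arr, target):
                score = (csum[pos + L] - csum[pos]) / L
                hits.append(
                    MotifHit(
                        gene=gene,
                        motif=motif.name,
                        start=int(pos) - half,
                        strand=strand,
                        score=float(score),
                    )
                )
    return hits


def scan_promoters(
    promoters: PromoterSet,
    motifs: Iterable[MotifDef] | None = None,
    strands: Sequence[str] = ("+", "-"),
) -> pd.DataFrame:
    """Scan every promoter window; returns a tidy hits table.

    Columns: gene, motif, start (TSS-relative), strand, score.
    """
    if motifs is None:
        motifs = default_motifs()
    motifs = list(motifs)
    rows = []
    for gene in promoters.sequences:
        for hit in scan_window(
            promoters.sequences[gene],
            promoters.conservation[gene],
            motifs,
            strands,
            gene=gene,
        ):
            rows.append((hit.gene, hit.motif, hit.start, hit.strand, hit.score))
    return pd.DataFrame(
        rows, columns=["gene", "motif", "start", "strand", "score"]
    )


def hit_counts(hits: pd.DataFrame, genes: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-gene x per-motif hit counts (zero-filled over ``genes``)."""
    counts = (
        hits.groupby(["gene", "motif"]).size().unstack(fill_value=0)
        if len(hits)
        else pd.DataFrame()
    )
    for name in AHRE_PATTERNS:
        if name not in counts.columns:
            counts[name] = 0
    if genes is not None:
        counts = counts.reindex(list(genes), fill_value=0)
    return counts[list(AHRE_PATTERNS)].astype(int)


def score_summary(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-gene x per-motif conservation aggregation (mean and max)."""
    if not len(hits):
        return pd.DataFrame(columns=["gene", "motif", "mean_score", "max_score"])
    agg = hits.groupby(["gene", "motif"])["score"].agg(["mean", "max"])
    agg.columns = ["mean_score", "max_score"]
    return agg.reset_index()


def class_fractions(
    counts: pd.DataFrame,
    significant: Iterable[str],
    non_significant: Iterable[str],
    motif: str | None = None,
    thresholds: Sequence[int] = (1, 2, 3),
) -> pd.DataFrame:
    """Fractions of genes carrying >= k motif instances, per gene class.

    ``counts`` is the per-gene count table from :func:`hit_counts`; classes
    must be disjoint and non-empty.  When ``motif`` is None every motif is
    reported.  The returned table has one row per (motif, threshold) with the
    fraction of significant / non-significant genes at or above the count.
    """
    sig = set(significant)
    non = set(non_significant)
    if not sig or not non:
        raise ValueError("both gene classes must be non-empty")
    if sig & non:
        raise ValueError("gene classes must be disjoint")
    motif_names = [motif] if motif else list(counts.columns)
    rows = []
    for name in motif_names:
        sig_counts = counts.reindex(sorted(sig), fill_value=0)[name]
        non_counts = counts.reindex(sorted(non), fill_value=0)[name]
        for k in thresholds:
            rows.append(
                {
                    "motif": name,
                    "min_count": k,
                    "significant_fraction": float((sig_counts >= k).mean()),
                    "non_significant_fraction": float((non_counts >= k).mean()),
                }
            )
    return pd.DataFrame(rows)
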