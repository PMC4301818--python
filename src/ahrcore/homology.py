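"""Cross-species alignment of per-study results through homology IDs.

Each species' platform maps gene IDs to integer homology identifiers (HIDs),
a surrogate for gene homology across species.  Cleaning removes genes with
no HID and, by default, every member of a many-to-one HID group within a
species (strict de-duplication — no arbitrary representative is kept; a
``keep_first`` policy is available).  Studies are then aligned on the
intersection of the cleaned per-study HID sets: the shared universe against
which all set-level statistics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .diffabund import DifferentialResult

__all__ = [
    "HomologyMap",
    "AlignedResults",
    "clean_map",
    "align_studies",
]

DuplicatePolicy = Literal["drop_all", "keep_first"]


class AlignmentError(ValueError):
    pass


@dataclass
class HomologyMap:
    """(species, gene_id, hid) records; ``hid`` is a nullable positive int."""

    records: pd.DataFrame
    n_genes: int | None = None  # ground-truth universe size, when known

    def __post_init__(self) -> None:
        required = {"species", "gene_id", "hid"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"homology table lacks columns {sorted(missing)}")
        recs = self.records.copy()
        recs["hid"] = recs["hid"].astype("Int64")
        if (recs["hid"].dropna() <= 0).any():
            raise ValueError("HIDs must be positive")
        dup = recs.duplicated(subset=["species", "gene_id"])
        if dup.any():
            raise ValueError("gene_id must be unique within species")
        self.records = recs

    def species_table(self, species: str) -> pd.DataFrame:
        return self.records[self.records["species"] == species]

    def hid_sets(self) -> dict[str, set[int]]:
        """Mapped HID set per species (no cleaning applied)."""
        out = {}
        for species, grp in self.records.groupby("species"):
            out[str(species)] = set(grp["hid"].dropna().astype(int))
        return out

    def write_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "HomologyMap":
        recs = pd.read_csv(path, sep="\t", dtype={"species": str, "gene_id": str})
        return cls(records=recs)


def clean_map(
    hmap: HomologyMap, duplicate_policy: DuplicatePolicy = "drop_all"
) -> HomologyMap:
    """Apply the removal rules: unannotated genes and duplicate HID groups.

    ``drop_all`` (default) removes every member of a within-species
    many-to-one HID group; ``keep_first`` keeps the first record of each
    group in table order.  Cleaning is idempotent under either policy.
    """
    recs = hmap.records.dropna(subset=["hid"]).copy()
    if duplicate_policy == "drop_all":
        recs = recs[~recs.duplicated(subset=["species", "hid"], keep=False)]
    elif duplicate_policy == "keep_first":
        recs = recs[~recs.duplicated(subset=["species", "hid"], keep="first")]
    else:
        raise ValueError(f"unknown duplicate policy {duplicate_policy!r}")
    return HomologyMap(records=recs.reset_index(drop=True), n_genes=hmap.n_genes)


@dataclass
class AlignedResults:
    """Per-study differential results re-keyed on a shared HID universe.

    ``universe`` is the ordered list of HIDs present on every study's
    cleaned platform; each table in ``results`` has exactly one row per
    universe HID.  ``species`` records the species label per study key.
    """

    universe: list[int]
    results: dict[str, pd.DataFrame]
    species: dict[str, str]

    def __post_init__(self) -> None:
        for key, table in self.results.items():
            if len(table) != len(self.universe):
                raise AlignmentError(
                    f"study {key!r} has {len(table)} rows, expected "
                    f"{len(self.universe)}"
                )

    @property
    def n(self) -> int:
        return len(self.universe)

    def significant_sets(self, q_threshold: float = 0.05) -> dict[str, set[int]]:
        return {
            key: set(tab.index[tab["q"] < q_threshold])
            for key, tab in self.results.items()
        }

    def signs(self) -> pd.DataFrame:
        """Sign of M per HID (rows) and study (columns)."""
        import numpy as np

        return pd.DataFrame(
            {key: np.sign(tab["M"]) for key, tab in self.results.items()}
        )

    def write_tsv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.Series(self.universe, name="hid").to_csv(
            outdir / "universe.tsv", sep="\t", index=False
        )
        for key, table in self.results.items():
            table.to_csv(outdir / f"aligned_{key}.tsv", sep="\t")

    @classmethod
    def read_tsv(cls, outdir: str | Path,
                 species: Mapping[str, str] | None = None) -> "AlignedResults":
        outdir = Path(outdir)
        universe = pd.read_csv(outdir / "universe.tsv", sep="\t")["hid"].tolist()
        results = {}
        for path in sorted(outdir.glob("aligned_*.tsv")):
            key = path.stem[len("aligned_"):]
            results[key] = pd.read_csv(path, sep="\t", index_col=0)
        spec = dict(species) if species else {
            key: key.split("_", 1)[0] for key in results
        }
        return cls(universe=universe, results=results, species=spec)


def align_studies(
    results: Sequence[DifferentialResult],
    hmap: HomologyMap,
    duplicate_policy: DuplicatePolicy = "drop_all",
) -> AlignedResults:
    """Re-key per-study results by HID on the cross-platform universe.

    The universe is the intersection, over studies, of the cleaned HIDs
    whose gene is actually present in that study's result table; genes
    outside the universe are dropped.  Raises when the intersection is
    empty.
    """
    if not results:
        raise AlignmentError("no studies to align")
    cleaned = clean_map(hmap, duplicate_policy)
    universe: set[int] | None = None
    per_study_maps: list[pd.Series] = []
    for res in results:
        table = cleaned.species_table(res.species)
        if table.empty:
            raise AlignmentError(
                f"homology map has no entries for species {res.species!r}"
            )
        gene_to_hid = table.set_index("gene_id")["hid"].astype(int)
        present = gene_to_hid[gene_to_hid.index.isin(res.table.index)]
        per_study_maps.append(present)
        hids = set(present)
        universe = hids if universe is None else universe & hids
    if not universe:
        raise AlignmentError("aligned universe is empty: no shared HIDs")
    ordered = sorted(universe)
    aligned: dict[str, pd.DataFrame] = {}
    species: dict[str, str] = {}
    for res, gene_to_hid in zip(results, per_study_maps):
        mapping = gene_to_hid[gene_to_hid.isin(universe)]
        table = res.table.loc[mapping.index].copy()
        table.index = pd.Index(mapping.values, name="hid")
        aligned[res.key] = table.loc[ordered]
        species[res.key] = res.species
    return AlignedResults(universe=ordered, results=aligned, species=species)
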