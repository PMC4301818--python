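"""Synthetic inputs with known ground truth for the whole pipeline.

The generator emulates a cross-species constitutive-expression study at the
normalized-matrix level: two species, several tissues, a small planted
"core battery" of genes whose abundance depends on receptor genotype in
every tissue, i.i.d. Gaussian log2 noise, a homology table with unmapped and
many-to-one entries, TSS-centred promoter windows carrying planted response
elements with elevated conservation, replicate ChIP probe intensities for a
known bound-gene set, and a small rooted ontology DAG with gene annotations.

Identifier scheme: genes have a canonical index ``i`` (0-based) shared
across resources.  The canonical gene id is ``g{i+1:05d}``; the homology
identifier (HID) is the integer ``i+1``; species-level expression rows use
``{species}_g{i+1:05d}``.  Promoters, probe tables, chromosome assignments
and ontology annotations are keyed by the canonical gene id.

All randomness flows from ``SimulationConfig.seed`` through fixed
``numpy.random.SeedSequence`` spawn keys, one stream per artifact, so any
artifact can be regenerated independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diffabund import ExpressionStudy
from .homology import HomologyMap
from .goenrich import GoDag
from .motifs import AHRE_PATTERNS, PromoterSet, compile_motif

__all__ = [
    "StudyDesign",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticData",
    "default_studies",
    "gene_id",
    "hid_to_gene_id",
    "make_ground_truth",
    "generate_study",
    "generate_homology_map",
    "generate_promoters",
    "generate_binding_probes",
    "generate_go_dag",
    "gene_chromosomes",
    "tss_table",
    "generate_all",
    "write_all",
]

N_CHROMOSOMES = 20

# fixed spawn keys: one independent random stream per artifact
_STREAM_STUDY = 0
_STREAM_HOMOLOGY = 1
_STREAM_PROMOTERS = 2
_STREAM_BINDING = 3
_STREAM_DAG = 4
_STREAM_TRUTH = 5


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class StudyDesign:
    species: str
    tissue: str
    n_active: int
    n_less_active: int


def default_studies() -> tuple[StudyDesign, ...]:
    """Five studies, two species x several tissues, n=4 per genotype group."""
    return (
        StudyDesign("mouse", "kidney", 4, 4),
        StudyDesign("mouse", "liver", 4, 4),
        StudyDesign("rat", "liver", 4, 4),
        StudyDesign("rat", "adipose", 4, 4),
        StudyDesign("rat", "hypothalamus", 4, 4),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults: 2,000 genes, five studies (two species), a 20-gene battery
    planted with a 1.0 log2 shift (within the fold-change range reported for
    constitutive receptor targets) against 0.5 log2 replicate noise, 90% of
    genes homology-mapped with 5% many-to-one collisions, and 6 kb (±3 kb)
    promoter windows.
    """

    n_genes: int = 2000
    studies: tuple[StudyDesign, ...] = field(default_factory=default_studies)
    battery_size: int = 20
    effect_size_log2: float = 1.0
    noise_sd_log2: float = 0.5
    species_flip_fraction: float = 0.2
    homology_mapped_fraction: float = 0.9
    homology_duplicate_fraction: float = 0.05
    promoter_length: int = 6000
    motif_rate: float = 0.5
    motif_rate_battery: float = 2.0
    n_binding_replicates: int = 3
    binding_shift_log2: float = 1.0
    binding_sd_log2: float = 1.0
    bound_background_rate: float = 0.05
    n_go_terms: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not self.studies:
            raise ConfigurationError("at least one study is required")
        if self.battery_size > self.n_genes:
            raise ConfigurationError("battery_size must not exceed n_genes")
        for d in self.studies:
            if d.n_active < 2 or d.n_less_active < 2:
                raise ConfigurationError(
                    f"{d.species}/{d.tissue}: all group sizes must be >= 2"
                )
        if self.noise_sd_log2 < 0:
            raise ConfigurationError("noise_sd_log2 must be >= 0")
        for frac in (
            self.homology_mapped_fraction,
            self.homology_duplicate_fraction,
            self.species_flip_fraction,
            self.bound_background_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("fractions must lie in [0, 1]")
        if self.promoter_length <= 0 or self.promoter_length % 2:
            raise ConfigurationError("promoter_length must be a positive even integer")
        if self.n_binding_replicates < 2:
            raise ConfigurationError("need >= 2 binding replicates")

    @property
    def species_list(self) -> list[str]:
        seen: list[str] = []
        for d in self.studies:
            if d.species not in seen:
                seen.append(d.species)
        return seen

    def rng(self, *spawn_key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=spawn_key)
        )


def gene_id(index: int) -> str:
    """Canonical gene id for 0-based gene ``index``."""
    return f"g{index + 1:05d}"


def hid_to_gene_id(hid: int) -> str:
    """Canonical gene id of the homology group ``hid`` (HID = index + 1)."""
    return gene_id(int(hid) - 1)


def species_gene_id(species: str, index: int) -> str:
    return f"{species}_{gene_id(index)}"


@dataclass
class GroundTruth:
    """What was planted: battery effects, motif instances, bound genes.

    ``battery_effects`` maps canonical gene id -> per-study-index signed log2
    effect; ``planted_motifs`` maps canonical gene id -> list of
    (motif name, TSS-relative offset, strand); ``bound_genes`` is the set of
    canonical gene ids with a real ChIP signal.
    """

    battery_effects: dict[str, dict[int, float]]
    planted_motifs: dict[str, list[tuple[str, int, str]]]
    bound_genes: set[str]

    @property
    def battery_genes(self) -> set[str]:
        return set(self.battery_effects)

    def battery_hids(self) -> set[int]:
        return {int(g[1:]) for g in self.battery_effects}


def make_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Deterministically derive the planted truth from the configuration."""
    rng = config.rng(_STREAM_TRUTH)
    battery_idx = np.sort(
        rng.choice(config.n_genes, size=config.battery_size, replace=False)
    )
    species = config.species_list
    # per-gene sign by species: base direction is "up in less-active";
    # a configurable fraction of battery genes flips sign in the 2nd+ species
    flips = rng.random(config.battery_size) < config.species_flip_fraction
    battery_effects: dict[str, dict[int, float]] = {}
    for g_pos, (idx, flip) in enumerate(zip(battery_idx, flips)):
        per_study: dict[int, float] = {}
        for s_i, design in enumerate(config.studies):
            sign = 1.0
            if flip and species.index(design.species) > 0:
                sign = -1.0
            per_study[s_i] = sign * config.effect_size_log2
        battery_effects[gene_id(int(idx))] = per_study

    # planted motif instances: Poisson counts, higher rate for battery genes
    motif_names = list(AHRE_PATTERNS)
    motif_lengths = {
        name: len(compile_motif(pat, name)) for name, pat in AHRE_PATTERNS.items()
    }
    half = config.promoter_length // 2
    battery_set = set(int(i) for i in battery_idx)
    planted: dict[str, list[tuple[str, int, str]]] = {}
    rates = np.where(
        np.isin(np.arange(config.n_genes), battery_idx),
        config.motif_rate_battery,
        config.motif_rate,
    )
    counts = rng.poisson(rates)
    for idx in range(config.n_genes):
        if counts[idx] == 0:
            continue
        entries = []
        for _ in range(counts[idx]):
            name = motif_names[rng.integers(len(motif_names))]
            length = motif_lengths[name]
            offset = int(rng.integers(-half, half - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            entries.append((name, offset, strand))
        planted[gene_id(idx)] = entries

    # bound genes: the battery plus a background fraction
    background = rng.random(config.n_genes) < config.bound_background_rate
    bound = {gene_id(i) for i in range(config.n_genes)
             if background[i] or i in battery_set}
    return GroundTruth(
        battery_effects=battery_effects,
        planted_motifs=planted,
        bound_genes=bound,
    )


# ---------------------------------------------------------------------------
# expression studies
# ---------------------------------------------------------------------------

def generate_study(
    config: SimulationConfig,
    study_index: int,
    truth: GroundTruth | None = None,
) -> ExpressionStudy:
    """One normalized log2 expression study.

    Abundance = per-gene baseline + genotype effect (battery genes only, in
    the less-active group) + i.i.d. Gaussian noise with sd
    ``noise_sd_log2``.  Deterministic given config + seed.
    """
    if not 0 <= study_index < len(config.studies):
        raise ConfigurationError(f"study_index {study_index} out of range")
    if truth is None:
        truth = make_ground_truth(config)
    design = config.studies[study_index]
    rng = config.rng(_STREAM_STUDY, study_index)
    n = config.n_genes
    n1, n2 = design.n_active, design.n_less_active

    baseline = rng.normal(8.0, 2.0, size=n)
    effect = np.zeros(n)
    for gene, per_study in truth.battery_effects.items():
        effect[int(gene[1:]) - 1] = per_study[study_index]
    noise = rng.normal(0.0, config.noise_sd_log2, size=(n, n1 + n2))
    matrix = baseline[:, None] + noise
    matrix[:, n1:] += effect[:, None]

    sample_ids = [
        f"{design.species}_{design.tissue}_active_{k + 1}" for k in range(n1)
    ] + [
        f"{design.species}_{design.tissue}_lessactive_{k + 1}" for k in range(n2)
    ]
    genotype = ["active"] * n1 + ["less_active"] * n2
    return ExpressionStudy(
        gene_ids=[species_gene_id(design.species, i) for i in range(n)],
        sample_ids=sample_ids,
        matrix=matrix,
        genotype=genotype,
        species=design.species,
        tissue=design.tissue,
    )


# ---------------------------------------------------------------------------
# homology map
# ---------------------------------------------------------------------------

def generate_homology_map(config: SimulationConfig) -> HomologyMap:
    """Per-species gene -> HID table with unmapped and many-to-one entries.

    Each gene maps to its own HID with probability ``mapped_fraction``; a
    ``duplicate_fraction`` of mapped genes instead takes the HID of another
    random gene, creating many-to-one groups that downstream cleaning drops.
    """
    rng = config.rng(_STREAM_HOMOLOGY)
    n = config.n_genes
    frames = []
    for species in config.species_list:
        mapped = rng.random(n) < config.homology_mapped_fraction
        dup = rng.random(n) < config.homology_duplicate_fraction
        donors = rng.integers(0, n, size=n)
        hid = np.arange(1, n + 1, dtype=float)
        hid[dup] = donors[dup] + 1
        hid[~mapped] = np.nan
        frames.append(
            pd.DataFrame(
                {
                    "species": species,
                    "gene_id": [species_gene_id(species, i) for i in range(n)],
                    "hid": hid,
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    records["hid"] = records["hid"].astype("Int64")
    return HomologyMap(records=records, n_genes=n)


# ---------------------------------------------------------------------------
# promoters, conservation, TSS
# ---------------------------------------------------------------------------

def gene_chromosomes(config: SimulationConfig) -> dict[str, str]:
    """Deterministic round-robin chromosome assignment for every gene."""
    return {
        gene_id(i): f"chr{(i % N_CHROMOSOMES) + 1}"
        for i in range(config.n_genes)
    }


def _tss_position(index: int) -> int:
    return 100_000 + (index // N_CHROMOSOMES) * 20_000


def tss_table(config: SimulationConfig, genes: Sequence[str] | None = None) -> pd.DataFrame:
    """BED-like TSS table (chrom, start, end, gene, strand) for ``genes``."""
    half = config.promoter_length // 2
    chroms = gene_chromosomes(config)
    if genes is None:
        genes = [gene_id(i) for i in range(config.n_genes)]
    rows = []
    for gene in genes:
        idx = int(gene[1:]) - 1
        tss = _tss_position(idx)
        rows.append((chroms[gene], tss - half, tss + half, gene, "+"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "strand"])


def generate_promoters(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
    genes: Sequence[str] | None = None,
) -> PromoterSet:
    """Uniform-random promoter windows with planted motifs and conservation.

    Background bases are uniform over ACGT; planted instances are concrete
    realizations of the named motif written at the recorded TSS-relative
    offset (reverse-complemented for minus-strand plants).  Conservation is
    Beta(1,3) background and Beta(8,1) over planted footprints, keeping the
    two score distributions well separated (an arbitrary but documented
    choice).
    """
    if truth is None:
        truth = make_ground_truth(config)
    rng = config.rng(_STREAM_PROMOTERS)
    L = config.promoter_length
    half = L // 2
    if genes is None:
        genes = [gene_id(i) for i in range(config.n_genes)]
    motif_defs = {name: compile_motif(pat, name) for name, pat in AHRE_PATTERNS.items()}
    bases = np.frombuffer(b"ACGT", dtype="S1")
    sequences: dict[str, str] = {}
    conservation: dict[str, np.ndarray] = {}
    for gene in genes:
        seq = rng.integers(0, 4, size=L)
        cons = rng.beta(1.0, 3.0, size=L)
        for name, offset, strand in truth.planted_motifs.get(gene, []):
            motif = motif_defs[name]
            mlen = len(motif)
            pos = offset + half
            if pos < 0 or pos + mlen > L:
                raise ConfigurationError(
                    f"planted motif offset {offset} outside ±{half} window"
                )
            instance = motif.realize(rng)
            if strand == "-":
                instance = "".join(
                    {"A": "T", "C": "G", "G": "C", "T": "A"}[b]
                    for b in reversed(instance)
                )
            seq[pos:pos + mlen] = np.array(["ACGT".index(b) for b in instance])
            cons[pos:pos + mlen] = rng.beta(8.0, 1.0, size=mlen)
        sequences[gene] = bases[seq].tobytes().decode()
        conservation[gene] = cons
    return PromoterSet(
        sequences=sequences,
        conservation=conservation,
        tss=tss_table(config, genes),
        window=L,
    )


# ---------------------------------------------------------------------------
# binding probes
# ---------------------------------------------------------------------------

def generate_binding_probes(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Replicate ChIP probe log-ratios near each TSS.

    Bound genes receive probes with mean ``binding_shift_log2``; unbound
    genes mean 0; all probes carry ``n_binding_replicates`` replicate
    intensity columns with sd ``binding_sd_log2``.  Probe coordinates fall
    within ±1 kb of the TSS.
    """
    if truth is None:
        truth = make_ground_truth(config)
    rng = config.rng(_STREAM_BINDING)
    if genes is None:
        genes = [gene_id(i) for i in range(config.n_genes)]
    chroms = gene_chromosomes(config)
    reps = config.n_binding_replicates
    rows = []
    for gene in genes:
        idx = int(gene[1:]) - 1
        tss = _tss_position(idx)
        n_probes = 1 + rng.poisson(1.5)
        centers = rng.integers(tss - 800, tss + 800, size=n_probes)
        shift = config.binding_shift_log2 if gene in truth.bound_genes else 0.0
        for j, center in enumerate(centers):
            intens = rng.normal(shift, config.binding_sd_log2, size=reps)
            rows.append(
                (f"{gene}_p{j + 1}", chroms[gene], int(center) - 25,
                 int(center) + 25, *np.round(intens, 6))
            )
    cols = ["probe_id", "chrom", "start", "end"] + [
        f"rep{r + 1}" for r in range(reps)
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# ontology DAG
# ---------------------------------------------------------------------------

def generate_go_dag(config: SimulationConfig) -> GoDag:
    """A small rooted ontology DAG with ancestor-propagated annotations.

    Four levels below a single root; roughly a third of non-root terms get a
    second parent from the level above (diamonds).  Leaf terms directly
    annotate random gene subsets of size 5-40; ancestors inherit the union
    of their descendants' genes.
    """
    rng = config.rng(_STREAM_DAG)
    n_terms = max(config.n_go_terms, 8)
    term_ids = [f"T{k:03d}" for k in range(n_terms)]
    # split terms into 4 levels below the root
    n_mid1 = max(2, n_terms // 6)
    n_mid2 = max(3, n_terms // 3)
    root = term_ids[0]
    level1 = term_ids[1:1 + n_mid1]
    level2 = term_ids[1 + n_mid1:1 + n_mid1 + n_mid2]
    leaves = term_ids[1 + n_mid1 + n_mid2:]
    edges: list[tuple[str, str]] = [(t, root) for t in level1]
    for child_level, parent_level in ((level2, level1), (leaves, level2)):
        for term in child_level:
            parents = rng.choice(
                len(parent_level),
                size=min(len(parent_level), 1 + (rng.random() < 0.34)),
                replace=False,
            )
            for p in parents:
                edges.append((term, parent_level[p]))
    annotations: dict[str, set[str]] = {}
    for term in leaves:
        size = int(rng.integers(5, 41))
        picked = rng.choice(config.n_genes, size=min(size, config.n_genes),
                            replace=False)
        annotations[term] = {gene_id(int(i)) for i in picked}
    return GoDag(edges=edges, annotations=annotations)


# ---------------------------------------------------------------------------
# bundle + persistence
# ---------------------------------------------------------------------------

@dataclass
class SyntheticData:
    config: SimulationConfig
    truth: GroundTruth
    studies: list[ExpressionStudy]
    homology: HomologyMap
    promoters: PromoterSet
    probes: pd.DataFrame
    dag: GoDag
    chromosomes: dict[str, str]


def generate_all(
    config: SimulationConfig,
    promoter_genes: Sequence[str] | None = None,
) -> SyntheticData:
    """Generate every pipeline input from one configuration."""
    truth = make_ground_truth(config)
    studies = [
        generate_study(config, i, truth) for i in range(len(config.studies))
    ]
    return SyntheticData(
        config=config,
        truth=truth,
        studies=studies,
        homology=generate_homology_map(config),
        promoters=generate_promoters(config, truth, promoter_genes),
        probes=generate_binding_probes(config, truth),
        dag=generate_go_dag(config),
        chromosomes=gene_chromosomes(config),
    )


def write_all(data: SyntheticData, outdir: str | Path) -> list[Path]:
    """Write every artifact as plain-text tables under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _path(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    for study in data.studies:
        study.write_tsv(
            _path(f"expr_{study.key}.tsv"), _path(f"samples_{study.key}.tsv")
        )
    data.homology.write_tsv(_path("homology.tsv"))
    data.promoters.write(
        _path("promoters.fasta"), _path("conservation.tsv"), _path("tss.tsv")
    )
    data.probes.to_csv(_path("binding_probes.tsv"), sep="\t", index=False)
    data.dag.write_tsv(_path("go_edges.tsv"), _path("go_annotations.tsv"))
    pd.DataFrame(
        sorted(data.chromosomes.items()), columns=["gene", "chrom"]
    ).to_csv(_path("chromosomes.tsv"), sep="\t", index=False)
    truth_rows = [
        {"gene": g, "study_index": s, "effect_log2": e}
        for g, per in sorted(data.truth.battery_effects.items())
        for s, e in sorted(per.items())
    ]
    pd.DataFrame(truth_rows).to_csv(
        _path("truth_battery.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        {"gene": sorted(data.truth.bound_genes)}
    ).to_csv(_path("truth_bound.tsv"), sep="\t", index=False)
    return written
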