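"""End-to-end orchestration: synthesis -> per-study tests -> cross-species
alignment -> overlap / motif / binding / ontology stages -> run report.

All randomness flows from one root seed through fixed per-stage spawn keys;
no stage touches global random state, so identical configurations produce
byte-identical reports.  Every written artifact is hashed into a MANIFEST.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import binding as binding_mod
from . import diffabund, goenrich, homology, motifs, overlap, synthdata
from .synthdata import SimulationConfig, StudyDesign, hid_to_gene_id

logger = logging.getLogger("ahrcore")

__all__ = ["RunConfig", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and synthesis parameters for one pipeline run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    q_gene: float = 0.05
    q_go: float = 0.01
    bootstrap_reps: int = 100_000
    min_studies: int = 4
    qc_threshold: float = 0.8
    n_go_permutations: int = 1000
    n_promoter_genes: int = 200
    multi_tissue_min: int = 2
    outdir: str = "ahrcore_run"

    def __post_init__(self) -> None:
        for thr in (self.q_gene, self.q_go):
            if not 0.0 < thr < 1.0:
                raise ValueError("q thresholds must lie in (0, 1)")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        studies = sim_raw.pop("studies", None)
        if studies is not None:
            sim_raw["studies"] = tuple(StudyDesign(**s) for s in studies)
        return cls(sim=SimulationConfig(**sim_raw), **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["sim"]["studies"] = [asdict(s) for s in self.sim.studies]
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _round(obj: Any, digits: int = 6) -> Any:
    """Recursively round floats for a stable, readable report."""
    if isinstance(obj, dict):
        return {k: _round(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, digits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), digits)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def _promoter_gene_set(config: RunConfig, truth) -> list[str]:
    """Battery genes plus evenly spaced background genes (deterministic)."""
    n = config.sim.n_genes
    want = min(config.n_promoter_genes, n)
    chosen = set(truth.battery_genes)
    step = max(1, n // max(1, want))
    for i in range(0, n, step):
        if len(chosen) >= want:
            break
        chosen.add(synthdata.gene_id(i))
    return sorted(chosen)


@_stage("synthesis")
def _synthesize(config: RunConfig):
    truth = synthdata.make_ground_truth(config.sim)
    return synthdata.generate_all(
        config.sim, promoter_genes=_promoter_gene_set(config, truth)
    )


def run_all(config: RunConfig, write_outputs: bool = True) -> dict:
    """Run every stage; returns (and optionally writes) the run report."""
    outdir = Path(config.outdir)
    data = _synthesize(config)
    truth = data.truth
    report: dict[str, Any] = {
        "config": {
            "seed": config.sim.seed,
            "n_genes": config.sim.n_genes,
            "battery_size": config.sim.battery_size,
            "effect_size_log2": config.sim.effect_size_log2,
            "noise_sd_log2": config.sim.noise_sd_log2,
            "q_gene": config.q_gene,
            "q_go": config.q_go,
            "min_studies": config.min_studies,
            "bootstrap_reps": config.bootstrap_reps,
        }
    }

    # --- QC -----------------------------------------------------------
    @_stage("qc")
    def _qc():
        out = {}
        for study in data.studies:
            rep = diffabund.qc_outlier_screen(study, config.qc_threshold)
            out[study.key] = {
                "flagged": rep.flagged,
                "min_median_correlation": float(
                    np.nanmin(rep.median_correlation.to_numpy())
                ),
            }
        return out

    report["qc"] = _qc()

    # --- per-study differential abundance ------------------------------
    @_stage("differential")
    def _diff():
        results = [diffabund.fit_study(s) for s in data.studies]
        counts = {
            r.key: int(len(r.significant(config.q_gene))) for r in results
        }
        return results, counts

    results, probe_level_counts = _diff()
    report["significant_counts_platform"] = probe_level_counts

    # --- homology alignment --------------------------------------------
    @_stage("homology")
    def _align():
        aligned = homology.align_studies(results, data.homology)
        sig_sets = aligned.significant_sets(config.q_gene)
        return aligned, sig_sets

    aligned, sig_sets = _align()
    report["universe_size"] = aligned.n
    report["significant_counts_aligned"] = {
        k: len(v) for k, v in sig_sets.items()
    }

    # --- pairwise overlap + bootstrap ----------------------------------
    @_stage("overlap")
    def _overlap():
        pairs = overlap.all_pairwise(sig_sets, aligned.n)
        # joint overlap bootstrap over the species with the most studies
        by_species: dict[str, list[str]] = {}
        for key, sp in aligned.species.items():
            by_species.setdefault(sp, []).append(key)
        species, keys = max(by_species.items(), key=lambda kv: len(kv[1]))
        boot = None
        if len(keys) >= 3:
            sets = [sig_sets[k] for k in keys]
            joint = set.intersection(*sets)
            boot = overlap.bootstrap_multiset_overlap(
                sizes=[len(s) for s in sets],
                n=aligned.n,
                observed=len(joint),
                reps=config.bootstrap_reps,
                seed=config.sim.rng(100),
            )
            boot_dict = {
                "species": species,
                "study_keys": keys,
                "sizes": [len(s) for s in sets],
                "observed": boot.observed,
                "reps": boot.reps,
                "exceed_count": boot.exceed_count,
                "p": boot.p_report,
                "p_pseudocount": boot.p_pseudocount,
                "perm_mean": boot.perm_mean,
            }
        else:
            boot_dict = {"note": f"species {species} has < 3 studies"}
        return pairs, boot_dict

    pair_table, boot_dict = _overlap()
    report["pairwise_overlap"] = _round(pair_table.to_dict(orient="records"))
    report["bootstrap"] = _round(boot_dict)

    # --- core battery ---------------------------------------------------
    @_stage("battery")
    def _battery():
        battery = overlap.core_battery(
            aligned, q_threshold=config.q_gene, min_studies=config.min_studies
        )
        truth_hids = truth.battery_hids() & set(aligned.universe)
        found = battery.genes
        tp = len(found & truth_hids)
        sensitivity = tp / len(truth_hids) if truth_hids else float("nan")
        fdr = (len(found) - tp) / len(found) if found else 0.0
        sig_m = [
            battery.table.loc[h, f"M_{k}"]
            for h in battery.table.index
            for k in aligned.results
            if battery.table.loc[h, f"q_{k}"] < config.q_gene
        ]
        direction = (
            overlap.direction_consistency_test(sig_m, expected_direction=1.0)
            if sig_m
            else None
        )
        return battery, {
            "n_battery": len(found),
            "recoverable_truth_genes": len(truth_hids),
            "sensitivity": sensitivity,
            "fdr": fdr,
            "direction_classes": battery.table["direction_class"]
            .value_counts()
            .to_dict(),
            "direction_test": (
                {
                    "proportion": direction.proportion,
                    "n": direction.n_total,
                    "p_exact": direction.p_exact,
                    "ci_low": direction.ci[0],
                }
                if direction
                else None
            ),
        }

    battery, battery_summary = _battery()
    report["battery"] = _round(battery_summary)

    # --- chromosome bias ------------------------------------------------
    @_stage("chromosome_bias")
    def _chrom():
        universe_genes = [hid_to_gene_id(h) for h in aligned.universe]
        out = {}
        for key, hids in sig_sets.items():
            table = overlap.chromosome_bias(
                {hid_to_gene_id(h) for h in hids},
                data.chromosomes,
                universe_genes,
            )
            out[key] = {
                "min_q": float(table["q"].min()),
                "n_biased": int((table["q"] < 0.05).sum()),
            }
        return out

    report["chromosome_bias"] = _round(_chrom())

    # --- gene classes for regulatory analyses ---------------------------
    study_count = pd.Series(0, index=aligned.universe, dtype=int)
    for hids in sig_sets.values():
        study_count.loc[sorted(hids)] += 1
    multi_hids = set(study_count.index[study_count >= config.multi_tissue_min])
    never_hids = set(study_count.index[study_count == 0])
    multi_genes = {hid_to_gene_id(h) for h in multi_hids}
    never_genes = {hid_to_gene_id(h) for h in never_hids}

    # --- motifs ----------------------------------------------------------
    @_stage("motifs")
    def _motifs():
        hits = motifs.scan_promoters(data.promoters)
        counts = motifs.hit_counts(hits, genes=list(data.promoters.sequences))
        promoter_genes = set(data.promoters.sequences)
        sig = multi_genes & promoter_genes
        non = never_genes & promoter_genes
        if sig and non:
            fractions = motifs.class_fractions(counts, sig, non)
            frac_records = _round(fractions.to_dict(orient="records"))
        else:
            frac_records = []
        return {
            "n_hits": int(len(hits)),
            "n_promoters": len(promoter_genes),
            "class_sizes": {"significant": len(sig), "non_significant": len(non)},
            "fractions": frac_records,
        }

    report["motifs"] = _motifs()

    # --- binding ----------------------------------------------------------
    @_stage("binding")
    def _binding():
        tss = synthdata.tss_table(config.sim)
        summary = binding_mod.gene_binding_summary(data.probes, tss)
        covered = set(summary.gene_p.index)
        out: dict[str, Any] = {"n_genes_with_probes": len(covered)}
        sig = multi_genes & covered
        non = never_genes & covered
        if sig:
            out["fraction_significant"] = binding_mod.binding_fraction(sig, summary)
        if non:
            out["fraction_non_significant"] = binding_mod.binding_fraction(
                non, summary
            )
        # direction strata within the highest-signal study
        key = max(sig_sets, key=lambda k: len(sig_sets[k]))
        strata = binding_mod.stratified_binding(
            aligned.results[key],
            summary,
            q_threshold=config.q_gene,
            gene_map=lambda h: hid_to_gene_id(int(h)),
        )
        out["strata_study"] = key
        out["strata"] = _round(strata.fillna("").to_dict(orient="records"))
        # cross-condition proportions: the synthetic ligand-responsive set is
        # the planted bound-gene set (documented proxy for a treated contrast)
        universe_genes = {hid_to_gene_id(h) for h in aligned.universe}
        cross = binding_mod.cross_condition_overlap(
            multi_genes, truth.bound_genes, universe_genes
        )
        out["cross_condition"] = _round(cross.to_dict(orient="records"))
        return out, summary

    binding_report, binding_summary = _binding()
    report["binding"] = binding_report

    # --- ontology enrichment ---------------------------------------------
    @_stage("goenrich")
    def _go():
        universe_genes = sorted(hid_to_gene_id(h) for h in aligned.universe)
        per_study_terms: dict[str, set[str]] = {}
        n_tested = 0
        for key, hids in sig_sets.items():
            genes = {hid_to_gene_id(h) for h in hids}
            if not genes:
                per_study_terms[key] = set()
                continue
            table = goenrich.enrich_terms(
                genes,
                universe_genes,
                data.dag,
                n_perm=config.n_go_permutations,
                seed=config.sim.rng(101),
            )
            n_tested = max(n_tested, len(table))
            per_study_terms[key] = set(
                table.loc[table["fdr"] < config.q_go, "term"]
            )
        term_overlaps = []
        if n_tested and sum(bool(s) for s in per_study_terms.values()) >= 2:
            term_overlaps = _round(
                goenrich.term_overlap_between_studies(
                    per_study_terms, n_tested
                ).to_dict(orient="records")
            )
        return {
            "n_terms_tested": n_tested,
            "enriched_terms": {
                k: sorted(v) for k, v in per_study_terms.items()
            },
            "term_overlap": term_overlaps,
        }

    report["goenrich"] = _go()

    # --- persist ----------------------------------------------------------
    if write_outputs:
        @_stage("write")
        def _write():
            outdir.mkdir(parents=True, exist_ok=True)
            written = synthdata.write_all(data, outdir / "inputs")
            for res in results:
                path = outdir / f"result_{res.key}.tsv"
                res.write_tsv(path)
                written.append(path)
            aligned.write_tsv(outdir / "aligned")
            written.extend(sorted((outdir / "aligned").glob("*.tsv")))
            pair_path = outdir / "overlap_pairs.tsv"
            pair_table.to_csv(pair_path, sep="\t", index=False)
            written.append(pair_path)
            bat_path = outdir / "battery.tsv"
            battery.table.to_csv(bat_path, sep="\t")
            written.append(bat_path)
            bind_path = outdir / "binding_summary.tsv"
            binding_summary.write_tsv(bind_path)
            written.append(bind_path)
            report_path = outdir / "report.json"
            report_path.write_text(
                json.dumps(_round(report), indent=2, sort_keys=True) + "\n"
            )
            written.append(report_path)
            manifest = outdir / "MANIFEST"
            manifest.write_text(
                "".join(
                    f"{_sha256(p)}  {p.relative_to(outdir)}\n"
                    for p in sorted(written)
                )
            )
        _write()
    return _round(report)
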