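"""Configured, logged, reproducible end-to-end runs.

``run_pipeline`` executes simulate -> assign -> profiles -> networks ->
stats from a strict YAML configuration, writing every intermediate artifact
plus a manifest recording versions, seeds, input digests and per-stage
record counts.  Reads are conserved at every run:
``reads_in == removed_by_length_filter + sum of reads per assigned rank``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._rng import child_seed
from . import io as pio
from .assign import AssignmentRule, CurationMap, apply_curation, assign_reads, length_filter, tally
from .containers import UNKNOWN_LABEL
from .networks import build_network, network_h2prime, species_dprime
from .profiles import entomophilous_coverage, jaccard_input_filter, to_percent, to_presence_absence
from .simulate import SimulationConfig, simulate_hit_table, simulate_loads_and_reads, simulate_taxonomy_and_refs
from .stats import default_contrast_battery, jaccard_distances, kruskal_wallis, permanova, run_contrast_battery

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

_TOP_KEYS = {"seed", "outdir", "simulate", "inputs", "assignment",
             "profiles", "stats", "log_level"}
_INPUT_KEYS = {"refs", "taxonomy", "reads", "hits", "insects", "sites", "curation"}
_ASSIGN_KEYS = {"top_k", "genus_fraction", "min_length"}
_PROFILE_KEYS = {"presence_min_reads", "rare_above_genus_threshold"}
_STATS_KEYS = {"n_perm", "alpha"}


@dataclass
class PipelineConfig:
    seed: int
    outdir: Path
    simulate: SimulationConfig | None
    inputs: dict[str, Path]
    rule: AssignmentRule
    presence_min_reads: int
    rare_above_genus_threshold: float
    n_perm: int
    alpha: float
    log_level: str = "INFO"


def _reject_unknown(payload: dict, allowed: set, where: str) -> None:
    unknown = set(payload) - allowed
    if unknown:
        raise ValueError(f"unknown configuration key(s) in {where}: {sorted(unknown)}")


def load_config(path) -> PipelineConfig:
    """Parse and validate a pipeline YAML, applying the standard defaults.

    Defaults: top_k 20, genus_fraction 0.60, min_length 450, presence
    threshold 1 read, 1% rare-above-genus filter, 9999 permutations,
    alpha 0.05.  Unknown keys are rejected by name.
    """
    payload = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(payload, dict):
        raise ValueError("pipeline configuration must be a mapping")
    _reject_unknown(payload, _TOP_KEYS, "top level")
    if "outdir" not in payload:
        raise ValueError("missing required configuration key: outdir")

    sim_cfg = None
    if "simulate" in payload:
        sim = dict(payload["simulate"] or {})
        sim.setdefault("seed", int(payload.get("seed", 0)))
        sim_cfg = SimulationConfig.from_dict(sim)

    inputs = {}
    if "inputs" in payload:
        _reject_unknown(payload["inputs"], _INPUT_KEYS, "inputs")
        inputs = {k: Path(v) for k, v in payload["inputs"].items()}
    if sim_cfg is None:
        required = {"refs", "taxonomy", "reads", "hits", "insects"}
        missing = required - set(inputs)
        if missing:
            raise ValueError(
                f"missing required input path(s) (no simulate section): {sorted(missing)}")

    assignment = dict(payload.get("assignment", {}) or {})
    _reject_unknown(assignment, _ASSIGN_KEYS, "assignment")
    rule = AssignmentRule(
        top_k=int(assignment.get("top_k", 20)),
        genus_fraction=float(assignment.get("genus_fraction", 0.60)),
        min_length_exclusive=int(assignment.get("min_length", 450)),
    )

    profiles = dict(payload.get("profiles", {}) or {})
    _reject_unknown(profiles, _PROFILE_KEYS, "profiles")
    stats = dict(payload.get("stats", {}) or {})
    _reject_unknown(stats, _STATS_KEYS, "stats")

    return PipelineConfig(
        seed=int(payload.get("seed", 0)),
        outdir=Path(payload["outdir"]),
        simulate=sim_cfg,
        inputs=inputs,
        rule=rule,
        presence_min_reads=int(profiles.get("presence_min_reads", 1)),
        rare_above_genus_threshold=float(
            profiles.get("rare_above_genus_threshold", 0.01)),
        n_perm=int(stats.get("n_perm", 9999)),
        alpha=float(stats.get("alpha", 0.05)),
        log_level=str(payload.get("log_level", "INFO")),
    )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(manifest: dict, name: str, **counts) -> None:
    logger.info("[stage:%s] %s", name,
                " ".join(f"{k}={v}" for k, v in counts.items()))
    manifest["stages"].append({"name": name, **counts})


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            name: child_seed(config.seed, name)
            for name in ("simulate", "stats")
        },
        "stages": [],
        "inputs": {},
        "outputs": {},
    }

    # ----- stage 1: simulate (or load) ---------------------------------
    try:
        if config.simulate is not None:
            refdb = simulate_taxonomy_and_refs(config.simulate)
            data = simulate_loads_and_reads(config.simulate, refdb)
            hits = simulate_hit_table(data.reads, refdb,
                                      top_n=config.simulate.hit_depth)
            reads = data.reads
            insects = data.insects
            site_lists = data.site_lists
            pio.write_fasta(
                [(rid, seq) for rid, seq in refdb.sequences.items()],
                out / "refs.fasta")
            refdb.taxonomy.to_csv(out / "taxonomy.csv", index_label="ref_id")
            pio.write_fasta(reads, out / "reads.fasta")
            pio.write_hit_table(hits, out / "hits.tsv")
            pio.write_insect_table(insects, out / "insects.csv")
            pio.write_site_plant_list(site_lists, out / "sites.csv")
            pio.write_matrix_csv(data.true_loads, out / "true_loads.csv")
            _stage(manifest, "simulate", n_refs=len(refdb),
                   n_insects=len(insects), n_reads=len(reads),
                   n_hits=len(hits))
            curation = None
        else:
            refdb = pio.read_reference(config.inputs["refs"],
                                       config.inputs["taxonomy"])
            reads = [(r.id, str(r.seq)) for r in pio.read_fasta(config.inputs["reads"])]
            hits = pio.read_hit_table(config.inputs["hits"])
            insects = pio.read_insect_table(config.inputs["insects"])
            site_lists = (pio.read_site_plant_list(config.inputs["sites"])
                          if "sites" in config.inputs else None)
            curation = (CurationMap.from_csv(config.inputs["curation"])
                        if "curation" in config.inputs else None)
            for key, path in config.inputs.items():
                manifest["inputs"][key] = _digest(Path(path))
            _stage(manifest, "load", n_refs=len(refdb),
                   n_insects=len(insects), n_reads=len(reads),
                   n_hits=len(hits))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'simulate/load' failed: {exc}") from exc

    # ----- stage 2: assignment ----------------------------------------
    try:
        kept = length_filter(reads, config.rule)
        removed = len(reads) - len(kept)
        kept_ids = [rid for rid, _ in kept]
        kept_hits = hits[hits["qseqid"].isin(set(kept_ids))]
        assignments = assign_reads(kept_hits, refdb.taxonomy, config.rule,
                                   query_ids=kept_ids)
        if curation is not None:
            assignments, audit = apply_curation(assignments, curation,
                                                refdb.taxonomy)
            audit.to_csv(out / "curation_audit.csv", index=False)
        pcm = tally(assignments, insects)
        assignments.to_csv(out / "assignments.csv", index=False)
        pio.write_matrix_csv(pcm.counts, out / "counts.csv")
        pcm.ranks.rename("rank").to_csv(out / "taxon_ranks.csv",
                                        index_label="taxon")
        by_rank = assignments["rank"].value_counts().to_dict()
        _stage(manifest, "assign", reads_in=len(reads),
               removed_short=removed, **{f"rank_{k}": v for k, v in by_rank.items()})
        conserved = len(reads) == removed + sum(by_rank.values())
        manifest["reads_conserved"] = bool(conserved)
        if not conserved:
            raise RuntimeError("read conservation violated")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'assign' failed: {exc}") from exc

    # ----- stage 3: profiles ------------------------------------------
    try:
        percent = to_percent(pcm)
        pa = to_presence_absence(pcm, config.presence_min_reads)
        pa_filtered = jaccard_input_filter(
            pcm, config.rare_above_genus_threshold, config.presence_min_reads)
        pio.write_matrix_csv(percent.percent, out / "percent.csv")
        pio.write_matrix_csv(pa.data.astype(int), out / "pa.csv")
        pio.write_matrix_csv(pa_filtered.data.astype(int), out / "pa_filtered.csv")
        coverage = {}
        if site_lists is not None:
            for site in sorted(insects["site"].unique()):
                at_site = pa.insects.index[pa.insects["site"] == site]
                present = pa.data.loc[at_site].any(axis=0)
                taxa = {t: pa.ranks[t] for t in pa.data.columns[present]}
                cov = entomophilous_coverage(site_lists, taxa, site,
                                             taxonomy=refdb.taxonomy)
                coverage[site] = {
                    "n_entomophilous": cov.n_entomophilous,
                    "n_detected": cov.n_detected,
                    "fraction": cov.fraction,
                }
            pio.write_json(coverage, out / "coverage.json")
        _stage(manifest, "profiles", n_insects=len(percent.percent),
               n_taxa=len(percent.percent.columns),
               n_taxa_filtered=len(pa_filtered.data.columns))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'profiles' failed: {exc}") from exc

    # ----- stage 4: networks ------------------------------------------
    try:
        network_metrics = {}
        dprime_by_species: dict[str, list[float]] = {}
        for site in sorted(insects["site"].unique()):
            im = build_network(pa, site)
            pio.write_matrix_csv(im.table, out / f"network_{site}.csv")
            spec = network_h2prime(im)
            per_species = [] if spec.degenerate else species_dprime(im)
            network_metrics[site] = {
                "h2": spec.h2, "h2min": spec.h2min, "h2max": spec.h2max,
                "h2prime": spec.h2prime, "degenerate": spec.degenerate,
                "dprime": {s.species: {"d": s.d, "dmin": s.dmin,
                                       "dmax": s.dmax, "dprime": s.dprime}
                           for s in per_species},
            }
            for s in per_species:
                dprime_by_species.setdefault(s.species, []).append(s.dprime)
        pio.write_json(network_metrics, out / "network_metrics.json")
        _stage(manifest, "networks", n_sites=len(network_metrics))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'networks' failed: {exc}") from exc

    # ----- stage 5: statistics ----------------------------------------
    try:
        stats_out: dict = {}
        dm = jaccard_distances(pa_filtered)
        meta = pa_filtered.insects.loc[list(dm.ids)]
        stats_seed = manifest["stage_seeds"]["stats"]
        if meta["genus"].nunique() > 1:
            omnibus = permanova(dm, meta["genus"], strata=meta["site"],
                                n_perm=config.n_perm, seed=stats_seed)
            stats_out["omnibus_genus"] = omnibus.as_dict()
            suite = run_contrast_battery(
                dm, default_contrast_battery(meta), alpha=config.alpha,
                n_perm=config.n_perm, seed=stats_seed)
            stats_out["contrasts"] = suite.as_dict()
        groups = {sp: vals for sp, vals in dprime_by_species.items() if vals}
        if len(groups) >= 2:
            try:
                kw = kruskal_wallis(groups)
                stats_out["kruskal_wallis_dprime"] = {
                    "H": kw.H, "df": kw.df, "p": kw.p}
            except ValueError as exc:
                stats_out["kruskal_wallis_dprime"] = {"error": str(exc)}
        pio.write_json(stats_out, out / "stats.json")
        _stage(manifest, "stats",
               n_contrasts=len(stats_out.get("contrasts", {}).get("contrasts", {})))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'stats' failed: {exc}") from exc

    for artifact in sorted(out.iterdir()):
        if artifact.name != "manifest.json" and artifact.is_file():
            manifest["outputs"][artifact.name] = _digest(artifact)
    pio.write_json(manifest, out / "manifest.json")
    return manifest
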