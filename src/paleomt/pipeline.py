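"""End-to-end orchestration with reproducible, checksummed run reports.

A pipeline run executes the stages in dependency order —
simulate → consensus → curate → place → diversity → tempsignal → spatial —
driven by a single configuration mapping (YAML on disk). Every stage is
optional; outputs of each stage are plain-text files declared in the run
report together with their SHA-256 checksums, so identical configurations
and seeds produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import ConsensusPolicy, ContaminationEstimate, process_sample, depth_table
from .curate import CurationPolicy, completeness_filter, site_deletion
from .diversity import compare_site_diversity, distance_matrix, distances_long_table
from .placement import node_defining_snps, place_sequence
from .simulate import (
    ClockModel,
    DamageProfile,
    SliceSpec,
    SpreadScenario,
    evolve_sequences,
    fragment_and_damage,
    mutated_copy,
    newick_string,
    read_alignment_fasta,
    read_fragments_tsv,
    realized_substitution_tree,
    simulate_localities,
    simulate_tree,
    tip_ages,
    write_alignment_fasta,
    write_fragments_tsv,
)
from .spatial import filter_and_slice, hotspot_permutation_test, kde_density, rarefy_spread
from .temporal import fit_temporal_regression, root_to_tip_distances

log = logging.getLogger("paleomt")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "stages": ["simulate", "consensus", "curate", "place", "diversity", "tempsignal", "spatial"],
    "simulate": {
        "n_tips": 12,
        "tip_age_range": [40_000, 120_000],
        "pop_size": 50_000,
        "length": 4_000,
        "clock": {"rate": 1.57e-8, "model": "TN93", "invariant_fraction": 0.3},
        "damage": {"p_ct_5p": 0.30, "coverage": 20.0, "contamination_frac": 0.05},
        "localities": {
            "slices": [
                [80, 70, 60, 5.0, 30.0],
                [70, 60, 80, 8.0, 40.0],
                [60, 50, 90, 10.0, 45.0],
            ]
        },
    },
    "consensus": {"min_depth": 3, "agreement": 0.65, "contamination": 0.15, "threshold": 0.10, "damage_window": 3},
    "curate": {"max_n": 2600, "deletion_mode": "partial", "partial_p": 0.90},
    "place": {"omit_damage": True},
    "tempsignal": {"per_bp": True},
    "spatial": {
        "max_range_ky": 30,
        "window_ky": 10,
        "cell": 1.0,
        "band": 3.0,
        "hotspot_reps": 199,
        "rarefy_n": 40,
        "rarefy_reps": 500,
        "bin_width": 2.0,
    },
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    _deep_update(merged, cfg)
    return merged


def _deep_update(base: dict, new: dict) -> None:
    for k, v in new.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, outdir: str | Path, force: bool = False) -> dict:
    """Execute the configured stages and write a checksummed run report."""
    outdir = Path(outdir)
    report_path = outdir / "report.json"
    if report_path.exists() and not force:
        raise FileExistsError(f"{report_path} exists; pass force=True to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)

    seed = int(config.get("seed", 1))
    stages = list(config.get("stages", []))
    report: dict = {"version": __version__, "seed": seed, "config": config, "stages": {}, "outputs": {}}
    outputs: list[Path] = []
    state: dict = {}

    def declare(path: Path) -> None:
        outputs.append(path)

    if "simulate" in stages:
        state.update(_stage_simulate(config["simulate"], seed, outdir, declare, report))
    if "consensus" in stages:
        _stage_consensus(config["consensus"], outdir, declare, report, state, config)
    if "curate" in stages:
        _stage_curate(config["curate"], outdir, declare, report, state)
    if "place" in stages:
        _stage_place(config["place"], outdir, declare, report, state)
    if "diversity" in stages:
        _stage_diversity(outdir, declare, report, state)
    if "tempsignal" in stages:
        _stage_tempsignal(config["tempsignal"], outdir, declare, report, state)
    if "spatial" in stages:
        _stage_spatial(config["spatial"], seed, outdir, declare, report, state)

    for p in outputs:
        report["outputs"][p.name] = _sha256(p)
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    return report


def _stage_simulate(cfg: dict, seed: int, outdir: Path, declare, report: dict) -> dict:
    log.info("stage simulate")
    clock = ClockModel(**cfg.get("clock", {}))
    tree = simulate_tree(
        n_tips=cfg["n_tips"],
        tip_age_range=tuple(cfg["tip_age_range"]),
        seed=seed,
        pop_size=cfg.get("pop_size", 50_000),
    )
    sim = evolve_sequences(tree, clock, cfg["length"], seed=seed + 1)
    genome = sim.alignment[next(iter(sim.alignment))]
    contaminant = mutated_copy(genome, max(5, cfg["length"] // 200), seed=seed + 2)
    frags = fragment_and_damage(
        genome, DamageProfile(**cfg.get("damage", {})), contaminant, seed=seed + 3
    )
    scenario = SpreadScenario(
        slices=[SliceSpec(*row) for row in cfg["localities"]["slices"]]
    )
    localities = simulate_localities(scenario, seed=seed + 4)

    (outdir / "tree.nwk").write_text(newick_string(tree))
    write_alignment_fasta(sim.alignment, outdir / "alignment.fasta")
    write_alignment_fasta({"sample_genome": genome}, outdir / "genome.fasta")
    write_fragments_tsv(frags.fragments, outdir / "fragments.tsv")
    localities.to_csv(outdir / "localities.csv", index=False)
    ages = tip_ages(tree)
    pd.DataFrame(
        {"id": list(ages), "age_bp": [ages[t] for t in ages], "dated": True}
    ).to_csv(outdir / "tip_ages.csv", index=False)
    for name in ("tree.nwk", "alignment.fasta", "genome.fasta", "fragments.tsv", "localities.csv", "tip_ages.csv"):
        declare(outdir / name)
    report["stages"]["simulate"] = {
        "n_tips": cfg["n_tips"],
        "alignment_length": cfg["length"],
        "n_fragments": len(frags.fragments),
        "n_localities": len(localities),
    }
    return {
        "tree": tree,
        "sim": sim,
        "genome": genome,
        "fragments": frags.fragments,
        "localities": localities,
        "tip_ages": ages,
    }


def _stage_consensus(cfg: dict, outdir: Path, declare, report: dict, state: dict, full_cfg: dict) -> None:
    log.info("stage consensus")
    if "fragments" not in state:
        ref_path = cfg.get("reference")
        frag_path = cfg.get("fragments")
        if not ref_path or not frag_path:
            raise FileNotFoundError(
                "consensus stage: 'reference' and 'fragments' paths are required "
                "when the simulate stage is disabled"
            )
        genome = read_alignment_fasta(ref_path)
        genome = genome[next(iter(genome))]
        state["genome"] = genome
        state["fragments"] = read_fragments_tsv(frag_path, genome)
    policy = ConsensusPolicy(
        min_depth=cfg["min_depth"],
        min_agreement=cfg["agreement"],
        damage_window=cfg["damage_window"],
    )
    estimate = ContaminationEstimate(point=cfg["contamination"])
    cons, qc = process_sample(
        state["fragments"], estimate, policy, threshold=cfg["threshold"],
        ref_length=len(state["genome"]),
    )
    state["consensus"] = cons
    write_alignment_fasta({"consensus": cons.calls}, outdir / "consensus.fasta")
    depth_table(cons).to_csv(outdir / "depth.csv", index=False)
    (outdir / "consensus_qc.json").write_text(json.dumps(qc, indent=2, sort_keys=True) + "\n")
    for name in ("consensus.fasta", "depth.csv", "consensus_qc.json"):
        declare(outdir / name)
    report["stages"]["consensus"] = qc


def _stage_curate(cfg: dict, outdir: Path, declare, report: dict, state: dict) -> None:
    log.info("stage curate")
    aln = dict(state["sim"].alignment) if "sim" in state else {}
    if "consensus" in state:
        cons = state["consensus"].calls
        if not aln or len(cons) == len(next(iter(aln.values()))):
            aln["consensus"] = cons
    policy = CurationPolicy(max_n=cfg["max_n"], min_completeness=1 - cfg["max_n"] / 16_569)
    retained, excl = completeness_filter(aln, policy)
    mode = cfg.get("deletion_mode", "partial")
    filtered, kept_cols = site_deletion(retained, mode=mode, p=cfg.get("partial_p", 0.90))
    state["curated"] = filtered
    write_alignment_fasta(filtered, outdir / "curated.fasta")
    excl.to_csv(outdir / "exclusions.csv", index=False)
    declare(outdir / "curated.fasta")
    declare(outdir / "exclusions.csv")
    report["stages"]["curate"] = {
        "n_in": len(aln),
        "n_retained": len(retained),
        "n_columns_kept": int(len(kept_cols)),
        "deletion_mode": mode,
    }


def _stage_place(cfg: dict, outdir: Path, declare, report: dict, state: dict) -> None:
    log.info("stage place")
    tree = state["tree"]
    aln = state["sim"].alignment
    outgroup = sorted(aln)[0]
    table = node_defining_snps(aln, tree, outgroup=outgroup)
    query = state["consensus"].calls[: state["sim"].length] if "consensus" in state else None
    table.to_csv(outdir / "diagnostic_snps.csv", index=False)
    declare(outdir / "diagnostic_snps.csv")
    summary = {"n_snps": int(len(table)), "outgroup": outgroup}
    if query is not None:
        result = place_sequence(query, table, tree, omit_damage=cfg.get("omit_damage", True))
        placement = {
            "assigned_node": result.assigned_node,
            "confidence": result.confidence_note,
            "sites_omitted_damage": result.sites_omitted_damage,
            "path_support": result.path_support,
        }
        (outdir / "placement.json").write_text(json.dumps(placement, indent=2, sort_keys=True) + "\n")
        declare(outdir / "placement.json")
        summary["assigned_node"] = result.assigned_node
    report["stages"]["place"] = summary


def _stage_diversity(outdir: Path, declare, report: dict, state: dict) -> None:
    log.info("stage diversity")
    aln = state.get("curated") or state["sim"].alignment
    ids = sorted(aln)
    sites = {"siteA": {i: aln[i] for i in ids[0::2]}, "siteB": {i: aln[i] for i in ids[1::2]}}
    comparisons = compare_site_diversity(sites, aln)
    dm = distance_matrix(aln)
    distances_long_table(dm).to_csv(outdir / "distances.csv", index=False)
    out = [
        {
            "group": c.group,
            "W": c.statistic,
            "p_raw": c.p_raw,
            "p_adjusted": c.p_adjusted,
            "adjustment": c.adjustment,
        }
        for c in comparisons
    ]
    (outdir / "diversity.json").write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
    declare(outdir / "distances.csv")
    declare(outdir / "diversity.json")
    report["stages"]["diversity"] = {"n_comparisons": len(out)}


def _stage_tempsignal(cfg: dict, outdir: Path, declare, report: dict, state: dict) -> None:
    log.info("stage tempsignal")
    subs_tree = realized_substitution_tree(state["tree"], state["sim"])
    dist = root_to_tip_distances(subs_tree)
    reg = fit_temporal_regression(dist, state["tip_ages"])
    out = {
        "slope_subs_per_bp_per_year": reg.slope,
        "intercept": reg.intercept,
        "r_squared": reg.r_squared,
        "root_age_estimate": reg.root_age_estimate,
        "n_dated": reg.n_dated,
    }
    (outdir / "tempsignal.json").write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
    declare(outdir / "tempsignal.json")
    report["stages"]["tempsignal"] = out


def _stage_spatial(cfg: dict, seed: int, outdir: Path, declare, report: dict, state: dict) -> None:
    log.info("stage spatial")
    loc = state["localities"]
    slices = filter_and_slice(loc, cfg["max_range_ky"], cfg["window_ky"])
    membership = pd.concat(
        [s.records.assign(slice=s.label) for s in slices], ignore_index=True
    )
    membership.to_csv(outdir / "slice_membership.csv", index=False)
    declare(outdir / "slice_membership.csv")

    gx, gy, dens = kde_density(loc["longitude"], loc["latitude"])
    dens_df = pd.DataFrame(dens, index=np.round(gy, 4), columns=np.round(gx, 4))
    dens_df.to_csv(outdir / "density_grid.csv")
    declare(outdir / "density_grid.csv")

    summary: dict = {"n_slices": len(slices)}
    if len(slices) >= 2:
        hot = hotspot_permutation_test(
            slices, reps=cfg["hotspot_reps"], seed=seed + 10,
            cell=cfg["cell"], band=cfg["band"],
        )
        hot.to_csv(outdir / "hotspots.csv", index=False)
        declare(outdir / "hotspots.csv")
        summary["hotspot_p"] = dict(zip(hot["slice"], hot["p"]))

        base, targ = slices[0], slices[1]
        n = min(cfg["rarefy_n"], len(targ.records["site_id"].unique()))
        rar = rarefy_spread(base, targ, n=n, reps=cfg["rarefy_reps"], bin_width=cfg["bin_width"], seed=seed + 11)
        rar_out = {
            "baseline": rar.baseline_label,
            "target": rar.target_label,
            "n": rar.n,
            "replicates": rar.replicates,
            "baseline_metrics": rar.baseline_metrics,
            "medians": rar.medians,
            "p_perm": rar.p_perm,
        }
        (outdir / "rarefaction.json").write_text(json.dumps(rar_out, indent=2, sort_keys=True) + "\n")
        declare(outdir / "rarefaction.json")
        summary["rarefaction_p"] = rar.p_perm
    report["stages"]["spatial"] = summary
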