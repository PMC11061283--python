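"""End-to-end orchestration of the scan stages on one chromosome.

``run_all`` wires the stages into the full flow — synthetic data (or an
ingested VCF), per-SNP statistics, windowed scans with resampling
significance, candidate-SNP ranking, archaic-introgression calling,
phenotype association and biobank-style enrichment — writing TSV/BED
outputs plus a JSON manifest of every parameter and seed, so a rerun with
the same configuration reproduces identical outputs.

Both scan directions are run: the "target" scan looks for selection in the
target population, the "reference" scan role-swaps the populations (the
XP-EHH track is negated rather than recomputed, and PBS swaps target and
reference), so one code path serves both.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import archaic_scan, association, enrichment, selection_stats, synthetic_data
from . import window_scan as ws
from .io_formats import HaplotypePanel, Region, build_site_table, write_regions_bed
from .trajectory_rank import TrajectoryModel, rank_candidates

logger = logging.getLogger("sweepscan")

__all__ = ["PipelineConfig", "compute_tracks", "scan_selection", "run_all"]


@dataclass
class PipelineConfig:
    """Declarative configuration for a full run; no hidden defaults.

    Every scan parameter (20/5 windows, 10 kb merge, 50 kb flanks, 99th
    percentile, DAF >= 0.05, mean_prob >= 0.8, r^2 > 0.5, +/-50 bp lookup,
    per-method p thresholds) is carried in the nested configs and logged
    in the run manifest.
    """

    seed: int = 7
    outdir: str = "sweepscan_run"
    sim: synthetic_data.SimConfig = field(default_factory=synthetic_data.SimConfig)
    scan: ws.ScanConfig = field(default_factory=ws.ScanConfig)
    xpehh: selection_stats.XPEHHConfig = field(default_factory=selection_stats.XPEHHConfig)
    trajectory: TrajectoryModel = field(default_factory=TrajectoryModel)
    hmm: archaic_scan.HmmConfig = field(default_factory=archaic_scan.HmmConfig)
    n_phenotypes_lookup: int = 1470
    enrichment_resamples: int = 10_000

    @classmethod
    def from_yaml(cls, path, seed: int | None = None,
                  outdir: str | None = None) -> "PipelineConfig":
        """Build a configuration from a declarative YAML file.

        Top-level keys ``seed``, ``outdir``, ``sim``, ``scan``, ``xpehh``,
        ``trajectory`` and ``hmm`` override the demo defaults; nested keys
        map onto the corresponding config dataclass fields (``sim.sweep``
        and ``sim.archaic`` onto :class:`SweepSpec` /
        :class:`ArchaicSourceSpec`).  Command-line ``seed``/``outdir``
        take precedence over the file.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls.demo(seed=seed if seed is not None else raw.get("seed", 7),
                       outdir=outdir if outdir is not None else raw.get("outdir", "sweepscan_run"))
        sim_raw = dict(raw.get("sim", {}))
        if "sweep" in sim_raw:
            sweep = sim_raw.pop("sweep")
            sim_raw["sweep"] = None if sweep is None \
                else synthetic_data.SweepSpec(**sweep)
        if "archaic" in sim_raw:
            sources = sim_raw.pop("archaic") or ()
            sim_raw["archaic"] = tuple(
                synthetic_data.ArchaicSourceSpec(**s) for s in sources)
        if "phenotype" in sim_raw:
            phen = sim_raw.pop("phenotype")
            sim_raw["phenotype"] = None if phen is None \
                else synthetic_data.PhenotypeSpec(**phen)
        from dataclasses import replace as dc_replace
        sim_raw.setdefault("seed", cfg.seed)
        cfg.sim = dc_replace(cfg.sim, **sim_raw)
        cfg.scan = demo_scan_config(cfg.sim.S)
        for attr in ("scan", "xpehh", "hmm"):
            if raw.get(attr):
                setattr(cfg, attr, dc_replace(getattr(cfg, attr), **raw[attr]))
        if raw.get("trajectory"):
            cfg.trajectory = TrajectoryModel(**raw["trajectory"])
        return cfg

    @classmethod
    def demo(cls, seed: int = 7, outdir: str = "sweepscan_run") -> "PipelineConfig":
        """Desk-scale demo: one sweep, two archaic sources, causal phenotype.

        The per-method significance thresholds are set for the demo track
        length: the resampling p of a score unit is floored near
        1/(number of units), so the genome-scale thresholds are replaced
        by cutoffs that admit roughly the ten best-supported units per
        method (see the scan configuration).
        """
        sim = synthetic_data.SimConfig(
            seed=seed,
            sweep=synthetic_data.SweepSpec(),
            archaic=(
                synthetic_data.ArchaicSourceSpec(ancestry="Neanderthal", anchor=400_000),
                synthetic_data.ArchaicSourceSpec(ancestry="Denisova", anchor=1_100_000),
            ),
            phenotype=synthetic_data.PhenotypeSpec(),
        )
        scan = demo_scan_config(sim.S)
        return cls(seed=seed, outdir=outdir, sim=sim, scan=scan)


def demo_scan_config(n_snps: int) -> ws.ScanConfig:
    """Desk-scale thresholds: ~10 admissible units per method."""
    t_snp = 10 / n_snps
    n_windows = max(1, (n_snps - 20) // 5 + 1)
    t_win = 10 / n_windows
    return ws.ScanConfig(
        p_thresholds={ws.METHOD_XPEHH: t_snp, ws.METHOD_PBS: t_win,
                      ws.METHOD_FISHER: t_win},
        n_resamples={ws.METHOD_XPEHH: 100_000, ws.METHOD_PBS: 100_000,
                     ws.METHOD_FISHER: 100_000},
    )


# ---------------------------------------------------------------------------
# Tracks and scans
# ---------------------------------------------------------------------------

def compute_tracks(panel: HaplotypePanel, target: str, reference: str, outgroup: str,
                   xpehh_config: selection_stats.XPEHHConfig | None = None) -> pd.DataFrame:
    """Per-SNP PBS (both scan directions) and XP-EHH tracks.

    Returns a DataFrame with position, pbs_target, pbs_reference,
    xpehh_raw, xpehh (z-normalized; positive = selection in target).
    """
    freqs = {}
    counts = {}
    for pop in (target, reference, outgroup):
        k, n = panel.derived_counts(pop)
        freqs[pop] = np.where(n > 0, k / np.maximum(n, 1), np.nan)
        counts[pop] = n
    fst = lambda a, b: selection_stats.hudson_fst(freqs[a], counts[a], freqs[b], counts[b])
    f_tr = fst(target, reference)
    f_to = fst(target, outgroup)
    f_ro = fst(reference, outgroup)
    pbs_target = selection_stats.pbs(f_tr, f_to, f_ro)
    pbs_reference = selection_stats.pbs(f_tr, f_ro, f_to)

    xp = selection_stats.xpehh(panel.submatrix(target), panel.submatrix(reference),
                               panel.positions, xpehh_config)
    return pd.DataFrame({
        "position": panel.positions,
        "pbs_target": pbs_target,
        "pbs_reference": pbs_reference,
        "xpehh_raw": xp["raw"].to_numpy(),
        "xpehh": xp["score"].to_numpy(),
    })


def scan_selection(tracks: pd.DataFrame, config: ws.ScanConfig, chrom: str,
                   direction: str, seed: int,
                   chrom_length: int | None = None) -> tuple[list[Region], dict]:
    """One scan direction (selection in target or in reference).

    For the reference direction the XP-EHH track is negated (lowest scores
    mean selection in the reference) and the role-swapped PBS track is
    used, so "top" is always the upper tail internally.
    """
    if direction == "target":
        pbs_col, sign = "pbs_target", 1.0
    elif direction == "reference":
        pbs_col, sign = "pbs_reference", -1.0
    else:
        raise ValueError("direction must be 'target' or 'reference'")
    track = pd.DataFrame({
        "position": tracks["position"],
        "pbs": tracks[pbs_col],
        "xpehh": sign * tracks["xpehh"],
    })
    windows = ws.fisher_combine(ws.make_windows(track, config))
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 3]))

    snp_scores = track["xpehh"].to_numpy()
    per_method = {}
    xp_regions = ws.top_snps_xpehh(track.rename(columns={"xpehh": "score"}),
                                   config, tail="upper", chrom=chrom)
    per_method[ws.METHOD_XPEHH] = ws.attach_pvalues(
        xp_regions, snp_scores, ws.METHOD_XPEHH, config, rng)
    pbs_regions = ws.top_windows(windows, "pbs_mean", config, chrom, ws.METHOD_PBS)
    per_method[ws.METHOD_PBS] = ws.attach_pvalues(
        pbs_regions, windows["pbs_mean"].to_numpy(), ws.METHOD_PBS, config, rng)
    fisher_regions = ws.top_windows(windows, "fisher", config, chrom, ws.METHOD_FISHER)
    per_method[ws.METHOD_FISHER] = ws.attach_pvalues(
        fisher_regions, windows["fisher"].to_numpy(), ws.METHOD_FISHER, config, rng)

    final = ws.finalize_regions(per_method, config, chrom_length)
    return final, {"windows": windows, "per_method": per_method}


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_all(config: PipelineConfig) -> dict:
    """Run every stage; write outputs under ``config.outdir``.

    Returns a dict of in-memory stage results.  Any stage failure raises
    with the stage name; the introgression stage is skipped with a logged
    notice when no archaic sources are configured.
    """
    from pathlib import Path

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    sim = config.sim
    target, reference, outgroup = sim.pop_target, sim.pop_ref, sim.pop_out

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("simulate")
        panel, truth = synthetic_data.simulate_panel(sim)
        archaic_panels = None
        if sim.archaic:
            panel, truth, archaic_panels = synthetic_data.inject_archaic(
                panel, truth, tuple(sim.archaic), population=target, outgroup=outgroup,
                rng=np.random.default_rng(np.random.SeedSequence([sim.seed, 2])))
        results["panel"], results["truth"] = panel, truth
        build_site_table(panel).to_csv(out / "sites.tsv", sep="\t", index=False)
    except Exception as e:
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e

    try:
        stage("scan-stats")
        tracks = compute_tracks(panel, target, reference, outgroup, config.xpehh)
        tracks.to_csv(out / "tracks.tsv", sep="\t", index=False)
        results["tracks"] = tracks
    except Exception as e:
        raise RuntimeError(f"stage 'scan-stats' failed: {e}") from e

    try:
        stage("scan")
        chrom_length = int(sim.L)
        results["regions"] = {}
        for direction in ("target", "reference"):
            regions, detail = scan_selection(tracks, config.scan, sim.chrom,
                                             direction, config.seed, chrom_length)
            results["regions"][direction] = regions
            write_regions_bed(regions, out / f"regions_{direction}.bed")
    except Exception as e:
        raise RuntimeError(f"stage 'scan' failed: {e}") from e

    try:
        stage("candidates")
        pop_of = {"target": target, "reference": reference}
        results["candidates"] = {}
        rows = []
        for direction, regions in results["regions"].items():
            cands = []
            for i, region in enumerate(regions):
                cand = rank_candidates(region, panel, config.trajectory,
                                       pop_of[direction],
                                       seed=config.seed + i)
                cands.append(cand)
                rows.append((direction, region.chrom, region.start, region.end,
                             cand.position, cand.daf, cand.mean_loglr_stage2))
            results["candidates"][direction] = cands
        pd.DataFrame(rows, columns=["direction", "chrom", "start", "end",
                                    "candidate_pos", "daf", "mean_loglr"]) \
            .to_csv(out / "candidates.tsv", sep="\t", index=False)
    except Exception as e:
        raise RuntimeError(f"stage 'candidates' failed: {e}") from e

    if archaic_panels is None:
        logger.info("no archaic panels configured; skipping introgression stage")
        results["introgression"] = None
    else:
        try:
            stage("introgression")
            segments = archaic_scan.detect_all_segments(
                panel, target, outgroup, config.hmm, chrom_length=int(sim.L))
            reports = []
            for region, cand in zip(results["regions"]["target"],
                                    results["candidates"]["target"]):
                kept = archaic_scan.filter_for_region(segments, region, archaic_panels)
                for seg in kept:
                    seg.ancestry = archaic_scan.assign_ancestry(
                        seg.asnp_positions, archaic_panels)
                haps = archaic_scan.cluster_haplotypes(
                    kept, panel, target, region, archaic_panels)
                rep = archaic_scan.region_report(haps, panel, target, cand.position)
                rep.update(region_start=region.start, region_end=region.end)
                reports.append(rep)
            results["introgression"] = reports
            pd.DataFrame([
                {k: v for k, v in r.items() if k != "haplotype"} for r in reports
            ]).to_csv(out / "introgression.tsv", sep="\t", index=False)
        except Exception as e:
            raise RuntimeError(f"stage 'introgression' failed: {e}") from e

    if sim.phenotype is None:
        logger.info("no phenotype spec; skipping association stage")
        results["association"] = None
    else:
        try:
            stage("association")
            phen = synthetic_data.simulate_phenotypes(
                panel, sim.phenotype, seed=config.seed,
                populations=[target, reference])
            phen.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
            keep = np.flatnonzero(np.isin(np.asarray(panel.populations),
                                          [target, reference]))
            G_all = ((panel.H[2 * keep] == 1).astype(int)
                     + (panel.H[2 * keep + 1] == 1).astype(int))
            K = association.kinship_matrix(G_all)
            cand_sites = sorted({c.site_index for d in results["candidates"].values()
                                 for c in d if c.site_index is not None})
            if not cand_sites:
                raise ValueError("no candidate SNPs to test")
            pv_rows = []
            for phen_name, group in association.PHENOTYPE_GROUP.items():
                resid = association.correct_phenotype(phen[phen_name],
                                                      phen, group)
                res = association.lmm_assoc(G_all[:, cand_sites], resid, K)
                for _, r in res.iterrows():
                    pv_rows.append((int(cand_sites[int(r["snp"])]), phen_name,
                                    r["beta"], r["p"]))
            pvals = pd.DataFrame(pv_rows, columns=["snp", "phenotype", "beta", "p"])
            calls = association.adjust_and_call(pvals)
            calls.to_csv(out / "association.tsv", sep="\t", index=False)
            results["association"] = calls
        except Exception as e:
            raise RuntimeError(f"stage 'association' failed: {e}") from e

    try:
        stage("enrichment")
        cand_pos = [c.position for d in results["candidates"].values()
                    for c in d if c.position is not None]
        spec = synthetic_data.AssocTableSpec(
            blood_hits=tuple(cand_pos[:2]))
        table = synthetic_data.simulate_assoc_table(
            panel.positions, spec, seed=config.seed)
        table.to_csv(out / "assoc_lookup.tsv", sep="\t", index=False)
        res = enrichment.blood_enrichment_test(
            cand_pos, table, n_phenotypes=spec.n_phenotypes_tested,
            n_resamples=config.enrichment_resamples,
            rng=np.random.default_rng(np.random.SeedSequence([config.seed, 5])))
        results["enrichment"] = res
        with open(out / "enrichment.json", "w") as fh:
            json.dump(res, fh, indent=2)
    except Exception as e:
        raise RuntimeError(f"stage 'enrichment' failed: {e}") from e

    manifest = {
        "seed": config.seed,
        "sim": _to_jsonable(asdict(sim)),
        "scan": _to_jsonable(asdict(config.scan)),
        "xpehh": _to_jsonable(asdict(config.xpehh)),
        "trajectory": {"generations": config.trajectory.generations,
                       "Ne": config.trajectory.Ne,
                       "n_bins": config.trajectory.n_bins,
                       "s_grid": list(map(float, config.trajectory.s_grid))},
        "hmm": _to_jsonable(asdict(config.hmm)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
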