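"""End-to-end orchestration: simulate -> scan -> calibrate -> call -> ancestry.

The pipeline mirrors a multi-population selection scan: per population
class (admixed / unadmixed) it derives neutral critical values for each
statistic, scores simulated (or user-supplied) data with the windowed
SFS classifier and iHS, calls candidate windows with the strict
class-specific threshold, and — for admixed populations — assigns and
masks local ancestry, tests candidate windows for ancestry enrichment,
and reports unbalanced-ancestry regions.  Candidate sets of several
populations are intersected into a shared-signal matrix.

All randomness flows from one root seed; per-stage child seeds are
derived from it and written to the run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry, calibrate, genome_io, ihs_scan, sfs_scan
from .genome_io import GenomicWindow, WindowSpec
from .simulate import SweepParams, build_demography, simulate_neutral, simulate_sweep

logger = logging.getLogger(__name__)


@dataclass
class ScanResult:
    """One population's scores, thresholds and candidate windows."""

    population: str
    statistic: str
    windows: pd.DataFrame          # per-window table with a score column
    score_column: str
    threshold: calibrate.Thresholds
    candidates: list[GenomicWindow]


@dataclass
class SharedSignalMatrix:
    """Candidate counts per population and pairwise intersections."""

    populations: list[str]
    counts: np.ndarray             # symmetric; diagonal = per-population n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.populations,
                            columns=self.populations)


def shared_signal_matrix(results: list[ScanResult]) -> SharedSignalMatrix:
    """Pairwise intersection of candidate window sets (exact identity)."""
    specs = {
        (r.windows["end"] - r.windows["start"]).iloc[0] if len(r.windows) else None
        for r in results
    }
    if len(specs) > 1:
        raise ValueError("candidate sets use different window grids")
    sets = [set(r.candidates) for r in results]
    n = len(results)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            counts[i, j] = len(sets[i] & sets[j]) if i != j else len(sets[i])
    return SharedSignalMatrix([r.population for r in results], counts)


DEFAULT_CONFIG = {
    "seed": 1,
    "out_dir": "admixscan_out",
    "chunk_length": 2_000_000,
    "n_chunks": 4,
    "mu": 1.25e-8,
    "r": 1e-8,
    "maf": 0.05,
    "window": {"size": 30_000, "step": 25_000},
    "calibration": {"q": 99.99, "n_chunks": 4, "chunk_length": 2_000_000},
    "sfs": {"bins": 20, "C": 1.0, "n_rep_per_grid": 5, "n_neutral": 100},
    "ancestry": {"block": 20, "smooth_k": 17, "ref_hap": 24,
                 "n_resamples": 100_000},
    "populations": [
        {"name": "afro1", "preset": "afroasiatic", "n_hap": 48},
        {"name": "gumuz", "preset": "gumuz", "n_hap": 46},
    ],
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _child_seeds(seed: int, names: list[str]) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    return {name: int(rng.integers(1, 2**31 - 1)) for name in names}


def train_default_classifier(
    model, *, cfg_sfs: dict, n_hap: int, L: int = 30_000,
    mu: float, r: float, seed: int,
) -> sfs_scan.ClassifierModel:
    """Train the SFS classifier on single-population neutral vs swept windows.

    Both classes are simulated in a constant-size population of the
    focal deme's size, so the classifier learns the sweep distortion of
    the spectrum rather than demography differences.
    """
    rng = np.random.default_rng(seed)
    B = cfg_sfs["bins"]
    window = GenomicWindow("train", 0, L)
    grid = cfg_sfs.get("grid") or sfs_scan.DEFAULT_GRID
    neutral, swept = [], []
    for _ in range(cfg_sfs["n_neutral"]):
        haps = simulate_sweep(
            model, SweepParams(s=0.0, tau=0, position=L // 2), n_hap, L,
            mu=mu, r=r, seed=int(rng.integers(1, 2**31 - 1)), chrom="train",
        )
        neutral.append(sfs_scan.window_sfs_feature(haps, window, B))
    for s, tau in grid:
        for _ in range(cfg_sfs["n_rep_per_grid"]):
            haps = simulate_sweep(
                model, SweepParams(s=s, tau=tau, position=L // 2), n_hap, L,
                mu=mu, r=r, seed=int(rng.integers(1, 2**31 - 1)), chrom="train",
            )
            swept.append(sfs_scan.window_sfs_feature(haps, window, B))
    return sfs_scan.train_sfselect(
        neutral, swept, C=cfg_sfs["C"], seed=seed,
        metadata={"grid": [list(g) for g in grid],
                  "n_rep_per_grid": cfg_sfs["n_rep_per_grid"], "L": L},
    )


def calibrate_class(
    preset: str, cfg: dict, seed: int, out_dir: Path,
    classifier: sfs_scan.ClassifierModel,
) -> dict[str, calibrate.Thresholds]:
    """Neutral thresholds (iHS per SNP, iHS per window, SFS score) for a class.

    Cached as JSON in ``out_dir``; delete the files to force
    recalibration (recalibration with the same seed reproduces them).
    """
    pop_class = "admixed" if preset == "afroasiatic" else "unadmixed"
    cal = cfg["calibration"]
    spec = WindowSpec(**cfg["window"])
    n_hap = 48 if pop_class == "admixed" else 46
    paths = {
        name: out_dir / f"thresholds_{pop_class}_{name}.json"
        for name in ("ihs_snp", "ihs_window", "sfselect")
    }
    if all(p.exists() for p in paths.values()):
        return {name: calibrate.Thresholds.load(p) for name, p in paths.items()}
    model = build_demography(preset)
    abs_snp, window_means, _ = calibrate.neutral_ihs_null(
        model, n_hap=n_hap, n_chunks=cal["n_chunks"],
        chunk_length=cal["chunk_length"], mu=cfg["mu"], r=cfg["r"],
        seed=seed, maf=cfg["maf"], window_spec=spec,
    )
    prov = {"preset": preset, "seed": seed, "n_chunks": cal["n_chunks"],
            "chunk_length": cal["chunk_length"]}
    out = {
        "ihs_snp": calibrate.percentile_threshold(
            abs_snp, cal["q"], statistic="ihs_snp",
            population_class=pop_class, provenance=prov),
        "ihs_window": calibrate.percentile_threshold(
            window_means, cal["q"], statistic="ihs_window",
            population_class=pop_class, provenance=prov),
    }
    # SFS-score null: score neutral windows with the trained classifier
    rng = np.random.default_rng(seed + 1)
    feats = []
    for i in range(cal["n_chunks"]):
        haps, _ = simulate_neutral(
            model, n_hap, cal["chunk_length"], mu=cfg["mu"], r=cfg["r"],
            seed=int(rng.integers(1, 2**31 - 1)), chrom=f"cal{i}",
        )
        for w in genome_io.make_windows(cal["chunk_length"], spec, chrom=f"cal{i}"):
            feats.append(sfs_scan.window_sfs_feature(haps, w, cfg["sfs"]["bins"]))
    scores = sfs_scan.score_windows(feats, classifier)
    out["sfselect"] = calibrate.percentile_threshold(
        scores, cal["q"], statistic="sfselect",
        population_class=pop_class, provenance=prov)
    for name, thr in out.items():
        thr.save(paths[name])
    return out


def _windows_to_bed(path, windows: list[GenomicWindow], name: str) -> None:
    genome_io.write_bed(path, [(w.chrom, w.start, w.end, name) for w in windows])


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the full scan on simulated populations; returns the report bundle.

    Deterministic for a fixed config: every stage seed is derived from
    the root seed.  Writes scores (TSV), thresholds (JSON), candidate
    windows (BED + annotated TSV), ancestry tracks, enrichment results,
    the shared-signal matrices and a run log into ``out_dir``.
    """
    cfg = load_config(config) if not isinstance(config, dict) else {
        **json.loads(json.dumps(DEFAULT_CONFIG)), **config}
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = ["classifier", "calibration", "data", "ancestry", "enrichment"]
    seeds = _child_seeds(cfg["seed"], stages)
    log_lines = [f"root seed: {cfg['seed']}"] + [
        f"stage seed {k}: {v}" for k, v in seeds.items()]
    spec = WindowSpec(**cfg["window"])
    genes = (genome_io.read_bed_genes(cfg["genes_bed"])
             if cfg.get("genes_bed") else None)

    const_model = build_demography("constant", constant_size=14474)
    classifier_path = out_dir / "sfs_classifier.json"
    if classifier_path.exists():
        classifier = sfs_scan.ClassifierModel.load(classifier_path)
    else:
        classifier = train_default_classifier(
            const_model, cfg_sfs=cfg["sfs"], n_hap=46,
            mu=cfg["mu"], r=cfg["r"], seed=seeds["classifier"],
        )
        classifier.save(classifier_path)

    thresholds = {
        "admixed": calibrate_class("afroasiatic", cfg, seeds["calibration"],
                                   out_dir, classifier),
        "unadmixed": calibrate_class("gumuz", cfg, seeds["calibration"] + 1,
                                     out_dir, classifier),
    }

    results_sfs: list[ScanResult] = []
    results_ihs: list[ScanResult] = []
    data_rng = np.random.default_rng(seeds["data"])
    report: dict = {"thresholds": thresholds, "populations": {}}
    for pop_cfg in cfg["populations"]:
        name, preset, n_hap = pop_cfg["name"], pop_cfg["preset"], pop_cfg["n_hap"]
        pop_class = "admixed" if preset == "afroasiatic" else "unadmixed"
        thr = thresholds[pop_class]
        log_lines.append(f"population {name}: preset={preset} class={pop_class}")
        model = build_demography(preset)
        extra = None
        if pop_class == "admixed":
            ref_hap = cfg["ancestry"]["ref_hap"]
            extra = {"AFR": ref_hap, "EUR": ref_hap}
        tables, windows_all, feats, wins = [], [], [], []
        track_parts, sel_tracks = [], []
        for i in range(cfg["n_chunks"]):
            child = int(data_rng.integers(1, 2**31 - 1))
            haps, tracts = simulate_neutral(
                model, n_hap, cfg["chunk_length"], mu=cfg["mu"], r=cfg["r"],
                seed=child, chrom=f"{name}_chr{i}", extra_samples=extra,
            )
            ids = np.array(haps.haplotype_ids)
            focal = haps.take_haplotypes(
                np.where(np.char.startswith(ids, model.focal_population))[0])
            filtered = genome_io.maf_filter(focal, cfg["maf"])
            tables.append(ihs_scan.ihs_table(filtered))
            cw = genome_io.make_windows(cfg["chunk_length"], spec,
                                        chrom=f"{name}_chr{i}")
            windows_all.extend(cw)
            for w in cw:
                feats.append(sfs_scan.window_sfs_feature(
                    filtered, w, cfg["sfs"]["bins"]))
            if pop_class == "admixed":
                joint = genome_io.maf_filter(haps, cfg["maf"])
                jids = np.array(joint.haplotype_ids)
                q = joint.take_haplotypes(
                    np.where(np.char.startswith(jids, model.focal_population))[0])
                ra = joint.take_haplotypes(np.where(np.char.startswith(jids, "AFR_"))[0])
                rw = joint.take_haplotypes(np.where(np.char.startswith(jids, "EUR_"))[0])
                asg = ancestry.assign_local_ancestry(
                    q, ra, rw, block=cfg["ancestry"]["block"],
                    smooth_k=cfg["ancestry"]["smooth_k"])
                masked = ancestry.mask(q, asg)
                track_parts.append(ancestry.window_ancestry_track(masked, cw))
        records = ihs_scan.standardize(pd.concat(tables, ignore_index=True))
        records = ihs_scan.add_pvalues(records)
        wtab = ihs_scan.window_ihs(records, windows_all)
        wtab["sfs_score"] = sfs_scan.score_windows(feats, classifier)
        records.to_csv(out_dir / f"{name}_ihs_records.tsv", sep="\t", index=False)
        wtab.to_csv(out_dir / f"{name}_windows.tsv", sep="\t", index=False)

        pop_report = {"class": pop_class}
        for stat, column in (("sfselect", "sfs_score"), ("ihs_window", "mean_abs_ihs")):
            hits = calibrate.call_candidates(wtab, thr[stat], column)
            cand = [GenomicWindow(r.chrom, int(r.start), int(r.end))
                    for r in hits.itertuples()]
            _windows_to_bed(out_dir / f"{name}_candidates_{stat}.bed", cand, stat)
            annotated = hits.copy()
            annotated["threshold"] = thr[stat].value
            if genes is not None:
                annotated["genes"] = [",".join(g) for g in
                                      genome_io.intersect_genes(cand, genes)]
            annotated.to_csv(out_dir / f"{name}_candidates_{stat}.tsv",
                             sep="\t", index=False)
            result = ScanResult(name, stat, wtab, column, thr[stat], cand)
            (results_sfs if stat == "sfselect" else results_ihs).append(result)
            pop_report[f"n_candidates_{stat}"] = len(cand)
            if pop_class == "admixed" and track_parts:
                track = np.concatenate(track_parts)
                sel_idx = [i for i, w in enumerate(windows_all) if w in set(cand)]
                if sel_idx:
                    enr = ancestry.enrichment_resampling(
                        track, np.array(sel_idx),
                        n_resamples=cfg["ancestry"]["n_resamples"],
                        seed=seeds["enrichment"])
                    with open(out_dir / f"{name}_enrichment_{stat}.json", "w") as fh:
                        json.dump(enr.__dict__, fh, indent=1, default=str)
                    pop_report[f"enrichment_{stat}_p"] = enr.p
        if pop_class == "admixed" and track_parts:
            track = np.concatenate(track_parts)
            pd.DataFrame({
                "chrom": [w.chrom for w in windows_all],
                "start": [w.start for w in windows_all],
                "end": [w.end for w in windows_all],
                "wea_fraction": track,
            }).to_csv(out_dir / f"{name}_ancestry_track.tsv", sep="\t", index=False)
            regions = ancestry.unbalanced_regions(
                track, windows_all, seed=seeds["enrichment"] + 1)
            genome_io.write_bed(
                out_dir / f"{name}_unbalanced.bed",
                [(rg.chrom, rg.start, rg.end, f"{rg.mean_fraction:.3f}")
                 for rg in regions])
            pop_report["genome_wea_fraction"] = float(np.nanmean(track))
            pop_report["n_unbalanced_regions"] = len(regions)
        report["populations"][name] = pop_report

    for stat, results in (("sfselect", results_sfs), ("ihs", results_ihs)):
        if results:
            matrix = shared_signal_matrix(results)
            matrix.to_frame().to_csv(out_dir / f"shared_{stat}.tsv", sep="\t")
            report[f"shared_{stat}"] = matrix
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, calibrate.Thresholds):
        return obj.__dict__
    if isinstance(obj, SharedSignalMatrix):
        return {"populations": obj.populations, "counts": obj.counts.tolist()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
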