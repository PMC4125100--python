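"""Config-driven orchestration of the analysis stages.

A run takes a sync table plus manifest (or generates a synthetic
experiment), applies the SNP screens, the Salt-vs-Cad differentiation
scan with its permutation null, window summaries, diversity-by-ancestral-
differentiation comparisons, coverage-matched F_ST, and the
conditional-neutrality / correlation diagnostics, writing per-stage TSVs
and a machine-readable summary.  A single global seed deterministically
derives per-stage seeds so stages can be rerun independently.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import evoregime
from evoregime import differentiation as diff
from evoregime import diversity_fst as dfst
from evoregime import genome_patterns as gp
from evoregime import site_screens as scr
from evoregime.experiment import ExperimentConfig, generate_experiment
from evoregime.sync_io import PopulationManifest, read_sync


@dataclass
class RunConfig:
    sync: str | None = None
    manifest: str | None = None
    synth: dict | None = None  # ExperimentConfig fields
    stages: tuple = ("screens", "scan", "null", "windows", "diversity", "fst", "patterns")
    screen: dict = field(default_factory=dict)
    scan_rule: str = "combined"
    fdr: float = 1e-5
    null_combinations: int = 15
    fst_repeats: int = 10
    window_diff: int = 5000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the stage name."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def treatment_columns(bi: scr.BiallelicTable, treatment: str, ancestor: str | None = None):
    """Minor-allele counts and allelic coverages for a treatment's
    replicate populations, optionally with the ancestor as column 0."""
    names = ([ancestor] if ancestor else []) + bi.manifest.treatment(treatment)
    cols = bi.manifest.indices(names)
    return bi.minor_count[:, cols], bi.allelic_cov[:, cols]


def site_pi_matrix(bi: scr.BiallelicTable, populations) -> np.ndarray:
    """Per-site biallelic heterozygosity 2 f (1-f) for the populations."""
    cols = bi.manifest.indices(populations)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(
            bi.allelic_cov[:, cols] > 0, bi.minor_count[:, cols] / bi.allelic_cov[:, cols], np.nan
        )
    return 2.0 * f * (1.0 - f)


def headline_patterns(seed: int, n_sites: int = 20_000, s_eas: float = 0.1) -> dict:
    """Run a planted-selection experiment and check the headline
    diversity / differentiation orderings among treatments.

    Returns the treatment means plus boolean flags: at strongly
    ancestrally differentiated sites pi orders Spatial > Temp > both
    constants; at weakly differentiated sites Temp is lowest; and the
    coverage-matched within-treatment F_ST at weakly differentiated
    sites is highest for Temp.
    """
    xcfg = ExperimentConfig(n_sites=n_sites, s_eas=s_eas, seed=seed)
    sync, manifest, truth = generate_experiment(xcfg)
    bi = scr.reduce_biallelic(sync)
    chi = scr.screen_chi(bi)
    scfg = scr.ScreenConfig()
    high_pi = np.nan_to_num(bi.pi_ini) > scfg.high_pi_threshold
    strata = scr.stratify_d(np.nan_to_num(bi.d), scfg)["stratum"].to_numpy()
    treatments = ("Salt", "Cad", "Temp", "Spatial")
    pi_mean = {}
    for stratum in ("low", "high"):
        keep = chi & high_pi & (strata == stratum)
        for t in treatments:
            mat = site_pi_matrix(bi, bi.manifest.treatment(t))[keep]
            pi_mean[(t, stratum)] = float(np.nanmean(mat)) if keep.any() else np.nan
    keep = chi & high_pi & (strata == "low")
    tr = {t: tuple(a[keep] for a in treatment_columns(bi, t)) for t in treatments}
    fst = dfst.coverage_matched_fst(tr, repeats=10, seed=seed)
    fst_of = dict(zip(fst["treatment"], fst["fst"]))
    out = {
        "pi": {f"{t}:{s}": v for (t, s), v in pi_mean.items()},
        "fst": fst_of,
        "high_d_order": (
            pi_mean[("Spatial", "high")] > pi_mean[("Temp", "high")] >
            max(pi_mean[("Salt", "high")], pi_mean[("Cad", "high")])
        ),
        "low_d_temp_lowest": (
            pi_mean[("Temp", "low")] == min(pi_mean[(t, "low")] for t in treatments)
        ),
        "fst_temp_highest": fst_of["Temp"] == max(fst_of.values()),
    }
    return out


def run(cfg: RunConfig, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"evoregime {evoregime.__version__}", f"seed {cfg.seed}"]
    summary: dict = {"seed": cfg.seed}

    # ------------------------------------------------------------------ data
    if cfg.synth is not None:
        xcfg = ExperimentConfig(**{**cfg.synth, "seed": stage_seed(cfg.seed, "synth")})
        sync, manifest, truth = generate_experiment(xcfg)
        truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
        log.append(f"synth: {xcfg.n_sites} sites, seed {xcfg.seed}")
    elif cfg.sync and cfg.manifest:
        manifest = PopulationManifest.read_tsv(cfg.manifest)
        sync = read_sync(cfg.sync, manifest)
        truth = None
        log.append(f"loaded {len(sync)} sites from {cfg.sync}")
    else:
        raise FileNotFoundError("RunConfig needs either synth parameters or sync+manifest paths")

    scfg = scr.ScreenConfig(**cfg.screen)
    try:
        # -------------------------------------------------------------- screens
        bi = scr.reduce_biallelic(sync)
        alpha = scr.screen_alpha(bi, scfg)
        chi = scr.screen_chi(bi, scfg)
        strata = scr.stratify_d(np.nan_to_num(bi.d), scfg)
        sites = bi.to_frame()
        sites["alpha"] = alpha
        sites["chi"] = chi
        sites["high_pi"] = sites["pi_ini"] > scfg.high_pi_threshold
        sites["d_stratum"] = strata["stratum"].to_numpy()
        if "screens" in cfg.stages:
            sites.to_csv(outdir / "sites.tsv", sep="\t", index=False)
        summary["n_sites"] = int(len(sync))
        summary["n_biallelic"] = int(len(bi))
        summary["n_alpha"] = int(alpha.sum())
        summary["n_chi"] = int(chi.sum())
        log.append(f"screens: {alpha.sum()} alpha, {chi.sum()} chi of {len(bi)} biallelic")

        # -------------------------------------------------------------- scan
        scan = None
        if "scan" in cfg.stages:
            m1, c1 = treatment_columns(bi, "Salt", ancestor="AS")
            m2, c2 = treatment_columns(bi, "Cad", ancestor="AC")
            a = np.flatnonzero(alpha)
            scan = diff.scan_pair(m1[a], c1[a], m2[a], c2[a], rule=cfg.scan_rule, fdr=cfg.fdr)
            scan.insert(0, "chrom", bi.chrom[a])
            scan.insert(1, "pos", bi.pos[a])
            scan.to_csv(outdir / "beta.tsv", sep="\t", index=False)
            summary["n_beta"] = int(scan["beta"].sum())
            log.append(f"scan: {summary['n_beta']} beta-sites at FDR {cfg.fdr}")

        if "null" in cfg.stages:
            mS, cS = treatment_columns(bi, "Salt")
            mC, cC = treatment_columns(bi, "Cad")
            a = np.flatnonzero(alpha)
            null = diff.pseudo_treatment_null(
                mC[a], cC[a], mS[a], cS[a],
                n_combinations=cfg.null_combinations,
                seed=stage_seed(cfg.seed, "null"),
                rule=cfg.scan_rule, fdr=cfg.fdr,
            )
            null.to_csv(outdir / "pseudo_null.tsv", sep="\t", index=False)
            summary["null_beta_mean"] = null.attrs["mean_beta"]
            summary["null_beta_max"] = null.attrs["max_beta"]
            log.append(f"null: mean {null.attrs['mean_beta']:.1f}, max {null.attrs['max_beta']}")

        if "windows" in cfg.stages and scan is not None:
            win = diff.window_differentiation(
                scan, scan["chrom"].to_numpy(), scan["pos"].to_numpy(), cfg.window_diff
            )
            win.to_csv(outdir / "windows.tsv", sep="\t", index=False)

        # -------------------------------------------------------------- diversity
        if "diversity" in cfg.stages:
            keep = chi & (sites["high_pi"].to_numpy())
            rows = []
            for t in ("Salt", "Cad", "Temp", "Spatial"):
                mat = site_pi_matrix(bi, bi.manifest.treatment(t))[keep]
                st = dfst.pi_by_stratum(np.nan_to_num(mat), sites.loc[keep, "d_stratum"].to_numpy())
                st.insert(0, "treatment", t)
                rows.append(st)
            piv = pd.concat(rows, ignore_index=True)
            piv.to_csv(outdir / "pi_by_stratum.tsv", sep="\t", index=False)
            summary["pi_by_stratum"] = {
                f"{r.treatment}:{r.stratum}": r.mean_pi for r in piv.itertuples()
            }

        # -------------------------------------------------------------- fst
        if "fst" in cfg.stages:
            keep = chi & sites["high_pi"].to_numpy() & (sites["d_stratum"] == "low").to_numpy()
            tr = {}
            for t in ("Salt", "Cad", "Temp", "Spatial"):
                m, c = treatment_columns(bi, t)
                tr[t] = (m[keep], c[keep])
            fst = dfst.coverage_matched_fst(
                tr, repeats=cfg.fst_repeats, seed=stage_seed(cfg.seed, "fst")
            )
            fst.to_csv(outdir / "fst.tsv", sep="\t", index=False)
            summary["fst"] = dict(zip(fst["treatment"], fst["fst"]))
            log.append("fst: " + ", ".join(f"{k}={v:.4f}" for k, v in summary["fst"].items()))

        # -------------------------------------------------------------- patterns
        if "patterns" in cfg.stages and scan is not None and scan["beta"].any():
            a = np.flatnonzero(alpha)
            beta_idx = a[scan["beta"].to_numpy()]
            freqs = bi.freqs()
            man = bi.manifest
            mean_f = lambda t: np.nanmean(freqs[:, man.indices(man.treatment(t))], axis=1)
            labels = gp.classify_conditional_neutrality(
                freqs[beta_idx, man.index("GA")],
                freqs[beta_idx, man.index("AC")],
                freqs[beta_idx, man.index("AS")],
                mean_f("Cad")[beta_idx],
                mean_f("Salt")[beta_idx],
            )
            vals, cts = np.unique(labels, return_counts=True)
            summary["conditional_neutrality"] = dict(zip(vals.tolist(), cts.astype(int).tolist()))
    except Exception as exc:  # partial outputs stay on disk for debugging
        log.append(f"FAILED: {exc}")
        (outdir / "run.log").write_text("\n".join(log) + "\n")
        raise
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float) + "\n")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return summary
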