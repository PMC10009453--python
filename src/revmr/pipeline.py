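"""End-to-end study orchestration: simulate/ingest through report.

``run_study`` executes the configured stages in dependency order —
simulate (or ingest), instrument selection and LD pruning, per-outcome
harmonisation and estimation, radial outlier screening, multivariable
MR, age-stratified estimation with cross-stratum contrasts, the
correlated-trait multiplicity threshold, and the two-exposure profile
comparison — writing long-format tab-separated tables plus a manifest
with a SHA-256 digest of every output.  A single master seed fans out to
per-stage streams; re-running an identical configuration reproduces
identical digests.

The configuration is a YAML mapping; see :data:`DEFAULT_STUDY_CONFIG`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import scale_per_doubling
from .exceptions import ConfigError, ReportError, RevmrError
from .harmonise import harmonise
from .panel import (
    PanelResult,
    contrasts_to_frame,
    effective_tests_threshold,
    profile_comparison,
    run_panel,
    stratum_contrast,
)
from .robustness import mvmr_ivw, radial_ivw
from .simulate import SimulationConfig, simulate_study
from .sumstats import (
    exclude_snps,
    ld_prune,
    mean_f_statistic,
    read_ld_matrix,
    read_sumstats,
    select_instruments,
    write_ld_matrix,
    write_sumstats,
)

logger = logging.getLogger(__name__)

DEFAULT_STUDY_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_snp": 150,
        "theta": 0.3,
        "ld_n_blocks": 30,
        "panel": {"n_traits": 8, "trait_corr": 0.3},
        "strata": {"medication_modifier": -2.5},
        "second_exposure": {"theta2": 0.1, "gamma_corr": 0.5},
    },
    "instruments": {"p_threshold": 5e-8, "r2_threshold": 0.001},
    "harmonise": {"palindrome_eaf_limit": 0.42},
    "exclude": [],
    "estimators": {"n_boot": 300, "phi": 1.0, "re_model": "multiplicative_random"},
    "radial": {"p_threshold": 0.05},
    "mvmr": {"enabled": "auto"},
    "multiplicity": {"variance_fraction": 0.95, "alpha": 0.05, "n_components": None},
}


@dataclass
class StageRecord:
    stage: str
    status: str  # "ok" | "failed" | "skipped"
    outputs: dict[str, str] = field(default_factory=dict)
    message: str = ""
    elapsed_s: float = 0.0


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config: dict
    seed: int
    version: str
    stages: list[StageRecord] = field(default_factory=list)
    started: str = ""
    finished: str = ""
    warnings: int = 0

    @property
    def ok(self) -> bool:
        return all(s.status != "failed" for s in self.stages)

    @property
    def output_digests(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for s in self.stages:
            out.update(s.outputs)
        return out

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "started": self.started,
            "finished": self.finished,
            "warnings": self.warnings,
            "stages": [dataclasses.asdict(s) for s in self.stages],
        }

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_STUDY_CONFIG))
    for key, value in (user or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def load_config(path_or_dict: str | Path | dict | None) -> dict:
    if path_or_dict is None:
        user = {}
    elif isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        user = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    cfg = _merge_config(user)
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    """Fail fast, before any stage runs."""
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigError("config must provide either 'simulate' or 'inputs'")
    two_exposures = bool(
        cfg.get("simulate", {}).get("second_exposure")
        or cfg.get("inputs", {}).get("exposure2")
    )
    if cfg.get("mvmr", {}).get("enabled") is True and not two_exposures:
        raise ConfigError("multivariable MR requested but only one exposure configured")
    p = cfg["instruments"]["p_threshold"]
    if not (0 < p <= 1):
        raise ConfigError("instruments.p_threshold must be in (0, 1]")
    r2 = cfg["instruments"]["r2_threshold"]
    if not (0 <= r2 < 1):
        raise ConfigError("instruments.r2_threshold must be in [0, 1)")


class _Study:
    """Resolved inputs for one run, simulated or ingested."""

    def __init__(self, cfg: dict, out_dir: Path):
        self.cfg = cfg
        self.out = out_dir
        self.exposures = []
        self.outcomes = []
        self.strata_tables = {}
        self.ld = None
        self.panel_corr = None
        self.truth = None

    def materialise(self) -> list[Path]:
        written: list[Path] = []
        if "simulate" in self.cfg:
            sim_cfg = SimulationConfig.from_dict(
                {**self.cfg["simulate"], "seed": self.cfg["seed"]})
            study = simulate_study(sim_cfg)
            self.exposures = [study.exposure]
            if study.exposure2 is not None:
                self.exposures.append(study.exposure2)
            self.outcomes = study.panel_tables or [study.outcome]
            self.strata_tables = study.strata_tables
            self.ld = study.ld
            self.panel_corr = study.panel_corr
            self.truth = study.truth
            inputs = self.out / "inputs"
            inputs.mkdir(parents=True, exist_ok=True)
            for t in self.exposures + self.outcomes:
                p = inputs / f"{t.trait_name}.tsv"
                write_sumstats(t, p)
                written.append(p)
            for label, t in self.strata_tables.items():
                p = inputs / f"{t.trait_name}_{label}.tsv"
                write_sumstats(t, p)
                written.append(p)
            p = inputs / "ld_matrix.tsv"
            write_ld_matrix(self.ld, p)
            written.append(p)
        else:
            spec = self.cfg["inputs"]
            self.exposures = [read_sumstats(spec["exposure"],
                                            trait_type="binary_disease")]
            if spec.get("exposure2"):
                self.exposures.append(read_sumstats(spec["exposure2"],
                                                    trait_type="binary_disease"))
            self.outcomes = [read_sumstats(p) for p in spec["outcomes"]]
            if spec.get("ld"):
                self.ld = read_ld_matrix(spec["ld"])
        return written


def run_study(config: str | Path | dict | None, out_dir: str | Path) -> RunManifest:
    """Execute all configured stages; failures are recorded, not raised.

    Returns the manifest; callers map ``manifest.ok`` onto the process
    exit status.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=int(cfg["seed"]), version=__version__,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    study = _Study(cfg, out)
    instruments = []
    panels: list[PanelResult] = []
    est_cfg = cfg["estimators"]

    def stage(name: str, fn, *, skip: str | None = None):
        rec = StageRecord(stage=name, status="skipped", message=skip or "")
        if skip is None:
            t0 = time.perf_counter()
            try:
                paths = fn() or []
                rec.status = "ok"
                rec.outputs = {str(p.relative_to(out)): _sha256(p) for p in paths}
            except RevmrError as exc:
                rec.status = "failed"
                rec.message = str(exc)
                logger.error("stage %s failed: %s", name, exc)
            rec.elapsed_s = round(time.perf_counter() - t0, 3)
        manifest.stages.append(rec)
        return rec.status == "ok"

    ok_inputs = stage("inputs", study.materialise)

    def do_instruments():
        paths = []
        for exp in study.exposures:
            sel = select_instruments(exp, cfg["instruments"]["p_threshold"])
            if study.ld is not None:
                sel = ld_prune(sel, study.ld, cfg["instruments"]["r2_threshold"])
            if cfg.get("exclude"):
                sel = exclude_snps(sel, cfg["exclude"])
            instruments.append(sel)
            p = out / f"instruments_{sel.trait_name}.tsv"
            write_sumstats(sel, p)
            paths.append(p)
        diag = pd.DataFrame(
            {
                "exposure": [s.trait_name for s in instruments],
                "n_instruments": [len(s) for s in instruments],
                "mean_f": [mean_f_statistic(s) for s in instruments],
            }
        )
        p = out / "instrument_strength.tsv"
        diag.to_csv(p, sep="\t", index=False)
        paths.append(p)
        return paths

    ok_instruments = stage("instruments", do_instruments,
                           skip=None if ok_inputs else "inputs failed")

    def do_panel():
        frames = []
        for i, exp_instruments in enumerate(instruments):
            pr = run_panel(
                exp_instruments, study.outcomes,
                palindrome_eaf_limit=cfg["harmonise"]["palindrome_eaf_limit"],
                n_boot=est_cfg["n_boot"], seed=int(cfg["seed"]) + i,
                phi=est_cfg["phi"], re_model=est_cfg["re_model"],
            )
            panels.append(pr)
            frames.append(pr.to_frame())
        p = out / "results_panel.tsv"
        pd.concat(frames, ignore_index=True).to_csv(p, sep="\t", index=False)
        return [p]

    ok_panel = stage("panel", do_panel,
                     skip=None if ok_instruments else "instruments failed")

    def do_radial():
        rows, qrows = [], []
        exp = instruments[0]
        for outcome in study.outcomes:
            h = harmonise(exp, outcome, cfg["harmonise"]["palindrome_eaf_limit"])
            res = radial_ivw(h, p_threshold=cfg["radial"]["p_threshold"])
            for which, e in (("all_snps", res.estimate_with),
                             ("outliers_excluded", res.estimate_without)):
                e = scale_per_doubling(e)
                rows.append({"exposure": exp.trait_name,
                             "outcome": outcome.trait_name, "fit": which,
                             "beta": e.beta, "se": e.se, "pval": e.pval,
                             "n_snp": e.n_snp,
                             "n_outliers": len(res.outliers),
                             "q_total": res.q_total})
            for rs, q in res.per_snp_q.items():
                qrows.append({"outcome": outcome.trait_name, "rsid": rs,
                              "q": q, "outlier": rs in res.outliers})
        p1 = out / "radial_summary.tsv"
        pd.DataFrame(rows).to_csv(p1, sep="\t", index=False)
        p2 = out / "radial_per_snp_q.tsv"
        pd.DataFrame(qrows).to_csv(p2, sep="\t", index=False)
        return [p1, p2]

    stage("radial", do_radial,
          skip=None if ok_instruments else "instruments failed")

    mvmr_requested = cfg["mvmr"]["enabled"] is True or (
        cfg["mvmr"]["enabled"] == "auto" and len(study.exposures) > 1)

    def do_mvmr():
        est = mvmr_ivw(study.exposures, study.outcomes[0], ld=study.ld,
                       p_threshold=cfg["instruments"]["p_threshold"],
                       r2_threshold=cfg["instruments"]["r2_threshold"])
        df = pd.DataFrame({
            "exposure": est.exposure_names,
            "beta": est.betas, "se": est.ses, "pval": est.pvals,
            "n_snp": est.n_snp, "note": est.conditioning_note,
        })
        p = out / "mvmr.tsv"
        df.to_csv(p, sep="\t", index=False)
        return [p]

    stage("mvmr", do_mvmr,
          skip=None if (ok_instruments and mvmr_requested)
          else ("instruments failed" if mvmr_requested else "single exposure"))

    def do_strata():
        frames, per_stratum = [], {}
        for label, table in study.strata_tables.items():
            pr = run_panel(
                instruments[0], [table], stratum_label=label,
                palindrome_eaf_limit=cfg["harmonise"]["palindrome_eaf_limit"],
                n_boot=est_cfg["n_boot"], seed=int(cfg["seed"]),
                phi=est_cfg["phi"], re_model=est_cfg["re_model"],
            )
            per_stratum[label] = pr
            frames.append(pr.to_frame())
        p1 = out / "results_strata.tsv"
        pd.concat(frames, ignore_index=True).to_csv(p1, sep="\t", index=False)
        labels = list(per_stratum)
        contrasts = stratum_contrast(per_stratum[labels[-1]],
                                     per_stratum[labels[0]], method="ivw")
        p2 = out / "stratum_contrasts.tsv"
        contrasts_to_frame(contrasts).to_csv(p2, sep="\t", index=False)
        return [p1, p2]

    stage("strata", do_strata,
          skip=None if (ok_instruments and study.strata_tables)
          else ("instruments failed" if study.strata_tables else "no strata configured"))

    def do_multiplicity():
        mcfg = cfg["multiplicity"]
        if mcfg.get("n_components"):
            k = int(mcfg["n_components"])
            raw = mcfg["alpha"] / k
            eff = {"n_components": k, "threshold": raw,
                   "threshold_rounded": float(f"{raw:.0e}")}
        else:
            if study.panel_corr is None:
                raise ConfigError("no panel correlation available; set "
                                  "multiplicity.n_components explicitly")
            res = effective_tests_threshold(
                study.panel_corr, mcfg["variance_fraction"], mcfg["alpha"])
            eff = {"n_components": res.n_components, "threshold": res.threshold,
                   "threshold_rounded": res.threshold_rounded}
        p = out / "effective_tests.tsv"
        pd.DataFrame([eff]).to_csv(p, sep="\t", index=False)
        return [p]

    stage("multiplicity", do_multiplicity,
          skip=None if ok_panel else "panel failed")

    def do_profile():
        pc = profile_comparison(panels[0], panels[1], method="ivw")
        df = pd.DataFrame({"trait": pc.traits, "beta_exposure1": pc.x,
                           "beta_exposure2": pc.y})
        p1 = out / "profile_xy.tsv"
        df.to_csv(p1, sep="\t", index=False)
        p2 = out / "profile_fit.tsv"
        pd.DataFrame([{"slope": pc.slope, "intercept": pc.intercept,
                       "r2": pc.r2, "n_traits": pc.n_traits}]).to_csv(
            p2, sep="\t", index=False)
        return [p1, p2]

    stage("profile", do_profile,
          skip=None if (ok_panel and len(instruments) > 1)
          else ("panel failed" if len(study.exposures) > 1 else "single exposure"))

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.warnings = sum(1 for s in manifest.stages if s.status == "failed")
    manifest.write(out / "manifest.json")
    return manifest


def report(results_dir: str | Path, make_plot: bool = True) -> str:
    """Human-readable summary of a completed run.

    Sorts panel estimates, flags those passing the effective-tests
    threshold (writing ``flagged.tsv``), and draws the two-exposure XY
    scatter when profile output is present.
    """
    out = Path(results_dir)
    panel_path = out / "results_panel.tsv"
    eff_path = out / "effective_tests.tsv"
    for p in (panel_path, eff_path):
        if not p.exists():
            raise ReportError(f"missing results table: {p.name}")
    panel = pd.read_csv(panel_path, sep="\t")
    if panel.empty:
        raise ReportError("results_panel.tsv is empty")
    eff = pd.read_csv(eff_path, sep="\t").iloc[0]
    threshold = float(eff["threshold_rounded"])

    flagged = panel[panel["pval"] < threshold].sort_values(
        ["exposure", "outcome", "method"])
    flagged.to_csv(out / "flagged.tsv", sep="\t", index=False)

    lines = [
        f"revmr report — {out}",
        f"effective number of tests: {int(eff['n_components'])}; "
        f"p threshold {threshold:g}",
        f"estimates: {len(panel)} rows over "
        f"{panel['outcome'].nunique()} outcome(s), "
        f"{panel['exposure'].nunique()} exposure(s)",
        f"flagged at p < {threshold:g}: {len(flagged)} rows "
        f"({flagged['outcome'].nunique()} outcome(s))",
    ]
    fit_path = out / "profile_fit.tsv"
    xy_path = out / "profile_xy.tsv"
    if fit_path.exists() and xy_path.exists():
        fit = pd.read_csv(fit_path, sep="\t").iloc[0]
        lines.append(
            f"profile comparison: slope {fit['slope']:.3f}, "
            f"R2 {fit['r2']:.3f} over {int(fit['n_traits'])} traits")
        if make_plot:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            xy = pd.read_csv(xy_path, sep="\t")
            fig, ax = plt.subplots(figsize=(5, 5))
            ax.scatter(xy["beta_exposure1"], xy["beta_exposure2"], s=18)
            grid = np.linspace(xy["beta_exposure1"].min(),
                               xy["beta_exposure1"].max(), 10)
            ax.plot(grid, fit["intercept"] + fit["slope"] * grid, lw=1)
            ax.axhline(0, lw=0.5, color="grey")
            ax.axvline(0, lw=0.5, color="grey")
            ax.set_xlabel("effect per doubling of liability, exposure 1")
            ax.set_ylabel("effect per doubling of liability, exposure 2")
            fig.tight_layout()
            fig.savefig(out / "profile_xy.png", dpi=120, metadata={"Date": None})
            plt.close(fig)
            lines.append("wrote profile_xy.png")
    text = "\n".join(lines)
    (out / "report.txt").write_text(text + "\n")
    return text
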