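"""End-to-end orchestration of the synthetic fracture-risk experiment.

simulate -> split -> GWAS on train -> LD prune -> LASSO over the p-value
threshold grid -> select on the held-out set -> score the test set ->
standardize -> odds-space FRAX adjustment -> evaluation battery
(association, discrimination, reclassification). Every stage logs its
seed and row/variant counts; a fixed seed reproduces the run byte for
byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate, frax, gwas, prs, synthetic

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """All scientific parameters of a pipeline run, with the method
    constants as defaults (per-SD odds ratios 1.42/1.80, split
    0.80/0.0125/0.1875, LD r^2 cutoff 0.05, the six-threshold grid,
    treatment cutoffs 0.20/0.03, 200 bootstrap replicates)."""

    n: int = 20000
    m: int = 1000
    block_size: int = 10
    rho: float = 0.3
    maf_low: float = 0.05
    maf_high: float = 0.5
    h2: float = 0.25
    prop_causal: float = 0.05
    per_sd_or_mof: float = 1.42
    per_sd_or_hip: float = 1.80
    base_rate_mof: float = synthetic.DEFAULT_BASE_RATES[0]
    base_rate_hip: float = synthetic.DEFAULT_BASE_RATES[1]
    followup_years: float = 10.0
    train_fraction: float = 0.80
    select_fraction: float = 0.0125
    test_fraction: float = 0.1875
    threshold_grid: tuple[float, ...] = prs.DEFAULT_THRESHOLD_GRID
    r2_max: float = 0.05
    factor_mof: float = 1.42
    factor_hip: float = 1.80
    cutoff_mof: float = 0.20
    cutoff_hip: float = 0.03
    bootstrap_B: int = 200
    n_pcs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.n >= 1 and self.m >= 1, "n and m must be >= 1"),
            (0 < self.h2 < 1, "h2 must be in (0, 1)"),
            (0 < self.prop_causal <= 1, "prop_causal must be in (0, 1]"),
            (self.per_sd_or_mof > 0 and self.per_sd_or_hip > 0, "odds ratios must be positive"),
            (0 <= self.rho < 1, "rho must be in [0, 1)"),
            (0 < self.r2_max <= 1, "r2_max must be in (0, 1]"),
            (0 < self.cutoff_mof < 1 and 0 < self.cutoff_hip < 1, "cutoffs must be in (0, 1)"),
            (
                abs(self.train_fraction + self.select_fraction + self.test_fraction - 1) < 1e-9,
                "split fractions must sum to 1",
            ),
            (self.bootstrap_B >= 1, "bootstrap_B must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["threshold_grid"] = list(self.threshold_grid)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "threshold_grid" in raw:
            raw["threshold_grid"] = tuple(float(t) for t in raw["threshold_grid"])
        return cls(**raw)


def _stage(name: str, **info):
    logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full experiment; returns a report bundle (dict of
    metric dictionaries plus stage metadata) and optionally writes the
    scoring file, adjusted cohort and JSON report under ``outdir``."""
    t0 = time.time()
    cfg = config
    rng_seed = cfg.seed
    bundle: dict = {"config": dataclasses.asdict(cfg), "stages": {}}

    def record(name, **info):
        info["elapsed_s"] = round(time.time() - t0, 2)
        bundle["stages"][name] = info
        _stage(name, **info)

    try:
        G = synthetic.simulate_genotypes(
            cfg.n, cfg.m, cfg.block_size, cfg.rho,
            (cfg.maf_low, cfg.maf_high), seed=rng_seed,
        )
        record("simulate_genotypes", n=cfg.n, m=cfg.m, seed=rng_seed)

        sos, arch = synthetic.simulate_sos(G, cfg.h2, cfg.prop_causal, seed=rng_seed + 1)
        cohort = synthetic.simulate_clinical_factors(cfg.n, seed=rng_seed + 2)
        cohort["sos"] = sos
        cohort = synthetic.default_baseline_risk(
            cohort, (cfg.base_rate_mof, cfg.base_rate_hip)
        )
        cohort = synthetic.simulate_fractures(
            cohort, sos, cfg.per_sd_or_mof, cfg.per_sd_or_hip,
            (cfg.base_rate_mof, cfg.base_rate_hip), cfg.followup_years,
            seed=rng_seed + 3,
        )
        cohort = synthetic.split_cohort(
            cohort,
            (cfg.train_fraction, cfg.select_fraction, cfg.test_fraction),
            seed=rng_seed + 4,
        )
        record(
            "simulate_cohort",
            n=cfg.n,
            mof_events=int(cohort["incident_mof"].sum()),
            hip_events=int(cohort["incident_hip"].sum()),
        )

        idx = {s: np.flatnonzero((cohort["split"] == s).to_numpy()) for s in ("train", "select", "test")}
        G_train = G.subset_individuals(idx["train"])
        G_select = G.subset_individuals(idx["select"])
        G_test = G.subset_individuals(idx["test"])
        y_train = sos[idx["train"]]
        y_select = sos[idx["select"]]

        pcs = gwas.compute_pcs(G_train, k=min(cfg.n_pcs, len(idx["train"]) - 2, cfg.m))
        covars = np.column_stack(
            [
                cohort["age"].to_numpy()[idx["train"]],
                cohort["sex"].to_numpy()[idx["train"]],
                pcs,
            ]
        )
        summaries = gwas.run_gwas(G_train, y_train, covars)
        record("gwas", n=len(idx["train"]), m=cfg.m, n_pcs=pcs.shape[1])

        candidates = prs.fit_grid(
            G_train, y_train, summaries, G_select, y_select,
            thresholds=cfg.threshold_grid, r2_max=cfg.r2_max,
        )
        model = prs.select_model(candidates)
        record(
            "prs_training",
            threshold=model.threshold,
            n_active=model.n_active,
            r2_select=round(model.r2_select, 4),
        )

        raw_scores = prs.score(G_test, model)
        if np.std(raw_scores) == 0:
            raise RuntimeError("selected model produced a constant score on the test set")
        z = frax.standardize_scores(raw_scores)
        test = cohort.iloc[idx["test"]].reset_index(drop=True)
        test["gsos"] = z
        test = frax.adjust_cohort(
            test, z,
            frax.AdjustmentSpec("mof", cfg.factor_mof),
            frax.AdjustmentSpec("hip", cfg.factor_hip),
        )
        record("adjust", n_test=len(test))

        bundle["metrics"] = evaluate_cohort(
            test,
            cutoff_mof=cfg.cutoff_mof,
            cutoff_hip=cfg.cutoff_hip,
            B=cfg.bootstrap_B,
            seed=rng_seed + 5,
        )
        record("evaluate", n_metrics=len(bundle["metrics"]))
    except Exception as exc:  # annotate which stage died
        done = list(bundle["stages"])
        bundle["failure"] = {
            "after_stage": done[-1] if done else None,
            "error": f"{type(exc).__name__}: {exc}",
        }
        if outdir is not None:
            _write_artifacts(bundle, None, None, None, outdir, failed=True)
        raise RuntimeError(
            f"pipeline failed after stage {done[-1] if done else '<start>'}: {exc}"
        ) from exc

    if outdir is not None:
        _write_artifacts(bundle, model, G.variant_meta, test, outdir)
    return bundle


def _write_artifacts(bundle, model, variant_meta, test, outdir, failed=False):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if failed:
        (outdir / "FAILED").write_text(json.dumps(bundle.get("failure", {}), indent=2))
    report = json.loads(json.dumps(bundle, default=float))
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    if model is not None:
        prs.write_scoring_file(model, outdir / "gsos_scoring.txt", variant_meta)
    if test is not None:
        synthetic.write_cohort(test, outdir / "adjusted_cohort.tsv")


def evaluate_cohort(
    cohort: pd.DataFrame,
    z_col: str = "gsos",
    cutoff_mof: float = evaluate.MOF_CUTOFF,
    cutoff_hip: float = evaluate.HIP_CUTOFF,
    B: int = 200,
    seed: int = 0,
) -> dict:
    """The reporting battery on an adjusted cohort table.

    For each outcome: per-SD logistic odds ratio (age/sex-adjusted) with
    likelihood-ratio p, AUROC/AUPRC of baseline vs adjusted probabilities
    with bootstrap CIs and DeLong comparison, C-index from an age-scale
    Cox fit, and NRI/IDI at the clinical cutoff.
    """
    out: dict = {}
    z = cohort[z_col].to_numpy(dtype=float)
    age = cohort["age"].to_numpy(dtype=float)
    sex = cohort["sex"].to_numpy(dtype=float)
    for outcome, cutoff in (("mof", cutoff_mof), ("hip", cutoff_hip)):
        y = cohort[f"incident_{outcome}"].to_numpy(dtype=int)
        if y.sum() == 0 or y.sum() == len(y):
            out[outcome] = {"error": "degenerate outcome"}
            continue
        p_old = cohort[f"frax_{outcome}"].to_numpy(dtype=float)
        p_new = cohort[f"frax_gsos_{outcome}"].to_numpy(dtype=float)

        # per-SD association: odds of fracture per SD *decrease* in gSOS
        base = evaluate.logistic_fit(np.column_stack([age, sex]), y, ["age", "sex"])
        full = evaluate.logistic_fit(
            np.column_stack([-z, age, sex]), y, ["neg_gsos", "age", "sex"]
        )
        j = full.names.index("neg_gsos")
        lrt_p = evaluate.likelihood_ratio_test(base.loglik, full.loglik, df=1)
        res: dict = {
            "or_per_sd": evaluate.MetricResult(
                f"or_per_sd_decrease_{outcome}",
                float(full.odds_ratios[j]),
                float(full.or_ci_low[j]),
                float(full.or_ci_high[j]),
                "analytic",
                full.n,
            ).to_dict(),
            "lrt_pvalue": lrt_p,
        }
        if "sos" in cohort.columns:
            # generative self-consistency: the configured per-SD effect is on
            # the true SOS; the gSOS OR above is attenuated by imperfect
            # prediction of SOS
            s = cohort["sos"].to_numpy(dtype=float)
            s = (s - s.mean()) / s.std()
            sos_fit = evaluate.logistic_fit(
                np.column_stack([-s, age, sex]), y, ["neg_sos", "age", "sex"]
            )
            jj = sos_fit.names.index("neg_sos")
            res["or_per_sd_sos"] = evaluate.MetricResult(
                f"or_per_sd_decrease_sos_{outcome}",
                float(sos_fit.odds_ratios[jj]),
                float(sos_fit.or_ci_low[jj]),
                float(sos_fit.or_ci_high[jj]),
                "analytic",
                sos_fit.n,
            ).to_dict()

        for label, p in (("frax", p_old), ("frax_gsos", p_new)):
            auroc = evaluate.roc_auc(p, y)
            lo, hi = evaluate.bootstrap_ci(evaluate.roc_auc, p, y, B=B, seed=seed)
            auprc = evaluate.pr_auc(p, y)
            plo, phi = evaluate.bootstrap_ci(evaluate.pr_auc, p, y, B=B, seed=seed + 1)
            res[f"auroc_{label}"] = evaluate.MetricResult(
                f"auroc_{label}_{outcome}", auroc, lo, hi, f"bootstrap:{B}", len(y)
            ).to_dict()
            res[f"auprc_{label}"] = evaluate.MetricResult(
                f"auprc_{label}_{outcome}", auprc, plo, phi, f"bootstrap:{B}", len(y)
            ).to_dict()
        diff, var, p_delong = evaluate.delong_test(p_new, p_old, y)
        res["delong"] = {"auroc_diff": diff, "variance": var, "pvalue": p_delong}

        try:
            cox = evaluate.cox_fit(
                cohort["entry_age"].to_numpy(dtype=float),
                cohort["exit_age"].to_numpy(dtype=float),
                y,
                np.column_stack([np.log(p_new / (1 - p_new))]),
                names=[f"logit_frax_gsos_{outcome}"],
            )
            res["c_index"] = evaluate.MetricResult(
                f"c_index_frax_gsos_{outcome}", cox.c_index, np.nan, np.nan,
                "analytic", cox.n,
            ).to_dict()
        except (RuntimeError, ValueError) as exc:
            res["c_index"] = {"error": str(exc)}

        nri_res = evaluate.nri(p_old, p_new, y, cutoffs=cutoff)
        res["categorical_nri"] = nri_res["categorical_nri"].to_dict()
        res["continuous_nri"] = nri_res["continuous_nri"].to_dict()
        res["idi"] = evaluate.idi(p_old, p_new, y).to_dict()
        out[outcome] = res
    return out


# ---------------------------------------------------------------------------
# reporting


_SECTIONS = (
    ("association", ("or_per_sd", "or_per_sd_sos", "lrt_pvalue")),
    (
        "discrimination",
        ("auroc_frax", "auroc_frax_gsos", "auprc_frax", "auprc_frax_gsos", "delong", "c_index"),
    ),
    ("reclassification", ("categorical_nri", "continuous_nri", "idi")),
)


def make_report(bundle: dict) -> str:
    """Human-readable summary of a pipeline bundle, deterministic order."""
    metrics = bundle.get("metrics", {})
    lines: list[str] = []
    if not metrics:
        return "no metrics\n"
    for outcome in sorted(metrics):
        res = metrics[outcome]
        lines.append(f"== outcome: {outcome} ==")
        if "error" in res:
            lines.append(f"  (not evaluated: {res['error']})")
            continue
        for section, keys in _SECTIONS:
            lines.append(f"[{section}]")
            for key in keys:
                val = res.get(key)
                if val is None:
                    lines.append(f"  {key}: <missing: metric was not computed>")
                elif isinstance(val, dict) and "estimate" in val:
                    lines.append(
                        f"  {key}: {val['estimate']:.4f} "
                        f"(95% CI {val['ci_low']:.4f}-{val['ci_high']:.4f}; {val['method']})"
                    )
                elif isinstance(val, dict) and "pvalue" in val:
                    lines.append(
                        f"  {key}: diff {val.get('auroc_diff', float('nan')):.4f}, "
                        f"p = {val['pvalue']:.3g}"
                    )
                elif isinstance(val, dict) and "error" in val:
                    lines.append(f"  {key}: <missing: {val['error']}>")
                else:
                    lines.append(f"  {key}: {val:.3g}" if isinstance(val, float) else f"  {key}: {val}")
        lines.append("")
    return "\n".join(lines) + "\n"
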