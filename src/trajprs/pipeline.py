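"""End-to-end orchestration: generate, harmonize, fit, weight, associate.

``run_all`` executes the whole analysis on a synthetic cohort and writes every
intermediate artifact (CSV/JSON tables, trajectory and quartile-AOR figures)
plus a manifest with the seed, package versions and SHA-256 checksums of the
data artifacts, so a rerun with the same configuration is verifiably
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__, assoc, lgmm
from . import weights as weights_mod
from .datagen import PRS_COLUMNS, GeneratorConfig, generate
from .harmonize import harmonize_table


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5)
    families: tuple[str, ...] = ("lgmm", "lcga")
    multistart: tuple[int, int] = (100, 100)
    polish: bool = True
    min_class_share: float = 0.03
    max_entropy_drop: float = 0.05
    weight_method: str = "stack"
    weight_folds: int = 5
    truncation_quantiles: tuple[float, float] | None = (0.01, 0.99)
    covariates: tuple[str, ...] = assoc.DEFAULT_COVARIATES
    prs_list: tuple[str, ...] = PRS_COLUMNS
    quartile_prs: tuple[str, ...] = ("prs_ptsd", "prs_mdd")
    alpha: float = 0.05
    m_tests: int = 6
    make_plots: bool = True
    seed: int = 0

    def validate(self) -> None:
        self.generator.validate()
        if not self.k_range or min(self.k_range) < 1 or max(self.k_range) > 5:
            raise ValueError("k_range must lie within 1..5")
        for fam in self.families:
            if fam not in {"lgmm", "lcga"}:
                raise ValueError("families must be 'lgmm' and/or 'lcga'")


def _family_spec(family: str, K: int, cfg: RunConfig) -> lgmm.LGMMSpec:
    re = "intercept+slope" if family == "lgmm" else "none"
    return lgmm.LGMMSpec(
        n_classes=K, random_effects=re, multistart=cfg.multistart,
        polish=cfg.polish, seed=cfg.seed + 1000 + 10 * K + (family == "lcga"),
    )


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def config_to_yaml(cfg: RunConfig) -> str:
    d = dataclasses.asdict(cfg)
    d["generator"]["prs_class_logor"] = np.asarray(
        cfg.generator.prs_class_logor).tolist()
    d["generator"]["covariate_class_logor"] = np.asarray(
        cfg.generator.covariate_class_logor).tolist()
    return yaml.safe_dump(_to_jsonable(d), sort_keys=True)


def config_from_yaml(text: str) -> RunConfig:
    d = yaml.safe_load(text) or {}
    gen = d.pop("generator", {})
    for key in ("class_shares", "class_intercepts", "class_slopes", "new_pte_rates",
                "wave_item_counts"):
        if key in gen:
            gen[key] = tuple(gen[key])
    for key in ("prs_class_logor", "covariate_class_logor", "re_cov"):
        if key in gen:
            gen[key] = np.asarray(gen[key]) if key != "re_cov" else tuple(
                tuple(r) for r in gen[key])
    if "followup_times" in gen:
        gen["followup_times"] = tuple(tuple(t) for t in gen["followup_times"])
    for key in ("k_range", "families", "covariates", "prs_list", "quartile_prs"):
        if key in d:
            d[key] = tuple(d[key])
    for key in ("multistart", "truncation_quantiles"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return RunConfig(generator=GeneratorConfig(**gen), **d)


def _plot_trajectories(fit: lgmm.LGMMFit, labels: dict[int, str], path: Path) -> None:
    t = np.linspace(0.0, 12.0, 49)
    fig, ax = plt.subplots(figsize=(6, 4))
    for k in range(fit.n_classes):
        mean = fit.beta[k, 0] + fit.beta[k, 1] * t
        share = 100.0 * fit.class_shares[k]
        ax.plot(t, mean, label=f"{labels[k + 1]} ({share:.1f}%)")
    ax.set_xlabel("months since post-deployment assessment")
    ax.set_ylabel("harmonized symptom score (% of maximum)")
    ax.set_ylim(bottom=0)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_quartile_aors(qtab: pd.DataFrame, path: Path) -> None:
    prs_names = sorted(qtab["prs"].unique())
    pairs = sorted(set(zip(qtab["class_a"], qtab["class_b"])))
    fig, axes = plt.subplots(1, len(prs_names), figsize=(5 * len(prs_names), 4),
                             squeeze=False)
    for ax, prs in zip(axes[0], prs_names):
        sub = qtab[qtab["prs"] == prs]
        for a, b in pairs:
            s = sub[(sub["class_a"] == a) & (sub["class_b"] == b)]
            ax.errorbar(s["quartile"], s["aor"],
                        yerr=[s["aor"] - s["ci_low"], s["ci_high"] - s["aor"]],
                        marker="o", capsize=2, label=f"{a} vs {b}")
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_xticks([2, 3, 4])
        ax.set_xlabel("PRS quartile (vs Q1)")
        ax.set_ylabel("adjusted odds ratio")
        ax.set_title(prs)
        ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage and write artifacts under ``outdir``.

    Returns the run manifest (also written as ``manifest.json``).
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def save_csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format="%.10g")
        artifacts[name] = p

    def save_json(obj, name: str) -> None:
        p = out / name
        p.write_text(json.dumps(_to_jsonable(obj), indent=1, sort_keys=True))
        artifacts[name] = p

    # stage 1: synthetic cohort
    gen = config.generator.replace(seed=config.seed)
    try:
        cohort, long = generate(gen)
    except Exception as e:  # pragma: no cover - stage tagging
        raise RuntimeError(f"[datagen] {e}") from e
    save_csv(cohort, "cohort.csv")

    # stage 2: harmonization (recomputed from raw totals)
    try:
        long = harmonize_table(long.drop(columns=["harmonized"]),
                               config.generator.wave_item_counts)
    except Exception as e:
        raise RuntimeError(f"[harmonize] {e}") from e
    save_csv(long, "long.csv")
    (out / "config.yaml").write_text(config_to_yaml(config))
    artifacts["config.yaml"] = out / "config.yaml"

    # stage 3: mixture grid, comparison and selection
    try:
        fits: dict[tuple[str, int], lgmm.LGMMFit] = {}
        start_log = {}
        for family in config.families:
            for K in config.k_range:
                spec = _family_spec(family, K, config)
                fit = lgmm.fit_lgmm(long, cohort, spec)
                fits[(family, K)] = fit
                start_log[f"{family}_K{K}"] = fit.start_logliks
                save_json({
                    "family": family, "n_classes": K,
                    "beta": fit.beta, "psi": fit.psi, "sigma2": fit.sigma2,
                    "gamma": fit.gamma, "loglik": fit.loglik,
                    "n_params": fit.n_params, "converged": fit.converged,
                    "class_shares": fit.class_shares,
                }, f"fit_{family}_K{K}.json")
        comparison = lgmm.comparison_table(fits)
        save_csv(comparison, "comparison.csv")
        save_json(start_log, "start_logliks.json")
        family, K = lgmm.select_model(
            comparison, min_class_share=config.min_class_share,
            max_entropy_drop=config.max_entropy_drop)
        chosen = fits[(family, K)]
    except RuntimeError:
        raise
    except Exception as e:
        raise RuntimeError(f"[lgmm] {e}") from e

    posterior = lgmm.posterior_probs(chosen, long, cohort)
    save_csv(posterior, "posteriors.csv")
    classified, mean_max_post = lgmm.classify(chosen)
    save_csv(classified, "classified.csv")
    labels = lgmm.label_classes(chosen)

    # stage 4: response propensities and combined weights
    try:
        subject_w, expanded = weights_mod.build_weight_set(
            cohort, long, posterior, folds=config.weight_folds,
            seed=config.seed + 7, method=config.weight_method,
            truncation_quantiles=config.truncation_quantiles)
    except Exception as e:
        raise RuntimeError(f"[weights] {e}") from e
    save_csv(subject_w, "weights_subject.csv")
    save_csv(expanded, "weights_expanded.csv")

    # stage 5: association models
    try:
        omnibus = {}
        tables = []
        for prs in config.prs_list:
            res = assoc.fit_weighted_multinomial(
                expanded, cohort, prs, config.covariates)
            omnibus[prs] = assoc.omnibus_test(res)["p_value"]
            tables.append(assoc.aor_table(res, labels))
        table2 = pd.concat(tables, ignore_index=True)
        save_csv(table2, "table2_aors.csv")
        qtabs = [assoc.quartile_aor(expanded, cohort, prs, config.covariates)
                 for prs in config.quartile_prs]
        qtab = pd.concat(qtabs, ignore_index=True) if qtabs else pd.DataFrame()
        if len(qtab):
            save_csv(qtab, "fig2_quartile_aors.csv")
        pte_tests = assoc.compare_new_pte_rates(classified, cohort)
        save_csv(pte_tests, "new_pte_tests.csv")
    except Exception as e:
        raise RuntimeError(f"[assoc] {e}") from e

    figures = []
    if config.make_plots:
        _plot_trajectories(chosen, labels, out / "fig1_trajectories.png")
        figures.append("fig1_trajectories.png")
        if len(qtab):
            _plot_quartile_aors(qtab, out / "fig2_quartile_aors.png")
            figures.append("fig2_quartile_aors.png")

    threshold = assoc.bonferroni_threshold(config.alpha, config.m_tests)
    summary = {
        "selected_family": family,
        "selected_classes": K,
        "class_shares": chosen.class_shares,
        "class_labels": {str(k): v for k, v in labels.items()},
        "entropy": lgmm.entropy(chosen) if K > 1 else None,
        "mean_max_posterior": mean_max_post,
        "omnibus_p": omnibus,
        "bonferroni_threshold": threshold,
        "significant_prs": [p for p, v in omnibus.items() if v < threshold],
        "n_subjects": int(len(cohort)),
        "n_modeled": int(chosen.n_subjects),
    }
    save_json(summary, "summary.json")

    manifest = {
        "seed": config.seed,
        "versions": {"trajprs": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "checksums": {name: _sha256(p) for name, p in sorted(artifacts.items())},
        "figures": figures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
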