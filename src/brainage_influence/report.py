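"""Run outputs: CSV tables, progression-curve figures, and a JSON manifest.

Every output directory carries a ``manifest.json`` tying the files to the
master seed, the fully-defaulted configuration and its hash, so any figure
or table can be regenerated exactly.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .config import RunConfig
from .experiments import FeatureInfluenceResult, ModelVsLogisticResult
from .ranking import write_ranking_csv

__all__ = ["write_report"]

logger = logging.getLogger("brainage_influence")


def _package_version() -> str:
    try:
        return version("brainage-influence")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def _write_manifest(out_dir: Path, config: RunConfig, files: list[str], kind: str) -> Path:
    manifest = {
        "pipeline": kind,
        "master_seed": config.seeds.master,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": _package_version(),
        "outputs": sorted(files),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return path


def _plot_feature_influence(result: FeatureInfluenceResult, path: Path) -> None:
    fig, (ax_mae, ax_auc) = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    styles = {"age": ":", "discrimination": "-"}
    for crit, curve in result.curves.items():
        p = curve.points
        ax_mae.plot(p["k"], p["mae"], styles[crit], marker="o", label=f"{crit} ordering")
        ax_mae.fill_between(
            p["k"], p["mae"] - p["mae_ci95"], p["mae"] + p["mae_ci95"], alpha=0.2
        )
        ax_auc.plot(p["k"], p["auc"], styles[crit], marker="o", label=f"{crit} ordering")
        ax_auc.fill_between(
            p["k"], p["auc"] - p["auc_ci95"], p["auc"] + p["auc_ci95"], alpha=0.2
        )
    ax_mae.set_xlabel("number of features"), ax_mae.set_ylabel("MAE (years)")
    ax_auc.set_xlabel("number of features"), ax_auc.set_ylabel("AUC")
    ax_auc.axhline(0.5, color="grey", lw=0.5)
    ax_mae.legend(), ax_auc.legend()
    fig.suptitle(f"Feature influence — {result.pair}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_model_comparison(result: ModelVsLogisticResult, path: Path) -> None:
    orderings = sorted({c.ordering for c in result.curves})
    fig, axes = plt.subplots(1, len(orderings), figsize=(5 * len(orderings), 4), squeeze=False)
    for ax, ordering in zip(axes[0], orderings):
        for curve in result.curves:
            if curve.ordering != ordering:
                continue
            p = curve.points
            ax.errorbar(p["k"], p["auc_mean"], yerr=p["auc_sd"], marker="o",
                        capsize=2, label=curve.model_kind)
        ax.set_title(f"{ordering} ordering")
        ax.set_xlabel("number of features"), ax.set_ylabel("AUC")
        ax.axhline(0.5, color="grey", lw=0.5)
        ax.legend(fontsize=8)
    fig.suptitle(f"Age-model deltas vs direct logistic — {result.pair}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(
    result: Union[FeatureInfluenceResult, ModelVsLogisticResult],
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> list[Path]:
    """Write ranking + curve CSVs, figures and the manifest; returns paths."""
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pair_tag = str(result.pair)
    written: list[Path] = []

    written.append(
        write_ranking_csv(list(result.rankings.values()), out_dir / f"rankings_{pair_tag}.csv")
    )
    if isinstance(result, FeatureInfluenceResult):
        curve_path = out_dir / f"feature_influence_{pair_tag}.csv"
        result.table().to_csv(curve_path, index=False)
        written.append(curve_path)
        if config.output.plots:
            fig_path = out_dir / f"feature_influence_{pair_tag}.png"
            _plot_feature_influence(result, fig_path)
            written.append(fig_path)
    else:
        curve_path = out_dir / f"model_vs_logistic_{pair_tag}.csv"
        result.table().to_csv(curve_path, index=False)
        written.append(curve_path)
        if result.augmentation is not None:
            aug_path = out_dir / f"augmentation_{pair_tag}.csv"
            result.augmentation.to_csv(aug_path, index=False)
            written.append(aug_path)
        if config.output.plots:
            fig_path = out_dir / f"model_vs_logistic_{pair_tag}.png"
            _plot_model_comparison(result, fig_path)
            written.append(fig_path)

    kind = (
        "model_feature_influence"
        if isinstance(result, FeatureInfluenceResult)
        else "age_model_vs_logistic_regression"
    )
    written.append(_write_manifest(out_dir, config, [p.name for p in written], kind))
    logger.info("report written to %s (%d files)", out_dir, len(written))
    return written
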