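"""End-to-end monolayer shape analysis as a model/results pair.

:class:`MonolayerShapeModel` holds the study's label masks and an
:class:`AnalysisConfig`; :meth:`MonolayerShapeModel.fit` measures every
cell, applies quality control, computes per-image median-centred
orientation deviations, pools per condition, and runs the configured
rank tests.  The returned :class:`MonolayerShapeResults` carries the
per-cell table, per-condition elongation and alignment summaries, the
test results, and knows how to serialise itself and draw the standard
figures (elongation violin/box plot, radial rose plots).

The whole computation is deterministic given masks and config, and
invariant to the order of manifest rows (outputs are sorted by
condition, replicate, image and label).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .alignment import (
    AlignmentSummary,
    ElongationSummary,
    alignment_cv,
    axial_median,
    deviations_from_median,
)
from .io import LabelMask, Manifest
from .morphometry import measure_cells
from .qc import QCConfig, apply_qc
from .stats import StatResult, compare_groups, significance_stars

__all__ = ["AnalysisConfig", "MonolayerShapeModel", "MonolayerShapeResults"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for one analysis run.

    Defaults reproduce the study conventions: QC at 20% minimum area,
    aspect ratio 10, border removal on; per-image median with deviations
    pooled per condition; 36 radial bins of 10°; Mann-Whitney U for two
    conditions, Kruskal-Wallis with Bonferroni-adjusted Dunn post hoc for
    three or more; alpha 0.05.
    """

    qc: QCConfig = field(default_factory=QCConfig)
    pooling: str = "per-condition"  # or "per-image": CV averaged over images
    n_radial_bins: int = 36
    stat_metric: str = "elongation_factor"  # or "deviation_abs"
    adjustment: str = "bonferroni"
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pooling not in {"per-condition", "per-image"}:
            raise ValueError("pooling must be 'per-condition' or 'per-image'")
        if self.stat_metric not in {"elongation_factor", "deviation_abs"}:
            raise ValueError("unknown stat_metric")


class MonolayerShapeModel:
    """Shape/alignment analysis of a set of segmented monolayer images.

    Parameters
    ----------
    masks
        Label masks with condition/replicate metadata attached.
    config
        Analysis settings; defaults follow the study conventions.
    """

    def __init__(self, masks: list[LabelMask], config: AnalysisConfig | None = None):
        if not masks:
            raise ValueError("need at least one label mask")
        self.masks = list(masks)
        self.config = config or AnalysisConfig()

    @classmethod
    def from_manifest(
        cls, manifest: str | Path | Manifest, config: AnalysisConfig | None = None
    ) -> "MonolayerShapeModel":
        """Build the model from a manifest file (or parsed Manifest)."""
        if not isinstance(manifest, Manifest):
            manifest = fio.load_manifest(manifest)
        masks = [
            fio.read_label_mask(
                row.mask_path,
                condition=row.condition,
                replicate=row.replicate,
                flow_angle_deg=row.flow_angle_deg,
            )
            for row in manifest
        ]
        return cls(masks, config=config)

    def fit(self) -> "MonolayerShapeResults":
        """Run the full pipeline and return the results object."""
        cfg = self.config
        records: list[dict] = []
        image_summaries: list[dict] = []
        # deterministic processing order regardless of input order
        masks = sorted(
            self.masks, key=lambda m: (m.condition, m.replicate, m.image_id)
        )
        for mask in masks:
            cells = measure_cells(mask)
            qc_res = apply_qc(cells, cfg.qc)
            status = {id(c): (True, "") for c in qc_res.kept}
            status.update({id(c): (False, reason) for c, reason in qc_res.removed})
            for cell in sorted(cells, key=lambda c: c.label):
                kept, reason = status[id(cell)]
                records.append(
                    {
                        "image_id": mask.image_id,
                        "condition": mask.condition,
                        "replicate": mask.replicate,
                        "label": cell.label,
                        "area_px": cell.area_px,
                        "centroid_row": cell.centroid[0],
                        "centroid_col": cell.centroid[1],
                        "orientation_deg": cell.orientation_deg,
                        "major_len": cell.major_len,
                        "minor_len": cell.minor_len,
                        "elongation_factor": cell.elongation_factor,
                        "touches_border": cell.touches_border,
                        "qc_kept": kept,
                        "qc_reason": reason,
                    }
                )
            if not qc_res.kept:
                logger.warning(
                    "image %s: no cells kept after QC; excluded from summaries",
                    mask.image_id,
                )
                continue
            orientations = [c.orientation_deg for c in qc_res.kept]
            med = axial_median(orientations)
            deviations = deviations_from_median(orientations)
            image_summaries.append(
                {
                    "image_id": mask.image_id,
                    "condition": mask.condition,
                    "replicate": mask.replicate,
                    "n_kept": len(qc_res.kept),
                    "n_removed": len(qc_res.removed),
                    "median_orientation_deg": med,
                    "deviations": deviations,
                    "elongation": np.array(
                        [c.elongation_factor for c in qc_res.kept]
                    ),
                }
            )

        cells_df = pd.DataFrame(records, columns=fio.CELLS_TABLE_COLUMNS)

        conditions: list[str] = sorted({s["condition"] for s in image_summaries})
        elongation: dict[str, ElongationSummary] = {}
        alignment: dict[str, AlignmentSummary] = {}
        per_image_cv: dict[str, list[float]] = {}
        for cond in conditions:
            img_sums = [s for s in image_summaries if s["condition"] == cond]
            pooled_dev = np.concatenate([s["deviations"] for s in img_sums])
            pooled_ef = np.concatenate([s["elongation"] for s in img_sums])
            elongation[cond] = ElongationSummary(scope=cond, values=pooled_ef)
            summary = AlignmentSummary.from_deviations(
                pooled_dev, scope=cond, n_bins=cfg.n_radial_bins
            )
            if cfg.pooling == "per-image":
                cvs = [
                    alignment_cv(s["deviations"])
                    for s in img_sums
                    if len(s["deviations"]) >= 2
                ]
                summary.cv = float(np.mean(cvs))
                per_image_cv[cond] = cvs
            alignment[cond] = summary

        stat_results: list[StatResult] = []
        if len(conditions) >= 2:
            if cfg.stat_metric == "elongation_factor":
                samples = [elongation[c].values for c in conditions]
            else:
                samples = [np.abs(alignment[c].deviations_deg) for c in conditions]
            stat_results.append(
                compare_groups(samples, names=conditions, adjustment=cfg.adjustment)
            )
        else:
            logger.warning("fewer than two conditions; group statistics skipped")

        return MonolayerShapeResults(
            model=self,
            cells=cells_df,
            image_summaries=image_summaries,
            elongation=elongation,
            alignment=alignment,
            stats=stat_results,
            per_image_cv=per_image_cv,
        )


@dataclass
class MonolayerShapeResults:
    """Fitted results: tables, summaries, statistics, figures, files."""

    model: MonolayerShapeModel
    cells: pd.DataFrame
    image_summaries: list[dict]
    elongation: dict[str, ElongationSummary]
    alignment: dict[str, AlignmentSummary]
    stats: list[StatResult]
    per_image_cv: dict[str, list[float]] = field(default_factory=dict)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.elongation)

    # ------------------------------------------------------------------ text
    def summary(self) -> str:
        """Human-readable run summary."""
        lines = ["Monolayer shape analysis", "=" * 24, ""]
        lines.append(
            f"{'condition':<16}{'n cells':>8}{'EF median':>11}{'EF mean':>9}"
            f"{'EF sd':>8}{'align CV':>10}"
        )
        for cond in self.conditions:
            ef = self.elongation[cond]
            al = self.alignment[cond]
            lines.append(
                f"{cond:<16}{ef.n_cells:>8}{ef.median:>11.3f}{ef.mean:>9.3f}"
                f"{ef.sd:>8.3f}{al.cv:>10.3f}"
            )
        for res in self.stats:
            lines.append("")
            lines.append(
                f"{res.method}: statistic = {res.statistic:.4f}, "
                f"p = {res.p_value:.3g} {significance_stars(res.p_value)}"
            )
            for row in res.posthoc:
                lines.append(
                    f"  {row.group_a} vs {row.group_b}: z = {row.z:.3f}, "
                    f"adj p = {row.p_adjusted:.3g} "
                    f"{significance_stars(row.p_adjusted)}"
                )
        return "\n".join(lines)

    # ----------------------------------------------------------------- files
    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write all result artefacts into ``outdir``.

        Produces ``cells.csv``, ``condition_summary.csv``, ``stats.csv``,
        ``radial_bins.json`` and ``run_log.json``; returns the paths.
        Output is byte-deterministic for identical inputs and config.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["cells"] = outdir / "cells.csv"
        fio.write_cells_table(
            self.cells.to_dict(orient="records"), paths["cells"]
        )

        cond_rows = []
        for cond in self.conditions:
            ef, al = self.elongation[cond], self.alignment[cond]
            cond_rows.append(
                {
                    "condition": cond,
                    "n_cells": ef.n_cells,
                    "ef_mean": ef.mean,
                    "ef_sd": ef.sd,
                    "ef_median": ef.median,
                    "median_orientation_deg": al.median_orientation_deg,
                    "alignment_cv": al.cv,
                }
            )
        paths["condition_summary"] = outdir / "condition_summary.csv"
        pd.DataFrame(cond_rows).to_csv(
            paths["condition_summary"], index=False, float_format="%.12g",
            lineterminator="\n",
        )

        stat_rows = []
        for res in self.stats:
            stat_rows.append(
                {
                    "method": res.method,
                    "groups": "|".join(res.groups),
                    "comparison": "omnibus",
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "stars": significance_stars(res.p_value),
                }
            )
            for row in res.posthoc:
                stat_rows.append(
                    {
                        "method": "dunn-posthoc",
                        "groups": "|".join(res.groups),
                        "comparison": f"{row.group_a} vs {row.group_b}",
                        "statistic": row.z,
                        "p_value": row.p_adjusted,
                        "stars": significance_stars(row.p_adjusted),
                    }
                )
        paths["stats"] = outdir / "stats.csv"
        pd.DataFrame(
            stat_rows,
            columns=["method", "groups", "comparison", "statistic", "p_value", "stars"],
        ).to_csv(paths["stats"], index=False, float_format="%.12g", lineterminator="\n")

        radial = {
            cond: {
                "bin_start_deg": [b for b, _ in self.alignment[cond].radial_bins],
                "count": [c for _, c in self.alignment[cond].radial_bins],
            }
            for cond in self.conditions
        }
        paths["radial_bins"] = outdir / "radial_bins.json"
        with open(paths["radial_bins"], "w", encoding="utf-8") as fh:
            json.dump(radial, fh, indent=1, sort_keys=True)

        log = {
            "config": {
                "qc": asdict(self.model.config.qc),
                "pooling": self.model.config.pooling,
                "n_radial_bins": self.model.config.n_radial_bins,
                "stat_metric": self.model.config.stat_metric,
                "adjustment": self.model.config.adjustment,
                "alpha": self.model.config.alpha,
                "rng_seed": self.model.config.rng_seed,
            },
            "images": [
                {
                    "image_id": s["image_id"],
                    "condition": s["condition"],
                    "replicate": s["replicate"],
                    "n_kept": int(s["n_kept"]),
                    "n_removed": int(s["n_removed"]),
                    "median_orientation_deg": float(s["median_orientation_deg"]),
                }
                for s in self.image_summaries
            ],
        }
        paths["run_log"] = outdir / "run_log.json"
        with open(paths["run_log"], "w", encoding="utf-8") as fh:
            json.dump(log, fh, indent=1, sort_keys=True)
        return paths

    # --------------------------------------------------------------- figures
    def plot_elongation(self, ax=None):
        """Violin/box plot of elongation factors per condition with n and
        significance stars from the configured tests."""
        import matplotlib.pyplot as plt

        if not self.elongation:
            raise ValueError("no conditions to plot")
        if ax is None:
            _, ax = plt.subplots(figsize=(1.6 * len(self.conditions) + 1.5, 4))
        data = [self.elongation[c].values for c in self.conditions]
        positions = np.arange(1, len(data) + 1)
        ax.violinplot(data, positions=positions, showextrema=False)
        ax.boxplot(data, positions=positions, widths=0.15, showfliers=False)
        labels = [
            f"{c}\n(n={self.elongation[c].n_cells})" for c in self.conditions
        ]
        ax.set_xticks(positions)
        ax.set_xticklabels(labels)
        ax.set_ylabel("elongation factor (major/minor axis)")
        if self.stats:
            res = self.stats[0]
            ax.set_title(
                f"{res.method}: p = {res.p_value:.2g} "
                f"{significance_stars(res.p_value)}"
            )
        return ax

    def plot_rose(self, condition: str, ax=None):
        """Radial rose plot of orientation deviations for one condition;
        each cell contributes a diameter (two opposite spokes)."""
        import matplotlib.pyplot as plt

        al = self.alignment[condition]
        if ax is None:
            _, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
        starts = np.radians([b for b, _ in al.radial_bins])
        counts = np.array([c for _, c in al.radial_bins], dtype=float)
        width = 2 * np.pi / len(starts)
        ax.bar(starts + width / 2, counts, width=width, alpha=0.75)
        ax.set_title(f"{condition} (n={al.n_cells}, CV={al.cv:.2f})")
        return ax

    def make_report(self, outdir: str | Path) -> dict[str, Path]:
        """Write the standard figures (PNG) into ``outdir``."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if not self.elongation:
            raise ValueError("empty result bundle")
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        ax = self.plot_elongation()
        paths["elongation"] = outdir / "elongation_factor.png"
        ax.figure.savefig(paths["elongation"], dpi=150, bbox_inches="tight")
        plt.close(ax.figure)

        for cond in self.conditions:
            ax = self.plot_rose(cond)
            p = outdir / f"rose_{cond}.png"
            ax.figure.savefig(p, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
            paths[f"rose_{cond}"] = p
        return paths
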