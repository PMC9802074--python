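"""End-to-end analysis: morphometry + contacts + complexes + statistics.

``run_pipeline`` takes labeled volumes from both light conditions and
produces the per-instance morphometry table, per-site and per-pair contact
tables, complex-category fractions, the statistical comparison battery and
(optionally) summary figures. All CSV outputs are written with fixed float
formatting so identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import complexes as cpx
from . import stats as st
from .contact import ContactTable, cell_contactome
from .io import CHLOROPLAST, CONTACT_CLASSES, MITOCHONDRION, LabelVolume
from .morphometry import extract_instances, instances_frame, volume_um3

FLOAT_FMT = "%.10g"

PAIRS = [
    f"{a}-{b}"
    for i, a in enumerate(CONTACT_CLASSES)
    for b in CONTACT_CLASSES[i + 1:]
]


@dataclass
class PipelineConfig:
    """Knobs of the analysis run (all logged into the report)."""

    out_dir: str | Path | None = None
    shell_connectivity: int = 6
    correlation_method: str = "pearson"
    make_plots: bool = False
    measure_length: bool = True
    #: classes receiving full morphometry (surface mesh, skeleton);
    #: remaining labels contribute volumes only (cell-volume accounting)
    morphometry_classes: tuple[str, ...] = CONTACT_CLASSES


@dataclass
class ConditionSummary:
    """All tables and test results of one dark/light comparison."""

    instances: pd.DataFrame
    sites: pd.DataFrame
    pair_cells: pd.DataFrame          # per cell x pair: n_sites, total area
    fractions: pd.DataFrame           # complex categories
    assignments: pd.DataFrame
    cell_stats: pd.DataFrame          # per cell: volumes, counts
    tests: pd.DataFrame               # statistical battery
    correlations: pd.DataFrame
    percent_change: pd.DataFrame
    config: PipelineConfig = field(repr=False, default=None)

    def frames(self) -> dict[str, pd.DataFrame]:
        return {
            "instances": self.instances,
            "sites": self.sites,
            "pair_cells": self.pair_cells,
            "fractions": self.fractions,
            "assignments": self.assignments,
            "cell_stats": self.cell_stats,
            "tests": self.tests,
            "correlations": self.correlations,
            "percent_change": self.percent_change,
        }

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.frames().items():
            df.to_csv(out / f"{name}.csv", index=False, float_format=FLOAT_FMT)


def _cell_tables(vol: LabelVolume, config: PipelineConfig):
    insts = extract_instances(vol, classes=config.morphometry_classes,
                              measure_length=config.measure_length)
    inst_df = instances_frame(insts, cell_id=vol.cell_id,
                              condition=vol.condition)
    table: ContactTable = cell_contactome(
        vol, connectivity=config.shell_connectivity
    )
    counts = np.bincount(vol.labels.ravel())
    cell_volume = volume_um3(int(counts[1:].sum()), vol.spacing_nm)
    per_class_vol = {
        cls: volume_um3(
            int(sum(counts[lbl] for lbl in vol.labels_of_class(cls)
                    if lbl < len(counts))),
            vol.spacing_nm,
        )
        for cls in set(vol.class_map.values())
    }
    cell_row = {"cell_id": vol.cell_id, "condition": vol.condition,
                "cell_volume_um3": cell_volume}
    for cls in CONTACT_CLASSES:
        cell_row[f"n_{cls}"] = len(vol.labels_of_class(cls))
        cell_row[f"volume_{cls}_um3"] = per_class_vol.get(cls, 0.0)
    return inst_df, table, cell_row


def _condition_of(df: pd.DataFrame, cond: str) -> pd.DataFrame:
    return df[df["condition"] == cond]


def run_pipeline(
    volumes: list[LabelVolume], config: PipelineConfig | None = None
) -> ConditionSummary:
    """Analyze a panel of labeled cell volumes (both conditions).

    Every volume must carry a ``condition``; at least one cell per
    condition is required for between-condition tests (per-cell t tests
    are skipped with a warning when a condition has fewer than 2 cells).
    """
    config = config or PipelineConfig()
    if not volumes:
        raise ValueError("no volumes given")
    inst_frames, site_frames, pair_frames, cell_rows = [], [], [], []
    assignments: list[cpx.ComplexAssignment] = []
    for vol in volumes:
        inst_df, table, cell_row = _cell_tables(vol, config)
        inst_frames.append(inst_df)
        site_frames.append(table.sites_frame())
        pair_frames.append(table.pair_frame())
        cell_rows.append(cell_row)
        assignments.extend(cpx.classify(table))

    instances = pd.concat(inst_frames, ignore_index=True)
    sites = pd.concat(site_frames, ignore_index=True)
    pair_cells = pd.concat(pair_frames, ignore_index=True)
    cell_stats = pd.DataFrame(cell_rows)
    fractions = cpx.population_fractions(assignments)
    assign_df = cpx.assignments_frame(assignments)

    conditions = [c for c in ("dark", "light")
                  if (instances["condition"] == c).any()]
    tests_rows, corr_rows, change_rows = [], [], []
    if len(conditions) == 2:
        d, li = "dark", "light"

        # --- pooled per-instance distributions: Mann-Whitney ------------
        for cls in CONTACT_CLASSES:
            sub = instances[instances["organelle_class"] == cls]
            metrics = ["volume_um3", "sphericity", "mci"]
            if cls == MITOCHONDRION and config.measure_length:
                metrics.append("length_um")
            for metric in metrics:
                xs = _condition_of(sub, d)[metric].dropna().to_numpy()
                ys = _condition_of(sub, li)[metric].dropna().to_numpy()
                if len(xs) == 0 or len(ys) == 0:
                    continue
                res = st.mann_whitney(xs, ys)
                tests_rows.append(
                    {"test": "mann_whitney", "quantity": f"{cls}:{metric}",
                     "statistic": res.U, "df": np.nan, "p": res.p,
                     "n_dark": len(xs), "n_light": len(ys)}
                )
                change_rows.append(
                    {"quantity": f"{cls}:{metric}",
                     "median_dark": float(np.median(xs)),
                     "median_light": float(np.median(ys)),
                     "percent_change": st.median_percent_change(xs, ys)}
                )

        # --- per-site proximity areas: Mann-Whitney ----------------------
        for pair in PAIRS:
            sub = sites[sites["pair"] == pair]
            xs = _condition_of(sub, d)["area_um2"].to_numpy()
            ys = _condition_of(sub, li)["area_um2"].to_numpy()
            if len(xs) == 0 or len(ys) == 0:
                continue
            res = st.mann_whitney(xs, ys)
            tests_rows.append(
                {"test": "mann_whitney", "quantity": f"site_area:{pair}",
                 "statistic": res.U, "df": np.nan, "p": res.p,
                 "n_dark": len(xs), "n_light": len(ys)}
            )
            change_rows.append(
                {"quantity": f"site_area:{pair}",
                 "median_dark": float(np.median(xs)),
                 "median_light": float(np.median(ys)),
                 "percent_change": st.median_percent_change(xs, ys)}
            )

        # --- per-cell totals: Welch's t ----------------------------------
        enough_cells = all(
            (cell_stats["condition"] == c).sum() >= 2 for c in (d, li)
        )
        if not enough_cells:
            warnings.warn("a condition has < 2 cells; per-cell Welch t "
                          "tests skipped")
        else:
            for pair in PAIRS:
                sub = pair_cells[pair_cells["pair"] == pair]
                for metric in ("n_sites", "total_area_um2"):
                    xs = _condition_of(sub, d)[metric].to_numpy(dtype=float)
                    ys = _condition_of(sub, li)[metric].to_numpy(dtype=float)
                    try:
                        t, df_, p = st.welch_t(xs, ys)
                    except ValueError:
                        continue
                    tests_rows.append(
                        {"test": "welch_t", "quantity": f"{metric}:{pair}",
                         "statistic": t, "df": df_, "p": p,
                         "n_dark": len(xs), "n_light": len(ys)}
                    )

        # --- alone vs engaged: Fisher's exact ----------------------------
        for cls in CONTACT_CLASSES:
            counts2 = cpx.alone_vs_engaged_counts(fractions, cls)
            if d in counts2 and li in counts2:
                tab = [list(counts2[d]), list(counts2[li])]
                odds, p = st.fisher_exact_2x2(tab)
                tests_rows.append(
                    {"test": "fisher_exact",
                     "quantity": f"alone_vs_engaged:{cls}",
                     "statistic": odds, "df": np.nan, "p": p,
                     "n_dark": sum(counts2[d]), "n_light": sum(counts2[li])}
                )

        # --- correlations -------------------------------------------------
        # median chloroplast volume vs cell volume, across all cells
        chl = instances[instances["organelle_class"] == CHLOROPLAST]
        med_by_cell = chl.groupby("cell_id")["volume_um3"].median()
        cellv = cell_stats.set_index("cell_id")["cell_volume_um3"]
        common = med_by_cell.index.intersection(cellv.index)
        if len(common) >= 3:
            r, p = st.correlation(cellv[common], med_by_cell[common],
                                  config.correlation_method)
            corr_rows.append(
                {"quantity": "median_chloroplast_volume_vs_cell_volume",
                 "condition": "both", "r": r, "p": p, "n": len(common)}
            )
        # peroxisome volume vs its chloroplast proximity area, per condition
        per_area = _per_organelle_pair_area(sites, "peroxisome",
                                            "chloroplast-peroxisome")
        per_inst = instances[instances["organelle_class"] == "peroxisome"]
        for cond in (d, li):
            sub = _condition_of(per_inst, cond)
            if len(sub) < 3:
                continue
            key = list(zip(sub["cell_id"], sub["label"]))
            areas = np.array([per_area.get(k, 0.0) for k in key])
            r, p = st.correlation(sub["volume_um3"].to_numpy(), areas,
                                  config.correlation_method)
            corr_rows.append(
                {"quantity": "peroxisome_volume_vs_chl_proximity_area",
                 "condition": cond, "r": r, "p": p, "n": len(sub)}
            )

    tests = pd.DataFrame(
        tests_rows, columns=["test", "quantity", "statistic", "df", "p",
                             "n_dark", "n_light"]
    )
    correlations = pd.DataFrame(
        corr_rows, columns=["quantity", "condition", "r", "p", "n"]
    )
    percent_change = pd.DataFrame(
        change_rows, columns=["quantity", "median_dark", "median_light",
                              "percent_change"]
    )

    summary = ConditionSummary(
        instances=instances, sites=sites, pair_cells=pair_cells,
        fractions=fractions, assignments=assign_df, cell_stats=cell_stats,
        tests=tests, correlations=correlations,
        percent_change=percent_change, config=config,
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        summary.save(out)
        (out / "run_config.json").write_text(
            json.dumps(
                {
                    "shell_connectivity": config.shell_connectivity,
                    "correlation_method": config.correlation_method,
                    "measure_length": config.measure_length,
                    "morphometry_classes": list(config.morphometry_classes),
                    "n_cells": len(volumes),
                    "cell_ids": [v.cell_id for v in volumes],
                },
                indent=2,
            )
            + "\n"
        )
        if config.make_plots:
            from .plots import report_figures

            report_figures(summary, out / "plots")
    return summary


def _per_organelle_pair_area(sites: pd.DataFrame, organelle_class: str,
                             pair: str) -> dict:
    """Total pair area per (cell_id, organelle label) of one class."""
    sub = sites[sites["pair"] == pair]
    col = ("secondary_id"
           if pair.split("-")[1] == organelle_class else "primary_id")
    grouped = sub.groupby(["cell_id", col])["area_um2"].sum()
    return {(c, int(lbl)): float(a) for (c, lbl), a in grouped.items()}
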