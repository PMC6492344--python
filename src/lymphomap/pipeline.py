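"""End-to-end pipeline orchestration, run report and figure export.

``run_pipeline`` executes the stages in their canonical order —
preprocess → SOM training → portraits → spot modules → PATs →
enrichment → hallmarks → survival → similarity — writing every stage
output as plain text under the output directory and returning a JSON
report with a parameter echo, per-stage counts and SHA-256 checksums of
every output file.  A rerun with the same config reproduces identical
checksums.  A stage failure halts the run with the stage name and
cause.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import hallmarks as hm
from . import pats as pats_mod
from . import preprocessing, similarity, som, spots, survival
from .matrix import read_expression, write_expression

log = logging.getLogger("lymphomap")

__all__ = ["PipelineConfig", "run_pipeline", "export_figures"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; YAML-serializable."""

    expression: str = ""
    annotation: str = ""
    gene_sets: str = ""  # GMT for spot-module enrichment (optional)
    hallmark_sets: str = ""  # GMT with exactly 8 hallmark sets (optional)
    out_dir: str = "lymphomap_run"
    rows: int = 50
    cols: int = 50
    seed: int = 42
    epochs: int = 20
    skip_quantile: bool = False
    spot_threshold: float = 0.9
    sample_call_threshold: float = 0.5
    min_spot_size: int = 2
    min_cases: int = 5
    r_rescue: float = 0.8
    network_threshold: float = 0.5
    ht_k: int = 5
    adjust_therapy: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.spot_threshold < 1.0:
            raise ValueError("spot_threshold must be in (0, 1)")
        if not 0.0 < self.r_rescue <= 1.0:
            raise ValueError("r_rescue must be in (0, 1]")
        if not -1.0 < self.network_threshold < 1.0:
            raise ValueError("network_threshold must be in (-1, 1)")
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    """Context manager that prefixes failures with the stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise RuntimeError(f"stage {self.name!r} failed: {exc}") from exc
        log.info("stage %s: done", self.name)


def _write_portrait_matrix(path: str, portraits: dict) -> None:
    ids = list(portraits)
    mat = pd.DataFrame(
        np.vstack([portraits[i].values for i in ids]),
        index=ids,
        columns=[f"u{u:04d}" for u in range(next(iter(portraits.values())).values.size)],
    )
    mat.to_csv(path, sep="\t", index_label="id", float_format="%.8g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the run report."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    written: list[str] = []

    def save_frame(frame: pd.DataFrame, rel: str, **kwargs) -> None:
        path = os.path.join(out, rel)
        os.makedirs(os.path.dirname(path), exist_ok=True)
        frame.to_csv(path, sep="\t", float_format="%.8g", **kwargs)
        written.append(rel)

    report: dict = {"parameters": config.to_dict(), "counts": {}, "seed": config.seed}

    with _Stage("load"):
        matrix = read_expression(config.expression)
        ann = survival.read_annotation(config.annotation) if config.annotation else None
        report["counts"]["n_genes"] = matrix.n_genes
        report["counts"]["n_samples"] = matrix.n_samples

    with _Stage("preprocess"):
        matrix = preprocessing.preprocess(matrix, skip_quantile=config.skip_quantile)
        write_expression(matrix, os.path.join(out, "preprocessed.tsv"))
        written.append("preprocessed.tsv")

    with _Stage("train"):
        model = som.train_som(
            matrix, rows=config.rows, cols=config.cols,
            seed=config.seed, epochs=config.epochs,
        )
        som.save_model(model, os.path.join(out, "model"))
        written.extend(
            os.path.join("model", f) for f in ("codebook.tsv", "assignment.tsv", "model.json")
        )

    with _Stage("portraits"):
        portraits = som.sample_portraits(model, matrix)
        _write_portrait_matrix(os.path.join(out, "portraits.tsv"), portraits)
        written.append("portraits.tsv")
        classes = None
        group_portraits = {}
        if ann is not None:
            classes = ann.set_index("sample_id")["class"]
            for cls_label, members in classes.groupby(classes).groups.items():
                members = [s for s in members if s in portraits]
                if members:
                    group_portraits[str(cls_label)] = som.mean_portrait(
                        [portraits[s] for s in members], str(cls_label)
                    )
            _write_portrait_matrix(
                os.path.join(out, "group_portraits.tsv"), group_portraits
            )
            written.append("group_portraits.tsv")

    with _Stage("spots"):
        basis = list(group_portraits.values()) or list(portraits.values())
        modules = spots.build_summary_map(
            basis, model, matrix,
            threshold_frac=config.spot_threshold, min_size=config.min_spot_size,
        )
        mod_rows = [
            {
                "label": mod.label,
                "n_units": len(mod.units),
                "n_genes": len(mod.genes),
                "peak_value": mod.peak_value,
                "units": ";".join(f"{r},{c}" for r, c in sorted(mod.units)),
                "genes": ";".join(mod.genes),
            }
            for mod in modules
        ]
        save_frame(pd.DataFrame(mod_rows), "spots/modules.tsv", index=False)
        enr.write_gmt(
            {f"spot_{mod.label}": mod.genes for mod in modules if mod.genes},
            os.path.join(out, "spots", "modules.gmt"),
        )
        written.append(os.path.join("spots", "modules.gmt"))
        # per-sample calls: detection threshold, min_size=1 (see spots module)
        inc = spots.spot_incidence(
            modules, portraits, threshold_frac=config.sample_call_threshold,
        )
        save_frame(inc, "spots/incidence.tsv", index_label="sample_id")
        if classes is not None:
            assoc, count_dist = spots.spot_statistics(inc, classes)
            save_frame(assoc, "spots/class_association.tsv", index_label="class")
            save_frame(count_dist, "spots/spot_counts.tsv", index_label="class")
        save_frame(spots.cooccurrence(inc), "spots/cooccurrence.tsv", index=False)
        report["counts"]["n_spot_modules"] = len(modules)

    with _Stage("pats"):
        module_expr = pd.DataFrame({mod.label: mod.profile for mod in modules}).T
        pat_classes = (
            classes if classes is not None
            else pd.Series("all", index=inc.index)
        )
        assignments = pats_mod.assign_pats(
            inc, pat_classes, module_expr,
            min_cases=config.min_cases, r_rescue=config.r_rescue,
        )
        group_map = pats_mod.group_pats(assignments)
        pat_portraits = pats_mod.pat_mean_portraits(assignments, portraits)
        group_means = {}
        for grp in sorted(set(group_map.values())):
            members = assignments.index[assignments["pat_group"] == grp].tolist()
            if members:
                group_means[grp] = som.mean_portrait(
                    [portraits[s] for s in members], grp
                )
        if group_means:
            assignments = pats_mod.distribute_nopat(
                assignments, portraits, group_means
            )
        save_frame(assignments, "pats/assignments.tsv")
        summary = {
            "pat_groups": group_map,
            "route_counts": assignments["assignment_route"].value_counts().to_dict(),
            "pat_sizes": assignments["pat_label"].value_counts().to_dict(),
        }
        with open(os.path.join(out, "pats", "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1, ensure_ascii=False, sort_keys=True)
        written.append(os.path.join("pats", "summary.json"))
        report["counts"]["n_pats"] = len(
            [l for l in assignments["pat_label"].unique() if l != pats_mod.NO_PAT]
        )
        report["counts"]["n_pat_groups"] = len(set(group_map.values()))
        report["counts"]["routes"] = summary["route_counts"]

    if config.gene_sets:
        with _Stage("enrichment"):
            sets = enr.read_gmt(config.gene_sets)
            universe = set(model.gene_assignment.index)
            table = enr.enrich_modules(modules, sets, universe)
            save_frame(table, "enrichment/enrichment.tsv", index=False)
            save_frame(
                enr.gsz_matrix(sets, matrix), "enrichment/gsz.tsv",
                index_label="gene_set",
            )

    ht_labels = None
    if config.hallmark_sets:
        with _Stage("hallmarks"):
            hsets = enr.read_gmt(config.hallmark_sets)
            scores = hm.hallmark_scores(hsets, matrix)
            save_frame(scores, "hallmarks/scores.tsv")
            k = min(config.ht_k, len(scores))
            ht_labels = hm.cluster_hallmark_types(scores, k=k)
            save_frame(ht_labels.to_frame(), "hallmarks/ht.tsv", index_label="entity")
            report["counts"]["n_hallmark_types"] = int(ht_labels.nunique())

    if ann is not None and "time" in ann.columns:
        with _Stage("survival"):
            hr_map = survival.prognostic_map(
                portraits, ann, adjust=config.adjust_therapy
            )
            save_frame(hr_map.to_frame(), "survival/hr_map.tsv", index=False)
            ann_idx = ann.set_index("sample_id")
            for cls_label, members in ann_idx.groupby("class").groups.items():
                sub = ann_idx.loc[members]
                km = survival.km_estimate(sub["time"], sub["status"])
                save_frame(km, f"survival/km_{cls_label}.tsv", index=False)
            strata = ann_idx["class"]
            if strata.nunique() >= 2:
                pw = survival.pairwise_cox(
                    ann, strata, adjust=config.adjust_therapy
                )
                save_frame(pw, "survival/pairwise.tsv", index=False)
            report["counts"]["n_hr_units_defined"] = int(hr_map.defined.sum())

    with _Stage("similarity"):
        net = similarity.correlation_network(
            list(portraits.values()),
            threshold=config.network_threshold,
            classes=classes.to_dict() if classes is not None else None,
        )
        edges = pd.DataFrame(
            [
                {"source": u, "target": v, "weight": d["weight"]}
                for u, v, d in sorted(net.edges(data=True))
            ]
        )
        save_frame(edges, "similarity/network_edges.tsv", index=False)
        import networkx as nx

        nx.write_graphml(net, os.path.join(out, "similarity", "network.graphml"))
        written.append(os.path.join("similarity", "network.graphml"))
        for level, port_dict in (
            ("classes", group_portraits),
            ("pats", pat_portraits),
        ):
            if len(port_dict) >= 3:
                tree = similarity.phenotype_tree(list(port_dict.values()))
                path = os.path.join(out, "similarity", f"tree_{level}.nwk")
                with open(path, "w") as fh:
                    fh.write(similarity.tree_to_newick(tree) + "\n")
                written.append(os.path.join("similarity", f"tree_{level}.nwk"))
        report["counts"]["n_network_edges"] = net.number_of_edges()

    with _Stage("report"):
        report["checksums"] = {
            rel: _sha256(os.path.join(out, rel)) for rel in sorted(set(written))
        }
        with open(os.path.join(out, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1, ensure_ascii=False, sort_keys=True)
    return report


def export_figures(run_dir: str | os.PathLike) -> dict:
    """Render PNG figures for a completed run; returns the manifest.

    Writes the individual-portrait gallery, group mean portraits, the
    summary spot map and the HR map under ``<run_dir>/figures`` and a
    ``manifest.json`` listing every file.  Re-export is idempotent.
    """
    run_dir = str(run_dir)
    fig_dir = os.path.join(run_dir, "figures")
    os.makedirs(fig_dir, exist_ok=True)
    manifest: list[str] = []

    with open(os.path.join(run_dir, "model", "model.json")) as fh:
        meta = json.load(fh)
    rows, cols = meta["grid_rows"], meta["grid_cols"]

    def render_matrix(rel: str, subdir: str, kind: str) -> None:
        path = os.path.join(run_dir, rel)
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing stage output {rel!r}: run the pipeline first")
        mat = pd.read_csv(path, sep="\t", index_col=0)
        os.makedirs(os.path.join(fig_dir, subdir), exist_ok=True)
        for pid, row in mat.iterrows():
            p = som.Portrait(
                sample_or_group_id=str(pid), values=row.to_numpy(dtype=float),
                grid_rows=rows, grid_cols=cols, kind=kind,
            )
            png = os.path.join(fig_dir, subdir, f"{pid}.png")
            som.render_portrait(p, png)
            manifest.append(os.path.relpath(png, run_dir))

    render_matrix("portraits.tsv", "portraits", "single-sample")
    if os.path.exists(os.path.join(run_dir, "group_portraits.tsv")):
        render_matrix("group_portraits.tsv", "groups", "group-mean")

    # summary spot map: module labels on the grid
    mod_path = os.path.join(run_dir, "spots", "modules.tsv")
    if os.path.exists(mod_path):
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        mods = pd.read_csv(mod_path, sep="\t")
        grid = np.zeros((rows, cols))
        fig, ax = plt.subplots(figsize=(4, 4))
        for i, row in mods.iterrows():
            coords = [
                tuple(map(int, rc.split(","))) for rc in str(row["units"]).split(";")
            ]
            for r, c in coords:
                grid[r, c] = i + 1
            rr = [r for r, _ in coords]
            cc = [c for _, c in coords]
            ax.text(float(np.mean(cc)), float(np.mean(rr)), row["label"],
                    ha="center", va="center", fontsize=10)
        ax.imshow(grid, cmap="tab20", interpolation="nearest")
        ax.set_xticks([])
        ax.set_yticks([])
        png = os.path.join(fig_dir, "spot_map.png")
        fig.savefig(png, dpi=120, bbox_inches="tight")
        plt.close(fig)
        manifest.append(os.path.relpath(png, run_dir))

    hr_path = os.path.join(run_dir, "survival", "hr_map.tsv")
    if os.path.exists(hr_path):
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        hr = pd.read_csv(hr_path, sep="\t")
        grid = np.full((rows, cols), np.nan)
        for _, row in hr.iterrows():
            if bool(row["defined"]):
                grid[int(row["row"]), int(row["col"])] = np.log2(row["hr"])
        fig, ax = plt.subplots(figsize=(4, 4))
        lim = np.nanmax(np.abs(grid)) if np.isfinite(grid).any() else 1.0
        im = ax.imshow(grid, cmap="RdBu_r", vmin=-lim, vmax=lim,
                       interpolation="nearest")
        fig.colorbar(im, ax=ax, label="log2 HR")
        ax.set_xticks([])
        ax.set_yticks([])
        png = os.path.join(fig_dir, "hr_map.png")
        fig.savefig(png, dpi=120, bbox_inches="tight")
        plt.close(fig)
        manifest.append(os.path.relpath(png, run_dir))

    payload = {"files": sorted(manifest)}
    with open(os.path.join(fig_dir, "manifest.json"), "w") as fh:
        json.dump(payload, fh, indent=1)
    return payload
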