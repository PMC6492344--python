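"""Gene-set enrichment: right-tailed Fisher tests, GSZ profiles, gene maps.

Spot-module gene lists are tested against a gene-set collection with
the right-tailed Fisher exact test (upper hypergeometric tail), with
Benjamini–Hochberg FDR reported alongside the raw p-values.  The gene
set Z-score (GSZ) summarizes a set's expression in each sample as a
standardized mean: the set mean minus the transcriptome-wide mean,
scaled by the transcriptome SD over the square root of the set size —
a parameter-free per-sample enrichment profile.  Gene maps report the
invariant grid position of individual genes.
"""

from __future__ import annotations

import math
import os

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix
from .som import SOMModel
from .spots import SpotModule

__all__ = [
    "read_gmt",
    "write_gmt",
    "fisher_enrichment",
    "enrich_modules",
    "gsz_profile",
    "gsz_matrix",
    "gene_map",
]


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT file into name → deduplicated member list."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if members:
                sets[name] = members
    return sets


def write_gmt(
    sets: dict[str, list[str]], path: str | os.PathLike, description: str = "na"
) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def fisher_enrichment(
    module_genes: set, gene_set: set, universe: set
) -> tuple[float, int, float]:
    """Right-tailed Fisher exact test of a module against one gene set.

    Returns ``(p, overlap, fold)`` where p = P(X >= k) under the
    hypergeometric null for the observed overlap k, and fold is the
    observed over expected overlap ratio.  The gene set is intersected
    with the universe before testing.
    """
    if not universe:
        raise ValueError("empty universe")
    module_genes = set(module_genes)
    if not module_genes <= universe:
        raise ValueError("module genes must be a subset of the universe")
    gene_set = set(gene_set) & universe
    M = len(universe)
    n_mod = len(module_genes)
    n_set = len(gene_set)
    k = len(module_genes & gene_set)
    # P(X >= k) with X ~ Hypergeom(M, n_set, n_mod)
    p = float(stats.hypergeom.sf(k - 1, M, n_set, n_mod))
    p = min(max(p, 0.0), 1.0)
    if n_mod == 0 or n_set == 0:
        fold = math.nan
    else:
        fold = (k / n_mod) / (n_set / M)
    return p, k, fold


def enrich_modules(
    modules: list[SpotModule] | dict[str, list[str]],
    gene_sets: dict[str, list[str]],
    universe: set,
) -> pd.DataFrame:
    """Fisher enrichment of every module × gene-set pair, with BH FDR."""
    if isinstance(modules, list):
        module_map = {m.label: m.genes for m in modules}
    else:
        module_map = modules
    rows = []
    for mod_label, mod_genes in module_map.items():
        for set_name, members in gene_sets.items():
            p, k, fold = fisher_enrichment(set(mod_genes), set(members), universe)
            rows.append(
                {
                    "module": mod_label,
                    "gene_set": set_name,
                    "overlap": k,
                    "p_value": p,
                    "fold": fold,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        from statsmodels.stats.multitest import multipletests

        table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table


def gsz_profile(gene_set: set, m: ExpressionMatrix) -> pd.Series:
    """Per-sample GSZ score of one gene set.

    z(s) = (mean over set members in s − mean over all genes in s)
    / (SD over all genes in s / sqrt(n_set)).
    """
    members = sorted(set(gene_set) & set(m.data.index))
    if len(members) < 2:
        missing = sorted(set(gene_set) - set(m.data.index))
        raise ValueError(
            f"gene set needs >= 2 members present in the matrix; missing ids: "
            f"{missing[:10]}"
        )
    values = m.values
    set_mean = m.data.loc[members].mean(axis=0)
    all_mean = values.mean(axis=0)
    all_sd = values.std(axis=0, ddof=1)
    z = (set_mean - all_mean) / (all_sd / math.sqrt(len(members)))
    z.name = "gsz"
    return z


def gsz_matrix(gene_sets: dict[str, list[str]], m: ExpressionMatrix) -> pd.DataFrame:
    """GSZ profiles for a whole collection: set × sample score matrix."""
    return pd.DataFrame(
        {name: gsz_profile(set(members), m) for name, members in gene_sets.items()}
    ).T


def gene_map(
    model: SOMModel,
    gene_ids: list[str],
    modules: list[SpotModule] | None = None,
) -> pd.DataFrame:
    """Grid coordinates of selected genes, with nearest spot-module label.

    Unknown genes are reported with ``missing=True`` rather than raised.
    """
    unit_of = {}
    if modules:
        for mod in modules:
            for coord in mod.units:
                unit_of[coord] = mod.label
    rows = []
    for gid in gene_ids:
        if gid in model.gene_assignment.index:
            unit = int(model.gene_assignment[gid])
            r, c = model.unit_coord(unit)
            rows.append(
                {
                    "gene_id": gid,
                    "unit_index": unit,
                    "row": r,
                    "col": c,
                    "module": unit_of.get((r, c), "none"),
                    "missing": False,
                }
            )
        else:
            rows.append(
                {
                    "gene_id": gid,
                    "unit_index": pd.NA,
                    "row": pd.NA,
                    "col": pd.NA,
                    "module": "none",
                    "missing": True,
                }
            )
    return pd.DataFrame(rows)
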