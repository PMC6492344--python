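"""Self-organizing map training and expression portraits.

A SOM compresses the N gene expression profiles (vectors of length
M = number of samples) into K = rows × cols *metagene* profiles arranged
on a two-dimensional grid, using Euclidean distance in profile space.
Genes with similar profiles end up in the same or in nearby grid units,
so clusters of co-expressed genes appear as contiguous "spots" when one
sample's metagene values are rendered on the grid — its *portrait*.

Training is the classic online algorithm: genes are presented in
seeded random order; the best-matching unit (BMU, minimal Euclidean
distance, ties to the lowest unit index) and its grid neighborhood are
pulled toward the presented profile with a Gaussian neighborhood kernel.
Radius and learning rate decay exponentially — from max(rows, cols)/2
to 0.7 grid units and from 0.3 to 0.05 by default — so the map spends
comparable time at every organization scale and keeps enough plasticity
late in training to resolve tight gene clusters into multi-unit spots.
The codebook is initialized linearly along the first two principal
components of the gene profiles, which makes the outcome reproducible
up to the seeded presentation order.  With a final radius of 0 the
update degenerates to online k-means.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = ["SOMModel", "Portrait", "train_som", "portrait", "mean_portrait",
           "render_portrait", "save_model", "load_model"]


@dataclass
class SOMModel:
    grid_rows: int
    grid_cols: int
    codebook: np.ndarray = field(repr=False)  # K x n_samples
    gene_assignment: pd.Series = field(repr=False)  # gene id -> unit index
    sample_ids: list = field(default_factory=list)
    training_meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols

    def unit_coord(self, unit: int) -> tuple[int, int]:
        return divmod(int(unit), self.grid_cols)

    @property
    def unit_gene_lists(self) -> dict[int, list[str]]:
        """unit index -> gene ids assigned to it (empty units omitted)."""
        out: dict[int, list[str]] = {}
        for gene, unit in self.gene_assignment.items():
            out.setdefault(int(unit), []).append(gene)
        return out

    @property
    def empty_units(self) -> np.ndarray:
        occupied = np.zeros(self.n_units, dtype=bool)
        occupied[self.gene_assignment.to_numpy()] = True
        return ~occupied


@dataclass
class Portrait:
    """K metagene values of one sample (or group mean) on the grid."""

    sample_or_group_id: str
    values: np.ndarray = field(repr=False)  # length K, row-major
    grid_rows: int = 0
    grid_cols: int = 0
    kind: str = "single-sample"  # or "group-mean"
    interpolated: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.grid_rows * self.grid_cols != self.values.size:
            raise ValueError("portrait length must equal grid_rows * grid_cols")

    @property
    def grid(self) -> np.ndarray:
        return self.values.reshape(self.grid_rows, self.grid_cols)


def _linear_init(X: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Codebook spanned by the first two principal components of X."""
    mean = X.mean(axis=0)
    Xc = X - mean
    # deterministic thin SVD; sign fixed by forcing the largest-magnitude
    # loading of each component to be positive
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = vt.shape[0]
    sd = s / max(np.sqrt(X.shape[0] - 1), 1.0)
    comps = []
    for i in range(min(2, k)):
        v = vt[i]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        comps.append(v * sd[i])
    while len(comps) < 2:
        comps.append(np.zeros(X.shape[1]))
    a_r = np.linspace(-1, 1, rows) if rows > 1 else np.zeros(1)
    a_c = np.linspace(-1, 1, cols) if cols > 1 else np.zeros(1)
    # rows vary along the larger-variance component
    code = (
        mean[None, None, :]
        + a_r[:, None, None] * comps[0][None, None, :]
        + a_c[None, :, None] * comps[1][None, None, :]
    )
    if rows == 1 and cols > 1:  # single row: span PC1 along the columns
        code = mean[None, None, :] + a_c[None, :, None] * comps[0][None, None, :]
    return code.reshape(rows * cols, X.shape[1]).astype(float)


def _grid_distance2(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    diff = coords[:, None, :] - coords[None, :, :]
    return (diff**2).sum(axis=2)


def assign_genes(codebook: np.ndarray, X: np.ndarray) -> np.ndarray:
    """BMU index per gene; ties resolved to the lowest unit index."""
    # chunked to bound memory on large N
    out = np.empty(X.shape[0], dtype=int)
    cb_norm2 = (codebook**2).sum(axis=1)
    for start in range(0, X.shape[0], 2048):
        chunk = X[start : start + 2048]
        d2 = cb_norm2[None, :] - 2.0 * chunk @ codebook.T
        out[start : start + 2048] = np.argmin(d2, axis=1)
    return out


def train_som(
    m: ExpressionMatrix,
    rows: int = 50,
    cols: int = 50,
    seed: int = 0,
    epochs: int = 20,
    learning_rate: tuple[float, float] = (0.3, 0.05),
    radius: tuple[float | None, float] = (None, 0.7),
) -> SOMModel:
    """Train the metagene SOM on a preprocessed expression matrix.

    Parameters
    ----------
    m:
        Preprocessed (centralized) matrix; profiles live in sample space.
    rows, cols:
        Grid geometry; K = rows * cols metagenes.
    seed:
        Governs the gene presentation order (initialization is
        deterministic PCA).
    radius:
        (initial, final) Gaussian neighborhood radius in grid units;
        initial ``None`` means max(rows, cols) / 2.  A final radius of 0
        reduces the update to online k-means.
    """
    X = m.values
    if not np.all(np.isfinite(X)):
        raise ValueError("expression matrix contains non-finite values")
    K = rows * cols
    if K < 1:
        raise ValueError("grid must have at least one unit")
    if K > m.n_genes:
        import warnings

        warnings.warn(
            f"grid has {K} units but only {m.n_genes} genes: empty units guaranteed",
            stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    codebook = _linear_init(X, rows, cols)
    gd2 = _grid_distance2(rows, cols)
    r0 = radius[0] if radius[0] is not None else max(rows, cols) / 2.0
    r1 = radius[1]
    lr0, lr1 = learning_rate
    total = epochs * X.shape[0]
    step = 0
    denom = max(total - 1, 1)
    cb_norm2 = (codebook**2).sum(axis=1)
    for _epoch in range(epochs):
        order = rng.permutation(X.shape[0])
        for gi in order:
            x = X[gi]
            frac = step / denom
            if r1 > 0 and r0 > 0:
                sigma = r0 * (r1 / r0) ** frac  # exponential decay
            else:
                sigma = r0 + (r1 - r0) * frac
            lr = lr0 * (lr1 / lr0) ** frac if lr0 > 0 and lr1 > 0 else (
                lr0 + (lr1 - lr0) * frac
            )
            d2 = cb_norm2 - 2.0 * (codebook @ x)
            bmu = int(np.argmin(d2))
            if sigma <= 0:
                codebook[bmu] += lr * (x - codebook[bmu])
                cb_norm2[bmu] = codebook[bmu] @ codebook[bmu]
            else:
                h = np.exp(-gd2[bmu] / (2.0 * sigma * sigma))
                active = np.flatnonzero(h > 1e-4)  # skip negligible updates
                codebook[active] += (lr * h[active])[:, None] * (
                    x - codebook[active]
                )
                cb_norm2[active] = (codebook[active] ** 2).sum(axis=1)
            step += 1
    units = assign_genes(codebook, X)
    assignment = pd.Series(units, index=m.data.index, name="unit_index")
    return SOMModel(
        grid_rows=rows,
        grid_cols=cols,
        codebook=codebook,
        gene_assignment=assignment,
        sample_ids=m.sample_ids,
        training_meta={
            "seed": int(seed),
            "epochs": epochs,
            "learning_rate": list(learning_rate),
            "radius": [r0, r1],
        },
    )


def portrait(model: SOMModel, m: ExpressionMatrix, sample_id: str) -> Portrait:
    """One sample's metagene portrait.

    Occupied units carry the mean expression of their assigned genes in
    that sample; empty units fall back to the trained codebook value and
    are flagged as interpolated.
    """
    if sample_id not in m.data.columns:
        raise KeyError(f"unknown sample id {sample_id!r}")
    col = m.data[sample_id]
    j = model.sample_ids.index(sample_id) if sample_id in model.sample_ids else None
    values = np.zeros(model.n_units)
    interpolated = model.empty_units.copy()
    sums = np.zeros(model.n_units)
    counts = np.zeros(model.n_units)
    units = model.gene_assignment.reindex(m.data.index)
    if units.isna().any():
        missing = units.index[units.isna()].tolist()
        raise KeyError(f"genes absent from the model: {missing[:5]}")
    np.add.at(sums, units.to_numpy(dtype=int), col.to_numpy(dtype=float))
    np.add.at(counts, units.to_numpy(dtype=int), 1.0)
    occupied = counts > 0
    values[occupied] = sums[occupied] / counts[occupied]
    if j is not None:
        values[~occupied] = model.codebook[~occupied, j]
    return Portrait(
        sample_or_group_id=sample_id,
        values=values,
        grid_rows=model.grid_rows,
        grid_cols=model.grid_cols,
        kind="single-sample",
        interpolated=interpolated,
    )


def sample_portraits(model: SOMModel, m: ExpressionMatrix) -> dict[str, Portrait]:
    """Portraits for every sample in the matrix."""
    return {s: portrait(model, m, s) for s in m.sample_ids}


def mean_portrait(portraits: list[Portrait], group_id: str) -> Portrait:
    """Element-wise mean of member portraits (a group/subtype portrait)."""
    if not portraits:
        raise ValueError(f"empty group {group_id!r}")
    lengths = {p.values.size for p in portraits}
    if len(lengths) != 1:
        raise ValueError("portraits have unequal lengths")
    stacked = np.vstack([p.values for p in portraits])
    first = portraits[0]
    interp = None
    masks = [p.interpolated for p in portraits if p.interpolated is not None]
    if masks:
        interp = np.logical_or.reduce(masks)
    return Portrait(
        sample_or_group_id=group_id,
        values=stacked.mean(axis=0),
        grid_rows=first.grid_rows,
        grid_cols=first.grid_cols,
        kind="group-mean",
        interpolated=interp,
    )


# -- rendering & persistence ---------------------------------------------

_PORTRAIT_CMAP = None


def _portrait_cmap():
    """Blue -> white/yellow -> maroon, min to max per portrait."""
    global _PORTRAIT_CMAP
    if _PORTRAIT_CMAP is None:
        from matplotlib.colors import LinearSegmentedColormap

        _PORTRAIT_CMAP = LinearSegmentedColormap.from_list(
            "portrait",
            ["#00007f", "#0055ff", "#7fffff", "#ffff55", "#ff5500", "#7f0000"],
        )
    return _PORTRAIT_CMAP


def render_portrait(
    p: Portrait, path: str | os.PathLike, csv_path: str | os.PathLike | None = None
) -> None:
    """Write the portrait heat map as PNG (and optionally the grid as CSV).

    The color scale spans this portrait's own min -> max (blue -> maroon).
    """
    if not np.all(np.isfinite(p.values)):
        raise ValueError("portrait contains non-finite values")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(p.grid, cmap=_portrait_cmap(), interpolation="nearest")
    ax.set_title(p.sample_or_group_id, fontsize=8)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    if csv_path is not None:
        np.savetxt(csv_path, p.grid, delimiter=",", fmt="%.10g")


def save_model(model: SOMModel, directory: str | os.PathLike) -> None:
    """Persist codebook (TSV), assignment (TSV) and metadata (JSON)."""
    os.makedirs(directory, exist_ok=True)
    pd.DataFrame(
        model.codebook,
        columns=model.sample_ids,
        index=[f"u{u:04d}" for u in range(model.n_units)],
    ).to_csv(os.path.join(directory, "codebook.tsv"), sep="\t", index_label="unit")
    model.gene_assignment.rename("unit_index").to_csv(
        os.path.join(directory, "assignment.tsv"), sep="\t", index_label="gene_id"
    )
    meta = {
        "grid_rows": model.grid_rows,
        "grid_cols": model.grid_cols,
        "sample_ids": model.sample_ids,
        "training_meta": model.training_meta,
    }
    with open(os.path.join(directory, "model.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_model(directory: str | os.PathLike) -> SOMModel:
    with open(os.path.join(directory, "model.json")) as fh:
        meta = json.load(fh)
    codebook = pd.read_csv(
        os.path.join(directory, "codebook.tsv"), sep="\t", index_col=0
    ).to_numpy(dtype=float)
    assignment = pd.read_csv(
        os.path.join(directory, "assignment.tsv"), sep="\t", index_col=0
    )["unit_index"]
    return SOMModel(
        grid_rows=meta["grid_rows"],
        grid_cols=meta["grid_cols"],
        codebook=codebook,
        gene_assignment=assignment,
        sample_ids=meta["sample_ids"],
        training_meta=meta.get("training_meta", {}),
    )
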