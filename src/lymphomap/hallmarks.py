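"""Cancer-hallmark scoring and hallmark-type (HT) clustering.

Eight hallmark gene-set signatures — angiogenesis, controlling genomic
instability, glucose energetics, inflammation, invasion and metastasis,
proliferation, replicative immortality, resisting death — are scored
per sample with the GSZ statistic of each hallmark's pooled gene list
and averaged per entity (sample, PAT, ...).  Entities are then grouped
into hallmark types by Ward agglomerative clustering on the 8-vector of
scores (deterministic — no random initialization), with HT labels
ordered by decreasing mean proliferation score: HT1 is the most
proliferative type.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .enrichment import gsz_profile
from .matrix import ExpressionMatrix

__all__ = [
    "HALLMARK_NAMES",
    "hallmark_scores",
    "cluster_hallmark_types",
    "polar_diagram",
]

HALLMARK_NAMES = (
    "angiogenesis",
    "controlling genomic instability",
    "glucose energetics",
    "inflammation",
    "invasion and metastasis",
    "proliferation",
    "replicative immortality",
    "resisting death",
)


def hallmark_scores(
    hallmark_sets: dict[str, list[str]],
    m: ExpressionMatrix,
    grouping: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Entity × 8 hallmark GSZ score matrix.

    ``grouping`` maps sample id → entity id (e.g. PAT label); ``None``
    scores each sample as its own entity.  Exactly eight hallmark sets
    are required; columns follow the canonical hallmark order when the
    provided names match it, otherwise the given names sorted.
    """
    if len(hallmark_sets) != 8:
        raise ValueError(
            f"exactly 8 hallmark sets required, got {len(hallmark_sets)}"
        )
    names = list(hallmark_sets)
    if set(names) == set(HALLMARK_NAMES):
        names = list(HALLMARK_NAMES)
    else:
        names = sorted(names)
    per_sample = pd.DataFrame(
        {name: gsz_profile(set(hallmark_sets[name]), m) for name in names}
    )
    if grouping is None:
        scores = per_sample
    else:
        grouping = pd.Series(grouping)
        scores = per_sample.groupby(grouping.loc[per_sample.index]).mean()
    scores.index.name = "entity"
    return scores


def cluster_hallmark_types(profiles: pd.DataFrame, k: int = 5) -> pd.Series:
    """Ward/Euclidean agglomeration of hallmark profiles into k HTs.

    Labels HT1..HTk are assigned in order of decreasing mean
    proliferation score (falling back to the overall score mean when no
    proliferation column is present).
    """
    n = len(profiles)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == n:
        raw = np.arange(1, n + 1)
    else:
        Z = linkage(profiles.to_numpy(dtype=float), method="ward")
        raw = fcluster(Z, t=k, criterion="maxclust")
    key = (
        profiles["proliferation"]
        if "proliferation" in profiles.columns
        else profiles.mean(axis=1)
    )
    order = (
        pd.Series(key.to_numpy(), index=raw)
        .groupby(level=0)
        .mean()
        .sort_values(ascending=False)
        .index.tolist()
    )
    rename = {cl: f"HT{i + 1}" for i, cl in enumerate(order)}
    return pd.Series([rename[c] for c in raw], index=profiles.index, name="HT")


def polar_diagram(
    profile: pd.Series,
    path: str | os.PathLike,
    csv_path: str | os.PathLike | None = None,
) -> None:
    """8-axis radar plot of one hallmark profile.

    Axes follow the profile's column order counter-clockwise starting
    at 12 o'clock; a CSV companion with the raw scores can be written
    alongside.
    """
    if not np.all(np.isfinite(profile.to_numpy(dtype=float))):
        raise ValueError("hallmark profile contains non-finite scores")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    names = profile.index.tolist()
    values = profile.to_numpy(dtype=float)
    angles = np.linspace(0, 2 * np.pi, len(names), endpoint=False) + np.pi / 2
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(polar=True)
    closed_angles = np.concatenate([angles, angles[:1]])
    closed_values = np.concatenate([values, values[:1]])
    ax.plot(closed_angles, closed_values, lw=1.5)
    ax.fill(closed_angles, closed_values, alpha=0.25)
    ax.set_xticks(angles)
    ax.set_xticklabels(names, fontsize=6)
    ax.set_title(str(profile.name), fontsize=9)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    if csv_path is not None:
        profile.to_frame("score").to_csv(csv_path)
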