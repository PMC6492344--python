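"""Over-expression spot-module segmentation and spot statistics.

Spots are contiguous regions of grid units whose metagene value exceeds
a fraction (default 90%) of the portrait's maximum.  Segmenting the
class-mean portraits and unioning the masks yields a *summary map* of
labeled spot modules (A, B, C, ... by decreasing peak height); each
module owns the genes assigned to its units and a per-sample mean
expression profile.  Per-sample spot calls against that catalog give a
boolean sample × module incidence matrix, from which class-association
histograms, spot-count distributions and co-occurrence (association
rule) tables are derived.

Only over-expression (positive values on the centralized Δe scale) is
segmented; under-expression regions are not part of the module catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .matrix import ExpressionMatrix
from .som import Portrait, SOMModel

__all__ = [
    "SpotModule",
    "segment_spots",
    "build_summary_map",
    "call_sample_spots",
    "spot_incidence",
    "spot_statistics",
    "cooccurrence",
]

_STRUCTURE_8 = np.ones((3, 3), dtype=bool)
_STRUCTURE_4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class SpotModule:
    """A labeled connected over-expression region of the summary map."""

    label: str
    units: frozenset  # of (row, col)
    genes: list = field(default_factory=list)
    profile: pd.Series | None = field(default=None, repr=False)
    peak_value: float = 0.0


def _connectivity(conn: int) -> np.ndarray:
    if conn == 8:
        return _STRUCTURE_8
    if conn == 4:
        return _STRUCTURE_4
    raise ValueError("connectivity must be 4 or 8")


def segment_spots(
    p: Portrait,
    threshold_frac: float = 0.9,
    min_size: int = 2,
    connectivity: int = 8,
) -> list[set[tuple[int, int]]]:
    """Connected components of units above threshold_frac × max value.

    Returns unit-coordinate sets ordered by decreasing peak value; empty
    when the portrait has no positive value (no over-expression on the
    centralized scale).  Components smaller than ``min_size`` units are
    discarded as speckle.  Units flagged as interpolated (empty
    metagenes, which carry no genes and whose values are codebook
    interpolation artifacts) are excluded from the mask so they cannot
    bridge distinct gene modules.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    grid = p.grid
    if p.interpolated is not None:
        grid = np.where(
            p.interpolated.reshape(grid.shape), -np.inf, grid
        )
    peak = grid.max()
    if peak <= 0:
        return []
    mask = grid > threshold_frac * peak
    labels, n = ndimage.label(mask, structure=_connectivity(connectivity))
    spots = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        if len(coords) < min_size:
            continue
        spots.append(
            (
                float(grid[labels == lab].max()),
                {(int(r), int(c)) for r, c in coords},
            )
        )
    spots.sort(key=lambda t: (-t[0], min(t[1])))
    return [units for _, units in spots]


def _split_by_profile(
    mask: np.ndarray,
    codebook: np.ndarray,
    cols: int,
    split_r: float,
    connectivity: int,
) -> list[np.ndarray]:
    """Split one connected mask into profile-coherent sub-components.

    Adjacent units stay together only when their metagene (codebook)
    profiles correlate with Pearson r > split_r.  Units of one
    co-expression module are near-duplicates (r ≈ 1) while two distinct
    modules that happen to touch on the grid — because they are
    co-activated in some class — correlate only weakly, so the cut is
    sharp.
    """
    coords = [tuple(rc) for rc in np.argwhere(mask)]
    if len(coords) < 2:
        return [mask]
    profs = np.vstack([codebook[r * cols + c] for r, c in coords])
    centered = profs - profs.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    corr = (centered / norms[:, None]) @ (centered / norms[:, None]).T
    # complete linkage on correlation distance: mixed boundary units that
    # correlate with both sides cannot chain two modules together
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(Z, t=1.0 - split_r, criterion="distance")
    out = []
    for lab in np.unique(labels):
        sub = np.zeros_like(mask)
        for (r, c), l in zip(coords, labels):
            if l == lab:
                sub[r, c] = True
        # a profile cluster that is spatially disconnected falls apart
        # into its connected pieces
        pieces, n_p = ndimage.label(sub, structure=_connectivity(connectivity))
        for k in range(1, n_p + 1):
            out.append(pieces == k)
    return out


def build_summary_map(
    group_portraits: list[Portrait],
    model: SOMModel,
    m: ExpressionMatrix,
    threshold_frac: float = 0.9,
    min_size: int = 2,
    connectivity: int = 8,
    split_r: float | None = 0.5,
) -> list[SpotModule]:
    """Union the group portraits' spot masks into labeled summary modules.

    Connected components of the unioned mask become SpotModules labeled
    A, B, ... in order of decreasing peak value (peak over all group
    portraits); ties break on the row-major coordinate of the peak.
    Because a spot module is a cluster of *correlated* metagenes, a
    connected component whose units carry clearly distinct profiles —
    two different modules co-activated in the same class and touching on
    the grid — is split along the profile-correlation boundary
    (``split_r``, default 0.5; ``None`` disables the refinement).
    Each module's gene list is the union of the genes assigned to its
    units, and its profile is the per-sample mean expression of those
    genes.
    """
    if not group_portraits:
        raise ValueError("at least one group portrait required")
    rows, cols = model.grid_rows, model.grid_cols
    union = np.zeros((rows, cols), dtype=bool)
    peak_grid = np.full((rows, cols), -np.inf)
    for p in group_portraits:
        for units in segment_spots(p, threshold_frac, min_size, connectivity):
            for r, c in units:
                union[r, c] = True
        peak_grid = np.maximum(peak_grid, p.grid)
    labels, n = ndimage.label(union, structure=_connectivity(connectivity))
    masks = []
    for lab in range(1, n + 1):
        mask = labels == lab
        if split_r is not None:
            masks.extend(
                _split_by_profile(mask, model.codebook, cols, split_r, connectivity)
            )
        else:
            masks.append(mask)
    comps = []
    for mask in masks:
        if mask.sum() < min_size:
            continue
        peak = float(peak_grid[mask].max())
        peak_coord = min(
            (int(r), int(c))
            for r, c in np.argwhere(mask & (peak_grid == peak))
        )
        comps.append((peak, peak_coord, mask))
    comps.sort(key=lambda t: (-t[0], t[1]))

    unit_genes = model.unit_gene_lists
    modules = []
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for i, (peak, _, mask) in enumerate(comps):
        label = letters[i] if i < len(letters) else f"Z{i}"
        units = frozenset((int(r), int(c)) for r, c in np.argwhere(mask))
        genes: list[str] = []
        for r, c in sorted(units):
            genes.extend(unit_genes.get(r * cols + c, []))
        if genes:
            profile = m.data.loc[genes].mean(axis=0)
        else:
            profile = pd.Series(0.0, index=m.data.columns)
        modules.append(
            SpotModule(
                label=label,
                units=units,
                genes=genes,
                profile=profile,
                peak_value=peak,
            )
        )
    return modules


def call_sample_spots(
    modules: list[SpotModule],
    p: Portrait,
    threshold_frac: float = 0.5,
    min_size: int = 1,
    connectivity: int = 8,
) -> set[str]:
    """Module labels whose units overlap the sample's own spots.

    Per-sample calling is a detection problem, unlike the boundary-
    drawing 90% criterion applied to the low-noise class-mean portraits:
    an active module sits near the portrait maximum while inactive
    modules are strongly negative on the centralized scale, so the
    robust operating point is halfway (threshold_frac = 0.5) — far from
    both the noise floor and the active level.  min_size = 1 because a
    single above-threshold unit inside a known module is real evidence
    (single-sample portraits fragment), while background units cannot
    reach the threshold.
    """
    called = set()
    for units in segment_spots(p, threshold_frac, min_size, connectivity):
        for module in modules:
            if units & module.units:
                called.add(module.label)
    return called


def spot_incidence(
    modules: list[SpotModule],
    portraits: dict[str, Portrait],
    threshold_frac: float = 0.5,
    min_size: int = 1,
    connectivity: int = 8,
) -> pd.DataFrame:
    """Boolean sample × module incidence matrix."""
    labels = [mod.label for mod in modules]
    rows = {}
    for sid, p in portraits.items():
        called = call_sample_spots(modules, p, threshold_frac, min_size, connectivity)
        rows[sid] = [lab in called for lab in labels]
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels)


def spot_statistics(
    inc: pd.DataFrame, classes: pd.Series | dict
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class-association fractions and per-class spot-count distributions.

    Returns ``(assoc, counts)`` where ``assoc[c, m]`` is the fraction of
    class-c samples showing module m, and ``counts[c, k]`` the fraction
    of class-c samples with exactly k called spots (rows sum to 1).
    """
    classes = pd.Series(classes)
    unknown = [s for s in inc.index if s not in classes.index]
    if unknown:
        raise KeyError(f"samples without class label: {unknown[:5]}")
    cls = classes.loc[inc.index]
    assoc = inc.astype(float).groupby(cls).mean()
    n_spots = inc.sum(axis=1)
    max_k = int(n_spots.max()) if len(n_spots) else 0
    counts = (
        pd.crosstab(cls, n_spots, normalize="index")
        .reindex(columns=range(max_k + 1), fill_value=0.0)
    )
    counts.columns = [int(c) for c in counts.columns]
    return assoc, counts


def cooccurrence(inc: pd.DataFrame) -> pd.DataFrame:
    """Association-rule table over module pairs.

    For each ordered pair (i, j): joint probability P(i∧j), confidence
    P(j|i) and lift P(i∧j)/(P(i)P(j)).  Confidence and lift are NaN
    where the conditioning marginal is zero.
    """
    if inc.shape[0] < 1:
        raise ValueError("incidence matrix needs at least one sample")
    X = inc.to_numpy(dtype=float)
    n = X.shape[0]
    marg = X.mean(axis=0)
    joint = (X.T @ X) / n
    rows = []
    for i, mi in enumerate(inc.columns):
        for j, mj in enumerate(inc.columns):
            pij = joint[i, j]
            conf = pij / marg[i] if marg[i] > 0 else np.nan
            lift = (
                pij / (marg[i] * marg[j])
                if marg[i] > 0 and marg[j] > 0
                else np.nan
            )
            rows.append(
                {
                    "module_i": mi,
                    "module_j": mj,
                    "joint": pij,
                    "confidence": conf,
                    "lift": lift,
                }
            )
    return pd.DataFrame(rows)
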