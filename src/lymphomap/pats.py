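"""Combinatorial pattern types (PATs).

A PAT is the combination of spot modules concertedly over-expressed in
a sample, written as the space-joined sorted module letters ("A B D").
Assignment proceeds in three passes:

1. **by spots** — each sample's raw PAT is its called module set; a raw
   PAT is retained only if at least ``min_cases`` samples (default 5)
   of at least one subtype carry it, which suppresses rare patterns.
2. **by correlation** — samples holding a rejected raw PAT, and samples
   with no spot at all, are rescued into the retained PAT whose
   centroid (mean module-expression vector over by-spot members) they
   correlate with best, provided Pearson r exceeds ``r_rescue``
   (default 0.8).
3. **unassigned** — everything else is labeled "∅" (no PAT).

Retained PATs are further grouped by their most characteristic module,
∅ samples can be distributed into PAT groups by nearest group-mean
portrait, and PAT mean portraits are plain element-wise averages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .som import Portrait, mean_portrait

__all__ = [
    "NO_PAT",
    "assign_pats",
    "group_pats",
    "distribute_nopat",
    "pat_mean_portraits",
]

NO_PAT = "∅"


def _pat_label(modules) -> str:
    return " ".join(sorted(modules)) if modules else NO_PAT


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def assign_pats(
    inc: pd.DataFrame,
    classes: pd.Series | dict,
    module_expr: pd.DataFrame,
    min_cases: int = 5,
    r_rescue: float = 0.8,
) -> pd.DataFrame:
    """Assign every sample a PAT label (or ∅).

    Parameters
    ----------
    inc:
        Boolean sample × module incidence matrix.
    classes:
        Sample → subtype label; min_cases is evaluated per subtype.
    module_expr:
        Module × sample mean-expression matrix (the module profiles);
        the space in which rescue correlations are computed.
    min_cases:
        A raw PAT is retained iff ≥ min_cases samples of at least one
        subtype carry it.
    r_rescue:
        Pearson threshold for the correlation rescue (strictly greater).

    Returns a DataFrame indexed by sample with columns ``pat_label``
    (sorted letters or ∅), ``assignment_route`` (by-spots /
    by-correlation / unassigned) and an empty ``pat_group`` column to be
    filled by :func:`group_pats` / :func:`distribute_nopat`.
    """
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    if not 0.0 < r_rescue <= 1.0:
        raise ValueError("r_rescue must be in (0, 1]")
    classes = pd.Series(classes)
    samples = inc.index.tolist()
    raw = {
        s: _pat_label([m for m in inc.columns if inc.at[s, m]]) for s in samples
    }
    # retention: >= min_cases carriers within at least one subtype
    tab = pd.DataFrame(
        {"pat": [raw[s] for s in samples], "subtype": classes.loc[samples].to_numpy()}
    )
    counts = tab[tab["pat"] != NO_PAT].groupby(["pat", "subtype"]).size()
    retained = sorted(
        {pat for (pat, _), n in counts.items() if n >= min_cases}
    )

    by_spots = [s for s in samples if raw[s] in retained]
    pending = [s for s in samples if raw[s] not in retained]

    # centroids in module-expression space, from by-spot members only
    centroids: dict[str, np.ndarray] = {}
    for pat in retained:
        members = [s for s in by_spots if raw[s] == pat]
        centroids[pat] = module_expr.loc[:, members].mean(axis=1).to_numpy()

    records = {}
    for s in by_spots:
        records[s] = (raw[s], "by-spots")
    for s in pending:
        if not retained:
            records[s] = (NO_PAT, "unassigned")
            continue
        vec = module_expr[s].to_numpy()
        best_pat, best_r = None, -np.inf
        for pat in retained:
            r = _pearson(vec, centroids[pat])
            if np.isfinite(r) and r > best_r:
                best_pat, best_r = pat, r
        if best_pat is not None and best_r > r_rescue:
            records[s] = (best_pat, "by-correlation")
        else:
            records[s] = (NO_PAT, "unassigned")

    out = pd.DataFrame.from_dict(
        records, orient="index", columns=["pat_label", "assignment_route"]
    ).loc[samples]
    out.index.name = "sample_id"
    out["pat_group"] = pd.NA
    return out


def group_pats(assignments: pd.DataFrame) -> dict[str, str]:
    """Group retained PATs by their most characteristic module.

    Module support = number of assigned samples whose PAT label contains
    the module; each PAT's characteristic module is its member module
    with the highest support (ties alphabetical), and the group label is
    that module letter.  Returns pat_label → group label and fills the
    ``pat_group`` column in place for non-∅ samples.
    """
    labels = [l for l in assignments["pat_label"].unique() if l != NO_PAT]
    if not labels:
        return {}
    support: dict[str, int] = {}
    for label, n in assignments["pat_label"].value_counts().items():
        if label == NO_PAT:
            continue
        for mod in label.split():
            support[mod] = support.get(mod, 0) + int(n)
    mapping = {}
    for label in sorted(labels):
        mods = label.split()
        mapping[label] = min(mods, key=lambda m: (-support.get(m, 0), m))
    assignments["pat_group"] = assignments["pat_label"].map(
        lambda l: mapping.get(l, pd.NA)
    )
    return mapping


def distribute_nopat(
    assignments: pd.DataFrame,
    sample_portraits: dict[str, Portrait],
    group_mean_portraits: dict[str, Portrait],
) -> pd.DataFrame:
    """Distribute ∅ samples into PAT groups by nearest group-mean portrait.

    The pat_label stays ∅; only ``pat_group`` is filled, using minimum
    Euclidean distance between the sample portrait and each group mean
    portrait.  Ties go to the lowest-sorting group label.
    """
    if not group_mean_portraits:
        raise ValueError("at least one group mean portrait required")
    group_labels = sorted(group_mean_portraits)
    centroids = np.vstack([group_mean_portraits[g].values for g in group_labels])
    for s in assignments.index[assignments["pat_label"] == NO_PAT]:
        v = sample_portraits[s].values
        d2 = ((centroids - v[None, :]) ** 2).sum(axis=1)
        assignments.at[s, "pat_group"] = group_labels[int(np.argmin(d2))]
    return assignments


def pat_mean_portraits(
    assignments: pd.DataFrame, portraits: dict[str, Portrait]
) -> dict[str, Portrait]:
    """Element-wise mean portrait per (non-∅) PAT."""
    out = {}
    for pat, members in assignments.groupby("pat_label").groups.items():
        if pat == NO_PAT:
            continue
        out[pat] = mean_portrait([portraits[s] for s in members], str(pat))
    return out
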