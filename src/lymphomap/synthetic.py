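"""Synthetic cohorts with planted modular co-expression and survival structure.

The generator emulates the statistical structure the portrait pipeline
assumes in a real tumor-transcriptome cohort: blocks ("modules") of
co-expressed genes that are over-expressed in defined sample classes,
classes defined by *combinations* of active modules, i.i.d. Gaussian
log2 noise on top, and survival times whose hazard depends
multiplicatively on module activation.  Ground-truth labels are carried
alongside so that recovery can be measured at every pipeline stage.

Default conditions: 5,000 genes, 8 modules of 60 genes, additive module
effect 2.0 log2 units over a baseline of 8.0, noise SD 0.5, and six
classes of 50 samples, each class activating modules so that every
module is active in exactly two classes.  Equal module prevalence keeps
the centralized over-expression heights of the spots within one class
equal, which is the regime the 90%-of-maximum segmentation criterion is
designed for.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigurationError",
    "simulate_expression",
    "simulate_survival",
    "export_gene_sets",
    "default_config",
    "factorial_survival_config",
]

MODULE_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


class ConfigurationError(ValueError):
    """A simulation config violates one of its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    class_definitions is a list of (class name, set of active module
    letters, sample count).  module_betas maps module letters to log
    hazard ratios conferred by activation of that module.
    """

    n_genes: int = 5000
    n_modules: int = 8
    genes_per_module: int = 60
    module_effect: float = 2.0  # additive shift, log2 units
    noise_sd: float = 0.5  # log2 units
    baseline: float = 8.0  # typical microarray log2 level
    class_definitions: list[tuple[str, frozenset, int]] = field(default_factory=list)
    baseline_hazard: float = 0.1  # events per unit time
    module_betas: dict = field(default_factory=dict)
    censor_rate: float = 0.3
    therapy_confounded: bool = False
    shared_contamination_module: str | None = None  # tonsil-like module letter
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.class_definitions:
            self.class_definitions = _default_classes()
        self.class_definitions = [
            (name, frozenset(mods), int(count))
            for name, mods, count in self.class_definitions
        ]
        self.validate()

    @property
    def module_labels(self) -> list[str]:
        return list(MODULE_LETTERS[: self.n_modules])

    @property
    def n_samples(self) -> int:
        return sum(count for _, _, count in self.class_definitions)

    def validate(self) -> None:
        if self.n_modules * self.genes_per_module > self.n_genes:
            raise ConfigurationError(
                "invariant violated: n_modules * genes_per_module <= n_genes "
                f"({self.n_modules} * {self.genes_per_module} > {self.n_genes})"
            )
        universe = set(self.module_labels)
        for name, mods, count in self.class_definitions:
            if not mods <= universe:
                raise ConfigurationError(
                    f"invariant violated: class {name!r} activates unknown "
                    f"modules {sorted(mods - universe)}"
                )
            if count < 1:
                raise ConfigurationError(f"class {name!r} has sample count < 1")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ConfigurationError("invariant violated: censor_rate must be in [0,1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("invariant violated: noise_sd must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if not set(self.module_betas) <= universe:
            raise ConfigurationError(
                f"module_betas refers to unknown modules "
                f"{sorted(set(self.module_betas) - universe)}"
            )


@dataclass
class GroundTruth:
    """Planted structure of one synthetic cohort."""

    module_gene_map: dict  # module letter -> list of gene ids
    sample_class: dict  # sample id -> class name
    sample_active_modules: dict  # sample id -> frozenset of module letters
    true_betas: dict  # module letter -> log HR
    gene_ids: list = field(default_factory=list)  # full universe

    def __post_init__(self) -> None:
        seen: set = set()
        for label, genes in self.module_gene_map.items():
            overlap = seen & set(genes)
            if overlap:
                raise ConfigurationError(
                    f"module gene sets not disjoint: {sorted(overlap)[:3]}"
                )
            seen |= set(genes)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "module_gene_map": {k: list(v) for k, v in self.module_gene_map.items()},
            "sample_class": self.sample_class,
            "sample_active_modules": {
                k: sorted(v) for k, v in self.sample_active_modules.items()
            },
            "true_betas": self.true_betas,
            "gene_ids": list(self.gene_ids),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _default_classes() -> list[tuple[str, frozenset, int]]:
    # 8 modules, each active in exactly 2 of 6 classes -> equal prevalence
    # 1/3, hence equal centralized spot heights within every class, and
    # pairwise-distinct class signatures so no two modules are confounded
    return [
        ("c1", frozenset("AB"), 50),
        ("c2", frozenset("CD"), 50),
        ("c3", frozenset("EF"), 50),
        ("c4", frozenset("GH"), 50),
        ("c5", frozenset("ACEG"), 50),
        ("c6", frozenset("BDFH"), 50),
    ]


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default planted-module cohort (see module docstring)."""
    return SimulationConfig(seed=seed, **overrides)


def factorial_survival_config(seed: int = 0, beta: float = 0.7) -> SimulationConfig:
    """A cohort designed for prognostic-map recovery.

    Four modules in a 2^4 full-factorial class design (16 classes of 25
    samples): every module is active in exactly half the samples and any
    two modules are independent.  Prevalence 1/2 aligns the HR map's
    median dichotomization with module activation, and independence
    keeps the hazard signal of the one prognostic module (D, log HR
    ``beta``) out of the other modules' map regions.
    """
    labels = "ABCD"
    classes = []
    for bits in range(16):
        active = frozenset(l for i, l in enumerate(labels) if bits >> i & 1)
        classes.append((f"f{bits:02d}", active, 25))
    return SimulationConfig(
        n_genes=2000,
        n_modules=4,
        genes_per_module=50,
        class_definitions=classes,
        module_betas={"D": beta},
        censor_rate=0.2,
        seed=seed,
    )


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw the planted-block expression matrix and its ground truth.

    Gene g in module m has mean ``baseline + module_effect`` in samples
    whose class activates m and mean ``baseline`` elsewhere; all entries
    carry i.i.d. Gaussian noise of SD ``noise_sd``.  Deterministic for a
    given config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n_genes, n_samples = config.n_genes, config.n_samples
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    sample_ids, classes = [], []
    for name, _, count in config.class_definitions:
        for k in range(count):
            sample_ids.append(f"{name}_s{k:03d}")
            classes.append(name)
    class_mods = {name: mods for name, mods, _ in config.class_definitions}

    module_gene_map = {}
    for i, label in enumerate(config.module_labels):
        start = i * config.genes_per_module
        module_gene_map[label] = gene_ids[start : start + config.genes_per_module]

    values = config.baseline + rng.normal(0.0, config.noise_sd, (n_genes, n_samples))
    sample_active = {}
    for j, (sid, cname) in enumerate(zip(sample_ids, classes)):
        active = class_mods[cname]
        if config.shared_contamination_module is not None:
            active = active | {config.shared_contamination_module}
        sample_active[sid] = frozenset(active)
        for label in active:
            i0 = config.module_labels.index(label) * config.genes_per_module
            values[i0 : i0 + config.genes_per_module, j] += config.module_effect

    matrix = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    truth = GroundTruth(
        module_gene_map=module_gene_map,
        sample_class=dict(zip(sample_ids, classes)),
        sample_active_modules=sample_active,
        true_betas={
            label: float(config.module_betas.get(label, 0.0))
            for label in config.module_labels
        },
        gene_ids=gene_ids,
    )
    return matrix, truth


def _solve_censor_hazard(hazards: np.ndarray, target: float) -> float:
    """Censoring rate c with mean_i c/(c+h_i) = target, by bisection."""
    lo, hi = 1e-12, float(hazards.max()) * 1e6
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        frac = float(np.mean(mid / (mid + hazards)))
        if frac < target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def simulate_survival(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Draw survival annotation for the cohort.

    Event times are exponential with per-sample hazard
    ``baseline_hazard * exp(sum of active-module betas)``; censoring is
    independent exponential, calibrated so the expected censored
    fraction equals ``censor_rate``.  Binary therapy covariates are
    drawn independently of the hazard unless ``therapy_confounded``.

    Returns a DataFrame with columns sample_id, class, time, status,
    chemotherapy, rituximab.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    sample_ids = list(truth.sample_class)
    hazards = np.array(
        [
            config.baseline_hazard
            * math.exp(
                sum(truth.true_betas.get(m, 0.0) for m in truth.sample_active_modules[s])
            )
            for s in sample_ids
        ]
    )
    event_times = rng.exponential(1.0 / hazards)
    if config.censor_rate <= 0.0:
        time, status = event_times, np.ones(len(sample_ids), dtype=int)
    elif config.censor_rate >= 1.0:
        time, status = event_times, np.zeros(len(sample_ids), dtype=int)
    else:
        c = _solve_censor_hazard(hazards, config.censor_rate)
        censor_times = rng.exponential(1.0 / c, len(sample_ids))
        status = (event_times <= censor_times).astype(int)
        time = np.minimum(event_times, censor_times)

    if config.therapy_confounded:
        # therapy probability rises with hazard -> adjusted and unadjusted
        # Cox fits are expected to differ
        p = 1.0 / (1.0 + np.exp(-(np.log(hazards / config.baseline_hazard))))
        chemo = (rng.random(len(sample_ids)) < p).astype(int)
        ritux = (rng.random(len(sample_ids)) < p).astype(int)
    else:
        chemo = rng.integers(0, 2, len(sample_ids))
        ritux = rng.integers(0, 2, len(sample_ids))

    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "class": [truth.sample_class[s] for s in sample_ids],
            "time": time,
            "status": status,
            "chemotherapy": chemo,
            "rituximab": ritux,
        }
    )


def export_gene_sets(
    truth: GroundTruth, n_decoys: int = 0, seed: int = 0
) -> dict[str, list[str]]:
    """Planted module gene sets plus size-matched random decoy sets.

    Decoys are sampled from the full gene universe recorded in the
    ground truth.  The result is GMT-serializable via
    :func:`lymphomap.enrichment.write_gmt`.
    """
    if n_decoys < 0:
        raise ConfigurationError("n_decoys must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    sets = {f"module_{m}": list(genes) for m, genes in truth.module_gene_map.items()}
    universe = list(truth.gene_ids) or sorted(
        {g for genes in truth.module_gene_map.values() for g in genes}
    )
    sizes = [len(g) for g in truth.module_gene_map.values()] or [20]
    for d in range(n_decoys):
        size = sizes[d % len(sizes)]
        members = rng.choice(universe, size=size, replace=False)
        sets[f"decoy_{d:03d}"] = sorted(members)
    return sets
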