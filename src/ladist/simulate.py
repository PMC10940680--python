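"""Synthetic longitudinal scRNA-seq data with a bifurcating trajectory.

The generator emulates a 7-cell-type differentiation tree: a stem type S
bifurcates into multipotent types A and B, which terminate in A1/A2 and
B1/B2. Each type has an ideal nonnegative expression profile over (by
default) 200 genes; intermediate states along an edge parent -> child use the
mixture profile theta*parent + (1-theta)*child with theta drawn uniformly
from the stage's interval. Seven samples are collected over four days with
compositions advancing along the tree (day 1 half stem / half early
transitional, through day 4 half late transitional / half terminal). Each
sample is a batch: a random shared subset of genes receives a different
additive shift per batch, per-cell Gaussian noise is added, means are clipped
at zero, and integer counts are drawn from a Poisson distribution. The true
per-batch shift vectors are stored so downstream recovery can be checked
against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = [
    "TrajectoryTopology",
    "StageComponent",
    "SampleSpec",
    "SimulatedDataset",
    "default_design",
    "make_ideal_profiles",
    "mixture_profile",
    "assign_transition_label",
    "generate",
]

TYPE_NAMES = ["S", "A", "B", "A1", "A2", "B1", "B2"]
EDGES = [("S", "A"), ("S", "B"), ("A", "A1"), ("A", "A2"), ("B", "B1"), ("B", "B2")]

#: theta interval for transitional stages; it doubles as the ambiguity band of
#: ``assign_transition_label`` so every transitional draw keeps its arrow label.
TRANSITION_THETA = (0.25, 0.75)


@dataclass
class TrajectoryTopology:
    """Differentiation tree plus the ideal expression profile of each type."""

    type_names: list[str]
    edges: list[tuple[str, str]]
    ideal_profiles: np.ndarray  # types x genes, nonnegative Poisson means

    def __post_init__(self) -> None:
        self.ideal_profiles = np.asarray(self.ideal_profiles, dtype=float)
        if self.ideal_profiles.shape[0] != len(self.type_names):
            raise InvalidParameterError("one profile row required per type")
        if np.any(self.ideal_profiles < 0):
            raise InvalidParameterError("ideal profiles must be nonnegative")
        children = [c for _, c in self.edges]
        if len(set(children)) != len(children):
            raise InvalidParameterError("every child type must have exactly one parent")

    @property
    def n_genes(self) -> int:
        return self.ideal_profiles.shape[1]

    def profile(self, type_name: str) -> np.ndarray:
        return self.ideal_profiles[self.type_names.index(type_name)]


@dataclass
class StageComponent:
    """One component of a sample's composition: either a pure type or a
    transitional stage along an edge with a theta interval."""

    fraction: float
    type_name: str | None = None
    edge: tuple[str, str] | None = None
    theta_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if (self.type_name is None) == (self.edge is None):
            raise InvalidParameterError("specify exactly one of type_name or edge")
        if self.edge is not None:
            lo, hi = self.theta_range if self.theta_range else TRANSITION_THETA
            if not (0.0 <= lo <= hi <= 1.0):
                raise InvalidParameterError(f"theta interval {self.theta_range} outside [0, 1]")
            self.theta_range = (lo, hi)


@dataclass
class SampleSpec:
    """Collection day and cell-state composition of one sample (= batch)."""

    day: int
    composition: list[StageComponent]
    n_cells: int = 300

    def __post_init__(self) -> None:
        total = sum(c.fraction for c in self.composition)
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError(f"composition fractions sum to {total}, not 1")
        if self.n_cells < 1:
            raise InvalidParameterError("n_cells must be positive")


def default_design(n_cells_per_sample: int = 300) -> list[SampleSpec]:
    """Seven samples over four days tracking the bifurcating trajectory.

    Day 1 (1 sample): half pure S, half early S->A / S->B transitional.
    Day 2 (2 samples): half S->A / S->B transitional, half pure A / B.
    Day 3 (2 samples): half pure A / B, half late transitional (A->A1, A->A2,
    B->B1, B->B2). Day 4 (2 samples): half late transitional, half terminal
    A1/A2/B1/B2. Branch and terminal assignments are split evenly within each
    half.
    """
    early = [StageComponent(0.25, edge=e) for e in EDGES[:2]]
    late = [StageComponent(0.125, edge=e) for e in EDGES[2:]]
    mid_pure = [StageComponent(0.25, type_name=t) for t in ("A", "B")]
    terminal = [StageComponent(0.125, type_name=t) for t in ("A1", "A2", "B1", "B2")]

    day1 = [StageComponent(0.5, type_name="S"), *early]
    day2 = [*early, *mid_pure]
    day3 = [*mid_pure, *late]
    day4 = [*late, *terminal]

    specs = []
    for day, comp, n_samples in ((1, day1, 1), (2, day2, 2), (3, day3, 2), (4, day4, 2)):
        for _ in range(n_samples):
            specs.append(SampleSpec(day=day, composition=list(comp), n_cells=n_cells_per_sample))
    return specs


def make_ideal_profiles(
    n_genes: int = 200,
    rng_seed: int = 0,
    expression_scale: float = 1.0,
) -> TrajectoryTopology:
    """Draw one ideal profile per type, children perturbed from parents.

    The stem profile is Gamma(shape=2, scale=2) * expression_scale per gene
    (mean ~4 counts). Each child multiplies its parent's profile by i.i.d.
    LogNormal(0, 0.5) factors, so profiles stay nonnegative and each child
    correlates more with its parent (and its parent's branch) than with the
    opposite branch.
    """
    if n_genes < 1:
        raise InvalidParameterError("n_genes must be >= 1")
    if not expression_scale > 0:
        raise InvalidParameterError("expression_scale must be > 0")
    rng = np.random.default_rng(rng_seed)
    profiles = {"S": expression_scale * rng.gamma(shape=2.0, scale=2.0, size=n_genes)}
    for parent, child in EDGES:
        profiles[child] = profiles[parent] * rng.lognormal(0.0, 0.5, size=n_genes)
    return TrajectoryTopology(
        type_names=list(TYPE_NAMES),
        edges=list(EDGES),
        ideal_profiles=np.array([profiles[t] for t in TYPE_NAMES]),
    )


def mixture_profile(parent_profile: np.ndarray, child_profile: np.ndarray, theta: float) -> np.ndarray:
    """Gradual-state profile theta*parent + (1-theta)*child."""
    if not 0.0 <= theta <= 1.0:
        raise InvalidParameterError(f"theta must be in [0, 1], got {theta}")
    parent = np.asarray(parent_profile, dtype=float)
    child = np.asarray(child_profile, dtype=float)
    return theta * parent + (1.0 - theta) * child


def assign_transition_label(
    edge: tuple[str, str],
    theta: float,
    ambiguity_band: tuple[float, float] = TRANSITION_THETA,
) -> str:
    """Label a mixture cell: the arrow label inside the ambiguity band around
    theta = 0.5, otherwise the nearer endpoint's type name."""
    if not 0.0 <= theta <= 1.0:
        raise InvalidParameterError(f"theta must be in [0, 1], got {theta}")
    parent, child = edge
    lo, hi = ambiguity_band
    if lo <= theta <= hi:
        return f"{parent} -> {child}"
    return parent if theta > 0.5 else child


@dataclass
class SimulatedDataset:
    """Counts with full per-cell and per-batch ground truth."""

    counts: np.ndarray  # cells x genes, nonnegative integers
    cell_ids: list[str]
    gene_ids: list[str]
    cell_type_label: np.ndarray
    theta: np.ndarray
    batch_id: np.ndarray
    day: np.ndarray
    batch_shift: dict  # batch id -> gene-length vector, zero off the affected set
    affected_genes: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def cells_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "batch": self.batch_id,
                "day": self.day,
                "cell_type": self.cell_type_label,
                "theta": self.theta,
            }
        )

    def genes_frame(self) -> pd.DataFrame:
        affected = np.zeros(self.n_genes, dtype=int)
        affected[self.affected_genes] = 1
        frame = pd.DataFrame({"gene_id": self.gene_ids, "affected": affected})
        for batch, shift in self.batch_shift.items():
            frame[f"shift_{batch}"] = shift
        return frame


def _draw_cell_stage(rng: np.random.Generator, spec: SampleSpec) -> StageComponent:
    fractions = np.array([c.fraction for c in spec.composition])
    return spec.composition[rng.choice(len(fractions), p=fractions / fractions.sum())]


def generate(
    design: list[SampleSpec] | None = None,
    topology: TrajectoryTopology | None = None,
    n_cells_per_sample: int | None = None,
    n_affected_genes: int = 40,
    batch_effect_sd: float = 3.0,
    noise_sd: float = 0.5,
    rng_seed: int = 0,
) -> SimulatedDataset:
    """Simulate the longitudinal multi-sample dataset.

    Per cell: draw a stage from the sample's composition, draw theta uniform
    in the stage's interval (pure types have theta = 1), form the mixture
    profile, add the batch's additive shift on the shared affected gene set,
    add N(0, noise_sd) per gene, clip at zero, and draw Poisson counts.
    Everything is reproducible from ``rng_seed``.

    Parameters
    ----------
    design
        Sample specs; defaults to :func:`default_design`.
    topology
        Trajectory and ideal profiles; defaults to
        ``make_ideal_profiles(rng_seed=rng_seed)``.
    n_cells_per_sample
        Overrides every spec's cell count when given.
    n_affected_genes, batch_effect_sd
        Size of the shared batch-affected gene set and the standard deviation
        of the i.i.d. normal per-batch additive components on it.
    noise_sd
        Per-cell, per-gene Gaussian noise on the Poisson mean.
    """
    if batch_effect_sd < 0 or noise_sd < 0:
        raise InvalidParameterError("batch_effect_sd and noise_sd must be >= 0")
    rng = np.random.default_rng(rng_seed)
    if topology is None:
        topology = make_ideal_profiles(rng_seed=rng_seed)
    if design is None:
        design = default_design()
    if n_cells_per_sample is not None:
        design = [
            SampleSpec(day=s.day, composition=s.composition, n_cells=n_cells_per_sample)
            for s in design
        ]
    n_genes = topology.n_genes
    if not 0 <= n_affected_genes <= n_genes:
        raise InvalidParameterError("n_affected_genes must be in [0, n_genes]")

    affected = np.sort(rng.choice(n_genes, size=n_affected_genes, replace=False))
    batch_ids = [f"sample{i + 1}" for i in range(len(design))]
    shifts = {}
    for b in batch_ids:
        vec = np.zeros(n_genes)
        vec[affected] = rng.normal(0.0, batch_effect_sd, size=n_affected_genes)
        shifts[b] = vec

    counts, labels, thetas, batches, days = [], [], [], [], []
    zero_mean_cells = 0
    for spec, batch in zip(design, batch_ids):
        shift = shifts[batch]
        for _ in range(spec.n_cells):
            comp = _draw_cell_stage(rng, spec)
            if comp.type_name is not None:
                theta = 1.0
                profile = topology.profile(comp.type_name)
                label = comp.type_name
            else:
                lo, hi = comp.theta_range
                theta = float(rng.uniform(lo, hi))
                parent, child = comp.edge
                profile = mixture_profile(
                    topology.profile(parent), topology.profile(child), theta
                )
                label = assign_transition_label(comp.edge, theta)
            mean = profile + shift + rng.normal(0.0, noise_sd, size=n_genes)
            np.clip(mean, 0.0, None, out=mean)
            if not mean.any():
                zero_mean_cells += 1
            counts.append(rng.poisson(mean))
            labels.append(label)
            thetas.append(theta)
            batches.append(batch)
            days.append(spec.day)
    if zero_mean_cells:
        warnings.warn(
            f"{zero_mean_cells} cells had an all-zero mean vector; kept with all-zero counts",
            UserWarning,
            stacklevel=2,
        )

    counts = np.asarray(counts, dtype=np.int64)
    return SimulatedDataset(
        counts=counts,
        cell_ids=[f"cell{i + 1}" for i in range(counts.shape[0])],
        gene_ids=[f"gene{j + 1}" for j in range(n_genes)],
        cell_type_label=np.asarray(labels, dtype=object),
        theta=np.asarray(thetas),
        batch_id=np.asarray(batches, dtype=object),
        day=np.asarray(days, dtype=int),
        batch_shift=shifts,
        affected_genes=affected,
        config={
            "n_samples": len(design),
            "n_genes": n_genes,
            "n_affected_genes": int(n_affected_genes),
            "batch_effect_sd": float(batch_effect_sd),
            "noise_sd": float(noise_sd),
            "rng_seed": int(rng_seed),
            "cells_per_sample": [s.n_cells for s in design],
        },
    )
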