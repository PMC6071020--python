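"""Simulation of two-class expression datasets with known DEP structure.

Each simulated dataset holds ``n_pathways`` pathways (half of them true
DEPs) over disjoint gene sets, with balanced two-class samples
(control vs. case, ``n_per_class`` each). Pathway topology is either a
ten-gene cascade (nine consecutive links) or a bundled 15-gene, 20-link
complex graph with branch and convergence points, mimicking a curated
signaling map such as the cell cycle.

The generative model: every gene has a *major* regulatory state per
class. In a non-DEP pathway (and for non-DEG genes of a DEP) the major
state is the same, uniformly drawn, in both classes; in a DEP, a
fraction ``rho`` of the genes are DEGs whose case-class major state is
redrawn to differ from the control one — DEPs therefore carry different
principal state patterns between classes.

``r`` is the probability of a pathway's dominant pattern and reflects
the variability of the cell system under a phenotype: in each sample,
with probability ``r`` a pathway exhibits its principal pattern (every
member gene in its major state), otherwise each gene falls to one of
its two minor states with equal probability. Either way a gene shows
its major state with marginal probability ``r`` and each minor state
with ``(1 - r) / 2``. Setting ``correlated=False`` switches to fully
independent per-gene state draws with the same marginals (a strictly
weaker, topology-free variant).

Continuous expression is emitted from the realized state: normal with
means 1/3/5 (sd 2, i.e. variance 4) for D/N/U when the state is the
gene's major state, and gamma with shapes 1/3/5 (scale 0.5) when it is
a minor state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np

from .discretize import ExpressionMatrix, StateMatrix
from .pathway_analysis import Pathway

__all__ = ["SimulationConfig", "SimulatedDataset", "make_cascade",
           "make_complex", "simulate_dataset", "write_dataset"]


@dataclass
class SimulationConfig:
    """Parameters of the simulation study.

    Defaults are the benchmark's standard conditions: balanced classes
    of 60 samples, 200 pathways (half DEP), 20 datasets per scenario.
    ``r`` must exceed 1/3 so the major state actually dominates.
    """

    structure: str = "cascade"
    n_per_class: int = 60
    n_pathways: int = 200
    r: float = 0.5
    rho: float = 0.5
    n_datasets: int = 20
    seed: int = 0
    correlated: bool = True
    normal_means: tuple[float, float, float] = (1.0, 3.0, 5.0)
    normal_sd: float = 2.0
    gamma_shapes: tuple[float, float, float] = (1.0, 3.0, 5.0)
    gamma_scale: float = 0.5
    complex_edges: list | None = None

    def __post_init__(self):
        if self.structure not in ("cascade", "complex"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if not (1 / 3 < self.r <= 1):
            raise ValueError(f"r must lie in (1/3, 1], got {self.r}")
        if not (0 < self.rho <= 1):
            raise ValueError(f"rho must lie in (0, 1], got {self.rho}")
        if self.n_per_class < 2 or self.n_pathways < 1:
            raise ValueError("need n_per_class >= 2 and n_pathways >= 1")


@dataclass
class SimulatedDataset:
    """A simulated dataset with its generating ground truth.

    ``dep_truth[i]`` flags pathway i as a true DEP; ``deg_truth[g]``
    flags gene row g as a true DEG (every DEG lies in a DEP).
    ``major_states`` is the (2, M) matrix of per-class generating major
    states underlying the data.
    """

    expression: ExpressionMatrix
    states: StateMatrix
    pathways: list[Pathway]
    dep_truth: np.ndarray
    deg_truth: np.ndarray
    major_states: np.ndarray
    config: SimulationConfig


def make_cascade(n_genes: int = 10, prefix: str = "g") -> Pathway:
    """Cascade pathway: ``n_genes`` genes chained by consecutive links."""
    genes = [f"{prefix}{i + 1:02d}" for i in range(n_genes)]
    return Pathway("cascade", list(zip(genes, genes[1:])))


def make_complex(edge_list: list | None = None) -> Pathway:
    """Complex pathway topology with branching and convergence.

    Without ``edge_list`` the bundled default is used: a 15-gene,
    20-link directed graph (shipped as ``data/complex_topology.sif`` so
    users can substitute their own curated topology). A supplied edge
    list must form a non-empty weakly connected directed graph.
    """
    if edge_list is None:
        text = (resources.files("dynsig") / "data" / "complex_topology.sif").read_text()
        edge_list = [(p[0], p[2]) for line in text.strip().splitlines()
                     if (p := line.split("\t"))]
    edge_list = [(s, t) for s, t in edge_list]
    if not edge_list:
        raise ValueError("empty edge list")
    graph = nx.DiGraph(edge_list)
    if graph.number_of_nodes() < 2 or not nx.is_weakly_connected(graph):
        raise ValueError("complex topology must be a weakly connected directed graph")
    return Pathway("complex", edge_list)


def _template(cfg: SimulationConfig) -> Pathway:
    if cfg.structure == "cascade":
        return make_cascade()
    return make_complex(cfg.complex_edges)


def simulate_dataset(cfg: SimulationConfig, rng=None) -> SimulatedDataset:
    """Draw one dataset under the configured scenario.

    All randomness comes from ``rng`` (or a generator seeded with
    ``cfg.seed``); the same seed reproduces the dataset bit for bit.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    template = _template(cfg)
    tpl_genes = sorted(template.genes)
    G = len(tpl_genes)
    tpl_index = {g: i for i, g in enumerate(tpl_genes)}
    n_dep = cfg.n_pathways // 2
    n_deg = int(round(cfg.rho * G))
    if n_deg < 1:
        warnings.warn(f"rho * genes-per-pathway = {cfg.rho * G:.2f} < 1; "
                      "enforcing one DEG per DEP")
        n_deg = 1

    M = cfg.n_pathways * G
    pathways: list[Pathway] = []
    gene_ids: list[str] = []
    dep_truth = np.zeros(cfg.n_pathways, dtype=bool)
    dep_truth[:n_dep] = True
    deg_truth = np.zeros(M, dtype=bool)
    majors = np.empty((2, M), dtype=np.int8)   # per-class major states

    width = len(str(cfg.n_pathways))
    for p in range(cfg.n_pathways):
        name = f"P{p + 1:0{width}d}"
        rename = {g: f"{name}_{g}" for g in tpl_genes}
        pathways.append(Pathway(name, [(rename[s], rename[t])
                                       for s, t in template.links]))
        gene_ids.extend(rename[g] for g in tpl_genes)
        base = rng.integers(0, 3, size=G)
        majors[0, p * G:(p + 1) * G] = base
        majors[1, p * G:(p + 1) * G] = base
        if dep_truth[p]:
            deg_pos = rng.choice(G, size=n_deg, replace=False)
            # case-class major state redrawn among the two other states
            shift = rng.integers(1, 3, size=n_deg)
            majors[1, p * G + deg_pos] = (base[deg_pos] + shift) % 3
            deg_truth[p * G + deg_pos] = True

    n = cfg.n_per_class
    N = 2 * n
    labels = np.array(["control"] * n + ["case"] * n, dtype=object)
    sample_ids = [f"control_{i + 1:03d}" for i in range(n)] + \
                 [f"case_{i + 1:03d}" for i in range(n)]

    states = np.empty((M, N), dtype=np.int8)
    values = np.empty((M, N), dtype=float)
    means = np.asarray(cfg.normal_means)
    shapes = np.asarray(cfg.gamma_shapes)
    for c, cols in enumerate((slice(0, n), slice(n, N))):
        major = majors[c][:, None]                       # (M, 1)
        # the two minor states, in ascending state order
        minor_a = np.where(major == 0, 1, 0)
        minor_b = np.where(major == 2, 1, 2)
        if cfg.correlated:
            # pattern switch per (pathway, sample); off-pattern genes
            # fall independently to one of their two minors
            on = np.repeat(rng.random((cfg.n_pathways, n)) < cfg.r, G, axis=0)
            pick = rng.random((M, n)) < 0.5
            s = np.where(on, major, np.where(pick, minor_a, minor_b))
        else:
            u = rng.random((M, n))
            s = np.where(u < cfg.r, major,
                         np.where(u < cfg.r + (1 - cfg.r) / 2, minor_a, minor_b))
        is_major = s == major
        v = rng.normal(means[s], cfg.normal_sd)
        v_minor = rng.gamma(shapes[s], cfg.gamma_scale)
        values[:, cols] = np.where(is_major, v, v_minor)
        states[:, cols] = s

    expr = ExpressionMatrix(values, gene_ids, sample_ids, labels)
    smat = StateMatrix(states, gene_ids, sample_ids, labels)
    return SimulatedDataset(expression=expr, states=smat, pathways=pathways,
                            dep_truth=dep_truth, deg_truth=deg_truth,
                            major_states=majors, config=cfg)


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write a simulated dataset as plain TSV files.

    Emits ``expression.tsv``, ``labels.tsv``, ``states.tsv`` (in the
    -1/0/1 encoding), ``pathways.tsv`` (pathway, source, target) and the
    two ground-truth tables."""
    from . import io as dio  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dio.write_expression(ds.expression, outdir / "expression.tsv")
    dio.write_labels(ds.expression.sample_ids, ds.expression.labels,
                     outdir / "labels.tsv")
    dio.write_state_matrix(ds.states, outdir / "states.tsv")
    with open(outdir / "pathways.tsv", "w") as fh:
        fh.write("pathway\tsource\ttarget\n")
        for pw in ds.pathways:
            for s, t in pw.links:
                fh.write(f"{pw.name}\t{s}\t{t}\n")
    with open(outdir / "truth_pathways.tsv", "w") as fh:
        fh.write("pathway\tis_dep\n")
        for pw, flag in zip(ds.pathways, ds.dep_truth):
            fh.write(f"{pw.name}\t{int(flag)}\n")
    with open(outdir / "truth_genes.tsv", "w") as fh:
        fh.write("gene\tis_deg\tmajor_control\tmajor_case\n")
        names = ("D", "N", "U")
        for i, g in enumerate(ds.expression.gene_ids):
            fh.write(f"{g}\t{int(ds.deg_truth[i])}\t"
                     f"{names[ds.major_states[0, i]]}\t"
                     f"{names[ds.major_states[1, i]]}\n")
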