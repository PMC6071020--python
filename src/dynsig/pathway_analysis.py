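"""Pathway-level differential expression from link classification power.

A pathway is a named set of directed gene links. Its differential
expression between two sample classes is summarized by the DEP
statistic — the mean LOOCV classification accuracy of its links — and
assessed against a permutation null: random pathways built from the
same genes with the same number of links, scored under shuffled class
labels. The permutation p-value is the fraction of random pathways
whose DEP strictly exceeds the observed one; q-values come from
Benjamini–Hochberg step-up adjustment.

Randomness is controlled per pathway by a seed derived from the run seed
and a stable hash of the pathway name, so p-values do not depend on the
order in which pathways are supplied.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from statsmodels.stats.multitest import multipletests

from .discretize import ExpressionMatrix, StateMatrix, discretize_matrix
from .mcmlink import LinkScoreTable, link_permutation_pvalue, loocv_scores

__all__ = [
    "Pathway",
    "PathwayResult",
    "RunConfig",
    "dep_score",
    "random_pathway_pvalue",
    "adjust_qvalues",
    "run_dynsig",
]


@dataclass
class Pathway:
    """A named, ordered collection of directed gene links.

    Self-links are dropped and duplicate directed links collapsed at
    construction; the member gene set is derived from the links.
    """

    name: str
    links: list[tuple]

    def __post_init__(self):
        seen = set()
        cleaned = []
        for link in self.links:
            src, dst = link[0], link[1]
            if src == dst:
                continue
            if (src, dst) in seen:
                continue
            seen.add((src, dst))
            cleaned.append((src, dst))
        if not cleaned:
            raise ValueError(f"pathway {self.name!r} has no valid (non-self) links")
        self.links = cleaned

    @property
    def L(self) -> int:
        return len(self.links)

    @property
    def genes(self) -> set:
        out = set()
        for s, t in self.links:
            out.add(s)
            out.add(t)
        return out

    def restrict_to(self, states: StateMatrix) -> "Pathway | None":
        """Pathway reduced to links whose genes are both present in the
        data; None if no link survives."""
        links = [(s, t) for s, t in self.links if s in states and t in states]
        if not links:
            return None
        return Pathway(self.name, links)


@dataclass
class PathwayResult:
    """Result of scoring one pathway: DEP statistic, permutation
    p-value, adjusted q-value, and the underlying link scores."""

    name: str
    n_links: int
    dep: float
    p: float
    q: float | None = None
    link_scores: LinkScoreTable | None = None


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Attributes
    ----------
    discretizer : {'zscore', 'fixed', 'quantile'}
        Rule mapping continuous expression to D/N/U states.
    k, thresholds, quantiles : discretizer parameters.
    Z : number of random pathways per permutation null (1000 default).
    gene_pool, shuffle_labels : null-distribution design (see
        :func:`random_pathway_pvalue`).
    B : per-link label permutations; 0 skips per-link p-values.
    alpha : Laplace pseudocount for TPM rows (0 = literal frequencies).
    smoothed : use the (1 + hits) / (1 + B) permutation estimator.
    p_cutoff, q_cutoff : reporting cutoffs (exposed, not hard-coded).
    seed : master seed for all resampling.
    """

    discretizer: str = "zscore"
    k: float = 1.0
    thresholds: tuple[float, float] = (2.0, 4.0)
    quantiles: tuple[float, float] = (0.25, 0.75)
    Z: int = 1000
    gene_pool: str = "pathway"
    shuffle_labels: bool = True
    B: int = 0
    alpha: float = 0.0
    smoothed: bool = False
    p_cutoff: float = 0.05
    q_cutoff: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.Z < 1:
            raise ValueError("Z must be >= 1")
        if not (0 < self.p_cutoff < 1 and 0 < self.q_cutoff < 1):
            raise ValueError("cutoffs must lie in (0, 1)")

    def discretizer_kwargs(self) -> dict:
        return {"zscore": {"k": self.k},
                "fixed": {"thresholds": self.thresholds},
                "quantile": {"quantiles": self.quantiles}}.get(self.discretizer, {})


def dep_score(d) -> float:
    """DEP statistic: mean link classification power of a pathway."""
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("dep_score requires at least one link accuracy")
    return float(d.mean())


def _pathway_rng(seed: int, name: str) -> np.random.Generator:
    """Generator keyed by (run seed, pathway name): p-values become
    invariant to pathway input order."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def _sample_pair_ids(rng, n_genes: int, L: int, Z: int) -> np.ndarray:
    """Z draws of L distinct ordered non-self pairs, as ids in
    [0, n_genes*(n_genes-1))."""
    n_pairs = n_genes * (n_genes - 1)
    if n_pairs <= 4096:
        # argsort of uniforms = uniform sample without replacement
        return np.argsort(rng.random((Z, n_pairs)), axis=1)[:, :L]
    out = np.empty((Z, L), dtype=np.intp)
    for z in range(Z):
        out[z] = rng.choice(n_pairs, size=L, replace=False)
    return out


def _ids_to_pairs(ids: np.ndarray, n_genes: int) -> np.ndarray:
    """Map pair ids to (i, j) index pairs with i != j."""
    i = ids // (n_genes - 1)
    j = ids % (n_genes - 1)
    j = j + (j >= i)
    return np.stack([i, j], axis=-1)


def _links_to_rows(links, states: StateMatrix) -> np.ndarray:
    return np.asarray([[states.gene_row(s), states.gene_row(t)] for s, t in links],
                      dtype=np.intp)


def _sample_gene_sets(rng, n_pool: int, g: int, Z: int) -> np.ndarray:
    """Z draws of g distinct gene indices from a pool of n_pool."""
    if g > n_pool:
        raise ValueError(f"cannot draw {g} distinct genes from {n_pool}")
    if n_pool <= 4 * g:
        return np.argsort(rng.random((Z, n_pool)), axis=1)[:, :g]
    out = rng.integers(0, n_pool, size=(Z, g))
    while True:  # redraw the (rare) rows with duplicate genes
        bad = np.array([len(set(row)) < g for row in out])
        if not bad.any():
            return out
        out[bad] = rng.integers(0, n_pool, size=(int(bad.sum()), g))


def _loocv_d_batched(states: np.ndarray, src: np.ndarray, dst: np.ndarray,
                     masks: np.ndarray, n1: int, *, alpha: float = 0.0
                     ) -> np.ndarray:
    """LOOCV accuracies for a (Z, L) batch of links, each draw z scored
    under its own class-1 mask ``masks[z]``. Returns d of shape (Z, L).

    Same count identity as :func:`dynsig.mcmlink.loocv_scores`, with a
    leading draw dimension so a whole permutation null is scored in one
    vectorized pass.
    """
    Z, L = src.shape
    N = masks.shape[1]
    n2 = N - n1
    q = 3 * states[src].astype(np.int16) + states[dst]        # (Z, L, N)
    m1 = masks[:, None, :]
    C1 = np.zeros((Z, L, 9))
    C2 = np.zeros((Z, L, 9))
    for k in range(9):
        eq = q == k
        C1[..., k] = (eq & m1).sum(-1)
        C2[..., k] = (eq & ~m1).sum(-1)
    R1 = C1.reshape(Z, L, 3, 3).sum(-1)
    R2 = C2.reshape(Z, L, 3, 3).sum(-1)
    x = q // 3

    def _lik(C, R, n, held_out):
        cnt = np.take_along_axis(C, q, axis=2)
        nx = np.take_along_axis(R, x, axis=2)
        if held_out:
            cnt = cnt - 1
            nx = nx - 1
            n = n - 1
        if alpha > 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                lik = (nx / n) * (cnt + alpha) / (nx + 3 * alpha)
            return np.where(nx > 0, lik, 0.0)
        return np.where(nx > 0, cnt / n, 0.0)

    a1 = _lik(C1, R1, n1, True) > _lik(C2, R2, n2, False)
    a2 = _lik(C2, R2, n2, True) > _lik(C1, R1, n1, False)
    a = np.where(m1, a1, a2)
    return a.mean(-1)


def random_pathway_pvalue(pathway: Pathway, states: StateMatrix,
                          Z: int = 1000, rng=None, *,
                          gene_pool: str = "pathway",
                          shuffle_labels: bool = True,
                          smoothed: bool = False, alpha: float = 0.0) -> float:
    """Permutation p-value of a pathway's DEP statistic.

    ``Z`` random pathways are drawn, each with the pathway's genes
    (those present in the data) and its number of links L: L distinct
    directed non-self links sampled uniformly. Each random pathway is
    scored with the full LOOCV link permutation pipeline — by default
    under a fresh random shuffle of the class labels, which makes the
    null distribution class-signal-free — and ``p`` is the fraction of
    random pathways whose DEP strictly exceeds the observed DEP.

    Options cover the design space of the null:

    - ``gene_pool='pathway'`` (default) keeps the pathway's own genes;
      ``'genome'`` draws each random pathway's gene set uniformly from
      all genes in the data.
    - ``shuffle_labels=True`` (default) rescores each random pathway
      under a permuted label vector, so the null asks whether the
      observed links separate the *observed* classes better than
      same-shaped pathways separate random classes. With ``False`` the
      observed labels are kept and only the wiring (and optionally the
      genes) is randomized; in data whose class signal is spread over
      many genes this null retains that signal and loses power.
    """
    if Z < 1:
        raise ValueError("Z must be >= 1")
    if gene_pool not in ("genome", "pathway"):
        raise ValueError(f"unknown gene_pool {gene_pool!r}")
    rng = np.random.default_rng(rng)
    present = pathway.restrict_to(states)
    if present is None:
        raise ValueError(f"pathway {pathway.name!r} has no link present in the data")
    genes = sorted(present.genes)
    g = len(genes)
    L = present.L
    max_links = g * (g - 1)
    if L > max_links:
        warnings.warn(f"pathway {pathway.name!r}: gene set supports only "
                      f"{max_links} distinct links; reducing L from {L}")
        L = max_links
    mask1 = states.class_mask(states.classes[0])
    n1 = int(mask1.sum())

    obs_rows = _links_to_rows(present.links, states)
    _, d_obs = loocv_scores(states.states, obs_rows, mask1, alpha=alpha)
    dep_obs = dep_score(d_obs)

    if gene_pool == "genome":
        gene_sets = _sample_gene_sets(rng, states.n_genes, g, Z)   # (Z, g)
    else:
        rows = np.asarray([states.gene_row(x) for x in genes], dtype=np.intp)
        gene_sets = np.broadcast_to(rows, (Z, g))
    ids = _sample_pair_ids(rng, g, L, Z)                           # (Z, L)
    pairs = _ids_to_pairs(ids, g)                                  # (Z, L, 2)
    src = np.take_along_axis(gene_sets, pairs[..., 0], axis=1)
    dst = np.take_along_axis(gene_sets, pairs[..., 1], axis=1)

    if shuffle_labels:
        masks = np.stack([rng.permutation(mask1) for _ in range(Z)])
        r_dep = _loocv_d_batched(states.states, src, dst, masks,
                                 n1, alpha=alpha).mean(axis=1)
    else:
        flat = np.stack([src.ravel(), dst.ravel()], axis=1)
        uniq, inv = np.unique(flat, axis=0, return_inverse=True)
        _, d_uniq = loocv_scores(states.states, uniq, mask1, alpha=alpha)
        r_dep = d_uniq[inv.reshape(Z, L)].mean(axis=1)
    hits = int((dep_obs < r_dep).sum())
    if smoothed:
        return (1 + hits) / (1 + Z)
    return hits / Z


def adjust_qvalues(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def run_dynsig(data: ExpressionMatrix | StateMatrix, pathways: list[Pathway],
               config: RunConfig | None = None) -> list[PathwayResult]:
    """Run the full pipeline on a dataset and a pathway collection.

    Continuous input is discretized per the configuration (a supplied
    :class:`StateMatrix` is used as-is). Each pathway is restricted to
    links with both genes present; pathways with fewer than two present
    links are dropped. For the rest: per-link LOOCV accuracies, the DEP
    statistic, a random-pathway permutation p-value (and per-link
    permutation p-values when ``config.B > 0``), then BH q-values.
    Results are sorted by (p, name).
    """
    config = config or RunConfig()
    if isinstance(data, StateMatrix):
        states = data
    else:
        states = discretize_matrix(data, config.discretizer,
                                   **config.discretizer_kwargs())
    mask1 = states.class_mask(states.classes[0])
    if mask1.sum() < 2 or (~mask1).sum() < 2:
        raise ValueError("each class needs >= 2 samples")
    if not pathways:
        raise ValueError("at least one pathway is required")

    results: list[PathwayResult] = []
    for pw in pathways:
        present = pw.restrict_to(states)
        if present is None or present.L <= 1:
            warnings.warn(f"pathway {pw.name!r} dropped: "
                          f"{0 if present is None else present.L} link(s) present")
            continue
        rows = _links_to_rows(present.links, states)
        a, d = loocv_scores(states.states, rows, mask1, alpha=config.alpha)
        rng = _pathway_rng(config.seed, pw.name)
        p = random_pathway_pvalue(present, states, Z=config.Z, rng=rng,
                                  gene_pool=config.gene_pool,
                                  shuffle_labels=config.shuffle_labels,
                                  smoothed=config.smoothed, alpha=config.alpha)
        p_link = None
        if config.B > 0:
            p_link = np.array([
                link_permutation_pvalue(states.states[r0], states.states[r1],
                                        states.labels, B=config.B, rng=rng,
                                        smoothed=config.smoothed, alpha=config.alpha)
                for r0, r1 in rows])
        table = LinkScoreTable(links=present.links, a=a, d=d, p_link=p_link,
                               sample_ids=states.sample_ids)
        results.append(PathwayResult(name=pw.name, n_links=present.L,
                                     dep=dep_score(d), p=p, link_scores=table))
    if not results:
        warnings.warn("no pathway survived the presence filter")
        return []
    qs = adjust_qvalues([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    results.sort(key=lambda r: (r.p, r.name))
    return results
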