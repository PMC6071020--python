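"""Markov chain models of single gene links and their LOOCV scoring.

A directed gene link ``g1 -> g2`` is modeled, per sample class, as a
two-node Markov chain over the regulatory states (D, N, U): an initial
distribution ``P0`` for the source gene (state frequencies in the
training samples) and a 3x3 transition probability matrix ``M`` whose
entry ``m[i, j]`` is the conditional frequency of the destination gene
being in state ``j`` given the source gene in state ``i``. The joint
likelihood of an observed state pair ``(x, y)`` is ``P0(x) * m[x, y]``.

A link's ability to separate two sample classes ("classification power")
is measured by leave-one-out cross-validation: each sample is classified
to the class whose link model gives the larger joint likelihood, fitted
with that sample held out of its own class. The per-link accuracy ``d``
is the fraction of correctly classified samples; significance can be
attached by shuffling class labels.

Row-normalization convention: a source state never observed in training
yields an all-zero TPM row (0/0 := 0), so unseen observations get zero
likelihood. An optional Laplace pseudocount ``alpha`` smooths TPM rows;
``P0`` is never smoothed. Ties in likelihood (including 0 vs 0) count as
incorrect classifications — a deterministic, seed-free rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discretize import STATES, as_state_codes

__all__ = [
    "MCMLinkModel",
    "LinkScoreTable",
    "fit_mcmlink",
    "link_likelihood",
    "classify_sample",
    "loocv_link_score",
    "loocv_scores",
    "link_permutation_pvalue",
]


@dataclass(frozen=True)
class MCMLinkModel:
    """Per-class Markov chain model of one gene link.

    Attributes
    ----------
    P0 : (3,) array
        Initial state distribution of the source gene over (D, N, U).
    M : (3, 3) array
        Transition probability matrix; each row sums to 1 or is all zero
        (source state unobserved in training).
    n_train : int
        Number of training samples the model was fitted on.
    link : optional (source, destination) gene identifier pair.
    """

    P0: np.ndarray
    M: np.ndarray
    n_train: int
    link: tuple | None = None

    def __post_init__(self):
        P0 = np.asarray(self.P0, dtype=float)
        M = np.asarray(self.M, dtype=float)
        object.__setattr__(self, "P0", P0)
        object.__setattr__(self, "M", M)
        if P0.shape != (3,) or M.shape != (3, 3):
            raise ValueError("P0 must be a 3-vector and M a 3x3 matrix")
        if (P0 < 0).any() or (M < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(P0.sum() - 1.0) > 1e-9:
            raise ValueError("P0 must sum to 1")
        rows = M.sum(axis=1)
        if not np.all((np.abs(rows - 1.0) <= 1e-9) | (rows == 0.0)):
            raise ValueError("each TPM row must sum to 1 or be all zero")
        if self.n_train < 1:
            raise ValueError("n_train must be >= 1")

    @property
    def joint(self) -> np.ndarray:
        """Joint state-pair probabilities ``P0[i] * M[i, j]`` (3x3)."""
        return self.P0[:, None] * self.M


def _pair_counts(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """3x3 matrix of observed (source, destination) state-pair counts."""
    counts = np.zeros((3, 3), dtype=float)
    np.add.at(counts, (c1, c2), 1.0)
    return counts


def fit_mcmlink(states_g1, states_g2, *, alpha: float = 0.0,
                link: tuple | None = None) -> MCMLinkModel:
    """Fit a link model from paired source/destination state vectors.

    ``P0`` is the empirical source-state frequency; TPM rows are
    conditional destination-state frequencies. With ``alpha > 0`` every
    transition count gets a Laplace pseudocount (unseen source states
    then get uniform rows, but still zero likelihood via ``P0``).
    """
    c1 = as_state_codes(states_g1)
    c2 = as_state_codes(states_g2)
    if c1.shape != c2.shape or c1.ndim != 1:
        raise ValueError("state vectors must be 1-D and of equal length")
    n = c1.size
    if n < 1:
        raise ValueError("at least one training sample is required")
    counts = _pair_counts(c1, c2)
    row_tot = counts.sum(axis=1)
    P0 = row_tot / n
    M = np.zeros((3, 3))
    if alpha > 0:
        M = (counts + alpha) / (row_tot[:, None] + 3 * alpha)
    else:
        seen = row_tot > 0
        M[seen] = counts[seen] / row_tot[seen, None]
    return MCMLinkModel(P0=P0, M=M, n_train=n, link=link)


def link_likelihood(model: MCMLinkModel, obs) -> float:
    """Joint likelihood ``P0(x) * M[x, y]`` of an observed state pair."""
    x, y = as_state_codes(list(obs))
    return float(model.P0[x] * model.M[x, y])


def classify_sample(model_c1: MCMLinkModel, model_c2: MCMLinkModel, obs,
                    labels: tuple = ("class1", "class2")):
    """Assign an observed state pair to the class with the strictly
    larger joint likelihood; equal likelihoods (including 0 = 0) give
    ``'tie'``."""
    l1 = link_likelihood(model_c1, obs)
    l2 = link_likelihood(model_c2, obs)
    if l1 > l2:
        return labels[0]
    if l2 > l1:
        return labels[1]
    return "tie"


def _class_masks(labels) -> tuple[np.ndarray, np.ndarray, tuple]:
    labels = np.asarray(labels, dtype=object)
    classes: dict = {}
    for v in labels:
        classes.setdefault(v, None)
    classes = tuple(classes)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    mask1 = labels == classes[0]
    return mask1, ~mask1, classes


def loocv_link_score(states_g1, states_g2, labels, *, alpha: float = 0.0
                     ) -> tuple[np.ndarray, float]:
    """Leave-one-out accuracy of one link over all samples.

    For each sample, both class models are fitted with the sample removed
    from its own class's training set (the other class stays complete),
    and the sample is classified by larger joint likelihood. Returns the
    per-sample correctness vector ``a`` (ties count 0) and its mean ``d``.

    This is the per-sample reference implementation; :func:`loocv_scores`
    computes the same quantity vectorized over many links.
    """
    c1 = as_state_codes(states_g1)
    c2 = as_state_codes(states_g2)
    if c1.shape != c2.shape or c1.ndim != 1:
        raise ValueError("state vectors must be 1-D and of equal length")
    mask1, mask2, classes = _class_masks(labels)
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValueError("each class needs >= 2 samples for leave-one-out scoring")
    labels = np.asarray(labels, dtype=object)
    n = c1.size
    a = np.zeros(n, dtype=np.uint8)
    for t in range(n):
        own = labels == labels[t]
        train_own = own.copy()
        train_own[t] = False
        other = ~own
        m_own = fit_mcmlink(c1[train_own], c2[train_own], alpha=alpha)
        m_oth = fit_mcmlink(c1[other], c2[other], alpha=alpha)
        obs = (c1[t], c2[t])
        pred = classify_sample(m_own, m_oth, obs, labels=("own", "other"))
        a[t] = 1 if pred == "own" else 0
    return a, float(a.mean())


def loocv_scores(states: np.ndarray, links: np.ndarray, class1_mask: np.ndarray,
                 *, alpha: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized LOOCV over many links at once.

    Parameters
    ----------
    states : (M, N) int8 array of state codes.
    links : (L, 2) int array of (source, destination) gene row indices.
    class1_mask : (N,) boolean mask of class-1 samples.

    Returns
    -------
    a : (N, L) uint8 correctness matrix; d : (L,) accuracy vector.

    Notes
    -----
    Relies on the identity ``P0(x) * M[x, y] = C[x, y] / n_train`` (with
    the 0/0 := 0 row convention), where ``C`` is the 3x3 state-pair count
    matrix — the held-out sample's own-class likelihood is
    ``(C_own[x, y] - 1) / (n_own - 1)`` and the other class's is
    ``C_other[x, y] / n_other``. With ``alpha > 0`` the smoothed form
    ``(n_x / n) * (C + alpha) / (n_x + 3 alpha)`` is used.
    """
    links = np.asarray(links, dtype=np.intp).reshape(-1, 2)
    L = links.shape[0]
    class1_mask = np.asarray(class1_mask, dtype=bool)
    N = class1_mask.size
    n1 = int(class1_mask.sum())
    n2 = N - n1
    if n1 < 2 or n2 < 2:
        raise ValueError("each class needs >= 2 samples for leave-one-out scoring")
    s1 = states[links[:, 0]]
    s2 = states[links[:, 1]]
    q = (3 * s1.astype(np.int16) + s2)          # pair code 0..8, (L, N)
    a = np.empty((N, L), dtype=np.uint8)
    masks = (class1_mask, ~class1_mask)
    # pair-count and source-count tables per class
    C = []
    R = []
    for mask in masks:
        qc = q[:, mask]
        Cc = np.empty((L, 9))
        for k in range(9):
            Cc[:, k] = (qc == k).sum(axis=1)
        C.append(Cc)
        R.append(Cc.reshape(L, 3, 3).sum(axis=2))  # source-state counts (L, 3)

    def _lik(Cc, Rc, n, q_at, x_at, held_out):
        """Joint likelihood of each (link, sample) pair under one class."""
        cnt = np.take_along_axis(Cc, q_at, axis=1)
        nx = np.take_along_axis(Rc, x_at, axis=1)
        if held_out:
            cnt = cnt - 1
            nx = nx - 1
            n = n - 1
        if alpha > 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                lik = (nx / n) * (cnt + alpha) / (nx + 3 * alpha)
            return np.where(nx > 0, lik, 0.0)
        return np.where(nx > 0, cnt / n, 0.0)

    for mask, (Cown, Rown), (Coth, Roth), n_own, n_oth in (
            (masks[0], (C[0], R[0]), (C[1], R[1]), n1, n2),
            (masks[1], (C[1], R[1]), (C[0], R[0]), n2, n1)):
        q_at = q[:, mask]
        x_at = s1[:, mask].astype(np.intp)
        own = _lik(Cown, Rown, n_own, q_at, x_at, held_out=True)
        oth = _lik(Coth, Roth, n_oth, q_at, x_at, held_out=False)
        a[mask] = (own > oth).T
    d = a.mean(axis=0)
    return a, d


def link_permutation_pvalue(states_g1, states_g2, labels, B: int = 1000,
                            rng=None, *, smoothed: bool = False,
                            alpha: float = 0.0) -> float:
    """Permutation p-value for a link's LOOCV accuracy.

    Class labels are shuffled ``B`` times; each shuffle is rescored and
    ``p`` is the fraction of shuffled accuracies strictly exceeding the
    observed one. The literal estimator permits ``p = 0``; with
    ``smoothed=True`` the positively biased ``(1 + hits) / (1 + B)``
    variant is returned instead (preferable for downstream FDR control).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(rng)
    c1 = as_state_codes(states_g1)
    c2 = as_state_codes(states_g2)
    mask1, _, _ = _class_masks(labels)
    states = np.stack([c1, c2])
    link = np.array([[0, 1]])
    _, d_obs = loocv_scores(states, link, mask1, alpha=alpha)
    d_obs = d_obs[0]
    hits = 0
    for _ in range(B):
        _, rd = loocv_scores(states, link, rng.permutation(mask1), alpha=alpha)
        if d_obs < rd[0]:
            hits += 1
    if smoothed:
        return (1 + hits) / (1 + B)
    return hits / B


@dataclass
class LinkScoreTable:
    """LOOCV scoring results for the links of one pathway.

    Attributes
    ----------
    links : list of (source, destination) gene pairs.
    a : (N, L) binary matrix; ``a[i, j] = 1`` iff sample i was correctly
        classified by link j.
    d : (L,) per-link accuracy (column means of ``a``).
    p_link : optional (L,) per-link permutation p-values.
    sample_ids : optional sample identifiers for the rows of ``a``.
    """

    links: list[tuple]
    a: np.ndarray
    d: np.ndarray
    p_link: np.ndarray | None = None
    sample_ids: list | None = None

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=np.uint8)
        self.d = np.asarray(self.d, dtype=float)
        L = len(self.links)
        if self.a.shape[1] != L or self.d.shape != (L,):
            raise ValueError("links, a and d have inconsistent shapes")
        if not np.allclose(self.d, self.a.mean(axis=0)):
            raise ValueError("d must equal the column means of a")
        if self.p_link is not None:
            self.p_link = np.asarray(self.p_link, dtype=float)
            if self.p_link.shape != (L,) or ((self.p_link < 0) | (self.p_link > 1)).any():
                raise ValueError("p_link must be L probabilities in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: one row per link, one column per sample."""
        cols = {"link_source": [l[0] for l in self.links],
                "link_target": [l[1] for l in self.links],
                "d": self.d}
        if self.p_link is not None:
            cols["p_link"] = self.p_link
        df = pd.DataFrame(cols)
        ids = self.sample_ids or [f"s{i+1}" for i in range(self.a.shape[0])]
        for i, sid in enumerate(ids):
            df[sid] = self.a[i]
        return df
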