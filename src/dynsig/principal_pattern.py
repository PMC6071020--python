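"""Class-specific principal signaling patterns along gene chains.

A cascade chain ``g1 -> g2 -> ... -> gk`` carries signaling whose
dominant behavior in one sample class can be summarized as a single
state sequence: the principal pattern. Each link is modeled separately
(per class), and the pattern is assembled backward from the ending link,
which is usually the biologically decisive one:

1. ending link — choose the transition mode ``(i, j)`` with the largest
   probability among the nine; this fixes the last two genes' states;
2. each earlier link — with the destination gene's principal state
   ``k*`` already fixed, choose the source state with the largest
   transition probability into ``k*``.

Two readings of "largest probability" are supported. The default,
``mode='joint'``, maximizes the joint mode probability
(``P0(i) * m[i, j]`` for the ending link; the observed transition
counts into ``k*`` for backward steps, i.e. the source state most
probable conditioned on the destination being ``k*``).
``mode='conditional'`` maximizes raw conditional TPM entries instead
(``m[i, j]`` over the nine modes, then the column ``m[:, k*]``); it
ignores how often each source state occurs, so a source state observed
in only a handful of training samples can tie or beat the dominant one
on a noisy small-denominator estimate — the joint rule weighs rows by
their support and avoids this. Ties are broken by the fixed state
order D < N < U.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .discretize import STATES, StateMatrix
from .mcmlink import MCMLinkModel, fit_mcmlink

__all__ = ["GeneChain", "PrincipalPattern", "principal_pattern",
           "pattern_from_models"]


@dataclass
class GeneChain:
    """An ordered gene chain ``g1 -> g2 -> ... -> gk`` (k >= 2) with the
    implied consecutive links."""

    genes: list

    def __post_init__(self):
        self.genes = list(self.genes)
        if len(self.genes) < 2:
            raise ValueError("a gene chain needs at least two genes")
        for a, b in zip(self.genes, self.genes[1:]):
            if a == b:
                raise ValueError(f"consecutive chain genes must differ, got {a!r} twice")

    @property
    def links(self) -> list[tuple]:
        return list(zip(self.genes, self.genes[1:]))


@dataclass
class PrincipalPattern:
    """Principal state sequence along a chain for one class.

    ``states`` holds one of 'D'/'N'/'U' per chain gene, or ``None``
    where the pattern is undefined (no training sample reaches the
    required downstream state)."""

    genes: list
    states: list
    class_label: object

    def __post_init__(self):
        if len(self.states) != len(self.genes):
            raise ValueError("pattern length must equal chain length")

    def __str__(self) -> str:
        return " -> ".join(s if s is not None else "?" for s in self.states)


def _argmax_cell(mat: np.ndarray) -> tuple[int, int]:
    """Argmax over a 3x3 matrix; flat (row-major) tie-break realizes the
    fixed D < N < U state order, source state first."""
    flat = int(np.argmax(mat))
    return flat // 3, flat % 3


def pattern_from_models(models: list[MCMLinkModel], mode: str = "joint"
                        ) -> list:
    """Assemble a principal pattern from per-link models (first model =
    first link of the chain). Returns k state codes, ``None`` where
    undefined."""
    if mode not in ("joint", "conditional"):
        raise ValueError(f"unknown mode {mode!r}; expected 'joint' or 'conditional'")
    k = len(models) + 1
    pattern: list = [None] * k
    end = models[-1]
    cell = end.joint if mode == "joint" else end.M
    i, j = _argmax_cell(cell)
    pattern[-2], pattern[-1] = i, j
    for t in range(len(models) - 2, -1, -1):
        model = models[t]
        k_star = pattern[t + 1]
        col = (model.joint if mode == "joint" else model.M)[:, k_star]
        if not col.any():
            warnings.warn("no training sample reaches the required state "
                          f"{STATES[k_star]} at chain position {t + 2}; "
                          "pattern undefined upstream of it")
            break
        pattern[t] = int(np.argmax(col))
    return pattern


def principal_pattern(chain: GeneChain, states: StateMatrix, class_label,
                      *, mode: str = "joint", alpha: float = 0.0
                      ) -> PrincipalPattern:
    """Principal pattern of a gene chain for one sample class.

    Fits an MCM link model on the class's samples for every consecutive
    link, then assembles the most probable state sequence backward from
    the ending link (see module docstring for the two modes).
    """
    mask = states.class_mask(class_label)
    if not mask.any():
        raise ValueError(f"no samples labeled {class_label!r}")
    missing = [g for g in chain.genes if g not in states]
    if missing:
        raise ValueError(f"chain genes absent from the data: {missing}")
    models = []
    for src, dst in chain.links:
        s1 = states.states[states.gene_row(src)][mask]
        s2 = states.states[states.gene_row(dst)][mask]
        models.append(fit_mcmlink(s1, s2, alpha=alpha, link=(src, dst)))
    codes = pattern_from_models(models, mode=mode)
    named = [STATES[c] if c is not None else None for c in codes]
    return PrincipalPattern(genes=list(chain.genes), states=named,
                            class_label=class_label)
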