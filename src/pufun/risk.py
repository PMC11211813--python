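"""Positive-unlabeled risk estimators for multilabel function prediction.

For a binary decision function g with logistic loss l(z) = -ln sigmoid(z),
the classical positive-negative risk is

    R(g) = pi * RP+(g) + (1 - pi) * RN-(g).

With no negative set, (1-pi) RN- can be rewritten as RU- - pi RP-, giving
the unbiased PU (uPU) estimator

    R(g) = pi RP+ - pi RP- + RU-,

whose negative-risk part can go below zero on flexible models; the
non-negative (nnPU) estimator clamps it:

    R(g) = pi RP+ + max{0, RU- - pi RP- + beta},     0 <= beta <= pi,

with beta = gamma * pi for a margin factor gamma in [0, 1].  The multilabel
risk sums the clamped per-class risks over ontology classes, each with its
own prior pi_i derived from propagated annotation frequencies.  The ranking
variant replaces the sigmoid unlabeled risk with a pairwise logistic risk
that only asks positives to be scored above unlabeled samples:

    RU-_rank = -(1 / |P||U|) sum_{x in P} sum_{y in U} ln sigmoid(g(x) - g(y)).

All estimators here are per-minibatch: P_i / U_i are the batch's rows for
class i, and classes whose batch lacks one side are skipped (reported, not
raised).  Each risk function also exposes an analytic gradient with respect
to the logits so the whole loss can be backpropagated without an autodiff
framework.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import expit

from .ontology import PriorVector

Variant = Literal["pn_bce", "pu_basic", "pu_ranking", "pu_go"]

#: sentinel returned when a batch side needed by a component is empty
SKIP = None


def softplus(z: np.ndarray | float) -> np.ndarray | float:
    """Numerically safe -ln sigmoid(-z) = ln(1 + e^z)."""
    return np.logaddexp(0.0, z)


@dataclass
class RiskConfig:
    """Loss-variant selection and its hyperparameters.

    ``pu_basic`` uses the sigmoid unlabeled risk with a uniform prior pi_o
    for every class; ``pu_ranking`` swaps in the pairwise ranking risk;
    ``pu_go`` additionally uses hierarchy-derived per-class priors.
    ``pn_bce`` is the treat-unlabeled-as-negative baseline.
    """

    variant: Variant = "pu_go"
    pi_o: float = 1e-3
    gamma: float = 0.05
    clamp: bool = True

    def __post_init__(self) -> None:
        if self.variant not in ("pn_bce", "pu_basic", "pu_ranking", "pu_go"):
            raise ValueError(f"unknown loss variant {self.variant!r}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")

    @property
    def uses_ranking(self) -> bool:
        return self.variant in ("pu_ranking", "pu_go")

    @property
    def uses_hierarchical_priors(self) -> bool:
        return self.variant == "pu_go"


@dataclass
class ClassRisk:
    """Per-class components of the clamped risk for one batch."""

    rp_plus: float | None
    rp_minus: float | None
    ru_minus: float | None
    risk: float | None
    clamp_active: bool
    n_pos: int
    n_unl: int
    skipped: bool = False


@dataclass
class BatchRiskReport:
    """Total batch loss with its per-class decomposition."""

    total: float
    per_class: list[ClassRisk]
    n_contributing: int
    n_skipped: int


def risk_components(logits: np.ndarray, labels: np.ndarray):
    """Empirical risk components (RP+, RP-, RU-_sigmoid) for one class.

    RP+  = -mean over labeled positives of ln sigmoid(g)
    RP-  = -mean over labeled positives of ln sigmoid(-g)
    RU-  = -mean over unlabeled samples of ln sigmoid(-g)

    A component whose subset is empty comes back as the skip sentinel
    (``None``) rather than raising — batch semantics.
    """
    logits = np.asarray(logits, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if logits.shape != labels.shape:
        raise ValueError("logits and labels must be conformable")
    pos = logits[labels]
    unl = logits[~labels]
    rp_plus = float(softplus(-pos).mean()) if pos.size else SKIP
    rp_minus = float(softplus(pos).mean()) if pos.size else SKIP
    ru_minus = float(softplus(unl).mean()) if unl.size else SKIP
    return rp_plus, rp_minus, ru_minus


def ranking_unlabeled_risk(logits: np.ndarray, labels: np.ndarray):
    """Pairwise logistic ranking risk of positives vs unlabeled samples.

    -(1/|P||U|) sum over all positive x unlabeled pairs of
    ln sigmoid(g_pos - g_unl).  Invariant to adding a constant to every
    logit.  Returns the skip sentinel when either side is empty.
    """
    logits = np.asarray(logits, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if logits.shape != labels.shape:
        raise ValueError("logits and labels must be conformable")
    pos = logits[labels]
    unl = logits[~labels]
    if pos.size == 0 or unl.size == 0:
        return SKIP
    diffs = pos[:, None] - unl[None, :]
    return float(softplus(-diffs).mean())


def nnpu_class_risk(
    rp_plus: float,
    rp_minus: float,
    ru_minus: float,
    pi: float,
    beta: float = 0.0,
    clamp: bool = True,
) -> tuple[float, bool]:
    """Single-class risk; returns (value, clamp_active).

    With the clamp on (nnPU): pi*RP+ + max{0, RU- - pi*RP- + beta}, which is
    bounded below by pi*RP+ >= 0.  With the clamp off (uPU):
    pi*RP+ - pi*RP- + RU- (beta is ignored).
    """
    if not 0.0 < pi < 1.0:
        raise ValueError("class prior must lie in (0, 1)")
    if not 0.0 <= beta <= pi:
        raise ValueError("beta must satisfy 0 <= beta <= pi")
    if not clamp:
        return pi * rp_plus - pi * rp_minus + ru_minus, False
    inner = ru_minus - pi * rp_minus + beta
    if inner <= 0.0:
        return pi * rp_plus, True
    return pi * rp_plus + inner, False


def _resolve_priors(k: int, priors: PriorVector, config: RiskConfig):
    if config.uses_hierarchical_priors:
        if priors is None:
            raise ValueError("pu_go requires a PriorVector")
        if len(priors.pi) != k:
            raise ValueError("prior vector length does not match class count")
        return priors.pi, priors.beta
    pi = np.full(k, config.pi_o)
    return pi, config.gamma * pi


def pugo_loss(
    logits: np.ndarray,
    labels: np.ndarray,
    priors: PriorVector | None,
    config: RiskConfig,
    with_grad: bool = False,
):
    """Multilabel PU risk summed over classes, with optional logit gradient.

    Per class the variant's unlabeled risk (sigmoid for ``pu_basic``,
    ranking for ``pu_ranking``/``pu_go``) feeds :func:`nnpu_class_risk`;
    classes whose batch lacks positives or unlabeled rows are skipped and
    counted in the report.  ``pn_bce`` delegates to :func:`bce_loss` (no
    skipping: every cell contributes).

    Returns ``report`` or ``(report, dlogits)`` when ``with_grad``.
    """
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels)
    if logits.shape != labels.shape or logits.ndim != 2:
        raise ValueError("logits and labels must be conformable n x k arrays")
    n, k = logits.shape

    if config.variant == "pn_bce":
        value, grad = bce_loss(logits, labels, with_grad=True)
        report = BatchRiskReport(
            total=value,
            per_class=[],
            n_contributing=k,
            n_skipped=0,
        )
        return (report, grad) if with_grad else report

    pi_vec, beta_vec = _resolve_priors(k, priors, config)
    lab = labels.astype(bool)
    total = 0.0
    per_class: list[ClassRisk] = []
    dlogits = np.zeros_like(logits) if with_grad else None

    for j in range(k):
        col = logits[:, j]
        mask = lab[:, j]
        pos = col[mask]
        unl = col[~mask]
        if pos.size == 0 or unl.size == 0:
            per_class.append(
                ClassRisk(None, None, None, None, False, pos.size, unl.size, True)
            )
            continue
        pi, beta = float(pi_vec[j]), float(beta_vec[j])
        rp_plus = float(softplus(-pos).mean())
        rp_minus = float(softplus(pos).mean())
        if config.uses_ranking:
            diffs = pos[:, None] - unl[None, :]
            ru_minus = float(softplus(-diffs).mean())
        else:
            ru_minus = float(softplus(unl).mean())
        value, clamp_active = nnpu_class_risk(
            rp_plus, rp_minus, ru_minus, pi, beta, clamp=config.clamp
        )
        total += value
        per_class.append(
            ClassRisk(rp_plus, rp_minus, ru_minus, value, clamp_active,
                      pos.size, unl.size)
        )
        if not with_grad:
            continue
        # d(pi*RP+)/dg on positives: -pi/|P| * sigmoid(-g)
        gcol = np.zeros(n)
        gcol[mask] = -pi / pos.size * expit(-pos)
        include_inner = (not config.clamp) or (not clamp_active)
        if include_inner:
            # d(-pi*RP-)/dg on positives: -pi/|P| * sigmoid(g)
            gcol[mask] += -pi / pos.size * expit(pos)
            if config.uses_ranking:
                s = expit(-(pos[:, None] - unl[None, :]))  # d softplus(-d)/dd = -s
                scale = 1.0 / (pos.size * unl.size)
                gcol[mask] += -scale * s.sum(axis=1)
                gcol[~mask] += scale * s.sum(axis=0)
            else:
                gcol[~mask] += expit(unl) / unl.size
        dlogits[:, j] += gcol

    n_skipped = sum(1 for c in per_class if c.skipped)
    if n_skipped == k:
        raise ValueError("no class contributes to the batch risk (degenerate batch)")
    report = BatchRiskReport(
        total=total,
        per_class=per_class,
        n_contributing=k - n_skipped,
        n_skipped=n_skipped,
    )
    return (report, dlogits) if with_grad else report


def bce_loss(logits: np.ndarray, labels: np.ndarray, with_grad: bool = False):
    """Mean binary cross-entropy over all protein x class cells.

    The treat-unlabeled-as-negative baseline: every zero cell is penalized
    as a negative.
    """
    logits = np.asarray(logits, dtype=float)
    y = np.asarray(labels, dtype=float)
    if logits.shape != y.shape:
        raise ValueError("logits and labels must be conformable")
    value = float(np.mean(softplus(logits) - logits * y))
    if not with_grad:
        return value
    grad = (expit(logits) - y) / logits.size
    return value, grad
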