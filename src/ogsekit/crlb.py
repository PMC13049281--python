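"""Cramer-Rao lower bounds and waveform-combination ranking.

For i.i.d. Gaussian MK noise of standard deviation sigma, the Fisher
information of the protocol at a true parameter point theta is
``I = J^T J / sigma^2`` with J the Jacobian of the forward model, and the
variance of any unbiased estimator of theta_i is bounded below by
``[I^-1]_ii``.  The scale-free precision metric is the coefficient of
variation ``cv_i = sqrt(CRLB_i) / |theta_i|``; sigma rescales all cv equally
and therefore never affects a ranking.

The asymptotic offset k_inf carries no frequency dependence, so it is held
fixed by default and the four remaining parameters are ranked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .karger import PARAM_NAMES, TissueParams
from .model import ForwardOperator
from .protocol import Protocol

__all__ = [
    "DEFAULT_FREE_PARAMS",
    "CRLBReport",
    "CombinationRanking",
    "compute_crlb",
    "rank_combinations",
]

DEFAULT_FREE_PARAMS = ("t_ex", "f_ic", "alpha_d", "alpha_c")


@dataclass(frozen=True)
class CRLBReport:
    """Fisher information and per-parameter precision at one tissue point."""

    theta_true: TissueParams
    free_params: tuple[str, ...]
    labels: tuple[str, ...]
    jacobian: np.ndarray  # (M, P)
    fisher: np.ndarray    # (P, P)
    crlb: np.ndarray      # (P,) variance lower bounds
    cv: np.ndarray        # (P,) sqrt(CRLB)/|theta|
    sigma: float


@dataclass
class CombinationRanking:
    """Accumulated scores of waveform subsets, per parameter, over ROIs."""

    k: int
    free_params: tuple[str, ...]
    combinations: tuple[tuple[str, ...], ...]
    scores: dict[str, dict[tuple[str, ...], float]]
    cv_table: pd.DataFrame  # columns: roi, parameter, combination, cv

    def best(self, parameter: str) -> tuple[str, ...]:
        """Subset with the highest accumulated score for one parameter."""
        sc = self.scores[parameter]
        # ties break lexicographically by the label tuple
        return min(sc, key=lambda c: (-sc[c], c))

    def to_frame(self) -> pd.DataFrame:
        med = (
            self.cv_table.groupby(["parameter", "combination"])["cv"].median().to_dict()
        )
        rows = [
            {
                "parameter": p,
                "combination": "+".join(c),
                "accumulated_score": s,
                "median_cv": med.get((p, c), math.nan),
            }
            for p, sc in self.scores.items()
            for c, s in sc.items()
        ]
        return pd.DataFrame(rows).sort_values(
            ["parameter", "accumulated_score"], ascending=[True, False]
        ).reset_index(drop=True)


def _jacobian(
    operator: ForwardOperator,
    theta: np.ndarray,
    free_idx: Sequence[int],
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Central finite-difference Jacobian of the MK prediction, (M, P)."""
    cols = []
    for i in free_idx:
        h = rel_step * max(abs(theta[i]), 1e-8)
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        cols.append((operator.predict(tp) - operator.predict(tm)) / (2.0 * h))
    return np.stack(cols, axis=1)


def compute_crlb(
    protocol: Protocol | ForwardOperator,
    theta_true: TissueParams,
    sigma: float = 0.02,
    free_params: Sequence[str] | None = None,
) -> CRLBReport:
    """CRLB variances and coefficients of variation for one parameter point.

    Raises
    ------
    ValueError
        If the protocol has fewer waveforms than free parameters, or the
        Fisher information is singular (the error names the most collinear
        parameter pair).
    """
    operator = protocol if isinstance(protocol, ForwardOperator) else ForwardOperator(protocol)
    if free_params is None:
        free_params = DEFAULT_FREE_PARAMS
    free_params = tuple(free_params)
    unknown = set(free_params) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter names {sorted(unknown)}")
    if len(operator.labels) < len(free_params):
        raise ValueError(
            f"{len(operator.labels)} waveforms cannot bound {len(free_params)} parameters"
        )
    theta_true.validate()
    theta = theta_true.as_array()
    free_idx = [PARAM_NAMES.index(n) for n in free_params]
    jac = _jacobian(operator, theta, free_idx)
    fisher = jac.T @ jac / sigma**2
    cond = np.linalg.cond(fisher)
    # the model is legitimately ill-conditioned (the disorder parameters are
    # near-collinear over a narrow V_w range), so only true numerical
    # singularity is an error
    if not np.isfinite(cond) or cond > 1e15:
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.corrcoef(jac.T)
        corr = np.nan_to_num(corr, nan=1.0)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            "Fisher information is singular: sensitivities of "
            f"{free_params[i]} and {free_params[j]} are collinear "
            f"(|r| = {abs(corr[i, j]):.4f})"
        )
    crlb = np.diag(np.linalg.inv(fisher))
    if np.any(crlb <= 0):  # inversion broke down: treat as singular
        k = int(np.argmin(crlb))
        raise ValueError(
            "Fisher information is numerically singular: non-positive "
            f"variance bound for {free_params[k]}"
        )
    truth = theta[free_idx]
    cv = np.sqrt(crlb) / np.abs(truth)
    return CRLBReport(
        theta_true=theta_true,
        free_params=free_params,
        labels=operator.labels,
        jacobian=jac,
        fisher=fisher,
        crlb=crlb,
        cv=cv,
        sigma=sigma,
    )


def rank_combinations(
    protocol: Protocol,
    roi_truths: Iterable[TissueParams],
    k: int = 4,
    sigma: float = 0.02,
    free_params: Sequence[str] | None = None,
    top: int = 10,
) -> CombinationRanking:
    """Score all size-k waveform subsets by per-parameter CRLB precision.

    For each ROI truth and each free parameter, the C(M, k) subsets are
    ranked by coefficient of variation (ascending, ties broken
    lexicographically by labels); the ``top`` best receive weights
    ``top .. 1`` ("weighted by the opposite of the rank") and the weights
    accumulate over ROIs.  Subsets with singular Fisher information are
    excluded from that ROI's ranking.
    """
    if free_params is None:
        free_params = DEFAULT_FREE_PARAMS
    free_params = tuple(free_params)
    if k < len(free_params):
        raise ValueError(
            f"subset size k = {k} is below the number of free parameters "
            f"({len(free_params)}): the fit would be degenerate"
        )
    labels = protocol.labels
    subsets = tuple(tuple(c) for c in combinations(labels, k))
    operators = {c: ForwardOperator(protocol.subset(c)) for c in subsets}

    scores: dict[str, dict[tuple[str, ...], float]] = {
        p: {c: 0.0 for c in subsets} for p in free_params
    }
    records = []
    for roi_idx, truth in enumerate(roi_truths):
        cv_by_subset: dict[tuple[str, ...], np.ndarray] = {}
        for c in subsets:
            try:
                rep = compute_crlb(operators[c], truth, sigma=sigma, free_params=free_params)
            except ValueError:
                continue
            cv_by_subset[c] = rep.cv
            for p, v in zip(free_params, rep.cv):
                records.append(
                    {"roi": roi_idx, "parameter": p, "combination": c, "cv": float(v)}
                )
        for pi, p in enumerate(free_params):
            ranked = sorted(cv_by_subset, key=lambda c: (cv_by_subset[c][pi], c))
            for rank, c in enumerate(ranked[:top], start=1):
                scores[p][c] += top + 1 - rank
    return CombinationRanking(
        k=k,
        free_params=free_params,
        combinations=subsets,
        scores=scores,
        cv_table=pd.DataFrame(records),
    )
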