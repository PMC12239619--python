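"""Genomic prediction: GRM, univariate REML gBLUP, selection index, accuracy.

The relationship matrix is VanRaden method 1 computed on the pooled
training+candidate set.  Per trait, a single-genetic-variance mixed model
``y = mu + g + e`` with ``g ~ N(0, sg2 * G)`` is fitted by REML via a
spectral decomposition of the training block; candidate EBVs are the BLUP
conditional means given the training phenotypes.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import scipy.linalg
import scipy.optimize

logger = logging.getLogger(__name__)

__all__ = [
    "build_grm",
    "fit_gblup",
    "GBLUPResult",
    "PredictionModel",
    "selection_index",
    "prediction_accuracy",
]


def build_grm(genotypes: np.ndarray, allele_freq: np.ndarray | None = None, dtype=np.float64) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    ``G = Z Z' / (2 sum p(1-p))`` with ``Z`` the column-centered allele-count
    matrix.  Allele frequencies default to the pooled sample frequencies;
    monomorphic markers are centered to zero and contribute nothing.
    """
    geno = np.asarray(genotypes)
    if geno.ndim != 2 or geno.shape[0] < 2:
        raise ValueError("genotypes must be an (n >= 2, M) matrix")
    g = geno.astype(dtype, copy=False)
    p = g.mean(axis=0) / 2.0 if allele_freq is None else np.asarray(allele_freq, dtype=dtype)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all markers are monomorphic; GRM undefined")
    z = g - 2.0 * p
    return (z @ z.T) / denom


@dataclasses.dataclass
class GBLUPResult:
    """Variance components and EBVs for one trait."""

    sigma_g2: float
    sigma_e2: float
    mu: float
    ebv_train: np.ndarray
    ebv_candidates: np.ndarray
    reml_converged: bool = True

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else np.nan


class _TrainDecomposition:
    """Eigendecomposition of the training block, shared across traits."""

    def __init__(self, G: np.ndarray, train_idx: np.ndarray):
        gtt = np.asarray(G, dtype=np.float64)[np.ix_(train_idx, train_idx)]
        w, u = scipy.linalg.eigh(gtt)
        if w.min() < -1e-6 * max(w.max(), 1.0):
            bump = -w.min() + 1e-8
            logger.info("training GRM not PSD; inflating diagonal by %.3e", bump)
            w = w + bump
        self.w = np.clip(w, 0.0, None)
        self.u = u
        self.n = len(train_idx)


def _reml_fit(dec: _TrainDecomposition, y: np.ndarray, log_gamma_bounds=(-10.0, 10.0)):
    """Profile REML over gamma = sg2/se2 on the rotated training data."""
    ry = dec.u.T @ y
    r1 = dec.u.T @ np.ones(dec.n)
    n = dec.n

    def neg2_reml(log_gamma: float) -> float:
        gamma = np.exp(log_gamma)
        d = gamma * dec.w + 1.0
        s11 = np.sum(r1 * r1 / d)
        mu = np.sum(r1 * ry / d) / s11
        resid = ry - mu * r1
        se2 = np.sum(resid * resid / d) / (n - 1)
        if se2 <= 0:
            return np.inf
        return np.sum(np.log(d)) + np.log(s11) + (n - 1) * np.log(se2)

    res = scipy.optimize.minimize_scalar(
        neg2_reml, bounds=log_gamma_bounds, method="bounded", options={"xatol": 1e-6}
    )
    gamma = float(np.exp(res.x))
    d = gamma * dec.w + 1.0
    s11 = np.sum(r1 * r1 / d)
    mu = float(np.sum(r1 * ry / d) / s11)
    resid = ry - mu * r1
    se2 = float(np.sum(resid * resid / d) / (n - 1))
    sg2 = gamma * se2
    # alpha solves (gamma*Gtt + I) alpha = (y - mu); EBV = gamma * G[., train] @ alpha
    alpha = dec.u @ (resid / d)
    return sg2, se2, mu, gamma, alpha, bool(res.success)


def fit_gblup(
    G: np.ndarray,
    phenotypes: np.ndarray,
    train_idx,
    cand_idx,
    trait_names=None,
    gamma: float | None = None,
) -> "PredictionModel":
    """Fit univariate gBLUP for each phenotype column.

    ``G`` is the relationship matrix over the pooled set; ``train_idx`` and
    ``cand_idx`` index into it.  ``phenotypes`` is (n_train, T) in training
    order.  Returns EBVs for all candidates (and the training set).  If
    ``gamma`` (= sg2/se2) is given, variance components are fixed instead of
    REML-estimated.
    """
    train_idx = np.asarray(train_idx, dtype=np.intp)
    cand_idx = np.asarray(cand_idx, dtype=np.intp)
    y = np.asarray(phenotypes, dtype=np.float64)
    if y.ndim == 1:
        y = y[:, None]
    if len(train_idx) < 10:
        raise ValueError(f"need at least 10 training records, got {len(train_idx)}")
    if y.shape[0] != len(train_idx):
        raise ValueError("phenotype rows must match training ids")
    dec = _TrainDecomposition(G, train_idx)
    g_ct = np.asarray(G, dtype=np.float64)[np.ix_(cand_idx, train_idx)]
    g_tt = np.asarray(G, dtype=np.float64)[np.ix_(train_idx, train_idx)]
    results = []
    for t in range(y.shape[1]):
        yt = y[:, t]
        if np.var(yt) == 0.0:
            results.append(
                GBLUPResult(
                    sigma_g2=0.0,
                    sigma_e2=0.0,
                    mu=float(yt[0]) if len(yt) else 0.0,
                    ebv_train=np.zeros(len(train_idx)),
                    ebv_candidates=np.zeros(len(cand_idx)),
                )
            )
            continue
        if gamma is None:
            sg2, se2, mu, gam, alpha, ok = _reml_fit(dec, yt)
        else:
            gam, ok = float(gamma), True
            d = gam * dec.w + 1.0
            ry, r1 = dec.u.T @ yt, dec.u.T @ np.ones(dec.n)
            mu = float(np.sum(r1 * ry / d) / np.sum(r1 * r1 / d))
            resid = ry - mu * r1
            se2 = float(np.sum(resid * resid / d) / (dec.n - 1))
            sg2 = gam * se2
            alpha = dec.u @ (resid / d)
        results.append(
            GBLUPResult(
                sigma_g2=sg2,
                sigma_e2=se2,
                mu=mu,
                ebv_train=gam * (g_tt @ alpha),
                ebv_candidates=gam * (g_ct @ alpha),
                reml_converged=ok,
            )
        )
    names = tuple(trait_names) if trait_names is not None else tuple(f"trait_{t}" for t in range(y.shape[1]))
    return PredictionModel(
        train_idx=train_idx, cand_idx=cand_idx, results=results, trait_names=names
    )


@dataclasses.dataclass
class PredictionModel:
    """Per-trait gBLUP fits over a shared relationship matrix."""

    train_idx: np.ndarray
    cand_idx: np.ndarray
    results: list
    trait_names: tuple

    @property
    def ebv(self) -> np.ndarray:
        """Candidate EBVs, shape (n_candidates, T)."""
        return np.column_stack([r.ebv_candidates for r in self.results])

    @property
    def variance_components(self) -> dict:
        return {
            name: (r.sigma_g2, r.sigma_e2) for name, r in zip(self.trait_names, self.results)
        }

    def accuracy(self, truth: np.ndarray) -> tuple[np.ndarray, float]:
        """Realized accuracy against candidate true values (n_candidates, T)."""
        return prediction_accuracy(self.ebv, truth)

    def to_frame(self, candidate_ids=None):
        """Candidate EBV table (one column per trait) as a DataFrame."""
        import pandas as pd

        ids = np.asarray(candidate_ids) if candidate_ids is not None else self.cand_idx
        return pd.DataFrame(
            {"individual": ids}
            | {f"ebv_{n}": r.ebv_candidates for n, r in zip(self.trait_names, self.results)}
        )


def selection_index(values: np.ndarray, weights=(1.0, 1.0, -1.0), gsd_units=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Equal-weight three-trait index: raise the first two stages, lower the final one.

    ``values`` is (n, 3) — EBVs or true genetic values of the three traits of
    a single variant (DH or cross); ``gsd_units`` are the per-trait genetic
    standard deviations used to put traits on a common scale (1 when values
    are already standardized).
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if v.shape[1] != 3:
        raise ValueError("selection index expects exactly three traits of one variant")
    w = np.asarray(weights, dtype=float) / np.asarray(gsd_units, dtype=float)
    return v @ w


def prediction_accuracy(ebv: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-trait Pearson correlation of EBV with true genomic value.

    Traits with zero variance on either side get NaN; the mean is taken over
    non-missing traits.
    """
    ebv = np.atleast_2d(np.asarray(ebv, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if ebv.shape != truth.shape:
        raise ValueError("ebv and truth must have identical shape")
    accs = np.full(ebv.shape[1], np.nan)
    for t in range(ebv.shape[1]):
        a, b = ebv[:, t], truth[:, t]
        if np.std(a) == 0.0 or np.std(b) == 0.0:
            continue
        accs[t] = float(np.corrcoef(a, b)[0, 1])
    mean = float(np.nanmean(accs)) if np.any(~np.isnan(accs)) else np.nan
    return accs, mean
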