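"""Diffusion-mode classification of pooled transit-time distributions.

Free 2D diffusion produces lognormally distributed transit times (their
natural logarithm is normal); nano-scale hindered diffusion (transient
trapping) adds a second, slower population, producing a double-lognormal.
Candidate models — single lognormal, double lognormal and Gaussian — are fit
by maximum likelihood on the transit times (ms, natural scale; the mixture
is optimised on the log scale with the Jacobian included so that
likelihoods are comparable across models), ranked by the Bayesian
information criterion BIC = k ln(n) - 2 logL, and summarised by relative
likelihoods RL = exp((BIC_min - BIC)/2): the best-supported model has RL = 1,
all others less.  RL = 1 for the lognormal identifies free diffusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CandidateModel",
    "ModelSelectionResult",
    "fit_model",
    "select_model",
    "DiffusionModeModel",
    "MODEL_N_PARAMS",
]

MODEL_N_PARAMS = {"lognormal": 2, "double_lognormal": 5, "gaussian": 2}

_WEIGHT_BOUNDS = (0.01, 0.99)


@dataclass(frozen=True)
class CandidateModel:
    """A candidate transit-time distribution fitted by maximum likelihood."""

    model_id: str
    n_params: int
    params: Dict[str, float]
    log_likelihood: float

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.model_id == "lognormal":
            return stats.lognorm.pdf(x, s=p["sigma"], scale=math.exp(p["mu"]))
        if self.model_id == "gaussian":
            return stats.norm.pdf(x, loc=p["mu"], scale=p["sigma"])
        return p["weight"] * stats.lognorm.pdf(
            x, s=p["sigma1"], scale=math.exp(p["mu1"])
        ) + (1.0 - p["weight"]) * stats.lognorm.pdf(
            x, s=p["sigma2"], scale=math.exp(p["mu2"])
        )


def _mixture_negll(theta: np.ndarray, lx: np.ndarray) -> float:
    """Negative log-likelihood of a 2-normal mixture on log-data (no Jacobian)."""
    w, mu1, s1, mu2, s2 = theta
    f1 = stats.norm.logpdf(lx, mu1, s1)
    f2 = stats.norm.logpdf(lx, mu2, s2)
    m = np.maximum(f1, f2)
    ll = m + np.log(
        w * np.exp(f1 - m) + (1.0 - w) * np.exp(f2 - m)
    )
    return -float(np.sum(ll))


def fit_model(
    transit_times_ms: Sequence[float],
    model_id: str,
    n_starts: int = 8,
    seed: int = 0,
) -> CandidateModel:
    """Maximum-likelihood fit of one candidate transit-time distribution.

    Lognormal and Gaussian have closed-form MLEs (moments of the log / raw
    data).  The double lognormal is maximised numerically on the log scale
    with deterministic seeded multi-starts; one start is the degenerate
    single-lognormal solution, which guarantees the nesting inequality
    logL(double) >= logL(single).  Components are ordered mu1 < mu2.
    """
    x = np.asarray(transit_times_ms, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 transit times")
    if model_id not in MODEL_N_PARAMS:
        raise ValueError(f"unknown model_id {model_id!r}")
    if model_id != "gaussian" and np.any(x <= 0):
        raise ValueError("lognormal models require strictly positive values")
    if np.all(x == x[0]):
        raise ValueError("degenerate sample: all values identical")

    if model_id == "gaussian":
        mu, sigma = float(x.mean()), float(x.std())
        ll = float(np.sum(stats.norm.logpdf(x, mu, sigma)))
        return CandidateModel("gaussian", 2, {"mu": mu, "sigma": sigma}, ll)

    lx = np.log(x)
    jacobian = -float(np.sum(lx))  # d/dx of the log transform, common to all
    mu_hat, sig_hat = float(lx.mean()), float(lx.std())

    if model_id == "lognormal":
        ll = float(np.sum(stats.norm.logpdf(lx, mu_hat, sig_hat))) + jacobian
        return CandidateModel("lognormal", 2, {"mu": mu_hat, "sigma": sig_hat}, ll)

    # double lognormal: bounded multi-start optimisation on the log scale
    n_starts = max(int(n_starts), 1)
    rng = np.random.default_rng(seed)
    smin = max(sig_hat * 1e-3, 1e-6)
    bounds = [
        _WEIGHT_BOUNDS,
        (lx.min() - 1.0, lx.max() + 1.0),
        (smin, 10.0 * sig_hat + 1e-6),
        (lx.min() - 1.0, lx.max() + 1.0),
        (smin, 10.0 * sig_hat + 1e-6),
    ]
    starts: List[np.ndarray] = [
        # degenerate start = the nested single-lognormal optimum
        np.array([0.5, mu_hat, sig_hat, mu_hat, sig_hat]),
        # split at the median
        np.array(
            [
                0.5,
                float(np.median(lx[lx <= np.median(lx)])),
                max(sig_hat / 2, smin),
                float(np.median(lx[lx >= np.median(lx)])),
                max(sig_hat / 2, smin),
            ]
        ),
    ]
    while len(starts) < n_starts:
        w = rng.uniform(*_WEIGHT_BOUNDS)
        m1, m2 = np.sort(rng.uniform(lx.min(), lx.max(), size=2))
        s1, s2 = rng.uniform(0.2 * sig_hat + smin, sig_hat + smin, size=2)
        starts.append(np.array([w, m1, s1, m2, s2]))

    best: Optional[optimize.OptimizeResult] = None
    for theta0 in starts:
        res = optimize.minimize(
            _mixture_negll,
            theta0,
            args=(lx,),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    w, mu1, s1, mu2, s2 = best.x
    if mu1 > mu2:  # fix label symmetry: component 1 is the faster (smaller mu)
        w, mu1, s1, mu2, s2 = 1.0 - w, mu2, s2, mu1, s1
    ll = -float(best.fun) + jacobian
    return CandidateModel(
        "double_lognormal",
        5,
        {"weight": float(w), "mu1": float(mu1), "sigma1": float(s1),
         "mu2": float(mu2), "sigma2": float(s2)},
        ll,
    )


@dataclass
class ModelSelectionResult:
    """BIC ranking of candidate transit-time models."""

    n: int
    candidates: Dict[str, CandidateModel]
    bic: Dict[str, float]
    rl: Dict[str, float]
    best_model: str

    def summary(self) -> str:
        lines = [f"Diffusion-mode model selection (n = {self.n})"]
        lines.append(f"  best model: {self.best_model}"
                     + ("  (free diffusion)" if self.best_model == "lognormal" else ""))
        lines.append(f"  {'model':>18s} {'k':>3s} {'logL':>12s} {'BIC':>12s} {'RL':>8s}")
        for mid, cand in self.candidates.items():
            lines.append(
                f"  {mid:>18s} {cand.n_params:>3d} "
                f"{cand.log_likelihood:>12.2f} {self.bic[mid]:>12.2f} "
                f"{self.rl[mid]:>8.3g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "best_model": self.best_model,
            "models": {
                mid: {
                    "n_params": c.n_params,
                    "params": c.params,
                    "log_likelihood": c.log_likelihood,
                    "bic": self.bic[mid],
                    "rl": self.rl[mid],
                }
                for mid, c in self.candidates.items()
            },
        }


def select_model(
    transit_times_ms: Sequence[float],
    candidates: Optional[Dict[str, CandidateModel]] = None,
    n_starts: int = 8,
    seed: int = 0,
    model_ids: Sequence[str] = ("lognormal", "double_lognormal", "gaussian"),
) -> ModelSelectionResult:
    """Fit candidate models (unless supplied) and rank them by BIC.

    RL_m = exp((BIC_min - BIC_m)/2); ties between equal-BIC models are
    broken toward fewer parameters, so exactly one model has RL = 1.
    """
    x = np.asarray(transit_times_ms, dtype=float)
    if candidates is None:
        candidates = {
            mid: fit_model(x, mid, n_starts=n_starts, seed=seed) for mid in model_ids
        }
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate models")
    n = x.size
    bic = {
        mid: c.n_params * math.log(n) - 2.0 * c.log_likelihood
        for mid, c in candidates.items()
    }
    best = min(bic, key=lambda mid: (bic[mid], candidates[mid].n_params))
    rl = {mid: math.exp((bic[best] - b) / 2.0) for mid, b in bic.items()}
    rl[best] = 1.0
    return ModelSelectionResult(n=n, candidates=dict(candidates), bic=bic, rl=rl,
                                best_model=best)


class DiffusionModeModel:
    """statsmodels-style wrapper: construct from pooled transit times, fit().

    >>> result = DiffusionModeModel(tau_ms).fit(seed=1)
    >>> print(result.summary())
    """

    def __init__(
        self,
        transit_times_ms: Sequence[float],
        model_ids: Sequence[str] = ("lognormal", "double_lognormal", "gaussian"),
    ) -> None:
        self.transit_times_ms = np.asarray(transit_times_ms, dtype=float)
        self.model_ids = tuple(model_ids)

    def fit(self, n_starts: int = 8, seed: int = 0) -> ModelSelectionResult:
        return select_model(
            self.transit_times_ms, n_starts=n_starts, seed=seed,
            model_ids=self.model_ids,
        )
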