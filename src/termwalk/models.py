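"""Maximum-likelihood fitting and AIC selection of step-length models.

Three competing truncated densities on [l_min, l_max] describe a step
sample:

* TPL — truncated power law, ``p(l) = C_TPL * l**-mu`` with
  ``C_TPL = (mu - 1) / (l_min**(1-mu) - l_max**(1-mu))``: a Lévy walk
  confined to a bounded arena.
* TE — truncated exponential, ``p(l) = C_TE * exp(-lam*l)`` with
  ``C_TE = lam / (exp(-lam*l_min) - exp(-lam*l_max))``: boundary-limited
  Brownian motion.
* BiExp — a two-rate exponential mixture
  ``w*lam1*exp(-lam1*l) + (1-w)*lam2*exp(-lam2*l)``, renormalized to the
  observed domain so all three models are compared on the same support:
  composite Brownian motion with intensive and extensive modes.

Negative log-likelihoods are minimized with L-BFGS-B; models are ranked
by AIC = 2k - 2 ln L and Akaike weights, with a 0.9 weight declaring a
decisive winner.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "ModelFit",
    "ModelSelection",
    "nll_tpl",
    "nll_te",
    "nll_biexp",
    "fit_model",
    "akaike_weights",
    "select_model",
    "cohort_summary",
]

MODEL_ORDER = ("TPL", "TE", "BiExp")
N_PARAMS = {"TPL": 1, "TE": 1, "BiExp": 3}
MU_BOUNDS = (1.001, 5.0)
DECISIVE_WEIGHT = 0.9
MIN_STEPS = 10


@dataclass(frozen=True)
class ModelFit:
    model: str
    params: dict
    nll: float
    n: int

    @property
    def k(self) -> int:
        return N_PARAMS[self.model]

    @property
    def aic(self) -> float:
        return 2 * self.k + 2 * self.nll


@dataclass(frozen=True)
class ModelSelection:
    """AIC comparison of the three fits for one individual.

    ``winner`` has the minimal AIC; ``decisive`` records whether its
    Akaike weight exceeded 0.9 (otherwise lowest AIC alone decides).
    """

    id: str
    fits: tuple[ModelFit, ...]
    weights: np.ndarray
    winner: str
    decisive: bool


def _check_domain(lengths: np.ndarray, l_min: float, l_max: float) -> np.ndarray:
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("empty length sample")
    if not (0 < l_min < l_max):
        raise ValueError("require 0 < l_min < l_max")
    tol = 1e-9 * max(1.0, l_max)
    if lengths.min() < l_min - tol or lengths.max() > l_max + tol:
        raise ValueError("lengths outside [l_min, l_max]")
    return np.clip(lengths, l_min, l_max)


def nll_tpl(mu: float, lengths: np.ndarray, l_min: float, l_max: float) -> float:
    """Negative log-likelihood of the truncated power law."""
    lengths = _check_domain(lengths, l_min, l_max)
    if mu <= 1:
        raise ValueError("TPL requires mu > 1 on a truncated domain")
    log_c = np.log(mu - 1.0) - np.log(l_min ** (1 - mu) - l_max ** (1 - mu))
    nll = -lengths.size * log_c + mu * np.log(lengths).sum()
    if not np.isfinite(nll):
        raise FloatingPointError("non-finite TPL likelihood")
    return float(nll)


def nll_te(lam: float, lengths: np.ndarray, l_min: float, l_max: float) -> float:
    """Negative log-likelihood of the truncated exponential."""
    lengths = _check_domain(lengths, l_min, l_max)
    if lam <= 0:
        raise ValueError("TE requires lam > 0")
    # log C = log lam - log(exp(-lam*l_min) - exp(-lam*l_max)), computed stably
    log_mass = -lam * l_min + np.log1p(-np.exp(-lam * (l_max - l_min)))
    nll = -lengths.size * (np.log(lam) - log_mass) + lam * lengths.sum()
    if not np.isfinite(nll):
        raise FloatingPointError("non-finite TE likelihood")
    return float(nll)


def nll_biexp(
    w: float,
    lam1: float,
    lam2: float,
    lengths: np.ndarray,
    l_min: float,
    l_max: float,
) -> float:
    """Negative log-likelihood of the domain-renormalized two-rate mixture."""
    lengths = _check_domain(lengths, l_min, l_max)
    if not (0 <= w <= 1) or lam1 <= 0 or lam2 <= 0:
        raise ValueError("invalid BiExp parameters")
    dens = w * lam1 * np.exp(-lam1 * lengths) + (1 - w) * lam2 * np.exp(
        -lam2 * lengths
    )
    z = w * (np.exp(-lam1 * l_min) - np.exp(-lam1 * l_max)) + (1 - w) * (
        np.exp(-lam2 * l_min) - np.exp(-lam2 * l_max)
    )
    if z <= 0 or np.any(dens <= 0):
        raise FloatingPointError("degenerate BiExp density")
    nll = -(np.log(dens).sum() - lengths.size * np.log(z))
    if not np.isfinite(nll):
        raise FloatingPointError("non-finite BiExp likelihood")
    return float(nll)


def _fit_tpl(lengths, l_min, l_max):
    s = np.log(lengths).sum()
    n = lengths.size

    def f(theta):
        mu = theta[0]
        log_c = np.log(mu - 1.0) - np.log(l_min ** (1 - mu) - l_max ** (1 - mu))
        return -n * log_c + mu * s

    best = None
    for mu0 in (1.2, 1.6, 2.5):
        res = minimize(f, [mu0], method="L-BFGS-B", bounds=[MU_BOUNDS])
        if best is None or res.fun < best.fun:
            best = res
    return {"mu": float(best.x[0])}, float(best.fun)


def _fit_te(lengths, l_min, l_max):
    mean_excess = max(lengths.mean() - l_min, 1e-9)
    lam0 = 1.0 / mean_excess

    def f(theta):
        return nll_te(theta[0], lengths, l_min, l_max)

    best = None
    for scale in (1.0, 0.3, 3.0):
        res = minimize(
            f, [lam0 * scale], method="L-BFGS-B", bounds=[(1e-8, 1e4)]
        )
        if best is None or res.fun < best.fun:
            best = res
    return {"lam": float(best.x[0])}, float(best.fun)


def _fit_biexp(lengths, l_min, l_max):
    # 5 deterministic quantile-based starts: split the sample at a quantile
    # and seed each rate with the reciprocal mean excess of its half
    def f(theta):
        try:
            return nll_biexp(*theta, lengths, l_min, l_max)
        except FloatingPointError:
            return 1e12

    starts = []
    for q in (0.3, 0.5, 0.7):
        cut = np.quantile(lengths, q)
        lo = lengths[lengths <= cut]
        hi = lengths[lengths > cut]
        lam_fast = 1.0 / max(lo.mean() - l_min, 1e-6) if lo.size else 2.0
        lam_slow = 1.0 / max(hi.mean() - l_min, 1e-6) if hi.size else 0.2
        starts.append((q, lam_fast, lam_slow))
    lam_all = 1.0 / max(lengths.mean() - l_min, 1e-6)
    starts.append((0.5, lam_all * 4.0, lam_all * 0.5))
    starts.append((0.9, lam_all * 2.0, lam_all * 0.1))

    bounds = [(0.0, 1.0), (1e-8, 1e4), (1e-8, 1e4)]
    best = None
    for x0 in starts:
        res = minimize(f, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    w, lam1, lam2 = (float(v) for v in best.x)
    if lam1 < lam2:  # identifiability: lam1 is the faster rate
        lam1, lam2, w = lam2, lam1, 1.0 - w
    return {"w": w, "lam1": lam1, "lam2": lam2}, float(best.fun)


def fit_model(
    model: str,
    lengths: np.ndarray,
    l_min: float,
    l_max: float | None = None,
    min_steps: int = MIN_STEPS,
) -> ModelFit:
    """Fit one truncated model to a step sample by bounded L-BFGS-B.

    ``l_max`` defaults to the largest observed step.  The TPL exponent is
    constrained to (1.001, 5]; the BiExp mixture uses five deterministic
    quantile-based starts to escape local optima and reports ``w`` as the
    weight of the faster rate (``lam1 > lam2``).
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size < min_steps:
        raise ValueError(
            f"need at least {min_steps} steps to fit, got {lengths.size}"
        )
    if l_max is None:
        l_max = float(lengths.max())
    lengths = _check_domain(lengths, l_min, l_max)
    if model == "TPL":
        params, nll = _fit_tpl(lengths, l_min, l_max)
    elif model == "TE":
        params, nll = _fit_te(lengths, l_min, l_max)
    elif model == "BiExp":
        params, nll = _fit_biexp(lengths, l_min, l_max)
    else:
        raise ValueError(f"unknown model {model!r}")
    if not np.isfinite(nll):
        raise RuntimeError(f"{model} fit did not converge to a finite likelihood")
    return ModelFit(model=model, params=params, nll=nll, n=lengths.size)


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-d_i/2) / sum_j exp(-d_j/2), d_i = AIC_i - min AIC."""
    aics = np.asarray(aics, dtype=float)
    if aics.size < 2:
        raise ValueError("need at least 2 AIC values")
    if not np.all(np.isfinite(aics)):
        raise ValueError("non-finite AIC")
    rel = np.exp(-0.5 * (aics - aics.min()))
    return rel / rel.sum()


def select_model(fits: Sequence[ModelFit], id: str = "") -> ModelSelection:
    """Pick the best model: decisive if its Akaike weight exceeds 0.9,
    otherwise lowest AIC; exact AIC ties break toward parsimony (fewest
    parameters), then the fixed order TPL < TE < BiExp."""
    if len(fits) != len(MODEL_ORDER):
        raise ValueError(f"expected {len(MODEL_ORDER)} fits, got {len(fits)}")
    fits = tuple(sorted(fits, key=lambda f: MODEL_ORDER.index(f.model)))
    aics = np.array([f.aic for f in fits])
    weights = akaike_weights(aics)
    min_aic = aics.min()
    tied = [f for f, a in zip(fits, aics) if a == min_aic]
    winner = min(tied, key=lambda f: (f.k, MODEL_ORDER.index(f.model)))
    decisive = bool(weights[fits.index(winner)] > DECISIVE_WEIGHT)
    return ModelSelection(
        id=id, fits=fits, weights=weights, winner=winner.model, decisive=decisive
    )


def cohort_summary(
    selections: Iterable[ModelSelection],
    grouping: Mapping[str, tuple[str, int]],
) -> pd.DataFrame:
    """Per-(caste, N) fractions of individuals won by each model.

    ``grouping`` maps individual id to its (caste, group size).  Returns
    a table with columns caste, N, n, prop_TPL, prop_TE, prop_BiExp;
    proportions sum to 1 within each group.
    """
    rows = []
    for sel in selections:
        caste, n_group = grouping[sel.id]
        rows.append({"caste": caste, "N": n_group, "winner": sel.winner})
    if not rows:
        raise ValueError("no selections to summarize")
    df = pd.DataFrame(rows)
    out = []
    for (caste, n_group), grp in df.groupby(["caste", "N"]):
        counts = grp["winner"].value_counts()
        rec = {"caste": caste, "N": n_group, "n": len(grp)}
        for m in MODEL_ORDER:
            rec[f"prop_{m}"] = counts.get(m, 0) / len(grp)
        out.append(rec)
    return pd.DataFrame(out).sort_values(["caste", "N"]).reset_index(drop=True)
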