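"""Inverse Ising inference: Boltzmann-machine fit of (h, J) to data moments.

Maximum-likelihood fitting of the pairwise maximum-entropy model reduces to
moment matching: ascend the log-likelihood with the gradient

    dL/dh_i  = <s_i>_data   - <s_i>_model
    dL/dJ_ij = <s_i s_j>_data - <s_i s_j>_model,

which is the canonical Boltzmann-machine learning rule.  The log-likelihood
is concave in (h, J), so with a small enough step the iteration converges to
the unique model whose moments match the data's.  Model moments come from
exact enumeration for small N (the default) or from persistent Monte Carlo
chains above the enumeration cap.

The J = 0 "null" mode fits an independent-nodes model: each field then has
the closed form h_i = atanh(<s_i>), and the fitted distribution factorises,
reproducing per-node means but no inter-node correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .occupancy_data import MomentSet, StateDistribution, pair_indices
from .spin_glass_core import ENUMERATION_CAP, SpinGlassModel, enumerate_spin_states

logger = logging.getLogger(__name__)

__all__ = ["FitConfig", "FitResult", "fit", "fit_null", "divergence"]

SATURATION_EPS = 1e-9


@dataclass
class FitConfig:
    """Settings for the Boltzmann-machine fit.

    tol_moments is the maximum absolute spin-moment mismatch accepted as
    converged; the defaults (1e-6 exact, 1e-3 MC) reflect the noise floor of
    each gradient mode.
    """

    learning_rate: float = 0.1
    max_iters: int = 50_000
    tol_moments: float = 1e-6
    gradient_mode: str = "exact-enumeration"  # or "mc-sampled"
    mc_samples: int = 2000
    mc_sweeps_per_iter: int = 1
    seed: int = 0
    clamp_J_zero: bool = False
    log_every: int = 0  # iterations between progress log lines; 0 = silent

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.tol_moments <= 0:
            raise ValueError("tol_moments must be positive")
        if self.gradient_mode not in ("exact-enumeration", "mc-sampled"):
            raise ValueError(f"unknown gradient_mode: {self.gradient_mode!r}")


@dataclass
class FitResult:
    model: SpinGlassModel
    trace: np.ndarray  # columns: nll per frame, max abs moment mismatch
    converged: bool
    iterations_used: int
    config: FitConfig | None = field(default=None, repr=False)

    @property
    def final_mismatch(self) -> float:
        return float(self.trace[-1, 1]) if len(self.trace) else np.inf


def _check_saturation(moments: MomentSet) -> None:
    if np.any(np.abs(moments.spin_means) >= 1 - SATURATION_EPS) or np.any(
        np.abs(moments.spin_pairs) >= 1 - SATURATION_EPS
    ):
        raise ValueError(
            "saturated empirical moments (|<s>| = 1 or deterministic pair): "
            "fields would diverge; re-estimate the state histogram with a "
            "pseudocount (empirical_distribution(..., pseudocount=...))"
        )


def fit(data_moments: MomentSet, config: FitConfig | None = None) -> FitResult:
    """Fit (h, J) so model moments match ``data_moments``.

    Initialisation is the independent-nodes warm start h = atanh(<s_i>),
    J = 0.  With ``config.clamp_J_zero`` the couplings stay identically zero
    and only the fields are learned (the null model).  Deterministic given
    ``config.seed`` (relevant in mc-sampled mode only).
    """
    config = config or FitConfig()
    _check_saturation(data_moments)
    n = data_moments.n_nodes
    target_s = data_moments.spin_means
    target_p = data_moments.spin_pairs

    h = np.arctanh(np.clip(target_s, -1 + 1e-12, 1 - 1e-12))
    j = np.zeros(n * (n - 1) // 2)

    exact = config.gradient_mode == "exact-enumeration"
    if exact:
        if n > ENUMERATION_CAP:
            raise ValueError(
                f"N={n} exceeds the enumeration cap; use gradient_mode='mc-sampled'"
            )
        spins = enumerate_spin_states(n)
        pairs = pair_indices(n)
        pi = np.array([p[0] for p in pairs], dtype=int)
        pj = np.array([p[1] for p in pairs], dtype=int)
        pairprod = spins[:, pi] * spins[:, pj]
    else:
        from .mc_dynamics import _chain_moments_persistent  # lazy: numba import

        rng = np.random.default_rng(config.seed)
        chains = -np.ones((config.mc_samples, n), dtype=np.int8)  # start all-empty

    trace = np.empty((config.max_iters, 2))
    converged = False
    it = 0
    best = (np.inf, h.copy(), j.copy())
    for it in range(1, config.max_iters + 1):
        if exact:
            logits = spins @ h + pairprod @ j  # beta = 1 during learning
            shift = logits.max()
            w = np.exp(logits - shift)
            logz = float(np.log(w.sum()) + shift)
            w /= w.sum()
            model_s = w @ spins
            model_p = w @ pairprod
            # per-frame NLL = log Z - (h . <s>_data + J . <ss>_data)
            nll = logz - float(h @ target_s + j @ target_p)
        else:
            model_s, model_p, chains = _chain_moments_persistent(
                h, j, chains, config.mc_sweeps_per_iter, rng
            )
            nll = np.nan  # log Z not available without enumeration

        gh = target_s - model_s
        gj = target_p - model_p
        if config.clamp_J_zero:  # pair moments are not fitted in null mode
            err = float(np.abs(gh).max())
        else:
            err = max(np.abs(gh).max(), np.abs(gj).max() if gj.size else 0.0)
        trace[it - 1] = (nll, err)
        if err < best[0]:
            best = (err, h.copy(), j.copy())
        if config.log_every and it % config.log_every == 0:
            logger.info("fit iter %d: max moment mismatch %.3g, nll %.6g", it, err, nll)
        if err <= config.tol_moments:
            converged = True
            break
        h = h + config.learning_rate * gh
        if not config.clamp_J_zero:
            j = j + config.learning_rate * gj

    if not converged:
        _, h, j = best
        logger.warning(
            "fit did not converge in %d iterations (best mismatch %.3g)",
            config.max_iters, best[0],
        )
    model = SpinGlassModel.from_upper(h, j)
    return FitResult(model, trace[:it].copy(), converged, it, config)


def fit_null(data_moments: MomentSet, config: FitConfig | None = None) -> FitResult:
    """Fit the independent-nodes null model (J clamped to 0).

    The iterative result is cross-checked against the closed form
    h_i = atanh(<s_i>); a discrepancy beyond tolerance raises.
    """
    config = config or FitConfig()
    cfg = FitConfig(**{**config.__dict__, "clamp_J_zero": True})
    result = fit(data_moments, cfg)
    closed = np.arctanh(np.clip(data_moments.spin_means, -1 + 1e-12, 1 - 1e-12))
    if result.converged and not np.allclose(result.model.h, closed, atol=1e-3):
        raise RuntimeError("null fit disagrees with closed form atanh(<s_i>)")
    return result


def divergence(p: StateDistribution, q: StateDistribution) -> float:
    """Kullback-Leibler divergence KL(p || q) = sum p log(p/q), in nats.

    0 log 0 = 0; q must be strictly positive wherever p is (always true for
    Boltzmann model distributions).
    """
    if p.n_nodes != q.n_nodes:
        raise ValueError("distributions must share N")
    mask = p.probs > 0
    if np.any(q.probs[mask] <= 0):
        raise ValueError("KL undefined: q has zero mass where p > 0")
    return float(np.sum(p.probs[mask] * np.log(p.probs[mask] / q.probs[mask])))
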