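"""Bayesian posterior prediction of a focal species' trait from a
phylogenetic regression fitted without it.

The question answered here is "is the focal species exceptional?": fit the
log–log allometry to every *other* species, propagate uncertainty in the
regression parameters (β, σ², λ) and in the phylogeny (one tree drawn
uniformly per MCMC iteration from a supplied tree set), and for each
retained iteration draw the focal species' predicted trait from its
conditional normal given its phylogenetic position:

    mean = x₀'β + v₀' V⁻¹ (y − Xβ),   var = σ² (v₀₀ − v₀' V⁻¹ v₀),

where v₀ is the focal tip's (λ-scaled) covariance with the sample. The
observed value's percentile within the retained draws, and its position
relative to the credible interval, give the verdict.

Sampler: Metropolis–Hastings with flat priors on β and log σ², a uniform
prior on λ ∈ [0,1] (proposals reflected at the bounds), and Gaussian
random-walk proposals initialised from the PGLS fit and adapted toward a
20–45% acceptance rate during burn-in only. Retained draw count is
floor((iterations − burn_in)/thinning); the conventional settings
(100,100 iterations, burn-in 100, thin 100) retain exactly 1,000 draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .allometry import TraitTable, fit_pgls
from .errors import NumericalError, ValidationError
from .trees import PhyloTree

__all__ = ["PosteriorPredictive", "posterior_predict",
           "exceptionality_report"]

log = logging.getLogger(__name__)


@dataclass
class PosteriorPredictive:
    """Retained MCMC draws of a focal species' predicted trait (log₁₀)."""

    draws: np.ndarray                      # predicted trait, one per retained iter
    params: np.ndarray = field(repr=False)  # columns: intercept, slope, sigma2, lambda
    observed: float = np.nan
    target: str = ""
    response: str = ""
    predictor: str = ""
    settings: dict = field(default_factory=dict)
    n_trees: int = 0
    seed: int | None = None
    acceptance_rate: float = np.nan

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    @property
    def percentile(self) -> float:
        """Percentile of the observed value within the retained draws."""
        return float(stats.percentileofscore(self.draws, self.observed,
                                             kind="mean"))

    def credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.draws, [a, 1.0 - a])
        return float(lo), float(hi)


def _loglik_state(resid, V, sigma2):
    """Gaussian log-density of residuals with covariance sigma2 * V."""
    try:
        c, low = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise NumericalError("singular covariance in MCMC") from exc
    n = len(resid)
    logdet = 2.0 * np.sum(np.log(np.diag(c))) + n * np.log(sigma2)
    quad = float(resid @ linalg.cho_solve((c, low), resid)) / sigma2
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def _reflect01(v: float) -> float:
    """Reflect a real into [0,1] (keeps a random walk symmetric)."""
    v = v % 2.0
    return 2.0 - v if v > 1.0 else v


def posterior_predict(trees: list[PhyloTree], traits: TraitTable,
                      target: str, response: str, predictor: str, *,
                      iterations: int = 100_100, burn_in: int = 100,
                      thinning: int = 100, seed: int | None = None,
                      fix_sigma2: float | None = None,
                      fix_lambda: float | None = None) -> PosteriorPredictive:
    """Posterior-predictive distribution for `target`, which is excluded
    from the regression but placed on the tree for the prediction step."""
    if iterations <= burn_in:
        raise ValidationError("iterations must exceed burn_in")
    if thinning < 1:
        raise ValidationError("thinning must be >= 1")
    if not trees:
        raise ValidationError("need at least one tree")
    if target not in traits.species:
        raise ValidationError(f"target {target!r} not in trait table")
    others = [s for s in traits.species if s != target]
    if len(others) < 4:
        raise ValidationError("need at least 4 non-target species")
    for k, t in enumerate(trees, start=1):
        if target not in t.tip_labels:
            raise ValidationError(f"target {target!r} missing from tree {k}")

    order = sorted(others)
    full_order = order + [target]
    df = traits.df.loc[full_order, [response, predictor]]
    bad = df.index[~(df[df.columns] > 0).all(axis=1)].tolist()
    if bad:
        raise ValidationError(f"non-positive trait values for: {bad}")
    y_all = np.log10(df[response].to_numpy(dtype=float))
    x_all = np.log10(df[predictor].to_numpy(dtype=float))
    y, x = y_all[:-1], x_all[:-1]
    x0, y0_obs = x_all[-1], y_all[-1]
    n = len(y)

    # unscaled shared-path matrices, target last, one per tree
    Cs = [t.shared_path_matrix(order=full_order)[1] for t in trees]

    rng = np.random.default_rng(seed)
    n_retained = (iterations - burn_in) // thinning
    settings = {"iterations": iterations, "burn_in": burn_in,
                "thinning": thinning, "n_retained": n_retained}

    # degenerate no-noise model: parameters collapse to the GLS point
    # estimate and every draw is the regression-line value at x0
    if fix_sigma2 is not None and fix_sigma2 == 0.0:
        lam0 = 1.0 if fix_lambda is None else float(fix_lambda)
        sub = TraitTable(df.iloc[:-1].reset_index())
        # any tree works for the point fit; use the first
        fit = fit_pgls(trees[0], sub, response, predictor, lam=lam0,
                       intersect=True)
        val = fit.intercept + fit.slope * x0
        draws = np.full(n_retained, val)
        params = np.column_stack([
            np.full(n_retained, fit.intercept),
            np.full(n_retained, fit.slope),
            np.zeros(n_retained),
            np.full(n_retained, lam0)])
        return PosteriorPredictive(draws=draws, params=params,
                                   observed=y0_obs, target=target,
                                   response=response, predictor=predictor,
                                   settings=settings, n_trees=len(trees),
                                   seed=seed, acceptance_rate=np.nan)

    def V_blocks(C, lam):
        Vf = C * lam
        np.fill_diagonal(Vf, np.diag(C))
        return Vf[:n, :n], Vf[:n, n], Vf[n, n]

    # initialise at the PGLS fit on the first tree (non-target species)
    sub = TraitTable(df.iloc[:-1].reset_index())
    init = fit_pgls(trees[0], sub, response, predictor,
                    lam="ML" if fix_lambda is None else float(fix_lambda),
                    intersect=True)
    b0, b1 = init.intercept, init.slope
    logs2 = np.log(max(init.sigma2 * init.residual_df / init.n, 1e-12))
    lam = init.lam if fix_lambda is None else float(fix_lambda)

    se = np.sqrt(np.diag(init.beta_cov_unit) * init.sigma2)
    step = np.array([max(se[0], 1e-3), max(se[1], 1e-3),
                     np.sqrt(2.0 / n), 0.1])
    free_lam = fix_lambda is None

    theta = np.array([b0, b1, logs2, lam])

    def loglik(th, C):
        Vn, _, _ = V_blocks(C, th[3])
        resid = y - (th[0] + th[1] * x)
        return _loglik_state(resid, Vn, np.exp(th[2]))

    draws = np.empty(n_retained)
    params = np.empty((n_retained, 4))
    k = 0
    n_acc = 0
    n_prop = 0
    acc_window = 0
    win = 0
    cur_tree = -1
    cur_ll = None
    for it in range(1, iterations + 1):
        tree_idx = int(rng.integers(len(trees)))
        C = Cs[tree_idx]
        if tree_idx != cur_tree or cur_ll is None:
            cur_ll = loglik(theta, C)
            cur_tree = tree_idx
        z = rng.standard_normal(4)
        prop = theta + step * z
        if free_lam:
            prop[3] = _reflect01(prop[3])
        else:
            prop[3] = theta[3]
        try:
            prop_ll = loglik(prop, C)
        except NumericalError:
            prop_ll = -np.inf
        n_prop += 1
        win += 1
        if np.log(rng.uniform()) < prop_ll - cur_ll:
            theta, cur_ll = prop, prop_ll
            n_acc += 1
            acc_window += 1
        if it <= burn_in and win >= 20:
            rate = acc_window / win
            # nudge all step sizes toward the 20–45% acceptance window
            step *= np.exp(rate - 0.3)
            acc_window = 0
            win = 0
        if it > burn_in and (it - burn_in) % thinning == 0 and k < n_retained:
            Vn, v0, v00 = V_blocks(C, theta[3])
            s2 = np.exp(theta[2])
            c, low = linalg.cho_factor(Vn, lower=True)
            Viv0 = linalg.cho_solve((c, low), v0)
            resid = y - (theta[0] + theta[1] * x)
            mean = theta[0] + theta[1] * x0 + float(resid @ Viv0)
            var = s2 * max(v00 - float(v0 @ Viv0), 0.0)
            draws[k] = mean + np.sqrt(var) * rng.standard_normal()
            params[k] = theta
            k += 1
    acc_rate = n_acc / n_prop if n_prop else np.nan
    log.info("MCMC finished: %d retained draws, acceptance %.1f%%",
             k, 100 * acc_rate)
    return PosteriorPredictive(draws=draws[:k], params=params[:k],
                               observed=y0_obs, target=target,
                               response=response, predictor=predictor,
                               settings=settings, n_trees=len(trees),
                               seed=seed, acceptance_rate=acc_rate)


def exceptionality_report(pp: PosteriorPredictive,
                          level: float = 0.95) -> dict:
    """Verdict on whether the observed value is below/within/above the
    level-credible interval of the posterior-predictive draws."""
    if pp.n_draws < 100:
        raise ValidationError(
            f"need >= 100 retained draws; have {pp.n_draws}")
    if not (0.0 < level < 1.0):
        raise ValidationError(f"level must lie in (0,1); got {level}")
    lo, hi = pp.credible_interval(level)
    if pp.observed > hi:
        verdict = "above"
    elif pp.observed < lo:
        verdict = "below"
    else:
        verdict = "within"
    return {
        "target": pp.target,
        "response": pp.response,
        "predictor": pp.predictor,
        "observed": float(pp.observed),
        "percentile": pp.percentile,
        "level": level,
        "interval": [lo, hi],
        "verdict": verdict,
        "n_draws": pp.n_draws,
        "settings": pp.settings,
        "n_trees": pp.n_trees,
        "seed": pp.seed,
    }
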