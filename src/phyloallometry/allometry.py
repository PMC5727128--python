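"""Log–log allometric regression by phylogenetic generalized least squares.

The model: for species trait values on the log₁₀ scale,

    y = β₀ + β₁ x + ε,   ε ~ N(0, σ² V(λ)),

where V(λ) is the phylogenetic covariance of the tree with Pagel's λ applied
to its off-diagonal (shared-history) entries. λ is estimated by maximizing
the profile likelihood over [0, 1] (β and σ² profiled out analytically); a
REML variant is available. At λ=0, or on a star phylogeny, the fit collapses
to ordinary least squares.

σ̂² is reported per unit branch length: the residual quadratic form
r'V(λ)⁻¹r divided by the residual degrees of freedom (n − 2). r² is the GLS
analogue 1 − RSS/TSS with the total sum of squares taken about the
GLS-estimated phylogenetic mean, in the V(λ)⁻¹ metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .errors import NumericalError, ValidationError
from .trees import PhyloTree

__all__ = ["TraitTable", "AllometricFit", "fit_pgls", "profile_lambda",
           "allometry_table"]

log = logging.getLogger(__name__)


class TraitTable:
    """Species × trait table.

    One row per species (labels matched exactly, case-sensitively, to tree
    tips after trimming whitespace); trait columns are numeric. Values are
    stored on the raw scale; the log₁₀ transform happens inside the fits.
    """

    def __init__(self, df: pd.DataFrame, species_col: str | None = None):
        df = df.copy()
        if species_col is not None:
            df = df.set_index(species_col)
        elif df.index.name is None and "species" in df.columns:
            df = df.set_index("species")
        df.index = df.index.astype(str).str.strip()
        df.index.name = "species"
        if df.index.duplicated().any():
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate species rows: {dupes}")
        self.df = df

    @classmethod
    def read(cls, path: str, species_col: str | None = None) -> "TraitTable":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        return cls(pd.read_csv(path, sep=sep), species_col=species_col)

    def write(self, path: str) -> None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        self.df.to_csv(path, sep=sep)

    @property
    def species(self) -> list[str]:
        return list(self.df.index)

    @property
    def traits(self) -> list[str]:
        return [c for c in self.df.columns
                if pd.api.types.is_numeric_dtype(self.df[c])]

    def with_difference(self, minuend: str, subtrahend: str,
                        name: str | None = None) -> "TraitTable":
        """Add a derived raw-scale trait ``minuend − subtrahend`` (e.g.
        brain-minus-olfactory-bulb volume as a scaling denominator)."""
        name = name or f"{minuend}_minus_{subtrahend}"
        df = self.df.copy()
        df[name] = df[minuend] - df[subtrahend]
        return TraitTable(df)

    def column(self, trait: str) -> pd.Series:
        if trait not in self.df.columns:
            raise ValidationError(f"trait {trait!r} not in table "
                                  f"(have {list(self.df.columns)})")
        return self.df[trait]

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class AllometricFit:
    """Result of one PGLS log–log regression, plus the internals the
    prediction machinery needs (covariance in the fitted species order)."""

    response: str
    predictor: str
    slope: float
    intercept: float
    lam: float
    r_squared: float
    sigma2: float
    n: int
    residual_df: int
    loglik: float
    species: list[str]
    lambda_method: str  # "ML", "REML" or "fixed"
    tree_height: float
    # fitted-model internals (species order = `species`)
    V: np.ndarray = field(repr=False, default=None)
    Vinv: np.ndarray = field(repr=False, default=None)
    X: np.ndarray = field(repr=False, default=None)
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    beta_cov_unit: np.ndarray = field(repr=False, default=None)  # (X'V⁻¹X)⁻¹
    residuals: np.ndarray = field(repr=False, default=None)

    def predict(self, x0: float | np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x0, dtype=float)

    def to_row(self) -> dict:
        return {"response": self.response, "predictor": self.predictor,
                "slope": self.slope, "intercept": self.intercept,
                "lambda": self.lam, "r_squared": self.r_squared,
                "sigma2": self.sigma2, "n": self.n,
                "loglik": self.loglik}


def _align(tree: PhyloTree, traits: TraitTable, names: list[str],
           intersect: bool) -> tuple[list[str], pd.DataFrame]:
    tips = set(tree.tip_labels)
    tab = set(traits.species)
    if tips != tab:
        if not intersect:
            diff = sorted(tips.symmetric_difference(tab))
            raise ValidationError(
                "tree tips and trait-table species differ; symmetric "
                f"difference: {diff} (pass intersect=True to drop)")
        common = sorted(tips & tab)
        log.info("intersecting tree and table: keeping %d of %d/%d species",
                 len(common), len(tips), len(tab))
    else:
        common = sorted(tips)
    df = traits.df.loc[common, names]
    for trait in names:
        bad = df.index[~(df[trait] > 0)].tolist()
        if bad:
            raise ValidationError(
                f"trait {trait!r} must be strictly positive for a log10 "
                f"fit; offending species: {bad}")
    return common, df


def _gls_profile(X: np.ndarray, y: np.ndarray, V: np.ndarray, lam: float):
    """GLS estimates and profile quantities for a given covariance.

    Returns (beta, rss, logdetV, XtViX_inv, Vinv). Raises NumericalError if
    V is singular.
    """
    try:
        c, low = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise NumericalError(
            f"phylogenetic covariance singular at lambda={lam:.6g}") from exc
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    ViX = linalg.cho_solve((c, low), X)
    Viy = linalg.cho_solve((c, low), y)
    XtViX = X.T @ ViX
    try:
        XtViX_inv = linalg.inv(XtViX)
    except linalg.LinAlgError as exc:
        raise NumericalError(
            f"design matrix singular under lambda={lam:.6g}") from exc
    beta = XtViX_inv @ (X.T @ Viy)
    resid = y - X @ beta
    rss = float(resid @ linalg.cho_solve((c, low), resid))
    Vinv = linalg.cho_solve((c, low), np.eye(len(y)))
    return beta, rss, logdetV, XtViX_inv, Vinv


def _loglik(X, y, V, lam, reml: bool) -> float:
    n, p = X.shape
    beta, rss, logdetV, XtViX_inv, _ = _gls_profile(X, y, V, lam)
    if reml:
        df = n - p
        s2 = rss / df
        sign, logdetXtViX = np.linalg.slogdet(np.linalg.inv(XtViX_inv))
        return float(-0.5 * (df * np.log(2 * np.pi * s2) + logdetV
                             + logdetXtViX + df))
    s2 = rss / n
    return float(-0.5 * (n * np.log(2 * np.pi * s2) + logdetV + n))


def fit_pgls(tree: PhyloTree, traits: TraitTable, response: str,
             predictor: str, lam: float | str = "ML", *,
             reml: bool = False, intersect: bool = False) -> AllometricFit:
    """Fit ``log10(response) ~ log10(predictor)`` by PGLS.

    ``lam`` may be a fixed value in [0, 1] or ``"ML"`` to estimate Pagel's λ
    by bounded maximum (restricted, if ``reml``) likelihood.
    """
    species, df = _align(tree, traits, [response, predictor], intersect)
    if len(species) < 4:
        raise ValidationError(
            f"need at least 4 species; have {len(species)}")
    y = np.log10(df[response].to_numpy(dtype=float))
    x = np.log10(df[predictor].to_numpy(dtype=float))
    X = np.column_stack([np.ones_like(x), x])
    _, C = tree.shared_path_matrix(order=species)
    diag = np.diag(C).copy()

    def V_of(l):
        V = C * l
        np.fill_diagonal(V, diag)
        return V

    if isinstance(lam, str):
        if lam.upper() != "ML":
            raise ValidationError(f"lam must be a float or 'ML'; got {lam!r}")
        def safe_ll(l):
            try:
                return _loglik(X, y, V_of(l), l, reml)
            except NumericalError:
                return -np.inf
        res = optimize.minimize_scalar(
            lambda l: -safe_ll(l),
            bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-6})
        candidates = [(res.x, -res.fun)]
        for l in (0.0, 1.0):
            candidates.append((l, safe_ll(l)))
        lam_hat, ll = max(candidates, key=lambda t: t[1])
        method = "REML" if reml else "ML"
    else:
        lam_hat = float(lam)
        if not (0.0 <= lam_hat <= 1.0):
            raise ValidationError(f"lambda must lie in [0,1]; got {lam_hat}")
        ll = _loglik(X, y, V_of(lam_hat), lam_hat, reml)
        method = "fixed"

    V = V_of(lam_hat)
    beta, rss, _, XtViX_inv, Vinv = _gls_profile(X, y, V, lam_hat)
    n = len(y)
    residual_df = n - 2
    sigma2 = rss / residual_df
    # GLS r²: total SS about the GLS phylogenetic mean, in the V⁻¹ metric
    ones = np.ones(n)
    mu = float(ones @ Vinv @ y) / float(ones @ Vinv @ ones)
    tss = float((y - mu) @ Vinv @ (y - mu))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    resid = y - X @ beta
    return AllometricFit(
        response=response, predictor=predictor,
        slope=float(beta[1]), intercept=float(beta[0]), lam=lam_hat,
        r_squared=float(np.clip(r2, 0.0, 1.0)), sigma2=float(sigma2),
        n=n, residual_df=residual_df, loglik=float(ll), species=species,
        lambda_method=method, tree_height=float(np.max(diag)),
        V=V, Vinv=Vinv, X=X, x=x, y=y, beta_cov_unit=XtViX_inv,
        residuals=resid)


def profile_lambda(tree: PhyloTree, traits: TraitTable, response: str,
                   predictor: str, grid: list[float] | np.ndarray, *,
                   reml: bool = False,
                   intersect: bool = False) -> pd.DataFrame:
    """Profile log-likelihood of Pagel's λ over a grid (β, σ² profiled out)."""
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValidationError("lambda grid is empty")
    if np.any((grid < 0) | (grid > 1)):
        raise ValidationError("grid values must lie in [0, 1]")
    species, df = _align(tree, traits, [response, predictor], intersect)
    y = np.log10(df[response].to_numpy(dtype=float))
    x = np.log10(df[predictor].to_numpy(dtype=float))
    X = np.column_stack([np.ones_like(x), x])
    _, C = tree.shared_path_matrix(order=species)
    diag = np.diag(C).copy()
    rows = []
    for l in grid:
        V = C * l
        np.fill_diagonal(V, diag)
        rows.append({"lambda": float(l),
                     "loglik": _loglik(X, y, V, l, reml)})
    return pd.DataFrame(rows)


def allometry_table(tree: PhyloTree, traits: TraitTable,
                    pairs: list[tuple], *, lam: float | str = "ML",
                    reml: bool = False,
                    intersect: bool = False) -> pd.DataFrame:
    """Fit a batch of (response, predictor[, subtract]) regressions.

    A three-element pair ``(response, predictor, subtract)`` regresses on
    ``predictor − subtract`` computed on the raw volume scale before the
    log transform (the "brain minus OB" style denominators). Per-row errors
    are recorded in an ``error`` column; remaining rows still run.
    """
    rows = []
    for pair in pairs:
        if len(pair) == 2:
            response, predictor = pair
            subtract = None
        else:
            response, predictor, subtract = pair
        tab = traits
        pred_name = predictor
        try:
            if subtract:
                pred_name = f"{predictor}_minus_{subtract}"
                tab = traits.with_difference(predictor, subtract, pred_name)
            fit = fit_pgls(tree, tab, response, pred_name, lam=lam,
                           reml=reml, intersect=intersect)
            row = fit.to_row()
            row["error"] = ""
        except Exception as exc:
            log.warning("fit %s ~ %s failed: %s", response, pred_name, exc)
            row = {"response": response, "predictor": pred_name,
                   "error": str(exc)}
        rows.append(row)
    cols = ["response", "predictor", "slope", "intercept", "lambda",
            "r_squared", "sigma2", "n", "loglik", "error"]
    out = pd.DataFrame(rows)
    return out.reindex(columns=[c for c in cols if c in out.columns])


def write_fit_table(fits: pd.DataFrame, path: str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fits.to_csv(path, sep="\t", index=False)
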