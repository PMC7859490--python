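"""Linear mixed models with a single genetic relationship kernel.

The model class is

    y = X b + u + e,   u ~ N(0, K sigma_g^2),   e ~ N(0, I sigma_e^2)

with K a pedigree (A) or genomic (G) relationship matrix aligned with y.
:class:`MixedModel.fit` estimates the variance components by REML: K is
eigendecomposed once and the restricted log-likelihood, profiled down to the
single ratio delta = sigma_g^2 / sigma_e^2, is maximised by bounded scalar
search in log delta over [-6, 6]; sigma_e^2 is recovered analytically at the
optimum. The same eigenbasis then gives GLS fixed effects and BLUPs in O(n p)
per evaluation.

:func:`solve_mme` solves Henderson's mixed-model equations directly (used as
the algebraic cross-check of the eigenbasis route), :class:`GBLUP` predicts
breeding values for animals without records, and
:func:`correct_phenotypes` pre-corrects phenotypes for fixed effects under a
pedigree-based animal model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .kinship import build_a_matrix
from .types import Pedigree, RelationshipMatrix

RIDGE = 1e-6
LOG_DELTA_BOUNDS = (-6.0, 6.0)


def build_design_matrix(
    table: pd.DataFrame,
    factors: tuple = ("sex", "contemporary_group"),
    covariates: tuple = ("slaughter_age",),
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design: intercept, reference-level-dropped factor dummies
    and centred covariates. Raises if the result is rank deficient, naming
    the confounded columns."""
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for f in factors:
        if f not in table.columns:
            continue
        d = pd.get_dummies(table[f].astype(str), prefix=f, drop_first=True)
        for c in d.columns:
            cols.append(d[c].to_numpy(dtype=np.float64))
            names.append(c)
    for c in covariates:
        if c not in table.columns:
            continue
        v = table[c].to_numpy(dtype=np.float64)
        cols.append(v - v.mean())
        names.append(c)
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"rank-deficient fixed design ({rank} < {x.shape[1]}): "
            f"confounded columns among {names[1:]}"
        )
    return x, names


@dataclass
class VarianceComponents:
    """REML variance components for one trait and one relationship matrix."""

    sigma2_g: float
    sigma2_e: float
    reml_loglik: float
    converged: bool
    n_iterations: int
    at_boundary: bool = False

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0

    @property
    def delta(self) -> float:
        return self.sigma2_g / self.sigma2_e if self.sigma2_e > 0 else np.inf


class MixedModel:
    """Single-kernel linear mixed model fitted by REML.

    Parameters
    ----------
    y : (n,) observations.
    X : (n, p) full-column-rank fixed-effect design (with intercept).
    K : RelationshipMatrix or (n, n) array aligned with ``y``.
    ids : optional animal ids, taken from ``K`` when it is a
        RelationshipMatrix.
    """

    def __init__(self, y, X, K, ids=None):
        self.y = np.asarray(y, dtype=np.float64)
        self.X = np.asarray(X, dtype=np.float64)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if isinstance(K, RelationshipMatrix):
            self.ids = list(K.ids) if ids is None else list(ids)
            K = K.values
        else:
            self.ids = list(ids) if ids is not None else None
        self.K = np.asarray(K, dtype=np.float64)
        n = len(self.y)
        if self.K.shape != (n, n) or self.X.shape[0] != n:
            raise ValueError("y, X and K dimensions disagree")
        p = self.X.shape[1]
        if n <= p + 1:
            raise ValueError("too few records for REML (n <= p + 1)")
        if np.linalg.matrix_rank(self.X) < p:
            raise ValueError("fixed design is rank deficient")
        if np.var(self.y) <= 0:
            raise ValueError("degenerate data: y has no variance")
        # one eigendecomposition serves every likelihood evaluation
        d, u = np.linalg.eigh(self.K)
        # single-precision GRM builds can leave tiny negative eigenvalues
        if d.min() < -1e-4 * max(1.0, d.max()):
            raise ValueError("relationship matrix is not PSD (beyond ridge)")
        self._d = np.maximum(d, 0.0)
        self._u = u
        self._yt = u.T @ self.y
        self._xt = u.T @ self.X
        self._n, self._p = n, p

    # -- restricted likelihood ------------------------------------------------
    def _profile(self, log_delta: float):
        """Profile REML pieces at ratio delta: returns (loglik, sigma2_e, bt)."""
        delta = np.exp(log_delta)
        w = delta * self._d + 1.0
        xw = self._xt / w[:, None]
        xtx = xw.T @ self._xt
        xty = xw.T @ self._yt
        chol = np.linalg.cholesky(xtx)
        b = np.linalg.solve(xtx, xty)
        r = self._yt - self._xt @ b
        q = np.sum(r * r / w)
        nf = self._n - self._p
        sigma2_e = q / nf
        logdet_xvx = 2.0 * np.sum(np.log(np.diag(chol)))
        ll = -0.5 * (
            nf * np.log(2.0 * np.pi * sigma2_e)
            + np.sum(np.log(w))
            + logdet_xvx
            + nf
        )
        return ll, sigma2_e, b

    def reml_loglik(self, log_delta: float) -> float:
        """Profiled restricted log-likelihood at log(sigma_g^2 / sigma_e^2)."""
        return self._profile(log_delta)[0]

    def fit(self, grad_tol: float = 1e-6) -> "MixedModelResults":
        lo, hi = LOG_DELTA_BOUNDS
        res = optimize.minimize_scalar(
            lambda t: -self.reml_loglik(t),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10, "maxiter": 500},
        )
        log_delta = float(res.x)
        # the bounded optimiser never returns the exact bound; snap if better
        for edge in (lo, hi):
            if self.reml_loglik(edge) > -res.fun:
                log_delta = edge
        ll, sigma2_e, b = self._profile(log_delta)
        h = 1e-4
        grad = (self.reml_loglik(log_delta + h) - self.reml_loglik(log_delta - h)) / (2 * h)
        at_boundary = log_delta <= lo + 1e-6 or log_delta >= hi - 1e-6
        converged = bool(abs(grad) < grad_tol) and not at_boundary
        delta = np.exp(log_delta)
        vc = VarianceComponents(
            sigma2_g=float(delta * sigma2_e),
            sigma2_e=float(sigma2_e),
            reml_loglik=float(ll),
            converged=converged,
            n_iterations=int(res.nfev),
            at_boundary=at_boundary,
        )
        return MixedModelResults(self, vc, log_delta, b)


@dataclass
class MixedModelResults:
    """REML estimates plus GLS fixed effects and BLUPs at the optimum."""

    model: MixedModel
    vc: VarianceComponents
    log_delta: float
    _b: np.ndarray

    @property
    def fixed_effects(self) -> np.ndarray:
        return self._b

    def fixed_effects_series(self, names) -> pd.Series:
        return pd.Series(self._b, index=list(names))

    @property
    def h2(self) -> float:
        return self.vc.h2

    def blups(self) -> np.ndarray:
        """u_hat = delta K V*^-1 (y - X b), computed in the eigenbasis."""
        m = self.model
        delta = np.exp(self.log_delta)
        w = delta * m._d + 1.0
        r = (m._yt - m._xt @ self._b) / w
        return m._u @ (delta * m._d * r)

    def fitted_fixed(self) -> np.ndarray:
        return self.model.X @ self._b

    def summary(self) -> str:
        vc = self.vc
        lines = [
            "Mixed model REML results",
            "=" * 40,
            f"n records        {self.model._n}",
            f"fixed effects    {self.model._p}",
            f"sigma2_g         {vc.sigma2_g:.6g}",
            f"sigma2_e         {vc.sigma2_e:.6g}",
            f"h2               {vc.h2:.4f}",
            f"REML loglik      {vc.reml_loglik:.4f}",
            f"converged        {vc.converged}"
            + ("  (boundary)" if vc.at_boundary else ""),
        ]
        return "\n".join(lines)


def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    K: np.ndarray | RelationshipMatrix,
    lam: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Henderson's mixed-model equations for y = Xb + Zu + e.

    ``lam`` is the variance ratio sigma_e^2 / sigma_u^2. Returns (b_hat,
    u_hat). K is inverted with a 1e-6 ridge when needed; the ridge is never
    stored back.
    """
    if isinstance(K, RelationshipMatrix):
        K = K.values
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    Z = np.asarray(Z, dtype=np.float64)
    if np.isinf(lam):
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        return b, np.zeros(K.shape[0])
    try:
        kinv = np.linalg.inv(K)
    except np.linalg.LinAlgError:
        kinv = np.linalg.inv(K + RIDGE * np.eye(K.shape[0]))
    p, q = X.shape[1], Z.shape[1]
    lhs = np.empty((p + q, p + q))
    lhs[:p, :p] = X.T @ X
    lhs[:p, p:] = X.T @ Z
    lhs[p:, :p] = lhs[:p, p:].T
    lhs[p:, p:] = Z.T @ Z + kinv * lam
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("MME system singular: check fixed-design rank") from exc
    return sol[:p], sol[p:]


class GBLUP:
    """Genomic BLUP: predict breeding values for all animals in G.

    Training animals carry corrected-phenotype records; validation animals
    are treated as record-free. With V = sigma_g^2 G_tt + sigma_e^2 I on the
    training block, the overall mean is estimated by GLS and
    g_hat = sigma_g^2 G[:, t] V^-1 (yc_t - mu_hat) for every animal in G.
    """

    def __init__(
        self,
        yc_train: pd.Series,
        G_all: RelationshipMatrix,
        vc: VarianceComponents | None = None,
    ):
        if len(yc_train) == 0:
            raise ValueError("empty training set")
        self.yc = yc_train.astype(np.float64)
        self.G = G_all
        self.train_idx = G_all.index_of(list(yc_train.index))
        self.vc = vc

    def fit(self) -> "GBLUPResults":
        t = self.train_idx
        g_tt = self.G.values[np.ix_(t, t)]
        vc = self.vc
        if vc is None:
            x = np.ones((len(t), 1))
            vc = MixedModel(self.yc.to_numpy(), x, g_tt).fit().vc
        y = self.yc.to_numpy()
        n_t = len(t)
        if vc.sigma2_g <= 0:
            mu = y.mean()
            gebv = np.zeros(self.G.n)
        else:
            from scipy.linalg import cho_factor, cho_solve

            v = vc.sigma2_g * g_tt + vc.sigma2_e * np.eye(n_t)
            try:
                cf = cho_factor(v, lower=True)
            except np.linalg.LinAlgError:
                v += RIDGE * np.eye(n_t)
                cf = cho_factor(v, lower=True)
            rhs = np.column_stack([y, np.ones(n_t)])
            sol = cho_solve(cf, rhs)
            mu = float(np.ones(n_t) @ sol[:, 0] / (np.ones(n_t) @ sol[:, 1]))
            alpha = sol[:, 0] - mu * sol[:, 1]
            gebv = vc.sigma2_g * (self.G.values[:, t] @ alpha)
        trained = np.zeros(self.G.n, dtype=bool)
        trained[t] = True
        table = pd.DataFrame(
            {"animal_id": self.G.ids, "gebv": gebv, "trained_on": trained}
        )
        return GBLUPResults(model=self, vc=vc, mu=mu, gebv_table=table)


@dataclass
class GBLUPResults:
    model: GBLUP
    vc: VarianceComponents
    mu: float
    gebv_table: pd.DataFrame

    def gebv(self, ids=None) -> pd.Series:
        s = self.gebv_table.set_index("animal_id")["gebv"]
        return s if ids is None else s.loc[list(ids)]

    def summary(self) -> str:
        n_train = int(self.gebv_table["trained_on"].sum())
        return (
            "GBLUP results\n"
            + "=" * 40
            + f"\nanimals          {len(self.gebv_table)}"
            + f"\ntrained on       {n_train}"
            + f"\nmu               {self.mu:.6g}"
            + f"\nsigma2_g         {self.vc.sigma2_g:.6g}"
            + f"\nsigma2_e         {self.vc.sigma2_e:.6g}"
            + f"\nh2               {self.vc.h2:.4f}"
        )


@dataclass
class CorrectionResult:
    """Fixed-effect estimates and corrected phenotypes yc = y - X b_hat."""

    fixed_effects: pd.Series
    corrected: pd.Series
    vc: VarianceComponents


def correct_phenotypes(
    phenotypes: pd.DataFrame,
    pedigree: Pedigree,
    trait: str,
    factors: tuple = ("sex", "contemporary_group"),
    covariates: tuple = ("slaughter_age",),
    a_matrix: RelationshipMatrix | None = None,
) -> CorrectionResult:
    """Pre-correct one trait for fixed effects under a pedigree animal model.

    Fits y = Xb + a + e with a ~ N(0, A sigma_a^2) by REML (A restricted to
    the phenotyped animals, which leaves the marginal model unchanged) and
    returns yc = y - X b_hat; random effects are deliberately NOT removed.
    """
    ids = list(phenotypes["animal_id"])
    ped_ids = set(pedigree.animal_ids)
    orphans = [a for a in ids if a not in ped_ids]
    if orphans:
        raise ValueError(f"phenotyped animals missing from pedigree: {orphans[:5]}")
    if a_matrix is None:
        a_matrix = build_a_matrix(pedigree)
    a_sub = a_matrix.subset(ids)
    x, names = build_design_matrix(phenotypes, factors, covariates)
    y = phenotypes[trait].to_numpy(dtype=np.float64)
    fit = MixedModel(y, x, a_sub.values).fit()
    yc = y - x @ fit.fixed_effects
    return CorrectionResult(
        fixed_effects=fit.fixed_effects_series(names),
        corrected=pd.Series(yc, index=ids, name=f"{trait}_corrected"),
        vc=fit.vc,
    )
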