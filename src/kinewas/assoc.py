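"""Per-probe kinship-aware mixed-model association of methylation with age.

For one probe, the M value of individual *i* is modeled as

    Y_i = mu + X_i beta + g_i + eps_i

with fixed effects X (age in years, sex, five cell-type proportions), an
additive polygenic effect g with covariance ``2 Phi sigma_g^2`` (Phi the
pedigree kinship matrix), and iid residual noise with variance
``sigma_eps^2``.  Under this model

    cov(Y_i, Y_j) = 2 phi_ij sigma_g^2          (i != j)
    var(Y_i)      = sigma_g^2 + sigma_eps^2     (non-inbred diagonal)

All parameters are estimated by maximum likelihood. The covariance is
diagonalized once per cohort: with ``2 Phi = U diag(lam) U'``, rotating y and X
by ``U'`` gives independent observations with variances
``sigma^2 (h2 lam_k + 1 - h2)`` where ``h2 = sigma_g^2 / (sigma_g^2 +
sigma_eps^2)``.  For fixed h2 the GLS coefficients and the total variance
``sigma^2`` profile out in closed form, leaving a 1-D bounded search over h2.

The age association P value is a likelihood-ratio chi-square test (1 df)
comparing the ML fits with and without the age column; a Wald z test on the
age coefficient is available as a cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .pedigree import KinshipMatrix

__all__ = [
    "AssociationModel",
    "AssociationResult",
    "SignificanceConfig",
    "KinshipCovariance",
    "fit_probe",
    "test_age",
    "bonferroni_threshold",
    "run_ewas",
    "direction_summary",
]

H2_UPPER = 1.0 - 1e-6
OPT_XATOL = 1e-8
PSD_TOL = -1e-8

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class SignificanceConfig:
    """Family-wise error control for the genome-wide scan."""

    alpha: float = 0.05
    n_tests: int = 1

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")


def bonferroni_threshold(cfg: SignificanceConfig) -> float:
    """Genome-wide significance cutoff ``alpha / n_tests``."""
    return cfg.alpha / cfg.n_tests


class KinshipCovariance:
    """One-time eigendecomposition of ``2 Phi`` shared across a probe scan."""

    def __init__(self, K: KinshipMatrix | np.ndarray):
        two_phi = K.two_phi if isinstance(K, KinshipMatrix) else np.asarray(K, float)
        if two_phi.shape[0] != two_phi.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(two_phi, two_phi.T):
            raise ValueError("kinship matrix must be symmetric")
        lam, U = np.linalg.eigh(two_phi)
        if lam.min() < PSD_TOL:
            raise ValueError(
                f"2*Phi has eigenvalue {lam.min():.3g} below tolerance; not PSD"
            )
        self.lam = np.clip(lam, 0.0, None)
        self.U = U
        self.n = two_phi.shape[0]

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.U.T @ a


@dataclass
class _Fit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_g: float
    sigma2_e: float
    h2: float
    loglik: float
    converged: bool


@dataclass
class AssociationModel:
    """Fitted mixed model for one probe: full fit plus what a re-fit needs."""

    column_names: list[str]  # fitted fixed-effect names, intercept first
    fit: _Fit
    cov: KinshipCovariance
    yt: np.ndarray  # rotated response
    Xt: np.ndarray  # rotated design (incl. intercept)
    n_samples: int
    dropped: list[str] = field(default_factory=list)  # constant columns excluded

    def coef(self, name: str) -> tuple[float, float]:
        """(estimate, standard error) for one fixed effect."""
        if name in self.dropped:
            return np.nan, np.nan
        k = self.column_names.index(name)
        return float(self.fit.beta[k]), float(np.sqrt(self.fit.cov_beta[k, k]))


@dataclass
class AssociationResult:
    probe_id: str
    beta_age: float
    se_age: float
    p_age: float
    beta_sex: float
    sigma2_g: float
    sigma2_e: float
    h2: float
    converged: bool
    n_samples: int


# ---------------------------------------------------------------------------
# Profiled likelihood machinery
# ---------------------------------------------------------------------------

def _profile(h2: float, lam: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """GLS fit at fixed variance ratio; returns (-loglik, beta, XtWX_inv, sigma2)."""
    n = yt.shape[0]
    w = h2 * lam + (1.0 - h2)
    if np.any(w <= 0):
        return np.inf, None, None, None
    sw = 1.0 / np.sqrt(w)
    Xw = Xt * sw[:, None]
    yw = yt * sw
    gram = Xw.T @ Xw
    try:
        gram_inv = np.linalg.inv(gram)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular fixed-effect design") from None
    beta = gram_inv @ (Xw.T @ yw)
    r = yw - Xw @ beta
    sigma2 = float(r @ r) / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    ll = -0.5 * (n * _LOG2PI + n * math.log(sigma2) + float(np.sum(np.log(w))) + n)
    return -ll, beta, gram_inv, sigma2


def _ml_fit(cov: KinshipCovariance, yt: np.ndarray, Xt: np.ndarray) -> _Fit:
    lam = cov.lam
    neg_ll = lambda h2: _profile(h2, lam, yt, Xt)[0]
    try:
        res = minimize_scalar(
            neg_ll, bounds=(0.0, H2_UPPER), method="bounded",
            options={"xatol": OPT_XATOL},
        )
        # the bounded search never evaluates the exact endpoints; check h2=0
        candidates = [(neg_ll(0.0), 0.0)]
        if res.success and np.isfinite(res.fun):
            candidates.append((float(res.fun), float(res.x)))
        nll, h2 = min(candidates)
        converged = np.isfinite(nll)
    except np.linalg.LinAlgError:
        raise
    if not converged:
        return _Fit(np.full(Xt.shape[1], np.nan), np.full((Xt.shape[1],) * 2, np.nan),
                    np.nan, np.nan, np.nan, -np.inf, False)
    _, beta, gram_inv, sigma2 = _profile(h2, lam, yt, Xt)
    return _Fit(
        beta=beta,
        cov_beta=gram_inv * sigma2,
        sigma2_g=h2 * sigma2,
        sigma2_e=(1.0 - h2) * sigma2,
        h2=h2,
        loglik=-nll,
        converged=True,
    )


def _design(X: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Intercept-augmented design; constant columns are dropped with a warning.

    A constant covariate is collinear with the intercept and carries no
    information, so dropping it keeps the design full-rank while letting a
    test on that term report a zero likelihood ratio (p = 1 by convention).
    """
    vals = X.to_numpy(float)
    const = np.all(vals == vals[0:1, :], axis=0) if len(vals) else np.zeros(0, bool)
    dropped = [str(c) for c, k in zip(X.columns, const) if k]
    if dropped:
        warnings.warn(f"dropping constant covariate column(s): {dropped}", stacklevel=3)
    keep = [c for c, k in zip(X.columns, const) if not k]
    names = ["intercept"] + [str(c) for c in keep]
    mat = np.column_stack([np.ones(len(X)), vals[:, ~const]])
    return mat, names, dropped


def fit_probe(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    K: KinshipMatrix | KinshipCovariance,
) -> AssociationModel:
    """ML fit of the polygenic mixed model for one probe.

    ``y`` holds the per-sample M values, ``X`` the fixed-effect columns
    (without intercept; one is added), and ``K`` the kinship structure. Rows
    of y, X and K must be aligned to the same samples in the same order.
    """
    yv = np.asarray(y, dtype=float)
    cov = K if isinstance(K, KinshipCovariance) else KinshipCovariance(K)
    if len(yv) != cov.n or len(X) != cov.n:
        raise ValueError("y, X and kinship matrix are not sample-aligned")
    n_fixed = X.shape[1] + 1
    if cov.n <= n_fixed + 1:
        raise ValueError(f"need n > {n_fixed + 1} samples to fit {n_fixed} fixed effects")
    mat, names, dropped = _design(X)
    yt = cov.rotate(yv)
    Xt = cov.rotate(mat)
    fit = _ml_fit(cov, yt, Xt)
    return AssociationModel(
        column_names=names, fit=fit, cov=cov, yt=yt, Xt=Xt, n_samples=cov.n,
        dropped=dropped,
    )


def lrt_drop_term(model: AssociationModel, term: str) -> tuple[float, float, bool]:
    """Likelihood-ratio test (1 df) of dropping one fixed-effect column.

    Returns ``(statistic, p, converged)``. A column that is constant after
    rotation adds nothing to the full model, giving a zero statistic and
    p = 1 by convention.
    """
    if term in model.dropped:
        return 0.0, 1.0, True
    if term not in model.column_names:
        raise ValueError(f"term {term!r} not in design ({model.column_names})")
    if not model.fit.converged:
        return np.nan, np.nan, False
    k = model.column_names.index(term)
    Xt0 = np.delete(model.Xt, k, axis=1)
    fit0 = _ml_fit(model.cov, model.yt, Xt0)
    if not fit0.converged:
        return np.nan, np.nan, False
    stat = max(0.0, 2.0 * (model.fit.loglik - fit0.loglik))
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return stat, p, True


def test_age(
    model: AssociationModel,
    probe_id: str = "",
    age_col: str = "age",
    sex_col: str = "sex",
    test: str = "lrt",
) -> AssociationResult:
    """Age-association test for a fitted probe model.

    ``test='lrt'`` (default) uses the likelihood-ratio chi-square with 1 df;
    ``'wald'`` uses the z statistic on the age coefficient.
    """
    if test not in ("lrt", "wald"):
        raise ValueError(f"test must be 'lrt' or 'wald', got {test!r}")
    f = model.fit
    if not f.converged:
        return AssociationResult(probe_id, np.nan, np.nan, np.nan, np.nan,
                                 np.nan, np.nan, np.nan, False, model.n_samples)
    beta_age, se_age = model.coef(age_col)
    beta_sex = model.coef(sex_col)[0] if sex_col in model.column_names else np.nan
    if age_col in model.dropped:
        p_age, ok = 1.0, True
    elif test == "lrt":
        _, p_age, ok = lrt_drop_term(model, age_col)
    else:
        z = beta_age / se_age if se_age > 0 else 0.0
        p_age, ok = float(2.0 * stats.norm.sf(abs(z))), True
        if se_age == 0:
            p_age = 1.0
    return AssociationResult(
        probe_id=probe_id,
        beta_age=beta_age,
        se_age=se_age,
        p_age=p_age,
        beta_sex=beta_sex,
        sigma2_g=f.sigma2_g,
        sigma2_e=f.sigma2_e,
        h2=f.h2,
        converged=ok,
        n_samples=model.n_samples,
    )


# ---------------------------------------------------------------------------
# Genome-wide scan
# ---------------------------------------------------------------------------

def run_ewas(
    m_matrix: pd.DataFrame,
    phenotypes: pd.DataFrame,
    K: KinshipMatrix,
    cell_covariates: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    sig: SignificanceConfig | None = None,
    test: str = "lrt",
    age_col: str = "age",
    sex_col: str = "sex",
) -> pd.DataFrame:
    """Scan every probe of an M matrix for age association.

    ``m_matrix`` is probe x sample; ``phenotypes`` must carry ``age`` and
    ``sex`` indexed by sample id; ``cell_covariates`` the five cell-proportion
    columns. Samples with missing age or sex are dropped (complete-case)
    before the scan. Per-probe failures are flagged, never raised.

    Returns a DataFrame indexed by probe id with the association estimates, a
    ``significant`` column at the Bonferroni threshold over the scanned
    probes, and annotation columns when an annotation table is supplied.
    """
    samples = [s for s in m_matrix.columns if s in phenotypes.index]
    pheno = phenotypes.loc[samples, [age_col, sex_col]]
    keep = pheno.notna().all(axis=1)
    if not keep.all():
        warnings.warn(
            f"dropping {(~keep).sum()} samples with missing {age_col}/{sex_col}",
            stacklevel=2,
        )
    samples = [s for s, k in zip(samples, keep) if k]
    X = phenotypes.loc[samples, [age_col, sex_col]].astype(float)
    if cell_covariates is not None:
        X = X.join(cell_covariates.loc[samples].astype(float))
    order = [K.sample_ids.index(s) for s in samples]
    cov = KinshipCovariance(K.two_phi[np.ix_(order, order)])
    mat, names, dropped = _design(X)
    Xt = cov.rotate(mat)
    Yt = cov.rotate(m_matrix[samples].to_numpy(float).T)  # n x probes

    rows = []
    for j, probe in enumerate(m_matrix.index):
        try:
            fit = _ml_fit(cov, Yt[:, j], Xt)
            model = AssociationModel(names, fit, cov, Yt[:, j], Xt, len(samples),
                                     dropped=dropped)
            res = test_age(model, probe_id=str(probe), age_col=age_col,
                           sex_col=sex_col, test=test)
        except np.linalg.LinAlgError:
            res = AssociationResult(str(probe), np.nan, np.nan, np.nan, np.nan,
                                    np.nan, np.nan, np.nan, False, len(samples))
        rows.append(res)

    out = pd.DataFrame([vars(r) for r in rows]).set_index("probe_id")
    sig = sig or SignificanceConfig(n_tests=out.shape[0])
    thr = bonferroni_threshold(sig)
    out["significant"] = (out["p_age"] < thr) & out["converged"]
    if annotation is not None:
        out = out.join(annotation, how="left")
    out.attrs["bonferroni_threshold"] = thr  # set last: join drops attrs
    return out


def direction_summary(results: pd.DataFrame) -> dict:
    """Counts of significant probes gaining vs losing methylation with age.

    Returns total significant sites, positive and negative slope counts and
    the positive/negative ratio (methylation increasing vs decreasing).
    """
    sig = results[results["significant"].astype(bool)]
    n_pos = int((sig["beta_age"] > 0).sum())
    n_neg = int((sig["beta_age"] < 0).sum())
    return {
        "n_significant": int(sig.shape[0]),
        "n_positive": n_pos,
        "n_negative": n_neg,
        "ratio_pos_neg": (n_pos / n_neg) if n_neg else math.inf,
    }
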