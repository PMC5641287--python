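"""G-BLUP mixed model: Henderson's equations, the variance ratio, and REML.

The model is ``y = X beta + Z u + e`` with ``u ~ N(0, K sigma_g^2)``,
``e ~ N(0, I sigma_e^2)`` and ``lambda = sigma_e^2 / sigma_g^2``. The
fixed part defaults to a single intercept. Predictions (GEBV) solve

    [ X'X        X'Z          ] [beta_hat]   [X'y]
    [ Z'X   Z'Z + lambda K^-1 ] [u_hat   ] = [Z'y]

over a model set that may include unphenotyped target individuals; their
GEBV are obtained through their relationship to the calibration set.

Because K is exactly singular whenever the allele frequencies were
computed on the genotyped set itself (rows of K sum to zero), every
inversion of K in this package adds a small diagonal ridge
(``DEFAULT_RIDGE``) first; the ridge is used consistently here and in the
reliability (CD) computations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import minimize_scalar

from .genotypes import KinshipMatrix

#: diagonal ridge added to K before inversion, everywhere in the package
DEFAULT_RIDGE = 1e-6

#: REML search interval for lambda = sigma_e^2 / sigma_g^2
LAMBDA_BOUNDS = (1e-4, 1e4)


def lambda_from_h2(h2: float) -> float:
    """Variance ratio implied by a heritability: ``lambda = 1/h2 - 1``.

    h2 = 0.5 gives lambda = 1, the conventional choice when no phenotypes
    are available yet (calibration-set optimization before phenotyping).
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError(f"h2 must lie strictly in (0, 1), got {h2}")
    return 1.0 / h2 - 1.0


def ridged(K: np.ndarray, ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    return K + ridge * np.eye(K.shape[0])


@dataclass
class MixedModelSpec:
    """Which records calibrate the model, which individuals it predicts.

    ``model_ids`` is the full individual set entering ``u`` (calibration
    plus targets, in stable order); ``calibration_ids`` are the subset
    with phenotype records. ``fixed_design`` is the X matrix over records
    (one row per calibration record); None means a single intercept.
    """

    calibration_ids: list[str]
    model_ids: list[str]
    lam: float
    fixed_design: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calibration_ids = [str(i) for i in self.calibration_ids]
        self.model_ids = [str(i) for i in self.model_ids]
        if not np.isfinite(self.lam) or self.lam <= 0:
            raise ValueError(f"lambda must be a finite positive real, got {self.lam}")
        missing = set(self.calibration_ids) - set(self.model_ids)
        if missing:
            raise ValueError(f"calibration ids not in model set: {sorted(missing)[:5]}")
        if self.fixed_design is not None:
            self.fixed_design = np.atleast_2d(np.asarray(self.fixed_design, float))
            if self.fixed_design.shape[0] != len(self.calibration_ids):
                raise ValueError("fixed_design must have one row per record")


@dataclass
class BlupSolution:
    """Solution of the mixed-model equations.

    ``u_hat`` covers every model individual (calibration and targets);
    ``coeff_inverse`` is the inverse MME coefficient matrix, retained so
    that prediction error variances can be read off without re-solving.
    """

    beta_hat: np.ndarray
    u_hat: pd.Series
    coeff_inverse: np.ndarray


def incidence(calibration_ids, model_ids) -> np.ndarray:
    """Records x model-individuals 0/1 incidence matrix Z."""
    pos = {ind: k for k, ind in enumerate(model_ids)}
    Z = np.zeros((len(calibration_ids), len(model_ids)))
    for r, ind in enumerate(calibration_ids):
        Z[r, pos[ind]] = 1.0
    return Z


def solve_gblup(
    y: np.ndarray | pd.Series,
    K: KinshipMatrix,
    spec: MixedModelSpec,
    ridge: float = DEFAULT_RIDGE,
) -> BlupSolution:
    """Solve Henderson's equations for the G-BLUP model.

    ``y`` holds one phenotype per calibration record (a Series is aligned
    on its index to ``spec.calibration_ids``). ``K`` may cover a superset
    of the model set; it is restricted to ``spec.model_ids``.
    """
    if isinstance(y, pd.Series):
        y = y.loc[spec.calibration_ids].to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
    if y.shape != (len(spec.calibration_ids),):
        raise ValueError(
            f"y has shape {y.shape}, expected ({len(spec.calibration_ids)},)"
        )
    Ksub = K.subset(spec.model_ids).K if K.individual_ids != spec.model_ids else K.K
    n, N = len(spec.calibration_ids), len(spec.model_ids)
    Z = incidence(spec.calibration_ids, spec.model_ids)
    X = spec.fixed_design if spec.fixed_design is not None else np.ones((n, 1))
    Kinv = np.linalg.inv(ridged(Ksub, ridge))
    C = np.block(
        [[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + spec.lam * Kinv]]
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular mixed-model coefficient matrix (after ridge); "
            "check the fixed-effect design for rank deficiency"
        ) from exc
    sol = Cinv @ rhs
    p = X.shape[1]
    return BlupSolution(
        beta_hat=sol[:p],
        u_hat=pd.Series(sol[p:], index=spec.model_ids, name="u_hat"),
        coeff_inverse=Cinv,
    )


# ---------------------------------------------------------------------------
# REML estimation of lambda
# ---------------------------------------------------------------------------


def _restricted_spectrum(
    y: np.ndarray, K: np.ndarray, ridge: float
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues d and rotated data w of the intercept-projected problem."""
    n = len(y)
    P = null_space(np.ones((1, n)))  # n x (n-1) orthonormal basis of 1-perp
    Kt = P.T @ ridged(K, ridge) @ P
    d, U = np.linalg.eigh((Kt + Kt.T) / 2.0)
    d = np.clip(d, 0.0, None)
    w = U.T @ (P.T @ y)
    return d, w


def _profile_loglik(lam: float, d: np.ndarray, w: np.ndarray) -> float:
    """Restricted log-likelihood profiled over sigma_g^2, up to a constant."""
    m = len(d)
    sg2 = float(np.mean(w**2 / (d + lam)))
    return -0.5 * (m * np.log(sg2) + float(np.sum(np.log(d + lam))) + m)


def reml_loglikelihood(
    y: np.ndarray | pd.Series,
    K: KinshipMatrix,
    lam: float,
    ridge: float = DEFAULT_RIDGE,
) -> float:
    """Profiled restricted log-likelihood of the intercept+polygenic model.

    Up to an additive constant; useful for checking that the estimator
    returns a maximizer.
    """
    y = np.asarray(y, dtype=float)
    d, w = _restricted_spectrum(y, K.K, ridge)
    return _profile_loglik(lam, d, w)


def estimate_lambda_reml(
    y: np.ndarray | pd.Series,
    K: KinshipMatrix,
    ridge: float = DEFAULT_RIDGE,
) -> tuple[float, float, float]:
    """REML estimates ``(lambda, sigma_g^2, sigma_e^2)`` from calibration data.

    The model is an intercept plus a polygenic term with covariance
    ``K sigma_g^2``. After projecting out the intercept and rotating to
    the eigenbasis of K the restricted likelihood is one-dimensional in
    lambda; it is maximized by a bounded golden-section/parabolic search
    on log(lambda) over ``LAMBDA_BOUNDS`` (tolerance 1e-6). If K is
    numerically proportional to the identity the two components are not
    identifiable: a warning is issued and a boundary estimate returned.
    """
    y = y.to_numpy(dtype=float) if isinstance(y, pd.Series) else np.asarray(y, float)
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("REML needs at least 3 records")
    if K.n != len(y):
        raise ValueError("K must cover exactly the calibration records")
    d, w = _restricted_spectrum(y, K.K, ridge)
    if np.ptp(d) <= 1e-8 * max(1.0, float(d.max())):
        warnings.warn(
            "K is numerically proportional to the identity; sigma_g^2 and "
            "sigma_e^2 are not identifiable and a boundary estimate of "
            "lambda will be returned",
            UserWarning,
            stacklevel=2,
        )
    lo, hi = np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])
    res = minimize_scalar(
        lambda t: -_profile_loglik(np.exp(t), d, w),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(np.exp(res.x))
    # a boundary point can beat the interior optimum when the optimum is at an edge
    for edge in LAMBDA_BOUNDS:
        if _profile_loglik(edge, d, w) > _profile_loglik(lam, d, w):
            lam = float(edge)
    sg2 = float(np.mean(w**2 / (d + lam)))
    return lam, sg2, lam * sg2
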