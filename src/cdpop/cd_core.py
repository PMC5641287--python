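"""Generalized coefficient of determination (CD) of contrasts, and the
criteria built on it for structured populations.

The reliability of predicting a contrast ``c`` (any weight vector with
``1'c = 0``) of genetic values under G-BLUP is

    CD(c) = c' (K - lambda (Z'MZ + lambda K^-1)^-1) c / (c' K c)

with M the projector orthogonal to the fixed-effect design over records
(for the default intercept, ``M = I - 11'/n``), Z the incidence of the
calibration records on the model individuals and
``lambda = sigma_e^2 / sigma_g^2``. CD is the squared correlation between
the true and the predicted contrast, i.e. the expected reliability; the
related prediction error variance is

    PEV(c) = c' (Z'MZ + lambda K^-1)^-1 c / (c'c) * sigma_e^2.

For a structured target population the relevant contrasts compare each
target individual to the mean of its family (within-family Mendelian
sampling) or to the mean of all targets (structure-ignoring). Averaging
the square roots of those CDs gives the forecast accuracies:

* ``cdpop``      — mean sqrt(CD) of individual-vs-family-mean contrasts
                   of one family (within-family accuracy forecast),
* ``cdpop_mean`` — unweighted mean of the per-family cdpop values,
* ``cdallnam``   — mean sqrt(CD) of individual-vs-overall-mean contrasts
                   over all targets (global accuracy forecast).

``crit_kin`` (mean calibration-target relationship) is the baseline
criterion the CD criteria are compared against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .gblup import DEFAULT_RIDGE, incidence, ridged
from .genotypes import KinshipMatrix

#: negative CD values beyond this magnitude indicate numerical failure
NEGATIVE_CD_TOLERANCE = 1e-9


@dataclass
class ContrastMatrix:
    """Columns of contrast weights over an ordered model individual set."""

    model_ids: list[str]
    C: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.model_ids = [str(i) for i in self.model_ids]
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        if self.C.shape[0] != len(self.model_ids):
            raise ValueError(
                f"contrast matrix has {self.C.shape[0]} rows for "
                f"{len(self.model_ids)} model ids"
            )
        sums = self.C.sum(axis=0)
        if np.abs(sums).max(initial=0.0) > 1e-12:
            raise ValueError(f"contrast columns must sum to 0 (got sums {sums})")
        if self.C.shape[1] and not np.abs(self.C).max(axis=0).all():
            raise ValueError("all-zero contrast column")
        if self.labels is None:
            self.labels = [f"c{k}" for k in range(self.C.shape[1])]
        if len(self.labels) != self.C.shape[1]:
            raise ValueError("one label per contrast column required")

    @property
    def n_contrasts(self) -> int:
        return self.C.shape[1]


@dataclass
class CDResult:
    """Per-contrast CDs plus an optional aggregated criterion value."""

    per_contrast_cd: np.ndarray
    aggregate: float | None = None
    criterion_kind: str = "raw"
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.per_contrast_cd = np.asarray(self.per_contrast_cd, dtype=float)
        if self.per_contrast_cd.size and (
            self.per_contrast_cd.min() < -NEGATIVE_CD_TOLERANCE
            or self.per_contrast_cd.max() > 1.0 + NEGATIVE_CD_TOLERANCE
        ):
            raise ValueError("CD values outside [0, 1] beyond tolerance")


def _mean_deviation_columns(
    model_ids: Sequence[str], member_ids: Sequence[str], what: str
) -> ContrastMatrix:
    model_ids = [str(i) for i in model_ids]
    member_ids = [str(i) for i in member_ids]
    if len(set(member_ids)) != len(member_ids):
        raise ValueError(f"duplicate {what} ids")
    pos = {ind: k for k, ind in enumerate(model_ids)}
    outside = [i for i in member_ids if i not in pos]
    if outside:
        raise ValueError(f"{what} ids not in the model set: {outside[:5]}")
    N_i = len(member_ids)
    if N_i < 2:
        raise ValueError(
            f"need at least 2 {what} individuals to form mean-deviation "
            f"contrasts (got {N_i})"
        )
    C = np.zeros((len(model_ids), N_i))
    rows = [pos[i] for i in member_ids]
    C[rows, :] = -1.0 / N_i
    for col, r in enumerate(rows):
        C[r, col] = 1.0 - 1.0 / N_i
    return ContrastMatrix(model_ids, C, labels=list(member_ids))


def family_mean_contrasts(
    model_ids: Sequence[str], family_members: Sequence[str]
) -> ContrastMatrix:
    """One contrast per family member against its family mean.

    Column j carries ``1 - 1/N_i`` at member j, ``-1/N_i`` at the other
    members of the predicted family and 0 at every other model individual
    (in particular at calibration-only individuals).
    """
    return _mean_deviation_columns(model_ids, family_members, "family")


def population_mean_contrasts(
    model_ids: Sequence[str], target_ids: Sequence[str]
) -> ContrastMatrix:
    """One contrast per target against the mean of all targets (no structure)."""
    return _mean_deviation_columns(model_ids, target_ids, "target")


# ---------------------------------------------------------------------------
# CD / PEV of arbitrary contrasts
# ---------------------------------------------------------------------------


def _information_core(
    K: KinshipMatrix,
    calibration_ids: Sequence[str],
    contrasts: ContrastMatrix,
    lam: float,
    fixed_design: np.ndarray | None,
    ridge: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (K_ridged, (Z'MZ + lambda K^-1)^-1) over the model set."""
    if [str(i) for i in K.individual_ids] != contrasts.model_ids:
        raise ValueError("contrasts.model_ids must equal K.individual_ids")
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError(f"lambda must be a finite positive real, got {lam}")
    calibration_ids = [str(i) for i in calibration_ids]
    model_ids = contrasts.model_ids
    missing = set(calibration_ids) - set(model_ids)
    if missing:
        raise ValueError(f"calibration ids not in model set: {sorted(missing)[:5]}")
    n = len(calibration_ids)
    Kr = ridged(K.K, ridge)
    Kinv = np.linalg.inv(Kr)
    Z = incidence(calibration_ids, model_ids)
    if fixed_design is None:
        # intercept-only: Z'MZ = Z'Z - (Z'1)(1'Z)/n
        z1 = Z.sum(axis=0)
        ZMZ = Z.T @ Z - np.outer(z1, z1) / n
    else:
        X = np.atleast_2d(np.asarray(fixed_design, float))
        if X.shape[0] != n:
            raise ValueError("fixed_design must have one row per record")
        M = np.eye(n) - X @ np.linalg.pinv(X.T @ X) @ X.T
        ZMZ = Z.T @ M @ Z
    Ainv = np.linalg.inv(ZMZ + lam * Kinv)
    return Kr, Ainv


def _finalize_cd(cd: np.ndarray, labels) -> np.ndarray:
    bad_low = cd < -NEGATIVE_CD_TOLERANCE
    bad_high = cd > 1.0 + NEGATIVE_CD_TOLERANCE
    if bad_low.any() or bad_high.any():
        k = int(np.flatnonzero(bad_low | bad_high)[0])
        raise FloatingPointError(
            f"CD of contrast {labels[k]!r} is {cd[k]!r}, outside [0, 1] beyond "
            f"round-off tolerance: numerical failure"
        )
    return np.clip(cd, 0.0, 1.0)


def generalized_cd(
    K: KinshipMatrix,
    calibration_ids: Sequence[str],
    contrasts: ContrastMatrix,
    lam: float,
    fixed_design: np.ndarray | None = None,
    ridge: float = DEFAULT_RIDGE,
) -> CDResult:
    """Expected reliability CD of each contrast column.

    ``K`` must be indexed exactly by ``contrasts.model_ids``. With an
    empty calibration set no information flows into the model and every
    CD is 0 (returned explicitly, since M is undefined for n = 0). The
    ridge applied to K is used consistently in the numerator and the
    denominator.
    """
    if len(list(calibration_ids)) == 0:
        return CDResult(
            np.zeros(contrasts.n_contrasts), labels=list(contrasts.labels)
        )
    Kr, Ainv = _information_core(
        K, calibration_ids, contrasts, lam, fixed_design, ridge
    )
    C = contrasts.C
    cKc = np.einsum("ij,ij->j", C, Kr @ C)
    if cKc.min(initial=np.inf) <= 0.0:
        k = int(np.argmin(cKc))
        raise ValueError(
            f"contrast {contrasts.labels[k]!r} has non-positive genetic "
            f"variance c'Kc = {cKc[k]!r}"
        )
    cAc = np.einsum("ij,ij->j", C, Ainv @ C)
    cd = (cKc - lam * cAc) / cKc
    return CDResult(
        _finalize_cd(cd, contrasts.labels), labels=list(contrasts.labels)
    )


def pev(
    K: KinshipMatrix,
    calibration_ids: Sequence[str],
    contrasts: ContrastMatrix,
    lam: float,
    sigma_e2: float,
    fixed_design: np.ndarray | None = None,
    ridge: float = DEFAULT_RIDGE,
) -> np.ndarray:
    """Prediction error variance of each contrast column.

    ``PEV(c) = c'(Z'MZ + lambda K^-1)^-1 c / (c'c) * sigma_e2``; related
    to the CD through ``CD(c) = 1 - lambda c'(.)^-1 c / (c'Kc)``.
    """
    if sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be positive")
    if len(list(calibration_ids)) == 0:
        raise ValueError("PEV requires a non-empty calibration set")
    _, Ainv = _information_core(
        K, calibration_ids, contrasts, lam, fixed_design, ridge
    )
    C = contrasts.C
    cAc = np.einsum("ij,ij->j", C, Ainv @ C)
    cc = np.einsum("ij,ij->j", C, C)
    return cAc / cc * sigma_e2


# ---------------------------------------------------------------------------
# aggregated criteria
# ---------------------------------------------------------------------------


def _stable_model_ids(
    K: KinshipMatrix, calibration_ids: Sequence[str], target_ids: Sequence[str]
) -> list[str]:
    """Calibration union targets, ordered as they appear in K."""
    wanted = set(map(str, calibration_ids)) | set(map(str, target_ids))
    unknown = wanted - set(K.individual_ids)
    if unknown:
        raise KeyError(f"ids not present in the kinship matrix: {sorted(unknown)[:5]}")
    return [i for i in K.individual_ids if i in wanted]


def cd_criterion(
    K: KinshipMatrix,
    calibration_ids: Sequence[str],
    targets: "Sequence[str] | Mapping[str, Sequence[str]]",
    kind: str,
    lam: float = 1.0,
    ridge: float = DEFAULT_RIDGE,
) -> CDResult:
    """Aggregated CD criterion of a calibration set for a target population.

    ``kind='cdpop'``: ``targets`` is one family's id list; the criterion
    is the mean square-root CD of the family-mean contrasts, a forecast
    of within-family prediction accuracy. ``kind='cdpop_mean'``:
    ``targets`` maps family label -> id list; unweighted mean of the
    per-family cdpop values, each computed in its own model set
    (calibration plus that family). ``kind='cdallnam'``: ``targets`` is
    the pooled target id list; mean square-root CD of the
    target-vs-overall-mean contrasts. ``K`` may cover any superset of the
    individuals involved; the model set for each CD evaluation is
    calibration union targets in K's order. An individual may sit in both
    sets (e.g. when calibrating inside the target population).
    """
    calibration_ids = [str(i) for i in calibration_ids]
    if kind == "cdpop_mean":
        if not isinstance(targets, Mapping):
            raise TypeError("cdpop_mean requires a mapping family -> ids")
        per_family = {}
        cds = []
        labels = []
        for fam in targets:
            sub = cd_criterion(
                K, calibration_ids, targets[fam], "cdpop", lam=lam, ridge=ridge
            )
            per_family[fam] = sub.aggregate
            cds.append(sub.per_contrast_cd)
            labels.extend(f"{fam}:{l}" for l in sub.labels)
        return CDResult(
            np.concatenate(cds) if cds else np.empty(0),
            aggregate=float(np.mean(list(per_family.values()))),
            criterion_kind="cdpop_mean",
            labels=labels,
        )
    if kind not in ("cdpop", "cdallnam"):
        raise ValueError(f"unknown criterion kind {kind!r}")
    target_ids = [str(i) for i in targets]
    model_ids = _stable_model_ids(K, calibration_ids, target_ids)
    Ksub = K.subset(model_ids)
    builder = family_mean_contrasts if kind == "cdpop" else population_mean_contrasts
    contrasts = builder(model_ids, target_ids)
    res = generalized_cd(Ksub, calibration_ids, contrasts, lam, ridge=ridge)
    return CDResult(
        res.per_contrast_cd,
        aggregate=float(np.mean(np.sqrt(res.per_contrast_cd))),
        criterion_kind=kind,
        labels=res.labels,
    )


def crit_kin(
    K: KinshipMatrix,
    calibration_ids: Sequence[str],
    target_ids: Sequence[str],
) -> float:
    """Mean genomic relationship between calibration and target individuals.

    The plain double mean over all (calibration, target) pairs; an
    individual present in both sets contributes its self-relationship.
    """
    calibration_ids = list(calibration_ids)
    target_ids = list(target_ids)
    if not calibration_ids or not target_ids:
        raise ValueError("calibration and target sets must both be non-empty")
    ci = K.indices(calibration_ids)
    ti = K.indices(target_ids)
    return float(K.K[np.ix_(ci, ti)].mean())
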