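"""Reference structural covariance network (rSCN) from a control cohort.

The rSCN is the matrix of partial Pearson correlations between regional
grey-matter volumes across control subjects, adjusting for the nuisance
covariates age, sex and total intracranial volume.  Partialling is against
the covariates only, implemented as OLS residualization followed by plain
Pearson correlation of the residuals — the standard structural-covariance
construction, and algebraically identical to the precision-matrix partial
correlation of each region pair given the covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ValidationError, VolumeMatrix

DEFAULT_COVARIATES = ("age", "sex", "tiv")


@dataclass
class ReferenceNetwork:
    """Control-group partial-correlation network.

    Attributes
    ----------
    r
        Symmetric regions x regions partial Pearson correlation matrix,
        unit diagonal.
    n
        Number of control subjects the network was estimated from.
    covariates_used
        Names of the nuisance covariates regressed out.
    """

    r: np.ndarray
    n: int
    covariates_used: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))


def design_matrix(covariates: pd.DataFrame, names=DEFAULT_COVARIATES) -> np.ndarray:
    """Intercept + covariate design, column order [1, *names*]."""
    cols = [np.ones(len(covariates))]
    cols.extend(np.asarray(covariates[c], dtype=float) for c in names)
    return np.column_stack(cols)


def _check_rank(design: np.ndarray, names) -> None:
    # identify (near-)collinear columns via the R diagonal of a QR factorization
    r = np.linalg.qr(design, mode="r")
    diag = np.abs(np.diag(r))
    scale = max(diag.max(), 1.0)
    labels = ["intercept", *names]
    bad = [labels[i] for i in range(len(diag)) if diag[i] < 1e-10 * scale]
    if bad:
        raise ValidationError(
            f"covariate design is rank deficient; collinear columns: {bad}"
        )


def residualize(
    values: np.ndarray, covariates: pd.DataFrame, names=DEFAULT_COVARIATES
) -> np.ndarray:
    """OLS residuals of each region's volumes against [1, age, sex, TIV].

    Parameters
    ----------
    values
        Subjects x regions matrix.
    covariates
        Per-subject covariate table containing the columns in *names*.
    """
    values = np.asarray(values, dtype=float)
    X = design_matrix(covariates, names)
    if X.shape[0] != values.shape[0]:
        raise ValidationError("covariate rows do not match volume rows")
    _check_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def build_rscn(
    control_volumes: VolumeMatrix | np.ndarray,
    control_covariates: pd.DataFrame,
    names=DEFAULT_COVARIATES,
) -> ReferenceNetwork:
    """Estimate the reference network from controls.

    Requires at least 5 controls and n >= 4 + number of covariates so the
    residual correlation is defined after losing the design's degrees of
    freedom.
    """
    values = (
        control_volumes.values
        if isinstance(control_volumes, VolumeMatrix)
        else np.asarray(control_volumes, dtype=float)
    )
    n = values.shape[0]
    if n < 5:
        raise ValidationError(f"need at least 5 controls, got {n}")
    if n < 4 + len(names):
        raise ValidationError(
            f"need n >= {4 + len(names)} controls for {len(names)} covariates, got {n}"
        )
    resid = residualize(values, control_covariates, names)
    sd = resid.std(axis=0)
    raw_sd = values.std(axis=0)
    zero = np.flatnonzero(sd <= 1e-10 * np.maximum(raw_sd, 1.0))
    if zero.size:
        raise ValidationError(
            f"zero-variance residuals for region column(s) {zero.tolist()}"
        )
    r = np.corrcoef(resid, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return ReferenceNetwork(r=r, n=n, covariates_used=list(names))
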