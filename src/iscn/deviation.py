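"""Individual deviation networks (iSCN) via network template perturbation.

A single patient is appended to the control cohort, the covariate-adjusted
partial-correlation network is re-estimated on the n+1 subjects (the
perturbed network, pSCN), and the edge-wise difference from the reference
network is standardized to a Z score:

    Z_ij = (pSCN_ij - rSCN_ij) / ((1 - rSCN_ij^2) / (n - 1))

where n is the size of the control group.  Large |Z| marks an edge whose
covariance the patient's anatomy breaks; edges with |Z| > 2 are labelled
abnormal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ValidationError, VolumeMatrix
from .normative import DEFAULT_COVARIATES, ReferenceNetwork, build_rscn

DEFAULT_THRESHOLD = 2.0


@dataclass
class DeviationNetwork:
    """Per-patient Z-scored deviation network."""

    patient_id: str
    z: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    abnormal_edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    invalid_edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)


def build_pscn(
    control_volumes: VolumeMatrix | np.ndarray,
    control_covariates: pd.DataFrame,
    patient_volumes: np.ndarray,
    patient_covariates: pd.Series | dict,
    names=DEFAULT_COVARIATES,
    fixed_covariate_fit: bool = False,
) -> np.ndarray:
    """Perturbed network: controls + one patient, same construction as the rSCN.

    By default the covariate regression is refit on the n+1 stacked sample.
    With ``fixed_covariate_fit=True`` the control-only regression
    coefficients are reused to residualize the patient row (documented
    alternative; the study does not state which variant it used).
    """
    values = (
        control_volumes.values
        if isinstance(control_volumes, VolumeMatrix)
        else np.asarray(control_volumes, dtype=float)
    )
    prow = np.asarray(patient_volumes, dtype=float).reshape(1, -1)
    if prow.shape[1] != values.shape[1]:
        raise ValidationError("patient regions do not align with control regions")
    pcov = pd.DataFrame([dict(patient_covariates)])[list(names)]
    stacked_cov = pd.concat(
        [control_covariates[list(names)].reset_index(drop=True), pcov],
        ignore_index=True,
    )
    stacked = np.vstack([values, prow])
    if not fixed_covariate_fit:
        return build_rscn(stacked, stacked_cov, names).r
    # reuse control-fit coefficients for all rows, then correlate
    from .normative import design_matrix, residualize  # local to avoid cycle noise

    Xc = design_matrix(control_covariates, names)
    beta, *_ = np.linalg.lstsq(Xc, values, rcond=None)
    Xs = design_matrix(stacked_cov, names)
    resid = stacked - Xs @ beta
    r = np.corrcoef(resid, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return np.clip((r + r.T) / 2.0, -1.0, 1.0)


def compute_z(
    pscn: np.ndarray,
    rscn: ReferenceNetwork,
    patient_id: str = "",
    threshold: float = DEFAULT_THRESHOLD,
) -> DeviationNetwork:
    """Z-score the perturbed-minus-reference difference.

    Edges where the reference correlation is exactly +/-1 have a degenerate
    scale; they are flagged invalid (with a warning) and excluded from the
    abnormal-edge set rather than reported as infinite.
    """
    if rscn.n <= 2:
        raise ValidationError("reference network needs n > 2 controls")
    r = rscn.r
    p = r.shape[0]
    if pscn.shape != r.shape:
        raise ValidationError("pSCN and rSCN dimensions differ")
    denom = (1.0 - r**2) / (rscn.n - 1)
    off = ~np.eye(p, dtype=bool)
    degenerate = (np.abs(r) >= 1.0) & off
    invalid = frozenset(
        (int(i), int(j)) for i, j in zip(*np.nonzero(np.triu(degenerate, 1)))
    )
    if invalid:
        warnings.warn(
            f"{len(invalid)} edge(s) with |r|=1 in the reference network; "
            "flagged invalid (likely duplicated input rows)",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (pscn - r) / denom
    z[~off] = 0.0
    z[degenerate] = 0.0
    z = (z + z.T) / 2.0
    abnormal = threshold_abnormal(z, threshold, invalid)
    return DeviationNetwork(
        patient_id=patient_id,
        z=z,
        threshold=threshold,
        abnormal_edges=abnormal,
        invalid_edges=invalid,
    )


def threshold_abnormal(
    z: np.ndarray,
    tau: float = DEFAULT_THRESHOLD,
    invalid: frozenset[tuple[int, int]] | None = None,
) -> frozenset[tuple[int, int]]:
    """Unordered region-index pairs with |z| strictly greater than tau."""
    if tau <= 0:
        raise ValidationError("threshold tau must be positive")
    iu, ju = np.nonzero(np.triu(np.abs(z) > tau, 1))
    edges = {(int(i), int(j)) for i, j in zip(iu, ju)}
    if invalid:
        edges -= set(invalid)
    return frozenset(edges)


def patient_deviation(
    control_volumes: VolumeMatrix | np.ndarray,
    control_covariates: pd.DataFrame,
    rscn: ReferenceNetwork,
    patient_id: str,
    patient_volumes: np.ndarray,
    patient_covariates: pd.Series | dict,
    threshold: float = DEFAULT_THRESHOLD,
    fixed_covariate_fit: bool = False,
) -> DeviationNetwork:
    """Convenience: build the pSCN for one patient and Z-score it."""
    pscn = build_pscn(
        control_volumes,
        control_covariates,
        patient_volumes,
        patient_covariates,
        names=rscn.covariates_used,
        fixed_covariate_fit=fixed_covariate_fit,
    )
    return compute_z(pscn, rscn, patient_id=patient_id, threshold=threshold)
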