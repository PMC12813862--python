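"""Minimal LCMV (linearly constrained minimum variance) beamformer.

Per source location, three orthogonal spatial filters (one per dipole axis)
pass that location with unit gain while minimizing output variance; they are
then combined into a single filter along the orientation of maximal
projected variance.  A common filter built from condition-pooled covariance
avoids spurious between-condition differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochSet

__all__ = [
    "BeamformerFilters",
    "lcmv_vector_filters",
    "combine_max_variance",
    "apply_filters",
    "epoch_covariance",
]


@dataclass
class BeamformerFilters:
    """LCMV filter bank.

    Attributes
    ----------
    vector : (n_locations, 3, n_sensors) array
        The three orthogonal unit-gain filters per location.
    combined : (n_locations, n_sensors) array or None
        Max-variance single-orientation filters (after combination).
    orientation : (n_locations, 3) array or None
        Unit combination weights chosen per location.
    regularization : float
        Diagonal loading actually added to the covariance.
    cond_number : float
        Condition number of the regularized covariance.
    """

    vector: np.ndarray
    combined: np.ndarray | None
    orientation: np.ndarray | None
    regularization: float
    cond_number: float


def epoch_covariance(epochs: EpochSet) -> np.ndarray:
    """Sensor covariance pooled over epochs and samples (zero-mean per epoch)."""
    x = epochs.data - epochs.data.mean(axis=2, keepdims=True)
    n = x.shape[0] * x.shape[2]
    return np.einsum("eis,ejs->ij", x, x) / n


def lcmv_vector_filters(
    covariance: np.ndarray,
    lead_field: np.ndarray,
    regularization: float = 0.05,
) -> BeamformerFilters:
    """Classical LCMV with diagonal loading.

    Parameters
    ----------
    covariance : (n_sensors, n_sensors) symmetric PSD array
    lead_field : (n_sensors, 3 * n_locations) array
        Three columns per location (x, y, z dipole axes).
    regularization : float
        Diagonal loading as a fraction of the mean sensor variance
        (proportional loading keeps the filters scale-invariant).

    The filter for location q is ``W_q = (L_q' C⁻¹ L_q)⁻¹ L_q' C⁻¹`` which
    satisfies the unit-gain constraint ``W_q L_q = I₃``.
    """
    c = np.asarray(covariance, dtype=float)
    lf = np.asarray(lead_field, dtype=float)
    if c.shape[0] != c.shape[1] or lf.shape[0] != c.shape[0]:
        raise ValueError("covariance and lead field dimensions disagree")
    if lf.shape[1] % 3:
        raise ValueError("lead field must have 3 columns per location")
    n_loc = lf.shape[1] // 3
    load = regularization * np.trace(c) / c.shape[0]
    c_reg = c + load * np.eye(c.shape[0])
    try:
        c_inv = np.linalg.inv(c_reg)
    except np.linalg.LinAlgError as e:  # pragma: no cover
        raise np.linalg.LinAlgError("regularized covariance is singular") from e
    cond = float(np.linalg.cond(c_reg))
    filters = np.empty((n_loc, 3, c.shape[0]))
    for q in range(n_loc):
        lq = lf[:, 3 * q : 3 * q + 3]
        g = lq.T @ c_inv @ lq
        try:
            filters[q] = np.linalg.solve(g, lq.T @ c_inv)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(f"rank-deficient lead field at location {q}") from e
    return BeamformerFilters(
        vector=filters, combined=None, orientation=None,
        regularization=float(load), cond_number=cond,
    )


def combine_max_variance(
    filters: BeamformerFilters, covariance: np.ndarray, lead_field: np.ndarray | None = None
) -> BeamformerFilters:
    """Collapse the 3 filters per location onto the max-variance orientation.

    The orientation is the dominant eigenvector of the 3x3 projected
    covariance ``W C W'`` (unit-norm combination weights).  Sign convention:
    positive projection of the combined filter onto the location's first
    lead-field column when a lead field is given, else first nonzero weight
    positive.
    """
    c = np.asarray(covariance, dtype=float)
    n_loc = filters.vector.shape[0]
    combined = np.empty((n_loc, filters.vector.shape[2]))
    orient = np.empty((n_loc, 3))
    for q in range(n_loc):
        w = filters.vector[q]
        p = w @ c @ w.T  # 3x3 projected covariance
        if not np.all(np.isfinite(p)) or np.allclose(p, 0):
            raise ValueError(f"degenerate projected covariance at location {q}")
        evals, evecs = np.linalg.eigh(p)
        u = evecs[:, -1]  # dominant orientation; eigh ties broken deterministically
        wq = u @ w
        if lead_field is not None:
            s = float(wq @ lead_field[:, 3 * q])
        else:
            nz = u[np.nonzero(np.abs(u) > 1e-12)[0]]
            s = float(nz[0]) if nz.size else 1.0
        if s < 0:
            u, wq = -u, -wq
        combined[q], orient[q] = wq, u
    return BeamformerFilters(
        vector=filters.vector, combined=combined, orientation=orient,
        regularization=filters.regularization, cond_number=filters.cond_number,
    )


def apply_filters(filters: BeamformerFilters, sensor_epochs: EpochSet) -> EpochSet:
    """Project sensor epochs to source space with the combined filters.

    Linear, so condition labels carry over unchanged.  The filters should be
    common across conditions (covariance from condition-stratified pooled
    data) to avoid filter-induced condition differences.
    """
    if filters.combined is None:
        raise ValueError("combine_max_variance must be applied first")
    if sensor_epochs.n_locations != filters.combined.shape[1]:
        raise ValueError("sensor count does not match the filters")
    src = np.einsum("qs,esn->eqn", filters.combined, sensor_epochs.data)
    return EpochSet(src, sensor_epochs.sfreq, sensor_epochs.t0, sensor_epochs.labels)
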