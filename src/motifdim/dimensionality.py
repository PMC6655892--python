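"""Participation-ratio dimensionality of covariance matrices.

The participation ratio

    Dim(C) = (Tr C)^2 / Tr(C^2) = (sum_i lambda_i)^2 / sum_i lambda_i^2

is a weighted count of the number of axes a cloud of population activity
vectors explores: it equals N when all eigenvalues of the covariance are
equal, M when the variance is spread evenly over M modes, and interpolates
in between.  It is computed here purely from traces -- Tr(C^2) is the
squared Frobenius norm of a symmetric C -- so no eigendecomposition is
needed; the eigenvalue form is kept for test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = ["DimensionalityResult", "participation_ratio", "dim_decomposed"]

#: methods that can produce a DimensionalityResult
METHODS = ("exact", "cumulant_lowdim", "cumulant_highdim", "closed_form_ER")


@dataclass(frozen=True)
class DimensionalityResult:
    """A participation-ratio value together with how it was obtained.

    Attributes
    ----------
    raw:
        The participation ratio itself, in "number of dimensions" units
        (between 1 and N for any exact nonzero PSD covariance; cumulant
        approximations may fall slightly outside).
    normalized:
        ``raw / n_neurons`` -- the convention used for ensemble summaries,
        where "a dimensionality of 0.5" means half the network size.
    method:
        One of ``exact``, ``cumulant_lowdim``, ``cumulant_highdim``,
        ``closed_form_ER``.
    n_neurons:
        Network size the value refers to (``None`` if unknown, in which case
        ``normalized`` is ``None`` too).
    """

    raw: float
    method: str
    n_neurons: int | None = None

    @property
    def normalized(self) -> float | None:
        if self.n_neurons is None:
            return None
        return self.raw / self.n_neurons

    def __float__(self) -> float:
        return float(self.raw)


def _check_square_symmetric(C: np.ndarray, atol: float, name: str) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValidationError(f"{name} must be a square matrix, got shape {C.shape}")
    if not np.all(np.isfinite(C)):
        raise ValidationError(f"{name} contains non-finite entries")
    scale = max(1.0, float(np.abs(C).max()))
    if np.abs(C - C.T).max() > atol * scale:
        raise ValidationError(f"{name} is not symmetric within tolerance {atol}")
    return C


def participation_ratio(C: np.ndarray, *, atol: float = 1e-8) -> DimensionalityResult:
    """Participation ratio (Tr C)^2 / Tr(C^2) of a symmetric PSD matrix.

    Parameters
    ----------
    C:
        Symmetric positive-semidefinite covariance matrix (N x N), not
        identically zero.
    atol:
        Relative symmetry tolerance.

    Raises
    ------
    ValidationError
        If ``C`` is not square/symmetric, or is (numerically) the zero
        matrix, for which the dimensionality is undefined.
    """
    C = _check_square_symmetric(C, atol, "C")
    tr = float(np.trace(C))
    tr2 = float(np.sum(C * C))  # Tr(C^2) for symmetric C
    if tr2 <= 0.0:
        raise ValidationError("participation ratio undefined for the zero matrix")
    return DimensionalityResult(raw=tr * tr / tr2, method="exact", n_neurons=C.shape[0])


def dim_decomposed(C_int: np.ndarray, C_ext: np.ndarray, *, atol: float = 1e-8
                   ) -> DimensionalityResult:
    """Participation ratio of ``C_int + C_ext`` from its five trace blocks.

    Evaluates

        Dim = (Tr C_int + Tr C_ext)^2
              / (Tr C_int^2 + Tr C_ext^2 + 2 Tr(C_int C_ext))

    which is algebraically identical to ``participation_ratio(C_int + C_ext)``
    but exposes the internal/external interplay: the cross trace
    ``Tr(C_int C_ext)`` is the only term mixing the two sources of
    covariability.
    """
    Ci = _check_square_symmetric(C_int, atol, "C_int")
    Ce = _check_square_symmetric(C_ext, atol, "C_ext")
    if Ci.shape != Ce.shape:
        raise ValidationError(
            f"C_int and C_ext sizes differ: {Ci.shape} vs {Ce.shape}")
    tci = float(np.trace(Ci))
    tce = float(np.trace(Ce))
    tci2 = float(np.sum(Ci * Ci))
    tce2 = float(np.sum(Ce * Ce))
    cross = float(np.sum(Ci * Ce))  # Tr(C_int C_ext) for symmetric inputs
    denom = tci2 + tce2 + 2.0 * cross
    if denom <= 0.0:
        raise ValidationError("participation ratio undefined for the zero matrix")
    raw = (tci + tce) ** 2 / denom
    return DimensionalityResult(raw=raw, method="exact", n_neurons=Ci.shape[0])
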