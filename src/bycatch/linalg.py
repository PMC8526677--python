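"""Sparse symmetric-positive-definite factorization utilities.

A GMRF with sparse precision Q needs three primitives: solves Q⁻¹b, the
log-determinant, and draws from N(0, Q⁻¹).  All three come from a single
LDLᵀ-style factorization obtained from SuperLU run in symmetric mode with
diagonal pivoting disabled, which for SPD input yields ``Pr Q Pc = L U`` with
``perm_r == perm_c`` and ``U = D Lᵀ``, i.e. ``Q = Prᵀ L D Lᵀ Pr``.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu, spsolve_triangular

log = logging.getLogger(__name__)


class NotPositiveDefiniteError(ValueError):
    """Raised when a matrix expected to be SPD fails to factorize."""


class SPDFactor:
    """Cholesky-style factorization of a sparse SPD matrix.

    Parameters
    ----------
    Q : sparse matrix, assumed symmetric positive definite.
    jitter : diagonal jitter added (once, logged) if the first factorization
        produces a non-positive pivot; a second failure raises
        :class:`NotPositiveDefiniteError`.
    """

    def __init__(self, Q: sp.spmatrix, jitter: float = 1e-8):
        Q = sp.csc_matrix(Q)
        self.n = Q.shape[0]
        try:
            self._factor(Q)
        except NotPositiveDefiniteError:
            log.warning("factorization failed; retrying with %g diagonal jitter",
                        jitter)
            self._factor(Q + jitter * sp.identity(self.n, format="csc"))

    def _factor(self, Q):
        try:
            lu = splu(Q, permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0,
                      options=dict(SymmetricMode=True))
        except RuntimeError as exc:  # singular
            raise NotPositiveDefiniteError(str(exc)) from exc
        d = lu.U.diagonal()
        if np.any(d <= 0) or not np.all(np.isfinite(d)):
            raise NotPositiveDefiniteError("non-positive pivot encountered")
        self._lu = lu
        self._d = np.asarray(d)
        self._perm = np.asarray(lu.perm_r)
        # upper-triangular factor Mᵀ = sqrt(D) Lᵀ of the permuted matrix
        self._Mt = (sp.diags(np.sqrt(self._d)) @ lu.L.T).tocsr()

    @property
    def logdet(self) -> float:
        return float(np.sum(np.log(self._d)))

    def solve(self, b: np.ndarray) -> np.ndarray:
        return self._lu.solve(np.asarray(b, dtype=float))

    def sample(self, rng: np.random.Generator, n_draws: int,
               mean: np.ndarray | None = None) -> np.ndarray:
        """Draws from N(mean, Q⁻¹), shape (n_draws, n)."""
        eps = rng.standard_normal((self.n, n_draws))
        w = spsolve_triangular(self._Mt, eps, lower=False)
        x = w[self._perm, :].T
        if mean is not None:
            x = x + np.asarray(mean)[None, :]
        return x


def sparse_logdet(Q: sp.spmatrix) -> float:
    return SPDFactor(Q).logdet
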