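"""Latent model terms: design columns, prior precision blocks, hyperpriors.

Each term owns (i) its design columns for a set of records, (ii) the matching
block of the latent prior precision matrix given its hyperparameter values,
and (iii) penalized-complexity-style log hyperpriors on the log scale.
Categorical effects are coded with one column per level plus a soft
sum-to-zero constraint in the prior (a high-precision penalty on the level
sum), which keeps the latent model Gaussian throughout; RW1 smooths carry the
same constraint to resolve their intrinsic rank deficiency.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np
import pandas as pd
import scipy.sparse as sp

from bycatch.mesh import BarrierMesh, FEMOperators, assemble_fem, make_projector
from bycatch.spde import FieldParams, precision_barrier, precision_stationary
from bycatch.linalg import SPDFactor


class UnseenLevelError(KeyError):
    """A categorical level at prediction time was absent from training data."""


def pc_prec_logprior(log_tau: float, u: float, alpha: float) -> float:
    """PC prior for a precision, parameterized on log tau (sd = tau^-1/2)."""
    lam = -np.log(alpha) / u
    sd = np.exp(-0.5 * log_tau)
    return float(np.log(lam) - lam * sd + np.log(sd / 2.0))


def pc_range_logprior(log_range: float, r0: float) -> float:
    """PC prior for a Matérn range (d=2) with median r0, on log range."""
    lam = -np.log(0.5) * r0
    return float(np.log(lam) - log_range - lam * np.exp(-log_range))


def pc_sigma_logprior(log_sigma: float, u: float, alpha: float) -> float:
    """PC (exponential) prior for a field sd, on log sigma."""
    lam = -np.log(alpha) / u
    return float(np.log(lam) - lam * np.exp(log_sigma) + log_sigma)


class Term(ABC):
    """One additive component of a linear predictor."""

    name: str
    n_cols: int
    hyper_names: tuple = ()

    @abstractmethod
    def design(self, df: pd.DataFrame) -> sp.csr_matrix:
        """(n, n_cols) design block for the given records."""

    @abstractmethod
    def prior_precision(self, hypers: dict) -> sp.csr_matrix:
        """(n_cols, n_cols) prior precision block."""

    def prior_logdet(self, hypers: dict) -> float:
        return float(np.linalg.slogdet(self.prior_precision(hypers).toarray())[1])

    def hyper_logprior(self, hypers: dict) -> float:
        return 0.0

    def hyper_init(self) -> dict:
        return {}


class InterceptTerm(Term):
    def __init__(self, prior_sd: float = 31.6):
        self.name = "intercept"
        self.n_cols = 1
        self.prior_sd = prior_sd

    def design(self, df):
        return sp.csr_matrix(np.ones((len(df), 1)))

    def prior_precision(self, hypers):
        return sp.csr_matrix(np.array([[1.0 / self.prior_sd ** 2]]))


class LinearTerm(Term):
    """Standardized linear effect of a continuous covariate."""

    def __init__(self, column: str, prior_sd: float = 31.6,
                 center: float | None = None, scale: float | None = None):
        self.name = column
        self.column = column
        self.n_cols = 1
        self.prior_sd = prior_sd
        self.center = center
        self.scale = scale

    def fit_metadata(self, df):
        x = df[self.column].to_numpy(dtype=float)
        if self.center is None:
            self.center = float(x.mean())
        if self.scale is None:
            s = float(x.std())
            self.scale = s if s > 0 else 1.0

    def design(self, df):
        if self.center is None:
            self.fit_metadata(df)
        x = (df[self.column].to_numpy(dtype=float) - self.center) / self.scale
        return sp.csr_matrix(x[:, None])

    def prior_precision(self, hypers):
        return sp.csr_matrix(np.array([[1.0 / self.prior_sd ** 2]]))


class CategoricalTerm(Term):
    """One column per level; soft sum-to-zero constraint in the prior."""

    def __init__(self, column: str, prior_sd: float = 31.6,
                 sumzero_precision: float = 1e4, levels=None):
        self.name = column
        self.column = column
        self.prior_sd = prior_sd
        self.sumzero_precision = sumzero_precision
        self.levels = list(levels) if levels is not None else None
        self.n_cols = len(self.levels) if self.levels else 0

    def fit_metadata(self, df):
        if self.levels is None:
            self.levels = sorted(df[self.column].astype(str).unique())
            self.n_cols = len(self.levels)

    def design(self, df):
        if self.levels is None:
            self.fit_metadata(df)
        idx = {lv: k for k, lv in enumerate(self.levels)}
        vals = df[self.column].astype(str).to_numpy()
        unseen = set(vals) - set(idx)
        if unseen:
            raise UnseenLevelError(
                f"unseen level(s) {sorted(unseen)} for {self.column}")
        cols = np.array([idx[v] for v in vals])
        return sp.csr_matrix((np.ones(len(df)), (np.arange(len(df)), cols)),
                             shape=(len(df), self.n_cols))

    def prior_precision(self, hypers):
        k = self.n_cols
        Q = np.full((k, k), self.sumzero_precision / k)
        Q[np.diag_indices(k)] += 1.0 / self.prior_sd ** 2
        return sp.csr_matrix(Q)


class VesselTerm(CategoricalTerm):
    """I.i.d. Gaussian random effect per vessel with PC-prior precision."""

    hyper_names = ("log_tau",)

    def __init__(self, column: str = "vessel_id", tau_u: float = 1.0,
                 tau_alpha: float = 0.1):
        super().__init__(column)
        self.name = "vessel"
        self.tau_u = tau_u
        self.tau_alpha = tau_alpha

    def design(self, df):
        if self.levels is None:
            self.fit_metadata(df)
        idx = {lv: k for k, lv in enumerate(self.levels)}
        vals = df[self.column].astype(str).to_numpy()
        rows, cols = [], []
        for i, v in enumerate(vals):
            if v in idx:  # unseen vessels get a zero row (population effect)
                rows.append(i)
                cols.append(idx[v])
        return sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                             shape=(len(df), self.n_cols))

    def unseen_mask(self, df) -> np.ndarray:
        known = set(self.levels or [])
        return ~df[self.column].astype(str).isin(known).to_numpy()

    def prior_precision(self, hypers):
        tau = np.exp(hypers["log_tau"])
        return sp.identity(self.n_cols, format="csr") * tau

    def prior_logdet(self, hypers):
        return self.n_cols * hypers["log_tau"]

    def hyper_logprior(self, hypers):
        return pc_prec_logprior(hypers["log_tau"], self.tau_u, self.tau_alpha)

    def hyper_init(self):
        return {"log_tau": np.log(4.0)}   # sd 0.5


class SmoothTerm(Term):
    """RW1 smooth on equal-width bins of a continuous covariate.

    Bins are half-open [a, b); values beyond the training range clip to the
    edge bins.  The RW1 structure matrix has rank m-1; a soft sum-to-zero
    constraint makes the prior proper.
    """

    hyper_names = ("log_tau",)

    def __init__(self, column: str, m: int = 20, tau_u: float = 1.0,
                 tau_alpha: float = 0.1, sumzero_precision: float = 1e4):
        self.name = column
        self.column = column
        self.m = m
        self.n_cols = m
        self.tau_u = tau_u
        self.tau_alpha = tau_alpha
        self.sumzero_precision = sumzero_precision
        self.edges = None

    def fit_metadata(self, df):
        x = df[self.column].to_numpy(dtype=float)
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            hi = lo + 1.0
        self.edges = np.linspace(lo, hi, self.m + 1)

    @property
    def knots(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def bin_of(self, x) -> np.ndarray:
        # np.digitize with right=False gives half-open [a, b) bins
        b = np.digitize(np.asarray(x, dtype=float), self.edges[1:-1], right=False)
        return np.clip(b, 0, self.m - 1)

    def design(self, df):
        if self.edges is None:
            self.fit_metadata(df)
        cols = self.bin_of(df[self.column].to_numpy(dtype=float))
        return sp.csr_matrix((np.ones(len(df)), (np.arange(len(df)), cols)),
                             shape=(len(df), self.m))

    def structure_matrix(self) -> sp.csr_matrix:
        D = sp.diags([np.full(self.m - 1, -1.0), np.ones(self.m - 1)],
                     [0, 1], shape=(self.m - 1, self.m))
        return (D.T @ D).tocsr()

    def prior_precision(self, hypers):
        tau = np.exp(hypers["log_tau"])
        R = tau * self.structure_matrix()
        S = sp.csr_matrix(np.full((self.m, self.m),
                                  self.sumzero_precision / self.m))
        return (R + S).tocsr()

    def hyper_logprior(self, hypers):
        return pc_prec_logprior(hypers["log_tau"], self.tau_u, self.tau_alpha)

    def hyper_init(self):
        return {"log_tau": np.log(4.0)}


class FieldTerm(Term):
    """Matérn spatial field on the mesh nodes, optionally replicated by year.

    Replicates (one field realization per year) are conditionally independent
    given the shared (range, sigma) hyperparameters, so the prior precision is
    block-diagonal with identical blocks.
    """

    hyper_names = ("log_range", "log_sigma")

    def __init__(self, mesh: BarrierMesh, domain=None, barrier: bool = True,
                 replicated: bool = False, years=None,
                 range_median: float | None = None,
                 sigma_u: float = 1.0, sigma_alpha: float = 0.1,
                 barrier_range_fraction: float = 0.1,
                 fem: FEMOperators | None = None):
        self.name = "spatial_t" if replicated else "spatial"
        self.mesh = mesh
        self.domain = domain
        self.barrier = barrier and mesh.barrier_flag.any()
        self.replicated = replicated
        self.years = sorted(int(y) for y in years) if years is not None else None
        self.fem = fem if fem is not None else assemble_fem(mesh)
        if range_median is None:
            span = mesh.nodes.max(axis=0) - mesh.nodes.min(axis=0)
            range_median = 0.5 * float(np.hypot(*span))
        self.range_median = range_median
        self.sigma_u = sigma_u
        self.sigma_alpha = sigma_alpha
        self.barrier_range_fraction = barrier_range_fraction
        self._q_cache = {}
        self.n_cols = mesh.n_nodes * (len(self.years) if self.replicated and
                                      self.years else 1)

    def fit_metadata(self, df):
        if self.replicated and self.years is None:
            self.years = sorted(int(y) for y in df["year"].unique())
            self.n_cols = self.mesh.n_nodes * len(self.years)

    def _points_km(self, df) -> np.ndarray:
        if self.domain is not None:
            x, y = self.domain.to_planar(df["lon"].to_numpy(),
                                         df["lat"].to_numpy())
        else:
            x, y = df["lon"].to_numpy(), df["lat"].to_numpy()
        return np.column_stack([x, y])

    def design(self, df):
        if self.replicated and self.years is None:
            self.fit_metadata(df)
        proj = make_projector(self.mesh, self._points_km(df))
        A = proj.A
        if not proj.valid.all():
            # zero out rows for out-of-mesh points; caller flags them
            mask = sp.diags(proj.valid.astype(float))
            A = mask @ A
        self.last_valid = proj.valid
        if not self.replicated:
            return A.tocsr()
        n = len(df)
        k = self.mesh.n_nodes
        year_idx = {y: j for j, y in enumerate(self.years)}
        blocks = sp.lil_matrix((n, self.n_cols))
        yrs = df["year"].to_numpy()
        A = A.tocsr()
        for y, j in year_idx.items():
            sel = np.flatnonzero(yrs == y)
            if sel.size:
                blocks[sel, j * k:(j + 1) * k] = A[sel]
        return blocks.tocsr()

    def _field_q(self, hypers) -> sp.csc_matrix:
        key = (round(hypers["log_range"], 10), round(hypers["log_sigma"], 10))
        if key not in self._q_cache:
            params = FieldParams(range_r=float(np.exp(hypers["log_range"])),
                                 sigma=float(np.exp(hypers["log_sigma"])),
                                 barrier_range_fraction=self.barrier_range_fraction)
            if self.barrier:
                Q = precision_barrier(self.fem, self.mesh, params)
            else:
                Q = precision_stationary(self.fem, params)
            self._q_cache[key] = (Q, SPDFactor(Q).logdet)
        return self._q_cache[key]

    def prior_precision(self, hypers):
        Q, _ = self._field_q(hypers)
        if not self.replicated:
            return Q.tocsr()
        return sp.block_diag([Q] * len(self.years), format="csr")

    def prior_logdet(self, hypers):
        _, ld = self._field_q(hypers)
        reps = len(self.years) if self.replicated else 1
        return reps * ld

    def hyper_logprior(self, hypers):
        return (pc_range_logprior(hypers["log_range"], self.range_median)
                + pc_sigma_logprior(hypers["log_sigma"], self.sigma_u,
                                    self.sigma_alpha))

    def hyper_init(self):
        return {"log_range": float(np.log(self.range_median)),
                "log_sigma": float(np.log(0.5))}
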