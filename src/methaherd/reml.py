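"""REML variance components for the repeatability animal model.

The model for a vector of lactation records y is::

    y = X b + Z a + W pe + e

with fixed effects b (parity, herd, year, season of calving, and lactation
length as a covariate), additive genetic effects ``a ~ N(0, A s2a)`` where A
is the pedigree numerator relationship matrix, permanent-environment effects
``pe ~ N(0, I s2pe)`` shared across a cow's repeated records, and residuals
``e ~ N(0, I s2e)``.  ``a`` and ``pe`` are uncorrelated.

Estimation is restricted maximum likelihood on Henderson's mixed-model
equations (MME).  One engine handles k traits recorded on the same records
(k=1 univariate, k=2 bivariate with 2x2 covariance blocks G_a, G_pe, R_0):

* the permanent-environment equations form a (block-)diagonal system and are
  absorbed analytically, leaving a dense symmetric core over fixed effects
  and animals that is Cholesky-factorized;
* EM-REML updates use conditional expectations (quadratic forms in the MME
  solutions plus traces of the MME-inverse recovered through the absorption),
  which makes the log-likelihood provably non-decreasing across EM steps;
* an average-information (AI) step accelerates convergence; when an AI
  proposal leaves the parameter space or decreases the likelihood the engine
  falls back to the EM step for that iteration;
* covariance blocks are projected to the nearest symmetric PSD matrix, with
  eigenvalues floored at 1e-8 of the phenotypic scale;
* standard errors come from the inverse AI matrix at convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.linalg import lapack

from .pedigree import NrmInverse

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "VarianceComponents",
    "BivariateComponents",
    "build_design",
    "reml_univariate",
    "reml_bivariate",
    "aic",
]

_TWO_PI = 2.0 * np.pi


def aic(logL: float, n_params: int) -> float:
    """Akaike information criterion, ``-2 logL + 2 n_params``.

    Under REML, ``n_params`` counts the estimated (co)variance parameters
    only; REML likelihoods are comparable across models sharing one fixed
    structure, which is the intended use here.
    """
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    return -2.0 * logL + 2.0 * n_params


# ---------------------------------------------------------------------------
# model specification and design matrices


@dataclass(frozen=True)
class ModelSpec:
    """Fixed and random structure of the repeatability animal model.

    The random part (animal + permanent environment + residual) is implied;
    only the response and fixed effects vary between analyses.
    """

    trait: str = "mpe1"
    fixed_factors: tuple[str, ...] = ("parity", "herd", "year", "season")
    covariates: tuple[str, ...] = ("lactation_length",)


@dataclass
class DesignMatrices:
    """Sparse design matrices plus the bookkeeping to rebuild rows.

    X carries an intercept, reference-coded factor dummies (first level
    dropped) and mean-centered covariates.  Z (records x animals in pedigree
    order) and W (records x cows with records) are 0/1 incidence matrices
    with exactly one 1 per row; they are also kept as index arrays.
    """

    X: sp.csr_matrix
    Z: sp.csr_matrix
    W: sp.csr_matrix
    animal_idx: np.ndarray
    cow_idx: np.ndarray
    animal_ids: list[str]
    cow_ids: list[str]
    x_columns: list[str]
    factor_levels: dict[str, list]
    covariate_means: dict[str, float]

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    def transform(self, records: pd.DataFrame) -> sp.csr_matrix:
        """Fixed-effect rows for new records; unseen factor levels error."""
        cols = [np.ones(len(records))]
        for fac, levels in self.factor_levels.items():
            vals = records[fac].to_numpy()
            lut = {lev: i for i, lev in enumerate(levels)}
            unseen = sorted({v for v in vals if v not in lut})
            if unseen:
                raise ValueError(f"unseen level(s) {unseen[:5]} for factor {fac!r}")
            codes = np.array([lut[v] for v in vals])
            for j in range(1, len(levels)):
                cols.append((codes == j).astype(float))
        for cov, mean in self.covariate_means.items():
            cols.append(records[cov].to_numpy(dtype=float) - mean)
        return sp.csr_matrix(np.column_stack(cols))


def build_design(records: pd.DataFrame, ped, spec: ModelSpec) -> DesignMatrices:
    """Assemble X, Z, W for a phenotype table against a pedigree.

    Every record's cow must appear in the pedigree.  Factor levels are taken
    from the data and sorted for determinism; one reference level per factor
    is dropped.  Covariates are centered at their sample mean.  Raises if the
    resulting X is column-rank deficient (confounded fixed effects).
    """
    if len(records) < 2:
        raise ValueError("need at least two records")
    n = len(records)

    missing = [c for c in records["cow"] if c not in ped]
    if missing:
        raise ValueError(
            f"{len(missing)} record cow(s) absent from pedigree, e.g. {missing[:3]}"
        )
    animal_idx = np.fromiter(
        (ped.index(c) for c in records["cow"]), dtype=np.int64, count=n
    )
    cow_ids = list(pd.unique(records["cow"]))
    cow_lut = {c: i for i, c in enumerate(cow_ids)}
    cow_idx = np.fromiter((cow_lut[c] for c in records["cow"]), dtype=np.int64, count=n)

    cols = [np.ones(n)]
    names = ["intercept"]
    factor_levels: dict[str, list] = {}
    for fac in spec.fixed_factors:
        if fac not in records.columns:
            raise ValueError(f"factor {fac!r} missing from phenotype table")
        vals = records[fac].to_numpy()
        levels = sorted(pd.unique(vals).tolist())
        factor_levels[fac] = levels
        lut = {lev: i for i, lev in enumerate(levels)}
        codes = np.array([lut[v] for v in vals])
        for j in range(1, len(levels)):
            cols.append((codes == j).astype(float))
            names.append(f"{fac}[{levels[j]}]")
    covariate_means: dict[str, float] = {}
    for cov in spec.covariates:
        if cov not in records.columns:
            raise ValueError(f"covariate {cov!r} missing from phenotype table")
        v = records[cov].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"covariate {cov!r} has non-finite values")
        covariate_means[cov] = float(v.mean())
        cols.append(v - covariate_means[cov])
        names.append(cov)

    Xd = np.column_stack(cols)
    xtx = Xd.T @ Xd
    eig = np.linalg.eigvalsh(xtx)
    if eig[0] <= 1e-10 * eig[-1]:
        raise ValueError(
            "fixed-effect design is rank deficient after reference coding "
            "(confounded factors?)"
        )
    ones = np.ones(n)
    Z = sp.csr_matrix((ones, (np.arange(n), animal_idx)), shape=(n, len(ped)))
    W = sp.csr_matrix((ones, (np.arange(n), cow_idx)), shape=(n, len(cow_ids)))
    return DesignMatrices(
        X=sp.csr_matrix(Xd),
        Z=Z,
        W=W,
        animal_idx=animal_idx,
        cow_idx=cow_idx,
        animal_ids=list(ped.ids),
        cow_ids=cow_ids,
        x_columns=names,
        factor_levels=factor_levels,
        covariate_means=covariate_means,
    )


# ---------------------------------------------------------------------------
# results


@dataclass
class VarianceComponents:
    """Univariate REML estimates for one trait."""

    trait: str
    sigma2_a: float
    sigma2_pe: float
    sigma2_e: float
    se_a: float = float("nan")
    se_pe: float = float("nan")
    se_e: float = float("nan")
    cov_params: np.ndarray | None = None  # 3x3 sampling covariance (a, pe, e)
    logL: float = float("nan")
    aic: float = float("nan")
    n_params: int = 3
    converged: bool = False
    iterations: int = 0
    logL_history: list = field(default_factory=list)

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_a + self.sigma2_pe + self.sigma2_e


@dataclass
class BivariateComponents:
    """Bivariate REML estimates: 2x2 covariance blocks for a trait pair."""

    traits: tuple[str, str]
    G_a: np.ndarray
    G_pe: np.ndarray
    R: np.ndarray
    cov_params: np.ndarray | None = None  # 9x9, order per param_order
    param_order: tuple = (
        "Ga[0,0]", "Ga[0,1]", "Ga[1,1]",
        "Gpe[0,0]", "Gpe[0,1]", "Gpe[1,1]",
        "R[0,0]", "R[0,1]", "R[1,1]",
    )
    logL: float = float("nan")
    aic: float = float("nan")
    n_params: int = 9
    converged: bool = False
    iterations: int = 0
    logL_history: list = field(default_factory=list)

    @property
    def P(self) -> np.ndarray:
        """Phenotypic (co)variance block G_a + G_pe + R."""
        return self.G_a + self.G_pe + self.R

    def rg(self) -> float:
        from .genparams import correlation

        return correlation(self.G_a[0, 1], self.G_a[0, 0], self.G_a[1, 1])

    def rp(self) -> float:
        from .genparams import correlation

        P = self.P
        return correlation(P[0, 1], P[0, 0], P[1, 1])

    def rg_se(self) -> float:
        from .genparams import correlation_se

        if self.cov_params is None:
            return float("nan")
        sub = self.cov_params[np.ix_([0, 1, 2], [0, 1, 2])]
        return correlation_se(self.G_a[0, 1], self.G_a[0, 0], self.G_a[1, 1], sub)

    def marginal(self, which: int) -> VarianceComponents:
        """Marginal components of trait 0 or 1 as a VarianceComponents."""
        i = int(which)
        return VarianceComponents(
            trait=self.traits[i],
            sigma2_a=float(self.G_a[i, i]),
            sigma2_pe=float(self.G_pe[i, i]),
            sigma2_e=float(self.R[i, i]),
            logL=self.logL,
            aic=self.aic,
            n_params=self.n_params,
            converged=self.converged,
            iterations=self.iterations,
        )


# ---------------------------------------------------------------------------
# the multi-trait engine


def _sym(M):
    return 0.5 * (M + M.T)


def _psd_floor(M, floor):
    """Nearest symmetric PSD matrix with eigenvalues >= floor."""
    M = _sym(np.atleast_2d(np.asarray(M, dtype=float)))
    w, V = np.linalg.eigh(M)
    return (V * np.maximum(w, floor)) @ V.T


def _inv_logdet(M, floor):
    M = _psd_floor(M, floor)
    w, V = np.linalg.eigh(M)
    return (V * (1.0 / w)) @ V.T, float(np.log(w).sum())


def _param_basis(k):
    """Symmetric basis matrices E_st for the lower triangle of a kxk block."""
    out = []
    for s in range(k):
        for t in range(s, k):
            E = np.zeros((k, k))
            E[s, t] = E[t, s] = 1.0
            out.append((s, t, E))
    return out


class _Engine:
    """Shared state for one (X, Z, W, A-inverse, Y) REML problem."""

    def __init__(self, dm: DesignMatrices, Ainv, Y: np.ndarray):
        if isinstance(Ainv, NrmInverse):
            self.Ainv = Ainv.matrix.tocsr()
            self.logdet_A = Ainv.log_det_A
        else:
            self.Ainv = sp.csr_matrix(Ainv)
            lu = sp.linalg.splu(self.Ainv.tocsc())
            self.logdet_A = -float(
                np.log(np.abs(lu.U.diagonal())).sum()
                + np.log(np.abs(lu.L.diagonal())).sum()
            )
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] != dm.n_records:
            Y = Y.T
        self.Y = Y
        self.n, self.k = Y.shape
        self.p = dm.X.shape[1]
        self.q = len(dm.animal_ids)
        self.c = len(dm.cow_ids)
        if self.Ainv.shape != (self.q, self.q):
            raise ValueError("A-inverse dimension does not match the pedigree")
        self.dim0 = self.p + self.q
        self.dim = self.k * self.dim0
        X, ai, ci = dm.X, dm.animal_idx, dm.cow_idx
        self.X, self.animal_idx, self.cow_idx = X, ai, ci
        self.nrec_animal = np.bincount(ai, minlength=self.q).astype(float)
        self.nrec_cow = np.bincount(ci, minlength=self.c).astype(float)

        XtX = (X.T @ X).toarray()
        XtZ = (X.T @ dm.Z).tocsr()
        XtW = (X.T @ dm.W).tocsr()
        ZtW = (dm.Z.T @ dm.W).tocsr()
        TT = sp.bmat(
            [[sp.csr_matrix(XtX), XtZ], [XtZ.T, sp.diags(self.nrec_animal)]],
            format="csr",
        )
        self.TT_dense = TT.toarray()
        ttc = TT.tocoo()
        self.tt_row, self.tt_col, self.tt_data = ttc.row, ttc.col, ttc.data
        U = sp.vstack([XtW, ZtW]).tocsc()
        self.U = U
        self.u_idx = [
            U.indices[U.indptr[j] : U.indptr[j + 1]] for j in range(self.c)
        ]
        self.u_val = [
            U.data[U.indptr[j] : U.indptr[j + 1]] for j in range(self.c)
        ]
        ac = self.Ainv.tocoo()
        self.ai_row, self.ai_col, self.ai_data = ac.row, ac.col, ac.data

        self.XtY = (X.T @ Y) if sp.issparse(X) else X.T @ Y
        self.XtY = np.asarray(self.XtY)
        self.ZtY = np.column_stack(
            [np.bincount(ai, weights=Y[:, t], minlength=self.q) for t in range(self.k)]
        )
        self.WtY = np.column_stack(
            [np.bincount(ci, weights=Y[:, t], minlength=self.c) for t in range(self.k)]
        )
        self.vary = Y.var(axis=0, ddof=1)
        self.floor = 1e-8 * float(self.vary.mean())
        self.basis = _param_basis(self.k)
        self.m = 3 * len(self.basis)

    # -- one full evaluation at a parameter point --------------------------
    def evaluate(self, theta):
        Ga, Gpe, R0 = theta
        k, p, q, c, n, dim0 = self.k, self.p, self.q, self.c, self.n, self.dim0
        Ri, ldR0 = _inv_logdet(R0, self.floor)
        Gai, ldGa = _inv_logdet(Ga, self.floor)
        Gpei, ldGpe = _inv_logdet(Gpe, self.floor)

        D = self.nrec_cow[:, None, None] * Ri + Gpei  # (c,k,k)
        Dinv = np.linalg.inv(D)
        sign, ldD_each = np.linalg.slogdet(D)
        ldD = float(ldD_each.sum())
        M1 = np.einsum("su,cuv->csv", Ri, Dinv)  # Ri D^-1 per cow
        Mfull = np.einsum("csu,ut->cst", M1, Ri)  # Ri D^-1 Ri per cow

        # core system S = C_top - F D^-1 F'
        S = np.kron(Ri, self.TT_dense)
        for s in range(k):
            for t in range(k):
                r0, c0 = s * dim0, t * dim0
                S[r0 + p + self.ai_row, c0 + p + self.ai_col] += (
                    Gai[s, t] * self.ai_data
                )
                Esp = (self.U @ sp.diags(Mfull[:, s, t]) @ self.U.T).tocoo()
                S[r0 + Esp.row, c0 + Esp.col] -= Esp.data

        # near-singular covariance blocks (e.g. exactly collinear traits at
        # the variance floor) can leave S numerically indefinite: retry with
        # a growing ridge before giving up
        ridge = 0.0
        mean_diag = float(np.mean(np.diag(S)))
        for attempt in range(4):
            L, info = lapack.dpotrf(S + ridge * np.eye(self.dim), lower=1)
            if info == 0:
                break
            ridge = max(ridge * 100.0, 1e-12 * mean_diag)
        if info != 0:
            raise np.linalg.LinAlgError(
                f"MME core not positive definite (info={info}); "
                "check design rank and variance floors"
            )
        logdetS = 2.0 * float(np.log(np.diag(L)).sum())
        Sinv, info = lapack.dpotri(L, lower=1)
        if info != 0:
            raise np.linalg.LinAlgError("dpotri failed")
        Sinv = np.tril(Sinv) + np.tril(Sinv, -1).T

        solve = lambda rhs: sla.cho_solve((L, True), rhs, check_finite=False)

        # solutions for y
        sol_top, pe_sol, resid = self._solve_system(self.Y, Ri, Dinv, M1, solve)
        v = resid @ Ri  # P y, per record and trait
        yPy = float((self.Y * v).sum())
        neg2logL = (
            k * (n - p) * np.log(_TWO_PI)
            + n * ldR0
            + q * ldGa
            + k * self.logdet_A
            + c * ldGpe
            + ldD
            + logdetS
            + yPy
        )
        logL = -0.5 * neg2logL

        ahat = sol_top[:, p:]  # (k, q)
        bhat = sol_top[:, :p]

        # quadratic forms
        AinvA = (self.Ainv @ ahat.T)  # (q, k)
        Qa = ahat @ AinvA
        Qpe = pe_sol.T @ pe_sol
        Ee = resid.T @ resid
        Qv = v.T @ v

        # trace machinery via the Schur complement
        TrA = np.empty((k, k))
        for s in range(k):
            for t in range(k):
                TrA[s, t] = float(
                    np.dot(
                        self.ai_data,
                        Sinv[s * dim0 + p + self.ai_row, t * dim0 + p + self.ai_col],
                    )
                )
        psi = self._psi(Sinv)  # (c,k,k): U_j' Sinv^(s,s') U_j
        Phi = np.einsum("cst,csu,cuv->ctv", M1, psi, M1)
        TrPe = Dinv.sum(axis=0) + Phi.sum(axis=0)

        # residual trace matrix T[s,t] = tr of (s,t) record-block of M C^-1 M'
        T = np.empty((k, k))
        for s in range(k):
            for t in range(k):
                T[s, t] = float(
                    np.dot(
                        self.tt_data,
                        Sinv[s * dim0 + self.tt_row, t * dim0 + self.tt_col],
                    )
                )
        pm = np.einsum("csu,cut->cst", psi, M1).sum(axis=0)  # sum_j psi_j M1_j
        T -= pm + pm.T
        T += np.einsum("c,cst->st", self.nrec_cow, Dinv + Phi)

        return {
            "theta": theta,
            "Ri": Ri,
            "Gai": Gai,
            "Gpei": Gpei,
            "Dinv": Dinv,
            "M1": M1,
            "solve": solve,
            "bhat": bhat,
            "ahat": ahat,
            "pe": pe_sol,
            "resid": resid,
            "v": v,
            "logL": logL,
            "Qa": Qa,
            "Qpe": Qpe,
            "Qv": Qv,
            "Ee": Ee,
            "TrA": TrA,
            "TrPe": TrPe,
            "T": T,
        }

    def _psi(self, Sinv):
        """Per-cow quadratic forms U_j' Sinv^(s,s') U_j across trait blocks."""
        k, dim0 = self.k, self.dim0
        offsets = np.arange(k) * dim0
        psi = np.empty((self.c, k, k))
        for j in range(self.c):
            idx = self.u_idx[j]
            val = self.u_val[j]
            m = idx.size
            I = (offsets[:, None] + idx[None, :]).reshape(-1)
            sub = Sinv[np.ix_(I, I)].reshape(k, m, k, m)
            psi[j] = np.einsum("i,sitj,j->st", val, sub, val)
        return psi

    def _solve_system(self, F, Ri, Dinv, M1, solve):
        """Solve the absorbed MME for data-like right-hand sides F (n,k).

        Returns (sol_top (k, dim0), pe (c,k), resid (n,k)) where resid is
        F - X b - Z a - W pe per trait.
        """
        p, k = self.p, self.k
        XtF = np.asarray(self.X.T @ F)
        ZtF = np.column_stack(
            [
                np.bincount(self.animal_idx, weights=F[:, t], minlength=self.q)
                for t in range(k)
            ]
        )
        WtF = np.column_stack(
            [
                np.bincount(self.cow_idx, weights=F[:, t], minlength=self.c)
                for t in range(k)
            ]
        )
        TopF = np.vstack([XtF, ZtF])  # (dim0, k)
        r_top = TopF @ Ri  # (dim0, k); column s = sum_t Ri[s,t] TopF[:,t]
        r_pe = WtF @ Ri  # (c, k)
        rho = np.einsum("cst,ct->cs", Dinv, r_pe)
        w = rho @ Ri  # (c, k): (M1_j r_pe_j)[s]
        corr = np.asarray(self.U @ w)  # (dim0, k)
        rhs = (r_top - corr).T.reshape(-1)  # trait-major flatten
        sol = solve(rhs).reshape(k, self.dim0)
        Us = np.asarray(self.U.T @ sol.T)  # (c, k): U_j . sol_top[s]
        fps = Us @ Ri  # (c, k): (F' sol_top)_(t,j)
        pe = np.einsum("ctu,cu->ct", Dinv, r_pe - fps)
        fitted = (
            np.asarray(self.X @ sol[:, :p].T)
            + sol[:, p:][:, self.animal_idx].T
            + pe.T[:, self.cow_idx].T
        )
        return sol, pe, F - fitted

    # -- updates -----------------------------------------------------------
    def em_step(self, st):
        Ga = _psd_floor((st["Qa"] + st["TrA"]) / self.q, self.floor)
        Gpe = _psd_floor((st["Qpe"] + st["TrPe"]) / self.c, self.floor)
        R0 = _psd_floor((st["Ee"] + st["T"]) / self.n, self.floor)
        return (Ga, Gpe, R0)

    def score(self, st):
        out = []
        for blk, Bi, Tr, Q, count in (
            ("a", st["Gai"], st["TrA"], st["Qa"], self.q),
            ("pe", st["Gpei"], st["TrPe"], st["Qpe"], self.c),
            ("r", st["Ri"], st["T"], st["Qv"], self.n),
        ):
            for s, t, E in self.basis:
                BEB = Bi @ E @ Bi
                if blk == "r":
                    trPH = count * np.trace(E @ Bi) - np.trace(BEB @ Tr)
                    yphpy = np.trace(E @ Q)
                else:
                    trPH = count * np.trace(E @ Bi) - np.trace(BEB @ Tr)
                    yphpy = np.trace(BEB @ Q)
                out.append(-0.5 * (trPH - yphpy))
        return np.array(out)

    def ai_matrix(self, st):
        """Average information: AI_ij = 0.5 f_i' P f_j."""
        n, k = self.n, self.k
        fs = []
        for blk in ("a", "pe", "r"):
            for s, t, E in self.basis:
                if blk == "a":
                    mix = (E @ st["Gai"]) @ st["ahat"]  # (k, q)
                    fs.append(mix[:, self.animal_idx].T)
                elif blk == "pe":
                    mix = (E @ st["Gpei"]) @ st["pe"].T  # (k, c)
                    fs.append(mix[:, self.cow_idx].T)
                else:
                    fs.append(st["v"] @ E)
        AI = np.empty((self.m, self.m))
        Pfs = [
            self._solve_system(f, st["Ri"], st["Dinv"], st["M1"], st["solve"])[2]
            @ st["Ri"]
            for f in fs
        ]
        for i, fi in enumerate(fs):
            for j in range(i, self.m):
                AI[i, j] = AI[j, i] = 0.5 * float((fi * Pfs[j]).sum())
        return AI

    def pack(self, theta):
        Ga, Gpe, R0 = theta
        vals = []
        for M in (Ga, Gpe, R0):
            for s, t, _ in self.basis:
                vals.append(M[s, t])
        return np.array(vals)

    def unpack(self, vec):
        nb = len(self.basis)
        mats = []
        for b in range(3):
            M = np.zeros((self.k, self.k))
            for (s, t, _), val in zip(self.basis, vec[b * nb : (b + 1) * nb]):
                M[s, t] = M[t, s] = val
            mats.append(_psd_floor(M, self.floor))
        return tuple(mats)


@dataclass
class _FitOutcome:
    theta: tuple
    logL: float
    converged: bool
    iterations: int
    history: list
    cov_params: np.ndarray | None


def _run_fit(engine: _Engine, start, method, max_iter, rtol, ltol):
    theta = tuple(_psd_floor(np.atleast_2d(m), engine.floor) for m in start)
    st = engine.evaluate(theta)
    history = [st["logL"]]
    converged = False
    it = 0
    dlog = float("nan")
    for it in range(1, max_iter + 1):
        used_ai = False
        theta_prop = None
        if method == "ai" and it > 1:
            try:
                AI = engine.ai_matrix(st)
                step = np.linalg.solve(AI, engine.score(st))
                cand = engine.pack(theta) + step
                theta_prop = engine.unpack(cand)
                # an ill-conditioned AI matrix (likelihood unbounded along a
                # ray, e.g. exactly collinear traits) can propose physically
                # meaningless scales: fall back to EM instead
                cap = 1e4 * float(engine.vary.mean())
                if any(np.trace(M) > cap for M in theta_prop):
                    theta_prop = None
                else:
                    used_ai = True
            except np.linalg.LinAlgError:
                theta_prop = None
        if theta_prop is None:
            theta_prop = engine.em_step(st)
        try:
            st_prop = engine.evaluate(theta_prop)
            if not np.isfinite(st_prop["logL"]):
                st_prop = None
        except np.linalg.LinAlgError:
            st_prop = None
        if used_ai and st_prop is None:
            theta_prop = engine.em_step(st)
            try:
                st_prop = engine.evaluate(theta_prop)
            except np.linalg.LinAlgError:
                st_prop = None
        if st_prop is None or not np.isfinite(st_prop["logL"]):
            # parameters have degenerated (typically a boundary of the PSD
            # cone with collinear traits): keep the last good state
            warnings.warn(
                "REML stopped at iteration "
                f"{it}: parameter update left the numerically feasible "
                "region; returning the last evaluable estimates",
                stacklevel=3,
            )
            break
        if used_ai and st_prop["logL"] < st["logL"] - 1e-8:
            theta_prop = engine.em_step(st)
            st_prop = engine.evaluate(theta_prop)
        if st_prop["logL"] < st["logL"] - 1e-8:
            # even the EM step decreases the likelihood: only possible at a
            # numerical boundary (variance floors / PSD projection); stop
            # with the current estimates rather than drift
            warnings.warn(
                f"REML stopped at iteration {it}: no update improves the "
                "restricted likelihood (numerical boundary)",
                stacklevel=3,
            )
            break
        old = engine.pack(theta)
        new = engine.pack(theta_prop)
        # components at the variance floor are effectively zero; measure their
        # change against the phenotypic scale, not their own magnitude
        scale = np.maximum(np.abs(old), 1e-6 * float(engine.vary.mean()))
        rel = float(np.max(np.abs(new - old) / scale))
        dlog = st_prop["logL"] - st["logL"]
        theta, st = theta_prop, st_prop
        history.append(st["logL"])
        if rel < rtol or abs(dlog) < ltol:
            converged = True
            break
    cov = None
    try:
        AI = engine.ai_matrix(st)
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        pass
    if not converged:
        warnings.warn(
            f"REML did not converge in {it} iterations (last dlogL={dlog:.3g})",
            stacklevel=3,
        )
    return _FitOutcome(theta, st["logL"], converged, it, history, cov)


# ---------------------------------------------------------------------------
# public fitting interfaces


def _default_start_univariate(y):
    v = float(np.var(y, ddof=1))
    return (
        np.array([[0.3 * v]]),
        np.array([[0.2 * v]]),
        np.array([[0.5 * v]]),
    )


def reml_univariate(
    dm: DesignMatrices,
    Ainv,
    y,
    start=None,
    trait: str = "trait",
    method: str = "ai",
    max_iter: int = 500,
    rtol: float = 1e-8,
    ltol: float = 1e-6,
) -> VarianceComponents:
    """Univariate EM/AI-REML fit of the repeatability animal model.

    ``start`` may be a VarianceComponents or a (s2a, s2pe, s2e) triple;
    ``method`` is "ai" (AI with EM fallback, default) or "em" (pure EM,
    monotone log-likelihood).  Non-convergence is returned with
    ``converged=False`` and a warning, never silently.
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    eng = _Engine(dm, Ainv, y[:, None])
    if start is None:
        theta0 = _default_start_univariate(y)
    else:
        if hasattr(start, "sigma2_a"):
            vals = (start.sigma2_a, start.sigma2_pe, start.sigma2_e)
        else:
            vals = tuple(start)
        if any(v <= 0 for v in vals):
            raise ValueError("starting components must be positive")
        theta0 = tuple(np.array([[float(v)]]) for v in vals)
    out = _run_fit(eng, theta0, method, max_iter, rtol, ltol)
    Ga, Gpe, R0 = out.theta
    ses = (float("nan"),) * 3
    if out.cov_params is not None:
        d = np.sqrt(np.maximum(np.diag(out.cov_params), 0.0))
        ses = tuple(d[:3])
    vc = VarianceComponents(
        trait=trait,
        sigma2_a=float(Ga[0, 0]),
        sigma2_pe=float(Gpe[0, 0]),
        sigma2_e=float(R0[0, 0]),
        se_a=ses[0],
        se_pe=ses[1],
        se_e=ses[2],
        cov_params=out.cov_params,
        logL=out.logL,
        aic=aic(out.logL, 3),
        n_params=3,
        converged=out.converged,
        iterations=out.iterations,
        logL_history=out.history,
    )
    return vc


def reml_bivariate(
    dm: DesignMatrices,
    Ainv,
    y1,
    y2,
    start=None,
    traits: tuple[str, str] = ("trait1", "trait2"),
    method: str = "ai",
    max_iter: int = 500,
    rtol: float = 1e-8,
    ltol: float = 1e-6,
) -> BivariateComponents:
    """Bivariate EM/AI-REML fit for two traits observed on the same records.

    Starting values default to univariate fits of each trait with
    cross-covariances seeded at half the phenotypic correlation; blocks that
    leave the PSD cone during updates are projected back.
    """
    y1 = np.asarray(y1, dtype=float).reshape(-1)
    y2 = np.asarray(y2, dtype=float).reshape(-1)
    Y = np.column_stack([y1, y2])
    eng = _Engine(dm, Ainv, Y)
    if start is None:
        u1 = reml_univariate(dm, Ainv, y1, method="ai", max_iter=max_iter)
        u2 = reml_univariate(dm, Ainv, y2, method="ai", max_iter=max_iter)
        ry = float(np.corrcoef(y1, y2)[0, 1])
        seed = 0.5 * ry

        def block(a, b):
            off = seed * np.sqrt(a * b)
            return np.array([[a, off], [off, b]])

        theta0 = (
            block(u1.sigma2_a, u2.sigma2_a),
            block(u1.sigma2_pe, u2.sigma2_pe),
            block(u1.sigma2_e, u2.sigma2_e),
        )
    else:
        theta0 = tuple(np.asarray(m, dtype=float) for m in start)
    out = _run_fit(eng, theta0, method, max_iter, rtol, ltol)
    Ga, Gpe, R0 = out.theta
    return BivariateComponents(
        traits=tuple(traits),
        G_a=Ga,
        G_pe=Gpe,
        R=R0,
        cov_params=out.cov_params,
        logL=out.logL,
        aic=aic(out.logL, 9),
        n_params=9,
        converged=out.converged,
        iterations=out.iterations,
        logL_history=out.history,
    )
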