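"""Restricted maximum likelihood for pedigree mixed models.

This module implements the numerical core used by the model classes in
:mod:`crosslay.animal_model`: average-information REML (AI-REML) with EM
fallback steps, for Gaussian mixed models of the form

    y = X beta + sum_i Z_i u_i + e,
    u_i ~ N(0, G0_i (x) K_i),      e ~ N(0, R),

where each random term has a known structure matrix ``K_i`` (a numerator
relationship matrix for additive genetic effects, the identity for
permanent environmental effects) and a small ``t x t`` covariance block
``G0_i`` (a scalar variance for univariate terms, a 2 x 2 block for
bivariate fits).  The residual is either a diagonal with one variance per
record group (heterogeneous residuals across genetic groups) or a paired
2 x 2 block structure for bivariate fits.

All quantities flow through the mixed model equations.  Scalar
identity-structure terms whose levels do not share records (permanent
environmental effects) contribute a diagonal block to the coefficient
matrix; those equations are absorbed exactly via the Schur complement, so
only the remaining (fixed + pedigree-structured) equations are factorised
densely.  This is pure linear algebra - the likelihood, scores and updates
are identical to the unabsorbed system.

The restricted log-likelihood is reported up to an additive constant as
``-0.5 * (log|R| + log|G| + log|C| + y'Py)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg import lapack as _lapack

__all__ = ["RandomTerm", "DiagonalResidual", "PairedResidual", "REMLProblem", "REMLFit"]


# ---------------------------------------------------------------------- #
@dataclass
class RandomTerm:
    """One random effect: ``u ~ N(0, G0 (x) K)``, trait-major ordering.

    Parameters
    ----------
    name : str
    level_idx : int array (n_records,)
        Level of the effect each record maps to, ``-1`` when the record is
        not linked to this term (used by the group-specific multivariate
        model, where each pseudo-trait only sees its own records).
    q : int
        Number of levels.
    kinv : sparse matrix (q, q)
        Inverse of the structure matrix K (A-inverse or identity).
    logdet_k : float
        log|K| (0 for the identity).
    n_traits : int
        Dimension of the G0 block (1 or 2).
    trait_idx : int array (n_records,), optional
        Which trait each record belongs to (all zeros when ``n_traits=1``).
    identity_k : bool
        Declares K to be the identity; such scalar terms are eligible for
        absorption.
    """

    name: str
    level_idx: np.ndarray
    q: int
    kinv: sparse.spmatrix
    logdet_k: float = 0.0
    n_traits: int = 1
    trait_idx: np.ndarray | None = None
    identity_k: bool = False

    def __post_init__(self):
        if self.trait_idx is None:
            self.trait_idx = np.zeros_like(self.level_idx)
        self.n_params = self.n_traits * (self.n_traits + 1) // 2

    def incidence(self, n: int) -> sparse.csr_matrix:
        linked = self.level_idx >= 0
        rows = np.flatnonzero(linked)
        cols = self.trait_idx[linked] * self.q + self.level_idx[linked]
        data = np.ones(rows.size)
        return sparse.coo_matrix(
            (data, (rows, cols)), shape=(n, self.n_traits * self.q)
        ).tocsr()


def _sym_elementaries(t: int) -> list[np.ndarray]:
    """Symmetric elementary matrices in (v11, c21, v22, ...) order."""
    out = []
    for i in range(t):
        for j in range(i + 1):
            E = np.zeros((t, t))
            E[i, j] = E[j, i] = 1.0
            out.append(E)
    return out


def _pack(G0: np.ndarray) -> np.ndarray:
    t = G0.shape[0]
    return np.array([G0[i, j] for i in range(t) for j in range(i + 1)])


def _unpack(theta: np.ndarray, t: int) -> np.ndarray:
    G0 = np.zeros((t, t))
    k = 0
    for i in range(t):
        for j in range(i + 1):
            G0[i, j] = G0[j, i] = theta[k]
            k += 1
    return G0


# ---------------------------------------------------------------------- #
@dataclass
class DiagonalResidual:
    """Heterogeneous diagonal residual: one variance per record group."""

    group_idx: np.ndarray
    n_groups: int

    @property
    def n_params(self) -> int:
        return self.n_groups

    def rinv_diag(self, theta: np.ndarray) -> np.ndarray:
        return 1.0 / theta[self.group_idx]

    def logdet(self, theta: np.ndarray) -> float:
        counts = np.bincount(self.group_idx, minlength=self.n_groups)
        return float(np.sum(counts * np.log(theta)))


@dataclass
class PairedResidual:
    """2 x 2 residual blocks for bivariate fits.

    Records carry a trait index (0/1) and a pair id; the two records of a
    pair (same animal, same repeat) have residual covariance ``c12``;
    unpaired records only contribute their trait's variance.
    Parameters are ordered ``(v1, c12, v2)``.
    """

    trait_idx: np.ndarray
    pair_id: np.ndarray  # -1 for unpaired

    def __post_init__(self):
        self.n = self.trait_idx.shape[0]
        order = np.lexsort((self.trait_idx, self.pair_id))
        pid = self.pair_id[order]
        self.i0, self.i1 = [], []
        k = 0
        while k < len(order):
            if pid[k] < 0:
                k += 1
                continue
            if k + 1 < len(order) and pid[k + 1] == pid[k]:
                a, b = order[k], order[k + 1]
                if self.trait_idx[a] == 1:
                    a, b = b, a
                self.i0.append(a)
                self.i1.append(b)
                k += 2
            else:
                k += 1
        self.i0 = np.asarray(self.i0, dtype=np.int64)
        self.i1 = np.asarray(self.i1, dtype=np.int64)
        in_pair = np.zeros(self.n, dtype=bool)
        in_pair[self.i0] = True
        in_pair[self.i1] = True
        self.singles = np.flatnonzero(~in_pair)

    @property
    def n_params(self) -> int:
        return 3

    def rinv_sparse(self, theta: np.ndarray) -> sparse.csr_matrix:
        v1, c, v2 = theta
        det = v1 * v2 - c * c
        npair = self.i0.size
        rows = [self.i0, self.i1, self.i0, self.i1, self.singles]
        cols = [self.i0, self.i1, self.i1, self.i0, self.singles]
        sv = np.where(self.trait_idx[self.singles] == 0, 1.0 / v1, 1.0 / v2)
        vals = [
            np.full(npair, v2 / det),
            np.full(npair, v1 / det),
            np.full(npair, -c / det),
            np.full(npair, -c / det),
            sv,
        ]
        return sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        ).tocsr()

    def dr_sparse(self, k: int) -> sparse.csr_matrix:
        """dR/dtheta_k as a sparse matrix."""
        if k in (0, 2):
            t = 0 if k == 0 else 1
            idx = np.flatnonzero(self.trait_idx == t)
            rows, cols, vals = idx, idx, np.ones(idx.size)
        else:
            rows = np.concatenate([self.i0, self.i1])
            cols = np.concatenate([self.i1, self.i0])
            vals = np.ones(rows.size)
        return sparse.coo_matrix((vals, (rows, cols)), shape=(self.n, self.n)).tocsr()

    def logdet(self, theta: np.ndarray) -> float:
        v1, c, v2 = theta
        det = v1 * v2 - c * c
        n_s0 = int(np.sum(self.trait_idx[self.singles] == 0))
        n_s1 = self.singles.size - n_s0
        return float(
            self.i0.size * np.log(det) + n_s0 * np.log(v1) + n_s1 * np.log(v2)
        )


# ---------------------------------------------------------------------- #
@dataclass
class REMLFit:
    converged: bool
    n_iter: int
    loglik: float
    theta: np.ndarray
    theta_se: np.ndarray
    theta_cov: np.ndarray
    beta: np.ndarray
    beta_cov: np.ndarray
    u: dict
    pinned: np.ndarray
    message: str = ""
    history: list = field(default_factory=list)
    degenerate: bool = False


class _State:
    """Factorised mixed model equations at one parameter value.

    Columns are split into a dense part (fixed effects + pedigree-structured
    random terms) and an absorbed part (diagonal blocks).  With S the dense
    block, D the absorbed diagonal and B the coupling, the object holds the
    Cholesky factor of the Schur complement ``S - B D^-1 B'`` and exposes
    solves, log-determinant and the pieces of C^-1 the REML updates need.
    """

    def __init__(self, prob, theta):
        self.prob = prob
        self.theta = theta
        res = prob.residual
        if isinstance(res, DiagonalResidual):
            rinv = res.rinv_diag(theta[prob.res_slice])
            self.Rinv = sparse.diags(rinv)
        else:
            self.Rinv = res.rinv_sparse(theta[prob.res_slice])
        Wr, Wa = prob.Wr, prob.Wa
        RWr = self.Rinv @ Wr
        S = (Wr.T @ RWr).toarray()
        logdet_g = 0.0
        for t, sl in zip(prob.terms, prob.slices):
            G0 = _unpack(theta[sl], t.n_traits)
            sign, ld = np.linalg.slogdet(G0)
            logdet_g += t.q * ld + t.n_traits * t.logdet_k
            if t.name in prob.absorbed:
                continue
            s0, s1 = prob.rest_span[t.name]
            G0inv = np.linalg.inv(G0)
            S[s0:s1, s0:s1] += sparse.kron(G0inv, t.kinv).toarray()
        self.logdet_g = logdet_g
        rhs_r = Wr.T @ (self.Rinv @ prob.y)
        if prob.n_abs:
            d = np.asarray((Wa.T @ self.Rinv @ Wa).diagonal()).ravel()
            for t, sl in zip(prob.terms, prob.slices):
                if t.name in prob.absorbed:
                    a0, a1 = prob.abs_span[t.name]
                    d[a0:a1] += 1.0 / theta[sl][0]
            B = (Wr.T @ (self.Rinv @ Wa)).tocsc()
            self.d = d
            self.B = B
            Bd = B.multiply(1.0 / d)  # B D^-1
            S = S - (Bd @ B.T).toarray()
            rhs_a = Wa.T @ (self.Rinv @ prob.y)
            rhs_r = rhs_r - Bd @ rhs_a
            self._rhs_a = rhs_a
            self._Bd = Bd.tocsc()
        else:
            self.d = np.empty(0)
            self.B = None
        self.cf = cho_factor(S, lower=True, check_finite=False)
        self.logdet_c = 2.0 * float(np.sum(np.log(np.diag(self.cf[0])))) + float(
            np.sum(np.log(self.d)) if prob.n_abs else 0.0
        )
        sol_r = cho_solve(self.cf, rhs_r, check_finite=False)
        sol = np.zeros(prob.M)
        sol[prob.rest_cols] = sol_r
        if prob.n_abs:
            sol_a = (self._rhs_a - self.B.T @ sol_r) / self.d
            sol[prob.abs_cols] = sol_a
        self.sol = sol
        self.e_hat = prob.y - prob.W @ sol
        self.Py = self.Rinv @ self.e_hat
        self.yPy = float(prob.y @ self.Py)
        logdet_r = res.logdet(theta[prob.res_slice])
        self.ll = -0.5 * (logdet_r + logdet_g + self.logdet_c + self.yPy)
        self._Sinv = None
        self._X = None  # Sinv @ B
        self._qdiag = None  # diag(B' Sinv B)

    # -- lazily computed inverse pieces --------------------------------- #
    @property
    def Sinv(self) -> np.ndarray:
        if self._Sinv is None:
            inv, info = _lapack.dpotri(self.cf[0], lower=1)
            if info != 0:
                raise np.linalg.LinAlgError("dpotri failed")
            self._Sinv = np.tril(inv) + np.tril(inv, -1).T
        return self._Sinv

    @property
    def X_SinvB(self) -> np.ndarray:
        if self._X is None:
            if self.prob.n_abs:
                self._X = self.Sinv @ self.B.toarray()
            else:
                self._X = np.zeros((self.prob.n_rest, 0))
        return self._X

    @property
    def qdiag(self) -> np.ndarray:
        if self._qdiag is None:
            if self.prob.n_abs:
                self._qdiag = np.asarray(
                    self.B.multiply(self.X_SinvB).sum(axis=0)
                ).ravel()
            else:
                self._qdiag = np.empty(0)
        return self._qdiag

    # -- C^-1 pieces ----------------------------------------------------- #
    def cinv_rest_block(self, s0: int, s1: int) -> np.ndarray:
        """C^-1 block of dense columns [s0:s1) (rest indexing)."""
        return self.Sinv[s0:s1, s0:s1]

    def cinv_abs_trace(self, a0: int, a1: int) -> float:
        """trace of the C^-1 diagonal block of absorbed columns [a0:a1)."""
        d = self.d[a0:a1]
        return float(np.sum(1.0 / d) + np.sum(self.qdiag[a0:a1] / d**2))

    def solve(self, V: np.ndarray) -> np.ndarray:
        """C^-1 @ V for full-length right-hand sides (2-D allowed)."""
        prob = self.prob
        V = np.asarray(V)
        one_d = V.ndim == 1
        if one_d:
            V = V[:, None]
        vr = V[prob.rest_cols]
        out = np.zeros_like(V)
        if prob.n_abs:
            va = V[prob.abs_cols]
            vr = vr - self._Bd @ va
            xr = cho_solve(self.cf, vr, check_finite=False)
            xa = (va - self.B.T @ xr) / self.d[:, None]
            out[prob.rest_cols] = xr
            out[prob.abs_cols] = xa
        else:
            out[prob.rest_cols] = cho_solve(self.cf, vr, check_finite=False)
        return out[:, 0] if one_d else out

    def hat_diag(self) -> np.ndarray:
        """diag(W C^-1 W') per record."""
        prob = self.prob
        Sinv = self.Sinv
        idx, val = prob.wr_idx, prob.wr_val
        sub = Sinv[idx[:, :, None], idx[:, None, :]]
        h = np.einsum("nk,nkl,nl->n", val, sub, val)
        if prob.n_abs:
            j = prob.rec_abs_col  # -1 when the record has no absorbed column
            m = j >= 0
            jm = j[m]
            # a' Sinv B[:, j]: gather X = Sinv B at the record's dense columns
            a_dot = np.einsum("nk,nk->n", val[m], self.X_SinvB[idx[m], jm[:, None]])
            d = self.d[jm]
            h[m] += -2.0 * a_dot / d + 1.0 / d + self.qdiag[jm] / d**2
        return h


class REMLProblem:
    """A REML estimation problem: response, fixed design, random terms."""

    def __init__(self, y, X, terms: list[RandomTerm], residual, absorb: bool = True):
        self.y = np.asarray(y, dtype=float)
        self.n = self.y.shape[0]
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.X = X
        self.p = X.shape[1]
        self.terms = terms
        self.residual = residual
        blocks = [sparse.csr_matrix(X)] + [t.incidence(self.n) for t in terms]
        self.W = sparse.hstack(blocks, format="csr")
        self.M = self.W.shape[1]
        sizes = np.array([t.n_traits * t.q for t in terms], dtype=int)
        self.offsets = self.p + np.cumsum(sizes)  # end offset per random block
        self.starts = self.offsets - sizes
        # parameter layout
        self.slices = []
        k = 0
        for t in terms:
            self.slices.append(slice(k, k + t.n_params))
            k += t.n_params
        self.res_slice = slice(k, k + residual.n_params)
        self.n_params = k + residual.n_params

        # -- column partition: absorbed (diagonal identity terms) vs rest --
        self.absorbed: set[str] = set()
        if absorb and isinstance(residual, DiagonalResidual):
            n_links = np.zeros(self.n, dtype=int)
            cand = [
                t for t in terms
                if t.identity_k and t.n_traits == 1 and t.q > 0
            ]
            for t in cand:
                n_links += (t.level_idx >= 0).astype(int)
            if cand and n_links.max() <= 1:
                self.absorbed = {t.name for t in cand}
        abs_mask = np.zeros(self.M, dtype=bool)
        self.rest_span: dict[str, tuple[int, int]] = {}
        self.abs_span: dict[str, tuple[int, int]] = {}
        a_off = 0
        for t, s0, s1 in zip(terms, self.starts, self.offsets):
            if t.name in self.absorbed:
                abs_mask[s0:s1] = True
                self.abs_span[t.name] = (a_off, a_off + (s1 - s0))
                a_off += s1 - s0
        self.abs_cols = np.flatnonzero(abs_mask)
        self.rest_cols = np.flatnonzero(~abs_mask)
        self.n_abs = self.abs_cols.size
        self.n_rest = self.rest_cols.size
        rest_pos = np.full(self.M, -1, dtype=np.int64)
        rest_pos[self.rest_cols] = np.arange(self.n_rest)
        abs_pos = np.full(self.M, -1, dtype=np.int64)
        abs_pos[self.abs_cols] = np.arange(self.n_abs)
        r_off = 0
        for t, s0, s1 in zip(terms, self.starts, self.offsets):
            if t.name not in self.absorbed:
                self.rest_span[t.name] = (rest_pos[s0], rest_pos[s0] + (s1 - s0))
        self.rest_span["__fixed__"] = (0, self.p)
        self.Wr = self.W[:, self.rest_cols].tocsr()
        self.Wa = self.W[:, self.abs_cols].tocsr() if self.n_abs else None

        # padded row structure of the dense part of W, for hat diagonals
        Wrcoo = self.Wr.tocoo()
        counts = np.bincount(Wrcoo.row, minlength=self.n)
        self.kmax = int(counts.max()) if counts.size else 1
        self.wr_idx = np.zeros((self.n, self.kmax), dtype=np.int64)
        self.wr_val = np.zeros((self.n, self.kmax))
        fill = np.zeros(self.n, dtype=np.int64)
        for r, c, v in zip(Wrcoo.row, Wrcoo.col, Wrcoo.data):
            self.wr_idx[r, fill[r]] = c
            self.wr_val[r, fill[r]] = v
            fill[r] += 1
        # at most one absorbed column per record (guaranteed above)
        self.rec_abs_col = np.full(self.n, -1, dtype=np.int64)
        if self.n_abs:
            Wacoo = self.Wa.tocoo()
            self.rec_abs_col[Wacoo.row] = Wacoo.col

        self._vscale = max(float(np.var(self._ols_resid())), 1e-12)
        self.var_floor = 1e-8 * self._vscale

    # ------------------------------------------------------------------ #
    def _ols_resid(self) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        return self.y - self.X @ beta

    def start_values(self) -> np.ndarray:
        """Observed phenotypic variance split equally over the components."""
        resid = self._ols_resid()
        theta = np.zeros(self.n_params)
        if isinstance(self.residual, PairedResidual):
            for trait in (0, 1):
                m = np.flatnonzero(self.residual.trait_idx == trait)
                v = float(np.var(resid[m])) if m.size > 1 else self._vscale
                share = v / (len(self.terms) + 1)
                for t, sl in zip(self.terms, self.slices):
                    G0 = _unpack(theta[sl].copy(), t.n_traits)
                    G0[trait, trait] = share
                    theta[sl] = _pack(G0)
                rtheta = theta[self.res_slice].copy()
                rtheta[0 if trait == 0 else 2] = share
                theta[self.res_slice] = rtheta
        else:
            v = float(np.var(resid))
            share = v / (len(self.terms) + 1)
            for t, sl in zip(self.terms, self.slices):
                theta[sl] = _pack(np.eye(t.n_traits) * share)
            theta[self.res_slice] = share
        lo = np.where(self._is_variance(), self.var_floor, theta)
        return np.maximum(theta, lo)

    def _is_variance(self) -> np.ndarray:
        mask = np.zeros(self.n_params, dtype=bool)
        for t, sl in zip(self.terms, self.slices):
            sub = []
            for i in range(t.n_traits):
                for j in range(i + 1):
                    sub.append(i == j)
            mask[sl] = sub
        if isinstance(self.residual, DiagonalResidual):
            mask[self.res_slice] = True
        else:
            mask[self.res_slice] = [True, False, True]
        return mask

    # ------------------------------------------------------------------ #
    def _assemble(self, theta) -> _State:
        return _State(self, theta)

    # ------------------------------------------------------------------ #
    def score_and_f(self, theta, state: _State):
        """Score vector and the dV/dtheta_k * Py vectors (for AI)."""
        Py = state.Py
        sol = state.sol
        score = np.zeros(self.n_params)
        F = np.zeros((self.n, self.n_params))
        for t, sl, s0, s1 in zip(self.terms, self.slices, self.starts, self.offsets):
            G0 = _unpack(theta[sl], t.n_traits)
            G0inv = np.linalg.inv(G0)
            U = sol[s0:s1].reshape(t.n_traits, t.q)
            Z = self.W[:, s0:s1]
            if t.name in self.absorbed:
                a0, a1 = self.abs_span[t.name]
                tr_cuu = state.cinv_abs_trace(a0, a1)
                sg2 = theta[sl][0]
                tr_PdV = t.q / sg2 - tr_cuu / sg2**2
                f = Z @ (U.reshape(-1) / sg2)
                F[:, sl.start] = f
                score[sl.start] = -0.5 * (tr_PdV - float(f @ Py))
                continue
            r0, r1 = self.rest_span[t.name]
            Cuu = state.cinv_rest_block(r0, r1)
            for k, E in enumerate(_sym_elementaries(t.n_traits)):
                M1 = G0inv @ E @ G0inv
                tr1 = t.q * float(np.trace(G0inv @ E))
                tr2 = 0.0
                for s in range(t.n_traits):
                    for r in range(t.n_traits):
                        if M1[s, r] != 0.0:
                            block = Cuu[r * t.q:(r + 1) * t.q, s * t.q:(s + 1) * t.q]
                            tr2 += M1[s, r] * float(np.sum(t.kinv.multiply(block.T)))
                tr_PdV = tr1 - tr2
                fu = (E @ G0inv @ U).reshape(-1)
                f = Z @ fu
                F[:, sl.start + k] = f
                score[sl.start + k] = -0.5 * (tr_PdV - float(f @ Py))
        if isinstance(self.residual, DiagonalResidual):
            h = state.hat_diag()
            rtheta = theta[self.res_slice]
            for g in range(self.residual.n_groups):
                m = self.residual.group_idx == g
                ng = int(m.sum())
                sg2 = rtheta[g]
                tr_PdV = ng / sg2 - float(h[m].sum()) / sg2**2
                f = np.where(m, Py, 0.0)
                k = self.res_slice.start + g
                F[:, k] = f
                score[k] = -0.5 * (tr_PdV - float(f @ Py))
        else:
            Rinv = state.Rinv
            Cinv = state.Sinv  # no absorption with paired residuals
            for k in range(3):
                dR = self.residual.dr_sparse(k)
                S = Rinv @ dR @ Rinv
                T = (self.W.T @ (S @ self.W)).tocoo()
                tr2 = float(np.sum(Cinv[T.col, T.row] * T.data))
                tr1 = float((Rinv.multiply(dR.T)).sum())
                f = dR @ Py
                kk = self.res_slice.start + k
                F[:, kk] = f
                score[kk] = -0.5 * ((tr1 - tr2) - float(f @ Py))
        return score, F

    def ai_matrix(self, state: _State, F) -> np.ndarray:
        Rinv = state.Rinv
        T1 = Rinv @ F
        T2 = self.W.T @ T1
        X2 = state.solve(T2)
        PF = T1 - Rinv @ (self.W @ X2)
        return 0.5 * F.T @ PF

    # ------------------------------------------------------------------ #
    def em_step(self, theta, state: _State) -> np.ndarray:
        """One EM update of every parameter (monotone in the likelihood)."""
        sol = state.sol
        e_hat = state.e_hat
        new = theta.copy()
        for t, sl, s0, s1 in zip(self.terms, self.slices, self.starts, self.offsets):
            U = sol[s0:s1].reshape(t.n_traits, t.q)
            if t.name in self.absorbed:
                a0, a1 = self.abs_span[t.name]
                quad = float(U.reshape(-1) @ U.reshape(-1))
                new[sl] = (quad + state.cinv_abs_trace(a0, a1)) / t.q
                continue
            r0, r1 = self.rest_span[t.name]
            Cuu = state.cinv_rest_block(r0, r1)
            G0n = np.zeros((t.n_traits, t.n_traits))
            for s in range(t.n_traits):
                for r in range(s + 1):
                    quad = float(U[s] @ (t.kinv @ U[r]))
                    block = Cuu[r * t.q:(r + 1) * t.q, s * t.q:(s + 1) * t.q]
                    trc = float(np.sum(t.kinv.multiply(block.T)))
                    G0n[s, r] = G0n[r, s] = (quad + trc) / t.q
            new[sl] = _pack(G0n)
        if isinstance(self.residual, DiagonalResidual):
            h = state.hat_diag()
            rnew = np.empty(self.residual.n_groups)
            for g in range(self.residual.n_groups):
                m = self.residual.group_idx == g
                rnew[g] = (float((e_hat[m] ** 2).sum()) + float(h[m].sum())) / m.sum()
            new[self.res_slice] = rnew
        else:
            res = self.residual
            Cinv = state.Sinv
            idx, val = self.wr_idx, self.wr_val

            def hat(i, j):
                sub = Cinv[idx[i][:, :, None], idx[j][:, None, :]]
                return np.einsum("nk,nkl,nl->n", val[i], sub, val[j])

            t0 = np.flatnonzero(res.trait_idx == 0)
            t1 = np.flatnonzero(res.trait_idx == 1)
            v1 = (float((e_hat[t0] ** 2).sum()) + float(hat(t0, t0).sum())) / t0.size
            v2 = (float((e_hat[t1] ** 2).sum()) + float(hat(t1, t1).sum())) / t1.size
            if res.i0.size:
                c = (
                    float((e_hat[res.i0] * e_hat[res.i1]).sum())
                    + float(hat(res.i0, res.i1).sum())
                ) / res.i0.size
            else:
                c = 0.0
            new[self.res_slice] = [v1, c, v2]
        return self._project(new)

    # ------------------------------------------------------------------ #
    def _project(self, theta: np.ndarray) -> np.ndarray:
        """Clip variances at the floor and covariance blocks to validity."""
        out = theta.copy()
        for t, sl in zip(self.terms, self.slices):
            G0 = _unpack(out[sl], t.n_traits)
            for i in range(t.n_traits):
                G0[i, i] = max(G0[i, i], self.var_floor)
            if t.n_traits == 2:
                cap = 0.999999 * np.sqrt(G0[0, 0] * G0[1, 1])
                G0[0, 1] = G0[1, 0] = np.clip(G0[0, 1], -cap, cap)
            out[sl] = _pack(G0)
        r = out[self.res_slice].copy()
        if isinstance(self.residual, DiagonalResidual):
            r = np.maximum(r, self.var_floor)
        else:
            r[0] = max(r[0], self.var_floor)
            r[2] = max(r[2], self.var_floor)
            cap = 0.999999 * np.sqrt(r[0] * r[2])
            r[1] = np.clip(r[1], -cap, cap)
        out[self.res_slice] = r
        return out

    # ------------------------------------------------------------------ #
    def fit(
        self,
        start: np.ndarray | None = None,
        maxiter: int = 200,
        tol_ll: float = 1e-6,
        tol_par: float = 1e-5,
        method: str = "ai",
        verbose: bool = False,
    ) -> REMLFit:
        theta = (
            self.start_values()
            if start is None
            else self._project(np.asarray(start, float))
        )
        if self._vscale <= 1e-10 * max(1.0, float(np.mean(self.y) ** 2)):
            floor_theta = self._project(np.full(self.n_params, self.var_floor))
            state = self._assemble(floor_theta)
            return self._result(
                floor_theta, state, True, 0,
                "degenerate: response has (near) zero residual variance",
                degenerate=True,
            )
        state = self._assemble(theta)
        ll = state.ll
        history = [ll]
        is_var = self._is_variance()
        pinned = np.zeros(self.n_params, dtype=bool)
        converged = False
        message = "maximum iterations reached"
        n_em_start = 2 if method == "ai" else maxiter
        it = 0
        for it in range(1, maxiter + 1):
            if method == "em" or it <= n_em_start:
                cand = self.em_step(theta, state)
                cand_state = self._assemble(cand)
            else:
                score, F = self.score_and_f(theta, state)
                # hold a variance at the floor only while the score pushes it
                # further down; it is released as soon as the gradient flips
                pinned = is_var & (theta <= self.var_floor * 1.000001) & (score <= 0.0)
                free = ~pinned
                step = np.zeros(self.n_params)
                AI = self.ai_matrix(state, F)
                try:
                    step[free] = np.linalg.solve(AI[np.ix_(free, free)], score[free])
                except np.linalg.LinAlgError:
                    step[free] = score[free] / np.maximum(np.diag(AI)[free], 1e-12)
                accepted = False
                factor = 1.0
                cand, cand_state = theta, state
                for _ in range(6):
                    trial = self._project(theta + factor * step)
                    trial[pinned] = theta[pinned]
                    try:
                        trial_state = self._assemble(trial)
                    except np.linalg.LinAlgError:
                        factor *= 0.5
                        continue
                    if trial_state.ll >= ll - 1e-10:
                        cand, cand_state, accepted = trial, trial_state, True
                        break
                    factor *= 0.5
                if not accepted:
                    # EM fallback when the AI update leaves the likelihood
                    cand = self.em_step(theta, state)
                    cand_state = self._assemble(cand)
            delta_ll = cand_state.ll - ll
            denom = np.maximum(np.abs(theta), 1e-3 * self._vscale)
            delta_par = float(np.max(np.abs(cand - theta) / denom))
            theta, state, ll = cand, cand_state, cand_state.ll
            history.append(ll)
            if verbose:
                print(f"iter {it}: ll={ll:.6f} dll={delta_ll:.3e} dpar={delta_par:.3e}")
            if it > n_em_start and abs(delta_ll) < tol_ll and delta_par < tol_par:
                converged = True
                message = "converged"
                break
        pinned = is_var & (theta <= self.var_floor * 1.000001)
        return self._result(
            theta, state, converged, it, message, pinned=pinned, history=history
        )

    # ------------------------------------------------------------------ #
    def _result(self, theta, state: _State, converged, n_iter, message,
                pinned=None, history=None, degenerate=False) -> REMLFit:
        if pinned is None:
            pinned = np.zeros(self.n_params, dtype=bool)
        beta = state.sol[: self.p]
        beta_cov = state.cinv_rest_block(0, self.p)
        u = {}
        for t, s0, s1 in zip(self.terms, self.starts, self.offsets):
            u[t.name] = state.sol[s0:s1].reshape(t.n_traits, t.q)
        theta_cov = np.full((self.n_params, self.n_params), np.nan)
        theta_se = np.full(self.n_params, np.nan)
        if not degenerate:
            try:
                score, F = self.score_and_f(theta, state)
                AI = self.ai_matrix(state, F)
                free = ~pinned
                cov = np.zeros_like(AI)
                cov[np.ix_(free, free)] = np.linalg.inv(AI[np.ix_(free, free)])
                theta_cov = cov
                theta_se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            except np.linalg.LinAlgError:
                pass
        return REMLFit(
            converged=converged,
            n_iter=n_iter,
            loglik=state.ll,
            theta=theta,
            theta_se=theta_se,
            theta_cov=theta_cov,
            beta=beta,
            beta_cov=beta_cov,
            u=u,
            pinned=pinned,
            message=message,
            history=history or [],
            degenerate=degenerate,
        )
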