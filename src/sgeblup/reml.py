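"""Average-information REML for the direct-social animal model.

The mixed model is

    y = X b + Z_D a_D [+ Z_S a_S] + W l + V g + e,
    (a_D, a_S) ~ N(0, C (x) K),  l ~ N(0, I s2_l),  g ~ N(0, I s2_g),
    e ~ N(0, I s2_e),

where K is the pedigree numerator relationship matrix A or the single-step
hybrid matrix H (only K^-1 is ever used).  Variance parameters are updated by
Newton steps on the REML log-likelihood with the average-information (AI)
matrix, falling back to an EM-REML step whenever an AI step would leave the
parameter space (negative variance or non-PSD C).

The REML log-likelihood is computed as

    logL = -0.5 [ (n - p) log 2*pi + log|R| + log|G| + log|M| + y' P y ],

with M the full mixed-model-equations coefficient matrix; the (n - p) log 2*pi
constant is included so logL values are comparable across models with the
same fixed-effect structure (it cancels in every delta-AIC).

All derivative quantities are obtained from the MME factorization:
Z' P Z = G^-1 - G^-1 C_uu G^-1 (C_uu = random-effect block of the inverse
coefficient matrix) supplies the traces for the gradient and EM updates, and
the AI matrix needs only extra MME solves, not extra inversions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .components import VarianceComponents
from .design import DesignMatrices, SocialModelSpec
from .genomic import build_H_inverse
from .pedigree import PedigreeTable, build_A_inverse, logdet_A

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticKernel",
    "FitResult",
    "MixedModelSystem",
    "fit_reml",
    "aic",
    "omega_grid",
    "default_start",
]


class RemlError(RuntimeError):
    pass


@dataclass
class GeneticKernel:
    """Relationship-matrix inverse plus its log-determinant and a K-multiply."""

    K_inv: sp.csr_matrix
    logdet_K: float
    label: str = "pedigree"

    def __post_init__(self) -> None:
        self.K_inv = sp.csr_matrix(self.K_inv)
        self._lu = None

    def _factor(self):
        if self._lu is None:
            self._lu = spla.splu(self.K_inv.tocsc())
        return self._lu

    def K_dot(self, v: np.ndarray) -> np.ndarray:
        """K v computed as K_inv^{-1} v via a cached sparse LU factorization."""
        return self._factor().solve(v)

    @property
    def n(self) -> int:
        return self.K_inv.shape[0]

    @classmethod
    def from_pedigree(cls, ped: PedigreeTable) -> "GeneticKernel":
        return cls(build_A_inverse(ped), logdet_A(ped), "pedigree")

    @classmethod
    def identity(cls, n: int) -> "GeneticKernel":
        return cls(sp.identity(n, format="csr"), 0.0, "identity")

    @classmethod
    def single_step(
        cls,
        ped: PedigreeTable,
        A22: np.ndarray,
        G_b: np.ndarray,
        genotyped_ids,
        tau: float = 1.0,
        omega: float = 1.0,
    ) -> "GeneticKernel":
        A_inv = build_A_inverse(ped)
        gix = ped.indices_of(genotyped_ids)
        H_inv = build_H_inverse(A_inv, A22, G_b, tau, omega, gix)
        sign, ld = np.linalg.slogdet(H_inv.toarray())
        if sign <= 0:
            raise np.linalg.LinAlgError(
                "H-inverse is not positive definite; reduce omega or blend more pedigree"
            )
        return cls(H_inv, -ld, f"single-step(tau={tau}, omega={omega})")


@dataclass
class FitResult:
    components: VarianceComponents
    logL: float
    aic: float
    converged: bool
    n_iter: int
    model_label: str
    trajectory: pd.DataFrame | None = None


def aic(logL: float, k: int) -> float:
    """Akaike information criterion, -2 logL + 2 k free (co)variance parameters."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return -2.0 * logL + 2.0 * k


def default_start(design: DesignMatrices, spec: SocialModelSpec) -> VarianceComponents:
    """Neutral start: the phenotypic variance split equally across components."""
    vy = float(np.var(design.y))
    n_parts = 2 + int(spec.include_litter) + int(spec.include_group) + int(spec.include_social)
    share = vy / n_parts
    return VarianceComponents(
        sigma2_aD=share,
        sigma_aDaS=0.0,
        sigma2_aS=share if spec.include_social else 0.0,
        sigma2_g=share if spec.include_group else 0.0,
        sigma2_l=share if spec.include_litter else 0.0,
        sigma2_e=share,
    )


def _drop_dependent_columns(X: sp.csr_matrix, names: list):
    """Remove linearly dependent fixed-effect columns (pivoted QR on X'X)."""
    Xd = X.toarray()
    _, R, piv = sla.qr(Xd, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xd.shape) * np.finfo(float).eps
    keep = np.sort(piv[: int((diag > tol).sum())])
    if len(keep) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in set(keep)]
        logger.info("dropping %d dependent fixed-effect columns: %s", len(dropped), dropped)
    return sp.csr_matrix(Xd[:, keep]), [names[j] for j in keep]


class MixedModelSystem:
    """Henderson MME machinery shared by REML and the BLUP solver.

    Equation order: fixed effects, a_D, [a_S], litter, group.
    """

    def __init__(self, design: DesignMatrices, kernel: GeneticKernel, spec: SocialModelSpec):
        if spec.include_social and design.Z_S is None:
            raise RemlError("spec includes social effects but design has no Z_S")
        self.design = design
        self.kernel = kernel
        self.spec = spec
        X, names = _drop_dependent_columns(design.X, design.fixed_names)
        self.fixed_names = names
        blocks = [X, design.Z_D]
        self.m = design.Z_D.shape[1]
        if kernel.n != self.m:
            raise RemlError(
                f"kernel dimension {kernel.n} does not match animal count {self.m}"
            )
        if spec.include_social:
            blocks.append(design.Z_S)
        if spec.include_litter:
            if design.W is None:
                raise RemlError("spec includes litter but design has no W")
            blocks.append(design.W)
        if spec.include_group:
            if design.V is None:
                raise RemlError("spec includes group but design has no V")
            blocks.append(design.V)
        self.W_all = sp.hstack(blocks, format="csr")
        self.p = X.shape[1]
        self.L = design.W.shape[1] if spec.include_litter else 0
        self.P = design.V.shape[1] if spec.include_group else 0
        self.n = design.y.shape[0]
        self.y = design.y
        self.n_gen = 2 if spec.include_social else 1
        # offsets
        self.off_g = self.p
        self.off_l = self.p + self.n_gen * self.m
        self.off_v = self.off_l + self.L
        self.n_eq = self.off_v + self.P
        self.WtW = (self.W_all.T @ self.W_all).tocoo()
        # dense copy pays ~n_eq^2 memory once to make per-iteration assembly a
        # single scaled copy instead of a scatter-add
        self._WtW_dense = self.WtW.toarray()
        self.Wty = self.W_all.T @ self.y
        self.yty = float(self.y @ self.y)
        Kcoo = kernel.K_inv.tocoo()
        self._K_rows, self._K_cols, self._K_data = Kcoo.row, Kcoo.col, Kcoo.data
        self.q_total = self.n_gen * self.m + self.L + self.P

    # ---- parameter vector <-> components ----
    def theta(self, comp: VarianceComponents) -> np.ndarray:
        parts = [comp.sigma2_aD]
        if self.spec.include_social:
            parts += [comp.sigma_aDaS, comp.sigma2_aS]
        if self.spec.include_litter:
            parts.append(comp.sigma2_l)
        if self.spec.include_group:
            parts.append(comp.sigma2_g)
        parts.append(comp.sigma2_e)
        return np.array(parts, dtype=float)

    def components(self, theta: np.ndarray) -> VarianceComponents:
        i = 0
        s_aD = theta[i]; i += 1
        s_DS = s_aS = 0.0
        if self.spec.include_social:
            s_DS, s_aS = theta[i], theta[i + 1]; i += 2
        s_l = 0.0
        if self.spec.include_litter:
            s_l = theta[i]; i += 1
        s_g = 0.0
        if self.spec.include_group:
            s_g = theta[i]; i += 1
        return VarianceComponents(s_aD, s_DS, s_aS, s_g, s_l, theta[i])

    def _C(self, theta: np.ndarray) -> np.ndarray:
        if self.spec.include_social:
            return np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
        return np.array([[theta[0]]])

    def _scalars(self, theta: np.ndarray):
        """(sigma2_l, sigma2_g, sigma2_e) positions handled generically."""
        i = 3 if self.spec.include_social else 1
        s_l = theta[i] if self.spec.include_litter else None
        if self.spec.include_litter:
            i += 1
        s_g = theta[i] if self.spec.include_group else None
        if self.spec.include_group:
            i += 1
        return s_l, s_g, theta[i]

    # ---- assembly and factorization ----
    def assemble(self, theta: np.ndarray) -> np.ndarray:
        s_l, s_g, s_e = self._scalars(theta)
        C = self._C(theta)
        Cinv = np.linalg.inv(C)
        M = self._WtW_dense / s_e
        for a in range(self.n_gen):
            for b in range(self.n_gen):
                np.add.at(
                    M,
                    (self.off_g + a * self.m + self._K_rows,
                     self.off_g + b * self.m + self._K_cols),
                    Cinv[a, b] * self._K_data,
                )
        if self.L:
            ix = self.off_l + np.arange(self.L)
            M[ix, ix] += 1.0 / s_l
        if self.P:
            ix = self.off_v + np.arange(self.P)
            M[ix, ix] += 1.0 / s_g
        return M

    def factorize(self, theta: np.ndarray):
        M = self.assemble(theta)
        try:
            cho = sla.cho_factor(M, lower=True, check_finite=False)
        except sla.LinAlgError as exc:
            raise RemlError(f"singular MME coefficient matrix: {exc}") from exc
        logdet_M = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        return cho, logdet_M

    def solve(self, cho, rhs: np.ndarray) -> np.ndarray:
        return sla.cho_solve(cho, rhs, check_finite=False)

    def logdet_G(self, theta: np.ndarray) -> float:
        s_l, s_g, _ = self._scalars(theta)
        C = self._C(theta)
        sign, ldC = np.linalg.slogdet(C)
        if sign <= 0:
            raise RemlError("genetic covariance matrix C is not positive definite")
        out = self.m * ldC + self.n_gen * self.kernel.logdet_K
        if self.L:
            out += self.L * np.log(s_l)
        if self.P:
            out += self.P * np.log(s_g)
        return out

    def loglik_parts(self, theta: np.ndarray, cho, logdet_M: float):
        _, _, s_e = self._scalars(theta)
        sol = self.solve(cho, self.Wty / s_e)
        yPy = (self.yty - self.Wty @ sol) / s_e
        logL = -0.5 * (
            (self.n - self.p) * np.log(2.0 * np.pi)
            + self.n * np.log(s_e)
            + self.logdet_G(theta)
            + logdet_M
            + yPy
        )
        return float(logL), sol, float(yPy)

    def loglik(self, comp: VarianceComponents) -> float:
        theta = self.theta(comp)
        cho, logdet_M = self.factorize(theta)
        logL, _, _ = self.loglik_parts(theta, cho, logdet_M)
        return logL

    # ---- pieces used by the REML iteration ----
    def _inverse(self, cho) -> np.ndarray:
        from scipy.linalg.lapack import dpotri

        inv, info = dpotri(cho[0], lower=True)
        if info != 0:
            raise RemlError(f"dpotri failed with info={info}")
        inv = np.tril(inv) + np.tril(inv, -1).T
        return inv

    def _genetic_traces(self, Minv: np.ndarray) -> np.ndarray:
        """T_ab = tr(K^-1 Cuu_ab) over the genetic blocks of the MME inverse."""
        T = np.zeros((self.n_gen, self.n_gen))
        r, c, d = self._K_rows, self._K_cols, self._K_data
        for a in range(self.n_gen):
            for b in range(a, self.n_gen):
                blk = Minv[self.off_g + a * self.m :, self.off_g + b * self.m :][
                    : self.m, : self.m
                ]
                T[a, b] = T[b, a] = float(np.sum(d * blk[c, r]))
        return T

    def _deriv_mats(self):
        """Symmetric dC matrices, one per genetic parameter."""
        if self.spec.include_social:
            return [
                np.array([[1.0, 0.0], [0.0, 0.0]]),
                np.array([[0.0, 1.0], [1.0, 0.0]]),
                np.array([[0.0, 0.0], [0.0, 1.0]]),
            ]
        return [np.array([[1.0]])]


def _psd_project(C: np.ndarray, floor_frac: float = 1e-8) -> np.ndarray:
    ev, U = np.linalg.eigh(C)
    floor = floor_frac * max(np.trace(C), 0.0)
    if floor <= 0:
        floor = floor_frac
    ev = np.clip(ev, floor, None)
    return (U * ev) @ U.T


def fit_reml(
    design: DesignMatrices,
    kernel: GeneticKernel,
    spec: SocialModelSpec,
    start: VarianceComponents | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    model_label: str | None = None,
    stall_tol: float = 1e-7,
    method: str = "ai",
) -> FitResult:
    """AI-REML with EM fallback; see module docstring for the algorithm.

    method="em" disables the AI step entirely and iterates plain EM-REML —
    slower, monotone, useful as an independent optimizer cross-check.
    """
    if method not in ("ai", "em"):
        raise ValueError(f"unknown REML method {method!r}")
    sys_ = MixedModelSystem(design, kernel, spec)
    if start is None:
        start = default_start(design, spec)
    start.validate()
    theta = sys_.theta(start)
    var_y = float(np.var(sys_.y))
    floor = 1e-10 * var_y
    n_genpar = 3 if spec.include_social else 1
    k_par = len(theta)

    def project(th):
        th = th.copy()
        C = _psd_project(sys_._C(th))
        th[0] = C[0, 0]
        if spec.include_social:
            th[1], th[2] = C[0, 1], C[1, 1]
        th[n_genpar:] = np.maximum(th[n_genpar:], floor)
        return th

    theta = project(theta)
    traj = []
    converged = False
    it = 0
    stall = 0  # consecutive iterations with a numerically unchanged logL
    last_step = 1.0
    cho, logdet_M = sys_.factorize(theta)
    logL, sol, yPy = sys_.loglik_parts(theta, cho, logdet_M)
    for it in range(1, max_iter + 1):
        Minv = sys_._inverse(cho)
        s_l, s_g, s_e = sys_._scalars(theta)
        C = sys_._C(theta)
        Cinv = np.linalg.inv(C)
        T = sys_._genetic_traces(Minv)
        Py = (sys_.y - sys_.W_all @ sol) / s_e

        # working vectors z_a = Z_a' P y, K z_a
        z = np.empty((sys_.n_gen, sys_.m))
        Kz = np.empty_like(z)
        z[0] = design.Z_D.T @ Py
        if sys_.n_gen == 2:
            z[1] = design.Z_S.T @ Py
        for a in range(sys_.n_gen):
            Kz[a] = kernel.K_dot(z[a])
        Q = z @ Kz.T  # Q_ab = z_a' K z_b
        Q = 0.5 * (Q + Q.T)

        # gradient
        grad = np.zeros(k_par)
        fvecs = []
        for j, dC in enumerate(sys_._deriv_mats()):
            trPV = sys_.m * np.trace(Cinv @ dC) - np.trace(Cinv @ dC @ Cinv @ T)
            quad = float(np.sum(dC * Q))
            grad[j] = -0.5 * (trPV - quad)
            # f = Z (dC (x) K) Z' P y
            f = np.zeros(sys_.n)
            for a in range(sys_.n_gen):
                Zb = design.Z_D if a == 0 else design.Z_S
                coefs = dC[a]
                acc = np.zeros(sys_.m)
                for b in range(sys_.n_gen):
                    if coefs[b] != 0.0:
                        acc += coefs[b] * Kz[b]
                f += Zb @ acc
            fvecs.append(f)
        jpar = n_genpar
        if spec.include_litter:
            trCll = float(np.trace(Minv[sys_.off_l :, sys_.off_l :][: sys_.L, : sys_.L]))
            wty_v = design.W.T @ Py
            trPV = sys_.L / s_l - trCll / s_l**2
            grad[jpar] = -0.5 * (trPV - float(wty_v @ wty_v))
            fvecs.append(design.W @ wty_v)
            jpar += 1
        if spec.include_group:
            trCgg = float(np.trace(Minv[sys_.off_v :, sys_.off_v :][: sys_.P, : sys_.P]))
            vty_v = design.V.T @ Py
            trPV = sys_.P / s_g - trCgg / s_g**2
            grad[jpar] = -0.5 * (trPV - float(vty_v @ vty_v))
            fvecs.append(design.V @ vty_v)
            jpar += 1
        # residual
        tr_gamma_Cuu = float(np.sum(Cinv * T))
        if spec.include_litter:
            tr_gamma_Cuu += trCll / s_l
        if spec.include_group:
            tr_gamma_Cuu += trCgg / s_g
        trP = (sys_.n - sys_.p - sys_.q_total + tr_gamma_Cuu) / s_e
        grad[jpar] = -0.5 * (trP - float(Py @ Py))
        fvecs.append(Py.copy())

        # average information from MME solves
        Pf = []
        for f in fvecs:
            sf = sys_.solve(cho, (sys_.W_all.T @ f) / s_e)
            Pf.append((f - sys_.W_all @ sf) / s_e)
        AI = 0.5 * np.array([[fi @ pfj for pfj in Pf] for fi in fvecs])
        AI = 0.5 * (AI + AI.T)

        ct = sys_.components(theta)
        traj.append((it, logL, ct.sigma2_aD, ct.sigma_aDaS, ct.sigma2_aS,
                     ct.sigma2_g, ct.sigma2_l, ct.sigma2_e))

        # active-set AI (quasi-Newton) step: scalar variances pinned at their
        # floor with an outward-pointing gradient are excluded from the update
        free = np.ones(k_par, dtype=bool)
        for i in range(n_genpar, k_par):
            if theta[i] <= floor * 1.01 and grad[i] < 0:
                free[i] = False
        delta = np.zeros(k_par)
        try:
            ridge = 1e-10 * np.trace(AI) * np.eye(int(free.sum()))
            delta[free] = np.linalg.solve(AI[np.ix_(free, free)] + ridge, grad[free])
        except np.linalg.LinAlgError:
            delta[:] = 0.0

        # backtracking on the REML logL; the factorization of the accepted
        # candidate is reused as the next iteration's factorization.  The
        # search starts from twice the last accepted step so that persistent
        # short steps near a ridge do not pay for failed full steps each time.
        accepted = None
        step = min(1.0, 2.0 * last_step)
        if method == "em":
            delta[:] = 0.0
        if np.any(delta):
            for _ in range(5):
                cand = project(theta + step * delta)
                try:
                    cho_c, ldM_c = sys_.factorize(cand)
                    logL_c, sol_c, yPy_c = sys_.loglik_parts(cand, cho_c, ldM_c)
                except (RemlError, FloatingPointError, np.linalg.LinAlgError):
                    step *= 0.5
                    continue
                if logL_c >= logL - 1e-9 * max(1.0, abs(logL)):
                    accepted = (cand, cho_c, logL_c, sol_c, yPy_c)
                    last_step = step
                    break
                step *= 0.5
        if accepted is None:
            # EM-REML step: guaranteed uphill, used when the AI step fails
            cand = project(_em_update(sys_, theta, sol, Minv, T, yPy))
            cho_c, ldM_c = sys_.factorize(cand)
            logL_c, sol_c, yPy_c = sys_.loglik_parts(cand, cho_c, ldM_c)
            accepted = (cand, cho_c, logL_c, sol_c, yPy_c)
            last_step = 0.25
            logger.debug("iteration %d: EM fallback step", it)

        new_theta, cho, logL_new, sol, yPy = accepted
        denom = np.maximum(np.abs(theta), 1e-3 * var_y)
        rel = float(np.max(np.abs(new_theta - theta) / denom))
        # secondary stop: the likelihood has stopped moving (flat ridge or
        # boundary creep); two stalled iterations count as converged
        stall = stall + 1 if abs(logL_new - logL) < stall_tol * max(1.0, abs(logL)) else 0
        theta = new_theta
        logger.debug(
            "iter %3d logL %.6f dlogL %.2e step %.3g rel %.2e",
            it, logL_new, logL_new - logL, step, rel,
        )
        logL = logL_new
        if rel < tol or stall >= 2:
            converged = True
            break

    comp = sys_.components(theta)
    k = spec.n_variance_parameters
    label = model_label or ("PED_social" if spec.include_social else "PED_classic")
    if not converged:
        logger.warning("REML did not converge in %d iterations (model %s)", max_iter, label)
    traj_df = pd.DataFrame(
        traj,
        columns=["iteration", "logL", "sigma2_aD", "sigma_aDaS", "sigma2_aS",
                 "sigma2_g", "sigma2_l", "sigma2_e"],
    )
    return FitResult(
        components=comp,
        logL=logL,
        aic=aic(logL, k),
        converged=converged,
        n_iter=it,
        model_label=label,
        trajectory=traj_df,
    )


def _em_update(sys_: MixedModelSystem, theta, sol, Minv, T, yPy) -> np.ndarray:
    """One EM-REML step from the current MME solution and inverse blocks."""
    spec = sys_.spec
    m = sys_.m
    U = np.column_stack(
        [sol[sys_.off_g + a * m : sys_.off_g + (a + 1) * m] for a in range(sys_.n_gen)]
    )
    KinvU = sys_.kernel.K_inv @ U
    C_new = (U.T @ KinvU + T) / m
    out = [C_new[0, 0]]
    if spec.include_social:
        out += [C_new[0, 1], C_new[1, 1]]
    s_l, s_g, s_e = sys_._scalars(theta)
    if spec.include_litter:
        lhat = sol[sys_.off_l : sys_.off_l + sys_.L]
        trCll = float(np.trace(Minv[sys_.off_l :, sys_.off_l :][: sys_.L, : sys_.L]))
        out.append((float(lhat @ lhat) + trCll) / sys_.L)
    if spec.include_group:
        ghat = sol[sys_.off_v : sys_.off_v + sys_.P]
        trCgg = float(np.trace(Minv[sys_.off_v :, sys_.off_v :][: sys_.P, : sys_.P]))
        out.append((float(ghat @ ghat) + trCgg) / sys_.P)
    out.append(s_e * yPy / (sys_.n - sys_.p))
    return np.array(out)


def omega_grid(
    design: DesignMatrices,
    pedigree: PedigreeTable,
    A22: np.ndarray | None,
    G_b: np.ndarray | None,
    genotyped_ids,
    spec: SocialModelSpec,
    omegas=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    tau: float = 1.0,
    start: VarianceComponents | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    stall_tol: float = 1e-7,
) -> pd.DataFrame:
    """Fit PED_classic, PED_social and one single-step model per omega.

    Each omega fit is warm-started from the previous fit's components.  The
    returned table mirrors the published layout: components, r, sigma2_P,
    T^2 at the data's average group size, logL, AIC and delta-AIC relative
    to the grid minimum.
    """
    from . import evaluate as ev

    ped_kernel = GeneticKernel.from_pedigree(pedigree)
    rows = []
    classic_spec = replace(spec, include_social=False, relationship="pedigree")
    classic_design = replace(design, Z_S=None)
    fits = {}
    res = fit_reml(classic_design, ped_kernel, classic_spec, None, tol, max_iter,
                   model_label="PED_classic", stall_tol=stall_tol)
    fits["PED_classic"] = res
    rows.append(res)

    social_spec = replace(spec, include_social=True, relationship="pedigree")
    warm = start
    res = fit_reml(design, ped_kernel, social_spec, warm, tol, max_iter,
                   model_label="PED_social", stall_tol=stall_tol)
    fits["PED_social"] = res
    rows.append(res)
    warm = res.components

    have_geno = (
        A22 is not None and G_b is not None
        and genotyped_ids is not None and len(genotyped_ids) > 0
    )
    if not have_geno:
        logger.info("no genotypes supplied; omega grid restricted to pedigree models")
    else:
        for om in omegas:
            if not 0.0 < om <= 1.0:
                raise ValueError(f"omega must lie in (0, 1], got {om}")
            label = f"omega_{om:.1f}"
            try:
                kernel = GeneticKernel.single_step(
                    pedigree, A22, G_b, genotyped_ids, tau=tau, omega=om
                )
                ss_spec = replace(spec, include_social=True, relationship="single-step",
                                  tau=tau, omega=om)
                res = fit_reml(design, kernel, ss_spec, warm, tol, max_iter,
                               model_label=label, stall_tol=stall_tol)
                fits[label] = res
                rows.append(res)
                warm = res.components
            except (RemlError, np.linalg.LinAlgError) as exc:
                logger.error("fit failed for %s: %s", label, exc)
                rows.append(FitResult(
                    components=VarianceComponents(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan),
                    logL=np.nan, aic=np.nan, converged=False, n_iter=0, model_label=label,
                ))

    n_bar = design.avg_group_size
    recs = []
    for r in rows:
        c = r.components
        social = not np.isnan(c.sigma2_aS) and r.model_label != "PED_classic"
        sigma2_P = ev.phenotypic_variance(c, n_bar if social else 1.0)
        t2 = ev.total_heritability(c, n_bar if social else 1.0)
        corr = (
            ev.genetic_correlation(c)
            if social and c.sigma2_aS > 0 and c.sigma2_aD > 0
            else np.nan
        )
        recs.append({
            "model": r.model_label,
            "sigma2_aD": c.sigma2_aD, "sigma_aDaS": c.sigma_aDaS if social else np.nan,
            "sigma2_aS": c.sigma2_aS if social else np.nan,
            "sigma2_g": c.sigma2_g, "sigma2_l": c.sigma2_l, "sigma2_e": c.sigma2_e,
            "r": corr, "sigma2_P": sigma2_P, "T2": t2,
            "logL": r.logL, "AIC": r.aic, "converged": r.converged,
            "n_iter": r.n_iter,
        })
    table = pd.DataFrame(recs)
    table["dAIC"] = table.AIC - np.nanmin(table.AIC)
    table.attrs["fits"] = fits
    return table
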