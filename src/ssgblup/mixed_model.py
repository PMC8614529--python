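"""Repeated-records animal model: design matrices, MME solving, EM-REML.

The model is

    y = X b + Z u + W p + e,
    u ~ N(0, K sigma_u2),  p ~ N(0, I sigma_c2),  e ~ N(0, I sigma_e2),

where b holds the fixed effects (contemporary-group year, fleece color,
age in days as linear + quadratic covariate, sex-by-physiological-status),
u the additive breeding values over all pedigree animals, p the permanent
environmental effect of each animal with records, and K is the pedigree
relationship matrix A (BLUP) or the single-step combined matrix H
(ssGBLUP) — only K⁻¹ ever enters the equations.

Henderson's mixed-model equations with variance ratios
lambda_u = sigma_e2/sigma_u2, lambda_c = sigma_e2/sigma_c2:

    [XᵀX    XᵀZ          XᵀW       ] [b]   [Xᵀy]
    [ZᵀX    ZᵀZ+K⁻¹λu    ZᵀW       ] [u] = [Zᵀy]
    [WᵀX    WᵀZ          WᵀW+Iλc   ] [p]   [Wᵀy]

Variance components are estimated by EM-REML, which is monotone in the
REML log-likelihood.  Each iteration needs the u- and p-blocks of the
inverse coefficient matrix; since the permanent-environment block
WᵀW + Iλc is diagonal (each record belongs to exactly one animal), those
equations are absorbed analytically and only the (b,u) system is factored
densely per iteration — algebraically identical to inverting the full
coefficient matrix, and validated against that oracle in the tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import splu

from .io_formats import Pedigree, PhenotypeTable
from .relationship_matrices import RelationshipMatrix

logger = logging.getLogger("ssgblup")


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """(sigma_u2, sigma_c2, sigma_e2) in squared trait units."""

    sigma_u2: float
    sigma_c2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        for name in ("sigma_u2", "sigma_c2", "sigma_e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> float:
        return self.sigma_u2 + self.sigma_c2 + self.sigma_e2

    @property
    def h2(self) -> float:
        return heritability(self)


def heritability(components: VarianceComponents) -> float:
    """h2 = sigma_u2 / (sigma_u2 + sigma_c2 + sigma_e2)."""
    if components.total == 0:
        raise ValueError("all variance components are zero; h2 undefined")
    return components.sigma_u2 / components.total


@dataclass
class ModelMatrices:
    """Design matrices of the repeated-records animal model."""

    y: np.ndarray
    X: np.ndarray                    # dense, reference-level constrained
    Z: sp.csr_matrix                 # records x all pedigree animals
    W: sp.csr_matrix                 # records x animals-with-records
    pe_animals: np.ndarray           # internal IDs behind W's columns (sorted)
    x_columns: list[str] = field(default_factory=list)
    age_transform: dict = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_animals(self) -> int:
        return self.Z.shape[1]


@dataclass
class EvaluationResult:
    """Solutions of one genetic evaluation (PBV under A, GPBV under H)."""

    b: np.ndarray
    u: np.ndarray                    # breeding values, internal ID order 1..N
    p: np.ndarray                    # permanent-environment solutions
    pe_animals: np.ndarray
    kernel: str                      # "blup" (A⁻¹) or "ssgblup" (H⁻¹)
    components: VarianceComponents
    x_columns: list[str] = field(default_factory=list)
    trait: str = "trait"
    diagnostics: dict = field(default_factory=dict)


@dataclass
class REMLResult:
    components: VarianceComponents
    h2: float
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    message: str = ""


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def build_design(
    phenotypes: PhenotypeTable, pedigree: Pedigree
) -> ModelMatrices:
    """Build y, X, Z, W for the repeated-records animal model.

    X gets an intercept, dummies for year / color / sex_status with the
    first (sorted) level dropped as reference, and standardized age and
    age² covariates (age is standardized before squaring, then the square
    standardized again, to avoid near-collinearity; the transform is
    recorded for back-transformation).  Degenerate columns — single-level
    factors or constant age — are dropped with a warning.  A residual rank
    deficiency raises an error naming the aliased columns.
    """
    df = phenotypes.data
    n = len(df)
    if n == 0:
        raise ValueError("no phenotype records")
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    for factor in ("year", "color", "sex_status"):
        levels = sorted(map(str, df[factor].unique()))
        if len(levels) == 1:
            logger.warning("factor %s has a single level; no dummies added", factor)
            continue
        vals = df[factor].astype(str).to_numpy()
        for lv in levels[1:]:
            cols.append((vals == lv).astype(float))
            names.append(f"{factor}[{lv}]")

    age = df["age_days"].to_numpy(dtype=float)
    transform: dict = {}
    if np.ptp(age) == 0:
        logger.warning("age_days is constant; age covariates dropped")
    else:
        mu, sd = age.mean(), age.std()
        a1 = (age - mu) / sd
        a2 = a1**2
        mu2, sd2 = a2.mean(), a2.std()
        if sd2 == 0:
            logger.warning("age² is degenerate after standardization; dropped")
            cols.append(a1); names.append("age_std")
        else:
            cols.append(a1); names.append("age_std")
            cols.append((a2 - mu2) / sd2); names.append("age2_std")
        transform = {"age_mean": mu, "age_sd": sd, "age2_mean": mu2, "age2_sd": sd2}

    X = np.column_stack(cols)
    # rank check via pivoted QR: name aliased columns if any
    _, R, piv = la.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    deficient = diag <= tol
    if deficient.any():
        aliased = [names[piv[k]] for k in np.flatnonzero(deficient)]
        raise ValueError(
            f"design matrix is rank deficient; aliased columns: {aliased}"
        )

    animals = df["animal"].to_numpy(dtype=np.int64)
    q = pedigree.n_animals
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), animals - 1)), shape=(n, q)
    )
    pe_animals = np.unique(animals)
    pos = {a: i for i, a in enumerate(pe_animals)}
    W = sp.csr_matrix(
        (np.ones(n), (np.arange(n), [pos[a] for a in animals])),
        shape=(n, len(pe_animals)),
    )
    return ModelMatrices(
        y=df["value"].to_numpy(dtype=float),
        X=X, Z=Z, W=W,
        pe_animals=pe_animals,
        x_columns=names,
        age_transform=transform,
    )


# ---------------------------------------------------------------------------
# MME solving
# ---------------------------------------------------------------------------

def _assemble_mme(
    mm: ModelMatrices,
    components: VarianceComponents,
    kernel_inverse: RelationshipMatrix,
    include_pe: bool,
):
    lam_u = components.sigma_e2 / components.sigma_u2
    X = sp.csr_matrix(mm.X)
    Z, W, y = mm.Z, mm.W, mm.y
    Ki = kernel_inverse.matrix.tocsr()
    blocks = [
        [X.T @ X, X.T @ Z],
        [Z.T @ X, (Z.T @ Z + lam_u * Ki)],
    ]
    rhs = [mm.X.T @ y, Z.T @ y]
    if include_pe:
        lam_c = components.sigma_e2 / components.sigma_c2
        blocks[0].append(X.T @ W)
        blocks[1].append(Z.T @ W)
        blocks.append(
            [W.T @ X, W.T @ Z, W.T @ W + lam_c * sp.identity(W.shape[1])]
        )
        rhs.append(W.T @ y)
    lhs = sp.bmat(blocks, format="csc")
    return lhs, np.concatenate(rhs)


def solve_mme(
    mm: ModelMatrices,
    components: VarianceComponents,
    kernel_inverse: RelationshipMatrix,
    kernel_label: str | None = None,
    trait: str = "trait",
) -> EvaluationResult:
    """Solve the mixed-model equations by sparse direct factorization.

    Animals without records receive breeding values through K⁻¹.  The
    normal-equations residual is checked against 1e-8·‖RHS‖∞ and stored in
    the diagnostics.
    """
    if components.sigma_u2 <= 0:
        raise ValueError("sigma_u2 must be positive to solve the MME")
    include_pe = components.sigma_c2 > 0 and mm.W.shape[1] > 0
    lhs, rhs = _assemble_mme(mm, components, kernel_inverse, include_pe)
    try:
        lu = splu(lhs)
    except RuntimeError as err:  # singular factorization
        raise ValueError(f"MME coefficient matrix is singular: {err}") from err
    sol = lu.solve(rhs)
    resid = np.abs(lhs @ sol - rhs).max()
    scale = max(np.abs(rhs).max(), 1.0)
    if resid > 1e-8 * scale:
        raise ValueError(
            f"MME solve failed the residual check ({resid:.2e} > 1e-8*{scale:.2e})"
        )
    px = mm.X.shape[1]
    q = mm.n_animals
    b = sol[:px]
    u = sol[px:px + q]
    p = sol[px + q:] if include_pe else np.zeros(mm.W.shape[1])
    label = kernel_label or (
        "ssgblup" if kernel_inverse.label == "H_inv" else "blup"
    )
    return EvaluationResult(
        b=b, u=u, p=p,
        pe_animals=mm.pe_animals,
        kernel=label,
        components=components,
        x_columns=mm.x_columns,
        trait=trait,
        diagnostics={"residual_max": float(resid), "n_equations": lhs.shape[0]},
    )


# ---------------------------------------------------------------------------
# EM-REML
# ---------------------------------------------------------------------------

def _sparse_logdet(mat: sp.spmatrix) -> float:
    """log|M| for a symmetric positive-definite sparse matrix."""
    lu = splu(mat.tocsc())
    return float(np.log(np.abs(lu.U.diagonal())).sum())


class _AbsorbedMME:
    """Workspace for EM-REML: p-equations absorbed, (b,u) factored densely.

    The W-block of the coefficient matrix is diagonal plus the identity
    ridge, so absorbing it is exact and O(q).  The remaining dense
    factorization provides solutions, the inverse blocks C_uu (directly)
    and diag(C_pp) (by back-substitution through the absorption), and
    log|coefficient matrix| for the REML log-likelihood.
    """

    def __init__(self, mm: ModelMatrices, kernel_inverse: RelationshipMatrix,
                 include_pe: bool):
        self.y = mm.y
        self.X = mm.X
        self.n, self.px = mm.X.shape
        self.q = mm.n_animals
        self.include_pe = include_pe
        self.counts_u = np.asarray(mm.Z.sum(axis=0)).ravel()
        self.u_of_p = mm.pe_animals - 1          # 0-based u indices
        self.counts_p = self.counts_u[self.u_of_p]
        self.qp = len(self.u_of_p) if include_pe else 0
        self.XtX = mm.X.T @ mm.X
        self.XtZ = (mm.Z.T @ mm.X).T             # px x q dense
        self.XtW = self.XtZ[:, self.u_of_p]
        self.Xty = mm.X.T @ mm.y
        self.Zty = mm.Z.T @ mm.y
        self.Wty = self.Zty[self.u_of_p]
        self.yty = float(mm.y @ mm.y)
        Ki = kernel_inverse.matrix.tocoo()
        self.Ki_csr = kernel_inverse.matrix.tocsr()
        self.Ki_dense = None
        if self.q <= 4000:
            self.Ki_dense = self.Ki_csr.toarray()
        self.Ki_rows, self.Ki_cols, self.Ki_data = Ki.row, Ki.col, Ki.data
        self.logdetK = -_sparse_logdet(kernel_inverse.matrix)

    def iterate(self, vc: VarianceComponents):
        """One factorization at vc: solutions, traces, log-likelihood parts."""
        px, q, qp = self.px, self.q, self.qp
        lam_u = vc.sigma_e2 / vc.sigma_u2
        m = px + q
        if not hasattr(self, "_Sbuf"):
            self._Sbuf = np.zeros((m, m))
        S = self._Sbuf
        S[:] = 0.0
        if self.Ki_dense is not None:
            np.multiply(self.Ki_dense, lam_u, out=S[px:, px:])
        else:
            S[px:, px:] = lam_u * self.Ki_csr.toarray()
        S[px:, px:][np.diag_indices(q)] += self.counts_u
        Sxz = self.XtZ.copy()
        rx = self.Xty.copy()
        rz = self.Zty.copy()
        if self.include_pe:
            lam_c = vc.sigma_e2 / vc.sigma_c2
            dp = self.counts_p + lam_c
            S[:px, :px] = self.XtX - (self.XtW / dp) @ self.XtW.T
            Sxz[:, self.u_of_p] -= self.XtW * (self.counts_p / dp)
            S[px:, px:][self.u_of_p, self.u_of_p] -= self.counts_p**2 / dp
            rx -= self.XtW @ (self.Wty / dp)
            rz[self.u_of_p] -= self.counts_p * self.Wty / dp
        else:
            dp = None
            S[:px, :px] = self.XtX
        S[:px, px:] = Sxz
        S[px:, :px] = Sxz.T

        # S is rebuilt from scratch every call, so factor/invert in place
        c, low = cho_factor(S, lower=True, check_finite=False,
                            overwrite_a=True)
        logdet_S = 2.0 * float(np.log(np.diag(c)).sum())
        sol = cho_solve((c, low), np.concatenate([rx, rz]), check_finite=False)
        inv, info = la.lapack.dpotri(c, lower=1)
        if info != 0:
            raise ValueError(f"dense inversion failed (dpotri info={info})")
        # dpotri fills only the lower triangle; mirror it
        Sinv = np.tril(inv) + np.tril(inv, -1).T

        b = sol[:px]
        u = sol[px:]
        Cuu = Sinv[px:, px:]
        tr_KiCuu = float(
            np.sum(self.Ki_data * Cuu[self.Ki_rows, self.Ki_cols])
        )
        uKu = float(u @ (self.Ki_csr @ u))

        if self.include_pe:
            p = (self.Wty - self.XtW.T @ b - self.counts_p * u[self.u_of_p]) / dp
            T = Sinv[:px, :px] @ self.XtW
            t1 = np.einsum("ki,ki->i", self.XtW, T)
            cols = Sinv[:px, px:][:, self.u_of_p]
            t2 = 2.0 * self.counts_p * np.einsum("ki,ki->i", self.XtW, cols)
            t3 = self.counts_p**2 * np.diag(Cuu)[self.u_of_p]
            tr_Cpp = float(np.sum(1.0 / dp) + np.sum((t1 + t2 + t3) / dp**2))
            pWty = float(p @ self.Wty)
            pp = float(p @ p)
            logdet_M = logdet_S + float(np.log(dp).sum())
        else:
            p = np.zeros(0)
            tr_Cpp = 0.0
            pWty = 0.0
            pp = 0.0
            logdet_M = logdet_S

        e_ty = self.yty - float(b @ self.Xty) - float(u @ self.Zty) - pWty
        # REML log-likelihood (constant terms dropped):
        # -2l = (n-px-q-qp) log se2 + q log su2 + log|K| + qp log sc2
        #       + log|M_lambda| + y'Py
        minus2l = (
            (self.n - px - q - qp) * np.log(vc.sigma_e2)
            + q * np.log(vc.sigma_u2)
            + self.logdetK
            + (qp * np.log(vc.sigma_c2) if self.include_pe else 0.0)
            + logdet_M
            + e_ty / vc.sigma_e2
        )
        return {
            "b": b, "u": u, "p": p,
            "uKu": uKu, "tr_KiCuu": tr_KiCuu,
            "pp": pp, "tr_Cpp": tr_Cpp,
            "e_ty": e_ty,
            "loglik": -0.5 * float(minus2l),
        }


def _em_update(
    vc: VarianceComponents,
    state: dict,
    q: int,
    qp: int,
    n: int,
    px: int,
    include_pe: bool,
    floor: float,
) -> VarianceComponents:
    """One EM-REML update from the E-step quantities at ``vc``."""
    su2 = (state["uKu"] + vc.sigma_e2 * state["tr_KiCuu"]) / q
    se2 = state["e_ty"] / (n - px)
    sc2 = (
        (state["pp"] + vc.sigma_e2 * state["tr_Cpp"]) / qp
        if include_pe else 0.0
    )
    new = [su2, sc2, se2]
    for k, v in enumerate(new):
        if k == 1 and not include_pe:
            continue
        if v < floor:
            logger.warning("variance component update %d went to %g; clamped", k, v)
            new[k] = floor
    return VarianceComponents(*new)


def _rel_change(a: VarianceComponents, b: VarianceComponents,
                include_pe: bool) -> float:
    pairs = [(a.sigma_u2, b.sigma_u2), (a.sigma_e2, b.sigma_e2)]
    if include_pe:
        pairs.append((a.sigma_c2, b.sigma_c2))
    return max(abs(x - y) / max(abs(x), 1e-12) for x, y in pairs)


def em_reml(
    mm: ModelMatrices,
    kernel_inverse: RelationshipMatrix | None,
    start: VarianceComponents | None = None,
    tol: float = 1e-8,
    maxiter: int = 500,
    accelerate: bool = True,
) -> REMLResult:
    """EM-REML variance components for the repeated-records animal model.

    Updates per iteration (q animals, q_p animals with records, current
    solutions û, p̂ and λ-form inverse blocks C):

        sigma_u2 <- (ûᵀK⁻¹û + sigma_e2·tr(K⁻¹ C_uu)) / q
        sigma_c2 <- (p̂ᵀp̂   + sigma_e2·tr(C_pp))     / q_p
        sigma_e2 <- êᵀy / (n − rank X)

    Iterates until the largest relative component change drops below
    ``tol`` or ``maxiter`` factorizations are spent (returned with
    ``converged=False``, never silently).  ``accelerate=True`` applies a
    squared-extrapolation (SQUAREM-type) step every cycle, accepted only
    if the REML log-likelihood does not decrease, so the recorded
    likelihood trace stays monotone either way; ``accelerate=False`` is
    the plain EM recursion.  With ``kernel_inverse=None`` the model
    reduces to fixed effects only and sigma_e2 equals the OLS residual
    mean square.  If no animal has repeated records the
    permanent-environment variance is unidentifiable: it is fixed at zero
    with a warning.
    """
    n, px = mm.X.shape
    if kernel_inverse is None:
        b, *_ = np.linalg.lstsq(mm.X, mm.y, rcond=None)
        resid = mm.y - mm.X @ b
        se2 = float(resid @ resid) / (n - px)
        vc = VarianceComponents(0.0, 0.0, se2)
        return REMLResult(vc, 0.0, [], True, 0, "fixed-effects-only model")

    counts = np.asarray(mm.W.sum(axis=0)).ravel()
    include_pe = bool((counts >= 2).any())
    if not include_pe:
        logger.warning(
            "no animal has repeated records; sigma_c2 is unidentifiable "
            "and fixed at 0"
        )

    var_y = float(np.var(mm.y))
    if start is None:
        third = max(var_y / 3.0, 1e-8)
        start = VarianceComponents(third, third if include_pe else 0.0, third)
    vc = VarianceComponents(
        max(start.sigma_u2, 1e-8),
        max(start.sigma_c2, 1e-8) if include_pe else 0.0,
        max(start.sigma_e2, 1e-8),
    )

    work = _AbsorbedMME(mm, kernel_inverse, include_pe)
    q = work.q
    qp = work.qp
    floor = 1e-10
    trace: list[float] = []
    converged = False
    it = 0  # counts factorizations (equivalently, plain EM iterations)

    def as_vec(v: VarianceComponents) -> np.ndarray:
        return np.array([v.sigma_u2, v.sigma_c2, v.sigma_e2])

    def from_vec(x: np.ndarray) -> VarianceComponents:
        x = np.maximum(x, floor)
        if not include_pe:
            x[1] = 0.0
        return VarianceComponents(*x)

    state0 = work.iterate(vc)
    it += 1
    trace.append(state0["loglik"])
    while it < maxiter and not converged:
        th1 = _em_update(vc, state0, q, qp, n, px, include_pe, floor)
        if _rel_change(vc, th1, include_pe) < tol:
            vc = th1
            converged = True
            break
        state1 = work.iterate(th1)
        it += 1
        trace.append(state1["loglik"])
        th2 = _em_update(th1, state1, q, qp, n, px, include_pe, floor)
        if not accelerate:
            vc, state0 = th1, state1
            continue
        # squared extrapolation through (vc, th1, th2); accept only if the
        # REML log-likelihood did not decrease, else fall back to th2
        r = as_vec(th1) - as_vec(vc)
        v = (as_vec(th2) - as_vec(th1)) - r
        vnorm = float(v @ v)
        alpha = -np.sqrt(float(r @ r) / vnorm) if vnorm > 0 else -1.0
        alpha = min(alpha, -1.0)
        accepted = False
        if alpha < -1.0:
            cand = from_vec(as_vec(vc) - 2.0 * alpha * r + alpha**2 * v)
            state_c = work.iterate(cand)
            it += 1
            if state_c["loglik"] >= state1["loglik"] - 1e-10:
                trace.append(state_c["loglik"])
                if _rel_change(vc, cand, include_pe) < tol:
                    converged = True
                vc, state0 = cand, state_c
                accepted = True
        if not accepted:
            state2 = work.iterate(th2)
            it += 1
            trace.append(state2["loglik"])
            if _rel_change(th1, th2, include_pe) < tol:
                converged = True
            vc, state0 = th2, state2

    msg = "" if converged else f"not converged after {it} factorizations"
    if msg:
        logger.warning("EM-REML %s", msg)
    return REMLResult(
        components=vc,
        h2=heritability(vc),
        loglik_trace=trace,
        converged=converged,
        n_iter=it,
        message=msg,
    )
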