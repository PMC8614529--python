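"""Pedigree and genomic relationship matrices: A, A⁻¹, A22, G, G*, H⁻¹.

The pedigree (numerator) relationship matrix A is built by the tabular
method; its sparse inverse comes from Henderson's rules with inbreeding,
with per-animal inbreeding coefficients from the Meuwissen–Luo algorithm.
The genomic matrix is VanRaden's first method,

    G = Z Zᵀ / (2 Σ_j p_j (1 − p_j)),

on observed-frequency-centred dosages.  For single-step evaluation G is
blended with the genotyped-subset pedigree block A22 as
G* = w·G + (1−w)·A22 (default w = 0.95), and the combined inverse is

    H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ − A22⁻¹]

on the genotyped rows/columns.  Inbreeding is always accounted for in A⁻¹:
ignoring it changes H⁻¹ materially in deep pedigrees.  No additional
compatibility tuning of G to the A22 scale is applied by default — only the
blend — though :func:`blend_G` accepts any weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .io_formats import Pedigree

#: reciprocal condition number below which G*/A22 are declared singular
RCOND_TOL = 1e-12


@dataclass
class RelationshipMatrix:
    """A labelled symmetric matrix over an explicit internal-ID list."""

    matrix: np.ndarray | sp.spmatrix
    ids: np.ndarray                  # internal pedigree IDs, row/col order
    label: str                       # A, A_inv, A22, A22_inv, G, G_blended,
                                     # G_inv, H_inv

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n) or len(self.ids) != n:
            raise ValueError("matrix/ID dimensions disagree")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def dense(self) -> np.ndarray:
        m = self.matrix
        return m.toarray() if sp.issparse(m) else np.asarray(m)

    def to_coord_text(self, path) -> None:
        """Export as lower-triangle coordinate text: ``i j value`` per line."""
        m = sp.coo_matrix(self.matrix)
        with open(path, "w") as fh:
            fh.write(f"# {self.label}, n={self.n}, ids are internal pedigree IDs\n")
            order = np.lexsort((m.col, m.row))
            for k in order:
                i, j, v = int(m.row[k]), int(m.col[k]), m.data[k]
                if j <= i and v != 0.0:
                    fh.write(f"{self.ids[i]} {self.ids[j]} {v:.12g}\n")


def _check_ordered(pedigree: Pedigree) -> None:
    ids = np.arange(1, pedigree.n_animals + 1)
    if np.any(pedigree.sire >= ids) or np.any(pedigree.dam >= ids):
        raise ValueError("pedigree must be topologically ordered (parents first)")


# ---------------------------------------------------------------------------
# A family
# ---------------------------------------------------------------------------

def tabular_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Dense numerator relationship matrix by the recursive tabular method.

    a_ij (i<j, j with parents s,d) = ½(a_is + a_id);  a_jj = 1 + ½ a_sd;
    unknown parents contribute zero.  Intended for pedigrees up to a few
    thousand animals — this is the dense oracle the sparse routines are
    checked against.
    """
    _check_ordered(pedigree)
    n = pedigree.n_animals
    A = np.zeros((n, n))
    s = pedigree.sire
    d = pedigree.dam
    for j in range(n):
        sj, dj = s[j], d[j]
        row = np.zeros(j)
        if sj:
            row += 0.5 * A[:j, sj - 1]
        if dj:
            row += 0.5 * A[:j, dj - 1]
        A[:j, j] = row
        A[j, :j] = row
        A[j, j] = 1.0 + (0.5 * A[sj - 1, dj - 1] if sj and dj else 0.0)
    return RelationshipMatrix(A, np.arange(1, n + 1), "A")


def inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients by the Meuwissen–Luo algorithm.

    Uses the A = L D Lᵀ decomposition: F_i = ½ a_{s,d} with
    a_{s,d} = Σ_k L_sk L_dk D_k over common ancestors k, where L rows are
    obtained by pushing gene-flow contributions down from each parent and
    D_k is the Mendelian-sampling variance of ancestor k.
    """
    _check_ordered(pedigree)
    n = pedigree.n_animals
    s = pedigree.sire
    d = pedigree.dam
    F = np.zeros(n)
    D = np.zeros(n)

    def l_row(top: int) -> np.ndarray:
        v = np.zeros(top + 1)
        v[top] = 1.0
        for k in range(top, 0, -1):
            vk = v[k]
            if vk != 0.0:
                if s[k - 1]:
                    v[s[k - 1]] += 0.5 * vk
                if d[k - 1]:
                    v[d[k - 1]] += 0.5 * vk
        return v

    for i in range(n):
        si, di = s[i], d[i]
        # Mendelian-sampling variance given parent knownness and inbreeding
        if si and di:
            D[i] = 0.5 - 0.25 * (F[si - 1] + F[di - 1])
        elif si or di:
            known = si or di
            D[i] = 0.75 - 0.25 * F[known - 1]
        else:
            D[i] = 1.0
        if si and di:
            vs = l_row(si)
            vd = l_row(di)
            m = min(len(vs), len(vd))
            F[i] = 0.5 * float(vs[1:m] @ (vd[1:m] * D[: m - 1]))
    return F


def a_inverse(
    pedigree: Pedigree, F: np.ndarray | None = None
) -> RelationshipMatrix:
    """Sparse A⁻¹ by Henderson's rules with inbreeding.

    For each animal j with Mendelian-sampling variance d_j (a function of
    the parents' inbreeding and knownness), add 1/d_j to (j,j), −1/(2 d_j)
    to (j, parent) entries and 1/(4 d_j) to parent-pair entries — at most 9
    nonzero contributions per animal.
    """
    _check_ordered(pedigree)
    if F is None:
        F = inbreeding(pedigree)
    n = pedigree.n_animals
    s = pedigree.sire
    d = pedigree.dam
    rows, cols, vals = [], [], []
    for j in range(n):
        sj, dj = s[j], d[j]
        if sj and dj:
            dm = 0.5 - 0.25 * (F[sj - 1] + F[dj - 1])
        elif sj or dj:
            dm = 0.75 - 0.25 * F[(sj or dj) - 1]
        else:
            dm = 1.0
        alpha = 1.0 / dm
        rows.append(j); cols.append(j); vals.append(alpha)
        for p in (sj, dj):
            if p:
                rows += [j, p - 1]
                cols += [p - 1, j]
                vals += [-alpha / 2.0, -alpha / 2.0]
        for p1 in (sj, dj):
            for p2 in (sj, dj):
                if p1 and p2:
                    rows.append(p1 - 1); cols.append(p2 - 1)
                    vals.append(alpha / 4.0)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    return RelationshipMatrix(Ainv, np.arange(1, n + 1), "A_inv")


def a22(
    pedigree: Pedigree,
    genotyped_ids,
    A_inv: RelationshipMatrix | None = None,
) -> RelationshipMatrix:
    """Genotyped-subset block of A, without forming the full dense A.

    Solves A⁻¹ x = e_i for each genotyped column (sparse LU), then takes the
    genotyped rows — exact and cheap for subsets of a few hundred animals.
    """
    genotyped_ids = np.asarray(genotyped_ids, dtype=np.int64)
    if len(genotyped_ids) == 0:
        raise ValueError("empty genotyped set; A22 is undefined")
    if genotyped_ids.min() < 1 or genotyped_ids.max() > pedigree.n_animals:
        raise ValueError("genotyped_ids must be internal pedigree IDs")
    if A_inv is None:
        A_inv = a_inverse(pedigree)
    n = pedigree.n_animals
    idx = genotyped_ids - 1
    lu = splu(A_inv.matrix.tocsc())
    rhs = np.zeros((n, len(idx)))
    rhs[idx, np.arange(len(idx))] = 1.0
    cols = lu.solve(rhs)
    block = cols[idx, :]
    block = 0.5 * (block + block.T)    # symmetrize float noise
    return RelationshipMatrix(block, genotyped_ids, "A22")


# ---------------------------------------------------------------------------
# G family
# ---------------------------------------------------------------------------

def vanraden_G(
    Z: np.ndarray, p: np.ndarray, ids=None
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix from centred dosages.

    ``Z`` must be the column-centred matrix from
    :func:`ssgblup.snp_qc.impute_and_center`; ``p`` the matching allele
    frequencies.
    """
    Z = np.asarray(Z, dtype=float)
    p = np.asarray(p, dtype=float)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom == 0.0:
        raise ValueError("all SNPs monomorphic; G denominator is zero")
    G = (Z @ Z.T) / denom
    if ids is None:
        ids = np.arange(1, Z.shape[0] + 1)
    return RelationshipMatrix(G, ids, "G")


def blend_G(
    G: RelationshipMatrix, A22_: RelationshipMatrix, w: float = 0.95
) -> RelationshipMatrix:
    """G* = w·G + (1−w)·A22, guaranteeing invertibility for w < 1."""
    if G.matrix.shape != A22_.matrix.shape:
        raise ValueError("G and A22 dimensions disagree")
    if not np.array_equal(G.ids, A22_.ids):
        raise ValueError("G and A22 must index the same animals in the same order")
    Gs = w * G.dense() + (1.0 - w) * A22_.dense()
    return RelationshipMatrix(Gs, G.ids, "G_blended")


def _checked_inverse(mat: np.ndarray, name: str) -> np.ndarray:
    svals = np.linalg.svd(mat, compute_uv=False)
    rcond = svals[-1] / svals[0] if svals[0] > 0 else 0.0
    if rcond < RCOND_TOL:
        raise ValueError(
            f"{name} is numerically singular (rcond={rcond:.2e}); "
            "review the blending weight or SNP QC"
        )
    inv = np.linalg.inv(mat)
    return 0.5 * (inv + inv.T)


def h_inverse(
    A_inv: RelationshipMatrix,
    G_blended: RelationshipMatrix | None,
    A22_: RelationshipMatrix | None,
) -> RelationshipMatrix:
    """Single-step combined inverse H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ − A22⁻¹].

    With no genotyped animals (``G_blended`` and ``A22_`` None or empty)
    this returns A⁻¹ unchanged, so single-step evaluation degenerates to
    pedigree BLUP exactly.
    """
    if G_blended is None or A22_ is None or G_blended.n == 0:
        return RelationshipMatrix(A_inv.matrix, A_inv.ids, "H_inv")
    if not np.array_equal(G_blended.ids, A22_.ids):
        raise ValueError("G* and A22 must index the same animals")
    Ginv = _checked_inverse(G_blended.dense(), "G*")
    A22inv = _checked_inverse(A22_.dense(), "A22")
    corr = Ginv - A22inv
    n = A_inv.n
    idx = np.searchsorted(A_inv.ids, G_blended.ids)
    if not np.array_equal(A_inv.ids[idx], G_blended.ids):
        raise ValueError("genotyped IDs not found in the full ordering")
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    block = sp.coo_matrix(
        (corr.ravel(), (ii.ravel(), jj.ravel())), shape=(n, n)
    )
    H = (A_inv.matrix.tocsc() + block.tocsc()).tocsc()
    return RelationshipMatrix(H, A_inv.ids, "H_inv")
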