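"""Fuse pedigree and genomic relationships into the hybrid H matrix.

G is first rescaled (``Ga = beta * G + alpha``) so that its diagonal
mean and overall mean match the pedigree submatrix of the genotyped
individuals (A22).  The hybrid matrix is then assembled blockwise::

    H11 = A11 + A12 A22^-1 (Ga - A22) A22^-1 A21
    H12 = A12 A22^-1 Ga
    H21 = Ga A22^-1 A21
    H22 = Ga

and finally converted to a correlation matrix and a scaled distance
matrix for the downstream subset optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .matrix import RelationshipMatrix


class FusionError(ValueError):
    pass


@dataclass
class ScaleResult:
    beta: float
    alpha: float
    scaled: RelationshipMatrix  # kind=Ga


def scale_g(G: RelationshipMatrix, A22: RelationshipMatrix) -> ScaleResult:
    """Solve ``Ga = beta*G + alpha`` so Ga matches A22's diagonal and overall means.

    The two constraints form a 2x2 linear system::

        beta * mean(diag G) + alpha = mean(diag A22)
        beta * mean(G)      + alpha = mean(A22)
    """
    if list(G.ids) != list(A22.ids):
        raise FusionError("G and A22 must share identical id order")
    dg, mg = float(np.mean(np.diag(G.values))), float(np.mean(G.values))
    da, ma = float(np.mean(np.diag(A22.values))), float(np.mean(A22.values))
    if np.isclose(dg, mg):
        raise FusionError(
            "degenerate scaling system (mean diagonal == overall mean of G); "
            "more markers or genotypes are needed"
        )
    beta = (da - ma) / (dg - mg)
    alpha = da - beta * dg
    scaled = RelationshipMatrix(list(G.ids), beta * G.values + alpha, "Ga")
    return ScaleResult(beta, alpha, scaled)


def build_h(A: RelationshipMatrix, Ga: RelationshipMatrix, genotyped,
            ridge: float | None = 1e-6) -> RelationshipMatrix:
    """Assemble the hybrid H matrix in pedigree order.

    ``genotyped`` lists the individuals with genomic data; they must all
    appear in ``A`` and match ``Ga``'s ids (as a set).  ``A22`` is
    inverted by a symmetric (Cholesky) solve; on singularity a ridge
    ``eps * I`` is added when ``ridge`` is not None, otherwise the error
    propagates.  The H22 block equals Ga exactly and the result is
    symmetrized to absorb floating-point asymmetry.
    """
    genotyped = [str(g) for g in genotyped]
    id_set = set(A.ids)
    absent = [g for g in genotyped if g not in id_set]
    if absent:
        raise FusionError(f"genotyped ids absent from pedigree matrix: {absent}")
    if set(Ga.ids) != set(genotyped):
        raise FusionError("Ga ids do not match the genotyped set")

    gen_order = [i for i in A.ids if i in set(genotyped)]
    ung_order = [i for i in A.ids if i not in set(genotyped)]
    gi = A.indices(gen_order)
    ui = A.indices(ung_order)
    A22 = A.values[np.ix_(gi, gi)]
    Gv = Ga.values[np.ix_(Ga.indices(gen_order), Ga.indices(gen_order))]

    try:
        cf = scipy.linalg.cho_factor(A22)
    except np.linalg.LinAlgError as exc:
        if ridge is None:
            raise FusionError(
                "A22 is singular (duplicated individuals?); supply a ridge epsilon"
            ) from exc
        cf = scipy.linalg.cho_factor(A22 + ridge * np.eye(len(gen_order)))

    H = A.values.copy()
    if ung_order:
        A12 = A.values[np.ix_(ui, gi)]
        # P = A12 * A22^-1  (solve on the right via the symmetric factor)
        P = scipy.linalg.cho_solve(cf, A12.T).T
        delta = Gv - A22
        H[np.ix_(ui, ui)] = A.values[np.ix_(ui, ui)] + P @ delta @ P.T
        H12 = P @ Gv
        H[np.ix_(ui, gi)] = H12
        H[np.ix_(gi, ui)] = H12.T
    H[np.ix_(gi, gi)] = Gv
    H = (H + H.T) / 2.0
    H[np.ix_(gi, gi)] = Gv  # keep H22 == Ga exactly
    return RelationshipMatrix(list(A.ids), H, "H")


def cov_to_cor(H: RelationshipMatrix) -> RelationshipMatrix:
    """Covariance-to-correlation: ``Hcor(i,j) = H(i,j) / sqrt(H(i,i) H(j,j))``."""
    diag = np.diag(H.values)
    bad = np.flatnonzero(diag <= 0)
    if bad.size:
        raise FusionError(
            f"non-positive diagonal for genotypes {[H.ids[k] for k in bad[:5]]}"
        )
    s = 1.0 / np.sqrt(diag)
    vals = H.values * np.outer(s, s)
    np.fill_diagonal(vals, 1.0)
    vals = (vals + vals.T) / 2.0
    return RelationshipMatrix(list(H.ids), vals, "Hcor")


def cor_to_dist(Hcor: RelationshipMatrix, mode: str = "normalized") -> RelationshipMatrix:
    """Convert a correlation matrix to a scaled distance matrix.

    ``mode="normalized"`` (default) computes ``D = (1 - Hcor) / (1 - min(Hcor))``,
    which guarantees a zero diagonal and off-diagonal values in [0, 1].
    ``mode="as_printed"`` evaluates
    ``D = ((1 - Hcor) + |min(Hcor)|) / (1 + |min(Hcor)|)`` verbatim;
    the two agree when ``min(Hcor) == 0``.  Distance ranking is a
    strictly decreasing affine function of Hcor in both modes.
    """
    if not np.allclose(np.diag(Hcor.values), 1.0):
        raise FusionError("cor_to_dist expects a unit diagonal")
    mn = float(Hcor.values.min())
    if np.isclose(mn, 1.0):
        raise FusionError("constant correlation matrix; distance range is zero")
    if mode == "normalized":
        vals = (1.0 - Hcor.values) / (1.0 - mn)
    elif mode == "as_printed":
        vals = ((1.0 - Hcor.values) + abs(mn)) / (1.0 + abs(mn))
    else:
        raise FusionError(f"unknown mode {mode!r}")
    if mode == "normalized":
        np.fill_diagonal(vals, 0.0)
        vals = np.clip(vals, 0.0, 1.0)
    vals = (vals + vals.T) / 2.0
    return RelationshipMatrix(list(Hcor.ids), vals, "D")
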