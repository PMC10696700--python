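"""Accuracy diagnostics comparing pedigree and genomic relationships.

Includes the overall and per-genotype A22-vs-Ga correlations, outlier
flagging (pair-level threshold boxes and low-correlation/high-
completeness genotypes), the marker-subsampling reliability analysis,
and PCA (classical MDS) of a relationship matrix.

Correlation conventions: matrix-level correlations use the strict upper
triangle (diagonal excluded); per-genotype correlations exclude the
self entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .curation import DosageMatrix, vanraden_g
from .matrix import RelationshipMatrix


class DiagnosticsError(ValueError):
    pass


def _check_aligned(A22: RelationshipMatrix, Ga: RelationshipMatrix) -> None:
    if list(A22.ids) != list(Ga.ids):
        raise DiagnosticsError("matrices must share identical id order")


def matrix_correlation(A22: RelationshipMatrix, Ga: RelationshipMatrix) -> float:
    """Pearson correlation over the strict upper triangles of two matrices."""
    _check_aligned(A22, Ga)
    iu = np.triu_indices(A22.n, k=1)
    x, y = A22.values[iu], Ga.values[iu]
    if x.std() == 0 or y.std() == 0:
        raise DiagnosticsError("constant upper triangle; correlation undefined")
    return float(scipy.stats.pearsonr(x, y).statistic)


def per_genotype_correlation(A22: RelationshipMatrix, Ga: RelationshipMatrix,
                             ) -> dict[str, float]:
    """Per genotype, Pearson r between its A22 and Ga columns (self excluded).

    Genotypes whose column is constant get NaN with a warning.
    """
    _check_aligned(A22, Ga)
    if A22.n < 3:
        raise DiagnosticsError("need >= 3 genotypes for per-genotype correlations")
    out: dict[str, float] = {}
    for k, g in enumerate(A22.ids):
        mask = np.ones(A22.n, dtype=bool)
        mask[k] = False
        x, y = A22.values[k, mask], Ga.values[k, mask]
        if x.std() == 0 or y.std() == 0:
            warnings.warn(f"constant relationship column for {g}; correlation undefined")
            out[g] = float("nan")
        else:
            out[g] = float(scipy.stats.pearsonr(x, y).statistic)
    return out


def flag_pair_outliers(A22: RelationshipMatrix, Ga: RelationshipMatrix,
                       high: float = 0.8, low: float = 0.2,
                       ) -> set[frozenset[str]]:
    """Pairs where one matrix says close kin (> high) and the other says not (< low)."""
    _check_aligned(A22, Ga)
    iu = np.triu_indices(A22.n, k=1)
    a, g = A22.values[iu], Ga.values[iu]
    hit = ((a > high) & (g < low)) | ((a < low) & (g > high))
    ids = A22.ids
    return {
        frozenset((ids[i], ids[j]))
        for i, j in zip(iu[0][hit], iu[1][hit])
    }


def flag_genotype_outliers(per_genotype_corr: dict[str, float],
                           completeness: dict[str, float],
                           corr_max: float = 0.2,
                           completeness_min: float = 5.0) -> set[str]:
    """Genotypes with low A-vs-G correlation despite a well-recorded pedigree."""
    if not set(per_genotype_corr) <= set(completeness):
        missing = set(per_genotype_corr) - set(completeness)
        raise DiagnosticsError(f"completeness missing for {sorted(missing)[:5]}")
    return {
        g for g, r in per_genotype_corr.items()
        if not np.isnan(r) and r < corr_max and completeness[g] > completeness_min
    }


@dataclass
class SubsampleReport:
    sizes: list[int]
    correlations: dict[int, list[float]]  # per size, one value per rep
    threshold: float
    reliable_size: int | None  # smallest size with min-over-reps >= threshold

    def medians(self) -> dict[int, float]:
        return {s: float(np.median(v)) for s, v in self.correlations.items()}

    def minima(self) -> dict[int, float]:
        return {s: float(np.min(v)) for s, v in self.correlations.items()}

    def iqr(self) -> dict[int, float]:
        return {
            s: float(np.percentile(v, 75) - np.percentile(v, 25))
            for s, v in self.correlations.items()
        }

    def to_dict(self) -> dict:
        return {
            "sizes": self.sizes,
            "correlations": {str(s): v for s, v in self.correlations.items()},
            "threshold": self.threshold,
            "reliable_size": self.reliable_size,
        }


def subsample_analysis(d: DosageMatrix, sizes=None, reps: int = 200,
                       seed: int = 0, threshold: float = 0.95) -> SubsampleReport:
    """How many markers are needed for a reliable G matrix.

    For each subset size, markers are drawn uniformly without
    replacement ``reps`` times; each subset's G is correlated (strict
    upper triangle) against the full-marker G.  The report records the
    smallest size whose minimum correlation over reps reaches
    ``threshold``.
    """
    if sizes is None:
        sizes = range(50, 3001, 50)
    sizes = sorted(int(s) for s in sizes)
    if np.isnan(d.dosages).any():
        raise DiagnosticsError("subsample_analysis requires imputed dosages")
    if sizes and sizes[-1] > d.n_markers:
        raise DiagnosticsError(
            f"largest subset size {sizes[-1]} exceeds marker count {d.n_markers}"
        )
    full = vanraden_g(d)
    iu = np.triu_indices(full.n, k=1)
    ref = full.values[iu]
    rng = np.random.default_rng(seed)
    correlations: dict[int, list[float]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # monomorphic-subset warnings
        for size in sizes:
            vals = []
            for _ in range(reps):
                pick = rng.choice(d.n_markers, size=size, replace=False)
                gs = vanraden_g(d.select_markers(np.sort(pick)))
                vals.append(float(scipy.stats.pearsonr(ref, gs.values[iu]).statistic))
            correlations[size] = vals
    reliable = next(
        (s for s in sizes if np.min(correlations[s]) >= threshold), None
    )
    return SubsampleReport(sizes, correlations, threshold, reliable)


@dataclass
class PCAResult:
    ids: list[str]
    coordinates: np.ndarray  # genotypes x axes
    explained: np.ndarray  # variance fractions, non-increasing
    eigenvalues: np.ndarray = field(default=None)


def pca_relationship(M: RelationshipMatrix, n_axes: int = 2) -> PCAResult:
    """Classical-MDS PCA of a relationship matrix.

    The matrix is double-centered, eigendecomposed, and coordinates are
    eigenvectors scaled by the square root of their (non-negative)
    eigenvalues.  Explained-variance fractions are eigenvalues over the
    trace of the centered matrix.
    """
    if not np.allclose(M.values, M.values.T, atol=1e-8):
        raise DiagnosticsError("PCA requires a symmetric matrix")
    n = M.n
    J = np.eye(n) - np.ones((n, n)) / n
    C = J @ M.values @ J
    C = (C + C.T) / 2.0
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_axes = min(n_axes, n)
    top = np.clip(evals[:n_axes], 0.0, None)
    coords = evecs[:, :n_axes] * np.sqrt(top)
    trace = float(np.trace(C))
    explained = top / trace if trace > 0 else np.zeros(n_axes)
    return PCAResult(list(M.ids), coords, explained, evals)
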