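"""SNP dosage curation and the VanRaden genomic relationship matrix.

Covers the marker-level filters (missingness, minor allele frequency),
mean imputation, greedy LD pruning, cross-platform merging by per-marker
concordance, and ``G = ZZ' / (2 * sum p_i (1 - p_i))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import RelationshipMatrix

_ALLOWED = np.array([0.0, 1.0, 2.0])


class CurationError(ValueError):
    pass


@dataclass
class DosageMatrix:
    """Genotypes x biallelic markers, dosages in {0, 1, 2} or missing (NaN).

    ``imputed=True`` marks matrices downstream of :func:`mean_impute`,
    where fractional dosages are allowed.  ``marker_meta`` optionally
    carries per-marker ``chrom``/``pos`` columns (indexed by marker id).
    """

    genotype_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    marker_meta: pd.DataFrame | None = None
    imputed: bool = False
    _gidx: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.genotype_ids = [str(g) for g in self.genotype_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.genotype_ids), len(self.marker_ids)):
            raise CurationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.genotype_ids)} genotypes x {len(self.marker_ids)} markers"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise CurationError("duplicate marker ids")
        if len(set(self.genotype_ids)) != len(self.genotype_ids):
            raise CurationError("duplicate genotype ids")
        if not self.imputed:
            vals = self.dosages[~np.isnan(self.dosages)]
            if vals.size and not np.isin(vals, _ALLOWED).all():
                bad = vals[~np.isin(vals, _ALLOWED)][:5]
                raise CurationError(f"dosages outside {{0,1,2}}: {bad}")
        if self.marker_meta is not None:
            missing = set(self.marker_ids) - set(map(str, self.marker_meta.index))
            if missing:
                raise CurationError(f"marker_meta missing markers: {sorted(missing)[:5]}")
        self._gidx = {g: i for i, g in enumerate(self.genotype_ids)}

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Per-marker frequency of the counted allele over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def select_markers(self, keep: np.ndarray) -> "DosageMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        meta = None
        ids = [self.marker_ids[k] for k in keep]
        if self.marker_meta is not None:
            meta = self.marker_meta.loc[ids]
        return DosageMatrix(
            list(self.genotype_ids), ids, self.dosages[:, keep], meta, self.imputed
        )

    def select_genotypes(self, ids) -> "DosageMatrix":
        idx = [self._gidx[str(g)] for g in ids]
        return DosageMatrix(
            [str(g) for g in ids], list(self.marker_ids),
            self.dosages[idx, :], self.marker_meta, self.imputed,
        )

    def write_tsv(self, path: str | Path) -> None:
        """Genotypes as rows, markers as columns, missing = NA."""
        df = pd.DataFrame(self.dosages, index=self.genotype_ids, columns=self.marker_ids)
        df.to_csv(path, sep="\t", index_label="genotype", na_rep="NA")

    @classmethod
    def read_tsv(cls, path: str | Path, marker_meta: pd.DataFrame | None = None,
                 imputed: bool = False) -> "DosageMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                         float_precision="round_trip")
        return cls(
            [str(i) for i in df.index], [str(c) for c in df.columns],
            df.to_numpy(dtype=float), marker_meta, imputed,
        )


def read_vcf(path: str | Path) -> DosageMatrix:
    """Read biallelic-site dosages from a VCF (GT field).

    0/0 -> 0, 0/1 -> 1, 1/1 -> 2, missing -> NaN.  Multi-allelic sites
    are rejected with a warning reporting their count.
    """
    from cyvcf2 import VCF  # optional heavyweight import

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids, rows, chroms, poss = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        name = var.ID or f"{var.CHROM}:{var.POS}"
        marker_ids.append(name)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        types = var.gt_types  # 0=hom_ref 1=het 2=unknown 3=hom_alt
        dos = np.array([0.0, 1.0, np.nan, 2.0])[types]
        rows.append(dos)
    if n_multi:
        warnings.warn(f"rejected {n_multi} multi-allelic sites")
    dosages = np.array(rows).T if rows else np.zeros((len(samples), 0))
    meta = pd.DataFrame({"chrom": chroms, "pos": poss}, index=marker_ids)
    return DosageMatrix(samples, marker_ids, dosages, meta)


@dataclass
class CurationReport:
    """Step table: markers and genotypes retained after each curation step."""

    steps: list[str] = field(default_factory=list)
    markers: list[int] = field(default_factory=list)
    genotypes: list[int] = field(default_factory=list)

    def add(self, step: str, d: DosageMatrix) -> None:
        self.steps.append(step)
        self.markers.append(d.n_markers)
        self.genotypes.append(d.n_genotypes)

    def extend(self, other: "CurationReport") -> "CurationReport":
        self.steps += other.steps
        self.markers += other.markers
        self.genotypes += other.genotypes
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": self.steps, "markers": self.markers, "genotypes": self.genotypes}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_markers(d: DosageMatrix, maf_min: float = 0.05,
                   miss_max: float = 0.10) -> tuple[DosageMatrix, CurationReport]:
    """Keep markers with missing fraction <= ``miss_max`` and MAF >= ``maf_min``.

    MAF is computed on non-missing calls only.  Raises if no marker
    survives.
    """
    if not 0 <= maf_min <= 0.5:
        raise CurationError(f"maf_min must be in [0, 0.5], got {maf_min}")
    if not 0 <= miss_max <= 1:
        raise CurationError(f"miss_max must be in [0, 1], got {miss_max}")
    report = CurationReport()
    report.add("input", d)
    miss = d.missing_fraction()
    kept = d.select_markers(miss <= miss_max)
    report.add(f"missingness <= {miss_max:g}", kept)
    with np.errstate(invalid="ignore"):
        kept = kept.select_markers(kept.maf() >= maf_min)
    report.add(f"MAF >= {maf_min:g}", kept)
    if kept.n_markers == 0:
        raise CurationError(
            "all markers removed by filters; review maf_min/miss_max thresholds"
        )
    return kept, report


def mean_impute(d: DosageMatrix) -> DosageMatrix:
    """Replace missing cells by the marker mean over non-missing calls."""
    all_missing = np.isnan(d.dosages).all(axis=0)
    if all_missing.any():
        bad = [d.marker_ids[k] for k in np.flatnonzero(all_missing)[:10]]
        raise CurationError(f"markers with no non-missing calls: {bad}")
    out = d.dosages.copy()
    means = np.nanmean(out, axis=0)
    rows, cols = np.nonzero(np.isnan(out))
    out[rows, cols] = means[cols]
    return DosageMatrix(list(d.genotype_ids), list(d.marker_ids), out,
                        d.marker_meta, imputed=True)


def ld_prune(d: DosageMatrix, r2_max: float = 0.5, window: int = 50,
             window_bp: int | None = None) -> DosageMatrix:
    """Greedy left-to-right LD pruning.

    A marker is kept unless its squared Pearson correlation with an
    already-kept marker within the window exceeds ``r2_max``.  The
    window is measured in marker positions, or in base pairs when
    ``window_bp`` is given (requires ``marker_meta`` with ``chrom`` and
    ``pos``).  Zero-variance markers are dropped with a warning.
    """
    if not d.imputed and np.isnan(d.dosages).any():
        raise CurationError("ld_prune requires imputed (no-missing) dosages")
    if window_bp is not None and d.marker_meta is None:
        raise CurationError("window_bp pruning requires marker_meta with chrom/pos")

    X = d.dosages
    sd = X.std(axis=0)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        warnings.warn(
            f"dropping {zero_var.size} zero-variance markers "
            f"(correlation undefined): {[d.marker_ids[k] for k in zero_var[:5]]}"
        )
    Xc = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    n = X.shape[0]

    if window_bp is not None:
        meta = d.marker_meta.loc[d.marker_ids]
        chrom = meta["chrom"].to_numpy()
        pos = meta["pos"].to_numpy(dtype=float)

    kept: list[int] = []
    for j in range(d.n_markers):
        if sd[j] == 0:
            continue
        in_window = []
        for k in reversed(kept):
            if window_bp is not None:
                if chrom[k] != chrom[j]:
                    break
                if pos[j] - pos[k] > window_bp:
                    break
            elif j - k > window:
                break
            in_window.append(k)
        drop = False
        for k in in_window:
            r = float(Xc[:, j] @ Xc[:, k]) / n
            if r * r > r2_max:
                drop = True
                break
        if not drop:
            kept.append(j)
    return d.select_markers(np.array(kept, dtype=int))


def merge_platforms(d1: DosageMatrix, d2: DosageMatrix,
                    min_concordance: float = 0.7, mode: str = "r2",
                    ) -> tuple[DosageMatrix, dict[str, float]]:
    """Merge two genotyping platforms on concordant shared markers.

    For every marker present in both inputs, the Pearson correlation of
    dosages across genotypes present in both is computed; markers whose
    squared correlation (``mode="r2"``, default) or plain correlation
    (``mode="r"``) reaches ``min_concordance`` are retained.  The result
    covers the union of genotypes on retained markers, with ``d1``
    taking precedence for genotypes present in both.
    """
    if mode not in ("r2", "r"):
        raise CurationError(f"mode must be 'r2' or 'r', got {mode!r}")
    overlap = [g for g in d1.genotype_ids if g in set(d2.genotype_ids)]
    if not overlap:
        raise CurationError("no overlapping genotypes between platforms")
    if len(overlap) < 2:
        raise CurationError(
            f"only {len(overlap)} overlapping genotype(s); correlation undefined"
        )
    shared = [m for m in d1.marker_ids if m in set(d2.marker_ids)]
    if not shared:
        raise CurationError("no shared markers between platforms")

    x1 = d1.select_genotypes(overlap)
    x2 = d2.select_genotypes(overlap)
    m1 = {m: k for k, m in enumerate(d1.marker_ids)}
    m2 = {m: k for k, m in enumerate(d2.marker_ids)}
    concordance: dict[str, float] = {}
    retained: list[str] = []
    for m in shared:
        a = x1.dosages[:, m1[m]]
        b = x2.dosages[:, m2[m]]
        ok = ~np.isnan(a) & ~np.isnan(b)
        if ok.sum() < 2 or a[ok].std() == 0 or b[ok].std() == 0:
            concordance[m] = float("nan")
            continue
        r = float(np.corrcoef(a[ok], b[ok])[0, 1])
        score = r * r if mode == "r2" else r
        concordance[m] = score
        if score >= min_concordance:
            retained.append(m)

    extra = [g for g in d2.genotype_ids if g not in set(d1.genotype_ids)]
    genotypes = list(d1.genotype_ids) + extra
    keep1 = d1.select_markers(np.array([m1[m] for m in retained], dtype=int))
    dosages = np.full((len(genotypes), len(retained)), np.nan)
    dosages[: d1.n_genotypes, :] = keep1.dosages
    if extra:
        x2e = d2.select_genotypes(extra)
        dosages[d1.n_genotypes:, :] = x2e.dosages[
            :, [m2[m] for m in retained]
        ]
    meta = None
    if d1.marker_meta is not None:
        meta = d1.marker_meta.loc[retained]
    merged = DosageMatrix(genotypes, retained, dosages, meta,
                          imputed=d1.imputed or d2.imputed)
    return merged, concordance


def vanraden_g(d: DosageMatrix) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix.

    ``G = ZZ' / (2 * sum_i p_i (1 - p_i))`` with ``Z = M - 2P`` and
    ``p_i`` the observed allele frequency of marker ``i`` in the data.
    Monomorphic markers are excluded from both ``Z`` and the
    denominator (with a warning); all-monomorphic input is an error.
    """
    if np.isnan(d.dosages).any():
        raise CurationError("vanraden_g requires imputed (no-missing) dosages")
    p = d.dosages.mean(axis=0) / 2.0
    poly = (d.dosages.std(axis=0) > 0) & (p > 0) & (p < 1)
    if not poly.any():
        raise CurationError("all markers monomorphic; G denominator is zero")
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic markers from G")
    M = d.dosages[:, poly]
    pp = p[poly]
    Z = M - 2.0 * pp
    denom = 2.0 * float(np.sum(pp * (1.0 - pp)))
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0
    return RelationshipMatrix(list(d.genotype_ids), G, "G")
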