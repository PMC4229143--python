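"""SNP dosage matrices: I/O, imputation, MAF filtering, and PCA.

Genotypes are held as real-valued dosages in [0, 2] (counts of the tracked
allele, diploidized for mixed-ploidy GBS calls) with an explicit missing-data
mask, so that missing calls are never silently treated as homozygous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from cyvcf2 import VCF


class SnpParseError(ValueError):
    """Raised when a genotype file cannot be interpreted."""


@dataclass
class SnpMatrix:
    """Samples-by-markers dosage matrix with a missing-call mask.

    Attributes
    ----------
    samples : list of str
        Ordered genotype (plant) identifiers, unique.
    markers : list of str
        Ordered marker identifiers, unique.
    dosages : ndarray, shape (n_samples, n_markers)
        Real-valued allele dosages in [0, 2]. Entries under ``missing_mask``
        are undefined (kept as 0 internally).
    missing_mask : ndarray of bool, same shape
        True where the call is absent.
    chrom : ndarray of object, optional
        Chromosome per marker ('' when unknown).
    pos : ndarray of int, optional
        1-based position per marker (0 when unknown).
    """

    samples: list[str]
    markers: list[str]
    dosages: np.ndarray
    missing_mask: np.ndarray
    chrom: np.ndarray = field(default=None)  # type: ignore[assignment]
    pos: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.dosages.shape != self.missing_mask.shape:
            raise ValueError("dosages and missing_mask shapes differ")
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise ValueError("matrix shape does not match sample/marker lists")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker identifiers")
        obs = self.dosages[~self.missing_mask]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("non-missing dosages must lie in [0, 2]")
        if self.chrom is None:
            self.chrom = np.asarray([""] * len(self.markers), dtype=object)
        if self.pos is None:
            self.pos = np.zeros(len(self.markers), dtype=int)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_samples(self, keep: list[str]) -> "SnpMatrix":
        """Restrict to ``keep`` (in the given order)."""
        index = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in keep if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        rows = [index[s] for s in keep]
        return SnpMatrix(
            samples=list(keep),
            markers=list(self.markers),
            dosages=self.dosages[rows].copy(),
            missing_mask=self.missing_mask[rows].copy(),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
        )

    def subset_markers(self, keep_idx: np.ndarray) -> "SnpMatrix":
        keep_idx = np.asarray(keep_idx)
        return SnpMatrix(
            samples=list(self.samples),
            markers=[self.markers[i] for i in keep_idx],
            dosages=self.dosages[:, keep_idx].copy(),
            missing_mask=self.missing_mask[:, keep_idx].copy(),
            chrom=self.chrom[keep_idx].copy(),
            pos=self.pos[keep_idx].copy(),
        )


@dataclass
class PcScores:
    """Principal-component coordinates of the samples."""

    samples: list[str]
    scores: np.ndarray  # (n_samples, k)
    explained_variance: np.ndarray  # k fractions, non-increasing

    @property
    def k(self) -> int:
        return self.scores.shape[1]


# ---------------------------------------------------------------------------
# I/O


def read_snp_matrix(path: str | Path, format: str = "tabular") -> SnpMatrix:
    """Read a dosage matrix from a VCF or the tabular TSV dialect.

    Tabular dialect: TSV; header row ``sample_id<TAB>marker1<TAB>...``;
    one row per sample; cells are dosages in [0, 2] (decimals allowed)
    or ``NA`` for missing.

    VCF: v4.x text, GT field only, biallelic SNPs, ``./.`` missing;
    the dosage counts ALT alleles.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "tabular":
        return _read_tabular(path)
    raise ValueError(f"unknown format {format!r}; expected 'vcf' or 'tabular'")


def _read_vcf(path: Path) -> SnpMatrix:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    cols: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise SnpParseError(
                f"multi-allelic record not supported: {var.ID or f'{var.CHROM}:{var.POS}'}"
            )
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        markers.append(mid)
        chroms.append(var.CHROM)
        positions.append(var.POS)
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types
        miss = gt == 2
        dose = np.where(gt == 3, 2.0, gt.astype(float))
        dose[miss] = 0.0
        cols.append(dose)
        masks.append(miss)
    if not markers:
        raise SnpParseError(f"no variant records in {path}")
    return SnpMatrix(
        samples=samples,
        markers=markers,
        dosages=np.column_stack(cols),
        missing_mask=np.column_stack(masks),
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(positions, dtype=int),
    )


def _read_tabular(path: Path) -> SnpMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise SnpParseError(f"{path}: empty file")
        fields = header.split("\t")
        markers = fields[1:]
        if not markers:
            raise SnpParseError(f"{path}:1: header has no marker columns")
        samples: list[str] = []
        rows: list[np.ndarray] = []
        masks: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(fields):
                raise SnpParseError(
                    f"{path}:{lineno}: expected {len(fields)} columns, got {len(parts)}"
                )
            samples.append(parts[0])
            vals = np.zeros(len(markers))
            miss = np.zeros(len(markers), dtype=bool)
            for j, cell in enumerate(parts[1:]):
                if cell in ("NA", "", "."):
                    miss[j] = True
                else:
                    try:
                        vals[j] = float(cell)
                    except ValueError as exc:
                        raise SnpParseError(
                            f"{path}:{lineno}: bad dosage {cell!r}"
                        ) from exc
            rows.append(vals)
            masks.append(miss)
    if not samples:
        raise SnpParseError(f"{path}: no sample rows")
    return SnpMatrix(
        samples=samples,
        markers=markers,
        dosages=np.vstack(rows),
        missing_mask=np.vstack(masks),
    )


def write_snp_matrix(m: SnpMatrix, path: str | Path) -> None:
    """Write the tabular TSV dialect (NA for missing)."""
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(m.markers) + "\n")
        for i, s in enumerate(m.samples):
            cells = [
                "NA" if m.missing_mask[i, j] else format(m.dosages[i, j], "g")
                for j in range(m.n_markers)
            ]
            fh.write(s + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Frequencies and filtering


def minor_allele_frequency(m: SnpMatrix) -> np.ndarray:
    """Per-marker minor allele frequency min(p, 1-p), p = mean dosage / 2.

    Only non-missing calls enter the frequency. A marker with no
    observed calls is an error.
    """
    n_obs = (~m.missing_mask).sum(axis=0)
    if (n_obs == 0).any():
        bad = [m.markers[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"markers with all calls missing: {bad[:10]}")
    dose = np.where(m.missing_mask, 0.0, m.dosages)
    p = dose.sum(axis=0) / (2.0 * n_obs)
    return np.minimum(p, 1.0 - p)


def filter_maf(m: SnpMatrix, threshold: float = 0.05) -> SnpMatrix:
    """Keep markers with MAF >= ``threshold``; marker order preserved."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("threshold must lie in [0, 0.5]")
    maf = minor_allele_frequency(m)
    keep = np.flatnonzero(maf >= threshold)
    if keep.size == 0:
        raise ValueError(f"MAF filter at {threshold} removed every marker")
    return m.subset_markers(keep)


# ---------------------------------------------------------------------------
# Imputation


def impute_missing(
    m: SnpMatrix, method: str = "marker_mean", rng_seed: int = 0, knn_k: int = 5
) -> SnpMatrix:
    """Fill missing dosages; returns a matrix with an all-false mask.

    marker_mean : column mean of the observed calls (preserves frequency).
    marker_mode : most frequent rounded observed dosage (ties -> smaller).
    knn         : mean over the ``knn_k`` nearest samples by Euclidean
                  distance on the markers both samples observe.
    """
    if method not in ("marker_mean", "marker_mode", "knn"):
        raise ValueError(f"unknown imputation method {method!r}")
    if not m.missing_mask.any():
        return SnpMatrix(
            list(m.samples), list(m.markers), m.dosages.copy(),
            np.zeros_like(m.missing_mask), m.chrom.copy(), m.pos.copy(),
        )
    n_obs = (~m.missing_mask).sum(axis=0)
    if (n_obs == 0).any():
        bad = [m.markers[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"cannot impute markers with no observed calls: {bad[:10]}")

    dose = np.where(m.missing_mask, np.nan, m.dosages)
    filled = dose.copy()
    if method == "marker_mean":
        col_mean = np.nanmean(dose, axis=0)
        idx = np.where(m.missing_mask)
        filled[idx] = col_mean[idx[1]]
    elif method == "marker_mode":
        for j in np.flatnonzero(m.missing_mask.any(axis=0)):
            obs = dose[:, j][~np.isnan(dose[:, j])]
            vals, counts = np.unique(np.round(obs), return_counts=True)
            mode = vals[np.argmax(counts)]  # np.unique sorts -> ties break low
            filled[np.isnan(dose[:, j]), j] = mode
    else:  # knn
        filled = _impute_knn(dose, knn_k)
    out = np.nan_to_num(filled)
    return SnpMatrix(
        list(m.samples), list(m.markers), out,
        np.zeros_like(m.missing_mask), m.chrom.copy(), m.pos.copy(),
    )


def _impute_knn(dose: np.ndarray, k: int) -> np.ndarray:
    n = dose.shape[0]
    obs = ~np.isnan(dose)
    z = np.nan_to_num(dose)
    # pairwise squared distance on shared observed markers, normalized per pair
    shared = obs.astype(float) @ obs.astype(float).T
    sq = (z**2) @ obs.T.astype(float) + obs.astype(float) @ (z**2).T - 2 * z @ z.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(shared > 0, sq / shared, np.inf)
    np.fill_diagonal(d2, np.inf)
    filled = dose.copy()
    col_mean = np.nanmean(dose, axis=0)
    for i in range(n):
        miss_j = np.flatnonzero(np.isnan(dose[i]))
        if miss_j.size == 0:
            continue
        order = np.argsort(d2[i])
        for j in miss_j:
            donors = [h for h in order if obs[h, j] and np.isfinite(d2[i, h])][:k]
            filled[i, j] = dose[donors, j].mean() if donors else col_mean[j]
    return filled


# ---------------------------------------------------------------------------
# PCA


def pca_scores(m: SnpMatrix, k: int = 2, scale: bool = False) -> PcScores:
    """Top-``k`` principal-component scores of the centered dosage matrix.

    Dosages are centered per marker; ``scale=True`` additionally divides by
    the per-marker standard deviation (default off, the common GBS
    convention). The sign of each component is fixed so the
    largest-magnitude loading is positive.
    """
    if m.missing_mask.any():
        raise ValueError("pca_scores requires a fully imputed matrix")
    max_k = min(m.n_samples - 1, m.n_markers)
    if k > max_k:
        raise ValueError(f"k={k} exceeds the maximum rank {max_k}")
    x = m.dosages - m.dosages.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = x / sd
    # SVD on the centered matrix: scores = U * S, loadings = columns of Vt
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    # fix sign: largest-|loading| entry positive
    for j in range(k):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            scores[:, j] *= -1.0
    total = (s**2).sum()
    if total == 0:
        raise ValueError("zero-variance matrix has no principal components")
    explained = (s[:k] ** 2) / total
    return PcScores(samples=list(m.samples), scores=scores, explained_variance=explained)


def write_pc_scores(pcs: PcScores, path: str | Path) -> None:
    """CSV: sample_id, PC1..PCk."""
    with open(path, "w") as fh:
        fh.write("sample_id," + ",".join(f"PC{j+1}" for j in range(pcs.k)) + "\n")
        for i, s in enumerate(pcs.samples):
            fh.write(s + "," + ",".join(f"{v:.10g}" for v in pcs.scores[i]) + "\n")
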