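"""SNP-by-SNP inbreeding estimation and marker filtering.

The central estimator is the correlation-between-uniting-gametes inbreeding
coefficient (PLINK's Fhat3, here ``YangInbreeding`` / :func:`f_yan`):

    F = (1/S) * sum_k [x_k^2 - (1 + 2 p_k) x_k + 2 p_k^2] / [2 p_k (1 - p_k)]

with x_k the minor-allele dosage (0/1/2) and p_k the *current* minor-allele
frequency computed from the analysis group itself. Under Hardy-Weinberg
proportions each per-SNP term has expectation zero; a heterozygote always
contributes exactly -1.

Genotype matrices are individuals x SNPs float arrays of minor-allele dosage
with ``nan`` for missing calls. Marker metadata travels in a
:class:`MarkerPanel`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "MarkerPanel",
    "minor_allele_recode",
    "allele_frequencies",
    "YangInbreeding",
    "f_yan",
    "LDPruner",
    "ld_prune",
    "MAFFilter",
    "maf_filter",
    "subsample_snps",
]


@dataclass(frozen=True)
class MarkerPanel:
    """Per-SNP metadata: chromosome, physical position (bp, 1-based) and the
    minor-allele frequency in the analysis group."""

    chrom: np.ndarray  # shape (S,), chromosome labels
    pos: np.ndarray  # shape (S,), int, strictly increasing within chromosome
    p: np.ndarray  # shape (S,), minor-allele frequency in (0, 0.5]

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chrom)
        pos = np.asarray(self.pos, dtype=np.int64)
        p = np.asarray(self.p, dtype=float)
        if not chrom.shape == pos.shape == p.shape:
            raise ValueError("chrom, pos and p must have equal length")
        for c in np.unique(chrom):
            pc = pos[chrom == c]
            if np.any(np.diff(pc) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        if np.any((p <= 0) | (p > 0.5)):
            raise ValueError("minor-allele frequencies must lie in (0, 0.5]")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos", pos)
        object.__setattr__(self, "p", p)

    @property
    def n_snps(self) -> int:
        return int(self.pos.size)

    def take(self, index: np.ndarray) -> "MarkerPanel":
        return MarkerPanel(self.chrom[index], self.pos[index], self.p[index])


def _as_dosage(X) -> np.ndarray:
    X = check_array(X, dtype=float, ensure_all_finite=False, ensure_min_features=1)
    bad = ~np.isnan(X) & ~np.isin(X, (0.0, 1.0, 2.0))
    if np.any(bad):
        raise ValueError("dosages must be 0, 1, 2 or nan (missing)")
    return X


def allele_frequencies(X) -> np.ndarray:
    """Counted-allele frequency per SNP, missing genotypes excluded."""
    X = _as_dosage(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(X, axis=0) / 2.0


def minor_allele_recode(X, alleles: tuple[np.ndarray, np.ndarray] | None = None):
    """Recode a dosage matrix so x counts the within-group minor allele.

    SNPs monomorphic within the group are dropped (the estimator denominator
    2p(1-p) is undefined there). At p = 0.5 exactly, the minor allele is the
    lexicographically smaller allele label when labels are given, otherwise
    the currently counted allele is kept; the estimator is symmetric under
    the swap at p = 0.5 either way.

    Returns ``(X_minor, p, kept_index)``.
    """
    X = _as_dosage(X)
    freq = allele_frequencies(X)
    keep = np.isfinite(freq) & (freq > 0.0) & (freq < 1.0)
    X = X[:, keep].copy()
    freq = freq[keep]
    flip = freq > 0.5
    if alleles is not None:
        ref = np.asarray(alleles[0])[keep]
        alt = np.asarray(alleles[1])[keep]
        tied = freq == 0.5
        # counted allele is alt; minor at ties = lexicographically smaller
        flip = flip | (tied & (alt > ref))
    X[:, flip] = 2.0 - X[:, flip]
    p = np.where(flip, 1.0 - freq, freq)
    return X, p, np.flatnonzero(keep)


def _yang_terms(X: np.ndarray, p: np.ndarray) -> np.ndarray:
    denom = 2.0 * p * (1.0 - p)
    return (X * X - (1.0 + 2.0 * p) * X + 2.0 * p * p) / denom


class YangInbreeding(TransformerMixin, BaseEstimator):
    """Correlation-of-uniting-gametes inbreeding coefficient (PLINK Fhat3).

    ``fit`` learns the within-group minor-allele frequencies (dropping SNPs
    monomorphic in the fitted group); ``transform`` returns one F value per
    individual as an (n, 1) column. Missing genotypes are excluded from the
    per-individual average (they reduce that individual's effective S).

    Parameters
    ----------
    frequencies : array of shape (n_snps,), optional
        Externally supplied minor-allele frequencies; if given, ``fit`` does
        not recompute them and no SNPs are dropped.
    """

    def __init__(self, frequencies=None):
        self.frequencies = frequencies

    def fit(self, X, y=None):
        X = _as_dosage(X)
        if self.frequencies is not None:
            p = np.asarray(self.frequencies, dtype=float)
            if p.size != X.shape[1]:
                raise ValueError("frequencies length must match n_snps")
            if np.any((p <= 0.0) | (p >= 1.0)):
                raise ValueError("frequencies must lie strictly in (0, 1)")
            self.p_ = p
            self.kept_index_ = np.arange(X.shape[1])
            self.flip_ = np.zeros(X.shape[1], dtype=bool)
        else:
            freq = allele_frequencies(X)
            keep = np.isfinite(freq) & (freq > 0.0) & (freq < 1.0)
            if not np.any(keep):
                raise ValueError("no polymorphic SNPs left in this group")
            self.kept_index_ = np.flatnonzero(keep)
            self.flip_ = freq[keep] > 0.5
            self.p_ = np.where(self.flip_, 1.0 - freq[keep], freq[keep])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "p_")
        X = _as_dosage(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("n_snps mismatch with fitted panel")
        Xm = X[:, self.kept_index_].copy()
        Xm[:, self.flip_] = 2.0 - Xm[:, self.flip_]
        terms = _yang_terms(Xm, self.p_)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f = np.nanmean(terms, axis=1)
        return f[:, None]

    def _more_tags(self):  # pragma: no cover - sklearn plumbing
        return {"allow_nan": True}


def f_yan(X, frequencies=None) -> np.ndarray:
    """Per-individual SNP-by-SNP inbreeding coefficient as a 1-D array.

    Frequencies default to the sample's own ("current") frequencies.
    """
    est = YangInbreeding(frequencies=frequencies).fit(X)
    return est.transform(X).ravel()


# ---------------------------------------------------------------------------
# marker filtering


class LDPruner(SelectorMixin, BaseEstimator):
    """Sliding-window LD pruning of highly linked SNPs (indep-pairwise style).

    Windows of ``window_snps`` SNPs advance by ``step`` SNPs; within every
    window, pairs of retained SNPs with squared dosage correlation above
    ``r2_threshold`` are resolved by dropping the member with the lower
    minor-allele frequency (tie: the later position). A single left-to-right
    pass leaves no retained pair above the threshold in any window.
    """

    def __init__(self, window_snps: int = 50, step: int = 5, r2_threshold: float = 0.9):
        self.window_snps = window_snps
        self.step = step
        self.r2_threshold = r2_threshold

    def fit(self, X, y=None):
        if self.window_snps < 2:
            raise ValueError("window must span at least 2 SNPs")
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must lie in (0, 1]")
        if self.step < 1:
            raise ValueError("step must be positive")
        X = _as_dosage(X)
        n, S = X.shape
        if S < 2:
            raise ValueError("need at least 2 SNPs to prune")
        freq = allele_frequencies(X)
        maf = np.minimum(freq, 1.0 - freq)
        keep = np.ones(S, dtype=bool)
        for start in range(0, S, self.step):
            stop = min(start + self.window_snps, S)
            idx = np.flatnonzero(keep[start:stop]) + start
            if idx.size < 2:
                if stop == S:
                    break
                continue
            r2 = _pairwise_r2(X[:, idx])
            for a in range(len(idx)):
                if not keep[idx[a]]:
                    continue
                for b in range(a + 1, len(idx)):
                    if not keep[idx[b]]:
                        continue
                    if r2[a, b] > self.r2_threshold:
                        ia, ib = idx[a], idx[b]
                        if maf[ia] < maf[ib]:
                            drop = ia
                        elif maf[ib] < maf[ia]:
                            drop = ib
                        else:
                            drop = max(ia, ib)
                        keep[drop] = False
                        if drop == ia:
                            break
            if stop == S:
                break
        self.support_ = keep
        self.n_features_in_ = S
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def _more_tags(self):  # pragma: no cover
        return {"allow_nan": True}


def _pairwise_r2(X: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, pairwise-complete."""
    mask = np.isfinite(X)
    Xf = np.where(mask, X, 0.0)
    m = mask.astype(float)
    n = m.T @ m
    sx = Xf.T @ m
    sxx = (Xf * Xf).T @ m
    sxy = Xf.T @ Xf
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        var_a = sxx - sx * sx / n
        var_b = var_a.T
        r2 = cov * cov / (var_a * var_b)
    r2 = np.where(np.isfinite(r2), r2, 0.0)
    return r2


def ld_prune(X, window_snps: int = 50, step: int = 5, r2_threshold: float = 0.9) -> np.ndarray:
    """Indices of SNPs retained after sliding-window LD pruning."""
    pruner = LDPruner(window_snps, step, r2_threshold).fit(X)
    return np.flatnonzero(pruner.support_)


class MAFFilter(SelectorMixin, BaseEstimator):
    """Remove SNPs whose within-group minor-allele frequency is below
    ``maf_min`` (computed on the fitted analysis group)."""

    def __init__(self, maf_min: float = 0.05):
        self.maf_min = maf_min

    def fit(self, X, y=None):
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        X = _as_dosage(X)
        freq = allele_frequencies(X)
        maf = np.minimum(freq, 1.0 - freq)
        self.support_ = np.isfinite(maf) & (maf >= self.maf_min)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def _more_tags(self):  # pragma: no cover
        return {"allow_nan": True}


def maf_filter(X, panel: MarkerPanel | None = None, maf_min: float = 0.05):
    """Filtered (X, panel) with SNPs of minor-allele frequency < maf_min removed."""
    sel = MAFFilter(maf_min=maf_min).fit(X)
    idx = np.flatnonzero(sel.support_)
    Xf = np.asarray(X, dtype=float)[:, idx]
    return (Xf, panel.take(idx) if panel is not None else None, idx)


def subsample_snps(panel: MarkerPanel, target_count: int, seed) -> tuple[MarkerPanel, np.ndarray]:
    """Uniform random SNP subset without replacement, original order kept.

    Returns the reduced panel and the selected column indices.
    """
    if not 0 < target_count <= panel.n_snps:
        raise ValueError("target_count must lie in [1, n_snps]")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(panel.n_snps, size=target_count, replace=False))
    return panel.take(idx), idx
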