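"""Runs-of-homozygosity detection and the F_ROH inbreeding coefficient.

The caller follows sliding-window semantics: a window of ``window_snps``
consecutive SNPs is slid one SNP at a time along each chromosome (windows are
truncated at the chromosome end and judged with the same absolute bounds); a
window is *homozygous* if it contains at most ``window_het_allowed``
heterozygotes and at most ``window_missing_allowed`` missing calls. Each
SNP's hit rate is the fraction of windows overlapping it that are homozygous;
SNPs with hit rate >= ``hit_threshold`` are ROH-eligible. Maximal runs of
eligible SNPs are split at inter-SNP gaps above ``max_gap_kb`` and reported
as segments if they satisfy the minimum SNP count, minimum physical length
and minimum SNP density. Segments carry their heterozygote count but no
additional per-segment heterozygote bound is applied beyond window
eligibility.

F_ROH is the summed length of all segments at or above a minimum length,
divided by ``l_auto``, the physical length of the autosomal genome covered
by markers. Positions are 1-based inclusive; segment length = end - start + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .markers import MarkerPanel, _as_dosage

__all__ = [
    "ROHParams",
    "ROHSegment",
    "ROHResult",
    "detect_roh",
    "f_roh",
    "ROHInbreeding",
]


@dataclass(frozen=True)
class ROHParams:
    """Parameters of the sliding-window ROH caller (PLINK-default values)."""

    window_snps: int = 50
    window_het_allowed: int = 1
    window_missing_allowed: int = 5
    hit_threshold: float = 0.05
    min_snps: int = 100
    min_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0
    min_length_kb: float = 100.0

    def __post_init__(self) -> None:
        if min(self.window_snps, self.min_snps) < 1:
            raise ValueError("window_snps and min_snps must be positive")
        if not 0.0 < self.hit_threshold <= 1.0:
            raise ValueError("hit_threshold must lie in (0, 1]")
        if min(self.min_density_kb_per_snp, self.max_gap_kb, self.min_length_kb) <= 0:
            raise ValueError("density, gap and length parameters must be positive")
        if min(self.window_het_allowed, self.window_missing_allowed) < 0:
            raise ValueError("window allowances must be non-negative")


@dataclass(frozen=True)
class ROHSegment:
    chrom: object
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


@dataclass(frozen=True)
class ROHResult:
    """Called segments for one individual."""

    segments: tuple[ROHSegment, ...]

    def sum_length_bp(self, min_length_kb: float = 0.0) -> int:
        return sum(
            s.length_bp for s in self.segments if s.length_kb >= min_length_kb
        )

    def n_segments(self, min_length_kb: float = 0.0) -> int:
        return sum(1 for s in self.segments if s.length_kb >= min_length_kb)


def _eligible_snps(het: np.ndarray, missing: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean ROH-eligibility per SNP from window hit rates (vectorised)."""
    n = het.size
    W = min(params.window_snps, n)
    # window starting at s covers snps [s, min(s + window, n))
    chet = np.concatenate(([0], np.cumsum(het)))
    cmis = np.concatenate(([0], np.cumsum(missing)))
    starts = np.arange(n)
    ends = np.minimum(starts + params.window_snps, n)
    ok = (
        (chet[ends] - chet[starts] <= params.window_het_allowed)
        & (cmis[ends] - cmis[starts] <= params.window_missing_allowed)
    )
    # SNP i is covered by windows starting in [max(0, i - window + 1), i]
    cok = np.concatenate(([0], np.cumsum(ok)))
    i = np.arange(n)
    lo = np.maximum(0, i - params.window_snps + 1)
    hits = cok[i + 1] - cok[lo]
    counts = i - lo + 1
    return hits / counts >= params.hit_threshold


def _segments_one_chrom(
    geno: np.ndarray, pos: np.ndarray, chrom_label, params: ROHParams
) -> list[ROHSegment]:
    het = geno == 1.0
    missing = np.isnan(geno)
    eligible = _eligible_snps(het, missing, params)
    segments: list[ROHSegment] = []
    n = geno.size
    i = 0
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and eligible[j + 1]
            and (pos[j + 1] - pos[j]) <= params.max_gap_kb * 1000.0
        ):
            j += 1
        n_snps = j - i + 1
        length = int(pos[j] - pos[i] + 1)
        if (
            n_snps >= params.min_snps
            and length >= params.min_length_kb * 1000.0
            and length / n_snps <= params.min_density_kb_per_snp * 1000.0
        ):
            segments.append(
                ROHSegment(
                    chrom=chrom_label,
                    start_bp=int(pos[i]),
                    end_bp=int(pos[j]),
                    n_snps=n_snps,
                    n_het=int(het[i : j + 1].sum()),
                )
            )
        i = j + 1
    return segments


def detect_roh(X, panel: MarkerPanel, params: ROHParams = ROHParams()) -> list[ROHResult]:
    """Call ROH segments for every individual (row) of a dosage matrix.

    SNPs must be sorted by position within chromosome (enforced by
    :class:`MarkerPanel`).
    """
    X = _as_dosage(X)
    if X.shape[1] != panel.n_snps:
        raise ValueError("dosage matrix and panel disagree on SNP count")
    chrom_slices = []
    chrom = panel.chrom
    boundaries = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [chrom.size]))
    results = []
    for row in X:
        segs: list[ROHSegment] = []
        for a, b in zip(starts, ends):
            segs.extend(
                _segments_one_chrom(row[a:b], panel.pos[a:b], chrom[a], params)
            )
        results.append(ROHResult(tuple(segs)))
    return results


def f_roh(result: ROHResult, min_length_kb: float, l_auto: int) -> float:
    """Summed segment length at or above ``min_length_kb``, over ``l_auto``."""
    if l_auto <= 0:
        raise ValueError("l_auto must be positive")
    return result.sum_length_bp(min_length_kb) / float(l_auto)


class ROHInbreeding(TransformerMixin, BaseEstimator):
    """F_ROH per individual at one or more minimum segment lengths.

    ``transform(X)`` returns an (n_individuals, len(min_lengths_kb)) array;
    column j is F_ROH with minimum segment length ``min_lengths_kb[j]``.
    Detection runs once at the smallest minimum length; larger minima are
    pure per-segment filters of the same candidate set, so
    F_ROH(1 Mb) <= F_ROH(0.1 Mb) holds by construction.

    The marker panel is feature metadata and is part of the estimator
    configuration (like feature names), not of the sample data.
    """

    def __init__(
        self,
        panel: MarkerPanel | None = None,
        l_auto: int | None = None,
        params: ROHParams = ROHParams(),
        min_lengths_kb: Sequence[float] = (100.0, 1000.0),
    ):
        self.panel = panel
        self.l_auto = l_auto
        self.params = params
        self.min_lengths_kb = min_lengths_kb

    def fit(self, X, y=None):
        if self.panel is None:
            raise ValueError("a MarkerPanel is required")
        if self.l_auto is None or self.l_auto <= 0:
            raise ValueError("l_auto (bp covered by markers) must be positive")
        X = _as_dosage(X)
        if X.shape[1] != self.panel.n_snps:
            raise ValueError("dosage matrix and panel disagree on SNP count")
        self.n_features_in_ = X.shape[1]
        self.detection_params_ = replace(
            self.params, min_length_kb=float(min(self.min_lengths_kb))
        )
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "detection_params_")
        results = detect_roh(X, self.panel, self.detection_params_)
        self.results_ = results
        out = np.empty((len(results), len(self.min_lengths_kb)))
        for i, res in enumerate(results):
            for j, ml in enumerate(self.min_lengths_kb):
                out[i, j] = f_roh(res, ml, self.l_auto)
        return out

    def _more_tags(self):  # pragma: no cover
        return {"allow_nan": True}
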