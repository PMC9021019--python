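"""Region-level contact-map computations for capture-C-style data.

Covers the matrix side of the analysis: iterative correction (ICE)
balancing, distance-decay expected curves, conversion of viewpoint
read counts to contact probabilities, Z-score/IQR noise filtering,
insertion-aware distance-normalized differential ratio maps with
bilinear smoothing, and quantification of the contact-probability drop
across TAD boundaries.

Coordinates are 0-based half-open throughout; matrices are symmetric
binned counts over a single captured region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import convolve2d

__all__ = [
    "BinnedContactMatrix",
    "ExpectedCurve",
    "ViewpointProfile",
    "DifferentialMap",
    "ice_balance",
    "expected_by_distance",
    "viewpoint_profile",
    "counts_to_probability",
    "zscore",
    "filter_noise",
    "distance_normalize",
    "bilinear_smooth",
    "differential_map",
    "boundary_drop",
]

DEFAULT_BIN_SIZE = 6400


@dataclass
class BinnedContactMatrix:
    """Symmetric binned contact counts over ``[start, end)`` of ``chrom``
    at ``bin_size`` resolution.  ``bin_mask`` flags bins excluded from
    all statistics (True = filtered)."""

    chrom: str
    start: int
    end: int
    bin_size: int
    counts: np.ndarray
    bin_mask: np.ndarray = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.n_bins
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{n} bins for [{self.start}, {self.end}) at {self.bin_size}")
        if not np.allclose(self.counts, self.counts.T, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        if self.bin_mask is None:
            self.bin_mask = np.zeros(n, dtype=bool)
        else:
            self.bin_mask = np.asarray(self.bin_mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return -(-(self.end - self.start) // self.bin_size)

    @property
    def bin_starts(self) -> np.ndarray:
        return self.start + self.bin_size * np.arange(self.n_bins)

    def bin_index(self, pos: int) -> int:
        if not (self.start <= pos < self.end):
            raise ValueError(f"position {pos} outside [{self.start}, {self.end})")
        return (pos - self.start) // self.bin_size

    # -- plain-text I/O ----------------------------------------------------
    def to_dense_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# chrom={self.chrom} start={self.start} "
                     f"end={self.end} binsize={self.bin_size}\n")
            np.savetxt(fh, self.counts, fmt="%.8g", delimiter="\t")

    @classmethod
    def from_dense_tsv(cls, path) -> "BinnedContactMatrix":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
            counts = np.loadtxt(fh, delimiter="\t", ndmin=2)
        return cls(meta["chrom"], int(meta["start"]), int(meta["end"]),
                   int(meta["binsize"]), counts)

    def to_triplets(self, path) -> None:
        iu = np.triu_indices(self.n_bins)
        df = pd.DataFrame({"bin_i": iu[0], "bin_j": iu[1],
                           "count": self.counts[iu]})
        df = df[df["count"] != 0]
        with open(path, "w") as fh:
            fh.write(f"# chrom={self.chrom} start={self.start} "
                     f"end={self.end} binsize={self.bin_size}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_triplets(cls, path) -> "BinnedContactMatrix":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
            df = pd.read_csv(fh, sep="\t")
        n = -(-(int(meta["end"]) - int(meta["start"])) // int(meta["binsize"]))
        counts = np.zeros((n, n))
        counts[df["bin_i"], df["bin_j"]] = df["count"]
        counts[df["bin_j"], df["bin_i"]] = df["count"]
        return cls(meta["chrom"], int(meta["start"]), int(meta["end"]),
                   int(meta["binsize"]), counts)


@dataclass
class ExpectedCurve:
    """Per-distance mean and s.d. of contacts within the captured
    region.  ``mean[d]``/``std[d]`` summarize all unmasked entries at
    bin separation ``d``; ``n[d]`` counts them (std is NaN where
    ``n < 2``)."""

    mean: np.ndarray
    std: np.ndarray
    n: np.ndarray
    bin_size: int


@dataclass
class ViewpointProfile:
    """Cross-section of the map at an anchor (viewpoint) bin."""

    chrom: str
    start: int
    bin_size: int
    anchor_bin: int
    values: np.ndarray
    is_probability: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def bin_starts(self) -> np.ndarray:
        return self.start + self.bin_size * np.arange(self.values.size)


@dataclass
class DifferentialMap:
    """Smoothed ratio of two distance-normalized maps; ``mask`` marks
    the 'grey pixels' that failed noise filtering."""

    ratio: np.ndarray
    mask: np.ndarray
    window: int
    insertion: Optional[tuple] = None


# ---------------------------------------------------------------------------

def ice_balance(m: BinnedContactMatrix, tol: float = 1e-8,
                max_iter: int = 500) -> BinnedContactMatrix:
    """Iterative correction: multiplicative per-bin factors equalizing
    unmasked row sums.  Bins with zero total contacts are masked first.
    The overall scale is kept at the mean unmasked row sum of the input.
    """
    counts = m.counts.copy()
    mask = m.bin_mask | (counts.sum(axis=1) == 0)
    active = ~mask
    if not active.any():
        raise ValueError("all bins masked; nothing to balance")
    w = counts[np.ix_(active, active)]
    target = w.sum(axis=1).mean()
    residual = np.inf
    for _ in range(max_iter):
        s = w.sum(axis=1)
        s = s / s.mean()
        w /= np.outer(s, s)
        residual = np.abs(s - 1).max()
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"ICE did not converge in {max_iter} iterations "
            f"(residual {residual:.3g} > tol {tol:g})")
    w *= target / w.sum(axis=1).mean()
    out = np.zeros_like(counts)
    out[np.ix_(active, active)] = w
    out = 0.5 * (out + out.T)   # restore exact symmetry
    return BinnedContactMatrix(m.chrom, m.start, m.end, m.bin_size, out,
                               bin_mask=mask)


def _entry_mask(m: BinnedContactMatrix) -> np.ndarray:
    """Entry-level mask induced by the bin-level mask."""
    return m.bin_mask[:, None] | m.bin_mask[None, :]


def expected_by_distance(m: BinnedContactMatrix) -> ExpectedCurve:
    """Mean and s.d. of unmasked entries at each genomic (bin) distance."""
    n = m.n_bins
    bad = _entry_mask(m)
    mean = np.full(n, np.nan)
    std = np.full(n, np.nan)
    cnt = np.zeros(n, dtype=int)
    for d in range(n):
        vals = np.diagonal(m.counts, offset=d)
        keep = ~np.diagonal(bad, offset=d)
        vals = vals[keep]
        cnt[d] = vals.size
        if vals.size:
            mean[d] = vals.mean()
            std[d] = vals.std(ddof=0) if vals.size >= 2 else np.nan
    return ExpectedCurve(mean, std, cnt, m.bin_size)


def viewpoint_profile(m: BinnedContactMatrix, anchor_pos: int) -> ViewpointProfile:
    b = m.bin_index(anchor_pos)
    return ViewpointProfile(m.chrom, m.start, m.bin_size, b,
                            m.counts[b].copy())


def counts_to_probability(v: ViewpointProfile,
                          reference: str = "adjacent") -> ViewpointProfile:
    """Convert a viewpoint profile from counts to contact probabilities.

    The default rule divides by the mean of the two bins adjacent to the
    anchor (short-range contacts are taken as certain) and clips to
    [0, 1].  The rule applied is recorded in the profile metadata since
    absolute contact probabilities are calibration-dependent.
    """
    if reference != "adjacent":
        raise ValueError(f"unknown reference rule {reference!r}")
    b = v.anchor_bin
    neigh = [v.values[i] for i in (b - 1, b + 1)
             if 0 <= i < v.values.size]
    if not neigh:
        raise ValueError("anchor-adjacent bins absent")
    ref = float(np.mean(neigh))
    if ref == 0:
        raise ValueError("zero reference count at anchor-adjacent bins")
    vals = np.clip(v.values / ref, 0.0, 1.0)
    meta = dict(v.metadata, conversion=f"reference={reference}", ref_value=ref)
    return ViewpointProfile(v.chrom, v.start, v.bin_size, b, vals,
                            is_probability=True, metadata=meta)


def zscore(m: BinnedContactMatrix, e: ExpectedCurve) -> np.ndarray:
    """Entrywise ``(obs - exp) / stdev`` at each entry's bin distance;
    NaN where the expected s.d. is undefined or zero, or the entry is
    masked."""
    n = m.n_bins
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    exp = e.mean[d]
    std = e.std[d]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (m.counts - exp) / std
    z[std == 0] = np.nan
    z[_entry_mask(m)] = np.nan
    return z


def filter_noise(m: BinnedContactMatrix,
                 e: Optional[ExpectedCurve] = None,
                 singleton_percentile: float = 0.1,
                 iqr_factor: float = 1.5) -> np.ndarray:
    """Noise mask (True = filtered) combining three rules:

    * entries with no reported interactions (zero counts);
    * per-distance outliers under the interquartile rule
      (outside ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` of the entries at the
      same bin distance);
    * singletons: the top ``singleton_percentile`` percent (default top
      0.1 percentile) of Z-scores.
    """
    if e is None:
        e = expected_by_distance(m)
    n = m.n_bins
    mask = _entry_mask(m) | (m.counts == 0)
    # per-distance IQR rule
    for d in range(n):
        rows = np.arange(n - d)
        cols = rows + d
        vals = m.counts[rows, cols]
        ok = ~mask[rows, cols]
        if ok.sum() >= 4:
            q1, q3 = np.percentile(vals[ok], [25, 75])
            iqr = q3 - q1
            out = (vals < q1 - iqr_factor * iqr) | (vals > q3 + iqr_factor * iqr)
            out &= ok
            mask[rows[out], cols[out]] = True
            mask[cols[out], rows[out]] = True
    # singleton rule on Z-scores
    z = zscore(m, e)
    finite = np.isfinite(z) & ~mask
    if finite.any():
        cut = np.percentile(z[finite], 100.0 - singleton_percentile)
        hot = finite & (z >= cut) & (z > 0)
        mask |= hot | hot.T
    return mask


def _corrected_distance(m: BinnedContactMatrix,
                        insertion: Optional[tuple]) -> np.ndarray:
    """Pairwise genomic distance (bp) between bin centres, adding the
    insertion length to pairs spanning the insertion point.

    ``insertion`` is ``(position, length)`` in this matrix's coordinate
    system: an ectopic sequence of ``length`` bp sits at ``position``,
    so loci on opposite sides are farther apart in that genome than the
    reference coordinates suggest.
    """
    centers = m.bin_starts + m.bin_size / 2
    d = np.abs(centers[:, None] - centers[None, :])
    if insertion is not None:
        pos, length = insertion
        left = centers < pos
        spans = left[:, None] != left[None, :]
        d = d + spans * float(length)
    return d


def distance_normalize(m: BinnedContactMatrix,
                       insertion: Optional[tuple] = None,
                       reference: Optional[ExpectedCurve] = None) -> np.ndarray:
    """Each entry divided by the expected contact count at its
    (insertion-corrected) genomic distance; NaN where undefined.

    ``reference`` supplies the expected curve to normalize against;
    by default the matrix's own curve is used.  When two maps are
    compared, both must be normalized against a *common* reference so
    that genuine fold differences between them survive normalization.
    """
    e = reference if reference is not None else expected_by_distance(m)
    dist_bp = _corrected_distance(m, insertion)
    d_grid = m.bin_size * np.arange(m.n_bins)
    good = np.isfinite(e.mean)
    exp = np.interp(dist_bp, d_grid[good], e.mean[good])
    with np.errstate(invalid="ignore", divide="ignore"):
        out = m.counts / exp
    out[~np.isfinite(out)] = np.nan
    return out


def bilinear_smooth(values: np.ndarray, mask: np.ndarray,
                    window: int = 2) -> np.ndarray:
    """Mean filter over a ``(2*window+1)``-square neighbourhood ignoring
    masked entries; masked entries stay NaN."""
    k = np.ones((2 * window + 1, 2 * window + 1))
    valid = (~mask & np.isfinite(values)).astype(float)
    filled = np.where(valid > 0, values, 0.0)
    num = convolve2d(filled, k, mode="same")
    den = convolve2d(valid, k, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[valid == 0] = np.nan
    return out


def differential_map(a: BinnedContactMatrix, b: BinnedContactMatrix,
                     insertion: Optional[tuple] = None,
                     window: int = 2) -> DifferentialMap:
    """Smoothed ratio a/b of distance-normalized, noise-filtered maps.

    ``insertion`` (position, length) corrects genomic distances in
    map ``a`` for an ectopic sequence present in its genome.  Both maps
    are normalized against the expected curve of ``b`` (the reference
    genome without the ectopic sequence), so global and local fold
    differences between the maps are preserved.  The ratio is computed
    on unmasked entries only, then bilinear-smoothed over a
    ``window``-bin neighbourhood; filtered entries remain NaN.
    """
    if (a.bin_size != b.bin_size or a.n_bins != b.n_bins
            or a.chrom != b.chrom or a.start != b.start):
        raise ValueError("matrices have incompatible geometries")
    ref = expected_by_distance(b)
    norm_a = distance_normalize(a, insertion, reference=ref)
    norm_b = distance_normalize(b, reference=ref)
    mask = filter_noise(a) | filter_noise(b)
    mask |= ~np.isfinite(norm_a) | ~np.isfinite(norm_b) | (norm_b == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = norm_a / norm_b
    smoothed = bilinear_smooth(ratio, mask, window)
    return DifferentialMap(smoothed, mask, window, insertion)


def boundary_drop(v: ViewpointProfile, boundary: int, flank: int = 3) -> float:
    """Fold change of mean contact probability across a TAD boundary:
    mean over ``flank`` bins on the anchor (inside) side divided by the
    mean over ``flank`` bins on the far side."""
    if not v.is_probability:
        raise ValueError("profile must be on the probability scale")
    if flank < 1:
        raise ValueError("flank must be >= 1")
    # classify bins by centre so a bin straddling the boundary goes to
    # the side holding most of it
    centers = v.bin_starts + v.bin_size / 2
    bbin = int(np.searchsorted(centers, boundary))
    if not (0 < bbin < v.values.size):
        raise ValueError("boundary outside profile")
    if v.anchor_bin < bbin:
        inside = v.values[max(0, bbin - flank):bbin]
        outside = v.values[bbin:bbin + flank]
    else:
        inside = v.values[bbin:bbin + flank]
        outside = v.values[max(0, bbin - flank):bbin]
    om = outside.mean()
    if om == 0:
        return float("inf")
    return float(inside.mean() / om)
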