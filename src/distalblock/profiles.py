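"""Binned density profiles, peak-normalized histograms and set comparison.

Features are binned into probability density functions with fixed bin widths
(5° for the angles φ, ψ, χ1; 0.05 Å for dBlock) on half-open bins anchored at
zero, so bin edges are reproducible across datasets.  A *normalized* pdf
(npdf) divides both curves of a two-set comparison by the peak density of the
designated reference set, so the reference peaks at exactly 1 and the other
curve is directly read as a peak-relative probability.  2D histograms are
normalized by their own modal cell; each cell value is then the population
ratio with respect to the most popular conformation.

Peak calling uses strict local maxima (plateau ties resolved to the leftmost
bin) with a prominence threshold expressed as a fraction of the global
maximum; the global maximum itself is always reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import EmptyProfileError, NormalizationError, UndefinedRatioError

__all__ = [
    "ANGLE_BIN_WIDTH",
    "LENGTH_BIN_WIDTH",
    "PDFProfile",
    "NormalizedPDF",
    "Hist2D",
    "Peak",
    "build_pdf",
    "normalize_by_reference",
    "build_hist2d",
    "find_peaks",
    "population_ratio",
    "interval_mass",
    "compare_sets",
    "FeatureComparison",
    "ComparisonReport",
    "ANGLE_FEATURES",
    "FEATURES",
]

ANGLE_BIN_WIDTH = 5.0
LENGTH_BIN_WIDTH = 0.05
ANGLE_FEATURES = ("phi", "psi", "chi1")
FEATURES = ANGLE_FEATURES + ("dblock",)

#: Default peak prominence threshold, as a fraction of the global maximum.
DEFAULT_PROMINENCE = 0.05
#: Minimum number of consecutive excess bins for an exceedance call.
DEFAULT_MIN_RUN = 2


@dataclass(frozen=True)
class PDFProfile:
    """1D binned probability density for one feature.

    ``edges`` has one more entry than ``counts``; bin *i* is the half-open
    interval [edges[i], edges[i+1]).  ``density`` is counts/(N·width), so the
    densities integrate to 1.
    """

    feature: str
    bin_width: float
    anchor: float
    edges: np.ndarray
    counts: np.ndarray
    n_total: int

    @property
    def density(self) -> np.ndarray:
        return self.counts / (self.n_total * self.bin_width)

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.centers, "count": self.counts,
                             "density": self.density})


@dataclass(frozen=True)
class NormalizedPDF:
    """A pdf rescaled by the peak density of a reference profile."""

    feature: str
    bin_width: float
    anchor: float
    edges: np.ndarray
    values: np.ndarray
    ref_id: str
    n_total: int

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.centers, "npdf": self.values})


@dataclass(frozen=True)
class Peak:
    center: float
    height: float


@dataclass(frozen=True)
class Hist2D:
    """2D histogram of two features, normalized by its own modal cell."""

    x_feature: str
    y_feature: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # shape (nx, ny), integer

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def ratio(self) -> np.ndarray:
        return self.counts / self.counts.max()

    @property
    def modal_cell(self) -> Tuple[int, int]:
        """Index of the most populated cell (leftmost-lowest on ties)."""
        flat = int(np.argmax(self.counts))
        return np.unravel_index(flat, self.counts.shape)

    def to_frame(self) -> pd.DataFrame:
        xc = (self.x_edges[:-1] + self.x_edges[1:]) / 2.0
        yc = (self.y_edges[:-1] + self.y_edges[1:]) / 2.0
        xi, yi = np.nonzero(self.counts)
        return pd.DataFrame({
            self.x_feature: xc[xi], self.y_feature: yc[yi],
            "count": self.counts[xi, yi], "ratio": self.ratio[xi, yi],
        })


def _grid_edges(values: np.ndarray, width: float, anchor: float,
                limits: Optional[Tuple[float, float]]) -> np.ndarray:
    """Bin edges anchored at ``anchor`` covering the data (or fixed limits)."""
    if limits is not None:
        lo, hi = limits
        i0 = int(np.floor((lo - anchor) / width))
        i1 = int(np.ceil((hi - anchor) / width)) - 1
    else:
        i0 = int(np.floor((values.min() - anchor) / width))
        i1 = int(np.floor((values.max() - anchor) / width))
    return anchor + width * np.arange(i0, i1 + 2)


def build_pdf(values: Sequence[float], bin_width: float, anchor: float = 0.0,
              feature: str = "", limits: Optional[Tuple[float, float]] = None
              ) -> PDFProfile:
    """Bin feature values into a :class:`PDFProfile`.

    ``values`` must be non-empty and free of missing entries.  Bins are
    half-open [edge, edge+width) anchored at ``anchor``; ``limits`` fixes the
    grid extent (e.g. (0, 360) for angles) independently of the data.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)] if arr.size else arr
    if arr.size == 0:
        raise EmptyProfileError(f"no observations to bin for {feature or 'feature'}")
    edges = _grid_edges(arr, bin_width, anchor, limits)
    counts, _ = np.histogram(arr, bins=edges)
    return PDFProfile(feature=feature, bin_width=bin_width, anchor=anchor,
                      edges=edges, counts=counts.astype(np.int64),
                      n_total=int(arr.size))


def _common_grid(a: PDFProfile, b: PDFProfile) -> np.ndarray:
    lo = min(a.edges[0], b.edges[0])
    hi = max(a.edges[-1], b.edges[-1])
    i0 = int(round((lo - a.anchor) / a.bin_width))
    i1 = int(round((hi - a.anchor) / a.bin_width))
    return a.anchor + a.bin_width * np.arange(i0, i1 + 1)


def _on_grid(profile: PDFProfile, edges: np.ndarray) -> np.ndarray:
    """Profile counts re-indexed onto a wider anchored grid."""
    out = np.zeros(edges.size - 1, dtype=np.int64)
    off = int(round((profile.edges[0] - edges[0]) / profile.bin_width))
    out[off:off + profile.counts.size] = profile.counts
    return out


def normalize_by_reference(target: PDFProfile, reference: PDFProfile,
                           ref_id: str = "reference"
                           ) -> Tuple[NormalizedPDF, NormalizedPDF]:
    """Divide BOTH pdfs by the reference's peak density.

    Returns ``(target_npdf, reference_npdf)`` on a common grid; the reference
    npdf has max exactly 1.  Profiles must share feature, bin width and
    anchor.
    """
    if (target.feature != reference.feature
            or target.bin_width != reference.bin_width
            or target.anchor != reference.anchor):
        raise ValueError("profiles must share feature, bin width and anchor")
    peak = float(reference.density.max())
    if peak <= 0:
        raise NormalizationError("reference profile has zero peak density")
    edges = _common_grid(target, reference)
    t_density = _on_grid(target, edges) / (target.n_total * target.bin_width)
    r_density = _on_grid(reference, edges) / (reference.n_total * reference.bin_width)
    mk = lambda d, n: NormalizedPDF(target.feature, target.bin_width,
                                    target.anchor, edges, d / peak, ref_id, n)
    return mk(t_density, target.n_total), mk(r_density, reference.n_total)


def build_hist2d(x_values: Sequence[float], y_values: Sequence[float],
                 x_feature: str = "phi", y_feature: str = "dblock",
                 x_width: float = ANGLE_BIN_WIDTH, y_width: float = LENGTH_BIN_WIDTH,
                 x_limits: Optional[Tuple[float, float]] = (0.0, 360.0),
                 y_limits: Optional[Tuple[float, float]] = None) -> Hist2D:
    """2D histogram of paired feature values, e.g. (φ, dBlock).

    Pairs with a missing value in either coordinate are dropped; an empty
    result raises :class:`EmptyProfileError`.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise EmptyProfileError("no complete observation pairs to bin")
    xe = _grid_edges(x, x_width, 0.0, x_limits)
    ye = _grid_edges(y, y_width, 0.0, y_limits)
    counts, _, _ = np.histogram2d(x, y, bins=(xe, ye))
    return Hist2D(x_feature, y_feature, xe, ye, counts.astype(np.int64))


def find_peaks(profile, min_prominence: float = DEFAULT_PROMINENCE) -> List[Peak]:
    """Local maxima of a profile, tallest first.

    A peak is a bin (or plateau of equal bins, reported at its leftmost bin
    center) strictly higher than both neighbors; profile boundaries count as
    lower neighbors.  Peaks must have prominence ≥ ``min_prominence`` times
    the global maximum, except that the global maximum itself is always
    reported — a flat profile therefore yields exactly one peak at its
    leftmost bin.
    """
    if isinstance(profile, NormalizedPDF):
        vals = profile.values
        centers = profile.centers
    elif isinstance(profile, PDFProfile):
        vals = profile.density
        centers = profile.centers
    else:
        vals = np.asarray(profile, dtype=float)
        centers = np.arange(vals.size, dtype=float)
    n = vals.size
    if n == 0:
        return []
    global_max = float(vals.max())
    peaks: List[Peak] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and vals[j + 1] == vals[i]:
            j += 1
        left_ok = i == 0 or vals[i - 1] < vals[i]
        right_ok = j == n - 1 or vals[j + 1] < vals[i]
        if left_ok and right_ok:
            h = float(vals[i])

            # base on each side: minimum between the peak and the nearest
            # strictly higher point (or the profile edge); a side with no
            # bins at all does not constrain the prominence
            def side_min(start: int, step: int) -> Optional[float]:
                m = None
                k = start
                while 0 <= k < n and vals[k] <= h:
                    m = float(vals[k]) if m is None else min(m, float(vals[k]))
                    k += step
                return m

            bases = [m for m in (side_min(i - 1, -1), side_min(j + 1, 1))
                     if m is not None]
            prominence = h - max(bases) if bases else h
            if h == global_max or prominence >= min_prominence * global_max:
                peaks.append(Peak(center=float(centers[i]), height=h))
        i = j + 1
    # tallest first; ties keep leftmost-first order
    peaks.sort(key=lambda p: (-p.height, p.center))
    return peaks


def population_ratio(hist: Hist2D, cell_a: Tuple[int, int],
                     cell_b: Optional[Tuple[int, int]] = None) -> float:
    """counts[a] / counts[b]; ``cell_b`` defaults to the modal cell.

    This is the population of one (φ, dBlock) cell relative to the most
    popular conformation.  Raises :class:`UndefinedRatioError` when the
    denominator cell is empty.
    """
    if cell_b is None:
        cell_b = hist.modal_cell
    denom = int(hist.counts[cell_b])
    if denom == 0:
        raise UndefinedRatioError(f"cell {cell_b} is empty")
    return float(hist.counts[cell_a]) / denom


def interval_mass(profile: PDFProfile, lo: float, hi: float) -> float:
    """Fraction of observations with feature value in (lo, hi].

    Bins fully inside the interval contribute their whole count; partial
    bins are split proportionally to their overlap.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    left = profile.edges[:-1]
    right = profile.edges[1:]
    overlap = np.clip(np.minimum(right, hi) - np.maximum(left, lo), 0.0, None)
    frac = overlap / profile.bin_width
    return float((frac * profile.counts).sum() / profile.n_total)


# ---------------------------------------------------------------------------
# two-set comparison
# ---------------------------------------------------------------------------

@dataclass
class FeatureComparison:
    feature: str
    npdf_a: NormalizedPDF
    npdf_b: NormalizedPDF
    peaks_a: List[Peak]
    peaks_b: List[Peak]


@dataclass
class ExceedanceInterval:
    """Contiguous dBlock range where set B's npdf exceeds set A's."""

    lo: float
    hi: float
    mass_a: float
    mass_b: float


@dataclass
class ComparisonReport:
    residue_type: str
    comparable: bool
    reason: str = ""
    features: Dict[str, FeatureComparison] = field(default_factory=dict)
    exceedance: List[ExceedanceInterval] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {"residue_type": self.residue_type, "comparable": self.comparable,
               "reason": self.reason, "features": {}, "exceedance": []}
        for name, fc in self.features.items():
            out["features"][name] = {
                "peaks_a": [[p.center, p.height] for p in fc.peaks_a],
                "peaks_b": [[p.center, p.height] for p in fc.peaks_b],
            }
        out["exceedance"] = [
            {"lo": e.lo, "hi": e.hi, "mass_a": e.mass_a, "mass_b": e.mass_b}
            for e in self.exceedance
        ]
        return out


def _feature_values(records: pd.DataFrame, feature: str) -> np.ndarray:
    vals = np.asarray(records[feature], dtype=float)
    return vals[~np.isnan(vals)]


def compare_sets(records_a: pd.DataFrame, records_b: pd.DataFrame,
                 residue_type: str,
                 angle_width: float = ANGLE_BIN_WIDTH,
                 length_width: float = LENGTH_BIN_WIDTH,
                 min_prominence: float = DEFAULT_PROMINENCE,
                 min_run: int = DEFAULT_MIN_RUN,
                 ref_id: str = "A") -> ComparisonReport:
    """Compare two record sets for one residue type, with A as reference.

    For each of the four features both sets are binned on a common anchored
    grid and normalized by A's peak density.  On dBlock, contiguous runs of
    at least ``min_run`` bins where B's npdf strictly exceeds A's are
    reported as exceedance intervals together with both sets' probability
    mass over the interval — the construct used to call regions where one
    set favors shorter side chains.
    """
    sub_a = records_a[records_a["res_type"] == residue_type]
    sub_b = records_b[records_b["res_type"] == residue_type]
    report = ComparisonReport(residue_type=residue_type, comparable=True)
    if len(sub_a) == 0 or len(sub_b) == 0:
        report.comparable = False
        report.reason = (f"residue type {residue_type} absent from "
                         f"{'set A' if len(sub_a) == 0 else 'set B'}")
        return report
    pdf_a_len = pdf_b_len = None
    for feature in FEATURES:
        va = _feature_values(sub_a, feature)
        vb = _feature_values(sub_b, feature)
        if va.size == 0 or vb.size == 0:
            continue
        if feature in ANGLE_FEATURES:
            width, limits = angle_width, (0.0, 360.0)
        else:
            width, limits = length_width, None
        pa = build_pdf(va, width, 0.0, feature, limits)
        pb = build_pdf(vb, width, 0.0, feature, limits)
        nb, na = normalize_by_reference(pb, pa, ref_id=ref_id)
        report.features[feature] = FeatureComparison(
            feature=feature, npdf_a=na, npdf_b=nb,
            peaks_a=find_peaks(na, min_prominence),
            peaks_b=find_peaks(nb, min_prominence),
        )
        if feature == "dblock":
            pdf_a_len, pdf_b_len = pa, pb
    if pdf_a_len is not None:
        fc = report.features["dblock"]
        diff = fc.npdf_b.values - fc.npdf_a.values
        edges = fc.npdf_a.edges
        n = diff.size
        i = 0
        while i < n:
            if diff[i] > 0:
                j = i
                while j + 1 < n and diff[j + 1] > 0:
                    j += 1
                if j - i + 1 >= min_run:
                    lo = float(edges[i])
                    hi = float(edges[j + 1])
                    report.exceedance.append(ExceedanceInterval(
                        lo=lo, hi=hi,
                        mass_a=interval_mass(pdf_a_len, lo, hi),
                        mass_b=interval_mass(pdf_b_len, lo, hi),
                    ))
                i = j + 1
            i += 1
    return report
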