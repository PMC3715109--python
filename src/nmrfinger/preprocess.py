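"""Spectral preprocessing: from raw spectra to the analysis-ready matrix.

The chain follows the procedure standard in urine NMR fingerprinting:
calibrate the ppm axis to the TMSP reference at 0.0,
truncate to 0.8-10.0 ppm, integrate 0.005-ppm bins, subtract a per-sample
baseline offset, normalize each spectrum to unit total area (removing
urine-dilution differences), apply the generalized log transform
g(x) = ln(x + sqrt(x^2 + lambda)) to stabilize variance, and mean-center
columns. Stage flags on the :class:`~nmrfinger.spectra.FeatureMatrix`
enforce the order; running a stage after a later one has been applied is
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .spectra import FeatureMatrix, RawSpectrum

DEFAULT_LO = 0.8
DEFAULT_HI = 10.0
DEFAULT_BIN_WIDTH = 0.005
DEFAULT_GLOG_LAMBDA = 1e-8


def calibrate_to_reference(
    s: RawSpectrum, ref_ppm: float = 0.0, search_halfwidth: float = 0.05
) -> RawSpectrum:
    """Shift the ppm axis so the reference peak sits exactly at ``ref_ppm``.

    The maximum-intensity point within ``ref_ppm +/- search_halfwidth`` is
    taken as the reference; ties break to the leftmost maximum.
    """
    s = s.ascending
    lo, hi = ref_ppm - search_halfwidth, ref_ppm + search_halfwidth
    if s.ppm[0] > lo or s.ppm[-1] < hi:
        raise ValueError(
            f"spectrum [{s.ppm[0]:.4g}, {s.ppm[-1]:.4g}] does not cover the "
            f"reference search window [{lo:.4g}, {hi:.4g}]"
        )
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    idx = np.flatnonzero(mask)
    window = s.intensity[idx]
    peak = idx[int(np.argmax(window))]  # argmax returns the leftmost maximum
    return s.shifted(ref_ppm - s.ppm[peak])


def truncate(
    s: RawSpectrum, lo: float = DEFAULT_LO, hi: float = DEFAULT_HI
) -> RawSpectrum:
    """Keep only points with lo <= ppm <= hi."""
    if lo >= hi:
        raise ValueError(f"lo ({lo}) must be < hi ({hi})")
    s = s.ascending
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    if mask.sum() < 2:
        raise ValueError(f"truncation to [{lo}, {hi}] leaves <2 points")
    return RawSpectrum(s.ppm[mask], s.intensity[mask], s.sample_id)


def bin_edges(lo: float, hi: float, width: float) -> np.ndarray:
    """Half-open bin grid [left, left+width) anchored at ``lo``."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    n = (hi - lo) / width
    n_bins = int(round(n))
    if abs(n - n_bins) > 1e-6 or n_bins < 1:
        raise ValueError(f"(hi - lo) = {hi - lo} is not a multiple of width {width}")
    edges = lo + np.arange(n_bins + 1) * width
    edges[-1] = hi  # close the last bin exactly at hi
    return edges


def bin_spectrum(
    s: RawSpectrum,
    width: float = DEFAULT_BIN_WIDTH,
    lo: float = DEFAULT_LO,
    hi: float = DEFAULT_HI,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate spectral area within each bin (trapezoidal rule).

    Returns ``(bin_centers, values)``. The integral of the piecewise-linear
    interpolant is computed exactly, so the bin values telescope to the
    whole-interval integral. A spectrum whose resolution is coarser than the
    bin width (leaving bins with no data point) is an error.
    """
    s = s.ascending
    edges = bin_edges(lo, hi, width)
    # tolerate missing coverage up to one grid step at either edge: after
    # calibration the sampling grid rarely lands exactly on lo/hi
    step = float(np.median(np.diff(s.ppm)))
    if s.ppm[0] > edges[0] + step or s.ppm[-1] < edges[-1] - step:
        raise ValueError(
            f"spectrum [{s.ppm[0]:.4g}, {s.ppm[-1]:.4g}] does not cover "
            f"the bin range [{lo}, {hi}]"
        )
    counts, _ = np.histogram(s.ppm, edges)
    empty = np.flatnonzero(counts == 0)
    if empty.size and step > width * (1 + 1e-9):
        centers = edges[empty] + width / 2
        shown = ", ".join(f"{c:.4f}" for c in centers[:5])
        more = "" if empty.size <= 5 else f" (+{empty.size - 5} more)"
        raise ValueError(
            f"spectrum resolution coarser than bin width: {empty.size} empty "
            f"bin(s) at ppm {shown}{more}"
        )
    cum = np.concatenate([[0.0], cumulative_trapezoid(s.intensity, s.ppm)])
    at_edges = np.interp(edges, s.ppm, cum)
    values = np.diff(at_edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, values


def assemble(
    rows: list[np.ndarray],
    bin_centers: np.ndarray,
    bin_width: float,
    sample_ids: list[str],
    extra_flags: tuple[str, ...] = (),
) -> FeatureMatrix:
    """Stack binned rows sharing one grid into a FeatureMatrix."""
    rows = [np.asarray(r, dtype=float) for r in rows]
    for r in rows:
        if r.shape != (len(bin_centers),):
            raise ValueError("all rows must share the bin grid")
    flags = frozenset({"binned", *extra_flags})
    return FeatureMatrix(np.vstack(rows), bin_centers, bin_width, list(sample_ids), flags)


def _require(m: FeatureMatrix, need: tuple[str, ...], forbid: tuple[str, ...],
             op: str) -> None:
    for stage in need:
        if not m.has_stage(stage):
            raise ValueError(f"{op} requires a {stage!r} matrix")
    for stage in forbid:
        if m.has_stage(stage):
            raise ValueError(f"{op} cannot be applied after {stage!r}")


def baseline_correct(m: FeatureMatrix, quantile: float = 0.01) -> FeatureMatrix:
    """Subtract a per-sample constant offset (a low quantile of bin values).

    Residual negatives (possible for bins below the quantile) are clipped
    to zero. All-zero rows pass through unchanged.
    """
    _require(m, ("binned",), ("baseline_corrected", "normalized", "glog", "centered"),
             "baseline_correct")
    offsets = np.quantile(m.values, quantile, axis=1, keepdims=True)
    out = np.clip(m.values - offsets, 0.0, None)
    zero_rows = ~np.any(m.values != 0.0, axis=1)
    out[zero_rows] = 0.0
    return m.with_values(out, add_stage="baseline_corrected")


def exclude_regions(
    m: FeatureMatrix, regions: tuple[tuple[float, float], ...]
) -> FeatureMatrix:
    """Zero out bins whose centers fall in any [lo, hi] ppm region.

    Intended for optional removal of solvent/urea artifacts before
    normalization; off by default throughout the package.
    """
    _require(m, ("binned",), ("normalized", "glog", "centered"), "exclude_regions")
    out = m.values.copy()
    for lo, hi in regions:
        out[:, (m.bin_centers >= lo) & (m.bin_centers <= hi)] = 0.0
    return m.with_values(out)


def normalize_total_area(m: FeatureMatrix) -> FeatureMatrix:
    """Divide each row by its total so every spectrum has unit area."""
    _require(m, ("binned", "baseline_corrected"), ("normalized", "glog", "centered"),
             "normalize_total_area")
    totals = m.values.sum(axis=1)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        ids = ", ".join(m.sample_ids[i] for i in bad[:5])
        raise ValueError(f"nonpositive total spectral area for sample(s): {ids}")
    return m.with_values(m.values / totals[:, None], add_stage="normalized")


def glog(x: np.ndarray, lambda_: float) -> np.ndarray:
    """Generalized log g(x) = ln(x + sqrt(x^2 + lambda))."""
    if lambda_ <= 0:
        raise ValueError("glog lambda must be positive")
    x = np.asarray(x, dtype=float)
    return np.log(x + np.sqrt(x * x + lambda_))


def glog_transform(
    m: FeatureMatrix, lambda_: float = DEFAULT_GLOG_LAMBDA
) -> FeatureMatrix:
    """Apply the generalized log transform elementwise."""
    _require(m, ("binned", "normalized"), ("glog", "centered"), "glog_transform")
    return m.with_values(glog(m.values, lambda_), add_stage="glog")


def center(m: FeatureMatrix) -> FeatureMatrix:
    """Subtract per-column means, storing them for held-out projection."""
    _require(m, ("binned",), ("centered",), "center")
    means = m.values.mean(axis=0)
    return m.with_values(m.values - means, add_stage="centered", column_means=means)


def assemble_and_center(
    rows: list[np.ndarray],
    bin_centers: np.ndarray,
    bin_width: float,
    sample_ids: list[str],
) -> FeatureMatrix:
    """Stack binned rows and mean-center the columns in one step."""
    return center(assemble(rows, bin_centers, bin_width, sample_ids))


def project_centered(m: FeatureMatrix, row: np.ndarray) -> np.ndarray:
    """Project a held-out binned row using the stored training column means."""
    if m.column_means is None:
        raise ValueError("matrix has no stored column means; center() it first")
    return np.asarray(row, dtype=float) - m.column_means


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the full preprocessing chain."""

    ref_ppm: float = 0.0
    search_halfwidth: float = 0.05
    calibrate: bool = True
    lo: float = DEFAULT_LO
    hi: float = DEFAULT_HI
    bin_width: float = DEFAULT_BIN_WIDTH
    baseline_quantile: float = 0.01
    glog_lambda: float = DEFAULT_GLOG_LAMBDA
    exclude: tuple[tuple[float, float], ...] = field(default_factory=tuple)
    do_center: bool = False


def preprocess_spectra(
    spectra: list[RawSpectrum], params: PreprocessParams | None = None
) -> FeatureMatrix:
    """Run the full chain on a list of spectra.

    Centering is off by default: analyses that cross-validate must center
    on training folds only, so they receive the uncentered glog matrix.
    """
    params = params or PreprocessParams()
    rows = []
    ids = []
    centers = None
    flags: tuple[str, ...] = ("truncated",)
    if params.calibrate:
        flags = ("calibrated", "truncated")
    for s in spectra:
        if params.calibrate:
            s = calibrate_to_reference(s, params.ref_ppm, params.search_halfwidth)
        s = truncate(s, params.lo, params.hi)
        c, v = bin_spectrum(s, params.bin_width, params.lo, params.hi)
        if centers is None:
            centers = c
        rows.append(v)
        ids.append(s.sample_id)
    m = assemble(rows, centers, params.bin_width, ids, extra_flags=flags)
    m = baseline_correct(m, params.baseline_quantile)
    if params.exclude:
        m = exclude_regions(m, params.exclude)
    m = normalize_total_area(m)
    m = glog_transform(m, params.glog_lambda)
    if params.do_center:
        m = center(m)
    return m
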