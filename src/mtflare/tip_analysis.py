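"""Shape metrics for protofilament traces.

Works identically on simulated tips (PF polylines projected into
their radial planes) and on externally supplied trace files, e.g.
cryoET-derived contours: LOESS smoothing, curl-origin detection, curl
length and mean curvature, per-MT raggedness (the standard deviation
of curl-origin axial positions), Spearman correlations between
adjacent PFs, and a synthetic fixture generator with known ground
truth.

Trace file format: tab-separated columns
``mt_id  pf_index  point_index  z_nm  x_nm`` with a commented header;
missing PFs are simply absent (partial rings, e.g. from the cryoET
missing wedge, are fine).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

N_PF = 13

#: radial deviation (nm) beyond which a PF is considered off the wall
DEFAULT_WALL_TOLERANCE = 1.5


@dataclass
class PFTrace:
    """Ordered 2D polyline of one PF: points (axial z, radial x) in nm,
    minus-to-plus order."""

    mt_id: int
    pf_index: int
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")
        if self.points.shape[0] < 2:
            raise ValueError("a trace needs at least 2 points")
        if not (0 <= self.pf_index < N_PF):
            raise ValueError("pf_index must be in 0..12")

    def arc_length(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class CurlOrigin:
    origin_z: float
    index: int        # first trace point inside the curl (= len-1 if blunt)
    blunt: bool
    crossing_z: float = 0.0   # where |x| first exceeds the tolerance
    ds_back: float = 0.0      # contour length between origin and crossing


@dataclass
class TipMetrics:
    """Per-MT summary of curl geometry."""

    mt_id: int
    pf_index: np.ndarray
    origin_z: np.ndarray
    curl_length: np.ndarray
    curvature: np.ndarray  # rad/nm; nan for blunt PFs

    @property
    def n_pf(self) -> int:
        return self.pf_index.size


def smooth_trace(trace: PFTrace, span: float = 0.25) -> PFTrace:
    """LOESS smoothing of the trace against its arc-length parameter.

    Both coordinates are locally regressed on arc length (a noisy
    axial coordinate distorts contour lengths and tangent headings as
    much as a noisy radial one).  span is the lowess fraction;
    endpoints are retained so curl extent is not shortened, and
    already-smooth traces pass through nearly unchanged.
    """
    n = trace.points.shape[0]
    if n < 4:
        raise ValueError("need >= 4 points to smooth")
    s = trace.arc_length()
    out = trace.points.copy()
    for c in (0, 1):
        sm = lowess(trace.points[:, c], s, frac=span, it=1,
                    return_sorted=False)
        out[1:-1, c] = sm[1:-1]
    return PFTrace(trace.mt_id, trace.pf_index, out)


def _curl_points(trace: PFTrace, index: int, crossing_z: float
                 ) -> np.ndarray:
    """Curl polyline starting at the interpolated tolerance crossing."""
    pts = trace.points[index:]
    if index > 0:
        p0 = trace.points[index - 1]
        p1 = trace.points[index]
        t = 0.0 if p1[0] == p0[0] else (crossing_z - p0[0]) / (p1[0] - p0[0])
        pts = np.vstack([p0 + t * (p1 - p0), pts])
    return pts


def _heading_fit(pts: np.ndarray):
    """Turning-rate fit over a polyline.

    Chord headings (unwrapped, relative to the axial direction) are
    regressed on mid-chord arc position, weighted by chord length:
    the slope magnitude is the mean curvature of an ideal arc and is
    robust to point noise; the intercept gives the heading at the
    polyline start.  Returns (kappa_signed, theta_start, total_len).
    """
    seg = np.diff(pts, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    keep = lens > 1e-12
    total = float(lens.sum())
    if keep.sum() < 2:
        return 0.0, 0.0, total
    ang = np.unwrap(np.arctan2(seg[keep, 1], seg[keep, 0]))
    s_mid = np.concatenate([[0.0], np.cumsum(lens)])[:-1][keep] \
        + 0.5 * lens[keep]
    w = lens[keep]
    sw = np.sum(w)
    sm = np.sum(w * s_mid) / sw
    am = np.sum(w * ang) / sw
    var = np.sum(w * (s_mid - sm) ** 2)
    if var <= 0:
        return 0.0, float(am), total
    slope = float(np.sum(w * (s_mid - sm) * (ang - am)) / var)
    theta0 = float(am - slope * sm)
    return slope, theta0, total


def curl_origin(trace: PFTrace,
                wall_tolerance: float = DEFAULT_WALL_TOLERANCE) -> CurlOrigin:
    """Axial position where the PF departs the cylindrical wall.

    Detection is two-stage: (1) scan backward from the tip while |x|
    stays above wall_tolerance and interpolate the tolerance crossing;
    (2) extrapolate back along the fitted curl geometry to the point
    where the tangent was parallel to the wall (heading zero), which
    removes the tolerance-dependent offset.  Traces that never leave
    the wall are blunt: origin = trace end, curl length 0.
    """
    z = trace.points[:, 0]
    xabs = np.abs(trace.points[:, 1])
    n = z.size
    i = n - 1
    while i >= 0 and xabs[i] > wall_tolerance:
        i -= 1
    if i == n - 1:
        return CurlOrigin(float(z[-1]), n - 1, True, float(z[-1]), 0.0)
    if i < 0:
        return CurlOrigin(float(z[0]), 0, False, float(z[0]), 0.0)
    x0, x1 = xabs[i], xabs[i + 1]
    f = 0.0 if x1 == x0 else (wall_tolerance - x0) / (x1 - x0)
    crossing_z = float(z[i] + f * (z[i + 1] - z[i]))
    pts = _curl_points(trace, i + 1, crossing_z)
    kappa, theta_c, _ = _heading_fit(pts)
    origin_z, ds_back = crossing_z, 0.0
    theta_c = abs(theta_c)
    if theta_c > 0.05:
        # arc back to zero heading; 2*tol/theta_c follows from
        # tol ~ theta_c * ds / 2 for a near-tangential departure and
        # is far less sensitive to the fitted curvature than theta/kappa
        ds = 2.0 * wall_tolerance / theta_c
        ds_cap = 1.5 * math.sqrt(2.0 * wall_tolerance
                                 / max(abs(kappa), 1e-3))
        ds = min(ds, ds_cap)
        dz = ds * math.sin(theta_c) / theta_c    # axial projection
        dz_max = max(0.0, crossing_z - float(z[0]))
        if dz > dz_max:
            ds *= dz_max / dz if dz > 0 else 0.0
            dz = dz_max
        origin_z = crossing_z - dz
        ds_back = ds
    return CurlOrigin(origin_z, i + 1, False, crossing_z, ds_back)


def curl_metrics(trace: PFTrace, origin: CurlOrigin
                 ) -> Tuple[float, float]:
    """(contour length nm, mean curvature rad/nm) of the curl.

    Length is the contour length from the origin to the tip
    (including the back-extrapolated stretch between the origin and
    the tolerance crossing); mean curvature is the turning of the
    tangent per unit contour length, estimated by the weighted
    heading-vs-arc-length fit, which equals total turn / length for
    an ideal arc.  Blunt traces give (0, nan).
    """
    if origin.blunt:
        return 0.0, float("nan")
    pts = _curl_points(trace, origin.index, origin.crossing_z)
    kappa, _, total_len = _heading_fit(pts)
    total_len += origin.ds_back
    if total_len == 0:
        return 0.0, float("nan")
    # signed turning rate: positive curls bend outward (+x); keeping
    # the sign avoids the folding bias of |noisy slope| when averaging
    return total_len, kappa


def analyze_tip(traces: Sequence[PFTrace],
                wall_tolerance: float = DEFAULT_WALL_TOLERANCE,
                span: Optional[float] = None) -> TipMetrics:
    """Per-PF curl origin/length/curvature for one MT's traces."""
    if not traces:
        raise ValueError("no traces given")
    pf, oz, cl, cv = [], [], [], []
    for tr in traces:
        if span is not None and tr.points.shape[0] >= 4:
            tr = smooth_trace(tr, span)
        o = curl_origin(tr, wall_tolerance)
        length, curv = curl_metrics(tr, o)
        pf.append(tr.pf_index)
        oz.append(o.origin_z)
        cl.append(length)
        cv.append(curv)
    return TipMetrics(traces[0].mt_id, np.array(pf), np.array(oz),
                      np.array(cl), np.array(cv))


def raggedness(tip: TipMetrics) -> float:
    """Standard deviation (n-1 denominator) of curl-origin axial
    positions across the scored PFs of one MT."""
    if tip.n_pf < 2:
        raise ValueError("raggedness needs >= 2 scored PFs")
    return float(np.std(tip.origin_z, ddof=1))


@dataclass
class CorrelationResult:
    r_s: float
    p_value: float
    n_pairs: int
    all_tied: bool = False


def neighbor_correlation(tips: Iterable[TipMetrics],
                         metric: str = "length",
                         min_pairs: int = 10) -> CorrelationResult:
    """Spearman rank correlation between adjacent PFs (pf_index mod 13)
    pooled across MTs; ties mid-ranked, p from the large-sample
    approximation."""
    if metric not in ("length", "curvature"):
        raise ValueError("metric must be 'length' or 'curvature'")
    a_vals, b_vals = [], []
    for tip in tips:
        vals = {int(p): (tip.curl_length[i] if metric == "length"
                         else tip.curvature[i])
                for i, p in enumerate(tip.pf_index)}
        for p, v in vals.items():
            q = (p + 1) % N_PF
            if q in vals and np.isfinite(v) and np.isfinite(vals[q]):
                a_vals.append(v)
                b_vals.append(vals[q])
    if len(a_vals) < min_pairs:
        raise ValueError(f"need >= {min_pairs} adjacent pairs, "
                         f"got {len(a_vals)}")
    a = np.asarray(a_vals)
    b = np.asarray(b_vals)
    if np.all(a == a[0]) or np.all(b == b[0]):
        return CorrelationResult(float("nan"), float("nan"), a.size, True)
    r, p = stats.spearmanr(a, b)
    return CorrelationResult(float(r), float(p), a.size)


# ---------------------------------------------------------------------------
# trace file I/O


def write_traces(path, traces: Sequence[PFTrace]) -> None:
    rows = []
    for tr in traces:
        for i, (z, x) in enumerate(tr.points):
            rows.append((tr.mt_id, tr.pf_index, i, z, x))
    df = pd.DataFrame(rows, columns=["mt_id", "pf_index", "point_index",
                                     "z_nm", "x_nm"])
    with open(path, "w") as fh:
        fh.write("# mt_id\tpf_index\tpoint_index\tz_nm\tx_nm\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_traces(path) -> List[PFTrace]:
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["mt_id", "pf_index", "point_index",
                            "z_nm", "x_nm"])
    traces = []
    for (mt, pf), grp in df.groupby(["mt_id", "pf_index"], sort=True):
        grp = grp.sort_values("point_index")
        traces.append(PFTrace(int(mt), int(pf),
                              grp[["z_nm", "x_nm"]].to_numpy()))
    return traces


def group_by_mt(traces: Sequence[PFTrace]) -> Dict[int, List[PFTrace]]:
    out: Dict[int, List[PFTrace]] = {}
    for tr in traces:
        out.setdefault(tr.mt_id, []).append(tr)
    return out


# ---------------------------------------------------------------------------
# synthetic fixtures


@dataclass
class FixtureSpec:
    """Ground truth for synthetic trace generation.

    Each PF trace is a straight wall section followed by a circular
    arc of the given curvature and contour length; curl origins are
    drawn around wall_length with the given spread.
    """

    n_mt: int = 10
    pf_per_mt: int = 8
    curvature: float = 0.04      # rad/nm
    curl_length: float = 30.0    # nm
    wall_length: float = 60.0    # nm
    origin_spread: float = 6.0   # nm (sd of curl origins)
    noise: float = 0.0           # nm, isotropic point noise
    point_spacing: float = 2.0   # nm


def make_fixture_traces(spec: FixtureSpec, seed: int = 0,
                        path=None) -> Tuple[List[PFTrace], pd.DataFrame]:
    """Generate traces with known curvature/length/raggedness.

    Returns (traces, truth table); optionally writes the trace file
    (and a sidecar .truth.tsv) so tests can round-trip the reader.
    """
    rng = np.random.default_rng(seed)
    traces: List[PFTrace] = []
    truth_rows = []
    for mt in range(spec.n_mt):
        for pf in range(spec.pf_per_mt):
            origin = spec.wall_length + rng.normal(0.0, spec.origin_spread)
            n_wall = max(2, int(origin / spec.point_spacing))
            z_wall = np.linspace(0.0, origin, n_wall, endpoint=False)
            pts = [np.column_stack([z_wall, np.zeros(n_wall)])]
            n_curl = max(2, int(round(spec.curl_length / spec.point_spacing)))
            s = np.linspace(0.0, spec.curl_length, n_curl + 1)[1:]
            kappa = spec.curvature
            if kappa > 0:
                r = 1.0 / kappa
                ang = s * kappa
                zc = origin + r * np.sin(ang)
                xc = r * (1.0 - np.cos(ang))
            else:
                zc = origin + s
                xc = np.zeros_like(s)
            pts.append(np.column_stack([zc, xc]))
            p = np.vstack(pts)
            if spec.noise > 0:
                p = p + rng.normal(0.0, spec.noise, p.shape)
            traces.append(PFTrace(mt, pf, p))
            truth_rows.append((mt, pf, origin, spec.curl_length,
                               spec.curvature))
    truth = pd.DataFrame(truth_rows, columns=["mt_id", "pf_index",
                                              "origin_z", "curl_length",
                                              "curvature"])
    if path is not None:
        write_traces(path, traces)
        truth.to_csv(str(path) + ".truth.tsv", sep="\t", index=False)
    return traces, truth


def summarize(traces: Sequence[PFTrace],
              wall_tolerance: float = DEFAULT_WALL_TOLERANCE,
              span: Optional[float] = 0.25) -> pd.DataFrame:
    """Per-MT summary table: mean curl length/curvature, raggedness, n."""
    rows = []
    for mt, trs in group_by_mt(traces).items():
        tip = analyze_tip(trs, wall_tolerance, span)
        rows.append({
            "mt_id": mt,
            "n_pf": tip.n_pf,
            "mean_curl_length": float(np.nanmean(tip.curl_length)),
            "mean_curvature": float(np.nanmean(tip.curvature)),
            "raggedness": raggedness(tip) if tip.n_pf >= 2 else np.nan,
        })
    return pd.DataFrame(rows)
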