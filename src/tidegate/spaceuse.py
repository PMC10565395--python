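"""Movement tracks and water-masked dynamic Brownian bridge space use.

Gate-array detections give positions only at receiver coordinates.  Tracks
are reconstructed with the study's rules: consecutive detections at
*different* receivers joined when separated by at least 5 min and at most
24 h; a silence longer than 24 h starts a new track; a gap under 5 min
between different receivers is treated as implausible transit and also
breaks the track; runs at a single receiver collapse to their first and
last fixes and contribute stationary occupancy rather than bridges.

The utilization distribution integrates, over each track:

* stationary segments (same position at both ends): the animal's location is
  a single point observed with error delta, so the segment contributes a
  circular Gaussian N(p, delta^2 I) weighted by its duration;
* moving bridges a->b over duration T: at fractional time tau the position
  is Gaussian with mean a + tau (b - a) and variance
  tau (1 - tau) T sigma_m^2 + (1 - tau)^2 delta^2 + tau^2 delta^2,
  time-integrated over the bridge and weighted by T.  The motion variance
  sigma_m^2 is estimated per sliding window by the leave-one-out bridge
  likelihood of interior fixes (the dynamic-BBMM estimator).

When a bridge chord crosses land the bridge is decomposed along the
shortest in-water path (visibility graph over the water polygon's
vertices), with time allocated to sub-bridges by path-length fraction.
Finally the accumulated density is masked to water cells and renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import shapely
from scipy.optimize import minimize_scalar
from shapely.geometry import LineString

__all__ = [
    "Track",
    "UtilizationDistribution",
    "ContourResult",
    "build_tracks",
    "motion_variance",
    "dbbmm_ud",
    "contour",
    "overlap",
    "in_water_path",
]

MIN_GAP_S = 300.0  # 5 min
MAX_GAP_S = 86400.0  # 24 h


@dataclass
class Track:
    tag_id: str
    times: np.ndarray  # seconds (float), strictly increasing
    xy: np.ndarray  # (n, 2) receiver positions, metres
    receivers: list

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if len(self.times) != len(self.xy):
            raise ValueError("times and positions length mismatch")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("track times must be strictly increasing")

    def __len__(self):
        return len(self.times)


def build_tracks(
    det: pd.DataFrame,
    receivers,
    min_gap: float = MIN_GAP_S,
    max_gap: float = MAX_GAP_S,
) -> list[Track]:
    """Reconstruct per-tag tracks from detections and receiver positions."""
    pos = {r.receiver_id: np.array([r.x, r.y], float) for r in receivers}
    tracks = []
    for tag, grp in det.groupby("tag_id", sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort")
        t = grp["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64) / 1e9
        rec = grp["receiver_id"].to_numpy()
        # split at long silences and at implausibly fast receiver switches
        cut = [0]
        for i in range(1, len(t)):
            gap = t[i] - t[i - 1]
            if gap > max_gap or (rec[i] != rec[i - 1] and gap < min_gap):
                cut.append(i)
        cut.append(len(t))
        for a, b in zip(cut, cut[1:]):
            tt, rr = t[a:b], rec[a:b]
            # collapse same-receiver runs to first/last fixes
            keep_t, keep_r = [], []
            i = 0
            while i < len(tt):
                j = i
                while j + 1 < len(tt) and rr[j + 1] == rr[i]:
                    j += 1
                keep_t.append(tt[i])
                keep_r.append(rr[i])
                if j > i:
                    keep_t.append(tt[j])
                    keep_r.append(rr[j])
                i = j + 1
            keep_t = np.array(keep_t)
            # de-duplicate identical consecutive times
            ok = np.concatenate([[True], np.diff(keep_t) > 0])
            keep_t = keep_t[ok]
            keep_r = [r for r, o in zip(keep_r, ok) if o]
            if len(keep_t) == 0:
                continue
            tracks.append(
                Track(
                    tag_id=str(tag),
                    times=keep_t,
                    xy=np.array([pos[r] for r in keep_r]),
                    receivers=list(keep_r),
                )
            )
    return tracks


# ---------------------------------------------------------------------------
# motion variance (dynamic estimator)


def _window_neg_loglik(log_s2, times, xy, err2):
    s2 = np.exp(log_s2)
    nll = 0.0
    for i in range(1, len(times) - 1):
        T = times[i + 1] - times[i - 1]
        if T <= 0:
            continue
        a = (times[i] - times[i - 1]) / T
        mu = xy[i - 1] + a * (xy[i + 1] - xy[i - 1])
        var = a * (1 - a) * T * s2 + (1 - a) ** 2 * err2 + a**2 * err2
        var = max(var, 1e-12)
        d2 = np.sum((xy[i] - mu) ** 2)
        nll += np.log(2 * np.pi * var) + d2 / (2 * var)
    return nll


def _window_mle(times, xy, err2) -> float:
    res = minimize_scalar(
        _window_neg_loglik,
        bounds=(-12.0, 18.0),
        args=(times, xy, err2),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def motion_variance(
    track: Track,
    window: int = 31,
    margin: int = 11,
    location_error: float = 0.0,
) -> np.ndarray:
    """Per-fix Brownian motion variance sigma_m^2 (m^2/s), sliding-window MLE.

    Windows of ``window`` fixes slide along the track; each window's
    leave-one-out MLE is assigned to its central fix, and the first/last
    ``margin`` fixes inherit the nearest estimate.  Tracks shorter than the
    window fall back to a single track-wide MLE.
    """
    if window < 2 * margin + 1:
        raise ValueError("window must be >= 2*margin + 1")
    if window % 2 == 0:
        raise ValueError("window must be an odd number of fixes")
    n = len(track)
    err2 = float(location_error) ** 2
    if n < 3:
        return np.zeros(n)
    if n < window:
        return np.full(n, _window_mle(track.times, track.xy, err2))
    out = np.full(n, np.nan)
    half = window // 2
    for c in range(half, n - half):
        sl = slice(c - half, c + half + 1)
        out[c] = _window_mle(track.times[sl], track.xy[sl], err2)
    # margins inherit the nearest interior estimate
    out[:half] = out[half]
    out[n - half :] = out[n - half - 1]
    return out


# ---------------------------------------------------------------------------
# in-water routing


_graph_cache: dict = {}


def _water_graph(water):
    key = id(water)
    if key not in _graph_cache:
        verts = list(water.exterior.coords[:-1])
        for ring in water.interiors:
            verts += list(ring.coords[:-1])
        hull = water.buffer(1e-6)
        G = nx.Graph()
        for i, v in enumerate(verts):
            G.add_node(i, xy=np.array(v))
        for i in range(len(verts)):
            for j in range(i + 1, len(verts)):
                seg = LineString([verts[i], verts[j]])
                if hull.covers(seg):
                    G.add_edge(i, j, weight=seg.length)
        _graph_cache[key] = (G, verts, hull)
    return _graph_cache[key]


def in_water_path(a, b, water) -> np.ndarray:
    """Shortest polyline from a to b staying inside the water polygon."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    seg = LineString([a, b])
    hull = water.buffer(1e-6)
    if hull.covers(seg):
        return np.array([a, b])
    G, verts, hull = _water_graph(water)
    G = G.copy()
    for name, p in (("src", a), ("dst", b)):
        G.add_node(name, xy=p)
        for i, v in enumerate(verts):
            s = LineString([p, v])
            if hull.covers(s):
                G.add_edge(name, i, weight=s.length)
    direct = LineString([a, b])
    if hull.covers(direct):
        G.add_edge("src", "dst", weight=direct.length)
    try:
        nodes = nx.shortest_path(G, "src", "dst", weight="weight")
    except nx.NetworkXNoPath as e:
        raise ValueError("no in-water path between fixes; check the polygon") from e
    return np.array([G.nodes[n]["xy"] for n in nodes])


# ---------------------------------------------------------------------------
# utilization distribution


@dataclass
class UtilizationDistribution:
    xs: np.ndarray  # cell-centre x (m)
    ys: np.ndarray  # cell-centre y (m)
    cell: float  # cell side (m)
    probs: np.ndarray  # (ny, nx), sums to 1 over water
    water_mask: np.ndarray  # (ny, nx) bool

    @property
    def cell_area(self) -> float:
        return self.cell**2


@dataclass
class ContourResult:
    level: float
    area: float  # m^2
    mask: np.ndarray  # (ny, nx) bool member cells
    mass: float

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def _add_gaussian(acc, xs, ys, center, var, weight):
    if weight <= 0 or var <= 0:
        return
    sd = np.sqrt(var)
    x0, y0 = center
    ix = np.searchsorted(xs, [x0 - 5 * sd, x0 + 5 * sd])
    iy = np.searchsorted(ys, [y0 - 5 * sd, y0 + 5 * sd])
    sx = slice(max(ix[0] - 1, 0), min(ix[1] + 1, len(xs)))
    sy = slice(max(iy[0] - 1, 0), min(iy[1] + 1, len(ys)))
    if sx.stop <= sx.start or sy.stop <= sy.start:
        return
    gx = np.exp(-((xs[sx] - x0) ** 2) / (2 * var))
    gy = np.exp(-((ys[sy] - y0) ** 2) / (2 * var))
    acc[sy, sx] += (weight / (2 * np.pi * var)) * np.outer(gy, gx)


def dbbmm_ud(
    tracks: list[Track],
    water=None,
    cell: float = 50.0,
    location_error: float = 200.0,
    window: int = 31,
    margin: int = 11,
    sigma2: float | np.ndarray | None = None,
    time_substeps: int | None = None,
    bounds: tuple | None = None,
) -> UtilizationDistribution:
    """Dynamic Brownian bridge utilization distribution on a water-masked grid.

    ``sigma2`` overrides the per-fix motion-variance estimate (useful for
    oracle checks); ``bounds`` is (xmin, ymin, xmax, ymax) and defaults to
    the water polygon's envelope, or the track envelope padded by 5 * delta.
    """
    if isinstance(tracks, Track):
        tracks = [tracks]
    if not tracks:
        raise ValueError("no tracks")
    err2 = float(location_error) ** 2
    if bounds is None:
        if water is not None:
            bounds = water.bounds
        else:
            allxy = np.concatenate([t.xy for t in tracks])
            pad = 5 * max(location_error, cell)
            bounds = (
                allxy[:, 0].min() - pad,
                allxy[:, 1].min() - pad,
                allxy[:, 0].max() + pad,
                allxy[:, 1].max() + pad,
            )
    xmin, ymin, xmax, ymax = bounds
    xs = np.arange(xmin + cell / 2, xmax, cell)
    ys = np.arange(ymin + cell / 2, ymax, cell)
    acc = np.zeros((len(ys), len(xs)))

    total_weight = 0.0
    for track in tracks:
        if len(track) < 2:
            # no elapsed time: a lone fix contributes its location error only
            _add_gaussian(acc, xs, ys, track.xy[0], err2, 1.0)
            total_weight += 1.0
            continue
        if sigma2 is None:
            s2 = motion_variance(
                track, window=window, margin=margin, location_error=location_error
            )
        else:
            s2 = np.broadcast_to(np.asarray(sigma2, float), (len(track),)).copy()
        for i in range(len(track) - 1):
            a, b = track.xy[i], track.xy[i + 1]
            T = track.times[i + 1] - track.times[i]
            if T <= 0:
                continue
            seg_s2 = 0.5 * (s2[i] + s2[i + 1])
            if np.allclose(a, b):
                _add_gaussian(acc, xs, ys, a, err2, T)
                total_weight += T
                continue
            path = (
                np.array([a, b]) if water is None else in_water_path(a, b, water)
            )
            seg_len = np.linalg.norm(np.diff(path, axis=0), axis=1)
            fracs = seg_len / seg_len.sum()
            for k in range(len(path) - 1):
                pa, pb = path[k], path[k + 1]
                Tk = T * fracs[k]
                if Tk <= 0:
                    continue
                if time_substeps is None:
                    # enough substeps that adjacent kernels overlap: spacing
                    # no wider than half the narrowest bridge width
                    min_sd = np.sqrt(err2 / 2.0) if err2 > 0 else cell
                    n_sub = int(
                        np.clip(
                            np.ceil(np.linalg.norm(pb - pa) / (0.5 * min_sd)), 10, 400
                        )
                    )
                else:
                    n_sub = time_substeps
                for j in range(n_sub):
                    tau = (j + 0.5) / n_sub
                    mu = pa + tau * (pb - pa)
                    var = (
                        tau * (1 - tau) * Tk * seg_s2
                        + (1 - tau) ** 2 * err2
                        + tau**2 * err2
                    )
                    _add_gaussian(acc, xs, ys, mu, var, Tk / n_sub)
                total_weight += Tk

    if water is not None:
        XX, YY = np.meshgrid(xs, ys)
        mask = shapely.contains_xy(water.buffer(1e-9), XX.ravel(), YY.ravel()).reshape(
            acc.shape
        )
    else:
        mask = np.ones(acc.shape, dtype=bool)
    acc[~mask] = 0.0
    total = acc.sum()
    if total <= 0:
        raise ValueError("utilization distribution has no mass on water cells")
    return UtilizationDistribution(
        xs=xs, ys=ys, cell=cell, probs=acc / total, water_mask=mask
    )


def contour(ud: UtilizationDistribution, level: float = 0.5) -> ContourResult:
    """Smallest highest-density cell set holding >= ``level`` of the mass.

    Ties in cell density are broken by flat cell index for determinism.
    """
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    flat = ud.probs.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level - 1e-12) + 1)
    k = min(k, int((flat > 0).sum())) if level >= 1 else k
    members = order[:k]
    mask = np.zeros(flat.size, dtype=bool)
    mask[members] = True
    mask = mask.reshape(ud.probs.shape)
    return ContourResult(
        level=level,
        area=float(k * ud.cell_area),
        mask=mask,
        mass=float(csum[k - 1]),
    )


def overlap(a: ContourResult, b: ContourResult, cell_area: float) -> tuple[float, float]:
    """Directed contour overlaps in percent: (share of a in b, share of b in a)."""
    inter = float((a.mask & b.mask).sum() * cell_area)
    pa = 100.0 * inter / a.area if a.area > 0 else 0.0
    pb = 100.0 * inter / b.area if b.area > 0 else 0.0
    return pa, pb
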