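"""Trajectory-level analyses of sampled activation spaces.

Sampled points of the stacked polytope are reshaped into trajectories
(trajectory x time x muscle), differentiated into activation-contraction
speeds, filtered by rate limits, and summarised.  The seeded/unseeded
comparison projects each time slice onto the first two principal
components of the *unseeded* distribution and reports the ratio of the
seeded to the unseeded convex-hull area — the fraction of the feasible
space still reachable once a starting activation has been committed to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.decomposition import PCA

from .constraints import Seed
from .exceptions import FormatError
from .model import SampleStore


@dataclass
class TrajectorySet:
    """Activation trajectories as an (n_traj, T, n_muscles) tensor."""

    data: np.ndarray
    muscle_names: tuple
    times: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise FormatError("trajectory tensor must be 3-D")
        n, T, M = self.data.shape
        self.muscle_names = tuple(self.muscle_names)
        self.times = tuple(int(t) for t in self.times)
        if len(self.muscle_names) != M or len(self.times) != T:
            raise FormatError("trajectory labels do not match tensor shape")

    @property
    def n_traj(self) -> int:
        return self.data.shape[0]

    @property
    def n_steps(self) -> int:
        return self.data.shape[1]

    @property
    def n_muscles(self) -> int:
        return self.data.shape[2]


@dataclass
class SpeedSet:
    """First differences of trajectories: (n_traj, T-1, n_muscles)."""

    data: np.ndarray
    muscle_names: tuple
    meta: dict = field(default_factory=dict)


@dataclass
class PCModel:
    """Per-timestep principal-component chart fitted on unseeded data."""

    mean: np.ndarray
    components: np.ndarray  # (2, n_muscles), orthonormal rows
    explained_variance_ratio: np.ndarray
    n_informative: int


def reshape_to_trajectories(store: SampleStore) -> TrajectorySet:
    """Reshape a sample store into trajectories, driven by its labels.

    The store's variable labels must form a complete (muscle x time) grid;
    column order is irrelevant — placement follows labels, never position.
    """
    muscles = []
    times = []
    for m, t in store.var_labels:
        if m not in muscles:
            muscles.append(m)
        if t not in times:
            times.append(t)
    times = sorted(times)
    expected = {(m, t) for m in muscles for t in times}
    got = set(store.var_labels)
    missing = expected - got
    if missing or len(store.var_labels) != len(expected):
        raise FormatError(
            "variable labels do not form a complete (muscle x time) grid; "
            f"missing: {sorted(missing)}"
        )
    n, T, M = store.n_samples, len(times), len(muscles)
    tensor = np.empty((n, T, M))
    col = {lab: j for j, lab in enumerate(store.var_labels)}
    for ti, t in enumerate(times):
        for mi, m in enumerate(muscles):
            tensor[:, ti, mi] = store.samples[:, col[(m, t)]]
    return TrajectorySet(data=tensor, muscle_names=tuple(muscles),
                         times=tuple(times), meta=dict(store.meta))


def differentiate(ts: TrajectorySet) -> SpeedSet:
    """Forward first difference along time: a_dot[t] = a[t+1] - a[t]."""
    if ts.n_steps < 2:
        raise FormatError("need at least two time slices to differentiate")
    return SpeedSet(data=np.diff(ts.data, axis=1),
                    muscle_names=ts.muscle_names, meta=dict(ts.meta))


def max_abs_speed(ss: SpeedSet) -> np.ndarray:
    """Per-(trajectory, muscle) maximum of |a_dot| over time."""
    return np.max(np.abs(ss.data), axis=1)


def filter_by_delta(ts: TrajectorySet, delta: float) -> TrajectorySet:
    """Keep trajectories whose largest |a_dot| over all muscles is <= delta."""
    if not (0.0 <= delta <= 1.0):
        raise ValueError("delta must lie in [0, 1]")
    maxima = max_abs_speed(differentiate(ts)).max(axis=1)
    keep = maxima <= delta + 1e-12
    return TrajectorySet(data=ts.data[keep], muscle_names=ts.muscle_names,
                         times=ts.times,
                         meta={**ts.meta, "filter_delta": delta})


def select_seeds(ts: TrajectorySet, k: int, rng_seed: int):
    """Uniformly choose k trajectories without replacement; return their
    t=0 activation slices as Seeds, in draw order."""
    if ts.n_traj == 0:
        raise ValueError("cannot select seeds from an empty trajectory set")
    if k > ts.n_traj:
        raise ValueError(f"requested {k} seeds from {ts.n_traj} trajectories")
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(ts.n_traj, size=k, replace=False)
    return [Seed(activation=ts.data[i, 0].copy()) for i in idx]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    fixed = components.copy()
    for i, row in enumerate(fixed):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            fixed[i] = -row
    return fixed


def fit_pc_per_timestep(unseeded: TrajectorySet) -> list:
    """Fit one 2-component PCA per time slice, on unseeded data only.

    Sign convention: each loading's largest-magnitude entry is positive.
    Rank-deficient slices yield fewer informative components, recorded in
    ``n_informative``.
    """
    if unseeded.n_traj < unseeded.n_muscles + 1:
        raise ValueError(
            "need at least n_muscles + 1 trajectories per slice to fit PCs"
        )
    models = []
    k = min(2, unseeded.n_muscles)
    for t in range(unseeded.n_steps):
        X = unseeded.data[:, t, :]
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(X)
        comps = _fix_signs(pca.components_)
        ratios = pca.explained_variance_ratio_
        informative = int(np.sum(pca.explained_variance_ > 1e-12))
        models.append(PCModel(mean=pca.mean_, components=comps,
                              explained_variance_ratio=ratios,
                              n_informative=informative))
    return models


def project(ts, models, t: int) -> np.ndarray:
    """Project slice ``t`` onto the unseeded PC plane of that slice.

    ``ts`` may be a TrajectorySet or an (n, n_muscles) array.  Seeded data
    must be projected through the *unseeded* model — the same centering
    vector and loadings — so both live in one chart.
    """
    if not (0 <= t < len(models)):
        raise IndexError(f"no PC model fitted for slice {t}")
    X = ts.data[:, t, :] if isinstance(ts, TrajectorySet) else np.atleast_2d(ts)
    model = models[t]
    return (X - model.mean) @ model.components.T


def hull_area(points) -> float:
    """Exact area of the planar convex hull of a 2-D point set.

    Fewer than 3 points, or collinear points, give area 0 with a
    degeneracy warning.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise FormatError("hull_area expects 2-D points")
    if pts.shape[0] < 3:
        warnings.warn("degenerate hull: fewer than 3 points", RuntimeWarning)
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is area
    except QhullError:
        warnings.warn("degenerate hull: points are collinear", RuntimeWarning)
        return 0.0


def seeded_reduction_ratio(seeded2d, unseeded2d) -> float:
    """Seeded-to-unseeded hull-area ratio in the PC plane.

    This is the fraction of the feasible space (as seen in the projection)
    that remains reachable after committing to a seed.
    """
    outer = hull_area(unseeded2d)
    if outer <= 0.0:
        raise ValueError("unseeded hull is degenerate; ratio undefined")
    inner = hull_area(seeded2d)
    return inner / outer


def hull_area_report(seeded_ts: TrajectorySet, unseeded_ts: TrajectorySet,
                     models, seed_id=0) -> pd.DataFrame:
    """Per-timestep seeded/unseeded hull areas and their ratio."""
    rows = []
    for t in range(unseeded_ts.n_steps):
        outer_pts = project(unseeded_ts, models, t)
        inner_pts = project(seeded_ts, models, t)
        outer = hull_area(outer_pts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            inner = hull_area(inner_pts)
        rows.append({
            "seed_id": seed_id,
            "t": t,
            "seeded_area": inner,
            "unseeded_area": outer,
            "ratio": inner / outer if outer > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def occupancy_summary(ts: TrajectorySet) -> pd.DataFrame:
    """Per-muscle ranges and quartiles of visited activations and speeds.

    Quartiles use linear interpolation.  Supports cross-condition
    comparisons of how rate limits shrink each muscle's visited subspace.
    """
    speeds = differentiate(ts) if ts.n_steps >= 2 else None
    rows = []
    for i, m in enumerate(ts.muscle_names):
        act = ts.data[:, :, i].ravel()
        row = {
            "muscle": m,
            "act_min": act.min(), "act_q25": np.quantile(act, 0.25),
            "act_median": np.quantile(act, 0.5),
            "act_q75": np.quantile(act, 0.75), "act_max": act.max(),
        }
        if speeds is not None:
            sp = speeds.data[:, :, i].ravel()
            row.update({
                "speed_min": sp.min(), "speed_q25": np.quantile(sp, 0.25),
                "speed_median": np.quantile(sp, 0.5),
                "speed_q75": np.quantile(sp, 0.75), "speed_max": sp.max(),
                "max_abs_speed": np.abs(sp).max(),
            })
        rows.append(row)
    return pd.DataFrame(rows).set_index("muscle")
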