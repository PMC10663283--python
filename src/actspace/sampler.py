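"""Uniform sampling inside feasible-activation polytopes.

The polytopes here are lower-dimensional bodies embedded in the activation
box: the wrench equalities confine points to an affine subspace.  Sampling
therefore runs in a *chart* — an orthonormal basis of the equality null
space anchored at an interior point — where the body is full-dimensional
and the classic Hit-and-Run walk applies: pick an isotropic random
direction, intersect it with the body to get the feasible chord, jump to a
uniform point on the chord.  The stationary distribution is uniform over
the body.

A brute-force rejection sampler over the chart's bounding box provides an
exactly-uniform oracle on low-dimensional fixtures for validation.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .constraints import PolytopeSpec
from .exceptions import DegenerateError, InfeasibleError
from .model import SampleStore

# relative rank tolerance for null-space extraction (x max singular value)
RANK_RTOL = 1e-10
# rows whose directional component is below this are parallel to the chord
CHORD_SKIP_TOL = 1e-12
# minimal Chebyshev slack for a positive-volume relative interior
INTERIOR_SLACK_TOL = 1e-9


@dataclass(frozen=True)
class ChainConfig:
    """Hit-and-Run chain settings: length, burn-in, thinning, rng seed."""

    n_samples: int
    burn_in: int = 1000
    thin: int = 10
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class NullSpaceChart:
    """Affine chart of the equality manifold with induced inequalities.

    Ambient points are ``x = anchor + basis @ z``; the feasible set in
    chart coordinates is ``{z : G z <= h}`` (bounds folded in as rows).
    """

    anchor: np.ndarray
    basis: np.ndarray  # (n_ambient, dim)
    G: np.ndarray
    h: np.ndarray
    rank_warning: bool = False
    row_origins: tuple = field(default=())

    @property
    def dim(self) -> int:
        return self.basis.shape[1]

    def to_ambient(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if z.ndim == 1:
            return self.anchor + self.basis @ z
        return self.anchor + z @ self.basis.T


def _null_space(A: np.ndarray, n: int):
    """Orthonormal null-space basis with a documented rank tolerance."""
    if A.size == 0:
        return np.eye(n), False
    u, s, vt = np.linalg.svd(A, full_matrices=True)
    tol = (s[0] if s.size else 0.0) * RANK_RTOL
    rank = int(np.sum(s > tol))
    ambiguous = bool(np.any((s > tol / 10) & (s <= tol * 10) & (s != 0)))
    return vt[rank:].T, ambiguous


def build_chart(spec: PolytopeSpec, anchor) -> NullSpaceChart:
    """Express the polytope in orthonormal null-space coordinates at anchor."""
    anchor = np.asarray(anchor, dtype=float).ravel()
    if spec.eq_matrix.size:
        resid = np.max(np.abs(spec.eq_matrix @ anchor - spec.eq_rhs))
        scale = 1.0 + np.max(np.abs(spec.eq_rhs))
        if resid > 1e-8 * scale:
            raise ValueError(
                f"anchor violates equality constraints (residual {resid:.3g})"
            )
    n = spec.n_vars
    basis, ambiguous = _null_space(spec.eq_matrix, n)
    if ambiguous:
        warnings.warn(
            "null-space rank detection is ambiguous (singular values near "
            "tolerance); chart dimension may be unreliable",
            RuntimeWarning,
        )
    rows, rhs, origins = [], [], []
    if spec.ineq_matrix.size:
        rows.append(spec.ineq_matrix @ basis)
        rhs.append(spec.ineq_rhs - spec.ineq_matrix @ anchor)
        origins.extend(spec.ineq_origins)
    rows.append(basis)  # x_j <= upper_j
    rhs.append(spec.upper - anchor)
    origins.extend(f"upper[{m}@t{t}]" for m, t in spec.var_labels)
    rows.append(-basis)  # -x_j <= -lower_j
    rhs.append(anchor - spec.lower)
    origins.extend(f"lower[{m}@t{t}]" for m, t in spec.var_labels)
    G = np.vstack(rows)
    h = np.concatenate(rhs)
    # drop rows orthogonal to the chart (constant over the manifold)
    norms = np.linalg.norm(G, axis=1)
    keep = norms > CHORD_SKIP_TOL
    if np.any(h[~keep] < -1e-9):
        raise InfeasibleError(
            "an inequality constant over the equality manifold is violated"
        )
    return NullSpaceChart(
        anchor=anchor, basis=basis, G=G[keep], h=h[keep],
        rank_warning=ambiguous,
        row_origins=tuple(o for o, k in zip(origins, keep) if k),
    )


def find_interior_point(spec: PolytopeSpec) -> np.ndarray:
    """Chebyshev-center-style interior point on the equality manifold.

    Maximizes the minimal slack of all inequality and bound rows restricted
    to the equality manifold.  Raises :class:`InfeasibleError` when the
    polytope is empty and :class:`DegenerateError` when its relative
    interior has zero volume (while the set itself is nonempty).
    """
    anchor = spec.check_feasible()
    chart = build_chart(spec, anchor)
    k = chart.dim
    if k == 0:
        return anchor
    norms = np.linalg.norm(chart.G, axis=1)
    # variables (z, s): maximize s subject to G z + ||g_i|| s <= h
    A_ub = np.hstack([chart.G, norms[:, None]])
    c = np.zeros(k + 1)
    c[-1] = -1.0
    res = linprog(c, A_ub=A_ub, b_ub=chart.h,
                  bounds=[(None, None)] * k + [(0.0, None)], method="highs")
    if not res.success:
        raise InfeasibleError(
            f"interior-point LP failed (status {res.status})", status=res.status
        )
    slack = res.x[-1]
    if slack <= INTERIOR_SLACK_TOL:
        raise DegenerateError(
            f"polytope has zero-volume relative interior (max slack {slack:.3g})"
        )
    return chart.to_ambient(res.x[:k])


def chord_extent(z: np.ndarray, d: np.ndarray, chart: NullSpaceChart):
    """Feasible interval (lo, hi) along direction d from chart point z.

    ``z + t d`` is feasible iff ``t in [lo, hi]`` with ``lo < 0 < hi``;
    rows nearly parallel to d (|g.d| <= 1e-12) are skipped.
    """
    r = chart.h - chart.G @ z
    if np.min(r) < 0:
        raise ValueError("chord_extent requires a strictly feasible point")
    a = chart.G @ d
    lo, hi = -np.inf, np.inf
    pos = a > CHORD_SKIP_TOL
    neg = a < -CHORD_SKIP_TOL
    if np.any(pos):
        hi = np.min(r[pos] / a[pos])
    if np.any(neg):
        lo = np.max(r[neg] / a[neg])
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise RuntimeError(
            "unbounded chord; the polytope is missing its box bounds"
        )
    return float(lo), float(hi)


def spec_hash(spec: PolytopeSpec) -> str:
    """Stable content hash of a polytope, for provenance stamps."""
    hsh = hashlib.sha256()
    for arr in (spec.eq_matrix, spec.eq_rhs, spec.ineq_matrix, spec.ineq_rhs,
                spec.lower, spec.upper):
        hsh.update(np.ascontiguousarray(arr, dtype=float).tobytes())
    hsh.update(repr(spec.var_labels).encode())
    return hsh.hexdigest()[:12]


def hit_and_run(spec: PolytopeSpec, config: ChainConfig,
                extra_meta: dict | None = None) -> SampleStore:
    """Sample the polytope uniformly at random with Hit-and-Run.

    Deterministic given ``config.rng_seed``.  The chain runs entirely in
    null-space chart coordinates, so equality constraints hold to numerical
    precision by construction; retained states are mapped back to ambient
    coordinates and stamped with provenance.  A zero-dimensional chart
    (unique point) is returned ``n_samples`` times with a warning.
    """
    interior = find_interior_point(spec)
    chart = build_chart(spec, interior)
    k = chart.dim
    meta = {
        "rng_seed": config.rng_seed,
        "burn_in": config.burn_in,
        "thin": config.thin,
        "chart_dim": k,
        "spec_hash": spec_hash(spec),
        "sampler": "hit-and-run",
    }
    if extra_meta:
        meta.update(extra_meta)
    if k == 0:
        warnings.warn(
            "polytope has a zero-dimensional chart; returning its unique "
            "point for every sample",
            RuntimeWarning,
        )
        samples = np.tile(interior, (config.n_samples, 1))
        return SampleStore(samples=samples, var_labels=spec.var_labels, meta=meta)

    rng = np.random.default_rng(config.rng_seed)
    z = np.zeros(k)
    r = chart.h - chart.G @ z
    out = np.empty((config.n_samples, k))
    n_kept = 0
    step = 0
    max_steps = 50 * (config.burn_in + config.n_samples * config.thin) + 10_000
    while n_kept < config.n_samples:
        if step >= max_steps:
            raise RuntimeError("hit-and-run exceeded its step budget")
        d = rng.standard_normal(k)
        d /= np.linalg.norm(d)
        a = chart.G @ d
        lo, hi = -np.inf, np.inf
        pos = a > CHORD_SKIP_TOL
        neg = a < -CHORD_SKIP_TOL
        if np.any(pos):
            hi = np.min(r[pos] / a[pos])
        if np.any(neg):
            lo = np.max(r[neg] / a[neg])
        t = lo + rng.uniform() * (hi - lo)
        # keep strictly interior: back off a landing on the boundary
        accepted = False
        for _ in range(8):
            r_new = r - t * a
            if np.min(r_new) > 0:
                accepted = True
                break
            t *= 0.999999
        if accepted:
            z = z + t * d
            r = r_new
        step += 1
        if step % 1024 == 0:
            r = chart.h - chart.G @ z  # refresh accumulated residual drift
        if step > config.burn_in and (step - config.burn_in) % config.thin == 0:
            out[n_kept] = z
            n_kept += 1
    samples = chart.anchor + out @ chart.basis.T
    store = SampleStore(samples=samples, var_labels=spec.var_labels, meta=meta)
    audit = audit_samples(spec, store.samples)
    if not audit["all_pass"]:
        raise RuntimeError(f"sampler produced infeasible points: {audit}")
    return store


def rejection_oracle(spec: PolytopeSpec, n: int, rng_seed: int) -> SampleStore:
    """Exactly-uniform rejection sampler for low-dimensional charts.

    Proposes uniform points in the chart's axis-aligned bounding box
    (found by per-coordinate LPs) and keeps the feasible ones.  Guarded to
    chart dimension <= 4; aborts if the acceptance rate falls below 1e-4.
    Used as the independent uniformity oracle in validation.
    """
    interior = find_interior_point(spec)
    chart = build_chart(spec, interior)
    k = chart.dim
    meta = {"rng_seed": rng_seed, "sampler": "rejection", "chart_dim": k,
            "spec_hash": spec_hash(spec)}
    if k == 0:
        return SampleStore(samples=np.tile(interior, (n, 1)),
                           var_labels=spec.var_labels, meta=meta)
    if k > 4:
        raise ValueError(
            f"rejection oracle limited to chart dimension <= 4 (got {k}); "
            "the acceptance rate would be impractically low"
        )
    lo = np.empty(k)
    hi = np.empty(k)
    for j in range(k):
        c = np.zeros(k)
        c[j] = 1.0
        r_min = linprog(c, A_ub=chart.G, b_ub=chart.h,
                        bounds=[(None, None)] * k, method="highs")
        r_max = linprog(-c, A_ub=chart.G, b_ub=chart.h,
                        bounds=[(None, None)] * k, method="highs")
        if not (r_min.success and r_max.success):
            raise InfeasibleError("bounding-box LP failed on the chart")
        lo[j], hi[j] = r_min.x[j], r_max.x[j]
    rng = np.random.default_rng(rng_seed)
    kept = []
    proposed = 0
    while sum(len(b) for b in kept) < n:
        batch = rng.uniform(lo, hi, size=(max(4 * n, 1000), k))
        feas = np.all(batch @ chart.G.T <= chart.h, axis=1)
        kept.append(batch[feas])
        proposed += batch.shape[0]
        accepted = sum(len(b) for b in kept)
        if proposed >= 200_000 and accepted / proposed < 1e-4:
            raise RuntimeError(
                "rejection acceptance rate below 1e-4; use hit_and_run or a "
                "lower-dimensional fixture"
            )
    z = np.vstack(kept)[:n]
    samples = chart.anchor + z @ chart.basis.T
    return SampleStore(samples=samples, var_labels=spec.var_labels, meta=meta)


def audit_samples(spec: PolytopeSpec, samples: np.ndarray,
                  bounds_tol: float = 1e-9, eq_tol: float = 1e-6) -> dict:
    """Constraint audit of sampled points against their polytope.

    Checks box bounds and inequality rows to ``bounds_tol`` and equality
    rows to ``eq_tol``; returns per-family worst-case violations and an
    ``all_pass`` verdict.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    report = {"n_samples": int(samples.shape[0])}
    lower_viol = float(np.max(spec.lower - samples, initial=0.0))
    upper_viol = float(np.max(samples - spec.upper, initial=0.0))
    report["bound_violation"] = max(lower_viol, upper_viol)
    if spec.ineq_matrix.size:
        report["ineq_violation"] = float(
            np.max(samples @ spec.ineq_matrix.T - spec.ineq_rhs, initial=0.0)
        )
    else:
        report["ineq_violation"] = 0.0
    if spec.eq_matrix.size:
        report["eq_residual"] = float(
            np.max(np.abs(samples @ spec.eq_matrix.T - spec.eq_rhs), initial=0.0)
        )
    else:
        report["eq_residual"] = 0.0
    report["all_pass"] = bool(
        report["bound_violation"] <= bounds_tol
        and report["ineq_violation"] <= bounds_tol
        and report["eq_residual"] <= eq_tol
    )
    return report
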