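"""Task wrench sequences and feasible-activation polytopes.

The feasible activation space for a single wrench target ``w`` is

    {a in [0,1]^M : H a = w},

a convex polytope in the muscle-activation box.  A time-varying task couples
``T`` such polytopes through activation-contraction (rate) constraints

    |a_{t+1,i} - a_{t,i}| <= delta,

yielding one stacked polytope over ``M * T`` variables — the spatiotemporal
tunnel.  This module builds those systems, plus seeded variants in which the
first (and optionally last) slice is pinned to a chosen feasible activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .exceptions import FormatError, InfeasibleError
from .model import HMatrix, TaskSpec

# tolerances: construction-time equality checks vs post-hoc sample audits
CONSTRUCTION_TOL = 1e-8
AUDIT_EQ_TOL = 1e-6


@dataclass(frozen=True)
class WrenchSequence:
    """Time-indexed wrench targets, one row per slice t = 0 ... T-1."""

    values: np.ndarray  # (T, n_wrench)
    wrench_names: tuple

    def __post_init__(self):
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "wrench_names", tuple(self.wrench_names))
        if values.shape[1] != len(self.wrench_names):
            raise FormatError("wrench labels do not match sequence width")
        if not np.all(np.isfinite(values)):
            raise FormatError("wrench sequence contains non-finite values")

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, t: int) -> np.ndarray:
        return self.values[t]


@dataclass(frozen=True)
class Seed:
    """A fixed feasible starting activation; with ``clamp`` the final
    slice must match it too."""

    activation: np.ndarray
    clamp: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "activation", np.asarray(self.activation, dtype=float).ravel()
        )


@dataclass(frozen=True)
class PolytopeSpec:
    """A convex polytope: A_eq x = b_eq, A_ub x <= b_ub, lower <= x <= upper.

    Variables are labeled (muscle, time-index) pairs in time-major,
    muscle-minor order; every row carries an origin tag for diagnostics.
    """

    eq_matrix: np.ndarray
    eq_rhs: np.ndarray
    ineq_matrix: np.ndarray
    ineq_rhs: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    var_labels: tuple
    eq_origins: tuple = field(default=())
    ineq_origins: tuple = field(default=())

    def __post_init__(self):
        for name in ("eq_matrix", "eq_rhs", "ineq_matrix", "ineq_rhs", "lower", "upper"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "var_labels",
                           tuple((str(m), int(t)) for m, t in self.var_labels))
        n = len(self.var_labels)
        eq = self.eq_matrix.reshape(-1, n) if self.eq_matrix.size else np.zeros((0, n))
        ub = self.ineq_matrix.reshape(-1, n) if self.ineq_matrix.size else np.zeros((0, n))
        object.__setattr__(self, "eq_matrix", eq)
        object.__setattr__(self, "ineq_matrix", ub)
        if self.eq_rhs.shape != (eq.shape[0],) or self.ineq_rhs.shape != (ub.shape[0],):
            raise FormatError("constraint right-hand sides do not match row counts")
        if self.lower.shape != (n,) or self.upper.shape != (n,):
            raise FormatError("bounds do not match variable count")
        if np.any(self.lower > self.upper + 1e-12):
            raise FormatError("lower bound exceeds upper bound")
        if np.any(self.lower < -1e-12) or np.any(self.upper > 1 + 1e-12):
            raise FormatError("activation bounds must lie within [0, 1]")
        if not self.eq_origins:
            object.__setattr__(self, "eq_origins",
                               tuple(f"eq[{i}]" for i in range(eq.shape[0])))
        if not self.ineq_origins:
            object.__setattr__(self, "ineq_origins",
                               tuple(f"ineq[{i}]" for i in range(ub.shape[0])))
        if len(self.eq_origins) != eq.shape[0] or len(self.ineq_origins) != ub.shape[0]:
            raise FormatError("row origin tags do not match row counts")

    @property
    def n_vars(self) -> int:
        return len(self.var_labels)

    def check_feasible(self):
        """Solve a phase-1 LP; return a feasible point or raise."""
        res = linprog(
            c=np.zeros(self.n_vars),
            A_ub=self.ineq_matrix if self.ineq_matrix.size else None,
            b_ub=self.ineq_rhs if self.ineq_matrix.size else None,
            A_eq=self.eq_matrix if self.eq_matrix.size else None,
            b_eq=self.eq_rhs if self.eq_matrix.size else None,
            bounds=list(zip(self.lower, self.upper)),
            method="highs",
        )
        if not res.success:
            raise InfeasibleError(
                f"polytope is empty (LP status {res.status}: {res.message})",
                status=res.status,
            )
        return res.x

    def export_lp_text(self) -> str:
        """Plain-text dump of all rows, labeled by origin, for debugging."""
        cols = [f"{m}@t{t}" for m, t in self.var_labels]
        lines = [f"vars: {', '.join(cols)}"]
        for origin, row, rhs in zip(self.eq_origins, self.eq_matrix, self.eq_rhs):
            terms = " + ".join(
                f"{c:+.6g}*{v}" for c, v in zip(row, cols) if c != 0.0
            )
            lines.append(f"{origin}: {terms} = {rhs:.6g}")
        for origin, row, rhs in zip(self.ineq_origins, self.ineq_matrix, self.ineq_rhs):
            terms = " + ".join(
                f"{c:+.6g}*{v}" for c, v in zip(row, cols) if c != 0.0
            )
            lines.append(f"{origin}: {terms} <= {rhs:.6g}")
        for v, lo, hi in zip(cols, self.lower, self.upper):
            lines.append(f"bound: {lo:.6g} <= {v} <= {hi:.6g}")
        return "\n".join(lines) + "\n"


def task_wrench_array(task: TaskSpec, n_wrench: int) -> np.ndarray:
    """Evaluate the task's wrench targets as a (T, n_wrench) array.

    The force direction progresses through the arc as a single cosine
    period peaking at the middle index: theta_t = (arc/2)(1 - cos(2 pi t /
    (T-1))).  For the 4-D fingertip wrench the rotation takes fx toward fz
    with fy and the torque held at zero; 1- and 2-component models use the
    documented planar reduction.
    """
    T = task.n_steps
    if T < 2:
        raise ValueError("a wrench sequence needs at least 2 steps")
    t = np.arange(T)
    theta = np.deg2rad((task.arc_degrees / 2.0) * (1.0 - np.cos(2.0 * np.pi * t / (T - 1))))
    m = task.magnitude
    if n_wrench == 4:
        w = np.column_stack(
            [m * np.cos(theta), np.zeros(T), m * np.sin(theta), np.zeros(T)]
        )
    elif n_wrench == 2:
        w = np.column_stack([m * np.cos(theta), m * np.sin(theta)])
    elif n_wrench == 1:
        if task.arc_degrees != 0:
            raise ValueError("1-D wrench models only support arc_degrees = 0")
        w = np.full((T, 1), m)
    else:
        if task.arc_degrees != 0:
            raise ValueError(
                f"no rotation convention for {n_wrench}-component wrenches; "
                "use arc_degrees = 0"
            )
        w = np.zeros((T, n_wrench))
        w[:, 0] = m
    return w


def build_task_wrenches(task: TaskSpec, model: HMatrix) -> WrenchSequence:
    """Build the time-indexed wrench targets of the force-redirection task."""
    values = task_wrench_array(task, model.n_wrench)
    return WrenchSequence(values=values, wrench_names=model.wrench_names)


def build_moment_polytope(model: HMatrix, w) -> PolytopeSpec:
    """Feasible activation space for a single wrench: {a in [0,1]^M : H a = w}."""
    w = np.asarray(w, dtype=float).ravel()
    if w.shape[0] != model.n_wrench:
        raise FormatError(
            f"wrench has {w.shape[0]} components; model expects {model.n_wrench}"
        )
    spec = PolytopeSpec(
        eq_matrix=model.values,
        eq_rhs=w,
        ineq_matrix=np.zeros((0, model.n_muscles)),
        ineq_rhs=np.zeros(0),
        lower=np.zeros(model.n_muscles),
        upper=np.ones(model.n_muscles),
        var_labels=tuple((m, 0) for m in model.muscle_names),
        eq_origins=tuple(f"wrench[{name}]" for name in model.wrench_names),
    )
    spec.check_feasible()
    return spec


def build_trajectory_polytope(
    model: HMatrix, seq: WrenchSequence, delta: float
) -> PolytopeSpec:
    """Stacked spatiotemporal polytope over all (muscle, time) variables.

    Equalities: block-diagonal H per slice (``n_wrench * T`` rows).
    Inequalities: two rows per muscle and consecutive-slice pair encoding
    ``+-(a_{t+1,i} - a_{t,i}) <= delta`` (``2 * M * (T-1)`` rows).
    Bounds: [0, 1] throughout.  Raises on emptiness, identifying the first
    infeasible prefix length via LPs on growing prefixes.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValueError("delta must lie in [0, 1]")
    T = len(seq)
    M = model.n_muscles
    W = model.n_wrench
    n = T * M
    labels = tuple((m, t) for t in range(T) for m in model.muscle_names)

    A_eq = np.zeros((T * W, n))
    b_eq = np.zeros(T * W)
    eq_origins = []
    for t in range(T):
        A_eq[t * W:(t + 1) * W, t * M:(t + 1) * M] = model.values
        b_eq[t * W:(t + 1) * W] = seq[t]
        eq_origins.extend(f"wrench[t={t},{name}]" for name in model.wrench_names)

    if delta == 0.0:
        # zero-rate limit: consecutive slices must coincide.  Encoded as
        # equality rows so the relative interior of the remaining degrees
        # of freedom stays full-dimensional for the sampler.
        extra = np.zeros((M * (T - 1), n))
        r = 0
        for t in range(T - 1):
            for i, name in enumerate(model.muscle_names):
                extra[r, (t + 1) * M + i] = 1.0
                extra[r, t * M + i] = -1.0
                eq_origins.append(f"lipschitz[=,{name},t={t}]")
                r += 1
        A_eq = np.vstack([A_eq, extra])
        b_eq = np.concatenate([b_eq, np.zeros(M * (T - 1))])
        A_ub = np.zeros((0, n))
        b_ub = np.zeros(0)
        ineq_origins = []
    else:
        n_rate = 2 * M * (T - 1)
        A_ub = np.zeros((n_rate, n))
        b_ub = np.full(n_rate, float(delta))
        ineq_origins = []
        r = 0
        for t in range(T - 1):
            for i, name in enumerate(model.muscle_names):
                A_ub[r, (t + 1) * M + i] = 1.0
                A_ub[r, t * M + i] = -1.0
                ineq_origins.append(f"lipschitz[+,{name},t={t}]")
                A_ub[r + 1, (t + 1) * M + i] = -1.0
                A_ub[r + 1, t * M + i] = 1.0
                ineq_origins.append(f"lipschitz[-,{name},t={t}]")
                r += 2

    spec = PolytopeSpec(
        eq_matrix=A_eq, eq_rhs=b_eq, ineq_matrix=A_ub, ineq_rhs=b_ub,
        lower=np.zeros(n), upper=np.ones(n), var_labels=labels,
        eq_origins=tuple(eq_origins), ineq_origins=tuple(ineq_origins),
    )
    try:
        spec.check_feasible()
    except InfeasibleError as exc:
        prefix = _first_infeasible_prefix(model, seq, delta)
        raise InfeasibleError(
            f"trajectory polytope is empty at delta={delta}; the first "
            f"infeasible prefix spans slices 0..{prefix - 1} "
            f"(prefix length {prefix})",
            status=exc.status,
            prefix_len=prefix,
        ) from exc
    return spec


def _first_infeasible_prefix(model: HMatrix, seq: WrenchSequence, delta: float) -> int:
    for k in range(1, len(seq) + 1):
        sub = WrenchSequence(values=seq.values[:k], wrench_names=seq.wrench_names)
        if k == 1:
            try:
                build_moment_polytope(model, sub[0])
                continue
            except InfeasibleError:
                return 1
        M, W, n = model.n_muscles, model.n_wrench, k * model.n_muscles
        A_eq = np.zeros((k * W, n))
        b_eq = np.zeros(k * W)
        for t in range(k):
            A_eq[t * W:(t + 1) * W, t * M:(t + 1) * M] = model.values
            b_eq[t * W:(t + 1) * W] = sub[t]
        rows = []
        for t in range(k - 1):
            for i in range(M):
                row = np.zeros(n)
                row[(t + 1) * M + i] = 1.0
                row[t * M + i] = -1.0
                rows.append(row)
                rows.append(-row)
        A_ub = np.array(rows) if rows else None
        b_ub = np.full(len(rows), delta) if rows else None
        res = linprog(np.zeros(n), A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=[(0.0, 1.0)] * n, method="highs")
        if not res.success:
            return k
    return len(seq)


def add_seed_constraint(spec: PolytopeSpec, seed: Seed) -> PolytopeSpec:
    """Pin the first slice (and, if clamped, the last) to a seed activation.

    The seed must lie in [0, 1] per muscle and reproduce the first slice's
    wrench target (checked against the spec's own slice-0 wrench rows).
    """
    times = sorted({t for _, t in spec.var_labels})
    t0, t_last = times[0], times[-1]
    idx0 = [j for j, (_, t) in enumerate(spec.var_labels) if t == t0]
    idx_last = [j for j, (_, t) in enumerate(spec.var_labels) if t == t_last]
    a = seed.activation
    if a.shape[0] != len(idx0):
        raise FormatError(
            f"seed has {a.shape[0]} muscles; polytope slice has {len(idx0)}"
        )
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise ValueError("seed activations must lie in [0, 1]")

    # verify the seed produces the first wrench, using the slice-0 wrench rows
    rows0 = [k for k, origin in enumerate(spec.eq_origins)
             if origin.startswith(f"wrench[t={t0},") or origin.startswith("wrench[")]
    rows0 = [k for k in rows0
             if np.all(spec.eq_matrix[k][[j for j in range(spec.n_vars) if j not in idx0]] == 0)]
    if rows0:
        H0 = spec.eq_matrix[np.ix_(rows0, idx0)]
        b0 = spec.eq_rhs[rows0]
        resid = np.max(np.abs(H0 @ a - b0))
        scale = 1.0 + np.max(np.abs(b0)) if b0.size else 1.0
        if resid > CONSTRUCTION_TOL * scale:
            raise InfeasibleError(
                "seed does not reproduce the first wrench target "
                f"(residual {resid:.3g}); it is not first-moment feasible"
            )

    n = spec.n_vars
    extra_rows, extra_rhs, extra_origins = [], [], []
    for i, j in enumerate(idx0):
        row = np.zeros(n)
        row[j] = 1.0
        extra_rows.append(row)
        extra_rhs.append(a[i])
        extra_origins.append(f"seed[{spec.var_labels[j][0]}]")
    if seed.clamp and t_last != t0:
        for i, j in enumerate(idx_last):
            row = np.zeros(n)
            row[j] = 1.0
            extra_rows.append(row)
            extra_rhs.append(a[i])
            extra_origins.append(f"clamp[{spec.var_labels[j][0]}]")

    return PolytopeSpec(
        eq_matrix=np.vstack([spec.eq_matrix, np.array(extra_rows)]),
        eq_rhs=np.concatenate([spec.eq_rhs, np.array(extra_rhs)]),
        ineq_matrix=spec.ineq_matrix,
        ineq_rhs=spec.ineq_rhs,
        lower=spec.lower,
        upper=spec.upper,
        var_labels=spec.var_labels,
        eq_origins=spec.eq_origins + tuple(extra_origins),
        ineq_origins=spec.ineq_origins,
    )
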