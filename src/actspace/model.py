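"""Models, tasks and sample stores.

This module holds the data objects the rest of the package computes on:

* :class:`HMatrix` — the linear activation-to-wrench map of a tendon-driven
  limb in a fixed posture.  Row ``j`` gives the contribution of each muscle,
  at 100% activation, to wrench component ``j``; moment arms and the posture
  Jacobian are already folded into the entries.
* :class:`TaskSpec` — a force-redirection task: hold a force of a given
  magnitude while rotating its direction through an arc, discretised into
  ``n_steps`` slices of ``step_ms`` each, under an activation-contraction
  (rate) limit ``delta`` per slice.
* :class:`SampleStore` — uniform-at-random points in a feasible polytope,
  with full provenance (rng seed, burn-in, thinning, delta, task hash).

It also provides readers/writers for these objects and synthetic / analytic
fixture models so every downstream stage is testable without lab data.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .exceptions import FormatError, GenerationError

# canonical wrench-component order for the 4-D fingertip wrench
WRENCH_NAMES_4D = ("fx", "fy", "fz", "ty")

# the seven muscles actuating a human index finger
INDEX_FINGER_MUSCLES = ("FDP", "FDS", "EIP", "EDC", "LUM", "DI", "PI")

STORE_SCHEMA = "actspace-samples"
STORE_VERSION = 1


@dataclass(frozen=True)
class HMatrix:
    """Linear activation-to-wrench map ``w = H a`` with labeled axes."""

    values: np.ndarray
    muscle_names: tuple
    wrench_names: tuple

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "muscle_names", tuple(self.muscle_names))
        object.__setattr__(self, "wrench_names", tuple(self.wrench_names))
        if values.ndim != 2:
            raise FormatError("H must be a 2-D matrix")
        n_wrench, n_muscles = values.shape
        if n_wrench < 1 or n_muscles < 1:
            raise FormatError("H must have at least one row and one column")
        if len(self.wrench_names) != n_wrench:
            raise FormatError(
                f"{len(self.wrench_names)} wrench labels for {n_wrench} rows"
            )
        if len(self.muscle_names) != n_muscles:
            raise FormatError(
                f"{len(self.muscle_names)} muscle labels for {n_muscles} columns"
            )
        if not np.all(np.isfinite(values)):
            raise FormatError("H contains non-finite entries")

    @property
    def n_wrench(self) -> int:
        return self.values.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TaskSpec:
    """A discretised isometric force-redirection task.

    Parameters
    ----------
    magnitude : float
        Force magnitude held throughout the task, in newtons.
    arc_degrees : float
        Total rotation of the force direction, in degrees.
    n_steps : int
        Number of 50-ms-scale time slices (wrench targets).
    step_ms : float
        Duration of one slice in milliseconds.
    delta : float
        Activation-contraction constraint: the maximum change of any
        muscle's activation between consecutive slices, as a fraction of
        maximal activation (dimensionless, in [0, 1]).
    """

    magnitude: float = 10.0
    arc_degrees: float = 30.0
    n_steps: int = 7
    step_ms: float = 50.0
    delta: float = 0.12

    def __post_init__(self):
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [0, 1]")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be positive")
        if not (0.0 <= self.arc_degrees < 180.0):
            raise ValueError("arc_degrees must lie in [0, 180)")

    def task_hash(self) -> str:
        payload = json.dumps(
            [self.magnitude, self.arc_degrees, self.n_steps, self.step_ms, self.delta]
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _label_str(label) -> str:
    muscle, t = label
    return f"{muscle}@t{int(t)}"


def _parse_label(text: str):
    try:
        muscle, t = text.rsplit("@t", 1)
        return (muscle, int(t))
    except ValueError as exc:
        raise FormatError(f"malformed variable label {text!r}") from exc


@dataclass
class SampleStore:
    """Points sampled from a polytope, as rows over labeled variables."""

    samples: np.ndarray
    var_labels: tuple  # ordered (muscle, time-index) pairs
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.var_labels = tuple((str(m), int(t)) for m, t in self.var_labels)
        if self.samples.shape[1] != len(self.var_labels):
            raise FormatError(
                f"{self.samples.shape[1]} columns for {len(self.var_labels)} labels"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


def read_h_matrix(path) -> HMatrix:
    """Read an activation-to-wrench matrix from a labeled CSV file.

    The header row carries muscle names; the first column carries wrench
    component names (conventionally fx, fy, fz, ty); the body is numeric.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"H matrix file not found: {path}")
    try:
        df = pd.read_csv(path, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"could not parse H matrix CSV {path}: {exc}") from exc
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise FormatError(f"H matrix CSV {path} has no numeric body")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric or blank cell in {path} at row "
            f"{df.index[row]!r}, column {df.columns[col]!r}"
        )
    return HMatrix(
        values=numeric.to_numpy(dtype=float),
        muscle_names=tuple(str(c) for c in df.columns),
        wrench_names=tuple(str(r) for r in df.index),
    )


def write_h_matrix(model: HMatrix, path) -> None:
    """Write an HMatrix in the CSV dialect :func:`read_h_matrix` reads."""
    df = pd.DataFrame(
        model.values, index=list(model.wrench_names), columns=list(model.muscle_names)
    )
    df.to_csv(path)


def make_planar_toy():
    """Return the analytic one-wrench two-muscle fixture model.

    ``H = [[1, 1]]`` with a constant unit-wrench task: the single-moment
    feasible set is the segment ``{a1 + a2 = 1}`` inside the unit square,
    whose geometry is known in closed form (a uniform point on it has a
    uniform first coordinate).
    """
    model = HMatrix(
        values=np.array([[1.0, 1.0]]),
        muscle_names=("m1", "m2"),
        wrench_names=("fx",),
    )
    task = TaskSpec(magnitude=1.0, arc_degrees=0.0, n_steps=7, step_ms=50.0, delta=1.0)
    return model, task


def _task_wrench_targets(task: TaskSpec, n_wrench: int) -> np.ndarray:
    # local import to avoid a cycle: constraints imports model types
    from .constraints import task_wrench_array

    return task_wrench_array(task, n_wrench)


def generate_synthetic_h(
    n_muscles: int,
    n_wrench: int,
    rng_seed: int,
    task: TaskSpec | None = None,
    max_attempts: int = 25,
) -> HMatrix:
    """Draw a random activation-to-wrench matrix feasible for a task.

    Entries are standard normal scaled by ``1/sqrt(n_muscles)``; the matrix
    is then rescaled globally so every wrench of the task's sequence is
    producible with activations strictly inside [0, 1] (verified by linear
    program, solved with an interior margin of 0.05 on each activation),
    and so that the stacked trajectory system admits solutions at
    activation-contraction rates well below the smallest rate the study
    grid uses.  Deterministic given ``rng_seed``; redrawn a bounded number
    of times on failure.
    """
    if n_muscles <= n_wrench:
        raise ValueError(
            "n_muscles must exceed n_wrench so the map has a null space "
            f"(got {n_muscles} muscles, {n_wrench} wrench components)"
        )
    task = task or TaskSpec()
    wrenches = _task_wrench_targets(task, n_wrench)
    rng = np.random.default_rng(rng_seed)
    margin = 0.05
    for _ in range(max_attempts):
        G = rng.standard_normal((n_wrench, n_muscles)) / np.sqrt(n_muscles)
        lam_lo, lam_hi = [], []
        ok = True
        for w in wrenches:
            # feasible scale factors: G a = lam * w with a in the margin box
            A_eq = np.hstack([G, -w[:, None]])
            bounds = [(margin, 1.0 - margin)] * n_muscles + [(None, None)]
            c = np.zeros(n_muscles + 1)
            c[-1] = 1.0
            lo = linprog(c, A_eq=A_eq, b_eq=np.zeros(n_wrench), bounds=bounds,
                         method="highs")
            hi = linprog(-c, A_eq=A_eq, b_eq=np.zeros(n_wrench), bounds=bounds,
                         method="highs")
            if not (lo.success and hi.success):
                ok = False
                break
            lam_lo.append(lo.x[-1])
            lam_hi.append(hi.x[-1])
        if not ok:
            continue
        lo = max(max(lam_lo), 0.0)
        hi = min(lam_hi)
        if hi <= lo or hi <= 0:
            continue
        lam = 0.5 * (lo + hi)
        if lam <= 0:
            continue
        H = G / lam
        muscle_names = (
            INDEX_FINGER_MUSCLES
            if n_muscles == len(INDEX_FINGER_MUSCLES)
            else tuple(f"m{i + 1}" for i in range(n_muscles))
        )
        wrench_names = (
            WRENCH_NAMES_4D
            if n_wrench == 4
            else tuple(f"w{i + 1}" for i in range(n_wrench))
        )
        model = HMatrix(values=H, muscle_names=muscle_names, wrench_names=wrench_names)
        if _min_rate_feasible(model, task, wrenches):
            return model
    raise GenerationError(
        f"no feasible synthetic H after {max_attempts} draws "
        f"(n_muscles={n_muscles}, n_wrench={n_wrench}, seed={rng_seed})"
    )


def _min_rate_feasible(model: HMatrix, task: TaskSpec, wrenches: np.ndarray,
                       rate_cap: float = 0.025) -> bool:
    """Check the instance supports slow activation-contraction rates.

    Solves ``min s`` over trajectories with ``|a_{t+1} - a_t| <= s``; the
    instance is accepted only when the optimum is below ``rate_cap`` so
    the whole study grid of rate limits is runnable on it.
    """
    T, W = wrenches.shape
    M = model.n_muscles
    n = T * M
    A_eq = np.zeros((T * W, n + 1))
    b_eq = np.zeros(T * W)
    for t in range(T):
        A_eq[t * W:(t + 1) * W, t * M:(t + 1) * M] = model.values
        b_eq[t * W:(t + 1) * W] = wrenches[t]
    rows = []
    for t in range(T - 1):
        for i in range(M):
            r = np.zeros(n + 1)
            r[(t + 1) * M + i] = 1.0
            r[t * M + i] = -1.0
            r[-1] = -1.0
            rows.append(r.copy())
            r[(t + 1) * M + i] = -1.0
            r[t * M + i] = 1.0
            rows.append(r)
    A_ub = np.array(rows)
    b_ub = np.zeros(len(rows))
    c = np.zeros(n + 1)
    c[-1] = 1.0
    bounds = [(0.0, 1.0)] * n + [(0.0, None)]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                  method="highs")
    return bool(res.success) and res.x[-1] <= rate_cap


# ---------------------------------------------------------------------------
# sample stores

def save_samples(store: SampleStore, path) -> None:
    """Write a SampleStore to CSV (small runs) or HDF5 (.h5/.hdf5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _save_h5(store, path)
    else:
        _save_csv(store, path)


def load_samples(path) -> SampleStore:
    """Read a SampleStore written by :func:`save_samples`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"sample store not found: {path}")
    if path.suffix in (".h5", ".hdf5"):
        return _load_h5(path)
    return _load_csv(path)


def _save_csv(store: SampleStore, path: Path) -> None:
    buf = io.StringIO()
    buf.write(f"# {STORE_SCHEMA} v{STORE_VERSION}\n")
    buf.write(f"# meta={json.dumps(store.meta, sort_keys=True)}\n")
    df = pd.DataFrame(store.samples, columns=[_label_str(l) for l in store.var_labels])
    df.to_csv(buf, index=False)  # default shortest-repr floats round-trip
    path.write_text(buf.getvalue())


def _load_csv(path: Path) -> SampleStore:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise FormatError(f"{path} is not an actspace sample store")
        schema = header.lstrip("# ").strip()
        if schema != f"{STORE_SCHEMA} v{STORE_VERSION}":
            raise FormatError(f"unknown sample-store schema {schema!r} in {path}")
        meta_line = fh.readline().strip()
        if not meta_line.startswith("# meta="):
            raise FormatError(f"missing meta line in {path}")
        meta = json.loads(meta_line[len("# meta="):])
        df = pd.read_csv(fh, float_precision="round_trip")
    labels = tuple(_parse_label(c) for c in df.columns)
    return SampleStore(samples=df.to_numpy(dtype=float), var_labels=labels, meta=meta)


def _save_h5(store: SampleStore, path: Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["schema"] = STORE_SCHEMA
        fh.attrs["version"] = STORE_VERSION
        fh.attrs["meta"] = json.dumps(store.meta, sort_keys=True)
        fh.create_dataset("samples", data=store.samples)
        fh.create_dataset(
            "var_labels",
            data=np.array([_label_str(l) for l in store.var_labels], dtype="S"),
        )


def _load_h5(path: Path) -> SampleStore:
    with h5py.File(path, "r") as fh:
        if fh.attrs.get("schema") != STORE_SCHEMA or fh.attrs.get("version") != STORE_VERSION:
            raise FormatError(
                f"unknown sample-store schema "
                f"{fh.attrs.get('schema')!r} v{fh.attrs.get('version')!r} in {path}"
            )
        samples = fh["samples"][...]
        labels = tuple(_parse_label(s.decode()) for s in fh["var_labels"][...])
        meta = json.loads(fh.attrs["meta"])
    return SampleStore(samples=samples, var_labels=labels, meta=meta)
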