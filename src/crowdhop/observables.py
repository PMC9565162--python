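"""Analysis of simulation trajectories.

Everything downstream of the Monte Carlo engine lives here: mean squared
displacement and diffusion coefficients (Einstein relation), time-unit
calibration against reference diffusion data, the free-volume
(Cohen-Turnbull) concentration fit, cluster/aggregation statistics from
the bond graph, docking-bond residence times, melting curves over a
temperature scan, and the size dependence of the diffusional slowdown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse import csgraph

__all__ = [
    "DiffusionResult",
    "CohenTurnbullFit",
    "ClusterStats",
    "ResidenceResult",
    "MeltingCurve",
    "SizeDependence",
    "msd",
    "msd_time_averaged",
    "diffusion_coefficient",
    "calibrate_time",
    "cohen_turnbull_fit",
    "cluster_stats",
    "clusters",
    "residence_time",
    "smooth",
    "find_inflection",
    "melting_curve",
    "size_dependence",
]


# --------------------------------------------------------------------------
# mean squared displacement and diffusion

def msd(traj, type_id: int | None = None,
        reference_step: int | None = None) -> np.ndarray:
    """Mean squared displacement on unwrapped coordinates.

    ``MSD[lag] = < |u(ref + lag) - u(ref)|^2 >`` averaged over the copies
    of ``type_id`` (all copies when None).  The reference step defaults to
    the configured one (step 100) so the early off-lattice relaxation of
    the initial grid state is excluded.
    """
    if reference_step is None:
        reference_step = traj.config.msd_reference_step
    u = traj.unwrapped
    if len(u) <= reference_step + 1:
        raise ValueError(
            f"trajectory has {len(u) - 1} steps; needs > {reference_step}")
    if type_id is not None:
        u = u[:, traj.types == type_id, :]
    ref = u[reference_step]
    d = u[reference_step:] - ref
    return np.mean(np.sum(d * d, axis=2), axis=1)


def msd_time_averaged(traj, lags, type_id: int | None = None,
                      start: int | None = None) -> np.ndarray:
    """Time-origin-averaged MSD at selected lags.

    Averages ``|u(t + L) - u(t)|^2`` over every available time origin
    ``t >= start`` as well as over copies — the standard variance-reduced
    estimator for stationary dynamics, much tighter than the
    single-reference MSD when a quantitative diffusion coefficient is
    needed.  ``start`` defaults to the configured reference step.
    """
    if start is None:
        start = traj.config.msd_reference_step
    u = traj.unwrapped[start:]
    if type_id is not None:
        u = u[:, traj.types == type_id, :]
    out = []
    for lag in lags:
        lag = int(lag)
        if not 0 < lag < len(u):
            raise ValueError(f"lag {lag} outside trajectory")
        d = u[lag:] - u[:-lag]
        out.append(float(np.mean(np.sum(d * d, axis=2))))
    return np.array(out)


@dataclass(frozen=True)
class DiffusionResult:
    """Diffusion coefficient from the Einstein relation, D = MSD(t)/6t."""

    d: float                 # Angstrom^2 / ns
    d_per_step: float        # Angstrom^2 / step
    window: tuple            # (first lag, last lag) used for the fit
    r_squared: float
    quality_warning: bool


def diffusion_coefficient(msd_series: np.ndarray, ns_per_step: float = 1.0,
                          window: tuple | None = None) -> DiffusionResult:
    """Least-squares slope of MSD through the origin, divided by 6.

    ``window`` selects the lag range (in steps) of the fit; by default
    lags between 10% and 50% of the series length are used, avoiding both
    the reference-step transient and the noisy tail.  A quality warning is
    raised on strongly sub-linear (saturating) MSD.
    """
    m = np.asarray(msd_series, dtype=float)
    n = len(m)
    if n < 3:
        raise ValueError("MSD series too short")
    if window is None:
        lo = max(1, int(0.1 * (n - 1)))
        hi = max(lo + 1, int(0.5 * (n - 1)))
    else:
        lo, hi = window
        lo = max(1, int(lo))
        hi = min(n - 1, int(hi))
    lags = np.arange(lo, hi + 1, dtype=float)
    y = m[lo:hi + 1]
    slope = float(np.dot(y, lags) / np.dot(lags, lags))
    resid = y - slope * lags
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    # sub-linearity probe: compare late-half to early-half secant slopes
    mid = (lo + hi) // 2
    early = (m[mid] - m[lo]) / max(mid - lo, 1)
    late = (m[hi] - m[mid]) / max(hi - mid, 1)
    warn = bool(early > 0 and late < 0.5 * early) or r2 < 0.9
    d_step = slope / 6.0
    return DiffusionResult(
        d=d_step / ns_per_step, d_per_step=d_step,
        window=(lo, hi), r_squared=r2, quality_warning=warn)


def calibrate_time(d_sim_per_step: float, d_ref_per_ns: float,
                   correction: float = 3.0) -> float:
    """Nanoseconds per simulation step from matching diffusion rates.

    ``d_sim_per_step`` is the simulated diffusion coefficient in
    Angstrom^2/step; ``d_ref_per_ns`` a reference value in Angstrom^2/ns.
    The reference is divided by ``correction`` (default 3) because the
    reference MD diffusion rate used for calibration runs three times
    faster than experiment.
    """
    if d_sim_per_step <= 0 or d_ref_per_ns <= 0:
        raise ValueError("diffusion rates must be positive")
    return d_sim_per_step / (d_ref_per_ns / correction)


# --------------------------------------------------------------------------
# concentration dependence

@dataclass(frozen=True)
class CohenTurnbullFit:
    """Free-volume fit D(V) = D0 * exp(-gamma * V / (1 - V))."""

    d0: float
    gamma: float
    residuals: np.ndarray
    d0_linear: float        # cross-check from the log-linear regression
    gamma_linear: float

    def predict(self, v):
        v = np.asarray(v, dtype=float)
        return self.d0 * np.exp(-self.gamma * v / (1.0 - v))


def cohen_turnbull_fit(fractions, diffusion) -> CohenTurnbullFit:
    """Fit the Cohen-Turnbull free-volume law to D versus volume fraction.

    Solved twice: nonlinear least squares on D, and ordinary linear
    regression of ln D on V/(1-V) (used as the starting point and kept as
    a cross-check).
    """
    v = np.asarray(fractions, dtype=float)
    d = np.asarray(diffusion, dtype=float)
    if len(v) < 3 or len(np.unique(v)) < 3:
        raise ValueError("need at least 3 distinct volume fractions")
    if np.any((v <= 0) | (v >= 1)):
        raise ValueError("volume fractions must lie in (0, 1)")
    if np.any(d <= 0):
        raise ValueError("diffusion rates must be positive")
    x = v / (1.0 - v)
    slope, intercept = np.polyfit(x, np.log(d), 1)
    d0_lin, gamma_lin = float(np.exp(intercept)), float(-slope)

    def model(vv, d0, gamma):
        return d0 * np.exp(-gamma * vv / (1.0 - vv))

    popt, _ = optimize.curve_fit(model, v, d, p0=[d0_lin, gamma_lin],
                                 maxfev=10_000)
    resid = d - model(v, *popt)
    return CohenTurnbullFit(d0=float(popt[0]), gamma=float(popt[1]),
                            residuals=resid, d0_linear=d0_lin,
                            gamma_linear=gamma_lin)


# --------------------------------------------------------------------------
# clusters / aggregation

@dataclass(frozen=True)
class ClusterStats:
    """Aggregation statistics of one bond-graph snapshot.

    ``n_c`` averages clusters of two or more docked proteins (1.0 with
    ``all_monomers`` set when no cluster exists); monomers are copies
    participating in no match at all and are reported separately.
    ``n_c_with_monomers`` is the mean over all connected components
    including singletons.
    """

    n_c: float
    n_c_with_monomers: float
    monomer_fraction: float
    sizes: np.ndarray            # component size per component
    all_monomers: bool

    @property
    def histogram(self) -> pd.Series:
        vals, counts = np.unique(self.sizes, return_counts=True)
        return pd.Series(counts, index=vals, name="clusters")


def cluster_stats(bond_rec: np.ndarray) -> ClusterStats:
    """Cluster statistics from the outgoing-bond array.

    ``bond_rec[i]`` is the receptor of copy ``i`` (-1 when unbonded);
    clusters are connected components of the undirected bond graph.
    """
    bond_rec = np.asarray(bond_rec)
    n = len(bond_rec)
    lig = np.flatnonzero(bond_rec >= 0)
    rec = bond_rec[lig]
    graph = sparse.coo_matrix(
        (np.ones(len(lig)), (lig, rec)), shape=(n, n))
    _, labels = csgraph.connected_components(graph, directed=False)
    sizes = np.bincount(labels)
    multi = sizes[sizes >= 2]
    all_monomers = len(multi) == 0
    n_c = float(multi.mean()) if not all_monomers else 1.0
    return ClusterStats(
        n_c=n_c,
        n_c_with_monomers=float(sizes.mean()),
        monomer_fraction=float(np.sum(sizes == 1) / n),
        sizes=sizes,
        all_monomers=all_monomers)


def clusters(state) -> ClusterStats:
    """Cluster statistics of a live system state."""
    return cluster_stats(state.out_rec)


# --------------------------------------------------------------------------
# residence time

@dataclass(frozen=True)
class ResidenceResult:
    """Mean docking-bond lifetime over completed episodes.

    An episode starts when a ligand docks onto a receptor and ends when
    its outgoing match moves to a *different* receptor; re-docking onto
    the same partner with a new pose keeps the pair alive.  Episodes
    still alive at the end of the run are right-censored: excluded from
    the mean and counted.
    """

    mean_ns: float
    mean_steps: float
    n_completed: int
    n_censored: int
    lifetimes_steps: np.ndarray


def residence_time(traj, ns_per_step: float | None = None) -> ResidenceResult:
    """Mean ligand-receptor pair lifetime from the bond event log."""
    if ns_per_step is None:
        ns_per_step = traj.config.ns_per_step
    events = traj.bond_events
    open_ep: dict[int, tuple[int, int]] = {}   # ligand -> (receptor, start)
    lifetimes = []
    for step, lig, old_rec, new_rec in events:
        cur = open_ep.get(lig)
        if cur is not None and cur[0] != new_rec:
            lifetimes.append(step - cur[1])
            cur = None
        if cur is None:
            open_ep[lig] = (new_rec, step)
    lifetimes = np.array(lifetimes, dtype=float)
    mean_steps = float(lifetimes.mean()) if len(lifetimes) else float("nan")
    return ResidenceResult(
        mean_ns=mean_steps * ns_per_step,
        mean_steps=mean_steps,
        n_completed=len(lifetimes),
        n_censored=len(open_ep),
        lifetimes_steps=lifetimes)


# --------------------------------------------------------------------------
# melting curves

def smooth(series: np.ndarray, window: int = 100) -> np.ndarray:
    """Sliding-window (boxcar) average; window clipped to the series."""
    y = np.asarray(series, dtype=float)
    w = max(1, min(int(window), len(y)))
    kernel = np.ones(w) / w
    return np.convolve(y, kernel, mode="valid")


def find_inflection(temperatures, values):
    """Inflection of a response curve versus log10 temperature.

    Locates the sign change of the second divided difference of the
    response with respect to ``log10 T`` (the steepest-rise midpoint) and
    interpolates the zero crossing.  Returns ``(T_inflection, confident)``;
    ``T_inflection`` is None for degenerate (flat) curves, and confidence
    is low when the curvature changes sign more than once (noise).
    """
    t = np.asarray(temperatures, dtype=float)
    y = np.asarray(values, dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    x = np.log10(t)
    if len(x) < 4:
        raise ValueError("need at least 4 temperatures")
    if np.ptp(y) == 0:
        return None, False
    # second divided differences at interior nodes
    d2 = np.empty(len(x) - 2)
    for k in range(1, len(x) - 1):
        left = (y[k] - y[k - 1]) / (x[k] - x[k - 1])
        right = (y[k + 1] - y[k]) / (x[k + 1] - x[k])
        d2[k - 1] = 2.0 * (right - left) / (x[k + 1] - x[k - 1])
    xi = x[1:-1]
    zeros = []
    for k in range(len(d2)):
        if d2[k] == 0.0:
            zeros.append(xi[k])
        elif k + 1 < len(d2) and d2[k] * d2[k + 1] < 0:
            frac = d2[k] / (d2[k] - d2[k + 1])
            zeros.append(xi[k] + frac * (xi[k + 1] - xi[k]))
    if not zeros:
        return None, False
    sign_changes = int(np.sum(np.diff(np.sign(d2[d2 != 0])) != 0))
    confident = len(zeros) == 1 and sign_changes <= 1
    return float(10.0 ** zeros[0]), confident


@dataclass(frozen=True)
class MeltingCurve:
    """Terminal observables versus temperature with the melting point."""

    temperatures: np.ndarray
    energy: np.ndarray
    shift: np.ndarray
    msd: np.ndarray
    acceptance: np.ndarray
    inflection_temperature: float | None
    confident: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "temperature": self.temperatures,
            "energy": self.energy,
            "shift": self.shift,
            "msd": self.msd,
            "acceptance": self.acceptance,
        })


def melting_curve(runs: dict, window: int = 100) -> MeltingCurve:
    """Melting behavior from a temperature scan.

    ``runs`` maps temperature to a trajectory.  Each per-step series is
    smoothed with a sliding window and its terminal window averaged; the
    inflection is detected on the shift curve (the most direct mobility
    readout) versus log10 T.
    """
    temps = np.array(sorted(runs), dtype=float)
    energy, shift_v, msd_v, acc = [], [], [], []
    for t in temps:
        traj = runs[t]
        energy.append(_terminal(traj.energy, window))
        shift_v.append(_terminal(traj.shift, window))
        acc.append(_terminal(traj.acceptance, window))
        m = msd(traj)
        msd_v.append(float(m[-1]))
    shift_v = np.array(shift_v)
    t_inf, confident = find_inflection(temps, shift_v)
    return MeltingCurve(
        temperatures=temps, energy=np.array(energy), shift=shift_v,
        msd=np.array(msd_v), acceptance=np.array(acc),
        inflection_temperature=t_inf, confident=confident)


def _terminal(series: np.ndarray, window: int) -> float:
    s = smooth(series, window)
    w = max(1, min(window, len(s)))
    return float(s[-w:].mean())


# --------------------------------------------------------------------------
# size dependence

@dataclass(frozen=True)
class SizeDependence:
    """Diffusional slowdown versus protein size.

    ``slowdown`` is D_max/D per type.  The exponential model
    ``slowdown = exp(c * N + b)`` is fit in log space against residue
    count N; the Einstein-Stokes-like linear model is checked against
    N^(1/3) (a radius proxy for globular proteins).
    """

    type_ids: list
    n_residues: np.ndarray
    slowdown: np.ndarray
    exp_rate: float            # c in slowdown ~ exp(c * N)
    exp_intercept: float
    exp_r_squared: float
    linear_slope: float        # slowdown ~ a + slope * N^(1/3)
    linear_intercept: float
    linear_r_squared: float


def _r2(y, yhat) -> float:
    ss = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss if ss > 0 else 1.0


def size_dependence(d_by_type: dict, n_res_by_type: dict) -> SizeDependence:
    """Slowdown table and size-scaling fits from per-type diffusion."""
    if len(d_by_type) < 2:
        raise ValueError("need at least two protein types")
    ids = sorted(d_by_type)
    d = np.array([d_by_type[k] for k in ids], dtype=float)
    n = np.array([n_res_by_type[k] for k in ids], dtype=float)
    if np.any(d <= 0):
        raise ValueError("diffusion rates must be positive")
    slowdown = d.max() / d

    c, b = np.polyfit(n, np.log(slowdown), 1)
    exp_r2 = _r2(np.log(slowdown), c * n + b)
    r = n ** (1.0 / 3.0)
    sl, ic = np.polyfit(r, slowdown, 1)
    lin_r2 = _r2(slowdown, sl * r + ic)
    return SizeDependence(
        type_ids=ids, n_residues=n, slowdown=slowdown,
        exp_rate=float(c), exp_intercept=float(b), exp_r_squared=exp_r2,
        linear_slope=float(sl), linear_intercept=float(ic),
        linear_r_squared=lin_r2)
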