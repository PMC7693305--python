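"""Six-mass lumped-element model of vocal-fold oscillation.

The glottis is modelled as two vocal folds, each discretised into three
point masses that move laterally (perpendicular to the glottal midline).
Two fixed anchors close the glottal outline: the posterior point ``p``
(optionally split into ``p1``/``p2`` by a posterior gap, as seen in
healthy female subjects) and the anterior point ``a``.  The line ``p-a``
is the glottal midline and is known by construction, which makes the
model a ground-truth generator for midline-detection benchmarks.

State variable: the half-width ``xi[s, i]`` of fold ``s`` at station
``i`` — the signed distance of mass ``i`` from the midline (positive =
open, negative = the folds overlap and collide).

Each mass obeys

    m * xi'' = F_anchor + F_vertical + F_longitudinal + F_collision + F_drive

with

* ``F_anchor``       — spring to the prephonatory rest half-width with a
  cubic stiffening term, plus damping proportional to velocity only;
* ``F_vertical``     — linear springs to the neighbouring masses of the
  same fold (and to the fixed anchors at the ends of the chain);
* ``F_longitudinal`` — tension of the fold pulling each mass toward the
  straight chord between the posterior and anterior anchors;
* ``F_collision``    — a stiff linear spring engaged while the two folds
  overlap at a station, pushing both outward;
* ``F_drive``        — subglottal pressure pushing the folds apart,
  modulated by the lateral velocity (``1 + beta * tanh(v / v0)``), a
  lumped stand-in for the mucosal-wave phase lag that feeds energy into
  the oscillation.

Six dimensionless factors randomise the model: ``Q1`` (mass), ``Q2``
(anchor stiffness), ``Q3`` (vertical coupling), ``Q4`` (longitudinal
tension) per side, plus ``Q5`` (subglottal pressure) and ``Q6``
(collision stiffness) shared by both sides.  Asymmetric Q1-Q4 values
produce asymmetric oscillation up to complete one-sided insufficiency.

Lengths are in units of the posterior-anterior distance, time in
seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "SimulationConfig",
    "ForceModel",
    "TrajectorySet",
    "GlottalOutline",
    "SimulationDiverged",
    "Q_RANGES",
    "sample_config",
    "simulate",
    "is_oscillating",
    "outline_from_state",
    "glottal_area_waveform",
]

#: Uniform sampling ranges of the dimensionless model factors.
Q_RANGES = {
    "q1": (0.5, 2.0),
    "q2": (0.5, 2.0),
    "q3": (0.5, 2.0),
    "q4": (0.5, 2.0),
    "q5": (1.0, 4.0),
    "q6": (0.5, 6.0),
}

#: Normalised y positions (along the midline) of the moving masses.
STATION_Y = np.array([0.25, 0.5, 0.75])


class SimulationDiverged(RuntimeError):
    """Integration produced NaN/Inf; carries the offending config."""

    def __init__(self, config: "SimulationConfig", t: float):
        super().__init__(f"six-mass integration diverged at t={t:.6f}s")
        self.config = config
        self.t = t


@dataclass
class SimulationConfig:
    """Sampled factors plus integration / rendering settings."""

    q1_left: float = 1.0
    q2_left: float = 1.0
    q3_left: float = 1.0
    q4_left: float = 1.0
    q1_right: float = 1.0
    q2_right: float = 1.0
    q3_right: float = 1.0
    q4_right: float = 1.0
    q5: float = 2.5
    q6: float = 3.0
    posterior_gap: float = 0.0
    sim_duration: float = 150e-3
    discard_duration: float = 85e-3
    dt: float = 1e-5
    frame_rate: float = 4000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q1", "q2", "q3", "q4"):
            for side in ("left", "right"):
                v = getattr(self, f"{name}_{side}")
                lo, hi = Q_RANGES[name]
                if not (lo <= v <= hi):
                    raise ValueError(f"{name}_{side}={v} outside [{lo}, {hi}]")
        for name in ("q5", "q6"):
            lo, hi = Q_RANGES[name]
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.posterior_gap < 0:
            raise ValueError("posterior_gap must be >= 0")
        if not self.discard_duration < self.sim_duration:
            raise ValueError("discard_duration must be < sim_duration")
        if self.dt <= 0 or self.frame_rate <= 0:
            raise ValueError("dt and frame_rate must be positive")

    def q_side(self, side: str) -> np.ndarray:
        return np.array([getattr(self, f"q{k}_{side}") for k in range(1, 5)])

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SimulationConfig":
        return cls(**json.loads(s))


@dataclass
class ForceModel:
    """Coefficients of the five force terms (model units).

    Defaults are tuned so that at Q = 1 the fundamental frequency sits
    near 140 Hz and limit-cycle half-width amplitudes are a few percent
    of the fold length, matching the 80-250 Hz speaking range when the
    Q factors sweep their boundaries.
    """

    masses: tuple = (1.0, 1.2, 1.0)            # per-station mass
    k_anchor: tuple = (4.0e5, 4.0e5, 4.0e5)    # anchor spring stiffness
    eta: float = 800.0                          # cubic stiffening (1/len^2)
    damping: float = 170.0                      # velocity damping
    k_vertical: float = 1.2e5                   # neighbour coupling spring
    k_longitudinal: float = 1.0e5               # chord-tension restoring
    k_collision: float = 2.4e6                  # contact spring (per overlap)
    pressure: float = 3800.0                    # subglottal driving force
    beta: float = 0.5                           # velocity modulation depth
    v0: float = 0.5                             # modulation velocity scale
    drive_offset: float = 0.15                  # static fraction of the drive
    rest_halfwidth: tuple = (0.01, 0.01, 0.01)  # prephonatory half-widths

    def __post_init__(self) -> None:
        for name in ("k_anchor", "masses", "rest_halfwidth"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} entries must be > 0")
        for name in ("damping", "k_vertical", "k_longitudinal",
                     "k_collision", "pressure"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TrajectorySet:
    """Mass half-width trajectories over the retained time window."""

    times: np.ndarray                   # [N] seconds, strictly increasing
    positions: np.ndarray               # [N, 2, 3] (side: 0=left, 1=right)
    velocities: np.ndarray              # [N, 2, 3]
    config: SimulationConfig = None

    def interpolate(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of positions at times ``t`` -> [len(t), 2, 3]."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if t.min() < self.times[0] - 1e-12 or t.max() > self.times[-1] + 1e-12:
            raise ValueError("requested times outside retained window")
        out = np.empty((len(t), 2, 3))
        for s in range(2):
            for i in range(3):
                out[:, s, i] = np.interp(t, self.times, self.positions[:, s, i])
        return out


@dataclass
class GlottalOutline:
    """Closed polygon of the glottal area for one frame, plus the true axis.

    Vertices run p1 -> left masses (posterior to anterior) -> a ->
    right masses (anterior to posterior) -> p2, in model coordinates
    (x lateral, y along the midline from posterior 0 to anterior 1).
    """

    vertices: np.ndarray                # [8, 2]
    true_midline: tuple                 # ((x_p, y_p), (x_a, y_a))
    time: float

    @property
    def area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def sample_config(rng_seed: int, symmetric: bool = False,
                  gap_probability: float = 0.5,
                  max_gap: float = 0.15, **overrides) -> SimulationConfig:
    """Draw a random model configuration.

    Q1-Q4 are drawn per side (equal for both sides when ``symmetric``),
    Q5/Q6 shared.  A posterior gap is present with ``gap_probability``
    and its width is uniform in [0, ``max_gap``] fold lengths.
    """
    rng = np.random.default_rng(rng_seed)
    qs = {}
    for k in range(1, 5):
        lo, hi = Q_RANGES[f"q{k}"]
        left = rng.uniform(lo, hi)
        right = left if symmetric else rng.uniform(lo, hi)
        qs[f"q{k}_left"] = left
        qs[f"q{k}_right"] = right
    qs["q5"] = rng.uniform(*Q_RANGES["q5"])
    qs["q6"] = rng.uniform(*Q_RANGES["q6"])
    gap = rng.uniform(0.0, max_gap) if rng.uniform() < gap_probability else 0.0
    qs["posterior_gap"] = gap
    qs["seed"] = int(rng_seed)
    qs.update(overrides)
    return SimulationConfig(**qs)


try:
    from numba import njit as _njit
except ImportError:                                    # pragma: no cover
    def _njit(*a, **k):
        def wrap(f):
            return f
        return wrap(a[0]) if a and callable(a[0]) else wrap


@_njit(cache=True)
def _acc(xi, vel, m, k_a, eta, damping, k_v, k_l, k_c, q6,
         drive, beta, v0, c0, rest, chord, half_gap):
    """Accelerations for state xi/vel of shape [2, 3] (numba core)."""
    out = np.empty((2, 3))
    for s in range(2):
        for i in range(3):
            x = xi[s, i]
            v = vel[s, i]
            dx = x - rest[i]
            # Anchor spring (cubic stiffening) + damping on velocity only.
            F = -k_a[s, i] * (dx + eta * dx ** 3) - damping * v
            # Vertical coupling: chain springs; ends attach to anchors.
            left = half_gap if i == 0 else xi[s, i - 1]
            right = 0.0 if i == 2 else xi[s, i + 1]
            F += -k_v[s] * ((x - left) + (x - right))
            # Longitudinal tension toward the straight chord p -> a.
            F += -k_l[s] * (x - chord[i])
            # Collision while folds overlap at this station.
            overlap = -(xi[0, i] + xi[1, i])
            if overlap > 0.0:
                F += q6 * k_c * overlap
            # Driving pressure: small static push plus a part modulated by
            # the shared opening velocity at this station (glottal flow is
            # common to both folds).  Injects energy into the common mode,
            # phase-locking the folds, and keeps the oscillation centered
            # on the midline instead of statically displacing the folds.
            gdot = vel[0, i] + vel[1, i]
            F += drive * (c0 + beta * np.tanh(gdot / v0))
            out[s, i] = F / m[s, i]
    return out


@_njit(cache=True)
def _integrate(n_steps, dt, m, k_a, eta, damping, k_v, k_l, k_c, q6,
               drive, beta, v0, c0, rest, chord, half_gap):
    xi = np.empty((2, 3))
    vel = np.zeros((2, 3))
    for s in range(2):
        for i in range(3):
            xi[s, i] = rest[i]
    pos_hist = np.empty((n_steps + 1, 2, 3))
    vel_hist = np.empty((n_steps + 1, 2, 3))
    pos_hist[0] = xi
    vel_hist[0] = vel
    args = (m, k_a, eta, damping, k_v, k_l, k_c, q6, drive, beta, v0, c0,
            rest, chord, half_gap)
    diverged_at = -1
    for n in range(n_steps):
        k1v = _acc(xi, vel, *args)
        k2x = vel + 0.5 * dt * k1v
        k2v = _acc(xi + 0.5 * dt * vel, k2x, *args)
        k3x = vel + 0.5 * dt * k2v
        k3v = _acc(xi + 0.5 * dt * k2x, k3x, *args)
        k4x = vel + dt * k3v
        k4v = _acc(xi + dt * k3x, k4x, *args)
        xi = xi + (dt / 6.0) * (vel + 2 * k2x + 2 * k3x + k4x)
        vel = vel + (dt / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
        pos_hist[n + 1] = xi
        vel_hist[n + 1] = vel
        if not (np.all(np.isfinite(xi)) and np.all(np.isfinite(vel))):
            diverged_at = n + 1
            break
    return pos_hist, vel_hist, diverged_at


def simulate(config: SimulationConfig,
             forces: ForceModel | None = None) -> TrajectorySet:
    """Integrate the model with classical fixed-step RK4.

    Runs over ``[0, sim_duration]`` and returns only the retained window
    ``[discard_duration, sim_duration]`` (the start-up transient is
    discarded).  Initial conditions: all masses at their rest
    half-widths, zero velocity.

    Raises
    ------
    SimulationDiverged
        If the state becomes non-finite; the exception carries the
        config so callers can discard and resample the model.
    """
    forces = forces or ForceModel()
    q_side = np.stack([config.q_side("left"), config.q_side("right")])
    dt = config.dt
    n_steps = int(round(config.sim_duration / dt))
    times = np.arange(n_steps + 1) * dt
    half_gap = config.posterior_gap / 2.0

    pos_hist, vel_hist, diverged_at = _integrate(
        n_steps, dt,
        np.asarray(forces.masses) * q_side[:, 0:1],
        np.asarray(forces.k_anchor) * q_side[:, 1:2],
        forces.eta, forces.damping,
        forces.k_vertical * q_side[:, 2],
        forces.k_longitudinal * q_side[:, 3],
        forces.k_collision, config.q6,
        config.q5 * forces.pressure, forces.beta, forces.v0,
        forces.drive_offset,
        np.asarray(forces.rest_halfwidth, dtype=float),
        half_gap * (1.0 - STATION_Y), half_gap)
    if diverged_at >= 0:
        raise SimulationDiverged(config, times[diverged_at])

    keep = times >= config.discard_duration - 1e-12
    return TrajectorySet(times=times[keep], positions=pos_hist[keep],
                         velocities=vel_hist[keep], config=config)


def _station_widths(xi: np.ndarray, half_gap: float) -> np.ndarray:
    """Total glottal widths at y = 0, .25, .5, .75, 1 (clipped at contact)."""
    widths = np.concatenate([[2 * half_gap],
                             np.maximum(0.0, xi[..., 0, :] + xi[..., 1, :]),
                             [0.0]])
    return widths


def glottal_area_waveform(traj: TrajectorySet,
                          split: bool = False) -> np.ndarray:
    """Glottal area over time by trapezoidal integration of station widths.

    With ``split=True`` returns an [N, 2] array of (left, right) area
    contributions relative to the midline.
    """
    half_gap = traj.config.posterior_gap / 2.0 if traj.config else 0.0
    y = np.concatenate([[0.0], STATION_Y, [1.0]])
    sides = []
    for s in range(2):
        w = np.concatenate([
            np.full((len(traj.times), 1), half_gap),
            np.maximum(0.0, traj.positions[:, s, :]),
            np.zeros((len(traj.times), 1))], axis=1)
        sides.append(np.trapezoid(w, y, axis=1))
    left, right = sides
    if split:
        return np.stack([left, right], axis=1)
    return left + right


def is_oscillating(traj: TrajectorySet, config: SimulationConfig,
                   min_maxima: int = 3, floor_fraction: float = 0.05,
                   reference_halfwidth: float = 0.2) -> bool:
    """Whether the retained window shows sustained oscillation.

    True iff the glottal area waveform has at least ``min_maxima`` local
    maxima and its peak-to-peak amplitude reaches ``floor_fraction`` of
    the area of a reference glottis fully opened to
    ``reference_halfwidth`` on both sides.
    """
    from scipy.signal import find_peaks

    gaw = glottal_area_waveform(traj)
    y = np.concatenate([[0.0], STATION_Y, [1.0]])
    ref_w = np.concatenate([[config.posterior_gap],
                            np.full(3, 2 * reference_halfwidth), [0.0]])
    ref_area = np.trapezoid(ref_w, y)
    ptp = gaw.max() - gaw.min()
    if ptp < floor_fraction * ref_area:
        return False
    peaks, _ = find_peaks(gaw, prominence=0.1 * max(ptp, 1e-30))
    return len(peaks) >= min_maxima


def outline_from_state(traj: TrajectorySet, config: SimulationConfig,
                       frame_times: Sequence[float]) -> list[GlottalOutline]:
    """Glottal outline polygons at the requested frame times.

    Half-widths are clipped at zero (folds in contact cannot cross the
    midline in the rendered area).  The true midline is the fixed p-a
    axis, identical for every frame.
    """
    half_gap = config.posterior_gap / 2.0
    pos = traj.interpolate(np.asarray(frame_times))    # [T, 2, 3]
    midline = ((0.0, 0.0), (0.0, 1.0))
    outlines = []
    for t, xi in zip(np.atleast_1d(frame_times), pos):
        xi = np.maximum(0.0, xi)
        # vertices: p1, L1..L3, a, R3..R1, p2 (p1 == p2 when gap is zero)
        verts = np.array(
            [[-half_gap, 0.0]]
            + [[-xi[0, i], STATION_Y[i]] for i in range(3)]
            + [[0.0, 1.0]]
            + [[xi[1, i], STATION_Y[i]] for i in reversed(range(3))]
            + [[half_gap, 0.0]])
        outlines.append(GlottalOutline(vertices=verts, true_midline=midline,
                                       time=float(t)))
    return outlines


def export_trajectories_csv(traj: TrajectorySet, path) -> None:
    """times + per-mass half-widths as CSV (left1..3, right1..3)."""
    import pandas as pd

    cols = {"time_s": traj.times}
    for s, side in enumerate(("left", "right")):
        for i in range(3):
            cols[f"{side}_m{i + 1}"] = traj.positions[:, s, i]
    pd.DataFrame(cols).to_csv(path, index=False)
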