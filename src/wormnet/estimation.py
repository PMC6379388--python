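"""Motility-parameter estimation from centroid tracks.

Isolated dauer larvae crawl along smoothly turning paths: the heading
theta(t) drifts at a slowly varying rotation rate omega(t) that behaves
like an Ornstein--Uhlenbeck process.  This module estimates the four
motility parameters (v0, omega0, sigma_omega, tau) from short centroid
tracks sampled at a uniform interval, converts them to the simulation's
dimensionless units, and measures incoming/outgoing angles of pair
collisions.

The sigma/tau estimator works on the sign-weighted ensemble drift

    Y(t) = < s_i (theta_i(t) - omega0 t) >,
    s_i  = sign(theta_i(t_end) - theta_i(0) - omega0 t_end)

whose expectation, for OU rotation rates started in stationarity, is
theta_0 + sqrt(2/pi) sigma_omega tau (1 - exp(-t/tau)), i.e. to second
order theta_0 + sqrt(2/pi) sigma_omega (t - t^2 / (2 tau)).  A least
squares quadratic a + b t + c t^2 then yields

    sigma_omega = b sqrt(pi/2),    tau = -b / (2 c).

Confidence intervals come from a percentile bootstrap over animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TrackSet",
    "MotilityEstimate",
    "DimensionlessMotility",
    "CollisionEvent",
    "headings_from_track",
    "estimate_v0",
    "estimate_omega0",
    "fit_sigma_tau",
    "estimate_motility",
    "to_dimensionless",
    "collision_angles",
]


@dataclass(frozen=True)
class TrackSet:
    """Centroid tracks of n animals at uniform sampling interval dt.

    ``positions`` has shape (n_animals, n_points, 2); units are micrometres
    and seconds for experimental data, but any consistent pair works.
    """

    positions: np.ndarray
    dt: float
    ids: tuple = ()

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 3 or pos.shape[2] != 2:
            raise ValueError("positions must have shape (n_animals, n_points, 2)")
        if pos.shape[1] < 3:
            raise ValueError("tracks need at least 3 time points")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(pos)):
            raise ValueError("tracks contain non-finite positions")
        if not self.ids:
            object.__setattr__(self, "ids", tuple(range(pos.shape[0])))

    @property
    def n_animals(self) -> int:
        return self.positions.shape[0]

    @property
    def n_points(self) -> int:
        return self.positions.shape[1]

    @property
    def t_end(self) -> float:
        """Track duration (n_points - 1) * dt."""
        return (self.n_points - 1) * self.dt


@dataclass
class MotilityEstimate:
    """Estimated motility parameters with bootstrap confidence intervals."""

    v0: float
    v0_sd: float
    omega0: float
    omega0_se: float
    sigma_omega: float
    tau: float
    sigma_omega_ci: tuple
    tau_ci: tuple
    t_e: float
    n_animals: int

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise ValueError("v0 must be positive")
        # NaN marks a flagged, unidentifiable correlation time (drift
        # curve without concave rise); otherwise tau must be positive
        if not np.isnan(self.tau) and self.tau <= 0:
            raise ValueError("tau must be positive (or NaN if unidentifiable)")
        if self.sigma_omega < 0:
            raise ValueError("sigma_omega must be non-negative")
        for lo, hi in (self.sigma_omega_ci, self.tau_ci):
            if hi < lo:
                raise ValueError("CI bounds out of order")


@dataclass(frozen=True)
class DimensionlessMotility:
    """Motility parameters in simulation units.

    The length unit is half the body length (worms shorten while
    undulating, so half the nominal length matches the effective
    interaction scale); the time unit is the time to travel it,
    ``length_unit / v0``.
    """

    length_unit: float
    time_unit: float
    omega0: float
    sigma_omega: float
    tau: float

    def __post_init__(self) -> None:
        if self.length_unit <= 0 or self.time_unit <= 0 or self.tau <= 0:
            raise ValueError("units and tau must be positive")


@dataclass(frozen=True)
class CollisionEvent:
    """Incoming/outgoing angle of one pair collision, both in [0, pi]."""

    incoming: float
    outgoing: float
    contact_time: float

    def __post_init__(self) -> None:
        for a in (self.incoming, self.outgoing):
            if not (0.0 <= a <= np.pi + 1e-12):
                raise ValueError("collision angles must lie in [0, pi]")


def headings_from_track(
    track: np.ndarray,
    dt: float,
    min_step_fraction: float = 1e-3,
) -> np.ndarray:
    """Unwrapped movement directions of the forward displacements.

    ``track`` is an (m, 2) position sequence; the result has length m - 1,
    with heading k the direction of the step from sample k to k + 1,
    unwrapped so successive differences lie in (-pi, pi].  Steps shorter
    than ``min_step_fraction`` times the mean step inherit the previous
    heading (the direction of a near-zero displacement is pure noise).
    """
    track = np.asarray(track, dtype=float)
    disp = np.diff(track, axis=0)
    norms = np.hypot(disp[:, 0], disp[:, 1])
    floor = min_step_fraction * norms.mean()
    if not np.any(norms > floor):
        raise ValueError("track has no displacements above the noise floor")
    raw = np.arctan2(disp[:, 1], disp[:, 0])
    ok = norms > floor
    if not ok.all():
        # inherit previous valid heading; leading gaps take the first valid
        first = np.flatnonzero(ok)[0]
        raw[:first] = raw[first]
        ok[:first] = True
        idx = np.where(ok, np.arange(len(raw)), -1)
        np.maximum.accumulate(idx, out=idx)
        raw = raw[idx]
    return np.unwrap(raw)


def estimate_v0(tracks: TrackSet) -> tuple[float, float]:
    """Mean speed |dr| / dt: returns (mean over animals, s.d. across animals)."""
    disp = np.diff(tracks.positions, axis=1)
    speeds = np.hypot(disp[..., 0], disp[..., 1]).mean(axis=1) / tracks.dt
    return float(speeds.mean()), float(speeds.std(ddof=1)) if len(speeds) > 1 else 0.0


def _heading_matrix(tracks: TrackSet) -> np.ndarray:
    return np.stack(
        [headings_from_track(tracks.positions[i], tracks.dt)
         for i in range(tracks.n_animals)]
    )


def estimate_omega0(headings: np.ndarray, t_e: float) -> tuple[float, float]:
    """Mean rotation rate <theta(t_end) - theta(0)> / t_e with its s.e.

    ``headings`` is (n_animals, K) of unwrapped headings; the total heading
    change is taken between the first and last available heading and
    referred to the track duration ``t_e``.
    """
    turn = (headings[:, -1] - headings[:, 0]) / t_e
    n = len(turn)
    se = float(turn.std(ddof=1) / np.sqrt(n)) if n > 1 else np.inf
    return float(turn.mean()), se


def _signed_drift(headings: np.ndarray, omega0: float, t: np.ndarray) -> np.ndarray:
    resid_end = headings[:, -1] - headings[:, 0] - omega0 * t[-1]
    s = np.sign(resid_end)
    s[s == 0] = 1.0
    return (s[:, None] * (headings - omega0 * t[None, :])).mean(axis=0)


def _quad_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    design = np.column_stack([np.ones_like(t), t, t * t])
    (a, b, c), *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(a), float(b), float(c)


def fit_sigma_tau(
    headings: np.ndarray,
    omega0: float,
    dt: float,
    n_boot: int = 1000,
    seed: int = 0,
    model: str = "quadratic",
) -> tuple[float, float, tuple, tuple]:
    """Estimate (sigma_omega, tau) from the sign-weighted ensemble drift.

    ``headings`` is (n_animals, K); the drift curve is fitted on the
    heading time grid t_k = k dt.  ``model='quadratic'`` uses the
    second-order expansion (the estimator's defining form);
    ``model='exponential'`` fits the full saturating curve instead.
    Returns (sigma_omega, tau, sigma_ci, tau_ci) with 95% percentile
    bootstrap intervals over animals.
    """
    headings = np.asarray(headings, dtype=float)
    if headings.ndim != 2 or headings.shape[0] < 3:
        raise ValueError("need a (n_animals >= 3, K) heading matrix")
    K = headings.shape[1]
    t = np.arange(K) * dt

    def estimate(h: np.ndarray, w0: float) -> tuple[float, float]:
        y = _signed_drift(h, w0, t)
        if model == "quadratic":
            _, b, c = _quad_fit(t, y)
            if b <= 0:
                raise FloatingPointError("drift curve does not rise")
            if c >= 0:
                # no concave curvature within the window: the relaxation
                # time cannot be identified from this sample
                return b * np.sqrt(np.pi / 2.0), np.nan
            return b * np.sqrt(np.pi / 2.0), -b / (2.0 * c)
        elif model == "exponential":
            def f(tt, th0, sig, tau):
                return th0 + np.sqrt(2 / np.pi) * sig * tau * (1 - np.exp(-tt / tau))
            p0 = (y[0], 0.1, t[-1])
            popt, _ = curve_fit(f, t, y, p0=p0, maxfev=10000)
            return abs(popt[1]), abs(popt[2])
        raise ValueError(f"unknown model {model!r}")

    sigma, tau = estimate(headings, omega0)
    rng = np.random.default_rng(seed)
    n = headings.shape[0]
    sig_bs, tau_bs = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        h = headings[idx]
        w0 = (h[:, -1] - h[:, 0]).mean() / t[-1] if t[-1] > 0 else omega0
        try:
            sg, tu = estimate(h, w0)
        except (FloatingPointError, RuntimeError):
            continue
        sig_bs.append(sg)
        if np.isfinite(tu):
            tau_bs.append(tu)
    floor = max(20, n_boot // 10)
    sigma_ci = (
        tuple(np.percentile(sig_bs, [2.5, 97.5]))
        if len(sig_bs) >= floor else (np.nan, np.nan)
    )
    tau_ci = (
        tuple(np.percentile(tau_bs, [2.5, 97.5]))
        if len(tau_bs) >= floor else (np.nan, np.nan)
    )
    return float(sigma), float(tau), sigma_ci, tau_ci


def estimate_motility(
    tracks: TrackSet,
    n_boot: int = 1000,
    seed: int = 0,
    model: str = "quadratic",
) -> MotilityEstimate:
    """Full single-track estimation pipeline on a TrackSet."""
    v0, v0_sd = estimate_v0(tracks)
    H = _heading_matrix(tracks)
    t_e = tracks.t_end
    omega0, omega0_se = estimate_omega0(H, t_e)
    sigma, tau, sig_ci, tau_ci = fit_sigma_tau(
        H, omega0, tracks.dt, n_boot=n_boot, seed=seed, model=model
    )
    return MotilityEstimate(
        v0=v0,
        v0_sd=v0_sd,
        omega0=omega0,
        omega0_se=omega0_se,
        sigma_omega=sigma,
        tau=tau,
        sigma_omega_ci=sig_ci,
        tau_ci=tau_ci,
        t_e=t_e,
        n_animals=tracks.n_animals,
    )


def to_dimensionless(
    est: MotilityEstimate,
    half_body_length: float,
) -> DimensionlessMotility:
    """Convert estimates to simulation units.

    length unit = half body length; time unit = length unit / v0 (the
    average time during movement over half a body length); then
    omega0' = omega0 * time_unit, sigma' = sigma_omega * time_unit,
    tau' = tau / time_unit.
    """
    if half_body_length <= 0:
        raise ValueError("half_body_length must be positive")
    tu = half_body_length / est.v0
    return DimensionlessMotility(
        length_unit=half_body_length,
        time_unit=tu,
        omega0=est.omega0 * tu,
        sigma_omega=est.sigma_omega * tu,
        tau=est.tau / tu,
    )


def _mean_direction(track: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Direction of the net displacement between samples lo..hi."""
    v = track[hi] - track[lo]
    norm = np.hypot(*v)
    if norm == 0:
        raise ValueError("zero net displacement in collision window")
    return v / norm


def collision_angles(
    track_a: np.ndarray,
    track_b: np.ndarray,
    contact_index: int,
    window: int = 10,
    dt: float = 1.0,
) -> CollisionEvent:
    """Incoming and outgoing angle of a pair collision.

    The incoming (outgoing) angle is the full angle in [0, pi] between
    the two animals' mean directions of motion over the ``window``
    samples before (after) contact.  Swapping the tracks leaves both
    angles unchanged.
    """
    track_a = np.asarray(track_a, dtype=float)
    track_b = np.asarray(track_b, dtype=float)
    if contact_index - window < 0 or contact_index + window >= len(track_a):
        raise ValueError("window exceeds track support around the contact")
    ua = _mean_direction(track_a, contact_index - window, contact_index)
    ub = _mean_direction(track_b, contact_index - window, contact_index)
    va = _mean_direction(track_a, contact_index, contact_index + window)
    vb = _mean_direction(track_b, contact_index, contact_index + window)
    incoming = float(np.arccos(np.clip(ua @ ub, -1.0, 1.0)))
    outgoing = float(np.arccos(np.clip(va @ vb, -1.0, 1.0)))
    return CollisionEvent(incoming, outgoing, contact_index * dt)
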