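"""Enhancer Switching model of gene-expression waves.

A row of cells, each carrying a three-gene circuit in which every gene is
driven by two enhancers: a *dynamic* enhancer wiring the genes into a
repressilator-like clock, and a *static* enhancer wiring them into a
multi-stable network. A morphogen gradient, the speed regulator ``R``
(anterior low, posterior high, ``0 <= R <= 1``), activates the dynamic
enhancers (multiplication by ``R``) and represses the static ones
(multiplication by ``1 - R``). Posterior cells therefore oscillate quickly,
anterior cells freeze into stable states, and the phase gradient in between
is seen as expression waves that sweep from posterior to anterior before
stabilizing into stripes.

Per cell, with gene activities ``G_1..G_3``::

    D_i = R * 1 / (1 + G_succ(i)^n)          succ: 1->2, 2->3, 3->1
    S_i = (1-R) * G_i^n/(1+G_i^n) * prod_{j != i} 1/(1+G_j^n)
    dG_i/dt = alpha_i * D_i + beta_i * S_i - lambda * G_i

Optional reporter genes read out one gene's dynamic and static enhancer
separately::

    dRD/dt = D_g - lambda * RD
    dRS/dt = S_g - lambda * RS

Cells are independent (no cell-cell coupling) and the dynamics are
deterministic; an optional seed only jitters initial conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .constants import SPECIES

__all__ = [
    "GRNParameters",
    "SpeedProfile",
    "SimulationResult",
    "IntegrationError",
    "DEFAULT_PARAMS",
    "WEAK_STATIC_PARAMS",
    "dynamic_activity",
    "static_activity",
    "gene_rhs",
    "reporter_rhs",
    "make_speed_profile",
    "deletion_experiment",
    "simulate",
    "measure_period",
]

_SUCC = (1, 2, 0)  # succ(i): gene repressing D_i (0-based: D1<-G2, D2<-G3, D3<-G1)


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


@dataclass(frozen=True)
class GRNParameters:
    """Kinetic parameters of the three-gene enhancer-switching circuit.

    Parameters
    ----------
    n : float
        Hill coefficient of all regulatory interactions (dimensionless, > 0).
    lam : float
        First-order mRNA decay rate ``lambda`` (1/time, > 0).
    alpha : 3-tuple of float
        Strengths of the dynamic enhancers (1/time, >= 0).
    beta : 3-tuple of float
        Strengths of the static enhancers (1/time, >= 0).
    """

    n: float = 5.0
    lam: float = 0.5
    alpha: tuple[float, float, float] = (1.5, 1.5, 1.5)
    beta: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        if len(self.alpha) != 3 or len(self.beta) != 3:
            raise ValueError("alpha and beta must each have exactly 3 entries")
        vals = (self.n, self.lam, *self.alpha, *self.beta)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all parameters must be finite")
        if self.n <= 0:
            raise ValueError(f"Hill coefficient n must be > 0, got {self.n}")
        if self.lam <= 0:
            raise ValueError(f"decay rate lam must be > 0, got {self.lam}")
        if any(a < 0 for a in self.alpha) or any(b < 0 for b in self.beta):
            raise ValueError("enhancer strengths alpha, beta must be >= 0")


#: Strong static stabilization: waves resolve into persistent anterior stripes.
DEFAULT_PARAMS = GRNParameters(n=5.0, lam=0.5, alpha=(1.5, 1.5, 1.5), beta=(1.0, 1.0, 1.0))

#: Weakened static enhancers: anterior stripes form but decay after formation.
WEAK_STATIC_PARAMS = GRNParameters(n=5.0, lam=0.5, alpha=(1.5, 1.5, 1.5), beta=(0.5, 0.5, 0.5))


@dataclass(frozen=True)
class SpeedProfile:
    """Speed-regulator concentration per cell along the AP axis.

    ``R[0]`` is the anterior-most cell. Values lie in ``[0, 1]``. The profile
    is static by default; ``retraction_rate`` > 0 makes the gradient retract
    toward the posterior over time (anterior cells see ``R`` fall), mimicking
    the posterior-ward withdrawal of the morphogen source:
    ``R(x, t) = R0(x - rate * t)`` with the anterior value extended leftward.
    """

    R: np.ndarray
    retraction_rate: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 1 or R.size < 1:
            raise ValueError("R must be a 1-D vector with at least one cell")
        if not np.all(np.isfinite(R)):
            raise ValueError("R must be finite")
        if R.min() < 0.0 or R.max() > 1.0:
            raise ValueError("speed-regulator values must lie in [0, 1]")
        object.__setattr__(self, "R", R)

    @property
    def n_cells(self) -> int:
        return self.R.size

    def at_time(self, t: float) -> np.ndarray:
        """Profile at time ``t`` (equals ``R`` unless retracting)."""
        if self.retraction_rate == 0.0 or t == 0.0:
            return self.R
        x = np.arange(self.n_cells, dtype=float) - self.retraction_rate * t
        return np.interp(x, np.arange(self.n_cells, dtype=float), self.R)


def make_speed_profile(
    n_cells: int,
    shape: Literal["linear", "exponential", "custom"] = "linear",
    *,
    minimum: float = 0.0,
    maximum: float = 1.0,
    decay_length: float = 20.0,
    values: Sequence[float] | None = None,
    retraction_rate: float = 0.0,
) -> SpeedProfile:
    """Build a speed-regulator gradient over ``n_cells`` cells.

    Built-in shapes are monotone non-decreasing from anterior (index 0) to
    posterior. ``linear`` ramps from ``minimum`` to ``maximum``;
    ``exponential`` decays anterior-ward from the posterior end with length
    scale ``decay_length`` (in cells): ``R[k] = exp(-(n_cells-1-k)/decay_length)``.
    ``custom`` takes ``values`` verbatim (must lie in [0, 1]).
    """
    if n_cells < 2 and shape != "custom":
        raise ValueError("built-in profiles need n_cells >= 2")
    if shape == "linear":
        if not (0.0 <= minimum <= maximum <= 1.0):
            raise ValueError("need 0 <= minimum <= maximum <= 1")
        R = np.linspace(minimum, maximum, n_cells)
    elif shape == "exponential":
        if decay_length <= 0:
            raise ValueError("decay_length must be > 0")
        R = np.exp(-(n_cells - 1 - np.arange(n_cells)) / decay_length)
    elif shape == "custom":
        if values is None:
            raise ValueError("custom profile requires values")
        R = np.asarray(values, dtype=float)
    else:
        raise ValueError(f"unknown profile shape {shape!r}")
    return SpeedProfile(R=R, retraction_rate=retraction_rate)


# ---------------------------------------------------------------------------
# Regulatory functions (instantaneous algebraic form)
# ---------------------------------------------------------------------------

def _check_G_R(G: np.ndarray, R: np.ndarray) -> None:
    if np.any(G < 0) or not np.all(np.isfinite(G)):
        raise ValueError("gene activities must be finite and >= 0")
    if np.any(R < 0) or np.any(R > 1):
        raise ValueError("speed regulator R must lie in [0, 1]")


def _dynamic_kernel(G: np.ndarray, R: np.ndarray, n: float) -> np.ndarray:
    # G: (..., 3), R: (...); D_i = R / (1 + G_succ(i)^n)
    Gn = np.power(G, n)
    return R[..., None] / (1.0 + Gn[..., _SUCC])


def _static_kernel(G: np.ndarray, R: np.ndarray, n: float) -> np.ndarray:
    # S_i = (1-R) * G_i^n/(1+G_i^n) * 1/(1+G_j^n) * 1/(1+G_k^n), j,k != i
    Gn = np.power(G, n)
    rep = 1.0 / (1.0 + Gn)
    act = Gn * rep
    return (1.0 - R)[..., None] * act * rep[..., [1, 2, 0]] * rep[..., [2, 0, 1]]


def dynamic_activity(G: Sequence[float], R: float, params: GRNParameters) -> np.ndarray:
    """Dynamic-enhancer activities ``D_i = R / (1 + G_succ(i)^n)``.

    The dynamic enhancers wire the clock: each gene's dynamic enhancer is
    repressed by the next gene in the cycle (1->2->3->1) and activated by the
    speed regulator. Each ``D_i`` lies in ``[0, R]``.
    """
    G = np.asarray(G, dtype=float)
    Rv = np.asarray(R, dtype=float)
    if G.shape[-1] != 3:
        raise ValueError("G must hold 3 gene activities")
    _check_G_R(G, Rv)
    return _dynamic_kernel(G, Rv, params.n)


def static_activity(G: Sequence[float], R: float, params: GRNParameters) -> np.ndarray:
    """Static-enhancer activities of the multi-stable network.

    ``S_i = (1-R) * [G_i^n/(1+G_i^n)] * prod_{j != i} 1/(1+G_j^n)``: each gene's
    static enhancer requires self-activation and is repressed by the other two
    genes and by the speed regulator. Each ``S_i`` lies in ``[0, 1-R]`` and is
    zero whenever ``G_i`` is zero.
    """
    G = np.asarray(G, dtype=float)
    Rv = np.asarray(R, dtype=float)
    if G.shape[-1] != 3:
        raise ValueError("G must hold 3 gene activities")
    _check_G_R(G, Rv)
    return _static_kernel(G, Rv, params.n)


def gene_rhs(
    G: Sequence[float], D: Sequence[float], S: Sequence[float], params: GRNParameters
) -> np.ndarray:
    """Time derivative ``dG_i/dt = alpha_i * D_i + beta_i * S_i - lambda * G_i``."""
    G, D, S = (np.asarray(a, dtype=float) for a in (G, D, S))
    if not (G.shape == D.shape == S.shape) or G.shape[-1] != 3:
        raise ValueError("G, D, S must share shape (..., 3)")
    return np.asarray(params.alpha) * D + np.asarray(params.beta) * S - params.lam * G


def reporter_rhs(enhancer_activity: float, reporter_level: float, params: GRNParameters):
    """Reporter dynamics ``d(level)/dt = activity - lambda * level``.

    An in-silico reporter transcribes at the rate of the enhancer it carries
    and decays like any other transcript.
    """
    a = np.asarray(enhancer_activity, dtype=float)
    r = np.asarray(reporter_level, dtype=float)
    if np.any(a < 0) or np.any(r < 0):
        raise ValueError("enhancer activity and reporter level must be >= 0")
    return a - params.lam * r


def deletion_experiment(
    params: GRNParameters, which: Literal["static", "dynamic"], gene: int
) -> GRNParameters:
    """Parameters for an in-silico enhancer deletion.

    Deleting a gene's static enhancer sets ``beta_gene = 0``; deleting its
    dynamic enhancer sets ``alpha_gene = 0``. ``gene`` is 1-based (1..3).
    Idempotent: deleting an already-deleted enhancer changes nothing.
    """
    if gene not in (1, 2, 3):
        raise ValueError(f"gene must be 1, 2 or 3, got {gene!r}")
    i = gene - 1
    if which == "static":
        beta = list(params.beta)
        beta[i] = 0.0
        return replace(params, beta=tuple(beta))
    if which == "dynamic":
        alpha = list(params.alpha)
        alpha[i] = 0.0
        return replace(params, alpha=tuple(alpha))
    raise ValueError(f"which must be 'static' or 'dynamic', got {which!r}")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Trajectory of all species over (time step x cell x species).

    ``activity[k, c, s]`` is species ``SPECIES[s]`` in cell ``c`` at
    ``times[k]``. Enhancer activities D/S are the instantaneous regulatory
    functions of the recorded gene state (or integrated states in relaxation
    mode). ``profile`` and ``params`` are the inputs used; ``metadata``
    records integrator, step size, initial conditions and seed.
    """

    activity: np.ndarray
    times: np.ndarray
    dt: float
    t_max: float
    profile: SpeedProfile
    params: GRNParameters
    species: tuple[str, ...] = SPECIES
    metadata: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.activity.shape[1]

    def get(self, species: str) -> np.ndarray:
        """(time x cell) slice for one species name."""
        try:
            idx = self.species.index(species)
        except ValueError:
            raise KeyError(f"unknown species {species!r}; have {self.species}") from None
        return self.activity[:, :, idx]

    def to_dataframe(self):
        """Long-format table with columns t, cell, species, value."""
        import pandas as pd

        k, c, s = self.activity.shape
        return pd.DataFrame(
            {
                "t": np.repeat(self.times, c * s),
                "cell": np.tile(np.repeat(np.arange(c), s), k),
                "species": np.tile(np.array(self.species), k * c),
                "value": self.activity.ravel(),
            }
        )

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset(
                "activity", data=self.activity, compression="gzip", track_times=False
            )
            f.create_dataset("times", data=self.times, track_times=False)
            f.create_dataset("profile_R", data=self.profile.R, track_times=False)
            f.attrs["dt"] = self.dt
            f.attrs["t_max"] = self.t_max
            f.attrs["retraction_rate"] = self.profile.retraction_rate
            f.attrs["species"] = ",".join(self.species)
            f.attrs["n"] = self.params.n
            f.attrs["lam"] = self.params.lam
            f.attrs["alpha"] = self.params.alpha
            f.attrs["beta"] = self.params.beta
            for key, val in self.metadata.items():
                f.attrs[f"meta_{key}"] = str(val)

    @classmethod
    def load_hdf5(cls, path) -> "SimulationResult":
        import h5py

        with h5py.File(path, "r") as f:
            params = GRNParameters(
                n=float(f.attrs["n"]),
                lam=float(f.attrs["lam"]),
                alpha=tuple(f.attrs["alpha"]),
                beta=tuple(f.attrs["beta"]),
            )
            profile = SpeedProfile(
                R=f["profile_R"][:], retraction_rate=float(f.attrs["retraction_rate"])
            )
            meta = {
                k[5:]: f.attrs[k] for k in f.attrs if isinstance(k, str) and k.startswith("meta_")
            }
            return cls(
                activity=f["activity"][:],
                times=f["times"][:],
                dt=float(f.attrs["dt"]),
                t_max=float(f.attrs["t_max"]),
                profile=profile,
                params=params,
                species=tuple(str(f.attrs["species"]).split(",")),
                metadata=meta,
            )


def _default_ics(n_cells: int) -> np.ndarray:
    # Symmetric all-zero ICs are a fixed point of the posterior clock and
    # never ignite; seed the first gene instead.
    G0 = np.zeros((n_cells, 3))
    G0[:, 0] = 1.0
    return G0


def simulate(
    params: GRNParameters,
    profile: SpeedProfile,
    ics: np.ndarray | Sequence[float] | None = None,
    *,
    integrator: Literal["euler", "rk4"] = "euler",
    dt: float = 0.01,
    t_max: float = 60.0,
    track_reporters: bool = True,
    reporter_gene: int = 2,
    ds_mode: Literal["algebraic", "relaxation"] = "algebraic",
    relaxation_tau: float = 1.0,
    record_every: int = 1,
    ic_jitter: float = 0.0,
    seed: int | None = None,
) -> SimulationResult:
    """Integrate the enhancer-switching circuit in every cell of ``profile``.

    Cells are independent; the only spatial structure is the speed-regulator
    gradient. By default D/S are instantaneous algebraic functions of the
    current gene state; ``ds_mode='relaxation'`` instead integrates them as
    ODE states with a first-order lag ``dD/dt = (D_target - D)/tau`` for
    sensitivity analysis (do not mix modes within a comparison).

    Reporters (RD, RS) read out ``reporter_gene``'s dynamic and static
    enhancer. ``record_every`` thins the stored trajectory (the integration
    step is always ``dt``).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_max < dt:
        raise ValueError("t_max must be >= dt")
    if integrator == "euler" and dt * params.lam >= 1.0:
        raise ValueError("euler requires dt * lam < 1 for positivity")
    if reporter_gene not in (1, 2, 3):
        raise ValueError("reporter_gene must be 1, 2 or 3")
    if record_every < 1:
        raise ValueError("record_every must be >= 1")

    n_cells = profile.n_cells
    if ics is None:
        G = _default_ics(n_cells)
    else:
        G = np.asarray(ics, dtype=float)
        if G.ndim == 1:
            G = np.broadcast_to(G, (n_cells, 3)).copy()
        if G.shape != (n_cells, 3):
            raise ValueError(f"ics must have shape ({n_cells}, 3)")
        if np.any(G < 0):
            raise ValueError("initial gene activities must be >= 0")
        G = G.copy()
    rng = np.random.default_rng(seed)
    if ic_jitter > 0.0:
        G = np.clip(G + rng.normal(0.0, ic_jitter, G.shape), 0.0, None)

    rg = reporter_gene - 1
    n = params.n
    alpha = np.asarray(params.alpha)
    beta = np.asarray(params.beta)
    lam = params.lam
    relax = ds_mode == "relaxation"
    if relax and relaxation_tau <= 0:
        raise ValueError("relaxation_tau must be > 0")
    if relax and integrator == "euler" and dt >= relaxation_tau:
        raise ValueError("euler relaxation mode requires dt < relaxation_tau")

    n_steps = int(round(t_max / dt))
    rec_idx = list(range(0, n_steps + 1, record_every))
    if rec_idx[-1] != n_steps:
        rec_idx.append(n_steps)
    out = np.empty((len(rec_idx), n_cells, len(SPECIES)))
    times = np.asarray(rec_idx, dtype=float) * dt

    RD = np.zeros(n_cells)
    RS = np.zeros(n_cells)
    static_R = profile.retraction_rate == 0.0
    R = profile.at_time(0.0)
    D = _dynamic_kernel(G, R, n)
    S = _static_kernel(G, R, n)

    def rhs(G, D, S, RD, RS, R):
        Dt = _dynamic_kernel(G, R, n)
        St = _static_kernel(G, R, n)
        if relax:
            dD = (Dt - D) / relaxation_tau
            dS = (St - S) / relaxation_tau
            Duse, Suse = D, S
        else:
            dD = dS = None
            Duse, Suse = Dt, St
        dG = alpha * Duse + beta * Suse - lam * G
        dRD = Duse[:, rg] - lam * RD
        dRS = Suse[:, rg] - lam * RS
        return dG, dD, dS, dRD, dRS

    def record(row, G, D, S, RD, RS, R):
        if not relax:
            D = _dynamic_kernel(G, R, n)
            S = _static_kernel(G, R, n)
        out[row, :, 0:3] = G
        out[row, :, 3:6] = D
        out[row, :, 6:9] = S
        out[row, :, 9] = RD
        out[row, :, 10] = RS

    row = 0
    rec_set = set(rec_idx)
    if 0 in rec_set:
        record(row, G, D, S, RD, RS, R)
        row += 1

    for step in range(1, n_steps + 1):
        t_prev = (step - 1) * dt
        if not static_R:
            R = profile.at_time(t_prev)
        if integrator == "euler":
            dG, dD, dS, dRD, dRS = rhs(G, D, S, RD, RS, R)
            G = G + dt * dG
            RD = RD + dt * dRD
            RS = RS + dt * dRS
            if relax:
                D = D + dt * dD
                S = S + dt * dS
        elif integrator == "rk4":
            state = (G, D, S, RD, RS)

            def deriv(st, R):
                return rhs(*st, R)

            R_mid = R if static_R else profile.at_time(t_prev + dt / 2)
            R_end = R if static_R else profile.at_time(t_prev + dt)
            k1 = deriv(state, R)
            s2 = _advance(state, k1, dt / 2, relax)
            k2 = deriv(s2, R_mid)
            s3 = _advance(state, k2, dt / 2, relax)
            k3 = deriv(s3, R_mid)
            s4 = _advance(state, k3, dt, relax)
            k4 = deriv(s4, R_end)
            G = G + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            RD = RD + dt / 6 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
            RS = RS + dt / 6 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
            if relax:
                D = D + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
                S = S + dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        else:
            raise ValueError(f"unknown integrator {integrator!r}")
        # rk4 can undershoot zero by O(dt^5); clamp tiny negatives
        G = np.maximum(G, 0.0)
        RD = np.maximum(RD, 0.0)
        RS = np.maximum(RS, 0.0)
        if not np.all(np.isfinite(G)):
            bad = np.argwhere(~np.isfinite(G))[0]
            raise IntegrationError(
                f"non-finite gene activity at step {step} (t={step * dt:.4g}), "
                f"cell {bad[0]}, gene {bad[1] + 1}"
            )
        if step in rec_set:
            R_now = R if static_R else profile.at_time(step * dt)
            record(row, G, D, S, RD, RS, R_now)
            row += 1

    return SimulationResult(
        activity=out,
        times=times,
        dt=dt,
        t_max=t_max,
        profile=profile,
        params=params,
        metadata={
            "integrator": integrator,
            "ds_mode": ds_mode,
            "reporter_gene": reporter_gene,
            "ics": "default G=(1,0,0)" if ics is None else "user",
            "ic_jitter": ic_jitter,
            "seed": seed,
        },
    )


def _advance(state, k, h, relax):
    G, D, S, RD, RS = state
    dG, dD, dS, dRD, dRS = k
    G2 = np.maximum(G + h * dG, 0.0)
    RD2 = np.maximum(RD + h * dRD, 0.0)
    RS2 = np.maximum(RS + h * dRS, 0.0)
    if relax:
        return (G2, D + h * dD, S + h * dS, RD2, RS2)
    return (G2, D, S, RD2, RS2)


def measure_period(series: np.ndarray, times: np.ndarray, *, min_prominence: float = 0.05):
    """Oscillation period from the mean spacing of local maxima.

    Returns ``nan`` if fewer than two maxima are found. ``min_prominence`` is
    relative to the series range.
    """
    from scipy.signal import find_peaks

    series = np.asarray(series, dtype=float)
    rng = series.max() - series.min()
    if rng <= 0:
        return float("nan")
    peaks, _ = find_peaks(series, prominence=min_prominence * rng)
    if len(peaks) < 2:
        return float("nan")
    return float(np.mean(np.diff(np.asarray(times)[peaks])))
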