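"""Three-population neural-mass simulation of postsynaptic membrane potential.

A single population follows the Wendling variant of the Jansen–Rit model:
four coupled second-order ODEs describing pyramidal cells, excitatory
interneurons and two inhibitory interneuron pools (slow and fast kinetics).
Three such populations, tuned to the low (4–12 Hz), medium (12–30 Hz) and
high (>30 Hz) EEG bands, run in parallel and are mixed by nonnegative
weights to form the source potential that later feeds the dipole forward
model.

Two readings of the fast-inhibitory drive are supported (``fast_inhibition``):

``"state"`` (default)
    Sigm[C5*y0 - C6*y2], i.e. the fast interneurons are inhibited by the
    slow-inhibition synaptic state. In these scaled variables this is the
    original Wendling form (the slow-inhibition output feeding the fast
    cells obeys the same ODE as y2), and it is the only variant whose fast
    loop is ever active: it yields the documented band-specific spectral
    peaks.
``"nested"``
    Sigm[C5*y0 - C6*Sigm(C3*y0)]. With the shipped connectivity constants
    the nested term saturates near 2*e0 so the argument stays far below
    threshold, the fast loop never engages and all three parameter sets
    relax to a heavily damped fixed point with no band-tuned resonance.
    Kept for reference.

The high-band parameter set is bistable: besides the gamma-band limit cycle
it has a quiet stable equilibrium whose basin contains the origin. Unless a
``state0`` is given, integration therefore starts from the equilibrium with
the largest pyramidal input (see :func:`equilibrium_state`), which selects
the oscillatory attractor where one exists and is the unique fixed point for
the low and medium sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

__all__ = [
    "SigmoidParams",
    "ConnectivityParams",
    "PopulationParams",
    "NMMState",
    "ExogenousInputSpec",
    "BandDefinition",
    "PopulationWeights",
    "DEFAULT_SIGMOID",
    "DEFAULT_CONNECTIVITY",
    "BAND_PARAMS",
    "DEFAULT_BANDS",
    "REFERENCE_WEIGHTS",
    "DivergenceError",
    "sigmoid",
    "nmm_derivatives",
    "exogenous_noise",
    "integrate_population",
    "integrate_populations_batch",
    "mix_populations",
    "band_weights_from_reference",
    "welch_psd",
    "dominant_frequency",
]


class DivergenceError(RuntimeError):
    """Raised when the state of an integration exceeds the blow-up bound."""


@dataclass(frozen=True)
class SigmoidParams:
    """Static nonlinearity converting membrane potential to firing rate."""

    e0: float = 2.5  # half of maximum firing rate, 1/s
    s0: float = 6.0  # mean firing threshold, mV
    r: float = 0.56  # slope, 1/mV

    def __post_init__(self) -> None:
        if not (self.e0 > 0 and self.r > 0):
            raise ValueError("sigmoid requires e0 > 0 and r > 0")


@dataclass(frozen=True)
class ConnectivityParams:
    """Dimensionless coupling constants between neural subgroups."""

    C1: float = 135.0
    C2: float = 108.0
    C3: float = 33.75
    C4: float = 33.75
    C5: float = 40.5
    C6: float = 13.5
    C7: float = 108.0

    def __post_init__(self) -> None:
        if any(getattr(self, f"C{i}") < 0 for i in range(1, 8)):
            raise ValueError("connectivity constants must be >= 0")


@dataclass(frozen=True)
class PopulationParams:
    """Synaptic gains (mV) and lumped rate constants (1/s) of one population."""

    band: str
    A: float
    B: float
    G: float
    a: float
    b: float
    g: float

    def __post_init__(self) -> None:
        if not all(v > 0 for v in (self.A, self.B, self.G, self.a, self.b, self.g)):
            raise ValueError("gains and rate constants must be > 0")


@dataclass(frozen=True)
class NMMState:
    """Four state variables (mV) and their first time-derivatives (mV/s)."""

    y0: float = 0.0
    y1: float = 0.0
    y2: float = 0.0
    y3: float = 0.0
    dy0: float = 0.0
    dy1: float = 0.0
    dy2: float = 0.0
    dy3: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.y0, self.y1, self.y2, self.y3, self.dy0, self.dy1, self.dy2, self.dy3],
            dtype=float,
        )

    @classmethod
    def from_array(cls, x: np.ndarray) -> "NMMState":
        return cls(*(float(v) for v in np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class ExogenousInputSpec:
    """Gaussian exogenous drive P(t): i.i.d. samples, one per integration step."""

    mean: float = 60.0
    variance: float = 100.0
    seed: int = 0
    n: int = 1000
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_low: float
    f_high: float  # may be np.inf for an open-ended band

    def __post_init__(self) -> None:
        if not self.f_low < self.f_high:
            raise ValueError("band requires f_low < f_high")


@dataclass(frozen=True)
class PopulationWeights:
    w_low: float
    w_medium: float
    w_high: float

    def __post_init__(self) -> None:
        w = (self.w_low, self.w_medium, self.w_high)
        if any(v < 0 for v in w):
            raise ValueError("weights must be >= 0")
        if all(v == 0 for v in w):
            raise ValueError("weights must not all be zero")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_low, self.w_medium, self.w_high], dtype=float)


DEFAULT_SIGMOID = SigmoidParams()
DEFAULT_CONNECTIVITY = ConnectivityParams()

#: Band-specific synaptic gains and rate constants.
BAND_PARAMS: dict[str, PopulationParams] = {
    "low": PopulationParams("low", A=2.7, B=3.2, G=27.0, a=40.0, b=20.0, g=300.0),
    "medium": PopulationParams("medium", A=5.2, B=4.5, G=43.0, a=85.0, b=30.0, g=350.0),
    "high": PopulationParams("high", A=5.6, B=3.8, G=75.0, a=110.0, b=40.0, g=400.0),
}

DEFAULT_BANDS: tuple[BandDefinition, BandDefinition, BandDefinition] = (
    BandDefinition("low", 4.0, 12.0),
    BandDefinition("medium", 12.0, 30.0),
    BandDefinition("high", 30.0, 55.0),
)

#: Per-class mixing weights derived from band energies of a reference session.
REFERENCE_WEIGHTS: dict[str, PopulationWeights] = {
    "mRB": PopulationWeights(0.1190, 0.3332, 0.5478),
    "mFB": PopulationWeights(0.0845, 0.0487, 0.0357),
    "mLS": PopulationWeights(0.0887, 0.0574, 0.0467),
    "mRS": PopulationWeights(0.0996, 0.0550, 0.0509),
}

_BLOWUP = 1e6  # mV; any |state| beyond this is treated as divergence


def sigmoid(v, sp: SigmoidParams = DEFAULT_SIGMOID):
    """Firing rate 2*e0 / (1 + exp(r*(s0 - v))) for membrane potential ``v`` (mV)."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    arg = np.clip(sp.r * (sp.s0 - v), -700.0, 700.0)
    out = 2.0 * sp.e0 / (1.0 + np.exp(arg))
    return float(out) if out.ndim == 0 else out


def nmm_derivatives(
    s: NMMState,
    pp: PopulationParams,
    cp: ConnectivityParams = DEFAULT_CONNECTIVITY,
    sp: SigmoidParams = DEFAULT_SIGMOID,
    p: float = 0.0,
    fast_inhibition: str = "state",
) -> NMMState:
    """Time-derivative of the 8-dimensional first-order state."""
    x = s.as_array()
    dx = _derivs(
        x[None, :], pp_arrays(pp), cp, sp, np.array([p], dtype=float),
        fast_inhibition,
    )[0]
    return NMMState.from_array(dx)


def pp_arrays(pp: PopulationParams | list[PopulationParams]) -> dict[str, np.ndarray]:
    """Stack population parameters into per-field arrays for batch integration."""
    pps = [pp] if isinstance(pp, PopulationParams) else list(pp)
    return {
        k: np.array([getattr(q, k) for q in pps], dtype=float)
        for k in ("A", "B", "G", "a", "b", "g")
    }


def _derivs(x, pa, cp: ConnectivityParams, sp: SigmoidParams, p,
            fast_inhibition: str = "state"):
    """Vectorized RHS; ``x`` is (batch, 8), ``p`` (batch,), ``pa`` broadcastable."""
    y0, y1, y2, y3 = x[:, 0], x[:, 1], x[:, 2], x[:, 3]
    d0, d1, d2, d3 = x[:, 4], x[:, 5], x[:, 6], x[:, 7]
    A, B, G = pa["A"], pa["B"], pa["G"]
    a, b, g = pa["a"], pa["b"], pa["g"]

    def sigm(v):
        return 2.0 * sp.e0 / (1.0 + np.exp(sp.r * (sp.s0 - v)))

    v_pyr = cp.C2 * y1 - cp.C4 * y2 - cp.C7 * y3
    s3 = sigm(cp.C3 * y0)
    if fast_inhibition == "state":
        fast_arg = cp.C5 * y0 - cp.C6 * y2
    elif fast_inhibition == "nested":
        fast_arg = cp.C5 * y0 - cp.C6 * s3
    else:
        raise ValueError("fast_inhibition must be 'state' or 'nested'")
    out = np.empty_like(x)
    out[:, 0] = d0
    out[:, 1] = d1
    out[:, 2] = d2
    out[:, 3] = d3
    out[:, 4] = A * a * sigm(v_pyr) - 2.0 * a * d0 - a * a * y0
    out[:, 5] = A * a * (sigm(cp.C1 * y0) + p / cp.C2) - 2.0 * a * d1 - a * a * y1
    out[:, 6] = B * b * s3 - 2.0 * b * d2 - b * b * y2
    out[:, 7] = G * g * sigm(fast_arg) - 2.0 * g * d3 - g * g * y3
    return out


def equilibrium_state(
    pp: PopulationParams,
    cp: ConnectivityParams = DEFAULT_CONNECTIVITY,
    sp: SigmoidParams = DEFAULT_SIGMOID,
    p_mean: float = 60.0,
    fast_inhibition: str = "state",
    v_range: tuple[float, float] = (-80.0, 80.0),
) -> NMMState:
    """Fixed point of the population with the largest pyramidal input.

    Equilibria are roots of a scalar self-consistency function of the
    pyramidal input v; they are bracketed on a fine grid and refined by
    bisection. Velocity components of the returned state are zero.
    """

    def sigm(v):
        return 2.0 * sp.e0 / (1.0 + np.exp(sp.r * (sp.s0 - np.asarray(v, float))))

    def parts(v):
        y0 = (pp.A / pp.a) * sigm(v)
        y2 = (pp.B / pp.b) * sigm(cp.C3 * y0)
        if fast_inhibition == "state":
            arg = cp.C5 * y0 - cp.C6 * y2
        else:
            arg = cp.C5 * y0 - cp.C6 * sigm(cp.C3 * y0)
        y3 = (pp.G / pp.g) * sigm(arg)
        y1 = (pp.A / pp.a) * (sigm(cp.C1 * y0) + p_mean / cp.C2)
        return y0, y1, y2, y3

    def f(v):
        y0, y1, y2, y3 = parts(v)
        return cp.C2 * y1 - cp.C4 * y2 - cp.C7 * y3 - v

    vs = np.linspace(v_range[0], v_range[1], 40001)
    fv = f(vs)
    idx = np.where(np.diff(np.sign(fv)) != 0)[0]
    if idx.size == 0:
        raise RuntimeError("no equilibrium found in the scanned range")
    lo, hi = vs[idx[-1]], vs[idx[-1] + 1]  # largest-v root
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.sign(f(mid)) == np.sign(f(lo)):
            lo = mid
        else:
            hi = mid
    v_star = 0.5 * (lo + hi)
    y0, y1, y2, y3 = (float(q) for q in parts(v_star))
    return NMMState(y0, y1, y2, y3, 0.0, 0.0, 0.0, 0.0)


def exogenous_noise(spec: ExogenousInputSpec) -> np.ndarray:
    """Seeded i.i.d. Gaussian drive with the configured mean and variance."""
    rng = np.random.default_rng(spec.seed)
    return spec.mean + np.sqrt(spec.variance) * rng.standard_normal(spec.n)


def integrate_populations_batch(
    pps: list[PopulationParams],
    noise: np.ndarray,
    dt: float,
    cp: ConnectivityParams = DEFAULT_CONNECTIVITY,
    sp: SigmoidParams = DEFAULT_SIGMOID,
    state0: np.ndarray | None = None,
    gain_scale: np.ndarray | None = None,
    fast_inhibition: str = "state",
) -> np.ndarray:
    """Fixed-step RK4 over a batch of independent populations.

    Parameters
    ----------
    pps
        One parameter set per batch row.
    noise
        Exogenous drive, shape (batch, n_steps). Held constant within the
        four stage evaluations of each RK4 step.
    gain_scale
        Optional per-row multiplicative jitter applied to (A, B, G).

    Returns
    -------
    (batch, n_steps) array of the population observable
    V = C2*y1 - C4*y2 - C7*y3 sampled after each step.
    """
    noise = np.atleast_2d(np.asarray(noise, dtype=float))
    nb, n = noise.shape
    if len(pps) != nb:
        raise ValueError("one parameter set per noise row required")
    pps = [pps] if isinstance(pps, PopulationParams) else list(pps)
    if gain_scale is not None:
        gs = np.asarray(gain_scale, dtype=float)
        pps = [
            PopulationParams(q.band, q.A * s, q.B * s, q.G * s, q.a, q.b, q.g)
            for q, s in zip(pps, gs)
        ]
    pa = pp_arrays(pps)
    if state0 is None:
        x = np.stack(
            [equilibrium_state(q, cp, sp, float(np.mean(noise[i])),
                               fast_inhibition).as_array()
             for i, q in enumerate(pps)]
        )
    else:
        x = np.array(state0, dtype=float)
    if x.shape != (nb, 8):
        raise ValueError("state0 must have shape (batch, 8)")
    out = np.empty((nb, n))
    h = dt
    fi = fast_inhibition
    for i in range(n):
        p = noise[:, i]
        k1 = _derivs(x, pa, cp, sp, p, fi)
        k2 = _derivs(x + 0.5 * h * k1, pa, cp, sp, p, fi)
        k3 = _derivs(x + 0.5 * h * k2, pa, cp, sp, p, fi)
        k4 = _derivs(x + h * k3, pa, cp, sp, p, fi)
        x = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[:, i] = cp.C2 * x[:, 1] - cp.C4 * x[:, 2] - cp.C7 * x[:, 3]
        if i % 256 == 0 and not np.all(np.abs(x) < _BLOWUP):
            bad = int(np.argmax(np.max(np.abs(x), axis=1)))
            raise DivergenceError(
                f"integration diverged for parameter set {pps[bad]!r} at step {i}"
            )
    if not np.all(np.isfinite(out)):
        raise DivergenceError("non-finite output encountered")
    return out


def integrate_population(
    pp: PopulationParams,
    cp: ConnectivityParams = DEFAULT_CONNECTIVITY,
    sp: SigmoidParams = DEFAULT_SIGMOID,
    input_spec: ExogenousInputSpec = ExogenousInputSpec(),
    t_total: float = 10.0,
    burn_in: float = 2.0,
    state0: NMMState | None = None,
    fast_inhibition: str = "state",
) -> np.ndarray:
    """Integrate one population and return V_k(t) with burn-in discarded.

    ``input_spec.n`` is ignored; the number of steps follows ``t_total`` and
    ``input_spec.dt``. When ``state0`` is omitted the integration starts at
    the population's largest-v equilibrium. Identical seeds yield
    bit-identical series.
    """
    if not (t_total > burn_in >= 0):
        raise ValueError("require t_total > burn_in >= 0")
    dt = input_spec.dt
    n = int(round(t_total / dt))
    spec = ExogenousInputSpec(
        mean=input_spec.mean, variance=input_spec.variance, seed=input_spec.seed,
        n=n, dt=dt,
    )
    noise = exogenous_noise(spec)[None, :]
    out = integrate_populations_batch(
        [pp], noise, dt, cp, sp,
        state0=None if state0 is None else state0.as_array()[None, :],
        fast_inhibition=fast_inhibition,
    )[0]
    skip = int(round(burn_in / dt))
    return out[skip:]


def mix_populations(outputs, w: PopulationWeights) -> np.ndarray:
    """Pointwise weighted sum of the three band outputs."""
    arrs = [np.asarray(o, dtype=float) for o in outputs]
    if len(arrs) != 3:
        raise ValueError("exactly three population outputs expected")
    n = arrs[0].shape[-1]
    if any(a.shape[-1] != n for a in arrs):
        raise ValueError("population outputs must have equal length")
    wv = w.as_array()
    return wv[0] * arrs[0] + wv[1] * arrs[1] + wv[2] * arrs[2]


def welch_psd(x: np.ndarray, fs: float, seg_seconds: float = 2.0):
    """Welch PSD with Hann windows of ``seg_seconds`` and 50% overlap."""
    x = np.asarray(x, dtype=float)
    nperseg = min(int(round(seg_seconds * fs)), x.shape[-1])
    return _sig.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)


def dominant_frequency(x: np.ndarray, fs: float, f_min: float = 1.0,
                       f_max: float = 80.0) -> float:
    """Frequency of the largest Welch-PSD value within [f_min, f_max]."""
    f, p = welch_psd(x, fs)
    m = (f >= f_min) & (f <= f_max)
    return float(f[m][np.argmax(p[m])])


def band_weights_from_reference(
    reference: np.ndarray,
    fs: float,
    bands=DEFAULT_BANDS,
    f_total: tuple[float, float] = (4.0, 55.0),
) -> PopulationWeights:
    """Mixing weights from the band-energy profile of a reference recording.

    ``reference`` is (trials, samples, channels) or (samples, channels) or 1-D.
    The PSD is averaged over trials and channels; each weight is the energy in
    its band divided by the energy over the full analysis band ``f_total``
    (clipped at Nyquist), so the three weights need not sum to one.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("reference must be non-empty")
    if ref.ndim == 1:
        ref = ref[None, :, None]
    elif ref.ndim == 2:
        ref = ref[None, :, :]
    f, p = welch_psd(np.moveaxis(ref, 1, -1), fs)  # (trials, channels, nfreq)
    psd = p.reshape(-1, f.size).mean(axis=0)
    nyq = fs / 2.0
    lo_t, hi_t = f_total[0], min(f_total[1], nyq)
    total_mask = (f >= lo_t) & (f <= hi_t)
    total = float(np.trapezoid(psd[total_mask], f[total_mask]))
    if total <= 0:
        raise ValueError("reference has no energy in the analysis band")
    weights = []
    for band in bands:
        hi = min(band.f_high, nyq)
        if hi <= band.f_low:
            raise ValueError(f"band {band.name!r} empty after clipping to Nyquist")
        m = (f >= band.f_low) & (f <= hi)
        weights.append(float(np.trapezoid(psd[m], f[m])) / total)
    return PopulationWeights(*weights)
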