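"""Rate-based circuit model of multimodal signal selection.

A threshold-linear firing-rate network reproducing the dynamics of song
and vibration around optogenetic activation of the central neurons:

* **pC2l** drives the song descending neuron **pIP10** directly and
  excites **P1a** weakly;
* **P1a** drives the vibration descending neuron **DNvib** directly, has
  intrinsically slow activity decay (time constant 5-10 s), and — only
  when strongly activated — engages a recurrent network (**RNN**) whose
  self-excitation sustains activity for tens of seconds, biased more
  strongly toward DNvib than pIP10;
* the two descending neurons inhibit each other through interneurons
  (the DNvib->pIP10 interneuron adapts, acting as a high-pass filter);
  both DNs adapt, and Gaussian noise on their rates enables stochastic
  switching between song and vibration in the persistent phase;
* DN rates map linearly (clipped to [0, 1]) onto the probabilities of
  observing song and vibration.

Integration uses a per-node exponential-Euler update (exact relaxation
toward the drive frozen over the step; Euler-Maruyama for the noise
term) with a 1 ms default step.  Sexual satiation is modeled as a gain
scale on pC2l, P1a and the RNN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .signals import TrialEpochs

__all__ = [
    "CircuitParams",
    "StimulusProtocol",
    "SimResult",
    "simulate",
    "run_trials",
    "ablate_rnn",
    "remove_mutual_inhibition",
    "apply_satiation",
    "decay_timescale",
]

NODES = ("pC2l", "P1a", "RNN", "pIP10", "DNvib", "inh_sv", "inh_vs")


@dataclass(frozen=True)
class CircuitParams:
    """Parameterization of the rate model.

    Time constants in seconds; weights are signed (excitatory >= 0,
    inhibitory <= 0).  ``w_rnn_self`` is the RNN's self-excitation and
    ``theta_rnn`` the drive threshold it must exceed to engage; with
    the defaults the RNN's effective persistence time is in the tens of
    seconds while P1a's intrinsic decay (``tau_p1a``) sits inside
    5-10 s.  ``sigma`` is the SD of the Gaussian noise added to the DN
    rates each step (Euler-Maruyama, scaled by sqrt(dt)).
    """

    # time constants (s)
    tau_pc2l: float = 0.2
    tau_p1a_rise: float = 0.2  # P1a activates quickly ...
    tau_p1a: float = 8.0  # ... and decays slowly (5-10 s)
    tau_rnn: float = 8.0
    tau_pip10: float = 0.1
    tau_dnvib: float = 0.1
    tau_inh_sv: float = 0.1
    tau_inh_vs: float = 0.3
    # connection weights (excitatory >= 0, inhibitory <= 0)
    w_pc2l_pip10: float = 1.5
    w_pc2l_p1a: float = 0.2  # weak
    w_p1a_dnvib: float = 1.5
    w_p1a_rnn: float = 1.0
    w_rnn_dnvib: float = 1.5  # RNN favors the vibration DN ...
    w_rnn_pip10: float = 0.5  # ... over the song DN
    w_rnn_self: float = 1.0
    w_pip10_inh: float = 1.0
    w_dnvib_inh: float = 1.0
    w_inh_dnvib: float = -1.5
    w_inh_pip10: float = -1.5
    # RNN persistence threshold
    theta_rnn: float = 0.25
    # subtractive adaptation (strength, timescale)
    beta_pip10: float = 0.5
    tau_a_pip10: float = 2.0
    beta_dnvib: float = 0.5
    tau_a_dnvib: float = 2.0
    beta_inh_vs: float = 0.7  # adapting interneuron: high-pass inhibition
    tau_a_inh_vs: float = 1.5
    # excitability gains (satiation scales the first three)
    g_pc2l: float = 1.0
    g_p1a: float = 1.0
    g_rnn: float = 1.0
    g_pip10: float = 1.0
    g_dnvib: float = 1.0
    # noise and integration
    sigma: float = 0.05
    dt: float = 0.001
    # DN rate -> probability mapping
    output_gain_song: float = 1.0
    output_gain_vib: float = 1.0
    output_offset: float = 0.0  # optional DN-rate floor below which p = 0
    output_map: str = "linear"  # or "saturating" (1 - exp(-gain * r))

    def __post_init__(self):
        taus = [
            self.tau_pc2l, self.tau_p1a_rise, self.tau_p1a, self.tau_rnn,
            self.tau_pip10, self.tau_dnvib, self.tau_inh_sv, self.tau_inh_vs,
        ]
        if any(t <= 0 for t in taus):
            raise ValueError("all time constants must be positive")
        if self.dt <= 0 or self.dt > min(taus) / 10.0:
            raise ValueError("dt must be positive and at most min(tau)/10")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        for name in ("w_pc2l_pip10", "w_pc2l_p1a", "w_p1a_dnvib", "w_p1a_rnn",
                     "w_rnn_dnvib", "w_rnn_pip10", "w_rnn_self",
                     "w_pip10_inh", "w_dnvib_inh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} is excitatory and must be >= 0")
        for name in ("w_inh_dnvib", "w_inh_pip10"):
            if getattr(self, name) > 0:
                raise ValueError(f"{name} is inhibitory and must be <= 0")
        if self.output_map not in ("linear", "saturating"):
            raise ValueError("output_map must be 'linear' or 'saturating'")
        if not 5.0 <= self.tau_p1a <= 10.0:
            raise ValueError("tau_p1a (P1a intrinsic decay) must lie in 5-10 s")


@dataclass(frozen=True)
class StimulusProtocol:
    """One optogenetic-style activation trial, repeated with fresh noise.

    The stimulus is a step of ``amplitude`` into ``target`` lasting
    ``duration_s`` from t = 0; each trial simulates ``pre_s`` seconds
    before and ``post_s`` after stimulus onset.  Trials are independently
    initialized (quiescent) with independent noise streams.
    """

    target: str = "P1a"
    duration_s: float = 5.0
    amplitude: float = 1.0
    n_trials: int = 100
    pre_s: float = 10.0
    post_s: float = 35.0

    def __post_init__(self):
        if self.target not in ("P1a", "pC2l"):
            raise ValueError("target must be 'P1a' or 'pC2l'")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class SimResult:
    """Simulated trial ensemble.

    ``time_s`` is relative to stimulus onset.  ``p_song`` and ``p_vib``
    are (n_trials, n_samples) probability traces; ``rates`` holds the
    trial-averaged rate of every node.
    """

    time_s: np.ndarray
    p_song: np.ndarray
    p_vib: np.ndarray
    rates: dict = field(repr=False, default_factory=dict)
    params: CircuitParams | None = None
    protocol: StimulusProtocol | None = None

    @property
    def mean_p_song(self) -> np.ndarray:
        return self.p_song.mean(axis=0)

    @property
    def mean_p_vib(self) -> np.ndarray:
        return self.p_vib.mean(axis=0)

    def epoch_means(self, epochs: TrialEpochs | None = None) -> pd.DataFrame:
        """Across-trial mean signal probability per epoch.

        Rows ``song``/``vib``/``any`` (``any`` = per-step max of the two),
        columns the epoch names.
        """
        if epochs is None:
            epochs = TrialEpochs()
        out = {}
        p_any = np.maximum(self.p_song, self.p_vib)
        for name in epochs.names:
            a, b = epochs.window(name)
            sel = (self.time_s >= a) & (self.time_s < b)
            if not sel.any():
                out[name] = {"song": np.nan, "vib": np.nan, "any": np.nan}
                continue
            out[name] = {
                "song": float(self.p_song[:, sel].mean()),
                "vib": float(self.p_vib[:, sel].mean()),
                "any": float(p_any[:, sel].mean()),
            }
        return pd.DataFrame(out)

    def coactivity(self, window=(0.0, 35.0)) -> float:
        """Mean of p_song * p_vib over ``window`` (song/vibration
        co-activity; low when mutual inhibition separates the signals)."""
        sel = (self.time_s >= window[0]) & (self.time_s < window[1])
        return float((self.p_song[:, sel] * self.p_vib[:, sel]).mean())


def _relu(x):
    return np.maximum(x, 0.0)


def simulate(
    params: CircuitParams,
    protocol: StimulusProtocol,
    seed: int = 0,
    record_rate_hz: float = 100.0,
) -> SimResult:
    """Integrate the circuit for ``protocol.n_trials`` independent trials.

    Exponential-Euler steps of ``params.dt`` from quiescence; Gaussian
    noise of SD ``params.sigma`` (scaled by sqrt(dt)) enters the two DN
    rates each step.  Rates are kept nonnegative; a divergence guard
    raises if any rate exceeds 1e3.  Traces are recorded at
    ``record_rate_hz``.
    """
    p = params
    dt = p.dt
    n_trials = protocol.n_trials
    T_total = protocol.pre_s + protocol.post_s
    n_steps = int(round(T_total / dt))
    every = max(int(round(1.0 / (record_rate_hz * dt))), 1)
    n_rec = n_steps // every
    rng = np.random.default_rng(seed)

    r = {n: np.zeros(n_trials) for n in NODES}
    a_pip10 = np.zeros(n_trials)
    a_dnvib = np.zeros(n_trials)
    a_inh_vs = np.zeros(n_trials)

    p_song = np.empty((n_trials, n_rec))
    p_vib = np.empty((n_trials, n_rec))
    mean_rates = {n: np.empty(n_rec) for n in NODES}
    time_s = np.empty(n_rec)

    stim_on = int(round(protocol.pre_s / dt))
    stim_off = int(round((protocol.pre_s + protocol.duration_s) / dt))
    sq = np.sqrt(dt)
    # per-step relaxation factors 1 - exp(-dt/tau)
    decay = lambda tau: -np.expm1(-dt / tau)  # noqa: E731
    al_pc2l = decay(p.tau_pc2l)
    al_p1a_rise = decay(p.tau_p1a_rise)
    al_p1a_decay = decay(p.tau_p1a)
    al_rnn = decay(p.tau_rnn)
    al_pip10 = decay(p.tau_pip10)
    al_dnvib = decay(p.tau_dnvib)
    al_inh_sv = decay(p.tau_inh_sv)
    al_inh_vs = decay(p.tau_inh_vs)
    al_a_pip10 = decay(p.tau_a_pip10)
    al_a_dnvib = decay(p.tau_a_dnvib)
    al_a_inh_vs = decay(p.tau_a_inh_vs)

    def to_prob(rate, gain):
        shifted = np.maximum(rate - p.output_offset, 0.0)
        if p.output_map == "linear":
            return np.clip(gain * shifted, 0.0, 1.0)
        return 1.0 - np.exp(-gain * shifted)

    k_rec = 0
    for step in range(n_steps):
        I_p1a = protocol.amplitude if (
            protocol.target == "P1a" and stim_on <= step < stim_off
        ) else 0.0
        I_pc2l = protocol.amplitude if (
            protocol.target == "pC2l" and stim_on <= step < stim_off
        ) else 0.0

        d_pc2l = p.g_pc2l * _relu(I_pc2l)
        drive_p1a = p.g_p1a * _relu(I_p1a + p.w_pc2l_p1a * r["pC2l"])
        d_rnn = p.g_rnn * _relu(
            p.w_p1a_rnn * r["P1a"] + p.w_rnn_self * r["RNN"] - p.theta_rnn
        )
        d_pip10 = p.g_pip10 * _relu(
            p.w_pc2l_pip10 * r["pC2l"]
            + p.w_rnn_pip10 * r["RNN"]
            + p.w_inh_pip10 * r["inh_vs"]
            - p.beta_pip10 * a_pip10
        )
        d_dnvib = p.g_dnvib * _relu(
            p.w_p1a_dnvib * r["P1a"]
            + p.w_rnn_dnvib * r["RNN"]
            + p.w_inh_dnvib * r["inh_sv"]
            - p.beta_dnvib * a_dnvib
        )
        d_inh_sv = _relu(p.w_pip10_inh * r["pIP10"])
        d_inh_vs = _relu(p.w_dnvib_inh * r["DNvib"] - p.beta_inh_vs * a_inh_vs)

        # exponential-Euler update: exact relaxation toward the drive
        # frozen over the step (machine-precision step response for an
        # uncoupled node under piecewise-constant input)
        r["pC2l"] += al_pc2l * (d_pc2l - r["pC2l"])
        # P1a: fast rise, slow (5-10 s) intrinsic decay
        al_p1a = np.where(drive_p1a > r["P1a"], al_p1a_rise, al_p1a_decay)
        r["P1a"] += al_p1a * (drive_p1a - r["P1a"])
        r["RNN"] += al_rnn * (d_rnn - r["RNN"])
        noise_s = p.sigma * sq * rng.standard_normal(n_trials)
        noise_v = p.sigma * sq * rng.standard_normal(n_trials)
        r["pIP10"] += al_pip10 * (d_pip10 - r["pIP10"]) + noise_s
        r["DNvib"] += al_dnvib * (d_dnvib - r["DNvib"]) + noise_v
        r["inh_sv"] += al_inh_sv * (d_inh_sv - r["inh_sv"])
        r["inh_vs"] += al_inh_vs * (d_inh_vs - r["inh_vs"])
        a_pip10 += al_a_pip10 * (r["pIP10"] - a_pip10)
        a_dnvib += al_a_dnvib * (r["DNvib"] - a_dnvib)
        a_inh_vs += al_a_inh_vs * (r["inh_vs"] - a_inh_vs)
        for n in NODES:
            np.maximum(r[n], 0.0, out=r[n])

        if (step + 1) % every == 0:
            if r["RNN"].max() > 1e3 or r["DNvib"].max() > 1e3 or r["pIP10"].max() > 1e3:
                raise RuntimeError(
                    "circuit integration diverged (rate > 1e3); reduce dt"
                )
            time_s[k_rec] = (step + 1) * dt - protocol.pre_s
            p_song[:, k_rec] = to_prob(r["pIP10"], p.output_gain_song)
            p_vib[:, k_rec] = to_prob(r["DNvib"], p.output_gain_vib)
            for n in NODES:
                mean_rates[n][k_rec] = r[n].mean()
            k_rec += 1

    return SimResult(
        time_s=time_s,
        p_song=p_song,
        p_vib=p_vib,
        rates=mean_rates,
        params=params,
        protocol=protocol,
    )


def run_trials(
    params: CircuitParams,
    protocol: StimulusProtocol,
    seed: int = 0,
    epochs: TrialEpochs | None = None,
):
    """Simulate the trial ensemble and attach epoch statistics.

    Returns ``(result, epoch_table)`` where ``epoch_table`` is the
    across-trial mean signal probability per epoch window.
    """
    result = simulate(params, protocol, seed=seed)
    return result, result.epoch_means(epochs)


def ablate_rnn(params: CircuitParams) -> CircuitParams:
    """Zero the RNN's output and recurrence (idempotent)."""
    return replace(params, w_rnn_dnvib=0.0, w_rnn_pip10=0.0, w_rnn_self=0.0, g_rnn=0.0)


def remove_mutual_inhibition(params: CircuitParams) -> CircuitParams:
    """Zero both inhibitory interneuron pathways (idempotent)."""
    return replace(params, w_inh_dnvib=0.0, w_inh_pip10=0.0)


def apply_satiation(params: CircuitParams, scale: float) -> CircuitParams:
    """Scale the excitability of pC2l, P1a and the RNN by ``scale``
    (sexual satiation reduces circuit excitability; scale in (0, 1])."""
    if not 0 < scale <= 1:
        raise ValueError("satiation scale must lie in (0, 1]")
    return replace(
        params,
        g_pc2l=params.g_pc2l * scale,
        g_p1a=params.g_p1a * scale,
        g_rnn=params.g_rnn * scale,
    )


def decay_timescale(time_s, trace, window, floor_frac: float = 0.2) -> float:
    """Effective exponential decay timescale of ``trace`` over ``window``.

    Log-linear least squares on the samples within ``window`` whose value
    exceeds ``floor_frac`` of the window's peak (excluding the noise-floor
    tail, where the log-slope is meaningless); returns NaN if fewer than
    5 usable samples or if the trace is not decaying.
    """
    time_s = np.asarray(time_s, dtype=float)
    trace = np.asarray(trace, dtype=float)
    sel = (time_s >= window[0]) & (time_s < window[1])
    t, x = time_s[sel], trace[sel]
    if x.size == 0 or np.nanmax(x) <= 0:
        return float("nan")
    good = x > floor_frac * np.nanmax(x)
    t, x = t[good], x[good]
    if t.size < 5:
        warnings.warn("decay_timescale: too few samples for a fit")
        return float("nan")
    slope, _ = np.polyfit(t, np.log(x), 1)
    if slope >= 0:
        return float("nan")
    return float(-1.0 / slope)
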