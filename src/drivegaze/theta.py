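"""Frontal-midline-theta surrogate: band power and active-vs-baseline
pseudo-t contrasts at the sensor level.

The theta (3–9 Hz) band power of a single neural channel is measured inside
each 4-s analysis window with a zero-phase FFT band-pass (raised-cosine
transitions, 1 Hz wide by default).  Per-trial active-minus-baseline power
differences are reduced to a noise-normalized pseudo-t,
``mean(d) / (sd(d)/sqrt(n))``, the sensor-level analogue of beamformer
differential-power statistics.  High-control windows are flagged *elevated*
when the pseudo-t exceeds a configurable decision threshold (default 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sp_fft

from .errors import DegenerateVarianceError, InsufficientDataError
from .traces import NeuralTrace

DEFAULT_BAND = (3.0, 9.0)


def bandpass_fft(x: np.ndarray, fs: float,
                 band: tuple[float, float] = DEFAULT_BAND,
                 transition: float = 1.0) -> np.ndarray:
    """Zero-phase band-pass via an FFT amplitude mask.

    The mask is 1 inside ``band``, 0 outside, with raised-cosine edges of
    total width ``transition`` Hz centred on each band edge.  Being a pure
    real amplitude mask, the filter introduces no phase shift.
    """
    lo, hi = band
    if not 0.0 < lo < hi < fs / 2.0:
        raise ValueError(f"band {band} must lie within (0, {fs / 2}) Hz")
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        return x.copy()
    nfft = sp_fft.next_fast_len(n)  # zero-pad to a fast FFT length
    f = sp_fft.rfftfreq(nfft, d=1.0 / fs)
    half = transition / 2.0

    def edge(freq, center, rising):
        u = np.clip((freq - (center - half)) / max(transition, 1e-12), 0.0, 1.0)
        r = 0.5 - 0.5 * np.cos(np.pi * u)
        return r if rising else 1.0 - r

    mask = edge(f, lo, rising=True) * edge(f, hi, rising=False)
    return sp_fft.irfft(sp_fft.rfft(x, nfft) * mask, nfft)[:n]


def bandpass_power(trace: NeuralTrace,
                   band: tuple[float, float] = DEFAULT_BAND,
                   window: tuple[float, float] | None = None,
                   transition: float = 1.0) -> float:
    """Mean squared amplitude of the band-limited signal over ``window``
    (the whole trace when ``window`` is None)."""
    filtered = bandpass_fft(trace.samples, trace.sample_rate, band, transition)
    if window is not None:
        sl = trace.sample_slice(*window)
        if sl.start < 0 or sl.stop > len(trace) or sl.stop <= sl.start:
            raise ValueError("window outside trace extent")
        filtered = filtered[sl]
    return float(np.mean(filtered ** 2))


def band_powers(trace: NeuralTrace, windows: list[tuple[float, float]],
                band: tuple[float, float] = DEFAULT_BAND,
                transition: float = 1.0) -> np.ndarray:
    """Band power for many windows, filtering the trace once."""
    filtered = bandpass_fft(trace.samples, trace.sample_rate, band, transition)
    out = np.empty(len(windows))
    for k, (a, b) in enumerate(windows):
        sl = trace.sample_slice(a, b)
        if sl.start < 0 or sl.stop > len(trace) or sl.stop <= sl.start:
            raise ValueError(f"window ({a}, {b}) outside trace extent")
        out[k] = np.mean(filtered[sl] ** 2)
    return out


@dataclass(frozen=True)
class PseudoT:
    """Noise-normalized differential band power across trials."""

    label: str
    value: float
    n_trials: int


def pseudo_t(active_powers, baseline_powers, label: str = "Hi") -> PseudoT:
    """Across-trial t of per-trial active-minus-baseline power differences."""
    a = np.asarray(active_powers, dtype=float)
    b = np.asarray(baseline_powers, dtype=float)
    if a.size != b.size:
        raise ValueError("active and baseline powers must pair one-to-one")
    if a.size < 2:
        raise InsufficientDataError("pseudo-t needs at least 2 trials")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateVarianceError(
            "all per-trial power differences are identical")
    value = d.mean() / (sd / np.sqrt(d.size))
    return PseudoT(label, float(value), int(d.size))


def validate_fmt(neural: NeuralTrace | None, windows: pd.DataFrame,
                 band: tuple[float, float] = DEFAULT_BAND,
                 threshold: float = 2.0,
                 transition: float = 1.0) -> pd.DataFrame:
    """Per-label theta report: is band power elevated versus the rest
    baseline?

    ``windows`` needs columns ``trial_id, label, t_start, t_end`` with labels
    in {Lo, Hi, Baseline}.  Each Hi (and Lo) window is paired with the
    Baseline window of the same trial; trials missing either side are
    dropped.  Returns one row per label with the pseudo-t, trial count and
    the elevation flag (pseudo-t > ``threshold``).
    """
    if neural is None:
        raise InsufficientDataError("no neural trace available")
    base = windows[windows["label"] == "Baseline"].set_index("trial_id")
    rows = []
    for label in ("Hi", "Lo"):
        act = windows[windows["label"] == label]
        shared = act[act["trial_id"].isin(base.index)]
        if len(shared) < 2:
            raise InsufficientDataError(
                f"fewer than 2 usable {label}/Baseline trial pairs")
        act_wins = [(r.t_start, r.t_end) for r in shared.itertuples()]
        base_rows = base.loc[shared["trial_id"]]
        base_wins = list(zip(base_rows["t_start"], base_rows["t_end"]))
        pa = band_powers(neural, act_wins, band, transition)
        pb = band_powers(neural, base_wins, band, transition)
        pt = pseudo_t(pa, pb, label=label)
        rows.append({"label": label, "pseudo_t": pt.value,
                     "n_trials": pt.n_trials,
                     "elevated": pt.value > threshold})
    return pd.DataFrame(rows)
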