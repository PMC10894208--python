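"""Macroscale phase-drift analysis of phase-triggered MEP trials.

Motor-evoked potentials are probed at four phases (0, 90, 180, 270 deg)
of the ongoing AC stimulation.  Amplitudes are normalized per block, the
per-phase means are condensed into a polar excitability vector

    x = M(180) - M(0),   y = M(270) - M(90),

whose direction (mapped so that a pure +x vector points to 180 deg and a
pure +y vector to 270 deg) equals the amplitude-weighted circular mean
of the four phase means.  A sliding window over trials (55-trial
windows, 5-trial steps, averaged over blocks) yields a phase track whose
drift is assessed by circular-linear correlation, with a within-block
permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circular import (
    CircularSummary,
    PhaseSample,
    circ_lin_corr,
    wrap_deg,
)
from .precession import WindowedPhaseTrack

__all__ = [
    "MEPSeries",
    "PolarExcitabilityVector",
    "PHASE_LABELS",
    "normalize_meps",
    "phase_means",
    "polar_vector",
    "windowed_polar_track",
    "drift_correlation",
    "amplitude_trend",
    "permutation_null_drift",
]

PHASE_LABELS = (0, 90, 180, 270)
MAG_TOL = 1e-12


@dataclass(frozen=True)
class MEPSeries:
    """Ordered phase-labelled TMS-probe trials."""

    trials: pd.DataFrame  # columns: trial_index, block, phase_deg, amplitude_mv

    def __post_init__(self):
        df = self.trials.copy()
        required = {"trial_index", "block", "phase_deg", "amplitude_mv"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"MEP table missing columns {sorted(missing)}")
        if (df["amplitude_mv"] < 0).any():
            raise ValueError("MEP amplitudes must be non-negative")
        bad = ~df["phase_deg"].isin(PHASE_LABELS)
        if bad.any():
            raise ValueError(
                f"phase labels must be in {PHASE_LABELS}; "
                f"found {sorted(df.loc[bad, 'phase_deg'].unique())}")
        object.__setattr__(self, "trials", df.reset_index(drop=True))

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def blocks(self):
        return sorted(self.trials["block"].unique())

    def block_counts(self) -> pd.Series:
        return self.trials.groupby("block").size()

    @classmethod
    def from_csv(cls, path) -> "MEPSeries":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)


@dataclass(frozen=True)
class PolarExcitabilityVector:
    """Excitability asymmetry across the four probed phases."""

    x: float
    y: float

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.x, self.y))

    @property
    def phase_defined(self) -> bool:
        return self.magnitude > MAG_TOL

    @property
    def preferred_phase(self) -> float:
        """Direction in degrees; equals the weighted circular mean of the
        phase means (pure +x -> 180 deg, pure +y -> 270 deg)."""
        if not self.phase_defined:
            return float("nan")
        return float(wrap_deg(np.rad2deg(np.arctan2(-self.y, -self.x))))


def normalize_meps(series: MEPSeries, scope: str = "block") -> MEPSeries:
    """Divide each amplitude by its scope mean (block or session).

    After block-scope normalization every block has mean amplitude 1,
    removing between-block gain differences.
    """
    df = series.trials.copy()
    if scope == "session":
        mean = df["amplitude_mv"].mean()
        if mean <= 0:
            raise ValueError("zero session mean amplitude")
        df["amplitude_mv"] = df["amplitude_mv"] / mean
    elif scope == "block":
        means = df.groupby("block")["amplitude_mv"].transform("mean")
        if (means <= 0).any():
            raise ValueError("zero block mean amplitude")
        df["amplitude_mv"] = df["amplitude_mv"] / means
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return MEPSeries(df)


def phase_means(series: MEPSeries) -> pd.DataFrame:
    """Mean normalized amplitude per phase label; missing phases flagged."""
    rows = []
    for ph in PHASE_LABELS:
        sel = series.trials.loc[series.trials["phase_deg"] == ph, "amplitude_mv"]
        rows.append({
            "phase_deg": ph,
            "mean_amplitude": sel.mean() if len(sel) else float("nan"),
            "n_trials": len(sel),
            "present": len(sel) > 0,
        })
    return pd.DataFrame(rows)


def polar_vector(means: pd.DataFrame) -> PolarExcitabilityVector:
    """Polar excitability vector from the 4-entry phase-mean table."""
    if not means["present"].all():
        raise ValueError("all four phase means must be present")
    m = means.set_index("phase_deg")["mean_amplitude"]
    return PolarExcitabilityVector(x=float(m[180] - m[0]), y=float(m[270] - m[90]))


def windowed_polar_track(series: MEPSeries, window: int = 55, step: int = 5,
                         n_windows: int = 20) -> WindowedPhaseTrack:
    """Sliding-window polar-vector track, vector-averaged over blocks.

    Window w of each block covers within-block trials
    ``[w*step, w*step + window)``; the per-block vectors at matched
    window index are averaged componentwise.  Implemented with
    per-phase cumulative sums so the permutation null can recompute the
    full track cheaply.
    """
    needed = window + (n_windows - 1) * step
    label_index = {ph: i for i, ph in enumerate(PHASE_LABELS)}
    starts = step * np.arange(n_windows)
    xs = np.zeros(n_windows)
    ys = np.zeros(n_windows)
    n_blocks = 0
    for _, g in series.trials.groupby("block"):
        if len(g) < needed:
            raise ValueError(
                f"block needs >= {needed} trials for {n_windows} windows "
                f"of {window} trials at step {step}; got {len(g)}")
        amp = g["amplitude_mv"].to_numpy(dtype=float)
        code = g["phase_deg"].map(label_index).to_numpy()
        means = np.empty((4, n_windows))
        for l in range(4):
            sel = np.where(code == l, amp, 0.0)
            csum = np.concatenate(([0.0], np.cumsum(sel)))
            ccnt = np.concatenate(([0.0], np.cumsum(code == l)))
            s = csum[starts + window] - csum[starts]
            n = ccnt[starts + window] - ccnt[starts]
            means[l] = np.divide(s, n, out=np.full(n_windows, np.nan),
                                 where=n > 0)
        xs += means[label_index[180]] - means[label_index[0]]
        ys += means[label_index[270]] - means[label_index[90]]
        n_blocks += 1
    xs /= n_blocks
    ys /= n_blocks
    summaries, magnitudes = [], []
    for w in range(n_windows):
        v = PolarExcitabilityVector(float(xs[w]), float(ys[w]))
        defined = v.phase_defined and np.isfinite(xs[w]) and np.isfinite(ys[w])
        summaries.append(CircularSummary(
            plv=v.magnitude if defined else 0.0,
            preferred_phase=v.preferred_phase if defined else float("nan"),
            rayleigh_p=0.0 if defined else 1.0,
            n=window * n_blocks, phase_defined=defined))
        magnitudes.append(v.magnitude if defined else float("nan"))
    return WindowedPhaseTrack(tuple(summaries), unit_id="mep",
                              magnitudes=tuple(magnitudes))


def drift_correlation(track: WindowedPhaseTrack) -> tuple[float, float]:
    """Circular-linear correlation of window preferred phase vs index."""
    phases = track.preferred_phases
    defined = np.array([s.phase_defined for s in track.summaries])
    if defined.sum() < 3:
        raise ValueError("need >= 3 windows with a defined phase")
    idx = np.flatnonzero(defined).astype(float)
    return circ_lin_corr(PhaseSample.from_degrees(phases[defined]), idx)


def amplitude_trend(series: MEPSeries) -> tuple[float, float]:
    """Pearson correlation of normalized amplitude vs within-block trial
    index, pooled over blocks."""
    df = series.trials
    if len(df) < 3:
        raise ValueError("need >= 3 trials")
    idx = df.groupby("block").cumcount().to_numpy(dtype=float)
    amp = df["amplitude_mv"].to_numpy(dtype=float)
    if np.ptp(amp) == 0:
        raise ValueError("constant amplitudes: trend undefined")
    r, p = stats.pearsonr(amp, idx)
    return float(r), float(p)


def permutation_null_drift(series: MEPSeries, n_perm: int = 500,
                           seed: int | None = None, window: int = 55,
                           step: int = 5, n_windows: int = 20) -> dict:
    """Permutation null for the drift correlation.

    Phase labels are shuffled within block (trial order and amplitudes
    preserved) ``n_perm`` times; the full windowed polar track and drift
    correlation are recomputed each time.  ``p_perm`` is the fraction of
    null r values at least as large as the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    track = windowed_polar_track(series, window, step, n_windows)
    r_obs, _ = drift_correlation(track)
    null_r = np.empty(n_perm)
    df = series.trials
    codes = df["phase_deg"].to_numpy()
    blocks = df["block"].to_numpy()
    block_idx = [np.flatnonzero(blocks == b) for b in np.unique(blocks)]
    for k in range(n_perm):
        perm_codes = codes.copy()
        for idx in block_idx:
            perm_codes[idx] = perm_codes[idx][rng.permutation(idx.size)]
        t = windowed_polar_track(MEPSeries(df.assign(phase_deg=perm_codes)),
                                 window, step, n_windows)
        try:
            null_r[k], _ = drift_correlation(t)
        except ValueError:
            null_r[k] = 0.0
    p_perm = float((np.sum(null_r >= r_obs) + 1) / (n_perm + 1))
    return {"r_observed": r_obs, "null_r": null_r, "p_perm": p_perm}
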