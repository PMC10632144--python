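"""Ratiometric two-photon trace analysis.

The signal channel (a calcium indicator such as GCaMP6f) is divided
frame-by-frame by a co-expressed reference fluorophore (tdTomato) to
cancel motion artifacts, hemispheres are averaged, and each
stimulus-evoked response is expressed as dR/R0 relative to the mean ratio
over a pre-onset baseline window. Peaks are read from a fixed post-onset
window, and physiological-state contrasts are summarised as per-frame
mean-difference curves with unpaired-t confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

DEFAULT_FRAME_RATE = 5.74  # Hz
PEAK_WINDOW_S = 20.0


@dataclass(frozen=True)
class StimulusEvent:
    onset: float            # seconds from trace start
    duration: float
    modality: str           # MCH | OCT | water | sucrose
    trial_index: int = 1


@dataclass(frozen=True)
class RoiTraceSet:
    """Per-frame channel means for one ROI in one hemisphere."""

    roi: str                # bp2 | g4 | g5n | background
    hemisphere: str         # left | right
    signal: np.ndarray
    reference: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE


@dataclass(frozen=True)
class NormalizedResponse:
    """dR/R0 values for a whole trace, aligned to one stimulus onset."""

    values: np.ndarray
    r0: float
    onset_index: int
    baseline_window: float  # seconds
    frame_rate: float


@dataclass(frozen=True)
class DifferenceCurve:
    diff: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    significant: np.ndarray  # CI excludes zero, per frame
    pvalues: np.ndarray
    alpha: float


def ratiometric(signal, reference=None) -> np.ndarray:
    """Per-frame ratio R of signal to reference channel.

    A multiplicative artifact applied to both channels (sample motion,
    acquisition gain) cancels exactly. Accepts arrays or a
    :class:`RoiTraceSet` as the first argument.
    """
    if isinstance(signal, RoiTraceSet):
        signal, reference = signal.signal, signal.reference
    if reference is None:
        raise TypeError("reference channel required unless a RoiTraceSet is given")
    sig = np.asarray(signal, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if sig.shape != ref.shape:
        raise ValueError("signal and reference must have equal frame counts")
    bad = np.flatnonzero(ref <= 0)
    if bad.size:
        raise ValueError(f"nonpositive reference intensity at frame {bad[0]}")
    return sig / ref


def hemisphere_average(
    left: np.ndarray | None, right: np.ndarray | None
) -> tuple[np.ndarray, bool]:
    """Frame-wise mean of the two hemisphere ratio traces.

    With one hemisphere absent the other passes through unchanged and the
    single-hemisphere flag is set.
    """
    if left is None and right is None:
        raise ValueError("at least one hemisphere trace required")
    if left is None:
        return np.asarray(right, dtype=float).copy(), True
    if right is None:
        return np.asarray(left, dtype=float).copy(), True
    L, R = np.asarray(left, dtype=float), np.asarray(right, dtype=float)
    if L.shape != R.shape:
        raise ValueError("hemisphere traces differ in frame count")
    return (L + R) / 2.0, False


def _frame(t_s: float, frame_rate: float) -> int:
    """Nearest-frame index for a time in seconds."""
    return int(round(t_s * frame_rate))


def normalize(
    trace: np.ndarray,
    event: StimulusEvent,
    baseline_s: float = 5.0,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> NormalizedResponse:
    """dR/R0 for one stimulus presentation.

    R0 is the arithmetic mean of the ratio trace over the ``baseline_s``
    seconds before onset (half-open window ending at the onset frame); the
    returned values are (R - R0)/R0 for every frame, so the mean of the
    baseline window is zero by construction.
    """
    R = np.asarray(trace, dtype=float)
    onset = _frame(event.onset, frame_rate)
    nb = _frame(baseline_s, frame_rate)
    if onset - nb < 0 or nb < 1:
        raise ValueError("insufficient pre-onset frames for the baseline window")
    r0 = float(R[onset - nb : onset].mean())
    if r0 <= 0:
        raise ValueError("baseline ratio R0 must be positive")
    return NormalizedResponse(
        values=(R - r0) / r0,
        r0=r0,
        onset_index=onset,
        baseline_window=baseline_s,
        frame_rate=frame_rate,
    )


def peak(resp: NormalizedResponse, window_s: float = PEAK_WINDOW_S) -> float:
    """Maximum dR/R0 in the half-open window [onset, onset + 20 s).

    A trace shorter than the window is truncated (the available frames are
    used); an empty window is an error.
    """
    start = resp.onset_index
    stop = min(start + _frame(window_s, resp.frame_rate), len(resp.values))
    if stop <= start:
        raise ValueError("empty peak window")
    return float(resp.values[start:stop].max())


def mean_difference(
    group_a: Sequence[np.ndarray] | np.ndarray,
    group_b: Sequence[np.ndarray] | np.ndarray,
    alpha: float = 0.05,
    *,
    equal_var: bool = True,
) -> DifferenceCurve:
    """Per-frame mean difference between two fly groups with a t CI.

    For each frame: mean(A) - mean(B), a two-sided unpaired t confidence
    interval at level 1 - alpha (pooled variance by default, Welch with
    ``equal_var=False``), uncorrected for multiple comparisons. A frame is
    significant when its CI excludes zero.
    """
    A = np.asarray(group_a, dtype=float)
    B = np.asarray(group_b, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("groups must be 2-D (flies x frames) on a shared frame grid")
    na, nb = A.shape[0], B.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two flies")
    diff = A.mean(axis=0) - B.mean(axis=0)
    va, vb = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    if equal_var:
        dof = np.full(diff.shape, na + nb - 2, dtype=float)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            dof = se**4 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        dof = np.where(np.isfinite(dof), dof, na + nb - 2)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, dof)
    half = tcrit * se
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf))
    pvalues = 2.0 * stats.t.sf(np.abs(tstat), dof)
    ci_lo, ci_hi = diff - half, diff + half
    return DifferenceCurve(
        diff=diff,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        significant=(ci_lo > 0) | (ci_hi < 0),
        pvalues=pvalues,
        alpha=alpha,
    )


def baseline_relative(
    roi: Mapping[str, np.ndarray],
    background: Mapping[str, np.ndarray],
    onset_s: float,
    frame_rate: float = DEFAULT_FRAME_RATE,
    window_s: float = 60.0,
) -> float:
    """Baseline signal of an ROI relative to a background region.

    The signal-channel mean over the ``window_s`` seconds before onset is
    divided by the matching background-ROI mean within each hemisphere,
    then averaged across hemispheres. ``roi`` and ``background`` map
    hemisphere name -> signal-channel trace.
    """
    onset = _frame(onset_s, frame_rate)
    nw = _frame(window_s, frame_rate)
    if onset - nw < 0:
        raise ValueError("insufficient pre-onset frames for the baseline window")
    ratios = []
    for hemi, trace in roi.items():
        if hemi not in background:
            raise ValueError(f"background ROI missing for hemisphere {hemi}")
        r = float(np.asarray(trace, dtype=float)[onset - nw : onset].mean())
        b = float(np.asarray(background[hemi], dtype=float)[onset - nw : onset].mean())
        if b == 0:
            raise ValueError(f"zero background mean in hemisphere {hemi}")
        ratios.append(r / b)
    return float(np.mean(ratios))


def process_fly(
    traces: Mapping[str, RoiTraceSet],
    events: Sequence[StimulusEvent],
    baseline_s: float = 5.0,
) -> dict[int, NormalizedResponse]:
    """Standard per-fly pipeline for one ROI: ratio, average, normalise.

    ``traces`` maps hemisphere -> RoiTraceSet. Hemisphere averaging is
    applied to the ratio traces before normalisation, so a single R0 per
    presentation is computed on the averaged trace.
    """
    ratios = {h: ratiometric(ts) for h, ts in traces.items()}
    mean_trace, _ = hemisphere_average(ratios.get("left"), ratios.get("right"))
    fr = next(iter(traces.values())).frame_rate
    return {
        e.trial_index: normalize(mean_trace, e, baseline_s=baseline_s, frame_rate=fr)
        for e in events
    }
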