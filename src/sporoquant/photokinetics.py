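"""Acceptor-photobleaching FRET ratios and FRAP recovery fitting.

FRET: after photobleaching the acceptor, a donor that was transferring
energy to it dequenches, so its intensity rises.  The measurement protocol
is fixed: the pre-bleach intensity is the average of the three frames
immediately before the bleach, the post-bleach intensity the average of the
first three frames after it, and the reported quantity is the post/pre
ratio (ratio > 1 indicates interaction).  The conventional FRET efficiency
E = 1 - i_pre / i_post is emitted alongside.

FRAP: the bleached-ROI trace, corrected for imaging bleach against a
non-bleached reference region and normalized to a pre-bleach mean of 1, is
fit with a single-exponential recovery
``I(t) = floor + (plateau - floor) (1 - exp(-k t))`` on the post-bleach
frames (t = 0 at the first post-bleach frame).  The half-time of recovery
is t1/2 = ln 2 / k, and the mobile fraction (plateau - floor) / (1 - floor).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import IntensityTrace, ParameterError

__all__ = [
    "FretResult",
    "FretAggregate",
    "FrapFit",
    "fretap_efficiency",
    "aggregate_fret",
    "bleach_correct",
    "fit_frap",
]

#: Frames averaged on each side of the bleach (fixed acquisition protocol).
N_PROTOCOL_FRAMES = 3


@dataclass(frozen=True)
class FretResult:
    """Per-ROI acceptor-photobleaching measurement."""

    i_pre: float
    i_post: float
    roi_id: str = "roi"

    @property
    def ratio(self) -> float:
        return self.i_post / self.i_pre

    @property
    def efficiency(self) -> float:
        return 1.0 - self.i_pre / self.i_post


@dataclass(frozen=True)
class FretAggregate:
    """Mean/sd/n of post-pre ratios, with a Welch test versus a control."""

    mean_ratio: float
    sd: float
    n: int
    t_vs_control: float | None = None
    p_vs_control: float | None = None


@dataclass(frozen=True)
class FrapFit:
    """Fitted single-exponential FRAP recovery.

    ``converged`` is False (with an explanatory ``message`` and NaN rate)
    when the optimizer fails or no recovery amplitude is present; no
    exception is raised for those cases.
    """

    k_per_s: float
    mobile_fraction: float
    floor: float
    plateau: float
    rss: float
    converged: bool
    message: str = ""

    @property
    def t_half_s(self) -> float:
        return math.log(2) / self.k_per_s


def fretap_efficiency(trace: IntensityTrace) -> FretResult:
    """Apply the fixed 3 + 3 frame protocol to one donor trace.

    Uses exactly the three frames immediately before the bleach and the
    first three frames after it, regardless of trace length.
    """
    if trace.bleach_index < N_PROTOCOL_FRAMES:
        raise ParameterError(
            f"need >= {N_PROTOCOL_FRAMES} pre-bleach frames, have {trace.bleach_index}"
        )
    n_post = len(trace) - trace.bleach_index
    if n_post < N_PROTOCOL_FRAMES:
        raise ParameterError(
            f"need >= {N_PROTOCOL_FRAMES} post-bleach frames, have {n_post}"
        )
    i_pre = float(trace.intensities[trace.bleach_index - N_PROTOCOL_FRAMES : trace.bleach_index].mean())
    i_post = float(trace.intensities[trace.bleach_index : trace.bleach_index + N_PROTOCOL_FRAMES].mean())
    if i_pre <= 0:
        raise ParameterError("pre-bleach intensity must be > 0")
    return FretResult(i_pre=i_pre, i_post=i_post, roi_id=trace.roi_id)


def aggregate_fret(results: list[FretResult],
                   control: list[FretResult] | None = None) -> FretAggregate:
    """Mean, sample sd and n of ratios; two-sided Welch test vs control.

    The control test is skipped (None statistics) when fewer than two
    results or controls are available.
    """
    if not results:
        raise ParameterError("aggregate_fret needs at least one result")
    ratios = np.array([r.ratio for r in results])
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    t_stat = p = None
    if control and len(control) >= 2 and len(ratios) >= 2:
        ctrl = np.array([r.ratio for r in control])
        res = stats.ttest_ind(ratios, ctrl, equal_var=False)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return FretAggregate(float(ratios.mean()), sd, len(ratios), t_stat, p)


def bleach_correct(trace: IntensityTrace, reference: IntensityTrace) -> IntensityTrace:
    """Divide out imaging bleach measured in a non-bleached reference ROI.

    corrected(t) = trace(t) / (reference(t) / mean pre-bleach reference),
    then normalized so the corrected pre-bleach mean is 1.
    """
    if len(trace) != len(reference) or not np.allclose(trace.times_s, reference.times_s):
        raise ParameterError("trace and reference must share a time axis")
    if trace.bleach_index != reference.bleach_index:
        raise ParameterError("trace and reference must share the bleach index")
    if np.any(reference.intensities == 0):
        raise ParameterError("reference trace contains zero intensities")
    ref_norm = reference.intensities / reference.pre.mean()
    corrected = trace.intensities / ref_norm
    pre_mean = corrected[: trace.bleach_index].mean()
    if pre_mean <= 0:
        raise ParameterError("corrected pre-bleach mean must be > 0")
    return IntensityTrace(
        trace.times_s.copy(), corrected / pre_mean, trace.bleach_index, trace.roi_id
    )


def _recovery_model(t: np.ndarray, floor: float, plateau: float, k: float) -> np.ndarray:
    return floor + (plateau - floor) * (1.0 - np.exp(-k * t))


def _failed_fit(floor: float, plateau: float, rss: float, message: str) -> FrapFit:
    return FrapFit(
        k_per_s=math.nan,
        mobile_fraction=max(0.0, min(1.0, (plateau - floor) / (1.0 - floor)))
        if floor < 1.0
        else 0.0,
        floor=floor,
        plateau=plateau,
        rss=rss,
        converged=False,
        message=message,
    )


def fit_frap(trace: IntensityTrace, min_post_frames: int = 6) -> FrapFit:
    """Least-squares single-exponential fit of a bleach-corrected trace.

    The fit uses only post-bleach frames, with t = 0 at the first
    post-bleach frame.  Initialization: floor from the first post-bleach
    value, plateau from the last, k from a log-linear regression of
    (plateau - I); the solver then refines all three.
    """
    post = trace.post
    if len(post) < min_post_frames:
        raise ParameterError(f"need >= {min_post_frames} post-bleach frames, have {len(post)}")
    t = trace.times_s[trace.bleach_index :] - trace.times_s[trace.bleach_index]

    floor0 = float(post[0])
    plateau0 = float(post[-1])
    if plateau0 - floor0 < 1e-8:
        return _failed_fit(floor0, plateau0, float(np.sum((post - post.mean()) ** 2)),
                           "no recovery amplitude")

    resid0 = plateau0 * 1.02 - post  # small headroom so the last point stays usable
    usable = resid0 > 0
    if usable.sum() >= 2:
        slope = np.polyfit(t[usable], np.log(resid0[usable]), 1)[0]
        k0 = max(-slope, 1e-3)
    else:
        k0 = math.log(2) / max(t[-1] / 2.0, 1e-6)

    try:
        popt, _ = optimize.curve_fit(
            _recovery_model, t, post,
            p0=[floor0, plateau0, k0],
            bounds=([-0.5, 0.0, 1e-8], [1.5, 3.0, 1e4]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
        )
    except RuntimeError as exc:
        return _failed_fit(floor0, plateau0, math.inf, f"optimizer failed: {exc}")

    floor, plateau, k = (float(v) for v in popt)
    rss = float(np.sum((_recovery_model(t, *popt) - post) ** 2))
    if k <= 0 or plateau <= floor:
        return _failed_fit(floor, plateau, rss, "non-physical fit (k <= 0 or no recovery)")
    mobile = (plateau - floor) / (1.0 - floor) if floor < 1.0 else math.nan
    return FrapFit(
        k_per_s=k,
        mobile_fraction=float(np.clip(mobile, 0.0, 1.0)),
        floor=floor,
        plateau=plateau,
        rss=rss,
        converged=True,
    )
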