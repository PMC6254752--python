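"""Beat pairing across runs and robust ensemble PWV estimation.

Every diameter beat in every selected group is paired with every velocity
beat in every selected group; the pairing-level wave speeds are summarized
by a trimmed mean (default: 10% of the most extreme values excluded, split
evenly over the two tails) with the within-subject SD of the retained
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats import BeatGroup
from .errors import NoEstimateError
from .loop import DEFAULT_DT, DEFAULT_FIT_R2, LoopFit, align_and_truncate, fit_loop

__all__ = ["PwvEstimate", "all_pairings", "trimmed_mean_pwv", "cohort_summary"]

DEFAULT_TRIM_FRACTION = 0.10


@dataclass
class PwvEstimate:
    """Ensemble summary of pairing-level PWV values for one subject."""

    values: np.ndarray  # all unflagged pairing-level PWV values, m/s
    trimmed_mean: float
    wsd: float  # within-subject SD of retained values
    n_total: int
    n_retained: int
    trim_fraction: float
    removed_low: np.ndarray = field(default_factory=lambda: np.array([]))
    removed_high: np.ndarray = field(default_factory=lambda: np.array([]))
    n_flagged: int = 0
    flags: list[str] = field(default_factory=list)


def all_pairings(
    d_groups: list[BeatGroup],
    u_groups: list[BeatGroup],
    dt: float = DEFAULT_DT,
    fit_r2: float = DEFAULT_FIT_R2,
) -> list[LoopFit]:
    """Fit a ln(D)U-loop for every (D beat, U beat) combination.

    ``d_groups``/``u_groups`` hold one selected group per run; the output
    length is (total D beats) x (total U beats).  Loops that fail to fit are
    returned flagged, not dropped.
    """
    if not d_groups or not u_groups:
        raise ValueError("need at least one selected group on each side")
    d_beats = [b for g in d_groups for b in g.beats]
    u_beats = [b for g in u_groups for b in g.beats]
    fits: list[LoopFit] = []
    for d in d_beats:
        for u in u_beats:
            pair = align_and_truncate(d, u, dt=dt)
            fits.append(fit_loop(pair, r2_min=fit_r2))
    return fits


def trimmed_mean_pwv(
    values,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    per_tail: bool = False,
    n_flagged: int = 0,
) -> PwvEstimate:
    """Trimmed mean and within-subject SD of pairing-level PWV values.

    ``trim_fraction`` is the *total* fraction excluded, split evenly over
    both tails with floor rounding (``k = floor(n * trim_fraction / 2)`` per
    tail).  With ``per_tail=True`` the fraction is instead applied to each
    tail.  Removed values are retained for audit.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise NoEstimateError("no unflagged loops; cannot estimate PWV")
    if not 0 <= trim_fraction < 1:
        raise ValueError("trim_fraction must lie in [0, 1)")
    n = vals.size
    k = int(np.floor(n * (trim_fraction if per_tail else trim_fraction / 2.0)))
    order = np.argsort(vals, kind="stable")
    if 2 * k >= n:
        raise NoEstimateError(f"trimming {2 * k} of {n} values leaves nothing")
    retained = vals[order[k : n - k]]
    wsd = float(np.std(retained, ddof=1)) if retained.size > 1 else 0.0
    return PwvEstimate(
        values=vals,
        trimmed_mean=float(np.mean(retained)),
        wsd=wsd,
        n_total=n,
        n_retained=int(retained.size),
        trim_fraction=trim_fraction,
        removed_low=vals[order[:k]],
        removed_high=vals[order[n - k :]],
        n_flagged=n_flagged,
        flags=["n=1"] if n == 1 else [],
    )


def cohort_summary(estimates: list[PwvEstimate], subject_ids=None) -> dict:
    """Mean and SD of per-subject trimmed means, plus a per-subject table."""
    if not estimates:
        raise ValueError("need at least one subject estimate")
    if subject_ids is None:
        subject_ids = list(range(1, len(estimates) + 1))
    means = np.array([e.trimmed_mean for e in estimates])
    sd = float(np.std(means, ddof=1)) if means.size > 1 else 0.0
    table = [
        {"subject_id": sid, "pwv": float(e.trimmed_mean), "wsd": float(e.wsd)}
        for sid, e in zip(subject_ids, estimates)
    ]
    return {
        "n_subjects": len(estimates),
        "mean_pwv": float(np.mean(means)),
        "sd_pwv": sd,
        "flags": ["n=1"] if len(estimates) == 1 else [],
        "subjects": table,
    }
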