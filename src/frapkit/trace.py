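"""Raw FRAP traces: one cell's region-mean intensity time series.

A trace holds, per acquired frame, the mean intensity of the bleached
region of interest (ROI), the whole nucleus, and a background region
outside the cell, together with the number of prebleach (prescan)
frames. Times are acquisition times; re-zeroing at the bleach event is
the quantification layer's job, so the raw record stays unmodified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TraceError(ValueError):
    """Base class for invalid raw-trace data."""


class TraceLengthError(TraceError):
    """Channel/time arrays disagree in length."""


class NonMonotoneTimeError(TraceError):
    """Acquisition times are not strictly increasing."""


class PrebleachCountError(TraceError):
    """Prebleach frame count outside [1, n_frames - 1]."""


class NonFiniteIntensityError(TraceError):
    """A channel contains NaN or infinite values."""


class PrebleachSignalError(TraceError):
    """Background-subtracted prebleach signal is not positive."""


@dataclass(frozen=True)
class RawTrace:
    """Measured intensity time series for a single cell.

    Parameters
    ----------
    cell_id : str
        Label identifying the cell.
    time_s : ndarray
        Acquisition time of each frame, seconds, strictly increasing.
    f_roi, f_total, f_bg : ndarray
        Mean intensity of the bleached ROI, the total nucleus, and the
        background region at each frame (arbitrary units).
    n_prebleach : int
        Number of leading prebleach (prescan) frames; the bleach event
        falls between frame ``n_prebleach - 1`` and ``n_prebleach``.
    """

    cell_id: str
    time_s: np.ndarray
    f_roi: np.ndarray
    f_total: np.ndarray
    f_bg: np.ndarray
    n_prebleach: int

    def __post_init__(self) -> None:
        for name in ("time_s", "f_roi", "f_total", "f_bg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        n = self.time_s.size
        for name in ("f_roi", "f_total", "f_bg"):
            if getattr(self, name).size != n:
                raise TraceLengthError(
                    f"{self.cell_id}: {name} has {getattr(self, name).size} "
                    f"frames, time_s has {n}"
                )
        if n < 2:
            raise TraceLengthError(f"{self.cell_id}: need at least 2 frames")
        if not np.all(np.diff(self.time_s) > 0):
            raise NonMonotoneTimeError(
                f"{self.cell_id}: time_s must be strictly increasing"
            )
        if not (1 <= self.n_prebleach < n):
            raise PrebleachCountError(
                f"{self.cell_id}: n_prebleach={self.n_prebleach} "
                f"not in [1, {n - 1}]"
            )
        for name in ("f_roi", "f_total", "f_bg"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise NonFiniteIntensityError(
                    f"{self.cell_id}: non-finite values in {name}"
                )

    def check_prebleach_signal(self) -> None:
        """Require positive background-subtracted prebleach signal.

        Enforced at normalization time (the quantities divided there),
        not at construction: raw extractions from degenerate images are
        representable, just not quantifiable.
        """
        pre = slice(0, self.n_prebleach)
        if np.any(self.f_total[pre] - self.f_bg[pre] <= 0):
            raise PrebleachSignalError(
                f"{self.cell_id}: prebleach total signal does not exceed "
                "background"
            )

    @property
    def n_frames(self) -> int:
        return int(self.time_s.size)

    @property
    def n_post(self) -> int:
        return self.n_frames - self.n_prebleach
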