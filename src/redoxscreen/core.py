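"""Shared domain containers for time-resolved data.

The TCSPC time axis follows the standard 80 MHz configuration: ``n_bins``
histogram bins spanning one 12.5 ns laser period, bin centers at
``(k + 0.5) * bin_width``.  Relative delays used in convolutions are
``t_m = m * bin_width`` for integer lags ``m >= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InterfaceError, ParameterError

#: Laser repetition period for an 80 MHz source, in picoseconds.
REP_PERIOD_PS = 12_500.0

#: Default number of TCSPC histogram bins.
DEFAULT_N_BINS = 256

#: Default TCSPC bin width (ps) for 256 bins over one 12.5 ns period.
DEFAULT_BIN_WIDTH_PS = REP_PERIOD_PS / DEFAULT_N_BINS


@dataclass(frozen=True)
class IRF:
    """Instrument response function as a 1-D temporal histogram.

    Parameters
    ----------
    counts
        Non-negative per-bin response, any overall scale (normalize with
        :meth:`normalized`).
    bin_width
        Bin width in picoseconds.
    """

    counts: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH_PS

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1:
            raise ParameterError("IRF counts must be a 1-D histogram")
        if counts.size < 64:
            raise ParameterError("IRF must have at least 64 bins")
        if np.any(counts < 0):
            raise ParameterError("IRF counts must be non-negative")
        total = counts.sum()
        if not total > 0:
            raise ParameterError("IRF counts must sum to a positive value")
        peak = int(np.argmax(counts))
        if peak == 0 or peak == counts.size - 1:
            raise ParameterError("IRF peak must lie strictly inside the window")
        if not self.bin_width > 0:
            raise ParameterError("IRF bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def peak_bin(self) -> int:
        return int(np.argmax(self.counts))

    def normalized(self) -> "IRF":
        """Return a copy whose counts sum to exactly 1."""
        return IRF(self.counts / self.counts.sum(), self.bin_width)

    def shifted(self, lag: int) -> "IRF":
        """Return a copy shifted by ``lag`` bins (positive = later), zero-padded."""
        out = np.zeros_like(self.counts)
        if lag >= 0:
            out[lag:] = self.counts[: self.counts.size - lag]
        else:
            out[:lag] = self.counts[-lag:]
        return IRF(out, self.bin_width)


@dataclass
class DecayCube:
    """Per-pixel TCSPC photon histograms, shape ``(rows, cols, n_bins)``.

    ``counts`` holds non-negative integer photon counts; ``bin_width`` is in
    picoseconds.  ``truth`` optionally carries the generating ground truth
    when the cube is synthetic.
    """

    counts: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH_PS
    truth: object | None = field(default=None, repr=False)

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise InterfaceError("DecayCube counts must have shape (rows, cols, n_bins)")
        if np.any(counts < 0):
            raise InterfaceError("DecayCube counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise InterfaceError("DecayCube counts must be integer-valued")
            counts = np.round(counts).astype(np.int64)
        self.counts = counts
        if not self.bin_width > 0:
            raise ParameterError("DecayCube bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def time_axis(self) -> np.ndarray:
        """Bin-center times in picoseconds."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def photons(self) -> np.ndarray:
        """Total photon count per pixel, shape (rows, cols)."""
        return self.counts.sum(axis=2)

    def check_irf(self, irf: IRF) -> None:
        if irf.n_bins != self.n_bins:
            raise InterfaceError(
                f"IRF has {irf.n_bins} bins but cube has {self.n_bins}"
            )


def measure_fwhm(counts: np.ndarray, bin_width: float) -> float:
    """Full width at half maximum of a 1-D histogram, in the units of
    ``bin_width``, using linear interpolation across the half-max crossings.
    """
    counts = np.asarray(counts, dtype=float)
    peak = int(np.argmax(counts))
    half = counts[peak] / 2.0

    def _cross(idx_range, reverse):
        prev = peak
        for k in idx_range:
            if counts[k] < half:
                # interpolate between k and prev
                y0, y1 = counts[k], counts[prev]
                frac = (half - y0) / (y1 - y0)
                return k + frac * (prev - k)
            prev = k
        return idx_range[-1] if len(idx_range) else peak

    left = _cross(range(peak - 1, -1, -1), True)
    right = _cross(range(peak + 1, len(counts)), False)
    return float((right - left) * bin_width)
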