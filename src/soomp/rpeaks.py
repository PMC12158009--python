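"""QRS detection: a simplified energy-based R-peak detector.

The detector follows the classic recipe — bandpass filtering to isolate
QRS energy, differentiation, squaring and moving-window integration,
then adaptive thresholding with a refractory period — and finally refines
each detection to the extremum of the (baseline-removed) raw signal in a
short window.  It is deliberately simple and pluggable: any caller that
has better annotations (e.g. database reference marks) can pass peak
positions directly to the codec instead.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

__all__ = ["detect_rpeaks"]


def detect_rpeaks(
    record,
    sampling_rate: float,
    refractory: float = 0.2,
    threshold_fraction: float = 0.25,
) -> np.ndarray:
    """Detect R-peaks in a 1-D ECG record.

    Parameters
    ----------
    record : array-like
        The ECG samples.
    sampling_rate : float
        Samples per second (> 0).
    refractory : float
        Minimum peak separation in seconds (default 200 ms).
    threshold_fraction : float
        Detection threshold as a fraction of a robust (95th percentile)
        amplitude of the integrated energy signal.

    Returns
    -------
    numpy.ndarray
        Strictly increasing sample indices of detected R-peaks; empty
        (with a warning) if nothing crosses the threshold.
    """
    x = np.asarray(record, dtype=np.float64).ravel()
    fs = float(sampling_rate)
    if fs <= 0:
        raise ValueError("sampling_rate must be positive")
    if x.size < 3 or not np.any(x != x[0]):
        warnings.warn("no R-peaks found in record", stacklevel=2)
        return np.empty(0, dtype=int)

    # bandpass 5-15 Hz isolates QRS energy
    nyq = fs / 2.0
    hi = min(15.0, 0.9 * nyq)
    lo = min(5.0, 0.5 * hi)
    sos = sps.butter(2, [lo / nyq, hi / nyq], btype="band", output="sos")
    bp = sps.sosfiltfilt(sos, x)

    energy = np.gradient(bp) ** 2
    win = max(1, int(round(0.15 * fs)))
    integrated = np.convolve(energy, np.ones(win) / win, mode="same")

    thr = threshold_fraction * np.percentile(integrated, 95)
    if thr <= 0:
        warnings.warn("no R-peaks found in record", stacklevel=2)
        return np.empty(0, dtype=int)
    locs, _ = sps.find_peaks(integrated, height=thr, distance=max(1, int(refractory * fs)))
    if locs.size == 0:
        warnings.warn("no R-peaks found in record", stacklevel=2)
        return np.empty(0, dtype=int)

    # refine each detection to the raw-signal extremum (R waves may be
    # positive or negative depending on lead polarity)
    half = max(1, int(round(0.075 * fs)))
    centered = x - np.median(x)
    peaks = []
    for loc in locs:
        a, b = max(0, loc - half), min(x.size, loc + half + 1)
        peaks.append(a + int(np.argmax(np.abs(centered[a:b]))))
    peaks = np.unique(peaks)
    # enforce refractory after refinement
    keep = [int(peaks[0])]
    for p in peaks[1:]:
        if p - keep[-1] >= int(refractory * fs):
            keep.append(int(p))
        elif np.abs(centered[p]) > np.abs(centered[keep[-1]]):
            keep[-1] = int(p)
    return np.asarray(keep, dtype=int)
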