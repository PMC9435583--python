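"""Band-averaged imaginary-coherency functional connectivity.

Coherency between two channels x, y at frequency f is the normalized
cross-spectrum

    C_xy(f) = S_xy(f) / sqrt(S_xx(f) S_yy(f)),

estimated here Welch-style (Hann-tapered overlapping windows).  Its
imaginary part vanishes for any instantaneous (zero-lag) linear mixing of
sources, which makes |Im C| a connectivity index that is insensitive to
volume-conduction-like crosstalk and responds only to lagged interaction.
The per-segment FC value of an edge is the mean of |Im C_xy(f)| over the
analysis band (1-40 Hz by default); self-connectivity is identically zero.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal import get_window
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .features import vectorize_fc

__all__ = [
    "estimate_csd",
    "imaginary_coherency_fc",
    "merge_to_parcels",
    "ImaginaryCoherency",
]


def _frame(signals: np.ndarray, nperseg: int, nstep: int) -> np.ndarray:
    """Sliding windows (..., n_windows, nperseg) over the last axis."""
    n = signals.shape[-1]
    n_win = (n - nperseg) // nstep + 1
    idx = nstep * np.arange(n_win)[:, None] + np.arange(nperseg)[None, :]
    return signals[..., idx]


def estimate_csd(
    signals: np.ndarray,
    sample_rate_hz: float,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch cross-spectral density matrix of a multichannel segment.

    Parameters
    ----------
    signals : (..., n_channels, n_samples)
        One segment (or a leading batch of segments).
    sample_rate_hz : sampling rate.
    window_s : Hann window length in seconds; sets the frequency
        resolution 1/window_s.
    overlap : fractional window overlap in [0, 1).

    Returns
    -------
    csd : (..., n_channels, n_channels, n_freqs) complex
        Hermitian at every frequency; diagonal real and >= 0.
    freqs_hz : (n_freqs,) one-sided frequency grid.

    Notes
    -----
    Scaling follows the one-sided density convention (as
    ``scipy.signal.csd`` with ``detrend=False``); coherency is invariant
    to this choice.
    """
    signals = np.asarray(signals, dtype=float)
    nperseg = int(round(window_s * sample_rate_hz))
    if signals.shape[-1] < nperseg:
        raise ValueError(
            f"segment has {signals.shape[-1]} samples < window of {nperseg}"
        )
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    nstep = max(1, int(round(nperseg * (1 - overlap))))

    win = get_window("hann", nperseg)
    frames = _frame(signals, nperseg, nstep) * win  # (..., ch, n_win, nperseg)
    spec = rfft(frames, axis=-1)  # (..., ch, n_win, n_freq)
    # one-sided density scaling, doubled except DC/Nyquist
    scale = 1.0 / (sample_rate_hz * (win ** 2).sum())
    # conj on the first factor matches the scipy.signal.csd convention
    csd = np.einsum("...iwf,...jwf->...ijf", np.conj(spec), spec)
    csd *= scale / frames.shape[-2]
    freqs = rfftfreq(nperseg, d=1.0 / sample_rate_hz)
    dbl = np.ones(freqs.shape[0])
    dbl[1:] = 2.0
    if nperseg % 2 == 0:
        dbl[-1] = 1.0
    csd *= dbl
    return csd, freqs


def imaginary_coherency_fc(
    csd: np.ndarray,
    freqs_hz: np.ndarray,
    band_hz: tuple[float, float] = (1.0, 40.0),
    signed: bool = False,
) -> np.ndarray:
    """Band-averaged imaginary-coherency FC matrix from a CSD.

    FC_ij = mean over band bins of |Im C_ij(f)| (or of Im C_ij(f) when
    ``signed``); FC_ii = 0 exactly.  Entries lie in [0, 1] for the
    default magnitude convention.

    Raises if any channel's auto-spectrum vanishes on a band bin
    (degenerate channel: coherency undefined).
    """
    csd = np.asarray(csd)
    freqs_hz = np.asarray(freqs_hz)
    lo, hi = band_hz
    sel = (freqs_hz >= lo) & (freqs_hz <= hi)
    if not sel.any():
        raise ValueError(f"band {band_hz} not covered by frequency grid")
    sub = csd[..., sel]
    auto = np.real(np.einsum("...iif->...if", sub))
    if np.any(auto <= 0):
        raise ValueError("zero auto-spectrum inside the band: degenerate channel")
    norm = np.sqrt(auto[..., :, None, :] * auto[..., None, :, :])
    im = np.imag(sub) / norm
    fc = im.mean(axis=-1) if signed else np.abs(im).mean(axis=-1)
    # exact zeros on the diagonal (Im of a real self-coherency)
    i = np.arange(fc.shape[-1])
    fc[..., i, i] = 0.0
    return fc


def merge_to_parcels(fc_full: np.ndarray, parcel_of: np.ndarray,
                     n_parcels: int | None = None) -> np.ndarray:
    """Average a node-level FC matrix onto a coarser parcel grid.

    ``parcel_of`` maps each node to its parcel index.  The parcel-pair
    value is the mean of node-pair values over all node pairs spanning the
    two parcels (for a parcel with itself: all distinct node pairs within
    it, but the output diagonal is set to 0 to keep the self-connectivity
    convention).  Every parcel must own at least one node.
    """
    fc_full = np.asarray(fc_full, dtype=float)
    parcel_of = np.asarray(parcel_of)
    n_nodes = fc_full.shape[0]
    if parcel_of.shape[0] != n_nodes:
        raise ValueError("parcel_of length must equal the node count")
    p = int(parcel_of.max()) + 1 if n_parcels is None else n_parcels
    counts = np.bincount(parcel_of, minlength=p)
    if (counts == 0).any():
        empty = np.flatnonzero(counts == 0)
        raise ValueError(f"empty parcel(s): {empty.tolist()}")
    # indicator matrix nodes x parcels
    ind = np.zeros((n_nodes, p))
    ind[np.arange(n_nodes), parcel_of] = 1.0
    sums = ind.T @ fc_full @ ind
    npairs = np.outer(counts, counts).astype(float)
    # within-parcel: exclude the zero self-pairs from the average
    np.fill_diagonal(npairs, counts * (counts - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        merged = np.where(npairs > 0, sums / np.maximum(npairs, 1), 0.0)
    np.fill_diagonal(merged, 0.0)
    return merged


class ImaginaryCoherency(TransformerMixin, BaseEstimator):
    """Transform segment time series into imaginary-coherency FC features.

    Input ``X`` has shape (n_segments, n_channels, n_samples).  Output is
    either the stack of symmetric FC matrices (``output="matrix"``) or the
    canonical lower-triangle feature vectors ready for selection and
    classification (``output="vector"``, default), shape
    (n_segments, n_channels(n_channels+1)/2).

    Parameters
    ----------
    sample_rate_hz : sampling rate of the segments (default 100).
    band_hz : analysis band averaged over, default (1, 40).
    window_s, overlap : Welch parameters (1-s Hann windows, 50% overlap:
        7 windows on a 4-s segment).
    signed : keep the signed imaginary part instead of its magnitude.
    batch_size : segments per CSD batch, bounds peak memory.
    """

    def __init__(self, sample_rate_hz: float = 100.0,
                 band_hz: tuple[float, float] = (1.0, 40.0),
                 window_s: float = 1.0, overlap: float = 0.5,
                 signed: bool = False, output: str = "vector",
                 batch_size: int = 128):
        self.sample_rate_hz = sample_rate_hz
        self.band_hz = band_hz
        self.window_s = window_s
        self.overlap = overlap
        self.signed = signed
        self.output = output
        self.batch_size = batch_size

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("X must be (n_segments, n_channels, n_samples)")
        if self.output not in ("vector", "matrix"):
            raise ValueError("output must be 'vector' or 'matrix'")
        self.n_channels_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X)
        if X.ndim != 3 or X.shape[1] != self.n_channels_:
            raise ValueError("X must match the fitted (n_channels, .) layout")
        mats = []
        for start in range(0, X.shape[0], self.batch_size):
            chunk = X[start:start + self.batch_size]
            csd, freqs = estimate_csd(chunk, self.sample_rate_hz,
                                      self.window_s, self.overlap)
            mats.append(imaginary_coherency_fc(csd, freqs, self.band_hz,
                                               signed=self.signed))
        fc = np.concatenate(mats, axis=0)
        if self.output == "matrix":
            return fc
        return np.stack([vectorize_fc(m) for m in fc])
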