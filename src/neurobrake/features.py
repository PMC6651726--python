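"""Feature extraction: FFT relative band power and Burg AR coefficients.

Band power
----------
Each 1-s, 128-sample channel is zero-padded to a 512-point periodogram
(0.25 Hz bins, no taper by default).  Absolute power ``PB_i`` is the
PSD sum over band i with half-open edges [low, high) so adjacent bands
never double-count a bin; the relative power is
``rPB_i = PB_i / sum_j PB_j``.  Bands: delta 1-4, theta 4-8, alpha
8-14, beta 14-30, gamma 30-60 Hz; 5 bands x 8 channels = 40 features.

Autoregressive model
--------------------
Each channel is modeled as ``X_t = c + sum_i phi_i X_{t-i} + eps_t``.
The coefficients are estimated with the Burg method — the recursion
minimizes combined forward/backward prediction error through reflection
coefficients (|k| <= 1 by construction) and updates phi via the
Levinson recursion — which gives stable high-resolution estimates from
128-sample segments.  Series are mean-centered first; the mean is
recorded as the intercept and excluded from the feature vector, which
holds the p coefficients plus the innovation variance per channel
(8 x (p+1) values: 32..168 for orders 3..20).

Both feature vectors are laid out channel-major (all of channel F3,
then F4, ...) with band/coefficient minor; downstream models rely on
this layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import EEG_CHANNELS, MultichannelWindow

#: Canonical EEG band edges in Hz, half-open [low, high).
BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 14.0),
    ("beta", 14.0, 30.0),
    ("gamma", 30.0, 60.0),
)

N_FFT = 512


@dataclass
class BandPowerFeature:
    """Absolute and relative band powers, 8 channels x 5 bands."""

    absolute: np.ndarray  # (8, 5)
    relative: np.ndarray  # (8, 5)
    degenerate_channels: tuple[int, ...] = ()

    @property
    def vector(self) -> np.ndarray:
        """Relative powers flattened channel-major, length 40."""
        return self.relative.reshape(-1)


@dataclass
class ARFit:
    """Per-channel AR(p) fits of one window."""

    order: int
    coefficients: np.ndarray  # (8, p)
    noise_variance: np.ndarray  # (8,)
    intercept: np.ndarray  # (8,)
    stationary: np.ndarray  # (8,) bool

    @property
    def vector(self) -> np.ndarray:
        """Per-channel [phi_1..phi_p, noise_variance], channel-major.

        Length 8 * (p + 1), matching the classifier input sizes
        32..168 for orders 3..20.
        """
        return np.hstack(
            [self.coefficients, self.noise_variance[:, None]]
        ).reshape(-1)


def band_power_features(
    window: MultichannelWindow, taper: str | None = None
) -> BandPowerFeature:
    """Relative band power of each channel from a 512-point periodogram.

    An all-zero (or constant) channel has no spectral content; its
    relative powers are set to the uniform 1/5 by convention and the
    channel index is flagged in ``degenerate_channels``.
    """
    win = "boxcar" if taper is None else taper
    freqs, psd = signal.periodogram(
        window.samples,
        fs=window.fs,
        nfft=N_FFT,
        window=win,
        detrend=False,
        axis=1,
    )
    absolute = np.empty((8, len(BANDS)))
    for j, (_, lo, hi) in enumerate(BANDS):
        sel = (freqs >= lo) & (freqs < hi)
        absolute[:, j] = psd[:, sel].sum(axis=1)
    totals = absolute.sum(axis=1)
    degenerate = tuple(int(i) for i in np.flatnonzero(totals <= 0))
    safe_tot = np.where(totals > 0, totals, 1.0)
    relative = absolute / safe_tot[:, None]
    for i in degenerate:
        relative[i] = 1.0 / len(BANDS)
    return BandPowerFeature(
        absolute=absolute, relative=relative, degenerate_channels=degenerate
    )


def burg_ar(series, order: int) -> tuple[np.ndarray, float, np.ndarray]:
    """Burg estimate of AR coefficients for one mean-centered series.

    Returns ``(phi, noise_variance, reflection)`` where phi follows the
    convention ``x_t = sum_i phi_i x_{t-i} + eps_t``.  The recursion
    minimizes the summed forward and backward prediction error; each
    reflection coefficient satisfies |k| <= 1, which keeps the model on
    or inside the stationarity boundary.

    Raises
    ------
    ValueError
        If ``order >= len(series) / 2`` or the series has zero variance.
    """
    x = np.asarray(series, dtype=np.float64).ravel()
    n = x.size
    if order < 1:
        raise ValueError("order must be >= 1")
    if order >= n / 2:
        raise ValueError(f"order {order} too high for series length {n}")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance series has no AR representation")

    f = x.copy()  # forward prediction errors
    b = x.copy()  # backward prediction errors
    a = np.zeros(order)  # polynomial coefficients, sign: A(z) x = eps
    reflection = np.zeros(order)
    energy = float(x @ x) / n
    for m in range(order):
        fs = f[m + 1 :]
        bs = b[m:-1]
        denom = float(fs @ fs + bs @ bs)
        if denom <= 0:
            # perfectly predictable: remaining reflections are zero
            break
        k = -2.0 * float(fs @ bs) / denom
        reflection[m] = k
        # Levinson update of the polynomial coefficients
        a_prev = a[:m].copy()
        a[:m] = a_prev + k * a_prev[::-1]
        a[m] = k
        # update error sequences
        f_new = fs + k * bs
        b_new = bs + k * fs
        f[m + 1 :] = f_new
        b[m + 1 :] = b_new
        energy *= 1.0 - k * k
    phi = -a
    return phi, energy, reflection


def ar_features(window: MultichannelWindow, order: int = 10) -> ARFit:
    """Burg AR(p) fit of every channel, concatenated channel-major.

    Channels are mean-centered before fitting; the recorded intercept
    is the channel mean.  Errors from the underlying fit are re-raised
    naming the offending channel.
    """
    coeffs = np.empty((8, order))
    noise = np.empty(8)
    intercept = np.empty(8)
    stationary = np.empty(8, dtype=bool)
    for i in range(8):
        mean = window.samples[i].mean()
        try:
            phi, sigma2, _ = burg_ar(window.samples[i] - mean, order)
        except ValueError as err:
            raise ValueError(
                f"channel {EEG_CHANNELS[i]}: {err}"
            ) from err
        coeffs[i] = phi
        noise[i] = sigma2
        intercept[i] = mean
        roots = np.roots(np.concatenate(([1.0], -phi)))
        stationary[i] = bool(np.all(np.abs(roots) < 1.0 + 1e-8))
    return ARFit(
        order=order,
        coefficients=coeffs,
        noise_variance=noise,
        intercept=intercept,
        stationary=stationary,
    )
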