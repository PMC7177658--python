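"""Fixed-length frequency-domain features from variable-length episodes.

Episodes differ in length, so raw series cannot feed a classifier
directly. The discrete Fourier transform of each channel (gap, speed,
acceleration) is truncated to its first ``n_keep`` coefficients
(default 15) and converted to amplitudes |DFT_k| / N, discarding the
higher frequencies as noise. Dividing by N makes amplitudes comparable
across episode lengths — the k = 0 amplitude is then exactly the
absolute series mean.

An optional band-limited mode keeps instead every coefficient with
frequency k / (N*dt) <= f_max, padding/truncating to a fixed width, for
workflows that think in hertz rather than coefficient counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trajectory_io import CarFollowingEpisode

__all__ = [
    "CHANNEL_ORDER",
    "dft_amplitudes",
    "band_limited_amplitudes",
    "build_feature_matrix",
]

#: Fixed channel order for concatenation.
CHANNEL_ORDER = ("gap", "speed", "acceleration")

_CHANNEL_ATTR = {"gap": "d", "speed": "v_f", "acceleration": "a_f"}


def dft_amplitudes(series, n_keep: int = 15) -> np.ndarray:
    """First ``n_keep`` DFT amplitudes |DFT_k| / N of a real series."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < n_keep:
        raise ValueError(f"series length {n} < n_keep {n_keep}")
    coeffs = np.fft.fft(x)[:n_keep]
    return np.abs(coeffs) / n


def band_limited_amplitudes(
    series, dt: float, f_max: float = 1.5, width: int = 15
) -> np.ndarray:
    """Amplitudes for frequencies k/(N*dt) <= f_max, fixed to ``width``.

    Keeps coefficients up to f_max hertz; the result is truncated or
    zero-padded to ``width`` entries so rows remain stackable.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    k_max = int(np.floor(f_max * n * dt))
    amps = np.abs(np.fft.fft(x)[: k_max + 1]) / n
    out = np.zeros(width)
    m = min(width, len(amps))
    out[:m] = amps[:m]
    return out


def build_feature_matrix(
    episodes: list[CarFollowingEpisode],
    labels: pd.DataFrame,
    channels=("gap", "speed", "acceleration"),
    n_keep: int = 15,
    mode: str = "fixed_count",
    f_max: float = 1.5,
) -> pd.DataFrame:
    """Stack per-driver channel amplitude vectors into a labeled matrix.

    ``labels`` must carry ``driver_id`` and a binary ``label`` column
    (1 = aggressive). Channels are concatenated in the fixed order
    gap, speed, acceleration regardless of the order given. Returns a
    DataFrame indexed by driver_id with columns ``<channel>_k<j>`` plus
    ``label``.
    """
    chans = [c for c in CHANNEL_ORDER if c in set(channels)]
    unknown = set(channels) - set(CHANNEL_ORDER)
    if unknown:
        raise ValueError(f"unknown channel(s): {sorted(unknown)}")
    if not chans:
        raise ValueError("need at least one channel")
    label_map = dict(
        zip(labels["driver_id"].astype(int), labels["label"].astype(int))
    )
    rows, index, y = [], [], []
    for ep in episodes:
        if ep.follower_id not in label_map:
            raise KeyError(f"no label for driver {ep.follower_id}")
        vecs = []
        for c in chans:
            series = getattr(ep, _CHANNEL_ATTR[c])
            if mode == "fixed_count":
                vecs.append(dft_amplitudes(series, n_keep))
            elif mode == "band_limited":
                vecs.append(band_limited_amplitudes(series, ep.dt, f_max, n_keep))
            else:
                raise ValueError(f"unknown mode {mode!r}")
        rows.append(np.concatenate(vecs))
        index.append(ep.follower_id)
        y.append(label_map[ep.follower_id])
    cols = [f"{c}_k{j}" for c in chans for j in range(n_keep)]
    df = pd.DataFrame(rows, columns=cols, index=pd.Index(index, name="driver_id"))
    df["label"] = y
    return df
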