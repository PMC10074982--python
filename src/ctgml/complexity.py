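"""Non-linear fetal heart rate complexity indices.

Two families of indices characterise the irregularity of a fetal heart
rate (fHR) trace:

* **Multiscale sample entropy (MSE)** — sample entropy (SampEn) computed
  on coarse-grained copies of the series at scales 1..S.  SampEn(m, r) is
  the negative log of the conditional probability that two sequences that
  match for ``m`` points (Chebyshev distance <= ``r``, self-matches
  excluded) keep matching for ``m + 1`` points.

* **Multiscale compression (MSC)** — the same coarse-graining scheme with
  the entropy estimator replaced by the bzip2-compressed size of the
  series, a practical proxy for Kolmogorov complexity.  From the
  compressed size the compression ratio

      CR(s) = 100 * compressed_bytes(s) / raw_bytes(s)

  is derived per scale; CR at scale 2 (CR2) is the headline
  discriminative index.

Each scale curve over the first five scales is summarised by its sum, its
ordinary-least-squares slope against the scale index, and the product of
the two, yielding fifteen indices in total.
"""

from __future__ import annotations

import bz2
import math
from dataclasses import dataclass, fields
from typing import Callable, Iterable, Mapping

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ComplexityConfig",
    "ComplexityIndices",
    "ComplexityFeatures",
    "INDEX_NAMES",
    "coarse_grain",
    "sample_entropy",
    "mse_curve",
    "curve_summary",
    "encode_series",
    "decode_series",
    "compressed_size",
    "compression_ratio",
    "compute_indices",
]

#: Quantisation step of the byte encoding, in beats per minute.
QUANT_STEP = 0.25

#: Bytes per encoded sample (16-bit unsigned little-endian).
BYTES_PER_SAMPLE = 2

#: MSCsum is rescaled by this factor to bring it to order unity.
MSCSUM_RESCALE = 10_000.0

INDEX_NAMES = (
    "SampEn1", "SampEn2", "MSEsum", "MSEslope", "MSEss",
    "SC1", "SC2", "MSCsum", "MSCslope", "MSCss",
    "CR1", "CR2", "MSCsumCR", "MSCslopeCR", "MSCssCR",
)

_COMPRESSORS: Mapping[str, Callable[[bytes], bytes]] = {
    "bzip2": lambda data: bz2.compress(data, 9),
}


@dataclass(frozen=True)
class ComplexityConfig:
    """Parameters of the complexity index computation.

    Parameters
    ----------
    m : int
        SampEn template length (default 2).
    r_fraction : float
        SampEn tolerance as a fraction of the standard deviation of the
        *original* (scale-1) series; the resulting absolute tolerance is
        reused at every scale (default 0.15).
    n_scales : int
        Number of coarse-graining scales for the multiscale curves
        (default 5).
    compressor : str
        Label of the compressor used for the MSC family (default
        ``"bzip2"``).
    """

    m: int = 2
    r_fraction: float = 0.15
    n_scales: int = 5
    compressor: str = "bzip2"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if not self.r_fraction > 0:
            raise ValueError(f"r_fraction must be > 0, got {self.r_fraction}")
        if self.n_scales < 2:
            raise ValueError(f"n_scales must be >= 2, got {self.n_scales}")
        if self.compressor not in _COMPRESSORS:
            raise ValueError(f"unknown compressor {self.compressor!r}")


@dataclass(frozen=True)
class ComplexityIndices:
    """The fifteen non-linear indices for one signal.

    Entropy indices are in nats; SC1/SC2 in bytes; MSCsum in units of
    10,000 bytes; CR indices in percent.  Degenerate entropies (no
    template matches) are ``inf``; curve summaries built from them are
    ``nan`` and downstream screening treats them as missing.
    """

    SampEn1: float
    SampEn2: float
    MSEsum: float
    MSEslope: float
    MSEss: float
    SC1: float
    SC2: float
    MSCsum: float
    MSCslope: float
    MSCss: float
    CR1: float
    CR2: float
    MSCsumCR: float
    MSCslopeCR: float
    MSCssCR: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _as_series(series) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {x.shape}")
    return x


def coarse_grain(series, s: int) -> np.ndarray:
    """Coarse-grain a series by averaging blocks of ``s`` consecutive points.

    Output element ``j`` is the mean of input elements ``j*s .. (j+1)*s - 1``
    (0-based); a trailing remainder shorter than ``s`` is dropped, so the
    output has ``floor(N / s)`` elements.
    """
    x = _as_series(series)
    if s < 1:
        raise ValueError(f"scale must be >= 1, got {s}")
    if x.size == 0:
        raise ValueError("cannot coarse-grain an empty series")
    if x.size < s:
        raise ValueError(f"series of length {x.size} too short for scale {s}")
    if s == 1:
        return x.copy()
    n = x.size // s
    return x[: n * s].reshape(n, s).mean(axis=1)


def sample_entropy(series, m: int = 2, r: float = 0.0) -> float:
    """Sample entropy of a series with template length ``m``, tolerance ``r``.

    SampEn = -ln(A / B) where B counts ordered pairs of distinct m-point
    templates within Chebyshev distance ``r`` and A the same for
    (m+1)-point templates; both use the N-m templates whose (m+1)-point
    extension exists, and self-matches are excluded.  Returns ``inf``
    when A or B is zero (entropy undefined; flagged, not an error).
    """
    x = _as_series(series)
    n = x.size
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if r < 0:
        raise ValueError(f"tolerance r must be >= 0, got {r}")
    if n <= m + 1:
        raise ValueError(f"series of length {n} too short for m={m}")

    # Both template sets use the n-m windows whose (m+1)-point extension
    # exists; the m-point Chebyshev distance is the running max over the
    # first m coordinates and extends to m+1 with one more coordinate.
    n_templates = n - m
    coords = [x[k:k + n_templates] for k in range(m + 1)]
    a = 0
    b = 0
    chunk = max(1, (1 << 23) // max(n_templates, 1))
    for start in range(0, n_templates, chunk):
        sl = slice(start, start + chunk)
        d = np.abs(np.subtract.outer(coords[0][sl], coords[0]))
        for k in range(1, m):
            np.maximum(d, np.abs(np.subtract.outer(coords[k][sl], coords[k])),
                       out=d)
        b += int((d <= r).sum())
        np.maximum(d, np.abs(np.subtract.outer(coords[m][sl], coords[m])),
                   out=d)
        a += int((d <= r).sum())
    # Remove self-matches (distance 0 <= r always); ordered double-counting
    # cancels in the ratio.
    a -= n_templates
    b -= n_templates
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def mse_curve(series, config: ComplexityConfig = ComplexityConfig()) -> np.ndarray:
    """Sample entropy at scales 1..n_scales (tolerance fixed from scale 1).

    The tolerance is ``r_fraction * SD`` of the original series and is
    reused unchanged at every scale, the usual multiscale-entropy
    convention.
    """
    x = _as_series(series)
    if x.size // config.n_scales <= config.m + 1:
        raise ValueError(
            f"series of length {x.size} too short for {config.n_scales} scales "
            f"with m={config.m}"
        )
    r = config.r_fraction * float(np.std(x))
    return np.array(
        [sample_entropy(coarse_grain(x, s), config.m, r)
         for s in range(1, config.n_scales + 1)]
    )


def curve_summary(curve) -> tuple[float, float, float]:
    """Summarise a scale curve as (sum, OLS slope vs scale index, sum*slope)."""
    y = _as_series(curve)
    if y.size < 2:
        raise ValueError("curve must span at least two scales")
    if not np.all(np.isfinite(y)):
        raise ValueError("curve contains non-finite entries")
    s = np.arange(1, y.size + 1, dtype=float)
    slope = float(np.polyfit(s, y, 1)[0])
    total = float(y.sum())
    return total, slope, total * slope


def encode_series(series) -> bytes:
    """Serialise a series to bytes: 0.25-bpm quantisation, 16-bit LE.

    Each sample is rounded to the nearest 0.25 bpm and stored as an
    unsigned 16-bit little-endian integer count of quantisation steps, so
    an N-sample series is exactly 2N bytes and the mapping is
    deterministic across platforms.
    """
    x = _as_series(series)
    if x.size == 0:
        raise ValueError("cannot encode an empty series")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    q = np.rint(x / QUANT_STEP)
    if q.min() < 0 or q.max() > np.iinfo(np.uint16).max:
        raise ValueError(
            "series outside encodable range "
            f"[0, {np.iinfo(np.uint16).max * QUANT_STEP}] bpm"
        )
    return q.astype("<u2").tobytes()


def decode_series(data: bytes) -> np.ndarray:
    """Inverse of :func:`encode_series` up to the 0.125-bpm quantisation bound."""
    if len(data) == 0 or len(data) % BYTES_PER_SAMPLE:
        raise ValueError("byte length is not a positive multiple of 2")
    return np.frombuffer(data, dtype="<u2").astype(float) * QUANT_STEP


def compressed_size(series, compressor: str = "bzip2") -> int:
    """Size in bytes of the compressed byte encoding of a series."""
    try:
        compress = _COMPRESSORS[compressor]
    except KeyError:
        raise ValueError(f"unknown compressor {compressor!r}") from None
    return len(compress(encode_series(series)))


def compression_ratio(series, compressor: str = "bzip2") -> float:
    """Compressed size as a percentage of the raw encoded size."""
    raw = encode_series(series)
    try:
        compress = _COMPRESSORS[compressor]
    except KeyError:
        raise ValueError(f"unknown compressor {compressor!r}") from None
    return 100.0 * len(compress(raw)) / len(raw)


def compute_indices(signal, config: ComplexityConfig = ComplexityConfig()) -> ComplexityIndices:
    """Compute all fifteen indices for one signal.

    ``signal`` may be a 1-D array of fHR samples or any object with a
    ``samples`` attribute (e.g. :class:`ctgml.signals.FhrSignal`).
    """
    x = _as_series(getattr(signal, "samples", signal))
    scales = range(1, config.n_scales + 1)
    grained = [coarse_grain(x, s) for s in scales]

    mse = mse_curve(x, config)
    if np.all(np.isfinite(mse)):
        mse_sum, mse_slope, mse_ss = curve_summary(mse)
    else:
        mse_sum = mse_slope = mse_ss = math.nan

    sc = np.array([float(compressed_size(g, config.compressor)) for g in grained])
    cr = np.array([compression_ratio(g, config.compressor) for g in grained])
    sc_sum, sc_slope, _ = curve_summary(sc)
    cr_sum, cr_slope, cr_ss = curve_summary(cr)

    msc_sum = sc_sum / MSCSUM_RESCALE
    return ComplexityIndices(
        SampEn1=float(mse[0]),
        SampEn2=float(mse[1]),
        MSEsum=mse_sum,
        MSEslope=mse_slope,
        MSEss=mse_ss,
        SC1=sc[0],
        SC2=sc[1],
        MSCsum=msc_sum,
        MSCslope=sc_slope,
        MSCss=msc_sum * sc_slope,
        CR1=cr[0],
        CR2=cr[1],
        MSCsumCR=cr_sum,
        MSCslopeCR=cr_slope,
        MSCssCR=cr_ss,
    )


class ComplexityFeatures(TransformerMixin, BaseEstimator):
    """Transformer mapping fHR signals to the fifteen complexity indices.

    Stateless apart from configuration; ``fit`` only validates parameters.
    ``transform`` accepts an iterable of signals (arrays or objects with a
    ``samples`` attribute) and returns a ``pandas.DataFrame`` with one row
    per signal and the index columns of :data:`INDEX_NAMES`; the row index
    carries each signal's ``subject_id`` when present.
    """

    def __init__(self, m: int = 2, r_fraction: float = 0.15,
                 n_scales: int = 5, compressor: str = "bzip2") -> None:
        self.m = m
        self.r_fraction = r_fraction
        self.n_scales = n_scales
        self.compressor = compressor

    def _config(self) -> ComplexityConfig:
        return ComplexityConfig(
            m=self.m, r_fraction=self.r_fraction,
            n_scales=self.n_scales, compressor=self.compressor,
        )

    def fit(self, X: Iterable = None, y=None) -> "ComplexityFeatures":
        self.config_ = self._config()
        return self

    def transform(self, X: Iterable):
        import pandas as pd

        config = self._config()
        rows, index = [], []
        for i, sig in enumerate(X):
            rows.append(compute_indices(sig, config).as_dict())
            index.append(getattr(sig, "subject_id", i))
        return pd.DataFrame(rows, index=index, columns=list(INDEX_NAMES))
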