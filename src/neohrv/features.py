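"""Per-epoch HRV feature battery.

Time domain (SDSD, SDNN, RMSSD, pNN50, TRI, TINN, CD, SD2, SD1SD2ratio,
HR), frequency domain on the linearly interpolated RR tachogram (VLF
< 0.04 Hz, LF 0.04–0.3 Hz, HF 0.3–1.3 Hz — the neonatal bands — plus
TotalPower, LF/HF ratio, pLF, pHF), approximate entropy, and multiscale
sample/distribution entropy via coarse graining (scales 1–4 for 180 s
epochs, scale 1 only for 60 s epochs): 20 features at 60 s, 26 at 180 s.

A feature whose preconditions fail (too few beats for a stable estimate)
is returned as NaN, to be imputed by the model stage; no exception
propagates from feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .preprocessing import RRSeries

# Frequency bands (Hz), half-open partitions of [0, 1.3)
VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.3)
HF_BAND = (0.3, 1.3)

#: RR histogram bin width for TRI/TINN: one sample at 128 Hz, the standard
#: HRV convention matched to the acquisition rate.
TRI_BIN_MS = 1000.0 / 128.0

TACHOGRAM_FS = 8.0  # Hz, comfortably above 2 x 1.3 Hz


@dataclass
class EntropyParams:
    """Parameters of the entropy estimators.

    m : embedding dimension (2); r : tolerance as a fraction of the scale-1
    series SD (0.2), converted once to an absolute value and held fixed
    across scales; tau : delay (1); n_bins : DistEn histogram bins (512);
    scales : coarse-graining scales; min_points : minimum series length per
    scale (100) below which that scale is missing.
    """

    m: int = 2
    r: float = 0.2
    tau: int = 1
    n_bins: int = 512
    scales: tuple = (1, 2, 3, 4)
    min_points: int = 100

    def __post_init__(self) -> None:
        if self.m < 1 or self.r <= 0 or self.n_bins < 2 or not self.scales:
            raise ValueError("invalid entropy parameters")


def feature_names(epoch_length_s: float) -> list[str]:
    """Canonical ordered feature names: 20 for 60 s epochs, 26 for 180 s."""
    scales = (1, 2, 3, 4) if epoch_length_s >= 180 else (1,)
    return BASE_FEATURE_NAMES + [f"MDE_{s}" for s in scales] + [f"MSE_{s}" for s in scales]


BASE_FEATURE_NAMES = [
    "SDSD", "SDNN", "RMSSD", "pNN50", "TRI", "TINN", "CD", "SD2",
    "SD1SD2ratio", "HR",
    "VLF", "LF", "HF", "LFHFratio", "TotalPower", "pLF", "pHF",
    "ApEn",
]


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def time_domain(rr: RRSeries) -> dict:
    """SDNN, SDSD, RMSSD (ms), pNN50 (%), HR (bpm); sample SDs (n-1)."""
    out = dict.fromkeys(("SDNN", "SDSD", "RMSSD", "pNN50", "HR"), np.nan)
    x = rr.rr_ms
    if x.size < 3:
        return out
    d = np.diff(x)
    out["SDNN"] = float(np.std(x, ddof=1))
    out["SDSD"] = float(np.std(d, ddof=1))
    out["RMSSD"] = float(np.sqrt(np.mean(d ** 2)))
    out["pNN50"] = float(100.0 * np.mean(np.abs(d) > 50.0))
    out["HR"] = float(60000.0 / np.mean(x))
    return out


def _rr_histogram(x, bin_ms=TRI_BIN_MS):
    lo = np.floor(x.min() / bin_ms) * bin_ms
    n_bins = int(np.floor((x.max() - lo) / bin_ms)) + 1
    edges = lo + bin_ms * np.arange(n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    return counts, edges


def geometric(rr: RRSeries, bin_ms: float = TRI_BIN_MS) -> dict:
    """Triangular index (histogram area / mode height) and TINN (base width
    of the least-squares triangular fit to the RR histogram), bin width
    7.8125 ms."""
    out = {"TRI": np.nan, "TINN": np.nan}
    x = rr.rr_ms
    if x.size < 20:
        return out
    counts, edges = _rr_histogram(x, bin_ms)
    out["TRI"] = float(x.size / counts.max())
    if counts.size == 1:
        out["TINN"] = float(bin_ms)
        return out
    out["TINN"] = float(_tinn(counts, bin_ms))
    return out


def _tinn(counts, bin_ms):
    """Base width M - N of the best triangular interpolation of the
    histogram: apex fixed at the mode, (N, M) searched exhaustively, error
    summed over all bins with the triangle evaluated at bin centers."""
    k = counts.size
    mode = int(np.argmax(counts))
    y = counts[mode]
    centers = np.arange(k) + 0.5
    apex = mode + 0.5
    best = (np.inf, 1.0)
    for n in range(-1, mode):          # left base bin index (center n + 0.5)
        ncen = n + 0.5
        for m in range(mode + 1, k + 1):
            mcen = m + 0.5
            tri = np.zeros(k)
            left = (centers > ncen) & (centers <= apex)
            right = (centers > apex) & (centers < mcen)
            tri[left] = y * (centers[left] - ncen) / (apex - ncen)
            tri[right] = y * (mcen - centers[right]) / (mcen - apex)
            err = float(np.sum((counts - tri) ** 2))
            if err < best[0] - 1e-12:
                best = (err, (mcen - ncen) * bin_ms)
    return best[1]


def poincare(rr: RRSeries) -> dict:
    """Poincaré descriptors from the SDNN/SDSD identities:
    SD1 = SDSD/sqrt(2), SD2 = sqrt(2 SDNN^2 - SDSD^2/2)."""
    out = {"SD2": np.nan, "SD1SD2ratio": np.nan}
    x = rr.rr_ms
    if x.size < 3:
        return out
    sdnn = np.std(x, ddof=1)
    sdsd = np.std(np.diff(x), ddof=1)
    sd1 = np.sqrt(0.5) * sdsd
    sd2_sq = 2.0 * sdnn ** 2 - 0.5 * sdsd ** 2
    sd2 = float(np.sqrt(max(sd2_sq, 0.0)))
    out["SD2"] = sd2
    out["SD1SD2ratio"] = float(sd1 / sd2) if sd2 > 0 else np.nan
    return out


def correlation_dimension(rr: RRSeries, n_radii: int = 12) -> float:
    """Grassberger–Procaccia correlation dimension of the RR series,
    embedding dimension 2, delay 1: slope of log C(rho) vs log rho over the
    scaling region (1st–25th percentile of pairwise distances; larger radii
    leave the scaling regime as C saturates toward 1)."""
    x = rr.rr_ms
    if x.size < 100:
        return np.nan
    emb = np.column_stack([x[:-1], x[1:]])
    diff = emb[:, None, :] - emb[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    iu = np.triu_indices(d.shape[0], k=1)
    dist = d[iu]
    dist = dist[dist > 0]
    if dist.size < 10:
        return np.nan
    lo, hi = np.percentile(dist, [1, 25])
    if hi <= lo:
        return np.nan
    radii = np.exp(np.linspace(np.log(lo), np.log(hi), n_radii))
    c = np.array([np.mean(d[iu] < r) for r in radii])
    ok = c > 0
    if ok.sum() < 2:
        return np.nan
    slope = np.polyfit(np.log(radii[ok]), np.log(c[ok]), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------

def _band_power(freqs, psd, lo, hi):
    """Integral of the piecewise-linear PSD over [lo, hi]; adjacent bands
    share their edge value, so a partition's powers sum exactly."""
    lo = max(lo, freqs[0])
    hi = min(hi, freqs[-1])
    if hi <= lo:
        return 0.0
    inner = freqs[(freqs > lo) & (freqs < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    vals = np.interp(grid, freqs, psd)
    return float(np.trapezoid(vals, grid))


def frequency_domain(rr: RRSeries, start_s: float, end_s: float) -> dict:
    """Band powers of the linearly interpolated RR tachogram, resampled at
    8 Hz over the epoch and analyzed with an unwindowed FFT periodogram.

    Powers are in ms^2; TotalPower = VLF + LF + HF; pLF and pHF are
    percentages of (TotalPower - VLF) and sum to 100 when defined.
    """
    keys = ("VLF", "LF", "HF", "TotalPower", "LFHFratio", "pLF", "pHF")
    out = dict.fromkeys(keys, np.nan)
    peaks = rr.peak_times_s
    x = rr.rr_ms
    if x.size < 10 or (peaks[-1] - peaks[1]) < (end_s - start_s) / 2.0:
        return out
    t_grid = np.arange(start_s, end_s, 1.0 / TACHOGRAM_FS)
    tach = np.interp(t_grid, peaks[1:], x)
    tach = tach - tach.mean()
    freqs, psd = sps.periodogram(tach, fs=TACHOGRAM_FS, window="boxcar", detrend=False)
    vlf = _band_power(freqs, psd, *VLF_BAND)
    lf = _band_power(freqs, psd, *LF_BAND)
    hf = _band_power(freqs, psd, *HF_BAND)
    out["VLF"], out["LF"], out["HF"] = vlf, lf, hf
    out["TotalPower"] = vlf + lf + hf
    out["LFHFratio"] = lf / hf if hf > 0 else np.nan
    denom = out["TotalPower"] - vlf
    if denom > 0:
        out["pLF"] = 100.0 * lf / denom
        out["pHF"] = 100.0 * hf / denom
    return out


# ---------------------------------------------------------------------------
# entropies
# ---------------------------------------------------------------------------

def _templates(x, m, tau=1):
    n = x.size - (m - 1) * tau
    if n <= 0:
        return np.empty((0, m))
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]

def _chebyshev_pairs(t):
    """Upper-triangle Chebyshev distances between template rows."""
    d = np.abs(t[:, None, :] - t[None, :, :]).max(-1)
    return d[np.triu_indices(t.shape[0], k=1)]


def sample_entropy(x, m: int = 2, r_abs: float | None = None) -> float:
    """SampEn = -log(A/B): A and B count template pairs of length m+1 and m
    (self-matches excluded) with Chebyshev distance strictly below the
    tolerance.  Undefined (NaN) when either count is zero."""
    x = np.asarray(x, dtype=float)
    if x.size < m + 2 or r_abs is None or r_abs <= 0:
        return np.nan
    # standard convention: n - m templates at both lengths
    tm = _templates(x, m)[: x.size - m]
    tm1 = _templates(x, m + 1)
    b = int(np.count_nonzero(_chebyshev_pairs(tm) < r_abs))
    a = int(np.count_nonzero(_chebyshev_pairs(tm1) < r_abs))
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def approximate_entropy(x, m: int = 2, r_abs: float | None = None) -> float:
    """ApEn = Phi(m) - Phi(m+1) with self-matches included, so the match
    fractions are always positive and the value is always defined."""
    x = np.asarray(x, dtype=float)
    if x.size < m + 2 or r_abs is None or r_abs <= 0:
        return np.nan

    def phi(mm):
        t = _templates(x, mm)
        d = np.abs(t[:, None, :] - t[None, :, :]).max(-1)
        c = np.count_nonzero(d < r_abs, axis=1) / t.shape[0]
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def distribution_entropy(x, m: int = 2, tau: int = 1, n_bins: int = 512) -> float:
    """Normalized Shannon entropy (base 2, divided by log2 of the bin
    count) of the histogram of pairwise Chebyshev distances between
    m-dimensional delay vectors; bins are equal-width over [0, max
    distance].  A constant series concentrates all distances in one bin and
    scores 0; distances uniform over the bins score 1."""
    x = np.asarray(x, dtype=float)
    if x.size < m + 1:
        return np.nan
    t = _templates(x, m, tau)
    if t.shape[0] < 2:
        return np.nan
    d = _chebyshev_pairs(t)
    dmax = d.max()
    if dmax == 0:
        return 0.0
    counts, _ = np.histogram(d, bins=n_bins, range=(0.0, dmax))
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum() / np.log2(n_bins))


def coarse_grain(x, scale: int):
    """Non-overlapping block means of ``scale`` consecutive points."""
    x = np.asarray(x, dtype=float)
    if scale < 1:
        raise ValueError("scale must be >= 1")
    n = x.size // scale
    if n == 0:
        return np.empty(0)
    return x[: n * scale].reshape(n, scale).mean(axis=1)


def multiscale(x, kind: str, params: EntropyParams) -> dict:
    """Multiscale SampEn or DistEn over the configured scales.

    The SampEn tolerance is 0.2 x SD of the original (scale-1) series and
    stays fixed across scales.  Scales whose coarse-grained series is
    shorter than ``params.min_points`` are missing.
    """
    if kind not in ("SampEn", "DistEn"):
        raise ValueError(f"unknown entropy kind {kind!r}")
    x = np.asarray(x, dtype=float)
    r_abs = params.r * np.std(x, ddof=1) if x.size > 1 else np.nan
    out = {}
    for s in params.scales:
        cg = coarse_grain(x, s) if x.size >= s else np.empty(0)
        if cg.size < params.min_points:
            out[s] = np.nan
        elif kind == "SampEn":
            out[s] = sample_entropy(cg, params.m, r_abs)
        else:
            out[s] = distribution_entropy(cg, params.m, params.tau, params.n_bins)
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def extract_features(
    rr: RRSeries,
    epoch_length_s: float,
    start_s: float | None = None,
    end_s: float | None = None,
    params: EntropyParams | None = None,
) -> dict:
    """Assemble the full named feature vector for one epoch.

    Returns 20 named values for 60 s epochs and 26 for 180 s epochs;
    sub-threshold inputs produce NaN fields, never exceptions.
    """
    scales = (1, 2, 3, 4) if epoch_length_s >= 180 else (1,)
    if params is None:
        params = EntropyParams(scales=scales)
    names = feature_names(epoch_length_s)
    out = dict.fromkeys(names, np.nan)
    x = rr.rr_ms
    if start_s is None and rr.peak_times_s.size:
        start_s = float(rr.peak_times_s[0])
    if end_s is None and rr.peak_times_s.size:
        end_s = start_s + epoch_length_s
    if x.size == 0:
        return out

    out.update(time_domain(rr))
    out.update(geometric(rr))
    out.update(poincare(rr))
    out["CD"] = correlation_dimension(rr)
    out.update(frequency_domain(rr, start_s, end_s))
    if x.size >= params.m + 2:
        r_abs = params.r * np.std(x, ddof=1)
        out["ApEn"] = approximate_entropy(x, params.m, r_abs)
    mse = multiscale(x, "SampEn", params)
    mde = multiscale(x, "DistEn", params)
    for s in params.scales:
        if f"MSE_{s}" in out:
            out[f"MSE_{s}"] = mse[s]
        if f"MDE_{s}" in out:
            out[f"MDE_{s}"] = mde[s]
    return out
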