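"""Epitope hot-spot detection on a protein sequence.

Two complementary views are provided:

* **Windowed hydrophilicity** (Hopp–Woods): the mean of a per-residue
  hydrophilicity value over a sliding window (default 6 aa); maxima of the
  profile mark likely antigenic, surface-exposed stretches.
* **Resonant Recognition Method (RRM)**: each residue is replaced by its
  electron–ion interaction pseudo-potential (EIIP, in Rydberg), and the
  periodogram of the resulting numeric series is computed.  Dominant spectral
  peaks ("hot spots") are proposed interaction-relevant regions; the peak
  position estimate on the sequence is 2 · frequency · length.

The periodogram ordinate at frequency k/N is (a_k² + b_k²)·N/2 with a_k, b_k
the cosine/sine Fourier coefficients — equivalently (2/N)·|X_k|² with X_k the
DFT.  The two residue scales carry close-to-independent information
(Pearson r ≈ 0.16 across the 20 amino acids).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .genetic_code import AMINO_ACIDS, AlphabetError

__all__ = [
    "ResidueScale",
    "PropertyProfile",
    "Periodogram",
    "HotSpot",
    "PeakSet",
    "SCALES",
    "load_scale",
    "sliding_profile",
    "eiip_series",
    "periodogram",
    "top_peaks",
    "peak_position",
    "scale_correlation",
    "sequence_correlation",
]

#: Canonical residue order used whenever two scales are compared.
_RESIDUE_ORDER = tuple(sorted(AMINO_ACIDS))


@dataclass(frozen=True)
class ResidueScale:
    """A named per-residue property scale over the 20 standard amino acids."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != AMINO_ACIDS:
            raise ValueError(f"scale {self.name!r} must cover exactly the 20 amino acids")

    def __getitem__(self, aa: str) -> float:
        try:
            return self.values[aa]
        except KeyError:
            raise AlphabetError(
                f"residue {aa!r} has no value on scale {self.name!r}"
            ) from None

    def series(self, seq: str) -> np.ndarray:
        """Element-wise lookup of the scale over a sequence."""
        return np.array([self[aa] for aa in seq], dtype=float)


# Hopp–Woods hydrophilicity (kcal/mol-derived solvent parameter values) and
# EIIP (electron–ion interaction pseudo-potential, Rydberg units).
HOPP_WOODS = ResidueScale("hopp_woods", {
    "R": 3.0, "K": 3.0, "D": 3.0, "E": 3.0, "S": 0.3, "N": 0.2, "Q": 0.2,
    "P": 0.0, "G": 0.0, "T": -0.4, "H": -0.5, "A": -0.5, "C": -1.0,
    "M": -1.3, "V": -1.5, "L": -1.8, "I": -1.8, "Y": -2.3, "F": -2.5,
    "W": -3.4,
})

EIIP = ResidueScale("eiip", {
    "R": 0.0959, "K": 0.0371, "D": 0.1263, "E": 0.0058, "S": 0.0829,
    "N": 0.0036, "Q": 0.0761, "P": 0.0198, "G": 0.0050, "T": 0.0941,
    "H": 0.0242, "A": 0.0373, "C": 0.0829, "M": 0.0823, "V": 0.0057,
    "L": 0.0000, "I": 0.0000, "Y": 0.0516, "F": 0.0946, "W": 0.0548,
})

SCALES: dict[str, ResidueScale] = {s.name: s for s in (HOPP_WOODS, EIIP)}


def load_scale(name: str) -> ResidueScale:
    """Return a packaged residue scale by name (``hopp_woods`` or ``eiip``)."""
    try:
        return SCALES[name]
    except KeyError:
        avail = ", ".join(sorted(SCALES))
        raise KeyError(f"unknown scale {name!r}; available: {avail}") from None


def _check_sequence(seq: str) -> None:
    bad = [(i + 1, aa) for i, aa in enumerate(seq) if aa not in AMINO_ACIDS]
    if bad:
        pos, aa = bad[0]
        raise AlphabetError(f"non-standard residue {aa!r} at position {pos}")


@dataclass(frozen=True)
class PropertyProfile:
    """Sliding-window mean of a residue scale along a sequence.

    ``positions`` are 1-based window-center indices (offset ceil(window/2)
    from the window start); no end padding, so the profile has
    len(sequence) − window + 1 values.
    """

    sequence: str
    scale: str
    window: int
    positions: np.ndarray
    values: np.ndarray


def sliding_profile(seq: str, scale: ResidueScale, window: int = 6) -> PropertyProfile:
    """Mean scale value over each contiguous window of ``seq``."""
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if len(seq) < window:
        raise ValueError(
            f"sequence length {len(seq)} shorter than window {window}"
        )
    _check_sequence(seq)
    series = scale.series(seq)
    kernel = np.full(window, 1.0 / window)
    values = np.convolve(series, kernel, mode="valid")
    center = (window + 1) // 2  # 1-based center of the first window
    positions = np.arange(len(values)) + center
    return PropertyProfile(seq, scale.name, window, positions, values)


def eiip_series(seq: str) -> np.ndarray:
    """Numeric EIIP series of a sequence (RRM encoding)."""
    _check_sequence(seq)
    return EIIP.series(seq)


@dataclass(frozen=True)
class Periodogram:
    """Single-series periodogram at the Fourier frequencies k/N, k=1..⌊N/2⌋."""

    frequencies: np.ndarray  # cycles per observation
    power: np.ndarray        # (a_k² + b_k²)·N/2, non-negative
    n: int                   # series length


def periodogram(series: Sequence[float], mean_center: bool = True) -> Periodogram:
    """Periodogram of a numeric series.

    Ordinate_k = (a_k² + b_k²)·N/2 where a_k = (2/N)Σx·cos(2πkt/N) and
    b_k = (2/N)Σx·sin(2πkt/N); computed via the FFT as (2/N)·|X_k|².
    Mean-centering (default on) removes the k=0 leakage-free offset only;
    the k=0 term itself is never reported.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"series too short for a periodogram: N={n} < 4")
    if mean_center:
        x = x - x.mean()
    spec = np.fft.rfft(x)[1 : n // 2 + 1]
    power = (2.0 / n) * np.abs(spec) ** 2
    freqs = np.arange(1, n // 2 + 1) / n
    return Periodogram(frequencies=freqs, power=power, n=n)


@dataclass(frozen=True)
class HotSpot:
    """One ranked periodogram peak; ``position_estimate`` = 2·frequency·n."""

    rank: int
    frequency: float
    power: float
    position_estimate: float


@dataclass(frozen=True)
class PeakSet:
    """Ranked hot spots plus bookkeeping on how many were requested/found."""

    hotspots: tuple[HotSpot, ...]
    requested: int
    found: int

    @property
    def exhausted(self) -> bool:
        """True when fewer local maxima existed than were requested."""
        return self.found < self.requested

    def __iter__(self):
        return iter(self.hotspots)

    def __len__(self) -> int:
        return len(self.hotspots)


def top_peaks(p: Periodogram, k: int = 5) -> PeakSet:
    """Top-``k`` strict local maxima of the periodogram, by decreasing power.

    A peak is an interior ordinate strictly greater than both neighbours;
    ties in power are broken toward the lower frequency.  If fewer than
    ``k`` maxima exist, all are returned and the result's ``exhausted``
    flag is set.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    pw = p.power
    idx = [i for i in range(1, len(pw) - 1) if pw[i] > pw[i - 1] and pw[i] > pw[i + 1]]
    idx.sort(key=lambda i: (-pw[i], p.frequencies[i]))
    chosen = idx[:k]
    spots = tuple(
        HotSpot(
            rank=r + 1,
            frequency=float(p.frequencies[i]),
            power=float(pw[i]),
            position_estimate=peak_position(float(p.frequencies[i]), p.n),
        )
        for r, i in enumerate(chosen)
    )
    return PeakSet(hotspots=spots, requested=k, found=len(idx))


def peak_position(frequency: float, n: int) -> float:
    """Sequence-position estimate of a spectral peak: 2 · frequency · n."""
    if not 0.0 < frequency <= 0.5:
        raise ValueError(f"frequency must be in (0, 0.5], got {frequency}")
    return 2.0 * frequency * n


def scale_correlation(a: ResidueScale, b: ResidueScale) -> tuple[float, float]:
    """Pearson r (and two-sided p, t distribution with 18 df) between two
    residue scales over the 20 amino acids."""
    xa = np.array([a[aa] for aa in _RESIDUE_ORDER])
    xb = np.array([b[aa] for aa in _RESIDUE_ORDER])
    return _pearson(xa, xb)


def sequence_correlation(
    seq: str, a: ResidueScale, b: ResidueScale
) -> tuple[float, float]:
    """Pearson r between the two per-residue value series of a sequence."""
    _check_sequence(seq)
    if len(seq) < 3:
        raise ValueError("sequence too short for a correlation")
    return _pearson(a.series(seq), b.series(seq))


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
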