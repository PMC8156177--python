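"""Per-band 167-dimensional texture / intensity feature extraction.

Each corrected, masked fluorescence image yields a fixed-order feature
vector of 167 values:

* 28 Haralick features — 14 gray-level co-occurrence statistics, each
  summarized as the mean and range over the four distance-1 offsets
  (0, 45, 90, 135 degrees);
* 59 local binary pattern features — the normalized histogram of uniform
  LBP codes (8 neighbours, radius 1; 58 uniform patterns + 1 pooled
  non-uniform bin);
* 67 Gabor features — mean and standard deviation of the response magnitude
  of a 4-frequency x 8-orientation DC-free filter bank over the mask
  (64 values) plus 3 bank-level aggregates;
* 6 basic intensity features — mean, SD, min, max, skewness, kurtosis of
  the in-mask intensities;
* 7 Hu invariant moments of the masked intensity image (signed-log scaled).

Fusing the 675 nm and 750 nm vectors of a sample by concatenation (675 block
first) gives the 334-dimensional dual-band representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal, stats
from skimage.feature import graycomatrix
from skimage.filters import gabor_kernel
from skimage.measure import moments_central, moments_hu, moments_normalized

__all__ = [
    "FeatureVector",
    "FeatureTable",
    "haralick_features",
    "lbp_features",
    "gabor_features",
    "intensity_features",
    "hu_moments",
    "extract_all",
    "fuse",
    "GROUP_SIZES",
]

GROUP_SIZES = {"haralick": 28, "lbp": 59, "gabor": 67, "intensity": 6, "hu": 7}
SINGLE_BAND_LENGTH = sum(GROUP_SIZES.values())  # 167
FUSED_LENGTH = 2 * SINGLE_BAND_LENGTH  # 334

GLCM_LEVELS = 32
_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

_HARALICK_NAMES = [
    "asm", "contrast", "correlation", "variance", "idm", "sum_average",
    "sum_variance", "sum_entropy", "entropy", "diff_variance", "diff_entropy",
    "imc1", "imc2", "mcc",
]


# ---------------------------------------------------------------------------
# Haralick / GLCM


def glcm_matrices(image: np.ndarray, mask: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Normalized symmetric GLCMs, shape (levels, levels, n_angles).

    In-mask intensities are linearly quantized over their range into
    ``levels`` gray levels; pixels outside the mask are assigned a sentinel
    level whose row/column are dropped before normalization, so only pairs
    with both pixels inside the mask contribute.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = image[mask]
    if vals.size < 2:
        raise ValueError("mask too small for co-occurrence statistics")
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        q = np.floor((image - lo) / (hi - lo) * levels).astype(np.int64)
        q = np.clip(q, 0, levels - 1)
    else:
        q = np.zeros(image.shape, dtype=np.int64)
    q[~mask] = levels  # sentinel
    glcm = graycomatrix(
        q.astype(np.uint8) if levels < 255 else q.astype(np.int64),
        distances=[1], angles=list(_GLCM_ANGLES),
        levels=levels + 1, symmetric=True, normed=False,
    )[: levels, : levels, 0, :].astype(float)
    sums = glcm.sum(axis=(0, 1))
    if np.any(sums == 0):
        raise ValueError("mask admits no co-occurring in-mask pixel pairs")
    return glcm / sums


def _haralick_stats(p: np.ndarray) -> np.ndarray:
    """The 14 Haralick statistics of one normalized symmetric GLCM."""
    L = p.shape[0]
    i = np.arange(L, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((i - mu_y) ** 2) @ py))
    ii, jj = np.meshgrid(i, i, indexing="ij")

    def xlogx(v):
        v = np.asarray(v, dtype=float)
        out = np.zeros_like(v)
        nz = v > 0
        out[nz] = v[nz] * np.log(v[nz])
        return out

    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float((((ii - mu_x) ** 2) * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())

    # diagonal-sum and diagonal-difference distributions
    ksum = np.arange(2 * L - 1, dtype=float)  # i+j in [0, 2L-2]
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    kdiff = np.arange(L, dtype=float)  # |i-j|
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    sum_average = float(ksum @ p_sum)
    sum_variance = float(((ksum - sum_average) ** 2) @ p_sum)
    sum_entropy = float(-xlogx(p_sum).sum())
    entropy = float(-xlogx(p).sum())
    diff_average = float(kdiff @ p_diff)
    diff_variance = float(((kdiff - diff_average) ** 2) @ p_diff)
    diff_entropy = float(-xlogx(p_diff).sum())

    # information measures of correlation
    hx = float(-xlogx(px).sum())
    hy = float(-xlogx(py).sum())
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxy = np.where(pxy > 0, np.log(pxy), 0.0)
    hxy1 = float(-(p * log_pxy).sum())
    hxy2 = float(-(pxy * log_pxy).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    # maximal correlation coefficient: sqrt of the 2nd-largest eigenvalue of Q
    nz = (px > 0) & (py > 0)
    if nz.sum() >= 2:
        ps = p[np.ix_(nz, nz)]
        q = (ps / px[nz, None]) @ (ps / py[None, nz]).T
        eig = np.sort(np.abs(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eig[-2].real)))
    else:
        mcc = 0.0

    return np.array([
        asm, contrast, correlation, variance, idm, sum_average, sum_variance,
        sum_entropy, entropy, diff_variance, diff_entropy, imc1, imc2, mcc,
    ])


def haralick_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """28 Haralick features: 14 GLCM statistics x {mean, range over 4 offsets}."""
    glcm = glcm_matrices(image, mask)
    per_angle = np.stack([_haralick_stats(glcm[:, :, a]) for a in range(glcm.shape[2])])
    means = per_angle.mean(axis=0)
    ranges = per_angle.max(axis=0) - per_angle.min(axis=0)
    return np.concatenate([means, ranges])


# ---------------------------------------------------------------------------
# Uniform LBP


@lru_cache(maxsize=1)
def _uniform_lbp_lut() -> np.ndarray:
    """Map each 8-bit pattern to a bin: uniform patterns (<= 2 circular
    transitions) get bins 0..57 ordered by integer value; others pool in 58."""
    lut = np.full(256, 58, dtype=np.int64)
    bin_idx = 0
    for code in range(256):
        bits = [(code >> b) & 1 for b in range(8)]
        transitions = sum(bits[b] != bits[(b + 1) % 8] for b in range(8))
        if transitions <= 2:
            lut[code] = bin_idx
            bin_idx += 1
    assert bin_idx == 58
    return lut


# neighbour order: E, NE, N, NW, W, SW, S, SE (bit 0 = east, counter-clockwise)
_LBP_OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def lbp_codes(image: np.ndarray) -> np.ndarray:
    """Uniform LBP bin index per interior pixel (border excluded), P=8, R=1.

    A neighbour contributes a 1-bit iff it is strictly brighter than the
    centre, so constant neighbourhoods map to the all-zeros pattern (bin 0).
    """
    image = np.asarray(image, dtype=float)
    centre = image[1:-1, 1:-1]
    code = np.zeros(centre.shape, dtype=np.int64)
    for bit, (dy, dx) in enumerate(_LBP_OFFSETS):
        nb = image[1 + dy: image.shape[0] - 1 + dy, 1 + dx: image.shape[1] - 1 + dx]
        code |= (nb > centre).astype(np.int64) << bit
    return _uniform_lbp_lut()[code]


def lbp_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """59-bin normalized uniform-LBP histogram over in-mask interior pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 9:
        raise ValueError("mask must cover at least 9 pixels")
    codes = lbp_codes(image)
    inner = mask[1:-1, 1:-1]
    hist = np.bincount(codes[inner], minlength=59).astype(float)
    total = hist.sum()
    if total == 0:
        raise ValueError("no in-mask interior pixels for LBP")
    return hist / total


# ---------------------------------------------------------------------------
# Gabor bank


@lru_cache(maxsize=4)
def _gabor_bank(n_freq: int = 4, n_theta: int = 8,
                f_lo: float = 0.05, f_hi: float = 0.4) -> tuple:
    """DC-free complex Gabor kernels at geometrically spaced frequencies."""
    freqs = f_lo * (f_hi / f_lo) ** (np.arange(n_freq) / (n_freq - 1))
    bank = []
    for f in freqs:
        for t in range(n_theta):
            k = gabor_kernel(frequency=float(f), theta=t * np.pi / n_theta)
            k = k - k.mean()  # remove DC so flat regions give zero response
            bank.append((float(f), t * np.pi / n_theta, k))
    return tuple(bank)


def _filter_magnitude(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """|image * kernel| with reflective border handling, same shape as input."""
    py, px = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(image, ((py, py), (px, px)), mode="reflect")
    resp = signal.fftconvolve(padded, kernel, mode="valid")
    return np.abs(resp)


def gabor_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """67 Gabor features: per-filter mask mean + SD (32 x 2) and 3 aggregates.

    The aggregates are the mean, the standard deviation and the total energy
    (sum over filters of the mask-mean squared magnitude) of the bank's
    in-mask response magnitudes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    image = np.asarray(image, dtype=float)
    means, sds = [], []
    sq_means = []
    for _, _, kernel in _gabor_bank():
        mag = _filter_magnitude(image, kernel)[mask]
        means.append(mag.mean())
        sds.append(mag.std())
        sq_means.append((mag**2).mean())
    means = np.asarray(means)
    sds = np.asarray(sds)
    all_mean = means.mean()
    # pooled SD over all filters' in-mask magnitudes
    all_sd = float(np.sqrt(np.mean(np.asarray(sq_means)) - all_mean**2)) if (
        np.mean(sq_means) >= all_mean**2) else 0.0
    energy = float(np.sum(sq_means))
    out = np.empty(67)
    out[0:32] = means
    out[32:64] = sds
    out[64:67] = (all_mean, all_sd, energy)
    return out


# ---------------------------------------------------------------------------
# Intensity statistics and Hu moments


def intensity_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean, population SD, min, max, skewness, excess kurtosis of in-mask
    intensities; for a degenerate (constant) distribution the skewness and
    kurtosis are defined as 0."""
    vals = np.asarray(image, dtype=float)[np.asarray(mask, dtype=bool)]
    if vals.size < 2:
        raise ValueError("mask must cover at least 2 pixels")
    sd = float(vals.std())  # population (ddof=0)
    if sd == 0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(vals, bias=True))
        kurt = float(stats.kurtosis(vals, fisher=True, bias=True))
    return np.array([vals.mean(), sd, vals.min(), vals.max(), skew, kurt])


def hu_moments(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """The 7 Hu invariant moments of the masked intensity image.

    A sign-preserving log-magnitude transform, -sign(h) * log10|h|, is
    applied for numeric conditioning (the raw invariants span many orders of
    magnitude); exact zeros map to 0.
    """
    masked = np.asarray(image, dtype=float) * np.asarray(mask, dtype=bool)
    if masked.sum() <= 0:
        raise ValueError("masked image has zero total intensity")
    hu = moments_hu(moments_normalized(moments_central(masked)))
    out = np.zeros(7)
    nz = hu != 0
    out[nz] = -np.sign(hu[nz]) * np.log10(np.abs(hu[nz]))
    return out


# ---------------------------------------------------------------------------
# Assembly and fusion


@dataclass
class FeatureVector:
    """An ordered, named feature vector for one band (167) or fused (334)."""

    values: np.ndarray
    names: list[str]
    band: str  # "675", "750" or "fused"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = FUSED_LENGTH if self.band == "fused" else SINGLE_BAND_LENGTH
        if self.values.size != expected:
            raise ValueError(
                f"band {self.band!r} expects {expected} features, got {self.values.size}"
            )
        if len(self.names) != self.values.size:
            raise ValueError("names and values length mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")


def _feature_names(band: str) -> list[str]:
    names = []
    for i in range(14):
        names.append(f"haralick_{_HARALICK_NAMES[i]}_mean")
    for i in range(14):
        names.append(f"haralick_{_HARALICK_NAMES[i]}_range")
    names += [f"lbp_{i:02d}" for i in range(59)]
    names += [f"gabor_f{i // 8}_t{i % 8}_mean" for i in range(32)]
    names += [f"gabor_f{i // 8}_t{i % 8}_sd" for i in range(32)]
    names += ["gabor_bank_mean", "gabor_bank_sd", "gabor_bank_energy"]
    names += ["intensity_mean", "intensity_sd", "intensity_min",
              "intensity_max", "intensity_skew", "intensity_kurtosis"]
    names += [f"hu_{i+1}" for i in range(7)]
    return [f"{n}_{band}" for n in names]


def extract_all(image: np.ndarray, mask: np.ndarray, band: str) -> FeatureVector:
    """Concatenate haralick | lbp | gabor | intensity | hu into 167 named values."""
    if band not in ("675", "750"):
        raise ValueError("band must be '675' or '750'")
    values = np.concatenate([
        haralick_features(image, mask),
        lbp_features(image, mask),
        gabor_features(image, mask),
        intensity_features(image, mask),
        hu_moments(image, mask),
    ])
    assert values.size == SINGLE_BAND_LENGTH
    return FeatureVector(values=values, names=_feature_names(band), band=band)


def fuse(v675: FeatureVector, v750: FeatureVector) -> FeatureVector:
    """Concatenate the two band vectors, 675 block first, into 334 values."""
    if {v675.band, v750.band} != {"675", "750"}:
        raise ValueError(f"need one '675' and one '750' vector, got "
                         f"{v675.band!r} and {v750.band!r}")
    if v675.band == "750":  # arguments swapped
        v675, v750 = v750, v675
    return FeatureVector(
        values=np.concatenate([v675.values, v750.values]),
        names=list(v675.names) + list(v750.names),
        band="fused",
    )


# ---------------------------------------------------------------------------
# Feature table and normalization


class FeatureTable:
    """Per-sample feature vectors with labels and train-fitted normalization.

    Wraps a pandas DataFrame indexed by sample id.  ``normalize`` fits
    per-feature mean / SD on the training rows only and transforms every row
    with those statistics, so the test rows never leak into the scaling.
    """

    def __init__(self, df: pd.DataFrame, labels: pd.Series,
                 norm_stats: tuple[pd.Series, pd.Series] | None = None):
        if not df.index.equals(labels.index):
            raise ValueError("features and labels must share an index")
        self.df = df
        self.labels = labels
        self.norm_stats = norm_stats

    @classmethod
    def from_vectors(cls, vectors: dict, labels: dict) -> "FeatureTable":
        ids = list(vectors)
        names = vectors[ids[0]].names
        data = {sid: vectors[sid].values for sid in ids}
        for sid in ids:
            if vectors[sid].names != names:
                raise ValueError("inconsistent feature names across samples")
        df = pd.DataFrame.from_dict(data, orient="index", columns=names)
        return cls(df, pd.Series({sid: labels[sid] for sid in ids}, name="label").loc[df.index])

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    def select_band(self, band: str) -> "FeatureTable":
        """Restrict to the columns of one band (suffix '_675' or '_750')."""
        cols = [c for c in self.df.columns if c.endswith(f"_{band}")]
        if not cols:
            raise ValueError(f"no columns for band {band!r}")
        return FeatureTable(self.df[cols].copy(), self.labels.copy())

    def select_features(self, names: list[str]) -> "FeatureTable":
        return FeatureTable(self.df[list(names)].copy(), self.labels.copy())

    def normalize(self, train_ids) -> "FeatureTable":
        """Standardize all rows using mean/SD fitted on ``train_ids`` only.

        A zero-variance training feature is centred and left at 0 (its SD is
        treated as 1) with a warning, guarding the division.
        """
        import warnings as _warnings

        train = self.df.loc[list(train_ids)]
        if len(train) < 2:
            raise ValueError("need at least 2 training rows")
        means = train.mean(axis=0)
        sds = train.std(axis=0, ddof=0)
        zero = sds == 0
        if zero.any():
            _warnings.warn(
                f"{int(zero.sum())} zero-variance training feature(s) standardized to 0",
                stacklevel=2,
            )
            sds = sds.mask(zero, 1.0)
        df = (self.df - means) / sds
        return FeatureTable(df, self.labels.copy(), norm_stats=(means, sds))

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, index_label="sample_id")

    @classmethod
    def read_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="sample_id")
        labels = df.pop("label")
        return cls(df, labels)

    def __len__(self) -> int:
        return len(self.df)
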