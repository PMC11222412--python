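"""High-throughput gray/texture/wavelet features over a masked region.

Each image channel (SWI, or a TTP/CBV/CBF perfusion map) restricted to the
peri-infarct ROI yields 513 named features: 57 base features computed on the
original image and on each of the 8 sub-bands of a single-level 3-D discrete
wavelet transform (57 x 9 = 513). The 57 base features are

* 18 first-order intensity statistics,
* 24 gray-level co-occurrence (GLCM, Haralick-style) statistics on a
  32-level min-max quantization, averaged over the 13 unique 3-D unit
  offsets,
* 15 gray-level run-length (GLRLM) statistics over the same 13 directions.

Conventions: population (biased) variance everywhere; entropies in bits;
histogram features (entropy, uniformity) on the quantized levels; degenerate
regions (a single gray level) fall back to the documented constants
(entropy 0, uniformity 1, correlation 0, contrast 0, ...), never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "RadiomicsConfig",
    "FeatureVector",
    "FeatureMatrix",
    "first_order_features",
    "glcm_features",
    "glrlm_features",
    "wavelet_channels",
    "extract_channel_features",
    "extract_case_features",
    "normalize_features",
]

#: The 13 unique positive 3-D unit offsets (distance-1 neighborhood, no
#: antipodal duplicates; symmetrized matrices make the other 13 redundant).
OFFSETS_13 = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

FIRST_ORDER_NAMES = (
    "energy", "entropy", "minimum", "maximum", "mean", "median",
    "percentile10", "percentile90", "interquartile_range", "range",
    "mean_absolute_deviation", "robust_mean_absolute_deviation",
    "root_mean_squared", "standard_deviation", "variance",
    "skewness", "kurtosis", "uniformity",
)

GLCM_NAMES = (
    "contrast", "correlation", "joint_energy", "joint_entropy",
    "inverse_difference_moment", "dissimilarity", "autocorrelation",
    "cluster_shade", "cluster_prominence", "cluster_tendency",
    "maximum_probability", "sum_average", "sum_entropy",
    "difference_entropy", "difference_variance", "joint_average",
    "imc1", "imc2", "inverse_difference", "idn", "idmn",
    "inverse_variance", "mcc", "sum_of_squares",
)

GLRLM_NAMES = (
    "short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "run_length_nonuniformity",
    "run_length_nonuniformity_normalized", "run_percentage",
    "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis",
    "gray_level_variance", "run_length_variance",
)

#: Wavelet sub-band order: approximation first, then detail bands by axis.
BAND_ORDER = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


@dataclass(frozen=True)
class RadiomicsConfig:
    """Feature-extraction settings: quantization bins, wavelet basis,
    whether wavelet sub-bands are included."""

    n_levels: int = 32
    wavelet: str = "db4"  # orthonormal 8-tap basis
    use_wavelet: bool = True


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: tuple
    channel: str

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.names),):
            raise ValueError("values and names lengths differ")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature vector contains undefined values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------

def quantize(values: np.ndarray, n_levels: int = 32) -> np.ndarray:
    """Min-max quantization of intensities into levels 1..n_levels.

    A constant input maps entirely to level 1 (hence shift-invariant texture).
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones(values.shape, dtype=np.int64)
    q = np.floor((values - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
    return np.clip(q, 1, n_levels)


def _crop_to_mask(image: np.ndarray, mask: np.ndarray):
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return image[sl], mask[sl]


# ---------------------------------------------------------------------------
# First order
# ---------------------------------------------------------------------------

def first_order_features(image: np.ndarray, mask: np.ndarray, n_levels: int = 32) -> np.ndarray:
    """18 intensity statistics of the in-mask voxels (see FIRST_ORDER_NAMES)."""
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(image, dtype=float)[mask]
    if x.size < 2:
        raise ValueError("first-order features need >= 2 voxels in the mask")
    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev**2)
    sd = np.sqrt(m2)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    sub = x[(x >= p10) & (x <= p90)]
    rmad = np.abs(sub - sub.mean()).mean() if sub.size else 0.0
    skew = float(np.mean(dev**3) / m2**1.5) if m2 > 0 else 0.0
    kurt = float(np.mean(dev**4) / m2**2 - 3.0) if m2 > 0 else 0.0
    q = quantize(x, n_levels)
    p = np.bincount(q, minlength=n_levels + 1)[1:] / x.size
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((p**2).sum())
    return np.array([
        float((x**2).sum()), entropy, x.min(), x.max(), mean, p50,
        p10, p90, p75 - p25, x.max() - x.min(),
        float(np.abs(dev).mean()), float(rmad),
        float(np.sqrt(np.mean(x**2))), float(sd), float(m2),
        skew, kurt, uniformity,
    ])


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _offset_slices(shape, offset):
    src, dst = [], []
    for size, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(0, size - o))
            dst.append(slice(o, size))
        else:
            src.append(slice(-o, size))
            dst.append(slice(0, size + o))
    return tuple(src), tuple(dst)


def _glcm_matrix(q: np.ndarray, mask: np.ndarray, offset, n_levels: int):
    """Symmetric co-occurrence counts for one offset; None if no pairs."""
    src, dst = _offset_slices(q.shape, offset)
    pair = mask[src] & mask[dst]
    if not pair.any():
        return None
    a = q[src][pair] - 1
    b = q[dst][pair] - 1
    counts = np.bincount(a * n_levels + b, minlength=n_levels * n_levels)
    mat = counts.reshape(n_levels, n_levels).astype(float)
    return mat + mat.T


def _glcm_statistics(p: np.ndarray) -> np.ndarray:
    """24 Haralick-style statistics of a normalized symmetric GLCM."""
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())          # == mu_x == mu_y (symmetric)
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)
    diff = ii - jj
    absdiff = np.abs(diff)

    contrast = float((diff**2 * p).sum())
    dissimilarity = float((absdiff * p).sum())
    joint_energy = float((p**2).sum())
    nzp = p[p > 0]
    joint_entropy = float(-(nzp * np.log2(nzp)).sum())
    idm = float((p / (1.0 + diff**2)).sum())
    autocorr = float((ii * jj * p).sum())
    correlation = float((autocorr - mu * mu) / sigma2) if sigma2 > 0 else 0.0
    csum = ii + jj - 2 * mu
    cluster_tendency = float((csum**2 * p).sum())
    cluster_shade = float((csum**3 * p).sum())
    cluster_prominence = float((csum**4 * p).sum())
    max_prob = float(p.max())

    # sum / difference distributions
    ks = np.arange(2, 2 * n + 1, dtype=float)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in ks])
    kd = np.arange(0, n, dtype=float)
    p_diff = np.array([p[absdiff == k].sum() for k in kd])
    sum_average = float((ks * p_sum).sum())
    nzs = p_sum[p_sum > 0]
    sum_entropy = float(-(nzs * np.log2(nzs)).sum())
    nzd = p_diff[p_diff > 0]
    diff_entropy = float(-(nzd * np.log2(nzd)).sum())
    diff_avg = float((kd * p_diff).sum())
    diff_variance = float(((kd - diff_avg) ** 2 * p_diff).sum())

    # informational measures of correlation
    nzx = px[px > 0]
    hx = float(-(nzx * np.log2(nzx)).sum())
    pxy = np.outer(px, px)
    m = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[m] * np.log2(pxy[m])).sum())
    mm = pxy > 0
    hxy2 = float(-(pxy[mm] * np.log2(pxy[mm])).sum())
    imc1 = float((joint_entropy - hxy1) / hx) if hx > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy))
    imc2 = float(np.sqrt(max(arg, 0.0)))

    inv_diff = float((p / (1.0 + absdiff)).sum())
    idn = float((p / (1.0 + absdiff / n)).sum())
    idmn = float((p / (1.0 + diff**2 / n**2)).sum())
    off = absdiff > 0
    inverse_variance = float((p[off] / diff[off] ** 2).sum())

    # maximal correlation coefficient
    if sigma2 > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            q_mat = (p / px[:, None]) @ (p / px[None, :]).T
        q_mat = np.nan_to_num(q_mat)
        eig = np.sort(np.abs(np.linalg.eigvals(q_mat)))
        mcc = float(np.sqrt(max(eig[-2], 0.0))) if eig.size >= 2 else 1.0
    else:
        mcc = 1.0
    sum_of_squares = float(((ii - mu) ** 2 * p).sum())

    return np.array([
        contrast, correlation, joint_energy, joint_entropy, idm,
        dissimilarity, autocorr, cluster_shade, cluster_prominence,
        cluster_tendency, max_prob, sum_average, sum_entropy, diff_entropy,
        diff_variance, mu, imc1, imc2, inv_diff, idn, idmn,
        inverse_variance, mcc, sum_of_squares,
    ])


def glcm_features(image: np.ndarray, mask: np.ndarray, n_levels: int = 32,
                  offsets=OFFSETS_13) -> np.ndarray:
    """24 co-occurrence statistics (GLCM_NAMES) from the offset-averaged,
    symmetrized, normalized co-occurrence matrix of the quantized region."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("texture features need >= 2 voxels in the mask")
    image, mask = _crop_to_mask(np.asarray(image, dtype=float), mask)
    q = np.zeros(mask.shape, dtype=np.int64)
    q[mask] = quantize(image[mask], n_levels)
    active = int(q.max())
    mats = []
    for off in offsets:
        mat = _glcm_matrix(q, mask, off, active)
        if mat is not None and mat.sum() > 0:
            mats.append(mat / mat.sum())
    if not mats:  # isolated voxels only: treat as a single self-pair
        p = np.zeros((active, active))
        p[0, 0] = 1.0
    else:
        p = np.mean(mats, axis=0)
    return _glcm_statistics(p)


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _runs_in_direction(q: np.ndarray, mask: np.ndarray, d):
    """(levels, lengths) of all maximal same-level runs along direction d."""
    d = np.asarray(d)
    shape = np.asarray(q.shape)
    idx = np.argwhere(mask)
    prev = idx - d
    inb = np.all((prev >= 0) & (prev < shape), axis=1)
    prev_same = np.zeros(len(idx), dtype=bool)
    if inb.any():
        pi = tuple(prev[inb].T)
        ci = tuple(idx[inb].T)
        prev_same[inb] = mask[pi] & (q[pi] == q[ci])
    starts = idx[~prev_same]
    lengths = np.ones(len(starts), dtype=np.int64)
    cur = starts.copy()
    alive = np.arange(len(starts))
    while alive.size:
        nxt = cur[alive] + d
        inb2 = np.all((nxt >= 0) & (nxt < shape), axis=1)
        ok = np.zeros(alive.size, dtype=bool)
        if inb2.any():
            ni = tuple(nxt[inb2].T)
            ci = tuple(cur[alive][inb2].T)
            ok[inb2] = mask[ni] & (q[ni] == q[ci])
        grow = alive[ok]
        lengths[grow] += 1
        cur[grow] += d
        alive = grow
    return q[tuple(starts.T)], lengths


def glrlm_features(image: np.ndarray, mask: np.ndarray, n_levels: int = 32,
                   directions=OFFSETS_13) -> np.ndarray:
    """15 run-length statistics (GLRLM_NAMES) from the direction-averaged
    run-length matrix of the quantized region."""
    mask = np.asarray(mask, dtype=bool)
    n_vox = int(mask.sum())
    if n_vox < 2:
        raise ValueError("texture features need >= 2 voxels in the mask")
    image, mask = _crop_to_mask(np.asarray(image, dtype=float), mask)
    q = np.zeros(mask.shape, dtype=np.int64)
    q[mask] = quantize(image[mask], n_levels)
    active = int(q.max())

    runs = [_runs_in_direction(q, mask, d) for d in directions]
    max_len = max(int(lengths.max()) for _, lengths in runs)
    r = np.zeros((active, max_len))
    for levels, lengths in runs:
        np.add.at(r, (levels - 1, lengths - 1), 1.0)
    r /= len(directions)

    nr = r.sum()
    i = np.arange(1, active + 1, dtype=float)[:, None]
    j = np.arange(1, max_len + 1, dtype=float)[None, :]
    rg = r.sum(axis=1)  # per gray level
    rl = r.sum(axis=0)  # per run length
    p = r / nr
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    return np.array([
        float((r / j**2).sum() / nr),             # SRE
        float((r * j**2).sum() / nr),             # LRE
        float((rg**2).sum() / nr),                # GLN
        float((rg**2).sum() / nr**2),             # GLNN
        float((rl**2).sum() / nr),                # RLN
        float((rl**2).sum() / nr**2),             # RLNN
        float(nr / n_vox),                        # RP
        float((r / i**2).sum() / nr),             # LGLRE
        float((r * i**2).sum() / nr),             # HGLRE
        float((r / (i**2 * j**2)).sum() / nr),    # SRLGLE
        float((r * i**2 / j**2).sum() / nr),      # SRHGLE
        float((r * j**2 / i**2).sum() / nr),      # LRLGLE
        float((r * i**2 * j**2).sum() / nr),      # LRHGLE
        float((p * (i - mu_i) ** 2).sum()),       # GLV
        float((p * (j - mu_j) ** 2).sum()),       # RLV
    ])


# ---------------------------------------------------------------------------
# Wavelet
# ---------------------------------------------------------------------------

def wavelet_channels(image: np.ndarray, wavelet: str = "db4") -> dict:
    """Single-level 3-D separable DWT; returns the 8 sub-bands keyed
    LLL..HHH (L = approximation, H = detail, per axis).

    Periodized orthonormal transform: on even-length axes the coefficients
    satisfy Parseval's identity and the inverse reproduces the input.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or any(s < 2 for s in image.shape):
        raise ValueError("image must be 3-D with every axis length >= 2")
    coeffs = pywt.dwtn(image, wavelet, mode="periodization")
    return {key.replace("a", "L").replace("d", "H").upper(): band
            for key, band in coeffs.items()}


def _subband_mask(mask: np.ndarray, band_shape) -> np.ndarray:
    """ROI on the half-resolution wavelet grid: 2x nearest-neighbor
    downsampling (floor), grown if needed so >= 2 voxels survive."""
    from scipy import ndimage

    down = mask[::2, ::2, ::2]
    down = down[tuple(slice(0, s) for s in band_shape)]
    if down.shape != tuple(band_shape):
        padded = np.zeros(band_shape, dtype=bool)
        padded[tuple(slice(0, s) for s in down.shape)] = down
        down = padded
    if down.sum() < 2:
        if not down.any():
            seed = np.argwhere(mask)[0] // 2
            seed = np.minimum(seed, np.asarray(band_shape) - 1)
            down = np.zeros(band_shape, dtype=bool)
            down[tuple(seed)] = True
        while down.sum() < 2:
            down = ndimage.binary_dilation(down)
    return down


# ---------------------------------------------------------------------------
# Channel / case assembly
# ---------------------------------------------------------------------------

def _base_features(image, mask, n_levels):
    return np.concatenate([
        first_order_features(image, mask, n_levels),
        glcm_features(image, mask, n_levels),
        glrlm_features(image, mask, n_levels),
    ])


_BASE_NAMES = tuple(
    [f"firstorder.{n}" for n in FIRST_ORDER_NAMES]
    + [f"glcm.{n}" for n in GLCM_NAMES]
    + [f"glrlm.{n}" for n in GLRLM_NAMES]
)


def extract_channel_features(image: np.ndarray, mask: np.ndarray,
                             config: RadiomicsConfig = RadiomicsConfig(),
                             channel: str = "IMG") -> FeatureVector:
    """513 named features of one channel: 57 base features on the original
    image and on each wavelet sub-band.

    Non-finite voxels (e.g. unfitted perfusion voxels) are removed from the
    mask and imputed with the in-mask mean before the wavelet transform.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    finite = np.isfinite(image)
    use = mask & finite
    if use.sum() < 2:
        raise ValueError("mask must contain >= 2 finite voxels")
    fill = image[use].mean()
    clean = np.where(finite, image, fill)

    values = [_base_features(clean, use, config.n_levels)]
    names = [f"{channel}.original.{n}" for n in _BASE_NAMES]
    if config.use_wavelet:
        bands = wavelet_channels(clean, config.wavelet)
        for key in BAND_ORDER:
            band = bands[key]
            bmask = _subband_mask(use, band.shape)
            values.append(_base_features(band, bmask, config.n_levels))
            names.extend(f"{channel}.wavelet-{key}.{n}" for n in _BASE_NAMES)
    vec = np.concatenate(values)
    vec = np.nan_to_num(vec, nan=0.0, posinf=0.0, neginf=0.0)
    return FeatureVector(values=vec, names=tuple(names), channel=channel)


def extract_case_features(patient, rois: dict, modalities=("SWI", "CTP"),
                          maps=None, config: RadiomicsConfig = RadiomicsConfig(),
                          frame_interval_s: float = 1.5) -> FeatureVector:
    """Concatenated multimodal feature vector for one case.

    ``modalities`` may contain "SWI" (513 features from the SWI volume over
    ``rois['swi']``) and/or "CTP" (3 x 513 from the TTP, CBV and CBF maps
    over ``rois['ctp']``). ``maps`` may supply precomputed
    :class:`~srstroke.perfusion.PerfusionMaps`; otherwise they are fitted
    from ``patient.ctp``.
    """
    modalities = tuple(m.upper() for m in modalities)
    for m in modalities:
        if m not in ("SWI", "CTP"):
            raise ValueError(f"unknown modality {m!r}")
    parts = []
    if "SWI" in modalities:
        if "swi" not in rois:
            raise ValueError("missing ROI for modality SWI")
        parts.append(extract_channel_features(patient.swi, rois["swi"].mask,
                                              config, channel="SWI"))
    if "CTP" in modalities:
        if "ctp" not in rois:
            raise ValueError("missing ROI for modality CTP")
        if maps is None:
            from .perfusion import build_perfusion_maps

            maps = build_perfusion_maps(patient.ctp, rois["ctp"].mask,
                                        frame_interval_s=frame_interval_s)
        for channel, img in (("TTP", maps.ttp), ("CBV", maps.cbv), ("CBF", maps.cbf)):
            parts.append(extract_channel_features(img, rois["ctp"].mask,
                                                  config, channel=channel))
    if not parts:
        raise ValueError("no modality requested")
    values = np.concatenate([p.values for p in parts])
    names = tuple(n for p in parts for n in p.names)
    return FeatureVector(values=values, names=names, channel="+".join(modalities))


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """m samples x D named features with labels; normalization statistics,
    when present, always come from a training split."""

    matrix: np.ndarray
    labels: np.ndarray
    names: tuple
    normalization: dict | None = field(default=None)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.names = tuple(self.names)
        if self.matrix.ndim != 2 or self.matrix.shape != (len(self.labels), len(self.names)):
            raise ValueError("matrix must be (n_samples, n_features) matching labels/names")

    @classmethod
    def from_cases(cls, vectors, labels):
        names = vectors[0].names
        for v in vectors[1:]:
            if v.names != names:
                raise ValueError("inconsistent feature names across cases")
        return cls(matrix=np.stack([v.values for v in vectors]),
                   labels=np.asarray(labels, dtype=int), names=names)

    def subset(self, indices) -> "FeatureMatrix":
        indices = np.asarray(indices, dtype=int)
        return FeatureMatrix(matrix=self.matrix[:, indices], labels=self.labels,
                             names=tuple(self.names[i] for i in indices))

    def select_channels(self, channels) -> "FeatureMatrix":
        """Columns whose name starts with one of the channel prefixes."""
        prefixes = tuple(f"{c}." for c in channels)
        idx = [i for i, n in enumerate(self.names) if n.startswith(prefixes)]
        if not idx:
            raise ValueError(f"no features for channels {channels!r}")
        return self.subset(idx)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.matrix, columns=list(self.names))
        df.insert(0, "label", self.labels)
        return df

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        import pandas as pd

        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy(dtype=int)
        return cls(matrix=df.to_numpy(dtype=float), labels=labels,
                   names=tuple(df.columns))


def normalize_features(train: FeatureMatrix, test: FeatureMatrix):
    """Z-score both splits by the TRAINING mean/sd per column.

    Zero-variance training columns are set to 0 in both splits and recorded
    under ``normalization['constant_columns']``.
    """
    if train.names != test.names:
        raise ValueError("train and test feature names differ")
    mean = train.matrix.mean(axis=0)
    sd = train.matrix.std(axis=0)  # population convention
    constant = sd == 0
    safe_sd = np.where(constant, 1.0, sd)
    tr = (train.matrix - mean) / safe_sd
    te = (test.matrix - mean) / safe_sd
    tr[:, constant] = 0.0
    te[:, constant] = 0.0
    norm = {"mean": mean, "sd": sd,
            "constant_columns": [train.names[i] for i in np.flatnonzero(constant)]}
    return (
        FeatureMatrix(matrix=tr, labels=train.labels, names=train.names, normalization=norm),
        FeatureMatrix(matrix=te, labels=test.labels, names=test.names, normalization=norm),
    )
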