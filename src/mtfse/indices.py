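"""Band segmentation of the TFSI and the eight 2-D Shannon-entropy indices.

The TFSI over 0-0.4 Hz is split along the frequency axis into the canonical
HRV bands — VLF [0, 0.04), LF [0.04, 0.15), HF [0.15, 0.4] — and each
sub-image, plus the total image, is summarized by the Shannon entropy of its
quantized pixel intensities:

    ShEn = - sum_k p_k log p_k

where p_k is the fraction of pixels falling in intensity bin k. Pixel values
are quantized into K equal-width bins spanning the *total* image's range, so
the sub-image entropies are mutually comparable and every index is invariant
under a global rescaling of the power. The feature vector is

    F = (ShEnVLF, ShEnLF, ShEnHF, ShEnTotal,
         ShEnpVLF, ShEnpLF, ShEnpHF, ShEnLF/HF)

with ShEnpX = ShEnX / ShEnTotal and ShEnLF/HF = ShEnLF / ShEnHF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spectrum import TFSI, F_MAX_HZ

__all__ = [
    "BAND_EDGES",
    "INDEX_NAMES",
    "Quantizer",
    "IndexVector",
    "split_bands",
    "shannon_entropy_image",
    "compute_indices",
]

#: half-open band membership [low, high); 0.4 Hz itself belongs to HF.
BAND_EDGES = {
    "VLF": (0.0, 0.04),
    "LF": (0.04, 0.15),
    "HF": (0.15, F_MAX_HZ),
}

INDEX_NAMES = (
    "ShEnVLF",
    "ShEnLF",
    "ShEnHF",
    "ShEnTotal",
    "ShEnpVLF",
    "ShEnpLF",
    "ShEnpHF",
    "ShEnLF/HF",
)


@dataclass(frozen=True)
class Quantizer:
    """Linear equal-width quantization of pixel intensities.

    ``n_levels`` bins span the range of the parent total image; entropies are
    reported in logarithms of ``log_base`` (base 10 by default, so the maximum
    possible entropy is log10(256) ~ 2.41).
    """

    n_levels: int = 256
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.log_base <= 1.0:
            raise ValueError("log_base must exceed 1")

    @property
    def max_entropy(self) -> float:
        return math.log(self.n_levels) / math.log(self.log_base)


@dataclass(frozen=True)
class IndexVector:
    """The eight MTFSE indices; ratio indices are None when their denominator
    entropy is zero (degenerate segment), never silently NaN."""

    shen_vlf: float
    shen_lf: float
    shen_hf: float
    shen_total: float
    shen_pvlf: float | None
    shen_plf: float | None
    shen_phf: float | None
    shen_lf_hf: float | None

    def as_dict(self) -> dict:
        return dict(zip(INDEX_NAMES, self.as_tuple()))

    def as_tuple(self) -> tuple:
        return (
            self.shen_vlf,
            self.shen_lf,
            self.shen_hf,
            self.shen_total,
            self.shen_pvlf,
            self.shen_plf,
            self.shen_phf,
            self.shen_lf_hf,
        )

    def as_array(self) -> np.ndarray:
        """Values in the fixed index order, missing ratios as NaN."""
        return np.array(
            [np.nan if v is None else v for v in self.as_tuple()], dtype=float
        )

    @property
    def is_complete(self) -> bool:
        return all(v is not None for v in self.as_tuple())


def _band_mask(freqs: np.ndarray, name: str) -> np.ndarray:
    low, high = BAND_EDGES[name]
    if name == "HF":  # closed upper edge: 0.4 Hz is an HF pixel
        return (freqs >= low) & (freqs <= high + 1e-12)
    return (freqs >= low) & (freqs < high)


def split_bands(tfsi: TFSI) -> dict[str, np.ndarray]:
    """Partition TFSI columns into the VLF/LF/HF sub-images.

    Every frequency column belongs to exactly one band; all time rows are
    retained in each sub-image.
    """
    f = tfsi.freq_axis
    if f[0] > 1e-9 or abs(f[-1] - F_MAX_HZ) > 1e-9:
        raise ValueError(
            f"TFSI frequency axis must span [0, {F_MAX_HZ}] Hz, got "
            f"[{f[0]}, {f[-1]}]"
        )
    subs = {name: tfsi.power[:, _band_mask(f, name)] for name in BAND_EDGES}
    total = sum(s.shape[1] for s in subs.values())
    if total != tfsi.n_freq:
        raise ValueError("band masks do not partition the frequency axis")
    return subs


def shannon_entropy_image(
    image: np.ndarray,
    quantizer: Quantizer,
    global_range: tuple[float, float],
) -> float:
    """2-D Shannon entropy of an image quantized over a shared intensity range.

    Pixels are binned into ``quantizer.n_levels`` equal-width bins spanning
    ``global_range`` (values at the maximum fall in the top bin); the entropy
    of the bin-occupancy distribution is returned in ``log_base`` units. A
    constant image has entropy 0.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("cannot compute entropy of an empty image")
    gmin, gmax = global_range
    if gmax < gmin:
        raise ValueError("global_range must satisfy max >= min")
    k = quantizer.n_levels
    if gmax == gmin:
        bins = np.zeros(img.size, dtype=np.intp)
    else:
        scaled = (img.ravel() - gmin) / (gmax - gmin)
        bins = np.clip(np.floor(scaled * k).astype(np.intp), 0, k - 1)
    counts = np.bincount(bins, minlength=k)
    p = counts[counts > 0] / img.size
    # + 0.0 normalizes the -0.0 produced by a single occupied bin
    return float(-(p * np.log(p)).sum() / math.log(quantizer.log_base) + 0.0)


def compute_indices(tfsi: TFSI, quantizer: Quantizer | None = None) -> IndexVector:
    """Compute the eight-index MTFSE feature vector of a TFSI.

    The quantization range is taken once from the total image and reused for
    all sub-images. Ratio indices with a zero denominator are reported as
    missing (None) so degenerate segments stay visible downstream.
    """
    if quantizer is None:
        quantizer = Quantizer()
    subs = split_bands(tfsi)
    grange = (float(tfsi.power.min()), float(tfsi.power.max()))
    shen_total = shannon_entropy_image(tfsi.power, quantizer, grange)
    shen = {
        name: shannon_entropy_image(sub, quantizer, grange)
        for name, sub in subs.items()
    }

    def ratio(num: float, den: float) -> float | None:
        return None if den == 0.0 else num / den

    return IndexVector(
        shen_vlf=shen["VLF"],
        shen_lf=shen["LF"],
        shen_hf=shen["HF"],
        shen_total=shen_total,
        shen_pvlf=ratio(shen["VLF"], shen_total),
        shen_plf=ratio(shen["LF"], shen_total),
        shen_phf=ratio(shen["HF"], shen_total),
        shen_lf_hf=ratio(shen["LF"], shen["HF"]),
    )
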