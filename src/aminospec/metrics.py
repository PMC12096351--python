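"""The four pairwise spectral prediction-accuracy measures.

All four operate on a :class:`~aminospec.spectra.PaddedPair` — two intensity
vectors zero-padded onto a common m/z grid starting at 0:

* **RMSE** — root-mean-square intensity difference over all N padded
  positions (including the zero region), on the base-peak-100 relative
  intensity scale.  Lower is better; 0 means identical.
* **SCA** — spectral contrast angle, the angle in degrees between the two
  spectra viewed as vectors in peak-intensity space.  0° means
  indistinguishable, 90° means no shared signal.  Because only the angle
  matters, SCA weighs each peak equally and ignores overall intensity scale.
* **WCS** — weighted cosine similarity: cosine of the angle after each
  element is transformed to (m/z)^alpha * intensity^beta (defaults
  alpha = 1, beta = 0.5), emphasising heavier fragments.  In [0, 1].
* **SEN** — spectral entropy similarity: a Jensen–Shannon-type similarity
  of the two spectra treated as probability distributions over m/z,
  1 - (2 H(m) - H(p) - H(q)) / ln 4 with m the half-half mixture, in [0, 1].

:func:`evaluate_pair` is the convenience front door: integer binning,
base-peak-100 normalization, padding, then all four metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spectra import PaddedPair, Spectrum, bin_to_integer, normalize, pad_pair

__all__ = [
    "MetricParams",
    "SimilarityResult",
    "rmse_padded",
    "spectral_contrast_angle",
    "weighted_cosine",
    "entropy_similarity",
    "evaluate_pair",
]

_LN4 = math.log(4.0)


@dataclass(frozen=True)
class MetricParams:
    """Tunable knobs of the weighted-cosine and entropy metrics.

    wcs_mz_exponent / wcs_intensity_exponent are the powers applied to m/z
    and intensity before the cosine (the convention used to train
    neural-network EI-MS predictors); sen_apply_li_weighting enables the
    low-entropy intensity re-weighting of the original entropy-similarity
    method (off by default).  The entropy log base is fixed to e.
    """

    wcs_mz_exponent: float = 1.0
    wcs_intensity_exponent: float = 0.5
    sen_apply_li_weighting: bool = False

    def as_dict(self) -> dict:
        return {
            "wcs_mz_exponent": self.wcs_mz_exponent,
            "wcs_intensity_exponent": self.wcs_intensity_exponent,
            "sen_apply_li_weighting": self.sen_apply_li_weighting,
        }


@dataclass(frozen=True)
class SimilarityResult:
    """The four accuracy values for one observed/predicted pair."""

    compound_id: str
    rmse: float
    sca_deg: float
    wcs: float
    sen: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.rmse, self.sca_deg, self.wcs, self.sen)


def rmse_padded(pair: PaddedPair) -> float:
    """Root-mean-square intensity difference over all N padded positions."""
    if pair.n == 0:
        raise ValueError("empty padded pair")
    diff = pair.predicted - pair.observed
    return float(math.sqrt(float(np.mean(diff * diff))))


def spectral_contrast_angle(pair: PaddedPair) -> float:
    """Angle between the two intensity vectors, in degrees, clamped to [0, 90]."""
    a, b = pair.observed, pair.predicted
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-norm spectrum in contrast-angle computation")
    # 2*arcsin(|u - v|/2) on unit vectors: equivalent to arccos of the
    # normalized dot product but exact at 0 and accurate for small angles
    half_chord = 0.5 * float(np.linalg.norm(a / na - b / nb))
    theta = 2.0 * math.asin(min(1.0, half_chord))
    return float(np.clip(math.degrees(theta), 0.0, 90.0))


def weighted_cosine(pair: PaddedPair, params: MetricParams | None = None) -> float:
    """Cosine similarity of m/z- and intensity-weighted vectors, in [0, 1]."""
    params = params or MetricParams()
    mz = np.arange(pair.n, dtype=float)
    with np.errstate(divide="ignore"):
        wa = mz ** params.wcs_mz_exponent * pair.observed ** params.wcs_intensity_exponent
        wb = mz ** params.wcs_mz_exponent * pair.predicted ** params.wcs_intensity_exponent
    na = float(np.linalg.norm(wa))
    nb = float(np.linalg.norm(wb))
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-norm weighted spectrum")
    return float(np.clip(float(np.dot(wa, wb)) / (na * nb), 0.0, 1.0))


def _shannon_entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def _li_reweight(p: np.ndarray) -> np.ndarray:
    # Low-entropy spectra are intensity-reweighted (I^(0.25 + 0.25 S), then
    # renormalized) before the similarity, following the entropy-similarity
    # method's original calibration; applied only below entropy 3.
    s = _shannon_entropy(p)
    if s >= 3.0:
        return p
    w = 0.25 + 0.25 * s
    q = p ** w
    return q / q.sum()


def entropy_similarity(pair: PaddedPair, params: MetricParams | None = None) -> float:
    """Jensen–Shannon-type entropy similarity of the two spectra, in [0, 1]."""
    params = params or MetricParams()
    sa = pair.observed.sum()
    sb = pair.predicted.sum()
    if sa <= 0 or sb <= 0:
        raise ValueError("zero-sum spectrum in entropy similarity")
    p = pair.observed / sa
    q = pair.predicted / sb
    if params.sen_apply_li_weighting:
        p = _li_reweight(p)
        q = _li_reweight(q)
    m = 0.5 * (p + q)
    value = 1.0 - (2.0 * _shannon_entropy(m) - _shannon_entropy(p) - _shannon_entropy(q)) / _LN4
    return float(np.clip(value, 0.0, 1.0))


def evaluate_pair(
    observed: Spectrum,
    predicted: Spectrum,
    params: MetricParams | None = None,
) -> SimilarityResult:
    """Score one observed/predicted pair with all four metrics.

    Both spectra are integer-binned and base-peak-100 normalized, then
    zero-padded onto a common grid.  SEN renormalizes to probability
    distributions internally.
    """
    params = params or MetricParams()
    if observed.compound_id and predicted.compound_id:
        if observed.compound_id != predicted.compound_id:
            raise ValueError(
                f"compound_id mismatch: {observed.compound_id!r} vs {predicted.compound_id!r}"
            )
    obs = normalize(bin_to_integer(observed), "base_peak_100")
    pred = normalize(bin_to_integer(predicted), "base_peak_100")
    pair = pad_pair(obs, pred)
    return SimilarityResult(
        compound_id=observed.compound_id or predicted.compound_id,
        rmse=rmse_padded(pair),
        sca_deg=spectral_contrast_angle(pair),
        wcs=weighted_cosine(pair, params),
        sen=entropy_similarity(pair, params),
    )
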