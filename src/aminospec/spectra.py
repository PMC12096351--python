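"""Canonical stick-spectrum representation and plain-text MSP I/O.

Everything downstream (metrics, curation, pipeline) consumes the
:class:`Spectrum` defined here: an ordered map from m/z to intensity plus
compound-level metadata.  Spectra read from accurate-mass instruments may
carry fractional m/z; :func:`bin_to_integer` collapses them onto the integer
Thomson grid that electron-ionization library spectra use.  Two integer-m/z
spectra are aligned on a common grid with :func:`pad_pair`, which zero-pads
both from m/z = 0 up to the larger maximum m/z — the representation all four
similarity metrics are defined on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "PaddedPair",
    "MspParseError",
    "read_msp",
    "write_msp",
    "bin_to_integer",
    "normalize",
    "pad_pair",
    "strip_zeros",
]


class MspParseError(ValueError):
    """Raised when an MSP record violates the dialect contract."""


# Header keys that map onto typed Spectrum fields.  Anything else is kept
# verbatim in the passthrough ``extra`` map.
_TYPED_KEYS = {
    "name": "compound_id",
    "smiles": "smiles",
    "instrument": "instrument",
    "source_library": "source_library",
    "derivatized": "derivatized",
}


@dataclass
class Spectrum:
    """A centroided stick spectrum with provenance metadata.

    Parameters
    ----------
    peaks
        Mapping from m/z (non-negative, integer after binning) to
        intensity (finite, >= 0).  At least one intensity must be positive.
    compound_id
        Identifier used to pair observed and predicted spectra.
    """

    peaks: dict[float, float]
    compound_id: str = ""
    smiles: str | None = None
    source_library: str = ""
    instrument: str | None = None
    derivatized: bool | None = None
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[float, float] = {}
        for mz, inten in sorted(self.peaks.items()):
            mz = float(mz)
            inten = float(inten)
            if mz < 0:
                raise ValueError(f"negative m/z {mz} in spectrum {self.compound_id!r}")
            if not math.isfinite(mz) or not math.isfinite(inten):
                raise ValueError(f"non-finite peak ({mz}, {inten}) in {self.compound_id!r}")
            if inten < 0:
                raise ValueError(f"negative intensity {inten} in {self.compound_id!r}")
            cleaned[int(mz) if mz.is_integer() else mz] = inten
        if not cleaned or not any(v > 0 for v in cleaned.values()):
            raise ValueError(f"spectrum {self.compound_id!r} has no positive-intensity peak")
        self.peaks = cleaned

    # -- convenience views -------------------------------------------------
    @property
    def mz(self) -> np.ndarray:
        return np.array(list(self.peaks.keys()), dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array(list(self.peaks.values()), dtype=float)

    @property
    def max_mz(self) -> float:
        return max(self.peaks)

    @property
    def base_peak_mz(self) -> float:
        return max(self.peaks, key=lambda k: (self.peaks[k], -k))

    def has_integer_mz(self) -> bool:
        return all(float(mz).is_integer() for mz in self.peaks)

    def copy(self, **changes) -> "Spectrum":
        kwargs = dict(
            peaks=dict(self.peaks),
            compound_id=self.compound_id,
            smiles=self.smiles,
            source_library=self.source_library,
            instrument=self.instrument,
            derivatized=self.derivatized,
            extra=dict(self.extra),
        )
        kwargs.update(changes)
        return Spectrum(**kwargs)


@dataclass
class PaddedPair:
    """Two intensity vectors aligned on the grid m/z = 0 .. N-1.

    ``observed[i]`` / ``predicted[i]`` hold the intensity at m/z = i, zero
    where the spectrum has no peak; N is one more than the larger maximum
    m/z of the two spectra.
    """

    observed: np.ndarray
    predicted: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.observed.shape != (self.n,) or self.predicted.shape != (self.n,):
            raise ValueError("padded vectors must both have length n")


def bin_to_integer(spectrum: Spectrum) -> Spectrum:
    """Round fractional m/z half-up to integers, summing colliding peaks.

    Total intensity is conserved exactly (collisions merge by addition).
    """
    binned: dict[float, float] = {}
    for mz, inten in spectrum.peaks.items():
        if mz < 0:
            raise ValueError(f"negative m/z {mz}")
        key = int(math.floor(mz + 0.5))  # half-up, not banker's rounding
        binned[key] = binned.get(key, 0.0) + inten
    return spectrum.copy(peaks=binned)


def normalize(spectrum: Spectrum, mode: str = "base_peak_100") -> Spectrum:
    """Rescale intensities: base peak to 100, or total intensity to 1."""
    total = sum(spectrum.peaks.values())
    peak = max(spectrum.peaks.values())
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    if mode == "base_peak_100":
        scale = 100.0 / peak
    elif mode == "sum_to_one":
        scale = 1.0 / total
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return spectrum.copy(peaks={mz: inten * scale for mz, inten in spectrum.peaks.items()})


def pad_pair(observed: Spectrum, predicted: Spectrum) -> PaddedPair:
    """Zero-pad both spectra from m/z = 0 to the larger maximum m/z."""
    for s in (observed, predicted):
        if not s.has_integer_mz():
            raise ValueError(
                f"spectrum {s.compound_id!r} has fractional m/z; bin_to_integer first"
            )
    n = int(max(observed.max_mz, predicted.max_mz)) + 1
    obs = np.zeros(n)
    pred = np.zeros(n)
    for mz, inten in observed.peaks.items():
        obs[int(mz)] = inten
    for mz, inten in predicted.peaks.items():
        pred[int(mz)] = inten
    return PaddedPair(observed=obs, predicted=pred, n=n)


def strip_zeros(vector: np.ndarray) -> dict[int, float]:
    """Inverse of padding: recover the sparse peak map of one vector."""
    return {int(i): float(v) for i, v in enumerate(np.asarray(vector, dtype=float)) if v != 0}


# ---------------------------------------------------------------------------
# MSP dialect (NIST text): records separated by blank lines, "Key: value"
# headers, then "Num Peaks: k" followed by exactly k whitespace- or
# semicolon-separated "m/z intensity" pairs, possibly several per line.
# ---------------------------------------------------------------------------

def read_msp(path: str | Path) -> list[Spectrum]:
    """Parse an MSP file into a list of spectra.

    Raises :class:`MspParseError` (naming the record and line) on a declared
    peak-count mismatch, a negative intensity, or an unparseable line.
    Duplicate m/z within one record are merged by intensity sum with a
    logged warning.  An empty file yields an empty list.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    lines = path.read_text().splitlines()

    record_lines: list[tuple[int, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        if raw.strip():
            record_lines.append((lineno, raw))
        elif record_lines:
            spectra.append(_parse_record(record_lines, path))
            record_lines = []
    if record_lines:
        spectra.append(_parse_record(record_lines, path))
    return spectra


def _parse_record(record_lines: list[tuple[int, str]], path: Path) -> Spectrum:
    fields: dict[str, object] = {"extra": {}}
    name = "<unnamed>"
    declared: int | None = None
    peaks: dict[float, float] = {}
    n_pairs = 0
    start_line = record_lines[0][0]

    it = iter(record_lines)
    for lineno, raw in it:
        if declared is None:
            if ":" not in raw:
                raise MspParseError(
                    f"{path}:{lineno}: expected 'Key: value' header in record "
                    f"starting at line {start_line}, got {raw!r}"
                )
            key, _, value = raw.partition(":")
            key = key.strip()
            value = value.strip()
            lowered = key.lower().replace(" ", "_")
            if lowered == "num_peaks":
                try:
                    declared = int(value)
                except ValueError as exc:
                    raise MspParseError(f"{path}:{lineno}: bad Num Peaks value {value!r}") from exc
                continue
            if lowered == "name":
                name = value
            if lowered in _TYPED_KEYS:
                target = _TYPED_KEYS[lowered]
                if target == "derivatized":
                    fields[target] = value.strip().lower() in {"true", "1", "yes"}
                else:
                    fields[target] = value
            else:
                fields["extra"][key] = value  # type: ignore[index]
        else:
            tokens = raw.replace(";", " ").split()
            if len(tokens) % 2 != 0:
                raise MspParseError(
                    f"{path}:{lineno}: odd number of values in peak line of record {name!r}"
                )
            for mz_tok, int_tok in zip(tokens[::2], tokens[1::2]):
                try:
                    mz = float(mz_tok)
                    inten = float(int_tok)
                except ValueError as exc:
                    raise MspParseError(
                        f"{path}:{lineno}: unparseable peak pair "
                        f"({mz_tok!r}, {int_tok!r}) in record {name!r}"
                    ) from exc
                if inten < 0:
                    raise MspParseError(
                        f"{path}:{lineno}: negative intensity {inten} in record {name!r}"
                    )
                if mz in peaks:
                    logger.warning(
                        "%s:%d: duplicate m/z %s in record %r merged by intensity sum",
                        path, lineno, mz, name,
                    )
                    peaks[mz] += inten
                else:
                    peaks[mz] = inten
                n_pairs += 1

    if declared is None:
        raise MspParseError(
            f"{path}:{start_line}: record {name!r} has no 'Num Peaks' line"
        )
    if n_pairs != declared:
        raise MspParseError(
            f"{path}:{start_line}: record {name!r} declares {declared} peaks "
            f"but lists {n_pairs}"
        )
    try:
        return Spectrum(peaks=peaks, **fields)  # type: ignore[arg-type]
    except ValueError as exc:
        raise MspParseError(f"{path}:{start_line}: record {name!r}: {exc}") from exc


def write_msp(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra in the MSP dialect; read_msp(write_msp(x)) == x."""
    path = Path(path)
    blocks: list[str] = []
    for s in spectra:
        lines = [f"Name: {s.compound_id}"]
        if s.smiles is not None:
            lines.append(f"SMILES: {s.smiles}")
        if s.instrument is not None:
            lines.append(f"Instrument: {s.instrument}")
        if s.source_library:
            lines.append(f"Source_Library: {s.source_library}")
        if s.derivatized is not None:
            lines.append(f"Derivatized: {str(bool(s.derivatized)).lower()}")
        for key, value in s.extra.items():
            lines.append(f"{key}: {value}")
        lines.append(f"Num Peaks: {len(s.peaks)}")
        for mz, inten in s.peaks.items():
            mz_repr = int(mz) if float(mz).is_integer() else repr(mz)
            lines.append(f"{mz_repr} {inten!r}")
        blocks.append("\n".join(lines))
    path.write_text("\n\n".join(blocks) + ("\n" if blocks else ""))
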