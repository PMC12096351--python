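"""Synthetic paired-spectra generator.

Real inputs for this kind of evaluation — a curated reference library of
experimental GC-EI-MS amino-acid spectra and the matching machine-predicted
spectra — are proprietary or produced by external predictors.  This module
emulates both sides so every pipeline stage is testable with no external
data:

* molecules are drawn from a pool of real Type Ia amino-acid SMILES
  (proteinogenic plus norleucine, norvaline, homoserine, 2-aminobutyric
  acid) extended by programmatic homologation of 2-aminoalkanoic acids to
  widen the molecular-weight range (~75-500 Da with derivatization); a
  configured fraction receive bis-TBDMS derivatization (amine + acid),
  mirroring MTBSTFA treatment;
* each molecule gets an "observed" stick spectrum — integer m/z drawn
  without replacement up to the molecular ion (always present at
  round(MW)), long-tailed (log-normal) intensities, base peak scaled
  to 100;
* the "predicted" spectrum is the observed spectrum passed through a
  tunable :class:`DistortionModel` (peak dropout, +/-1 Da mass shifts,
  multiplicative intensity jitter, spurious peaks), whose single ``level``
  scalar scales all four components linearly from zero.  Level 0 reproduces
  the observed spectrum exactly; the base peak is never dropped.

Everything is reproducible: a root seed plus a per-molecule counter drives
an independent substream per molecule, so (config, seed) determines every
output byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .curation import MoleculeRecord, annotate_properties
from .spectra import Spectrum, write_msp

__all__ = [
    "DistortionModel",
    "SyntheticLibraryConfig",
    "SpectrumPair",
    "AMINO_ACID_POOL",
    "derivatize_bis_tbdms",
    "generate_molecules",
    "generate_observed_spectrum",
    "distort",
    "generate_paired_library",
    "welch_rejection_rate",
]

# Real Type Ia monosubstituted alpha-amino acids (free forms).
AMINO_ACID_POOL: tuple[tuple[str, str], ...] = (
    ("glycine", "NCC(=O)O"),
    ("alanine", "CC(N)C(=O)O"),
    ("valine", "CC(C)C(N)C(=O)O"),
    ("leucine", "CC(C)CC(N)C(=O)O"),
    ("isoleucine", "CCC(C)C(N)C(=O)O"),
    ("serine", "OCC(N)C(=O)O"),
    ("threonine", "CC(O)C(N)C(=O)O"),
    ("cysteine", "SCC(N)C(=O)O"),
    ("methionine", "CSCCC(N)C(=O)O"),
    ("aspartic_acid", "OC(=O)CC(N)C(=O)O"),
    ("glutamic_acid", "OC(=O)CCC(N)C(=O)O"),
    ("asparagine", "NC(=O)CC(N)C(=O)O"),
    ("glutamine", "NC(=O)CCC(N)C(=O)O"),
    ("lysine", "NCCCCC(N)C(=O)O"),
    ("phenylalanine", "NC(Cc1ccccc1)C(=O)O"),
    ("tyrosine", "NC(Cc1ccc(O)cc1)C(=O)O"),
    ("tryptophan", "NC(Cc1c[nH]c2ccccc12)C(=O)O"),
    ("histidine", "NC(Cc1c[nH]cn1)C(=O)O"),
    ("norvaline", "CCCC(N)C(=O)O"),
    ("norleucine", "CCCCC(N)C(=O)O"),
    ("homoserine", "OCCC(N)C(=O)O"),
    ("2-aminobutyric_acid", "CCC(N)C(=O)O"),
)

_TBDMS_ACID = AllChem.ReactionFromSmarts(
    "[CX3:1](=[OX1:2])[OX2H1:3]>>[C:1](=[O:2])[O:3][Si](C)(C)C(C)(C)C"
)
# Target the alpha-amine specifically (the nitrogen on the carbon bearing
# the carbonyl) so polyfunctional side chains are left alone.
_TBDMS_AMINE = AllChem.ReactionFromSmarts(
    "[NX3;H2:1][CX4:2][CX3:3]=[OX1:4]>>[N:1]([Si](C)(C)C(C)(C)C)[C:2][C:3]=[O:4]"
)


def derivatize_bis_tbdms(smiles: str) -> str:
    """Attach one TBDMS to the carboxylic acid and one to the alpha-amine."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    for rxn, what in ((_TBDMS_ACID, "carboxylic acid"), (_TBDMS_AMINE, "alpha-amine")):
        products = rxn.RunReactants((mol,))
        if not products:
            raise ValueError(f"no {what} to derivatize in {smiles!r}")
        mol = products[0][0]
        Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class DistortionModel:
    """Tunable disagreement between observed and predicted spectra.

    Each component magnitude is ``level * <component parameter>``, so the
    single ``level`` scalar in [0, 1] moves all four distortions linearly
    from zero (level 0 => predicted == observed exactly).
    """

    intensity_jitter_sd: float = 0.4     # log-normal sigma, multiplicative
    dropout_prob: float = 0.35           # per-peak deletion probability
    spurious_rate: float = 6.0           # expected count of added noise peaks
    mass_shift_prob: float = 0.15        # per-peak +/-1 Da shift probability
    level: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ValueError("level must lie in [0, 1]")

    def with_level(self, level: float) -> "DistortionModel":
        return DistortionModel(
            intensity_jitter_sd=self.intensity_jitter_sd,
            dropout_prob=self.dropout_prob,
            spurious_rate=self.spurious_rate,
            mass_shift_prob=self.mass_shift_prob,
            level=level,
        )

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SyntheticLibraryConfig:
    """Size, composition and reproducibility knobs of a synthetic library."""

    n_molecules: int = 100
    fraction_derivatized: float = 0.5
    mz_range: tuple[int, int] = (50, 1200)
    peaks_min: int = 5
    peaks_max: int = 60
    homolog_fraction: float = 0.3   # fraction drawn as chain-extended homologs
    seed: int = 0
    source_library: str = "synthetic"

    def as_dict(self) -> dict:
        d = asdict(self)
        d["mz_range"] = list(self.mz_range)
        return d


@dataclass
class SpectrumPair:
    """One molecule with its observed and predicted spectra."""

    molecule: MoleculeRecord
    observed: Spectrum
    predicted: Spectrum


def generate_molecules(config: SyntheticLibraryConfig) -> list[MoleculeRecord]:
    """Draw annotated molecule records from the amino-acid pool.

    A ``homolog_fraction`` of records are linear 2-aminoalkanoic acids with
    randomly drawn chain length (widening the MW range); an exact
    round(n * fraction_derivatized) subset, chosen at random, is bis-TBDMS
    derivatized.
    """
    if config.n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if not AMINO_ACID_POOL:
        raise ValueError("empty amino-acid pool")
    rng = np.random.default_rng(config.seed)
    n = config.n_molecules
    n_deriv = int(round(n * config.fraction_derivatized))
    deriv_idx = set(rng.permutation(n)[:n_deriv].tolist())

    records: list[MoleculeRecord] = []
    for i in range(n):
        if rng.random() < config.homolog_fraction:
            chain = int(rng.integers(1, 13))  # norvaline-like up to C14 homolog
            name = f"2-aminoalkanoate_C{chain + 2}"
            smiles = "C" * chain + "C(N)C(=O)O"
        else:
            name, smiles = AMINO_ACID_POOL[int(rng.integers(len(AMINO_ACID_POOL)))]
        derivatized = i in deriv_idx
        if derivatized:
            smiles = derivatize_bis_tbdms(smiles)
        record = MoleculeRecord(
            compound_id=f"SYN{i:05d}_{name}" + ("_tbdms" if derivatized else ""),
            smiles=smiles,
            source_library=config.source_library,
        )
        records.append(annotate_properties(record))
    return records


def generate_observed_spectrum(
    molecule: MoleculeRecord,
    config: SyntheticLibraryConfig,
    rng: np.random.Generator,
) -> Spectrum:
    """A stick spectrum for one molecule: integer m/z up to the molecular
    ion (always included at round(MW)), long-tailed intensities, base
    peak = 100."""
    mw = int(math.floor(molecule.molecular_weight + 0.5))
    lo = config.mz_range[0]
    if mw < lo:
        raise ValueError(
            f"molecular weight {molecule.molecular_weight:.1f} below m/z range minimum {lo}"
        )
    candidates = np.arange(lo, mw + 2)  # molecular ion + possible M+1
    n_peaks = int(rng.integers(config.peaks_min, config.peaks_max + 1))
    n_peaks = min(n_peaks, candidates.size)
    chosen = rng.choice(candidates, size=n_peaks, replace=False)
    if mw not in chosen:
        chosen[0] = mw  # molecular-ion peak is always present
    chosen = np.unique(chosen)
    intensities = rng.lognormal(mean=2.0, sigma=1.5, size=chosen.size)
    intensities *= 100.0 / intensities.max()
    return Spectrum(
        peaks={int(m): float(v) for m, v in zip(chosen, intensities)},
        compound_id=molecule.compound_id,
        smiles=molecule.smiles,
        source_library=molecule.source_library,
        instrument="GC-EI-TOF",
        derivatized=molecule.derivatized,
    )


def distort(
    observed: Spectrum,
    model: DistortionModel,
    rng: np.random.Generator,
) -> Spectrum:
    """Apply dropout, mass shift, intensity jitter and spurious peaks.

    Applied in that order, each scaled by ``model.level``; the base peak is
    never dropped, and the output is renormalized to base peak 100.
    Level 0 returns an identical copy.
    """
    if model.level == 0.0:
        return observed.copy()
    lvl = model.level
    p_drop = lvl * model.dropout_prob
    p_shift = lvl * model.mass_shift_prob
    jitter_sd = lvl * model.intensity_jitter_sd
    spurious_mean = lvl * model.spurious_rate

    mz = observed.mz.astype(int)
    inten = observed.intensities
    base_idx = int(np.argmax(inten))

    # per-peak dropout; the base peak is protected so a spectrum survives
    keep = rng.random(mz.size) >= p_drop
    keep[base_idx] = True
    mz, inten = mz[keep], inten[keep]

    # +/- 1 Da shifts; collisions merge by intensity sum
    shift_mask = rng.random(mz.size) < p_shift
    shifts = rng.choice([-1, 1], size=mz.size)
    mz = np.where(shift_mask, np.maximum(mz + shifts, 0), mz)

    # multiplicative log-normal intensity jitter
    inten = inten * rng.lognormal(mean=0.0, sigma=jitter_sd, size=inten.size)

    peaks: dict[float, float] = {}
    for m, v in zip(mz.tolist(), inten.tolist()):
        peaks[m] = peaks.get(m, 0.0) + v

    # spurious peaks at uniform random m/z within the spectrum's range
    n_spurious = int(rng.poisson(spurious_mean))
    if n_spurious:
        lo = int(observed.mz.min())
        hi = int(observed.max_mz) + 1
        spur_mz = rng.integers(lo, hi + 1, size=n_spurious)
        spur_int = rng.lognormal(mean=1.5, sigma=1.0, size=n_spurious)
        for m, v in zip(spur_mz.tolist(), spur_int.tolist()):
            peaks[int(m)] = peaks.get(int(m), 0.0) + float(v)

    scale = 100.0 / max(peaks.values())
    peaks = {m: v * scale for m, v in peaks.items()}
    return observed.copy(peaks=peaks)


def generate_paired_library(
    config: SyntheticLibraryConfig,
    model: DistortionModel,
    out_dir: str | Path | None = None,
) -> tuple[list[SpectrumPair], list[MoleculeRecord]]:
    """One (observed, predicted = distort(observed)) pair per molecule.

    Each molecule draws from its own counter-based substream of the root
    seed, so the library is bit-reproducible.  When ``out_dir`` is given,
    writes observed.msp, predicted.msp, molecules.csv and a generation
    manifest (manifest.json).
    """
    molecules = generate_molecules(config)
    pairs: list[SpectrumPair] = []
    for i, record in enumerate(molecules):
        sub = np.random.default_rng([config.seed, i])
        obs = generate_observed_spectrum(record, config, sub)
        pred = distort(obs, model, sub)
        pairs.append(SpectrumPair(molecule=record, observed=obs, predicted=pred))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_msp([p.observed for p in pairs], out / "observed.msp")
        write_msp([p.predicted for p in pairs], out / "predicted.msp")
        molecules_to_csv(molecules, out / "molecules.csv")
        manifest = {
            "config": config.as_dict(),
            "distortion": model.as_dict(),
            "n_pairs": len(pairs),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return pairs, molecules


def molecules_to_csv(molecules: Sequence[MoleculeRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(m) for m in molecules]).to_csv(path, index=False)


def molecules_from_csv(path: str | Path) -> list[MoleculeRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.to_dict(orient="records"):
        row = {k: row[k] for k in (
            "compound_id", "smiles", "structure_key", "molecular_weight", "logp",
            "is_type1a_alpha_aa", "derivatized", "tbdms_count", "source_library",
        ) if k in row}
        records.append(MoleculeRecord(**row))
    return records


def welch_rejection_rate(
    n_replicates: int,
    n_per_group: int,
    level_a: float,
    level_b: float,
    seed: int,
    alpha: float = 0.05,
    model: DistortionModel | None = None,
    metric: str = "sca_deg",
    pool_size: int = 60,
) -> float:
    """Monte-Carlo rejection rate of the derivatized-vs-free Welch test.

    Simulates ``n_replicates`` experiments in which group A pairs are
    distorted at ``level_a`` and group B pairs at ``level_b``; each
    replicate runs a two-sided Welch t-test on the chosen metric and the
    fraction of p-values below ``alpha`` is returned.  Equal levels give
    the empirical type-I error rate; unequal levels give power.  A fixed
    pool of observed spectra is drawn once and resampled across replicates
    to keep the simulation affordable.
    """
    from .metrics import evaluate_pair  # local import to avoid cycle at module load

    base = model or DistortionModel()
    cfg = SyntheticLibraryConfig(n_molecules=pool_size, fraction_derivatized=0.5, seed=seed)
    molecules = generate_molecules(cfg)
    rng = np.random.default_rng([seed, 987_001])
    pool = [
        generate_observed_spectrum(m, cfg, np.random.default_rng([seed, 555_000 + i]))
        for i, m in enumerate(molecules)
    ]
    model_a = base.with_level(level_a)
    model_b = base.with_level(level_b)

    from .stats import welch_ttest

    rejections = 0
    for _ in range(n_replicates):
        vals_a = []
        vals_b = []
        for _ in range(n_per_group):
            obs = pool[int(rng.integers(len(pool)))]
            pred = distort(obs, model_a, rng)
            vals_a.append(getattr(evaluate_pair(obs, pred), metric))
        for _ in range(n_per_group):
            obs = pool[int(rng.integers(len(pool)))]
            pred = distort(obs, model_b, rng)
            vals_b.append(getattr(evaluate_pair(obs, pred), metric))
        _, p = welch_ttest(vals_a, vals_b)
        if p < alpha:
            rejections += 1
    return rejections / n_replicates
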