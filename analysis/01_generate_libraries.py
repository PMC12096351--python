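#!/usr/bin/env python
"""Generate the synthetic paired spectral libraries used by the analysis.

Writes one library (observed.msp, predicted.msp, molecules.csv,
manifest.json) per distortion level into results/libraries/level_<x>/.
Level 0 is the perfect-prediction control; higher levels emulate
increasingly inaccurate predictions.
"""

from pathlib import Path

from aminospec.synthetic import DistortionModel, SyntheticLibraryConfig, generate_paired_library

LEVELS = (0.0, 0.2, 0.4, 0.6, 0.8)
SEED = 1
N_MOLECULES = 200

out_root = Path(__file__).resolve().parents[1] / "results" / "libraries"

config = SyntheticLibraryConfig(n_molecules=N_MOLECULES, fraction_derivatized=0.5, seed=SEED)
for level in LEVELS:
    out = out_root / f"level_{level:.1f}"
    pairs, molecules = generate_paired_library(config, DistortionModel(level=level), out_dir=out)
    n_deriv = sum(m.derivatized for m in molecules)
    print(f"level {level:.1f}: {len(pairs)} pairs ({n_deriv} derivatized) -> {out}")

print(f"\nlibraries written under {out_root}")
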