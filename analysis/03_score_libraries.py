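#!/usr/bin/env python
"""Score every generated library with the four accuracy metrics.

Runs the full evaluation (curation, pairing, metrics, summaries,
correlations, group comparisons, threshold classification) on each
distortion level generated by 01_generate_libraries.py, and collects the
per-level mean accuracy into results/degradation_curve.csv.
"""

from pathlib import Path

import pandas as pd

from aminospec.pipeline import RunConfig, run_evaluation

root = Path(__file__).resolve().parents[1] / "results"
lib_root = root / "libraries"
if not lib_root.exists():
    raise SystemExit("run analysis/01_generate_libraries.py first")

rows = []
for lib_dir in sorted(lib_root.iterdir()):
    level = lib_dir.name.removeprefix("level_")
    report = run_evaluation(RunConfig(
        observed_path=str(lib_dir / "observed.msp"),
        predicted_path=str(lib_dir / "predicted.msp"),
        molecules_path=str(lib_dir / "molecules.csv"),
        library_name=lib_dir.name,
        instrument_pattern="GC-EI",
        out_dir=str(root / "reports" / lib_dir.name),
    ))
    s = report.summary
    rows.append({
        "level": float(level),
        "n_pairs": s.n_pairs,
        "mean_rmse": s.mean_rmse,
        "mean_sca_deg": s.mean_sca_deg,
        "mean_wcs": s.mean_wcs,
        "mean_sen": s.mean_sen,
        **{f"frac_{k}": v for k, v in report.classification_rates.items()},
    })
    print(f"{lib_dir.name}: n={s.n_pairs}  RMSE={s.mean_rmse:.2f}  "
          f"SCA={s.mean_sca_deg:.1f} deg  WCS={s.mean_wcs:.3f}  SEN={s.mean_sen:.3f}")

curve = pd.DataFrame(rows).sort_values("level")
curve.to_csv(root / "degradation_curve.csv", index=False)
monotone = (curve["mean_sca_deg"].is_monotonic_increasing
            and curve["mean_wcs"].is_monotonic_decreasing
            and curve["mean_sen"].is_monotonic_decreasing)
print(f"\ndegradation curve written; monotone in all bounded metrics: {monotone}")
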