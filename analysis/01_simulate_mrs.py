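"""Simulate one control/gammaATP-saturated acquisition pair plus the
inversion-recovery series for a control-group animal, and write them in the
package's TSV+sidecar interchange format.

Run from the repository root:  python analysis/01_simulate_mrs.py
The (large) spectra land in scratch/spectra/; downstream scripts simulate
their own inputs, so this step is a demonstration of the interchange format.
"""

import json
from pathlib import Path

import numpy as np

import satflux as sf
from satflux import io as sfio
from satflux.pipeline import DEFAULT_INVERSION_TIMES

OUT = Path("scratch/spectra")
OUT.mkdir(parents=True, exist_ok=True)

base = {p.label: p for p in sf.default_muscle_peaks()}
exchange = {
    "Pi": sf.ExchangeSpec.from_observed(m0=base["Pi"].amplitude, t1obs=1.59, kf=0.304),
    "PCr": sf.ExchangeSpec.from_observed(m0=base["PCr"].amplitude, t1obs=1.59, kf=0.15),
}
cfg = sf.SimulationConfig(exchange=exchange, noise_sd=0.1, seed=20260923)

control, saturated = sf.simulate_saturation_pair(cfg)
sfio.save_fid(control, OUT / "control_fid.tsv")
sfio.save_fid(saturated, OUT / "saturated_fid.tsv")

spec = sf.process_fid(control, 8000, 30.0)
sfio.save_spectrum(spec, OUT / "control_spectrum.tsv")

series = sf.simulate_inversion_recovery(cfg, DEFAULT_INVERSION_TIMES)
(OUT / "inversion_recovery.json").write_text(
    json.dumps({k: sfio.dataclass_to_jsonable(v) for k, v in series.items()}, indent=1)
)

print(f"wrote control/saturated FIDs ({cfg.n_points} pts, {cfg.sweep_width_hz:.0f} Hz sweep)")
print(f"ground truth: Pi dM/M0 = {exchange['Pi'].dm_over_m0:.4f}, "
      f"PCr dM/M0 = {exchange['PCr'].dm_over_m0:.4f}")
print(f"IR series over {DEFAULT_INVERSION_TIMES[0]:.3f}-{DEFAULT_INVERSION_TIMES[-1]:.3f} s "
      f"-> {OUT}/")
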