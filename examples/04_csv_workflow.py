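"""Round-trip workflow through the CSV lane schema.

Writes a simulated series to the on-disk format a densitometry export
would use (one row per lane: condition, conc_nM, replicate, band0, band1,
band2), reads it back, summarises replicates, and fits.  The same files
drive the command-line interface:

    emsafit simulate --scenario wt_sps --seed 1 -o out/
    emsafit fit out/wt_sps.csv -o out/fit
    emsafit bootstrap out/wt_sps.csv --n-boot 5000 --seed 1 -o out/boot
    emsafit report out/fit
"""

import tempfile
from pathlib import Path

from emsafit import (
    fit_model,
    preset_scenarios,
    read_titration_table,
    simulate_series,
    summarize_replicates,
    write_titration_table,
)

workdir = Path(tempfile.mkdtemp())
csv_path = workdir / "wt_sps.csv"

write_titration_table(simulate_series(preset_scenarios()["wt_sps"].with_seed(3)), csv_path)
print(f"wrote {csv_path}")
print(csv_path.read_text().splitlines()[0])  # the schema header

series = read_titration_table(csv_path)[0]
summary = summarize_replicates(series)
print(f"\nread back {len(series)} lanes, "
      f"{series.n_distinct_concentrations()} concentrations")
print("mean band fractions per concentration:")
print(summary.mean.round(3).to_string())

fit = fit_model(series)
print(f"\nfit: Kd = {fit.params.kd:.1f} nM, C = {fit.params.C:.2f}, "
      f"f = {fit.params.f:.3f}")
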