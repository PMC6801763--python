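"""Generate a synthetic titration dataset on disk and read it back.

Writes per-point peak-list CSVs, a YAML titration config and a ground-truth
JSON for the weak synthetic-peptide condition (0.78 mM protein, 7 increments
to 4:1, true K_D = 1.19 mM — a visibly non-saturating curve), then reloads
the series from the files and prints the weighted CSP of the strongest
binder at each titration point.
"""
import json
import tempfile
from pathlib import Path

from cspfit import build_profiles, load_titration, reference_fixtures
from cspfit.cli import _do_simulate

spec = reference_fixtures()["ww4_smad7_synthetic"]
out = Path(tempfile.mkdtemp(prefix="cspfit_demo_"))
cfg = _do_simulate(spec, out, seed=7)
print(f"wrote {len(list(out.glob('point_*.csv')))} peak lists + config to {out}")

series = load_titration(cfg)
truth = json.loads((out / "ground_truth.json").read_text())
amps = {int(k): v for k, v in truth["amplitudes_ppm"].items()}
rid = max(amps, key=amps.get)

profile = next(p for p in build_profiles(series) if p.residue_id == rid)
print(f"\nresidue {rid} (true saturation shift {amps[rid]:.3f} ppm):")
print("ratio  ligand_mM  weighted_CSP_ppm")
for point, dd in zip(series.points, profile.delta_delta):
    print(f"{point.ratio:5.1f}  {point.ligand_conc:9.3f}  {dd:12.4f}")
print("\nThe curve keeps rising at 4:1 ligand — binding is far from "
      "saturation because K_D (1.19 mM) exceeds the protein concentration.")
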