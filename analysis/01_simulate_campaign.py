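#!/usr/bin/env python
"""Simulate a desk-scale passive-sampling campaign.

Two locations with very different dust loads (a crushing station and a
concentrate terminal), each sampled over 24 h with both collection
surfaces (PC and CT), plus one field blank per surface carrying only
handling contamination.  Every stub gets rendered SEM-like tiles, a
ground-truth particle table, and fabricated impactor/OPC references.

Images and truth tables go to scratch/campaign/ (large, regenerable);
the campaign manifest and the reference concentrations go to results/.
"""

import sys
from pathlib import Path

import pandas as pd
import yaml

from uncsampler import default_config, synth

ROOT = Path(__file__).resolve().parents[1]
CAMPAIGN = ROOT / "scratch" / "campaign"
RESULTS = ROOT / "results"

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20170805 % (2**31)

#: location → true airborne concentration, mg m⁻³ (high-dust crushing
#: station vs. cleaner concentrate terminal)
LOCATIONS = {"crushing_station": 6.0, "concentrate_terminal": 0.8}
SURFACES = ("PC", "CT")
#: expected handling-contamination particles per blank stub
BLANK_CONTAMINATION = {"PC": 140.0, "CT": 20.0}


def main() -> int:
    cfg = default_config()
    CAMPAIGN.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    manifest = {"occasions": [], "stubs": []}
    reference_rows = []
    truth_rows = []
    stub_no = 0

    for location, conc in LOCATIONS.items():
        for surface in SURFACES:
            stub_no += 1
            occasion_id = f"{location}-{surface}"
            scen = synth.TruthScenario(
                true_concentration_mg_m3=conc, cmad_um=2.5, gsd=1.6,
                duration_h=24.0, deposition_area_mm2=1.0,
                seed=SEED + stub_no, stub_id=occasion_id,
            )
            particles = synth.sample_population(scen, cfg)
            stub = synth.render_tiles(particles, scen, cfg)
            synth.save_stub(stub, CAMPAIGN / occasion_id)
            manifest["occasions"].append(
                {"occasion_id": occasion_id, "location": location, "surface": surface,
                 "role": "sample", "duration_h": 24.0}
            )
            manifest["stubs"].append(
                {"occasion_id": occasion_id, "tiles": f"campaign/{occasion_id}"}
            )
            truth = synth.true_pm_concentrations(scen, cfg)
            truth_rows.append({"occasion_id": occasion_id, **{f"true_{k}": v for k, v in truth.items()},
                               "n_particles": len(particles)})
            print(f"{occasion_id}: {len(particles)} particles deposited")

        # one impactor + OPC reference per location (shared by PC and CT)
        scen_ref = synth.TruthScenario(
            true_concentration_mg_m3=conc, cmad_um=2.5, gsd=1.6,
            duration_h=24.0, deposition_area_mm2=1.0, seed=SEED,
        )
        gains, spectrum = synth.fabricate_references(scen_ref, cfg)
        truth = synth.true_pm_concentrations(scen_ref, cfg)
        for fraction in ("pm2.5", "pm10"):
            reference_rows.append(
                {"location": location, "fraction": fraction,
                 "filter_gain_mg": gains[fraction], "mg_per_m3": truth[fraction]}
            )

    # field blanks: contamination only, one per surface
    for surface in SURFACES:
        occasion_id = f"blank-{surface}"
        scen = synth.TruthScenario(
            true_concentration_mg_m3=0.0, cmad_um=2.5, gsd=1.6,
            duration_h=24.0, deposition_area_mm2=1.0,
            contamination_rate=BLANK_CONTAMINATION[surface],
            seed=SEED + 90 + (surface == "CT"), stub_id=occasion_id,
        )
        particles = synth.sample_population(scen, cfg)
        stub = synth.render_tiles(particles, scen, cfg)
        synth.save_stub(stub, CAMPAIGN / occasion_id)
        manifest["occasions"].append(
            {"occasion_id": occasion_id, "location": "all", "surface": surface,
             "role": "field_blank", "duration_h": 24.0}
        )
        manifest["stubs"].append({"occasion_id": occasion_id, "tiles": f"campaign/{occasion_id}"})
        print(f"{occasion_id}: {len(particles)} contamination particles")

    (CAMPAIGN.parent / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    pd.DataFrame(reference_rows).to_csv(RESULTS / "reference_concentrations.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(RESULTS / "campaign_truth.csv", index=False)
    print(f"manifest -> {CAMPAIGN.parent / 'manifest.yaml'}")
    print(f"references -> {RESULTS / 'reference_concentrations.csv'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
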