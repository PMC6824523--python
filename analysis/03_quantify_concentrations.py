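#!/usr/bin/env python
"""Invert deposited particles into PM concentrations and correct blanks.

Sizes every detected particle (projected-area → aerodynamic diameter →
mass), inverts the deposition flux to per-occasion PM2.5/PM10
concentrations, subtracts the per-surface field-blank means (negatives
retained), and reports duration-weighted means per surface alongside the
uncorrected sensitivity mode.  Tables land in results/.
"""

from pathlib import Path

import pandas as pd
import yaml

from uncsampler import default_config
from uncsampler import quantify as q
from uncsampler import segmentation as seg

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def load_particles(stub_dir: Path, occasion_id: str):
    table = pd.read_csv(stub_dir / "particles.csv")
    records = [
        seg.ParticleRecord(
            pixel_count=int(r.pixel_count), area_um2=float(r.area_um2),
            centroid_rc=(0.0, 0.0), tile_index=int(r.tile), stub_id=occasion_id,
        )
        for r in table.itertuples()
    ]
    area = float(table["analyzed_area_mm2"].iloc[0]) if len(table) else 0.0
    return records, area


def main() -> int:
    cfg = default_config()
    manifest = yaml.safe_load((SCRATCH / "manifest.yaml").read_text())
    occasions = [
        q.SamplingOccasion(
            occasion_id=o["occasion_id"], location=o["location"], surface=o["surface"],
            role=o.get("role", "sample"), duration_h=float(o["duration_h"]),
        )
        for o in manifest["occasions"]
    ]
    occ_by_id = {o.occasion_id: o for o in occasions}

    results = []
    for stub in manifest["stubs"]:
        occ = occ_by_id[stub["occasion_id"]]
        records, area = load_particles(SCRATCH / stub["tiles"], occ.occasion_id)
        sized = q.size_particles(records, cfg)
        results.append(q.stub_concentration(sized, area, occ, cfg))

    for enabled, name in ((True, "concentrations.csv"), (False, "concentrations_uncorrected.csv")):
        corrected, stats = q.blank_correct(results, occasions, enabled=enabled)
        q.results_to_frame(corrected).to_csv(RESULTS / name, index=False)
        if enabled:
            pd.DataFrame([vars(s) for s in stats]).to_csv(RESULTS / "blank_stats.csv", index=False)
            tw_rows = []
            samples = [r for r in corrected if occ_by_id[r.occasion_id].role == "sample"]
            for surface in ("PC", "CT"):
                rows = [r for r in samples if occ_by_id[r.occasion_id].surface == surface]
                tw = q.time_weighted_mean(rows, occasions)
                tw_rows.append({"surface": surface, "pm25_mg_per_m3": tw["pm2.5"],
                                "pm10_mg_per_m3": tw["pm10"], "total_hours": tw["total_hours"]})
                print(f"{surface}: time-weighted PM2.5 {tw['pm2.5']:.4f}, "
                      f"PM10 {tw['pm10']:.4f} mg/m3 over {tw['total_hours']:.0f} h")
            pd.DataFrame(tw_rows).to_csv(RESULTS / "time_weighted_means.csv", index=False)

    print(f"tables -> {RESULTS}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
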