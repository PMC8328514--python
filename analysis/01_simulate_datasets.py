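#!/usr/bin/env python
"""Generate the synthetic study datasets.

Emulated inputs for every downstream stage, each with a ground-truth
manifest: SEC traces for the full-length wild type and the N359/P354
C-terminal truncations, a wild-type blot lane, a symmetric-dimer frame
series with planted contacts and a 30 degree TM7 tilt, a DSF melt curve,
and an NaCl turbidity series.  Everything is seeded, so rerunning this
script reproduces the files byte for byte.
"""

from pathlib import Path

import pandas as pd

from a2aolig import chromatography as ch
from a2aolig import structure_io as sio
from a2aolig import synthetic as syn

SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    for preset, planted in syn.SEC_STUDY_PRESETS.items():
        trace, truth = syn.gen_chromatogram(
            seed=SEED, label=preset,
            areas={"HMW": planted["hmw_level"], "DIMER": planted["dimer_level"],
                   "MONOMER": 1.0})
        ch.write_chromatogram(trace, OUT / f"sec_{preset}.csv")
        truth.to_json(OUT / f"sec_{preset}.manifest.json")
        print(f"SEC trace {preset}: planted dimer level "
              f"{truth['levels']['dimer_level']:.2f}")

    lane, truth = syn.gen_lane_profile(seed=SEED)
    pd.DataFrame({"position": lane.position, "intensity": lane.intensity}).to_csv(
        OUT / "blot_wt.csv", index=False, float_format="%.10g")
    truth.to_json(OUT / "blot_wt.manifest.json")
    print(f"blot lane: planted dimer level {truth['dimer_level']:.2f}")

    frames, truth = syn.gen_dimer_frames(
        seed=SEED, cluster_sizes=[5, 3, 2], tilt_plan={"TM7": 30.0})
    sio.write_dimer_frames(frames, OUT / "dimer_frames.pdb")
    sio.write_annotation(OUT / "dimer_annotation.toml")
    truth.to_json(OUT / "dimer_frames.manifest.json")
    print(f"dimer frames: {len(frames)} frames, planted clusters "
          f"{truth['cluster_sizes']}, contacts {truth['counts']}")

    curve, truth = syn.gen_melt_curve(seed=SEED)
    pd.DataFrame({"temperature_C": curve.temperature_C,
                  "fluorescence": curve.fluorescence}).to_csv(
        OUT / "dsf_cterm.csv", index=False, float_format="%.10g")
    truth.to_json(OUT / "dsf_cterm.manifest.json")
    print(f"DSF curve: planted Tm {truth['tm']} C, quench {truth['quench_T']} C")

    series, truth = syn.gen_turbidity_series(seed=SEED)
    pd.DataFrame({"ionic_strength_M": series.ionic_strength_M,
                  "a450": series.a450}).to_csv(
        OUT / "turbidity_nacl.csv", index=False, float_format="%.10g")
    truth.to_json(OUT / "turbidity_nacl.manifest.json")
    print(f"turbidity series: aggregation step at {truth['step_at']} M")


if __name__ == "__main__":
    main()
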