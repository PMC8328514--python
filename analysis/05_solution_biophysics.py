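#!/usr/bin/env python
"""Solution-biophysics report.

Computes the ionic strengths of the three running buffers, the Debye
screening length at the working conditions, the DSF melt/quench
temperatures of the isolated C-terminal peptide, and the turbidity-based
aggregation states across NaCl concentrations.
"""

import json
from pathlib import Path

import pandas as pd

from a2aolig import solution as sol
from a2aolig.solution import BufferComposition

ROOT = Path(__file__).resolve().parents[1] / "results"

BUFFERS = {
    "low": {"NaCl": 0, "NaH2PO4": 4, "Na2HPO4": 49},
    "mid": {"NaCl": 300, "NaH2PO4": 4, "Na2HPO4": 49},
    "high": {"NaCl": 800, "NaH2PO4": 4, "Na2HPO4": 49},
}


def main() -> None:
    report = {}

    rows = []
    for name, components in BUFFERS.items():
        buf = BufferComposition.from_components(components, temperature_C=4.0)
        I_mM = sol.ionic_strength(buf)
        rows.append({"buffer": name, **components,
                     "ionic_strength_mM": I_mM,
                     "ionic_strength_M": round(I_mM / 1000.0, 2),
                     "debye_length_A": sol.debye_length(I_mM / 1000.0, 277.15)})
    buffers = pd.DataFrame(rows)
    buffers.to_csv(ROOT / "buffer_table.csv", index=False, float_format="%.6g")
    print(buffers.to_string(index=False))
    report["buffers"] = rows

    kappa_inv = sol.debye_length(0.34, 277.15)
    print(f"Debye length at 0.34 M, 4 C: {kappa_inv:.2f} A "
          f"(rounds to {round(kappa_inv)} A) - electrostatic bonds beyond "
          "~5 A are screened at this ionic strength")
    report["debye_0p34M_4C_A"] = kappa_inv

    df = pd.read_csv(ROOT / "data" / "dsf_cterm.csv")
    curve = sol.melt_derivative(sol.MeltCurve(df.iloc[:, 0].to_numpy(),
                                              df.iloc[:, 1].to_numpy()))
    tm, quench = sol.detect_melt_events(curve)
    manifest = json.loads((ROOT / "data" / "dsf_cterm.manifest.json").read_text())
    print(f"DSF: Tm {tm} C, quench onset {quench} C "
          f"(planted {manifest['tm']} / {manifest['quench_T']})")
    report["dsf"] = {"tm_C": tm, "quench_T_C": quench}

    df = pd.read_csv(ROOT / "data" / "turbidity_nacl.csv")
    series = sol.TurbiditySeries(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())
    states = sol.classify_aggregation(series)
    print("turbidity states:",
          ", ".join(f"{c:g} M -> {s}" for c, s in
                    zip(series.ionic_strength_M, states)))
    report["turbidity"] = dict(zip(map(float, series.ionic_strength_M), states))

    (ROOT / "solution_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    print(f"wrote {ROOT / 'solution_report.json'}")


if __name__ == "__main__":
    main()
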