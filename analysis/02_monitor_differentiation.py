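"""Monitor edge-cell coverage in control vs differentiation-stimulated
cultures and find the earliest sustained statistical separation.

Thirty-six random fields of view are sampled per arm every 30 minutes;
the treated arm receives the differentiation stimulus at 3 h.  A Welch
t-test per timepoint with a 3-frame sustain rule gives the separation
time.  Writes the per-timepoint summary to results/separation.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from colonypat import scenarios as sc
from colonypat import separation_time

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 2


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    times, control, treated = sc.monitoring_series(seed=SEED)
    res = separation_time(control, treated, times, alpha=0.05, sustain=3)
    table = pd.DataFrame(
        {
            "time_h": times,
            "control_mean_edge_pct": control.mean(axis=1),
            "treated_mean_edge_pct": treated.mean(axis=1),
            "p_value": res.p_values,
        }
    )
    table.to_csv(RESULTS / "separation.csv", index=False)
    print(table.round(4).to_string(index=False))
    print(f"\nstimulus applied at {sc.MONITORING_ONSET_H} h;"
          f" sustained separation (p <= 0.05, 3 frames) at {res.separation_time_h} h")
    print(f"detection lag: {res.separation_time_h - sc.MONITORING_ONSET_H:.1f} h with "
          f"{control.shape[1]} images per timepoint")


if __name__ == "__main__":
    main()
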