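"""Relate initial colony size to the differentiation response, and compare
diameter-triggered stimulation at 300 um vs 750 um.

A nine-colony population straddling the 400 um core-retention threshold
is stimulated at t=0 and followed for 30 h through the full pipeline
(classify, segment, track).  Separately, growing cultures are stimulated
when their measured mean colony diameter crosses 300 um or 750 um, and
the post-trigger edge-response slope is compared.  Writes
results/size_response.csv and results/trigger_response.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from colonypat import (
    build_default_library,
    response_rate,
    size_response,
    track_colonies,
)
from colonypat import scenarios as sc

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 4


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    library = build_default_library(200, seed=1)

    spec = sc.size_response_population(seed=SEED)
    n_frames = int(sc.POPULATION_HORIZON_H / spec.frame_interval_h) + 1
    frames, _ = sc.classified_population_series(spec, library, seed=SEED, n_frames=n_frames)
    tracks = track_colonies(frames)
    result = size_response(tracks, 0.0, sc.POPULATION_HORIZON_H)
    result.table.to_csv(RESULTS / "size_response.csv", index=False)
    print(result.table.round(1).to_string(index=False))
    print(f"\nPearson r = {result.pearson_r:.3f} "
          f"(slope {result.slope_pct_per_um:.3f} %/um): the smaller the colony,")
    print("the larger the fraction converting to edge morphology; colonies above")
    print("the retention threshold keep an unconverted core.")

    rows = []
    for threshold in (300.0, 750.0):
        trig, times, edge = sc.run_triggered_differentiation(threshold, library, seed=SEED)
        slope = response_rate(times, edge, times[0], sc.TRIGGER_RESPONSE_WINDOW_H)
        rows.append({"threshold_um": threshold, "trigger_time_h": trig.trigger_time_h,
                     "response_slope_pct_per_h": slope,
                     "final_edge_pct_of_cells": edge[-1]})
        print(f"\ntrigger at {threshold:.0f} um fired at {trig.trigger_time_h} h; "
              f"edge response slope {slope:.2f} %/h")
    pd.DataFrame(rows).to_csv(RESULTS / "trigger_response.csv", index=False)
    print("\nthe small-diameter trigger produces the faster, more complete response.")


if __name__ == "__main__":
    main()
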