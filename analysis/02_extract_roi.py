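"""Render thermograph stacks and recover traces through ROI extraction.

For one animal per group, renders a full synthetic thermograph stack
(Gaussian hotspot on a body footprint, camera noise, quantization), locates
the 30-pixel hotspot ROI at the global spatiotemporal maximum, reduces each
frame to the ROI mean ± SD, and verifies that fitting the extracted trace
recovers the generating time constant. Writes the extracted traces under
results/.
"""

from pathlib import Path

import pandas as pd

from pttherm.io import write_results, write_traces
from pttherm.kinetics import FitOptions, fit_first_order
from pttherm.roi import locate_roi, roi_trace
from pttherm.synth import SceneSpec, animal_seed, default_paper_params, simulate_stack

SEED = 1
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    scene = SceneSpec(exposure_s=90.0, pre_exposure_s=5.0)
    rows, traces = [], []
    for g in default_paper_params():
        aid = f"{g.wavelength}nm_{g.injection}_stack"
        stack = simulate_stack(g, scene=scene, animal_id=aid,
                               seed=animal_seed(SEED, g.wavelength, g.injection, 0))
        roi = locate_roi(stack, diameter_px=30)
        trace = roi_trace(stack, roi)
        trace.group = g.group
        traces.append(trace)
        fit = fit_first_order(trace, FitOptions(exposure_s=90.0))
        rows.append({
            "animal_id": aid, "roi_center": str(roi.center), "roi_pixels": roi.n_pixels,
            "hotspot_true": str(stack.truth["hotspot_center"]),
            "tau_true": stack.truth["tau"], "tau_fitted": fit.tau_hat,
            "tau_rel_err": abs(fit.tau_hat - stack.truth["tau"]) / stack.truth["tau"],
        })
    table = pd.DataFrame(rows)
    write_traces(traces, OUT / "extracted_traces.csv")
    write_results(table, OUT / "roi_recovery.csv")
    print(table.to_string(index=False))
    print(f"\nworst tau recovery error: {table.tau_rel_err.max():.3%} "
          "(ROI averaging preserves the time constant)")


if __name__ == "__main__":
    main()
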