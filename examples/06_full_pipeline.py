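"""One-click run of the whole pipeline on a tiled device phantom.

Generates tiles with a simulated implanted-device void, then runs mosaic ->
enhance -> segment -> classify -> trace -> morpho from a single config, with
every stage's parameters and status logged to the run record.
"""

import pandas as pd

from microtrace.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    output_dir="scratch/example_run", seed=7,
    params={
        "phantom": dict(shape=(20, 72, 72), tile_grid=(2, 2), overlap=0.25,
                        tile_shifts=[[0, 0, 0], [0, 2, -1], [0, -1, 2], [0, 1, 1]],
                        cell_counts={"microglia": 3, "astrocyte": 4, "neuron": 4},
                        device_box=((0, 20), (0, 10), (0, 72))),
        "enhance": dict(median_radius=1, curvelet=True, tile=64),
        "segment": dict(dice=(20, 40, 40), pad=8, sigma_range_um=(1.0, 3.0)),
        "classify": dict(budget=20),
        "trace": dict(max_arbor_um=15, margin_um=5, max_link_cost=8.0,
                      candidate_percentile=92),
        "morpho": dict(k=2),
    })

record = run_pipeline(cfg)
for e in record.entries:
    print(f"{e['stage']:10s} {e['status']:4s} {e['outputs']}")

forest = pd.read_csv("scratch/example_run/traces/forest.csv")
print("\ntraced microglia forest:")
print(forest.to_string(index=False))
# Re-running with the same config and seed reproduces every output file
# byte for byte; the run record in logs/ snapshots each stage's parameters.
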