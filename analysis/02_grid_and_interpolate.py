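"""Rasterize the panel to 100 km cells, interpolate Modified Shepard
surfaces and build the constant-quality emission indices.

Adds cells.csv, aggregates.csv, surfaces.csv, indices.csv,
regional_series.csv and index_changes.csv to results/run/; prints the
1998 -> 2012 percent change of each pollutant's nationwide index.
"""

import logging

import pandas as pd

from pollugrid.pipeline import run_pipeline

logging.basicConfig(level="INFO", format="%(message)s")

if __name__ == "__main__":
    from importlib import import_module
    CONFIG = import_module("01_simulate").CONFIG
    run_pipeline(CONFIG, stages=["grid", "interpolate", "index"])
    changes = pd.read_csv("results/run/index_changes.csv")
    print("\nindex percent change 1998 -> 2012 (All cells):")
    print(changes[changes.region == "All"]
          [["pollutant", "pct_change"]].to_string(index=False))
    print("\nby region:")
    print(changes.pivot(index="pollutant", columns="region",
                        values="pct_change").round(1).to_string())
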