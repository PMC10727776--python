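#!/usr/bin/env python
"""Temporal-network link metrics over the threshold sweep.

Builds the state-driven temporal network from the simulated cohort,
binarizes it over 10 thresholds spanning 1-10% of the maximum FC weight,
and writes per-link burstiness/activation metrics plus the zone-class
medians under results/temporal/.
"""

import warnings
from pathlib import Path

import metadfc as m
from metadfc.states import build_temporal_network, fit_states, standardize_and_concatenate
from metadfc.temporal import metrics_table, threshold_grid

BASE = Path(__file__).resolve().parents[1] / "results"
SEED = 2


def main() -> None:
    sessions, atlas = m.read_cohort(BASE / "data" / "states" / "manifest.csv")
    out = BASE / "temporal"
    out.mkdir(parents=True, exist_ok=True)

    frames = standardize_and_concatenate(sessions)
    model = fit_states(frames, 4, n_init=100, seed=SEED, atlas=atlas)
    tnet = build_temporal_network(model)
    thetas = threshold_grid(tnet.state_link_weights, n_points=10)
    print(f"threshold grid: {thetas.min():.4f} .. {thetas.max():.4f} "
          f"(MAX FC weight = {tnet.state_link_weights.max():.3f})")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = metrics_table(tnet, thetas, atlas)
    table.to_csv(out / "link_metrics.tsv", sep="\t", index=False, float_format="%.6g")

    med = table.groupby("zone_class")[["beta", "mu", "tau", "memory"]].median()
    med.to_csv(out / "zone_medians.tsv", sep="\t")
    print("zone-class medians:")
    print(med.round(3))
    print("interzone links are more intermittent: higher beta, lower tau/mu "
          "than intrazone links"
          if med.loc["interzone", "beta"] > med.loc["intrazone", "beta"]
          else "WARNING: expected zone ordering not observed")


if __name__ == "__main__":
    main()
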