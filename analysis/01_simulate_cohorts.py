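#!/usr/bin/env python
"""Generate the three synthetic cohorts used by the downstream analyses.

Writes, under results/data/:
* ``states/``    — 20 subjects x 208 frames from the four-state two-zone
                   Markov-switching model (ground-truth frame labels kept);
* ``entangled/`` — 10 subjects x 2000 frames with two disjoint covariance
                   modulators (planted MC modules and genuine trimers);
* ``graded/``    — 4 groups x 10 subjects x 1000 frames with progressively
                   more intermittent and decoupled interzone gating.
"""

import json
from pathlib import Path

import metadfc as m

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 1


def main() -> None:
    cfg = m.make_default_two_zone_model()
    sessions, labels = m.generate_bold_cohort(cfg, 20, 208, seed=SEED)
    m.write_cohort(
        sessions, cfg.atlas, OUT / "states",
        ground_truth={"state_labels": {s.subject_id: l for s, l in zip(sessions, labels)}},
    )
    print(f"states cohort: {len(sessions)} subjects x {sessions[0].n_frames} frames "
          f"-> {OUT / 'states'}")

    ccfg = m.make_default_entangled_model()
    sessions, truth = m.generate_entangled_bold(ccfg, 10, 2000, seed=SEED)
    m.write_cohort(sessions, ccfg.atlas, OUT / "entangled", ground_truth=truth)
    print(f"entangled cohort: {len(sessions)} subjects, "
          f"{len(truth['genuine_trimers'])} planted genuine trimers, "
          f"{len(set(truth['modules'].values()))} planted MC modules")

    sessions, truth = m.generate_graded_cohorts(10, 1000, seed=SEED)
    slim = {k: v for k, v in truth.items() if k != "gates"}
    m.write_cohort(sessions, m.default_limbic_atlas(), OUT / "graded", ground_truth=slim)
    print(f"graded cohort: groups {truth['groups']}, gate duration shapes "
          f"{truth['shapes']}, agreement fractions {truth['agreement']}")


if __name__ == "__main__":
    main()
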