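#!/usr/bin/env python
"""Generate the synthetic study cohort.

Emulates the data-collection protocol: every subject walks one minute per
emotion condition (neutral / happy / angry) with the accelerometer at
each wear site (wrist / ankle), recorded at 5 samples/s → 300 triaxial
samples per recording.  Writes the cohort in the long-form recording
format plus a generation-parameters sidecar.
"""
import json
from pathlib import Path

import emogait as eg

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 1
N_SUBJECTS = 40


def main() -> None:
    cfg = eg.CohortConfig(n_subjects=N_SUBJECTS, seed=SEED)
    recordings = eg.generate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    path = eg.write_recordings(recordings, OUT / "recordings.csv")
    (OUT / "generation_params.json").write_text(
        json.dumps(
            {
                "n_subjects": cfg.n_subjects,
                "sites": list(cfg.sites),
                "duration_s": cfg.duration_s,
                "sampling_rate": cfg.sampling_rate,
                "effect_scale": cfg.effect_scale,
                "seed": cfg.seed,
            },
            indent=2,
        )
        + "\n"
    )
    print(f"wrote {len(recordings)} recordings "
          f"({cfg.n_subjects} subjects x {len(cfg.sites)} sites x 3 emotions), "
          f"{len(recordings[0])} samples each -> {path}")


if __name__ == "__main__":
    main()
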