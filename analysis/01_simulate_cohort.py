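#!/usr/bin/env python
"""Generate a synthetic study cohort and report its protocol bookkeeping.

Writes one CSV + JSON sidecar per subject under scratch/data/ (large,
regenerable at will) and prints the sample accounting that the protocol
implies: 400 samples per 40 s session at 10 Hz, 7 sessions per trial,
14,000 samples for a 5-trial subject.
"""

from pathlib import Path

from fmgforce import BandLayout, CouplingModel, ProtocolConfig, generate_subject, save_dataset

OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"
N_SUBJECTS = 3
SEED = 2026


def main() -> None:
    cfg = ProtocolConfig()  # the full 5-trial protocol
    layout = BandLayout()
    for s in range(N_SUBJECTS):
        subject_seed = SEED + 1000 * s
        coupling = CouplingModel.default(layout, seed=subject_seed + 1)
        ds = generate_subject(cfg, coupling, layout, seed=subject_seed)
        path = save_dataset(ds, OUT / f"subject_{s + 1:02d}.csv")
        print(
            f"subject {s + 1}: {ds.n_samples} samples "
            f"({cfg.n_trials} trials x 7 sessions x {cfg.samples_per_session}), "
            f"{ds.n_channels} channels -> {path}"
        )
    print(f"\ncohort of {N_SUBJECTS} subjects written under {OUT}")


if __name__ == "__main__":
    main()
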