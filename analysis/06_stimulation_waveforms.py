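#!/usr/bin/env python
"""Synthesize the stimulation protocols and verify them from raw samples.

Active: 6 Hz theta carrier at 2 mA peak-to-peak with 80 Hz, 0.9 mA
peak-to-peak six-cycle gamma bursts on every theta peak (peak-coupled
phase-amplitude coupling), 15 s fades.  Sham: two 90 s ramp blocks
around an 85 Hz, 50 uA carrier.  The verifier re-measures every
parameter from the samples alone.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from tacstrial import waveform
from tacstrial.pipeline import dump_json

OUT = Path("results/waveforms")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    active = waveform.synthesize_active(
        waveform.WaveformSpec(duration_s=300.0, sample_rate=10_000.0)
    )
    rep = waveform.verify_signal(active)
    sham = waveform.synthesize_sham(
        waveform.ShamSpec(
            duration_s=1200.0,
            sample_rate=2000.0,
            active=waveform.WaveformSpec(sample_rate=2000.0),
        )
    )
    srep = waveform.verify_sham(sham)

    dump_json(
        {
            "active": rep.__dict__,
            "sham": srep.__dict__,
            "schedule_minutes": waveform.total_stimulation_minutes(),
        },
        OUT / "verification.json",
    )

    fig, axes = plt.subplots(2, 1, figsize=(9, 5))
    i0 = int(60 * active.sample_rate)
    n = int(0.5 * active.sample_rate)
    axes[0].plot(active.times[i0 : i0 + n], active.samples[i0 : i0 + n], lw=0.7)
    axes[0].set_title("active theta-gamma (0.5 s, steady state)")
    axes[0].set_ylabel("mA")
    step = 50
    axes[1].plot(sham.times[::step], sham.samples[::step], lw=0.4)
    axes[1].set_title("sham protocol (full 20 min, decimated)")
    axes[1].set_ylabel("mA")
    axes[1].set_xlabel("s")
    fig.tight_layout()
    fig.savefig(OUT / "waveforms.png", dpi=120)

    print(
        f"active: {rep.theta_freq_hz:.2f} Hz theta {rep.theta_amp_pp:.2f} mA pp, "
        f"{rep.gamma_freq_hz:.1f} Hz gamma {rep.gamma_amp_pp_max:.2f} mA pp, "
        f"{rep.cycles_per_burst:.0f} cycles/burst, "
        f"peak-coupled: {rep.peak_coupled}"
    )
    print(
        f"sham: blocks {srep.block_durations_s[0]:.0f}s + "
        f"{srep.block_durations_s[1]:.0f}s, interior "
        f"{srep.interior_freq_hz:.1f} Hz at {1000 * srep.interior_amp_pp:.0f} uA pp"
    )
    print(f"schedule: {waveform.total_stimulation_minutes():.0f} min over 16 sessions")


if __name__ == "__main__":
    main()
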