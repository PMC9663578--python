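#!/usr/bin/env python
"""Generate the five archetype specimen panels used by the downstream
gating demonstration.

Event-level CSVs are large, so they go under scratch/; the per-panel
ground truth is printed here and summarized again by 02_gate_panels.py.
"""

from pathlib import Path

from hxfacs.simulate import _PRESETS, preset_panel, truth_active_share, write_panel

OUT = Path(__file__).resolve().parents[1] / "scratch" / "panels"
SEED = 1
N_EVENTS = 20_000   # per tube; surgical specimens yield ~1e5-1e6, biopsies ~1e4


def main() -> None:
    print(f"writing panels to {OUT} (seed={SEED}, {N_EVENTS} events/tube)")
    for i, archetype in enumerate(sorted(_PRESETS)):
        panel = preset_panel(archetype, seed=SEED + i, n_events=N_EVENTS)
        manifest = write_panel(panel, OUT)
        share = truth_active_share(panel)
        print(f"  {archetype:<18} truth active-tumor share = {share:6.1%}  -> {manifest.name}")


if __name__ == "__main__":
    main()
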