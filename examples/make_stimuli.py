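"""Render the three stimulus templates and a full run's artifacts.

Writes the upright/inverted/rotated templates as PGM images, then runs a
short (two-saccade) visual search through the scenario runner, which
drops tidy CSVs, salience-map images, a JSON summary and figure panels
into an output directory.
"""

from actinf.runner import RunConfig, make_stimuli, report, simulate

stimuli = make_stimuli("outputs/stimuli")
print("templates written:")
for p in stimuli:
    print("  ", p)

manifest = simulate(RunConfig(
    experiment="visual-search", scenario="fig3-default", seed=1,
    output_dir="outputs/demo-run", overrides={"schedule.n_saccades": 2},
))
print("\nrun artifacts:", ", ".join(manifest["artifacts"]))

panels = report("outputs/demo-run")
print("figure panels:", ", ".join(p.split("/")[-1] for p in panels))
print()
print("Re-running with the same seed and scenario reproduces every CSV")
print("byte for byte.")
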