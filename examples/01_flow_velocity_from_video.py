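"""Track the wet front of a paper-chip flow video and estimate velocity.

Builds a small synthetic video with a known flow velocity (2 px/frame), a
pre-flow idle period and two corrupted frames, then runs the full chain:
front detection → profile cleanup → onset shift → windowed OLS velocity.
"""

from atflow import FlowVideoSpec, analyze_video
from atflow.synthetic import generate_flow_video

spec = FlowVideoSpec(
    n_frames=60,
    idle_frames=8,          # the chip sits dry for 8 frames before loading
    corrupt_frames=(20, 21),  # two glitched frames mid-flow
    channel_length_px=150,
)
stack, truth = generate_flow_video(spec, v=2.0, seed=0)

estimate, profile = analyze_video(stack, spec.geometry(), window_frames=35)

print(f"flow onset detected at frame {profile.f0} (planted: {spec.idle_frames})")
print(f"frames removed by cleanup:   {profile.provenance} (planted: [20, 21])")
print(f"velocity estimate:           {estimate.velocity:.6f} px/frame (planted: 2.0)")
print(f"per-line slopes:             {[round(s, 4) for s in estimate.per_line]}")
print(f"fitting window:              first {estimate.window[1]} frames "
      f"= {estimate.window_seconds:.2f} s at {estimate.fps:.0f} fps")
# The velocity is the mean OLS slope of front distance vs frame over the
# four measurement lines; with no positional jitter it recovers the planted
# velocity exactly, and the corrupted frames are excluded automatically.
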