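"""Generate a labeled synthetic two-agent behavior video and inspect it.

The generator renders two Gaussian-ellipse "animals" in a dark arena whose
motion follows a 3-state Markov ethogram (idle / chase / contact).  Frames,
per-frame state labels and agent centroid tracks come back together, so
every downstream stage can be scored against ground truth.
"""

import numpy as np

from selfee.synthetic import default_two_agent_script, generate_scene_video

script = default_two_agent_script(duration=2000, seed=7, arena_size=96)
scene = generate_scene_video(script, arena=(96, 96))

freq = np.bincount(scene.labels, minlength=3) / len(scene.labels)
dist = np.linalg.norm(scene.agent_tracks[:, 0] - scene.agent_tracks[:, 1], axis=1)

print(f"frames: {scene.frames.shape}, dtype {scene.frames.dtype}")
for name, f in zip(scene.state_names, freq):
    print(f"state {name!r}: {f:.1%} of frames")
for name in scene.state_names:
    idx = scene.labels == scene.state_names.index(name)
    print(f"mean inter-agent distance in {name!r}: {dist[idx].mean():.1f} px")

# The three states occupy the chain's stationary shares, and the mean
# inter-agent distance separates them (idle far, chase moderate, contact ~0),
# which is what makes the scenes learnable without labels.
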