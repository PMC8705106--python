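"""Parse OpenPose keypoint JSON and convert COCO indexing to the H3.6M subset."""

from gaitid.skeleton import coco_to_h36m, h36m_column, parse_openpose_json
from gaitid.synthetic import WalkerParams, generate_walk, openpose_json_frames

# project a synthetic walker to OpenPose-style 2D documents (stand-in for
# real detector output)
seq, _ = generate_walk(WalkerParams(seed=3), n_strides=2, fps=25.0)
doc = openpose_json_frames(seq)[0]

frames = parse_openpose_json(doc)
f = frames[0]
print(f"parsed {len(frames)} person(s); scheme {f.scheme.value}, "
      f"{f.joints.shape[0]} joints")
print(f"COCO nose (index 0): x={f.joints[0, 0]:.1f}px y={f.joints[0, 1]:.1f}px "
      f"conf={f.joints[0, 2]:.2f}")

h = coco_to_h36m(f)
hip_center = h.joints[h36m_column(0)]
spine = h.joints[h36m_column(12)]
print(f"H3.6M hip center (synthesized as hip midpoint): "
      f"({hip_center[0]:.1f}, {hip_center[1]:.1f})")
print(f"H3.6M spine (midpoint of hip center and thorax): "
      f"({spine[0]:.1f}, {spine[1]:.1f})")

# The converted frame carries the 17 H3.6M joints a 2D-to-3D lifting network
# expects; synthesized joints get the minimum confidence of their sources.
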