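"""Build a seeded randomized 8 x 60K-style array layout with embedded controls.

Places biological probes, 20 replicate probes (10 copies each) and the
control manifest (spike-in series, stringency probes, corner markers) on one
subarray, then shows the class arithmetic.
"""

import numpy as np

from carpoligo.layout import LayoutSpec, build_layout
from carpoligo.probe_design import ProbeRecord

rng = np.random.default_rng(1)
probes = [
    ProbeRecord(
        f"CP{i:06d}", f"g{i}", f"g{i}.t1",
        "".join(rng.choice(list("ACGT"), size=60)), 0, "designed",
    )
    for i in range(1, 2001)
]

spec = LayoutSpec(subarrays=1, seed=17)  # 62,976 features, 1,319 controls
layout = build_layout(probes, spec)
counts = layout.class_counts(0)

print(f"features per subarray : {len(layout.subarrays[0])}")
for cls, n in sorted(counts.items()):
    print(f"  {cls:<11}: {n}")
non_control = counts["biological"] + counts["replicate"]
print(f"non-control positions : {non_control} (= 62,976 - 1,319)")
print()
print("Replicate probes appear exactly 10x each; the remaining capacity is")
print("filled round-robin with biological probes; the same seed reproduces")
print("the layout byte for byte.")
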