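"""Generate a small synthetic cohort of arena recordings and read it back.

Builds 2-minute trajectories for two castes at two group sizes (real
recordings are 51 min at 5 Hz; shortened here so the example runs in
seconds), writes one CSV per individual plus a manifest, then re-reads
and preprocesses one file.
"""

import tempfile
from pathlib import Path

from termwalk import Arena, CohortGroup, WalkSpec, make_cohort, preprocess, read_trajectory

out = Path(tempfile.mkdtemp(prefix="termwalk_cohort_"))

queen_spec = WalkSpec(model="TPL", mu=1.36, l_min=0.5, l_max=90.0,
                      duration_s=120.0, gap_prob=0.002)
worker_spec = WalkSpec(model="TPL", mu=1.08, l_min=0.5, l_max=90.0,
                       duration_s=120.0, gap_prob=0.002)

groups = [
    CohortGroup("queen", 1, 3, queen_spec),
    CohortGroup("worker", 1, 3, worker_spec),
    CohortGroup("queen", 100, 3, queen_spec),
    CohortGroup("worker", 100, 3, worker_spec),
]
manifest = make_cohort(groups, out, seed=42, arena=Arena())
print(f"wrote {len(manifest)} trajectory files to {out}")
print(manifest[["id", "caste", "N", "model", "seed"]].to_string(index=False))

traj = read_trajectory(out / manifest.iloc[0]["file"], rate_hz=5.0,
                       arena=Arena(), caste=manifest.iloc[0]["caste"])
print(f"\n{traj.id}: {len(traj)} samples, {traj.n_gaps} tracking gaps")
clean = preprocess(traj)
print(f"after gap interpolation: {clean.n_gaps} gaps remain "
      f"({clean.duration_s:.0f} s of continuous positions)")
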