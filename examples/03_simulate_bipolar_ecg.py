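"""Simulate the QRS complex for all 35 diagonal bipolar chest leads.

A dipole marches along the ventricular conduction system (A-V node -> His ->
branches -> two Purkinje trees); each dipole's surface potential map is
solved once and sampled at every electrode, and the bipolar samples are
assembled into waveforms on a uniform 1 ms grid.
"""

import numpy as np

import ecgforge as ef
from ecgforge.phantom import coarse_geometry

vol = ef.build_phantom(coarse_geometry(8.0))
seq = ef.build_path(vol, ef.default_path_spec(vol.heart_centroid_mm()))
print(f"conduction path: {len(seq)} dipoles, QRS duration {seq.duration_s * 1e3:.1f} ms")

sys = ef.assemble(vol, ef.default_tissue_table())
cfg = ef.SolverConfig(method="multigrid_preconditioned", tolerance=1e-6)
fields = ef.solve_sequence(sys, seq, cfg)

grid = ef.place_grid(vol)
pairs = ef.lead_pairs(grid)
print(f"{len(pairs)} bipolar pairs, inter-electrode distance "
      f"{np.mean([p.distance_mm for p in pairs]):.0f} mm on average")

rows = []
for pair in pairs:
    w = ef.assemble_waveform(fields, pair)
    g = ef.pair_geometry(vol, seq, pair)
    rows.append((pair.pair_id, w.sa * 1e3, g.d_mm, g.theta_deg))

rows.sort(key=lambda r: -r[1])
print("\nstrongest five leads (SA = |Vmax - Vmin|):")
print("pair    SA(mV)   d(mm)  theta(deg)")
for pid, sa, d, th in rows[:5]:
    print(f"{pid}   {sa:6.3f}  {d:6.1f}   {th:6.1f}")
# the largest amplitudes cluster over the heart (small mean heart-electrode
# distance d, large subtended angle theta) — the geometric mechanism that
# drives electrode-placement recommendations.
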