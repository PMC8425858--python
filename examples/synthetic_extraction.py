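"""Round trip: synthetic dose-rate tables -> TG-43 parameter extraction.

Builds tally tables from a known ground truth (the published values of this
source), adds realistic per-voxel noise, runs the extraction chain, and
prints recovered vs true parameters -- the calibration exercise behind
every stochastic test in the suite.
"""
import numpy as np

from ybrachy import extract_parameters
from ybrachy.synthetic import (default_ground_truth, generate_air_kerma,
                               generate_dose_table)

gt = default_ground_truth()
table = generate_dose_table(gt, seed=42, noise=0.005)   # 0.5% voxel noise
tally = generate_air_kerma(gt, seed=43, noise=0.002)
ps = extract_parameters(table, tally, gt.i_gamma)

print(f"S_k    : {ps.sk_u_per_mci:.4f} U/mCi   (truth {gt.sk_star})")
print(f"Lambda : {ps.lambda_cgy_per_hu:.4f} cGy/(h U)  (truth {gt.lambda_star})"
      f"  +- {ps.lambda_rel_unc:.1%} (stat + interaction data)")
print("\n r (cm)   g_L(r)   truth")
g = ps.g_table
for r in (0.5, 1.0, 2.0, 5.0, 10.0):
    got = float(g.g[np.isclose(g.r_cm, r)].iloc[0])
    print(f"  {r:5}   {got:.4f}   {float(gt.g_star(r)):.4f}")
print(f"\nfifth-order fit max residual: {ps.poly.max_rel_residual:.2%} "
      f"({'within' if ps.poly.residual_ok else 'beyond'} the 2% planning criterion)")
f = ps.f_table
cell = f[np.isclose(f.r_cm, 1.0) & np.isclose(f.theta_deg, 10.0)]
print(f"F(1 cm, 10 deg) = {float(cell.F.iloc[0]):.3f}  (truth {gt.f_star(1.0, 10.0):.3f})")
print("\nWith the noise switched off the recovery is exact to machine "
      "precision: extraction inverts the generator identically.")
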